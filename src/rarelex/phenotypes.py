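"""Score standardization and phenotype-class assignment.

Test scores arrive on a population scale with mean 100 and SD 15; z-scores
are ``(raw - 100) / 15``. Classification rules, following the published
inclusion criteria literally in their boundary strictness:

* discovery dyslexia case — at least one reading measure at or below -1 SD
  (inclusive) with performance IQ at or above -1 SD;
* RD (reading difficulties) case — follow-up battery (SWR, NWR, ACC, COMP,
  RR): at least one score strictly more than 1 SD below the mean, PIQ >= -1
  SD, and no DAWBA ASD diagnosis;
* TD (typically developing) control — PIQ >= -1 SD, single-word reading
  strictly above the mean, no DAWBA ASD diagnosis;
* mild reading difficulties — at least one reading z strictly below -1, or a
  mean reading z at or below -0.25 (used for relatives in segregation).

Parents are never classified from test scores; their affection status comes
from self-report (see :mod:`rarelex.segregation`).
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Optional

import numpy as np

from .io_formats import IntegrityError
from .model import (
    FOLLOWUP_READING_MEASURES,
    PhenotypeClass,
    PhenotypeProfile,
    Thresholds,
)


class ClassificationError(ValueError):
    """Profile lacks the measures a classification rule requires."""


def to_z(raw: Optional[float], th: Optional[Thresholds] = None) -> Optional[float]:
    """Standardize a raw score: z = (raw - pop_mean) / pop_sd."""
    th = th or Thresholds()
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    return (raw - th.pop_mean) / th.pop_sd


def standardize(profile: PhenotypeProfile, th: Optional[Thresholds] = None
                ) -> PhenotypeProfile:
    """Fill z_scores from raw_scores in place; returns the profile."""
    th = th or Thresholds()
    profile.z_scores = {
        m: to_z(v, th) for m, v in profile.raw_scores.items() if v is not None
    }
    return profile


def _piq_ok(p: PhenotypeProfile, th: Thresholds) -> bool:
    piq = p.z_scores.get("PIQ")
    if piq is None:
        raise ClassificationError(f"{p.individual_id}: PIQ required but missing")
    return piq >= th.z_piq_cut


def classify_discovery_case(p: PhenotypeProfile, th: Optional[Thresholds] = None
                            ) -> bool:
    """Discovery inclusion: min reading z <= -1 (inclusive) and PIQ z >= -1."""
    th = th or Thresholds()
    reading = p.reading_z()
    if not reading:
        raise ClassificationError(
            f"{p.individual_id}: no reading measures to classify"
        )
    worst = min(reading.values())
    low_enough = (worst <= th.z_reading_cut if th.discovery_reading_inclusive
                  else worst < th.z_reading_cut)
    return low_enough and _piq_ok(p, th)


def classify_rd_case(p: PhenotypeProfile, th: Optional[Thresholds] = None) -> bool:
    """Follow-up RD case: PIQ >= -1, a follow-up reading score strictly below
    -1, and no ASD diagnosis."""
    th = th or Thresholds()
    if p.dawba_asd is True:
        return False
    reading = p.reading_z(FOLLOWUP_READING_MEASURES)
    if not reading:
        return False
    return min(reading.values()) < th.z_reading_cut and _piq_ok(p, th)


def classify_td_control(p: PhenotypeProfile, th: Optional[Thresholds] = None) -> bool:
    """Follow-up TD control: PIQ >= -1, SWR strictly above the mean, no ASD."""
    th = th or Thresholds()
    if p.dawba_asd is True:
        return False
    swr = p.z_scores.get("SWR")
    if swr is None:
        raise ClassificationError(f"{p.individual_id}: SWR required but missing")
    return swr > th.z_td_swr_cut and _piq_ok(p, th)


def classify_mild(p: PhenotypeProfile, th: Optional[Thresholds] = None) -> bool:
    """Mild reading difficulties: one reading z < -1, or mean reading z <= -0.25."""
    th = th or Thresholds()
    reading = p.reading_z()
    if not reading:
        raise ClassificationError(
            f"{p.individual_id}: no reading measures to classify"
        )
    zs = list(reading.values())
    return min(zs) < th.z_reading_cut or (sum(zs) / len(zs)) <= th.z_mild_avg_cut


def _followup_qualifies(p: PhenotypeProfile, th: Thresholds) -> bool:
    try:
        return classify_rd_case(p, th) or classify_td_control(p, th)
    except ClassificationError:
        return False


def select_twin(
    pair: tuple[PhenotypeProfile, PhenotypeProfile],
    seed: int,
    qualifies: Optional[Callable[[PhenotypeProfile], bool]] = None,
    th: Optional[Thresholds] = None,
) -> Optional[str]:
    """Pick one twin of a pair for cohort inclusion.

    If exactly one twin meets the inclusion criteria, that twin is chosen;
    if both do, one is chosen uniformly at random, reproducibly from ``seed``
    and the pair id; if neither does, None.
    """
    th = th or Thresholds()
    a, b = pair
    if a.twin_pair_id is None or a.twin_pair_id != b.twin_pair_id:
        raise IntegrityError(
            f"profiles {a.individual_id}/{b.individual_id} are not the same twin pair"
        )
    crit = qualifies or (lambda p: _followup_qualifies(p, th))
    ok_a, ok_b = crit(a), crit(b)
    if not ok_a and not ok_b:
        return None
    if ok_a != ok_b:
        return a.individual_id if ok_a else b.individual_id
    # both qualify: seed a generator from (seed, pair id bytes) so the draw
    # is stable per pair and across runs
    rng = np.random.default_rng([seed % (2**31), *a.twin_pair_id.encode()])
    return a.individual_id if rng.random() < 0.5 else b.individual_id


def classify_profiles(
    profiles: Iterable[PhenotypeProfile], th: Optional[Thresholds] = None
) -> list[PhenotypeProfile]:
    """Standardize and assign a phenotype class to each profile.

    Discovery-cohort members are checked against the discovery case rule;
    follow-up members against RD then TD; relatives against case-then-mild.
    Parents and profiles with no scores stay ``unknown``.
    """
    th = th or Thresholds()
    out = []
    for p in profiles:
        standardize(p, th)
        cls = PhenotypeClass.UNKNOWN
        try:
            if p.role == "parent" or not p.reading_z():
                cls = PhenotypeClass.UNKNOWN
            elif p.cohort == "discovery":
                cls = (PhenotypeClass.CASE if classify_discovery_case(p, th)
                       else PhenotypeClass.UNKNOWN)
            elif p.cohort == "followup":
                if classify_rd_case(p, th):
                    cls = PhenotypeClass.CASE
                elif classify_td_control(p, th):
                    cls = PhenotypeClass.TD
                elif classify_mild(p, th):
                    cls = PhenotypeClass.MILD
                else:
                    cls = PhenotypeClass.UNAFFECTED
            else:  # family relatives
                if classify_discovery_case(p, th):
                    cls = PhenotypeClass.CASE
                elif classify_mild(p, th):
                    cls = PhenotypeClass.MILD
                else:
                    cls = PhenotypeClass.UNAFFECTED
        except ClassificationError:
            cls = PhenotypeClass.UNKNOWN
        p.phenotype_class = cls
        out.append(p)
    return out
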