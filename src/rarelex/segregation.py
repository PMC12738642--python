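"""Pedigree segregation assessment under a dominant model with variable
expressivity.

Children are called affected from the test battery (discovery-case criteria
or mild reading difficulties); parents, who were not formally assessed, from
self-reported reading problems ("maybe" and absent answers are unknown). A
family's pattern for a focal variant is *consistent* with a dominant effect
of variable expressivity when every carrier with known phenotype shows some
form of reading difficulty; a single unaffected carrier makes the pattern
*violated*. Affected non-carriers do not violate — they point to other risk
factors. Families with fewer than two genotyped members of known affection
are *uninformative* rather than vacuously consistent.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Optional

from .model import (
    CarrierStatus,
    Pedigree,
    PhenotypeProfile,
    SegregationPattern,
    SegregationResult,
    SelfReport,
    Thresholds,
)
from .phenotypes import (
    ClassificationError,
    classify_discovery_case,
    classify_mild,
    standardize,
)


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


def member_affection(p: Optional[PhenotypeProfile],
                     th: Optional[Thresholds] = None) -> Affection:
    """Affection status of one family member.

    Children: affected iff they meet the discovery-case criteria or the mild
    reading-difficulties criteria; unaffected iff classifiable and neither.
    Parents: from self-report (yes -> affected, no -> unaffected, maybe or
    missing -> unknown).
    """
    th = th or Thresholds()
    if p is None:
        return Affection.UNKNOWN
    if p.role == "parent":
        return {
            SelfReport.YES: Affection.AFFECTED,
            SelfReport.NO: Affection.UNAFFECTED,
        }.get(p.self_report, Affection.UNKNOWN)
    if not p.z_scores and p.raw_scores:
        standardize(p, th)
    try:
        case = classify_discovery_case(p, th)
    except ClassificationError:
        case = None
    try:
        mild = classify_mild(p, th)
    except ClassificationError:
        mild = None
    if case is None and mild is None:
        return Affection.UNKNOWN
    if case or mild:
        return Affection.AFFECTED
    return Affection.UNAFFECTED


def assess_family(
    ped: Pedigree, variant_key: str, th: Optional[Thresholds] = None
) -> SegregationResult:
    """Classify one family's carrier/phenotype co-occurrence at one variant."""
    th = th or Thresholds()
    counts = {
        (CarrierStatus.CARRIER, Affection.AFFECTED): 0,
        (CarrierStatus.CARRIER, Affection.UNAFFECTED): 0,
        (CarrierStatus.CARRIER, Affection.UNKNOWN): 0,
        (CarrierStatus.NON_CARRIER, Affection.AFFECTED): 0,
        (CarrierStatus.NON_CARRIER, Affection.UNAFFECTED): 0,
        (CarrierStatus.NON_CARRIER, Affection.UNKNOWN): 0,
    }
    n_informative = 0
    for m in ped.members:
        status = ped.carrier_status(m.individual_id, variant_key)
        if status is CarrierStatus.UNKNOWN:
            continue
        aff = member_affection(m.phenotype, th)
        counts[(status, aff)] += 1
        if aff is not Affection.UNKNOWN:
            n_informative += 1

    if counts[(CarrierStatus.CARRIER, Affection.UNAFFECTED)] > 0:
        pattern = SegregationPattern.VIOLATED
    elif n_informative < 2:
        pattern = SegregationPattern.UNINFORMATIVE
    else:
        pattern = SegregationPattern.CONSISTENT
    return SegregationResult(
        family_id=ped.family_id,
        variant_key=variant_key,
        pattern=pattern,
        carrier_affected=counts[(CarrierStatus.CARRIER, Affection.AFFECTED)],
        carrier_unaffected=counts[(CarrierStatus.CARRIER, Affection.UNAFFECTED)],
        carrier_unknown=counts[(CarrierStatus.CARRIER, Affection.UNKNOWN)],
        noncarrier_affected=counts[(CarrierStatus.NON_CARRIER, Affection.AFFECTED)],
        noncarrier_unaffected=counts[(CarrierStatus.NON_CARRIER, Affection.UNAFFECTED)],
        noncarrier_unknown=counts[(CarrierStatus.NON_CARRIER, Affection.UNKNOWN)],
    )


def multi_variant_profile(
    ped: Pedigree, variant_keys: Iterable[str]
) -> dict[str, set]:
    """Per-member sets of carried focal variants (joint-carriage reporting,
    e.g. a proband carrying three risk variants whose sibling shares one)."""
    out: dict[str, set] = {}
    for m in ped.members:
        carried = {
            vk for vk in variant_keys
            if ped.carrier_status(m.individual_id, vk) is CarrierStatus.CARRIER
        }
        out[m.individual_id] = carried
    return out
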