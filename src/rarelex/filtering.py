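"""High-impact variant filtering.

A *high-impact* variant is rare in the reference population (PM2-style:
gnomAD-NFE frequency below 1%, or absent from gnomAD entirely) and predicted
to damage protein function (PP3-style: a unanimous "damaging" verdict from
SIFT, PolyPhen2, LRT, MutationTaster and FATHMM, or an existing ClinVar
pathogenic / likely-pathogenic assertion). Calls additionally pass per-site
quality and per-genotype depth QC. Identical criteria apply to every cohort;
the cohort label only annotates the surviving calls.

Predicates are evaluated in a fixed order (qc -> rare -> consequence ->
damaging) and the first failing predicate of each removed call is recorded
in an exclusion log so the filter's behavior is auditable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .io_formats import IntegrityError
from .model import (
    ClinvarSig,
    CohortLabel,
    ExonicFunc,
    FuncClass,
    GenotypeCall,
    HighImpactCall,
    PredictorCall,
    PREDICTORS,
    Thresholds,
    VariantRecord,
)


def qc_pass(call: GenotypeCall, record: VariantRecord, th: Thresholds) -> bool:
    """Site quality >= min_qual and genotype depth >= min_depth.

    A missing depth fails QC (no evidence the genotype is well supported).
    """
    if record.site_qual < th.min_qual:
        return False
    return call.depth is not None and call.depth >= th.min_depth


def is_rare(record: VariantRecord, th: Thresholds) -> bool:
    """Population frequency below the rarity cutoff.

    A variant absent from gnomAD counts as rare: absence from a large
    reference panel supports rarity (the PM2 rationale) and novel variants
    must survive the filter.
    """
    return record.af_nfe is None or record.af_nfe < th.max_af


def is_consequence_retained(record: VariantRecord) -> bool:
    """Drop synonymous, intronic and intergenic variants; keep the rest."""
    if record.exonic_func is ExonicFunc.SYNONYMOUS:
        return False
    return record.func_class not in (FuncClass.INTRONIC, FuncClass.INTERGENIC)


def is_predicted_damaging(record: VariantRecord) -> bool:
    """Unanimous damaging verdict from all five predictors, or ClinVar P/LP.

    A missing predictor call breaks the five-way consensus (conservative);
    ClinVar pathogenic or likely-pathogenic rescues regardless of predictors.
    """
    if record.clinvar_sig in (ClinvarSig.PATHOGENIC, ClinvarSig.LIKELY_PATHOGENIC):
        return True
    return all(
        record.predictor_calls.get(p) is PredictorCall.DAMAGING for p in PREDICTORS
    )


#: fixed evaluation order of the filter predicates
PREDICATE_ORDER = ("qc", "rare", "consequence", "damaging")


@dataclass
class FilterResult:
    calls: list = field(default_factory=list)  # list[HighImpactCall]
    #: one entry per removed non-reference call: first failing predicate
    exclusion_log: list = field(default_factory=list)

    def exclusion_counts(self) -> Counter:
        return Counter(reason for _, _, reason in self.exclusion_log)


def filter_high_impact(
    records: Iterable[VariantRecord],
    calls: Iterable[GenotypeCall],
    cohort_labels: Mapping[str, CohortLabel],
    th: Optional[Thresholds] = None,
) -> FilterResult:
    """Apply the four filter predicates to every non-reference genotype call.

    Parameters
    ----------
    records
        annotated variants; calls must reference these by variant key.
    calls
        per-sample genotype calls.
    cohort_labels
        individual id -> cohort label; unknown individuals are
        ``unassigned``. Labels only annotate: the same criteria apply to
        every cohort.
    th
        thresholds (defaults reproduce the published cutoffs).
    """
    th = th or Thresholds()
    by_key = {r.variant_key: r for r in records}
    result = FilterResult()
    for call in calls:
        if call.variant_key not in by_key:
            raise IntegrityError(
                f"genotype call references unknown variant {call.variant_key}"
            )
        if not call.is_carrier:
            continue
        record = by_key[call.variant_key]
        reason = first_failing_predicate(call, record, th)
        if reason is None:
            result.calls.append(
                HighImpactCall(
                    individual_id=call.individual_id,
                    variant_key=call.variant_key,
                    gene=record.gene,
                    cohort_label=cohort_labels.get(
                        call.individual_id, CohortLabel.UNASSIGNED
                    ),
                )
            )
        else:
            result.exclusion_log.append(
                (call.individual_id, call.variant_key, reason)
            )
    return result


def first_failing_predicate(
    call: GenotypeCall, record: VariantRecord, th: Thresholds
) -> Optional[str]:
    """Name of the first failing predicate in fixed order, or None if all pass."""
    if not qc_pass(call, record, th):
        return "qc"
    if not is_rare(record, th):
        return "rare"
    if not is_consequence_retained(record):
        return "consequence"
    if not is_predicted_damaging(record):
        return "damaging"
    return None


def per_individual_counts(
    hi_calls: Iterable[HighImpactCall],
    individuals: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Per-individual high-impact variant counts.

    ``individuals`` optionally fixes the denominator (individuals with zero
    surviving calls then appear with count 0). The frame carries the mean in
    ``df.attrs``: ``mean`` (2 decimals), ``mean_rounded`` (nearest integer),
    both None when the table is empty.
    """
    counts = Counter(c.individual_id for c in hi_calls)
    ids = list(individuals) if individuals is not None else sorted(counts)
    df = pd.DataFrame(
        {"individual_id": ids, "count": [counts.get(i, 0) for i in ids]}
    )
    if len(df):
        mean = df["count"].sum() / len(df)
        df.attrs["mean"] = round(mean, 2)
        df.attrs["mean_rounded"] = int(round(mean))
    else:
        df.attrs["mean"] = None
        df.attrs["mean_rounded"] = None
    return df
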