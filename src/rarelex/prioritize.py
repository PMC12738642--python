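"""Recurrence-based gene prioritization across cohorts.

A gene becomes a candidate when high-impact variants are observed in at
least three unrelated discovery cases (the discovery gate — a
recurrence-across-unrelated-individuals criterion in the spirit of the
Genomics England traffic-light system, applied without a formal significance
test). To warrant follow-up the gene must additionally carry at least one
high-impact variant among replication (RD) cases — possibly a different
variant from the discovery ones — while no variant carried by a discovery or
RD case may appear in a typically developing (TD) control. The TD exclusion
is variant-level: a TD-only variant in the same gene does not disqualify,
it is merely flagged.

Carriers are counted as distinct individuals: someone with two qualifying
variants in one gene counts once.
"""

from __future__ import annotations

from typing import Iterable, Optional

from scipy import stats

from .model import CohortLabel, GeneCandidate, HighImpactCall, Thresholds

_COHORT_SLOT = {
    CohortLabel.DISCOVERY: "discovery",
    CohortLabel.RD_CASE: "rd",
    CohortLabel.TD_CONTROL: "td",
}


def count_recurrent_genes(
    hi_calls: Iterable[HighImpactCall],
    th: Optional[Thresholds] = None,
    variant_af: Optional[dict] = None,
) -> list[GeneCandidate]:
    """Build one candidate per gene with at least one high-impact call and
    set the discovery gate from the count of distinct discovery carriers.

    Calls labeled ``relative`` or ``unassigned`` never contribute to carrier
    counts (relatives are reserved for segregation).
    """
    th = th or Thresholds()
    cands: dict[str, GeneCandidate] = {}
    for call in hi_calls:
        cand = cands.setdefault(call.gene, GeneCandidate(gene=call.gene))
        cand.variants.add(call.variant_key)
        if variant_af and call.variant_key in variant_af:
            cand.variant_af[call.variant_key] = variant_af[call.variant_key]
        slot = _COHORT_SLOT.get(call.cohort_label)
        if slot is None:
            continue
        getattr(cand, f"carriers_{slot}").add(call.individual_id)
        getattr(cand, f"variants_{slot}").add(call.variant_key)
        cand.variant_carriers.setdefault(slot, {}).setdefault(
            call.variant_key, set()
        ).add(call.individual_id)
    for cand in cands.values():
        cand.passes_discovery_gate = (
            len(cand.carriers_discovery) >= th.min_discovery_cases
        )
    return sorted(cands.values(), key=lambda c: c.gene)


def apply_followup_gate(
    candidates: Iterable[GeneCandidate],
    th: Optional[Thresholds] = None,
) -> list[GeneCandidate]:
    """Set the follow-up gate on candidates whose carrier sets are filled.

    ``case_variant_in_td`` is true iff any variant carried by a discovery or
    RD case is also carried by a TD control. A gene passes the follow-up
    gate iff it passes the discovery gate, has at least ``min_rd_cases`` RD
    carriers, and the number of TD carriers of case variants does not exceed
    ``max_td_case_variant_carriers`` (zero by default).
    """
    th = th or Thresholds()
    out = []
    for cand in candidates:
        case_variants = cand.variants_discovery | cand.variants_rd
        td_vc = cand.variant_carriers.get("td", {})
        td_case_carriers = set().union(
            *(td_vc.get(v, set()) for v in case_variants)
        ) if case_variants else set()
        cand.case_variant_in_td = (
            len(td_case_carriers) > th.max_td_case_variant_carriers
        )
        cand.flag_td_variant_differs = bool(
            cand.variants_td - case_variants
        )
        cand.passes_followup_gate = (
            cand.passes_discovery_gate
            and len(cand.carriers_rd) >= th.min_rd_cases
            and not cand.case_variant_in_td
        )
        out.append(cand)
    return out


def prioritize(
    hi_calls: Iterable[HighImpactCall],
    th: Optional[Thresholds] = None,
    variant_af: Optional[dict] = None,
) -> list[GeneCandidate]:
    """Full prioritization: recurrence gate then follow-up gate."""
    th = th or Thresholds()
    return apply_followup_gate(
        count_recurrent_genes(hi_calls, th, variant_af=variant_af), th
    )


def passing_genes(candidates: Iterable[GeneCandidate]) -> list[str]:
    return [c.gene for c in candidates if c.passes_followup_gate]


def gene_overlap_test(
    n_set1: int, n_set2: int, n_overlap: int, background: int
) -> float:
    """Upper-tail hypergeometric probability of observing at least
    ``n_overlap`` shared genes between random sets of the given sizes drawn
    from a background universe (the usual gene-set overlap test)."""
    if not (0 <= n_overlap <= min(n_set1, n_set2) <= background):
        raise ValueError(
            "require n_overlap <= min(set sizes) <= background, all non-negative"
        )
    if max(n_set1, n_set2) > background:
        raise ValueError("set sizes cannot exceed the background")
    # P(X >= n_overlap), X ~ Hypergeom(background, n_set1, n_set2)
    return float(stats.hypergeom.sf(n_overlap - 1, background, n_set1, n_set2))
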