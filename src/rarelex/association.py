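"""Carrier-based exact association tests and cohort comparisons.

Two complementary tests for a recurrent variant:

* cases vs typically developing controls — two-sided Fisher's exact test on
  the 2x2 carrier table (carriers / non-carriers by group);
* cases vs the reference population — one-sided exact binomial test of the
  observed alternate-allele count against a fixed population allele
  frequency (the population panel's denominator is huge relative to the
  cohort, so the frequency is treated as known).

Cohort phenotype comparisons use Welch two-sample t-tests per measure with
Bonferroni adjustment.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import CarrierTable, PhenotypeProfile, PopComparison, Thresholds


def fisher_carrier_test(t: CarrierTable) -> float:
    """Two-sided Fisher exact p-value for the carrier 2x2 table.

    Two-sided in the standard exact sense: the sum of probabilities of all
    tables with the same margins no more probable than the observed one.
    """
    table = [
        [t.carriers_cases, t.n_cases - t.carriers_cases],
        [t.carriers_controls, t.n_controls - t.carriers_controls],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def population_af_test(c: PopComparison) -> float:
    """One-sided (greater) exact binomial p-value: P(X >= observed alt
    alleles) with n = total case alleles and p = the population frequency."""
    if c.pop_af == 0.0 and c.alt_alleles_cases > 0:
        warnings.warn(
            "population AF is 0 with observed alt alleles: p-value degenerates to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(
        stats.binomtest(
            c.alt_alleles_cases, c.total_alleles_cases, c.pop_af,
            alternative="greater",
        ).pvalue
    )


def case_allele_frequency(c: PopComparison) -> tuple[float, Optional[float]]:
    """Observed case allele frequency and its fold-change over the
    population frequency (None when the population frequency is zero)."""
    if c.total_alleles_cases == 0:
        raise ValueError("total alleles must be positive")
    freq = c.alt_alleles_cases / c.total_alleles_cases
    fold = freq / c.pop_af if c.pop_af > 0 else None
    return freq, fold


def cohort_ttests(
    group_a: Iterable[PhenotypeProfile],
    group_b: Iterable[PhenotypeProfile],
    measures: Iterable[str],
    th: Optional[Thresholds] = None,
) -> pd.DataFrame:
    """Welch two-sample t-test per measure, absolute t reported,
    Bonferroni-adjusted p capped at 1."""
    th = th or Thresholds()
    rows = []
    for m in measures:
        a = np.array([p.raw_scores[m] for p in group_a if m in p.raw_scores])
        b = np.array([p.raw_scores[m] for p in group_b if m in p.raw_scores])
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"measure {m}: need >=2 observations per group")
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            # identical constant groups: no evidence of difference
            rows.append({"measure": m, "t": 0.0, "p_raw": 1.0, "p_adjusted": 1.0})
            continue
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError(f"measure {m}: degenerate (zero) variance in both groups")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({
            "measure": m,
            "t": abs(float(t)),
            "p_raw": float(p),
            "p_adjusted": min(1.0, float(p) * th.bonferroni_m),
        })
    return pd.DataFrame(rows)


def carrier_table_from_calls(
    hi_calls,
    variant_key: str,
    case_ids: set,
    control_ids: set,
) -> CarrierTable:
    """Assemble the 2x2 carrier table for one variant from high-impact calls."""
    carriers = {c.individual_id for c in hi_calls if c.variant_key == variant_key}
    return CarrierTable(
        carriers_cases=len(carriers & case_ids),
        n_cases=len(case_ids),
        carriers_controls=len(carriers & control_ids),
        n_controls=len(control_ids),
    )
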