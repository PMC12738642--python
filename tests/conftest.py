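"""Shared fixtures: a small hand-written annotated VCF, phenotype rows, and
brute-force statistical oracles used to cross-check the library's tests."""

from __future__ import annotations

import math

import pytest

from rarelex.model import PhenotypeProfile, SelfReport, Thresholds
from rarelex.phenotypes import standardize

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=7>
##contig=<ID=16>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=FUNC,Number=1,Type=String,Description="Functional class">
##INFO=<ID=EXONICFUNC,Number=1,Type=String,Description="Exonic consequence">
##INFO=<ID=AF_NFE,Number=1,Type=Float,Description="gnomAD NFE allele frequency">
##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT call">
##INFO=<ID=PP2,Number=1,Type=String,Description="PolyPhen2 call">
##INFO=<ID=LRT,Number=1,Type=String,Description="LRT call">
##INFO=<ID=MT,Number=1,Type=String,Description="MutationTaster call">
##INFO=<ID=FATHMM,Number=1,Type=String,Description="FATHMM call">
##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar significance">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
7\t100\t.\tC\tT\t15\tPASS\tGENE=GX;FUNC=intronic\tGT:DP\t0/1:8\t./.:.
7\t73769649\trs139191328\tG\tA\t50\tPASS\tGENE=CLDN3;FUNC=exonic;EXONICFUNC=nonsynonymous_SNV;AF_NFE=0.0078335;SIFT=D;PP2=D;LRT=D;MT=D;FATHMM=D\tGT:DP\t0/1:30\t0/0:25
16\t57901371\t.\tT\tA\t45\tPASS\tGENE=CNGB1;FUNC=exonic;EXONICFUNC=nonsynonymous_SNV;AF_NFE=0.00113;SIFT=D;PP2=D;LRT=D;MT=T;FATHMM=D\tGT:DP\t0/0:20\t0/1:22
"""


@pytest.fixture
def vcf_text():
    return VCF_TEXT


@pytest.fixture
def small_vcf(tmp_path):
    p = tmp_path / "small.vcf"
    p.write_text(VCF_TEXT)
    return p


def make_profile(iid="X", piq=100.0, cohort="discovery", role="proband",
                 dawba=None, self_report=SelfReport.MISSING, **reading):
    """Profile from raw scores on the 100/15 scale, standardized."""
    raw = {"PIQ": piq, **reading}
    p = PhenotypeProfile(
        individual_id=iid, cohort=cohort, role=role,
        raw_scores={k: v for k, v in raw.items() if v is not None},
        dawba_asd=dawba, self_report=self_report,
    )
    return standardize(p, Thresholds())


def profile_from_z(iid="X", piq_z=0.0, cohort="discovery", role="proband",
                   dawba=None, self_report=SelfReport.MISSING, **reading_z):
    """Profile specified directly in z units."""
    return make_profile(
        iid=iid, piq=100 + 15 * piq_z if piq_z is not None else None,
        cohort=cohort, role=role, dawba=dawba, self_report=self_report,
        **{m: 100 + 15 * z for m, z in reading_z.items() if z is not None},
    )


# ---------------------------------------------------------------------------
# independent statistical oracles (brute force, math.comb only)
# ---------------------------------------------------------------------------

def hypergeom_pmf(k: int, M: int, K: int, n: int) -> float:
    """P(X = k) drawing n from M with K successes."""
    if k < max(0, n - (M - K)) or k > min(K, n):
        return 0.0
    return math.comb(K, k) * math.comb(M - K, n - k) / math.comb(M, n)


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration of tables with the
    observed margins: sum of probabilities of tables no more probable than
    the observed one."""
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom_pmf(a, n, c1, r1)
    total = 0.0
    for k in range(max(0, r1 - (n - c1)), min(r1, c1) + 1):
        p = hypergeom_pmf(k, n, c1, r1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def hypergeom_upper_tail_enumeration(n1: int, n2: int, k: int, M: int) -> float:
    """P(overlap >= k) for random sets of sizes n1, n2 from a universe M."""
    return sum(hypergeom_pmf(j, M, n1, n2) for j in range(k, min(n1, n2) + 1))


def binom_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) by direct summation."""
    return sum(
        math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
    )
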