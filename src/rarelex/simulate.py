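"""Synthetic-cohort generator.

The study's raw sequencing and phenotype data are not deposited, so every
pipeline stage is exercised on simulated cohorts with the same statistical
structure: a discovery cohort of 53 unrelated dyslexia cases, a follow-up
twin cohort classified into 38 reading-difficulty (RD) cases and 82
typically developing (TD) controls, roughly 11 high-impact variants per
individual after filtering, a handful of planted recurrent risk genes,
correlated reading measures on the population 100/15 scale, dizygotic twin
pairs, and small nuclear pedigrees for segregation.

Background rare variation is drawn from a pool of exonic sites whose
allele frequencies follow a log-uniform site-frequency distribution on
[1e-5, 9e-3]; each individual carries a site with probability 2*AF
(Hardy-Weinberg heterozygote rate for a rare allele), so per-individual
counts are approximately Poisson with mean ``background_hi_rate`` and an
occasional background gene acquires two carriers while three-carrier
background recurrence stays rare at the default gene-pool size.

Phenotypes are multivariate normal over the battery with exchangeable
correlation ``measure_corr``; carriers of planted variants are shifted on
all reading measures by ``liability_shift`` (an additive displacement of the
latent reading liability). Cohort membership is enforced by rejection
sampling so emitted cases and controls satisfy their class definitions by
construction.

A parallel :func:`make_published_fixture` emits the published per-gene
variant/carrier structure of the five prioritized genes (including the
asterisked follow-up variants that differ from the discovery variants) plus
a CFTR-like decoy whose discovery variant recurs in a TD control, for
worked-example tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io_formats import (
    write_annotated_vcf,
    write_pedigrees,
    write_phenotypes,
)
from .model import (
    CarrierStatus,
    ClinvarSig,
    CohortLabel,
    DISCOVERY_READING_MEASURES,
    ExonicFunc,
    FOLLOWUP_READING_MEASURES,
    FuncClass,
    Genotype,
    GenotypeCall,
    HighImpactCall,
    Pedigree,
    PedigreeMember,
    PhenotypeProfile,
    PredictorCall,
    PREDICTORS,
    SelfReport,
    Thresholds,
    VariantRecord,
)
from .phenotypes import (
    classify_discovery_case,
    classify_mild,
    classify_rd_case,
    classify_td_control,
    standardize,
)


@dataclass
class PlantedVariant:
    """Specification of one planted recurrent risk variant."""

    gene: str
    variant_key: str
    af_nfe: Optional[float]
    carriers_discovery: int
    carriers_rd: int
    carriers_td: int
    liability_shift: float = -0.8  # z units on the reading measures


@dataclass
class SimParams:
    """Study-condition parameters of the simulator.

    Defaults reproduce the analyzed cohort sizes (53 discovery cases, 38 RD
    cases, 82 TD controls) and the observed average of ~11 high-impact
    variants per individual.
    """

    n_discovery: int = 53
    n_rd: int = 38
    n_td: int = 82
    n_twin_pairs: int = 6
    n_families: int = 4
    n_genes: int = 15000
    background_hi_rate: float = 11.0
    #: allele-frequency range of the background site-frequency distribution
    af_range: tuple = (1e-5, 9e-3)
    planted: list = field(default_factory=list)  # list[PlantedVariant]
    measure_corr: float = 0.6
    qc_fail_rate: float = 0.05
    predictor_discordance_rate: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.measure_corr < 1.0):
            raise ValueError("measure_corr must lie in [0,1)")
        for pv in self.planted:
            if (pv.carriers_discovery > self.n_discovery
                    or pv.carriers_rd > self.n_rd
                    or pv.carriers_td > self.n_td):
                raise ValueError(
                    f"planted variant {pv.variant_key}: carrier counts exceed "
                    "cohort sizes"
                )


def default_planted() -> list[PlantedVariant]:
    """Planted risk variants mirroring the recurrence structure of the
    published candidate genes: one strongly recurrent variant (5/1/0) and
    two moderately recurrent genes (3/1/0), plus a decoy whose discovery
    variant also appears in a TD control and so must fail the follow-up
    gate."""
    return [
        PlantedVariant("GENE_A", "7-1000001-G-A", 0.0078, 5, 1, 0),
        PlantedVariant("GENE_B", "17-2000001-C-T", 0.0030, 3, 1, 0),
        PlantedVariant("GENE_C", "3-3000001-A-G", None, 3, 1, 0),
        PlantedVariant("GENE_TD", "11-4000001-T-C", 0.0050, 3, 1, 1),
    ]


@dataclass
class SimTruth:
    """Ground truth emitted alongside the files."""

    planted_carriers: dict = field(default_factory=dict)  # variant_key -> set ids
    affected_ids: set = field(default_factory=set)
    expected_pass_discovery: set = field(default_factory=set)  # gene symbols
    expected_pass_followup: set = field(default_factory=set)
    cohort_of: dict = field(default_factory=dict)  # individual_id -> label


@dataclass
class SimulatedCohort:
    records: list
    calls: list
    profiles: list
    pedigrees: list
    truth: SimTruth
    params: SimParams


# phenotype z-score means by cohort, matching the published descriptive
# statistics (discovery battery: PIQ 0.17, reading around -2; RD: PIQ -0.10,
# reading around -0.85; TD: PIQ 0.47, reading around +0.6)
_DISCOVERY_MEANS = {"PIQ": 0.17, "SWR": -2.04, "NWR": -1.52, "SPELL": -2.30,
                    "IWR": -2.39, "ORTH": -1.79, "PA": -1.25}
_RD_MEANS = {"PIQ": -0.10, "SWR": -0.71, "NWR": -0.80, "ACC": -1.05,
             "COMP": -1.00, "RR": -0.67}
_TD_MEANS = {"PIQ": 0.47, "SWR": 0.97, "NWR": 0.73, "ACC": 0.34,
             "COMP": 0.27, "RR": 0.62}


def _mvn_scores(rng, means: dict, corr: float, shift: float = 0.0) -> dict:
    """One draw of correlated z-scores; the shift displaces reading
    measures only (PIQ is untouched by the reading liability)."""
    measures = list(means)
    k = len(measures)
    cov = np.full((k, k), corr)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal([means[m] for m in measures], cov,
                                method="cholesky")
    out = {}
    for m, v in zip(measures, z):
        out[m] = v + (shift if m != "PIQ" else 0.0)
    return out


def _sample_profile(rng, iid, cohort, means, corr, shift, check, th,
                    max_tries=4000, **kwargs) -> PhenotypeProfile:
    """Rejection-sample a profile until it satisfies its class definition."""
    for _ in range(max_tries):
        zs = _mvn_scores(rng, means, corr, shift)
        p = PhenotypeProfile(
            individual_id=iid, cohort=cohort,
            raw_scores={m: round(th.pop_mean + th.pop_sd * z, 4)
                        for m, z in zs.items()},
            **kwargs,
        )
        standardize(p, th)
        if check(p):
            return p
    raise RuntimeError(
        f"could not satisfy class definition for {iid} in {max_tries} draws; "
        "liability shift and class means are likely inconsistent"
    )


def _background_pool(rng, params: SimParams) -> list[VariantRecord]:
    """Pool of exonic background variants with log-uniform rare AFs sized so
    the expected per-individual count of *passing* variants equals
    background_hi_rate (the pool is inflated to offset QC losses)."""
    pool = []
    total = 0.0
    target = params.background_hi_rate / (1.0 - params.qc_fail_rate)
    lo, hi = params.af_range
    i = 0
    while total < target:
        i += 1
        af = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        af = float(f"{af:.4g}")
        gene = f"BG{rng.integers(params.n_genes):05d}"
        chrom = str(rng.integers(1, 23))
        pos = int(10_000_000 + i * 137)
        discordant = rng.random() < params.predictor_discordance_rate
        calls = {p: PredictorCall.DAMAGING for p in PREDICTORS}
        if discordant:
            calls[PREDICTORS[int(rng.integers(len(PREDICTORS)))]] = PredictorCall.TOLERATED
        pool.append(VariantRecord(
            chrom=chrom, pos=pos, ref="G", alt="A", gene=gene,
            func_class=FuncClass.EXONIC, exonic_func=ExonicFunc.NONSYNONYMOUS,
            af_nfe=af, predictor_calls=calls,
            clinvar_sig=ClinvarSig.MISSING,
            site_qual=float(f"{rng.uniform(25, 60):.4g}"),
        ))
        if not discordant:
            total += 2 * af  # only filter-passing variants count toward the rate
    return pool


def simulate_cohort(params: Optional[SimParams] = None,
                    out_dir: Optional[str] = None,
                    th: Optional[Thresholds] = None) -> SimulatedCohort:
    """Generate a full annotated cohort; optionally persist it to ``out_dir``
    (VCF, phenotype TSV, PED, truth tables). Deterministic given
    ``params.seed``."""
    params = params or SimParams(planted=default_planted())
    th = th or Thresholds()
    rng = np.random.default_rng(params.seed)
    truth = SimTruth()

    disc_ids = [f"D{i:03d}" for i in range(params.n_discovery)]
    rd_ids = [f"R{i:03d}" for i in range(params.n_rd)]
    td_ids = [f"T{i:03d}" for i in range(params.n_td)]
    for i in disc_ids:
        truth.cohort_of[i] = CohortLabel.DISCOVERY.value
    for i in rd_ids:
        truth.cohort_of[i] = CohortLabel.RD_CASE.value
    for i in td_ids:
        truth.cohort_of[i] = CohortLabel.TD_CONTROL.value

    # --- planted variants and their carriers -----------------------------
    records: list[VariantRecord] = []
    planted_records = {}
    carrier_shift: dict[str, float] = {}
    for pv in params.planted:
        chrom, pos, ref, alt = pv.variant_key.split("-")
        rec = VariantRecord(
            chrom=chrom, pos=int(pos), ref=ref, alt=alt, gene=pv.gene,
            func_class=FuncClass.EXONIC, exonic_func=ExonicFunc.NONSYNONYMOUS,
            af_nfe=pv.af_nfe,
            predictor_calls={p: PredictorCall.DAMAGING for p in PREDICTORS},
            site_qual=50.0,
        )
        planted_records[pv.variant_key] = rec
        records.append(rec)
        carriers = set()
        for ids, k in ((disc_ids, pv.carriers_discovery),
                       (rd_ids, pv.carriers_rd),
                       (td_ids, pv.carriers_td)):
            chosen = rng.choice(ids, size=k, replace=False) if k else []
            carriers.update(str(c) for c in chosen)
        truth.planted_carriers[pv.variant_key] = carriers
        for c in carriers:
            if truth.cohort_of[c] != CohortLabel.TD_CONTROL.value:
                carrier_shift[c] = carrier_shift.get(c, 0.0) + pv.liability_shift

    # expected gate outcomes
    by_gene: dict[str, list[PlantedVariant]] = {}
    for pv in params.planted:
        by_gene.setdefault(pv.gene, []).append(pv)
    for gene, pvs in by_gene.items():
        n_disc = sum(pv.carriers_discovery for pv in pvs)
        n_rd = sum(pv.carriers_rd for pv in pvs)
        case_in_td = any(
            pv.carriers_td > 0 and (pv.carriers_discovery or pv.carriers_rd)
            for pv in pvs
        )
        if n_disc >= th.min_discovery_cases:
            truth.expected_pass_discovery.add(gene)
            if n_rd >= th.min_rd_cases and not case_in_td:
                truth.expected_pass_followup.add(gene)

    # --- background pool and genotypes ------------------------------------
    pool = _background_pool(rng, params)
    records.extend(pool)
    all_ids = disc_ids + rd_ids + td_ids
    afs = np.array([r.af_nfe for r in pool])
    carry = rng.random((len(all_ids), len(pool))) < 2 * afs  # HW het rate
    # a qc_fail_rate fraction of carried background genotypes get low depth
    qc_fail = rng.random(carry.shape) < params.qc_fail_rate
    depths_ok = rng.integers(th.min_depth, 80, size=carry.shape)
    depths_low = rng.integers(2, max(th.min_depth, 3), size=carry.shape)

    calls: list[GenotypeCall] = []
    for vk, carriers in sorted(truth.planted_carriers.items()):
        for iid in all_ids:
            calls.append(GenotypeCall(
                individual_id=iid, variant_key=vk,
                genotype=Genotype.HET if iid in carriers else Genotype.HOM_REF,
                depth=int(rng.integers(20, 80)),
            ))
    # non-carriers of background variants are left implicit (hom-ref /
    # uncalled in the emitted VCF); the filter only consumes carrier calls
    carrier_idx = np.argwhere(carry)
    for i, j in carrier_idx:
        depth = int(depths_low[i, j]) if qc_fail[i, j] else int(depths_ok[i, j])
        calls.append(GenotypeCall(
            individual_id=all_ids[i], variant_key=pool[j].variant_key,
            genotype=Genotype.HET, depth=depth,
        ))

    # --- phenotypes --------------------------------------------------------
    profiles: list[PhenotypeProfile] = []
    for iid in disc_ids:
        shift = carrier_shift.get(iid, 0.0)
        profiles.append(_sample_profile(
            rng, iid, "discovery", _DISCOVERY_MEANS, params.measure_corr,
            shift, lambda p: classify_discovery_case(p, th), th,
            sex="M" if rng.random() < 0.75 else "F",
        ))
        truth.affected_ids.add(iid)

    # follow-up rows: RD cases must classify RD (and not TD), TD controls
    # must classify TD (and not RD), so class assignment is a partition
    def rd_ok(p):
        return classify_rd_case(p, th) and not classify_td_control(p, th)

    def td_ok(p):
        return classify_td_control(p, th) and not classify_rd_case(p, th)

    twin_rd = min(params.n_twin_pairs, params.n_rd)
    for k, iid in enumerate(rd_ids):
        shift = carrier_shift.get(iid, 0.0)
        pair = f"TP{k:03d}" if k < twin_rd else None
        profiles.append(_sample_profile(
            rng, iid, "followup", _RD_MEANS, params.measure_corr, shift,
            rd_ok, th, sex="M" if rng.random() < 0.6 else "F",
            twin_pair_id=pair, role="proband", dawba_asd=False,
        ))
        truth.affected_ids.add(iid)
    for iid in td_ids:
        profiles.append(_sample_profile(
            rng, iid, "followup", _TD_MEANS, params.measure_corr, 0.0,
            td_ok, th, sex="M" if rng.random() < 0.45 else "F",
            role="proband", dawba_asd=False,
        ))
    # dizygotic co-twins of the first RD cases: each planted variant of the
    # proband is transmitted to the co-twin with probability 0.5 (DZ sharing)
    for k in range(twin_rd):
        proband = rd_ids[k]
        iid = f"RT{k:03d}"
        shared = [
            vk for vk, cs in sorted(truth.planted_carriers.items())
            if proband in cs and rng.random() < 0.5
        ]
        shift = sum(
            pv.liability_shift for pv in params.planted if pv.variant_key in shared
        )
        for vk in shared:
            calls.append(GenotypeCall(
                individual_id=iid, variant_key=vk, genotype=Genotype.HET,
                depth=int(rng.integers(20, 80)),
            ))
        profiles.append(_sample_profile(
            rng, iid, "followup", _RD_MEANS, params.measure_corr, shift,
            lambda p: True, th, sex="M" if rng.random() < 0.5 else "F",
            twin_pair_id=f"TP{k:03d}", role="twin", dawba_asd=False,
        ))

    # --- pedigrees around planted discovery carriers ----------------------
    # families are drawn round-robin across the planted variants of
    # follow-up-candidate genes first, mirroring segregation follow-up of
    # prioritized genes
    pedigrees: list[Pedigree] = []
    gene_of = {pv.variant_key: pv.gene for pv in params.planted}
    ordered_vks = sorted(
        truth.planted_carriers,
        key=lambda vk: (gene_of[vk] not in truth.expected_pass_followup, vk),
    )
    carrier_lists = [
        (vk, sorted(c for c in truth.planted_carriers[vk]
                    if truth.cohort_of.get(c) == CohortLabel.DISCOVERY.value))
        for vk in ordered_vks
    ]
    planted_disc = []
    depth_idx = 0
    while len(planted_disc) < sum(len(cs) for _, cs in carrier_lists):
        progressed = False
        for vk, cs in carrier_lists:
            if depth_idx < len(cs):
                planted_disc.append((vk, cs[depth_idx]))
                progressed = True
        if not progressed:
            break
        depth_idx += 1
    fam_no = 0
    used_probands: set[str] = set()
    for vk, proband in planted_disc:
        if fam_no >= params.n_families:
            break
        if proband in used_probands:
            continue
        used_probands.add(proband)
        fam_no += 1
        fid = f"FAM{fam_no:02d}"
        father, mother = f"{fid}_F", f"{fid}_M"
        sib = f"{fid}_S1"
        transmitting = father if rng.random() < 0.5 else mother
        ped = Pedigree(family_id=fid)
        fprof = PhenotypeProfile(
            individual_id=father, family_id=fid, role="parent",
            cohort="family", sex="M",
            self_report=(SelfReport.YES if transmitting == father
                         else SelfReport.NO),
        )
        mprof = PhenotypeProfile(
            individual_id=mother, family_id=fid, role="parent",
            cohort="family", sex="F",
            self_report=(SelfReport.YES if transmitting == mother
                         else (SelfReport.NO if rng.random() < 0.5
                               else SelfReport.MAYBE)),
        )
        sib_carrier = rng.random() < 0.5
        sib_check = (lambda p: classify_mild(p, th)) if sib_carrier \
            else (lambda p: not classify_mild(p, th)
                  and not classify_discovery_case(p, th))
        sib_means = dict(_DISCOVERY_MEANS)
        for m in sib_means:
            if m != "PIQ":
                sib_means[m] = -0.6 if sib_carrier else 0.3
        sprof = _sample_profile(
            rng, sib, "family", sib_means, params.measure_corr,
            0.0, sib_check, th, family_id=fid, role="sibling",
            sex="M" if rng.random() < 0.5 else "F",
        )
        profiles.extend([fprof, mprof, sprof])
        pb_prof = next(p for p in profiles if p.individual_id == proband)
        pb_prof.family_id = fid
        ped.members = [
            PedigreeMember(father, None, None, "M", fprof),
            PedigreeMember(mother, None, None, "F", mprof),
            PedigreeMember(proband, father, mother,
                           pb_prof.sex or "M", pb_prof),
            PedigreeMember(sib, father, mother, sprof.sex, sprof),
        ]
        for iid, carrier in (
            (father, transmitting == father),
            (mother, transmitting == mother),
            (proband, True),
            (sib, sib_carrier),
        ):
            ped.genotypes[(iid, vk)] = (
                CarrierStatus.CARRIER if carrier else CarrierStatus.NON_CARRIER
            )
        pedigrees.append(ped)
        for iid in (father, mother, sib):
            truth.cohort_of[iid] = CohortLabel.RELATIVE.value
        # family members also get genotype calls at the focal variant
        for iid, carrier in (
            (father, transmitting == father),
            (mother, transmitting == mother),
            (sib, sib_carrier),
        ):
            calls.append(GenotypeCall(
                individual_id=iid, variant_key=vk,
                genotype=Genotype.HET if carrier else Genotype.HOM_REF,
                depth=int(rng.integers(20, 80)),
            ))

    # stable output order: by position, then sample id order from calls
    records.sort(key=lambda r: (r.chrom, r.pos, r.alt))
    sim = SimulatedCohort(records=records, calls=calls, profiles=profiles,
                          pedigrees=pedigrees, truth=truth, params=params)
    if out_dir is not None:
        _persist(sim, Path(out_dir))
    return sim


def _persist(sim: SimulatedCohort, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_annotated_vcf(sim.records, sim.calls, out / "cohort.vcf")
    write_phenotypes(sim.profiles, out / "phenotypes.tsv")
    write_pedigrees(sim.pedigrees, out / "families.ped")
    with open(out / "truth_cohorts.tsv", "w") as fh:
        fh.write("individual_id\tcohort_label\n")
        for iid, lab in sorted(sim.truth.cohort_of.items()):
            fh.write(f"{iid}\t{lab}\n")
    with open(out / "truth_planted.tsv", "w") as fh:
        fh.write("variant_key\tindividual_id\n")
        for vk, carriers in sorted(sim.truth.planted_carriers.items()):
            for iid in sorted(carriers):
                fh.write(f"{vk}\t{iid}\n")
    with open(out / "truth_genes.tsv", "w") as fh:
        fh.write("gene\tpasses_discovery\tpasses_followup\n")
        genes = sim.truth.expected_pass_discovery | sim.truth.expected_pass_followup
        for g in sorted(genes):
            fh.write(
                f"{g}\t{int(g in sim.truth.expected_pass_discovery)}"
                f"\t{int(g in sim.truth.expected_pass_followup)}\n"
            )


# ---------------------------------------------------------------------------
# Published worked-example fixture
# ---------------------------------------------------------------------------

#: the five published candidate genes with their per-variant carrier
#: structure: (gene, variant_key, af_nfe, n_discovery, n_rd, n_td).
#: Gene-level totals match the published candidate table: CLDN3 5/1/1*,
#: CACNA1G 4/1/0, CACNA1D 3/1*/0, CNGB1 3/2*/0, CP 3/1/1* (asterisk: the
#: follow-up variant differs from the discovery variants).
PUBLISHED_GENES = [
    ("CLDN3", "7-73769649-G-A", 0.0078335, 5, 1, 0),
    ("CLDN3", "7-73769000-C-T", 0.002, 0, 0, 1),          # TD-only, different
    ("CACNA1G", "17-50600739-G-A", 0.0034283, 3, 1, 0),
    ("CACNA1G", "17-50601149-G-A", 0.0000313, 1, 0, 0),
    ("CACNA1D", "3-53747393-G-A", 0.0000155, 1, 0, 0),
    ("CACNA1D", "3-53749301-G-T", None, 1, 0, 0),          # novel, no gnomAD AF
    ("CACNA1D", "3-53751789-G-A", 0.0000465, 1, 1, 0),
    ("CNGB1", "16-57897524-C-T", 0.0061342, 2, 1, 0),
    ("CNGB1", "16-57901371-T-A", 0.00113, 1, 1, 0),
    ("CP", "3-149178609-C-G", 0.00232, 1, 0, 0),
    ("CP", "3-149199783-G-A", 0.00422, 1, 0, 0),
    ("CP", "3-149207611-T-C", 0.0006, 1, 1, 0),
    ("CP", "3-149210000-A-G", 0.003, 0, 0, 1),             # TD-only, different
    # CFTR-like decoy: six discovery variants in seven individuals, one of
    # which recurs in a TD control, so the gene fails the follow-up gate
    ("CFTR", "7-117559590-G-A", 0.004, 2, 1, 1),
    ("CFTR", "7-117559620-C-T", 0.003, 1, 0, 0),
    ("CFTR", "7-117559650-A-G", 0.002, 1, 0, 0),
    ("CFTR", "7-117559680-T-C", 0.001, 1, 0, 0),
    ("CFTR", "7-117559710-G-C", 0.0005, 1, 0, 0),
    ("CFTR", "7-117559740-C-A", 0.0002, 1, 0, 0),
]


def make_published_fixture() -> tuple[list[HighImpactCall], dict, dict]:
    """High-impact calls realizing the published candidate-table structure.

    Returns (calls, cohort_labels, variant_af). Carrier ids are deterministic
    (sequential per cohort and gene), unrelated by construction.
    """
    calls: list[HighImpactCall] = []
    labels: dict[str, CohortLabel] = {}
    variant_af: dict[str, Optional[float]] = {}
    counters = {"discovery": 0, "rd": 0, "td": 0}
    per_gene_ids: dict[str, dict[str, list]] = {}

    for gene, vk, af, n_disc, n_rd, n_td in PUBLISHED_GENES:
        variant_af[vk] = af
        slots = per_gene_ids.setdefault(
            gene, {"discovery": [], "rd": [], "td": []}
        )
        for slot, n, label, prefix in (
            ("discovery", n_disc, CohortLabel.DISCOVERY, "D"),
            ("rd", n_rd, CohortLabel.RD_CASE, "R"),
            ("td", n_td, CohortLabel.TD_CONTROL, "T"),
        ):
            for _ in range(n):
                iid = f"{prefix}{counters[slot]:03d}"
                counters[slot] += 1
                slots[slot].append(iid)
                labels[iid] = label
                calls.append(HighImpactCall(
                    individual_id=iid, variant_key=vk, gene=gene,
                    cohort_label=label,
                ))
    return calls, labels, variant_af
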