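"""Shared data model for the rare-variant prioritization pipeline.

Every numeric cutoff of the analysis lives in a single :class:`Thresholds`
record so that a run is auditable from one object. Variant-level annotation
(gene, functional class, population frequency, in-silico predictor calls,
ClinVar status) is carried by :class:`VariantRecord`; per-sample genotypes by
:class:`GenotypeCall`; per-individual phenotypes by
:class:`PhenotypeProfile`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class FuncClass(str, Enum):
    """Broad functional class of a variant (ANNOVAR Func.refGene style)."""

    EXONIC = "exonic"
    SPLICING = "splicing"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    UTR = "UTR"
    OTHER = "other"


class ExonicFunc(str, Enum):
    """Exonic consequence (ANNOVAR ExonicFunc.refGene style)."""

    NONSYNONYMOUS = "nonsynonymous_SNV"
    SYNONYMOUS = "synonymous_SNV"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    FRAMESHIFT = "frameshift"
    NONFRAMESHIFT = "nonframeshift"
    UNKNOWN = "unknown"
    NA = "NA"


class PredictorCall(str, Enum):
    """One in-silico pathogenicity predictor's verdict."""

    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    MISSING = "missing"


class ClinvarSig(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    BENIGN = "benign"
    VUS = "VUS"
    OTHER = "other"
    MISSING = "missing"


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


#: the five predictors whose unanimous "damaging" verdict defines PP3-style
#: computational support
PREDICTORS = ("SIFT", "PP2", "LRT", "MT", "FATHMM")

#: reading measures of the discovery battery
DISCOVERY_READING_MEASURES = ("SWR", "NWR", "SPELL", "IWR", "ORTH", "PA")
#: reading measures of the follow-up (twin-cohort) battery
FOLLOWUP_READING_MEASURES = ("SWR", "NWR", "ACC", "COMP", "RR")
#: every phenotype measure, reading + performance IQ
ALL_MEASURES = ("PIQ", "SWR", "NWR", "SPELL", "IWR", "ORTH", "PA", "ACC", "COMP", "RR")


def parse_clinvar(raw: Optional[str]) -> ClinvarSig:
    """Map a raw ClinVar significance string to the controlled vocabulary.

    Matching is case-insensitive and combined labels such as
    ``Pathogenic/Likely_pathogenic`` count as pathogenic — only the P/LP vs
    not-P/LP distinction matters downstream.
    """
    if raw is None or raw in ("", "."):
        return ClinvarSig.MISSING
    low = raw.lower()
    if "pathogenicity" in low:  # e.g. "Conflicting_interpretations_of_pathogenicity"
        return ClinvarSig.OTHER
    if "pathogenic" in low and "benign" not in low:
        if "likely" in low and "pathogenic/" not in low and not low.startswith("pathogenic"):
            return ClinvarSig.LIKELY_PATHOGENIC
        return ClinvarSig.PATHOGENIC
    if "benign" in low:
        return ClinvarSig.BENIGN
    if "uncertain" in low or low == "vus":
        return ClinvarSig.VUS
    return ClinvarSig.OTHER


@dataclass(frozen=True)
class VariantRecord:
    """One annotated biallelic site (one record per ALT allele)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    func_class: FuncClass
    exonic_func: ExonicFunc
    af_nfe: Optional[float]  # gnomAD NFE allele frequency; None = absent
    predictor_calls: dict = field(hash=False, compare=True, default_factory=dict)
    clinvar_sig: ClinvarSig = ClinvarSig.MISSING
    site_qual: float = 0.0

    def __post_init__(self):
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")
        if self.af_nfe is not None and not (0.0 <= self.af_nfe <= 1.0):
            raise ValueError(f"af_nfe {self.af_nfe} outside [0,1]")
        if self.site_qual < 0:
            raise ValueError("site_qual must be non-negative")
        for p in PREDICTORS:
            self.predictor_calls.setdefault(p, PredictorCall.MISSING)

    @property
    def variant_key(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one variant."""

    individual_id: str
    variant_key: str
    genotype: Genotype
    depth: Optional[int] = None  # read depth; None = missing

    def __post_init__(self):
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be non-negative")

    @property
    def is_carrier(self) -> bool:
        return self.genotype in (Genotype.HET, Genotype.HOM_ALT)


@dataclass
class Thresholds:
    """Every numeric cutoff of the analysis, in one auditable record.

    Defaults reproduce the published analysis: QC removal below site quality
    20 or read depth 10; rarity below 1% gnomAD-NFE frequency; a discovery
    recurrence gate of >=3 unrelated carriers; follow-up support of >=1
    replication case and zero typically-developing carriers of a case
    variant; z cutoffs on the 100/15 standardized score scale; Bonferroni
    over six test measures.
    """

    min_qual: float = 20.0
    min_depth: int = 10
    max_af: float = 0.01
    min_discovery_cases: int = 3
    min_rd_cases: int = 1
    max_td_case_variant_carriers: int = 0
    z_reading_cut: float = -1.0
    z_piq_cut: float = -1.0
    z_td_swr_cut: float = 0.0
    z_mild_avg_cut: float = -0.25
    pop_mean: float = 100.0
    pop_sd: float = 15.0
    bonferroni_m: int = 6
    #: whether the QC quality is the site QUAL or a genotype-level quality
    qual_source: str = "site"
    #: inclusive (<=) vs strict (<) reading of "1 SD below" for discovery cases
    discovery_reading_inclusive: bool = True

    def __post_init__(self):
        if not (0.0 < self.max_af <= 1.0):
            raise ValueError("max_af must lie in (0,1]")
        if self.pop_sd <= 0:
            raise ValueError("pop_sd must be positive")
        for name in ("min_depth", "min_discovery_cases", "min_rd_cases",
                     "max_td_case_variant_carriers", "bonferroni_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class CohortLabel(str, Enum):
    DISCOVERY = "discovery"
    RD_CASE = "rd_case"
    TD_CONTROL = "td_control"
    RELATIVE = "relative"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class HighImpactCall:
    """One individual x variant pair that survived all filter predicates."""

    individual_id: str
    variant_key: str
    gene: str
    cohort_label: CohortLabel


class PhenotypeClass(str, Enum):
    CASE = "case"
    TD = "td"
    MILD = "mild"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class SelfReport(str, Enum):
    YES = "yes"
    NO = "no"
    MAYBE = "maybe"
    MISSING = "missing"


@dataclass
class PhenotypeProfile:
    """One individual's standardized test scores and cohort bookkeeping.

    ``raw_scores`` are on the population 100/15 scale; ``z_scores`` are
    filled by :func:`rarelex.phenotypes.standardize` and satisfy
    ``z = (raw - pop_mean) / pop_sd`` for every present measure.
    """

    individual_id: str
    family_id: Optional[str] = None
    twin_pair_id: Optional[str] = None
    role: str = "proband"  # proband | sibling | parent | twin
    cohort: str = "discovery"  # discovery | followup | family
    sex: Optional[str] = None
    age_months: Optional[float] = None
    raw_scores: dict = field(default_factory=dict)
    z_scores: dict = field(default_factory=dict)
    dawba_asd: Optional[bool] = None
    self_report: SelfReport = SelfReport.MISSING
    phenotype_class: PhenotypeClass = PhenotypeClass.UNKNOWN

    def reading_z(self, measures=None) -> dict:
        """z-scores of the reading measures (everything but PIQ), optionally
        restricted to a battery subset; missing measures are simply absent."""
        keys = [m for m in (measures or ALL_MEASURES) if m != "PIQ"]
        return {m: z for m, z in self.z_scores.items()
                if m in keys and z is not None and not math.isnan(z)}


@dataclass
class GeneCandidate:
    """Per-gene carrier and variant sets split by cohort, plus gate flags."""

    gene: str
    variants: set = field(default_factory=set)
    variants_discovery: set = field(default_factory=set)
    variants_rd: set = field(default_factory=set)
    variants_td: set = field(default_factory=set)
    carriers_discovery: set = field(default_factory=set)
    carriers_rd: set = field(default_factory=set)
    carriers_td: set = field(default_factory=set)
    #: per-variant carrier sets, cohort -> variant_key -> set of individuals
    variant_carriers: dict = field(default_factory=dict)
    case_variant_in_td: bool = False
    flag_td_variant_differs: bool = False
    passes_discovery_gate: bool = False
    passes_followup_gate: bool = False
    #: gnomAD-NFE AF per variant_key, for reporting
    variant_af: dict = field(default_factory=dict)


@dataclass
class PedigreeMember:
    individual_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: Optional[str]
    phenotype: Optional[PhenotypeProfile] = None


class CarrierStatus(str, Enum):
    CARRIER = "carrier"
    NON_CARRIER = "non_carrier"
    UNKNOWN = "unknown"


@dataclass
class Pedigree:
    """Family structure with genotypes at focal variants."""

    family_id: str
    members: list = field(default_factory=list)  # list[PedigreeMember]
    #: (individual_id, variant_key) -> CarrierStatus
    genotypes: dict = field(default_factory=dict)

    def member_ids(self):
        return [m.individual_id for m in self.members]

    def carrier_status(self, individual_id: str, variant_key: str) -> CarrierStatus:
        return self.genotypes.get((individual_id, variant_key), CarrierStatus.UNKNOWN)


class SegregationPattern(str, Enum):
    CONSISTENT = "consistent_dominant_variable_expressivity"
    VIOLATED = "violated"
    UNINFORMATIVE = "uninformative"


@dataclass
class SegregationResult:
    family_id: str
    variant_key: str
    pattern: SegregationPattern
    carrier_affected: int = 0
    carrier_unaffected: int = 0
    carrier_unknown: int = 0
    noncarrier_affected: int = 0
    noncarrier_unaffected: int = 0
    noncarrier_unknown: int = 0


@dataclass
class CarrierTable:
    """2x2 carrier table: cases vs controls."""

    carriers_cases: int
    n_cases: int
    carriers_controls: int
    n_controls: int

    def __post_init__(self):
        if min(self.carriers_cases, self.n_cases,
               self.carriers_controls, self.n_controls) < 0:
            raise ValueError("counts must be non-negative")
        if self.carriers_cases > self.n_cases or self.carriers_controls > self.n_controls:
            raise ValueError("carriers exceed group size")


@dataclass
class PopComparison:
    """Observed case alleles vs a fixed population allele frequency."""

    alt_alleles_cases: int
    total_alleles_cases: int
    pop_af: float

    def __post_init__(self):
        if self.alt_alleles_cases < 0 or self.alt_alleles_cases > self.total_alleles_cases:
            raise ValueError("alt alleles must lie in [0, total]")
        if self.total_alleles_cases % 2 != 0:
            raise ValueError("total alleles must be even (2 per individual)")
        if not (0.0 <= self.pop_af <= 1.0):
            raise ValueError("pop_af must lie in [0,1]")
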