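"""Readers and writers for the pipeline's file formats.

The annotated-VCF dialect carries per-variant annotation in INFO keys
(``GENE``, ``FUNC``, ``EXONICFUNC``, ``AF_NFE``, the five predictor keys
``SIFT``/``PP2``/``LRT``/``MT``/``FATHMM`` as D/T characters, ``CLNSIG``)
and per-sample ``GT:DP``. Phenotypes travel as a TSV with one row per
individual; pedigrees as standard 6-column PED; the gene report as a TSV
mirroring the published candidate-gene table layout.

VCF access goes through pysam. pysam holds INFO floats in single precision,
so allele frequencies and site quality are normalized to 6 significant
digits on read; the writer never emits more than 6 significant digits, which
makes write-then-read round-trips exact.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import pandas as pd
import pysam

from .model import (
    ALL_MEASURES,
    ClinvarSig,
    CohortLabel,
    ExonicFunc,
    FuncClass,
    GeneCandidate,
    Genotype,
    GenotypeCall,
    Pedigree,
    PedigreeMember,
    PhenotypeProfile,
    PredictorCall,
    PREDICTORS,
    SelfReport,
    VariantRecord,
    parse_clinvar,
)


class ParseError(ValueError):
    """Malformed input file."""


class IntegrityError(ValueError):
    """Structurally valid input that violates a data-model invariant."""


_VCF_HEADER_LINES = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=FUNC,Number=1,Type=String,Description="Functional class">',
    '##INFO=<ID=EXONICFUNC,Number=1,Type=String,Description="Exonic consequence">',
    '##INFO=<ID=AF_NFE,Number=1,Type=Float,Description="gnomAD NFE allele frequency">',
    '##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT call (D/T)">',
    '##INFO=<ID=PP2,Number=1,Type=String,Description="PolyPhen2 call (D/T)">',
    '##INFO=<ID=LRT,Number=1,Type=String,Description="LRT call (D/T)">',
    '##INFO=<ID=MT,Number=1,Type=String,Description="MutationTaster call (D/T)">',
    '##INFO=<ID=FATHMM,Number=1,Type=String,Description="FATHMM call (D/T)">',
    '##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar significance">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
]


def _sig6(x: Optional[float]) -> Optional[float]:
    """Normalize to 6 significant digits (pysam float32 round-trip)."""
    if x is None:
        return None
    return float(f"{float(x):.6g}")


def _strip_chr(label: str) -> str:
    return label[3:] if label.lower().startswith("chr") else label


_FUNC_ALIASES = {
    "exonic": FuncClass.EXONIC,
    "splicing": FuncClass.SPLICING,
    "exonic;splicing": FuncClass.EXONIC,
    "intronic": FuncClass.INTRONIC,
    "intergenic": FuncClass.INTERGENIC,
    "utr": FuncClass.UTR,
    "utr3": FuncClass.UTR,
    "utr5": FuncClass.UTR,
}

_EXONIC_ALIASES = {
    "nonsynonymous_snv": ExonicFunc.NONSYNONYMOUS,
    "synonymous_snv": ExonicFunc.SYNONYMOUS,
    "stopgain": ExonicFunc.STOPGAIN,
    "stoploss": ExonicFunc.STOPLOSS,
    "frameshift": ExonicFunc.FRAMESHIFT,
    "frameshift_insertion": ExonicFunc.FRAMESHIFT,
    "frameshift_deletion": ExonicFunc.FRAMESHIFT,
    "nonframeshift": ExonicFunc.NONFRAMESHIFT,
    "nonframeshift_insertion": ExonicFunc.NONFRAMESHIFT,
    "nonframeshift_deletion": ExonicFunc.NONFRAMESHIFT,
    "unknown": ExonicFunc.UNKNOWN,
}


def _parse_func(raw: Optional[str]) -> FuncClass:
    if not raw or raw == ".":
        return FuncClass.OTHER
    return _FUNC_ALIASES.get(raw.lower(), FuncClass.OTHER)


def _parse_exonic(raw: Optional[str]) -> ExonicFunc:
    if not raw or raw == ".":
        return ExonicFunc.NA
    return _EXONIC_ALIASES.get(raw.lower(), ExonicFunc.UNKNOWN)


def _parse_predictor(raw) -> PredictorCall:
    if raw in (None, "", "."):
        return PredictorCall.MISSING
    s = str(raw).upper()
    if s == "D":
        return PredictorCall.DAMAGING
    if s == "T":
        return PredictorCall.TOLERATED
    return PredictorCall.MISSING


def read_annotated_vcf(path) -> tuple[list[VariantRecord], list[GenotypeCall]]:
    """Read an annotated VCF into variant records and genotype calls.

    Multiallelic sites are split into one record per ALT allele, genotypes
    recoded per allele. Missing INFO keys map to missing states. File order
    is preserved.

    Raises
    ------
    ParseError
        on a malformed header or record (pysam-level failure).
    IntegrityError
        on a duplicate variant key.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc

    records: list[VariantRecord] = []
    calls: list[GenotypeCall] = []
    seen: set[str] = set()
    samples = list(vf.header.samples)
    with vf:
        for rec in vf:
            info = rec.info
            alts = rec.alts or ()
            for alt_idx, alt in enumerate(alts):
                predictor_calls = {
                    p: _parse_predictor(info.get(p)) for p in PREDICTORS
                }
                vr = VariantRecord(
                    chrom=_strip_chr(rec.chrom),
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    gene=str(info.get("GENE", ".")) if info.get("GENE") else ".",
                    func_class=_parse_func(info.get("FUNC")),
                    exonic_func=_parse_exonic(info.get("EXONICFUNC")),
                    af_nfe=_sig6(info.get("AF_NFE")),
                    predictor_calls=predictor_calls,
                    clinvar_sig=parse_clinvar(info.get("CLNSIG")),
                    site_qual=_sig6(rec.qual) if rec.qual is not None else 0.0,
                )
                if vr.variant_key in seen:
                    raise IntegrityError(
                        f"duplicate variant key {vr.variant_key} in {path}"
                    )
                seen.add(vr.variant_key)
                records.append(vr)
                allele_no = alt_idx + 1
                for sid in samples:
                    sample = rec.samples[sid]
                    gt = sample.get("GT")
                    dp = sample.get("DP")
                    if gt is None or all(a is None for a in gt):
                        geno = Genotype.MISSING
                    else:
                        n_alt = sum(1 for a in gt if a == allele_no)
                        n_called = sum(1 for a in gt if a is not None)
                        if n_alt == 0:
                            geno = Genotype.HOM_REF
                        elif n_alt >= n_called:
                            geno = Genotype.HOM_ALT
                        else:
                            geno = Genotype.HET
                    calls.append(
                        GenotypeCall(
                            individual_id=sid,
                            variant_key=vr.variant_key,
                            genotype=geno,
                            depth=int(dp) if dp is not None else None,
                        )
                    )
    return records, calls


def write_annotated_vcf(records: Iterable[VariantRecord],
                        calls: Iterable[GenotypeCall], path) -> None:
    """Write variant records and genotype calls as an uncompressed VCF."""
    records = list(records)
    calls = list(calls)
    samples = sorted({c.individual_id for c in calls}) if calls else []
    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    chroms = []
    for r in records:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    for c in chroms:
        header.add_line(f"##contig=<ID={c}>")
    for s in samples:
        header.add_sample(s)

    by_variant: dict[str, dict[str, GenotypeCall]] = {}
    for c in calls:
        by_variant.setdefault(c.variant_key, {})[c.individual_id] = c

    _GT = {
        Genotype.HOM_REF: (0, 0),
        Genotype.HET: (0, 1),
        Genotype.HOM_ALT: (1, 1),
        Genotype.MISSING: (None, None),
    }
    _PRED = {
        PredictorCall.DAMAGING: "D",
        PredictorCall.TOLERATED: "T",
    }
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt)
            )
            rec.qual = _sig6(r.site_qual)
            rec.info["GENE"] = r.gene
            rec.info["FUNC"] = r.func_class.value
            rec.info["EXONICFUNC"] = r.exonic_func.value
            if r.af_nfe is not None:
                rec.info["AF_NFE"] = _sig6(r.af_nfe)
            for p in PREDICTORS:
                call = r.predictor_calls.get(p, PredictorCall.MISSING)
                if call in _PRED:
                    rec.info[p] = _PRED[call]
            if r.clinvar_sig is not ClinvarSig.MISSING:
                rec.info["CLNSIG"] = r.clinvar_sig.value
            for s in samples:
                call = by_variant.get(r.variant_key, {}).get(s)
                if call is None:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = _GT[call.genotype]
                    if call.depth is not None:
                        rec.samples[s]["DP"] = call.depth
            out.write(rec)


_PHENO_COLUMNS = [
    "individual_id", "family_id", "twin_pair_id", "role", "cohort", "sex",
    "age_months", *ALL_MEASURES, "dawba_asd", "self_report",
]

_VALID_COHORTS = {"discovery", "followup", "family"}
_VALID_ROLES = {"proband", "sibling", "parent", "twin"}


def _opt_str(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v in ("", "NA"):
        return None
    return str(v)


def read_phenotypes(path) -> list[PhenotypeProfile]:
    """Read the phenotype TSV into profiles (raw scores only, no z yet)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("individual_id", "cohort") if c not in df.columns]
    if missing:
        raise ParseError(f"phenotype TSV lacks required columns {missing}")
    profiles: list[PhenotypeProfile] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        iid = row["individual_id"]
        if iid in seen:
            raise IntegrityError(f"duplicate individual_id {iid}")
        seen.add(iid)
        cohort = row["cohort"]
        if cohort not in _VALID_COHORTS:
            raise ParseError(f"unknown cohort label {cohort!r} for {iid}")
        role = _opt_str(row.get("role")) or "proband"
        if role not in _VALID_ROLES:
            raise ParseError(f"unknown role {role!r} for {iid}")
        raw_scores = {}
        for m in ALL_MEASURES:
            v = _opt_str(row.get(m))
            if v is not None:
                raw_scores[m] = float(v)
        dawba = _opt_str(row.get("dawba_asd"))
        sr = _opt_str(row.get("self_report"))
        age = _opt_str(row.get("age_months"))
        profiles.append(
            PhenotypeProfile(
                individual_id=iid,
                family_id=_opt_str(row.get("family_id")),
                twin_pair_id=_opt_str(row.get("twin_pair_id")),
                role=role,
                cohort=cohort,
                sex=_opt_str(row.get("sex")),
                age_months=float(age) if age is not None else None,
                raw_scores=raw_scores,
                dawba_asd=None if dawba is None else dawba in ("1", "True", "true"),
                self_report=SelfReport(sr) if sr in ("yes", "no", "maybe") else SelfReport.MISSING,
            )
        )
    return profiles


def write_phenotypes(profiles: Iterable[PhenotypeProfile], path) -> None:
    rows = []
    for p in profiles:
        row = {
            "individual_id": p.individual_id,
            "family_id": p.family_id or "NA",
            "twin_pair_id": p.twin_pair_id or "NA",
            "role": p.role,
            "cohort": p.cohort,
            "sex": p.sex or "NA",
            "age_months": p.age_months if p.age_months is not None else "NA",
        }
        for m in ALL_MEASURES:
            v = p.raw_scores.get(m)
            row[m] = f"{v:.4f}" if v is not None else "NA"
        row["dawba_asd"] = ("NA" if p.dawba_asd is None else int(p.dawba_asd))
        row["self_report"] = (p.self_report.value
                              if p.self_report is not SelfReport.MISSING else "NA")
        rows.append(row)
    pd.DataFrame(rows, columns=_PHENO_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pedigrees(path, profiles: Optional[Iterable[PhenotypeProfile]] = None
                   ) -> list[Pedigree]:
    """Read a 6-column PED file into one Pedigree per family.

    Unknown parents are coded 0. When ``profiles`` is given, members are
    linked to their phenotype profiles by individual id.
    """
    prof_by_id = {p.individual_id: p for p in (profiles or [])}
    fams: dict[str, Pedigree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 PED columns")
            fid, iid, pat, mat, sex, _pheno = parts[:6]
            ped = fams.setdefault(fid, Pedigree(family_id=fid))
            ped.members.append(
                PedigreeMember(
                    individual_id=iid,
                    father_id=None if pat == "0" else pat,
                    mother_id=None if mat == "0" else mat,
                    sex={"1": "M", "2": "F"}.get(sex),
                    phenotype=prof_by_id.get(iid),
                )
            )
    for ped in fams.values():
        ids = set(ped.member_ids())
        for m in ped.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in ids:
                    raise IntegrityError(
                        f"family {ped.family_id}: member {m.individual_id} "
                        f"references unknown parent {parent}"
                    )
        _check_acyclic(ped)
    return list(fams.values())


def _check_acyclic(ped: Pedigree) -> None:
    parents = {
        m.individual_id: [p for p in (m.father_id, m.mother_id) if p]
        for m in ped.members
    }
    state: dict[str, int] = {}  # 0=visiting, 1=done

    def visit(node: str, stack: list) -> None:
        if state.get(node) == 1:
            return
        if state.get(node) == 0:
            raise IntegrityError(
                f"family {ped.family_id}: cyclic parentage at {node}"
            )
        state[node] = 0
        for p in parents.get(node, []):
            visit(p, stack)
        state[node] = 1

    for iid in parents:
        visit(iid, [])


def write_pedigrees(pedigrees: Iterable[Pedigree], path) -> None:
    with open(path, "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                sex = {"M": "1", "F": "2"}.get(m.sex or "", "0")
                fh.write(
                    f"{ped.family_id}\t{m.individual_id}\t"
                    f"{m.father_id or 0}\t{m.mother_id or 0}\t{sex}\t0\n"
                )


_REPORT_COLUMNS = ["gene", "variant_key", "af_nfe", "n_discovery", "n_rd",
                   "n_td", "flag_td_variant_differs"]


def write_gene_report(candidates: list[GeneCandidate], path) -> None:
    """Write the candidate-gene table: one row per variant plus an
    ``All variants`` summary row per gene, with an asterisk marking
    follow-up carrier counts whose variant differs from the case variants."""
    rows = []
    for cand in candidates:
        disc_vc = cand.variant_carriers.get("discovery", {})
        rd_vc = cand.variant_carriers.get("rd", {})
        td_vc = cand.variant_carriers.get("td", {})
        for vk in sorted(cand.variants):
            af = cand.variant_af.get(vk)
            rows.append({
                "gene": cand.gene,
                "variant_key": vk,
                "af_nfe": "" if af is None else f"{af:.7g}",
                "n_discovery": len(disc_vc.get(vk, ())),
                "n_rd": len(rd_vc.get(vk, ())),
                "n_td": len(td_vc.get(vk, ())),
                "flag_td_variant_differs": "",
            })
        n_td = len(cand.carriers_td)
        td_cell = f"{n_td}*" if (n_td and cand.flag_td_variant_differs) else str(n_td)
        rows.append({
            "gene": cand.gene,
            "variant_key": "All variants",
            "af_nfe": "",
            "n_discovery": len(cand.carriers_discovery),
            "n_rd": len(cand.carriers_rd),
            "n_td": td_cell,
            "flag_td_variant_differs": "*" if cand.flag_td_variant_differs else "",
        })
    pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(path, sep="\t", index=False)
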