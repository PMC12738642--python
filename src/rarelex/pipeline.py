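"""End-to-end orchestration: filter -> classify -> prioritize -> associate
-> segregate -> report.

Stages communicate through documented TSVs persisted in the output directory
so each can be rerun or inspected in isolation, and the final summary report
only restates counts that are re-derivable from those files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io_formats
from .association import (
    carrier_table_from_calls,
    case_allele_frequency,
    fisher_carrier_test,
    population_af_test,
)
from .filtering import filter_high_impact, per_individual_counts
from .model import (
    CarrierStatus,
    CohortLabel,
    Genotype,
    HighImpactCall,
    PhenotypeClass,
    PopComparison,
    Thresholds,
)
from .phenotypes import classify_profiles
from .prioritize import passing_genes, prioritize
from .segregation import assess_family

logger = logging.getLogger("rarelex")


@dataclass
class RunConfig:
    vcf: str
    phenotypes: str
    out_dir: str
    pedigrees: Optional[str] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    #: "column" trusts the TSV cohort column + classification; reserved for
    #: future explicit label files
    cohort_source: str = "column"
    seed: int = 0
    verbosity: str = "INFO"


def cohort_labels_from_profiles(profiles) -> dict[str, CohortLabel]:
    """Map classified profiles to the cohort labels the filter and the
    prioritization consume. Discovery probands are discovery cases;
    follow-up probands split into RD cases and TD controls by phenotype
    class; family members and unselected follow-up individuals (e.g.
    unchosen co-twins) are relatives / unassigned."""
    labels: dict[str, CohortLabel] = {}
    for p in profiles:
        if p.cohort == "discovery":
            labels[p.individual_id] = CohortLabel.DISCOVERY
        elif p.cohort == "family":
            labels[p.individual_id] = CohortLabel.RELATIVE
        elif p.cohort == "followup" and p.role in ("proband",):
            if p.phenotype_class is PhenotypeClass.CASE:
                labels[p.individual_id] = CohortLabel.RD_CASE
            elif p.phenotype_class is PhenotypeClass.TD:
                labels[p.individual_id] = CohortLabel.TD_CONTROL
            else:
                labels[p.individual_id] = CohortLabel.UNASSIGNED
        else:
            labels[p.individual_id] = CohortLabel.UNASSIGNED
    return labels


def write_calls_tsv(hi_calls, path) -> None:
    pd.DataFrame(
        [
            {
                "individual_id": c.individual_id,
                "variant_key": c.variant_key,
                "gene": c.gene,
                "cohort_label": c.cohort_label.value,
            }
            for c in hi_calls
        ],
        columns=["individual_id", "variant_key", "gene", "cohort_label"],
    ).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> list[HighImpactCall]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        HighImpactCall(
            individual_id=r.individual_id,
            variant_key=r.variant_key,
            gene=r.gene,
            cohort_label=CohortLabel(r.cohort_label),
        )
        for r in df.itertuples()
    ]


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage; returns the report directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = cfg.thresholds
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "vcf": cfg.vcf,
                "phenotypes": cfg.phenotypes,
                "pedigrees": cfg.pedigrees,
                "out_dir": cfg.out_dir,
                "seed": cfg.seed,
                "cohort_source": cfg.cohort_source,
                "thresholds": vars(th),
            },
            fh,
        )

    stage = "read inputs"
    try:
        records, calls = io_formats.read_annotated_vcf(cfg.vcf)
        profiles = io_formats.read_phenotypes(cfg.phenotypes)
        logger.info("read %d variant records, %d genotype calls, %d profiles",
                    len(records), len(calls), len(profiles))

        stage = "classify"
        classify_profiles(profiles, th)
        cls_df = pd.DataFrame(
            [
                {
                    "individual_id": p.individual_id,
                    "cohort": p.cohort,
                    "role": p.role,
                    "phenotype_class": p.phenotype_class.value,
                }
                for p in profiles
            ]
        )
        cls_df.to_csv(out / "classification.tsv", sep="\t", index=False)
        labels = cohort_labels_from_profiles(profiles)

        stage = "filter"
        result = filter_high_impact(records, calls, labels, th)
        write_calls_tsv(result.calls, out / "high_impact_calls.tsv")
        for reason, n in sorted(result.exclusion_counts().items()):
            logger.info("filter excluded %d calls (first failing: %s)", n, reason)
        logger.info("%d high-impact calls across %d genes",
                    len(result.calls), len({c.gene for c in result.calls}))
        core_ids = [i for i, lab in labels.items()
                    if lab in (CohortLabel.DISCOVERY, CohortLabel.RD_CASE,
                               CohortLabel.TD_CONTROL)]
        core_calls = [c for c in result.calls if c.individual_id in set(core_ids)]
        counts = per_individual_counts(core_calls, core_ids)
        counts.to_csv(out / "per_individual_counts.tsv", sep="\t", index=False)

        stage = "prioritize"
        variant_af = {r.variant_key: r.af_nfe for r in records}
        candidates = prioritize(result.calls, th, variant_af=variant_af)
        io_formats.write_gene_report(
            [c for c in candidates if c.passes_discovery_gate],
            out / "gene_report.tsv",
        )
        winners = passing_genes(candidates)
        logger.info("genes passing discovery gate: %d; follow-up gate: %d",
                    sum(c.passes_discovery_gate for c in candidates),
                    len(winners))

        stage = "associate"
        assoc_rows = []
        case_ids = {i for i, lab in labels.items()
                    if lab in (CohortLabel.DISCOVERY, CohortLabel.RD_CASE)}
        td_ids = {i for i, lab in labels.items()
                  if lab is CohortLabel.TD_CONTROL}
        for cand in candidates:
            if not cand.passes_followup_gate:
                continue
            # test the gene's most recurrent case variant
            disc_vc = cand.variant_carriers.get("discovery", {})
            if not disc_vc:
                continue
            vk = max(sorted(disc_vc), key=lambda v: len(disc_vc[v]))
            table = carrier_table_from_calls(result.calls, vk, case_ids, td_ids)
            pop_af = variant_af.get(vk)
            row = {
                "gene": cand.gene,
                "variant_key": vk,
                "carriers_cases": table.carriers_cases,
                "n_cases": table.n_cases,
                "carriers_td": table.carriers_controls,
                "n_td": table.n_controls,
                "fisher_p": fisher_carrier_test(table),
            }
            if pop_af:
                comp = PopComparison(
                    alt_alleles_cases=table.carriers_cases,
                    total_alleles_cases=2 * table.n_cases,
                    pop_af=pop_af,
                )
                freq, fold = case_allele_frequency(comp)
                row.update(
                    case_af=freq, fold_vs_pop=fold,
                    binom_p=population_af_test(comp),
                )
            assoc_rows.append(row)
        pd.DataFrame(assoc_rows).to_csv(out / "association.tsv", sep="\t",
                                        index=False)

        stage = "segregate"
        seg_rows = []
        if cfg.pedigrees:
            pedigrees = io_formats.read_pedigrees(cfg.pedigrees, profiles)
            geno_by_ind: dict[str, dict[str, Genotype]] = {}
            for c in calls:
                if c.genotype is not Genotype.MISSING:
                    geno_by_ind.setdefault(c.individual_id, {})[
                        c.variant_key
                    ] = c.genotype
            for ped in pedigrees:
                # fill pedigree genotypes from the VCF where present
                member_ids = ped.member_ids()
                for iid in member_ids:
                    for vk, g in geno_by_ind.get(iid, {}).items():
                        ped.genotypes[(iid, vk)] = (
                            CarrierStatus.CARRIER
                            if g in (Genotype.HET, Genotype.HOM_ALT)
                            else CarrierStatus.NON_CARRIER
                        )
                # a variant is focal for the family when at least two
                # members are genotyped at it
                n_genotyped: dict[str, int] = {}
                for (_, vk) in ped.genotypes:
                    n_genotyped[vk] = n_genotyped.get(vk, 0) + 1
                focal = sorted(vk for vk, n in n_genotyped.items() if n >= 2)
                for vk in focal:
                    res = assess_family(ped, vk, th)
                    seg_rows.append({
                        "family_id": res.family_id,
                        "variant_key": res.variant_key,
                        "pattern": res.pattern.value,
                        "carrier_affected": res.carrier_affected,
                        "carrier_unaffected": res.carrier_unaffected,
                        "carrier_unknown": res.carrier_unknown,
                        "noncarrier_affected": res.noncarrier_affected,
                    })
            pd.DataFrame(seg_rows).to_csv(out / "segregation.tsv", sep="\t",
                                          index=False)

        stage = "report"
        with open(out / "summary.txt", "w") as fh:
            fh.write("rarelex pipeline summary\n")
            fh.write("========================\n\n")
            fh.write(f"variant records: {len(records)}\n")
            fh.write(f"high-impact calls: {len(result.calls)}\n")
            fh.write(f"genes with high-impact calls: "
                     f"{len({c.gene for c in result.calls})}\n")
            mean = counts.attrs.get("mean")
            if mean is None:
                fh.write("mean high-impact per individual: undefined (no calls)\n")
            else:
                fh.write(f"mean high-impact per individual: {mean:.2f} "
                         f"(~{counts.attrs['mean_rounded']})\n")
            fh.write(f"genes passing discovery gate: "
                     f"{sum(c.passes_discovery_gate for c in candidates)}\n")
            fh.write(f"genes passing follow-up gate: {len(winners)}\n")
            if winners:
                fh.write("candidates: " + ", ".join(sorted(winners)) + "\n")
            for row in assoc_rows:
                fh.write(
                    f"\n{row['gene']} {row['variant_key']}: "
                    f"{row['carriers_cases']}/{row['n_cases']} case carriers vs "
                    f"{row['carriers_td']}/{row['n_td']} TD, "
                    f"Fisher p={row['fisher_p']:.2g}"
                )
                if "binom_p" in row:
                    fh.write(
                        f"; case AF={row['case_af']:.3f} "
                        f"({row['fold_vs_pop']:.1f}x population), "
                        f"binomial p={row['binom_p']:.2g}"
                    )
                fh.write("\n")
            if seg_rows:
                fh.write("\nsegregation:\n")
                for r in seg_rows:
                    fh.write(
                        f"  family {r['family_id']} {r['variant_key']}: "
                        f"{r['pattern']} (carriers affected "
                        f"{r['carrier_affected']}, unaffected "
                        f"{r['carrier_unaffected']})\n"
                    )
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
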