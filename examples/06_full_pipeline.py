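"""Simulate a full annotated cohort, persist it, and run every stage.

The simulator emits an annotated VCF, a phenotype TSV, a PED file and truth
tables; the pipeline reads them back, filters, classifies, prioritizes,
tests association, assesses segregation and writes a summary report.
"""

import tempfile
from pathlib import Path

from rarelex import RunConfig, run_pipeline
from rarelex.simulate import SimParams, default_planted, simulate_cohort

base = Path(tempfile.mkdtemp())
data = base / "data"
simulate_cohort(SimParams(seed=1, planted=default_planted()), out_dir=data)

out = run_pipeline(RunConfig(
    vcf=str(data / "cohort.vcf"),
    phenotypes=str(data / "phenotypes.tsv"),
    pedigrees=str(data / "families.ped"),
    out_dir=str(base / "report"),
))

print((out / "summary.txt").read_text())
print(f"stage outputs under {out}")
# GENE_A reproduces the headline association (6/91 case carriers, 0/82 TD,
# Fisher P ~ 0.03, ~4-fold population enrichment); GENE_TD is planted with a
# case variant in a control and must never appear among the candidates.
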