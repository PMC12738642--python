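"""Assign phenotype classes from standardized reading scores.

Scores arrive on the population scale (mean 100, SD 15). A follow-up
individual is an RD (reading difficulties) case when PIQ >= -1 SD and at
least one reading score is more than 1 SD below the mean; a TD (typically
developing) control when PIQ >= -1 SD and single-word reading is above the
mean; relatives qualify as "mild" with one reading z below -1 or a mean
reading z at or below -0.25.
"""

from rarelex import PhenotypeProfile, Thresholds, classify_profiles

profiles = [
    PhenotypeProfile(individual_id="RD-like", cohort="followup",
                     raw_scores={"PIQ": 117, "SWR": 55, "NWR": 70,
                                 "ACC": 82, "COMP": 85, "RR": 90}),
    PhenotypeProfile(individual_id="TD-like", cohort="followup",
                     raw_scores={"PIQ": 107, "SWR": 115, "NWR": 111,
                                 "ACC": 105, "COMP": 104, "RR": 109}),
    PhenotypeProfile(individual_id="mild-sibling", cohort="family",
                     role="sibling",
                     raw_scores={"PIQ": 124, "SWR": 92, "NWR": 90,
                                 "ACC": 95, "COMP": 93, "RR": 96}),
]

for p in classify_profiles(profiles, Thresholds()):
    zs = {m: f"{z:+.2f}" for m, z in sorted(p.z_scores.items())}
    print(f"{p.individual_id:>12}: class={p.phenotype_class.value:<10} z={zs}")
# "RD-like" has SWR z = -3 with high PIQ -> case; "TD-like" reads above the
# mean -> td; the sibling's average reading z of about -0.6 -> mild.
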