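"""Segregation assessment in a nuclear family.

Children are called affected from the test battery (case or mild reading
difficulties); parents from self-report. The pattern is consistent with a
dominant effect of variable expressivity when every carrier with known
phenotype shows some reading difficulty; affected non-carriers point to
other risk factors but do not violate.
"""

from rarelex import Pedigree, PhenotypeProfile, Thresholds, assess_family
from rarelex.model import CarrierStatus, PedigreeMember, SelfReport
from rarelex.phenotypes import standardize
from rarelex.segregation import multi_variant_profile

VK = "7-73769649-G-A"
th = Thresholds()

def child(iid, **raw):
    return standardize(PhenotypeProfile(individual_id=iid, cohort="family",
                                        role="sibling", raw_scores=raw), th)

father = PhenotypeProfile(individual_id="father", role="parent",
                          cohort="family", self_report=SelfReport.YES)
mother = PhenotypeProfile(individual_id="mother", role="parent",
                          cohort="family", self_report=SelfReport.MAYBE)
proband = child("proband", PIQ=110, SWR=62, NWR=74, SPELL=70)   # case
sibling = child("sibling", PIQ=118, SWR=93, NWR=91, SPELL=95)   # mild
good_reader = child("good_reader", PIQ=105, SWR=120, NWR=112, SPELL=113)

ped = Pedigree(family_id="FAM18")
for prof in (father, mother, proband, sibling, good_reader):
    ped.members.append(PedigreeMember(prof.individual_id, None, None, None, prof))
for iid, status in [("father", CarrierStatus.CARRIER),
                    ("mother", CarrierStatus.NON_CARRIER),
                    ("proband", CarrierStatus.CARRIER),
                    ("sibling", CarrierStatus.CARRIER),
                    ("good_reader", CarrierStatus.NON_CARRIER)]:
    ped.genotypes[(iid, VK)] = status

res = assess_family(ped, VK, th)
print(f"family {res.family_id}, variant {VK}")
print(f"pattern: {res.pattern.value}")
print(f"carriers affected={res.carrier_affected} "
      f"unaffected={res.carrier_unaffected} unknown={res.carrier_unknown}; "
      f"non-carriers affected={res.noncarrier_affected}")
print("carried-variant sets:", multi_variant_profile(ped, [VK]))
# All three carriers with known phenotype (father by self-report, the case
# proband, the mild sibling) show reading difficulties, so the pattern is
# consistent with dominance under variable expressivity.
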