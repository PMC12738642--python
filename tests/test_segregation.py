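"""Pedigree segregation under dominance with variable expressivity."""

import numpy as np
import pytest

from conftest import profile_from_z

from rarelex.model import (
    CarrierStatus,
    Pedigree,
    PedigreeMember,
    SegregationPattern,
    SelfReport,
    Thresholds,
)
from rarelex.segregation import (
    Affection,
    assess_family,
    member_affection,
    multi_variant_profile,
)

TH = Thresholds()
C, N = CarrierStatus.CARRIER, CarrierStatus.NON_CARRIER


def parent(iid, report):
    p = profile_from_z(iid=iid, cohort="family", role="parent", piq_z=None)
    p.self_report = report
    return p


class TestMemberAffection:
    def test_mild_sibling_is_affected(self):
        # average reading z of -0.54 with a high PIQ: mild, hence affected
        sib = profile_from_z(iid="S", role="sibling", cohort="family",
                             piq_z=1.7, SWR=-0.54, NWR=-0.54, SPELL=-0.54,
                             IWR=-0.54, ORTH=-0.54, PA=-0.54)
        assert member_affection(sib, TH) is Affection.AFFECTED

    def test_parent_maybe_is_unknown(self):
        assert member_affection(parent("P", SelfReport.MAYBE), TH) \
            is Affection.UNKNOWN
        assert member_affection(parent("P", SelfReport.MISSING), TH) \
            is Affection.UNKNOWN

    def test_parent_yes_and_no(self):
        assert member_affection(parent("P", SelfReport.YES), TH) \
            is Affection.AFFECTED
        assert member_affection(parent("P", SelfReport.NO), TH) \
            is Affection.UNAFFECTED

    def test_good_reader_sibling_unaffected(self):
        sib = profile_from_z(iid="S", role="sibling", cohort="family",
                             piq_z=0.5, SWR=1.3, NWR=0.4, SPELL=0.2,
                             IWR=0.6, ORTH=0.1, PA=0.3)
        assert member_affection(sib, TH) is Affection.UNAFFECTED

    def test_unscored_child_unknown(self):
        sib = profile_from_z(iid="S", role="sibling", cohort="family",
                             piq_z=None)
        assert member_affection(sib, TH) is Affection.UNKNOWN


class TestAssessFamily:
    VK = "7-73769649-G-A"

    def _member(self, prof):
        return PedigreeMember(prof.individual_id, None, None, prof.sex, prof)

    def test_fully_segregating_family(self):
        """Carrier father with self-reported problems, three carrier
        children (one case, two mild), one unaffected non-carrier."""
        ped = Pedigree(family_id="F18")
        profs = [
            parent("DAD", SelfReport.YES),
            profile_from_z(iid="P1", piq_z=0.5, SWR=-2.0),
            profile_from_z(iid="K2", piq_z=0.8, SWR=-0.6, NWR=-0.6),
            profile_from_z(iid="K3", piq_z=0.9, SWR=-0.4, NWR=-0.8),
            profile_from_z(iid="K4", piq_z=0.3, SWR=1.3, NWR=0.5),
        ]
        ped.members = [self._member(p) for p in profs]
        for iid, status in [("DAD", C), ("P1", C), ("K2", C), ("K3", C),
                            ("K4", N)]:
            ped.genotypes[(iid, self.VK)] = status
        res = assess_family(ped, self.VK, TH)
        assert res.pattern is SegregationPattern.CONSISTENT
        assert res.carrier_affected == 4
        assert res.carrier_unaffected == 0

    def test_affected_noncarrier_does_not_violate(self):
        """A mild non-carrier sibling suggests other risk factors but keeps
        the pattern consistent."""
        ped = Pedigree(family_id="F4")
        profs = [
            parent("DAD", SelfReport.YES),
            profile_from_z(iid="P1", piq_z=0.5, SWR=-2.0),
            profile_from_z(iid="SIB", piq_z=0.6, SWR=-0.5, NWR=-0.3),
        ]
        ped.members = [self._member(p) for p in profs]
        for iid, status in [("DAD", C), ("P1", C), ("SIB", N)]:
            ped.genotypes[(iid, self.VK)] = status
        res = assess_family(ped, self.VK, TH)
        assert res.pattern is SegregationPattern.CONSISTENT
        assert res.noncarrier_affected == 1

    def test_unaffected_carrier_violates(self):
        ped = Pedigree(family_id="FX")
        profs = [
            profile_from_z(iid="P1", piq_z=0.5, SWR=-2.0),
            profile_from_z(iid="SIB", piq_z=0.5, SWR=1.0, NWR=0.8),
        ]
        ped.members = [self._member(p) for p in profs]
        ped.genotypes[("P1", self.VK)] = C
        ped.genotypes[("SIB", self.VK)] = C
        res = assess_family(ped, self.VK, TH)
        assert res.pattern is SegregationPattern.VIOLATED
        assert res.carrier_unaffected == 1

    def test_ungenotyped_variant_uninformative(self):
        ped = Pedigree(family_id="FY")
        ped.members = [self._member(profile_from_z(iid="P1", piq_z=0.5,
                                                   SWR=-2.0))]
        res = assess_family(ped, "1-1-A-G", TH)
        assert res.pattern is SegregationPattern.UNINFORMATIVE
        assert res.carrier_affected == 0

    def test_single_informative_member_uninformative(self):
        ped = Pedigree(family_id="FZ")
        profs = [
            profile_from_z(iid="P1", piq_z=0.5, SWR=-2.0),
            parent("MUM", SelfReport.MAYBE),
        ]
        ped.members = [self._member(p) for p in profs]
        ped.genotypes[("P1", self.VK)] = C
        ped.genotypes[("MUM", self.VK)] = C
        res = assess_family(ped, self.VK, TH)
        assert res.pattern is SegregationPattern.UNINFORMATIVE

    def test_pattern_invariant_to_member_order(self):
        ped = Pedigree(family_id="F18")
        profs = [
            parent("DAD", SelfReport.YES),
            profile_from_z(iid="P1", piq_z=0.5, SWR=-2.0),
            profile_from_z(iid="K4", piq_z=0.3, SWR=1.3, NWR=0.5),
        ]
        for iid, status in [("DAD", C), ("P1", C), ("K4", N)]:
            ped.genotypes[(iid, self.VK)] = status
        results = []
        import itertools
        for perm in itertools.permutations(profs):
            ped.members = [self._member(p) for p in perm]
            results.append(assess_family(ped, self.VK, TH).pattern)
        assert len(set(results)) == 1

    def test_consistent_implies_no_unaffected_carrier(self):
        """Monte-Carlo over random small pedigrees: whenever the pattern is
        consistent, the unaffected-carrier count is zero; with a fully
        penetrant variant and liability-derived affection, the violation
        rate tracks the misclassification rate."""
        rng = np.random.default_rng(9)
        violations = 0
        n_fams = 300
        miscls_rate = 0.15
        for f in range(n_fams):
            ped = Pedigree(family_id=f"SIM{f}")
            for k in range(4):
                carrier = rng.random() < 0.5
                # carriers are truly affected; a miscls_rate fraction of
                # carriers nevertheless score as unaffected
                if carrier:
                    affected = rng.random() > miscls_rate
                else:
                    affected = rng.random() < 0.2
                z = -2.0 if affected else 1.0
                prof = profile_from_z(iid=f"I{k}", piq_z=0.5, SWR=z, NWR=z)
                ped.members.append(self._member(prof))
                ped.genotypes[(f"I{k}", self.VK)] = C if carrier else N
            res = assess_family(ped, self.VK, TH)
            if res.pattern is SegregationPattern.CONSISTENT:
                assert res.carrier_unaffected == 0
            if res.carrier_unaffected > 0:
                assert res.pattern is SegregationPattern.VIOLATED
                violations += 1
        # expected violated fraction: P(>=1 of ~2 carriers misclassified)
        # ~ 1-(1-0.15)^2 ~ 0.28 of families; allow a wide Monte-Carlo band
        assert 0.15 <= violations / n_fams <= 0.42


class TestMultiVariantProfile:
    KEYS = ["16-57901371-T-A", "7-73769649-G-A", "3-53751789-G-A"]

    def _ped(self):
        ped = Pedigree(family_id="F32")
        for iid in ("P1", "SIB"):
            ped.members.append(PedigreeMember(iid, None, None, None, None))
        return ped

    def test_proband_three_sibling_one(self):
        ped = self._ped()
        for vk in self.KEYS:
            ped.genotypes[("P1", vk)] = C
        ped.genotypes[("SIB", self.KEYS[1])] = C
        for vk in (self.KEYS[0], self.KEYS[2]):
            ped.genotypes[("SIB", vk)] = N
        sets = multi_variant_profile(ped, self.KEYS)
        assert len(sets["P1"]) == 3
        assert sets["SIB"] == {self.KEYS[1]}

    def test_no_genotypes_empty_sets(self):
        sets = multi_variant_profile(self._ped(), self.KEYS)
        assert sets == {"P1": set(), "SIB": set()}

    def test_partial_carriage(self):
        ped = self._ped()
        ped.genotypes[("P1", self.KEYS[0])] = C
        ped.genotypes[("P1", self.KEYS[1])] = C
        ped.genotypes[("P1", self.KEYS[2])] = N
        sets = multi_variant_profile(ped, self.KEYS)
        assert len(sets["P1"]) == 2
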