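"""High-impact filter: predicate boundaries, conjunction, monotonicity."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarelex.filtering import (
    filter_high_impact,
    first_failing_predicate,
    is_consequence_retained,
    is_predicted_damaging,
    is_rare,
    per_individual_counts,
    qc_pass,
)
from rarelex.io_formats import IntegrityError
from rarelex.model import (
    ClinvarSig,
    CohortLabel,
    ExonicFunc,
    FuncClass,
    Genotype,
    GenotypeCall,
    HighImpactCall,
    PredictorCall,
    PREDICTORS,
    Thresholds,
    VariantRecord,
)

TH = Thresholds()


def make_record(pos=1, af=0.001, func=FuncClass.EXONIC,
                exonic=ExonicFunc.NONSYNONYMOUS, qual=50.0,
                predictors=None, clinvar=ClinvarSig.MISSING):
    calls = {p: PredictorCall.DAMAGING for p in PREDICTORS}
    if predictors:
        calls.update(predictors)
    return VariantRecord(
        chrom="1", pos=pos, ref="A", alt="G", gene=f"G{pos}",
        func_class=func, exonic_func=exonic, af_nfe=af,
        predictor_calls=calls, clinvar_sig=clinvar, site_qual=qual,
    )


class TestQcPass:
    @pytest.mark.parametrize(
        "qual,depth,expected",
        [
            (20.0, 10, True),    # exact removal boundary is retained
            (19.9, 50, False),   # quality just below cutoff
            (99.0, 9, False),    # depth just below cutoff
            (50.0, None, False),  # missing depth fails
        ],
    )
    def test_boundaries(self, qual, depth, expected):
        rec = make_record(qual=qual)
        call = GenotypeCall("I", rec.variant_key, Genotype.HET, depth)
        assert qc_pass(call, rec, TH) is expected


class TestIsRare:
    @pytest.mark.parametrize(
        "af,expected",
        [
            (0.0078335, True),   # the recurrent variant's gnomAD frequency
            (0.01, False),       # >= 1% is removed, boundary inclusive
            (None, True),        # absent from gnomAD counts as rare (PM2)
            (0.0099, True),
        ],
    )
    def test_rarity(self, af, expected):
        assert is_rare(make_record(af=af), TH) is expected


class TestConsequence:
    @pytest.mark.parametrize(
        "func,exonic,expected",
        [
            (FuncClass.EXONIC, ExonicFunc.NONSYNONYMOUS, True),
            (FuncClass.INTRONIC, ExonicFunc.NA, False),
            (FuncClass.INTERGENIC, ExonicFunc.NA, False),
            (FuncClass.EXONIC, ExonicFunc.SYNONYMOUS, False),
            (FuncClass.SPLICING, ExonicFunc.NA, True),
            (FuncClass.EXONIC, ExonicFunc.STOPGAIN, True),
        ],
    )
    def test_retention(self, func, exonic, expected):
        assert is_consequence_retained(make_record(func=func, exonic=exonic)) \
            is expected


class TestPredictedDamaging:
    def test_unanimous_damaging_without_clinvar(self):
        assert is_predicted_damaging(make_record()) is True

    def test_single_tolerated_breaks_consensus(self):
        rec = make_record(predictors={"MT": PredictorCall.TOLERATED},
                          clinvar=ClinvarSig.VUS)
        assert is_predicted_damaging(rec) is False

    def test_clinvar_pathogenic_rescues_missing_predictors(self):
        rec = make_record(
            predictors={p: PredictorCall.MISSING for p in PREDICTORS},
            clinvar=ClinvarSig.PATHOGENIC,
        )
        assert is_predicted_damaging(rec) is True

    def test_missing_predictor_breaks_consensus(self):
        rec = make_record(predictors={"SIFT": PredictorCall.MISSING})
        assert is_predicted_damaging(rec) is False


class TestFilterHighImpact:
    def test_all_hom_ref_yields_empty(self):
        rec = make_record()
        calls = [GenotypeCall(f"I{i}", rec.variant_key, Genotype.HOM_REF, 30)
                 for i in range(5)]
        res = filter_high_impact([rec], calls, {}, TH)
        assert res.calls == []
        assert res.exclusion_log == []

    def test_depth_boundary_toggles_inclusion(self):
        rec = make_record()
        low = GenotypeCall("I", rec.variant_key, Genotype.HET, TH.min_depth - 1)
        ok = GenotypeCall("I", rec.variant_key, Genotype.HET, TH.min_depth)
        assert filter_high_impact([rec], [low], {}, TH).calls == []
        kept = filter_high_impact([rec], [ok], {}, TH).calls
        assert len(kept) == 1 and kept[0].variant_key == rec.variant_key

    def test_unknown_variant_key_rejected(self):
        rec = make_record()
        call = GenotypeCall("I", "9-999-A-T", Genotype.HET, 30)
        with pytest.raises(IntegrityError):
            filter_high_impact([rec], [call], {}, TH)

    def test_hom_alt_retained(self):
        rec = make_record()
        call = GenotypeCall("I", rec.variant_key, Genotype.HOM_ALT, 30)
        assert len(filter_high_impact([rec], [call], {}, TH).calls) == 1

    def test_cohort_labels_only_annotate(self):
        recs = [make_record(pos=i) for i in range(1, 6)]
        calls = [GenotypeCall(f"I{i}", r.variant_key, Genotype.HET, 30)
                 for i, r in enumerate(recs)]
        labels_a = {f"I{i}": CohortLabel.DISCOVERY for i in range(5)}
        labels_b = {f"I{i}": CohortLabel.TD_CONTROL for i in range(5)}
        keys_a = {(c.individual_id, c.variant_key)
                  for c in filter_high_impact(recs, calls, labels_a, TH).calls}
        keys_b = {(c.individual_id, c.variant_key)
                  for c in filter_high_impact(recs, calls, labels_b, TH).calls}
        assert keys_a == keys_b

    def test_exclusion_log_names_first_failing_predicate(self):
        recs = [
            make_record(pos=1, qual=5.0),
            make_record(pos=2, af=0.5),
            make_record(pos=3, func=FuncClass.INTRONIC, exonic=ExonicFunc.NA),
            make_record(pos=4, predictors={"LRT": PredictorCall.TOLERATED}),
        ]
        calls = [GenotypeCall("I", r.variant_key, Genotype.HET, 30) for r in recs]
        res = filter_high_impact(recs, calls, {}, TH)
        reasons = [reason for _, _, reason in res.exclusion_log]
        assert reasons == ["qc", "rare", "consequence", "damaging"]


# strategy for a random annotated variant
variant_st = st.builds(
    make_record,
    pos=st.integers(1, 10**6),
    af=st.one_of(st.none(), st.floats(0, 0.05, allow_nan=False)),
    func=st.sampled_from(list(FuncClass)),
    exonic=st.sampled_from(list(ExonicFunc)),
    qual=st.floats(0, 100, allow_nan=False),
    predictors=st.dictionaries(
        st.sampled_from(PREDICTORS), st.sampled_from(list(PredictorCall)),
        max_size=5,
    ),
    clinvar=st.sampled_from(list(ClinvarSig)),
)


@st.composite
def cohort_st(draw):
    records = draw(st.lists(variant_st, min_size=1, max_size=12,
                            unique_by=lambda r: r.variant_key))
    calls = []
    for i in range(draw(st.integers(1, 4))):
        for r in records:
            geno = draw(st.sampled_from(list(Genotype)))
            depth = draw(st.one_of(st.none(), st.integers(0, 60)))
            calls.append(GenotypeCall(f"I{i}", r.variant_key, geno, depth))
    return records, calls


class TestFilterProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(cohort_st())
    def test_conjunction_matches_bruteforce(self, cohort):
        """Filter output equals an independent re-evaluation of the four
        predicates on every non-reference call."""
        records, calls = cohort
        by_key = {r.variant_key: r for r in records}
        got = {(c.individual_id, c.variant_key)
               for c in filter_high_impact(records, calls, {}, TH).calls}
        expected = set()
        for call in calls:
            r = by_key[call.variant_key]
            if call.genotype not in (Genotype.HET, Genotype.HOM_ALT):
                continue
            ok_qc = (r.site_qual >= TH.min_qual and call.depth is not None
                     and call.depth >= TH.min_depth)
            ok_rare = r.af_nfe is None or r.af_nfe < TH.max_af
            ok_cons = not (
                r.exonic_func is ExonicFunc.SYNONYMOUS
                or r.func_class in (FuncClass.INTRONIC, FuncClass.INTERGENIC)
            )
            ok_dmg = (
                r.clinvar_sig in (ClinvarSig.PATHOGENIC,
                                  ClinvarSig.LIKELY_PATHOGENIC)
                or all(r.predictor_calls.get(p) is PredictorCall.DAMAGING
                       for p in PREDICTORS)
            )
            if ok_qc and ok_rare and ok_cons and ok_dmg:
                expected.add((call.individual_id, call.variant_key))
        assert got == expected

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        cohort_st(),
        st.floats(0.0001, 0.01, allow_nan=False),
        st.floats(0, 60, allow_nan=False),
        st.integers(0, 40),
    )
    def test_stricter_thresholds_never_add_calls(self, cohort, max_af,
                                                 min_qual, min_depth):
        """Lowering max_af or raising min_qual/min_depth is antitone: the
        surviving call set can only shrink."""
        records, calls = cohort
        loose = filter_high_impact(records, calls, {}, TH)
        strict_th = dataclasses.replace(
            TH,
            max_af=min(TH.max_af, max_af),
            min_qual=max(TH.min_qual, min_qual),
            min_depth=max(TH.min_depth, min_depth),
        )
        strict = filter_high_impact(records, calls, {}, strict_th)
        loose_keys = {(c.individual_id, c.variant_key) for c in loose.calls}
        strict_keys = {(c.individual_id, c.variant_key) for c in strict.calls}
        assert strict_keys <= loose_keys


class TestPerIndividualCounts:
    def test_single_carrier_among_three(self):
        calls = [HighImpactCall("A", f"1-{i}-A-G", "G", CohortLabel.DISCOVERY)
                 for i in range(6)]
        df = per_individual_counts(calls, ["A", "B", "C"])
        assert sorted(df["count"]) == [0, 0, 6]
        assert df.attrs["mean"] == 2.0

    def test_counts_partition_calls(self):
        calls = [
            HighImpactCall(f"I{i % 4}", f"1-{i}-A-G", "G", CohortLabel.DISCOVERY)
            for i in range(10)
        ]
        df = per_individual_counts(calls)
        assert df["count"].sum() == 10

    def test_empty_table_flags_undefined_mean(self):
        df = per_individual_counts([])
        assert len(df) == 0
        assert df.attrs["mean"] is None

    def test_printed_totals_round_to_eleven(self):
        """580 high-impact calls across 53 individuals average 10.94,
        reported as 11 at integer precision."""
        ids = [f"I{i:02d}" for i in range(53)]
        calls = [
            HighImpactCall(ids[i % 53], f"1-{i}-A-G", f"G{i}",
                           CohortLabel.DISCOVERY)
            for i in range(580)
        ]
        df = per_individual_counts(calls, ids)
        assert df.attrs["mean"] == 10.94
        assert df.attrs["mean_rounded"] == 11
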