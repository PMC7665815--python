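"""Categorization-engine unit and property tests."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lirads_dta import (
    ApheSource,
    AphePattern,
    Diagnosis,
    GrowthClass,
    GrowthDialect,
    GrowthRecord,
    LesionObservation,
    LiradsCategory,
    SubtractionPattern,
    ValidationError,
    assign_category,
    classify_growth,
    table_cell_oracle,
)

settings.register_profile("repro", derandomize=True, max_examples=200)
settings.load_profile("repro")


def obs(**kw):
    defaults = dict(id="x", diagnosis=Diagnosis.HCC, size_mm=25.0)
    defaults.update(kw)
    return LesionObservation(**defaults)


class TestGrowthClassification:
    @pytest.mark.parametrize(
        "growth, dialect, expected",
        [
            # a doubling over more than six months is subthreshold under
            # v2018 but threshold under v2017
            (GrowthRecord(pct_increase=120, interval_months=8), GrowthDialect.V2018, GrowthClass.SUBTHRESHOLD),
            (GrowthRecord(pct_increase=120, interval_months=8), GrowthDialect.V2017, GrowthClass.THRESHOLD),
            (None, GrowthDialect.V2018, GrowthClass.NONE),
            # boundary inclusive: exactly 50% at exactly 6 months
            (GrowthRecord(pct_increase=50, interval_months=6), GrowthDialect.V2018, GrowthClass.THRESHOLD),
            (GrowthRecord(interval_months=12, is_new_nodule_ge10mm=True), GrowthDialect.V2018, GrowthClass.SUBTHRESHOLD),
            (GrowthRecord(interval_months=12, is_new_nodule_ge10mm=True), GrowthDialect.V2017, GrowthClass.THRESHOLD),
            # a new nodule observed after more than 24 months qualifies under
            # neither dialect
            (GrowthRecord(interval_months=30, is_new_nodule_ge10mm=True), GrowthDialect.V2017, GrowthClass.NONE),
            (GrowthRecord(pct_increase=30, interval_months=5, unequivocal_increase=True), GrowthDialect.V2018, GrowthClass.SUBTHRESHOLD),
        ],
    )
    def test_dialects(self, growth, dialect, expected):
        assert classify_growth(growth, dialect) is expected

    def test_negative_interval_rejected(self):
        with pytest.raises(ValidationError):
            GrowthRecord(pct_increase=50, interval_months=-1)


class TestAssignCategory:
    def test_no_aphe_washout_large_is_lr4(self):
        # washout without arterial hyperenhancement: one feature in the
        # no-APHE >=20 mm row
        a = assign_category(obs(size_mm=30, washout_pvp=True))
        assert a.category is LiradsCategory.LR4
        assert a.major_feature_count == 1 and not a.aphe_used

    def test_rim_aphe_is_lrm(self):
        a = assign_category(obs(size_mm=23, aphe_ordinary=AphePattern.RIM))
        assert a.category is LiradsCategory.LRM

    def test_global_subtraction_rescues_rim_to_lr5_with_growth(self):
        o = obs(
            size_mm=23,
            aphe_ordinary=AphePattern.RIM,
            aphe_subtraction=SubtractionPattern.GLOBAL,
            growth=GrowthRecord(pct_increase=60, interval_months=4),
        )
        assert assign_category(o).category is LiradsCategory.LRM
        a = assign_category(o, aphe_source=ApheSource.ORDINARY_OR_SUBTRACTION)
        assert a.category is LiradsCategory.LR5

    def test_aphe_washout_lr5_and_masked_washout_lr4(self):
        o = obs(size_mm=25, aphe_ordinary=AphePattern.NONRIM, washout_pvp=True)
        assert assign_category(o).category is LiradsCategory.LR5
        no_washout = obs(size_mm=25, aphe_ordinary=AphePattern.NONRIM)
        assert assign_category(no_washout).category is LiradsCategory.LR4

    def test_10_19mm_one_feature_cell_split(self):
        capsule = obs(size_mm=15, aphe_ordinary=AphePattern.NONRIM, enhancing_capsule=True)
        washout = obs(size_mm=15, aphe_ordinary=AphePattern.NONRIM, washout_pvp=True)
        assert assign_category(capsule).category is LiradsCategory.LR4
        assert assign_category(washout).category is LiradsCategory.LR5

    def test_benignity_gates_precede_everything(self):
        o = obs(size_mm=30, aphe_ordinary=AphePattern.NONRIM, washout_pvp=True,
                definite_benign=True)
        assert assign_category(o).category is LiradsCategory.LR1
        o2 = obs(size_mm=30, probable_benign=True)
        assert assign_category(o2).category is LiradsCategory.LR2

    def test_ancillary_upgrade_downgrade_and_conflict(self):
        from lirads_dta import AfMalignancyGeneral

        base = dict(size_mm=15, aphe_ordinary=AphePattern.NONRIM)
        af = frozenset({AfMalignancyGeneral.RESTRICTED_DIFFUSION})
        up = assign_category(obs(**base, af_malignancy_general=af))
        assert up.category is LiradsCategory.LR4 and up.upgraded_from_lr3
        down = assign_category(obs(**base, af_benign=frozenset({"ISO"})))
        assert down.category is LiradsCategory.LR2
        both = assign_category(
            obs(**base, af_malignancy_general=af, af_benign=frozenset({"ISO"}))
        )
        assert both.category is LiradsCategory.LR3

    def test_ancillary_never_creates_lr5(self):
        from lirads_dta import AfMalignancyGeneral

        o = obs(
            size_mm=30,
            aphe_ordinary=AphePattern.NONRIM,
            af_malignancy_general=frozenset({AfMalignancyGeneral.RESTRICTED_DIFFUSION}),
        )
        a = assign_category(o)
        assert a.pre_ancillary_category is LiradsCategory.LR4
        assert a.category is LiradsCategory.LR4

    def test_reader_override_wins_and_is_flagged(self):
        o = obs(size_mm=30, washout_pvp=True, reader_category_override=LiradsCategory.LR5)
        a = assign_category(o)
        assert a.category is LiradsCategory.LR5 and a.override_applied

    def test_missing_subtraction_reading_rejected(self):
        o = obs(size_mm=25, aphe_subtraction=None)
        with pytest.raises(ValidationError):
            assign_category(o, aphe_source=ApheSource.ORDINARY_OR_SUBTRACTION)


FEATURE_KW = {
    "washout": dict(washout_pvp=True),
    "capsule": dict(enhancing_capsule=True),
    "threshold_growth": dict(growth=GrowthRecord(pct_increase=60, interval_months=4)),
}


def test_exhaustive_table_agreement_with_oracle():
    """Engine step 3 equals the transcribed table over the full grid of
    APHE states, size bins and feature subsets."""
    for aphe, size, subset in itertools.product(
        (False, True),
        (5.0, 15.0, 25.0),
        itertools.chain.from_iterable(
            itertools.combinations(FEATURE_KW, r) for r in range(4)
        ),
    ):
        kw = {}
        for f in subset:
            kw.update(FEATURE_KW[f])
        o = obs(
            size_mm=size,
            aphe_ordinary=AphePattern.NONRIM if aphe else AphePattern.ABSENT,
            **kw,
        )
        got = assign_category(o).pre_ancillary_category
        assert got is table_cell_oracle(aphe, size, subset), (aphe, size, subset)


@st.composite
def table_inputs(draw):
    aphe = draw(st.booleans())
    size = draw(st.floats(min_value=1, max_value=120, allow_nan=False))
    subset = draw(st.sets(st.sampled_from(sorted(FEATURE_KW))))
    return aphe, size, subset


@given(table_inputs())
def test_no_aphe_never_lr5_pre_ancillary(inputs):
    aphe, size, subset = inputs
    kw = {}
    for f in subset:
        kw.update(FEATURE_KW[f])
    o = obs(size_mm=size, aphe_ordinary=AphePattern.NONRIM if aphe else AphePattern.ABSENT, **kw)
    a = assign_category(o)
    if not aphe:
        assert a.pre_ancillary_category is not LiradsCategory.LR5


@given(table_inputs(), st.sampled_from(sorted(FEATURE_KW)))
def test_adding_a_major_feature_never_lowers_category(inputs, extra):
    aphe, size, subset = inputs
    def build(fs):
        kw = {}
        for f in fs:
            kw.update(FEATURE_KW[f])
        return obs(
            size_mm=size,
            aphe_ordinary=AphePattern.NONRIM if aphe else AphePattern.ABSENT,
            **kw,
        )
    before = assign_category(build(subset)).pre_ancillary_category
    after = assign_category(build(subset | {extra})).pre_ancillary_category
    assert after >= before


def test_determinism(cohort):
    from lirads_dta import categorize_cohort

    assert categorize_cohort(cohort) == categorize_cohort(cohort)


def test_lrm_has_no_ordinal_rank():
    with pytest.raises(TypeError):
        LiradsCategory.LRM < LiradsCategory.LR5  # noqa: B015
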