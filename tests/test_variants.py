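"""Category-adjustment condition tests: per-condition behavior on the
reference cohort, and direction/idempotence properties on simulated data."""

import pytest

from lirads_dta import (
    ADJUSTMENT_VARIANTS,
    AfMalignancyGeneral,
    AphePattern,
    Diagnosis,
    LesionObservation,
    LiradsCategory,
    PositivityRule,
    VariantId,
    apply_variant,
    categorize_cohort,
    positivity,
)

C1 = VariantId.C1_AF_MALIGNANCY
C2 = VariantId.C2_AF_HCC
C3 = VariantId.C3_SUBTRACTION_APHE
C4 = VariantId.C4_WASHOUT_REQUIRES_APHE
C5 = VariantId.C5_TP_WASHOUT
C6 = VariantId.C6_SUBTHRESHOLD_AS_THRESHOLD


class TestReferenceCohortMoves:
    @pytest.mark.parametrize(
        "variant, n_hcc_moves, n_other_moves_to_lr5",
        [(C1, 83, 8), (C2, 36, 1)],
    )
    def test_af_upgrade_mover_counts(self, cohort, baseline, variant, n_hcc_moves, n_other_moves_to_lr5):
        _, audit = apply_variant(cohort, baseline, variant)
        diag = {o.id: o.diagnosis for o in cohort}
        hcc = [m for m in audit.moves if diag[m.observation_id] is Diagnosis.HCC]
        assert len(hcc) == n_hcc_moves
        assert len(audit.moves) - len(hcc) == n_other_moves_to_lr5
        assert all(
            m.category_before is LiradsCategory.LR4 and m.category_after is LiradsCategory.LR5
            for m in audit.moves
        )

    def test_c4_demotes_exactly_three_override_lr5s(self, cohort, baseline):
        _, audit = apply_variant(cohort, baseline, C4)
        demoted = [m for m in audit.moves if m.category_before is LiradsCategory.LR5]
        diag = {o.id: o.diagnosis for o in cohort}
        assert len(demoted) == 3
        assert all(m.category_after is LiradsCategory.LR4 for m in demoted)
        assert all(diag[m.observation_id] is Diagnosis.HCC for m in demoted)

    def test_c3_upgrades_include_one_lrm(self, cohort, baseline):
        _, audit = apply_variant(cohort, baseline, C3)
        to_lr5 = [m for m in audit.moves if m.category_after is LiradsCategory.LR5]
        assert len(to_lr5) == 13
        from_lrm = [m for m in to_lr5 if m.category_before is LiradsCategory.LRM]
        assert len(from_lrm) == 1

    def test_benign_af_blocks_upgrade(self, cohort, baseline):
        _, audit = apply_variant(cohort, baseline, C1)
        moved = {m.observation_id for m in audit.moves}
        blocked = [o.id for o in cohort if o.af_benign and o.af_malignancy_general]
        assert blocked and not moved & set(blocked)

    def test_af_upgraded_lr3_not_eligible(self, cohort, baseline):
        _, audit = apply_variant(cohort, baseline, C1)
        moved = {m.observation_id for m in audit.moves}
        provenance = {
            a.observation_id for a in baseline if a.upgraded_from_lr3
        }
        assert provenance and not moved & provenance

    def test_baseline_positivity_counts(self, baseline):
        assert positivity(baseline, PositivityRule.LR5_ONLY).sum() == 371
        assert positivity(baseline, PositivityRule.LR4_OR_LR5).sum() == 488

    def test_lrm_is_negative_under_both_rules(self):
        from lirads_dta.observations import LiradsAssignment

        cats = [LiradsCategory.LR5, LiradsCategory.LRM, LiradsCategory.LR4]
        assignments = [
            LiradsAssignment(observation_id=str(i), category=c, pre_ancillary_category=c)
            for i, c in enumerate(cats)
        ]
        assert list(positivity(assignments, PositivityRule.LR5_ONLY)) == [True, False, False]
        assert list(positivity(assignments, PositivityRule.LR4_OR_LR5)) == [True, False, True]


class TestVariantProperties:
    def test_c1_moves_superset_of_c2(self, sim_cohort, sim_baseline):
        _, a1 = apply_variant(sim_cohort, sim_baseline, C1)
        _, a2 = apply_variant(sim_cohort, sim_baseline, C2)
        ids1 = {m.observation_id for m in a1.moves}
        ids2 = {m.observation_id for m in a2.moves}
        assert ids2 <= ids1

    @pytest.mark.parametrize("variant", [C1, C2, C3, C5, C6])
    def test_upgrade_conditions_never_demote(self, sim_cohort, sim_baseline, variant):
        _, audit = apply_variant(sim_cohort, sim_baseline, variant)
        for m in audit.moves:
            if m.category_before.is_ordinal and m.category_after.is_ordinal:
                assert m.category_after >= m.category_before
            else:
                # only LR-M -> ordinal re-entries are possible
                assert m.category_before is LiradsCategory.LRM

    def test_c4_never_promotes(self, sim_cohort, sim_baseline):
        _, audit = apply_variant(sim_cohort, sim_baseline, C4)
        for m in audit.moves:
            assert m.category_after.is_ordinal
            if m.category_before.is_ordinal:
                assert m.category_after <= m.category_before

    @pytest.mark.parametrize("variant", list(ADJUSTMENT_VARIANTS))
    def test_idempotence(self, sim_cohort, sim_baseline, variant):
        once, _ = apply_variant(sim_cohort, sim_baseline, variant)
        twice, audit2 = apply_variant(sim_cohort, once, variant)
        assert [a.category for a in twice] == [a.category for a in once]

    @pytest.mark.parametrize("variant", list(ADJUSTMENT_VARIANTS))
    def test_lr1_lr2_untouched(self, sim_cohort, sim_baseline, variant):
        adjusted, _ = apply_variant(sim_cohort, sim_baseline, variant)
        for before, after in zip(sim_baseline, adjusted):
            if before.category in (LiradsCategory.LR1, LiradsCategory.LR2):
                assert after.category is before.category

    @pytest.mark.parametrize("variant", list(ADJUSTMENT_VARIANTS))
    def test_audit_conserves_positive_counts(self, sim_cohort, sim_baseline, variant):
        adjusted, audit = apply_variant(sim_cohort, sim_baseline, variant)
        before = positivity(sim_baseline, PositivityRule.LR5_ONLY).sum()
        after = positivity(adjusted, PositivityRule.LR5_ONLY).sum()
        inflow = sum(
            n
            for (a, b), n in audit.counts_by_transition.items()
            if b is LiradsCategory.LR5 and a is not LiradsCategory.LR5
        )
        outflow = sum(
            n
            for (a, b), n in audit.counts_by_transition.items()
            if a is LiradsCategory.LR5 and b is not LiradsCategory.LR5
        )
        assert after == before + inflow - outflow

    def test_counts_by_transition_sums_to_moves(self, sim_cohort, sim_baseline):
        _, audit = apply_variant(sim_cohort, sim_baseline, C1)
        assert sum(audit.counts_by_transition.values()) == len(audit.moves)
        assert all(a is not b for a, b in audit.counts_by_transition)
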