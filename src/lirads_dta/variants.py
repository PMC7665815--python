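"""The study's six category-adjustment conditions and positivity rules.

Each condition is evaluated independently from the default-parameter
baseline (conditions are never stacked):

C1  upgrade baseline LR-4 to LR-5 given any ancillary feature favoring
    malignancy in general (no benignity feature, not itself the product of
    an ancillary LR-3 -> LR-4 upgrade);
C2  as C1 but restricted to ancillary features favoring HCC in particular;
C3  re-read APHE on the arterial subtraction image (a global subtraction
    pattern counts as nonrim APHE and overrides an absent or rim ordinary
    reading);
C4  washout counts only in the presence of APHE; reader-overridden LR-5
    observations whose override was washout-dependent are demoted to LR-4;
C5  transitional-phase hypointensity also counts as washout (the matching
    ancillary feature is dropped for that evaluation so one finding is not
    counted twice);
C6  the v2017 threshold-growth definitions apply, promoting subthreshold
    growth to a major feature (again dropping the matching ancillary
    feature).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .engine import (
    ApheSource,
    GrowthClass,
    GrowthDialect,
    WashoutDef,
    assign_category,
    classify_growth,
)
from .observations import (
    AfMalignancyGeneral,
    LesionObservation,
    LiradsAssignment,
    LiradsCategory,
    ValidationError,
)

__all__ = [
    "VariantId",
    "PositivityRule",
    "Move",
    "ReclassificationAudit",
    "apply_variant",
    "positivity",
    "ADJUSTMENT_VARIANTS",
]


class VariantId(enum.Enum):
    BASELINE_LR5 = "baseline_lr5"
    BASELINE_LR45 = "baseline_lr45"
    C1_AF_MALIGNANCY = "c1"
    C2_AF_HCC = "c2"
    C3_SUBTRACTION_APHE = "c3"
    C4_WASHOUT_REQUIRES_APHE = "c4"
    C5_TP_WASHOUT = "c5"
    C6_SUBTHRESHOLD_AS_THRESHOLD = "c6"


ADJUSTMENT_VARIANTS = (
    VariantId.C1_AF_MALIGNANCY,
    VariantId.C2_AF_HCC,
    VariantId.C3_SUBTRACTION_APHE,
    VariantId.C4_WASHOUT_REQUIRES_APHE,
    VariantId.C5_TP_WASHOUT,
    VariantId.C6_SUBTHRESHOLD_AS_THRESHOLD,
)


class PositivityRule(enum.Enum):
    LR5_ONLY = "lr5"
    LR4_OR_LR5 = "lr45"


@dataclass(frozen=True)
class Move:
    observation_id: str
    category_before: LiradsCategory
    category_after: LiradsCategory
    reason: str


@dataclass(frozen=True)
class ReclassificationAudit:
    """Every category change a condition produced; identity transitions excluded."""

    variant: VariantId
    moves: tuple[Move, ...]

    @property
    def counts_by_transition(self) -> dict[tuple[LiradsCategory, LiradsCategory], int]:
        return dict(Counter((m.category_before, m.category_after) for m in self.moves))


def _af_upgrade_eligible(
    obs: LesionObservation, assignment: LiradsAssignment, hcc_specific_only: bool
) -> bool:
    if assignment.category is not LiradsCategory.LR4:
        return False
    if assignment.upgraded_from_lr3:
        return False
    if obs.af_benign:
        return False
    if hcc_specific_only:
        return bool(obs.af_hcc_specific)
    return bool(obs.af_malignancy_general or obs.af_hcc_specific)


def apply_variant(
    cohort: Sequence[LesionObservation],
    baseline: Sequence[LiradsAssignment],
    variant: VariantId,
) -> tuple[list[LiradsAssignment], ReclassificationAudit]:
    """Apply one condition to a baseline-categorized cohort.

    ``baseline`` must have been produced with default engine parameters
    (washout in the portal venous phase only, no APHE requirement for
    washout, ordinary arterial reading, v2018 growth dialect).
    """
    if len(cohort) != len(baseline):
        raise ValidationError("cohort and baseline lengths differ")
    for obs, a in zip(cohort, baseline):
        if obs.id != a.observation_id:
            raise ValidationError(
                f"cohort/baseline misaligned at observation {obs.id!r} vs {a.observation_id!r}"
            )

    if variant in (VariantId.BASELINE_LR5, VariantId.BASELINE_LR45):
        return list(baseline), ReclassificationAudit(variant=variant, moves=())

    if variant in (VariantId.C1_AF_MALIGNANCY, VariantId.C2_AF_HCC):
        hcc_only = variant is VariantId.C2_AF_HCC
        reason = "c2:af_hcc_upgrade" if hcc_only else "c1:af_malignancy_upgrade"
        out: list[LiradsAssignment] = []
        moves: list[Move] = []
        for obs, a in zip(cohort, baseline):
            if _af_upgrade_eligible(obs, a, hcc_only):
                out.append(
                    replace(a, category=LiradsCategory.LR5, trace=a.trace + (reason,))
                )
                moves.append(Move(obs.id, a.category, LiradsCategory.LR5, reason))
            else:
                out.append(a)
        return out, ReclassificationAudit(variant=variant, moves=tuple(moves))

    if variant is VariantId.C3_SUBTRACTION_APHE:
        missing = [o.id for o in cohort if o.aphe_subtraction is None]
        if missing:
            raise ValidationError(
                "subtraction readings required for the subtraction-APHE condition but "
                f"absent for: {', '.join(missing[:5])}"
                + ("..." if len(missing) > 5 else ""),
                field="aphe_subtraction",
            )
        recomputed = [
            assign_category(o, aphe_source=ApheSource.ORDINARY_OR_SUBTRACTION) for o in cohort
        ]
        return _audited(variant, cohort, baseline, recomputed, "c3:subtraction_aphe", clamp="up")

    if variant is VariantId.C4_WASHOUT_REQUIRES_APHE:
        out = []
        moves = []
        for obs, a in zip(cohort, baseline):
            new = assign_category(obs, washout_requires_aphe=True)
            if (
                new.override_applied
                and obs.reader_category_override is LiradsCategory.LR5
                and obs.override_washout_dependent
            ):
                new = replace(
                    new,
                    category=LiradsCategory.LR4,
                    trace=new.trace + ("c4:override_demoted",),
                )
                reason = "c4:override_demoted"
            else:
                reason = "c4:washout_masked"
            new = _clamped(a, new, "down")
            out.append(new)
            if new.category is not a.category:
                moves.append(Move(obs.id, a.category, new.category, reason))
        return out, ReclassificationAudit(variant=variant, moves=tuple(moves))

    if variant is VariantId.C5_TP_WASHOUT:
        modified = []
        for obs in cohort:
            if obs.tp_hypointensity and not obs.washout_pvp:
                # TP hypointensity is consumed as washout: do not also count
                # it as an ancillary feature
                modified.append(
                    obs.with_af_malignancy_removed(AfMalignancyGeneral.TP_HYPOINTENSITY)
                )
            else:
                modified.append(obs)
        recomputed = [
            assign_category(o, washout_def=WashoutDef.PVP_OR_TP) for o in modified
        ]
        return _audited(variant, cohort, baseline, recomputed, "c5:tp_washout", clamp="up")

    if variant is VariantId.C6_SUBTHRESHOLD_AS_THRESHOLD:
        modified = []
        for obs in cohort:
            promoted = (
                classify_growth(obs.growth, GrowthDialect.V2018) is not GrowthClass.THRESHOLD
                and classify_growth(obs.growth, GrowthDialect.V2017) is GrowthClass.THRESHOLD
            )
            if promoted:
                modified.append(
                    obs.with_af_malignancy_removed(AfMalignancyGeneral.SUBTHRESHOLD_GROWTH)
                )
            else:
                modified.append(obs)
        recomputed = [
            assign_category(o, growth_dialect=GrowthDialect.V2017) for o in modified
        ]
        return _audited(
            variant, cohort, baseline, recomputed, "c6:threshold_growth_v2017", clamp="up"
        )

    raise ValidationError(f"unknown variant {variant!r}", field="variant")


def _clamped(base: LiradsAssignment, new: LiradsAssignment, clamp: str) -> LiradsAssignment:
    """Hold a recomputed assignment to the direction its condition permits.

    The re-reading conditions are readjustments of specific findings, not a
    second blank-slate read: observations already resolved as LR-1/LR-2
    stay put, the evidence-extending conditions (subtraction APHE, TP
    washout, v2017 growth) never lower a category, and masking washout
    never raises one.
    """
    if base.category in (LiradsCategory.LR1, LiradsCategory.LR2):
        return base
    if base.category.is_ordinal and new.category.is_ordinal:
        if clamp == "up" and new.category < base.category:
            return base
        if clamp == "down" and new.category > base.category:
            return base
    return new


def _audited(variant, cohort, baseline, recomputed, reason, clamp):
    out = [_clamped(a, n, clamp) for a, n in zip(baseline, recomputed)]
    moves = tuple(
        Move(obs.id, a.category, n.category, reason)
        for obs, a, n in zip(cohort, baseline, out)
        if n.category is not a.category
    )
    return out, ReclassificationAudit(variant=variant, moves=moves)


def positivity(
    assignments: Iterable[LiradsAssignment], rule: PositivityRule
) -> np.ndarray:
    """Boolean test-positive vector under a positivity rule (LR-M is negative)."""
    cats = [a.category for a in assignments]
    if rule is PositivityRule.LR5_ONLY:
        return np.array([c is LiradsCategory.LR5 for c in cats], dtype=bool)
    if rule is PositivityRule.LR4_OR_LR5:
        return np.array(
            [c in (LiradsCategory.LR4, LiradsCategory.LR5) for c in cats], dtype=bool
        )
    raise ValidationError(f"unknown positivity rule {rule!r}", field="rule")
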