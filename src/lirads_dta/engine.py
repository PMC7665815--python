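"""Deterministic LI-RADS v2018 categorization engine.

The engine evaluates one observation at a time, in a fixed order:

1. benignity gates (definitely benign -> LR-1, probably benign -> LR-2);
2. targetoid gate: rim arterial enhancement or any other targetoid feature
   sends the observation to LR-M;
3. the v2018 major-feature diagnostic table over effective arterial-phase
   hyperenhancement (APHE), size, nonperipheral washout, enhancing capsule
   and threshold growth;
4. ancillary-feature adjustment by at most one category, never creating
   LR-5;
5. an optional reader-assigned category override.

The evaluation is parameterized so that the study's modified criteria are
expressible: where washout may be read (portal venous phase only, or also
transitional-phase hypointensity), whether washout requires APHE, whether
APHE may be rescued from the arterial subtraction image, and which growth
dialect (v2018 or v2017) defines threshold growth.

Size bins are half-open: <10, [10, 20), >=20 mm.  A 10-19 mm observation
with nonrim APHE and exactly one additional feature is LR-5 when that
feature is washout or threshold growth and LR-4 when it is capsule alone.
"""

from __future__ import annotations

import enum
from typing import Iterable, Optional, Sequence

from .observations import (
    AphePattern,
    GrowthRecord,
    LesionObservation,
    LiradsAssignment,
    LiradsCategory,
    SubtractionPattern,
    ValidationError,
)

__all__ = [
    "WashoutDef",
    "ApheSource",
    "GrowthDialect",
    "GrowthClass",
    "classify_growth",
    "assign_category",
    "categorize_cohort",
    "table_cell_oracle",
]


class WashoutDef(enum.Enum):
    """Which phases count toward washout."""

    PVP_ONLY = "PVP_ONLY"
    PVP_OR_TP = "PVP_OR_TP"


class ApheSource(enum.Enum):
    """Which reading defines effective APHE."""

    ORDINARY = "ORDINARY"
    ORDINARY_OR_SUBTRACTION = "ORDINARY_OR_SUBTRACTION"


class GrowthDialect(enum.Enum):
    V2018 = "V2018"
    V2017 = "V2017"


class GrowthClass(enum.Enum):
    NONE = "NONE"
    SUBTHRESHOLD = "SUBTHRESHOLD"
    THRESHOLD = "THRESHOLD"


def classify_growth(g: Optional[GrowthRecord], dialect: GrowthDialect = GrowthDialect.V2018) -> GrowthClass:
    """Classify a growth record as threshold growth, subthreshold growth, or none.

    Under v2018 only ">=50% size increase within <=6 months" is threshold
    growth; a >=100% increase over more than 6 months and a new >=10 mm
    nodule within 24 months are subthreshold.  Under v2017 all three
    definitions count as threshold growth.  Boundaries are inclusive.
    """
    if g is None:
        return GrowthClass.NONE
    fifty_in_six = g.pct_increase >= 50 and g.interval_months <= 6
    hundred_beyond_six = g.pct_increase >= 100 and g.interval_months > 6
    new_nodule = g.is_new_nodule_ge10mm and g.interval_months <= 24
    if dialect is GrowthDialect.V2017:
        if fifty_in_six or hundred_beyond_six or new_nodule:
            return GrowthClass.THRESHOLD
        return GrowthClass.SUBTHRESHOLD if g.unequivocal_increase else GrowthClass.NONE
    if dialect is GrowthDialect.V2018:
        if fifty_in_six:
            return GrowthClass.THRESHOLD
        if g.unequivocal_increase or hundred_beyond_six or new_nodule:
            return GrowthClass.SUBTHRESHOLD
        return GrowthClass.NONE
    raise ValidationError(f"unknown growth dialect {dialect!r}", field="growth_dialect")


def _size_bin(size_mm: float) -> str:
    if size_mm < 10:
        return "lt10"
    if size_mm < 20:
        return "10to19"
    return "ge20"


def _major_feature_table(aphe_nonrim: bool, size_mm: float, features: frozenset[str]) -> LiradsCategory:
    """The v2018 diagnostic table (additional features: washout, capsule,
    threshold growth), expressed as count logic."""
    n = len(features)
    if not aphe_nonrim:
        if size_mm < 20:
            return LiradsCategory.LR4 if n >= 2 else LiradsCategory.LR3
        return LiradsCategory.LR4 if n >= 1 else LiradsCategory.LR3
    if size_mm < 10:
        return LiradsCategory.LR4 if n >= 1 else LiradsCategory.LR3
    if size_mm < 20:
        if n == 0:
            return LiradsCategory.LR3
        if "washout" in features or "threshold_growth" in features:
            return LiradsCategory.LR5
        return LiradsCategory.LR4  # capsule alone
    return LiradsCategory.LR5 if n >= 1 else LiradsCategory.LR4


def _effective_aphe(obs: LesionObservation, aphe_source: ApheSource) -> tuple[AphePattern, bool]:
    """Return (effective pattern, whether subtraction rescued it).

    With ORDINARY_OR_SUBTRACTION, a GLOBAL subtraction pattern overrides both
    an ABSENT and a RIM ordinary reading and counts as nonrim APHE; a RIM
    subtraction pattern never rescues anything.
    """
    if aphe_source is ApheSource.ORDINARY:
        return obs.aphe_ordinary, False
    if aphe_source is ApheSource.ORDINARY_OR_SUBTRACTION:
        if obs.aphe_subtraction is None:
            raise ValidationError(
                f"{obs.id}: subtraction reading required but absent", field="aphe_subtraction"
            )
        if obs.aphe_subtraction is SubtractionPattern.GLOBAL and obs.aphe_ordinary is not AphePattern.NONRIM:
            return AphePattern.NONRIM, True
        return obs.aphe_ordinary, False
    raise ValidationError(f"unknown APHE source {aphe_source!r}", field="aphe_source")


def assign_category(
    obs: LesionObservation,
    washout_def: WashoutDef = WashoutDef.PVP_ONLY,
    washout_requires_aphe: bool = False,
    aphe_source: ApheSource = ApheSource.ORDINARY,
    growth_dialect: GrowthDialect = GrowthDialect.V2018,
) -> LiradsAssignment:
    """Assign a LI-RADS category to one untreated, non-tumor-in-vein observation."""
    trace: list[str] = []

    if obs.definite_benign:
        cat = LiradsCategory.LR1
        trace.append("gate:definitely_benign")
        return _finish(obs, cat, cat, 0, False, False, False, trace)
    if obs.probable_benign:
        cat = LiradsCategory.LR2
        trace.append("gate:probably_benign")
        return _finish(obs, cat, cat, 0, False, False, False, trace)

    effective_aphe, rescued = _effective_aphe(obs, aphe_source)
    if rescued:
        trace.append("aphe:subtraction_global")
    if effective_aphe is AphePattern.RIM or obs.targetoid_other:
        trace.append("gate:targetoid")
        cat = LiradsCategory.LRM
        return _finish(obs, cat, cat, 0, False, False, False, trace)

    aphe_nonrim = effective_aphe is AphePattern.NONRIM
    if washout_def is WashoutDef.PVP_ONLY:
        washout = obs.washout_pvp
    elif washout_def is WashoutDef.PVP_OR_TP:
        washout = obs.washout_pvp or obs.tp_hypointensity
    else:
        raise ValidationError(f"unknown washout definition {washout_def!r}", field="washout_def")
    if washout_requires_aphe and not aphe_nonrim:
        if washout:
            trace.append("washout:masked_no_aphe")
        washout = False

    growth_class = classify_growth(obs.growth, growth_dialect)
    features = set()
    if washout:
        features.add("washout")
    if obs.enhancing_capsule:
        features.add("capsule")
    if growth_class is GrowthClass.THRESHOLD:
        features.add("threshold_growth")
    features = frozenset(features)

    pre = _major_feature_table(aphe_nonrim, obs.size_mm, features)
    trace.append(
        f"table:{'aphe' if aphe_nonrim else 'no_aphe'}:{_size_bin(obs.size_mm)}:n{len(features)}"
    )

    cat = pre
    upgraded_from_lr3 = False
    has_malig_af = bool(obs.af_malignancy_general or obs.af_hcc_specific)
    has_benign_af = bool(obs.af_benign)
    if has_malig_af and has_benign_af:
        trace.append("af:conflict_no_change")
    elif has_malig_af:
        if cat is LiradsCategory.LR3:
            cat = LiradsCategory.LR4
            upgraded_from_lr3 = True
            trace.append("af:upgrade_lr3_to_lr4")
        elif cat is LiradsCategory.LR4:
            trace.append("af:upgrade_capped_lr4")
        # LR-5 cannot be created (or exceeded) by ancillary features
    elif has_benign_af:
        if cat.rank > 1:
            cat = cat.down()
            trace.append("af:downgrade")

    return _finish(
        obs, cat, pre, len(features), aphe_nonrim, washout, upgraded_from_lr3, trace
    )


def _finish(obs, cat, pre, n_features, aphe_used, washout_used, upgraded_from_lr3, trace):
    override_applied = False
    if obs.reader_category_override is not None:
        cat = obs.reader_category_override
        override_applied = True
        trace.append("override:reader_category")
    return LiradsAssignment(
        observation_id=obs.id,
        category=cat,
        pre_ancillary_category=pre,
        major_feature_count=n_features,
        aphe_used=aphe_used,
        washout_used=washout_used,
        upgraded_from_lr3=upgraded_from_lr3 or obs.upgraded_from_lr3,
        override_applied=override_applied,
        trace=tuple(trace),
    )


def categorize_cohort(
    cohort: Iterable[LesionObservation], **params
) -> list[LiradsAssignment]:
    """Run :func:`assign_category` over a cohort, preserving order."""
    return [assign_category(obs, **params) for obs in cohort]


# ---------------------------------------------------------------------------
# Independent transcription of the diagnostic table, used as a test oracle.
# Direct lookup over the full cross product of APHE state, size bin and
# additional-feature subset; deliberately not shared with the rule logic
# above.

_W, _C, _G = "washout", "capsule", "threshold_growth"
_SUBSETS = [
    frozenset(),
    frozenset({_W}),
    frozenset({_C}),
    frozenset({_G}),
    frozenset({_W, _C}),
    frozenset({_W, _G}),
    frozenset({_C, _G}),
    frozenset({_W, _C, _G}),
]

_TABLE_ORACLE: dict[tuple[bool, str, frozenset[str]], LiradsCategory] = {}
for _s in _SUBSETS:
    # no APHE, <20 mm: LR-3 for 0-1 features, LR-4 for >=2
    _TABLE_ORACLE[(False, "lt10", _s)] = (
        LiradsCategory.LR4 if len(_s) >= 2 else LiradsCategory.LR3
    )
    _TABLE_ORACLE[(False, "10to19", _s)] = (
        LiradsCategory.LR4 if len(_s) >= 2 else LiradsCategory.LR3
    )
    # no APHE, >=20 mm: LR-3 for 0, LR-4 for >=1
    _TABLE_ORACLE[(False, "ge20", _s)] = (
        LiradsCategory.LR4 if len(_s) >= 1 else LiradsCategory.LR3
    )
    # nonrim APHE, <10 mm: LR-3 for 0, LR-4 for >=1
    _TABLE_ORACLE[(True, "lt10", _s)] = (
        LiradsCategory.LR4 if len(_s) >= 1 else LiradsCategory.LR3
    )
    # nonrim APHE, 10-19 mm: capsule-only cell splits from washout/growth
    if len(_s) == 0:
        _TABLE_ORACLE[(True, "10to19", _s)] = LiradsCategory.LR3
    elif _W in _s or _G in _s:
        _TABLE_ORACLE[(True, "10to19", _s)] = LiradsCategory.LR5
    else:
        _TABLE_ORACLE[(True, "10to19", _s)] = LiradsCategory.LR4
    # nonrim APHE, >=20 mm: LR-4 for 0, LR-5 for >=1
    _TABLE_ORACLE[(True, "ge20", _s)] = (
        LiradsCategory.LR5 if len(_s) >= 1 else LiradsCategory.LR4
    )


def table_cell_oracle(aphe: bool, size_mm: float, features: Iterable[str]) -> LiradsCategory:
    """Category of one diagnostic-table cell by direct lookup.

    ``features`` must be a subset of {washout, capsule, threshold_growth}.
    """
    fs = frozenset(features)
    unknown = fs - {_W, _C, _G}
    if unknown:
        raise ValidationError(f"unknown feature token(s): {sorted(unknown)}", field="features")
    return _TABLE_ORACLE[(bool(aphe), _size_bin(size_mm), fs)]
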