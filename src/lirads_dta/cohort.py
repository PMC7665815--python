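"""Cohort reconstruction and simulation.

:func:`build_reference_cohort` deterministically reconstructs a
792-observation cohort (508 HCC, 55 non-HCC malignancies, 229 benign
lesions) whose baseline LI-RADS v2018 categories and per-condition
reclassification counts match the published accuracy table exactly.  The
cohort is assembled from named strata - groups of identical feature
vectors - so every count is auditable: each stratum is designed to land in
one baseline category and to respond (or not) to each of the six
category-adjustment conditions.

:func:`simulate_cohort` draws arbitrary cohorts from a diagnosis-
conditional feature model for property testing; it shares the record
vocabulary but none of the fixed counts.

:func:`validate_constraints` re-derives every constrained count from a
cohort by running the categorization engine and the adjustment conditions,
and reports HARD (must hold) and SOFT (narrative; may deviate with a
logged note) constraints separately.  Expected values live in the
versioned ``resources/constraints.yaml``.
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import yaml

from .engine import GrowthClass, GrowthDialect, categorize_cohort, classify_growth
from .observations import (
    AfHccSpecific,
    AfMalignancyGeneral,
    AphePattern,
    Diagnosis,
    GrowthRecord,
    LesionObservation,
    LiradsCategory,
    SubtractionPattern,
)
from .variants import ADJUSTMENT_VARIANTS, PositivityRule, VariantId, apply_variant, positivity
from .stats import confusion, truth_vector

__all__ = [
    "build_reference_cohort",
    "simulate_cohort",
    "SimulationParams",
    "ClassFeatureProbs",
    "validate_constraints",
    "load_constraints",
    "ConstraintResult",
    "ConstraintReport",
]

# ---------------------------------------------------------------------------
# Reference cohort strata

_G_SUB_PCT = GrowthRecord(pct_increase=120.0, interval_months=8.0)
_G_SUB_NODULE = GrowthRecord(interval_months=12.0, is_new_nodule_ge10mm=True)
_G_THRESHOLD = GrowthRecord(pct_increase=60.0, interval_months=4.0)

_AF_TP = frozenset({AfMalignancyGeneral.TP_HYPOINTENSITY})
_AF_SUBTHR = frozenset({AfMalignancyGeneral.SUBTHRESHOLD_GROWTH})
_HCC_AF_CYCLE = (
    AfHccSpecific.MOSAIC,
    AfHccSpecific.NODULE_IN_NODULE,
    AfHccSpecific.NONENHANCING_CAPSULE,
    AfHccSpecific.INTRALESIONAL_FAT,
    AfHccSpecific.BLOOD_PRODUCTS,
)

_HCC = Diagnosis.HCC
_MAL = Diagnosis.NON_HCC_MALIGNANCY
_BEN = Diagnosis.BENIGN

# (stratum name, count, diagnosis, record template kwargs).  Strata whose
# qualifying HCC-specific AF or growth form varies cycle deterministically
# through a short list (see _expand).
_STRATA: tuple[tuple[str, int, Diagnosis, dict], ...] = (
    # --- HCC, baseline LR-5 -------------------------------------------------
    ("lr5_aphe_washout_large", 267, _HCC,
     dict(size_mm=28, aphe_ordinary=AphePattern.NONRIM, washout_pvp=True)),
    ("lr5_aphe_washout_small", 71, _HCC,
     dict(size_mm=15, aphe_ordinary=AphePattern.NONRIM, washout_pvp=True)),
    ("lr5_subthreshold_growth", 8, _HCC,
     dict(size_mm=30, aphe_ordinary=AphePattern.NONRIM, washout_pvp=True,
          growth=_G_SUB_PCT, af_malignancy_general=_AF_SUBTHR)),
    ("lr5_tp_capsule", 16, _HCC,
     dict(size_mm=25, aphe_ordinary=AphePattern.NONRIM, enhancing_capsule=True,
          tp_hypointensity=True, af_malignancy_general=_AF_TP)),
    # three reader-overridden LR-5s: no APHE, washout-dependent override;
    # one also shows a global subtraction pattern
    ("lr5_override_washout", 2, _HCC,
     dict(size_mm=32, washout_pvp=True,
          reader_category_override=LiradsCategory.LR5, override_washout_dependent=True)),
    ("lr5_override_washout_subtr", 1, _HCC,
     dict(size_mm=32, washout_pvp=True, aphe_subtraction=SubtractionPattern.GLOBAL,
          reader_category_override=LiradsCategory.LR5, override_washout_dependent=True)),
    # --- HCC, baseline LR-4 -------------------------------------------------
    ("lr4_subtraction_aphe", 12, _HCC,
     dict(size_mm=30, washout_pvp=True, aphe_subtraction=SubtractionPattern.GLOBAL)),
    ("lr4_tp_aphe", 19, _HCC,
     dict(size_mm=26, aphe_ordinary=AphePattern.NONRIM, tp_hypointensity=True,
          af_malignancy_general=_AF_TP)),
    ("lr4_tp_no_aphe", 1, _HCC,
     dict(size_mm=24, enhancing_capsule=True, tp_hypointensity=True,
          af_malignancy_general=_AF_TP)),
    ("lr4_growth_aphe", 15, _HCC,
     dict(size_mm=27, aphe_ordinary=AphePattern.NONRIM, growth="cycle_subthreshold",
          af_malignancy_general=_AF_SUBTHR)),
    ("lr4_growth_no_aphe", 7, _HCC,
     dict(size_mm=29, washout_pvp=True, growth=_G_SUB_NODULE,
          af_malignancy_general=_AF_SUBTHR)),
    ("lr4_hcc_af_no_aphe", 33, _HCC,
     dict(size_mm=25, washout_pvp=True, af_hcc_specific="cycle_hcc_af")),
    ("lr4_hcc_af_aphe", 3, _HCC,
     dict(size_mm=22, aphe_ordinary=AphePattern.NONRIM,
          af_hcc_specific=frozenset({AfHccSpecific.NODULE_IN_NODULE}))),
    ("lr4_small_diffusion", 5, _HCC,
     dict(size_mm=8, aphe_ordinary=AphePattern.NONRIM, washout_pvp=True,
          af_malignancy_general=frozenset({AfMalignancyGeneral.RESTRICTED_DIFFUSION}))),
    ("lr4_no_aphe_washout", 6, _HCC,
     dict(size_mm=30, washout_pvp=True)),
    ("lr4_conflicting_af", 3, _HCC,
     dict(size_mm=26, washout_pvp=True,
          af_malignancy_general=frozenset({AfMalignancyGeneral.MILD_MODERATE_T2_HYPER}),
          af_benign=frozenset({"HBP_ISOINTENSITY"}))),
    ("lr4_upgraded_from_lr3", 3, _HCC,
     dict(size_mm=15, aphe_ordinary=AphePattern.NONRIM,
          af_malignancy_general=frozenset({AfMalignancyGeneral.RESTRICTED_DIFFUSION}))),
    # --- HCC, baseline LR-M -------------------------------------------------
    ("lrm_rim_subtraction_growth", 1, _HCC,
     dict(size_mm=23, aphe_ordinary=AphePattern.RIM,
          aphe_subtraction=SubtractionPattern.GLOBAL, growth=_G_THRESHOLD)),
    ("lrm_rim_tp", 3, _HCC,
     dict(size_mm=28, aphe_ordinary=AphePattern.RIM,
          aphe_subtraction=SubtractionPattern.RIM, tp_hypointensity=True,
          af_malignancy_general=_AF_TP)),
    ("lrm_rim_washout", 4, _HCC,
     dict(size_mm=30, aphe_ordinary=AphePattern.RIM,
          aphe_subtraction=SubtractionPattern.RIM, washout_pvp=True)),
    ("lrm_rim", 12, _HCC,
     dict(size_mm=30, aphe_ordinary=AphePattern.RIM,
          aphe_subtraction=SubtractionPattern.RIM)),
    # --- HCC, baseline LR-3 -------------------------------------------------
    ("lr3_washout_small", 13, _HCC, dict(size_mm=15, washout_pvp=True)),
    ("lr3_subtraction_small", 3, _HCC,
     dict(size_mm=15, aphe_subtraction=SubtractionPattern.GLOBAL)),
    # --- non-HCC malignancies ----------------------------------------------
    ("lrm_rim_malignancy", 40, _MAL,
     dict(size_mm=35, aphe_ordinary=AphePattern.RIM,
          aphe_subtraction=SubtractionPattern.RIM, targetoid_other=True)),
    ("lr3_malignancy", 5, _MAL, dict(size_mm=25)),
    ("lr5_fp_malignancy", 4, _MAL,
     dict(size_mm=30, aphe_ordinary=AphePattern.NONRIM, washout_pvp=True)),
    ("lr4_hcc_af_malignancy", 1, _MAL,
     dict(size_mm=28, washout_pvp=True,
          af_hcc_specific=frozenset({AfHccSpecific.MOSAIC}))),
    ("lr4_tp_malignancy", 2, _MAL,
     dict(size_mm=27, aphe_ordinary=AphePattern.NONRIM, tp_hypointensity=True,
          af_malignancy_general=_AF_TP)),
    ("lr4_growth_malignancy", 2, _MAL,
     dict(size_mm=30, washout_pvp=True, growth=_G_SUB_PCT,
          af_malignancy_general=_AF_SUBTHR)),
    ("lr4_plain_malignancy", 1, _MAL,
     dict(size_mm=24, aphe_ordinary=AphePattern.NONRIM)),
    # --- benign lesions -----------------------------------------------------
    ("lr1_benign", 116, _BEN, dict(size_mm=12, definite_benign=True)),
    ("lr2_benign", 52, _BEN, dict(size_mm=10, probable_benign=True)),
    ("lr3_benign", 42, _BEN, dict(size_mm=12)),
    ("lrm_benign", 13, _BEN, dict(size_mm=18, targetoid_other=True)),
    ("lr5_fp_benign", 2, _BEN,
     dict(size_mm=22, aphe_ordinary=AphePattern.NONRIM, washout_pvp=True)),
    ("lr4_tp_benign", 1, _BEN,
     dict(size_mm=25, aphe_ordinary=AphePattern.NONRIM, tp_hypointensity=True,
          af_malignancy_general=_AF_TP)),
    ("lr4_growth_benign", 2, _BEN,
     dict(size_mm=26, washout_pvp=True, growth=_G_SUB_PCT,
          af_malignancy_general=_AF_SUBTHR)),
    ("lr4_plain_benign", 1, _BEN,
     dict(size_mm=21, aphe_ordinary=AphePattern.NONRIM)),
)

_GROWTH_CYCLE = (_G_SUB_PCT, _G_SUB_NODULE)


def build_reference_cohort() -> list[LesionObservation]:
    """Deterministically reconstruct the 792-observation study cohort.

    Fully deterministic: no randomness, stable stratum and record ordering,
    bit-identical across runs and platforms.
    """
    out: list[LesionObservation] = []
    for name, count, diagnosis, template in _STRATA:
        for i in range(count):
            kwargs = dict(template)
            if kwargs.get("growth") == "cycle_subthreshold":
                kwargs["growth"] = _GROWTH_CYCLE[i % len(_GROWTH_CYCLE)]
            if kwargs.get("af_hcc_specific") == "cycle_hcc_af":
                kwargs["af_hcc_specific"] = frozenset({_HCC_AF_CYCLE[i % len(_HCC_AF_CYCLE)]})
            out.append(
                LesionObservation(id=f"{name}-{i + 1:03d}", diagnosis=diagnosis, **kwargs)
            )
    return out


# ---------------------------------------------------------------------------
# Stochastic simulator


@dataclass(frozen=True)
class ClassFeatureProbs:
    """Feature prevalences conditional on one diagnosis class."""

    p_aphe_nonrim: float = 0.0
    p_aphe_rim: float = 0.0
    p_subtraction_global: float = 0.0  # given ordinary reading not nonrim
    p_washout_pvp: float = 0.0
    p_tp_hypointensity: float = 0.0
    p_hbp_hypointensity: float = 0.0
    p_capsule: float = 0.0
    p_targetoid_other: float = 0.0
    p_growth: float = 0.0
    p_growth_threshold: float = 0.0  # given a growth record, v2018-threshold form
    p_af_general: float = 0.0  # per-feature inclusion, general-malignancy AFs
    p_af_hcc: float = 0.0  # per-feature inclusion, HCC-specific AFs
    p_af_benign: float = 0.0
    p_definite_benign: float = 0.0
    p_probable_benign: float = 0.0

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_aphe_nonrim + self.p_aphe_rim > 1.0:
            raise ValueError("APHE pattern probabilities exceed 1")
        if self.p_definite_benign + self.p_probable_benign > 1.0:
            raise ValueError("benignity gate probabilities exceed 1")


# Defaults emulate the study cohort: 84% of HCCs show APHE ((508-81)/508),
# 85% show portal venous washout (432/508), roughly one in five no-APHE
# HCCs lights up on the subtraction image, and class prevalences follow the
# 508/55/229 composition.
_DEFAULT_CLASS_PROBS: dict[Diagnosis, ClassFeatureProbs] = {
    Diagnosis.HCC: ClassFeatureProbs(
        p_aphe_nonrim=0.80, p_aphe_rim=0.04, p_subtraction_global=0.20,
        p_washout_pvp=0.85, p_tp_hypointensity=0.50, p_hbp_hypointensity=0.70,
        p_capsule=0.35, p_targetoid_other=0.02, p_growth=0.12,
        p_growth_threshold=0.30, p_af_general=0.20, p_af_hcc=0.10,
        p_af_benign=0.02,
    ),
    Diagnosis.NON_HCC_MALIGNANCY: ClassFeatureProbs(
        p_aphe_nonrim=0.15, p_aphe_rim=0.65, p_subtraction_global=0.05,
        p_washout_pvp=0.30, p_tp_hypointensity=0.30, p_hbp_hypointensity=0.60,
        p_capsule=0.10, p_targetoid_other=0.30, p_growth=0.05,
        p_growth_threshold=0.50, p_af_general=0.25, p_af_hcc=0.02,
        p_af_benign=0.05,
    ),
    Diagnosis.BENIGN: ClassFeatureProbs(
        p_aphe_nonrim=0.06, p_aphe_rim=0.02, p_subtraction_global=0.02,
        p_washout_pvp=0.08, p_tp_hypointensity=0.05, p_hbp_hypointensity=0.15,
        p_capsule=0.02, p_targetoid_other=0.05, p_growth=0.02,
        p_growth_threshold=0.10, p_af_general=0.05, p_af_hcc=0.0,
        p_af_benign=0.50, p_definite_benign=0.50, p_probable_benign=0.23,
    ),
}


@dataclass(frozen=True)
class SimulationParams:
    """Generative model for cohorts of lesion observations."""

    n_observations: int = 792
    prevalence: tuple[float, float, float] = (508 / 792, 55 / 792, 229 / 792)
    class_probs: dict = field(default_factory=lambda: dict(_DEFAULT_CLASS_PROBS))
    seed: int = 0

    def __post_init__(self):
        if self.n_observations <= 0:
            raise ValueError("n_observations must be positive")
        p = np.asarray(self.prevalence, dtype=float)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("prevalences must be non-negative and sum to 1")


_SIZE_LOGNORM = {  # (mean, sigma) of log size in mm, per class
    Diagnosis.HCC: (3.3, 0.45),
    Diagnosis.NON_HCC_MALIGNANCY: (3.5, 0.45),
    Diagnosis.BENIGN: (2.4, 0.5),
}

_GENERAL_AF_FREE = (  # general AFs with no paired presence flag
    AfMalignancyGeneral.RESTRICTED_DIFFUSION,
    AfMalignancyGeneral.MILD_MODERATE_T2_HYPER,
    AfMalignancyGeneral.CORONA_ENHANCEMENT,
    AfMalignancyGeneral.FAT_SPARING,
    AfMalignancyGeneral.IRON_SPARING,
)


def simulate_cohort(params: SimulationParams) -> list[LesionObservation]:
    """Draw a reproducible random cohort from the diagnosis-conditional model.

    Every generated record satisfies :class:`LesionObservation` validation;
    marginal feature frequencies converge to the per-class probabilities as
    the cohort grows.
    """
    rng = np.random.default_rng(params.seed)
    classes = (Diagnosis.HCC, Diagnosis.NON_HCC_MALIGNANCY, Diagnosis.BENIGN)
    draws = rng.choice(3, size=params.n_observations, p=np.asarray(params.prevalence))
    out: list[LesionObservation] = []
    for i, ci in enumerate(draws):
        diagnosis = classes[int(ci)]
        cp: ClassFeatureProbs = params.class_probs[diagnosis]
        mu, sigma = _SIZE_LOGNORM[diagnosis]
        size = float(np.clip(rng.lognormal(mu, sigma), 3.0, 150.0))

        definite = rng.random() < cp.p_definite_benign
        probable = (not definite) and rng.random() < cp.p_probable_benign

        u = rng.random()
        if u < cp.p_aphe_nonrim:
            aphe = AphePattern.NONRIM
        elif u < cp.p_aphe_nonrim + cp.p_aphe_rim:
            aphe = AphePattern.RIM
        else:
            aphe = AphePattern.ABSENT
        if aphe is AphePattern.NONRIM:
            subtraction = SubtractionPattern.GLOBAL
        elif rng.random() < cp.p_subtraction_global:
            subtraction = SubtractionPattern.GLOBAL
        else:
            subtraction = (
                SubtractionPattern.RIM if aphe is AphePattern.RIM else SubtractionPattern.ABSENT
            )

        washout = rng.random() < cp.p_washout_pvp
        tp = rng.random() < cp.p_tp_hypointensity
        hbp = rng.random() < cp.p_hbp_hypointensity
        capsule = rng.random() < cp.p_capsule
        targetoid_other = rng.random() < cp.p_targetoid_other

        growth: Optional[GrowthRecord] = None
        if rng.random() < cp.p_growth:
            if rng.random() < cp.p_growth_threshold:
                growth = GrowthRecord(pct_increase=60.0, interval_months=4.0)
            elif rng.random() < 0.5:
                growth = GrowthRecord(pct_increase=120.0, interval_months=8.0)
            else:
                growth = GrowthRecord(interval_months=12.0, is_new_nodule_ge10mm=True)

        af_general: set[AfMalignancyGeneral] = set()
        for af in _GENERAL_AF_FREE:
            if rng.random() < cp.p_af_general:
                af_general.add(af)
        if tp and rng.random() < cp.p_af_general:
            af_general.add(AfMalignancyGeneral.TP_HYPOINTENSITY)
        if hbp and rng.random() < cp.p_af_general:
            af_general.add(AfMalignancyGeneral.HBP_HYPOINTENSITY)
        if (
            growth is not None
            and classify_growth(growth, GrowthDialect.V2018) is GrowthClass.SUBTHRESHOLD
            and rng.random() < cp.p_af_general
        ):
            af_general.add(AfMalignancyGeneral.SUBTHRESHOLD_GROWTH)
        af_hcc = frozenset(a for a in AfHccSpecific if rng.random() < cp.p_af_hcc)
        af_benign = (
            frozenset({"HBP_ISOINTENSITY"}) if rng.random() < cp.p_af_benign else frozenset()
        )

        out.append(
            LesionObservation(
                id=f"sim-{params.seed}-{i + 1:05d}",
                diagnosis=diagnosis,
                size_mm=round(size, 1),
                aphe_ordinary=aphe,
                aphe_subtraction=subtraction,
                washout_pvp=washout,
                tp_hypointensity=tp,
                hbp_hypointensity=hbp,
                enhancing_capsule=capsule,
                growth=growth,
                targetoid_other=targetoid_other,
                definite_benign=definite,
                probable_benign=probable,
                af_malignancy_general=frozenset(af_general),
                af_hcc_specific=af_hcc,
                af_benign=af_benign,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Constraint validation


@dataclass(frozen=True)
class ConstraintResult:
    name: str
    description: str
    kind: str  # HARD or SOFT
    expected: int
    observed: int

    @property
    def passed(self) -> bool:
        return self.expected == self.observed


@dataclass(frozen=True)
class ConstraintReport:
    results: tuple[ConstraintResult, ...]

    @property
    def hard_ok(self) -> bool:
        return all(r.passed for r in self.results if r.kind == "HARD")

    @property
    def hard_failures(self) -> list[ConstraintResult]:
        return [r for r in self.results if r.kind == "HARD" and not r.passed]

    @property
    def soft_deviations(self) -> list[ConstraintResult]:
        return [r for r in self.results if r.kind == "SOFT" and not r.passed]

    def first_violation(self) -> Optional[ConstraintResult]:
        for r in self.results:
            if r.kind == "HARD" and not r.passed:
                return r
        return None

    def __str__(self) -> str:
        lines = []
        for r in self.results:
            status = "ok" if r.passed else ("FAIL" if r.kind == "HARD" else "deviates")
            lines.append(
                f"[{r.kind}] {r.name}: expected {r.expected}, observed {r.observed} "
                f"({status}) - {r.description}"
            )
        return "\n".join(lines)


class _Context:
    """Lazily computed engine/variant results shared by constraint extractors."""

    def __init__(self, cohort: Sequence[LesionObservation]):
        self.cohort = list(cohort)
        self._baseline = None
        self._variants: dict[VariantId, list] = {}
        self._audits: dict[VariantId, object] = {}

    @property
    def baseline(self):
        if self._baseline is None:
            self._baseline = categorize_cohort(self.cohort)
        return self._baseline

    def variant(self, vid: VariantId):
        if vid not in self._variants:
            assignments, audit = apply_variant(self.cohort, self.baseline, vid)
            self._variants[vid] = assignments
            self._audits[vid] = audit
        return self._variants[vid]

    def audit(self, vid: VariantId):
        self.variant(vid)
        return self._audits[vid]

    def diagnosis_of(self, observation_id: str) -> Diagnosis:
        if not hasattr(self, "_diag_index"):
            self._diag_index = {o.id: o.diagnosis for o in self.cohort}
        return self._diag_index[observation_id]

    def conf(self, vid: VariantId):
        pos = positivity(self.variant(vid), PositivityRule.LR5_ONLY)
        return confusion(pos, [o.diagnosis for o in self.cohort])

    def n_category(self, cat: LiradsCategory, diagnosis: Optional[Diagnosis] = None) -> int:
        return sum(
            1
            for o, a in zip(self.cohort, self.baseline)
            if a.category is cat and (diagnosis is None or o.diagnosis is diagnosis)
        )

    def no_aphe_hcc(self) -> list[tuple[LesionObservation, object]]:
        return [
            (o, a)
            for o, a in zip(self.cohort, self.baseline)
            if o.diagnosis is Diagnosis.HCC and o.aphe_ordinary is AphePattern.ABSENT
        ]

    def no_washout_hcc(self) -> list[tuple[LesionObservation, object]]:
        return [
            (o, a)
            for o, a in zip(self.cohort, self.baseline)
            if o.diagnosis is Diagnosis.HCC and not o.washout_pvp
        ]

    def subthreshold(self) -> list[tuple[LesionObservation, object]]:
        non_m = (LiradsCategory.LR3, LiradsCategory.LR4, LiradsCategory.LR5)
        return [
            (o, a)
            for o, a in zip(self.cohort, self.baseline)
            if a.category in non_m
            and classify_growth(o.growth, GrowthDialect.V2018) is GrowthClass.SUBTHRESHOLD
        ]


def _n_diag(ctx: _Context, d: Diagnosis) -> int:
    return sum(1 for o in ctx.cohort if o.diagnosis is d)


_EXTRACTORS: dict[str, Callable[[_Context], int]] = {
    "n_total": lambda c: len(c.cohort),
    "n_hcc": lambda c: _n_diag(c, Diagnosis.HCC),
    "n_non_hcc_malignancy": lambda c: _n_diag(c, Diagnosis.NON_HCC_MALIGNANCY),
    "n_benign": lambda c: _n_diag(c, Diagnosis.BENIGN),
    "baseline_lr1": lambda c: c.n_category(LiradsCategory.LR1),
    "baseline_lr2": lambda c: c.n_category(LiradsCategory.LR2),
    "baseline_lr3": lambda c: c.n_category(LiradsCategory.LR3),
    "baseline_lrm": lambda c: c.n_category(LiradsCategory.LRM),
    "baseline_lr4_total": lambda c: c.n_category(LiradsCategory.LR4),
    "baseline_lr4_hcc": lambda c: c.n_category(LiradsCategory.LR4, Diagnosis.HCC),
    "baseline_lr5_total": lambda c: c.n_category(LiradsCategory.LR5),
    "baseline_lr5_hcc": lambda c: c.n_category(LiradsCategory.LR5, Diagnosis.HCC),
    "baseline_lr45_total": lambda c: c.n_category(LiradsCategory.LR4)
    + c.n_category(LiradsCategory.LR5),
    "c1_tp": lambda c: c.conf(VariantId.C1_AF_MALIGNANCY).tp,
    "c1_tn": lambda c: c.conf(VariantId.C1_AF_MALIGNANCY).tn,
    "c2_tp": lambda c: c.conf(VariantId.C2_AF_HCC).tp,
    "c2_tn": lambda c: c.conf(VariantId.C2_AF_HCC).tn,
    "c3_tp": lambda c: c.conf(VariantId.C3_SUBTRACTION_APHE).tp,
    "c3_tn": lambda c: c.conf(VariantId.C3_SUBTRACTION_APHE).tn,
    "c4_tp": lambda c: c.conf(VariantId.C4_WASHOUT_REQUIRES_APHE).tp,
    "c4_tn": lambda c: c.conf(VariantId.C4_WASHOUT_REQUIRES_APHE).tn,
    "c5_tp": lambda c: c.conf(VariantId.C5_TP_WASHOUT).tp,
    "c5_tn": lambda c: c.conf(VariantId.C5_TP_WASHOUT).tn,
    "c6_tp": lambda c: c.conf(VariantId.C6_SUBTHRESHOLD_AS_THRESHOLD).tp,
    "c6_tn": lambda c: c.conf(VariantId.C6_SUBTHRESHOLD_AS_THRESHOLD).tn,
    # narrative (SOFT)
    "hcc_no_aphe": lambda c: len(c.no_aphe_hcc()),
    "hcc_no_aphe_washout": lambda c: sum(1 for o, _ in c.no_aphe_hcc() if o.washout_pvp),
    "hcc_no_aphe_subtraction": lambda c: sum(
        1 for o, _ in c.no_aphe_hcc() if o.aphe_subtraction is SubtractionPattern.GLOBAL
    ),
    "hcc_no_washout": lambda c: len(c.no_washout_hcc()),
    "hcc_no_washout_tp": lambda c: sum(
        1 for o, _ in c.no_washout_hcc() if o.tp_hypointensity
    ),
    "hcc_no_washout_tp_lr4": lambda c: sum(
        1
        for o, a in c.no_washout_hcc()
        if o.tp_hypointensity and a.category is LiradsCategory.LR4
    ),
    "hcc_no_washout_tp_lr5": lambda c: sum(
        1
        for o, a in c.no_washout_hcc()
        if o.tp_hypointensity and a.category is LiradsCategory.LR5
    ),
    "hcc_no_washout_tp_lrm": lambda c: sum(
        1
        for o, a in c.no_washout_hcc()
        if o.tp_hypointensity and a.category is LiradsCategory.LRM
    ),
    "subthreshold_total": lambda c: len(c.subthreshold()),
    "subthreshold_hcc": lambda c: sum(
        1 for o, _ in c.subthreshold() if o.diagnosis is Diagnosis.HCC
    ),
    "subthreshold_lr4": lambda c: sum(
        1 for _, a in c.subthreshold() if a.category is LiradsCategory.LR4
    ),
    "subthreshold_lr5": lambda c: sum(
        1 for _, a in c.subthreshold() if a.category is LiradsCategory.LR5
    ),
    "c4_lr5_demotions": lambda c: sum(
        1
        for m in c.audit(VariantId.C4_WASHOUT_REQUIRES_APHE).moves
        if m.category_before is LiradsCategory.LR5
    ),
    "c5_lr4_to_lr5_moves": lambda c: sum(
        1
        for m in c.audit(VariantId.C5_TP_WASHOUT).moves
        if m.category_before is LiradsCategory.LR4
        and m.category_after is LiradsCategory.LR5
        and c.diagnosis_of(m.observation_id) is Diagnosis.HCC
    ),
    "c6_lr4_to_lr5_moves": lambda c: sum(
        1
        for m in c.audit(VariantId.C6_SUBTHRESHOLD_AS_THRESHOLD).moves
        if m.category_before is LiradsCategory.LR4 and m.category_after is LiradsCategory.LR5
    ),
    "narrative_baseline_lr4": lambda c: c.n_category(LiradsCategory.LR4),
    "narrative_baseline_lr5": lambda c: c.n_category(LiradsCategory.LR5),
    "narrative_c1_movers": lambda c: len(c.audit(VariantId.C1_AF_MALIGNANCY).moves),
    "narrative_c2_movers": lambda c: len(c.audit(VariantId.C2_AF_HCC).moves),
    "narrative_c3_movers": lambda c: len(c.audit(VariantId.C3_SUBTRACTION_APHE).moves),
}


def load_constraints() -> list[dict]:
    """Load the versioned constraint table shipped with the package."""
    text = (
        importlib.resources.files("lirads_dta")
        .joinpath("resources/constraints.yaml")
        .read_text(encoding="utf-8")
    )
    doc = yaml.safe_load(text)
    return doc["constraints"]


def validate_constraints(
    cohort: Sequence[LesionObservation], constraints: Optional[Iterable[dict]] = None
) -> ConstraintReport:
    """Re-derive every constrained count from the cohort and compare.

    HARD failures flip :attr:`ConstraintReport.hard_ok`; SOFT failures are
    reported as logged deviations only.
    """
    if constraints is None:
        constraints = load_constraints()
    ctx = _Context(cohort)
    results = []
    for spec in constraints:
        name = spec["name"]
        extractor = _EXTRACTORS.get(name)
        if extractor is None:
            raise KeyError(f"no extractor registered for constraint {name!r}")
        results.append(
            ConstraintResult(
                name=name,
                description=spec.get("description", ""),
                kind=spec.get("kind", "HARD"),
                expected=int(spec["expected"]),
                observed=int(extractor(ctx)),
            )
        )
    return ConstraintReport(results=tuple(results))
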