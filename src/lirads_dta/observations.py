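"""Domain types for hepatic-observation records.

One :class:`LesionObservation` holds the imaging-feature vector of a single
untreated hepatic observation in an at-risk patient, as read on gadoxetate
disodium-enhanced MRI, together with its reference (histopathologic or
follow-up) diagnosis.  The vocabulary follows LI-RADS v2018: major features
(size, nonrim arterial phase hyperenhancement, nonperipheral washout,
enhancing capsule, threshold growth), targetoid features, and ancillary
features favoring malignancy in general, HCC in particular, or benignity.

Records can be constructed in code or round-tripped through CSV/TSV files
(one row per observation, header with the exact field names, feature sets
encoded as semicolon-delimited tokens, absent growth as empty cells).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "Diagnosis",
    "AphePattern",
    "SubtractionPattern",
    "AfMalignancyGeneral",
    "AfHccSpecific",
    "LiradsCategory",
    "GrowthRecord",
    "LesionObservation",
    "LiradsAssignment",
    "ValidationError",
    "read_observations",
    "write_observations",
    "read_assignments",
    "write_assignments",
]


class ValidationError(ValueError):
    """Invalid record; ``field`` names the offending attribute or column."""

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class Diagnosis(enum.Enum):
    """Reference-standard diagnosis of the observation."""

    HCC = "HCC"
    NON_HCC_MALIGNANCY = "NON_HCC_MALIGNANCY"
    BENIGN = "BENIGN"


class AphePattern(enum.Enum):
    """Arterial-phase enhancement as read on the ordinary late arterial phase."""

    ABSENT = "ABSENT"
    NONRIM = "NONRIM"
    RIM = "RIM"


class SubtractionPattern(enum.Enum):
    """Enhancement pattern on the arterial-minus-precontrast subtraction image."""

    ABSENT = "ABSENT"
    GLOBAL = "GLOBAL"
    RIM = "RIM"


class AfMalignancyGeneral(enum.Enum):
    """Ancillary features favoring malignancy in general (v2018)."""

    SUBTHRESHOLD_GROWTH = "SUBTHRESHOLD_GROWTH"
    RESTRICTED_DIFFUSION = "RESTRICTED_DIFFUSION"
    MILD_MODERATE_T2_HYPER = "MILD_MODERATE_T2_HYPER"
    CORONA_ENHANCEMENT = "CORONA_ENHANCEMENT"
    FAT_SPARING = "FAT_SPARING"
    IRON_SPARING = "IRON_SPARING"
    TP_HYPOINTENSITY = "TP_HYPOINTENSITY"
    HBP_HYPOINTENSITY = "HBP_HYPOINTENSITY"


class AfHccSpecific(enum.Enum):
    """Ancillary features favoring HCC in particular (v2018)."""

    NONENHANCING_CAPSULE = "NONENHANCING_CAPSULE"
    NODULE_IN_NODULE = "NODULE_IN_NODULE"
    MOSAIC = "MOSAIC"
    BLOOD_PRODUCTS = "BLOOD_PRODUCTS"
    INTRALESIONAL_FAT = "INTRALESIONAL_FAT"


_CATEGORY_RANK = {"LR-1": 1, "LR-2": 2, "LR-3": 3, "LR-4": 4, "LR-5": 5}


class LiradsCategory(enum.Enum):
    """LI-RADS diagnostic category.

    LR-1 (definitely benign) through LR-5 (definitely HCC) are ordinal and
    comparable; LR-M (probably malignant, not HCC specific) sits outside the
    ordinal scale and any order comparison involving it raises ``TypeError``.
    """

    LR1 = "LR-1"
    LR2 = "LR-2"
    LR3 = "LR-3"
    LR4 = "LR-4"
    LR5 = "LR-5"
    LRM = "LR-M"

    @property
    def is_ordinal(self) -> bool:
        return self is not LiradsCategory.LRM

    @property
    def rank(self) -> int:
        if self is LiradsCategory.LRM:
            raise TypeError("LR-M has no ordinal rank")
        return _CATEGORY_RANK[self.value]

    def _cmp_rank(self, other: "LiradsCategory") -> tuple[int, int]:
        if not isinstance(other, LiradsCategory):
            raise TypeError(f"cannot compare LiradsCategory with {type(other)!r}")
        return self.rank, other.rank

    def __lt__(self, other):
        a, b = self._cmp_rank(other)
        return a < b

    def __le__(self, other):
        a, b = self._cmp_rank(other)
        return a <= b

    def __gt__(self, other):
        a, b = self._cmp_rank(other)
        return a > b

    def __ge__(self, other):
        a, b = self._cmp_rank(other)
        return a >= b

    def up(self) -> "LiradsCategory":
        """Category one step higher (LR-5 stays LR-5)."""
        return _RANK_CATEGORY[min(self.rank + 1, 5)]

    def down(self) -> "LiradsCategory":
        """Category one step lower (LR-1 stays LR-1)."""
        return _RANK_CATEGORY[max(self.rank - 1, 1)]

    @classmethod
    def parse(cls, token: str) -> "LiradsCategory":
        t = token.strip().upper().replace("LR", "LR-").replace("LR--", "LR-")
        for member in cls:
            if member.value == t:
                return member
        raise ValidationError(f"unknown LI-RADS category {token!r}", field="category")


_RANK_CATEGORY = {v: LiradsCategory(k) for k, v in _CATEGORY_RANK.items()}


@dataclass(frozen=True)
class GrowthRecord:
    """Size change relative to a prior examination.

    ``pct_increase`` is the percent size increase versus the prior exam over
    ``interval_months``; ``is_new_nodule_ge10mm`` marks a new nodule of at
    least 10 mm (in which case the percent increase is not meaningful);
    ``unequivocal_increase`` records unequivocal growth below any defined
    threshold.
    """

    pct_increase: float = 0.0
    interval_months: float = 0.0
    is_new_nodule_ge10mm: bool = False
    unequivocal_increase: bool = False

    def __post_init__(self):
        if self.interval_months <= 0 or not math.isfinite(self.interval_months):
            raise ValidationError(
                f"growth interval must be a positive number of months, got {self.interval_months!r}",
                field="growth.interval_months",
            )
        if self.pct_increase < 0 or not math.isfinite(self.pct_increase):
            raise ValidationError(
                f"growth percent increase must be >= 0, got {self.pct_increase!r}",
                field="growth.pct_increase",
            )


@dataclass(frozen=True)
class LesionObservation:
    """One hepatic observation: imaging features plus reference diagnosis."""

    id: str
    diagnosis: Diagnosis
    size_mm: float
    aphe_ordinary: AphePattern = AphePattern.ABSENT
    aphe_subtraction: Optional[SubtractionPattern] = SubtractionPattern.ABSENT
    washout_pvp: bool = False
    tp_hypointensity: bool = False
    hbp_hypointensity: bool = False
    enhancing_capsule: bool = False
    growth: Optional[GrowthRecord] = None
    targetoid_other: bool = False
    definite_benign: bool = False
    probable_benign: bool = False
    af_malignancy_general: frozenset[AfMalignancyGeneral] = frozenset()
    af_hcc_specific: frozenset[AfHccSpecific] = frozenset()
    af_benign: frozenset[str] = frozenset()
    upgraded_from_lr3: bool = False
    reader_category_override: Optional[LiradsCategory] = None
    override_washout_dependent: bool = False

    def __post_init__(self):
        if not isinstance(self.diagnosis, Diagnosis):
            raise ValidationError(
                f"diagnosis must be a Diagnosis, got {self.diagnosis!r}", field="diagnosis"
            )
        if not (self.size_mm > 0 and math.isfinite(self.size_mm)):
            raise ValidationError(
                f"size_mm must be a positive real, got {self.size_mm!r}", field="size_mm"
            )
        if not isinstance(self.aphe_ordinary, AphePattern):
            raise ValidationError("invalid aphe_ordinary value", field="aphe_ordinary")
        if self.aphe_subtraction is not None and not isinstance(
            self.aphe_subtraction, SubtractionPattern
        ):
            raise ValidationError("invalid aphe_subtraction value", field="aphe_subtraction")
        object.__setattr__(self, "af_malignancy_general", frozenset(self.af_malignancy_general))
        object.__setattr__(self, "af_hcc_specific", frozenset(self.af_hcc_specific))
        object.__setattr__(self, "af_benign", frozenset(self.af_benign))
        # an AF may only be recorded when the underlying finding is present
        if AfMalignancyGeneral.TP_HYPOINTENSITY in self.af_malignancy_general and not self.tp_hypointensity:
            raise ValidationError(
                f"{self.id}: TP_HYPOINTENSITY ancillary feature recorded but "
                "tp_hypointensity is false",
                field="af_malignancy_general",
            )
        if AfMalignancyGeneral.HBP_HYPOINTENSITY in self.af_malignancy_general and not self.hbp_hypointensity:
            raise ValidationError(
                f"{self.id}: HBP_HYPOINTENSITY ancillary feature recorded but "
                "hbp_hypointensity is false",
                field="af_malignancy_general",
            )
        if AfMalignancyGeneral.SUBTHRESHOLD_GROWTH in self.af_malignancy_general and self.growth is None:
            raise ValidationError(
                f"{self.id}: SUBTHRESHOLD_GROWTH ancillary feature recorded but no "
                "growth record is present",
                field="af_malignancy_general",
            )

    def with_af_malignancy_removed(self, af: AfMalignancyGeneral) -> "LesionObservation":
        """Copy of the record with one general-malignancy AF removed."""
        return replace(self, af_malignancy_general=self.af_malignancy_general - {af})


@dataclass(frozen=True)
class LiradsAssignment:
    """Engine output for one observation, with a derivation trace."""

    observation_id: str
    category: LiradsCategory
    pre_ancillary_category: LiradsCategory
    major_feature_count: int = 0
    aphe_used: bool = False
    washout_used: bool = False
    upgraded_from_lr3: bool = False
    override_applied: bool = False
    trace: tuple[str, ...] = ()

    def __post_init__(self):
        if self.major_feature_count not in (0, 1, 2, 3):
            raise ValidationError(
                f"major_feature_count must be in 0..3, got {self.major_feature_count}",
                field="major_feature_count",
            )


# ---------------------------------------------------------------------------
# CSV/TSV round-tripping

_OBS_COLUMNS = [
    "id",
    "diagnosis",
    "size_mm",
    "aphe_ordinary",
    "aphe_subtraction",
    "washout_pvp",
    "tp_hypointensity",
    "hbp_hypointensity",
    "enhancing_capsule",
    "growth_pct_increase",
    "growth_interval_months",
    "growth_is_new_nodule_ge10mm",
    "growth_unequivocal_increase",
    "targetoid_other",
    "definite_benign",
    "probable_benign",
    "af_malignancy_general",
    "af_hcc_specific",
    "af_benign",
    "upgraded_from_lr3",
    "reader_category_override",
    "override_washout_dependent",
]

_ASSIGN_COLUMNS = [
    "observation_id",
    "category",
    "pre_ancillary_category",
    "major_feature_count",
    "aphe_used",
    "washout_used",
    "upgraded_from_lr3",
    "override_applied",
    "trace",
]


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","


def _fmt_bool(v: bool) -> str:
    return "true" if v else "false"


def _parse_bool(v, column: str) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", "", "nan"):
        return False
    raise ValidationError(f"cannot parse boolean {v!r} in column {column}", field=column)


def _is_blank(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == ""


def _parse_set(v, enum_cls, column: str) -> frozenset:
    if _is_blank(v):
        return frozenset()
    out = set()
    for token in str(v).split(";"):
        token = token.strip()
        if not token:
            continue
        if enum_cls is None:
            out.add(token)
        else:
            try:
                out.add(enum_cls(token))
            except ValueError as exc:
                raise ValidationError(
                    f"unknown token {token!r} in column {column}", field=column
                ) from exc
    return frozenset(out)


def observation_to_row(obs: LesionObservation) -> dict:
    g = obs.growth
    return {
        "id": obs.id,
        "diagnosis": obs.diagnosis.value,
        "size_mm": obs.size_mm,
        "aphe_ordinary": obs.aphe_ordinary.value,
        "aphe_subtraction": "" if obs.aphe_subtraction is None else obs.aphe_subtraction.value,
        "washout_pvp": _fmt_bool(obs.washout_pvp),
        "tp_hypointensity": _fmt_bool(obs.tp_hypointensity),
        "hbp_hypointensity": _fmt_bool(obs.hbp_hypointensity),
        "enhancing_capsule": _fmt_bool(obs.enhancing_capsule),
        "growth_pct_increase": "" if g is None else g.pct_increase,
        "growth_interval_months": "" if g is None else g.interval_months,
        "growth_is_new_nodule_ge10mm": "" if g is None else _fmt_bool(g.is_new_nodule_ge10mm),
        "growth_unequivocal_increase": "" if g is None else _fmt_bool(g.unequivocal_increase),
        "targetoid_other": _fmt_bool(obs.targetoid_other),
        "definite_benign": _fmt_bool(obs.definite_benign),
        "probable_benign": _fmt_bool(obs.probable_benign),
        "af_malignancy_general": ";".join(sorted(a.value for a in obs.af_malignancy_general)),
        "af_hcc_specific": ";".join(sorted(a.value for a in obs.af_hcc_specific)),
        "af_benign": ";".join(sorted(obs.af_benign)),
        "upgraded_from_lr3": _fmt_bool(obs.upgraded_from_lr3),
        "reader_category_override": (
            "" if obs.reader_category_override is None else obs.reader_category_override.value
        ),
        "override_washout_dependent": _fmt_bool(obs.override_washout_dependent),
    }


def observation_from_row(row: dict) -> LesionObservation:
    missing = [c for c in _OBS_COLUMNS if c not in row]
    if missing:
        raise ValidationError(f"missing column(s): {', '.join(missing)}", field=missing[0])
    try:
        diagnosis = Diagnosis(str(row["diagnosis"]).strip())
    except ValueError as exc:
        raise ValidationError(
            f"unknown diagnosis {row['diagnosis']!r}", field="diagnosis"
        ) from exc
    try:
        aphe = AphePattern(str(row["aphe_ordinary"]).strip())
    except ValueError as exc:
        raise ValidationError(
            f"unknown aphe_ordinary {row['aphe_ordinary']!r}", field="aphe_ordinary"
        ) from exc
    sub_raw = row["aphe_subtraction"]
    if _is_blank(sub_raw):
        subtraction = None
    else:
        try:
            subtraction = SubtractionPattern(str(sub_raw).strip())
        except ValueError as exc:
            raise ValidationError(
                f"unknown aphe_subtraction {sub_raw!r}", field="aphe_subtraction"
            ) from exc
    if _is_blank(row["growth_interval_months"]) and _is_blank(row["growth_pct_increase"]):
        growth = None
    else:
        growth = GrowthRecord(
            pct_increase=float(row["growth_pct_increase"] or 0.0),
            interval_months=float(row["growth_interval_months"]),
            is_new_nodule_ge10mm=_parse_bool(
                row["growth_is_new_nodule_ge10mm"], "growth_is_new_nodule_ge10mm"
            ),
            unequivocal_increase=_parse_bool(
                row["growth_unequivocal_increase"], "growth_unequivocal_increase"
            ),
        )
    override_raw = row["reader_category_override"]
    override = None if _is_blank(override_raw) else LiradsCategory.parse(str(override_raw))
    return LesionObservation(
        id=str(row["id"]),
        diagnosis=diagnosis,
        size_mm=float(row["size_mm"]),
        aphe_ordinary=aphe,
        aphe_subtraction=subtraction,
        washout_pvp=_parse_bool(row["washout_pvp"], "washout_pvp"),
        tp_hypointensity=_parse_bool(row["tp_hypointensity"], "tp_hypointensity"),
        hbp_hypointensity=_parse_bool(row["hbp_hypointensity"], "hbp_hypointensity"),
        enhancing_capsule=_parse_bool(row["enhancing_capsule"], "enhancing_capsule"),
        growth=growth,
        targetoid_other=_parse_bool(row["targetoid_other"], "targetoid_other"),
        definite_benign=_parse_bool(row["definite_benign"], "definite_benign"),
        probable_benign=_parse_bool(row["probable_benign"], "probable_benign"),
        af_malignancy_general=_parse_set(
            row["af_malignancy_general"], AfMalignancyGeneral, "af_malignancy_general"
        ),
        af_hcc_specific=_parse_set(row["af_hcc_specific"], AfHccSpecific, "af_hcc_specific"),
        af_benign=_parse_set(row["af_benign"], None, "af_benign"),
        upgraded_from_lr3=_parse_bool(row["upgraded_from_lr3"], "upgraded_from_lr3"),
        reader_category_override=override,
        override_washout_dependent=_parse_bool(
            row["override_washout_dependent"], "override_washout_dependent"
        ),
    )


def write_observations(observations: Iterable[LesionObservation], path) -> None:
    path = Path(path)
    df = pd.DataFrame([observation_to_row(o) for o in observations], columns=_OBS_COLUMNS)
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_observations(path) -> list[LesionObservation]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    missing = [c for c in _OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path.name}: missing column(s): {', '.join(missing)}", field=missing[0]
        )
    out = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            out.append(observation_from_row(row))
        except ValidationError as exc:
            raise ValidationError(f"{path.name} row {i + 2}: {exc}", field=exc.field) from exc
    return out


def write_assignments(assignments: Iterable[LiradsAssignment], path) -> None:
    path = Path(path)
    rows = [
        {
            "observation_id": a.observation_id,
            "category": a.category.value,
            "pre_ancillary_category": a.pre_ancillary_category.value,
            "major_feature_count": a.major_feature_count,
            "aphe_used": _fmt_bool(a.aphe_used),
            "washout_used": _fmt_bool(a.washout_used),
            "upgraded_from_lr3": _fmt_bool(a.upgraded_from_lr3),
            "override_applied": _fmt_bool(a.override_applied),
            "trace": ";".join(a.trace),
        }
        for a in assignments
    ]
    pd.DataFrame(rows, columns=_ASSIGN_COLUMNS).to_csv(path, sep=_sep_for(path), index=False)


def read_assignments(path) -> list[LiradsAssignment]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    missing = [c for c in _ASSIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path.name}: missing column(s): {', '.join(missing)}", field=missing[0]
        )
    return [
        LiradsAssignment(
            observation_id=str(r["observation_id"]),
            category=LiradsCategory.parse(r["category"]),
            pre_ancillary_category=LiradsCategory.parse(r["pre_ancillary_category"]),
            major_feature_count=int(r["major_feature_count"]),
            aphe_used=_parse_bool(r["aphe_used"], "aphe_used"),
            washout_used=_parse_bool(r["washout_used"], "washout_used"),
            upgraded_from_lr3=_parse_bool(r["upgraded_from_lr3"], "upgraded_from_lr3"),
            override_applied=_parse_bool(r["override_applied"], "override_applied"),
            trace=tuple(t for t in str(r["trace"]).split(";") if t),
        )
        for r in df.to_dict("records")
    ]
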