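"""End-to-end evaluation pipeline and report rendering.

``run_pipeline`` ties the stages together: read (or accept) a cohort,
categorize it with default v2018 parameters, apply the requested
category-adjustment conditions, and write per-condition assignments and
reclassification audits, an accuracy table (one row per condition:
sensitivity/specificity/PPV/NPV/accuracy with exact CIs and McNemar
p-values against the baseline LR-5 rule) and an AUC table with paired
DeLong comparisons, plus a machine-readable JSON sidecar carrying every
count at full precision.

Displayed percentages are rounded half-up to one decimal; p-values print
to three decimals with "<0.001" and ">0.999" end caps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .engine import categorize_cohort
from .observations import (
    LesionObservation,
    LiradsAssignment,
    ValidationError,
    read_observations,
    write_assignments,
)
from .stats import DtaReport, confusion, delong_paired, metrics
from .variants import (
    ADJUSTMENT_VARIANTS,
    PositivityRule,
    ReclassificationAudit,
    VariantId,
    apply_variant,
    positivity,
)

logger = logging.getLogger("lirads_dta")

__all__ = ["RunConfig", "PipelineResult", "VariantEvaluation", "run_pipeline",
           "evaluate_cohort", "fmt_pct", "fmt_p", "round_half_up"]

_ROW_LABELS = {
    VariantId.BASELINE_LR45: "LI-RADS v2018 LR-4 and 5",
    VariantId.BASELINE_LR5: "LI-RADS v2018 LR-5",
    VariantId.C1_AF_MALIGNANCY: "Upgraded LR-5 using malignancy AF in general",
    VariantId.C2_AF_HCC: "Upgraded LR-5 using HCC AF",
    VariantId.C3_SUBTRACTION_APHE: "LR-5 with APHE extended to the subtraction image",
    VariantId.C4_WASHOUT_REQUIRES_APHE: "LR-5 considering no washout if no APHE",
    VariantId.C5_TP_WASHOUT: "LR-5 with washout extended from PVP to TP",
    VariantId.C6_SUBTHRESHOLD_AS_THRESHOLD: "LR-5 with subthreshold growth as threshold",
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (1.25 -> 1.3 at one digit)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fmt_pct(x: float) -> str:
    return f"{round_half_up(100 * x, 1):.1f}"


def fmt_p(p: Optional[float]) -> str:
    if p is None:
        return "-"
    if p < 0.001:
        return "<0.001"
    if p > 0.999:
        return ">0.999"
    return f"{round_half_up(p, 3):.3f}"


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run."""

    input_path: str
    out_dir: str
    variants: tuple[VariantId, ...] = ADJUSTMENT_VARIANTS
    rule: PositivityRule = PositivityRule.LR5_ONLY
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}", field="alpha")
        if not self.variants:
            raise ValidationError("variant list must be non-empty", field="variants")
        unknown = [v for v in self.variants if not isinstance(v, VariantId)]
        if unknown:
            raise ValidationError(f"unknown variant(s): {unknown}", field="variants")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if "variants" in doc:
            doc["variants"] = tuple(VariantId(v) for v in doc["variants"])
        if "rule" in doc:
            doc["rule"] = PositivityRule(doc["rule"])
        return cls(**doc)


@dataclass(frozen=True)
class VariantEvaluation:
    """One accuracy-table row: a condition's assignments, audit and metrics."""

    variant: VariantId
    rule: PositivityRule
    assignments: tuple[LiradsAssignment, ...]
    audit: ReclassificationAudit
    report: DtaReport
    p_sens_mcnemar: Optional[float]
    p_spec_mcnemar: Optional[float]
    p_delong: Optional[float]
    delta_auc: Optional[float]


@dataclass(frozen=True)
class PipelineResult:
    rows: tuple[VariantEvaluation, ...]
    baseline: tuple[LiradsAssignment, ...]

    def row(self, variant: VariantId) -> VariantEvaluation:
        for r in self.rows:
            if r.variant is variant:
                return r
        raise KeyError(variant)


def evaluate_cohort(
    cohort: Sequence[LesionObservation],
    variants: Sequence[VariantId] = ADJUSTMENT_VARIANTS,
    alpha: float = 0.05,
) -> PipelineResult:
    """Categorize, adjust and score a cohort; the computational core of
    :func:`run_pipeline` (no I/O)."""
    baseline = categorize_cohort(cohort)
    truth = [o.diagnosis for o in cohort]
    base_pos = positivity(baseline, PositivityRule.LR5_ONLY)

    ordered = [VariantId.BASELINE_LR45, VariantId.BASELINE_LR5] + [
        v for v in variants if v not in (VariantId.BASELINE_LR45, VariantId.BASELINE_LR5)
    ]
    rows = []
    for vid in ordered:
        rule = (
            PositivityRule.LR4_OR_LR5
            if vid is VariantId.BASELINE_LR45
            else PositivityRule.LR5_ONLY
        )
        assignments, audit = apply_variant(cohort, baseline, vid)
        pos = positivity(assignments, rule)
        ct = confusion(pos, truth)
        report = metrics(ct, alpha=alpha, variant=vid)
        if vid in (VariantId.BASELINE_LR45, VariantId.BASELINE_LR5):
            p_sens = p_spec = p_roc = d_auc = None
        else:
            sens_pair = delong_paired(pos, base_pos, truth, discordant_on="positives")
            spec_pair = delong_paired(pos, base_pos, truth, discordant_on="negatives")
            p_sens = sens_pair.p_mcnemar
            p_spec = spec_pair.p_mcnemar
            p_roc = sens_pair.p_delong
            d_auc = sens_pair.delta_auc
        logger.info(
            "%s: %d reclassification(s); sens %s spec %s",
            vid.value,
            len(audit.moves),
            fmt_pct(report.sensitivity.value),
            fmt_pct(report.specificity.value),
        )
        rows.append(
            VariantEvaluation(
                variant=vid,
                rule=rule,
                assignments=tuple(assignments),
                audit=audit,
                report=report,
                p_sens_mcnemar=p_sens,
                p_spec_mcnemar=p_spec,
                p_delong=p_roc,
                delta_auc=d_auc,
            )
        )
    return PipelineResult(rows=tuple(rows), baseline=tuple(baseline))


def _metric_cell(p) -> str:
    if not p.defined:
        return "undefined"
    return f"{fmt_pct(p.value)} ({p.numerator}/{p.denominator}) [{fmt_pct(p.ci_low)}, {fmt_pct(p.ci_high)}]"


def _metrics_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for r in result.rows:
        rep = r.report
        rows.append(
            {
                "categorization": _ROW_LABELS[r.variant],
                "sensitivity_pct": _metric_cell(rep.sensitivity),
                "specificity_pct": _metric_cell(rep.specificity),
                "ppv_pct": _metric_cell(rep.ppv),
                "npv_pct": _metric_cell(rep.npv),
                "accuracy_pct": _metric_cell(rep.accuracy),
                "p_sensitivity_vs_lr5": fmt_p(r.p_sens_mcnemar),
                "p_specificity_vs_lr5": fmt_p(r.p_spec_mcnemar),
            }
        )
    return pd.DataFrame(rows)


def _auc_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for r in result.rows:
        rows.append(
            {
                "categorization": _ROW_LABELS[r.variant],
                "auc": f"{round_half_up(r.report.auc, 3):.3f}",
                "auc_ci": f"[{round_half_up(r.report.auc_ci[0], 3):.3f}, "
                f"{round_half_up(r.report.auc_ci[1], 3):.3f}]",
                "p_vs_lr5": fmt_p(r.p_delong),
            }
        )
    return pd.DataFrame(rows)


def _json_sidecar(result: PipelineResult) -> dict:
    out = {}
    for r in result.rows:
        rep = r.report
        out[r.variant.value] = {
            "rule": r.rule.value,
            "confusion": {
                "tp": rep.sensitivity.numerator,
                "fn": rep.sensitivity.denominator - rep.sensitivity.numerator,
                "tn": rep.specificity.numerator,
                "fp": rep.specificity.denominator - rep.specificity.numerator,
            },
            "metrics": {
                name: dataclasses.asdict(getattr(rep, name))
                for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy")
            },
            "auc": rep.auc,
            "auc_ci": list(rep.auc_ci),
            "p_sensitivity_mcnemar": r.p_sens_mcnemar,
            "p_specificity_mcnemar": r.p_spec_mcnemar,
            "p_delong": r.p_delong,
            "delta_auc": r.delta_auc,
            "n_reclassified": len(r.audit.moves),
            "transitions": {
                f"{a.value}->{b.value}": n
                for (a, b), n in sorted(
                    r.audit.counts_by_transition.items(),
                    key=lambda kv: (kv[0][0].value, kv[0][1].value),
                )
            },
        }
    return out


def _write_audit(audit: ReclassificationAudit, path: Path) -> None:
    rows = [
        {
            "observation_id": m.observation_id,
            "category_before": m.category_before.value,
            "category_after": m.category_after.value,
            "reason": m.reason,
        }
        for m in audit.moves
    ]
    pd.DataFrame(
        rows, columns=["observation_id", "category_before", "category_after", "reason"]
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full pipeline and write report files under ``config.out_dir``.

    Re-running with identical config and inputs yields byte-identical
    reports.  Returns the in-memory result.
    """
    logging.basicConfig(level=config.log_level)
    cohort = read_observations(config.input_path)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    result = evaluate_cohort(cohort, variants=config.variants, alpha=config.alpha)

    write_assignments(result.baseline, out_dir / "assignments_baseline.csv")
    for r in result.rows:
        if r.variant in (VariantId.BASELINE_LR45, VariantId.BASELINE_LR5):
            continue
        write_assignments(r.assignments, out_dir / f"assignments_{r.variant.value}.csv")
        _write_audit(r.audit, out_dir / f"audit_{r.variant.value}.tsv")

    _metrics_frame(result).to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
    _auc_frame(result).to_csv(out_dir / "auc.tsv", sep="\t", index=False)
    (out_dir / "report.json").write_text(
        json.dumps(_json_sidecar(result), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return result
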