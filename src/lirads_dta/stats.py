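"""Diagnostic-test-accuracy statistics for paired binary rules.

Sensitivity, specificity, predictive values and accuracy with exact
(Clopper-Pearson) binomial confidence intervals; the exact two-sided
McNemar test on discordant pairs; and the two-point ROC of a binary rule,
whose trapezoidal AUC equals (sensitivity + specificity) / 2, with a
DeLong-type placement-value covariance estimator for comparing the
correlated AUCs of two rules evaluated on the same subjects.

Throughout, the positive truth class is HCC; non-HCC malignancies and
benign lesions both count as truth-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .observations import Diagnosis

__all__ = [
    "ConfusionTable",
    "Proportion",
    "DtaReport",
    "PairedResult",
    "confusion",
    "metrics",
    "clopper_pearson",
    "mcnemar_exact",
    "mcnemar_asymptotic",
    "binary_roc_auc",
    "delong_paired",
    "truth_vector",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-tabulation of a positivity rule against HCC truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive_truth(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative_truth(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class Proportion:
    """A ratio with its exact binomial confidence interval.

    ``defined`` is False when the denominator is zero, in which case the
    estimate and interval are NaN rather than an exception.
    """

    numerator: int
    denominator: int
    value: float
    ci_low: float
    ci_high: float
    defined: bool = True

    @classmethod
    def from_counts(cls, x: int, n: int, alpha: float = 0.05) -> "Proportion":
        if n == 0:
            return cls(0, 0, math.nan, math.nan, math.nan, defined=False)
        lo, hi = clopper_pearson(x, n, alpha)
        return cls(x, n, x / n, lo, hi)


@dataclass(frozen=True)
class DtaReport:
    """Point estimates with 95% CIs for one positivity rule; the machine
    twin of one accuracy-table row."""

    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion
    accuracy: Proportion
    auc: float
    auc_ci: tuple[float, float]
    variant: Optional[object] = None


@dataclass(frozen=True)
class PairedResult:
    """Paired comparison of two rules on the same subjects.

    ``b`` counts subjects positive under rule 1 but negative under rule 2
    (within the requested truth class); ``c`` the reverse.
    """

    b: int
    c: int
    p_mcnemar: float
    delta_auc: float
    z: float
    p_delong: float


def truth_vector(diagnoses: Sequence[Diagnosis]) -> np.ndarray:
    """Boolean HCC-truth vector (non-HCC malignancy and benign are negative)."""
    return np.array([d is Diagnosis.HCC for d in diagnoses], dtype=bool)


def confusion(positives: Sequence[bool], truth: Sequence) -> ConfusionTable:
    """Cross-tabulate a boolean positivity vector against HCC truth.

    ``truth`` may be a boolean vector or a sequence of :class:`Diagnosis`.
    """
    pos = np.asarray(positives, dtype=bool)
    if len(truth) and isinstance(truth[0], Diagnosis):
        t = truth_vector(truth)
    else:
        t = np.asarray(truth, dtype=bool)
    if pos.shape != t.shape:
        raise ValueError(f"length mismatch: {pos.shape} positives vs {t.shape} truth")
    return ConfusionTable(
        tp=int(np.sum(pos & t)),
        fp=int(np.sum(pos & ~t)),
        fn=int(np.sum(~pos & t)),
        tn=int(np.sum(~pos & ~t)),
    )


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for x/n.

    Lower bound is 0 when x = 0 and upper bound is 1 when x = n; otherwise
    the bounds are beta-distribution quantiles.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    lo = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def mcnemar_exact(b: int, c: int) -> float:
    """Two-sided exact McNemar test on discordant-pair counts.

    Exact binomial test of b successes in b + c trials at rate 1/2:
    p = min(1, 2 * P(X <= min(b, c))).  Returns 1 when b + c = 0.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * sps.binom.cdf(min(b, c), n, 0.5)))


def mcnemar_asymptotic(b: int, c: int, continuity: bool = True) -> float:
    """Chi-square McNemar test; provided for reference, not the default."""
    n = b + c
    if n == 0:
        return 1.0
    num = (abs(b - c) - 1) ** 2 if continuity else (b - c) ** 2
    return float(sps.chi2.sf(num / n, df=1))


def binary_roc_auc(positives: Sequence[bool], truth: Sequence) -> float:
    """Trapezoidal AUC of the two-point ROC of a binary rule.

    Equals (sensitivity + specificity) / 2, and equally the Mann-Whitney
    statistic on the 0/1 score with ties counted one half.
    """
    ct = confusion(positives, truth)
    if ct.n_positive_truth == 0 or ct.n_negative_truth == 0:
        raise ValueError("degenerate truth vector: need at least one positive and one negative")
    sens = ct.tp / ct.n_positive_truth
    spec = ct.tn / ct.n_negative_truth
    return (sens + spec) / 2.0


def _placements(scores_pos: np.ndarray, scores_neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values for each positive (vs negatives) and each
    negative (vs positives), with ties counted one half."""
    v10 = np.array(
        [
            (np.sum(scores_neg < s) + 0.5 * np.sum(scores_neg == s)) / len(scores_neg)
            for s in scores_pos
        ]
    )
    v01 = np.array(
        [
            (np.sum(scores_pos > s) + 0.5 * np.sum(scores_pos == s)) / len(scores_pos)
            for s in scores_neg
        ]
    )
    return v10, v01


def delong_paired(
    pos1: Sequence[bool],
    pos2: Sequence[bool],
    truth: Sequence,
    discordant_on: str = "positives",
) -> PairedResult:
    """Compare the correlated AUCs of two binary rules on the same subjects.

    Uses the placement-value covariance estimator on the 0/1 scores (massive
    ties are handled by half-counting, which matches the two-point ROC).
    Also reports the discordant-pair counts and the exact McNemar p-value on
    the truth-positive subset (``discordant_on="positives"``, a sensitivity
    comparison) or the truth-negative subset (``"negatives"``, specificity).
    """
    s1 = np.asarray(pos1, dtype=float)
    s2 = np.asarray(pos2, dtype=float)
    if len(truth) and isinstance(truth[0], Diagnosis):
        t = truth_vector(truth)
    else:
        t = np.asarray(truth, dtype=bool)
    if not (s1.shape == s2.shape == t.shape):
        raise ValueError("pos1, pos2 and truth must have equal lengths")
    m = int(t.sum())
    n = int((~t).sum())
    if m == 0 or n == 0:
        raise ValueError("degenerate truth vector: need at least one positive and one negative")

    v10_1, v01_1 = _placements(s1[t], s1[~t])
    v10_2, v01_2 = _placements(s2[t], s2[~t])
    auc1 = float(v10_1.mean())
    auc2 = float(v10_2.mean())
    delta = auc1 - auc2

    if discordant_on == "positives":
        sub1, sub2 = s1[t].astype(bool), s2[t].astype(bool)
    elif discordant_on == "negatives":
        sub1, sub2 = s1[~t].astype(bool), s2[~t].astype(bool)
    else:
        raise ValueError("discordant_on must be 'positives' or 'negatives'")
    b = int(np.sum(sub1 & ~sub2))
    c = int(np.sum(~sub1 & sub2))
    p_mc = mcnemar_exact(b, c)

    if np.array_equal(s1, s2):
        return PairedResult(b=b, c=c, p_mcnemar=p_mc, delta_auc=0.0, z=0.0, p_delong=1.0)

    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        z = 0.0 if delta == 0 else math.copysign(math.inf, delta)
    else:
        z = delta / math.sqrt(var)
    p = 1.0 if not math.isfinite(z) else float(2 * sps.norm.sf(abs(z)))
    if not math.isfinite(z):
        p = 0.0
    return PairedResult(b=b, c=c, p_mcnemar=p_mc, delta_auc=delta, z=z, p_delong=p)


def _auc_ci(ct: ConfusionTable, alpha: float = 0.05) -> tuple[float, float]:
    """Wald interval on the binary-rule AUC from the DeLong variance of a
    single two-point ROC."""
    m, n = ct.n_positive_truth, ct.n_negative_truth
    sens = ct.tp / m
    spec = ct.tn / n
    auc = (sens + spec) / 2
    # var of mean placement: sens*(1-sens)/4m + spec*(1-spec)/4n
    var = sens * (1 - sens) / (4 * m) + spec * (1 - spec) / (4 * n)
    zq = float(sps.norm.ppf(1 - alpha / 2))
    half = zq * math.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def metrics(ct: ConfusionTable, alpha: float = 0.05, variant=None) -> DtaReport:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact CIs.

    Zero denominators yield undefined metrics flagged on the
    :class:`Proportion`, not an exception for the whole report.
    """
    sens = Proportion.from_counts(ct.tp, ct.tp + ct.fn, alpha)
    spec = Proportion.from_counts(ct.tn, ct.tn + ct.fp, alpha)
    ppv = Proportion.from_counts(ct.tp, ct.tp + ct.fp, alpha)
    npv = Proportion.from_counts(ct.tn, ct.tn + ct.fn, alpha)
    acc = Proportion.from_counts(ct.tp + ct.tn, ct.n, alpha)
    if sens.defined and spec.defined:
        auc = (sens.value + spec.value) / 2
        auc_ci = _auc_ci(ct, alpha)
    else:
        auc, auc_ci = math.nan, (math.nan, math.nan)
    return DtaReport(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=acc,
        auc=auc,
        auc_ci=auc_ci,
        variant=variant,
    )
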