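"""Diagnostic-accuracy statistics against independent oracles.

Clopper-Pearson bounds are checked against a bisection solver on the
binomial tail (and scipy's binomtest interval); the exact McNemar test
against statsmodels' exact implementation; the paired DeLong z against a
plain nested-loop transcription of the placement-covariance formula.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from lirads_dta import (
    ConfusionTable,
    Diagnosis,
    binary_roc_auc,
    clopper_pearson,
    confusion,
    delong_paired,
    mcnemar_exact,
    metrics,
)

settings.register_profile("repro", derandomize=True, max_examples=200)
settings.load_profile("repro")


# ---------------------------------------------------------------------------
# independent oracles


def _binom_cdf(k, n, p):
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k + 1))


def cp_bisect(x, n, alpha=0.05, tol=1e-10):
    """Clopper-Pearson bounds by bisection on the binomial tail."""

    def solve(f):
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if f(mid):
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lower = 0.0 if x == 0 else solve(lambda p: 1 - _binom_cdf(x - 1, n, p) < alpha / 2)
    upper = 1.0 if x == n else solve(lambda p: _binom_cdf(x, n, p) >= alpha / 2)
    return lower, upper


def delong_z_loops(scores1, scores2, truth):
    """Nested-loop transcription of the DeLong covariance computation."""
    pos = [i for i, t in enumerate(truth) if t]
    neg = [i for i, t in enumerate(truth) if not t]
    m, n = len(pos), len(neg)

    def psi(a, b):
        return 1.0 if a > b else (0.5 if a == b else 0.0)

    v10 = {1: [], 2: []}
    v01 = {1: [], 2: []}
    for k, s in ((1, scores1), (2, scores2)):
        for i in pos:
            v10[k].append(sum(psi(s[i], s[j]) for j in neg) / n)
        for j in neg:
            v01[k].append(sum(psi(s[i], s[j]) for i in pos) / m)
    auc = {k: sum(v10[k]) / m for k in (1, 2)}

    def cov(xs, ys):
        mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
        return sum((a - mx) * (b - my) for a, b in zip(xs, ys)) / (len(xs) - 1)

    var = (
        cov(v10[1], v10[1]) + cov(v10[2], v10[2]) - 2 * cov(v10[1], v10[2])
    ) / m + (cov(v01[1], v01[1]) + cov(v01[2], v01[2]) - 2 * cov(v01[1], v01[2])) / n
    delta = auc[1] - auc[2]
    return delta / math.sqrt(var)


# ---------------------------------------------------------------------------


class TestClopperPearson:
    @pytest.mark.parametrize(
        "x, n, expected",
        [
            (0, 10, (0.0, 0.3085)),
            (10, 10, (0.6915, 1.0)),
            (365, 508, (0.6774, 0.7572)),
        ],
    )
    def test_frozen_values(self, x, n, expected):
        lo, hi = clopper_pearson(x, n)
        assert lo == pytest.approx(expected[0], abs=5e-4)
        assert hi == pytest.approx(expected[1], abs=5e-4)

    @pytest.mark.parametrize("x, n", [(0, 10), (3, 10), (17, 40), (365, 508)])
    def test_matches_bisection_and_scipy(self, x, n):
        lo, hi = clopper_pearson(x, n)
        blo, bhi = cp_bisect(x, n)
        assert lo == pytest.approx(blo, abs=1e-6)
        assert hi == pytest.approx(bhi, abs=1e-6)
        ci = sps.binomtest(x, n).proportion_ci(confidence_level=0.95, method="exact")
        assert lo == pytest.approx(ci.low, abs=1e-9)
        assert hi == pytest.approx(ci.high, abs=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(11, 10)


class TestMcNemarExact:
    @pytest.mark.parametrize(
        "b, c, expected",
        [(3, 0, 0.25), (8, 0, 0.0078125), (0, 0, 1.0), (5, 5, 1.0)],
    )
    def test_frozen_values(self, b, c, expected):
        assert mcnemar_exact(b, c) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("b, c", [(3, 0), (8, 2), (12, 7), (1, 1)])
    def test_matches_statsmodels_exact(self, b, c):
        table = [[0, b], [c, 0]]
        expected = sm_mcnemar(table, exact=True).pvalue
        assert mcnemar_exact(b, c) == pytest.approx(expected, rel=1e-9)

    @given(st.integers(0, 40), st.integers(0, 40))
    def test_symmetry(self, b, c):
        assert mcnemar_exact(b, c) == mcnemar_exact(c, b)

    @given(st.integers(1, 60), st.integers(0, 30))
    def test_p_nonincreasing_in_imbalance(self, total, k):
        # at fixed b + c, widening |b - c| can only shrink the p-value
        k = min(k, total // 2)
        if k >= 1:
            assert mcnemar_exact(k - 1, total - k + 1) <= mcnemar_exact(k, total - k) + 1e-12


class TestConfusionAndMetrics:
    def test_fixture_baseline_confusion(self, cohort, baseline):
        from lirads_dta import PositivityRule, positivity

        truth = [o.diagnosis for o in cohort]
        ct = confusion(positivity(baseline, PositivityRule.LR5_ONLY), truth)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (365, 6, 143, 278)
        ct45 = confusion(positivity(baseline, PositivityRule.LR4_OR_LR5), truth)
        assert (ct45.tp, ct45.fp, ct45.fn, ct45.tn) == (472, 16, 36, 268)

    def test_all_negative_predictor(self, cohort):
        truth = [o.diagnosis for o in cohort]
        ct = confusion(np.zeros(len(cohort), bool), truth)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (0, 0, 508, 284)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([True], [Diagnosis.HCC, Diagnosis.BENIGN])

    def test_metric_point_estimates(self):
        rep = metrics(ConfusionTable(tp=365, fp=6, fn=143, tn=278))
        assert rep.sensitivity.value == pytest.approx(0.719, abs=5e-4)
        assert rep.specificity.value == pytest.approx(0.979, abs=5e-4)
        assert rep.ppv.value == pytest.approx(0.984, abs=5e-4)
        assert rep.npv.value == pytest.approx(0.660, abs=5e-4)
        assert rep.accuracy.value == pytest.approx(0.812, abs=5e-4)

    def test_perfect_classifier(self):
        rep = metrics(ConfusionTable(tp=1, fp=0, fn=0, tn=1))
        assert rep.sensitivity.value == rep.specificity.value == rep.accuracy.value == 1.0

    def test_zero_denominator_flags_not_raises(self):
        rep = metrics(ConfusionTable(tp=3, fp=0, fn=1, tn=0))
        assert not rep.specificity.defined and math.isnan(rep.specificity.value)
        assert rep.sensitivity.defined

    def test_ci_contains_point_estimate(self):
        rep = metrics(ConfusionTable(tp=365, fp=6, fn=143, tn=278))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            p = getattr(rep, name)
            assert p.ci_low <= p.value <= p.ci_high


class TestRocAuc:
    def test_binary_auc_values(self):
        rng = np.random.default_rng(7)
        truth = np.array([True] * 508 + [False] * 284)
        pos = np.concatenate([rng.random(508) < 0.719, rng.random(284) < 1 - 0.979])
        ct = confusion(pos, truth)
        sens = ct.tp / ct.n_positive_truth
        spec = ct.tn / ct.n_negative_truth
        assert binary_roc_auc(pos, truth) == pytest.approx((sens + spec) / 2, abs=1e-15)

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            binary_roc_auc([True, False], [True, True])

    def test_identical_rules_give_null_comparison(self):
        truth = np.array([True, True, False, False, True])
        pos = np.array([True, False, False, True, True])
        r = delong_paired(pos, pos, truth)
        assert r.delta_auc == 0.0 and r.p_delong == 1.0 and r.p_mcnemar == 1.0

    def test_delong_z_matches_loop_oracle(self):
        truth = [True] * 6 + [False] * 4
        pos1 = [1, 1, 1, 0, 1, 0, 0, 1, 0, 0]
        pos2 = [1, 0, 1, 0, 0, 0, 0, 0, 1, 0]
        r = delong_paired(pos1, pos2, truth)
        z_oracle = delong_z_loops(pos1, pos2, truth)
        assert r.z == pytest.approx(z_oracle, rel=1e-12)

    def test_discordant_counts_per_truth_class(self):
        truth = [True, True, True, False, False]
        pos1 = [True, True, False, True, False]
        pos2 = [False, True, True, False, False]
        r_pos = delong_paired(pos1, pos2, truth, discordant_on="positives")
        assert (r_pos.b, r_pos.c) == (1, 1)
        r_neg = delong_paired(pos1, pos2, truth, discordant_on="negatives")
        assert (r_neg.b, r_neg.c) == (1, 0)
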