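"""Rank tests and regressions: enumeration oracles and recovery simulations."""
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vocemo import (feature_emotion_contrasts, holm_adjust, mann_whitney,
                    multiple_regression, simple_regression, spearman)
from vocemo.errors import CollinearityError, InvalidSpecError


def exact_mw_p(x, y):
    """Brute-force two-sided exact p: enumerate all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    n = len(pooled)
    mu = n1 * len(y) / 2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    target = abs(u_obs - mu)
    hits = sum(
        abs(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2 - mu) >= target - 1e-9
        for idx in combinations(range(n), n1)
    )
    return hits / comb(n, n1)


class TestMannWhitney:
    def test_identical_samples_midpoint(self):
        res = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.u_statistic == 8.0  # n1*n2/2
        assert res.z_score == 0.0
        assert res.p_value == 1.0

    def test_fully_separated_small_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(2 / 20)  # both extreme labelings

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_mode_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(2, 6))
        n2 = int(rng.integers(2, 13 - n1))
        x = rng.integers(0, 5, size=n1).astype(float)  # ties on purpose
        y = rng.integers(0, 5, size=n2).astype(float)
        res = mann_whitney(x, y, mode="auto")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(exact_mw_p(x, y))

    def test_normal_approx_matches_scipy(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=25)
        y = rng.normal(0.5, size=30)
        res = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        assert res.u_statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_all_values_tied_degenerate(self):
        res = mann_whitney([2.0] * 5, [2.0] * 7)
        assert res.p_value == 1.0
        assert res.z_score == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidSpecError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(10.0)
        assert spearman(x, x**3)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_ties_match_manual_midranks(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0]
        y = [2.0, 1.0, 4.0, 4.0, 5.0]
        rho, _ = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        manual = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(manual)

    def test_constant_input_rejected(self):
        with pytest.raises(InvalidSpecError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSimpleRegression:
    def test_perfect_fit(self):
        x = np.arange(20.0)
        res = simple_regression(x, 2 * x + 1)
        assert res.r_squared == pytest.approx(1.0)
        assert res.beta_std[0] == pytest.approx(1.0)
        assert res.df1 == 1 and res.df2 == 18

    def test_beta_squared_equals_r_squared(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        y = 0.3 * x + rng.normal(size=100)
        res = simple_regression(x, y)
        assert res.beta_std[0] ** 2 == pytest.approx(res.r_squared)

    def test_standardized_slope_recovery(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        y = 0.5 * x + rng.normal(size=500)
        res = simple_regression(x, y)
        assert res.beta_std[0] == pytest.approx(0.45, abs=0.1)

    def test_constant_predictor_rejected(self):
        with pytest.raises(InvalidSpecError):
            simple_regression(np.ones(10), np.arange(10.0))


class TestMultipleRegression:
    def test_exact_solve_on_orthonormal_design(self):
        rng = np.random.default_rng(4)
        raw = rng.normal(size=(200, 2))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = q * np.sqrt(len(q) - 1)  # standardized, orthogonal predictors
        y = X @ np.array([0.4, 0.6])
        res = multiple_regression(X, y, names=["a", "b"])
        assert res.b_unstd == pytest.approx([0.4, 0.6], abs=1e-8)
        assert res.r_squared == pytest.approx(1.0)
        # orthogonal predictors: standardized betas satisfy sum(beta^2) = R^2
        assert np.sum(res.beta_std**2) == pytest.approx(1.0, abs=1e-8)

    def test_report_carries_all_columns(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=["f0", "e0", "dur"])
        y = X["f0"] + rng.normal(size=50)
        frame = multiple_regression(X, y).to_frame()
        assert list(frame.columns) == ["beta", "se_beta", "b", "se_b", "t", "p"]
        assert list(frame.index) == ["f0", "e0", "dur"]

    def test_collinearity_names_offender(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=40)
        X = pd.DataFrame({"a": a, "b": rng.normal(size=40), "a_copy": 2 * a})
        with pytest.raises(CollinearityError, match="a"):
            multiple_regression(X, rng.normal(size=40))

    def test_correlated_design_recovery(self):
        rng = np.random.default_rng(7)
        beta = np.array([0.5, -0.3, 0.2])
        cov = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        est = np.zeros(3)
        reps = 200
        for _ in range(reps):
            X = rng.multivariate_normal(np.zeros(3), cov, size=1000)
            y = X @ beta + rng.normal(size=1000)
            est += multiple_regression(X, y).b_unstd
        assert est / reps == pytest.approx(beta, abs=0.05)

    def test_residuals_orthogonal_to_predictors(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 2))
        y = X @ np.array([1.0, -2.0]) + rng.normal(size=80)
        res = multiple_regression(X, y)
        fitted = res.intercept + X @ res.b_unstd
        resid = y - fitted
        assert np.abs(X.T @ resid).max() < 1e-8


class TestContrasts:
    @staticmethod
    def _features(n=30, means=(280, 240, 210, 260), sd=20.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for emotion, mu in zip(("joy", "neutral", "sadness", "anger"), means):
            for v in rng.normal(mu, sd, size=n):
                rows.append({"emotion": emotion, "f0_max": v})
        return pd.DataFrame(rows)

    def test_expected_directions_significant(self):
        table = feature_emotion_contrasts(
            self._features(), feature_columns=("f0_max",))
        by_label = table.set_index("contrast")
        assert by_label.loc["N<J", "p"] < 0.05
        assert by_label.loc["S<J", "p"] < 0.05

    def test_null_contrast_rarely_significant(self):
        """Two emotions drawn from one distribution: ~5% false-positive rate."""
        hits = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({
                "emotion": ["joy"] * 20 + ["neutral"] * 20,
                "f0_max": rng.normal(250, 20, size=40),
            })
            out = feature_emotion_contrasts(df, feature_columns=("f0_max",))
            hits += bool(out["significant"].iloc[0])
        assert reps - hits >= 0.94 * reps

    def test_tiny_class_skipped_with_warning(self):
        df = pd.DataFrame({
            "emotion": ["joy"] * 10 + ["neutral"],
            "f0_max": np.r_[np.random.default_rng(0).normal(280, 10, 10), 240.0],
        })
        with pytest.warns(UserWarning, match="skipped"):
            out = feature_emotion_contrasts(df, feature_columns=("f0_max",))
        assert out.empty

    def test_holm_adjustment_monotone(self):
        p = np.array([0.001, 0.02, 0.04, 0.2])
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        assert adj[0] == pytest.approx(0.004)
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)
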