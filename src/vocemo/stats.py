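"""Nonparametric tests and regressions linking acoustics to labels.

The Mann-Whitney U test is implemented here directly: exact enumeration of
all C(n1+n2, n1) group assignments (with midranks for ties) when the
combined sample is small, otherwise the tie-corrected normal approximation
with an optional continuity correction.  Spearman correlation and the OLS
regressions delegate to scipy / statsmodels; regression results carry both
standardized (beta) and unstandardized (B) coefficients with standard
errors, matching the conventional multiple-regression report layout.

Raw p-values are reported uncorrected by default; a Holm step-down
adjustment is available behind a flag for the pairwise contrast table.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .emotions import EMOTIONS, EmotionLabel
from .errors import CollinearityError, InvalidSpecError

EXACT_MAX_COMBINED_N = 12  # enumeration cost bound: C(12, 6) = 924 splits

#: Feature columns the pairwise contrast table covers by default.
CONTRAST_FEATURES = (
    "f0_mean", "f0_max", "f0_min", "f0_range",
    "emax_over_e0", "e0min_over_e0", "emax_over_emin", "duration_ms",
)


@dataclass
class RankTestResult:
    u_statistic: float
    z_score: float
    p_value: float
    n1: int
    n2: int
    method: str = "normal_approx"


@dataclass
class RegressionResult:
    f_statistic: float
    df1: int
    df2: int
    r_squared: float
    beta_std: np.ndarray      # standardized coefficients (per predictor)
    b_unstd: np.ndarray       # unstandardized coefficients (per predictor)
    se_beta: np.ndarray
    se_b: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    f_p_value: float
    intercept: float
    predictor_names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Per-coefficient report with the five conventional columns."""
        return pd.DataFrame({
            "beta": self.beta_std, "se_beta": self.se_beta,
            "b": self.b_unstd, "se_b": self.se_b, "t": self.t_values,
            "p": self.p_values,
        }, index=self.predictor_names)


# ---------------------------------------------------------------------------
# Mann-Whitney U

def _u_from_ranks(ranks_x: np.ndarray, n1: int) -> float:
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney(
    x,
    y,
    mode: str = "auto",
    continuity: bool = True,
) -> RankTestResult:
    """Two-sided Mann-Whitney U test with midranks for ties.

    mode='auto' enumerates exactly when n1 + n2 <= 12, otherwise uses the
    tie-corrected normal approximation (continuity correction on by
    default).  Identical samples give U = n1*n2/2, Z = 0, p = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise InvalidSpecError("both samples must be non-empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise InvalidSpecError("mode must be exact, normal_approx or auto")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    u1 = _u_from_ranks(ranks[:n1], n1)
    mu = n1 * n2 / 2.0

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        return RankTestResult(u1, 0.0, 1.0, n1, n2, "degenerate")
    sigma = np.sqrt(var)
    diff = u1 - mu
    cc = 0.5 if continuity else 0.0
    z = 0.0 if diff == 0 else (diff - np.sign(diff) * cc) / sigma

    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_MAX_COMBINED_N)
    if use_exact:
        total = comb(n, n1)
        extreme = 0
        target = abs(diff)
        for subset in combinations(range(n), n1):
            u = _u_from_ranks(ranks[list(subset)], n1)
            if abs(u - mu) >= target - 1e-9:
                extreme += 1
        p = extreme / total
        method = "exact"
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
        method = "normal_approx"
    return RankTestResult(u1, float(z), min(p, 1.0), n1, n2, method)


# ---------------------------------------------------------------------------
# Spearman correlation

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on midranks) with t-approximation p."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise InvalidSpecError("need paired samples of length >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise InvalidSpecError("zero variance in ranks; correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# OLS regressions

def _standardize_result(model, X: np.ndarray, y: np.ndarray,
                        names: list[str]) -> RegressionResult:
    sd_x = X.std(axis=0, ddof=1)
    sd_y = y.std(ddof=1)
    b = model.params[1:]
    se_b = model.bse[1:]
    scale = sd_x / sd_y
    return RegressionResult(
        f_statistic=float(model.fvalue),
        df1=int(model.df_model),
        df2=int(model.df_resid),
        r_squared=float(model.rsquared),
        beta_std=b * scale,
        b_unstd=np.asarray(b),
        se_beta=se_b * scale,
        se_b=np.asarray(se_b),
        t_values=np.asarray(model.tvalues[1:]),
        p_values=np.asarray(model.pvalues[1:]),
        f_p_value=float(model.f_pvalue),
        intercept=float(model.params[0]),
        predictor_names=names,
    )


def simple_regression(x, y) -> RegressionResult:
    """OLS of y on a single predictor; reports F(1, n-2), R-squared and the
    standardized beta (for which beta**2 = R-squared)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise InvalidSpecError("need paired samples of length >= 3")
    if np.std(x) == 0:
        raise InvalidSpecError("constant predictor")
    X = x[:, None]
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return _standardize_result(model, X, y, ["x"])


def multiple_regression(X, y, names: list[str] | None = None) -> RegressionResult:
    """OLS with intercept on a full-rank predictor matrix.

    Raises :class:`CollinearityError` naming the dependent columns when the
    design is rank deficient.
    """
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        names = names or [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if n <= p + 1:
        raise InvalidSpecError(f"need n > p + 1 observations (n={n}, p={p})")
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc)
    if rank < p + 1:
        # QR with column pivoting: columns pivoted beyond the rank are the offenders
        from scipy.linalg import qr

        _, _, piv = qr(Xc, pivoting=True)
        bad = sorted(
            names[j - 1] for j in piv[rank:] if j > 0
        )
        raise CollinearityError(f"rank-deficient design; dependent columns: {bad}")
    model = sm.OLS(y, Xc).fit()
    return _standardize_result(model, X, y, names)


# ---------------------------------------------------------------------------
# pairwise feature contrasts

def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(p_values, dtype=np.float64)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank_i, idx in enumerate(order):
        running = max(running, (m - rank_i) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def feature_emotion_contrasts(
    features: pd.DataFrame,
    labels=None,
    feature_columns: tuple[str, ...] = CONTRAST_FEATURES,
    speech_type: str = "",
    group: str = "",
    holm: bool = False,
) -> pd.DataFrame:
    """Mann-Whitney contrasts between every emotion pair for each feature.

    Direction follows the median: the contrast label is ``"X<Y"`` with X the
    lower-median emotion (single-letter aliases).  Classes with fewer than
    two utterances are skipped with a warning.  Returns a tidy table with
    columns speech_type, feature, contrast, p, group, significant.
    """
    if labels is not None:
        features = features.assign(emotion=list(labels))
    if "emotion" not in features.columns:
        raise InvalidSpecError("features table needs an 'emotion' column or labels")
    emo_col = features["emotion"].map(lambda e: EmotionLabel.from_string(e))

    rows = []
    for feat in feature_columns:
        if feat not in features.columns:
            continue
        for ea, eb in combinations(EMOTIONS, 2):
            xa = features.loc[emo_col == ea, feat].to_numpy(dtype=float)
            xb = features.loc[emo_col == eb, feat].to_numpy(dtype=float)
            if xa.size < 2 or xb.size < 2:
                warnings.warn(
                    f"contrast {ea.value} vs {eb.value} on {feat}: "
                    "fewer than 2 utterances in a class; skipped", stacklevel=2,
                )
                continue
            res = mann_whitney(xa, xb)
            med_a, med_b = np.median(xa), np.median(xb)
            lo, hi = (ea, eb) if med_a <= med_b else (eb, ea)
            rows.append({
                "speech_type": speech_type,
                "feature": feat,
                "contrast": f"{lo.letter}<{hi.letter}",
                "p": res.p_value,
                "group": group,
            })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if holm:
        out["p_adjusted"] = holm_adjust(out["p"].to_numpy())
        out["significant"] = out["p_adjusted"] < 0.05
    else:
        out["significant"] = out["p"] < 0.05
    return out
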