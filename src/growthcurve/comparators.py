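"""Baseline procedures the homologous test is compared against.

* pooled-variance two-sample t test (the conventional per-timepoint analysis),
* closed-form noncentral-t power for both the t test and the homologous test,
* a linear mixed model with fixed group, time and group x time effects and
  per-animal random intercepts, with the group difference evaluated at the
  final time point.

The LMM is fitted by a dedicated profiled-REML solver specialised to the
random-intercept covariance (two distinct eigenvalues per animal block), which
makes it fast enough to sit inside 10,000-replicate Monte-Carlo loops.  Its
estimates are checked against ``statsmodels.MixedLM`` in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TTestResult",
    "LmmResult",
    "two_sample_t",
    "analytic_t_power",
    "analytic_homologous_power",
    "lmm_group_diff_at_final",
    "RandomInterceptModel",
]

Sides = Literal["two", "greater", "less"]


@dataclass(frozen=True)
class TTestResult:
    """Pooled-variance two-sample t test (group 1 minus group 0)."""

    diff: float
    se: float
    t_stat: float
    df: int
    p_two_sided: float
    p_one_sided_greater: float
    p_one_sided_less: float

    def p_value(self, sides: Sides = "two") -> float:
        return {
            "two": self.p_two_sided,
            "greater": self.p_one_sided_greater,
            "less": self.p_one_sided_less,
        }[sides]


@dataclass(frozen=True)
class LmmResult:
    """Wald inference on the LMM group difference at the final time point."""

    estimate: float
    se: float
    stat: float
    p_two_sided: float | None
    converged: bool
    sigma2_animal: float | None = None
    sigma2_resid: float | None = None
    df: float | None = None


def two_sample_t(y0, y1, sides: Sides = "two") -> TTestResult:
    """Student t test with pooled variance on ``n0 + n1 - 2`` df."""
    y0 = np.asarray(y0, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    n0, n1 = len(y0), len(y1)
    if n0 < 2 or n1 < 2:
        raise ValueError("need at least 2 observations per group")
    diff = float(y1.mean() - y0.mean())
    df = n0 + n1 - 2
    ss = float(((y0 - y0.mean()) ** 2).sum() + ((y1 - y1.mean()) ** 2).sum())
    pooled_var = ss / df
    se = float(np.sqrt(pooled_var * (1.0 / n0 + 1.0 / n1)))
    if se == 0.0:
        if diff == 0.0:
            t_stat = 0.0
        else:
            raise ValueError(
                "zero pooled variance with a nonzero mean difference: "
                "the t statistic is undefined"
            )
    else:
        t_stat = diff / se
    p_greater = float(stats.t.sf(t_stat, df))
    p_less = float(stats.t.cdf(t_stat, df))
    p_two = min(1.0, 2.0 * min(p_greater, p_less))
    return TTestResult(
        diff=diff,
        se=se,
        t_stat=float(t_stat),
        df=df,
        p_two_sided=p_two,
        p_one_sided_greater=p_greater,
        p_one_sided_less=p_less,
    )


def _noncentral_t_power(ncp: float, df: int, alpha: float, sides: Sides) -> float:
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if sides == "two":
        tc = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(tc, df, ncp) + stats.nct.cdf(-tc, df, ncp))
    if sides == "greater":
        tc = stats.t.ppf(1 - alpha, df)
        return float(stats.nct.sf(tc, df, ncp))
    if sides == "less":
        tc = stats.t.ppf(alpha, df)
        return float(stats.nct.cdf(tc, df, ncp))
    raise ValueError(f"unknown sides {sides!r}")


def analytic_t_power(
    n_per_group: int,
    delta: float,
    sd: float,
    alpha: float = 0.05,
    sides: Sides = "two",
) -> float:
    """Exact power of the pooled two-sample t test, balanced groups.

    Noncentrality ``delta / (sd * sqrt(2 / n))`` on ``2n - 2`` degrees of
    freedom.  With ``delta = 0`` this returns ``alpha`` exactly.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    ncp = delta / (sd * np.sqrt(2.0 / n_per_group))
    return _noncentral_t_power(ncp, 2 * n_per_group - 2, alpha, sides)


def analytic_homologous_power(
    n0: int,
    n1: int,
    delta: float,
    conditional_sd: float,
    alpha: float = 0.05,
    sides: Sides = "two",
) -> float:
    """Exact power of the homologous test under the combined regression model.

    ``conditional_sd`` is the residual SD of the outcome given the lagged
    volume (i.e. the marginal SD shrunk by ``sqrt(1 - rho^2)``).  The
    noncentrality is ``delta / (conditional_sd * sqrt(1/n0 + 1/n1))`` on
    ``n0 + n1 - 4`` degrees of freedom.
    """
    if n0 + n1 < 5:
        raise ValueError("need n0 + n1 >= 5 (df = n - 4)")
    if conditional_sd <= 0:
        raise ValueError("conditional_sd must be positive")
    ncp = delta / (conditional_sd * np.sqrt(1.0 / n0 + 1.0 / n1))
    return _noncentral_t_power(ncp, n0 + n1 - 4, alpha, sides)


class RandomInterceptModel:
    """Profiled-REML solver for ``y = X beta + b_animal + e``.

    The marginal covariance within an animal block of size ``m`` is
    ``sigma2_e * (I + gamma * J)`` with ``gamma = sigma2_b / sigma2_e``; its
    inverse and determinant are closed-form, so REML reduces to a 1-D
    optimisation over ``gamma``.  The design is held fixed so repeated fits
    on fresh outcome vectors (Monte-Carlo replicates) are cheap.

    Rows must be sorted so each animal's observations are contiguous;
    ``block_sizes`` gives the number of observations per animal.
    """

    def __init__(self, X: np.ndarray, block_sizes: Sequence[int]):
        X = np.asarray(X, dtype=float)
        sizes = np.asarray(block_sizes, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if sizes.sum() != X.shape[0]:
            raise ValueError("block sizes do not sum to the number of rows")
        if (sizes < 1).any():
            raise ValueError("empty animal block")
        self.X = X
        self.sizes = sizes
        self.n, self.p = X.shape
        if np.linalg.matrix_rank(X) < self.p:
            raise ValueError("rank-deficient fixed-effects design")
        # per-block row sums of X: shape (n_blocks, p)
        edges = np.concatenate([[0], np.cumsum(sizes)])
        self._edges = edges
        self.Xsum = np.add.reduceat(X, edges[:-1], axis=0)
        self.XtX = X.T @ X

    def _profile(self, gamma: float, y: np.ndarray):
        """GLS quantities at fixed variance ratio ``gamma`` (unit error scale)."""
        w = gamma / (1.0 + self.sizes * gamma)  # shrinkage per block
        ysum = np.add.reduceat(y, self._edges[:-1])
        XtVX = self.XtX - (self.Xsum * w[:, None]).T @ self.Xsum
        XtVy = self.X.T @ y - (self.Xsum * w[:, None]).T @ ysum
        ytVy = y @ y - w @ ysum**2
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - beta @ XtVy
        return beta, rss, XtVX

    def _reml_criterion(self, gamma: float, y: np.ndarray) -> float:
        _, rss, XtVX = self._profile(gamma, y)
        if rss <= 0:
            return np.inf
        logdet_v = float(np.log1p(self.sizes * gamma).sum())
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        return (self.n - self.p) * np.log(rss) + logdet_v + logdet_x

    def fit(self, y: np.ndarray, gamma_max: float = 1e4):
        """REML fit; returns (beta, cov_beta, sigma2_e, sigma2_b, converged)."""
        y = np.asarray(y, dtype=float)
        res = optimize.minimize_scalar(
            self._reml_criterion,
            args=(y,),
            bounds=(0.0, gamma_max),
            method="bounded",
            options={"xatol": 1e-8},
        )
        gamma = float(res.x)
        # the bounded minimiser never lands exactly on 0; snap if flat there
        if self._reml_criterion(0.0, y) <= self._reml_criterion(gamma, y):
            gamma = 0.0
        beta, rss, XtVX = self._profile(gamma, y)
        sigma2_e = rss / (self.n - self.p)
        cov_beta = sigma2_e * np.linalg.inv(XtVX)
        return beta, cov_beta, float(sigma2_e), float(gamma * sigma2_e), bool(res.success)

    def _neg2_reml(self, s2b: float, s2e: float, y: np.ndarray) -> float:
        """-2 x restricted log-likelihood (additive constant dropped)."""
        if s2e <= 0 or s2b < 0:
            return np.inf
        gamma = s2b / s2e
        _, rss, XtVX = self._profile(gamma, y)
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0 or rss <= 0:
            return np.inf
        logdet_v = self.n * np.log(s2e) + float(np.log1p(self.sizes * gamma).sum())
        return logdet_v + logdet_x - self.p * np.log(s2e) + rss / s2e

    def satterthwaite_df(self, z: np.ndarray, y: np.ndarray, s2b: float, s2e: float) -> float:
        """Satterthwaite denominator df for the contrast ``z' beta``.

        ``df = 2 f^2 / (g' W g)`` where ``f(theta) = z' cov_beta(theta) z``,
        ``g`` its gradient in ``theta = (s2b, s2e)`` and ``W`` the asymptotic
        covariance of the REML variance estimates (twice the inverse Hessian
        of the -2 restricted log-likelihood), all by central differences.
        Falls back to the residual df at the ``s2b = 0`` boundary or when
        the Hessian is not positive definite.
        """
        resid_df = float(self.n - self.p)
        if s2b <= 1e-10 * max(s2e, 1e-300):
            return resid_df
        y = np.asarray(y, dtype=float)
        theta = np.array([s2b, s2e])

        def f(th):
            gamma = th[0] / th[1]
            _, _, XtVX = self._profile(gamma, y)
            return th[1] * float(z @ np.linalg.solve(XtVX, z))

        h = 1e-4 * theta
        grad = np.empty(2)
        for k in range(2):
            e = np.zeros(2)
            e[k] = h[k]
            grad[k] = (f(theta + e) - f(theta - e)) / (2 * h[k])

        def l(th):
            return self._neg2_reml(th[0], th[1], y)

        H = np.empty((2, 2))
        for k in range(2):
            e = np.zeros(2)
            e[k] = h[k]
            H[k, k] = (l(theta + e) - 2 * l(theta) + l(theta - e)) / h[k] ** 2
        e01 = np.array([h[0], h[1]])
        e0m1 = np.array([h[0], -h[1]])
        H[0, 1] = H[1, 0] = (
            l(theta + e01) - l(theta + e0m1) - l(theta - e0m1) + l(theta - e01)
        ) / (4 * h[0] * h[1])
        try:
            W = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return resid_df
        denom = float(grad @ W @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return resid_df
        df = 2.0 * f(theta) ** 2 / denom
        return float(min(max(df, 1.0), resid_df))


def _long_frame(long_data) -> pd.DataFrame:
    df = pd.DataFrame(long_data)
    missing = {"animal", "group", "time", "volume"} - set(df.columns)
    if missing:
        raise ValueError(f"long data missing columns: {sorted(missing)}")
    return df


def lmm_group_diff_at_final(
    long_data,
    df_method: Literal["satterthwaite", "normal", "residual"] = "satterthwaite",
) -> LmmResult:
    """LMM estimate of the between-group difference at the final time point.

    Fixed effects: intercept, group, time (continuous) and group x time;
    random per-animal intercepts, fitted by REML.  The reported estimate is
    the Wald contrast ``beta_group + t_final * beta_interaction``.  The
    p-value is a t test on Satterthwaite denominator df by default (what
    lme4/lmerTest report; a plain normal reference over-rejects at these
    sample sizes because the contrast SE ignores variance-component
    uncertainty); ``"normal"`` and residual-df ``"residual"`` references
    are also available.

    ``long_data`` is anything :class:`pandas.DataFrame` accepts with columns
    ``animal``, ``group`` (0/1), ``time`` (numeric) and ``volume``.
    """
    df = _long_frame(long_data)
    if not np.isin(df["group"].unique(), (0, 1)).all():
        raise ValueError("group must be coded 0/1")
    if df.groupby("group")["animal"].nunique().min() < 2:
        raise ValueError("need at least 2 animals per group")
    if df["time"].nunique() < 2:
        raise ValueError("need at least 2 time points")
    df = df.sort_values(["animal", "time"], kind="stable")
    sizes = df.groupby("animal", sort=False).size().to_numpy()
    g = df["group"].to_numpy(dtype=float)
    t = df["time"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), g, t, g * t])
    t_final = float(df["time"].max())
    model = RandomInterceptModel(X, sizes)
    try:
        beta, cov, s2e, s2b, converged = model.fit(df["volume"].to_numpy(dtype=float))
    except np.linalg.LinAlgError:
        return LmmResult(np.nan, np.nan, np.nan, None, converged=False)
    z = np.array([0.0, 1.0, 0.0, t_final])
    est = float(z @ beta)
    se = float(np.sqrt(z @ cov @ z))
    stat = est / se if se > 0 else 0.0
    if not converged:
        return LmmResult(est, se, float(stat), None, False, s2b, s2e)
    y = df["volume"].to_numpy(dtype=float)
    if df_method == "normal":
        p = 2.0 * float(stats.norm.sf(abs(stat)))
        ddf = None
    elif df_method == "residual":
        ddf = float(len(df) - 4)
        p = 2.0 * float(stats.t.sf(abs(stat), ddf))
    elif df_method == "satterthwaite":
        ddf = model.satterthwaite_df(z, y, s2b, s2e)
        p = 2.0 * float(stats.t.sf(abs(stat), ddf))
    else:
        raise ValueError(f"unknown df_method {df_method!r}")
    return LmmResult(est, se, float(stat), min(1.0, p), True, s2b, s2e, ddf)
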