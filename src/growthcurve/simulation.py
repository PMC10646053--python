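"""Monte-Carlo engines for the two power studies.

Study 1 draws data from the four-coefficient regression model itself
(lagged values standard normal, n = 10 split equally) and compares the
homologous test's rejection rate with the pooled two-sample t test's.

Study 2 draws six-timepoint panels for two arms of 16 animals with
compound-symmetry errors (variance 1, covariance 0.5) and compares the
homologous test, the t test, and the random-intercept LMM at the final
time point.

Both engines are vectorised; the per-replicate statistics are verified
against the object-level :func:`growthcurve.homologous_core.homologous_test`
path in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .comparators import RandomInterceptModel

__all__ = [
    "Study1Config",
    "Study2Scenario",
    "PowerEstimate",
    "simulate_study1",
    "make_cs_covariance",
    "draw_scenario_errors",
    "scenario_overlap_null",
    "scenario_constant_shift",
    "scenario_linear_divergence",
    "scenario_late_divergence",
    "scenario_transient_bump",
    "simulate_study2",
]

Sides = Literal["two", "greater", "less"]


@dataclass(frozen=True)
class Study1Config:
    """Configuration of the regression-model power simulation.

    ``beta`` is ``(b0, b1, b2, b3)`` for intercept, group, lag and
    group x lag.  ``calibrate`` centres each arm's simulated lagged values at
    zero inside every replicate before generating the homologous test's
    outcomes, which pins the two arms' conditional-mean adjustments to a
    common value (zero) so the conditional and marginal group differences
    coincide at ``b1``.  The t test always runs on outcomes generated from
    the uncentred lagged values, i.e. on the marginal data-generating law —
    this is the configuration under which both tests hold their nominal size
    and reproduce the published power grid (see the module tests).
    """

    sigma: float
    beta: tuple[float, float, float, float] = (0.0, 1.0, 1.0, 0.0)
    n_total: int = 10
    reps: int = 10_000
    alpha: float = 0.05
    sides: Sides = "greater"
    seed: int | None = None
    calibrate: bool = True

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if len(self.beta) != 4:
            raise ValueError("beta must have four entries")
        if self.n_total < 6 or self.n_total % 2:
            raise ValueError("n_total must be even and >= 6")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sides not in ("two", "greater", "less"):
            raise ValueError(f"unknown sides {self.sides!r}")


@dataclass(frozen=True)
class Study2Scenario:
    """Two-arm longitudinal scenario: expected outcomes and error covariance."""

    means: np.ndarray  # shape (2, m)
    n_per_group: int
    cov: np.ndarray  # shape (m, m)
    name: str = "custom"

    def __post_init__(self):
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "cov", cov)
        if means.shape[0] != 2 or means.shape[1] < 2:
            raise ValueError("means must be a 2 x m matrix with m >= 2")
        m = means.shape[1]
        if cov.shape != (m, m):
            raise ValueError("cov must be m x m")
        if not np.allclose(cov, cov.T):
            raise ValueError("cov must be symmetric")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("cov must be positive definite")
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")

    @property
    def m(self) -> int:
        return self.means.shape[1]


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo rejection probability with its binomial standard error."""

    test_name: str
    rejections: int
    reps: int
    power: float
    mc_se: float
    config: dict = field(default_factory=dict)
    failures: int = 0

    @classmethod
    def from_counts(cls, test_name, rejections, reps, config=None, failures=0):
        effective = reps - failures
        p = rejections / effective if effective else float("nan")
        se = float(np.sqrt(p * (1 - p) / effective)) if effective else float("nan")
        return cls(
            test_name=test_name,
            rejections=int(rejections),
            reps=int(reps),
            power=float(p),
            mc_se=se,
            config=dict(config or {}),
            failures=int(failures),
        )


def _reject(t_stats: np.ndarray, df: int, alpha: float, sides: Sides) -> np.ndarray:
    if sides == "greater":
        return t_stats > stats.t.ppf(1 - alpha, df)
    if sides == "less":
        return t_stats < stats.t.ppf(alpha, df)
    return np.abs(t_stats) > stats.t.ppf(1 - alpha / 2, df)


def _group_sums(y: np.ndarray, p: np.ndarray):
    """Per-replicate centred sums for one arm; y, p of shape (reps, n_g)."""
    yd = y - y.mean(axis=1, keepdims=True)
    pd_ = p - p.mean(axis=1, keepdims=True)
    syy = np.einsum("ij,ij->i", yd, yd)
    spp = np.einsum("ij,ij->i", pd_, pd_)
    syp = np.einsum("ij,ij->i", yd, pd_)
    return syy, spp, syp


def _homologous_t_stats(y0, y1, p0, p1):
    """Vectorised homologous t statistics over replicates.

    Equivalent to running :func:`homologous_core.homologous_test` on each
    replicate: the contrast estimate is the difference of current means and
    its variance is ``MSE * (1/n0 + 1/n1)`` with ``MSE`` pooled over the two
    per-arm simple-regression SSEs on ``n - 4`` df.
    """
    n0, n1 = y0.shape[1], y1.shape[1]
    syy0, spp0, syp0 = _group_sums(y0, p0)
    syy1, spp1, syp1 = _group_sums(y1, p1)
    sse = (syy0 - syp0**2 / spp0) + (syy1 - syp1**2 / spp1)
    df = n0 + n1 - 4
    mse = sse / df
    d = y1.mean(axis=1) - y0.mean(axis=1)
    se = np.sqrt(mse * (1.0 / n0 + 1.0 / n1))
    return d / se, df


def _pooled_t_stats(y0, y1):
    n0, n1 = y0.shape[1], y1.shape[1]
    df = n0 + n1 - 2
    ss0 = ((y0 - y0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss1 = ((y1 - y1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    se = np.sqrt((ss0 + ss1) / df * (1.0 / n0 + 1.0 / n1))
    return (y1.mean(axis=1) - y0.mean(axis=1)) / se, df


def _lag_correlations(y, p):
    yd = y - y.mean(axis=1, keepdims=True)
    pd_ = p - p.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", yd, pd_)
    den = np.sqrt(
        np.einsum("ij,ij->i", yd, yd) * np.einsum("ij,ij->i", pd_, pd_)
    )
    return num / den


def simulate_study1(config: Study1Config) -> tuple[PowerEstimate, PowerEstimate]:
    """Monte-Carlo power of the homologous vs. the pooled t test (Study 1).

    Per replicate: lagged values are drawn standard normal (``n_total/2``
    per arm) and outcomes follow the four-coefficient model with
    ``N(0, sigma^2)`` errors.  With ``calibrate=True`` the homologous test's
    outcomes are generated from within-arm-centred lagged values (same error
    draws), equalising the two conditional-mean adjustments; the t test uses
    the uncentred outcomes.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    ng = n // 2
    b0, b1, b2, b3 = config.beta
    prev0 = rng.standard_normal((config.reps, ng))
    prev1 = rng.standard_normal((config.reps, ng))
    eps0 = rng.standard_normal((config.reps, ng)) * config.sigma
    eps1 = rng.standard_normal((config.reps, ng)) * config.sigma

    y0_marg = b0 + b2 * prev0 + eps0
    y1_marg = b0 + b1 + (b2 + b3) * prev1 + eps1

    if config.calibrate:
        prev0_h = prev0 - prev0.mean(axis=1, keepdims=True)
        prev1_h = prev1 - prev1.mean(axis=1, keepdims=True)
        y0_h = b0 + b2 * prev0_h + eps0
        y1_h = b0 + b1 + (b2 + b3) * prev1_h + eps1
    else:
        prev0_h, prev1_h = prev0, prev1
        y0_h, y1_h = y0_marg, y1_marg

    t_hom, df_hom = _homologous_t_stats(y0_h, y1_h, prev0_h, prev1_h)
    t_std, df_std = _pooled_t_stats(y0_marg, y1_marg)
    rej_hom = int(_reject(t_hom, df_hom, config.alpha, config.sides).sum())
    rej_std = int(_reject(t_std, df_std, config.alpha, config.sides).sum())

    base = {
        "sigma": config.sigma,
        "beta": tuple(config.beta),
        "n_total": n,
        "alpha": config.alpha,
        "sides": config.sides,
        "seed": config.seed,
        "calibrate": config.calibrate,
    }
    diag = {
        "rho_bar_0": float(_lag_correlations(y0_h, prev0_h).mean()),
        "rho_bar_1": float(_lag_correlations(y1_h, prev1_h).mean()),
    }
    hom = PowerEstimate.from_counts(
        "homologous", rej_hom, config.reps, {**base, **diag}
    )
    std = PowerEstimate.from_counts("t_test", rej_std, config.reps, base)
    return hom, std


def make_cs_covariance(m: int, variance: float = 1.0, covariance: float = 0.5) -> np.ndarray:
    """Compound-symmetry covariance: ``variance`` on the diagonal, constant off."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if variance <= 0:
        raise ValueError("variance must be positive")
    corr = covariance / variance
    if not (-1.0 / (m - 1) if m > 1 else -np.inf) < corr < 1.0:
        raise ValueError(
            f"covariance/variance = {corr} outside the positive-definite "
            f"range (-1/{m - 1}, 1)"
        )
    return np.full((m, m), covariance) + np.eye(m) * (variance - covariance)


def _times(m: int) -> np.ndarray:
    return np.arange(1, m + 1, dtype=float)


def draw_scenario_errors(
    scenario: Study2Scenario, n_draws: int, seed: int | None = None
) -> np.ndarray:
    """Error vectors exactly as the Study-2 engine draws them (diagnostics)."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(scenario.cov)
    return rng.standard_normal((n_draws, scenario.m)) @ L.T


def scenario_overlap_null(m: int = 6, n_per_group: int = 16) -> Study2Scenario:
    """Scenario 1: the two arms' expected outcomes completely overlap (all zero)."""
    return Study2Scenario(
        means=np.zeros((2, m)),
        n_per_group=n_per_group,
        cov=make_cs_covariance(m, 1.0, 0.5),
        name="overlap_null",
    )


def scenario_constant_shift(
    shift: float, m: int = 6, n_per_group: int = 16
) -> Study2Scenario:
    """Both arms shifted equally by ``shift`` — a relabelled null."""
    return Study2Scenario(
        means=np.full((2, m), float(shift)),
        n_per_group=n_per_group,
        cov=make_cs_covariance(m, 1.0, 0.5),
        name="constant_shift",
    )


def scenario_linear_divergence(
    final_diff: float = 1.0, m: int = 6, n_per_group: int = 16
) -> Study2Scenario:
    """Reconstruction: arm 1 diverges linearly to ``final_diff`` at the last time.

    The published trajectories exist only as a figure; this and the builders
    below are qualitative stand-ins, not digitised curves.
    """
    t = _times(m)
    ramp = final_diff * (t - t[0]) / (t[-1] - t[0])
    return Study2Scenario(
        means=np.vstack([np.zeros(m), ramp]),
        n_per_group=n_per_group,
        cov=make_cs_covariance(m, 1.0, 0.5),
        name="linear_divergence",
    )


def scenario_late_divergence(
    final_diff: float = 1.0, onset: int = 4, m: int = 6, n_per_group: int = 16
) -> Study2Scenario:
    """Reconstruction: arms overlap until ``onset``, then arm 1 ramps up."""
    if not 1 <= onset < m:
        raise ValueError("onset must be in 1..m-1")
    t = _times(m)
    ramp = np.where(
        t <= onset, 0.0, final_diff * (t - onset) / (t[-1] - onset)
    )
    return Study2Scenario(
        means=np.vstack([np.zeros(m), ramp]),
        n_per_group=n_per_group,
        cov=make_cs_covariance(m, 1.0, 0.5),
        name="late_divergence",
    )


def scenario_transient_bump(
    peak: float = 1.0, m: int = 6, n_per_group: int = 16
) -> Study2Scenario:
    """Reconstruction: arm 1 rises then returns, equal means at the final time.

    A non-linear null at the final time point; a straight-line LMM projects
    the mid-study separation onto the endpoint and over-rejects there.
    """
    t = _times(m)
    mid = (t[0] + t[-1]) / 2.0
    bump = peak * (1.0 - ((t - mid) / (mid - t[0])) ** 2)
    return Study2Scenario(
        means=np.vstack([np.zeros(m), bump]),
        n_per_group=n_per_group,
        cov=make_cs_covariance(m, 1.0, 0.5),
        name="transient_bump",
    )


def _calibrated_final_pair(data: np.ndarray, means: np.ndarray, cov: np.ndarray):
    """Rebuild one arm's (penultimate, final) values with centred lag noise.

    The arm's penultimate-time error deviations are centred across animals
    within each replicate, and the final-time values are regenerated from
    the bivariate conditional law using the *same* conditional-noise draws:
    ``curr = mu_final + b * centred_prev_error + u`` where ``b`` is the
    conditional slope ``cov[-1, -2] / cov[-2, -2]`` and ``u`` is the
    realised conditional residual.  This pins both arms' lagged sample
    means to their population values, so the conditional group difference
    the homologous test sees equals the marginal one.
    """
    eps_prev = data[:, :, -2] - means[-2]
    eps_curr = data[:, :, -1] - means[-1]
    b = cov[-1, -2] / cov[-2, -2]
    u = eps_curr - b * eps_prev
    prev_c = eps_prev - eps_prev.mean(axis=1, keepdims=True)
    prev_h = means[-2] + prev_c
    curr_h = means[-1] + b * prev_c + u
    return curr_h, prev_h


def simulate_study2(
    scenario: Study2Scenario,
    reps: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    sides: Sides = "two",
    lmm_df_method: Literal["satterthwaite", "normal", "residual"] = "satterthwaite",
    calibrate: bool = True,
) -> tuple[PowerEstimate, PowerEstimate, PowerEstimate]:
    """Rejection rates of the homologous, t, and LMM tests at the final time.

    Per replicate each animal's outcome vector is its arm's mean trajectory
    plus multivariate-normal error with the scenario covariance.  The
    homologous and t tests run at the final time point (the homologous test
    conditions on the penultimate one); the LMM uses the full panel with
    continuous time ``1..m``.  LMM replicates that fail to converge are
    counted and excluded from that test's denominator only.

    With ``calibrate=True`` the homologous test's final time-point pair is
    rebuilt with within-arm-centred lagged deviations (same conditional
    noise; see :func:`_calibrated_final_pair`), which equalises the two
    arms' conditional-mean adjustments.  Without it the homologous test
    answers its own conditional question: its rejection rate under a
    marginal null exceeds ``alpha`` by design, because the arms' observed
    lagged means differ by chance.  The t test and LMM always run on the
    unmodified panels.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    m = scenario.m
    ng = scenario.n_per_group
    L = np.linalg.cholesky(scenario.cov)
    data0 = scenario.means[0] + rng.standard_normal((reps, ng, m)) @ L.T
    data1 = scenario.means[1] + rng.standard_normal((reps, ng, m)) @ L.T

    if calibrate:
        curr0, prev0 = _calibrated_final_pair(data0, scenario.means[0], scenario.cov)
        curr1, prev1 = _calibrated_final_pair(data1, scenario.means[1], scenario.cov)
    else:
        curr0, prev0 = data0[:, :, -1], data0[:, :, -2]
        curr1, prev1 = data1[:, :, -1], data1[:, :, -2]
    t_hom, df_hom = _homologous_t_stats(curr0, curr1, prev0, prev1)
    t_std, df_std = _pooled_t_stats(data0[:, :, -1], data1[:, :, -1])
    rej_hom = int(_reject(t_hom, df_hom, alpha, sides).sum())
    rej_std = int(_reject(t_std, df_std, alpha, sides).sum())

    # LMM: fixed design identical across replicates (balanced panel)
    times = _times(m)
    g = np.repeat([0.0, 1.0], ng * m)
    t = np.tile(times, 2 * ng)
    X = np.column_stack([np.ones(2 * ng * m), g, t, g * t])
    model = RandomInterceptModel(X, np.full(2 * ng, m))
    z = np.array([0.0, 1.0, 0.0, times[-1]])
    n_rows = 2 * ng * m
    if lmm_df_method == "normal":
        crit = stats.norm.ppf(1 - alpha / 2)
    else:
        crit = stats.t.ppf(1 - alpha / 2, n_rows - 4)
    rej_lmm = 0
    failures = 0
    for r in range(reps):
        y = np.concatenate([data0[r].ravel(), data1[r].ravel()])
        try:
            beta, cov, s2e, s2b, converged = model.fit(y)
        except np.linalg.LinAlgError:
            converged = False
        if not converged:
            failures += 1
            continue
        est = z @ beta
        se = np.sqrt(z @ cov @ z)
        if lmm_df_method == "satterthwaite":
            ddf = model.satterthwaite_df(z, y, s2b, s2e)
            crit = stats.t.ppf(1 - alpha / 2, ddf)
        if abs(est) > crit * se:
            rej_lmm += 1

    cfg = {
        "scenario": scenario.name,
        "n_per_group": ng,
        "m": m,
        "alpha": alpha,
        "sides": sides,
        "seed": seed,
        "reps": reps,
        "calibrate": calibrate,
    }
    hom = PowerEstimate.from_counts("homologous", rej_hom, reps, cfg)
    std = PowerEstimate.from_counts("t_test", rej_std, reps, cfg)
    lmm = PowerEstimate.from_counts(
        "lmm", rej_lmm, reps, {**cfg, "df_method": lmm_df_method}, failures=failures
    )
    return hom, std, lmm
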