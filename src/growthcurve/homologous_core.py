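"""Lag-conditioned ("homologous") comparison of two treatment arms at one time point.

The test compares the two groups' expected volumes at time point ``j``, each
conditioned on its own group mean at time point ``j - 1``.  Conditioning on the
previous measurement replaces the marginal outcome variance by the conditional
one, ``Var(Y_j) * (1 - rho^2)``, so with strongly autocorrelated growth curves
the resulting t test is far more efficient than the plain two-sample t test,
while its point estimate of the group difference is algebraically identical to
the difference of the raw time-``j`` group means.

Inference runs through a single four-coefficient regression of the time-``j``
volumes on (intercept, group, lagged volume, group x lagged volume), which fits
each group's line independently.  The group contrast is read off with the
vector ``z = (0, 1, m1_prev - m0_prev, m1_prev)`` where ``m{g}_prev`` is group
``g``'s sample mean at the previous time point; the t statistic uses the
pooled residual mean square on ``n - 4`` degrees of freedom.

Time-point indices ``j`` are 1-based throughout (``j = 1`` is the baseline,
which has no lagged measurement and therefore no homologous test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DatasetError",
    "DegenerateLagError",
    "GrowthCurveDataset",
    "GroupLagSummary",
    "GroupConditionalFit",
    "RegressionFit",
    "HomologousResult",
    "group_lag_summary",
    "fit_group_regression",
    "fit_combined_regression",
    "homologous_contrast",
    "homologous_test",
]

Sides = Literal["two", "greater", "less"]


class DatasetError(ValueError):
    """Raised for structurally invalid growth-curve data."""


class DegenerateLagError(ValueError):
    """Raised when the lagged volumes are constant within a group.

    The conditional regression is singular in that case; the plain two-sample
    t test (:func:`growthcurve.comparators.two_sample_t`) remains available.
    """


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class GrowthCurveDataset:
    """Wide-format growth-curve data: animals x time points, two arms.

    Parameters
    ----------
    animal_ids
        Opaque per-animal labels, unique.
    group
        Per-animal binary arm indicator; 0 is the reference/control arm.
    times
        Strictly increasing measurement times (e.g. study days).
    volumes
        ``(n_animals, n_times)`` matrix of tumor volumes; no missing values.
    scale
        ``"raw"`` or ``"log"`` — whether volumes are on the natural-log scale.
    unit
        Free-text unit metadata (default cubic millimetres).
    """

    animal_ids: tuple
    group: np.ndarray
    times: np.ndarray
    volumes: np.ndarray
    scale: Literal["raw", "log"] = "raw"
    unit: str = "mm3"

    def __post_init__(self):
        object.__setattr__(self, "animal_ids", tuple(self.animal_ids))
        group = np.asarray(self.group, dtype=int)
        times = np.asarray(self.times, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "volumes", volumes)

        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise DatasetError("duplicate animal_ids")
        if group.ndim != 1 or len(group) != len(self.animal_ids):
            raise DatasetError("group must have one entry per animal")
        if not np.isin(group, (0, 1)).all():
            raise DatasetError("group must contain only 0 and 1")
        if not ((group == 0).any() and (group == 1).any()):
            raise DatasetError("both groups must be present")
        if times.ndim != 1 or len(times) < 1:
            raise DatasetError("times must be a non-empty vector")
        if not np.all(np.diff(times) > 0):
            raise DatasetError("times must be strictly increasing")
        if volumes.shape != (len(self.animal_ids), len(times)):
            raise DatasetError(
                f"volumes shape {volumes.shape} does not match "
                f"({len(self.animal_ids)} animals, {len(times)} times)"
            )
        if np.isnan(volumes).any():
            raise DatasetError(
                "volumes contain missing values; complete cases are required"
            )
        if not np.all(np.isfinite(volumes)):
            raise DatasetError("volumes contain non-finite values")
        if self.scale not in ("raw", "log"):
            raise DatasetError(f"unknown scale {self.scale!r}")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_times(self) -> int:
        return len(self.times)

    def group_size(self, g: int) -> int:
        return int((self.group == g).sum())

    def volumes_at(self, j: int, group: int | None = None) -> np.ndarray:
        """Volume vector at 1-based time-point index ``j``, optionally one arm."""
        if not 1 <= j <= self.n_times:
            raise IndexError(f"time-point index {j} out of range 1..{self.n_times}")
        col = self.volumes[:, j - 1]
        if group is None:
            return col.copy()
        return col[self.group == group]


@dataclass(frozen=True)
class GroupLagSummary:
    """Moment summaries of one arm at a (previous, current) time-point pair.

    ``rho`` is the Pearson correlation between the paired current and lagged
    volumes; it is ``None`` (never silently zero) when either SD vanishes.
    """

    group: int
    j: int
    n: int
    mean_curr: float
    mean_prev: float
    sd_curr: float
    sd_prev: float
    rho: float | None

    @property
    def rho_defined(self) -> bool:
        return self.rho is not None


@dataclass(frozen=True)
class GroupConditionalFit:
    """Least-squares fit of one arm's current volumes on its lagged volumes.

    ``fitted_at_mean`` — the conditional-mean estimate evaluated at the lagged
    group mean — equals the arm's plain sample mean at the current time point.
    ``se_conditional_mean`` is ``sqrt(mse / n)`` with ``mse`` on ``n - 2``
    degrees of freedom, the efficient "homologous" standard error.
    """

    group: int
    n: int
    intercept: float
    slope: float
    mse: float
    se_conditional_mean: float
    fitted_at_mean: float


@dataclass(frozen=True)
class RegressionFit:
    """Four-coefficient combined fit (intercept, group, lag, group x lag)."""

    beta: np.ndarray
    beta_cov: np.ndarray
    xtx_inv: np.ndarray
    sse: float
    mse: float
    df: int
    n0: int
    n1: int


@dataclass(frozen=True)
class HomologousResult:
    """Full inference output of the homologous test at one time point."""

    j: int
    d_hat: float
    se_d: float
    t_stat: float
    df: int
    p_two_sided: float
    p_one_sided_greater: float
    p_one_sided_less: float
    contrast: np.ndarray
    sides: Sides
    alpha: float
    reject: bool
    group_summaries: tuple[GroupLagSummary, GroupLagSummary]
    group_fits: tuple[GroupConditionalFit, GroupConditionalFit]
    fit: RegressionFit = field(repr=False)

    def p_value(self, sides: Sides | None = None) -> float:
        sides = self.sides if sides is None else sides
        return {
            "two": self.p_two_sided,
            "greater": self.p_one_sided_greater,
            "less": self.p_one_sided_less,
        }[sides]


def group_lag_summary(curr, prev, group: int, j: int) -> GroupLagSummary:
    """Means, SDs (``n - 1`` denominator) and lag correlation for one arm.

    ``curr`` and ``prev`` are the arm's volumes at time ``j`` and ``j - 1``,
    paired by animal.
    """
    curr = _as_float_vector(curr, "curr")
    prev = _as_float_vector(prev, "prev")
    if len(curr) != len(prev):
        raise ValueError(f"curr (n={len(curr)}) and prev (n={len(prev)}) differ in length")
    n = len(curr)
    if n < 2:
        raise ValueError(f"need at least 2 animals per group, got {n}")

    sd_curr = float(np.std(curr, ddof=1))
    sd_prev = float(np.std(prev, ddof=1))
    if sd_curr == 0.0 or sd_prev == 0.0:
        rho = None
    else:
        dc = curr - curr.mean()
        dp = prev - prev.mean()
        rho = float(dc @ dp / np.sqrt((dc @ dc) * (dp @ dp)))
        rho = min(1.0, max(-1.0, rho))
    return GroupLagSummary(
        group=int(group),
        j=int(j),
        n=n,
        mean_curr=float(curr.mean()),
        mean_prev=float(prev.mean()),
        sd_curr=sd_curr,
        sd_prev=sd_prev,
        rho=rho,
    )


def fit_group_regression(curr, prev, group: int) -> GroupConditionalFit:
    """Simple least-squares regression of one arm's current on lagged volumes.

    Requires ``n >= 3`` (residual df ``n - 2``) and non-constant lagged
    volumes.  The slope is ``rho * sd_curr / sd_prev`` and the fit evaluated
    at the lagged mean reproduces the current sample mean exactly.
    """
    curr = _as_float_vector(curr, "curr")
    prev = _as_float_vector(prev, "prev")
    if len(curr) != len(prev):
        raise ValueError("curr and prev must have the same length")
    n = len(curr)
    if n < 3:
        raise ValueError(f"per-group regression needs n >= 3, got {n}")
    dp = prev - prev.mean()
    spp = float(dp @ dp)
    if spp == 0.0:
        raise DegenerateLagError(
            f"lagged volumes are constant in group {group}; the conditional "
            "regression is singular — consider the plain two-sample t test"
        )
    dc = curr - curr.mean()
    slope = float(dc @ dp) / spp
    intercept = float(curr.mean() - slope * prev.mean())
    resid = dc - slope * dp
    sse = float(resid @ resid)
    mse = sse / (n - 2)
    return GroupConditionalFit(
        group=int(group),
        n=n,
        intercept=intercept,
        slope=slope,
        mse=mse,
        se_conditional_mean=float(np.sqrt(mse / n)),
        fitted_at_mean=float(curr.mean()),
    )


def _design_matrix(prev: np.ndarray, group: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(prev), group, prev, group * prev]
    )


def fit_combined_regression(curr, prev, group) -> RegressionFit:
    """Fit the combined four-coefficient model to all animals at once.

    Design columns are (1, group, lagged volume, group x lagged volume); the
    full interaction fits each arm's line independently, so the combined SSE
    is the sum of the two per-arm simple-regression SSEs.  Solved by QR
    least squares; a rank-deficient design (constant lag within an arm, or a
    missing arm) is a hard error, never a silent pseudo-inverse.
    """
    curr = _as_float_vector(curr, "curr")
    prev = _as_float_vector(prev, "prev")
    group = np.asarray(group, dtype=float)
    if not (len(curr) == len(prev) == len(group)):
        raise ValueError("curr, prev and group must have the same length")
    if not np.isin(group, (0.0, 1.0)).all():
        raise ValueError("group must contain only 0 and 1")
    n = len(curr)
    n1 = int(group.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both groups must be present")
    if n < 5:
        raise ValueError(f"combined regression needs n >= 5 (df = n - 4), got {n}")
    for g in (0, 1):
        pg = prev[group == g]
        if np.ptp(pg) == 0.0:
            raise DegenerateLagError(
                f"lagged volumes are constant in group {g}; the design matrix "
                "is rank-deficient — consider the plain two-sample t test"
            )

    X = _design_matrix(prev, group)
    if np.linalg.matrix_rank(X) < 4:
        raise DegenerateLagError("rank-deficient design matrix")
    beta, _, _, _ = np.linalg.lstsq(X, curr, rcond=None)
    resid = curr - X @ beta
    sse = float(resid @ resid)
    df = n - 4
    mse = sse / df
    xtx_inv = np.linalg.inv(X.T @ X)
    beta_cov = mse * xtx_inv
    return RegressionFit(
        beta=beta,
        beta_cov=beta_cov,
        xtx_inv=xtx_inv,
        sse=sse,
        mse=mse,
        df=df,
        n0=n0,
        n1=n1,
    )


def homologous_contrast(
    fit: RegressionFit, summ0: GroupLagSummary, summ1: GroupLagSummary
) -> tuple[float, float, np.ndarray]:
    """Group-difference estimate, its SE, and the contrast vector.

    The contrast ``z = (0, 1, m1_prev - m0_prev, m1_prev)`` maps the
    coefficients onto the conditional group difference; algebraically the
    estimate equals the difference of the raw time-``j`` group means, and
    ``z (X'X)^{-1} z' = 1/n0 + 1/n1``.
    """
    z = np.array(
        [0.0, 1.0, summ1.mean_prev - summ0.mean_prev, summ1.mean_prev]
    )
    d_hat = float(z @ fit.beta)
    se_d = float(np.sqrt(z @ fit.beta_cov @ z))
    return d_hat, se_d, z


def homologous_test(
    dataset: GrowthCurveDataset,
    j: int,
    sides: Sides = "two",
    alpha: float = 0.05,
) -> HomologousResult:
    """Run the homologous test at 1-based time-point index ``j`` (``j > 1``).

    The statistic ``d_hat / se_d`` is referred to a t distribution on
    ``n - 4`` degrees of freedom.  All three p-values are reported; the
    ``reject`` flag applies ``alpha`` to the requested sidedness (one-sided
    ``greater`` means group 1 exceeds group 0).
    """
    if j <= 1:
        raise ValueError(
            "no homologous test at the baseline time point (j = 1): "
            "there is no lagged measurement to condition on"
        )
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if sides not in ("two", "greater", "less"):
        raise ValueError(f"unknown sides {sides!r}")
    n0 = dataset.group_size(0)
    n1 = dataset.group_size(1)
    if min(n0, n1) < 3:
        raise ValueError(f"need at least 3 animals per group, got {n0} and {n1}")

    curr0 = dataset.volumes_at(j, group=0)
    prev0 = dataset.volumes_at(j - 1, group=0)
    curr1 = dataset.volumes_at(j, group=1)
    prev1 = dataset.volumes_at(j - 1, group=1)

    summ0 = group_lag_summary(curr0, prev0, group=0, j=j)
    summ1 = group_lag_summary(curr1, prev1, group=1, j=j)
    fit0 = fit_group_regression(curr0, prev0, group=0)
    fit1 = fit_group_regression(curr1, prev1, group=1)

    curr = np.concatenate([curr0, curr1])
    prev = np.concatenate([prev0, prev1])
    grp = np.concatenate([np.zeros(n0), np.ones(n1)])
    fit = fit_combined_regression(curr, prev, grp)

    d_hat, se_d, z = homologous_contrast(fit, summ0, summ1)
    if se_d == 0.0:
        t_stat = 0.0 if d_hat == 0.0 else np.inf * np.sign(d_hat)
    else:
        t_stat = d_hat / se_d
    p_greater = float(stats.t.sf(t_stat, fit.df))
    p_less = float(stats.t.cdf(t_stat, fit.df))
    p_two = min(1.0, 2.0 * min(p_greater, p_less))
    p_by_sides = {"two": p_two, "greater": p_greater, "less": p_less}
    return HomologousResult(
        j=int(j),
        d_hat=d_hat,
        se_d=se_d,
        t_stat=float(t_stat),
        df=fit.df,
        p_two_sided=p_two,
        p_one_sided_greater=p_greater,
        p_one_sided_less=p_less,
        contrast=z,
        sides=sides,
        alpha=alpha,
        reject=bool(p_by_sides[sides] <= alpha),
        group_summaries=(summ0, summ1),
        group_fits=(fit0, fit1),
        fit=fit,
    )
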