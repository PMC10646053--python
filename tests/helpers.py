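"""Independent brute-force oracles and dataset builders for the test suite.

The oracles deliberately avoid the package's code paths: explicit summation
formulas for the moment summaries, and an explicit normal-equations solve
(``inv(X'X) X'y``) plus t-tail evaluation for the combined regression test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from growthcurve.homologous_core import GrowthCurveDataset


def textbook_summary(curr, prev):
    """Moment summaries via raw power sums (sum x, sum y, sum xy, ...)."""
    x = np.asarray(prev, dtype=float)
    y = np.asarray(curr, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    var_x = (sxx - sx**2 / n) / (n - 1)
    var_y = (syy - sy**2 / n) / (n - 1)
    rho = (sxy - sx * sy / n) / np.sqrt((sxx - sx**2 / n) * (syy - sy**2 / n))
    return {
        "mean_curr": sy / n,
        "mean_prev": sx / n,
        "sd_curr": np.sqrt(var_y),
        "sd_prev": np.sqrt(var_x),
        "rho": rho,
    }


def explicit_combined_fit(curr, prev, group):
    """Combined 4-coefficient fit by the explicit inv(X'X) X'y solve."""
    curr = np.asarray(curr, dtype=float)
    prev = np.asarray(prev, dtype=float)
    group = np.asarray(group, dtype=float)
    X = np.column_stack([np.ones_like(prev), group, prev, group * prev])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ curr
    sse = float(curr @ curr - beta @ X.T @ curr)
    n = len(curr)
    mse = sse / (n - 4)
    return beta, xtx_inv, sse, mse


def oracle_homologous(curr, prev, group):
    """Full homologous-test oracle from the explicit matrix formulation."""
    curr = np.asarray(curr, dtype=float)
    prev = np.asarray(prev, dtype=float)
    group = np.asarray(group, dtype=float)
    beta, xtx_inv, sse, mse = explicit_combined_fit(curr, prev, group)
    m0_prev = prev[group == 0].mean()
    m1_prev = prev[group == 1].mean()
    z = np.array([0.0, 1.0, m1_prev - m0_prev, m1_prev])
    d = float(z @ beta)
    se = float(np.sqrt(mse * z @ xtx_inv @ z))
    df = len(curr) - 4
    t = d / se
    p_greater = float(stats.t.sf(t, df))
    p_less = float(stats.t.cdf(t, df))
    return {
        "beta": beta,
        "sse": sse,
        "mse": mse,
        "d_hat": d,
        "se_d": se,
        "t_stat": t,
        "df": df,
        "p_two_sided": min(1.0, 2 * min(p_greater, p_less)),
        "p_one_sided_greater": p_greater,
        "p_one_sided_less": p_less,
        "contrast": z,
    }


def random_dataset(rng, n0=5, n1=5, m=4, rho=0.8, sd=1.0, diff=0.0):
    """Random two-arm dataset with AR(1)-correlated columns (never degenerate)."""
    n = n0 + n1
    vols = np.empty((n, m))
    vols[:, 0] = rng.normal(0.0, sd, size=n)
    innov = sd * np.sqrt(1 - rho**2)
    for j in range(1, m):
        vols[:, j] = rho * vols[:, j - 1] + rng.normal(0.0, innov, size=n)
    vols[n0:] += diff
    return GrowthCurveDataset(
        animal_ids=tuple(f"a{i}" for i in range(n)),
        group=np.repeat([0, 1], [n0, n1]),
        times=np.arange(1.0, m + 1.0),
        volumes=vols,
    )
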