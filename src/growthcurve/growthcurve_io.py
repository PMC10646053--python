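"""Dataset I/O, the per-timepoint analysis report, and a fixture generator.

The canonical input is a wide CSV (``animal_id,group,<t1>,<t2>,...``); a long
dialect (``animal_id,group,time,volume``) is accepted and pivoted.  The
report produces one row per time point with, for each arm, the mean volume,
the lag-conditioned ("homologous") SE, the conventional SE and the lag
correlation, plus p-values from both tests.  The first time point has no
lagged measurement, so it carries the t test only.

The fixture generator emulates a small two-arm xenograft study (4 animals per
arm, nine measurement days) whose raw values are not republishable: per-arm
log-scale mean growth curves with stationary AR(1) animal-level deviations,
exponentiated to positive volumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .comparators import two_sample_t
from .homologous_core import (
    DatasetError,
    DegenerateLagError,
    GrowthCurveDataset,
    HomologousResult,
    Sides,
    homologous_test,
)

__all__ = [
    "TimepointReportRow",
    "FixtureSpec",
    "read_growth_csv",
    "write_growth_csv",
    "to_long",
    "analyze_curves",
    "report_frame",
    "render_report",
    "report_json",
    "generate_fixture",
]


@dataclass(frozen=True)
class TimepointReportRow:
    """One report row: per-arm summaries and both tests at a time point."""

    time: float
    j: int
    mean_0: float
    mean_1: float
    se_homologous_0: float | None
    se_homologous_1: float | None
    se_standard_0: float
    se_standard_1: float
    rho_0: float | None
    rho_1: float | None
    p_homologous: float | None
    p_ttest: float
    flag: str = ""  # "", "baseline", or a degenerate-fit message


@dataclass(frozen=True)
class FixtureSpec:
    """Synthetic two-arm growth-curve study layout.

    Log-volume for animal ``i`` in arm ``g`` at day ``t``:
    ``log_baseline[g] + growth_rate[g] * (t - t0) + r_it`` where ``r`` is a
    stationary AR(1) process with lag-one correlation ``rho`` and marginal SD
    ``noise_sd``, then exponentiated when ``scale == "raw"``.
    """

    n_per_group: int = 4
    times: tuple = (3, 5, 7, 12, 14, 17, 19, 21, 24)
    log_baseline: tuple[float, float] = (1.4, 1.4)
    growth_rates: tuple[float, float] = (0.19, 0.22)
    rho: float = 0.9
    noise_sd: float = 0.15
    seed: int | None = None
    scale: Literal["raw", "log"] = "raw"

    def __post_init__(self):
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if len(self.times) < 2:
            raise ValueError("need at least 2 time points")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("lag-correlation target must be in (-1, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _map_groups(raw: pd.Series, control: str | None) -> np.ndarray:
    values = raw.astype(str).str.strip()
    labels = sorted(values.unique())
    if set(labels) <= {"0", "1"}:
        return values.astype(int).to_numpy()
    if len(labels) != 2:
        raise DatasetError(
            f"expected exactly two group labels, found {labels}"
        )
    if control is None:
        raise DatasetError(
            f"non-numeric group labels {labels}: pass control=<label> to "
            "name the reference (group 0) arm"
        )
    if control not in labels:
        raise DatasetError(
            f"control label {control!r} not among group labels {labels}"
        )
    return (values != control).astype(int).to_numpy()


def _volumes_from_frame(frame: pd.DataFrame, value_cols) -> np.ndarray:
    block = frame[value_cols]
    for col in value_cols:
        bad = block[col].isna()
        if bad.any():
            row = frame.index[bad][0]
            raise DatasetError(
                f"missing or non-numeric volume for animal "
                f"{frame.loc[row, 'animal_id']!r}, column {col!r}"
            )
    return block.to_numpy(dtype=float)


def read_growth_csv(
    path,
    dialect: Literal["wide", "long"] = "wide",
    log_transform: bool = False,
    control: str | None = None,
) -> GrowthCurveDataset:
    """Load a growth-curve CSV into a validated dataset.

    Wide dialect: header ``animal_id,group,<t1>,<t2>,...`` with numeric time
    columns.  Long dialect: ``animal_id,group,time,volume`` (pivoted; every
    animal must have every time).  ``control`` names the label mapped to
    group 0 when labels are not already 0/1.  ``log_transform`` applies the
    natural log (volumes must be positive) and marks the dataset scale.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip() for c in df.columns]
    if dialect == "long":
        required = ["animal_id", "group", "time", "volume"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise DatasetError(f"long CSV missing columns {missing}")
        if df.duplicated(["animal_id", "time"]).any():
            raise DatasetError("duplicate (animal_id, time) records")
        wide = df.pivot(index="animal_id", columns="time", values="volume")
        if wide.isna().any().any():
            animal = wide.index[wide.isna().any(axis=1)][0]
            raise DatasetError(
                f"animal {animal!r} is missing one or more time points"
            )
        groups = df.drop_duplicates("animal_id").set_index("animal_id")["group"]
        if df.groupby("animal_id")["group"].nunique().max() > 1:
            raise DatasetError("an animal appears with two different groups")
        wide = wide.sort_index(axis=1)
        frame = wide.reset_index()
        frame.insert(1, "group", groups.loc[frame["animal_id"]].to_numpy())
        time_cols = list(wide.columns)
    elif dialect == "wide":
        if list(df.columns[:2]) != ["animal_id", "group"]:
            raise DatasetError(
                "wide CSV must start with columns animal_id,group; got "
                f"{list(df.columns[:2])}"
            )
        time_cols = list(df.columns[2:])
        if not time_cols:
            raise DatasetError("wide CSV has no time columns")
        frame = df
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    try:
        times = np.array([float(c) for c in time_cols])
    except (TypeError, ValueError) as exc:
        raise DatasetError(f"non-numeric time column header: {exc}") from exc
    if frame["animal_id"].duplicated().any():
        dup = frame.loc[frame["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise DatasetError(f"duplicate animal_id {dup!r}")

    numeric = frame.copy()
    for col in time_cols:
        numeric[col] = pd.to_numeric(frame[col], errors="coerce")
    volumes = _volumes_from_frame(numeric, time_cols)
    group = _map_groups(frame["group"], control)
    scale: Literal["raw", "log"] = "raw"
    if log_transform:
        if (volumes <= 0).any():
            raise DatasetError("log transform requires strictly positive volumes")
        volumes = np.log(volumes)
        scale = "log"
    return GrowthCurveDataset(
        animal_ids=tuple(frame["animal_id"].astype(str)),
        group=group,
        times=times,
        volumes=volumes,
        scale=scale,
    )


def write_growth_csv(dataset: GrowthCurveDataset, path) -> None:
    """Write the wide-dialect CSV (round-trips through :func:`read_growth_csv`)."""
    frame = pd.DataFrame(
        dataset.volumes, columns=[repr(float(t)) for t in dataset.times]
    )
    frame.insert(0, "group", dataset.group)
    frame.insert(0, "animal_id", dataset.animal_ids)
    frame.to_csv(path, index=False)


def to_long(dataset: GrowthCurveDataset) -> pd.DataFrame:
    """Long-format records (animal, group, time, volume), e.g. for the LMM."""
    n, m = dataset.volumes.shape
    return pd.DataFrame(
        {
            "animal": np.repeat(dataset.animal_ids, m),
            "group": np.repeat(dataset.group, m),
            "time": np.tile(dataset.times, n),
            "volume": dataset.volumes.ravel(),
        }
    )


def analyze_curves(
    dataset: GrowthCurveDataset,
    sides: Sides = "two",
    alpha: float = 0.05,
) -> list[TimepointReportRow]:
    """Per-timepoint report over the whole study.

    Row 1 (baseline) carries the two-sample t test only; later rows add the
    homologous test, the per-arm conditional ("homologous") SEs and the lag
    correlations.  A degenerate conditional fit flags its row rather than
    aborting the report.
    """
    if dataset.n_times < 2:
        raise ValueError("need at least 2 time points")
    rows: list[TimepointReportRow] = []
    for j in range(1, dataset.n_times + 1):
        y0 = dataset.volumes_at(j, group=0)
        y1 = dataset.volumes_at(j, group=1)
        tt = two_sample_t(y0, y1, sides=sides)
        se0 = float(np.std(y0, ddof=1) / math.sqrt(len(y0)))
        se1 = float(np.std(y1, ddof=1) / math.sqrt(len(y1)))
        common = dict(
            time=float(dataset.times[j - 1]),
            j=j,
            mean_0=float(y0.mean()),
            mean_1=float(y1.mean()),
            se_standard_0=se0,
            se_standard_1=se1,
            p_ttest=tt.p_value(sides),
        )
        if j == 1:
            rows.append(
                TimepointReportRow(
                    **common,
                    se_homologous_0=None,
                    se_homologous_1=None,
                    rho_0=None,
                    rho_1=None,
                    p_homologous=None,
                    flag="baseline",
                )
            )
            continue
        try:
            res = homologous_test(dataset, j, sides=sides, alpha=alpha)
        except DegenerateLagError as exc:
            rows.append(
                TimepointReportRow(
                    **common,
                    se_homologous_0=None,
                    se_homologous_1=None,
                    rho_0=None,
                    rho_1=None,
                    p_homologous=None,
                    flag=f"degenerate: {exc}",
                )
            )
            continue
        s0, s1 = res.group_summaries
        f0, f1 = res.group_fits
        rows.append(
            TimepointReportRow(
                **common,
                se_homologous_0=f0.se_conditional_mean,
                se_homologous_1=f1.se_conditional_mean,
                rho_0=s0.rho,
                rho_1=s1.rho,
                p_homologous=res.p_value(sides),
            )
        )
    return rows


def report_frame(rows: Sequence[TimepointReportRow]) -> pd.DataFrame:
    """Full-precision report as a DataFrame (one row per time point)."""
    return pd.DataFrame([asdict(r) for r in rows])


def render_report(rows: Sequence[TimepointReportRow]) -> str:
    """Human-readable TSV report, rounded to 3 decimals."""
    frame = report_frame(rows)
    num_cols = [c for c in frame.columns if c not in ("flag", "j")]
    frame[num_cols] = frame[num_cols].astype(float).round(3)
    return frame.to_csv(sep="\t", index=False, na_rep="NA")


def report_json(rows: Sequence[TimepointReportRow], metadata: dict | None = None) -> str:
    """Machine-readable report: full precision plus run metadata."""
    doc = {
        "metadata": metadata or {},
        "rows": [asdict(r) for r in rows],
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def generate_fixture(spec: FixtureSpec) -> GrowthCurveDataset:
    """Deterministic synthetic dataset emulating a small xenograft study.

    Per-animal deviations around the arm's log-scale mean curve follow a
    stationary AR(1) with lag-one correlation ``spec.rho``, so adjacent
    measurements are strongly correlated like real growth curves.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.times, dtype=float)
    m = len(times)
    n = spec.n_per_group
    t0 = times[0]
    volumes = np.empty((2 * n, m))
    innov_sd = spec.noise_sd * math.sqrt(1.0 - spec.rho**2)
    for g in (0, 1):
        mean_curve = spec.log_baseline[g] + spec.growth_rates[g] * (times - t0)
        r = np.empty((n, m))
        r[:, 0] = rng.normal(0.0, spec.noise_sd, size=n)
        for j in range(1, m):
            r[:, j] = spec.rho * r[:, j - 1] + rng.normal(0.0, innov_sd, size=n)
        volumes[g * n : (g + 1) * n] = mean_curve + r
    if spec.scale == "raw":
        volumes = np.exp(volumes)
    animal_ids = [f"{'AB'[g]}{i + 1}" for g in (0, 1) for i in range(n)]
    return GrowthCurveDataset(
        animal_ids=tuple(animal_ids),
        group=np.repeat([0, 1], n),
        times=times,
        volumes=volumes,
        scale=spec.scale,
    )
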