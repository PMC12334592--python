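"""Core trajectory containers and tabular I/O.

Two observables drive everything downstream: counts of receptor-proximal
signaling assemblies ("complex I", CI) visualized as NEMO puncta, and the
nuclear fold change of the NF-kB subunit RelA.  Both are sampled on a uniform
time grid, by default 46 points at 4-minute spacing (0-180 min).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

DEFAULT_N_POINTS = 46
DEFAULT_DT_MIN = 4.0


def default_grid(n_points: int = DEFAULT_N_POINTS, dt: float = DEFAULT_DT_MIN) -> np.ndarray:
    """Uniform acquisition grid in minutes."""
    return np.arange(n_points, dtype=float) * dt


def _check_uniform_increasing(times: np.ndarray) -> None:
    d = np.diff(times)
    if len(times) < 2 or np.any(d <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.allclose(d, d[0], rtol=1e-8, atol=1e-10):
        raise ValueError("times must lie on a uniform grid")


@dataclass
class CITrajectory:
    """Time course of CI (NEMO-puncta) counts for one cell or condition average."""

    times: np.ndarray
    counts: np.ndarray
    cell_id: str = ""
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape:
            raise ValueError("times and counts must have equal length")
        _check_uniform_increasing(self.times)
        if np.any(self.counts < -1e-12):
            raise ValueError("CI counts must be nonnegative")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def copy(self) -> "CITrajectory":
        return CITrajectory(self.times.copy(), self.counts.copy(), self.cell_id,
                            self.condition, dict(self.meta))


@dataclass
class NFkBTrajectory:
    """Nuclear NF-kB fold change (nuclear intensity / intensity at t=0)."""

    times: np.ndarray
    fold_change: np.ndarray
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fold_change = np.asarray(self.fold_change, dtype=float)
        if self.times.shape != self.fold_change.shape:
            raise ValueError("times and fold_change must have equal length")
        _check_uniform_increasing(self.times)
        if np.any(self.fold_change < -1e-12):
            raise ValueError("fold change must be nonnegative")


# ---------------------------------------------------------------------------
# Long-format CSV dialect: cell_id, condition, time_min, ci_count, nfkb_fc
# ---------------------------------------------------------------------------

LONG_COLUMNS = ["cell_id", "condition", "time_min", "ci_count", "nfkb_fc"]


def cohort_to_frame(pairs: Iterable[tuple[CITrajectory, NFkBTrajectory]]) -> pd.DataFrame:
    rows = []
    for ci, nf in pairs:
        if ci.cell_id != nf.cell_id:
            raise ValueError(f"unpaired cell ids: {ci.cell_id!r} vs {nf.cell_id!r}")
        rows.append(pd.DataFrame({
            "cell_id": ci.cell_id,
            "condition": ci.condition,
            "time_min": ci.times,
            "ci_count": ci.counts,
            "nfkb_fc": nf.fold_change,
        }))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=LONG_COLUMNS)


def frame_to_cohort(df: pd.DataFrame) -> list[tuple[CITrajectory, NFkBTrajectory]]:
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for (cell, cond), g in df.groupby(["cell_id", "condition"], sort=False):
        g = g.sort_values("time_min")
        t = g["time_min"].to_numpy(float)
        out.append((
            CITrajectory(t, g["ci_count"].to_numpy(float), str(cell), str(cond)),
            NFkBTrajectory(t, g["nfkb_fc"].to_numpy(float), str(cell), str(cond)),
        ))
    return out


def read_cohort_csv(path) -> list[tuple[CITrajectory, NFkBTrajectory]]:
    return frame_to_cohort(pd.read_csv(path))


def write_cohort_csv(path, pairs: Iterable[tuple[CITrajectory, NFkBTrajectory]]) -> None:
    cohort_to_frame(pairs).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Excel reader for per-trajectory sheets (one row per trajectory).
#
# The sheet layout is configurable because published supplementary workbooks
# of this shape vary: rows carry a condition label, a cell label, and then
# either the 12 Gaussian-sum parameters (a1..a4, b1..b4, c1..c4) or sampled
# counts in time columns.
# ---------------------------------------------------------------------------

DEFAULT_XLSX_LAYOUT: dict[str, Any] = {
    "sheet": 0,
    "condition_column": "condition",
    "cell_column": "cell_id",
    # "gaussians": columns a1..a4,b1..b4,c1..c4 ; "samples": remaining columns
    # are counts at times parsed from the column headers (minutes).
    "value_kind": "samples",
    "gaussian_columns": [f"{p}{i}" for p in ("a", "b", "c") for i in range(1, 5)],
}


def read_ikk_trajectories_excel(path, layout: Mapping[str, Any] | None = None,
                                n_points: int = DEFAULT_N_POINTS,
                                dt: float = DEFAULT_DT_MIN):
    """Read per-trajectory CI data from an Excel workbook.

    Returns a list of ``CITrajectory`` (value_kind="samples") or a list of
    ``(condition, cell_id, a, b, c)`` Gaussian parameter tuples
    (value_kind="gaussians").
    """
    cfg = dict(DEFAULT_XLSX_LAYOUT)
    if layout:
        cfg.update(layout)
    df = pd.read_excel(path, sheet_name=cfg["sheet"])
    cond_col, cell_col = cfg["condition_column"], cfg["cell_column"]
    for col in (cond_col, cell_col):
        if col not in df.columns:
            raise ValueError(f"layout column {col!r} not in sheet columns {list(df.columns)}")
    if cfg["value_kind"] == "gaussians":
        cols = cfg["gaussian_columns"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"missing Gaussian parameter columns: {missing}")
        out = []
        for _, row in df.iterrows():
            vals = row[cols].to_numpy(float)
            a, b, c = vals[0:4], vals[4:8], vals[8:12]
            out.append((str(row[cond_col]), str(row[cell_col]), a, b, c))
        return out
    # sampled counts: time columns are everything else, headers parse as minutes
    tcols = [c for c in df.columns if c not in (cond_col, cell_col)]
    try:
        times = np.array([float(c) for c in tcols])
    except (TypeError, ValueError):
        times = default_grid(len(tcols), dt)
    order = np.argsort(times)
    times = times[order]
    tcols = [tcols[i] for i in order]
    return [
        CITrajectory(times, row[tcols].to_numpy(float), str(row[cell_col]), str(row[cond_col]))
        for _, row in df.iterrows()
    ]
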