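"""Feature-space scans over CI pulse geometry.

Sweeps triangular CI inputs over a (peak height x adaptation time) grid with
the peak fixed at 28 minutes, simulating each pulse through the model and
recording peak nuclear fold change, the export-order score, and a relative
chromatin-permissiveness summary; a companion (total nuclear NF-kB x
permissiveness) grid evaluates the equilibrium free fraction of the
DNA-binding sub-model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import (NonResponderError, export_order_score, fit_gaussian_sum)
from .model import (S_INDEX, SimulationError, free_nfkb_fraction,
                    run_to_steady_state, simulate_response)
from .params import ParameterSet
from .synthetic import DEFAULT_PEAK_TIME_MIN, make_triangular_ci
from .trajectories import NFkBTrajectory


@dataclass
class ScanResult:
    peak_grid: np.ndarray           # puncta
    t_adapt_grid: np.ndarray        # minutes
    peak_fold_change: np.ndarray    # |peak| x |t_adapt|
    export_order: np.ndarray        # SSE difference score (NaN where undefined)
    relative_permissiveness: np.ndarray   # in [0, 1]: (NPio - Ps0)/Ps summary
    free_fraction: np.ndarray | None = None    # sub-model grid
    nfkb_total_grid: np.ndarray | None = None
    npio_grid: np.ndarray | None = None
    params_id: str = ""
    meta: dict = field(default_factory=dict)


def scan_feature_space(p: ParameterSet,
                       peak_grid,
                       t_adapt_grid,
                       peak_time: float = DEFAULT_PEAK_TIME_MIN,
                       permissiveness_summary: str = "mean",
                       nfkb_total_grid=None,
                       npio_grid=None) -> ScanResult:
    """Scan CI pulse geometry and the DNA-binding sub-model.

    For each (peak height, adaptation time) cell a triangular CI pulse is
    built, Gaussian-fitted, and simulated; failures leave NaN cells.  The
    permissiveness summary is the time average of (NPio - Ps0)/Ps over the
    horizon ("mean") or the final value ("final").
    """
    peak_grid = np.asarray(peak_grid, dtype=float)
    t_adapt_grid = np.asarray(t_adapt_grid, dtype=float)
    if peak_grid.size == 0 or t_adapt_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if permissiveness_summary not in ("mean", "final"):
        raise ValueError("permissiveness_summary must be 'mean' or 'final'")

    ss = run_to_steady_state(p.variant, p)
    shape = (peak_grid.size, t_adapt_grid.size)
    pk_fc = np.full(shape, np.nan)
    export = np.full(shape, np.nan)
    perm = np.full(shape, np.nan)
    for i, peak in enumerate(peak_grid):
        for j, t_adapt in enumerate(t_adapt_grid):
            if peak <= 0:
                pk_fc[i, j] = 1.0
                perm[i, j] = 0.0
                continue   # export score undefined for the unstimulated row
            try:
                ci = make_triangular_ci(peak, t_adapt, peak_time=peak_time)
                sim = simulate_response(p.variant, p, fit_gaussian_sum(ci),
                                        steady_state=ss, times_min=ci.times)
            except (SimulationError, ValueError, RuntimeError):
                continue
            pk_fc[i, j] = float(sim.fold_change.max())
            rel = (sim.npio - p["Ps0"]) / p["Ps"] if p["Ps"] > 0 else np.zeros_like(sim.npio)
            perm[i, j] = float(rel.mean() if permissiveness_summary == "mean" else rel[-1])
            try:
                tr = NFkBTrajectory(sim.times_min, np.maximum(sim.fold_change, 0.0))
                export[i, j] = export_order_score(tr).score
            except (NonResponderError, ValueError):
                pass

    free = tot_grid = np_grid = None
    if nfkb_total_grid is not None and npio_grid is not None:
        tot_grid = np.asarray(nfkb_total_grid, dtype=float)
        np_grid = np.asarray(npio_grid, dtype=float)
        ikba_ss = float(ss.state[S_INDEX["N.IkBa"]])
        free = np.full((tot_grid.size, np_grid.size), np.nan)
        for i, tot in enumerate(tot_grid):
            for j, npio in enumerate(np_grid):
                free[i, j] = free_nfkb_fraction(tot, npio, p, ikba_ss)

    return ScanResult(peak_grid=peak_grid, t_adapt_grid=t_adapt_grid,
                      peak_fold_change=pk_fc, export_order=export,
                      relative_permissiveness=perm, free_fraction=free,
                      nfkb_total_grid=tot_grid, npio_grid=np_grid,
                      meta={"peak_time_min": peak_time,
                            "permissiveness_summary": permissiveness_summary})
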