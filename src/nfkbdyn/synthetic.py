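"""Synthetic study-condition generator.

Triangular CI pulse templates emulate the live-cell NEMO-puncta time courses:
counts rise linearly from zero to a controllable peak at 28 minutes, fall
linearly back to zero at a controllable adaptation time, and are smoothed by a
width-3 rolling mean so that downstream Gaussian-sum fitting is well behaved.
Paired NF-kB cohorts are simulated from a known ground-truth parameter set,
giving a fully self-contained benchmark for calibration and classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .trajectories import (CITrajectory, NFkBTrajectory, DEFAULT_N_POINTS,
                           DEFAULT_DT_MIN, default_grid, write_cohort_csv)

DEFAULT_PEAK_TIME_MIN = 28.0


class TriangleGeometryError(ValueError):
    """Raised when adaptation time does not exceed the peak time."""


def rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean; the window shrinks to the valid range at edges.

    Edge shrinking keeps the first sample an average over existing points only,
    so a trace that starts at zero stays anchored near zero.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return x.astype(float).copy()
    half = window // 2
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def make_triangular_ci(peak_height: float,
                       adaptation_time: float,
                       peak_time: float = DEFAULT_PEAK_TIME_MIN,
                       n_points: int = DEFAULT_N_POINTS,
                       dt: float = DEFAULT_DT_MIN,
                       smooth_window: int = 3,
                       cell_id: str = "",
                       condition: str = "") -> CITrajectory:
    """Build a triangular CI pulse on the acquisition grid.

    Counts interpolate linearly 0 -> peak_height over [0, peak_time], then
    peak_height -> 0 over [peak_time, adaptation_time], and stay 0 afterwards;
    a centered rolling mean of width ``smooth_window`` is applied last.
    """
    if peak_height <= 0:
        raise ValueError("peak_height must be positive")
    times = default_grid(n_points, dt)
    if not (0 < peak_time < adaptation_time):
        raise TriangleGeometryError(
            f"need 0 < peak_time ({peak_time}) < adaptation_time ({adaptation_time})")
    if adaptation_time > times[-1]:
        raise TriangleGeometryError(
            f"adaptation_time {adaptation_time} exceeds last grid time {times[-1]}")
    meta = {}
    peak_idx = int(round(peak_time / dt))
    snapped = peak_idx * dt
    if abs(snapped - peak_time) > 1e-9:
        meta["peak_time_snapped_from"] = float(peak_time)
        meta["peak_time_snapped_to"] = float(snapped)
    peak_time = snapped

    counts = np.interp(times, [0.0, peak_time, adaptation_time], [0.0, peak_height, 0.0])
    counts[times > adaptation_time] = 0.0
    counts = rolling_mean(counts, smooth_window)
    counts = np.maximum(counts, 0.0)
    meta.update(peak_height=float(peak_height), peak_time=float(peak_time),
                adaptation_time=float(adaptation_time), smooth_window=int(smooth_window))
    return CITrajectory(times, counts, cell_id=cell_id, condition=condition, meta=meta)


# ---------------------------------------------------------------------------
# Named pulse-condition templates.
#
# Heights/adaptation times mirror the qualitative structure of the stimulus
# panel: pulse trains ("4x1.5-like") conserve the CI dose (AUC) of the single
# 6-minute pulse while prolonging adaptation; longer single pulses scale the
# dose up.  Values are design choices of this generator, documented in
# docs/methods.md, not measurements.
# ---------------------------------------------------------------------------

_TEMPLATE_SPECS: dict[str, tuple[float, float]] = {
    # label: (peak_height [puncta], adaptation_time [min])
    "1x6-like": (60.0, 60.0),
    "2x3-like": (45.0, 84.0),
    "3x2-like": (38.0, 104.0),
    "4x1.5-like": (30.0, 120.0),
    "1x15-like": (75.0, 84.0),
    "1x30-like": (90.0, 100.0),
}


def make_pulse_condition_library(n_points: int = DEFAULT_N_POINTS,
                                 dt: float = DEFAULT_DT_MIN,
                                 smooth_window: int = 3) -> dict[str, CITrajectory]:
    """Named CI templates for the stimulus panel, plus an all-zero control."""
    lib = {
        name: make_triangular_ci(peak, adapt, n_points=n_points, dt=dt,
                                 smooth_window=smooth_window, condition=name)
        for name, (peak, adapt) in _TEMPLATE_SPECS.items()
    }
    times = default_grid(n_points, dt)
    lib["control"] = CITrajectory(times, np.zeros(n_points), condition="control",
                                  meta={"peak_height": 0.0})
    return lib


@dataclass
class SyntheticCohort:
    """Paired CI/NF-kB single-cell trajectories from a known ground truth."""

    ci_trajectories: list[CITrajectory]
    nfkb_trajectories: list[NFkBTrajectory]
    ground_truth: "object"           # ParameterSet
    noise_spec: dict = field(default_factory=dict)
    seed: int = 0
    dropped_cells: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids_ci = [c.cell_id for c in self.ci_trajectories]
        ids_nf = [n.cell_id for n in self.nfkb_trajectories]
        if ids_ci != ids_nf:
            raise ValueError("CI/NF-kB pairing must be 1:1 by cell_id")

    def pairs(self) -> list[tuple[CITrajectory, NFkBTrajectory]]:
        return list(zip(self.ci_trajectories, self.nfkb_trajectories))

    def by_condition(self) -> dict[str, list[tuple[CITrajectory, NFkBTrajectory]]]:
        out: dict[str, list] = {}
        for pair in self.pairs():
            out.setdefault(pair[0].condition, []).append(pair)
        return out

    def write(self, csv_path, sidecar_path=None) -> None:
        write_cohort_csv(csv_path, self.pairs())
        if sidecar_path is not None:
            payload = {
                "seed": self.seed,
                "noise_spec": self.noise_spec,
                "ground_truth": self.ground_truth.to_dict(),
                "dropped_cells": self.dropped_cells,
            }
            with open(sidecar_path, "w") as fh:
                json.dump(payload, fh, indent=2)


def _cell_rng(master_seed: int, counter: int) -> np.random.Generator:
    # One master seed; per-cell substreams by counter so partial cohorts are
    # reproducible irrespective of how many cells precede them.
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(counter,)))


def generate_cohort(ground_truth,
                    templates: list[CITrajectory],
                    n_cells_per_condition: int = 20,
                    ci_jitter: float = 0.15,
                    noise_sd: float = 0.05,
                    seed: int = 0,
                    extrinsic_fraction: float = 0.0,
                    extrinsic_sd: float = 0.6) -> SyntheticCohort:
    """Simulate a paired single-cell cohort from a ground-truth parameter set.

    Per cell the template's peak height and adaptation time receive
    multiplicative lognormal jitter (sd ``ci_jitter`` on the log scale is
    approximated by sigma of the underlying normal), the NF-kB response is
    simulated from the jittered CI pulse, and additive Gaussian measurement
    noise of sd ``noise_sd`` (floored at 0) is applied to the fold change.
    The master seed fully determines the cohort.

    ``extrinsic_fraction`` > 0 adds downstream cell-to-cell variability: in
    that fraction of cells the CI-to-IKK coupling ``ka`` is scaled by a
    lognormal factor (sd ``extrinsic_sd``), so their NF-kB response is *not*
    predictable from their CI input alone.  This emulates the minority of
    real cells whose responses deviate from receptor-level determinism and
    gives prediction benchmarks a genuine low-quality tail.  The basal steady
    state is unaffected (``ka`` only scales the stimulus coupling).
    """
    from .model import build_model, run_to_steady_state, simulate_response, SimulationError
    from .features import fit_gaussian_sum

    variant = getattr(ground_truth, "variant", "d2fc2")
    model = build_model(variant)
    ss = run_to_steady_state(model, ground_truth)

    cis: list[CITrajectory] = []
    nfs: list[NFkBTrajectory] = []
    dropped: list[str] = []
    counter = 0
    for tpl in templates:
        cond = tpl.condition or "condition"
        for j in range(n_cells_per_condition):
            rng = _cell_rng(seed, counter)
            counter += 1
            cell_id = f"{cond}_cell{j:03d}"
            meta = tpl.meta
            if meta.get("peak_height", 0.0) <= 0.0:       # control template
                ci = tpl.copy()
                ci.cell_id, ci.condition = cell_id, cond
            else:
                fac_p = float(np.exp(rng.normal(0.0, ci_jitter))) if ci_jitter > 0 else 1.0
                fac_a = float(np.exp(rng.normal(0.0, ci_jitter))) if ci_jitter > 0 else 1.0
                adapt = meta["adaptation_time"] * fac_a
                adapt = min(max(adapt, meta["peak_time"] + 2 * tpl.dt), tpl.times[-1])
                ci = make_triangular_ci(meta["peak_height"] * fac_p, adapt,
                                        peak_time=meta["peak_time"],
                                        n_points=len(tpl.times), dt=tpl.dt,
                                        smooth_window=meta.get("smooth_window", 3),
                                        cell_id=cell_id, condition=cond)
            cell_params = ground_truth
            if extrinsic_fraction > 0 and rng.random() < extrinsic_fraction:
                cell_params = ground_truth.with_updates(
                    ka=ground_truth["ka"] * float(np.exp(rng.normal(0.0, extrinsic_sd))))
            try:
                if ci.counts.max() > 0:
                    gfit = fit_gaussian_sum(ci)
                    sim = simulate_response(model, cell_params, gfit, steady_state=ss,
                                            times_min=ci.times)
                    fc = sim.fold_change.copy()
                else:
                    fc = np.ones_like(ci.times)
            except SimulationError:
                dropped.append(cell_id)
                continue
            if noise_sd > 0:
                fc = fc + rng.normal(0.0, noise_sd, size=fc.shape)
            fc = np.maximum(fc, 0.0)
            fc[0] = 1.0                  # fold change is defined relative to t=0
            cis.append(ci)
            nfs.append(NFkBTrajectory(ci.times, fc, cell_id=cell_id, condition=cond))

    return SyntheticCohort(cis, nfs, ground_truth,
                           noise_spec={"ci_jitter": ci_jitter, "noise_sd": noise_sd,
                                       "extrinsic_fraction": extrinsic_fraction,
                                       "extrinsic_sd": extrinsic_sd},
                           seed=seed, dropped_cells=dropped)
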