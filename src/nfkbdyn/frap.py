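"""FRAP recovery-curve processing.

Double normalization of bleach-spot and whole-compartment reference
intensities, two-component exponential recovery fitting

    F(t) = y0 + A1 (1 - exp(-t/tau1)) + A2 (1 - exp(-t/tau2)),

and estimation of the immobile fraction from the fit plateau.  The
unrecovered plateau fraction estimates the amount of the tagged factor
immobilized on DNA during the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

PLATEAU_TOL = 0.05


@dataclass
class FRAPCurve:
    """Double-normalized recovery curve; times are seconds from bleach."""

    times: np.ndarray
    intensities: np.ndarray
    n_prebleach: int = 10
    prebleach_mean: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")
        if self.times[0] != 0.0:
            raise ValueError("times must start at 0 (first post-bleach frame)")


def double_normalize(raw_roi, whole_ref, n_prebleach: int = 10,
                     dt: float = 0.25) -> FRAPCurve:
    """Double-normalized recovery: (ROI/ROI_pre) * (Ref_pre/Ref).

    The first ``n_prebleach`` samples of both series are pre-bleach frames;
    their means anchor the normalization, so acquisition photofading of the
    reference cancels and the pre-bleach level maps to 1.
    """
    roi = np.asarray(raw_roi, dtype=float)
    ref = np.asarray(whole_ref, dtype=float)
    if roi.shape != ref.shape:
        raise ValueError("ROI and reference series must have equal length")
    if len(roi) <= n_prebleach:
        raise ValueError("series shorter than the pre-bleach segment")
    roi_pre = roi[:n_prebleach].mean()
    ref_pre = ref[:n_prebleach].mean()
    if roi_pre <= 0 or ref_pre <= 0 or np.any(ref[n_prebleach:] <= 0):
        raise ValueError("non-positive reference intensities")
    post_roi = roi[n_prebleach:]
    post_ref = ref[n_prebleach:]
    f = (post_roi / roi_pre) * (ref_pre / post_ref)
    times = np.arange(len(f), dtype=float) * dt
    return FRAPCurve(times, f, n_prebleach=n_prebleach, prebleach_mean=float(roi_pre))


class FRAPFitError(RuntimeError):
    pass


@dataclass
class FRAPFit:
    y0: float          # immediate post-bleach offset (fraction of pre-bleach)
    A1: float
    tau1: float        # seconds; tau1 <= tau2 by canonical ordering
    A2: float
    tau2: float
    sse: float
    degenerate: bool = False    # tau1 ~ tau2: effectively single-component

    @property
    def plateau(self) -> float:
        return self.y0 + self.A1 + self.A2

    mobile_fraction = plateau

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.y0 + self.A1 * (1.0 - np.exp(-t / self.tau1))
                + self.A2 * (1.0 - np.exp(-t / self.tau2)))


def fit_recovery(curve: FRAPCurve, tau_grid=(0.3, 1.0, 3.0, 10.0, 30.0, 100.0),
                 ) -> FRAPFit:
    """Nonlinear least-squares two-component recovery fit.

    All five parameters are bounded nonnegative; a deterministic multi-start
    over (tau1, tau2) decade pairs guards against local minima.  The returned
    fit is canonicalized to tau1 <= tau2; a tau ratio under 1.5 is flagged as
    effectively single-component.
    """
    t, y = curve.times, curve.intensities
    if len(t) < 10:
        raise ValueError("need at least 10 post-bleach points")

    def resid(x):
        y0, a1, lt1, a2, lt2 = x
        return y0 + a1 * (1 - np.exp(-t / np.exp(lt1))) + a2 * (1 - np.exp(-t / np.exp(lt2))) - y

    y0_guess = max(float(y[0]), 0.0)
    amp = max(float(y[-1]) - y0_guess, 0.05)
    lb = [0.0, 0.0, np.log(1e-3), 0.0, np.log(1e-3)]
    ub = [1.5, 1.5, np.log(1e4), 1.5, np.log(1e4)]
    best = None
    for i, t1 in enumerate(tau_grid):
        for t2 in tau_grid[i + 1:]:
            x0 = [y0_guess, amp / 2, np.log(t1), amp / 2, np.log(t2)]
            try:
                sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                                    max_nfev=2000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise FRAPFitError("recovery fit failed from every start")
    y0, a1, lt1, a2, lt2 = best.x
    tau1, tau2 = float(np.exp(lt1)), float(np.exp(lt2))
    if tau1 > tau2:
        a1, a2, tau1, tau2 = a2, a1, tau2, tau1
    sse = float(2 * best.cost)
    degenerate = tau2 / max(tau1, 1e-12) < 1.5
    return FRAPFit(y0=float(y0), A1=float(a1), tau1=tau1, A2=float(a2),
                   tau2=tau2, sse=sse, degenerate=degenerate)


def immobile_fraction(fit: FRAPFit, prebleach_nuclear_intensity: float
                      ) -> tuple[float, float]:
    """(immobile fraction, total immobile amount).

    The fraction is 1 minus the fit plateau; the amount scales it by the
    nuclear intensity on the first pre-bleach frame.
    """
    plateau = fit.plateau
    if plateau > 1.0 + PLATEAU_TOL:
        raise ValueError(f"fit plateau {plateau:.3f} exceeds 1: normalization fault upstream")
    frac = max(1.0 - plateau, 0.0)
    return frac, frac * prebleach_nuclear_intensity


def read_frap_csv(path, n_prebleach: int = 10) -> FRAPCurve:
    """Per-cell CSV of (time_s, roi_intensity, reference_intensity)."""
    df = pd.read_csv(path)
    need = {"time_s", "roi_intensity", "reference_intensity"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    dt = float(np.diff(df["time_s"].to_numpy())[0]) if len(df) > 1 else 0.25
    return double_normalize(df["roi_intensity"].to_numpy(),
                            df["reference_intensity"].to_numpy(),
                            n_prebleach=n_prebleach, dt=dt)


def synthesize_frap_series(y0: float, A1: float, tau1: float, A2: float,
                           tau2: float, *, n_prebleach: int = 10,
                           duration_s: float = 60.0, dt: float = 0.25,
                           prebleach_level: float = 1000.0,
                           fading_rate: float = 0.0,
                           noise_sd: float = 0.0,
                           rng: np.random.Generator | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic raw (ROI, reference) series for a known recovery curve.

    Builds pre-bleach frames at ``prebleach_level``, a post-bleach recovery
    following the two-component model, optional exponential acquisition
    photofading applied to both channels, and optional Gaussian noise.
    The independent forward model used to exercise double normalization.
    """
    n_post = int(round(duration_s / dt)) + 1
    t_post = np.arange(n_post) * dt
    f = y0 + A1 * (1 - np.exp(-t_post / tau1)) + A2 * (1 - np.exp(-t_post / tau2))
    roi = np.concatenate([np.full(n_prebleach, prebleach_level), prebleach_level * f])
    ref = np.full(n_prebleach + n_post, prebleach_level)
    if fading_rate > 0:
        frames = np.arange(len(roi), dtype=float)
        fade = np.exp(-fading_rate * frames)
        roi = roi * fade
        ref = ref * fade
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        roi = roi + rng.normal(0, noise_sd * prebleach_level, roi.shape)
        ref = ref + rng.normal(0, noise_sd * prebleach_level, ref.shape)
    return roi, ref
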