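#!/usr/bin/env python
"""FRAP recovery fitting demonstration on synthetic bleach series.

Forward-simulates raw (bleach spot, whole nucleus) intensity series for two
stimulus groups that differ in their immobile fraction — emulating enhanced
DNA immobilization of nuclear RelA after a pulse train — then runs double
normalization, two-component recovery fitting, and immobile-fraction
estimation, and summarizes recovery per group.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nfkbdyn.frap import (double_normalize, fit_recovery, immobile_fraction,
                          synthesize_frap_series)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 99

#: Two synthetic stimulus groups; the pulse-train group immobilizes ~2x more.
GROUPS = {
    "single-pulse-like": dict(y0=0.25, A1=0.35, tau1=2.0, A2=0.25, tau2=15.0),
    "pulse-train-like": dict(y0=0.20, A1=0.30, tau1=2.0, A2=0.20, tau2=18.0),
}


def main() -> None:
    rng = np.random.default_rng(SEED)
    rows = []
    for group, true in GROUPS.items():
        for cell in range(20):
            roi, ref = synthesize_frap_series(**true, noise_sd=0.015,
                                              fading_rate=2e-4, rng=rng)
            curve = double_normalize(roi, ref)
            fit = fit_recovery(curve)
            frac, amount = immobile_fraction(fit, curve.prebleach_mean)
            rows.append(dict(group=group, cell=cell, y0=fit.y0, A1=fit.A1,
                             tau1=fit.tau1, A2=fit.A2, tau2=fit.tau2,
                             plateau=fit.plateau, immobile_fraction=frac,
                             immobile_total=amount))
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "frap_fits.csv", index=False, float_format="%.6g")
    summary = df.groupby("group")["immobile_fraction"].describe()[["25%", "50%", "75%"]]
    print(summary.round(3))
    for group, true in GROUPS.items():
        truth = 1.0 - (true["y0"] + true["A1"] + true["A2"])
        med = df[df.group == group]["immobile_fraction"].median()
        print(f"{group}: true immobile fraction {truth:.2f}, recovered median {med:.3f}")


if __name__ == "__main__":
    main()
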