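#!/usr/bin/env python
"""Calibrate both model architectures by PSO and compare them.

Fits the chromatin model (d2fc2) and the base model (d2fc) to the
condition-average trajectories of the four training conditions, then ranks
replicates by the three post-hoc criteria (emergent-property score, mean
training SSE, validation SSE).  The chromatin model reproduces the pulse-
train enhancement; the base architecture cannot, whatever its parameters.

Desk-scale sizes (3 replicates, swarm 40) keep this script to a few minutes;
pass --replicates/--swarm for larger samplings.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from nfkbdyn.calibrate import ObjectiveSpec, evaluate_criteria, run_calibration
from nfkbdyn.params import default_parameters
from nfkbdyn.pso import PSOConfig
from nfkbdyn.trajectories import CITrajectory, NFkBTrajectory, read_cohort_csv

RESULTS = Path(__file__).resolve().parents[1] / "results"
TRAIN = ["control", "1x6-like", "4x1.5-like", "1x30-like"]
VALIDATION = ["1x15-like", "2x3-like", "3x2-like"]


def condition_averages(pairs, conditions):
    by_cond = {}
    for ci, nf in pairs:
        by_cond.setdefault(ci.condition, []).append((ci, nf))
    out = {}
    for cond in conditions:
        cells = by_cond[cond]
        t = cells[0][0].times
        out[cond] = (CITrajectory(t, np.mean([c.counts for c, _ in cells], axis=0),
                                  condition=cond),
                     NFkBTrajectory(t, np.mean([n.fold_change for _, n in cells], axis=0),
                                    condition=cond))
    return out, by_cond


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--replicates", type=int, default=3)
    ap.add_argument("--swarm", type=int, default=40)
    ap.add_argument("--seed", type=int, default=2024)
    args = ap.parse_args()

    pairs = read_cohort_csv(RESULTS / "cohort.csv")
    train_avg, by_cond = condition_averages(pairs, TRAIN)
    val_avg, _ = condition_averages(pairs, VALIDATION)
    spec = ObjectiveSpec(train_avg)
    val = ObjectiveSpec(val_avg)
    cfg = PSOConfig(swarm_size=args.swarm, stall_iterations=15,
                    max_iterations=80, seed=args.seed)

    summary = {}
    for variant in ("d2fc2", "d2fc"):
        res = run_calibration(spec, default_parameters(variant), config=cfg,
                              n_replicates=args.replicates, seed=args.seed)
        rows = []
        for rep in res.ranked():
            ep, tr_sse, v_sse = evaluate_criteria(rep.params, spec, val, by_cond)
            rows.append(dict(J=rep.J, ep_score=ep, mean_train_sse=tr_sse,
                             validation_sse=v_sse))
        summary[variant] = rows
        best = res.best
        with open(RESULTS / f"calibration_{variant}.json", "w") as fh:
            json.dump({"result": res.to_dict(), "criteria": rows}, fh, indent=2)
        print(f"{variant}: best J={best.J:.4g}, best ep={min(r['ep_score'] for r in rows):.4g}")

    gap = (min(r["ep_score"] for r in summary["d2fc"])
           - min(r["ep_score"] for r in summary["d2fc2"]))
    print(f"\nemergent-property separation (base - chromatin, best replicates): {gap:.3f}"
          f" -> {'chromatin model wins' if gap > 0 else 'no separation'}")


if __name__ == "__main__":
    main()
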