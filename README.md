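# nfkbdyn

Modeling and analysis of IKK→NF-κB signal transduction under time-varying
cytokine stimuli.

Cytokine receptors cluster into supramolecular assemblies ("complex I", CI)
that activate the IKK kinase; IKK releases the transcription factor NF-κB
(RelA) from its IκB inhibitors, and nuclear NF-κB fold change is the
downstream observable.  Dose-conserving cytokine *pulse trains* prolong CI
lifetimes and disproportionately enhance nuclear NF-κB retention, switching
its nuclear export from first-order (exponential) to pseudo-zero-order
(linear) kinetics.  This package provides, for systems biologists working on
NF-κB dynamics:

* **ODE models** driven by CI (NEMO-puncta) count trajectories: a
  two-feedback core model (`d2fc`), a chromatin extension with cooperative
  NF-κB–DNA binding and pioneering-dependent permissiveness (`d2fc2`), and
  two alternative inhibitor architectures (`d2fc_ikbe`, `d2fc_ikbb`);
* **trajectory statistics**: response AUC, CI pulse features
  (t_max, t_adapt), Gaussian-sum CI fits used as analytic model forcing, a
  zero- vs first-order nuclear-export classifier with a rate floor of
  0.0167 min⁻¹, and elbow-based prediction-quality classes;
* **particle-swarm calibration** in log10 parameter space with a composite
  objective (trajectory SSE + basal nuclear/cytoplasmic localization
  heuristic) and three post-hoc criteria including the emergent-property
  score on median-AUC ratios;
* a **synthetic-data generator** (triangular CI pulses, paired simulated
  NF-κB cohorts with controlled noise) so every analysis runs without any
  external download;
* **FRAP recovery fitting**: double normalization, two-component
  exponential fits, immobile-fraction estimation.

The core DNA-binding rate law of the chromatin model is

    rate = ka1d · DCoop · NPio
    DCoop = (NFkB/kdNFKB)^h2 / (1 + (NFkB/kdNFKB)^h2)
    NPio  = Ps0 + Ps · (NFkBDNA/KDNA)^h3 / (1 + (NFkBDNA/KDNA)^h3)

whose positive feedback (bound NF-κB opens more chromatin, recruiting more
NF-κB) integrates CI *duration* rather than amplitude: only stimuli that
hold nuclear NF-κB up long enough engage the loop, sequester NF-κB on DNA,
and produce the linear export phenotype.  See `docs/methods.md` for the full
model statement, parameter meanings, and numerical choices.

## Worked example

```python
import numpy as np
from nfkbdyn import (default_parameters, make_triangular_ci, fit_gaussian_sum,
                     simulate_response, auc_fold_change, export_order_score,
                     NFkBTrajectory)

p = default_parameters("d2fc2")          # ground-truth chromatin model
for label, (peak, t_adapt) in {"single 6-min-like pulse": (60, 60),
                               "4x1.5-min-like train": (30, 120)}.items():
    ci = make_triangular_ci(peak_height=peak, adaptation_time=t_adapt)
    sim = simulate_response("d2fc2", p, fit_gaussian_sum(ci))
    tr = NFkBTrajectory(sim.times_min, np.maximum(sim.fold_change, 0))
    es = export_order_score(tr)
    print(f"{label}: CI AUC {np.trapezoid(ci.counts, ci.times):.0f}, "
          f"peak FC {sim.fold_change.max():.2f}, "
          f"NF-kB AUC {auc_fold_change(tr):.1f}, export {es.order_class} "
          f"(score {es.score:+.1f})")
```

prints

```
single 6-min-like pulse: CI AUC 1797, peak FC 3.43, NF-kB AUC 105.3, export first (score -1.1)
4x1.5-min-like train: CI AUC 1799, peak FC 3.00, NF-kB AUC 258.8, export zero (score +74.0)
```

— the pulse train delivers the same integrated CI dose (AUC ≈ 1800
puncta·min) yet ~2.5× the NF-κB response, and its export is classified
pseudo-zero-order (positive score: a line beats the rate-floored
exponential), while the single pulse decays first-order.

## Analysis pipeline

Numbered drivers under `analysis/` run the full study on synthetic data and
write their tables under `results/`:

| script | what it does |
|---|---|
| `01_simulate_cohort.py` | generates the paired CI/NF-κB cohort (`results/cohort.csv`) |
| `02_trajectory_features.py` | per-cell features; condition summary (dose conservation vs AUC enhancement) |
| `03_calibrate_models.py` | PSO calibration of `d2fc2` vs `d2fc`; three-criteria comparison |
| `04_single_cell_predictions.py` | per-cell predictions, elbow classes |
| `05_feature_space_scan.py` | (peak × adaptation) encoding-space heatmaps, sub-model free-fraction grid |
| `06_frap_immobile_fraction.py` | synthetic FRAP groups, recovery fits, immobile fractions |

A thin CLI wraps the same library calls
(`nfkbdyn simulate-cohort / features / fit / score / predict / scan /
frap-fit`); every command writes a manifest with seed and config hash.

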