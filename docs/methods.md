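# Methods

## The system and the question

Inflammatory cytokines such as IL-1 trigger receptor clustering into
supramolecular assemblies ("complex I", CI) that recruit and activate the IKK
kinase through its NEMO subunit.  CI assemblies are countable in live cells
as NEMO puncta; downstream, IKK drives degradation of the IκB inhibitors,
releasing NF-κB (RelA) into the nucleus, where its fold change over the
pre-stimulus level is the transcriptional observable.  Dose-conserving
cytokine *pulse trains* — e.g. four 1.5-minute pulses versus a single
6-minute pulse — prolong CI lifetimes without increasing the integrated CI
dose, yet disproportionately enhance and prolong nuclear NF-κB, switching its
nuclear export from first-order (exponential) to pseudo-zero-order (linear)
decline.  This package implements the computational side of that analysis:
ODE models of the IKK→NF-κB axis driven by CI counts, a chromatin
DNA-binding/pioneering extension that reproduces the pulse-train enhancement,
particle-swarm calibration, trajectory statistics, and FRAP recovery fitting.

## Model architectures

All variants share a two-feedback core ("d2fc"):

* **IKK module.**  Neutral IKK is activated at rate `ka · IKKSpots(t) · IKKn`,
  where `IKKSpots(t)` is the CI count trajectory supplied as an analytic
  sum of four Gaussians.  Active IKK inactivates at `ki·(1 + ka20·A20)·IKK`
  (A20-type feedback) and recycles slowly from the inactive pool.
* **IκBα module.**  IκBα binds free NF-κB in both compartments; active IKK
  degrades free and complexed IκBα, releasing NF-κB; free NF-κB shuttles into
  the nucleus, where newly imported IκBα re-captures it and exports the
  complex.  IκBα transcription is a Hill function of nuclear NF-κB
  (negative feedback); translation and mRNA turnover are first order.
* **Compartments.**  Concentrations live in nuclear and cytoplasmic
  compartments with volume ratio `cv = V_cyt/V_nuc` (default 3.5); transport
  fluxes carry the volume factors so that total NF-κB *amount* is exactly
  conserved — the model contains no NF-κB synthesis or degradation, which the
  test suite asserts to integrator tolerance.

The chromatin extension ("d2fc2") adds one nuclear species, DNA-bound NF-κB
(`NFkBDNA`), with association flux

    rate = ka1d · DCoop · NPio,
    DCoop = (NFkB/kdNFKB)^h2 / (1 + (NFkB/kdNFKB)^h2),
    NPio  = Ps0 + Ps · (NFkBDNA/KDNA)^h3 / (1 + (NFkBDNA/KDNA)^h3),

and two dissociation routes: IκBα stripping (`ka2a·[N.IkBa]·[NFkBDNA]`,
producing the nuclear IκBα:NF-κB complex) and basal release
(`kd1d·[NFkBDNA]`).  `DCoop` makes binding cooperative in free nuclear NF-κB;
`NPio` is the chromatin permissiveness, rising from the basal `Ps0 = 1`
(fixed) to `Ps0 + Ps` as bound NF-κB pioneers new sites.  Note the
association rate law carries **no** separate mass-action factor in free
NF-κB: `DCoop → 0` as NF-κB → 0 supplies the vanishing limit.  Numerically
the NF-κB argument of `DCoop` is clipped at zero so the flux shuts off
smoothly at the boundary; this is a safeguard, not a model change.  (The
two-species equilibrium sub-model below *does* carry the explicit
`[N.NFkB]` factor in its binding rate; the two rate laws are implemented
exactly as each is defined, and the inconsistency between them is inherited
from the model's original statement.)

Two alternative architectures extend the *base* model instead: a second
NF-κB-inducible inhibitor whose transcription is gated by a Hill function of
time with midpoint 45 min (2700 s, "d2fc_ikbe" — the delay clock runs only
during stimulation, evaluated in log space so step-like delay coefficients
cannot overflow), and a constitutively synthesized inhibitor independent of
NF-κB ("d2fc_ikbb").  Both bind cytoplasmic NF-κB with the IκBα reaction
structure and their own constants.

The core's rate equations are this package's reconstruction: the base model
is validated against behavioral contracts (basal nuclear-to-cytoplasmic
ratio, transient pulse response and adaptation, conservation), not against a
published coefficient table, and every constant is configuration.

## How the chromatin loop encodes CI duration

`kdNFKB` sits low relative to stimulated free nuclear NF-κB, so `DCoop`
saturates for any supra-threshold response and the DNA pool integrates
*time-above-threshold* rather than peak amplitude.  `ka1d` is slow: only
inputs that hold nuclear NF-κB up for longer than roughly an hour push
`NFkBDNA` past `KDNA`, engaging the `NPio` positive feedback.  Once engaged,
binding outcompetes IκBα-mediated export; the bound pool (which fluoresces as
nuclear RelA) is cleared by stripping at a roughly constant flux, producing
the linear, pseudo-zero-order export phenotype.  Short tall pulses end before
the loop engages and decay exponentially through IκBα feedback.  With the
default parameters this yields a 4×1.5-like/1×6-like median AUC ratio of
~2.4 at matched CI dose, first-order export for the single 6-minute pulse,
zero-order export for every condition whose CI adaptation time exceeds
~72 min, and a basal nuclear/cytoplasmic ratio R ≈ 0.115.

## Numerical treatment

Internal time is seconds (the delay Hill is defined in seconds); minutes at
every I/O boundary.  The right-hand side is compiled with numba and
integrated with LSODA (`scipy.integrate.odeint`), relative tolerance 1e-8 and
absolute 1e-10 by default; calibration loops relax to 1e-6/1e-9, below the
46-point objective's sensitivity.  Steady states come from a 10-day
unstimulated integration (doubling changes no species by more than 1e-6
relative).  The CI forcing is evaluated analytically from the Gaussian-sum
fit, so the integrator never sees interpolation kinks; amplitudes are
constrained nonnegative and the t=0 residual is up-weighted (default 50×) so
simulations start from the unstimulated state.  Negative concentrations
beyond −1e-6 raise an error rather than being clipped silently.

## Trajectory statistics

* **Response AUC**: trapezoidal integral of `max(FC − 1, 0)` over time.
* **CI features**: `t_max` is the time of the (first) count maximum;
  `t_adapt` is the first time after the peak at which counts fall to
  ≤ 10% of peak *and stay there*; the fraction is configurable because no
  numeric definition is canonical, and traces that never adapt are flagged
  right-censored.
* **Export-order score**: from the fold-change maximum (decay onset; global
  maximum, first on ties) to the trace end, two models are fitted — an
  unconstrained line `y = m·t + b` and an exponential `y = N0·e^(−k·t)` with
  `N0` pinned to the onset value and `k ≥ 0.0167 min⁻¹`.  The score is the
  SSE difference signed so that **positive = the line wins = pseudo-zero-
  order**.  The rate floor corresponds to ~95% nuclear exit within 180 min;
  slower exponentials are indistinguishable from lines on a 3-hour trace and
  are deliberately classified zero-order.  The optimizer upper bound is a
  generous 10 min⁻¹.
* **Fit-quality classes**: per-cell prediction SSEs are swept as candidate
  thresholds against the count of cells above threshold; both axes are
  min–max normalized (making the knee unit-free — an implementation choice,
  since axis scaling is not canonical) and the point furthest from the
  first-to-last chord is the elbow.  SSE ≤ elbow/2 is "excellent",
  ≤ elbow "high", else "low"; boundaries are inclusive.  Predictions with
  SSE < 1e-6 (numerically perfect on a 46-point grid) are excellent by
  definition — in the zero-SSE limit the knee would otherwise partition
  integrator round-off.

## Calibration

The objective sums squared fold-change residuals over all timepoints of the
training conditions (control, 1×6-like, 4×1.5-like, 1×30-like condition
averages) and adds a basal-localization heuristic: 0 inside
`0.01 < R < 0.3`, 100 at or below the lower edge, `5·R` at or above the
upper (boundaries take the penalized branch; crashed simulations return a
1e8 sentinel so the swarm keeps moving).  Optimization is global-best PSO
over log10-transformed parameters: inertia 0.729, cognitive = social =
1.49445, velocity clamped to half the box, positions clamped with velocity
zeroing, stopping after 20 stall iterations (relative improvement < 1e-6) or
an iteration cap.  Free parameters default to the chromatin/coupling
constants `(ka, ka1d, Ps, KDNA, ka2a, kd1d)` for d2fc2 and to feedback
constants `(ka, ki, kr, ktr, K_tr, kc)` for the base model; prior bounds are
±1 decade around the current values and ship as editable configuration
(the original study's prior table is not public).

Post-hoc, each replicate is scored on: (i) the emergent-property score — the
absolute discrepancy between experimental and simulated median-AUC ratios,
`|r(4×1.5/1×6)_exp − r_sim| + |r(1×15/1×6)_exp − r_sim|`, with simulated
medians over per-cell predictions of every single cell; (ii) mean
per-condition training SSE; (iii) total SSE on held-out validation
condition averages.

## The synthetic-data generator

Study conditions are emulated, not downloaded.  CI inputs are triangles on
the 46-point, 4-minute grid: zero to a controllable peak at 28 min (index 7;
off-grid peaks snap to the nearest index and record the snap), linearly back
to zero at a controllable adaptation time, then a centered width-3 rolling
mean whose window shrinks at the edges.  The template library fixes the
panel geometry — (peak, adaptation) = (60, 60) for 1×6-like, (30, 120) for
4×1.5-like (same CI AUC within 10%, adaptation longer by > 40 min),
(75, 84) for 1×15-like, (90, 100) for 1×30-like, intermediate trains between,
and an all-zero control — heights and adaptation times are design choices
mirroring the qualitative structure of the experimental panel (longer pulses
persist longer), not measurements.

Cohorts are generated from a ground-truth parameter set: per cell, template
peak and adaptation receive multiplicative lognormal jitter (sd 0.15 by
default), the NF-κB response is simulated, and additive Gaussian measurement
noise (sd 0.05, floored at zero, fold change re-pinned to 1 at t=0) is
applied.  One master seed with per-cell counter-derived substreams makes any
subset reproducible; regeneration is bit-identical.  An optional *extrinsic*
term scales the CI-coupling rate `ka` by a lognormal factor (sd 0.6) in a
configurable fraction of cells (default off; 20% in the prediction
benchmarks): with measurement noise alone every prediction SSE sits at a
homogeneous noise floor and the elbow knee lands inside the bulk, whereas
real cohorts contain a minority of cells whose responses are not explained
by their receptor input.  The extrinsic subpopulation reproduces that
low-quality tail without touching the basal steady state.

What the generator does *not* emulate: discrete pulse-by-pulse CI structure
(trains are represented by their prolonged-adaptation envelope), receptor-
level stochasticity in puncta counts, photobleaching or tracking artifacts,
cell division and movement, and any transcriptional readout downstream of
NF-κB.  Passing tests therefore demonstrate correctness of the machinery and
internal consistency of the model family on data of known provenance — not
biological validity on real images.

## Chromatin sub-model

To isolate the permissiveness effect, a two-species equilibrium keeps only
free and DNA-bound nuclear NF-κB dynamic, holding nuclear IκBα at its
pre-stimulus steady-state value and `NPio` at a constant scanned value:
binding `ka1d·DCoop(free)·NPio_const·[free]` balances
`(kd1d + ka2a·IkBa_ss)·[bound]`.  The equilibrium is found by bracketed root
finding on the monotone net flux; an independent long-time integration of
the same two-ODE system agrees to better than 1e-4 relative, and the free
fraction is strictly decreasing in permissiveness.

## FRAP

Recovery curves are double-normalized — `(ROI/ROI_pre)·(Ref_pre/Ref)` with
pre-bleach means (10 frames) as anchors, so acquisition photofading cancels —
and fitted to `F(t) = y0 + A1(1−e^(−t/τ1)) + A2(1−e^(−t/τ2))` by bounded
nonlinear least squares with a deterministic multi-start over τ decade pairs
(0.3–100 s), canonicalized to τ1 ≤ τ2; near-equal time constants are flagged
as effectively single-component.  All parameters are constrained nonnegative
(the original constraint convention is unstated; nonnegativity is the
physical choice).  The immobile fraction is `1 − (y0 + A1 + A2)`, and the
total immobile amount multiplies it by the nuclear intensity of the first
pre-bleach frame.  Amplitudes are identifiable to ~1% on noiseless curves
when τ2/τ1 ≳ 3 and to ~10% median error at noise sd 0.02.

## Problem sizes

The test suite and the acceptance script run desk-scale analogues of the
full study: PSO with 3 replicates of swarm 40 (recovery) or swarm 30 (model
comparison) instead of 500 replicates of swarm 100; cohorts of 8–15 cells
per condition instead of ~20; and a 100-decay classifier benchmark.  These
sizes are the package's defaults for its own verification runs — every
routine accepts larger values, and `analysis/03_calibrate_models.py` exposes
them as flags.

## Known limitations

* The base-model reconstruction is behavioral, not coefficient-identical to
  any published table; absolute rate constants are calibration targets, not
  measurements.
* The export-order score applied to trajectories that plateau at baseline
  (fold change ≈ 1) favors the line for purely geometric reasons; the rate
  floor mitigates but does not remove this, and borderline single-pulse
  trajectories score near zero.
* Sum-of-four-Gaussians forcing is non-identifiable; only the fitted curve,
  never its parameters, is meaningful.
* The elbow classification requires genuine heterogeneity in fit quality;
  on homogeneous cohorts the knee is arbitrary (hence the perfect-SSE guard
  and the extrinsic-noise option).
* SBML export is not provided; the reaction network serializes to JSON.
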