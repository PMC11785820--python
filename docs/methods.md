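# Methods

## Cargo model and the φ statistic

The simulator (`trajsim`) represents a cargo pulled by *n* identical,
independently stepping motors on a microtubule. Each motor is a Poisson
stepper: in a time bin Δt it takes Poisson(λΔt) steps with sizes drawn
i.i.d. from a finite mixture on the ±{4, 8, 16, 24} nm lattice (binding
sites are 8 nm apart; with two heads and midpoint coupling the observable
half-lattice is 4 nm, which is also why the minimum cargo step is 4 nm).
Coupling is rigid averaging: the cargo sits at the arithmetic mean of the
motor positions, so one d-nm motor step displaces the cargo by d/n. The
half-step argument fixes this rule at n = 2; we extend the same averaging
to all n and do not model elastic linkages.

Compound-Poisson moments of cargo displacements over a delay τ:

    μ(τ)  = λ τ d                      (independent of n)
    s²(τ) = λ τ (d² + v) / n + 2σ²     (σ: localization noise SD)

so φ(τ) = 2μ/s² relaxes toward n·2d/(d²+v). These closed forms are the
oracles for the simulator tests and for the φ-pipeline recovery tests.

**Calibration.** The single-motor mixture defaults to mean d = 8 nm and
variance v = 96 nm², giving the quantum φ₁ = 2d/(d²+v) = 0.1 nm⁻¹. Only d
(the 8-nm step mode) and φ₁ (the observed unit) are measured quantities;
v is derived from them, and the in vivo multi-motor stepping rate is not
separately measurable, so λ defaults to 150 s⁻¹ (8 nm × 150 s⁻¹ =
1.2 μm s⁻¹, a typical retrograde speed). Mixture probabilities are solved
from the three moment constraints by non-negative least squares;
(d, v) pairs outside the lattice's moment body are rejected.

Motion-state switching (diffusive / retrograde at 2.81 μm s⁻¹ /
anterograde at 5.06 μm s⁻¹) is a continuous-time Markov chain sampled at
Δt, with default mean state durations of 2 s ("stop-and-go"). Localization
noise is i.i.d. Gaussian per frame and axis — the shot-noise-limited,
background-free regime; no drift, vignetting or read noise. Every
generator consumes one seeded `numpy` Generator and stores the seed plus
full ground truth (true positions, state path, step times/sizes) in the
trajectory metadata.

**What the generator does not emulate:** vesicle-size variation and
drag-dependent load, elastic motor-cargo linkages, microtubule geometry
(curvature, obstacles, lattice defects), tug-of-war force balance, and
heterogeneity between cargos. Passing tests therefore demonstrate that the
estimators recover the parameters of this idealized process, not that
real-data complications are handled.

## Localization layer

`locfit` renders diffraction-limited spots as Poisson realizations of a
pixel-integrated Gaussian (SD = (λ_em/2NA)/2.355; defaults λ_em = 605 nm,
NA = 1.49, 160-nm pixels) and localizes them by unweighted least-squares
Gaussian fits. The textbook shot-noise estimate δx ~ (λ/2NA)/√n uses the
FWHM-scale width; the actual precision of a Gaussian fit is governed by
√(s² + a²/12)/√n (s: spot SD, a: pixel size), about half that. Since the
emission wavelength behind any particular printed precision is an
instrument detail, the package treats only the photon-count *scaling* as
physical: tests assert the √5 ratio between 1,000- and 5,000-photon
precisions and the n^(−1/2) power law, plus absolute agreement with the
pixel-integrated bound within the least-squares efficiency factor.
Linking is greedy nearest-neighbor with a distance gate, matching closest
pairs first (order-independent); it replaces multi-hypothesis
multiple-target tracing and is adequate for the one-spot-per-region
fixtures used here.

## Motion-state annotation

`segment` fits Gaussian hidden Markov models to the per-frame
displacements projected on the track's principal axis: K = 1..3 states,
EM with quantile-seeded means and multiple restarts, K selected by
minimum BIC, labels from the Viterbi path. This is a deliberate
simplification of variational-Bayes model evidence; BIC is its
large-sample limit and behaves identically on the long trajectories this
analysis requires. Localization noise is folded into each state's
emission variance rather than treated by a Kalman filter. A state is
"diffusive" when |mean displacement| < 0.5 of its emission SD; directed
states are signed by their velocity. Viterbi ties break toward the lower
state index.

Two caveats are deliberate: (1) the projection cannot know which
direction is retrograde, so DV+/DV− are defined up to the segment-level
sign convention (each extracted segment is re-signed
retrograde-positive); (2) stepping noise is non-Gaussian, and BIC may
split one transport direction into two emission components — segment
extraction therefore groups runs by directed *label*, and a velocity
coefficient-of-variation gate (block velocities over 0.5 s, CV ≤ 0.3 by
default) rejects runs whose speed actually varies. The CV gate is our
declared convention for "roughly constant velocity"; nothing in the
source fixes a specific rule.

## φ analysis

`motorcount` computes μ and s² per delay from all overlapping pairs
(maximizing data at the cost of serial correlation; a block bootstrap
over 0.5-s blocks is provided for asymptote SEs). The default τ grid is
10-ms steps from 10 to 200 ms; the asymptote is the tail mean over
τ ≥ 120 ms, declared converged only when the fitted linear trend moves φ
by < 10% across the tail. When σ is known (always, for synthetic data)
the static 2σ² offset is subtracted from s²; at the defaults the tail
bias from skipping this is < 2%, so curves from unknown-σ data are still
usable. Cluster count for pooled asymptotes uses an elbow rule — the
largest k still preceded by a relative within-cluster-sum-of-squares
drop ≥ 0.5; splitting a true Gaussian cluster only drops WCSS by
(1−2/π)/k, safely below the gate for k ≥ 2 — and centers are regressed
onto integer multiples of a fitted quantum φ₁, which turns cluster
membership into a motor count automatically. The fraction of real
segments whose φ converges is a property of cargo heterogeneity that the
idealized generator does not reproduce; the converged/non-converged
classifier itself is tested on constructed flat and drifting curves.

## Step finding and dwell kinetics

`stepkin.find_steps` is an iterative chi-square staircase fitter: the
step whose placement maximally reduces the residual sum of squares is
added greedily (a heap of per-plateau best splits makes this O(N log N)),
steps are accepted while the reduction exceeds the change-point
significance threshold 2σ̂²ln N (σ̂: robust noise SD from first
differences — the factor 2 is Yao's BIC-type constant), boundaries are
refined by coordinate descent, and adjacent plateaus closer than the 4-nm
experimental noise floor are merged. We evaluated the counter-fit
quality-ratio peak (steps forced to plateau midpoints) as the stopping
rule; on staircases with Erlang-2 dwells the ratio curve is a broad noisy
plateau whose argmax systematically undercounts steps, so the ratio is
reported as the fit-quality score but not used to stop. At the 22 °C-like
operating point (mean dwell 144 ms, 2.5-ms frames, 2-nm noise) the
fitter recovers ≥ 95% of true steps within one frame with step-size
RMSE < 2 nm.

Dwell times are inter-step intervals; dwells under 2 frames are censored
(a step must rest on two samples), which biases k̂ = 2/mean *downward* by
well under 3% when the frame interval is ≤ 5% of the mean dwell — the
bias is a pure lengthening of the surviving mean. MLE is on raw, unbinned
dwells: closed forms for the exponential (k̂ = 1/mean, SE k̂/√n) and
Erlang-2 (k̂ = 2/mean, SE k̂/√(2n), the Fisher bound), numerical MLE for
the two-parameter gamma (SEs from the analytic Fisher matrix) and for the
unconstrained two-rate hypoexponential (parametrized k₂ = k₁ + δ, δ ≥ 0,
with a series-stabilized density so the equal-rate limit is exact).
Binned-histogram fitting exists only as a comparison mode — bin choice
can suppress the fast-rising part of the distribution. Model comparison
is by AIC; a gamma shape near 2 and a two-rate fit with k₁ ≈ k₂
independently support two equal sequential rate-limiting transitions.

The randomness parameter uses the plain moment estimator
r = (⟨τ²⟩−⟨τ⟩²)/⟨τ⟩² with a 1,000-resample bootstrap CI; n_min = 1/r
(exactly m for Erlang-m). The Arrhenius fit regresses ln k on 1/T
(T = °C + 273.15) by unweighted least squares, with R = 1.987×10⁻³
kcal mol⁻¹ K⁻¹ so activation energies come out in kcal/mol; an
SE-weighted mode (weights 1/SE(ln k)) is provided. On the measured rate
triple (13.9, 56.1, 97.1 s⁻¹ at 22/30/37 °C) the unweighted fit gives
Ea ≈ 23.9 kcal/mol and the weighted fit ≈ 22 kcal/mol; with three points
the uncertainty is large, and neither mode is privileged.

## Chemomechanical cycles

`cyclesim` models one stepping cycle as an ordered chain of irreversible
transitions (Apo → ATP → ADP·Pi → ADP → Apo per catalytic site; the
two-ATP scheme runs the AAA1 block strictly before the AAA3 block). The
ATP binding rate is k_MT·[ATP] with k_MT = 0.29 μM⁻¹ s⁻¹ (870 s⁻¹ at the
3 mM axonal ATP), Pi release defaults to the 37 °C stepping rate
97.1 s⁻¹, and hydrolysis/ADP release default to 5,000 s⁻¹ (sub-ms); an
`instantaneous_fast` flag removes them, reducing the chain to its
rate-limiting transitions so the Erlang predictions are exact. Note the
unit choice: k_MT is adopted in μM⁻¹ s⁻¹ because only that unit is
consistent with 0.29 × 3 mM = 870 s⁻¹. For a linear chain the dwell is a
sum of independent exponentials, so mean = Σ1/kᵢ and variance = Σ1/kᵢ²
are exact, sampling is a direct sum of exponential draws (equivalent to
Gillespie for a linear chain), and dwell statistics are invariant to
transition order. Velocity is step/mean-dwell; with fast steps
instantaneous the two-ATP velocity is exactly Michaelis–Menten with
Vmax = d·k_Pi/2 = 388.4 nm s⁻¹ and K = k_Pi/k_MT ≈ 334.8 μM, and the
Hill fit (least squares, initialized Vmax = max v, K = S at half-max,
n = 1) returns n = 1.000. The discriminating observable is n_min(S):
2 → 4 → 2 for two-ATP (maximum exactly where k_MT·S = k_Pi), approaching
1 at high S for one-ATP. With fast rates at 5,000 s⁻¹ instead of
instantaneous, n_min at 3 mM moves from 2.44 to 2.61 — the sensitivity to
the unprinted fast rates is reported by computing both, not assumed away.
ADP-gating of microtubule affinity and force generation are out of scope.

## Pipeline and reproducibility

`pipeline` defines the text file contracts (tab-separated trajectories
with `#` metadata lines; per-stage TSV tables; JSON structured reports)
and an end-to-end runner driven by a YAML-serializable config. Every
stochastic stage derives its seed from the config seed via
`SeedSequence.spawn`, and the report records a hash of the scientific
parameters (the output path is excluded), so a rerun of the same config
is bit-identical. Problem sizes in the packaged demo and tests — 60-s
segments at 10-ms frames, cohorts of 6–8 segments per motor number,
stepping traces of 150–920 steps, 10⁵-draw dwell samples, 1,000-replicate
estimator-spread studies — are chosen so each statistical assertion has
3-σ headroom under its Monte-Carlo error while the whole suite runs in
about a minute.

## Known limitations

- The HMM annotation assumes Gaussian emissions; heavy-tailed stepping
  noise can inflate the selected state count (handled downstream by
  label-grouping plus the CV gate, but the BIC count itself is then not a
  physical state count).
- Motor counting assumes equal load sharing and identical motors; mixed
  dynein/kinesin activity or elastic linkages would blur the φ quanta in
  ways the generator does not produce.
- The step finder's significance threshold assumes roughly stationary
  noise; strongly position-dependent noise would need a local σ̂.
- Censored-dwell correction is exclusion-only by default; the
  truncated-likelihood alternative exists behind the comparison API but
  is not the headline estimator.
- Cycle models are dwell-statistics only: no spatial force generation,
  no load dependence, no Pi-per-step bookkeeping.
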