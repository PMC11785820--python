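# dyntrack

Analysis pipeline for nanometer-resolution single-particle tracking of
dynein-driven cargo transport in neurons: how many motors are pulling a
vesicle, and what kinetics govern each molecular step.

Cytoplasmic dynein carries endosomes retrogradely (toward the soma) along
axonal microtubules. Long, high-rate tracking of single cargos makes two
quantitative analyses possible, and this package implements both, together
with the synthetic-data generators needed to exercise them:

1. **Motor counting from displacement fluctuations.** For a segment of
   roughly constant velocity, the displacements Δx(t, τ) = x(t+τ) − x(t)
   are near-Gaussian with mean μ(τ) and variance s²(τ). For *n* motors
   stepping independently at rate λ with per-step displacement mean d and
   variance v (cargo at the mean of the motor positions, so each motor step
   moves it by step/n),

   φ(τ) ≡ 2μ/s² = 2λτd / (λτ(d²+v)/n + 2σ²) → n · 2d/(d²+v)  as τ → ∞.

   The asymptote is an integer multiple of a single-motor quantum φ₁
   (0.1 nm⁻¹ at the calibration d = 8 nm, v = 96 nm²): pooled asymptotes
   cluster at quantized values, and k-means plus a fitted quantum converts
   each segment into a motor count. Velocity, by contrast, is λd
   independent of n — quantized φ with unquantized velocity is the
   signature of the motor number.

2. **Stepping kinetics.** Stepping traces are staircases blurred by
   localization noise. A chi-square staircase fitter extracts steps and
   dwell times; the dwell distribution follows the convolution of two
   equal-rate exponentials, P(τ) = k²τe^(−kτ) (Erlang-2, mean 2/k), fit by
   maximum likelihood on the raw dwells (k̂ = 2/mean, SE k̂/√(2n)). The
   randomness parameter r = (⟨τ²⟩−⟨τ⟩²)/⟨τ⟩² bounds the number of
   rate-limiting transitions per cycle via n_min = 1/r, and an Arrhenius
   fit of ln k against 1/T gives the activation energy. A
   chemomechanical-cycle module compares the classical one-ATP
   ("active-cycling") scheme against the two-ATP sequential scheme
   (hydrolysis at AAA1 then AAA3): both give Michaelis–Menten velocity
   with Hill coefficient 1, but n_min(ATP) discriminates them — the
   two-ATP chain stays at 2 at both ATP extremes and peaks at 4 where the
   ATP on-rate equals the Pi desorption rate, while one-ATP decays to 1 at
   saturating ATP.

Module map: `trajsim` (multi-motor cargo simulator, stepping traces, dwell
generators) · `locfit` (PSF rendering, 2-D Gaussian localization,
nearest-neighbor linking) · `segment` (HMM motion-state annotation,
constant-velocity segment extraction) · `motorcount` (φ statistics,
asymptotes, quantized clustering) · `stepkin` (step finding, dwell MLE,
randomness, Arrhenius) · `cyclesim` (cycle models, MM/Hill, n_min vs ATP)
· `pipeline`/`cli` (file I/O, configs, end-to-end runs).

## Worked example

```sh
dyntrack demo --out demo_run --seed 0
```

runs the packaged demo — a cohort of 1-, 2- and 3-motor cargo segments at
37 °C plus stepping traces at 22/30/37 °C — and prints (abridged):

```
motor counting:
  cluster centers [1/nm]: [0.100213, 0.203722, 0.29455]
  quantum phi_1 [1/nm]: 0.099379
  mean motors n: 2.0 +/- 0.1703 (SE)
dwell fit at 22.0 C: k = 14.0246 +/- 0.5905 1/s (n = 282 dwells), mean dwell 142.6064 ms, n_min = 2.2568
dwell fit at 30.0 C: k = 54.8736 +/- 2.3791 1/s (n = 266 dwells), mean dwell 36.4474 ms, n_min = 2.2537
dwell fit at 37.0 C: k = 98.744 +/- 2.3171 1/s (n = 908 dwells), mean dwell 20.2544 ms, n_min = 2.0297
Arrhenius: Ea = 23.887 +/- 4.1787 kcal/mol
cycle two_ATP: binding rate 870.0 1/s, Vmax 388.4 nm/s, K 334.8276 uM, Hill n = 1.0, n_min(high ATP) = 2.1338, n_min(max) = 3.9967
cycle one_ATP: binding rate 870.0 1/s, Vmax 776.8 nm/s, K 334.8276 uM, Hill n = 1.0, n_min(high ATP) = 1.0669, n_min(max) = 1.9984
```

Reading it: the φ asymptotes cluster at 0.10/0.20/0.29 nm⁻¹ — one, two and
three engaged motors on the quantum φ₁ ≈ 0.1 nm⁻¹ — and the dwell fits
recover the generating rates (13.9, 56.1, 97.1 s⁻¹) within their standard
errors, with n_min ≈ 2 at every temperature (two rate-limiting
transitions per step). The three rates lie on a single Arrhenius line
(Ea ≈ 24 kcal/mol, thermally activated Pi desorption), and the cycle
block shows the discriminating prediction: both schemes are
Michaelis–Menten with Hill n = 1, but only the two-ATP scheme keeps
n_min = 2 at high ATP and peaks at 4 at intermediate ATP.

The same stages are available as library calls (`dyntrack.run_pipeline`,
or the individual functions re-exported from `dyntrack`) and as the
subcommands `simulate`, `segment`, `phi`, `count-motors`, `find-steps`,
`fit-dwells`, `arrhenius`, `cycle`, `report`.

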