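# Methods

## Model and assumptions

The model is a two-compartment mammillary system — plasma (volume $V_p$) and
brain ($V_b$), both assumed homogeneous — with first-order exchange across
the blood–brain barrier and Michaelis–Menten elimination confined to plasma:

    dC1/dt = -Vmax*C1/(KM + C1) - Kpb*C1 + Kbp*C2
    dC2/dt = (Vp/Vb) * (Kpb*C1 - Kbp*C2)

Assumptions worth keeping in mind:

- **Instantaneous i.v. bolus**: C1(0) = dose/(MW·V_p) with cocaine free-base
  MW 303.35 g/mol, C2(0) = 0. No absorption routes, no protein binding, no
  DAT-binding submodel, no additional compartments.
- **Single elimination route**: butyrylcholinesterase-type hydrolysis in
  plasma. When an exogenous hydrolase is present its activity dwarfs the
  endogenous enzyme (>1000-fold higher catalytic efficiency), so a scenario
  always uses exactly one `EnzymeKinetics`; endogenous wtBChE is neglected in
  exogenous-enzyme scenarios.
- **Constant enzyme concentration** [E]: the therapeutic scenario of interest
  is gene-transfer-sustained expression, so Vmax = k_cat·[E] does not decay.
- The exchange terms conserve amount exactly: V_p·C1 + V_b·C2 is constant
  when Vmax = 0, and `mass_balance_residual` verifies the full budget
  (amount present + amount eliminated) along any trajectory.

Structural identifiability: the four unknowns (V_b, V_p, K_pb, K_bp) are
uniquely determined by noise-free observations of both compartments *given
the dose*, because V_p is pinned by C1(0) = D/(MW·V_p) and the volumes
otherwise enter only through V_p/V_b. This package probes the property
numerically (multi-start recovery on noise-free data) rather than
symbolically; see below for what breaks when observations are partial or
noisy.

## Parameters

| symbol | meaning | units | reference value |
|---|---|---|---|
| V_p | effective plasma volume | L | 11.89 |
| V_b | effective brain volume | L | 0.3292 |
| K_pb | plasma→brain diffusion | min⁻¹ | 0.01898 |
| K_bp | brain→plasma diffusion | min⁻¹ | 0.01780 |
| k_cat, K_M | enzyme catalytic constants | min⁻¹, µM | per panel entry |
| [E] | enzyme active-site concentration | µM | 0.035 (physiological), 0.5 (gene transfer) |

V_p is an *effective* volume (≈4× anatomical plasma volume) because cocaine
distributes beyond plasma and brain; V_b is flagged implausible outside the
striatum-to-whole-brain window [0.00633, 1.2538] L, which is also the default
fitting bound. All four parameters must be strictly positive.

The enzyme panel: wtBChE (k_cat 4.1 min⁻¹, K_M 4.5 µM), CocE (468, 0.64),
CocH1 (3060, 3.1), CocH2 (1730, 1.1), CocH3 (5700, 3.1). [E] always means
the molar concentration of *active sites* (a BChE tetramer has two).

## Numerical choices

- **Integrator**: LSODA with an analytic Jacobian, rtol 1e-9 / atol 1e-12 by
  default, dense output retained for metric refinement. High-activity
  scenarios are mildly stiff (plasma collapses within a minute while the
  brain tail stretches for hours); LSODA's automatic stiffness switching
  handles both phases. Undershoot below zero is clipped, with a warning if it
  exceeds 1000·atol. A fixed-step RK4 oracle at dt = 0.001 min cross-checks
  the adaptive solution to within 0.5% in the tests.
- **Output grid**: geometric spacing from 1e-3 min (default 2001–4001 points)
  so sub-minute transients and multi-hour tails are resolved together;
  uniform spacing is available via `dt`.
- **AUC**: plain trapezoidal rule on the stored grid. `auc_infinity`
  quadruples the horizon until the estimated exponential tail
  C(T)/λ_z (λ_z from a log-linear fit to the last decade of samples)
  contributes < 1e-4 of the accumulated integral, then adds that tail
  correction. This makes AUC∞ grid- and horizon-independent to 4 significant
  figures. A non-decaying trajectory (Vmax = 0) raises an error.
- **Peak**: grid argmax refined on the dense solution by bounded scalar
  minimization (~1e-4 min), or by quadratic interpolation of the three
  bracketing samples when no dense output is attached. Ties break earliest.
- **Half-life**: first post-peak crossing of half the peak value, located by
  Brent root-finding on the dense solution. Two conventions are implemented:
  `absolute` (time from injection) and `from_peak` (time from the peak).
  The historical lookup values are numerically consistent only with
  `from_peak` (e.g. the baseline 1 µM scenario gives 32.1 min absolute vs
  27.0 min from peak, matching the tabulated 27.006), so `from_peak` is the
  default and the reproduction suite asserts the selection.
- **Threshold search** (`max_preventable_c0`): integer-µM scan (1 µM steps to
  20 µM, 5 µM above) brackets the exceedance, Brent refines the boundary to
  ±0.1 µM, and the result reports both the refined boundary and the largest
  not-exceeding integer. Rounding *down* was chosen because the refined
  boundaries floor to the historical integer table almost everywhere;
  the CocH3/0.5 µM cell is a genuine knife edge (brain peak at C1(0) = 40 µM
  exceeds the 0.22 µM threshold by < 0.03%), so this search reports 39 where
  older analyses, working at two-decimal print precision, reported ~40.
- **Thresholds**: the no-effect (0.16 µM) and minimal-effect (0.32 µM)
  calibration doses are simulated with endogenous wtBChE only, and the
  peak/AUC thresholds are the midpoints of the resulting brackets, recomputed
  at runtime (never hard-coded constants).

## Calibration

`fit` minimizes the unweighted joint sum of squared residuals over both
compartments (all points equal weight), in log-parameter space with the
trust-region-reflective solver inside positivity bounds, from `n_starts`
log-uniform random starts (default 25). Relative-units datasets are handled
by normalizing the model output by its own C1(0) before residuals. The
fitted AUC2∞/AUC1∞ ratio is checked against the microdialysis-derived
plausibility window [1.02, 1.38] and flagged (not rejected) outside it.
Seeded runs are bit-reproducible.

What is recoverable depends on the data:

- absolute units + known dose: all four parameters (noise-free recovery is
  within 1% from random starts; the identifiability probe finds a single
  positive-orthant minimum at the truth);
- relative units, or absolute units with only C1(0) known: K_pb, K_bp and
  the ratio V_p/V_b — the volumes separately are unidentifiable;
- plasma-only observations: K_pb and the product (V_p/V_b)·K_bp only; the
  probe flags V_b (and K_bp) as unrecovered.

### Practical identifiability under noise

The transformation (V_b, K_pb, K_bp) → (αV_b, αK_pb, αK_bp) leaves the brain
equation exactly invariant and perturbs plasma only through the net exchange
flux, which is slaved to quasi-equilibrium after ~1/((V_p/V_b)K_bp) ≈ 1.6
min. A 50% scaling along this direction changes the sampled curves by ~1.4%.
Consequently, with 5% proportional observation noise no 20-point design
recovers V_b, K_pb or K_bp to better than ~100% expected relative error
(linearized covariance of the unweighted least-squares estimator, confirmed
by Monte-Carlo recovery at tracer, 5 µM and 50 µM doses with uniform,
log-spaced and early-dense schedules); only V_p (~2%, pinned by the dose
scale) is robust. The packaged recovery study therefore uses the most
informative of the candidate designs (5 µM dose, log-spaced 0.25–120 min
schedule, chosen by the covariance analysis) and its noisy-recovery check is
expected to fail the 15% mark — an honest statement about this model, not a
defect of the optimizer. Precise historical calibrations of this model were
possible because digitized mean curves are essentially noise-free.

## Synthetic data

`generate` simulates a truth scenario, samples each compartment on its
schedule (default: 36 points, 0–35 min, both compartments — the span of the
tracer experiment it emulates), applies seeded noise, and writes the
calibration input format. Noise kinds: none, additive Gaussian (sigma in
data units), multiplicative lognormal (sigma as a fraction; CV ≈ sigma —
the default at 5%, since PET count statistics give roughly proportional
errors). Negative noisy observations are clipped at zero and flagged.
`reference_fixture` is the deterministic noise-free tracer scenario
(reference parameters, wtBChE, 11 µg ≈ 0.00305 µM initial plasma
concentration).

What the generator does *not* emulate: radioactive decay correction, scanner
resolution and partial-volume effects, metabolite radio-signal
contamination, inter-subject variability. Passing recovery tests therefore
demonstrate correctness of the estimation machinery on data that match the
model family exactly, not robustness to the systematic errors of real PET
curves.

## Known limitations

- AUC∞ of slow-decaying baseline (wtBChE) scenarios accumulates ~5% of its
  mass after t = 100 min; analyses that truncate integration near that
  horizon report correspondingly smaller values for the 0.16–1 µM scenarios
  (e.g. 35.1 vs the converged 37.1 µM·min at 1 µM, and 5.2/10.5 vs 5.4/11.1
  µM·min at the threshold-calibration doses, shifting the AUC threshold
  midpoint from 7.9 to 8.3 µM·min). This package always reports the
  converged integral.
- The exchange constants are not mechanistic BBB permeabilities; together
  with the effective volumes they are descriptive parameters of a
  coarse-grained model calibrated to striatal uptake.
- The linear half-life-versus-dose summaries (`half_life_vs_dose`) are
  regime-dependent conveniences: the line is excellent in the saturated
  regime (slope ≈ 1/(2·Vmax)) and degrades at doses below K_M.
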