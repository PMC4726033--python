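# Methods

`bksensor` operationalises the idea of using the BK channel — a K⁺ channel
gated jointly by membrane potential and intracellular Ca²⁺ — as a fast,
quantitative sensor of the local Ca²⁺ concentration near its membrane
neighbourhood. This note describes the models, the estimators built on
them, the synthetic data they are exercised on, and the numerical and
design choices a user should know about.

## Gating model

### Equilibrium (MWC)

The channel is a concerted two-conformation allosteric protein with
`n_sites` identical Ca²⁺ binding sites (default 4). Its equilibrium open
probability is

    P_o(V, Ca) = 1 / (1 + L(V) · [(1 + Ca/K_C)/(1 + Ca/K_O)]^n),
    L(V) = L(0) · exp(−Q·F·V/(R·T)),

with `L(0)` the closed/open bias of the Ca²⁺-free channel at 0 mV, `Q`
the equivalent gating charge, and `K_C > K_O` the Ca²⁺ dissociation
constants of the closed and open conformations. Defaults (`L0=1000`,
`Q=1.4 e₀`, `K_C=11 µM`, `K_O=1.1 µM`, `T=295 K`) are classic
literature-scale values for the mSlo1 α-subunit; they are configuration,
not fitted results.

### Kinetics (10-state Q-matrix)

The kinetic scheme is two tiers of five states, C0..C4 and O0..O4,
indexed by bound Ca²⁺. Binding is mass-action with a single forward rate
constant `k_b` on both tiers (off-rates `k_b·K_C` and `k_b·K_O`); the
concerted C↔O step carries the voltage dependence:

    opening(i) = alpha0 · exp(q_α·F·V/RT) · (K_C/K_O)^(i·φ)
    closing(i) = beta0  · exp(−q_β·F·V/RT) · (K_C/K_O)^(−i·(1−φ))

with `q_α + q_β = Q` and `beta0/alpha0 = L0`. This parameterisation
satisfies detailed balance around every elementary 4-cycle by
construction (`detailed_balance_report` verifies it numerically), and its
stationary distribution reproduces the closed-form `P_o` exactly — the
central internal consistency check of the package.

Kinetic defaults: `k_b = 0.18 µM⁻¹ms⁻¹` (the measured forward binding
rate of mSlo1, the quantity this whole approach turns on), `alpha0 =
0.008 ms⁻¹`, `beta0 = 8 ms⁻¹`, `q_α = 1.9`, `q_β = −0.5`, `φ = 0.5`.
The split of charge was chosen, once, on a physical argument: the fast
component of a flash-evoked current is a response to a sub-millisecond
Ca²⁺ spike, so reproducing the observed voltage dependence of the fast
fraction requires the C↔O equilibration to be fast (τ ≈ 0.2–0.8 ms) at
+30 mV yet slow (≈ 10 ms and above) at −50 mV, i.e. a steep voltage
dependence of the activation rate. Placing slightly more than the total
charge on the opening rate (a negative partial charge on closing, which
the scheme admits and which leaves the equilibrium untouched) achieves
that dynamic range. With these defaults the model driven by the standard
uncaging transient produces a hooked biphasic current at +30 mV
(τ_fast < 1 ms, τ_slow ≈ 9 ms) and a fast fraction R_f that rises with
voltage onto a saturating, Boltzmann-like plateau — the qualitative
flash phenomenology. On the plateau the decomposition scatters by about
±0.02, which is the tolerance the phenomenology tests allow.

## Propagation

State occupancies evolve as `dp/dt = p·Q(V(t), Ca(t))`. The engine uses
piecewise-constant coefficients: uniform steps of at most `dt_max`
(default 0.01 ms), coefficients frozen at the step midpoint, and the
exact matrix exponential per step. Every step is therefore a proper
stochastic map — probabilities stay in the simplex for arbitrarily stiff
inputs, which an adaptive ODE solver does not guarantee. The scheme is
second-order in the coefficient freezing; halving `dt_max` changes any
`P_o(t)` sample by far less than 1e−4 on the standard inputs. Non-uniform
input waveforms are linearly interpolated onto the stepping grid.
Identical consecutive (V, Ca) pairs reuse the cached exponential, so
step-protocol simulations cost only a handful of matrix exponentials.

Macroscopic current is `I = n·ĝ·P_o·(V − E)` with `ĝ` in pS, V in mV and
I in pA.

## Estimators

* **Boltzmann fits** (G–V and R_f–V): Levenberg–Marquardt least squares
  of `y = y_max/(1+exp((V½−V)/s))`; standard errors from the Jacobian.
* **Biphasic decomposition**: the post-flash rise above the pre-flash
  steady level is modelled as a fast rise-and-decay component (rise τ_f,
  decay τ_f-off, unit-peak normalised, amplitude h₁ at the hook maximum)
  plus a slow rise (τ_s, amplitude h₂); `R_f = h₁/(h₁+h₂)`. The form was
  chosen to reproduce the hooked morphology; the fit multi-starts on τ_f
  because the objective has local minima in the time constants. A flash
  response below a 5σ baseline-noise floor is rejected as degenerate
  (the maximum of ~10³ pure-noise samples already reaches ≈3.5σ).
* **C–O rise fit**: `I(t) = I₀ + a(1−exp(−t/τ))` on a caller-selected
  fast-phase window (default: flash to hook maximum). A Wald–Wolfowitz
  runs test on the residual signs flags windows that leak into the hook.
* **k_b estimate**: `k_b = 1/(τ·([Ca]_a + k_d))`, where `[Ca]_a` is the
  trapezoidal time-average of Ca²⁺ over the fast rising window and `k_d`
  the sensor's dissociation constant (supplied by the caller, e.g. from
  a dose-response curve). The identity `k_b·τ·([Ca]_a+k_d) = 1` is
  enforced structurally.
* **Global kinetic fit**: seeded differential evolution in log-parameter
  space around an initial guess, polished by trust-region least squares
  on the pooled residual vector. Markov-model fits are structurally
  degenerate, so the fit is judged — and reported — on the `P_o(V, Ca)`
  surface, not on raw parameters; a flat objective direction (Jacobian
  condition number > 1e10) or a dataset with a single Ca²⁺ level
  attaches a non-identifiability warning instead of raising.
* **Mean-variance analysis**: per-time ensemble mean and unbiased
  variance across sweeps, pooled into equal-occupancy bins (default 50;
  the binning is our choice), then ordinary least squares of
  `σ² = i·I − I²/N`, which is linear in `(i, 1/N)`. Standard errors come
  from a seeded bootstrap over sweeps when the raw sweeps are supplied —
  time samples within a sweep are correlated over the gating relaxation
  time, so point-based formulas are badly calibrated — with a
  heteroscedasticity-consistent sandwich formula as fallback. A
  significant linear trend of per-sweep mean against sweep index
  triggers a rundown warning (no correction is applied).

## Ca²⁺ reconstruction (the inverse method)

Three steps: (1) a fitted kinetic model supplies `P_o(V, Ca)`; (2) the
channel number follows from a steady-state current at known (V, Ca);
(3) marching over the trace in steps of `dt`, the Ca²⁺ of each step is
chosen so that the model current at the step end matches the measured
current, with the occupancy vector carrying the full gating history.
The driving force is evaluated at the step-end voltage while the
generator is frozen at the midpoint, matching the forward engine's
node-time current readout; `n_substeps` optionally subdivides the
voltage within a coarse Ca²⁺ step.

Two per-step solvers are provided. `bisection` exploits the (checked)
monotonicity of the one-step predicted current in Ca²⁺ and solves to
near machine precision. `es` is a seeded (µ+λ) evolution strategy
(µ=5, λ=20, ≤50 generations, self-adaptive log-normal step sizes) whose
population warm-starts at the previous step's Ca²⁺; because the one-step
current moves only by O(rate·dt) per unit Ca²⁺, the ES iterates to an
internal threshold three decades below the reporting tolerance —
stopping at the tolerance itself would leave a wide Ca²⁺ equivalence
class and corrupt the carried state. Both modes agree to a fraction of
a percent of the peak on the standard scenario.

Diagnostics: each step records a relative current residual (normalised
by max(|target|, trace maximum)). Steps that miss the tolerance are
*flagged*; more than 20% flagged aborts with the partial result
attached. Steps whose optimum sits on a search bound are reported
separately as *bound hits*: in a quiescent stretch any admissible Ca²⁺
reproduces a near-zero current, so a bound hit with an in-tolerance
residual marks unidentifiability, not failure.

### What the current does and does not constrain

The instantaneous Ca²⁺ is identifiable only where the current actually
depends on it. Two regimes defeat any inverse method: near-zero currents
(nothing to match) and deactivation-dominated stretches — after strong
repolarisation the current decays at the channel-closing rate and is
almost independent of Ca²⁺ for several milliseconds. Reconstructions
should therefore be windowed to the signal-dominated stretch, which is
also the experimental practice (starting the calculation where the
command crosses about −5 mV).

With noisy data the marching inversion is a deadbeat estimator: it
reproduces each sample exactly, amplifying high-frequency noise by the
inverse of the small one-step sensitivity. Two controls keep this in
check: (a) pre-smoothing with `condition_current`, a zero-phase
Savitzky–Golay filter applied to log|I| — recording noise on large
currents is well-described as multiplicative, and log-domain smoothing
prevents nA-scale samples from bleeding into pA-scale stretches across
protocol edges, which a linear filter does catastrophically; (b) a
coarser reconstruction step (the per-step Ca²⁺ sensitivity grows with
`dt`), trading time resolution for noise robustness. A per-step-frozen
estimate represents the step interior, so at coarse `dt` it should be
compared against mid-step truth.

## Synthetic data — what it emulates, and what it does not

No raw recordings accompany the study, so all pipelines run on synthetic
inputs:

* **Uncaging transient**: base 0.1 µM; spike peaking at 48.30 µM
  (rise 0.05 ms, decay 2.4 ms) on a slow approach (τ = 10 ms) to a 10 µM
  plateau. The spike amplitude absorbs the small slow-phase contribution
  at the spike-peak time so the trace maximum equals the nominal peak
  exactly. The two-exponential spike shape is a stand-in; the true
  photolysis shape between flash and peak is model-derived in the source
  experiments.
* **Pseudo-AP**: raised-cosine depolarisation (default −60 → +20 mV,
  1 ms rise, 2 ms fall) with an optional appended square test step.
* **Cav stand-in**: a single activation gate `m` relaxing to
  `m_∞(V) = 1/(1+exp((V½−V)/s))` with τ = 0.1 ms by default, current
  `g_max·m·(V−E_Ca)`, and local Ca²⁺ coupled linearly and
  instantaneously to |I_Ca| (the zero-dimensional nanodomain limit).
  The fast gate makes the local Ca²⁺ peak during the AP itself; real
  L-type channels have slower kinetics and pronounced tail currents,
  which would move Ca²⁺ into the deactivation-dominated (unidentifiable)
  stretch. The standard scenario (`standard_ap_scenario`) fixes the
  AP + 10 ms step-to-+50 mV protocol, an ensemble of 1662 channels of
  258 pS at E = −80 mV, a ~28 µM Ca²⁺ peak, and the reconstruction
  window 1.0–3.8 ms.
* **Stochastic ensembles**: independent channels advanced as a
  discrete-time chain with the midpoint-frozen matrix exponential as the
  one-step transition matrix and multinomial state-count updates — exact
  for exchangeable channels and fast for thousands of them.
  `variance_benchmark_sweeps` drives two-state channels (τ = 0.1 ms,
  P_o cycling 0↔0.9 under a Ca²⁺ pulse train) at the published
  single-channel parameters (i = 12.9 pA at +50 mV, N = 1662); the fast
  gating decorrelates the ensemble many times per sweep, which is what
  makes i and N recoverable to a few percent from 1000 sweeps.

Passing round trips on these inputs demonstrates the estimators are
correct and internally consistent; they do not certify performance on
real recordings, whose noise is only approximately multiplicative, whose
leak/capacitive artefacts are absent here, and whose channel populations
are neither perfectly homogeneous nor independent of rundown.

Every generator is a pure function of its spec and seed. Default
sampling is 50 kHz.

## Noise model

Where noisy currents are simulated, noise is multiplicative: `I·(1+ε)`,
`ε ~ N(0, 0.02)` for the standard 2% level. A whole-cell protocol spans
two to three decades of current; additive noise scaled to the peak would
make the small-current stretches pure noise, where no inverse method can
recover anything — the multiplicative model keeps the signal-to-noise
ratio uniform, which is the regime in which "graceful degradation with
noise" is a meaningful property. On the standard scenario the noisy
reconstruction (window-25 log-domain smoothing, dt = 0.2 ms, Ca²⁺ bounds
0.001–40 µM) achieves a mean RMSE of ≈8% of the Ca²⁺ peak over seeded
noise replicates, versus ≈0.4–2% noiseless at dt = 0.01–0.05 ms.

## Microdomain arithmetic

Membrane area from capacitance (1 pF at 1 µF/cm² = 100 µm²); channel
counts from saturating currents (`count = |I|/(ĝ·(V−E)·P_o)`); densities
per µm² reported to one decimal; expected source channels per sensor as
the density ratio with an integer bracket. The steady-state profile
around a point source under a linearised mobile buffer is

    ΔCa(r) = i_Ca/(4π·z·F·D·r) · exp(−r/λ),   λ = √(D/(k_on·[B])),

inverted for distance by bracketed bisection to 0.1 nm. Defaults
(D_Ca = 220 µm²/s; k_on = 2.7×10⁶ M⁻¹s⁻¹ for EGTA, 4×10⁸ for BAPTA) are
standard buffered-diffusion values and are exposed as configuration.

## Known limitations

* One ligand class: the low-affinity and high-affinity Ca²⁺ sites are
  not distinguished; no Mg²⁺ sensitivity, no β-subunits.
* The inverse method estimates Ca²⁺ only, with the kinetic model fixed;
  joint estimation and cross-step regularisation are out of scope.
* Behaviour when the measured current exceeds the model's attainable
  maximum is to clamp at the upper search bound and mark the step.
* The 11-parameter fit is judged on the P_o surface; individual rate
  constants from `fit_mwc_global` should not be over-interpreted.
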