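# Methods

`ornsim` simulates a pheromone-sensitive olfactory receptor neuron (ORN) of
a male moth as two chained deterministic stages, and provides the fitting
and evaluation machinery needed to adapt the model to spike-train
recordings.

## Model

### Receptor-activation kinetics (`ornsim.kinetics`)

Airborne pheromone at concentration L_air is adsorbed into the sensillum
lymph at rate k_i, giving the local odorant concentration L.  L binds the
free receptor R with an effective cooperativity exponent n (rate k1·Lⁿ),
forming the complex R_L, which converts reversibly (k2, k−2) into the
activated receptor R*.  In parallel, a deactivating enzyme N binds L
(k3, k−3) and degrades it (k4) into an inactive product that is not
tracked.  Receptor and enzyme pools are conserved
(R + R_L + R* = R_tot, N + N_L = N_tot), which reduces the six mass-action
ODEs to four in (L, R, R*, N); the complexed states are derived
quantities.  The reduced right-hand sides are implemented exactly as
written; because n is fractional, L is clamped at zero before
exponentiation and 0ⁿ is defined as 0 (the equations are physical only for
L ≥ 0; Euler steps can undershoot by rounding).

With the default parameters, steady state has closed-form structure: the
receptor and enzyme balances are linear given L, and the odorant balance
reduces to adsorption = degradation, k_i·L_air = k3·k4·N_tot·L/(k3·L +
k−3 + k4).  `steady_state_kinetics` solves this directly and is used as an
integrator-independent oracle in the tests.  No steady state exists once
adsorption exceeds the degradation capacity k4·N_tot; the solver raises in
that regime.

### Spike generation (`ornsim.neuron`)

The membrane follows C_m·dV/dt = −g_L(V − E_L) − γ·R*(t)·(V − E_R): the
activated receptor opens a conductance γ·R* with reversal E_R.  A spike is
emitted when V ≥ θ(t); V resets instantly to V_reset.  Two threshold
modes:

* **constant** — θ = θ₀ plus an absolute refractory period t_ref (default
  3 ms) during which V is clamped at V_reset.  This is the standard leaky
  integrate-and-fire model; its rate tracks the stimulus monotonically.
* **adaptive** — between spikes τ·dθ/dt = −(θ − θ₀); each spike increments
  the pre-spike (left-limit) threshold by Δ/τ.  The jump-and-decay
  threshold produces spike-frequency adaptation and the phasic–tonic
  response: with the default parameters a 0.5 s pulse at the 100 pg dose
  yields a transient rate peak ~0.1 s after onset that decays toward a
  sustained plateau before the pulse ends.

### Units

Time s, concentration μM, voltage mV, conductance nS, capacitance nF.
These are mutually consistent (C_m/g_L = 1 ms, the membrane time
constant), and γ·R*·(V − E_R) lands in nA·mV-free units matching
C_m·dV/dt.  Doses in pg map linearly to airborne concentration:
1 pg → 0.1 pM = 1e-7 μM (calibrated points 1/10/100/1000 pg).

## Numerics

* Forward Euler at dt = 1e-5 s (0.01 ms) for both stages defines the
  reference output; the kernels are numba-compiled.  Per step: kinetics
  update, membrane update with the current step's R*, threshold decay,
  crossing test V ≥ θ (ties resolved as crossings; they are measure-zero
  at this dt), then reset and jump/refractory.  Spike times are grid
  times; no sub-step interpolation (bias ≪ any reported quantity at
  0.01 ms).
* States are clamped at zero after each kinetics step; an undershoot
  beyond a tolerance (default 1e-3 μM) raises an instability error.  Plain
  Euler on the kinetics is unstable for dt ≳ 5e-5 s (the enzyme balance
  has rate k−3 + k4 ≈ 4×10⁴ s⁻¹), which the error surfaces explicitly
  rather than silently mis-integrating.
* Firing rates: sum of unit-mass Gaussians (SD 0.03 s) at the spike times,
  evaluated on a 1 ms grid, kernel truncated at ±8 SD; no edge
  renormalization.  Integrals (ISE, R² numerator/denominator, rate mass)
  are trapezoidal on that grid.
* R² = 1 − ∫(f_d − f_m)²dt / ∫(f_d − ⟨f_d⟩)²dt with ⟨f_d⟩ the data mean
  over the same scored window; undefined (raised) for constant data.

## Fitting

Stage one fits the four free parameters (n, γ, τ, Δ) to dose-resolved
average responses to a 0.5 s pulse by minimizing the integrated squared
rate error summed over the four doses (ε²_ave).  Stage two adapts a
per-cell subset — γ, (Δ, τ), or (γ, Δ, τ) — to each recording by
minimizing the same integral over a 10 s training window (ε²_ind), all
other parameters fixed; performance is the R² on the following 10 s
prediction window.  Model simulations for scored windows start 1 s before
the window from the resting state (burn-in), and additionally run one
kernel support (8 SD = 0.24 s) past the window end so that spikes just
outside the window contribute the same smoothing mass on both the data and
model side.

Optimization is Nelder–Mead on log-transformed parameters (positivity by
construction).  The objective is piecewise smooth — spike counts are
integers — and direct minimization from a distant start stalls on
plateaus: the measured basin of attraction of the stage-one optimum is
only about ±10% per parameter.  Both stages therefore run Nelder–Mead
through a *multiscale continuation*: the objective is first evaluated with
both data and model rates convolved with an extra Gaussian (0.12 s, then
0.06 s, then the plain objective; stage one inserts 0.03 s as well), each
stage warm-starting the next.  Extra smoothing is applied identically to
both sides, so the global optimum (a self-match) scores zero at every
scale while the basin widens substantially at the coarse scales.  Stage
one additionally launches the coarsest stage from an 8-point Sobol cloud
within ±2× of the initial guess and keeps the best coarse optimum.  The
three-parameter per-cell scheme warm-starts from the nested (Δ, τ)
optimum, which guarantees the scheme-nesting property (richer schemes
never fit worse).  The reported objective is always the plain, unsmoothed
ε².  With this driver the stage-one refit recovers all four generating
parameters exactly (ε² = 0) from ×[0.5, 2] perturbed starts in every
seeded trial we ran; plain Nelder–Mead with a restart recovered none.

Within a per-cell fit the transduction cascade is independent of all free
parameters, so R*(t) is simulated once per cell and only the spike
generator re-runs per objective evaluation (~30 ms per evaluation at
dt = 1e-5 s).

## Synthetic population (`ornsim.synthpop`)

The original 84-cell dataset is not publicly deposited, so the pipeline is
exercised on synthetic populations: each cell is the model itself with
(Δ, τ) drawn from a bivariate normal with means (0.5 mV·s, 1.2 s), SDs
(0.23, 0.38) and correlation −0.48 — the reported population statistics —
truncated at zero by redraw.  The recording protocol mirrors the
experimental design: random valve sequences with 50 ms bins (41 cells) or
100 ms bins (43 cells), open probability 0.5 per bin, unique seeded
sequence per cell, doses cycled over 1/10/100/1000 pg.  Default recording
length is 21 s — exactly burn-in + training + prediction — whereas real
sessions lasted minutes; this is the desk-scale choice that keeps the full
84-cell pipeline under ~10 minutes.

Recordings are noise-free model output with the generating parameters
stored alongside.  A green recovery test therefore establishes that the
pipeline is self-consistent — objectives, windows, smoothing and optimizer
all cohere — but not that the model describes any real neuron, and not
that fitting is robust to biological trial-to-trial variability, electrode
noise or spike-sorting errors.  Optional spike-jitter and spike-deletion
knobs (off by default) allow probing robustness; no noise model is part of
the stated defaults.  Per-cell γ spread for the γ-heterogeneity scheme has
no reported statistics; when enabled it is lognormal with a documented
multiplicative SD (tests use ~20%).

## Known limitations

* The inactive degradation product is a sink, not a state; no perireceptor
  diffusion, plume turbulence, or valve rise time (valves switch in < 5 ms,
  below the bin scale; an optional first-order filter exists, default off).
* No Hodgkin–Huxley spike shapes, no Ca²⁺- or second-messenger-dependent
  transduction feedback: all adaptation lives in the threshold.
* The fractional cooperativity n ≈ 0.056 makes the binding step an
  effective, not mechanistic, description; the equations are implemented
  as stated.
* Euler is the only production integrator (it defines the reference
  output); there is no adaptive-step fallback, only the instability guard.
* Prediction R² on held-out windows is bounded below 1 by the 1 s
  burn-in-from-rest convention for cells with slow thresholds (τ ≫ 1 s);
  this matches the stated evaluation procedure rather than a numerical
  defect.
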