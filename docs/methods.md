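# Methods

## Model

The state is (x, y, φ): membrane potential, recovery variable, magnetic
flux.  The vector field

```
x' = y + a x² − b x³ + k W(φ) x + I₁(t) + I₂(t)
y' = c − d x² − y
φ' = x − φ
```

uses the flux-controlled memductance W(φ) = α + βφ² and two sinusoidal
current sources Iⱼ = Aⱼ sin(2π fⱼ t).  Defaults: a=3, b=1, c=1, d=5, α=0,
β=0.01; single excitation is A₂=0.  All quantities are dimensionless; the
drive frequencies are cycles per unit time.  The system is treated in
non-autonomous form — time is an explicit argument, no auxiliary time state
is added, and consequently the Lyapunov spectrum has exactly three
exponents and no structurally zero one.

The coefficients a–d are symbolic with the canonical defaults, so the
undriven, uncoupled HR core (k=0, A=0) and the full model share one
implementation.  α is carried through every formula even though the
canonical configuration sets it to zero; the equilibrium Jacobian entry
(1,1) then gains +kα and the equilibrium cubic a linear term kα·η.

## Equilibria of the forced system

Equilibria are defined by freezing I₁+I₂ at its instantaneous value — the
convention that makes "the equilibrium at time t" meaningful for a forced
system.  Substituting y = c − d·η², φ = η = x gives the cubic

P(η) = (βk − b)η³ + (a − d)η² + (αk)η + (c + I) = 0,

solved by Cardano's method: depressed-cubic coefficients p, q, discriminant
Δ = q²/4 + p³/27, with the root-count trichotomy (Δ>0: one real root, Δ<0:
three, Δ=0: two).  Numerical choices:

- The three-real-root branch uses the trigonometric form
  2√(−p/3)·cos(θ/3 − 2πj/3) rather than complex cube roots, avoiding
  branch-cut ambiguity; the clamp |cos θ| ≤ 1 guards rounding at Δ→0⁻.
- Every closed-form root is polished by up to three Newton steps, which
  decouples reported accuracy (|P(η)| ≤ 1e−12·max(1, η²)) from the closed
  form; the test suite checks all roots against a bracketing-bisection
  oracle on a Cauchy-bound grid.
- Δ is declared zero when |Δ| ≤ 1e−12·max(1, q²), making the double-root
  case reachable in floating point.
- The leading coefficient vanishes at k = b/β (k=100 canonically); this
  degeneracy is flagged and solved as a quadratic (empty root set when the
  quadratic has no real roots, an error in the constant sub-case).

Stability comes from the characteristic polynomial λ³ + m₁λ² + m₂λ + m₃ of
the equilibrium Jacobian.  Because the flux row is φ' = x − φ, (J + I) is
singular for every (η, k): −1 is always an eigenvalue, and the identity
m₂ = m₁ + m₃ − 1 holds exactly.  An equilibrium is labelled *stable* iff
every real part is < −10⁻⁹; any positive real part — including the
saddle-type mixed-sign case — is labelled *unstable*, and the per-root
eigenvalues are exposed so callers can re-derive a finer taxonomy.  Over
the symmetric two-tone window t ∈ (5, 25) (k=1, A₁=A₂=1, f₁=f₂=0.05) the
unique-root branch is stable exactly where I(t) < −1, i.e. t ∈ (11.67,
18.33); fold bifurcations at I ≈ 0.209 additionally create a coexisting
stable root on t ∈ (9.68, 11.67) ∪ (18.33, 20.33), which the track reports
as separate rows.

One tabulated value did not survive recomputation: at η = −2.02, k = 1 the
eigenvalue near zero is −0.1596, not the −0.1505 sometimes quoted; the
other two eigenvalues (−25.1599, −1) reproduce exactly, so we report the
recomputed value.

## Integration

Trajectories use an adaptive Dormand–Prince 5(4) pair (the "ODE45"
contract) compiled with numba: FSAL, PI-free step control with factor
0.9·err^(−1/5) clamped to [0.2, 5], error norm RMS over
atol + rtol·max(|y|, |y_new|).  Defaults rtol = 1e−8, atol = 1e−10.  The
maximum step is capped at min(1/(20f₁), 1/(20f₂), 0.1) so the drive is
always resolved regardless of the error estimate.  Dense output on a
uniform grid (default sample_dt = 0.01) uses cubic Hermite interpolation on
each accepted step — fourth-order, far below the step-control tolerance at
these settings.  The stepper is validated against the closed-form harmonic
oscillator (≤ 1e−6 over ten periods at rtol 1e−8) and pointwise against
scipy's RK45 on the neuron system itself.  Spike peak values are refined by
a parabolic fit through the three samples around each discrete maximum, so
peak amplitudes do not carry the sampling quantization.

Default horizons: t_end = 2000–3000 with the first 500 time units
discarded for statistics; convergence-time analyses keep t from 0.
Pointwise tolerance-sensitivity is only asserted for periodic orbits;
chaotic conditions are checked through ergodic averages (exponents, ISI
statistics), never pointwise.

## Lyapunov spectra

The full spectrum integrates the 3-d variational system alongside the
trajectory and reorthonormalizes the tangent frame by modified Gram–Schmidt
every renorm_dt = 1.0, accumulating log column norms (Benettin's method).
The augmented system uses fixed-step RK4 (dt = 0.005): an ergodic average
gains nothing from step adaptivity, and the fast contraction (λ₃ ≈ −17,
|λ₃|·dt ≈ 0.09) is comfortably inside RK4's accuracy and stability range.
Defaults: transient 1000, horizon 10000 — long enough that the leading
exponent's running estimate moves < 0.01 over the final decade.  The result
carries the running-estimate trace and a convergence flag (final 10 % of
the trace within 0.05).

Validation is three-fold: a decoupled linear system with rates (−1, −2, −3)
is recovered to 1e−3; a two-trajectory Benettin estimate (independent
algorithm, separation 1e−8) agrees with the tangent method within 0.02 on
the standard conditions; and Σλᵢ matches the time-averaged divergence
(2a·x − 3b·x² + kW(φ)) − 2 along the attractor.  The third exponent of
slow-envelope conditions (f₂ = 0.002, drive period 500) fluctuates on a
~0.15 scale per envelope cycle, so the sum identity is checked on matched
multi-cycle windows (horizon 20000), where the residual is ≈ 0.05.

Chaos calls use LE₁ > 0.005 ⇒ chaotic, LE₁ < −0.005 ⇒ regular, the band
between ⇒ indeterminate.

## Firing taxonomy

Spike and burst thresholds have no universal definitions; the ones below
are this package's operational choices, all exposed as arguments:

- **Spikes**: local maxima of x with height ≥ 0, topographic prominence
  ≥ 1.5 and separation ≥ 0.5.  In this model genuine action potentials
  rise > 2 x-units above the local envelope while drive-induced
  subthreshold ripples stay below ≈ 1.1, so prominence separates them with
  a wide margin.
- **Burst segmentation**: an ISI ≥ 3× the median of the short-ISI mode
  opens a new burst (bimodality rule).
- **Bursting vs spiking**: segmented groups must average ≥ 2 spikes; under
  a high-low tone pair (frequency ratio ≥ 5) the groups must additionally
  be locked to the slow cycle (group rate within [0.5, 2.5]×f_slow).
  Without the locking requirement, chaotic spiking whose spikes cluster
  incidentally on a fraction of the slow crests (the f₂ = 0.07 condition)
  would be mislabelled as bursting.
- **Period count**: distinct spike peak-amplitude clusters (tolerance
  1e−2) of a periodic tonic train — period-2 spiking has two alternating
  peak heights.
- **Quiescent**: spike rate < 1e−3 with tail state variance < 1e−4;
  a spike-free trajectory with large variance is a **subthreshold
  oscillation** (the driven limit-cycle branches), a label added beyond
  the plain spiking/bursting dichotomy because those branches are neither
  quiescent nor spiking.

Periodic vs chaotic always comes from the leading Lyapunov exponent, never
from the spike train, so the taxonomy stays consistent with the dynamics
modules.  The slow-envelope condition f₂ = 0.002 is labelled *periodic
bursting* (LE₁ < 0) with the intra-burst ISI dispersion reported as an
irregularity descriptor (CV ≈ 0.3), rather than as a chaotic label.

## Bifurcation sweeps

The bifurcation ordinate is the multiset of post-transient local maxima of
x (peak sampling, the standard picture for HR-type models); a stroboscopic
variant (one sample per drive period) is available for cross-checks.  Each
grid point restarts from the declared initial condition — no state
inheritance — so branches keep their IC identity and results are
independent of traversal order.  Sweep defaults: 400-point grids for
headline figures; the test suite uses 8–15-point grids, which is enough to
assert the qualitative structure (reverse period-doubling from (−5,0,0),
an everywhere-regular (5,0,0) branch, chaos inside the low-f₁ window,
coexistence onset between f₁ = 0.3 and 0.5).

## Multistability

An **attractor fingerprint** summarizes a post-transient run: leading
Lyapunov exponent, mean and standard deviation of x, an ISI histogram on
fixed bins (25 linear bins over [0, 50] plus overflow, normalized), and
the peak-amplitude cluster count.  The distance is
|ΔLE₁| + |Δmean| + |Δstd| + ½·L1(histograms); windowed fingerprints omit
the LE term.  Calibration on the model's own scenarios — distinct
attractor pairs score 2.3–2.5, same-attractor comparisons (two halves of
one chaotic run, merged pairs) score ≤ 0.13 — puts the coexistence
tolerance at 0.25, an order of magnitude of separation on either side.

**Coexistence**: two ICs integrated to t_end (default 2000–3000),
fingerprints on the final 50 %, coexists ⇔ distance > 0.25.
**Merging time**: the first IC's run defines the asymptotic reference; a
50-unit window slides over the second run (kept from t = 0) and the
earliest window start from which every later window matches is reported.
Because windowed fingerprints of a chaotic attractor scatter, the match
threshold is self-calibrated as 1.15× the largest distance between the
reference run's own asymptotic windows and its long-run fingerprint.  The
estimator resolves the transition to roughly ± half a window.
**Elimination threshold**: detect_coexistence along an ascending k grid
(default −8…−6, step 0.1, t_end 3000), reporting the largest merged k
refined by one bisection step; monotonicity of the boundary is reported,
not assumed, since chaotic transients can make it fuzzy.

## Circuit mapping

The analog realization uses inverting integrator/adder stages and
0.1-gain multipliers; matching coefficients gives one identity per
parameter (a = R7/(10R1), b = R7/(100R3), k = R7/(10R4), c = R11/R9,
d = R11/(10R8), β = Ro/(10R15)) with anchors R7 = 300 kΩ,
R11 = R14 = R15 = 100 kΩ, C = 50 nF and τ₀ = 1/(RC) = 10⁴ 1/s (base
R = 2 kΩ).  β variations are absorbed by Ro with R15 held fixed.  The
mapping is algebraically exact, round-trips to 1e−12, and rejects
non-realizable sets (non-positive resistances; α ≠ 0 has no branch in this
topology).  Physical drive frequency is f·τ₀ Hz.  No E-series rounding or
op-amp non-ideality modelling is attempted.

## Known limitations and non-reproduced values

- The merging times at strong negative coupling are measured ≈ 20 % earlier
  than the published visual readings (≈ 270 and ≈ 200).  The underlying
  regime switches are robust properties of the equations — the k = −7 run
  from (5,0,0) leaves its quiescent phase at t = 222.6 under every
  tolerance from 1e−3 to 1e−12, under max-step changes, under 1e−6…1e−2
  IC perturbations, and under an independent RK45 implementation — so we
  report the computed values rather than calibrating toward the readings.
- The elimination threshold depends on the observation horizon: at
  t_end = 3000 the boundary sits at −6.45 (merging near the boundary takes
  longer than a short figure window shows).  Longer horizons move it
  further toward zero, not toward more negative values.
- Finite-time fluctuation of the most negative exponent (±0.15 over
  10⁴-unit horizons on slow-envelope conditions) limits third-exponent
  agreement to ~0.3; the leading exponent is stable to < 0.01.
- The synthetic burst fixtures used in the spike-detection tests are
  Gaussian bumps on a flat baseline; they exercise timing and prominence
  logic but not spike-shape asymmetry or baseline drift of real membrane
  traces, so passing them says nothing about electrophysiological
  recordings — the package analyses this model, not experimental data.
- No two-parameter bifurcation surfaces, no equilibrium continuation, no
  basin maps beyond the paired-IC protocol, no stiff solver, and no
  transient circuit (SPICE-level) simulation.
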