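# Methods

## The circuit model

`bgflux` models the basal ganglia–thalamo-cortical motor loop as seven
coupled Hopfield-type rate units: motor cortex (1), striatal direct-
and indirect-pathway populations (D1 = 2, D2 = 3), the GPi/SNr output
complex (4), GPe (5), motor thalamus (6) and STN (7).  Each activity
x_i obeys

    C dx_i/dt = I_i − x_i/R + Σ_j (±) T_{i,j} f(x_j)  [± D_input],

with the Hill response f(x) = x^n/(s^n + x^n), s = 2, n = 2.  The sign
pattern encodes the anatomy: cortex and thalamus excite the striatum,
the striatal and pallidal projections are inhibitory, the STN is
excitatory, and the constant dopamine drive D_input enters the D1
equation with a plus sign and the D2 equation with a minus sign.
Defaults: R = 1.67, τ = RC = 6 ms (so C = τ/R and the leak rate is
exactly 1/τ), T ∈ [1, 3.2] as listed in `bgflux.params`, external
inputs I = (0.1, 0.05, 1.2, 4.4, 2.8, 2.0, 1.2).

Two modelling choices deserve mention:

* **Negative activities are not clamped.**  The equations are
  integrated as written; because the even Hill exponent makes f
  symmetric about zero, a `ValidityWarning` is emitted when a
  coordinate drops below −s/10, flagging a regime where the rate
  interpretation breaks down (this occurs e.g. at very low dopamine,
  where the STN mean goes slightly negative, and under strong DBS
  offsets).
* **The stored STN→cortex strength (T_{1,7} = 1.8) is excluded from
  the drift by default** since the cortex equation contains no STN
  term; `include_T17=True` adds it for exploration.

## Deterministic analysis

Fixed points are found by Newton–Krylov style root finding from a
deterministic start lattice plus relaxation endpoints, with stability
from the Jacobian spectrum.  Limit cycles are detected by integrating
past a transient scaled to the linear growth rate (≈10 e-folding
times, capped at 40–60 s of model time), locating cortex maxima with
parabolic sub-sample refinement (raw peak times are quantized to the
recording step and would alias into the period), and requiring
inter-peak consistency (CV ≤ 1%) plus a settled envelope.  The
peak-to-peak amplitude threshold separating damped ringing from a
sustained cycle is 1e-3.  Hopf points are located by bisection on the
leading eigenvalue's real part, to a bracket width of 1e-3 in
D_input; numerical continuation software is deliberately avoided —
two sign changes in a scalar parameter do not need it.

With the default parameters the oscillatory block is
D_input ≈ (0.669, 1.118); periods run from ≈62 ms at the lower edge to
≈44.5 ms at the upper edge (16–22.5 Hz, inside the beta band), period
strictly decreasing in dopamine, and the attractor-mean cortex
activity increasing with dopamine.

## Stochastic closure and the landscape

Additive Gaussian white noise with scalar diffusion D (default
`D_diff = 0.01`; chosen small enough for the Gaussian closure to be
meaningful at the circuit's activity scale ~0.1–5, large enough that
probability grids are non-degenerate) gives Langevin dynamics whose
probability evolution is approximated by a Gaussian moment closure:
the mean follows the deterministic drift, and only the *diagonal*
variances are retained,

    dσ_ii/dt = 2 A_ii σ_ii + 2 D.

Because no population couples to itself, A_ii = −1/τ exactly, so the
closure variance relaxes to D·τ (= 0.06) on every coordinate — the
probability "tube" around the attractor has constant width √(Dτ) ≈
0.245.  The joint probability is factorised into per-variable
Gaussians (mean-field product ansatz), so a 2-D projection is the
product of the two projected marginals.  In the mono-stable regime
the steady state is the converged snapshot; in the oscillatory regime
it is the average of 200 snapshots spaced uniformly in time over
exactly one period (doubling to 400 changes the grid by < 1e-4 in
total variation).  Default grids are 200×200 cells spanning the
attractor projection padded by 4√σ_max.

The potential is U = −ln max(P, floor) with a floor of 1e-12 of the
grid maximum, and the flux is J = F·P − D ∇P with central differences
(one-sided at borders).  Because the drift is a function of all seven
coordinates, its two projected components are evaluated with the five
off-projection coordinates closed to their probability-weighted
conditional phase means (mono-stable: the fixed-point values); a
nearest-orbit-point closure is available behind a switch.  Both are
approximations; their continuum residual is visible as a nonzero
divergence of J (≈0.03 at D_input = 0.8) that does *not* vanish under
grid refinement, whereas the discretisation error of the decomposition
identity F = J/P − D∇U converges at second order (cells whose
difference stencils touch the probability floor are excluded from
that statistic, since the clamp injects an O(1) artefact).

Scalar summaries:

* **Barrier height** U_max − U_min, where U_min is U interpolated
  along the projected cycle polyline and U_max is the maximum over
  grid cells strictly inside the cycle polygon (point-in-polygon
  test).  Using the deterministic cycle to define "inside" avoids any
  threshold on U.
* **Average flux** J_Average = ∮|J| dl / ∮dl along the cycle,
  resampled uniformly in arc length (4000 points; stable to 0.5%
  under resampling).  The magnitude is integrated by default; the
  signed tangential component is available and differs by ≈2% on the
  ring (the flux is nearly parallel to the orbit: median angle ≈7°).
* **Entropy production rate** Σ_cells |J|²/(D·P) × cell area, the
  standard dissipation functional for constant isotropic diffusion;
  non-negative, zero exactly when J vanishes.

Across the oscillatory block both barrier height and average flux
rise and then fall (single interior maximum), the entropy production
rate co-varies with the flux, and flux × period correlates positively
with the loop length of the projected cycle.

## The Langevin oracle

`bgflux.langevin` is a brute-force Euler–Maruyama simulator (default
dt = 0.01 ms; noise increments of variance 2·D·dt per coordinate per
step; vectorised over walker ensembles; bit-reproducible per seed).
Histogram landscapes of long runs validate the closure.  A Gaussian
smoothing option (in cells) is provided for when the histogram is
used as a mode or ridge estimator rather than a raw density.

What the oracle comparison shows — and what it does not:

* The leak-only (linear OU) limit reproduces mean I·R and variance
  D·τ within Monte-Carlo error, exactly as the closure predicts.
* In the oscillatory regime the mean-field ring ridge is covered
  ≥ 90% by the empirical ridge.  The converse containment is
  structurally impossible: the diagonal closure underestimates the
  tube width (the full Lyapunov covariance at the fixed points has
  marginal σ ≈ 0.5–0.9 versus the closure's 0.245), so the empirical
  ridge is always wider.
* In the mono-stable regime the empirical stationary density is
  skewed: its mode sits ~0.2–0.3σ away from the deterministic fixed
  point (a noise-induced O(σ²) effect of the Hill nonlinearity that
  any Gaussian closure centred on the deterministic mean ignores).
  At D_diff = 0.01 this displacement is about 2 cells on a σ/5
  comparison grid; it shrinks proportionally with D_diff.

These are honest limitations of the diagonal Gaussian closure, not of
the oracle; tests assert the properties that the closure can and does
satisfy and quantify the ones it cannot.

## Sensitivity analysis and DBS

The sensitivity scan perturbs one labelled connection at a time over
a percent grid (default ±50% in 10% steps; the 0% row is the baseline
bit-for-bit) and reruns the whole pipeline.  At D_input = 1.00
strengthening the indirect-pathway projection (striatum D2→GPe)
ignites the oscillation; at 1.25 strengthening the direct-pathway
projection (striatum D1→GPi) quenches it; at 0.95 the signed
responses show the direct/indirect asymmetry (indirect strengthening
raises barrier and flux, direct strengthening lowers them).  Note the
metrics are non-monotone along the oscillatory block, so only the
strengthening direction relative to baseline is a robust signed
statement.

DBS is modelled as a constant (DC) input, not pulsatile stimulation:
`direct_inhibition` adds a negative offset to the target's input;
`decoupled` additionally multiplies every coupling sourced at the
target by an efferent gain ≥ 1, representing axonal activation
decoupled from somatic inhibition.  The "decrease of neural activity"
reported per point is the drop of the target's attractor-mean
activity from baseline.  At D_input = 0.9: GPi inhibition reduces the
average flux monotonically until the oscillation dies; GPe inhibition
produces a rise-then-fall; STN inhibition shows a small (~2%) initial
flux rise before the dominant decrease — this rise is robust to grid
refinement and to the magnitude/signed flux choice, i.e. a genuine
property of these equations under this flux measure.  All decoupled
protocols suppress the flux below 50% of baseline on a sufficiently
long offset grid.

## Problem sizes and numerics

Default tolerances: RK45 with rtol 1e-7 / atol 1e-9 everywhere
(shared through one solver helper, so the analytic test systems
exercise the same path); fixed-point residual < 1e-8; duplicate roots
merged within 1e-4.  Landscape grids are 200×200 for the dopamine
sweep and 100×100 for the sensitivity/DBS scans (each scan point is a
full pipeline run); oracle comparisons use ensembles of 64–80 walkers
for ~1.3×10⁶ post-burn-in samples.  Variance floor 1e-8 before logs;
probability floor 1e-12 of the grid maximum.  All stochastic
components take explicit seeds and are bit-reproducible.

## Known limitations

* The diagonal Gaussian closure narrows the probability tube and
  centres it on the deterministic attractor; width-sensitive and
  mode-location comparisons against the true stochastic density carry
  O(σ) / O(σ²) systematic errors quantified above.
* The 2-D drift closure makes the plotted flux field an approximation
  whose continuum divergence does not vanish.
* DC stimulation does not model high-frequency pulse trains; synaptic
  delays, plasticity and receptor kinetics are outside scope.
* The circuit is a rate model with one unit per nucleus; no
  spiking-level statements are possible.
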