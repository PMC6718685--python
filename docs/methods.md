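# Methods

## Model

The package simulates a discrete-time neural system of one excitatory and
one inhibitory threshold-linear neuron,

    x(t+1) = F_a(w_EE x(t) - w_EI y(t)),
    y(t+1) = F_b(w_IE x(t) - w_II y(t)),

where `F_g(X) = clip(g X, -1, 1)` saturates at ±1 beyond the activation
threshold `1/g`.  Under the weight-ratio constraint
`w_EI/w_EE = w_II/w_IE = k` the pair collapses exactly onto a
one-dimensional map for the effective neural potential `z = x - k y`:

    z(t+1) = F(z) = F_a(z) - k F_b(z).

`MapParams` enforces the constraint at construction (relative tolerance
1e-12), so the 2-D and reduced dynamics are interchangeable; this identity
is property-tested.

For the studied parameters (`b = 3.42`, `k = 1.3811`, `a` near 6) the map is
odd with one chaotic band on each side of `z = 0`.  Three forcing terms can
be added:

* **RRO feedback** `K u(z)`, with `u(z) = -(z - z_d) exp(-(z-z_d)^2 / 2σ²)`,
  a Gaussian-windowed restoring term acting only near the merging point
  `z_d`.  Negative `K` deepens the map's extrema and merges the two bands;
  positive `K` separates them.  Defaults: `z_d = 0`, `σ = 1/a` (the distance
  from the merging point to the local extremum of the map).
* **Weak sinusoid** `S(t) = A sin(2πΩt)`; the phase runs on the absolute
  iteration clock, including discarded transients, so the retained window's
  phase is well defined.
* **Additive noise** `D ξ(t)`, ξ i.i.d. standard Gaussian from a seeded
  `numpy.random.Generator`.

## Attractor merging condition

An orbit trapped on the positive band ranges up to `f_max`, the local
maximum *value* of the iterated map, so it escapes to the negative side
exactly when the image of that value is negative.  Merging (chaos–chaos
intermittency) therefore occurs iff

    full_map(f_max) < 0   and   full_map(f_min) > 0,

with `f_max`/`f_min` the local extremum values of the full map, feedback
included.  Note this is a second-iterate condition: the condition on the
extremum value's *image*, not on the extremum value itself — the extremum
value `1 - kb/a` is positive throughout the studied range and cannot change
sign.  With `b = 3.42`, `k = 1.3811` the condition has the closed-form
no-feedback threshold `a* = (kb)²/(kb - 1) = 5.992`, which the numerical
bisection reproduces; the critical feedback strengths it yields
(−0.068 / −0.052 / −0.036 for a = 5.95 / 5.96 / 5.97) match the reported
phenomenology of negative-feedback merging.

Extrema are located on the full map `F + Ku` by a 10⁴-point grid on
`[-(1+k), 1+k]` (the map's range bound) followed by bounded scalar
minimization to ~1e-10.  Strict grid-local extrema are used, which makes
the saturated plateaus (exactly flat) invisible to the search by
construction.  `critical_a` / `critical_K` bisect the boolean condition to
1e-6 and are reported at 2–3 decimals.

## Initial conditions and the spurious period-2 cycle

Any state with both activations saturated maps to `±(1 - k) = ∓0.3811`, and
`0.3811 > 1/b`, so the points `±(k-1)` form a superstable period-2 cycle
(derivative 0) that alternates sign every iteration.  Its basin contains
all `|z| ≳ 1/b ≈ 0.292`, and it survives weak drive and noise.  This orbit
is not the chaotic dynamics of interest: the chaotic band spans roughly
`[0.02, 0.21]` and its basin is `|z0| < 1/(kb) ≈ 0.212` (states up to
~0.292 enter the band after one sign change).  All defaults therefore start
orbits at `z0 = ±0.2`, and per-trial initial conditions are drawn uniformly
from `±[0.1, 0.2]`.  Starting at, e.g., `z0 = 0.3` silently measures the
period-2 cycle (P_t ≈ 1, λ → -∞) and should be avoided.

## Indices

* **P_t** — chaos–chaos intermittency probability: the number of sign
  changes of the binarized series `Z(t) = sign(z(t))` (with `z = 0 → +1`)
  between consecutive retained samples, divided by the retained length.
* **C(τ)** — normalized delayed cross-correlation between `S` and `Z`,
  `C(τ) = C_SZ(τ)/√(C_SS C_ZZ)`, all averages over the overlapping window
  at each delay.  The response index is `max_τ C(τ)` over 64 integer delays
  spanning one drive period.  A constant `Z` (no intermittency) makes the
  correlation undefined; sweeps record such points as missing.
* **λ** — Lyapunov exponent by perturbed restarts: M clones offset by
  `d0 = 1e-8`, evolved τ = 1 step under identical drive and noise
  (common-noise convention, so λ measures state-space divergence only),
  averaging `ln(d(τ)/d0)/τ`.  Noise-free, this equals the orbit average of
  `ln|F'(z) + K u'(z)|`, which the tests check to 2%.

## Experiments

Bifurcation scans run each grid value from `z0 = ±0.2` and record P_t, λ,
the merging-condition values, and the last 200 retained states.  Response
curves and surfaces average `max_τ C(τ)` over 10 trials with independent
noise seeds and random initial signs; surfaces also annotate, per control
value, whether merging occurs without the sinusoid (analytically for the
feedback axis, by a drive-free run for the noise axis).  All seeds are
drawn from a single root seed and recorded in the result, so every scan is
exactly reproducible.

Default problem sizes: transient 10⁴ discarded, T = 2×10⁵ retained (20
periods of the slowest studied drive Ω = 1e-4); scans used in the test
suite are shortened (T = 3×10⁴–10⁵, 3–6 trials) after checking that the
extracted thresholds and peaks are stable at those sizes.

## Drive parameters for the resonance curves

The fixed drive behind the response curves is `A = 1e-2`, `Ω = 1e-4` for
both the feedback (chaotic-resonance) and noise (stochastic-resonance)
curves.  At substantially larger amplitudes (A ≳ 2×10⁻²) the sinusoid alone
switches the attractor and the noise curve loses its unimodal peak, i.e.
stochastic resonance is no longer the mechanism being measured; at
`A = 1e-2` the noise curve peaks at `D ≈ 2.5×10⁻³`, just past the merging
onset, which is the resonance signature of interest.  The representative
band points use `(K, A) = (-0.06, 1e-2)` for chaotic resonance and
`(D, A) = (4e-3, 5e-2)` for stochastic resonance.

## Numerical choices

* Iteration kernels are numba-compiled; noise is pre-drawn per run so the
  perturbed Lyapunov clone can share the identical realization.
* λ guards exact-zero separations with a 1e-300 floor.
* `find_peak` breaks exact ties toward the weakest control (smallest |K| or
  |D|); `find_threshold` warns and returns the first onset if the predicate
  flips more than once.
* Delimited outputs use 17-significant-digit floats and are read back with
  round-trip parsing, so read(write(x)) is bit-exact.

## What the simulations do and do not show

All quantities are properties of this specific piecewise-linear map; the
synthetic forcing (pure sinusoid, white Gaussian noise) is the idealized
setting of the resonance analysis.  Passing tests demonstrate the
attractor-merging control and resonance phenomenology of the model, not of
biological neurons: no refractoriness, heterogeneity, coupling delays, or
colored noise are represented.  Known limitations: the merging thresholds
are exact only for the symmetric map (`z_d = 0`); the chaotic-band basin
analysis above holds for the studied parameter window (a ≈ 5.6–6.1) and is
not a general basin computation; and the measured response-surface maxima
(≈0.89 chaotic, ≈0.73 stochastic at Ω = 1e-4) sit above the curve-peak
values (≈0.7 and ≈0.4), because the surfaces include near-threshold
hotspots that the single-amplitude curves do not visit — the chaotic
maximum exceeds the stochastic one in every configuration examined.
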