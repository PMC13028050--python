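# Methods

## Model and conventions

The membrane model is the classical Hodgkin–Huxley system in the
absolute-voltage convention: the membrane potential E is in mV with rest
near −65 mV, and the rate-function prefactors (0.108, 0.0027, 0.0555 ms⁻¹)
are the classical squid-axon values 4, 0.07 and 0.125 with the −65 mV
resting shift absorbed into the exponentials (e.g.
4·e^(−65/18) = 0.10797 ≈ 0.108). Units are fixed package-wide — mV, ms,
mS/cm², µA/cm², µF/cm² — with no conversion layer, so a number is always in
the unit its field name declares.

The six rates are built from three functional forms:
linear-over-expm1 `k(E−E₀)/(1−e^{−(E−E₀)/s})` (α_m, α_n), pure exponential
`k·e^{(E−E₀)/s}` (β_m, α_h, β_n) and logistic `k/(1+e^{−(E−E₀)/s})` (β_h).
Only these renderings keep every rate positive on the physiological range
and reproduce the classical kinetics. A fourth form, `constant`, supports
synthetic gates with a voltage-independent rate.

One deliberate correction: the n-gate relaxation is implemented as
`dn/dt = α_n(1−n) − β_n·n`. A variant with `−β_n·h` circulates in some
transcriptions; it is dimensionally and biophysically wrong (the closing
term of a gate must act on that gate's own occupancy) and destroys the
boundedness property, so it is not offered.

### Numerical handling of the rate functions

- Removable singularities of the linear-over-expm1 form (α_m at −40 mV,
  α_n at −55 mV) return the series limit k·s when |E−E₀| < 10⁻⁷ mV,
  keeping the function C¹-continuous without a 0/0.
- Exponential arguments beyond ±700 are rejected with a diagnostic rather
  than silently saturating to 0/inf.
- The integrator uses an arithmetically identical scalar fast path for the
  six canonical rates (same expm1-based formulas and the same singularity
  window) to keep millisecond-scale simulations cheap.

## Membrane parameters

Maximal conductances ḡ_Na = 120 and ḡ_K = 36 mS/cm² are the classical
values (ratio 3.33). The leak conductance (0.3 mS/cm²), reversal potentials
(E_Na = +50, E_K = −77, E_L = −54.387 mV) and capacitance (1 µF/cm²) are
conventional squid-axon values consistent with the voltage convention; they
are defaults, not fitted quantities, and every one is overridable in the
run configuration. E_L is the classical value tuned so the resting
potential sits near −65 mV; `resting_state()` solves
I_ion(E, ξ∞(E)) = 0 by bracketed root finding (Brent, xtol 10⁻¹²) rather
than assuming −65 exactly, which is what makes the "equilibrium stays
constant to 10⁻⁶ over 50 ms" property an honest test.

## Integration

Classical fixed-step RK4, default dt = 0.01 ms, with a documented
stability contract of dt ≤ 0.05 ms (larger steps are accepted but recorded
as a provenance warning). Fourth-order convergence is verified on an
action-potential trajectory by step halving. Voltage clamp sets E to the
command value and integrates only the gates; gate trajectories then match
the closed-form relaxation ξ(t) = ξ∞ + (ξ₀−ξ∞)e^{−t/τ} to better than
10⁻⁵, which serves as the integrator's analytic oracle. Strongly
hyperpolarizing stimuli (more negative than about −10 µA/cm² sustained)
push the membrane far below rest where β_m grows exponentially and the
gate equations become stiff for a fixed-step explicit method; this regime
is outside the integrator's contract and the randomized-protocol tests
sample stimuli in the −10…+30 µA/cm² band.

## Synthetic clamp data

The generator emulates step-protocol voltage-clamp experiments: from a
holding potential the command jumps to a test level, and conductance
g(t) = ḡ·act(t)^p·inact(t)^q is recorded with gates evolved by the exact
closed-form clamp solution — not the ODE integrator — so the fixtures are
oracle-exact and any fitting error is attributable to the fitter. Defaults
(hold −65 mV, 20 ms traces, 0.05 ms sampling, steps spanning −40…+20 mV)
cover at least five relaxation time constants of every gate involved.
Noise is additive i.i.d. Gaussian on conductance with an explicit integer
seed recorded in the output; noiseless datasets are bit-reproducible.
Exponents may be non-integer so that symmetry-broken data can be produced
for the fractional-exponent diagnostic.

What the generator does *not* emulate: leak subtraction artifacts, series
resistance, capacitive transients, channel noise, rundown. Passing the
round-trip tests therefore shows generator/fitter consistency under the
stated model, not robustness to real-recording artifacts.

## Exponent inference

At a known clamp voltage the gate time courses follow from the canonical
rate functions, so for each integer candidate (p, q) only ḡ is free and is
fitted by one-parameter linear least squares on g against act^p·inact^q;
the candidate minimizing the summed squared residual wins, with ties
broken toward the smallest exponent. When the SSE profile is flat
(max/min < 1.05 across candidates, or across q at the best p), the result
is flagged "weak identifiability" — this fires, for example, when traces
are truncated before inactivation develops.

The symmetry-breaking diagnostic refits with a real-valued activation
exponent (bounded scalar minimization on p ∈ [0.5, 8], the inactivation
exponent held at its integer estimate). The integer fit is flagged as
elevated when its SSE exceeds 1.1× the fractional optimum plus an absolute
floor of 10⁻⁹ of the total signal energy; the floor keeps
numerically-perfect integer fits (both SSEs at rounding level) from being
flagged. On data generated with exponent 2.5 the fractional optimum lands
at 2.5 and the flag raises; on true-integer data it stays quiet.

## Lie structure

Vector fields carry per-coordinate coefficient functions, optionally
backed by sympy expressions; brackets are computed two ways — central
differences (step 10⁻⁵) for any field, exact symbolic differentiation for
sympy-backed fields — and cross-checked (antisymmetry to 10⁻⁸, Jacobi
identity to 10⁻⁵ on random polynomial fields).

The bare coordinate generators X_c = ∂/∂θ, X_g = g∂/∂g, X_t = ∂/∂t commute
pairwise, so the commutation table with nonzero γ₁, γ₂ requires a coupled
realization. The package provides

    X_t ↦ ∂/∂t + g(γ₂·ln g + γ₁·θ)·∂/∂g      (g > 0),

which satisfies [X_c,X_g] = 0, [X_c,X_t] = γ₁X_g and [X_g,X_t] = γ₂X_g
exactly (symbolic proof in the test suite). The ln g term is essential: any
deformation whose g-component is homogeneous of degree one in g — e.g.
γ₂·t·g∂/∂g — commutes with X_g and cannot produce a nonzero γ₂. When
nonzero structure constants are requested without a realization, the
verifier reports "unrealized" rather than failing, making the gap explicit
instead of asserting a particular realization as canonical.

γ₂ is computed as 1/E₀ where E₀ is the arithmetic mean of the e-fold
voltage scales of the exponential factors in the six rates
({10, 18, 20, 10, 10, 80} mV → E₀ = 24.67 mV, γ₂ = 0.0405 mV⁻¹). The mean
is the simplest declared aggregate and lands inside the empirical
20–30 mV window; alternatives (median, geometric mean) would also, but
only one choice is offered to keep the quantity reproducible. γ₁ has no
independent normalization and is reported at the same magnitude with an
explicit approximate flag, excluded from pass/fail gates. The thermal
voltage k_BT/e (26.7 mV at 310 K, CODATA constants) is reported alongside
as the physical anchor of the scale, and a Q₁₀ factor (default 3 per
10 °C) rescales γ₂ across temperatures.

Not all rates are pure exponentials: the linear-over-expm1 and logistic
forms are composite, so the exponential-form audit reports a fitted e-fold
scale and an R² verdict (pure iff R² > 1−10⁻¹⁰ for ln rate vs E) instead
of forcing an exponential reading; composite forms are flagged with their
local log-slope.

## Audit tolerances

Invariance has no intrinsic numeric threshold, so all audit tolerances are
declared package decisions, chosen tight because fixed-step deterministic
integration makes them honest: gate excursion ≤ 10⁻⁹; time-shifted
re-integration sup-norm ≤ 10⁻¹⁰ (the shifted run performs identical
arithmetic, so the observed metric is 0); conductance-ratio invariance
exact at the bit level (λ·ḡ_Na/λ·ḡ_K rounds the same real quotient as
ḡ_Na/ḡ_K); current scaling by λ to 10⁻¹² *relative to the current
magnitude scale* Σ|terms| — the net current is a cancellation-small
difference near rest, so normalizing by it would be ill-conditioned, and
per-term floating-point rounding prevents bit-exactness of λ·I_ion.

## Problem sizes

Default test and reproduction runs use 20 ms clamp traces at 0.05 ms
sampling (401 points/trace, 3–4 traces per dataset), 30–50 ms
current-clamp simulations at dt = 0.01 ms, a 141-point voltage grid for
function-level identities, and 20 replicates for the noisy-diagnostic
checks; these sizes resolve every relaxation timescale in the model while
keeping the whole suite interactive.

## Known limitations

- Fixed-step explicit integration only; no adaptive or stiff solvers, no
  spatial (cable) extension, no stochastic channel gating.
- The exponent fitter assumes the clamp voltage and the rate functions are
  known exactly; it does not estimate kinetics jointly with exponents, and
  multi-state Markov schemes are out of scope.
- The winding-number bookkeeping implements the net count p − q only; no
  representation label beyond that arithmetic is assigned.
- γ₁ is order-of-magnitude; treating it as a measured constant would
  overstate what the e-fold-scale aggregation supports.
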