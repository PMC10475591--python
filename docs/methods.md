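# Methods

## Model

The left ventricle is idealised as a thick-walled sphere of
incompressible, isotropic myocardium undergoing centrosymmetric
deformation. Lengths are normalised by the endocardial radius of the
stress-free reference configuration and volumes by the reference cavity
volume `V₀`, so the geometry is described by a single dimensionless
number, the normalised wall thickness `Δ = (R_epi − R_endo)/R_endo`.
Incompressibility (`det F = 1`) plus symmetry reduce the deformation at
wall depth `δ` and cavity volume ratio `V̂` to the diagonal stretches

    λρ = (1+δ)²/r̂²,  λθ = λφ = r̂/(1+δ),  r̂³ = (1+δ)³ + V̂ − 1,

with `λρλθ² = 1` identically and first invariant `I₁ = λρ² + 2/λρ ≥ 3`.
The cavity pressure follows from the work balance `P = dW/dV` with zero
external pressure:

    P(V̂) = −2 ∫₀^Δ (λρ²/r̂)(dΨ/dλρ) dδ.

Two energy contributions are supported. The passive wall follows the
isotropic exponential law `Ψ_p = a/(2b)(e^{b(I₁−3)} − 1)`; substituting
its derivative gives the end-diastolic relationship
`P_ED = 2a ∫ (1−λρ³)/r̂ · e^{b(I₁−3)} dδ`, which vanishes identically at
`V̂ = 1` and is exactly proportional to `a`. Active contraction is an
additive stress acting in the tangential plane: with structure tensor
`H_a = I − e_r⊗e_r` the sarcomere stretch is `λ = √(C:H_a) = √(2/λρ)`
and `Ψ_a = T_a(λ²/2 − λ₀λ)`, giving
`P_a = 2T_a ∫ (1 − λ₀√(λρ/2))/r̂ dδ > 0` (since `λ₀ < √2`) and the
end-systolic relationship `P_ES = P_ED + P_a`. At `V̂ = 1` the active
integral is elementary: `P_a = 2T_a(1 − λ₀/√2)ln(1+Δ)`, used throughout
as an analytic anchor.

Assumptions worth keeping in mind: spherical geometry, no residual
stress, no fibre architecture (isotropy), additive rather than
multiplicative active coupling, and quasi-static states — the model
describes the ED and ES loci, not the trajectory between them.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| `a` | passive stiffness scale | kPa | 1.15 (healthy human fit) |
| `b` | exponential stiffening | – | 3.82 (healthy human fit) |
| `delta_wall` (`Δ`) | wall thickness / endocardial radius | – | 0.27 (healthy human) |
| `t_a` (`T_a`) | maximum active stress | kPa | 76.9 (healthy human ES fit) |
| `lambda0` (`λ₀`) | reference sarcomere stretch `l₀/l_r` | – | 1.58/1.85 ≈ 0.85405 |
| `v0` (`V₀`) | stress-free cavity volume | mL | optional, only for de-normalising |

`λ₀` is stored at full precision; the literature usually rounds it to
0.85 and the examples and tests use that rounded value where they quote
published parameter sets. `b = 0` reduces the passive law to an
incompressible neo-Hookean solid (a rubber balloon); the energy switches
to a second-order series in `b` below `1e-8` so the map `b ↦ Ψ_p` is
continuous there.

All internal pressures are kPa; mmHg appears only at the I/O surface
with 1 kPa = 7.500617 mmHg.

## Numerics

*Quadrature.* The transmural integrand is smooth in `δ`, so the default
scheme is 64-point Gauss–Legendre on `[0, Δ]` — deterministic, fast, and
accurate to ~1e-12 relative against a 10⁶-panel composite-trapezoid
oracle (checked in the tests and recomputed by the acceptance script).
An adaptive scheme (scipy `quad`, rel. tol. 1e-10) is available as a
cross-check.

*Curve inversion.* `volume_at_pressure` brackets and solves
`P(V̂) = p` by Brent's method to 1e-10 in `V̂`, widening the default
bracket [0.3, 10] automatically up to [0.05, 100]. The passive branch is
monotone and solved directly. The end-systolic branch can be non-monotone
(for weak passive stiffness and large `T_a` the curve peaks and falls,
the balloon-type instability); there the bracket is scanned for all sign
changes, the largest root is returned — the end-systolic state sits on
the ascending limb at physiological parameters, and when it does not the
descending-limb root is the mechanically consistent choice — and a
warning reports multiplicity.

*Fitting.* The objective is the mean squared pressure error in mmHg²
(the axis convention of published EDPVR comparisons; achieved MSE values
of order 1–3 are only plausible on that scale). Free amplitude
parameters — `a`, `T_a`, and the empirical amplitudes `A`, `A_n` — enter
every model curve linearly, so they are profiled out by linear least
squares at each objective evaluation (variable projection) and clipped
to their bounds; the remaining nonlinear parameters are searched by
bounded Nelder–Mead from 8 seeded Latin-hypercube starts. This makes
`T_a`-only ESPVR fits a single exact solve and removes a spurious
boundary attractor at `b → 0` that a plain simplex over `(a, b)` can
fall into. Default bounds: `a ∈ [0.01, 50]` kPa, `b ∈ [1e-6, 30]`,
`Δ ∈ [0.05, 1]`, `T_a ∈ [0, 500]` kPa. `Δ` is excluded from the default
free sets — it is weakly coupled to the other parameters (see the
Hessian below) and better measured than fitted — but remains fittable on
request. Fits are deterministic given data and seed.

*Physics EDPVR on the normalised volume axis.* For comparison with the
empirical models the shell EDPVR is reparameterised onto the Klotz axis
`V_n = (V̂−1)/(V̂₃₀−1)` by solving `P_ED(V̂₃₀) = 30 mmHg`, so all three
curves share the anchors (0, 0) and (1, 30 mmHg). On this axis the
amplitude `a` also moves the axis anchor, so no linear profiling applies
and the fit runs the full simplex.

*Sensitivity.* One-at-a-time ratios
`S = [(P(θ(1+f)) − P(θ))/P(θ)]/f` are computed by direct perturbation at
an operating point (undefined where the base pressure vanishes, i.e. at
`V̂ = 1` on the passive branch). Exact structure provides free checks:
`S(a) = 1` on the passive branch for any `f`, and on the end-systolic
branch `S(T_a) = 1 − P_p/P_ES` exactly — slightly above 1 below the
reference volume, where the passive pressure is negative. The Hessian of
`P` with respect to `(a, b, Δ, T_a)` uses central differences with a
relative step of 1e-4 (balancing truncation against cancellation for
kPa-scale outputs); `∂²P/∂a²` and `∂²P/∂a∂T_a` vanish identically by
linearity and additivity, which the finite differences reproduce to
rounding.

## Synthetic data

The human ex vivo EDPVR compilation (~80 hearts, pressures up to
30 mmHg on the Klotz-normalised axis) and afterload-sweep ESPVR
measurements that such models are validated against are not publicly
deposited, so the generator emulates their shape: volumes uniform (or
gridded) over the stated range, truth pressures from a chosen model,
plus i.i.d. zero-mean Gaussian noise in mmHg. Defaults are n = 80,
`V_n ∈ [0, 1]` (hence 0–30 mmHg), and noise sd 0.5 mmHg — a realistic
catheter-scale measurement error, small against the 30 mmHg span.
Afterload sweeps place 12 end-systolic points on `V̂ ∈ [0.6, 1.4]`.

What it does not emulate: inter-heart variability (one truth curve, not
a population), volume measurement error, heteroscedastic or correlated
noise. Passing recovery tests therefore demonstrates estimator
correctness under the stated noise model, not robustness to real
population scatter.

Problem sizes used by the test suite and the acceptance script — 50
points for noisy EDPVR recovery, 12 for afterload sweeps, 20-point
volume grids and 10⁶-panel oracles for quadrature checks, 100 random
parameter sets for the reference-volume anchor — are chosen as the
smallest sizes at which the checked statistics are stable.

## Known limitations

- The `(a, b)` pair is sloppy: stiffness scale and stiffening exponent
  trade off along a curve of near-equivalent fits, so parameter-level
  recovery is not asserted — curve-level recovery (RMS pressure error)
  is the meaningful criterion.
- Published least-squares parameter values for the ex vivo datasets
  cannot be re-derived here (data not deposited), and the published
  optimizer settings are unknown; the package promises recovery on its
  own synthetic data instead.
- With extreme contractility and weak passive stiffness the ESPVR is
  non-monotone; loop metrics near that regime depend on the largest-root
  convention documented above.
- The spherical, isotropic idealisation underestimates the geometric
  detail of a real ventricle; the model targets whole-chamber PV
  behaviour, not local wall stress.
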