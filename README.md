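# pvshell

Physics-based pressure–volume relationships of the left ventricle.

Clinicians and modellers summarise ventricular function with two curves:
the end-diastolic pressure–volume relationship (EDPVR), which encodes
passive chamber stiffness, and the end-systolic pressure–volume
relationship (ESPVR), which encodes contractility. Empirical fits — the
exponential EDPVR `P = A(e^{B·V_n} − 1)` and the Klotz power law
`P = A_n·V_n^{B_n}` — describe these curves but their parameters carry no
physical meaning. `pvshell` implements a mechanistic alternative: the
ventricle as a thick-walled incompressible sphere whose wall follows an
isotropic exponential strain-energy law, with contraction modelled as an
additive active stress in the tangential plane.

## The model

Normalising lengths by the endocardial radius and volumes by the
stress-free cavity volume `V₀`, incompressibility fixes the kinematics at
wall depth `δ ∈ [0, Δ]` for any cavity volume ratio `V̂ = V/V₀`:

    r̂³ = (1+δ)³ + V̂ − 1,   λρ = (1+δ)²/r̂²,   λθ = λφ = r̂/(1+δ),
    I₁ = λρ² + 2/λρ

The work balance `P = dW/dV` for a shell loaded by cavity pressure alone
gives the pressure as a one-dimensional integral across the wall,

    P(V̂) = −2 ∫₀^Δ (λρ²/r̂) · dΨ/dλρ dδ

With the passive law `Ψ_p = a/(2b)·(e^{b(I₁−3)} − 1)` this yields the
EDPVR

    P_ED = 2a ∫₀^Δ (1 − λρ³)/r̂ · e^{b(I₁−3)} dδ

and with the active energy `Ψ_a = T_a(λ²/2 − λ₀λ)`, where
`λ = √(2/λρ)` is the sarcomere stretch and `λ₀ = l₀/l_r ≈ 0.854` its
reference value, the active contribution

    P_a = 2T_a ∫₀^Δ (1 − λ₀√(λρ/2))/r̂ dδ,     P_ES = P_ED + P_a

Every parameter is physical: `a` (kPa) and `b` set myocardial stiffness,
`Δ` is the wall thickness relative to the endocardial radius (~0.27 for a
healthy human LV), `T_a` (kPa) is the maximum active stress. `P_ED`
vanishes at `V̂ = 1` and is exactly proportional to `a`; `P_a` is exactly
proportional to `T_a`.

## Worked example

```python
import pvshell as ps

model = ps.ShellModel.from_parameters(a=1.15, b=3.82, delta_wall=0.27,
                                      t_a=76.9, lambda0=0.85)

# active pressure generated at the stress-free volume
p_ref = ps.active_pressure(1.0, model)               # 14.666 kPa
print(ps.kpa_to_mmhg(p_ref))                         # 110.0 mmHg

# PV-loop metrics for a 10 mmHg filling / 110 mmHg ejection pressure
lm = ps.loop_metrics(ps.mmhg_to_kpa(10), ps.mmhg_to_kpa(110), model)
print(lm.edv_hat, lm.esv_hat, lm.ejection_fraction)
# 2.0103 0.9998 0.5027
```

A healthy-human parameter set thus produces ~110 mmHg of purely active
pressure at the reference volume and an ejection fraction of 0.50 —
both in the normal physiological range.

Fitting uses a model/results interface. With synthetic noisy passive
data (the ex vivo compilations these curves are usually fitted to are
not publicly deposited, so the package generates its own):

```python
truth = ps.ShellModel.from_parameters(a=1.15, b=3.82, delta_wall=0.27)
v30 = ps.volume_at_pressure(ps.mmhg_to_kpa(30), truth)
data = ps.generate_synthetic(ps.SyntheticSpec(
    truth=truth, n=50, volume_axis="v_hat", volume_range=(1.001, v30),
    noise_sd=0.5, seed=11))
res = ps.PhysicsEDPVRModel(data, delta=0.27).fit(free=["a", "b"], seed=0)
print(res.summary())
```

```
PhysicsEDPVRModel fit (physics_ed)
======================================================
observations: 50   axis: v_hat   unit: mmHg
MSE: 0.231385 mmHg^2   RMS: 0.481025 mmHg
converged: True   evaluations: 692   best start: 7
------------------------------------------------------
parameter            value  status
a                  1.17621  free
b                  3.78923  free
delta                 0.27  fixed
======================================================
```

The recovered curve deviates from the generating curve by under
0.1 mmHg RMS even though `a` and `b` individually trade off against each
other. A command-line interface (`pvshell curve | fit | sensitivity |
loop | simulate`) wraps the same functionality.

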