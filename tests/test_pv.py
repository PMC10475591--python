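"""Pressure-volume curves from the work-balance integral."""

import math

import numpy as np
import pytest

from conftest import active_reference_closed_form, neo_hookean_pressure, trapezoid_pressure
from pvshell import (
    ConfigurationError,
    DomainError,
    PhysiologyError,
    QuadratureSpec,
    ShellModel,
    active_dpsi_dlambda,
    active_pressure,
    active_pressure_at_reference,
    curve,
    edpvr_pressure,
    espvr_pressure,
    kpa_to_mmhg,
    loop_metrics,
    passive_dpsi_dlambda,
    pressure_from_energy,
    volume_at_pressure,
)


class TestPressureFromEnergy:
    def test_zero_derivative_gives_zero_pressure(self, passive_model):
        for v in (0.5, 1.0, 2.5):
            p = pressure_from_energy(lambda lam: np.zeros_like(lam), v, passive_model.geometry)
            assert p == 0.0

    def test_reproduces_passive_pressure(self, passive_model):
        """Plugging the passive energy derivative into the generic integral
        reproduces the closed EDPVR integrand transformation."""
        law = passive_model.passive
        for v in (0.6, 1.3, 2.0, 3.0):
            generic = pressure_from_energy(
                lambda lam: passive_dpsi_dlambda(lam, law), v, passive_model.geometry
            )
            assert generic == pytest.approx(edpvr_pressure(v, passive_model), rel=1e-10, abs=1e-14)

    def test_reproduces_active_pressure(self, base_model):
        law = base_model.active
        for v in (0.6, 1.0, 1.8):
            generic = pressure_from_energy(
                lambda lam: active_dpsi_dlambda(lam, law), v, base_model.geometry
            )
            assert generic == pytest.approx(active_pressure(v, base_model), rel=1e-10)


class TestEDPVR:
    def test_zero_at_reference_volume(self):
        for a, b, d in [(1.15, 3.82, 0.27), (2.10, 8.71, 0.27), (0.5, 0.0, 0.8)]:
            m = ShellModel.from_parameters(a=a, b=b, delta_wall=d)
            assert edpvr_pressure(1.0, m) == 0.0

    def test_sign_convention(self, passive_model):
        assert edpvr_pressure(1.5, passive_model) > 0
        assert edpvr_pressure(0.7, passive_model) < 0

    def test_against_dense_trapezoid_oracle(self, passive_model):
        got = edpvr_pressure(2.0, passive_model)
        want = trapezoid_pressure(2.0, a=1.15, b=3.82, delta_wall=0.27)
        assert got == pytest.approx(want, rel=1e-6)

    def test_neo_hookean_reduction(self):
        """With b = 0 the shell is a neo-Hookean rubber balloon; the default
        quadrature must match an independent dense evaluation."""
        m = ShellModel.from_parameters(a=1.15, b=0.0, delta_wall=0.27)
        for v in (0.5, 1.5, 2.0, 4.0):
            assert edpvr_pressure(v, m) == pytest.approx(
                neo_hookean_pressure(v, a=1.15, delta_wall=0.27), rel=1e-8
            )

    def test_exact_linearity_in_stiffness(self, passive_model):
        m2 = ShellModel.from_parameters(a=2 * 1.15, b=3.82, delta_wall=0.27)
        for v in (0.7, 1.5, 2.4):
            p1, p2 = edpvr_pressure(v, passive_model), edpvr_pressure(v, m2)
            assert p2 == pytest.approx(2.0 * p1, rel=1e-12)

    def test_thin_wall_limit(self):
        """For a very thin wall the integral approaches thickness times the
        endocardial integrand: P ~ 2*Delta*(1-lam^3)/r * exp(b*(I1-3)) at delta=0."""
        d = 1e-4
        m = ShellModel.from_parameters(a=1.15, b=3.82, delta_wall=d)
        v = 1.8
        r = (1.0 + v - 1.0) ** (1 / 3)
        lam = 1.0 / r**2
        i1 = lam**2 + 2 / lam
        approx = 2.0 * d * 1.15 * (1.0 - lam**3) / r * math.exp(3.82 * (i1 - 3.0))
        assert edpvr_pressure(v, m) == pytest.approx(approx, rel=1e-3)

    def test_monotone_thickness_effect(self):
        """Passive pressure at doubled volume strictly increases with wall thickness."""
        pressures = [
            edpvr_pressure(2.0, ShellModel.from_parameters(a=1.15, b=3.82, delta_wall=d))
            for d in (0.1, 0.2, 0.27, 0.4, 0.5)
        ]
        assert all(p2 > p1 for p1, p2 in zip(pressures, pressures[1:]))

    def test_adaptive_scheme_agrees_with_gauss(self, passive_model):
        adaptive = QuadratureSpec(scheme="adaptive", rel_tol=1e-10)
        for v in (0.6, 1.7, 2.9):
            assert edpvr_pressure(v, passive_model, adaptive) == pytest.approx(
                edpvr_pressure(v, passive_model), rel=1e-9
            )


class TestActivePressure:
    def test_zero_without_active_stress(self):
        m = ShellModel.from_parameters(a=1.15, b=3.82, delta_wall=0.27, t_a=0.0)
        assert active_pressure(1.3, m) == 0.0

    def test_closed_form_at_reference_volume(self, base_model):
        got = active_pressure(1.0, base_model)
        want = active_reference_closed_form(76.9, 0.85, 0.27)
        assert got == pytest.approx(want, rel=1e-12)
        # ~14.67 kPa ~ 110 mmHg: a systolic pressure from contraction alone
        assert got == pytest.approx(14.67, abs=0.01)
        assert kpa_to_mmhg(got) == pytest.approx(110.0, abs=0.5)

    def test_exact_linearity_in_active_stress(self):
        m1 = ShellModel.from_parameters(a=1.15, b=3.82, delta_wall=0.27, t_a=40.0, lambda0=0.85)
        m2 = ShellModel.from_parameters(a=1.15, b=3.82, delta_wall=0.27, t_a=80.0, lambda0=0.85)
        for v in (0.6, 1.0, 1.6):
            assert active_pressure(v, m2) == pytest.approx(2.0 * active_pressure(v, m1), rel=1e-12)

    def test_strictly_positive(self, base_model):
        for v in (0.3, 0.8, 1.0, 2.0, 5.0):
            assert active_pressure(v, base_model) > 0

    def test_requires_active_law(self, passive_model):
        with pytest.raises(ConfigurationError):
            active_pressure(1.2, passive_model)


class TestESPVR:
    def test_additive_decomposition(self, base_model):
        for v in (0.6, 1.0, 1.4):
            assert espvr_pressure(v, base_model) == pytest.approx(
                edpvr_pressure(v, base_model) + active_pressure(v, base_model), rel=1e-14
            )

    def test_reduces_to_edpvr_without_contraction(self, passive_model):
        for v in (0.8, 1.5):
            assert espvr_pressure(v, passive_model) == edpvr_pressure(v, passive_model)

    def test_equals_active_closed_form_at_reference(self, base_model):
        assert espvr_pressure(1.0, base_model) == pytest.approx(
            active_reference_closed_form(76.9, 0.85, 0.27), rel=1e-12
        )

    def test_against_dense_trapezoid_oracle(self, base_model):
        for v in (0.6, 1.0, 1.5):
            want = trapezoid_pressure(v, a=1.15, b=3.82, delta_wall=0.27, t_a=76.9, lambda0=0.85)
            assert espvr_pressure(v, base_model) == pytest.approx(want, rel=1e-6)

    def test_decomposition_signs_below_reference(self, base_model):
        """At small end-systolic volumes the passive part resists contraction
        (negative pressure), the active part drives it, the total sits between."""
        passive = edpvr_pressure(0.6, base_model)
        active = active_pressure(0.6, base_model)
        total = espvr_pressure(0.6, base_model)
        assert passive < 0 < active
        assert passive < total < active

    def test_increasing_over_physiological_volumes(self, base_model):
        grid = np.linspace(0.5, 1.5, 21)
        p = np.asarray(espvr_pressure(grid, base_model))
        assert np.all(np.diff(p) > 0)


class TestCurve:
    def test_reference_anchor_on_grid(self, passive_model):
        c = curve([1.0], passive_model)
        assert c.pressure[0] == 0.0

    def test_split_components_sum_to_total(self, base_model):
        grid = np.linspace(0.6, 2.0, 15)
        c = curve(grid, base_model, branch="espvr", split=True)
        assert np.allclose(c.pressure, c.passive + c.active, rtol=1e-12, atol=1e-14)

    def test_edpvr_strictly_increasing(self, passive_model):
        c = curve(np.linspace(1.0, 3.0, 30), passive_model)
        assert np.all(np.diff(c.pressure) > 0)

    def test_grid_validation(self, passive_model):
        with pytest.raises(ConfigurationError):
            curve([1.0, 0.9], passive_model)
        with pytest.raises(DomainError):
            curve([-1.0, 2.0], passive_model)

    def test_dataframe_export_converts_units(self, base_model):
        c = curve(np.linspace(1.0, 2.0, 5), base_model, branch="espvr", split=True)
        df = c.to_dataframe(pressure_unit="mmHg")
        assert list(df.columns) == ["v_hat", "pressure", "pressure_passive", "pressure_active"]
        assert df["pressure"].iloc[0] == pytest.approx(kpa_to_mmhg(c.pressure[0]))


class TestVolumeAtPressure:
    def test_zero_pressure_returns_reference_volume(self, passive_model):
        assert volume_at_pressure(0.0, passive_model) == pytest.approx(1.0, abs=1e-9)

    def test_edpvr_round_trip(self, passive_model):
        p = edpvr_pressure(2.0, passive_model)
        assert volume_at_pressure(p, passive_model) == pytest.approx(2.0, abs=1e-8)
        assert edpvr_pressure(volume_at_pressure(p, passive_model), passive_model) == pytest.approx(
            p, abs=1e-8
        )

    def test_espvr_round_trip(self, base_model):
        p = espvr_pressure(0.8, base_model)
        assert volume_at_pressure(p, base_model, "espvr") == pytest.approx(0.8, abs=1e-8)

    def test_unreachable_pressure_raises(self):
        """The neo-Hookean balloon's pressure is bounded, so a huge target
        pressure cannot be bracketed even after automatic widening."""
        from pvshell import BracketingError

        m = ShellModel.from_parameters(a=1.15, b=0.0, delta_wall=0.27)
        with pytest.raises(BracketingError):
            volume_at_pressure(10.0, m, bracket=(0.5, 2.0))

    def test_non_monotone_espvr_returns_largest_root_with_warning(self):
        """With weak passive stiffness and huge contractility the ESPVR peaks
        and then falls (balloon-type instability); for a target pressure with
        several crossings the largest root is returned, with a warning."""
        m = ShellModel.from_parameters(a=0.05, b=0.1, delta_wall=0.27, t_a=400.0, lambda0=0.85)
        grid = np.linspace(0.05, 3.0, 300)
        p = np.asarray(espvr_pressure(grid, m))
        peak_v = grid[np.argmax(p)]
        target = float(espvr_pressure(1.6, m))  # between P(end) and the peak
        crossings = np.sum(np.diff(np.sign(p - target)) != 0)
        assert crossings >= 2  # the chosen target really is multi-rooted
        with pytest.warns(UserWarning, match="non-monotone"):
            v = volume_at_pressure(target, m, "espvr", bracket=(0.05, 3.0))
        assert v > peak_v  # descending limb, i.e. the largest root
        assert float(espvr_pressure(v, m)) == pytest.approx(target, abs=1e-8)


class TestLoopMetrics:
    def test_esv_at_reference_when_esp_is_closed_form(self, base_model):
        esp = active_reference_closed_form(76.9, 0.85, 0.27)
        edp = edpvr_pressure(2.0, base_model)
        lm = loop_metrics(edp, esp, base_model)
        assert lm.esv_hat == pytest.approx(1.0, abs=1e-8)
        assert lm.edv_hat == pytest.approx(2.0, abs=1e-8)
        assert lm.sv_hat == pytest.approx(1.0, abs=1e-8)
        assert lm.ejection_fraction == pytest.approx(0.5, abs=1e-8)

    def test_ef_nondecreasing_in_contractility(self):
        edp, esp = 1.0, 12.0  # kPa
        efs = []
        for t_a in (70.0, 90.0, 110.0):
            m = ShellModel.from_parameters(a=1.15, b=3.82, delta_wall=0.27, t_a=t_a, lambda0=0.85)
            efs.append(loop_metrics(edp, esp, m).ejection_fraction)
        assert efs[0] <= efs[1] <= efs[2]

    def test_ef_nondecreasing_in_thickness(self):
        """A thicker contractile wall (e.g. an engineered-tissue patch) shifts
        the ESPVR up-left and raises the ejection fraction at fixed pressures."""
        edp, esp = 1.0, 12.0
        efs = []
        for d in (0.22, 0.27, 0.35):
            m = ShellModel.from_parameters(a=1.15, b=3.82, delta_wall=d, t_a=76.9, lambda0=0.85)
            efs.append(loop_metrics(edp, esp, m).ejection_fraction)
        assert efs[0] <= efs[1] <= efs[2]

    def test_physiological_inconsistency_raises(self, base_model):
        with pytest.raises(PhysiologyError):
            # tiny filling pressure with a huge ejection pressure: ESV >= EDV
            loop_metrics(0.001, 17.0, base_model)

    def test_reference_pressure_example(self, base_model):
        """EDP 10 mmHg / ESP 110 mmHg at the healthy-human parameters gives a
        physiological ejection fraction (~0.50)."""
        from pvshell import mmhg_to_kpa

        lm = loop_metrics(mmhg_to_kpa(10.0), mmhg_to_kpa(110.0), base_model)
        assert 0.45 < lm.ejection_fraction < 0.60


def test_quadrature_spec_validation():
    with pytest.raises(ConfigurationError):
        QuadratureSpec(n_points=4)
    with pytest.raises(ConfigurationError):
        QuadratureSpec(rel_tol=0.1)
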