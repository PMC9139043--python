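"""Two-region C-V model: widths, plateaus, curve assembly, readouts."""

import numpy as np
import pytest
from scipy.optimize import brentq

from eiscap import (
    NanoparticleLayer,
    capacitance_change_at_voltage,
    ceq_accumulation,
    ceq_depletion,
    ceq_inversion,
    cv_shift_at_capacitance,
    depletion_width,
    flat_band_voltages,
    simulate_cv,
    solve_concap_voltage,
)
from eiscap.cv_model import ceq_depletion_series
from conftest import C_WORK, DELTA_PHI


def layer_with(n, dphi=DELTA_PHI):
    return NanoparticleLayer(coverage=n, delta_phi=dphi)


class TestDepletionWidth:
    def test_zero_at_flat_band(self, device):
        assert depletion_width(0.0, device) == 0.0

    def test_40mV_canonical(self, device):
        assert depletion_width(0.040, device) == pytest.approx(6.76e-8, rel=1e-3)

    def test_monotone_increasing(self, device):
        v = np.linspace(0, 2.0, 200)
        w = depletion_width(v, device)
        assert (np.diff(w) > 0).all()

    def test_rejects_negative_voltage(self, device):
        with pytest.raises(ValueError):
            depletion_width(-0.01, device)

    def test_agrees_with_charge_balance_oracle(self, device):
        # independent oracle: the applied voltage divides between the
        # insulator (q N_a w / C_i0) and the depleted semiconductor
        # (q N_a w^2 / (2 eps_s)); invert that balance numerically for w
        q = device.constants.q
        n_a = device.semiconductor.acceptor_density
        eps_s = device.eps_s
        c_i0 = device.c_i0

        def balance(w, v_eff):
            return q * n_a * w / c_i0 + q * n_a * w**2 / (2 * eps_s) - v_eff

        for v_eff in [0.001, 0.01, 0.04, 0.1, 0.5, 1.5]:
            w_oracle = brentq(balance, 0.0, 1e-5, args=(v_eff,), xtol=1e-14)
            assert depletion_width(v_eff, device) == pytest.approx(
                w_oracle, abs=0.1e-9
            )


class TestFlatBandVoltages:
    def test_canonical_values(self, device):
        v_fb, v_fb_np = flat_band_voltages(device, layer_with(0.25))
        assert v_fb == pytest.approx(0.010, abs=1e-12)
        assert v_fb_np == pytest.approx(-0.030, abs=1e-12)

    def test_no_particles_no_difference(self, device):
        v_fb, v_fb_np = flat_band_voltages(device, layer_with(0.25, dphi=0.0))
        assert v_fb == v_fb_np

    def test_negative_charge_flips_the_shift(self, device):
        layer = NanoparticleLayer(coverage=0.25, delta_phi=0.040, charge_sign=-1)
        v_fb, v_fb_np = flat_band_voltages(device, layer)
        assert v_fb_np == pytest.approx(v_fb + 0.040, abs=1e-12)


class TestPlateaus:
    def test_accumulation_plateau(self, device):
        assert ceq_accumulation(device) == pytest.approx(4.933e-8, rel=1e-3)

    def test_accumulation_is_coverage_independent(self, device):
        v = -0.2  # both sub-regions accumulated
        c0 = ceq_depletion(v, device, layer_with(0.0))
        c9 = ceq_depletion(v, device, layer_with(0.9))
        assert c0 == pytest.approx(ceq_accumulation(device), rel=1e-12)
        assert c9 == pytest.approx(c0, rel=1e-12)

    def test_accumulation_linear_in_area(self, device):
        import dataclasses

        doubled = dataclasses.replace(device, area=2 * device.area)
        assert ceq_accumulation(doubled) == pytest.approx(
            2 * ceq_accumulation(device), rel=1e-12
        )

    def test_inversion_plateau(self, device):
        assert ceq_inversion(device) == pytest.approx(9.55e-9, rel=1e-3)

    def test_inversion_identity_with_max_width(self, device):
        assert ceq_inversion(device) == pytest.approx(
            device.eps_s * device.area / device.w_max, rel=1e-14
        )


class TestDepletionCapacitance:
    def test_bare_device_at_50mV(self, device):
        assert ceq_depletion(0.050, device, layer_with(0.0)) == pytest.approx(
            C_WORK, rel=1e-2
        )

    def test_equals_accumulation_value_at_flat_band(self, device):
        v_fb, _ = flat_band_voltages(device, layer_with(0.0))
        assert ceq_depletion(v_fb, device, layer_with(0.0)) == pytest.approx(
            ceq_accumulation(device), rel=1e-12
        )

    def test_partial_coverage_lies_between_limits(self, device):
        for v in [0.05, 0.2, 0.5]:
            c_bare = ceq_depletion(v, device, layer_with(0.0))
            c_full = ceq_depletion(v, device, layer_with(1.0))
            c_half = ceq_depletion(v, device, layer_with(0.5))
            assert c_full < c_half < c_bare

    def test_closed_form_matches_series_composition(self, device):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.uniform(0.05, 0.95)
            dphi = rng.uniform(-0.1, 0.1)
            layer = layer_with(n, dphi)
            v = rng.uniform(0.12, 0.45)  # both sub-regions depleted, not saturated
            closed = ceq_depletion(v, device, layer)
            series = ceq_depletion_series(v, device, layer)
            assert series == pytest.approx(closed, rel=1e-12)


class TestSimulateCV:
    def test_bare_curve_plateaus_and_bounds(self, device):
        curve = simulate_cv(-0.5, 1.5, 2001, device, layer_with(0.0))
        c = curve.capacitances
        assert c[0] == pytest.approx(ceq_accumulation(device), rel=1e-12)
        assert c[-1] == pytest.approx(ceq_inversion(device), rel=1e-9)
        assert (np.diff(c) <= 1e-18).all()  # non-increasing
        assert (c >= ceq_inversion(device) - 1e-15).all()
        assert (c <= ceq_accumulation(device) + 1e-15).all()

    def test_curve_is_continuous_on_fine_grid(self, device):
        fine = simulate_cv(-0.1, 1.2, 13001, device, layer_with(0.5))
        coarse = simulate_cv(-0.1, 1.2, 1301, device, layer_with(0.5))
        # steps shrink with the grid spacing (no fixed-size discontinuity)
        fine_step = np.abs(np.diff(fine.capacitances)).max()
        coarse_step = np.abs(np.diff(coarse.capacitances)).max()
        assert fine_step < 0.1e-9
        assert fine_step < 0.2 * coarse_step

    def test_zero_coverage_ignores_delta_phi(self, device):
        a = simulate_cv(-0.5, 1.5, 401, device, layer_with(0.0, dphi=0.0))
        b = simulate_cv(-0.5, 1.5, 401, device, layer_with(0.0, dphi=0.123))
        np.testing.assert_array_equal(a.capacitances, b.capacitances)

    def test_zero_delta_phi_ignores_coverage(self, device):
        a = simulate_cv(-0.5, 1.5, 401, device, layer_with(0.0, dphi=0.0))
        b = simulate_cv(-0.5, 1.5, 401, device, layer_with(0.7, dphi=0.0))
        np.testing.assert_allclose(a.capacitances, b.capacitances, rtol=1e-14)

    def test_full_coverage_is_bare_curve_shifted(self, device):
        bare = simulate_cv(-0.5, 1.5, 2001, device, layer_with(0.0))
        full = simulate_cv(-0.5, 1.5, 2001, device, layer_with(1.0))
        shift = cv_shift_at_capacitance(bare, full, C_WORK)
        assert shift == pytest.approx(-DELTA_PHI, abs=1e-5)

    def test_region_labels(self, device):
        curve = simulate_cv(-0.5, 1.5, 2001, device, layer_with(0.5))
        labels = set(curve.region_labels)
        assert {"accumulation", "depletion", "inversion", "mixed"} >= labels
        assert "mixed" in labels  # flat bands of the two sub-regions differ
        assert curve.region_labels[0] == "accumulation"
        assert curve.region_labels[-1] == "inversion"

    def test_positive_particles_shift_curves_negative_and_monotone(self, device):
        bare = simulate_cv(-0.5, 1.5, 2001, device, layer_with(0.0))
        shifts = []
        for n in [0.25, 0.5, 0.75, 0.9]:
            cur = simulate_cv(-0.5, 1.5, 2001, device, layer_with(n))
            shifts.append(cv_shift_at_capacitance(bare, cur, C_WORK))
        assert all(s < 0 for s in shifts)
        assert all(b < a for a, b in zip(shifts, shifts[1:]))  # growing magnitude

    def test_csv_export(self, device, tmp_path):
        curve = simulate_cv(-0.1, 0.3, 41, device, layer_with(0.25))
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        lines = path.read_text().splitlines()
        header = [ln for ln in lines if ln.startswith("#")]
        assert any("d_i_nm" in ln for ln in header)
        body = [ln for ln in lines if not ln.startswith("#")]
        assert body[0] == "V_G_mV,C_eq_nF,region"
        v, c, lab = body[1].split(",")
        assert float(v) == pytest.approx(-100.0)
        assert float(c) == pytest.approx(
            ceq_depletion(-0.1, device, layer_with(0.25)) / 1e-9, abs=1e-5
        )


class TestCurveReadouts:
    def test_identical_curves_give_zero_shift_and_change(self, device):
        a = simulate_cv(-0.5, 1.5, 2001, device, layer_with(0.25))
        b = simulate_cv(-0.5, 1.5, 2001, device, layer_with(0.25))
        assert cv_shift_at_capacitance(a, b, C_WORK) == 0.0
        assert capacitance_change_at_voltage(a, b, 0.05) == 0.0

    def test_shift_matches_concap_solver_at_half_coverage(self, device):
        bare = simulate_cv(-0.5, 1.5, 2001, device, layer_with(0.0))
        half = simulate_cv(-0.5, 1.5, 2001, device, layer_with(0.5))
        shift = cv_shift_at_capacitance(bare, half, C_WORK)
        assert -DELTA_PHI < shift < 0
        concap = solve_concap_voltage(C_WORK, device, layer_with(0.5))
        assert shift == pytest.approx(concap.delta_v, abs=5e-5)

    def test_capacitance_drops_at_fixed_voltage_with_growing_coverage(self, device):
        bare = simulate_cv(-0.5, 1.5, 2001, device, layer_with(0.0))
        changes = []
        for n in [0.25, 0.5, 0.75, 0.9]:
            cur = simulate_cv(-0.5, 1.5, 2001, device, layer_with(n))
            changes.append(capacitance_change_at_voltage(bare, cur, 0.050))
        assert all(dc < 0 for dc in changes)
        assert all(abs(b) > abs(a) for a, b in zip(changes, changes[1:]))

    def test_out_of_range_reference_errors(self, device):
        a = simulate_cv(-0.5, 1.5, 201, device, layer_with(0.0))
        b = simulate_cv(-0.5, 1.5, 201, device, layer_with(0.5))
        with pytest.raises(ValueError):
            cv_shift_at_capacitance(a, b, 100e-9)
        with pytest.raises(ValueError):
            capacitance_change_at_voltage(a, b, 2.0)
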