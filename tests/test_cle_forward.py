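"""Series forward model: characteristic roots, equilibrium, ramp-hold traces."""

import numpy as np
import pytest
from scipy.special import j0, j1, jn_zeros

from scleramech import cle_forward as cf
from scleramech.exceptions import (
    InvalidInputError,
    InvalidParameterError,
)
from scleramech.materials import (
    CLEMaterial,
    RampHoldStep,
    StressTrace,
    isotropic_material,
    log_spaced_times,
)

from conftest import draw_valid_material


def scan_roots(func, n_roots, upper=40.0, grid=1e-4):
    """Independent oracle: sign-change scan on a fine grid + bisection."""
    xs = np.arange(grid, upper, grid)
    vals = func(xs)
    idx = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0][:n_roots]
    roots = []
    for i in idx:
        lo, hi = xs[i], xs[i + 1]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if np.sign(func(mid)) == np.sign(func(lo)):
                lo = mid
            else:
                hi = mid
        roots.append(0.5 * (lo + hi))
    return np.asarray(roots)


class TestCharacteristicRoots:
    def test_zero_shape_param_gives_j1_zeros(self):
        # frozen from the sign-scan oracle applied to J1
        expected = scan_roots(j1, 3, upper=12.0)
        np.testing.assert_allclose(expected, [3.83171, 7.01559, 10.17347],
                                   atol=1e-5)
        np.testing.assert_allclose(cf.characteristic_roots(0.0, 3), expected,
                                   rtol=1e-10)

    def test_large_shape_param_approaches_j0_zero(self):
        expected = scan_roots(lambda x: x * j0(x), 1, upper=4.0)
        np.testing.assert_allclose(expected, [2.40483], atol=1e-5)
        root = cf.characteristic_roots(1e8, 1)[0]
        assert abs(root - expected[0]) < 1e-6

    @pytest.mark.parametrize("beta", [0.05, 0.3, 0.7, 1.0, 2.5, 50.0])
    def test_matches_scan_oracle_and_ordering(self, beta):
        roots = cf.characteristic_roots(beta, 5)
        assert np.all(np.diff(roots) > 0)
        expected = scan_roots(lambda x: j1(x) - beta * x * j0(x), 5, upper=25.0)
        np.testing.assert_allclose(roots, expected, rtol=1e-8)

    @pytest.mark.parametrize("beta", [0.1, 0.6, 1.0, 4.0, 1e3])
    def test_interlacing_with_bessel_zeros(self, beta):
        """Each root lies between a zero of J1 and the next zero of J0."""
        roots = cf.characteristic_roots(beta, 6)
        a0 = jn_zeros(0, 10)
        b1 = np.concatenate([[0.0], jn_zeros(1, 10)])
        for root in roots:
            m = np.searchsorted(a0, root)
            assert b1[m] < root < a0[m]
        # at most one root per (J1-zero, J0-zero) bracket
        brackets = [np.sum((roots > b1[m]) & (roots < a0[m])) for m in range(8)]
        assert max(brackets) <= 1

    def test_invalid_arguments(self):
        with pytest.raises(InvalidParameterError):
            cf.characteristic_roots(np.nan, 3)
        with pytest.raises(InvalidParameterError):
            cf.characteristic_roots(-1.0, 3)
        with pytest.raises(InvalidParameterError):
            cf.characteristic_roots(1.0, 0)


class TestEquilibriumModulus:
    def test_isotropic_limit_matches_youngs_modulus(self):
        # H = lam + 2 mu, E = mu (3 lam + 2 mu)/(lam + mu)
        lam, mu, k = 3.0e5, 2.0e5, 1e-15
        material = CLEMaterial(H_A_plus=lam + 2 * mu, H_A_minus=lam + 2 * mu,
                               lambda2=lam, k=k)
        expected = mu * (3 * lam + 2 * mu) / (lam + mu)
        assert cf.equilibrium_modulus(material) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_modulus_rejected(self):
        with pytest.raises(InvalidParameterError):
            CLEMaterial(H_A_plus=1e5, H_A_minus=1e3, lambda2=9e4, k=1e-15)

    def test_long_time_limit_matches_oracle(self, default_material, geometry):
        """Packaged default parameters: series plateau equals the drained
        finite-difference limit run to ten gel-diffusion times."""
        from scleramech import fd_oracle

        tau = cf.gel_diffusion_time(default_material, geometry)
        t_end = 10.0 * tau
        times = np.array([t_end * 0.99, t_end])
        step = RampHoldStep(0.05, 10.0, t_end - 10.0, times)
        trace = fd_oracle.solve_unconfined(default_material, geometry, step,
                                           fd_oracle.GridSpec(48, 1.0))
        e_eq = cf.equilibrium_modulus(default_material)
        assert trace.stress[-1] / 0.05 == pytest.approx(e_eq, rel=5e-3)


class TestGelDiffusionTime:
    def test_direct_arithmetic(self, geometry):
        material = CLEMaterial(1e5, 5e3, 0.0, 2.5e-15)
        assert cf.gel_diffusion_time(material, geometry) == pytest.approx(1000.0)

    def test_halves_when_k_doubles(self, geometry, default_material):
        doubled = CLEMaterial(default_material.H_A_plus,
                              default_material.H_A_minus, 0.0,
                              2.0 * default_material.k)
        assert cf.gel_diffusion_time(doubled, geometry) == pytest.approx(
            cf.gel_diffusion_time(default_material, geometry) / 2.0)

    def test_default_config_relaxes_on_minutes_scale(self, default_material,
                                                     geometry, default_step):
        """Relaxation to within 5% of equilibrium takes tens of minutes,
        matching the reported first-step relaxation time (~12 min)."""
        trace = cf.ramp_hold_stress(default_material, geometry, default_step)
        e_eq = cf.equilibrium_modulus(default_material) * 0.05
        settled = trace.times[np.abs(trace.stress - e_eq) <= 0.05 * e_eq]
        t_settle = settled[0] / 60.0  # minutes
        assert 2.0 < t_settle < 60.0


class TestRampHoldStress:
    def test_zero_at_t0_peak_at_ramp_end_monotone_hold(self, default_material,
                                                       geometry, default_step):
        trace = cf.ramp_hold_stress(default_material, geometry, default_step)
        assert trace.stress[0] == 0.0
        i_peak = int(np.argmax(trace.stress))
        i_ramp_end = int(np.argmin(np.abs(trace.times - default_step.ramp_duration)))
        assert i_peak == i_ramp_end
        hold = trace.stress[trace.times >= default_step.ramp_duration]
        assert np.all(np.diff(hold) <= 1e-9 * trace.stress.max())
        e_eq = cf.equilibrium_modulus(default_material)
        assert trace.stress[-1] == pytest.approx(e_eq * 0.05, rel=1e-3)

    def test_equilibrium_linear_in_strain(self, fast_material, geometry):
        times = log_spaced_times(2.0, 600.0, n_hold=40)
        traces = []
        for eps in (0.02, 0.04):
            step = RampHoldStep(eps, 2.0, 600.0, times)
            traces.append(cf.ramp_hold_stress(fast_material, geometry, step))
        assert traces[1].stress[-1] == pytest.approx(2.0 * traces[0].stress[-1],
                                                     rel=1e-6)

    def test_doubling_moduli_doubles_stress_at_fixed_k(self, geometry,
                                                       default_step,
                                                       coupled_material):
        m = coupled_material
        doubled = CLEMaterial(2 * m.H_A_plus, 2 * m.H_A_minus, 2 * m.lambda2, m.k)
        t1 = cf.ramp_hold_stress(m, geometry, default_step)
        t2 = cf.ramp_hold_stress(doubled, geometry, default_step)
        # doubling all moduli doubles stress only in equilibrium (time
        # constants shift with H_A_plus), so assert the equilibrium scaling
        assert t2.stress[-1] == pytest.approx(2.0 * t1.stress[-1], rel=1e-3)

    def test_peak_to_equilibrium_ratio(self, geometry, default_step):
        """Overshoot >= 1 and non-decreasing in H_A_plus (tension-compression
        nonlinearity drives the transient)."""
        ratios = []
        for h_plus in (2e5, 1e6, 5e6):
            m = CLEMaterial(h_plus, 5e4, 0.0, 3e-16)
            tr = cf.ramp_hold_stress(m, geometry, default_step)
            ratios.append(tr.stress.max() / tr.stress[-1])
        assert all(r >= 1.0 for r in ratios)
        assert ratios == sorted(ratios)

    def test_vanishing_conductivity_freezes_relaxation(self, geometry):
        times = np.linspace(0.0, 500.0, 60)
        step = RampHoldStep(0.05, 10.0, 490.0, times)
        m = CLEMaterial(1e6, 5e4, 0.0, 1e-24)  # effectively impermeable
        trace = cf.ramp_hold_stress(m, geometry, step)
        hold = trace.stress[times >= 10.0]
        assert np.all(np.abs(hold - hold[0]) < 1e-4 * hold[0])

    def test_instantaneous_sum_rule(self, geometry, coupled_material):
        """sum(B_n) equals the undrained-minus-drained modulus gap."""
        B, _ = cf.series_coefficients(coupled_material, geometry, 200)
        m = coupled_material
        gap = m.instantaneous_modulus() - m.equilibrium_modulus()
        assert B.sum() == pytest.approx(gap, rel=2e-3)

    def test_empty_sample_times_rejected(self, default_material, geometry):
        with pytest.raises(InvalidInputError):
            RampHoldStep(0.05, 10.0, 100.0, np.array([]))

    def test_isotropic_reduction_matches_reference(self, geometry, default_step):
        """CLE path with H+ = H- and the Lame coupling equals the classical
        isotropic solution to < 0.1%."""
        H_A, nu, k = 5e5, 0.2, 1e-15
        material = isotropic_material(H_A, nu, k)
        cle = cf.ramp_hold_stress(material, geometry, default_step)
        ref = cf.isotropic_ramp_hold_stress(H_A, nu, k, geometry, default_step)
        mask = default_step.sample_times > 0
        rel = np.abs(cle.stress[mask] - ref.stress[mask]) / ref.stress[mask]
        assert rel.max() < 1e-3

    def test_trace_csv_round_trip(self, default_material, geometry,
                                  default_step, tmp_path):
        trace = cf.ramp_hold_stress(default_material, geometry, default_step)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        back = StressTrace.from_csv(path)
        np.testing.assert_allclose(back.stress, trace.stress, rtol=1e-6)
        assert back.meta["model"] == "cle_series"


class TestOracleEquivalence:
    def test_random_materials_match_fd_oracle(self, geometry):
        """Series vs finite-difference < 1% relative at hold times for random
        materials inside the fitting bounds (refined grid)."""
        from scleramech import fd_oracle

        rng = np.random.default_rng(42)
        times = log_spaced_times(10.0, 2000.0, n_hold=50)
        step = RampHoldStep(0.05, 10.0, 2000.0, times)
        hold = times > 12.0
        for _ in range(4):  # the 10-draw sweep runs in the acceptance suite
            m = draw_valid_material(rng)
            series = cf.ramp_hold_stress(m, geometry, step)
            oracle = fd_oracle.solve_unconfined(m, geometry, step,
                                                fd_oracle.GridSpec(96, 0.5))
            rel = np.abs(series.stress[hold] - oracle.stress[hold]) \
                / np.abs(series.stress[hold])
            assert rel.max() < 0.01
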