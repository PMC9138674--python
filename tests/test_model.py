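"""Forward-model limits, Bessel-branch stability, and the inverse fit."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import special

import ecisfence.model as m
from ecisfence.model import (
    CellParams,
    ElectrodeSpec,
    alpha_h_convert,
    bessel_disc_factor,
    cell_covered_specific_impedance,
    cell_free_specific_impedance,
    default_scan_frequencies,
    fit_cell_params,
    whole_well_impedance,
)
from ecisfence.synth import gen_frequency_scan


def series_i0_i1(z: complex, max_terms: int = 200):
    """Independent truncated-power-series evaluation of I0 and I1.

    Terms are added until relative convergence (or ``max_terms``), which is
    what a fixed short truncation cannot provide for large |z|.
    """
    q = z * z / 4.0
    i0 = term0 = complex(1.0)
    i1 = term1 = complex(1.0)
    for k in range(1, max_terms):
        term0 *= q / (k * k)
        term1 *= q / (k * (k + 1))
        i0 += term0
        i1 += term1
        if abs(term0) < 1e-18 * abs(i0) and abs(term1) < 1e-18 * abs(i1):
            break
    return i0, (z / 2.0) * i1


class TestCellFreeInterface:
    def test_pure_capacitor_limit(self):
        # with n = 1 the CPE is a capacitor of specific capacitance 1/A
        c_spec = 2.0 * math.pi * 5000.0
        el = ElectrodeSpec(cpe_magnitude=1.0 / c_spec, cpe_exponent=1.0)
        zn = cell_free_specific_impedance(5000.0, el)
        expected = 1.0 / (1j * 2.0 * math.pi * 5000.0 * c_spec)
        assert zn == pytest.approx(expected, rel=1e-12)

    def test_whole_well_resistance_at_40khz(self, electrode_1e, electrode_10e):
        # nominal cell-free well resistances of the two array types
        assert whole_well_impedance(40_000.0, electrode_1e).real == pytest.approx(2000.0, rel=1e-9)
        assert whole_well_impedance(40_000.0, electrode_10e).real == pytest.approx(300.0, rel=1e-9)

    def test_interfacial_impedance_scales_with_electrode_count(self, electrode_1e):
        # ten electrodes in parallel divide the interfacial part by ten
        el10 = dataclasses.replace(electrode_1e, n_electrodes=10)
        f = 1000.0
        part1 = whole_well_impedance(f, electrode_1e) - electrode_1e.r_solution_ohm
        part10 = whole_well_impedance(f, el10) - el10.r_solution_ohm
        assert part10 == pytest.approx(part1 / 10.0, rel=1e-12)

    def test_non_positive_frequency_rejected(self, electrode_1e):
        with pytest.raises(ValueError):
            cell_free_specific_impedance(0.0, electrode_1e)


class TestCoveredModel:
    def test_zero_cell_limit_over_scan_grid(self, electrode_1e):
        # Rb = alpha = 0 must collapse the covered model onto the bare one
        cells = CellParams(rb=0.0, cm=1.0, alpha=0.0)
        freqs = default_scan_frequencies()
        zn = cell_free_specific_impedance(freqs, electrode_1e)
        zc = cell_covered_specific_impedance(freqs, electrode_1e, cells)
        assert np.max(np.abs(zc - zn) / np.abs(zn)) < 1e-10

    def test_against_series_expansion_oracle(self, electrode_1e, control_cells):
        zn = cell_free_specific_impedance(4000.0, electrode_1e)
        zm = m.membrane_specific_impedance(4000.0, control_cells)
        inv_sum = 1.0 / zn + 1.0 / zm
        g = control_cells.alpha * np.sqrt(inv_sum)
        i0, i1 = series_i0_i1(complex(g))
        bracket = zn / (zn + zm) + (zm / (zn + zm)) / (
            (g / 2.0) * i0 / i1 + control_cells.rb * inv_sum
        )
        expected = 1.0 / ((1.0 / zn) * bracket)
        got = cell_covered_specific_impedance(4000.0, electrode_1e, control_cells)
        assert abs(got - expected) / abs(expected) < 1e-9

    def test_rb_sweep_increases_resistance(self, electrode_1e):
        # denser junctions block more current: Re(Z) rises strictly with Rb
        rbs = np.linspace(0.0, 10.0, 60)
        re_z = [
            whole_well_impedance(
                4000.0, electrode_1e, CellParams(rb=rb, cm=1.0, rc_um=11.72, h_nm=49.1535)
            ).real
            for rb in rbs
        ]
        assert np.all(np.diff(re_z) > 0)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            CellParams(rb=-1.0, cm=1.0, h_nm=50.0)


class TestBesselBranch:
    @pytest.mark.parametrize("mag", [1e-3, 1e-2, 0.5, 2.0, 10.0, 50.0])
    @pytest.mark.parametrize("phase_deg", [0.0, 20.0, 45.0, 80.0])
    def test_matches_direct_ratio(self, mag, phase_deg):
        z = mag * np.exp(1j * math.radians(phase_deg))
        direct = 0.5 * z * special.iv(0, z) / special.iv(1, z)
        assert abs(bessel_disc_factor(z) - direct) / abs(direct) < 1e-9

    @pytest.mark.parametrize("mag", [1e-3, 1.0, 50.0])
    def test_matches_series_oracle(self, mag):
        z = mag * np.exp(1j * 0.6)
        i0, i1 = series_i0_i1(complex(z))
        assert abs(bessel_disc_factor(z) - 0.5 * z * i0 / i1) / abs(0.5 * z * i0 / i1) < 1e-9

    def test_finite_and_asymptotic_at_large_modulus(self):
        # the ratio I0/I1 -> 1, so the factor approaches z/2
        for mag in (1e2, 1e3):
            z = mag * np.exp(1j * 0.3)
            val = bessel_disc_factor(z)
            assert np.isfinite(val)
            assert abs(val / (z / 2.0) - 1.0) < 1e-2

    def test_small_argument_limit(self):
        assert bessel_disc_factor(0.0) == pytest.approx(1.0)
        assert abs(bessel_disc_factor(1e-9) - 1.0) < 1e-12


class TestAlphaHConversion:
    def test_round_trip_identity(self):
        for alpha in (0.1, 1.0, 3.8846, 40.0):
            h = alpha_h_convert(alpha, "alpha_to_h", 54.0, 11.72)
            back = alpha_h_convert(h, "h_to_alpha", 54.0, 11.72)
            assert back == pytest.approx(alpha, rel=1e-12)

    def test_unit_conversion_oracle(self):
        # independent SI chain: h[cm] = rho[Ohm*cm] * (rc[cm])^2 / alpha^2
        rho, rc_um, h_nm = 54.0, 11.72, 49.1535
        alpha_oracle = math.sqrt(rho * (rc_um * 1e-4) ** 2 / (h_nm * 1e-7))
        assert alpha_h_convert(h_nm, "h_to_alpha", rho, rc_um) == pytest.approx(
            alpha_oracle, rel=1e-12
        )

    def test_inverse_square_power_law(self):
        h1 = alpha_h_convert(1.0, "alpha_to_h", 54.0, 11.0)
        h4 = alpha_h_convert(4.0, "alpha_to_h", 54.0, 11.0)
        assert h4 == pytest.approx(h1 / 16.0, rel=1e-12)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            alpha_h_convert(0.0, "alpha_to_h", 54.0, 11.0)

    def test_cellparams_consistency_enforced(self):
        with pytest.raises(ValueError):
            CellParams(rb=1.0, cm=1.0, rc_um=11.72, alpha=1.0, h_nm=49.1535)


class TestCoverageMixing:
    @pytest.mark.parametrize("coverage,matches", [(0.0, "free"), (1.0, "covered")])
    def test_endpoints(self, electrode_1e, control_cells, coverage, matches):
        z = whole_well_impedance(4000.0, electrode_1e, control_cells, coverage)
        z_free = whole_well_impedance(4000.0, electrode_1e)
        z_cov = whole_well_impedance(4000.0, electrode_1e, control_cells, 1.0)
        ref = z_free if matches == "free" else z_cov
        assert z == pytest.approx(ref, rel=1e-12)

    def test_half_coverage_parallel_circuit_oracle(self, electrode_1e, control_cells):
        # two half-area patches in parallel, in series with Rsol
        area = electrode_1e.total_area_cm2
        zn = cell_free_specific_impedance(4000.0, electrode_1e)
        zc = cell_covered_specific_impedance(4000.0, electrode_1e, control_cells)
        y = 0.5 * area / zn + 0.5 * area / zc
        expected = 1.0 / y + electrode_1e.r_solution_ohm
        got = whole_well_impedance(4000.0, electrode_1e, control_cells, 0.5)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_coverage_out_of_range(self, electrode_1e, control_cells):
        with pytest.raises(ValueError):
            whole_well_impedance(4000.0, electrode_1e, control_cells, 1.5)


class TestFit:
    def test_noiseless_round_trip(self, electrode_1e, control_cells):
        free = gen_frequency_scan(electrode_1e, None)
        covered = gen_frequency_scan(electrode_1e, control_cells)
        fit = fit_cell_params(covered, free, electrode_1e, n_starts=6, seed=0, rc_um=11.72)
        assert fit.converged
        assert fit.params.rb == pytest.approx(1.7267, rel=1e-2)
        assert fit.params.h_nm == pytest.approx(49.1535, rel=1e-2)
        assert fit.params.cm == pytest.approx(1.0, rel=1e-2)

    def test_no_cell_limit_drives_rb_alpha_to_lower_bound(self, electrode_1e):
        free = gen_frequency_scan(electrode_1e, None)
        covered = dataclasses.replace(free)
        covered.coverage_state = "cell_covered"
        fit = fit_cell_params(covered, free, electrode_1e, n_starts=4, seed=1)
        assert fit.params.rb <= m.DEFAULT_FIT_BOUNDS["rb"][0] * 1.5
        assert fit.params.alpha <= m.DEFAULT_FIT_BOUNDS["alpha"][0] * 1.5
        # bounded below away from the exact no-cell point, so a tiny but
        # nonzero residual remains
        assert fit.residual < 1e-5

    def test_parameter_recovery_over_seeded_box(self, electrode_1e):
        # noiseless recovery across the physiological parameter box
        free = gen_frequency_scan(electrode_1e, None)
        rng = np.random.default_rng(42)
        for i in range(30):
            rb = rng.uniform(0.5, 10.0)
            h = rng.uniform(20.0, 100.0)
            cm = rng.uniform(0.5, 4.0)
            covered = gen_frequency_scan(
                electrode_1e, CellParams(rb=rb, cm=cm, rc_um=11.0, h_nm=h)
            )
            p = fit_cell_params(covered, free, electrode_1e, n_starts=6, seed=i).params
            assert p.rb == pytest.approx(rb, rel=1e-2)
            assert p.h_nm == pytest.approx(h, rel=1e-2)
            assert p.cm == pytest.approx(cm, rel=1e-2)

    def test_scale_equivariance(self, electrode_1e, control_cells):
        # scaling all impedances by c maps (Rb, alpha, Cm) to
        # (c*Rb, sqrt(c)*alpha, Cm/c) after CPE recalibration
        c = 3.0
        free = gen_frequency_scan(electrode_1e, None)
        covered = gen_frequency_scan(electrode_1e, control_cells)
        free_s = m.FrequencyScan(free.frequencies, c * free.impedance, "cell_free")
        covered_s = m.FrequencyScan(covered.frequencies, c * covered.impedance, "cell_covered")
        bounds = {"rb": (1e-4, 300.0), "alpha": (0.05, 100.0), "cm": (0.01, 10.0)}
        p0 = fit_cell_params(covered, free, electrode_1e, bounds, n_starts=6, seed=0,
                             rc_um=11.72).params
        p1 = fit_cell_params(covered_s, free_s, electrode_1e, bounds, n_starts=6, seed=0,
                             rc_um=11.72).params
        assert p1.rb == pytest.approx(c * p0.rb, rel=1e-6)
        assert p1.alpha == pytest.approx(math.sqrt(c) * p0.alpha, rel=1e-6)
        assert p1.cm == pytest.approx(p0.cm / c, rel=1e-6)

    def test_mismatched_grids_rejected(self, electrode_1e, control_cells):
        free = gen_frequency_scan(electrode_1e, None, n_points=25)
        covered = gen_frequency_scan(electrode_1e, control_cells, n_points=24)
        with pytest.raises(ValueError):
            fit_cell_params(covered, free, electrode_1e)


class TestFrequencyScanValidation:
    def test_rejects_non_increasing_grid(self):
        with pytest.raises(ValueError):
            m.FrequencyScan(np.array([100.0, 50.0]), np.array([1 - 1j, 1 - 1j]))

    def test_rejects_non_capacitive_phase(self):
        with pytest.raises(ValueError):
            m.FrequencyScan(np.array([100.0, 200.0]), np.array([1 + 1j, 1 - 1j]))
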