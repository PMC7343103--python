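"""Single-shell model: dielectric dispersion, CM factor, crossover, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depscreen.shell_model import (
    EPSILON_0,
    CellShellParams,
    DielectricMedium,
    FrequencyGrid,
    NoCrossoverError,
    Spectrum,
    closed_form_crossover,
    complex_permittivity,
    crossover_frequency,
    dep_spectrum,
    fit_shell_params,
    re_cm,
    single_shell_effective_permittivity,
)


def two_layer_effective_permittivity(eps_mem_rel, sigma_mem, eps_cyt_rel, sigma_cyt,
                                     radius, thickness, frequency):
    """Finite-thickness shelled-sphere oracle (explicit two-layer mixing)."""
    w = 2 * np.pi * np.asarray(frequency, dtype=float)
    em = eps_mem_rel - 1j * sigma_mem / (w * EPSILON_0)
    ec = eps_cyt_rel - 1j * sigma_cyt / (w * EPSILON_0)
    gamma = (radius / (radius - thickness)) ** 3
    contrast = (ec - em) / (ec + 2 * em)
    return em * (gamma + 2 * contrast) / (gamma - contrast)


class TestComplexPermittivity:
    def test_zero_conductivity_is_real(self):
        assert complex_permittivity(78.0, 0.0, 1e5) == 78.0 + 0j

    def test_high_frequency_limit_kills_imaginary_part(self):
        val = complex_permittivity(78.0, 0.043, 1e15)
        assert abs(val.imag) < 1e-6
        assert val.real == pytest.approx(78.0)

    def test_matches_hand_computed_loss_term(self):
        # sigma/(2*pi*f*eps0) at 100 kHz, sigma = 43 mS/m
        expected = 0.043 / (2 * np.pi * 1e5 * EPSILON_0)
        val = complex_permittivity(78.0, 0.043, 1e5)
        assert -val.imag == pytest.approx(expected, rel=1e-12)
        assert val.real == 78.0

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            complex_permittivity(78.0, 0.043, 0.0)
        with pytest.raises(ValueError):
            complex_permittivity(78.0, 0.043, -1e3)


class TestEffectivePermittivity:
    def test_vanishing_shell_contrast_recovers_cytoplasm(self):
        # a membrane dielectrically identical to the cytoplasm, expressed
        # through a very thin shell, leaves the sphere homogeneous
        d = 1e-10
        cell = CellShellParams(
            radius=10e-6,
            membrane_capacitance=60.0 * EPSILON_0 / d,
            membrane_conductance=0.5 / d,
            cytoplasm_rel_permittivity=60.0,
            cytoplasm_conductivity=0.5,
        )
        f = 1e6
        eff = single_shell_effective_permittivity(cell, f)
        cyt = complex_permittivity(60.0, 0.5, f)
        assert eff == pytest.approx(cyt, rel=1e-3)

    def test_dc_limit_insulating_membrane_blocks_conduction(self):
        cell = CellShellParams(10e-6, 0.01, 0.0, 60.0, 0.5)
        f = 1e-3
        eff = single_shell_effective_permittivity(cell, f)
        sigma_eff = -eff.imag * 2 * np.pi * f * EPSILON_0
        assert sigma_eff == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("g_mem", [0.0, 200.0, 2000.0])
    def test_thin_shell_matches_finite_thickness_oracle(self, grid, g_mem):
        d = 5e-9
        cell = CellShellParams(10e-6, 0.01, g_mem, 60.0, 0.25)
        thin = single_shell_effective_permittivity(cell, grid.frequencies)
        full = two_layer_effective_permittivity(
            eps_mem_rel=cell.membrane_capacitance * d / EPSILON_0,
            sigma_mem=cell.membrane_conductance * d,
            eps_cyt_rel=60.0,
            sigma_cyt=0.25,
            radius=cell.radius,
            thickness=d,
            frequency=grid.frequencies,
        )
        assert np.all(np.abs(thin - full) / np.abs(full) < 0.01)

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            CellShellParams(-1e-6, 0.01, 0.0, 60.0, 0.5)


class TestReCM:
    def test_particle_identical_to_medium_gives_zero(self, medium):
        d = 1e-10
        cell = CellShellParams(
            radius=10e-6,
            membrane_capacitance=medium.rel_permittivity * EPSILON_0 / d,
            membrane_conductance=medium.conductivity / d,
            cytoplasm_rel_permittivity=medium.rel_permittivity,
            cytoplasm_conductivity=medium.conductivity,
        )
        for f in (1e4, 1e5, 1e7):
            assert re_cm(cell, medium, f) == pytest.approx(0.0, abs=1e-3)

    def test_dc_insulating_sphere_limit(self, medium):
        cell = CellShellParams(10e-6, 0.01, 0.0, 60.0, 0.5)
        assert re_cm(cell, medium, 1e-2) == pytest.approx(-0.5, abs=1e-4)

    def test_high_frequency_closed_form_limit(self, medium):
        cell = CellShellParams(10e-6, 0.01, 0.0, 60.0, 0.5)
        # the finite membrane capacitance leaves a ~0.5% series correction
        # on eps_cyt, so agreement with the ideal limit is to ~2%
        expected = (60.0 - 78.0) / (60.0 + 2 * 78.0)  # -0.0833
        assert re_cm(cell, medium, 1e12) == pytest.approx(expected, rel=0.03)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        radius=st.floats(2e-6, 30e-6),
        c_mem=st.floats(1e-3, 5e-2),
        g_mem=st.floats(0.0, 1e4),
        eps_cyt=st.floats(20.0, 120.0),
        sigma_cyt=st.floats(0.01, 2.0),
        log_f=st.floats(2.0, 9.0),
    )
    def test_bounded_for_all_parameters(self, radius, c_mem, g_mem, eps_cyt,
                                        sigma_cyt, log_f):
        cell = CellShellParams(radius, c_mem, g_mem, eps_cyt, sigma_cyt)
        medium = DielectricMedium(78.0, 0.043)
        val = re_cm(cell, medium, 10.0 ** log_f)
        assert np.isfinite(val)
        assert -0.5 - 1e-9 <= val <= 1.0 + 1e-9

    def test_continuous_no_nan_on_dense_grid(self, control_cell, medium):
        freqs = np.logspace(1, 10, 5000)
        vals = re_cm(control_cell, medium, freqs)
        assert np.all(np.isfinite(vals))
        assert np.max(np.abs(np.diff(vals))) < 0.01


class TestDepSpectrum:
    def test_values_bounded_and_all_valid(self, control_cell, medium, grid):
        spec = dep_spectrum(control_cell, medium, grid)
        assert len(spec.values) == 20
        assert spec.mask.all()
        assert np.all(spec.values >= -0.5) and np.all(spec.values <= 1.0)

    def test_matches_pointwise_re_cm(self, cancer_cell, medium, grid):
        spec = dep_spectrum(cancer_cell, medium, grid)
        pointwise = [re_cm(cancer_cell, medium, f) for f in grid.frequencies]
        np.testing.assert_allclose(spec.values, pointwise, rtol=1e-12)

    def test_two_state_contrast_matches_reported_shape(self, cancer_cell,
                                                       control_cell, medium, grid):
        """Cancer-like cells read lower below ~80 kHz and higher at the top
        of the band than control-like cells."""
        canc = dep_spectrum(cancer_cell, medium, grid).values
        ctrl = dep_spectrum(control_cell, medium, grid).values
        low = grid.frequencies < 8e4
        high = grid.frequencies > 1e5
        assert np.all(canc[low] < ctrl[low])
        assert np.all(canc[high] > ctrl[high])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            FrequencyGrid(np.array([]))


class TestCrossover:
    def test_root_agrees_with_thin_shell_closed_form(self, medium):
        # insulating membrane, cytoplasm far more conductive than medium
        cell = CellShellParams(10e-6, 0.01, 0.0, 60.0, 1.0)
        expected = closed_form_crossover(cell, medium)
        assert expected == pytest.approx(9.68e4, rel=0.01)
        root = crossover_frequency(cell, medium, (1e3, 45e6))
        assert root.frequency == pytest.approx(expected, rel=0.05)
        assert not root.additional_crossovers

    def test_doubling_radius_halves_closed_form(self, medium):
        small = CellShellParams(10e-6, 0.01, 0.0, 60.0, 1.0)
        big = CellShellParams(20e-6, 0.01, 0.0, 60.0, 1.0)
        assert closed_form_crossover(small, medium) == pytest.approx(
            2.0 * closed_form_crossover(big, medium)
        )

    def test_zero_contrast_has_no_crossover(self, medium):
        d = 1e-10
        cell = CellShellParams(
            radius=10e-6,
            membrane_capacitance=medium.rel_permittivity * EPSILON_0 / d,
            membrane_conductance=medium.conductivity / d,
            cytoplasm_rel_permittivity=medium.rel_permittivity,
            cytoplasm_conductivity=medium.conductivity,
        )
        with pytest.raises(NoCrossoverError):
            crossover_frequency(cell, medium, (1e4, 45e6))

    def test_root_is_a_sign_change(self, control_cell, medium):
        res = crossover_frequency(control_cell, medium, (1e4, 45e6))
        assert re_cm(control_cell, medium, res.frequency) == pytest.approx(0.0, abs=1e-8)
        assert re_cm(control_cell, medium, res.frequency * 0.9) < 0
        assert re_cm(control_cell, medium, res.frequency * 1.1) > 0


class TestFitShellParams:
    def test_noise_free_self_consistency(self, cancer_cell, medium, grid):
        spec = dep_spectrum(cancer_cell, medium, grid)
        fit = fit_shell_params(spec, medium, cancer_cell,
                               ("membrane_capacitance", "cytoplasm_conductivity"))
        assert fit.converged
        assert fit.residual_norm == pytest.approx(0.0, abs=1e-10)

    def test_noise_free_recovery_from_2x_off_start(self, cancer_cell, medium, grid):
        from dataclasses import replace

        spec = dep_spectrum(cancer_cell, medium, grid)
        start = replace(
            cancer_cell,
            membrane_capacitance=2 * cancer_cell.membrane_capacitance,
            cytoplasm_conductivity=2 * cancer_cell.cytoplasm_conductivity,
        )
        fit = fit_shell_params(spec, medium, start,
                               ("membrane_capacitance", "cytoplasm_conductivity"))
        assert fit.converged
        assert fit.params.membrane_capacitance == pytest.approx(
            cancer_cell.membrane_capacitance, rel=0.01
        )
        assert fit.params.cytoplasm_conductivity == pytest.approx(
            cancer_cell.cytoplasm_conductivity, rel=0.01
        )

    def test_masked_points_are_ignored(self, cancer_cell, medium, grid):
        spec = dep_spectrum(cancer_cell, medium, grid)
        spec.values[5] = 99.0  # corrupt one point, then mask it out
        spec.mask[5] = False
        fit = fit_shell_params(spec, medium, cancer_cell,
                               ("membrane_capacitance",))
        assert fit.residual_norm == pytest.approx(0.0, abs=1e-10)
        assert fit.n_points == 19

    def test_too_few_points_rejected(self, cancer_cell, medium):
        tiny = Spectrum(FrequencyGrid(np.array([1e5])), np.array([0.1]))
        with pytest.raises(ValueError):
            fit_shell_params(tiny, medium, cancer_cell,
                             ("membrane_capacitance", "cytoplasm_conductivity"))

    def test_unknown_free_parameter_rejected(self, cancer_cell, medium, grid):
        spec = dep_spectrum(cancer_cell, medium, grid)
        with pytest.raises(ValueError):
            fit_shell_params(spec, medium, cancer_cell, ("nucleus_radius",))
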