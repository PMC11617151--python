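"""Reflectance-factor computation and the spectral pretreatments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafchl.errors import (
    GridMismatchError,
    InvalidReferenceError,
    InvalidSpectrumError,
    ParameterError,
)
from leafchl.grid import CANONICAL_GRID, SpectralGrid
from _oracles import chord_oracle_continuum
from leafchl.spectra import (
    Spectrum,
    WhiteReferenceGroup,
    compute_reflectance,
    continuum_removal,
    log_inverse,
    savgol_derivative,
    transform_suite,
)


def const(value, kind="radiance", grid=CANONICAL_GRID):
    return Spectrum(values=np.full(grid.n_bands, value), kind=kind, grid=grid)


class TestGrid:
    def test_canonical_grid_has_2151_one_nm_bands(self):
        assert CANONICAL_GRID.n_bands == 2151
        assert CANONICAL_GRID.wavelengths[0] == 350
        assert CANONICAL_GRID.wavelengths[-1] == 2500

    def test_band_index_wavelength_roundtrip_is_bijective(self):
        g = CANONICAL_GRID
        idx = np.array([g.index_of(w) for w in g.wavelengths])
        assert np.array_equal(idx, np.arange(g.n_bands))
        assert all(g.wavelength_of(i) == w for i, w in zip(idx, g.wavelengths))

    def test_off_grid_wavelength_rejected(self):
        with pytest.raises(ParameterError):
            CANONICAL_GRID.index_of(350.5)
        with pytest.raises(ParameterError):
            CANONICAL_GRID.index_of(2501)


class TestReflectance:
    @pytest.mark.parametrize(
        "leaf_val, ref_vals, expected",
        [
            (2.0, [4.0], 0.5),            # constant ratio
            (1.0, [1.0, 3.0], 0.5),       # mean of refs is 2, hand arithmetic
        ],
    )
    def test_ratio_against_mean_reference(self, leaf_val, ref_vals, expected):
        refs = WhiteReferenceGroup([const(v) for v in ref_vals])
        out = compute_reflectance(const(leaf_val), refs)
        assert out.kind == "reflectance"
        np.testing.assert_allclose(out.values, expected)

    def test_spectrum_against_itself_is_all_ones(self):
        leaf = const(7.3)
        out = compute_reflectance(leaf, WhiteReferenceGroup([leaf]))
        np.testing.assert_allclose(out.values, 1.0)

    def test_grid_mismatch_is_structural_error(self):
        small = SpectralGrid(350, 360, 1)
        with pytest.raises(GridMismatchError):
            compute_reflectance(const(1.0), WhiteReferenceGroup([const(1.0, grid=small)]))

    def test_nonpositive_reference_band_rejected(self):
        ref = const(1.0)
        ref.values[5] = 0.0
        with pytest.raises(InvalidReferenceError):
            compute_reflectance(const(1.0), WhiteReferenceGroup([ref]))


class TestSavgolDerivative:
    def test_constant_spectrum_has_zero_first_derivative(self):
        out = savgol_derivative(const(0.3, "reflectance"), order=1)
        assert out.kind == "d1"
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_linear_spectrum_recovers_slope_per_nm(self):
        wl = CANONICAL_GRID.wavelengths
        s = Spectrum(values=0.001 * wl.astype(float), kind="reflectance")
        out = savgol_derivative(s, order=1)
        np.testing.assert_allclose(out.values, 0.001, atol=1e-12)

    def test_quadratic_second_derivative_matches_finite_difference_oracle(self):
        wl = CANONICAL_GRID.wavelengths.astype(float)
        a, b, c = 0.1, 1e-4, 3e-8
        s = Spectrum(values=a + b * wl + c * wl**2, kind="reflectance")
        out = savgol_derivative(s, order=2)
        # central finite-difference oracle on the interior
        oracle = np.diff(s.values, 2)  # step 1 nm
        np.testing.assert_allclose(out.values[1:-1], oracle, atol=1e-12)
        np.testing.assert_allclose(out.values, 2 * c, atol=1e-12)

    def test_derivative_operator_is_linear(self):
        rng = np.random.default_rng(0)
        s1 = Spectrum(values=rng.uniform(0.1, 0.9, 2151), kind="reflectance")
        s2 = Spectrum(values=rng.uniform(0.1, 0.9, 2151), kind="reflectance")
        a, b = 0.7, -1.3
        combo = Spectrum(values=a * s1.values + b * s2.values, kind="reflectance")
        lhs = savgol_derivative(combo, 1).values
        rhs = a * savgol_derivative(s1, 1).values + b * savgol_derivative(s2, 1).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_parameter_contract(self):
        s = const(0.5, "reflectance")
        with pytest.raises(ParameterError):
            savgol_derivative(s, order=1, window_bands=14)
        with pytest.raises(ParameterError):
            savgol_derivative(s, order=2, poly_order=1)

    def test_log_inv_input_yields_log_inv_derivative_kind(self):
        out = savgol_derivative(log_inverse(const(0.5, "reflectance")), 1)
        assert out.kind == "log_inv_d1"


class TestLogInverse:
    @pytest.mark.parametrize("rho, expected", [(0.1, 1.0), (1.0, 0.0), (0.01, 2.0)])
    def test_known_values(self, rho, expected):
        out = log_inverse(const(rho, "reflectance"))
        assert out.kind == "log_inv"
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_all_nonpositive_spectrum_rejected(self):
        with pytest.raises(InvalidSpectrumError):
            log_inverse(Spectrum(values=np.full(2151, -0.1), kind="radiance"))

    def test_noise_dips_are_clipped_not_fatal(self):
        s = const(0.5, "reflectance")
        s.values[100] = -0.001
        out = log_inverse(s)
        assert np.isfinite(out.values).all()


class TestContinuumRemoval:
    def test_linear_spectrum_maps_to_all_ones(self):
        g = SpectralGrid(350, 400, 1)
        wl = g.wavelengths.astype(float)
        s = Spectrum(values=0.2 + 0.001 * (wl - 350), kind="reflectance", grid=g)
        out = continuum_removal(s)
        np.testing.assert_allclose(out.values, 1.0, atol=1e-12)

    def test_single_dip_below_chord(self):
        g = SpectralGrid(350, 359, 1)
        vals = np.full(10, 0.8)
        vals[4] = 0.5
        out = continuum_removal(Spectrum(values=vals, kind="reflectance", grid=g))
        assert out.values[4] == pytest.approx(0.5 / 0.8)
        mask = np.ones(10, bool)
        mask[4] = False
        np.testing.assert_allclose(out.values[mask], 1.0)

    def test_five_band_toy_matches_chord_maximum_oracle(self, benchmarks):
        toy = benchmarks["hull_toy"]
        out = continuum_removal(toy)
        oracle_hull = chord_oracle_continuum(toy.wavelengths.astype(float), toy.values)
        np.testing.assert_allclose(out.values, toy.values / oracle_hull, atol=1e-12)

    def test_random_spectrum_matches_oracle(self):
        rng = np.random.default_rng(42)
        g = SpectralGrid(350, 399, 1)
        vals = rng.uniform(0.05, 0.9, g.n_bands)
        s = Spectrum(values=vals, kind="reflectance", grid=g)
        out = continuum_removal(s)
        oracle = vals / chord_oracle_continuum(g.wavelengths.astype(float), vals)
        np.testing.assert_allclose(out.values, oracle, atol=1e-10)

    def test_values_bounded_by_one_and_endpoints_equal_one(self, vegetation_spectrum):
        out = continuum_removal(vegetation_spectrum)
        assert out.values.max() <= 1.0 + 1e-12
        assert out.values[0] == pytest.approx(1.0)
        assert out.values[-1] == pytest.approx(1.0)
        assert out.values.min() > 0.0

    def test_idempotent_on_own_output(self, vegetation_spectrum):
        once = continuum_removal(vegetation_spectrum)
        twice = continuum_removal(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)

    def test_too_few_bands_rejected(self, vegetation_spectrum):
        with pytest.raises(ParameterError):
            continuum_removal(vegetation_spectrum, 700, 701)


class TestTransformSuite:
    def test_produces_exactly_seven_keyed_spectra(self, vegetation_spectrum):
        suite = transform_suite(vegetation_spectrum)
        assert set(suite) == {"reflectance", "d1", "d2", "log_inv",
                              "log_inv_d1", "log_inv_d2", "continuum_removed"}
        for key, s in suite.items():
            assert len(s.values) == 2151

    def test_constant_input_gives_flat_derivatives_and_unity_continuum(self):
        suite = transform_suite(const(0.4, "reflectance"))
        np.testing.assert_allclose(suite["d1"].values, 0.0, atol=1e-12)
        np.testing.assert_allclose(suite["d2"].values, 0.0, atol=1e-12)
        np.testing.assert_allclose(suite["continuum_removed"].values, 1.0)

    def test_composition_identity_for_log_inverse_derivative(self, vegetation_spectrum):
        suite = transform_suite(vegetation_spectrum)
        direct = savgol_derivative(log_inverse(vegetation_spectrum), 1)
        np.testing.assert_allclose(suite["log_inv_d1"].values, direct.values)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.floats(min_value=0.05, max_value=0.95),
       st.floats(min_value=1.05, max_value=20.0))
def test_reflectance_scaling_property(leaf_val, ref_val):
    """Reflectance factor scales inversely with the reference radiance."""
    g = SpectralGrid(350, 360, 1)
    leaf = Spectrum(values=np.full(g.n_bands, leaf_val), kind="radiance", grid=g)
    ref = WhiteReferenceGroup([Spectrum(values=np.full(g.n_bands, ref_val),
                                        kind="radiance", grid=g)])
    out = compute_reflectance(leaf, ref)
    np.testing.assert_allclose(out.values, leaf_val / ref_val, rtol=1e-12)
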