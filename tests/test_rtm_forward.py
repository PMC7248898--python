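"""Forward-model layer: parameter sampling, toy canopy physics, band
resampling, reflectance noise."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gflai as g
from gflai.rtm_forward import PARAM_NAMES, ParamDistribution, sample_parameter_array


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def test_sample_zero_returns_empty(full_spec):
    assert g.sample_parameters(full_spec, 0, seed=0) == []


def test_degenerate_std_yields_the_means(full_spec):
    frozen = {k: ParamDistribution(d.min, d.max, d.mean, 0.0) for k, d in full_spec.items()}
    out = g.sample_parameters(frozen, 5, seed=0)
    assert len(out) == 5
    for p in out:
        assert p.lai == 3.5 and p.cab == 50.0 and p.alia == 60.0


def test_invalid_distribution_rejected():
    with pytest.raises(ValueError):
        ParamDistribution(min=2.0, max=1.0, mean=1.5, std=0.1)
    with pytest.raises(ValueError):
        ParamDistribution(min=0.0, max=1.0, mean=0.5, std=-0.1)
    with pytest.raises(ValueError):
        ParamDistribution(min=0.0, max=1.0, mean=2.0, std=0.1)


def test_truncated_mean_matches_numeric_integration_oracle(full_spec):
    """Sample mean of the LAI law vs the truncated-normal mean computed by
    direct numerical integration of the density."""
    d = full_spec["lai"]
    x = np.linspace(d.min, d.max, 20001)
    density = np.exp(-((x - d.mean) ** 2) / (2 * d.std**2))
    density /= np.trapezoid(density, x)
    oracle_mean = np.trapezoid(x * density, x)
    oracle_var = np.trapezoid((x - oracle_mean) ** 2 * density, x)

    n = 10_000
    sample = sample_parameter_array(full_spec, n, seed=123)[:, PARAM_NAMES.index("lai")]
    se = np.sqrt(oracle_var / n)
    assert abs(sample.mean() - oracle_mean) < 3 * se


def test_samples_respect_truncation_bounds(full_spec):
    arr = sample_parameter_array(full_spec, 5000, seed=7)
    for j, name in enumerate(PARAM_NAMES):
        d = full_spec[name]
        assert arr[:, j].min() >= d.min and arr[:, j].max() <= d.max


def test_sampling_deterministic_per_seed(full_spec):
    a = sample_parameter_array(full_spec, 50, seed=9)
    b = sample_parameter_array(full_spec, 50, seed=9)
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# toy forward model
# ---------------------------------------------------------------------------

def test_bare_soil_limit(const_toy):
    spec = g.forward_model(g.CanopyParams(lai=0.0), backend=const_toy)
    np.testing.assert_array_equal(spec.reflectance, np.full_like(spec.wavelengths, 0.3))


def test_dense_canopy_asymptote(const_toy):
    spec = g.forward_model(g.CanopyParams(lai=50.0), backend=const_toy)
    assert np.max(np.abs(spec.reflectance - 0.5)) < 1e-8


def test_two_stream_closed_form(const_toy):
    # soil 0.3, dense canopy 0.5, k = 0.5, LAI = 2 -> 0.3 e^-1 + 0.5 (1 - e^-1)
    spec = g.forward_model(g.CanopyParams(lai=2.0), backend=const_toy)
    expected = 0.3 * np.exp(-1.0) + 0.5 * (1.0 - np.exp(-1.0))
    assert spec.reflectance[0] == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.4264, abs=5e-5)


def test_monotone_in_lai_wherever_endmembers_differ():
    toy = g.ToyCanopyModel()
    base = {"N": 1.5, "cab": 50.0, "alia": 60.0, "psoil": 0.5}
    curves = [g.forward_model(g.CanopyParams(lai=l, **base), backend=toy).reflectance
              for l in (0.0, 1.0, 2.0, 4.0, 7.0)]
    soil, leaf = toy.endmembers(toy.wavelengths, g.CanopyParams(**base))
    differs = np.abs(soil - leaf) > 1e-9
    for lo, hi in zip(curves, curves[1:]):
        diff = (hi - lo)[differs]
        assert np.all(diff > 0) or np.all(diff < 0) or np.all(np.sign(diff) == np.sign(leaf - soil)[differs])


def test_forward_model_deterministic():
    p, geom = g.CanopyParams(lai=2.2, cab=33.0), g.ViewGeometry()
    a = g.forward_model(p, geom, "toy").reflectance
    b = g.forward_model(p, geom, "toy").reflectance
    np.testing.assert_array_equal(a, b)


def test_batch_bands_match_scalar_path(full_spec):
    arr = sample_parameter_array(full_spec, 20, seed=3)
    batch = g.simulate_bands(arr)
    loop = np.array([
        g.resample_to_bands(g.forward_model(g.CanopyParams.from_array(row))).band_reflectance
        for row in arr
    ])
    np.testing.assert_allclose(batch, loop, atol=1e-12)


def test_unknown_backend_rejected():
    with pytest.raises(ValueError, match="backend"):
        g.forward_model(g.CanopyParams(), backend="sail6")


def test_missing_prosail_dependency_raises_capability_error():
    try:
        import prosail  # noqa: F401
        pytest.skip("prosail installed; capability error not reachable")
    except ImportError:
        pass
    with pytest.raises(g.BackendUnavailableError, match="prosail"):
        g.forward_model(g.CanopyParams(), backend="prosail")


def test_geometry_range_validation():
    with pytest.raises(ValueError):
        g.ViewGeometry(tts=10.0)
    with pytest.raises(ValueError):
        g.ViewGeometry(psi=150.0)


# ---------------------------------------------------------------------------
# band resampling
# ---------------------------------------------------------------------------

def test_flat_spectrum_resamples_to_constant():
    wl = np.arange(400.0, 1001.0)
    out = g.resample_to_bands(g.Spectrum(wl, np.full_like(wl, 0.2)))
    np.testing.assert_allclose(out.band_reflectance, 0.2, rtol=0, atol=1e-15)


def test_linear_spectrum_resamples_to_band_midpoint():
    wl = np.arange(400.0, 1001.0)
    spectrum = g.Spectrum(wl, 1e-4 * wl)  # linear in wavelength
    out = g.resample_to_bands(spectrum)
    nir = g.GF1_BANDS[3]
    midpoint = 0.5 * (nir.wavelength_lo + nir.wavelength_hi)
    assert midpoint == 830.0
    assert out.band_reflectance[3] == pytest.approx(1e-4 * midpoint, rel=1e-12)


def test_single_band_covering_grid_is_global_mean():
    wl = np.arange(400.0, 1001.0)
    refl = np.random.default_rng(0).uniform(0.1, 0.6, wl.size)
    band = g.BandDefinition("ALL", 400.0, 1000.0)
    out = g.resample_to_bands(g.Spectrum(wl, refl), [band])
    assert out.band_reflectance[0] == pytest.approx(refl.mean(), rel=1e-12)


def test_band_outside_coverage_names_the_band():
    wl = np.arange(400.0, 700.0)
    with pytest.raises(ValueError, match="B4"):
        g.resample_to_bands(g.Spectrum(wl, np.full_like(wl, 0.2)))


def test_resampling_preserves_bounds():
    rng = np.random.default_rng(5)
    wl = np.arange(400.0, 1001.0)
    refl = rng.uniform(0.05, 0.95, wl.size)
    out = g.resample_to_bands(g.Spectrum(wl, refl))
    assert np.all(out.band_reflectance >= refl.min())
    assert np.all(out.band_reflectance <= refl.max())


def test_response_curve_override():
    wl = np.arange(400.0, 1001.0)
    refl = 1e-3 * (wl - 400.0)
    w = np.zeros_like(wl)
    w[wl == 800.0] = 1.0  # delta response picks the value at 800 nm
    out = g.resample_to_bands(g.Spectrum(wl, refl), [g.GF1_BANDS[3]], response={"B4": w})
    assert out.band_reflectance[0] == pytest.approx(0.4, rel=1e-12)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def test_zero_noise_is_identity():
    s = g.SpectralSample([0.1, 0.2, 0.3, 0.4])
    out = g.add_noise(s, 0.0, seed=0)
    np.testing.assert_array_equal(out.band_reflectance, s.band_reflectance)


def test_noise_std_matches_sigma():
    base = np.full((10_000, 4), 0.5)
    noisy = g.add_noise(base, 0.01, seed=42)
    stds = noisy.std(axis=0)
    assert np.all(np.abs(stds - 0.01) < 0.05 * 0.01)


def test_noise_clipped_to_unit_interval():
    base = np.full((2000, 4), 0.999)
    noisy = g.add_noise(base, 0.05, seed=1)
    assert noisy.max() <= 1.0 and noisy.min() >= 0.0


def test_negative_sigma_rejected():
    with pytest.raises(ValueError):
        g.add_noise(g.SpectralSample([0.1, 0.2, 0.3, 0.4]), -0.01, seed=0)


@settings(max_examples=25, deadline=None)
@given(sigma=st.floats(0.001, 0.05), seed=st.integers(0, 2**16))
def test_noise_reproducible_and_bounded(sigma, seed):
    s = g.SpectralSample([0.2, 0.4, 0.1, 0.8])
    a = g.add_noise(s, sigma, seed=seed)
    b = g.add_noise(s, sigma, seed=seed)
    np.testing.assert_array_equal(a.band_reflectance, b.band_reflectance)
    assert a.band_reflectance.min() >= 0.0 and a.band_reflectance.max() <= 1.0
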