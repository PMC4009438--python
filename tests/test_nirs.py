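"""MBLL inversion and the denoising chain, with independent oracles."""

import numpy as np
import pytest

from nirseeg import paradigm as P
from nirseeg.errors import ConfigurationError, DataError, InvalidArgumentError
from nirseeg.nirs import (
    HemoglobinSeries,
    OpticalDensitySeries,
    OpticsConfig,
    causal_smooth,
    gaussian_lowpass,
    mbll_invert,
    nirs_features,
    optical_density,
    preprocess_nirs,
    wavelet_denoise,
)
from nirseeg.simulate import (
    SimulationConfig,
    forward_mbll,
    simulate_hemodynamics,
    simulate_session,
)


def _series(hbo, rate=1.81, hbr=None):
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    if hbo.shape[0] == 1:
        hbo = hbo.T
    hbr = -0.3 * hbo if hbr is None else hbr
    return HemoglobinSeries(hbo=hbo, hbr=hbr, rate=rate)


class TestOpticalDensity:
    def test_reference_intensity_maps_to_zero(self):
        inten = np.full((20, 12, 2), 3.7)
        od = optical_density(inten, 1.81)
        assert np.allclose(od.delta_a, 0.0)

    def test_one_neper_attenuation(self):
        inten = np.full((20, 12, 2), 2.0)
        inten[10:] /= np.e  # baseline interval covers the first samples only
        od = optical_density(inten, 1.81, baseline_interval=(0.0, 5.0))
        assert np.allclose(od.delta_a[10:], 1.0)

    def test_matches_forward_model_delta_a(self):
        cfg = SimulationConfig().noise_free()
        optics = OpticsConfig()
        _, hbo, hbr = simulate_hemodynamics(P.build_session(1), cfg)
        inten = forward_mbll(hbo, hbr, optics, cfg)
        od = optical_density(inten, cfg.nirs_rate, optics)
        ext = optics.extinction
        for w in range(2):
            expected = (ext[w, 0] * hbo + ext[w, 1] * hbr) * optics.l * optics.d[w]
            assert np.abs(od.delta_a[:, :, w] - expected).max() < 1e-12

    def test_non_positive_intensity_names_location(self):
        inten = np.full((10, 12, 2), 1.0)
        inten[3, 7, 1] = 0.0
        with pytest.raises(DataError, match="sample 3.*channel 8"):
            optical_density(inten, 1.81)


class TestMBLLInvert:
    def test_zero_od_gives_zero_concentration(self):
        od = OpticalDensitySeries(np.zeros((15, 12, 2)), 1.81)
        out = mbll_invert(od, OpticsConfig())
        assert np.all(out.hbo == 0.0) and np.all(out.hbr == 0.0)

    def test_identity_extinction_passthrough(self, rng):
        da = rng.normal(0, 1, (25, 12, 2))
        optics = OpticsConfig(
            extinction_hbo=(1.0, 0.0), extinction_hbr=(0.0, 1.0), l=1.0, d=(1.0, 1.0)
        )
        out = mbll_invert(OpticalDensitySeries(da, 1.81), optics)
        assert np.allclose(out.hbo, da[:, :, 0])
        assert np.allclose(out.hbr, da[:, :, 1])

    def test_matches_cofactor_closed_form(self, rng):
        """Independent oracle: explicit 2x2 cofactor solve per time point."""
        for _ in range(20):
            e = rng.uniform(0.2, 2.0, (2, 2))
            if abs(np.linalg.det(e)) < 1e-3:
                continue
            optics = OpticsConfig(
                extinction_hbo=(e[0, 0], e[1, 0]),
                extinction_hbr=(e[0, 1], e[1, 1]),
                l=rng.uniform(1, 4),
                d=tuple(rng.uniform(4, 8, 2)),
            )
            da = rng.normal(0, 0.05, (8, 3, 2))
            out = mbll_invert(OpticalDensitySeries(da, 1.81), optics)
            det = e[0, 0] * e[1, 1] - e[0, 1] * e[1, 0]
            for t in range(8):
                for c in range(3):
                    y1 = da[t, c, 0] / (optics.l * optics.d[0])
                    y2 = da[t, c, 1] / (optics.l * optics.d[1])
                    hbo = (e[1, 1] * y1 - e[0, 1] * y2) / det
                    hbr = (-e[1, 0] * y1 + e[0, 0] * y2) / det
                    assert out.hbo[t, c] == pytest.approx(hbo, rel=1e-9, abs=1e-12)
                    assert out.hbr[t, c] == pytest.approx(hbr, rel=1e-9, abs=1e-12)

    def test_linearity(self, rng):
        da1 = rng.normal(0, 0.1, (20, 12, 2))
        da2 = rng.normal(0, 0.1, (20, 12, 2))
        optics = OpticsConfig()
        a, b = 2.5, -1.25
        combo = mbll_invert(OpticalDensitySeries(a * da1 + b * da2, 1.81), optics)
        o1 = mbll_invert(OpticalDensitySeries(da1, 1.81), optics)
        o2 = mbll_invert(OpticalDensitySeries(da2, 1.81), optics)
        assert np.allclose(combo.hbo, a * o1.hbo + b * o2.hbo)
        assert np.allclose(combo.hbr, a * o1.hbr + b * o2.hbr)

    def test_singular_extinction_rejected(self):
        optics = OpticsConfig(extinction_hbo=(1.0, 2.0), extinction_hbr=(2.0, 4.0))
        with pytest.raises(ConfigurationError):
            mbll_invert(OpticalDensitySeries(np.zeros((5, 12, 2)), 1.81), optics)


class TestGaussianLowpass:
    def test_unit_dc_gain(self):
        s = _series(np.full(200, 4.2))
        out = gaussian_lowpass(s, 0.1)
        assert np.allclose(out.hbo, 4.2)

    def test_attenuates_above_cutoff(self):
        rate = 10.0
        t = np.arange(4000) / rate
        s = _series(np.sin(2 * np.pi * 0.9 * t), rate=rate)
        out = gaussian_lowpass(s, 0.1)
        mid = slice(500, 3500)  # avoid edge effects
        assert np.abs(out.hbo[mid]).max() < 0.05

    def test_reduces_white_noise_variance(self, rng):
        s = _series(rng.normal(0, 1, 500))
        out = gaussian_lowpass(s, 0.1)
        assert out.hbo.var() < s.hbo.var()

    def test_preserves_shape_and_rate(self, rng):
        s = _series(rng.normal(0, 1, (300, 12)).T[0])  # 300 x 1
        out = gaussian_lowpass(s, 0.1)
        assert out.hbo.shape == s.hbo.shape and out.rate == s.rate

    @pytest.mark.parametrize("cutoff", [0.0, -0.1, 0.905, 2.0])
    def test_invalid_cutoff(self, cutoff):
        with pytest.raises(InvalidArgumentError):
            gaussian_lowpass(_series(np.zeros(50)), cutoff)


class TestWaveletDenoise:
    def test_zero_in_zero_out(self):
        out = wavelet_denoise(_series(np.zeros(400)))
        assert np.allclose(out.hbo, 0.0)

    def test_smooth_ramp_untouched(self):
        out = wavelet_denoise(_series(np.linspace(0.0, 5.0, 512)))
        assert np.abs(out.hbo[:, 0] - np.linspace(0.0, 5.0, 512)).max() < 1e-8

    def test_improves_rmse_on_noisy_boxcar(self, rng):
        clean = np.zeros(600)
        clean[200:320] = 2.0
        noisy = clean + rng.normal(0, 0.4, 600)
        out = wavelet_denoise(_series(noisy))
        rmse_before = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_after = np.sqrt(np.mean((out.hbo[:, 0] - clean) ** 2))
        assert rmse_after < rmse_before

    def test_infeasible_level_rejected(self):
        with pytest.raises(InvalidArgumentError):
            wavelet_denoise(_series(np.zeros(32)), level=6)
        with pytest.raises(InvalidArgumentError):
            wavelet_denoise(_series(np.zeros(400)), level=0)


class TestNirsFeatures:
    def test_constant_window_mean(self):
        s = _series(np.full(100, 2.0))
        w = P.EpochWindow(10.0, 30.0, P.MENTAL_ARITHMETIC, "nirs")
        hbo, hbr = nirs_features(s, w)
        assert hbo == pytest.approx(2.0)
        assert hbr == pytest.approx(-0.6)

    def test_antisymmetric_window_mean_zero(self):
        x = np.concatenate([np.ones(50), -np.ones(50)])
        s = _series(x, rate=10.0)
        hbo, _ = nirs_features(s, P.EpochWindow(0.0, 10.0, P.REST, "nirs"))
        assert hbo == pytest.approx(0.0)

    def test_bad_requests_rejected(self):
        s = _series(np.zeros(50))
        with pytest.raises(InvalidArgumentError):
            nirs_features(s, P.EpochWindow(0.0, 100.0, P.REST, "nirs"))
        with pytest.raises(InvalidArgumentError):
            nirs_features(s, P.EpochWindow(0.0, 10.0, P.REST, "nirs"), channels=[])


class TestFullChain:
    def test_recovers_ground_truth_correlation(self):
        """simulate -> OD -> MBLL -> Gaussian recovers truth with r > 0.9."""
        for seed in range(5):
            rec = simulate_session(SimulationConfig(seed=seed), n_samples=2)
            series = preprocess_nirs(rec.nirs_intensity, rec.nirs_rate)
            r = np.corrcoef(series.hbo.mean(axis=1), rec.truth_hbo.mean(axis=1))[0, 1]
            assert r > 0.9

    def test_chain_preserves_shape_and_rate(self, noisy_session):
        series = preprocess_nirs(noisy_session.nirs_intensity, noisy_session.nirs_rate)
        assert series.hbo.shape == noisy_session.truth_hbo.shape
        assert series.rate == noisy_session.nirs_rate

    def test_mental_blocks_separable_from_rest(self):
        """Mean recovered HbO in mental blocks beats rest in >= 95% of seeds."""
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rec = simulate_session(SimulationConfig(seed=seed), n_samples=1)
            series = preprocess_nirs(rec.nirs_intensity, rec.nirs_rate)
            x = series.hbo.mean(axis=1)
            t = series.times
            lab = np.array([rec.schedule.label_at(v) for v in t])
            mental = np.isin(lab, P.MENTAL_LABELS)
            wins += x[mental].mean() > x[lab == P.REST].mean()
        assert wins >= 0.95 * n_seeds


class TestCausalSmooth:
    def test_trailing_average_is_causal(self, rng):
        x = rng.normal(0, 1, 100)
        full = causal_smooth(x, 1.81, 3.0)
        trunc = causal_smooth(x[:60], 1.81, 3.0)
        assert np.allclose(full[:60], trunc)
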