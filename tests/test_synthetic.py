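"""Generators: exactness of fGn, cascade mass conservation, coupling,
random-network statistics, feature-table balance."""

import numpy as np
import pytest
from scipy.signal import welch

import dfcomplexity as dfc
from dfcomplexity import (
    InvalidParameterError,
    RandomNetworkSpec,
    fgn_autocovariance,
    gen_cascade,
    gen_coupled_recording,
    gen_fgn,
    gen_random_dynamic_networks,
    gen_two_group_features,
)


class TestFGN:
    def test_h_half_is_white_noise(self):
        x = gen_fgn(2**14, 0.5, seed=0).values
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 0.03

    def test_deterministic_under_seed(self):
        a = gen_fgn(1024, 0.8, seed=7).values
        b = gen_fgn(1024, 0.8, seed=7).values
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("hurst", [-0.1, 0.0, 1.0, 1.5])
    def test_invalid_hurst_rejected(self, hurst):
        with pytest.raises(InvalidParameterError):
            gen_fgn(64, hurst, seed=0)

    @pytest.mark.parametrize("hurst", [0.3, 0.8])
    def test_empirical_autocovariance_matches_closed_form(self, hurst):
        # lags 0..5, averaged over 50 seeds of n=2^15, within 4 s.e.
        lags = np.arange(6)
        acv = []
        for seed in range(50):
            x = gen_fgn(2**15, hurst, seed=seed).values
            acv.append([np.mean(x[: len(x) - k] * x[k:]) for k in lags])
        acv = np.asarray(acv)
        mean = acv.mean(axis=0)
        se = acv.std(axis=0, ddof=1) / np.sqrt(len(acv))
        theory = fgn_autocovariance(hurst, lags)
        assert np.all(np.abs(mean - theory) < 4 * np.maximum(se, 1e-6))


class TestCascade:
    def test_mass_conserved(self):
        for levels, p in [(8, 0.3), (12, 0.25), (10, 0.45)]:
            c = gen_cascade(levels, p, seed=1)
            assert len(c) == 2**levels
            assert abs(c.values.sum() - 1.0) < 1e-12

    def test_degenerate_half_is_constant(self):
        c = gen_cascade(8, 0.5, seed=0)
        assert np.ptp(c.values) < 1e-15
        assert dfc.cascade_singularity_support(0.5) == 0.0

    def test_analytic_support_width(self):
        # closed form: log2((1-p)/p) for p < 1/2
        assert dfc.cascade_singularity_support(0.25) == pytest.approx(np.log2(3))

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2])
    def test_invalid_p_rejected(self, p):
        with pytest.raises(InvalidParameterError):
            gen_cascade(8, p, seed=0)

    def test_estimated_width_exceeds_fgn_width(self):
        # paired seeds: cascade p=0.3 is multifractal, fGn is not
        wins = 0
        for seed in range(20):
            fw_c = dfc.mf_spectrum(gen_cascade(15, 0.3, seed)).fwhm
            fw_g = dfc.mf_spectrum(gen_fgn(2**15, 0.7, seed)).fwhm
            wins += fw_c > fw_g
        assert wins >= 19


class TestCoupledRecording:
    def test_shape_and_band_limitation(self):
        fs, band = 250.0, (8.0, 13.0)
        rec = gen_coupled_recording(3, 2**13, fs, band, np.eye(3), 0.0, seed=2)
        assert rec.samples.shape == (3, 2**13)
        f, p = welch(rec.samples[0], fs=fs, nperseg=2048)
        in_band = p[(f >= band[0]) & (f <= band[1])].mean()
        out_band = p[(f >= 40) & (f <= 60)].mean()
        assert 10 * np.log10(in_band / out_band) >= 20.0

    def test_common_source_synchronizes_channels(self, toy_sl_params):
        mixing = np.ones((2, 1))  # one shared source, no noise
        rec = gen_coupled_recording(2, 1200, 250.0, (0.5, 4.0), mixing, 0.0, seed=3)
        t = dfc.sl_dynamic(rec, toy_sl_params)
        assert np.all(t.weights[:, 0, 1] == pytest.approx(1.0, abs=1e-9))

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(dfc.InvalidBandError):
            gen_coupled_recording(2, 512, 100.0, (10.0, 60.0), np.eye(2), 0.1, seed=0)


class TestRandomNetworks:
    def test_weight_statistics_and_determinism(self):
        spec = RandomNetworkSpec(
            n_nodes=10, n_timepoints=400, n_networks=2, seed=11
        )
        tensors = list(gen_random_dynamic_networks(spec))
        assert len(tensors) == 2
        flat = np.concatenate([t.upper_triangle().ravel() for t in tensors])
        se = np.sqrt(spec.edge_variance / len(flat))
        assert abs(flat.mean() - spec.edge_mean) < 3 * se
        assert np.std(flat) == pytest.approx(np.sqrt(spec.edge_variance), rel=0.05)
        again = list(gen_random_dynamic_networks(spec))
        np.testing.assert_array_equal(tensors[0].weights, again[0].weights)
        np.testing.assert_array_equal(tensors[1].weights, again[1].weights)

    def test_slices_symmetric_zero_diagonal(self):
        spec = RandomNetworkSpec(n_nodes=6, n_timepoints=50, n_networks=1, seed=0)
        (t,) = gen_random_dynamic_networks(spec)
        np.testing.assert_array_equal(t.weights, t.weights.transpose(0, 2, 1))
        assert np.all(t.weights[:, np.arange(6), np.arange(6)] == 0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(InvalidParameterError):
            RandomNetworkSpec(cost=0.0)
        with pytest.raises(InvalidParameterError):
            RandomNetworkSpec(edge_variance=-1.0)


class TestTwoGroupFeatures:
    def test_balance_and_determinism(self):
        ft = gen_two_group_features(14, 21, (0, 1), 1.0, seed=5)
        assert (ft["group"] == "HC").sum() == 14
        assert (ft["group"] == "SZ").sum() == 14
        ft2 = gen_two_group_features(14, 21, (0, 1), 1.0, seed=5)
        assert ft.equals(ft2)

    def test_shift_lands_on_requested_features(self):
        ft = gen_two_group_features(200, 4, (2,), 3.0, seed=6)
        hc = ft[ft["group"] == "HC"]
        sz = ft[ft["group"] == "SZ"]
        gap = (sz.mean(numeric_only=True) - hc.mean(numeric_only=True)).abs()
        assert gap["f02"] > 2.5
        assert gap[["f00", "f01", "f03"]].max() < 0.5

    def test_out_of_range_shift_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_two_group_features(5, 3, (3,), 1.0, seed=0)
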