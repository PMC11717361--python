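import numpy as np
import pytest

from retseq.preprocess import Trace, detrend
from retseq.receptive_fields import (
    clipped_gradient,
    decompose_rf,
    estimate_rf,
    estimate_rf_spikes,
    fit_dog,
    temporal_fwhm,
)
from retseq.stimulus import make_dense_noise
from retseq.synth import CellArchetype, make_archetype_bank, simulate_response


class TestClippedGradient:
    def test_monotone_decreasing_all_zero(self):
        tr = Trace(np.linspace(5, 0, 50), fs=10.0)
        assert np.all(clipped_gradient(tr).samples == 0)

    def test_direct_diff_convention(self):
        tr = Trace(np.array([0.0, 1.0, 0.0, 2.0]), fs=1.0)
        out = clipped_gradient(tr)
        assert np.allclose(out.samples, [1.0, 0.0, 2.0])
        assert len(out.samples) == 3

    def test_sine_gives_positive_cosine_halfwave(self):
        fs = 200.0
        t = np.arange(0, 2, 1 / fs)
        tr = Trace(np.sin(2 * np.pi * t), fs=fs)
        out = clipped_gradient(tr)
        expected = np.maximum(0.0, 2 * np.pi * np.cos(2 * np.pi * t[:-1]))
        assert np.max(np.abs(out.samples - expected)) < 0.2  # discretization

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            clipped_gradient(Trace(np.array([1.0]), fs=1.0))


class TestEstimateRF:
    def test_zero_weights_rejected(self, small_noise):
        w = Trace(np.zeros(400), fs=7.8125)
        with pytest.raises(ValueError):
            estimate_rf(w, small_noise)

    def test_single_unit_weight_sifts_stimulus(self):
        """One unit weight at t0 makes F(x,y,tau) = S(x,y,t0-tau) exactly."""
        stim = make_dense_noise(6, 5, rate=5.0, duration_s=20.0, seed=3)
        w = np.zeros(stim.n_frames)
        i0 = 50
        w[i0] = 1.0
        rf = estimate_rf(Trace(w, fs=stim.rate), stim, upsample=1,
                         lag_range_s=(0.0, 1.0), smooth=False)
        S = stim.frames.astype(float) - 0.5
        for j, lag in enumerate(rf.lags_s):
            frame = i0 - int(round(lag * stim.rate))
            assert np.array_equal(rf.F[:, :, j], S[:, :, frame])

    def test_linear_in_weights(self, small_noise):
        rng = np.random.default_rng(0)
        w1 = np.abs(rng.normal(size=small_noise.n_frames))
        w2 = np.abs(rng.normal(size=small_noise.n_frames))
        kw = dict(upsample=1, lag_range_s=(0.0, 0.6), smooth=False)
        f1 = estimate_rf(Trace(w1, fs=small_noise.rate), small_noise, **kw).F
        f2 = estimate_rf(Trace(w2, fs=small_noise.rate), small_noise, **kw).F
        f12 = estimate_rf(Trace(w1 + w2, fs=small_noise.rate), small_noise,
                          **kw).F
        assert np.allclose(f12, f1 + f2, atol=1e-9)

    def test_ln_cell_spatial_filter_recovered(self):
        stim = make_dense_noise(duration_s=300.0, seed=21)
        arch = make_archetype_bank("ln-basic")[0]
        m = simulate_response(arch, stim, n_reps=1, seed=2)
        grad = clipped_gradient(detrend(Trace(m.values[:, 0], m.fs)))
        rf = estimate_rf(grad, stim)
        dec = decompose_rf(rf)
        gen = arch.spatial_filter(stim.rows, stim.cols)
        r = np.corrcoef(dec.Fs.ravel(), gen.ravel())[0, 1]
        assert abs(r) > 0.8

    def test_spike_sta_shape(self):
        stim = make_dense_noise(duration_s=60.0, seed=5)
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, 60.0, 500))
        rf = estimate_rf_spikes(spikes, stim, n_lags=40)
        assert rf.F.shape == (stim.rows, stim.cols, 40)
        assert rf.source == "spike"


class TestDecomposeRF:
    def test_separable_rf_qi_one(self):
        rng = np.random.default_rng(0)
        fs = rng.normal(size=(10, 8))
        ft = np.sin(np.linspace(0, 3, 20))
        F = fs[:, :, None] * ft[None, None, :]
        from retseq.receptive_fields import ReceptiveField3D
        rf = ReceptiveField3D(F=F, lags_s=np.linspace(0, 1, 20), source="spike")
        dec = decompose_rf(rf)
        assert dec.qi_rf == pytest.approx(1.0, abs=1e-10)

    def test_scaling_conventions(self):
        rng = np.random.default_rng(1)
        F = rng.normal(size=(6, 6, 15))
        from retseq.receptive_fields import ReceptiveField3D
        rf = ReceptiveField3D(F=F, lags_s=np.linspace(0, 1, 15), source="spike")
        dec = decompose_rf(rf)
        assert np.max(np.abs(dec.Ft)) == pytest.approx(1.0)
        assert np.max(np.abs(dec.Fs)) == pytest.approx(np.max(np.abs(F)))

    def test_nonseparable_noise_fails_gate(self):
        """Strongly non-separable structure scores below the 0.45 gate."""
        rng = np.random.default_rng(2)
        F = rng.normal(size=(8, 8, 20))   # rank ~20, no dominant product term
        from retseq.receptive_fields import ReceptiveField3D
        rf = ReceptiveField3D(F=F, lags_s=np.linspace(0, 1, 20), source="spike")
        assert decompose_rf(rf).qi_rf < 0.45

    def test_all_zero_errors(self):
        from retseq.receptive_fields import ReceptiveField3D
        rf = ReceptiveField3D(F=np.zeros((4, 4, 5)),
                              lags_s=np.linspace(0, 1, 5), source="spike")
        with pytest.raises(ValueError):
            decompose_rf(rf)


class TestDoGFit:
    def _gauss(self, sx=2.0, sy=2.0, x0=7.0, y0=10.0, rows=20, cols=15):
        yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return np.exp(-0.5 * (((xx - x0) / sx) ** 2 + ((yy - y0) / sy) ** 2))

    def test_pure_gaussian_area_analytic(self):
        """Isotropic sigma=2 checks of 40 um: 2-sigma area = 4*pi*(80 um)^2."""
        res = fit_dog(self._gauss(), check_um=40.0, seed=0)
        assert res.surround_index == pytest.approx(0.0, abs=1e-6)
        assert res.center_area_um2 == pytest.approx(4 * np.pi * 80 * 80,
                                                    rel=0.05)

    def test_negation_flips_polarity_keeps_surround(self):
        G = self._gauss() - 0.3 * self._gauss(sx=4.0, sy=4.0)
        pos = fit_dog(G, seed=0)
        neg = fit_dog(-G, seed=0)
        assert pos.polarity == 1 and neg.polarity == -1
        assert neg.surround_index == pytest.approx(pos.surround_index,
                                                   abs=1e-6)

    def test_generative_dog_recovered(self):
        G = (self._gauss(sx=1.8, sy=1.5)
             - 0.3 * self._gauss(sx=3.6, sy=3.0))
        res = fit_dog(G, seed=0)
        assert res.fit.sigma_x == pytest.approx(1.8, rel=0.15)
        assert res.fit.sigma_y == pytest.approx(1.5, rel=0.15)
        assert np.hypot(res.fit.center_xy[0] - 7.0,
                        res.fit.center_xy[1] - 10.0) < 0.5
        assert res.fit.surround_scale == pytest.approx(0.3, rel=0.15)

    def test_surround_index_range(self):
        G = self._gauss() - 0.4 * self._gauss(sx=5.0, sy=5.0)
        res = fit_dog(G, seed=0)
        assert -1.0 <= res.surround_index <= 0.0


class TestTemporalFWHM:
    def test_triangular_lobe(self):
        lag = np.arange(101) * 0.001
        tri = np.concatenate([np.linspace(0, 1, 51), np.linspace(1, 0, 51)[1:]])
        w, ok = temporal_fwhm(tri, lag)
        assert ok and w == pytest.approx(0.050, abs=1e-9)

    def test_one_sided_exponential_analytic(self):
        lag = np.arange(0, 1.0, 0.0005)
        w, ok = temporal_fwhm(-np.exp(-lag / 0.2), lag)
        assert not ok                      # extremum at the grid boundary
        assert w == pytest.approx(0.2 * np.log(2), rel=0.01)

    def test_time_compression_scales_width(self):
        lag = np.arange(0, 2.0, 0.0005)
        kernel = -(lag / 0.1) * np.exp(1 - lag / 0.1)
        w1, _ = temporal_fwhm(kernel, lag)
        kernel_fast = -(lag * 2 / 0.1) * np.exp(1 - lag * 2 / 0.1)
        w2, _ = temporal_fwhm(kernel_fast, lag)
        assert w2 == pytest.approx(w1 / 2, rel=0.02)


class TestDrugKineticsProperty:
    def test_kappa_speeds_fwhm_leaves_area(self):
        """Speeding the generative temporal kernel shrinks the measured FWHM
        but leaves the fitted spatial ellipse area unchanged (within 10%)."""
        stim = make_dense_noise(duration_s=300.0, seed=31)
        arch = make_archetype_bank("ln-basic")[0]
        out = {}
        for tag, kappa in (("ctrl", 1.0), ("drug", 1.6)):
            a = arch.with_drug(0.0, kappa)
            m = simulate_response(a, stim, n_reps=1, seed=7)
            grad = clipped_gradient(detrend(Trace(m.values[:, 0], m.fs)))
            dec = decompose_rf(estimate_rf(grad, stim))
            w, _ = temporal_fwhm(dec.Ft, dec.lags_s)
            res = fit_dog(dec.Fs, check_um=stim.check_um, seed=0)
            out[tag] = (w, res.center_area_um2)
        assert out["drug"][0] < out["ctrl"][0]
        assert out["drug"][1] == pytest.approx(out["ctrl"][1], rel=0.10)
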