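import numpy as np
import pytest

from retseq.preprocess import (
    ResponseMatrix,
    Trace,
    compute_psth,
    detrend,
    normalize_average,
    preferred_direction_average,
    snippet_and_average,
)

FS = 7.8125


def make_trace(samples, fs=FS):
    return Trace(samples=np.asarray(samples, float), fs=fs)


class TestDetrend:
    def test_constant_trace_maps_to_zero(self):
        tr = make_trace(np.full(1000, 3.7))
        out = detrend(tr)
        assert np.max(np.abs(out.samples)) < 1e-9

    def test_slow_drift_removed_fast_transient_kept(self):
        t = np.arange(2000) / FS
        slow = np.sin(2 * np.pi * t / 120.0)
        fast = np.exp(-0.5 * ((t - 120) / 0.3) ** 2)
        slow_out = detrend(make_trace(slow)).samples
        fast_out = detrend(make_trace(fast)).samples
        assert np.max(np.abs(slow_out)) < 0.1 * np.max(np.abs(slow))
        mid = slice(800, 1100)
        assert np.max(np.abs(fast_out[mid])) > 0.9 * np.max(np.abs(fast))

    def test_linearity(self, rng):
        a = rng.normal(size=1500)
        b = rng.normal(size=1500)
        da = detrend(make_trace(a)).samples
        db = detrend(make_trace(b)).samples
        dab = detrend(make_trace(a + b)).samples
        assert np.allclose(dab, da + db, atol=1e-10)

    def test_idempotent_on_detrended_content(self, rng):
        """Once the slow content is gone, a second pass changes almost
        nothing (fast transients ride on a slow drift)."""
        t = np.arange(3000) / FS
        slow = 2.0 * np.sin(2 * np.pi * t / 150.0) + 0.01 * t
        fast = sum(a * np.sin(2 * np.pi * f * t + p)
                   for a, f, p in zip(rng.uniform(0.5, 1, 8),
                                      rng.uniform(0.5, 2.5, 8),
                                      rng.uniform(0, 6.28, 8)))
        once = detrend(make_trace(slow + fast)).samples
        twice = detrend(make_trace(once)).samples
        rms = np.sqrt(np.mean(once ** 2))
        assert np.sqrt(np.mean((twice - once) ** 2)) < 0.01 * rms

    def test_short_trace_errors_with_advice(self):
        with pytest.raises(ValueError, match="window"):
            detrend(make_trace(np.zeros(50)))


class TestSnippetAndAverage:
    def test_identical_snippets_average_to_each(self):
        template = np.array([0, 1.0, 2.0, 1.0, 0, 0, 0, 0])
        trace = make_trace(np.tile(template, 3), fs=1.0)
        matrix, mean = snippet_and_average(trace, [0.0, 8.0, 16.0], 8.0)
        assert matrix.n_reps == 3
        assert np.allclose(mean, template)

    def test_offgrid_triggers_align_to_nearest_sample(self):
        trace = make_trace(np.arange(20.0), fs=1.0)
        matrix, _ = snippet_and_average(trace, [4.4], 3.0)
        assert np.allclose(matrix.values[:, 0], [4.0, 5.0, 6.0])

    def test_out_of_range_triggers_dropped(self):
        trace = make_trace(np.arange(20.0), fs=1.0)
        matrix, _ = snippet_and_average(trace, [-5.0, 2.0, 19.0], 3.0)
        assert matrix.n_reps == 1
        with pytest.raises(ValueError):
            snippet_and_average(trace, [50.0], 3.0)

    def test_mean_converges_to_template(self, rng):
        template = np.sin(np.linspace(0, 2 * np.pi, 10))
        sigma = 0.5
        reps = template[None, :] + rng.normal(0, sigma, size=(200, 10))
        trace = make_trace(reps.ravel(), fs=1.0)
        triggers = np.arange(200) * 10.0
        _, mean = snippet_and_average(trace, triggers, 10.0)
        assert np.all(np.abs(mean - template) < 4 * sigma / np.sqrt(200))


class TestNormalizeAverage:
    def test_flat_trace_degenerate(self):
        avg = normalize_average(np.ones(4), fs=1.0, baseline_s=4.0)
        assert avg.degenerate
        assert np.all(avg.values == 0)

    def test_negative_peak_scaling(self):
        trace = np.array([0.0, 0.0, -2.0, -1.0])
        avg = normalize_average(trace, fs=1.0, baseline_s=2.0)
        assert np.max(np.abs(avg.values)) == pytest.approx(1.0)
        assert avg.values[2] == pytest.approx(-1.0)

    def test_contract_on_random_trace(self, rng):
        trace = rng.normal(size=100)
        avg = normalize_average(trace, fs=10.0, baseline_s=1.0)
        assert abs(np.mean(avg.values[:10])) < 1e-10
        assert np.max(np.abs(avg.values)) == pytest.approx(1.0)

    def test_idempotence(self, rng):
        trace = rng.normal(size=80) + 2.0
        once = normalize_average(trace, fs=10.0)
        twice = normalize_average(once.values, fs=10.0)
        assert np.allclose(once.values, twice.values, atol=1e-12)


class TestPreferredDirection:
    def _mats(self, energies, fs=8.0):
        out = {}
        for d, e in zip(range(0, 360, 45), energies):
            vals = np.zeros((16, 2))
            vals[4:8, :] = e
            out[float(d)] = ResponseMatrix(values=vals, fs=fs)
        return out

    def test_dominant_direction_selected(self):
        mats = self._mats([1, 1, 10, 1, 1, 1, 1, 1])
        avg = preferred_direction_average(mats)
        assert avg.meta["preferred_direction_deg"] == 90.0

    def test_tie_breaks_to_lowest_direction(self):
        mats = self._mats([5, 5, 5, 5, 5, 5, 5, 5])
        avg = preferred_direction_average(mats)
        assert avg.meta["preferred_direction_deg"] == 0.0

    def test_von_mises_tuned_cell_recovered(self, bar):
        """A direction-selective cell's selected direction is within one
        45-degree step of its generative preferred direction."""
        from retseq.synth import CellArchetype, simulate_response
        arch = CellArchetype(type_label="ds", polarity=1, baseline=0.2,
                             gain=2.0, ds_kappa=2.0,
                             preferred_direction_deg=135.0, noise_sd=0.05)
        mats = {d: simulate_response(arch, bar, 3, seed=int(d), direction_deg=d)
                for d in bar.directions_deg}
        avg = preferred_direction_average(mats)
        diff = abs(avg.meta["preferred_direction_deg"] - 135.0) % 360
        assert min(diff, 360 - diff) <= 45.0

    def test_requires_eight_directions(self):
        mats = self._mats([1] * 8)
        del mats[0.0]
        with pytest.raises(ValueError):
            preferred_direction_average(mats)


class TestPSTH:
    def test_no_spikes_all_zero(self):
        psth = compute_psth(np.array([]), [0.0], 1.0, bin_s=0.1)
        assert np.all(psth.samples == 0)

    def test_single_spike_rate_conversion(self):
        psth = compute_psth(np.array([0.05]), [0.0], 1.0, bin_s=0.1)
        assert psth.samples[0] == pytest.approx(10.0)
        assert np.all(psth.samples[1:] == 0)

    def test_homogeneous_poisson_rate_recovered(self, rng):
        rate, n_trials, dur = 20.0, 100, 2.0
        spikes = []
        for i in range(n_trials):
            n = rng.poisson(rate * dur)
            spikes.append(rng.uniform(0, dur, n) + i * dur)
        spikes = np.concatenate(spikes)
        triggers = np.arange(n_trials) * dur
        psth = compute_psth(spikes, triggers, dur, bin_s=0.1)
        se = np.sqrt(rate / (n_trials * 0.1))
        assert np.all(np.abs(psth.samples - rate) < 4 * se)

    def test_spike_count_conservation(self, rng):
        """PSTH integral x n_triggers equals the number of counted spikes."""
        spikes = np.sort(rng.uniform(0, 40, 500))
        triggers = np.arange(0, 40, 4.0)
        psth = compute_psth(spikes, triggers, 4.0, bin_s=0.1)
        total = psth.samples.sum() * 0.1 * len(triggers)
        counted = sum(((spikes >= t) & (spikes < t + 4.0)).sum()
                      for t in triggers)
        assert total == pytest.approx(counted)

    def test_no_triggers_errors(self):
        with pytest.raises(ValueError):
            compute_psth(np.array([1.0]), [], 1.0)
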