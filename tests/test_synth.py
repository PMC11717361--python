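import numpy as np
import pytest
from dataclasses import replace

from retseq.metrics import suppression_index
from retseq.preprocess import normalize_average
from retseq.synth import (
    CellArchetype,
    EffectSpec,
    make_archetype_bank,
    make_effect_spec,
    simulate_paired_experiment,
    simulate_response,
    simulate_spikes,
)

from conftest import gray_stimulus


class TestArchetypeBank:
    def test_unknown_preset_lists_presets(self):
        with pytest.raises(ValueError, match="g32-default"):
            make_archetype_bank("nope")

    def test_ln_basic_has_unsuppressed_on_cell(self):
        bank = make_archetype_bank("ln-basic")
        assert any(a.polarity == 1 and a.w_sup == 0 for a in bank)

    def test_g32_archetypes_are_suppressed_by_contrast(self, chirp):
        """Tonic activity drops below the gray-screen level during the
        frequency sweep for every g32 archetype."""
        for arch in make_archetype_bank("g32-default"):
            assert arch.baseline > 0 and arch.w_sup > 0
            quiet = replace(arch, noise_sd=0.0)
            m = simulate_response(quiet, chirp, n_reps=1, seed=0)
            t = np.arange(m.n_samples) / m.fs
            sweep = (t >= 10.5) & (t < 18)   # frequency sweep
            gray = t < 2.0
            assert m.values[sweep, 0].mean() < m.values[gray, 0].mean()

    def test_mixed_population_has_control_group(self):
        eff = make_effect_spec("mixed-population")
        bank = make_archetype_bank("mixed-population")
        assert any(eff.category(a.type_label) == "stable" for a in bank)


class TestEffectSpec:
    def test_rho_bounds_validated(self):
        with pytest.raises(ValueError):
            EffectSpec(drug={"x": (1.5, 1.0)})
        with pytest.raises(ValueError):
            EffectSpec(drug={"x": (0.5, 0.5)})

    def test_identity_effect_is_stable(self):
        eff = EffectSpec(drug={"x": (0.0, 1.0)}, adaptation={"x": {"on": 1.0}})
        assert eff.category("x") == "stable"


class TestSimulateResponse:
    def test_noiseless_repetitions_identical(self, chirp):
        arch = replace(make_archetype_bank("g32-default")[0], noise_sd=0.0)
        m = simulate_response(arch, chirp, n_reps=3, seed=0)
        assert np.array_equal(m.values[:, 0], m.values[:, 1])
        assert np.array_equal(m.values[:, 0], m.values[:, 2])

    def test_seed_reproducibility(self, chirp):
        arch = make_archetype_bank("g32-default")[0]
        a = simulate_response(arch, chirp, n_reps=4, seed=9)
        b = simulate_response(arch, chirp, n_reps=4, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_gray_stimulus_gives_filtered_baseline(self):
        arch = replace(make_archetype_bank("g32-default")[0], noise_sd=0.0)
        stim = gray_stimulus()
        m = simulate_response(arch, stim, n_reps=1, seed=0)
        assert np.allclose(m.values[:, 0], arch.baseline, atol=1e-6)

    def test_noise_mean_converges_to_noiseless(self, chirp):
        arch = make_archetype_bank("g32-default")[1]
        noiseless = simulate_response(replace(arch, noise_sd=0.0), chirp,
                                      n_reps=1, seed=0).values[:, 0]
        noisy = simulate_response(arch, chirp, n_reps=200, seed=5)
        se = arch.noise_sd / np.sqrt(200)
        assert np.all(np.abs(noisy.mean() - noiseless) < 4 * se)

    def test_n_reps_validated(self, chirp):
        arch = make_archetype_bank("g32-default")[0]
        with pytest.raises(ValueError):
            simulate_response(arch, chirp, n_reps=0)


class TestSimulateSpikes:
    def test_zero_activity_gives_no_spikes(self):
        arch = CellArchetype(type_label="dead", baseline=0.0, gain=0.0)
        spikes = simulate_spikes(arch, gray_stimulus(), 50.0, seed=0)
        assert len(spikes) == 0

    def test_constant_rate_count_within_poisson_bound(self):
        arch = CellArchetype(type_label="tonic", baseline=1.0, gain=0.0,
                             spike_scale=10.0)
        spikes = simulate_spikes(arch, gray_stimulus(), 100.0, seed=0)
        # 10 Hz x 100 s = 1000 expected; 2 ms dead time removes ~2%
        assert abs(len(spikes) - 1000) < 4 * np.sqrt(1000) + 20

    def test_dead_time_enforced(self, chirp):
        arch = make_archetype_bank("g32-default")[0]
        arch = replace(arch, spike_scale=50.0)
        spikes = simulate_spikes(arch, chirp, 60.0, seed=1)
        assert np.min(np.diff(spikes)) >= 0.002


class TestPairedExperiment:
    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError, match="protocol"):
            simulate_paired_experiment("ln-basic", "wash-out")

    def test_identity_effect_noiseless_recs_identical(self, windows):
        """With no adaptation, no drug, and no noise, rec1 == rec2."""
        arch = replace(make_archetype_bank("ln-basic")[0], noise_sd=0.0)
        m1 = simulate_response(arch, gray_stimulus(), 2, seed=1)
        m2 = simulate_response(arch, gray_stimulus(), 2, seed=2,
                               gain_windows={}, windows=windows)
        assert np.array_equal(m1.values, m2.values)

    def test_adaptation_gain_localized_to_window(self, chirp, windows):
        """A gain cut in one feature window shows up (nearly) only there."""
        arch = CellArchetype(type_label="on", polarity=1, baseline=0.3,
                             gain=2.0, tau_k=0.2, tau_ca=0.2, noise_sd=0.0)
        m1 = simulate_response(arch, chirp, 1, seed=0)
        m2 = simulate_response(arch, chirp, 1, seed=0,
                               gain_windows={"low_freq": 0.5}, windows=windows)
        delta = m2.values[:, 0] - m1.values[:, 0]
        t = np.arange(len(delta)) / m1.fs
        lo, hi = windows.window("low_freq")
        inside = np.abs(delta[(t >= lo) & (t < hi)]).mean()
        outside = np.abs(delta[(t < lo - 0.5) | (t >= hi + 0.5)]).mean()
        assert inside > 10 * outside
        assert delta[(t >= lo) & (t < hi)].mean() < 0

    def test_drug_reduces_suppression_index(self, chirp):
        """Larger rho monotonically lowers the post-drug SI of an SbC cell."""
        arch = replace(make_archetype_bank("g32-default")[0], noise_sd=0.0)
        sis = []
        for rho in (0.0, 0.4, 0.8):
            m = simulate_response(arch.with_drug(rho, 1.0), chirp, 1, seed=0)
            avg = normalize_average(m.mean(), m.fs)
            sis.append(suppression_index(avg).si)
        assert sis[0] > sis[1] > sis[2]

    def test_cell_ids_match_and_ground_truth_stored(self):
        exp = simulate_paired_experiment("ln-basic", "ctrl-drug", seed=0,
                                         n_cells_per_type=3, n_reps=2)
        assert all(c.archetype is not None for c in exp.cells)
        assert len(set(exp.cell_ids)) == len(exp.cells)
        assert exp.ground_truth_category("on") == "stable"
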