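"""Generative model: tuning draws, rate composition, determinism, planted
structure."""

import dataclasses

import numpy as np
import pytest

from speechbci.io import dataset_checksum
from speechbci.rsa import rsa_correlation, similarity_matrix
from speechbci.simulator import (SimConfig, make_tuning,
                                 random_condition_targets,
                                 random_walk_day_offsets, softplus,
                                 synthesize_dataset, synthesize_delay_task,
                                 synthesize_trial)

NOISELESS = dict(poisson=False, sbp_noise_sd=0.0, drift_hz_per_min=0.0)


class TestMakeTuning:
    def test_same_seed_identical(self, table):
        a = make_tuning(16, table, SimConfig(), seed=7)
        b = make_tuning(16, table, SimConfig(), seed=7)
        assert np.array_equal(a.W, b.W) and np.array_equal(a.b, b.b)

    def test_zero_tuning_sd_gives_untuned_population(self, table):
        t = make_tuning(8, table, SimConfig(tuning_sd_hz=0.0), seed=0)
        assert np.all(t.W == 0)

    def test_sample_sd_matches_config_scale(self, table):
        t = make_tuning(128, table, SimConfig(tuning_sd_hz=5.0), seed=1)
        assert abs(t.W.std() - 5.0) / 5.0 < 0.10

    def test_reference_day_and_nonneg_baselines(self, table):
        t = make_tuning(8, table, SimConfig(n_days=3, day_offset_sd_hz=2.0),
                        seed=2)
        assert np.allclose(t.day_offsets[0], 0)
        assert np.all(t.b >= 0)

    def test_rejects_nonpositive_electrodes(self, table):
        with pytest.raises(ValueError):
            make_tuning(0, table)


class TestSynthesizeTrial:
    def test_noiseless_counts_equal_softplus_rate(self, table, lexicon50, inv):
        cfg = SimConfig(coart_bins=1, **NOISELESS)
        t = make_tuning(12, table, cfg, seed=3)
        tr = synthesize_trial("yes", t, table, 0, "vocal", lexicon50, seed=4)
        for b in range(tr.n_bins):
            ph = tr.frame_labels[b]
            a = table.vector(inv.symbol(ph))
            expect = softplus(t.b + t.W @ a) * cfg.bin_s
            assert np.allclose(tr.tx[b], expect)

    def test_silent_mode_attenuates_rates(self, table, lexicon50):
        cfg = SimConfig(coart_bins=1, silent_atten=0.6, **NOISELESS)
        t = make_tuning(6, table, cfg, seed=3)
        v = synthesize_trial("yes", t, table, 0, "vocal", lexicon50, seed=4)
        s = synthesize_trial("yes", t, table, 0, "silent", lexicon50, seed=4)
        # identical dwell seeds: silent counts are 0.6x the vocal counts
        assert np.allclose(s.tx, 0.6 * v.tx)

    def test_untuned_rates_do_not_depend_on_phoneme(self, table, lexicon50):
        cfg = SimConfig(tuning_sd_hz=0.0, **NOISELESS)
        t = make_tuning(6, table, cfg, seed=5)
        tr = synthesize_trial("bring my glasses here", t, table, 0, "vocal",
                              lexicon50, seed=6)
        assert np.allclose(tr.tx, tr.tx[0])

    def test_poisson_mean_matches_analytic_rate(self, table, lexicon50):
        # delay epoch sits at baseline: mean count = softplus(b) * bin_s
        cfg = SimConfig(drift_hz_per_min=0.0)
        t = make_tuning(4, table, cfg, seed=7)
        counts, n_bins = np.zeros(4), 0
        for s in range(100):
            tr = synthesize_trial("yes", t, table, 0, "vocal", lexicon50,
                                  seed=1000 + s)
            delay = tr.tx[: tr.go_bin]
            counts += delay.sum(axis=0)
            n_bins += delay.shape[0]
        lam = softplus(t.b) * cfg.bin_s
        se = np.sqrt(lam / n_bins)
        assert np.all(np.abs(counts / n_bins - lam) < 3.5 * se)

    def test_invariants(self, table, lexicon50):
        t = make_tuning(8, table, SimConfig(), seed=8)
        tr = synthesize_trial("i am tired", t, table, 0, "vocal", lexicon50,
                              seed=9)
        assert np.all(tr.tx >= 0)
        assert tr.tx.shape == tr.sbp.shape
        assert 0 <= tr.go_bin < tr.n_bins
        assert len(tr.frame_labels) == tr.n_bins
        assert tr.tx.dtype.kind == "f" and np.allclose(tr.tx, tr.tx.astype(int))


class TestSynthesizeDataset:
    def test_days_assignment_and_count(self, table, lexicon50):
        t = make_tuning(4, table, SimConfig(n_days=2), seed=0)
        sents = ["yes", "no", "help", "okay", "hello", "goodbye"]
        trials, manifest = synthesize_dataset(sents, [0, 1], t, table,
                                              lexicon50, seed=1)
        assert len(trials) == 6
        assert sorted({tr.day for tr in trials}) == [0, 1]
        assert manifest["n_trials"] == 6 and manifest["days"] == [0, 1]

    def test_same_seed_identical_dataset(self, table, lexicon50):
        t = make_tuning(4, table, SimConfig(), seed=0)
        a, _ = synthesize_dataset(["yes", "no"], [0], t, table, lexicon50, seed=5)
        b, _ = synthesize_dataset(["yes", "no"], [0], t, table, lexicon50, seed=5)
        assert dataset_checksum(a) == dataset_checksum(b)

    def test_start_times_increase_within_day(self, table, lexicon50):
        t = make_tuning(4, table, SimConfig(), seed=0)
        trials, _ = synthesize_dataset(["yes"] * 5, [0], t, table, lexicon50,
                                       seed=2)
        times = [tr.trial_start_time for tr in trials]
        assert times == sorted(times) and times[0] < times[-1]

    def test_empty_sentences_rejected(self, table, lexicon50):
        t = make_tuning(4, table, SimConfig(), seed=0)
        with pytest.raises(ValueError):
            synthesize_dataset([], [0], t, table, lexicon50)

    def test_planted_drift_slope_recovered(self, table, lexicon50):
        cfg = SimConfig(drift_hz_per_min=0.5, poisson=False, sbp_noise_sd=0.0)
        t = make_tuning(16, table, cfg, seed=3)
        trials, _ = synthesize_dataset(["yes"] * 40, [0], t, table, lexicon50,
                                       seed=4)
        times = np.array([tr.trial_start_time for tr in trials])
        delay_means = np.stack([tr.tx[: tr.go_bin].mean(axis=0) / cfg.bin_s
                                for tr in trials])
        slopes = np.polyfit(times, delay_means, 1)[0]
        # d rate / d minute = drift * dir * sigmoid(b) at baseline
        expect = cfg.drift_hz_per_min * t.drift_dir / (1 + np.exp(-t.b))
        assert np.corrcoef(slopes, expect)[0, 1] > 0.99
        assert np.abs(np.linalg.norm(slopes) / np.linalg.norm(expect) - 1) < 0.1


class TestDelayTask:
    @pytest.mark.parametrize("n_cond,n_trials", [(50, 20), (39, 16)])
    def test_trial_counts(self, table, n_cond, n_trials):
        t = make_tuning(4, table, SimConfig(), seed=0)
        conds = random_condition_targets(n_cond, table.dim, seed=1)
        trials = synthesize_delay_task(conds, n_trials, t, table, seed=2)
        assert len(trials) == n_cond * n_trials
        assert len({tr.condition for tr in trials}) == n_cond

    def test_delay_epoch_at_baseline_movement_tuned(self, table):
        cfg = SimConfig(coart_bins=1, **NOISELESS)
        t = make_tuning(8, table, cfg, seed=1)
        trials = synthesize_delay_task(["AA"], 1, t, table, seed=2)
        tr = trials[0]
        base = softplus(t.b) * cfg.bin_s
        moved = softplus(t.b + t.W @ table.vector("AA")) * cfg.bin_s
        assert np.allclose(tr.tx[: tr.go_bin], base)
        assert np.allclose(tr.tx[tr.go_bin + 1:], moved)


def test_planted_articulatory_structure_recovered_at_zero_noise(table, inv):
    """Cosine structure of noiseless per-phoneme rate vectors matches the
    feature table's structure (the signal the RSA chain must detect)."""
    cfg = SimConfig(coart_bins=1, **NOISELESS)
    t = make_tuning(64, table, cfg, seed=11)
    phonemes = list(inv.phonemes)
    trials = synthesize_delay_task(phonemes, 1, t, table, seed=12)
    rate_vectors = {tr.condition: tr.tx[tr.go_bin + 2:].mean(axis=0)
                    for tr in trials}
    neural = similarity_matrix(
        {p: rate_vectors[p] - rate_vectors[p].mean() for p in phonemes},
        phonemes)
    artic = similarity_matrix({p: table.vector(p) for p in phonemes}, phonemes)
    assert rsa_correlation(neural, artic) > 0.9


def test_random_walk_day_offsets_accumulate(table):
    t = make_tuning(8, table, SimConfig(n_days=5), seed=1)
    rw = random_walk_day_offsets(t, step_sd_hz=1.0, seed=2)
    assert np.allclose(rw.day_offsets[0], 0)
    spread = np.linalg.norm(rw.day_offsets, axis=1)
    assert spread[4] > spread[1]
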