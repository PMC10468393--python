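"""Instructed-delay analyses: PSTH, naive Bayes, ANOVA and FVAF."""

import numpy as np
import pytest

from speechbci.simulator import (SimConfig, TrialRecord, make_tuning,
                                 synthesize_delay_task)
from speechbci.tuning import (ConditionDataset, anova_map, fvaf, fvaf_map,
                              naive_bayes_accuracy, psth,
                              time_resolved_accuracy)

NOISELESS = dict(poisson=False, sbp_noise_sd=0.0, drift_hz_per_min=0.0)


@pytest.fixture(scope="module")
def tuned_dataset(table):
    t = make_tuning(24, table, SimConfig(), seed=1)
    trials = synthesize_delay_task(["AA", "M", "S", "UW", "K"], 14, t, table,
                                   seed=2)
    return ConditionDataset.from_trials(trials)


@pytest.fixture(scope="module")
def untuned_dataset(table):
    t = make_tuning(24, table, SimConfig(tuning_sd_hz=0.0), seed=1)
    trials = synthesize_delay_task(["AA", "M", "S", "UW", "K"], 14, t, table,
                                   seed=3)
    return ConditionDataset.from_trials(trials)


@pytest.fixture(scope="module")
def noiseless_dataset(table):
    cfg = SimConfig(coart_bins=1, **NOISELESS)
    t = make_tuning(24, table, cfg, seed=1)
    trials = synthesize_delay_task(["AA", "M", "S"], 4, t, table, seed=4)
    return ConditionDataset.from_trials(trials)


class TestPSTH:
    def test_single_trial_ci_collapses_to_point(self, table):
        t = make_tuning(4, table, SimConfig(), seed=0)
        trials = synthesize_delay_task(["AA", "M"], 1, t, table, seed=1)
        ds = ConditionDataset.from_trials(trials)
        mean, lo, hi = psth(ds, "AA")
        assert np.array_equal(mean, lo) and np.array_equal(mean, hi)

    def test_noiseless_psth_equals_planted_rate(self, noiseless_dataset, table):
        from speechbci.simulator import softplus
        ds = noiseless_dataset
        t = make_tuning(24, table, SimConfig(coart_bins=1, **NOISELESS), seed=1)
        mean, _, _ = psth(ds, "AA", smooth_sd_ms=1e-6)
        moved = softplus(t.b + t.W @ table.vector("AA"))
        go = ds.trials["AA"][0].go_bin
        assert np.allclose(mean[go + 2], moved)

    def test_poisson_ci_width_tracks_analytic_se(self, table):
        t = make_tuning(6, table, SimConfig(tuning_sd_hz=0.0), seed=5)
        trials = synthesize_delay_task(["AA", "M"], 20, t, table, seed=6)
        ds = ConditionDataset.from_trials(trials)
        mean, lo, hi = psth(ds, "AA", smooth_sd_ms=1e-6, seed=0)
        rate = mean.mean(axis=0)
        # rate estimate from n=20 Poisson bins: se = sqrt(rate / (bin * n))
        se = np.sqrt(rate / (0.02 * 20))
        width = (hi - lo).mean(axis=0)
        assert np.all(np.abs(width / (2 * 1.96 * se) - 1) < 0.25)


class TestNaiveBayes:
    def test_chance_on_untuned_population(self, untuned_dataset):
        acc, _ = naive_bayes_accuracy(untuned_dataset, window_s=1.0)
        k, n = 5, 70
        band = 1.96 * np.sqrt((1 / k) * (1 - 1 / k) / n)
        assert abs(acc - 1 / k) <= band + 1e-9

    def test_perfect_on_noiseless_separable_classes(self, noiseless_dataset):
        acc, (lo, hi) = naive_bayes_accuracy(noiseless_dataset, window_s=1.0)
        assert acc == 1.0 and lo == 1.0 and hi == 1.0

    def test_well_above_chance_on_tuned_population(self, tuned_dataset):
        acc, _ = naive_bayes_accuracy(tuned_dataset, window_s=1.0)
        assert acc > 0.8

    def test_window_exceeding_trial_rejected(self, tuned_dataset):
        with pytest.raises(ValueError):
            naive_bayes_accuracy(tuned_dataset, window_s=99.0)

    def test_matches_brute_force_loo_rule_on_toy(self):
        # 2 classes, 1 electrode: enumerate the LOO Gaussian-NB decision rule
        from sklearn.naive_bayes import GaussianNB
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(1.0, 1.0, 9), rng.normal(2.0, 1.5, 9)])
        y = np.array(["a"] * 9 + ["b"] * 9)
        trials = []
        for xi, yi in zip(x, y):
            tx = np.full((60, 1), xi * 0.02)
            trials.append(TrialRecord(
                day=0, mode="vocal", sentence="", labels=np.empty(0, int),
                tx=tx, sbp=tx, go_bin=5, frame_labels=np.full(60, -1),
                trial_start_time=0.0, condition=str(yi)))
        ds = ConditionDataset.from_trials(trials)
        acc, _ = naive_bayes_accuracy(ds, window_s=1.0)

        var_floor = 1e-6 / max(x.var(), 1.0)
        correct = 0
        for i in range(len(x)):
            mask = np.arange(len(x)) != i
            xt, yt = x[mask], y[mask]
            eps = var_floor * xt.var()
            best, best_ll = None, -np.inf
            for c in ("a", "b"):
                g = xt[yt == c]
                mu, var = g.mean(), g.var() + eps
                ll = (np.log(len(g) / len(xt))
                      - 0.5 * np.log(2 * np.pi * var)
                      - 0.5 * (x[i] - mu) ** 2 / var)
                if ll > best_ll:
                    best, best_ll = c, ll
            correct += best == y[i]
        assert acc == pytest.approx(correct / len(x))


class TestTimeResolved:
    def test_chance_in_delay_rising_after_go(self, tuned_dataset):
        df = time_resolved_accuracy(tuned_dataset, window_ms=100)
        delay = df[df.time_s < -0.2]["accuracy"]
        move = df[df.time_s > 0.5]["accuracy"]
        chance = df["chance"].iloc[0]
        band = 1.96 * np.sqrt(chance * (1 - chance) / 70)
        assert delay.mean() < chance + 2 * band
        assert move.mean() > chance + 4 * band

    def test_first_crossing_is_after_go(self, tuned_dataset):
        df = time_resolved_accuracy(tuned_dataset, window_ms=100)
        chance = df["chance"].iloc[0]
        bound = chance + 1.96 * np.sqrt(chance * (1 - chance) / 70)
        crossing = df[df.accuracy > bound]["time_s"].min()
        assert crossing > -0.1


class TestAnova:
    def test_untuned_population_nowhere_significant(self, untuned_dataset):
        df = anova_map(untuned_dataset, bin_ms=800, alpha=1e-5)
        assert not df["significant"].any()

    def test_planted_single_tuned_electrode_flagged(self):
        rng = np.random.default_rng(8)
        trials = []
        for c, shift in (("a", 0.0), ("b", 3.0)):
            for _ in range(12):
                tx = rng.poisson(5.0, size=(50, 6)).astype(float)
                tx[:, 2] = rng.poisson(5.0 + shift * 5.0, size=50)  # electrode 2
                trials.append(TrialRecord(
                    day=0, mode="vocal", sentence="", labels=np.empty(0, int),
                    tx=tx, sbp=tx, go_bin=0, frame_labels=np.full(50, -1),
                    trial_start_time=0.0, condition=c))
        df = anova_map(ConditionDataset.from_trials(trials))
        assert df[df.electrode == 2]["significant"].item()
        assert df["significant"].sum() == 1

    def test_f_statistic_matches_hand_computation(self):
        # two conditions, three trials each, one electrode, one 800 ms bin
        vals = {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]}
        trials = []
        for c, xs in vals.items():
            for v in xs:
                tx = np.full((40, 1), v * 0.02)
                trials.append(TrialRecord(
                    day=0, mode="vocal", sentence="", labels=np.empty(0, int),
                    tx=tx, sbp=tx, go_bin=0, frame_labels=np.full(40, -1),
                    trial_start_time=0.0, condition=c))
        df = anova_map(ConditionDataset.from_trials(trials), bin_ms=800)
        # hand ANOVA: means 2 and 4, grand 3; SSB = 3*1+3*1 = 6 (df 1)
        # SSW = (1+0+1) + (4+0+4) = 10 (df 4); F = 6 / (10/4) = 2.4
        from scipy.stats import f as fdist
        expect_p = float(fdist.sf(2.4, 1, 4))
        assert df["p_min"].item() == pytest.approx(expect_p, rel=1e-9)


class TestFVAF:
    def test_equal_condition_means_give_zero(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        assert fvaf(vals, labels) == pytest.approx(0.0)

    def test_zero_within_condition_variance_gives_one(self):
        vals = np.array([1.0, 1.0, 5.0, 5.0])
        labels = np.array(["a", "a", "b", "b"])
        assert fvaf(vals, labels) == pytest.approx(1.0)

    def test_matches_planted_variance_ratio(self):
        rng = np.random.default_rng(9)
        delta, sd_w, n = 1.0, 1.0, 4000
        vals = np.concatenate([rng.normal(-delta, sd_w, n),
                               rng.normal(+delta, sd_w, n)])
        labels = np.array(["a"] * n + ["b"] * n)
        expect = delta**2 / (delta**2 + sd_w**2)
        assert fvaf(vals, labels) == pytest.approx(expect, abs=0.03)

    def test_map_values_bounded_and_tuned_exceeds_untuned(
            self, tuned_dataset, untuned_dataset):
        tuned = fvaf_map(tuned_dataset)["fvaf"]
        untuned = fvaf_map(untuned_dataset)["fvaf"]
        for v in (tuned, untuned):
            assert ((v >= 0) & (v <= 1)).all()
        assert tuned.mean() > untuned.mean()

    def test_fvaf_increases_with_planted_tuning_strength(self, table):
        from scipy.stats import spearmanr
        sds = [0.0, 2.0, 6.0, 12.0]
        means = []
        for sd in sds:
            t = make_tuning(12, table, SimConfig(tuning_sd_hz=sd), seed=3)
            trials = synthesize_delay_task(["AA", "M", "S"], 10, t, table,
                                           seed=4)
            ds = ConditionDataset.from_trials(trials)
            means.append(fvaf_map(ds)["fvaf"].mean())
        assert spearmanr(sds, means)[0] > 0.9
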