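"""Saliency extraction and representational-similarity machinery."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from speechbci.articulation import VOWELS
from speechbci.rnn import DecoderConfig, GRUDecoder
from speechbci.rsa import (cv_procrustes, extract_saliency, permutation_null,
                           rsa_correlation, similarity_matrix, vowel_plane)


class TestSimilarityMatrix:
    def test_orthonormal_vectors_give_identity(self):
        sm = similarity_matrix(np.eye(4), ["a", "b", "c", "d"])
        assert np.allclose(sm.matrix, np.eye(4))

    def test_duplicated_vectors_give_all_ones(self):
        X = np.tile(np.array([1.0, 2.0, 3.0]), (5, 1))
        sm = similarity_matrix(X)
        assert np.allclose(sm.matrix, 1.0)

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(0)
        sm = similarity_matrix(rng.normal(size=(8, 5)))
        assert np.allclose(sm.matrix, sm.matrix.T)
        assert np.allclose(np.diag(sm.matrix), 1.0)
        assert np.all((sm.matrix >= -1) & (sm.matrix <= 1))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            similarity_matrix(np.zeros((2, 3)))


class TestRSACorrelation:
    def test_identical_matrices_give_r_one(self):
        rng = np.random.default_rng(1)
        sm = similarity_matrix(rng.normal(size=(6, 4)))
        assert rsa_correlation(sm, sm) == pytest.approx(1.0)

    def test_independent_random_structures_weakly_correlated(self):
        rng = np.random.default_rng(2)
        rs = []
        for _ in range(20):
            a = similarity_matrix(rng.normal(size=(24, 10)))
            b = similarity_matrix(rng.normal(size=(24, 10)))
            rs.append(rsa_correlation(a, b))
        assert np.median(np.abs(rs)) < 0.3

    def test_label_reordering_is_respected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 4))
        labels = ["a", "b", "c", "d", "e"]
        sm1 = similarity_matrix(X, labels)
        sm2 = similarity_matrix(X[::-1], labels[::-1])
        assert rsa_correlation(sm1, sm2) == pytest.approx(1.0)


class TestPermutationNull:
    def test_p_value_floor_when_observed_tops_null(self):
        rng = np.random.default_rng(4)
        sm = similarity_matrix(rng.normal(size=(12, 8)))
        nulls, r, p = permutation_null(sm, sm, n=200, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 201)

    def test_null_distribution_centered_near_zero(self):
        rng = np.random.default_rng(5)
        a = similarity_matrix(rng.normal(size=(20, 8)))
        b = similarity_matrix(rng.normal(size=(20, 8)))
        nulls, _, _ = permutation_null(a, b, n=500, seed=1)
        n_pairs = 20 * 19 / 2
        assert abs(nulls.mean()) < 2 / np.sqrt(n_pairs)


class TestCvProcrustes:
    def test_planted_rotation_recovered_exactly(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(size=(10, 2))
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        neural = np.hstack([coords, np.zeros((10, 4))]) @ Q
        aligned, disparity = cv_procrustes(neural, coords, n_pcs=2)
        assert disparity < 1e-12
        assert np.allclose(aligned, coords, atol=1e-6)

    def test_three_point_toy_matches_hand_svd(self):
        # leave out point 2; fit on points 0,1 with the closed-form SVD
        A2 = np.array([[1.0, 0.0], [0.0, 2.0], [1.0, 1.0]])
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        Y = A2 @ R.T
        aligned, disparity = cv_procrustes(Y, A2, n_pcs=2)
        assert disparity < 1e-12

    def test_random_pairing_disparity_near_target_variance(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(16, 2))
        neural = rng.normal(size=(16, 8))
        _, disparity = cv_procrustes(neural, coords, n_pcs=4)
        var = ((coords - coords.mean(0)) ** 2).mean() * 2
        assert 0.3 * var < disparity < 3.0 * var

    def test_excessive_pcs_rejected(self):
        with pytest.raises(ValueError):
            cv_procrustes(np.random.default_rng(0).normal(size=(5, 3)),
                          np.zeros((5, 2)), n_pcs=4)


class TestVowelPlane:
    def test_exact_plane_gives_r2_one(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(10, 2))
        B = rng.normal(size=(2, 12))
        neural = coords @ B
        _, proj, r2 = vowel_plane(neural, coords)
        assert r2 == pytest.approx(1.0)
        assert np.allclose(proj, coords, atol=1e-8)

    def test_r2_decreases_with_orthogonal_noise(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(12, 2))
        B = rng.normal(size=(2, 20))
        r2s = []
        for sd in (0.0, 0.5, 2.0, 8.0):
            neural = coords @ B + rng.normal(0, sd, size=(12, 20))
            r2s.append(vowel_plane(neural, coords)[2])
        assert all(a >= b for a, b in zip(r2s, r2s[1:]))

    def test_simulator_vowels_preserve_height_and_backness_order(self, table):
        # noiseless per-vowel rate vectors: the planted articulatory plane
        from speechbci.simulator import SimConfig, make_tuning, \
            synthesize_delay_task
        cfg = SimConfig(coart_bins=1, poisson=False, sbp_noise_sd=0.0,
                        drift_hz_per_min=0.0)
        t = make_tuning(64, table, cfg, seed=10)
        trials = synthesize_delay_task(list(VOWELS), 1, t, table, seed=11)
        rates = {tr.condition: tr.tx[tr.go_bin + 2:].mean(axis=0)
                 for tr in trials}
        X = np.stack([rates[v] for v in VOWELS])
        # formant-style axes: F2 folds in rounding, which covaries with
        # backness — reading front/back off a plane needs that fold
        coords = table.vowel_formant_coords(VOWELS)
        _, proj, r2 = vowel_plane(X, coords)
        assert spearmanr(proj[:, 0], coords[:, 0])[0] > 0.9
        assert spearmanr(proj[:, 1], coords[:, 1])[0] > 0.9


@pytest.fixture(scope="module")
def planted_decoder():
    """Near-linear decoder: logits = x @ W_target (planted readout)."""
    rng = np.random.default_rng(12)
    D, C = 32, 6
    cfg = DecoderConfig(n_layers=1, hidden=D, input_dim=D, n_days=1,
                        n_tokens=C, seed=0)
    dec = GRUDecoder(cfg)
    W_target = rng.normal(size=(D, C))
    eps = 0.01
    p = dec.params
    p["Wh0"] = np.eye(D) * eps
    p["Uh0"] = np.zeros((D, D))
    p["Wz0"] = np.zeros((D, D))
    p["Uz0"] = np.zeros((D, D))
    p["bz0"] = np.full(D, 20.0)     # z ~ 1: h follows the candidate
    p["Wr0"] = np.zeros((D, D))
    p["Ur0"] = np.zeros((D, D))
    p["bh0"] = np.zeros(D)
    # logits ~= 0.5 * x @ W_target: non-saturating linear readout
    p["Wo"] = W_target * (0.5 / eps)
    p["bo"] = np.zeros(C)
    return dec, W_target


class TestSaliency:
    def test_recovers_planted_readout_direction(self, planted_decoder):
        # the sphere-constrained optimum aligns with the planted column
        # combination W (e_k - p), the softmax-competition-adjusted readout
        dec, W = planted_decoder
        C = dec.config.n_tokens
        for tok in (0, 3):
            res = extract_saliency(dec, tok, n_restarts=3, n_iters=120,
                                   seed=13)
            logits = 0.5 * (res.vector @ W)
            pr = np.exp(logits - logits.max())
            pr /= pr.sum()
            comb = W @ (np.eye(C)[tok] - pr)
            cos = res.vector @ comb / np.linalg.norm(comb)
            assert cos > 0.95

    def test_same_seed_identical(self, planted_decoder):
        dec, _ = planted_decoder
        a = extract_saliency(dec, 1, n_restarts=2, seed=3)
        b = extract_saliency(dec, 1, n_restarts=2, seed=3)
        assert np.array_equal(a.vector, b.vector)

    def test_unit_norm_output(self, planted_decoder):
        dec, _ = planted_decoder
        res = extract_saliency(dec, 2, n_restarts=1, seed=4)
        assert np.isclose(np.linalg.norm(res.vector), 1.0)

    def test_blank_token_rejected(self, planted_decoder):
        dec, _ = planted_decoder
        with pytest.raises(ValueError, match="blank"):
            extract_saliency(dec, dec.config.n_tokens - 1)
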