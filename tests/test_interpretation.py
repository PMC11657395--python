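"""Gradient attribution, attention pair scores, variant LOS, baselines."""

import numpy as np
import pytest
import autograd.numpy as anp
from scipy.stats import rankdata

from seq2epi.interpretation import (
    attention_pair_score,
    gis,
    gis_table,
    igis,
    kmer_features,
    log_ratio,
    los_attention,
    los_signal,
    percentile_rank,
    tf_input_predict_fn,
    variant_feature_vector,
)


class TestGIS:
    def test_linear_toy_model_recovers_weight(self):
        """For yhat[l, k] = w_k * tf[l, 0], GIS is exactly |w_k|."""
        w = np.array([1.5, -2.0])

        def predict_fn(tf_block):
            return anp.outer(tf_block[:, 0], w)

        tf_input = np.random.default_rng(0).random((6, 3))
        zeta = np.array([1, 3, 4])
        assert gis(predict_fn, tf_input, 0, 0, zeta) == pytest.approx(1.5)
        assert gis(predict_fn, tf_input, 0, 1, zeta) == pytest.approx(2.0)

    def test_output_independent_of_tf_gives_zero(self, rng):
        def predict_fn(tf_block):
            return anp.outer(tf_block[:, 0], anp.array([1.0]))

        tf_input = rng.random((4, 2))
        assert gis(predict_fn, tf_input, 1, 0, np.array([0, 2])) == 0.0

    def test_empty_binding_set_zero_with_warning(self, rng):
        def predict_fn(tf_block):
            return tf_block

        with pytest.warns(UserWarning, match="empty binding set"):
            assert gis(predict_fn, rng.random((3, 2)), 0, 0,
                       np.array([], dtype=int)) == 0.0

    def test_autodiff_matches_central_finite_differences(
        self, mini_config, mini_params, rng
    ):
        """Full-model GIS gradient vs a finite-difference oracle (h=1e-4)."""
        cfg = mini_config
        onehot = np.eye(4)[rng.integers(0, 4, cfg.input_length)]
        tf_input = rng.random((cfg.tokens, cfg.n_tf_padded))
        fn = tf_input_predict_fn(mini_params, cfg, onehot)
        zeta = np.array([2, 5])
        t, k, h = 1, 0, 1e-4
        value = gis(fn, tf_input, t, k, zeta)
        fd = []
        for l in zeta:
            up, dn = tf_input.copy(), tf_input.copy()
            up[l, t] += h
            dn[l, t] -= h
            fd.append(abs(
                (np.asarray(fn(up))[l, k] - np.asarray(fn(dn))[l, k]) / (2 * h)
            ))
        assert value == pytest.approx(float(np.mean(fd)), rel=1e-4)

    def test_gis_table_matches_scalar_gis(self, mini_config, mini_params, rng):
        cfg = mini_config
        onehot = np.eye(4)[rng.integers(0, 4, cfg.input_length)]
        motif = rng.random((cfg.tokens, cfg.n_tf_padded)) * (
            rng.random((cfg.tokens, cfg.n_tf_padded)) > 0.5
        )
        tf_input = motif * rng.random(cfg.n_tf_padded)[np.newaxis, :]
        fn = tf_input_predict_fn(mini_params, cfg, onehot)
        table = gis_table(fn, tf_input, motif)
        t = 1
        zeta = np.nonzero(motif[:, t] > 0)[0]
        for k in (0, cfg.n_signals - 1):
            assert table[t, k] == pytest.approx(
                gis(fn, tf_input, t, k, zeta), rel=1e-10
            )


class TestIGIS:
    def test_first_everywhere_is_one(self):
        g = np.array([[5.0, 9.0], [1.0, 2.0], [0.5, 0.1]])
        np.testing.assert_allclose(igis(g), [1.0, 2.0, 3.0])

    def test_two_way_tie_averages(self):
        g = np.array([[1.0, 1.0], [1.0, 1.0]])
        np.testing.assert_allclose(igis(g), [1.5, 1.5])

    def test_matches_brute_force_rank_loop(self, rng):
        g = rng.random((5, 8))
        expected = np.zeros(5)
        for k in range(8):
            expected += rankdata(-g[:, k], method="average")
        np.testing.assert_allclose(igis(g), expected / 8)

    def test_invariant_under_monotone_column_transform(self, rng):
        g = rng.random((7, 4))
        g2 = g.copy()
        g2[:, 2] = np.exp(3 * g2[:, 2]) + 1  # strictly monotone
        np.testing.assert_allclose(igis(g), igis(g2))


class TestAttentionPairScore:
    def test_uniform_attention_column_score_is_one(self):
        T = 8
        att = np.full((T, T), 1.0 / T)
        assert attention_pair_score(att, 3, 5) == pytest.approx(1.0)

    def test_identity_attention(self):
        att = np.eye(6)
        assert attention_pair_score(att, 2, 4, mode="column") == 1.0
        assert attention_pair_score(att, 2, 4, mode="direct") == 0.0
        assert attention_pair_score(att, 2, 2, mode="direct") == 1.0

    def test_random_matrix_matches_explicit_sum(self, rng):
        att = rng.random((8, 8))
        att /= att.sum(axis=1, keepdims=True)
        assert attention_pair_score(att, 5, 1) == pytest.approx(
            sum(att[q, 5] for q in range(8))
        )
        assert attention_pair_score(att, 5, 1, mode="direct") == att[5, 1]

    def test_column_scores_conserve_token_count(self, rng):
        att = rng.random((10, 10))
        att /= att.sum(axis=1, keepdims=True)
        total = sum(attention_pair_score(att, e, 0) for e in range(10))
        assert total == pytest.approx(10.0)

    def test_out_of_window_pair_rejected(self, rng):
        att = np.full((8, 8), 1 / 8)
        with pytest.raises(ValueError, match="separation"):
            attention_pair_score(att, 0, 7, max_separation=5)


class TestLOS:
    def test_identical_windows_zero_vector(self, rng):
        pred = rng.random((6, 8))
        np.testing.assert_allclose(los_signal(pred, pred, 3), 0.0)

    def test_doubled_output_gives_log2(self):
        ref = np.full((4, 8), 2.0)
        alt = ref.copy()
        alt[1] *= 2
        np.testing.assert_allclose(
            los_signal(ref, alt, 1), np.log(2), rtol=1e-6
        )

    def test_antisymmetry_exact(self, rng):
        ref, alt = rng.random((5, 8)), rng.random((5, 8))
        np.testing.assert_array_equal(
            los_signal(ref, alt, 2), -los_signal(alt, ref, 2)
        )

    def test_negative_outputs_floored(self):
        out = log_ratio(np.array([-1.0]), np.array([-2.0]))
        assert np.isfinite(out).all() and out[0] == 0.0


class TestLOSAttention:
    def _uniform(self, T=32):
        return np.full((T, T), 1.0 / T)

    def test_identical_attention_zero(self):
        att = self._uniform()
        assert los_attention(att, att, 16) == 0.0

    def test_one_bin_mass_doubled_gives_log2(self):
        att_ref = self._uniform()
        att_alt = att_ref.copy()
        att_alt[:, 10] *= 2  # column mass of bin 10 doubles
        assert los_attention(att_ref, att_alt, 10) == pytest.approx(
            np.log(2), rel=1e-5
        )

    def test_matches_hand_loop_over_eleven_offsets(self, rng):
        T = 32
        att_ref = rng.random((T, T))
        att_alt = rng.random((T, T))
        vb, eps = 15, 1e-6
        expected = 0.0
        for off in range(-5, 6):
            m_ref = att_ref[:, vb + off].sum()
            m_alt = att_alt[:, vb + off].sum()
            expected += abs(np.log((m_alt + eps) / (m_ref + eps)))
        assert los_attention(att_ref, att_alt, vb) == pytest.approx(expected)

    def test_edge_truncation_warns(self, rng):
        att = rng.random((12, 12))
        with pytest.warns(UserWarning, match="truncated"):
            los_attention(att, att * 1.1, 1)


class TestVariantFeatures:
    def test_full_scale_dimension(self, rng):
        feats = variant_feature_vector(rng.random((28, 8)), rng.random(28))
        assert feats.shape == (252,)

    def test_single_context_is_nine(self, rng):
        assert variant_feature_vector(rng.random((1, 8)),
                                      rng.random(1)).shape == (9,)

    def test_context_permutation_permutes_blocks(self, rng):
        sig, att = rng.random((4, 8)), rng.random(4)
        full = variant_feature_vector(sig, att).reshape(4, 9)
        perm = np.array([2, 0, 3, 1])
        permuted = variant_feature_vector(sig[perm], att[perm]).reshape(4, 9)
        np.testing.assert_allclose(permuted, full[perm])


class TestPercentileRank:
    def test_best_score_ranks_zero(self):
        assert percentile_rank(10.0, np.arange(9)) == 0.0

    def test_median_of_symmetric_background(self):
        bg = np.array([-2.0, -1.0, 1.0, 2.0])
        assert percentile_rank(0.0, bg) == 0.5

    def test_tie_midrank(self):
        assert percentile_rank(1.0, np.array([0.0, 1.0, 2.0])) == pytest.approx(
            (1 + 0.5) / 3
        )

    def test_null_calibration_monte_carlo(self):
        rng = np.random.default_rng(2024)
        ranks = [
            percentile_rank(rng.uniform(), rng.uniform(size=99))
            for _ in range(10_000)
        ]
        assert np.mean(ranks) == pytest.approx(0.5, abs=0.02)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            percentile_rank(1.0, np.array([]))


class TestKmerFeatures:
    def test_dimension_is_4_to_the_k(self):
        assert kmer_features("ACGTACGT", k=5).shape == (1024,)
        assert kmer_features("ACGT", k=2).shape == (16,)

    def test_single_kmer_hits_its_index(self):
        v = kmer_features("AAAAA", k=5)
        assert v[0] == 1 and v.sum() == 1
        v = kmer_features("TTTTT", k=5)
        assert v[-1] == 1 and v.sum() == 1

    def test_matches_dictionary_count_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        v = kmer_features(seq, k=5)
        counts = {}
        for i in range(len(seq) - 4):
            counts[seq[i : i + 5]] = counts.get(seq[i : i + 5], 0) + 1
        idx = {b: i for i, b in enumerate("ACGT")}
        for kmer, n in counts.items():
            code = 0
            for ch in kmer:
                code = code * 4 + idx[ch]
            assert v[code] == n
        assert v.sum() == len(seq) - 4

    def test_ambiguous_kmers_dropped(self):
        v = kmer_features("AANAA", k=5)
        assert v.sum() == 0

    def test_short_sequence_zero_with_warning(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert kmer_features("ACG", k=5).sum() == 0
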