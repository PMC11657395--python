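"""Losses (masked MSE, contact guidance), training loop, fine-tuning head."""

import numpy as np
import pytest
from autograd import grad

from seq2epi.core_data import make_bins
from seq2epi.model import ModelConfig, init_params, model_forward
from seq2epi.training import (
    ContactMatrix,
    TrainConfig,
    WindowDataset,
    anchor_bins,
    build_contact_matrix,
    contact_guidance_loss,
    ep_features,
    finetune_ep,
    masked_mse,
    read_bedpe,
    total_loss,
    train,
)


def brute_force_masked_mse(pred, target, avail):
    """Independent double-loop oracle for the masked multi-task loss."""
    total = 0.0
    B, T, K = pred.shape
    for i in range(B):
        n_avail = int(avail[i].sum())
        if n_avail == 0:
            continue
        inst = 0.0
        for j in range(T):
            s = 0.0
            for k in range(K):
                if avail[i, k]:
                    s += (target[i, j, k] - pred[i, j, k]) ** 2
            inst += s / n_avail
        total += inst / T
    return total / B


class TestMaskedMse:
    def test_hand_oracle_two_bins_two_signals(self):
        pred = np.array([[[1.0, 0.0], [0.0, 2.0]]])
        target = np.array([[[0.0, 0.0], [0.0, 0.0]]])
        avail = np.array([[True, True]])
        # bins: (1 + 0)/2 = 0.5 and (0 + 4)/2 = 2.0; mean over bins = 1.25
        assert masked_mse(pred, target, avail) == pytest.approx(1.25)

    def test_perfect_prediction_zero(self, rng):
        x = rng.random((2, 5, 4))
        assert masked_mse(x, x, np.ones((2, 4), bool)) == pytest.approx(0.0)

    def test_masked_cells_excluded(self, rng):
        pred = rng.random((1, 6, 3))
        target = pred.copy()
        target[0, :, 2] += 100.0  # differs only in the masked signal
        avail = np.array([[True, True, False]])
        assert masked_mse(pred, target, avail) == pytest.approx(0.0)

    def test_matches_brute_force_on_random_tensors(self, rng):
        pred = rng.normal(size=(4, 7, 5))
        target = rng.normal(size=(4, 7, 5))
        avail = rng.random((4, 5)) > 0.4
        assert masked_mse(pred, target, avail) == pytest.approx(
            brute_force_masked_mse(pred, target, avail), abs=1e-10
        )

    def test_all_masked_instance_contributes_zero(self, rng):
        pred = rng.random((2, 4, 3))
        target = rng.random((2, 4, 3))
        avail = np.array([[True, True, True], [False, False, False]])
        only_first = masked_mse(pred[:1], target[:1], avail[:1])
        assert masked_mse(pred, target, avail) == pytest.approx(only_first / 2)

    def test_nan_in_available_cell_rejected(self, rng):
        target = rng.random((1, 3, 2))
        target[0, 1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            masked_mse(np.zeros_like(target), target, np.ones((1, 2), bool))


class TestContactMatrix:
    def _loop_line(self, a, b, score, q):
        return {
            "chrom1": "chr1", "start1": a * 100, "end1": (a + 1) * 100,
            "chrom2": "chr1", "start2": b * 100, "end2": (b + 1) * 100,
            "score": score, "q": q,
        }

    def test_q_filter_drops_insignificant_loops(self):
        region = make_bins("chr1", 0, 1000, 100)
        loops = [self._loop_line(1, 5, 3.0, 0.01)]
        cm = build_contact_matrix(loops, region)
        assert not cm.H.any()

    def test_single_loop_symmetric_unit_rows(self):
        region = make_bins("chr1", 0, 1000, 100)
        cm = build_contact_matrix([self._loop_line(2, 7, 4.0, 1e-5)], region)
        assert cm.H[2, 7] == cm.H[7, 2] == 4.0
        ht = cm.H_tilde
        assert ht[2, 7] == 1.0 and ht[7, 2] == 1.0
        assert cm.valid_rows.sum() == 2

    def test_multi_loop_matches_brute_force(self, rng):
        region = make_bins("chr1", 0, 1200, 100)
        loops = [
            self._loop_line(int(a), int(b), float(s), 1e-4)
            for a, b, s in zip(
                rng.integers(0, 12, 20), rng.integers(0, 12, 20),
                rng.uniform(1, 9, 20),
            )
        ]
        cm = build_contact_matrix(loops, region)
        H = np.zeros((12, 12))
        for lp in loops:
            a, b = lp["start1"] // 100, lp["start2"] // 100
            H[a, b] += lp["score"]
            if a != b:
                H[b, a] += lp["score"]
        np.testing.assert_allclose(cm.H, H)

    def test_bedpe_parse_errors_carry_line_number(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text(
            "chr1\t0\t100\tchr1\t500\t600\tl1\t2.0\t1e-5\n"
            "chr1\t0\t100\tchr1\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            read_bedpe(p)

    def test_zero_rows_flagged_not_normalized(self):
        cm = ContactMatrix(np.array([[0.0, 0.0], [0.0, 3.0]]))
        ht = cm.H_tilde
        assert not ht[0].any()
        np.testing.assert_allclose(ht[1].sum(), 1.0)


def brute_force_csl(att, h_tilde):
    """Explicit per-row cosine loop."""
    cosines = []
    for i in range(h_tilde.shape[0]):
        h = h_tilde[i]
        if not h.any():
            continue
        a = att[i]
        cosines.append(a @ h / (np.linalg.norm(a) * np.linalg.norm(h)))
    return 1.0 - float(np.mean(cosines))


class TestContactGuidanceLoss:
    def test_proportional_rows_zero_loss(self, rng):
        h = rng.random((5, 5))
        h /= h.sum(axis=1, keepdims=True)
        assert contact_guidance_loss(3.7 * h, h) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_rows_loss_one(self):
        att = np.array([[1.0, 0.0], [1.0, 0.0]])
        h = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert contact_guidance_loss(att, h) == pytest.approx(1.0)

    def test_matches_brute_force_random_6x6(self, rng):
        att = rng.random((6, 6))
        h = rng.random((6, 6))
        h[2] = 0.0  # a missing row
        assert contact_guidance_loss(att, h) == pytest.approx(
            brute_force_csl(att, h), abs=1e-9
        )

    def test_range_zero_to_two(self, rng):
        for _ in range(20):
            att = rng.normal(size=(4, 4))
            h = np.abs(rng.normal(size=(4, 4)))
            loss = contact_guidance_loss(att, h)
            assert 0.0 <= loss <= 2.0

    def test_all_zero_rows_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="no nonzero"):
            assert contact_guidance_loss(np.eye(3), np.zeros((3, 3))) == 0.0


class TestTotalLoss:
    def test_alpha_zero_reduces_to_masked_mse(self, rng):
        pred = rng.random((1, 4, 2))
        target = rng.random((1, 4, 2))
        avail = np.ones((1, 2), bool)
        att, h = rng.random((4, 4)), rng.random((4, 4))
        assert total_loss(pred, target, avail, att, h, alpha=0.0) == (
            masked_mse(pred, target, avail)
        )

    def test_hand_arithmetic(self):
        # mse = 1, CSL = 1 - cos = 0.5, alpha = 2 -> total = 2.0
        pred = np.zeros((1, 1, 1))
        target = np.ones((1, 1, 1))
        avail = np.ones((1, 1), bool)
        att = np.array([[1.0, 0.0]])
        h = np.array([[0.5, np.sqrt(3) / 2]])  # cosine vs (1, 0) is 0.5
        assert total_loss(pred, target, avail, att, h, alpha=2.0) == (
            pytest.approx(1.0 + 2.0 * 0.5)
        )

    def test_monotone_in_alpha(self, rng):
        pred, target = rng.random((1, 3, 2)), rng.random((1, 3, 2))
        avail = np.ones((1, 2), bool)
        att = rng.random((3, 3))
        h = rng.random((3, 3))
        losses = [
            total_loss(pred, target, avail, att, h, alpha=a)
            for a in (0.0, 1.0, 2.0)
        ]
        assert losses[0] < losses[1] < losses[2]


TRAIN_CONFIG_FAST = ModelConfig(
    input_length=1024, bin_size=128, seq_channels=8, n_tf_padded=4,
    n_heads=2, n_layers=1, n_signals=3, conv_kernel=5,
)


def _tiny_dataset(rng, n_windows=2, n_contexts=2, contacts=False):
    cfg = TRAIN_CONFIG_FAST
    onehot = np.eye(4)[rng.integers(0, 4, (n_windows, cfg.input_length))]
    tf_motif = rng.random((n_windows, cfg.tokens, cfg.n_tf_padded))
    expression = rng.random((n_contexts, cfg.n_tf_padded))
    targets = rng.random((n_contexts, n_windows, cfg.tokens, cfg.n_signals))
    avail = np.ones((n_contexts, cfg.n_signals), bool)
    cms = None
    if contacts:
        cms = []
        for _ in range(n_windows):
            H = np.zeros((cfg.tokens, cfg.tokens))
            a, b = rng.choice(cfg.tokens, 2, replace=False)
            H[a, b] = H[b, a] = 1.0
            cms.append(ContactMatrix(H))
    return WindowDataset(
        onehot=onehot.astype(np.float32),
        tf_motif=tf_motif.astype(np.float32),
        expression=expression.astype(np.float32),
        targets=targets.astype(np.float32),
        avail=avail,
        contacts=cms,
    )


class TestTrain:
    def test_single_instance_overfit(self, rng):
        cfg = TRAIN_CONFIG_FAST
        ds = _tiny_dataset(rng, n_windows=1, n_contexts=1)
        tc = TrainConfig(learning_rate=3e-3, batch_size=2, steps=500,
                         alpha=0.0, seed=0)
        params, history = train(None, ds, cfg, tc)
        from seq2epi.training import masked_mse as mm

        pred, _, _ = model_forward(
            params, ds.onehot, ds.tf_block(0, 0)[np.newaxis], cfg
        )
        final = mm(np.asarray(pred), ds.targets[0], ds.avail)
        assert float(final) < 1e-3

    def test_seed_reproducibility(self, rng):
        ds = _tiny_dataset(rng)
        tc = TrainConfig(learning_rate=1e-3, batch_size=2, steps=30,
                         alpha=0.0, seed=42)
        _, h1 = train(None, ds, TRAIN_CONFIG_FAST, tc)
        _, h2 = train(None, ds, TRAIN_CONFIG_FAST, tc)
        assert h1 == h2

    def test_empty_dataset_rejected(self, rng):
        ds = _tiny_dataset(rng)
        ds.onehot = ds.onehot[:0]
        with pytest.raises(ValueError, match="empty"):
            train(None, ds, TRAIN_CONFIG_FAST,
                  TrainConfig(learning_rate=1e-3, steps=1))

    def test_loss_decreases_on_fixture(self, rng):
        ds = _tiny_dataset(rng)
        tc = TrainConfig(learning_rate=2e-3, batch_size=4, steps=150,
                         alpha=0.0, seed=1)
        _, history = train(None, ds, TRAIN_CONFIG_FAST, tc)
        assert np.mean(history[-10:]) < np.mean(history[:10])

    def test_gradient_flows_through_attention_with_alpha(self, rng):
        """CSL must reach attention weights even at an MSE stationary point."""
        cfg = TRAIN_CONFIG_FAST
        params = init_params(cfg, np.random.default_rng(0))
        onehot = np.eye(4)[rng.integers(0, 4, (1, cfg.input_length))]
        tfb = rng.random((1, cfg.tokens, cfg.n_tf_padded))
        h_tilde = np.zeros((cfg.tokens, cfg.tokens))
        h_tilde[0, 3] = 1.0
        # target equals the current prediction, so the MSE term sits at a
        # stationary point and any gradient must come through the CSL term
        target, _, _ = model_forward(params, onehot, tfb, cfg)
        target = np.asarray(target)

        def loss_with(p, alpha):
            import autograd.numpy as anp

            pred, attn, _ = model_forward(p, onehot, tfb, cfg,
                                          return_attention=True)
            att_avg_t = anp.mean(attn[-1], axis=1)[0]
            return total_loss(pred, target, np.ones((1, cfg.n_signals), bool),
                              att_avg_t, h_tilde, alpha=alpha)

        g = grad(lambda p: loss_with(p, 2.0))(params)
        assert np.abs(g["l0_Wq"]).max() > 0

    def test_divergence_aborts_with_last_checkpoint(self, rng):
        from seq2epi.training import TrainingDiverged

        ds = _tiny_dataset(rng)
        # targets beyond sqrt(float64 max): the squared error overflows to inf
        ds.targets = ds.targets.astype(np.float64) + 1e200
        tc = TrainConfig(learning_rate=1e3, batch_size=2, steps=50,
                         alpha=0.0, seed=0)
        with pytest.raises(TrainingDiverged) as exc_info:
            train(None, ds, TRAIN_CONFIG_FAST, tc)
        assert isinstance(exc_info.value.params, dict)


class TestFinetuneEP:
    def test_anchor_bin_selection_by_midpoint(self):
        region = make_bins("chr1", 0, 1024, 128)
        bins = anchor_bins(region, 100, 400)
        # midpoints 64, 192, 320, 448...; inside [100, 400): bins 1, 2
        np.testing.assert_array_equal(bins, [1, 2])

    def test_feature_width(self, rng):
        cfg = TRAIN_CONFIG_FAST
        params = init_params(cfg, np.random.default_rng(3))
        onehot = np.eye(4)[rng.integers(0, 4, (cfg.input_length,))]
        tfb = rng.random((cfg.tokens, cfg.n_tf_padded))
        feats = ep_features(params, cfg, onehot, tfb,
                            np.array([0, 1, 2]), np.array([5, 6, 7]))
        assert feats.shape == (6 * cfg.d_model,)

    def test_anchor_outside_window_rejected(self, rng):
        cfg = TRAIN_CONFIG_FAST
        params = init_params(cfg, np.random.default_rng(3))
        onehot = np.eye(4)[rng.integers(0, 4, (cfg.input_length,))]
        tfb = rng.random((cfg.tokens, cfg.n_tf_padded))
        with pytest.raises(ValueError, match="outside"):
            ep_features(params, cfg, onehot, tfb,
                        np.array([0]), np.array([cfg.tokens]))

    def test_planted_loops_classified_from_frozen_backbone(self, sim_small):
        """Pair features from a frozen backbone separate planted loops from
        mirrored equidistant negatives (auROC > 0.9 on the fixture)."""
        from sklearn.metrics import roc_auc_score

        from seq2epi.model import TOY_CONFIG
        from seq2epi.pipeline import ep_pair_table, load_bundle

        bundle = load_bundle(sim_small.outdir)
        params = init_params(TOY_CONFIG, np.random.default_rng(0),
                             dtype=np.float32)
        X, y = ep_pair_table(params, TOY_CONFIG, bundle, context=0)
        assert set(y) == {0, 1}
        head = finetune_ep(X, y, hidden=(16, 16), steps=400, seed=1)
        assert roc_auc_score(y, head.predict_proba(X)) > 0.9

    def test_backbone_untouched_and_separable_set_learned(self, rng):
        """The head must reach auROC > 0.9 on linearly separable features
        while the frozen backbone parameters stay bit-identical."""
        cfg = TRAIN_CONFIG_FAST
        params = init_params(cfg, np.random.default_rng(3))
        snapshot = {k: v.copy() for k, v in params.items()}
        n, d = 120, 24
        X = rng.normal(size=(n, d))
        w = rng.normal(size=d)
        y = (X @ w > 0).astype(float)
        head = finetune_ep(X, y, hidden=(16, 16), steps=400, seed=0)
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, head.predict_proba(X)) > 0.9
        for k in params:  # backbone gradients identically zero
            np.testing.assert_array_equal(params[k], snapshot[k])
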