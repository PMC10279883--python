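"""Online/target training scheme: loss algebra, EMA dynamics, gradient
isolation and seeded determinism."""

import numpy as np
import pytest

import psnsleep as ps
from psnsleep.siamese import (TrainConfig, ema_update, init_state,
                              pair_loss, pretrain, project_and_predict,
                              symmetric_loss, train_step)


@pytest.fixture
def state(micro_encoder_config):
    cfg = TrainConfig(batch_size=4, epochs=1, seed=3, encoder=micro_encoder_config,
                      augmentation=ps.AugmentationConfig(kind="time_shift"))
    return init_state(cfg)


def _pair_batch(rng, n=4, s=300):
    return ps.PositivePairBatch(anchor=rng.standard_normal((n, s)),
                                view=rng.standard_normal((n, s)))


class TestPairLoss:
    def test_identical_vectors_zero(self, rng):
        a = rng.standard_normal((6, 16))
        assert pair_loss(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_four(self, rng):
        a = rng.standard_normal((6, 16))
        assert pair_loss(a, -a) == pytest.approx(4.0, abs=1e-12)

    def test_orthogonal_two(self):
        a = np.array([[1.0, 0.0]])
        b = np.array([[0.0, 3.0]])
        assert pair_loss(a, b) == pytest.approx(2.0, abs=1e-12)

    def test_equals_two_minus_two_cosine(self, rng):
        """Algebraic identity checked against an independent cosine implementation."""
        for _ in range(1000):
            a = rng.standard_normal(8)
            b = rng.standard_normal(8)
            cos = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert pair_loss(a[None], b[None]) == pytest.approx(2 - 2 * cos, abs=1e-6)

    def test_invariant_to_positive_rescaling(self, rng):
        a = rng.standard_normal((5, 12))
        b = rng.standard_normal((5, 12))
        base = pair_loss(a, b)
        for lam in (1e-4, 0.5, 7.0, 1e4):
            assert pair_loss(lam * a, b) == pytest.approx(base, abs=1e-6)
            assert pair_loss(a, lam * b) == pytest.approx(base, abs=1e-6)

    def test_zero_row_guarded_with_warning(self):
        with pytest.warns(RuntimeWarning, match="zero-norm"):
            value = pair_loss(np.zeros((1, 4)), np.ones((1, 4)))
        assert np.isfinite(value)


class TestSymmetricLoss:
    def test_swap_invariance(self, state, rng):
        x = rng.standard_normal((4, 300))
        v = rng.standard_normal((4, 300))
        assert symmetric_loss(x, v, state) == pytest.approx(
            symmetric_loss(v, x, state), abs=1e-9)

    def test_bounded(self, state, rng):
        for _ in range(3):
            value = symmetric_loss(rng.standard_normal((4, 300)),
                                   rng.standard_normal((4, 300)), state)
            assert 0.0 <= value <= 4.0


class TestProjectAndPredict:
    def test_online_and_target_agree_at_init(self, state, rng):
        """epsilon starts as an exact copy of theta, so identical inputs map identically
        through encoder + projection (predictor excluded)."""
        x = rng.standard_normal((4, 300))
        c_on = state.online_encoder(x)
        c_tg = state.target_encoder(x)
        assert np.array_equal(c_on.data, c_tg.data)
        a_on = project_and_predict(c_on, "online", state, with_prediction=False)
        a_tg = project_and_predict(c_tg, "target", state)
        assert np.allclose(a_on.data, a_tg.data, atol=1e-12)
        assert a_on.shape == (4, state.config.encoder.representation_dim)

    def test_prediction_on_target_branch_rejected(self, state, rng):
        c = state.target_encoder(rng.standard_normal((2, 300)))
        with pytest.raises(ValueError, match="no prediction head"):
            project_and_predict(c, "target", state, with_prediction=True)

    def test_unknown_branch_rejected(self, state):
        with pytest.raises(ValueError, match="branch"):
            project_and_predict(np.zeros((1, 8)), "offline", state)


class TestEmaUpdate:
    @pytest.mark.parametrize("tau", [0.0, 0.1, 0.5, 1.0])
    def test_closed_form_under_fixed_theta(self, micro_encoder_config, tau):
        """With theta frozen, k EMA steps give eps_k = tau^k eps_0 + (1 - tau^k) theta."""
        cfg = TrainConfig(batch_size=4, epochs=1, tau=tau, seed=5,
                          encoder=micro_encoder_config)
        state = init_state(cfg)
        rng = np.random.default_rng(0)
        # desynchronize the branches so the recursion is nontrivial
        for p in state.target_parameters():
            p.data = p.data + rng.standard_normal(p.data.shape)
        eps0 = [p.data.copy() for p in state.target_parameters()]
        theta = [p.data.copy() for p in
                 state.online_encoder.parameters() + state.online_projection.parameters()]
        k = 5
        for _ in range(k):
            ema_update(state)
        for p, e0, th in zip(state.target_parameters(), eps0, theta):
            expected = tau**k * e0 + (1 - tau**k) * th
            assert np.allclose(p.data, expected, atol=1e-6)

    def test_tau_zero_copies_theta(self, state):
        state.tau = 0.0
        for p in state.target_parameters():
            p.data = p.data + 1.0
        ema_update(state)
        online = dict(state.online_encoder.named_parameters())
        for name, p in state.target_encoder.named_parameters():
            assert np.array_equal(p.data, online[name].data)


class TestTrainStep:
    def test_target_receives_no_gradient(self, state, rng):
        for _ in range(3):
            train_step(_pair_batch(rng), state)
        assert all(p.grad is None for p in state.target_parameters())

    def test_tau_one_freezes_target_bitwise(self, micro_encoder_config, rng):
        cfg = TrainConfig(batch_size=4, epochs=1, tau=1.0, seed=7,
                          encoder=micro_encoder_config)
        state = init_state(cfg)
        before = [p.data.copy() for p in state.target_parameters()]
        for _ in range(10):
            train_step(_pair_batch(rng), state)
        for p, b in zip(state.target_parameters(), before):
            assert np.array_equal(p.data, b)

    def test_online_parameters_move(self, state, rng):
        before = state.online_encoder.state_dict()
        train_step(_pair_batch(rng), state)
        after = state.online_encoder.state_dict()
        assert any(not np.array_equal(before[k], after[k]) for k in before)

    def test_loss_decreases_on_fixed_batch(self, micro_encoder_config):
        cfg = TrainConfig(batch_size=8, epochs=1, learning_rate=1e-3, seed=9,
                          encoder=micro_encoder_config)
        state = init_state(cfg)
        rng = np.random.default_rng(1)
        base = rng.standard_normal((8, 300))
        batch = ps.PositivePairBatch(anchor=base, view=base + 0.1 * rng.standard_normal((8, 300)))
        losses = [train_step(batch, state)[1] for _ in range(50)]
        assert np.mean(losses[-5:]) < np.mean(losses[:5])

    def test_step_counter_and_history(self, state, rng):
        for i in range(4):
            train_step(_pair_batch(rng), state)
        assert state.step == 4
        assert [h["step"] for h in state.history] == [1, 2, 3, 4]


class TestPretrain:
    def _config(self, enc, kind="time_shift", epochs=2, seed=21):
        return TrainConfig(batch_size=8, epochs=epochs, seed=seed, encoder=enc,
                           augmentation=ps.AugmentationConfig(kind=kind, seed=seed))

    def _recordings(self, n_epochs=33):
        # low-rate templates so the 10 Hz micro encoder's Nyquist holds
        templates = tuple(
            ps.StageSignalTemplate(s, ((0.5 + 0.8 * int(s), 1.0),))
            for s in ps.StageLabel)
        cfg = ps.SyntheticConfig(n_epochs=n_epochs, sampling_rate=10, seed=13,
                                 templates=templates)
        rec, _ = ps.generate_subject(cfg)
        return [ps.normalize(rec)[0]]

    def test_seeded_rerun_is_bitwise_identical(self, micro_encoder_config):
        recs = self._recordings()
        cfg = self._config(micro_encoder_config)
        enc1, hist1 = pretrain(recs, cfg)
        enc2, hist2 = pretrain(recs, cfg)
        s1, s2 = enc1.state_dict(), enc2.state_dict()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)
        assert [h["loss"] for h in hist1] == [h["loss"] for h in hist2]

    def test_history_length_is_epochs_times_batches(self, micro_encoder_config):
        recs = self._recordings(n_epochs=33)  # 32 time-shift pairs -> 4 batches of 8
        _, hist = pretrain(recs, self._config(micro_encoder_config, epochs=3))
        assert len(hist) == 3 * 4

    def test_representation_spread_stays_alive(self, micro_encoder_config):
        """Collapse monitor: the representation std never drops to (near) zero."""
        _, hist = pretrain(self._recordings(), self._config(micro_encoder_config, epochs=3))
        assert min(h["rep_std"] for h in hist) > 1e-3

    @pytest.mark.parametrize("kind", ["none", "mixup", "gaussian", "random_mask", "scaling"])
    def test_all_augmentations_train(self, micro_encoder_config, kind):
        _, hist = pretrain(self._recordings(), self._config(micro_encoder_config, kind=kind, epochs=1))
        assert len(hist) == 4 and np.isfinite([h["loss"] for h in hist]).all()

    def test_empty_dataset_rejected(self, micro_encoder_config):
        with pytest.raises(ValueError, match="empty"):
            pretrain([], self._config(micro_encoder_config))
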