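import numpy as np
import pytest

from rxnrl.datasets import DatasetBundle, LabeledReaction
from rxnrl.forward_model import ModelDims, Seq2SeqPolicy, Vocab
from rxnrl.nn.autodiff import Tensor
from rxnrl.nn.optim import Adam
from rxnrl.rl import (
    RLTrainConfig,
    TrainingCollapseError,
    ValueNetwork,
    collect_rollouts,
    estimate_value,
    policy_update,
    train_rl,
)


class StubReward:
    """Deterministic reward: 1 when the product starts with the target token."""

    def __init__(self, target="C"):
        self.target = target
        self.binary = False

    def reward_batch(self, pairs):
        return [1.0 if p.startswith(self.target) and p else 0.0 for _, p in pairs]


def bandit_policy(seed=0):
    vocab = Vocab(["C", "N", "O"])
    return Seq2SeqPolicy(
        vocab, ModelDims(d_model=16, n_heads=2, n_layers=1, d_ff=32, max_len=8), seed=seed
    )


def small_config(**kw):
    defaults = dict(
        rollouts_per_epoch=32, epochs=2, lr_policy=3e-3, lr_value=1e-2,
        max_len=4, seed=0, kl_coeff=0.02,
    )
    defaults.update(kw)
    return RLTrainConfig(**defaults)


class TestValueNetwork:
    def test_outputs_strictly_in_unit_interval(self, rng):
        net = ValueNetwork(8, seed=0)
        net.fc2.w.data[:] = rng.normal(size=net.fc2.w.data.shape) * 0.3
        x = rng.normal(size=(1000, 8))
        v = estimate_value(net, x)
        assert np.all((v > 0) & (v < 1))

    def test_zero_initialized_head_predicts_half(self, rng):
        net = ValueNetwork(8, seed=0)
        v = estimate_value(net, rng.normal(size=(50, 8)))
        np.testing.assert_allclose(v, 0.5, atol=1e-12)

    def test_shape_mismatch_raises(self, rng):
        net = ValueNetwork(8, seed=0)
        with pytest.raises(ValueError):
            estimate_value(net, rng.normal(size=(5, 9)))

    def test_regression_to_constant_reward(self, rng):
        """Value regression on constant reward 0.7 converges to 0.7."""
        net = ValueNetwork(8, seed=0)
        opt = Adam(net.parameters(), lr=1e-2)
        states = rng.normal(size=(64, 8))
        for _ in range(300):
            opt.zero_grad()
            v = net(Tensor(states))
            loss = ((v - 0.7) ** 2.0).mean()
            loss.backward()
            opt.step()
        np.testing.assert_allclose(estimate_value(net, states), 0.7, atol=0.05)


class TestCollectRollouts:
    def test_kl_term_zero_when_policy_equals_reference(self):
        policy = bandit_policy()
        batch = collect_rollouts(
            policy, policy.clone(), StubReward(), ["C.N"], small_config()
        )
        for it in batch.items:
            assert it.logp_policy == pytest.approx(it.logp_ref, abs=1e-4)

    def test_zero_kl_coeff_makes_return_equal_reward(self):
        policy = bandit_policy()
        ref = policy.clone()
        # perturb the reference so the KL term would be nonzero if weighted
        ref.out_proj.b.data[:] += 0.5
        batch = collect_rollouts(
            policy, ref, StubReward(), ["C.N"], small_config(kl_coeff=0.0)
        )
        for it in batch.items:
            assert it.kl_reward == it.reward

    def test_rewards_bounded(self):
        policy = bandit_policy()
        batch = collect_rollouts(
            policy, policy.clone(), StubReward(), ["C.N", "N.O"], small_config()
        )
        assert all(0.0 <= it.reward <= 1.0 for it in batch.items)

    def test_deterministic_given_generator(self):
        policy = bandit_policy()
        cfg = small_config()
        b1 = collect_rollouts(policy, policy.clone(), StubReward(), ["C.N"], cfg,
                              rng=np.random.default_rng(9))
        b2 = collect_rollouts(policy, policy.clone(), StubReward(), ["C.N"], cfg,
                              rng=np.random.default_rng(9))
        assert [it.sample.token_ids for it in b1.items] == [it.sample.token_ids for it in b2.items]


class TestPolicyUpdate:
    def _batch(self, policy, cfg):
        return collect_rollouts(policy, policy.clone(), StubReward(), ["C.N"], cfg,
                                value_net=None, rng=np.random.default_rng(0))

    def test_zero_advantages_leave_policy_unchanged(self):
        policy = bandit_policy()
        cfg = small_config(normalize_advantages=False)
        batch = self._batch(policy, cfg)
        for it in batch.items:
            it.advantage = 0.0
        before = {k: v.copy() for k, v in policy.state_dict().items()}
        net = ValueNetwork(policy.dims.d_model, seed=0)
        policy_update(policy, policy.clone(), net, batch, cfg)
        after = policy.state_dict()
        for k in before:
            np.testing.assert_allclose(before[k], after[k], atol=1e-7)

    def test_on_policy_first_step_has_zero_clip_fraction(self):
        policy = bandit_policy()
        cfg = small_config()
        batch = self._batch(policy, cfg)
        net = ValueNetwork(policy.dims.d_model, seed=0)
        _, _, stats = policy_update(policy, policy.clone(), net, batch, cfg)
        assert stats["clip_fraction"] == 0.0

    def test_empty_batch_rejected(self):
        policy = bandit_policy()
        net = ValueNetwork(policy.dims.d_model, seed=0)
        from rxnrl.rl import RolloutBatch

        with pytest.raises(ValueError):
            policy_update(policy, policy.clone(), net, RolloutBatch(items=[]), small_config())

    def test_bandit_reward_raises_target_probability(self):
        """Rewarding one first token steadily raises its sampling probability."""
        from rxnrl.forward_model import _encode_lhs

        policy = bandit_policy(seed=3)
        ref = policy.clone()
        net = ValueNetwork(policy.dims.d_model, seed=0)
        cfg = small_config(rollouts_per_epoch=48, kl_coeff=0.0, lr_policy=5e-3,
                           normalize_advantages=False)
        rng = np.random.default_rng(0)
        p_opt = Adam(policy.parameters(), lr=cfg.lr_policy)
        v_opt = Adam(net.parameters(), lr=cfg.lr_value)

        def p_target():
            from rxnrl.nn.autodiff import no_grad

            with no_grad():
                enc = _encode_lhs(policy, ["C.N"])
                logp = policy.decode_logprobs(enc, np.array([[policy.vocab.bos_id]]))
            tid = policy.vocab.index["C"]
            return float(np.exp(logp.data[0, -1, tid]))

        p0 = p_target()
        probs = [p0]
        for _ in range(50):
            batch = collect_rollouts(policy, ref, StubReward("C"), ["C.N"], cfg,
                                     value_net=net, rng=rng)
            policy_update(policy, ref, net, batch, cfg, p_opt, v_opt)
            probs.append(p_target())
        assert probs[-1] > p0
        assert probs[-1] > 0.5
        # overall trend is upward: most steps do not decrease the probability
        ups = sum(b >= a - 1e-6 for a, b in zip(probs, probs[1:]))
        assert ups >= 0.7 * len(probs[1:])


class TestTrainRL:
    def _bundle(self, policy):
        from rxnrl.chemio import Molecule, Reaction

        def lr(lhs, prod, label="positive"):
            return LabeledReaction(
                reaction=Reaction(
                    precursors=tuple(Molecule(p) for p in lhs.split(".")),
                    product=Molecule(prod),
                ),
                label=label,
            )

        train = [lr("C.N", "C"), lr("C.N", "N", "negative"), lr("N.O", "C")]
        valid = [lr("C.O", "C")]
        return DatasetBundle(train=train, valid=valid, test=valid)

    def test_reference_policy_and_input_policy_unchanged(self):
        policy = bandit_policy()
        before = {k: v.copy() for k, v in policy.state_dict().items()}
        bundle = self._bundle(policy)
        train_rl(policy, bundle, StubReward(), small_config(epochs=2))
        after = policy.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_history_is_deterministic_given_seed(self):
        policy = bandit_policy()
        bundle = self._bundle(policy)
        cfg = small_config(epochs=2, seed=11)
        _, h1 = train_rl(policy, bundle, StubReward(), cfg)
        _, h2 = train_rl(policy, bundle, StubReward(), cfg)
        assert h1 == h2

    def test_history_rewards_bounded_and_epochs_complete(self):
        policy = bandit_policy()
        bundle = self._bundle(policy)
        _, history = train_rl(policy, bundle, StubReward(), small_config(epochs=3))
        assert len(history) == 4  # epoch-0 baseline + 3 epochs
        for h in history[1:]:
            assert 0.0 <= h["mean_reward"] <= 1.0
            assert h["mean_kl"] > -0.5  # sample estimate may dip slightly below zero

    def test_kl_guard_aborts_collapsed_training(self):
        policy = bandit_policy()
        bundle = self._bundle(policy)
        cfg = small_config(epochs=2, kl_guard=1e-9, lr_policy=0.5, kl_coeff=0.0)
        with pytest.raises(TrainingCollapseError):
            train_rl(policy, bundle, StubReward(), cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RLTrainConfig(kl_coeff=-1)
        with pytest.raises(ValueError):
            RLTrainConfig(clip_eps=0)
        with pytest.raises(ValueError):
            RLTrainConfig(temperature=0)
        with pytest.raises(ValueError):
            RLTrainConfig(epochs=0)
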