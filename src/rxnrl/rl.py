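"""RLHF-style tuning of the forward-prediction policy against a learned reward.

Each epoch samples product sequences from the policy for training left-hand
sides, scores them with the composite reward model, applies a per-sequence KL
penalty toward the frozen reference policy, and takes clipped-surrogate policy
gradient steps with a sigmoid-output value network as baseline.  Negative
reactions never enter maximum-likelihood training; their information flows in
exclusively through the reward signal on these rollouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import DatasetBundle
from .forward_model import (
    MLEConfig,
    Seq2SeqPolicy,
    SampledSequence,
    _as_pairs,
    sample_decode_batch,
    top1_accuracy,
)
from .nn import autodiff as ad
from .nn.autodiff import Tensor, no_grad
from .nn.layers import Linear, Module
from .nn.optim import Adam
from .reward import RewardModel


class TrainingCollapseError(RuntimeError):
    """Mean KL to the reference exceeded the guard threshold."""


@dataclass
class RLTrainConfig:
    """Knobs of the RL tuner; defaults are the desk-scale working point."""

    kl_coeff: float = 0.1
    clip_eps: float = 0.2
    rollouts_per_epoch: int = 128
    epochs: int = 30
    lr_policy: float = 3e-5
    lr_value: float = 1e-3
    temperature: float = 1.0
    seed: int = 0
    binary_reward: bool = False
    update_iters: int = 2
    normalize_advantages: bool = True
    max_len: int = 64
    kl_guard: float = 50.0
    value_hidden: int = 64

    def __post_init__(self):
        if self.kl_coeff < 0 or self.clip_eps <= 0 or self.temperature <= 0:
            raise ValueError("kl_coeff >= 0, clip_eps > 0, temperature > 0 required")
        if min(self.rollouts_per_epoch, self.epochs) <= 0:
            raise ValueError("rollouts_per_epoch and epochs must be positive")


class ValueNetwork(Module):
    """State-value head over the pooled encoder representation of the input.

    Two linear layers separated by a ReLU, with a sigmoid output, so estimates
    live strictly in (0, 1) — matching the reward scale.  The final layer is
    zero-initialized, so an untrained network predicts 0.5.
    """

    def __init__(self, d_in: int, hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.fc1 = Linear(d_in, hidden, rng)
        self.fc2 = Linear(hidden, 1, rng)
        self.fc2.w.data[:] = 0.0
        self.fc2.b.data[:] = 0.0

    def __call__(self, state: Tensor) -> Tensor:
        return ad.sigmoid(self.fc2(ad.relu(self.fc1(state))))[:, 0]


def estimate_value(value_net: ValueNetwork, policy_state: Tensor | np.ndarray) -> np.ndarray:
    """Expected-reward baseline for pooled policy states, in (0, 1)."""
    state = policy_state if isinstance(policy_state, Tensor) else Tensor(np.atleast_2d(policy_state))
    if state.data.ndim != 2 or state.data.shape[1] != value_net.fc1.w.data.shape[0]:
        raise ValueError(
            f"expected (B, {value_net.fc1.w.data.shape[0]}) state, got {state.data.shape}"
        )
    with no_grad():
        return value_net(state).data


@dataclass
class RolloutItem:
    lhs: str
    sample: SampledSequence
    logp_policy: float
    logp_ref: float
    reward: float
    kl_reward: float  # reward minus KL penalty
    value: float
    advantage: float


@dataclass
class RolloutBatch:
    items: list[RolloutItem]

    def __len__(self) -> int:
        return len(self.items)

    @property
    def mean_reward(self) -> float:
        return float(np.mean([it.reward for it in self.items]))

    @property
    def mean_kl(self) -> float:
        return float(np.mean([it.logp_policy - it.logp_ref for it in self.items]))


def _ref_logprobs(policy: Seq2SeqPolicy, lhs_list: list[str], samples: list[SampledSequence]) -> np.ndarray:
    tgt = [[policy.vocab.bos_id] + s.token_ids for s in samples]
    with no_grad():
        picked, valid = policy.batch_logprobs(lhs_list, tgt)
    return (picked.data * valid).sum(axis=1)


def collect_rollouts(
    policy: Seq2SeqPolicy,
    ref_policy: Seq2SeqPolicy,
    reward_model: RewardModel,
    lhs_pool: list[str],
    config: RLTrainConfig,
    value_net: ValueNetwork | None = None,
    rng: np.random.Generator | None = None,
) -> RolloutBatch:
    """Sample products for training left-hand sides and score them.

    The KL-penalized return of a sampled sequence is
    ``r_tilde = r - kl_coeff * (log pi(seq) - log pi_ref(seq))``; at
    initialization, when the policy equals the reference, the penalty is zero
    for every item.  Invalid samples simply receive the invalid reward.
    """
    rng = rng or np.random.default_rng(config.seed)
    idx = rng.integers(len(lhs_pool), size=config.rollouts_per_epoch)
    lhs_list = [lhs_pool[int(i)] for i in idx]
    samples = sample_decode_batch(
        policy, lhs_list, temperature=config.temperature, rng=rng, max_len=config.max_len
    )
    logp_pol = np.array([s.total_logprob for s in samples])
    logp_ref = _ref_logprobs(ref_policy, lhs_list, samples)
    rewards = np.array(
        reward_model.reward_batch([(l, s.product) for l, s in zip(lhs_list, samples)])
    )
    kl_terms = logp_pol - logp_ref
    r_tilde = rewards - config.kl_coeff * kl_terms
    if value_net is not None:
        with no_grad():
            values = value_net(policy.pooled_state(lhs_list)).data
    else:
        values = np.zeros(len(lhs_list))
    adv = r_tilde - values
    if config.normalize_advantages and len(adv) > 1 and adv.std() > 1e-8:
        adv = (adv - adv.mean()) / adv.std()
    items = [
        RolloutItem(
            lhs=l,
            sample=s,
            logp_policy=float(lp),
            logp_ref=float(lr),
            reward=float(r),
            kl_reward=float(rt),
            value=float(v),
            advantage=float(a),
        )
        for l, s, lp, lr, r, rt, v, a in zip(
            lhs_list, samples, logp_pol, logp_ref, rewards, r_tilde, values, adv
        )
    ]
    return RolloutBatch(items=items)


def policy_update(
    policy: Seq2SeqPolicy,
    ref_policy: Seq2SeqPolicy,
    value_net: ValueNetwork,
    batch: RolloutBatch,
    config: RLTrainConfig,
    policy_opt: Adam | None = None,
    value_opt: Adam | None = None,
) -> tuple[Seq2SeqPolicy, ValueNetwork, dict]:
    """One clipped-surrogate policy-gradient step plus one value regression step.

    The sequence-level importance ratio against the rollout log-probabilities is
    clipped to ``[1 - eps, 1 + eps]``; the value network regresses toward the
    realized KL-penalized returns.  With all advantages zero the policy gradient
    vanishes and the policy is unchanged.
    """
    if not batch.items:
        raise ValueError("empty rollout batch")
    policy_opt = policy_opt or Adam(policy.parameters(), lr=config.lr_policy)
    value_opt = value_opt or Adam(value_net.parameters(), lr=config.lr_value)

    lhs_list = [it.lhs for it in batch.items]
    tgt = [[policy.vocab.bos_id] + it.sample.token_ids for it in batch.items]
    adv = np.array([it.advantage for it in batch.items])
    logp_old = np.array([it.logp_policy for it in batch.items])
    returns = np.array([it.kl_reward for it in batch.items])

    policy_opt.zero_grad()
    picked, valid = policy.batch_logprobs(lhs_list, tgt)
    logp_new = (picked * Tensor(valid)).sum(axis=1)
    ratio = ad.exp(logp_new - Tensor(logp_old))
    clipped = np.clip(ratio.data, 1 - config.clip_eps, 1 + config.clip_eps)
    # surrogate objective: elementwise min of unclipped and clipped terms
    use_clipped = (clipped * adv) < (ratio.data * adv)
    mask_un = Tensor((~use_clipped).astype(float) * adv)
    surrogate = ratio * mask_un + Tensor(use_clipped.astype(float) * clipped * adv)
    loss = -surrogate.mean()
    if not math.isfinite(loss.data.item()):
        raise FloatingPointError("non-finite policy loss")
    loss.backward()
    policy_opt.step()

    value_opt.zero_grad()
    states = policy.pooled_state(lhs_list)
    states = Tensor(states.data)  # value step must not backprop into the policy
    v = value_net(states)
    v_loss = ((v - Tensor(returns)) ** 2.0).mean()
    v_loss.backward()
    value_opt.step()

    clip_fraction = float(np.mean(np.abs(ratio.data - 1) > config.clip_eps))
    stats = {
        "mean_reward": batch.mean_reward,
        "mean_kl": batch.mean_kl,
        "clip_fraction": clip_fraction,
        "policy_loss": float(loss.data),
        "value_loss": float(v_loss.data),
    }
    return policy, value_net, stats


def train_rl(
    policy: Seq2SeqPolicy,
    bundle: DatasetBundle,
    reward_model: RewardModel,
    config: RLTrainConfig | None = None,
) -> tuple[Seq2SeqPolicy, list[dict]]:
    """Tune a copy of *policy* with RL; returns the best-validation checkpoint.

    The input policy is deep-copied twice: once as the trainable policy and once
    as the frozen reference, which is never updated.  Rollout left-hand sides
    are those of the training reactions — positives and negatives share them by
    construction, so even inputs whose positive outcome was withheld still
    steer the policy through reward.  After each epoch, greedy top-1 positive
    accuracy on the validation split is recorded; the starting model counts as
    the epoch-0 candidate, so an unsuccessful run falls back to it.
    """
    config = config or RLTrainConfig()
    if config.binary_reward and not reward_model.binary:
        reward_model = RewardModel(**{**vars(reward_model), "binary": True})
    ref_policy = policy.clone()
    policy = policy.clone()
    value_net = ValueNetwork(
        policy.dims.d_model, hidden=config.value_hidden, seed=config.seed
    )
    rng = np.random.default_rng(config.seed)
    lhs_pool = sorted({r.reaction.lhs for r in bundle.train})
    valid_pairs = _as_pairs(bundle.valid)
    policy_opt = Adam(policy.parameters(), lr=config.lr_policy)
    value_opt = Adam(value_net.parameters(), lr=config.lr_value)

    best_acc = top1_accuracy(policy, valid_pairs, max_len=config.max_len)
    best_state = policy.state_dict()
    history: list[dict] = [
        {"epoch": 0, "mean_reward": None, "mean_kl": 0.0,
         "clip_fraction": 0.0, "valid_top1": best_acc}
    ]
    for epoch in range(1, config.epochs + 1):
        batch = collect_rollouts(
            policy, ref_policy, reward_model, lhs_pool, config,
            value_net=value_net, rng=rng,
        )
        if abs(batch.mean_kl) > config.kl_guard:
            raise TrainingCollapseError(
                f"mean KL {batch.mean_kl:.2f} exceeded guard {config.kl_guard} "
                f"at epoch {epoch}"
            )
        for _ in range(config.update_iters):
            policy, value_net, stats = policy_update(
                policy, ref_policy, value_net, batch, config, policy_opt, value_opt
            )
        acc = top1_accuracy(policy, valid_pairs, max_len=config.max_len)
        entry = {"epoch": epoch, "valid_top1": acc, **stats}
        history.append(entry)
        if acc > best_acc:
            best_acc = acc
            best_state = policy.state_dict()
    policy.load_state_dict(best_state)
    return policy, history
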