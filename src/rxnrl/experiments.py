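"""End-to-end experiment harness: base-model pretraining, per-seed construction
of the abundant/scarce-positive regimes, fine-tuning and RL tuning, and the
multi-seed comparison between the two strategies.

The base policy is pretrained once on the synthetic corpus; seeds then vary
the family data splits and the initialization of the tuning stages, never the
base model — matching the protocol of comparing tuning strategies on multiple
random splits from a fixed pretrained starting point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .datasets import DatasetBundle, subsample_positives
from .evalx import evaluate_policy
from .forward_model import (
    MLEConfig,
    ModelDims,
    Seq2SeqPolicy,
    Vocab,
    top1_accuracy,
    train_mle,
)
from .reward import (
    ClassifierConfig,
    EncoderDims,
    ReactionEncoder,
    RewardModel,
    TuneConfig,
    build_reward_model,
    classification_tune,
)
from .rl import RLTrainConfig, train_rl
from .toychem import (
    HTE_CONDITIONS,
    PoolPartition,
    PretrainCorpus,
    ToySpec,
    make_pretrain_corpus,
    make_regio_family,
    partition_pool,
    scaffolds_to_records,
)

logger = logging.getLogger(__name__)


@dataclass
class BaseArtifacts:
    """Everything downstream stages need from the pretraining stage."""

    spec: ToySpec
    partition: PoolPartition
    corpus: PretrainCorpus
    vocab: Vocab
    policy: Seq2SeqPolicy
    pretrain_history: list[dict] = field(default_factory=list)
    _pretrain_top1: float | None = field(default=None, repr=False)

    def pretrain_test_pairs(self) -> list[tuple[str, str]]:
        return [(r.lhs, r.product.smiles) for r in self.corpus.test]

    def pretrain_top1(self) -> float:
        """Base policy's accuracy on the held-out pretraining slice (cached)."""
        if self._pretrain_top1 is None:
            self._pretrain_top1 = top1_accuracy(self.policy, self.pretrain_test_pairs())
        return self._pretrain_top1


def build_vocab(spec: ToySpec, partition: PoolPartition, corpus: PretrainCorpus) -> Vocab:
    """Vocabulary over the full toy grammar: corpus, family and condition tokens."""
    texts = []
    for r in corpus.reactions:
        texts.append(r.serialize())
        texts.append(r.training_target)
    for sc in partition.family + partition.reward_tune:
        pos = sc.positive_reaction()
        texts.append(pos.serialize())
        texts.append(pos.training_target)
        texts.extend(r.serialize() for r in sc.negative_reactions())
    for cat, solv in HTE_CONDITIONS:
        texts.append(f"{cat}.{solv}>>{cat}")
    return Vocab.from_texts(texts)


def prepare_base(
    spec: ToySpec | None = None,
    dims: ModelDims | None = None,
    pretrain_config: MLEConfig | None = None,
    n_valid: int = 60,
    n_test: int = 60,
) -> BaseArtifacts:
    """Generate the toy corpus and pretrain the base forward model on it.

    The checkpoint with the best top-1 accuracy on the held-out pretraining
    slice is kept; downstream stages treat this policy as the frozen starting
    point (and RL's reference).
    """
    spec = spec or ToySpec()
    partition = partition_pool(spec, n_valid=n_valid, n_test=n_test)
    corpus = make_pretrain_corpus(spec, partition=partition)
    vocab = build_vocab(spec, partition, corpus)
    dims = dims or ModelDims()
    policy = Seq2SeqPolicy(vocab, dims, seed=spec.seed)
    config = pretrain_config or MLEConfig(
        epochs=22, batch_size=64, lr=3e-3, seed=spec.seed, eval_every=3
    )
    logger.info("pretraining on %d reactions", len(corpus.train))
    policy, history = train_mle(policy, corpus.train, config, valid=corpus.test)
    return BaseArtifacts(
        spec=spec,
        partition=partition,
        corpus=corpus,
        vocab=vocab,
        policy=policy,
        pretrain_history=history,
    )


@dataclass
class TuningConfigs:
    """Per-seed tuning stage configurations (seeds are filled in per run)."""

    ft: MLEConfig = field(default_factory=lambda: MLEConfig(epochs=10, batch_size=16, lr=1e-3))
    reward_tune: TuneConfig = field(default_factory=TuneConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    rl: RLTrainConfig = field(default_factory=RLTrainConfig)
    encoder_dims: EncoderDims = field(default_factory=EncoderDims)


def build_reward_for_bundle(
    base: BaseArtifacts,
    bundle: DatasetBundle,
    configs: TuningConfigs,
    seed: int,
    binary: bool = False,
) -> tuple[RewardModel, ReactionEncoder, ReactionEncoder]:
    """Classification-tune a fresh reaction encoder and fit the SVM on the bundle.

    Returns (reward model, tuned encoder, base encoder).  The tuning data is the
    reward slice of the scaffold pool — disjoint from the family splits and from
    pretraining — with rule-generated negatives providing the failed class.
    """
    tune_records = scaffolds_to_records(base.partition.reward_tune, with_negatives=True)
    base_encoder = ReactionEncoder(base.vocab, configs.encoder_dims, seed=seed)
    tuned = classification_tune(
        base_encoder, tune_records, dc_replace(configs.reward_tune, seed=seed)
    )
    reward = build_reward_model(
        tuned, bundle, dc_replace(configs.classifier, seed=seed), binary=binary
    )
    return reward, tuned, base_encoder


def run_hte_workflow(
    base: BaseArtifacts,
    seed: int,
    configs: TuningConfigs | None = None,
    ratios: tuple[float, float, float] = (0.4, 0.4, 0.3),
    threshold_pct: float = 1.0,
    n_hte: int = 16,
) -> dict[str, float]:
    """Screening-grid variant: fine-tune against domain shift, then RL.

    A substrates x conditions grid with rule-driven yields is labeled by the
    strict yield threshold and split 40:40:30 (normalized proportions;
    negatives stay in train).  The policy is first fine-tuned on the grid's
    positives — screening reactions carry condition tokens the base model has
    never produced — and then RL-tuned with the *binary* reward, which
    encourages above-threshold reactions and discourages the rest.
    """
    from dataclasses import replace

    from .datasets import split_dataset
    from .forward_model import top1_accuracy
    from .toychem import make_hte_grid

    configs = configs or TuningConfigs()
    spec = replace(base.spec, hte=True)
    partition = partition_pool(spec, n_hte=n_hte)
    grid = make_hte_grid(spec, partition=partition)
    bundle = split_dataset(grid, ratios=ratios, seed=seed)
    valid_pairs = [(r.reaction.lhs, r.reaction.product.smiles) for r in bundle.valid]

    ft_policy, _ = train_mle(
        base.policy.clone(),
        bundle.train_positives,
        dc_replace(configs.ft, seed=seed),
        valid=bundle.valid,
    )
    reward, _, _ = build_reward_for_bundle(base, bundle, configs, seed, binary=True)
    rl_config = dc_replace(configs.rl, seed=seed, binary_reward=True)
    rl_policy, _ = train_rl(ft_policy, bundle, reward, rl_config)
    return {
        "base_valid_top1": top1_accuracy(base.policy, valid_pairs),
        "ft_valid_top1": top1_accuracy(ft_policy, valid_pairs),
        "rl_valid_top1": top1_accuracy(rl_policy, valid_pairs),
        "n_train_pos": float(len(bundle.train_positives)),
        "n_train_neg": float(len(bundle.train_negatives)),
    }


def reward_embedding_ordering(
    base: BaseArtifacts,
    seed: int,
    configs: TuningConfigs | None = None,
    subsample_fraction: float = 0.1,
    n_heldout: int = 40,
) -> dict[str, float]:
    """Compare reward classifiers on base vs classification-tuned embeddings.

    Both classifiers are fitted on the scarce-positive training split's
    embeddings and scored by balanced accuracy on a held-out set built from
    validation positives and their enumerable regio-negatives.  Classification
    tuning of the encoder is expected to cast the two classes further apart
    and lift this score.
    """
    from sklearn.metrics import balanced_accuracy_score

    from .datasets import generate_regio_negatives
    from .reward import embed_reactions, fit_reward_classifier

    configs = configs or TuningConfigs()
    bundle = make_regio_family(base.spec, partition=base.partition, split_seed=seed)
    bundle = subsample_positives(bundle, fraction=subsample_fraction, seed=seed)
    _, tuned, base_enc = build_reward_for_bundle(base, bundle, configs, seed)
    train_rxns = [r.reaction for r in bundle.train]
    y_train = np.array([1 if r.is_positive else 0 for r in bundle.train])
    held, y_held = [], []
    for rec in bundle.valid[:n_heldout]:
        held.append(rec.reaction)
        y_held.append(1)
        negs = generate_regio_negatives(rec.reaction)
        held.extend(negs)
        y_held.extend([0] * len(negs))
    y_held = np.array(y_held)
    out = {}
    for name, encoder in (("tuned", tuned), ("base", base_enc)):
        clf = fit_reward_classifier(
            embed_reactions(encoder, train_rxns), y_train,
            dc_replace(configs.classifier, seed=seed),
        )
        pred = clf.predict(embed_reactions(encoder, held))
        out[f"balanced_accuracy_{name}"] = float(balanced_accuracy_score(y_held, pred))
    return out


def run_ft_rl_comparison(
    base: BaseArtifacts,
    seed: int,
    regime: str = "low",
    subsample_fraction: float = 0.1,
    configs: TuningConfigs | None = None,
    n_valid: int = 60,
    n_test: int = 60,
    eval_beams: int = 10,
) -> dict[str, float]:
    """Fine-tune and RL-tune the base model on one data split; score both.

    ``regime="high"`` uses every available training positive; ``"low"``
    subsamples them to ``subsample_fraction`` while keeping the full negative
    pool.  RL starts from the base policy (not from the fine-tuned one).
    Returns validation/test accuracies for both strategies plus the
    pretraining-domain accuracy before and after RL (forgetting control).
    """
    configs = configs or TuningConfigs()
    bundle = make_regio_family(
        base.spec, partition=base.partition, n_valid=n_valid, n_test=n_test,
        split_seed=seed,
    )
    if regime == "low":
        bundle = subsample_positives(bundle, fraction=subsample_fraction, seed=seed)
    elif regime != "high":
        raise ValueError(f"unknown regime {regime!r}")

    base_valid_top1 = top1_accuracy(base.policy, [(r.reaction.lhs, r.reaction.product.smiles) for r in bundle.valid])

    ft_policy, _ = train_mle(
        base.policy.clone(),
        bundle.train_positives,
        dc_replace(configs.ft, seed=seed),
        valid=bundle.valid,
    )
    reward, _, _ = build_reward_for_bundle(base, bundle, configs, seed)
    rl_policy, rl_history = train_rl(
        base.policy, bundle, reward, dc_replace(configs.rl, seed=seed)
    )

    valid_pairs = [(r.reaction.lhs, r.reaction.product.smiles) for r in bundle.valid]
    pre_pairs = base.pretrain_test_pairs()
    ft_val = top1_accuracy(ft_policy, valid_pairs)
    rl_val = top1_accuracy(rl_policy, valid_pairs)
    ft_test, _ = evaluate_policy(ft_policy, bundle.test, ks=(1, 2), beams=eval_beams, seed=seed)
    rl_test, _ = evaluate_policy(rl_policy, bundle.test, ks=(1, 2), beams=eval_beams, seed=seed)
    return {
        "base_valid_top1": base_valid_top1,
        "ft_valid_top1": ft_val,
        "rl_valid_top1": rl_val,
        "ft_test_top1": ft_test.topk_accuracy[1],
        "ft_test_top2": ft_test.topk_accuracy[2],
        "rl_test_top1": rl_test.topk_accuracy[1],
        "rl_test_top2": rl_test.topk_accuracy[2],
        "ft_test_invalid_top1": ft_test.invalid_fraction[1],
        "rl_test_invalid_top1": rl_test.invalid_fraction[1],
        "pretrain_top1_before_rl": base.pretrain_top1(),
        "pretrain_top1_after_rl": top1_accuracy(rl_policy, pre_pairs),
        "rl_mean_reward_first": next(
            (h["mean_reward"] for h in rl_history if h["epoch"] == 1), float("nan")
        ),
        "rl_mean_reward_last": rl_history[-1].get("mean_reward", float("nan")),
        "n_train_pos": float(len(bundle.train_positives)),
        "n_train_neg": float(len(bundle.train_negatives)),
    }
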