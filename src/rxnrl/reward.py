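"""The reward model: reaction-fingerprint embeddings, classification tuning,
an imbalance-aware SVM, class-separation diagnostics, and the composite reward.

A compact bidirectional transformer encoder maps a serialized reaction to a
fixed-length fingerprint vector.  Optionally the encoder is tuned on the
auxiliary task of classifying successful vs. unsuccessful reactions (the head
is discarded afterwards), which casts negatives further from positives in the
embedding space and makes the downstream maximum-margin classifier far more
effective.  The composite reward consumed by RL is label-faithful on known
reactions and falls back to the calibrated classifier elsewhere.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import cross_val_predict, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import chemio
from .chemio import Reaction, tokenize
from .datasets import DatasetBundle, LabeledReaction
from .forward_model import Vocab, _pad_batch
from .nn import autodiff as ad
from .nn.autodiff import Tensor, no_grad
from .nn import layers
from .nn.layers import Module, Linear, LayerNorm, Embedding, padding_mask
from .nn.optim import Adam


class SingleClassError(ValueError):
    """Both outcome classes are required."""


@dataclass
class EncoderDims:
    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 2
    d_ff: int = 128
    max_len: int = 112


class ReactionEncoder(Module):
    """Bidirectional transformer encoder over full reaction strings.

    ``pooling`` is either ``"mean"`` (masked mean over positions, default) or
    ``"first"`` (the first token's state).  Embeddings are deterministic in
    inference mode.
    """

    def __init__(
        self,
        vocab: Vocab,
        dims: EncoderDims | None = None,
        pooling: str = "mean",
        seed: int = 0,
    ):
        if pooling not in ("mean", "first"):
            raise ValueError(f"unknown pooling {pooling!r}")
        self.vocab = vocab
        self.dims = dims or EncoderDims()
        self.pooling = pooling
        rng = np.random.default_rng(seed)
        d = self.dims.d_model
        self.tok_emb = Embedding(len(vocab), d, rng)
        self.pos_emb = Embedding(self.dims.max_len, d, rng)
        self.enc_layers = [
            layers.EncoderLayer(d, self.dims.n_heads, self.dims.d_ff, rng)
            for _ in range(self.dims.n_layers)
        ]
        self.norm = LayerNorm(d)

    def forward(self, texts: list[str]) -> Tensor:
        """(B, d) pooled reaction representations (differentiable)."""
        ids = [self.vocab.encode(tokenize(t)) for t in texts]
        src, src_len = _pad_batch(ids, self.vocab.pad_id)
        B, L = src.shape
        pos = np.broadcast_to(np.arange(L), (B, L))
        h = self.tok_emb(src) + self.pos_emb(pos)
        mask = padding_mask(src_len, L)
        for layer in self.enc_layers:
            h = layer(h, mask)
        h = self.norm(h)
        if self.pooling == "first":
            return h[:, 0, :]
        valid = (np.arange(L)[None, :] < src_len[:, None]).astype(float)[:, :, None]
        return (h * Tensor(valid)).sum(axis=1) / Tensor(src_len[:, None].astype(float))

    def clone(self) -> "ReactionEncoder":
        twin = ReactionEncoder(self.vocab, self.dims, self.pooling)
        twin.load_state_dict(self.state_dict())
        return twin


def embed_reaction(encoder: ReactionEncoder, reaction: Reaction) -> np.ndarray:
    """Fingerprint vector of a single reaction (canonical inputs assumed)."""
    return embed_reactions(encoder, [reaction])[0]


def embed_reactions(
    encoder: ReactionEncoder, reactions: list[Reaction] | list[str], batch_size: int = 128
) -> np.ndarray:
    """(N, d) fingerprint matrix; accepts Reactions or serialized strings."""
    texts = [r.serialize() if isinstance(r, Reaction) else r for r in reactions]
    out = []
    with no_grad():
        for i in range(0, len(texts), batch_size):
            out.append(encoder.forward(texts[i : i + batch_size]).data)
    return np.concatenate(out, axis=0) if out else np.zeros((0, encoder.dims.d_model))


# ---------------------------------------------------------------------------
# classification tuning
# ---------------------------------------------------------------------------

@dataclass
class TuneConfig:
    epochs: int = 8
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 0


def classification_tune(
    encoder: ReactionEncoder,
    labeled: list[LabeledReaction],
    config: TuneConfig | None = None,
) -> ReactionEncoder:
    """Tune the encoder on positive/negative reaction classification.

    A linear head on the pooled state is trained jointly with the encoder using
    class-weighted binary cross-entropy (the positives are typically heavily
    underrepresented); the head is discarded and the tuned encoder returned.
    The input encoder is left untouched.
    """
    config = config or TuneConfig()
    texts = [r.reaction.serialize() for r in labeled]
    y = np.array([1.0 if r.is_positive else 0.0 for r in labeled])
    if len(np.unique(y)) < 2:
        raise SingleClassError("classification tuning needs both outcome classes")
    tuned = encoder.clone()
    rng = np.random.default_rng(config.seed)
    head = Linear(tuned.dims.d_model, 1, rng)
    params = tuned.parameters() + head.parameters()
    opt = Adam(params, lr=config.lr)
    n_pos, n_neg = y.sum(), len(y) - y.sum()
    w_pos, w_neg = len(y) / (2 * n_pos), len(y) / (2 * n_neg)
    for _ in range(config.epochs):
        order = rng.permutation(len(texts))
        for start in range(0, len(texts), config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            z = head(tuned.forward([texts[i] for i in idx]))[:, 0]
            p = ad.sigmoid(z)
            yy = y[idx]
            w = np.where(yy == 1, w_pos, w_neg)
            eps = 1e-9
            loss = -(
                Tensor(w * yy) * ad.log(p + eps)
                + Tensor(w * (1 - yy)) * ad.log(1.0 - p + eps)
            ).mean()
            loss.backward()
            opt.step()
    return tuned


# ---------------------------------------------------------------------------
# separation diagnostics
# ---------------------------------------------------------------------------

@dataclass
class SeparationReport:
    """Class-separation diagnostics in an embedding space."""

    pca_projection: np.ndarray  # (N, 2)
    labels: np.ndarray
    #: mean between-class pairwise distance over mean within-class pairwise
    #: distance; ~1 for indistinguishable classes, > 1 when separated
    between_within_ratio: float
    linear_balanced_accuracy: float

    def dominates(self, other: "SeparationReport") -> bool:
        return self.linear_balanced_accuracy > other.linear_balanced_accuracy


def separation_report(
    embeddings: np.ndarray, labels: np.ndarray, seed: int = 0
) -> SeparationReport:
    """Quantify positive/negative separation of embedding vectors.

    Returns the first two principal components for plotting, the ratio of mean
    between-class to mean within-class pairwise distance (1 when the classes
    are indistinguishable), and the held-out balanced accuracy of a linear
    separator.  Degenerate geometry makes the ratio undefined (nan) instead of
    raising.
    """
    from scipy.spatial.distance import cdist, pdist

    labels = np.asarray(labels)
    y = labels.astype(bool) if labels.dtype != bool else labels
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least two points per class")
    n_comp = min(2, embeddings.shape[1], len(embeddings) - 1)
    proj = PCA(n_components=n_comp, random_state=seed).fit_transform(embeddings)
    between = cdist(embeddings[y], embeddings[~y]).mean()
    within_dists = np.concatenate([pdist(embeddings[y]), pdist(embeddings[~y])])
    within = within_dists.mean() if len(within_dists) else 0.0
    ratio = float(between / within) if within > 1e-12 else float("nan")
    try:
        Xtr, Xte, ytr, yte = train_test_split(
            embeddings, y, test_size=0.3, random_state=seed, stratify=y
        )
        clf = LogisticRegression(max_iter=500, class_weight="balanced").fit(Xtr, ytr)
        balacc = float(balanced_accuracy_score(yte, clf.predict(Xte)))
    except ValueError:
        balacc = float("nan")
    return SeparationReport(
        pca_projection=proj,
        labels=y,
        between_within_ratio=ratio,
        linear_balanced_accuracy=balacc,
    )


# ---------------------------------------------------------------------------
# SVM reward classifier and composite reward
# ---------------------------------------------------------------------------

@dataclass
class ClassifierConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    seed: int = 0


class CalibratedSVM(BaseEstimator, ClassifierMixin):
    """Class-weighted SVM with a balanced sigmoid (Platt) probability fit.

    The margin classifier uses class weights inversely proportional to class
    frequency.  Calibration fits a logistic sigmoid — itself class-weighted —
    on cross-validated decision margins, so the probability scale stays
    meaningful when positives are 30x rarer than negatives (a plain Platt fit
    would push every score below one half).
    """

    def __init__(self, kernel="rbf", C=1.0, gamma="scale", seed=0, cv=3):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.seed = seed
        self.cv = cv

    def fit(self, X, y):
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        self.svm_ = SVC(
            kernel=self.kernel, C=self.C, gamma=self.gamma,
            class_weight="balanced", random_state=self.seed,
        )
        n_min = min(np.bincount(y))
        cv = min(self.cv, n_min)
        if cv >= 2:
            margins = cross_val_predict(
                self.svm_, X, y, cv=cv, method="decision_function"
            )
        else:  # pragma: no cover - degenerate tiny class
            margins = self.svm_.fit(X, y).decision_function(X)
        self.svm_.fit(X, y)
        self.calibrator_ = LogisticRegression(class_weight="balanced", max_iter=500)
        self.calibrator_.fit(margins.reshape(-1, 1), y)
        return self

    def decision_function(self, X):
        return self.svm_.decision_function(X)

    def predict_proba(self, X):
        p1 = self.calibrator_.predict_proba(self.decision_function(X).reshape(-1, 1))[:, 1]
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def fit_reward_classifier(
    embeddings: np.ndarray, labels: np.ndarray, config: ClassifierConfig | None = None
) -> Pipeline:
    """Class-weighted maximum-margin classifier with calibrated probabilities.

    Class weights are inversely proportional to class frequencies, which keeps
    the decision boundary meaningful under extreme imbalance; the sigmoid
    calibration yields graded scores in (0, 1) monotone in the decision margin.
    """
    config = config or ClassifierConfig()
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise SingleClassError("reward classifier needs both outcome classes")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                CalibratedSVM(
                    kernel=config.kernel, C=config.C, gamma=config.gamma,
                    seed=config.seed,
                ),
            ),
        ]
    )
    pipe.fit(embeddings, y)
    return pipe


@dataclass
class RewardModel:
    """Composite reward over raw decoder outputs.

    Rules, in order: invalid SMILES -> ``invalid_reward``; canonical match to a
    known positive for this left-hand side -> ``match_bonus``; match to a known
    negative -> 0; otherwise the calibrated probability that the reaction is
    successful (thresholded to {0, 1} in binary mode).  Total on any decoder
    output, with values always in [0, 1].
    """

    encoder: ReactionEncoder
    classifier: Pipeline
    known_positives: set[str] = field(default_factory=set)
    known_negatives: set[str] = field(default_factory=set)
    invalid_reward: float = 0.0
    match_bonus: float = 1.0
    binary: bool = False

    def reward(self, lhs: str, predicted_product: str) -> float:
        return self.reward_batch([(lhs, predicted_product)])[0]

    def reward_batch(self, pairs: list[tuple[str, str]]) -> list[float]:
        out: list[float | None] = [None] * len(pairs)
        to_embed: list[tuple[int, str]] = []
        for i, (lhs, product) in enumerate(pairs):
            try:
                canon = chemio.canonicalize_smiles(product)
            except chemio.InvalidMoleculeError:
                out[i] = self.invalid_reward
                continue
            key = f"{lhs}>>{canon}"
            if key in self.known_positives:
                out[i] = self.match_bonus
            elif key in self.known_negatives:
                out[i] = 0.0
            else:
                to_embed.append((i, key))
        if to_embed:
            X = embed_reactions(self.encoder, [k for _, k in to_embed])
            probs = self.classifier.predict_proba(X)[:, 1]
            for (i, _), p in zip(to_embed, probs):
                out[i] = float(p >= 0.5) if self.binary else float(p)
        return [float(np.clip(r, 0.0, 1.0)) for r in out]

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "encoder.npz", **self.encoder.state_dict())
        with open(path / "classifier.pkl", "wb") as fh:
            pickle.dump(self.classifier, fh)
        meta = {
            "tokens": self.encoder.vocab.tokens,
            "dims": vars(self.encoder.dims),
            "pooling": self.encoder.pooling,
            "known_positives": sorted(self.known_positives),
            "known_negatives": sorted(self.known_negatives),
            "invalid_reward": self.invalid_reward,
            "match_bonus": self.match_bonus,
            "binary": self.binary,
        }
        (path / "meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "RewardModel":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        encoder = ReactionEncoder(
            Vocab(meta["tokens"]), EncoderDims(**meta["dims"]), meta["pooling"]
        )
        with np.load(path / "encoder.npz") as zf:
            encoder.load_state_dict({k: zf[k] for k in zf.files})
        with open(path / "classifier.pkl", "rb") as fh:
            classifier = pickle.load(fh)
        return cls(
            encoder=encoder,
            classifier=classifier,
            known_positives=set(meta["known_positives"]),
            known_negatives=set(meta["known_negatives"]),
            invalid_reward=meta["invalid_reward"],
            match_bonus=meta["match_bonus"],
            binary=meta["binary"],
        )


def compute_reward(model: RewardModel, lhs: str, predicted_product: str) -> float:
    """Composite reward of a raw decoder output (see :class:`RewardModel`)."""
    return model.reward(lhs, predicted_product)


def build_reward_model(
    encoder: ReactionEncoder,
    bundle: DatasetBundle,
    classifier_config: ClassifierConfig | None = None,
    binary: bool = False,
) -> RewardModel:
    """Fit the SVM on the training split's embeddings and assemble the reward.

    The known-positive/negative lookup tables are the training reactions
    themselves, so exact matches are label-faithful by construction.
    """
    train = bundle.train
    X = embed_reactions(encoder, [r.reaction for r in train])
    y = np.array([1 if r.is_positive else 0 for r in train])
    clf = fit_reward_classifier(X, y, classifier_config)
    return RewardModel(
        encoder=encoder,
        classifier=clf,
        known_positives={r.reaction.serialize() for r in train if r.is_positive},
        known_negatives={r.reaction.serialize() for r in train if not r.is_positive},
        binary=binary,
    )
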