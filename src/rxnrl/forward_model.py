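"""The sequence-to-sequence forward-prediction model.

A compact encoder-decoder transformer over SMILES tokens maps a serialized
precursor set ("A.B.C") to a product SMILES.  It is trained by maximum
likelihood (teacher forcing), decoded by beam search or ancestral sampling,
and doubles as the trainable policy in RL tuning — a frozen clone serves as
the reference policy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import chemio
from .chemio import BOS, EOS, PAD, UNK, tokenize, detokenize
from .datasets import LabeledReaction
from .nn import autodiff as ad
from .nn.autodiff import Tensor, no_grad
from .nn import layers
from .nn.layers import Module, Linear, Embedding, LayerNorm, causal_mask, padding_mask
from .nn.optim import Adam


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


class OutOfVocabError(KeyError):
    pass


class Vocab:
    """Token vocabulary with reserved pad/bos/eos/unk slots."""

    RESERVED = (PAD, BOS, EOS, UNK)

    def __init__(self, tokens: list[str]):
        seen = [t for t in tokens if t not in self.RESERVED]
        self.tokens = list(self.RESERVED) + sorted(set(seen))
        self.index = {t: i for i, t in enumerate(self.tokens)}

    @classmethod
    def from_texts(cls, texts: list[str]) -> "Vocab":
        toks: set[str] = set()
        for t in texts:
            toks.update(tokenize(t))
        return cls(sorted(toks))

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def bos_id(self) -> int:
        return 1

    @property
    def eos_id(self) -> int:
        return 2

    def encode(self, tokens: list[str], strict: bool = False) -> list[int]:
        if strict:
            bad = [t for t in tokens if t not in self.index]
            if bad:
                raise OutOfVocabError(f"tokens not in vocabulary: {bad}")
        unk = self.index[UNK]
        return [self.index.get(t, unk) for t in tokens]

    def decode(self, ids) -> list[str]:
        return [self.tokens[int(i)] for i in ids]


@dataclass
class ModelDims:
    """Architecture of the desk-scale encoder-decoder transformer."""

    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 2
    d_ff: int = 128
    max_len: int = 96


@dataclass
class EncodedSource:
    """Encoder outputs cached for decoding: memory, masks and copy lookups."""

    memory: Tensor
    cross_mask: np.ndarray
    src_onehot: np.ndarray
    src_len: np.ndarray

    def broadcast(self, n: int) -> "EncodedSource":
        """Tile a single-input encoding across *n* decoding rows (beam search)."""
        if self.memory.data.shape[0] != 1:
            raise ValueError("broadcast expects a single-input encoding")
        return EncodedSource(
            memory=Tensor(np.broadcast_to(self.memory.data, (n,) + self.memory.data.shape[1:]).copy()),
            cross_mask=np.broadcast_to(self.cross_mask, (n,) + self.cross_mask.shape[1:]),
            src_onehot=np.broadcast_to(self.src_onehot, (n,) + self.src_onehot.shape[1:]),
            src_len=np.broadcast_to(self.src_len, (n,)),
        )


def _pad_batch(seqs: list[list[int]], pad_id: int) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([len(s) for s in seqs])
    out = np.full((len(seqs), int(lengths.max())), pad_id, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out, lengths


class Seq2SeqPolicy(Module):
    """Encoder-decoder transformer over SMILES tokens.

    Conditional next-token distributions are softmax-normalized over the full
    vocabulary.  ``clone()`` produces an independent deep copy, used as the
    frozen reference policy during RL.
    """

    def __init__(self, vocab: Vocab, dims: ModelDims | None = None, seed: int = 0):
        self.vocab = vocab
        self.dims = dims or ModelDims()
        rng = np.random.default_rng(seed)
        d = self.dims.d_model
        self.tok_emb = Embedding(len(vocab), d, rng)
        self.pos_emb_src = Embedding(self.dims.max_len, d, rng)
        self.pos_emb_tgt = Embedding(self.dims.max_len, d, rng)
        self.enc_layers = [
            layers.EncoderLayer(d, self.dims.n_heads, self.dims.d_ff, rng)
            for _ in range(self.dims.n_layers)
        ]
        self.enc_norm = LayerNorm(d)
        self.dec_layers = [
            layers.DecoderLayer(d, self.dims.n_heads, self.dims.d_ff, rng)
            for _ in range(self.dims.n_layers)
        ]
        self.dec_norm = LayerNorm(d)
        self.out_proj = Linear(d, len(vocab), rng)
        # pointer-generator head: products largely copy their precursors'
        # substructure tokens, which a pure softmax head generalizes poorly
        # from small corpora; an attention-based copy distribution over the
        # source tokens, mixed in by a learned gate, fixes that
        self.copy_q = Linear(d, d, rng)
        self.copy_gate = Linear(d, 1, rng)

    # -- core passes ---------------------------------------------------------
    def encode_source(self, src_ids: np.ndarray, src_len: np.ndarray) -> "EncodedSource":
        B, L = src_ids.shape
        pos = np.broadcast_to(np.arange(L), (B, L))
        h = self.tok_emb(src_ids) + self.pos_emb_src(pos)
        mask = padding_mask(src_len, L)
        for layer in self.enc_layers:
            h = layer(h, mask)
        onehot = np.zeros((B, L, len(self.vocab)), dtype=ad.DTYPE)
        onehot[np.arange(B)[:, None], np.arange(L)[None, :], src_ids] = 1.0
        return EncodedSource(
            memory=self.enc_norm(h), cross_mask=mask, src_onehot=onehot, src_len=src_len
        )

    def decode_logprobs(self, enc: "EncodedSource", tgt_in: np.ndarray) -> Tensor:
        """(B, Lt, V) next-token log-probabilities under the pointer-generator mix."""
        B, L = tgt_in.shape
        pos = np.broadcast_to(np.arange(L), (B, L))
        h = self.tok_emb(tgt_in) + self.pos_emb_tgt(pos)
        self_mask = causal_mask(L)
        for layer in self.dec_layers:
            h = layer(h, enc.memory, self_mask, enc.cross_mask)
        h = self.dec_norm(h)
        gen = ad.softmax(self.out_proj(h), axis=-1)
        # copy attention over source positions (padded keys masked out)
        q = self.copy_q(h)
        scores = (q @ enc.memory.transpose((0, 2, 1))) * (
            1.0 / np.sqrt(self.dims.d_model)
        )
        scores = scores + Tensor(enc.cross_mask[:, 0, 0, :][:, None, :])
        alpha = ad.softmax(scores, axis=-1)
        copy = alpha @ Tensor(enc.src_onehot)
        gate = ad.sigmoid(self.copy_gate(h))
        probs = gate * gen + (1.0 - gate) * copy
        return ad.log(probs + 1e-9)

    # -- sequence preparation --------------------------------------------------
    def src_ids(self, lhs: str, strict: bool = False) -> list[int]:
        return self.vocab.encode(tokenize(lhs), strict=strict)

    def tgt_ids(self, product: str, strict: bool = False) -> list[int]:
        v = self.vocab
        return [v.bos_id] + v.encode(tokenize(product), strict=strict) + [v.eos_id]

    def batch_logprobs(self, lhs_list: list[str], tgt_full: list[list[int]]) -> tuple[Tensor, np.ndarray]:
        """Per-token log-probs of targets (BOS..EOS) under teacher forcing.

        Returns a (B, Lt-1) tensor of log-probabilities of the actual next
        tokens, and a matching 0/1 validity mask (pad positions excluded).
        """
        src, src_len = _pad_batch([self.src_ids(l) for l in lhs_list], self.vocab.pad_id)
        tgt, tgt_len = _pad_batch(tgt_full, self.vocab.pad_id)
        enc = self.encode_source(src, src_len)
        tgt_in, tgt_out = tgt[:, :-1], tgt[:, 1:]
        logp = self.decode_logprobs(enc, tgt_in)
        B, L = tgt_out.shape
        picked = logp[np.arange(B)[:, None], np.arange(L)[None, :], tgt_out]
        valid = (np.arange(L)[None, :] < (tgt_len - 1)[:, None]).astype(float)
        return picked, valid

    def pooled_state(self, lhs_list: list[str]) -> Tensor:
        """Mean-pooled encoder representation of each left-hand side."""
        src, src_len = _pad_batch([self.src_ids(l) for l in lhs_list], self.vocab.pad_id)
        memory = self.encode_source(src, src_len).memory
        B, L = src.shape
        valid = (np.arange(L)[None, :] < src_len[:, None]).astype(ad.DTYPE)[:, :, None]
        return (memory * Tensor(valid)).sum(axis=1) / Tensor(src_len[:, None].astype(ad.DTYPE))

    # -- persistence -----------------------------------------------------------
    def clone(self) -> "Seq2SeqPolicy":
        twin = Seq2SeqPolicy(self.vocab, ModelDims(**asdict(self.dims)))
        twin.load_state_dict(self.state_dict())
        return twin

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.state_dict())
        meta = {"tokens": self.vocab.tokens, "dims": asdict(self.dims)}
        (path / "meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "Seq2SeqPolicy":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        policy = cls(Vocab(meta["tokens"]), ModelDims(**meta["dims"]))
        with np.load(path / "weights.npz") as zf:
            policy.load_state_dict({k: zf[k] for k in zf.files})
        return policy


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

@dataclass
class DecodeResult:
    """Ranked decoding candidates for one input; log-probs non-increasing."""

    candidates: list[tuple[str, float]]
    beams: int

    def products(self) -> list[str]:
        return [c for c, _ in self.candidates]


def _encode_lhs(policy: Seq2SeqPolicy, lhs_list: list[str]) -> EncodedSource:
    src, src_len = _pad_batch([policy.src_ids(l) for l in lhs_list], policy.vocab.pad_id)
    return policy.encode_source(src, src_len)


def greedy_decode_batch(
    policy: Seq2SeqPolicy, lhs_list: list[str], max_len: int = 64
) -> list[tuple[str, float]]:
    """Argmax decoding for a batch of inputs; returns (product, total log-prob)."""
    v = policy.vocab
    with no_grad():
        enc = _encode_lhs(policy, lhs_list)
        B = len(lhs_list)
        seqs = np.full((B, 1), v.bos_id, dtype=np.int64)
        total = np.zeros(B)
        done = np.zeros(B, dtype=bool)
        for _ in range(max_len):
            logp = policy.decode_logprobs(enc, seqs).data[:, -1, :]
            nxt = logp.argmax(axis=1)
            nxt[done] = v.pad_id
            total += np.where(done, 0.0, logp[np.arange(B), nxt])
            seqs = np.concatenate([seqs, nxt[:, None]], axis=1)
            done |= nxt == v.eos_id
            if done.all():
                break
    out = []
    for i in range(B):
        ids = [t for t in seqs[i, 1:] if t not in (v.pad_id,)]
        if v.eos_id in ids:
            ids = ids[: ids.index(v.eos_id)]
        out.append((detokenize(v.decode(ids)), float(total[i])))
    return out


def beam_decode(
    policy: Seq2SeqPolicy, precursors: str, beams: int = 10, max_len: int = 64
) -> DecodeResult:
    """Length-bounded beam search without length normalization.

    Returns up to ``beams`` finished candidates ranked by total sequence
    log-probability; with ``beams=1`` this is greedy decoding.
    """
    if beams < 1:
        raise ValueError("beams must be >= 1")
    v = policy.vocab
    with no_grad():
        enc1 = _encode_lhs(policy, [precursors])
        live = [([v.bos_id], 0.0)]
        finished: list[tuple[list[int], float]] = []
        for _ in range(max_len):
            if not live:
                break
            B = len(live)
            seqs, _ = _pad_batch([s for s, _ in live], v.pad_id)
            logp = policy.decode_logprobs(enc1.broadcast(B), seqs).data[:, -1, :]
            expanded: list[tuple[float, list[int]]] = []
            for i, (seq, score) in enumerate(live):
                top = np.argsort(logp[i])[::-1][:beams]
                for t in top:
                    expanded.append((score + float(logp[i, t]), seq + [int(t)]))
            expanded.sort(key=lambda x: -x[0])
            live = []
            for score, seq in expanded[: beams * 2]:
                if seq[-1] == v.eos_id:
                    finished.append((seq, score))
                elif len(live) < beams:
                    live.append((seq, score))
            finished.sort(key=lambda x: -x[1])
            if len(finished) >= beams and live and finished[beams - 1][1] >= live[0][1]:
                break
    finished.sort(key=lambda x: -x[1])
    candidates = [
        (detokenize(v.decode(seq[1:-1])), score) for seq, score in finished[:beams]
    ]
    return DecodeResult(candidates=candidates, beams=beams)


@dataclass
class SampledSequence:
    tokens: list[str]
    token_ids: list[int]
    logprobs: list[float]
    truncated: bool = False

    @property
    def product(self) -> str:
        return detokenize(self.tokens)

    @property
    def total_logprob(self) -> float:
        return float(sum(self.logprobs))


def sample_decode_batch(
    policy: Seq2SeqPolicy,
    lhs_list: list[str],
    temperature: float = 1.0,
    rng: np.random.Generator | None = None,
    max_len: int = 64,
) -> list[SampledSequence]:
    """Ancestral sampling from the decoder at the given temperature.

    Returned per-token log-probabilities are those of the sampled tokens under
    the *untempered* policy, which is what importance ratios and KL penalties
    need.  Deterministic given the generator state.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    rng = rng or np.random.default_rng(0)
    v = policy.vocab
    B = len(lhs_list)
    with no_grad():
        enc = _encode_lhs(policy, lhs_list)
        seqs = np.full((B, 1), v.bos_id, dtype=np.int64)
        done = np.zeros(B, dtype=bool)
        all_logps: list[np.ndarray] = []
        for _ in range(max_len):
            logp = policy.decode_logprobs(enc, seqs).data[:, -1, :].astype(np.float64)
            tl = logp / temperature
            p = np.exp(tl - _logsumexp(tl))
            u = rng.random((B, 1))
            nxt = (p.cumsum(axis=1) < u).sum(axis=1)
            nxt = np.minimum(nxt, len(v) - 1)
            nxt[done] = v.pad_id
            all_logps.append(np.where(done, 0.0, logp[np.arange(B), nxt]))
            seqs = np.concatenate([seqs, nxt[:, None]], axis=1)
            done |= nxt == v.eos_id
            if done.all():
                break
    out = []
    lp = np.stack(all_logps, axis=1) if all_logps else np.zeros((B, 0))
    for i in range(B):
        ids = list(seqs[i, 1:])
        n = ids.index(v.eos_id) + 1 if v.eos_id in ids else len(ids)
        token_ids = [int(t) for t in ids[:n]]
        out.append(
            SampledSequence(
                tokens=v.decode(token_ids),
                token_ids=token_ids,
                logprobs=[float(x) for x in lp[i, :n]],
                truncated=v.eos_id not in ids,
            )
        )
    return out


def sample_decode(
    policy: Seq2SeqPolicy,
    precursors: str,
    temperature: float = 1.0,
    seed: int = 0,
    max_len: int = 64,
) -> SampledSequence:
    """Sample one product sequence for one input (see :func:`sample_decode_batch`)."""
    return sample_decode_batch(
        policy, [precursors], temperature, np.random.default_rng(seed), max_len
    )[0]


def _logsumexp(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=-1, keepdims=True)
    return m + np.log(np.exp(x - m).sum(axis=-1, keepdims=True))


def sequence_log_prob(policy: Seq2SeqPolicy, precursors: str, product_tokens: list[str]) -> float:
    """Total log-probability of a tokenized product under teacher forcing (<= 0)."""
    tgt = (
        [policy.vocab.bos_id]
        + policy.vocab.encode(product_tokens, strict=True)
        + [policy.vocab.eos_id]
    )
    with no_grad():
        picked, valid = policy.batch_logprobs([precursors], [tgt])
    return float((picked.data * valid).sum())


# ---------------------------------------------------------------------------
# maximum-likelihood training
# ---------------------------------------------------------------------------

@dataclass
class MLEConfig:
    epochs: int = 10
    batch_size: int = 32
    lr: float = 3e-3
    lr_decay: bool = True  # cosine decay to lr_floor_frac * lr over the run
    lr_floor_frac: float = 0.05
    seed: int = 0
    max_len: int = 64
    eval_every: int = 1  # epochs between validation evaluations


def _as_pairs(data, for_training: bool = False) -> list[tuple[str, str]]:
    """(lhs, product) pairs; training targets use the aligned serialization."""
    pairs = []
    for item in data:
        if isinstance(item, LabeledReaction):
            if not item.is_positive:
                raise ValueError("MLE training uses positive reactions only")
            rxn = item.reaction
        else:
            rxn = item
        pairs.append((rxn.lhs, rxn.training_target if for_training else rxn.product.smiles))
    return pairs


def top1_accuracy(policy: Seq2SeqPolicy, pairs: list[tuple[str, str]], max_len: int = 64) -> float:
    """Greedy top-1 exact-match accuracy on (lhs, canonical product) pairs."""
    if not pairs:
        return float("nan")
    preds = greedy_decode_batch(policy, [l for l, _ in pairs], max_len=max_len)
    hits = 0
    for (_, truth), (pred, _) in zip(pairs, preds):
        try:
            hits += chemio.canonicalize_smiles(pred) == truth
        except chemio.InvalidMoleculeError:
            pass
    return hits / len(pairs)


def train_mle(
    policy: Seq2SeqPolicy,
    data,
    config: MLEConfig | None = None,
    valid=None,
) -> tuple[Seq2SeqPolicy, list[dict]]:
    """Teacher-forced cross-entropy training; keeps the best-validation checkpoint.

    ``data`` is a list of Reactions or positive LabeledReactions; negatives are
    rejected (they enter training only through RL).  When ``valid`` is given,
    greedy top-1 accuracy on it is evaluated each epoch and the checkpoint with
    the best validation accuracy is restored before returning.  The history
    records per-epoch mean loss and validation accuracy.
    """
    config = config or MLEConfig()
    pairs = _as_pairs(data, for_training=True)
    if not pairs:
        raise ValueError("no training data")
    valid_pairs = _as_pairs(valid) if valid else None
    rng = np.random.default_rng(config.seed)
    opt = Adam(policy.parameters(), lr=config.lr)
    history: list[dict] = []
    best_acc, best_state = -1.0, None
    if valid_pairs is not None:
        # the starting model is the epoch-0 candidate: with too little data to
        # learn from, checkpoint selection falls back to it
        best_acc = top1_accuracy(policy, valid_pairs, max_len=config.max_len)
        best_state = policy.state_dict()
        history.append({"epoch": -1, "loss": float("nan"), "valid_top1": best_acc})
    for epoch in range(config.epochs):
        if config.lr_decay and config.epochs > 1:
            frac = epoch / (config.epochs - 1)
            floor = config.lr_floor_frac
            opt.lr = config.lr * (floor + (1 - floor) * 0.5 * (1 + math.cos(math.pi * frac)))
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(pairs), config.batch_size):
            batch = [pairs[i] for i in order[start : start + config.batch_size]]
            lhs = [l for l, _ in batch]
            tgt = [policy.tgt_ids(p) for _, p in batch]
            opt.zero_grad()
            picked, valid_mask = policy.batch_logprobs(lhs, tgt)
            n_tok = valid_mask.sum()
            loss = -(picked * Tensor(valid_mask)).sum() / n_tok
            if not math.isfinite(loss.data.item()):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "loss": float(np.mean(losses))}
        last_epoch = epoch == config.epochs - 1
        if valid_pairs is not None and (epoch % config.eval_every == 0 or last_epoch):
            acc = top1_accuracy(policy, valid_pairs, max_len=config.max_len)
            entry["valid_top1"] = acc
            if acc > best_acc:
                best_acc, best_state = acc, policy.state_dict()
        history.append(entry)
    if best_state is not None:
        policy.load_state_dict(best_state)
    return policy, history
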