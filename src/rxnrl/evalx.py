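"""Evaluation: top-k positive accuracy, invalid-prediction fraction, and
multi-seed statistics for the fine-tuning vs. RL comparison."""

from __future__ import annotations

import traceback
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import chemio
from .datasets import LabeledReaction
from .forward_model import DecodeResult, Seq2SeqPolicy, beam_decode


@dataclass
class EvalReport:
    """Beam-search evaluation on positive reactions.

    ``topk_accuracy[k]`` is the fraction of positives whose canonical product
    appears among the top-k beam candidates; ``invalid_fraction[k]`` the
    fraction of the k*n top-k candidate slots holding unparsable SMILES.
    """

    topk_accuracy: dict[int, float]
    invalid_fraction: dict[int, float]
    n_eval: int
    seed: int = 0


def _canonical_or_none(smiles: str) -> str | None:
    try:
        return chemio.canonicalize_smiles(smiles)
    except chemio.InvalidMoleculeError:
        return None


def evaluate_policy(
    policy: Seq2SeqPolicy,
    positives: Sequence[LabeledReaction],
    ks: Sequence[int] = (1, 2),
    beams: int = 10,
    max_len: int = 64,
    seed: int = 0,
) -> tuple[EvalReport, list[DecodeResult]]:
    """Beam-decode every positive once and score all requested depths."""
    if any(not r.is_positive for r in positives):
        raise ValueError("evaluation set must contain positives only")
    if max(ks) > beams:
        raise ValueError(f"k={max(ks)} exceeds beam width {beams}")
    results = [
        beam_decode(policy, r.reaction.lhs, beams=beams, max_len=max_len)
        for r in positives
    ]
    topk: dict[int, float] = {}
    for k in ks:
        hits = 0
        for rec, res in zip(positives, results):
            truth = rec.reaction.product.smiles
            cands = [_canonical_or_none(c) for c in res.products()[:k]]
            hits += truth in [c for c in cands if c is not None]
        topk[k] = hits / len(positives) if positives else float("nan")
    inv = {k: invalid_fraction(results, k) for k in ks}
    return EvalReport(topk_accuracy=topk, invalid_fraction=inv, n_eval=len(positives), seed=seed), results


def topk_positive_accuracy(
    policy: Seq2SeqPolicy,
    positives: Sequence[LabeledReaction],
    k: int,
    beams: int = 10,
    max_len: int = 64,
) -> float:
    """Fraction of positives whose true product is among the top-k beam candidates."""
    if k > beams:
        raise ValueError(f"k={k} exceeds beam width {beams}")
    report, _ = evaluate_policy(policy, positives, ks=(k,), beams=beams, max_len=max_len)
    return report.topk_accuracy[k]


def invalid_fraction(decode_results: Sequence[DecodeResult], k: int) -> float:
    """Fraction of invalid SMILES among the k*n top-k candidate slots."""
    if not decode_results:
        return float("nan")
    n_slots = k * len(decode_results)
    n_invalid = 0
    for res in decode_results:
        for cand in res.products()[:k]:
            if _canonical_or_none(cand) is None:
                n_invalid += 1
    return n_invalid / n_slots


@dataclass
class MultiSeedSummary:
    """Per-seed metrics with mean and standard deviation, failures marked."""

    per_seed: dict[int, dict[str, float]]
    failures: dict[int, str] = field(default_factory=dict)

    @property
    def metrics(self) -> list[str]:
        names: list[str] = []
        for m in self.per_seed.values():
            names.extend(k for k in m if k not in names)
        return names

    def mean(self) -> dict[str, float]:
        return {
            m: float(np.mean([v[m] for v in self.per_seed.values() if m in v]))
            for m in self.metrics
        }

    def sd(self) -> dict[str, float]:
        return {
            m: float(np.std([v[m] for v in self.per_seed.values() if m in v], ddof=1))
            if sum(m in v for v in self.per_seed.values()) > 1
            else 0.0
            for m in self.metrics
        }

    def breakdown(self) -> list[dict]:
        """Per-seed rows (the per-split breakdown view)."""
        return [{"seed": s, **m} for s, m in sorted(self.per_seed.items())]


def multi_seed_report(
    experiment_fn: Callable[[int], dict[str, float]],
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
) -> MultiSeedSummary:
    """Run an experiment once per seed and summarize mean and SD per metric.

    Each seed controls both the data split and the initialization inside
    ``experiment_fn``.  Individual seed failures are recorded in the summary
    instead of aborting the remaining seeds.
    """
    if len(seeds) < 2:
        raise ValueError("need at least two seeds for a spread estimate")
    per_seed: dict[int, dict[str, float]] = {}
    failures: dict[int, str] = {}
    for seed in seeds:
        try:
            per_seed[seed] = dict(experiment_fn(seed))
        except Exception:
            failures[seed] = traceback.format_exc(limit=3)
    return MultiSeedSummary(per_seed=per_seed, failures=failures)
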