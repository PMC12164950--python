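import itertools
import math

import numpy as np
import pytest

from rxnrl.chemio import tokenize
from rxnrl.forward_model import (
    DivergenceError,
    MLEConfig,
    ModelDims,
    OutOfVocabError,
    Seq2SeqPolicy,
    Vocab,
    beam_decode,
    greedy_decode_batch,
    sample_decode,
    sample_decode_batch,
    sequence_log_prob,
    top1_accuracy,
    train_mle,
)
from rxnrl.nn import autodiff as ad


def uniform_policy(tokens=("C", "N", "O", "F"), seed=0):
    """A policy whose next-token distribution is exactly uniform.

    The generation logits are zeroed and the pointer gate saturated toward pure
    generation, so every conditional is uniform over the vocabulary.
    """
    vocab = Vocab(list(tokens))
    policy = Seq2SeqPolicy(
        vocab, ModelDims(d_model=16, n_heads=2, n_layers=1, d_ff=32, max_len=16), seed=seed
    )
    policy.out_proj.w.data[:] = 0.0
    policy.out_proj.b.data[:] = 0.0
    policy.copy_gate.w.data[:] = 0.0
    policy.copy_gate.b.data[:] = 30.0  # sigmoid ~ 1: generation only
    return policy


class TestVocab:
    def test_reserved_slots_are_stable(self, tiny_vocab):
        assert tiny_vocab.tokens[:4] == ["<pad>", "<s>", "</s>", "<unk>"]

    def test_strict_encode_raises_on_oov(self, tiny_vocab):
        with pytest.raises(OutOfVocabError):
            tiny_vocab.encode(["[Xe]"], strict=True)

    def test_roundtrip(self, tiny_vocab):
        toks = tokenize("Cc1ccccc1Br")
        assert tiny_vocab.decode(tiny_vocab.encode(toks)) == toks


class TestTrainMLE:
    def test_single_reaction_is_memorized(self, tiny_reactions, tiny_vocab, tiny_dims):
        policy = Seq2SeqPolicy(tiny_vocab, tiny_dims, seed=1)
        policy, history = train_mle(
            policy, tiny_reactions[:1], MLEConfig(epochs=120, batch_size=1, lr=3e-3, seed=0)
        )
        assert history[-1]["loss"] < 0.01

    def test_ten_reactions_reach_perfect_train_accuracy(self, memorized_policy, tiny_reactions):
        pairs = [(r.lhs, r.product.smiles) for r in tiny_reactions]
        assert top1_accuracy(memorized_policy, pairs) == 1.0

    def test_negatives_are_rejected(self, tiny_reactions, tiny_vocab, tiny_dims):
        from rxnrl.datasets import LabeledReaction

        policy = Seq2SeqPolicy(tiny_vocab, tiny_dims)
        bad = [LabeledReaction(reaction=tiny_reactions[0], label="negative")]
        with pytest.raises(ValueError):
            train_mle(policy, bad, MLEConfig(epochs=1))

    def test_divergence_error_on_nonfinite_loss(self, tiny_reactions, tiny_vocab, tiny_dims):
        policy = Seq2SeqPolicy(tiny_vocab, tiny_dims)
        policy.out_proj.w.data[:] = np.nan
        with pytest.raises(DivergenceError):
            train_mle(policy, tiny_reactions[:2], MLEConfig(epochs=1, batch_size=2))


def enumerate_sequences(policy, lhs, max_len):
    """Brute-force oracle: score every finished sequence up to max_len tokens."""
    v = policy.vocab
    non_eos = [i for i in range(len(v)) if i != v.eos_id]
    finished = []
    for k in range(max_len):
        for body in itertools.product(non_eos, repeat=k):
            ids = list(body) + [v.eos_id]
            toks = v.decode(ids[:-1])
            score = sequence_log_prob(policy, lhs, toks)
            finished.append((ids, score))
    finished.sort(key=lambda x: -x[1])
    return finished


class TestBeamDecode:
    def test_beam_one_equals_greedy(self, memorized_policy, tiny_reactions):
        for r in tiny_reactions[:4]:
            greedy = greedy_decode_batch(memorized_policy, [r.lhs])[0]
            beam = beam_decode(memorized_policy, r.lhs, beams=1)
            assert beam.candidates[0][0] == greedy[0]
            assert beam.candidates[0][1] == pytest.approx(greedy[1], abs=1e-5)

    def test_ranking_matches_exhaustive_enumeration(self):
        """On a 4-letter/length-3 decoder a wide beam equals brute-force search."""
        policy = uniform_policy()
        # break the uniform tie structure with a random but fixed perturbation
        rng = np.random.default_rng(5)
        policy.out_proj.w.data[:] = rng.normal(0, 0.5, policy.out_proj.w.data.shape)
        policy.out_proj.b.data[:] = rng.normal(0, 0.5, policy.out_proj.b.data.shape)
        lhs = "C"
        oracle = enumerate_sequences(policy, lhs, max_len=3)
        result = beam_decode(policy, lhs, beams=64, max_len=3)
        got = [score for _, score in result.candidates[:10]]
        want = [score for _, score in oracle[:10]]
        np.testing.assert_allclose(got, want, atol=1e-4)

    def test_scores_non_increasing(self, memorized_policy, tiny_reactions):
        res = beam_decode(memorized_policy, tiny_reactions[0].lhs, beams=8)
        scores = [s for _, s in res.candidates]
        assert scores == sorted(scores, reverse=True)

    def test_wider_beam_never_worsens_best_scores(self):
        policy = uniform_policy()
        rng = np.random.default_rng(11)
        policy.out_proj.w.data[:] = rng.normal(0, 0.5, policy.out_proj.w.data.shape)
        narrow = beam_decode(policy, "N", beams=3, max_len=3)
        wide = beam_decode(policy, "N", beams=12, max_len=3)
        for (_, s_narrow), (_, s_wide) in zip(narrow.candidates, wide.candidates):
            assert s_wide >= s_narrow - 1e-9

    def test_invalid_beam_width(self, memorized_policy):
        with pytest.raises(ValueError):
            beam_decode(memorized_policy, "C", beams=0)


class TestSampleDecode:
    def test_same_seed_same_sample(self, memorized_policy, tiny_reactions):
        lhs = tiny_reactions[0].lhs
        s1 = sample_decode(memorized_policy, lhs, temperature=1.0, seed=42)
        s2 = sample_decode(memorized_policy, lhs, temperature=1.0, seed=42)
        assert s1.token_ids == s2.token_ids
        assert s1.logprobs == s2.logprobs

    def test_low_temperature_limit_reproduces_greedy(self, memorized_policy, tiny_reactions):
        lhs = tiny_reactions[0].lhs
        greedy = greedy_decode_batch(memorized_policy, [lhs])[0][0]
        s = sample_decode(memorized_policy, lhs, temperature=1e-4, seed=0)
        assert s.product == greedy

    def test_nonpositive_temperature_rejected(self, memorized_policy):
        with pytest.raises(ValueError):
            sample_decode(memorized_policy, "C", temperature=0.0)

    def test_truncation_is_flagged(self):
        policy = uniform_policy()
        # uniform over 8 symbols: a length-1 budget almost surely truncates
        s = sample_decode(policy, "C", temperature=1.0, seed=3, max_len=1)
        assert s.truncated == (s.token_ids[-1] != policy.vocab.eos_id)

    def test_sampling_frequencies_match_policy_distribution(self):
        """First-token frequencies over 10,000 draws agree with softmax within 3 SE."""
        policy = uniform_policy()
        rng = np.random.default_rng(7)
        policy.out_proj.b.data[:] = rng.normal(0, 1.0, policy.out_proj.b.data.shape)
        n = 10_000
        samples = sample_decode_batch(
            policy, ["C"] * n, temperature=1.0, rng=np.random.default_rng(123), max_len=1
        )
        first = np.array([s.token_ids[0] for s in samples])
        from rxnrl.forward_model import _encode_lhs
        from rxnrl.nn.autodiff import no_grad

        with no_grad():
            enc = _encode_lhs(policy, ["C"])
            logp = policy.decode_logprobs(enc, np.array([[policy.vocab.bos_id]])).data[0, -1]
        p = np.exp(logp - logp.max())
        p /= p.sum()
        for tok in range(len(policy.vocab)):
            observed = (first == tok).mean()
            se = math.sqrt(p[tok] * (1 - p[tok]) / n)
            assert abs(observed - p[tok]) <= 3 * se + 1e-12


class TestDistributionNormalization:
    def test_pointer_mixture_rows_sum_to_one(self, memorized_policy, tiny_reactions):
        """The gate-mixed generation/copy distribution is a proper distribution."""
        from rxnrl.forward_model import _encode_lhs
        from rxnrl.nn.autodiff import no_grad

        policy = memorized_policy
        with no_grad():
            enc = _encode_lhs(policy, [r.lhs for r in tiny_reactions[:3]])
            tgt = np.array([[policy.vocab.bos_id, 5, 6]] * 3)
            logp = policy.decode_logprobs(enc, tgt).data
        np.testing.assert_allclose(np.exp(logp).sum(axis=-1), 1.0, atol=1e-4)


class TestSequenceLogProb:
    def test_uniform_policy_gives_length_times_log_inverse_vocab(self):
        policy = uniform_policy()
        v = len(policy.vocab)
        toks = ["C", "N"]
        lp = sequence_log_prob(policy, "C", toks)
        assert lp == pytest.approx((len(toks) + 1) * math.log(1 / v), rel=1e-5)

    def test_total_mass_of_bounded_sequences_matches_closed_form(self):
        """Uniform policy: finished-sequence mass up to length L has a closed form."""
        policy = uniform_policy()
        v = len(policy.vocab)
        max_len = 3
        total = sum(
            math.exp(score) for _, score in enumerate_sequences(policy, "C", max_len)
        )
        want = sum((v - 1) ** k / v ** (k + 1) for k in range(max_len))
        assert total == pytest.approx(want, rel=1e-6)

    def test_nonpositive(self, memorized_policy, tiny_reactions):
        r = tiny_reactions[0]
        assert sequence_log_prob(memorized_policy, r.lhs, tokenize(r.product.smiles)) <= 0

    def test_greedy_output_beats_samples(self, memorized_policy, tiny_reactions):
        lhs = tiny_reactions[0].lhs
        greedy_lp = greedy_decode_batch(memorized_policy, [lhs])[0][1]
        samples = sample_decode_batch(
            memorized_policy, [lhs] * 100, temperature=1.5,
            rng=np.random.default_rng(0),
        )
        for s in samples:
            assert greedy_lp >= s.total_logprob - 1e-5

    def test_oov_product_raises(self, memorized_policy):
        with pytest.raises(OutOfVocabError):
            sequence_log_prob(memorized_policy, "C", ["[Xe]"])


class TestPersistence:
    def test_save_load_roundtrip_preserves_behavior(self, memorized_policy, tiny_reactions, tmp_path):
        memorized_policy.save(tmp_path / "ckpt")
        loaded = Seq2SeqPolicy.load(tmp_path / "ckpt")
        lhs = [r.lhs for r in tiny_reactions[:3]]
        out1 = greedy_decode_batch(memorized_policy, lhs)
        out2 = greedy_decode_batch(loaded, lhs)
        assert out1 == out2

    def test_clone_is_independent(self, memorized_policy):
        twin = memorized_policy.clone()
        twin.out_proj.b.data[:] += 1.0
        assert not np.allclose(
            twin.out_proj.b.data, memorized_policy.out_proj.b.data
        )
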