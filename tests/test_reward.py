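import numpy as np
import pytest

from rxnrl.chemio import parse_reaction
from rxnrl.datasets import LabeledReaction
from rxnrl.forward_model import Vocab
from rxnrl.reward import (
    ClassifierConfig,
    EncoderDims,
    ReactionEncoder,
    RewardModel,
    SingleClassError,
    TuneConfig,
    build_reward_model,
    classification_tune,
    embed_reaction,
    embed_reactions,
    fit_reward_classifier,
    separation_report,
)

SMALL_DIMS = EncoderDims(d_model=24, n_heads=2, n_layers=1, d_ff=48, max_len=64)


@pytest.fixture(scope="module")
def labeled_toy():
    """A small positive/negative family: halogen placed ortho (pos) or elsewhere (neg)."""
    from rxnrl.datasets import generate_regio_negatives

    positives = [
        "Cc1ccccc1.BrBr>>Cc1ccccc1Br",
        "CCc1ccccc1.BrBr>>CCc1ccccc1Br",
        "Oc1ccccc1.BrBr>>Oc1ccccc1Br",
        "COc1ccccc1.BrBr>>COc1ccccc1Br",
        "Nc1ccccc1.BrBr>>Nc1ccccc1Br",
        "Cc1ccncc1.BrBr>>Cc1ccncc1Br",
        "CCc1cccnc1.BrBr>>CCc1cccnc1Br",
        "Oc1ccncc1.BrBr>>Oc1ccncc1Br",
        "Cc1ccco1.BrBr>>Cc1ccc(Br)o1",
        "Cc1cccs1.BrBr>>Cc1ccc(Br)s1",
        "N#Cc1ccccc1.BrBr>>N#Cc1ccccc1Br",
        "CC(=O)c1ccccc1.BrBr>>CC(=O)c1ccccc1Br",
        "CCOc1ccccc1.BrBr>>CCOc1ccccc1Br",
        "CC(C)c1ccccc1.BrBr>>CC(C)c1ccccc1Br",
    ]
    records = []
    for line in positives:
        pos = parse_reaction(line)
        records.append(LabeledReaction(reaction=pos, label="positive"))
        records.extend(
            LabeledReaction(reaction=r, label="negative")
            for r in generate_regio_negatives(pos)
        )
    return records


@pytest.fixture(scope="module")
def toy_vocab(labeled_toy):
    return Vocab.from_texts([r.reaction.serialize() for r in labeled_toy])


@pytest.fixture(scope="module")
def base_encoder(toy_vocab):
    return ReactionEncoder(toy_vocab, SMALL_DIMS, seed=0)


@pytest.fixture(scope="module")
def tuned_encoder(base_encoder, labeled_toy):
    return classification_tune(
        base_encoder, labeled_toy, TuneConfig(epochs=14, batch_size=16, lr=2e-3, seed=0)
    )


class TestEmbedding:
    def test_vector_length_equals_encoder_width(self, base_encoder, labeled_toy):
        X = embed_reactions(base_encoder, [r.reaction for r in labeled_toy[:5]])
        assert X.shape == (5, SMALL_DIMS.d_model)

    def test_deterministic_and_canonical(self, base_encoder):
        # equivalent SMILES spellings canonicalize at parse time, so the
        # serialized reaction — and hence the fingerprint — is identical
        r1 = parse_reaction("Cc1ccccc1.BrBr>>Cc1ccccc1Br")
        r2 = parse_reaction("c1ccccc1C.BrBr>>Brc1ccccc1C")
        v1, v2 = embed_reaction(base_encoder, r1), embed_reaction(base_encoder, r2)
        np.testing.assert_array_equal(v1, v2)

    def test_first_token_pooling(self, toy_vocab, labeled_toy):
        enc = ReactionEncoder(toy_vocab, SMALL_DIMS, pooling="first", seed=0)
        X = embed_reactions(enc, [r.reaction for r in labeled_toy[:3]])
        assert X.shape == (3, SMALL_DIMS.d_model)

    def test_unknown_pooling_rejected(self, toy_vocab):
        with pytest.raises(ValueError):
            ReactionEncoder(toy_vocab, SMALL_DIMS, pooling="max")


class TestClassificationTune:
    def test_tuning_improves_linear_separability(self, base_encoder, tuned_encoder, labeled_toy):
        """Held-out separation is higher in the classification-tuned space."""
        reactions = [r.reaction for r in labeled_toy]
        y = np.array([r.is_positive for r in labeled_toy])
        rep_base = separation_report(embed_reactions(base_encoder, reactions), y, seed=0)
        rep_tuned = separation_report(embed_reactions(tuned_encoder, reactions), y, seed=0)
        assert rep_tuned.linear_balanced_accuracy > rep_base.linear_balanced_accuracy

    def test_shuffled_labels_carry_no_signal(self, base_encoder, labeled_toy):
        rng = np.random.default_rng(0)
        shuffled = [
            LabeledReaction(reaction=r.reaction, label=l)
            for r, l in zip(
                labeled_toy,
                rng.permutation([r.label for r in labeled_toy]).tolist(),
            )
        ]
        enc = classification_tune(
            base_encoder, shuffled, TuneConfig(epochs=4, batch_size=16, seed=0)
        )
        y = np.array([r.is_positive for r in labeled_toy])
        rep = separation_report(
            embed_reactions(enc, [r.reaction for r in labeled_toy]), y, seed=0
        )
        assert abs(rep.linear_balanced_accuracy - 0.5) < 0.25

    def test_deterministic_given_seed(self, base_encoder, labeled_toy):
        cfg = TuneConfig(epochs=2, batch_size=16, seed=3)
        e1 = classification_tune(base_encoder, labeled_toy, cfg)
        e2 = classification_tune(base_encoder, labeled_toy, cfg)
        for (_, p1), (_, p2) in zip(e1.named_parameters(), e2.named_parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_single_class_error(self, base_encoder, labeled_toy):
        pos_only = [r for r in labeled_toy if r.is_positive]
        with pytest.raises(SingleClassError):
            classification_tune(base_encoder, pos_only, TuneConfig(epochs=1))

    def test_input_encoder_untouched(self, base_encoder, labeled_toy):
        before = {k: v.copy() for k, v in base_encoder.state_dict().items()}
        classification_tune(base_encoder, labeled_toy, TuneConfig(epochs=1, seed=0))
        after = base_encoder.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])


class TestSeparationReport:
    def test_identical_clouds_are_indistinguishable(self, rng):
        X = rng.normal(size=(40, 6))
        emb = np.concatenate([X, X])
        y = np.array([True] * 40 + [False] * 40)
        rep = separation_report(emb, y, seed=0)
        assert rep.between_within_ratio == pytest.approx(1.0, abs=0.05)
        assert abs(rep.linear_balanced_accuracy - 0.5) < 0.2

    def test_separated_gaussians_fully_classified(self, rng):
        a = rng.normal(0, 0.2, size=(50, 4))
        b = rng.normal(8, 0.2, size=(50, 4))
        rep = separation_report(np.vstack([a, b]), np.array([True] * 50 + [False] * 50))
        assert rep.linear_balanced_accuracy == 1.0
        assert rep.between_within_ratio > 5
        assert rep.pca_projection.shape == (100, 2)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            separation_report(rng.normal(size=(3, 4)), np.array([True, False, False]))

    def test_degenerate_geometry_reports_nan(self):
        emb = np.zeros((10, 4))
        y = np.array([True] * 5 + [False] * 5)
        rep = separation_report(emb, y, seed=0)
        assert np.isnan(rep.between_within_ratio)


class TestRewardClassifier:
    def test_separable_data_fits_perfectly(self, rng):
        X = np.vstack([rng.normal(-5, 0.3, size=(30, 2)), rng.normal(5, 0.3, size=(30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        clf = fit_reward_classifier(X, y, ClassifierConfig(seed=0))
        assert (clf.predict(X) == y).mean() == 1.0

    def test_imbalanced_fit_beats_chance_and_unweighted(self, rng):
        """22 positives vs 748 negatives from shifted Gaussians."""
        from sklearn.metrics import balanced_accuracy_score
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        def draw(n_pos, n_neg, r):
            Xp = r.normal(1.2, 1.0, size=(n_pos, 5))
            Xn = r.normal(0.0, 1.0, size=(n_neg, 5))
            return np.vstack([Xp, Xn]), np.array([1] * n_pos + [0] * n_neg)

        Xtr, ytr = draw(22, 748, rng)
        Xte, yte = draw(200, 200, rng)
        weighted = fit_reward_classifier(Xtr, ytr, ClassifierConfig(seed=0))
        unweighted = Pipeline(
            [("scale", StandardScaler()), ("svm", SVC(probability=True, random_state=0))]
        ).fit(Xtr, ytr)
        bw = balanced_accuracy_score(yte, weighted.predict(Xte))
        bu = balanced_accuracy_score(yte, unweighted.predict(Xte))
        assert bw > 0.5
        assert bw > bu

    def test_probabilities_in_unit_interval_and_monotone_in_margin(self, rng):
        X = np.vstack([rng.normal(-2, 1, size=(40, 2)), rng.normal(2, 1, size=(40, 2))])
        y = np.array([0] * 40 + [1] * 40)
        clf = fit_reward_classifier(X, y, ClassifierConfig(seed=0))
        grid = rng.normal(0, 3, size=(100, 2))
        probs = clf.predict_proba(grid)[:, 1]
        margins = clf.decision_function(grid)
        assert np.all((probs > 0) & (probs < 1))
        order = np.argsort(margins)
        assert np.all(np.diff(probs[order]) > -1e-9)

    def test_single_class_error(self, rng):
        with pytest.raises(SingleClassError):
            fit_reward_classifier(rng.normal(size=(10, 2)), np.ones(10))


class TestCompositeReward:
    @pytest.fixture(scope="class")
    def model(self, tuned_encoder, labeled_toy):
        from rxnrl.datasets import DatasetBundle

        bundle = DatasetBundle(train=list(labeled_toy), valid=[], test=[])
        return build_reward_model(tuned_encoder, bundle)

    def test_invalid_product_gets_invalid_reward(self, model):
        assert model.reward("Cc1ccccc1.BrBr", "C1CC") == 0.0
        assert model.reward("Cc1ccccc1.BrBr", "xx") == 0.0

    def test_known_positive_gets_full_reward(self, model):
        assert model.reward("Cc1ccccc1.BrBr", "Cc1ccccc1Br") == 1.0

    def test_known_negative_gets_zero(self, model):
        assert model.reward("Cc1ccccc1.BrBr", "Cc1cccc(Br)c1") == 0.0

    def test_unknown_reaction_scored_by_classifier_in_unit_interval(self, model):
        r = model.reward("Clc1ccccc1.BrBr", "Clc1ccccc1Br")
        assert 0.0 < r < 1.0

    def test_binary_mode_is_zero_one(self, model):
        from dataclasses import replace

        binary = replace(model, binary=True)
        r = binary.reward("Clc1ccccc1.BrBr", "Clc1ccccc1Br")
        assert r in (0.0, 1.0)

    def test_mean_reward_orders_positives_above_negatives(self, model, labeled_toy):
        pos = [r for r in labeled_toy if r.is_positive]
        neg = [r for r in labeled_toy if not r.is_positive]
        rp = np.mean([model.reward(r.reaction.lhs, r.reaction.product.smiles) for r in pos])
        rn = np.mean([model.reward(r.reaction.lhs, r.reaction.product.smiles) for r in neg])
        assert rp > rn

    def test_save_load_roundtrip(self, model, tmp_path):
        model.save(tmp_path / "reward")
        loaded = RewardModel.load(tmp_path / "reward")
        pairs = [
            ("Cc1ccccc1.BrBr", "Cc1ccccc1Br"),
            ("Cc1ccccc1.BrBr", "Cc1cccc(Br)c1"),
            ("Clc1ccccc1.BrBr", "Clc1ccccc1Br"),
            ("Cc1ccccc1.BrBr", "C1CC"),
        ]
        assert loaded.reward_batch(pairs) == model.reward_batch(pairs)
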