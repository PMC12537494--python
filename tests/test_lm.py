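import numpy as np
import pytest

from vegsyntax import corpus, lm
from vegsyntax.corpus import MASK, Sentence, fit_vocabulary


@pytest.fixture(scope="module")
def memorized():
    """Tiny model trained on 50 copies of one 3-species sentence."""
    sents = [Sentence(f"p{i}", ("aa bb", "cc dd", "ee ff")) for i in range(50)]
    vocab = fit_vocabulary(sents, "species")
    cfg = lm.LMConfig(n_layers=1, d_model=32, n_heads=2, d_ff=64, epochs=30,
                      batch_size=16, seed=1, learning_rate=3e-3)
    return lm.train_mlm(sents, vocab, cfg), sents


@pytest.fixture(scope="module")
def pair_model():
    """Model trained only on two disjoint 2-species assemblages."""
    pairs = [("aa bb", "cc dd"), ("ee ff", "gg hh")]
    sents = [Sentence(f"q{i}", pairs[i % 2]) for i in range(200)]
    vocab = fit_vocabulary(sents, "species")
    cfg = lm.LMConfig(n_layers=1, d_model=32, n_heads=2, d_ff=64, epochs=20,
                      batch_size=16, seed=2, learning_rate=3e-3,
                      sep_mask_prob=0.15)
    return lm.train_mlm(sents, vocab, cfg)


class TestTrainMLM:
    def test_memorizes_degenerate_corpus(self, memorized):
        model, _ = memorized
        for i, true in enumerate(("aa bb", "cc dd", "ee ff")):
            query = ["aa bb", "cc dd", "ee ff"]
            query[i] = MASK
            top = lm.predict_topk(model, query, k=1)[0]
            assert top[0].token == true

    def test_same_seed_identical_loss_curves(self):
        sents = [Sentence(f"p{i}", ("aa bb", "cc dd")) for i in range(20)]
        vocab = fit_vocabulary(sents, "species")
        cfg = lm.LMConfig(n_layers=1, d_model=16, n_heads=2, d_ff=32,
                          epochs=3, seed=9)
        h1 = lm.train_mlm(sents, vocab, cfg).history
        h2 = lm.train_mlm(sents, vocab, cfg).history
        assert h1 == h2

    def test_empty_corpus_rejected(self):
        vocab = fit_vocabulary([Sentence("p", ("a a",))], "species")
        with pytest.raises(ValueError):
            lm.train_mlm([], vocab, lm.LMConfig(epochs=1))

    def test_training_reduces_loss(self, memorized):
        model, _ = memorized
        assert model.history[-1] < model.history[0] / 2


class TestPredictTopk:
    def test_renormalized_topk_sums_to_one(self, memorized):
        model, _ = memorized
        preds = lm.predict_topk(model, [MASK, "cc dd"], k=3)[0]
        assert abs(sum(p.probability for p in preds) - 1.0) < 1e-6

    def test_k1_gives_probability_one(self, memorized):
        model, _ = memorized
        preds = lm.predict_topk(model, [MASK, "cc dd"], k=1)[0]
        assert preds[0].probability == pytest.approx(1.0)

    def test_no_mask_is_error(self, memorized):
        model, _ = memorized
        with pytest.raises(ValueError):
            lm.predict_topk(model, ["aa bb"], k=1)

    def test_probabilities_descend(self, memorized):
        model, _ = memorized
        preds = lm.predict_topk(model, [MASK, "cc dd"], k=5,
                                renormalize=False)[0]
        ps = [p.probability for p in preds]
        assert ps == sorted(ps, reverse=True)


class UniformModel:
    """Stub assigning equal probability to every content token."""

    def __init__(self, vocab):
        self.vocab = vocab

    def logits(self, ids):
        out = np.full((*ids.shape, len(self.vocab)), -1e9, dtype=np.float64)
        out[:, :, self.vocab.content_ids] = 0.0
        return out


class TestPerplexity:
    def _corpus(self, n_species=40, n_sent=60, seed=0):
        rng = np.random.default_rng(seed)
        names = [f"gen{i} sp{i}" for i in range(n_species)]
        sents = []
        for i in range(n_sent):
            k = int(rng.integers(5, 15))
            chosen = rng.choice(n_species, k, replace=False)
            sents.append(Sentence(f"p{i}", tuple(names[j] for j in chosen)))
        return sents, fit_vocabulary(sents, "species")

    def test_uniform_model_perplexity_equals_content_vocab_size(self):
        sents, vocab = self._corpus()
        ppl = lm.perplexity(UniformModel(vocab), sents,
                            np.random.default_rng(0))
        assert ppl == pytest.approx(vocab.n_content, rel=1e-3)

    def test_perplexity_bounded_below_by_one(self, memorized):
        # a memorizing model approaches the perfect-prediction bound of 1
        model, sents = memorized
        ppl = lm.perplexity(model, sents, np.random.default_rng(0))
        assert 1.0 <= ppl < 1.5

    def test_log_perplexity_equals_mean_cross_entropy(self):
        sents, vocab = self._corpus(seed=3)
        ce = lm.masked_cross_entropy(UniformModel(vocab), sents,
                                     np.random.default_rng(7))
        ppl = lm.perplexity(UniformModel(vocab), sents,
                            np.random.default_rng(7))
        assert abs(np.log(ppl) - ce) < 1e-6

    def test_untrained_model_close_to_uniform(self):
        sents, vocab = self._corpus(seed=5)
        model = lm.train_mlm(sents, vocab, lm.LMConfig(epochs=0, seed=5))
        ppl = lm.perplexity(model, sents, np.random.default_rng(1))
        # random init gives near-uniform output over the full vocabulary
        assert vocab.n_content * 0.7 < ppl < len(vocab) * 1.3


class TestCompleteAssemblage:
    def test_stops_when_assemblage_complete(self, pair_model):
        added = lm.complete_assemblage(pair_model, ["aa bb", "cc dd"],
                                       max_additions=3)
        assert added == []

    def test_recovers_missing_partner(self, pair_model):
        added = lm.complete_assemblage(pair_model, ["aa bb"], max_additions=3)
        assert [p.token for p in added] == ["cc dd"]

    def test_max_additions_zero(self, pair_model):
        assert lm.complete_assemblage(pair_model, ["aa bb"],
                                      max_additions=0) == []

    def test_never_duplicates_observed(self, memorized):
        model, _ = memorized
        added = lm.complete_assemblage(model, ["aa bb"], max_additions=10)
        names = ["aa bb"] + [p.token for p in added]
        assert len(names) == len(set(names))


class OracleRankPredictor:
    """Always answers with the plot's most abundant species."""

    def predict(self, species, index):
        return [species[0]]


class TestRankMaskingEval:
    def _plots(self, n_species=12, n_plots=30):
        rng = np.random.default_rng(0)
        out = []
        for i in range(n_plots):
            names = tuple(f"g{j} s{j}" for j in
                          rng.permutation(40)[:n_species])
            out.append(Sentence(f"p{i}", names))
        return out

    def test_oracle_predictor_scores_one_at_rank_one_only(self):
        plots = self._plots()
        res = lm.rank_masking_eval(OracleRankPredictor(), plots)
        assert res.per_rank[0] == 1.0
        assert all(a == 0.0 for a in res.per_rank[1:])
        assert res.overall == pytest.approx(0.1)

    def test_exactly_ten_species_excluded(self):
        plots = self._plots(n_species=10)
        res = lm.rank_masking_eval(OracleRankPredictor(), plots)
        assert res.n_plots == 0

    def test_eleven_species_included(self):
        plots = self._plots(n_species=11)
        res = lm.rank_masking_eval(OracleRankPredictor(), plots)
        assert res.n_plots == len(plots)


class ConstantClassifier:
    def __init__(self, label):
        self.label = label

    def predict(self, sentences):
        return [self.label] * len(sentences)


class TestAblationEval:
    def _plots(self):
        return [Sentence(f"p{i}", ("a a", "b b", "c c"), (50.0, 30.0, 10.0))
                for i in range(10)]

    def test_drop_none_is_reference_accuracy(self):
        plots = self._plots()
        acc = lm.ablation_eval(ConstantClassifier("T11"), plots,
                               ["T11"] * 10, drop="none")
        assert acc == 1.0

    def test_drop_last_leaves_two_species(self):
        captured = {}

        class Spy(ConstantClassifier):
            def predict(self, sentences):
                captured["species"] = [s.species for s in sentences]
                return super().predict(sentences)

        lm.ablation_eval(Spy("T11"), self._plots(), ["T11"] * 10, drop="last")
        assert all(sp == ("a a", "b b") for sp in captured["species"])

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            lm.ablation_eval(ConstantClassifier("x"), self._plots(),
                             ["x"] * 10, drop="bogus")


class TestSaveLoad:
    def test_model_round_trip(self, memorized, tmp_path):
        model, _ = memorized
        model.save(tmp_path / "m")
        loaded = lm.EncoderModel.load(tmp_path / "m")
        q = [MASK, "cc dd", "ee ff"]
        a = lm.predict_topk(model, q, k=3)[0]
        b = lm.predict_topk(loaded, q, k=3)[0]
        assert [(p.token, p.probability) for p in a] == \
               [(p.token, p.probability) for p in b]
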