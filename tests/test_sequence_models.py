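"""Sentence-sequence classifiers: biLSTM-CRF and the NB+transitions baseline."""

import numpy as np
import pytest

from cnvreport.embeddings import hashed_embeddings, vocabulary
from cnvreport.models import CATEGORIES, Category, Sentence, SubParagraph
from cnvreport.sequence_models import (
    BiLSTMCRF,
    NaiveBayesCRF,
    TrainingConfig,
    classify_corpus,
    train_corpus_classifier,
)

SMALL = TrainingConfig(
    num_units=24, embedding_dim=16, num_epochs=30, batch_size=16, seed=0
)


def _labeled_sub(texts, cats):
    sents = [Sentence(text=t, index=i, category=c) for i, (t, c) in enumerate(zip(texts, cats))]
    return SubParagraph(sentences=sents)


@pytest.fixture(scope="module")
def toy_training_data():
    """Two-pattern corpus: keyword sentences with positional structure."""
    rng = np.random.default_rng(9)
    words = {
        Category.BASIC: ["segment", "interval", "copy"],
        Category.SYNDROME: ["syndrome", "dysmorphic"],
        Category.PAPER: ["literature", "cohort"],
        Category.PATIENT: ["patient", "phenotype"],
    }
    subs = []
    for _ in range(60):
        middle = [Category.SYNDROME, Category.PAPER]
        cats = (
            [Category.BASIC]
            + [middle[i] for i in rng.integers(0, 2, size=rng.integers(1, 4))]
            + [Category.PATIENT]
        )
        texts = [
            " ".join(words[c][i] for i in rng.integers(0, len(words[c]), size=2))
            for c in cats
        ]
        subs.append(_labeled_sub(texts, cats))
    return subs


@pytest.fixture(scope="module")
def toy_table(toy_training_data):
    texts = [s.text for sub in toy_training_data for s in sub.sentences]
    return hashed_embeddings(vocabulary(texts), dim=16, seed=0)


class TestBiLSTMGradients:
    def test_loss_gradients_match_finite_differences(self):
        config = TrainingConfig(num_units=4, embedding_dim=5, seed=3)
        model = BiLSTMCRF(config)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 5))
        tags = np.array([1, 0, 2])
        _, grads = model._loss_and_grads(X, tags)
        eps = 1e-6
        params = model._params()
        for name in ("Wp", "f.W", "b.U", "trans", "start", "f.b"):
            arr = params[name]
            flat_idx = (0,) * arr.ndim  # spot-check one entry per tensor
            orig = arr[flat_idx]
            arr[flat_idx] = orig + eps
            hi = model._loss_and_grads(X, tags)[0]
            arr[flat_idx] = orig - eps
            lo = model._loss_and_grads(X, tags)[0]
            arr[flat_idx] = orig
            num = (hi - lo) / (2 * eps)
            assert np.isclose(grads[name][flat_idx], num, atol=1e-4), name


class TestContracts:
    def test_single_category_corpus_predicts_it_everywhere(self, toy_table):
        subs = [
            _labeled_sub(["syndrome dysmorphic", "syndrome syndrome"], [Category.SYNDROME] * 2)
            for _ in range(10)
        ]
        model = train_corpus_classifier(subs, SMALL, toy_table, model_type="nb_crf")
        preds = model.predict_categories(subs[0])
        assert preds == [Category.SYNDROME, Category.SYNDROME]

    def test_unlabeled_sentence_errors(self, toy_table):
        sub = _labeled_sub(["a", "b"], [Category.BASIC, None])
        with pytest.raises(ValueError, match="unlabeled"):
            train_corpus_classifier([sub], SMALL, toy_table, model_type="nb")

    def test_long_subparagraph_is_chunked(self, toy_training_data, toy_table):
        config = TrainingConfig(
            num_units=8, embedding_dim=16, num_epochs=2, batch_size=8, seed=0,
            max_sequence_length=40,
        )
        model = train_corpus_classifier(toy_training_data, config, toy_table, model_type="nb_crf")
        long_sub = SubParagraph(
            sentences=[Sentence(text="patient phenotype", index=i) for i in range(150)]
        )
        preds = model.predict_categories(long_sub)
        assert len(preds) == 150
        assert all(p in CATEGORIES for p in preds)

    def test_classify_corpus_empty_input(self, toy_training_data, toy_table):
        model = train_corpus_classifier(toy_training_data, SMALL, toy_table, model_type="nb")
        assert classify_corpus([], model) == []


class TestLearning:
    def test_bilstm_learns_separable_patterns(self, toy_training_data, toy_table):
        model = train_corpus_classifier(
            toy_training_data, SMALL, toy_table, model_type="bilstm_crf"
        )
        correct = total = 0
        for sub in toy_training_data:
            preds = model.predict_categories(sub)
            gold = [s.category for s in sub.sentences]
            correct += sum(p == g for p, g in zip(preds, gold))
            total += len(gold)
        assert correct / total >= 0.95

    def test_seeded_training_is_reproducible(self, toy_training_data, toy_table):
        preds = []
        for _ in range(2):
            model = train_corpus_classifier(
                toy_training_data, SMALL, toy_table, model_type="bilstm_crf"
            )
            preds.append([model.predict_categories(sub) for sub in toy_training_data[:10]])
        assert preds[0] == preds[1]

    def test_transitions_recover_context_dependent_sentences(self, toy_table):
        """A generic trailing sentence is labeled from its neighbors."""
        rng = np.random.default_rng(4)
        subs = []
        for _ in range(80):
            cat = Category.SYNDROME if rng.random() < 0.5 else Category.PAPER
            lead = "syndrome dysmorphic" if cat is Category.SYNDROME else "literature cohort"
            subs.append(
                _labeled_sub([lead, "the of with", "the of with"], [cat, cat, cat])
            )
        table = hashed_embeddings(
            vocabulary([s.text for sub in subs for s in sub.sentences]), dim=16, seed=0
        )
        seq = train_corpus_classifier(subs, SMALL, table, model_type="nb_crf")
        per_sentence = train_corpus_classifier(subs, SMALL, table, model_type="nb")

        probe = _labeled_sub(
            ["syndrome dysmorphic", "the of with", "the of with"], [Category.SYNDROME] * 3
        )
        seq_preds = seq.predict_categories(probe)
        assert seq_preds == [Category.SYNDROME] * 3
        # the per-sentence model has no mechanism to prefer either topic on
        # the generic sentences; the sequence model is at least as accurate
        gold = [s.category for s in probe.sentences]
        ps_preds = per_sentence.predict_categories(probe)
        assert sum(p == g for p, g in zip(seq_preds, gold)) >= sum(
            p == g for p, g in zip(ps_preds, gold)
        )
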