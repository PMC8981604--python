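import numpy as np
import pytest
import scipy.sparse as sp

from bowexp import (
    Document,
    EmbeddingTable,
    FeatureSelectionConfig,
    associate_class,
    cbow_vector,
    chi_square_score,
    cosine_similarity,
    expand_counts,
    fit_vocabulary,
    select_features,
)
from bowexp.features import BowExpRepresentation, TfidfWeighter, count_matrix

from conftest import make_corpus


class TestVocabulary:
    def test_first_appearance_order(self):
        corpus = make_corpus({"x": [["a", "b"], ["b", "c"]], "y": [["d", "a"]]})
        assert fit_vocabulary(corpus) == ["a", "b", "c", "d"]

    def test_repeated_token_once(self):
        corpus = make_corpus({"x": [["x", "x", "x"]], "y": [["y"]]})
        assert fit_vocabulary(corpus) == ["x", "y"]


class TestChiSquare:
    def test_perfectly_indicative_feature(self):
        # feature in all 5 docs of its class and none of the other 5: chi2 = N = 10
        corpus = make_corpus({"a": [["sig", "t"]] * 5, "b": [["t"]] * 5})
        assert chi_square_score("sig", "a", corpus) == pytest.approx(10.0)

    def test_independent_feature_scores_zero(self):
        corpus = make_corpus({"a": [["w"], ["w"], ["x"], ["x"]],
                              "b": [["w"], ["w"], ["x"], ["x"]]})
        assert chi_square_score("w", "a", corpus) == 0.0

    def test_ubiquitous_feature_zero_margin(self):
        # present in every document -> absent margin is 0
        corpus = make_corpus({"a": [["t", "u"]] * 3, "b": [["t"]] * 3})
        assert chi_square_score("t", "a", corpus) == 0.0

    def test_unknown_feature_error(self, separable_corpus):
        with pytest.raises(KeyError):
            chi_square_score("nope", "flu", separable_corpus)


class TestAssociation:
    def test_majority_class_wins(self):
        corpus = make_corpus({"A": [["w"], ["w"], ["w"], ["x"]], "B": [["w"], ["x"]]})
        assert associate_class("w", corpus) == "A"

    def test_tie_goes_to_earlier_class(self):
        corpus = make_corpus({"A": [["w"], ["x"]], "B": [["w"], ["x"]]})
        assert associate_class("w", corpus) == "A"

    def test_exclusive_feature(self):
        corpus = make_corpus({"A": [["x"], ["x"]], "C": [["w"], ["w"]]})
        assert associate_class("w", corpus) == "C"


class TestSelectFeatures:
    def test_two_exclusive_signatures_per_class(self):
        corpus = make_corpus({
            "a": [["s1", "s2", "t"], ["s1", "s2"], ["s1", "t"], ["s2"]],
            "b": [["r1", "r2", "t"], ["r1", "r2"], ["r1", "t"], ["r2"]],
        })
        sel = select_features(corpus, FeatureSelectionConfig(k=2))
        assert len(sel) == 4
        assert sel.class_of["s1"] == "a" and sel.class_of["r2"] == "b"

    def test_k_exceeding_vocabulary_takes_all_associated(self):
        corpus = make_corpus({"a": [["s", "t"]] * 3, "b": [["r", "t"]] * 3})
        sel = select_features(corpus, FeatureSelectionConfig(k=50))
        # every feature lands with its associated class; union covers vocab
        assert set(sel.features) == {"s", "t", "r"}

    def test_per_class_budget_respected(self, separable_corpus):
        sel = select_features(separable_corpus, FeatureSelectionConfig(k=2))
        for c in separable_corpus.classes:
            assert sum(1 for w in sel.features if sel.class_of[w] == c) <= 2

    def test_deterministic(self, separable_corpus):
        s1 = select_features(separable_corpus)
        s2 = select_features(separable_corpus)
        assert s1.features == s2.features
        assert s1.score_of == s2.score_of


class TestCosine:
    def test_identity_orthogonal_and_diagonal(self):
        assert cosine_similarity([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)
        assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)
        assert cosine_similarity([1.0, 1.0], [1.0, 0.0]) == pytest.approx(0.7071, abs=1e-4)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])


class TestExpandCounts:
    def test_synonym_adds_selected_feature(self, toy_embeddings, separable_corpus):
        sel = _selected(["sig"])
        doc = Document("d", ("syn",), "flu")
        out = expand_counts(doc, {"syn": 1.0}, sel, toy_embeddings, t=0.9)
        assert out == {"syn": 1.0, "sig": 1.0}

    def test_self_match_doubles_count(self, toy_embeddings):
        sel = _selected(["sig"])
        doc = Document("d", ("sig",), "flu")
        out = expand_counts(doc, {"sig": 1.0}, sel, toy_embeddings, t=0.9)
        assert out == {"sig": 2.0}

    def test_below_threshold_is_noop(self, toy_embeddings):
        sel = _selected(["sig"])
        doc = Document("d", ("far",), "flu")
        out = expand_counts(doc, {"far": 1.0}, sel, toy_embeddings, t=0.9)
        assert out == {"far": 1.0}

    def test_token_without_embedding_skipped(self, toy_embeddings):
        sel = _selected(["sig"])
        doc = Document("d", ("unknowntoken",), "flu")
        out = expand_counts(doc, {"unknowntoken": 1.0}, sel, toy_embeddings, t=0.9)
        assert out == {"unknowntoken": 1.0}

    def test_per_occurrence_increment(self, toy_embeddings):
        sel = _selected(["sig"])
        doc = Document("d", ("syn", "syn", "syn"), "flu")
        out = expand_counts(doc, {"syn": 3.0}, sel, toy_embeddings, t=0.9)
        assert out["sig"] == 3.0


def _selected(features):
    from bowexp import SelectedFeatureSet
    return SelectedFeatureSet(tuple(features), {f: "flu" for f in features},
                              {f: 1.0 for f in features})


class TestTfidf:
    def test_idf_one_for_ubiquitous_token(self):
        counts = sp.csr_matrix(np.array([[1.0, 1.0], [1.0, 0.0]]))
        w = TfidfWeighter().fit(counts)
        assert w.idf[0] == pytest.approx(1.0)
        assert w.idf[1] == pytest.approx(np.log(3 / 2) + 1, abs=1e-9)

    def test_rows_l2_normalized(self):
        rng = np.random.default_rng(0)
        counts = sp.csr_matrix(rng.integers(0, 4, size=(6, 9)).astype(float))
        w = TfidfWeighter().fit(counts)
        X = w.transform(counts)
        norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
        nonzero = np.asarray(counts.sum(axis=1)).ravel() > 0
        assert np.allclose(norms[nonzero], 1.0)

    def test_matches_direct_formula(self):
        # independent elementwise oracle: tf * (ln((1+N)/(1+df)) + 1), L2 rows
        rng = np.random.default_rng(1)
        raw = rng.integers(0, 3, size=(8, 12)).astype(float)
        raw[:, 0] += 1  # ensure at least one dense column
        N = raw.shape[0]
        df = (raw > 0).sum(axis=0)
        expected = raw * (np.log((1 + N) / (1 + df)) + 1)
        norms = np.linalg.norm(expected, axis=1, keepdims=True)
        expected = np.where(norms > 0, expected / np.where(norms > 0, norms, 1), 0)
        got = TfidfWeighter().fit(sp.csr_matrix(raw)).transform(sp.csr_matrix(raw)).toarray()
        assert np.allclose(got, expected, atol=1e-9)

    def test_test_rows_reuse_training_idf(self):
        train = sp.csr_matrix(np.array([[1.0, 0.0], [1.0, 1.0]]))
        w = TfidfWeighter().fit(train)
        test = sp.csr_matrix(np.array([[0.0, 2.0]]))
        row = w.transform(test).toarray()[0]
        assert row[0] == 0.0 and row[1] == pytest.approx(1.0)  # single nonzero, normalized


class TestCbow:
    def test_single_token_identity(self, toy_embeddings):
        doc = Document("d", ("sig",), "x")
        assert np.allclose(cbow_vector(doc, toy_embeddings), toy_embeddings["sig"])

    def test_mean_and_per_occurrence_weighting(self):
        emb = EmbeddingTable({"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])})
        assert np.allclose(cbow_vector(Document("d", ("a", "b"), "x"), emb), [0.5, 0.5])
        assert np.allclose(cbow_vector(Document("d", ("a", "a", "b"), "x"), emb),
                           [2 / 3, 1 / 3])

    def test_no_embedded_token_error(self, toy_embeddings):
        with pytest.raises(ValueError):
            cbow_vector(Document("d", ("zzz",), "x"), toy_embeddings)


class TestBatchExpansionConsistency:
    def test_matrix_route_matches_per_document_route(self, separable_corpus):
        rng = np.random.default_rng(0)
        vocab = fit_vocabulary(separable_corpus)
        emb = EmbeddingTable({t: rng.standard_normal(8) for t in vocab})
        rep = BowExpRepresentation(emb, FeatureSelectionConfig(k=2, t=0.9))
        rep.fit(separable_corpus)
        raw = count_matrix(separable_corpus.documents, vocab)
        batch = rep._index.expand(separable_corpus.documents, raw).toarray()
        for i, doc in enumerate(separable_corpus.documents):
            raw_doc = {vocab[j]: raw[i, j] for j in raw[i].indices}
            per_doc = expand_counts(doc, raw_doc, rep.selected, emb, t=0.9)
            dense = {vocab[j]: v for j, v in enumerate(batch[i]) if v}
            assert dense == {k: v for k, v in per_doc.items() if v}

    def test_expansion_monotone_and_preserves_non_selected(self, separable_corpus):
        rng = np.random.default_rng(3)
        vocab = fit_vocabulary(separable_corpus)
        emb = EmbeddingTable({t: rng.standard_normal(8) for t in vocab})
        rep = BowExpRepresentation(emb, FeatureSelectionConfig(k=2, t=0.9))
        rep.fit(separable_corpus)
        raw = count_matrix(separable_corpus.documents, vocab)
        expanded = rep._index.expand(separable_corpus.documents, raw)
        diff = (expanded - raw).toarray()
        assert (diff >= 0).all()
        selected_cols = {vocab.index(w) for w in rep.selected.features}
        untouched = [j for j in range(len(vocab)) if j not in selected_cols]
        assert (diff[:, untouched] == 0).all()
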