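import json

import numpy as np
import pytest

from bowexp import (
    Corpus,
    Document,
    SplitPlan,
    class_prevalence,
    load_corpus,
    nested_subsample,
    rare_subset,
    save_corpus,
    stratified_split,
)

from conftest import make_corpus


class TestLoading:
    def test_jsonl_roundtrip(self, tmp_path):
        path = tmp_path / "c.jsonl"
        records = [
            {"id": "p1", "label": "flu", "tokens": ["cough", "fever"]},
            {"id": "p2", "label": "flu", "tokens": ["fever"]},
            {"id": "p3", "label": "rash", "tokens": ["itch"]},
        ]
        path.write_text("\n".join(json.dumps(r) for r in records))
        corpus = load_corpus(path, "jsonl")
        assert len(corpus) == 3
        assert corpus.classes == ("flu", "rash")
        save_corpus(corpus, tmp_path / "out.jsonl")
        again = load_corpus(tmp_path / "out.jsonl")
        assert again.documents == corpus.documents

    def test_tsv_line_parsing(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("p1\tflu\tcough fever\np2\trash\titch\n")
        corpus = load_corpus(path, "tsv")
        assert corpus.documents[0] == Document("p1", ("cough", "fever"), "flu")

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "c.jsonl"
        rec = {"id": "p1", "label": "flu", "tokens": ["a"]}
        path.write_text(json.dumps(rec) + "\n" + json.dumps(rec) + "\n")
        with pytest.raises(ValueError, match="p1"):
            load_corpus(path)

    def test_empty_tokens_rejected(self):
        with pytest.raises(ValueError, match="empty token"):
            Document("p1", (), "flu")

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "c.xyz"
        path.write_text("x")
        with pytest.raises(ValueError, match="format"):
            load_corpus(path, "xyz")


class TestPrevalence:
    def test_two_in_ten_thousand(self):
        docs = [Document(f"d{i}", ("t",), "common") for i in range(9998)]
        docs += [Document("r1", ("t",), "rare"), Document("r2", ("t",), "rare")]
        corpus = Corpus(tuple(docs))
        prev = class_prevalence(corpus)
        assert prev["rare"] == pytest.approx(0.0002)
        assert rare_subset(corpus, 0.0002) == {"rare"}  # inclusive threshold

    @pytest.mark.parametrize("counts,expected", [
        ((6, 3, 1), (0.6, 0.3, 0.1)),
        ((5,), (1.0,)),
    ])
    def test_prevalence_values(self, counts, expected):
        corpus = make_corpus({f"c{j}": [["t"]] * n for j, n in enumerate(counts)})
        prev = class_prevalence(corpus)
        assert tuple(prev[f"c{j}"] for j in range(len(counts))) == pytest.approx(expected)
        assert sum(prev.values()) == pytest.approx(1.0, abs=1e-12)

    def test_rare_subset_empty_when_all_common(self):
        corpus = make_corpus({"a": [["t"]] * 5, "b": [["t"]] * 5})
        assert rare_subset(corpus, 0.0002) == set()


class TestStratifiedSplit:
    def test_class_of_five_splits_four_one(self):
        corpus = make_corpus({"a": [["t"]] * 5, "b": [["t"]] * 5})
        train, test = stratified_split(corpus, 0.2, seed=0)
        assert train.class_counts() == {"a": 4, "b": 4}
        assert test.class_counts() == {"a": 1, "b": 1}

    def test_class_of_two_forces_one_each_side(self):
        corpus = make_corpus({"a": [["t"]] * 2, "b": [["t"]] * 10})
        train, test = stratified_split(corpus, 0.2, seed=0)
        assert train.class_counts()["a"] == 1
        assert test.class_counts()["a"] == 1

    def test_same_seed_same_partition(self, separable_corpus):
        s1 = stratified_split(separable_corpus, 0.2, seed=42)
        s2 = stratified_split(separable_corpus, 0.2, seed=42)
        assert [d.id for d in s1[0]] == [d.id for d in s2[0]]
        assert [d.id for d in s1[1]] == [d.id for d in s2[1]]

    def test_singleton_class_error_names_class(self):
        corpus = make_corpus({"a": [["t"]], "b": [["t"]] * 3})
        with pytest.raises(ValueError, match="'a'"):
            stratified_split(corpus, 0.2, seed=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_and_coverage_properties(self, seed):
        rng = np.random.default_rng(seed)
        corpus = make_corpus({
            f"c{j}": [["t"]] * int(rng.integers(2, 12)) for j in range(6)
        })
        train, test = stratified_split(corpus, 0.25, seed=seed)
        train_ids = {d.id for d in train}
        test_ids = {d.id for d in test}
        assert train_ids | test_ids == {d.id for d in corpus}
        assert not train_ids & test_ids
        for side in (train, test):
            assert set(side.classes) == set(corpus.classes)


class TestNestedSubsample:
    def test_ten_percent_of_ten_is_one(self):
        corpus = make_corpus({"a": [["t"]] * 10, "b": [["t"]] * 10})
        subsets = nested_subsample(corpus, [0.1, 1.0], seed=0)
        assert subsets[0].class_counts() == {"a": 1, "b": 1}

    def test_nesting_and_identity(self):
        corpus = make_corpus({"a": [["t"]] * 4, "b": [["t"]] * 7})
        subsets = nested_subsample(corpus, [0.5, 1.0], seed=1)
        ids = [{d.id for d in s} for s in subsets]
        assert ids[0] <= ids[1]
        assert subsets[0].class_counts()["a"] == 2
        assert ids[-1] == {d.id for d in corpus}

    @pytest.mark.parametrize("seed", range(3))
    def test_nesting_property_full_grid(self, seed):
        corpus = make_corpus({f"c{j}": [["t"]] * (j + 2) for j in range(5)})
        subsets = nested_subsample(corpus, [0.1, 0.3, 0.6, 1.0], seed=seed)
        for a, b in zip(subsets, subsets[1:]):
            assert {d.id for d in a} <= {d.id for d in b}

    def test_bad_proportions_rejected(self):
        corpus = make_corpus({"a": [["t"]] * 3, "b": [["t"]] * 3})
        with pytest.raises(ValueError):
            nested_subsample(corpus, [0.5, 0.4, 1.0], seed=0)
        with pytest.raises(ValueError):
            nested_subsample(corpus, [0.5, 0.9], seed=0)


class TestSplitPlan:
    def test_defaults_match_protocol(self):
        plan = SplitPlan()
        assert plan.test_fraction == 0.2
        assert plan.n_runs == 10
        assert plan.proportions == tuple(pytest.approx(p) for p in np.arange(1, 11) * 0.1)

    def test_invalid_plans_rejected(self):
        with pytest.raises(ValueError):
            SplitPlan(proportions=(0.5, 0.9))
        with pytest.raises(ValueError):
            SplitPlan(test_fraction=1.5)
        with pytest.raises(ValueError):
            SplitPlan(n_runs=0)
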