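import numpy as np
import pytest

import codoncontext as cc
from codoncontext.model import CASCADE_CUTOFFS, CASCADE_WINDOWS


@pytest.fixture(scope="module")
def split_corpora(context_rule):
    """Index corpus and held-out training corpus from the same generator rule."""
    index_spec = cc.CorpusSpec(n_genes=150, length_range=(60, 120),
                               rules=(context_rule,), seed=21)
    held_spec = cc.CorpusSpec(n_genes=30, length_range=(60, 120),
                              rules=(context_rule,), seed=22)
    return cc.generate_corpus(index_spec), cc.generate_corpus(held_spec)


@pytest.fixture(scope="module")
def w5_index(split_corpora):
    index_corpus, _ = split_corpora
    return cc.build_index(index_corpus, 5)


class TestMakeTrainingSet:
    def test_row_counts_match_brute_force(self, split_corpora, w5_index):
        """Row counts equal the number of held-out windows with >=1 match,
        cross-checked by an independent scan."""
        _, held = split_corpora
        sets = cc.make_training_set(held, w5_index, 0.9)
        direct: dict[str, int] = {}
        for cds in held:
            for frag in cc.extract_fragments(cds, 5):
                aa = frag.middle
                if w5_index.code.degeneracy(aa) == 1:
                    continue
                m = sum(cc.blosum62_score(q, q) for q in frag.peptide)
                hit = any(
                    rec.middle == aa
                    and sum(cc.blosum62_score(q, r)
                            for q, r in zip(frag.peptide, rec.peptide)) / m >= 0.9
                    for rec in w5_index.records.values()
                )
                if hit:
                    direct[aa] = direct.get(aa, 0) + 1
        assert {aa: len(ts) for aa, ts in sets.items()} == direct

    def test_exact_match_rows_have_p_one_features(self, w5_index):
        """A gene whose fragments all exist in the index yields rows built
        from the exact-match record at c=1."""
        peptide = next(iter(w5_index.records))
        rec = w5_index.records[peptide]
        matches = cc.search(w5_index, peptide, 1.0)
        assert len(matches) == 1 and matches[0].p == 1.0
        fv = cc.aggregate_features(matches, w5_index.code)
        codons = w5_index.code.codons_for(rec.middle)
        for i, codon in enumerate(codons):
            assert fv.values[i] == pytest.approx(rec.middle_dist.get(codon, 0.0))

    def test_multi_cutoff_equals_per_cutoff(self, split_corpora, w5_index):
        _, held = split_corpora
        held = held[:10]
        multi = cc.make_training_sets_multi(held, w5_index, (0.85, 1.0))
        for c in (0.85, 1.0):
            single = cc.make_training_set(held, w5_index, c)
            assert set(single) == set(multi[c])
            for aa in single:
                assert np.allclose(single[aa].X, multi[c][aa].X)
                assert (single[aa].y == multi[c][aa].y).all()

    def test_no_possible_match_gives_empty(self, w5_index):
        """Held-out windows over amino acids absent from the index match
        nothing, so their amino acids are untrainable."""
        foreign = [cc.make_cds("f", "ATG" + "TTT" * 10 + "TAA")]  # poly-Phe
        assert cc.make_training_set(foreign, w5_index, 0.8) == {}


class TestCodonClassifier:
    def _toy_set(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = np.where(rng.random(n) < 0.5, "GAA", "GAG")
        X = np.zeros((n, 8))
        X[:, 0] = (y == "GAA").astype(float)  # one-hot feature: separable
        X[:, 1] = (y == "GAG").astype(float)
        return cc.TrainingSet(amino_acid="E", w=3, c=1.0, X=X, y=y)

    def test_deterministic_under_seed(self):
        ts = self._toy_set()
        p1 = cc.train(ts, seed=7, n_trees=20).predict(ts.X)
        p2 = cc.train(ts, seed=7, n_trees=20).predict(ts.X)
        assert (p1 == p2).all()

    def test_classes_alphabetical(self):
        clf = cc.train(self._toy_set(), seed=0, n_trees=10)
        assert list(clf.classes_) == sorted(clf.classes_)
        assert not clf.single_class_

    def test_single_class_flagged(self):
        ts = cc.TrainingSet(amino_acid="E", w=3, c=1.0,
                            X=np.zeros((10, 8)), y=np.array(["GAA"] * 10))
        clf = cc.train(ts, seed=0, n_trees=5)
        assert clf.single_class_
        assert (clf.predict(np.zeros((3, 8))) == "GAA").all()

    def test_sklearn_params_round_trip(self):
        clf = cc.CodonClassifier(amino_acid="E", w=5, c=0.9, n_trees=10)
        params = clf.get_params()
        assert params["n_trees"] == 10 and params["c"] == 0.9
        clf.set_params(n_trees=20)
        assert clf.n_trees == 20


class TestCrossValidate:
    def test_separable_toy_perfect(self):
        ts = TestCodonClassifier()._toy_set(n=100)
        res = cc.cross_validate(ts, folds=5, seed=0, n_trees=20)
        assert res["accuracy"] == 1.0
        assert res["auc"] == 1.0

    def test_constant_labels(self):
        ts = cc.TrainingSet(amino_acid="E", w=3, c=1.0,
                            X=np.zeros((20, 8)), y=np.array(["GAA"] * 20))
        res = cc.cross_validate(ts, folds=5, seed=0, n_trees=5)
        assert res["accuracy"] == 1.0 and res["auc"] is None

    def test_context_free_accuracy_near_modal(self):
        """Features carry no label signal: CV accuracy matches the modal
        class frequency (70/30 split)."""
        rng = np.random.default_rng(4)
        n = 2000
        y = np.where(rng.random(n) < 0.7, "GAA", "GAG")
        X = rng.random((n, 8))
        ts = cc.TrainingSet(amino_acid="E", w=3, c=1.0, X=X, y=y)
        res = cc.cross_validate(ts, folds=5, seed=0, n_trees=50)
        modal = max((y == "GAA").mean(), (y == "GAG").mean())
        assert res["accuracy"] == pytest.approx(modal, abs=0.05)

    def test_small_class_falls_back_to_plain_kfold(self):
        y = np.array(["GAA"] * 30 + ["GAG"] * 3)
        X = np.random.default_rng(0).random((33, 8))
        ts = cc.TrainingSet(amino_acid="E", w=3, c=1.0, X=X, y=y)
        with pytest.warns(UserWarning, match="fewer than"):
            cc.cross_validate(ts, folds=10, seed=0, n_trees=5)


class TestBaselineAndCoverage:
    def test_baseline_accuracy_direct_count(self):
        rng = np.random.default_rng(5)
        y = np.where(rng.random(5000) < 0.7, "GAA", "GAG")
        ts = cc.TrainingSet(amino_acid="E", w=3, c=1.0,
                            X=np.zeros((5000, 8)), y=y)
        fc = cc.classify_frequency(cc.count_usage(
            [cc.make_cds("g", "ATG" + "GAA" * 7 + "GAG" * 3 + "TAA")]))
        assert cc.baseline_accuracy(ts, fc) == pytest.approx((y == "GAA").mean())

    def test_baseline_empty_absent(self):
        ts = cc.TrainingSet(amino_acid="E", w=3, c=1.0,
                            X=np.zeros((0, 8)), y=np.array([], dtype=str))
        fc = cc.classify_frequency(cc.count_usage(
            [cc.make_cds("g", "ATGGAAGAGTAA")]))
        assert cc.baseline_accuracy(ts, fc) is None

    def test_coverage_one_for_indexed_queries(self, synthetic_index):
        queries = list(synthetic_index.records)[:50]
        assert cc.coverage(synthetic_index, queries, 1.0) == 1.0

    def test_coverage_monotone_in_cutoff(self, synthetic_index, free_corpus):
        rng = np.random.default_rng(6)
        letters = "AEGKLRSV"
        queries = ["".join(rng.choice(list(letters), size=5)) for _ in range(100)]
        covs = [cc.coverage(synthetic_index, queries, c)
                for c in (0.8, 0.85, 0.9, 0.95, 1.0)]
        assert all(a >= b for a, b in zip(covs, covs[1:]))

    def test_coverage_brute_force_recount(self, synthetic_index):
        from test_match import brute_force_search

        rng = np.random.default_rng(7)
        peps = list(synthetic_index.records)
        queries = [peps[i] for i in rng.choice(len(peps), size=30, replace=False)]
        cov = cc.coverage(synthetic_index, queries, 0.9)
        direct = sum(
            1 for q in queries if brute_force_search(synthetic_index, q, 0.9)
        ) / len(queries)
        assert cov == direct


class TestCascade:
    def _dummy(self, aa, w, c):
        ts = cc.TrainingSet(amino_acid=aa, w=w, c=c,
                            X=np.zeros((4, 6 + w)),
                            y=np.array(["GAA", "GAG", "GAA", "GAG"]))
        return cc.train(ts, seed=0, n_trees=2)

    def test_full_grid_order(self):
        models = {
            (w, c): {"E": self._dummy("E", w, c)}
            for w in CASCADE_WINDOWS for c in CASCADE_CUTOFFS
        }
        cascade = cc.assemble_cascade(models)
        assert [(w, c) for w, c, _ in cascade] == [
            (7, 1.0), (7, 0.95), (7, 0.9), (7, 0.85), (7, 0.8),
            (5, 1.0), (5, 0.95), (5, 0.9), (5, 0.85), (5, 0.8),
        ]

    def test_partial_grid_keeps_order(self):
        models = {(5, c): {"E": self._dummy("E", 5, c)} for c in CASCADE_CUTOFFS}
        cascade = cc.assemble_cascade(models)
        assert [(w, c) for w, c, _ in cascade] == [
            (5, 1.0), (5, 0.95), (5, 0.9), (5, 0.85), (5, 0.8)
        ]

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            cc.assemble_cascade({})

    def test_save_load_round_trip(self, tmp_path):
        models = {(5, 1.0): {"E": self._dummy("E", 5, 1.0)}}
        cascade = cc.assemble_cascade(models)
        path = tmp_path / "cascade.joblib"
        from codoncontext.model import load_cascade, save_cascade

        save_cascade(cascade, path)
        back = load_cascade(path)
        assert [(w, c) for w, c, _ in back] == [(5, 1.0)]
        X = np.zeros((2, 11))
        assert (back.levels[0][2]["E"].predict(X)
                == cascade.levels[0][2]["E"].predict(X)).all()
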