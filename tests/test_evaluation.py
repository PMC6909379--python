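import numpy as np
import pytest

from idlda import (
    DiffusionParams,
    IDLDA,
    SyntheticSpec,
    auroc,
    cv_local,
    enrichment,
    grid_search,
    loocv,
    make_forest,
    make_network,
)
from idlda.evaluation import roc_points

from .oracles import auroc_oracle


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 1, 0, 0], [4, 3, 2, 1]) == 1.0

    def test_all_ties_is_chance(self):
        assert auroc([1, 0, 1, 0], [2, 2, 2, 2]) == 0.5

    def test_enumerated_pair_example(self):
        # pairs: (4>3), (4>1), (2<3), (2>1) -> 3/4
        assert auroc([1, 0, 1, 0], [4, 3, 2, 1]) == 0.75

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="positive and a negative"):
            auroc([1, 1], [0.2, 0.3])

    def test_matches_all_pairs_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 2, n)
            if labels.all() or not labels.any():
                continue
            scores = rng.integers(0, 5, n).astype(float)  # heavy ties
            assert auroc(labels, scores) == pytest.approx(auroc_oracle(labels, scores))

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        for _ in range(20):
            labels = rng.integers(0, 2, 50)
            if labels.all() or not labels.any():
                continue
            scores = rng.normal(size=50)
            assert auroc(labels, scores) == pytest.approx(sklearn_metrics.roc_auc_score(labels, scores))


class TestRocPoints:
    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        scores = rng.integers(0, 6, 40).astype(float)
        pts = roc_points(labels, scores)
        assert pts[0].tolist() == [0.0, 0.0]
        assert pts[-1].tolist() == [1.0, 1.0]
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()


class TestLoocv:
    def test_planted_signal_beats_shuffled_scores(self):
        spec = SyntheticSpec(seed=13)
        net, forest = make_network(spec), make_forest(spec)
        result = loocv(net, forest)
        assert result.auroc > 0.5
        rng = np.random.default_rng(13)
        shuffled = rng.permutation(result.scores)
        assert result.auroc > auroc(result.labels, shuffled)

    def test_near_complete_network_smoke(self):
        A = np.ones((3, 3))
        A[0, 0] = 0.0
        from idlda import AssociationNetwork

        net = AssociationNetwork(["a", "b", "c"], ["x", "y", "z"], A)
        result = loocv(net, None)
        assert 0.0 <= result.auroc <= 1.0

    def test_deterministic(self, planted):
        net, forest, _ = planted
        r1, r2 = loocv(net, forest), loocv(net, forest)
        assert r1.auroc == r2.auroc
        assert np.array_equal(r1.scores, r2.scores)

    def test_requires_two_associations(self):
        from idlda import AssociationNetwork

        net = AssociationNetwork(["a"], ["x"], np.ones((1, 1)))
        with pytest.raises(ValueError):
            loocv(net)

    def test_per_disease_aurocs_bounded(self, planted):
        net, forest, _ = planted
        result = loocv(net, forest)
        assert result.per_disease_auroc
        assert all(0.0 <= v <= 1.0 for v in result.per_disease_auroc.values())


class TestCvLocal:
    def test_same_seed_reproduces(self, planted):
        net, forest, _ = planted
        r1 = cv_local(net, forest, axis="rows", n_folds=4, seed=5)
        r2 = cv_local(net, forest, axis="rows", n_folds=4, seed=5)
        assert r1.auroc == r2.auroc and np.array_equal(r1.scores, r2.scores)

    def test_held_out_rows_receive_nonzero_scores(self, planted):
        net, forest, _ = planted
        r = cv_local(net, forest, axis="rows", n_folds=4, seed=1)
        assert r.scores.max() > 0.0

    def test_cols_axis_completes_with_kernel_fallback(self, planted):
        # held-out lncRNA columns have empty disease sets, so their
        # functional similarity is zero and the ensemble uses the kernel
        net, forest, _ = planted
        r = cv_local(net, forest, axis="cols", n_folds=4, seed=2)
        assert 0.0 <= r.auroc <= 1.0

    def test_held_out_disease_ranked_by_semantics_within_row(self):
        # when same-block diseases share a deep MeSH spine, a disease whose
        # row is fully masked still ranks its true partners highly; note the
        # pooled AUROC across folds is weaker than this because absolute
        # score scales differ between seed diseases
        from idlda import MeshForest
        from idlda.kernels import compute_similarities
        from idlda.model import ensemble_associations, score_disease
        from idlda.semantic import semantic_similarity_matrix

        spec = SyntheticSpec(seed=7, mesh_coverage=1.0)
        net = make_network(spec)
        rng = np.random.default_rng(0)
        mapping = {
            name: frozenset({f"C{(i % 2) + 1:02d}.100.200.{rng.integers(0, 1000):03d}"})
            for i, name in enumerate(spec.disease_names)
        }
        forest = MeshForest(mapping)
        SS = semantic_similarity_matrix(net.disease_names, forest).to_numpy()
        A_train = net.A.copy()
        A_train[0, :] = 0.0
        sims = compute_similarities(net, None, SS=SS, A=A_train)
        DA, LA = ensemble_associations(A_train, sims.DS, sims.LS)
        s = score_disease(0, DA, LA, DiffusionParams(0.3, 0.5))
        assert auroc(net.A[0], s) > 0.6

    def test_bad_axis_rejected(self, planted):
        net, forest, _ = planted
        with pytest.raises(ValueError, match="axis"):
            cv_local(net, forest, axis="diagonal")


class TestGridSearch:
    def test_single_point_grid(self, planted):
        net, forest, _ = planted
        a, b, best, table = grid_search(net, forest, alphas=(0.3,), betas=(0.5,))
        assert (a, b) == (0.3, 0.5)
        assert table.shape == (1, 1) and table[0, 0] == best

    def test_flat_grid_ties_break_lexicographically(self):
        # one disease, two known pairs: the held-out and candidate lncRNAs
        # always tie exactly, so the whole grid is chance level and the
        # argmax must fall back to the smallest (alpha, beta)
        from idlda import AssociationNetwork

        net = AssociationNetwork(["a"], ["x", "y", "z"], np.array([[1.0, 1.0, 0.0]]))
        a, b, best, table = grid_search(net, None, alphas=(0.0, 0.5, 1.0), betas=(0.0, 1.0))
        assert np.allclose(table, 0.5)
        assert (a, b) == (0.0, 0.0)

    def test_maximum_dominates_default_point(self, planted):
        net, forest, _ = planted
        _, _, best, table = grid_search(net, forest, alphas=(0.1, 0.3, 0.9), betas=(0.1, 0.5, 0.9))
        assert best >= table[1, 1]
        assert best == table.max()


class TestEnrichment:
    def test_all_positives_in_first_bin_identity(self):
        from idlda import AssociationNetwork

        A = np.zeros((2, 5))
        A[0, :2] = 1.0  # M = 2 positives
        net = AssociationNetwork(["a", "b"], [f"l{j}" for j in range(5)], A)
        R = np.zeros((2, 5))
        R[0, :2] = 1.0  # both positives top-ranked
        res = enrichment(R, net, x=10)  # x >= N: single bin
        assert res.fold_scores[0] == pytest.approx(res.total_pairs / 10)

    def test_direct_count_example(self):
        from idlda import AssociationNetwork

        A = np.zeros((2, 5))
        A[0, 0] = A[0, 1] = 1.0
        net = AssociationNetwork(["a", "b"], [f"l{j}" for j in range(5)], A)
        scores = np.arange(10, 0, -1, dtype=float).reshape(2, 5)
        res = enrichment(scores, net, x=5)
        assert res.fold_scores == pytest.approx([2.0, 0.0])

    def test_bin_counts_sum_to_total(self, planted):
        net, forest, _ = planted
        res = IDLDA(net, forest).fit()
        e = enrichment(res.R, net, x=7)
        assert sum(e.counts) == net.n_associations
        assert sum(e.bin_sizes) == net.n_diseases * net.n_lncrnas

    def test_mean_fold_score_is_one_when_bins_divide(self, planted):
        net, forest, _ = planted
        res = IDLDA(net, forest).fit()
        e = enrichment(res.R, net, x=20)  # 400 pairs / 20 = integer bins
        assert np.mean(e.fold_scores) == pytest.approx(1.0)

    def test_partial_last_bin_uses_true_size(self):
        from idlda import AssociationNetwork

        A = np.ones((1, 3))
        net = AssociationNetwork(["a"], ["x", "y", "z"], A)
        res = enrichment(np.array([[3.0, 2.0, 1.0]]), net, x=2)
        assert res.bin_sizes == [2, 1]
        assert res.fold_scores == pytest.approx([1.0, 1.0])

    def test_random_scores_enrich_nothing_on_average(self, planted):
        net, forest, _ = planted
        rng = np.random.default_rng(0)
        N = net.n_diseases * net.n_lncrnas
        n_shuffles = 200
        acc = None
        for _ in range(n_shuffles):
            R = rng.permutation(N).astype(float).reshape(net.A.shape)
            e = enrichment(R, net, x=100)
            acc = np.array(e.fold_scores) if acc is None else acc + e.fold_scores
        assert np.allclose(acc / n_shuffles, 1.0, atol=0.15)
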