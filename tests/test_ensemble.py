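import itertools

import numpy as np
import pandas as pd
import pytest

import dbupipe.ensemble as ens
from dbupipe.ensemble import (
    AMBIGUOUS,
    NOISE,
    DbscanParams,
    EnsembleConfig,
    UmapParams,
    _plurality_vote,
    align_labels,
    choose_eps_elbow,
    cluster_density,
    concordance,
    embed_2d,
    hierarchical_cluster,
    separation_score,
)
from dbupipe.iohub import ExpressionTable, PhenotypeTable

from conftest import two_blob_coords


def brute_force_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Independent oracle: direct neighborhood enumeration + BFS expansion."""
    n = len(points)
    dist = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    neighbors = [set(np.where(dist[i] <= eps)[0]) for i in range(n)]  # incl self
    core = [len(neighbors[i]) >= min_pts for i in range(n)]
    labels = np.full(n, NOISE)
    cluster = 0
    for i in range(n):
        if labels[i] != NOISE or not core[i]:
            continue
        frontier = [i]
        labels[i] = cluster
        while frontier:
            j = frontier.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == NOISE:
                    labels[k] = cluster
                    frontier.append(k)
        cluster += 1
    return labels


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Same partition up to label renaming; noise must match exactly."""
    if not np.array_equal(a == NOISE, b == NOISE):
        return False
    mask = a != NOISE
    pairs = set(zip(a[mask].tolist(), b[mask].tolist()))
    return len(pairs) == len(set(x for x, _ in pairs)) == len(set(y for _, y in pairs))


def make_blob_expr(n_per_class=25, n_genes=60, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_genes, n_per_class))
    b = rng.normal(0.0, 1.0, size=(n_genes, n_per_class))
    b[: n_genes // 2] += sep
    a[n_genes // 2 :] += sep
    data = np.hstack([a, b]) + 8.0
    cols = [f"a{i}" for i in range(n_per_class)] + [f"b{i}" for i in range(n_per_class)]
    return ExpressionTable(
        pd.DataFrame(data, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    )


class TestEmbed2d:
    def test_shape_and_finiteness(self):
        expr = make_blob_expr()
        coords = embed_2d(expr, UmapParams(n_neighbors=10, gene_count=60), seed=1)
        assert coords.shape == (50, 2)
        assert np.isfinite(coords.values).all()

    def test_determinism(self):
        expr = make_blob_expr()
        p = UmapParams(n_neighbors=10, gene_count=60)
        a = embed_2d(expr, p, seed=3)
        b = embed_2d(expr, p, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_too_few_samples_rejected(self, toy_expression):
        with pytest.raises(ValueError, match="n_neighbors"):
            embed_2d(toy_expression, UmapParams(n_neighbors=20, gene_count=3), seed=0)

    def test_separable_classes_score_above_one(self):
        expr = make_blob_expr(sep=8.0)
        coords = embed_2d(expr, UmapParams(n_neighbors=10, gene_count=60), seed=2)
        labels = np.array([0] * 25 + [1] * 25)
        assert separation_score(coords.values, labels) > 1.0


class TestClusterDensity:
    def test_two_blobs_exact(self):
        pts = two_blob_coords()
        labels = cluster_density(pts, DbscanParams(eps=2.0, min_pts=5))
        oracle = brute_force_dbscan(pts, 2.0, 5)
        assert partitions_equal(labels, oracle)
        assert len(set(labels)) == 2
        assert NOISE not in labels

    def test_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            pts = rng.uniform(0, 10, size=(40, 2))
            eps = rng.uniform(0.5, 3.0)
            min_pts = int(rng.integers(2, 7))
            got = cluster_density(pts, DbscanParams(eps=eps, min_pts=min_pts))
            want = brute_force_dbscan(pts, eps, min_pts)
            # Border points reachable from two clusters may land in either,
            # so compare noise sets, cluster counts, and the core-point
            # partition (which is unambiguous).
            assert np.array_equal(got == NOISE, want == NOISE)
            assert len(set(got[got != NOISE])) == len(set(want[want != NOISE]))
            dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            core = (dist <= eps).sum(axis=1) >= min_pts
            if core.any():
                assert partitions_equal(got[core], want[core])

    def test_isolated_points_all_noise(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
        labels = cluster_density(pts, DbscanParams(eps=2.0, min_pts=5))
        assert (labels == NOISE).all()

    def test_permutation_invariance_up_to_relabel(self):
        pts = two_blob_coords()
        labels = cluster_density(pts, DbscanParams(eps=2.0, min_pts=5))
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(pts))
        permuted = cluster_density(pts[perm], DbscanParams(eps=2.0, min_pts=5))
        assert partitions_equal(labels[perm], permuted)


class TestChooseEpsElbow:
    def test_two_blob_eps_recovers_clusters(self):
        # With 10-point blobs and min_pts=5 every 5th-neighbor distance is
        # intra-blob, so the k-distance curve stays below the inter scale;
        # the operative requirement is that the knee eps separates the blobs.
        pts = two_blob_coords()
        eps = choose_eps_elbow(pts, min_pts=5)
        assert 0.0 < eps < 10.0
        labels = cluster_density(pts, DbscanParams(eps=eps, min_pts=5))
        assert len(set(labels)) == 2
        assert NOISE not in labels

    def test_uniform_grid_finite(self):
        xs, ys = np.meshgrid(np.arange(6.0), np.arange(6.0))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        eps = choose_eps_elbow(pts, min_pts=4)
        assert 0 < eps < 6.0

    def test_degenerate_identical_points(self):
        pts = np.zeros((10, 2))
        with pytest.raises(ValueError, match="identical"):
            choose_eps_elbow(pts, min_pts=3)


class TestSeparationScore:
    def test_point_masses(self):
        pts = np.array([[0.0, 0.0]] * 5 + [[7.0, 0.0]] * 5)
        labels = np.array([0] * 5 + [1] * 5)
        assert separation_score(pts, labels) > 100

    def test_true_labels_beat_random(self):
        rng = np.random.default_rng(2)
        pts = np.vstack(
            [rng.normal(0, 1, (30, 2)), rng.normal(12, 1, (30, 2))]
        )
        true = np.array([0] * 30 + [1] * 30)
        random = rng.permutation(true)
        assert separation_score(pts, true) > separation_score(pts, random)

    def test_isometry_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 1, size=(20, 2))
        labels = np.array([0] * 10 + [1] * 10)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + np.array([5.0, -3.0])
        assert separation_score(pts, labels) == pytest.approx(
            separation_score(moved, labels), rel=1e-9
        )

    def test_single_cluster_signalled(self):
        pts = np.zeros((4, 2))
        with pytest.raises(ValueError, match="2 clusters"):
            separation_score(pts, np.zeros(4, dtype=int))


class TestAlignLabels:
    def test_swapped_names_recovered(self):
        ref = np.array([0, 0, 1, 1, 2, 2])
        swapped = np.array([2, 2, 0, 0, 1, 1])
        np.testing.assert_array_equal(align_labels(ref, swapped), ref)

    def test_contingency_example_matches_enumeration(self):
        # Contingency [[10,0,1],[0,9,0],[2,0,8]]: best mapping is diagonal
        # with overlap 27 -- verified by enumerating all 6 permutations.
        table = np.array([[10, 0, 1], [0, 9, 0], [2, 0, 8]])
        ref, lab = [], []
        for i in range(3):
            for j in range(3):
                ref += [j] * table[i, j]
                lab += [i] * table[i, j]
        ref, lab = np.array(ref), np.array(lab)
        best = max(
            itertools.permutations(range(3)),
            key=lambda perm: sum(table[i, perm[i]] for i in range(3)),
        )
        assert best == (0, 1, 2)
        assert sum(table[i, best[i]] for i in range(3)) == 27
        aligned = align_labels(ref, lab)
        overlap = int((aligned == ref).sum())
        assert overlap == 27

    def test_extra_cluster_gets_fresh_id(self):
        ref = np.array([0, 0, 1, 1, NOISE, NOISE])
        lab = np.array([0, 0, 1, 1, 2, 2])
        aligned = align_labels(ref, lab)
        assert set(aligned[:4]) == {0, 1}
        assert aligned[4] == aligned[5] == 2

    def test_invariant_to_input_relabelling(self):
        rng = np.random.default_rng(4)
        ref = rng.integers(0, 3, size=30)
        lab = rng.integers(0, 3, size=30)
        relabelled = np.select([lab == 0, lab == 1, lab == 2], [7, 5, 9])
        np.testing.assert_array_equal(
            align_labels(ref, lab), align_labels(ref, relabelled)
        )

    def test_noise_passes_through(self):
        ref = np.array([0, 0, 1, 1])
        lab = np.array([1, NOISE, 0, 0])
        aligned = align_labels(ref, lab)
        assert aligned[1] == NOISE


class TestPluralityVote:
    def test_seven_of_ten_inclusive_threshold(self):
        col = np.array([0] * 7 + [1] * 3)
        labels = np.tile(col[:, None], (1, 1))
        assignments, support = _plurality_vote(
            labels, pd.Index(["s"]), threshold=0.70, strict=False
        )
        assert assignments["s"] == "group1"
        assert support["s"] == pytest.approx(0.7)

    def test_sixtynine_percent_ambiguous(self):
        col = np.array([0] * 69 + [1] * 31)
        labels = col[:, None]
        assignments, support = _plurality_vote(
            labels, pd.Index(["s"]), threshold=0.70, strict=False
        )
        assert assignments["s"] == AMBIGUOUS
        assert support["s"] == pytest.approx(0.69)

    def test_noise_excluded_from_denominator_by_default(self):
        col = np.array([0] * 7 + [NOISE] * 3)
        assignments, support = _plurality_vote(
            col[:, None], pd.Index(["s"]), threshold=0.70, strict=False
        )
        assert assignments["s"] == "group1"
        assert support["s"] == 1.0

    def test_strict_denominator_counts_noise(self):
        col = np.array([0] * 7 + [NOISE] * 3)
        assignments, support = _plurality_vote(
            col[:, None], pd.Index(["s"]), threshold=0.75, strict=True
        )
        assert assignments["s"] == AMBIGUOUS
        assert support["s"] == pytest.approx(0.7)

    def test_unanimity(self):
        labels = np.zeros((10, 3), dtype=int)
        assignments, support = _plurality_vote(
            labels, pd.Index(["a", "b", "c"]), threshold=0.70, strict=False
        )
        assert (assignments == "group1").all()
        assert (support == 1.0).all()


class TestRunEnsemble:
    def test_consensus_contract(self, small_consensus):
        res = small_consensus
        assigned = res.assignments != AMBIGUOUS
        assert ((res.support >= 0) & (res.support <= 1)).all()
        assert (res.support[assigned] >= res.threshold).all()
        cc = res.coclustering.values
        np.testing.assert_allclose(cc, cc.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(cc), 1.0)

    def test_determinism(self, adjusted_discovery):
        adjusted, _ = adjusted_discovery
        cfg = EnsembleConfig(n_iterations=6, seed=42)
        a = ens.run_ensemble(adjusted, config=cfg)
        b = ens.run_ensemble(adjusted, config=cfg)
        pd.testing.assert_series_equal(a.assignments, b.assignments)
        pd.testing.assert_series_equal(a.support, b.support)
        pd.testing.assert_frame_equal(a.iteration_labels, b.iteration_labels)

    def test_gene_count_too_large_rejected(self, toy_expression):
        with pytest.raises(ValueError, match="gene_count"):
            ens.run_ensemble(
                toy_expression, UmapParams(n_neighbors=2, gene_count=100)
            )

    def test_surrogate_recovery(self, small_consensus, discovery_bundle):
        report = concordance(small_consensus, discovery_bundle.phenotype)
        assert report.accuracy >= 0.95
        assert report.ambiguous_rate <= 0.05


class TestConcordance:
    @staticmethod
    def _result_from(assignments: pd.Series) -> ens.ConsensusResult:
        n = len(assignments)
        return ens.ConsensusResult(
            assignments=assignments,
            support=pd.Series(1.0, index=assignments.index),
            iteration_labels=pd.DataFrame(
                np.zeros((1, n), dtype=int), columns=assignments.index
            ),
            coclustering=pd.DataFrame(
                np.eye(n), index=assignments.index, columns=assignments.index
            ),
            threshold=0.7,
        )

    @staticmethod
    def _pheno(histology: list[str], index) -> PhenotypeTable:
        return PhenotypeTable(
            pd.DataFrame(
                {"histology": histology, "batch": ["b1"] * len(histology)},
                index=index,
            )
        )

    def test_perfect_split(self):
        idx = pd.Index([f"s{i}" for i in range(89)])
        assignments = pd.Series(["group1"] * 53 + ["group2"] * 36, index=idx)
        pheno = self._pheno(["chRCC"] * 53 + ["RO"] * 36, idx)
        report = concordance(self._result_from(assignments), pheno)
        assert report.accuracy == 1.0
        assert report.ambiguous_rate == 0.0

    def test_87_of_89(self):
        idx = pd.Index([f"s{i}" for i in range(89)])
        # 2 chRCC samples land in the RO-dominated group.
        assignments = pd.Series(
            ["group1"] * 51 + ["group2"] * 2 + ["group2"] * 36, index=idx
        )
        pheno = self._pheno(["chRCC"] * 53 + ["RO"] * 36, idx)
        report = concordance(self._result_from(assignments), pheno)
        assert report.accuracy == pytest.approx(87 / 89, abs=1e-9)
        assert round(report.accuracy, 4) == 0.9775

    def test_group_id_swap_invariance(self):
        idx = pd.Index([f"s{i}" for i in range(20)])
        assignments = pd.Series(["group1"] * 12 + ["group2"] * 8, index=idx)
        swapped = assignments.map({"group1": "group2", "group2": "group1"})
        pheno = self._pheno(["chRCC"] * 12 + ["RO"] * 8, idx)
        a = concordance(self._result_from(assignments), pheno)
        b = concordance(self._result_from(swapped), pheno)
        assert a.accuracy == b.accuracy

    def test_normals_excluded(self):
        idx = pd.Index([f"s{i}" for i in range(10)])
        assignments = pd.Series(["group1"] * 5 + ["group2"] * 5, index=idx)
        pheno = self._pheno(["chRCC"] * 5 + ["RO"] * 3 + ["N"] * 2, idx)
        report = concordance(self._result_from(assignments), pheno)
        assert int(report.confusion.values.sum()) == 8


class TestHierarchicalCluster:
    def test_duplicated_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        base = rng.normal(8, 1, size=10)
        data = pd.DataFrame(
            {"s1": base, "s2": base, "s3": base + rng.normal(0, 2, 10)},
            index=[f"g{i}" for i in range(10)],
        )
        Z, _ = hierarchical_cluster(ExpressionTable(data))
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_constant_sample_rejected(self):
        data = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0], "s2": [5.0, 5.0, 5.0]},
            index=["g1", "g2", "g3"],
        )
        with pytest.raises(ValueError, match="s2"):
            hierarchical_cluster(ExpressionTable(data))

    def test_sample_order_invariance(self):
        expr = make_blob_expr(n_per_class=10, seed=6)
        Z1, labels1 = hierarchical_cluster(expr)
        perm = np.random.default_rng(0).permutation(expr.shape[1])
        shuffled = ExpressionTable(expr.data.iloc[:, perm])
        _, labels2 = hierarchical_cluster(shuffled)
        assert partitions_equal(
            labels1.loc[shuffled.samples].values - 1, labels2.values - 1
        )

    def test_two_cut_recovers_planted_classes(self):
        expr = make_blob_expr(n_per_class=20, sep=6.0, seed=7)
        _, labels = hierarchical_cluster(expr)
        truth = np.array([0] * 20 + [1] * 20)
        agreement = max(
            (labels.values - 1 == truth).mean(),
            (labels.values - 1 == 1 - truth).mean(),
        )
        assert agreement >= 0.95


class TestGridSearch:
    def test_product_count_and_argmax(self, adjusted_discovery):
        adjusted, _ = adjusted_discovery
        best, table = ens.grid_search(
            adjusted,
            gene_counts=[100, 400],
            n_neighbors_grid=[10, 20],
            min_dist_grid=[0.01],
            metrics=["manhattan", "euclidean"],
            seed=5,
        )
        assert len(table) == 2 * 2 * 1 * 2
        valid = table["score"].dropna()
        assert valid.iloc[0] == valid.max()
        assert best.gene_count in (100, 400)

    def test_empty_grid_rejected(self, adjusted_discovery):
        with pytest.raises(ValueError, match="non-empty"):
            ens.grid_search(adjusted_discovery[0], [], [10], [0.1], ["euclidean"])
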