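"""Clustering, the five validation indices, network metrics, hub genes."""

import numpy as np
import pandas as pd
import pytest

from apacca import (
    SimulationConfig,
    ValidationError,
    ad_adm,
    bhi,
    connectivity,
    dunn_index,
    estimate_k,
    hierarchical_cluster,
    module_eigengene_hubs,
    network_metrics,
    normalize_scores,
    planted_cluster_dataset,
    weight_matrix,
)


def blob_distance(sizes, within=0.1, between=0.9):
    """Block distance matrix with well separated blobs."""
    G = sum(sizes)
    d = np.full((G, G), between)
    start = 0
    for s in sizes:
        d[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------- brute force
def brute_connectivity(dist, labels, L):
    G = len(labels)
    total = 0.0
    for i in range(G):
        order = sorted((dist[i, j], j) for j in range(G) if j != i)
        for rank, (_, j) in enumerate(order[:L], start=1):
            if labels[j] != labels[i]:
                total += 1.0 / rank
    return total


def brute_dunn(dist, labels):
    cl = sorted(set(labels))
    diam = max(
        dist[i, j]
        for c in cl
        for i in range(len(labels))
        for j in range(len(labels))
        if labels[i] == c and labels[j] == c
    )
    sep = min(
        dist[i, j]
        for i in range(len(labels))
        for j in range(len(labels))
        if labels[i] != labels[j]
    )
    return sep / diam


class TestHierarchicalCluster:
    def test_forced_separation(self):
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        res = hierarchical_cluster(d, [2])
        labels = res.assignments[2]
        assert labels[0] == labels[1] != labels[2]

    def test_extreme_cuts(self):
        d = blob_distance([2, 2])
        res = hierarchical_cluster(d, [1, 4])
        assert len(set(res.assignments[1])) == 1
        assert len(set(res.assignments[4])) == 4

    def test_k_beyond_size_rejected(self):
        with pytest.raises(ValidationError):
            hierarchical_cluster(blob_distance([2, 2]), [5])


class TestEstimateK:
    def test_two_blobs(self):
        assert estimate_k(blob_distance([5, 5]), range(2, 6)) == 2

    def test_three_blobs(self):
        assert estimate_k(blob_distance([5, 5, 5]), range(2, 8)) == 3

    def test_tie_returns_smallest_k(self):
        d = np.full((6, 6), 0.5)
        np.fill_diagonal(d, 0.0)
        assert estimate_k(d, range(2, 5)) == 2


class TestConnectivity:
    def test_perfect_clustering_scores_zero(self):
        d = blob_distance([3, 3])
        labels = [0, 0, 0, 1, 1, 1]
        assert connectivity(d, labels, L=2) == 0.0

    def test_hand_example(self):
        # 4 points, neighbour lists (2,3),(1,3),(4,2),(3,2), clusters {1,2},{3,4}
        d = np.array(
            [
                [0.0, 1.0, 2.0, 9.0],
                [1.0, 0.0, 3.0, 9.0],
                [2.0, 3.0, 0.0, 1.5],
                [9.0, 9.0, 1.5, 0.0],
            ]
        )
        # neighbours: 1->(2,3); 2->(1,3); 3->(4,1) ... adjust to spec lists
        d[2, 0] = d[0, 2] = 3.5  # 3's neighbours become (4,2)
        d[3, 1] = d[1, 3] = 4.0  # 4's neighbours become (3,2)
        labels = [0, 0, 1, 1]
        assert connectivity(d, labels, L=2) == pytest.approx(2.0)

    def test_worst_case_value(self):
        # every point's L neighbours in other clusters: per point 1 + 1/2
        d = blob_distance([1, 1, 1, 1], between=1.0)
        labels = [0, 1, 2, 3]
        assert connectivity(d, labels, L=2) == pytest.approx(4 * 1.5)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            G = int(rng.integers(6, 25))
            d = rng.uniform(0.01, 1, (G, G))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            labels = rng.integers(0, 3, G)
            L = int(rng.integers(1, G - 1))
            assert connectivity(d, labels, L) == pytest.approx(
                brute_connectivity(d, labels, L), abs=1e-10
            )


class TestDunn:
    def test_hand_example(self):
        d = np.array(
            [
                [0, 1, 4, 4],
                [1, 0, 4, 4],
                [4, 4, 0, 2],
                [4, 4, 2, 0],
            ],
            dtype=float,
        )
        assert dunn_index(d, [0, 0, 1, 1]) == pytest.approx(2.0)

    def test_overlapping_clusters_below_one(self):
        d = blob_distance([3, 3], within=0.8, between=0.5)
        assert dunn_index(d, [0, 0, 0, 1, 1, 1]) < 1.0

    def test_scale_invariance(self, rng):
        G = 12
        d = rng.uniform(0.1, 1, (G, G))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        labels = rng.integers(0, 3, G)
        assert dunn_index(3.7 * d, labels) == pytest.approx(dunn_index(d, labels))

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            G = int(rng.integers(6, 25))
            d = rng.uniform(0.01, 1, (G, G))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            labels = rng.integers(0, 3, G)
            assert dunn_index(d, labels) == pytest.approx(
                brute_dunn(d, labels), abs=1e-10
            )

    def test_singletons_only_rejected(self):
        d = blob_distance([1, 1, 1])
        with pytest.raises(ValidationError):
            dunn_index(d, [0, 1, 2])


@pytest.fixture(scope="module")
def planted_small():
    cfg = SimulationConfig(
        n_experiments=8,
        replicates=3,
        seed=7,
        n_clusters=3,
        genes_per_cluster=5,
        effect=0.15,
        n_sites=3,
    )
    return planted_cluster_dataset(cfg)


class TestStability:
    def test_requires_three_experiments(self, planted_small):
        data, _ = planted_small
        two = data
        for e in ("E1", "E2", "E3", "E4", "E5", "E6"):
            two = two.drop_experiment(e)
        with pytest.raises(ValidationError):
            ad_adm(two, k=2)

    def test_matches_brute_force(self, planted_small):
        data, _ = planted_small
        from apacca.cluster import hierarchical_cluster as hc
        from apacca.similarity import to_distance

        k = 3
        ad, adm = ad_adm(data, k=k)

        # independent naive recomputation
        sim = weight_matrix(data)
        dist = to_distance(sim)
        full = hc(dist, [k]).assignments[k]
        genes, profiles = data.gene_totals()
        G = len(genes)
        ad_terms, adm_terms = [], []
        for exp in data.design.experiments:
            red = data.drop_experiment(exp)
            red_lab = hc(to_distance(weight_matrix(red)), [k]).assignments[k]
            for i in range(G):
                mates = [j for j in range(G) if j != i and red_lab[j] == red_lab[i]]
                if mates:
                    ad_terms.append(np.mean([dist[i, j] for j in mates]))
                c_full = profiles[full == full[i]].mean(axis=0)
                c_red = profiles[red_lab == red_lab[i]].mean(axis=0)
                adm_terms.append(np.linalg.norm(c_full - c_red))
        assert ad == pytest.approx(np.mean(ad_terms), abs=1e-10)
        assert adm == pytest.approx(np.mean(adm_terms), abs=1e-10)
        assert 0 <= ad <= 1.0  # distances are 1 - w in [0, 1]

    def test_stable_clustering_gives_zero_adm(self, planted_small):
        # strong planted structure: every leave-one-experiment-out clustering
        # matches the full clustering, so cluster centres never move
        data, truth = planted_small
        ad, adm = ad_adm(data, k=3)
        assert adm == pytest.approx(0.0, abs=1e-12)


class TestBHI:
    def test_shared_class_everywhere(self):
        ann = {g: {"X"} for g in "abcd"}
        assert bhi({"a": 1, "b": 1, "c": 2, "d": 2}, ann) == 1.0

    def test_no_shared_classes(self):
        ann = {"a": {"X"}, "b": {"Y"}, "c": {"Z"}}
        assert bhi({"a": 1, "b": 1, "c": 1}, ann) == 0.0

    def test_enumerated_fraction(self):
        ann = {"a": {"A"}, "b": {"A"}, "c": {"B"}}
        assert bhi({"a": 1, "b": 1, "c": 1}, ann) == pytest.approx(1 / 3)

    def test_small_clusters_skipped(self):
        ann = {"a": {"A"}, "b": {"A"}, "c": {"B"}}
        # cluster 2 has one annotated gene -> ignored
        assert bhi({"a": 1, "b": 1, "c": 2}, ann) == 1.0

    def test_no_eligible_cluster_rejected(self):
        with pytest.raises(ValidationError):
            bhi({"a": 1, "b": 2}, {"a": {"A"}, "b": {"A"}})


class TestNormalizeScores:
    def test_higher_better_and_flip(self):
        raw = pd.DataFrame({"DUNN": [2, 4, 6], "CON": [2, 4, 6]})
        out = normalize_scores(raw)
        np.testing.assert_allclose(out["DUNN"], [0, 0.5, 1])
        np.testing.assert_allclose(out["CON"], [1, 0.5, 0])

    def test_constant_metric_maps_to_half(self):
        out = normalize_scores(pd.DataFrame({"AD": [3, 3, 3]}))
        np.testing.assert_allclose(out["AD"], 0.5)


class TestNetworkMetrics:
    def test_triangle_clustering_one(self):
        W = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        ec, acc, _ = network_metrics(["a", "b", "c"], W, {"a": 0, "b": 0, "c": 0}, tau=0.5)
        assert acc == 1.0
        assert ec == pytest.approx(1.0)  # symmetric: all centralities equal

    def test_star_clustering_zero(self):
        W = np.zeros((4, 4))
        W[0, 1:] = W[1:, 0] = 1.0
        _, acc, _ = network_metrics(list("abcd"), W, dict.fromkeys("abcd", 0), tau=0.5)
        assert acc == 0.0

    def test_two_cliques_modularity_half(self):
        W = np.zeros((6, 6))
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    if i != j:
                        W[i, j] = 1.0
        genes = list("abcdef")
        modules = {g: (0 if i < 3 else 1) for i, g in enumerate(genes)}
        _, _, md = network_metrics(genes, W, modules, tau=0.5)
        assert md == pytest.approx(0.5)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            network_metrics(["a", "b"], np.zeros((2, 2)), {"a": 0, "b": 0})


class TestEigengeneHubs:
    def test_identical_profiles_all_hubs(self, rng):
        prof = np.tile(rng.normal(size=8), (5, 1))
        expr = pd.DataFrame(prof, index=[f"g{i}" for i in range(5)])
        hubs = module_eigengene_hubs(expr, {f"g{i}": 0 for i in range(5)})
        assert sorted(hubs[0]) == [f"g{i}" for i in range(5)]

    def test_anticorrelated_gene_not_hub(self, rng):
        base = rng.normal(size=10)
        rows = [base + rng.normal(0, 0.05, 10) for _ in range(4)] + [-base]
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(5)])
        hubs = module_eigengene_hubs(expr, {f"g{i}": 0 for i in range(5)})
        assert "g4" not in hubs[0]

    def test_planted_factor_recovery(self):
        rng = np.random.default_rng(42)
        factor = rng.normal(size=12)
        loading = 0.95
        rows = [
            loading * factor + np.sqrt(1 - loading**2) * rng.normal(size=12)
            for _ in range(20)
        ]
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(20)])
        hubs = module_eigengene_hubs(expr, {f"g{i}": 0 for i in range(20)}, threshold=0.7)
        assert len(hubs[0]) >= 18

    def test_singleton_module_skipped_with_warning(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 6)), index=["a", "b", "c"])
        with pytest.warns(UserWarning):
            hubs = module_eigengene_hubs(expr, {"a": 0, "b": 0, "c": 1})
        assert 1 not in hubs
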