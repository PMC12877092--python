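import itertools

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import spearmanr

from mbstage import (
    DisconnectedLineageError,
    ParameterError,
    io_core,
    lineage,
    synthetic_data,
)
from mbstage.lineage import (
    ClusterGraph,
    HVGSelection,
    bin_profiles,
    build_knn_graph,
    cluster_connectivity,
    pc1_pseudotime,
    prune_and_path,
    select_hvg,
)


class TestBuildKnnGraph:
    def test_two_points_one_edge(self):
        g = build_knn_graph(np.array([[0.0], [1.0]]), k=1)
        assert set(g.edges()) == {(0, 1)}

    def test_three_collinear_middle_connects_both(self):
        g = build_knn_graph(np.array([[0.0], [1.0], [2.0]]), k=1)
        assert g.has_edge(0, 1) and g.has_edge(1, 2)

    def test_k_too_large(self):
        with pytest.raises(ParameterError):
            build_knn_graph(np.zeros((3, 2)), k=3)

    def test_matches_bruteforce_on_random_cloud(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 3))
        k = 5
        g = build_knn_graph(X, k=k)
        d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        oracle = set()
        for i in range(100):
            for j in np.argsort(d[i], kind="stable")[:k]:
                oracle.add(tuple(sorted((i, int(j)))))
        assert {tuple(sorted(e)) for e in g.edges()} == oracle


class TestClusterConnectivity:
    def test_no_inter_edges_zero_weight(self):
        g = nx.Graph([(0, 1), (2, 3)])
        cg = cluster_connectivity(g, ["a", "a", "b", "b"])
        assert cg.edges == {}

    def test_fully_bipartite_two_plus_two(self):
        g = nx.Graph([(0, 2), (0, 3), (1, 2), (1, 3)])
        cg = cluster_connectivity(g, ["a", "a", "b", "b"])
        assert cg.edges[("a", "b")] == pytest.approx(1.0)  # 4 / min(4, 4)

    def test_invariant_to_label_renaming(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 3), (0, 3)])
        w1 = cluster_connectivity(g, ["a", "a", "b", "b"]).edges[("a", "b")]
        w2 = cluster_connectivity(g, ["x", "x", "y", "y"]).edges[("x", "y")]
        assert w1 == w2


class TestPruneAndPath:
    def test_prune_boundary_strict(self):
        cg = ClusterGraph(
            clusters={"a": 1, "b": 1, "c": 1},
            edges={("a", "b"): 0.05, ("b", "c"): 0.049},
        )
        g = cg.pruned()
        assert g.has_edge("a", "b") and not g.has_edge("b", "c")

    def test_root_equals_endpoint(self):
        cg = ClusterGraph(clusters={"a": 1, "b": 1}, edges={("a", "b"): 0.5})
        assert prune_and_path(cg, "a", "a").clusters == ["a"]

    def test_disconnected_error_names_components(self):
        cg = ClusterGraph(
            clusters={"a": 1, "b": 1, "c": 1},
            edges={("a", "b"): 0.5, ("b", "c"): 0.01},
        )
        with pytest.raises(DisconnectedLineageError) as exc:
            prune_and_path(cg, "a", "c")
        assert ["c"] in exc.value.components

    def test_waypoint_forces_route_and_collapses_duplicates(self):
        cg = ClusterGraph(
            clusters={c: 1 for c in "abcd"},
            edges={("a", "b"): 0.5, ("b", "d"): 0.5, ("a", "c"): 0.5, ("c", "d"): 0.5},
        )
        lp = prune_and_path(cg, "a", "d", waypoint="c")
        assert lp.clusters == ["a", "c", "d"]
        # waypoint behind the root: path backtracks and the loop collapses
        cg2 = ClusterGraph(
            clusters={c: 1 for c in "abc"},
            edges={("a", "b"): 0.5, ("b", "c"): 0.5},
        )
        lp2 = prune_and_path(cg2, "b", "c", waypoint="a")
        assert lp2.clusters == ["b", "c"]  # backtracking loop through a collapses

    @staticmethod
    def oracle_path(cg, root, endpoint):
        g = cg.pruned()
        if not nx.has_path(g, root, endpoint):
            return None
        best = None
        for path in nx.all_simple_paths(g, root, endpoint):
            key = (
                len(path),
                -min(g[a][b]["weight"] for a, b in zip(path[:-1], path[1:])),
                tuple(path),
            )
            if best is None or key < best[0]:
                best = (key, path)
        if root == endpoint:
            return [root]
        return best[1]

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        trials = 0
        while n_checked < 300 and trials < 2000:
            trials += 1
            n = int(rng.integers(4, 10))
            names = [f"c{i}" for i in range(n)]
            edges = {}
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.45:
                    edges[(names[i], names[j])] = float(np.round(rng.random(), 3))
            cg = ClusterGraph(clusters={c: 1 for c in names}, edges=edges)
            root, endpoint = rng.choice(names, 2, replace=False)
            expected = self.oracle_path(cg, root, endpoint)
            if expected is None:
                with pytest.raises(DisconnectedLineageError):
                    prune_and_path(cg, root, endpoint)
            else:
                assert prune_and_path(cg, root, endpoint).clusters == expected
            n_checked += 1
        assert n_checked == 300


class TestSelectHVG:
    def test_injected_set_algebra(self):
        sel = HVGSelection(
            per_replicate={
                ("t1", "r1"): ["a", "b", "c"],
                ("t1", "r2"): ["b", "c", "d"],
                ("t2", "r1"): ["c", "e"],
            }
        )
        assert sel.per_timepoint["t1"] == {"b", "c"}
        assert sel.per_timepoint["t2"] == {"c", "e"}
        assert sel.final == ["b", "c", "e"]

    def test_disjoint_replicates_contribute_nothing(self):
        sel = HVGSelection(per_replicate={("t1", "r1"): ["a"], ("t1", "r2"): ["b"]})
        assert sel.final == []

    def test_single_timepoint_single_replicate(self):
        sel = HVGSelection(per_replicate={("t1", "r1"): ["x", "y"]})
        assert sel.final == ["x", "y"]

    def test_monotone_under_added_timepoint(self):
        base = {("t1", "r1"): ["a", "b"], ("t1", "r2"): ["b", "c"]}
        s1 = HVGSelection(per_replicate=dict(base))
        base[("t2", "r1")] = ["z"]
        s2 = HVGSelection(per_replicate=base)
        assert set(s1.final) <= set(s2.final)

    def test_on_synthetic_data(self, sc_dataset):
        cfg, cm, meta, gt = sc_dataset
        sel = select_hvg(cm, meta, n_hvg=30)
        assert len(sel.per_replicate) == len(cfg.sc_timepoints) * len(cfg.sc_replicates)
        assert all(len(v) == 30 for v in sel.per_replicate.values())
        assert set(sel.final) == set().union(*sel.per_timepoint.values())

    def test_n_hvg_larger_than_gene_count_warns(self, sc_dataset, caplog):
        import logging

        cfg, cm, meta, gt = sc_dataset
        with caplog.at_level(logging.WARNING, logger="mbstage.lineage"):
            ranked = lineage.hvg_rank(cm, np.ones(len(cm.entities), bool), n_hvg=10_000)
        assert len(ranked) == len(cm.genes)


class TestPC1Pseudotime:
    def gradient_matrix(self, n=30):
        t = np.linspace(0, 1, n)
        X = np.c_[t * 2, 1 - t, t * 0.5] + 3.0
        cm = io_core.CountMatrix(
            entities=[f"c{i}" for i in range(n)],
            genes=["g0", "g1", "g2"],
            counts=sp.csr_matrix(np.ones((n, 3), int)),
        )
        cm.layers["lognorm"] = sp.csr_matrix(X)
        types = np.where(t < 0.5, "root", "tip")
        return cm, types, t

    def test_gradient_recovered_perfectly(self):
        cm, types, t = self.gradient_matrix()
        pt, r2 = pc1_pseudotime(cm, ["g0", "g1", "g2"], types, "root")
        assert abs(spearmanr(pt, t).statistic) == pytest.approx(1.0)
        assert pt[types == "root"].mean() < pt[types == "tip"].mean()

    def test_sign_flip_of_input_leaves_pseudotime_unchanged(self):
        cm, types, t = self.gradient_matrix()
        pt1, _ = pc1_pseudotime(cm, ["g0", "g1", "g2"], types, "root")
        cm.layers["lognorm"] = sp.csr_matrix(-cm.dense_layer("lognorm"))
        pt2, _ = pc1_pseudotime(cm, ["g0", "g1", "g2"], types, "root")
        assert np.allclose(pt1, pt2, atol=1e-9)

    def test_separated_types_high_adjusted_r2(self):
        rng = np.random.default_rng(1)
        n = 40
        X = np.r_[rng.normal(0, 0.01, (n // 2, 3)), rng.normal(5, 0.01, (n // 2, 3))]
        cm = io_core.CountMatrix(
            entities=[f"c{i}" for i in range(n)],
            genes=["g0", "g1", "g2"],
            counts=sp.csr_matrix(np.ones((n, 3), int)),
        )
        cm.layers["lognorm"] = sp.csr_matrix(X)
        types = ["root"] * (n // 2) + ["tip"] * (n // 2)
        pt, r2 = pc1_pseudotime(cm, ["g0", "g1", "g2"], np.array(types), "root")
        assert r2 >= 0.99

    @pytest.mark.parametrize("seed", range(5))
    def test_recovery_on_synthetic_lineage(self, seed):
        cfg = synthetic_data.SyntheticConfig(seed=seed, n_genes=120, n_cells=1000)
        cm, meta, gt = synthetic_data.generate_single_cell_dataset(cfg)
        io_core.lognormalize(cm)
        hvg = select_hvg(cm, meta, n_hvg=60)
        pt, r2 = pc1_pseudotime(cm, hvg, meta["cell_type"], root_type="progenitor")
        assert abs(spearmanr(pt, gt.pseudotime).statistic) >= 0.9


class TestBinProfiles:
    def make_cm(self, values):
        values = np.asarray(values, dtype=float).reshape(-1, 1)
        cm = io_core.CountMatrix(
            entities=[f"c{i}" for i in range(len(values))],
            genes=["g"],
            counts=sp.csr_matrix(np.ones(values.shape, int)),
        )
        cm.layers["lognorm"] = sp.csr_matrix(values)
        return cm

    def test_uniform_pseudotime_equal_width_edges(self):
        pt = np.linspace(0, 1, 101)
        cm = self.make_cm(np.zeros(101) + 1.0)
        # constant gene: no call, but edges partition the trimmed range evenly
        profs = bin_profiles(pt, cm, ["g"], trim=(0, 100), n_perm=99)
        assert np.allclose(np.diff(profs[0].bin_edges), 0.2)

    def test_strictly_increasing_gene_called_up(self):
        n = 100
        pt = np.linspace(0, 1, n)
        vals = pt * 6.0  # logFC between last and first bin well above 2
        profs = bin_profiles(pt, cm := self.make_cm(vals), ["g"], n_perm=9999, seed=0)
        means = profs[0].bin_means
        assert np.all(np.diff(means) >= 0)
        assert profs[0].start_end_call == "up"

    def test_hand_computed_bin_means(self):
        pt = np.array([0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95])
        vals = np.arange(10.0)
        profs = bin_profiles(pt, self.make_cm(vals), ["g"], trim=(0, 100), n_perm=99)
        assert np.allclose(profs[0].bin_means, [0.5, 2.5, 4.5, 6.5, 8.5])

    def test_trimming_drops_extreme_percentiles(self):
        pt = np.concatenate([[0.0], np.linspace(0.4, 0.6, 98), [1.0]])
        vals = np.zeros(100)
        vals[0] = vals[-1] = 100.0
        profs = bin_profiles(pt, self.make_cm(vals), ["g"], n_perm=99)
        assert np.nanmax(profs[0].bin_means) == 0.0  # extremes trimmed away

    def test_bin_means_within_value_range(self, sc_dataset):
        cfg, cm, meta, gt = sc_dataset
        gene = cfg.module_spec[0].genes[0]
        profs = bin_profiles(gt.pseudotime, cm, [gene], n_perm=99)
        v = cm.dense_layer("lognorm")[:, cm.genes.index(gene)]
        means = profs[0].bin_means
        assert np.nanmin(means) >= v.min() and np.nanmax(means) <= v.max()
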