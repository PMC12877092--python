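import numpy as np
import pytest

from mbstage import (
    DegenerateInputError,
    GeometryError,
    ParameterError,
    io_core,
    niche_similarity as ns,
    synthetic_data,
)
from mbstage.io_core import SampleMeta, SpotGrid


def make_abundance(values, types=None):
    values = np.asarray(values, dtype=float)
    types = types or [f"t{k}" for k in range(values.shape[1])]
    return ns.AbundanceMatrix(
        spots=[f"s{i}" for i in range(values.shape[0])], types=types, values=values
    )


def brute_force_pairs(grid, labeling):
    label_of = dict(zip(labeling.spots, labeling.labels))
    counts = {}
    for a, b in grid.adjacency:
        la, lb = label_of[a], label_of[b]
        if ns.UNASSIGNED in (la, lb):
            continue
        key = tuple(sorted((la, lb)))
        counts[key] = counts.get(key, 0) + 1
    return counts


def profile_dict(profile):
    iu = np.triu_indices(len(profile.types))
    return {
        tuple(sorted((profile.types[i], profile.types[j]))): int(profile.pair_counts[i, j])
        for i, j in zip(*iu)
        if profile.pair_counts[i, j] > 0
    }


class TestLabelSpots:
    def test_unique_argmax(self):
        lab = ns.label_spots(make_abundance([[0.7, 0.2, 0.1]]))
        assert lab.labels == ["t0"] and not lab.tie_flags[0]

    def test_tie_broken_by_declared_order_and_flagged(self):
        lab = ns.label_spots(make_abundance([[0.5, 0.5, 0.0]]))
        assert lab.labels == ["t0"] and lab.tie_flags[0]

    def test_all_zero_row_unassigned(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="mbstage.niche_similarity"):
            lab = ns.label_spots(make_abundance([[0.0, 0.0], [1.0, 0.0]]))
        assert lab.labels[0] == ns.UNASSIGNED

    def test_matches_bruteforce_rowwise_argmax(self):
        rng = np.random.default_rng(0)
        vals = rng.random((50, 4))
        lab = ns.label_spots(make_abundance(vals))
        expected = [f"t{int(np.argmax(r))}" for r in vals]
        assert lab.labels == expected


class TestBuildAdjacency:
    def test_two_spots_one_edge(self):
        grid = SpotGrid(["a", "b"], np.array([[0, 0], [0, 1]]), np.array([[0.0, 0.0], [1.0, 0.0]]))
        ns.build_adjacency(grid)
        assert grid.adjacency == {("a", "b")}

    def test_coincident_spots_error(self):
        grid = SpotGrid(["a", "b"], np.zeros((2, 2), int), np.zeros((2, 2)))
        with pytest.raises(GeometryError):
            ns.build_adjacency(grid)

    def test_jittered_lattice_matches_allpairs_oracle(self):
        rng = np.random.default_rng(2)
        arr, phys = synthetic_data.hex_disc(4)
        phys = phys + rng.normal(0.0, 0.02, phys.shape)  # jitter <= 2% of pitch
        spots = [f"s{i}" for i in range(len(phys))]
        grid = SpotGrid(spots, arr, phys)
        ns.build_adjacency(grid, scale_tolerance=1.05)
        d = np.linalg.norm(phys[:, None] - phys[None, :], axis=2)
        pitch = d[d > 0].min()
        oracle = {
            tuple(sorted((spots[i], spots[j])))
            for i in range(len(spots))
            for j in range(i + 1, len(spots))
            if d[i, j] <= 1.05 * pitch
        }
        assert grid.adjacency == oracle


class TestCountNeighborPairs:
    def chain_grid(self, labels):
        n = len(labels)
        spots = [f"s{i}" for i in range(n)]
        grid = SpotGrid(
            spots,
            np.array([[0, i] for i in range(n)]),
            np.array([[float(i), 0.0] for i in range(n)]),
            adjacency={(f"s{i}", f"s{i+1}") for i in range(n - 1)},
        )
        return grid, ns.SpotLabeling(spots, list(labels), np.zeros(n, bool))

    def test_chain_aba(self):
        grid, lab = self.chain_grid(["A", "B", "A"])
        p = ns.count_neighbor_pairs(grid, lab)
        assert profile_dict(p) == {("A", "B"): 2}
        assert p.freq.sum() == pytest.approx(1.0)

    def test_single_spot_zero_counts(self):
        grid, lab = self.chain_grid(["A"])
        p = ns.count_neighbor_pairs(grid, lab)
        assert p.n_edges == 0 and not p.freq.any()

    def test_homogeneous_labels(self):
        grid, lab = self.chain_grid(["A"] * 5)
        p = ns.count_neighbor_pairs(grid, lab)
        assert profile_dict(p) == {("A", "A"): 4}
        assert p.freq.tolist() == [1.0]

    def test_unassigned_edges_excluded_symmetrically(self):
        grid, lab = self.chain_grid(["A", ns.UNASSIGNED, "A"])
        p = ns.count_neighbor_pairs(grid, lab)
        assert p.n_edges == 0

    def test_edge_conservation_on_random_grids(self, hex_grid_r3):
        rng = np.random.default_rng(7)
        labels = rng.choice(["A", "B", "C", ns.UNASSIGNED], size=hex_grid_r3.n_spots, p=[0.4, 0.3, 0.2, 0.1])
        lab = ns.SpotLabeling(list(hex_grid_r3.spots), list(labels), np.zeros(hex_grid_r3.n_spots, bool))
        p = ns.count_neighbor_pairs(hex_grid_r3, lab)
        oracle = brute_force_pairs(hex_grid_r3, lab)
        assert profile_dict(p) == oracle
        excluded = len(hex_grid_r3.adjacency) - sum(oracle.values())
        assert p.n_edges == len(hex_grid_r3.adjacency) - excluded


class TestSampleSimilarity:
    def make_profile(self, counts, types):
        return ns.PairProfile(types=types, pair_counts=np.asarray(counts))

    def test_identical_profiles_warn_all_ones(self, caplog):
        import logging

        p = self.make_profile([[4, 1], [1, 2]], ["A", "B"])
        with caplog.at_level(logging.WARNING, logger="mbstage.niche_similarity"):
            sim = ns.sample_similarity([p, p], ["x", "y"])
        assert np.allclose(sim.S, 1.0) and np.allclose(sim.D, 0.0)

    def test_disjoint_single_pairs(self):
        pa = self.make_profile([[2, 0], [0, 0]], ["A", "B"])
        pb = self.make_profile([[0, 0], [0, 3]], ["A", "B"])
        sim = ns.sample_similarity([pa, pb], ["x", "y"])
        assert sim.D[0, 1] == pytest.approx(np.sqrt(2))
        assert sim.sim("x", "y") == pytest.approx(0.0)

    def test_three_sample_contract(self):
        pa = self.make_profile([[2, 0], [0, 0]], ["A", "B"])
        pb = self.make_profile([[0, 2], [2, 0]], ["A", "B"])
        pc = self.make_profile([[1, 1], [1, 1]], ["A", "B"])
        sim = ns.sample_similarity([pa, pb, pc], list("xyz"))
        S = sim.S
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(S, S.T) and np.allclose(np.diag(S), 1.0)
        assert S.min() >= 0 and S.max() <= 1 and S[off].min() == pytest.approx(0.0)

    def test_invariant_to_spot_and_type_permutation(self, hex_grid_r3):
        rng = np.random.default_rng(1)
        n = hex_grid_r3.n_spots
        vals_a, vals_b = rng.random((n, 3)), rng.random((n, 3))
        grids = [hex_grid_r3, hex_grid_r3]

        def build(vals_list, type_order, spot_perm):
            profs = []
            for vals in vals_list:
                v = vals[:, type_order][spot_perm]
                spots = [hex_grid_r3.spots[i] for i in spot_perm]
                ab = ns.AbundanceMatrix(spots=spots, types=[f"t{k}" for k in type_order], values=v)
                profs.append(ns.count_neighbor_pairs(hex_grid_r3, ns.label_spots(ab)))
            return ns.sample_similarity(profs, ["a", "b"]).S

        base = build([vals_a, vals_b], [0, 1, 2], np.arange(n))
        perm_spots = build([vals_a, vals_b], [0, 1, 2], rng.permutation(n))
        perm_types = build([vals_a, vals_b], [2, 0, 1], np.arange(n))
        assert np.allclose(base, perm_spots) and np.allclose(base, perm_types)


class TestTemporalAlignment:
    def make_sim(self, ids, S):
        S = np.asarray(S, dtype=float)
        return ns.SimilarityMatrix(sample_ids=ids, S=S, D=1 - S)

    def metas(self):
        return [
            SampleMeta("t7", "tissue", 7.0),
            SampleMeta("t11", "tissue", 11.0),
            SampleMeta("t17", "tissue", 17.0),
        ]

    def test_full_similarity_to_one_timepoint(self):
        sim = self.make_sim(
            ["q", "t7", "t11", "t17"],
            [[1, 0, 1, 0], [0, 1, 0, 0], [1, 0, 1, 0], [0, 0, 0, 1]],
        )
        ta = ns.temporal_alignment(sim, "q", self.metas())
        assert ta.estimated_timepoint == pytest.approx(11.0)

    def test_equal_similarity_midpoint(self):
        sim = self.make_sim(
            ["q", "t7", "t17"], [[1, 0.5, 0.5], [0.5, 1, 0], [0.5, 0, 1]]
        )
        ta = ns.temporal_alignment(sim, "q", [self.metas()[0], self.metas()[2]])
        assert ta.estimated_timepoint == pytest.approx(12.0)

    def test_weighted_mean(self):
        sim = self.make_sim(
            ["q", "t7", "t11", "t17"],
            [[1, 0.2, 0.3, 0.5], [0.2, 1, 0, 0], [0.3, 0, 1, 0], [0.5, 0, 0, 1]],
        )
        ta = ns.temporal_alignment(sim, "q", self.metas())
        assert ta.estimated_timepoint == pytest.approx(0.2 * 7 + 0.3 * 11 + 0.5 * 17)
        assert ta.weights.sum() == pytest.approx(1.0)

    def test_replicates_averaged_at_similarity_level(self):
        metas = [
            SampleMeta("t11a", "tissue", 11.0, "r1"),
            SampleMeta("t11b", "tissue", 11.0, "r2"),
            SampleMeta("t17", "tissue", 17.0),
        ]
        sim = self.make_sim(
            ["q", "t11a", "t11b", "t17"],
            [[1, 0.8, 0.4, 0.6], [0.8, 1, 0, 0], [0.4, 0, 1, 0], [0.6, 0, 0, 1]],
        )
        ta = ns.temporal_alignment(sim, "q", metas)
        # mean sim to 11 PCW = 0.6 equals sim to 17 PCW -> midpoint
        assert ta.estimated_timepoint == pytest.approx(14.0)

    def test_all_zero_similarity_is_an_error(self):
        sim = self.make_sim(["q", "t7", "t17"], [[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(DegenerateInputError):
            ns.temporal_alignment(sim, "q", [self.metas()[0], self.metas()[2]])

    def test_query_must_not_be_tissue(self):
        sim = self.make_sim(["t7", "t17"], [[1, 0.5], [0.5, 1]])
        with pytest.raises(ParameterError):
            ns.temporal_alignment(sim, "t7", self.metas()[:1] + self.metas()[2:])

    def test_needs_two_timepoints(self):
        sim = self.make_sim(["q", "t7"], [[1, 0.5], [0.5, 1]])
        with pytest.raises(ParameterError):
            ns.temporal_alignment(sim, "q", [self.metas()[0]])
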