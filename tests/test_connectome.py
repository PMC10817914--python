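"""Consensus backbone and graph metrics against hand-checkable oracles."""

import numpy as np
import pytest

import connectoshape as cs
from conftest import complete_graph, cycle_graph, path_graph, star_graph, toy_connectome


class TestGraphMetrics:
    def test_diameter_toy_graphs(self):
        assert cs.graph_diameter(path_graph(4)) == 3
        assert cs.graph_diameter(complete_graph(3)) == 1
        # brute-force all-pairs BFS oracle for the 6-cycle gives 3
        assert cs.graph_diameter(cycle_graph(6)) == 3

    def test_diameter_rejects_disconnected(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        with pytest.raises(ValueError, match="component"):
            cs.graph_diameter(toy_connectome(a))

    def test_nodal_efficiency_oracles(self):
        star = star_graph(3)
        assert cs.nodal_efficiency(star)[0] == pytest.approx(1.0)
        # end node of a 3-path: (1 + 1/2) / 2
        assert cs.nodal_efficiency(path_graph(3))[0] == pytest.approx(0.75)
        assert np.allclose(cs.nodal_efficiency(complete_graph(4)), 1.0)

    def test_mfpt_complete_graph_first_step_oracle(self):
        # K3: hitting time h solves h = 1 + h/2 -> h = 2
        mfpt = cs.mean_first_passage_time(complete_graph(3))
        assert np.allclose(mfpt, 2.0)

    def test_mfpt_three_node_path_linear_system(self):
        # hitting time 2 -> 1 on a path 0-1-2: from node 2 the walk reaches 1
        # in one step w.p. 1... solved 2x2 system gives E[0->2]=4, E[1->2]=3
        mfpt = cs.mean_first_passage_time(path_graph(3))
        # target node 2: sources 0 (h=4) and 1 (h=3) -> mean 3.5
        assert mfpt[2] == pytest.approx(3.5)
        # symmetric for node 0
        assert mfpt[0] == pytest.approx(3.5)

    def test_mfpt_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        # 12-cycle with random chords: connected by construction
        conn = cycle_graph(12)
        a = conn.adjacency.copy()
        for i, j in [(0, 5), (2, 9), (3, 7), (1, 10), (4, 11)]:
            a[i, j] = a[j, i] = 1
        conn = cs.Connectome(a, conn.distances)
        target = 0
        analytic = cs.mean_first_passage_time(conn)
        # Monte-Carlo walks: from every source, average steps to reach target
        a = conn.adjacency
        neighbors = [np.flatnonzero(a[i]) for i in range(12)]
        total = 0.0
        n_walk = 20000
        for src in range(1, 12):
            steps = np.zeros(n_walk)
            pos = np.full(n_walk, src)
            active = np.ones(n_walk, bool)
            t = 0
            while active.any() and t < 10000:
                t += 1
                idx = np.flatnonzero(active)
                pos[idx] = [neighbors[pp][rng.integers(len(neighbors[pp]))] for pp in pos[idx]]
                arrived = idx[pos[idx] == target]
                steps[arrived] = t
                active[arrived] = False
            total += steps.mean()
        mc = total / 11
        assert abs(mc - analytic[target]) / analytic[target] < 0.02

    def test_participation_coefficient(self):
        # all edges within own system -> 0
        c = path_graph(3)
        labels = np.array([1, 1, 1])
        assert np.allclose(cs.participation_coefficient(c, labels), 0.0)
        # middle node with one edge into each of two systems -> 1 - 2*(1/2)^2
        labels = np.array([1, 2, 3])
        assert cs.participation_coefficient(c, labels)[1] == pytest.approx(0.5)

    def test_participation_coefficient_bounds(self, conn100, parc100):
        pc = cs.participation_coefficient(conn100, parc100.system)
        k = len(np.unique(parc100.system))
        assert (pc >= 0).all() and (pc <= 1 - 1 / k + 1e-12).all()


def _random_individuals(n_subj, base, rng, flip=0.2):
    out = []
    iu, ju = np.nonzero(np.triu(np.ones_like(base), 1))
    for _ in range(n_subj):
        a = base.copy()
        sel = rng.random(iu.size) < flip
        a[iu[sel], ju[sel]] = 1 - a[iu[sel], ju[sel]]
        a[ju[sel], iu[sel]] = a[iu[sel], ju[sel]]
        out.append(a)
    return out


class TestConsensusBackbone:
    def test_identical_individuals_reproduced_exactly(self, parc100, conn100):
        d = cs.euclidean_distance_matrix(parc100)
        individuals = [conn100.adjacency.copy() for _ in range(4)]
        bb = cs.consensus_backbone(individuals, d, parcellation=parc100)
        assert np.array_equal(bb.adjacency, conn100.adjacency)

    def test_edge_count_equals_rounded_mean(self, parc100):
        rng = np.random.default_rng(8)
        base = cs.gen_connectome(parc100, 0.1, seed=8).adjacency
        individuals = _random_individuals(5, base, rng)
        d = cs.euclidean_distance_matrix(parc100)
        bb = cs.consensus_backbone(individuals, d, parcellation=parc100)
        target = int(round(np.mean([a.sum() / 2 for a in individuals])))
        assert bb.n_edges == target

    def test_frequency_ranking_beats_rare_edges(self):
        # 5 nodes, 3 subjects, 1 bin: an edge in 3/3 subjects is retained
        # before an edge in 1/3 when the quota binds (brute-force check)
        n = 5
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)

        def adj(edges):
            a = np.zeros((n, n), dtype=int)
            for i, j in edges:
                a[i, j] = a[j, i] = 1
            return a

        common = (0, 1)
        rare = (3, 4)
        individuals = [
            adj([common, (1, 2)]),
            adj([common, (2, 3)]),
            adj([common, rare]),
        ]
        bb = cs.consensus_backbone(individuals, d, n_bins=1)
        assert bb.adjacency[common] == 1
        assert bb.adjacency[rare] == 0
        assert bb.n_edges == 2  # rounded mean of (2, 2, 2)

    def test_permutation_equivariance(self, parc100):
        rng = np.random.default_rng(3)
        base = cs.gen_connectome(parc100, 0.1, seed=3).adjacency
        individuals = _random_individuals(4, base, rng)
        d = cs.euclidean_distance_matrix(parc100)
        bb = cs.consensus_backbone(individuals, d, n_bins=5).adjacency
        perm = rng.permutation(100)
        individuals_p = [a[np.ix_(perm, perm)] for a in individuals]
        bb_p = cs.consensus_backbone(
            individuals_p, d[np.ix_(perm, perm)], n_bins=5
        ).adjacency
        assert np.array_equal(bb[np.ix_(perm, perm)], bb_p)

    def test_rejects_bad_inputs(self, parc100):
        d = cs.euclidean_distance_matrix(parc100)
        one = [np.zeros((100, 100), dtype=int)]
        with pytest.raises(ValueError):
            cs.consensus_backbone(one, d)
        with pytest.raises(ValueError):
            cs.consensus_backbone([one[0], one[0]], d)  # empty candidate set
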