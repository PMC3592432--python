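"""Signal-path mining: relevance, sub-path extraction, pruning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clipper import paths, synthetic
from clipper.paths import (
    CliquePath,
    SubPath,
    best_subpath,
    enumerate_paths,
    extract_subpaths,
    prune_subpaths,
    relevance,
    standardized_relevance,
    subpath_dissimilarity,
)


def make_path(weights, pid=0):
    ids = tuple(range(len(weights)))
    genes = tuple((f"p{pid}c{i}a", f"p{pid}c{i}b") for i in ids)
    return CliquePath(pid, ids, tuple(weights), genes)


def make_subpath(r_star, length, start=0, r=1.0, m=1):
    return SubPath(
        path_id=0,
        start=start,
        clique_ids=tuple(range(start, start + length)),
        weights=(0.01,) * length,
        genes_by_clique=tuple((f"g{start + i}",) for i in range(length)),
        r=r,
        m=m,
        r_star=r_star,
    )


class TestRelevance:
    def test_running_scores_and_first_argmax(self):
        r, m = relevance([0.01, 0.02, 0.5])
        assert r == pytest.approx(1.94)
        assert m == 2

    def test_single_clique(self):
        r, m = relevance([0.01])
        assert r == pytest.approx(0.98) and m == 1

    def test_neutral_weights_tie_to_earliest(self):
        r, m = relevance([0.5, 0.5, 0.5])
        assert r == 0.0 and m == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            relevance([])

    def test_trailing_neutral_cliques_do_not_change_score(self):
        r, m = relevance([0.01, 0.02, 0.5])
        r2, m2 = relevance([0.01, 0.02, 0.5, 0.5, 0.5])
        assert (r, m) == (r2, m2)


class TestStandardizedRelevance:
    def test_example(self):
        assert standardized_relevance(1.94, 2) == pytest.approx(0.97)

    def test_m_one_identity(self):
        assert standardized_relevance(1.3, 1) == 1.3

    def test_doubling_m_halves(self):
        assert standardized_relevance(1.2, 4) == standardized_relevance(1.2, 2) / 2


class TestEnumeratePaths:
    def test_toy_tree_three_paths(self):
        jt = synthetic.toy_junction_tree()
        ps = enumerate_paths(jt, synthetic.toy_weights())
        assert len(ps) == 3
        assert all(p.clique_ids[0] == jt.root for p in ps)
        assert sorted(p.clique_ids[-1] for p in ps) == jt.leaves()

    def test_star_tree(self):
        import networkx as nx

        from clipper import graphs

        cg = nx.star_graph(["hub", "l1", "l2", "l3"])
        jt = graphs.build_junction_tree(graphs.find_cliques(cg), cg)
        ps = enumerate_paths(jt)
        # root is one of the 2-cliques; remaining leaves reached through hub
        assert all(len(p) >= 1 for p in ps)
        assert len(ps) == len(jt.leaves())

    def test_chain_single_path(self):
        import networkx as nx

        from clipper import graphs

        cg = nx.path_graph([f"n{i}" for i in range(6)])
        jt = graphs.build_junction_tree(graphs.find_cliques(cg), cg)
        (p,) = enumerate_paths(jt)
        assert len(p) == 5

    def test_single_clique_degenerate_path(self):
        import networkx as nx

        from clipper import graphs

        cg = nx.complete_graph("abc")
        jt = graphs.build_junction_tree(graphs.find_cliques(cg), cg)
        (p,) = enumerate_paths(jt)
        assert len(p) == 1


class TestExtractSubpaths:
    def test_toy_backbone_gives_four_subpaths(self):
        jt = synthetic.toy_junction_tree()
        ps = enumerate_paths(jt, synthetic.toy_weights())
        backbone = next(p for p in ps if p.clique_ids[-1] == 7)
        sps = extract_subpaths(backbone)
        assert len(sps) == 4
        spans = sorted((sp.start, sp.start + sp.length) for sp in sps)
        assert spans == [(0, 2), (0, 4), (3, 4), (6, 8)]

    def test_all_meaningful_whole_path(self):
        sps = extract_subpaths(make_path([0.01] * 5))
        assert len(sps) == 1 and sps[0].length == 5

    def test_two_gaps_cannot_be_bridged(self):
        sps = extract_subpaths(make_path([0.01, 0.5, 0.5, 0.01]))
        assert sorted(sp.clique_ids for sp in sps) == [(0,), (3,)]

    def test_no_meaningful_cliques_empty(self):
        assert extract_subpaths(make_path([0.5, 0.9, 0.99])) == []

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.001, 1.0), min_size=1, max_size=12))
    def test_subpath_validity_invariant(self, weights):
        alpha = 0.05
        for sp in extract_subpaths(make_path(weights), alpha=alpha):
            flags = [w < alpha for w in sp.weights]
            assert flags[0] and flags[-1]
            assert flags.count(False) <= 1
            assert sp.m <= sp.length
            assert sp.r_star == pytest.approx(sp.r / sp.m)


class TestBestSubpath:
    def test_single_candidate(self):
        (sp,) = extract_subpaths(make_path([0.01]))
        assert best_subpath([sp]) is sp

    def test_tie_prefers_longer(self):
        short = make_subpath(r_star=1.0, length=1)
        long = make_subpath(r_star=1.0, length=3)
        assert best_subpath([short, long]) is long

    def test_empty_returns_none(self):
        assert best_subpath([]) is None

    def test_argmax_r_star(self):
        a = make_subpath(r_star=0.5, length=2)
        b = make_subpath(r_star=0.9, length=1)
        assert best_subpath([a, b]) is b


class TestDissimilarity:
    def sp(self, genes):
        return SubPath(0, 0, (0,), (0.01,), (tuple(genes),))

    def test_nested_sets_collapse(self):
        A = self.sp(["g1", "g2"])
        B = self.sp(["g1", "g2", "g3"])
        assert subpath_dissimilarity(A, B) == 0.0

    def test_disjoint_sets_maximal(self):
        assert subpath_dissimilarity(self.sp(["a"]), self.sp(["b"])) == 1.0

    def test_partial_overlap(self):
        A = self.sp([f"g{i}" for i in range(1, 11)])
        B = self.sp([f"g{i}" for i in range(1, 9)] + ["h1", "h2"])
        assert subpath_dissimilarity(A, B) == pytest.approx(0.2)

    def test_symmetry_and_self_zero(self):
        A = self.sp(["a", "b", "c"])
        B = self.sp(["b", "c", "d", "e"])
        assert subpath_dissimilarity(A, B) == subpath_dissimilarity(B, A)
        assert subpath_dissimilarity(A, A) == 0.0


class TestPrune:
    def sp(self, genes, r_star=1.0):
        return SubPath(0, 0, (0,), (0.01,), (tuple(genes),), r=r_star, m=1, r_star=r_star)

    def test_identical_sets_always_collapse(self):
        a = self.sp(["g1", "g2"], r_star=0.5)
        b = self.sp(["g1", "g2"], r_star=0.9)
        rep = prune_subpaths([a, b], t=0.0).representatives
        assert len(rep) == 1 and rep[0].r_star == 0.9

    def test_all_distant_identity(self):
        sps = [self.sp([f"x{i}"]) for i in range(4)]
        report = prune_subpaths(sps, t=0.2)
        assert len(report.representatives) == 4

    def test_single_input(self):
        a = self.sp(["g"])
        report = prune_subpaths([a], t=0.2)
        assert report.representatives == [a]

    def test_representatives_pairwise_distant_and_clusters_cover(self):
        rng = np.random.default_rng(0)
        pool = [f"g{i}" for i in range(12)]
        for rep in range(30):
            sps = [
                self.sp(
                    sorted(rng.choice(pool, size=rng.integers(2, 7), replace=False)),
                    r_star=float(rng.uniform(0, 2)),
                )
                for _ in range(6)
            ]
            report = prune_subpaths(sps, t=0.2)
            for i, a in enumerate(report.representatives):
                for b in report.representatives[i + 1 :]:
                    assert subpath_dissimilarity(a, b) > 0.2
            assert set(report.cluster_of) == set(range(6))

    def test_determinism(self):
        jt = synthetic.toy_junction_tree()
        w = synthetic.toy_weights()
        r1 = paths.mine(jt, w)
        r2 = paths.mine(jt, w)
        assert [s.clique_ids for s in r1.representatives] == [
            s.clique_ids for s in r2.representatives
        ]


class TestMine:
    def test_toy_one_best_per_path(self):
        jt = synthetic.toy_junction_tree()
        report = paths.mine(jt, synthetic.toy_weights())
        assert 1 <= len(report.best_per_path) <= 3
        assert report.top() is not None

    def test_null_weights_yield_nothing(self):
        jt = synthetic.toy_junction_tree()
        report = paths.mine(jt, [0.9] * 12)
        assert report.best_per_path == [] and report.top() is None
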