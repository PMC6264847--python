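import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

import icmaldi as ic
from icmaldi.consensus import ConsensusPeak, IdentityError, VirtualSpectrum
from icmaldi.similarity import SIMILARITY_CMAP


def vspec(sample_id, mz_list):
    peaks = [ConsensusPeak(mz=m, support=10, mean_intensity=50.0)
             for m in sorted(mz_list)]
    return VirtualSpectrum(sample_id=sample_id, n_replicates=10, peaks=peaks)


class TestScore:
    def test_self_score_is_100(self, rng):
        a = vspec("A", np.sort(rng.uniform(1000, 20000, 30)))
        assert ic.score(a, a, 2.0) == 100.0

    def test_hand_counted_two_of_three(self):
        # query {5000, 8000, 12000} vs reference {5001, 11999}: 2/3 matched
        q = vspec("q", [5000.0, 8000.0, 12000.0])
        r = vspec("r", [5001.0, 11999.0])
        assert ic.score(q, r, 2.0) == pytest.approx(200.0 / 3.0)

    def test_one_reference_peak_certifies_one_query_peak(self):
        q = vspec("q", [5000.0, 5001.0])
        r = vspec("r", [5000.5])
        assert ic.score(q, r, 2.0) == pytest.approx(50.0)

    def test_asymmetry_of_denominator(self):
        q = vspec("q", [5000.0])
        r = vspec("r", [5000.0, 9000.0, 15000.0])
        assert ic.score(q, r, 2.0) == 100.0
        assert ic.score(r, q, 2.0) == pytest.approx(100.0 / 3.0)

    def test_boundary_inclusive_and_empty_query(self):
        q = vspec("q", [5000.0])
        r = vspec("r", [5002.0])
        assert ic.score(q, r, 2.0) == 100.0  # |Δ| == tol counts
        assert ic.score(q, vspec("r2", [5002.001]), 2.0) == 0.0
        empty = VirtualSpectrum(sample_id="e", n_replicates=10, peaks=[])
        assert ic.score(empty, r, 2.0) == 0.0

    def test_score_ignores_intensity(self):
        mzs = [4000.0, 9000.0]
        a = VirtualSpectrum("a", 10, [ConsensusPeak(m, 10, 5.0) for m in mzs])
        b = VirtualSpectrum("b", 10, [ConsensusPeak(m, 10, 500.0) for m in mzs])
        ref = vspec("r", [4001.0])
        assert ic.score(a, ref, 2.0) == ic.score(b, ref, 2.0)


class TestGreedyVsMaximumMatching:
    @staticmethod
    def max_cardinality(q, r, tol):
        rows, cols = [], []
        for i, a in enumerate(q):
            for j, b in enumerate(r):
                if abs(a - b) <= tol:
                    rows.append(i)
                    cols.append(j)
        if not rows:
            return 0
        m = csr_matrix((np.ones(len(rows)), (rows, cols)),
                       shape=(len(q), len(r)))
        return int((maximum_bipartite_matching(m, perm_type="column") >= 0).sum())

    def test_greedy_equals_maximum_on_500_replicate_like_instances(self):
        """Greedy nearest-first certification achieves maximum-cardinality
        matching on 500 seeded instances with ≤ 8 peaks per side, drawn from
        the replicate-spectrum regime (reference peaks are ±1 Da jittered
        counterparts of query peaks plus random extras)."""
        rng = np.random.default_rng(12345)
        for _ in range(500):
            nq, nr = rng.integers(1, 9, 2)
            q = np.sort(rng.uniform(1000, 20000, nq))
            n_common = min(nr, nq)
            base = rng.choice(q, size=n_common, replace=False) \
                + rng.normal(0, 1.0, n_common)
            extra = rng.uniform(1000, 20000, nr - n_common)
            r = np.sort(np.concatenate([base, extra]))
            greedy = len(ic.match_peaks(q, r, 2.0))
            assert greedy == self.max_cardinality(q, r, 2.0)


class TestSimilarityMatrix:
    def test_identical_spectra_all_100(self):
        lib = [vspec(s, [2000.0, 7000.0, 13000.0]) for s in "ABC"]
        m = ic.similarity_matrix(lib, 2.0)
        np.testing.assert_allclose(m.directed_scores, 100.0)

    def test_disjoint_spectra_off_diagonal_zero(self):
        m = ic.similarity_matrix([vspec("A", [2000.0, 7000.0]),
                                  vspec("B", [3000.0, 9000.0])], 2.0)
        np.testing.assert_allclose(m.directed_scores,
                                   [[100.0, 0.0], [0.0, 100.0]])

    def test_three_sample_hand_computation(self):
        # A {2000, 5000, 9000}, B {2001, 5002, 14000}, C {9000.5}
        # A vs B: 2000→2001, 5000→5002 → 2/3; A vs C: 9000→9000.5 → 1/3
        # B vs A: 2/3; B vs C: 0; C vs A: 1/1; C vs B: 0
        lib = [vspec("A", [2000.0, 5000.0, 9000.0]),
               vspec("B", [2001.0, 5002.0, 14000.0]),
               vspec("C", [9000.5])]
        m = ic.similarity_matrix(lib, 2.0)
        expected = np.array([[100.0, 200 / 3, 100 / 3],
                             [200 / 3, 100.0, 0.0],
                             [100.0, 0.0, 100.0]])
        np.testing.assert_allclose(m.directed_scores, expected)

    def test_duplicate_sample_ids_rejected(self):
        lib = [vspec("A", [2000.0]), vspec("A", [3000.0])]
        with pytest.raises(IdentityError):
            ic.similarity_matrix(lib, 2.0)

    def test_symmetric_distance_properties(self, rng):
        lib = [vspec(f"S{i}", np.sort(rng.uniform(1000, 20000, 20)))
               for i in range(4)]
        d = ic.similarity_matrix(lib, 2.0).symmetric_distance()
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)


class TestHeatmap:
    def test_colour_ramp_anchors(self):
        # red at 0, yellow at 50, dark green at 100
        r0, g0, b0, _ = SIMILARITY_CMAP(0.0)
        assert r0 > 0.7 and g0 < 0.3 and b0 < 0.3
        r5, g5, b5, _ = SIMILARITY_CMAP(0.5)
        assert r5 > 0.8 and g5 > 0.8 and b5 < 0.5
        r1, g1, b1, _ = SIMILARITY_CMAP(1.0)
        assert g1 > 0.3 and r1 < 0.2 and b1 < 0.2
        # monotone red-to-green transition across the ramp
        greens = [SIMILARITY_CMAP(x)[1] - SIMILARITY_CMAP(x)[0]
                  for x in (0.0, 0.25, 0.75, 1.0)]
        assert greens[0] < 0 < greens[-1]

    def test_renders_nonempty_file(self, tmp_path):
        m = ic.SimilarityMatrix(["A", "B"],
                                np.array([[100.0, 0.0], [0.0, 100.0]]), 2.0)
        out = tmp_path / "heat.png"
        ic.render_heatmap(m, out)
        assert out.exists() and out.stat().st_size > 0


class TestTree:
    def test_obvious_nearest_pair_topology(self):
        ids = ["A", "B", "C"]
        s = np.array([[100.0, 90.0, 10.0],
                      [90.0, 100.0, 10.0],
                      [10.0, 10.0, 100.0]])  # d(A,B)=10, d(·,C)=90
        tree = ic.build_tree(ic.SimilarityMatrix(ids, s, 2.0))
        ab = tree.lca([tree.find("A"), tree.find("B")])
        assert {t.name for t in ab.tips()} == {"A", "B"}

    def test_block_matrix_splits_groups_at_root(self):
        ids = ["A1", "A2", "B1", "B2"]
        s = np.full((4, 4), 0.0)
        s[:2, :2] = 100.0
        s[2:, 2:] = 100.0
        tree = ic.build_tree(ic.SimilarityMatrix(ids, s, 2.0))
        groups = [{t.name for t in child.tips()} or {child.name}
                  for child in tree.children]
        assert {frozenset(g) for g in groups} == \
            {frozenset({"A1", "A2"}), frozenset({"B1", "B2"})}

    def test_upgma_ultrametric(self, rng):
        ids = [f"S{i}" for i in range(6)]
        raw = rng.uniform(0, 100, (6, 6))
        s = (raw + raw.T) / 2
        np.fill_diagonal(s, 100.0)
        tree = ic.build_tree(ic.SimilarityMatrix(ids, s, 2.0))
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        assert max(depths.values()) - min(depths.values()) < 1e-9

    def test_deterministic_under_tie_and_label_permutation(self):
        # perfect tie: all off-diagonal distances equal
        ids = ["C", "A", "B"]
        s = np.full((3, 3), 40.0)
        np.fill_diagonal(s, 100.0)
        t1 = ic.build_tree(ic.SimilarityMatrix(ids, s, 2.0))
        t2 = ic.build_tree(ic.SimilarityMatrix(["A", "B", "C"], s, 2.0))
        # ties break toward lexicographically smallest labels: (A,B) first
        pair1 = min(({x.name for x in c.tips()} or {c.name}
                     for c in t1.children), key=len)
        pair2 = min(({x.name for x in c.tips()} or {c.name}
                     for c in t2.children), key=len)
        assert pair1 == pair2 == {"C"}

    def test_newick_round_trip(self, tmp_path):
        ids = ["A", "B", "C"]
        s = np.array([[100.0, 80.0, 20.0],
                      [80.0, 100.0, 20.0],
                      [20.0, 20.0, 100.0]])
        tree = ic.build_tree(ic.SimilarityMatrix(ids, s, 2.0))
        path = tmp_path / "t.nwk"
        ic.write_newick(tree, path)
        from icmaldi.similarity import read_newick
        back = read_newick(path)
        assert {t.name for t in back.tips()} == set(ids)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            ic.build_tree(ic.SimilarityMatrix(["A"], np.array([[100.0]]), 2.0))

    def test_matches_scipy_upgma_heights(self, rng):
        # cross-check cophenetic structure against scipy average linkage on a
        # tie-free random distance matrix
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform
        n = 6
        raw = rng.uniform(10, 90, (n, n))
        s = (raw + raw.T) / 2
        np.fill_diagonal(s, 100.0)
        ids = [f"S{i}" for i in range(n)]
        m = ic.SimilarityMatrix(ids, s, 2.0)
        tree = ic.build_tree(m)
        d = m.symmetric_distance()
        coph = squareform(cophenet(average(squareform(d))))
        for i in range(n):
            for j in range(i + 1, n):
                ti, tj = tree.find(ids[i]), tree.find(ids[j])
                dist = ti.accumulate_to_ancestor(tree.lca([ti, tj])) \
                    + tj.accumulate_to_ancestor(tree.lca([ti, tj]))
                assert dist == pytest.approx(coph[i, j], rel=1e-9)
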