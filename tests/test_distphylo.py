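"""Distances, the Grishin correction, NJ, balanced-ME refinement, exclusion."""

import io
import itertools
import math

import numpy as np
import pytest
from skbio import TreeNode

from scsurvey.distphylo import (
    DistanceMatrix,
    PhyloTree,
    balanced_length,
    build_tree,
    exclude_unalignable,
    grishin_distance,
    me_refine,
    nj_topology,
    pairwise_p,
    read_newick,
    topology_splits,
    _tree_to_adj,
)
from scsurvey.seqio import ProteinRecord
from scsurvey.synthetic_data import (
    SimConfig,
    evolve_family,
    random_background_sequence,
    random_tree,
)


def additive_matrix_from_tree(newick: str) -> tuple[TreeNode, DistanceMatrix]:
    t = TreeNode.read(io.StringIO(newick))
    names = sorted(l.name for l in t.tips())
    n = len(names)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = t.find(names[i]).distance(t.find(names[j]))
    return t, DistanceMatrix(ids=names, p=np.zeros((n, n)), d=d, coverage=np.ones((n, n)))


class TestGrishin:
    def test_limits(self):
        assert grishin_distance(0.0) == 0.0
        assert math.isinf(grishin_distance(1.0))

    def test_small_p_series_limit(self):
        p = 1e-4
        assert grishin_distance(p) / p == pytest.approx(1.0, abs=1e-3)

    def test_half_mismatch_value(self):
        # root of ln(1+2d)/(2d) = 0.5, verified by bisection beforehand
        assert grishin_distance(0.5) == pytest.approx(1.25643, abs=1e-4)

    @pytest.mark.parametrize("p", [0.01, 0.1, 0.3, 0.5, 0.7, 0.9, 0.99])
    def test_inverts_defining_equation(self, p):
        d = grishin_distance(p)
        q = math.log1p(2 * d) / (2 * d)
        assert abs((1 - q) - p) < 1e-9

    def test_strictly_increasing_and_convex(self):
        ps = np.linspace(0.01, 0.95, 50)
        ds = np.array([grishin_distance(p) for p in ps])
        assert np.all(np.diff(ds) > 0)
        assert np.all(np.diff(ds, 2) > -1e-9)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            grishin_distance(-0.1)


class TestPairwiseP:
    def test_identical_sequences(self, scheme, bg, rng):
        seq = random_background_sequence(100, rng, bg)
        recs = [ProteinRecord(f"r{i}", seq) for i in range(3)]
        D = pairwise_p(recs, scheme)
        assert np.allclose(D.p[np.triu_indices(3, 1)], 0.0)
        assert np.allclose(D.coverage[np.triu_indices(3, 1)], 1.0)
        assert np.allclose(D.d[np.triu_indices(3, 1)], 0.0)

    def test_one_mismatch_in_ten_columns(self, scheme):
        a = ProteinRecord("a", "WWWWWCWWWW")
        b = ProteinRecord("b", "WWWWWMWWWW")
        c = ProteinRecord("c", "WWWWWCWWWW")
        D = pairwise_p([a, b, c], scheme)
        i, j = D.ids.index("a"), D.ids.index("b")
        assert D.p[i, j] == pytest.approx(0.1)

    def test_simulated_family_p_near_expectation(self, scheme):
        # distances grow with divergence in a 3-taxon family
        recs, _ = evolve_family(SimConfig(seed=0, n_taxa=4, indel_rate=0.0))
        D = pairwise_p(recs, scheme)
        off = D.p[np.triu_indices(4, 1)]
        assert np.all(off > 0) and np.all(off < 0.6)

    def test_unalignable_pair_marked_undefined(self, scheme):
        recs = [
            ProteinRecord("a", "G" * 60),
            ProteinRecord("b", "P" * 60),
            ProteinRecord("c", "G" * 60),
        ]
        D = pairwise_p(recs, scheme)
        i, j = D.ids.index("a"), D.ids.index("b")
        assert np.isnan(D.p[i, j]) and math.isinf(D.d[i, j])
        assert D.coverage[i, j] == 0.0

    def test_phylip_output(self, scheme, bg, rng, tmp_path):
        recs = [ProteinRecord(f"r{i}", random_background_sequence(60, rng, bg)) for i in range(3)]
        D = pairwise_p(recs, scheme)
        path = tmp_path / "dist.phy"
        D.to_phylip(path)
        lines = path.read_text().splitlines()
        assert lines[0].strip() == "3"
        assert len(lines) == 4


class TestNeighborJoining:
    def test_three_leaves_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        D = DistanceMatrix(ids=["a", "b", "c"], p=d * 0, d=d, coverage=d * 0 + 1)
        tree = nj_topology(D).tree
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_four_leaf_additive_recovery(self):
        true, D = additive_matrix_from_tree("((a:1,b:2):1.5,(c:1,d:3):0.5);")
        tree = nj_topology(D).tree
        assert topology_splits(tree) == topology_splits(true)
        # additive distances are reproduced exactly by the fitted tree
        for x, y in itertools.combinations(D.ids, 2):
            got = tree.find(x).distance(tree.find(y))
            assert got == pytest.approx(D.d[D.ids.index(x), D.ids.index(y)], abs=1e-9)

    def test_ultrametric_five_leaf_topology(self):
        true, D = additive_matrix_from_tree(
            "(((a:1,b:1):1,(c:1.5,d:1.5):0.5):1,e:3);"
        )
        tree = nj_topology(D).tree
        assert topology_splits(tree) == topology_splits(true)

    def test_random_additive_trees_recovered(self):
        ok = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            sim = random_tree(8, rng, (0.05, 0.5))
            true, D = additive_matrix_from_tree(sim.newick())
            if topology_splits(nj_topology(D).tree) == topology_splits(true):
                ok += 1
        assert ok == 30

    def test_undefined_distances_rejected(self):
        d = np.array([[0, 1, math.inf], [1, 0, 1], [math.inf, 1, 0]])
        D = DistanceMatrix(ids=["a", "b", "c"], p=np.zeros((3, 3)), d=d,
                           coverage=np.ones((3, 3)))
        with pytest.raises(ValueError, match="exclude"):
            nj_topology(D)


class TestMinimumEvolution:
    def test_additive_optimum_is_fixed_point(self):
        true, D = additive_matrix_from_tree("((a:1,b:2):1.5,(c:1,d:3):0.5);")
        start = nj_topology(D)
        refined = me_refine(start, D)
        assert topology_splits(refined.tree) == topology_splits(true)

    def test_swapped_four_leaf_start_restored(self):
        true, D = additive_matrix_from_tree("((a:1,b:2):1.5,(c:1,d:3):0.5);")
        wrong = PhyloTree(tree=TreeNode.read(io.StringIO("((a:1,c:1):1,(b:1,d:1):1);")))
        refined = me_refine(wrong, D)
        assert topology_splits(refined.tree) == topology_splits(true)

    def test_balanced_length_never_increases(self):
        rng = np.random.default_rng(3)
        sim = random_tree(7, rng, (0.05, 0.5))
        true, D = additive_matrix_from_tree(sim.newick())
        noisy = D.d + rng.normal(0, 0.05, D.d.shape)
        noisy = np.abs((noisy + noisy.T) / 2)
        np.fill_diagonal(noisy, 0.0)
        Dn = DistanceMatrix(ids=D.ids, p=D.p, d=noisy, coverage=D.coverage)
        start = nj_topology(Dn)
        adj0, _ = _tree_to_adj(start.tree)
        before = balanced_length(adj0, Dn)
        refined = me_refine(start, Dn)
        adj1, _ = _tree_to_adj(refined.tree)
        assert balanced_length(adj1, Dn) <= before + 1e-9

    def test_pauplin_length_three_leaves(self):
        d = np.array([[0, 2.0, 3.0], [2.0, 0, 4.0], [3.0, 4.0, 0]])
        D = DistanceMatrix(ids=["a", "b", "c"], p=d * 0, d=d, coverage=d * 0 + 1)
        tree = nj_topology(D)
        adj, _ = _tree_to_adj(tree.tree)
        # star topology: every pair at 2 edges, weight 1/2 each
        assert balanced_length(adj, D) == pytest.approx((2 + 3 + 4) / 2)


class TestExclusion:
    def test_random_decoy_excluded(self, scheme, bg):
        recs, _ = evolve_family(SimConfig(seed=1, n_taxa=5))
        rng = np.random.default_rng(99)
        decoy = ProteinRecord("decoy", random_background_sequence(300, rng, bg))
        kept, excluded = exclude_unalignable(recs + [decoy], scheme)
        assert [e[0] for e in excluded] == ["decoy"]
        assert len(kept) == 5

    def test_identical_set_kept(self, scheme, bg, rng):
        seq = random_background_sequence(120, rng, bg)
        recs = [ProteinRecord(f"r{i}", seq) for i in range(4)]
        kept, excluded = exclude_unalignable(recs, scheme)
        assert excluded == [] and len(kept) == 4

    def test_too_few_survivors_error(self, scheme, bg, rng):
        recs = [
            ProteinRecord("a", "G" * 80),
            ProteinRecord("b", "P" * 80),
            ProteinRecord("c", random_background_sequence(80, rng, bg)),
        ]
        with pytest.raises(ValueError, match="no tree possible"):
            exclude_unalignable(recs, scheme)


class TestNewickRoundtrip:
    def test_write_read_write_idempotent(self, tmp_path):
        true, D = additive_matrix_from_tree("((a:1,b:2):1.5,(c:1,d:3):0.5);")
        tree = nj_topology(D)
        p1 = tmp_path / "t1.nwk"
        tree.write(p1)
        back = PhyloTree(tree=read_newick(p1))
        p2 = tmp_path / "t2.nwk"
        back.write(p2)
        assert p1.read_text() == p2.read_text()


class TestBuildTree:
    def test_pipeline_recovers_simulated_topology(self, scheme):
        recs, truth = evolve_family(SimConfig(seed=11))
        true = TreeNode.read(io.StringIO(truth.true_tree))
        tree, D = build_tree(recs, scheme)
        assert tree.excluded == []
        assert topology_splits(tree.tree) == topology_splits(true)
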