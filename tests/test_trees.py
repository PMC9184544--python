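"""Distance, neighbor-joining, quartet scoring and species-tree search,
cross-checked against independent oracles (scikit-bio NJ, dendropy path
distances, exhaustive enumeration)."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from islandrad import trees
from islandrad.trees import DistanceMatrix, Tree
from tests.conftest import make_alignment


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def dendropy_quartet_code(newick: str, quartet: tuple[str, str, str, str]) -> int | None:
    """Induced quartet topology via dendropy path distances (four-point).

    Returns 0 for ab|cd, 1 for ac|bd, 2 for ad|bc over the sorted quartet,
    or None when unresolved.  Independent of the package's BFS machinery.
    """
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = t.phylogenetic_distance_matrix()
    taxa = {x.label: x for x in t.taxon_namespace}
    a, b, c, d = sorted(quartet)
    dist = lambda x, y: pdm.path_edge_count(taxa[x], taxa[y])
    sums = (dist(a, b) + dist(c, d), dist(a, c) + dist(b, d), dist(a, d) + dist(b, c))
    lo = min(sums)
    return None if sums.count(lo) != 1 else sums.index(lo)


def random_binary_tree(taxa, rng, min_len=0.05, max_len=0.5) -> Tree:
    """Random topology + branch lengths built by random pair joining --
    independent of the package's enumeration code."""
    nodes = {}
    adj = {}
    labels = {}
    nid = 0
    roots = []
    for name in taxa:
        adj[nid] = {}
        labels[nid] = name
        roots.append(nid)
        nid += 1
    while len(roots) > 3:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        u, v = roots[i], roots[j]
        new = nid
        nid += 1
        adj[new] = {}
        for x in (u, v):
            ln = float(rng.uniform(min_len, max_len))
            adj[new][x] = ln
            adj[x][new] = ln
        roots = [r for r in roots if r not in (u, v)] + [new]
    center = nid
    adj[center] = {}
    for x in roots:
        ln = float(rng.uniform(min_len, max_len))
        adj[center][x] = ln
        adj[x][center] = ln
    return Tree(adj, labels)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


class TestPDistance:
    def test_identical_rows_zero(self):
        dm = trees.pdistance(make_alignment(list("abc"), ["ACGT"] * 3))
        assert np.all(dm.matrix == 0)

    def test_direct_count(self):
        dm = trees.pdistance(make_alignment(list("abc"), ["AAAA", "AAAT", "AAAA"]))
        assert dm.matrix[0, 1] == pytest.approx(0.25)

    def test_overlap_accounting_with_n(self):
        dm = trees.pdistance(make_alignment(list("abc"), ["AANA", "ATNA", "AAAA"]))
        assert dm.matrix[0, 1] == pytest.approx(1 / 3)

    def test_zero_overlap_flagged(self):
        dm = trees.pdistance(make_alignment(list("abc"), ["AANN", "NNAA", "ACGT"]))
        assert math.isnan(dm.matrix[0, 1])
        assert not dm.complete


class TestJC69:
    def test_zero_and_inverse(self):
        assert trees.jc69_correct(0.0) == 0.0
        # p chosen so that d = 0.1 exactly: p = 0.75 (1 - e^{-4 0.1/3})
        assert trees.jc69_correct(0.093620) == pytest.approx(0.1000, abs=5e-5)

    @pytest.mark.parametrize("p", [0.01, 0.1, 0.3, 0.6, 0.7])
    def test_correction_inflates(self, p):
        assert trees.jc69_correct(p) >= p

    def test_saturation(self):
        with pytest.raises(trees.SaturationError):
            trees.jc69_correct(0.75)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


class TestNeighborJoining:
    def test_three_taxon_lengths(self):
        """Three-point formulas: D(a,b)=3, D(a,c)=4, D(b,c)=5 gives
        la=1, lb=2, lc=3."""
        dm = DistanceMatrix(list("abc"), np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        t = trees.neighbor_joining(dm)
        center = next(n for n in t.adj if n not in t.labels)
        lengths = {t.labels[n]: ln for n, ln in t.adj[center].items()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_four_taxon_additive_recovery(self):
        truth = Tree.from_newick("((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05);")
        dm = truth.leaf_distance_matrix()
        rec = trees.neighbor_joining(dm)
        assert rec.topology_equal(truth)
        # branch lengths recovered too (additive case is exact)
        assert rec.leaf_distance_matrix(order=dm.taxa).matrix == pytest.approx(dm.matrix)

    @pytest.mark.parametrize("seed", range(8))
    def test_additive_recovery_and_skbio_agreement(self, seed):
        """Random additive 5-8 taxon matrices: our NJ and scikit-bio's NJ
        recover the generating topology."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        taxa = [f"t{i}" for i in range(n)]
        truth = random_binary_tree(taxa, rng)
        dm = truth.leaf_distance_matrix(order=taxa)
        ours = trees.neighbor_joining(dm)
        assert ours.topology_equal(truth)
        sk = sknj(SkDM(dm.matrix, ids=taxa))
        ours_from_sk = Tree.from_newick(str(sk).strip())
        assert ours.topology_equal(ours_from_sk)

    def test_label_invariance(self):
        rng = np.random.default_rng(42)
        taxa = [f"t{i}" for i in range(6)]
        truth = random_binary_tree(taxa, rng)
        dm = truth.leaf_distance_matrix(order=taxa)
        perm = list(rng.permutation(6))
        dm2 = DistanceMatrix([taxa[i] for i in perm], dm.matrix[np.ix_(perm, perm)])
        assert trees.neighbor_joining(dm).topology_equal(trees.neighbor_joining(dm2))

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(list("ab"), np.array([[0, 1], [2, 0]], float))
        with pytest.raises(ValueError):
            DistanceMatrix(list("ab"), np.array([[0, -1], [-1, 0]], float))


# ---------------------------------------------------------------------------
# newick round trip
# ---------------------------------------------------------------------------


class TestNewick:
    def test_round_trip_topology_and_lengths(self):
        nwk = "((A:0.1,B:0.2):0.05,(C:0.3,D:0.4):0.06,E:0.5);"
        t = Tree.from_newick(nwk)
        back = Tree.from_newick(t.to_newick())
        assert t.topology_equal(back)
        d1 = t.leaf_distance_matrix().matrix
        d2 = back.leaf_distance_matrix(order=t.leaves).matrix
        assert d2 == pytest.approx(d1, abs=1e-6)

    def test_gene_tree_file_round_trip(self, tmp_path):
        gts = trees.GeneTreeSet(trees=[
            Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);"),
            Tree.from_newick("((A:1,C:1):1,(B:1,D:1):1);"),
        ])
        trees.write_gene_trees(gts, tmp_path / "gt.nwk")
        back = trees.read_gene_trees(tmp_path / "gt.nwk")
        assert len(back) == 2
        for a, b in zip(gts.trees, back.trees):
            assert a.topology_equal(b)


# ---------------------------------------------------------------------------
# quartets and species tree
# ---------------------------------------------------------------------------


class TestQuartetScore:
    def test_full_agreement_count(self):
        t = Tree.from_newick("((A:1,B:1):1,((C:1,D:1):1,E:1):1);")
        k = 7
        gts = [t.copy() for _ in range(k)]
        assert trees.quartet_score(t, gts) == k * math.comb(5, 4)

    def test_conflicting_four_taxon_tree_contributes_zero(self):
        cand = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        conf = Tree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert trees.quartet_score(cand, [conf]) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dendropy_brute_force(self, seed):
        """Random 5-6 taxon instances: quartet score equals per-quartet
        enumeration through dendropy path distances."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 7))
        taxa = [f"t{i}" for i in range(n)]
        cand = random_binary_tree(taxa, rng)
        gts = [random_binary_tree(taxa, rng) for _ in range(3)]
        expected = 0
        for q in itertools.combinations(sorted(taxa), 4):
            c_code = dendropy_quartet_code(cand.to_newick(), q)
            for gt in gts:
                if dendropy_quartet_code(gt.to_newick(), q) == c_code:
                    expected += 1
        assert trees.quartet_score(cand, gts) == expected

    def test_missing_leaves_use_intersection(self):
        cand = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        small = Tree.from_newick("((A:1,B:1):1,C:1);")  # no 4-subset spanned
        assert trees.quartet_score(cand, [small]) == 0


class TestSpeciesTree:
    def test_unanimous_gene_trees(self):
        t = Tree.from_newick("((A:1,B:1):1,((C:1,D:1):1,E:1):1);")
        res = trees.infer_species_tree([t.copy() for _ in range(5)], mode="exhaustive")
        assert res.tree.topology_equal(t)
        assert all(s == pytest.approx(1.0) for s in res.support.values())
        assert res.quartet_score == 5 * math.comb(5, 4)

    def test_greedy_bounded_by_exhaustive(self):
        rng = np.random.default_rng(7)
        taxa = [f"t{i}" for i in range(5)]
        gts = [random_binary_tree(taxa, rng) for _ in range(9)]
        ex = trees.infer_species_tree(gts, mode="exhaustive")
        gr = trees.infer_species_tree(gts, mode="greedy")
        assert gr.quartet_score <= ex.quartet_score

    def test_exhaustive_matches_independent_enumeration(self):
        """Best exhaustive score equals brute-force maximum over all 15
        five-taxon topologies scored with the dendropy oracle."""
        rng = np.random.default_rng(13)
        taxa = [f"t{i}" for i in range(5)]
        gts = [random_binary_tree(taxa, rng) for _ in range(6)]
        cands = list(trees.enumerate_topologies(taxa))
        assert len(cands) == 15  # (2*5-5)!!
        best_oracle = -1
        for cand in cands:
            score = 0
            for q in itertools.combinations(sorted(taxa), 4):
                code = dendropy_quartet_code(cand.to_newick(), q)
                score += sum(
                    1 for gt in gts if dendropy_quartet_code(gt.to_newick(), q) == code
                )
            best_oracle = max(best_oracle, score)
        res = trees.infer_species_tree(gts, mode="exhaustive")
        assert res.quartet_score == best_oracle

    def test_truth_beats_nni_neighbors_on_concordant_input(self):
        truth = Tree.from_newick("((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);")
        gts = [truth.copy() for _ in range(4)]
        s_truth = trees.quartet_score(truth, gts)
        for nb in truth.nni_neighbors():
            assert trees.quartet_score(nb, gts) <= s_truth

    def test_too_few_leaves_rejected(self):
        t = Tree.from_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError):
            trees.infer_species_tree([t], mode="exhaustive")

    def test_support_floor_on_returned_tree(self):
        """Every branch of a maximized tree keeps the plurality of its
        spanning quartets: support never falls below 1/3."""
        rng = np.random.default_rng(3)
        taxa = [f"t{i}" for i in range(6)]
        gts = [random_binary_tree(taxa, rng) for _ in range(25)]
        res = trees.infer_species_tree(gts, mode="exhaustive")
        assert all(s >= 1 / 3 for s in res.support.values())


class TestBuildGeneTrees:
    def test_counts_and_skip_reasons(self):
        good = make_alignment(list("abcd"), ["AAAAAAAA", "AAAAAAAT", "TTAAAAAA", "TTAAAAAT"])
        identical = make_alignment(list("abcd"), ["ACGT"] * 4)
        no_overlap = make_alignment(list("abcd"), ["AANN", "NNAA", "ACGT", "ACGT"])
        out = trees.build_gene_trees([good, identical, no_overlap])
        assert len(out.trees) == 1
        reasons = [r for _, r in out.skipped]
        assert any("identical" in r for r in reasons)
        assert any("overlap" in r for r in reasons)

    def test_concordant_simulation_recovers_species_topology(self):
        """p_ils = 0, strong divergence: every usable gene tree matches the
        species topology."""
        from islandrad import simulate as sim
        from islandrad import windows

        tree = sim.SpeciesTreeSpec(
            newick="((A:0.02,B:0.02):0.02,(C:0.02,D:0.02):0.02);",
            theta={s: 0.0 for s in "ABCD"},
            n_individuals={s: 1 for s in "ABCD"},
        )
        cfg = sim.SimulationConfig(tree=tree, contig_lengths={"c": 140_000}, p_ils=0.0, seed=5)
        genomes, truth = sim.simulate(cfg)
        seqs = sim.pseudo_haploidize(genomes, seed=1)
        segs = windows.tile_from_start(100_000, 140_000, 2_000, 0, contig="c")
        plan = windows.SegmentPlan(2_000, 0, {"c": 100_000}, segs, seed=0)
        alns = windows.extract_alignments(seqs, plan)
        gts = trees.build_gene_trees(alns)
        expected = Tree.from_newick("((A_1:1,B_1:1):1,(C_1:1,D_1:1):1);")
        assert len(gts.trees) == len(segs)
        for t in gts.trees:
            assert t.topology_equal(expected)
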