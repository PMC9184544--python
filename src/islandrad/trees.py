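"""Gene trees and quartet-supported species-tree consensus.

Per-segment gene trees are built by neighbor joining on Jukes-Cantor
corrected p-distances (a deterministic, desk-scale surrogate for a
maximum-likelihood engine).  The species tree is the topology maximizing
the total quartet score against the gene trees -- the number of 4-leaf
subsets whose induced unrooted topology agrees between the candidate and a
gene tree, summed over gene trees.  For small leaf sets the maximization
is exhaustive over all unrooted topologies; otherwise a greedy
nearest-neighbor-interchange (NNI) hill climb starts from the
neighbor-joining tree of segment-averaged distances.  Branch support is
the fraction of gene-tree quartets spanning the branch that agree with it
(gene-tree conflict around the branch), which is related to -- but not the
same as -- a coalescent local posterior probability.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from islandrad.qc import N_CODE, WindowedAlignment

JC69_SATURATION = 0.75


class SaturationError(ValueError):
    """Raised when a mismatch proportion is at or beyond the JC69 ceiling."""


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix over an ordered taxon list.

    Entries may be nan to flag pairs with zero non-N overlap; such a
    matrix is unusable for tree building and the caller must check
    :attr:`complete`.
    """

    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        finite = np.isfinite(self.matrix)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            self.matrix[finite & finite.T], self.matrix.T[finite & finite.T]
        ):
            raise ValueError("matrix must be symmetric")
        if np.any(self.matrix[finite] < 0):
            raise ValueError("matrix entries must be nonnegative")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def complete(self) -> bool:
        return bool(np.isfinite(self.matrix).all())


def pdistance(aln: WindowedAlignment) -> DistanceMatrix:
    """Pairwise mismatch proportions over mutually non-N sites.

    Entry (i, j) is mismatches / overlap where overlap counts positions at
    which both rows are in {A,C,G,T}.  Pairs with zero overlap are flagged
    as nan.
    """
    if aln.n_taxa < 3:
        raise ValueError("need at least 3 taxa for a distance matrix")
    data = aln.data
    valid = data != N_CODE  # (n, L)
    n = aln.n_taxa
    mat = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        overlap = both.sum(axis=1)
        mism = ((data[i] != data[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(overlap > 0, mism / np.maximum(overlap, 1), np.nan)
        mat[i, i + 1 :] = d
        mat[i + 1 :, i] = d
    return DistanceMatrix(taxa=list(aln.taxa), matrix=mat)


def jc69_correct(p: float | np.ndarray) -> float | np.ndarray:
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p).

    Always >= p (the correction inflates); raises
    :class:`SaturationError` at or beyond p = 0.75.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0):
        raise ValueError("mismatch proportion must be nonnegative")
    if np.any(arr >= JC69_SATURATION):
        raise SaturationError("mismatch proportion at or beyond JC69 saturation (0.75)")
    d = -0.75 * np.log1p(-(4.0 / 3.0) * arr)
    return float(d) if np.isscalar(p) else d


# ---------------------------------------------------------------------------
# unrooted trees
# ---------------------------------------------------------------------------


class Tree:
    """Unrooted tree with branch lengths; internal nodes have degree 3.

    Stored as an adjacency map node-id -> {neighbor-id: branch length}.
    Leaves carry labels.  Topology comparisons go through canonical
    bipartitions so label order and rooting never matter.
    """

    def __init__(self, adj: dict[int, dict[int, float]], labels: dict[int, str]):
        self.adj = adj
        self.labels = labels  # leaf node id -> taxon name
        self._name_to_node = {v: k for k, v in labels.items()}
        if len(self._name_to_node) != len(labels):
            raise ValueError("duplicate leaf labels")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree) -> "Tree":
        adj: dict[int, dict[int, float]] = {}
        labels: dict[int, str] = {}
        ids: dict[object, int] = {}

        def nid(node) -> int:
            if node not in ids:
                ids[node] = len(ids)
                adj[ids[node]] = {}
            return ids[node]

        for edge in dt.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            u, v = nid(edge.tail_node), nid(edge.head_node)
            ln = float(edge.length) if edge.length is not None else 0.0
            adj[u][v] = ln
            adj[v][u] = ln
        for leaf in dt.leaf_node_iter():
            labels[nid(leaf)] = leaf.taxon.label if leaf.taxon else str(leaf)
        tree = cls(adj, labels)
        tree._suppress_degree_two()
        return tree

    def _suppress_degree_two(self) -> None:
        """Remove degree-2 nodes (e.g. a rooted tree's root), merging edges."""
        changed = True
        while changed:
            changed = False
            for node in list(self.adj):
                if node not in self.labels and len(self.adj[node]) == 2:
                    (a, la), (b, lb) = self.adj[node].items()
                    del self.adj[node]
                    del self.adj[a][node]
                    del self.adj[b][node]
                    self.adj[a][b] = la + lb
                    self.adj[b][a] = la + lb
                    changed = True

    def copy(self) -> "Tree":
        return Tree({u: dict(nbrs) for u, nbrs in self.adj.items()}, dict(self.labels))

    # -- basic queries -------------------------------------------------------

    @property
    def leaves(self) -> list[str]:
        return sorted(self.labels.values())

    def _leaf_node(self, name: str) -> int:
        return self._name_to_node[name]

    def _distances_from(self, source: int, unit: bool) -> dict[int, float]:
        dist = {source: 0.0}
        stack = [source]
        while stack:
            u = stack.pop()
            for v, ln in self.adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + (1.0 if unit else ln)
                    stack.append(v)
        return dist

    def leaf_distance_matrix(self, order: Sequence[str] | None = None, topological: bool = False) -> DistanceMatrix:
        """Pairwise leaf-to-leaf path distances (branch lengths or edge counts)."""
        names = list(order) if order is not None else self.leaves
        n = len(names)
        mat = np.zeros((n, n))
        for i, a in enumerate(names):
            dist = self._distances_from(self._leaf_node(a), unit=topological)
            for j, b in enumerate(names):
                if j != i:
                    mat[i, j] = dist[self._leaf_node(b)]
        mat = (mat + mat.T) / 2.0
        np.fill_diagonal(mat, 0.0)
        return DistanceMatrix(taxa=names, matrix=mat)

    def bipartitions(self) -> dict[frozenset[str], tuple[int, int]]:
        """Nontrivial splits, canonicalized as the side NOT holding the
        alphabetically smallest leaf; values are the defining edge."""
        ref = min(self.labels.values())
        out: dict[frozenset[str], tuple[int, int]] = {}
        seen = set()
        for u in self.adj:
            for v in self.adj[u]:
                if (v, u) in seen:
                    continue
                seen.add((u, v))
                side = self._leaves_behind(v, u)
                if len(side) < 2 or len(self.labels) - len(side) < 2:
                    continue
                if ref in side:
                    side = frozenset(self.labels.values()) - side
                    out[side] = (u, v)
                else:
                    out[frozenset(side)] = (v, u)
        return out

    def _leaves_behind(self, node: int, came_from: int) -> set[str]:
        """Leaf labels in the component containing ``node`` after cutting
        the edge (came_from, node)."""
        out = set()
        stack = [(node, came_from)]
        while stack:
            u, prev = stack.pop()
            if u in self.labels:
                out.add(self.labels[u])
            for v in self.adj[u]:
                if v != prev:
                    stack.append((v, u))
        return out

    def topology_equal(self, other: "Tree") -> bool:
        if set(self.labels.values()) != set(other.labels.values()):
            return False
        return set(self.bipartitions()) == set(other.bipartitions())

    # -- editing -------------------------------------------------------------

    def nni_neighbors(self) -> list["Tree"]:
        """All trees one NNI move away (two per internal edge)."""
        out = []
        for u, v in self._internal_edges():
            u_nbrs = [x for x in self.adj[u] if x != v]
            v_nbrs = [x for x in self.adj[v] if x != u]
            b = u_nbrs[1]
            for c in v_nbrs:
                t = self.copy()
                t._swap_subtrees(u, b, v, c)
                out.append(t)
        return out

    def _internal_edges(self) -> list[tuple[int, int]]:
        edges = []
        for u in sorted(self.adj):
            for v in sorted(self.adj[u]):
                if u < v and u not in self.labels and v not in self.labels:
                    edges.append((u, v))
        return edges

    def _swap_subtrees(self, u: int, b: int, v: int, c: int) -> None:
        lb = self.adj[u].pop(b)
        del self.adj[b][u]
        lc = self.adj[v].pop(c)
        del self.adj[c][v]
        self.adj[u][c] = lc
        self.adj[c][u] = lc
        self.adj[v][b] = lb
        self.adj[b][v] = lb

    # -- serialization -------------------------------------------------------

    def to_newick(
        self,
        lengths: bool = True,
        support: Mapping[frozenset[str], float] | None = None,
        precision: int = 6,
    ) -> str:
        """Serialize; internal-node labels carry support for the edge above."""
        if len(self.labels) == 1:
            (node,) = self.labels
            return f"{self.labels[node]};"
        root = next(n for n in sorted(self.adj) if n not in self.labels)
        ref = min(self.labels.values())
        all_leaves = frozenset(self.labels.values())

        def fmt(node: int, parent: int | None) -> str:
            if node in self.labels:
                s = self.labels[node]
            else:
                kids = [v for v in sorted(self.adj[node]) if v != parent]
                s = "(" + ",".join(fmt(k, node) for k in kids) + ")"
                if support is not None and parent is not None:
                    side = frozenset(self._leaves_behind(node, parent))
                    key = all_leaves - side if ref in side else side
                    if key in support:
                        s += f"{support[key]:.{4}f}"
            if lengths and parent is not None:
                s += f":{self.adj[parent][node]:.{precision}f}"
            return s

        return fmt(root, None) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({self.to_newick(lengths=False)})"


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Standard neighbor-joining agglomeration.

    Ties in the Q criterion are broken by the lowest (row, column) index
    pair, so the result is deterministic.  On additive matrices the
    generating topology is recovered exactly.  Negative branch-length
    estimates are clamped to zero.
    """
    if not dm.complete:
        raise ValueError("distance matrix has undefined (zero-overlap) entries")
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    D = dm.matrix.astype(float).copy()
    adj: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    labels = {i: t for i, t in enumerate(dm.taxa)}
    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (row, col) tie-break via argmin on the flattened matrix
        idx = int(np.argmin(np.round(Q, 12)))
        i_loc, j_loc = divmod(idx, m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = D[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = next_id
        next_id += 1
        newrow = 0.5 * (D[i, active] + D[j, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[u, active] = newrow
        D[active, u] = newrow
        D[u, u] = 0.0
        adj[u] = {}
        adj[u][i] = li
        adj[i][u] = li
        adj[u][j] = lj
        adj[j][u] = lj
        active = [a for a in active if a not in (i, j)] + [u]
    # final three-point join
    a, b, c = active
    u = next_id
    la = max(0.5 * (D[a, b] + D[a, c] - D[b, c]), 0.0)
    lb = max(0.5 * (D[a, b] + D[b, c] - D[a, c]), 0.0)
    lc = max(0.5 * (D[a, c] + D[b, c] - D[a, b]), 0.0)
    adj[u] = {}
    for node, ln in ((a, la), (b, lb), (c, lc)):
        adj[u][node] = ln
        adj[node][u] = ln
    return Tree(adj, labels)


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------


@dataclass
class GeneTreeSet:
    """Per-segment unrooted gene trees plus a log of skipped alignments."""

    trees: list[Tree] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (alignment id, reason)

    def __len__(self) -> int:
        return len(self.trees)


def build_gene_trees(alignments: Sequence[WindowedAlignment]) -> GeneTreeSet:
    """NJ gene tree per usable alignment; unusable ones skipped with reason.

    An alignment is unusable when a taxon pair has zero non-N overlap, when
    a pairwise mismatch proportion is JC69-saturated, or when all rows are
    identical (a star tree carries no topology).
    """
    out = GeneTreeSet()
    for i, aln in enumerate(alignments):
        ident = f"{aln.coords.contig}:{aln.coords.start}-{aln.coords.end}" if aln.coords else str(i)
        dm = pdistance(aln)
        if not dm.complete:
            out.skipped.append((ident, "zero-overlap pair"))
            continue
        if np.all(dm.matrix == 0):
            out.skipped.append((ident, "no variation (identical rows)"))
            continue
        try:
            corrected = jc69_correct(dm.matrix)
        except SaturationError:
            out.skipped.append((ident, "JC69 saturation"))
            continue
        np.fill_diagonal(corrected, 0.0)
        out.trees.append(neighbor_joining(DistanceMatrix(dm.taxa, corrected)))
    return out


# ---------------------------------------------------------------------------
# quartets
# ---------------------------------------------------------------------------


def _quartet_codes_for_tree(tree: Tree, taxa: list[str]) -> dict[tuple[int, int, int, int], int]:
    """Induced topology code for every 4-subset of ``taxa`` present in the
    tree.  Codes over the sorted quartet (a,b,c,d): 0 = ab|cd, 1 = ac|bd,
    2 = ad|bc; unresolved quartets are omitted."""
    present = [i for i, t in enumerate(taxa) if t in tree._name_to_node]
    names = [taxa[i] for i in present]
    topo = tree.leaf_distance_matrix(order=names, topological=True).matrix
    codes: dict[tuple[int, int, int, int], int] = {}
    for (ia, a), (ib, b), (ic, c), (id_, d) in itertools.combinations(enumerate(present), 4):
        s0 = topo[ia, ib] + topo[ic, id_]  # ab|cd
        s1 = topo[ia, ic] + topo[ib, id_]  # ac|bd
        s2 = topo[ia, id_] + topo[ib, ic]  # ad|bc
        sums = (s0, s1, s2)
        lo = min(sums)
        if sums.count(lo) != 1:
            continue  # unresolved (possible with zero-length display conventions)
        codes[(a, b, c, d)] = sums.index(lo)
    return codes


class QuartetTally:
    """Gene-tree quartet frequencies: for each 4-subset of the full taxon
    set, how many gene trees resolve it each of the three ways.

    Gene trees missing a leaf simply do not vote on quartets they do not
    span (intersection semantics)."""

    def __init__(self, gene_trees: Iterable[Tree], taxa: Sequence[str]):
        self.taxa = sorted(taxa)
        self.counts: dict[tuple[int, int, int, int], np.ndarray] = {
            q: np.zeros(3, dtype=np.int64)
            for q in itertools.combinations(range(len(self.taxa)), 4)
        }
        for tree in gene_trees:
            for q, code in _quartet_codes_for_tree(tree, self.taxa).items():
                self.counts[q][code] += 1

    def score(self, candidate: Tree) -> int:
        cand = _quartet_codes_for_tree(candidate, self.taxa)
        return int(sum(self.counts[q][code] for q, code in cand.items()))


def quartet_score(candidate: Tree, gene_trees: GeneTreeSet | Sequence[Tree]) -> int:
    """Total number of gene-tree quartets agreeing with the candidate."""
    trees = gene_trees.trees if isinstance(gene_trees, GeneTreeSet) else list(gene_trees)
    return QuartetTally(trees, candidate.leaves).score(candidate)


def enumerate_topologies(taxa: Sequence[str]) -> Iterable[Tree]:
    """All (2n-5)!! unrooted binary topologies over ``taxa`` (unit lengths)."""
    taxa = sorted(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")

    def grow(tree: Tree, remaining: list[str], next_label_id: list[int]):
        if not remaining:
            yield tree
            return
        name = remaining[0]
        edges = []
        seen = set()
        for u in sorted(tree.adj):
            for v in sorted(tree.adj[u]):
                if (v, u) not in seen:
                    seen.add((u, v))
                    edges.append((u, v))
        for u, v in edges:
            t = tree.copy()
            mid = next_label_id[0]
            leaf = mid + 1
            ln = t.adj[u].pop(v)
            del t.adj[v][u]
            t.adj[mid] = {u: ln / 2, v: ln / 2, leaf: 1.0}
            t.adj[u][mid] = ln / 2
            t.adj[v][mid] = ln / 2
            t.adj[leaf] = {mid: 1.0}
            t.labels[leaf] = name
            t._name_to_node[name] = leaf
            next_label_id[0] += 2
            yield from grow(t, remaining[1:], next_label_id)
            next_label_id[0] -= 2

    base_adj: dict[int, dict[int, float]] = {3: {0: 1.0, 1: 1.0, 2: 1.0}}
    for i in range(3):
        base_adj[i] = {3: 1.0}
    base = Tree(base_adj, {i: taxa[i] for i in range(3)})
    yield from grow(base, list(taxa[3:]), [100])


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


@dataclass
class SpeciesTreeResult:
    """Quartet-consensus topology with per-branch quartet support."""

    tree: Tree
    support: dict[frozenset[str], float]  # canonical bipartition -> support in [0, 1]
    quartet_score: int
    mode: str

    def newick(self) -> str:
        return self.tree.to_newick(lengths=False, support=self.support)


EXHAUSTIVE_LEAF_LIMIT = 7


def infer_species_tree(
    gene_trees: GeneTreeSet | Sequence[Tree],
    mode: str = "auto",
    start_tree: Tree | None = None,
) -> SpeciesTreeResult:
    """Maximize the quartet score over species-tree topologies.

    ``mode`` is ``"exhaustive"`` (all unrooted topologies; leaf sets up to
    7), ``"greedy"`` (NNI hill climb from ``start_tree`` or, by default,
    from the NJ tree of gene-tree-averaged path distances), or ``"auto"``
    (exhaustive when the leaf set allows it).
    """
    trees = gene_trees.trees if isinstance(gene_trees, GeneTreeSet) else list(gene_trees)
    if not trees:
        raise ValueError("no gene trees")
    taxa = sorted(set().union(*(set(t.leaves) for t in trees)))
    if len(taxa) < 4:
        raise ValueError("need at least 4 leaves to infer a species tree")
    if mode == "auto":
        mode = "exhaustive" if len(taxa) <= EXHAUSTIVE_LEAF_LIMIT else "greedy"
    tally = QuartetTally(trees, taxa)

    if mode == "exhaustive":
        if len(taxa) > EXHAUSTIVE_LEAF_LIMIT:
            raise ValueError(f"exhaustive mode limited to {EXHAUSTIVE_LEAF_LIMIT} leaves")
        best, best_score = None, -1
        for cand in enumerate_topologies(taxa):
            s = tally.score(cand)
            if s > best_score:
                best, best_score = cand.copy(), s
    elif mode == "greedy":
        current = start_tree.copy() if start_tree is not None else _average_distance_nj(trees, taxa)
        best_score = tally.score(current)
        improved = True
        while improved:
            improved = False
            for nb in current.nni_neighbors():
                s = tally.score(nb)
                if s > best_score:
                    current, best_score = nb, s
                    improved = True
                    break
        best = current
    else:
        raise ValueError(f"unknown mode {mode!r}")

    support = _branch_support(best, tally)
    return SpeciesTreeResult(tree=best, support=support, quartet_score=best_score, mode=mode)


def _average_distance_nj(trees: Sequence[Tree], taxa: list[str]) -> Tree:
    """NJ on path-length distances averaged across the gene trees."""
    n = len(taxa)
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for t in trees:
        present = [i for i, name in enumerate(taxa) if name in t._name_to_node]
        sub = t.leaf_distance_matrix(order=[taxa[i] for i in present]).matrix
        total[np.ix_(present, present)] += sub
        count[np.ix_(present, present)] += 1
    np.fill_diagonal(count, 1)
    if np.any(count == 0):
        raise ValueError("some taxon pair appears in no gene tree")
    avg = total / count
    np.fill_diagonal(avg, 0.0)
    return neighbor_joining(DistanceMatrix(taxa, avg))


def _branch_support(tree: Tree, tally: QuartetTally) -> dict[frozenset[str], float]:
    """Per-internal-branch agreement fraction among spanning quartets.

    A quartet spans a branch A|B when it takes two leaves from each side;
    the branch resolves it as (a1,a2 | b1,b2).  Support is agreeing
    gene-tree quartet votes over all resolved votes on spanning quartets.
    """
    taxa = tally.taxa
    index = {t: i for i, t in enumerate(taxa)}
    support: dict[frozenset[str], float] = {}
    all_leaves = set(taxa)
    for side, _edge in tree.bipartitions().items():
        a_side = sorted(index[t] for t in side)
        b_side = sorted(index[t] for t in all_leaves - side)
        agree = 0
        total = 0
        for a1, a2 in itertools.combinations(a_side, 2):
            for b1, b2 in itertools.combinations(b_side, 2):
                q = tuple(sorted((a1, a2, b1, b2)))
                counts = tally.counts[q]
                # which code corresponds to pairing (a1,a2)|(b1,b2)?
                sq = sorted((a1, a2, b1, b2))
                first = sq[0]
                partner = a2 if first == a1 else (a1 if first == a2 else (b2 if first == b1 else b1))
                others = [x for x in sq if x not in (first, partner)]
                rank = sorted([x for x in sq if x != first]).index(partner)
                agree += int(counts[rank])
                total += int(counts.sum())
        support[side] = (agree / total) if total else math.nan
    return support


def is_monophyletic(tree: Tree, group: Sequence[str]) -> bool:
    """True when ``group`` forms one side of a bipartition of the unrooted
    tree (or is trivially a single leaf / the complement of one)."""
    group_set = frozenset(group)
    leaves = frozenset(tree.leaves)
    if not group_set <= leaves:
        raise ValueError("group contains unknown leaves")
    if len(group_set) <= 1 or len(leaves - group_set) <= 1:
        return True
    splits = set(tree.bipartitions())
    ref = min(leaves)
    key = leaves - group_set if ref in group_set else group_set
    return key in splits


def read_gene_trees(path) -> GeneTreeSet:
    """Load externally computed gene trees from a multi-line Newick file."""
    out = GeneTreeSet()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.trees.append(Tree.from_newick(line))
    return out


def write_gene_trees(gts: GeneTreeSet, path) -> None:
    with open(path, "w") as fh:
        for t in gts.trees:
            fh.write(t.to_newick() + "\n")
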