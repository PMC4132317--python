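"""Distance-based trees for HORMA-domain protein families.

Pipeline: optimal pairwise local alignments give mismatch fractions
``p`` (1 - identity over aligned columns); the Grishin correction maps
``p`` to the expected number of substitutions per site ``d`` under
among-site rate variation, via the defining equation

    1 - p = ln(1 + 2 d) / (2 d)

a neighbor-joining topology is built from ``d`` and refined by
nearest-neighbor interchanges under the balanced minimum-evolution
criterion (Pauplin tree length), and unalignable sequences are dropped
automatically beforehand (best bit score below a floor against every
family member, or insufficient aligned coverage).

Because distances come from pairwise local alignments rather than a
multiple alignment, tree topologies for real families are qualitative
reproductions, not exact ones.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from .pairwise_align import ScoringScheme, local_align, percent_identity
from .seqio import ProteinRecord

UNDEFINED = math.inf


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Pairwise mismatch fractions, corrected distances and coverages."""

    ids: list[str]
    p: np.ndarray         # mismatch fraction in [0,1]; nan where undefined
    d: np.ndarray         # Grishin distance; inf where undefined
    coverage: np.ndarray  # aligned span / shorter sequence length

    def size(self) -> int:
        return len(self.ids)

    def finite(self) -> bool:
        return bool(np.isfinite(self.d).all())

    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP square distance-matrix format (corrected distances)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{self.d[i, j]:.6f}" for j in range(len(self.ids)))
                fh.write(f"{name[:10]:<10} {row}\n")


def grishin_distance(p: float) -> float:
    """Expected substitutions per site given mismatch fraction ``p``.

    Unique d >= 0 solving 1 - p = ln(1 + 2d)/(2d); solved numerically
    to |delta q| <= 1e-10.  p = 1 maps to the infinity marker.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("mismatch fraction must be in [0, 1]")
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return UNDEFINED

    q = 1.0 - p

    def f(d: float) -> float:
        return math.log1p(2.0 * d) / (2.0 * d) - q

    lo = 1e-12
    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - p would have to be ~1
            return UNDEFINED
    return float(brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200))


def pairwise_p(records: list[ProteinRecord], scheme: ScoringScheme) -> DistanceMatrix:
    """Mismatch fractions and coverages from optimal pairwise local
    alignments; fills ``d`` with the Grishin correction."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    n = len(records)
    p = np.zeros((n, n))
    cov = np.ones((n, n))
    for i, j in itertools.combinations(range(n), 2):
        res = local_align(records[i], records[j], scheme)
        if res.n_aligned == 0:
            p[i, j] = p[j, i] = np.nan
            cov[i, j] = cov[j, i] = 0.0
            continue
        pij = 1.0 - percent_identity(res)
        p[i, j] = p[j, i] = pij
        span = res.q_span[1] - res.q_span[0]
        cov[i, j] = cov[j, i] = span / min(len(records[i].seq), len(records[j].seq))
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = UNDEFINED if np.isnan(p[i, j]) else grishin_distance(p[i, j])
    return DistanceMatrix(ids=[r.id for r in records], p=p, d=d, coverage=cov)


def exclude_unalignable(
    records: list[ProteinRecord],
    scheme: ScoringScheme,
    min_coverage: float = 0.3,
    min_bits: float = 50.0,
) -> tuple[list[ProteinRecord], list[tuple[str, str]]]:
    """Drop records that align to no other family member.

    A record is excluded when its best bit score against every other
    record is below ``min_bits`` or its best aligned coverage is below
    ``min_coverage``.  Mirrors the automatic outlier removal of the
    reference tree pipeline; returns (kept, [(id, reason), ...]).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    n = len(records)
    best_bits = np.zeros(n)
    best_cov = np.zeros(n)
    for i, j in itertools.combinations(range(n), 2):
        res = local_align(records[i], records[j], scheme)
        denom = min(len(records[i].seq), len(records[j].seq))
        best_bits[i] = max(best_bits[i], res.bit_score)
        best_bits[j] = max(best_bits[j], res.bit_score)
        best_cov[i] = max(best_cov[i], (res.q_span[1] - res.q_span[0]) / denom)
        best_cov[j] = max(best_cov[j], (res.s_span[1] - res.s_span[0]) / denom)
    kept: list[ProteinRecord] = []
    excluded: list[tuple[str, str]] = []
    for idx, rec in enumerate(records):
        if best_bits[idx] < min_bits:
            excluded.append((rec.id, f"best bit score {best_bits[idx]:.1f} < {min_bits}"))
        elif best_cov[idx] < min_coverage:
            excluded.append((rec.id, f"best coverage {best_cov[idx]:.2f} < {min_coverage}"))
        else:
            kept.append(rec)
    if len(kept) < 3:
        raise ValueError(
            f"only {len(kept)} alignable records remain; no tree possible "
            f"(excluded: {[e[0] for e in excluded]})"
        )
    return kept, excluded


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Unrooted tree over the retained ids, plus exclusion records."""

    tree: TreeNode
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path))


def nj_topology(D: DistanceMatrix) -> PhyloTree:
    """Standard neighbor joining on the corrected distances.

    Negative branch lengths are clamped to zero.  Distances must all be
    finite: run :func:`exclude_unalignable` first otherwise.
    """
    if D.size() < 3:
        raise ValueError("need at least 3 leaves")
    if not D.finite():
        bad = [
            (D.ids[i], D.ids[j])
            for i, j in itertools.combinations(range(D.size()), 2)
            if not np.isfinite(D.d[i, j])
        ]
        raise ValueError(f"undefined distances present (exclude first): {bad}")
    if D.size() == 3:
        # closed-form three-point lengths around a single internal node
        a, b, c = D.d[0, 1], D.d[0, 2], D.d[1, 2]
        lens = [(a + b - c) / 2.0, (a + c - b) / 2.0, (b + c - a) / 2.0]
        root = TreeNode(name=None)
        for name, ln in zip(D.ids, lens):
            root.append(TreeNode(name=name, length=max(0.0, ln)))
        return PhyloTree(tree=root)
    sk = SkbioDM(D.d, ids=D.ids)
    tree = _skbio_nj(sk)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return PhyloTree(tree=tree)


# --- internal adjacency representation for balanced-ME refinement ---------

def _tree_to_adj(tree: TreeNode) -> tuple[dict, dict]:
    """skbio TreeNode -> (adjacency dict, edge length dict).

    Degree-2 nodes (e.g. a rooted representation's root) are
    suppressed.  Leaf keys are leaf names; internal keys are ints.
    """
    adj: dict = {}
    lengths: dict = {}
    counter = itertools.count()
    keys: dict = {}

    def key_of(node: TreeNode):
        nid = id(node)
        if nid not in keys:
            keys[nid] = node.name if node.is_tip() else next(counter)
        return keys[nid]

    def add_edge(u, v, ln):
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
        lengths[frozenset((u, v))] = ln

    for node in tree.traverse(include_self=True):
        for child in node.children:
            ln = child.length if child.length is not None else 0.0
            add_edge(key_of(node), key_of(child), ln)

    # suppress degree-2 internal nodes
    changed = True
    while changed:
        changed = False
        for u in list(adj):
            if isinstance(u, int) and len(adj[u]) == 2:
                a, b = adj[u]
                la = lengths.pop(frozenset((u, a)))
                lb = lengths.pop(frozenset((u, b)))
                adj[a].discard(u)
                adj[b].discard(u)
                adj[a].add(b)
                adj[b].add(a)
                lengths[frozenset((a, b))] = la + lb
                del adj[u]
                changed = True
    return adj, lengths


def _adj_to_tree(adj: dict, lengths: dict) -> TreeNode:
    root_key = next(k for k in adj if isinstance(k, int))

    def build(u, parent) -> TreeNode:
        node = TreeNode(name=u if isinstance(u, str) else None)
        if parent is not None:
            node.length = lengths.get(frozenset((u, parent)), 0.0)
        for v in sorted(adj[u], key=str):
            if v != parent:
                node.append(build(v, u))
        return node

    return build(root_key, None)


def _leaf_path_lengths(adj: dict) -> dict[tuple[str, str], int]:
    """Topological (edge-count) distances between all leaf pairs."""
    leaves = sorted(k for k in adj if isinstance(k, str))
    out: dict[tuple[str, str], int] = {}
    for leaf in leaves:
        dist = {leaf: 0}
        stack = [leaf]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    stack.append(v)
        for other in leaves:
            if other > leaf:
                out[(leaf, other)] = dist[other]
    return out


def balanced_length(adj: dict, D: DistanceMatrix) -> float:
    """Pauplin's balanced minimum-evolution tree length:
    sum over leaf pairs of D_ij * 2^(1 - topological distance)."""
    idx = {name: i for i, name in enumerate(D.ids)}
    total = 0.0
    for (a, b), k in _leaf_path_lengths(adj).items():
        total += D.d[idx[a], idx[b]] * 2.0 ** (1 - k)
    return total


def _nni_candidates(adj: dict):
    """Yield (u, v, x, y): swap subtree x (neighbor of u) with y (of v)."""
    for u in adj:
        if isinstance(u, str):
            continue
        for v in adj[u]:
            if isinstance(v, str) or u > v:
                continue
            nu = sorted((w for w in adj[u] if w != v), key=str)
            nv = sorted((w for w in adj[v] if w != u), key=str)
            if len(nu) < 2 or len(nv) < 2:
                continue
            yield (u, v, nu[1], nv[0])
            yield (u, v, nu[1], nv[1])


def _apply_nni(adj: dict, u, v, x, y) -> None:
    adj[u].discard(x)
    adj[x].discard(u)
    adj[v].discard(y)
    adj[y].discard(v)
    adj[u].add(y)
    adj[y].add(u)
    adj[v].add(x)
    adj[x].add(v)


def _ols_branch_lengths(adj: dict, D: DistanceMatrix) -> dict:
    """Ordinary least-squares branch lengths for a fixed topology,
    clamped at zero."""
    edges = sorted({frozenset((u, v)) for u in adj for v in adj[u]}, key=lambda e: sorted(map(str, e)))
    eidx = {e: i for i, e in enumerate(edges)}
    leaves = sorted(k for k in adj if isinstance(k, str))
    idx = {name: i for i, name in enumerate(D.ids)}
    rows = []
    rhs = []
    for a, b in itertools.combinations(leaves, 2):
        # path a -> b
        parent = {a: None}
        stack = [a]
        while stack:
            uu = stack.pop()
            for vv in adj[uu]:
                if vv not in parent:
                    parent[vv] = uu
                    stack.append(vv)
        row = np.zeros(len(edges))
        node = b
        while parent[node] is not None:
            row[eidx[frozenset((node, parent[node]))]] = 1.0
            node = parent[node]
        rows.append(row)
        rhs.append(D.d[idx[a], idx[b]])
    sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    return {e: max(0.0, float(sol[i])) for e, i in eidx.items()}


def me_refine(tree: PhyloTree, D: DistanceMatrix) -> PhyloTree:
    """Nearest-neighbor-interchange hill climb under balanced minimum
    evolution (Pauplin length); best improvement per sweep, stops at a
    local optimum.  The balanced length never increases; branch lengths
    of the refined topology are re-fit by ordinary least squares."""
    adj, _ = _tree_to_adj(tree.tree)
    current = balanced_length(adj, D)
    while True:
        best_move = None
        best_len = current
        for u, v, x, y in _nni_candidates(adj):
            _apply_nni(adj, u, v, x, y)
            cand = balanced_length(adj, D)
            _apply_nni(adj, u, v, y, x)  # undo
            if cand < best_len - 1e-12:
                best_len = cand
                best_move = (u, v, x, y)
        if best_move is None:
            break
        _apply_nni(adj, *best_move)
        assert best_len <= current + 1e-12, "balanced length increased"
        current = best_len
    lengths = _ols_branch_lengths(adj, D)
    return PhyloTree(tree=_adj_to_tree(adj, lengths), excluded=list(tree.excluded))


def topology_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, canonicalized as
    the side not containing the lexicographically smallest leaf."""
    adj, _ = _tree_to_adj(tree)
    leaves = sorted(k for k in adj if isinstance(k, str))
    ref = leaves[0]
    splits: set[frozenset[str]] = set()
    seen_edges = {frozenset((u, v)) for u in adj for v in adj[u]}
    for edge in seen_edges:
        u, v = tuple(edge)
        # leaves on v's side when edge removed
        side = set()
        stack = [v]
        visited = {u, v}
        while stack:
            w = stack.pop()
            if isinstance(w, str):
                side.add(w)
            for z in adj[w]:
                if z not in visited:
                    visited.add(z)
                    stack.append(z)
        if ref in side:
            side = set(leaves) - side
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(frozenset(side))
    return splits


def build_tree(
    records: list[ProteinRecord],
    scheme: ScoringScheme,
    min_coverage: float = 0.3,
    min_bits: float = 50.0,
    refine: bool = True,
) -> tuple[PhyloTree, DistanceMatrix]:
    """Full family pipeline: exclusion, distances, NJ, balanced-ME NNI."""
    kept, excluded = exclude_unalignable(records, scheme, min_coverage, min_bits)
    D = pairwise_p(kept, scheme)
    tree = nj_topology(D)
    tree.excluded = excluded
    if refine:
        tree = me_refine(tree, D)
    return tree, D
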