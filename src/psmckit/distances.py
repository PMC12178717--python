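"""Distance matrices from pseudo-diploid heterozygosities and NJ trees.

The genome-wide heterozygosity of a pseudo-diploid of individuals i and j is
an uncorrected per-site distance p(i,j).  Multiple substitutions are corrected
either by the Jukes–Cantor transform d = −(3/4)·ln(1 − (4/3)p) (default) or by
the pure Poisson transform d = −ln(1 − p); at the distance scale of closely
related genomes (p ~ 0.005) the two differ by well under one part in a
thousand and yield identical tree topologies.

Neighbor joining follows the canonical Saitou–Nei algorithm: iteratively join
the pair minimising Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), with
ties broken by the lowest (i,j) index pair, branch lengths from the standard
split formula, and the final three clusters joined at a trifurcating node.
Negative branch lengths are retained (not clamped) so that exactly additive
input matrices are reproduced exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .formats import format_length, quote_label
from .hetstats import HetSummary


def correct_distance(p: float, method: str = "jc") -> float:
    """Correct an observed per-site difference proportion for multiple hits."""
    if p < 0:
        raise ValueError(f"p must be >= 0, got {p}")
    if method == "jc":
        if p >= 0.75:
            raise ValueError(f"Jukes–Cantor correction undefined for p >= 0.75 "
                             f"(got {p})")
        return -0.75 * math.log1p(-4.0 * p / 3.0)
    if method == "poisson":
        if p >= 1.0:
            raise ValueError(f"Poisson correction undefined for p >= 1 (got {p})")
        return -math.log1p(-p)
    raise ValueError(f"unknown correction method {method!r} "
                     "(expected 'jc' or 'poisson')")


@dataclass
class DistanceMatrix:
    """Symmetric uncorrected (p) and corrected (d) distances over taxa."""

    taxa: list[str]
    p: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        for name, m in (("p", self.p), ("d", self.d)):
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.diagonal(m).any():
                raise ValueError(f"{name} must have a zero diagonal")


def build_matrix(pairwise: Mapping[tuple[str, str], "HetSummary | float"],
                 method: str = "jc") -> DistanceMatrix:
    """Assemble the distance matrix from pseudo-diploid pair heterozygosities.

    Keys are unordered taxon pairs (either orientation accepted, but a pair
    supplied twice with conflicting values is rejected); values are the
    pair's HetSummary or its plain heterozygosity.
    """
    canonical: dict[frozenset, float] = {}
    taxa_set: set[str] = set()
    for (a, b), v in pairwise.items():
        if a == b:
            raise ValueError(f"self-pair ({a!r}, {b!r}) not allowed")
        value = v.heterozygosity if isinstance(v, HetSummary) else float(v)
        key = frozenset((a, b))
        if key in canonical and not math.isclose(canonical[key], value,
                                                 rel_tol=0, abs_tol=0):
            raise ValueError(f"conflicting values for pair {sorted(key)}: "
                             f"{canonical[key]} vs {value}")
        canonical[key] = value
        taxa_set.update((a, b))
    taxa = sorted(taxa_set)
    n = len(taxa)
    missing = [(taxa[i], taxa[j]) for i in range(n) for j in range(i + 1, n)
               if frozenset((taxa[i], taxa[j])) not in canonical]
    if missing:
        raise ValueError(f"missing pairs: {missing}")
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p[i, j] = p[j, i] = canonical[frozenset((taxa[i], taxa[j]))]
    d = np.zeros_like(p)
    iu = np.triu_indices(n, k=1)
    d[iu] = [correct_distance(x, method) for x in p[iu]]
    d += d.T
    return DistanceMatrix(taxa=taxa, p=p, d=d)


class UnrootedTree:
    """Unrooted binary tree with branch lengths and a trifurcating root node.

    Stored as an adjacency map; node ids 0..n_leaves−1 are leaves in the order
    of ``leaves``.
    """

    def __init__(self, leaves: list[str]) -> None:
        self.leaves = list(leaves)
        self.adj: dict[int, list[tuple[int, float]]] = {
            i: [] for i in range(len(leaves))}
        self._next = len(leaves)
        self.root: int | None = None
        self.negative_branches: list[tuple[int, int, float]] = []

    def new_node(self) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = []
        return nid

    def add_edge(self, a: int, b: int, length: float) -> None:
        if not math.isfinite(length):
            raise ValueError(f"non-finite branch length on edge ({a},{b})")
        self.adj[a].append((b, length))
        self.adj[b].append((a, length))
        if length < 0:
            self.negative_branches.append((a, b, length))

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for a, nbrs in self.adj.items():
            for b, ln in nbrs:
                if a < b:
                    out.append((a, b, ln))
        return sorted(out)

    def _subtree_newick(self, node: int, parent: int) -> str:
        children = [(b, ln) for b, ln in self.adj[node] if b != parent]
        if not children:
            return quote_label(self.leaves[node])
        inner = ",".join(f"{self._subtree_newick(b, node)}:{format_length(ln)}"
                         for b, ln in children)
        return f"({inner})"

    def to_newick(self) -> str:
        root = self.root if self.root is not None else \
            max(self.adj, key=lambda n: len(self.adj[n]))
        inner = ",".join(f"{self._subtree_newick(b, root)}:{format_length(ln)}"
                         for b, ln in self.adj[root])
        return f"({inner});"


def neighbor_joining(m: DistanceMatrix, which: str = "corrected") -> UnrootedTree:
    """Saitou–Nei neighbor joining on the corrected (or raw) distance matrix."""
    if which == "corrected":
        dist = m.d.astype(float).copy()
    elif which == "uncorrected":
        dist = m.p.astype(float).copy()
    else:
        raise ValueError(f"which must be 'corrected' or 'uncorrected', got {which!r}")
    n = len(m.taxa)
    if n < 3:
        raise ValueError(f"neighbor joining requires >= 3 taxa, got {n}")

    tree = UnrootedTree(m.taxa)
    active: list[int] = list(range(n))       # tree-node id per active cluster

    while len(active) > 3:
        k = len(active)
        row_sum = dist.sum(axis=1)
        q = (k - 2) * dist - row_sum[:, None] - row_sum[None, :]
        # evaluate Q on the upper triangle only; lowest (i, j) index pair
        # among the minima, for determinism
        iu, ju = np.triu_indices(k, 1)
        qvals = q[iu, ju]
        qmin = qvals.min()
        pos = int(np.flatnonzero(qvals == qmin)[0])  # (i,j) lexicographic
        i, j = int(iu[pos]), int(ju[pos])

        li = 0.5 * dist[i, j] + (row_sum[i] - row_sum[j]) / (2.0 * (k - 2))
        lj = dist[i, j] - li
        parent = tree.new_node()
        tree.add_edge(parent, active[i], li)
        tree.add_edge(parent, active[j], lj)

        new_d = 0.5 * (dist[i] + dist[j] - dist[i, j])
        keep = [x for x in range(k) if x not in (i, j)]
        nd = np.empty((k - 1, k - 1))
        nd[:-1, :-1] = dist[np.ix_(keep, keep)]
        nd[-1, :-1] = nd[:-1, -1] = new_d[keep]
        nd[-1, -1] = 0.0
        dist = nd
        active = [active[x] for x in keep] + [parent]

    # join the last three clusters at a trifurcating node
    a, b, c = active
    dab, dac, dbc = dist[0, 1], dist[0, 2], dist[1, 2]
    root = tree.new_node()
    tree.add_edge(root, a, 0.5 * (dab + dac - dbc))
    tree.add_edge(root, b, 0.5 * (dab + dbc - dac))
    tree.add_edge(root, c, 0.5 * (dac + dbc - dab))
    tree.root = root
    return tree
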