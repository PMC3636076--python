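"""Binary band coding, Jaccard dissimilarity, Neighbor-joining, duplicates.

SSR polymorphisms are treated as dominant binary data: one column per
observed (locus, allele size) band, presence/absence per accession, with a
whole locus marked missing when it failed to amplify. Pairwise Jaccard
dissimilarity ignores joint absences and uses pairwise deletion for
missing loci. The phenogram is built by saturated Neighbor-joining with
deterministic tie-breaking (lowest index pair) and negative branch lengths
clamped to zero with the deficit moved onto the sister edge, so additive
input distances are reproduced exactly.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from musadiv.pipeline_io import GenotypeTable

log = logging.getLogger("musadiv")


@dataclass
class BinaryMatrix:
    """Accessions x (locus, allele) bands; entries 1/0/NaN (NaN = missing)."""

    accessions: list[str]
    locus_names: list[str]
    columns: list[tuple[str, int]]
    values: np.ndarray  # float, shape (n_accessions, n_columns)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")


def to_binary(table: GenotypeTable) -> BinaryMatrix:
    """Code a genotype table as presence/absence of every observed band."""
    if table.n_accessions == 0 or table.n_loci == 0:
        raise ValueError("empty genotype table")
    columns: list[tuple[str, int]] = []
    for j, locus in enumerate(table.locus_names):
        alleles = sorted({a for row in table.calls if row[j] is not None for a in row[j]})
        columns.extend((locus, a) for a in alleles)
    col_index = {col: c for c, col in enumerate(columns)}
    values = np.zeros((table.n_accessions, len(columns)))
    for i, row in enumerate(table.calls):
        for j, locus in enumerate(table.locus_names):
            cell = row[j]
            if cell is None:
                for locus2, a in columns:
                    if locus2 == locus:
                        values[i, col_index[(locus2, a)]] = np.nan
            else:
                for a in set(cell):
                    values[i, col_index[(locus, a)]] = 1.0
    return BinaryMatrix(list(table.accessions), list(table.locus_names), columns, values)


def jaccard_dissimilarity(binary: BinaryMatrix) -> DistanceMatrix:
    """Pairwise ``1 - a / (a + b + c)`` over mutually non-missing bands.

    ``a`` counts shared presences; ``b``/``c`` presences unique to either
    row; joint absences carry no signal and are ignored. Pairs with no
    mutually non-missing column are an error (no basis for comparison).
    """
    X = binary.values
    n = X.shape[0]
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = ~np.isnan(X[i]) & ~np.isnan(X[j])
        if not both.any():
            raise ValueError(
                f"no mutually non-missing bands for pair "
                f"({binary.accessions[i]}, {binary.accessions[j]})"
            )
        xi, xj = X[i, both], X[j, both]
        a = float(np.sum((xi == 1) & (xj == 1)))
        union = float(np.sum((xi == 1) | (xj == 1)))
        d[i, j] = d[j, i] = 1.0 - a / union if union else 0.0
    return DistanceMatrix(list(binary.accessions), d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saturated Neighbor-joining; returns an unrooted tree (trifurcating root).

    At each step the pair minimizing Q(i,j) = (m-2) d(i,j) - r_i - r_j is
    joined (ties: lowest index pair); branch lengths use the standard
    rate-corrected formulas, with negative lengths clamped to zero and the
    deficit transferred to the sister edge.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("Neighbor-joining requires at least 3 taxa")
    D = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dm.labels]
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> TreeNode:
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = li, lj
        return TreeNode(children=[ci, cj])

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best, pair = None, None
        for ai, aj in itertools.combinations(active, 2):
            q = (m - 2) * D[ai, aj] - r[ai] - r[aj]
            if best is None or q < best - 1e-12:
                best, pair = q, (ai, aj)
        i, j = pair
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            li, lj = 0.0, D[i, j]
        elif lj < 0:
            lj, li = 0.0, D[i, j]
        u = len(nodes)
        nodes.append(join(i, j, li, lj))
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k not in (i, j):
                D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for node, ln in zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)):
        node.length = max(ln, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    log.info("neighbor joining: %d taxa", n)
    return root


def edge_splits(tree: TreeNode) -> dict[frozenset[str], float]:
    """Map each edge's canonical leaf-side split to its branch length.

    The canonical side of a split is the one *not* containing the
    lexicographically smallest leaf, giving an orientation-free key for
    comparing unrooted trees.
    """
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    splits: dict[frozenset[str], float] = {}
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        if ref in side:
            side = leaves - side
        if side and side != leaves:
            splits[side] = splits.get(side, 0.0) + (node.length or 0.0)
    return splits


def detect_duplicates(dm: DistanceMatrix, tol: float = 0.0) -> list[list[str]]:
    """Groups of accessions with pairwise dissimilarity <= tol (transitive).

    Returns sorted groups of size >= 2; identical SSR profiles (d = 0)
    indicate putative duplicated accessions.
    """
    n = len(dm.labels)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(n), 2):
        if dm.values[i, j] <= tol:
            parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(dm.labels[i])
    return sorted([sorted(g) for g in groups.values() if len(g) > 1])
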