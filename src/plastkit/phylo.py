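"""Distance-based phylogeny: p-distance matrices and neighbor joining.

A light topology-level surface: uncorrected p-distances with pairwise
deletion, Saitou-Nei neighbor joining with deterministic tie-breaking,
and Newick round-tripping (via dendropy).  A column-resampling bootstrap
is provided for completeness; distance/NJ here is a desk-scale surrogate
for likelihood phylogenomics, aimed at clade-structure checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "p_distance_matrix",
    "nj_tree",
    "write_newick",
    "read_newick",
    "bootstrap_support",
]


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        self.matrix = m

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)


def p_distance_matrix(seqs: dict[str, str]) -> DistanceMatrix:
    """Uncorrected p-distances with pairwise deletion.

    ``seqs`` maps taxon id to an aligned row (equal lengths, gaps as
    ``-``); d_ij = mismatches / gap-free shared columns.
    """
    taxa = sorted(seqs)
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    lengths = {len(seqs[t]) for t in taxa}
    if len(lengths) != 1:
        raise ValueError("aligned rows differ in length")
    good = np.frombuffer(b"ACGT", dtype=np.uint8)
    arrs = {t: np.frombuffer(seqs[t].upper().encode(), dtype=np.uint8) for t in taxa}
    ok = {t: np.isin(arrs[t], good) for t in taxa}
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = ok[taxa[i]] & ok[taxa[j]]
            L = int(mask.sum())
            if L == 0:
                raise ValueError(f"{taxa[i]} and {taxa[j]} share no comparable columns")
            d = int(np.sum(arrs[taxa[i]][mask] != arrs[taxa[j]][mask])) / L
            m[i, j] = m[j, i] = d
    return DistanceMatrix(taxa=taxa, matrix=m)


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths, backed by a dendropy tree."""

    tree: dendropy.Tree
    negative_branches_clamped: bool = False

    @property
    def leaf_labels(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits as leaf-label sets (smaller side)."""
        labels = self.leaf_labels
        out = set()
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 1 < len(side) < len(labels) - 1:
                other = frozenset(labels - side)
                out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        if self.leaf_labels != other.leaf_labels:
            return False
        if self.bipartitions() != other.bipartitions():
            return False
        return abs(self.total_length() - other.total_length()) < 1e-9

    def total_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self.tree.preorder_edge_iter() if e.head_node
        )


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Deterministic: ties in Q are broken by the sorted labels of the
    candidate pair.  Negative branch lengths are clamped to zero and
    flagged on the returned tree.
    """
    taxa = list(d.taxa)
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    ns = dendropy.TaxonNamespace()
    nodes = {}
    labels = {}
    for t in taxa:
        taxon = dendropy.Taxon(label=t)
        ns.add_taxon(taxon)
        node = dendropy.Node(taxon=taxon)
        nodes[t] = node
        labels[t] = t  # sort key for tie-breaks: min leaf label in cluster
    dist: dict[tuple[str, str], float] = {}
    active = list(taxa)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            dist[(a, b)] = dist[(b, a)] = float(
                d.matrix[d.taxa.index(a), d.taxa.index(b)]
            )
    clamped = False
    counter = 0
    while len(active) > 3:
        r = len(active)
        totals = {a: sum(dist[(a, b)] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (r - 2) * dist[(a, b)] - totals[a] - totals[b]
                key = (q, *sorted((labels[a], labels[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = dist[(a, b)]
        la = 0.5 * dab + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = dab - la
        if la < 0 or lb < 0:
            clamped = True
            la, lb = max(la, 0.0), max(lb, 0.0)
        counter += 1
        new_id = f"__internal_{counter}"
        new_node = dendropy.Node()
        na, nb = nodes[a], nodes[b]
        new_node.add_child(na)
        new_node.add_child(nb)
        na.edge.length = la
        nb.edge.length = lb
        nodes[new_id] = new_node
        labels[new_id] = min(labels[a], labels[b])
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (dist[(a, c)] + dist[(b, c)] - dab)
            dist[(new_id, c)] = dist[(c, new_id)] = dc
        active = [c for c in active if c not in (a, b)] + [new_id]
    # join the final three nodes at an unrooted trifurcation
    a, b, c = sorted(active, key=lambda x: labels[x])
    la = 0.5 * (dist[(a, b)] + dist[(a, c)] - dist[(b, c)])
    lb = 0.5 * (dist[(a, b)] + dist[(b, c)] - dist[(a, c)])
    lc = 0.5 * (dist[(a, c)] + dist[(b, c)] - dist[(a, b)])
    if min(la, lb, lc) < 0:
        clamped = True
        la, lb, lc = max(la, 0.0), max(lb, 0.0), max(lc, 0.0)
    root = dendropy.Node()
    for node_id, ln in ((a, la), (b, lb), (c, lc)):
        child = nodes[node_id]
        root.add_child(child)
        child.edge.length = ln
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree=tree, negative_branches_clamped=clamped)


def write_newick(t: PhyloTree, path) -> None:
    if not list(t.tree.leaf_node_iter()):
        raise ValueError("cannot serialise an empty tree")
    with open(path, "w") as fh:
        fh.write(t.newick() + "\n")


def read_newick(path) -> PhyloTree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = False
    return PhyloTree(tree=tree)


def bootstrap_support(
    seqs: dict[str, str], replicates: int = 100, seed: int = 0
) -> dict[frozenset[str], float]:
    """Column-resampling bootstrap proportions for NJ bipartitions."""
    rng = np.random.default_rng(seed)
    taxa = sorted(seqs)
    ncols = len(seqs[taxa[0]])
    arrs = {t: np.frombuffer(seqs[t].upper().encode(), dtype=np.uint8) for t in taxa}
    counts: dict[frozenset[str], int] = {}
    for _ in range(replicates):
        idx = rng.integers(0, ncols, size=ncols)
        resampled = {t: arrs[t][idx].tobytes().decode() for t in taxa}
        try:
            tree = nj_tree(p_distance_matrix(resampled))
        except ValueError:
            continue
        for bp in tree.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    return {bp: c / replicates for bp, c in counts.items()}
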