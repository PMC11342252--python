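"""Alignment annotation and distance-based phylogenetics.

This module carries the recombination-detection machinery: per-column
physicochemical consensus of a protein MSA, uncorrected P-distance matrices,
a native neighbor-joining (NJ) implementation with documented tie-breaking,
Robinson-Foulds (RF) bipartition distances, and the segment-incongruence
test that compares trees built from disjoint alignment segments (e.g. the
4-REase core versus the Ulp1/SMT4 deubiquitinase segment of CifB).  A
nonzero RF distance between segment trees over the same sequences is the
operational signature of mosaicism produced by interlocus recombination.

NJ and RF are implemented natively so the incongruence test is
self-contained and deterministic; trees produced by external ML software can
be imported via newick.

Numerical conventions:

* P-distance: mismatches / compared columns, pairwise deletion of gapped
  columns.
* NJ: negative branch lengths are clamped to zero; ties in the Q criterion
  are broken by the lexicographically smallest (label, label) pair, where an
  internal node is labelled by its smallest descendant leaf.
* Consensus: gaps are excluded from the column denominator; the most
  specific category (smallest residue set, single residues first) whose
  member fraction meets the threshold wins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "MSA",
    "Tree",
    "Node",
    "DEFAULT_RESIDUE_CLASSES",
    "consensus_annotation",
    "p_distance_matrix",
    "nj_tree",
    "rf_distance",
    "conflicting_bipartitions",
    "SegmentTreePair",
    "segment_incongruence",
]

GAP = "-"
AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# MSA container
# ---------------------------------------------------------------------------

@dataclass
class MSA:
    """A protein multiple sequence alignment: equal-length rows, unique ids."""

    ids: list
    rows: list

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in MSA")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def slice(self, start: int, stop: int) -> "MSA":
        """Column slice, 0-based half-open."""
        if not (0 <= start < stop <= self.ncols):
            raise ValueError(f"empty or out-of-range segment [{start}, {stop})")
        return MSA(list(self.ids), [r[start:stop] for r in self.rows])

    @classmethod
    def from_fasta(cls, path) -> "MSA":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq))
        return cls(ids, rows)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, r in zip(self.ids, self.rows):
                fh.write(f">{i}\n{r}\n")


# ---------------------------------------------------------------------------
# Column consensus by physicochemical category
# ---------------------------------------------------------------------------

# Taylor-style residue classes; overlapping by design.  Shipped as data so
# users can edit or replace the scheme.
DEFAULT_RESIDUE_CLASSES: Dict[str, frozenset] = {
    "aliphatic": frozenset("ILV"),
    "aromatic": frozenset("FHWY"),
    "hydrophobic": frozenset("ACFGHIKLMTVWY"),
    "polar": frozenset("CDEHKNQRSTWY"),
    "positive": frozenset("HKR"),
    "negative": frozenset("DE"),
    "charged": frozenset("DEHKR"),
    "small": frozenset("ACDGNPSTV"),
    "tiny": frozenset("AGS"),
}


def consensus_annotation(msa: MSA, categories: Optional[Dict[str, frozenset]] = None,
                         threshold: float = 0.75) -> list:
    """Per-column consensus labels by physicochemical category.

    A column is labelled with the most specific category whose member
    fraction reaches ``threshold`` among non-gap residues (single-residue
    identity categories are implicit and most specific of all); columns with
    no qualifying category, or consisting entirely of gaps, get ``None``.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    cats = categories if categories is not None else DEFAULT_RESIDUE_CLASSES
    candidates = [(1, aa, frozenset(aa)) for aa in AA]
    candidates += [(len(members), name, frozenset(members)) for name, members in cats.items()]
    candidates.sort(key=lambda c: (c[0], c[1]))
    labels = []
    for col in range(msa.ncols):
        residues = [r[col] for r in msa.rows if r[col] != GAP]
        if not residues:
            labels.append(None)
            continue
        denom = len(residues)
        label = None
        for _, name, members in candidates:
            if sum(res in members for res in residues) / denom >= threshold:
                label = name
                break
        labels.append(label)
    return labels


# ---------------------------------------------------------------------------
# Uncorrected P-distances
# ---------------------------------------------------------------------------

def p_distance_matrix(msa: MSA) -> pd.DataFrame:
    """Uncorrected P-distance matrix with pairwise deletion of gaps.

    d(i, j) = mismatches / mutually ungapped columns.  A pair with zero
    comparable columns is an error (the distance is undefined).
    """
    if msa.nrows < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    arr = np.array([list(r) for r in msa.rows])
    ungapped = arr != GAP
    n = msa.nrows
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        comp = ungapped[i] & ungapped[j]
        total = int(comp.sum())
        if total == 0:
            raise ValueError(
                f"no comparable columns between {msa.ids[i]!r} and {msa.ids[j]!r}")
        mism = int((arr[i][comp] != arr[j][comp]).sum())
        d[i, j] = d[j, i] = mism / total
    return pd.DataFrame(d, index=list(msa.ids), columns=list(msa.ids))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class Node:
    """Tree node; ``length`` is the branch to the parent (0 at the root)."""

    __slots__ = ("label", "length", "children")

    def __init__(self, label: Optional[str] = None, length: float = 0.0,
                 children: Optional[list] = None):
        self.label = label
        self.length = float(length)
        self.children = children or []

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf():
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


class Tree:
    """An (effectively unrooted) tree with labelled leaves and branch lengths.

    Stored with an arbitrary root; all comparisons (bipartitions, RF) are
    root-invariant.  Newick serialization is deterministic: children are
    ordered by their smallest descendant leaf label.
    """

    def __init__(self, root: Node):
        self.root = root
        leaves = root.leaves()
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate leaf labels")

    # -- basic queries ---------------------------------------------------

    def leaf_set(self) -> frozenset:
        return frozenset(self.root.leaves())

    def bipartitions(self) -> frozenset:
        """Non-trivial bipartitions as canonical frozensets of leaf labels.

        Each edge splits the leaves in two; the side *not* containing the
        lexicographically smallest leaf is stored.  Trivial splits (single
        leaf vs rest) are omitted.  A degree-2 root contributes its edge
        once.
        """
        all_leaves = self.leaf_set()
        anchor = min(all_leaves)
        n = len(all_leaves)
        out = set()

        def walk(node: Node) -> frozenset:
            if node.is_leaf():
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= n - 2:
                side = all_leaves - below if anchor in below else below
                out.add(side)
            return below

        walk(self.root)
        return frozenset(out)

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""

        def chain(node, target, trail):
            trail = trail + [node]
            if node.is_leaf():
                return trail if node.label == target else None
            for c in node.children:
                r = chain(c, target, trail)
                if r is not None:
                    return r
            return None

        ca = chain(self.root, a, [])
        cb = chain(self.root, b, [])
        if ca is None or cb is None:
            raise KeyError(f"leaf not in tree: {a if ca is None else b}")
        common = 0
        for x, y in zip(ca, cb):
            if x is y:
                common += 1
            else:
                break
        return sum(n.length for n in ca[common:]) + sum(n.length for n in cb[common:])

    def relabel(self, mapping: Dict[str, str]) -> "Tree":
        """Return a copy with leaf labels swapped/renamed per ``mapping``."""

        def copy(node: Node) -> Node:
            if node.is_leaf():
                return Node(mapping.get(node.label, node.label), node.length)
            return Node(None, node.length, [copy(c) for c in node.children])

        return Tree(copy(self.root))

    # -- serialization ---------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf():
                return f"{node.label}:{node.length:.6g}"
            kids = sorted(node.children, key=lambda c: min(c.leaves()))
            inner = ",".join(fmt(c) for c in kids)
            return f"({inner}):{node.length:.6g}"

        kids = sorted(self.root.children, key=lambda c: min(c.leaves()))
        inner = ",".join(fmt(c) for c in kids)
        return f"({inner});"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        import dendropy

        dt = dendropy.Tree.get(data=text, schema="newick")

        def convert(dnode) -> Node:
            length = dnode.edge.length or 0.0
            if dnode.is_leaf():
                return Node(dnode.taxon.label.replace(" ", "_"), length)
            return Node(None, length, [convert(c) for c in dnode.child_nodes()])

        return cls(convert(dt.seed_node))


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: pd.DataFrame) -> Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Standard Saitou-Nei agglomeration.  Deterministic: ties in the Q
    criterion are broken by the smallest (label, label) pair, internal nodes
    inheriting their smallest descendant leaf label.  Negative branch
    lengths are clamped to zero.
    """
    labels = [str(x) for x in dm.index]
    D = np.asarray(dm, dtype=float).copy()
    if D.shape[0] != D.shape[1] or list(dm.columns.astype(str)) != labels:
        raise ValueError("distance matrix must be square with matching labels")
    if D.shape[0] < 3:
        raise ValueError("need at least 3 taxa for neighbor joining")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")

    nodes = [Node(lab) for lab in labels]
    keys = list(labels)  # smallest descendant leaf per active node

    while len(nodes) > 2:
        N = len(nodes)
        r = D.sum(axis=1)
        Q = (N - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=1e-12, atol=1e-12))
        pairs = {tuple(sorted((int(i), int(j)))) for i, j in cand}
        i, j = min(pairs, key=lambda p: tuple(sorted((keys[p[0]], keys[p[1]]))))
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (N - 2))
        lj = D[i, j] - li
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = max(0.0, li), max(0.0, lj)
        parent = Node(None, 0.0, [ni, nj])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(N) if k not in (i, j)]
        D2 = np.zeros((N - 1, N - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    a, b = nodes
    d = max(0.0, D[0, 1])
    a.length = b.length = d / 2
    return Tree(Node(None, 0.0, [a, b]))


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------

def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance: size of the bipartition symmetric difference."""
    if t1.leaf_set() != t2.leaf_set():
        raise ValueError("trees have different leaf sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


def conflicting_bipartitions(t1: Tree, t2: Tree) -> list:
    """The unshared bipartitions, as sorted tuples of leaf labels."""
    if t1.leaf_set() != t2.leaf_set():
        raise ValueError("trees have different leaf sets")
    diff = t1.bipartitions() ^ t2.bipartitions()
    return sorted(tuple(sorted(b)) for b in diff)


# ---------------------------------------------------------------------------
# Segment incongruence (recombination test)
# ---------------------------------------------------------------------------

@dataclass
class SegmentTreePair:
    """Trees from two alignment segments plus their topological conflict."""

    segments: tuple
    tree_a: Tree
    tree_b: Tree
    rf: int
    conflicting: list = field(default_factory=list)


def segment_incongruence(msa: MSA, segment_a: Tuple[int, int],
                         segment_b: Tuple[int, int]) -> SegmentTreePair:
    """Compare NJ trees built from two column segments of one alignment.

    Segments are 0-based half-open column ranges over the same sequence set.
    Each segment gets a P-distance NJ tree; the RF distance and the
    conflicting bipartitions quantify their incongruence.  RF > 0 indicates
    that the two segments carry discordant histories (mosaicism).
    """
    sub_a = msa.slice(*segment_a)
    sub_b = msa.slice(*segment_b)
    ta = nj_tree(p_distance_matrix(sub_a))
    tb = nj_tree(p_distance_matrix(sub_b))
    rf = rf_distance(ta, tb)
    return SegmentTreePair(
        segments=(tuple(segment_a), tuple(segment_b)),
        tree_a=ta,
        tree_b=tb,
        rf=rf,
        conflicting=conflicting_bipartitions(ta, tb),
    )
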