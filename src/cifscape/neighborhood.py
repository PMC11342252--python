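"""Gene neighborhoods of CIF dyads and conserved-family calling.

The unit of analysis is the CIF locus: a cifA-cifB dyad plus up to k
positional neighbor genes on each side (k = 15 by default).  Neighbor
proteins are grouped by single-linkage clustering on local-alignment
similarity (the grouping principle of BLASTCLUST), and clusters are called
conserved CIF-associated families by three criteria: proximity to the dyad,
persistence across at least two distinct CIF types, and sequence
diversification (within-cluster mean identity below a ceiling).

Neighborhoods never cross contig boundaries; circular wrapping is available
but off by default (draft-genome safety).  Clustering thresholds default to
identity >= 0.30 and coverage >= 0.80 of the shorter sequence — a
permissive family-level grouping; both are configurable, as is the
diversification ceiling (mean identity <= 0.90).

For large protein sets an optional shared-k-mer prefilter skips alignment
of pairs with fewer than a handful of shared 4-mers; unrelated random
proteins share essentially none, so the filter only prunes pairs that could
never reach the identity/coverage thresholds.  Pass ``prefilter=None`` to
force exhaustive all-vs-all alignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple
import warnings

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import Gene, Genome

__all__ = [
    "CifLocus",
    "FamilyCluster",
    "ConservedFamily",
    "extract_neighborhood",
    "dyad_locus",
    "pairwise_similarity",
    "SimilarityResult",
    "single_linkage_cluster",
    "conserved_neighbors",
]


# ---------------------------------------------------------------------------
# Loci
# ---------------------------------------------------------------------------

@dataclass
class CifLocus:
    """A dyad anchor plus its positional gene neighborhood.

    ``upstream``/``downstream`` are in genome order (upstream nearest-last,
    downstream nearest-first) and never include the dyad genes themselves.
    """

    genome_id: str
    cifB: str
    cifA: Optional[str] = None
    upstream: list = field(default_factory=list)
    downstream: list = field(default_factory=list)
    cif_type: Optional[str] = None

    @property
    def neighbors(self) -> list:
        return self.upstream + self.downstream

    def offsets(self) -> dict:
        """Gene id -> signed gene-count distance from the dyad.

        Immediate neighbors are at distance +-1.  Because the cifA partner
        is excluded from the neighbor lists, upstream offsets measure
        distance to the dyad as a unit, not to the cifB gene alone.
        """
        out = {}
        nup = len(self.upstream)
        for i, g in enumerate(self.upstream):
            out[g.id] = -(nup - i)
        for i, g in enumerate(self.downstream):
            out[g.id] = i + 1
        return out


def _window_indices(pos: int, n: int, k: int, wrap: bool) -> Tuple[list, list]:
    k = min(k, n - 1)
    if wrap:
        up = [(pos - j) % n for j in range(k, 0, -1)]
        down = []
        taken = set(up) | {pos}
        for j in range(1, k + 1):
            idx = (pos + j) % n
            if idx in taken:
                break
            down.append(idx)
        return up, down
    up = list(range(max(0, pos - k), pos))
    down = list(range(pos + 1, min(n, pos + k + 1)))
    return up, down


def extract_neighborhood(genome: Genome, anchor: Gene, k: int = 15,
                         wrap: bool = False) -> CifLocus:
    """Up to k positional neighbors on each side of an anchor gene.

    Truncated at contig ends for linear contigs; with ``wrap=True`` on a
    circular contig the window wraps around the origin but never duplicates
    a gene or revisits the anchor.
    """
    if anchor.id not in genome:
        raise KeyError(f"anchor {anchor.id} not in genome {genome.id}")
    contig_genes = genome.contig_genes(anchor.contig)
    pos = next(i for i, g in enumerate(contig_genes) if g.id == anchor.id)
    circular = genome.contig_topology(anchor.contig) == "circular"
    up, down = _window_indices(pos, len(contig_genes), k, wrap and circular)
    return CifLocus(
        genome_id=genome.id,
        cifB=anchor.id,
        upstream=[contig_genes[i] for i in up],
        downstream=[contig_genes[i] for i in down],
    )


def dyad_locus(genome: Genome, cifB_id: str, cifA_id: Optional[str] = None,
               k: int = 15, wrap: bool = False,
               cif_type: Optional[str] = None) -> CifLocus:
    """Neighborhood of a curated dyad; the cifA partner is excluded from the
    neighbor lists (the dyad is the query, not its own neighbor)."""
    locus = extract_neighborhood(genome, genome.get(cifB_id), k=k, wrap=wrap)
    locus.cifA = cifA_id
    locus.cif_type = cif_type
    if cifA_id is not None:
        locus.upstream = [g for g in locus.upstream if g.id != cifA_id]
        locus.downstream = [g for g in locus.downstream if g.id != cifA_id]
    return locus


# ---------------------------------------------------------------------------
# Pairwise similarity
# ---------------------------------------------------------------------------

class SimilarityResult(NamedTuple):
    score: float
    identity: float
    coverage: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_similarity(a: str, b: str) -> SimilarityResult:
    """Local-alignment similarity between two proteins.

    BLOSUM62, gap open -11 / extend -1.  Identity is identities over aligned
    columns; coverage is the aligned span of the *shorter* sequence over its
    length.  Symmetric in (a, b); a pair with no positive-scoring local
    alignment scores (0, 0, 0).
    """
    if not a or not b:
        raise ValueError("empty sequence in pairwise_similarity")
    # canonical order makes the result manifestly symmetric
    x, y = sorted((a, b), key=lambda s: (len(s), s))
    score = _ALIGNER.score(x, y)
    if score <= 0:
        return SimilarityResult(float(score), 0.0, 0.0)
    aln = _ALIGNER.align(x, y)[0]
    counts = aln.counts()
    length = aln.length
    identity = counts.identities / length if length else 0.0
    # span of the shorter sequence (x) covered by the local alignment
    blocks = aln.aligned[0]
    span = sum(int(e - s) for s, e in blocks)
    coverage = span / len(x)
    return SimilarityResult(float(score), identity, coverage)


def _kmer_set(seq: str, k: int = 4) -> frozenset:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


# ---------------------------------------------------------------------------
# Single-linkage clustering
# ---------------------------------------------------------------------------

@dataclass
class FamilyCluster:
    """One single-linkage protein family; representative is the longest
    member (ties: lexicographically smallest id)."""

    members: list
    representative: str
    annotation: str = ""


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def single_linkage_cluster(proteins: Dict[str, str], min_identity: float = 0.30,
                           min_coverage: float = 0.80,
                           prefilter: Optional[int] = 3) -> list:
    """Single-linkage families over a protein set.

    Two proteins are linked iff identity >= min_identity and coverage >=
    min_coverage; clusters are the connected components, so families chain
    through intermediates exactly as in BLASTCLUST.  The output is a
    partition of the input, independent of input order.  ``prefilter`` is
    the minimum number of shared 4-mers required before a pair is aligned
    (None disables the heuristic).
    """
    ids = sorted(proteins)
    uf = _UnionFind(ids)
    kmers = {i: _kmer_set(proteins[i]) for i in ids} if prefilter is not None else None
    for a, b in itertools.combinations(ids, 2):
        if uf.find(a) == uf.find(b):
            continue
        if kmers is not None and len(kmers[a] & kmers[b]) < prefilter:
            continue
        sim = pairwise_similarity(proteins[a], proteins[b])
        if sim.identity >= min_identity and sim.coverage >= min_coverage:
            uf.union(a, b)
    groups: dict = {}
    for i in ids:
        groups.setdefault(uf.find(i), []).append(i)
    clusters = []
    for members in groups.values():
        members = sorted(members)
        rep = sorted(members, key=lambda m: (-len(proteins[m]), m))[0]
        clusters.append(FamilyCluster(members=members, representative=rep))
    clusters.sort(key=lambda c: c.members[0])
    return clusters


# ---------------------------------------------------------------------------
# Conserved-neighbor calling
# ---------------------------------------------------------------------------

@dataclass
class ConservedFamily:
    """A cluster satisfying the three conservation criteria."""

    cluster: FamilyCluster
    supporting_types: tuple
    mean_distance: float
    mean_identity: float


def _mean_identity(members: Sequence[str], proteins: Dict[str, str]) -> float:
    pairs = list(itertools.combinations(members, 2))
    if not pairs:
        return 1.0
    total = sum(pairwise_similarity(proteins[a], proteins[b]).identity
                for a, b in pairs)
    return total / len(pairs)


def conserved_neighbors(loci: Sequence[CifLocus], clusters: Sequence[FamilyCluster],
                        proteins: Dict[str, str], min_types: int = 2,
                        max_mean_identity: float = 0.90) -> list:
    """Call conserved CIF-associated families.

    A cluster is reported iff (i) at least one member lies in a locus
    neighborhood, (ii) its members occur in loci of >= ``min_types``
    distinct CIF types, and (iii) its within-cluster mean identity is at
    most ``max_mean_identity`` (diversification).  Loci without a type
    label are excluded with a warning.  Results carry the supporting types
    and the mean gene-count distance of member occurrences from the dyad.
    """
    typed = [l for l in loci if l.cif_type is not None]
    if len(typed) < len(loci):
        warnings.warn(f"excluding {len(loci) - len(typed)} loci without cif_type")
    occurrence: dict = {}
    for locus in typed:
        offs = locus.offsets()
        for g in locus.neighbors:
            occurrence.setdefault(g.id, []).append((locus.cif_type, abs(offs[g.id])))
    out = []
    for cluster in clusters:
        occs = [o for m in cluster.members for o in occurrence.get(m, [])]
        if not occs:
            continue
        types = tuple(sorted({t for t, _ in occs}))
        if len(types) < min_types:
            continue
        mean_ident = _mean_identity(cluster.members, proteins)
        if mean_ident > max_mean_identity:
            continue
        mean_dist = sum(d for _, d in occs) / len(occs)
        out.append(ConservedFamily(cluster=cluster, supporting_types=types,
                                   mean_distance=mean_dist,
                                   mean_identity=mean_ident))
    out.sort(key=lambda f: f.cluster.members[0])
    return out
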