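"""Curation of candidate CifB homologs and copy-number tabulation.

A candidate survives curation iff its domain architecture shows the
four-tandem-REase core of CifB and is not CR-effector-like (leading ATPase
followed by a REase — the decoy architecture).  The gene directly upstream
is then checked for CifA identity; a missing CifA marks the homolog as an
orphan but does not reject it, since orphan CifB copies are a real feature
of endosymbiont genomes.

"Direct upstream" is strand-aware: the 5' positional neighbor of the CifB
CDS on its own coding strand (the previous gene in contig order on '+', the
next gene on '-').

Eukaryote-annotated candidates can additionally be screened for bacterial
provenance (mis-assembly / mis-annotation): a candidate is removed when a
strict majority of its genomic neighbors, or of its closest homologs, are
bacterial; ties retain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, Optional, Sequence

import pandas as pd

from .domain_annotation import (DomainArchitecture, is_4rease_core,
                                is_cr_effector_like)
from .genome_io import Gene, Genome

__all__ = [
    "CurationVerdict",
    "ACCEPTED",
    "NO_4REASE_CORE",
    "CR_EFFECTOR_LIKE",
    "ORPHAN",
    "curate_cifB",
    "retrieve_cifA",
    "upstream_candidates",
    "provenance_filter",
    "copy_number_table",
    "copy_number_histogram",
]

ACCEPTED = "accepted"
NO_4REASE_CORE = "no_4rease_core"
CR_EFFECTOR_LIKE = "cr_effector_like"
ORPHAN = "no_upstream_cifA"
BACTERIAL_CONTEXT = "bacterial_context_in_eukaryote"

CIFA_LABELS = frozenset({"CifA-HEAT"})


@dataclass
class CurationVerdict:
    gene_id: str
    accepted: bool
    reasons: list = field(default_factory=list)

    def __post_init__(self):
        if self.accepted and not set(self.reasons) <= {ACCEPTED, ORPHAN}:
            raise ValueError(f"inconsistent verdict for {self.gene_id}: {self.reasons}")


def upstream_candidates(genome: Genome, gene: Gene, max_gap: int = 0) -> list:
    """Up to ``max_gap + 1`` genes 5' of ``gene`` on its coding strand.

    Nearest first.  On '+' these precede the gene in contig order; on '-'
    they follow (larger start coordinates).  Truncated at the contig edge.
    """
    contig_genes = genome.contig_genes(gene.contig)
    pos = next(i for i, g in enumerate(contig_genes) if g.id == gene.id)
    step = -1 if gene.strand == "+" else 1
    out = []
    for gap in range(max_gap + 1):
        idx = pos + step * (gap + 1)
        if not 0 <= idx < len(contig_genes):
            break
        out.append(contig_genes[idx])
    return out


def retrieve_cifA(genome: Genome, cifB_gene: Gene, max_gap: int = 0) -> Optional[Gene]:
    """The direct upstream gene of a CifB candidate, or None at a contig edge.

    Upstream is strand-aware: the 5' positional neighbor on the candidate's
    coding strand.  The default is immediate adjacency; ``max_gap`` > 0
    tolerates intervening genes and returns the nearest candidate.
    """
    candidates = upstream_candidates(genome, cifB_gene, max_gap=max_gap)
    return candidates[0] if candidates else None


def curate_cifB(genome: Genome, architectures: Dict[str, DomainArchitecture],
                max_gap: int = 0,
                cifA_labels: Iterable[str] = CIFA_LABELS) -> list:
    """Apply the two curation criteria to every annotated protein.

    Returns one :class:`CurationVerdict` per gene present in
    ``architectures``.  Accepted iff 4-tandem-REase core and not
    CR-effector-like; accepted homologs whose upstream gene is absent or not
    CifA carry the orphan flag.
    """
    cifA_labels = frozenset(cifA_labels)
    verdicts = []
    for gene in genome.genes:
        arch = architectures.get(gene.id)
        if arch is None:
            continue
        reasons = []
        if not is_4rease_core(arch):
            reasons.append(NO_4REASE_CORE)
        if is_cr_effector_like(arch):
            reasons.append(CR_EFFECTOR_LIKE)
        accepted = not reasons
        if accepted:
            reasons.append(ACCEPTED)
            has_cifA = False
            for upstream in upstream_candidates(genome, gene, max_gap=max_gap):
                up_arch = architectures.get(upstream.id)
                if up_arch is not None and cifA_labels & set(up_arch.labels):
                    has_cifA = True
                    break
            if not has_cifA:
                reasons.append(ORPHAN)
        verdicts.append(CurationVerdict(gene_id=gene.id, accepted=accepted,
                                        reasons=reasons))
    return verdicts


def provenance_filter(candidate: Gene, neighbor_taxa: Sequence[str],
                      homolog_taxa: Sequence[str]) -> str:
    """Screen a eukaryote-annotated candidate for bacterial provenance.

    ``neighbor_taxa`` and ``homolog_taxa`` are labels already resolved to
    "bacterial"/"eukaryotic".  Returns "remove" when the candidate is
    annotated as eukaryotic but a strict majority of either evidence set is
    bacterial; otherwise "retain".  Empty evidence retains with a warning.
    """
    lineage = {t.lower() for t in candidate.taxon}
    is_euk = "eukaryota" in lineage or "eukaryotic" in lineage
    if not is_euk:
        return "retain"
    if not neighbor_taxa and not homolog_taxa:
        warnings.warn(f"no provenance evidence for {candidate.id}: retaining")
        return "retain"

    def bacterial_majority(taxa: Sequence[str]) -> bool:
        if not taxa:
            return False
        n_bact = sum(t.lower().startswith("bact") for t in taxa)
        return n_bact > len(taxa) / 2  # strict majority; ties retain

    if bacterial_majority(neighbor_taxa) or bacterial_majority(homolog_taxa):
        return "remove"
    return "retain"


def copy_number_table(genomes: Sequence[Genome],
                      verdicts: Dict[str, Sequence[CurationVerdict]]) -> pd.DataFrame:
    """Accepted CifB copy number per genome.

    ``verdicts`` maps genome id to that genome's verdict list.  Genomes with
    no verdicts count zero copies.
    """
    rows = []
    for genome in genomes:
        vs = verdicts.get(genome.id, [])
        rows.append({"genome_id": genome.id,
                     "n_cifB": sum(v.accepted for v in vs)})
    return pd.DataFrame(rows, columns=["genome_id", "n_cifB"])


def copy_number_histogram(table: pd.DataFrame) -> pd.Series:
    """Histogram of copy numbers; its total equals the number of accepted
    homologs when weighted by copy count."""
    return table["n_cifB"].value_counts().sort_index()
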