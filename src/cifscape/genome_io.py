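"""Annotated-genome I/O and the shared coordinate model.

Genomes are ordered lists of protein-coding genes.  Externally, coordinates
follow the GenBank convention: 1-based, inclusive on both ends.  Internally,
all window arithmetic (gene neighborhoods, scan windows) uses 0-based gene
*indices* into the ordered gene list; the two conventions never mix because
windows are counted in genes, not base pairs.

Gene order is positional: genes are sorted by (contig, start) regardless of
strand, so "upstream"/"downstream" at this layer mean "earlier/later on the
contig".  Strand-aware notions of upstream live in `homolog_curation`.
Pseudogenes stay in the gene order — they occupy neighborhood slots — but
carry no protein sequence.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Gene",
    "Genome",
    "read_genbank",
    "write_genbank",
    "read_gff_fasta",
    "write_protein_fasta",
    "write_tables",
    "read_table",
]


@dataclass
class Gene:
    """A single protein-coding gene (or pseudogene) on a contig.

    ``start``/``end`` are 1-based inclusive.  ``protein_seq`` is ``None`` for
    pseudogenes and for CDS features lacking a translation.
    """

    id: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""
    protein_seq: Optional[str] = None
    pseudo: bool = False
    taxon: tuple = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")
        if self.pseudo and self.protein_seq is not None:
            raise ValueError(f"gene {self.id}: pseudogene cannot carry a protein sequence")
        self.taxon = tuple(self.taxon)


@dataclass
class Genome:
    """An annotated genome: ordered genes plus per-contig topology.

    Genes are kept sorted by (contig, start); gene ids must be unique.
    ``topology`` maps contig name to ``"linear"`` or ``"circular"`` and
    defaults to linear for contigs not listed.
    """

    id: str
    taxon: tuple = ()
    genes: list = field(default_factory=list)
    topology: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.taxon = tuple(self.taxon)
        self.genes = sorted(self.genes, key=lambda g: (g.contig, g.start))
        ids = [g.id for g in self.genes]
        if len(ids) != len(set(ids)):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise ValueError(f"genome {self.id}: duplicate gene ids {sorted(dups)}")
        self._index = {g.id: i for i, g in enumerate(self.genes)}

    # -- lookup helpers -------------------------------------------------

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def get(self, gene_id: str) -> Gene:
        return self.genes[self._index[gene_id]]

    def index_of(self, gene_id: str) -> int:
        """0-based index of a gene in the global (contig, start) order."""
        return self._index[gene_id]

    def contigs(self) -> list:
        out = []
        for g in self.genes:
            if not out or out[-1] != g.contig:
                out.append(g.contig)
        return out

    def contig_genes(self, contig: str) -> list:
        return [g for g in self.genes if g.contig == contig]

    def contig_topology(self, contig: str) -> str:
        return self.topology.get(contig, "linear")

    def proteins(self) -> dict:
        """Mapping gene id -> protein sequence for all translated genes."""
        return {g.id: g.protein_seq for g in self.genes if g.protein_seq}


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def read_genbank(path) -> list:
    """Read a GenBank flat file into one :class:`Genome` per record.

    CDS ``/translation`` qualifiers become ``protein_seq``; ``/pseudo`` sets
    the pseudo flag.  A CDS with neither translation nor pseudo flag triggers
    a warning and is kept without a protein sequence.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ValueError(f"malformed GenBank file {path}: {exc}") from exc
    genomes = []
    for rec in records:
        taxon = tuple(rec.annotations.get("taxonomy", ()))
        topo = rec.annotations.get("topology", "linear")
        genes = []
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            gid = quals.get("locus_tag", quals.get("protein_id", [None]))[0]
            if gid is None:
                gid = f"{rec.id}_cds{len(genes)}"
            pseudo = "pseudo" in quals or "pseudogene" in quals
            translation = quals.get("translation", [None])[0]
            if translation is None and not pseudo:
                warnings.warn(f"CDS {gid} in {rec.id} has no translation and is not pseudo")
            genes.append(
                Gene(
                    id=gid,
                    contig=rec.id,
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    strand="-" if feat.location.strand == -1 else "+",
                    product=quals.get("product", [""])[0],
                    protein_seq=None if pseudo else translation,
                    pseudo=pseudo,
                    taxon=taxon,
                )
            )
        genomes.append(Genome(id=rec.id, taxon=taxon, genes=genes, topology={rec.id: topo}))
    return genomes


def write_genbank(genome: Genome, path) -> None:
    """Write a genome as a GenBank flat file, one record per contig.

    The nucleotide sequence itself is not modeled; contigs are emitted as
    runs of ``N`` long enough to hold every feature.  Coordinates, strands,
    products, translations and pseudo flags round-trip exactly through
    :func:`read_genbank`.
    """
    records = []
    for contig in genome.contigs() or [genome.id]:
        genes = genome.contig_genes(contig)
        length = max((g.end for g in genes), default=10) + 50
        rec = SeqRecord(Seq("N" * length), id=contig, name=contig[:16], description=genome.id)
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = genome.contig_topology(contig)
        if genome.taxon:
            rec.annotations["taxonomy"] = list(genome.taxon)
            rec.annotations["organism"] = genome.taxon[-1]
        for g in genes:
            quals = {"locus_tag": [g.id]}
            if g.product:
                quals["product"] = [g.product]
            if g.pseudo:
                quals["pseudo"] = [""]
            if g.protein_seq:
                quals["translation"] = [g.protein_seq]
            loc = SimpleLocation(g.start - 1, g.end, strand=1 if g.strand == "+" else -1)
            rec.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


# ---------------------------------------------------------------------------
# GFF3 + protein FASTA
# ---------------------------------------------------------------------------

def read_gff_fasta(gff_path, fasta_path, genome_id: Optional[str] = None, taxon: Sequence[str] = ()) -> Genome:
    """Read a GFF3 annotation plus a protein FASTA keyed by CDS ID.

    CDS IDs present in the GFF but missing from the FASTA produce a warning
    and a gene without protein sequence.  An annotation with no features
    yields an empty genome.
    """
    import gffutils

    gff_path = Path(gff_path)
    gid = genome_id or gff_path.stem
    body = [
        ln for ln in gff_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not body:
        return Genome(id=gid, taxon=tuple(taxon), genes=[])
    db = gffutils.create_db(str(gff_path), dbfn=":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    genes = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        fid = feat.attributes.get("ID", [feat.id])[0]
        pseudo = feat.attributes.get("pseudo", ["false"])[0].lower() in ("true", "1", "")
        seq = proteins.get(fid)
        if seq is None and not pseudo:
            warnings.warn(f"CDS {fid} has no matching FASTA entry")
        genes.append(
            Gene(
                id=fid,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand="-" if feat.strand == "-" else "+",
                product=feat.attributes.get("product", [""])[0],
                protein_seq=None if pseudo else seq,
                pseudo=pseudo,
                taxon=tuple(taxon),
            )
        )
    return Genome(id=gid, taxon=tuple(taxon), genes=genes)


def write_protein_fasta(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for g in genome.genes:
            if g.protein_seq:
                fh.write(f">{g.id} {g.product}\n{g.protein_seq}\n")


# ---------------------------------------------------------------------------
# Tabular results
# ---------------------------------------------------------------------------

def write_tables(objects, path) -> pd.DataFrame:
    """Write a result collection as TSV with a stable column order.

    ``objects`` may be a DataFrame or an iterable of dataclass instances (all
    of the same type; column order follows field order).  An empty collection
    with a known schema yields a header-only file.  Returns the DataFrame
    written, so callers can keep working with it.
    """
    if isinstance(objects, pd.DataFrame):
        df = objects
    else:
        rows = list(objects)
        if rows and dataclasses.is_dataclass(rows[0]):
            cols = [f.name for f in dataclasses.fields(rows[0])]
            df = pd.DataFrame([dataclasses.asdict(r) for r in rows], columns=cols)
        else:
            df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_tables`."""
    return pd.read_csv(path, sep="\t")
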