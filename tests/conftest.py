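"""Shared fixtures: handcrafted genes/proteins and a small simulated cohort."""

import numpy as np
import pytest

from cifscape.domain_annotation import PROFILE_BY_LABEL
from cifscape.genome_io import Gene, Genome
from cifscape.synthetic_data import SimConfig, generate_cohort

# deterministic handcrafted domain blocks (filler 'A' never collides with the
# E/D/K/Q active-site anchors)


def rease_domain(active: bool = True) -> str:
    tag = PROFILE_BY_LABEL["REase"].motif
    if active:
        return tag + "AAAAA" + "E" + "AAAAAA" + "D" + "AAAAAA" + "EIK" + "AAAAAA" + "Q" + "A"
    return tag + "A" * 30


def tagged_domain(label: str) -> str:
    return PROFILE_BY_LABEL[label].motif + "A" * 30


def cifB_protein(pattern=(False, True, False, True), extra=None) -> str:
    core = "".join(rease_domain(a) for a in pattern)
    tail = tagged_domain(extra) if extra else ""
    return "GGGGG" + core + tail + "GGGGG"


def cifA_protein() -> str:
    return "GGGGG" + tagged_domain("CifA-HEAT") + "GGGGG"


def decoy_protein() -> str:
    return "GGGGG" + tagged_domain("CR-ATPase") + "GGGGG" + rease_domain(True) + "GGGGG"


def make_genes(specs, contig="c1", spacing=50):
    """Build genes from (id, strand, protein|None) specs, laid out in order."""
    genes = []
    cursor = 1
    for gid, strand, prot in specs:
        length = 3 * len(prot) + 3 if prot else 300
        genes.append(Gene(id=gid, contig=contig, start=cursor,
                          end=cursor + length - 1, strand=strand,
                          product="", protein_seq=prot, pseudo=prot is None))
        cursor += length + spacing
    return genes


def make_genome(specs, genome_id="g", contig="c1", topology="linear"):
    return Genome(id=genome_id, genes=make_genes(specs, contig=contig),
                  topology={contig: topology})


@pytest.fixture(scope="session")
def small_cohort():
    """Ten simulated genomes, one CIF locus each, three locus types."""
    base = SimConfig(n_genes=120, n_cif_loci=1, decoy_rate=0.05,
                     pseudo_rate=0.05, genome_id="coh")
    return generate_cohort(10, seed=42, base=base,
                           cif_type_cycle=("type-1", "type-2", "type-3"))
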