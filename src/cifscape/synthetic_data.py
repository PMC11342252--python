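"""Synthetic Wolbachia-like genomes, CIF loci and mosaic protein families.

The generator emulates the data regime of reduced endosymbiont genomes:
a few hundred to a thousand genes, 0-9 planted cifA-cifB dyads per genome,
locus neighborhoods drawn from six functional categories (deubiquitinases,
ANK effectors, transposases, PDDEXK-transposon cargo, DNA-binding domains,
multi-gene elements), CR-effector-like decoys (leading ATPase followed by a
REase), pseudogenes, and — separately — mosaic CifB-like families whose
REase-core and deubiquitinase segments carry discordant histories.

Protein sequences are random background with embedded literal signature
blocks (see :mod:`cifscape.domain_annotation`), so every architecture call
made downstream is exactly testable against the recorded ground truth.
Within REase blocks the filler alphabet excludes E/D/K/Q, so the
active-site classification depends only on the planted anchor residues.

Seeding: one global seed expands into per-component streams through
``numpy.random.SeedSequence(seed).spawn()``, in a fixed order (layout,
loci, background, decoys/pseudogenes).  Category-gene *templates* are keyed
by a separate ``family_seed`` shared across a cohort, so homologous planted
families in different genomes descend from one template and cluster
together regardless of each genome's own seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alignment_phylo import MSA, Node, Tree
from .domain_annotation import PROFILE_BY_LABEL
from .genome_io import Gene, Genome

__all__ = [
    "SimConfig",
    "GroundTruth",
    "LocusTruth",
    "CATEGORIES",
    "CATEGORY_CODES",
    "CATEGORY_LABELS",
    "DYAD_CODE",
    "generate_genome",
    "generate_cohort",
    "CifFamily",
    "generate_cif_family",
    "generate_msa",
    "pick_nonsister_pair",
    "expected_p_distance",
]

AA = "ACDEFGHIKLMNPQRSTVWY"
# REase-block filler excludes the four active-site residues so that
# activity calls are decided solely by the planted anchors.
REASE_FILLER = "ACFGHILMNPRSTVWY"

# The six functional categories of CIF-locus neighbor genes, their integer
# codes for enrichment analysis (0 = background, 7 = the core dyad), and the
# domain label each category's proteins carry.
CATEGORIES = ("DUB", "ANK", "transposase", "PDDEXK", "DNA_binding", "element")
CATEGORY_CODES = {c: i + 1 for i, c in enumerate(CATEGORIES)}
DYAD_CODE = 7
CATEGORY_LABELS = {
    "DUB": "Ulp1",
    "ANK": "ANK",
    "transposase": "IS-transposase",
    "PDDEXK": "PDDEXK",
    "DNA_binding": "HTH",
    "element": "EamA",
}

_MUTATION_RATE = 0.15  # per-residue divergence of planted family members


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for one synthetic genome.

    ``category_plan`` gives, per locus, the category labels planted directly
    downstream of the dyad (default: all six).  ``rease_pattern`` is the
    per-domain activity pattern of planted CifB proteins; the default
    (inactive, active, inactive, active) mirrors the dominant arrangement in
    which REase domains 2 and 4 are catalytic.  Setting ``cifB_extra_domain``
    to e.g. ``"Ulp1"`` appends a deubiquitinase block (CidB-like).
    """

    n_genes: int = 200
    n_cif_loci: int = 1
    category_plan: Optional[Sequence[Sequence[str]]] = None
    decoy_rate: float = 0.05
    pseudo_rate: float = 0.05
    seed: int = 0
    genome_id: str = "synthetic"
    taxon: tuple = ("Bacteria", "Alphaproteobacteria", "Wolbachia")
    cif_types: Optional[Sequence[str]] = None
    rease_pattern: tuple = (False, True, False, True)
    cifB_extra_domain: Optional[str] = None
    family_seed: int = 0
    circular: bool = False

    def __post_init__(self):
        for name in ("decoy_rate", "pseudo_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.n_cif_loci <= 9:
            raise ValueError("n_cif_loci must be in 0..9")
        plan = self.resolved_plan()
        max_neighbors = max((len(p) for p in plan), default=0)
        if self.n_cif_loci > 0:
            cap = self.n_genes // (2 + max_neighbors)
            if self.n_cif_loci > cap:
                raise ValueError(
                    f"infeasible packing: {self.n_cif_loci} loci of "
                    f"{2 + max_neighbors} genes do not fit in {self.n_genes} genes")

    def resolved_plan(self) -> list:
        if self.category_plan is not None:
            plan = [list(p) for p in self.category_plan]
            if len(plan) != self.n_cif_loci:
                raise ValueError("category_plan must list one entry per locus")
        else:
            plan = [list(CATEGORIES) for _ in range(self.n_cif_loci)]
        for p in plan:
            for c in p:
                if c not in CATEGORIES:
                    raise ValueError(f"unknown category {c!r}")
        return plan

    def resolved_types(self) -> list:
        if self.cif_types is not None:
            types = list(self.cif_types)
            if len(types) != self.n_cif_loci:
                raise ValueError("cif_types must list one label per locus")
            return types
        return [f"synthetic-{i + 1}" for i in range(self.n_cif_loci)]


@dataclass
class LocusTruth:
    cifA: str
    cifB: str
    cif_type: str
    category_genes: dict  # gene id -> category name


@dataclass
class GroundTruth:
    """Complete record of what was planted where."""

    genome_id: str
    loci: list = field(default_factory=list)
    decoy_ids: list = field(default_factory=list)
    pseudo_ids: list = field(default_factory=list)

    @property
    def cifB_ids(self) -> list:
        return [l.cifB for l in self.loci]

    @property
    def cifA_ids(self) -> list:
        return [l.cifA for l in self.loci]

    @property
    def categories(self) -> dict:
        out = {}
        for l in self.loci:
            out.update(l.category_genes)
        return out

    @property
    def locus_types(self) -> dict:
        return {l.cifB: l.cif_type for l in self.loci}

    def category_codes(self) -> dict:
        """Gene id -> enrichment code (dyad genes coded 7)."""
        codes = {}
        for l in self.loci:
            codes[l.cifA] = DYAD_CODE
            codes[l.cifB] = DYAD_CODE
            for gid, cat in l.category_genes.items():
                codes[gid] = CATEGORY_CODES[cat]
        return codes

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["loci"] = [LocusTruth(**l) for l in data["loci"]]
        return cls(**data)


# ---------------------------------------------------------------------------
# Protein construction
# ---------------------------------------------------------------------------

def _rand_seq(rng, n: int, alphabet: str = AA) -> str:
    idx = rng.integers(0, len(alphabet), size=n)
    return "".join(alphabet[i] for i in idx)


def _rease_block(rng, active: bool) -> str:
    """A 40-residue REase domain block: anchor tag + active-site residues.

    Active blocks carry E, D, E-x-K, Q at fixed offsets with 6-residue
    spacers (within the 5-120 classifier window); inactive blocks replace
    every anchor with filler.
    """
    f = lambda n: _rand_seq(rng, n, REASE_FILLER)
    tag = PROFILE_BY_LABEL["REase"].motif
    if active:
        return tag + f(5) + "E" + f(6) + "D" + f(6) + "E" + f(1) + "K" + f(6) + "Q" + f(1)
    return tag + f(5) + f(1) + f(6) + f(1) + f(6) + f(1) + f(1) + f(1) + f(6) + f(1) + f(1)


def _domain_block(rng, label: str) -> str:
    return PROFILE_BY_LABEL[label].motif + _rand_seq(rng, 30)


def _cifB_protein(rng, pattern: Sequence[bool], extra: Optional[str]) -> str:
    core = "".join(_rease_block(rng, a) for a in pattern)
    tail = _domain_block(rng, extra) if extra else ""
    return _rand_seq(rng, 5) + core + tail + _rand_seq(rng, 5)


def _cifA_protein(rng) -> str:
    return _rand_seq(rng, 5) + _domain_block(rng, "CifA-HEAT") + _rand_seq(rng, 25)


def _decoy_protein(rng) -> str:
    return (_rand_seq(rng, 5) + _domain_block(rng, "CR-ATPase") + _rand_seq(rng, 5)
            + _rease_block(rng, True) + _rand_seq(rng, 10))


@lru_cache(maxsize=None)
def _category_template(category: str, family_seed: int) -> tuple:
    """Deterministic founder sequence for one planted family.

    Returns (sequence, protected_range): the signature anchor is protected
    from mutation so detection stays exact while the family diversifies.
    """
    digest = hashlib.sha256(category.encode()).digest()
    sub = int.from_bytes(digest[:4], "big") % (2 ** 31)
    rng = np.random.default_rng(np.random.SeedSequence([family_seed, sub]))
    label = CATEGORY_LABELS[category]
    seq = _rand_seq(rng, 40) + _domain_block(rng, label) + _rand_seq(rng, 40)
    return seq, (40, 50)


def _family_member(rng, category: str, family_seed: int) -> str:
    template, (p0, p1) = _category_template(category, family_seed)
    chars = list(template)
    for i in range(len(chars)):
        if p0 <= i < p1:
            continue
        if rng.random() < _MUTATION_RATE:
            alt = AA.replace(chars[i], "")
            chars[i] = alt[rng.integers(0, len(alt))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_genome(config: SimConfig) -> Tuple[Genome, GroundTruth]:
    """Build one synthetic genome plus its ground truth.

    Deterministic given ``config.seed``.  Loci are placed one per equal
    segment of the gene order (at a seeded offset), so dyads never collide;
    each locus is laid out as cifA, cifB, then its planted category genes
    downstream, all on the plus strand.  Remaining slots are background
    genes, CR-effector-like decoys (at ``decoy_rate``) and pseudogenes (at
    ``pseudo_rate``).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_layout, rng_loci, rng_bg, rng_other = (
        np.random.default_rng(s) for s in ss.spawn(4))

    plan = config.resolved_plan()
    types = config.resolved_types()
    n = config.n_genes

    slot_role: list = ["background"] * n
    truth = GroundTruth(genome_id=config.genome_id)
    locus_layouts = []
    if config.n_cif_loci:
        seg = n // config.n_cif_loci
        for i in range(config.n_cif_loci):
            block = 2 + len(plan[i])
            lo = i * seg
            hi = min((i + 1) * seg, n) - block
            start = int(rng_layout.integers(lo, hi + 1))
            locus_layouts.append((start, plan[i], types[i]))
            for j in range(block):
                slot_role[start + j] = ("locus", i, j)

    contig = f"{config.genome_id}_c1"
    genes: list = []
    cursor = 1
    locus_records: dict = {}
    for idx in range(n):
        gid = f"{config.genome_id}_g{idx:04d}"
        role = slot_role[idx]
        pseudo = False
        if role == "background":
            r = rng_other.random()
            if r < config.decoy_rate:
                prot = _decoy_protein(rng_bg)
                product = "CR-type effector (ATPase-REase)"
                truth.decoy_ids.append(gid)
            elif r < config.decoy_rate + config.pseudo_rate:
                prot = None
                pseudo = True
                product = "pseudogene"
                truth.pseudo_ids.append(gid)
            else:
                prot = _rand_seq(rng_bg, int(rng_bg.integers(80, 151)))
                product = "hypothetical protein"
            strand = "+" if rng_bg.random() < 0.5 else "-"
        else:
            _, locus_i, offset = role
            _, locus_plan, locus_type = locus_layouts[locus_i]
            strand = "+"
            if offset == 0:
                prot = _cifA_protein(rng_loci)
                product = "cytoplasmic incompatibility factor CifA"
                locus_records.setdefault(locus_i, {})["cifA"] = gid
            elif offset == 1:
                prot = _cifB_protein(rng_loci, config.rease_pattern,
                                     config.cifB_extra_domain)
                product = "cytoplasmic incompatibility factor CifB"
                locus_records.setdefault(locus_i, {})["cifB"] = gid
            else:
                cat = locus_plan[offset - 2]
                prot = _family_member(rng_loci, cat, config.family_seed)
                product = f"CIF-locus associated protein ({cat})"
                locus_records.setdefault(locus_i, {}).setdefault(
                    "cats", {})[gid] = cat
        length_nt = 3 * len(prot) + 3 if prot else int(rng_other.integers(150, 600))
        start = cursor
        end = start + length_nt - 1
        cursor = end + 1 + int(rng_layout.integers(20, 200))
        genes.append(Gene(id=gid, contig=contig, start=start, end=end, strand=strand,
                          product=product, protein_seq=prot, pseudo=pseudo,
                          taxon=config.taxon))

    for locus_i, rec in sorted(locus_records.items()):
        truth.loci.append(LocusTruth(
            cifA=rec["cifA"], cifB=rec["cifB"],
            cif_type=locus_layouts[locus_i][2],
            category_genes=rec.get("cats", {})))

    topo = "circular" if config.circular else "linear"
    genome = Genome(id=config.genome_id, taxon=config.taxon, genes=genes,
                    topology={contig: topo})
    return genome, truth


def generate_cohort(n_genomes: int, seed: int, base: Optional[SimConfig] = None,
                    cif_type_cycle: Sequence[str] = ("type-1", "type-2")) -> list:
    """Generate a cohort of genomes sharing family templates.

    Per-genome seeds are spawned from the cohort seed; locus type labels
    cycle through ``cif_type_cycle`` across genomes so each planted family
    ends up associated with more than one locus type.  Returns a list of
    (Genome, GroundTruth) pairs.
    """
    base = base or SimConfig()
    children = np.random.SeedSequence(seed).spawn(n_genomes)
    out = []
    for i, child in enumerate(children):
        gseed = int(child.generate_state(1)[0] % (2 ** 31))
        gtype = cif_type_cycle[i % len(cif_type_cycle)]
        cfg = SimConfig(
            n_genes=base.n_genes, n_cif_loci=base.n_cif_loci,
            category_plan=base.category_plan, decoy_rate=base.decoy_rate,
            pseudo_rate=base.pseudo_rate, seed=gseed,
            genome_id=f"{base.genome_id}-{i:03d}", taxon=base.taxon,
            cif_types=[gtype] * base.n_cif_loci,
            rease_pattern=base.rease_pattern,
            cifB_extra_domain=base.cifB_extra_domain,
            family_seed=base.family_seed, circular=base.circular)
        out.append(generate_genome(cfg))
    return out


# ---------------------------------------------------------------------------
# Sequence evolution on trees
# ---------------------------------------------------------------------------

def _random_tree(labels: Sequence[str], divergence: float, rng) -> Tree:
    """Random binary topology by successive joins; branch lengths are
    divergence/3 * U(0.5, 1.5) substitutions/site per edge."""
    nodes = [Node(lab) for lab in labels]

    def blen() -> float:
        return divergence / 3 * rng.uniform(0.5, 1.5)

    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length, b.length = blen(), blen()
        parent = Node(None, 0.0, [b, a])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    return Tree(nodes[0])


def generate_msa(tree, length: int, seed: int = 0, model: str = "poisson") -> MSA:
    """Evolve an ungapped protein alignment down a tree.

    The substitution scheme is a 20-state Jukes-Cantor-type (Poisson) model:
    along a branch of length b substitutions/site, a site differs from its
    parent with probability (19/20) * (1 - exp(-20 b / 19)) and then takes a
    uniformly random different residue.  Branch-length zero is legal (the
    child copies the parent); a tree with fewer than two leaves or a
    zero-column request is an error.
    """
    if isinstance(tree, str):
        tree = Tree.from_newick(tree)
    if model != "poisson":
        raise ValueError(f"unknown substitution model {model!r}")
    if length <= 0:
        raise ValueError("alignment length must be positive")
    if len(tree.leaf_set()) < 2:
        raise ValueError("tree must have at least two leaves")
    rng = np.random.default_rng(seed)
    rows: dict = {}

    def evolve(node: Node, parent_states: np.ndarray) -> None:
        b = node.length
        p_diff = (19 / 20) * (1 - math.exp(-20 * b / 19))
        states = parent_states.copy()
        if p_diff > 0:
            mask = rng.random(length) < p_diff
            k = int(mask.sum())
            if k:
                states[mask] = (states[mask] + rng.integers(1, 20, size=k)) % 20
        if node.is_leaf():
            rows[node.label] = states
        else:
            for c in node.children:
                evolve(c, states)

    root_states = rng.integers(0, 20, size=length)
    if tree.root.is_leaf():
        rows[tree.root.label] = root_states
    else:
        for c in tree.root.children:
            evolve(c, root_states)

    ids = sorted(rows)
    return MSA(ids, ["".join(AA[s] for s in rows[i]) for i in ids])


def expected_p_distance(total_branch_length: float) -> float:
    """Expected P-distance between two leaves at a given path length."""
    return (19 / 20) * (1 - math.exp(-20 * total_branch_length / 19))


# ---------------------------------------------------------------------------
# Mosaic CifB-like families
# ---------------------------------------------------------------------------

@dataclass
class CifFamily:
    """A simulated CifB-like family with per-segment true histories.

    ``sequences`` maps lineage -> concatenated protein (REase-core segment
    followed by the deubiquitinase segment); ``segments`` gives the two
    0-based half-open column ranges.  ``tree_core`` and ``tree_dub`` are the
    generating trees; with no swaps they are identical.
    """

    sequences: dict
    tree_core: Tree
    tree_dub: Tree
    segments: tuple
    swap_pairs: tuple


def generate_cif_family(n_lineages: int, divergence: float,
                        swap_pairs: Sequence[Tuple[str, str]] = (),
                        seed: int = 0, segment_length: int = 2000) -> CifFamily:
    """Simulate a CifB-like family with optional inter-locus recombination.

    The REase-core segment evolves on a random tree T1; the deubiquitinase
    segment evolves on T2, obtained from T1 by exchanging the positions of
    each pair in ``swap_pairs`` (a reciprocal segment swap between two
    lineages).  With no swaps the two true trees coincide.
    """
    if n_lineages < 4:
        raise ValueError("need at least 4 lineages for topology comparisons")
    labels = [f"L{i + 1:02d}" for i in range(n_lineages)]
    known = set(labels)
    for a, b in swap_pairs:
        missing = {a, b} - known
        if missing:
            raise ValueError(f"swap names unknown lineage(s): {sorted(missing)}")
    ss = np.random.SeedSequence(seed)
    s_topo, s_core, s_dub = ss.spawn(3)
    rng = np.random.default_rng(s_topo)
    t1 = _random_tree(labels, divergence, rng)
    mapping: dict = {}
    for a, b in swap_pairs:
        mapping[a], mapping[b] = b, a
    t2 = t1.relabel(mapping) if mapping else t1
    seed_core = int(s_core.generate_state(1)[0] % (2 ** 31))
    seed_dub = int(s_dub.generate_state(1)[0] % (2 ** 31))
    msa_core = generate_msa(t1, segment_length, seed=seed_core)
    msa_dub = generate_msa(t2, segment_length, seed=seed_dub)
    core = dict(zip(msa_core.ids, msa_core.rows))
    dub = dict(zip(msa_dub.ids, msa_dub.rows))
    seqs = {lab: core[lab] + dub[lab] for lab in labels}
    return CifFamily(
        sequences=seqs, tree_core=t1, tree_dub=t2,
        segments=((0, segment_length), (segment_length, 2 * segment_length)),
        swap_pairs=tuple(tuple(p) for p in swap_pairs))


def pick_nonsister_pair(tree: Tree, rng) -> Tuple[str, str]:
    """A deterministic (given rng) random leaf pair that is not a cherry.

    Swapping a cherry merely relabels the tree, so mosaic simulations that
    must change the topology need a non-sister pair.
    """
    cherries = set()

    def walk(node: Node):
        kids = node.children
        if len(kids) == 2 and all(c.is_leaf() for c in kids):
            cherries.add(frozenset(c.label for c in kids))
        for c in kids:
            walk(c)

    walk(tree.root)
    leaves = sorted(tree.leaf_set())
    candidates = [
        (a, b)
        for i, a in enumerate(leaves) for b in leaves[i + 1:]
        if frozenset((a, b)) not in cherries
    ]
    if not candidates:
        raise ValueError("tree has no non-sister leaf pair")
    return candidates[int(rng.integers(0, len(candidates)))]
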