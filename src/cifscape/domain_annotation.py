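"""Domain-architecture assignment and REase active-site classification.

Two evidence routes feed the same :class:`DomainArchitecture` record:

* a native, pluggable motif matcher (:func:`annotate_protein`) driven by a
  small profile set.  The default profile set is a *synthetic signature
  set*: literal 10-residue anchors planted by the simulator, one per domain
  family, which makes architecture calls on simulated proteins exact.  Real
  analyses replace it with profiles of their own or import external evidence;
* an importer for hmmscan per-domain tables (:func:`import_hmmscan_table`),
  mapping envelope coordinates onto proteins by name.

Restriction-endonuclease (REase) domains are additionally classified as
catalytically active or inactive by the ordered active-site residue motif
E ... D ... E-x-K ... Q.  The motif is matched as an ordered residue pattern
with configurable spacing windows between anchors (default 5-120 residues);
"E-x-K" is read literally as E, any single residue, K.  CifB toxins carry
four tandem REase domains; in most clades the second and fourth are active
while the first and third are not, and in the CidB (type-I-like) clade all
four are inactive.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import yaml

__all__ = [
    "DomainHit",
    "DomainArchitecture",
    "Profile",
    "DEFAULT_PROFILES",
    "annotate_protein",
    "import_hmmscan_table",
    "classify_rease_activity",
    "is_4rease_core",
    "is_cr_effector_like",
    "load_profiles",
    "save_profiles",
]

ACTIVE = "active"
INACTIVE = "inactive"


@dataclass(frozen=True)
class DomainHit:
    """One domain assignment on a protein; 1-based inclusive residue span."""

    label: str
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"domain hit {self.label}: start {self.start} > end {self.end}")

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class DomainArchitecture:
    """Ordered, non-overlapping domain hits for one protein.

    ``rease_activity`` holds one ACTIVE/INACTIVE call per REase hit, in hit
    order.
    """

    protein_id: str
    hits: list = field(default_factory=list)
    rease_activity: list = field(default_factory=list)

    @property
    def labels(self) -> list:
        return [h.label for h in self.hits]


@dataclass(frozen=True)
class Profile:
    """A literal-anchor domain profile.

    ``motif`` is an exact residue string whose occurrence marks the domain;
    the assigned hit spans ``length`` residues from the anchor start (clipped
    to the protein).  ``score`` ranks competing hits during overlap
    resolution.
    """

    label: str
    motif: str
    length: int
    score: float


# Synthetic signature anchors, one per domain family used by the simulator.
# None contains E/D/K/Q, so REase activity calls depend only on the planted
# active-site residues, never on the anchor itself.
DEFAULT_PROFILES = (
    Profile("REase", "CGNWRFHTSV", 40, 40.0),
    Profile("Ulp1", "WGHLCNSTRF", 40, 40.0),
    Profile("OTU", "FNCGWSHLTV", 40, 40.0),
    Profile("PL-OTU", "GWCTNHSFRL", 40, 40.0),
    Profile("ANK", "TPLHNAGRWS", 40, 40.0),
    Profile("CR-ATPase", "GPSGSGNTHW", 40, 40.0),
    Profile("Latrotoxin-CTD", "WNSFGHTRCV", 40, 40.0),
    Profile("CifA-HEAT", "HALWNSGTRC", 40, 40.0),
    Profile("IS-transposase", "RGNFHWSTCL", 40, 40.0),
    Profile("PDDEXK", "NWGSHCRFTL", 40, 40.0),
    Profile("HTH", "SRWHGNCTFL", 40, 40.0),
    Profile("EamA", "CWHGSNRLTF", 40, 40.0),
)

PROFILE_BY_LABEL = {p.label: p for p in DEFAULT_PROFILES}


def annotate_protein(seq: str, profiles: Sequence[Profile] = DEFAULT_PROFILES,
                     protein_id: str = "", min_gap: int = 5, max_gap: int = 120) -> DomainArchitecture:
    """Assign a maximal non-overlapping domain hit set to a protein.

    Candidate hits are every occurrence of every profile anchor; overlaps are
    resolved greedily by score, then by start, then by label, which makes the
    result independent of profile iteration order.  REase hits are classified
    for catalytic activity on their own substring.
    """
    if not seq:
        raise ValueError("empty protein sequence")
    if not profiles:
        warnings.warn("empty profile set: returning empty architecture")
        return DomainArchitecture(protein_id=protein_id)
    candidates = []
    for prof in profiles:
        pos = seq.find(prof.motif)
        while pos != -1:
            end = min(pos + prof.length, len(seq))
            candidates.append(DomainHit(prof.label, pos + 1, end, prof.score))
            pos = seq.find(prof.motif, pos + 1)
    candidates.sort(key=lambda h: (-h.score, h.start, h.label))
    kept: list = []
    for cand in candidates:
        if not any(cand.overlaps(k) for k in kept):
            kept.append(cand)
    kept.sort(key=lambda h: h.start)
    activity = [
        classify_rease_activity(seq[h.start - 1:h.end], min_gap=min_gap, max_gap=max_gap)
        for h in kept if h.label == "REase"
    ]
    return DomainArchitecture(protein_id=protein_id, hits=kept, rease_activity=activity)


def classify_rease_activity(domain_seq: str, min_gap: int = 5, max_gap: int = 120) -> str:
    """Classify one REase domain as catalytically active or inactive.

    Active iff the ordered motif E ... D ... E-x-K ... Q occurs with each
    inter-anchor spacing within [min_gap, max_gap] residues.  Sequences
    shorter than the minimal motif span are inactive by definition.
    """
    minimal_span = 3 * min_gap + 6
    if len(domain_seq) < minimal_span:
        return INACTIVE
    gap = f".{{{min_gap},{max_gap}}}"
    pattern = f"E{gap}D{gap}E.K{gap}Q"
    return ACTIVE if re.search(pattern, domain_seq) else INACTIVE


def is_4rease_core(arch: DomainArchitecture) -> bool:
    """True iff the architecture contains >=4 tandem REase hits.

    "Tandem" means consecutive in the resolved hit order with no intervening
    non-REase hit — the structural hallmark of CifB toxins.
    """
    run = 0
    for label in arch.labels:
        run = run + 1 if label == "REase" else 0
        if run >= 4:
            return True
    return False


def is_cr_effector_like(arch: DomainArchitecture) -> bool:
    """True iff a leading CR-ATPase domain is followed by a REase domain.

    This is the conserved architecture of Crinkler-RHS-type (CR) mobile
    effectors, the decoy class that homolog curation must exclude.
    """
    labels = arch.labels
    return bool(labels) and labels[0] == "CR-ATPase" and "REase" in labels[1:]


# ---------------------------------------------------------------------------
# External evidence: hmmscan per-domain tables
# ---------------------------------------------------------------------------

def import_hmmscan_table(path, known_ids: Optional[Iterable[str]] = None):
    """Import an hmmscan per-domain table (``--domtblout`` dialect).

    Envelope coordinates are used for the hit span and the per-domain
    independent score for ranking.  Rows naming a protein absent from
    ``known_ids`` (when given) and rows that fail to parse are skipped with
    a warning.

    Returns ``(hits, n_skipped)`` where ``hits`` maps protein id to a list of
    :class:`DomainHit`.
    """
    known = set(known_ids) if known_ids is not None else None
    hits: dict = {}
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            try:
                if len(parts) < 22:
                    raise ValueError("too few columns")
                label, protein = parts[0], parts[3]
                score = float(parts[13])
                env_from, env_to = int(parts[19]), int(parts[20])
                hit = DomainHit(label, env_from, env_to, score)
            except (ValueError, IndexError) as exc:
                warnings.warn(f"skipping malformed hmmscan row: {exc}")
                skipped += 1
                continue
            if known is not None and protein not in known:
                warnings.warn(f"skipping hmmscan row for unknown protein {protein!r}")
                skipped += 1
                continue
            hits.setdefault(protein, []).append(hit)
    for plist in hits.values():
        plist.sort(key=lambda h: h.start)
    return hits, skipped


# ---------------------------------------------------------------------------
# Profile serialization (simple YAML motif format)
# ---------------------------------------------------------------------------

def save_profiles(profiles: Sequence[Profile], path) -> None:
    data = [
        {"label": p.label, "motif": p.motif, "length": p.length, "score": p.score}
        for p in profiles
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_profiles(path) -> list:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [Profile(d["label"], d["motif"], int(d["length"]), float(d["score"])) for d in data]
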