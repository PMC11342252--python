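"""End-to-end orchestration: simulate -> curate -> neighborhoods -> enrich
-> incongruence.

Each stage writes its own artifacts under the output directory and
contributes a section to a machine-readable ``summary.json``; the resolved
configuration is written verbatim as ``resolved_config.yaml`` for
provenance.  Identical config + seed yields a byte-identical summary.

Category codes for the enrichment stage are derived from the *detected*
domain architectures (not from ground truth): any gene whose architecture
carries a category-defining domain label gets that category's code, and
curated dyads get the dyad code.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import (alignment_phylo, domain_annotation, enrichment, genome_io,
               homolog_curation, neighborhood, synthetic_data)
from .synthetic_data import CATEGORY_CODES, CATEGORY_LABELS, DYAD_CODE

__all__ = ["PipelineConfig", "run_pipeline", "derive_category_map"]

STAGES = ("simulate", "curate", "neighborhoods", "enrich", "incongruence")

# domain label -> enrichment category (several DUB families share one code)
_LABEL_TO_CATEGORY = {
    "Ulp1": "DUB", "OTU": "DUB", "PL-OTU": "DUB",
    "ANK": "ANK",
    "IS-transposase": "transposase",
    "PDDEXK": "PDDEXK",
    "HTH": "DNA_binding",
    "EamA": "element",
}


@dataclass
class PipelineConfig:
    """All stage parameters; defaults match the module defaults."""

    seed: int = 1
    stages: tuple = STAGES
    # simulate
    n_genomes: int = 3
    n_genes: int = 150
    n_cif_loci: int = 1
    decoy_rate: float = 0.05
    pseudo_rate: float = 0.05
    cif_type_cycle: tuple = ("type-1", "type-2")
    # neighborhoods
    k: int = 15
    min_identity: float = 0.30
    min_coverage: float = 0.80
    max_mean_identity: float = 0.90
    # enrich
    window: int = 19
    thresholds: tuple = (6, 7, 8)
    reps: int = 10000
    circular: bool = False
    # incongruence
    family_lineages: int = 8
    family_divergence: float = 0.3
    family_segment: int = 500
    family_swaps: int = 1

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.window < 1 or self.reps < 1 or self.k < 1:
            raise ValueError("window, reps and k must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("stages", "thresholds", "cif_type_cycle"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def derive_category_map(genome, architectures, accepted_cifB, cifA_partners) -> dict:
    """Gene id -> enrichment code from detected domain architectures."""
    codes = {}
    for gid, arch in architectures.items():
        for label in arch.labels:
            cat = _LABEL_TO_CATEGORY.get(label)
            if cat is not None:
                codes[gid] = CATEGORY_CODES[cat]
                break
    for b in accepted_cifB:
        codes[b] = DYAD_CODE
        partner = cifA_partners.get(b)
        if partner is not None:
            codes[partner] = DYAD_CODE
    return codes


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the configured stages; returns (and writes) the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")
    summary: dict = {"config_seed": config.seed}
    stage = None
    try:
        state: dict = {}
        for stage in config.stages:
            _STAGE_FUNCS[stage](config, outdir, state, summary)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, outdir, state, summary):
    gdir = outdir / "genomes"
    gdir.mkdir(exist_ok=True)
    base = synthetic_data.SimConfig(
        n_genes=cfg.n_genes, n_cif_loci=cfg.n_cif_loci,
        decoy_rate=cfg.decoy_rate, pseudo_rate=cfg.pseudo_rate,
        genome_id="sim")
    cohort = synthetic_data.generate_cohort(
        cfg.n_genomes, seed=cfg.seed, base=base,
        cif_type_cycle=cfg.cif_type_cycle)
    for genome, truth in cohort:
        genome_io.write_genbank(genome, gdir / f"{genome.id}.gbk")
        truth.to_json(gdir / f"{genome.id}.truth.json")
    state["cohort"] = cohort
    summary["simulate"] = {
        "n_genomes": len(cohort),
        "planted_cifB": sum(len(t.cifB_ids) for _, t in cohort),
    }


def _stage_curate(cfg, outdir, state, summary):
    cdir = outdir / "curation"
    cdir.mkdir(exist_ok=True)
    cohort = state["cohort"]
    all_verdicts = {}
    architectures = {}
    rows = []
    for genome, _truth in cohort:
        archs = {gid: domain_annotation.annotate_protein(seq, protein_id=gid)
                 for gid, seq in genome.proteins().items()}
        architectures[genome.id] = archs
        verdicts = homolog_curation.curate_cifB(genome, archs)
        all_verdicts[genome.id] = verdicts
        for v in verdicts:
            if v.accepted:
                rows.append({"genome_id": genome.id, "gene_id": v.gene_id,
                             "reasons": ";".join(v.reasons)})
    import pandas as pd

    genome_io.write_tables(
        pd.DataFrame(rows, columns=["genome_id", "gene_id", "reasons"]),
        cdir / "accepted_cifB.tsv")
    table = homolog_curation.copy_number_table(
        [g for g, _ in cohort], all_verdicts)
    genome_io.write_tables(table, cdir / "copy_number.tsv")
    state["verdicts"] = all_verdicts
    state["architectures"] = architectures
    summary["curate"] = {
        "accepted_total": int(table["n_cifB"].sum()),
        "copy_number": {str(k): int(v) for k, v in
                        homolog_curation.copy_number_histogram(table).items()},
    }


def _stage_neighborhoods(cfg, outdir, state, summary):
    ndir = outdir / "neighborhoods"
    ndir.mkdir(exist_ok=True)
    cohort = state["cohort"]
    loci = []
    neighbor_proteins: dict = {}
    for genome, truth in cohort:
        types = truth.locus_types
        for v in state["verdicts"][genome.id]:
            if not v.accepted:
                continue
            gene = genome.get(v.gene_id)
            partner = homolog_curation.retrieve_cifA(genome, gene)
            locus = neighborhood.dyad_locus(
                genome, v.gene_id,
                cifA_id=partner.id if partner else None,
                k=cfg.k, cif_type=types.get(v.gene_id))
            loci.append(locus)
            for g in locus.neighbors:
                if g.protein_seq:
                    neighbor_proteins[g.id] = g.protein_seq
    clusters = neighborhood.single_linkage_cluster(
        neighbor_proteins, min_identity=cfg.min_identity,
        min_coverage=cfg.min_coverage)
    conserved = neighborhood.conserved_neighbors(
        loci, clusters, neighbor_proteins,
        max_mean_identity=cfg.max_mean_identity)
    locus_json = [
        {"genome_id": l.genome_id, "cifA": l.cifA, "cifB": l.cifB,
         "cif_type": l.cif_type,
         "upstream": [g.id for g in l.upstream],
         "downstream": [g.id for g in l.downstream]}
        for l in loci
    ]
    with open(ndir / "loci.json", "w") as fh:
        json.dump(locus_json, fh, indent=2, sort_keys=True)
    import pandas as pd

    genome_io.write_tables(
        pd.DataFrame(
            [{"representative": c.representative, "size": len(c.members),
              "members": ";".join(c.members)} for c in clusters],
            columns=["representative", "size", "members"]),
        ndir / "clusters.tsv")
    genome_io.write_tables(
        pd.DataFrame(
            [{"representative": f.cluster.representative,
              "types": ";".join(f.supporting_types),
              "mean_distance": round(f.mean_distance, 3),
              "mean_identity": round(f.mean_identity, 3)} for f in conserved],
            columns=["representative", "types", "mean_distance", "mean_identity"]),
        ndir / "conserved_families.tsv")
    state["loci"] = loci
    summary["neighborhoods"] = {
        "n_loci": len(loci),
        "n_clusters": len(clusters),
        "n_conserved_families": len(conserved),
        "conserved_types": {
            f.cluster.representative: list(f.supporting_types) for f in conserved},
    }


def _stage_enrich(cfg, outdir, state, summary):
    edir = outdir / "enrichment"
    edir.mkdir(exist_ok=True)
    cohort = state["cohort"]
    ss = np.random.SeedSequence([cfg.seed, 7])
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(len(cohort))]
    results = {}
    for (genome, _truth), gseed in zip(cohort, seeds):
        archs = state["architectures"][genome.id]
        accepted = [v.gene_id for v in state["verdicts"][genome.id] if v.accepted]
        partners = {}
        for b in accepted:
            p = homolog_curation.retrieve_cifA(genome, genome.get(b))
            partners[b] = p.id if p else None
        cmap = derive_category_map(genome, archs, accepted, partners)
        vec = enrichment.code_genome(genome, cmap)
        multi = enrichment.rearrangement_test_multi(
            vec, cfg.window, cfg.thresholds, n_reps=cfg.reps, seed=gseed,
            circular=cfg.circular)
        results[genome.id] = {
            "n": vec.n, "m": vec.m,
            "observed": multi[cfg.thresholds[0]].observed,
            "p_values": {str(t): multi[t].p_value for t in cfg.thresholds},
            "seed": gseed,
        }
    with open(edir / "enrichment.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    summary["enrich"] = results


def _stage_incongruence(cfg, outdir, state, summary):
    idir = outdir / "incongruence"
    idir.mkdir(exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    fam_seed = int(rng.integers(0, 2 ** 31))
    plain = synthetic_data.generate_cif_family(
        cfg.family_lineages, cfg.family_divergence, seed=fam_seed,
        segment_length=cfg.family_segment)
    swaps = []
    for _ in range(cfg.family_swaps):
        swaps.append(synthetic_data.pick_nonsister_pair(plain.tree_core, rng))
    family = synthetic_data.generate_cif_family(
        cfg.family_lineages, cfg.family_divergence, swap_pairs=swaps,
        seed=fam_seed, segment_length=cfg.family_segment)
    ids = sorted(family.sequences)
    msa = alignment_phylo.MSA(ids, [family.sequences[i] for i in ids])
    pair = alignment_phylo.segment_incongruence(msa, *family.segments)
    record = {
        "swap_pairs": [list(p) for p in family.swap_pairs],
        "rf_distance": pair.rf,
        "conflicting_bipartitions": [list(b) for b in pair.conflicting],
        "tree_core_true": family.tree_core.to_newick(),
        "tree_dub_true": family.tree_dub.to_newick(),
        "tree_core_inferred": pair.tree_a.to_newick(),
        "tree_dub_inferred": pair.tree_b.to_newick(),
    }
    with open(idir / "incongruence.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
    summary["incongruence"] = {"rf_distance": pair.rf,
                               "swap_pairs": [list(p) for p in family.swap_pairs]}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "curate": _stage_curate,
    "neighborhoods": _stage_neighborhoods,
    "enrich": _stage_enrich,
    "incongruence": _stage_incongruence,
}
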