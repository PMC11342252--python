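"""Simulator ground truth, determinism, and sequence-evolution calibration."""

import numpy as np
import pytest

from cifscape.alignment_phylo import p_distance_matrix, rf_distance
from cifscape.domain_annotation import annotate_protein
from cifscape.synthetic_data import (CATEGORIES, SimConfig, expected_p_distance,
                                     generate_cif_family, generate_cohort,
                                     generate_genome, generate_msa,
                                     pick_nonsister_pair)


def as_tuple(genome):
    return tuple((g.id, g.start, g.end, g.strand, g.protein_seq, g.pseudo)
                 for g in genome.genes)


def test_deterministic_given_seed():
    cfg = dict(n_genes=200, n_cif_loci=2, decoy_rate=0.1, pseudo_rate=0.1, seed=7)
    g1, t1 = generate_genome(SimConfig(**cfg))
    g2, t2 = generate_genome(SimConfig(**cfg))
    assert as_tuple(g1) == as_tuple(g2)
    assert t1 == t2


def test_planted_dyads_at_recorded_positions():
    genome, truth = generate_genome(SimConfig(n_genes=200, n_cif_loci=2, seed=7))
    assert len(truth.loci) == 2
    for locus in truth.loci:
        ia, ib = genome.index_of(locus.cifA), genome.index_of(locus.cifB)
        assert ib == ia + 1  # cifA directly upstream on the plus strand
        for gid in locus.category_genes:
            assert abs(genome.index_of(gid) - ib) <= 15


def test_zero_decoy_rate_means_no_decoys():
    genome, truth = generate_genome(SimConfig(n_genes=150, decoy_rate=0.0, seed=1))
    assert truth.decoy_ids == []
    assert not any("CR-type" in g.product for g in genome.genes)


def test_infeasible_packing_rejected():
    with pytest.raises(ValueError, match="infeasible"):
        SimConfig(n_genes=20, n_cif_loci=4)


def test_ground_truth_complete_and_detectable():
    genome, truth = generate_genome(SimConfig(n_genes=120, n_cif_loci=1,
                                              decoy_rate=0.1, seed=9))
    for gid in (truth.cifB_ids + truth.cifA_ids + truth.decoy_ids
                + truth.pseudo_ids + list(truth.categories)):
        assert gid in genome
    # every planted feature recoverable from the emitted proteins
    arch_b = annotate_protein(genome.get(truth.cifB_ids[0]).protein_seq)
    assert arch_b.labels == ["REase"] * 4
    for gid, cat in truth.categories.items():
        labels = annotate_protein(genome.get(gid).protein_seq).labels
        assert labels, f"category gene {gid} ({cat}) carries no domain"


def test_copy_number_histogram_matches_drawn():
    rng = np.random.default_rng(2024)
    drawn = rng.integers(1, 10, size=100)
    emitted = []
    for i, k in enumerate(drawn):
        _, truth = generate_genome(SimConfig(n_genes=100, n_cif_loci=int(k),
                                             seed=1000 + i))
        emitted.append(len(truth.cifB_ids))
    assert np.array_equal(np.bincount(drawn, minlength=10),
                          np.bincount(emitted, minlength=10))


def test_ground_truth_json_roundtrip(tmp_path):
    from cifscape.synthetic_data import GroundTruth

    _, truth = generate_genome(SimConfig(n_genes=100, n_cif_loci=2, seed=3))
    path = tmp_path / "truth.json"
    truth.to_json(path)
    assert GroundTruth.from_json(path) == truth


def test_cohort_shares_family_templates(small_cohort):
    # the same category planted in two genomes must be recognizably homologous
    from cifscape.neighborhood import pairwise_similarity

    by_cat = {}
    for genome, truth in small_cohort[:4]:
        for gid, cat in truth.categories.items():
            by_cat.setdefault(cat, []).append(genome.get(gid).protein_seq)
    for cat in CATEGORIES:
        a, b = by_cat[cat][0], by_cat[cat][1]
        sim = pairwise_similarity(a, b)
        assert sim.identity >= 0.30 and sim.coverage >= 0.80, cat


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def test_star_tree_zero_branches_gives_identical_rows():
    msa = generate_msa("(A:0,B:0,C:0);", 100, seed=1)
    assert len(set(msa.rows)) == 1


def test_msa_errors():
    with pytest.raises(ValueError):
        generate_msa("(A:0.1,B:0.1);", 0, seed=1)
    with pytest.raises(ValueError):
        generate_msa("(A:0.1);", 10, seed=1)


def test_p_distances_match_path_expectation():
    """Observed P-distances track the closed-form expectation of the
    20-state Poisson model, with path lengths taken from an independent
    newick parser."""
    import dendropy

    newick = "((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.05);"
    msa = generate_msa(newick, 2000, seed=3)
    dm = p_distance_matrix(msa)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    for a in "ABCD":
        for b in "ABCD":
            if a >= b:
                continue
            path = pdm.patristic_distance(taxa[a], taxa[b])
            assert abs(dm.loc[a, b] - expected_p_distance(path)) < 0.05


# ---------------------------------------------------------------------------
# Mosaic families
# ---------------------------------------------------------------------------

def test_no_swap_family_has_identical_true_trees():
    fam = generate_cif_family(6, 0.3, seed=5, segment_length=50)
    assert rf_distance(fam.tree_core, fam.tree_dub) == 0


def test_single_nonsister_swap_changes_topology():
    plain = generate_cif_family(8, 0.3, seed=5, segment_length=50)
    rng = np.random.default_rng(0)
    pair = pick_nonsister_pair(plain.tree_core, rng)
    fam = generate_cif_family(8, 0.3, swap_pairs=[pair], seed=5, segment_length=50)
    assert rf_distance(fam.tree_core, fam.tree_dub) >= 2


def test_swap_unknown_lineage_rejected():
    with pytest.raises(ValueError, match="unknown"):
        generate_cif_family(4, 0.3, swap_pairs=[("L01", "nope")], seed=1)


def test_pick_nonsister_pair_is_not_a_cherry():
    fam = generate_cif_family(8, 0.3, seed=13, segment_length=50)
    rng = np.random.default_rng(1)
    a, b = pick_nonsister_pair(fam.tree_core, rng)
    swapped = fam.tree_core.relabel({a: b, b: a})
    assert rf_distance(fam.tree_core, swapped) > 0
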