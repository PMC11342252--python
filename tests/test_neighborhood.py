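"""Neighborhood windows, similarity, single-linkage clustering, conservation."""

import numpy as np
import pytest

from cifscape.genome_io import Gene, Genome
from cifscape.neighborhood import (CifLocus, conserved_neighbors, dyad_locus,
                                   extract_neighborhood, pairwise_similarity,
                                   single_linkage_cluster)
from conftest import make_genome


def plain_genome(n, topology="linear"):
    return make_genome([(f"g{i:02d}", "+", "M" + "A" * 20) for i in range(n)],
                       topology=topology)


def test_full_window_both_sides():
    g = plain_genome(40)
    locus = extract_neighborhood(g, g.get("g20"), k=15)
    assert len(locus.upstream) == 15 and len(locus.downstream) == 15
    assert locus.upstream[-1].id == "g19" and locus.downstream[0].id == "g21"
    assert "g20" not in [x.id for x in locus.neighbors]


def test_window_truncated_at_linear_edge():
    g = plain_genome(40)
    locus = extract_neighborhood(g, g.get("g03"), k=15)
    assert len(locus.upstream) == 3 and len(locus.downstream) == 15


def test_circular_wrap_never_duplicates():
    g = plain_genome(20, topology="circular")
    locus = extract_neighborhood(g, g.get("g10"), k=15, wrap=True)
    ids = [x.id for x in locus.neighbors]
    assert len(ids) == len(set(ids)) == 19  # everything but the anchor
    assert "g10" not in ids
    # wrap only applies when requested
    trunc = extract_neighborhood(g, g.get("g10"), k=15, wrap=False)
    assert len(trunc.neighbors) == 10 + 9


def test_dyad_locus_excludes_partner_and_reports_offsets():
    g = plain_genome(30)
    locus = dyad_locus(g, "g10", cifA_id="g09", k=5, cif_type="t")
    assert "g09" not in [x.id for x in locus.neighbors]
    offs = locus.offsets()
    # cifA (g09) belongs to the dyad, so g08 sits directly upstream of it
    assert offs["g11"] == 1 and offs["g08"] == -1 and offs["g15"] == 5


def test_absent_anchor_is_error():
    g = plain_genome(5)
    ghost = Gene(id="nope", contig="c1", start=1, end=3, strand="+")
    with pytest.raises(KeyError):
        extract_neighborhood(g, ghost)


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------

def test_identical_sequences_full_identity():
    s = "MKWVTFISLLLLFSSAYS"
    sim = pairwise_similarity(s, s)
    assert sim.identity == 1.0 and sim.coverage == 1.0


def test_unrelated_alphabets_zero_similarity():
    sim = pairwise_similarity("PPPPPPPPPP", "WWWWWWWWWW")
    assert sim.identity == 0.0 and sim.coverage == 0.0


def test_coverage_relative_to_shorter():
    full = "MKWVTFISLLLLFSSAYSRGVFRRDAHKSE"
    half = full[:15]
    sim = pairwise_similarity(full, half)
    assert sim.coverage == 1.0 and sim.identity == 1.0


def test_similarity_symmetric():
    a, b = "MKWVTFISLLLLFSSAYSRG", "MKWVTFMSLLLLFSAAYSGG"
    assert pairwise_similarity(a, b) == pairwise_similarity(b, a)


def test_empty_sequence_error():
    with pytest.raises(ValueError):
        pairwise_similarity("", "MA")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def mutate(seq, every, rng_letter="W"):
    return "".join(rng_letter if i % every == 0 else c for i, c in enumerate(seq))


BASE = ("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ"
        "FEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLSPLHSVYVDQWDWE")


def test_identical_triplet_single_cluster():
    clusters = single_linkage_cluster({"a": BASE, "b": BASE, "c": BASE},
                                      prefilter=None)
    assert len(clusters) == 1 and clusters[0].members == ["a", "b", "c"]


def test_single_linkage_chains_through_intermediate():
    # a~b and b~c share halves; a~c share nothing
    left, right, far = BASE[:60], BASE[60:], "W" * 60
    prots = {"a": left + far, "b": left + right, "c": far + right}
    clusters = single_linkage_cluster(prots, min_identity=0.3,
                                      min_coverage=0.45, prefilter=None)
    assert len(clusters) == 1  # chained into one family
    tight = single_linkage_cluster(prots, min_identity=0.95,
                                   min_coverage=0.95, prefilter=None)
    assert len(tight) == 3


def test_all_dissimilar_gives_singletons():
    prots = {"a": "P" * 30, "b": "W" * 30, "c": "G" * 30}
    clusters = single_linkage_cluster(prots, prefilter=None)
    assert [c.members for c in clusters] == [["a"], ["b"], ["c"]]


def test_clustering_order_invariant(small_cohort):
    genome, truth = small_cohort[0]
    prots = {gid: genome.get(gid).protein_seq for gid in truth.categories}
    genome2, truth2 = small_cohort[1]
    prots.update({gid: genome2.get(gid).protein_seq for gid in truth2.categories})
    fwd = single_linkage_cluster(dict(sorted(prots.items())))
    rev = single_linkage_cluster(dict(sorted(prots.items(), reverse=True)))
    assert [c.members for c in fwd] == [c.members for c in rev]


def test_prefilter_matches_exhaustive(small_cohort):
    genome, truth = small_cohort[0]
    prots = {gid: genome.get(gid).protein_seq for gid in truth.categories}
    prots.update({g.id: g.protein_seq for g in genome.genes[:20] if g.protein_seq})
    with_filter = single_linkage_cluster(prots, prefilter=3)
    without = single_linkage_cluster(prots, prefilter=None)
    assert [c.members for c in with_filter] == [c.members for c in without]


def test_raising_identity_threshold_only_refines():
    rng = np.random.default_rng(0)
    variants = {}
    for i in range(6):
        s = list(BASE)
        for j in rng.choice(len(s), size=10 + 8 * i, replace=False):
            s[j] = "W"
        variants[f"v{i}"] = "".join(s)
    loose = single_linkage_cluster(variants, min_identity=0.3, prefilter=None)
    strict = single_linkage_cluster(variants, min_identity=0.8, prefilter=None)
    loose_map = {m: i for i, c in enumerate(loose) for m in c.members}
    for c in strict:
        assert len({loose_map[m] for m in c.members}) == 1  # refinement


# ---------------------------------------------------------------------------
# Conserved-neighbor calling
# ---------------------------------------------------------------------------

def stub_gene(gid):
    return Gene(id=gid, contig="c", start=1, end=3, strand="+",
                protein_seq="M")


def make_locus(gid_neighbors, cif_type, genome_id="g"):
    return CifLocus(genome_id=genome_id, cifB=f"{genome_id}_b", cifA=None,
                    downstream=[stub_gene(g) for g in gid_neighbors],
                    cif_type=cif_type)


def random_protein(seed, length=120):
    rng = np.random.default_rng(seed)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aa[i] for i in rng.integers(0, 20, size=length))


def test_conserved_family_requires_two_types_and_divergence():
    r1, r2, r3 = (random_protein(s) for s in (1, 2, 3))  # unrelated founders
    prots = {"fam1_a": r1, "fam1_b": mutate(r1, 7), "same_a": r2, "same_b": r2,
             "solo_a": r3, "solo_b": mutate(r3, 8)}
    clusters = single_linkage_cluster(prots, prefilter=None)
    loci = [
        make_locus(["fam1_a", "same_a", "solo_a"], "type-1", "g1"),
        make_locus(["fam1_b", "same_b"], "type-2", "g2"),
        make_locus(["solo_b"], "type-1", "g3"),
    ]
    fams = conserved_neighbors(loci, clusters, prots)
    reported = {frozenset(f.cluster.members) for f in fams}
    # diversified family spanning two types: reported
    assert frozenset({"fam1_a", "fam1_b"}) in reported
    # identical copies fail the diversification ceiling
    assert frozenset({"same_a", "same_b"}) not in reported
    # family confined to one type: not reported
    assert frozenset({"solo_a", "solo_b"}) not in reported


def test_untyped_loci_excluded_with_warning():
    prots = {"x": BASE, "y": mutate(BASE, 7)}
    clusters = single_linkage_cluster(prots, prefilter=None)
    loci = [make_locus(["x"], None, "g1"), make_locus(["y"], "type-2", "g2")]
    with pytest.warns(UserWarning):
        fams = conserved_neighbors(loci, clusters, prots)
    assert fams == []


def test_no_loci_empty_report():
    assert conserved_neighbors([], [], {}) == []
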