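"""Consensus, P-distances, neighbor joining, Robinson-Foulds, incongruence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cifscape.alignment_phylo import (MSA, Tree, conflicting_bipartitions,
                                      consensus_annotation, nj_tree,
                                      p_distance_matrix, rf_distance,
                                      segment_incongruence)
from cifscape.synthetic_data import generate_cif_family, pick_nonsister_pair


# ---------------------------------------------------------------------------
# MSA and consensus
# ---------------------------------------------------------------------------

def column_msa(*columns):
    """Build an MSA from per-column residue strings (rows = positions)."""
    nrows = len(columns[0])
    rows = ["".join(col[i] for col in columns) for i in range(nrows)]
    return MSA([f"s{i}" for i in range(nrows)], rows)


def test_msa_invariants():
    with pytest.raises(ValueError):
        MSA(["a", "b"], ["AC", "A"])
    with pytest.raises(ValueError):
        MSA(["a", "a"], ["AC", "AC"])


def test_consensus_threshold_arithmetic():
    col_8_aliphatic = "ILVILVIL" + "KR"     # 8/10 aliphatic
    col_7_aliphatic = "ILVILVI" + "DDE"     # 7/10; no class reaches 75%
    msa = column_msa(col_8_aliphatic, col_7_aliphatic)
    labels = consensus_annotation(msa, threshold=0.75)
    assert labels == ["aliphatic", None]
    assert consensus_annotation(msa, threshold=0.80)[0] == "aliphatic"


def test_consensus_identity_beats_class():
    msa = column_msa("AAAAAAAAAA", "AAAAAAAAGG")
    labels = consensus_annotation(msa, threshold=0.75)
    assert labels[0] == "A"       # identity column labelled by the residue
    assert labels[1] == "A"       # 8/10 A still clears 75% as identity


def test_consensus_gap_handling():
    msa = column_msa("----------", "ILVI------")
    labels = consensus_annotation(msa, threshold=0.75)
    assert labels[0] is None             # all-gap column
    assert labels[1] == "aliphatic"      # 4/4 non-gap residues qualify


def test_consensus_threshold_validation():
    with pytest.raises(ValueError):
        consensus_annotation(column_msa("AA"), threshold=0.0)


# ---------------------------------------------------------------------------
# P-distances
# ---------------------------------------------------------------------------

def test_p_distance_basic():
    msa = MSA(["a", "b"], ["ACDEFGHIKLMN", "ACDEFGHIKWWW"])
    dm = p_distance_matrix(msa)
    assert dm.loc["a", "b"] == pytest.approx(3 / 12)
    assert dm.loc["a", "a"] == 0.0


def test_p_distance_pairwise_deletion():
    msa = MSA(["a", "b"], ["AC-EF", "ACW-F"])  # 3 mutually ungapped, 0 diffs
    assert p_distance_matrix(msa).loc["a", "b"] == 0.0


def test_p_distance_no_comparable_columns_error():
    msa = MSA(["a", "b", "c"], ["A--", "-C-", "AC-"])
    with pytest.raises(ValueError, match="'a'.*'b'|'b'.*'a'"):
        p_distance_matrix(msa)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def additive_matrix(tree: Tree) -> pd.DataFrame:
    leaves = sorted(tree.leaf_set())
    d = pd.DataFrame(0.0, index=leaves, columns=leaves)
    for a, b in itertools.combinations(leaves, 2):
        d.loc[a, b] = d.loc[b, a] = tree.path_length(a, b)
    return d


def test_nj_three_taxa():
    dm = pd.DataFrame([[0, 2, 3], [2, 0, 3], [3, 3, 0]],
                      index=list("ABC"), columns=list("ABC"))
    tree = nj_tree(dm)
    assert tree.leaf_set() == frozenset("ABC")
    assert tree.bipartitions() == frozenset()  # single unrooted topology


def test_nj_recovers_additive_quartet():
    truth = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    tree = nj_tree(additive_matrix(truth))
    assert rf_distance(tree, truth) == 0


def test_nj_rejects_asymmetric_matrix():
    dm = pd.DataFrame([[0, 1, 2], [9, 0, 3], [2, 3, 0]],
                      index=list("ABC"), columns=list("ABC"))
    with pytest.raises(ValueError, match="symmetric"):
        nj_tree(dm)


def test_nj_agrees_with_independent_implementation():
    """Cross-check topology against scikit-bio's NJ on a simulated matrix."""
    import skbio

    fam = generate_cif_family(7, 0.4, seed=21, segment_length=400)
    ids = sorted(fam.sequences)
    dm = p_distance_matrix(MSA(ids, [fam.sequences[i] for i in ids]))
    mine = nj_tree(dm)
    sk = skbio.tree.nj(skbio.DistanceMatrix(dm.values, ids=ids))
    theirs = Tree.from_newick(str(sk))
    assert rf_distance(mine, theirs) == 0


def test_nj_branch_lengths_nonnegative():
    fam = generate_cif_family(6, 0.2, seed=3, segment_length=200)
    ids = sorted(fam.sequences)
    tree = nj_tree(p_distance_matrix(MSA(ids, [fam.sequences[i] for i in ids])))

    def walk(node):
        assert node.length >= 0
        for c in node.children:
            walk(c)

    walk(tree.root)


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------

def test_rf_identical_trees_zero():
    t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    assert rf_distance(t, Tree.from_newick(t.to_newick())) == 0


def test_rf_distinct_quartets_two():
    t1 = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = Tree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
    assert rf_distance(t1, t2) == 2
    # canonical side of each split is the one without the smallest leaf (A)
    assert conflicting_bipartitions(t1, t2) == [("B", "D"), ("C", "D")]


def test_rf_caterpillar_vs_nni_neighbor():
    # one nearest-neighbor interchange on a 6-taxon caterpillar: exactly one
    # bipartition lost, one gained
    cat = Tree.from_newick("(A:1,(B:1,(C:1,(D:1,(E:1,F:1):1):1):1):1);")
    nni = Tree.from_newick("(A:1,(C:1,(B:1,(D:1,(E:1,F:1):1):1):1):1);")
    assert rf_distance(cat, nni) == 2


def test_rf_leafset_mismatch_error():
    t1 = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = Tree.from_newick("((A:1,B:1):1,(C:1,E:1):1);")
    with pytest.raises(ValueError):
        rf_distance(t1, t2)


def test_rf_agrees_with_dendropy():
    import dendropy

    for seed in range(5):
        fa = generate_cif_family(8, 0.3, seed=seed, segment_length=50)
        fb = generate_cif_family(8, 0.3, seed=seed + 100, segment_length=50)
        t1, t2 = fa.tree_core, fb.tree_core
        ns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                               taxon_namespace=ns)
        d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                               taxon_namespace=ns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert rf_distance(t1, t2) == expected


def test_rf_is_a_metric_spot_check():
    trees = [generate_cif_family(6, 0.3, seed=s, segment_length=50).tree_core
             for s in (1, 2, 3)]
    for ta, tb in itertools.combinations(trees, 2):
        assert rf_distance(ta, tb) == rf_distance(tb, ta)
    for ta, tb, tc in itertools.permutations(trees, 3):
        assert rf_distance(ta, tc) <= rf_distance(ta, tb) + rf_distance(tb, tc)


# ---------------------------------------------------------------------------
# Segment incongruence
# ---------------------------------------------------------------------------

def family_msa(fam):
    ids = sorted(fam.sequences)
    return MSA(ids, [fam.sequences[i] for i in ids])


def test_identical_segments_always_congruent():
    fam = generate_cif_family(6, 0.3, seed=17, segment_length=300)
    msa = family_msa(fam)
    pair = segment_incongruence(msa, (0, 300), (0, 300))
    assert pair.rf == 0 and pair.conflicting == []


def test_mosaic_family_detected():
    plain = generate_cif_family(8, 0.3, seed=23, segment_length=1000)
    pair_names = pick_nonsister_pair(plain.tree_core, np.random.default_rng(2))
    fam = generate_cif_family(8, 0.3, swap_pairs=[pair_names], seed=23,
                              segment_length=1000)
    result = segment_incongruence(family_msa(fam), *fam.segments)
    assert result.rf > 0
    assert result.conflicting


def test_empty_segment_error():
    fam = generate_cif_family(4, 0.3, seed=1, segment_length=100)
    with pytest.raises(ValueError):
        segment_incongruence(family_msa(fam), (0, 0), (0, 100))
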