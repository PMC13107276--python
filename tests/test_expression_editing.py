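"""FPKM, clustering, and the RNA-editing caller."""

import numpy as np
import pandas as pd
import pytest

from plastodecay.expression_editing import (
    EditingCallParams,
    call_editing_sites,
    cluster_expression,
    fpkm,
    shared_editing_sites,
)
from plastodecay.plastome_io import GeneFeature
from plastodecay.stats_core import anova_lsd


# ----------------------------------------------------------------------
# FPKM


def test_fpkm_formula_arithmetic():
    counts = pd.DataFrame({"s1": [10, 0]}, index=["a", "b"])
    lengths = pd.Series({"a": 1000, "b": 500})
    out = fpkm(counts, lengths, totals={"s1": 1_000_000})
    assert out.loc["a", "s1"] == pytest.approx(10.0)
    assert out.loc["b", "s1"] == 0.0


def test_fpkm_zero_iff_zero_count():
    rng = np.random.default_rng(51)
    counts = pd.DataFrame(rng.integers(0, 50, (8, 3)), columns=list("xyz"))
    counts.iloc[0, 0] = 0
    lengths = pd.Series(rng.integers(200, 3000, 8), index=counts.index)
    out = fpkm(counts, lengths)
    assert ((out == 0) == (counts == 0)).all().all()


def test_fpkm_conservation_identity():
    rng = np.random.default_rng(52)
    counts = pd.DataFrame(rng.integers(1, 10_000, (20, 4)), columns=list("abcd"))
    lengths = pd.Series(rng.integers(100, 5000, 20), index=counts.index)
    out = fpkm(counts, lengths)  # totals = column sums: features partition fragments
    identity = (out.mul(lengths / 1000.0, axis=0)).sum(axis=0)
    assert np.allclose(identity.values, 1e6, rtol=1e-9)


def test_fpkm_zero_total_raises():
    counts = pd.DataFrame({"s1": [0, 0]})
    lengths = pd.Series([100, 100], index=counts.index)
    with pytest.raises(ValueError):
        fpkm(counts, lengths)


# ----------------------------------------------------------------------
# clustering


def test_identical_profiles_merge_at_zero():
    m = pd.DataFrame(
        {"s1": [1.0, 1.0, 5.0], "s2": [1.0, 1.0, 5.0], "s3": [0.0, 0.0, 3.0]},
        index=["f1", "f2", "f3"],
    )
    out = cluster_expression(m)
    # features f1 and f2 are identical rows: first merge at height 0
    assert out.feature_linkage[0, 2] == pytest.approx(0.0)


def test_first_merge_of_collinear_points():
    m = pd.DataFrame({"s1": [0.0, 1.0, 10.0], "s2": [0.0, 1.0, 10.0]}, index=list("abc"))
    out = cluster_expression(m)
    first = set(out.feature_linkage[0, :2].astype(int))
    assert first == {0, 1}  # points 0 and 1 merge first


def test_average_linkage_matches_direct_recomputation():
    rng = np.random.default_rng(53)
    m = pd.DataFrame(rng.normal(size=(6, 4)))
    Z = cluster_expression(m).feature_linkage

    # independent UPGMA: track clusters and average pairwise Euclidean distance
    pts = [m.values[i : i + 1] for i in range(6)]
    clusters = {i: [i] for i in range(6)}
    heights = []
    next_id = 6
    active = list(range(6))
    while len(active) > 1:
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1 :]:
                d = np.mean(
                    [
                        np.linalg.norm(m.values[p] - m.values[q])
                        for p in clusters[a]
                        for q in clusters[b]
                    ]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters[a] + clusters[b]
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    assert np.allclose(sorted(Z[:, 2]), sorted(heights), rtol=1e-9)


def test_nan_matrix_rejected():
    m = pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, 1.0]})
    with pytest.raises(ValueError):
        cluster_expression(m)


def test_clustering_permutation_invariant():
    rng = np.random.default_rng(54)
    m = pd.DataFrame(rng.normal(size=(7, 4)), index=[f"f{i}" for i in range(7)])
    perm = m.sample(frac=1, random_state=1)
    h1 = sorted(cluster_expression(m).feature_linkage[:, 2])
    h2 = sorted(cluster_expression(perm).feature_linkage[:, 2])
    assert np.allclose(h1, h2)


# ----------------------------------------------------------------------
# editing caller


def _pileup_row(pos, strand, ref, **counts):
    base = {"A": 0, "C": 0, "G": 0, "T": 0}
    base.update(counts)
    return {"pos": pos, "strand": strand, "refbase": ref, **base}


def test_low_coverage_not_called():
    # coverage 59 at 50% variant: below the coverage floor
    df = pd.DataFrame(
        [_pileup_row(5, "+", "C", C=15, T=15), _pileup_row(5, "-", "C", C=14, T=15)]
    )
    sites, _ = call_editing_sites(df, "ACGTA" + "C" + "ACGTA" * 3)
    assert sites == []


def test_balanced_variant_called_with_efficiency():
    genome = "A" * 50 + "C" + "A" * 49
    df = pd.DataFrame(
        [_pileup_row(50, "+", "C", C=35, T=15), _pileup_row(50, "-", "C", C=35, T=15)]
    )
    sites, _ = call_editing_sites(df, genome)
    assert len(sites) == 1
    s = sites[0]
    assert s.efficiency == pytest.approx(0.30)
    assert s.edit_type == "C->U"
    # binomial tail at eps=0.001 is far below 1e-6
    assert s.variant_p < 1e-6


def test_strand_biased_site_rejected():
    genome = "A" * 50 + "C" + "A" * 49
    df = pd.DataFrame(
        [_pileup_row(50, "+", "C", C=20, T=58), _pileup_row(50, "-", "C", C=60, T=2)]
    )
    sites, _ = call_editing_sites(df, genome)
    assert sites == []


def test_g_to_a_is_antisense_editing():
    genome = "A" * 30 + "G" + "A" * 29
    df = pd.DataFrame(
        [_pileup_row(30, "+", "G", G=40, A=12), _pileup_row(30, "-", "G", G=40, A=12)]
    )
    sites, _ = call_editing_sites(df, genome)
    assert len(sites) == 1 and sites[0].edit_type == "C->U"


def test_non_editing_variant_reported_separately():
    genome = "A" * 30 + "C" + "A" * 29
    df = pd.DataFrame(
        [_pileup_row(30, "+", "C", C=40, G=12), _pileup_row(30, "-", "C", C=40, G=12)]
    )
    sites, others = call_editing_sites(df, genome)
    assert sites == [] and len(others) == 1


def test_codon_annotation_silent_vs_nonsilent():
    # gene on + strand: codons TCT(Ser) GCA(Ala); editing C in codon 2 pos 1 -> GCA->ACA? no:
    # plant ref C at codon position 2 of TCT -> TTT stays Ser? TCT->TTT is Ser->Phe (non-silent)
    cds = "ATGTCTGCATAA"
    genome = "A" * 20 + cds + "A" * 20
    feat = GeneFeature("gene1", "PS", "+", [(20, 20 + len(cds))])
    # position of the C in TCT codon (codon 2, codon position 2): index 20+4
    df = pd.DataFrame(
        [_pileup_row(24, "+", "C", C=50, T=30), _pileup_row(24, "-", "C", C=50, T=30)]
    )
    sites, _ = call_editing_sites(df, genome, [feat])
    assert len(sites) == 1
    s = sites[0]
    assert s.gene == "gene1"
    assert s.codon_position == 2
    assert s.silent is False
    # third-position change GCA->GCA? test a silent one: C at wobble of GCx
    df2 = pd.DataFrame(
        [_pileup_row(20 + 8, "+", "A", A=50, T=0)]  # sanity: non-variant position
    )
    # silent case: codon GCC -> GCT (Ala->Ala); rebuild gene
    cds2 = "ATGGCCTAA"
    genome2 = "A" * 10 + cds2 + "A" * 10
    feat2 = GeneFeature("gene2", "PS", "+", [(10, 10 + len(cds2))])
    df3 = pd.DataFrame(
        [_pileup_row(15, "+", "C", C=40, T=25), _pileup_row(15, "-", "C", C=40, T=25)]
    )
    sites3, _ = call_editing_sites(df3, genome2, [feat2])
    assert len(sites3) == 1
    assert sites3[0].codon_position == 3
    assert sites3[0].silent is True


def test_minus_strand_gene_annotation():
    from plastodecay._seedextend import revcomp

    cds = "ATGTCTGCATAA"  # on minus strand
    genome = "A" * 20 + revcomp(cds) + "A" * 20
    feat = GeneFeature("geneM", "PS", "-", [(20, 20 + len(cds))])
    # transcript C at codon 2 position 2 (TCT) maps to genome G
    # transcript index 4 -> genome position 20 + (len-1-4)
    gpos = 20 + len(cds) - 1 - 4
    assert genome[gpos] == "G"
    df = pd.DataFrame(
        [_pileup_row(gpos, "+", "G", G=50, A=30), _pileup_row(gpos, "-", "G", G=50, A=30)]
    )
    sites, _ = call_editing_sites(df, genome, [feat])
    assert len(sites) == 1
    s = sites[0]
    assert s.gene == "geneM" and s.codon_position == 2 and s.silent is False


def test_position_outside_genome_raises():
    df = pd.DataFrame([_pileup_row(99, "+", "C", C=70)])
    with pytest.raises(ValueError):
        call_editing_sites(df, "ACGT")


# ----------------------------------------------------------------------
# shared sites


def _site(gene, pos, eff):
    from plastodecay.expression_editing import EditingSite

    return EditingSite(pos, "C", "T", 100, eff, "C->U", gene=gene)


def test_shared_sites_intersection():
    a = [_site("g1", 10, 0.3), _site("g1", 50, 0.5)]
    b = [_site("g1", 10, 0.4), _site("g1", 50, 0.6)]
    c = [_site("g1", 10, 0.2)]
    keys, mat = shared_editing_sites({"A": a, "B": b})
    assert len(keys) == 2 and mat.shape == (2, 2)
    keys2, mat2 = shared_editing_sites({"A": a, "B": b, "C": c})
    assert keys2 == [("g1", 10)]
    assert mat2.shape == (3, 1)


def test_planted_low_efficiency_species_flagged_by_anova():
    rng = np.random.default_rng(55)
    n_sites = 12
    base = rng.uniform(0.4, 0.8, n_sites)
    lists = {}
    for sp, shift in (("A", -0.2), ("B", 0.0), ("C", 0.0)):
        effs = np.clip(base + shift + rng.normal(0, 0.02, n_sites), 0.01, 0.99)
        lists[sp] = [_site("g1", 10 * i, e) for i, e in enumerate(effs)]
    _, mat = shared_editing_sites(lists)
    res = anova_lsd({sp: mat.loc[sp].values for sp in mat.index})
    assert res.pvalue < 0.05
    assert res.letters["A"] != res.letters["B"]
    assert res.letters["B"] == res.letters["C"]
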