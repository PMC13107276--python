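"""FPKM, expression clustering, and C-to-U RNA-editing site calling.

Expression is summarized as FPKM from strand-specific fragment counts:

    FPKM = (fragments for feature * 10^6) / (total fragments in sample
            * feature length in kilobases)

where the per-sample total counts fragments mapped to both strands.
Editing sites are called from strand-resolved pileups with the
thresholds: coverage >= 60, variant frequency >= 10%, one-sided
binomial variant p <= 1e-6 against the sequencing error rate, and a
Fisher strand-bias screen that rejects sites whose variant reads are
significantly concentrated (> 65%) on one strand.  Only C->T (sense
C-to-U) and G->A (antisense) changes count as editing candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from . import _seedextend
from .codon import translate_codon
from .plastome_io import GeneFeature


# ----------------------------------------------------------------------
# FPKM


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    totals: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """FPKM matrix (features x samples) from a fragment-count matrix.

    ``totals`` defaults to the per-sample column sums; pass the true
    totals when the count table covers only a subset of mapped
    fragments.
    """
    counts = counts.astype(float)
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index)
        raise ValueError(f"missing lengths for features: {missing}")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = pd.Series(totals, dtype=float).reindex(counts.columns)
    if (totals <= 0).any() or totals.isna().any():
        raise ValueError("total fragment count must be positive for every sample")
    len_kb = lengths / 1000.0
    return counts.mul(1e6).div(totals, axis=1).div(len_kb, axis=0)


# ----------------------------------------------------------------------
# Clustering (heatmap dendrograms over samples and features)


@dataclass
class ExpressionClustering:
    sample_linkage: np.ndarray
    feature_linkage: np.ndarray
    sample_order: List[str]
    feature_order: List[str]
    sample_newick: str
    feature_newick: str


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = rec(node.left), rec(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return rec(tree) + ";"


def cluster_expression(matrix: pd.DataFrame) -> ExpressionClustering:
    """Average-linkage (UPGMA) clustering on Euclidean distances, rows and columns."""
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 features and 2 samples")
    if matrix.isna().any().any():
        raise ValueError("NaN values in expression matrix")
    feat_Z = hierarchy.linkage(matrix.values, method="average", metric="euclidean")
    samp_Z = hierarchy.linkage(matrix.values.T, method="average", metric="euclidean")
    feat_order = [matrix.index[i] for i in hierarchy.leaves_list(feat_Z)]
    samp_order = [matrix.columns[i] for i in hierarchy.leaves_list(samp_Z)]
    return ExpressionClustering(
        sample_linkage=samp_Z,
        feature_linkage=feat_Z,
        sample_order=list(samp_order),
        feature_order=list(feat_order),
        sample_newick=_linkage_to_newick(samp_Z, list(matrix.columns)),
        feature_newick=_linkage_to_newick(feat_Z, list(matrix.index)),
    )


# ----------------------------------------------------------------------
# RNA-editing calling


@dataclass(frozen=True)
class EditingCallParams:
    min_coverage: int = 60
    min_freq: float = 0.10
    max_variant_p: float = 1e-6
    strand_bias_p: float = 1e-5
    bias_threshold: float = 0.65
    error_rate: float = 0.001

    def __post_init__(self):
        if not (0 < self.min_freq < 1):
            raise ValueError("min_freq must lie in (0, 1)")
        if min(self.min_coverage, self.max_variant_p, self.strand_bias_p, self.error_rate) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class EditingSite:
    position: int
    ref: str
    alt: str
    coverage: int
    efficiency: float
    edit_type: str  # 'C->U' for both sense C->T and antisense G->A
    gene: Optional[str] = None
    codon_position: Optional[int] = None  # 1..3 within the CDS codon, None if intergenic
    silent: Optional[bool] = None
    variant_p: float = float("nan")
    strand_bias_pvalue: Optional[float] = None


_EDIT_ALT = {"C": "T", "G": "A"}


def _annotate_cds(
    pos: int, ref: str, alt: str, genome: str, cds_features: Sequence[GeneFeature]
) -> Tuple[Optional[str], Optional[int], Optional[bool]]:
    """Gene, codon position and silence of a substitution at ``pos`` (0-based)."""
    for feat in cds_features:
        offset = 0
        for a, b in feat.intervals:
            if a <= pos < b:
                cds_seq = "".join(genome[x:y] for x, y in feat.intervals)
                idx_fwd = offset + (pos - a)
                if feat.strand == "-":
                    cds_seq = _seedextend.revcomp(cds_seq)
                    idx = len(cds_seq) - 1 - idx_fwd
                    base_ref = _seedextend.revcomp(ref)
                    base_alt = _seedextend.revcomp(alt)
                else:
                    idx = idx_fwd
                    base_ref, base_alt = ref, alt
                codon_i, codon_pos = divmod(idx, 3)
                codon = cds_seq[3 * codon_i : 3 * codon_i + 3]
                if len(codon) < 3 or codon[codon_pos] != base_ref:
                    return feat.name, codon_pos + 1, None
                edited = codon[:codon_pos] + base_alt + codon[codon_pos + 1 :]
                silent = translate_codon(codon) == translate_codon(edited)
                return feat.name, codon_pos + 1, silent
            offset += b - a
    return None, None, None


def call_editing_sites(
    pileup: pd.DataFrame,
    genome: str,
    cds_features: Sequence[GeneFeature] = (),
    params: EditingCallParams = EditingCallParams(),
) -> Tuple[List[EditingSite], List[EditingSite]]:
    """Editing sites from a strand-resolved pileup table.

    ``pileup`` columns: pos (0-based), strand (+/-), refbase, A, C, G, T
    — counts of read bases per reference position and read strand.
    Returns (editing_sites, other_variants); only C->T / G->A changes
    are editing candidates, any other variant passing the same
    numerical filters is reported in the second list.
    """
    n = len(genome)
    required = {"pos", "strand", "refbase", "A", "C", "G", "T"}
    if not required.issubset(pileup.columns):
        raise ValueError(f"pileup must have columns {sorted(required)}")
    if (pileup["pos"] < 0).any() or (pileup["pos"] >= n).any():
        bad = pileup.loc[(pileup["pos"] < 0) | (pileup["pos"] >= n), "pos"].iloc[0]
        raise ValueError(f"pileup position {bad} outside genome [0,{n})")

    sites: List[EditingSite] = []
    others: List[EditingSite] = []
    bases = ["A", "C", "G", "T"]
    # vectorized prescreen: only positions with coverage >= min_coverage
    # and some non-reference base at >= min_freq need the full filters
    combined_all = pileup.groupby("pos", sort=True)[bases].sum()
    cov_all = combined_all.sum(axis=1)
    ref_all = pileup.groupby("pos", sort=True)["refbase"].first().str.upper()
    # max non-reference count: zero the reference column then take the max
    nonref = combined_all.copy()
    for b in bases:
        nonref.loc[ref_all == b, b] = 0
    candidates = cov_all.index[
        (cov_all >= params.min_coverage)
        & (nonref.max(axis=1) >= params.min_freq * cov_all)
        & ref_all.isin(bases)
    ]
    plus_all = pileup[pileup["strand"] == "+"].groupby("pos")[bases].sum()
    minus_all = pileup[pileup["strand"] == "-"].groupby("pos")[bases].sum()
    zero = pd.Series(0, index=bases, dtype=float)
    for pos in candidates:
        ref = ref_all.loc[pos]
        plus = plus_all.loc[pos] if pos in plus_all.index else zero
        minus = minus_all.loc[pos] if pos in minus_all.index else zero
        combined = combined_all.loc[pos]
        coverage = int(cov_all.loc[pos])
        for alt in bases:
            if alt == ref:
                continue
            x = int(combined[alt])
            if x == 0:
                continue
            freq = x / coverage
            if freq < params.min_freq:
                continue
            variant_p = float(stats.binom.sf(x - 1, coverage, params.error_rate))
            if variant_p > params.max_variant_p:
                continue
            vp, vm = int(plus[alt]), int(minus[alt])
            bias_p: Optional[float] = None
            if x > 0:
                top = max(vp, vm) / x
                if top > params.bias_threshold:
                    rp, rm = int(plus[ref]), int(minus[ref])
                    _, bias_p = stats.fisher_exact([[vp, rp], [vm, rm]], alternative="two-sided")
                    if bias_p < params.strand_bias_p:
                        continue  # significantly strand-biased: reject
            gene, codon_pos, silent = _annotate_cds(int(pos), ref, alt, genome, cds_features)
            site = EditingSite(
                position=int(pos), ref=ref, alt=alt, coverage=coverage,
                efficiency=freq, edit_type="C->U" if _EDIT_ALT.get(ref) == alt else f"{ref}->{alt}",
                gene=gene, codon_position=codon_pos, silent=silent,
                variant_p=variant_p, strand_bias_pvalue=bias_p,
            )
            if _EDIT_ALT.get(ref) == alt:
                sites.append(site)
            else:
                others.append(site)
    return sites, others


def sites_table(sites: Iterable[EditingSite]) -> pd.DataFrame:
    """VCF-like flat table of called sites."""
    rows = [
        {
            "pos": s.position, "ref": s.ref, "alt": s.alt, "coverage": s.coverage,
            "efficiency": s.efficiency, "gene": s.gene, "codon_pos": s.codon_position,
            "silent": s.silent, "edit_type": s.edit_type, "variant_p": s.variant_p,
        }
        for s in sites
    ]
    return pd.DataFrame(rows)


def shared_editing_sites(
    site_lists: Mapping[str, Sequence[EditingSite]],
) -> Tuple[List[Tuple], pd.DataFrame]:
    """Sites present in every species and their efficiency matrix.

    Sites are matched by (gene, position); the efficiency matrix is
    species x sites, suitable for downstream ANOVA + LSD.
    """
    if len(site_lists) < 2:
        raise ValueError("need site lists from at least 2 species")
    keysets = []
    for sp, sites in site_lists.items():
        keysets.append({(s.gene, s.position) for s in sites})
    shared = sorted(set.intersection(*keysets), key=lambda k: (str(k[0]), k[1]))
    if not shared:
        import warnings

        warnings.warn("no shared editing sites across species")
    data = {}
    for sp, sites in site_lists.items():
        by_key = {(s.gene, s.position): s.efficiency for s in sites}
        data[sp] = [by_key[k] for k in shared]
    cols = [f"{g}:{p}" for g, p in shared]
    return shared, pd.DataFrame(data, index=cols).T
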