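"""Coverage-based gene-status classification.

Each annotated ORF is aligned globally to the reference (tobacco-style)
CDS with the scoring match +1 / mismatch -1 / gap open -5 / gap extend
-1.  Coverage is the proportion of non-gap reference bases aligned with
bases of the query; ORFs with coverage >= 0.70 are called intact, below
that pseudogene, and genes with no detectable homologous region are
called lost.  ndh genes are additionally subject to a cascade: once any
ndh gene is a pseudogene or lost, the whole complex is considered
functionally lost and every ndh gene is downgraded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import Align

from . import _seedextend
from .intervals import intersect, merge, total_length
from .plastome_io import PlastomeRecord

NDH_GENES = tuple(f"ndh{c}" for c in "ABCDEFGHIJK")

#: genes allowed to stay intact below threshold (length variation is
#: commonly observed among autotrophs); configurable per call.
DEFAULT_OVERRIDES = frozenset({"psbI"})


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0
    mode: str = "global"

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend <= 0 < self.match):
            raise ValueError("require gap_open <= gap_extend <= 0 < match")


@dataclass
class CoverageResult:
    coverage: float
    aligned_ref_bases: int
    ref_length: int
    score: float


@dataclass
class GeneStatusCall:
    gene: str
    status: str  # intact | pseudogene | lost
    coverage: Optional[float] = None
    cascade_applied: bool = False
    reason: str = ""


@dataclass
class Orf:
    start: int  # genome coordinates, forward strand, half-open
    end: int
    strand: str
    n_codons: int  # including the stop codon when present


# ----------------------------------------------------------------------
# ORF scanning


def _scan_forward(seq: str, offset_map, strand: str, min_codons: int) -> List[Orf]:
    """ORFs in the three frames of ``seq`` read left to right.

    Within each stop-delimited segment of a frame the first ATG opens
    the ORF, which runs through the terminating stop codon (or to the
    frame end when no stop follows).
    """
    stops = {"TAA", "TAG", "TGA"}
    out: List[Orf] = []
    n = len(seq)
    for frame in range(3):
        start_codon = None
        for k in range(frame, n - 2, 3):
            codon = seq[k : k + 3]
            if codon in stops:
                if start_codon is not None:
                    ncod = (k + 3 - start_codon) // 3
                    if ncod >= min_codons:
                        out.append(offset_map(start_codon, k + 3, strand, ncod))
                    start_codon = None
            elif codon == "ATG" and start_codon is None:
                start_codon = k
        if start_codon is not None:
            last = frame + ((n - frame) // 3) * 3
            ncod = (last - start_codon) // 3
            if ncod >= min_codons:
                out.append(offset_map(start_codon, last, strand, ncod))
    return out


def orf_scan(sequence: str, strand: str = "both", min_codons: int = 10) -> List[Orf]:
    """Candidate ORFs (ATG start, in-frame stop or sequence end) in genome coordinates."""
    sequence = sequence.upper()
    n = len(sequence)
    orfs: List[Orf] = []
    if strand in ("+", "both"):
        orfs += _scan_forward(sequence, lambda a, b, s, c: Orf(a, b, s, c), "+", min_codons)
    if strand in ("-", "both"):
        rc = _seedextend.revcomp(sequence)
        orfs += _scan_forward(rc, lambda a, b, s, c: Orf(n - b, n - a, s, c), "-", min_codons)
    return sorted(orfs, key=lambda o: (o.start, o.end, o.strand))


# ----------------------------------------------------------------------
# Alignment & coverage


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = scoring.mode
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def global_align(
    ref_cds: str, query_orf: str, scoring: AlignmentScoring = AlignmentScoring()
) -> Tuple[object, CoverageResult]:
    """Optimal global alignment of a query ORF to the reference CDS.

    Returns the Biopython alignment (deterministic traceback) and the
    coverage result; coverage = aligned reference bases / reference
    length.
    """
    if not ref_cds or not query_orf:
        raise ValueError("empty sequence passed to global_align")
    aligner = _make_aligner(scoring)
    aln = aligner.align(ref_cds.upper(), query_orf.upper())[0]
    ref_blocks = aln.aligned[0]
    aligned_ref = int(sum(b - a for a, b in ref_blocks))
    cov = aligned_ref / len(ref_cds)
    return aln, CoverageResult(cov, aligned_ref, len(ref_cds), float(aln.score))


def classify_gene(coverage: float, threshold: float = 0.70) -> str:
    """Intact at coverage >= threshold (inclusive), else pseudogene."""
    if not (0.0 <= coverage <= 1.0):
        raise ValueError("coverage must lie in [0, 1]")
    return "intact" if coverage >= threshold else "pseudogene"


# ----------------------------------------------------------------------
# ndh cascade


def apply_ndh_cascade(calls: Mapping[str, GeneStatusCall]) -> Dict[str, GeneStatusCall]:
    """Downgrade every ndh gene once any ndh gene is pseudogenized or lost.

    Genes with sequence present become pseudogenes (coverage evidence
    preserved); absent genes stay lost.  Idempotent.
    """
    out = {g: replace(c) for g, c in calls.items()}
    ndh_present = [g for g in out if g in NDH_GENES]
    if not ndh_present:
        return out
    trigger = any(out[g].status in ("pseudogene", "lost") for g in ndh_present)
    if not trigger:
        return out
    for g in ndh_present:
        c = out[g]
        if c.status == "intact":
            out[g] = replace(
                c, status="pseudogene", cascade_applied=True,
                reason=(c.reason + "; " if c.reason else "") + "ndh cascade",
            )
    return out


def shared_gene_set(
    calls_by_genome: Mapping[str, Mapping[str, GeneStatusCall]],
    gene_universe: Sequence[str],
) -> List[str]:
    """Genes intact in every genome of the input set."""
    universe = list(gene_universe)
    for gid, calls in calls_by_genome.items():
        missing = [g for g in universe if g not in calls]
        if missing:
            raise ValueError(f"genome {gid} missing calls for: {missing}")
    return [
        g
        for g in universe
        if all(calls[g].status == "intact" for calls in calls_by_genome.values())
    ]


# ----------------------------------------------------------------------
# Whole-genome classification pipeline


def _homology_locus(
    ref_cds: str, genome: str, word_size: int = 11, cluster_gap: int = 1000
) -> Tuple[List, int]:
    """Strongest homologous locus of the reference CDS in the genome.

    Seed hits are merged, clustered (gaps over ``cluster_gap`` split
    loci), and the cluster with the largest homologous footprint is
    returned; isolated chance word matches elsewhere in the genome are
    thereby ignored.  Second value: strand vote of the hits in the
    winning locus (positive = forward).
    """
    hits = _seedextend.local_matches(ref_cds, genome, word_size=word_size, min_score=2 * word_size)
    merged = merge([(h.s_start, h.s_end) for h in hits])
    if not merged:
        return [], 0
    clusters: List[List] = [[merged[0]]]
    for iv in merged[1:]:
        if iv[0] - clusters[-1][-1][1] <= cluster_gap:
            clusters[-1].append(iv)
        else:
            clusters.append([iv])
    best = max(clusters, key=total_length)
    lo, hi = best[0][0], best[-1][1]
    strand_votes = sum(
        (1 if h.orientation == "direct" else -1)
        for h in hits
        if h.s_start < hi and h.s_end > lo
    )
    return best, strand_votes


def classify_genome(
    record: PlastomeRecord,
    ref_cds: Mapping[str, str],
    threshold: float = 0.70,
    scoring: AlignmentScoring = AlignmentScoring(),
    overrides: Iterable[str] = DEFAULT_OVERRIDES,
    min_homology: int = 50,
    min_codons: int = 10,
    apply_cascade: bool = True,
    locus_margin: int = 0,
) -> Dict[str, GeneStatusCall]:
    """Classify every reference gene as intact / pseudogene / lost in one genome.

    For each reference CDS the homologous locus is found by exact-word
    seeding; with no homologous region >= ``min_homology`` bp the gene
    is lost.  Otherwise the maximal-coverage ORF overlapping the locus
    is the query (falling back to the raw homologous segment when no
    ORF qualifies), the 70% rule decides intact vs pseudogene, the
    override list exempts genes whose short length is normal variation,
    and the ndh cascade is applied last.
    """
    overrides = set(overrides)
    orfs = orf_scan(record.sequence, "both", min_codons=min_codons)
    calls: Dict[str, GeneStatusCall] = {}
    for gene, cds in ref_cds.items():
        locus, strand_votes = _homology_locus(cds, record.sequence)
        if total_length(locus) < min_homology:
            calls[gene] = GeneStatusCall(gene, "lost", None, False, "no homologous region")
            continue
        lo = min(a for a, _ in locus)
        hi = max(b for _, b in locus)
        best: Optional[Tuple[int, float, CoverageResult]] = None
        # candidate choice: the ORF sharing the most homologous footprint
        # with the locus (alignment score breaks ties).  Raw coverage or
        # score alone would let a long chance ORF win: mismatch-aligned
        # junk accrues "aligned" reference bases
        for orf in orfs:
            overlap = total_length(intersect(locus, [(orf.start, orf.end)]))
            if overlap == 0:
                continue
            # clip to the locus span: ORF overhang beyond the homologous
            # region (e.g. a frame running past a truncation point) would
            # inflate coverage through mismatch alignment
            a = max(orf.start, lo - locus_margin)
            b = min(orf.end, hi + locus_margin)
            if b - a < 3:
                continue
            seq = record.sequence[a:b]
            if orf.strand == "-":
                seq = _seedextend.revcomp(seq)
            _, cov = global_align(cds, seq, scoring)
            if best is None or (overlap, cov.score) > (best[0], best[1]):
                best = (overlap, cov.score, cov)
        best_cov = best[2] if best else None
        reason = "best-scoring ORF"
        if best_cov is None:
            segment = record.sequence[lo:hi]
            if strand_votes < 0:
                segment = _seedextend.revcomp(segment)
            _, best_cov = global_align(cds, segment, scoring)
            reason = "no qualifying ORF; homologous segment aligned"
        status = classify_gene(best_cov.coverage, threshold)
        if status == "pseudogene" and gene in overrides:
            status = "intact"
            reason += "; override: short-gene exception"
        calls[gene] = GeneStatusCall(gene, status, best_cov.coverage, False, reason)
    if apply_cascade:
        calls = apply_ndh_cascade(calls)
    return calls


def status_matrix(calls_by_genome: Mapping[str, Mapping[str, GeneStatusCall]]):
    """Genes x genomes presence/status matrix for cross-species summaries."""
    import pandas as pd

    genes = sorted({g for calls in calls_by_genome.values() for g in calls})
    data = {
        gid: {g: calls[g].status if g in calls else "lost" for g in genes}
        for gid, calls in calls_by_genome.items()
    }
    return pd.DataFrame(data, index=genes)
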