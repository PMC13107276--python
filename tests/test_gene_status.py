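"""Coverage classifier: ORF scan, global alignment, threshold rule, ndh cascade."""

from functools import lru_cache

import numpy as np
import pytest

from plastodecay.gene_status import (
    NDH_GENES,
    AlignmentScoring,
    GeneStatusCall,
    apply_ndh_cascade,
    classify_gene,
    classify_genome,
    global_align,
    orf_scan,
    shared_gene_set,
)
from plastodecay.synthetic_data import compact_config, make_plastome

# ----------------------------------------------------------------------
# oracles


def affine_align_oracle(ref, qry, match=1, mismatch=-1, gap_open=-5, gap_extend=-1):
    """Optimal global affine-gap score by memoized recursion over all alignments.

    States: 0 = last move diagonal, 1 = last move gap in query (ref base
    consumed), 2 = gap in ref.  Independent of the library implementation.
    """

    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def best(i, j, state):
        if i == 0 and j == 0:
            return 0.0 if state == 0 else NEG
        if state == 0:
            if i > 0 and j > 0:
                sub = match if ref[i - 1] == qry[j - 1] else mismatch
                return max(best(i - 1, j - 1, s) for s in range(3)) + sub
            return NEG
        if state == 1:
            if i > 0:
                return max(
                    best(i - 1, j, 1) + gap_extend,
                    max(best(i - 1, j, 0), best(i - 1, j, 2)) + gap_open,
                )
            return NEG
        if j > 0:
            return max(
                best(i, j - 1, 2) + gap_extend,
                max(best(i, j - 1, 0), best(i, j - 1, 1)) + gap_open,
            )
        return NEG

    return max(best(len(ref), len(qry), s) for s in range(3))


def orf_oracle(seq, min_codons):
    """Brute-force six-frame ORF enumeration with the same ORF definition."""
    from plastodecay._seedextend import revcomp

    stops = {"TAA", "TAG", "TGA"}
    found = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        n = len(s)
        for frame in range(3):
            codon_starts = list(range(frame, n - 2, 3))
            segment_start = 0
            open_at = None
            for k in codon_starts:
                c = s[k : k + 3]
                if c in stops:
                    if open_at is not None:
                        found.append((strand, open_at, k + 3))
                    open_at = None
                elif c == "ATG" and open_at is None:
                    open_at = k
            if open_at is not None:
                end = frame + ((n - frame) // 3) * 3
                found.append((strand, open_at, end))
    out = set()
    for strand, a, b in found:
        if (b - a) // 3 < min_codons:
            continue
        if strand == "-":
            a, b = len(seq) - b, len(seq) - a
        out.add((a, b, strand))
    return out


# ----------------------------------------------------------------------
# ORF scanning


def test_orf_scan_minimal_orf():
    orfs = orf_scan("ATGAAATAA", min_codons=3)
    assert [(o.start, o.end, o.strand, o.n_codons) for o in orfs if o.strand == "+"] == [
        (0, 9, "+", 3)
    ]


def test_orf_scan_no_atg_empty():
    assert orf_scan("CCTTCCTTCCTTCCT", min_codons=2) == []


def test_orf_scan_matches_six_frame_oracle():
    rng = np.random.default_rng(21)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])
    got = {(o.start, o.end, o.strand) for o in orf_scan(seq, min_codons=10)}
    assert got == orf_oracle(seq, 10)


# ----------------------------------------------------------------------
# alignment & coverage


def test_identical_sequences_full_coverage():
    rng = np.random.default_rng(22)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
    _, cov = global_align(seq, seq)
    assert cov.score == 300
    assert cov.coverage == 1.0
    assert cov.aligned_ref_bases == 300


def test_internal_deletion_reduces_coverage():
    ref = "ATGGCTAAAGGT"
    qry = ref[:4] + ref[7:]  # 3-nt internal deletion
    _, cov = global_align(ref, qry)
    assert cov.aligned_ref_bases == 9
    assert cov.coverage == pytest.approx(9 / 12)
    assert cov.score == affine_align_oracle(ref, qry)


def test_alignment_score_matches_exhaustive_oracle_small_pairs():
    rng = np.random.default_rng(23)
    for _ in range(25):
        n1, n2 = rng.integers(1, 13, 2)
        ref = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n1)])
        qry = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n2)])
        _, cov = global_align(ref, qry)
        assert cov.score == pytest.approx(affine_align_oracle(ref, qry))


def test_deleting_ref_aligned_bases_never_increases_coverage():
    rng = np.random.default_rng(24)
    for _ in range(10):
        ref = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
        qry = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 55)])
        aln, cov = global_align(ref, qry)
        # drop query bases that are aligned to reference bases
        q_aligned = sorted(
            {q for qa, qb in aln.aligned[1] for q in range(qa, qb)}
        )
        drop = set(q_aligned[:: max(1, len(q_aligned) // 5)])
        shorter = "".join(c for i, c in enumerate(qry) if i not in drop)
        _, cov2 = global_align(ref, shorter)
        assert cov2.coverage <= cov.coverage + 1e-12


def test_empty_input_raises():
    with pytest.raises(ValueError):
        global_align("", "ACGT")


def test_scoring_invariant_validation():
    with pytest.raises(ValueError):
        AlignmentScoring(gap_open=-1, gap_extend=-5)


# ----------------------------------------------------------------------
# threshold rule


@pytest.mark.parametrize(
    "cov,expected",
    [(0.79, "intact"), (0.71, "intact"), (0.70, "intact"), (0.699, "pseudogene"), (0.49, "pseudogene")],
)
def test_seventy_percent_rule(cov, expected):
    assert classify_gene(cov) == expected


# ----------------------------------------------------------------------
# ndh cascade


def _calls(status_map):
    return {g: GeneStatusCall(g, s, 0.95 if s == "intact" else 0.4) for g, s in status_map.items()}


def test_cascade_noop_when_all_intact():
    calls = _calls({g: "intact" for g in NDH_GENES})
    out = apply_ndh_cascade(calls)
    assert all(c.status == "intact" and not c.cascade_applied for c in out.values())


def test_cascade_downgrades_all_on_one_pseudogene():
    calls = _calls({g: "intact" for g in NDH_GENES})
    calls["ndhA"] = GeneStatusCall("ndhA", "pseudogene", 0.4)
    out = apply_ndh_cascade(calls)
    assert all(c.status != "intact" for c in out.values())
    assert sum(c.cascade_applied for c in out.values()) == 10
    assert not out["ndhA"].cascade_applied


def test_cascade_preserves_coverage_evidence():
    calls = _calls({"ndhF": "lost", "ndhB": "intact"})
    calls["ndhB"].coverage = 0.99
    out = apply_ndh_cascade(calls)
    assert out["ndhB"].status == "pseudogene"
    assert out["ndhB"].coverage == 0.99
    assert out["ndhF"].status == "lost"


def test_cascade_idempotent():
    calls = _calls({g: "intact" for g in NDH_GENES})
    calls["ndhD"] = GeneStatusCall("ndhD", "pseudogene", 0.3)
    once = apply_ndh_cascade(calls)
    twice = apply_ndh_cascade(once)
    assert {g: (c.status, c.cascade_applied) for g, c in once.items()} == {
        g: (c.status, c.cascade_applied) for g, c in twice.items()
    }


def test_cascade_ignores_non_ndh():
    calls = _calls({"rbcL": "pseudogene", "ndhA": "intact"})
    out = apply_ndh_cascade(calls)
    assert out["ndhA"].status == "intact"


# ----------------------------------------------------------------------
# shared gene set


def test_shared_gene_set_basics():
    universe = ["rbcL", "rpl22", "ndhA"]
    g1 = _calls({"rbcL": "intact", "rpl22": "intact", "ndhA": "intact"})
    g2 = _calls({"rbcL": "intact", "rpl22": "pseudogene", "ndhA": "intact"})
    assert shared_gene_set({"a": g1, "b": g1}, universe) == universe
    assert shared_gene_set({"a": g1, "b": g2}, universe) == ["rbcL", "ndhA"]
    with pytest.raises(ValueError, match="missing"):
        shared_gene_set({"a": g1, "b": _calls({"rbcL": "intact"})}, universe)


# ----------------------------------------------------------------------
# end-to-end classification on a planted genome


def test_classify_genome_recovers_planted_statuses():
    cfg = compact_config(
        degradation={
            "ndhD": ("truncate", 0.45),
            "rpl22": ("truncate", 0.50),
            "ndhF": ("delete",),
            "rbcL": ("truncate", 0.85),
        }
    )
    rec, truth = make_plastome(cfg, seed=7)
    calls = classify_genome(rec, truth.ref_cds)
    for g, c in calls.items():
        expect = truth.gene_status[g]
        if g.startswith("ndh") and expect == "intact":
            expect = "pseudogene"  # cascade
        assert c.status == expect, (g, c)
    assert calls["ndhD"].coverage == pytest.approx(0.45, abs=0.03)
    assert calls["rbcL"].status == "intact"
    assert calls["ndhH"].cascade_applied
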