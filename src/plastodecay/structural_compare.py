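"""Reference-based homology mapping and indel / specific-fragment calling.

Genomes are compared IR-reduced (one inverted-repeat copy retained).
Query regions without homology in the reference are insertions;
reference regions without homology in the query are deletions.
Insertion content is normalized by the query genome length, deletion
content by the reference (tobacco) length.  Species-specific fragments
are the complement, on a target genome, of the union of its homology
footprints against every comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import _seedextend
from .intervals import Interval, complement, merge, total_length
from .plastome_io import GeneFeature


@dataclass
class HomologyMap:
    query_id: str
    reference_id: str
    intervals_on_query: List[Interval]
    intervals_on_reference: List[Interval]
    query_length: int
    reference_length: int


def homology_intervals(
    query: str,
    reference: str,
    word_size: int = 7,
    min_anchor: int = 30,
    query_id: str = "query",
    reference_id: str = "reference",
) -> HomologyMap:
    """Merged homologous footprints between two IR-reduced genomes.

    Local anchors come from the same seed-and-extend engine used for
    repeat finding, run cross-genome in both orientations; anchors
    shorter than ``min_anchor`` are ignored before merging.
    """
    hits = _seedextend.local_matches(
        query, reference, word_size=word_size, min_score=2 * word_size
    )
    q_ivs = [(h.q_start, h.q_end) for h in hits if h.length >= min_anchor]
    r_ivs = [(h.s_start, h.s_end) for h in hits if h.length >= min_anchor]
    return HomologyMap(
        query_id=query_id,
        reference_id=reference_id,
        intervals_on_query=merge(q_ivs),
        intervals_on_reference=merge(r_ivs),
        query_length=len(query),
        reference_length=len(reference),
    )


@dataclass
class IndelSet:
    insertions: List[Interval]
    deletions: List[Interval]
    insertion_length: int
    deletion_length: int
    insertion_content: float  # / query length
    deletion_content: float  # / reference length


def classify_indels(
    hmap: HomologyMap, min_fragment: int = 30
) -> IndelSet:
    """Insertions on the query and deletions on the reference from a homology map.

    Fragments shorter than ``min_fragment`` are dropped as seed-level
    noise.  Content denominators follow the definitions used for
    genome-size comparisons: query length for insertions, reference
    length for deletions.
    """
    ins = [
        iv
        for iv in complement(hmap.intervals_on_query, hmap.query_length)
        if iv[1] - iv[0] >= min_fragment
    ]
    dels = [
        iv
        for iv in complement(hmap.intervals_on_reference, hmap.reference_length)
        if iv[1] - iv[0] >= min_fragment
    ]
    ins_len = total_length(ins)
    del_len = total_length(dels)
    return IndelSet(
        insertions=ins,
        deletions=dels,
        insertion_length=ins_len,
        deletion_length=del_len,
        insertion_content=ins_len / hmap.query_length,
        deletion_content=del_len / hmap.reference_length,
    )


@dataclass
class SpecificFragment:
    interval: Interval
    length: int
    genes: List[str] = field(default_factory=list)
    in_ir: bool = False


@dataclass
class SpecificFragmentSet:
    target_id: str
    comparator_ids: List[str]
    fragments: List[SpecificFragment]

    @property
    def total_length(self) -> int:
        return sum(f.length for f in self.fragments)


def species_specific_fragments(
    target: str,
    comparators: Dict[str, str],
    min_fragment: int = 30,
    word_size: int = 7,
    min_anchor: int = 30,
    target_id: str = "target",
    features: Optional[Sequence[GeneFeature]] = None,
    ir_intervals: Optional[Sequence[Interval]] = None,
) -> SpecificFragmentSet:
    """Target regions with no homology in any comparator genome.

    The union of the target-side homology footprints against every
    comparator is complemented on the target; surviving fragments are
    annotated with overlapping genes and IR membership when feature /
    IR maps are supplied.
    """
    if not comparators:
        raise ValueError("need at least one comparator genome")
    union: List[Interval] = []
    for cid, cseq in comparators.items():
        hmap = homology_intervals(
            target, cseq, word_size=word_size, min_anchor=min_anchor,
            query_id=target_id, reference_id=cid,
        )
        union.extend(hmap.intervals_on_query)
    frags = []
    for a, b in complement(union, len(target)):
        if b - a < min_fragment:
            continue
        genes = []
        if features:
            for f in features:
                s, e = f.span
                if s < b and a < e:
                    genes.append(f.name)
        in_ir = False
        if ir_intervals:
            in_ir = any(s < b and a < e for s, e in ir_intervals)
        frags.append(SpecificFragment((a, b), b - a, genes, in_ir))
    return SpecificFragmentSet(target_id, list(comparators), frags)
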