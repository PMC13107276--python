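"""Half-open genomic interval arithmetic.

All coordinates in the package are 0-based half-open ``[start, end)``.
These helpers are deliberately tiny: merge, complement, total length,
intersection — the set algebra behind indel and fragment calling.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Union of intervals; overlapping or book-ended intervals coalesce."""
    ivs = sorted((int(a), int(b)) for a, b in intervals if b > a)
    out: List[Interval] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            if b > out[-1][1]:
                out[-1] = (out[-1][0], b)
        else:
            out.append((a, b))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(b - a for a, b in merge(intervals))


def complement(intervals: Iterable[Interval], span: int) -> List[Interval]:
    """Gaps of ``[0, span)`` not covered by ``intervals``."""
    out: List[Interval] = []
    pos = 0
    for a, b in merge(intervals):
        a, b = max(a, 0), min(b, span)
        if b <= 0 or a >= span:
            continue
        if a > pos:
            out.append((pos, a))
        pos = max(pos, b)
    if pos < span:
        out.append((pos, span))
    return out


def intersect(xs: Iterable[Interval], ys: Iterable[Interval]) -> List[Interval]:
    xs, ys = merge(xs), merge(ys)
    out: List[Interval] = []
    i = j = 0
    while i < len(xs) and j < len(ys):
        a = max(xs[i][0], ys[j][0])
        b = min(xs[i][1], ys[j][1])
        if b > a:
            out.append((a, b))
        if xs[i][1] < ys[j][1]:
            i += 1
        else:
            j += 1
    return out
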