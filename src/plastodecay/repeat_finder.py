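"""Short-repeat detection, merging, E-value profiles and the slope statistic.

The plastome with a single IR copy retained is self-compared with the
word-seeded ungapped engine (word size 7); matches of 500 bp or more
are excluded as large repeats, the remainder are the "short fragment
repeats".  Repeat content is the merged repeat footprint divided by the
non-redundant genome length, profiled across E-value thresholds, and
summarized by the OLS slope of content on log10(E).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import _seedextend
from ._seedextend import Hit
from .intervals import Interval, merge, total_length

SHORT_REPEAT_MAX = 500  # bp; hits at or above this length are not "short"


def find_short_repeats(
    sequence: str,
    word_size: int = 7,
    max_evalue: Optional[float] = None,
    xdrop: int = 20,
    min_score: Optional[int] = None,
) -> List[Hit]:
    """All non-self short-repeat hits of an IR-reduced genome against itself.

    Exact word seeding in both orientations, ungapped X-drop extension
    scored +2/-3, Karlin-Altschul E-values; hits with length >= 500 bp
    are discarded as large repeats.
    """
    if word_size < 4:
        raise ValueError("word_size < 4 would explode the seed index")
    hits = _seedextend.local_matches(
        sequence,
        None,
        word_size=word_size,
        xdrop=xdrop,
        min_score=2 * word_size if min_score is None else min_score,
        max_evalue=max_evalue,
    )
    return [h for h in hits if h.length < SHORT_REPEAT_MAX]


def merge_hits(hits: Sequence[Hit]) -> Tuple[List[Interval], int]:
    """Union of query and subject intervals of all hits; returns (intervals, total bp)."""
    ivs: List[Interval] = []
    for h in hits:
        ivs.append((h.q_start, h.q_end))
        ivs.append((h.s_start, h.s_end))
    merged = merge(ivs)
    return merged, total_length(merged)


@dataclass
class RepeatProfile:
    thresholds: List[float]
    lengths: List[int]
    contents: List[float]
    nonredundant_length: int


def repeat_content_curve(
    sequence: str,
    thresholds: Sequence[float] = (1e-10, 1e-5, 1e-2, 1.0, 6.0),
    word_size: int = 7,
) -> RepeatProfile:
    """Merged short-repeat content at each E-value threshold (monotone in E)."""
    thresholds = sorted(float(t) for t in thresholds)
    hits = find_short_repeats(sequence, word_size=word_size, max_evalue=max(thresholds))
    n = len(sequence)
    lengths, contents = [], []
    for t in thresholds:
        _, length = merge_hits([h for h in hits if h.evalue <= t])
        lengths.append(length)
        contents.append(length / n)
    # monotonicity is structural: a looser threshold keeps a superset of hits
    assert all(a <= b for a, b in zip(contents, contents[1:]))
    return RepeatProfile(thresholds, lengths, contents, n)


@dataclass
class SlopeFit:
    slope: float
    intercept: float
    ci95: Tuple[float, float]
    r2: float
    pvalue: float


def content_slope(profile: RepeatProfile) -> SlopeFit:
    """OLS of repeat content on log10(E-value threshold) with a t-based 95% CI."""
    if len(profile.thresholds) < 3:
        raise ValueError("need at least 3 thresholds for a slope")
    x = np.log10(np.asarray(profile.thresholds, dtype=float))
    y = np.asarray(profile.contents, dtype=float)
    if np.allclose(y, y[0]):
        return SlopeFit(0.0, float(y[0]), (0.0, 0.0), 0.0, 1.0)
    res = stats.linregress(x, y)
    dof = len(x) - 2
    tcrit = stats.t.ppf(0.975, dof)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci95=(float(ci[0]), float(ci[1])),
        r2=float(res.rvalue**2) if not math.isnan(res.rvalue) else 0.0,
        pvalue=float(res.pvalue),
    )
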