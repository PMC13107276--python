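"""Word-seeded, ungapped X-drop local matching.

Shared engine for plastome self-comparison (short-repeat search) and
cross-genome homology mapping: exact shared words of a configurable
size seed ungapped extensions scored +2/-3 with an X-drop cut-off.
Gapped extension is deliberately omitted — at word size 7 the short
matches this package cares about are dominated by ungapped alignments,
and the exhaustive-repeat oracle used in testing stays exact.

E-values follow the Karlin–Altschul form E = K*m*n*exp(-lambda*S).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

MATCH = 2
MISMATCH = -3
# Ungapped Karlin-Altschul constants used for this scoring scheme.
LAMBDA = 1.33
K_CONST = 0.62

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else -> 4 (never matches)."""
    table = np.full(256, 4, dtype=np.int8)
    for i, ch in enumerate("ACGT"):
        table[ord(ch)] = i
        table[ord(ch.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class Hit:
    """One ungapped local match between two (possibly identical) sequences."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    orientation: str  # 'direct' | 'inverted'
    score: int
    identity: float
    evalue: float = math.nan

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


def _word_codes(arr: np.ndarray, w: int) -> np.ndarray:
    """4^w word codes at every start position; -1 where the word has a non-ACGT base."""
    n = len(arr) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    a = arr.astype(np.int64)
    for k in range(w):
        codes = codes * 4 + a[k : k + n]
        bad |= a[k : k + n] > 3
    codes[bad] = -1
    return codes


def _extend(q: np.ndarray, s: np.ndarray, qpos: int, spos: int, w: int, xdrop: int):
    """Ungapped X-drop extension of an exact w-word seed; returns (qa, qb, score, matches)."""
    score = MATCH * w
    matches = w
    # right
    best, best_r, best_m = score, 0, matches
    cur, cur_m = score, matches
    i, j = qpos + w, spos + w
    r = 0
    while i < len(q) and j < len(s):
        if q[i] == s[j] and q[i] <= 3:
            cur += MATCH
            cur_m += 1
        else:
            cur += MISMATCH
        r += 1
        if cur > best:
            best, best_r, best_m = cur, r, cur_m
        elif best - cur > xdrop:
            break
        i += 1
        j += 1
    score, matches = best, best_m
    right = best_r
    # left
    best, best_l, best_m = score, 0, matches
    cur, cur_m = score, matches
    i, j = qpos - 1, spos - 1
    l = 0
    while i >= 0 and j >= 0:
        if q[i] == s[j] and q[i] <= 3:
            cur += MATCH
            cur_m += 1
        else:
            cur += MISMATCH
        l += 1
        if cur > best:
            best, best_l, best_m = cur, l, cur_m
        elif best - cur > xdrop:
            break
        i -= 1
        j -= 1
    qa = qpos - best_l
    qb = qpos + w + right
    return qa, qb, best, best_m


def evalue(score: int, m: int, n: int) -> float:
    return K_CONST * m * n * math.exp(-LAMBDA * score)


def _scan(
    q_arr: np.ndarray,
    s_arr: np.ndarray,
    word_size: int,
    xdrop: int,
    min_score: int,
    skip_self_diagonal: bool,
) -> List[tuple]:
    """All ungapped extensions between q and s (same orientation as given).

    Returns raw tuples (qa, qb, sa, sb, score, matches).  Seeds already
    covered by a previous extension on the same diagonal are skipped.
    """
    qcodes = _word_codes(q_arr, word_size)
    scodes = _word_codes(s_arr, word_size)
    index: Dict[int, List[int]] = {}
    for pos, code in enumerate(scodes):
        if code >= 0:
            index.setdefault(int(code), []).append(pos)

    pairs = []
    for qpos, code in enumerate(qcodes):
        if code < 0:
            continue
        for spos in index.get(int(code), ()):
            if skip_self_diagonal and qpos == spos:
                continue
            pairs.append((qpos - spos, qpos, spos))
    pairs.sort()

    hits = []
    last_end_on_diag = {}
    for diag, qpos, spos in pairs:
        if last_end_on_diag.get(diag, -1) >= qpos + word_size:
            continue
        qa, qb, score, matches = _extend(q_arr, s_arr, qpos, spos, word_size, xdrop)
        last_end_on_diag[diag] = qb
        if score >= min_score:
            hits.append((qa, qb, qa - diag, qb - diag, score, matches))
    # collapse duplicates (different seeds can yield the same extension)
    return sorted(set(hits))


def local_matches(
    query: str,
    subject: Optional[str] = None,
    word_size: int = 7,
    xdrop: int = 20,
    min_score: int = 2 * 7,
    max_evalue: Optional[float] = None,
) -> List[Hit]:
    """Seeded ungapped local matches between query and subject.

    ``subject=None`` requests a self-comparison: the trivial self-
    diagonal is excluded and mirrored duplicates (q and s intervals
    swapped) are deduplicated keeping the pair whose interval tuple is
    lexicographically smaller.
    Both orientations are always searched; inverted hits report subject
    coordinates on the forward strand.
    """
    if word_size < 4:
        raise ValueError("word_size < 4 would explode the seed index")
    is_self = subject is None
    subj = query if is_self else subject
    q_arr = encode(query)
    s_arr = encode(subj)
    s_rc_arr = encode(revcomp(subj))
    m, n = len(query), len(subj)

    hits: List[Hit] = []
    seen = set()

    for qa, qb, sa, sb, score, matches in _scan(
        q_arr, s_arr, word_size, xdrop, min_score, is_self
    ):
        if is_self:
            a, b = (qa, qb), (sa, sb)
            if a == b:
                continue
            key = (min(a, b), max(a, b), "direct")
            if key in seen:
                continue
            seen.add(key)
            (qa, qb), (sa, sb) = min(a, b), max(a, b)
        h = Hit(qa, qb, sa, sb, "direct", score, matches / (qb - qa))
        h.evalue = evalue(score, m, n)
        if max_evalue is None or h.evalue <= max_evalue:
            hits.append(h)

    for qa, qb, sa, sb, score, matches in _scan(
        q_arr, s_rc_arr, word_size, xdrop, min_score, False
    ):
        # map subject interval back to forward strand
        fa, fb = n - sb, n - sa
        if is_self:
            a, b = (qa, qb), (fa, fb)
            if a == b:  # perfect palindrome on itself: not a repeat pair
                continue
            key = (min(a, b), max(a, b), "inverted")
            if key in seen:
                continue
            seen.add(key)
        h = Hit(qa, qb, fa, fb, "inverted", score, matches / (qb - qa))
        h.evalue = evalue(score, m, n)
        if max_evalue is None or h.evalue <= max_evalue:
            hits.append(h)

    return hits
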