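"""Sense-codon alphabet and genetic-code bookkeeping.

The selection machinery works on the 61 sense codons of the universal
code (plastid protein genes use the bacterial-style code, whose sense
codon set and amino-acid assignments coincide with the universal table).
This module owns the codon index, synonymy relations, the single-
nucleotide neighbour structure used to build MG94 rate matrices, and
F3x4 codon frequencies.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Sequence

import numpy as np

NUCS = "TCAG"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

_CODE = {}
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(itertools.product(NUCS, repeat=3)):
    _CODE[_a + _b + _c] = _AAS[_i]

GENETIC_CODE: Dict[str, str] = dict(_CODE)
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
CODONS: List[str] = [c for c in GENETIC_CODE if c not in STOP_CODONS]
CODON_INDEX: Dict[str, int] = {c: i for i, c in enumerate(CODONS)}
N_CODONS = len(CODONS)  # 61
AA_OF: List[str] = [GENETIC_CODE[c] for c in CODONS]


def translate_codon(codon: str) -> str:
    """Amino acid (one-letter) for a codon; '*' for stops, 'X' if ambiguous."""
    codon = codon.upper().replace("U", "T")
    return GENETIC_CODE.get(codon, "X")


def is_stop(codon: str) -> bool:
    return codon.upper().replace("U", "T") in STOP_CODONS


# Single-nucleotide neighbour structure over sense codons: for every
# ordered pair (i, j) differing at exactly one position, record the
# position, the nucleotides exchanged, and whether the change is
# synonymous.  MG94 assigns rate 0 to every other off-diagonal pair.
_pairs_i, _pairs_j, _pairs_pos, _pairs_from, _pairs_to, _pairs_syn = [], [], [], [], [], []
for _i, _ci in enumerate(CODONS):
    for _j, _cj in enumerate(CODONS):
        if _i == _j:
            continue
        diffs = [p for p in range(3) if _ci[p] != _cj[p]]
        if len(diffs) != 1:
            continue
        p = diffs[0]
        _pairs_i.append(_i)
        _pairs_j.append(_j)
        _pairs_pos.append(p)
        _pairs_from.append(NUC_INDEX[_ci[p]])
        _pairs_to.append(NUC_INDEX[_cj[p]])
        _pairs_syn.append(AA_OF[_i] == AA_OF[_j])

NEIGHBOR_I = np.array(_pairs_i)
NEIGHBOR_J = np.array(_pairs_j)
NEIGHBOR_POS = np.array(_pairs_pos)
NEIGHBOR_FROM = np.array(_pairs_from)
NEIGHBOR_TO = np.array(_pairs_to)
NEIGHBOR_SYN = np.array(_pairs_syn, dtype=bool)

# transition (A<->G, C<->T) mask per neighbour pair
_PURINE = {NUC_INDEX["A"], NUC_INDEX["G"]}
NEIGHBOR_TRANSITION = np.array(
    [
        (f in _PURINE) == (t in _PURINE)
        for f, t in zip(NEIGHBOR_FROM, NEIGHBOR_TO)
    ],
    dtype=bool,
)


def codons_of(seq: str) -> List[str]:
    """Split a nucleotide string into codons; length must be divisible by 3."""
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[k : k + 3] for k in range(0, len(seq), 3)]


def encode_codons(seq: str) -> np.ndarray:
    """Codon-index array for a gap-free coding sequence (stops rejected)."""
    idx = []
    for k, c in enumerate(codons_of(seq)):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c} at codon {k}")
        if c not in CODON_INDEX:
            raise ValueError(f"unrecognized codon {c!r} at codon {k}")
        idx.append(CODON_INDEX[c])
    return np.array(idx, dtype=np.int64)


def f3x4_frequencies(sequences: Sequence[str]) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    Nucleotide frequencies are tallied separately at codon positions
    1-3 across all sequences; the frequency of a sense codon is the
    product of its three positional frequencies, renormalized over the
    61 sense codons.
    """
    counts = np.zeros((3, 4))
    for seq in sequences:
        for codon in codons_of(seq):
            for p, n in enumerate(codon):
                if n in NUC_INDEX:
                    counts[p, NUC_INDEX[n]] += 1
    if not counts.sum():
        raise ValueError("no countable bases for F3x4")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [freqs[0, NUC_INDEX[c[0]]] * freqs[1, NUC_INDEX[c[1]]] * freqs[2, NUC_INDEX[c[2]]] for c in CODONS]
    )
    s = pi.sum()
    if s <= 0:
        raise ValueError("degenerate positional frequencies")
    return pi / s


def f3x4_from_nucleotide_freqs(pos_freqs: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from a given (3, 4) positional table (TCAG order)."""
    pos_freqs = np.asarray(pos_freqs, dtype=float)
    if pos_freqs.shape != (3, 4):
        raise ValueError("positional frequency table must be 3x4 (TCAG)")
    pi = np.array(
        [pos_freqs[0, NUC_INDEX[c[0]]] * pos_freqs[1, NUC_INDEX[c[1]]] * pos_freqs[2, NUC_INDEX[c[2]]] for c in CODONS]
    )
    return pi / pi.sum()
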