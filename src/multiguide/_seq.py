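"""Low-level nucleotide utilities shared across modules.

Sequences are plain Python strings over {A,C,G,T,N}; hot loops work on
uint8 numpy arrays produced by :func:`encode`. ``N`` is encoded as 4 and
never matches any guide base or any IUPAC PAM symbol.
"""

from __future__ import annotations

import numpy as np

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# A,C,G,T -> 0..3; N -> 4. Everything else maps to 5 so encode() can detect it.
_ENC = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENC[ord(_b)] = _i

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_iupac(motif: str) -> str:
    return motif.translate(_IUPAC_COMP)[::-1]


def is_valid_iupac(motif: str) -> bool:
    return len(motif) > 0 and all(c in IUPAC for c in motif)


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N as 0..4 (uint8). Raises on any other character."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 4:
        pos = int(np.argmax(arr > 4))
        raise ValueError(f"non-IUPAC nucleotide {seq[pos]!r} at position {pos}")
    return arr


def iupac_masks(motif: str) -> np.ndarray:
    """Boolean table (len(motif), 5): table[i, code] = base matches motif[i].

    Column 4 (N in the genome) is always False: an ambiguous genome base
    can never satisfy a cleavage motif.
    """
    table = np.zeros((len(motif), 5), dtype=bool)
    for i, c in enumerate(motif):
        for b in IUPAC[c]:
            table[i, _ENC[ord(b)]] = True
    return table


def matches_iupac(seq: str, motif: str) -> bool:
    """True iff *seq* (A/C/G/T/N) matches the IUPAC *motif* base-for-base."""
    if len(seq) != len(motif):
        return False
    return all(b in IUPAC[m] for b, m in zip(seq, motif))
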