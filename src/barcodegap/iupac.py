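"""IUPAC nucleotide alphabet helpers.

Shared low-level utilities: degenerate-code bitmasks, reverse complement,
and integer encodings used by the alignment kernels. Inosine (``I``), which
appears in broad-range chaperonin primers, is treated as matching any base,
exactly like ``N``.
"""

from __future__ import annotations

import numpy as np

GAP_CHARS = "-."

# 4-bit encoding: A=1, C=2, G=4, T=8; degenerate codes are unions.
_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15, "I": 15, "X": 15,
    "-": 0, ".": 0,
}

# Lookup table mapping ASCII byte -> bitmask (unknown characters behave as N).
BITS_TABLE = np.full(256, 15, dtype=np.uint8)
for ch, val in _BITS.items():
    BITS_TABLE[ord(ch)] = val
    BITS_TABLE[ord(ch.lower())] = val

# Strict 2-bit code for unambiguous bases: A=0, C=1, G=2, T=3; everything
# else (including gaps) maps to 4 and never matches in the kernels.
CODE_TABLE = np.full(256, 4, dtype=np.uint8)
for i, ch in enumerate("ACGT"):
    CODE_TABLE[ord(ch)] = i
    CODE_TABLE[ord(ch.lower())] = i
CODE_TABLE[ord("U")] = 3
CODE_TABLE[ord("u")] = 3

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNIacgturyswkmbdhvni.-",
    "TGCAAYRSWMKVHDBNNtgcaayrswmkvhdbnn.-",
)

CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC degeneracies (I -> N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def degap(seq: str) -> str:
    """Remove alignment gap characters (``-`` and ``.``)."""
    return seq.replace("-", "").replace(".", "")


def encode(seq: str) -> np.ndarray:
    """Strict 2-bit encoding (A,C,G,T -> 0..3, anything else -> 4)."""
    return CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_bits(seq: str) -> np.ndarray:
    """Degenerate bitmask encoding (gap -> 0, N/I -> 15)."""
    return BITS_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` (code 4 becomes ``N``)."""
    return CODE_TO_BASE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on the 2-bit encoding (4 stays 4)."""
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    return comp[codes][::-1]


def is_iupac(seq: str) -> bool:
    """True if every character is an IUPAC nucleotide code (no gaps)."""
    return all(c.upper() in _BITS and c not in GAP_CHARS for c in seq)
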