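"""Low-level sequence helpers shared across modules.

Coordinates are 0-based half-open on the forward strand everywhere.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Standard-code codon -> amino acid (stop = '*'), built once.
CODON_TABLE: dict[str, str] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _c = _b1 + _b2 + _b3
            CODON_TABLE[_c] = str(Seq(_c).translate())

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")

#: amino acid -> list of codons (standard code), stops excluded
SYNONYMOUS_CODONS: dict[str, list[str]] = {}
for _c, _aa in CODON_TABLE.items():
    if _aa != "*":
        SYNONYMOUS_CODONS.setdefault(_aa, []).append(_c)

AMINO_ACIDS = sorted(SYNONYMOUS_CODONS)  # 20 letters

NUCLEOTIDES = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: transition partner of each nucleotide
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide string; ambiguous codons become X, stops '*'.

    Trailing partial codons are dropped.
    """
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


def is_transition(a: str, b: str) -> bool:
    """True if a->b is a transition (purine<->purine or pyrimidine<->pyrimidine)."""
    return a != b and ((a in PURINES) == (b in PURINES))


def encode(seq: str) -> np.ndarray:
    """Nucleotide string -> uint8 array (A,C,G,T -> 0..3; others -> 4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, idx in _NT_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` (code 4 -> N)."""
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)
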