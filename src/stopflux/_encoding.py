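"""Shared nucleotide encodings.

Bases are indexed A=0, C=1, G=2, T=3 throughout; anything that is not an
unambiguous base (N, IUPAC ambiguity codes, gaps) maps to 4 and is treated
as missing by every consumer. Trinucleotides are indexed 16*a + 4*b + c.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
MISSING = 4

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOPS = ("TAA", "TGA", "TAG")

TRINUCS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
TRINUC_INDEX = {t: i for i, t in enumerate(TRINUCS)}

DINUCS = tuple(a + b for a in BASES for b in BASES)
DINUC_INDEX = {d: i for i, d in enumerate(DINUCS)}

# byte-value -> code lookup for fast encoding (uppercase + lowercase)
_LUT = np.full(256, MISSING, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement; non-ACGT characters map through N."""
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (4 = missing)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    out = np.full(len(codes), ord("N"), dtype=np.uint8)
    for i, b in enumerate(BASES):
        out[codes == i] = ord(b)
    return out.tobytes().decode("ascii")


def gc_fraction(seq: str) -> float | None:
    """G+C fraction over unambiguous bases; None if no unambiguous base."""
    codes = encode(seq)
    valid = codes != MISSING
    n = int(valid.sum())
    if n == 0:
        return None
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / n
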