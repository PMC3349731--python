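"""IUPAC nucleotide ambiguity codes and bitmask encodings.

Each base maps to a 4-bit mask (A=1, C=2, G=4, T=8); an ambiguity code is the
union of the masks of the bases it denotes.  A read base matches a reference
symbol iff their masks intersect.  ``N`` in a *read* is encoded as 0 (matches
nothing), while ``N`` in a *reference* means "any base" per the IUPAC table.
"""

from __future__ import annotations

import numpy as np

A, C, G, T = 1, 2, 4, 8

#: IUPAC letter -> bitmask over {A, C, G, T}
CODE_TO_MASK: dict[str, int] = {
    "A": A, "C": C, "G": G, "T": T, "U": T,
    "R": A | G, "Y": C | T, "S": C | G, "W": A | T,
    "K": G | T, "M": A | C,
    "B": C | G | T, "D": A | G | T, "H": A | C | T, "V": A | C | G,
    "N": A | C | G | T,
}

MASK_TO_CODE: dict[int, str] = {}
for _c, _m in CODE_TO_MASK.items():
    if _c != "U":
        MASK_TO_CODE.setdefault(_m, _c)

CODE_TO_BASES: dict[str, frozenset[str]] = {
    c: frozenset(b for b in "ACGT" if CODE_TO_MASK[c] & CODE_TO_MASK[b])
    for c in CODE_TO_MASK
}

_REF_LUT = np.zeros(256, dtype=np.uint8)
for _c, _m in CODE_TO_MASK.items():
    _REF_LUT[ord(_c)] = _m
    _REF_LUT[ord(_c.lower())] = _m

_READ_LUT = _REF_LUT.copy()
_READ_LUT[ord("N")] = 0  # read N matches nothing
_READ_LUT[ord("n")] = 0

_COMPLEMENT_MASK = np.zeros(16, dtype=np.uint8)
for _m in range(16):
    out = 0
    if _m & A:
        out |= T
    if _m & T:
        out |= A
    if _m & C:
        out |= G
    if _m & G:
        out |= C
    _COMPLEMENT_MASK[_m] = out

_COMP_STR = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                          "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def ambiguity_code(bases) -> str:
    """Minimal IUPAC code covering a set of bases (e.g. {'A','G'} -> 'R')."""
    mask = 0
    for b in bases:
        mask |= CODE_TO_MASK[b.upper()]
    if mask == 0:
        raise ValueError("empty base set")
    return MASK_TO_CODE[mask]


def encode_ref(seq: str) -> np.ndarray:
    """Encode a reference sequence (IUPAC allowed) as a uint8 mask array."""
    return _REF_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_read(seq: str) -> np.ndarray:
    """Encode a read (N matches nothing) as a uint8 mask array."""
    return _READ_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp_masks(masks: np.ndarray) -> np.ndarray:
    return _COMPLEMENT_MASK[masks[::-1]]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_STR)[::-1]
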