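"""Protein alphabet shared by every module.

Integer codes: 0..19 the standard residues (alphabetical), 20 the gap,
21 ambiguity/non-standard codes (X, B, Z, J, U, O).  Entropy, distance
and property calculations all treat codes >= 20 as "not a residue".
"""

from __future__ import annotations

import numpy as np

STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHAR: str = "-"
AMBIGUOUS_RESIDUES: str = "XBZJUO"

GAP_CODE: int = 20
AMBIGUOUS_CODE: int = 21

RESIDUE_TO_CODE: dict[str, int] = {aa: i for i, aa in enumerate(STANDARD_RESIDUES)}

_LUT = np.full(128, -1, dtype=np.int8)
for _aa, _i in RESIDUE_TO_CODE.items():
    _LUT[ord(_aa)] = _i
_LUT[ord(GAP_CHAR)] = GAP_CODE
_LUT[ord(".")] = GAP_CODE  # "." is a common gap dialect; treated as "-"
for _aa in AMBIGUOUS_RESIDUES:
    _LUT[ord(_aa)] = AMBIGUOUS_CODE


def encode(sequence: str) -> np.ndarray:
    """Encode an upper-case sequence string to integer codes.

    Raises ValueError naming the first illegal character and its 1-based
    column.
    """
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _LUT[np.minimum(raw, 127)]
    bad = np.nonzero(codes < 0)[0]
    if bad.size:
        col = int(bad[0]) + 1
        raise ValueError(f"illegal character {sequence[bad[0]]!r} at column {col}")
    return codes.astype(np.int8)


def decode(codes: np.ndarray) -> str:
    table = STANDARD_RESIDUES + GAP_CHAR + "X"
    return "".join(table[c] for c in codes)
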