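"""2-bit integer packing of fixed-length nucleotide tags.

A 21-nt tag fits in 42 bits of an int64 (base A=0, C=1, G=2, T=3, two
bits per base, 5' base in the highest-order field), which makes exact
lookup and single-mismatch neighbourhood enumeration cheap numpy
operations instead of per-string Python loops.
"""

from __future__ import annotations

import numpy as np

TAG_LEN = 21
ANCHOR = "CATG"

_BASE_ORDER = "ACGT"
_ASCII_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASE_ORDER):
    _ASCII_TO_CODE[ord(_b)] = _i
    _ASCII_TO_CODE[ord(_b.lower())] = _i

# Anchor packed into the four highest 2-bit fields of a tag.
ANCHOR_CODE = 0
for _b in ANCHOR:
    ANCHOR_CODE = (ANCHOR_CODE << 2) | int(_ASCII_TO_CODE[ord(_b)])
ANCHOR_SHIFT = 2 * (TAG_LEN - len(ANCHOR))

# XOR masks generating the 63 sequences at Hamming distance exactly 1
# from any 21-mer: 3 alternative bases at each of 21 positions.
MISMATCH_MASKS = np.array(
    [d << (2 * p) for p in range(TAG_LEN) for d in (1, 2, 3)], dtype=np.int64
)


def encode_tags(tags: "list[str] | np.ndarray") -> np.ndarray:
    """Pack equal-length A/C/G/T strings into int64 codes (vectorised)."""
    if len(tags) == 0:
        return np.empty(0, dtype=np.int64)
    buf = np.frombuffer("".join(tags).encode("ascii"), dtype=np.uint8)
    codes = _ASCII_TO_CODE[buf].reshape(len(tags), -1)
    if codes.shape[1] != TAG_LEN:
        raise ValueError(f"expected {TAG_LEN}-nt tags, got length {codes.shape[1]}")
    if (codes == 255).any():
        bad = int(np.argmax((codes == 255).any(axis=1)))
        raise ValueError(f"non-ACGT character in tag {tags[bad]!r}")
    weights = (np.int64(1) << (2 * np.arange(TAG_LEN - 1, -1, -1, dtype=np.int64)))
    return codes.astype(np.int64) @ weights


def encode_tag(tag: str) -> int:
    return int(encode_tags([tag])[0])


def decode_tag(code: int, length: int = TAG_LEN) -> str:
    out = []
    for p in range(length - 1, -1, -1):
        out.append(_BASE_ORDER[(code >> (2 * p)) & 3])
    return "".join(out)


def starts_with_anchor(codes: np.ndarray) -> np.ndarray:
    """Boolean mask of tags whose first four bases are the CATG anchor."""
    return (codes >> ANCHOR_SHIFT) == ANCHOR_CODE
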