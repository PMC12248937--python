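"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: byte encoding used by the array scanners (A=0, C=1, G=2, T=3, N=4)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _b, _c in _CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as a uint8 array (N and unknowns map to 4)."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def count_occurrences(haystack: str, needle: str, limit: int | None = None) -> int:
    """Count (possibly overlapping) occurrences of ``needle`` in ``haystack``.

    Stops early once ``limit`` occurrences have been seen.
    """
    n = 0
    i = haystack.find(needle)
    while i != -1:
        n += 1
        if limit is not None and n >= limit:
            return n
        i = haystack.find(needle, i + 1)
    return n
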