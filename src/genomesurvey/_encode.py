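"""2-bit nucleotide encoding shared by the simulators and the k-mer counter.

A=0, C=1, G=2, T=3; anything else maps to 255 (invalid). Complement of a
valid code is ``3 - code``, so reverse complement is cheap on arrays.
"""

from __future__ import annotations

import numpy as np

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _LUT[_b] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

INVALID = np.uint8(255)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (255 for non-ACGT)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes (all < 4) back to an ACGT string."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT-only string."""
    codes = encode(seq)
    if (codes > 3).any():
        raise ValueError("revcomp requires an ACGT-only sequence")
    return decode(3 - codes[::-1])
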