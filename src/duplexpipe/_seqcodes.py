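"""Byte-level sequence encoding shared by the simulator and the consensus caller.

Bases are stored as uint8 codes: A=0, C=1, G=2, T=3, N=4.  Complement of a
code c < 4 is 3 - c, which makes reverse-complement a slice plus a subtraction.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

# ASCII byte -> code (unknown characters map to N)
ASCII_TO_CODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    ASCII_TO_CODE[ord(_b)] = _i
    ASCII_TO_CODE[ord(_b.lower())] = _i

CODE_TO_ASCII = np.frombuffer(BASES.encode(), dtype=np.uint8)

# code -> complement code (N stays N)
COMP = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """String -> uint8 code array."""
    return ASCII_TO_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """uint8 code array -> string."""
    return CODE_TO_ASCII[codes].tobytes().decode()


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis."""
    return COMP[codes][..., ::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))
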