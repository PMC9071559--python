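"""Low-level sequence helpers shared across modules.

Sequences are plain Python strings over {A,C,G,T,N}; numeric kernels work on
uint8 code arrays (A=0, C=1, G=2, T=3, N=4).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# uint8 code tables
A, C, G, T, N = 0, 1, 2, 3, 4
_CODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP_CODE = np.array([T, G, C, A, N], dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving map)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0,C=1,G=2,T=3, anything else=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def comp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_CODE[codes]


def gc_fraction(seq: str) -> float:
    codes = encode(seq)
    n = int(np.count_nonzero(codes != N))
    if n == 0:
        return 0.0
    return int(np.count_nonzero((codes == C) | (codes == G))) / n


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """i.i.d. random DNA with expected GC content ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p).astype(np.uint8))
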