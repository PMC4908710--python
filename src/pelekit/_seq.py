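"""Nucleotide / Phred helpers shared across the package.

Sequences travel as upper-case strings over {A,C,G,T,N} at module
boundaries and as uint8 code arrays (A=0, C=1, G=2, T=3, N=4) inside the
vectorised paths.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

_CODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_CHAR = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """String -> uint8 code array (unknown letters become N)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    return _CHAR[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][..., ::-1]


def encode_rows(seqs, length: int) -> np.ndarray:
    """Equal-length strings -> uint8 code matrix in one pass."""
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _CODE[buf].reshape(-1, length)


def decode_rows(mat: np.ndarray) -> list[str]:
    """uint8 code matrix -> list of strings in one pass."""
    raw = _CHAR[np.ascontiguousarray(mat, dtype=np.uint8)].tobytes()
    w = mat.shape[1]
    return [raw[i : i + w].decode("ascii") for i in range(0, len(raw), w)]


def phred_to_prob(q) -> np.ndarray:
    return np.power(10.0, -np.asarray(q, dtype=float) / 10.0)


def prob_to_phred(p) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return -10.0 * np.log10(np.asarray(p, dtype=float))


def qual_to_phred(qual: str) -> np.ndarray:
    """Phred+33 quality string -> integer Phred array."""
    arr = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64)
    return arr - 33


def phred_to_qual(phred: np.ndarray) -> str:
    arr = np.clip(np.asarray(phred, dtype=np.int64), 0, 93) + 33
    return arr.astype(np.uint8).tobytes().decode("ascii")
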