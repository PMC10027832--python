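"""Small nucleotide helpers shared across the pipeline.

Bases are encoded as uint8 codes (A=0, C=1, G=2, T=3, N=4) so per-read work
can stay in numpy.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (non-ACGT -> N)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def rotate(seq: str, offset: int) -> str:
    """Circularly rotate so position ``offset`` becomes the first base.

    Rotating by o1 then o2 equals rotating by (o1 + o2) mod len(seq).
    """
    if not seq:
        return seq
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


def longest_true_run(mask: np.ndarray) -> tuple[int, int]:
    """Return (start, end) of the longest run of True; (0, 0) if none.

    Ties are broken toward the smallest start.
    """
    if mask.size == 0 or not mask.any():
        return (0, 0)
    padded = np.concatenate(([False], mask, [False]))
    diffs = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diffs == 1)
    ends = np.flatnonzero(diffs == -1)
    lengths = ends - starts
    best = int(np.argmax(lengths))  # argmax takes the first maximum
    return (int(starts[best]), int(ends[best]))
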