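"""Tandem-repeat detection and repeat-unit consensus building.

A rolling-circle cDNA read consists of tandem copies of one RNA fragment.
:func:`detect_period` recovers the fragment length (the repeat period) from
the read alone via a lag-p self-comparison, and :func:`build_consensus`
reconciles all copies into a per-position consensus carrying the support
count, a unanimity flag and the summed Phred quality — the raw material for
the downstream per-base checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Union

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .config import PipelineConfig
from .seqs import N, decode, encode


@dataclass
class ReadRecord:
    """One sequencing read with per-base Phred qualities."""

    read_id: str
    seq: str
    qual: np.ndarray  # integer Phred values, same length as seq

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=np.int16)
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )
        if self.qual.size and (self.qual.min() < 0 or self.qual.max() > 60):
            raise ValueError(f"{self.read_id}: Phred values outside [0, 60]")


@dataclass(frozen=True)
class Rejection:
    """A read that carries no usable repeat evidence, with the reason."""

    read_id: str
    reason: str  # too_short | period_below_min | low_identity


@dataclass(frozen=True)
class RepeatDecomposition:
    read_id: str
    period: int
    n_full_copies: int
    partial_tail_len: int
    identity: float


@dataclass
class ConsensusUnit:
    """Per-position reconciliation of all repeat copies of one read.

    ``n_support`` counts the non-N calls contributing to each position,
    ``unanimous`` is True iff all contributing non-N calls agree, and
    ``quality_sum`` is the arithmetic sum of the contributing Phred values
    (N calls contribute zero quality).
    """

    read_id: str
    period: int
    seq: str  # majority call per position; ties become N
    n_support: np.ndarray
    unanimous: np.ndarray
    quality_sum: np.ndarray
    n_full_copies: int = 0
    identity: float = 1.0

    def __len__(self) -> int:
        return self.period


def read_fastq(path: Union[str, Path], phred_offset: int = 33) -> Iterator[ReadRecord]:
    """Iterate FASTQ records as :class:`ReadRecord`."""
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            read_id = title.split()[0]
            quals = (
                np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
                - phred_offset
            )
            yield ReadRecord(read_id, seq, quals)


def detect_period(
    read: ReadRecord, cfg: PipelineConfig
) -> Union[RepeatDecomposition, Rejection]:
    """Find the tandem-repeat period of a read, or reject it.

    Candidate periods p are scored by the lag-p self-identity: the fraction
    of positions i with seq[i] == seq[i+p], taken jointly over the whole
    read.  The maximising p wins, ties broken toward the smallest p, which
    selects the fundamental period for perfect repeats (p rather than 2p).
    The scan starts at p=1 so that a read whose true repeat unit is shorter
    than ``min_repeat_len`` is recognised and rejected instead of being
    silently re-described by a multiple of its fundamental period.

    Rejections: reads shorter than two minimal units (``too_short``), a best
    period below the minimum unit size (``period_below_min``), and best
    identity below ``min_repeat_identity`` (``low_identity``).  Reads with a
    single copy carry no repeat evidence, which the p <= len/2 bound
    enforces.
    """
    length = len(read.seq)
    if length < 2 * cfg.min_repeat_len:
        return Rejection(read.read_id, "too_short")
    codes = encode(read.seq)
    identities = np.zeros(length // 2 + 1)
    for p in range(1, length // 2 + 1):
        matches = int(np.count_nonzero(codes[p:] == codes[:-p]))
        identities[p] = matches / (length - p)
    best_p = int(np.argmax(identities))  # first maximum = smallest p
    best_identity = float(identities[best_p])
    if best_identity < cfg.min_repeat_identity:
        return Rejection(read.read_id, "low_identity")
    # fold a noisy multiple back onto the fundamental period: single-copy
    # artifacts are double-counted by the lag-p comparison at the true period
    # and can nudge the raw argmax to 2p; the smallest divisor still clearing
    # the identity threshold is the period the repeat structure supports
    period, identity = best_p, best_identity
    for d in range(1, best_p):
        if best_p % d == 0 and identities[d] >= cfg.min_repeat_identity:
            period, identity = d, float(identities[d])
            break
    if period < cfg.min_repeat_len:
        return Rejection(read.read_id, "period_below_min")
    return RepeatDecomposition(
        read_id=read.read_id,
        period=period,
        n_full_copies=length // period,
        partial_tail_len=length % period,
        identity=identity,
    )


def build_consensus(read: ReadRecord, decomp: RepeatDecomposition) -> ConsensusUnit:
    """Collapse the repeat copies of a read into one consensus unit.

    Copy k contributes its call read[j + k*period] to unit position j for
    every copy (including the trailing partial copy) that covers j.  The
    consensus base is the majority non-N call; a majority tie yields N and
    breaks unanimity.  N calls never count toward support or quality and
    break unanimity only when a non-N disagreement also exists.
    """
    p = decomp.period
    length = len(read.seq)
    n_rows = math.ceil(length / p)
    codes = np.full(n_rows * p, N, dtype=np.uint8)
    codes[:length] = encode(read.seq)
    quals = np.zeros(n_rows * p, dtype=np.int64)
    quals[:length] = read.qual
    codes = codes.reshape(n_rows, p)
    quals = quals.reshape(n_rows, p)

    informative = codes < N
    counts = np.stack(
        [np.count_nonzero(codes == b, axis=0, keepdims=False) for b in range(4)]
    )  # base-call tallies excluding N (N==4 never matches b<4)
    n_support = counts.sum(axis=0)
    quality_sum = np.where(informative, quals, 0).sum(axis=0)
    distinct = np.count_nonzero(counts > 0, axis=0)
    top = counts.max(axis=0)
    winner = counts.argmax(axis=0).astype(np.uint8)
    tie = np.count_nonzero(counts == top[None, :], axis=0) > 1
    consensus_codes = np.where((top > 0) & ~tie, winner, np.uint8(N))
    unanimous = distinct == 1

    return ConsensusUnit(
        read_id=read.read_id,
        period=p,
        seq=decode(consensus_codes),
        n_support=n_support.astype(np.int32),
        unanimous=unanimous,
        quality_sum=quality_sum,
        n_full_copies=decomp.n_full_copies,
        identity=decomp.identity,
    )


def write_consensus_files(
    units: Iterable[ConsensusUnit],
    fasta_path: Union[str, Path],
    table_path: Union[str, Path],
) -> None:
    """Write unit sequences as FASTA plus a per-position sidecar TSV."""
    fasta_path, table_path = Path(fasta_path), Path(table_path)
    with open(fasta_path, "w") as fa, open(table_path, "w") as tsv:
        tsv.write(
            "read_id\tperiod\tn_full_copies\tidentity\tposition\t"
            "n_support\tunanimous\tquality_sum\n"
        )
        for unit in units:
            fa.write(f">{unit.read_id}\n{unit.seq}\n")
            for j in range(unit.period):
                tsv.write(
                    f"{unit.read_id}\t{unit.period}\t{unit.n_full_copies}\t"
                    f"{unit.identity:.6f}\t{j}\t{unit.n_support[j]}\t"
                    f"{int(unit.unanimous[j])}\t{unit.quality_sum[j]}\n"
                )
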