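"""Rotation (5' end) search and genomic placement of repeat consensuses.

The rolling-circle RT reaction is randomly primed, so a repeat consensus is
a circular rotation of the original RNA fragment.  The rotation is recovered
by aligning the doubled consensus (the sequence concatenated with itself) to
the reference and choosing the rotation whose end-to-end placement leaves the
longest, most complete contiguous mapping — the 5' end of the fragment is
where the periodic sequence stops matching the genome.  Consensuses that
still carry mismatches after placement are re-evaluated at every rotation
(:func:`refine_mismatch_alignment`) so that a mis-located 5' end can never
manufacture a false mismatch.

The aligner is pluggable: :class:`BuiltinAligner` is an exact seed-and-extend
mapper (substitution-aware, unspliced) sufficient for compact references and
all tests; :func:`alignments_from_sam` ingests placements produced by any
external splice-aware aligner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import numpy as np

from .config import PipelineConfig
from .consensus import ConsensusUnit
from .seqs import encode, longest_true_run, revcomp, rotate

Op = Tuple[str, int]  # ("match" | "mismatch" | "insertion" | "deletion", length)


@dataclass
class GenomicAlignment:
    """Placement of a rotated consensus on the reference.

    ``start`` is the 0-based half-open position on the forward genomic
    strand; ``strand_start`` is the same placement expressed on the
    strand-oriented sequence (identical to ``start`` on '+').  Per-position
    metadata (support, unanimity, quality sums) are carried through the
    rotation so downstream checks index them in fragment orientation.
    """

    consensus_id: str
    chrom: Optional[str]
    start: int
    strand: str  # "+" or "-"
    rotation_offset: int
    aligned_ops: List[Op]
    n_mismatches: int
    mapped: bool
    reason: Optional[str] = None
    period: int = 0
    strand_start: int = 0
    mismatch_positions: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=np.int64)
    )
    rotated_seq: str = ""
    n_support: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int32))
    unanimous: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    quality_sum: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))


def _unmapped(cons: ConsensusUnit, reason: str) -> GenomicAlignment:
    return GenomicAlignment(
        consensus_id=cons.read_id,
        chrom=None,
        start=-1,
        strand="+",
        rotation_offset=0,
        aligned_ops=[],
        n_mismatches=0,
        mapped=False,
        reason=reason,
        period=cons.period,
    )


class BuiltinAligner:
    """Exact seed-and-extend mapper over a small in-memory reference.

    Both genomic strands are indexed with non-overlapping k-mer seeds; a
    query is placed on every seed-compatible diagonal and scored by Hamming
    distance.  There is no indel model: the repeat consensus is expected to
    be colinear with the reference, and reads whose repeat structure is
    broken by indels have already been rejected at period detection.
    """

    def __init__(self, genome: Mapping[str, str], seed_len: int = 20):
        self.seed_len = seed_len
        self.chrom_lengths: Dict[str, int] = {}
        self._strand_str: Dict[Tuple[str, str], str] = {}
        self._strand_codes: Dict[Tuple[str, str], np.ndarray] = {}
        self._index: Dict[str, List[Tuple[str, str, int]]] = {}
        for chrom in sorted(genome):
            seq = genome[chrom].upper()
            self.chrom_lengths[chrom] = len(seq)
            for strand, sseq in (("+", seq), ("-", revcomp(seq))):
                self._strand_str[(chrom, strand)] = sseq
                self._strand_codes[(chrom, strand)] = encode(sseq)
                for pos in range(0, len(sseq) - seed_len + 1):
                    kmer = sseq[pos : pos + seed_len]
                    self._index.setdefault(kmer, []).append((chrom, strand, pos))

    def strand_codes(self, chrom: str, strand: str) -> np.ndarray:
        return self._strand_codes[(chrom, strand)]

    def _seed_positions(self, qlen: int) -> List[int]:
        # half-overlapping seeds so a single substitution cannot knock out
        # every seed covering a short repeat unit
        k = self.seed_len
        if qlen < k:
            return []
        stride = max(1, k // 2)
        positions = list(range(0, qlen - k + 1, stride))
        if positions[-1] != qlen - k:
            positions.append(qlen - k)
        return positions

    def candidate_diagonals(
        self, query: str, seed_starts: Optional[Iterable[int]] = None
    ) -> List[Tuple[str, str, int]]:
        """Diagonals (chrom, strand, query-start-on-strand) hit by any seed."""
        hits = set()
        if seed_starts is None:
            seed_starts = self._seed_positions(len(query))
        for qpos in seed_starts:
            kmer = query[qpos : qpos + self.seed_len]
            for chrom, strand, pos in self._index.get(kmer, ()):
                hits.add((chrom, strand, pos - qpos))
        return sorted(hits)

    def match_profile(
        self, query_codes: np.ndarray, chrom: str, strand: str, g: int
    ) -> np.ndarray:
        """Per-position equality of the query placed at strand position g."""
        ref = self._strand_codes[(chrom, strand)]
        n = query_codes.size
        profile = np.zeros(n, dtype=bool)
        lo = max(0, -g)
        hi = min(n, ref.size - g)
        if hi > lo:
            profile[lo:hi] = query_codes[lo:hi] == ref[g + lo : g + hi]
        return profile

    def placements(
        self, query: str
    ) -> List[Tuple[str, str, int, int, np.ndarray]]:
        """Fully in-bounds placements: (chrom, strand, g, n_mism, mism_idx)."""
        codes = encode(query)
        out = []
        for chrom, strand, g in self.candidate_diagonals(query):
            if g < 0 or g + codes.size > self._strand_codes[(chrom, strand)].size:
                continue
            profile = self.match_profile(codes, chrom, strand, g)
            mism = np.flatnonzero(~profile)
            out.append((chrom, strand, g, int(mism.size), mism))
        return out


def find_five_prime(
    cons: ConsensusUnit, aligner: BuiltinAligner
) -> Optional[int]:
    """Locate the fragment 5' end; returns the rotation offset in [0, period).

    The doubled consensus is placed on every seed-compatible diagonal; for
    each rotation o the score is the number of reference-matching positions
    in the length-period window starting at o, i.e. how completely that
    rotation maps end-to-end.  The best-scoring rotation on the best diagonal
    wins (ties toward the smallest offset); for a clean fragment this window
    is exactly the longest continuous mapping region.  Returns None when no
    diagonal is found.
    """
    p = cons.period
    doubled = cons.seq + cons.seq
    codes = encode(doubled)
    # every circular seed start: a usable seed must dodge both the copy
    # junction and any template error, which can defeat sparse seeding on
    # short units
    dense_starts = range(0, min(p, len(doubled) - aligner.seed_len) + 1)
    best: Optional[Tuple[int, int, int]] = None  # (-score, -run_len, offset)
    for chrom, strand, g in aligner.candidate_diagonals(doubled, dense_starts):
        profile = aligner.match_profile(codes, chrom, strand, g)
        cum = np.concatenate(([0], np.cumsum(profile)))
        scores = cum[p : 2 * p + 1][: p] - cum[:p]  # window [o, o+p) for o<p
        top = int(scores.max())
        if top == 0:
            continue
        # rotations tying on total matches are separated by the length of
        # their longest continuous exactly-mapping stretch: a true rotation
        # keeps disagreements at the window edge, a wrapped one moves them
        # inboard and shortens the clean run
        for o in np.flatnonzero(scores == top):
            o = int(o)
            run_start, run_end = longest_true_run(profile[o : o + p])
            key = (-top, -(run_end - run_start), o)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return best[2]


def _ops_from_profile(mismatch_idx: np.ndarray, length: int) -> List[Op]:
    mask = np.zeros(length, dtype=bool)
    mask[mismatch_idx] = True
    ops: List[Op] = []
    i = 0
    while i < length:
        j = i
        while j < length and mask[j] == mask[i]:
            j += 1
        ops.append(("mismatch" if mask[i] else "match", j - i))
        i = j
    return ops


def map_consensus(
    cons: ConsensusUnit,
    offset: int,
    aligner: BuiltinAligner,
    cfg: PipelineConfig,
) -> GenomicAlignment:
    """Map the rotated consensus end-to-end; best Hamming placement wins.

    Two distinct placements tying at the minimum mismatch count make the
    consensus ambiguous and therefore unmapped (a multi-mapping consensus
    would corrupt per-site depth counts).
    """
    p = cons.period
    rseq = rotate(cons.seq, offset)
    placements = aligner.placements(rseq)
    if not placements:
        return _unmapped(cons, "unaligned")
    placements.sort(key=lambda t: (t[3], t[0], t[1], t[2]))
    best = placements[0]
    if len(placements) > 1 and placements[1][3] == best[3]:
        return _unmapped(cons, "ambiguous")
    chrom, strand, g, n_mism, mism_idx = best
    chrom_len = aligner.chrom_lengths[chrom]
    start = g if strand == "+" else chrom_len - g - p
    roll = -offset % p if p else 0
    return GenomicAlignment(
        consensus_id=cons.read_id,
        chrom=chrom,
        start=start,
        strand=strand,
        rotation_offset=offset,
        aligned_ops=_ops_from_profile(mism_idx, p),
        n_mismatches=n_mism,
        mapped=True,
        period=p,
        strand_start=g,
        mismatch_positions=mism_idx,
        rotated_seq=rseq,
        n_support=np.roll(cons.n_support, -offset),
        unanimous=np.roll(cons.unanimous, -offset),
        quality_sum=np.roll(cons.quality_sum, -offset),
    )


def refine_mismatch_alignment(
    aln: GenomicAlignment,
    cons: ConsensusUnit,
    aligner: BuiltinAligner,
    cfg: PipelineConfig,
) -> GenomicAlignment:
    """Re-evaluate every rotation of a mismatch-bearing alignment.

    If any rotation maps with strictly fewer mismatches it replaces the
    input; otherwise the input is confirmed.  Applying the function twice is
    a fixed point, and a mismatch that survives it cannot be an artifact of
    a mis-located 5' end.
    """
    if not aln.mapped or aln.n_mismatches < 1:
        raise ValueError("refinement requires a mapped alignment with >=1 mismatch")
    best = aln
    for offset in range(cons.period):
        if offset == aln.rotation_offset:
            continue
        candidate = map_consensus(cons, offset, aligner, cfg)
        if candidate.mapped and candidate.n_mismatches < best.n_mismatches:
            best = candidate
    return best


def max_plausible_mismatches(period: int, cfg: PipelineConfig) -> int:
    """Mismatch budget implied by the repeat-identity threshold."""
    return max(2, math.ceil((1.0 - cfg.min_repeat_identity) * period))


def locate_consensus(
    cons: ConsensusUnit, aligner: BuiltinAligner, cfg: PipelineConfig
) -> GenomicAlignment:
    """find_five_prime -> map -> refine, with a final plausibility gate.

    Placements that still disagree with the reference at more positions than
    the repeat-identity threshold allows are discarded as spurious hits
    rather than reported as error-dense alignments.
    """
    offset = find_five_prime(cons, aligner)
    if offset is None:
        return _unmapped(cons, "unaligned")
    aln = map_consensus(cons, offset, aligner, cfg)
    if not aln.mapped:
        return aln
    if aln.n_mismatches >= 1:
        aln = refine_mismatch_alignment(aln, cons, aligner, cfg)
    if aln.mapped and aln.n_mismatches > max_plausible_mismatches(cons.period, cfg):
        return _unmapped(cons, "poor_alignment")
    return aln


def write_alignment_table(
    alignments: Iterable[GenomicAlignment], path: Union[str, Path]
) -> None:
    with open(path, "w") as out:
        out.write(
            "consensus_id\tmapped\treason\tchrom\tstart\tstrand\t"
            "rotation_offset\tperiod\tn_mismatches\tops\n"
        )
        for aln in alignments:
            ops = ",".join(f"{op}:{ln}" for op, ln in aln.aligned_ops)
            out.write(
                f"{aln.consensus_id}\t{int(aln.mapped)}\t{aln.reason or '.'}\t"
                f"{aln.chrom or '.'}\t{aln.start}\t{aln.strand}\t"
                f"{aln.rotation_offset}\t{aln.period}\t{aln.n_mismatches}\t"
                f"{ops or '.'}\n"
            )


def alignments_from_sam(
    sam_path: Union[str, Path],
    units_by_id: Mapping[str, ConsensusUnit],
    cfg: PipelineConfig,
    reference: Optional[Mapping[str, str]] = None,
    rotation_offsets: Optional[Mapping[str, int]] = None,
) -> List[GenomicAlignment]:
    """Ingest placements of (already rotated) consensus sequences from SAM.

    The query sequences in the SAM are expected to be the rotated units as
    exported by the consensus stage.  Records below ``cfg.mapq_floor`` or
    flagged unmapped yield unmapped alignments; secondary and supplementary
    records are ignored.  Mismatch positions are taken from the MD tag when
    present, otherwise recomputed against ``reference``.
    """
    import pysam

    rotation_offsets = rotation_offsets or {}
    out: List[GenomicAlignment] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as handle:
        for rec in handle:
            if rec.is_secondary or rec.is_supplementary:
                continue
            name = rec.query_name
            cons = units_by_id.get(name)
            if cons is None:
                continue
            offset = int(rotation_offsets.get(name, 0))
            if rec.is_unmapped:
                out.append(_unmapped(cons, "unaligned"))
                continue
            if rec.mapping_quality < cfg.mapq_floor:
                out.append(_unmapped(cons, "low_mapq"))
                continue
            p = cons.period
            strand = "-" if rec.is_reverse else "+"
            # per-query-position ops
            ops: List[Op] = []
            mismatches: List[int] = []
            try:
                pairs = rec.get_aligned_pairs(with_seq=True)
            except ValueError:
                if reference is None:
                    raise ValueError(
                        f"{name}: SAM record lacks MD tag and no reference given"
                    )
                ref_seq = reference[rec.reference_name].upper()
                pairs = [
                    (q, r, ref_seq[r] if r is not None else None)
                    for q, r in rec.get_aligned_pairs()
                ]
            aligned_qseq = rec.query_sequence.upper()
            for qpos, rpos, refbase in pairs:
                if qpos is None:
                    ops.append(("deletion", 1))
                    continue
                if rpos is None:
                    ops.append(("insertion", 1))
                    continue
                # unit coordinates follow the rotated consensus orientation
                unit_idx = p - 1 - qpos if rec.is_reverse else qpos
                if refbase is None or aligned_qseq[qpos] == refbase.upper():
                    ops.append(("match", 1))
                else:
                    ops.append(("mismatch", 1))
                    mismatches.append(unit_idx)
            # merge runs
            merged: List[Op] = []
            for op, ln in ops:
                if merged and merged[-1][0] == op:
                    merged[-1] = (op, merged[-1][1] + ln)
                else:
                    merged.append((op, ln))
            rseq = rotate(cons.seq, offset)
            out.append(
                GenomicAlignment(
                    consensus_id=name,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    strand=strand,
                    rotation_offset=offset,
                    aligned_ops=merged,
                    n_mismatches=len(mismatches),
                    mapped=True,
                    period=p,
                    strand_start=rec.reference_start,
                    mismatch_positions=np.array(sorted(mismatches), dtype=np.int64),
                    rotated_seq=rseq,
                    n_support=np.roll(cons.n_support, -offset),
                    unanimous=np.roll(cons.unanimous, -offset),
                    quality_sum=np.roll(cons.quality_sum, -offset),
                )
            )
    return out
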