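"""The five per-base checks, the polymorphic-site filter, and error calling.

A consensus/reference mismatch only becomes a transcription-error call when
the base (1) is part of at least ``min_repeats`` repeat copies, (2) is called
identically by every copy, (3) carries a summed Phred quality strictly above
``min_quality_sum``, (4) sits strictly more than ``edge_margin`` nt away from
both ends of the rotated consensus, and (5) lies at a genomic site covered by
at least ``min_site_depth`` consensus reads of which strictly fewer than
``max_alt_fraction`` support a non-reference call.  Check 5 removes
heterozygous/polymorphic sites and RNA-editing positions, which recur across
reads, unlike transcription errors.

Every base that passes checks 1-4 at a check-5-passing site enters the
surveyed-base denominator; confirmed errors are the subset whose call differs
from the reference, so the numerator is a subset of the denominator by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np

from .config import PipelineConfig, PolymeraseClass
from .locate import GenomicAlignment
from .seqs import BASES, N, encode

CLASS_ORDER = list(PolymeraseClass)
_CLASS_CODE = {pc: i for i, pc in enumerate(CLASS_ORDER)}
_UNSET = np.int8(-1)
_UNASSIGNED_CODE = _CLASS_CODE[PolymeraseClass.UNASSIGNED]


@dataclass(frozen=True)
class SiteSummary:
    chrom: str
    site: int
    depth: int
    alt_count: int

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    def passes(self, cfg: PipelineConfig) -> bool:
        return self.depth >= cfg.min_site_depth and (
            self.alt_fraction < cfg.max_alt_fraction
        )


@dataclass
class CandidateError:
    """A consensus/reference disagreement with its per-check outcomes.

    ``ref_base`` and ``alt_base`` are reported in transcript orientation
    (for minus-strand placements the genomic bases are complemented).
    """

    consensus_id: str
    chrom: str
    site: int
    ref_base: str
    alt_base: str
    kind: str  # substitution | insertion | deletion
    c1_min_repeats: bool
    c2_unanimous: bool
    c3_quality_sum: bool
    c4_edge_margin: bool
    c5_site_filter: bool
    pol_class: PolymeraseClass = PolymeraseClass.UNASSIGNED
    unit_pos: int = -1

    @property
    def confirmed(self) -> bool:
        return (
            self.c1_min_repeats
            and self.c2_unanimous
            and self.c3_quality_sum
            and self.c4_edge_margin
            and self.c5_site_filter
        )


@dataclass
class ClassTally:
    n_errors: int = 0
    n_bases: int = 0
    den_by_ref: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=np.int64))
    n_insertions: int = 0
    n_deletions: int = 0


@dataclass
class SurveyLedger:
    """Numerator (confirmed errors) and denominator (surveyed bases) per class."""

    classes: Dict[PolymeraseClass, ClassTally] = field(
        default_factory=lambda: {pc: ClassTally() for pc in CLASS_ORDER}
    )

    @property
    def n_errors(self) -> int:
        return sum(t.n_errors for t in self.classes.values())

    @property
    def n_bases(self) -> int:
        return sum(t.n_bases for t in self.classes.values())

    @property
    def n_indels(self) -> int:
        return sum(t.n_insertions + t.n_deletions for t in self.classes.values())

    def rate(self) -> float:
        return self.n_errors / self.n_bases if self.n_bases else float("nan")

    def to_rows(self) -> List[dict]:
        rows = []
        for pc in CLASS_ORDER:
            t = self.classes[pc]
            rows.append(
                {
                    "pol_class": pc.value,
                    "n_errors": t.n_errors,
                    "n_bases": t.n_bases,
                    "n_insertions": t.n_insertions,
                    "n_deletions": t.n_deletions,
                    **{
                        f"bases_ref_{b}": int(t.den_by_ref[i])
                        for i, b in enumerate("ACGT")
                    },
                }
            )
        return rows


class ClassLookup:
    """Per-site polymerase-class assignment from transcript features.

    Features are (chrom, start, end, strand, PolymeraseClass) with 0-based
    half-open coordinates.  Overlapping features of conflicting classes mark
    the overlap unassigned; sites outside every feature are unassigned.
    """

    def __init__(
        self,
        chrom_lengths: Mapping[str, int],
        features: Iterable[Tuple[str, int, int, str, PolymeraseClass]],
    ):
        self._codes = {
            chrom: np.full(length, _UNSET, dtype=np.int8)
            for chrom, length in chrom_lengths.items()
        }
        for chrom, start, end, _strand, pc in features:
            arr = self._codes[chrom]
            code = np.int8(_CLASS_CODE[pc])
            segment = arr[start:end]
            conflict = (segment != _UNSET) & (segment != code)
            segment[~conflict] = code
            segment[conflict] = np.int8(_UNASSIGNED_CODE)
            arr[start:end] = segment

    def codes_at(self, chrom: str, sites: np.ndarray) -> np.ndarray:
        codes = self._codes[chrom][sites].astype(np.int64)
        codes[codes == _UNSET] = _UNASSIGNED_CODE
        return codes

    def class_of(self, chrom: str, site: int) -> PolymeraseClass:
        if chrom not in self._codes:
            return PolymeraseClass.UNASSIGNED
        return CLASS_ORDER[int(self.codes_at(chrom, np.array([site]))[0])]


class SitePileup:
    """Depth and alternate-call tallies per genomic site.

    One consensus-bearing read contributes one call per site it covers,
    regardless of how many repeat copies the read contains: the site-filter
    unit is reads.
    """

    def __init__(self, chrom_lengths: Mapping[str, int]):
        self.depth = {
            chrom: np.zeros(length, dtype=np.int32)
            for chrom, length in chrom_lengths.items()
        }
        self.alt = {
            chrom: np.zeros(length, dtype=np.int32)
            for chrom, length in chrom_lengths.items()
        }

    def add(self, aln: GenomicAlignment) -> None:
        if not aln.mapped:
            return
        sites = alignment_sites(aln)
        np.add.at(self.depth[aln.chrom], sites, 1)
        if aln.mismatch_positions.size:
            np.add.at(self.alt[aln.chrom], sites[aln.mismatch_positions], 1)

    def passes_mask(self, cfg: PipelineConfig) -> Dict[str, np.ndarray]:
        out = {}
        for chrom, depth in self.depth.items():
            alt = self.alt[chrom]
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
            out[chrom] = (depth >= cfg.min_site_depth) & (frac < cfg.max_alt_fraction)
        return out

    def summary(self, chrom: str, site: int) -> SiteSummary:
        return SiteSummary(
            chrom=chrom,
            site=site,
            depth=int(self.depth[chrom][site]),
            alt_count=int(self.alt[chrom][site]),
        )


def alignment_sites(aln: GenomicAlignment) -> np.ndarray:
    """Genomic site of each rotated-consensus position (transcript 5'->3')."""
    idx = np.arange(aln.period)
    if aln.strand == "+":
        return aln.start + idx
    return aln.start + aln.period - 1 - idx


def summarize_sites(
    alignments: Iterable[GenomicAlignment], chrom_lengths: Mapping[str, int]
) -> SitePileup:
    """Tally per-site depth and alternate calls over mapped consensuses."""
    pileup = SitePileup(chrom_lengths)
    for aln in alignments:
        pileup.add(aln)
    return pileup


def check_base(
    aln: GenomicAlignment,
    unit_pos: int,
    site_summary: SiteSummary,
    cfg: PipelineConfig,
) -> Tuple[bool, bool, bool, bool, bool]:
    """Evaluate the five checks for one consensus base (scalar form)."""
    p = aln.period
    c1 = bool(aln.n_support[unit_pos] >= cfg.min_repeats)
    c2 = bool(aln.unanimous[unit_pos])
    c3 = bool(aln.quality_sum[unit_pos] > cfg.min_quality_sum)
    c4 = bool(
        (unit_pos > cfg.edge_margin) and (unit_pos < p - 1 - cfg.edge_margin)
    )
    c5 = site_summary.passes(cfg)
    return c1, c2, c3, c4, c5


def _tx_ref_codes(
    genome_codes: Mapping[str, np.ndarray], aln: GenomicAlignment, sites: np.ndarray
) -> np.ndarray:
    """Reference codes at ``sites`` in transcript orientation."""
    ref = genome_codes[aln.chrom][sites]
    if aln.strand == "-":
        comp = ref.copy()
        valid = comp < N
        comp[valid] = 3 - comp[valid]
        return comp
    return ref


def _indel_candidates(
    aln: GenomicAlignment,
    checks: Dict[str, np.ndarray],
    passes: np.ndarray,
    cfg: PipelineConfig,
) -> List[Tuple[str, int, int]]:
    """(kind, unit_pos, length) of indel ops that pass the transplanted checks.

    Indel-specific thresholds are not separately defined; the substitution
    checks are applied to the flanking consensus positions, and the edge
    margin to the indel's own position.
    """
    out = []
    qpos = 0
    p = aln.period
    base_ok = (
        checks["c1"] & checks["c2"] & checks["c3"]
    )  # per-position repeat-level checks
    for op, length in aln.aligned_ops:
        if op in ("match", "mismatch"):
            qpos += length
            continue
        if op == "insertion":
            anchor = qpos
            qpos += length
        else:  # deletion sits between qpos-1 and qpos
            anchor = qpos
        left = min(max(anchor - 1, 0), p - 1)
        right = min(anchor, p - 1)
        flanks_ok = bool(base_ok[left] and base_ok[right])
        in_margin = (anchor > cfg.edge_margin) and (anchor < p - 1 - cfg.edge_margin)
        site_ok = bool(passes[left]) and bool(passes[right])
        if flanks_ok and in_margin and site_ok:
            out.append((op, anchor, length))
    return out


def call_errors(
    alignments: Sequence[GenomicAlignment],
    pileup: SitePileup,
    class_lookup: ClassLookup,
    genome: Mapping[str, str],
    cfg: PipelineConfig,
) -> Tuple[List[CandidateError], SurveyLedger]:
    """Apply the five checks to every mapped base; build the survey ledger.

    Returns every consensus/reference disagreement as a
    :class:`CandidateError` carrying its check vector (confirmed iff all
    five are true), together with the :class:`SurveyLedger` whose
    denominator counts all bases passing checks 1-4 at check-5-passing
    sites, stratified by polymerase class and by reference base.
    """
    genome_codes = {chrom: encode(seq.upper()) for chrom, seq in genome.items()}
    passes_by_chrom = pileup.passes_mask(cfg)
    ledger = SurveyLedger()
    errors: List[CandidateError] = []

    for aln in alignments:
        if not aln.mapped:
            continue
        p = aln.period
        idx = np.arange(p)
        sites = alignment_sites(aln)
        c1 = aln.n_support >= cfg.min_repeats
        c2 = aln.unanimous.astype(bool)
        c3 = aln.quality_sum > cfg.min_quality_sum
        c4 = (idx > cfg.edge_margin) & (idx < p - 1 - cfg.edge_margin)
        c5 = passes_by_chrom[aln.chrom][sites]
        counted = c1 & c2 & c3 & c4 & c5

        class_codes = class_lookup.codes_at(aln.chrom, sites)
        ref_codes = _tx_ref_codes(genome_codes, aln, sites)

        counted_idx = np.flatnonzero(counted)
        if counted_idx.size:
            cls = class_codes[counted_idx]
            refs = ref_codes[counted_idx]
            keep = refs < 4
            flat = cls[keep] * 4 + refs[keep]
            tallies = np.bincount(flat, minlength=len(CLASS_ORDER) * 4)
            per_class = np.bincount(cls, minlength=len(CLASS_ORDER))
            for ci, pc in enumerate(CLASS_ORDER):
                tally = ledger.classes[pc]
                tally.n_bases += int(per_class[ci])
                tally.den_by_ref += tallies[ci * 4 : ci * 4 + 4]

        checks = {"c1": c1, "c2": c2, "c3": c3, "c4": c4, "c5": c5}
        alt_codes = encode(aln.rotated_seq)
        for m in aln.mismatch_positions:
            m = int(m)
            pc = CLASS_ORDER[int(class_codes[m])]
            err = CandidateError(
                consensus_id=aln.consensus_id,
                chrom=aln.chrom,
                site=int(sites[m]),
                ref_base=BASES[int(ref_codes[m])],
                alt_base=BASES[int(alt_codes[m])],
                kind="substitution",
                c1_min_repeats=bool(c1[m]),
                c2_unanimous=bool(c2[m]),
                c3_quality_sum=bool(c3[m]),
                c4_edge_margin=bool(c4[m]),
                c5_site_filter=bool(c5[m]),
                pol_class=pc,
                unit_pos=m,
            )
            errors.append(err)
            if err.confirmed:
                ledger.classes[pc].n_errors += 1

        for kind, anchor, length in _indel_candidates(
            aln, checks, passes_by_chrom[aln.chrom][sites], cfg
        ):
            site = int(sites[min(anchor, p - 1)])
            pc = CLASS_ORDER[int(class_codes[min(anchor, p - 1)])]
            errors.append(
                CandidateError(
                    consensus_id=aln.consensus_id,
                    chrom=aln.chrom,
                    site=site,
                    ref_base="-" if kind == "insertion" else "N" * length,
                    alt_base="N" * length if kind == "insertion" else "-",
                    kind=kind,
                    c1_min_repeats=True,
                    c2_unanimous=True,
                    c3_quality_sum=True,
                    c4_edge_margin=True,
                    c5_site_filter=True,
                    pol_class=pc,
                    unit_pos=anchor,
                )
            )
            if kind == "insertion":
                ledger.classes[pc].n_insertions += 1
            else:
                ledger.classes[pc].n_deletions += 1

    return errors, ledger


def classify_error(
    error: CandidateError, class_lookup: ClassLookup
) -> PolymeraseClass:
    """Polymerase class of the transcript feature overlapping the error site."""
    return class_lookup.class_of(error.chrom, error.site)


def write_errors_table(
    errors: Iterable[CandidateError], path: Union[str, Path]
) -> None:
    """VCF-like TSV of candidate and confirmed errors (1-based positions)."""
    with open(path, "w") as out:
        out.write(
            "chrom\tpos\tref\talt\tkind\tpol_class\tconsensus_id\t"
            "c1_min_repeats\tc2_unanimous\tc3_quality_sum\tc4_edge_margin\t"
            "c5_site_filter\tconfirmed\n"
        )
        for e in errors:
            out.write(
                f"{e.chrom}\t{e.site + 1}\t{e.ref_base}\t{e.alt_base}\t{e.kind}\t"
                f"{e.pol_class.value}\t{e.consensus_id}\t"
                f"{int(e.c1_min_repeats)}\t{int(e.c2_unanimous)}\t"
                f"{int(e.c3_quality_sum)}\t{int(e.c4_edge_margin)}\t"
                f"{int(e.c5_site_filter)}\t{int(e.confirmed)}\n"
            )


def write_ledger_table(ledger: SurveyLedger, path: Union[str, Path]) -> None:
    import pandas as pd

    pd.DataFrame(ledger.to_rows()).to_csv(path, sep="\t", index=False)
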