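"""Synthetic rolling-circle read simulator with a ground-truth registry.

The generator emulates the physical structure of a circle-sequencing
library: an RNA fragment of 30-80 nt is circularised and reverse-transcribed
in rolling-circle fashion, so each read is several tandem copies of one
fragment starting at a random rotation.  Three error processes are injected
with known, separable provenance:

* transcription errors mutate the fragment template itself and therefore
  recur in every copy of the read;
* reverse-transcription errors strike individual cDNA copies;
* sequencing errors strike individual read bases and drag their Phred
  quality down.

Heterozygous genomic sites are emulated by giving a configurable fraction of
fragments overlapping the site the alternate allele.  Every injected event
is recorded in a :class:`TruthRegistry` so recovery and artifact-suppression
properties of the pipeline can be asserted exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import PolymeraseClass
from .consensus import ReadRecord
from .quantify import SUBSTITUTION_TYPES
from .seqs import BASES, decode, encode, revcomp


class PlacementError(ValueError):
    """Transcripts cannot be placed without overlap."""


class GeometryError(ValueError):
    """Fragment length and copy number are incompatible with the read length."""


def _default_class_fractions() -> Dict[PolymeraseClass, float]:
    return {
        PolymeraseClass.RNAPI: 0.20,
        PolymeraseClass.RNAPII: 0.50,
        PolymeraseClass.RNAPIII: 0.15,
        PolymeraseClass.MTRNAP: 0.15,
    }


def _default_spectrum() -> Dict[str, float]:
    # G>A-dominant spectrum with a strong C>U component, the signature shape
    # of RNA-polymerase errors; the remaining ten types share the rest.
    spectrum = {t: 0.02 for t in SUBSTITUTION_TYPES}
    spectrum["G>A"] = 0.50
    spectrum["C>U"] = 0.30
    return spectrum


@dataclass
class SimulationConfig:
    """All knobs of the synthetic library.

    ``mean_site_depth`` (reads per transcribed site, on average) determines
    the number of reads unless ``n_reads`` overrides it.
    """

    seed: int
    genome_length: int = 20_000
    n_transcripts: int = 12
    transcript_len: int = 700
    class_fractions: Dict[PolymeraseClass, float] = field(
        default_factory=_default_class_fractions
    )
    fragment_len_range: Tuple[int, int] = (40, 80)
    read_length: int = 250
    copies_per_read_range: Tuple[int, int] = (3, 6)
    txn_error_rate: float = 1e-4
    txn_spectrum: Dict[str, float] = field(default_factory=_default_spectrum)
    rt_error_rate: float = 1e-4
    seq_error_rate: float = 1e-3
    het_site_count: int = 50
    het_alt_fraction: float = 0.5
    # deep enough that the <1% site filter tolerates two non-reference reads
    # at one site (2/250 = 0.8%), matching the regime the >=200-read depth
    # floor creates on real libraries; at shallower depth a sporadic second
    # error at a site would erase both
    mean_site_depth: float = 250.0
    n_reads: Optional[int] = None

    def __post_init__(self) -> None:
        total = sum(self.txn_spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"txn_spectrum probabilities sum to {total}, not 1")
        if set(self.txn_spectrum) != set(SUBSTITUTION_TYPES):
            raise ValueError("txn_spectrum must cover exactly the 12 types")
        fmin, fmax = self.fragment_len_range
        if fmin < 1 or fmax < fmin:
            raise ValueError("invalid fragment_len_range")
        cmin, cmax = self.copies_per_read_range
        if cmin < 1 or cmax < cmin:
            raise ValueError("invalid copies_per_read_range")
        if cmin * fmax > self.read_length:
            raise GeometryError(
                f"{cmin} copies of a {fmax} nt fragment exceed the "
                f"{self.read_length} nt read length"
            )
        frac_total = sum(self.class_fractions.values())
        if self.n_transcripts > 0 and abs(frac_total - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")


@dataclass(frozen=True)
class TranscriptFeature:
    feature_id: str
    chrom: str
    start: int  # 0-based half-open genomic
    end: int
    strand: str
    pol_class: PolymeraseClass

    @property
    def length(self) -> int:
        return self.end - self.start

    def genomic_site(self, transcript_pos: int) -> int:
        if self.strand == "+":
            return self.start + transcript_pos
        return self.end - 1 - transcript_pos


@dataclass(frozen=True)
class TruthEvent:
    """One injected event; origins are mutually exclusive per event."""

    transcript_id: str
    transcript_pos: int
    chrom: str
    site: int
    ref_base: str  # transcript orientation
    alt_base: str
    origin: str  # transcription | rt | sequencing | het_site
    read_id: str = ""
    copy_index: int = -1


_TRUTH_COLUMNS = [
    "transcript_id",
    "transcript_pos",
    "chrom",
    "site",
    "ref_base",
    "alt_base",
    "origin",
    "read_id",
    "copy_index",
]


@dataclass
class TruthRegistry:
    events: List[TruthEvent] = field(default_factory=list)

    def add(self, event: TruthEvent) -> None:
        self.events.append(event)

    def of_origin(self, origin: str) -> List[TruthEvent]:
        return [e for e in self.events if e.origin == origin]

    def to_frame(self) -> pd.DataFrame:
        if not self.events:
            return pd.DataFrame(columns=_TRUTH_COLUMNS)
        return pd.DataFrame([e.__dict__ for e in self.events], columns=_TRUTH_COLUMNS)

    def __len__(self) -> int:
        return len(self.events)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TruthRegistry):
            return NotImplemented
        return self.events == other.events


def write_truth(truth: TruthRegistry, path: Union[str, Path]) -> None:
    """Write the registry as TSV; round-trips losslessly via read_truth."""
    truth.to_frame().to_csv(path, sep="\t", index=False)


def read_truth(path: Union[str, Path]) -> TruthRegistry:
    frame = pd.read_csv(
        path,
        sep="\t",
        dtype={c: str for c in ("transcript_id", "chrom", "ref_base", "alt_base",
                                "origin", "read_id")},
        keep_default_na=False,
    )
    events = [
        TruthEvent(
            transcript_id=row.transcript_id,
            transcript_pos=int(row.transcript_pos),
            chrom=row.chrom,
            site=int(row.site),
            ref_base=row.ref_base,
            alt_base=row.alt_base,
            origin=row.origin,
            read_id=row.read_id,
            copy_index=int(row.copy_index),
        )
        for row in frame.itertuples()
    ]
    return TruthRegistry(events)


def _class_counts(cfg: SimulationConfig) -> Dict[PolymeraseClass, int]:
    """Largest-remainder apportionment of transcripts to classes."""
    if cfg.n_transcripts == 0:
        return {}
    raw = {pc: frac * cfg.n_transcripts for pc, frac in cfg.class_fractions.items()}
    counts = {pc: int(math.floor(v)) for pc, v in raw.items()}
    short = cfg.n_transcripts - sum(counts.values())
    remainders = sorted(raw, key=lambda pc: raw[pc] - counts[pc], reverse=True)
    for pc in remainders[:short]:
        counts[pc] += 1
    return {pc: n for pc, n in counts.items() if n > 0}


def make_reference(
    cfg: SimulationConfig,
) -> Tuple[Dict[str, str], List[TranscriptFeature]]:
    """Random genome plus non-overlapping stranded transcript features.

    Mitochondrial-class transcripts live on their own sequence (``chrM``,
    one eighth of the total genome length) so the class structure mirrors a
    real nuclear/organellar split.  Raises :class:`PlacementError` when the
    transcripts cannot be placed without overlap.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = _class_counts(cfg)
    mt_count = counts.get(PolymeraseClass.MTRNAP, 0)
    mt_len = cfg.genome_length // 8 if mt_count else 0
    chr1_len = cfg.genome_length - mt_len
    genome = {"chr1": decode(rng.integers(0, 4, size=chr1_len).astype(np.uint8))}
    if mt_len:
        genome["chrM"] = decode(rng.integers(0, 4, size=mt_len).astype(np.uint8))

    placements: List[Tuple[str, int]] = []  # (chrom, count)
    nuclear = sum(n for pc, n in counts.items() if pc != PolymeraseClass.MTRNAP)
    features: List[TranscriptFeature] = []
    idx = 0

    def place(chrom: str, n: int, classes: List[PolymeraseClass]) -> None:
        nonlocal idx
        if n == 0:
            return
        chrom_len = len(genome[chrom])
        spacing = chrom_len // n
        if cfg.transcript_len + 2 > spacing:
            raise PlacementError(
                f"cannot place {n} transcripts of {cfg.transcript_len} nt "
                f"on {chrom} ({chrom_len} nt) without overlap"
            )
        for i in range(n):
            start = i * spacing + 1
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                TranscriptFeature(
                    feature_id=f"t{idx}",
                    chrom=chrom,
                    start=start,
                    end=start + cfg.transcript_len,
                    strand=strand,
                    pol_class=classes[i],
                )
            )
            idx += 1

    nuclear_classes: List[PolymeraseClass] = []
    for pc in (PolymeraseClass.RNAPI, PolymeraseClass.RNAPII, PolymeraseClass.RNAPIII):
        nuclear_classes.extend([pc] * counts.get(pc, 0))
    place("chr1", nuclear, nuclear_classes)
    if mt_count:
        place("chrM", mt_count, [PolymeraseClass.MTRNAP] * mt_count)
    return genome, features


def write_reference(
    genome: Mapping[str, str],
    features: Sequence[TranscriptFeature],
    fasta_path: Union[str, Path],
    gff3_path: Union[str, Path],
) -> None:
    with open(fasta_path, "w") as fa:
        for chrom in genome:
            fa.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 80):
                fa.write(seq[i : i + 80] + "\n")
    with open(gff3_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for feat in features:
            gff.write(
                f"{feat.chrom}\tcircfid-sim\ttranscript\t{feat.start + 1}\t"
                f"{feat.end}\t.\t{feat.strand}\t.\t"
                f"ID={feat.feature_id};pol_class={feat.pol_class.value}\n"
            )


def load_reference(fasta_path: Union[str, Path]) -> Dict[str, str]:
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }


def load_annotation(gff3_path: Union[str, Path]) -> List[TranscriptFeature]:
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    features = []
    for feat in db.all_features():
        label = feat.attributes.get("pol_class", ["unassigned"])[0]
        features.append(
            TranscriptFeature(
                feature_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                pol_class=PolymeraseClass.from_label(label),
            )
        )
    return features


def _transcript_seq(genome: Mapping[str, str], feat: TranscriptFeature) -> str:
    raw = genome[feat.chrom][feat.start : feat.end]
    return raw if feat.strand == "+" else revcomp(raw)


_RNA2DNA_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def simulate_reads(
    cfg: SimulationConfig,
    genome: Mapping[str, str],
    features: Sequence[TranscriptFeature],
) -> Tuple[List[ReadRecord], TruthRegistry]:
    """Generate rolling-circle reads and the registry of injected events.

    Reads are single-end, sense-strand tandem repeats truncated to
    ``read_length``.  Transcription errors are drawn per transcribed
    fragment (count Binomial(fragment_len, rate), type from the configured
    spectrum) and shared by all copies; RT errors are drawn per copied base;
    sequencing errors per read base, with low Phred qualities tied to the
    error positions (high copies sit at Q34-Q38, error bases at Q12-Q16).
    """
    if not features:
        return [], TruthRegistry()
    rng = np.random.default_rng(cfg.seed + 1)  # distinct stream from make_reference
    truth = TruthRegistry()

    tx_seqs = [encode(_transcript_seq(genome, f)) for f in features]
    tx_lens = np.array([f.length for f in features], dtype=np.int64)
    weights = tx_lens / tx_lens.sum()

    fmin, fmax = cfg.fragment_len_range
    mean_flen = (fmin + fmax) / 2.0
    n_reads = cfg.n_reads
    if n_reads is None:
        n_reads = int(round(cfg.mean_site_depth * tx_lens.sum() / mean_flen))

    # heterozygous sites: transcript-interior positions, one alt base each,
    # spaced at least one maximal fragment length apart so no single
    # fragment can span two sites (natural heterozygosity is kilobases
    # apart; co-located variants would confound rotation refinement in a
    # way real data does not)
    het_by_tx: Dict[int, Dict[int, int]] = {}
    if cfg.het_site_count > 0:
        margin = fmax
        eligible = [
            (ti, pos)
            for ti, f in enumerate(features)
            for pos in range(margin, f.length - margin, fmax)
        ]
        if cfg.het_site_count > len(eligible):
            raise ValueError(
                "het_site_count exceeds placeable sites at the required spacing"
            )
        chosen = rng.choice(len(eligible), size=cfg.het_site_count, replace=False)
        for flat in sorted(int(c) for c in chosen):
            ti, pos = eligible[flat]
            ref_code = int(tx_seqs[ti][pos])
            alt_code = int((ref_code + rng.integers(1, 4)) % 4)
            het_by_tx.setdefault(ti, {})[pos] = alt_code
            feat = features[ti]
            truth.add(
                TruthEvent(
                    transcript_id=feat.feature_id,
                    transcript_pos=pos,
                    chrom=feat.chrom,
                    site=feat.genomic_site(pos),
                    ref_base=BASES[ref_code],
                    alt_base=BASES[alt_code],
                    origin="het_site",
                )
            )

    spectrum_types = list(SUBSTITUTION_TYPES)
    spectrum_probs = np.array([cfg.txn_spectrum[t] for t in spectrum_types])
    spectrum_src = np.array([_RNA2DNA_CODE[t[0]] for t in spectrum_types])
    spectrum_dst = np.array([_RNA2DNA_CODE[t[2]] for t in spectrum_types])

    reads: List[ReadRecord] = []
    tx_choice = rng.choice(len(features), size=n_reads, p=weights)
    for i in range(n_reads):
        read_id = f"read{i:07d}"
        ti = int(tx_choice[i])
        feat = features[ti]
        tlen = int(tx_lens[ti])
        flen = int(rng.integers(fmin, fmax + 1))
        fstart = int(rng.integers(0, tlen - flen + 1))
        fragment = tx_seqs[ti][fstart : fstart + flen].copy()

        # heterozygous alleles: fragment-level, so present in every copy
        for pos, alt_code in het_by_tx.get(ti, {}).items():
            if fstart <= pos < fstart + flen and rng.random() < cfg.het_alt_fraction:
                fragment[pos - fstart] = alt_code

        # transcription errors: template-level, present in every copy
        n_txn = rng.binomial(flen, cfg.txn_error_rate)
        for _ in range(n_txn):
            for _attempt in range(100):
                t_idx = int(rng.choice(len(spectrum_types), p=spectrum_probs))
                positions = np.flatnonzero(fragment == spectrum_src[t_idx])
                if positions.size:
                    break
            else:
                continue
            pos = int(rng.choice(positions))
            tpos = fstart + pos
            if tpos in het_by_tx.get(ti, {}):
                continue  # keep event origins unambiguous
            ref_code = int(fragment[pos])
            fragment[pos] = spectrum_dst[t_idx]
            truth.add(
                TruthEvent(
                    transcript_id=feat.feature_id,
                    transcript_pos=tpos,
                    chrom=feat.chrom,
                    site=feat.genomic_site(tpos),
                    ref_base=BASES[ref_code],
                    alt_base=BASES[int(fragment[pos])],
                    origin="transcription",
                    read_id=read_id,
                )
            )

        k = int(rng.integers(cfg.copies_per_read_range[0], cfg.copies_per_read_range[1] + 1))
        rot = int(rng.integers(0, flen))
        rlen = min(k * flen, cfg.read_length)
        cdna = np.tile(fragment, k + 1)[rot : rot + rlen].copy()

        # RT errors: independent per copied base, confined to one copy
        n_rt = rng.binomial(rlen, cfg.rt_error_rate)
        if n_rt:
            rt_pos = rng.choice(rlen, size=n_rt, replace=False)
            for pos in sorted(int(p) for p in rt_pos):
                ref_code = int(cdna[pos])
                alt_code = int((ref_code + rng.integers(1, 4)) % 4)
                cdna[pos] = alt_code
                tpos = fstart + (rot + pos) % flen
                truth.add(
                    TruthEvent(
                        transcript_id=feat.feature_id,
                        transcript_pos=tpos,
                        chrom=feat.chrom,
                        site=feat.genomic_site(tpos),
                        ref_base=BASES[ref_code],
                        alt_base=BASES[alt_code],
                        origin="rt",
                        read_id=read_id,
                        copy_index=(rot + pos) // flen,
                    )
                )

        # sequencing errors: per read base, with degraded quality
        qual = rng.integers(34, 39, size=rlen).astype(np.int16)
        n_seq = rng.binomial(rlen, cfg.seq_error_rate)
        if n_seq:
            seq_pos = rng.choice(rlen, size=n_seq, replace=False)
            for pos in sorted(int(p) for p in seq_pos):
                ref_code = int(cdna[pos])
                alt_code = int((ref_code + rng.integers(1, 4)) % 4)
                cdna[pos] = alt_code
                qual[pos] = int(rng.integers(12, 17))
                tpos = fstart + (rot + pos) % flen
                truth.add(
                    TruthEvent(
                        transcript_id=feat.feature_id,
                        transcript_pos=tpos,
                        chrom=feat.chrom,
                        site=feat.genomic_site(tpos),
                        ref_base=BASES[ref_code],
                        alt_base=BASES[alt_code],
                        origin="sequencing",
                        read_id=read_id,
                        copy_index=(rot + pos) // flen,
                    )
                )

        reads.append(ReadRecord(read_id=read_id, seq=decode(cdna), qual=qual))

    return reads, truth


def write_fastq(
    reads: Iterable[ReadRecord], path: Union[str, Path], phred_offset: int = 33
) -> None:
    with open(path, "w") as out:
        for read in reads:
            qual = "".join(chr(int(q) + phred_offset) for q in read.qual)
            out.write(f"@{read.read_id}\n{read.seq}\n+\n{qual}\n")
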