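import numpy as np
import pytest

from circfid.config import PipelineConfig, PolymeraseClass
from circfid.consensus import RepeatDecomposition, build_consensus, detect_period
from circfid.seqs import revcomp
from circfid.simulate import (
    GeometryError,
    PlacementError,
    SimulationConfig,
    TranscriptFeature,
    load_annotation,
    load_reference,
    make_reference,
    read_truth,
    simulate_reads,
    write_fastq,
    write_reference,
    write_truth,
    TruthRegistry,
    TruthEvent,
)

SMALL = dict(
    genome_length=8000,
    n_transcripts=6,
    transcript_len=400,
    mean_site_depth=30,
    het_site_count=0,
)


class TestConfigValidation:
    def test_spectrum_must_sum_to_one(self):
        from circfid.quantify import SUBSTITUTION_TYPES

        bad = {t: 0.1 for t in SUBSTITUTION_TYPES}
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, txn_spectrum=bad)

    def test_incompatible_geometry_rejected(self):
        with pytest.raises(GeometryError):
            SimulationConfig(
                seed=1, fragment_len_range=(90, 120), copies_per_read_range=(3, 5),
                read_length=250,
            )

    def test_transcripts_that_cannot_fit_raise(self):
        with pytest.raises(PlacementError):
            make_reference(
                SimulationConfig(seed=1, genome_length=2000, n_transcripts=10,
                                 transcript_len=700)
            )


class TestMakeReference:
    def test_features_within_bounds_and_disjoint(self):
        cfg = SimulationConfig(seed=2, **SMALL)
        genome, feats = make_reference(cfg)
        assert len(feats) == 6
        by_chrom = {}
        for f in feats:
            assert 0 <= f.start < f.end <= len(genome[f.chrom])
            by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_mitochondrial_class_on_own_sequence(self):
        cfg = SimulationConfig(seed=2, **SMALL)
        genome, feats = make_reference(cfg)
        mt = [f for f in feats if f.pol_class is PolymeraseClass.MTRNAP]
        assert mt and all(f.chrom == "chrM" for f in mt)
        assert all(
            f.chrom == "chr1" for f in feats if f.pol_class is not PolymeraseClass.MTRNAP
        )

    def test_no_transcripts_degenerate(self):
        cfg = SimulationConfig(seed=2, genome_length=4000, n_transcripts=0,
                               het_site_count=0)
        genome, feats = make_reference(cfg)
        assert feats == []
        assert len(genome["chr1"]) == 4000

    def test_reference_files_deterministic(self, tmp_path):
        for run in ("a", "b"):
            cfg = SimulationConfig(seed=33, **SMALL)
            genome, feats = make_reference(cfg)
            write_reference(genome, feats, tmp_path / f"{run}.fa", tmp_path / f"{run}.gff3")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_reference_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=4, **SMALL)
        genome, feats = make_reference(cfg)
        write_reference(genome, feats, tmp_path / "ref.fa", tmp_path / "ann.gff3")
        assert load_reference(tmp_path / "ref.fa") == genome
        loaded = load_annotation(tmp_path / "ann.gff3")
        assert [(f.chrom, f.start, f.end, f.strand, f.pol_class) for f in loaded] == [
            (f.chrom, f.start, f.end, f.strand, f.pol_class) for f in feats
        ]


class TestSimulateReads:
    def test_zero_noise_reads_are_exact_tandem_repeats(self):
        cfg = SimulationConfig(
            seed=5, txn_error_rate=0, rt_error_rate=0, seq_error_rate=0, **SMALL
        )
        genome, feats = make_reference(cfg)
        reads, truth = simulate_reads(cfg, genome, feats)
        assert len(truth) == 0
        assert reads
        haystacks = [
            strand for c in genome for strand in (genome[c], revcomp(genome[c]))
        ]
        pcfg = PipelineConfig()
        for read in reads[:50]:
            d = detect_period(read, pcfg)
            assert isinstance(d, RepeatDecomposition)
            p = d.period
            assert all(
                read.seq[i] == read.seq[i + p] for i in range(len(read.seq) - p)
            )
            # some rotation of the unit is a genomic substring on one strand
            doubled = read.seq[:p] * 2
            assert any(
                doubled[o : o + p] in hay for o in range(p) for hay in haystacks
            )

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        outputs = []
        for run in ("x", "y"):
            cfg = SimulationConfig(seed=9, **SMALL)
            genome, feats = make_reference(cfg)
            reads, truth = simulate_reads(cfg, genome, feats)
            fq = tmp_path / f"{run}.fastq"
            tsv = tmp_path / f"{run}.tsv"
            write_fastq(reads, fq)
            write_truth(truth, tsv)
            outputs.append((fq.read_bytes(), tsv.read_bytes()))
        assert outputs[0] == outputs[1]

    def test_transcription_errors_shared_by_all_copies(self):
        cfg = SimulationConfig(
            seed=6, txn_error_rate=1e-2, rt_error_rate=0, seq_error_rate=0, **SMALL
        )
        genome, feats = make_reference(cfg)
        reads, truth = simulate_reads(cfg, genome, feats)
        assert len(truth.of_origin("transcription")) > 0
        pcfg = PipelineConfig()
        # template-level errors preserve perfect periodicity
        for read in reads[:200]:
            d = detect_period(read, pcfg)
            if isinstance(d, RepeatDecomposition):
                assert d.identity == 1.0

    def test_single_copy_artifacts_break_periodicity_once(self):
        cfg = SimulationConfig(
            seed=7, txn_error_rate=0, rt_error_rate=2e-3, seq_error_rate=0, **SMALL
        )
        genome, feats = make_reference(cfg)
        reads, truth = simulate_reads(cfg, genome, feats)
        by_read = {}
        for ev in truth.of_origin("rt"):
            by_read.setdefault(ev.read_id, []).append(ev)
        assert by_read
        pcfg = PipelineConfig()
        checked = 0
        for read in reads:
            events = by_read.get(read.read_id, [])
            if len(events) != 1:
                continue
            d = detect_period(read, pcfg)
            if not isinstance(d, RepeatDecomposition):
                continue
            unit = build_consensus(read, d)
            # exactly one position disagrees with the majority consensus
            mismatches = sum(
                1
                for i, base in enumerate(read.seq)
                if unit.seq[i % d.period] != "N" and base != unit.seq[i % d.period]
            )
            assert mismatches == 1
            checked += 1
        assert checked >= 5

    def test_injected_error_count_poisson_consistent(self):
        rate = 1e-3
        cfg = SimulationConfig(
            seed=8,
            genome_length=8000,
            n_transcripts=6,
            transcript_len=400,
            mean_site_depth=100,
            het_site_count=0,
            txn_error_rate=rate,
            rt_error_rate=0,
            seq_error_rate=0,
        )
        genome, feats = make_reference(cfg)
        reads, truth = simulate_reads(cfg, genome, feats)
        # expected events: rate x total fragment bases; fragments average
        # (40+80)/2 = 60 nt over n_reads
        lam = rate * 60 * len(reads)
        observed = len(truth.of_origin("transcription"))
        assert abs(observed - lam) <= 4 * np.sqrt(lam)

    def test_minus_strand_fragments_reverse_complement_genome(self):
        genome = {"chr1": None}
        rng = np.random.default_rng(11)
        from conftest import random_seq

        genome["chr1"] = random_seq(rng, 2000)
        feature = TranscriptFeature(
            "t0", "chr1", 100, 1900, "-", PolymeraseClass.RNAPII
        )
        cfg = SimulationConfig(
            seed=12, txn_error_rate=0, rt_error_rate=0, seq_error_rate=0,
            het_site_count=0, n_reads=50,
        )
        reads, _ = simulate_reads(cfg, genome, [feature])
        rc = revcomp(genome["chr1"][100:1900])
        pcfg = PipelineConfig()
        for read in reads:
            d = detect_period(read, pcfg)
            assert isinstance(d, RepeatDecomposition)
            doubled = read.seq[: d.period] * 2
            # the fragment (some rotation of the unit) lies on the transcript
            assert any(
                doubled[o : o + d.period] in rc for o in range(d.period)
            )

    def test_het_sites_spaced_and_recorded_once(self):
        cfg = SimulationConfig(seed=13, genome_length=12000, n_transcripts=8,
                               transcript_len=700, mean_site_depth=20,
                               het_site_count=30)
        genome, feats = make_reference(cfg)
        _, truth = simulate_reads(cfg, genome, feats)
        het = truth.of_origin("het_site")
        assert len(het) == 30
        keys = {(e.chrom, e.site) for e in het}
        assert len(keys) == 30
        by_tx = {}
        for e in het:
            by_tx.setdefault(e.transcript_id, []).append(e.transcript_pos)
        for positions in by_tx.values():
            positions.sort()
            assert all(b - a >= 80 for a, b in zip(positions, positions[1:]))


class TestTruthRegistry:
    def test_round_trip(self, tmp_path):
        truth = TruthRegistry(
            [
                TruthEvent("t0", 5, "chr1", 105, "G", "A", "transcription", "r1"),
                TruthEvent("t1", 9, "chr1", 900, "C", "T", "rt", "r2", 1),
                TruthEvent("t0", 50, "chr1", 150, "A", "C", "het_site"),
            ]
        )
        path = tmp_path / "truth.tsv"
        write_truth(truth, path)
        assert read_truth(path) == truth

    def test_empty_registry_header_only(self, tmp_path):
        path = tmp_path / "truth.tsv"
        write_truth(TruthRegistry(), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert read_truth(path) == TruthRegistry()
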