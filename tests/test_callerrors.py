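import numpy as np
import pytest

from circfid.callerrors import (
    CandidateError,
    ClassLookup,
    SitePileup,
    SiteSummary,
    alignment_sites,
    call_errors,
    check_base,
    classify_error,
    summarize_sites,
)
from circfid.config import PipelineConfig, PolymeraseClass
from circfid.consensus import build_consensus, detect_period
from circfid.locate import BuiltinAligner, GenomicAlignment, locate_consensus
from circfid.pipeline import analyze_reads
from circfid.seqs import revcomp
from circfid.simulate import (
    SimulationConfig,
    TranscriptFeature,
    make_reference,
    simulate_reads,
)

from conftest import make_read, random_seq


def manual_alignment(
    period=60,
    chrom="chr1",
    start=100,
    strand="+",
    n_support=3,
    unanimous=True,
    quality_sum=102,
    mismatches=(),
    seq=None,
    ops=None,
):
    p = period
    return GenomicAlignment(
        consensus_id="c1",
        chrom=chrom,
        start=start,
        strand=strand,
        rotation_offset=0,
        aligned_ops=ops or [("match", p)],
        n_mismatches=len(mismatches),
        mapped=True,
        period=p,
        mismatch_positions=np.array(sorted(mismatches), dtype=np.int64),
        rotated_seq=seq or "A" * p,
        n_support=np.full(p, n_support, dtype=np.int32),
        unanimous=np.full(p, unanimous, dtype=bool),
        quality_sum=np.full(p, quality_sum, dtype=np.int64),
    )


class TestSiteSummary:
    def test_heterozygous_site_fails(self):
        # a call in 100 of 200 reads is a heterozygous mutation, not an error
        s = SiteSummary("chr1", 10, depth=200, alt_count=100)
        assert s.alt_fraction == 0.5
        assert not s.passes(PipelineConfig())

    def test_low_alt_fraction_passes(self):
        s = SiteSummary("chr1", 10, depth=250, alt_count=1)
        assert s.alt_fraction == pytest.approx(0.004)
        assert s.passes(PipelineConfig())

    def test_depth_threshold_is_inclusive_at_200(self):
        assert not SiteSummary("chr1", 1, 199, 0).passes(PipelineConfig())
        assert SiteSummary("chr1", 1, 200, 0).passes(PipelineConfig())

    def test_alt_fraction_threshold_is_strict(self):
        # exactly 1% is not below 1%
        assert not SiteSummary("chr1", 1, 200, 2).passes(PipelineConfig())
        assert SiteSummary("chr1", 1, 201, 2).passes(PipelineConfig())


class TestCheckBase:
    def setup_method(self):
        self.cfg = PipelineConfig(min_site_depth=20)
        self.good_site = SiteSummary("chr1", 0, depth=50, alt_count=0)

    def test_all_checks_pass(self):
        aln = manual_alignment(quality_sum=101)
        checks = check_base(aln, 10, self.good_site, self.cfg)
        assert all(checks)

    def test_quality_sum_exactly_100_fails(self):
        aln = manual_alignment(quality_sum=100)
        assert check_base(aln, 10, self.good_site, self.cfg)[2] is False
        aln = manual_alignment(quality_sum=101)
        assert check_base(aln, 10, self.good_site, self.cfg)[2] is True

    def test_edge_distance_strictly_greater_than_two(self):
        aln = manual_alignment(period=60)
        # distance 2 from the start fails, distance 3 passes
        assert check_base(aln, 2, self.good_site, self.cfg)[3] is False
        assert check_base(aln, 3, self.good_site, self.cfg)[3] is True
        # symmetric at the 3' end
        assert check_base(aln, 57, self.good_site, self.cfg)[3] is False
        assert check_base(aln, 56, self.good_site, self.cfg)[3] is True

    def test_support_below_min_repeats_fails(self):
        aln = manual_alignment(n_support=2)
        assert check_base(aln, 10, self.good_site, self.cfg)[0] is False

    def test_nonunanimous_fails(self):
        aln = manual_alignment(unanimous=False)
        assert check_base(aln, 10, self.good_site, self.cfg)[1] is False


class TestPileup:
    def test_depth_and_alt_tally(self):
        pileup = SitePileup({"chr1": 300})
        pileup.add(manual_alignment(period=60, start=100, mismatches=(5,)))
        pileup.add(manual_alignment(period=60, start=130))
        assert pileup.summary("chr1", 105).depth == 1
        assert pileup.summary("chr1", 105).alt_count == 1
        assert pileup.summary("chr1", 140).depth == 2
        assert pileup.summary("chr1", 95).depth == 0

    def test_minus_strand_sites_reversed(self):
        aln = manual_alignment(period=60, start=100, strand="-", mismatches=(0,))
        sites = alignment_sites(aln)
        assert sites[0] == 159  # unit position 0 is the transcript 5' end
        assert sites[-1] == 100


class TestClassification:
    def test_class_lookup_and_conflicts(self):
        lookup = ClassLookup(
            {"chr1": 1000, "chrM": 200},
            [
                ("chr1", 100, 400, "+", PolymeraseClass.RNAPII),
                ("chr1", 350, 600, "-", PolymeraseClass.RNAPI),  # overlap
                ("chrM", 0, 200, "+", PolymeraseClass.MTRNAP),
            ],
        )
        assert lookup.class_of("chr1", 200) is PolymeraseClass.RNAPII
        assert lookup.class_of("chr1", 500) is PolymeraseClass.RNAPI
        assert lookup.class_of("chr1", 375) is PolymeraseClass.UNASSIGNED
        assert lookup.class_of("chr1", 700) is PolymeraseClass.UNASSIGNED
        assert lookup.class_of("chrM", 50) is PolymeraseClass.MTRNAP

    def test_classify_error_uses_site(self):
        lookup = ClassLookup(
            {"chr1": 1000}, [("chr1", 0, 500, "+", PolymeraseClass.RNAPII)]
        )
        err = CandidateError(
            "c1", "chr1", 30, "G", "A", "substitution",
            True, True, True, True, True,
        )
        assert classify_error(err, lookup) is PolymeraseClass.RNAPII


class TestMinusStrandOrientation:
    def test_genomic_c_to_t_reported_as_g_to_a(self, cfg, rng):
        """A genomic C>T call under a minus-strand transcript is a
        transcript-orientation G>A error."""
        genome = {"chr1": random_seq(rng, 1000)}
        # pick a site whose forward base is C
        site = genome["chr1"].index("C", 450)
        feature = TranscriptFeature(
            "t0", "chr1", 400, 520, "-", PolymeraseClass.RNAPII
        )
        # transcript-sense fragment around the site, carrying A where the
        # transcript template has G (genomic C)
        frag_start, frag_len = site - 30, 61
        fragment = list(revcomp(genome["chr1"][frag_start : frag_start + frag_len]))
        unit_pos = frag_start + frag_len - 1 - site  # transcript orientation
        assert fragment[unit_pos] == "G"
        clean = "".join(fragment[:unit_pos] + ["G"] + fragment[unit_pos + 1 :])
        fragment[unit_pos] = "A"
        # one erroneous molecule among 120 clean ones keeps the site below
        # the 1% alternate-fraction ceiling
        reads = [make_read(clean, 3, read_id=f"r{i}") for i in range(120)]
        reads.append(make_read("".join(fragment), 3, read_id="r_err"))
        pcfg = PipelineConfig(min_site_depth=5)
        result = analyze_reads(reads, genome, [feature], pcfg)
        confirmed = result.confirmed_errors
        assert confirmed, "expected the shared substitution to be confirmed"
        err = confirmed[0]
        assert (err.site, err.ref_base, err.alt_base) == (site, "G", "A")
        assert err.pol_class is PolymeraseClass.RNAPII


class TestCallErrors:
    def _small_run(self, **sim_overrides):
        params = dict(
            seed=5,
            genome_length=8000,
            n_transcripts=6,
            transcript_len=400,
            mean_site_depth=60,
            het_site_count=0,
        )
        params.update(sim_overrides)
        sim = SimulationConfig(**params)
        genome, feats = make_reference(sim)
        reads, truth = simulate_reads(sim, genome, feats)
        cfg = PipelineConfig(min_site_depth=10)
        return analyze_reads(reads, genome, feats, cfg), truth, cfg

    def test_zero_noise_null_model(self):
        result, truth, _ = self._small_run(
            txn_error_rate=0.0, rt_error_rate=0.0, seq_error_rate=0.0
        )
        assert len(truth) == 0
        assert result.ledger.n_errors == 0
        assert result.ledger.n_bases > 0
        assert result.ledger.rate() == 0.0

    def test_rt_only_artifacts_fail_unanimity(self):
        result, truth, _ = self._small_run(
            txn_error_rate=0.0, rt_error_rate=1e-3, seq_error_rate=0.0
        )
        assert len(truth.of_origin("rt")) > 0
        assert result.ledger.n_errors == 0

    def test_numerator_subset_of_denominator(self):
        # depth high enough that a lone erroneous read stays under the 1%
        # site ceiling
        result, _, _ = self._small_run(txn_error_rate=1e-3, mean_site_depth=150)
        assert result.ledger.n_errors > 0
        for tally in result.ledger.classes.values():
            assert 0 <= tally.n_errors <= tally.n_bases or tally.n_bases == 0
            assert tally.den_by_ref.sum() == tally.n_bases

    def test_denominator_monotone_under_relaxation(self):
        sim = SimulationConfig(
            seed=5, genome_length=8000, n_transcripts=6, transcript_len=400,
            mean_site_depth=60, het_site_count=0,
        )
        genome, feats = make_reference(sim)
        reads, _ = simulate_reads(sim, genome, feats)
        strict = analyze_reads(
            reads, genome, feats, PipelineConfig(min_site_depth=30)
        )
        relaxed_cfgs = [
            PipelineConfig(min_site_depth=10),
            PipelineConfig(min_site_depth=30, min_quality_sum=50),
            PipelineConfig(min_site_depth=30, edge_margin=1),
        ]
        for cfg in relaxed_cfgs:
            relaxed = analyze_reads(reads, genome, feats, cfg)
            assert relaxed.ledger.n_bases >= strict.ledger.n_bases

    def test_indel_op_recorded_with_transplanted_checks(self):
        genome = {"chr1": random_seq(np.random.default_rng(0), 300)}
        lookup = ClassLookup(
            {"chr1": 300}, [("chr1", 0, 300, "+", PolymeraseClass.RNAPII)]
        )
        aln = manual_alignment(
            period=60,
            start=100,
            seq=genome["chr1"][100:160],
            ops=[("match", 30), ("deletion", 1), ("match", 30)],
        )
        pileup = SitePileup({"chr1": 300})
        for _ in range(25):
            pileup.add(manual_alignment(period=60, start=100, seq=genome["chr1"][100:160]))
        cfg = PipelineConfig(min_site_depth=10)
        errors, ledger = call_errors([aln], pileup, lookup, genome, cfg)
        indels = [e for e in errors if e.kind == "deletion"]
        assert len(indels) == 1
        assert ledger.classes[PolymeraseClass.RNAPII].n_deletions == 1
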