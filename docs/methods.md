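# Methods

## The measurement problem

A transcription error is a base in an RNA molecule that differs from the
DNA it was transcribed from. Measuring the error rate of RNA polymerases in
vivo (~1e-6 to 1e-5 per bp) by sequencing is confounded by reverse
transcription and sequencing, which introduce artifacts at rates one to two
orders of magnitude higher. Circle-sequencing resolves this with library
structure: RNA fragments (tens of nt) are circularised before reverse
transcription, and rolling-circle RT produces a linear cDNA consisting of
tandem copies of the same fragment. A true transcription error was present
in the template molecule and therefore recurs in **every** copy within a
read; an RT or sequencing artifact strikes **one** copy. Requiring unanimity
across copies suppresses artifacts multiplicatively: three independent
artifacts would have to hit the same fragment position with the same
erroneous base.

## Pipeline

1. **Repeat detection** (`consensus.detect_period`). For each read, the
   lag-p self-identity — the fraction of positions i with read[i] ==
   read[i+p] — is computed for every candidate period p up to half the read
   length. The maximising p wins, ties toward the smallest p. Scanning from
   p = 1 lets a read whose true repeat unit is shorter than the 30 nt
   minimum be recognised and rejected (`period_below_min`) rather than
   re-described by a multiple of its fundamental period; for the same
   reason, when the raw argmax is a multiple of a period that also clears
   the identity threshold, the smallest such divisor is taken (single-copy
   artifacts are double-counted by the lag comparison at the true period
   and can otherwise nudge the argmax to 2p). Reads whose best identity
   falls below 90% are rejected; indels inside a read break periodicity and
   are rejected here rather than realigned.

2. **Consensus building** (`consensus.build_consensus`). Copy k contributes
   read[j + k·p] to unit position j, including the trailing partial copy.
   Per position the module records the majority base (ties → N), the number
   of contributing non-N calls (`n_support`), whether all non-N calls agree
   (`unanimous`), and the arithmetic sum of contributing Phred scores
   (`quality_sum`; N contributes zero). Raw Phred integers are summed — the
   threshold of >100 corresponds to e.g. three copies at Q34.

3. **5' end search and placement** (`locate`). The RT reaction is randomly
   primed, so the consensus is a circular rotation of the original
   fragment. The doubled consensus (sequence concatenated with itself) is
   placed on every seed-compatible diagonal of the reference; for each
   rotation the score is the number of reference-matching positions in its
   length-period window, i.e. how completely that rotation maps end to end.
   Ties are broken by the longest continuous exactly-mapping stretch, then
   the smallest offset. Seeding is exact 20-mers on both strands;
   half-overlapping seeds for linear queries and stride-1 seed starts over
   one period for the doubled sequence, because a usable seed must dodge
   both the copy junction and any template error. The rotated consensus is
   then mapped end to end to the best Hamming placement; two distinct
   placements tying at the minimum make the consensus `ambiguous` and it is
   dropped (a multi-mapper would corrupt site depths). Any alignment still
   carrying ≥1 mismatch is re-evaluated at **every** rotation
   (`refine_mismatch_alignment`); a rotation with strictly fewer mismatches
   replaces it, so a mis-located 5' end can never manufacture an error.
   Alignments whose residual mismatch count exceeds what the 90% identity
   threshold could produce are discarded as spurious hits.

4. **The five checks and the site filter** (`callerrors`). A consensus base
   is surveyed iff it (1) is supported by ≥3 repeat copies, (2) is called
   unanimously, (3) has summed quality strictly >100, (4) sits strictly
   more than 2 nt from both ends of the rotated consensus, and (5) lies at
   a genomic site covered by ≥200 consensus reads (configurable; the desk
   simulations relax this floor to 20) of which strictly fewer than 1%
   call a non-reference base. Check 5 removes heterozygous/polymorphic
   sites and RNA-editing positions, which recur across molecules; a variant
   in 100 of 200 reads is a heterozygous site, not an error. Surveyed bases
   form the denominator; surveyed bases whose call differs from the
   reference are confirmed errors, so numerator ⊆ denominator by
   construction. Calls are reported in transcript orientation (genomic
   bases complemented under minus-strand features). Indels present in the
   alignment ops are ledgered separately, with the substitution checks
   transplanted to their flanking positions; the builtin mapper itself is
   substitution-only, so indel records arise from externally supplied
   alignments.

5. **Quantification** (`quantify`). The error rate is confirmed errors
   divided by surveyed bases, per polymerase class (RNAPI/II/III, mtRNAP,
   assigned from the annotation; conflicting overlaps → unassigned).
   Cross-replicate summaries are the unweighted mean of per-replicate rates
   with the standard error of that mean — replicates are biologically
   independent libraries, not shards of one pool. The substitution spectrum
   resolves the 12 directed changes in RNA notation, each normalised by its
   own opportunity (surveyed bases whose reference is the source base), so
   types are comparable regardless of base composition. Group comparisons
   are unpaired two-tailed Welch's t-tests (Welch–Satterthwaite df); raw p
   values are reported, with Benjamini–Hochberg available behind a flag and
   off by default.

6. **Genetic-code impact** (`codonimpact`). For each of the 12 types, every
   codon-position pair holding the source base (48 per type; 576 in total)
   is substituted and classified: synonymous (amino acid unchanged;
   stop→stop included), non-synonymous otherwise, with stop-gained tracked
   as a subclass. Codons are weighted equally — the table describes the
   potential the code offers, not usage. Under the standard code all 16
   NNC→NNU wobble changes are synonymous and 14 of 16 NNG→NNA are (AUG and
   UGG excepted), which is why C>U and G>A attain the highest
   synonymous:non-synonymous ratios; note each transition ties with its
   reverse (C>U = U>C = 18/30, G>A = A>G = 15/33), so "highest" refers to
   distinct ratio values. Measured spectra are related to the ratios by
   Spearman rank correlation — the claim is monotone, not linear.

## The synthetic library

`simulate` generates the study conditions: a random genome (a nuclear
sequence plus a `chrM` carrying the mtRNAP transcripts), non-overlapping
stranded transcript features with a polymerase-class attribute, and
rolling-circle reads. Defaults, with reasons:

| parameter | default | why |
|---|---|---|
| fragment length | 40–80 nt | ≥3 copies of any fragment fit a 250 nt read, the structural requirement of check 1 |
| copies per read | 3–6 | rolling-circle yield at these fragment sizes |
| read length | 250 nt | matches the sequencing format the assay uses |
| transcription error rate | 1e-4/bp | high enough to measure with ~2e6 surveyed bases, low enough that sites rarely see two independent errors |
| spectrum | G>A 0.5, C>U 0.3, others 0.02 | the G>A/C>U-dominant signature of polymerase errors |
| RT errors | 1e-4 per copied base | injected per copy, never shared |
| sequencing errors | 1e-3 per base | injected per read base; error bases draw low qualities (Q12–16) while clean bases draw Q34–38, so three clean copies sum to >100 and any error-bearing copy also fails the quality-sum check |
| heterozygous sites | 50, alt fraction 0.5 | exercises the site filter; sites are spaced ≥ one maximal fragment length apart because natural heterozygosity is kilobases apart, and two variants inside one fragment create rotation ambiguities real data does not |
| mean site depth | 250 reads | the <1% filter must tolerate two non-reference reads at a site (2/250 = 0.8%), the regime the ≥200-read floor creates on real libraries; at shallower depth a sporadic second error at a site erases both |

Every injected event is recorded once in a truth registry (TSV-serialisable)
with its origin, so recovery and suppression are asserted against ground
truth rather than against the pipeline itself.

What the generator does **not** emulate: splicing, expression-level
variation beyond transcript length weighting, PCR duplicates, adapter
read-through, quality-by-cycle decay, RNA secondary-structure effects on
fragmentation, and paired-end mechanics (reads are single-end; a merged or
R1-only mode covers paired input at the interface level). Passing tests
therefore demonstrate the *logic* of artifact suppression and rate
recovery, not performance on any real library.

## Numerical and degenerate-input choices

- Majority ties in the consensus become N and break unanimity; N never
  counts toward support or quality and breaks unanimity only when a non-N
  disagreement also exists.
- Period-identity comparisons are exact integer match counts; identity ties
  resolve to the smallest period.
- A fragment whose flanking genomic base equals its opposite terminal base
  admits a ±1-shifted window that explains a clean read exactly as well;
  the posterior over the tied windows is uniform and the choice falls to
  the deterministic tie-break. Consequence: ~20% of placements jitter by
  one base, which smears per-site depth slightly and dilutes measured
  heterozygous alt fractions a few percent below the molecular 0.5. Near a
  heterozygous site this ambiguity leaves a false-positive floor on the
  order of 1e-6/bp — three orders of magnitude under the assay-scale
  signal, but visible in desk runs with error rates set to zero and het
  sites present.
- Desk-scale runs relax only `min_site_depth` (200 → 20); every other
  threshold is the published value. Problem sizes used by the tests and the
  acceptance script — ~30k reads / ~1.9M surveyed bases for recovery, five
  ~5k-read libraries for artifact immunity — were chosen so each
  simulation completes in about a minute on one core.
- Welch's t is computed from the closed form with scipy's t distribution;
  groups with both variances zero return p = 1 (equal means) or a
  degenerate flag (unequal). Single-replicate groups are refused.
- Mapping-quality floor 20 applies only to externally supplied SAM; the
  builtin mapper expresses ambiguity structurally (tied placements →
  dropped).

## Known limitations

- The builtin mapper is exact-seeded, unspliced and substitution-only: it
  is an instrument for compact synthetic references and tests. Real
  transcriptomes need the SAM adapter with a splice-aware aligner.
- Rotation refinement minimises mismatches; it cannot distinguish two
  placements that the read itself cannot distinguish (see the jitter note
  above).
- Indel error calling transplants the substitution checks to indel flanks;
  no indel-specific thresholds exist, and the simulator does not inject
  indels, so the indel path is exercised only by constructed fixtures.
- Error rates near or above ~1e-3/bp at modest depth collide with the <1%
  site filter (two real errors at one site veto each other); the assay
  regime of ≤1e-4 with depth ≥200 is where the estimator is unbiased.
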