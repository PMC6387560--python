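# Methods

This note documents the model implemented by `vihmm`, the choices made where
the design was genuinely open, and what the packaged tests do and do not
demonstrate.

## State space and transitions

Each alignment column pairs a reference symbol R ∈ {A,C,G,T,−} with an
unordered diploid genotype over the same alphabet.  The 15 genotypes are
enumerated in the fixed canonical order AA, AC, AG, AT, A−, CC, CG, CT, C−,
GG, GT, G−, TT, T−, −− (states s1–s15 at base columns, s16–s30 at insertion
columns).  Class labels are derived, not stored: at a base column, {R,R} is
Match, −− and the four single-"−" genotypes are Del, everything else is SNP;
at an insertion column, −− is the no-insertion state and the rest are Ins.
Two labeling conventions exist for the single-"−" genotypes (e.g. A− at
R=A): biologically they are heterozygous deletions and that is the default;
`--strict-classes` labels them SNP instead, which only changes how
class-level transition mass is routed, since variant records are always
built from the genotype content.

Transitions are supplied either as a full 30×30 row-stochastic matrix (TSV)
or, by default, expanded from a 4×4 class matrix.  The expansion puts the
class-level mass P(c′ | c) uniformly on the destination class's member
states at the destination column; the no-insertion state rides on the Match
row (it is the "nothing happened" outcome at an insertion column).  At
decode time each row is masked to the 15 states admissible at the next
column and renormalized, i.e. the chain is conditioned on the known column
type.  Mass into classes with no member at that column (Ins at a base
column, SNP/Del at an insertion column) is conditioned away by the
renormalization; the unnormalized split is exposed separately
(`dest_weights(..., renormalize=False)`) because the two dbSNP anchor
frequencies refer to it.

The packaged default class matrix is a reconstruction — the original
matrix is not printed anywhere reproducible — built from the two quotable
dbSNP-derived entries and Match-heavy remainders:

|        | Match   | SNP     | Del     | Ins     |
|--------|---------|---------|---------|---------|
| Match  | 0.99900 | 0.00070 | 0.00015 | 0.00015 |
| SNP    | 0.94990 | 0.04000 | 0.00500 | 0.00510 |
| Del    | 0.50000 | 0.00500 | 0.49000 | 0.00500 |
| Ins    | 0.28800 | 0.00700 | 0.00500 | 0.70000 |

This yields about one variant event per kilobase, mean deletion run ≈ 2 bp
and mean insertion run ≈ 3.3 bp.  Any 4×4 or 30×30 matrix can be substituted
via `--tm`.

The initial distribution is a free choice of this implementation; the default is
the masked, renormalized Match row for the first column's reference symbol
(genomes overwhelmingly start in Match).  Viterbi ties are broken toward
the lowest canonical state index for determinism.  All decoding is in
natural-log space with −∞ for structural zeros.

## Emissions

The pileup likelihood is the product over reads of the half/half two-allele
mixture; the allele term has two forms.  The *printed* form (e on mismatch,
1 − e/4 on match) sums to 1 + 15e/4 over the five symbols, i.e. it is not a
distribution; whether the original implementation normalized it is not
determinable.  Both are provided; the default is the *normalized* form
(1 − e on match, e/4 on mismatch), which is the defensible likelihood.  The
Viterbi ranking can differ between them at high error rates.  "−" is a
fifth emission symbol under the same error model, so deletion evidence and
spanning-read evidence against an insertion enter the product like base
mismatches.  Likelihoods are written as P(D|Z) throughout (the alternative
notation L(Z|D) denotes the same quantity).

Missing qualities ("−" observations) take the arithmetic mean of the
column's observed Phred scores; a column with no observed quality at all
uses a fallback of Q20 (the imputation rule is otherwise undefined there).
Columns with pileup depth < 5 (configurable `--min-depth`) contribute
log 1 = 0 for every admissible state rather than being skipped — this keeps
the chain connected so the path is defined everywhere — and any variant
decoded at such a column is suppressed as a no-call.  Reference N columns
are likewise no-call.  Error rates are clipped below at 1e−30 so the
three-term log decomposition used by the vectorised emission table never
forms ∞ − ∞; qualities produced by the caller itself are capped at Q60 so
the clip is never active in practice.

Duplicate reads and mapping quality are not filtered by default (`--min-mapq`
exists, default 0), matching the described input handling.

## Gapped columns and pileups

Insertion columns are hypothesised from the reads: a gap block exists at a
junction iff at least one read's CIGAR carries an I operation there, with
block length the maximum insertion length among those reads.  Reads with a
shorter insertion are padded with "−" (missing quality), and reads that
span the junction without any insertion contribute "−" at every block
column — without this the no-insertion state could never accumulate
evidence.  How competing insertion lengths should be reconciled is not
specified anywhere; max-over-reads is this package's choice.  No local
realignment, base-quality recalibration or indel left-shifting is
performed at the pileup level.

## Variant records

SNP states emit single-base records (adjacent SNPs are not merged into
MNPs, matching the locus-wise evaluation).  Maximal runs of consecutive
Del-class columns merge into one deletion anchored one reference base to
the left (anchored right at the contig start); insertion runs merge into
one record at their junction.  Runs mixing heterozygous and homozygous
states split at the zygosity change so every record has a single GT.  A
heterozygous deletion whose retained allele differs from the reference, or
a heterozygous insertion with two distinct inserted sequences, produces a
two-ALT record with GT 1/2.  The whole-path log probability is written as
the `PLP` INFO tag; the model defines no per-site quality, so QUAL is ".".

## Simulator

The generator reproduces the study conditions used to benchmark the caller:

* reference: i.i.d. uniform bases, default 50,000 bp;
* haplotype 1: the 4-class Markov chain above along the reference, with
  SNP columns substituting one of the three non-reference bases uniformly
  ([1/3,1/3,1/3]), insertion columns emitting uniform bases
  ([1/4,1/4,1/4,1/4]), deletion columns emitting "−";
* haplotype 2: each variant event of haplotype 1 independently reverted to
  the reference with the heterozygous rate (default 0.5 — the original
  value is unstated);
* reads: N = round(depth × L / read_length) reads of 100 bp, exactly half
  (±1) per haplotype, per-base error drawn uniformly from [0.001, 0.01]
  (Phred ≈ 20–30; the original states only "a uniform distribution"), the
  base flipped to a uniform alternative with that probability, and the
  quality written as round(−10 log10 e).

Read start positions are drawn uniformly over the interval extended by one
read length to the left, with reads truncated at the segment ends.  This
makes expected coverage uniform across the entire segment — the segment
behaves like a window on a longer genome — at the cost of slightly
shortened edge reads (read lengths are 100 bp *on average*).  The exact
chain is simulated with geometric jumps across Match stretches, which is
fast and distributionally identical to stepping column by column.  INDEL
truth lengths follow the run lengths of the class chain; no separate length
distribution is imposed.  Events after the last reference base that the
chain never returns from are dropped.

Outputs are FASTA, FASTQ, true-placement SAM (leading/trailing inserted
bases become soft clips, since an alignment cannot start or end with I),
truth VCF and a per-column state-track TSV.

What the simulator does *not* emulate: read-mapping error (reads carry
their true placement), paired ends and insert sizes, quality-by-cycle
profiles, context-dependent or homopolymer errors, duplicate reads.
Benchmarks on this generator therefore measure the decoding model in
isolation; figures obtained through a real aligner are lower bounds for
these conditions, and the packaged acceptance checks treat them as such.

## Evaluation

Matching is locus-exact within class (SNP vs INDEL), on the anchored VCF
POS, without genotype agreement (a strict mode exists).  Records are split
into bi-allelic primitives and trimmed (shared suffix, then shared prefix)
before matching, so externally produced VCFs compare on the same
representation; truth and calls produced by this package share one
anchoring convention, so no representation mismatch can occur internally.
INDEL stratification uses bins 1–6 and >6 on |len(REF) − len(ALT)|, with
calls matching only inside their truth record's bin.  Degenerate 0/0 ratios
are reported as 0 and flagged.  Replicate summaries are arithmetic means
with standard errors.

## Problem sizes used by the packaged checks

The test suite decodes full 50 kb replicates where the property under test
needs them (zero-error recovery at 20×: 20 replicates; the 15× accuracy
bounds: 100 replicates) and smaller 2–20 kb fixtures elsewhere.  The
acceptance script runs 100 replicates at each depth in {15, 20, 25, 30}.
The Viterbi implementation is verified exactly against brute-force
enumeration of all admissible state sequences on 200 random instances with
L ≤ 6, and the blocked production decoder is verified against the generic
30-state implementation on random instances.

## Known limitations

* The packaged transition matrix is a principled reconstruction, not the
  original; results depend quantitatively (not qualitatively) on it.
* Single-sample, diploid, single-contig regions; no gVCF, phasing, somatic
  mode or CRAM.
* No posterior per-site scores (Viterbi gives a single path, not
  marginals); forward–backward decoding is out of scope.
* Locus-exact INDEL matching is representation-sensitive for external
  callers despite the shared normalization pass; haplotype-aware comparison
  is out of scope.
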