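# Methods

## The dual genome scan

The pipeline compares a mixed-sex genome assembly against each sex's
short reads at the level of canonical k-mers (the lexicographically
smaller of a k-base word and its reverse complement, encoded in 2 bits
per base; k ≤ 31 so a code fits a 62-bit integer). Canonicalization is
essential: shotgun reads come from both strands, so strand-specific
matching would spuriously inflate unmatched fractions by ~50%.

1. **Assembly index.** Scaffolds shorter than `min_scaffold_len`
   (default 200 bp) and any scaffolds on an exclusion list (e.g.
   externally identified contaminants) are dropped. The distinct
   canonical k-mers of the remaining scaffolds are partitioned into
   *single-copy* (exactly one occurrence, counted per window over the
   whole retained assembly) and *repetitive* (more than one). Counting
   per window means within-scaffold duplicates and reverse-complement
   self-pairs are repetitive — exactly the multi-mapping sequence the
   filter is meant to remove. Windows containing non-ACGT characters
   are skipped individually; an N-gap invalidates only the windows that
   overlap it, not the scaffold, since draft assemblies are full of gap
   runs and discarding whole scaffolds would lose signal.
2. **Read k-mer sets.** Each sex's reads (FASTA/FASTQ, gzip
   autodetected, multiple files concatenated; pairing and qualities
   ignored — reads are assumed adapter/quality-trimmed upstream) are
   decomposed the same way. A k-mer is *present* in a sex if its total
   multiplicity is at least `min_read_count` (default 2): at ~20×
   coverage a true genomic k-mer is expected in far more than two
   reads, while most k-mers created by sequencing errors are
   singletons. At substantially lower coverage this threshold should be
   lowered to 1.
3. **Per-scaffold statistics.** For each retained scaffold, over its
   *distinct* canonical k-mers: `pct_absent_both` is the percentage
   absent from the union of the two read sets; `pct_unmatched_female`
   and `pct_unmatched_male` are the percentages of its *single-copy*
   k-mers absent from the female and male sets respectively. Distinct
   sets (rather than positional window counts) are used because a
   single-copy k-mer occurs once genome-wide anyway, and set semantics
   make the brute-force oracle unambiguous. Scaffolds whose k-mers are
   all repetitive have no defined unmatched statistic; they are
   reported with literal `NA` rather than silently dropped, because
   repeat-dominated scaffolds are exactly the ones prone to spurious
   signals and worth inspecting.
4. **QC.** A scaffold fails QC iff `pct_absent_both` strictly exceeds
   `low_quality_max_pct` (default 10): k-mers supported by neither
   sex's reads are attributed to assembly error, since a real k-mer of
   either sex would appear in that sex's reads. Whether the 10% rule
   should be evaluated on all k-mers or single-copy ones only is
   genuinely open; this implementation uses all distinct k-mers of the
   scaffold. QC-failed scaffolds are excluded from histograms and can
   never be candidates.
5. **Classification.** A QC-passing scaffold is an XY-side candidate
   (suspect Y-linked) iff `pct_unmatched_female` strictly exceeds
   `candidate_min_unmatched_pct` (default 70), and symmetrically a
   ZW-side candidate on `pct_unmatched_male`. Both thresholds are
   strict "more than" comparisons, so boundary values 10.0 and 70.0 are
   non-failing and non-candidate respectively.

Both scans share one assembly index and one pass over the scaffolds;
this is mathematically identical to running the scan twice with the two
read sets and halves the work. The scan path contains no randomness:
identical inputs give byte-identical output tables.

## The verdict rule

The classical readout judges bimodality visually. Here the call is an
explicit dominance rule over the two candidate summaries (count of
candidate scaffolds, summed bp). A side wins iff it has at least
`min_candidates` (default 20) scaffolds and `min_bp` (default 50,000)
bp, **and** at least `bp_ratio` (default 5) times the other side's bp
**and** `count_ratio` (default 3) times its count; anything else is
inconclusive. The margins are chosen so that a genuine sex-limited
chromosome (in the motivating dataset: ~1.2 Mb over 1539 scaffolds,
i.e. 7.5× / 6.9× the opposite tail) calls comfortably, while
repeat-artifact tails of a few hundred kb — misassembled transposable
elements showing high unmatched fractions on the wrong side — cannot
flip a call. A formal unimodality test (e.g. the dip statistic) was
deliberately not used: the near-0 and near-100 peaks are not always
centred at 0 and 100%, and candidate-mass dominance is robust to that.
For very small genomes the absolute minima should be revisited; all
four knobs are CLI flags.

The rule is antisymmetric (swapping summaries maps XY ↔ ZW) and can
never return both sides, since the ratio conditions cannot hold in both
directions for non-empty sides and empty sides fail the minima.

## The simulator

`SimSpec` defaults describe the study regime the scan targets: two
autosomes (800 kb + 600 kb), a 400 kb shared X (or Z), and a 200 kb
sex-limited Y (or W), sequenced to 20× per sex with 100 bp single-end
reads and a 0.5% per-base substitution rate. The sex-limited chromosome
is 80% fresh random sequence (`y_unique_fraction`) interleaved with
monomer copies of 5 repeat families (2 kb units) that are also planted
on the autosomes — modelling transposon sharing between the Y/W and the
rest of the genome. The "assembly" is the heterogametic individual's
chromosomes cut into `scaffold_length` fragments; the default is
5,000 bp because short-read draft assemblies of insect genomes are at
least that fragmented (contig N50s well under 2 kb are typical), and a
200 kb sex-limited chromosome then yields enough scaffolds (40) for the
default verdict minima to be meaningful. Reads are drawn uniformly over
valid start positions and strands (`round(depth · genome_bp /
read_length)` reads per sex), with substitutions to a uniformly chosen
different base. All randomness flows from a single integer seed; reads
for the two sexes use seeds derived from it (seed+1, seed+2), and gzip
output pins the header timestamp so repeated runs are byte-identical.

**What the simulator does not emulate:** the assembly process itself
(collapsed gametologs are assumed, not produced by an assembler),
X/Y sequence divergence (the sex-limited chromosome is fully
sex-specific rather than a diverged homolog), paired-end insert
structure, GC skew and other base-composition biases, contamination,
and coverage heterogeneity (in a real male, X and Y are at half the
autosomal depth; reads here are uniform over the chromosome set — at
20× and `min_read_count` 2 this distinction has no practical effect on
presence calls). Passing the recovery tests therefore demonstrates the
correctness of the scan logic and the verdict rule under the stated
generative model, not robustness to assembler artifacts, which is what
the QC filter and the repeat_fraction column are for on real data.

`evaluate_recovery` scores sensitivity over sex-limited scaffolds with
at least 50% unique-derived bases (repeat-dominated fragments may
legitimately have too few single-copy k-mers to classify), the
false-positive rate over autosome/X (or Z) scaffolds, and verdict
correctness. Scaffolds dropped by the length filter are not scored.

## Numerical and format choices

- Percentages are computed in double precision and written to the TSV
  with 2 decimal places; `ygs call` re-thresholds from the stored
  values, so a value within 0.005 of a strict threshold could in
  principle classify differently after a round-trip. This has not been
  observed; comparisons inside one run always use full precision.
- Histograms use left-closed right-open bins over [0, 100] with the
  last bin closed, so 100% is counted; the bin width must divide 100.
- k-mer sets are sorted `uint64` arrays with binary-search membership;
  building is streaming over ~32 Mb base blocks, so memory scales with
  the number of distinct k-mers, not the read count.
- The scan holds one scaffold's sequence at a time but parses the
  assembly twice (index build, then per-scaffold scan); assemblies are
  read from disk both times, so memory stays bounded for large genomes.
- Exit codes: 0 success, 2 input error (file missing/malformed), 3
  configuration error (parameter outside its invariants).

## Problem sizes used in validation

The test suite and the acceptance script validate against (a) exact
agreement with a naive string-multiset implementation on randomized
assemblies of ≤ ~1.5 kb with up to a few hundred reads at k ∈ {3, 5,
16}; (b) hand-enumerated two-scaffold fixtures; and (c) full
default-scale simulations (2 Mb genome, 20× per sex, both XY and ZW,
plus a label-swap control). The default-scale runs complete in about a
minute each; the whole suite runs in a few minutes.

## Known limitations

- Sensitivity of the verdict rule to `min_candidates`/`min_bp` on very
  small or extremely contiguous genomes (few but large sex-limited
  scaffolds): lower the minima or judge the histograms directly.
- The scan cannot distinguish a sex-limited chromosome from any other
  sequence present in only one sex's DNA (e.g. a strictly sex-limited
  endosymbiont); the exclusion list exists so externally identified
  contaminants can be removed before scanning.
- Heavily repeat-dominated sex-limited scaffolds yield NA statistics
  and are invisible to the candidate counts; the reported totals are
  therefore conservative under-estimates of sex-limited content.
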