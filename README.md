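# ygscan

K-mer genome scans for identifying sex-limited (Y- or W-linked) scaffolds
and calling the sex-chromosome system (XY vs ZW) of a species from
separate male and female whole-genome short-read data.

## The problem

In many animals the heterogametic sex cannot be identified from
karyotypes because the sex chromosomes are homomorphic, and classical
genetic approaches need crosses or live material. A purely computational
alternative needs only a mixed-sex draft assembly and one short-read
library per sex: sequence that exists **only** in the heterogametic sex
(the Y in XY males, the W in ZW females) will assemble, but its k-mers
will be absent from the homogametic sex's reads.

For each scaffold *i* the scan computes the *valid single-copy unmatched
percentage*

&nbsp;&nbsp;&nbsp;&nbsp;U_i(S) = 100 · |K_i^sc \ R_S| / |K_i^sc|

where K_i^sc is the set of the scaffold's distinct canonical k-mers that
occur exactly once in the whole assembly (repetitive k-mers are excluded
so transposons shared between, say, Y and autosomes cannot create false
sharing), and R_S is the set of canonical k-mers present at multiplicity
≥ 2 in the reads of sex *S*. Run against **female** reads (the "XY-GS"
scan) the distribution of U_i is bimodal in an XY system: autosome and X
scaffolds sit near 0%, Y scaffolds near 100%. Run against **male** reads
(the "ZW-GS" scan) the same genome is unimodal near 0. A ZW system
produces the inverse pattern, so performing both scans on the same
assembly reveals the system. Scaffolds with more than 10% of their
k-mers absent from *both* sexes' reads are treated as low-quality
(assembly artifacts) and removed; QC-passing scaffolds with more than
70% unmatched k-mers on one side are the candidate sex-limited
scaffolds. An explicit dominance rule (minimum candidate count and bp,
plus bp- and count-ratio margins) turns the two candidate tails into an
XY / ZW / inconclusive verdict.

The package also ships a simulator that generates a synthetic diploid
genome (autosomes, a shared X or Z, and a sex-limited Y or W that mixes
unique sequence with repeat families shared with the autosomes),
fragments it into a draft-like assembly, and samples error-bearing reads
per sex — so the whole pipeline can be validated end-to-end against
known truth labels.

## Worked example

Simulate a small XY genome (65 kb autosomes + 15 kb X + 8 kb Y, 20×
reads per sex), scan it, and score the result:

```bash
ygs simulate --spec spec.cfg -o sim
ygs scan --assembly sim/assembly.fasta \
         --male-reads sim/male_reads.fastq.gz \
         --female-reads sim/female_reads.fastq.gz \
         --min-candidates 4 --min-bp 3000 -o scan
ygs evaluate --scan-table scan/scan_table.tsv --truth sim/truth.tsv \
             --verdict scan/verdict.json -o eval
```

with `spec.cfg`:

```
system = XY
autosome_lengths = 30000, 20000
x_length = 15000
y_length = 8000
repeat_unit_len = 500
scaffold_length = 1000
seed = 11
```

The scan logs

```
[INFO] scan: k=16 min_kmer_count=2 low_quality_max=10.00 candidate_min=70.00
[INFO] scanned 73 scaffolds (0 low-quality, 0 bp)
[INFO] verdict: XY (0.9 s)
```

and `scan/scan_table.tsv` begins

```
scaffold_id  length_bp  n_distinct  n_repetitive  n_single_copy  repeat_fraction  pct_absent_both  qc_pass  pct_unmatched_female  pct_unmatched_male
A1_00000     1000       985         0             985            0.0000           0.51             true     0.71                  0.51
A1_00001     1000       985         0             985            0.0000           0.00             true     0.00                  0.00
```

Autosomal scaffolds are ~0% unmatched against both sexes (the 0.5–0.7%
residue comes from sequencing errors and chromosome-end coverage), while
the eight Y scaffolds are near-100% unmatched against female reads only.
`scan/verdict.json` reports `"system": "XY"` with 8 candidate scaffolds
totalling 8,000 bp on the XY side and none on the ZW side, and
`eval/recovery_metrics.json` scores the run against the simulation truth:

```json
{"sensitivity": 1.0, "false_positive_rate": 0.0, "verdict_correct": true,
 "n_truth_sex_limited": 7, "n_truth_other": 65}
```

(The eighth candidate is a Y scaffold that is mostly repeat-derived and
therefore not counted in the sensitivity denominator.)

`ygs call --scan-table scan/scan_table.tsv [rule flags] -o OUT`
re-thresholds a stored table without re-scanning, and `ygs scan` also
writes per-side histograms plus candidate FASTA files for downstream
marker design.

## Documentation

See `docs/methods.md` for the model, its assumptions, the defaults and
why, what the simulator does and does not emulate, and known
limitations.
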