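"""Per-scaffold sex-specificity statistics, QC filter, and classification.

For each retained scaffold the scan computes, over its *distinct*
canonical k-mers:

* ``pct_absent_both`` — percentage absent from the union of the male and
  female read k-mer sets.  Such k-mers are supported by neither sex's
  reads and are attributed to assembly error; scaffolds with more than
  ``low_quality_max_pct`` (default 10) fail QC.
* ``pct_unmatched_female`` — percentage of the scaffold's *single-copy*
  k-mers absent from the female read set (the XY-GS statistic: high for
  Y-linked scaffolds).
* ``pct_unmatched_male`` — the same against the male read set (the
  ZW-GS statistic: high for W-linked scaffolds).

A QC-passing scaffold whose unmatched percentage strictly exceeds
``candidate_min_unmatched_pct`` (default 70) on a side is a candidate
sex-limited scaffold on that side.  Scaffolds whose k-mers are all
repetitive have no defined unmatched statistic and are reported as NA,
never as candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .kmer_index import (
    AssemblyIndex,
    KmerParams,
    ReadKmerSet,
    build_assembly_index,
    build_read_kmer_set,
    sequence_kmer_codes,
)

__all__ = [
    "ScanParams",
    "ScaffoldRecord",
    "ScanResult",
    "scan_scaffold",
    "apply_qc",
    "classify",
    "run_dual_scan",
]


@dataclass(frozen=True)
class ScanParams:
    """Thresholds for QC and candidate classification.

    Both thresholds are strict ("more than"): a scaffold with exactly 10%
    of its k-mers unsupported still passes QC, and a scaffold with exactly
    70% unmatched single-copy k-mers is not a candidate.
    """

    low_quality_max_pct: float = 10.0
    candidate_min_unmatched_pct: float = 70.0
    kmer: KmerParams = field(default_factory=KmerParams)

    def __post_init__(self) -> None:
        for name in ("low_quality_max_pct", "candidate_min_unmatched_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ConfigError(f"{name} must be in [0, 100], got {v}")


@dataclass
class ScaffoldRecord:
    """Counts, statistics, and flags for one retained scaffold.

    ``pct_unmatched_*`` are ``None`` (reported as NA) when the scaffold
    has no single-copy k-mers.
    """

    scaffold_id: str
    length_bp: int
    n_distinct: int
    n_repetitive: int
    n_single_copy: int
    pct_absent_both: float | None
    pct_unmatched_female: float | None
    pct_unmatched_male: float | None
    qc_pass: bool = False
    is_candidate_xy: bool = False
    is_candidate_zw: bool = False

    @property
    def repeat_fraction(self) -> float | None:
        if self.n_distinct == 0:
            return None
        return self.n_repetitive / self.n_distinct


@dataclass
class ScanResult:
    """One record per retained scaffold plus run-level totals."""

    records: list[ScaffoldRecord]
    params: ScanParams
    female_label: str = "female"
    male_label: str = "male"

    @property
    def n_low_quality(self) -> int:
        return sum(1 for r in self.records if not r.qc_pass)

    @property
    def bp_low_quality(self) -> int:
        return sum(r.length_bp for r in self.records if not r.qc_pass)


def scan_scaffold(
    scaffold_id: str,
    seq: str,
    index: AssemblyIndex,
    female: ReadKmerSet,
    male: ReadKmerSet,
    params: ScanParams,
) -> ScaffoldRecord:
    """Compute all statistics for one scaffold against both read sets.

    Statistics are computed over the scaffold's distinct canonical k-mers;
    QC and classification are applied before returning.
    """
    if female.k != index.k or male.k != index.k:
        raise ConfigError(
            f"k mismatch: index k={index.k}, "
            f"female k={female.k}, male k={male.k}"
        )
    codes = np.unique(sequence_kmer_codes(seq, index.k))
    n_distinct = int(codes.size)
    if n_distinct == 0:
        # No valid window (e.g. an all-N scaffold): nothing is supported
        # by reads, so the scaffold cannot pass QC.
        rec = ScaffoldRecord(
            scaffold_id=scaffold_id,
            length_bp=len(seq),
            n_distinct=0,
            n_repetitive=0,
            n_single_copy=0,
            pct_absent_both=None,
            pct_unmatched_female=None,
            pct_unmatched_male=None,
        )
        rec.qc_pass = False
        return rec
    rep_mask = index.is_repetitive(codes)
    n_rep = int(rep_mask.sum())
    single = codes[~rep_mask]
    in_f = female.contains(codes)
    in_m = male.contains(codes)
    absent_both = ~(in_f | in_m)
    pct_absent_both = 100.0 * int(absent_both.sum()) / n_distinct
    if single.size:
        sf = in_f[~rep_mask]
        sm = in_m[~rep_mask]
        pct_uf = 100.0 * int((~sf).sum()) / single.size
        pct_um = 100.0 * int((~sm).sum()) / single.size
    else:
        pct_uf = None
        pct_um = None
    rec = ScaffoldRecord(
        scaffold_id=scaffold_id,
        length_bp=len(seq),
        n_distinct=n_distinct,
        n_repetitive=n_rep,
        n_single_copy=int(single.size),
        pct_absent_both=pct_absent_both,
        pct_unmatched_female=pct_uf,
        pct_unmatched_male=pct_um,
    )
    apply_qc(rec, params)
    classify(rec, params)
    return rec


def apply_qc(record: ScaffoldRecord, params: ScanParams) -> ScaffoldRecord:
    """Set ``qc_pass``: fails iff strictly more than the threshold of the
    scaffold's k-mers are absent from both sexes' reads."""
    if record.pct_absent_both is None:
        record.qc_pass = False
    else:
        record.qc_pass = record.pct_absent_both <= params.low_quality_max_pct
    return record


def classify(record: ScaffoldRecord, params: ScanParams) -> ScaffoldRecord:
    """Set candidate flags; QC-failed or NA-statistic scaffolds are never
    candidates."""
    thr = params.candidate_min_unmatched_pct
    record.is_candidate_xy = bool(
        record.qc_pass
        and record.pct_unmatched_female is not None
        and record.pct_unmatched_female > thr
    )
    record.is_candidate_zw = bool(
        record.qc_pass
        and record.pct_unmatched_male is not None
        and record.pct_unmatched_male > thr
    )
    return record


def run_dual_scan(
    assembly,
    male_reads,
    female_reads,
    params: ScanParams | None = None,
    exclude_ids=None,
) -> ScanResult:
    """Scan every retained scaffold against both sexes' read k-mer sets.

    The two scans of the classical protocol (assembly vs female reads to
    find the Y; assembly vs male reads to find the W) share one assembly
    index and one pass over the scaffolds, which is mathematically
    identical to two separate runs.

    Parameters
    ----------
    assembly:
        FASTA path or iterable of ``(id, sequence)`` pairs.
    male_reads, female_reads:
        FASTQ/FASTA path(s) (gzip allowed), or a prebuilt
        :class:`ReadKmerSet`.
    params:
        :class:`ScanParams`; defaults when omitted.
    exclude_ids:
        Scaffold IDs dropped before indexing.
    """
    params = params or ScanParams()
    index = build_assembly_index(assembly, params.kmer, exclude_ids)

    def as_set(obj, label: str) -> ReadKmerSet:
        if isinstance(obj, ReadKmerSet):
            return obj
        return build_read_kmer_set(obj, params.kmer, sex_label=label)

    male = as_set(male_reads, "male")
    female = as_set(female_reads, "female")
    retained = set(index.scaffold_lengths)
    records = []
    from .kmer_index import _iter_scaffolds

    for sid, seq in _iter_scaffolds(assembly):
        if sid not in retained:
            continue
        records.append(
            scan_scaffold(sid, seq, index, female, male, params)
        )
    return ScanResult(
        records=records,
        params=params,
        female_label=female.sex_label or "female",
        male_label=male.sex_label or "male",
    )
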