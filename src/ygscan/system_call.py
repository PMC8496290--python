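"""Turning the dual scan into an XY / ZW / inconclusive verdict.

The classical readout is visual: the unmatched-percentage distribution is
bimodal against the homogametic sex's reads (a near-0 mass from autosomes
and the shared sex chromosome, plus a high mass from the sex-limited
chromosome) and unimodal against the heterogametic sex's reads.  Here the
visual judgement is replaced by an explicit dominance rule over the two
candidate summaries: a side wins only if it meets absolute minima (enough
candidate scaffolds and base pairs to represent a chromosome) *and*
dominates the other side by configurable base-pair and count ratios.
Repeat-artifact tails — misassembled transposon scaffolds that show a
spurious high-unmatched signal on the wrong side — therefore cannot flip
a call, and genomes with no convincing signal come back inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .ygs_core import ScanResult

__all__ = [
    "CandidateSummary",
    "VerdictRule",
    "SystemVerdict",
    "summarize_candidates",
    "call_system",
    "histogram",
]

_SIDES = ("XY", "ZW")


@dataclass(frozen=True)
class CandidateSummary:
    """Candidate count and summed length for one side of the dual scan."""

    side: str  # "XY" or "ZW"
    n_scaffolds: int
    total_bp: int


@dataclass(frozen=True)
class VerdictRule:
    """Dominance rule for calling the sex-chromosome system.

    A side is called iff it has at least ``min_candidates`` candidate
    scaffolds totalling at least ``min_bp`` base pairs, and exceeds the
    other side by factors ``bp_ratio`` (on bp) and ``count_ratio`` (on
    scaffold counts).  Ties and ambiguity resolve to inconclusive.
    """

    min_candidates: int = 20
    min_bp: int = 50_000
    bp_ratio: float = 5.0
    count_ratio: float = 3.0

    def __post_init__(self) -> None:
        if self.min_candidates < 0 or self.min_bp < 0:
            raise ConfigError("min_candidates and min_bp must be >= 0")
        if self.bp_ratio < 1 or self.count_ratio < 1:
            raise ConfigError("bp_ratio and count_ratio must be >= 1")


@dataclass(frozen=True)
class SystemVerdict:
    """The call plus the evidence and rule behind it."""

    system: str  # "XY", "ZW", or "inconclusive"
    xy_summary: CandidateSummary
    zw_summary: CandidateSummary
    rule: VerdictRule


def summarize_candidates(scan: ScanResult, side: str) -> CandidateSummary:
    """Count QC-passing candidates of one side and sum their lengths."""
    if side not in _SIDES:
        raise ConfigError(f"side must be one of {_SIDES}, got {side!r}")
    flag = "is_candidate_xy" if side == "XY" else "is_candidate_zw"
    cands = [r for r in scan.records if getattr(r, flag)]
    return CandidateSummary(
        side=side,
        n_scaffolds=len(cands),
        total_bp=sum(r.length_bp for r in cands),
    )


def _dominates(a: CandidateSummary, b: CandidateSummary, rule: VerdictRule) -> bool:
    return (
        a.n_scaffolds >= rule.min_candidates
        and a.total_bp >= rule.min_bp
        and a.total_bp >= rule.bp_ratio * b.total_bp
        and a.n_scaffolds >= rule.count_ratio * b.n_scaffolds
    )


def call_system(
    xy: CandidateSummary,
    zw: CandidateSummary,
    rule: VerdictRule | None = None,
) -> SystemVerdict:
    """Apply the dominance rule to the two candidate summaries.

    The rule is antisymmetric: swapping the summaries maps an XY call to
    a ZW call and vice versa.  Both directions can only hold when both
    sides are empty, which fails the minima and yields inconclusive.
    """
    rule = rule or VerdictRule()
    xy_wins = _dominates(xy, zw, rule)
    zw_wins = _dominates(zw, xy, rule)
    if xy_wins and not zw_wins:
        system = "XY"
    elif zw_wins and not xy_wins:
        system = "ZW"
    else:
        system = "inconclusive"
    return SystemVerdict(system=system, xy_summary=xy, zw_summary=zw, rule=rule)


def histogram(
    scan: ScanResult, side: str, bin_width_pct: float = 2.0
) -> pd.DataFrame:
    """Bin QC-passing scaffolds by their unmatched percentage on one side.

    Bins are left-closed right-open over [0, 100]; the last bin is closed
    so 100% falls in it.  Scaffolds with NA statistics (no single-copy
    k-mers) and QC failures are excluded.  Returns a table with columns
    ``bin_start``, ``bin_end``, ``n_scaffolds``, ``total_bp``.
    """
    if side not in _SIDES:
        raise ConfigError(f"side must be one of {_SIDES}, got {side!r}")
    if bin_width_pct <= 0 or 100.0 % bin_width_pct != 0:
        raise ConfigError(
            f"bin_width_pct must evenly divide 100, got {bin_width_pct}"
        )
    attr = "pct_unmatched_female" if side == "XY" else "pct_unmatched_male"
    vals, lens = [], []
    for r in scan.records:
        v = getattr(r, attr)
        if r.qc_pass and v is not None:
            vals.append(v)
            lens.append(r.length_bp)
    n_bins = int(round(100.0 / bin_width_pct))
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    vals_a = np.asarray(vals, dtype=float)
    lens_a = np.asarray(lens, dtype=np.int64)
    idx = np.minimum(
        np.floor(vals_a / bin_width_pct).astype(int), n_bins - 1
    ) if vals_a.size else np.empty(0, dtype=int)
    n_scaff = np.bincount(idx, minlength=n_bins)
    total_bp = np.bincount(idx, weights=lens_a, minlength=n_bins).astype(np.int64)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "n_scaffolds": n_scaff,
            "total_bp": total_bp,
        }
    )
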