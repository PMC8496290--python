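"""Synthetic sex-chromosome genomes, per-sex reads, and recovery metrics.

The generator emulates the input regime of a whole-genome shotgun study of
a species with homomorphic sex chromosomes: assemblers collapse the
undiverged X/Y (or Z/W) gametologs, so only effectively sex-specific
sequence assembles separately.  The sex-limited chromosome (Y or W) is
therefore modelled as unique random sequence interleaved with copies of
repeat families that are also planted on the autosomes — the
transposon-like sharing that the repetitive-k-mer filter exists to defuse.
The "assembly" is the heterogametic individual's chromosomes fragmented
into fixed-size scaffolds, and reads are single-end with uniform coverage
and i.i.d. substitution errors.  Everything is deterministic given the
spec's seed.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .system_call import SystemVerdict
from .ygs_core import ScanResult

__all__ = [
    "SimSpec",
    "TruthTable",
    "SimulatedGenome",
    "RecoveryMetrics",
    "simulate_genome",
    "simulate_reads",
    "simulate_dataset",
    "evaluate_recovery",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the synthetic study.

    Defaults describe a compact 2 Mb genome sequenced to 20x per sex with
    100 bp reads and a 0.5% per-base substitution error rate, fragmented
    into 5 kb scaffolds — short-read draft assemblies of insect genomes
    are typically at least this fragmented.
    """

    system: str = "XY"  # "XY" or "ZW"
    autosome_lengths: tuple[int, ...] = (800_000, 600_000)
    x_length: int = 400_000
    y_length: int = 200_000
    y_unique_fraction: float = 0.8
    repeat_families: int = 5
    repeat_unit_len: int = 2_000
    repeat_copies_per_family: int = 3  # copies planted on autosomes
    scaffold_length: int = 5_000
    read_length: int = 100
    depth: float = 20.0
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.system not in ("XY", "ZW"):
            raise ConfigError(f"system must be 'XY' or 'ZW', got {self.system!r}")
        if not 0.0 <= self.y_unique_fraction <= 1.0:
            raise ConfigError("y_unique_fraction must be in [0, 1]")
        lengths = (*self.autosome_lengths, self.x_length, self.y_length)
        if any(l < self.read_length for l in lengths):
            raise ConfigError("all chromosome lengths must be >= read_length")
        if self.depth <= 0:
            raise ConfigError("depth must be > 0")
        if not 0.0 <= self.error_rate < 0.25:
            raise ConfigError("error_rate must be in [0, 0.25)")
        if self.scaffold_length < 1 or self.read_length < 1:
            raise ConfigError("scaffold_length and read_length must be >= 1")

    @property
    def sex_limited_name(self) -> str:
        return "Y" if self.system == "XY" else "W"

    @property
    def shared_name(self) -> str:
        return "X" if self.system == "XY" else "Z"


@dataclass
class TruthTable:
    """Origin and repeat-derived fraction of every emitted scaffold."""

    table: pd.DataFrame  # columns: scaffold_id, chromosome, repeat_fraction
    system: str

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# system: {self.system}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        system = None
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                system = first.split(":", 1)[1].strip() if ":" in first else None
            else:
                fh.seek(0)
            table = pd.read_csv(fh, sep="\t")
        if system is None or "scaffold_id" not in table.columns:
            raise InputError(f"malformed truth table: {path}")
        return cls(table=table, system=system)


@dataclass
class SimulatedGenome:
    """All artefacts of one simulated study."""

    spec: SimSpec
    scaffolds: list[tuple[str, str]]  # the draft "assembly"
    male_chromosomes: dict[str, str]
    female_chromosomes: dict[str, str]
    truth: TruthTable


def _arr_to_seq(arr: np.ndarray) -> str:
    return _BASE_BYTES[arr].tobytes().decode("ascii")


def _random_chrom(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def simulate_genome(spec: SimSpec) -> SimulatedGenome:
    """Build both sexes' chromosome sets, the fragmented assembly, and truth.

    Autosomes and the shared sex chromosome (X or Z) appear in both sexes;
    the sex-limited chromosome (Y or W) only in the heterogametic sex.
    ``y_unique_fraction`` of the sex-limited chromosome is fresh random
    sequence; the rest is monomer copies of the shared repeat families,
    which are also planted (``repeat_copies_per_family`` copies each) at
    random positions on the autosomes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    monomers = [
        _random_chrom(rng, spec.repeat_unit_len)
        for _ in range(spec.repeat_families)
    ]

    chroms: dict[str, np.ndarray] = {}
    repeat_masks: dict[str, np.ndarray] = {}
    for i, length in enumerate(spec.autosome_lengths, start=1):
        name = f"A{i}"
        chroms[name] = _random_chrom(rng, length)
        repeat_masks[name] = np.zeros(length, dtype=bool)
    # plant repeat copies on the autosomes so Y/W repeats are shared
    auto_names = [f"A{i}" for i in range(1, len(spec.autosome_lengths) + 1)]
    for mono in monomers:
        for _ in range(spec.repeat_copies_per_family):
            name = auto_names[rng.integers(0, len(auto_names))]
            arr = chroms[name]
            pos = int(rng.integers(0, len(arr) - len(mono) + 1))
            arr[pos : pos + len(mono)] = mono
            repeat_masks[name][pos : pos + len(mono)] = True

    shared = spec.shared_name
    chroms[shared] = _random_chrom(rng, spec.x_length)
    repeat_masks[shared] = np.zeros(spec.x_length, dtype=bool)

    limited = spec.sex_limited_name
    y_arr, y_mask = _build_sex_limited(rng, spec, monomers)
    chroms[limited] = y_arr
    repeat_masks[limited] = y_mask

    shared_set = [*auto_names, shared]
    if spec.system == "XY":
        male_names = [*shared_set, limited]
        female_names = shared_set
        het_names = male_names
    else:
        male_names = shared_set
        female_names = [*shared_set, limited]
        het_names = female_names

    scaffolds: list[tuple[str, str]] = []
    rows = []
    for name in het_names:
        arr = chroms[name]
        mask = repeat_masks[name]
        n_frag = (len(arr) + spec.scaffold_length - 1) // spec.scaffold_length
        for j in range(n_frag):
            lo = j * spec.scaffold_length
            hi = min(lo + spec.scaffold_length, len(arr))
            sid = f"{name}_{j:05d}"
            scaffolds.append((sid, _arr_to_seq(arr[lo:hi])))
            rows.append(
                {
                    "scaffold_id": sid,
                    "chromosome": name,
                    "repeat_fraction": float(mask[lo:hi].mean()),
                }
            )
    truth = TruthTable(
        table=pd.DataFrame(rows, columns=["scaffold_id", "chromosome", "repeat_fraction"]),
        system=spec.system,
    )
    return SimulatedGenome(
        spec=spec,
        scaffolds=scaffolds,
        male_chromosomes={n: _arr_to_seq(chroms[n]) for n in male_names},
        female_chromosomes={n: _arr_to_seq(chroms[n]) for n in female_names},
        truth=truth,
    )


def _build_sex_limited(
    rng: np.random.Generator, spec: SimSpec, monomers: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Interleave unique sequence with repeat-family copies on the Y/W."""
    total = spec.y_length
    n_rep_bases = int(round((1.0 - spec.y_unique_fraction) * total))
    unit = spec.repeat_unit_len
    pieces: list[np.ndarray] = []
    flags: list[np.ndarray] = []
    copies: list[np.ndarray] = []
    remaining = n_rep_bases
    while remaining > 0 and monomers:
        mono = monomers[rng.integers(0, len(monomers))]
        take = min(unit, remaining)
        copies.append(mono[:take])
        remaining -= take
    n_unique = total - n_rep_bases
    # split the unique bases into one chunk per gap around the repeat copies
    n_gaps = len(copies) + 1
    if n_gaps == 1:
        cuts = np.empty(0, dtype=np.int64)
    else:
        cuts = np.sort(rng.integers(0, n_unique + 1, size=n_gaps - 1))
    bounds = np.concatenate(([0], cuts, [n_unique]))
    for g in range(n_gaps):
        seg_len = int(bounds[g + 1] - bounds[g])
        if seg_len:
            pieces.append(_random_chrom(rng, seg_len))
            flags.append(np.zeros(seg_len, dtype=bool))
        if g < len(copies):
            pieces.append(copies[g])
            flags.append(np.ones(len(copies[g]), dtype=bool))
    arr = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
    mask = np.concatenate(flags) if flags else np.empty(0, dtype=bool)
    return arr, mask


_READ_CHUNK = 200_000


def simulate_reads(
    genome: dict[str, str] | Iterable[tuple[str, str]],
    spec: SimSpec,
    seed: int | None = None,
) -> Iterator[tuple[str, str]]:
    """Yield ``(read_id, sequence)`` single-end reads over a chromosome set.

    Read count is ``round(depth * total_bp / read_length)``; start
    positions are uniform over all valid positions, strands are uniform,
    and each base substitutes to a uniformly chosen different base with
    probability ``error_rate``.  Deterministic given ``seed`` (defaults
    to ``spec.seed``).
    """
    from .kmer_index import _encode_bases

    items = list(genome.items()) if isinstance(genome, dict) else list(genome)
    arrs = [_encode_bases(s) for _, s in items]
    L = spec.read_length
    for name, a in zip((n for n, _ in items), arrs):
        if len(a) < L:
            raise ConfigError(
                f"chromosome {name!r} shorter than read_length {L}"
            )
    total_bp = sum(len(a) for a in arrs)
    n_reads = int(round(spec.depth * total_bp / L))
    starts_per = np.array([len(a) - L + 1 for a in arrs], dtype=np.int64)
    starts_cum = np.cumsum(starts_per)
    offsets = np.concatenate(([0], np.cumsum([len(a) for a in arrs])[:-1]))
    cat = np.concatenate(arrs)
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed if seed is None else seed)
    )
    window = np.arange(L, dtype=np.int64)
    emitted = 0
    while emitted < n_reads:
        m = min(_READ_CHUNK, n_reads - emitted)
        g = rng.integers(0, starts_cum[-1], size=m)
        ci = np.searchsorted(starts_cum, g, side="right")
        within = g - np.concatenate(([0], starts_cum))[ci]
        pos = offsets[ci] + within
        reads = cat[pos[:, None] + window]
        flip = rng.random(m) < 0.5
        reads[flip] = 3 - reads[flip][:, ::-1]
        err = rng.random((m, L)) < spec.error_rate
        n_err = int(err.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            reads[err] = (reads[err] + shift) % 4
        ascii_rows = _BASE_BYTES[reads]
        for i in range(m):
            yield f"r{emitted + i:08d}", ascii_rows[i].tobytes().decode("ascii")
        emitted += m


def _open_det_gz(path):
    # mtime pinned to 0 so repeated runs are byte-identical
    raw = open(path, "wb")
    gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0, compresslevel=2)
    return io.TextIOWrapper(io.BufferedWriter(gz), encoding="ascii")


def write_fastq(records: Iterable[tuple[str, str]], path, quality_char: str = "I") -> None:
    """Write reads as FASTQ with a constant quality string (gzip if ``.gz``)."""
    path = str(path)
    fh = _open_det_gz(path) if path.endswith(".gz") else open(path, "w")
    with fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    """Write sequences as wrapped FASTA (gzip if ``.gz``)."""
    path = str(path)
    fh = _open_det_gz(path) if path.endswith(".gz") else open(path, "w")
    with fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_dataset(spec: SimSpec, outdir) -> dict[str, str]:
    """Run the full simulation and write assembly, reads, and truth to disk.

    Returns a dict of output paths: ``assembly``, ``male_reads``,
    ``female_reads``, ``truth``.  Read seeds are derived from the spec
    seed (male: seed+1, female: seed+2) so the two sexes get independent
    error and sampling realizations.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    sim = simulate_genome(spec)
    paths = {
        "assembly": os.path.join(outdir, "assembly.fasta"),
        "male_reads": os.path.join(outdir, "male_reads.fastq.gz"),
        "female_reads": os.path.join(outdir, "female_reads.fastq.gz"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_fasta(sim.scaffolds, paths["assembly"])
    write_fastq(
        simulate_reads(sim.male_chromosomes, spec, seed=spec.seed + 1),
        paths["male_reads"],
    )
    write_fastq(
        simulate_reads(sim.female_chromosomes, spec, seed=spec.seed + 2),
        paths["female_reads"],
    )
    sim.truth.to_tsv(paths["truth"])
    return paths


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well the scan recovered the simulated truth."""

    sensitivity: float | None
    false_positive_rate: float | None
    verdict_correct: bool
    n_truth_sex_limited: int  # eligible Y/W scaffolds (>= 50% unique-derived)
    n_truth_other: int

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "false_positive_rate": self.false_positive_rate,
            "verdict_correct": self.verdict_correct,
            "n_truth_sex_limited": self.n_truth_sex_limited,
            "n_truth_other": self.n_truth_other,
        }


def evaluate_recovery(
    scan: ScanResult,
    truth: TruthTable,
    verdict: SystemVerdict,
    min_unique_fraction: float = 0.5,
) -> RecoveryMetrics:
    """Score the scan and verdict against the simulation's truth labels.

    Sensitivity is the fraction of sex-limited (Y or W) scaffolds with at
    least ``min_unique_fraction`` unique-derived bases that were flagged
    candidates on the correct side; the false-positive rate is the
    fraction of autosomal / shared-chromosome scaffolds flagged on that
    side.  Scaffolds dropped by the scan's length filter are not scored.
    """
    limited = "Y" if truth.system == "XY" else "W"
    flag = "is_candidate_xy" if truth.system == "XY" else "is_candidate_zw"
    truth_map = {
        row.scaffold_id: (row.chromosome, row.repeat_fraction)
        for row in truth.table.itertuples()
    }
    unknown = [r.scaffold_id for r in scan.records if r.scaffold_id not in truth_map]
    if unknown:
        raise InputError(
            f"{len(unknown)} scanned scaffold(s) absent from truth table, "
            f"e.g. {unknown[0]!r}"
        )
    tp = fn = fp = tn = 0
    for rec in scan.records:
        chrom, rep_frac = truth_map[rec.scaffold_id]
        flagged = getattr(rec, flag)
        if chrom == limited:
            if 1.0 - rep_frac >= min_unique_fraction:
                if flagged:
                    tp += 1
                else:
                    fn += 1
        else:
            if flagged:
                fp += 1
            else:
                tn += 1
    n_pos = tp + fn
    n_neg = fp + tn
    return RecoveryMetrics(
        sensitivity=(tp / n_pos) if n_pos else None,
        false_positive_rate=(fp / n_neg) if n_neg else None,
        verdict_correct=(verdict.system == truth.system),
        n_truth_sex_limited=n_pos,
        n_truth_other=n_neg,
    )
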