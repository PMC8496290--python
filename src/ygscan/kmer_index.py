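"""Canonical k-mer encoding and k-mer set construction.

A k-mer is stored as the 2-bit encoding (A=0, C=1, G=2, T=3, most
significant base first) of the lexicographically smaller of the k-base
window and its reverse complement.  Because the base order coincides with
lexicographic order, the numeric minimum of the two codes encodes the
canonical (strand-collapsed) form.  Windows containing any character
outside ACGT (case-insensitive) carry no code and are skipped.

Two k-mer collections drive the scan:

* :class:`AssemblyIndex` partitions the distinct canonical k-mers of a
  genome assembly into *single-copy* (seen in exactly one window across
  all retained scaffolds) and *repetitive* (seen more than once) sets.
* :class:`ReadKmerSet` holds the canonical k-mers observed at sufficient
  multiplicity in one sex's reads.

Both are backed by sorted ``numpy`` ``uint64`` arrays, giving
O(log n) membership and vectorized bulk queries.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import ConfigError, InputError

__all__ = [
    "KmerParams",
    "AssemblyIndex",
    "ReadKmerSet",
    "canonical_encode",
    "decode_kmer",
    "sequence_kmers",
    "sequence_kmer_codes",
    "build_assembly_index",
    "build_read_kmer_set",
    "read_kmer_set_from_sequences",
]

_BASES = "ACGT"

# 256-entry translation table: ACGT/acgt -> 0..3, everything else -> 4
_TRANS = bytearray([4]) * 256
for _i, _b in enumerate(_BASES):
    _TRANS[ord(_b)] = _i
    _TRANS[ord(_b.lower())] = _i
_TRANS = bytes(_TRANS)


@dataclass(frozen=True)
class KmerParams:
    """Word length and presence thresholds for all k-mer operations.

    Parameters
    ----------
    k:
        k-mer length in bases.  Must satisfy ``2 <= k <= 31`` so a
        canonical code fits a 62-bit integer.  Default 16.
    min_read_count:
        Minimum multiplicity across one sex's reads for a k-mer to count
        as present in that sex.  Default 2: at ~20x coverage a genomic
        k-mer is expected in far more than two reads while most
        sequencing-error k-mers are singletons.
    min_scaffold_len:
        Scaffolds shorter than this many bp are dropped before any
        counting.  Default 200.
    """

    k: int = 16
    min_read_count: int = 2
    min_scaffold_len: int = 200

    def __post_init__(self) -> None:
        if not 2 <= self.k <= 31:
            raise ConfigError(f"k must be in [2, 31], got {self.k}")
        if self.min_read_count < 1:
            raise ConfigError(
                f"min_read_count must be >= 1, got {self.min_read_count}"
            )
        if self.min_scaffold_len < self.k:
            raise ConfigError(
                f"min_scaffold_len must be >= k ({self.k}), "
                f"got {self.min_scaffold_len}"
            )


def _encode_bases(seq: str) -> np.ndarray:
    """Map a DNA string to a uint8 array with A,C,G,T -> 0..3 and 4 elsewhere."""
    raw = seq.encode("latin-1", errors="replace").translate(_TRANS)
    return np.frombuffer(raw, dtype=np.uint8)


def canonical_encode(window: str, k: int) -> int | None:
    """Encode one k-base window as its canonical numeric code.

    Returns ``None`` if the window contains any non-ACGT character.
    Raises :class:`InputError` if the window length differs from ``k``.
    """
    if len(window) != k:
        raise InputError(
            f"window length {len(window)} does not match k={k}"
        )
    fwd = 0
    rev = 0
    for i, ch in enumerate(window):
        code = _TRANS[ord(ch) if ord(ch) < 256 else 0]
        if code >= 4:
            return None
        fwd = (fwd << 2) | code
        rev |= (3 - code) << (2 * i)
    return min(fwd, rev)


def decode_kmer(code: int, k: int) -> str:
    """Inverse of the 2-bit encoding (returns the encoded strand as stored)."""
    if not 0 <= code < 4**k:
        raise InputError(f"code {code} out of range for k={k}")
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def sequence_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical codes of all valid k-windows of ``seq``, in positional order.

    Windows containing non-ACGT characters are skipped; a sequence shorter
    than ``k`` yields an empty array.  Vectorized: two rolling 2-bit
    accumulators (forward and reverse-complement) are built in ``k``
    passes over the base array and combined with an elementwise minimum.
    """
    b = _encode_bases(seq)
    n = len(b) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = b >= 4
    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad)))
        ok = (cs[k:] - cs[:-k]) == 0
        b = np.where(bad, np.uint8(0), b)
    else:
        ok = None
    bb = b.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | bb[j : j + n]
        rev = (rev << np.uint64(2)) | (three - bb[k - 1 - j : k - 1 - j + n])
    canon = np.minimum(fwd, rev)
    if ok is not None:
        canon = canon[ok]
    return canon


def sequence_kmers(seq: str, k: int) -> Iterator[int]:
    """Stream the canonical codes of ``seq``'s valid windows in order."""
    return iter(sequence_kmer_codes(seq, k).tolist())


def _sorted_unique_members(arrays: list[np.ndarray], min_count: int) -> np.ndarray:
    """Codes whose total multiplicity across ``arrays`` is >= min_count."""
    if not arrays:
        return np.empty(0, dtype=np.uint64)
    allc = np.concatenate(arrays)
    if min_count <= 1:
        return np.unique(allc)
    uniq, counts = np.unique(allc, return_counts=True)
    return uniq[counts >= min_count]


def _in_sorted(sorted_arr: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Boolean membership of ``codes`` in a sorted unique array."""
    if sorted_arr.size == 0:
        return np.zeros(codes.shape, dtype=bool)
    idx = np.searchsorted(sorted_arr, codes)
    idx[idx == sorted_arr.size] = sorted_arr.size - 1
    return sorted_arr[idx] == codes


@dataclass
class AssemblyIndex:
    """Single-copy / repetitive partition of an assembly's canonical k-mers.

    ``single_copy`` holds codes occurring in exactly one window across all
    retained scaffolds; ``repetitive`` holds codes occurring more than once
    (including within-scaffold duplicates and reverse-complement self-pairs
    — exactly the multi-mapping sequences the filter targets).  Both are
    sorted unique ``uint64`` arrays and are disjoint by construction.
    """

    k: int
    single_copy: np.ndarray
    repetitive: np.ndarray
    scaffold_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n_distinct(self) -> int:
        return int(self.single_copy.size + self.repetitive.size)

    def is_repetitive(self, codes: np.ndarray) -> np.ndarray:
        return _in_sorted(self.repetitive, np.asarray(codes, dtype=np.uint64))


@dataclass
class ReadKmerSet:
    """Canonical k-mers present at sufficient multiplicity in one sex's reads."""

    k: int
    sex_label: str
    members: np.ndarray  # sorted unique uint64

    def __len__(self) -> int:
        return int(self.members.size)

    def __contains__(self, code: int) -> bool:
        return bool(_in_sorted(self.members, np.asarray([code], dtype=np.uint64))[0])

    def contains(self, codes: np.ndarray) -> np.ndarray:
        """Vectorized membership query."""
        return _in_sorted(self.members, np.asarray(codes, dtype=np.uint64))

    def relabel(self, sex_label: str) -> "ReadKmerSet":
        return ReadKmerSet(k=self.k, sex_label=sex_label, members=self.members)


def _iter_scaffolds(assembly) -> Iterator[tuple[str, str]]:
    # Accept a FASTA path or an iterable of (id, sequence) pairs.
    if isinstance(assembly, (str, os.PathLike)):
        from .cli_io import parse_fasta

        yield from parse_fasta(assembly)
    else:
        for rec in assembly:
            yield rec[0], rec[1]


def build_assembly_index(
    assembly,
    params: KmerParams | None = None,
    exclude_ids: Iterable[str] | None = None,
) -> AssemblyIndex:
    """Partition the retained assembly's distinct canonical k-mers.

    Parameters
    ----------
    assembly:
        FASTA path (gzip allowed) or an iterable of ``(id, sequence)``
        pairs.  Scaffold IDs must be unique.
    params:
        :class:`KmerParams`; defaults used when omitted.
    exclude_ids:
        Scaffold IDs to drop before counting (e.g. externally identified
        contaminants).

    Occurrences are counted per window over all retained scaffolds, so a
    k-mer appearing twice within one scaffold is repetitive.
    """
    params = params or KmerParams()
    excl = set(exclude_ids) if exclude_ids else set()
    lengths: dict[str, int] = {}
    seen_ids: set[str] = set()
    chunks: list[np.ndarray] = []
    n_parsed = 0
    for sid, seq in _iter_scaffolds(assembly):
        n_parsed += 1
        if sid in seen_ids:
            raise InputError(f"duplicate scaffold ID in assembly: {sid!r}")
        seen_ids.add(sid)
        if sid in excl or len(seq) < params.min_scaffold_len:
            continue
        lengths[sid] = len(seq)
        chunks.append(sequence_kmer_codes(seq, params.k))
    if n_parsed == 0:
        raise InputError("assembly contains no sequences")
    if not lengths:
        raise InputError(
            "no scaffold of length >= "
            f"{params.min_scaffold_len} bp remains after exclusions"
        )
    allc = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
    uniq, counts = np.unique(allc, return_counts=True)
    return AssemblyIndex(
        k=params.k,
        single_copy=uniq[counts == 1],
        repetitive=uniq[counts > 1],
        scaffold_lengths=lengths,
    )


def read_kmer_set_from_sequences(
    seqs: Iterable[str],
    params: KmerParams | None = None,
    sex_label: str = "",
) -> ReadKmerSet:
    """Build a :class:`ReadKmerSet` from in-memory read sequences."""
    params = params or KmerParams()
    chunks = [sequence_kmer_codes(s, params.k) for s in seqs]
    members = _sorted_unique_members(chunks, params.min_read_count)
    return ReadKmerSet(k=params.k, sex_label=sex_label, members=members)


# Reads are buffered into ~32 Mbase joined blocks (separated by 'N' so no
# window spans two reads) before vectorized encoding; keeps per-read
# Python overhead negligible at tens of millions of reads.
_BLOCK_BASES = 32_000_000


def build_read_kmer_set(
    sources: Sequence[str | os.PathLike] | str | os.PathLike,
    params: KmerParams | None = None,
    sex_label: str = "",
) -> ReadKmerSet:
    """Build one sex's k-mer presence set from FASTQ/FASTA files.

    ``sources`` is one path or a list of paths (gzip autodetected); paired
    files are simply concatenated — the scan ignores pairing.  Quality
    strings are ignored (reads are assumed pre-trimmed upstream).  A k-mer
    is a member iff its total canonical multiplicity over all input reads
    is at least ``params.min_read_count``.
    """
    from .cli_io import parse_reads

    params = params or KmerParams()
    if isinstance(sources, (str, os.PathLike)):
        sources = [sources]
    chunks: list[np.ndarray] = []
    buf: list[str] = []
    buf_bases = 0
    n_records = 0

    def flush() -> None:
        nonlocal buf, buf_bases
        if buf:
            chunks.append(sequence_kmer_codes("N".join(buf), params.k))
            buf = []
            buf_bases = 0

    for path in sources:
        for _rid, seq in parse_reads(path):
            n_records += 1
            buf.append(seq)
            buf_bases += len(seq) + 1
            if buf_bases >= _BLOCK_BASES:
                flush()
    flush()
    if n_records == 0:
        raise InputError(
            "no readable records in read input(s): "
            + ", ".join(str(p) for p in sources)
        )
    members = _sorted_unique_members(chunks, params.min_read_count)
    return ReadKmerSet(k=params.k, sex_label=sex_label, members=members)
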