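"""Brute-force string-based reference implementation of the scan.

Everything here works on canonical k-mer *strings* with plain dict/Counter
multisets, independent of the package's numeric encoding, so it can serve
as an oracle for the vectorized implementation on small instances.
"""

from collections import Counter

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def canon(s: str) -> str:
    rc = revcomp(s)
    return s if s <= rc else rc


def kmer_windows(seq: str, k: int) -> list[str]:
    """Canonical k-mer strings of all valid windows, in order."""
    seq = seq.upper()
    out = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if all(c in "ACGT" for c in w):
            out.append(canon(w))
    return out


def encode(s: str) -> int:
    code = 0
    for c in s:
        code = code * 4 + "ACGT".index(c)
    return code


def naive_read_set(reads, k: int, min_read_count: int) -> set[str]:
    counts = Counter()
    for r in reads:
        counts.update(kmer_windows(r, k))
    return {km for km, n in counts.items() if n >= min_read_count}


def naive_scan(
    scaffolds,
    female_reads,
    male_reads,
    k: int,
    min_read_count: int = 2,
    min_scaffold_len: int = 200,
    low_quality_max_pct: float = 10.0,
    candidate_min_unmatched_pct: float = 70.0,
):
    """Per-scaffold statistics as a list of dicts, by exhaustive counting."""
    retained = [(sid, s) for sid, s in scaffolds if len(s) >= min_scaffold_len]
    genome_counts = Counter()
    for _sid, s in retained:
        genome_counts.update(kmer_windows(s, k))
    repetitive = {km for km, n in genome_counts.items() if n > 1}
    fset = naive_read_set(female_reads, k, min_read_count)
    mset = naive_read_set(male_reads, k, min_read_count)
    out = []
    for sid, s in retained:
        distinct = set(kmer_windows(s, k))
        rep = distinct & repetitive
        single = distinct - rep
        n_distinct = len(distinct)
        absent_both = {km for km in distinct if km not in fset and km not in mset}
        pct_absent = 100.0 * len(absent_both) / n_distinct if n_distinct else None
        if single:
            pct_uf = 100.0 * len({km for km in single if km not in fset}) / len(single)
            pct_um = 100.0 * len({km for km in single if km not in mset}) / len(single)
        else:
            pct_uf = pct_um = None
        qc = pct_absent is not None and pct_absent <= low_quality_max_pct
        out.append(
            {
                "scaffold_id": sid,
                "length_bp": len(s),
                "n_distinct": n_distinct,
                "n_repetitive": len(rep),
                "n_single_copy": len(single),
                "pct_absent_both": pct_absent,
                "qc_pass": qc,
                "pct_unmatched_female": pct_uf,
                "pct_unmatched_male": pct_um,
                "is_candidate_xy": bool(
                    qc and pct_uf is not None and pct_uf > candidate_min_unmatched_pct
                ),
                "is_candidate_zw": bool(
                    qc and pct_um is not None and pct_um > candidate_min_unmatched_pct
                ),
            }
        )
    return out
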