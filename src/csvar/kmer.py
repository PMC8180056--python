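"""Canonical k-mer counting and case-specific k-mer extraction.

The counter is internal (no external tool): reads are concatenated with 'N'
sentinels, 2-bit encoded with numpy, and every N-free window contributes one
count to its canonical form (the lexicographic minimum of the window and its
reverse complement).  Lexicographic order on ACGT strings coincides with
numeric order on the big-endian 2-bit encoding, which makes canonicalization
a vectorized ``minimum``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Union

import numpy as np

from csvar.preprocess import ReadRecord

DEFAULT_K = 31
DEFAULT_MIN_COUNT = 3

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base -> 2-bit code; anything that is not ACGT maps to 4 (invalid)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(kmer: str) -> str:
    """Return the lexicographically smaller of ``kmer`` and its reverse complement.

    K-mers containing characters outside ACGT are rejected: windows with N
    never reach canonicalization (they are dropped by :func:`count_kmers`).
    """
    if any(c not in "ACGT" for c in kmer):
        raise ValueError(f"k-mer contains non-ACGT character: {kmer!r}")
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerCountTable:
    """Counts of canonical k-mers observed in one library."""

    k: int
    counts: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.counts)

    def get(self, kmer: str, default: int = 0) -> int:
        return self.counts.get(kmer, default)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as out:
            for kmer in sorted(self.counts):
                out.write(f"{kmer}\t{self.counts[kmer]}\n")


@dataclass
class CsKmerSet:
    """Case-specific k-mers with their case and raw-control counts."""

    k: int
    kmers: Set[str] = field(default_factory=set)
    case_counts: Dict[str, int] = field(default_factory=dict)
    control_raw_counts: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.kmers)


# ---------------------------------------------------------------------------
# encoding helpers
# ---------------------------------------------------------------------------

def encode_kmer(kmer: str) -> int:
    v = 0
    for c in kmer:
        v = (v << 2) | _BASES.index(c)
    return v


def decode_kmer(value: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[value & 3])
        value >>= 2
    return "".join(reversed(out))


def _decode_array(values: np.ndarray, k: int) -> List[str]:
    """Vectorized decode of an array of 2-bit packed k-mers to strings."""
    n = len(values)
    if n == 0:
        return []
    chars = np.empty((n, k), dtype=np.uint8)
    v = values.copy()
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    for j in range(k - 1, -1, -1):
        chars[:, j] = lut[(v & 3).astype(np.intp)]
        v >>= np.uint64(2)
    flat = np.ascontiguousarray(chars).view(f"S{k}").ravel()
    return [s.decode("ascii") for s in flat]


def _canonical_window_values(seqs: Sequence[str], k: int) -> np.ndarray:
    """2-bit packed canonical values of every N-free length-k window."""
    data = "N".join(seqs).encode("ascii")
    arr = np.frombuffer(data, dtype=np.uint8)
    code = _CODE[arr]
    n = len(code) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    valid = code < 4
    cs = np.concatenate(([0], np.cumsum(valid, dtype=np.int64)))
    win_ok = (cs[k:] - cs[:-k]) == k
    c = np.where(valid, code, 0).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | c[j : j + n]
        rev |= (np.uint64(3) - c[j : j + n]) << np.uint64(2 * j)
    return np.minimum(fwd, rev)[win_ok]


def count_kmers(
    reads: Iterable[Union[ReadRecord, str]], k: int = DEFAULT_K
) -> KmerCountTable:
    """Count canonical k-mers over all N-free windows of the given reads.

    ``reads`` may be ``ReadRecord`` objects or plain sequences.  Windows
    containing at least one N (or any non-ACGT character) contribute nothing.
    """
    if k < 5 or k % 2 == 0:
        raise ValueError("k must be odd and >= 5")
    if k > 32:
        raise ValueError("k must be <= 32 (2-bit packing in 64 bits)")
    seqs = [r.bases if isinstance(r, ReadRecord) else r for r in reads]
    if not seqs:
        return KmerCountTable(k=k)
    vals = _canonical_window_values(seqs, k)
    if len(vals) == 0:
        return KmerCountTable(k=k)
    uniq, cnt = np.unique(vals, return_counts=True)
    keys = _decode_array(uniq, k)
    return KmerCountTable(k=k, counts=dict(zip(keys, cnt.tolist())))


def filter_low_count(table: KmerCountTable, min_count: int = DEFAULT_MIN_COUNT) -> KmerCountTable:
    """Drop k-mers whose count is strictly below ``min_count``."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if min_count == 1:
        return KmerCountTable(k=table.k, counts=dict(table.counts))
    return KmerCountTable(
        k=table.k,
        counts={km: c for km, c in table.counts.items() if c >= min_count},
    )


def extract_cs_kmers(
    case_filtered: KmerCountTable,
    control_filtered: KmerCountTable,
    control_raw: KmerCountTable,
    max_control_count: int = DEFAULT_MIN_COUNT - 1,
) -> CsKmerSet:
    """Case-specific k-mers: in the filtered case table, absent from the
    filtered control table, and with raw control count <= ``max_control_count``.

    The raw-count guard keeps loci that are merely under-covered in the
    control from leaking through when a handful of control reads do carry
    the variant k-mer.
    """
    if not (case_filtered.k == control_filtered.k == control_raw.k):
        raise ValueError("k-mer tables were built with different k")
    cs = CsKmerSet(k=case_filtered.k)
    ctrl_f = control_filtered.counts
    ctrl_raw = control_raw.counts
    for kmer, count in case_filtered.counts.items():
        if kmer in ctrl_f:
            continue
        raw = ctrl_raw.get(kmer, 0)
        if raw > max_control_count:
            continue
        cs.kmers.add(kmer)
        cs.case_counts[kmer] = count
        cs.control_raw_counts[kmer] = raw
    return cs


def filter_panel_of_normals(
    cs: CsKmerSet,
    normal_tables: Sequence[KmerCountTable],
    max_normals: int = 1,
) -> CsKmerSet:
    """Remove cs-kmers seen in strictly more than ``max_normals`` normal samples.

    With the default ``max_normals=1`` a k-mer present in at least two normal
    libraries (count >= 1 in each) is excluded as a putative germline or
    recurrent-artifact k-mer.
    """
    for t in normal_tables:
        if t.k != cs.k:
            raise ValueError("panel table k differs from cs-kmer k")
    if not normal_tables:
        return CsKmerSet(
            k=cs.k,
            kmers=set(cs.kmers),
            case_counts=dict(cs.case_counts),
            control_raw_counts=dict(cs.control_raw_counts),
        )
    out = CsKmerSet(k=cs.k)
    for kmer in cs.kmers:
        hits = sum(1 for t in normal_tables if kmer in t.counts)
        if hits <= max_normals:
            out.kmers.add(kmer)
            out.case_counts[kmer] = cs.case_counts[kmer]
            out.control_raw_counts[kmer] = cs.control_raw_counts[kmer]
    return out
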