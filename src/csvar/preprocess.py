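"""Read cleaning: 3'-end quality trimming and internal low-quality masking.

Cleaning runs before k-mer extraction so that no k-mer ever contains a base
whose Phred score fell below the masking threshold (masked bases become 'N'
and windows containing 'N' are skipped by the counter).  Both the case and
the control library are cleaned with identical parameters.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_QUALITY_CUTOFF = 10
DEFAULT_MASK_THRESHOLD = 10

#: FASTQ qualities are fixed to Phred+33 ("Sanger"); scores above this bound
#: indicate a different encoding and are rejected.
MAX_PHRED = 93


@dataclass
class ReadRecord:
    """A single sequencing read with per-base Phred scores.

    ``quals`` is stored as ``bytes`` of raw Phred values (not ASCII), so
    iterating yields integers.  ``mate`` is 1/2 for paired-end data.
    """

    id: str
    bases: str
    quals: bytes
    mate: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: bases ({len(self.bases)}) and quals "
                f"({len(self.quals)}) differ in length"
            )
        if self.quals and (min(self.quals) < 0 or max(self.quals) > MAX_PHRED):
            raise ValueError(
                f"read {self.id!r}: Phred scores outside [0, {MAX_PHRED}]; "
                "only Phred+33 encoding is supported"
            )

    def __len__(self) -> int:
        return len(self.bases)


def trim_quality_ends(read: ReadRecord, cutoff: int = DEFAULT_QUALITY_CUTOFF) -> ReadRecord:
    """Trim the 3' end with the BWA-style partial-sum rule.

    The read is cut at the position that maximizes the running sum of
    ``cutoff - q`` accumulated from the 3' end; a non-positive maximum leaves
    the read unchanged.  Only the 3' end is trimmed.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    quals = read.quals
    n = len(quals)
    if n == 0 or min(quals) >= cutoff:  # fast path: no base below cutoff
        return read
    best, best_cut, s = 0, n, 0
    for i in range(n - 1, -1, -1):
        s += cutoff - quals[i]
        if s > best:
            best, best_cut = s, i
    if best_cut == n:
        return read
    return ReadRecord(read.id, read.bases[:best_cut], quals[:best_cut], read.mate)


def override_n(read: ReadRecord, threshold: int = DEFAULT_MASK_THRESHOLD) -> ReadRecord:
    """Replace every base with Phred score strictly below ``threshold`` by 'N'.

    Quality values are kept unchanged; the operation is idempotent.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    quals = read.quals
    if not quals or min(quals) >= threshold:
        return read
    bases = "".join(
        "N" if q < threshold else b for b, q in zip(read.bases, quals)
    )
    return ReadRecord(read.id, bases, quals, read.mate)


def clean_read(
    read: ReadRecord,
    quality_cutoff: int = DEFAULT_QUALITY_CUTOFF,
    mask_threshold: int = DEFAULT_MASK_THRESHOLD,
) -> ReadRecord:
    """Quality-trim the 3' end, then mask remaining low-quality bases."""
    return override_n(trim_quality_ends(read, quality_cutoff), mask_threshold)


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33 only; transparent gzip by file extension)
# ---------------------------------------------------------------------------

def _open_text(path: str, mode: str = "rt") -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ASCII -> Phred translation tables (offset 33); out-of-range low bytes map to
# 255 so that ReadRecord validation rejects non-Phred+33 input.
_QTAB_DECODE = bytes(max(i - 33, 0) if i >= 33 else 255 for i in range(256))
_QTAB_ENCODE = bytes(min(i + 33, 255) for i in range(256))


def read_fastq(path: str, mate: Optional[int] = None) -> Iterator[ReadRecord]:
    """Stream ``ReadRecord`` objects from a (possibly gzipped) FASTQ file."""
    with _open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            quals = qual.encode("latin-1").translate(_QTAB_DECODE)
            yield ReadRecord(title.split()[0], seq.upper(), quals, mate)


def write_fastq(reads: Iterable[ReadRecord], path: str) -> int:
    """Write reads as Phred+33 FASTQ; returns the number of records written."""
    n = 0
    with _open_text(path, "wt") as out:
        for r in reads:
            qual = bytes(r.quals).translate(_QTAB_ENCODE).decode("latin-1")
            out.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")
            n += 1
    return n


def clean_fastq(
    in_path: str,
    out_path: str,
    quality_cutoff: int = DEFAULT_QUALITY_CUTOFF,
    mask_threshold: int = DEFAULT_MASK_THRESHOLD,
) -> int:
    """Clean a FASTQ file end-to-end (standalone preprocessing mode)."""
    return write_fastq(
        (clean_read(r, quality_cutoff, mask_threshold) for r in read_fastq(in_path)),
        out_path,
    )
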