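"""Infer the wild-type reference contig for each mutant contig.

Two branches:

* ``ct_merge`` — when strictly more than half of the contig's member k-mers
  have Hamming-1 counterparts, the counterpart (ct) k-mers are merged with
  the same overlap rule as the mutant assembly.
* ``read_assembly`` — otherwise, control reads containing a window within
  one mismatch of any member k-mer are retrieved and assembled by a greedy
  exact-overlap consensus; the number of retrieved reads serves as the
  control-side coverage.

Count statistics use the median (not the mean) so that high-count k-mers
from repeats do not dominate.  Even-sized medians take the mean of the two
middle values rounded half down to an integer.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from csvar.assembly import Contig, merge_sequences
from csvar.kmer import KmerCountTable, canonicalize, encode_kmer, revcomp
from csvar.preprocess import ReadRecord

DEFAULT_MIN_READ_OVERLAP = 30
#: unique read sequences fed to the consensus assembler, for bounded runtime
DEFAULT_MAX_ASSEMBLY_READS = 120


@dataclass
class InferredReference:
    ref_seq: Optional[str]
    branch: str  # "ct_merge" | "read_assembly"
    cs_count_case: int
    coverage_case: int
    cs_count_control: int
    coverage_control: int
    n_support_reads: int = 0


def median_int(values: Sequence[int]) -> int:
    """Median as an integer; even sizes use mean-of-middles rounded half down."""
    if not values:
        return 0
    s = sorted(values)
    n = len(s)
    if n % 2:
        return s[n // 2]
    return (s[n // 2 - 1] + s[n // 2]) // 2


def _member_occurrence(contig: Contig, offset: int) -> str:
    return contig.seq[offset : offset + len(contig.members[0].kmer)]


def _orient_to(seq: str, target: str) -> str:
    """Pick the orientation of ``seq`` sharing more 11-mers with ``target``."""
    w = min(11, len(seq), len(target))
    if w == 0:
        return seq
    twin = {target[i : i + w] for i in range(len(target) - w + 1)}
    fwd = sum(1 for i in range(len(seq) - w + 1) if seq[i : i + w] in twin)
    rc = revcomp(seq)
    rev = sum(1 for i in range(len(rc) - w + 1) if rc[i : i + w] in twin)
    if rev > fwd or (rev == fwd and rc < seq):
        return rc
    return seq


def contig_ct_kmers(contig: Contig) -> List[str]:
    """Canonical ct-kmers of the contig's matched members."""
    return [canonicalize(m.pair.ct_kmer) for m in contig.members if m.matched and m.pair]


def infer_reference_matched(contig: Contig, min_overlap: int) -> Optional[str]:
    """Merge ct-kmers into a single reference sequence (ct_merge branch).

    Returns ``None`` when the ct-kmers do not merge into one sequence; the
    caller then falls back to the read_assembly branch.
    """
    if contig.matched_fraction <= 0.5:
        raise ValueError("ct_merge branch requires matched_fraction > 0.5")
    cts = contig_ct_kmers(contig)
    if not cts:
        return None
    k = len(cts[0])
    merged = merge_sequences(cts, k, min_overlap)
    if len(merged) != 1:
        return None
    return _orient_to(merged[0], contig.seq)


def compute_kmer_stats(
    contig: Contig,
    case_counts: KmerCountTable,
    control_counts: KmerCountTable,
) -> Tuple[int, int, int, int]:
    """(cs_count_case, coverage_case, cs_count_control, coverage_control).

    cs-count is the median member k-mer count; coverage adds the median
    counterpart k-mer count in the same library.  Control-side cs counts come
    from the raw (unfiltered) control table and are typically zero.
    """
    member_kmers = [m.kmer for m in contig.members]
    cts = contig_ct_kmers(contig)
    cs_case = median_int([case_counts.get(km) for km in member_kmers])
    cs_ctrl = median_int([control_counts.get(km) for km in member_kmers])
    ct_case = median_int([case_counts.get(km) for km in cts]) if cts else 0
    ct_ctrl = median_int([control_counts.get(km) for km in cts]) if cts else 0
    return cs_case, cs_case + ct_case, cs_ctrl, cs_ctrl + ct_ctrl


# ---------------------------------------------------------------------------
# read_assembly branch
# ---------------------------------------------------------------------------

def _neighborhood(oriented_kmer: str) -> List[str]:
    """All sequences within Hamming distance <= 1 of the k-mer (same strand)."""
    out = [oriented_kmer]
    for i, orig in enumerate(oriented_kmer):
        for b in "ACGT":
            if b != orig:
                out.append(oriented_kmer[:i] + b + oriented_kmer[i + 1 :])
    return out


def retrieve_control_reads(
    contig: Contig, control_reads: Iterable[ReadRecord]
) -> List[ReadRecord]:
    """Control reads with >= 1 window within one mismatch of a member k-mer.

    Either orientation of the read counts; retrieved reads are oriented to
    the contig strand so they can be assembled directly.
    """
    k = len(contig.members[0].kmer)
    fwd_vals: Set[str] = set()
    rc_vals: Set[str] = set()
    for m in contig.members:
        occ = _member_occurrence(contig, m.offset)
        for nb in _neighborhood(occ):
            fwd_vals.add(nb)
            rc_vals.add(revcomp(nb))
    hits: List[ReadRecord] = []
    for read in control_reads:
        seq = read.bases
        oriented = None
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if w in fwd_vals:
                oriented = read
                break
            if w in rc_vals:
                oriented = ReadRecord(read.id, revcomp(seq), read.quals[::-1], read.mate)
                break
        if oriented is not None:
            hits.append(oriented)
    return hits


def retrieve_control_reads_batch(
    contigs: Sequence[Contig], control_seqs: Sequence[str], k: int
) -> List[List[str]]:
    """Vectorized retrieval for many contigs over one pass of the control reads.

    Returns, per contig, the list of matching read sequences oriented to the
    contig strand.  Only sequences are returned (qualities are not needed for
    consensus assembly).
    """
    if not contigs or not control_seqs:
        return [[] for _ in contigs]
    # neighbor value -> list of (contig index, needs_rc)
    nb_map: Dict[int, List[Tuple[int, bool]]] = defaultdict(list)
    for ci, contig in enumerate(contigs):
        for m in contig.members:
            occ = _member_occurrence(contig, m.offset)
            for nb in _neighborhood(occ):
                nb_map[encode_kmer(nb)].append((ci, False))
                nb_map[encode_kmer(revcomp(nb))].append((ci, True))
    targets = np.fromiter(nb_map.keys(), dtype=np.uint64, count=len(nb_map))
    targets.sort()

    # forward (non-canonical) window values over all reads, with read mapping
    data = "N".join(control_seqs).encode("ascii")
    arr = np.frombuffer(data, dtype=np.uint8)
    from csvar.kmer import _CODE  # local import to reuse the lookup table

    code = _CODE[arr]
    n = len(code) - k + 1
    if n <= 0:
        return [[] for _ in contigs]
    valid = code < 4
    cs = np.concatenate(([0], np.cumsum(valid, dtype=np.int64)))
    win_ok = (cs[k:] - cs[:-k]) == k
    c = np.where(valid, code, 0).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | c[j : j + n]
    win_idx = np.nonzero(win_ok)[0]
    vals = fwd[win_idx]
    pos = np.searchsorted(targets, vals)
    pos[pos == len(targets)] = 0
    hit_mask = targets[pos] == vals
    hit_windows = win_idx[hit_mask]
    hit_vals = vals[hit_mask]

    starts = np.empty(len(control_seqs), dtype=np.int64)
    off = 0
    for i, s in enumerate(control_seqs):
        starts[i] = off
        off += len(s) + 1
    read_of_window = np.searchsorted(starts, hit_windows, side="right") - 1

    per_contig: List[Dict[int, bool]] = [dict() for _ in contigs]
    for w, v, r in zip(hit_windows.tolist(), hit_vals.tolist(), read_of_window.tolist()):
        for ci, needs_rc in nb_map[v]:
            # first hit decides the orientation for this (read, contig)
            per_contig[ci].setdefault(r, needs_rc)
    out: List[List[str]] = []
    for ci in range(len(contigs)):
        reads = []
        for r in sorted(per_contig[ci]):
            seq = control_seqs[r]
            reads.append(revcomp(seq) if per_contig[ci][r] else seq)
        out.append(reads)
    return out


def _max_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest L >= min_overlap with a's suffix equal to b's prefix (0 if none)."""
    for L in range(min(len(a), len(b)), min_overlap - 1, -1):
        if a[-L:] == b[:L]:
            return L
    return 0


def assemble_control_reads(
    reads: Sequence[Union[ReadRecord, str]],
    min_read_overlap: int = DEFAULT_MIN_READ_OVERLAP,
    max_assembly_reads: int = DEFAULT_MAX_ASSEMBLY_READS,
) -> Tuple[Optional[str], int]:
    """Greedy exact-overlap consensus assembly of retrieved control reads.

    Repeatedly merges the pair with the longest exact suffix-prefix overlap
    (>= ``min_read_overlap``), with per-column majority vote over read
    support.  Returns (longest assembled sequence or None, number of input
    reads).  The read count — not the assembly — is the coverage estimate
    for this branch.
    """
    n_reads = len(reads)
    if n_reads == 0:
        return None, 0
    seqs = [r.bases if isinstance(r, ReadRecord) else r for r in reads]
    support: Dict[str, int] = defaultdict(int)
    for s in seqs:
        support[s] += 1
    uniq = sorted(support)[:max_assembly_reads]

    # item: (consensus, profile) where profile[i] is {base: weight}
    items: List[Tuple[str, List[Dict[str, int]]]] = []
    for s in uniq:
        items.append((s, [{b: support[s]} for b in s]))

    def consensus_of(profile: List[Dict[str, int]]) -> str:
        out = []
        for col in profile:
            best = max(sorted(col), key=lambda b: col[b])
            out.append(best)
        return "".join(out)

    while len(items) > 1:
        best: Optional[Tuple[int, str, str, int, int]] = None  # (-L, seq_i, seq_j, i, j)
        for i, (si, _) in enumerate(items):
            for j, (sj, _) in enumerate(items):
                if i == j:
                    continue
                L = _max_overlap(si, sj, min_read_overlap)
                if L and (best is None or (-L, si, sj) < best[:3]):
                    best = (-L, si, sj, i, j)
        if best is None:
            break
        L, i, j = -best[0], best[3], best[4]
        si, pi = items[i]
        sj, pj = items[j]
        merged_profile = pi[: len(si) - L]
        for a, b in zip(pi[len(si) - L :], pj[:L]):
            col = dict(a)
            for base, w in b.items():
                col[base] = col.get(base, 0) + w
            merged_profile.append(col)
        merged_profile.extend(pj[L:])
        merged = (consensus_of(merged_profile), merged_profile)
        items = [it for idx, it in enumerate(items) if idx not in (i, j)]
        items.append(merged)

    ref = max(items, key=lambda it: (len(it[0]), it[0]))[0] if items else None
    return ref, n_reads


def infer_reference(
    contig: Contig,
    case_table: KmerCountTable,
    control_table: KmerCountTable,
    retrieved_reads: Sequence[Union[ReadRecord, str]],
    min_overlap: int,
    min_read_overlap: int = DEFAULT_MIN_READ_OVERLAP,
) -> InferredReference:
    """Route a contig through the appropriate branch and compute statistics.

    ``retrieved_reads`` must hold the control reads pre-retrieved for this
    contig (used when the contig lands in the read_assembly branch, including
    the fall-back case where ct-kmer merging fails).
    """
    member_kmers = [m.kmer for m in contig.members]
    cs_case = median_int([case_table.get(km) for km in member_kmers])
    cs_ctrl = median_int([control_table.get(km) for km in member_kmers])

    if contig.matched_fraction > 0.5:
        ref = infer_reference_matched(contig, min_overlap)
        if ref is not None:
            a, b, c, d = compute_kmer_stats(contig, case_table, control_table)
            return InferredReference(
                ref_seq=ref,
                branch="ct_merge",
                cs_count_case=a,
                coverage_case=b,
                cs_count_control=c,
                coverage_control=d,
            )

    ref, n = assemble_control_reads(retrieved_reads, min_read_overlap)
    if ref is not None:
        ref = _orient_to(ref, contig.seq)
        k = len(member_kmers[0]) if member_kmers else 31
        ref_kmers = []
        if len(ref) >= k:
            ref_kmers = [canonicalize(ref[i : i + k]) for i in range(len(ref) - k + 1)]
        wt_case = median_int([case_table.get(km) for km in ref_kmers]) if ref_kmers else 0
    else:
        wt_case = 0
    return InferredReference(
        ref_seq=ref,
        branch="read_assembly",
        cs_count_case=cs_case,
        coverage_case=cs_case + wt_case,
        cs_count_control=cs_ctrl,
        coverage_control=cs_ctrl + n,
        n_support_reads=n,
    )
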