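"""Pair case-specific k-mers with Hamming-distance-1 control counterparts.

The search uses end keys of length (k-1)/2: any two k-mers at Hamming
distance 1 keep at least one end intact (the single mismatch cannot touch
both the first and the last (k-1)/2 bases of an odd-length k-mer), so
bucketing by prefix/suffix keys finds every pair without an all-vs-all scan.
Both orientations of every k-mer are indexed because the canonical forms of
a mutant k-mer and of its wild-type counterpart may lie on opposite strands.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

from csvar.kmer import CsKmerSet, KmerCountTable, canonicalize, revcomp


@dataclass(frozen=True)
class MatchedPair:
    """A cs-kmer joined to its single-substitution control counterpart.

    ``ct_kmer`` is reported in the orientation matching ``cs_kmer`` (the
    canonical form of the cs-kmer), so the two strings differ at exactly
    ``mismatch_pos``.
    """

    cs_kmer: str
    ct_kmer: str
    mismatch_pos: int
    case_allele: str
    control_allele: str
    ct_count: int


@dataclass
class KeyIndex:
    key_len: int
    # key -> list of (oriented kmer, origin, orientation)
    buckets: Dict[str, List[Tuple[str, str, str]]] = field(default_factory=dict)


def _hamming1(a: str, b: str) -> int:
    """Mismatch position if hamming(a, b) == 1, else -1 (equal length assumed)."""
    pos = -1
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            if pos >= 0:
                return -1
            pos = i
    return pos


def build_key_index(cs: CsKmerSet, control: KmerCountTable) -> KeyIndex:
    """Bucket cs-kmers and control k-mers by shared (k-1)/2-base end keys."""
    if control.k != cs.k:
        raise ValueError("cs-kmer k and control table k differ")
    k = cs.k
    key_len = (k - 1) // 2
    buckets: Dict[str, List[Tuple[str, str, str]]] = defaultdict(list)
    keys: Set[str] = set()
    for kmer in cs.kmers:
        for orient, seq in (("fwd", kmer), ("rc", revcomp(kmer))):
            for key in (seq[:key_len], seq[-key_len:]):
                keys.add(key)
                buckets[key].append((seq, "case", orient))
    for kmer in control.counts:
        for orient, seq in (("fwd", kmer), ("rc", revcomp(kmer))):
            pre, suf = seq[:key_len], seq[-key_len:]
            if pre in keys:
                buckets[pre].append((seq, "control", orient))
            if suf in keys and suf != pre:
                buckets[suf].append((seq, "control", orient))
    index = KeyIndex(key_len=key_len)
    index.buckets = dict(buckets)
    return index


def find_pairs(index: KeyIndex, control: KmerCountTable) -> List[MatchedPair]:
    """All (cs, control) pairs at Hamming distance exactly 1.

    When several control counterparts exist for one cs-kmer, the one with the
    highest control count wins (ties broken by lexicographically smaller
    oriented counterpart).  Pairs are reported in the cs-kmer's canonical
    orientation and deduplicated across buckets/orientations.
    """
    # cs canonical -> (ct oriented to cs canonical, ct control count)
    best: Dict[str, Tuple[int, str]] = {}
    for bucket in index.buckets.values():
        case_entries = [e for e in bucket if e[1] == "case"]
        ctrl_entries = [e for e in bucket if e[1] == "control"]
        if not case_entries or not ctrl_entries:
            continue
        for cs_seq, _, cs_orient in case_entries:
            cs_canon = cs_seq if cs_orient == "fwd" else revcomp(cs_seq)
            for ct_seq, _, _ in ctrl_entries:
                pos = _hamming1(cs_seq, ct_seq)
                if pos < 0:
                    continue
                # express counterpart in the cs-kmer's canonical orientation
                ct_oriented = ct_seq if cs_orient == "fwd" else revcomp(ct_seq)
                count = control.get(canonicalize(ct_oriented))
                cur = best.get(cs_canon)
                cand = (-count, ct_oriented)
                if cur is None or cand < cur:
                    best[cs_canon] = cand
    pairs: List[MatchedPair] = []
    for cs_canon in sorted(best):
        neg_count, ct_oriented = best[cs_canon]
        pos = _hamming1(cs_canon, ct_oriented)
        pairs.append(
            MatchedPair(
                cs_kmer=cs_canon,
                ct_kmer=ct_oriented,
                mismatch_pos=pos,
                case_allele=cs_canon[pos],
                control_allele=ct_oriented[pos],
                ct_count=-neg_count,
            )
        )
    return pairs


def match_cs_kmers(cs: CsKmerSet, control: KmerCountTable) -> List[MatchedPair]:
    """Convenience wrapper: index then search."""
    return find_pairs(build_key_index(cs, control), control)


def partition_cs_kmers(
    cs: CsKmerSet, pairs: List[MatchedPair]
) -> Tuple[Set[str], Set[str]]:
    """Split cs-kmers into (matched, unmatched) by pair membership."""
    matched = {p.cs_kmer for p in pairs} & cs.kmers
    unmatched = cs.kmers - matched
    return matched, unmatched


def pairs_to_tsv(pairs: List[MatchedPair], path: str) -> None:
    with open(path, "w") as out:
        out.write("cs_kmer\tct_kmer\tpos\tcase_allele\tcontrol_allele\tct_count\n")
        for p in pairs:
            out.write(
                f"{p.cs_kmer}\t{p.ct_kmer}\t{p.mismatch_pos}\t"
                f"{p.case_allele}\t{p.control_allele}\t{p.ct_count}\n"
            )
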