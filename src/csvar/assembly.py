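"""Greedy assembly of cs-kmers into mutant contigs.

Sequences are merged iteratively with the required overlap length decreasing
from k-1 down to ``min_overlap`` (default 25 for k=31).  A merge happens only
when it is unambiguous in both directions: the extending end sees exactly one
candidate, and the candidate's receiving end sees exactly one extender.  This
mutual-uniqueness rule makes the result independent of processing order.
Contigs are stored in a canonical orientation (lexicographic minimum of the
sequence and its reverse complement) since k-mers are strandless.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from csvar.kmer import CsKmerSet, canonicalize, revcomp
from csvar.matching import MatchedPair

DEFAULT_MIN_OVERLAP = 25


@dataclass
class ContigMember:
    offset: int
    kmer: str  # canonical form
    case_count: int = 0
    matched: bool = False
    pair: Optional[MatchedPair] = None


@dataclass
class Contig:
    seq: str
    members: List[ContigMember] = field(default_factory=list)
    id: str = ""

    @property
    def matched_fraction(self) -> float:
        if not self.members:
            return 0.0
        return sum(1 for m in self.members if m.matched) / len(self.members)

    def __len__(self) -> int:
        return len(self.seq)


class _Item:
    __slots__ = ("seq", "members", "maxcount")

    def __init__(self, seq: str, members: List[Tuple[int, str]], maxcount: int):
        self.seq = seq
        self.members = members  # (offset, canonical kmer) in self.seq coords
        self.maxcount = maxcount


def _oriented(item: _Item, orient: str) -> str:
    return item.seq if orient == "fwd" else revcomp(item.seq)


def _flip_members(members: List[Tuple[int, str]], length: int, k: int) -> List[Tuple[int, str]]:
    return [(length - k - off, km) for off, km in members]


def _store_canonical(seq: str, members: List[Tuple[int, str]], k: int) -> Tuple[str, List[Tuple[int, str]]]:
    rc = revcomp(seq)
    if rc < seq:
        return rc, _flip_members(members, len(seq), k)
    return seq, members


def _assemble(
    seqs: Sequence[str],
    k: int,
    min_overlap: int,
    counts: Optional[Dict[str, int]] = None,
) -> List[Tuple[str, List[Tuple[int, str]]]]:
    """Core merge engine over length-k sequences; returns (seq, members)."""
    if min_overlap >= k:
        raise ValueError("min_overlap must be < k")
    counts = counts or {}
    items: Dict[int, _Item] = {}
    for i, s in enumerate(sorted(set(seqs))):
        canon = canonicalize(s)
        items[i] = _Item(canon, [(0, canon)], counts.get(canon, 0))

    for L in range(k - 1, min_overlap - 1, -1):
        pref: Dict[str, Set[Tuple[int, str]]] = defaultdict(set)
        suf: Dict[str, Set[Tuple[int, str]]] = defaultdict(set)

        def index_item(iid: int) -> None:
            it = items[iid]
            for orient in ("fwd", "rc"):
                s = _oriented(it, orient)
                pref[s[:L]].add((iid, orient))
                suf[s[-L:]].add((iid, orient))

        def unindex_item(iid: int) -> None:
            it = items[iid]
            for orient in ("fwd", "rc"):
                s = _oriented(it, orient)
                pref[s[:L]].discard((iid, orient))
                suf[s[-L:]].discard((iid, orient))

        for iid in items:
            index_item(iid)

        def try_extend_right(aid: int, orient_a: str) -> bool:
            a = items[aid]
            sa = _oriented(a, orient_a)
            cands = [(i, o) for i, o in pref.get(sa[-L:], ()) if i != aid]
            ids = {i for i, _ in cands}
            if len(ids) != 1:
                return False
            bid = ids.pop()
            b = items[bid]
            b_seqs = {_oriented(b, o) for _, o in cands}
            if len(b_seqs) != 1:
                return False  # both orientations fit with different extensions
            sb = b_seqs.pop()
            orient_b = "fwd" if _oriented(b, "fwd") == sb else "rc"
            # reverse check: the receiving end of B must see only A
            lefts = [(i, o) for i, o in suf.get(sb[:L], ()) if i != bid]
            left_ids = {i for i, _ in lefts}
            if left_ids != {aid}:
                return False
            a_seqs = {_oriented(a, o) for _, o in lefts}
            if len(a_seqs) != 1 or a_seqs.pop() != sa:
                return False
            # merge
            unindex_item(aid)
            unindex_item(bid)
            mem_a = a.members if orient_a == "fwd" else _flip_members(a.members, len(a.seq), k)
            mem_b = b.members if orient_b == "fwd" else _flip_members(b.members, len(b.seq), k)
            shift = len(sa) - L
            merged_seq = sa + sb[L:]
            merged_members = mem_a + [(off + shift, km) for off, km in mem_b]
            seq_c, mem_c = _store_canonical(merged_seq, merged_members, k)
            a.seq, a.members = seq_c, mem_c
            a.maxcount = max(a.maxcount, b.maxcount)
            del items[bid]
            index_item(aid)
            return True

        progress = True
        while progress:
            progress = False
            order = sorted(items, key=lambda i: (-items[i].maxcount, items[i].seq))
            for iid in order:
                if iid not in items:
                    continue
                extended = True
                while extended:
                    extended = try_extend_right(iid, "fwd") or try_extend_right(iid, "rc")
                    if extended:
                        progress = True

    out = [(it.seq, sorted(it.members)) for it in items.values()]
    out.sort(key=lambda t: t[0])
    return out


def assemble_contigs(
    cs: CsKmerSet,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    pairs: Optional[Sequence[MatchedPair]] = None,
) -> List[Contig]:
    """Assemble cs-kmers into mutant contigs.

    Every cs-kmer ends up in exactly one contig; isolated k-mers become
    length-k contigs.  Matched flags and pair references are attached from
    ``pairs`` when given.
    """
    pair_by_kmer = {p.cs_kmer: p for p in pairs} if pairs else {}
    raw = _assemble(sorted(cs.kmers), cs.k, min_overlap, counts=cs.case_counts)
    contigs: List[Contig] = []
    for idx, (seq, members) in enumerate(raw):
        contig = Contig(seq=seq, id=f"contig_{idx + 1}")
        for off, km in members:
            p = pair_by_kmer.get(km)
            contig.members.append(
                ContigMember(
                    offset=off,
                    kmer=km,
                    case_count=cs.case_counts.get(km, 0),
                    matched=p is not None,
                    pair=p,
                )
            )
        contigs.append(contig)
    return contigs


def merge_sequences(seqs: Sequence[str], k: int, min_overlap: int = DEFAULT_MIN_OVERLAP) -> List[str]:
    """Merge arbitrary length-k sequences with the contig merge rule.

    Used to fuse counterpart (ct) k-mers into a putative reference contig.
    """
    if not seqs:
        return []
    return [seq for seq, _ in _assemble(seqs, k, min_overlap)]


def contigs_to_fasta(contigs: Sequence[Contig], path: str) -> None:
    with open(path, "w") as out:
        for c in contigs:
            out.write(
                f">{c.id} n_members={len(c.members)} "
                f"matched_fraction={c.matched_fraction:.3f}\n{c.seq}\n"
            )
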