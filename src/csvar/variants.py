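"""Align mutant contigs to inferred references, classify events, export VCF.

Alignment uses Biopython's ``PairwiseAligner`` in local mode (match +2,
mismatch -1, gap open -2, gap extend -0.5, pairwise2 gap convention: a gap of
length g costs open + (g-1)*extend).  Local mode leaves divergent contig ends
unaligned, which is how junction contigs (structural variant breakpoints)
are recognized.  Classification depends only on the edit structure of the
alignment: substitution count, internal gap lengths, and clipped ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align

from csvar.kmer import revcomp
from csvar.scoring import VariantStats

SV_MIN_LEN = 50
#: a mutant end of at least this many unalignable bases marks a breakpoint
SV_MIN_CLIP = 20

_aligner = Align.PairwiseAligner()
_aligner.mode = "local"
_aligner.match_score = 2
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -0.5


@dataclass
class PairAlignment:
    """A local alignment of mutant (a) vs reference (b)."""

    a: str
    b: str
    a_aligned: str  # with '-' for gaps
    b_aligned: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    score: float


@dataclass
class VariantCall:
    contig_id: str
    mutant_seq: str
    ref_seq: Optional[str]
    var_type: str  # mutation | multiple_mutation | indel | sv | unresolved
    pos_in_contig: int  # 0-based in mutant contig
    pos_in_ref: int  # 0-based in inferred reference (-1 if no reference)
    ref_allele: str
    alt_allele: str
    stats: Optional[VariantStats] = None
    branch: str = ""
    chrom: Optional[str] = None
    genome_pos: Optional[int] = None  # 1-based
    passed: bool = True
    #: second breakend of an sv event, when the reference spans the junction
    partner_ref_pos: Optional[int] = None
    partner_genome_pos: Optional[int] = None


def align_contig_pair(mutant: str, ref: str) -> PairAlignment:
    """Best local alignment of the mutant contig against its reference.

    The first optimal alignment in Biopython's deterministic enumeration is
    used; the scoring scheme itself prefers a mismatch (-1) over a 1-base
    gap (-2), matching the documented tie-break intent.
    """
    if not mutant or not ref:
        raise ValueError("both sequences must be non-empty")
    aln = _aligner.align(mutant, ref)[0]
    blocks_a, blocks_b = aln.aligned
    a_parts: List[str] = []
    b_parts: List[str] = []
    prev_a = prev_b = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            da, db = a0 - prev_a, b0 - prev_b
            # between blocks exactly one sequence advances (no double gaps
            # under this scoring); emit the skipped bases against gaps
            a_parts.append(mutant[prev_a:a0] + "-" * db)
            b_parts.append("-" * da + ref[prev_b:b0])
        a_parts.append(mutant[a0:a1])
        b_parts.append(ref[b0:b1])
        prev_a, prev_b = a1, b1
    return PairAlignment(
        a=mutant,
        b=ref,
        a_aligned="".join(a_parts),
        b_aligned="".join(b_parts),
        a_start=int(blocks_a[0][0]),
        a_end=int(blocks_a[-1][1]),
        b_start=int(blocks_b[0][0]),
        b_end=int(blocks_b[-1][1]),
        score=float(aln.score),
    )


def _left_align_indel(
    ref: str, ref_pos: int, ref_allele: str, alt_allele: str, a_pos: int
) -> Tuple[int, str, str, int]:
    """Shift an anchored indel leftwards through a repeat (VCF normalization)."""
    while (
        ref_pos > 0
        and len(ref_allele) >= 1
        and len(alt_allele) >= 1
        and ref_allele[-1] == alt_allele[-1]
        and a_pos > 0
    ):
        prev = ref[ref_pos - 1]
        ref_allele = prev + ref_allele[:-1]
        alt_allele = prev + alt_allele[:-1]
        ref_pos -= 1
        a_pos -= 1
    return ref_pos, ref_allele, alt_allele, a_pos


_TRIM_WINDOW = 15
_TRIM_MIN_IDENTITY = 0.7


def _trim_divergent_ends(alignment: PairAlignment) -> Tuple[str, str]:
    """Strip low-identity alignment ends (in place) and return aligned strings.

    A local alignment can wander into foreign sequence past a breakpoint
    (random sequence still scores ~25% matches); trimming columns while the
    outermost window falls below 70% identity restores a clean clipped end,
    which the classifier reads as a junction.
    """
    cols = list(zip(alignment.a_aligned, alignment.b_aligned))

    def window_ok(window: List[Tuple[str, str]]) -> bool:
        matches = sum(1 for a, b in window if a == b and a != "-")
        return matches / len(window) >= _TRIM_MIN_IDENTITY

    lo, hi = 0, len(cols)
    while hi - lo >= _TRIM_WINDOW and not window_ok(cols[lo : lo + _TRIM_WINDOW]):
        a, b = cols[lo]
        if a != "-":
            alignment.a_start += 1
        if b != "-":
            alignment.b_start += 1
        lo += 1
    while hi - lo >= _TRIM_WINDOW and not window_ok(cols[hi - _TRIM_WINDOW : hi]):
        a, b = cols[hi - 1]
        if a != "-":
            alignment.a_end -= 1
        if b != "-":
            alignment.b_end -= 1
        hi -= 1
    alignment.a_aligned = "".join(a for a, _ in cols[lo:hi])
    alignment.b_aligned = "".join(b for _, b in cols[lo:hi])
    return alignment.a_aligned, alignment.b_aligned


_SEED_LEN = 20
#: more substitutions than this (with equal end offsets) is junction noise
_MAX_SUBS = 5


def _seed_hits(seed: str, ref: str) -> List[int]:
    """Occurrences of ``seed`` in ``ref`` (exact, else Hamming distance 1)."""
    hits = _find_all(ref, seed)
    if hits:
        return hits
    w = len(seed)
    return [j for j in range(len(ref) - w + 1) if _hamming_le1(ref[j : j + w], seed)]


def _walk_right(mutant: str, ref: str, off: int) -> int:
    """First mutant index (from the left, at ref offset ``off``) that mismatches."""
    i = max(0, -off)
    while i < len(mutant) and off + i < len(ref) and mutant[i] == ref[off + i]:
        i += 1
    return i


def _walk_left(mutant: str, ref: str, off: int) -> int:
    """Last mutant index (from the right, at ref offset ``off``) that mismatches."""
    j = min(len(mutant) - 1, len(ref) - 1 - off)
    while j >= 0 and off + j >= 0 and mutant[j] == ref[off + j]:
        j -= 1
    return j


def _breakpoint_call(
    mutant: str, ref: str, pos_a: int, pos_b: int
) -> VariantCall:
    pos_a = min(max(pos_a, 0), len(mutant) - 1)
    pos_b = min(max(pos_b, 0), len(ref) - 1)
    return VariantCall(
        contig_id="",
        mutant_seq=mutant,
        ref_seq=ref,
        var_type="sv",
        pos_in_contig=pos_a,
        pos_in_ref=pos_b,
        ref_allele=ref[pos_b],
        alt_allele="<SV>",
    )


def classify_variant(
    alignment: Optional[PairAlignment],
    mutant: str,
    ref: Optional[str],
    sv_min_len: int = SV_MIN_LEN,
    sv_min_clip: int = SV_MIN_CLIP,
    evidence: bool = True,
) -> VariantCall:
    """Derive the typed event for a mutant contig / reference pair.

    The primary parse anchors both contig ends in the reference with exact
    (or 1-mismatch) seeds and compares the two offsets: equal offsets give
    substitution events, a small offset difference an indel, a large or
    inconsistent one a structural variant; a contig end that cannot be
    anchored at all marks a junction (sv).  When neither end anchors, the
    pairwise alignment's edit structure is used as a fallback.  With no
    reference the contig is a candidate sv (unresolved when ``evidence`` is
    False, e.g. a bare single-k-mer contig).
    """
    if ref is None:
        return VariantCall(
            contig_id="",
            mutant_seq=mutant,
            ref_seq=None,
            var_type="sv" if evidence else "unresolved",
            pos_in_contig=0,
            pos_in_ref=-1,
            ref_allele=mutant[0] if mutant else "N",
            alt_allele="<SV>",
        )
    w = min(_SEED_LEN, len(mutant) // 2)
    offs_l: List[int] = []
    offs_r: List[int] = []
    if w >= 10:
        offs_l = _seed_hits(mutant[:w], ref)
        offs_r = [p - (len(mutant) - w) for p in _seed_hits(mutant[-w:], ref)]

    if offs_l and offs_r:
        off_l, off_r = min(
            ((a, b) for a in offs_l for b in offs_r),
            key=lambda ab: (abs(ab[1] - ab[0]), ab[0]),
        )
        diff = off_r - off_l  # reference surplus: >0 deletion, <0 insertion
        if diff == 0:
            over_l = max(0, -off_l)
            over_r = max(0, off_l + len(mutant) - len(ref))
            if max(over_l, over_r) >= sv_min_clip:
                return _breakpoint_call(
                    mutant, ref, _walk_right(mutant, ref, off_l) - 1,
                    off_l + _walk_right(mutant, ref, off_l) - 1,
                )
            subs = [
                i
                for i in range(over_l, len(mutant) - over_r)
                if mutant[i] != ref[off_l + i]
            ]
            call = VariantCall(
                contig_id="",
                mutant_seq=mutant,
                ref_seq=ref,
                var_type="unresolved",
                pos_in_contig=0,
                pos_in_ref=off_l,
                ref_allele=ref[max(off_l, 0)],
                alt_allele=".",
            )
            if len(subs) == 1:
                i = subs[0]
                call.var_type = "mutation"
                call.pos_in_contig = i
                call.pos_in_ref = off_l + i
                call.ref_allele = ref[off_l + i]
                call.alt_allele = mutant[i]
            elif 2 <= len(subs) <= _MAX_SUBS:
                i0, i1 = subs[0], subs[-1]
                call.var_type = "multiple_mutation"
                call.pos_in_contig = i0
                call.pos_in_ref = off_l + i0
                call.ref_allele = ref[off_l + i0 : off_l + i1 + 1]
                call.alt_allele = mutant[i0 : i1 + 1]
            elif len(subs) > _MAX_SUBS:
                i = _walk_right(mutant, ref, off_l)
                return _breakpoint_call(mutant, ref, i - 1, off_l + i - 1)
            return call
        if abs(diff) >= sv_min_len:
            i = _walk_right(mutant, ref, off_l)
            call = _breakpoint_call(mutant, ref, i - 1, off_l + i - 1)
            j = _walk_left(mutant, ref, off_r)
            call.partner_ref_pos = min(max(off_r + j + 1, 0), len(ref) - 1)
            return call
        # small indel: anchor at the end of the exact left match
        i = _walk_right(mutant, ref, off_l)
        anchor = max(i - 1, 0)
        b_anchor = off_l + anchor
        if 0 <= b_anchor < len(ref):
            if diff > 0:  # deletion of `diff` reference bases
                ref_allele = ref[b_anchor : b_anchor + 1 + diff]
                alt_allele = ref[b_anchor]
            else:  # insertion of `-diff` mutant bases
                ins = mutant[anchor + 1 : anchor + 1 - diff]
                ref_allele = ref[b_anchor]
                alt_allele = ref[b_anchor] + ins
            b_anchor, ref_allele, alt_allele, anchor = _left_align_indel(
                ref, b_anchor, ref_allele, alt_allele, anchor
            )
            return VariantCall(
                contig_id="",
                mutant_seq=mutant,
                ref_seq=ref,
                var_type="indel",
                pos_in_contig=anchor,
                pos_in_ref=b_anchor,
                ref_allele=ref_allele,
                alt_allele=alt_allele,
            )
    elif offs_l:
        i = _walk_right(mutant, ref, offs_l[0])
        return _breakpoint_call(mutant, ref, i - 1, offs_l[0] + i - 1)
    elif offs_r:
        j = _walk_left(mutant, ref, offs_r[0])
        return _breakpoint_call(mutant, ref, j + 1, offs_r[0] + j + 1)

    if alignment is None:
        alignment = align_contig_pair(mutant, ref)
    am, bm = _trim_divergent_ends(alignment)
    subs: List[Tuple[int, int]] = []  # (mutant idx, ref idx)
    gap_runs: List[Tuple[str, int, int, int]] = []  # (kind, col, length, anchor cols)
    ai, bi = alignment.a_start, alignment.b_start
    col = 0
    while col < len(am):
        if am[col] == "-":  # ref has extra bases: deletion in mutant
            length = 0
            start_ai, start_bi = ai, bi
            while col < len(am) and am[col] == "-":
                length += 1
                bi += 1
                col += 1
            gap_runs.append(("del", start_ai, start_bi, length))
        elif bm[col] == "-":  # mutant has extra bases: insertion
            length = 0
            start_ai, start_bi = ai, bi
            while col < len(am) and bm[col] == "-":
                length += 1
                ai += 1
                col += 1
            gap_runs.append(("ins", start_ai, start_bi, length))
        else:
            if am[col] != bm[col]:
                subs.append((ai, bi))
            ai += 1
            bi += 1
            col += 1

    left_clip = alignment.a_start
    right_clip = len(mutant) - alignment.a_end
    net_gap = sum(l if kind == "ins" else -l for kind, _, _, l in gap_runs)
    max_gap = max((l for _, _, _, l in gap_runs), default=0)

    call = VariantCall(
        contig_id="",
        mutant_seq=mutant,
        ref_seq=ref,
        var_type="unresolved",
        pos_in_contig=alignment.a_start,
        pos_in_ref=alignment.b_start,
        ref_allele=ref[alignment.b_start] if ref else "N",
        alt_allele="<SV>",
    )

    if max_gap >= sv_min_len or abs(net_gap) >= sv_min_len:
        kind, g_ai, g_bi, _ = max(gap_runs, key=lambda g: g[3])
        anchor_a = max(g_ai - 1, 0)
        anchor_b = max(g_bi - 1, 0)
        call.var_type = "sv"
        call.pos_in_contig = anchor_a
        call.pos_in_ref = anchor_b
        call.ref_allele = ref[anchor_b]
        call.alt_allele = "<SV>"
        return call
    if max(left_clip, right_clip) >= sv_min_clip:
        call.var_type = "sv"
        if right_clip >= left_clip:
            call.pos_in_contig = alignment.a_end - 1
            call.pos_in_ref = alignment.b_end - 1
        else:
            call.pos_in_contig = alignment.a_start
            call.pos_in_ref = alignment.b_start
        call.ref_allele = ref[call.pos_in_ref]
        call.alt_allele = "<SV>"
        return call
    if gap_runs and abs(net_gap) >= 1:
        kind, g_ai, g_bi, length = gap_runs[0]
        anchor_a = max(g_ai - 1, 0)
        anchor_b = max(g_bi - 1, 0)
        if kind == "ins":
            ref_allele = ref[anchor_b]
            alt_allele = ref[anchor_b] + mutant[g_ai : g_ai + length]
        else:
            ref_allele = ref[anchor_b : g_bi + length]
            alt_allele = ref[anchor_b]
        anchor_b, ref_allele, alt_allele, anchor_a = _left_align_indel(
            ref, anchor_b, ref_allele, alt_allele, anchor_a
        )
        call.var_type = "indel"
        call.pos_in_contig = anchor_a
        call.pos_in_ref = anchor_b
        call.ref_allele = ref_allele
        call.alt_allele = alt_allele
        return call
    if len(subs) == 1:
        ai, bi = subs[0]
        call.var_type = "mutation"
        call.pos_in_contig = ai
        call.pos_in_ref = bi
        call.ref_allele = ref[bi]
        call.alt_allele = mutant[ai]
        return call
    if len(subs) >= 2:
        (a0, b0), (a1, b1) = subs[0], subs[-1]
        call.var_type = "multiple_mutation"
        call.pos_in_contig = a0
        call.pos_in_ref = b0
        call.ref_allele = ref[b0 : b1 + 1]
        call.alt_allele = mutant[a0 : a1 + 1]
        return call
    return call


# ---------------------------------------------------------------------------
# genome placement
# ---------------------------------------------------------------------------

def _find_all(haystack: str, needle: str) -> List[int]:
    out, i = [], haystack.find(needle)
    while i >= 0:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _hamming_le1(a: str, b: str) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > 1:
                return False
    return True


def locate_sequence(
    seq: str, genome: Dict[str, str]
) -> Optional[Tuple[str, int, str]]:
    """(chrom, 0-based pos, strand) of an exact or 1-mismatch placement."""
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for chrom in sorted(genome):
            i = genome[chrom].find(s)
            if i >= 0:
                return chrom, i, strand
    half = len(seq) // 2
    if half == 0:
        return None
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for chrom in sorted(genome):
            g = genome[chrom]
            for i in _find_all(g, s[:half]):
                if i + len(s) <= len(g) and _hamming_le1(g[i : i + len(s)], s):
                    return chrom, i, strand
            for i in _find_all(g, s[half:]):
                j = i - half
                if j >= 0 and j + len(s) <= len(g) and _hamming_le1(g[j : j + len(s)], s):
                    return chrom, j, strand
    return None


def place_call(call: VariantCall, genome: Dict[str, str]) -> None:
    """Lift a call onto genome coordinates via its reference (or mutant) contig.

    The pipeline orients contig pairs to the forward genome strand before
    typing, so a '+' placement is expected; calls that cannot be placed keep
    contig coordinates and are flagged UNMAPPED in the VCF.
    """
    target = call.ref_seq if call.ref_seq else call.mutant_seq
    loc = locate_sequence(target, genome)
    if loc is None:
        return
    chrom, pos0, strand = loc
    offset = call.pos_in_ref if call.ref_seq else call.pos_in_contig
    call.chrom = chrom
    if strand == "+":
        call.genome_pos = pos0 + offset + 1
        if call.partner_ref_pos is not None:
            call.partner_genome_pos = pos0 + call.partner_ref_pos + 1
    else:
        call.genome_pos = pos0 + (len(target) - 1 - offset) + 1
        if call.partner_ref_pos is not None:
            call.partner_genome_pos = pos0 + (len(target) - 1 - call.partner_ref_pos) + 1


# ---------------------------------------------------------------------------
# VCF export
# ---------------------------------------------------------------------------

_VCF_HEADER_INFO = [
    '##INFO=<ID=VTYPE,Number=1,Type=String,Description="Event type">',
    '##INFO=<ID=BRANCH,Number=1,Type=String,Description="Reference inference branch">',
    '##INFO=<ID=CSCOUNT,Number=1,Type=Integer,Description="Median case-specific k-mer count (case)">',
    '##INFO=<ID=COV,Number=1,Type=Integer,Description="Coverage of both alleles (case)">',
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency cs-count/coverage">',
    '##INFO=<ID=PHRED,Number=1,Type=Float,Description="-10*log10 of Fisher exact P">',
    '##INFO=<ID=CTRLCS,Number=1,Type=Integer,Description="Variant support in control">',
    '##INFO=<ID=CTRLCOV,Number=1,Type=Integer,Description="Coverage in control">',
    '##INFO=<ID=MCTG,Number=1,Type=String,Description="Mutant contig sequence">',
    '##INFO=<ID=RCTG,Number=1,Type=String,Description="Inferred reference contig sequence">',
    '##INFO=<ID=CONTIG,Number=1,Type=String,Description="Source contig id">',
    '##INFO=<ID=UNMAPPED,Number=0,Type=Flag,Description="Could not be placed on the supplied genome">',
    '##ALT=<ID=SV,Description="Structural variant breakpoint">',
]


def _vcf_record(call: VariantCall, genome_given: bool) -> str:
    if call.chrom is not None and call.genome_pos is not None:
        chrom, pos = call.chrom, call.genome_pos
        unmapped = False
    else:
        chrom, pos = call.contig_id, call.pos_in_contig + 1
        unmapped = genome_given
    info = [f"VTYPE={call.var_type}"]
    if call.branch:
        info.append(f"BRANCH={call.branch}")
    if call.stats is not None:
        s = call.stats
        info += [
            f"CSCOUNT={s.cs_count}",
            f"COV={s.coverage}",
            f"AF={s.af:.4f}",
            f"PHRED={s.phred:.2f}",
            f"CTRLCS={s.control_cs_count}",
            f"CTRLCOV={s.control_coverage}",
        ]
    info.append(f"CONTIG={call.contig_id}")
    info.append(f"MCTG={call.mutant_seq}")
    if call.ref_seq:
        info.append(f"RCTG={call.ref_seq}")
    if unmapped:
        info.append("UNMAPPED")
    qual = f"{call.stats.phred:.2f}" if call.stats else "."
    filt = "PASS" if call.passed else "lowqual"
    ref_allele = call.ref_allele if call.ref_allele else "N"
    alt_allele = call.alt_allele if call.alt_allele else "."
    return "\t".join(
        [chrom, str(pos), call.contig_id, ref_allele, alt_allele, qual, filt, ";".join(info)]
    )


def write_vcf(
    calls: Sequence[VariantCall],
    out_path: str,
    genome: Optional[Dict[str, str]] = None,
    source: str = "csvar",
) -> None:
    """Write calls as VCF v4.2, sorted by CHROM then POS."""
    lines = ["##fileformat=VCFv4.2", f"##source={source}"]
    if genome:
        for chrom in sorted(genome):
            lines.append(f"##contig=<ID={chrom},length={len(genome[chrom])}>")
    lines.extend(_VCF_HEADER_INFO)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    def sort_key(c: VariantCall):
        if c.chrom is not None and c.genome_pos is not None:
            return (0, c.chrom, c.genome_pos, c.contig_id)
        return (1, c.contig_id, c.pos_in_contig, c.contig_id)

    for call in sorted(calls, key=sort_key):
        lines.append(_vcf_record(call, genome is not None))
    with open(out_path, "w") as out:
        out.write("\n".join(lines) + "\n")


def read_vcf_calls(path: str) -> List[Dict[str, object]]:
    """Parse a csvar VCF back into plain records (round-trip/evaluation use)."""
    out: List[Dict[str, object]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            info: Dict[str, str] = {}
            for item in f[7].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    info[k] = v
                else:
                    info[item] = "1"
            out.append(
                {
                    "chrom": f[0],
                    "pos": int(f[1]),
                    "id": f[2],
                    "ref": f[3],
                    "alt": f[4],
                    "qual": None if f[5] == "." else float(f[5]),
                    "filter": f[6],
                    "info": info,
                }
            )
    return out
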