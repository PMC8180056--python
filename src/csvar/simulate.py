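"""Matched case/control read simulation with planted variants, plus truth-based
evaluation of calls.

The simulator plants point mutations (a configurable fraction of which are
small indels) at a per-base rate, assigns each event a variant allele
fraction (VAF), and adds structural variants (deletions, tandem duplications
and insertional translocations longer than 50 bp).  VAF is realized by
including each event in a sequenced fragment with probability VAF, which is
equivalent to mixing per-variant mutant haplotypes.  The control sample
receives zero variants.  Base errors get Phred 10; clean bases Phred 30.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from csvar.kmer import revcomp
from csvar.preprocess import ReadRecord

_BASES = "ACGT"
#: minimum spacing between planted events (anchors and SV spans)
_EVENT_MARGIN = 300


@dataclass
class SimulationConfig:
    genome_len: int = 500_000
    snv_rate: float = 0.0001
    indel_fraction: float = 0.2
    vaf_choices: Tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    coverage: float = 50.0
    read_len: int = 100
    paired: bool = True
    error_rate: float = 0.001
    # list of (type in {deletion, duplication, translocation}, length > 50)
    sv_events: Tuple[Tuple[str, int], ...] = ()
    fragment_mean: int = 300
    fragment_sd: int = 25
    with_repeat: bool = False

    def __post_init__(self) -> None:
        for r in (self.snv_rate, self.indel_fraction, self.error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for t, length in self.sv_events:
            if t not in ("deletion", "duplication", "translocation"):
                raise ValueError(f"unknown SV type {t!r}")
            if length <= 50:
                raise ValueError("SV lengths must exceed 50 bp")


@dataclass
class TruthVariant:
    """A planted event. ``pos`` is the 0-based anchor base in the reference.

    vtype: snv | ins | del | sv_del | sv_dup | sv_tra.  For insertions the
    inserted sequence follows the anchor; for deletions ``length`` reference
    bases after the anchor are removed; duplications anchor at the last base
    of the duplicated span; translocations insert a distant segment
    (``src``) after the anchor.
    """

    pos: int
    vtype: str
    ref: str
    alt: str
    vaf: float
    length: int = 0
    src: int = -1
    chrom: str = "chr1"


def truth_category(v: TruthVariant) -> str:
    if v.vtype == "snv":
        return "snv"
    if v.vtype in ("ins", "del"):
        return "indel"
    return "sv"


def call_category(var_type: str) -> Optional[str]:
    return {
        "mutation": "snv",
        "multiple_mutation": "snv",
        "indel": "indel",
        "sv": "sv",
    }.get(var_type)


# ---------------------------------------------------------------------------
# genome and variant planting
# ---------------------------------------------------------------------------

def generate_genome(length: int, seed: int, with_repeat: bool = False) -> str:
    """Uniform random ACGT sequence; optionally copies a 1 kb segment to a
    second locus to create an exact repeat."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    rng = np.random.default_rng(seed)
    arr = rng.integers(0, 4, size=length)
    genome = "".join(_BASES[i] for i in arr)
    if with_repeat and length >= 10_000:
        src = length // 4
        dst = 3 * length // 4
        seg = genome[src : src + 1000]
        genome = genome[:dst] + seg + genome[dst + 1000 :]
    return genome


def _pick_positions(
    rng: np.random.Generator, length: int, n: int, occupied: List[Tuple[int, int]], margin: int
) -> List[int]:
    out: List[int] = []
    tries = 0
    while len(out) < n and tries < 100 * n + 1000:
        tries += 1
        p = int(rng.integers(margin, length - margin))
        if all(p < a - margin or p > b + margin for a, b in occupied):
            occupied.append((p, p))
            out.append(p)
    return out


def plant_variants(
    genome: str, config: SimulationConfig, seed: int
) -> List[TruthVariant]:
    """Draw the truth set of non-overlapping planted events."""
    rng = np.random.default_rng(seed)
    L = len(genome)
    truth: List[TruthVariant] = []
    occupied: List[Tuple[int, int]] = []

    # structural variants first (they need room for their spans)
    for svtype, length in config.sv_events:
        vaf = float(rng.choice(config.vaf_choices))
        placed = False
        for _ in range(1000):
            start = int(rng.integers(_EVENT_MARGIN, L - length - _EVENT_MARGIN))
            span = (start, start + length)
            if not all(span[1] < a - _EVENT_MARGIN or span[0] > b + _EVENT_MARGIN for a, b in occupied):
                continue
            if svtype == "deletion":
                truth.append(
                    TruthVariant(
                        pos=start - 1,
                        vtype="sv_del",
                        ref=genome[start - 1 : start + length],
                        alt=genome[start - 1],
                        vaf=vaf,
                        length=length,
                    )
                )
            elif svtype == "duplication":
                truth.append(
                    TruthVariant(
                        pos=start + length - 1,
                        vtype="sv_dup",
                        ref=genome[start + length - 1],
                        alt="<DUP>",
                        vaf=vaf,
                        length=length,
                        src=start,
                    )
                )
            else:  # translocation: distant segment inserted at the anchor
                for _ in range(1000):
                    src = int(rng.integers(0, L - length))
                    if abs(src - start) > 10 * length + _EVENT_MARGIN:
                        break
                truth.append(
                    TruthVariant(
                        pos=start,
                        vtype="sv_tra",
                        ref=genome[start],
                        alt="<TRA>",
                        vaf=vaf,
                        length=length,
                        src=src,
                    )
                )
            occupied.append(span)
            placed = True
            break
        if not placed:
            raise ValueError("genome too short to place requested SVs")

    n_small = int(rng.binomial(L, config.snv_rate))
    for pos in _pick_positions(rng, L, n_small, occupied, _EVENT_MARGIN):
        vaf = float(rng.choice(config.vaf_choices))
        if rng.random() < config.indel_fraction:
            ilen = int(rng.integers(1, 11))
            if rng.random() < 0.5:  # insertion
                ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=ilen))
                truth.append(
                    TruthVariant(
                        pos=pos,
                        vtype="ins",
                        ref=genome[pos],
                        alt=genome[pos] + ins,
                        vaf=vaf,
                        length=ilen,
                    )
                )
            else:
                truth.append(
                    TruthVariant(
                        pos=pos,
                        vtype="del",
                        ref=genome[pos : pos + 1 + ilen],
                        alt=genome[pos],
                        vaf=vaf,
                        length=ilen,
                    )
                )
        else:
            ref = genome[pos]
            alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            truth.append(
                TruthVariant(pos=pos, vtype="snv", ref=ref, alt=alt, vaf=vaf)
            )
    truth.sort(key=lambda v: v.pos)
    return truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _apply_event(local: str, i: int, ev: TruthVariant, genome: str) -> str:
    if ev.vtype == "snv":
        return local[:i] + ev.alt + local[i + 1 :]
    if ev.vtype == "ins":
        return local[: i + 1] + ev.alt[1:] + local[i + 1 :]
    if ev.vtype in ("del", "sv_del"):
        return local[: i + 1] + local[i + 1 + ev.length :]
    if ev.vtype == "sv_dup":
        seg = genome[ev.src : ev.src + ev.length]
        return local[: i + 1] + seg + local[i + 1 :]
    if ev.vtype == "sv_tra":
        seg = genome[ev.src : ev.src + ev.length]
        return local[: i + 1] + seg + local[i + 1 :]
    raise ValueError(f"unknown event type {ev.vtype!r}")


def simulate_reads(
    genome: str,
    truth: Sequence[TruthVariant],
    config: SimulationConfig,
    seed: int,
    sample: str = "case",
) -> Tuple[List[ReadRecord], List[ReadRecord]]:
    """Simulate reads; returns (mate-1 list, mate-2 list).

    ``sample="control"`` ignores the truth set entirely.  Single-end mode
    returns an empty second list.  Read count follows
    genome_len * coverage / (read_len * mates).
    """
    rng = np.random.default_rng(seed)
    L = len(genome)
    rl = config.read_len
    mates = 2 if config.paired else 1
    n_frags = int(round(L * config.coverage / (rl * mates)))
    events = list(truth) if sample == "case" else []
    positions = np.array([ev.pos for ev in events], dtype=np.int64)
    max_del = max(
        (ev.length for ev in events if ev.vtype in ("del", "sv_del")), default=0
    )

    frag_lens = (
        np.clip(
            np.rint(rng.normal(config.fragment_mean, config.fragment_sd, size=n_frags)),
            2 * rl if config.paired else rl,
            None,
        ).astype(np.int64)
        if config.paired
        else np.full(n_frags, rl, dtype=np.int64)
    )
    wlens = frag_lens + max_del + 20
    starts = (rng.random(n_frags) * (L - wlens)).astype(np.int64)
    incl_draws = rng.random((n_frags, min(len(events), 8) or 1))

    r1: List[ReadRecord] = []
    r2: List[ReadRecord] = []
    frags: List[str] = []
    for fi in range(n_frags):
        s = int(starts[fi])
        flen = int(frag_lens[fi])
        wlen = int(wlens[fi])
        lo = int(np.searchsorted(positions, s, side="left"))
        hi = int(np.searchsorted(positions, s + wlen, side="left"))
        if lo == hi:
            frag = genome[s : s + flen]
        else:
            local = genome[s : s + wlen]
            for en, ei in enumerate(range(hi - 1, lo - 1, -1)):
                ev = events[ei]
                draw = incl_draws[fi, en] if en < incl_draws.shape[1] else rng.random()
                if draw < ev.vaf:
                    local = _apply_event(local, ev.pos - s, ev, genome)
            frag = local[:flen]
        frags.append(frag)

    # sequencing errors: global draw, then applied per read
    n_reads = n_frags * mates
    n_err = int(rng.binomial(n_reads * rl, config.error_rate))
    err_by_read: Dict[int, List[int]] = defaultdict(list)
    if n_err:
        err_reads = rng.integers(0, n_reads, size=n_err)
        err_pos = rng.integers(0, rl, size=n_err)
        err_shift = rng.integers(1, 4, size=n_err)
        for ridx, p, sh in zip(err_reads.tolist(), err_pos.tolist(), err_shift.tolist()):
            err_by_read[ridx].append((p << 2) | sh)

    clean_quals = bytes([30] * rl)

    def make_read(idx: int, seq: str, name: str, mate: Optional[int]) -> ReadRecord:
        errs = err_by_read.get(idx)
        if not errs:
            return ReadRecord(name, seq, clean_quals, mate)
        bases = list(seq)
        quals = bytearray(clean_quals)
        for packed in errs:
            p, sh = packed >> 2, packed & 3
            bases[p] = _BASES[(_BASES.index(bases[p]) + sh) % 4]
            quals[p] = 10
        return ReadRecord(name, "".join(bases), bytes(quals), mate)

    for fi, frag in enumerate(frags):
        if config.paired:
            r1.append(make_read(2 * fi, frag[:rl], f"{sample}_{fi}/1", 1))
            r2.append(make_read(2 * fi + 1, revcomp(frag[-rl:]), f"{sample}_{fi}/2", 2))
        else:
            r1.append(make_read(fi, frag[:rl], f"{sample}_{fi}", None))
    return r1, r2


# ---------------------------------------------------------------------------
# truth I/O
# ---------------------------------------------------------------------------

def write_genome_fasta(genome: str, path: str, chrom: str = "chr1") -> None:
    with open(path, "w") as out:
        out.write(f">{chrom}\n")
        for i in range(0, len(genome), 80):
            out.write(genome[i : i + 80] + "\n")


def read_genome_fasta(path: str) -> Dict[str, str]:
    genome: Dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


def write_truth_vcf(truth: Sequence[TruthVariant], path: str, genome_len: int = 0) -> None:
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n##source=csvar-simulate\n")
        if genome_len:
            out.write(f"##contig=<ID=chr1,length={genome_len}>\n")
        out.write(
            '##INFO=<ID=TYPE,Number=1,Type=String,Description="Planted event type">\n'
            '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">\n'
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Event length">\n'
            '##INFO=<ID=SRC,Number=1,Type=Integer,Description="Source locus (0-based)">\n'
        )
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, v in enumerate(sorted(truth, key=lambda t: t.pos)):
            info = f"TYPE={v.vtype};VAF={v.vaf:g}"
            if v.length:
                info += f";SVLEN={v.length}"
            if v.src >= 0:
                info += f";SRC={v.src}"
            out.write(
                f"{v.chrom}\t{v.pos + 1}\ttruth_{i + 1}\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n"
            )


def read_truth_vcf(path: str) -> List[TruthVariant]:
    out: List[TruthVariant] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            info = dict(
                item.split("=", 1) if "=" in item else (item, "1")
                for item in f[7].split(";")
            )
            out.append(
                TruthVariant(
                    pos=int(f[1]) - 1,
                    vtype=info.get("TYPE", "snv"),
                    ref=f[3],
                    alt=f[4],
                    vaf=float(info.get("VAF", 0.5)),
                    length=int(info.get("SVLEN", 0)),
                    src=int(info.get("SRC", -1)),
                    chrom=f[0],
                )
            )
    return out


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def metrics_from_counts(tp: int, fp: int, fn: int) -> Dict[str, float]:
    """Recall/FDR/precision/F1 from confusion counts.

    Degenerate denominators yield 0.0 and set ``defined`` to False.
    """
    defined = True
    recall = tp / (tp + fn) if tp + fn else 0.0
    if tp + fp:
        precision = tp / (tp + fp)
        fdr = fp / (tp + fp)
    else:
        precision, fdr, defined = 0.0, 0.0, False
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return {
        "TP": tp,
        "FP": fp,
        "FN": fn,
        "recall": recall,
        "FDR": fdr,
        "precision": precision,
        "F1": f1,
        "defined": defined,
    }


def _call_pos0(call) -> Optional[Tuple[str, int, Optional[str]]]:
    """(chrom, 0-based pos, category) from a VariantCall or a VCF record dict."""
    if isinstance(call, dict):
        cat = call_category(str(call["info"].get("VTYPE", "")))
        return str(call["chrom"]), int(call["pos"]) - 1, cat
    if call.chrom is None or call.genome_pos is None:
        return None
    return call.chrom, call.genome_pos - 1, call_category(call.var_type)


def truth_targets(v: TruthVariant) -> List[List[int]]:
    """Matchable targets (lists of acceptable 0-based positions) for an event.

    SNVs and small indels have a single anchor.  A structural variant is
    matched at any of its genomic breakpoints, because a junction contig can
    be anchored on either side of the novel junction (the caller merges
    breakend-partner calls of one event before export).
    """
    if truth_category(v) != "sv":
        return [[v.pos]]
    if v.vtype == "sv_del":
        return [[v.pos, v.pos + v.length]]
    if v.vtype == "sv_dup":
        return [[v.pos, v.src]]
    if v.vtype == "sv_tra":
        return [[v.pos, v.src, v.src + v.length - 1]]
    return [[v.pos]]


def evaluate_calls(
    calls: Sequence[object],
    truth: Sequence[TruthVariant],
    tolerance: int = 10,
) -> Dict[str, Dict[str, float]]:
    """Match calls against the truth set and compute per-category metrics.

    A call matches an unmatched truth target of the same category when the
    positions agree exactly (SNV) or within ``tolerance`` bp (indel/SV).
    Each truth target matches at most one call.  Unplaced calls count as
    false positives.  Returns metrics for 'snv', 'indel', 'sv' and 'overall'.
    """
    # targets: (chrom, category, acceptable positions)
    targets: List[Tuple[str, str, List[int]]] = []
    for t in truth:
        for positions in truth_targets(t):
            targets.append((t.chrom, truth_category(t), positions))
    n_targets = {c: 0 for c in ("snv", "indel", "sv")}
    for _, cat, _ in targets:
        n_targets[cat] += 1
    matched = [False] * len(targets)
    counts = {c: {"TP": 0, "FP": 0} for c in ("snv", "indel", "sv")}

    prepared = [_call_pos0(call) for call in calls]
    for loc in sorted(
        (l for l in prepared if l is not None and l[2] is not None),
        key=lambda l: (l[0], l[1]),
    ):
        chrom, pos0, cat = loc
        tol = 0 if cat == "snv" else tolerance
        best = None
        for ti, (t_chrom, t_cat, positions) in enumerate(targets):
            if matched[ti] or t_chrom != chrom or t_cat != cat:
                continue
            d = min(abs(p - pos0) for p in positions)
            if d <= tol and (best is None or d < best[0]):
                best = (d, ti)
        if best is None:
            counts[cat]["FP"] += 1
        else:
            matched[best[1]] = True
            counts[cat]["TP"] += 1
    # unplaced or unresolved calls are overall false positives
    n_uncategorized = sum(1 for l in prepared if l is None or l[2] is None)

    out: Dict[str, Dict[str, float]] = {}
    tot_tp = tot_fp = tot_fn = 0
    for cat in ("snv", "indel", "sv"):
        tp = counts[cat]["TP"]
        fp = counts[cat]["FP"]
        fn = n_targets[cat] - tp
        out[cat] = metrics_from_counts(tp, fp, fn)
        tot_tp += tp
        tot_fp += fp
        tot_fn += fn
    out["overall"] = metrics_from_counts(tot_tp, tot_fp + n_uncategorized, tot_fn)
    return out
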