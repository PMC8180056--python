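"""End-to-end orchestration: clean -> count -> contrast -> match -> assemble ->
infer reference -> score -> type -> export.

Stage products are checkpointed as small text files in the output directory
(cs-kmer TSV, pair TSV, contig FASTA, stats TSV, VCFs) so individual stages
can be inspected or rerun.  Execution is single-threaded and fully
deterministic; the ``threads`` option is accepted for interface
compatibility and never changes results.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from csvar import assembly, kmer, matching, preprocess, refinfer, scoring, variants
from csvar.simulate import read_genome_fasta

logger = logging.getLogger("csvar")


@dataclass
class PipelineConfig:
    case_fastqs: Sequence[str] = ()
    control_fastqs: Sequence[str] = ()
    k: int = kmer.DEFAULT_K
    min_count: int = kmer.DEFAULT_MIN_COUNT
    max_control_count: Optional[int] = None  # default: min_count - 1
    min_overlap: int = assembly.DEFAULT_MIN_OVERLAP
    min_read_overlap: int = refinfer.DEFAULT_MIN_READ_OVERLAP
    quality_cutoff: int = preprocess.DEFAULT_QUALITY_CUTOFF
    mask_threshold: int = preprocess.DEFAULT_MASK_THRESHOLD
    min_cs_count: int = scoring.DEFAULT_MIN_CS_COUNT
    min_cov: int = scoring.DEFAULT_MIN_COV
    min_af: float = scoring.DEFAULT_MIN_AF
    min_phred: float = scoring.DEFAULT_MIN_PHRED
    genome_path: Optional[str] = None
    normal_fastqs: Sequence[Sequence[str]] = ()
    max_normals: int = 1
    threads: int = 10
    outdir: str = "csvar_out"

    def resolved_max_control_count(self) -> int:
        if self.max_control_count is not None:
            return self.max_control_count
        return self.min_count - 1


def _load_cleaned(paths: Sequence[str], cfg: PipelineConfig) -> List[str]:
    seqs: List[str] = []
    for path in paths:
        if not os.path.exists(path):
            raise FileNotFoundError(f"input FASTQ not found: {path}")
        for read in preprocess.read_fastq(path):
            cleaned = preprocess.clean_read(read, cfg.quality_cutoff, cfg.mask_threshold)
            if len(cleaned) > 0:
                seqs.append(cleaned.bases)
    return seqs


def _orient_pair_to_genome(
    mutant: str, ref: Optional[str], genome: Optional[Dict[str, str]]
) -> Tuple[str, Optional[str]]:
    """Flip the contig pair so its placement target lies on the + strand."""
    if not genome:
        return mutant, ref
    target = ref if ref else mutant
    loc = variants.locate_sequence(target, genome)
    if loc is not None and loc[2] == "-":
        mutant = kmer.revcomp(mutant)
        ref = kmer.revcomp(ref) if ref else None
    return mutant, ref


def _sv_coords(call: variants.VariantCall, genome: Dict[str, str]) -> List[Tuple[str, int]]:
    """Breakend coordinates of an sv call: its anchor plus the placements of
    the clipped (foreign) contig segment, which is the partner breakend."""
    coords: List[Tuple[str, int]] = [(call.chrom, call.genome_pos)]
    if call.partner_genome_pos is not None:
        coords.append((call.chrom, call.partner_genome_pos))
    for seg in (
        call.mutant_seq[: call.pos_in_contig],
        call.mutant_seq[call.pos_in_contig + 1 :],
    ):
        if len(seg) < 16:
            continue
        loc = variants.locate_sequence(seg, genome)
        if loc is not None:
            chrom, pos0, strand = loc
            coords.append((chrom, pos0 + 1))
            coords.append((chrom, pos0 + len(seg)))
    return coords


def _dedup_calls(
    calls: List[variants.VariantCall],
    genome: Optional[Dict[str, str]],
    link_tolerance: int = 30,
) -> Tuple[List[variants.VariantCall], List[variants.VariantCall]]:
    """Collapse redundant placed calls.

    Exact duplicates (same locus, type and alleles, e.g. from a split
    contig) are collapsed for all types.  sv calls are additionally linked
    when any of their breakend coordinates lie within ``link_tolerance``:
    the two junction contigs of one translocation (or a split junction
    contig) then export as a single representative call.
    """
    keep: List[variants.VariantCall] = []
    dropped: List[variants.VariantCall] = []

    def phred(c: variants.VariantCall) -> float:
        return c.stats.phred if c.stats else 0.0

    by_locus: Dict[Tuple, variants.VariantCall] = {}
    svs: List[variants.VariantCall] = []
    for c in sorted(calls, key=lambda c: (-phred(c), c.contig_id)):
        if c.chrom is None or c.genome_pos is None:
            keep.append(c)
            continue
        if c.var_type == "sv" and genome:
            svs.append(c)
            continue
        key = (c.chrom, c.genome_pos, c.var_type, c.ref_allele, c.alt_allele)
        if key in by_locus:
            dropped.append(c)
        else:
            by_locus[key] = c
            keep.append(c)

    if svs:
        coords = [_sv_coords(c, genome) for c in svs]

        def windows(seq: str, w: int = 16) -> set:
            out = set()
            for s in (seq, kmer.revcomp(seq)):
                out.update(s[i : i + w] for i in range(len(s) - w + 1))
            return out

        winsets = [windows(c.mutant_seq) for c in svs]
        parent = list(range(len(svs)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(svs)):
            for j in range(i + 1, len(svs)):
                linked = any(
                    ci[0] == cj[0] and abs(ci[1] - cj[1]) <= link_tolerance
                    for ci in coords[i]
                    for cj in coords[j]
                ) or not winsets[i].isdisjoint(winsets[j])
                if linked:
                    parent[find(i)] = find(j)
        clusters: Dict[int, List[variants.VariantCall]] = {}
        for i, c in enumerate(svs):
            clusters.setdefault(find(i), []).append(c)
        for members in clusters.values():
            members.sort(key=lambda c: (-phred(c), c.contig_id))
            keep.append(members[0])
            dropped.extend(members[1:])
    return keep, dropped


def run_call(cfg: PipelineConfig) -> Dict[str, object]:
    """Run the full variant-calling workflow; returns a result summary.

    Outputs in ``cfg.outdir``: calls.vcf (passing calls), rejected.vcf,
    contigs.fa, cs_kmers.tsv, pairs.tsv, stats.tsv and run.log.
    """
    t0 = time.time()
    if not cfg.case_fastqs or not cfg.control_fastqs:
        raise ValueError("both case and control FASTQ inputs are required")
    for p in list(cfg.case_fastqs) + list(cfg.control_fastqs):
        if not os.path.exists(p):
            raise FileNotFoundError(f"input FASTQ not found: {p}")
    os.makedirs(cfg.outdir, exist_ok=True)
    log_path = os.path.join(cfg.outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        stage = "preprocess"
        case_seqs = _load_cleaned(cfg.case_fastqs, cfg)
        control_seqs = _load_cleaned(cfg.control_fastqs, cfg)
        logger.info(
            "cleaned reads: case=%d control=%d", len(case_seqs), len(control_seqs)
        )

        stage = "count"
        case_raw = kmer.count_kmers(case_seqs, cfg.k)
        control_raw = kmer.count_kmers(control_seqs, cfg.k)
        case_f = kmer.filter_low_count(case_raw, cfg.min_count)
        control_f = kmer.filter_low_count(control_raw, cfg.min_count)
        logger.info(
            "k-mers (raw/filtered): case=%d/%d control=%d/%d",
            len(case_raw), len(case_f), len(control_raw), len(control_f),
        )

        stage = "cs-extract"
        cs = kmer.extract_cs_kmers(
            case_f, control_f, control_raw, cfg.resolved_max_control_count()
        )
        if cfg.normal_fastqs:
            panel = []
            for paths in cfg.normal_fastqs:
                normal_seqs = _load_cleaned(paths, cfg)
                panel.append(kmer.count_kmers(normal_seqs, cfg.k))
            cs = kmer.filter_panel_of_normals(cs, panel, cfg.max_normals)
        logger.info("cs-kmers: %d", len(cs))
        with open(os.path.join(cfg.outdir, "cs_kmers.tsv"), "w") as out:
            out.write("kmer\tcase_count\tcontrol_raw_count\n")
            for km in sorted(cs.kmers):
                out.write(f"{km}\t{cs.case_counts[km]}\t{cs.control_raw_counts[km]}\n")

        stage = "match"
        pairs = matching.match_cs_kmers(cs, control_f)
        matched, unmatched = matching.partition_cs_kmers(cs, pairs)
        logger.info("matched=%d unmatched=%d", len(matched), len(unmatched))
        matching.pairs_to_tsv(pairs, os.path.join(cfg.outdir, "pairs.tsv"))

        stage = "assemble"
        contigs = assembly.assemble_contigs(cs, cfg.min_overlap, pairs)
        assembly.contigs_to_fasta(contigs, os.path.join(cfg.outdir, "contigs.fa"))
        logger.info("contigs: %d", len(contigs))

        stage = "infer-reference"
        need_reads: List[int] = []
        merged_refs: Dict[int, Optional[str]] = {}
        for i, contig in enumerate(contigs):
            if contig.matched_fraction > 0.5:
                merged_refs[i] = refinfer.infer_reference_matched(contig, cfg.min_overlap)
                if merged_refs[i] is None:
                    need_reads.append(i)
            else:
                need_reads.append(i)
        retrieved = refinfer.retrieve_control_reads_batch(
            [contigs[i] for i in need_reads], control_seqs, cfg.k
        )
        reads_for = {i: r for i, r in zip(need_reads, retrieved)}
        inferences: List[refinfer.InferredReference] = []
        for i, contig in enumerate(contigs):
            inferences.append(
                refinfer.infer_reference(
                    contig,
                    case_raw,
                    control_raw,
                    reads_for.get(i, []),
                    cfg.min_overlap,
                    cfg.min_read_overlap,
                )
            )

        stage = "score"
        stats_list: List[scoring.VariantStats] = []
        for inf in inferences:
            stats_list.append(
                scoring.make_stats(
                    inf.cs_count_case,
                    inf.coverage_case,
                    inf.cs_count_control,
                    inf.coverage_control,
                )
            )
        with open(os.path.join(cfg.outdir, "stats.tsv"), "w") as out:
            out.write(
                "contig_id\tbranch\tref_seq\tcs_count_case\tcoverage_case\t"
                "cs_count_control\tcoverage_control\tn_support_reads\t"
                "af\tp_value\tphred\n"
            )
            for contig, inf, st in zip(contigs, inferences, stats_list):
                out.write(
                    f"{contig.id}\t{inf.branch}\t{inf.ref_seq or '.'}\t"
                    f"{inf.cs_count_case}\t{inf.coverage_case}\t"
                    f"{inf.cs_count_control}\t{inf.coverage_control}\t"
                    f"{inf.n_support_reads}\t{st.af:.4f}\t{st.p_value:.4g}\t"
                    f"{st.phred:.2f}\n"
                )

        stage = "type-export"
        genome = read_genome_fasta(cfg.genome_path) if cfg.genome_path else None
        calls: List[variants.VariantCall] = []
        for contig, inf, st in zip(contigs, inferences, stats_list):
            mutant, ref = _orient_pair_to_genome(contig.seq, inf.ref_seq, genome)
            aln = variants.align_contig_pair(mutant, ref) if ref else None
            call = variants.classify_variant(
                aln, mutant, ref, evidence=len(contig.members) > 1
            )
            call.contig_id = contig.id
            call.branch = inf.branch
            call.stats = st
            call.passed = scoring.apply_filters(
                st, cfg.min_cs_count, cfg.min_cov, cfg.min_af, cfg.min_phred
            )
            if genome:
                variants.place_call(call, genome)
            calls.append(call)

        passing = [c for c in calls if c.passed]
        rejected = [c for c in calls if not c.passed]
        passing, duplicates = _dedup_calls(passing, genome)
        rejected.extend(duplicates)
        vcf_path = os.path.join(cfg.outdir, "calls.vcf")
        variants.write_vcf(passing, vcf_path, genome)
        variants.write_vcf(rejected, os.path.join(cfg.outdir, "rejected.vcf"), genome)
        logger.info(
            "calls: %d passing, %d rejected (%.1fs)",
            len(passing), len(rejected), time.time() - t0,
        )
        return {
            "vcf": vcf_path,
            "rejected_vcf": os.path.join(cfg.outdir, "rejected.vcf"),
            "contigs_fasta": os.path.join(cfg.outdir, "contigs.fa"),
            "stats_tsv": os.path.join(cfg.outdir, "stats.tsv"),
            "log": log_path,
            "n_cs_kmers": len(cs),
            "n_contigs": len(contigs),
            "n_passing": len(passing),
            "calls": passing,
            "rejected": rejected,
        }
    except Exception as exc:
        logger.exception("pipeline failed at stage %s", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
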