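"""End-to-end benchmark harness: simulate a matched pair, run the caller,
score against truth.  Used by the acceptance suite and report script."""

from __future__ import annotations

import os
import shutil
import tempfile
from typing import Dict, Optional, Sequence, Tuple

from csvar.pipeline import PipelineConfig, run_call
from csvar.preprocess import write_fastq
from csvar.simulate import (
    SimulationConfig,
    evaluate_calls,
    generate_genome,
    metrics_from_counts,
    plant_variants,
    simulate_reads,
    write_genome_fasta,
    write_truth_vcf,
)

#: protocol defaults mirroring the benchmarked WGS simulation: 50X paired
#: 2x100 reads, case mutation rate 1e-4 (20% indels), VAF 0.1-0.5, and a
#: panel of structural variants longer than 50 bp
BENCH_SV_EVENTS: Tuple[Tuple[str, int], ...] = tuple(
    [
        ("deletion", 120),
        ("deletion", 300),
        ("duplication", 90),
        ("duplication", 200),
        ("translocation", 80),
        ("translocation", 250),
    ]
    * 2
)


def bench_config(genome_len: int = 500_000) -> SimulationConfig:
    return SimulationConfig(
        genome_len=genome_len,
        snv_rate=0.0001,
        indel_fraction=0.2,
        vaf_choices=(0.1, 0.2, 0.3, 0.4, 0.5),
        coverage=50.0,
        read_len=100,
        paired=True,
        error_rate=0.001,
        sv_events=BENCH_SV_EVENTS,
    )


def run_benchmark_seed(
    seed: int,
    workdir: Optional[str] = None,
    genome_len: int = 500_000,
) -> Dict[str, Dict[str, float]]:
    """Simulate, call and evaluate one replicate; returns evaluate_calls output.

    All randomness derives from ``seed``.  ``workdir`` (a scratch directory)
    is created and removed automatically when not supplied.
    """
    own_dir = workdir is None
    workdir = workdir or tempfile.mkdtemp(prefix="csvar_bench_")
    os.makedirs(workdir, exist_ok=True)
    try:
        cfg = bench_config(genome_len)
        genome = generate_genome(cfg.genome_len, seed * 10 + 1)
        truth = plant_variants(genome, cfg, seed * 10 + 2)
        case = simulate_reads(genome, truth, cfg, seed * 10 + 3, "case")
        ctrl = simulate_reads(genome, truth, cfg, seed * 10 + 4, "control")
        genome_path = os.path.join(workdir, "genome.fa")
        write_genome_fasta(genome, genome_path)
        write_truth_vcf(truth, os.path.join(workdir, "truth.vcf"), len(genome))
        paths = {}
        for name, (r1, r2) in (("case", case), ("control", ctrl)):
            p1 = os.path.join(workdir, f"{name}_1.fq")
            p2 = os.path.join(workdir, f"{name}_2.fq")
            write_fastq(r1, p1)
            write_fastq(r2, p2)
            paths[name] = [p1, p2]
        result = run_call(
            PipelineConfig(
                case_fastqs=paths["case"],
                control_fastqs=paths["control"],
                genome_path=genome_path,
                outdir=os.path.join(workdir, "out"),
            )
        )
        return evaluate_calls(result["calls"], truth)
    finally:
        if own_dir:
            shutil.rmtree(workdir, ignore_errors=True)


def aggregate_benchmark(
    seeds: Sequence[int],
    genome_len: int = 500_000,
    workroot: Optional[str] = None,
) -> Dict[str, Dict[str, float]]:
    """Pool confusion counts over replicates and recompute the metrics."""
    agg = {c: {"TP": 0, "FP": 0, "FN": 0} for c in ("snv", "indel", "sv")}
    for seed in seeds:
        workdir = os.path.join(workroot, f"seed_{seed}") if workroot else None
        m = run_benchmark_seed(seed, workdir, genome_len)
        for cat in agg:
            for key in agg[cat]:
                agg[cat][key] += int(m[cat][key])
    return {
        cat: metrics_from_counts(v["TP"], v["FP"], v["FN"]) for cat, v in agg.items()
    }
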