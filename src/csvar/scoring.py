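"""Variant scoring: allele frequency, Fisher exact test, Phred quality, filters."""

from __future__ import annotations

from dataclasses import dataclass
from math import log10
from typing import Optional

from scipy.stats import hypergeom

DEFAULT_MIN_CS_COUNT = 3
DEFAULT_MIN_COV = 10
DEFAULT_MIN_AF = 0.05
DEFAULT_MIN_PHRED = 5.0

#: p-values are floored here before the Phred transform, capping the score.
MIN_PVALUE = 1e-300


@dataclass
class VariantStats:
    cs_count: int
    coverage: int
    af: float
    p_value: float
    phred: float
    control_cs_count: int = 0
    control_coverage: int = 0


def fisher_pvalue(
    cs_case: int, cov_case: int, cs_ctrl: int, cov_ctrl: int, two_sided: bool = False
) -> float:
    """Fisher exact test on the 2x2 table [[cs_case, cs_ctrl], [ref_case, ref_ctrl]].

    Rows are (variant support, reference support) and columns (case, control).
    The default is the one-sided upper hypergeometric tail for enrichment of
    the variant allele in the case library; ``two_sided=True`` gives the
    conventional two-sided test.
    """
    if not (cov_case >= cs_case >= 0 and cov_ctrl >= cs_ctrl >= 0):
        raise ValueError("require cov >= cs >= 0 in both libraries")
    n_total = cov_case + cov_ctrl
    if n_total == 0:
        return 1.0
    k_variant = cs_case + cs_ctrl
    if two_sided:
        from scipy.stats import fisher_exact

        table = [[cs_case, cs_ctrl], [cov_case - cs_case, cov_ctrl - cs_ctrl]]
        return float(fisher_exact(table, alternative="two-sided")[1])
    # P(X >= cs_case) for X ~ Hypergeom(N=n_total, K=k_variant, n=cov_case)
    return float(hypergeom.sf(cs_case - 1, n_total, k_variant, cov_case))


def phred_score(p: float) -> float:
    """-10*log10(p); p is floored at MIN_PVALUE so the score is capped."""
    if p > 1.0:
        raise ValueError("p-value > 1")
    return -10.0 * log10(max(p, MIN_PVALUE))


def make_stats(
    cs_case: int, cov_case: int, cs_ctrl: int, cov_ctrl: int
) -> VariantStats:
    """Bundle the per-call statistics from the four support counts."""
    p = fisher_pvalue(cs_case, cov_case, cs_ctrl, cov_ctrl)
    return VariantStats(
        cs_count=cs_case,
        coverage=cov_case,
        af=cs_case / cov_case if cov_case > 0 else 0.0,
        p_value=p,
        phred=phred_score(p),
        control_cs_count=cs_ctrl,
        control_coverage=cov_ctrl,
    )


def apply_filters(
    stats: VariantStats,
    min_cs: int = DEFAULT_MIN_CS_COUNT,
    min_cov: int = DEFAULT_MIN_COV,
    min_af: float = DEFAULT_MIN_AF,
    min_phred: float = DEFAULT_MIN_PHRED,
) -> bool:
    """True iff all four inclusive thresholds are met."""
    return (
        stats.cs_count >= min_cs
        and stats.coverage >= min_cov
        and stats.af >= min_af
        and stats.phred >= min_phred
    )
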