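import itertools

import pytest

from csvar.assembly import assemble_contigs
from csvar.kmer import (
    CsKmerSet,
    KmerCountTable,
    canonicalize,
    count_kmers,
    filter_low_count,
    extract_cs_kmers,
    revcomp,
)
from csvar.matching import match_cs_kmers
from csvar.preprocess import ReadRecord
from csvar.refinfer import (
    assemble_control_reads,
    compute_kmer_stats,
    infer_reference,
    infer_reference_matched,
    median_int,
    retrieve_control_reads,
)

from conftest import make_read, random_seq


def snv_fixture(rng, k=31, flank=200):
    """Wild-type sequence, mutant with one SNV, cs set, pairs and contig."""
    wt = random_seq(rng, 2 * flank)
    pos = flank
    alt = "ACGT"[("ACGT".index(wt[pos]) + 1) % 4]
    mut = wt[:pos] + alt + wt[pos + 1 :]
    window = mut[pos - k + 1 : pos + k]
    cs_kmers = {canonicalize(window[i : i + k]) for i in range(len(window) - k + 1)}
    cs = CsKmerSet(
        k=k,
        kmers=cs_kmers,
        case_counts={km: 7 for km in cs_kmers},
        control_raw_counts={km: 0 for km in cs_kmers},
    )
    control = count_kmers([wt], k)
    pairs = match_cs_kmers(cs, control)
    contigs = assemble_contigs(cs, 25, pairs)
    assert len(contigs) == 1
    return wt, mut, pos, cs, control, pairs, contigs[0]


class TestMedianInt:
    def test_odd(self):
        assert median_int([9, 5, 7]) == 7

    def test_single(self):
        assert median_int([4]) == 4

    def test_even_mean_of_middles(self):
        assert median_int([4, 6]) == 5

    def test_even_half_rounds_down(self):
        assert median_int([4, 5]) == 4

    def test_empty(self):
        assert median_int([]) == 0

    def test_against_sort_oracle(self, rng):
        for _ in range(100):
            vals = [int(v) for v in rng.integers(0, 50, size=int(rng.integers(1, 15)))]
            s = sorted(vals)
            n = len(s)
            if n % 2:
                expected = s[n // 2]
            else:
                lo, hi = s[n // 2 - 1], s[n // 2]
                expected = int((lo + hi) // 2)  # mean of middles, half down
            assert median_int(vals) == expected


class TestInferReferenceMatched:
    def test_snv_reverted(self, rng):
        wt, mut, pos, cs, control, pairs, contig = snv_fixture(rng)
        assert contig.matched_fraction == 1.0
        ref = infer_reference_matched(contig, 25)
        window_wt = wt[pos - 30 : pos + 31]
        assert ref in (window_wt, revcomp(window_wt))

    def test_rejects_low_matched_fraction(self, rng):
        wt, mut, pos, cs, control, pairs, contig = snv_fixture(rng)
        for m in contig.members:
            m.matched = False
            m.pair = None
        with pytest.raises(ValueError):
            infer_reference_matched(contig, 25)

    def test_boundary_half_routes_to_read_assembly(self, rng):
        wt, mut, pos, cs, control, pairs, contig = snv_fixture(rng)
        half = len(contig.members) // 2
        for m in contig.members[half:]:
            m.matched = False
            m.pair = None
        if contig.matched_fraction > 0.5:
            for m in contig.members[half - 1 :]:
                m.matched = False
                m.pair = None
        assert contig.matched_fraction <= 0.5
        case_t = KmerCountTable(31, dict(cs.case_counts))
        inf = infer_reference(contig, case_t, KmerCountTable(31), [], 25)
        assert inf.branch == "read_assembly"


class TestComputeKmerStats:
    def test_worked_example(self, rng):
        """cs counts [5,7,9], ct counts [10,12,20] -> cs 7, coverage 19."""
        wt, mut, pos, cs, control, pairs, contig = snv_fixture(rng)
        members = contig.members[:3]
        contig.members = members
        case_counts = {}
        for count, m in zip([5, 7, 9], members):
            case_counts[m.kmer] = count
        for count, m in zip([10, 12, 20], members):
            case_counts[canonicalize(m.pair.ct_kmer)] = count
        case_t = KmerCountTable(31, case_counts)
        ctrl_t = KmerCountTable(31, {})
        cs_case, cov_case, cs_ctrl, cov_ctrl = compute_kmer_stats(contig, case_t, ctrl_t)
        assert cs_case == 7
        assert cov_case == 19
        assert cs_ctrl == 0 and cov_ctrl == 0

    def test_single_member(self, rng):
        wt, mut, pos, cs, control, pairs, contig = snv_fixture(rng)
        contig.members = contig.members[:1]
        case_t = KmerCountTable(31, {contig.members[0].kmer: 11})
        cs_case, cov_case, _, _ = compute_kmer_stats(contig, case_t, KmerCountTable(31))
        assert cs_case == 11


class TestRetrieveControlReads:
    def _contig(self, rng):
        _, _, _, _, _, _, contig = snv_fixture(rng)
        return contig

    def test_verbatim_member_retrieved(self, rng):
        contig = self._contig(rng)
        occ = contig.seq[:31]
        read = make_read("AAA" + occ + "TTT")
        assert retrieve_control_reads(contig, [read]) != []

    def test_one_mismatch_retrieved(self, rng):
        contig = self._contig(rng)
        occ = contig.seq[:31]
        mm = "ACGT"[("ACGT".index(occ[15]) + 1) % 4]
        near = occ[:15] + mm + occ[16:]
        read = make_read(near)
        assert retrieve_control_reads(contig, [read]) != []

    def test_reverse_complement_retrieved_and_oriented(self, rng):
        contig = self._contig(rng)
        occ = contig.seq[:31]
        read = make_read(revcomp("AA" + occ))
        hits = retrieve_control_reads(contig, [read])
        assert len(hits) == 1
        assert occ in hits[0].bases

    def test_two_mismatches_not_retrieved(self, rng):
        contig = self._contig(rng)
        occ = contig.seq[:31]
        b = lambda c: "ACGT"[("ACGT".index(c) + 1) % 4]
        far = b(occ[0]) + occ[1:30] + b(occ[30])
        assert retrieve_control_reads(contig, [make_read(far)]) == []


def oracle_assembly_outcomes(reads, min_overlap):
    """All outcomes reachable by repeatedly merging any maximal-overlap pair."""
    def max_ov(a, b):
        for L in range(min(len(a), len(b)), min_overlap - 1, -1):
            if a[-L:] == b[:L]:
                return L
        return 0

    def rec(items):
        pairs = [
            (max_ov(a, b), i, j)
            for i, a in enumerate(items)
            for j, b in enumerate(items)
            if i != j and max_ov(a, b) >= min_overlap
        ]
        if not pairs:
            return {max(items, key=lambda s: (len(s), s))}
        best = max(L for L, _, _ in pairs)
        out = set()
        for L, i, j in pairs:
            if L != best:
                continue
            merged = items[i] + items[j][L:]
            rest = [s for t, s in enumerate(items) if t not in (i, j)] + [merged]
            out |= rec(rest)
        return out

    return rec(list(reads))


class TestAssembleControlReads:
    def test_two_overlapping_reads(self, rng):
        src = random_seq(rng, 150)
        r1, r2 = src[:100], src[50:]
        ref, n = assemble_control_reads([r1, r2], 30)
        assert n == 2
        assert ref == src

    def test_zero_reads(self):
        assert assemble_control_reads([], 30) == (None, 0)

    def test_matches_exhaustive_merge_oracle(self, rng):
        for _ in range(20):
            src = random_seq(rng, 60)
            starts = sorted(int(s) for s in rng.integers(0, 30, size=5))
            reads = [src[s : s + 30] for s in starts]
            got, n = assemble_control_reads(reads, 10)
            assert n == len(reads)
            assert got in oracle_assembly_outcomes(set(reads), 10) | {src}

    def test_accepts_read_records(self, rng):
        src = random_seq(rng, 120)
        reads = [ReadRecord("a", src[:80], bytes([30] * 80)),
                 ReadRecord("b", src[40:], bytes([30] * 80))]
        ref, n = assemble_control_reads(reads, 30)
        assert ref == src and n == 2


class TestInferReferenceDispatch:
    def test_snv_goes_ct_merge_and_reverts_base(self, rng):
        wt, mut, pos, cs, control, pairs, contig = snv_fixture(rng)
        case_t = KmerCountTable(31, dict(cs.case_counts))
        ctrl_raw = count_kmers([wt] * 3, 31)
        inf = infer_reference(contig, case_t, ctrl_raw, [], 25)
        assert inf.branch == "ct_merge"
        window_wt = wt[pos - 30 : pos + 31]
        assert inf.ref_seq in (window_wt, revcomp(window_wt))
        assert inf.coverage_case >= inf.cs_count_case
        assert inf.coverage_control >= inf.cs_count_control

    def test_read_assembly_coverage_counts_reads(self, rng):
        wt, mut, pos, cs, control, pairs, contig = snv_fixture(rng)
        for m in contig.members:
            m.matched = False
            m.pair = None
        reads = [contig.seq[i : i + 60] for i in (0, 1)]
        inf = infer_reference(
            contig, KmerCountTable(31, dict(cs.case_counts)), KmerCountTable(31), reads, 25
        )
        assert inf.branch == "read_assembly"
        assert inf.n_support_reads == 2
        assert inf.coverage_control == inf.cs_count_control + 2

    def test_statistics_non_negative(self, rng):
        wt, mut, pos, cs, control, pairs, contig = snv_fixture(rng)
        inf = infer_reference(contig, KmerCountTable(31), KmerCountTable(31), [], 25)
        for v in (
            inf.cs_count_case,
            inf.coverage_case,
            inf.cs_count_control,
            inf.coverage_control,
            inf.n_support_reads,
        ):
            assert isinstance(v, int) and v >= 0
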