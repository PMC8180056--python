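from functools import lru_cache

import pysam
import pytest

from csvar.kmer import revcomp
from csvar.scoring import VariantStats
from csvar.variants import (
    VariantCall,
    align_contig_pair,
    classify_variant,
    locate_sequence,
    place_call,
    read_vcf_calls,
    write_vcf,
)

from conftest import random_seq

MATCH, MISMATCH, OPEN, EXTEND = 2.0, -1.0, -2.0, -0.5


def oracle_local_score(a, b):
    """Brute-force best local alignment score under the affine scheme
    (gap of length g costs OPEN + (g-1)*EXTEND), independent of the aligner."""

    @lru_cache(maxsize=None)
    def best_ending_at(i, j, state):
        # state: 0 diagonal, 1 gap in b (consume a), 2 gap in a (consume b)
        if state == 0:
            s = MATCH if a[i] == b[j] else MISMATCH
            prev = 0.0
            if i > 0 and j > 0:
                prev = max(
                    0.0,
                    best_ending_at(i - 1, j - 1, 0),
                    best_ending_at(i - 1, j - 1, 1),
                    best_ending_at(i - 1, j - 1, 2),
                )
            return prev + s
        if state == 1:
            opts = []
            if i > 0:
                opts.append(best_ending_at(i - 1, j, 0) + OPEN)
                opts.append(best_ending_at(i - 1, j, 1) + EXTEND)
            return max(opts) if opts else -1e9
        opts = []
        if j > 0:
            opts.append(best_ending_at(i, j - 1, 0) + OPEN)
            opts.append(best_ending_at(i, j - 1, 2) + EXTEND)
        return max(opts) if opts else -1e9

    best = 0.0
    for i in range(len(a)):
        for j in range(len(b)):
            best = max(best, best_ending_at(i, j, 0))
    return best


def sub(base):
    return "ACGT"[("ACGT".index(base) + 1) % 4]


class TestAlignContigPair:
    def test_single_mismatch(self):
        aln = align_contig_pair("ACGTA", "ACCTA")
        assert aln.a_aligned.replace("-", "") == "ACGTA"
        mism = [
            (x, y)
            for x, y in zip(aln.a_aligned, aln.b_aligned)
            if x != y and x != "-" and y != "-"
        ]
        assert mism == [("G", "C")]

    def test_one_base_deletion(self):
        aln = align_contig_pair("ACGA" + "T" * 10, "ACGTA" + "T" * 10)
        gaps = sum(1 for c in aln.a_aligned if c == "-")
        assert gaps == 1
        assert aln.b_aligned.count("-") == 0

    def test_score_matches_brute_force_oracle(self, rng):
        for _ in range(40):
            a = random_seq(rng, int(rng.integers(3, 12)))
            b = random_seq(rng, int(rng.integers(3, 12)))
            aln = align_contig_pair(a, b)
            assert aln.score == pytest.approx(oracle_local_score(a, b))

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            align_contig_pair("", "ACGT")


class TestClassifyVariant:
    def _pair(self, rng, n=120):
        ref = random_seq(rng, n)
        return ref

    def test_single_substitution_is_mutation(self, rng):
        ref = self._pair(rng)
        pos = 60
        mutant = ref[:pos] + sub(ref[pos]) + ref[pos + 1 :]
        call = classify_variant(None, mutant, ref)
        assert call.var_type == "mutation"
        assert call.pos_in_contig == pos and call.pos_in_ref == pos
        assert call.ref_allele == ref[pos] and call.alt_allele == mutant[pos]

    def test_three_base_deletion_is_indel(self, rng):
        ref = self._pair(rng)
        mutant = ref[:60] + ref[63:]
        call = classify_variant(None, mutant, ref)
        assert call.var_type == "indel"
        assert len(call.ref_allele) - len(call.alt_allele) == 3
        assert abs(call.pos_in_ref - 59) <= 3  # left-aligned through repeats

    def test_insertion_is_indel(self, rng):
        ref = self._pair(rng)
        ins = random_seq(rng, 4)
        mutant = ref[:60] + ins + ref[60:]
        call = classify_variant(None, mutant, ref)
        assert call.var_type == "indel"
        assert len(call.alt_allele) - len(call.ref_allele) == 4

    def test_sixty_base_deletion_is_sv(self, rng):
        ref = self._pair(rng, 200)
        mutant = ref[:60] + ref[120:]
        call = classify_variant(None, mutant, ref)
        assert call.var_type == "sv"
        assert abs(call.pos_in_ref - 59) <= 3
        assert call.partner_ref_pos is not None
        assert abs(call.partner_ref_pos - 120) <= 3

    def test_junction_clip_is_sv(self, rng):
        ref = self._pair(rng, 120)
        foreign = random_seq(rng, 31)
        mutant = ref[30:60] + foreign
        call = classify_variant(None, mutant, ref)
        assert call.var_type == "sv"
        assert abs(call.pos_in_ref - 59) <= 3

    def test_two_substitutions_multiple_mutation(self, rng):
        ref = self._pair(rng)
        mutant = ref[:40] + sub(ref[40]) + ref[41:70] + sub(ref[70]) + ref[71:]
        call = classify_variant(None, mutant, ref)
        assert call.var_type == "multiple_mutation"
        assert call.pos_in_ref == 40

    def test_no_reference_is_sv_with_evidence(self):
        call = classify_variant(None, "ACGT" * 10, None, evidence=True)
        assert call.var_type == "sv"
        call = classify_variant(None, "ACGT" * 10, None, evidence=False)
        assert call.var_type == "unresolved"

    def test_classification_rc_invariant(self, rng):
        for _ in range(20):
            ref = random_seq(rng, 150)
            kind = int(rng.integers(0, 3))
            if kind == 0:
                mutant = ref[:70] + sub(ref[70]) + ref[71:]
            elif kind == 1:
                mutant = ref[:70] + ref[74:]
            else:
                mutant = ref[:40] + random_seq(rng, 35)
            fwd = classify_variant(None, mutant, ref)
            rev = classify_variant(None, revcomp(mutant), revcomp(ref))
            assert fwd.var_type == rev.var_type


class TestLocateSequence:
    def test_exact_forward(self, rng):
        g = {"chr1": random_seq(rng, 5000)}
        seq = g["chr1"][1000:1060]
        assert locate_sequence(seq, g) == ("chr1", 1000, "+")

    def test_exact_reverse(self, rng):
        g = {"chr1": random_seq(rng, 5000)}
        seq = revcomp(g["chr1"][1000:1060])
        assert locate_sequence(seq, g) == ("chr1", 1000, "-")

    def test_one_mismatch(self, rng):
        g = {"chr1": random_seq(rng, 5000)}
        seq = list(g["chr1"][1000:1060])
        seq[40] = sub(seq[40])
        assert locate_sequence("".join(seq), g) == ("chr1", 1000, "+")

    def test_absent(self, rng):
        g = {"chr1": random_seq(rng, 2000)}
        probe = random_seq(rng, 60)
        loc = locate_sequence(probe, g)
        if loc is not None:  # vanishingly unlikely random hit
            assert g["chr1"][loc[1] : loc[1] + 60] != ""


def _call(contig_id, var_type, pos, ref_a, alt_a, mutant, refseq):
    return VariantCall(
        contig_id=contig_id,
        mutant_seq=mutant,
        ref_seq=refseq,
        var_type=var_type,
        pos_in_contig=pos,
        pos_in_ref=pos,
        ref_allele=ref_a,
        alt_allele=alt_a,
        stats=VariantStats(7, 40, 0.175, 1e-6, 60.0, 0, 38),
    )


class TestVcfExport:
    def test_contig_space_record_valid_and_round_trips(self, tmp_path, rng):
        mutant = random_seq(rng, 61)
        refseq = mutant[:30] + sub(mutant[30]) + mutant[31:]
        calls = [_call("contig_1", "mutation", 30, refseq[30], mutant[30], mutant, refseq)]
        path = str(tmp_path / "out.vcf")
        write_vcf(calls, path)
        with pysam.VariantFile(path) as vf:
            recs = list(vf)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.chrom == "contig_1"
        assert rec.pos == 31
        assert rec.ref == refseq[30]
        assert rec.alts == (mutant[30],)
        parsed = read_vcf_calls(path)[0]
        assert parsed["info"]["VTYPE"] == "mutation"
        assert int(parsed["info"]["CSCOUNT"]) == 7
        assert float(parsed["info"]["AF"]) == pytest.approx(0.175)
        assert parsed["info"]["MCTG"] == mutant

    def test_genome_placement_exact_position(self, tmp_path, rng):
        genome = {"chr1": random_seq(rng, 4000)}
        p0 = 2000  # 0-based planted SNV position
        refseq = genome["chr1"][p0 - 30 : p0 + 31]
        mutant = refseq[:30] + sub(refseq[30]) + refseq[31:]
        call = classify_variant(None, mutant, refseq)
        call.contig_id = "contig_1"
        call.stats = VariantStats(7, 40, 0.175, 1e-6, 60.0, 0, 38)
        place_call(call, genome)
        assert (call.chrom, call.genome_pos) == ("chr1", p0 + 1)
        path = str(tmp_path / "g.vcf")
        write_vcf([call], path, genome)
        with pysam.VariantFile(path) as vf:
            rec = next(iter(vf))
        assert rec.pos == p0 + 1
        assert genome["chr1"][rec.pos - 1] == rec.ref

    def test_records_sorted_by_chrom_then_pos(self, tmp_path, rng):
        genome = {"chr1": random_seq(rng, 3000), "chr2": random_seq(rng, 3000)}
        calls = []
        for chrom, pos in (("chr2", 100), ("chr1", 500), ("chr1", 50)):
            c = _call("ctg", "mutation", 10, "A", "C", "ACGT" * 10, "ACGT" * 10)
            c.chrom, c.genome_pos = chrom, pos
            calls.append(c)
        path = str(tmp_path / "s.vcf")
        write_vcf(calls, path, genome)
        recs = [(r["chrom"], r["pos"]) for r in read_vcf_calls(path)]
        assert recs == [("chr1", 50), ("chr1", 500), ("chr2", 100)]

    def test_unmapped_flag_only_with_genome(self, tmp_path, rng):
        genome = {"chr1": random_seq(rng, 2000)}
        c = _call("contig_9", "sv", 5, "A", "<SV>", random_seq(rng, 40), None)
        path = str(tmp_path / "u.vcf")
        write_vcf([c], path, genome)
        assert "UNMAPPED" in read_vcf_calls(path)[0]["info"]
        write_vcf([c], str(tmp_path / "u2.vcf"))
        assert "UNMAPPED" not in read_vcf_calls(str(tmp_path / "u2.vcf"))[0]["info"]
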