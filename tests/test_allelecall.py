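"""Parental SNP calling, read-wise vs SNP-wise assignment, count tables."""

import itertools

import numpy as np
import pytest

from hybridase.allelecall import (
    ParentalSNP,
    ReadClass,
    assign_reads_readwise,
    call_parental_snps,
    count_snpwise,
    percent_assignable,
)
from hybridase.preprocess import Alignment, ReadRecord, TranscriptPileup


def _pileup(ref_len, sites):
    """sites: {pos: {base: count}}"""
    tp = TranscriptPileup(
        length=ref_len,
        base_counts=np.zeros((ref_len, 4), dtype=np.int64),
        del_depth=np.zeros(ref_len, dtype=np.int64),
    )
    for pos, counts in sites.items():
        for base, n in counts.items():
            tp.base_counts[pos, "ACGT".index(base)] = n
    return {"t1": tp}


def _snp(pos, apo, ir64, tid="t1"):
    return ParentalSNP(tid, pos, apo, ir64, 30, 30, 1.0, 1.0)


def _read(rid, seq):
    return ReadRecord(rid, seq, tuple([35] * len(seq)))


class TestParentalSNPCalling:
    def test_clean_biallelic_site_called(self):
        pa = _pileup(10, {4: {"A": 10}})
        pb = _pileup(10, {4: {"G": 10}})
        snps = call_parental_snps(pa, pb)
        assert len(snps) == 1
        s = snps[0]
        assert (s.position, s.apo_allele, s.ir64_allele) == (4, "A", "G")

    def test_depth_below_three_not_called(self):
        pa = _pileup(10, {4: {"A": 2}})
        pb = _pileup(10, {4: {"G": 10}})
        assert call_parental_snps(pa, pb) == []

    def test_same_majority_allele_not_called(self):
        pa = _pileup(10, {4: {"A": 10}})
        pb = _pileup(10, {4: {"A": 10}})
        assert call_parental_snps(pa, pb) == []

    def test_proportion_exactly_080_not_called(self):
        pa = _pileup(10, {4: {"A": 8, "C": 2}})
        pb = _pileup(10, {4: {"G": 10}})
        assert call_parental_snps(pa, pb) == []

    def test_planted_snps_recovered_at_depth_30(self, variant_recovery):
        assert variant_recovery.parental_recall >= 0.95


def _scenario(read_specs, snps, ref_len=60):
    """read_specs: (rid, start, length, {snp_pos: base})"""
    reads, alns = [], []
    for rid, start, length, bases in read_specs:
        seq = ["A"] * length
        for pos, base in bases.items():
            seq[pos - start] = base
        reads.append(_read(rid, "".join(seq)))
        alns.append(Alignment(rid, "t1", start, 0, True, f"{length}M"))
    return alns, reads, snps


class TestReadWise:
    def test_read_covering_two_apo_snps_counts_once(self):
        snps = [_snp(10, "C", "G"), _snp(20, "T", "G")]
        alns, reads, snps = _scenario(
            [("r0", 5, 25, {10: "C", 20: "T"})], snps
        )
        res = assign_reads_readwise(alns, reads, snps)
        assert res.assignments[0].klass is ReadClass.APO
        assert res.assignments[0].votes_apo == 2
        row = res.gene_counts.iloc[0]
        assert (row["apo_reads"], row["ir64_reads"]) == (1, 0)

    def test_conflicting_votes_are_unspecified(self):
        snps = [_snp(10, "C", "G"), _snp(20, "T", "G")]
        alns, reads, snps = _scenario(
            [("r0", 5, 25, {10: "C", 20: "G"})], snps
        )
        res = assign_reads_readwise(alns, reads, snps)
        assert res.assignments[0].klass is ReadClass.CONFLICT
        row = res.gene_counts.iloc[0]
        assert (row["apo_reads"], row["ir64_reads"], row["unspecified_reads"]) == (0, 0, 1)

    def test_error_base_is_ignored_not_a_veto(self):
        snps = [_snp(10, "C", "G"), _snp(20, "T", "G")]
        alns, reads, snps = _scenario(
            [("r0", 5, 25, {10: "C", 20: "A"})], snps  # A matches neither
        )
        res = assign_reads_readwise(alns, reads, snps)
        assert res.assignments[0].klass is ReadClass.APO

    def test_uninformative_reads_counted_unspecified(self):
        snps = [_snp(50, "C", "G")]
        alns, reads, snps = _scenario([("r0", 0, 20, {})], snps)
        res = assign_reads_readwise(alns, reads, snps)
        assert res.assignments == []  # covers no SNP
        row = res.gene_counts.iloc[0]
        assert row["unspecified_reads"] == 1 and res.mapped_total == 1

    def test_snp_outside_transcript_raises(self):
        snps = [_snp(100, "C", "G")]
        alns, reads, snps = _scenario([("r0", 0, 20, {})], snps)
        with pytest.raises(ValueError, match="beyond"):
            assign_reads_readwise(alns, reads, snps, reference={"t1": "A" * 60})

    def test_parent_label_swap_swaps_counts(self):
        snps = [_snp(10, "C", "G"), _snp(30, "T", "A")]
        specs = [
            ("r0", 5, 25, {10: "C"}),
            ("r1", 5, 30, {10: "G", 30: "A"}),
            ("r2", 25, 20, {30: "T"}),
        ]
        alns, reads, _ = _scenario(specs, snps)
        res = assign_reads_readwise(alns, reads, snps)
        swapped = [
            ParentalSNP(s.transcript_id, s.position, s.ir64_allele, s.apo_allele,
                        s.depth_ir64, s.depth_apo, s.prop_ir64, s.prop_apo)
            for s in snps
        ]
        res_sw = assign_reads_readwise(alns, reads, swapped)
        a, b = res.gene_counts.iloc[0], res_sw.gene_counts.iloc[0]
        assert a["apo_reads"] == b["ir64_reads"]
        assert a["ir64_reads"] == b["apo_reads"]


class TestSnpWiseComparison:
    def test_one_read_two_snps_double_counted_snpwise(self):
        snps = [_snp(10, "C", "G"), _snp(20, "T", "G")]
        alns, reads, snps = _scenario([("r0", 5, 25, {10: "C", 20: "T"})], snps)
        snpwise = count_snpwise(alns, reads, snps)
        readwise = assign_reads_readwise(alns, reads, snps)
        assert int(snpwise.iloc[0]["apo_obs"]) == 2
        assert int(readwise.gene_counts.iloc[0]["apo_reads"]) == 1

    def test_schematic_twelve_read_fixture(self):
        """8 Apo reads (two covering both SNPs) and 4 IR64 reads (two
        covering both): read-wise (8, 4) vs SNP-wise (10, 6)."""
        snps = [_snp(10, "C", "G"), _snp(20, "T", "A")]
        specs = []
        for i in range(2):  # Apo reads over both SNPs
            specs.append((f"a2_{i}", 5, 25, {10: "C", 20: "T"}))
        for i in range(6):  # Apo reads over one SNP
            specs.append((f"a1_{i}", 5, 10, {10: "C"}))
        for i in range(2):  # IR64 reads over both SNPs
            specs.append((f"b2_{i}", 5, 25, {10: "G", 20: "A"}))
        for i in range(2):  # IR64 reads over one SNP
            specs.append((f"b1_{i}", 15, 10, {20: "A"}))
        alns, reads, snps = _scenario(specs, snps)
        readwise = assign_reads_readwise(alns, reads, snps)
        snpwise = count_snpwise(alns, reads, snps)
        assert len(reads) == 12
        assert (readwise.gene_counts.iloc[0]["apo_reads"],
                readwise.gene_counts.iloc[0]["ir64_reads"]) == (8, 4)
        assert (int(snpwise.iloc[0]["apo_obs"]),
                int(snpwise.iloc[0]["ir64_obs"])) == (10, 6)

    def test_dominance_by_exhaustive_enumeration(self):
        """Over every configuration of two reads covering subsets of two
        SNPs with either parent's alleles, SNP-wise counts dominate
        read-wise counts, with equality iff no informative read covers more
        than one SNP."""
        snps = [_snp(10, "C", "G"), _snp(20, "T", "A")]
        apo_alleles = {10: "C", 20: "T"}
        ir64_alleles = {10: "G", 20: "A"}
        coverage_opts = [(10,), (20,), (10, 20)]
        parent_opts = ["apo", "ir64"]
        for cov1, par1, cov2, par2 in itertools.product(
            coverage_opts, parent_opts, coverage_opts, parent_opts
        ):
            specs = []
            for rid, (cov, par) in enumerate([(cov1, par1), (cov2, par2)]):
                alleles = apo_alleles if par == "apo" else ir64_alleles
                start, end = min(cov) - 2, max(cov) + 2
                specs.append(
                    (f"r{rid}", start, end - start + 1,
                     {p: alleles[p] for p in cov})
                )
            alns, reads, _ = _scenario(specs, snps)
            rw = assign_reads_readwise(alns, reads, snps).gene_counts.iloc[0]
            sw = count_snpwise(alns, reads, snps).iloc[0]
            assert sw["apo_obs"] >= rw["apo_reads"]
            assert sw["ir64_obs"] >= rw["ir64_reads"]
            multi = any(len(c) > 1 for c in (cov1, cov2))
            equal = (sw["apo_obs"] == rw["apo_reads"]) and (
                sw["ir64_obs"] == rw["ir64_reads"]
            )
            assert equal == (not multi)


class TestTables:
    def test_percent_assignable_truncates(self):
        assert percent_assignable(276_827, 282_901, 21_860_178) == 2.56
        assert percent_assignable(1_399_485, 1_454_190, 54_525_736) == 5.23
        assert percent_assignable(1_378_264, 1_403_493, 51_364_894) == 5.41
        assert percent_assignable(0, 0, 100) == 0.0

    def test_partition_holds_end_to_end(self, recovery_result):
        t = recovery_result.allele_table
        assert (t["from_apo"] + t["from_ir64"] + t["unspecified"] == t["mapped"]).all()

    def test_seventy_thirty_mixture_recovered(self, rng):
        from hybridase.preprocess import map_reads
        from hybridase.simulate import (
            SimulationConfig,
            derive_parental_haplotypes,
            generate_reference_transcriptome,
            simulate_reads,
        )

        cfg = SimulationConfig(
            n_genes=8, gene_length_range=(400, 700), parental_snp_rate=5.0,
            depth_per_gene=400, base_error_rate=0.0, seed=21,
        )
        ref = generate_reference_transcriptome(cfg)
        apo, ir64, truth = derive_parental_haplotypes(ref, cfg)
        reads = simulate_reads(
            (apo, ir64), {t: 0.7 for t in ref}, cfg, rng, "f1_x_rep1"
        )
        alns = map_reads(reads, ref, max_mismatches=3, seed_length=20)
        snps = [
            ParentalSNP(r.transcript_id, r.pos, r.apo_allele, r.ir64_allele,
                        30, 30, 1.0, 1.0)
            for r in truth.variants.itertuples(index=False)
            if r.kind == "parental_snp"
        ]
        res = assign_reads_readwise(alns, reads, snps)
        for row in res.gene_counts.itertuples(index=False):
            n = row.apo_reads + row.ir64_reads
            if n < 30:
                continue
            share = row.apo_reads / n
            assert abs(share - 0.7) <= 2.58 * np.sqrt(0.21 / n) + 0.02
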