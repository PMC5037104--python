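"""Trimming, mapping, SAM exchange and pileup construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridase.preprocess import (
    Alignment,
    ReadRecord,
    build_pileup,
    compute_mapping_rate,
    gene_of,
    import_alignments,
    left_normalize_indel,
    map_reads,
    quality_trim_replicate,
    write_sam,
)


def _read(rid, seq, qual=None):
    return ReadRecord(rid, seq, tuple(qual if qual is not None else [35] * len(seq)))


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------


class TestTrimming:
    def test_uniform_high_quality_is_identity(self):
        reads = [_read(f"r{i}", "ACGTACGTAC") for i in range(4)]
        res = quality_trim_replicate(reads)
        assert res.removed_positions == ()
        assert res.reads == reads

    def test_threshold_zero_is_identity(self):
        reads = [_read("r0", "ACGT", [2, 2, 2, 2])]
        res = quality_trim_replicate(reads, threshold=0.0)
        assert res.reads == reads

    def test_low_quality_block_removed_everywhere(self):
        # positions 80..89 carry 75th-percentile quality 20 (< 28)
        rng = np.random.default_rng(0)
        reads = []
        for i in range(40):
            qual = [35] * 90
            for p in range(80, 90):
                qual[p] = 20
            seq = "".join(rng.choice(list("ACGT"), size=90))
            reads.append(_read(f"r{i}", seq, qual))
        res = quality_trim_replicate(reads)
        assert res.removed_positions == tuple(range(80, 90))
        assert all(len(r.sequence) == 80 for r in res.reads)
        assert res.reads[0].sequence == reads[0].sequence[:80]

    def test_percentile_against_brute_force(self, rng):
        # independent oracle: positionwise sorted-list interpolation quantile
        n, L = 25, 30
        quals = rng.integers(2, 41, size=(n, L))
        reads = [
            _read(f"r{i}", "A" * L, list(map(int, quals[i]))) for i in range(n)
        ]
        res = quality_trim_replicate(reads, threshold=28.0, percentile=0.75)
        removed = set(res.removed_positions)
        for pos in range(L):
            col = sorted(int(q) for q in quals[:, pos])
            h = 0.75 * (n - 1)
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            q75 = col[lo] + (h - lo) * (col[hi] - col[lo])
            assert (pos in removed) == (q75 < 28.0)

    def test_idempotence(self, rng):
        quals = rng.integers(10, 41, size=(20, 40))
        reads = [
            _read(f"r{i}", "C" * 40, list(map(int, quals[i]))) for i in range(20)
        ]
        once = quality_trim_replicate(reads).reads
        twice = quality_trim_replicate(once).reads
        assert once == twice

    def test_fully_failing_replicate_raises(self):
        reads = [_read("r0", "ACGT", [2, 2, 2, 2])]
        with pytest.raises(ValueError, match="entirely trimmed"):
            quality_trim_replicate(reads)


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------


REF = {
    "LOC_Os01g00010.1": "ACGTACGGTACCTTGACGATCGATTACGGATCCTAGCTAGGCTAGCTAACGGATCGCGAT"
    "TACGCTAGCATCGGATCGATCGGCTAACGTACGATCGATCCGATCGATGCA",
}


class TestMapper:
    def test_exact_substring_maps_uniquely(self):
        seq = REF["LOC_Os01g00010.1"][10:40]
        alns = map_reads([_read("r0", seq)], REF, max_mismatches=2, seed_length=10)
        a = alns[0]
        assert a.mapped and a.start == 10 and a.mismatches == 0 and a.cigar == "30M"

    def test_too_many_mismatches_unmapped(self):
        seq = list(REF["LOC_Os01g00010.1"][10:40])
        for i in (2, 12, 22):  # 3 subs > max_mismatches=2, away from seeds? no: seeds are exact
            seq[i] = "A" if seq[i] != "A" else "C"
        alns = map_reads(
            [_read("r0", "".join(seq))], REF, max_mismatches=2, seed_length=5
        )
        assert not alns[0].mapped

    def test_seed_longer_than_read_rejected(self):
        with pytest.raises(ValueError):
            map_reads([_read("r0", "ACGT")], REF, seed_length=10)

    def test_multi_gene_tie_unmapped_splice_tie_lexicographic(self):
        seq = "ACGTACGTTGCATGCATCGA" * 3
        ref_genes = {"LOC_Os01g00010.1": seq, "LOC_Os02g00020.1": seq}
        alns = map_reads([_read("r0", seq[5:35])], ref_genes, seed_length=10)
        assert not alns[0].mapped  # best hit ties across two genes
        ref_splice = {"LOC_Os01g00010.2": seq, "LOC_Os01g00010.1": seq}
        alns = map_reads([_read("r0", seq[5:35])], ref_splice, seed_length=10)
        assert alns[0].mapped and alns[0].transcript_id == "LOC_Os01g00010.1"

    def test_against_exhaustive_hamming_oracle(self, rng):
        ref = {
            f"LOC_Os0{i}g0001{i}.1": "".join(rng.choice(list("ACGT"), size=300))
            for i in range(1, 4)
        }
        reads = []
        truth_best = []
        for j in range(60):
            tid = list(ref)[j % 3]
            start = int(rng.integers(0, 300 - 50))
            seq = list(ref[tid][start : start + 50])
            for _ in range(int(rng.integers(0, 3))):
                p = int(rng.integers(0, 50))
                seq[p] = "ACGT"[int(rng.integers(0, 4))]
            reads.append(_read(f"r{j}", "".join(seq)))
        alns = map_reads(reads, ref, max_mismatches=2, seed_length=15, max_indel=0)
        for read, aln in zip(reads, alns):
            # oracle: exhaustive ungapped scan over all placements
            best = 51
            n_best_genes = set()
            for tid, seq in ref.items():
                for s in range(0, len(seq) - 50 + 1):
                    mm = sum(
                        1 for a, b in zip(read.sequence, seq[s : s + 50]) if a != b
                    )
                    if mm < best:
                        best, n_best_genes = mm, {gene_of(tid)}
                    elif mm == best:
                        n_best_genes.add(gene_of(tid))
            if best <= 2 and len(n_best_genes) == 1:
                assert aln.mapped, (read.read_id, best)
                assert aln.mismatches == best
            elif best > 2:
                assert not aln.mapped

    def test_error_free_library_fully_mapped_on_own_haplotypes(self, rng):
        from hybridase.simulate import (
            SimulationConfig,
            derive_parental_haplotypes,
            generate_reference_transcriptome,
            simulate_reads,
        )

        cfg = SimulationConfig(n_genes=6, gene_length_range=(400, 800),
                               depth_per_gene=40, base_error_rate=0.0, seed=3)
        ref = generate_reference_transcriptome(cfg)
        apo, ir64, _ = derive_parental_haplotypes(ref, cfg)
        reads = simulate_reads((apo, ir64), {t: 1.0 for t in ref}, cfg, rng, "f1_x_r1")
        alns = map_reads(reads, apo, max_mismatches=2, seed_length=20)
        assert compute_mapping_rate(alns) == 100.0

    def test_single_deletion_read_maps_with_indel_cigar(self):
        ref_seq = REF["LOC_Os01g00010.1"]
        # read skips 2 reference bases in the middle
        seq = ref_seq[5:30] + ref_seq[32:57]
        alns = map_reads([_read("r0", seq)], REF, max_mismatches=2, seed_length=12)
        a = alns[0]
        assert a.mapped and "D" in a.cigar and a.start == 5 and a.mismatches == 0
        assert a.reference_span == 52

    def test_mapping_rate_arithmetic(self):
        alns = [Alignment(f"r{i}", "t", 0, 0, i < 8, "5M") for i in range(10)]
        assert compute_mapping_rate(alns) == 80.0
        assert compute_mapping_rate([a for a in alns if a.mapped]) == 100.0


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


class TestSAM:
    def test_pos_conversion_and_flag4(self, tmp_path):
        path = tmp_path / "mini.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:t1\tLN:20\n"
            "r0\t0\tt1\t1\t255\t5M\t*\t0\t0\tACGTA\tIIIII\n"
            "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGTA\tIIIII\n"
        )
        alns = import_alignments(path, {"t1": "ACGTACGTACGTACGTACGT"})
        assert alns[0].mapped and alns[0].start == 0
        assert not alns[1].mapped

    def test_header_name_mismatch_raises(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text("@SQ\tSN:unknown\tLN:20\n")
        with pytest.raises(ValueError, match="unknown"):
            import_alignments(path, {"t1": "ACGT"})

    def test_roundtrip_export_import(self, tmp_path, rng):
        ref = {"LOC_Os01g00010.1": "".join(rng.choice(list("ACGT"), size=200))}
        reads = []
        for i in range(20):
            s = int(rng.integers(0, 160))
            reads.append(_read(f"r{i}", ref["LOC_Os01g00010.1"][s : s + 40]))
        reads.append(_read("unmappable", "T" * 40))
        alns = map_reads(reads, ref, max_mismatches=1, seed_length=10)
        path = tmp_path / "out.sam"
        write_sam(alns, reads, ref, path)
        back = import_alignments(path, ref)
        assert [(a.read_id, a.transcript_id, a.start, a.mismatches, a.mapped, a.cigar)
                for a in alns] == \
               [(a.read_id, a.transcript_id, a.start, a.mismatches, a.mapped, a.cigar)
                for a in back]


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------


class TestPileup:
    def test_single_error_free_read(self):
        ref = {"t1": "ACGTACGTAC"}
        reads = [_read("r0", "GTAC")]
        alns = [Alignment("r0", "t1", 2, 0, True, "4M")]
        pile = build_pileup(alns, reads, ref)
        tp = pile["t1"]
        for offset, base in enumerate("GTAC"):
            pos = 2 + offset
            assert tp.depth(pos) == 1
            assert tp.base_counts[pos, "ACGT".index(base)] == 1
        assert tp.depth(0) == 0

    def test_disagreeing_overlap(self):
        ref = {"t1": "ACGTACGTAC"}
        reads = [_read("r0", "GTAC"), _read("r1", "GAAC")]
        alns = [Alignment(r.read_id, "t1", 2, 0, True, "4M") for r in reads]
        tp = build_pileup(alns, reads, ref)["t1"]
        assert tp.depth(3) == 2
        assert tp.base_counts[3, "ACGT".index("T")] == 1
        assert tp.base_counts[3, "ACGT".index("A")] == 1

    def test_against_brute_force_recount(self, rng):
        ref = {"t1": "".join(rng.choice(list("ACGT"), size=120))}
        reads, alns = [], []
        for i in range(50):
            s = int(rng.integers(0, 100))
            seq = list(ref["t1"][s : s + 20])
            if rng.random() < 0.5:
                seq[int(rng.integers(0, 20))] = "ACGT"[int(rng.integers(0, 4))]
            reads.append(_read(f"r{i}", "".join(seq)))
            alns.append(Alignment(f"r{i}", "t1", s, 0, True, "20M"))
        tp = build_pileup(alns, reads, ref)["t1"]
        expect = np.zeros((120, 4), dtype=int)
        for read, aln in zip(reads, alns):
            for k, base in enumerate(read.sequence):
                expect[aln.start + k, "ACGT".index(base)] += 1
        assert np.array_equal(tp.base_counts, expect)

    def test_depth_conservation(self, rng):
        ref = {"t1": "".join(rng.choice(list("ACGT"), size=100))}
        reads, alns = [], []
        for i in range(30):
            s = int(rng.integers(0, 80))
            reads.append(_read(f"r{i}", ref["t1"][s : s + 20]))
            alns.append(Alignment(f"r{i}", "t1", s, 0, True, "20M"))
        tp = build_pileup(alns, reads, ref)["t1"]
        total_columns = int(tp.base_counts.sum())
        assert total_columns == sum(a.aligned_length for a in alns)

    def test_out_of_bounds_alignment_raises(self):
        ref = {"t1": "ACGT"}
        reads = [_read("r0", "ACGTACGT")]
        alns = [Alignment("r0", "t1", 2, 0, True, "8M")]
        with pytest.raises(ValueError, match="out of bounds"):
            build_pileup(alns, reads, ref)

    def test_deletion_and_insertion_observations(self):
        ref = {"t1": "ACGTAAGGTTCC"}
        # read with a 2 bp deletion of "AG"? use deletion of positions 4-5 ("AA")
        reads = [_read("rdel", "ACGT" + "GGTTCC"), _read("rins", "ACGTAA" + "TT" + "GGTT")]
        alns = [
            Alignment("rdel", "t1", 0, 0, True, "4M2D6M"),
            Alignment("rins", "t1", 0, 0, True, "6M2I4M"),
        ]
        tp = build_pileup(alns, reads, ref)["t1"]
        del_keys = [k for c in tp.indels.values() for k in c if k.startswith("-")]
        ins_keys = [k for c in tp.indels.values() for k in c if k.startswith("+")]
        assert del_keys == ["-AA"] and ins_keys == ["+TT"]
        assert tp.del_depth[4] == 1 and tp.del_depth[5] == 1

    @given(st.text(alphabet="AC", min_size=3, max_size=12), st.integers(0, 11))
    @settings(max_examples=50, deadline=None)
    def test_left_normalization_is_idempotent(self, seq, anchor):
        anchor = min(anchor, len(seq) - 2)
        key = "-" + seq[anchor + 1]
        a1, k1 = left_normalize_indel(seq, anchor, key)
        a2, k2 = left_normalize_indel(seq, a1, k1) if a1 >= 0 else (a1, k1)
        assert (a1, k1) == (a2, k2)
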