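"""Read preprocessing: quality trimming, transcript mapping, SAM exchange, pileups.

The mapper is a deterministic in-process seed-and-extend aligner for
transcript (cDNA) references.  Placements are scored by Hamming distance;
a single short insertion or deletion (<= ``max_indel`` bp) per read is
recognised through a two-seed placement so that reads spanning the small
InDels that separate *indica* parents from the *japonica* reference remain
mappable.  Gapped/spliced alignment beyond that is out of scope and is
delegated to SAM import from an external aligner.
"""

from __future__ import annotations

import logging
import os
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

PHRED_OFFSET = 33
_BASES = "ACGT"
BASE_TO_IDX = {b: i for i, b in enumerate(_BASES)}
_CIGAR_RE = re.compile(r"(\d+)([MID])")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


@dataclass(frozen=True)
class Alignment:
    """Ungapped (or single-InDel) placement of a read on one transcript.

    ``start`` is a 0-based offset on the transcript; ``cigar`` uses M/I/D
    operations only (e.g. ``"90M"`` or ``"40M2D50M"``).  Unmapped reads carry
    ``mapped=False`` and a ``"*"`` cigar.
    """

    read_id: str
    transcript_id: str | None
    start: int
    mismatches: int
    mapped: bool
    cigar: str = "*"

    def cigar_ops(self) -> list[tuple[int, str]]:
        return [(int(n), op) for n, op in _CIGAR_RE.findall(self.cigar)]

    @property
    def reference_span(self) -> int:
        """Number of reference bases consumed (M + D)."""
        return sum(n for n, op in self.cigar_ops() if op in "MD")

    @property
    def aligned_length(self) -> int:
        """Number of read bases placed on the reference (M only)."""
        return sum(n for n, op in self.cigar_ops() if op == "M")


@dataclass
class TranscriptPileup:
    """Per-position base and InDel tallies for one transcript."""

    length: int
    base_counts: np.ndarray  # (length, 4) int64, columns A,C,G,T
    del_depth: np.ndarray  # (length,) reads whose deletion spans the position
    indels: dict[int, Counter] = field(default_factory=dict)
    # indels: anchor position (last aligned base before the event) ->
    # Counter over "+SEQ" (insertion after anchor) / "-SEQ" (deleted bases)

    def depth(self, pos: int) -> int:
        return int(self.base_counts[pos].sum() + self.del_depth[pos])


class Pileup(dict):
    """Mapping ``transcript_id -> TranscriptPileup``."""


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------


def read_fastq(path: str | os.PathLike) -> list[ReadRecord]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = tuple(rec.letter_annotations["phred_quality"])
        reads.append(ReadRecord(rec.id, str(rec.seq).upper(), quals))
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# quality trimming
# ---------------------------------------------------------------------------


@dataclass
class TrimResult:
    reads: list[ReadRecord]
    removed_positions: tuple[int, ...]


def quality_trim_replicate(
    reads: Sequence[ReadRecord],
    threshold: float = 28.0,
    percentile: float = 0.75,
) -> TrimResult:
    """Drop read positions whose replicate-wide quality percentile is low.

    For each position along the read, the ``percentile`` quantile of the
    Phred qualities across all reads of the replicate is computed; positions
    whose quantile falls below ``threshold`` are removed from every read.
    Positions are dropped wherever they occur, so the surviving read need not
    be a contiguous block of the original.
    """
    if not reads:
        raise ValueError("empty replicate")
    lengths = {len(r.sequence) for r in reads}
    if len(lengths) != 1:
        raise ValueError(f"replicate has non-uniform read lengths: {sorted(lengths)}")
    qmat = np.array([r.qualities for r in reads], dtype=float)
    perc = np.percentile(qmat, percentile * 100.0, axis=0)
    keep = perc >= threshold
    if not keep.any():
        raise ValueError("replicate entirely trimmed: every position fails the filter")
    removed = tuple(int(i) for i in np.flatnonzero(~keep))
    if not removed:
        return TrimResult(list(reads), ())
    kept_idx = np.flatnonzero(keep)
    trimmed = []
    for r in reads:
        seq = "".join(r.sequence[i] for i in kept_idx)
        qual = tuple(r.qualities[i] for i in kept_idx)
        trimmed.append(ReadRecord(r.read_id, seq, qual))
    return TrimResult(trimmed, removed)


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------


def gene_of(transcript_id: str) -> str:
    """Strip a splice-variant suffix (``LOC_Os01g01010.2 -> LOC_Os01g01010``)."""
    base, dot, suffix = transcript_id.rpartition(".")
    if dot and suffix.isdigit():
        return base
    return transcript_id


class ReferenceIndex:
    """Exact k-mer index over a transcript reference for seed lookup."""

    def __init__(self, reference: Mapping[str, str], seed_length: int = 20):
        if not reference:
            raise ValueError("reference is empty")
        if seed_length < 1:
            raise ValueError("seed_length must be >= 1")
        self.seed_length = seed_length
        self.raw: dict[str, str] = dict(reference)
        self.arrays: dict[str, np.ndarray] = {
            tid: np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            for tid, seq in reference.items()
        }
        k = seed_length
        kmers: dict[bytes, list[tuple[str, int]]] = {}
        for tid, seq in reference.items():
            b = seq.encode("ascii")
            for i in range(len(b) - k + 1):
                kmers.setdefault(b[i : i + k], []).append((tid, i))
        self.kmers = kmers


def _best_indel_breakpoint(
    ref: np.ndarray, arr: np.ndarray, start: int, d: int
) -> tuple[int, int] | None:
    """Best single-InDel split of a read placed at ``start`` with offset ``d``.

    ``d > 0``: the read skips ``d`` reference bases (deletion, CIGAR D);
    ``d < 0``: the read carries ``-d`` extra bases absent from the reference
    (insertion, CIGAR I).  Returns ``(prefix_len, mismatches)`` for the
    mismatch-minimising breakpoint, or None if the placement leaves the
    reference.  Ties prefer the smallest prefix length.
    """
    L = arr.size
    if d > 0:  # deletion of d reference bases
        if start < 0 or start + L + d > ref.size:
            return None
        mm_left = np.concatenate(([0], np.cumsum(ref[start : start + L] != arr)))
        diff_r = ref[start + d : start + d + L] != arr
        mm_right_total = int(diff_r.sum())
        mm_right = np.concatenate(([0], np.cumsum(diff_r)))
        b_range = np.arange(1, L)  # both segments non-empty
        scores = mm_left[b_range] + (mm_right_total - mm_right[b_range])
        i = int(np.argmin(scores))
        return int(b_range[i]), int(scores[i])
    ilen = -d  # insertion of ilen read bases
    if start < 0 or start + L - ilen > ref.size:
        return None
    b_max = L - ilen - 1  # suffix segment non-empty
    if b_max < 1:
        return None
    # prefix length never exceeds b_max, so compare only L - ilen bases
    mm_left = np.concatenate(
        ([0], np.cumsum(ref[start : start + L - ilen] != arr[: L - ilen]))
    )
    # read base j (j >= b+ilen) aligns to ref[start + j - ilen]
    diff_r = ref[start : start + L - ilen] != arr[ilen:]
    # diff_r[j-ilen] compares read[j] with ref[start + j - ilen]
    mm_right_total = int(diff_r.sum())
    mm_right = np.concatenate(([0], np.cumsum(diff_r)))
    b_range = np.arange(1, b_max + 1)
    scores = mm_left[b_range] + (mm_right_total - mm_right[b_range])
    i = int(np.argmin(scores))
    return int(b_range[i]), int(scores[i])


def map_reads(
    reads: Sequence[ReadRecord],
    reference: Mapping[str, str] | ReferenceIndex,
    max_mismatches: int = 2,
    seed_length: int = 20,
    max_indel: int = 3,
) -> list[Alignment]:
    """Map reads to transcripts by exact-seed lookup and Hamming extension.

    The best placement (fewest mismatches; ungapped preferred over
    single-InDel at equal mismatches) is reported when its mismatch count is
    at most ``max_mismatches``.  Ties across transcripts of *different* genes
    leave the read unmapped; ties among splice variants of one gene resolve
    to the lexicographically first transcript.
    """
    index = (
        reference
        if isinstance(reference, ReferenceIndex)
        else ReferenceIndex(reference, seed_length)
    )
    k = index.seed_length
    out: list[Alignment] = []
    for read in reads:
        L = len(read.sequence)
        if k > L:
            raise ValueError(
                f"seed_length {k} exceeds read length {L} (read {read.read_id})"
            )
        b = read.sequence.encode("ascii")
        arr = np.frombuffer(b, dtype=np.uint8)
        seed_offsets = sorted({0, (L - k) // 2, L - k})
        seed_hits = [index.kmers.get(b[off : off + k], ()) for off in seed_offsets]
        # ungapped candidates
        placements: set[tuple[str, int]] = set()
        for off, hits in zip(seed_offsets, seed_hits):
            for tid, pos in hits:
                placements.add((tid, pos - off))
        # candidates: (mismatches, indel_flag, tid, start, cigar)
        candidates: list[tuple[int, int, str, int, str]] = []
        for tid, s in placements:
            ref = index.arrays[tid]
            if s < 0 or s + L > ref.size:
                continue
            mm = int(np.count_nonzero(ref[s : s + L] != arr))
            if mm <= max_mismatches:
                candidates.append((mm, 0, tid, s, f"{L}M"))
        # single-InDel candidates from left/right seed placement disagreement
        if max_indel > 0:
            left = {(tid, pos) for tid, pos in seed_hits[0]}
            right_off = seed_offsets[-1]
            pairs: set[tuple[str, int, int]] = set()
            for tid, pos in seed_hits[-1]:
                s_right = pos - right_off
                for tid_l, s_left in left:
                    if tid_l != tid:
                        continue
                    d = s_right - s_left
                    if d != 0 and abs(d) <= max_indel:
                        pairs.add((tid, s_left, d))
            for tid, s, d in pairs:
                res = _best_indel_breakpoint(index.arrays[tid], arr, s, d)
                if res is None:
                    continue
                bp, mm = res
                if mm > max_mismatches:
                    continue
                if d > 0:
                    cig = f"{bp}M{d}D{L - bp}M"
                else:
                    cig = f"{bp}M{-d}I{L - bp + d}M"
                candidates.append((mm, 1, tid, s, cig))
        if not candidates:
            out.append(Alignment(read.read_id, None, -1, -1, False))
            continue
        best_key = min(c[:2] for c in candidates)
        best = [c for c in candidates if c[:2] == best_key]
        genes = {gene_of(c[2]) for c in best}
        if len(genes) > 1:
            out.append(Alignment(read.read_id, None, -1, -1, False))
            continue
        mm, _, tid, s, cig = min(best, key=lambda c: (c[2], c[3]))
        out.append(Alignment(read.read_id, tid, s, mm, True, cig))
    return out


def compute_mapping_rate(alignments: Sequence[Alignment]) -> float:
    """Percentage of reads mapped."""
    if not alignments:
        raise ValueError("no alignments given")
    mapped = sum(1 for a in alignments if a.mapped)
    return 100.0 * mapped / len(alignments)


# ---------------------------------------------------------------------------
# SAM exchange
# ---------------------------------------------------------------------------


def write_sam(
    alignments: Sequence[Alignment],
    reads: Sequence[ReadRecord],
    reference: Mapping[str, str],
    path: str | os.PathLike,
) -> None:
    """Write alignments as minimal SAM (QNAME/FLAG/RNAME/POS/MAPQ/CIGAR/SEQ/QUAL)."""
    by_id = {r.read_id: r for r in reads}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for tid, seq in reference.items():
            fh.write(f"@SQ\tSN:{tid}\tLN:{len(seq)}\n")
        for a in alignments:
            r = by_id[a.read_id]
            qual = "".join(chr(q + PHRED_OFFSET) for q in r.qualities)
            if a.mapped:
                fields = [
                    a.read_id, "0", a.transcript_id, str(a.start + 1), "255",
                    a.cigar, "*", "0", "0", r.sequence, qual, f"NM:i:{a.mismatches}",
                ]
            else:
                fields = [
                    a.read_id, "4", "*", "0", "0", "*", "*", "0", "0",
                    r.sequence, qual,
                ]
            fh.write("\t".join(fields) + "\n")


def import_alignments(
    path: str | os.PathLike, reference: Mapping[str, str]
) -> list[Alignment]:
    """Import a SAM file, converting 1-based POS to the internal 0-based start.

    Header sequence names must be a subset of the reference; mismatch counts
    are taken from the NM tag when present and recomputed otherwise.
    """
    out: list[Alignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for name in sam.references:
            if name not in reference:
                raise ValueError(
                    f"SAM sequence {name!r} not present in the reference"
                )
        for i, rec in enumerate(sam):
            if rec.is_unmapped:
                out.append(Alignment(rec.query_name, None, -1, -1, False))
                continue
            tid = rec.reference_name
            if tid not in reference:
                raise ValueError(f"record {i} ({rec.query_name}): unknown reference {tid}")
            cigar = rec.cigarstring
            if cigar is None or not re.fullmatch(r"(\d+[MID])+", cigar):
                raise ValueError(
                    f"record {i} ({rec.query_name}): unsupported CIGAR {cigar!r}"
                )
            start = rec.reference_start  # pysam is already 0-based
            aln = Alignment(rec.query_name, tid, start, 0, True, cigar)
            if rec.has_tag("NM"):
                mm = int(rec.get_tag("NM"))
            else:
                mm = _count_mismatches(aln, rec.query_sequence, reference[tid])
            out.append(
                Alignment(rec.query_name, tid, start, mm, True, cigar)
            )
    return out


def _count_mismatches(aln: Alignment, seq: str, ref: str) -> int:
    mm = 0
    rpos, qpos = aln.start, 0
    for n, op in aln.cigar_ops():
        if op == "M":
            mm += sum(1 for a, b in zip(seq[qpos : qpos + n], ref[rpos : rpos + n]) if a != b)
            rpos += n
            qpos += n
        elif op == "D":
            rpos += n
        else:
            qpos += n
    return mm


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------


def left_normalize_indel(seq: str, anchor: int, key: str) -> tuple[int, str]:
    """Shift an InDel observation to its leftmost equivalent anchor.

    ``key`` is "+SEQ" (insertion after the anchor) or "-SEQ" (deleted
    bases).  An InDel inside a repeat run admits several equivalent
    placements; the canonical one anchors furthest left, so observations of
    the same event from different reads coalesce.
    """
    kind, allele = key[0], key[1:]
    while anchor >= 0 and allele and allele[-1] == seq[anchor]:
        allele = seq[anchor] + allele[:-1]
        anchor -= 1
    return anchor, kind + allele


def build_pileup(
    alignments: Sequence[Alignment],
    reads: Sequence[ReadRecord],
    reference: Mapping[str, str],
) -> Pileup:
    """Tally per-position base and InDel observations from mapped reads."""
    by_id = {r.read_id: r for r in reads}
    pile = Pileup()
    for tid, seq in reference.items():
        pile[tid] = TranscriptPileup(
            length=len(seq),
            base_counts=np.zeros((len(seq), 4), dtype=np.int64),
            del_depth=np.zeros(len(seq), dtype=np.int64),
        )
    base_codes = np.full(256, -1, dtype=np.int64)
    for b, i in BASE_TO_IDX.items():
        base_codes[ord(b)] = i
    for a in alignments:
        if not a.mapped:
            continue
        if a.transcript_id not in pile:
            raise ValueError(f"alignment to unknown transcript {a.transcript_id!r}")
        tp = pile[a.transcript_id]
        read = by_id[a.read_id]
        arr = np.frombuffer(read.sequence.encode("ascii"), dtype=np.uint8)
        if a.start < 0 or a.start + a.reference_span > tp.length:
            raise ValueError(
                f"alignment of {a.read_id} out of bounds on {a.transcript_id}"
            )
        rpos, qpos = a.start, 0
        for n, op in a.cigar_ops():
            if op == "M":
                codes = base_codes[arr[qpos : qpos + n]]
                valid = codes >= 0
                rows = np.arange(rpos, rpos + n)[valid]
                tp.base_counts[rows, codes[valid]] += 1
                rpos += n
                qpos += n
            elif op == "D":
                tp.del_depth[rpos : rpos + n] += 1
                deleted = reference[a.transcript_id][rpos : rpos + n]
                anchor, key = left_normalize_indel(
                    reference[a.transcript_id], rpos - 1, "-" + deleted
                )
                if anchor >= 0:
                    tp.indels.setdefault(anchor, Counter())[key] += 1
                rpos += n
            else:  # insertion
                inserted = read.sequence[qpos : qpos + n]
                anchor, key = left_normalize_indel(
                    reference[a.transcript_id], rpos - 1, "+" + inserted
                )
                if anchor >= 0:
                    tp.indels.setdefault(anchor, Counter())[key] += 1
                qpos += n
    return pile


def merge_pileups(a: Pileup, b: Pileup) -> Pileup:
    """Pool two pileups built against the same reference (e.g. replicates)."""
    if set(a) != set(b):
        raise ValueError("pileups cover different transcript sets")
    out = Pileup()
    for tid in a:
        ta, tb = a[tid], b[tid]
        merged = TranscriptPileup(
            length=ta.length,
            base_counts=ta.base_counts + tb.base_counts,
            del_depth=ta.del_depth + tb.del_depth,
        )
        for src in (ta.indels, tb.indels):
            for pos, ctr in src.items():
                merged.indels.setdefault(pos, Counter()).update(ctr)
        out[tid] = merged
    return out
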