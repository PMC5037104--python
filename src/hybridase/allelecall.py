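"""Inter-parental SNP calling and read-wise assignment of F1 reads.

SNPs between the two parents (called on the pseudo-reference) act as
copy-specific tags.  Under the read-wise strategy each mapped F1 read is
inspected at every parental-SNP position it covers and contributes at most
one count to the parent whose alleles it carries; the SNP-wise strategy,
kept for comparison, counts every (read, SNP) observation and therefore
over-counts reads spanning several SNPs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import Alignment, Pileup, ReadRecord, gene_of

logger = logging.getLogger(__name__)

_IDX_TO_BASE = "ACGT"


@dataclass(frozen=True)
class ParentalSNP:
    """A pseudo-reference position with distinct parental majority alleles."""

    transcript_id: str
    position: int  # 0-based on the pseudo-reference
    apo_allele: str
    ir64_allele: str
    depth_apo: int
    depth_ir64: int
    prop_apo: float
    prop_ir64: float


class ReadClass(str, Enum):
    APO = "APO"
    IR64 = "IR64"
    CONFLICT = "CONFLICT"
    UNINFORMATIVE = "UNINFORMATIVE"


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    transcript_id: str
    informative_snps_covered: int
    votes_apo: int
    votes_ir64: int
    klass: ReadClass


@dataclass
class SampleAssignment:
    """Per-sample result: read assignments plus per-gene allele counts."""

    assignments: list[ReadAssignment]
    gene_counts: pd.DataFrame  # gene_id, apo_reads, ir64_reads, unspecified_reads
    mapped_total: int

    @property
    def apo_total(self) -> int:
        return int(self.gene_counts["apo_reads"].sum())

    @property
    def ir64_total(self) -> int:
        return int(self.gene_counts["ir64_reads"].sum())


def call_parental_snps(
    pileup_apo: Pileup,
    pileup_ir64: Pileup,
    min_depth: int = 3,
    min_prop: float = 0.8,
) -> list[ParentalSNP]:
    """Sites where each parent has a clear majority allele and they differ.

    Each parent needs column depth >= ``min_depth`` and a single majority
    base at a proportion strictly greater than ``min_prop``; the site is
    emitted only when the two majority bases differ.
    """
    snps: list[ParentalSNP] = []
    for tid in pileup_apo:
        if tid not in pileup_ir64:
            continue
        ta, tb = pileup_apo[tid], pileup_ir64[tid]
        depth_a = ta.base_counts.sum(axis=1) + ta.del_depth
        depth_b = tb.base_counts.sum(axis=1) + tb.del_depth
        maj_a = ta.base_counts.argmax(axis=1)
        maj_b = tb.base_counts.argmax(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            prop_a = np.where(
                depth_a > 0,
                ta.base_counts[np.arange(ta.length), maj_a] / depth_a, 0.0,
            )
            prop_b = np.where(
                depth_b > 0,
                tb.base_counts[np.arange(tb.length), maj_b] / depth_b, 0.0,
            )
        ok = (
            (depth_a >= min_depth)
            & (depth_b >= min_depth)
            & (prop_a > min_prop)
            & (prop_b > min_prop)
            & (maj_a != maj_b)
        )
        for pos in np.flatnonzero(ok):
            snps.append(
                ParentalSNP(
                    tid, int(pos),
                    _IDX_TO_BASE[maj_a[pos]], _IDX_TO_BASE[maj_b[pos]],
                    int(depth_a[pos]), int(depth_b[pos]),
                    float(prop_a[pos]), float(prop_b[pos]),
                )
            )
    snps.sort(key=lambda s: (s.transcript_id, s.position))
    return snps


def _snp_lookup(snps: Sequence[ParentalSNP]):
    by_tid: dict[str, tuple[np.ndarray, list[str], list[str]]] = {}
    tmp: dict[str, list[ParentalSNP]] = {}
    for s in snps:
        tmp.setdefault(s.transcript_id, []).append(s)
    for tid, lst in tmp.items():
        lst.sort(key=lambda s: s.position)
        pos = np.array([s.position for s in lst], dtype=np.int64)
        by_tid[tid] = (pos, [s.apo_allele for s in lst], [s.ir64_allele for s in lst])
    return by_tid


def _read_base_at(aln: Alignment, seq: str, refpos: int) -> str | None:
    """Base of the read aligned to reference position ``refpos`` (None if the
    position falls in a deletion or outside the alignment)."""
    rpos, qpos = aln.start, 0
    for n, op in aln.cigar_ops():
        if op == "M":
            if rpos <= refpos < rpos + n:
                return seq[qpos + (refpos - rpos)]
            rpos += n
            qpos += n
        elif op == "D":
            if rpos <= refpos < rpos + n:
                return None
            rpos += n
        else:
            qpos += n
    return None


def assign_reads_readwise(
    f1_alignments: Sequence[Alignment],
    f1_reads: Sequence[ReadRecord],
    snps: Sequence[ParentalSNP],
    reference: Mapping[str, str] | None = None,
) -> SampleAssignment:
    """Classify every mapped F1 read by the parental alleles it carries.

    Each covered parental-SNP position casts at most one vote: a base equal
    to the Apo allele votes Apo, equal to the IR64 allele votes IR64, and a
    base matching neither (a sequencing error) is ignored.  A read voting
    for exactly one parent counts once toward that parent's allele of its
    gene; conflicting and uninformative reads are tallied as unspecified.
    """
    lookup = _snp_lookup(snps)
    if reference is not None:
        for tid, (pos, _, _) in lookup.items():
            if tid in reference and pos.size and pos[-1] >= len(reference[tid]):
                raise ValueError(
                    f"parental SNP beyond end of {tid}: position {int(pos[-1])}"
                )
    reads_by_id = {r.read_id: r for r in f1_reads}
    assignments: list[ReadAssignment] = []
    counts: dict[str, list[int]] = {}  # gene -> [apo, ir64, mapped]
    mapped_total = 0
    for aln in f1_alignments:
        if not aln.mapped:
            continue
        mapped_total += 1
        gene = gene_of(aln.transcript_id)
        tally = counts.setdefault(gene, [0, 0, 0])
        tally[2] += 1
        entry = lookup.get(aln.transcript_id)
        if entry is None:
            continue
        pos, apo_alleles, ir64_alleles = entry
        span_end = aln.start + aln.reference_span
        lo = int(np.searchsorted(pos, aln.start, side="left"))
        hi = int(np.searchsorted(pos, span_end, side="left"))
        if lo == hi:
            continue
        seq = reads_by_id[aln.read_id].sequence
        votes_apo = votes_ir64 = covered = 0
        for i in range(lo, hi):
            base = _read_base_at(aln, seq, int(pos[i]))
            if base is None:
                continue
            covered += 1
            if base == apo_alleles[i]:
                votes_apo += 1
            elif base == ir64_alleles[i]:
                votes_ir64 += 1
        if votes_apo and not votes_ir64:
            klass = ReadClass.APO
            tally[0] += 1
        elif votes_ir64 and not votes_apo:
            klass = ReadClass.IR64
            tally[1] += 1
        elif votes_apo and votes_ir64:
            klass = ReadClass.CONFLICT
        else:
            klass = ReadClass.UNINFORMATIVE
        if covered:
            assignments.append(
                ReadAssignment(aln.read_id, aln.transcript_id, covered,
                               votes_apo, votes_ir64, klass)
            )
    rows = [
        {"gene_id": g, "apo_reads": a, "ir64_reads": b,
         "unspecified_reads": m - a - b}
        for g, (a, b, m) in sorted(counts.items())
    ]
    gene_counts = pd.DataFrame(
        rows, columns=["gene_id", "apo_reads", "ir64_reads", "unspecified_reads"]
    )
    return SampleAssignment(assignments, gene_counts, mapped_total)


def count_snpwise(
    f1_alignments: Sequence[Alignment],
    f1_reads: Sequence[ReadRecord],
    snps: Sequence[ParentalSNP],
) -> pd.DataFrame:
    """Per-gene counts of (read, SNP) allele observations, no deduplication."""
    lookup = _snp_lookup(snps)
    reads_by_id = {r.read_id: r for r in f1_reads}
    counts: dict[str, list[int]] = {}
    for aln in f1_alignments:
        if not aln.mapped:
            continue
        entry = lookup.get(aln.transcript_id)
        if entry is None:
            continue
        pos, apo_alleles, ir64_alleles = entry
        span_end = aln.start + aln.reference_span
        lo = int(np.searchsorted(pos, aln.start, side="left"))
        hi = int(np.searchsorted(pos, span_end, side="left"))
        if lo == hi:
            continue
        seq = reads_by_id[aln.read_id].sequence
        gene = gene_of(aln.transcript_id)
        tally = counts.setdefault(gene, [0, 0])
        for i in range(lo, hi):
            base = _read_base_at(aln, seq, int(pos[i]))
            if base == apo_alleles[i]:
                tally[0] += 1
            elif base == ir64_alleles[i]:
                tally[1] += 1
    rows = [
        {"gene_id": g, "apo_obs": a, "ir64_obs": b}
        for g, (a, b) in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "apo_obs", "ir64_obs"])


def percent_assignable(apo: int, ir64: int, mapped: int) -> float:
    """Share of mapped reads assignable to a parent, truncated to 2 decimals.

    Truncation (not rounding) matches how the published per-sample
    percentages relate to their raw counts.
    """
    if mapped < 1:
        raise ValueError("mapped read count must be >= 1")
    a, b, m = int(apo), int(ir64), int(mapped)
    if a == apo and b == ir64 and m == mapped:  # exact integer arithmetic
        return ((a + b) * 10000 // m) / 100.0
    return math.floor((apo + ir64) / mapped * 10000.0) / 100.0


def tabulate_allele_counts(
    samples: Mapping[tuple[str, str], SampleAssignment],
) -> pd.DataFrame:
    """Per-sample totals in the published layout, with percent assignable.

    ``samples`` maps (condition, replicate) to that sample's assignment
    result.  APO + IR64 + unspecified always partitions the mapped total.
    """
    rows = []
    for (condition, replicate), sa in sorted(samples.items()):
        apo, ir64 = sa.apo_total, sa.ir64_total
        rows.append(
            {"condition": condition, "replicate": replicate,
             "mapped": sa.mapped_total, "from_apo": apo, "from_ir64": ir64,
             "unspecified": sa.mapped_total - apo - ir64,
             "pct_assignable": percent_assignable(apo, ir64, sa.mapped_total)
             if sa.mapped_total else 0.0}
        )
    return pd.DataFrame(
        rows, columns=["condition", "replicate", "mapped", "from_apo",
                       "from_ir64", "unspecified", "pct_assignable"]
    )


def allele_count_matrix(
    samples: Mapping[tuple[str, str], SampleAssignment], condition: str
) -> pd.DataFrame:
    """Gene x (allele, replicate) raw count matrix for one condition.

    Columns are a MultiIndex (allele in {apo, ir64}, replicate); genes with
    no informative reads in any replicate of the condition are dropped.
    """
    pieces = {}
    for (cond, rep), sa in samples.items():
        if cond != condition:
            continue
        df = sa.gene_counts.set_index("gene_id")
        pieces[("apo", rep)] = df["apo_reads"]
        pieces[("ir64", rep)] = df["ir64_reads"]
    if not pieces:
        raise ValueError(f"no samples for condition {condition!r}")
    mat = pd.DataFrame(pieces).fillna(0).astype(int)
    mat.columns = pd.MultiIndex.from_tuples(mat.columns, names=["allele", "replicate"])
    mat = mat.loc[mat.sum(axis=1) > 0]
    mat = mat.sort_index().sort_index(axis=1)
    return mat
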