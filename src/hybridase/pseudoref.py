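"""Shared-variant calling and pseudo-reference construction.

Both *indica* parents are compared to the *japonica*-derived transcript
reference; sites where each parent independently shows the same
non-reference allele (SNPs at >0.8 proportion and >=5x depth, InDels at
>=0.5 proportion and >=5x depth) are edited into the reference.  Because
InDel edits shift coordinates, a per-transcript liftover map is built
alongside the edited sequences so positions can be translated in both
directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import BASE_TO_IDX, Pileup

logger = logging.getLogger(__name__)

_IDX_TO_BASE = "ACGT"

Kind = Literal["SNP", "insertion", "deletion"]


@dataclass(frozen=True)
class VariantCall:
    """A shared variant of both parents against the reference.

    ``position`` is 0-based: the substituted base for SNPs, the anchor (last
    reference base before the event) for InDels.  ``ref_allele`` is empty for
    insertions, ``alt_allele`` empty for deletions.
    """

    transcript_id: str
    position: int
    kind: Kind
    ref_allele: str
    alt_allele: str
    depth_apo: int
    depth_ir64: int
    prop_apo: float
    prop_ir64: float

    @property
    def length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass
class LiftoverMap:
    """Bidirectional coordinate maps between reference and pseudo-reference.

    For every transcript two integer arrays are kept: original->pseudo
    (positions inside deleted spans map to the deletion's left edge and are
    flagged) and pseudo->original (inserted positions map to their anchor and
    are flagged).
    """

    forward_pos: dict[str, np.ndarray] = field(default_factory=dict)
    forward_deleted: dict[str, np.ndarray] = field(default_factory=dict)
    inverse_pos: dict[str, np.ndarray] = field(default_factory=dict)
    inverse_inserted: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def identity(cls, reference: Mapping[str, str]) -> "LiftoverMap":
        m = cls()
        for tid, seq in reference.items():
            idx = np.arange(len(seq), dtype=np.int64)
            m.forward_pos[tid] = idx
            m.forward_deleted[tid] = np.zeros(len(seq), dtype=bool)
            m.inverse_pos[tid] = idx.copy()
            m.inverse_inserted[tid] = np.zeros(len(seq), dtype=bool)
        return m


def lift_coordinate(
    position: int,
    transcript_id: str,
    liftover: LiftoverMap,
    direction: Literal["forward", "inverse"] = "forward",
) -> tuple[int, bool]:
    """Translate a coordinate; the flag marks positions with no true image
    (inside a deleted span going forward, inside an inserted span going back)."""
    if direction == "forward":
        pos_map, flag_map = liftover.forward_pos, liftover.forward_deleted
    else:
        pos_map, flag_map = liftover.inverse_pos, liftover.inverse_inserted
    if transcript_id not in pos_map:
        raise KeyError(f"unknown transcript {transcript_id!r}")
    arr = pos_map[transcript_id]
    if not 0 <= position < arr.size:
        raise IndexError(
            f"position {position} outside transcript {transcript_id} "
            f"(length {arr.size})"
        )
    return int(arr[position]), bool(flag_map[transcript_id][position])


@dataclass
class PseudoReference:
    sequences: dict[str, str]
    provenance: list[VariantCall]
    liftover: LiftoverMap


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------


def _parent_snp_site(tp, pos: int, ref_idx: int, min_depth: int, min_prop: float):
    """Return (alt_base, depth, prop) if this parent supports a non-reference
    allele at the site, else None.  The proportion denominator is the column
    depth including reads whose deletion spans the site."""
    counts = tp.base_counts[pos]
    depth = int(counts.sum() + tp.del_depth[pos])
    if depth < min_depth:
        return None
    alt_counts = counts.copy()
    alt_counts[ref_idx] = 0
    alt_idx = int(alt_counts.argmax())
    prop = alt_counts[alt_idx] / depth
    if prop > min_prop:  # strictly greater: "more than 0.8"
        return _IDX_TO_BASE[alt_idx], depth, float(prop)
    return None


def call_shared_variants(
    pileup_apo: Pileup,
    pileup_ir64: Pileup,
    reference: Mapping[str, str],
    snp_min_depth: int = 5,
    snp_min_prop: float = 0.8,
    indel_min_depth: int = 5,
    indel_min_prop: float = 0.5,
) -> list[VariantCall]:
    """Call SNPs and InDels common to both parents against the reference.

    A SNP is emitted iff in *each* parent independently the column depth is
    >= ``snp_min_depth`` and the same non-reference base exceeds
    ``snp_min_prop`` (strict).  An InDel is emitted iff both parents observe
    the identical inserted/deleted string at >= ``indel_min_prop``
    (inclusive) of the anchor-column depth, with depth >= ``indel_min_depth``.
    """
    calls: list[VariantCall] = []
    for tid, seq in reference.items():
        if tid not in pileup_apo or tid not in pileup_ir64:
            continue
        ta, tb = pileup_apo[tid], pileup_ir64[tid]
        depth_a = ta.base_counts.sum(axis=1) + ta.del_depth
        depth_b = tb.base_counts.sum(axis=1) + tb.del_depth
        cand = np.flatnonzero(
            (depth_a >= snp_min_depth) & (depth_b >= snp_min_depth)
        )
        for pos in cand:
            ref_base = seq[pos]
            ref_idx = BASE_TO_IDX.get(ref_base)
            if ref_idx is None:
                continue
            ra = _parent_snp_site(ta, int(pos), ref_idx, snp_min_depth, snp_min_prop)
            rb = _parent_snp_site(tb, int(pos), ref_idx, snp_min_depth, snp_min_prop)
            if ra is None or rb is None or ra[0] != rb[0]:
                continue
            calls.append(
                VariantCall(tid, int(pos), "SNP", ref_base, ra[0],
                            ra[1], rb[1], ra[2], rb[2])
            )
        anchors = set(ta.indels) & set(tb.indels)
        for anchor in sorted(anchors):
            if anchor < 0:
                continue
            da = int(ta.base_counts[anchor].sum() + ta.del_depth[anchor])
            db = int(tb.base_counts[anchor].sum() + tb.del_depth[anchor])
            if da < indel_min_depth or db < indel_min_depth:
                continue
            common = set(ta.indels[anchor]) & set(tb.indels[anchor])
            for key in sorted(common):
                pa = ta.indels[anchor][key] / da
                pb = tb.indels[anchor][key] / db
                if pa < indel_min_prop or pb < indel_min_prop:  # inclusive >=
                    continue
                if key.startswith("+"):
                    calls.append(
                        VariantCall(tid, anchor, "insertion", "", key[1:],
                                    da, db, float(pa), float(pb))
                    )
                else:
                    calls.append(
                        VariantCall(tid, anchor, "deletion", key[1:], "",
                                    da, db, float(pa), float(pb))
                    )
    calls.sort(key=lambda v: (v.transcript_id, v.position, v.kind))
    return calls


def resolve_overlaps(variants: Sequence[VariantCall]) -> list[VariantCall]:
    """Drop lower-supported calls whose edit spans overlap (greedy by support)."""
    kept: list[VariantCall] = []
    by_tid: dict[str, list[tuple[int, int]]] = {}
    ordered = sorted(
        variants,
        key=lambda v: (-min(v.prop_apo, v.prop_ir64), -min(v.depth_apo, v.depth_ir64)),
    )
    for v in ordered:
        span = _edit_span(v)
        spans = by_tid.setdefault(v.transcript_id, [])
        if any(not (span[1] < s or e < span[0]) for s, e in spans):
            logger.info("dropping overlapping call %s:%d %s", v.transcript_id,
                        v.position, v.kind)
            continue
        spans.append(span)
        kept.append(v)
    kept.sort(key=lambda v: (v.transcript_id, v.position, v.kind))
    return kept


def _edit_span(v: VariantCall) -> tuple[int, int]:
    if v.kind == "SNP":
        return (v.position, v.position)
    if v.kind == "insertion":
        return (v.position, v.position)
    return (v.position, v.position + len(v.ref_allele))  # deletion incl. anchor


# ---------------------------------------------------------------------------
# editing
# ---------------------------------------------------------------------------


def build_pseudo_reference(
    reference: Mapping[str, str], variants: Sequence[VariantCall]
) -> PseudoReference:
    """Edit shared variants into the reference and build the liftover map.

    SNP substitutions and InDel edits are applied right-to-left per
    transcript; overlapping edit spans raise with the offending calls named.
    """
    by_tid: dict[str, list[VariantCall]] = {}
    for v in variants:
        if v.transcript_id not in reference:
            raise KeyError(f"variant on unknown transcript {v.transcript_id!r}")
        by_tid.setdefault(v.transcript_id, []).append(v)
    sequences: dict[str, str] = {}
    lift = LiftoverMap()
    for tid, seq in reference.items():
        edits = sorted(by_tid.get(tid, []), key=lambda v: v.position)
        for prev, nxt in zip(edits, edits[1:]):
            if _edit_span(nxt)[0] <= _edit_span(prev)[1]:
                raise ValueError(
                    f"overlapping variants on {tid}: "
                    f"{prev.kind}@{prev.position} and {nxt.kind}@{nxt.position}"
                )
        L = len(seq)
        out = seq
        for v in reversed(edits):
            p = v.position
            if v.kind == "SNP":
                if seq[p] != v.ref_allele:
                    raise ValueError(
                        f"{tid}:{p}: reference base {seq[p]} != call {v.ref_allele}"
                    )
                out = out[:p] + v.alt_allele + out[p + 1 :]
            elif v.kind == "insertion":
                out = out[: p + 1] + v.alt_allele + out[p + 1 :]
            else:
                dl = len(v.ref_allele)
                if seq[p + 1 : p + 1 + dl] != v.ref_allele:
                    raise ValueError(
                        f"{tid}:{p}: deleted bases do not match the reference"
                    )
                out = out[: p + 1] + out[p + 1 + dl :]
        sequences[tid] = out
        # forward map: original -> pseudo
        fwd = np.empty(L, dtype=np.int64)
        deleted = np.zeros(L, dtype=bool)
        delta = 0
        # walk original positions in order, applying offsets at edit sites
        pos = 0
        for v in edits:
            p = v.position
            fwd[pos : p + 1] = np.arange(pos, p + 1) + delta
            pos = p + 1
            if v.kind == "insertion":
                delta += len(v.alt_allele)
            elif v.kind == "deletion":
                dl = len(v.ref_allele)
                left_edge = fwd[p]
                fwd[pos : pos + dl] = left_edge
                deleted[pos : pos + dl] = True
                pos += dl
                delta -= dl
        fwd[pos:L] = np.arange(pos, L) + delta
        lift.forward_pos[tid] = fwd
        lift.forward_deleted[tid] = deleted
        # inverse map: pseudo -> original
        Lp = len(out)
        inv = np.empty(Lp, dtype=np.int64)
        inserted = np.zeros(Lp, dtype=bool)
        inv_filled = np.zeros(Lp, dtype=bool)
        orig_idx = np.flatnonzero(~deleted)
        inv[fwd[orig_idx]] = orig_idx
        inv_filled[fwd[orig_idx]] = True
        # remaining pseudo positions are inserted bases: map to their anchor
        gap = np.flatnonzero(~inv_filled)
        for g in gap:
            # anchor = original position of the last filled pseudo position left of g
            left = g - 1
            while left >= 0 and not inv_filled[left]:
                left -= 1
            inv[g] = inv[left] if left >= 0 else 0
            inserted[g] = True
        lift.inverse_pos[tid] = inv
        lift.inverse_inserted[tid] = inserted
    return PseudoReference(
        sequences=sequences,
        provenance=sorted(variants, key=lambda v: (v.transcript_id, v.position)),
        liftover=lift,
    )


def variants_to_frame(variants: Sequence[VariantCall]) -> pd.DataFrame:
    """VCF-like table (1-based positions) of shared variant calls."""
    rows = [
        {"transcript_id": v.transcript_id, "pos": v.position + 1, "kind": v.kind,
         "ref": v.ref_allele or ".", "alt": v.alt_allele or ".",
         "depth_apo": v.depth_apo, "depth_ir64": v.depth_ir64,
         "prop_apo": round(v.prop_apo, 4), "prop_ir64": round(v.prop_ir64, 4)}
        for v in variants
    ]
    return pd.DataFrame(
        rows, columns=["transcript_id", "pos", "kind", "ref", "alt",
                       "depth_apo", "depth_ir64", "prop_apo", "prop_ir64"]
    )
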