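"""Condition-mediated ASE profiles: tPAV, bidirectional, unidirectional.

Per-gene AI records from the two conditions are pairwise-compared.  Genes
with informative reads in exactly one condition show transcript
presence/absence variation (tPAV); genes asymmetric (fold magnitude >= the
threshold) in both conditions either switch their favored allele
(bidirectional) or keep it (unidirectional); genes below the fold
threshold in either condition stay biallelic_unclassified, since a
sub-threshold fold difference cannot anchor an allele preference.

The gene universe is gated by a significance rule: lenient keeps genes with
p < alpha in one or both conditions (the default), stringent demands
p < alpha in both except for tPAV genes, which are tested only where they
are expressed.  The stringent universe is always a subset of the lenient
one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PROFILE_CLASSES = (
    "tPAV_normal", "tPAV_stress",
    "bidirectional_ir64_to_apo", "bidirectional_apo_to_ir64",
    "unidirectional_apo", "unidirectional_ir64",
    "biallelic_unclassified",
)


@dataclass(frozen=True)
class ProfileSummary:
    n_total: int
    n_common: int
    n_unique_control: int
    n_unique_stress: int
    class_counts: dict[str, int]
    class_percentages: dict[str, float]  # of n_total, one decimal


def compare_conditions(
    records_control: pd.DataFrame,
    records_stress: pd.DataFrame,
    mode: str = "lenient",
    threshold: float = 1.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify each gene's condition-mediated ASE behavior.

    Inputs are the per-condition AI record tables (genes present in a table
    were detected there, i.e. had informative reads).  Returns one row per
    universe gene with columns gene_id, profile_class, log2fc/p per
    condition.
    """
    if mode not in ("lenient", "stringent"):
        raise ValueError(f"unknown mode {mode!r}")
    for name, rec in (("control", records_control), ("stress", records_stress)):
        if not rec.empty and rec["gene_id"].duplicated().any():
            dup = rec.loc[rec["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids in {name} records: {dup[:5]}")
    ctrl = records_control.set_index("gene_id") if not records_control.empty else pd.DataFrame()
    strs = records_stress.set_index("gene_id") if not records_stress.empty else pd.DataFrame()
    genes = sorted(set(ctrl.index) | set(strs.index))
    rows = []
    for gid in genes:
        in_c, in_s = gid in ctrl.index, gid in strs.index
        p_c = float(ctrl.loc[gid, "p_binomial"]) if in_c else np.nan
        p_s = float(strs.loc[gid, "p_binomial"]) if in_s else np.nan
        sig_c = in_c and p_c < alpha
        sig_s = in_s and p_s < alpha
        if mode == "lenient":
            in_universe = sig_c or sig_s
        else:
            if in_c and in_s:
                in_universe = sig_c and sig_s
            else:
                in_universe = sig_c or sig_s  # tPAV: tested where expressed
        if not in_universe:
            continue
        if in_c and not in_s:
            klass = "tPAV_normal"
        elif in_s and not in_c:
            klass = "tPAV_stress"
        else:
            mag_c = float(ctrl.loc[gid, "magnitude"])
            mag_s = float(strs.loc[gid, "magnitude"])
            dir_c = ctrl.loc[gid, "direction"]
            dir_s = strs.loc[gid, "direction"]
            asym_c = mag_c >= threshold and dir_c is not None
            asym_s = mag_s >= threshold and dir_s is not None
            if asym_c and asym_s:
                if dir_c == dir_s:
                    klass = f"unidirectional_{dir_c}"
                elif dir_c == "apo":
                    klass = "bidirectional_apo_to_ir64"
                else:
                    klass = "bidirectional_ir64_to_apo"
            else:
                klass = "biallelic_unclassified"
        rows.append(
            {"gene_id": gid, "profile_class": klass,
             "log2fc_control": float(ctrl.loc[gid, "log2fc"]) if in_c else np.nan,
             "log2fc_stress": float(strs.loc[gid, "log2fc"]) if in_s else np.nan,
             "p_control": p_c, "p_stress": p_s,
             "detected_control": in_c, "detected_stress": in_s}
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "profile_class", "log2fc_control",
                       "log2fc_stress", "p_control", "p_stress",
                       "detected_control", "detected_stress"]
    )


def profile_summary(records: pd.DataFrame) -> ProfileSummary:
    """Class counts and percentages of the profile universe.

    Percentages are of the full universe (common plus condition-unique
    genes), one decimal.  tPAV classes coincide with the condition-unique
    gene sets, so ``n_total = n_common + n_unique_control + n_unique_stress``.
    """
    n_total = len(records)
    if n_total == 0:
        return ProfileSummary(0, 0, 0, 0,
                              {c: 0 for c in PROFILE_CLASSES},
                              {c: 0.0 for c in PROFILE_CLASSES})
    counts = {
        c: int((records["profile_class"] == c).sum()) for c in PROFILE_CLASSES
    }
    pcts = {c: round(100.0 * n / n_total, 1) for c, n in counts.items()}
    n_unique_control = int(
        (records["detected_control"] & ~records["detected_stress"]).sum()
    )
    n_unique_stress = int(
        (records["detected_stress"] & ~records["detected_control"]).sum()
    )
    return ProfileSummary(
        n_total=n_total,
        n_common=n_total - n_unique_control - n_unique_stress,
        n_unique_control=n_unique_control,
        n_unique_stress=n_unique_stress,
        class_counts=counts,
        class_percentages=pcts,
    )


def grouped_percentages(summary: ProfileSummary) -> dict[str, float]:
    """Percentages of the three headline behaviors (tPAV, bidirectional,
    unidirectional) over the profile universe, one decimal."""
    n = summary.n_total
    if n == 0:
        return {"tPAV": 0.0, "bidirectional": 0.0, "unidirectional": 0.0}
    c = summary.class_counts
    return {
        "tPAV": round(100.0 * (c["tPAV_normal"] + c["tPAV_stress"]) / n, 1),
        "bidirectional": round(
            100.0 * (c["bidirectional_apo_to_ir64"] + c["bidirectional_ir64_to_apo"]) / n, 1
        ),
        "unidirectional": round(
            100.0 * (c["unidirectional_apo"] + c["unidirectional_ir64"]) / n, 1
        ),
    }
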