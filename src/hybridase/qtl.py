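"""Marker co-localization and selective-genotyping single-marker regression.

Allelically imbalanced genes are associated with grain-yield QTL in two
ways: physically, by co-localizing gene spans with SSR marker positions on
the same chromosome within a distance window; and statistically, by
regressing line-mean phenotypes of the phenotypic tails of a RIL panel on
an additive genotype score at each marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: genotype codes as scored from parental banding patterns
CODE_MISSING, CODE_IR64_HOM, CODE_APO_HOM, CODE_HET = 0, 1, 2, 3

#: additive regression coding: IR64 homozygote 0, heterozygote 1, Apo homozygote 2
ADDITIVE_SCORE = {CODE_IR64_HOM: 0.0, CODE_HET: 1.0, CODE_APO_HOM: 2.0}


@dataclass
class RILPanel:
    """Line x marker genotype codes with replicated phenotypes.

    ``genotypes``: DataFrame indexed by line id, one integer-coded column per
    marker (0 missing, 1 IR64 hom, 2 Apo hom, 3 het).  ``phenotypes``:
    DataFrame indexed by line id with replicate columns (NaN = missing).
    """

    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(np.unique(self.genotypes.to_numpy())) - {0, 1, 2, 3}
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        if not self.genotypes.index.equals(self.phenotypes.index):
            raise ValueError("genotype and phenotype line ids differ")


@dataclass(frozen=True)
class AssociationResult:
    marker: str
    n: int
    slope: float
    r_squared: float  # percent
    p_value: float
    monomorphic: bool = False


def colocalize(
    genes: pd.DataFrame, markers: pd.DataFrame, window_kb: float = 500.0
) -> pd.DataFrame:
    """Pair genes and markers on the same chromosome within ``window_kb``.

    ``genes`` needs columns gene_id/chrom/start/end (1-based inclusive bp);
    ``markers`` needs name/chrom/pos_bp.  Distance is 0 when the marker lies
    within the gene span, else the bp gap to the nearer gene end, in kb.
    Pairs are returned sorted by distance (ties by marker, then gene id).
    """
    rows = []
    for m in markers.itertuples(index=False):
        same = genes[genes["chrom"] == m.chrom]
        for g in same.itertuples(index=False):
            if g.start <= m.pos_bp <= g.end:
                dist = 0.0
            else:
                dist = min(abs(m.pos_bp - g.start), abs(m.pos_bp - g.end)) / 1000.0
            if dist <= window_kb:
                rows.append(
                    {"marker": m.name, "gene_id": g.gene_id, "chrom": m.chrom,
                     "distance_kb": dist}
                )
    out = pd.DataFrame(rows, columns=["marker", "gene_id", "chrom", "distance_kb"])
    return out.sort_values(
        ["distance_kb", "marker", "gene_id"], ignore_index=True
    )


def ls_means(phenotypes: pd.DataFrame) -> pd.Series:
    """Least-squares mean of replicate phenotypes per line.

    With a balanced two-replicate design this is the arithmetic mean of the
    replicates; a missing replicate leaves the other value.
    """
    if phenotypes.isna().all(axis=1).any():
        bad = phenotypes.index[phenotypes.isna().all(axis=1)].tolist()
        raise ValueError(f"lines with no phenotype observation: {bad}")
    return phenotypes.mean(axis=1, skipna=True)


def select_tails(line_means: pd.Series, fraction: float = 0.25) -> pd.Index:
    """Select the highest and lowest ``fraction/2`` of lines by mean phenotype.

    Ties are broken by line id; the two tails are disjoint unless the
    fraction covers the whole population, in which case all lines return.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = len(line_means)
    k = math.ceil(n * fraction / 2.0)
    order = line_means.reset_index()
    order.columns = ["line", "value"]
    ranked = order.sort_values(["value", "line"])["line"]
    low, high = ranked.head(k), ranked.tail(k)
    return pd.Index(sorted(set(low) | set(high)))


def single_marker_regression(
    panel: RILPanel, marker: str, lines: pd.Index | None = None
) -> AssociationResult:
    """OLS of line-mean phenotype on the additive genotype score at one marker.

    Missing genotypes (code 0) are excluded; the F-test p-value of the
    regression (equivalently the two-sided t-test on the slope, n-2
    denominator degrees of freedom) is reported, with R^2 as a percentage.
    """
    geno = panel.genotypes[marker]
    pheno = ls_means(panel.phenotypes)
    if lines is not None:
        geno = geno.loc[lines]
        pheno = pheno.loc[lines]
    mask = geno != CODE_MISSING
    geno, pheno = geno[mask], pheno[mask]
    if len(geno) < 3:
        raise ValueError(
            f"marker {marker}: fewer than 3 lines with non-missing genotype"
        )
    score = geno.map(ADDITIVE_SCORE).to_numpy(dtype=float)
    y = pheno.to_numpy(dtype=float)
    if np.all(score == score[0]):
        return AssociationResult(
            marker, len(score), float("nan"), float("nan"), float("nan"),
            monomorphic=True,
        )
    fit = stats.linregress(score, y)
    return AssociationResult(
        marker=marker,
        n=len(score),
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2 * 100.0),
        p_value=float(fit.pvalue),
        monomorphic=False,
    )


def association_table(
    panel: RILPanel, lines: pd.Index | None = None
) -> pd.DataFrame:
    """Single-marker regression across every marker of the panel."""
    rows = []
    for marker in panel.genotypes.columns:
        try:
            res = single_marker_regression(panel, marker, lines)
        except ValueError:
            continue
        rows.append(
            {"marker": res.marker, "n": res.n, "slope": res.slope,
             "r_squared_pct": res.r_squared, "p_value": res.p_value,
             "monomorphic": res.monomorphic}
        )
    return pd.DataFrame(
        rows, columns=["marker", "n", "slope", "r_squared_pct", "p_value",
                       "monomorphic"]
    )


def percent_polymorphic(n_polymorphic: int, n_markers: int) -> float:
    """Share of surveyed markers showing clear parental polymorphism, in %."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return round(100.0 * n_polymorphic / n_markers)
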