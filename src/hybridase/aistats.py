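"""Allelic-imbalance statistics: normalization, tests, fold change, classes.

Per condition, the gene x (allele, replicate) informative-read counts are
normalized by median-of-ratios size factors, the two replicates of each
allele are summed, and each gene is tested for departure from the 1:1
allelic null with an exact two-sided binomial test (a 1-df chi-square test
is computed alongside, filtered where the expected count n/2 falls below
5).  Fold change is Apo over IR64; at a significance level alpha, genes are
classified at a fold threshold (1.25x or 2.0x) as biallelic, Apo- or
IR64-favoring, with monoallelic subclasses when one allele contributes no
informative reads.

Significance for classification and all downstream profiling uses the
binomial p-value: unlike the chi-square it carries no sample-size filter.
No multiple-testing correction gates any class; a Benjamini-Hochberg
column is emitted for information only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ASE_CLASSES = (
    "biallelic", "apo_favoring", "ir64_favoring",
    "monoallelic_apo", "monoallelic_ir64", "not_significant",
)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def compute_size_factors(raw: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per column.

    For every gene with strictly positive counts in all columns, the
    geometric mean across columns is taken; each column's factor is the
    median over those genes of count / geometric mean.
    """
    if (raw < 0).any().any():
        raise ValueError("raw counts must be non-negative")
    positive = raw.loc[(raw > 0).all(axis=1)]
    if positive.empty:
        raise ValueError(
            "no gene has positive counts in every column; "
            "filter the matrix or pool further before normalizing"
        )
    geomean = np.exp(np.log(positive).mean(axis=1))
    ratios = positive.div(geomean, axis=0)
    return ratios.median(axis=0)


def normalize_and_combine(raw: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide by size factors, then sum replicates within each allele.

    ``raw`` has MultiIndex columns (allele, replicate); the result has one
    ``{allele}_combined`` column per allele.
    """
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    norm = raw.div(factors, axis=1)
    combined = norm.T.groupby(level="allele").sum().T
    combined.columns = [f"{a}_combined" for a in combined.columns]
    return combined


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


def binomial_ai_test(apo: float, ir64: float) -> float:
    """Exact two-sided binomial test of (apo, ir64) against a 1:1 null.

    Counts are rounded to the nearest integer first (normalized counts are
    fractional).  The p-value sums the probabilities of all outcomes no more
    likely than the observed one, capped at 1.
    """
    a, b = int(round(apo)), int(round(ir64))
    n = a + b
    if n < 1:
        raise ValueError("binomial AI test undefined for a zero-count gene")
    return min(1.0, stats.binomtest(a, n, 0.5).pvalue)


def chisq_ai_test(apo: float, ir64: float) -> float | None:
    """1-df chi-square of (apo, ir64) against expected (n/2, n/2).

    No continuity correction; returns None (gene filtered) when the
    expected count n/2 is below 5, the usual validity floor of the
    normal approximation.
    """
    a, b = int(round(apo)), int(round(ir64))
    n = a + b
    if n < 1:
        raise ValueError("chi-square AI test undefined for a zero-count gene")
    expected = n / 2.0
    if expected < 5.0:
        return None
    statistic = (a - expected) ** 2 / expected + (b - expected) ** 2 / expected
    return float(stats.chi2.sf(statistic, df=1))


@dataclass(frozen=True)
class FoldChange:
    fc: float  # Apo / IR64
    log2fc: float
    magnitude: float  # max/min, infinite when one side is zero
    direction: str | None  # "apo", "ir64", or None when exactly equal


def fold_change(apo: float, ir64: float) -> FoldChange:
    """Apo/IR64 expression ratio with magnitude and favored direction."""
    if apo == 0 and ir64 == 0:
        raise ValueError("fold change undefined when both alleles are zero")
    fc = apo / ir64 if ir64 > 0 else float("inf")
    log2fc = float(np.log2(fc)) if fc > 0 else float("-inf")
    if apo > ir64:
        direction = "apo"
    elif ir64 > apo:
        direction = "ir64"
    else:
        direction = None
    if min(apo, ir64) == 0:
        magnitude = float("inf")
    else:
        magnitude = max(apo, ir64) / min(apo, ir64)
    return FoldChange(fc, log2fc, magnitude, direction)


def classify_ase(
    p_value: float,
    apo_combined: float,
    ir64_combined: float,
    threshold: float,
    alpha: float = 0.05,
) -> str:
    """ASE class of one gene at a fold threshold.

    Non-significant genes stay unclassified; significant genes below the
    threshold are biallelic; at or above it, the favored parent's class
    applies, refined to monoallelic when the other allele is absent.
    """
    if p_value >= alpha:
        return "not_significant"
    fcr = fold_change(apo_combined, ir64_combined)
    if fcr.magnitude < threshold:
        return "biallelic"
    if fcr.direction == "apo":
        return "monoallelic_apo" if ir64_combined == 0 else "apo_favoring"
    return "monoallelic_ir64" if apo_combined == 0 else "ir64_favoring"


# ---------------------------------------------------------------------------
# per-condition table
# ---------------------------------------------------------------------------


def ai_table(
    raw_counts: pd.DataFrame,
    condition: str,
    alpha: float = 0.05,
    thresholds: tuple[float, ...] = (1.25, 2.0),
) -> pd.DataFrame:
    """Full AI record table for one condition.

    ``raw_counts``: gene x (allele, replicate) informative-read counts.
    Genes whose combined normalized counts are both zero are skipped with a
    log notice.  Output columns: combined counts, fc/log2fc/magnitude/
    direction, p_binomial, p_chisq (NaN where filtered), q_binomial
    (Benjamini-Hochberg, informational), and one ``class_{threshold}``
    column per threshold.
    """
    factors = compute_size_factors(raw_counts)
    combined = normalize_and_combine(raw_counts, factors)
    rows = []
    for gene_id, rec in combined.iterrows():
        apo_c, ir64_c = float(rec["apo_combined"]), float(rec["ir64_combined"])
        if round(apo_c) + round(ir64_c) < 1:
            logger.info("gene %s: zero combined counts in %s, skipped",
                        gene_id, condition)
            continue
        fcr = fold_change(apo_c, ir64_c)
        p_binom = binomial_ai_test(apo_c, ir64_c)
        p_chi = chisq_ai_test(apo_c, ir64_c)
        row = {
            "gene_id": gene_id, "condition": condition,
            "apo_combined": apo_c, "ir64_combined": ir64_c,
            "fc": fcr.fc, "log2fc": fcr.log2fc, "magnitude": fcr.magnitude,
            "direction": fcr.direction, "p_binomial": p_binom,
            "p_chisq": np.nan if p_chi is None else p_chi,
        }
        for t in thresholds:
            row[_class_col(t)] = classify_ase(p_binom, apo_c, ir64_c, t, alpha)
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q_binomial"] = stats.false_discovery_control(out["p_binomial"])
        cols = [c for c in out.columns if not c.startswith("class_")]
        cols = cols + [c for c in out.columns if c.startswith("class_")]
        out = out[cols]
    return out


def _class_col(threshold: float) -> str:
    return f"class_{str(threshold).replace('.', 'p')}"


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AISummary:
    """Counts of preferentially expressed genes at one fold threshold.

    Monoallelic genes are counted inside their favored side, so
    ``n_total_ai = n_apo_favoring + n_ir64_favoring`` always holds.
    ``pct_ai_over_significant`` is the AI share of all genes significant at
    alpha, rounded to one decimal (None when nothing is significant).
    """

    threshold: float
    n_apo_favoring: int
    n_ir64_favoring: int
    n_total_ai: int
    n_significant: int
    n_biallelic: int
    pct_ai_over_significant: float | None

    @classmethod
    def from_counts(
        cls,
        n_apo: int,
        n_ir64: int,
        n_significant: int,
        threshold: float = 1.25,
        n_biallelic: int | None = None,
    ) -> "AISummary":
        total = n_apo + n_ir64
        if n_biallelic is None:
            n_biallelic = n_significant - total
        pct = (
            round(100.0 * total / n_significant, 1) if n_significant else None
        )
        return cls(threshold, n_apo, n_ir64, total, n_significant, n_biallelic, pct)


def summarize_ai(records: pd.DataFrame, threshold: float = 1.25) -> AISummary:
    """Tally AI classes of one condition's record table at one threshold."""
    if records.empty:
        return AISummary.from_counts(0, 0, 0, threshold, 0)
    col = _class_col(threshold)
    if col not in records.columns:
        raise KeyError(f"records carry no class column for threshold {threshold}")
    classes = records[col]
    n_apo = int(classes.isin(["apo_favoring", "monoallelic_apo"]).sum())
    n_ir64 = int(classes.isin(["ir64_favoring", "monoallelic_ir64"]).sum())
    n_sig = int((classes != "not_significant").sum())
    n_biallelic = int((classes == "biallelic").sum())
    return AISummary.from_counts(n_apo, n_ir64, n_sig, threshold, n_biallelic)


def summary_frame(summaries: dict[tuple[str, float], AISummary]) -> pd.DataFrame:
    """Stack per-(condition, threshold) summaries into one report table."""
    rows = []
    for (condition, threshold), s in sorted(summaries.items()):
        rows.append(
            {"condition": condition, "threshold": threshold,
             "n_apo_favoring": s.n_apo_favoring,
             "n_ir64_favoring": s.n_ir64_favoring,
             "n_total_ai": s.n_total_ai, "n_significant": s.n_significant,
             "n_biallelic": s.n_biallelic,
             "pct_ai_over_significant": s.pct_ai_over_significant}
        )
    return pd.DataFrame(rows)
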