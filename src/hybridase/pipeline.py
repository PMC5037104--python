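"""End-to-end orchestration: simulate -> trim -> map -> pseudo-reference ->
assign -> AI test -> profiles -> QTL association, with file reports.

Every stage writes its table to the output directory so any stage can be
re-run or inspected in isolation; a manifest records the seed and every
threshold.  Re-running with the same configuration reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .aistats import AISummary, ai_table, summarize_ai, summary_frame
from .allelecall import (
    SampleAssignment,
    allele_count_matrix,
    assign_reads_readwise,
    call_parental_snps,
    tabulate_allele_counts,
)
from .io import write_fasta
from .preprocess import (
    ReferenceIndex,
    build_pileup,
    compute_mapping_rate,
    map_reads,
    merge_pileups,
    quality_trim_replicate,
)
from .profiles import compare_conditions, grouped_percentages, profile_summary
from .pseudoref import (
    build_pseudo_reference,
    call_shared_variants,
    resolve_overlaps,
    variants_to_frame,
)
from .qtl import association_table, colocalize, ls_means, select_tails
from .simulate import (
    SimulationConfig,
    generate_marker_panel,
    simulate_experiment,
    simulate_ril_panel,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the published defaults."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # trimming
    trim_quality_threshold: float = 28.0
    trim_percentile: float = 0.75
    # mapping
    max_mismatches: int = 2
    seed_length: int = 20
    max_indel: int = 3
    # shared-variant calling (vs the reference)
    snp_min_depth: int = 5
    snp_min_prop: float = 0.8
    indel_min_depth: int = 5
    indel_min_prop: float = 0.5
    # inter-parental SNP calling (on the pseudo-reference)
    parental_min_depth: int = 3
    parental_min_prop: float = 0.8
    # AI testing and classification
    alpha: float = 0.05
    fc_thresholds: tuple[float, float] = (1.25, 2.0)
    profile_threshold: float = 1.25
    mode: str = "lenient"
    # QTL association
    window_kb: float = 500.0
    tail_fraction: float = 0.25
    n_ril_lines: int = 160
    n_markers: int = 22
    qtl_effect: float = 2.0
    heritability: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("snp_min_depth", "indel_min_depth", "parental_min_depth",
                     "max_mismatches", "seed_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(t <= 0 for t in self.fc_thresholds):
            raise ValueError("fold-change thresholds must be positive")
        if self.mode not in ("lenient", "stringent"):
            raise ValueError("mode must be lenient or stringent")


@dataclass
class PipelineResult:
    config: PipelineConfig
    mapping_rates_original: dict[str, float]
    mapping_rates_pseudo: dict[str, float]
    variants: pd.DataFrame
    n_parental_snps: int
    allele_table: pd.DataFrame
    ai_records: dict[str, pd.DataFrame]
    ai_summaries: dict[tuple[str, float], AISummary]
    profile_records: pd.DataFrame
    profile_summary: "object"
    confusion: pd.DataFrame
    recovery_rate: float | None
    colocalization: pd.DataFrame
    association: pd.DataFrame
    selected_lines: list[str]
    outdir: Path | None


def run_pipeline(
    config: PipelineConfig, outdir: str | os.PathLike | None = None
) -> PipelineResult:
    """Execute every stage on a synthetic experiment and write reports."""
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate: %d genes", config.sim.n_genes)
    sim = simulate_experiment(config.sim)

    logger.info("stage trim")
    trimmed = {}
    for sample, reads in sim.reads.items():
        if reads:
            trimmed[sample] = quality_trim_replicate(
                reads, config.trim_quality_threshold, config.trim_percentile
            ).reads
        else:
            trimmed[sample] = []

    logger.info("stage map (original reference)")
    ref_index = ReferenceIndex(sim.reference, config.seed_length)
    parent_samples = [s for s in trimmed if not s.startswith("f1")]
    f1_samples = [s for s in trimmed if s.startswith("f1")]
    aln_orig = {
        s: map_reads(trimmed[s], ref_index, config.max_mismatches,
                     config.seed_length, config.max_indel)
        for s in parent_samples
    }
    rates_orig = {s: compute_mapping_rate(aln_orig[s]) for s in parent_samples if aln_orig[s]}

    logger.info("stage pseudoref")
    piles = {
        s: build_pileup(aln_orig[s], trimmed[s], sim.reference)
        for s in parent_samples
    }
    pile_apo = merge_pileups(piles["apo_rep1"], piles["apo_rep2"])
    pile_ir64 = merge_pileups(piles["ir64_rep1"], piles["ir64_rep2"])
    shared = call_shared_variants(
        pile_apo, pile_ir64, sim.reference,
        config.snp_min_depth, config.snp_min_prop,
        config.indel_min_depth, config.indel_min_prop,
    )
    shared = resolve_overlaps(shared)
    pseudo = build_pseudo_reference(sim.reference, shared)

    logger.info("stage map (pseudo-reference)")
    pseudo_index = ReferenceIndex(pseudo.sequences, config.seed_length)
    aln_pseudo = {
        s: map_reads(trimmed[s], pseudo_index, config.max_mismatches,
                     config.seed_length, config.max_indel)
        for s in parent_samples + f1_samples
    }
    rates_pseudo = {
        s: compute_mapping_rate(aln_pseudo[s])
        for s in parent_samples + f1_samples
        if aln_pseudo[s]
    }

    logger.info("stage parental SNPs")
    piles_pseudo = {
        s: build_pileup(aln_pseudo[s], trimmed[s], pseudo.sequences)
        for s in parent_samples
    }
    p_apo = merge_pileups(piles_pseudo["apo_rep1"], piles_pseudo["apo_rep2"])
    p_ir64 = merge_pileups(piles_pseudo["ir64_rep1"], piles_pseudo["ir64_rep2"])
    parental_snps = call_parental_snps(
        p_apo, p_ir64, config.parental_min_depth, config.parental_min_prop
    )

    logger.info("stage assign: %d parental SNPs", len(parental_snps))
    samples: dict[tuple[str, str], SampleAssignment] = {}
    for s in f1_samples:
        _, cond, rep = s.split("_")
        samples[(cond, rep)] = assign_reads_readwise(
            aln_pseudo[s], trimmed[s], parental_snps, pseudo.sequences
        )
    allele_table = tabulate_allele_counts(samples)

    logger.info("stage aitest")
    conditions = list(config.sim.conditions)
    ai_records: dict[str, pd.DataFrame] = {}
    ai_summaries: dict[tuple[str, float], AISummary] = {}
    for cond in conditions:
        try:
            counts = allele_count_matrix(samples, cond)
            rec = ai_table(counts, cond, config.alpha, config.fc_thresholds)
        except ValueError as exc:
            logger.warning("condition %s: %s", cond, exc)
            rec = pd.DataFrame(columns=["gene_id", "condition", "p_binomial"])
        ai_records[cond] = rec
        for t in config.fc_thresholds:
            ai_summaries[(cond, t)] = (
                summarize_ai(rec, t) if not rec.empty
                else AISummary.from_counts(0, 0, 0, t, 0)
            )

    logger.info("stage profiles")
    prof = compare_conditions(
        ai_records[conditions[0]], ai_records[conditions[1]],
        config.mode, config.profile_threshold, config.alpha,
    )
    psummary = profile_summary(prof)
    confusion, recovery = _profile_recovery(sim, prof)

    logger.info("stage QTL association")
    markers, ril_truth = generate_marker_panel(
        sim.gene_loci, config.seed, config.n_markers,
        effect=config.qtl_effect, heritability=config.heritability,
    )
    coloc = colocalize(sim.gene_loci, markers, config.window_kb)
    panel = simulate_ril_panel(ril_truth, config.n_ril_lines, config.seed + 17)
    means = ls_means(panel.phenotypes)
    selected = select_tails(means, config.tail_fraction)
    assoc = association_table(panel, selected)

    result = PipelineResult(
        config=config,
        mapping_rates_original=rates_orig,
        mapping_rates_pseudo=rates_pseudo,
        variants=variants_to_frame(shared),
        n_parental_snps=len(parental_snps),
        allele_table=allele_table,
        ai_records=ai_records,
        ai_summaries=ai_summaries,
        profile_records=prof,
        profile_summary=psummary,
        confusion=confusion,
        recovery_rate=recovery,
        colocalization=coloc,
        association=assoc,
        selected_lines=list(selected),
        outdir=out,
    )
    if out is not None:
        write_reports(result, sim, pseudo, out)
    return result


def _profile_recovery(sim, prof: pd.DataFrame):
    """Confusion of planted vs recovered profile classes.

    Scored over planted genes that carry at least one inter-parental SNP
    (genes without one are uninformative by construction).  The recovery
    rate covers the planted tPAV/bidirectional/unidirectional classes.
    """
    from .preprocess import gene_of

    truth = sim.truth.classes
    snp_genes = {
        gene_of(t)
        for t in sim.truth.variants.loc[
            sim.truth.variants["kind"] == "parental_snp", "transcript_id"
        ]
    }
    observed = prof.set_index("gene_id")["profile_class"] if not prof.empty else pd.Series(dtype=object)
    rows = []
    for rec in truth.itertuples(index=False):
        gene = gene_of(rec.gene_id)
        if gene not in snp_genes:
            continue
        got = observed.get(gene, "absent")
        rows.append(
            {"gene_id": gene, "truth_class": rec.truth_class,
             "expected_profile": rec.expected_profile, "observed_profile": got}
        )
    confusion = pd.DataFrame(
        rows, columns=["gene_id", "truth_class", "expected_profile",
                       "observed_profile"]
    )
    scored = confusion[
        confusion["truth_class"].isin(
            ["tPAV_normal", "tPAV_stress", "bidirectional", "unidirectional"]
        )
    ]
    recovery = (
        float((scored["expected_profile"] == scored["observed_profile"]).mean())
        if len(scored)
        else None
    )
    return confusion, recovery


def write_reports(result: PipelineResult, sim, pseudo, out: Path) -> None:
    """Write every stage table, the pseudo-reference, and the run manifest."""
    write_fasta(pseudo.sequences, out / "pseudo_reference.fasta")
    result.variants.to_csv(out / "shared_variants.tsv", sep="\t", index=False)
    result.allele_table.to_csv(out / "allele_counts.tsv", sep="\t", index=False)
    for cond, rec in result.ai_records.items():
        rec.to_csv(out / f"ai_records_{cond}.tsv", sep="\t", index=False)
    summary_frame(result.ai_summaries).to_csv(
        out / "ai_summary.tsv", sep="\t", index=False
    )
    result.profile_records.to_csv(out / "profiles.tsv", sep="\t", index=False)
    ps = result.profile_summary
    prof_sum = pd.DataFrame(
        [{"n_total": ps.n_total, "n_common": ps.n_common,
          "n_unique_control": ps.n_unique_control,
          "n_unique_stress": ps.n_unique_stress,
          **{f"n_{k}": v for k, v in ps.class_counts.items()},
          **{f"pct_{k}": v for k, v in grouped_percentages(ps).items()}}]
    )
    prof_sum.to_csv(out / "profile_summary.tsv", sep="\t", index=False)
    result.confusion.to_csv(out / "profile_confusion.tsv", sep="\t", index=False)
    result.colocalization.to_csv(out / "colocalization.tsv", sep="\t", index=False)
    result.association.to_csv(out / "association.tsv", sep="\t", index=False)
    manifest = {
        "package": "hybridase",
        "version": __version__,
        "seed": result.config.seed,
        "sim_seed": result.config.sim.seed,
        "thresholds": {
            k: v for k, v in dataclasses.asdict(result.config).items()
            if k != "sim"
        },
        "sim": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(result.config.sim).items()
            if k != "ratio_spec"
        },
        "n_shared_variants": int(len(result.variants)),
        "n_parental_snps": result.n_parental_snps,
        "n_profile_genes": int(result.profile_summary.n_total),
        "recovery_rate": result.recovery_rate,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
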