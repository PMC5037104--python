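"""Calibration and recovery experiments on synthetic data.

Each function sets up a seeded synthetic experiment, runs the relevant
pipeline stages, and scores the result against the planted truth: variant
recall and mapping-rate improvement from the pseudo-reference, binomial
test calibration and power, agreement of the two AI tests, end-to-end
profile-class recovery, and QTL detection by tail-selected single-marker
regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aistats import binomial_ai_test, chisq_ai_test, classify_ase
from .allelecall import call_parental_snps
from .pipeline import PipelineConfig
from .preprocess import (
    ReferenceIndex,
    build_pileup,
    compute_mapping_rate,
    left_normalize_indel,
    map_reads,
    merge_pileups,
)
from .pseudoref import (
    build_pseudo_reference,
    call_shared_variants,
    lift_coordinate,
    resolve_overlaps,
)
from .qtl import ls_means, select_tails, single_marker_regression
from .simulate import (
    RILTruth,
    SimulationConfig,
    derive_parental_haplotypes,
    generate_reference_transcriptome,
    simulate_reads,
    simulate_ril_panel,
)

_TRUTH_KIND = {"SNP": "shared_snp", "insertion": "shared_ins", "deletion": "shared_del"}


def recovery_pipeline_config(seed: int = 11, n_genes: int = 200) -> PipelineConfig:
    """End-to-end profile-recovery conditions: strong planted effects with
    enough inter-parental SNPs and depth that genes carry >= ~100
    informative reads per condition, the regime the profile classifier
    assumes."""
    return PipelineConfig(
        sim=SimulationConfig(
            n_genes=n_genes,
            gene_length_range=(500, 1000),
            parental_snp_rate=4.0,
            depth_per_gene=250,
            parent_depth_per_gene=100,
            base_error_rate=0.001,
            seed=seed,
        ),
        seed=seed,
    )


@dataclass
class VariantRecovery:
    """Outcome of the parental variant-recovery experiment."""

    n_planted_shared: int
    n_planted_parental: int
    shared_recall: float
    shared_snp_recall: float
    shared_indel_recall: float
    parental_recall: float
    n_false_alt: int
    n_residual_shared_at_planted: int
    mapping_rate_original: float
    mapping_rate_pseudo: float

    @property
    def improvement(self) -> float:
        return self.mapping_rate_pseudo - self.mapping_rate_original


def variant_recovery_experiment(
    seed: int = 7,
    n_genes: int = 120,
    gene_length_range: tuple[int, int] = (1000, 2000),
    coverage: float = 30.0,
    base_error_rate: float = 0.001,
    max_mismatches: int = 2,
    seed_length: int = 20,
) -> VariantRecovery:
    """Plant variants at the published densities, sequence both parents at
    ~``coverage`` x, and score shared-variant and parental-SNP recovery.

    Parents are mapped to the original reference to call shared variants
    (recall vs the planted truth), the pseudo-reference is built and both
    parents re-mapped (the mapping rate must not drop), and inter-parental
    SNPs are called on the pseudo-reference and lifted back for comparison
    with the planted truth.
    """
    config = SimulationConfig(
        n_genes=n_genes,
        gene_length_range=gene_length_range,
        depth_per_gene=1.0,
        parent_depth_per_gene=coverage / 2.0,  # two replicates per parent
        depth_is_coverage=True,
        base_error_rate=base_error_rate,
        seed=seed,
    )
    reference = generate_reference_transcriptome(config)
    hap_apo, hap_ir64, truth = derive_parental_haplotypes(reference, config)
    rng = np.random.default_rng(config.seed + 3)
    haps = (hap_apo, hap_ir64)
    libraries = {}
    for parent, frac in (("apo", 1.0), ("ir64", 0.0)):
        mixture = {tid: frac for tid in reference}
        for rep in (1, 2):
            name = f"{parent}_rep{rep}"
            libraries[name] = simulate_reads(haps, mixture, config, rng, name)

    ref_index = ReferenceIndex(reference, seed_length)
    aln_orig = {
        s: map_reads(reads, ref_index, max_mismatches, seed_length)
        for s, reads in libraries.items()
    }
    all_orig = [a for alns in aln_orig.values() for a in alns]
    rate_orig = compute_mapping_rate(all_orig)

    piles = {
        s: build_pileup(aln_orig[s], libraries[s], reference) for s in libraries
    }
    pile_apo = merge_pileups(piles["apo_rep1"], piles["apo_rep2"])
    pile_ir64 = merge_pileups(piles["ir64_rep1"], piles["ir64_rep2"])
    calls = resolve_overlaps(call_shared_variants(pile_apo, pile_ir64, reference))

    shared_truth = truth.variants[truth.variants["kind"] != "parental_snp"]
    truth_keys = set()
    for r in shared_truth.itertuples(index=False):
        if r.kind == "shared_snp":
            truth_keys.add((r.transcript_id, r.pos, r.kind, r.alt))
        else:
            sign = "+" if r.kind == "shared_ins" else "-"
            allele = r.alt if r.kind == "shared_ins" else r.ref
            anchor, key = left_normalize_indel(
                reference[r.transcript_id], r.pos, sign + allele
            )
            truth_keys.add((r.transcript_id, anchor, r.kind, key[1:]))
    called_keys = {
        (v.transcript_id, v.position, _TRUTH_KIND[v.kind],
         v.alt_allele if v.kind != "deletion" else v.ref_allele)
        for v in calls
    }
    hit = truth_keys & called_keys
    snp_truth = {k for k in truth_keys if k[2] == "shared_snp"}
    indel_truth = truth_keys - snp_truth
    n_false_alt = sum(
        1
        for v in calls
        if v.kind == "SNP"
        and (v.transcript_id, v.position, "shared_snp", v.alt_allele) not in truth_keys
        and any(
            (v.transcript_id, v.position) == (t, p) for t, p, k, _ in snp_truth
        )
    )

    pseudo = build_pseudo_reference(reference, calls)
    pseudo_index = ReferenceIndex(pseudo.sequences, seed_length)
    aln_pseudo = {
        s: map_reads(reads, pseudo_index, max_mismatches, seed_length)
        for s, reads in libraries.items()
    }
    all_pseudo = [a for alns in aln_pseudo.values() for a in alns]
    rate_pseudo = compute_mapping_rate(all_pseudo)

    piles_p = {
        s: build_pileup(aln_pseudo[s], libraries[s], pseudo.sequences)
        for s in libraries
    }
    p_apo = merge_pileups(piles_p["apo_rep1"], piles_p["apo_rep2"])
    p_ir64 = merge_pileups(piles_p["ir64_rep1"], piles_p["ir64_rep2"])

    # idempotence: the edited sites should no longer be called as shared
    residual = call_shared_variants(p_apo, p_ir64, pseudo.sequences)
    applied = {(v.transcript_id, v.position) for v in pseudo.provenance}
    lifted_applied = set()
    for tid, pos in applied:
        lp, _ = lift_coordinate(pos, tid, pseudo.liftover, "forward")
        lifted_applied.add((tid, lp))
    n_residual = sum(
        1 for v in residual if (v.transcript_id, v.position) in lifted_applied
    )

    snps = call_parental_snps(p_apo, p_ir64)
    parental_truth = truth.variants[truth.variants["kind"] == "parental_snp"]
    ptruth_keys = set()
    for r in parental_truth.itertuples(index=False):
        lp, deleted = lift_coordinate(r.pos, r.transcript_id, pseudo.liftover)
        if not deleted:
            ptruth_keys.add((r.transcript_id, lp, r.apo_allele, r.ir64_allele))
    pcalled = {(s.transcript_id, s.position, s.apo_allele, s.ir64_allele) for s in snps}
    p_hit = ptruth_keys & pcalled

    return VariantRecovery(
        n_planted_shared=len(truth_keys),
        n_planted_parental=len(ptruth_keys),
        shared_recall=len(hit) / len(truth_keys) if truth_keys else float("nan"),
        shared_snp_recall=(
            len(hit & snp_truth) / len(snp_truth) if snp_truth else float("nan")
        ),
        shared_indel_recall=(
            len(hit & indel_truth) / len(indel_truth) if indel_truth else float("nan")
        ),
        parental_recall=(
            len(p_hit) / len(ptruth_keys) if ptruth_keys else float("nan")
        ),
        n_false_alt=n_false_alt,
        n_residual_shared_at_planted=n_residual,
        mapping_rate_original=rate_orig,
        mapping_rate_pseudo=rate_pseudo,
    )


# ---------------------------------------------------------------------------
# AI test calibration
# ---------------------------------------------------------------------------


def binomial_type1_rate(
    seed: int = 0, n_genes: int = 5000, depth: int = 40, alpha: float = 0.05
) -> float:
    """Rejection rate of the binomial AI test on balanced (50:50) genes.

    The exact test is conservative by discreteness, so the rate should sit
    at or below alpha.
    """
    rng = np.random.default_rng(seed)
    apo = rng.binomial(depth, 0.5, size=n_genes)
    rejections = sum(
        1 for a in apo if binomial_ai_test(int(a), depth - int(a)) < alpha
    )
    return rejections / n_genes


def detection_power(
    seed: int = 0,
    n_genes: int = 1000,
    depth: int = 100,
    apo_fraction: float = 0.7,
    threshold: float = 1.25,
    alpha: float = 0.05,
) -> float:
    """Fraction of truly imbalanced genes classified asymmetric toward the
    correct parent at the given fold threshold."""
    rng = np.random.default_rng(seed)
    apo = rng.binomial(depth, apo_fraction, size=n_genes)
    favored = ("apo_favoring", "monoallelic_apo") if apo_fraction > 0.5 else (
        "ir64_favoring", "monoallelic_ir64")
    n_ok = 0
    for a in apo:
        a = int(a)
        b = depth - a
        p = binomial_ai_test(a, b)
        if classify_ase(p, a, b, threshold, alpha) in favored:
            n_ok += 1
    return n_ok / n_genes


def chisq_binomial_agreement(
    seed: int = 0, n_genes: int = 2000, alpha: float = 0.05
) -> float:
    """Share of genes where the chi-square and binomial tests agree on
    reject/accept at alpha.

    Genes follow the generator's default population: mostly balanced with a
    minority of clearly imbalanced ratios, at combined depths of 50-200
    informative reads (so the chi-square filter never triggers).
    Disagreement concentrates in the thin band of effects right at the
    rejection boundary, where the exact test is slightly more conservative.
    """
    rng = np.random.default_rng(seed)
    fracs = rng.choice(
        [0.5, 0.7, 0.3, 0.8, 0.2], size=n_genes, p=[0.6, 0.15, 0.15, 0.05, 0.05]
    )
    depths = rng.integers(50, 201, size=n_genes)
    apo = rng.binomial(depths, fracs)
    agree = 0
    for a, n in zip(apo, depths):
        a, b = int(a), int(n - a)
        pb = binomial_ai_test(a, b)
        pc = chisq_ai_test(a, b)
        agree += (pb < alpha) == (pc < alpha)
    return agree / n_genes


# ---------------------------------------------------------------------------
# QTL detection
# ---------------------------------------------------------------------------


def qtl_detection_experiment(
    seed: int = 0,
    n_seeds: int = 25,
    n_lines: int = 160,
    n_markers: int = 22,
    effect: float = 2.0,
    heritability: float = 0.9,
    tail_fraction: float = 0.25,
    random_subset: bool = False,
) -> float:
    """Fraction of seeded panels where the causal marker attains the
    smallest regression p-value among all polymorphic markers.

    With ``random_subset`` the same genotyping budget (the tail count) is
    spent on randomly chosen lines instead of the phenotypic tails.
    """
    marker_names = tuple(f"RM{2000 + i}" for i in range(n_markers))
    hits = 0
    for s in range(n_seeds):
        truth = RILTruth(
            marker_names=marker_names,
            qtl_effects={marker_names[0]: effect},
            heritability=heritability,
        )
        panel = simulate_ril_panel(truth, n_lines, seed=seed * 1000 + s)
        means = ls_means(panel.phenotypes)
        if random_subset:
            rng = np.random.default_rng(seed * 1000 + s + 500)
            n_sel = len(select_tails(means, tail_fraction))
            lines = panel.genotypes.index[
                rng.choice(n_lines, size=n_sel, replace=False)
            ]
        else:
            lines = select_tails(means, tail_fraction)
        best_marker, best_p = None, np.inf
        for m in marker_names:
            try:
                res = single_marker_regression(panel, m, lines)
            except ValueError:
                continue
            if not res.monomorphic and res.p_value < best_p:
                best_marker, best_p = m, res.p_value
        hits += best_marker == marker_names[0]
    return hits / n_seeds


def smr_null_rejection_rate(
    seed: int = 0,
    n_panels: int = 1000,
    n_lines: int = 40,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of single-marker regression when no effect is planted
    (phenotype is pure noise); should sit near alpha."""
    marker = ("RM9000",)
    rejections = 0
    tested = 0
    for s in range(n_panels):
        truth = RILTruth(marker_names=marker, qtl_effects={}, heritability=0.5)
        panel = simulate_ril_panel(
            truth, n_lines, seed=seed * 2000 + s, noise_sd=1.0,
            missing_fraction=0.0,
        )
        res = single_marker_regression(panel, marker[0])
        if res.monomorphic:
            continue
        tested += 1
        rejections += res.p_value < alpha
    return rejections / tested
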