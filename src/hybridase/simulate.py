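"""Synthetic-data generation for the full ASE pipeline.

Emulates the study system: a *japonica*-like reference transcriptome, two
*indica*-like parents (Apo, the paternal drought-tolerant line, and IR64,
the maternal high-yielding line) that share SNPs/InDels against the
reference at ~0.92 SNPs/kb and ~0.07 InDels/kb while differing from each
other at ~0.72 SNPs per gene, F1 libraries drawn as per-gene mixtures of
the two parental haplotypes with condition-dependent allelic ratios, and a
recombinant-inbred-line (RIL) panel with planted marker effects for
selective genotyping.

Every generated read encodes its gene and haplotype of origin in its
identifier, and every planted variant is recorded in a truth table, so all
downstream stages can be scored against known ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .preprocess import ReadRecord
from .qtl import RILPanel

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: truth class -> (Apo fraction under control, Apo fraction under stress);
#: None means the gene is not expressed in the hybrid under that condition.
DEFAULT_RATIO_SPEC: dict[str, tuple[float | None, float | None]] = {
    "biallelic": (0.5, 0.5),
    "apo_favoring": (0.7, 0.7),
    "ir64_favoring": (0.3, 0.3),
    "monoallelic_apo": (1.0, 1.0),
    "monoallelic_ir64": (0.0, 0.0),
    "tPAV_normal": (0.7, None),
    "tPAV_stress": (None, 0.7),
    "bidirectional": (0.8, 0.2),
    "unidirectional": (0.8, 0.65),
}

#: default truth-class mix.  Most genes are biallelic, as in real hybrid
#: transcriptomes: the median gene must be allelically balanced for
#: median-of-ratios size factors over allele x replicate columns to reflect
#: library depth rather than allelic imbalance.
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "biallelic": 0.50,
    "apo_favoring": 0.06,
    "ir64_favoring": 0.06,
    "monoallelic_apo": 0.03,
    "monoallelic_ir64": 0.03,
    "tPAV_normal": 0.06,
    "tPAV_stress": 0.06,
    "bidirectional": 0.08,
    "unidirectional": 0.12,
}

#: profile class the pipeline is expected to assign to each planted class
#: when informative depth is sufficient (used by recovery scoring).
EXPECTED_PROFILE = {
    "apo_favoring": "unidirectional_apo",
    "ir64_favoring": "unidirectional_ir64",
    "monoallelic_apo": "unidirectional_apo",
    "monoallelic_ir64": "unidirectional_ir64",
    "tPAV_normal": "tPAV_normal",
    "tPAV_stress": "tPAV_stress",
    "bidirectional": "bidirectional_apo_to_ir64",
    "unidirectional": "unidirectional_apo",
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Rates are planted densities: ``shared_snp_rate`` and
    ``shared_indel_rate`` are events per kilobase of transcript (both
    parents carry the event against the reference), ``parental_snp_rate``
    is the Poisson mean of inter-parental SNPs per gene.  ``depth_per_gene``
    is the Poisson-mean read count per gene per F1 sample;
    ``parent_depth_per_gene`` (defaulting to the same value) applies to each
    parental replicate.
    """

    n_genes: int = 200
    gene_length_range: tuple[int, int] = (500, 3000)
    shared_snp_rate: float = 0.92
    shared_indel_rate: float = 0.07
    parental_snp_rate: float = 0.72
    read_length: int = 90
    depth_per_gene: float = 100.0
    parent_depth_per_gene: float | None = None
    #: when True, depths are mean per-base coverages: the per-gene mean read
    #: count becomes depth * gene_length / read_length
    depth_is_coverage: bool = False
    base_error_rate: float = 0.001
    conditions: tuple[str, str] = ("control", "stress")
    ratio_spec: Mapping[str, tuple[float | None, float | None]] = field(
        default_factory=lambda: dict(DEFAULT_RATIO_SPEC)
    )
    class_weights: Mapping[str, float] | None = None
    low_quality_tail: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.gene_length_range
        if lo > hi or lo < 1:
            raise ValueError("invalid gene_length_range")
        if lo < self.read_length:
            raise ValueError(
                "gene_length_range lower bound must be >= read_length"
            )
        for name in ("shared_snp_rate", "shared_indel_rate", "parental_snp_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.base_error_rate < 1.0:
            raise ValueError("base_error_rate must be in [0, 1)")
        for cls, fracs in self.ratio_spec.items():
            for f in fracs:
                if f is not None and not 0.0 <= f <= 1.0:
                    raise ValueError(f"ratio for class {cls} outside [0, 1]")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are required")

    @property
    def parent_depth(self) -> float:
        return (
            self.depth_per_gene
            if self.parent_depth_per_gene is None
            else self.parent_depth_per_gene
        )


@dataclass
class TruthSet:
    """Ground truth of one simulated experiment.

    ``variants`` records every planted event in 0-based reference
    coordinates; ``classes`` holds the per-gene truth class and the Apo
    fraction under each condition.
    """

    variants: pd.DataFrame
    classes: pd.DataFrame


@dataclass
class RILTruth:
    """Planted marker effects for the RIL panel.

    ``qtl_effects`` maps marker name to the phenotype change per Apo-allele
    substitution (additive coding); ``heritability`` is the fraction of the
    variance of line-mean phenotypes that is genetic.
    """

    marker_names: tuple[str, ...]
    qtl_effects: dict[str, float]
    heritability: float = 0.9

    def validate(self) -> None:
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError("heritability must be within [0, 1]")
        for m, e in self.qtl_effects.items():
            if not math.isfinite(e):
                raise ValueError(f"non-finite effect for marker {m}")
            if m not in self.marker_names:
                raise ValueError(f"effect on unknown marker {m}")


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    reference: dict[str, str]
    hap_apo: dict[str, str]
    hap_ir64: dict[str, str]
    truth: TruthSet
    reads: dict[str, list[ReadRecord]]
    gene_loci: pd.DataFrame


# ---------------------------------------------------------------------------
# reference and haplotypes
# ---------------------------------------------------------------------------


def generate_reference_transcriptome(config: SimulationConfig) -> dict[str, str]:
    """Random transcript sequences under LOC-style identifiers."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_range
    ref: dict[str, str] = {}
    for i in range(config.n_genes):
        chrom = i % 12 + 1
        tid = f"LOC_Os{chrom:02d}g{10010 + 10 * i:05d}.1"
        length = int(rng.integers(lo, hi + 1))
        seq = bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")
        ref[tid] = seq
    return ref


def generate_gene_loci(
    reference: Mapping[str, str], seed: int = 0, spacing_bp: int = 150_000
) -> pd.DataFrame:
    """Assign genomic coordinates (chrom, 1-based start/end) to each gene."""
    rng = np.random.default_rng(seed + 101)
    rows = []
    next_start: dict[int, int] = {}
    for tid, seq in reference.items():
        chrom = int(tid[6:8])
        start = next_start.get(chrom, 1) + int(rng.integers(0, spacing_bp))
        end = start + len(seq) - 1
        next_start[chrom] = end + 1
        rows.append({"gene_id": tid, "chrom": chrom, "start": start, "end": end})
    return pd.DataFrame(rows)


def _draw_positions(
    rng: np.random.Generator, length: int, n: int, occupied: set[int], span: int = 1
) -> list[int]:
    """Draw ``n`` non-overlapping event positions, re-drawing on conflict."""
    out = []
    for _ in range(n):
        for _attempt in range(200):
            # keep a read-length-free margin of 1 at both ends for anchoring
            pos = int(rng.integers(1, length - span))
            window = range(pos - 1, pos + span + 1)
            if all(p not in occupied for p in window):
                occupied.update(range(pos, pos + span))
                out.append(pos)
                break
        else:
            logger.warning("could not place event after 200 draws; skipping")
    return out


def derive_parental_haplotypes(
    reference: Mapping[str, str], config: SimulationConfig
) -> tuple[dict[str, str], dict[str, str], TruthSet]:
    """Plant shared and inter-parental variants and build both haplotypes.

    Shared SNPs/InDels (both parents differ identically from the reference)
    are planted at ``shared_snp_rate``/``shared_indel_rate`` per kb; at each
    inter-parental SNP one randomly chosen parent carries a non-reference
    allele while the other retains the reference base.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    var_rows = []
    hap_apo: dict[str, str] = {}
    hap_ir64: dict[str, str] = {}
    for tid, seq in reference.items():
        L = len(seq)
        occupied: set[int] = set()
        kb = L / 1000.0
        n_snp = rng.poisson(config.shared_snp_rate * kb)
        n_indel = rng.poisson(config.shared_indel_rate * kb)
        n_parental = rng.poisson(config.parental_snp_rate)
        events: list[dict] = []
        for pos in _draw_positions(rng, L, n_snp, occupied):
            ref_base = seq[pos]
            alt = _other_base(rng, ref_base)
            events.append(
                dict(transcript_id=tid, pos=pos, kind="shared_snp",
                     ref=ref_base, alt=alt, apo_allele=alt, ir64_allele=alt)
            )
        for _ in range(n_indel):
            ilen = int(rng.integers(1, 4))
            kind = "shared_ins" if rng.random() < 0.5 else "shared_del"
            span = ilen + 1 if kind == "shared_del" else 1
            placed = _draw_positions(rng, L, 1, occupied, span=span)
            if not placed:
                continue
            pos = placed[0]  # anchor: base after which the event occurs
            if kind == "shared_ins":
                ins = bytes(_BASES[rng.integers(0, 4, size=ilen)]).decode()
                events.append(
                    dict(transcript_id=tid, pos=pos, kind=kind, ref="", alt=ins,
                         apo_allele=ins, ir64_allele=ins)
                )
            else:
                deleted = seq[pos + 1 : pos + 1 + ilen]
                events.append(
                    dict(transcript_id=tid, pos=pos, kind=kind, ref=deleted,
                         alt="", apo_allele="", ir64_allele="")
                )
        for pos in _draw_positions(rng, L, n_parental, occupied):
            ref_base = seq[pos]
            alt = _other_base(rng, ref_base)
            carrier = "apo" if rng.random() < 0.5 else "ir64"
            events.append(
                dict(transcript_id=tid, pos=pos, kind="parental_snp",
                     ref=ref_base, alt=alt,
                     apo_allele=alt if carrier == "apo" else ref_base,
                     ir64_allele=alt if carrier == "ir64" else ref_base)
            )
        var_rows.extend(events)
        hap_apo[tid] = _apply_events(seq, events, "apo_allele")
        hap_ir64[tid] = _apply_events(seq, events, "ir64_allele")
    variants = pd.DataFrame(
        var_rows,
        columns=["transcript_id", "pos", "kind", "ref", "alt",
                 "apo_allele", "ir64_allele"],
    )
    classes = assign_truth_classes(list(reference), config)
    return hap_apo, hap_ir64, TruthSet(variants=variants, classes=classes)


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, len(choices)))]


def _apply_events(seq: str, events: list[dict], allele_field: str) -> str:
    out = seq
    for ev in sorted(events, key=lambda e: e["pos"], reverse=True):
        pos, kind = ev["pos"], ev["kind"]
        allele = ev[allele_field]
        if kind.endswith("snp"):
            out = out[:pos] + allele + out[pos + 1 :]
        elif kind == "shared_ins":
            out = out[: pos + 1] + allele + out[pos + 1 :]
        else:  # shared_del
            out = out[: pos + 1] + out[pos + 1 + len(ev["ref"]) :]
    return out


def assign_truth_classes(
    gene_ids: list[str], config: SimulationConfig
) -> pd.DataFrame:
    """Assign each gene exactly one truth class and its per-condition ratios."""
    rng = np.random.default_rng(config.seed + 2)
    classes = list(config.ratio_spec)
    spec_weights = (
        DEFAULT_CLASS_WEIGHTS if config.class_weights is None else config.class_weights
    )
    weights = np.array([spec_weights.get(c, 0.0) for c in classes])
    if weights.sum() <= 0:
        weights = np.ones(len(classes))
    weights = weights / weights.sum()
    drawn = rng.choice(len(classes), size=len(gene_ids), p=weights)
    rows = []
    cond_a, cond_b = config.conditions
    for gid, ci in zip(gene_ids, drawn):
        cls = classes[int(ci)]
        fa, fb = config.ratio_spec[cls]
        rows.append(
            {"gene_id": gid, "truth_class": cls,
             f"apo_fraction_{cond_a}": fa, f"apo_fraction_{cond_b}": fb,
             "expected_profile": EXPECTED_PROFILE.get(cls, "biallelic_unclassified")}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    haplotypes: tuple[Mapping[str, str], Mapping[str, str]],
    mixture: Mapping[str, float | None],
    config: SimulationConfig,
    rng: np.random.Generator,
    sample: str,
) -> list[ReadRecord]:
    """Draw reads for one library as a per-gene mixture of the two haplotypes.

    ``mixture[gene]`` is the probability that a read originates from the Apo
    haplotype (None: the gene is silent in this library).  Read identifiers
    take the form ``{sample}:{serial}|{transcript}|{apo|ir64}``.
    """
    hap_apo, hap_ir64 = haplotypes
    if not hap_apo or not hap_ir64:
        raise ValueError("empty haplotype set")
    rl = config.read_length
    err = config.base_error_rate
    qual = [35] * rl
    if config.low_quality_tail:
        qual[rl - config.low_quality_tail :] = [2] * config.low_quality_tail
    qual_t = tuple(qual)
    reads: list[ReadRecord] = []
    serial = 0
    for tid in hap_apo:
        frac = mixture.get(tid)
        if frac is None:
            continue
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"mixture fraction for {tid} outside [0, 1]")
        depth = config.depth_per_gene if sample.startswith("f1") else config.parent_depth
        if config.depth_is_coverage:
            depth = depth * len(hap_apo[tid]) / rl
        n = int(rng.poisson(depth))
        if n == 0:
            continue
        from_apo = rng.random(n) < frac
        arrs = {
            True: np.frombuffer(hap_apo[tid].encode(), dtype=np.uint8),
            False: np.frombuffer(hap_ir64[tid].encode(), dtype=np.uint8),
        }
        for is_apo in (True, False):
            src = arrs[is_apo]
            count = int(from_apo.sum()) if is_apo else int(n - from_apo.sum())
            if count == 0:
                continue
            if src.size < rl:
                raise ValueError(f"haplotype of {tid} shorter than read length")
            starts = rng.integers(0, src.size - rl + 1, size=count)
            hap_name = "apo" if is_apo else "ir64"
            for s in starts:
                frag = src[s : s + rl].copy()
                if err > 0:
                    mask = rng.random(rl) < err
                    n_err = int(mask.sum())
                    if n_err:
                        # substitute with a uniformly random *different* base
                        shifts = rng.integers(1, 4, size=n_err)
                        idx = np.flatnonzero(mask)
                        cur = np.searchsorted(_BASES, frag[idx])
                        frag[idx] = _BASES[(cur + shifts) % 4]
                reads.append(
                    ReadRecord(
                        f"{sample}:{serial:07d}|{tid}|{hap_name}",
                        bytes(frag).decode("ascii"),
                        qual_t,
                    )
                )
                serial += 1
    return reads


def read_truth(read_id: str) -> tuple[str, str]:
    """Decode (transcript_id, haplotype) from a simulated read identifier."""
    _, tid, hap = read_id.rsplit("|", 2)
    return tid, hap


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate the full input set: reference, haplotypes, truth, libraries.

    Libraries: two replicates per parent (``apo_rep1`` ...) drawn purely from
    that parent's haplotype, and two replicates per condition for the F1
    (``f1_control_rep1`` ...) drawn at each gene's truth allelic ratio.
    """
    config.validate()
    reference = generate_reference_transcriptome(config)
    hap_apo, hap_ir64, truth = derive_parental_haplotypes(reference, config)
    rng = np.random.default_rng(config.seed + 3)
    haps = (hap_apo, hap_ir64)
    reads: dict[str, list[ReadRecord]] = {}
    for parent, frac in (("apo", 1.0), ("ir64", 0.0)):
        for rep in (1, 2):
            mixture = {tid: frac for tid in reference}
            reads[f"{parent}_rep{rep}"] = simulate_reads(
                haps, mixture, config, rng, f"{parent}_rep{rep}"
            )
    classes = truth.classes.set_index("gene_id")
    for cond in config.conditions:
        col = f"apo_fraction_{cond}"
        mixture = {
            tid: (None if pd.isna(classes.loc[tid, col]) else float(classes.loc[tid, col]))
            for tid in reference
        }
        for rep in (1, 2):
            name = f"f1_{cond}_rep{rep}"
            reads[name] = simulate_reads(haps, mixture, config, rng, name)
    gene_loci = generate_gene_loci(reference, config.seed)
    return SimulatedExperiment(
        config=config,
        reference=reference,
        hap_apo=hap_apo,
        hap_ir64=hap_ir64,
        truth=truth,
        reads=reads,
        gene_loci=gene_loci,
    )


# ---------------------------------------------------------------------------
# RIL panel
# ---------------------------------------------------------------------------

GENO_MISSING, GENO_IR64_HOM, GENO_APO_HOM, GENO_HET = 0, 1, 2, 3


def generate_marker_panel(
    gene_loci: pd.DataFrame,
    seed: int = 0,
    n_markers: int = 22,
    n_qtl: int = 1,
    effect: float = 2.0,
    heritability: float = 0.9,
    max_offset_bp: int = 200_000,
) -> tuple[pd.DataFrame, RILTruth]:
    """Place RM-style SSR markers near randomly chosen genes; plant QTL effects."""
    rng = np.random.default_rng(seed + 11)
    n_markers = min(n_markers, len(gene_loci))
    picks = rng.choice(len(gene_loci), size=n_markers, replace=False)
    rows = []
    for j, gi in enumerate(sorted(int(p) for p in picks)):
        g = gene_loci.iloc[gi]
        pos = max(0, int(g["start"]) + int(rng.integers(-max_offset_bp, max_offset_bp)))
        rows.append({"name": f"RM{1000 + j}", "chrom": int(g["chrom"]), "pos_bp": pos})
    markers = pd.DataFrame(rows)
    qtl_idx = rng.choice(n_markers, size=min(n_qtl, n_markers), replace=False)
    effects = {markers.iloc[int(i)]["name"]: effect for i in qtl_idx}
    truth = RILTruth(
        marker_names=tuple(markers["name"]),
        qtl_effects=effects,
        heritability=heritability,
    )
    return markers, truth


def simulate_ril_panel(
    truth: RILTruth,
    n_lines: int,
    seed: int = 0,
    het_fraction: float = 0.0625,
    missing_fraction: float = 0.02,
    noise_sd: float | None = None,
    baseline: float = 20.0,
) -> RILPanel:
    """Simulate an F3:5 RIL panel with genotype codes and replicated phenotypes.

    Genotype codes: 1 IR64 homozygote, 2 Apo homozygote, 3 heterozygote
    (residual at the F3:5 expectation of ~1/16), 0 missing.  The line-mean
    phenotype is the sum of planted additive marker effects over centred
    scores plus Gaussian noise scaled so that the heritability of line means
    matches ``truth.heritability`` (overridden by an explicit ``noise_sd``
    per replicate).  Missing codes mask the observation only; phenotypes are
    generated from the underlying genotype.
    """
    truth.validate()
    if n_lines < 4:
        raise ValueError("n_lines must be >= 4")
    rng = np.random.default_rng(seed)
    markers = list(truth.marker_names)
    p_hom = (1.0 - het_fraction) / 2.0
    codes = rng.choice(
        [GENO_IR64_HOM, GENO_APO_HOM, GENO_HET],
        size=(n_lines, len(markers)),
        p=[p_hom, p_hom, het_fraction],
    )
    score = np.select(
        [codes == GENO_IR64_HOM, codes == GENO_HET, codes == GENO_APO_HOM],
        [0, 1, 2],
    ).astype(float)
    effects = np.array([truth.qtl_effects.get(m, 0.0) for m in markers])
    genetic = baseline + (score - 1.0) @ effects
    var_g = float(np.var(genetic))
    if noise_sd is not None:
        sigma_rep = float(noise_sd)
    elif var_g == 0.0:
        sigma_rep = 0.0
    elif truth.heritability == 0.0:
        raise ValueError("heritability 0 with non-zero marker effects is degenerate")
    else:
        h2 = truth.heritability
        var_e_mean = var_g * (1.0 - h2) / h2
        sigma_rep = math.sqrt(2.0 * var_e_mean)
    phen = genetic[:, None] + rng.normal(0.0, sigma_rep or 0.0, size=(n_lines, 2))
    observed = codes.copy()
    if missing_fraction > 0:
        observed[rng.random(codes.shape) < missing_fraction] = GENO_MISSING
    line_ids = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    genotypes = pd.DataFrame(observed, index=line_ids, columns=markers)
    phenotypes = pd.DataFrame(phen, index=line_ids, columns=["rep1", "rep2"])
    return RILPanel(genotypes=genotypes, phenotypes=phenotypes)
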