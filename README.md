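# hybridase

Allele-specific expression (ASE) analysis of an F1 rice hybrid under two
water regimes, with association of allelically imbalanced genes to
drought-yield QTL markers.

In an IR64 × Apo (*indica* × *indica*) hybrid, the two parental alleles of
a gene share one nucleus and one pool of *trans* factors, so a difference
in their transcript abundance — allelic imbalance (AI) — points to
*cis*-regulatory or epigenetic variation. Measuring AI from RNA-seq of the
hybrid is complicated by two things: the public reference transcriptome is
a *japonica* cultivar (Nipponbare MSU7 cDNA), which biases read mapping
against both *indica* parents, and the two parents are so similar that only
sparse SNPs distinguish their alleles. `hybridase` implements the full
pipeline that deals with both, plus a synthetic-data generator so every
stage is testable against known ground truth:

1. **Quality trimming** — read positions whose 75th-percentile base quality
   across a replicate falls below Q28 are removed from all reads.
2. **Pseudo-reference construction** — parental reads are mapped to the
   reference transcriptome; sites where *both* parents carry the same
   non-reference allele (SNPs at depth ≥ 5 and proportion > 0.8, InDels at
   depth ≥ 5 and proportion ≥ 0.5) are edited into the reference. InDel
   edits shift coordinates, so a bidirectional liftover map is built
   alongside. Re-mapping against the pseudo-reference strictly improves
   alignment rates.
3. **Parental SNP calling** — on the pseudo-reference, sites where each
   parent shows a distinct majority allele (depth ≥ 3, proportion > 0.8)
   become copy-specific tags.
4. **Read-wise allele assignment** — each mapped F1 read is inspected at
   every parental SNP it covers and counts *once* toward the parent whose
   alleles it carries (the SNP-wise alternative, which counts every
   (read, SNP) observation and over-counts multi-SNP reads, is implemented
   for comparison). Conflicting and uninformative reads are "unspecified".
5. **AI testing** — per condition, gene × (allele, replicate) counts are
   normalized by median-of-ratios size factors, replicates are summed per
   allele, and each gene is tested against the 1:1 null with an exact
   two-sided binomial test (and a 1-df chi-square test, filtered when the
   expected count n/2 < 5). With fold change FC = Apo/IR64, significant
   genes (P < 0.05) are classified at the 1.25× and 2.0× thresholds as
   biallelic (magnitude < threshold), Apo- or IR64-favoring, or monoallelic
   when one allele contributes no reads.
6. **ASE profiles** — per-gene AI is compared between control and water
   stress: genes detected in only one condition show transcript
   presence/absence variation (tPAV); genes asymmetric in both either
   switch the favored allele (bidirectional) or keep it (unidirectional).
7. **QTL association** — AI genes are co-localized with SSR markers on the
   same chromosome within a distance window (default 500 kb), and
   marker–phenotype association is tested by single-marker regression of
   line-mean grain yield on an additive genotype score (IR64 hom = 0,
   het = 1, Apo hom = 2) in the phenotypic tails (25 %) of a 160-line RIL
   panel.

## Worked example

Run the whole pipeline on a synthetic experiment with strong planted
effects (60 genes, ~4 inter-parental SNPs/gene, 250 reads per gene per F1
library):

```python
from hybridase import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    sim=SimulationConfig(n_genes=60, gene_length_range=(500, 1000),
                         parental_snp_rate=4.0, depth_per_gene=250,
                         parent_depth_per_gene=100, base_error_rate=0.001,
                         seed=3),
    seed=3,
)
res = run_pipeline(cfg, "out")
print(res.allele_table.to_string(index=False))
s = res.ai_summaries[("control", 1.25)]
print(f"control 1.25x: {s.n_apo_favoring} Apo-favoring, "
      f"{s.n_ir64_favoring} IR64-favoring, "
      f"{s.n_total_ai}/{s.n_significant} AI ({s.pct_ai_over_significant} %)")
ps = res.profile_summary
print(f"profile universe: {ps.n_total} genes ({ps.n_common} common, "
      f"{ps.n_unique_control}+{ps.n_unique_stress} unique); "
      f"recovery {res.recovery_rate:.3f}")
```

prints

```
condition replicate  mapped  from_apo  from_ir64  unspecified  pct_assignable
  control      rep1   14060      2986       2265         8809           37.34
  control      rep2   13966      3069       2133         8764           37.24
   stress      rep1   14663      2618       2900         9145           37.63
   stress      rep2   14426      2616       2907         8903           38.28
control 1.25x: 20 Apo-favoring, 17 IR64-favoring, 37/37 AI (100.0 %)
profile universe: 42 genes (37 common, 2+3 unique); recovery 0.944
```

The first table is the per-sample partition of mapped F1 reads into
Apo-assigned, IR64-assigned and unspecified (reads covering no informative
SNP, or voting for both parents), with the assignable percentage truncated
to two decimals. The AI summary counts genes favoring each parental allele
at the 1.25× threshold among genes with significant allelic imbalance.
The last line is the cross-condition profile universe and the fraction of
planted tPAV/bidirectional/unidirectional genes recovered with their
planted class — at these depths the pipeline recovers ~94 % of them.
`out/` holds every stage table (shared variants, pseudo-reference FASTA,
allele counts, AI records, profiles, co-localization, association) plus a
run manifest; re-running the same config reproduces the files byte for
byte.

The same stages are available as a CLI (`hybridase simulate | trim | map |
pileup | pseudoref | assign | aitest | profiles | colocalize | smr | run`).

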