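# Methods

This note documents the models, thresholds and design choices behind
`hybridase`, and what the synthetic-data experiments do and do not
establish about real data.

## The measurement model

A gene in the F1 hybrid produces transcripts from two haplotypes, Apo
(paternal) and IR64 (maternal). Only reads overlapping an inter-parental
SNP carry parental information; for a gene with combined informative
counts (a, b) after normalization, the null of balanced expression is
a ~ Binomial(a+b, ½). The exact two-sided binomial test (summing the
probabilities of all outcomes no more likely than the observed one) gates
everything downstream; a 1-df chi-square against expected (n/2, n/2) is
reported alongside but filtered when n/2 < 5, where the normal
approximation is unreliable. The binomial was chosen as the gating test
because it carries no sample-size filter, so the significant gene set is
not truncated by the chi-square validity floor. No multiple-testing
correction gates any class — classification thresholds raw P < 0.05, as
is conventional for this assay — but a Benjamini–Hochberg column is
emitted for information.

Fold change is FC = Apo/IR64 on normalized combined counts; magnitude
max/min and direction are classified at 1.25× (the assay's customary
sensitivity threshold) and 2.0× (the stricter convention). "Monoallelic"
means the minor allele contributed zero informative reads, a sub-case of
the favored side.

Normalized replicate counts are *summed* per allele (not averaged) before
testing; the two readings are equivalent up to a factor of ~2 in effective
depth and summation preserves integer-like scale for the exact test.
Fractional normalized counts are rounded to the nearest integer for the
binomial and chi-square tests only; fold changes use the unrounded values.

### Size factors

Median-of-ratios, per condition, over the four allele × replicate columns:
for genes with strictly positive counts in all columns, factor_j =
median_g(count_gj / geometric-mean_g). This is the standard count
normalization recipe; a cross-check against an independent implementation
(pydeseq2) agrees to ~1e-6. Because the columns are *alleles*, the
procedure assumes the median informative gene is allelically balanced —
true of real hybrid transcriptomes and of the generator's default class
mix (50 % biallelic). A generator configuration in which most genes are
imbalanced would make the factors absorb genuine allelic signal; this is a
property of the method itself, not of this implementation.

## Pipeline thresholds

| Stage | Parameter | Default | Note |
|---|---|---|---|
| trimming | quality threshold | Q28 | 75th-percentile per position, across the replicate |
| trimming | percentile | 0.75 | positions are dropped wherever they occur, not 3′-clipped |
| shared SNP | depth / proportion | ≥ 5× / > 0.8 | per parent, strictly greater; identical alt required in both |
| shared InDel | depth / proportion | ≥ 5× / ≥ 0.5 | inclusive; denominator is the anchor-column depth |
| parental SNP | depth / proportion | ≥ 3× / > 0.8 | majority alleles must differ between parents |
| AI | alpha | 0.05 | raw p, binomial gates classes |
| AI | fold thresholds | 1.25×, 2.0× | "≥ threshold" is asymmetric (boundary inclusive) |
| chi-square | expected-count filter | 5 | gene dropped from chi-square results only |
| profiles | mode | lenient | P < 0.05 in one or both conditions |
| co-localization | window | 500 kb | distance 0 inside the gene span, else gap to nearer end |
| selective genotyping | tail fraction | 0.25 | ⌈n·f/2⌉ highest + lowest by LS-mean phenotype |

Parental pileups pool both replicates per parent before thresholding, so
the depth rules apply to the parent, not to individual libraries.
Multi-allelic sites (different passing alt alleles in the two parents) are
never edited into the pseudo-reference: "shared" requires identity.

## Mapper

An in-process deterministic seed-and-extend aligner for transcript
references: exact k-mer seeds (default k = 20) at the read's start, middle
and end; candidate placements scored by Hamming distance; best placement
reported if mismatches ≤ 2. Ties across transcripts of *different* genes
leave the read unmapped (no arbitrary multi-mapping); ties among splice
variants of one gene resolve to the lexicographically first transcript, so
counts are reproducible. When the start and end seeds of a read place it
at offsets differing by up to 3 bp on one transcript, the mismatch-
minimising single-InDel split is scored as well (ungapped preferred at
equal mismatches). This single-InDel extension exists because the
pseudo-reference stage must *observe* the short InDels that separate the
parents from the reference; without it, every read spanning a planted
InDel would be unmappable and the InDel-editing contract would be vacuous.
InDel observations are left-normalized (shifted to the leftmost equivalent
anchor) so observations of one event from different reads coalesce.
Anything beyond one short InDel — spliced or clipped alignment — is out of
scope; externally produced SAM can be imported instead.

Coordinates are 0-based half-open internally; 1-based only at SAM and
VCF-like boundaries. The liftover between reference and pseudo-reference
is stored as explicit per-transcript position arrays in both directions
(transcripts are short, so this is a few MB); positions inside deleted
spans map to the deletion's left edge with a flag, inserted positions map
back to their anchor with a flag. Round-trip identity off those spans is a
tested invariant.

## Read-wise assignment

Each covered parental-SNP position casts at most one vote per read; a base
matching neither parental allele (a sequencing error) is ignored rather
than treated as a veto, so a single error cannot discard an otherwise
consistent read. Reads voting for both parents (CONFLICT) are counted as
unspecified — the conservative reading of "assignable". The counting unit
is the read; SNP-wise observation counts are emitted for comparison and
are provably ≥ the read-wise counts, with equality exactly when no
informative read covers more than one SNP. Percent-assignable is
*truncated* (not rounded) to two decimals, matching how the published
per-sample percentages relate to their raw counts.

## Profile classification

The gene universe is gated by the lenient rule (P < 0.05 in ≥ 1 condition)
by default; the stringent rule (both conditions, except tPAV genes tested
only where expressed) yields a subset. "Detected" means ≥ 1 informative
assigned read in that condition and 0 in the other for tPAV; the detection
floor is a design choice, as none is standard. A gene asymmetric in one
condition but below 1.25× in the other is `biallelic_unclassified`: a
sub-threshold fold difference cannot anchor an allele preference, so the
condition-mediated behavior cannot be ascertained. Percentages use the
full universe as denominator.

## Synthetic data

The generator emulates the study system: random transcript references
(LOC-style identifiers, 500–3000 bp), two parental haplotypes sharing
0.92 SNPs/kb and 0.07 InDels/kb (1–3 bp, uniform) against the reference
and differing from each other at Poisson(0.72) SNPs per gene, with the
non-reference allele assigned to a random parent. F1 libraries draw each
read from the Apo haplotype with a per-gene, per-condition probability
fixed by the gene's truth class:

| class | control | stress |
|---|---|---|
| biallelic | 0.5 | 0.5 |
| apo / ir64_favoring | 0.7 / 0.3 | 0.7 / 0.3 |
| monoallelic_apo / _ir64 | 1.0 / 0.0 | 1.0 / 0.0 |
| tPAV_normal / _stress | 0.7 / silent | silent / 0.7 |
| bidirectional | 0.8 | 0.2 |
| unidirectional | 0.8 | 0.65 |

The true per-gene allelic ratios of the original experiment are unknowable
from the publication; these are the package's own choices of clearly
separated effects. The default class mix is 50 % biallelic with the
remaining classes sharing the rest (see the size-factor assumption above).
Reads are single-end 90 bp at constant Q35 (optionally with a low-quality
tail to exercise trimming), with uniform substitution errors at 0.001/base
and no sequencing InDels — matching what the ungapped-extension mapper can
see. Read counts are Poisson per gene; with `depth_is_coverage` the mean
scales with gene length so thresholds defined per pileup column (e.g.
"30× coverage") are meaningful. Read identifiers encode gene and haplotype
of origin, and every planted variant is recorded in a truth table.

What the generator does **not** emulate: GC and positional bias, fragment
length, spliced reads, paired ends, real quality profiles, linkage between
markers, and overdispersion of counts beyond Poisson. Passing recovery
tests therefore demonstrate the *logic* of the pipeline under its own
assumptions, not robustness to those artifacts.

The RIL panel draws genotype codes per marker at F3:5 expectations
(heterozygote residual 1/16, 2 % missing), phenotype = baseline + additive
marker effects on centred scores + Gaussian noise scaled so line means hit
the target heritability (default 0.9 for the planted 2.0-unit effect),
two replicates per line. Markers are independent (no genetic map); the
regression codes het = 1 (intermediate), a low-impact choice since F3:5
lines are ~94 % homozygous. Regression runs on the selected tails only, as
only the tails are genotyped; no ascertainment correction is applied.

## Problem sizes of the shipped experiments

* Profile recovery: 200 genes, 500–1000 bp, 4 inter-parental SNPs/gene,
  250 reads/gene per F1 library — so scored genes carry ≥ ~100 informative
  reads per condition, the regime the classifier assumes. Recovery is
  scored over planted tPAV/bidirectional/unidirectional genes that carry
  ≥ 1 inter-parental SNP; genes without one are undetectable by
  construction.
* Variant recovery: 120 genes, 1000–2000 bp, ~30× parental coverage,
  0.1 % base error. Planted sites within ~15 bp of a transcript end fall
  below the callers' depth floors (read-geometry edge effect), which
  bounds attainable recall at ≈ 0.97–0.98.
* Calibration: 5000 null genes at depth 40 (type-I), 1000 genes at
  100 reads and 70:30 (power), 25 seeded RIL panels (QTL detection),
  1000 null panels (regression calibration).

These sizes are the package's chosen desk-scale defaults; all scale up via
their function arguments.

## Known limitations

* The mapper's mismatch cap (2) and single-InDel model make mapping rates
  incomparable in magnitude to a full gapped aligner's; only the
  *improvement* of the pseudo-reference over the original reference is a
  meaningful, tested property.
* Expression estimation is informative-read counting; no EM-based
  multi-mapping resolution, so splice variants sharing their informative
  SNPs are aggregated to the gene.
* The negative-binomial treatment-vs-treatment differential expression
  test is out of scope; the package tests allele-vs-allele within
  condition only.
* `ls_means` equals the arithmetic mean only because the shipped design is
  balanced with two replicates; unbalanced multi-factor designs would need
  a proper linear-model fit.
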