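# Methods

## Coordinates and inputs

All intervals are 0-based half-open, matching BED and the stored form of
UCSC refFlat. Genes with multiple isoforms are collapsed to the widest span
(min start, max end) at read time. Strand is read and preserved but ignored
downstream: overlap and flank logic is strand-symmetric. JPT and CHB
samples are merged into one ASN panel when a population map is loaded.
CNV gain/loss labels and formation-mechanism classes (VNTR, NAHR, TEI, NHR)
are taken as input annotation, not inferred.

## Gene areas and the pseudo-transcriptome

A gene area is the gene span ± a flank (default 10 kb for enrichment and
frequency maps), clipped at the chromosome origin; no clipping at the
chromosome end is applied unless a length table is given. Where two flanked
areas overlap, the contested bases go to the gene whose body is nearer: the
boundary is floor((left body end + right body start) / 2), which is also
the midpoint of the body overlap when bodies themselves overlap. Bases at
or beyond the boundary belong to the right-hand gene. With more than two
chained overlaps the rule is applied to consecutive sorted pairs; an area
squeezed to zero width is dropped with a warning. This disjointification is
a design choice — it keeps "the boundary between two gene areas" well
defined for the pairing rules; the alternative (merging overlapping areas)
would lose per-gene attribution.

Per chromosome the disjoint areas are concatenated in genomic order; the
mapping between genomic and concatenated coordinates is a bijection on
covered bases (property-tested on 10,000 random bases).

## Truncation, permutation and pairing

CNVs are clipped to the union of gene areas; CNVs outside every area are
discarded. A multi-segment truncated CNV is treated as one object of its
total clipped size and permuted as one contiguous block — the simplest
reading of "maintaining the number and size of CNVs per chromosome".
Null replicates place each truncated CNV independently and uniformly on
[0, L − size] of its own chromosome's concatenated axis; mutual overlaps
between placed CNVs are allowed, keeping the null exchangeable. Placements
use counter-based Philox substreams keyed on (seed, replicate, chromosome
index), so results do not depend on iteration order, and all pathways are
scored against the same replicate stream (paired nulls).

Pairing rules (observed and permuted placements alike, always on the
truncated footprint): R1 — every area entirely inside the CNV is paired;
R2 — a CNV within a single area pairs with that gene; R3 — a straddling
CNV pairs with the area holding strictly more than half its length, with
an exact 50 % split going to the lower-coordinate area (deterministic and
order-independent). The per-pathway statistic is the count of distinct
pathway genes in ≥ 1 pair; pathway genes missing from the annotation are
dropped from both numerator and pathway size, with a warning.

P-values use the add-one estimator p = (1 + #{null ≥ obs}) / (n_perm + 1)
(never zero); n_perm defaults to 1000, matching a 0.001 resolution.
Because both tails count ties, p_enrich + p_deplete ≥ 1 + 1/(n_perm + 1).

For simple co-location (frequency maps at 10 kb, association at 1 Mb) the
pairing is plain interval intersection of the CNV with the flanked gene
span — no 50 % rule.

## Population differentiation

Fst treats each diploid CN call as an allele-like category, A0–A4 with
CN ≥ 5 binned as > A4, ignoring phase. Multi-state CNVs are *not* reduced
to diallelic form — the category formula handles any number of states — but
a `diallelic_only` filter (≤ 2 observed categories pooled across
populations) is available, since the original treatment is ambiguous on
this point. H_t = 0 (both populations fixed for the same state) defines
Fst = 0. By convexity of x ↦ Σx², H_t ≥ H_s always, so Fst ∈ [0, 1];
tiny float excursions are clamped.

Empirical cutoffs per population pair are upper-tail ranks: with values
sorted ascending, index ceil((1 − tail)·n), i.e. the smallest sample value
with at most `tail` of the distribution at or above it. (On the grid
0.00…0.99 with tail 0.05 this yields 0.95.) Cutoffs are reported raw and
rounded to two decimals. "Differentiated" uses Fst ≥ cutoff — a closed
boundary, counting ties conservatively toward significance.

Polymorphism frequency of a CNV in population P is 1 − P's frequency of
the CNV's major CN state in the reference panel (CEU); major-state ties
break to the lower CN category. Pathway frequency maps place one row per
CNV-gene pair (the pair inherits its CNV's frequencies and Fst unchanged)
and one column per population (YRI, CEU, ASN); rows are ordered by
complete-linkage hierarchical clustering on Euclidean distances, with
scipy's deterministic tie handling. Rendering to an image is an optional
thin layer; the tested artifact is the matrix plus leaf order.

A pathway is differentiated at a level when ≥ 1 of its pairs reaches the
cutoff of any population pair; the pathway takes the strongest level
attained. The seven-region Venn partition of pathways (or genes) by
flagging population pair is checked to be disjoint and exhaustive. The
fraction of differentiated pairs per pathway is reported over pathways
with ≥ 1 pair; pathways with no pairs contribute fraction 0.

## Expression association

Per population (CEU and YRI; no ASN expression), each 1 Mb CNV-gene pair is
tested two ways on samples with non-missing genotypes: dosage — ordinary
least-squares regression of expression on numeric CN, two-sided slope
t-test, requiring ≥ 3 samples and ≥ 2 distinct CN values; allelic — one-way
ANOVA over CN categories (Kruskal–Wallis by flag), dropping categories with
fewer than `min_per_state` = 3 samples and requiring ≥ 2 eligible
categories. Skipped tests carry an explicit reason. Degenerate constant
expression reports p = 1.

FDR correction is Benjamini–Hochberg per population *and per test family*
(all dosage p-values one family, all allelic p-values another); a pair is
functional when either family rejects at q (default 0.05). The combination
rule is switchable (`min`, `dosage_only`, `allelic_only`) because the
appropriate pooling of the two families is genuinely open. Hypergeometric
pathway enrichment of functional genes uses the upper tail P(X ≥ k) on the
universe of pathway-annotated genes with ≥ 1 tested pair.

## Proportion comparisons

Composition shifts (mechanism classes, gain/loss) between a CNV subset and
a reference set use the pooled two-sample z-test, two-sided, no continuity
correction; fold = (k1/n1)/(k2/n2), undefined when k2 = 0; a pooled
proportion of 0 or 1 gives z = 0, p = 1. CNVs labelled `both` or `unknown`
are excluded from the gain/loss comparison. Classes are tested one-vs-rest
without multiplicity correction (a BH option exists); the reference group
defaults to the full set, with a complement option.

## Synthetic data

The generator's default scale is 2 chromosomes × 5 Mb, 200 genes
(log-normal lengths, median ≈ 8 kb), 50 pathways of 5–25 genes, 300 CNVs
(log-normal lengths, median ≈ 3 kb, matching the few-kb median of
array-derived CNV calls), genotype panels of 180 CEU, 180 YRI and 90 ASN,
and expression for 60 CEU and 69 YRI samples — the panel sizes of the
HapMap populations the analysis is designed around. Baseline
between-population divergence is F = 0.05 (continental-scale), planted
differentiated CNVs default to F = 0.4, and 2 % of genotypes are missing.

Genotypes follow a Balding–Nichols-style model on CN categories directly:
an ancestral frequency vector over states 0–5 is drawn from a Dirichlet
centred on the diploid state; each population's vector is drawn from
Dirichlet(ancestral × (1 − F)/F), and individuals i.i.d. from it. F = 0
means shared frequencies exactly. Expression is μ_g + β·CN + N(0, σ_e) for
planted functional pairs (β = 1, σ_e = 0.5 by default) and μ_g + N(0, 1)
otherwise.

Enrichment planting raises the expected per-base CNV density on a
pathway's gene areas to ρ × baseline by adding
round((ρ − 1)·n_cnvs·area_bp/genome_bp) extra CNVs placed uniformly within
the areas. Planting targets the largest pathways: at this scale the
per-gene hit probability under the null is high, and a count-of-hit-genes
statistic on a 5-gene set cannot exceed its saturation ceiling no matter
how dense the planted signal — the signal is only identifiable in larger
sets. For the same reason, the null-calibration experiment uses a larger
design (600 genes, 200 pathways of 30–60 genes, CNVs placed uniformly on
the pseudo-transcriptome) where the discrete permutation statistic has
enough attainable levels for the nominal 5 % rate to be meaningful; at the
default scale the test is valid but conservative, rejecting less often
than nominal.

All stages derive their randomness from per-stage `SeedSequence`
substreams of a single seed; a fixed seed reproduces every output file
byte-for-byte.

### What the generator does and does not emulate

It reproduces the analysis-relevant structure: size distributions, pathway
membership, population stratification of CN states, dosage effects, and
missingness. It does not emulate linkage disequilibrium between CNVs,
segmental-duplication clustering, mechanism-class genomic biases,
platform-specific call noise, or expression covariates (batch, ancestry
structure within panels). Passing tests therefore demonstrate correctness
and calibration of the statistics under the stated model, not robustness
to those real-data complications.

## Known limitations

- The disjointification of overlapping gene areas is a declared choice;
  other conventions (merge, first-come) would shift boundary pairings.
- The permutation null keeps CNVs independent; real CNVs cluster, which
  the test does not model.
- No covariate correction in the association tests, and no trans effects
  beyond the 1 Mb window.
- Fst here is the category-frequency estimator, not a variance-component
  (Weir–Cockerham) estimator; no haplotype-phase awareness.
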