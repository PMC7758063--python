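# Methods

`stratsim` simulates genome-wide association studies (GWAS) in
spatially structured populations and measures how much population
stratification survives the standard corrections. This note records
the models, the parameter choices and their rationale, the numerical
devices, and what the package's reduced-scale runs can and cannot show.

## Demographic models

Structure lives on a 6×6 lattice of demes (row 0 is the northernmost
row), each of constant size N = 10,000 diploids, exchanging migrants
with rook-adjacent neighbours at a symmetric per-generation rate *m*.
A migration-matrix entry is the proportion of a deme replaced per
generation by migrants from one adjacent deme; the same value is the
backward-time lineage migration rate handed to the coalescent engine
(the standard equivalence for conservative migration).

Three histories share this geography:

* **perpetual** — the stepping stone extends indefinitely into the
  past (τ = ∞).
* **recent** — all demes collapse into a single ancestral population
  of 10,000 diploids τ = 100 generations ago, the upper bound
  suggested by the near-complete population turnover of Bronze-Age
  Britain.
* **complex** — demes are created 100 generations ago by admixture
  between two source populations along a north–south ancestry cline
  (fractions linear in the row index); the sources exchange migrants
  at rate m₁ = 0.004 and may optionally descend from a three-population
  hunter-gatherer / early-farmer style layered history. The ancient
  layer's split times and mixture proportions are not calibrated
  quantities anywhere; they are explicit, documented fields of
  `AdmixtureSpec` with defaults chosen only to be qualitatively
  plausible (all sizes 10,000; layer admixture at 250 generations,
  hunter-gatherer split at 2,000, root at 6,000).

The calibrated rates are m = 0.05 (recent) and m = 0.07 (perpetual);
both reproduce a mean between-deme Weir–Cockerham FST near 2×10⁻⁴ —
UK-Biobank-like structure — from qualitatively different histories,
which is the study's central construction. An England/Wales-style
geography is shipped as a synthetic 35-region adjacency fixture with
non-uniform sampling weights (one far-south-western region expects 17
of 9,000 samples instead of 250) to mimic uneven biobank recruitment;
it is a stand-in, not the real NUTS2 map.

### The perpetual model's deep-history horizon

A literal τ = ∞ stepping stone is prohibitively slow to simulate at
m = 0.07: lineages migrate ~0.28 times per generation for on the
order of 10⁶ generations, which is minutes of engine time per
megabase. At Nm ≈ 700 the model sits deep in the strong-migration
regime, whose long-time limit is a panmictic population of the total
metapopulation size (36 × 10,000). The engine therefore truncates the
structured phase at a configurable horizon (default 1,000 generations
— more than ten times the slowest spatial relaxation time of the
grid, ~50 generations at m = 0.07) and merges all demes into a
panmictic population of 360,000 diploids beyond it. Measured FST is
indistinguishable for horizons between 1,000 and 50,000 generations.
`perpetual_horizon=None` restores the literal model. The
`DemographySpec` itself records no collapse for the perpetual model;
the horizon is an engine-level numerical device.

## Genotype simulation

Chromosomes are independent coalescent replicates (seeds derived
deterministically from the master seed and the stage name via a
stable CRC32 hash, all below 2³¹). Mutations use an infinite-sites
binary model on a continuous genome, so every variant is biallelic
with ancestral allele 0 and derived allele 1; dosages count derived
alleles. Mutation and recombination rates are both 10⁻⁸ per bp per
generation, making the genetic map uniform with 1 cM = 1 Mb. Two
genome presets: calibration (10 × 1 Mb) and main (20 × 10 Mb).

Datasets keep their tree sequences as the source of truth. Genotypes
are decoded on demand by random access to the requested sites
(`tskit.Variant.decode`), restricted to the requested individuals, so
cohorts with >10⁶ variants never materialize a full genotype matrix.
Derived-allele counts are read directly off the marginal trees (the
count at a site is the number of samples below its unique mutation),
which costs seconds even for millions of sites.

Variant classes follow the analyzed sample in hand, not the parent
cohort: *common* means minor-allele frequency strictly above 5%,
*rare* means minor-allele count 2–4, *ultra-rare* means derived
frequency below 0.1%. VCF 4.2 export integerizes the continuous
positions (1-based, ties bumped to the next free coordinate) and
writes phased genotypes so a round trip reproduces dosages exactly.

## Structure statistics

FST is the multi-population Weir & Cockerham (1984) estimator with
the ratio-of-averages convention: the among-deme component a and the
total a+b+c are summed over variants before dividing. Input variants
are LD-pruned common variants (greedy scan, window 100 variants, step
10, r² threshold 0.1; the earlier variant of a violating pair is
kept, windows never span chromosomes). Confidence intervals use a
block bootstrap over 1 Mb variant blocks (1,000 resamples), since
per-variant FST values are strongly autocorrelated through linkage —
the estimator itself does not prescribe a CI method, so this is a
package choice.

Genomic inflation λp is the observed p-th percentile of the
association χ² statistics divided by the p-th quantile of χ²₁. The
median (p = 0.5) is the headline definition; p = 0.999 ("tail λ") is
used where stratification affects only a small variant subset, which
shifts the extreme quantiles but not the median. λ − 1 scales
linearly with sample size, so an inflation observed at one N can be
mapped to another: λ_N = (N/N₀)(λ_N₀ − 1) + 1. With the biobank
anchors λ ≈ 12 at N = 300,000, this maps to ≈ 1.33 at N = 9,000;
migration rates were calibrated so that a GWAS of the latitude (grid
row) coordinate at N = 9,000 gives a median λ in this neighbourhood
(1.68 at m = 0.05, recent model). Note the anchor value 1.36
sometimes quoted for this rescaling does not follow from the formula
with λ = 12 exactly; the formula is authoritative here.

## Relatedness matrices and PCA

Genotype GRMs standardize each variant by √(2p(1−p)) of its
derived-allele frequency and average ZZᵀ over variants (monomorphic
variants are dropped with a warning). The IBD GRM sums exact
identity-by-descent segments — maximal intervals over which two
haplotypes share their most recent common ancestor, extracted from
the simulated genealogies via `tskit.ibd_segments` — above a 10 cM
length threshold, over the four haplotype pairings of each individual
pair, divided by twice the haploid genome length (a duplicated genome
scores 1, full sibs average ½). Real-data users must substitute a
detector (e.g. GERMLINE-class software); the exact-genealogy route
exists only in simulation.

PCA double-centers the GRM (projecting out the all-ones direction —
the estimator is centered; the choice is standard practice) and takes
the top k = 100 eigenpairs; eigenvector signs are fixed by making
each column's largest-magnitude loading positive so results are
reproducible. "Variance explained" of one PC by a PC set is the R² of
an OLS fit with intercept.

### Detectability at reduced scale

Whether PCA *can* see structure of a given strength is a
sharp-threshold phenomenon: a spatial mode of differentiation f is
recoverable only when f ≳ 1/√(nM) (n individuals, M effectively
independent variants). At the calibrated FST of ~2×10⁻⁴ spread
across 35 spatial modes, the leading mode carries roughly 4×10⁻⁵ —
*above* threshold at the published scale (n = 9,000 with hundreds of
thousands of weakly linked variants from 200 Mb) and *below* it for
desktop-scale cohorts simulated on a 10 Mb genome, where LD limits
the effective variant count regardless of how many sites are used.
Consequently the published contrast "100 common-PCs explain 50% of
rare-PC1 under perpetual structure but 3% under recent structure"
compresses at reduced scale: the ordering (recent ≪ perpetual) is
reproduced, but the perpetual value falls well short of 50% because
common-PC1 itself is mostly below the detection threshold. The
acceptance script reports the honest reduced-scale values; the
recent-model value (~3%) is scale-insensitive because it is near the
floor at any scale.

## Phenotypes

Non-heritable phenotypes are y ~ N(μ_deme, σ²). Smooth environment:
μ linear in the grid row, anchored at 0 in the northernmost row with
range 2σ (only differences matter; the anchor is a convention).
Sharp environment: μ = 2σ in exactly one deme. Heritable traits pick
one causal variant uniformly at random per 100 kb half-open window
(2,000 causal variants at the 200 Mb preset), draw effects
βk ~ N(0, σ_l²[2p_k(1−p_k)]^α) with α = −0.4 (the height-like
frequency coupling: rarer variants get larger effects), and solve
σ_l² so that the expected genetic variance
σ_g² = σ_l² Σ[2p_k(1−p_k)]^(α+1) equals h² = 0.8. Writing the
per-variant effect variance on the 2p(1−p) scale is the unique
self-consistent reading of this variance decomposition — the
alternative [p(1−p)]^α convention misses the target h² by the
constant 2^(−α). For heritable traits the environmental noise sd is
√(1−h²), so the structured shift of 2σ is expressed relative to the
residual scale (the absolute scale of the shift is otherwise
unspecified; this convention is recorded here deliberately). The
true decomposition y = g + μ + ε is stored, never reconstructed.

## Association tests

The linear scan projects the covariates (plus intercept) out of the
phenotype and the dosages once and fits each variant by OLS on the
residuals (Frisch–Waugh–Lovell); p-values use the t distribution with
n − k − 2 degrees of freedom, which matters with 100-PC covariate
blocks. Constant-dosage variants are flagged and skipped.

The LOCO mixed model rebuilds, for each chromosome, a GRM from all
*other* chromosomes (avoiding proximal contamination), estimates the
variance ratio once per chromosome by restricted maximum likelihood
on the GRM eigenbasis (grid search over h² ∈ [0, 0.99] with a bounded
refinement — ample resolution for a nuisance parameter feeding GLS),
and tests each variant by generalized least squares with the PCs as
fixed effects. Forcing h² = 0 reduces exactly to the linear scan.

Sibling-difference tests regress Δy on Δx across pairs *without an
intercept*: Δ quantities are symmetric about zero by Mendelian
segregation, so an intercept would only spend a degree of freedom
(recorded as a design choice; published descriptions do not state the
intercept convention).

## Siblings

Matings are structured: both parents come from the same deme, drawn
without replacement, no parent reused, two children per pair. A child
receives one whole haplotype of each parent per chromosome —
transmission without recombination, with the chromosome as the
biologically coherent unit of independent segregation. Both sibs
share the deme and hence the environmental mean exactly; their
genotype differences are pure Mendelian noise, which is why the
design is immune to any deme-level environment.

## Polygenic scores

Scores are Σ β̂·x over an ascertained variant panel in a held-out test
sample (never the training half). Ascertainment is
clumping-and-thresholding: windows of 100 kb centered on each causal
variant (each tested variant is assigned to its nearest causal
variant, so overlapping windows never claim a SNP twice), keeping
either the causal variant itself ("causal") or the window's
minimum-p variant ("lead SNP"), in both cases only when p < 5×10⁻⁴;
ties break to the smaller position. Residual scores subtract the
individual's true simulated genetic value; per-deme means of the
residual, averaged over phenotype iterations (20 at full scale),
form the bias map, summarized by the correlation between deme mean
residual and grid row ("gradient correlation"). Accuracy is the
squared correlation between score and true genetic value. The hybrid
design reestimates the GWAS-ascertained lead SNPs' effects in an
independent cohort of sibling pairs (sib-difference regression) or
unrelated individuals (plain OLS); a guard refuses reestimation in
any cohort overlapping the discovery individuals. Score variants
absent from the test sample contribute zero and are counted.

## Gene burden

Genes follow a human-average layout: 8 exons × 160 bp with 6,938 bp
introns. Introns only matter as recombining spacers, so
recombination-free genes are simulated as the bare 1,280 bp of exon.
Burden is the per-individual count of derived alleles at exonic
variants with derived frequency < 0.1% in the analyzed cohort.
To compare histories without conflating variant *numbers* with
variant *geography*, perpetual-model genes are thinned to a rare
variant count drawn per gene from N(16, 4²) (rounded, floored at 0),
matching the recent model's empirical distribution. Spatial
concentration of burden uses the Gini coefficient on cumulative
per-deme shares sorted increasing (normalized so the last cumulative
share is 1 — the only reading under which the formula is exactly 0
for uniform burden and (n−1)/n for single-deme concentration).
Default gene panels are 1,000–2,000 genes rather than the 100,000 of
a full study; confidence intervals widen accordingly.

Large gene panels use a hybrid engine: discrete-time Wright–Fisher
for the 100-generation structured epoch (batching its many migration
events generation by generation) and the standard coalescent beyond.
At deme size 10,000 the two agree — the coalescent is the WF limit —
and measured rare-variant counts per gene are statistically
indistinguishable (means 15–16.5 under both engines), while the
hybrid is several-fold faster.

## Problem sizes used by the shipped runs

The acceptance script runs the calibration design as published
(10 Mb as 10 × 1 Mb, 250 diploids per deme, 9,000 individuals) for
the recent-model FST and λ quantities; the birthplace GWAS runs over
all segregating variants — the convention under which the published
inflation values reproduce — while FST uses LD-pruned common
variants, subsampled to at most 60,000 before pruning. The perpetual
cohort runs at 100 per deme (the Weir–Cockerham estimator corrects
for sample size, so the mean is unchanged and only the CI widens).
The PC variance-explained contrast uses 100-per-deme cohorts (3,600
individuals) with variant panels capped at 30,000 per class, and the
burden content check simulates 600 genes at 9,000 individuals
(replicate-mean standard error ~0.17 against a ±2 margin). The test suite
uses smaller cohorts (2×2 or 6×6 grids, 0.1–10 Mb genomes, tens to
hundreds per deme) chosen so each scientific assertion retains power
at its scale. Passing tests demonstrate internal correctness and the
qualitative mechanisms (which corrections remove which inflation,
immunity of sib designs, burden robustness); they do not demonstrate
performance on real data, where genotyping error, imputation,
ascertainment and non-equilibrium history add failure modes the
generator does not emulate.

## Known limitations

* No array ascertainment, genotyping error or imputation; all
  variants are sequenced truth.
* Exact-genealogy IBD replaces a detector; real-data IBD is noisy.
* The complex model's ancient layers are schematic defaults, not an
  inferred European history.
* One-generation pedigrees only; no assortative mating, dominance,
  epistasis or gene–environment interaction beyond additive
  structured means.
* The perpetual-model PC contrast is threshold-limited at desk scale
  (see "Detectability at reduced scale").
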