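# Methods

This note documents the models, procedures, parameter choices and known
limitations of each pipeline stage, and what the synthetic generators
do and do not emulate.

## Stain-image lignin quantification

The Wiesner (phloroglucinol–HCl) stain turns lignin cinnamaldehyde
groups red against pale tissue. The segmentation procedure is: (1)
per-channel Gaussian blur, σ = 2.0 px, reflective borders, re-quantized
to 8 bits by rounding; (2) sRGB (D65) → CIELAB, with L\* rescaled
0..100 → 0..255 and a\*/b\* shifted by +128, so all three channels live
on the familiar 8-bit histogram axis; (3) adaptive thresholding from
the image's own 256-bin histograms: a pixel is lignin when its
lightness lies in the modal bin or below **and** its green–red value
lies in the modal bin or above; the blue–yellow channel is
unrestricted. Because unstained tissue and background dominate the
histograms, the modes track the pale phase and the red stain falls in
the selected dark/red tails. Ties between equally full bins resolve to
the lowest bin index.

Choices worth making explicit:

- **Denominator of the cortex percentage.** Reported as stained cortex
  pixels / cortex-ROI pixels × 100 — the only denominator comparable
  across sections of different total size. The ratio is clipped to
  [0, 100] because stained-boundary pixels just outside the cortex ROI
  enter the subtraction numerator.
- **ROIs are supplied, not segmented.** Xylem selection is an
  annotation step (as in manual practice); masks come from the
  generator or from single-channel PNG files.
- **Degenerate inputs.** On a constant image every pixel satisfies both
  conditions relative to its own mode, so the mask covers the frame.
  This is documented behavior, not an error: the procedure presupposes
  a dominant unstained phase.
- **Peaks are recomputed per image** (after the blur), never carried
  over from a reference image.

The section generator renders concentric annuli (pith, xylem ring,
cortex, epidermis) on a neutral background, stains contiguous angular
sectors of the cortex, and adds clipped Gaussian RGB noise (sd 4).
Default colors place unstained tissue at a8 ≈ 114 and stain at
a8 ≈ 143, symmetric about the neutral background mode (128), so the
adaptive threshold falls at the half-maximum of blurred stain edges and
boundary pixels do not bias the area estimate in either direction.
Stained sectors grow from seeded start angles in a fixed order, making
the stain set at a low fraction a subset of the set at a higher one
(a monotone fixture ladder at fixed seed). The generator emulates the
topology and contrast of real sections, not their histology: no cell
walls, no uneven illumination, no out-of-plane tissue. Passing the
recovery tests therefore shows the threshold logic is correct and
unbiased on clean geometry, not that it is robust to arbitrary
real-world staining artifacts.

## Differential expression

Counts are normalized to CPM (each sample column rescaled to 1e6) and
modelled per gene as an ordinary linear model on log2(CPM + 0.5). The
pseudocount guards log(0); BH is the multiple-testing adjustment
throughout. Two routes:

- **Interaction contrast**: reference-cell coding of
  condition + genotype + condition:genotype; the tested quantity is the
  difference between two genotypes' infestation responses
  (difference-of-differences of the four stratum means on the log2
  scale), with a t-test on the contrast and selection at adjusted
  p < 0.1 and |log2FC| > 1.
- **Omnibus two-way ANOVA**: the cell-means model against the
  intercept-only model (detects any main or interaction effect),
  selection at FDR < 0.1.

This is a deliberate divergence from a negative-binomial GLM with
dispersion shrinkage: the selection logic (interaction contrast,
adjusted p, fold-change cutoff) is the part the pipeline depends on,
and the log-linear model is calibratable by simulation — on null
simulations of the four-cultivar design (1,000 genes, 3 replicates per
stratum) the raw p < 0.05 fraction averages 0.050 across generator
seeds. No dispersion shrinkage, independent filtering or outlier
replacement is performed. Per-gene fits are vectorized linear algebra
and are cross-checked against statsmodels OLS in the tests.

## Expression clustering

Profiles are z-scored per gene (sample sd, ddof = 1; constant genes
become all-zero and are flagged), embedded with Barnes–Hut t-SNE
(perplexity 20, θ = 0.5, 1000 iterations, PCA initialization, seed 2),
and grouped by density. The backend's early-exaggeration phase runs a
fixed 250 iterations, which is exactly the configured "lying" value;
other values are rejected rather than silently ignored. Grouping is
DBSCAN with `min_samples` equal to the size cutoff (20) and the
neighborhood radius taken from the knee (maximum perpendicular distance
to the end-to-end chord) of the sorted k-NN distance curve, k = cutoff.
Setting `min_samples` to the cutoff means a core point must sit in a
neighborhood as populous as the smallest admissible cluster, which
suppresses density bridges between adjacent groups. Any surviving
group smaller than the cutoff dissolves into the explicit noise label
(−1); survivors are renumbered by decreasing size.

Determinism is promised only within one software environment at a fixed
seed (the embedding is bitwise reproducible across invocations there);
coordinate equality across t-SNE implementations is explicitly not a
contract — only structure recovery is. On planted three-cluster
simulations the assignment recovers the planted genes' partition with
ARI ≥ 0.8 across seeds; scattered background genes carry no
ground-truth cluster, so recovery is scored on the planted genes, with
a separate check that every surviving group meets the size cutoff.

## Co-expression networks

Within one stratum (genotype × condition), Pearson correlations between
the selected genes' log2-CPM profiles are Fisher z-transformed,
standardized by the off-diagonal mean and sd, and pairs exceeding the
standard-normal quantile at q = 0.997 (≈ 2.748) become edges carrying
the original correlation. Only the upper tail forms edges in this
default mode — edges are co-expression connections. An alternative
`empirical` mode thresholds |r| at its empirical q-quantile instead and
can admit strong negative correlations; it exists because a quantile
rule on a Gaussian reference and an empirical percentile are both
defensible readings of a "normal quantile cutoff", and the Gaussian
reading is the default. Note the standardization makes the threshold
adaptive: in a structure-free stratum roughly 0.3% of pairs will still
exceed it, so "isolated" is meaningful relative to strata that carry
real modules. Constant genes yield undefined correlations and are
excluded from edge formation. Communities come from greedy modularity
maximization; hubs are ranked by degree with ties broken by gene id;
degree-0 genes are listed separately, mirroring the isolated-gene lists
of stratified network figures.

## Variants and motifs

All coordinates are 1-based inclusive (VCF/GFF3 convention); BED export
converts to 0-based half-open. The resistance filter compares genotype
calls as unordered allele sets: a biallelic SNP is resistance-specific
when the two resistant cultivars' calls are identical and differ from
the susceptible cultivar's (covering both susceptible-equals-reference
and third-allele cases). Indels, multiallelic records and records with
missing calls are skipped and counted. Promoter windows span up to
5 kb upstream of the gene feature's 5′ end (no UTR refinement), clipped
at chromosome ends; a + strand gene starting at S gets
[max(1, S−5000), S−1]. The W-box scan matches the IUPAC pattern
TTGACY (Y = C/T) at every position on the forward strand and, for
reverse-strand hits, reports the leftmost forward coordinate with the
strand label; N never matches. Overlap reports list every
resistance-specific SNP inside a promoter window whose position falls
within a hit's 6-bp span, annotated with whether substituting the alt
allele destroys the match on both strands.

The variant generator plants exactly round(n_sites × fraction)
qualifying sites by construction and builds every other site to fail
the rule (resistant cultivars disagree, or all three genotypes agree).
Planted W-box hexamers are written into the reference at requested
positions (random strand and Y base); a chosen number of
resistance-specific SNPs is placed inside planted promoter W-boxes and
the remainder outside promoter windows, so the expected overlap count
is exact. Sites are biallelic SNPs only — the generator does not
emulate indels, multiallelic sites, call errors or linkage.

## Lignin chemistry

%ABSL follows Beer–Lambert: absorbance divided by extinction
coefficient (17.2 mL mg⁻¹ cm⁻¹ — a *Nicotiana benthamiana* stem value,
used because no tomato-specific coefficient exists) and path length
(1 cm; a 10-mm cuvette), times extraction volume over biomass, times
100. The reference point A = 17.2, 1 mL, 100 mg gives exactly 1.0%.
Pyrolysis GC-MS peak areas arrive pre-assigned to compound classes
(H, G, S, p-coumarate, other); normalization divides by the per-sample
total and sums fractions by class. Fractions conserve to 1 within
1e−12 and are invariant to rescaling all areas.

## Count simulation

Counts are gamma–Poisson (negative binomial, dispersion φ = 0.05
by default) with expected per-sample totals fixed at the library size
(5e5), so planted swings change composition rather than depth — this
mirrors sequencing at a set depth and avoids spurious
normalization-induced correlation between unrelated genes. Per-gene
base abundances are log-normal (log2-sd 1). Planted structure:

- **Clusters** add per-stratum log2 mean shifts to blocks of genes.
- **Modules** share one standard-normal latent factor per sample,
  entering multiplicatively on the log scale with loadings calibrated
  to a target pairwise correlation, λ = σ·sqrt(ρ/(1−ρ)) with
  σ² = (1/μ + φ)/ln(2)², and a first-order correction for the
  fixed-depth compensation of the module's own library share. A hub
  gene gets a loading far above the noise scale so it tracks the factor
  itself: hub–member correlation ≈ sqrt(ρ) while members
  inter-correlate at ρ — a star-topped module whose hub ranks first by
  degree. Modules can be restricted to strata, leaving their genes
  independent elsewhere (the stratum-specific-hub fixture).
- **Background patterns** (optional) give unplanted genes idiosyncratic
  per-stratum shifts so they scatter in profile space instead of
  forming one flat pseudo-cluster.

The loading calibration is first-order: very module-heavy designs
(module genes a large fraction of the library) still realize lower
correlations than requested, so fixtures keep modules below ~10% of
genes. Under exact independence the mean |r| between genes at n
samples is sqrt(2/π)/sqrt(n−1) (≈ 0.18 at n = 20) — the floor any
simulation check must respect.

## Problem sizes

Test and acceptance runs use 512×512 sections (20 for the oracle
sweep), 1,000-gene count matrices for calibration/power, 180 genes for
cluster recovery, 200 genes × 20 samples for network recovery,
1,000-site variant tables with 100-kb references, and a 600-gene
demonstration design for the end-to-end run — sizes at which every
planted property is comfortably detectable and the whole suite runs in
a few minutes on one CPU.

## Known limitations

- The imaging rule is histogram-adaptive and assumes a dominant pale
  phase; heavily stained sections (most of the frame red) would flip
  the modes and invert the logic.
- The log-linear DGE model has no dispersion shrinkage, so at very
  small replicate counts it is less powerful than shrinkage-based NB
  methods; its calibration has been verified only on the simulated
  design family.
- DBSCAN-on-t-SNE cluster counts depend on the embedding's local
  density and are not comparable across software environments.
- The adaptive network threshold always admits ~(1−q) of pairs in a
  structure-free stratum; cross-stratum comparisons should use the
  same gene list and q.
- Genotype calls are taken as given; no variant-calling uncertainty is
  propagated.
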