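# Methods

`imagecca` links tissue morphology to molecular variation in three stages:
an image-embedding stage that turns each stained-tissue slide into a fixed
vector of learned features, a sparse canonical correlation stage that finds
paired sets of genes and image features varying together across samples,
and an association stage that maps genotypes onto the image features of
those components (image-morphology QTLs, "imQTLs"). A synthetic-data module
generates paired slides, expression, covariates and genotypes with planted
shared structure so every stage can be validated against known truth.

## Image embedding

**Tiling and window sampling.** Slides are divided into square tiles
(1000 x 1000 px on real slides; the synthetic slides use 128 px tiles). A
tile is kept only if its mean gray value (ITU-R BT.601 luminance) and the
mean gray values of its four edge neighbours are all darker than 180/255 —
a cheap tissue-density filter that discards background and tissue edges.
The means are computed on a x16 box-filtered downsample of the slide, since
tile statistics at full resolution add cost without changing the decision.
Tiles on the slide border lack a full neighbourhood and are never selected;
the selection rule is undefined there and dropping them loses little
tissue. Training windows (128 x 128 px) are sampled uniformly over
(selected tile, valid offset) and augmented by rotations restricted to
multiples of 90 degrees, which avoids interpolation artifacts. Whether
sampling should instead be uniform over pixels when slides differ in tile
counts is left open; uniform over (tile, offset) is the implemented choice.

**Autoencoder.** The encoder applies blocks of 5 x 5 same-padding
convolution, ReLU and 2 x 2 max pooling, doubling the filter count each
block (default 4 blocks starting at 32 filters: maps 128 -> 64 -> 32 ->
16 -> 8 with 32, 64, 128, 256 filters), and ends in a fully connected
bottleneck of 1024 units. The decoder mirrors it: a linear projection
reshaped to the last encoder map, then blocks of nearest-neighbour 2x
upsampling, convolution and ReLU, with a final sigmoid onto [0, 1] pixels.
Training minimises mean squared reconstruction error with Adam (default
learning rate 1e-3, batch 32); runs are deterministic given the seed. The
network is implemented directly on numpy with explicit backpropagation
(shifted-slice accumulation for the convolutions), which is fast enough for
the compact configurations this package targets on a single core. The
base filter count, the linear bottleneck and the sigmoid output are design
choices; all are configurable.

Test and example runs use a compact configuration (base_filters 2-4, a few
epochs, 100-200 training windows) so the whole synthetic study finishes in
minutes on one core. The full m = 100 windows per sample are kept even in
the compact runs because the bag-of-features average sharpens as
1/sqrt(m) and the downstream association scan depends on that precision.
The compact sizes demonstrate the machinery, not image-representation
quality; a real study would train the default architecture for many more
epochs.

**Bag of features and whitening.** Each sample is represented by the
elementwise mean of its m window codes (m = 100 by default; the mean is
accumulated in sorted order per dimension so it is bitwise invariant to
window order). Averaging integrates out where structures sit in the slide
while keeping what they look like. The n x 1024 matrix of averaged codes is
then PCA-whitened: centred, rotated to principal axes, and each retained
axis scaled to unit variance. Axes with eigenvalue below 1e-8 are dropped
to avoid amplifying numerical noise, so with n samples at most
min(n - 1, 1024) whitened features remain and the sample covariance is the
identity on them. The fitted basis (mean, rotation, scales) is stored and
can transform new samples.

**Supervised variant.** A classifier head (dense 128-unit ReLU layer, then
softmax — or a single sigmoid unit for binary labels) can be attached to
the trained encoder and trained by cross-entropy on window labels. Its
128-unit hidden activations, averaged and whitened like the unsupervised
codes, serve as supervised image features. Whether the encoder should be
fine-tuned or frozen during head training is genuinely ambiguous; both
modes are exposed (`fine_tune` flag). The same head supports dense patch
classification: every stride-offset 128 x 128 patch of an image is scored
with the class-1 probability, yielding a heatmap of
(floor((H-128)/stride)+1) x (floor((W-128)/stride)+1) cells.

## Expression preprocessing

The genes x samples abundance matrix (TPM or RPKM; quantification is
upstream of this package) is transformed by log2(x + 1) — the base and
pseudocount are conventions, both configurable — then each gene is centred
and scaled to unit sample standard deviation so CCA weights are comparable
across genes. Zero-variance genes are dropped with a warning. Samples are
intersected with (and ordered by) the imaged samples.

## Sparse CCA by penalized matrix decomposition

With X (n x p standardized expression) and Z (n x q whitened image
features), components are extracted from the cross-product matrix
C = X'Z/(n-1) as rank-1 factors under unit-l2 / bounded-l1 constraints:

    maximise u'Cv  subject to  ||u||2 <= 1, ||v||2 <= 1,
                               ||u||1 <= c_genes, ||v||1 <= c_images.

Within-view covariances are treated as the identity (diagonal-covariance
CCA) — standard for p, q >> n, where exact within-view whitening of the
gene view is ill-posed. The l1 budgets are parameterised as fractions:
c = lambda * sqrt(dimension), so lambda = 1 is the dense limit and the
defaults lambda_images = 0.15 and lambda_genes = 0.05 (0.10 for
multi-tissue data) are meaningful across dimensions.

Each rank-1 problem is solved by alternating u <- S(Cv)/||.||2 and
v <- S(C'u)/||.||2, where S is soft-thresholding with the smallest
threshold that brings the l1 norm of the normalised vector under its
budget. That threshold is found in closed form: the l1/l2 ratio is
piecewise smooth between the sorted magnitudes, so the crossing segment is
located with cumulative sums and the crossing solved as a quadratic
(an interval bisection backs up ill-conditioned segments). When the
largest magnitudes are exactly tied the ratio plateaus and no threshold
attains the bound; the routine then returns the true constrained
maximiser, a uniform spike set over the floor(c^2) leading coordinates. Iteration stops when the largest change in v
falls below 1e-6 (max 1000 iterations; a convergence flag is recorded).
The alternating objective is non-decreasing, and in the dense limit the
solution is the leading singular pair of C.

The problem is non-convex, and the leading singular vector of a noisy
cross-product matrix can point away from a sparse block that scores higher
under the l1 bounds. Each extraction therefore uses deterministic
multi-start: the leading right singular vector plus coordinate inits at
the three columns of C with the largest l2 norm; the fit with the largest
d = u'Cv is kept, with ties resolved in candidate order. After each
component, C is deflated by d_k u_k v_k' and the next component is fitted
conditional on the previous ones; K = 100 components by default (greedy
and deterministic, so any K' < K gives the same leading components). For
reporting, each component's sign is flipped so its strongest image-feature
weight is positive, with scores and gene weights flipped consistently.

**PVE.** The proportion of variance explained by component k is defined as
d_k^2 / sum_j d_j^2. Because fitting is greedy with heterogeneous
sparsity, d_k need not decrease monotonically in k, and the PVE sequence
is allowed to be non-monotone.

**Hyperparameter tuning.** A grid over (lambda_images, lambda_genes) is
scored by held-out cross-view reconstruction: the model is fitted on a
training split, each held-out view is reconstructed by the least-squares
linear map from the other view's canonical scores (fitted on the training
rows), and the flattened Pearson correlation between reconstruction and
truth is reported per view. Held-out rather than in-sample scoring is the
implemented choice since in-sample reconstruction improves monotonically
with model capacity.

**Permutation validation.** Cross-view structure is tested by the
statistic sum of d_k over the top K' components (default 10). The null is
built by refitting after permuting the sample rows of one view; the
empirical p-value is (1 + #{null >= observed}) / (1 + n_perms). Because
the fit is deterministic given the data, no restarts beyond the
permutations themselves are needed. Grouped (e.g. within-tissue)
permutation is a natural refinement and the machinery leaves room for it;
full row permutation is what is implemented.

## Component interpretation

* **Extreme samples.** For a component, samples are ranked by the
  image-side canonical score Z v_k (the gene side is available by flag) and
  the bottom and top ceil(fraction * n) sample IDs are reported (default
  10% / 90%), ties broken by sample ID.
* **Tissue specificity.** For the non-zero-weight genes of a component,
  the per-tissue mean raw expression is computed and each gene's row is
  normalised by its l1 norm, giving a probability simplex over tissues; a
  tissue without images can be appended for comparison. (A row can only
  "sum to one with maximum one" when it is one-hot; sum-to-one is the
  implemented normalisation.)
* **Covariate correlations.** Pearson correlation of each component's
  image-side score with each numeric-coded covariate (categoricals coded
  as integer levels in file order), pairwise-deleting missing entries.
  Each component is sign-flipped so its correlation with a chosen
  reference covariate is non-negative; the flip negates the whole row, so
  applying it twice is the identity.
* **Gene-set enrichment.** One-sided Fisher's exact tests (hypergeometric
  upper tail) of a component's gene set against user-supplied GMT gene
  sets, intersected with the analysis universe. p-values are reported
  uncorrected. Graph-aware ontology methods (e.g. parent-child
  elimination on the GO DAG) are out of scope.

## Image-morphology QTL mapping

Image features are first normalised by projecting each feature onto the
quantiles of the empirical distribution pooled over all n x q feature
values, at the feature's within-sample fractional ranks ((rank - 0.5)/n,
average ranks for ties). Pooling across features is the implemented
reading of "the distribution over all features"; per-feature z-scoring is
available by flag since both normalisations are defensible.

The test set is restricted before any regression: a (SNP, feature, tissue)
triple is tested only if some component k <= 100 gives the feature non-zero
weight and contains a non-zero-weight gene for which the SNP is a known
cis-eQTL in that tissue (the cis-eQTL table is an input, not something this
package discovers), the tissue has at least 20 imaged samples, and the
mediating gene is expressed in that tissue (median raw expression > 0).
Each surviving pair is tested by univariate OLS of feature on allele
dosage within the tissue: effect beta per allele, standard error,
T = beta/se, and a two-sided p-value on n_used - 2 degrees of freedom,
with missing dosages dropped pairwise and zero-variance genotypes skipped.
No covariates enter the model by default (the model is univariate);
residualisation hooks exist but are off.

Discoveries are declared by Benjamini-Hochberg at FDR 0.1, pooled across
all tests in a run; per-tissue pooling is available by flag since the
choice between the two is not dictated by the model.

## Synthetic data

The generator plants K_true latent factors per dataset. Each factor loads
on a disjoint block of genes in log2-expression space with per-gene
loading a = sqrt(s / ((1 - s) g)) for block size g, so the block average
correlates with the factor at sqrt(s) and two views built this way share a
canonical correlation of s (the `signal` parameter, default 0.8). Factor 1
scales nucleus density multiplicatively (density = 60 e^{0.25 f} nuclei
per 10^4 px^2 — strictly increasing in f, spanning roughly 30-130 over the
typical factor range), factor 2 scales nucleus radius, factor 3 tints the
background. One SNP per factor, simulated at Hardy-Weinberg proportions
with MAF 0.3 (independent SNPs — linkage is irrelevant to the machinery
under test), shifts its factor by 0.8 per alternate allele, a strong but
realistic cis effect; five extra SNPs are null. Samples cycle over three
tissues, each gene receives a small N(0, 0.3) per-tissue shift, and the
bundled cis-eQTL table links the causal SNPs to their support genes in
every tissue (decoy rows link null SNPs to non-support genes).

Images are rendered as Poisson-placed, anti-aliased filled ellipses with
Gaussian-jittered radii in a dark nuclear-stain colour on a pale
background whose luminance (about 170/255) keeps every tile under the
180/255 selection threshold. Defaults are n = 100 samples, 500 genes,
512 x 512 px slides. The generator emulates the statistical structure the
pipeline exploits — morphology monotone in latent factors shared with
expression — and none of the texture, staining variation, magnification
heterogeneity or spatial autocorrelation of real histology; passing tests
therefore validate the estimation machinery, not robustness to real-slide
artifacts. Expression noise, genotype draws, image rendering and covariate
noise use independent child streams of one seed, so no stage leaks
randomness into another.

A matrix-level generator (`planted_cca_matrices`) plants the same sparse
canonical structure directly in two noise matrices (disjoint gene and
feature supports) for tests that need known feature-side truth without the
image stage.

## Numerical conventions and degenerate inputs

* Sample (ddof = 1) standard deviations throughout.
* Closed-form (exact) l1-bound thresholds; PMD convergence tol 1e-6 on v.
* Whitening eigenvalue floor 1e-8; retained rank min(n - 1, q).
* Soft-threshold budget c = 1 returns the single-spike solution at the
  first maximal coordinate (deterministic tie-break).
* Zero-residual regressions report the smallest positive double as p and
  are flagged degenerate; constant features map to the pooled median under
  quantile normalisation (with a warning); constant reference covariates
  disable the sign flip (with a warning).
* K is truncated to min(p, q) with a warning when asked for more.

## Known limitations

Slide ingestion is limited to standard raster formats (PNG/TIFF);
pyramidal whole-slide containers, stain normalisation and magnification
harmonisation are out of scope. The autoencoder is sized for single-core
CPU training — it demonstrates the representation-learning stage rather
than competing with GPU-scale models. Enrichment is plain Fisher on
user-supplied gene sets. Only two views are supported (no group factor
analysis), and the association model is univariate with no LD handling or
conditional analysis.
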