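# Methods

`dynfuse` implements a "dynamic fusion" analysis that links one fixed
subject × SNP genotype matrix to multiple dynamic functional network
connectivity (dFNC) states through parallel joint ICA decompositions. This
note documents the models and procedures, the parameters that matter, what
the synthetic-data generator does and does not emulate, and the numerical
and design choices that were genuinely open.

## Pipeline model

**Windowed FNC.** Per-subject ICN time courses are post-processed in a fixed
order: per-ICN linear detrend; despiking by clipping samples beyond
median ± 4·MAD (unscaled median absolute deviation) to the boundary;
optional OLS regression of realignment parameters and their derivatives
(skipped when absent, as for synthetic data); zero-phase band-pass with a
5th-order Butterworth applied forward and backward (default 0.01–0.15 Hz);
re-standardization to unit variance. The despiking rule and filter order
are conventions of this implementation — the upstream literature names the
steps but not their exact parameterization.

Connectivity is estimated on a tapered sliding window: a rectangle of
`window_trs` TRs (default 20) convolved with a Gaussian kernel of
`sigma_trs` TRs (default 3, support ±3σ), normalized to sum 1. For each
window position (stride 1 TR by default, half-open sample ranges) the
taper-weighted sample correlation is fed to the graphical lasso
(`sklearn`, penalty `glasso_lambda`, default 0.1, diagonal unpenalized);
the implied covariance is converted back to correlation, capped at
|r| ≤ 1−10⁻⁶, and Fisher r-to-z transformed over the strict upper triangle
(row-major pair order). With the penalty taken to zero this reduces to
plain tapered Pearson correlation (verified to max |Δz| < 0.02). The
graphical-lasso dual-gap tolerance is 5·10⁻³ with at most 50 iterations —
band-passed windows are strongly autocorrelated and near-singular, where
tighter tolerances cost an order of magnitude of run time without changing
the z values at the precision the downstream clustering uses; degenerate
windows are retried once with 10⁻⁴ shrinkage toward the identity before
being dropped and reported.

**States.** K-means (k-means++, squared-Euclidean, default 10 restarts)
clusters all subjects' windows jointly; the number of states is the k
maximizing the second difference of the inertia curve over a scanned range
(default 2–8; the "elbow"). All windows are clustered directly — exemplar
subsampling is unnecessary at desk scale. Windows are assigned to the
nearest centroid (ties to the lowest state index); a subject's windows in
one state are averaged into the subject's state-average dFNC (sa-dFNC)
vector, and subjects who never visit a state are excluded from that
state's fusion sample, so per-state sample sizes differ. A validation
cohort's windows are assigned to the discovery centroids, never
re-clustered.

**Residualization.** Before fusion, each sa-dFNC feature is residualized by
OLS on age, sex, and dummy-coded site; the SNP block on sex, site, and the
top genotype principal components (default 4, computed from
column-standardized dosages with a deterministic sign convention), which
stand in for population stratification control. Categorical covariates are
dummy-coded dropping one level; rank-deficient designs are rejected with
the collinear columns named.

**Joint ICA.** The fusion model is X = A·S on the horizontally concatenated
subjects × (SNP + dFNC) matrix. Features are z-scored and each modality
block is rescaled by 1/√(feature count) so both modalities contribute equal
expected total variance (a simple balancing; adaptive per-feature weighting
is out of scope). The subject dimension is reduced by SVD to the model
order C and whitened; Infomax — natural-gradient maximum-likelihood ICA
with a logistic nonlinearity, the classic choice for super-Gaussian
sources — unmixes the whitened rows. Hyperparameters follow common Infomax
practice: initial learning rate 0.00065/ln C, minibatches of
⌊√(p/3)⌋ samples, rate annealed by 0.9 when the angle between successive
weight updates exceeds 60°, stop when the squared weight change falls
below 10⁻⁶ or after 512 passes; on numerical blow-up the unmixing matrix
restarts from identity at half the rate. Source rows are standardized to
unit variance (scale absorbed into A), signed to positive skewness, and
ordered by descending explained variance; A = X·S⁺, so A·S equals the
rank-C PCA reconstruction exactly. Components are flagged super-Gaussian
when the joint source row's excess kurtosis exceeds a threshold (default
0; the exact selection rule used upstream is not recoverable, so the
threshold is exposed and logged).

**Model order.** Per input matrix, the scree of subject-covariance
eigenvalues is summarized by its knee — the point farthest from the chord
joining the first and last scree points (the scree normalized to the unit
square) — and the shared order is the median of the per-matrix knees,
raised if needed to the smallest C retaining a floor fraction (default
75%) of variance in every connectivity matrix. The order is fixed and
shared across the parallel fusions so the across-state comparison is
symmetric.

**Across-state similarity.** For each component of each fusion, the best
counterpart in each other fusion is found separately per modality by the
absolute Pearson correlation of the SNP and dFNC source sub-vectors
(directional, with replacement — best-match symmetry is not assumed; a
greedy bijective variant exists for stability testing only). The
across-state similarity per modality is the mean of the best |r| over the
other fusions; the headline "most similar counterpart" is chosen by the
combined similarity (mean of the two modality |r| values), a choice this
implementation records explicitly because either modality alone is equally
defensible. Components are labeled state-invariant at similarity ≥ 0.85
and state-variant at ≤ 0.40 by default — reporting conveniences, always
configurable and echoed in output.

**Validation.** Discovery dFNC sources are projected onto the independent
cohort's residualized sa-dFNC matrices via the Moore–Penrose pseudo-inverse
(SVD, singular values below max(dim)·eps·σ_max treated as zero):
A_val = X_val·S⁺. Projected loadings are residualized on age, sex, site,
and mean framewise displacement and compared between cases and controls by
a pooled-variance two-sample t-test (df = n₁+n₂−2; Welch behind a flag —
the variance assumption of the upstream analysis is unstated, and pooled is
the conventional reading of the t²/(t²+df) effect size). The explained
variance of the group difference is r² = t²/(t²+df). Benjamini–Hochberg FDR
is applied jointly across all components of all fusions (one family).
Cognitive and symptom partial correlations (residualizing age, sex, site,
plus diagnosis for cognition; patients only for symptoms) are reported
uncorrected by design, as an interpretation aid.

**Interpretation.** Source sub-vectors are z-scored within modality block
(not over the joint row, since the blocks have different scales after
balancing) and features beyond |z| > 3 are the component's top SNPs and
connectivity pairs; pairs are annotated with ICN labels and functional
domains, SNPs with genes from a user-supplied map (pure lookup — no
external databases, no pathway enrichment). Gene-set overlap between
components is Jaccard, reported as a percentage (the overlap coefficient is
available behind a flag). Domain summaries aggregate retained pairs into
domain × domain counts split by weight sign and flag hub ICNs
participating in at least half the retained pairs.

## Synthetic-data generator

The generator emulates the *structure* of a multimodal imaging-genomics
study, not any real cohort: it is the fixture against which every stage is
tested, with a recoverable planted truth.

- **Joint sources** are sparse-Laplace rows (default 20% active features,
  scale-only standardization so inactive features stay exactly zero):
  super-Gaussian by construction, and SNPs with no planted weight remain
  genuinely null for the Hardy–Weinberg property checks.
- **Loadings** are standard normal per subject; the case half of subjects
  receives an additive shift (default 0.5 SD on one designated component),
  matching the validation stage's two-sample contrast.
- **Genotypes** discretize the continuous liability `loadings @ sources +
  noise` (per-SNP noise set by the design SNR; unit noise for null SNPs) by
  per-SNP empirical quantile cuts at the HWE proportions (1−maf)² and
  (1−maf)²+2maf(1−maf), preserving the drawn minor allele frequency by
  construction while the planted loading–dosage correlation survives.
- **States** are factor-structured correlation matrices whose 2-factor
  subspaces are drawn mutually orthogonal across states (one QR basis split
  into blocks), giving well-separated planted centroids; each is nearest-PD
  repaired (eigenvalue clipping at 10⁻⁶, re-normalization to unit diagonal,
  iterated). Subjects follow a per-TR Markov chain with uniform switch
  probabilities and mean dwell `dwell_mean` TRs (default 60) — at the
  default 1-TR stride a visit of d TRs contributes ≈ d windows, so this
  matches a per-window dwell reading up to the window support. Within a
  visit, samples are drawn i.i.d. from a zero-mean multivariate normal with
  the state's (subject-perturbed) correlation.
- **Randomness** flows from one integer seed through fixed-purpose
  substreams plus a counter-based substream per subject, so any piece of a
  fixture regenerates independently and identically.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, dosage uncertainty in [0,2], hemodynamic response or autocorrelated
scanner noise, site- or motion-related artifacts correlated with diagnosis,
and realistic effect-size spectra. Passing tests therefore demonstrate that
the estimators recover what they are designed to recover under their own
assumptions — identifiability, calibration, bookkeeping — not that the
pipeline is robust to the full messiness of real cohort data.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale sizes chosen to make every
planted quantity comfortably identifiable: ICA recovery uses 500 subjects ×
(300 SNPs + 45 pairs) at SNR 2 and 5 components over 10 seeds; state
recovery uses the full default fixture (200 subjects × 400 TRs × 10 ICNs,
4 states) with a 2-TR window stride; FDR calibration uses 50 null
replicates of 4 × 35 projected components at n = 200; the power check uses
20 replicates of a 0.5-SD shift on 2 of 35 components at n = 400. Correlation
capping before atanh keeps Fisher z finite; K-means ties and the
nearest-centroid assignment break toward the lowest state index; the elbow
needs at least three scanned k values and falls back to the smallest k
otherwise; an Infomax run that reaches the iteration cap returns its result
flagged `converged=False` rather than failing.

## Known limitations

The modality balancing is global per block, not adaptive per feature; hard
state assignment discards partial state membership (fuzzy or meta-state
approaches are deliberately out of scope); the elbow statistic and the
super-Gaussianity threshold are conventions exposed in configuration; the
cognitive-battery harmonization of a real multi-site study is reduced to
per-cohort standardized scores in the generator.
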