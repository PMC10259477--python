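# Methods

This note documents the models and procedures implemented in `songcircuit`,
the assumptions behind them, the parameters that matter, and the numerical
choices made where the underlying method left the design open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Song simulation (`simulate`)

Each bird sings bouts of harmonic-stack syllables. A syllable of type *i*
is a sum of `n_harmonics` sinusoids at multiples of a fundamental
`f0_means[i]`, with 1/k amplitude decay, a raised-cosine onset/offset
envelope (5 ms ramps), and additive Gaussian noise (`noise_sd`, default 5%
of the unit syllable amplitude). Rendition-to-rendition fundamental
frequency (FF) jitter is multiplicative with coefficient of variation
`ff_jitter_cv` (default 2%, within the range observed for Bengalese finch
harmonic stacks).

Feedback-deprived ("deaf") birds drift after day 0: on post-manipulation
day *d* the per-type fundamental becomes `f0 · (1 + drift_magnitude · d)`,
and both the jitter CV and the noise floor inflate by the same
`(1 + drift_magnitude · d)` factor — a multiplicative FF displacement plus
noise-floor (spectral-flatness) elevation. This mirrors the qualitative
phenomenology of deafening-induced destabilization (gradual spectral drift
plus increased noisiness); no attempt is made to model changes in syllable
sequencing. Hearing birds never drift. The default of **seven syllable
types** is a deliberate study condition: real Bengalese finch repertoires
contain roughly 5–10 types, and it places the true cluster count inside
the 5–12 component range scanned by the mixture selection below.

Randomness is split deterministically per `(seed, bird, day)`, so any
subset of days is reproducible independently.

## Count simulation (`simulate`)

Counts are gamma-Poisson (negative binomial): `var = mu + phi·mu²` with
dispersion `phi` (default 0.3, typical for sparse 3'-tag data). The
log-mean of gene *g* in a section from bird *b*, region *r* is

    log mu = baseline_g + region_effect_{g,r} + bird_effect_{g,b,r}
             + log(2)·beta_{g,r}·SongDKL_b + latent contributions,

normalized across genes and scaled by a per-section library size (default
50k–200k). Bird effects are Gaussian on the log scale (sd 0.2) and drawn
independently per bird × region, so technical sections within a bird-region
cell are correlated but regions are not spuriously coupled. Planted
covariate effects `beta` are in log2 units per unit Song D_KL and are
recorded in a `GroundTruth` object keyed by (gene, region, covariate).
Latent factors implement inter-region coupling: for each configured gene
set and region pair, one standard-normal factor per bird loads on the set's
genes in both regions; under `condition_decorrelation` the factor is drawn
independently per region in deaf birds, abolishing the coupling there.

The default design — 8 regions (4 song nuclei, 4 adjacent comparator
regions) × 18 birds (9 hearing, 9 deaf) × 2–6 sections — emulates the
structure of the deafening study (~600 samples). Bird-level Song D_KL
covariates are drawn around 0.14 (hearing) and 0.52 (deaf) so the graded
behavioral covariate, not a binary condition label, drives planted
expression effects.

What the generator does *not* emulate: gene-gene correlation beyond the
planted sets, batch/pool artifacts, surrogate-variable structure, zero
inflation beyond NB sampling, and 3'-bias. Passing tests therefore
demonstrate correctness of the statistical machinery under a clean NB
world, not robustness to every artifact of real SLCR-seq data.

## Song features (`song_features`)

- **Segmentation**: rectified waveform smoothed with a 2 ms moving
  average; maximal runs above `amp_threshold` merged across gaps shorter
  than `min_gap` (default 5 ms) and discarded below `min_duration`
  (default 10 ms). Boundaries are accurate to about one smoothing window.
- **Mean PSD**: mean magnitude spectrum over Hann-windowed 512-sample
  frames, zero overlap, max-normalized; 256 bins to Nyquist.
- **Spectrogram features**: STFT (512 window, 0.5 ms hop) → band-limit to
  500–15,000 Hz → 128-channel triangular mel filterbank (implemented
  in-package) → linear time-compression to 640 frames/s → symmetric
  zero-pad or center-clip to 128 frames → 16×16 block average → flattened
  256-vector. Padding is symmetric and block-averaging exact, so the map
  is deterministic and gain-covariant (equal up to scale under global
  gain).
- **FF estimation**: a single 1024-sample Hann-windowed frame at the
  requested offset, zero-padded 64× so the spectrum is sampled about every
  0.7 Hz, Akima-spline interpolated onto an integer-Hz grid over
  [fmin, fmax]; the argmax is the FF. For noiseless tones the error is
  bounded by the grid (≤ 1 Hz).
- **Wiener entropy**: log(geometric mean / arithmetic mean) of the power
  bins with a floor of 1e-12 (the Sound Analysis Pro convention): 0 for a
  flat spectrum, strongly negative for tonal sounds.
- **Rolling CV**: sample sd over mean across the current and 10 prior
  renditions (window 11), undefined until the window fills or when the
  window mean is zero. In `cv_change_vs_baseline` the window restarts at
  each day, so between-day FF steps (e.g. across the manipulation) do not
  masquerade as rendition-to-rendition variability. The group contrast is
  a linear mixed model fitted by maximum likelihood: period (pre/post) as
  fixed effect, random intercepts for bird and for syllable nested in
  bird; the p-value is the Wald test on the period coefficient.

## Song D_KL (`song_divergence`)

Syllable PSDs are represented by Euclidean distances to `n_refs = 50`
reference syllables sampled from the pre-manipulation training split
(`n_train = 500`; a 70/30 split with a warning when fewer pre syllables are
available). Per replicate (default 10): a diagonal-covariance Gaussian
mixture is fitted to the pre training distances for k = 5..12; the model
minimizing the second-order BIC difference (BIC in the higher-is-better
convention; ties toward smaller k) is selected; a post mixture with the
same k is fitted to the post training distances; and the replicate value is
the mean over held-out pre syllables of `log2 L_pre − log2 L_post`. Song
D_KL is the replicate mean — a Monte-Carlo estimator of the KL divergence
between the pre and post syllable distributions. The literally printed
form `log2(L1̄ − L2̄)` is additionally available behind
`literal_formula=True`; it is undefined whenever the mean post likelihood
exceeds the mean pre likelihood, which is why the per-syllable
log-difference form is the default.

Three numerical choices keep the null (unchanged song) calibrated near
zero; all three were required to bring the null bias and EM-initialization
noise well below the 0.2-bit scale at 500 training syllables:

1. **Reference rows are excluded from the fitted matrices.** A reference
   syllable's distance vector contains an exact zero (its self-distance);
   leaving those 50 rows in the pre training matrix systematically degrades
   the pre fit relative to the post fit.
2. **The post mixture is warm-started from the pre model's parameters**
   (weights, means, precisions) and refined by EM on the post data. With
   random k-means initialization the two fits land in different local
   optima and the held-out likelihood difference reflects initialization
   noise (~1 bit) rather than distributional change. Warm starting plays
   the role of the deterministic hierarchical initialization used by
   classical model-based clustering software, and does not blunt real
   divergence: EM moves the components to the post data regardless of the
   start.
3. **A per-dimension variance floor (`reg_covar = 0.1`)** on the
   squared-distance scale of max-normalized PSDs prevents razor-thin
   components whose density spikes amplify fit-to-fit differences.

Under these defaults the unchanged-song null satisfies |D_KL| < 0.2 and
the statistic rises monotonically with drift magnitude until it saturates
(around 1%/day drift over 14 days the post distribution is essentially
disjoint from the pre support); the acceptance ladder stays below that
regime.

## UMAP density differences (`song_divergence`)

Feature vectors are reduced by PCA (10 components) and embedded in 2-D by
seeded UMAP. Per-day densities are axis-aligned product-Gaussian KDEs on a
200×200 grid over a common bounding box (data range over all days, padded
5%). The per-axis bandwidth follows the normal-reference rule
(1.06·min(sd, IQR/1.349)·n^(-1/5), the `kde2d` convention), computed once
from the pooled baseline-day points and shared across days — a per-day
bandwidth would over-smooth days whose point cloud is split between the
old and new song regions. The day statistic is the grid sum of
max(density − baseline mean, 0), reported raw and multiplied by the cell
area. The normalized variant is a total-variation-style overlap measure:
≈0 for a day resampled from baseline, ≈1 for a fully displaced day, ≈0.5
when half the mass moves; residual KDE noise keeps the null near 0.08 at
~1500 syllables per day. Group differences per day are two-sided Student
t-tests on bird-level statistics, flagged at p < 0.05 unadjusted.

## Expression model (`expression`)

- **Filters**: genes with total counts below n_samples/8 are removed (the
  divisor is the number of regions assayed); samples with a cellular
  detection rate (detected genes / 18,674 annotated) below 30% are
  removed, with retention at exactly 30%.
- **Normalization**: trimmed mean of M-values against the deepest sample
  (30% log-ratio trim, 5% abundance trim, precision weights), with
  singleton pairing: genes detected in only one of the two libraries are
  rank-paired largest-with-largest into pseudo-pairs (the sparse-safe
  "wsp" behavior). Factors are rescaled to geometric mean 1.
- **Technical replication**: sections within a bird × region cell are
  treated as technical replicates and averaged before contrast fitting
  (declared in the result metadata). This replaces consensus-correlation
  blocking; it is conservative (uses cell means) and keeps the design
  full-rank at the cell level.
- **Model**: log2-CPM with a 0.5 pseudocount on effective library sizes;
  optional (default on) voom-style observation weights — per-gene OLS
  residual sd on the quarter-root scale regressed on mean log-count by
  lowess (span 0.5), evaluated at each observation's fitted log-count,
  weights 1/sd⁴; per-gene weighted least squares; empirical-Bayes
  moderation by moment-matching log residual variances to a scaled
  inverse-chi-square prior (digamma/trigamma matching, Newton inversion of
  the trigamma function). Moderated t uses d_resid + d_prior degrees of
  freedom; BH adjustment within contrast; the differential threshold
  adjusted p < 0.1 is recorded on every result. When the spread of log
  variances does not exceed chi-square sampling noise the prior df is
  infinite; literally identical variances are left untouched (fixed
  point).
- **Designs** are declarative: a cell-means factor (region, or bird×region
  for per-bird estimates, or hemisphere group for the lesion contrast),
  region × covariate interactions (continuous, or categorical with the
  first level as reference), plain covariates (z-scored by default), and
  factor covariates (e.g. bird fixed effects for the within-bird
  ipsi-vs-contra lesion contrast). Rank deficiency is rejected with the
  aliased columns named. A helper discretizes Song D_KL into three
  equal-size ordered bins for bin-based contrasts.
- **DEG scores**: per gene sign(logFC)·(−log10 adj p); the up-score sums
  positive values, the down-score negative values, reported separately
  (their sum is the single signed total). Display tables cap |signed
  −log10 p| at 5.
- **Per-bird-region estimates**: the saturated cell-means fit with CDR and
  mitochondrial-fraction covariates; moderated SE =
  sqrt(s2_post)·stdev_unscaled. Constant covariates are dropped so the
  saturated identity (one sample per cell ⇒ estimate = that sample's
  log-CPM) holds exactly.

At the full study scale (8 regions × 18 birds) the moderated t is
calibrated (type-I error ≈ 0.05 at α = 0.05 for a bird-level covariate
with no planted effect). At much smaller designs (~24 cells) the
observation-weight trend can be mildly anticonservative, a known property
of trend-based weights at low replication; weights can be disabled per
fit.

## Networks (`network`)

Variable genes are ranked by trend-standardized variance (lowess of log
variance on log mean; residual rank). All-pairs signed Pearson
correlations are thresholded by permutation FDR: sample labels are
permuted independently per gene (50 permutations), FDR(t) = mean permuted
count ≥ t over observed count ≥ t along a ladder of |r| thresholds, and
edges at the smallest threshold with FDR < 0.05 are retained. An exact
variant enumerates all relative sample permutations for small n (used as
its own oracle in tests). The planar filtered network inserts edges in
descending |r| (ties by gene-id pair), keeping an edge iff the graph
remains planar; the result attains the maximal planar bound 3(n−2) on
complete inputs. Modules come from seeded Louvain modularity maximization
on the |r|-weighted planar graph at a resolution ladder (default 0.5, 1,
2); each finer module's parent is the coarser module containing the
plurality of its genes; minimum size 10.

Module tests follow the sampling-null pattern: the observed mean per-gene
coefficient per module against 100 means of random same-size gene sets
(flag outside the 1st/99th percentiles — ≈2% false flags by
construction); hub genes by within-module connectivity against 100
link-weight permutations of the whole planar network, BH-adjusted, hubs at
adjusted p < 0.05; eigengenes as the first principal component of the
standardized module submatrix, sign-aligned to positive mean member
correlation, with module membership the network-wide gene–eigengene
correlation. Module preservation is a simplified composite Z — the mean of
a density Z (observed within-module mean |r| in the test data vs random
same-size sets) and a connectivity Z (Spearman correlation of intramodular
connectivity between datasets vs a random-gene null) — with an empirical
p, Bonferroni-adjusted, and min-max scaling for display. This score is
*not* numerically comparable to the classical Zsummary statistic.

## Cross-region comparison (`region_comparison`)

Top-n gene lists (default 250) per region and direction are ordered by p
with ties broken by |logFC| then gene id; overlap significance is the
upper-tail hypergeometric p over the shared tested universe, reported as
−log10 p. Preranked GSEA ranks genes by statistic descending, uses the
weighted Kolmogorov-Smirnov running sum (hit increments ∝ |stat|, miss
increments uniform), builds the null from random same-size gene sets
(default 2000 permutations, shared across sets of equal size), computes
NES as ES over the mean |null ES| of matching sign and p from the
matching-sign tail with a +1 pseudocount (the convention that keeps null
p-values uniform), BH-adjusts across sets, reports at adjusted p < 0.2,
and prunes redundant sets greedily at Jaccard 0.75.

## Inter-region correlation (`interregion`)

Per region, the 500 most variable genes by variance-mean ratio of non-log
expression across birds (zero-mean genes excluded); per gene and region
pair, Pearson r of per-bird estimates across birds present in both (≥ 4
birds). Significance uses a shuffled-bird null: one region's bird labels
are permuted 100 times, breaking exactly the cross-region pairing while
preserving both marginals; genes outside the 2.5/97.5 percentiles are
flagged, and per-pair flag counts are z-scored across pairs. Correlation
patterns over the four anatomically connected pairs (HVC–RA, LMAN–RA,
HVC–X, LMAN–X) are clustered by seeded k-means into 8 clusters.
Differential correlation computes Δ = |r_deaf| − |r_hearing| per gene and
pair against a within-condition bird-permutation null (100 shuffles);
genes below the 2.5% quantile are "decorrelated", above the 97.5%
"gained". With 100 shuffles the interpolated extreme quantiles are
slightly anticonservative (null flag rates ~5–7% rather than exactly 5%);
this matches the 100-shuffle design and is visible in the calibration
outputs.

## Cell types (`celltype`)

Specificity of gene *g* for cluster *n* is S[n,g] = x_n·ln(K·x_n) with x
the cluster-normalized profile and 0·ln 0 = 0; the per-gene scalar (row
sum) is the KL divergence from the uniform profile — ln K for one-hot, 0
for uniform, and equal to ln K minus the profile's Shannon entropy.
Natural logarithm throughout. Condition scores select differential genes
(adjusted p < 0.1, capped at the 50 smallest p per direction), split by
coefficient sign, and form the dot product S · logFC per cell type. The
null band (1st/99th percentiles of 100 random same-size sets) draws from
the **same-sign** gene pool: the observed set is sign-conditioned, and an
unconditioned null is mis-centered (≈14% false flags instead of the ≈2%
the band implies). Marker abundance tests compare each type's median
marker logFC with medians of random same-size gene sets.

## Pipeline and problem sizes

`run_pipeline` executes the synthetic study end-to-end in dependency order
and writes tidy TSVs plus per-stage manifests (stage, seed, config hash).
The demo defaults are scaled for interactive use (1,200 genes, 300
syllables per side, 5 Song D_KL replicates). The acceptance script and
test suite use the sizes at which each guarantee is stated: 600 syllables
per side and 10 replicates for the Song D_KL null; 6–10 birds per drift
rung; 1,500 embedded syllables per day for the density limits; 2,000
genes × 12 birds per condition for effect recovery; 20 birds per condition
for decorrelation power. These sizes are the package's chosen study
conditions and are printed alongside every acceptance value.

## Known limitations

- The Song D_KL absolute scale depends on the PSD normalization, the
  reference-set size, and the variance floor; values are comparable within
  a configuration, not across configurations (and not to values computed
  by other implementations on real recordings).
- The consensus-correlation approximation (averaging technical sections)
  discards within-cell replication information; SEs are conservative for
  designs with many sections per cell.
- Module preservation and module detection are substitutable engines:
  results depend on the resolution ladder, and module identifiers are not
  stable across datasets.
- The mixed model for FF CV uses bird-level random intercepts; with very
  few birds the Wald p-value is approximate.
- 100-shuffle quantile nulls (the study's own design) carry ~1–2 points of
  anticonservatism at the 5% level, as quantified in the calibration
  outputs.
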