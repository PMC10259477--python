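# songcircuit

Analysis pipeline linking the destabilization of learned birdsong to
gene-expression change across the song-control circuit. Adult songbirds
(e.g. Bengalese finches) use auditory feedback to keep their song stable;
removing feedback by deafening causes the song to drift over days. This
package implements the statistics used to quantify that drift from audio,
and the transcriptomic analyses that relate it to expression measured in
the song nuclei (HVC, RA, LMAN, Area X) and their adjacent comparator
regions — exercised end-to-end on synthetic data with planted ground truth,
or on user-supplied WAV audio and count matrices.

## What it computes

**Song change from audio**

- *Song D_KL* — syllables are segmented by amplitude threshold, reduced to
  mean power spectral densities (512-sample windows, max-normalized), and
  described by their Euclidean distances to 50 reference syllables.
  Diagonal-covariance Gaussian mixtures (5–12 components, BIC second-
  difference selection) are fitted to the pre- and post-manipulation
  distance distributions, and

  D_KL = E_x [ log2 L_pre(x) − log2 L_post(x) ]

  over held-out pre syllables, averaged over 10 reference resamplings — a
  Monte-Carlo estimate of the KL divergence between the pre and post
  syllable distributions. Near 0 for unchanged song, increasingly positive
  with drift.
- *UMAP density difference* — per-syllable 16×16 mel-spectrogram features,
  PCA to 10 components, 2-D UMAP; per-day kernel densities on a 200×200
  grid; the per-day statistic sums the positive part of (day − baseline)
  density, area-normalized to [0, 1].
- *FF variability* — fundamental frequency per rendition (interpolated
  1024-sample spectrum at 1 Hz resolution), rolling coefficient of
  variation over 11 renditions, and a mixed model (period fixed effect,
  syllable nested in bird) for the percent change from baseline.

**Expression modeling** — gene filtering (total counts < n_samples/8),
CDR-based sample QC, TMMwsp normalization, log2-CPM, observation-level
precision weights from a lowess mean-variance trend, per-gene weighted
least squares with empirical-Bayes variance moderation, BH-adjusted
moderated t statistics, signed −log10(p) DEG scores per region, and
per-bird-region expression estimates with moderated standard errors.

**Downstream structure** — planar filtered coexpression networks with
permutation-FDR edge selection and multiresolution modules tested against
random-gene nulls (module means, hub connectivity, eigengenes,
preservation); hypergeometric overlap of top gene lists across regions;
permutation preranked GSEA; across-bird inter-region correlation with
shuffled-bird nulls, 8-cluster correlation patterns, and permutation tests
for deafening-associated loss or gain of inter-region correlation; cell-type
specificity scores S[n,g] = x_n ln(K·x_n) (ln K for a one-hot gene, 0 for
uniform) combined with fold-changes into cell-type condition scores.

The `simulate` module generates all of this synthetically: harmonic-stack
song with configurable post-manipulation drift, and negative-binomial
3'-tag count matrices (8 regions × 18 birds, 2–6 technical sections per
bird-region) with planted covariate effects and latent factors coupling
regions within birds.

## Worked example

```python
from songcircuit.simulate import SongSimConfig
from songcircuit.pipeline import collect_psds
from songcircuit.song_divergence import song_dkl

cfg = SongSimConfig(seed=1, songs_per_day=100, drift_magnitude=0.004)
pre = collect_psds(cfg, bird=0, days=[-2, -1], condition="deaf",
                   max_syllables=600)
post = collect_psds(cfg, bird=0, days=[13, 14], condition="deaf",
                    max_syllables=600)
res = song_dkl(pre, post, seed=0)
print(f"Song D_KL = {res.mean_dkl:.3f}  (components: {res.n_components})")
```

prints

```
Song D_KL = 14.614  (components: [6, 6, 7, 7, 7, 6, 6, 6, 7, 7])
```

a strongly positive divergence: after 14 days at 0.4%/day fundamental-
frequency drift, post syllables sit far from the pre-song mixture, so the
pre model assigns held-out pre syllables ~15 bits more likelihood than the
post model does. Rerunning with `drift_magnitude=0.0` gives a value near 0
(|D_KL| < 0.2). The selected component counts sit at the seven planted
syllable types (occasionally merging the two closest).

The full synthetic workflow (song → expression → networks → inter-region →
cell types) runs from the command line:

```bash
songcircuit demo --outdir demo_out --seed 1
```

and writes tidy TSV tables plus a per-stage manifest (seed, config hash)
under `demo_out/`.

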