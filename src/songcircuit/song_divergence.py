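"""Song-change statistics: GMM-based Song D_KL and the UMAP
kernel-density-difference statistic.

Song D_KL models the distribution of syllable-to-reference spectral distances
before and after a manipulation with Gaussian mixtures and reports the mean
held-out log2-likelihood difference — a Monte-Carlo estimate of the KL
divergence between the pre and post syllable distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

__all__ = [
    "MixtureModel",
    "SongDKLResult",
    "select_k_from_bic",
    "fit_song_gmm",
    "song_dkl",
    "embed_syllables",
    "density_change_statistic",
    "group_daywise_test",
]


@dataclass
class MixtureModel:
    """A fitted diagonal-covariance Gaussian mixture with its BIC trace."""

    model: GaussianMixture
    n_components: int
    bic_by_k: dict[int, float]

    def log2_likelihood(self, X: np.ndarray) -> np.ndarray:
        """Per-sample log2 density under the mixture."""
        return self.model.score_samples(X) / np.log(2)


@dataclass
class SongDKLResult:
    """Replicate-level and mean Song D_KL estimates for one bird."""

    replicates: list[float]
    mean_dkl: float
    n_components: list[int]
    n_train_pre: int
    n_heldout_pre: int
    n_train_post: int
    literal_dkl: float | None = None
    extra: dict = field(default_factory=dict)


def select_k_from_bic(bic_by_k: dict[int, float]) -> int:
    """Component count minimizing the second-order BIC difference.

    BIC here follows the higher-is-better convention (2 log L minus the
    complexity penalty). For consecutive fitted k the second difference
    d2(k) = BIC(k+1) - 2 BIC(k) + BIC(k-1) is evaluated at interior k; the k
    with minimal d2 is returned, ties broken toward smaller k.
    """
    ks = sorted(bic_by_k)
    if len(ks) < 3:
        return ks[int(np.argmax([bic_by_k[k] for k in ks]))]
    best_k, best_d2 = None, np.inf
    for i in range(1, len(ks) - 1):
        if ks[i - 1] + 1 != ks[i] or ks[i] + 1 != ks[i + 1]:
            continue
        d2 = (
            bic_by_k[ks[i + 1]] - 2 * bic_by_k[ks[i]] + bic_by_k[ks[i - 1]]
        )
        if d2 < best_d2:  # strict: ties keep the smaller k
            best_d2, best_k = d2, ks[i]
    if best_k is None:
        return ks[int(np.argmax([bic_by_k[k] for k in ks]))]
    return best_k


def fit_song_gmm(
    train_distances: np.ndarray,
    k_range: tuple[int, int] = (5, 12),
    seed: int = 0,
    n_components: int | None = None,
    reg_covar: float = 0.1,
    n_init: int = 3,
) -> MixtureModel:
    """Fit diagonal-covariance GMMs over a component-count ladder and select
    by minimal second-order BIC difference.

    ``train_distances`` is a syllable x reference distance matrix. When
    ``n_components`` is given the selection is skipped and that k is fit
    directly (used for the post model, which reuses the pre model's k).
    """
    X = np.asarray(train_distances, dtype=float)
    k_lo, k_hi = k_range
    if n_components is None and X.shape[0] < k_hi + 1:
        raise ValueError(
            f"need >= {k_hi + 1} training rows for selection, got {X.shape[0]}"
        )

    def _fit(k: int) -> GaussianMixture:
        return GaussianMixture(
            n_components=k,
            covariance_type="diag",
            n_init=n_init,
            max_iter=200,
            reg_covar=reg_covar,
            random_state=seed,
        ).fit(X)

    if n_components is not None:
        gm = _fit(n_components)
        return MixtureModel(
            model=gm,
            n_components=n_components,
            bic_by_k={n_components: -gm.bic(X)},
        )

    bic_by_k: dict[int, float] = {}
    models: dict[int, GaussianMixture] = {}
    for k in range(k_lo, k_hi + 1):
        try:
            gm = _fit(k)
        except Exception as err:  # non-convergence at this k
            warnings.warn(f"GMM with k={k} failed ({err}); skipped")
            continue
        models[k] = gm
        bic_by_k[k] = -gm.bic(X)  # higher-is-better convention
    if not models:
        raise RuntimeError("all mixture fits failed")
    k_sel = select_k_from_bic(bic_by_k)
    return MixtureModel(model=models[k_sel], n_components=k_sel, bic_by_k=bic_by_k)


def _distances(psds: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Euclidean distances from each PSD row to each reference PSD."""
    from scipy.spatial.distance import cdist

    return cdist(psds, refs, metric="euclidean")


def song_dkl(
    pre_psds: np.ndarray,
    post_psds: np.ndarray,
    n_refs: int = 50,
    n_train: int = 500,
    n_reps: int = 10,
    seed: int = 0,
    k_range: tuple[int, int] = (5, 12),
    literal_formula: bool = False,
    reg_covar: float = 0.1,
) -> SongDKLResult:
    """Song D_KL between pre- and post-manipulation syllable PSD sets.

    Per replicate: sample ``n_refs`` reference PSDs from the pre training
    split; form distance matrices for pre-train, pre-held-out and post-train
    (the reference rows themselves are excluded from the fitted matrices —
    their zero self-distances would otherwise bias the pre fit); fit the pre
    mixture (BIC-selected k) and the post mixture at the same k, the post
    fit warm-started from the pre model's parameters so both fits occupy the
    same EM optimum and likelihood differences reflect distributional change
    rather than initialization noise. The replicate value is the mean over
    held-out pre syllables of log2 L_pre(x) - log2 L_post(x); Song D_KL is
    the replicate mean.

    ``reg_covar`` is the per-dimension variance floor of the mixtures, on
    the squared-distance scale of max-normalized PSDs.

    ``literal_formula`` additionally evaluates log2(L1_bar - L2_bar) on the
    replicate-averaged per-syllable likelihoods (NaN where the difference is
    non-positive).
    """
    pre = np.asarray(pre_psds, dtype=float)
    post = np.asarray(post_psds, dtype=float)
    k_hi = k_range[1]
    if post.shape[0] < k_hi + 1:
        raise ValueError(
            f"need >= {k_hi + 1} post syllables, got {post.shape[0]}"
        )
    rng = np.random.default_rng(seed)

    if pre.shape[0] >= n_train + k_hi + 1:
        nt = n_train
    else:
        nt = int(0.7 * pre.shape[0])
        warnings.warn(
            f"only {pre.shape[0]} pre syllables; using a 70/30 split ({nt} train)"
        )
    if nt < n_refs:
        raise ValueError("training split smaller than n_refs")
    perm = rng.permutation(pre.shape[0])
    pre_train = pre[perm[:nt]]
    pre_held = pre[perm[nt:]]
    if pre_held.shape[0] == 0:
        raise ValueError("no held-out pre syllables")
    n_post_train = min(post.shape[0], n_train)
    post_train = post[rng.permutation(post.shape[0])[:n_post_train]]

    reps, ks = [], []
    l1_acc = np.zeros(pre_held.shape[0])
    l2_acc = np.zeros(pre_held.shape[0])
    for r in range(n_reps):
        ref_idx = rng.choice(pre_train.shape[0], size=n_refs, replace=False)
        refs = pre_train[ref_idx]
        fit_rows = np.setdiff1d(np.arange(pre_train.shape[0]), ref_idx)
        n_fit = len(fit_rows)
        post_rows = rng.choice(
            post_train.shape[0], size=min(post_train.shape[0], n_fit), replace=False
        )
        d_pre_train = _distances(pre_train[fit_rows], refs)
        d_pre_held = _distances(pre_held, refs)
        d_post_train = _distances(post_train[post_rows], refs)
        pre_gmm = fit_song_gmm(
            d_pre_train, k_range=k_range, seed=seed + r, reg_covar=reg_covar
        )
        m = pre_gmm.model
        post_model = GaussianMixture(
            n_components=pre_gmm.n_components,
            covariance_type="diag",
            reg_covar=reg_covar,
            weights_init=m.weights_,
            means_init=m.means_,
            precisions_init=1.0 / m.covariances_,
            n_init=1,
            max_iter=200,
            random_state=seed + r,
        ).fit(d_post_train)
        ll_pre = pre_gmm.log2_likelihood(d_pre_held)
        ll_post = post_model.score_samples(d_pre_held) / np.log(2)
        reps.append(float(np.mean(ll_pre - ll_post)))
        ks.append(pre_gmm.n_components)
        if literal_formula:
            l1_acc += np.exp2(ll_pre)
            l2_acc += np.exp2(ll_post)

    literal = None
    if literal_formula:
        diff = l1_acc / n_reps - l2_acc / n_reps
        with np.errstate(invalid="ignore", divide="ignore"):
            per_syl = np.where(diff > 0, np.log2(np.maximum(diff, 1e-300)), np.nan)
        literal = float(np.nanmean(per_syl)) if np.isfinite(per_syl).any() else None

    return SongDKLResult(
        replicates=reps,
        mean_dkl=float(np.mean(reps)),
        n_components=ks,
        n_train_pre=pre_train.shape[0],
        n_heldout_pre=pre_held.shape[0],
        n_train_post=post_train.shape[0],
        literal_dkl=literal,
    )


def embed_syllables(
    features: np.ndarray,
    n_pcs: int = 10,
    seed: int = 0,
    **umap_kwargs,
) -> np.ndarray:
    """PCA to ``n_pcs`` components followed by a seeded 2-D UMAP embedding."""
    import umap

    X = np.asarray(features, dtype=float)
    if X.shape[0] < n_pcs + 1:
        raise ValueError(f"need at least {n_pcs + 1} syllables")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("features are constant; nothing to embed")
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    reducer = umap.UMAP(n_components=2, random_state=seed, **umap_kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return reducer.fit_transform(pcs)


def _nrd_bandwidth(v: np.ndarray) -> float:
    """Normal-reference (Silverman) bandwidth for one axis."""
    n = len(v)
    sd = np.std(v, ddof=1)
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        scale = max(np.abs(v).max(), 1.0) * 1e-3
    return 1.06 * scale * n ** (-1 / 5)


def _kde2d(
    pts: np.ndarray, gx: np.ndarray, gy: np.ndarray, hx: float, hy: float
) -> np.ndarray:
    """Axis-aligned product-Gaussian KDE on a rectangular grid."""
    kx = np.exp(-0.5 * ((gx[:, None] - pts[None, :, 0]) / hx) ** 2) / (
        hx * np.sqrt(2 * np.pi)
    )
    ky = np.exp(-0.5 * ((gy[:, None] - pts[None, :, 1]) / hy) ** 2) / (
        hy * np.sqrt(2 * np.pi)
    )
    return kx @ ky.T / pts.shape[0]  # (len(gx), len(gy))


def density_change_statistic(
    coords_by_day: dict[int, np.ndarray],
    baseline_days: list[int],
    grid: int = 200,
    min_points: int = 5,
    pad: float = 0.05,
) -> pd.DataFrame:
    """Per-day summed positive density difference from the baseline embedding.

    All days share one bounding box (data range padded by ``pad``). The
    baseline density is the mean KDE over ``baseline_days``; each day's raw
    statistic is the grid sum of max(density - baseline, 0), and the
    normalized variant multiplies by the grid-cell area (so a fully displaced
    day approaches 1). Days with fewer than ``min_points`` points are
    reported as NaN.

    The kernel bandwidth is set per axis by the normal-reference rule on the
    pooled baseline-day points and shared across all days, so every day's
    density is smoothed at the baseline's spatial scale and days with
    displaced point clouds are not over-smoothed.
    """
    if not baseline_days:
        raise ValueError("baseline_days must be nonempty")
    missing = [d for d in baseline_days if d not in coords_by_day]
    if missing:
        raise ValueError(f"baseline days absent from coords: {missing}")
    all_pts = np.vstack([np.asarray(c) for c in coords_by_day.values()])
    lo = all_pts.min(axis=0)
    hi = all_pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    lo -= pad * span
    hi += pad * span
    gx = np.linspace(lo[0], hi[0], grid)
    gy = np.linspace(lo[1], hi[1], grid)
    cell_area = (gx[1] - gx[0]) * (gy[1] - gy[0])
    base_pts = np.vstack([np.asarray(coords_by_day[d]) for d in baseline_days])
    hx = _nrd_bandwidth(base_pts[:, 0])
    hy = _nrd_bandwidth(base_pts[:, 1])

    densities: dict[int, np.ndarray | None] = {}
    for day, pts in coords_by_day.items():
        pts = np.asarray(pts, dtype=float)
        if pts.shape[0] < min_points:
            warnings.warn(f"day {day}: fewer than {min_points} points; omitted")
            densities[day] = None
        else:
            densities[day] = _kde2d(pts, gx, gy, hx, hy)

    base_stack = [densities[d] for d in baseline_days if densities[d] is not None]
    if not base_stack:
        raise ValueError("no baseline day has enough points")
    baseline = np.mean(base_stack, axis=0)

    rows = []
    for day in sorted(coords_by_day):
        d = densities[day]
        if d is None:
            rows.append({"day": day, "raw": np.nan, "normalized": np.nan})
            continue
        pos = np.clip(d - baseline, 0, None).sum()
        rows.append(
            {"day": day, "raw": float(pos), "normalized": float(pos * cell_area)}
        )
    return pd.DataFrame(rows).set_index("day")


def group_daywise_test(stats_table: pd.DataFrame) -> pd.DataFrame:
    """Two-sided two-sample t-test of bird-level statistics per day.

    ``stats_table`` needs columns ``day``, ``condition`` (two levels) and
    ``value``. Days where either group has fewer than two birds are skipped
    with a warning. Flags days at p < 0.05 (unadjusted).
    """
    req = {"day", "condition", "value"}
    if not req.issubset(stats_table.columns):
        raise ValueError(f"stats_table must have columns {sorted(req)}")
    groups = sorted(stats_table["condition"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two conditions required")
    rows = []
    for day, grp in stats_table.groupby("day"):
        a = grp.loc[grp["condition"] == groups[0], "value"].dropna().to_numpy()
        b = grp.loc[grp["condition"] == groups[1], "value"].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"day {day}: a group has n < 2; skipped")
            continue
        if a.std() == 0 and b.std() == 0:
            p = 1.0 if a.mean() == b.mean() else np.finfo(float).tiny
        else:
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        rows.append({"day": day, "p": p, "flagged": p < 0.05})
    if not rows:
        return pd.DataFrame(columns=["p", "flagged"], index=pd.Index([], name="day"))
    return pd.DataFrame(rows).set_index("day")
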