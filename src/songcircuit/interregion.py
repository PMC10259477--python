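"""Across-bird gene-expression correlation between brain regions: variable
gene selection, pairwise correlation with shuffled-bird nulls, correlation
pattern clustering, and condition-dependent gain/loss of correlation.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "variable_genes_vmr",
    "region_pair_correlations",
    "shuffle_significance",
    "cluster_correlation_patterns",
    "differential_correlation",
]

#: The anatomically connected song-system pairs of the 8-cluster analysis.
CONNECTED_PAIRS = (("HVC", "RA"), ("LMAN", "RA"), ("HVC", "X"), ("LMAN", "X"))


def variable_genes_vmr(
    expr_by_region: dict[str, pd.DataFrame], n: int = 500
) -> dict[str, list[str]]:
    """Top-n genes per region by variance-mean ratio of non-log expression.

    ``expr_by_region`` maps region -> genes x birds non-log expression.
    Genes with zero mean have undefined VMR and are excluded.
    """
    out = {}
    for region, expr in expr_by_region.items():
        if expr.shape[1] < 2:
            raise ValueError(f"region {region}: need >= 2 birds")
        mean = expr.mean(axis=1)
        var = expr.var(axis=1, ddof=1)
        ok = mean > 0
        vmr = (var[ok] / mean[ok]).sort_values(ascending=False, kind="stable")
        out[region] = list(vmr.index[: min(n, len(vmr))])
    return out


def _pair_frame(
    estimates: pd.DataFrame, region_a: str, region_b: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align bird columns of two regions from a gene x (bird|region) matrix."""
    cols = estimates.columns
    birds_a = {c.split("|")[0] for c in cols if c.endswith(f"|{region_a}")}
    birds_b = {c.split("|")[0] for c in cols if c.endswith(f"|{region_b}")}
    shared = sorted(birds_a & birds_b)
    A = estimates[[f"{b}|{region_a}" for b in shared]]
    B = estimates[[f"{b}|{region_b}" for b in shared]]
    A.columns = B.columns = shared
    return A, B


def _rowwise_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between matched rows of A and B (NaN for constant rows)."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    num = (A * B).sum(axis=1)
    den = np.sqrt((A**2).sum(axis=1) * (B**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def region_pair_correlations(
    estimates: pd.DataFrame,
    genes: list[str] | None = None,
    regions: list[str] | None = None,
    min_birds: int = 4,
) -> pd.DataFrame:
    """Across-bird Pearson correlation per gene for every region pair.

    ``estimates`` is genes x (bird|region) expression estimates. Pairs with
    fewer than ``min_birds`` shared birds are skipped. Returns a long table
    (gene, region_a, region_b, r, n_birds).
    """
    if regions is None:
        regions = sorted({c.split("|")[1] for c in estimates.columns})
    if genes is not None:
        estimates = estimates.loc[[g for g in genes if g in estimates.index]]
    rows = []
    for ra, rb in combinations(regions, 2):
        A, B = _pair_frame(estimates, ra, rb)
        if A.shape[1] < min_birds:
            warnings.warn(f"pair ({ra}, {rb}): fewer than {min_birds} shared birds")
            continue
        r = _rowwise_corr(A.to_numpy(dtype=float), B.to_numpy(dtype=float))
        rows.append(
            pd.DataFrame(
                {
                    "gene": estimates.index,
                    "region_a": ra,
                    "region_b": rb,
                    "r": r,
                    "n_birds": A.shape[1],
                }
            )
        )
    if not rows:
        raise ValueError("no region pair has enough shared birds")
    return pd.concat(rows, ignore_index=True)


def shuffle_significance(
    estimates: pd.DataFrame,
    correlations: pd.DataFrame,
    n_shuffle: int = 100,
    quantiles: tuple[float, float] = (2.5, 97.5),
    seed: int = 0,
    exclude_pairs: list[tuple[str, str]] | None = None,
) -> dict:
    """Flag gene-level correlations against a shuffled-bird null, per pair.

    For each region pair, bird labels of one region's expression vector are
    permuted ``n_shuffle`` times and correlations recomputed; genes outside
    the (2.5, 97.5) percent null quantiles are flagged. Per-pair significant
    counts are Z-scored across pairs (optionally excluding listed pairs).

    Returns {"flags": long table, "pair_counts": table with z-scores}.
    """
    rng = np.random.default_rng(seed)
    flag_frames = []
    counts = []
    for (ra, rb), sub in correlations.groupby(["region_a", "region_b"], sort=True):
        A, B = _pair_frame(estimates.loc[sub["gene"]], ra, rb)
        Av, Bv = A.to_numpy(dtype=float), B.to_numpy(dtype=float)
        null = np.empty((n_shuffle, len(sub)))
        for i in range(n_shuffle):
            null[i] = _rowwise_corr(Av, Bv[:, rng.permutation(Bv.shape[1])])
        lo = np.nanpercentile(null, quantiles[0], axis=0)
        hi = np.nanpercentile(null, quantiles[1], axis=0)
        r = sub["r"].to_numpy()
        flagged = (r < lo) | (r > hi)
        frame = sub.copy()
        frame["null_lo"] = lo
        frame["null_hi"] = hi
        frame["flagged"] = flagged & np.isfinite(r)
        flag_frames.append(frame)
        counts.append(
            {
                "region_a": ra,
                "region_b": rb,
                "n_flagged": int(frame["flagged"].sum()),
                "n_genes": len(frame),
            }
        )
    flags = pd.concat(flag_frames, ignore_index=True)
    pair_counts = pd.DataFrame(counts)
    mask = np.ones(len(pair_counts), dtype=bool)
    if exclude_pairs:
        ex = {tuple(sorted(p)) for p in exclude_pairs}
        mask = ~pair_counts.apply(
            lambda row: tuple(sorted((row["region_a"], row["region_b"]))) in ex,
            axis=1,
        ).to_numpy()
    vals = pair_counts.loc[mask, "n_flagged"].to_numpy(dtype=float)
    z = np.full(len(pair_counts), np.nan)
    if mask.sum() > 1 and vals.std(ddof=0) > 0:
        z[mask] = (vals - vals.mean()) / vals.std(ddof=0)
    pair_counts["z"] = z
    return {"flags": flags, "pair_counts": pair_counts}


def cluster_correlation_patterns(
    correlations: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] = CONNECTED_PAIRS,
    k: int = 8,
    seed: int = 0,
) -> dict:
    """K-means clustering of per-gene correlation patterns over region pairs.

    Builds the gene x pair matrix of correlations for the given pairs
    (genes present in all pairs), clusters with seeded k-means, and returns
    assignments plus the mean pattern and size per cluster.
    """
    from sklearn.cluster import KMeans

    cols = {}
    for ra, rb in pairs:
        sub = correlations[
            (correlations["region_a"].isin([ra, rb]))
            & (correlations["region_b"].isin([ra, rb]))
        ]
        cols[f"{ra}-{rb}"] = sub.set_index("gene")["r"]
    mat = pd.DataFrame(cols).dropna()
    if k > len(mat):
        raise ValueError(f"k={k} exceeds {len(mat)} genes with complete patterns")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(mat.to_numpy())
    assign = pd.Series(km.labels_, index=mat.index, name="cluster")
    centers = pd.DataFrame(km.cluster_centers_, columns=mat.columns)
    centers["size"] = assign.value_counts().reindex(range(k)).fillna(0).astype(int)
    return {"assignments": assign, "patterns": centers, "matrix": mat}


def differential_correlation(
    estimates_hearing: pd.DataFrame,
    estimates_deaf: pd.DataFrame,
    genes: list[str] | None = None,
    regions: list[str] | None = None,
    n_perm: int = 100,
    quantiles: tuple[float, float] = (2.5, 97.5),
    seed: int = 0,
    min_birds: int = 4,
) -> pd.DataFrame:
    """Deafening-associated gain or loss of inter-region correlation.

    Per gene and pair, the statistic is |r_deaf| - |r_hearing|. The null
    permutes bird identities within each condition (breaking the
    cross-region pairing while preserving marginals) ``n_perm`` times; genes
    below the lower null quantile are flagged "decorrelated" and above the
    upper "gained". Genes constant in either condition are excluded.
    """
    rng = np.random.default_rng(seed)
    if regions is None:
        regions = sorted(
            {c.split("|")[1] for c in estimates_hearing.columns}
            & {c.split("|")[1] for c in estimates_deaf.columns}
        )
    if genes is not None:
        estimates_hearing = estimates_hearing.loc[genes]
        estimates_deaf = estimates_deaf.loc[genes]
    rows = []
    for ra, rb in combinations(regions, 2):
        Ah, Bh = _pair_frame(estimates_hearing, ra, rb)
        Ad, Bd = _pair_frame(estimates_deaf, ra, rb)
        if Ah.shape[1] < min_birds or Ad.shape[1] < min_birds:
            warnings.warn(f"pair ({ra}, {rb}): fewer than {min_birds} birds; skipped")
            continue
        Ahv, Bhv = Ah.to_numpy(dtype=float), Bh.to_numpy(dtype=float)
        Adv, Bdv = Ad.to_numpy(dtype=float), Bd.to_numpy(dtype=float)
        r_h = _rowwise_corr(Ahv, Bhv)
        r_d = _rowwise_corr(Adv, Bdv)
        delta = np.abs(r_d) - np.abs(r_h)
        null = np.empty((n_perm, len(delta)))
        for i in range(n_perm):
            rh = _rowwise_corr(Ahv, Bhv[:, rng.permutation(Bhv.shape[1])])
            rd = _rowwise_corr(Adv, Bdv[:, rng.permutation(Bdv.shape[1])])
            null[i] = np.abs(rd) - np.abs(rh)
        lo = np.nanpercentile(null, quantiles[0], axis=0)
        hi = np.nanpercentile(null, quantiles[1], axis=0)
        valid = np.isfinite(delta)
        flag = np.where(
            ~valid, "excluded", np.where(delta < lo, "decorrelated",
                                         np.where(delta > hi, "gained", "none"))
        )
        rows.append(
            pd.DataFrame(
                {
                    "gene": estimates_hearing.index,
                    "region_a": ra,
                    "region_b": rb,
                    "r_hearing": r_h,
                    "r_deaf": r_d,
                    "delta_abs_r": delta,
                    "null_lo": lo,
                    "null_hi": hi,
                    "flag": flag,
                }
            )
        )
    if not rows:
        raise ValueError("no region pair has enough birds in both conditions")
    return pd.concat(rows, ignore_index=True)
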