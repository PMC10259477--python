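"""Cell-type specificity scoring of bulk differential-expression changes.

The specificity of gene *g* for cluster *n* is S[n, g] = x_n * ln(x_n / x̄)
where x_n is the cluster-mean expression normalized to sum 1 across the K
clusters and x̄ = 1/K is the uniform reference; the per-gene scalar score
(the row sum over clusters) is the KL divergence of the gene's profile from
uniform: 0 for a uniform gene and ln K for a one-hot gene.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .expression import DEResult

__all__ = [
    "specificity_matrix",
    "specificity_scores",
    "scale_specificity_display",
    "celltype_condition_score",
    "marker_abundance_test",
]


def specificity_matrix(cluster_expr: pd.DataFrame) -> pd.DataFrame:
    """Celltype x gene specificity contributions S[n, g] = x_n ln(K x_n).

    ``cluster_expr`` holds nonnegative cluster-mean expression (celltypes x
    genes). Genes with zero total expression have undefined specificity and
    are returned as NaN columns with a warning. 0 * ln 0 is taken as 0.
    """
    X = cluster_expr.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("cluster expression must be nonnegative")
    K = X.shape[0]
    totals = X.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} genes have zero total expression; scores undefined"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        xn = X / totals
        S = np.where(xn > 0, xn * np.log(xn * K), 0.0)
    S[:, zero] = np.nan
    return pd.DataFrame(S, index=cluster_expr.index, columns=cluster_expr.columns)


def specificity_scores(S: pd.DataFrame) -> pd.Series:
    """Per-gene scalar specificity: the column sum of S, in [0, ln K]."""
    return S.sum(axis=0, skipna=False).rename("specificity")


def scale_specificity_display(S: pd.DataFrame) -> pd.DataFrame:
    """Per-gene min-max scaling of specificity contributions to [0, 1]."""
    lo = S.min(axis=0)
    hi = S.max(axis=0)
    span = (hi - lo).replace(0, np.nan)
    return (S - lo) / span


def celltype_condition_score(
    S: pd.DataFrame,
    de: DEResult,
    contrast: str,
    top_n: int = 50,
    n_null: int = 100,
    seed: int = 0,
    adj_p_threshold: float = 0.1,
    quantiles: tuple[float, float] = (1.0, 99.0),
    use_scalar: bool = False,
) -> pd.DataFrame:
    """Cell-type-resolved score of a condition contrast's expression change.

    Differential genes (adjusted p below threshold, capped at the ``top_n``
    smallest p) are split by coefficient sign; per cell type and direction
    the score is sum_g S[n, g] * logFC_g (the dot product of the specificity
    matrix with the fold-change vector). The null band is the 1st/99th
    percentile of scores from ``n_null`` random same-size gene sets drawn
    from the same-sign universe (so the band reflects the sign conditioning
    of the observed set); observations outside the band are flagged.
    A direction with no differential genes reports zero scores, unflagged.
    """
    rng = np.random.default_rng(seed)
    tab = de.contrast(contrast)
    universe = [g for g in tab.index if g in S.columns]
    tab = tab.loc[universe]
    Smat = S[universe]
    if use_scalar:
        Smat = pd.DataFrame(
            specificity_scores(Smat).to_frame().T.to_numpy(),
            index=["scalar"],
            columns=universe,
        )
    rows = []
    for direction, sign in (("up", 1), ("down", -1)):
        same_sign = tab[np.sign(tab["logFC"]) == sign]
        sel = same_sign[same_sign["adj_p"] < adj_p_threshold].sort_values(
            "p", kind="stable"
        )
        if len(sel) == 0:
            for ct in Smat.index:
                rows.append(
                    {"celltype": ct, "direction": direction, "score": 0.0,
                     "null_lo": np.nan, "null_hi": np.nan, "flagged": False,
                     "n_genes": 0}
                )
            continue
        if len(sel) < top_n:
            warnings.warn(
                f"{direction}: only {len(sel)} differential genes (cap {top_n})"
            )
        sel = sel.iloc[:top_n]
        genes = list(sel.index)
        lfc = sel["logFC"]
        obs = Smat[genes].to_numpy() @ lfc.to_numpy()
        pool = list(same_sign.index)
        pool_lfc = same_sign["logFC"]
        null = np.empty((n_null, Smat.shape[0]))
        for i in range(n_null):
            idx = rng.choice(
                len(pool), size=len(genes), replace=len(pool) < len(genes)
            )
            rg = [pool[j] for j in idx]
            null[i] = Smat[rg].to_numpy() @ pool_lfc.loc[rg].to_numpy()
        lo = np.percentile(null, quantiles[0], axis=0)
        hi = np.percentile(null, quantiles[1], axis=0)
        for n_i, ct in enumerate(Smat.index):
            rows.append(
                {
                    "celltype": ct,
                    "direction": direction,
                    "score": float(obs[n_i]),
                    "null_lo": float(lo[n_i]),
                    "null_hi": float(hi[n_i]),
                    "flagged": bool(obs[n_i] < lo[n_i] or obs[n_i] > hi[n_i]),
                    "n_genes": len(genes),
                }
            )
    return pd.DataFrame(rows)


def marker_abundance_test(
    marker_map: dict[str, list[str]],
    de: DEResult,
    contrast: str,
    n_null: int = 1000,
    seed: int = 0,
    quantiles: tuple[float, float] = (1.0, 99.0),
) -> pd.DataFrame:
    """Median marker fold-change per cell type against a random-gene null.

    For each cell type with >= 3 markers in the DE universe, the observed
    median logFC over markers is compared with medians of random same-size
    gene sets; types outside the 1%/99% null band are flagged.
    """
    rng = np.random.default_rng(seed)
    tab = de.contrast(contrast)
    lfc = tab["logFC"]
    rows = []
    for ct, markers in marker_map.items():
        present = [g for g in markers if g in lfc.index]
        if len(present) < 3:
            warnings.warn(f"celltype {ct}: fewer than 3 markers in universe; skipped")
            continue
        obs = float(lfc.loc[present].median())
        vals = lfc.to_numpy()
        null = np.array(
            [
                np.median(vals[rng.choice(len(vals), len(present), replace=False)])
                for _ in range(n_null)
            ]
        )
        lo, hi = np.percentile(null, quantiles)
        rows.append(
            {
                "celltype": ct,
                "n_markers": len(present),
                "median_logFC": obs,
                "null_lo": float(lo),
                "null_hi": float(hi),
                "flagged": bool(obs < lo or obs > hi),
            }
        )
    return pd.DataFrame(rows)
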