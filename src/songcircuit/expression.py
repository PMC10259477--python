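"""Count filtering, normalization, and moderated linear modeling of 3'-tag
expression data.

The modeling pipeline mirrors the standard limma-voom workflow for sparse
tag counts: trimmed-mean-of-M-values normalization with singleton pairing
(TMMwsp), log2-CPM with a 0.5 pseudocount, observation-level precision
weights from a lowess mean-variance trend, per-gene weighted least squares,
and empirical-Bayes moderation of residual variances against a scaled
inverse-chi-square prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "DesignSpec",
    "DEResult",
    "filter_genes",
    "filter_samples_by_cdr",
    "normalization_factors",
    "log_cpm",
    "benjamini_hochberg",
    "fit_de",
    "deg_score",
    "cap_signed_logp",
    "per_bird_region_estimates",
    "bin_covariate",
]

#: Differential threshold recorded in every result header.
ADJ_P_THRESHOLD = 0.1


def filter_genes(counts: pd.DataFrame) -> pd.DataFrame:
    """Drop lowly expressed genes: total count across samples below
    n_samples / 8 (one-eighth, the number of brain regions assayed)."""
    threshold = counts.shape[1] / 8
    return counts.loc[counts.sum(axis=1) >= threshold]


def filter_samples_by_cdr(
    counts: pd.DataFrame,
    n_annotated: int = 18674,
    min_frac: float = 0.30,
) -> tuple[pd.DataFrame, pd.Series]:
    """Remove samples whose cellular detection rate falls below ``min_frac``.

    CDR is the fraction of the annotated gene universe (default 18,674
    genes) detected (count > 0) in the sample. Samples are retained when
    CDR >= ``min_frac``. Returns the filtered matrix and the per-sample CDR.
    """
    cdr = (counts > 0).sum(axis=0) / n_annotated
    keep = cdr >= min_frac
    if not keep.any():
        raise ValueError(
            f"all {counts.shape[1]} samples fall below CDR {min_frac}; "
            f"max observed CDR = {cdr.max():.3f}"
        )
    return counts.loc[:, keep], cdr


def _tmm_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
    pair_singletons: bool = True,
) -> float:
    """Trimmed mean of M-values of one sample against the reference.

    With ``pair_singletons`` genes detected in only one of the two libraries
    are rank-paired largest-with-largest into pseudo-pairs so their
    information is not discarded (the sparse-safe "wsp" behavior).
    """
    n_obs, n_ref = obs.sum(), ref.sum()
    both = (obs > 0) & (ref > 0)
    o, r = obs[both].astype(float), ref[both].astype(float)
    if pair_singletons:
        only_o = np.sort(obs[(obs > 0) & (ref == 0)])[::-1]
        only_r = np.sort(ref[(ref > 0) & (obs == 0)])[::-1]
        n_pair = min(len(only_o), len(only_r))
        if n_pair:
            o = np.concatenate([o, only_o[:n_pair].astype(float)])
            r = np.concatenate([r, only_r[:n_pair].astype(float)])
    if len(o) == 0:
        warnings.warn("no co-detected genes with reference; factor set to 1")
        return 1.0
    p_o, p_r = o / n_obs, r / n_ref
    M = np.log2(p_o / p_r)
    A = 0.5 * np.log2(p_o * p_r)
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    finite = np.isfinite(M) & np.isfinite(A)
    M, A, w = M[finite], A[finite], w[finite]
    if len(M) == 0:
        return 1.0
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = len(M)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(M)
    rank_a = stats.rankdata(A)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(w[keep] * M[keep]) / np.sum(w[keep])
    return float(2**f)


def normalization_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM normalization factors with singleton pairing.

    The reference sample is the column with the highest library size; factors
    are rescaled to geometric mean 1.
    """
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("every sample must have at least one nonzero gene")
    mat = counts.to_numpy(dtype=float)
    ref_idx = int(np.argmax(mat.sum(axis=0)))
    ref = mat[:, ref_idx]
    factors = np.array(
        [
            _tmm_factor(mat[:, j], ref, logratio_trim, abundance_trim)
            for j in range(mat.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def log_cpm(
    counts: pd.DataFrame,
    norm_factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million with a pseudocount, on effective library sizes."""
    lib = counts.sum(axis=0).astype(float)
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(counts.columns)
    return np.log2((counts + prior_count).div(lib + 1.0, axis=1) * 1e6)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# design specification


@dataclass
class DesignSpec:
    """Declarative design for the cell-means expression model.

    ``cell_factor`` contributes one indicator column per level (no
    intercept). Each ``(factor, covariate)`` interaction contributes one
    column per factor level (continuous covariate) or per level x
    non-reference covariate level (categorical covariate). ``covariates``
    enter as plain columns, z-scored when ``scale_covariates``. Contrasts
    are named linear combinations of design columns.
    """

    cell_factor: str = "region"
    interactions: list[tuple[str, str]] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    factor_covariates: list[str] = field(default_factory=list)
    blocking: tuple[str, ...] = ("bird", "region")
    contrasts: dict[str, dict[str, float]] = field(default_factory=dict)
    scale_covariates: bool = True

    def build_matrix(self, metadata: pd.DataFrame) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}

        def scaled(name: str) -> np.ndarray | None:
            v = metadata[name].to_numpy(dtype=float)
            if self.scale_covariates:
                sd = v.std(ddof=0)
                if sd == 0:
                    return None
                v = (v - v.mean()) / sd
            return v

        levels = sorted(metadata[self.cell_factor].astype(str).unique())
        fac = metadata[self.cell_factor].astype(str).to_numpy()
        for lev in levels:
            cols[f"{self.cell_factor}[{lev}]"] = (fac == lev).astype(float)
        for factor, cov in self.interactions:
            flev = sorted(metadata[factor].astype(str).unique())
            fvals = metadata[factor].astype(str).to_numpy()
            if metadata[cov].dtype.kind in "OUb" or isinstance(
                metadata[cov].dtype, pd.CategoricalDtype
            ):
                clev = sorted(metadata[cov].astype(str).unique())
                cvals = metadata[cov].astype(str).to_numpy()
                for fl in flev:
                    for cl in clev[1:]:  # first level is the reference
                        cols[f"{factor}[{fl}]:{cov}[{cl}]"] = (
                            (fvals == fl) & (cvals == cl)
                        ).astype(float)
            else:
                v = scaled(cov)
                if v is None:
                    warnings.warn(f"covariate {cov!r} is constant; interaction dropped")
                    continue
                for fl in flev:
                    cols[f"{factor}[{fl}]:{cov}"] = (fvals == fl) * v
        for fac_cov in self.factor_covariates:
            flev = sorted(metadata[fac_cov].astype(str).unique())
            fvals = metadata[fac_cov].astype(str).to_numpy()
            for lev in flev[1:]:  # first level is the reference
                cols[f"{fac_cov}[{lev}]"] = (fvals == lev).astype(float)
        for cov in self.covariates:
            v = scaled(cov)
            if v is None:
                warnings.warn(f"covariate {cov!r} is constant; dropped")
                continue
            cols[cov] = v
        X = pd.DataFrame(cols, index=metadata.index)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            _, R = np.linalg.qr(X.to_numpy())
            k = min(R.shape)
            aliased = [X.columns[j] for j in range(k) if abs(R[j, j]) < 1e-8]
            aliased += list(X.columns[k:])
            raise ValueError(f"design matrix is rank-deficient; aliased: {aliased}")
        return X


def bin_covariate(values: pd.Series, n_bins: int = 3) -> pd.Series:
    """Discretize a covariate into equal-size ordered bins (bin0 < bin1 < ...)."""
    return pd.qcut(values, n_bins, labels=[f"bin{i}" for i in range(n_bins)]).astype(
        str
    )


# ---------------------------------------------------------------------------
# moderated fitting


@dataclass
class DEResult:
    """Per-gene, per-contrast moderated differential-expression statistics."""

    table: pd.DataFrame  # gene, contrast, logFC, SE, t, p, adj_p
    df_residual: float
    df_prior: float
    s2_prior: float
    s2_post: pd.Series
    design_columns: list[str]
    adj_p_threshold: float = ADJ_P_THRESHOLD
    info: dict = field(default_factory=dict)

    def contrast(self, name: str) -> pd.DataFrame:
        sub = self.table[self.table["contrast"] == name]
        if sub.empty:
            raise KeyError(f"no contrast named {name!r}")
        return sub.set_index("gene")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, as in variance moderation)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes squeeze of residual variances toward a common prior.

    Moment-matches log residual variances to a scaled inverse-chi-square
    prior; returns (prior df d0, prior variance s0^2, posterior variances).
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2)
    if evar > 0:
        d0 = 2 * _trigamma_inverse(evar)
        s20 = np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2))
    else:
        # no excess spread beyond chi-square sampling noise: pool completely
        d0 = np.inf
        if z.var(ddof=1) < 1e-12:
            # literally identical variances: keep them as the fixed point
            s20 = np.exp(z.mean())
        else:
            s20 = np.exp(emean)
    if np.isfinite(d0):
        s2_post = (d0 * s20 + df * s2) / (d0 + df)
    else:
        s2_post = np.full_like(s2, s20)
    return float(d0), float(s20), s2_post


def _voom_weights(
    y: np.ndarray, X: np.ndarray, lib_eff: np.ndarray, span: float = 0.5
) -> np.ndarray:
    """Observation-level precision weights from the lowess mean-variance trend.

    Per-gene OLS residual standard deviations (quarter-root scale) are
    regressed on mean log-count abundance; the trend evaluated at each
    fitted log2-CPM gives predicted sd, and weights are 1 / sd^4.
    """
    n_genes, n_obs = y.shape
    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T
    fitted = beta @ X.T
    resid = y - fitted
    df = n_obs - X.shape[1]
    sigma = np.sqrt((resid**2).sum(axis=1) / df)
    # mean log2 count abundance per gene (shift CPM back to count scale)
    mean_lcpm = y.mean(axis=1)
    sx = mean_lcpm + np.mean(np.log2(lib_eff + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    lo = lowess(sy, sx, frac=span, return_sorted=True)
    lx, ly = lo[:, 0], np.maximum(lo[:, 1], 1e-4)
    fitted_count = fitted + (np.log2(lib_eff + 1.0) - np.log2(1e6))[None, :]
    pred_sqrt_sd = np.interp(fitted_count, lx, ly)
    return 1.0 / pred_sqrt_sd**4


def _collapse_technical(
    counts: pd.DataFrame, metadata: pd.DataFrame, keys: tuple[str, ...]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average technical sections within each blocking cell (e.g. bird x region)."""
    key_series = metadata[list(keys)].astype(str).agg("|".join, axis=1)
    groups = key_series.groupby(key_series).groups
    new_cols, meta_rows = {}, []
    num_cols = metadata.select_dtypes(include="number").columns
    for key, samples in groups.items():
        samples = list(samples)
        new_cols[key] = counts[samples].mean(axis=1)
        row = metadata.loc[samples[0]].copy()
        for c in num_cols:
            row[c] = metadata.loc[samples, c].mean()
        row["n_sections"] = len(samples)
        meta_rows.append(row.rename(key))
    collapsed = pd.DataFrame(new_cols)
    meta = pd.DataFrame(meta_rows)
    meta.index.name = "sample"
    return collapsed, meta


def fit_de(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    design: DesignSpec,
    use_voom_weights: bool = True,
    average_technical: bool = True,
    lowess_span: float = 0.5,
) -> DEResult:
    """Fit the moderated cell-means model and evaluate the declared contrasts.

    Technical sections within a blocking cell are averaged before fitting
    (declared in the result info). Per-gene weighted least squares on
    log2-CPM is followed by empirical-Bayes variance moderation; moderated t
    uses ``df_residual + df_prior`` degrees of freedom and p-values are
    BH-adjusted within each contrast.
    """
    metadata = metadata.loc[counts.columns]
    if average_technical and design.blocking:
        counts, metadata = _collapse_technical(counts, metadata, design.blocking)

    nf = normalization_factors(counts.round().astype(int))
    lib_eff = (counts.sum(axis=0) * nf).to_numpy(dtype=float)
    y = log_cpm(counts, nf).to_numpy(dtype=float)
    X_df = design.build_matrix(metadata)
    X = X_df.to_numpy(dtype=float)
    n_genes, n_obs = y.shape
    df_resid = n_obs - X.shape[1]
    if df_resid < 2:
        raise ValueError(f"only {df_resid} residual df; need >= 2")

    if use_voom_weights:
        W = _voom_weights(y, X, lib_eff, span=lowess_span)
    else:
        W = np.ones_like(y)

    p = X.shape[1]
    betas = np.empty((n_genes, p))
    xtx_inv = np.empty((n_genes, p, p))
    s2 = np.empty(n_genes)
    for g in range(n_genes):
        w = W[g]
        Xw = X * w[:, None]
        A = X.T @ Xw
        Ainv = np.linalg.pinv(A)
        b = Ainv @ (Xw.T @ y[g])
        resid = y[g] - X @ b
        betas[g] = b
        xtx_inv[g] = Ainv
        s2[g] = float(np.sum(w * resid**2) / df_resid)

    d0, s20, s2_post = squeeze_var(s2, df_resid)
    df_total = df_resid + (d0 if np.isfinite(d0) else 1e6)

    contrasts = design.contrasts or {
        c: {c: 1.0} for c in X_df.columns
    }
    rows = []
    genes = counts.index.to_numpy()
    for cname, combo in contrasts.items():
        cvec = np.zeros(p)
        for col, wgt in combo.items():
            if col not in X_df.columns:
                raise KeyError(f"contrast {cname!r} references unknown column {col!r}")
            cvec[X_df.columns.get_loc(col)] = wgt
        coef = betas @ cvec
        stdev_unscaled = np.sqrt(np.einsum("i,gij,j->g", cvec, xtx_inv, cvec))
        se = stdev_unscaled * np.sqrt(s2_post)
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = coef / se
        pval = 2 * stats.t.sf(np.abs(tval), df_total)
        adj = benjamini_hochberg(pval)
        rows.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "contrast": cname,
                    "logFC": coef,
                    "SE": se,
                    "t": tval,
                    "p": pval,
                    "adj_p": adj,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return DEResult(
        table=table,
        df_residual=float(df_resid),
        df_prior=d0,
        s2_prior=s20,
        s2_post=pd.Series(s2_post, index=genes),
        design_columns=list(X_df.columns),
        info={
            "average_technical": average_technical,
            "blocking": list(design.blocking),
            "use_voom_weights": use_voom_weights,
            "n_samples_fit": n_obs,
        },
    )


def deg_score(
    de: DEResult, contrast: str, p_threshold: float | None = None
) -> tuple[float, float]:
    """Signed -log10 adjusted-p summary of a contrast's response.

    Per gene the signed value is sign(logFC) * (-log10 adj_p); the up-score
    sums the positive values and the down-score the negative ones (the
    down-score is reported as a negative number). ``p_threshold`` optionally
    restricts to genes below an adjusted-p cutoff.
    """
    sub = de.contrast(contrast)
    if p_threshold is not None:
        sub = sub[sub["adj_p"] < p_threshold]
    with np.errstate(divide="ignore"):
        signed = np.sign(sub["logFC"]) * (-np.log10(np.maximum(sub["adj_p"], 1e-300)))
    return float(signed[signed > 0].sum()), float(signed[signed < 0].sum())


def cap_signed_logp(values: np.ndarray | pd.Series, cap: float = 5.0):
    """Clip signed -log10 adjusted p-values at +/-cap for display tables."""
    return np.clip(values, -cap, cap)


def per_bird_region_estimates(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: tuple[str, ...] = ("cdr", "frac_mito"),
    use_voom_weights: bool = True,
) -> dict:
    """Per-gene expression estimate and moderated SE for every bird x region.

    Fits the saturated cell-means model (one indicator per bird x region
    cell) with the quality covariates; the moderated SE is
    sqrt(s2_post) * stdev_unscaled. These estimates feed the inter-region
    correlation analysis.
    """
    metadata = metadata.loc[counts.columns].copy()
    metadata["_cell"] = (
        metadata["bird"].astype(str) + "|" + metadata["region"].astype(str)
    )
    usable_covs = [
        c
        for c in covariates
        if c in metadata.columns and metadata[c].astype(float).std(ddof=0) > 0
    ]
    design = DesignSpec(
        cell_factor="_cell",
        covariates=usable_covs,
        blocking=(),
        contrasts={},
    )
    de = fit_de(
        counts,
        metadata,
        design,
        use_voom_weights=use_voom_weights,
        average_technical=False,
    )
    cells = sorted(metadata["_cell"].unique())
    est = pd.DataFrame(index=counts.index, columns=cells, dtype=float)
    se = pd.DataFrame(index=counts.index, columns=cells, dtype=float)
    for cell in cells:
        sub = de.contrast(f"_cell[{cell}]")
        est[cell] = sub["logFC"]
        se[cell] = sub["SE"]
    return {"estimate": est, "se": se, "fit": de}
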