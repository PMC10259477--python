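"""Signed coexpression networks: permutation-FDR edge selection, planar
filtered sparsification, multiresolution module detection, and module /
hub / eigengene significance tests against sampling nulls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .expression import benjamini_hochberg

__all__ = [
    "GeneNetwork",
    "ModuleSet",
    "select_variable_genes",
    "correlation_fdr",
    "planar_filtered_network",
    "detect_modules",
    "module_coefficient_test",
    "hub_genes",
    "module_eigengene",
    "module_preservation",
]

DEFAULT_SCALES = (0.5, 1.0, 2.0)


@dataclass
class GeneNetwork:
    """A planar signed-correlation graph over genes."""

    graph: nx.Graph  # edge attrs: r (signed), weight (=|r|)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "r": d["r"], "weight": d["weight"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows)


@dataclass
class Module:
    module_id: str
    genes: set[str]
    parent: str | None
    scale: float
    mean_coefficient: float | None = None
    null_band: tuple[float, float] | None = None
    significant: bool | None = None
    hubs: list[str] = field(default_factory=list)


@dataclass
class ModuleSet:
    modules: dict[str, Module]

    def __iter__(self):
        return iter(self.modules.values())

    def __getitem__(self, key: str) -> Module:
        return self.modules[key]


def select_variable_genes(log_expr: pd.DataFrame, n: int = 2000) -> list[str]:
    """Top-n variable genes by trend-standardized variance.

    A lowess trend of log variance on log mean expression is fitted across
    genes; genes are ranked by the residual (observed minus expected log
    variance) and the top n returned. Constant genes are never selected.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    mean = log_expr.mean(axis=1)
    var = log_expr.var(axis=1, ddof=1)
    ok = var > 0
    if n >= ok.sum():
        return list(log_expr.index[ok])
    lm = np.log10(np.maximum(mean[ok] - mean[ok].min() + 1e-3, 1e-6))
    lv = np.log10(var[ok])
    trend = lowess(lv.to_numpy(), lm.to_numpy(), frac=0.3, return_sorted=True)
    expected = np.interp(lm, trend[:, 0], trend[:, 1])
    resid = lv - expected
    return list(resid.sort_values(ascending=False, kind="stable").index[:n])


def correlation_fdr(
    expr: pd.DataFrame,
    n_perm: int = 50,
    fdr: float = 0.05,
    seed: int = 0,
    n_thresholds: int = 100,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """All-pairs signed Pearson correlations retained at a permutation FDR.

    ``expr`` is genes x samples. The null is built by permuting sample
    labels independently per gene; for a ladder of |r| thresholds,
    FDR(t) = mean permuted count(|r| >= t) / observed count(|r| >= t), and
    the retained edges are those with |r| at or above the smallest threshold
    achieving FDR < ``fdr``. Returns an edge table (gene_a, gene_b, r).

    ``exhaustive`` replaces the Monte-Carlo null with its exact expectation
    by enumerating every relative sample permutation (feasible only for
    small sample counts); ``n_perm`` is then ignored.
    """
    X = expr.to_numpy(dtype=float)
    genes = list(expr.index)
    n_genes, n_samples = X.shape
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    rng = np.random.default_rng(seed)

    def _upper_corr(M: np.ndarray) -> np.ndarray:
        sd = M.std(axis=1)
        keep = sd > 0
        C = np.corrcoef(M[keep])
        iu = np.triu_indices(keep.sum(), k=1)
        full = np.zeros((n_genes, n_genes))
        full[np.ix_(keep, keep)] = C
        return full

    C = _upper_corr(X)
    iu = np.triu_indices(n_genes, k=1)
    obs = np.abs(C[iu])

    thresholds = np.linspace(0.0, 1.0, n_thresholds + 1)[1:]
    perm_counts = np.zeros(len(thresholds))
    if exhaustive:
        from itertools import permutations as _perms

        Z = X - X.mean(axis=1, keepdims=True)
        sd = np.sqrt((Z**2).sum(axis=1))
        sd[sd == 0] = np.inf
        Z = Z / sd[:, None]
        all_perms = list(_perms(range(n_samples)))
        for pi in all_perms:
            M = Z @ Z[:, list(pi)].T  # r(x_i, x_j[pi])
            pc = np.abs(M[iu])
            perm_counts += np.array([(pc >= t).sum() for t in thresholds])
        perm_counts /= len(all_perms)
    else:
        for _ in range(n_perm):
            Xp = np.array([row[rng.permutation(n_samples)] for row in X])
            pc = np.abs(_upper_corr(Xp)[iu])
            perm_counts += np.array([(pc >= t).sum() for t in thresholds])
        perm_counts /= n_perm
    obs_counts = np.array([(obs >= t).sum() for t in thresholds])
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_curve = np.where(obs_counts > 0, perm_counts / obs_counts, 0.0)
    ok = np.where((fdr_curve < fdr) & (obs_counts > 0))[0]
    if len(ok) == 0:
        return pd.DataFrame(columns=["gene_a", "gene_b", "r"])
    t_star = thresholds[ok[0]]
    keep = obs >= t_star
    rows = {
        "gene_a": [genes[i] for i in iu[0][keep]],
        "gene_b": [genes[j] for j in iu[1][keep]],
        "r": C[iu][keep],
    }
    return pd.DataFrame(rows)


def planar_filtered_network(edges: pd.DataFrame) -> GeneNetwork:
    """Planar maximally filtered sparsification of a weighted edge list.

    Edges are inserted greedily in descending |r| (ties broken by the
    (gene_a, gene_b) id pair); an edge is kept iff the graph stays planar.
    The result satisfies the planar bound of 3(n - 2) edges.
    """
    df = edges.copy()
    df["weight"] = df["r"].abs()
    pair = df.apply(
        lambda row: tuple(sorted((str(row["gene_a"]), str(row["gene_b"])))), axis=1
    ) if len(df) else pd.Series(dtype=object)
    if len(df):
        df["_a"] = [p[0] for p in pair]
        df["_b"] = [p[1] for p in pair]
        df = df.sort_values(
            ["weight", "_a", "_b"], ascending=[False, True, True], kind="stable"
        )
    n_nodes = len(set(df["_a"]).union(df["_b"])) if len(df) else 0
    max_edges = max(3 * (n_nodes - 2), 1)
    G = nx.Graph()
    for _, row in df.iterrows():
        if G.number_of_edges() >= max_edges:
            break  # planar bound reached; no further edge can be added
        a, b = row["_a"], row["_b"]
        if a == b or G.has_edge(a, b):
            continue
        G.add_edge(a, b, r=float(row["r"]), weight=float(row["weight"]))
        ok, _ = nx.check_planarity(G)
        if not ok:
            G.remove_edge(a, b)
            if G.degree(a) == 0:
                G.remove_node(a)
            if G.degree(b) == 0:
                G.remove_node(b)
    return GeneNetwork(graph=G)


def detect_modules(
    network: GeneNetwork,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    min_size: int = 10,
    seed: int = 0,
) -> ModuleSet:
    """Multiresolution community detection on the |r|-weighted planar graph.

    Louvain modularity optimization is run at each resolution in ``scales``
    (ascending, so earlier scales are coarser); each finer module's parent is
    the coarser-scale module containing the plurality of its genes. Modules
    smaller than ``min_size`` are discarded.
    """
    G = network.graph
    modules: dict[str, Module] = {}
    prev_scale_mods: list[Module] = []
    counter = 0
    for scale in sorted(scales):
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=scale, seed=seed
        )
        this_scale: list[Module] = []
        for comm in sorted(comms, key=lambda c: (-len(c), sorted(c)[0] if c else "")):
            if len(comm) < min_size:
                continue
            counter += 1
            parent = None
            if prev_scale_mods:
                overlaps = [(len(comm & m.genes), m.module_id) for m in prev_scale_mods]
                best = max(overlaps)
                if best[0] > 0:
                    parent = best[1]
            mod = Module(
                module_id=f"M{counter}",
                genes=set(comm),
                parent=parent,
                scale=scale,
            )
            modules[mod.module_id] = mod
            this_scale.append(mod)
        if this_scale:
            prev_scale_mods = this_scale
    return ModuleSet(modules=modules)


def module_coefficient_test(
    modules: ModuleSet,
    coefficients: pd.Series,
    n_draws: int = 100,
    seed: int = 0,
    quantiles: tuple[float, float] = (1.0, 99.0),
) -> pd.DataFrame:
    """Mean module coefficient against a random same-size gene-set null.

    For each module the observed mean of per-gene coefficients is compared
    with ``n_draws`` means of random same-size sets drawn without
    replacement from the coefficient universe; the module is flagged when
    the observed mean falls below the 1st or above the 99th percentile.
    """
    rng = np.random.default_rng(seed)
    universe = coefficients.dropna()
    vals = universe.to_numpy()
    rows = []
    for mod in modules:
        genes = [g for g in mod.genes if g in universe.index]
        if len(genes) < 3:
            warnings.warn(f"module {mod.module_id} has < 3 scored genes; skipped")
            continue
        obs = float(universe.loc[genes].mean())
        null = np.array(
            [
                vals[rng.choice(len(vals), size=len(genes), replace=False)].mean()
                for _ in range(n_draws)
            ]
        )
        lo, hi = np.percentile(null, quantiles)
        flag = obs < lo or obs > hi
        mod.mean_coefficient = obs
        mod.null_band = (float(lo), float(hi))
        mod.significant = bool(flag)
        rows.append(
            {
                "module": mod.module_id,
                "n_genes": len(genes),
                "mean_coefficient": obs,
                "null_lo": lo,
                "null_hi": hi,
                "significant": flag,
                "direction": "high" if obs > hi else ("low" if obs < lo else "none"),
            }
        )
    return pd.DataFrame(rows)


def _within_module_connectivity(
    G: nx.Graph, genes: set[str]
) -> pd.Series:
    conn = {}
    for g in genes:
        if g not in G:
            conn[g] = 0.0
            continue
        conn[g] = sum(
            d["weight"] for _, nb, d in G.edges(g, data=True) if nb in genes
        )
    return pd.Series(conn)


def hub_genes(
    network: GeneNetwork,
    modules: ModuleSet,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Hub detection by link-weight permutation of the planar network.

    Within-module connectivity (sum of |r| link weights to co-module genes)
    is compared per gene with its null over networks whose edge weights are
    globally permuted; p = P(null >= observed) with a +1 pseudocount, BH
    adjusted within module, hubs at adjusted p < ``alpha``.
    """
    rng = np.random.default_rng(seed)
    G = network.graph
    edge_list = list(G.edges())
    weights = np.array([G[a][b]["weight"] for a, b in edge_list])
    rows = []
    for mod in modules:
        genes = set(mod.genes) & set(G.nodes)
        if not genes:
            continue
        obs = _within_module_connectivity(G, genes)
        exceed = pd.Series(0.0, index=obs.index)
        for _ in range(n_perm):
            wp = weights[rng.permutation(len(weights))]
            Gp = nx.Graph()
            Gp.add_nodes_from(G.nodes)
            for (a, b), w in zip(edge_list, wp):
                Gp.add_edge(a, b, weight=w)
            null_conn = _within_module_connectivity(Gp, genes)
            exceed += (null_conn >= obs - 1e-12).astype(float)
        pvals = ((exceed + 1) / (n_perm + 1)).to_numpy()
        adj = benjamini_hochberg(pvals)
        hubs = []
        for g, p, ap, c in zip(obs.index, pvals, adj, obs.to_numpy()):
            is_hub = ap < alpha
            if is_hub:
                hubs.append(g)
            rows.append(
                {
                    "module": mod.module_id,
                    "gene": g,
                    "connectivity": c,
                    "p": p,
                    "adj_p": ap,
                    "hub": is_hub,
                }
            )
        mod.hubs = sorted(hubs)
    return pd.DataFrame(rows)


def module_eigengene(
    expr: pd.DataFrame, module_genes: set[str] | list[str]
) -> tuple[pd.Series, pd.Series]:
    """First-PC eigengene of a module and network-wide module membership.

    The eigengene is the first principal-component score vector of the
    standardized module submatrix (samples as observations), sign-aligned so
    the mean correlation with member genes is positive. Membership is each
    gene's Pearson correlation with the eigengene across samples.
    """
    genes = [g for g in module_genes if g in expr.index]
    if not genes:
        raise ValueError("no module genes present in expression matrix")
    sub = expr.loc[genes]
    sds = sub.std(axis=1, ddof=1)
    if (sds == 0).all():
        raise ValueError("module submatrix is constant")
    sub = sub[sds > 0]
    Z = ((sub.T - sub.mean(axis=1)) / sub.std(axis=1, ddof=1)).T.to_numpy()
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = pd.Series(Vt[0] * S[0], index=expr.columns, name="eigengene")
    member_corr = np.array(
        [np.corrcoef(expr.loc[g], eig)[0, 1] for g in sub.index]
    )
    if np.nanmean(member_corr) < 0:
        eig = -eig
    membership = {}
    for g in expr.index:
        v = expr.loc[g].to_numpy(dtype=float)
        if v.std() == 0:
            membership[g] = np.nan
        else:
            membership[g] = float(np.corrcoef(v, eig)[0, 1])
    return eig, pd.Series(membership, name="module_membership")


def module_preservation(
    modules_ref: ModuleSet,
    expr_ref: pd.DataFrame,
    expr_test: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Simplified composite preservation Z of reference modules in test data.

    Z_density compares the observed mean within-module |r| in the test
    expression against random same-size gene sets; Z_connectivity compares
    the Spearman correlation of intramodular connectivity (row sums of |r|)
    between reference and test networks against a permuted-gene null. The
    composite is their mean; the empirical p is Bonferroni-adjusted across
    modules, and scores are min-max scaled across modules for display.
    """
    from scipy.stats import spearmanr

    rng = np.random.default_rng(seed)
    shared = [g for g in expr_ref.index if g in expr_test.index]
    rows = []
    for mod in modules_ref:
        genes = [g for g in mod.genes if g in shared]
        if len(genes) < 3:
            warnings.warn(f"module {mod.module_id}: genes absent from test; skipped")
            continue
        m = len(genes)

        def mean_abs_r(expr: pd.DataFrame, gs: list[str]) -> float:
            C = np.corrcoef(expr.loc[gs].to_numpy())
            iu = np.triu_indices(len(gs), k=1)
            return float(np.nanmean(np.abs(C[iu])))

        def conn(expr: pd.DataFrame, gs: list[str]) -> np.ndarray:
            C = np.abs(np.corrcoef(expr.loc[gs].to_numpy()))
            np.fill_diagonal(C, 0)
            return C.sum(axis=1)

        obs_density = mean_abs_r(expr_test, genes)
        obs_conn_corr = float(
            spearmanr(conn(expr_ref, genes), conn(expr_test, genes)).statistic
        )

        null_density = np.empty(n_perm)
        null_conn = np.empty(n_perm)
        for i in range(n_perm):
            rand = list(np.array(shared)[rng.choice(len(shared), m, replace=False)])
            null_density[i] = mean_abs_r(expr_test, rand)
            null_conn[i] = spearmanr(
                conn(expr_ref, genes), conn(expr_test, rand)
            ).statistic
        z_density = (obs_density - null_density.mean()) / (null_density.std() + 1e-12)
        z_conn = (obs_conn_corr - np.nanmean(null_conn)) / (
            np.nanstd(null_conn) + 1e-12
        )
        z = 0.5 * (z_density + z_conn)
        # empirical p: probability a random module scores as high on both axes
        null_z = 0.5 * (
            (null_density - null_density.mean()) / (null_density.std() + 1e-12)
            + (null_conn - np.nanmean(null_conn)) / (np.nanstd(null_conn) + 1e-12)
        )
        p_emp = float((np.sum(null_z >= z) + 1) / (n_perm + 1))
        rows.append(
            {
                "module": mod.module_id,
                "n_genes": m,
                "z_density": float(z_density),
                "z_connectivity": float(z_conn),
                "z_composite": float(z),
                "p": p_emp,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    zmin, zmax = out["z_composite"].min(), out["z_composite"].max()
    out["score_scaled"] = (
        (out["z_composite"] - zmin) / (zmax - zmin) if zmax > zmin else 1.0
    )
    return out
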