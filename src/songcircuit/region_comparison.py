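"""Cross-region comparison of differential-expression responses:
hypergeometric overlap of top gene lists and preranked gene-set enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import DEResult, benjamini_hochberg

__all__ = [
    "GeneList",
    "EnrichmentResult",
    "top_n_genes",
    "overlap_test",
    "gsea_preranked",
    "enrichment_score",
    "prune_similar_sets",
]


@dataclass
class GeneList:
    """Top differential genes for one region and direction, ordered by p."""

    region: str
    direction: str  # "up" or "down"
    genes: list[str]


def top_n_genes(
    de: DEResult, contrast: str, direction: str, n: int = 250
) -> GeneList:
    """The n genes with smallest p among those with the requested sign.

    Ordered by p ascending; ties broken by |logFC| descending, then gene id.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sub = de.contrast(contrast).reset_index()
    sign = 1 if direction == "up" else -1
    sub = sub[np.sign(sub["logFC"]) == sign].copy()
    sub["_abs_fc"] = -sub["logFC"].abs()
    sub = sub.sort_values(["p", "_abs_fc", "gene"], kind="stable")
    if len(sub) < n:
        warnings.warn(
            f"only {len(sub)} genes with {direction} sign (requested {n})"
        )
    return GeneList(region=contrast, direction=direction, genes=list(sub["gene"][:n]))


def overlap_test(
    list_a: GeneList | list[str],
    list_b: GeneList | list[str],
    universe_size: int,
) -> float:
    """Upper-tail hypergeometric -log10 p for the overlap of two gene lists.

    p = P(X >= k) with X ~ Hypergeom(N=universe, K=|A|, n=|B|), k=|A n B|.
    """
    a = set(list_a.genes if isinstance(list_a, GeneList) else list_a)
    b = set(list_b.genes if isinstance(list_b, GeneList) else list_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("universe smaller than a gene list")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return -np.log10(max(p, 1e-300))


# ---------------------------------------------------------------------------
# preranked GSEA


@dataclass
class EnrichmentResult:
    """Enrichment of one gene set against a ranked statistic."""

    set_id: str
    es: float
    nes: float
    p: float
    adj_p: float
    size: int
    leading_edge: list[str] = field(default_factory=list)


def enrichment_score(
    ranked_genes: list[str],
    ranked_stats: np.ndarray,
    gene_set: set[str],
    weight: float = 1.0,
) -> tuple[float, list[str]]:
    """Weighted Kolmogorov-Smirnov enrichment score and leading edge.

    Genes must be ranked by statistic descending. Hit increments are
    proportional to |stat|^weight, miss increments uniform; the ES is the
    running-sum value of maximal absolute deviation, and the leading edge is
    the hits encountered up to (and including) the extremum for positive ES,
    or from the extremum onward for negative ES.
    """
    n = len(ranked_genes)
    is_hit = np.array([g in gene_set for g in ranked_genes])
    n_hits = int(is_hit.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must hit a strict subset of the ranking")
    w = np.abs(ranked_stats) ** weight
    hit_w = np.where(is_hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = is_hit.astype(float)
        denom = n_hits
    steps = hit_w / denom - (~is_hit) / (n - n_hits)
    running = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        le = [g for g, h in zip(ranked_genes[: i_ext + 1], is_hit[: i_ext + 1]) if h]
    else:
        le = [g for g, h in zip(ranked_genes[i_ext:], is_hit[i_ext:]) if h]
    return es, le


def gsea_preranked(
    gene_stats: pd.Series,
    gene_sets: dict[str, set[str] | list[str]],
    min_size: int = 20,
    max_size: int = 200,
    n_perm: int = 2000,
    seed: int = 0,
    weight: float = 1.0,
    adj_p_report: float = 0.2,
) -> pd.DataFrame:
    """Permutation preranked gene-set enrichment analysis.

    Genes are ranked by ``gene_stats`` descending; the null distribution of
    each set's ES comes from gene-label permutations (random same-size sets);
    NES divides ES by the mean |null ES| of matching sign, and p is the
    matching-sign null tail probability with a +1 pseudocount. BH adjustment
    is applied across sets; rows are annotated as reportable at
    ``adj_p < adj_p_report``.
    """
    gene_stats = gene_stats.dropna()
    if not np.isfinite(gene_stats).all():
        raise ValueError("gene statistics must be finite")
    order = gene_stats.sort_values(ascending=False, kind="stable")
    ranked_genes = list(order.index)
    ranked_stats = order.to_numpy(dtype=float)
    universe = set(ranked_genes)
    rng = np.random.default_rng(seed)

    kept = {}
    for sid, members in gene_sets.items():
        inter = set(members) & universe
        if min_size <= len(inter) <= max_size:
            kept[sid] = inter
        else:
            warnings.warn(f"gene set {sid!r} outside size bounds after filtering")
    results = []
    # group sets by size so null draws are shared per size
    by_size: dict[int, list[str]] = {}
    for sid, members in kept.items():
        by_size.setdefault(len(members), []).append(sid)
    n_genes = len(ranked_genes)
    for size, sids in sorted(by_size.items()):
        null_es = np.empty(n_perm)
        for i in range(n_perm):
            idx = rng.choice(n_genes, size=size, replace=False)
            rand_set = {ranked_genes[j] for j in idx}
            null_es[i], _ = enrichment_score(
                ranked_genes, ranked_stats, rand_set, weight
            )
        pos = null_es[null_es >= 0]
        neg = null_es[null_es < 0]
        for sid in sids:
            es, le = enrichment_score(ranked_genes, ranked_stats, kept[sid], weight)
            if es >= 0:
                tail = pos
                p = (np.sum(tail >= es) + 1) / (len(tail) + 1)
                nes = es / np.mean(np.abs(tail)) if len(tail) else np.nan
            else:
                tail = neg
                p = (np.sum(tail <= es) + 1) / (len(tail) + 1)
                nes = -abs(es) / np.mean(np.abs(tail)) if len(tail) else np.nan
            results.append(
                {
                    "set_id": sid,
                    "es": es,
                    "nes": nes,
                    "p": float(p),
                    "size": size,
                    "leading_edge": ",".join(le),
                }
            )
    if not results:
        return pd.DataFrame(
            columns=["set_id", "es", "nes", "p", "adj_p", "size", "leading_edge"]
        )
    out = pd.DataFrame(results)
    out["adj_p"] = benjamini_hochberg(out["p"].to_numpy())
    out["reportable"] = out["adj_p"] < adj_p_report
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def prune_similar_sets(
    results: pd.DataFrame,
    gene_sets: dict[str, set[str] | list[str]],
    jaccard_threshold: float = 0.75,
) -> pd.DataFrame:
    """Greedy Jaccard-overlap pruning of redundant enriched sets.

    Sets are visited in ascending-p order; a set is dropped when its Jaccard
    similarity with any retained set exceeds the threshold.
    """
    kept_ids: list[str] = []
    keep_mask = []
    for sid in results["set_id"]:
        s = set(gene_sets[sid])
        redundant = False
        for kid in kept_ids:
            k = set(gene_sets[kid])
            j = len(s & k) / len(s | k) if s | k else 0.0
            if j > jaccard_threshold:
                redundant = True
                break
        keep_mask.append(not redundant)
        if not redundant:
            kept_ids.append(sid)
    out = results.copy()
    out["retained_after_prune"] = keep_mask
    return out
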