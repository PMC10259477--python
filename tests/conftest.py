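"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from songcircuit import expression as em
from songcircuit.simulate import ExprSimConfig, SongSimConfig, simulate_counts


@pytest.fixture(scope="session")
def song_config() -> SongSimConfig:
    return SongSimConfig(seed=7, songs_per_day=20)


@pytest.fixture(scope="session")
def small_counts():
    """A small deafening-style count matrix with 30 planted Song D_KL genes."""
    cfg = ExprSimConfig(
        n_genes=600,
        n_birds_per_condition=6,
        dkl_effect_genes={(g, "RA"): 2.0 for g in range(30)},
        seed=11,
    )
    counts, metadata, truth = simulate_counts(cfg)
    return counts, metadata, truth, cfg


@pytest.fixture(scope="session")
def small_de(small_counts):
    """Moderated fit of the small matrix with the region x Song D_KL design."""
    counts, metadata, _, cfg = small_counts
    design = em.DesignSpec(
        cell_factor="region",
        interactions=[("region", "song_dkl")],
        covariates=["cdr", "frac_mito"],
        blocking=("bird", "region"),
        contrasts={f"dkl_{r}": {f"region[{r}]:song_dkl": 1.0} for r in cfg.regions},
        scale_covariates=False,
    )
    return em.fit_de(em.filter_genes(counts), metadata, design)


def make_de_result(
    genes: list[str],
    logfc: np.ndarray,
    adj_p: np.ndarray,
    p: np.ndarray | None = None,
    contrast: str = "c",
) -> em.DEResult:
    """Construct a DEResult directly from per-gene statistics (test helper)."""
    p = adj_p if p is None else p
    table = pd.DataFrame(
        {
            "gene": genes,
            "contrast": contrast,
            "logFC": logfc,
            "SE": np.ones(len(genes)),
            "t": logfc,
            "p": p,
            "adj_p": adj_p,
        }
    )
    return em.DEResult(
        table=table,
        df_residual=10.0,
        df_prior=5.0,
        s2_prior=1.0,
        s2_post=pd.Series(np.ones(len(genes)), index=genes),
        design_columns=["c"],
    )
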