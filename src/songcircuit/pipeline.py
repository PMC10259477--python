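"""Pipeline orchestration: configuration, the synthetic end-to-end demo
workflow (song statistics -> expression modeling -> networks -> inter-region
correlation -> cell-type scoring), and the unilateral-lesion ipsi-vs-contra
contrast workflow.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import celltype, interregion, network, song_divergence, song_features
from . import expression as expr_mod
from . import io as scio
from .simulate import (
    CorrelatedSet,
    ExprSimConfig,
    SongSimConfig,
    simulate_celltype_profiles,
    simulate_counts,
    simulate_song_day,
)

__all__ = ["PipelineConfig", "run_pipeline", "lesion_contrast_workflow", "collect_psds"]


@dataclass
class PipelineConfig:
    """Configuration of the synthetic demo pipeline.

    All stages derive their randomness from ``seed``; the config is echoed
    (with its hash) into every stage manifest so outputs are reproducible
    from config + inputs alone.
    """

    outdir: str = "songcircuit_demo"
    seed: int = 0
    # stage toggles
    run_song: bool = True
    run_expression: bool = True
    run_network: bool = True
    run_interregion: bool = True
    run_celltype: bool = True
    # song stage
    n_song_birds_per_condition: int = 2
    syllables_per_side: int = 300
    drift_magnitude: float = 0.02
    song_dkl_n_reps: int = 5
    # expression stage
    n_genes: int = 1200
    n_birds_per_condition: int = 9
    n_dkl_genes: int = 60
    dkl_logfc: float = 1.5
    nb_dispersion: float = 0.3
    # network stage
    network_region: str = "RA"
    n_variable_genes: int = 300
    corr_fdr_perms: int = 20
    # interregion stage
    n_vmr_genes: int = 200
    n_shuffles: int = 100
    # celltype stage
    n_celltypes: int = 8
    markers_per_type: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _manifest(outdir: Path, stage: str, config: PipelineConfig, **counts) -> None:
    scio.write_json(
        outdir / f"manifest_{stage}.json",
        {"stage": stage, "seed": config.seed, "config_hash": config.config_hash(),
         **counts},
    )


def collect_psds(config: SongSimConfig, bird: int, days: list[int],
                 condition: str, max_syllables: int) -> np.ndarray:
    """Simulate the given days and return up to ``max_syllables`` syllable PSDs."""
    psds = []
    for day in days:
        for song in simulate_song_day(config, bird, day, condition=condition):
            for seg in _segments_of(song, config.sample_rate):
                try:
                    psds.append(song_features.mean_psd(seg).power)
                except ValueError:
                    continue
                if len(psds) >= max_syllables:
                    return np.array(psds)
    return np.array(psds)


def _segments_of(song, sample_rate):
    return song_features.segment_syllables(
        song.waveform, sample_rate=sample_rate, amp_threshold=0.05,
        min_duration=20, min_gap=10,
    )


def _song_stage(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    rows = []
    n = config.n_song_birds_per_condition
    for bird in range(2 * n):
        condition = "hearing" if bird < n else "deaf"
        sim = SongSimConfig(
            n_birds=2 * n,
            drift_magnitude=config.drift_magnitude if condition == "deaf" else 0.0,
            seed=config.seed,
        )
        pre = collect_psds(sim, bird, [-2, -1], condition, config.syllables_per_side)
        post = collect_psds(
            sim, bird, [sim.days_post - 1, sim.days_post], condition,
            config.syllables_per_side,
        )
        res = song_divergence.song_dkl(
            pre, post, n_reps=config.song_dkl_n_reps, seed=config.seed + bird
        )
        rows.append(
            {"bird": f"bird{bird:02d}", "condition": condition,
             "song_dkl": res.mean_dkl, "n_pre": len(pre), "n_post": len(post)}
        )
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "song_dkl.tsv", sep="\t", index=False)
    _manifest(outdir, "song", config, n_birds=len(rows))
    return table


def _expression_stage(config: PipelineConfig, outdir: Path):
    rng = np.random.default_rng(config.seed + 100)
    dkl_genes = rng.choice(config.n_genes, config.n_dkl_genes, replace=False)
    sim = ExprSimConfig(
        n_genes=config.n_genes,
        n_birds_per_condition=config.n_birds_per_condition,
        nb_dispersion=config.nb_dispersion,
        dkl_effect_genes={
            (int(g), "RA"): config.dkl_logfc for g in dkl_genes
        },
        correlated_gene_sets=[
            CorrelatedSet(
                genes=list(range(40)),
                region_pairs=[("HVC", "RA"), ("LMAN", "RA")],
                loading=1.0,
            )
        ],
        condition_decorrelation=True,
        seed=config.seed,
    )
    counts, metadata, truth = simulate_counts(sim)
    counts = expr_mod.filter_genes(counts)
    design = expr_mod.DesignSpec(
        cell_factor="region",
        interactions=[("region", "song_dkl")],
        covariates=["cdr", "frac_mito"],
        blocking=("bird", "region"),
        contrasts={
            f"dkl_{r}": {f"region[{r}]:song_dkl": 1.0} for r in sim.regions
        },
    )
    de = expr_mod.fit_de(counts, metadata, design)
    de.table.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    scores = {
        r: expr_mod.deg_score(de, f"dkl_{r}") for r in sim.regions
    }
    pd.DataFrame(
        [{"region": r, "up_score": u, "down_score": d} for r, (u, d) in scores.items()]
    ).to_csv(outdir / "deg_scores.tsv", sep="\t", index=False)
    est = expr_mod.per_bird_region_estimates(counts, metadata)
    est["estimate"].to_csv(outdir / "bird_region_estimates.tsv", sep="\t")
    _manifest(
        outdir, "expression", config,
        n_genes_in=config.n_genes, n_genes_after_filter=counts.shape[0],
        n_samples=counts.shape[1],
    )
    return counts, metadata, truth, de, est


def _network_stage(config: PipelineConfig, outdir: Path, counts, metadata, de):
    region = config.network_region
    samples = metadata.index[metadata["region"] == region]
    logc = expr_mod.log_cpm(counts[samples])
    genes = network.select_variable_genes(logc, n=config.n_variable_genes)
    edges = network.correlation_fdr(
        logc.loc[genes], n_perm=config.corr_fdr_perms, seed=config.seed
    )
    net = network.planar_filtered_network(edges)
    scio.write_network(outdir / "network_RA", net)
    mods = network.detect_modules(net, seed=config.seed)
    coef = de.contrast(f"dkl_{region}")["logFC"]
    modtest = network.module_coefficient_test(mods, coef, seed=config.seed)
    modtest.to_csv(outdir / "module_tests.tsv", sep="\t", index=False)
    hubs = network.hub_genes(net, mods, seed=config.seed)
    hubs.to_csv(outdir / "hub_genes.tsv", sep="\t", index=False)
    _manifest(
        outdir, "network", config, n_edges_retained=len(edges),
        n_edges_planar=net.graph.number_of_edges(),
        n_modules=len(list(mods)),
    )
    return net, mods


def _interregion_stage(config: PipelineConfig, outdir: Path, metadata, est):
    estimates = est["estimate"]
    bird_cond = metadata.groupby("bird")["condition"].first()
    hearing = [b for b, c in bird_cond.items() if c == "hearing"]
    deaf = [b for b, c in bird_cond.items() if c == "deaf"]

    def _cols(birds):
        return [c for c in estimates.columns if c.split("|")[0] in birds]

    corr = interregion.region_pair_correlations(estimates)
    sig = interregion.shuffle_significance(
        estimates, corr, n_shuffle=config.n_shuffles, seed=config.seed
    )
    sig["pair_counts"].to_csv(outdir / "pair_counts.tsv", sep="\t", index=False)
    diff = interregion.differential_correlation(
        estimates[_cols(hearing)], estimates[_cols(deaf)],
        n_perm=config.n_shuffles, seed=config.seed,
    )
    diff.to_csv(outdir / "differential_correlation.tsv", sep="\t", index=False)
    _manifest(
        outdir, "interregion", config,
        n_pairs=len(sig["pair_counts"]),
        n_decorrelated=int((diff["flag"] == "decorrelated").sum()),
        n_gained=int((diff["flag"] == "gained").sum()),
    )
    return diff


def _celltype_stage(config: PipelineConfig, outdir: Path, de):
    profiles, marker_map = simulate_celltype_profiles(
        config.n_celltypes, config.n_genes, config.markers_per_type,
        seed=config.seed,
    )
    S = celltype.specificity_matrix(profiles)
    scores = celltype.celltype_condition_score(
        S, de, "dkl_RA", seed=config.seed
    )
    scores.to_csv(outdir / "celltype_scores.tsv", sep="\t", index=False)
    markers = celltype.marker_abundance_test(
        marker_map, de, "dkl_RA", seed=config.seed
    )
    markers.to_csv(outdir / "marker_tests.tsv", sep="\t", index=False)
    _manifest(outdir, "celltype", config, n_celltypes=config.n_celltypes)
    return scores


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the synthetic end-to-end demo in dependency order.

    Returns a dict of the principal stage outputs; every stage writes its
    tables and a manifest (stage, seed, config hash) under ``config.outdir``.
    Stages that are toggled off cause dependent stages to fail fast with the
    name of the missing stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    results: dict = {}
    if config.run_song:
        results["song"] = _song_stage(config, outdir)
    if config.run_expression:
        counts, metadata, truth, de, est = _expression_stage(config, outdir)
        results.update(
            {"counts": counts, "metadata": metadata, "truth": truth,
             "de": de, "estimates": est}
        )
    if config.run_network:
        if "de" not in results:
            raise RuntimeError("network stage requires the expression stage")
        net, mods = _network_stage(
            config, outdir, results["counts"], results["metadata"], results["de"]
        )
        results.update({"network": net, "modules": mods})
    if config.run_interregion:
        if "estimates" not in results:
            raise RuntimeError("interregion stage requires the expression stage")
        results["differential_correlation"] = _interregion_stage(
            config, outdir, results["metadata"], results["estimates"]
        )
    if config.run_celltype:
        if "de" not in results:
            raise RuntimeError("celltype stage requires the expression stage")
        results["celltype_scores"] = _celltype_stage(config, outdir, results["de"])
    return results


def lesion_contrast_workflow(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    use_voom_weights: bool = True,
) -> expr_mod.DEResult:
    """Within-bird ipsi-vs-contra contrast for the unilateral-lesion design.

    ``metadata`` needs columns ``bird``, ``group`` (ipsi / contra) and
    ``cdr``. Bird identity enters as fixed effects so the lesion contrast is
    a paired within-bird comparison; birds contributing only one hemisphere
    are excluded with a warning.
    """
    metadata = metadata.loc[counts.columns]
    ok_birds = [
        b for b, grp in metadata.groupby("bird")
        if grp["group"].nunique() == 2
    ]
    dropped = sorted(set(metadata["bird"]) - set(ok_birds))
    if dropped:
        warnings.warn(f"excluding single-hemisphere birds: {dropped}")
    keep = metadata["bird"].isin(ok_birds)
    metadata = metadata[keep]
    counts = counts.loc[:, metadata.index]
    design = expr_mod.DesignSpec(
        cell_factor="group",
        factor_covariates=["bird"],
        covariates=["cdr"],
        blocking=("bird", "group"),
        contrasts={
            "ipsi_vs_contra": {"group[ipsi]": 1.0, "group[contra]": -1.0}
        },
    )
    return expr_mod.fit_de(
        counts, metadata, design, use_voom_weights=use_voom_weights
    )
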