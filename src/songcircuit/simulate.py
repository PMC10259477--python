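"""Synthetic song audio and expression-count generators with recorded ground truth.

Every downstream stage of the pipeline is exercised on data from this module:
harmonic-stack song bouts whose fundamental frequency drifts after an
auditory-feedback manipulation, and negative-binomial 3'-tag count matrices
with planted region effects, behavioral-covariate effects, and latent factors
that couple gene expression between brain regions within a bird.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Song-system nuclei and their adjacent comparator ("non-song") regions.
DEFAULT_REGIONS = ("HVC", "RA", "LMAN", "X", "NC", "Arco", "NR", "Stri")


@dataclass
class SongSimConfig:
    """Parameters of the harmonic-stack song simulator.

    Each syllable type is a harmonic stack with fundamental ``f0_means[i]``;
    after day 0, "deaf" birds drift multiplicatively in fundamental frequency
    (``drift_magnitude`` per day) with proportionally inflated
    rendition-to-rendition jitter and an elevated noise floor.
    """

    n_birds: int = 6
    syllable_types_per_bird: int = 7
    f0_means: tuple[float, ...] = (
        800.0, 1200.0, 1700.0, 2300.0, 3000.0, 3800.0, 4700.0
    )
    n_harmonics: int = 5
    syllable_duration: float = 80.0  # ms
    gap_duration: float = 40.0  # ms
    noise_sd: float = 0.05  # fraction of unit syllable amplitude
    drift_magnitude: float = 0.02  # fractional f0 shift per post day
    ff_jitter_cv: float = 0.02
    days_pre: int = 4
    days_post: int = 14
    songs_per_day: int = 10
    syllables_per_song: int = 6
    sample_rate: int = 44100
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = self.sample_rate / 2
        if not all(0 < f < nyq for f in self.f0_means):
            raise ValueError(f"f0_means must lie in (0, {nyq}) Hz")
        if self.drift_magnitude < 0:
            raise ValueError("drift_magnitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.f0_means) < self.syllable_types_per_bird:
            raise ValueError("need one f0 mean per syllable type")


@dataclass
class SimulatedSong:
    """One song bout: waveform plus per-syllable ground truth."""

    waveform: np.ndarray
    labels: list[int]
    onsets: np.ndarray  # seconds
    offsets: np.ndarray  # seconds
    true_ff: np.ndarray  # Hz, per syllable rendition


def _syllable_waveform(
    f0: float,
    n_harmonics: int,
    n_samples: int,
    sample_rate: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    t = np.arange(n_samples) / sample_rate
    wave = np.zeros(n_samples)
    nyq = sample_rate / 2
    for k in range(1, n_harmonics + 1):
        fk = k * f0
        if fk >= nyq:
            break
        wave += np.sin(2 * np.pi * fk * t + rng.uniform(0, 2 * np.pi)) / k
    wave /= np.max(np.abs(wave)) + 1e-12
    # raised-cosine onset/offset ramps (5 ms) as the amplitude envelope
    ramp = min(int(0.005 * sample_rate), n_samples // 4)
    env = np.ones(n_samples)
    if ramp > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = r
        env[-ramp:] = r[::-1]
    wave = wave * env + rng.normal(0, noise_sd, n_samples)
    return wave


def simulate_song_day(
    config: SongSimConfig,
    bird: int,
    day: int,
    condition: str = "deaf",
) -> list[SimulatedSong]:
    """Simulate all song bouts of one bird on one day.

    ``day`` is a signed index relative to the manipulation (day 0). For
    ``condition="deaf"`` and day > 0 the per-syllable fundamental means are
    displaced by ``drift_magnitude * day * f0`` and both FF jitter and the
    noise floor are inflated by the same factor; "hearing" birds never drift.
    Deterministic given ``(config.seed, bird, day)``.
    """
    if not (-config.days_pre <= day <= config.days_post):
        raise ValueError(
            f"day {day} outside [-{config.days_pre}, {config.days_post}]"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, bird, day + config.days_pre])
    )
    drifting = condition == "deaf" and day > 0
    drift = config.drift_magnitude * day if drifting else 0.0
    jitter_cv = config.ff_jitter_cv * (1 + drift)
    noise_sd = config.noise_sd * (1 + drift)

    sr = config.sample_rate
    n_syl_samples = int(config.syllable_duration / 1000 * sr)
    n_gap_samples = int(config.gap_duration / 1000 * sr)
    songs = []
    for _ in range(config.songs_per_day):
        labels = list(
            rng.integers(0, config.syllable_types_per_bird, config.syllables_per_song)
        )
        chunks, onsets, offsets, true_ff = [], [], [], []
        pos = n_gap_samples
        chunks.append(np.zeros(n_gap_samples))
        for lab in labels:
            f0 = config.f0_means[lab] * (1 + drift)
            f0_rend = f0 * (1 + jitter_cv * rng.normal())
            chunks.append(
                _syllable_waveform(
                    f0_rend, config.n_harmonics, n_syl_samples, sr, noise_sd, rng
                )
            )
            onsets.append(pos / sr)
            offsets.append((pos + n_syl_samples) / sr)
            true_ff.append(f0_rend)
            pos += n_syl_samples
            chunks.append(np.zeros(n_gap_samples))
            pos += n_gap_samples
        songs.append(
            SimulatedSong(
                waveform=np.concatenate(chunks),
                labels=labels,
                onsets=np.array(onsets),
                offsets=np.array(offsets),
                true_ff=np.array(true_ff),
            )
        )
    return songs


# ---------------------------------------------------------------------------
# expression counts


@dataclass
class CorrelatedSet:
    """A planted latent factor coupling genes across region pairs within birds."""

    genes: list[int]
    region_pairs: list[tuple[str, str]]
    loading: float = 1.0


@dataclass
class ExprSimConfig:
    """Parameters of the negative-binomial count simulator.

    Counts follow a gamma-Poisson (NB) law with
    ``var = mu + nb_dispersion * mu**2``. The log-mean of gene *g* in a
    section from bird *b*, region *r* is baseline + region effect +
    bird-within-region effect + planted covariate effects + latent-factor
    contributions. Latent factors are shared across the configured region
    pairs within a bird, and decoupled (drawn independently per region) in
    "deaf" birds when ``condition_decorrelation`` is set.
    """

    n_genes: int = 2000
    regions: tuple[str, ...] = DEFAULT_REGIONS
    n_birds_per_condition: int = 9
    sections_per_bird_region: tuple[int, int] = (2, 6)
    nb_dispersion: float = 0.3
    region_effect_sd: float = 0.3
    bird_effect_sd: float = 0.2
    dkl_effect_genes: dict[tuple[int, str], float] = field(default_factory=dict)
    correlated_gene_sets: list[CorrelatedSet] = field(default_factory=list)
    condition_decorrelation: bool = False
    library_size_range: tuple[int, int] = (50_000, 200_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for (g, r), _ in self.dkl_effect_genes.items():
            if not 0 <= g < self.n_genes:
                raise ValueError(f"planted gene index {g} >= n_genes")
            if r not in self.regions:
                raise ValueError(f"planted effect references unknown region {r!r}")
        for cs in self.correlated_gene_sets:
            for g in cs.genes:
                if not 0 <= g < self.n_genes:
                    raise ValueError(f"correlated-set gene index {g} >= n_genes")
            for a, b in cs.region_pairs:
                if a not in self.regions or b not in self.regions:
                    raise ValueError(f"region pair ({a}, {b}) references unknown region")


@dataclass
class GroundTruth:
    """Planted effects, retrievable by (gene, region, covariate) key."""

    true_logfc: dict[tuple[int, str, str], float]
    correlated_sets: list[CorrelatedSet]
    bird_covariates: pd.DataFrame

    def lookup(self, gene: int, region: str, covariate: str) -> float:
        return self.true_logfc.get((gene, region, covariate), 0.0)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def simulate_counts(
    config: ExprSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a gene x sample count matrix with metadata and ground truth.

    Returns ``(counts, metadata, truth)`` where ``counts`` is genes x samples
    (gene ids ``g0000``...), and ``metadata`` has one row per sample with
    bird, region, condition, song covariates, CDR and mitochondrial fraction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    G = config.n_genes
    regions = list(config.regions)
    n_per = config.n_birds_per_condition
    birds = [f"bird{i:02d}" for i in range(2 * n_per)]
    conditions = ["hearing"] * n_per + ["deaf"] * n_per

    # behavioral covariates per bird; song divergence is graded, higher in deaf
    song_dkl = np.where(
        np.array(conditions) == "hearing",
        np.clip(rng.normal(0.14, 0.12, 2 * n_per), 0.01, None),
        np.clip(rng.normal(0.52, 0.26, 2 * n_per), 0.05, None),
    )
    songs_euth = rng.poisson(60, 2 * n_per)
    songs_pre = rng.poisson(120, 2 * n_per)
    bird_cov = pd.DataFrame(
        {
            "bird": birds,
            "condition": conditions,
            "song_dkl": song_dkl,
            "songs_on_euth_date": songs_euth,
            "songs_per_day_pre": songs_pre,
        }
    )

    log_base = rng.normal(1.0, 1.5, G)  # relative log-abundance per gene
    region_eff = rng.normal(0.0, config.region_effect_sd, (G, len(regions)))

    truth: dict[tuple[int, str, str], float] = {}
    for (g, r), lfc in config.dkl_effect_genes.items():
        truth[(g, r, "song_dkl")] = lfc

    # latent factor draws per (set, bird[, region])
    latent = np.zeros((G, 2 * n_per, len(regions)))
    for si, cs in enumerate(config.correlated_gene_sets):
        involved = sorted({r for pair in cs.region_pairs for r in pair})
        for bi, b in enumerate(birds):
            if config.condition_decorrelation and conditions[bi] == "deaf":
                for r in involved:
                    z = rng.normal()
                    latent[cs.genes, bi, regions.index(r)] += cs.loading * z
            else:
                z = rng.normal()
                for r in involved:
                    latent[cs.genes, bi, regions.index(r)] += cs.loading * z

    cols, meta_rows = [], []
    counts_cols = []
    lo, hi = config.sections_per_bird_region
    for bi, b in enumerate(birds):
        for ri, r in enumerate(regions):
            eta = (
                log_base
                + region_eff[:, ri]
                + rng.normal(0, config.bird_effect_sd, G)
                + latent[:, bi, ri]
            )
            # planted covariate effects: log2 fold-change per unit Song D_KL
            for (g, rr), lfc in config.dkl_effect_genes.items():
                if rr == r:
                    eta[g] += np.log(2) * lfc * song_dkl[bi]
            p = np.exp(eta)
            p /= p.sum()
            n_sections = int(rng.integers(lo, hi + 1))
            lib_lo, lib_hi = config.library_size_range
            for s in range(n_sections):
                lib = rng.integers(lib_lo, max(lib_hi, lib_lo + 1))
                c = _nb_draw(rng, p * lib, config.nb_dispersion)
                sid = f"{b}_{r}_s{s}"
                cols.append(sid)
                counts_cols.append(c)
                meta_rows.append(
                    {
                        "sample": sid,
                        "bird": b,
                        "region": r,
                        "section": s,
                        "condition": conditions[bi],
                        "song_dkl": song_dkl[bi],
                        "songs_on_euth_date": songs_euth[bi],
                        "songs_per_day_pre": songs_pre[bi],
                    }
                )

    gene_ids = [f"g{i:04d}" for i in range(G)]
    counts = pd.DataFrame(
        np.column_stack(counts_cols), index=gene_ids, columns=cols
    )
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    metadata["cdr"] = (counts.values > 0).mean(axis=0)
    mito = rng.dirichlet([50, 950], len(cols))[:, 0]
    metadata["frac_mito"] = mito
    truth_obj = GroundTruth(
        true_logfc=truth,
        correlated_sets=list(config.correlated_gene_sets),
        bird_covariates=bird_cov,
    )
    return counts, metadata, truth_obj


def simulate_celltype_profiles(
    n_celltypes: int,
    n_genes: int,
    markers_per_type: int,
    seed: int = 0,
    marker_map: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Simulate a cell-cluster x gene mean-expression reference.

    Marker genes are expressed predominantly in their own cluster; all other
    genes are near-uniform across clusters. Returns the cluster x gene matrix
    and the marker map (celltype -> marker gene ids).
    """
    if markers_per_type * n_celltypes > n_genes:
        raise ValueError("markers_per_type * n_celltypes must be <= n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    types = [f"ct{i}" for i in range(n_celltypes)]
    if marker_map is None:
        marker_map = {
            t: genes[i * markers_per_type : (i + 1) * markers_per_type]
            for i, t in enumerate(types)
        }
    else:
        seen: set[str] = set()
        for t, gs in marker_map.items():
            dup = seen.intersection(gs)
            if dup:
                raise ValueError(f"marker genes assigned to multiple types: {sorted(dup)}")
            seen.update(gs)
    expr = rng.uniform(0.8, 1.2, (n_celltypes, n_genes))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for ti, t in enumerate(types):
        for g in marker_map.get(t, []):
            gi = gene_idx[g]
            expr[:, gi] = rng.uniform(0.01, 0.05, n_celltypes)
            expr[ti, gi] = rng.uniform(5.0, 10.0)
    return pd.DataFrame(expr, index=types, columns=genes), marker_map
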