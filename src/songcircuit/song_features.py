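"""Per-syllable acoustic features: segmentation, PSDs, spectrogram vectors,
fundamental frequency, Wiener entropy, and rolling FF variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "SyllableSegment",
    "PSDVector",
    "segment_syllables",
    "mean_psd",
    "spectrogram_features",
    "estimate_ff",
    "wiener_entropy",
    "rolling_cv",
    "cv_change_vs_baseline",
]


@dataclass
class SyllableSegment:
    """A segmented vocal unit: the atomic observation of all song statistics."""

    samples: np.ndarray
    onset: float  # seconds
    offset: float  # seconds
    sample_rate: int = 44100
    bird: str | int | None = None
    day: int | None = None
    label: str | int | None = None

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")
        if len(self.samples) == 0:
            raise ValueError("segment has no samples")


@dataclass
class PSDVector:
    """Mean power spectral density of a syllable on a fixed frequency grid."""

    frequencies: np.ndarray
    power: np.ndarray
    normalized: bool = True


def segment_syllables(
    waveform: np.ndarray,
    sample_rate: int = 44100,
    amp_threshold: float = 0.05,
    min_duration: float = 10.0,
    min_gap: float = 5.0,
    smooth_ms: float = 2.0,
) -> list[SyllableSegment]:
    """Segment a waveform into syllables by amplitude threshold crossings.

    The envelope is the rectified signal smoothed with a ``smooth_ms`` moving
    average. Maximal runs above ``amp_threshold`` are merged across gaps
    shorter than ``min_gap`` ms and discarded if shorter than
    ``min_duration`` ms. Silence yields an empty list.
    """
    if amp_threshold <= 0:
        raise ValueError("amp_threshold must be > 0")
    waveform = np.asarray(waveform, dtype=float)
    win = max(int(smooth_ms / 1000 * sample_rate), 1)
    env = np.convolve(np.abs(waveform), np.ones(win) / win, mode="same")
    above = env > amp_threshold
    if not above.any():
        return []
    # run boundaries
    d = np.diff(above.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(waveform))
    # merge across short gaps
    min_gap_n = int(min_gap / 1000 * sample_rate)
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < min_gap_n:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_dur_n = int(min_duration / 1000 * sample_rate)
    return [
        SyllableSegment(
            samples=waveform[s:e],
            onset=s / sample_rate,
            offset=e / sample_rate,
            sample_rate=sample_rate,
        )
        for s, e in merged
        if e - s >= min_dur_n
    ]


def mean_psd(
    segment: SyllableSegment | np.ndarray,
    sample_rate: int | None = None,
    window_length: int = 512,
    overlap: float = 0.0,
    normalize: bool = True,
) -> PSDVector:
    """Mean short-time magnitude spectrum of a syllable.

    Hann-windowed frames of ``window_length`` samples with the given overlap
    fraction; the mean over frames of the magnitude spectrum is returned on a
    ``window_length // 2``-bin grid, max-normalized when ``normalize``.
    """
    if isinstance(segment, SyllableSegment):
        x = segment.samples
        sr = segment.sample_rate
    else:
        x = np.asarray(segment, dtype=float)
        sr = sample_rate or 44100
    if len(x) < window_length:
        raise ValueError(
            f"segment length {len(x)} shorter than window_length {window_length}"
        )
    step = max(int(window_length * (1 - overlap)), 1)
    n_frames = 1 + (len(x) - window_length) // step
    window = np.hanning(window_length)
    spec = np.zeros(window_length // 2)
    for i in range(n_frames):
        frame = x[i * step : i * step + window_length] * window
        spec += np.abs(np.fft.rfft(frame))[: window_length // 2]
    spec /= n_frames
    if normalize:
        spec = spec / (spec.max() + (spec.max() == 0))
    freqs = np.fft.rfftfreq(window_length, 1 / sr)[: window_length // 2]
    return PSDVector(frequencies=freqs, power=spec, normalized=normalize)


def _mel_filterbank(
    n_mels: int, n_fft: int, sample_rate: int, fmin: float, fmax: float
) -> np.ndarray:
    """Triangular mel filterbank (HTK mel scale), n_mels x (n_fft//2 + 1)."""

    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fft_freqs = np.fft.rfftfreq(n_fft, 1 / sample_rate)
    fb = np.zeros((n_mels, len(fft_freqs)))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m : m + 3]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-9)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-9)
        fb[m] = np.clip(np.minimum(up, down), 0, None)
    return fb


def spectrogram_features(
    segment: SyllableSegment | np.ndarray,
    sample_rate: int | None = None,
    fmin: float = 500.0,
    fmax: float = 15000.0,
    mel_channels: int = 128,
    target_fps: int = 640,
    pad_dim: int = 128,
    reduced_dim: int = 16,
) -> np.ndarray:
    """Flattened 16x16 reduced mel spectrogram (256-vector) of a syllable.

    STFT (512 window, 0.5 ms step) -> band-limit to [fmin, fmax] -> mel
    filterbank -> linear time-compression to ``target_fps`` -> symmetric
    zero-pad / center-clip to ``pad_dim`` frames -> block-average to
    ``reduced_dim`` x ``reduced_dim`` -> flatten.
    """
    if isinstance(segment, SyllableSegment):
        x = segment.samples
        sr = segment.sample_rate
    else:
        x = np.asarray(segment, dtype=float)
        sr = sample_rate or 44100
    if not (fmin < fmax < sr / 2):
        raise ValueError("require fmin < fmax < Nyquist")
    n_fft = 512
    hop = max(int(round(0.0005 * sr)), 1)  # 0.5 ms step
    if len(x) < n_fft:
        x = np.pad(x, (0, n_fft - len(x)))
    _, _, Z = signal.stft(
        x, fs=sr, window="hann", nperseg=n_fft, noverlap=n_fft - hop, boundary=None
    )
    S = np.abs(Z)  # (n_fft//2+1, frames)
    fb = _mel_filterbank(mel_channels, n_fft, sr, fmin, fmax)
    M = fb @ S  # (mel, frames)
    # compress time axis to target_fps
    native_fps = sr / hop
    n_out = max(int(round(M.shape[1] * target_fps / native_fps)), 1)
    src_t = np.linspace(0, 1, M.shape[1])
    dst_t = np.linspace(0, 1, n_out)
    Mc = np.vstack([np.interp(dst_t, src_t, row) for row in M])
    # symmetric zero-pad or center-clip to pad_dim frames
    if Mc.shape[1] < pad_dim:
        tot = pad_dim - Mc.shape[1]
        Mc = np.pad(Mc, ((0, 0), (tot // 2, tot - tot // 2)))
    elif Mc.shape[1] > pad_dim:
        s = (Mc.shape[1] - pad_dim) // 2
        Mc = Mc[:, s : s + pad_dim]
    # block-average (mel_channels x pad_dim) down to reduced_dim x reduced_dim
    r0 = mel_channels // reduced_dim
    r1 = pad_dim // reduced_dim
    out = Mc.reshape(reduced_dim, r0, reduced_dim, r1).mean(axis=(1, 3))
    return out.ravel()


def estimate_ff(
    segment: SyllableSegment | np.ndarray,
    t_offset: float = 0.0,
    fmin: float = 500.0,
    fmax: float = 8000.0,
    sample_rate: int | None = None,
    n_fft: int = 1024,
) -> float:
    """Fundamental frequency at ``t_offset`` seconds into the syllable.

    A single ``n_fft``-sample Hann-windowed FFT is taken at the offset, the
    magnitude spectrum is interpolated (Akima spline) onto a 1 Hz grid over
    [fmin, fmax], and the argmax frequency is returned.
    """
    if isinstance(segment, SyllableSegment):
        x = segment.samples
        sr = segment.sample_rate
    else:
        x = np.asarray(segment, dtype=float)
        sr = sample_rate or 44100
    if not (0 < fmin < fmax):
        raise ValueError("require 0 < fmin < fmax")
    if fmax > sr / 2:
        raise ValueError(f"fmax {fmax} exceeds Nyquist {sr / 2}")
    start = int(t_offset * sr)
    if start < 0 or start >= len(x):
        raise ValueError("t_offset outside segment")
    frame = x[start : start + n_fft]
    if len(frame) < n_fft:
        frame = np.pad(frame, (0, n_fft - len(frame)))
    # zero-pad 64x so the spectrum is sampled well below the 1 Hz grid step,
    # then spline-interpolate onto the integer-Hz grid
    n_pad = n_fft * 64
    spec = np.abs(np.fft.rfft(frame * np.hanning(n_fft), n=n_pad))
    freqs = np.fft.rfftfreq(n_pad, 1 / sr)
    grid = np.arange(fmin, fmax + 1.0)
    from scipy.interpolate import Akima1DInterpolator

    interp = Akima1DInterpolator(freqs, spec)(grid)
    return float(grid[np.argmax(interp)])


def wiener_entropy(psd: PSDVector | np.ndarray, floor: float = 1e-12) -> float:
    """Log ratio of geometric to arithmetic mean power: 0 for a flat
    spectrum, strongly negative for tonal sounds."""
    power = psd.power if isinstance(psd, PSDVector) else np.asarray(psd, dtype=float)
    if not (power > 0).any():
        raise ValueError("PSD has no positive bins")
    p = np.maximum(power, floor)
    return float(np.mean(np.log(p)) - np.log(np.mean(p)))


def rolling_cv(values: np.ndarray | pd.Series, window: int = 11) -> np.ndarray:
    """Rolling coefficient of variation (sample sd / mean) over the current
    value and the ``window - 1`` prior ones; NaN until the window fills or
    when the window mean is zero."""
    if window < 2:
        raise ValueError("window must be >= 2")
    v = pd.Series(np.asarray(values, dtype=float))
    roll = v.rolling(window)
    mean = roll.mean()
    sd = roll.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv[mean == 0] = np.nan
    return cv.to_numpy()


def cv_change_vs_baseline(
    ff_table: pd.DataFrame,
    baseline_days: list[int] | None = None,
    post_days: list[int] | None = None,
    window: int = 11,
) -> dict:
    """Percent change of rolling FF CV after a manipulation, with a mixed model.

    ``ff_table`` needs columns ``bird``, ``syllable``, ``day``, ``ff`` in
    rendition order. Rolling CVs are computed per bird x syllable, expressed
    as a percentage of that syllable's mean pre-period CV, and the group
    contrast is a linear mixed model (ML) with period as fixed effect and
    syllable nested in bird as random intercepts.

    Returns per-syllable percent changes, the fixed-effect estimate (percent
    change of the post period), and its Wald p-value.
    """
    import statsmodels.formula.api as smf

    req = {"bird", "syllable", "day", "ff"}
    if not req.issubset(ff_table.columns):
        raise ValueError(f"ff_table must have columns {sorted(req)}")
    if baseline_days is None:
        baseline_days = sorted(d for d in ff_table["day"].unique() if d < 0)
    if post_days is None:
        post_days = sorted(d for d in ff_table["day"].unique() if d > 0)
    if not baseline_days or not post_days:
        raise ValueError("both baseline and post periods must be nonempty")

    rows = []
    for (bird, syl), grp in ff_table.groupby(["bird", "syllable"], sort=True):
        grp = grp.sort_values("day", kind="stable")
        # the rolling window restarts at each day so that between-day FF
        # steps (e.g. across the manipulation) do not masquerade as
        # rendition-to-rendition variability
        cvs = np.concatenate(
            [
                rolling_cv(day_grp["ff"].to_numpy(), window=window)
                for _, day_grp in grp.groupby("day", sort=True)
            ]
        )
        days = np.concatenate(
            [day_grp["day"].to_numpy() for _, day_grp in grp.groupby("day", sort=True)]
        )
        pre = cvs[np.isin(days, baseline_days)]
        pre = pre[~np.isnan(pre)]
        if len(pre) == 0:
            warnings.warn(f"bird {bird} syllable {syl}: no baseline CVs; excluded")
            continue
        base = pre.mean()
        for d, cv in zip(days, cvs):
            if np.isnan(cv) or base == 0:
                continue
            period = (
                "pre" if d in baseline_days else "post" if d in post_days else None
            )
            if period is None:
                continue
            rows.append(
                {
                    "bird": str(bird),
                    "syllable": f"{bird}|{syl}",
                    "period": period,
                    "cv_pct": 100.0 * cv / base,
                }
            )
    long = pd.DataFrame(rows)
    if long.empty or long["period"].nunique() < 2:
        raise ValueError("insufficient data for the period contrast")

    per_syl = (
        long.groupby(["syllable", "period"])["cv_pct"].mean().unstack("period")
    )
    per_syl["pct_change"] = per_syl.get("post") - per_syl.get("pre")

    long["post"] = (long["period"] == "post").astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "cv_pct ~ post",
            long,
            groups="bird",
            re_formula="1",
            vc_formula={"syllable": "0 + C(syllable)"},
        )
        fit = model.fit(reml=False)
    est = float(fit.params["post"])
    pval = float(fit.pvalues["post"])
    return {
        "per_syllable": per_syl,
        "estimate_pct_change": est,
        "p_value": pval,
        "n_obs": len(long),
    }
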