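"""File-format bindings: WAV audio, count matrices (TSV / MatrixMarket),
metadata tables, GMT gene sets, and network exports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.io import wavfile
from scipy.sparse import csr_matrix


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: int = 44100) -> None:
    """Write a float waveform as PCM 16-bit WAV, peak-normalized to 0.9."""
    x = np.asarray(waveform, dtype=float)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak * 0.9
    wavfile.write(path, sample_rate, (x * 32767).astype(np.int16))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file to a float waveform in [-1, 1] and its sample rate."""
    sr, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data.astype(float) / 32768
    elif data.dtype == np.int32:
        data = data.astype(float) / 2147483648
    elif data.dtype == np.uint8:
        data = (data.astype(float) - 128) / 128
    else:
        data = data.astype(float)
    if data.ndim > 1:
        data = data.mean(axis=1)
    return data, int(sr)


def write_counts_tsv(path: str | Path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_mtx(prefix: str | Path, counts: pd.DataFrame) -> None:
    """Write counts as MatrixMarket with genes.tsv / samples.tsv sidecars."""
    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    mmwrite(str(prefix / "counts.mtx"), csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(prefix / "genes.tsv", index=False, header=False)
    pd.Series(counts.columns).to_csv(prefix / "samples.tsv", index=False, header=False)


def read_counts_mtx(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = mmread(str(prefix / "counts.mtx")).toarray()
    genes = pd.read_csv(prefix / "genes.tsv", header=None)[0]
    samples = pd.read_csv(prefix / "samples.tsv", header=None)[0]
    return pd.DataFrame(mat, index=genes, columns=samples)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT (set id, description, members per line)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_json(path: str | Path, obj: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def write_network(path_prefix: str | Path, network) -> None:
    """Write a GeneNetwork as edge-list TSV and GraphML."""
    import networkx as nx

    prefix = Path(path_prefix)
    network.edge_table().to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
    nx.write_graphml(network.graph, prefix.with_suffix(".graphml"))
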