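"""Plain-text and array I/O for connectomes, signals, and result tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synthetic import Connectome


def save_connectome(conn: Connectome, directory: str | Path, stem: str = "connectome") -> None:
    """Write adjacency and distance matrices (whitespace-delimited) plus labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / f"{stem}_adjacency.txt", conn.adjacency, fmt="%d")
    np.savetxt(directory / f"{stem}_distances.txt", conn.distances, fmt="%.6f")
    (directory / f"{stem}_labels.txt").write_text("\n".join(conn.labels) + "\n")


def load_connectome(directory: str | Path, stem: str = "connectome") -> Connectome:
    directory = Path(directory)
    adj = np.loadtxt(directory / f"{stem}_adjacency.txt").astype(int)
    dist = np.loadtxt(directory / f"{stem}_distances.txt")
    labels = (directory / f"{stem}_labels.txt").read_text().split()
    return Connectome(adjacency=adj, distances=dist, labels=labels)


def save_signals(path: str | Path, signals: np.ndarray, fs: float,
                 channels: list[str] | None = None, seed: int | None = None) -> None:
    """Binary array container (.npy) with a JSON sidecar holding fs/channels/seed."""
    path = Path(path)
    np.save(path, np.asarray(signals))
    meta = {"fs": fs, "channels": channels or [f"ch{i:03d}" for i in range(len(signals))],
            "seed": seed}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_signals(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    data = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return data, meta


def load_matrix(path: str | Path) -> np.ndarray:
    """Delimited text or .npy matrix."""
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    return np.loadtxt(path)
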