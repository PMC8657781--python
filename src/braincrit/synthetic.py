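"""Synthetic inputs: connectomes, natural frequencies, surrogate EEG, and parcel BOLD.

Real diffusion-imaging connectomes, scalp EEG and fMRI volumes are not bundled
with the package; every downstream stage is instead exercised on generated data
whose statistical structure matches what the analyses assume — a hub-heterogeneous
structural network with millimetre-scale distances, band-limited multichannel
oscillations with controllable global synchronization, and parcel-by-volume BOLD
with planted recurring co-activation templates.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
from scipy import signal as sps


@dataclasses.dataclass(frozen=True)
class Connectome:
    """Structural network: binary adjacency, inter-node distances (mm), labels."""

    adjacency: np.ndarray
    distances: np.ndarray
    labels: list[str]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Structural node degree (row sums of the adjacency)."""
        return self.adjacency.sum(axis=1).astype(int)

    def __post_init__(self) -> None:
        a, d = np.asarray(self.adjacency), np.asarray(self.distances)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if d.shape != a.shape:
            raise ValueError("distances shape must match adjacency")
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if not np.allclose(d, d.T) or np.any(d < 0):
            raise ValueError("distances must be symmetric and non-negative")
        if np.any((a == 1) & (d <= 0)):
            raise ValueError("connected node pairs must have positive distance")
        if len(self.labels) != a.shape[0]:
            raise ValueError("one label per node required")
        if not nx.is_connected(nx.from_numpy_array(a)):
            raise ValueError("graph must be a single connected component")


@dataclasses.dataclass(frozen=True)
class FrequencySet:
    """Angular natural frequencies (rad/s), one per oscillator."""

    omega: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.omega) <= 0):
            raise ValueError("natural frequencies must be positive")

    @property
    def hz(self) -> np.ndarray:
        return np.asarray(self.omega) / (2 * np.pi)


def generate_connectome(
    n_nodes: int = 78,
    density: float = 0.15,
    hub_fraction: float = 0.15,
    seed: int = 0,
    box_mm: float = 150.0,
    max_retries: int = 50,
) -> Connectome:
    """Spatially embedded random graph with designated hub nodes.

    Nodes are placed uniformly in a cube of side ``box_mm`` and distances are
    Euclidean. A hub subset (fraction ``hub_fraction``) receives extra edges
    until each hub's degree is at least twice the median non-hub degree,
    producing the right-skewed degree distribution structural brain networks
    show. Retries with perturbed seeds until the graph is connected.
    """
    if not 0 < density < 1:
        raise ValueError("density must be in (0, 1)")
    if not 0 < hub_fraction < 0.5:
        raise ValueError("hub_fraction must be in (0, 0.5)")
    if n_nodes < 10:
        raise ValueError("need at least 10 nodes")

    n_hubs = max(1, int(round(hub_fraction * n_nodes)))
    for attempt in range(max_retries):
        rng = np.random.default_rng([seed, attempt])
        pos = rng.uniform(0.0, box_mm, size=(n_nodes, 3))
        dist = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))

        # distance-penalized random wiring at the requested density
        iu = np.triu_indices(n_nodes, k=1)
        scale = np.median(dist[iu])
        w = np.exp(-dist[iu] / scale)
        n_edges = int(round(density * len(iu[0])))
        p = w / w.sum()
        chosen = rng.choice(len(iu[0]), size=n_edges, replace=False, p=p)
        adj = np.zeros((n_nodes, n_nodes), dtype=int)
        adj[iu[0][chosen], iu[1][chosen]] = 1
        adj += adj.T

        hubs = rng.choice(n_nodes, size=n_hubs, replace=False)
        # boost hubs until each reaches 2x the overall median degree; adding
        # edges shifts the median, so iterate to a fixed point
        for _ in range(20):
            target = 2 * int(np.median(adj.sum(1)))
            deficits = target - adj[hubs].sum(1)
            if np.all(deficits <= 0):
                break
            for h, deficit in zip(hubs, deficits):
                if deficit > 0:
                    candidates = np.flatnonzero((adj[h] == 0) & (np.arange(n_nodes) != h))
                    add = rng.choice(candidates, size=min(deficit, len(candidates)),
                                     replace=False)
                    adj[h, add] = adj[add, h] = 1

        if nx.is_connected(nx.from_numpy_array(adj)):
            np.fill_diagonal(dist, 0.0)
            labels = [f"node{i:03d}" for i in range(n_nodes)]
            return Connectome(adjacency=adj, distances=dist, labels=labels)
    raise RuntimeError(f"failed to generate a connected graph after {max_retries} retries")


def generate_frequencies(
    n_nodes: int, mean_hz: float = 10.0, sd_hz: float = 0.5, seed: int = 0
) -> FrequencySet:
    """Gaussian natural frequencies in Hz, converted to rad/s; negative draws redrawn."""
    if mean_hz <= 0:
        raise ValueError("mean_hz must be positive")
    if sd_hz < 0:
        raise ValueError("sd_hz must be non-negative")
    rng = np.random.default_rng(seed)
    hz = rng.normal(mean_hz, sd_hz, size=n_nodes)
    while np.any(hz <= 0):
        bad = hz <= 0
        hz[bad] = rng.normal(mean_hz, sd_hz, size=bad.sum())
    return FrequencySet(omega=2 * np.pi * hz, seed=seed)


def _narrowband_noise(rng: np.random.Generator, n_samples: int, fs: float,
                      band: tuple[float, float]) -> np.ndarray:
    x = rng.standard_normal(n_samples)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y / y.std()


def generate_surrogate_eeg(
    n_channels: int,
    duration: float,
    fs: float,
    sync_profile: np.ndarray,
    band: tuple[float, float] = (4.0, 12.0),
    noise_sd: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Band-limited multichannel signals with controllable global synchronization.

    Each channel mixes a shared narrowband oscillation with an independent one,
    ``w(t)*common + (1-w(t))*own + noise``, where the mixing weight ``w`` tracks
    ``sync_profile`` (linearly interpolated to the sample grid). The realized
    windowed order parameter increases monotonically with the profile level.
    Returns a (n_channels, n_samples) array.
    """
    if fs < 250:
        raise ValueError("fs must be at least 250 Hz")
    if not 0 < band[0] < band[1] < fs / 2:
        raise ValueError("band must lie within (0, Nyquist)")
    sync_profile = np.asarray(sync_profile, dtype=float)
    if np.any(sync_profile < 0) or np.any(sync_profile > 1):
        raise ValueError("sync_profile values must be in [0, 1]")

    n_samples = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    t_profile = np.linspace(0, n_samples - 1, num=len(sync_profile))
    w = np.interp(np.arange(n_samples), t_profile, sync_profile)

    common = _narrowband_noise(rng, n_samples, fs, band)
    out = np.empty((n_channels, n_samples))
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    for c in range(n_channels):
        own = _narrowband_noise(rng, n_samples, fs, band)
        mix = w * common + (1.0 - w) * own + noise_sd * rng.standard_normal(n_samples)
        out[c] = sps.sosfiltfilt(sos, mix)
    return out


def default_cap_templates(k: int, n_parcels: int, seed: int = 0) -> np.ndarray:
    """Smooth random co-activation templates, unit RMS, row per template.

    Template 0 is rectified to a spatially uniform sign (a global co-activation
    pattern); the remaining templates are centered to mixed sign.
    """
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((k, n_parcels))
    kernel = np.exp(-0.5 * (np.arange(-4, 5) / 2.0) ** 2)
    kernel /= kernel.sum()
    smooth = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, raw)
    mag = np.abs(smooth)
    out = np.empty_like(mag)
    out[0] = mag[0]
    for i in range(1, k):
        # balanced random sign pattern keeps the mixed templates incoherent
        # regardless of the magnitude profile drawn
        signs = np.ones(n_parcels)
        signs[: n_parcels // 2] = -1
        out[i] = mag[i] * rng.permutation(signs)
        out[i] -= out[i].mean()
    return out / np.sqrt((out**2).mean(axis=1, keepdims=True))


def generate_parcel_bold(
    n_parcels: int,
    n_volumes: int,
    templates: np.ndarray,
    occupancy_by_class: dict[str, np.ndarray],
    noise_sd: float = 0.2,
    high_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parcel-by-volume BOLD with planted templates and sync-class structure.

    Each volume is one template plus Gaussian noise. Volumes assigned to the
    high-synchronization class are rendered with a spatially uniform sign
    (rectified template: global co-activation), low-class volumes with mixed
    sign (spatially centered template), so a volume-wise synchronization
    classifier can separate the classes.

    Returns ``(volumes [n_volumes × n_parcels], true_template, true_class)``
    where ``true_class`` is 0 for low and 1 for high.
    """
    templates = np.asarray(templates, dtype=float)
    k = templates.shape[0]
    if templates.shape[1] != n_parcels:
        raise ValueError("templates must have n_parcels columns")
    if k > n_volumes:
        raise ValueError("more templates than volumes")
    for cls in ("low", "high"):
        row = np.asarray(occupancy_by_class[cls], dtype=float)
        if row.shape != (k,) or not np.isclose(row.sum(), 1.0):
            raise ValueError(f"occupancy row for class {cls!r} must sum to 1 over {k} templates")

    rng = np.random.default_rng(seed)
    true_class = (rng.random(n_volumes) < high_fraction).astype(int)
    true_template = np.empty(n_volumes, dtype=int)
    volumes = np.empty((n_volumes, n_parcels))
    rendered = {
        0: templates - templates.mean(axis=1, keepdims=True),  # mixed sign
        1: np.abs(templates),  # uniform sign, co-activation
    }
    for cls_idx, cls_name in ((0, "low"), (1, "high")):
        sel = np.flatnonzero(true_class == cls_idx)
        true_template[sel] = rng.choice(k, size=len(sel), p=occupancy_by_class[cls_name])
        volumes[sel] = rendered[cls_idx][true_template[sel]]
    volumes += noise_sd * rng.standard_normal(volumes.shape)
    return volumes, true_template, true_class
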