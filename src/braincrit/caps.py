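"""Co-activation pattern (CAP) analysis for parcel-level BOLD volumes.

Volumes pooled across subjects and conditions are clustered with k-means into
k spatial templates; each volume carries one CAP label. The cluster count is
selected by the separability index (CC + UU) / (2 CU), the ratio of
inter-dataset similarity within conscious-like (CC) and unresponsive-like (UU)
groups to the similarity across them (CU), computed on per-group CAP
occurrence-rate distributions. Volumes are classed low/high by the order
parameter across parcels, and per-class CAP occurrence rates are tested
against a permutation null that shuffles CAP labels uniformly in time.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy import signal as sps
from sklearn.cluster import KMeans

from .sync import order_parameter


@dataclasses.dataclass(frozen=True)
class CapResult:
    templates: np.ndarray  # (k, n_parcels)
    labels: np.ndarray  # per-volume template index
    k: int
    occurrence: dict[str, np.ndarray]  # class -> per-template rate
    null_quantiles: dict[str, np.ndarray]  # class -> one-sided (1-alpha) bound
    significant: dict[str, np.ndarray]  # class -> bool per template
    alpha: float


def extract_caps(
    volumes: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """k-means CAP templates and per-volume labels (Euclidean, multi-restart)."""
    volumes = np.asarray(volumes, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > volumes.shape[0]:
        raise ValueError("k cannot exceed the number of volumes")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(volumes)
    return km.cluster_centers_, labels


def occurrence_rates(labels: np.ndarray, k: int) -> np.ndarray:
    counts = np.bincount(np.asarray(labels, dtype=int), minlength=k)
    total = counts.sum()
    return counts / total if total else np.full(k, np.nan)


def select_k(
    groups: dict[str, list[np.ndarray]],
    k_range: range | list[int] = range(2, 31),
    seed: int = 0,
) -> dict[int, float]:
    """Separability index per candidate k.

    ``groups`` maps 'conscious' and 'unresponsive' to lists (>= 2 each) of
    volume matrices. For each k, all volumes are pooled and clustered, each
    group's occurrence-rate vector computed, and the index
    (CC + UU) / (2 CU) formed with similarity = 1 / Euclidean distance
    (averaged within conscious pairs, unresponsive pairs, and across).
    """
    cons = groups.get("conscious", [])
    uncs = groups.get("unresponsive", [])
    if len(cons) < 2 or len(uncs) < 2:
        raise ValueError("need at least 2 groups per condition side")
    pooled = np.vstack(cons + uncs)
    sizes = [g.shape[0] for g in cons + uncs]
    bounds = np.cumsum([0] + sizes)
    n_cons = len(cons)

    out = {}
    for k in k_range:
        _, labels = extract_caps(pooled, k=k, seed=seed)
        rates = [occurrence_rates(labels[bounds[i] : bounds[i + 1]], k)
                 for i in range(len(sizes))]
        cc = _mean_dist(rates[:n_cons])
        uu = _mean_dist(rates[n_cons:])
        cu = float(np.mean([np.linalg.norm(a - b)
                            for a in rates[:n_cons] for b in rates[n_cons:]]))
        if np.isclose(cc, uu) and np.isclose(uu, cu):
            out[k] = 1.0  # all groups equally (dis)similar, incl. identical
        elif cc + uu == 0:
            out[k] = float("inf")
        else:
            # inverse-distance similarity, aggregated as the ratio of the mean
            # across-group distance to the mean within-group distance (robust
            # to a single zero within-pair distance)
            out[k] = 2.0 * cu / (cc + uu)
    return out


def _mean_dist(rates: list[np.ndarray]) -> float:
    return float(np.mean([np.linalg.norm(a - b)
                          for a, b in itertools.combinations(rates, 2)]))


def volume_sync(volumes: np.ndarray, detrend: bool = True) -> np.ndarray:
    """Per-volume synchronization r across parcels.

    Each parcel's time course is (linearly detrended and) Hilbert transformed;
    the order parameter across parcel phases is evaluated at every volume.
    """
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim != 2 or volumes.shape[1] < 2:
        raise ValueError("volumes must be (n_volumes, n_parcels >= 2)")
    series = volumes.T  # (n_parcels, n_volumes)
    if np.any(series.std(axis=1) == 0):
        raise ValueError("constant parcel time course: phase undefined")
    if detrend:
        series = sps.detrend(series, axis=1)
    phases = np.angle(sps.hilbert(series, axis=1))
    return order_parameter(phases).r


def classify_volumes(r: np.ndarray, pooled_stats: tuple[float, float] | None = None
                     ) -> np.ndarray:
    """Low/neither/high class per volume with pooled mean -/+ 0.5 SD thresholds."""
    r = np.asarray(r, dtype=float)
    if pooled_stats is None:
        pooled_stats = (float(r.mean()), float(r.std()))
    mean, sd = pooled_stats
    out = np.full(r.shape, "neither", dtype=object)
    out[r < mean - 0.5 * sd] = "low"
    out[r > mean + 0.5 * sd] = "high"
    return out


def occurrence_permutation_test(
    labels: np.ndarray,
    sync_class: np.ndarray,
    k: int | None = None,
    n_perm: int = 20000,
    alpha: float = 0.005,
    seed: int = 0,
    templates: np.ndarray | None = None,
) -> CapResult:
    """Permutation test for dominant CAPs within each synchronization class.

    Null CAP time series are generated by uniformly permuting the labels in
    time (preserving the label multiset); per-class occurrence rates are
    recomputed at the same time points. A template is dominant in a class when
    its observed rate exceeds the one-sided (1 - alpha) null quantile.
    Volumes classed 'neither' enter no test.
    """
    labels = np.asarray(labels, dtype=int)
    sync_class = np.asarray(sync_class, dtype=object)
    if labels.shape != sync_class.shape:
        raise ValueError("labels and sync_class must align per volume")
    if n_perm < 1000:
        raise ValueError("need at least 1000 permutations")
    if k is None:
        k = int(labels.max()) + 1

    rng = np.random.default_rng(seed)
    class_masks = {c: sync_class == c for c in ("low", "high")}
    occurrence, null_q, significant = {}, {}, {}
    for cls, m in class_masks.items():
        if not m.any():
            occurrence[cls] = np.full(k, np.nan)
            null_q[cls] = np.full(k, np.nan)
            significant[cls] = np.zeros(k, dtype=bool)
            continue
        obs = occurrence_rates(labels[m], k)
        null = np.empty((n_perm, k))
        for p in range(n_perm):
            null[p] = occurrence_rates(rng.permutation(labels)[m], k)
        q = np.quantile(null, 1 - alpha, axis=0)
        occurrence[cls] = obs
        null_q[cls] = q
        significant[cls] = obs > q
    return CapResult(
        templates=templates if templates is not None else np.zeros((k, 0)),
        labels=labels, k=k, occurrence=occurrence,
        null_quantiles=null_q, significant=significant, alpha=alpha,
    )
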