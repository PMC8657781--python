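"""Global synchronization metrics: order parameter, PCF, susceptibility, windows.

The instantaneous level of network synchronization is the Kuramoto order
parameter, r(t) e^{i psi(t)} = (1/N) sum_j e^{i theta_j(t)}: r = 0 for phases
spread uniformly on the circle, r = 1 for complete phase locking. Its temporal
variance scaled by network size, PCF = N * Var[r(t)], peaks at the critical
coupling and serves as the criticality indicator; the susceptibility
chi = N * Var[r] / Mean[r] within a window proxies responsiveness to external
perturbation.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np


@dataclasses.dataclass(frozen=True)
class SyncSeries:
    """Instantaneous order parameter r(t) and mean phase psi(t)."""

    r: np.ndarray
    psi: np.ndarray
    fs: float
    n_units: int


@dataclasses.dataclass(frozen=True)
class WindowMetrics:
    window_start: int
    R: float
    chi: float
    smi: float
    s_amp: float
    sync_class: str


def order_parameter(phases: np.ndarray, fs: float = 1.0) -> SyncSeries:
    """Kuramoto order parameter across units at every sample."""
    phases = np.asarray(phases)
    if phases.ndim != 2 or phases.shape[0] < 2:
        raise ValueError("phases must be (n_units >= 2, n_samples)")
    if not np.all(np.isfinite(phases)):
        raise ValueError("phases must be finite")
    mean_vec = np.exp(1j * phases).mean(axis=0)
    return SyncSeries(
        r=np.abs(mean_vec), psi=np.angle(mean_vec), fs=fs, n_units=phases.shape[0]
    )


def pcf(sync: SyncSeries) -> float:
    """Pair correlation function: N times the temporal variance of r(t)."""
    if sync.r.size < 2:
        raise ValueError("need at least 2 samples")
    return float(sync.n_units * sync.r.var())


def susceptibility(r_window: np.ndarray, n_units: int) -> float:
    """chi = N (⟨r²⟩ − ⟨r⟩²) / ⟨r⟩ over a window; NaN when ⟨r⟩ = 0."""
    r = np.asarray(r_window, dtype=float)
    mean = r.mean()
    if mean == 0:
        return float("nan")
    return float(n_units * r.var() / mean)


def windowize(series_length: int, fs: float, window: float, overlap: float) -> list[range]:
    """Half-open sample windows tiling the series with the given overlap.

    Windows are anchored at sample 0 with stride (window - overlap); a final
    partial window is dropped. Returns an empty list when the series is
    shorter than one window.
    """
    if overlap >= window:
        raise ValueError("window must exceed overlap")
    win = int(round(window * fs))
    stride = int(round((window - overlap) * fs))
    return [range(s, s + win) for s in range(0, series_length - win + 1, stride)]


def classify_windows(
    R_values: np.ndarray,
    mode: str = "fixed",
    fixed_low: float = 0.3,
    fixed_high: float = 0.5,
    pooled_stats: tuple[float, float] | None = None,
) -> np.ndarray:
    """Label windows low / neither / high by their mean synchronization R.

    ``fixed`` mode uses the two explicit thresholds (model analysis);
    ``pooled`` uses mean -/+ 0.5*SD of R pooled over all windows, subjects and
    conditions (empirical analysis).
    """
    R = np.asarray(R_values, dtype=float)
    if mode == "fixed":
        low_thr, high_thr = fixed_low, fixed_high
        if not low_thr < high_thr:
            raise ValueError("fixed_low must be below fixed_high")
    elif mode == "pooled":
        if pooled_stats is None:
            pooled_stats = (float(R.mean()), float(R.std()))
        mean, sd = pooled_stats
        low_thr, high_thr = mean - 0.5 * sd, mean + 0.5 * sd
    else:
        raise ValueError("mode must be 'fixed' or 'pooled'")
    out = np.full(R.shape, "neither", dtype=object)
    out[R < low_thr] = "low"
    out[R > high_thr] = "high"
    if R.size and not (np.any(out == "low") or np.any(out == "high")):
        warnings.warn("thresholds classified no window as low or high", stacklevel=2)
    return out


def joint_histogram(
    smi_values: np.ndarray,
    chi_values: np.ndarray,
    smi_bin: float = 0.02,
    chi_bin: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D counts of (SMI, chi) pairs on fixed-width bins anchored at 0.

    Returns (counts, smi_edges, chi_edges) with right-open bins.
    """
    smi_values = np.asarray(smi_values, dtype=float)
    chi_values = np.asarray(chi_values, dtype=float)
    if smi_values.shape != chi_values.shape:
        raise ValueError("inputs must have equal length")
    ok = np.isfinite(smi_values) & np.isfinite(chi_values)
    smi_values, chi_values = smi_values[ok], chi_values[ok]
    if smi_values.size == 0:
        return np.zeros((0, 0)), np.zeros(0), np.zeros(0)

    def edges(vals, width):
        hi = int(np.floor(vals.max() / width)) + 1
        lo = min(0, int(np.floor(vals.min() / width)))
        return width * np.arange(lo, hi + 1)

    se, ce = edges(smi_values, smi_bin), edges(chi_values, chi_bin)
    counts, _, _ = np.histogram2d(smi_values, chi_values, bins=(se, ce))
    return counts.astype(int), se, ce
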