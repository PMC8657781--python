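"""Functional topography: wPLI connectivity, node degrees, and S^amp.

The weighted phase lag index quantifies consistent phase lead/lag between two
signals from the imaginary part of their cross-spectrum only, which makes it
robust to zero-lag mixing (volume conduction): wPLI = |E[Im C_XY]| / E[|Im C_XY|],
1 for a fixed lead/lag relation, 0 for a perfectly balanced one. Node degree is
extracted from per-epoch wPLI matrices binarized at the top 30% of values.

The topographic similarity S^amp(t) is the instantaneous Spearman correlation
between node degrees (structural degree for the model; wPLI-derived degree for
sensor data) and instantaneous amplitudes. Positive S^amp marks hub-dominant
network configurations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps
from scipy import stats


@dataclasses.dataclass(frozen=True)
class WPLIMatrix:
    epoch_matrices: np.ndarray  # (n_epochs, n_units, n_units)
    binarized: np.ndarray  # bool, same shape
    degrees: np.ndarray  # mean degree per unit over epochs


@dataclasses.dataclass(frozen=True)
class TopographyResult:
    s_amp_t: np.ndarray  # instantaneous Spearman correlation per sample
    window_means: np.ndarray  # S^amp per window


def wpli_pair(x: np.ndarray, y: np.ndarray) -> float:
    """wPLI between two band-limited signals via their analytic signals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    cross = sps.hilbert(x) * np.conj(sps.hilbert(y))
    return _wpli_from_imag(cross.imag, float(np.abs(cross).mean()))


def _wpli_from_imag(imag: np.ndarray, scale: float) -> float:
    denom = np.abs(imag).mean()
    # an imaginary part at rounding level of the cross-spectrum magnitude means
    # no lagged interaction is detectable (identical or zero-lag signals)
    if denom <= 1e-12 * scale:
        return 0.0
    return float(np.abs(imag.mean()) / denom)


def wpli_matrix(signals: np.ndarray) -> np.ndarray:
    """All-pairs wPLI of (n_units, n_samples) band-limited signals."""
    analytic = sps.hilbert(np.asarray(signals, dtype=float), axis=1)
    n = analytic.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        cross = analytic[i][None, :] * np.conj(analytic[i + 1 :])
        scales = np.abs(cross).mean(axis=1)
        for off, imag in enumerate(cross.imag):
            out[i, i + 1 + off] = out[i + 1 + off, i] = _wpli_from_imag(imag, scales[off])
    return out


def binarize_top_fraction(mat: np.ndarray, top_fraction: float = 0.30) -> np.ndarray:
    """Keep the strongest ``top_fraction`` of off-diagonal pairs.

    Exactly ceil(top_fraction * n_pairs) pairs are retained; ties at the
    cutoff are broken by ascending pair index so the result is deterministic.
    """
    n = mat.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = mat[iu]
    n_keep = int(np.ceil(top_fraction * vals.size))
    # stable selection: sort by (-value, pair index)
    order = np.lexsort((np.arange(vals.size), -vals))
    keep = order[:n_keep]
    out = np.zeros_like(mat, dtype=bool)
    out[iu[0][keep], iu[1][keep]] = True
    return out | out.T


def wpli_degrees(
    signals: np.ndarray,
    fs: float,
    epoch: float = 30.0,
    epoch_overlap: float = 5.0,
    top_fraction: float = 0.30,
) -> WPLIMatrix:
    """Per-epoch wPLI matrices, binarized degree per channel, mean over epochs."""
    if epoch <= epoch_overlap:
        raise ValueError("epoch must exceed epoch_overlap")
    signals = np.asarray(signals, dtype=float)
    n_samples = signals.shape[1]
    win = int(round(epoch * fs))
    stride = int(round((epoch - epoch_overlap) * fs))
    starts = list(range(0, n_samples - win + 1, stride))
    if not starts:
        raise ValueError("signals shorter than one epoch")
    mats = np.stack([wpli_matrix(signals[:, s : s + win]) for s in starts])
    bins = np.stack([binarize_top_fraction(m, top_fraction) for m in mats])
    degrees = bins.sum(axis=2).mean(axis=0)
    return WPLIMatrix(epoch_matrices=mats, binarized=bins, degrees=degrees)


def instantaneous_spearman(fixed: np.ndarray, samples: np.ndarray) -> np.ndarray:
    """Spearman correlation of a fixed vector with each column of ``samples``.

    Average ranks are used for ties; returns NaN where a column (or the fixed
    vector) is constant.
    """
    fixed = np.asarray(fixed, dtype=float)
    samples = np.asarray(samples, dtype=float)
    n = fixed.size
    if samples.shape[0] != n:
        raise ValueError("row count must match the fixed vector length")
    fr = stats.rankdata(fixed)
    if np.all(fr == fr[0]):
        return np.full(samples.shape[1], np.nan)
    sr = stats.rankdata(samples, axis=0)
    fr_c = fr - fr.mean()
    sr_c = sr - sr.mean(axis=0)
    denom = np.sqrt((fr_c**2).sum() * (sr_c**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (fr_c @ sr_c) / denom
    return rho


def s_amp(
    degrees: np.ndarray,
    amplitudes: np.ndarray,
    windows: list[range] | None = None,
) -> TopographyResult:
    """Topographic similarity: per-sample Spearman(degree, amplitude), window means."""
    s_t = instantaneous_spearman(degrees, amplitudes)
    if windows is None:
        means = np.array([np.nanmean(s_t)]) if s_t.size else np.array([])
    else:
        means = np.array([np.nanmean(s_t[w.start : w.stop]) for w in windows])
    return TopographyResult(s_amp_t=s_t, window_means=means)
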