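"""Ordinal-pattern symbolization and symbolic mutual information (SMI).

Signals are mapped to sequences over the m! rank-order (ordinal) patterns of
m samples separated by a lag of tau samples. SMI between two symbol sequences
is the plug-in mutual information of their empirical joint pattern frequencies
normalized by log(m!), so it lies in [0, 1]; it proxies shared, internally
integrated information between channels. At 500 Hz with m = 3 and tau = 14 the
transform resolves oscillations up to fs/(m*tau) ≈ 11.9 Hz, matching the
4–12 Hz band of interest. For sensor-level signals, pairwise SMI values can be
screened against phase-randomized surrogates (rank-sum test) before averaging.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats


@dataclasses.dataclass(frozen=True)
class SymbolicConfig:
    m: int = 3
    tau_sym: int = 14  # samples at 500 Hz -> 28 ms separation
    n_surrogates: int = 20
    alpha_sig: float = 0.01

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be at least 2")
        if self.tau_sym < 1:
            raise ValueError("tau_sym must be at least 1")

    @property
    def span(self) -> int:
        """Samples covered by one pattern: (m - 1) * tau_sym + 1."""
        return (self.m - 1) * self.tau_sym + 1

    def rescaled(self, fs: float, fs_ref: float = 500.0) -> "SymbolicConfig":
        """Keep the pattern separation fixed in time at a different rate."""
        tau = max(1, int(round(self.tau_sym * fs / fs_ref)))
        return dataclasses.replace(self, tau_sym=tau)


@dataclasses.dataclass(frozen=True)
class SmiResult:
    pairwise: np.ndarray  # symmetric (n_units, n_units), NaN diagonal
    significant_mask: np.ndarray | None
    mean_smi: float


def alphabet_size(m: int) -> int:
    """Number of ordinal patterns of length m: m!."""
    return math.factorial(m)


def max_resolved_frequency(fs: float, m: int, tau_sym: int) -> float:
    """Highest frequency the ordinal transform resolves: fs / (m * tau)."""
    return fs / (m * tau_sym)


def _pattern_codes(m: int) -> dict[tuple[int, ...], int]:
    from itertools import permutations

    return {p: i for i, p in enumerate(permutations(range(m)))}


def symbolize(x: np.ndarray, cfg: SymbolicConfig) -> np.ndarray:
    """Ordinal-pattern symbol sequence of a 1-D signal.

    Position t carries the rank-order pattern of (x_t, x_{t+tau}, ...,
    x_{t+(m-1)tau}); ties are broken by temporal order (argsort stability), a
    measure-zero event for continuous signals. Output length is
    len(x) - (m-1)*tau.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    if x.size < cfg.span:
        raise ValueError(f"signal shorter than one pattern span ({cfg.span} samples)")
    return _symbolize_rows(x[None, :], cfg)[0]


def _symbolize_rows(xs: np.ndarray, cfg: SymbolicConfig) -> np.ndarray:
    """Vectorized symbolization of each row of a (n_units, n_samples) array."""
    m, tau = cfg.m, cfg.tau_sym
    n_units, n_samples = xs.shape
    L = n_samples - (m - 1) * tau
    if L < 1:
        raise ValueError("signals shorter than one pattern span")
    # stack the lagged copies: (n_units, L, m)
    lags = np.stack([xs[:, k * tau : k * tau + L] for k in range(m)], axis=-1)
    ranks = np.argsort(np.argsort(lags, axis=-1, kind="stable"), axis=-1, kind="stable")
    # encode the rank tuple as an integer, then map to a dense 0..m!-1 code
    base = m ** np.arange(m - 1, -1, -1)
    raw = (ranks * base).sum(axis=-1)
    codes = _pattern_codes(m)
    lut = np.full(m**m, -1, dtype=np.int64)
    for pat, idx in codes.items():
        lut[int((np.array(pat) * base).sum())] = idx
    return lut[raw]


def smi(xs: np.ndarray, ys: np.ndarray, m: int = 3) -> float:
    """Normalized symbolic mutual information between two symbol sequences.

    Plug-in MI of the empirical joint symbol distribution divided by log(m!).
    """
    xs = np.asarray(xs, dtype=np.int64)
    ys = np.asarray(ys, dtype=np.int64)
    if xs.shape != ys.shape:
        raise ValueError("sequences must have equal length")
    if xs.size == 0:
        raise ValueError("sequences must be non-empty")
    if ys.tobytes() < xs.tobytes():
        xs, ys = ys, xs  # canonical order makes smi(x, y) == smi(y, x) bitwise
    a = alphabet_size(m)
    joint = np.bincount(xs * a + ys, minlength=a * a).reshape(a, a) / xs.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])).sum())
    return mi / np.log(a)


def _pairwise_smi_window(sym: np.ndarray, m: int) -> np.ndarray:
    """All-pairs normalized SMI from a (n_units, L) symbol block (matmul trick)."""
    n_units, L = sym.shape
    a = alphabet_size(m)
    onehot = np.zeros((n_units, a, L), dtype=np.float32)
    u_idx = np.repeat(np.arange(n_units), L)
    onehot[u_idx, sym.ravel(), np.tile(np.arange(L), n_units)] = 1.0
    flat = onehot.reshape(n_units * a, L)
    # float32 matmul accumulates exact integer counts (<= L < 2^24), cast up after
    joint = (flat @ flat.T).astype(np.float64).reshape(n_units, a, n_units, a) / L
    p_marg = onehot.astype(np.float64).mean(axis=2)  # (n_units, a)
    denom = p_marg[:, :, None, None] * p_marg[None, None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / denom)
    mi = np.nansum(np.where(joint > 0, terms, 0.0), axis=(1, 3)) / np.log(a)
    np.fill_diagonal(mi, np.nan)
    return mi.astype(float)


def phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Surrogate with the same amplitude spectrum and randomized Fourier phases."""
    x = np.asarray(x, dtype=float)
    n = x.size
    spec = np.fft.rfft(x)
    phases = rng.uniform(0, 2 * np.pi, spec.size)
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0  # Nyquist bin must stay real
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n)


def pairwise_smi(
    signals: np.ndarray,
    windows: list[range],
    cfg: SymbolicConfig,
    surrogate_filter: bool = False,
    seed: int = 0,
) -> list[SmiResult]:
    """Per-window all-pairs SMI, optionally screened by phase-randomized surrogates.

    With ``surrogate_filter``, each pair's real per-window SMI values are
    compared (Wilcoxon rank-sum across windows) with the pooled per-window SMI
    of ``cfg.n_surrogates`` phase-randomized copies; pairs not significant at
    ``cfg.alpha_sig`` are excluded from every window mean. Returns one
    :class:`SmiResult` per window.
    """
    signals = np.asarray(signals, dtype=float)
    n_units = signals.shape[0]
    if not windows:
        return []
    win_len = len(windows[0])
    if win_len < cfg.span:
        raise ValueError("window shorter than one pattern span")

    def window_matrices(sig):
        sym = _symbolize_rows(sig, cfg)
        L = win_len - (cfg.span - 1)
        return np.stack([_pairwise_smi_window(sym[:, w.start : w.start + L], cfg.m)
                         for w in windows])

    real = window_matrices(signals)  # (n_windows, n_units, n_units)

    mask = None
    if surrogate_filter:
        rng = np.random.default_rng(seed)
        surr = []
        for _ in range(cfg.n_surrogates):
            s = np.stack([phase_randomize(ch, rng) for ch in signals])
            surr.append(window_matrices(s))
        surr = np.concatenate(surr)  # pooled over surrogates
        mask = np.zeros((n_units, n_units), dtype=bool)
        iu = np.triu_indices(n_units, k=1)
        for i, j in zip(*iu):
            stat = stats.ranksums(real[:, i, j], surr[:, i, j], alternative="greater")
            if stat.pvalue < cfg.alpha_sig:
                mask[i, j] = mask[j, i] = True

    results = []
    for w_idx in range(len(windows)):
        mat = real[w_idx]
        if mask is not None:
            vals = mat[np.triu_indices(n_units, k=1)][mask[np.triu_indices(n_units, k=1)]]
        else:
            vals = mat[np.triu_indices(n_units, k=1)]
        mean = float(np.mean(vals)) if vals.size else float("nan")
        results.append(SmiResult(pairwise=mat, significant_mask=mask, mean_smi=mean))
    return results
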