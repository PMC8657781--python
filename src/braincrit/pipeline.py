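"""End-to-end experiment orchestration: model sweeps and signal analyses.

``run_model_experiment`` sweeps the (lambda, K) plane, computes per-window
R / chi / SMI / S^amp for every cell, correlates them across windows, and
locates the critical coupling (PCF maximum) per lambda. ``run_signal_experiment``
applies the same windowed metrics to multichannel band-limited signals per
condition, classifies windows with pooled thresholds, and compares low vs high
classes with rank-based tests.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .simulate import SimulationResult, StuartLandauParams, sweep
from .smi import SymbolicConfig, pairwise_smi
from .sync import classify_windows, order_parameter, pcf, susceptibility, windowize
from .synthetic import Connectome
from .topography import s_amp as compute_s_amp
from .topography import wpli_degrees


@dataclasses.dataclass
class RunConfig:
    """All analysis settings in one validated place; YAML round-trippable."""

    band: tuple[float, float] = (4.0, 12.0)
    window: float = 0.25
    overlap: float = 0.05
    threshold_mode: str = "fixed"  # 'fixed' for model, 'pooled' for signals
    fixed_low: float = 0.3
    fixed_high: float = 0.5
    smi: SymbolicConfig = dataclasses.field(default_factory=SymbolicConfig)
    surrogate_filter: bool = False
    epoch: float = 30.0
    epoch_overlap: float = 5.0
    top_fraction: float = 0.30
    dwell_x_min: float = 0.2
    rereference: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("band must be an increasing positive pair")
        if self.overlap >= self.window:
            raise ValueError("window must exceed overlap")
        if self.threshold_mode not in ("fixed", "pooled"):
            raise ValueError("threshold_mode must be 'fixed' or 'pooled'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(d["band"])
        if isinstance(d.get("smi"), dict):
            d["smi"] = SymbolicConfig(**d["smi"])
        return cls(**d)


def cell_window_metrics(
    res: SimulationResult,
    degrees: np.ndarray,
    window: float = 0.25,
    overlap: float = 0.05,
    smi_cfg: SymbolicConfig | None = None,
) -> pd.DataFrame:
    """Per-window R, chi, SMI and S^amp for one simulation."""
    cfg = smi_cfg or SymbolicConfig()
    phases = res.phases
    amps = res.amplitudes
    sync = order_parameter(phases, fs=res.fs)
    wins = windowize(phases.shape[1], res.fs, window, overlap)
    # SMI is computed on the real part of z, the model's analogue of the
    # band-limited activity signal symbolized in sensor data
    smi_res = pairwise_smi(res.z.real, wins, cfg)
    topo = compute_s_amp(degrees, amps, wins)
    rows = []
    for w, sm, sa in zip(wins, smi_res, topo.window_means):
        r_win = sync.r[w.start : w.stop]
        rows.append({
            "window_start": w.start,
            "R": float(r_win.mean()),
            "chi": susceptibility(r_win, sync.n_units),
            "smi": sm.mean_smi,
            "s_amp": float(sa),
        })
    return pd.DataFrame(rows)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return float("nan")
    return float(stats.spearmanr(a[ok], b[ok]).statistic)


def run_model_experiment(
    conn: Connectome,
    lam_grid: np.ndarray,
    K_grid: np.ndarray,
    n_seeds: int = 5,
    params: StuartLandauParams | None = None,
    cfg: RunConfig | None = None,
) -> dict:
    """Sweep cells, correlate windowed metrics, and locate the critical K.

    Returns a dict with ``cells`` (per-cell table: mean_R, pcf, rho_R_smi,
    rho_R_chi, rho_R_samp pooled over seeds), ``windows`` (all per-window
    rows), and ``critical`` (PCF-argmax K per lambda). Divergent cells are
    reported and skipped.
    """
    params = params or StuartLandauParams()
    cfg = cfg or RunConfig()
    table = sweep(
        conn, lam_grid, K_grid, n_seeds, params,
        base_seed=cfg.seed, window=cfg.window, overlap=cfg.overlap,
        collect_windows=True, smi_cfg=cfg.smi,
    )
    cell_rows, window_rows = [], []
    for (lam, K), grp in table.groupby(["lam", "K"]):
        ok = grp[~grp["diverged"]]
        if ok.empty:
            cell_rows.append({"lam": lam, "K": K, "diverged": True})
            continue
        wins = pd.concat(
            [w.assign(seed=s) for w, s in zip(ok["windows"], ok["seed"])],
            ignore_index=True,
        )
        wins["sync_class"] = classify_windows(
            wins["R"].to_numpy(), mode=cfg.threshold_mode,
            fixed_low=cfg.fixed_low, fixed_high=cfg.fixed_high,
        )
        wins.insert(0, "K", K)
        wins.insert(0, "lam", lam)
        window_rows.append(wins)
        R = wins["R"].to_numpy()
        cell_rows.append({
            "lam": lam, "K": K, "diverged": False,
            "mean_R": float(ok["mean_R"].mean()),
            "pcf": float(ok["pcf"].mean()),
            "rho_R_smi": _spearman(R, wins["smi"].to_numpy()),
            "rho_R_chi": _spearman(R, wins["chi"].to_numpy()),
            "rho_R_samp": _spearman(R, wins["s_amp"].to_numpy()),
            "n_windows": len(wins),
        })
    cells = pd.DataFrame(cell_rows)
    critical = (
        cells[~cells["diverged"]]
        .loc[lambda d: d.groupby("lam")["pcf"].idxmax()]
        [["lam", "K", "pcf"]]
        .rename(columns={"K": "critical_K"})
        .reset_index(drop=True)
    )
    windows = pd.concat(window_rows, ignore_index=True) if window_rows else pd.DataFrame()
    return {"cells": cells, "windows": windows, "critical": critical}


def representative_critical_cell(result: dict, pcf_fraction: float = 0.75) -> float:
    """Pick a near-critical coupling whose windows populate both sync classes.

    Among sweep cells with PCF within ``pcf_fraction`` of the maximum, returns
    the K whose low/high window counts are most balanced — the natural choice
    for illustrating the two information modes, since exactly at the PCF
    argmax the mean synchronization can sit low enough that high-R windows
    are rare.
    """
    cells = result["cells"]
    windows = result["windows"]
    ok = cells[~cells["diverged"]]
    candidates = ok[ok["pcf"] >= pcf_fraction * ok["pcf"].max()]
    best_K, best_balance = None, -1
    for K in candidates["K"]:
        w = windows[np.isclose(windows["K"], K)]
        counts = w["sync_class"].value_counts()
        balance = min(counts.get("low", 0), counts.get("high", 0))
        if balance > best_balance:
            best_K, best_balance = float(K), balance
    return best_K


def bandpass(signals: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signals, dtype=float), axis=-1)


def artifact_reject(
    signals: np.ndarray,
    fs: float,
    sd_threshold: float = 100.0,
    amp_threshold: float = 300.0,
    reject_span: float = 0.2,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Excise blocks with excessive amplitude or channel standard deviation.

    The series is tiled into ``reject_span``-second blocks; a block is removed
    when any sample exceeds ``amp_threshold`` or any channel's within-block SD
    exceeds ``sd_threshold``. Returns the cleaned (concatenated) signals and
    the list of removed (start, stop) sample spans. Warns when more than half
    the data is removed.
    """
    if sd_threshold <= 0 or amp_threshold <= 0:
        raise ValueError("thresholds must be positive")
    signals = np.asarray(signals, dtype=float)
    n = signals.shape[1]
    span = max(1, int(round(reject_span * fs)))
    keep, removed = [], []
    for start in range(0, n, span):
        block = signals[:, start : start + span]
        bad = np.any(np.abs(block) > amp_threshold) or np.any(block.std(axis=1) > sd_threshold)
        if bad:
            removed.append((start, min(start + span, n)))
        else:
            keep.append(block)
    if sum(e - s for s, e in removed) > n / 2:
        warnings.warn("more than 50% of the data was rejected", stacklevel=2)
    cleaned = np.concatenate(keep, axis=1) if keep else signals[:, :0]
    return cleaned, removed


def signal_window_metrics(
    signals: np.ndarray,
    fs: float,
    cfg: RunConfig,
    degrees: np.ndarray | None = None,
) -> pd.DataFrame:
    """Windowed R/chi/SMI/S^amp of one recording (channels x samples).

    Signals are optionally re-referenced to the common average (sensor-level
    recordings carry a reference electrode; source-level or synthetic signals
    are reference-free, so the default is off), band-passed, and phases /
    amplitudes taken from the analytic signal. When ``degrees`` is None the
    wPLI degree of this recording is used (baseline-condition convention).
    """
    signals = np.asarray(signals, dtype=float)
    if cfg.rereference:
        signals = signals - signals.mean(axis=0, keepdims=True)
    filt = bandpass(signals, fs, cfg.band)
    analytic = sps.hilbert(filt, axis=1)
    phases = np.angle(analytic)
    amps = np.abs(analytic)
    if degrees is None:
        degrees = wpli_degrees(filt, fs, cfg.epoch, cfg.epoch_overlap,
                               cfg.top_fraction).degrees
    sync = order_parameter(phases, fs=fs)
    smi_cfg = cfg.smi.rescaled(fs)
    wins = windowize(phases.shape[1], fs, cfg.window, cfg.overlap)
    smi_res = pairwise_smi(filt, wins, smi_cfg,
                           surrogate_filter=cfg.surrogate_filter, seed=cfg.seed)
    topo = compute_s_amp(degrees, amps, wins)
    rows = []
    for w, sm, sa in zip(wins, smi_res, topo.window_means):
        r_win = sync.r[w.start : w.stop]
        rows.append({
            "window_start": w.start,
            "R": float(r_win.mean()),
            "chi": susceptibility(r_win, sync.n_units),
            "smi": sm.mean_smi,
            "s_amp": float(sa),
        })
    return pd.DataFrame(rows)


def run_signal_experiment(
    conditions: dict[str, list[tuple[np.ndarray, float]]],
    cfg: RunConfig | None = None,
    baseline: str | None = None,
) -> dict:
    """Windowed metrics, pooled-threshold classes, and low/high comparisons.

    ``conditions`` maps condition name to a list of (signals, fs) recordings.
    wPLI degrees are extracted from the ``baseline`` condition (first listed
    when None) and reused for the perturbed conditions, subject-matched by
    list position. Classification pools R over all windows of all conditions
    (mean -/+ 0.5 SD). Per-condition PCF, rank-sum comparisons of SMI and chi
    between classes, and joint-histogram inputs are returned.
    """
    cfg = cfg or RunConfig(threshold_mode="pooled")
    if not conditions:
        raise ValueError("need at least one condition")
    names = list(conditions)
    baseline = baseline or names[0]

    def _preproc(sig, fs):
        sig = np.asarray(sig, dtype=float)
        if cfg.rereference:
            sig = sig - sig.mean(axis=0, keepdims=True)
        return bandpass(sig, fs, cfg.band)

    baseline_degrees: dict[int, np.ndarray] = {}
    for idx, (sig, fs) in enumerate(conditions[baseline]):
        baseline_degrees[idx] = wpli_degrees(
            _preproc(sig, fs), fs, cfg.epoch, cfg.epoch_overlap, cfg.top_fraction
        ).degrees

    frames = []
    pcfs = []
    for name in names:
        for idx, (sig, fs) in enumerate(conditions[name]):
            deg = baseline_degrees.get(idx)
            wm = signal_window_metrics(sig, fs, cfg, degrees=deg)
            wm.insert(0, "subject", idx)
            wm.insert(0, "condition", name)
            frames.append(wm)
            filt = _preproc(sig, fs)
            sync = order_parameter(np.angle(sps.hilbert(filt, axis=1)), fs=fs)
            pcfs.append({"condition": name, "subject": idx, "pcf": pcf(sync)})
    windows = pd.concat(frames, ignore_index=True)
    pooled = (float(windows["R"].mean()), float(windows["R"].std()))
    windows["sync_class"] = classify_windows(
        windows["R"].to_numpy(), mode="pooled", pooled_stats=pooled
    )

    comparisons = []
    for name in names:
        sub = windows[windows["condition"] == name]
        lo = sub[sub["sync_class"] == "low"]
        hi = sub[sub["sync_class"] == "high"]
        row = {"condition": name, "n_low": len(lo), "n_high": len(hi)}
        for col in ("smi", "chi"):
            a = lo[col].dropna().to_numpy()
            b = hi[col].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2:
                row[f"{col}_p"] = float("nan")
                row[f"{col}_stat"] = float("nan")
            else:
                res = stats.ranksums(b, a)
                row[f"{col}_stat"] = float(res.statistic)
                row[f"{col}_p"] = float(res.pvalue)
        comparisons.append(row)

    return {
        "windows": windows,
        "pcf": pd.DataFrame(pcfs),
        "pooled_stats": pooled,
        "comparisons": pd.DataFrame(comparisons),
    }
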