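# braincrit

Criticality and internal/external information-processing modes in oscillatory
brain networks.

Conscious brains appear to operate near a critical point — the border between
incoherent and globally synchronized dynamics — where the moment-to-moment
fluctuation of network synchronization is largest. `braincrit` implements a
complete pipeline for studying what those fluctuations do: it simulates
delay-coupled Stuart–Landau oscillators on a structural connectome, quantifies
windowed synchronization and criticality, and tests whether windows of high and
low synchronization carry distinct information-processing preferences — an
*internal* mode (high shared information, low sensitivity to perturbation) and
an *external* mode (the reverse) — together with their network signatures. It
is aimed at computational neuroscientists working on whole-brain models,
criticality, and states of consciousness.

## The model and the measures

Each of N network nodes follows the normal form of a supercritical Hopf
bifurcation with delayed diffusive coupling and additive noise:

    dz_j/dt = (λ + iω_j − |z_j|²) z_j + K Σ_k A_jk [ z_k(t − τ_jk) − α z_j ] + β ξ_j(t)

with natural frequencies ω_j ~ N(10 Hz, 0.5 Hz), binary structural adjacency
A_jk, conduction delays τ_jk = D_jk/s (distances in mm, s = 7 m/s), diffusive
weight α = 0.5 and noise amplitude β = 0.05, integrated by the
Stratonovich–Heun scheme at dt = 1 ms and output at 500 Hz. An uncoupled node
settles on a limit cycle of radius √λ (λ > 0) or decays to a focus (λ < 0).

From the phases θ_j(t) the pipeline computes, in sliding sub-second windows
(250 ms, 50 ms overlap):

- **r(t), R** — Kuramoto order parameter and its window mean (level of
  synchronization);
- **PCF** = N·Var[r(t)] — pair correlation function, maximal at criticality;
- **χ** = N·Var[r]/Mean[r] per window — susceptibility to external input;
- **SMI** — symbolic mutual information between channel pairs (ordinal
  patterns, m = 3, lag 14 samples ≙ 28 ms, normalized by log 3! ), a proxy for
  internally shared information;
- **S^amp** — instantaneous Spearman correlation between node degree and
  oscillation amplitude: positive values mark hub-dominant configurations.

Downstream analyses include wPLI-based functional degrees for sensor data,
power-law vs exponential fits of hub-dominance dwell times, and a co-activation
pattern (CAP) analysis of parcel-level BOLD volumes with a permutation test of
per-synchronization-class occurrence rates. A synthetic-data module generates
hub-heterogeneous connectomes, surrogate multichannel EEG with controllable
synchronization, and parcel BOLD with planted CAP structure, so that the whole
chain is testable without external data.

## Worked example

```python
import numpy as np
import braincrit as bc

conn = bc.generate_connectome(n_nodes=78, density=0.15, hub_fraction=0.15, seed=1)
params = bc.StuartLandauParams(lam=0.6, t_saturate=15.0, t_analyze=30.0)
out = bc.run_model_experiment(
    conn,
    lam_grid=np.array([0.6]),
    K_grid=np.linspace(0.02, 0.40, 20),
    n_seeds=3,
    params=params,
    cfg=bc.RunConfig(seed=1),
)
cells = out["cells"]
crit = cells.loc[cells["pcf"].idxmax()]
print(f"critical K = {crit['K']:.2f}  PCF = {crit['pcf']:.2f}")
print(f"rho(R, SMI)   = {crit['rho_R_smi']:+.2f}")
print(f"rho(R, chi)   = {crit['rho_R_chi']:+.2f}")
print(f"rho(R, S^amp) = {crit['rho_R_samp']:+.2f}")
```

prints (a few minutes on one CPU):

```
critical K = 0.24  PCF = 1.21
rho(R, SMI)   = +0.60
rho(R, chi)   = -0.73
rho(R, S^amp) = +0.77
```

The PCF peaks at an interior coupling K — the critical point of this
connectome. There, window-level synchronization correlates positively with
shared information and hub dominance and negatively with susceptibility:
highly synchronized windows prefer internal integration on a hub-dominant
configuration, incoherent windows are maximally receptive to external input.
Away from the peak all three correlations shrink.

The same metrics run on recordings via `run_signal_experiment`, and the CLI
exposes the stages as subcommands (`braincrit sweep`, `metrics`, `dwell`,
`caps`, `report`).

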