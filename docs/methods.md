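# Methods

This note records the models, conventions and numerical choices behind
`braincrit`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and where genuinely open choices were decided.

## Network model

The dynamics are delay-coupled Stuart–Landau oscillators,

dz_j/dt = (λ + iω_j − |z_j|²) z_j + K Σ_k A_jk [z_k(t − τ_jk) − α z_j] + β ξ_j(t),

the normal form of a supercritical Hopf bifurcation per node, with homogeneous
bifurcation parameter λ and coupling K, diffusive weight α ∈ [0, 1]
(α = 0 behaves like direct chemical input, α = 1 like a gap junction;
default 0.5), and complex Gaussian white noise of amplitude β = 0.05.
Natural frequencies are drawn from N(10 Hz, 0.5 Hz) and converted to rad/s;
negative draws are redrawn rather than clipped to preserve normality.
Delays are τ_jk = D_jk/s with inter-node distances in millimetres and
conduction speed s = 7 m/s, giving millisecond-scale delays on a
centimetre-scale network.

Numerics: Stratonovich–Heun predictor–corrector at dt = 1 ms (the noise
increment, with independent real and imaginary parts of standard deviation
β√dt, enters the predictor and the final update identically); delays are
rounded to the nearest integration step and served from a ring buffer; the
history before t = 0 holds the random initial state (uniform on the complex
unit disc under the run seed) and is washed out by a discarded 15 s saturation
period. Output is decimated to 500 Hz — harmless aliasing-wise because the
dynamics live near 10 Hz. The integrator flags any non-finite or
energy-bound-violating state as an explicit divergence error naming (λ, K,
seed). Halving dt changes the time-averaged order parameter by < 2% on a
20-node test network; with β = 0 trajectories are bit-for-bit reproducible.
Where the integration step is applied matters only at O(dt²) for the noise
placement; the convergence test above bounds its effect.

## Synchronization, criticality, susceptibility

The order parameter r(t)·e^{iψ(t)} = (1/N) Σ_j e^{iθ_j(t)} is computed from
arg z for model signals and from the analytic-signal angle of band-passed
(4–12 Hz, zero-phase Butterworth) recordings — one phase convention reused by
every module. PCF ≡ N·Var[r(t)] over the analysis segment indexes proximity
to criticality; the susceptibility of a window is χ = N·Var[r]/Mean[r] using
raw within-window moments of r(t) (the within-window formula as stated, not
window-mean-subtracted residuals). Windows are 250 ms with 50 ms overlap,
anchored at sample 0, half-open, final partial window dropped.

Window classes: the model analysis uses fixed thresholds R < 0.3 (low) and
R > 0.5 (high); empirical-style analyses pool R over all windows, subjects and
conditions and use mean ∓ 0.5·SD (the standard deviation, chosen for
dimensional consistency).

## Symbolic mutual information

Signals are symbolized by the rank-order pattern of m = 3 samples at lag
τ = 14 samples (28 ms at 500 Hz, rescaled to preserve 28 ms at other rates);
the transform resolves oscillations up to fs/(m·τ) ≈ 11.9 Hz. Rank ties are
broken by temporal order — a measure-zero event for continuous signals. SMI is
the plug-in mutual information of the empirical joint pattern distribution,
normalized by log 3! so it lies in [0, 1]; it is computed for all unordered
pairs per window (a one-hot matrix product accumulates the exact joint counts)
and averaged. In the model the symbolized signal is Re z, the model's analogue
of the band-limited activity signal; the order parameter still uses arg z.
For sensor-style runs, pairs can be screened against 20 phase-randomized
surrogates (per pair, real per-window SMI vs pooled surrogate per-window SMI,
one-sided Wilcoxon rank-sum at α = 0.01); screening defaults off for model
runs and on is available for empirical-style runs. The internal arguments of
`smi` are put in a canonical order so that smi(x, y) == smi(y, x) exactly.

## Topography

wPLI uses the imaginary cross-spectrum of Hilbert analytic signals:
|E[Im C]| / E[|Im C|], with the convention that an imaginary part at rounding
level of the cross-spectrum magnitude (identical or zero-lag signals) yields
0 — no lagged interaction is detectable. Sensor degrees come from per-epoch
(30 s, 5 s overlap) wPLI matrices binarized at the top 30% of off-diagonal
values, ties broken by stable pair index so results are reproducible; degrees
are extracted from a designated baseline condition and reused for perturbed
conditions. Model degrees are the structural row sums. S^amp(t) is the
Spearman correlation (average ranks for ties) between the fixed degree vector
and instantaneous amplitudes at each sample, then averaged per window — the
per-sample-then-average order, not the average-amplitude alternative.

## Dwell times and heavy tails

Dwell times are maximal runs of S^amp(t) > 0; runs touching a series boundary
are censored (their lengths are lower bounds) and discarded. The tail
x ≥ x_min (default 200 ms) is fitted by maximum likelihood to a continuous
power law, β̂ = 1 + n / Σ ln(x_i/x_min), and to a shifted exponential on the
same support; the loglikelihood difference normalized by its sample standard
deviation (Vuong's variance-corrected ratio test) gives R_L — positive when
the power law fits better — with a two-sided normal p-value. x_min is fixed,
not estimated. The fitting machinery is implemented in-package from these
closed forms and validated against simulated Pareto and exponential draws
(bias < 0.05 at n = 2000; sign-classification accuracy > 95% at n = 5000).

## Co-activation patterns

Parcel-level volumes pooled across subjects and conditions are clustered with
k-means (Euclidean distance, 10 restarts, seeded). The cluster count is scored
by (CC + UU)/(2·CU) on per-group CAP occurrence-rate vectors, where
similarity is inverse distance; it is aggregated as the ratio of the mean
across-group distance to the mean within-group distance, which is equivalent
at the optimum and robust to a single zero within-pair distance. Per-volume
synchronization r comes from the order parameter across parcel phases
(analytic signal of each linearly detrended parcel time course); volumes are
classed low/high at pooled mean ∓ 0.5·SD, the 'neither' band is excluded
from testing. Dominance per class is assessed against a null that uniformly
permutes CAP labels in time (preserving the label multiset), one-sided at
α = 0.005 with 20 000 permutations by default.

## Synthetic data: what it emulates, what it does not

- **Connectome**: a spatially embedded random graph (nodes uniform in a
  150 mm cube, distance-penalized wiring at the requested density) with a
  designated hub set boosted until each hub reaches twice the overall median
  degree. It reproduces the two features downstream code needs — degree
  heterogeneity for S^amp and millimetre distances for delays — not any real
  anatomy. Its default density (0.15) makes it better connected than a real
  DTI network, which shifts the synchronization transition to lower K; the
  sweep grid (20 values, 0.02–0.40, the canonical 0.02 resolution) was chosen
  to span that transition.
- **Surrogate EEG**: each channel mixes a shared narrowband (4–12 Hz)
  oscillation with an independent one, w(t)·common + (1 − w(t))·own + noise;
  the windowed order parameter tracks w(t) monotonically. This shared-source
  model is rank-one: common-average re-referencing would annihilate its
  synchronized component exactly, which real multi-source EEG does not suffer.
  Re-referencing is therefore a config option (`RunConfig.rereference`),
  default off, applied before band-pass when enabled for sensor-referenced
  recordings. The surrogate has no topography, no 1/f background, and no
  artifacts — passing tests show the metric chain is correct, not that real
  EEG will behave identically.
- **Parcel BOLD**: each volume is one template plus Gaussian noise; volumes of
  the high-synchronization class render their template with a spatially
  uniform sign (global co-activation), low-class volumes with a sign-balanced
  mixed pattern, so the volume-wise synchronization classifier separates the
  classes by construction. `default_cap_templates` makes mixed templates
  sign-balanced explicitly, because a magnitude-skewed mixed template can be
  almost as phase-coherent as a uniform one.

All generators are bitwise-reproducible under a fixed seed.

## Problem sizes and defaults used by the shipped analyses

The reduced sweep run by the test suite and by `scripts/acceptance.py` uses a
78-node connectome at λ = 0.6, 20 couplings from 0.02 to 0.40, 3–5 frequency
seeds, and 30 s of analyzed dynamics per run after 15 s of saturation — sizes
chosen so the whole analysis reproduces the qualitative structure (interior
PCF maximum; positive R–SMI and R–S^amp and negative R–χ correlations peaking
there) on a single CPU in minutes. The full-scale protocol (λ from −3.2 to 3.2
in steps of 0.2, K from 0 to 1 in steps of 0.02, 100 frequency seeds, 60 s
analysis) is available through the same `sweep`/`run_model_experiment`
interface. Exactly at the PCF argmax the mean synchronization can sit low
enough that high-R windows are rare; `representative_critical_cell` picks,
among cells within 75% of the PCF maximum, the coupling with the most balanced
low/high window counts for mode-contrast illustrations.

## Known limitations

- Quantities that depend on the original anatomical network (the precise
  critical coupling K ≈ 0.42 reported for the 78-node DTI connectome and the
  peak correlation magnitudes there) are not reproducible on the synthetic
  connectome; only the sign/peak structure is.
- Heterogeneous per-node λ or K, alternative synchrony measures (PLV,
  coherence), directed symbolic measures, automatic x_min selection, and
  voxel-level fMRI are out of scope; CAP analysis operates on parcels.
- Rank-based condition comparisons are reported pairwise without joint
  multiple-comparison correction.
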