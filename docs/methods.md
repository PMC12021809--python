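# Methods

`fibrotwin` is a desk-scale re-creation of an in-silico pipeline for
predicting atrial-fibrillation (AF) ablation outcomes from fibrosis imaging:
synthetic fibrosis maps from a denoising diffusion model, quality control by
spatial statistics, biophysical AF simulation on fibrotic tissue, feature
extraction, and a Siamese fusion classifier. This note records the models,
the parameter choices, and — importantly — what the desk-scale world can and
cannot establish.

## Fibrosis maps and spatial statistics

All maps are 96×96 pixel fields (configurable) in image-intensity-ratio
(IIR) units: LGE-MRI intensity over blood-pool intensity, ≈1 for healthy
myocardium, >1.2 for dense fibrosis.

**Noise baselines** are i.i.d. standard-normal draws min–max rescaled to
[0.25, 1.75] IIR. Over 100 maps the grand mean is ≈1.0 IIR with pixel SD
≈0.2 — matching the summary statistics of clinical baselines.

**LGE-like fixtures** stand in for clinical maps: a Gaussian random field
(white noise smoothed at half the correlation length, default 8 px) is
rank-matched to a lognormal marginal with mean 1.1 IIR and SD 0.25, clipped
to [0, 2]. This reproduces per-map mean, spread, right skew, and patchy
suprathreshold clusters (5–40 % of pixels above 1.22 IIR), but *not* the
anatomy-locked spatial layout of real atrial fibrosis (posterior-wall
predominance, vein ostia patterns). Tests green on fixtures certify the
pipeline's mechanics, not clinical realism.

**Shannon entropy.** The literal mass-weighted formula
SE = −(1/log₂N) Σ P log₂ P with P the pixel's share of total intensity is
maximized by *uniform* maps: after heavy smoothing, pure noise scores
SE ≈ 1, structured maps slightly less, which cannot reproduce the reported
ordering (noise ≈ 0.33 far below structured ≈ 0.8). Which estimator actually
separates the two is ambiguous in the published description, so three are
shipped:

* `weighted_eq34` — the literal formula (kept for reference, ordering
  inverted by construction);
* `histogram` — gray-level histogram entropy over [0, 2], normalized by
  log₂ of the pixel count;
* `binary_fraction` (default) — binary entropy of the fraction of pixels
  above 1.22 IIR, which reproduces the reported magnitudes
  (suprathreshold fractions ≈0.0/0.25 for smoothed noise/structured maps).

The quality filter rejects maps with SE ≤ 0.66 under the configured
estimator, computed after Gaussian smoothing with σ = 3 px ("kernel 3" read
as σ = 3: only heavy smoothing is consistent with Moran's I ≈ 0.978 on
smoothed noise, since the lag-1 autocorrelation of σ-smoothed white noise is
exp(−1/4σ²) ≈ 0.973 at σ = 3). Absolute SE values are estimator-dependent
and are not acceptance-gated; the ordering and the filter semantics are.

**Moran's I** uses row-normalized rook (4-neighbor) weights on the smoothed
map; edge pixels keep their reduced neighborhoods. The checkerboard gives
−1 exactly, i.i.d. noise ≈ −1/(n−1), smoothed noise ≈ 0.973.

## Diffusion model

Standard DDPM: forward kernel q(x_t|x_{t−1}) = N(√(1−β_t)x_{t−1}, β_t I)
with the closed-form marginal used for training; an ε-predicting U-Net
(3 resolution levels, single-head self-attention at levels 2 and 3,
sinusoidal timestep embedding, zero-initialized output head); MSE loss;
ancestral sampling with σ_t² = β_t and no noise at t = 1. Maps train in
[−1, 1] (IIR [0, 2] mapped linearly); samples are mapped back and clipped.

Reference configuration: T = 1000 linear β ∈ [10⁻⁴, 2×10⁻²], Adam 2.5×10⁻⁵,
500 epochs, channels (64, 128, 256). Desk-scale runs shrink everything
(16×16 maps, T = 300 with β ∈ [5×10⁻⁴, 0.05] so that ᾱ_T < 10⁻³ still
holds, channels (12, 24, 48), a few hundred epochs at lr ~10⁻³) because the
networks run on a numpy autodiff core (no GPU frameworks in the
environment). Two additions proved necessary for usable samples at this
scale and are defaults: a warmup exponential moving average of the weights
(d_t = min(d_max, (1+t)/(10+t)); short runs track live weights) and an
optional per-epoch learning-rate decay. ε̂ errors accumulate roughly
linearly along the reverse chain, so sample quality demands training close
to the memorization floor of the tiny dataset; the end-to-end test verifies
that ≥80 % of 50 samples from a fixture-trained model pass the SE filter.

## Tissue remodeling rules

Structural: conductivity bins 0.40/0.31/0.28/0.19 S/m for IIR in
[0, 0.9)/[0.9, 1.4)/[1.4, 1.6)/[1.6, ∞). The published bins use strict
inequalities, leaving the edges unassigned; edges join the higher-fibrosis bin so the
mapping is total and deterministic.

Ionic, three multiplicative layers on the Courtemanche maxima:
baseline g_Na×2 (upstroke velocity), g_K1×0.8 (restitution); AF electrical
remodeling g_to×0.5, g_Kur×0.5, g_CaL×0.3 (applied everywhere in AF
simulations); fibrotic remodeling g_K1×0.5, g_Na×0.6, g_CaL×0.5 above a
fibrosis threshold. The fibrotic *remodeling* threshold is not
published; it reuses the ablation-mask threshold 1.22 IIR for internal
consistency. Layers are pure multiplications, hence order-independent.

Ablation masks: the LA always carries two non-conducting PVI annuli
(centers (0.2, 0.8) and (0.8, 0.8) in unit coordinates, radius 0.12, width
2 px — the unfolded-geometry placement is a package choice, configurable;
ring interiors stay conducting but isolated). Strategies add all pixels
with IIR > 1.22 in the LA and/or RA; the RA mask under PVI-only is all
zeros. Masks nest: PVI ⊆ PVI+LA ⊆ PVI+LA+RA.

## Electrophysiology

The Courtemanche–Ramirez–Nattel human atrial model (21 states) supplies
I_ion; published parameters and initial conditions, with the per-node
multipliers above. Two integration paths share one rate evaluation:
Rush–Larsen (exact exponential gate relaxation, forward-Euler V and
concentrations) for production, and a plain derivative vector for
`scipy.integrate` as an integrator-independent oracle. The production
stepper tabulates the 12 voltage-gated steady states/decay factors and six
voltage-dependent current factors on a 0.05 mV grid with linear
interpolation (≈6× faster; agrees with the exact kernel to <10⁻⁴ mV over an
action potential, and with LSODA to ~1 mV away from the upstroke). The
modified conductances shift the true resting potential to ≈ −79.7 mV;
`equilibrated_state` provides the settled rest for quiescence-sensitive
uses.

Monodomain: ∂V/∂t = ∇·(σ/χ ∇V) − I_ion/C_m on one flat sheet per atrium
(the 3D bilayer is out of scope), 5-point flux-form Laplacian with
arithmetic-mean interface conductivity, no-flux boundaries, non-conducting
nodes carry no flux and receive no stimulus. Three point bridges couple the
LA right edge to the RA left edge (configurable, disable-able). Operator
splitting: reaction at dt = 0.02 ms (default), diffusion every 0.1 ms.
χ (surface-to-volume × capacitance) is the single free constant, calibrated
once so planar CV at 0.40 S/m is 0.81 m/s on a 100-node, 0.25 mm reference
strand (χ ≈ 2.28 S·ms·m⁻¹·mm⁻²); CV is measured between probes 20 nodes
from the ends, from −40 mV upstroke crossings. Calibration excludes the
fibrotic ionic layer: the printed CVs are structural-remodeling
calibrations, and g_Na×0.6 would depress them below the printed values.
Measured CVs at 0.31/0.28/0.19 S/m land 4–9 % below the printed
0.74/0.71/0.58 m/s — the monodomain square-root law plus grid dispersion at
0.25 mm versus the published 3D-mesh calibrations — within the ±10 % acceptance band,
and converging toward √σ scaling as the strand is refined.

AF initiation seeds an Archimedean multi-spiral phase field
φ = Σ_c (±θ_c − k·r_c), wrapped (summing, not patching per core, avoids
spurious seam singularities; chirality alternates), mapped onto a
precomputed single-cell limit cycle; cores are seeded-uniform in the sheet
interior, two per atrium for the default four spirals. An episode is
*sustained* if the latest −40 mV upstroke falls at ≥60 % of its duration.

**Desk-scale honesty.** On affordable 2D sheets (≤48×48 nodes, ≤24 mm) the
AF-remodeled wavelength (CV×APD ≳ 20–60 mm) exceeds the domain: spiral
waves meander and self-terminate within ~0.2–0.3 s even with coupling
scaled down 32-fold (the smoke profile's χ). Consequently every
post-ablation episode terminates and the smoke cohort's ground-truth labels
are degenerate (all "terminated"). `run_experiment` detects this, skips
classifier training, and reports NaN AUCs with a `labels_degenerate` flag;
the classifier's training/evaluation path is exercised end-to-end by
injecting synthetic cohorts with controlled labels. Label variety at the
reference scale requires the full 15 s bilayer simulations, which are out
of desk scope by design.

## Features and labels

Dominant frequency: per node, detrended Hann-windowed periodogram of the
1 kHz-resampled voltage; DF is the peak frequency at ≤20 Hz; nodes that
never cross −40 mV get DF = 0. Traces shorter than 1 s are rejected (1 Hz
resolution floor); sub-second smoke episodes are zero-order-hold padded.

Phase: analytic-signal (Hilbert) angle of the mean-removed voltage.
Singularities: ±2π winding of wrapped phase differences around each 2×2
plaquette, charge ±1. PSD: per-pixel count of detections over all frames,
Gaussian-smoothed (σ = 2 px); pre-smoothing mass equals the detection count.

Ground truth: per node, the time of the last action-potential peak (local
maxima above −40 mV, 50 ms refractory) as a fraction of the recording,
0 for silent nodes, NaN-excluded for non-conducting nodes; averaged over
both atria. Terminated iff the average ≤ 0.6 ("0–60 %" read as inclusive).

Classifier input per atrium: five 96×96 channels — PVI mask, PVI+fibrosis
mask, PSD (divided by its own max; zeros if empty), DF (divided by 20 Hz),
fibrosis (divided by 2). The RA's PVI channel is identically zero to keep
both Siamese heads shape-compatible.

## Classifier

One shared compact CNN backbone (`densenet_like`: three 2-layer dense
blocks; or `convnext_like`: three conv stages with GELU and pointwise
expansion) maps each stack to a 32-latent. Fusion: `concat`;
`moab` — the four outer arithmetic operations (sum, product, difference,
ε-stabilized division, ε = 10⁻⁶) stacked as 32×32 channels and reduced by a
conv; `foaa` — the same outer operations computed between learned queries
of one atrium and keys of the other serve as attention scores
(softmax-normalized over the key axis), weighting the values; both
directions use separate projections (cross-attention is
direction-sensitive), the four attended outputs are summed and added to the
latents via a skip connection, then 1D conv → FC 48 → FC 30 → layer norm →
dropout → ReLU. All fusion modes end in the same 30-wide tail and a final
4-logit sigmoid layer, so swapping fusion changes nothing else — including
the backbone initialization (comparison fairness, asserted in tests).

Training: summed BCE, Adam. The full-cohort reference rate is 4×10⁻⁷;
desk cohorts of tens of cases use 10⁻³ (the reference rate cannot move a
network in 50 epochs on 40 samples). Early stopping (patience 20) on
validation mean ROC-AUC, falling back to validation BCE when every output
is single-class. k-fold CV merges cases sharing a fibrosis map into groups
(union-find) and deals groups to folds, so no map id crosses folds.

## Cohort pipeline

Map pools per split mirror the 80/10/10 leakage split (maps reused within,
never across splits); the comparison training split draws noise maps or
externally sampled synthetic maps. Non-sustained pre-ablation cases are
kept (with labels computed), matching the reference design; a config switch
excludes them. Post-ablation episodes restart from the pre-ablation final
state with the masks applied — the restart convention is not published and is
chosen here; continuity of the handoff is exact (a split run
bit-matches an unsplit one). Every artifact traces to the global seed
through per-purpose derived sub-seeds recorded in the cohort manifest.

Profiles: `reference` (400/400/100/100 cases, 15 s, 192×192 grids — preserved
in configuration, never run here), desk default (40/40/10/10, 2 s), and
`smoke` (48×48 maps, 0.2 s episodes, χ×32, 10 cases) sized for minutes on
one CPU.

## Known limitations

* 2D sheets with point bridges; no fiber anisotropy, regional ionic
  heterogeneity, or 3D bilayer geometry.
* Fixture maps match clinical summary statistics, not clinical spatial
  patterns; DDPM quality is judged only through the SE filter.
* Desk-scale AF is non-sustained by physics; classifier results on
  simulated desk cohorts are therefore structural tests, not performance
  claims. The reported reference AUCs (≈0.95) are explicitly out of scope.
* Forward-Euler concentrations limit dt to ≲0.05 ms; the solver checks for
  instability and names the offending step.
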