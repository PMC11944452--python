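# Methods

This note documents the models, conventions and design choices behind
`lignosense`, in the package's own terms. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

One *condition* is an HTL (hydrothermal liquefaction) temperature in
[240, 410] °C; the four anchors 250/300/350/400 °C are the measured
conditions. Per condition the pipeline handles:

* a raw thermogram — % of initial mass vs. furnace temperature, ~22,000
  points spanning roughly 40–787 °C;
* three FT-IR transmittance replicates on a fixed 3476-point wavenumber
  grid (649.8934–4000.6047 cm⁻¹), with occasional >100% values from
  instrument noise;
* a GC-MS derivative table — 114 compounds in 9 groups, each a % of total;
  detected totals fall short of 100% (compounds lost to poor volatility,
  thermal degradation or weak ionization).

All tables are CSV (UTF-8, dot decimal, one header row); floats are
written at `%.17g` so write→read round trips are exact to well below
1e-12. Validation is total: every malformed input maps to a named rule
violation, never a crash.

## Preprocessing

**TGA.** Readings outside [40, 760] °C are discarded (above ~760 °C the
signal is dominated by instrument noise), then averaged in centered 1 °C
bins [t−0.5, t+0.5), one value per integer °C (721 values). Centered bins
make each bin value an unbiased local mean; the operation is idempotent on
already-binned data. Empty bins — impossible on dense instrument exports,
possible on sparse synthetic input — are filled by linear interpolation
between the nearest non-empty bins. The **information-loss audit** is the
Wasserstein-1 distance between the empirical distributions of raw (within
the window) and resampled mass values on the mass-fraction scale.

**FT-IR.** Per wavenumber: mean over replicates → clip at 100 → subtract
from 101 → floor at 10⁻⁶ → log. The clip handles noise overshoots above
100% transmittance; the offset maps a fully transmitting point to
log(1) = 0; the floor is retained verbatim for fidelity even though it is
unreachable after clipping (101 − min(·, 100) ≥ 1). The log base is
decimal — transmittance/absorbance conventions are decimal — and
configurable. Outputs are bounded in [0, log₁₀ 101] for any non-negative
input.

**GC-MS.** Detected derivative percentages are summed per group; an
"Other" class absorbs `1 − Σ group fractions`, so every composition is a
point on the 10-simplex. Undetected rows contribute nothing to group sums;
they are exactly the mass the Other class represents.

**Grid-size convention.** The 40–760 °C window at 1 °C yields 721 TGA
values, and that is the package default (`tga_dim=721`, configurable).

## Study simulator

The lab data are not publicly deposited, so the simulator generates data
with the study's statistical structure at any condition; its defaults
*are* the study conditions used throughout the tests.

* **TGA**: `mass(T) = 100 − Σ aᵢ(τ)·σ((T−cᵢ(τ))/wᵢ)` with
  τ = (T_HTL−250)/150 and three logistic steps — moisture (~3% at 80 °C,
  width 12 °C), main devolatilization (35%+3τ at 330+20τ °C, width 35 °C)
  and a slow char step (15% at 550+10τ °C, width 60 °C) — over a ≥45%
  residue plateau; Gaussian noise σ = 0.05%; points every 0.034 °C from
  ~39.6 to ~787.6 °C (≈22,000). Start/end jitter is a deterministic
  function of the condition, so noiseless curves are seed-independent.
* **FT-IR**: baseline 98.5% plus a slow 1% sinusoidal ripple minus
  Gaussian dips at the standard lignin bands (3400 O–H, 2930 C–H, 1730
  C=O, 1600/1510 aromatic skeletal, 1215, 1030 cm⁻¹) whose depths drift
  linearly in τ; replicate noise σ = 0.3%. The ripple plus noise makes
  some points exceed 100%, the artifact the preprocessing clip exists for.
* **GC-MS**: group fractions are a softmax of quadratic-in-τ logits chosen
  so syringyl/guaiacyl decline and light fractions rise with temperature;
  fractions are split over 114 rows by fixed geometric within-group
  weights. The detection shortfall u(τ) is a deterministic quadratic
  spanning ≈[0.088, 0.139] (detected totals ≈86–91%); a seeded greedy pass
  flags rows undetected until the flagged mass reaches 100·u(τ).

The **ground-truth oracle** runs the noiseless simulation through the
standard preprocessing, so oracle vectors live exactly on the model
scales; for GC-MS it uses the closed-form composition
(`gᵢ(τ)(1−u(τ))`, Other = u(τ)). It is seed-independent and used only for
evaluation, never training.

What the simulator does **not** emulate: Arrhenius kinetics, baseline
drift/scatter in FT-IR beyond the smooth ripple, correlated instrument
noise, mass-spectral fragmentation, and real biological variability
between lignin batches. Tests passing on synthetic data therefore
demonstrate that the machinery is correct and that the method works when
its smoothness assumptions hold — not that it generalizes to any
particular real lignin substrate.

## Generation models

One decoder-style conditional CNN per modality, input = the scalar τ
(length-1 sequence, so the Conv1d stacks act as learned per-channel
mixings of the condition):

| modality | feature extractor | head |
|---|---|---|
| TGA | Conv(1→16)+ReLU, Conv(16→32)+ReLU | Flatten, Linear(32→1024)+ReLU, Linear(1024→721) |
| FT-IR | Conv(1→16), Conv(16→32), Conv(32→64), each +ReLU | Flatten, Linear(64→1024)+ReLU, Dropout(0.3), Linear(1024→3476) |
| GC-MS | Conv(1→64)+ReLU ×3 | GAP, Linear(64→128)+ReLU, Linear(128→10), Softmax |

All kernels 3, stride 1, padding 1. The generators are deterministic (no
noise channel): the study produces one dataset per temperature. Training
targets are scale-matched — TGA mass % divided by 100, FT-IR log values
as-is, GC-MS fractions as-is — keeping MSE magnitudes comparable.

**Training regime** (uniform across all models): Adam, initial learning
rate 10⁻³, ×0.1 after 75 epochs, batch 32, 100 epochs. With four anchor
pairs each epoch is a single saturated batch. Before optimization the
output layer's bias is initialized to the training-target mean (log-mean
for the softmax head): a standard output-prior initialization that spends
the fixed budget on learning the condition dependence rather than
rediscovering the mean curve.

## MVAE-MoE predictor

Encoders (per modality): Conv(1→16)+ReLU+AvgPool(4),
Conv(16→32)+ReLU+AvgPool(4), Flatten, Linear(→256)+ReLU, Linear(256→2·16)
split into (μ, log σ²). The average pooling between conv blocks is the
standard treatment of long 1-D spectra; without it the FT-IR flatten layer
alone would hold ~28M parameters and dominate runtime for no accuracy
benefit (`encoder_pool=1` disables it). Encoder inputs are z-scored per
feature over the training set (statistics stored with the model); the raw
modality scales differ by orders of magnitude in per-feature variance.

**Fusion**: product of Gaussian experts including a standard-normal prior
expert — precisions add (`p = 1 + Σ e^{−logvar_i}`), means are
precision-weighted, fused logvar = −log p. A concatenation+linear fusion
is available as `fusion="concat"`. **Sampling**: z = μ + e^{logvar/2}·ε
(reparameterization trick) during training; inference uses μ directly
(one deterministic prediction per condition).

**Decoders**: Linear(16→1024)+ReLU+Linear(1024→dim), reconstructing the
raw modality scale. **MoE head**: 4 experts
(Linear(16→64)+ReLU+Linear(64→10)+Softmax) mixed convexly by a gating
network (Linear(16→32)+ReLU+Linear(32→4)+Softmax). Mixing simplex points
convexly (rather than mixing logits) guarantees the simplex invariant for
any gate. `n_experts=4` and `latent_dim=16` are deliberately small for a
10-sample training set; both are configurable.

**Loss**: `L = L_recon^TGA + L_recon^FT-IR + L_pred + L_KL`, unweighted.
The data terms are sample-indexed MSE, `(1/n) Σᵢ ‖yᵢ − ŷᵢ‖²` — squared
error summed over a vector's components, averaged over samples — and the
KL is `−½ Σ_dims (1 + log σ² − μ² − σ²)` averaged over the batch. The
matching sum-over-dimensions convention on both sides is the standard VAE
balance; normalizing the data terms by vector length instead would let the
KL dominate and collapse the posterior to the prior within the fixed
100-epoch budget, leaving the predictor stuck at the mean composition.
Expert output biases are initialized to the log of the training-mean
composition, so training starts from the best constant predictor and
improves from there.

**Training set**: the 4 anchor triplets plus 6 generated triplets at
260/280/315/345/365/390 °C (10 total). Note the evaluation temperatures
coincide with the augmentation temperatures — the augmented points are
themselves model output, so this is in-sample with respect to the
generators; the honest held-out check is the comparison against the
simulator oracle in `workflow.compare_to_baselines`.

## Evaluation protocol

References at unmeasured temperatures are linear interpolations
`y = y₁ + (x−x₁)/(x₂−x₁)·(y₂−y₁)` between the nearest bracketing anchors
(260, 280 from 250/300; 315, 345 from 300/350; 365, 390 from 350/400).
Metrics per temperature, elementwise across a vector's components: MAE,
R² = 1 − SS_res/SS_tot (may be negative), Pearson r with population
moments (the ratio is convention-invariant). Wasserstein-1 between
equal-size samples is the mean absolute difference of sorted values;
unequal sizes use the ECDF-difference integral. Metrics are computed on
the preprocessed scales the models emit. Degenerate rows (a constant
prediction has undefined correlation) report NaN rather than aborting a
report.

## Numerical choices

* Network parameters and activations are float32 with in-place Adam
  updates; data processing, metrics and closed-form checks are float64.
* Log-variances are clipped to ±12 for stability; gradients are zeroed on
  the clipped branch.
* The step schedule is 1-indexed: epochs 1–75 at 10⁻³, 76–150 at 10⁻⁴.
* Seeds: every workflow stage derives its seed from the global seed by a
  fixed offset (simulate +0, generators +101/102/103, predictor +201);
  sub-streams are spawned via `numpy.random.SeedSequence`. Identical
  configurations yield bit-identical artifacts and manifests.
* Loss-history totals are stored as the exact sum of their four
  components, so additivity holds to float accuracy on every record.

## Known limitations

* Four anchors cannot identify nonlinear composition–temperature
  relationships; everything between anchors is effectively a smooth
  interpolation, and the evaluation references are themselves linear
  interpolations.
* The predictor's advantage over the constant-mean baseline on synthetic
  data is real but modest; with 10 training samples and 100 epochs this is
  expected, and per-seed variability remains visible.
* The simulator's smooth, low-dimensional temperature dependence is
  friendlier than real lignin chemistry; transfer to other biomass types
  or instruments is untested by construction.
* Per-compound (114-dimensional) prediction is out of scope; the model
  predicts the 10 group fractions only.
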