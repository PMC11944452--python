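# lignosense

Predicting GC-MS compositional profiles of depolymerized lignin from TGA
thermograms and FT-IR spectra.

## The problem

Lignin depolymerized by hydrothermal liquefaction (HTL) yields a complex
mixture of aromatic monomers (syringyl, guaiacyl units), poly- and other
aromatics, alkanes, fatty acids, alcohols and glycerol-derived compounds.
GC-MS quantifies this composition precisely but is expensive per sample;
TGA and FT-IR are cheap. `lignosense` implements a deep-learning pipeline
that predicts the 10-group GC-MS composition (9 compound groups plus an
"Other" class that closes the detection shortfall to 100%) from a TGA
thermogram and an FT-IR spectrum, for lab campaigns that measured only a
few anchor HTL temperatures (250/300/350/400 °C).

The pipeline has four parts:

1. **Preprocessing.** TGA curves (~22,000 points) are clipped to 40–760 °C
   and averaged in 1 °C bins (721 values). FT-IR replicates are merged by
   `D = log₁₀(max(101 − min(mean(Dᵢ), 100), 10⁻⁶))` per wavenumber
   (3476 values) — the clip handles noise pushing transmittance above
   100%. GC-MS derivative tables (114 compounds, 9 groups) are aggregated
   to group fractions with an "Other" closure class, so compositions live
   on the 10-simplex. A Wasserstein-1 audit quantifies the information the
   TGA resampling discards.
2. **Conditional CNN generators.** One decoder-style 1-D CNN per modality
   maps the scalar normalized condition τ = (T_HTL − 250)/150 to a full
   modality vector (channel stacks 16/32 for TGA, 16/32/64 + dropout 0.3
   for FT-IR, 64/64/64 + global average pooling + softmax for GC-MS).
   Trained on the anchors (MSE, Adam 10⁻³, ×0.1 after 75 epochs, batch 32,
   100 epochs), they synthesize training triplets at unseen temperatures.
3. **MVAE-MoE predictor.** Convolutional encoders map each modality to a
   diagonal-Gaussian posterior (μ, log σ²); a product-of-experts with a
   standard-normal prior fuses them (`precision = 1 + Σ σᵢ⁻²`); the
   reparameterized latent z feeds two reconstruction decoders and a
   mixture-of-experts head whose gating network convexly combines expert
   simplex outputs. The loss is the unweighted sum
   `L = L_recon^TGA + L_recon^FT-IR + L_pred + L_KL` with
   `L_KL = −½ Σ (1 + log σ² − μ² − σ²)`. Inference uses the fused
   posterior mean (no sampling).
4. **Evaluation.** No measurements exist at intermediate temperatures, so
   references there are linear interpolations between the bracketing
   anchors; rows report MAE, R² and Pearson r per temperature.

Because the original lab data are not deposited, the package bundles a
seeded simulator that reproduces the *statistical structure* of the study
(logistic-step thermograms, Gaussian-dip IR spectra with >100% noise
excursions, softmax-in-τ group compositions with an 8–14% detection
shortfall) plus a noiseless ground-truth oracle for honest held-out
evaluation. Everything — models included — runs on numpy; no GPU or
deep-learning framework is required.

## Worked example

```python
from lignosense.workflow import ExperimentConfig, run_full_experiment, compare_to_baselines

cfg = ExperimentConfig(global_seed=0, output_dir="demo_run")
result = run_full_experiment(cfg)
print("TGA resampling audit (Wasserstein-1, mass fraction):")
for temp, w in sorted(result.audit.items()):
    print(f"  {temp:.0f} °C: {w:.2e}")
print("GC-MS prediction vs interpolated references:")
for row in result.prediction_rows:
    print(f"  {row.temperature_c:.0f} °C  MAE={row.mae:.4f}  R2={row.r2:.3f}  r={row.pearson:.3f}")
df = compare_to_baselines(result)
print("predictor mean MAE vs oracle: %.4f (mean-composition baseline: %.4f)"
      % (df.predictor_mae.mean(), df.mean_baseline_mae.mean()))
```

prints

```
TGA resampling audit (Wasserstein-1, mass fraction):
  250 °C: 2.27e-04
  300 °C: 2.29e-04
  350 °C: 2.30e-04
  400 °C: 2.33e-04
GC-MS prediction vs interpolated references:
  260 °C  MAE=0.0277  R2=0.843  r=0.921
  280 °C  MAE=0.0170  R2=0.931  r=0.968
  315 °C  MAE=0.0079  R2=0.989  r=0.995
  345 °C  MAE=0.0127  R2=0.973  r=0.987
  365 °C  MAE=0.0149  R2=0.964  r=0.983
  390 °C  MAE=0.0189  R2=0.945  r=0.975
predictor mean MAE vs oracle: 0.0159 (mean-composition baseline: 0.0171)
```

The audit says 1 °C resampling moves the mass-value distribution by only
~2×10⁻⁴ on the mass-fraction scale (information loss is negligible). The
per-temperature rows score the predicted composition against the
interpolated reference: MAE is the mean absolute error per group fraction
(0.008–0.028, i.e. under three percentage points per group), and R²/r say
how much of the compositional variation the prediction captures. The last
line compares against the simulator's noiseless ground truth: the trained
predictor outperforms the naive constant mean-composition baseline.

The same pipeline is scriptable from the shell:

```bash
lignosense simulate --anchors 250,300,350,400 --seed 0 --out raw
lignosense preprocess --in raw --out proc
lignosense train-gen --modality all --data proc --seed 0 --out gens
lignosense generate --models gens --temps 260,280,315,345,365,390 --out aug
lignosense train-pred --data proc --extra aug --seed 0 --out model
lignosense predict --model model --tga aug/tga_resampled_315.csv \
    --ftir aug/ftir_preprocessed_315.csv --out comp.csv
lignosense run --out fullrun --seed 0       # everything at once
```

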