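# qeeg — quantitative-EEG biomarkers of cognitive decline in Parkinson's disease

Cognitive decline in Parkinson's disease (normal cognition → mild
cognitive impairment → dementia) leaves a characteristic signature in the
resting EEG: the spectrum *slows*.  Theta power rises, the relative beta
share falls, and summary slowing indices — the **alpha/theta ratio**
P<sub>α</sub>/P<sub>θ</sub> and the **spectral power ratio**
SPR = (P<sub>α</sub>+P<sub>β</sub>)/(P<sub>δ</sub>+P<sub>θ</sub>) —
decrease, while theta-band phase coupling between posterior and frontal
regions increases.  This package turns raw 19-channel, 10–20-montage,
eyes-closed EEG into those biomarkers and runs the group comparison
machinery a clinical study would apply to them.  It is aimed at
neurophysiology researchers who want the full chain — preprocessing,
spectral and connectivity feature extraction, and statistics —
reproducible from one seeded configuration.

The pipeline:

1. **Preprocess** — 50 Hz zero-phase FIR notch, 0.1 Hz FIR high-pass,
   5-s epochs, detrend + baseline correction, annotation-based epoch
   removal, cross-validated global peak-to-peak artifact rejection,
   average reference.
2. **Spectral** — DPSS multitaper PSD (NW = 4, 7 tapers) over 0.5–45 Hz,
   averaged over epochs; absolute (dB re 1 µV²) and relative (%) power in
   delta/theta/alpha(low, high)/beta/gamma; alpha/theta ratio and SPR;
   global, regional, and lateralised-regional aggregates; electrode-map
   export.
3. **Connectivity** — phase lag index PLI = |⟨sign Δφ⟩| per band
   (theta–gamma), global and between lateralised region pairs; PLI is
   blind to zero-lag (volume-conducted) coupling by construction.
4. **Statistics** — assumption-gated three-group comparison
   (Shapiro–Wilk + group-size chi-square → Kruskal–Wallis with ε², or
   Levene → ANOVA / Welch-ANOVA with η²), Holm-corrected pairwise
   post-hocs, and scale-aware correlations (Pearson/Spearman).

Because clinical recordings are not distributable, the package includes a
**synthetic cohort generator** (`qeeg.synthetic`): 1/f background plus
narrowband oscillations, lagged inter-regional coupling, and blink and
movement artifacts with ground-truth annotations.  Its `paper-like`
preset emulates a 43/30/25 three-group cohort in which the dementia group
shows elevated theta (+3.2 dB absolute, ≈ +1.1 relative points), a
reduced alpha/theta ratio (≈ −0.12), and stronger posterior–frontal theta
coupling.  Every stage of the pipeline is validated against this known
truth — see `docs/methods.md` for the model and its limitations.

## Worked example

Generate a small synthetic cohort (12 subjects per group, 60-s recordings
at 128 Hz) and push it through the whole pipeline:

```python
import pandas as pd
from qeeg import paper_like_spec, generate_cohort, PipelineConfig, run_pipeline

spec = paper_like_spec(sizes={"PD-CogN": 12, "PD-MCI": 12, "PD-D": 12},
                       duration_s=60.0, fs=128.0, seed=7)
cohort = generate_cohort(spec)
cfg = PipelineConfig(seed=7, crop=(0.0, 60.0), pli_bands=("theta",),
                     scopes=("global",), min_kept_epochs=5)
result = run_pipeline(cfg, recordings=cohort.iter_recordings(),
                      metadata=cohort.metadata)
comp = result.comparisons.set_index("metric")
print(comp.loc[["abs_theta", "rel_theta", "alpha_theta_ratio", "spr"],
               ["mean_PD-CogN", "mean_PD-D", "test", "p_value",
                "effect_size", "p_holm_PD-CogN_vs_PD-D"]].round(4))
```

which prints:

```
                   mean_PD-CogN  mean_PD-D   test  p_value  effect_size  p_holm_PD-CogN_vs_PD-D
metric
abs_theta               18.6286    21.9772  anova   0.0033       0.2923                  0.0016
rel_theta               23.9798    25.0118  anova   0.1082       0.1261                  0.1845
alpha_theta_ratio        1.2978     1.1701  anova   0.0109       0.2396                  0.0309
spr                      2.0036     1.8881  anova   0.0715       0.1477                  0.1074
```

Reading this: global absolute theta power is 3.3 dB higher in the
dementia group and survives the Holm-corrected pairwise comparison
(p = 0.0016, η² = 0.29); the alpha/theta ratio drops by 0.13 and is also
significant (p = 0.031); the relative-theta and SPR shifts point the
right way but 12 subjects per group are not enough to establish them —
with the full 43/30/25 structure they are recovered reliably (see the
acceptance script below).  `result.biomarkers` holds the subject-level
long-format table, `result.epoch_status` the per-epoch rejection
bookkeeping, and `result.log` every assumption-check decision.

The same run works from the shell on EDF files:

```sh
qeeg generate --preset paper-like --seed 7 --outdir cohort/ --duration 60 --fs 128
qeeg run --config cfg.yaml        # input_dir: cohort/, output_dir: results/
qeeg stats --biomarkers results/biomarkers.csv --out stats.csv
```

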