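# gfptract

Quantification and inference for **in vivo GFP-sperm occupancy** of the
insect female reproductive tract.

In sperm-storage experiments (e.g. in the red flour beetle *Tribolium
castaneum*), males carry sperm whose heads express GFP, and
fluorescence micrographs of the dissected female tract are used to
measure where, and how much, sperm is stored — in the whole tract and
in the long-term storage organ, the spermatheca — under crossed
treatments such as male heat stress, prior female mating, and time
since insemination. A companion paternity assay scores the proportion
of offspring sired by the focal male (P2) against a competitor carrying
a dominant antenna marker.

`gfptract` provides the full measurement-and-analysis chain as a
tested, reusable library:

- **`gfptract.simulate`** — ground-truthed synthetic data: two-channel
  (green 520 nm / red 624 nm + bright-field) 14-bit micrographs with
  punctate sperm-head signal, chitinous autofluorescence with a known
  green/red crosstalk ratio *k*, uneven illumination and shot + read
  noise; and factorial experiment tables with multiplicative treatment
  effects and beta-binomially overdispersed proportions.
- **`gfptract.imaging`** — the quantification chain: rolling-ball
  background subtraction (grayscale opening with a 25 px ball),
  autofluorescence correction via a sperm-free reference ROI
  (factor = Int_GFP / Int_Auto, then `green − factor · red`),
  intermodes histogram thresholding, and per-ROI occupancy metrics
  (mean/median intensity, percentage cover, presence).
- **`gfptract.glm`** — the inference stage: logit-linked quasi-binomial
  GLMs for percentage cover entered as cbind(percent, 100 − percent),
  identity-linked Gaussian GLMs for mean intensity, Pearson dispersion
  φ = Σr²/df, drop1 likelihood-ratio tests (F for continuous
  responses, scaled-deviance χ² for proportions), pruning of
  non-significant two-way interactions, Wald post-hoc contrasts with
  percent changes, pseudo-R² (explained deviance), Spearman
  correlations and mean ± s.e. summaries.
- **`gfptract.pipeline` / `gfptract` CLI** — end-to-end orchestration
  (`simulate`, `quantify`, `analyze`, `full`) over 16-bit TIFFs, ROI
  JSON, CSV metrics and a reproducibility manifest.

## The model in brief

Percentage cover *y* ∈ [0, 100] per female × site is analysed as

    cbind(y, 100 − y) ~ thermal + female_status + time   (+ 2-way interactions)

with a logit link and quasi-binomial dispersion; mean fluorescence
intensity uses an identity-link Gaussian GLM on the same design. Terms
are judged by drop1 LLRTs — F = (ΔD/Δdf)/φ for continuous responses,
ΔD/φ ~ χ² for proportions — interactions are dropped when p ≥ 0.05
(mains always retained), and treatment effects are summarised as Wald
z/t statistics and response-scale percent changes relative to the
control / virgin / 30 min reference levels. Paternity counts
(filiform vs clubbed offspring) get the same quasi-binomial treatment
with male treatment as the single factor.

## Worked example

```python
from gfptract import (ImagingParams, simulate_tract_image, quantify_sample,
                      DesignSpec, EffectSpec, simulate_experiment,
                      analyze_occupancy)

# one synthetic sample through the imaging chain
stack, rois, truth = simulate_tract_image(ImagingParams(seed=42))
q = quantify_sample(stack, rois)
print(f"correction factor: {q.correction.factor:.3f} (truth {truth.crosstalk_k})")
m = q.metrics["total_tract"]
print(f"tract cover: {m.percent_cover:.1f}% "
      f"(truth {truth.true_cover_percent['total_tract']:.1f}%), "
      f"mean intensity {m.mean_intensity:.0f}, presence {m.presence}")

# a full factorial experiment through the GLM chain
records, _ = simulate_experiment(DesignSpec(), EffectSpec(), seed=42)
results = analyze_occupancy(records)
rep = results.reports[("total_tract", "cover")]
c = next(c for c in rep.contrasts if c.factor == "thermal")
print(f"thermal contrast: {c.percent_change:+.1f}% "
      f"(z = {c.statistic:.1f}, p = {c.p_value:.3g}); "
      f"phi = {rep.dispersion_phi:.2f}, pseudo-R2 = {rep.pseudo_r2:.2f}")
```

prints

```
correction factor: 0.308 (truth 0.3)
tract cover: 10.5% (truth 12.7%), mean intensity 515, presence True
thermal contrast: -21.8% (z = -4.2, p = 2.6e-05); phi = 6.51, pseudo-R2 = 0.55
```

The correction factor recovers the injected crosstalk ratio to a few
percent; measured cover tracks the rendered sperm-footprint truth to
about two percentage points; and the fitted contrast estimates the
injected heat effect for this single draw (the generator's default
thermal multiplier on tract cover is 0.68, i.e. −32% on average — any
one simulated experiment scatters around that). `results.to_table()`
returns the flat per-term summary (factor, df, χ²/F, p, family,
pseudo-R²) with one residual row per model.

The same chain runs from the shell:

```bash
gfptract full --seed 7 --out runs/full          # 190 females, images + GLMs
gfptract quantify --input runs/full/images --out metrics.csv
gfptract analyze --metrics runs/full/metrics.csv --out runs/analysis
```

Real micrographs are consumed the same way: a directory of per-sample
`<id>_{brightfield,green,red}.tif` (16-bit, 14-bit range) plus
`<id>_rois.json` with `total_tract`, `spermatheca` and
`autofluorescence_reference` polygons.

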