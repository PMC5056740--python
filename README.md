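# ricetpe

Crop-model-based varietal evaluation for rainfed rice: drought TPE
classification, yield-stability indicators and cluster ranking over
genotype-by-environment (GEI) simulation output.

## The problem

Multi-environment trials (MET) evaluate rice varieties in at most a handful
of locations, but rainfed drought environments vary enormously across a
region and between seasons. A process-based crop model, run for every
variety over thousands of gridded environments, many sowing dates and many
years under both irrigated and rainfed water management, gives the
genotype-by-environment interaction at a scale field trials cannot reach.
This package implements the analysis chain that turns such simulation output
into a varietal evaluation:

1. **Matrix organisation and cleaning.** Per environment, irrigated yield
   `PY`, rainfed yield `AY` and the stage drought indices `AV` (vegetative)
   and `AR` (reproductive) are organised as sowing date × year matrices per
   variety and stacked across varieties. Any sowing date with a zero
   irrigated yield is unsuitable for rice and its row is removed from all
   four matrices.
2. **Best rainfed season.** Per sowing date *i*, the mean rainfed yield
   RYᵢ = Σᵥ Σⱼ aᵢⱼᵥ / (m·c) and its coefficient of variation CVᵢ are
   computed over m years and c varieties; the best season is the date with
   the smallest CV among the three highest RY.
3. **TPE classification.** From the best-season arrays, f₇₅ is the
   frequency at which rainfed:irrigated yield falls below 0.75. Severity is
   S (f₇₅ ≥ 50%), M (25% ≤ f₇₅ < 50%) or L (f₇₅ < 25%); timing is
   vegetative (1) if av̄ < ar̄, reproductive (2) if ar̄ < 0.9·av̄, else
   mixed (3) — giving nine target-population-of-environment classes
   L1 … S3.
4. **Stability indicators.** Per variety, over the best-season yield
   matrices YP = |yp_jk| and YA = |ya_jk| (year × environment):
   γ (mean rainfed yield), δ = RMS(yp − ya)/mean(yp) (drought yield
   penalty), λ = CV of YA (overall stability), φ (CV of environment means,
   spatial) and ψ (CV of year means, temporal). By the law of total
   variance λ ≥ φ and λ ≥ ψ.
5. **Ranking.** Varieties are clustered (Ward linkage on z-scored
   indicator profiles, γ negated so lower is better everywhere) into five
   groups ranked 1 (best) to 5 (worst), per drought-severity scope, per
   timing scope and overall.
6. **Model certification statistics.** For measured/simulated pairs:
   OLS slope/intercept/R², Welch's t-test p, normalised RMSE
   (RMSEn = RMS(Y−X)/mean(X)·100) and the index of modelling agreement
   Meff = 1 − Σ(Y−X)² / Σ(|Y−X̄|+|X−X̄|)².

Because no crop-model run archive is distributed, a synthetic GEI generator
(`ricetpe.synthetic`) emulates the *structure* of that output — 24 sowing
dates/year at 15-day intervals, 14 years, two water regimes, 672 runs per
variety per environment, drought indices in [0, 1] with 1 = no stress,
rainfed ≤ irrigated yield — with designed drought regimes as ground truth,
so every downstream stage is testable end to end.

## Worked example

```sh
python analysis/01_simulate_grid.py
python analysis/02_best_seasons.py
python analysis/03_classify_tpe.py
python analysis/04_stability_indicators.py
python analysis/05_rank_varieties.py
```

The last step prints the adaptability table for the default 11-variety
panel on a 90-environment designed grid (severity scopes S/M/L, timing
scopes V/R/V+R, and the overall "Sum" rank):

```
                      S  M  L  V  R  V+R  Sum
GSR-IR1-1-Y4-Y1       1  1  1  1  1    1    1
GSR-IR1-8-S6-S3-Y2    1  1  1  1  1    1    1
IR74371-70-1-1        2  3  3  2  2    2    2
...
NSICRc158             5  5  5  5  5    5    5

bundled field-trial vs site-simulation rank concordance: r = 0.927, R^2 = 0.86 over 11 varieties
```

Rank 1 means the cluster of most adaptable varieties in that scope. The
two lines designed as high-yielding and drought-tolerant rank first in
every scope; the drought-sensitive irrigated check ranks last. The final
line is the Pearson concordance between the bundled field-MET rank order
and its site-specific simulation counterpart: R² = 0.86, the benchmark that
simulation reproduces a field evaluation at matched sites.

`analysis/06_genotype_sensitivity.py` reruns the classification on variety
subsets and shows the TPE class proportions only stabilise once ten or
more genotypes are used; `analysis/07_model_agreement.py` exercises the
certification statistics on synthetic paired series (RMSEn ≈ 9–11% at
8–10% measurement noise, Meff ≥ 0.98).

The same stages are available as a CLI (`ricetpe simulate|best-season|
classify|stability|rank|evaluate|sensitivity|run-all`) configured by YAML;
`ricetpe run-all` writes every table, GeoJSON maps and a manifest recording
seed and thresholds.

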