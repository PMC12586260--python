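# pfcrosslink

IRT-based linking of the 10-item SF-36 physical-function scale (PF-10) onto
the PROMIS physical-function T-score metric, with the assumption checks and
agreement statistics needed to validate the linkage in a new clinical
sample.

Physical function is measured by many instruments whose raw scores are not
comparable. The PROMIS metric standardizes them: latent trait θ is scaled so
the reference population has T = 50 + 10·θ (mean 50, SD 10). When a 20-item
PROMIS short form (the *anchor*) and the PF-10 (the *linked* instrument)
measure the same unidimensional construct under a graded response model
(GRM), PF-10 responses can be converted to anchor-metric T-scores three
ways, all implemented here:

1. **Item-level linking** — EAP-score PF-10 response patterns directly with
   the PF-10 item parameters from the original joint calibration:
   θ̂ = Σ_g θ_g w_g L(x|θ_g) / Σ_g w_g L(x|θ_g) on a quadrature grid with a
   N(0,1) prior.
2. **Crosswalk table** — a lookup from the raw summed score (10–30 for ten
   3-category items) to a T-score, built by the Lord–Wingersky recursion for
   L(s|θ) followed by summed-score EAP. No modelling software is needed to
   apply it.
3. **Fixed-parameter re-estimation** — re-fit the PF-10 item parameters on
   the new sample by marginal maximum likelihood (EM on the grid) while the
   anchor parameters stay fixed at their published values, which transfers
   the anchor metric; then EAP-score with the re-estimated parameters.

Around the linking engines the package provides pre-linking assumption
screening (polychoric correlations, one-factor ULS fit indices, exploratory
bifactor ECV/ω_H, DIF screening by nested proportional-odds models with the
Nagelkerke ΔR² > 0.03 rule), agreement evaluation (Pearson r, MD(SD),
MAE/RMSE with percentile-bootstrap CIs, pooled-SD paired SMD with the
|SMD| < 0.2 negligibility convention, Bland–Altman limits of agreement), a
synthetic-data generator emulating three clinical subsamples with
contamination processes (reversed-coding responders, wholly missing
questionnaires) and an exclusion screen, and a config-driven pipeline plus
a CLI.

The linking engines are sklearn-style estimators (`EAPScorer`,
`CrosswalkLinker`, `FixedParameterCalibrator`) and compose with sklearn
tooling; module-level functions wrap them.

## Worked example

Run the full validation flow on a generated study-scale sample
(three clinical subsamples, n = 185/172/262, both instruments):

```python
from pfcrosslink.pipeline import run_synthetic_study, derive_summary_checks

report = run_synthetic_study(seed=20250429, bootstrap_B=1000)
print(report.table3().query("sample == 'analytic'"))
```

```
      method   sample   n    r    MD   SD
  item_level analytic 619 0.89 -0.73 3.84
   crosswalk analytic 619 0.89 -0.76 3.88
reestimation analytic 619 0.89 -0.94 3.82
```

Each row compares one linked score set with the observed 20-item benchmark:
`r` is the Pearson correlation, `MD` the mean difference (benchmark −
linked, in T-score points; negative means the linked scores sit slightly
above the benchmark), `SD` the SD of the paired differences. The accuracy
and effect-size table (`report.table5()`) for the same run:

```
      method  MAE [95% CI]      RMSE [95% CI]     SMD [95% CI]
  item_level 3.06 [2.87; 3.26]  3.91 [3.64; 4.18] -0.09 [-0.12; -0.05]
   crosswalk 3.09 [2.89; 3.28]  3.95 [3.67; 4.21] -0.09 [-0.13; -0.06]
reestimation 3.08 [2.89; 3.28]  3.93 [3.66; 4.20] -0.11 [-0.15; -0.08]
```

Individual-level error is about 3–4 T-points for every approach, and all
|SMD| < 0.2: group-level differences are negligible, so any of the three
conversions — including the lookup-table crosswalk, which needs no
statistics software — reproduces benchmark T-scores adequately.
`derive_summary_checks(report)` confirms the internal identities
(RMSE² = MD² + SD²·(n−1)/n, SMD recomputation, crosswalk monotonicity,
sample bookkeeping) all hold.

From the shell, the same flow (plus contamination and the exclusion screen):

```bash
pfcrosslink simulate --seed 11 --out-dir sim
pfcrosslink validate --synthetic-seed 11 --out-dir out
pfcrosslink crosswalk --linked sim/linked_params.csv --out crosswalk.csv
```

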