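# aptdki

Quantitative-MRI analysis pipeline for predicting cervical-cancer lymph-node
metastasis (LNM) from primary-tumor imaging markers, exercised end to end on
synthetic phantoms and cohorts with known ground truth.

The pipeline covers two imaging contrasts and the cohort-level inference that
ties them to nodal status:

- **APTw (amide proton transfer-weighted) CEST.** Per voxel, a 63-frame
  Z-spectrum `Z(Δω) = S_sat(Δω)/S_0` is normalised (repeats averaged), shifted
  by the static-field offset estimated from a dual-echo gradient-echo phase
  pair (`Δf = wrap(Δφ)/(2π·ΔTE)`, ΔTE = 4.92 ms), and reduced to the
  asymmetry at the amide resonance,
  `MTRasym(3.5 ppm) = Z(−3.5) − Z(+3.5)`, reported in percent.
- **Diffusion kurtosis (DKI).** The five-b-value signal
  `S(b) = S0·exp(−b·MD + b²·MD²·MK/6)` (b = 0…2000 s/mm²) is fitted voxelwise
  (log-polynomial initialiser, bounded signal-domain refinement) for mean
  diffusivity MD (10⁻³ mm²/s) and mean kurtosis MK.
- **Reader study + inference.** Two-reader ROI means are averaged and their
  agreement scored with ICC(2,1); cohort tables then flow through
  normality-gated group tests (KS → t / Mann–Whitney), χ²/Fisher contingency
  tests, univariate-screened multivariate logistic regression with Wald
  odds-ratio CIs, per-marker and combined ROC with DeLong variance/tests and
  Youden cutoffs, Spearman associations, and an exact point-scale nomogram.

Because raw patient data for this design are not publicly deposited, the
package ships first-class generators that emulate the study conditions: a
Lorentzian-pool CEST phantom with spatially varying B0, a Rician-noise DKI
phantom, and a 61-patient cohort generator (17 LNM vs 44 non-LNM) that hits
the printed categorical margins exactly and draws the markers from the
printed group summaries (APTw 3.7 ± 1.1 vs 2.4 ± 1.0 %, MK 1.065 ± 0.185 vs
0.909 ± 0.189, MD 0.989 ± 0.195 vs 1.193 ± 0.337).

Intended users: imaging scientists who want a transparent, testable
re-implementation of this analysis chain, or a harness for validating their
own CEST/DKI post-processing against known ground truth.

## Worked example

```python
>>> from aptdki import generate_cohort, univariate_logit, roc_with_delong
>>> from aptdki.roc import combine_predictors
>>> df = generate_cohort(seed=0)           # 61 patients, 17 LNM / 44 non-LNM
>>> fit = univariate_logit(df, "depth_deep")
>>> fit.table.loc["depth_deep", ["odds_ratio", "ci_lower", "ci_upper"]].round(3)
odds_ratio     23.111
ci_lower        2.808
ci_upper      190.202
Name: depth_deep, dtype: float64
>>> roc = roc_with_delong(df.lnm.to_numpy(), df.aptw.to_numpy())
>>> round(roc.auc, 3), round(roc.youden_cutoff, 3)
(0.791, 3.106)
>>> _, _, combo = combine_predictors(df, ["aptw", "mk", "md"])
>>> round(combo.auc, 3)
0.906
```

The deep-invasion odds ratio (23.111, Wald CI 2.808–190.202) is fixed by the
cohort's 2×2 margins, which the generator reproduces exactly; the APTw AUC
(≈0.79 at this seed) scatters around the binormal value implied by the group
summaries, and the three-marker logistic combination improves on any single
marker in-sample.

The same chain runs as numbered drivers over files:

```bash
python analysis/01_simulate_inputs.py --seed 0   # phantom + cohort
python analysis/02_fit_maps.py                   # B0/APTw/MD/MK + recovery table
python analysis/03_roi_agreement.py              # two-reader ROIs + ICC
python analysis/04_cohort_inference.py           # tables, ROC, nomogram
```

Images land under `scratch/`, tables under `results/analysis/`.  The same
stages are also exposed as a CLI (`aptdki simulate|cest|dki|stats|run`).

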