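# cardiorelax

Myocardial T1/T2 mapping analysis for 3 T cardiac MR: a digital
short-axis phantom, pixel-wise relaxometry, AHA 16-segment quantification
with automated quality control, and mixed-model reference statistics.

## The problem

Quantitative T1 and T2 maps of the left-ventricular myocardium support
tissue characterisation (edema, fibrosis, storage disease), but the
measured relaxation times depend strongly on field strength, sequence and
analysis choices, so each setting needs its own reference values —
least-square means with tolerance intervals per slice and per segment,
together with the influencing factors (age, sex, heart rate, blood
pressure) and the inter-subject scatter that limits diagnostic cut-offs.
`cardiorelax` implements that whole analysis as a reusable, tested
pipeline. Because raw cohort data of this kind are not publicly
deposited, the package ships a first-class synthetic-data generator that
emulates the acquisition (T2-prepared SSFP triplets at TE = 0/24/55 ms;
11-image MOLLI with a 3-3-5 pattern before and after contrast; Rician
noise; inferolateral susceptibility artifacts; inter-frame motion) and a
cohort with known statistical structure, so every downstream stage is
verifiable by parameter recovery.

## Models

* **T2**: S(TE) = S0·exp(−TE/T2), two-parameter least squares per pixel.
* **T1**: S(TI) = A − B·exp(−TI/T1\*) fitted to polarity-restored MOLLI
  magnitudes (all 12 prefix sign-flip candidates; lowest residual wins),
  then the Look-Locker correction T1 = T1\*·(B/A − 1).
* **Statistics**: linear mixed model on log values (slice/segment fixed
  effects, subject random intercept, REML) with backward elimination of
  cofactors; back-transformed LS means, 95%/90% tolerance intervals
  (Howe's k), and the scatter factor exp(√(σ²ₛ+σ²ₑ)); Bland-Altman
  observer agreement; Spearman cofactor correlations.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from cardiorelax import reference_pipeline_config, run_reference_experiment

cfg = reference_pipeline_config(n_total=8, seed=0)   # small demo cohort
bundle = run_reference_experiment(cfg, bullseye_models=False, cofactors=())
print(bundle.reference_table.round(2).to_string(index=False))
```

prints (seed 0, 8 subjects; `cofactors=()` skips backward elimination,
which overfits at this tiny size):

```
map_kind  slice  ls_mean  tol_lower  tol_upper     min     max  scatter_factor
      t2   base    43.28      33.06      56.66   37.31   50.60            1.09
      t2 middle    44.22      33.78      57.90   38.26   51.55            1.09
      t2   apex    45.95      35.10      60.16   39.71   53.51            1.09
  t1_pre   base  1146.61    1044.83    1258.31 1100.09 1197.25            1.03
  t1_pre middle  1148.14    1046.22    1259.98 1101.29 1199.05            1.03
  t1_pre   apex  1170.61    1066.70    1284.65 1124.01 1222.37            1.03
 t1_post   base   473.44     335.74     667.62  417.11  535.47            1.12
 t1_post middle   456.04     323.40     643.08  402.49  515.47            1.12
 t1_post   apex   442.89     314.07     624.54  389.38  500.41            1.12
```

Each row is one short-axis slice of one map type: the back-transformed
least-square mean (ms), its 95%-confidence/90%-coverage tolerance
interval, the observed range of per-subject slice means, and the
recovered scatter factor (multiplicative inter-subject SD). The demo
cohort's deviations from the configured geometric means (T2
44.1/45.1/46.9 ms, T1 pre 1157.1/1158.7/1180.6 ms, T1 post
427.3/411.2/399.7 ms) and scatter factors (1.08/1.05/1.11) are sampling
noise at n = 8; the packaged 40-subject experiment recovers the means
within 3% and the scatter factors within ±0.03. `bundle` also carries
the long-format segment table, QC reports and summary, per-segment
bulls-eye means, and observer-agreement results.

The same pipeline is scriptable from the shell:

```bash
cardiorelax run --out report/ --seed 0
cardiorelax simulate --out sim/ --seed 0        # NIfTI series + cohort.csv
cardiorelax fit-t1 --in sim/S001_base_molli_pre.nii.gz --out t1.nii.gz
```

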