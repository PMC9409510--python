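# radibias

Quantify — and correct — the noise-induced bias of PET radiomic features.

## The problem

Radiomic features extracted from PET images are only clinically useful if they
reflect tumor biology rather than image quality. In low count-statistics
settings (short frame durations, low injected activity, ⁸⁹Zr-immuno-PET),
many features remain highly *repeatable* between replicate reconstructions of
the same acquisition, yet drift *systematically* with the noise level: a
precise but inaccurate measurement. `radibias` implements a complete phantom
workflow to detect this bias and remove it:

1. **Synthetic phantom study.** A digital phantom with three insert
   morphologies (homogeneous uptake; necrotic core; one of two compartments
   filled) at three tumor-to-background ratios (10:1, 5:1, 2.5:1) — nine
   simulated tumors. Per tumor: one long (2400 s), nearly noise-free reference
   frame plus 10 replicate frames each at 5, 10, 30 and 120 s. Noise is an
   additive Gaussian field with SD ∝ 1/√t, post-smoothed by the
   reconstruction PSF (EARL1-like: 6.5 mm FWHM; EARL2-like: 5.0 mm).
2. **Feature extraction.** 455 active IBSI-aligned non-morphological features
   (statistics, histogram, intensity-volume histogram, local intensity, GLCM,
   GLRLM, GLSZM, GLDZM, NGTDM, NGLDM with their 2D/2.5D/3D aggregations),
   after resampling to 2 mm isotropic voxels (tri-linear) and fixed-bin-width
   discretisation at 0.25 SUV.
3. **Precision** — intraclass correlation (two-way model, absolute agreement,
   single measurement) over tumors × replicates:

   ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))

4. **Accuracy** — the similarity distance metric. With σ²ₗ the between-tumor
   variance of the reference-scan feature and d²(l,s) the per-replicate mean
   squared distance between noisy and reference values over the n tumors:

   SDM = (1/m) Σₛ σ²ₗ / ( d²(l,s) + σ²ₗ )  ∈ [0, 1]

   Both are banded poor (< 0.5) / moderate (< 0.75) / good (< 0.9) /
   excellent (≥ 0.9).
5. **Correctability screen.** Features with ICC ≥ 0.9 but SDM < 0.9 at the
   noisiest duration pass four gates (SDM strictly monotone in duration;
   short-vs-long rank correlation ≥ 0.7; a common per-tumor trend direction;
   replicate COV < 30%) before correction is attempted.
6. **Bias correction.** The local noise of a replicate pair is estimated from
   their difference image (SD_diff, COV_diff inside the VOI). Feature bias
   (RF_diff = RF_long − RF_short, or RF_ratio = RF_long / RF_short) is
   regressed on the noise estimate with a 15-model zoo (linear, exponential,
   sigmoid, power-law, rational forms), weighted by replicate variability;
   the lowest-AIC fit predicts the corrected value and the SDM is re-scored.
   Fit parameters can be transferred between reconstruction protocols
   (EARL1 → EARL2).

## Worked example

A reduced study (one protocol, two feature families, 5 replicates, small
grid) runs in about half a minute:

```python
from radibias import PhantomSpec, RunConfig, run_pipeline

spec = PhantomSpec(grid_shape=(48, 48, 32), insert_scale=0.55, n_replicates=5, seed=7)
cfg = RunConfig(spec=spec, protocols=("EARL1",),
                families=("statistics", "intensity_histogram"), seed=7)
res = run_pipeline(cfg).protocols["EARL1"]

overall = res.icc.groupby("duration_s")["category"].apply(
    lambda c: round(100 * (c == "excellent").mean(), 2))
print(overall.to_string())
```

prints

```
% excellent ICC per frame duration:
duration_s
5.0      76.19
10.0     85.71
30.0     90.48
120.0    97.62
```

i.e. at the 120 s (clinical-FDG-like) noise level nearly every feature is
excellently repeatable, and repeatability degrades as frames shorten. The
same run reports accuracy (`res.sdm`), the feature classification
(`res.correctability`: here 27 ideal, 5 potential, 10 unusable features, of
which 2 pass all correctability gates) and the correction result — for the
two correctable features the mean SDM at 5 s rises from 0.801 to 0.927
(additive mode, RF_diff vs SD_diff) and 0.928 (multiplicative mode, RF_ratio
vs COV_diff), with the AIC-selected forms recorded per feature in
`res.fits`:

```
feature_id           mode model_name        aic
ih_entropy       additive     linear  34.678239
ih_entropy multiplicative reciprocal  42.282034
stat_range       additive     linear -14.127115
stat_range multiplicative reciprocal  29.930309
```

The same pipeline is available from the shell:

```sh
radibias all --seed 1 --outdir out --protocol both
```

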