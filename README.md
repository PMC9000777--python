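# aquarocket

NIR spectral pretreatment, chemometrics and aquagram analysis for
shelf-life monitoring of packaged leafy vegetables (e.g. ready-to-eat
rocket salad under modified-atmosphere packaging), together with a
synthetic-data generator that emulates the spectral and leakage structure
of such a storage experiment so every pipeline stage is testable without
proprietary instrument data.

## Who this is for

Postharvest and food-quality researchers who monitor bagged produce with a
portable NIR spectrometer (900–1600 nm), an electrolyte-leakage assay and a
MOS-sensor electronic nose, and who want a reproducible, scriptable version
of the standard analysis chain instead of point-and-click chemometrics
software.

## What it computes

**Pretreatment.** Moving-average smoothing, Savitzky–Golay
smoothing/derivatives, Norris gap derivatives, Standard Normal Variate
(SNV), Multiplicative Scatter Correction (MSC), wavelength truncation, and
the aquaphotomic column normalization

    z(λ) = (A(λ) − μ(λ)) / σ(λ)

where μ(λ), σ(λ) are the mean and standard deviation of all (transformed)
spectra at wavelength λ. Three named presets bundle the standard chains:
`pca_prep` (boxcar 15 → Norris gap 21 → 1300–1600 nm), `pls_prep` (SNV → SG
second derivative, window 11) and `aqua_prep` (SG second derivative, window
21 → MSC → 1300–1600 nm → column normalization).

**Chemometrics.** Exploratory PCA (SVD, deterministic sign convention) and
PLS regression of the index of leaf damage on spectra, reporting the
calibration correlation r_cal, the cross-validated correlation r_cv and the
standard error of cross-validation SECV = √(Σ(ŷ_cv − y)²/(n − 1)).

**Aquaphotomics.** The 12 canonical water absorbance bands (WABs) of the
first overtone of water — one per water matrix coordinate C1–C12, from
1342 nm (ν3) through 1416 nm (free water, S0) to 1509 nm (strongly bound
water) — plus data-driven band selection within the coordinate ranges and
radar-chart aquagrams of the water absorbance spectral patterns (WASPs) per
treatment and storage day.

**Damage statistics.** The electrolyte-leakage index I_LD = 100·IC/FC,
one-way ANOVA with Fisher LSD or Tukey HSD post-hoc tests, sensor-wise
E-nose comparisons and a standardized PCA biplot of the 10-sensor table.

**Synthetic data.** Gaussian water-band spectra with a conserved
bound→free water redistribution driven by a logistic latent damage score
(flat during the first storage week, rising afterwards; treatment rates
C > A > B), per-bag-side multiplicative/additive scatter, linked leakage
records and drifting broad-range E-nose sensors. Ground truth is emitted
alongside every dataset.

## Worked example

```python
import numpy as np
import aquarocket as aq
from aquarocket import spectra_io, pretreatment, chemometrics
from aquarocket.damage_stats import leakage_frame

sc = aq.TRIAL1.replace(seed=1)                 # default storage scenario
spectra, truth = aq.generate_spectra(sc)       # 1080 reflectance spectra
absorbance = spectra_io.reflectance_to_absorbance(spectra)

checkpoints = spectra_io.checkpoint_means(absorbance)
prepped, _ = pretreatment.apply_pipeline(checkpoints, "pca_prep")
pca = chemometrics.fit_pca(prepped, n_components=2)
print("PCA explained variance (%):", pca.explained_variance_pct.round(2))

bags = spectra_io.bag_means(absorbance)
prepped, _ = pretreatment.apply_pipeline(bags, "pls_prep")
records, _ = aq.generate_leakage(sc)
ild = leakage_frame(records).groupby(["treatment", "day", "bag"])["ild"].mean()
y = np.array([ild.loc[(s.treatment, s.day, s.bag)] for s in prepped.samples])
pls = chemometrics.fit_pls(prepped, y, n_components=4, seed=1)
print(f"PLS: r_cal={pls.r_cal:.3f}  r_cv={pls.r_cv:.3f}  SECV={pls.secv:.2f}%")

prepped, _ = pretreatment.apply_pipeline(absorbance, "aqua_prep")
agr = aq.compute_aquagram(prepped)
row = agr.to_frame().query("treatment == 'C' and day == 13").iloc[0]
print("C day-13 WASP at C5 (1416 nm):", round(row["C5_1416nm"], 2))
print("C day-13 WASP at C12 (1509 nm):", round(row["C12_1509nm"], 2))
```

Output:

```
PCA explained variance (%): [83.66 16.34]
PLS: r_cal=1.000  r_cv=0.999  SECV=0.42%
C day-13 WASP at C5 (1416 nm): -2.19
C day-13 WASP at C12 (1509 nm): 2.21
```

The two principal components capture essentially all checkpoint-mean
variation; the cross-validated PLS model recovers the leakage index to
within half a percentage point; and by day 13 of storage the free-water
band (1416 nm) has moved sharply in the opposite direction to the
strongly-bound-water band (1509 nm) on the normalized second-derivative
scale — the bound→free shift that signals loss of freshness (on the
rendered aquagram the sign is flipped so growing absorbance points
outward).

The same analyses are available from the shell:

```bash
aquarocket simulate --preset trial1 --seed 1 --outdir data/
aquarocket run --preset trial1 --seed 1 --outdir results/run1
aquarocket aquagram --in data/spectra.csv --outdir results/aq --wabs default
```

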