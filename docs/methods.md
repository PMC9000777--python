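# Methods

This note documents the models and procedures implemented in `aquarocket`,
the defaults chosen where the methodology is genuinely open, and what the
synthetic-data generator does and does not emulate.

## Data model

A `SpectralDataset` couples a strictly increasing wavelength grid (nm) with
an `n_spectra × n_wavelengths` matrix and one metadata record per row
(treatment A/B/C, storage day, bag, bag side, replicate). The instrument
convention is a handheld spectrometer recording 125 points over
900–1600 nm; only the endpoints and the count are fixed, so the grid is
generated evenly spaced (spacing ≈ 5.645 nm). Treatments encode the
packaging atmospheres: A = air (21% O₂/78% N₂), B = 30% O₂/70% N₂,
C = 10% CO₂/5% O₂/85% N₂; the sampling schedule is storage days
0, 1, 4, 7, 11, 13 at 4 °C.

Acquisition corrections: reflectance is converted to absorbance as
A = log₁₀(1/R); the mean of a packaging-film reference dataset can be
subtracted from every spectrum. The subtraction is performed in the
dataset's current mode; the pipeline default subtracts in absorbance,
because subtracting a mean spectrum is only well defined per mode and the
acquisition convention does not fix one. Replicate averaging is
hierarchical — sides within bag, then bags within treatment×day — so
unbalanced replicate counts cannot bias a checkpoint mean.

## Pretreatment operators

All windowed operators **trim** the affected edge points instead of
padding; padding would fabricate data next to the 1300/1600 nm boundaries
where the water absorbance bands live. Operators never reorder rows and
pass metadata through unchanged.

* **Moving average** — centered boxcar, window in points (odd, ≥ 3).
* **Savitzky–Golay** — least-squares polynomial convolution; derivatives
  are scaled by the actual nm spacing (units AU·nm⁻ᵈ) so results are
  comparable across grids. Exact on polynomials up to the fit order. The
  grid must be uniform within 0.2% relative spacing — a tolerance that
  absorbs the rounding of wide-CSV wavelength headers while rejecting
  genuinely irregular grids.
* **Norris gap derivative** — symmetric finite difference over a fixed
  span: d(λᵢ) = (A₍ᵢ₊g₎ − A₍ᵢ₋g₎)/(λ₍ᵢ₊g₎ − λ₍ᵢ₋g₎). "Gap size N points"
  is read as the total span N (odd), i.e. g = (N−1)/2 points per side. The
  gap convention differs between chemometrics packages, so the span is
  fully configurable.
* **SNV** — per-spectrum standardization (mean 0, sd 1 across wavelengths;
  sd with ddof = 1).
* **MSC** — per-spectrum ordinary least squares against a reference
  (dataset mean by default): x ≈ a·ref + b, corrected spectrum
  (x − b)/a. Fitted (a, b) pairs are returned; a non-positive slope is
  reported as a warning because the corrected spectrum is then suspect.
* **Aquaphotomic normalization** — column standardization
  z(λ) = (A(λ) − μ(λ))/σ(λ) over the whole spectra set (σ with ddof = 1);
  the (μ, σ) statistics are returned so new spectra can be projected into,
  or recovered from, the same normalized space.

### Preset chains

* `pca_prep`: moving average (15 points) → Norris gap first derivative
  (span 21) → truncate to 1300–1600 nm.
* `pls_prep`: SNV → SG second derivative (window 11, polynomial order 2).
  The polynomial order for this chain is not fixed by convention; order 2
  mirrors the aquagram chain.
* `aqua_prep`: SG second derivative (window 21, order 2) → MSC → truncate
  to 1300–1600 nm → column normalization. Truncation is placed **before**
  the normalization so μ and σ are estimated on the analysis range only;
  whether to truncate before or after is an open methodological choice and
  this order keeps the normalization statistics independent of
  out-of-range wavelengths.
* `pls_prep_smooth`: moving average → Norris gap, an alternative
  damage-index chain that behaves better on heterogeneous (second-harvest)
  material; window sizes reuse the standard chain's.

## Chemometrics

PCA is computed by SVD of the column-centered matrix. Signs are fixed
deterministically (largest-magnitude loading element positive). Explained
variance percentages refer to the total variance of the centered data and
equal the covariance eigenvalue spectrum.

PLS uses the NIPALS algorithm (via scikit-learn's `PLSRegression`,
unscaled). Reported metrics: r_cal and r_cv are Pearson correlations of
fitted and held-out predictions against the observations (the "R-value"
convention, not R²); SECV = √(Σ(ŷ_cv − y)²/(n − 1)) in the percentage
units of the leakage index. Cross-validation defaults to leave-one-out for
n ≤ 40 and to 10 shuffled segments with a fixed seed otherwise, since no
single scheme is canonical. Component count selection uses the
one-standard-error parsimony rule on the SECV curve.

By default the models consume aggregated spectra — checkpoint means
(treatment×day) for PCA and bag means for PLS, the bag being the
experimental unit shared with the leakage assay; raw-spectrum mode is
available by calling the fit functions on the unaggregated dataset.

## Aquaphotomics

The canonical 12-band table (one water absorbance band per water matrix
coordinate C1–C12, 1342–1509 nm, assignments from ν-combination bands
through the S0–S4 hydrogen-bonding species) is built in as
`default_wabs()`. Candidate ranges for data-driven selection default to
±6 nm around each canonical band (coordinates are 6–20 nm wide).
`select_wabs` scores the grid wavelengths inside each range by a
**rank-sum** over the available criteria — the largest group-mean |z| of
the normalized spectra, |PCA loading| and |PLS loading| where supplied —
because the criteria are known but their weighting is not; ties break to
the lower wavelength, which makes the selection deterministic and stable
under sample duplication. Neighbouring ranges may overlap (C2/C3 are 7 nm
apart), so selections are additionally constrained to be strictly
increasing across coordinates.

Aquagram values are the group-mean normalized values at the selected
bands; since the ~5.6 nm instrument grid does not contain the canonical
wavelengths exactly, the value at a band is linearly interpolated between
the two flanking grid points (and equals the grid value exactly on
coincidence). `compute_aquagram` itself returns the values on the
normalized second-derivative scale unmodified, which keeps its algebraic
properties simple (mirror groups give mirror rows; the count-weighted
grand mean is 0 because the normalization centers columns). For display
and for trajectory interpretation the package uses the negated convention
(`flip_sign`): a Gaussian absorbance band growing by δ changes its central
second derivative by −δ·const, so negation makes "more absorbance" point
outward on the radar chart — the reading used throughout the aquagram
literature. Radar charts draw the 12 axes C1→C12 clockwise from the top,
one closed polyline per group, with radial limits shared across the panels
of a run so patterns are comparable between treatments.

## Damage statistics

I_LD = 100·IC/FC (percent), IC and FC being the bath conductivities before
and after freeze-induced total cell rupture. IC > FC is flagged as
physically suspect rather than rejected. One-way ANOVA uses the classical
between/within decomposition; when every observation is identical, F is
defined as 0 (no evidence of differences) with p = 1. Fisher's LSD uses
t(1−α/2, df_within)·√(MSE·(1/nᵢ+1/nⱼ)); Tukey's HSD uses the studentized
range with the Tukey–Kramer correction. LSD is anti-conservative relative
to HSD by construction (q ≥ t√2), which the tests verify.

Leakage replicates are aggregated to bag means before testing (3 bags × 3
measurements per treatment×day; the bag is the experimental unit).
Sensor-wise E-nose ANOVA treats each of the 10 sensors independently per
treatment across days, with no multiplicity correction across sensors —
matching the per-sensor significance marks conventional for sensor trend
plots. The E-nose PCA biplot standardizes the per-(treatment, day) mean
sensor table column-wise so every sensor contributes on an equal footing.

## Synthetic-data generator

The generator defines the study conditions used by the tests:

* **Spectra.** Absorbance = 0.15 AU baseline + Gaussian bands: three broad
  water absorptions (975 nm σ=40, amplitude 0.35; 1160 nm σ=35, 0.25;
  1435 nm σ=45, 0.60) and twelve fine bands (σ=8, amplitude 0.06) at the
  canonical WAB positions. Storage shifts amplitude from the
  strongly-bound-water bands (1490, 1509 nm) to the free/weakly-bonded
  bands (1416, 1428 nm) at ±0.030 AU per unit latent damage — a conserved
  redistribution between water species, not a change in total water.
* **Latent damage.** Per bag: rate(treatment)·logistic((day − 8)/1.8) plus
  bag-level jitter (sd 0.03), clipped at 0. The logistic is flat through
  the first week and rises steeply after, reproducing the observed leakage
  time course; rates are A = 1.0, B = 0.7, C = 1.5 (the CO₂-rich
  atmosphere deteriorates fastest, the O₂-enriched one slowest).
* **Scatter and noise.** Multiplicative slope (sd 0.04) and additive
  offset (sd 0.015 AU) drawn per bag side; Gaussian noise (sd 0.002 AU)
  per spectrum. Reflectance is emitted as R = 10⁻ᴬ. Replication is 3 bags
  × 2 sides × 10 scans per treatment and day (60 spectra per
  treatment-checkpoint).
* **Leakage.** I_LD = 3.0 + 28·damage + N(0, 0.35), three measurements per
  bag; (IC, FC) pairs are back-solved at FC = 1500 µS/cm so the index
  round-trips exactly through `compute_ild`.
* **E-nose.** Broad-range sensors (W5S, W1S, W2S) drift upward by a factor
  (1 + 1.2·damage); the seven compound-specific sensors stay at their
  baselines; noise is multiplicative lognormal (σ = 0.03); measurements on
  days 1–13 only.
* **Seeding.** One scenario seed feeds named substreams, so spectra,
  leakage and E-nose tables share the same latent bag damage and each
  generator is bit-reproducible.

Effect magnitudes are synthetic conventions calibrated once to make the
pipeline's behavior detectable at realistic noise levels; no quantitative
effect sizes exist to copy. A second preset (`TRIAL2`) models
second-harvest material: 2.5× scatter variance and the opposite
redistribution direction.

**What the generator does not emulate:** packaging-film spectral
contributions (the reference-subtraction path is exercised only on real
file input), wavelength-dependent scatter, instrument drift between
checkpoints, non-Gaussian band shapes, leaf/petiole morphological
heterogeneity, and any microbiological or sensory covariates. Passing
recovery tests therefore demonstrates internal consistency of the analysis
chain under the modelled structure, not performance on real produce.

## Numerical conventions and degenerate inputs

* Standard deviations use ddof = 1 throughout (SNV, normalization, SECV).
* Windowed operators require odd windows ≥ 3 and reject windows larger
  than the grid; SNV rejects constant spectra; the normalization rejects
  any wavelength with zero variance, naming it.
* The day 0→1 increment of the damage logistic (~0.009) is smaller than
  the bag jitter (sd 0.03), so trajectory tests assert monotone trend
  (rank correlation) and endpoint ordering rather than strict
  consecutive-checkpoint monotonicity — strictness between days 0 and 1 is
  not a property of these conditions.
* Tests of the Monte-Carlo calibration of the statistics use 500 null and
  200 alternative replicates; model-recovery tests run the full default
  replication (1080 spectra), which keeps the whole suite in the tens of
  seconds on one CPU.

## Known limitations

* Band selection combines its criteria by rank-sum; other weightings are
  defensible and can change the picked wavelength within a coordinate.
* The PLS sample unit (raw spectra vs bag means vs checkpoint means) is a
  modelling choice; defaults use bag means, and conclusions can differ at
  other aggregation levels.
* The published leakage-threshold values reported for real produce derive
  from raw conductivities that are not public; they are narrative context,
  not reproducible targets, and are not asserted anywhere.
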