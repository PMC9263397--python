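# Methods

`gfcpipe` implements a voxel-wise **global functional connectivity (GFC)**
analysis of resting-state fMRI for a three-group clinical design — two
patient groups (depressed patients with and without gastrointestinal
symptoms, labelled `S1` and `S0`) and healthy controls (`HC`) — together
with a synthetic-cohort generator that provides ground truth for every
downstream stage. This note documents the models, the defaults and why
they were chosen, the numerical conventions, and what validation on
synthetic data does and does not establish.

## The GFC statistic

For a subject with preprocessed series \(y_i(t)\) at the \(N\) voxels of a
gray-matter mask, the GFC of voxel \(i\) is

\[ \mathrm{GFC}(i) \;=\; \frac{1}{N-1}\sum_{j \ne i} \operatorname{atanh}(r_{ij}), \]

the mean Fisher-z-transformed Pearson correlation of voxel \(i\) with every
*other* mask voxel. Conventions:

- The Fisher transform is applied **before** averaging. This rules out the
  fast "correlation with the mean signal" shortcut, so `gfc_map` streams
  the \(N \times N\) correlation matrix in blocks of mask voxels
  (`chunk_size`, default 2048). Peak additional memory is
  \(O(N \cdot \text{chunk\_size} + N t)\), never \(O(N^2)\); the result is
  independent of the block size. `gfc_map_bruteforce` materializes the
  full matrix and is kept solely as a test oracle.
- Self-correlation is excluded and the denominator is \(N-1\).
- Negative correlations enter the mean as-is (signed z). Clipping,
  thresholding or weighting of negative \(r\) are deliberately not applied.
- \(|r|\) is clipped to \(1 - 10^{-7}\) before `atanh`, so maps are finite.
- A voxel whose series has zero temporal variance has no defined
  correlation: it is removed from other voxels' numerators *and*
  denominators (to avoid biasing neighbours) and its own GFC is NaN,
  counted in a QC summary.
- The gray-matter mask keeps voxels with tissue probability strictly
  greater than the threshold (default 0.2).

## Preprocessing

Default chain, in order: **discard** the first 10 volumes → per-voxel
**linear detrend** → temporal **band-pass 0.01–0.08 Hz** → **nuisance
regression**. The order is configurable and recorded in the run manifest;
the source protocol does not pin it down completely, and changing it
changes the output.

- Band-pass is an ideal (rectangular) frequency-domain filter after
  demeaning: FFT bins strictly outside the band are zeroed. This matches
  the behaviour of the classic resting-state toolboxes. A zero-phase
  4th-order Butterworth (`filter_type: butterworth`) is available; being an
  IIR filter applied forward-backward it leaves edge transients on short
  series, which the ideal filter does not.
- Nuisance regressors: the Friston-24 motion expansion (six rigid-body
  parameters, their one-frame lags zero-padded at the first frame, and
  both sets squared), plus mean series of designated white-matter and CSF
  compartments, plus an intercept (27 columns). The global mean signal is
  never offered as a regressor. All-zero columns (e.g. from a motionless
  synthetic trace) are dropped as no-ops; genuine collinearity is an error
  naming the offending columns.
- **Motion QC**: a subject fails when any displacement relative to the
  first retained frame strictly exceeds 2 mm in translation or 2° in
  rotation. The reference frame is a convention choice (the protocol does
  not state one); strict inequality means "exactly at the limit" passes.
- **Frame-wise displacement** uses the Power formula:
  \(\mathrm{FD}(t) = \sum |\Delta d| + 50\,\mathrm{mm} \cdot \sum |\Delta \theta|\)
  (rotations as arc length on a 50 mm sphere), \(\mathrm{FD}(0)=0\); the
  subject-level covariate is the arithmetic mean. QC and FD operate on the
  trimmed trace, aligned with the retained volumes.

Slice-timing correction, realignment, spatial normalization, smoothing and
frame censoring are out of scope; synthetic data are generated already "in
register", and FD enters the analysis only as a covariate.

## Group inference

Maps are analysed voxel-by-voxel with OLS model comparison. The **ANCOVA**
F for the group factor compares the full model (intercept, two group
dummies, age, gender, education years, mean FD) with the model without the
dummies:

\[ F = \frac{(\mathrm{RSS}_{red} - \mathrm{RSS}_{full})/q}{\mathrm{RSS}_{full}/(n-k)},\qquad df=(q,\,n-k), \]

followed by covariate-adjusted pairwise **post hoc t-tests** (the t of the
group-dummy coefficient). Covariates are mean-centered (numerics only;
F and t are unchanged). Voxels with numerically zero residual variance are
flagged NaN rather than reported as significant.

Multiple comparisons use the **Benjamini–Hochberg step-up** at q = 0.05,
applied at the voxel level within the analysis mask — the literal reading
of "FDR corrected at p < 0.05"; post hoc maps are by default tested over
the whole mask, with an option to restrict to ANCOVA-surviving voxels.
Surviving voxels are grouped into connected components (default
26-connectivity, the fMRI-toolbox convention; 6 and 18 available), split
by sign for t maps, with no extent threshold by default (`min_extent: 1`)
because the reference analysis states none. Each cluster reports its size,
its peak statistic (maximal |stat|; ties broken by lowest linear voxel
index) and the peak's world coordinate through the image affine (0-based
voxel indices, world millimetres).

## Clinical statistics and correlations

Cohort description uses a textbook one-way ANOVA (also reconstructable
from printed mean ± SD and n, via \(SS_b=\sum n_g(m_g-\bar m)^2\),
\(SS_w=\sum(n_g-1)s_g^2\)), a Pearson chi-square without continuity
correction for gender (a 3×2 table, where the Yates correction does not
apply), and a pooled-variance Student t for illness duration — pooling,
not Welch, is what reproduces the published t value. Degenerate inputs
have defined behaviour: zero between-group variance gives F = 0; zero
within-group variance with distinct means gives an infinite statistic.

Correlations between regional mean z-values and clinical scores are
Pearson r with two-sided p from the t transform. The BH family is
explicit: within each subject subset (all patients / S1 only / S0 only),
all region × variable pairs computed together form one family. The
published corrected p-values imply a particular family size that is not
stated; making the family an input rather than a guess is the only
defensible choice. Pairs with n < 4 or zero variance are skipped with a
warning and do not enter the family.

## Classification

Leave-one-out cross-validated SVM on regional mean GFC z features. The
reference analysis names LIBSVM but no parameters, so the defaults follow
that package: RBF kernel, C = 1, gamma = 1/n_features; a linear kernel and
an unscaled mode are switches. Feature standardization is computed on the
training fold only — fitting the scaler on the full table is information
leakage, and the test suite contains a constructed instance where the two
choices give different predictions. Confusion counts take the
symptomatic-patient group as positives; accuracy, sensitivity and
specificity are exact fractions rounded to two decimals only for
reporting. `feature_subset_search` exhaustively evaluates all nonempty
feature subsets up to a size cap, ranked by accuracy, then fewer features,
then sensitivity. No nested hyperparameter tuning is performed.

## Synthetic cohort

The generator's defaults mirror the reference study: 35/17/28 subjects,
TR = 2 s, 250 volumes. The spatial grid defaults to 12³ voxels at 3 mm —
a deliberately small "desk-scale" brain that keeps full-cohort simulations
cheap while leaving several hundred mask voxels for mass-univariate
inference; the statistical machinery is dimension-agnostic.

- **Template**: a smooth ellipsoidal *shell* of gray-matter probability —
  near 1 on the shell, near 0 both outside the head and in the deep core,
  mimicking the cortical-ribbon topology. The p > 0.2 mask is connected
  and covers ≥ 30% of the grid. WM/CSF nuisance compartments are
  designated core regions (below mask threshold); no segmentation is
  simulated.
- **BOLD**: \(y_v(t) = \ell_v s(t) + \sigma \varepsilon_v(t)\) with a
  band-limited (0.01–0.08 Hz) unit-variance Gaussian latent \(s\), loading
  \(\ell_v\) equal to the gray-matter probability, and white noise with
  `noise_sd` σ = 1. σ = 1 puts in-band SNR near 3.5 (white noise spreads
  its power over the whole spectrum, the latent concentrates in-band),
  giving baseline gray-matter correlations around 0.75–0.8 — the high end
  of, but comparable to, empirical low-frequency coherence. A planted
  effect multiplies the loading by \(1+\delta\) inside a 3×3×3 region (one
  of eight fixed in-shell anchors) for subjects of one group, which raises
  or lowers that region's GFC; a δ of 0.5 shifts regional GFC by roughly
  0.15 z — the magnitude of the group differences the method is meant to
  detect.
- **Clinical scores**: truncated normals at the published per-group
  moments, integer-rounded and clipped to each scale's range (HRSD-17
  total 0–52; factors bounded by their item sums); controls' weight-loss
  and cognitive factors have zero variance and are exactly 0. Only
  factor-level moments are emulated — per-item distributions are not
  published. Gender is Bernoulli at the published male fractions.
- **Motion**: Gaussian random walks (step SD 0.04 mm / 4·10⁻⁴ rad,
  giving mean FD ≈ 0.1–0.2 mm, typical of compliant adults), plus optional
  single-frame spikes to exercise QC.
- **Determinism**: every draw flows from one seed through named
  substreams (`SeedSequence([seed, crc32(stage), subject])`), so a fixed
  (config, seed) reproduces the bundle bit for bit, including file
  checksums through the pipeline.

What the generator does *not* emulate: hemodynamic response shape,
physiological (cardiac/respiratory) noise, scanner drift and artifacts,
spatial autocorrelation beyond the shared latent, motion-coupled signal
corruption, and between-subject anatomical variability. Passing tests
therefore establish the *statistical machinery* — calibration of the FDR
procedure under the null, recovery of planted covariance effects,
correctness of the arithmetic — not robustness to the full physics of real
data.

## Validation design and problem sizes

- Chunked GFC is checked against the brute-force oracle on seeded random
  instances (masks up to ~500 voxels, 60–120 frames, random block sizes)
  at 1e-10, plus an analytic two-voxel case (r = 0.5 ⇒ z = atanh 0.5) at
  1e-12.
- ANCOVA/post hoc reduce exactly (1e-8) to one-way ANOVA / pooled t when
  covariates are absent, and two-group F = t²; BH decisions match hand
  stepping and an independent reference implementation.
- Calibration: 20 seeded null cohorts (δ = 0, 10/10/10 subjects, 12³
  grid) must yield any FDR discovery in at most 20% of runs; 20 seeded
  effect cohorts (δ = 0.5, 15/15/15) must show a surviving cluster
  overlapping the planted region, with the planted sign, in at least 80%.
  Observed behaviour is comfortably inside both bounds (0/20 and 20/20 at
  the default seeds). These sizes keep the full suite to a few minutes.
- The file-based pipeline run twice with one seed must reproduce
  identical SHA-256 checksums for every deterministic stage output.

## Known limitations

- The latent model is rank-1 within the mask; real connectivity has rich
  network structure. Region-level contrasts and classification are
  correspondingly easier than in real data.
- The ideal band-pass assumes stationarity and periodicity; its sharp
  bins are exact only on the FFT grid.
- Voxel-level BH-FDR assumes the positive-dependence conditions for
  validity; spatially smoothed real data satisfy them in practice, the
  synthetic shared-latent structure likewise.
- LOOCV accuracy on small cohorts has high variance and a slight
  pessimistic bias for balanced classes; reported percentages carry no
  significance test by design.
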