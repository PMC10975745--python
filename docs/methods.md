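# Methods

## Problem setting

The package calibrates near-infrared reflectance spectra of dried cannabis
inflorescence against reference cannabinoid concentrations. Spectra live on
a 950–1650 nm grid at 4 nm spacing (176 channels); each sample is scanned
ten times and the channel-wise mean scan is modelled. Reference values are
total CBD, total THC and total CBG in % w/w of dry mass, each total formed
from the neutral and acidic forms as `neutral + 0.877 × acidic`; the factor
0.877 is the mass ratio after the acidic form loses CO₂ on decarboxylation
(e.g. CBDA → CBD). Totals of the three analytes sum to a total-cannabinoid
figure.

## Pipeline and conventions

Order of operations is fixed: replicate scans are averaged first, then a
pre-processing transform is applied per sample spectrum, then PLS1 is fitted
per analyte. Averaging-then-transforming is the convention throughout;
transforming per scan and then averaging is deliberately not offered
(SNV does not commute with averaging once noise is present).

**SNV.** Each spectrum is centred by its own mean and scaled by its own
sample SD (n−1 denominator — chosen to match the package-wide SD convention;
with this choice SNV is exactly idempotent). SNV removes channel-constant
additive offsets and positive multiplicative factors exactly. Constant
spectra are rejected rather than mapped to zero.

**Savitzky–Golay.** Coefficients are derived from the defining window
least-squares problem (Vandermonde normal equations over offsets −m..m),
not hard-coded: a degree-p polynomial is fitted to the 2m+1 window values
and its d-th derivative evaluated at the centre. Defaults m=3, p=3, d=0
(7-point cubic smoothing; kernel (−2,3,6,7,6,3,−2)/21). Edge points are
handled by fitting the same-degree polynomial to the first/last full window
and evaluating it in place, which preserves length and keeps reproduction of
degree-≤p polynomials exact everywhere; mirror padding was rejected because
it breaks cubic reproduction at the boundary. Some formulations print an
explicit 1/(2m+1) prefactor in front of the coefficient sum; since
least-squares coefficients already sum to one for d=0, applying that
prefactor literally would rescale the spectrum. The least-squares reading is
the default and the literal one is available as
`sg_smooth(..., convention="windowed")`.

**PLS1 (NIPALS).** X and y are mean-centred on the training data only.
Per-channel autoscaling is not applied: SNV already row-normalises, and
column autoscaling on top would double-normalise (exposed via
`PLSModel(..., center=...)` only as centering on/off). For a univariate
response each NIPALS component is obtained in one pass (w ∝ X'y), so there
is no convergence tolerance to tune; X is deflated by t·p' after each
component. Prediction uses the collapsed regression vector
β = W(P'W)⁻¹c; the score route (sequential deflation of new spectra) is
retained and agrees to machine precision. Components are nested, so
truncating a large-A fit to a components reproduces the a-component model
exactly — cross-validation exploits this to fit once per fold.

**Cross-validation and splitting.** The sample set is split 70/30 by a
seeded uniform permutation (unstratified; |train| = round(0.7·n)). Ten-fold
CV runs inside the training partition only, consistent with reporting
RMSECV and RMSEP on disjoint data; folds are a seeded permutation sliced
into near-equal blocks. RMSECV/R²CV are computed on the pooled out-of-fold
predictions. The replication-mode component count is fixed at A=20; CV-based
selection (argmin RMSECV, ties toward smaller A) is available as the
alternative. Negative concentration predictions are reported as-is — metrics
are computed on raw model output, and clipping would bias RMSEP comparisons
between pre-processing variants.

**Metrics.** R² is 1 − SS_res/SS_tot (not squared Pearson correlation);
RPD is the test-set sample SD divided by RMSEP. Under these definitions
RPD = √(n/(n−1))·(1 − R²P)^(−1/2) exactly, and RPD × RMSEP equals the
test-set SD, hence is constant across pre-processing variants within one
analyte and split — both identities are enforced in tests. The test-set SD
(not the full-dataset SD) is the RPD denominator convention adopted; it is
the only convention under which published metric triples are internally
consistent.

## Synthetic data: what it emulates, what it does not

Real inflorescence spectra for this calibration are not publicly released,
so the generator produces datasets with the statistical structure the
pipeline assumes:

- **Concentrations.** Each analyte's total is drawn independently from a
  normal with the study's reported moments (total CBD: mean 7.40, SD 5.12,
  range 0–22.16; total THC: 2.49, 3.88, 0–16.33; total CBG: 0.66, 1.34,
  0–13.76 % w/w), truncated to its range by rejection sampling (clipping
  would put point masses on the bounds). Truncation shifts the realised
  moments — e.g. the CBD mean rises to ≈8.1 — and tests assert against
  closed-form truncated-normal moments, not the raw targets. No
  inter-analyte correlation or chemotype class structure is imposed: only
  marginal moments are documented, so independence is the default.
- **Acidic/neutral split.** References report totals; the per-form columns
  exist so the conversion formulas are exercised. By default 90 % of each
  total is carried by the acidic form: neutral = 0.1·T and
  acidic = 0.9·T/0.877, so derived totals reproduce the drawn values
  exactly.
- **Clean spectra.** A Beer–Lambert-style linear mixture: two Gaussian
  bands per analyte (amplitudes ≈7–12 mAU per % w/w) plus a fixed
  background of a gentle slope and three strong broad humps (0.25–0.35 AU)
  representing the bulk cellulose/water matrix. The humps sit *between* the
  analyte bands so the background, not the analytes, dominates each
  spectrum's channel-wise variance; that makes the SNV scale factor nearly
  concentration-independent, the regime in which row normalisation corrects
  scatter without distorting the analyte signal — as it does in real plant
  spectra, where the matrix dominates. Band positions are placeholders, not
  physically assigned cannabinoid overtones.
- **Distortions.** Each scan is `b·clean + a + ε` with
  b = exp(N(0, 0.05)) multiplicative scatter, a ~ N(0, 0.02 AU) channel-
  constant baseline offset, and ε ~ N(0, 5 mAU) white channel noise —
  magnitudes chosen once as typical for portable NIR instruments on
  granular samples. Per-scan (a, b) are logged so recovery tests can
  reconstruct ground truth.

What passing tests therefore show: the pipeline recovers known
concentrations through the distortion classes SNV and SG target, and SNV's
advantage under strong scatter is reproduced qualitatively. What they do not
show: performance on real inflorescence spectra, whose scatter is
wavelength-dependent, whose bands shift and saturate, and which contain
moisture/terpene confounders — none of which the forward model includes.
The study's absolute error figures are not reproducible from synthetic data
and are not targeted.

## Numerical choices and degenerate inputs

- Sample SD (n−1) everywhere: summaries, SNV, RPD.
- CSV interchange: wide matrix with a wavelength header (12 significant
  digits, lossless round-trip); a replicate dialect adds a scan-index
  column. Malformed rows are rejected with their row number.
- Zero-variance spectra (SNV), zero-variance observed vectors (R², RPD),
  negative concentrations, rank-exceeding component counts and infeasible
  truncation bounds all raise informative errors rather than propagating
  NaNs.
- The expolinear curve y = (c_m/r_m)·ln(1 + e^{r_m(t−t_b)}) (a smooth
  zero-to-linear transition used for display) is evaluated through a
  softplus (`logaddexp`) so large arguments cannot overflow.
- Seeds are explicit everywhere randomness enters (generation, splitting,
  fold assignment) and are echoed in outputs; identical config + seeds give
  byte-identical reports.

## Problem sizes in the test suite

Recovery experiments run at n = 500 samples × 10 replicates (the SNV-vs-raw
scatter comparison over 10 generator seeds), grid checks at n = 100–200, and
oracle equivalence on small instances (12 × 8 for the minimum-norm OLS
check). These sizes estimate the relevant qualitative behaviour stably while
keeping the full suite in the seconds range.

## Known limitations

- PLS1 only (one model per analyte); no PLS2, variable selection, or
  prediction intervals.
- No derivative pre-processing presets (d ≥ 1 is supported by the SG core
  but unused by the comparison grid), no MSC or detrending, and no combined
  SNV+SG variant — the grid compares techniques individually.
- Reflectance→absorbance conversion is not performed; the matrix is
  consumed as recorded.
- SNV is intrinsically nonlinear in the concentrations (its scale factor
  depends on them), so on perfectly linear noise-free spectra a linear PLS
  after SNV plateaus slightly below exactness (R²P ≈ 0.995 on the default
  forward model) while raw and SG recover essentially perfectly.
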