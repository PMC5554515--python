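# Methods

## Problem and scope

On combined PET/MR scanners the attenuation map must be derived from MR
rather than measured by CT, and imperfect MR-based attenuation correction
(AC) propagates into the PET activity values. For amino-acid (FET) PET of
brain tumors the clinical read rests on a small set of semi-quantitative
metrics — a background mean B from a contralateral healthy-brain ROI, the
biological tumor volume (BTV) enclosed by the adaptive isocontour at
1.6 × B, the tumor mean and maximum uptake (T_MEAN, T_MAX), the ratios
T_MEAN/B and T_MAX/B with diagnostic cut-offs at 2.0 (reactive) and 2.4
(active tumor), and the peak-uptake location used as a biopsy target. The
package implements the full quantitative evaluation of a test AC method
against a reference: delineation, paired metric comparison, clinical
acceptance classification, log-scale Bland-Altman agreement with
repeated-measures correction, spatial agreement (Jaccard, peak shift,
shape-deviation analysis), and longitudinal follow-up consistency — and a
synthetic phantom cohort generator that emulates the AC error structure so
the whole pipeline can be exercised and validated end to end.

Not modelled anywhere: attenuation physics, sinogram-level reconstruction,
MR image synthesis, attenuation-map synthesis, registration (all inputs are
assumed co-registered, as on a simultaneous scanner), and SUV dose/weight
normalisation (every metric used is a ratio or a volume, so the absolute
calibration cancels).

## Delineation model

* Threshold: strictly above `threshold_ratio × B` (default 1.6). Ties at
  exactly the threshold are excluded — relevant only on synthetic data,
  where an isocontour can pass exactly through voxel centres.
* Components: 26-connected. With a tumor prior mask (clinician seed
  analogue; on phantoms the ground-truth region), components intersecting
  the prior are kept; without one, components ≥ `min_component_ml`
  (default 0.1 mL) survive.
* T_MAX ties break to the lexicographically smallest voxel index.
  Coordinates are 0-based; world = origin + index × spacing (voxel-centre
  convention); distances in mm.
* An empty delineation is a valid result (BTV = 0, NaN scalars), not an
  exception; ratio metrics refuse to compute on it.
* Peak criterion: a displacement of exactly 10 mm counts as exceeding the
  "< 10 mm" biopsy-scale criterion.

## Shape deviation

The signed indicator difference between test and reference masks is
smoothed with a Gaussian of FWHM 5 mm (the scale of the clinical PET
post-filter) and binarized at |value| > 0.5. A uniform one-voxel contour
shift — clinically benign background-estimation jitter — produces a thin
rim whose smoothed amplitude stays well below 0.5 (≈ 0.36 for a 2 mm rim at
5 mm FWHM) and vanishes, while a focal nodular warp survives binarization;
surviving 26-connected components above 1 mL are counted as distinct warps.
Both parameters are configurable; the defaults are chosen to realise
exactly this discrimination and are verified by construction in the tests.
Smoothing uses zero boundary conditions (nothing outside the volume).

## Agreement statistics

Between-method ratios of the clinical metrics are treated as log-normal.
With d_i = ln(test_i / ref_i):

* mean % difference = 100·(exp(d̄) − 1)
* 95% CI of the mean = 100·(exp(d̄ ± 1.96·SD_d/√n) − 1)
* 95% limits of agreement = 100·(exp(d̄ ± 1.96·SD_d) − 1)
* 95% CI of each limit = 100·(exp((d̄ ± 1.96·SD_d) ± 1.96·√3·SD_d/√n) − 1),
  the standard large-sample variance of an agreement limit. A narrower
  `eq3="literal"` variant, exp(d̄ ± 3·SD_d/√(2n)), is selectable for
  sensitivity analysis; the default is the `anova` reading.

`n` counts studies; the number of distinct subjects is reported alongside.
When subjects contribute repeated examinations, SD_d is the one-way
variance-components estimate (between-subject + within-subject mean
squares, unbalanced-design m₀, negative between-component truncated at
zero); with one study per subject it reduces exactly to the ordinary
sample SD. A single subject with replicates is an error (the
between-subject variance is inestimable). The paired t-test on the d_i
provides the reported p-value.

Acceptance criteria: a metric passes when either its absolute or its
relative difference is strictly inside the bound — T_MEAN/B ±0.05 or 5%,
T_MAX/B ±0.1 or 5%, BTV ±2 mL or 10% (reference value as denominator).
The absolute/relative mix reflects that larger absolute changes are
acceptable in large or highly active tumors. Diagnostic categories:
T_MAX/B < 2.0 reactive, > 2.4 active; the closed interval [2.0, 2.4] is
equivocal, a deliberate, testable boundary choice.

Follow-up changes use the first (baseline-role) value of the pairing as
the percent denominator, including the mixed CT↔MR pairings; deviations
from the reference change are flagged above 5 percentage points (ratios)
or 10 points (BTV), strictly. The "stable" direction band is ±2%, an
artifact parameter (direction words are otherwise undefined at a
boundary). Percentages are rounded to the nearest integer, half away from
zero, only at presentation.

## Phantom cohort generator

AC error is modelled as a post-reconstruction multiplicative bias field
rather than by simulating attenuation physics: the phenomenology being
evaluated is exactly a spatially structured multiplicative under/over-
estimation of activity, and this keeps the pipeline desk-scale. The field
is

    field = global_scale · (1 + g(depth)) · Π nodules · Π voids

inside the brain (global_scale outside), where depth is the Euclidean
distance to the brain edge normalised to [0, 1] and g interpolates
linearly from the surface error to the centre error — the radial gradient
that bone misclassification produces. Nodules are Gaussian bumps
(1 + A·exp(−r²/2σ²)); voids are spherical multiplicative depressions
(metal-implant artifacts). The identity model yields a field of exactly 1;
any non-positive field aborts generation. Bias application multiplies the
noiseless truth by the field and by (1 + ε), ε ~ N(0, noise_sd) i.i.d. per
voxel — a stand-in for residual post-filter reconstruction noise; Poisson
and reconstruction-correlated noise are out of scope. Default relative
noise SD 0.02.

Anatomy: an ellipsoidal brain (semi-axes 0.36/0.40/0.33 of the grid
extent), a thin skull shell, spherical tumor foci, an optional photopenic
resection cavity, and extratumoral high-uptake spheres in the scalp
(skin/vessel analogues) that feed the exclusion mask. Each focus has a
uniform core with a mild central peaking (8% at the centre, giving a
unique, noise-robust T_MAX location) and a 6 mm linear penumbra positioned
so that the noiseless 1.6 × B isocontour falls exactly at the stated focus
radius. The penumbra matters: a hard-edged sphere would make the BTV
completely insensitive to smooth bias fields, hiding precisely the
contour-shift effect the cohort exists to propagate; with the calibrated
ramp the ground-truth mask is still the analytic sphere. The background
ROI is auto-placed as a curved slab ("banana" analogue): brain voxels
3–10 mm below the surface, in the hemisphere contralateral to the first
focus, above the mid-axial plane, ≥ 15 mm from every focus surface,
trimmed to 15 mL (a free parameter — no quantitative ROI size is defined
clinically) by angular proximity to a direction opposite the tumor.
Generation is rejected when that placement is impossible.

Cohorts draw subject-specific bias parameters from per-method profiles.
The global scale error is a normal truncated at the reported maximum —
this reproduces a mean ± SD (max) error triplet — with defaults taken from
the three MR-based methods' reported T_MEAN errors: RESOLUTE −1.9 ± 1.9%
(max 7.6%), Dixon −14.9 ± 5.2% (max 29.3%), UTE −7.2 ± 3.1% (max 16.9%).
Gradient endpoints are normal with SDs chosen so the simulated per-method
T_MEAN/B limits of agreement sit at the clinically reported scale
(Dixon ≈ ±4.5%, UTE ≈ ±2%, RESOLUTE ≈ ±1.3%); because the background ROI
lies near the skull and the tumor deeper, the subject-to-subject gradient
variability — not its mean — is what widens the ratio distribution, which
is also the clinically described mechanism. Nodule probability/amplitude
(Dixon 37% at +0.15, UTE 11% at +0.08) and a small metal-void probability
complete the profiles. Tumor geometry varies per subject: radius
9–16 mm, contrast 2.2–4.0, random hemisphere and position. Follow-up
scenes rescale the focus radius by (1 + ΔBTV%/100)^(1/3) and the contrast
by (1 + ΔTBR%/100); requested shrinkage below the 1 mL inclusion floor is
rejected, and cohort generation halves a rejected change until realisable.
Everything is reproducible bit-for-bit from the integer seed
(`numpy.random.SeedSequence` spawning per subject).

## Problem sizes

Analyses, tests and the reproduction script run the cohort at 48³ voxels
of 3 mm (brain ≈ 2.2 L, tumors 3–17 mL) with 30 subjects and a 20%
follow-up fraction; the generator's own default grid is 128³ at 2 mm, the
resolution class of clinical reconstructions. Brute-force oracle suites
(flood-fill delineation, direct-convolution shape analysis) run on 200
random 15³ grids; Bland-Altman coverage is checked on 2000 simulated
studies. These sizes are the package's choices for a fast, deterministic
reproduction; all are configurable upward.

## What passing tests do and do not show

The phantom reproduces the error *structure* (global scale, radial
gradient, focal nodules, voids) but not real anatomy. In particular the
smooth ellipsoid has no skull base, nasal cavity or post-surgical anatomy,
which in patients produce multi-mL contour warps and the largest ratio
failures; simulated Jaccard values (≈ 0.95–0.97) are accordingly higher
and warp counts lower than clinical ones, and the cohort-level failure
fractions are qualitative (ordering Dixon > UTE > RESOLUTE), not
quantitative, analogues. Metric arithmetic, the delineation operator, the
agreement statistics and the follow-up algebra are validated exactly
against independent oracles and hand computations; conclusions about real
data inherit only those guarantees, not the phantom's effect sizes.

## Known limitations

* One focus per subject in generated cohorts (the API supports several).
* i.i.d. Gaussian relative noise; no spatial noise correlation.
* The background ROI is placed by a fixed geometric rule, not by a reader.
* The `literal` reading of the agreement-limit CI is provided but the
  `anova` reading is the default; the two differ at small n.
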