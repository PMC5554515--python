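# fetquant

Quantitative evaluation of PET attenuation-correction (AC) methods for
amino-acid (FET) brain-tumor imaging, against a CT-based reference.

On PET/MR scanners the attenuation map is derived from MR, and its errors
propagate into every clinical FET-PET metric: the background mean B, the
biological tumor volume (BTV, the volume above the 1.6 × B isocontour),
T_MEAN/B and T_MAX/B (diagnostic cut-offs 2.0 and 2.4), and the
peak-uptake biopsy target. `fetquant` implements the complete evaluation
methodology a physics/nuclear-medicine group needs to decide whether an
MR-based AC method can replace the CT reference:

* isocontour tumor delineation with a shared background ROI and
  exclusion of extratumoral uptake (`fetquant.imaging`),
* paired clinical-metric comparison, acceptance-criteria classification
  (T_MEAN/B < ±0.05 or 5%, T_MAX/B < ±0.1 or 5%, BTV < ±2 mL or 10%),
  T_MAX/B categorisation, and Bland-Altman agreement on log ratios

      mean % = 100·(e^{d̄} − 1),   LoA = 100·(e^{d̄ ± 1.96·SD_d} − 1)

  with SD_d corrected for repeated examinations by a one-way
  variance-components estimate (`fetquant.agreement`),
* spatial agreement: Jaccard overlap, peak displacement against the 10 mm
  biopsy criterion, and a shape-deviation analysis that separates focal
  contour warps (> 1 mL) from benign one-voxel shifts (`fetquant.imaging`),
* longitudinal follow-up consistency, including the mixed CT↔MR pairings
  that emulate switching AC method mid-follow-up (`fetquant.followup`),
* a seedable synthetic phantom cohort whose multiplicative bias fields
  (global scale, surface-to-centre radial gradient, focal nodules,
  metal-void artifacts) emulate the reported AC error structure
  (`fetquant.phantom`), and
* orchestration from a single JSON config with NIfTI/CSV/JSON I/O and a
  CLI (`fetquant.pipeline`, `fetquant.cli`).

Since clinical acquisitions of this kind are not publicly shareable, the
repository is organised as an analysis over the synthetic cohort: the
numbered drivers under `analysis/` run each stage and write tables under
`results/`, while all computation lives in the importable package.

## Worked example

```bash
python analysis/02_delineate_and_compare.py --seed 1
python analysis/03_agreement_statistics.py  --seed 1
python analysis/04_followup_consistency.py  --seed 1
```

Step 02 delineates a 30-subject cohort (36 studies; 6 subjects have a
follow-up) under three MR-like AC methods plus the reference and prints:

```
144 delineations over 36 studies
  DIXON     failing acceptance: 5/36  Jaccard 0.95 +/- 0.03  peak>10mm: 8%
  RESOLUTE  failing acceptance: 0/36  Jaccard 0.97 +/- 0.03  peak>10mm: 6%
  UTE       failing acceptance: 3/36  Jaccard 0.96 +/- 0.03  peak>10mm: 8%
```

i.e. the Dixon-like profile (global activity underestimation −14.9 ± 5.2%
plus the strongest radial gradient and nodular warps) fails the clinical
acceptance criteria most often, the RESOLUTE-like profile (−1.9 ± 1.9%)
never does, and tumor overlap with the reference contour orders the same
way. Step 03 prints the Bland-Altman table (excerpt):

```
  method        metric  mean_pct  ci_mean_lo_pct  ci_mean_hi_pct  loa_lo_pct  loa_hi_pct  p_value
   DIXON        t_mean    -14.68          -16.91          -12.39      -27.22        0.01     0.00
   DIXON t_mean_over_b      0.07           -0.51            0.65       -3.34        3.59     0.82
RESOLUTE        t_mean     -2.45           -2.98           -1.91       -5.63        0.84     0.00
RESOLUTE t_mean_over_b     -0.02           -0.17            0.12       -0.89        0.84     0.65
     UTE        t_mean     -8.31           -9.65           -6.95      -16.06        0.16     0.00
     UTE t_mean_over_b      0.44           -0.02            0.91       -2.29        3.25     0.05
```

The raw T_MEAN recovers each method's injected global bias, while the
T_MEAN/B *ratio* is nearly unbiased on average — the global error cancels
in the ratio and only the spatially varying bias (gradient, nodules)
widens the limits of agreement, which is exactly the clinically relevant
failure mode. Step 04 flags follow-up reads that deviate from the
reference change by more than 5 %-points (ratios) or 10 %-points (BTV);
with seed 1 the mixed CT→Dixon pairing is flagged 3/18 times with one
discordant direction (progression read as response), while every other
pairing — in particular everything involving the RESOLUTE-like method —
stays within criteria.

`analysis/01_simulate_cohort.py` additionally writes the cohort itself as
NIfTI studies (under `scratch/`) with a CSV manifest, and the same
pipeline is scriptable via the `fetquant` CLI
(`fetquant all --seed 1 --out analysis_out`).

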