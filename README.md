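# l3comp — multi-slice L3 CT body-composition analysis

Body composition on abdominal CT is conventionally measured on a single
axial slice at the middle of the third lumbar vertebra (mid-L3): the
cross-sectional areas and mean radiodensities of skeletal muscle (SM),
visceral adipose tissue (VAT) and subcutaneous adipose tissue (SAT) at
that level are standard imaging biomarkers for sarcopenia and oncology
outcomes. But L3 spans roughly a dozen slices, and a measurement taken
on any other slice of the stack differs from the mid-L3 value. `l3comp`
quantifies that slice-to-slice variability and tests whether it differs
between sexes.

The package is aimed at imaging researchers who want the complete
analysis chain — DICOM reading, segmentation, per-slice measures,
variability statistics — as tested, scriptable building blocks, plus a
synthetic phantom generator so every stage can be validated without
patient data.

## Method

For each patient the pipeline:

1. reads the ordered L3 slice stack from DICOM, converting stored
   pixels to Hounsfield units, `HU = pixel × RescaleSlope +
   RescaleIntercept`, and applies automated quality-control checks
   (tissue cut off by the field of view, excessive noise, major
   artefacts). The mid-L3 slice is always a designated input, never
   inferred;
2. segments SM, VAT and SAT with the Alberta-protocol HU thresholds
   (SM −29…150, VAT −150…−50, SAT −190…−30, inclusive) plus a
   morphological compartment split: the muscle wall is closed and
   filled, fat inside that contour is visceral, fat outside it (within
   the body) is subcutaneous. Agreement with reference masks is scored
   by the Sørensen–Dice coefficient `2|A∩B|/(|A|+|B|)`;
3. measures, per slice and tissue, surface area
   `A = n_pixels · s_row · s_col / 100` (cm²) and radiodensity = mean
   HU over the tissue's pixels;
4. computes, per patient and measure, the **average percent
   difference**

   `APD = mean over non-mid slices of |(x_i − x_mid) / x_mid| × 100`,

   summarises the cohort as median (IQR), and compares sexes with a
   two-sided Mann–Whitney U test — exact (full permutation
   distribution, ties via midranks) for small groups, tie-corrected
   normal approximation with continuity correction otherwise;
   significance at p < 0.05.

The phantom generator builds nested elliptical compartments (SAT ring,
muscle wall, visceral cavity with a fat region and bowel gas) whose
areas have closed forms, with monotone-plus-jitter slice-to-slice
modulation and sex-dependent geometry, so the pipeline's outputs can be
checked against analytic ground truth.

## Worked example

```sh
l3comp simulate --n-female 5 --n-male 5 --seed 7 --out demo/cohort
l3comp run-all --manifest demo/cohort/manifest.csv --out demo/run
l3comp report --summary demo/run/table2.csv
```

which prints:

```
         measure                all              female              male p_value
         sm_area  3.91% (3.53–4.20)   4.26% (4.03–4.28) 3.55% (3.49–3.79)    0.10
 sm_radiodensity  2.94% (2.22–3.23)   2.19% (1.96–2.73) 3.23% (3.20–3.98)    0.03
        vat_area 8.99% (8.08–10.15) 10.42% (9.37–10.47) 7.90% (6.35–8.60)   0.008
vat_radiodensity  1.29% (0.86–1.86)   1.92% (0.88–2.56) 0.96% (0.65–1.62)    0.22
        sat_area  6.69% (5.83–7.92)   5.80% (5.63–5.93) 7.96% (7.80–8.03)   0.008
sat_radiodensity  1.04% (0.77–1.24)   1.14% (0.93–1.25) 0.85% (0.70–1.21)    0.42
```

Read: with this synthetic cohort, a VAT area measured on a non-mid-L3
slice differs from the mid-L3 value by a median of ~9% — the largest of
the six measures, as the visceral compartment is the most variable along
L3 — and the areas vary far more than the radiodensities. Females show
larger VAT-area variability and males larger SAT-area variability, and
at n = 5 + 5 those two differences already reach p < 0.05 (the exact
permutation test is used automatically at these group sizes).
`demo/run/` also contains the per-slice measures, per-patient
variability records, the mid-L3 summary table and the QC report.

The same analysis is available as a library:

```python
from l3comp import generate_cohort, write_cohort, RunConfig, run_pipeline

manifest = write_cohort(generate_cohort(5, 5, seed=7), "demo/cohort")
result = run_pipeline(RunConfig(manifest=str(manifest), output_dir="demo/run"))
```

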