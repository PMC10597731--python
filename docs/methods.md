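# Methods

## Problem and scope

`l3comp` measures how body-composition values obtained from a single
mid-L3 axial CT slice differ from values obtained on the other slices
spanning the L3 vertebra, per patient and by sex. The unit of analysis
is a *study*: one patient's ordered L3 slice stack with a designated
mid slice. Mid-L3 designation is treated strictly as input — in
clinical practice it is a trained grader's judgement, and inferring it
automatically would change the question being asked.

## Segmentation model

Tissue candidates are defined purely by Hounsfield-unit ranges
(inclusive, the SliceOmatic / Alberta-protocol convention):

| tissue | HU range |
|---|---|
| skeletal muscle (SM) | −29 … 150 |
| visceral fat (VAT) | −150 … −50 |
| subcutaneous fat (SAT) | −190 … −30 |

The VAT range is a subset of the SAT range, so HU alone cannot assign a
fat pixel to a compartment; geometry must. The compartment rule is:

1. **body mask** — pixels above −190 HU, morphological closing (disk,
   radius 3 px), hole filling, then the largest 8-connected component.
   Filling precedes component selection so that a gas-separated
   interior region (e.g. a large visceral-fat island surrounded by
   bowel gas) can never outgrow and displace the body wall component.
2. **muscle** — SM-range pixels within the body, with objects smaller
   than 20 px removed (8-connectivity).
3. **muscle contour** — the muscle mask closed with a disk of radius
   5 px and hole-filled (4-connectivity): the whole region enclosed by
   the abdominal muscle wall.
4. **SAT** — SAT-range pixels inside the body and outside the contour;
   **VAT** — VAT-range pixels inside the contour. Fat pixels inside
   the contour whose HU lies only in the SAT range stay background, as
   do SAT-range-only pixels there; labels live in a single integer
   grid, so disjointness holds by construction.

Closing radius, minimum object size and connectivity choices are
conventions, exposed as `MorphologyParams`; they are not estimated from
data. Agreement with reference masks is scored by the Sørensen–Dice
coefficient, defined as 1 when both masks are empty.

This thresholds-plus-morphology segmenter is the package's own design.
It is exact on the phantom geometry below, but HU thresholding has a
structural blind spot on real anatomy: abdominal organs (~20–60 HU)
overlap the muscle range, and nothing in an HU rule can separate them
from the muscle wall — which is why clinical-grade segmentation at L3
uses learned models. The phantom is constructed so this ambiguity does
not arise (see *Phantom*), and a dedicated test documents the failure
mode when it does.

## Measures

Per slice and tissue: surface area = pixel count × row spacing ×
column spacing / 100 (cm²). The spacing factor is the *physical pixel
area*; a single linear spacing factor would not produce cm² and would
mis-handle anisotropic pixels. Radiodensity = arithmetic mean HU over
the tissue's pixels of the unmodified image (no re-thresholding or
smoothing). An empty tissue has area 0 and an *undefined* radiodensity,
carried as NaN — never 0, which is the HU of water.

## Variability statistic

For measure x with mid-slice value x_mid and non-mid values x_i:

    APD = mean_i | (x_i − x_mid) / x_mid | × 100   (percent)

APD is undefined (NaN, recorded rather than raised) when x_mid is 0 or
undefined, or when no defined non-mid value exists; undefined values
are excluded per measure, not per patient, so one empty compartment
does not shrink the sample for the other measures. APD is
scale-invariant and non-negative, zero exactly when every non-mid value
equals the mid value.

Cohort summaries are median and 25th/75th percentiles with linear
interpolation between order statistics (the default convention of
mainstream statistics environments).

## Mann–Whitney U test

U is reported for the first group: the number of pairs it wins plus
half the ties (equivalently R₁ − n₁(n₁+1)/2 with midranks). Two
modes:

* **exact** — the permutation distribution of U over all C(N, n₁)
  group assignments of the pooled values, computed by subset-sum
  dynamic programming over doubled midranks (integer arithmetic, exact
  with ties). The two-sided p is P(|U − n₁n₂/2| ≥ |u_obs − n₁n₂/2|),
  which reduces to the familiar doubled tail for tie-free data.
* **asymptotic** — normal approximation with tie-corrected variance
  n₁n₂/12 · (N+1 − Σ(t³−t)/(N(N−1))) and 0.5 continuity correction;
  p = 1 when the variance degenerates (all values tied).

`auto` uses exact when min(n) ≤ 8 and max(n) ≤ 12 — exactness matters
precisely for small groups, and the DP cost there is negligible. Tests
verify the exact mode against an independent brute-force enumeration
(all group sizes ≤ 6, with ties) and against an independent library
implementation on tie-free data. Two-sided p-values throughout, raw
α = 0.05 per comparison, no multiple-testing correction across the six
measures — matching how such cohort tables are conventionally reported.

## Phantom

One slice = nested ellipses centred in a 512×512 grid: body (semi-axes
a, b), SAT ring (thickness t_sat), muscle wall (thickness t_m), and a
visceral cavity containing a central fat ellipse occupying fraction f
of the cavity area, the rest bowel gas. Every tissue area is analytic:
π(a₁b₁ − a₂b₂) × pixel area for rings, π·a·b·f for the visceral fat.
Default HU: muscle 40, visceral fat −90, subcutaneous fat −105 (all
strictly inside their threshold ranges), gas −300, air −1000; pixel
noise is independent Gaussian per tissue (default SDs 10–15 HU),
quantised to integer storage in [−1024, 3071].

The non-fat cavity content is modelled as **gas**, not organ-like soft
tissue: soft tissue at ~20 HU sits inside the muscle HU range, and no
threshold rule could keep it out of the muscle label, making analytic
area recovery impossible in principle. Gas-dominant bowel is a
legitimate cavity composition, keeps the phantom solvable by the
segmenter under test, and the organ-HU case remains reachable through
the `cavity` HU parameter (with a test demonstrating the resulting
muscle over-segmentation). Consequently, recovery results on phantoms
certify the geometry and bookkeeping of the pipeline — not threshold
segmentation's adequacy on real organs.

Slice-to-slice variation: each component (body scale, t_sat, t_m, f)
is multiplied by 1 + ramp·u + ε, where u = (i − mid)/(n−1) is the
normalised slice offset (zero at the mid slice, so the ramp is monotone
along z) and ε is per-slice Gaussian jitter. Defaults (ramp, jitter SD):
body (0.04, 0.006), SAT (0.16, 0.025), muscle (0.10, 0.018), VAT
(0.20, 0.03); per-slice tissue-mean HU offsets have SD 1.4 / 1.45 /
1.1 HU for SM / VAT / SAT. These were chosen once so that the resulting
average percent differences are of the same order as published
multi-slice L3 variability (areas: muscle ≈ 3.5%, subcutaneous ≈ 5.5%,
visceral ≈ 6.5%; radiodensities ≈ 1–3%), not to match any cohort's
numbers.

Cohort generation: patient-level anatomy is drawn around the defaults
(body scale SD 5%, t_sat SD 2.5 px, t_m SD 1.5 px, f SD 0.06), slice
counts follow a discrete triangular distribution on 8–12 (median 10,
IQR 9–11), and sex enters as multipliers — female body ×0.95, SAT
thickness ×1.35, muscle thickness ×0.85, visceral fat fraction ×0.75,
VAT modulation ×1.3; male SAT modulation ×1.5 — reproducing the
qualitative orderings of clinical cohorts (females: more SAT, less SM
and VAT, larger VAT variability; males: larger SAT variability).
Per-patient seeds derive from the master seed; all outputs, including
written DICOM bytes (derived UIDs, no date/time tags), are pure
functions of the parameters.

What the phantom does **not** emulate: real anatomy (non-elliptic,
non-convex muscle walls; intermuscular fat; organs), beam hardening and
streak artefacts (QC criteria are exercised by constructed cases
instead), contrast phase, and kVp-dependent HU shifts. Passing the
phantom suite therefore validates the measurement and statistics chain
and the segmenter's geometric logic, not its clinical accuracy.

## Quality control

Automated analogues of the usual exclusion criteria, applied per study:
`sat_cutoff` / `muscle_cutoff` when a labelled SAT/SM pixel touches the
image border (tissue extending outside the field of view);
`low_quality` when a robust noise estimate exceeds 25 HU — the
estimator is the median absolute horizontal difference between adjacent
body-interior pixels scaled for Gaussian noise, insensitive to anatomy
away from tissue boundaries; `major_artefact` when any |HU| > 3000
inside the body. The thresholds are explicit config values standing in
for what is a human judgement in practice. Flagged patients are
excluded from the statistics but always listed with their flags
(`include_flagged` retains them for sensitivity analysis).

## Numerical and I/O choices

* Written DICOM uses int16 storage with slope 1, intercept −1024
  (stored values clamped to the 12-bit CT range [−1024, 3071]),
  explicit-VR little endian — integer HU round-trip is bit-exact.
  Readers honour arbitrary slope/intercept and clamp converted HU to
  the plausibility range [−1100, 3100].
* Pixel spacing is (row, column) per the DICOM attribute; only the
  product enters area math, so an axis swap cannot corrupt results.
* Slices order by ascending ImagePositionPatient z; duplicate z is an
  error (stack identity must be unambiguous), as is a mid designation
  matching zero or several slices.
* CSV outputs use a fixed float format, making pipeline reruns on
  unchanged inputs byte-identical.
* Statistical simulations (calibration, power) run on the generator's
  analytic truth measures rather than rendered images: the geometry
  draws are shared with the rendering path, and the imaging chain is
  validated separately by parameter recovery, so the statistics can use
  hundreds of replicates at negligible cost. Problem sizes used by the
  validation suite: 20 phantoms for parameter recovery, 200 replicates
  of 15+15 patients for type-I calibration, 50 replicates of 30+30 for
  injected-effect detection.

## Known limitations

* HU thresholding cannot separate organs from muscle on real scans
  (see *Segmentation model*); the package's segmenter is a transparent,
  deterministic baseline, not a replacement for learned segmentation.
* No height-normalised indices (patient height is out of scope), no
  3-D volume estimation, no intermuscular adipose tissue, no bone.
* The exact Mann–Whitney mode is limited by design to small groups;
  large-cohort p-values use the asymptotic path, as is standard.
* The modulation profile is a stand-in for real L3 anatomy drift; no
  quantitative slice-to-slice geometry model of real cohorts exists to
  estimate it from, so its defaults are conventions.
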