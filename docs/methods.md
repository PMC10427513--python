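# Methods

## Problem and model

`airwayfat` quantifies upper-airway anatomy and adiposity from modified
Dixon (mDixon) MRI. One scan session yields four co-registered magnitude
volumes — in-phase, out-of-phase, fat-saturated (F) and water-saturated
(W) — plus an expert-drawn integer label mask naming seven disjoint
structures: the airway column, soft palate, upper tongue, tongue base,
velopharyngeal and oropharyngeal lateral walls, and the parapharyngeal
fat pads. The package computes, per structure and session, tissue volume,
intra-tissue fat volume and percent, voxel fat-fraction histograms, and
airway-region volumetrics; across a paired baseline/follow-up cohort it
produces the change summary with paired t-tests and repeated-measures
effect sizes.

### Fat-signal fraction

The two-point Dixon fat-signal fraction of a voxel is

    f = 100 · F / (F + W)   [percent]

defined only where `F + W > background_threshold` (default 0, so only
zero-signal voxels such as airway air are excluded; inside anatomical
masks the threshold affects essentially no voxels, but it is configurable
for noisy data). No T2*, multi-peak fat-spectrum or bias-field correction
is applied: the quantity is the fat *signal* fraction, not a corrected
proton-density fat fraction. Fractions are stored in percent (0–100).

The tissue fat percent of a structure is the **mean of the defined voxel
fractions** inside its 3-D mask, and the intra-tissue fat volume is that
percent applied to the tissue volume — equivalently Σ f·(voxel volume).
The ratio-of-summed-signals alternative, 100·ΣF/Σ(F+W), is exposed as
`fat_percent_ratio_of_sums` for sensitivity checks; the two agree exactly
when total signal is uniform across the structure and differ when signal
amplitude correlates with fat content. Mean-of-fractions was chosen
because the per-voxel percentage map is the primitive object (histograms
aggregate the same values), making volume, percent and histogram mutually
consistent by construction.

Histograms use equal-width bins over [0, 100] %, default 50 bins of 2 %,
half-open `[lo, hi)` with the last bin closed at 100 so pure-fat voxels
are counted. Medians are computed on the raw voxel values, never on
binned values.

### Volumetrics and airway subdivision

Structure volume is labelled-voxel count × voxel volume (mm³ → cm³).
The airway is subdivided along the axial axis (third array axis, slice
index increasing superior → inferior) by four landmark slices supplied
per subject and session — hard palate, uvula tip, epiglottis base, vocal
folds — into velopharynx `[hp, ut)`, oropharynx `[ut, eb)` and
hypopharynx `[eb, vf]`. Half-open intervals with the final boundary
closed make the three regions an exact partition of the airway over the
landmark span; boundary ownership is otherwise a free convention.
Landmarks are manual inputs, mirroring the anatomy-guided segmentation
protocol; no auto-detection is attempted.

Cross-sectional area per axial slice is in-plane labelled-pixel count ×
pixel area; the mean and minimum are taken over slices containing at
least one labelled voxel, so an empty slice inside the span contributes
zero volume but cannot force min CSA to zero ambiguously. Airway length
is the centre-to-centre distance between the first and last occupied
slice, `(last − first) × axial spacing`; a single-slice region therefore
has length 0. This differs by one slice thickness from the plausible
`count × spacing` alternative — callers comparing against calliper-style
measurements should note the convention.

These identities hold exactly (up to float associativity) and are
asserted as properties: regional volumes sum to the airway volume over
the landmark span; structure volume equals Σ CSA × axial spacing.

## Cohort statistics

Input is a long-format table (subject, session ∈ {baseline, followup},
metric, value). Per metric, only complete pairs enter a comparison
(listwise deletion, no imputation); per-subject absolute change is
`followup − baseline` and percent change is `100·Δ/baseline` (undefined,
and reported as such, when the baseline is 0). Cohort percent change is
the mean ± SD of per-subject percent changes, not the ratio of means.
The paired t-test is two-sided with α = 0.05; because the analysis is
exploratory and descriptive, **no multiple-comparison adjustment is
applied** and every metric is reported with its own unadjusted p.

Effect sizes for the paired design:

- `d_z = mean(Δ) / SD(Δ)` — change standardised by change spread;
- `d_rm = d_z · √(2(1−r))` with r the pre/post correlation — change
  standardised by the pooled between-subject spread, comparable to
  between-group d (the default, and the variant named in the study
  design this package follows);
- `d_av = mean(Δ) / ((SD₁+SD₂)/2)`.

Magnitude classes on |d|: > 0.2 small, > 0.5 medium, > 0.8 large.

### Confidence intervals

The default CI inverts the noncentral-t distribution of the paired t
statistic in its noncentrality parameter: `√n·d_z ~ nct(df=n−1,
ncp=√n·δ)`, so the 95 % interval for δ is the set of noncentrality values
not rejected at 5 %. This is exact for d_z under normality; for d_rm and
d_av the d_z interval is rescaled by the variant's (data-dependent)
standardiser ratio, the standard approximation for repeated-measures d.
A seeded percentile bootstrap over subjects (default 10,000 resamples)
remains available as `ci_method="percentile"`. It is not the default
because, at the sample sizes typical of paired imaging cohorts (n ≈ 18),
the percentile interval of a standardised effect size undercovers badly:
in our calibration simulations at n = 18, δ = −1.5 it covered the truth
in ~86 % of replicates (BCa ~90 %), versus ~96 % for noncentral-t
inversion. Degenerate inputs (zero change variance, zero arm SD, |r| = 1
for d_rm) raise typed errors; the cohort summary converts them to
per-row status annotations rather than aborting.

## Synthetic data generator

The phantom emulates the study conditions, not anatomy: seven disjoint
compartments on a 64³ grid at 1 mm isotropic spacing (small enough that
the full suite runs in seconds), with an air-filled pharyngeal tube
(zero signal), paired lateral-wall slabs and fat-pad lobes flanking it,
tongue/tongue-base ellipsoids and a soft-palate ellipsoid. Overlaps
after voxelization are resolved by a fixed priority order (airway >
fat pads > lateral walls > soft palate > tongue base > tongue), keeping
masks disjoint. Default ground-truth fat fractions are 30 % (tongue,
soft palate), 23 % (tongue base), 20 % (lateral walls) — the 20–30 %
range reported for upper-airway muscular tissues in obese cohorts — and
80 % for the adipose fat pads. Signal follows the two-point Dixon model
`water = A(1−f/100)`, `fat = A·f/100`, `in-phase = F+W`,
`out-of-phase = |W−F|` at amplitude A = 100; richer physics (chemical
shift, T2*, k-space effects) is deliberately omitted because the
pipeline under test consumes only F and W.

Noise is Rician, the magnitude-MRI model: `s → √((s+g₁)² + g₂²)` with
independent zero-mean Gaussians of SD σ per channel. Noise inflates low
signals, biasing recovered fat percent upward for low-fat tissue; the
bias shrinks monotonically as σ falls (measured mean |bias| for the
tongue: 0.104 / 0.029 / 0.009 / 0.003 percentage points at σ = 4 / 2 /
1 / 0.5 % of amplitude). The noisy-recovery test tolerance of **0.3
percentage points at σ = 2 % of amplitude** was frozen in advance from a
100-replicate Monte-Carlo oracle (max observed error 0.18 pp across
tongue, soft palate, lateral wall and fat pads).

Paired phantom subjects scale tissue geometry isotropically by a
per-structure volume factor (in-plane for the airway tube, whose slice
extent is anatomically pinned) and shift true fat fractions additively.
A 32/64/128-cube resolution sweep put the voxelization error of a 0.9
tongue-volume factor at 0.7–1.4 % relative, so paired-recovery tests use
a **2 % relative bound**; fat-fraction changes are exact at σ = 0
because fractions are uniform within each tissue.

Paired cohorts are drawn per metric from a bivariate normal over
(baseline, follow-up) parameterised by baseline mean/SD, mean change,
and either follow-up SD + change SD (the generator derives the implied
pre/post correlation from SD_Δ² = SD₁² + SD₂² − 2rSD₁SD₂) or a stated
correlation. Default metric parameters mirror a bariatric weight-loss
cohort of n = 18: tongue volume 89.2 ± 18.2 → −9.0 ± 7.0 cm³, tongue fat
30.4 ± 6.1 → −5.0 ± 3.2 pp, velopharyngeal airway +1.1 ± 1.7 cm³, and so
on. All generator outputs are bit-reproducible under a fixed seed
(per-channel noise streams are spawned from one `SeedSequence`).

### What the phantom does and does not show

Passing recovery tests demonstrates that the arithmetic pipeline —
masking, fraction mapping, aggregation, subdivision, paired statistics —
is correct and calibrated. The phantom has uniform per-tissue fat,
convex geometry, no partial-volume mixing at tissue boundaries, no bias
fields, no motion, no registration error between sessions, and no
segmentation variability; none of the corresponding real-data error
sources are exercised, and accuracy on real scans is bounded by those
effects, not by the ones tested here.

## Numerical and design notes

- Volumes assumed co-registered; NIfTI header orientation beyond "third
  axis is axial" is ignored, and spatial registration is out of scope.
- Statistical calibration checks run at n = 18 with 1000 replicates
  (500 for CI coverage), sizes chosen so the whole suite stays fast
  while Monte-Carlo margins (binomial 99 % intervals) remain tight
  enough to detect miscalibration.
- The t statistic's small-sample expectation oracle is
  `E[d_z] = δ·√(df/2)·Γ((df−1)/2)/Γ(df/2)` from the noncentral-t mean;
  at n = 18, δ = −1.5 this is −1.5705.
- `scipy.stats.nct.cdf` returns NaN in far tails; the CI inversion maps
  those to the correct limit (0 or 1) before root-finding.
- Printed effect sizes in small paired studies are often not exactly
  reproducible from rounded summary statistics, and different d variants
  differ materially when pre/post correlation is high; reports therefore
  always name the variant used.

## Known limitations

- Fat-signal fraction ≠ proton-density fat fraction; no T2*/multi-peak
  correction.
- Airway length is slice-span based, not centreline length; curved
  airways are under-measured.
- The d_rm/d_av noncentral-t CIs treat the standardiser ratio as fixed,
  an approximation that degrades at very small n or extreme correlation.
- The phantom's tissue fat is uniform, so histogram-shape behaviour
  (spread, skew) is only weakly exercised.
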