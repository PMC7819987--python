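# Methods

This note documents the models, rules, and numerical choices behind
`fuzzyct`: what each component assumes, which parameters matter and why
they default the way they do, what the synthetic data do and do not
emulate, and where the design was genuinely open.

## 1. The imaging marker

### Segmentation and volumetry

Hematomas are segmented by a fixed Hounsfield-unit threshold: voxels
with HU ≥ `clot_threshold_hu` (default **50 HU**, the conventional
lower bound of acute clotted blood) are grouped into 26-connected
components and filtered at `min_component_ml` (default **0.1 mL**) to
suppress noise speckles.  Volume is voxel count × voxel volume; each
component also carries its mean HU, centroid, and 3-D Feret diameter
(largest boundary-to-boundary distance, computed on the convex hull of
the component's surface voxels, in millimetres so anisotropic grids are
handled correctly).  The 50 HU default is configurable; the clinical
display window (width 110 / level 50) is a viewing convention, not a
segmentation threshold, and is not used.

Total hematoma burden is the sum over components, matching how
multifocal contusion volumes are reported; expansion compares these
totals between baseline and follow-up:
relative growth ≥ 30% **or** absolute growth ≥ 5 mL, both inclusive.

### The sign detector

Three criteria, all required:

1. **Multiplicity/adjacency (c1).**  Build a graph over components with
   an edge wherever the nearest-surface (edge-to-edge, Euclidean,
   in mm) separation is at most `d_max`, the Feret diameter of the
   largest-by-volume component (ties broken by higher mean HU, then
   lower label).  c1 holds iff the largest connected cluster has ≥ 3
   components.  A chain configuration qualifies: the criterion asks for
   a cluster of mutually related hematomas, not a pairwise clique — the
   graph-connectivity reading of "adjacent to each other".
2. **Blood-density gap (c2).**  For every edge of that cluster, sample
   the corridor between the nearest surface points: voxels within 2
   in-plane voxel widths of the connecting segment, excluding hematoma
   voxels (radius grown geometrically if the corridor is empty).  c2
   holds iff each corridor's mean HU lies strictly inside the
   (parenchyma-high, clot-threshold) band, default (40, 50) HU — the
   gap is unclotted blood, not gray/white matter.
3. **Contrast (c3).**  For every such pair, the mean HU of the two
   clots minus the corridor mean must be ≥ **20 HU**.

c2 and c3 are universally quantified over the cluster's adjacent pairs
and hold *vacuously* when no pair is adjacent.  This makes the criteria
report the specific rule a scan violates: a two-hematoma scan fails c1
alone, a wide-separation scan fails c1 alone, a gray-matter gap fails
c2 alone, a low-contrast gap fails c3 alone.  The sign itself is always
the conjunction, so vacuous c2/c3 never produce a positive call.

Open choices, resolved as follows: the 20 HU rule compares *means*
(pair mean clot HU vs. corridor mean) rather than extrema — means are
stable under noise and match how density differences are read off
region-of-interest statistics; adjacency uses the *global* largest
component's diameter (a per-cluster definition is circular, since the
cluster depends on the threshold it defines).

## 2. Phantoms

Phantoms rasterize axis-aligned ellipsoidal clots (50–90 HU) and
cylindrical fuzz corridors (40–50 HU) onto a 160×160×16 grid of
0.5×0.5×5 mm voxels (80×80×80 mm field of view; 5 mm slices match
routine trauma CT).  Background parenchyma is 33 HU with additive
Gaussian noise (SD 3 HU) everywhere, clipped to the representable CT
range.  Ellipsoids give an analytic volume oracle
$V = \tfrac{4}{3}\pi r_1 r_2 r_3$; truth masks are the exact
rasterizations.

Scenario families (all randomized within constraints, all seeded):

| scenario | geometry | designed failure |
|---|---|---|
| `positive` | 3 clots in a gently bent chain, gaps 4.5–7 mm, all pairs bridged by fuzz 21+ HU below the clots | none |
| `two_blobs` | identical densities, 2 clots | c1 |
| `far_apart` | 3 clots with gaps beyond the adjacency limit | c1 |
| `low_contrast_bridge` | bridged clots with 13–17 HU contrast | c3 |
| `parenchyma_gap` | adjacent clots, gaps left at background density | c2 |
| `single_blob` | one clot | c1 |

Numerical choices worth recording:

- **Slice-axis radii 13–16 mm, centers snapped to slice centers.**  At
  5 mm slices, voxel-counting a short ellipsoid is midpoint-rule
  integration of its cross-section with very few nodes; radii below
  ~10 mm can miss the analytic volume by more than 5% depending on how
  the center falls between slices.  Snapping the center and keeping the
  polar radius ≥ 13 mm bounds the rasterization error near 3%, which is
  what the volumetry tests verify.
- **Fuzz at 43–45 HU, corridors of radius 4.5 mm.**  With noise SD
  3 HU, fuzz voxels cross the 50 HU segmentation threshold with
  probability ~5%, below the site-percolation threshold of the
  26-neighborhood lattice (~0.145), so noisy fuzz cannot form bridges
  that merge two clots into one component.  The corridor is generously
  wider than the detector's 1 mm sampling radius so that the sampled
  segment — which runs between *segmented* surface points and can sit
  1–2 mm off the geometric axis — stays inside fuzz.
- **Chain layout with every pair bridged.**  Three blobs in a triangle
  with all sides bridged leave a background pocket at the centroid that
  the outer pair's corridor can clip; a near-collinear chain has no
  interior pockets, and the outer pair's corridor runs through the fuzz
  sleeve around the middle blob.  Overlapping corridors take the first
  bridge's density rather than stacking.
- The `far_apart` geometry keeps worst-case gaps ≥ 3 mm beyond the
  largest possible adjacency limit so that measurement error cannot
  create spurious adjacency.

What phantoms do **not** emulate: skull/CSF anatomy, partial-volume
blur, beam hardening, motion, or textured "fuzz" (the corridor is
homogeneous hypodense blood plus noise — the published marker's
qualitative "fuzziness" has no quantitative definition to implement).
Perfect detector accuracy on phantoms therefore demonstrates that the
rule set is implemented correctly and is robust to acquisition noise at
realistic contrast, not that real-scan reading is solved.  A dedicated
test verifies the detector degrades (never improves) as noise grows.

## 3. Cohort simulation

One row per patient.  Covariates are drawn from distributions read off
the published baseline table's pooled columns: sex Bernoulli(0.75), age
N(51, 17.5²) truncated ≥ 18, hypertension 0.13, diabetes 0.06, MAP
N(102, 14²), coagulopathy 0.165, GCS (mild/moderate/severe =
0.50/0.22/0.28), location (frontal/temporal/parietal/occipital/deep =
0.485/0.421/0.033/0.029/0.032), IVH 0.083, SAH 0.83, SDH 0.77, time to
baseline CT U(0.5, 6) h, baseline-to-follow-up time U(6, 48) h, and
baseline volume lognormal matched to mean 9.1 / SD 9.8 mL resampled
≥ 2 mL (truncation lifts the realized mean slightly; reported medians
and IQRs are approximated by these normal/uniform forms — this is
emulation, not reproduction).

The sign and the outcome are logistic in centered covariates:

- sign: intercept −0.3111 plus 0.045/mL baseline volume, 0.02/mmHg MAP,
  0.75 frontal, 0.85 SAH, 0.80 SDH — producing pre-matching
  standardized differences of ~25–35% on exactly those five covariates
  and ~0 elsewhere, the imbalance pattern the matched design exists to
  correct;
- expansion: intercept −0.1714, **β_sign = log 9.5**, plus attenuated
  versions of the same confounders and −0.18/h for time to CT (earlier
  scans leave more growth ahead).

Both intercepts were calibrated once by large-n simulation so the
marginals hit sign prevalence 43.9% and expansion incidence 63.7%, then
frozen.  β_sign = log 9.5 places the crude (confounded, marginal) OR
near 11–12, inside the published 10–16 range, while keeping the
conditional effect at the matched-estimate scale; note the crude OR
exceeds the conditional one both through confounding and despite
non-collapsibility of the odds ratio.  Hematoma counts are 3 + Poisson(1)
for sign-positive scans (the sign requires ≥ 3) and 1 + Poisson(1.1)
otherwise, giving the "multiple hematomas" comparator predictor and the
≥ 3-hematoma sensitivity subset.  An optional effect-modification hook
(`interaction_coef`) adds covariate-dependent sign effects for subgroup
calibration studies, and `simulate_matched_pairs` generates 1:1 pairs
with an exact pair-conditional odds ratio for estimator-recovery
experiments.

## 4. Statistical procedures

- **Logistic regression**: Newton–Raphson/IRLS on the exact
  log-likelihood; covariance is the inverse observed information at the
  MLE; convergence by gradient norm; coefficients beyond ±30 on the
  logit scale raise a separation error (no finite MLE), rank-deficient
  designs are rejected.  Cross-checked against statsmodels in tests.
- **Propensity scores**: nonparsimonious logistic model of the sign on
  every baseline covariate (GCS as two dummies vs. mild; location as
  four dummies vs. frontal).  The score equation guarantees the mean
  fitted score equals the treated fraction — used as a self-test.
- **Matching**: greedy 1:1 nearest-neighbor without replacement,
  caliper **0.05 on the probability scale** (the literal reading of a
  "5%" caliper; the 0.2·SD-of-logit alternative is provided as
  `logit_caliper`).  Treated subjects are visited in a seeded random
  permutation; distance ties resolve to the lowest control id, making
  matching fully deterministic given the seed.  An O(n²)
  exhaustive-search oracle in the tests confirms exact agreement.
- **Balance**: absolute standardized differences, pooled-SD form for
  continuous covariates and p(1−p) form for binary ones, with < 10%
  as the balance convention.  On default confounded cohorts of
  n = 2000 the post-matching worst-case SMD is ~5%.
- **Effect ladder**: crude 2×2 OR (Haldane–Anscombe 0.5 correction iff
  a cell is zero, flagged); logistic ORs adjusted by sex+age, by all
  individual confounders, and by the propensity score as a single
  covariate; and the matched pair-stratified conditional estimator
  n₁₀/n₀₁ with McNemar's test.  For 1:1 binary data the conditional
  logistic MLE reduces exactly to the discordant-pair ratio, which is
  the estimator a pair-stratified model targets; a stratified
  proportional-hazards formulation is not identifiable here because no
  event times exist.  All CIs are 95% Wald on the log-OR scale;
  significance is two-tailed at 0.05; no multiplicity correction is
  applied across subgroups.
- **Subgroups/interaction**: per-level 2×2 ORs on the matched sample
  over the six predefined factors (sex; age < 65; GCS mild vs.
  moderate+severe; baseline volume < 10 mL; time to CT < 3 h;
  coagulopathy), with the interaction p-value from the Wald test on the
  exposure×factor product term in an unconditional logistic model.
  Null calibration (uniform p-values) and recovery of generated
  stratum effects (6.25 vs. 9.5) are verified by simulation.
- **ROC**: Mann–Whitney AUC with ties counted ½, DeLong variance from
  placement values, CI clipped to [0, 1].  For a binary marker the AUC
  equals (sensitivity+specificity)/2 exactly — asserted as an identity
  against the rank computation.  Time to CT enters negated so that
  earlier scanning (higher residual growth risk) scores higher.

## 5. Pipeline and problem sizes

`run_study` is deterministic given its seed: the cohort, matching
order, and every derived table are reproduced byte-identically on
rerun, and reports serialize to sorted-key JSON plus plot-ready CSVs
(balance/Love data, ROC staircases, subgroup forest rows).  Matching
below 10 pairs aborts with a diagnostic rather than returning fragile
estimates.

Default problem sizes were chosen so every check runs comfortably on a
single CPU: 10 phantoms per scenario (60 volumes) for detector
validation; n = 2000 × 20 seeds for the balance contract; 200
replicates of 1000 pairs for estimator recovery (median within ±20% of
a true conditional OR of 10) and 400 null replicates for CI coverage
(≥ 93%); one development-sized run (n = 482) for the report itself.
At n = 482 the matched sample is small (~160 pairs), so post-matching
SMDs can exceed 10% on some draws; the balance *contract* is stated at
n = 2000 where the matched estimator has room to work.

## 6. Known limitations

- The detector's corridor statistic is a mean over a thin cylinder; on
  real scans partial-volume effects and textured fuzz would demand a
  more robust statistic (median, or a learned texture feature).
- Phantom geometry is convex and axis-aligned; real contusion hematomas
  are irregular, and nearest-surface distances on real masks would be
  noisier.
- Simulated cohorts share the published covariate *marginals* but
  invent the joint dependence structure (covariates are mutually
  independent given the generating models); site-specific covariate
  shifts of an external validation cohort are not modeled.
- The discordant-pair CI is Wald-based and degrades when discordant
  counts are small (the ≥ 3-hematoma matched sensitivity analysis on
  n = 482 cohorts can produce very wide intervals, as its published
  analogue does).
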