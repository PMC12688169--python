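# Methods

## Overview

`ctcgate` implements an automated rare-cell enumeration pipeline for
CellSearch-style multi-channel fluorescence cartridges, together with the
statistical machinery used to compare an automated count against a manual
gallery review and to relate counts to patient survival. The pipeline is

    cartridge image stack
      → per-channel segmentation
      → cross-channel event merging
      → feature extraction
      → gate classification (CTC / CHC / OTHER)
      → per-patient counts
      → concordance + survival analysis

Every stage is driven by explicit, documented parameters; nothing depends on
hidden state, and all randomness flows through seeded NumPy generators.

## Event detection and measurement

**Segmentation** (`detection.segment_channel`). Each channel of each field
of view is processed independently: grey white-top-hat background removal
(disk footprint, default radius 8 µm), optional Gaussian pre-smoothing
(default σ 0.5 µm), a global triangle threshold on the flattened image
(an absolute AU threshold may be substituted), 8-connected labeling, an
optional watershed split of touching objects on the distance transform
(off by default — simulated cells do not touch), and removal of objects
below an area floor (default 6 µm²). A contrast-free frame yields an empty
mask, not an error.

**Half-maximum mask refinement** (`refine_fraction`, default 0.5). A global
threshold on a blurred image keeps pixels deep in the point-spread skirt of
every object. Those pixels carry little signal, so object *means* measured
inside such masks sit far below the stain's true level (empirically ~2×
low for 2.5 µm cells at 0.8 µm blur), which corrupts the absolute-AU gate
semantics. Each labeled object is therefore trimmed to the pixels at or
above `refine_fraction` × its own maximum (on the background-subtracted
image). For a Gaussian-blurred disk the half-maximum contour tracks the
true disk boundary, so refined areas also approximate true areas. Setting
`refine_fraction = 0` restores the raw global-threshold masks.

**Event merging** (`detection.merge_events`). Objects from different
channels of the same frame that share at least one pixel are merged into
one *event* by transitive closure (union–find), so the output is a
partition of all objects. Events never span frames: each field of view is
an independent observation.

**Features** (`detection.extract_features`). For each channel present in an
event, mean and maximum raw intensity (AU, no rescaling — the gates are
absolute), size (pixel count × pixel size², µm²), moment-ellipse
eccentricity, contour perimeter (µm), and perimeter-to-area ratio (1/µm)
are measured inside that channel's own mask. Overlays are area fractions:
`ck_dapi_overlay` = |CK ∩ DAPI| / |CK| and analogously for CD45, bounded in
[0, 1]. Auxiliary marker-channel means are measured inside the union mask
(configurable to the CK mask; the field's tools are not explicit on this
point). Channels absent from an event contribute zeros, which matters for
gate semantics below. All features are translation invariant, and size /
perimeter scale as pixel-size² / pixel-size (tested properties).

## Gate classification

The shipped gate sets (module `gating`) are conjunctions of threshold
predicates, all values absolute:

| feature            | CTC       | CHC       |
|--------------------|-----------|-----------|
| cd45_mean          | ≤ 5 AU    | > 30 AU   |
| cd45_max           | —         | > 50 AU   |
| dapi_mean          | > 45 AU   | > 45 AU   |
| ck_mean            | > 60 AU   | > 60 AU   |
| ck_size            | > 16 µm²  | > 16 µm²  |
| ck_size            | ≤ 400 µm² | ≤ 400 µm² |
| ck_dapi_overlay    | > 0.2     | > 0.2     |
| marker1_mean       | ≤ 5 AU    | ≤ 5 AU    |
| marker2_mean       | ≤ 5 AU    | ≤ 5 AU    |
| cd45_dapi_overlay  | —         | > 0.2     |
| cd45_size          | —         | > 16 µm²  |
| cd45_size          | —         | ≤ 400 µm² |

Comparator strictness is honored exactly: `cd45_mean == 5` passes the CTC
gate, `ck_size == 16` fails both sets. The marker gates pass when the
auxiliary channels are absent (0 ≤ 5), so a three-channel kit is never
blocked. The CTC and CHC sets are mutually exclusive by construction
(`cd45_mean ≤ 5` vs `> 30`); custom configs are rejected at load time
unless some feature's combined feasible interval is empty — a sound and
complete check because gates constrain features independently.

**Manual-review emulation** (`classify_manual_emulated`) operationalizes
qualitative gallery criteria: equivalent-circle diameter of the CK object
2·√(area/π) > 4 µm; "visible nucleus" as DAPI mean above 45 AU;
CK-positive as CK mean above 60 AU; CD45-negative as CD45 mean ≤ 5 AU
(tumor cell) vs CD45-positive as CD45 mean > 30 AU (hybrid). The
visibility thresholds default to the automated gate values because the
reviewer criteria are qualitative; all are config keys. An optional
operator-noise model flips each positive call to OTHER with a configured
probability (seeded), emulating inter-operator variability. Between the
CD45 ceiling and the positivity threshold an event is neither CTC nor CHC.

## Synthetic cartridges

`synthetic.simulate_cartridge` renders planted, labeled cells as hard disks
convolved with a Gaussian point spread, added to a background with a linear
gradient, then Poisson shot noise and Gaussian read noise. Class templates
follow the stain chemistry: CTC = DAPI+/CK+, CHC = DAPI+/CK+/CD45+,
WBC = DAPI+/CD45+, DEBRIS = anucleate CK fragments. Defaults (one
cartridge): 10 CTC, 5 CHC, 200 WBC, 20 debris over two 600×600 frames at
0.64 µm/px; radii 2.5–4.5 µm (CTC/CHC), 3–5 µm (WBC), 1–2.2 µm (debris);
peak amplitudes DAPI 140 ± 20, CK 160 ± 25, CD45 140 ± 20 AU over a 3 AU
background with a 2 AU gradient; blur σ 0.8 µm; read noise σ 2 AU. These
emulate the high stain-to-background contrast of enriched, stained
cartridge galleries. Cells are placed by rejection sampling with a 6 µm
edge-to-edge clearance; a density cap raises an error rather than silently
overlapping cells. The same seed reproduces the stack bit for bit.

What the simulator does **not** model: textured or lobed nuclei, optical
aberrations and vignetting, stain bleed-through, touching or overlapping
cells, focus drift, and the intensity autofluorescence structure of real
blood smears. Passing recovery tests therefore demonstrate that the
detection + gating chain is correct and calibrated for well-separated
disk-like events — not that it would match a human reviewer on real
archived images.

## Synthetic cohorts

`synthetic.simulate_cohort` draws per-patient data with the structure the
analysis assumes:

* **Counts.** A latent true count per analyte from a zero-inflated negative
  binomial. Defaults for CTC: zero-inflation 0.5, NB mean 33, dispersion
  0.15 — rare-cell counts are strongly zero-inflated and overdispersed
  (cohort medians of 0–1 coexist with totals in the hundreds concentrated
  in a few patients). CHC: zero-inflation 0.35, mean 2.2, dispersion 0.8.
* **Two methods.** Manual and automated observed counts are independent
  binomial thinnings of the latent count (default detection probability
  0.85 each) plus additive Poisson false positives (defaults 0.2 and 0.3)
  — a single interpretable mechanism that produces realistic sub-100%
  concordance.
* **Survival.** Exponential baseline OS (scale 95 months) with the hazard
  multiplied by e^log-HR (default HR 2.9) for patients whose *true* count
  reaches the cutoff (default ≥ 1); independent uniform censoring on
  (0, 170] months. These defaults were calibrated once so the observed
  cohort median OS sits near 32 months with roughly 40% censoring, matching
  a long-follow-up retrospective metastatic colorectal cohort. PFS is OS
  times a uniform fraction (0.3–0.8), giving the strong OS–PFS rank
  correlation such cohorts show. Clinical covariates are drawn from fixed
  marginal frequencies typical of the disease setting.

Parameter-recovery runs (Cox coverage/bias) disable thinning, false
positives and censoring so the regressor equals the true indicator;
otherwise measurement noise attenuates the hazard ratio — which is
precisely the phenomenon the concordance machinery is for, not an
estimator defect.

## Statistics

* **Kaplan–Meier** via lifelines; the median is the smallest step time with
  S(t) ≤ 0.5 (evaluated with a 10⁻⁹ tolerance so a product that lands on
  0.5 up to round-off is treated as reaching it), `None` if never reached.
* **Log-rank** via lifelines' k-sample statistic (χ², k−1 df); verified in
  tests against a hand-rolled hypergeometric-moments implementation.
* **Cox regression** via lifelines with Efron tie handling and convergence
  tightened (`precision 1e-14`, `r_precision 1e-15`) so the Newton solution
  agrees with an independent implementation to < 10⁻⁶. Breslow ties are
  provided by an internal single-covariate Newton solver. Wald 95% CI on
  the log scale. Monotone likelihoods (complete separation) are returned
  flagged, never as silent divergence.
* **Rank statistics** via scipy: tie-corrected Spearman, Mann–Whitney U
  (exact null for samples up to 25 without ties, tie-corrected normal
  approximation otherwise), Kruskal–Wallis with tie correction.
* **Fisher's exact test** two-sided by point-probability ordering (scipy,
  identical to R's `fisher.test` convention); verified against full
  enumeration of all margin-fixed tables for totals ≤ 8.
* Cohort-level median OS with IQR is the raw sample median (KM medians
  carry no IQR); group medians in survival comparisons are KM medians.

## Concordance accounting

A patient is *status concordant* at cutoff c when both methods fall on the
same side of count ≥ c, and *numerically discordant* when statuses agree
but raw counts differ (both-zero pairs are numerically equal by
construction). `detection_concordance` returns the 2×2 status crosstab
(cells sum to the cohort size; margins equal per-method positive counts),
the concordance rate, and the numerical-discordance count; it is symmetric
in the two methods, and both-positive counts are non-increasing in the
cutoff (tested properties).

## The concordant-cohort benchmark

`benchmark_discordant` asks which of two enumeration methods better matches
observed survival on the patients where they disagree. Concordant patients
form a benchmark cohort; its negative/positive strata are fit by
Kaplan–Meier. Each discordant patient's *expected status* is derived from
their observed OS under a configurable adjudication policy, a method is
correct when its own call equals the expected status, and the 2×2
method × correctness matrix is tested with the two-sided Fisher exact test.

Shipped policies (no published rule pins one down, so the choice is
explicit and configurable):

* `nearest_median` (default): the stratum whose KM median is closer to the
  patient's OS; equidistant → positive.
* `midpoint`: threshold OS at the mean of the two medians, positive side =
  the shorter-surviving stratum.
* `km_likelihood` (experimental): the stratum whose survival probability at
  the patient's OS is nearer 0.5; when both strata are equally
  (un)informative — e.g. OS beyond both curves' support — the tie falls
  back to median proximity, so a patient surviving far beyond both medians
  is always adjudicated negative.

Policies needing medians raise an instructive error when a concordant
stratum never reaches S = 0.5. With zero discordant patients the result is
flagged with an empty matrix and undefined p.

Because adjudication against exponential survival is intrinsically noisy
(even a truly negative patient dies early ~1/3 of the time), the benchmark
is validated by construction: when one method reports the latent true
counts and the other adds random false positives, the truth-faithful method
scores at least as accurate in ≥ 90% of replicates — provided each
replicate carries enough discordant patients for the comparison to have
power (the test uses 200-patient cohorts with a 0.7 false-positive rate,
~45 discordant each).

## Problem sizes used by the test suite and acceptance script

Gate-oracle equivalence: 10⁵ random feature vectors straddling every
threshold, with ~3% planted exactly on each boundary. Planted-cell
recovery: 20 cartridges at the default conditions (10 CTC / 5 CHC /
200 WBC / 20 debris each), events matched to planted cells by optimal
assignment with a one-cell-radius (+2 µm slack) distance cap, F1 pooled
over cartridges. Cox recovery: 200 cohorts of 500 patients per hazard
ratio. Benchmark construction: 100 replicates. The synthetic cohort
analysis uses the 67-patient default.

## Known limitations

* Segmentation is deliberately simple; it is calibrated on disk-like,
  well-separated synthetic cells and makes no claim to reproduce any
  specific production tool's numerics.
* Whether marker-channel means should be taken in the union or CK mask is
  genuinely ambiguous; both are supported, union is the default.
* The manual-review emulation shares its visibility thresholds with the
  automated gates by default, so manual-vs-automated differences in
  simulation come only from the operator-noise model and the diameter
  criterion, not from systematically different perception.
* The cohort simulator's PFS is a deterministic fraction of OS plus shared
  censoring — adequate for rank-correlation plumbing, not a model of
  progression dynamics.
* Only univariate Cox stratification is provided; multivariate model
  selection, competing risks and time-varying covariates are out of scope.
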