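# ctcgate

Automated enumeration of circulating tumor cells (CTC) and circulating
hybrid cells (CHC) from multi-channel fluorescence cartridge images, with
manual-vs-automated concordance accounting and survival analysis.

## The problem

In metastatic colorectal cancer, CTC counted in 7.5 mL of blood carry
prognostic information, but the reference workflow — immunomagnetic
enrichment, DAPI/CK/CD45 staining, and *manual* review of an image gallery
by a trained operator — is subject to inter-operator variability,
especially at the low counts typical of this disease. Automated
re-analysis of the archived images replaces the reviewer with explicit
threshold *gates* over measured event features. This package provides that
full automated path and the statistics needed to compare it with a manual
count:

* **Detection** — per-channel segmentation of cartridge frames, merging of
  co-located detections into events, and measurement of the gate feature
  set: per-channel mean/max intensity (AU), size (µm²), eccentricity,
  perimeter (µm), perimeter-to-area, and bounded channel-overlay fractions.
* **Gating** — declarative conjunctive thresholds. An event is a **CTC**
  when CD45 mean ≤ 5 AU, DAPI mean > 45 AU, CK mean > 60 AU,
  16 < CK size ≤ 400 µm², CK-DAPI overlay > 0.2 (plus auxiliary-marker
  ceilings); a **CHC** additionally shows leukocyte signal: CD45 mean
  > 30 AU, CD45 max > 50 AU, CD45-DAPI overlay > 0.2,
  16 < CD45 size ≤ 400 µm². A manual-review emulation (diameter > 4 µm,
  visible nucleus, CK±/CD45± calls, optional seeded operator noise) mirrors
  the gallery criteria.
* **Enumeration & concordance** — per-patient counts, totals/positivity,
  and two-method agreement at a count cutoff (status crosstab, concordance
  rate, numerical discordance).
* **Survival** — Kaplan–Meier estimation S(t) = ∏_{t_i ≤ t}(1 − d_i/n_i),
  the log-rank test, univariate Cox proportional-hazards regression
  h(t|x) = h₀(t)·e^{βx} (Efron ties, Wald CI), Spearman/Mann–Whitney/
  Kruskal–Wallis rank statistics, and the two-sided Fisher exact test —
  plus the *concordant-cohort benchmark*: patients on whom both methods
  agree define reference KM strata, and each method's call on every
  discordant patient is scored against the stratum the patient's observed
  survival points to.
* **Synthetic data** — seeded generators for cartridges with planted,
  labeled cells (blurred disks + background gradient + Poisson/Gaussian
  noise) and for cohort tables (zero-inflated negative-binomial counts,
  two noisy observation channels, exponential proportional-hazards
  survival), so the whole pipeline is testable without patient data.

See `docs/methods.md` for the model details, parameter defaults and the
reasoning behind them.

## Worked example

Simulate a small cartridge, detect and gate it:

```sh
$ ctcgate simulate --kind cartridge --spec cart_spec.json --seed 2 --out cart.tiff
wrote cart.tiff (41 planted cells)
$ ctcgate detect cart.tiff --out features.csv
wrote features.csv (41 events)
$ ctcgate gate features.csv --out calls.csv
wrote calls.csv (CTC 4, CHC 2, other 35)
```

with `cart_spec.json` requesting 4 CTC, 2 CHC, 30 leukocytes and 5 debris
fragments: all 41 planted cells are detected and the gate calls recover
the planted class counts exactly (the 35 "other" events are the leukocytes
and debris, which correctly fail the CTC/CHC gates).

Simulate a 67-patient cohort and run the comparison analyses:

```sh
$ ctcgate simulate --kind cohort --seed 5 --out cohort.csv
wrote cohort.csv (67 patients)
$ ctcgate concord cohort.csv --cutoff 1 --out conc.json
CTC concordance at >= 1: 76.1%
$ ctcgate survive cohort.csv --count-col ctc_manual --cutoff 1 --out surv.json
HR 1.67 (95% CI 0.93-2.99), log-rank p = 0.08081
$ ctcgate benchmark cohort.csv --cutoff 1 --out bm.json
manual correct 7/16, automated correct 9/16, Fisher p = 0.724
```

Reading: the two simulated enumeration methods agree on CTC positivity for
76.1% of patients; patients with ≥ 1 manually-counted CTC have a fitted
hazard ratio of 1.67 for overall survival (not significant at this seed's
n = 67); and of the 16 patients the methods disagree on, the automated
counts matched the survival-based expectation for 9 versus 7 for the
manual counts — a difference Fisher's exact test finds unremarkable
(p = 0.72), as expected when both observation channels are equally noisy.

The same operations are available as library functions
(`ctcgate.enumerate_cartridge`, `ctcgate.detection_concordance`,
`ctcgate.stratify_and_compare`, `ctcgate.benchmark_discordant`, …), which
is the intended interface for scripted analysis.

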