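# Methods

`urorisk` implements a multivariable risk-modelling workflow for prostate
biopsy triage from urine biomarkers: stability feature selection with the
Boruta algorithm under bootstrap resampling, regression random forests
trained on a continuous Gleason-derived label with out-of-bag (OOB) risk
scores, discrimination and effect-size statistics, and decision-curve
analysis reweighted to a reference population's outcome mix. This note
records the model assumptions, the tunable parameters and their defaults,
the numerical choices, and what the synthetic cohorts do and do not emulate.

## Cohort model and the synthetic generator

A cohort is one record per patient: age (years), serum PSA (ng/mL), a
DRE prostate-size category (Small/Medium/Large/Unknown), urine volume (mL),
one EN2 ELISA concentration, raw counts for a panel of cf-RNA NanoString
probes plus positive-control probes, and the biopsy outcome — one of
unbiopsied no-evidence-of-cancer (NEC, PSA < 4), biopsy-negative, Gleason 6,
3+4, 4+3, or ≥8 — with a metastatic flag and an optional weeks-since-biopsy
field.

The generator (`urorisk.synthetic`) emulates the structure of the
single-site development cohort this workflow was designed around:

* **Class counts.** Defaults are the development-cohort sizes
  (25/52/30/48/24/28 across NEC, biopsy-negative, Gs6, Gs3+4, Gs4+3, Gs≥8;
  n = 207), with an optional metastatic class for exercising exclusion
  filters.
* **PSA and EN2** are log-normal — strictly positive, right-skewed — with
  per-class locations moment-matched to the published cohort table's
  medians and IQR ratios (log-normal IQR ratio `exp(1.349 σ)`). NEC is
  truncated below 4 ng/mL (the class is defined by not meeting the biopsy
  threshold); biopsied classes are truncated to [4, 100); the metastatic
  class sits above 100 ng/mL.
* **cf-RNA counts** are negative-binomial on the raw-count scale
  (dispersion `count_dispersion`, default size 10), around per-probe
  baselines (log-uniform 50–2000 counts) with three multiplicative layers:
  a per-class log2 shift for ground-truth informative probes, a per-sample
  per-probe biological log-normal (default 0.8 log2 sd), and a per-sample
  technical scale factor (default 0.3 natural-log sd) that also multiplies
  the positive-control probes and is therefore removed by normalisation.
* **Informative probes.** By default the first 11 probes carry a monotone
  per-class log2 shift (0 → 0.10 → 0.35 → 0.60 → 0.80 → 0.95 across the
  outcome classes), mirroring the size of the cf-RNA signature the
  motivating analysis retained. Marker effect sizes (EN2 shifts
  0.4–2.5 log2, probe shifts above, PSA class locations) were calibrated
  once so the single-mode model variants reach out-of-bag any-cancer AUCs
  near the reported comparator levels (clinical ≈ 0.75–0.8, EN2-only ≈ 0.8,
  probes-only ≈ 0.8, integrated ≈ 0.88) and then frozen; they are the
  package's stated study conditions, not fitting targets.

One integer seed fully determines a cohort; every stage of the pipeline
derives independent child streams from the root seed with
`numpy.random.SeedSequence` spawn keys (stage- and feature-name-keyed, so
e.g. a shadow permutation does not depend on column order). The generator
does **not** emulate assay chemistry, batch or inter-site effects, probe–probe
biological correlation beyond shared class membership, or missing data.
Consequently, passing tests demonstrate that the algorithms recover known
planted structure under realistic marginal noise — not that the models would
reach the same accuracy on real cohorts, where probes are correlated and
effects are smaller and messier.

## Preprocessing

* **Exclusions.** A record is removed if it had a prostate biopsy or TURP
  fewer than 6 weeks before sampling, a positive bone scan, or PSA
  > 100 ng/mL; the exclusion log records every applicable reason.
  Boundary values (exactly 6 weeks, exactly 100 ng/mL) are eligible.
* **Normalisation.** Counts are scaled per sample by
  `reference / geomean(positive controls)` and log2-transformed with
  pseudocount 1 (zero counts occur in urinary cf-RNA). The cohort reference
  is the geometric mean of the per-sample geometric means — under which the
  two-sample worked example (control geomeans 4 and 16) gives reference 8
  and scale factors 2 and 0.5. A fixed external `reference` can be supplied
  instead; only against a fixed reference is a whole-sample rescaling
  exactly invariant, since a cohort-derived reference itself moves by
  `2^(1/n)` when one sample's counts double.
* **Training label.** Biopsy outcome maps to a continuous label:
  0 for NEC *and* biopsy-negative, 0.5 for Gleason 6 and 3+4, 1 for
  Gleason ≥ 4+3 — acknowledging that equal Gleason scores do not imply
  equal tumour burden. The label is used for training only; every
  evaluation uses the categorical outcome.
* **Variable sets.** SoC = {age, PSA, DRE size, urine volume}; Engrailed =
  {EN2}; ExoRNA = the probe panel; ExoGrail = all of them (172 predictors
  at the default panel size). EN2 and PSA enter untransformed (trees are
  invariant to monotone transforms); DRE size is ordinal-coded with
  "Unknown" as an explicit level. T-stage and clinician DRE impression are
  not modelled (no schema for them); urine volume is kept as a candidate
  even though selection never retains it.

## Random forest and OOB risk scores

Forests are regression ensembles of 401 trees. Per-tree samples are drawn
*without* replacement at fraction 0.632 of n — the without-replacement
counterpart of a bootstrap sample's expected unique fraction —
so each tree leaves a clean OOB set; minimum leaf size is 5 and
features-per-split is ⌊p/3⌋ (min 1), the classical regression defaults.
A sample's risk score is the equal-weight mean prediction of the trees that
did not train on it (expected OOB tree count 401 × 0.368 ≈ 148); with
labels in {0, 0.5, 1} every score lies in [0, 1]. A single-feature forest
(the EN2-only variant) is effectively a bagged-stump ensemble and is
permitted. Samples in-bag for every tree (possible only in tiny forests)
are flagged and excluded from metrics.

## Boruta and stability selection

One Boruta run iterates: build "shadow features" (independently permuted
copies of the in-play columns — same marginals, no label association), fit
a forest on real + shadow columns, and compute OOB permutation importance —
the mean increase in a tree's OOB squared error when one feature is
permuted among that tree's OOB samples ("mean decrease in accuracy" for a
regression forest). Each undecided feature's importance is normalised to a
Z-score against the shadow-importance distribution and compared with the
*maximal* shadow importance: significantly below (one-sided, level `alpha`,
default 0.01) ⇒ Rejected and dropped; significantly above ⇒ Confirmed.
Survivors at `max_iter` (default 15) remain Tentative and count as not
selected — selection is deliberately conservative.

Three design choices matter and were made after observing failure modes of
the naive scheme:

* **Confirmed features stay in the model** until the run ends (only
  rejected features are dropped), so strong signal keeps absorbing
  importance and its shadows keep feeding the null distribution.
* **The shadow pool is padded to at least 64 columns** (extra independent
  permutations, cycling over in-play features). With a small pool the
  maximum of the shadow importances collapses towards their mean, and
  features whose only "signal" is an in-sample chance correlation (|r| up
  to ~0.2 at n ≈ 200 among dozens of probes) would be waved through.
* **Confirmation is Bonferroni-guarded at `alpha / max_iter`**, because
  every iteration offers a fresh confirmation opportunity against a freshly
  rolled shadow maximum, while a real feature's chance correlation persists.
  Rejection stays at `alpha` per iteration.

The internal forest uses 401 trees and `sqrt(p)` features per split (the
customary Boruta heuristic, which also keeps many-shadow fits affordable).

Stability selection reruns Boruta on `B` bootstrap resamples (with
replacement, size n; default B = 1000) and retains features confirmed in at
least a fraction `threshold` (default 0.9, inclusive: confirmed in exactly
90% of resamples is retained). The resample schedule depends only on
(n, B, seed), so every model variant sees identical resamples, and model
training shares the same root seed.

## Evaluation

* **Endpoints.** Any cancer (all Gleason classes), Gleason ≥ 3+4, and
  Gleason ≥ 4+3; NEC and biopsy-negative are always negative.
* **AUC** is the Mann–Whitney concordance probability with ties counted ½;
  95% CIs come from 1000 stratified bootstrap resamples (cases and
  controls resampled separately, percentile 2.5/97.5 without interpolation
  refinement). AUC differences between paired score sets use the same
  stratified resampling applied to both sets on identical indices, with a
  two-sided p from the normal approximation (mean/SD) of the resampled
  difference distribution; a DeLong-style analytic test is deliberately not
  substituted, to keep the bootstrap contract.
* **Ordinal association** is a proportional-odds (ordinal logistic) fit of
  outcome level on risk score, reported as the odds ratio per 0.1 risk
  increase, `exp(0.1 β)`, with a delta-method CI. Outcome levels are
  {no cancer (NEC pooled with biopsy-negative), Gs6, Gs3+4, Gs ≥ 4+3} —
  four levels; whether the motivating analysis split NEC from
  biopsy-negative is not stated, so the pooled four-level coding is this
  package's assumption.
* **Group mean differences** of risk scores (each outcome group vs the
  unbiopsied NEC reference, with biopsy-negative kept as its own
  comparison group) use bias-corrected and accelerated (BCa) bootstrap
  intervals: 1000 resamples; bias correction from the fraction of
  resampled differences below the observed one; acceleration from the
  jackknife skewness over both groups' observations. With a singleton
  group the acceleration is undefined and the interval falls back to plain
  percentiles with a warning; BCa reduces to the percentile interval when
  bias and acceleration vanish.
* **Threshold summaries** report the largest score cut-off reaching a
  target sensitivity and the fraction of negatives at or above it.

## Decision-curve analysis

Net benefit at decision threshold p_t is `TP/n − (FP/n)·p_t/(1−p_t)`;
standardised net benefit divides by prevalence, so treat-none is 0,
a perfect classifier is 1, and treat-all follows the closed form
`1 − ((1−prev)/prev)·p_t/(1−p_t)`. Curves are evaluated on a 0.01–0.50
threshold grid (step 0.01) after stratified bootstrap reweighting of the
cohort to a reference population's biopsy-outcome mix — by default 60.6%
no cancer, 23.6% Gleason 6, 8.7% Gleason 7, 7.1% Gleason ≥ 8, in resamples
of exactly 197 drawn with largest-remainder rounding per stratum
(119/47/17/14); the Gleason-7 stratum pools 3+4 and 4+3 and draws uniformly
from the pool, preserving their cohort ratio in expectation. Reported
curves are means over 1000 resamples.

The net reduction in biopsies per 100 patients from adopting a model at
threshold p_t is `(NB_model − NB_reference) × (1−p_t)/p_t × 100`. Both
reference conventions are provided — treat-all, and a comparator model
(e.g. the clinical standard-of-care model) — because the two appear in
different places in the motivating analysis and are not reconciled there;
the default is treat-all.

## Problem sizes and numerical choices

Bootstrap-heavy defaults follow the motivating analysis (B = 1000 stability
resamples, 1000 evaluation resamples, 1000 prevalence-matching resamples,
401 trees). The test suite exercises the same code paths at reduced sizes
chosen as the package's own trade-off between statistical resolution and
turnaround: stability selection checks use B = 25–100 with 48–64-tree
internal forests; coverage checks use 200–400 trials; the recovery check
plants 11 informative probes (≥1.5 log2 shift) in a 40-probe panel.
`PipelineConfig.scaled_down()` (and the CLI's `--scaled-down`) divides all
resample counts by ten for smoke runs.

Degenerate inputs are defined errors, not silent results: single-class
labels (selection and AUC undefined), empty groups, non-finite values,
empty resampling strata, and thresholds outside (0, 1) all raise typed
exceptions. Ties at the retention threshold are kept (≥); ties in scores
count ½ in the AUC; the percentile bounds use numpy's linear interpolation.

## Known limitations

* Synthetic probes are conditionally independent given class; real cf-RNA
  panels are correlated, so selection stability on real data will be lower
  at equal effect sizes.
* The proportional-odds fit can fail to converge under complete separation;
  the estimate is returned flagged rather than raising.
* OOB risk scores are internal validation only; nothing here substitutes
  for external-cohort validation of a clinical model.
* The published real-data headline numbers (e.g. integrated-model AUCs of
  0.89/0.90/0.84 across endpoints) require the deposited patient-level
  cohort and are not reproduced by the synthetic workflow; the pipeline
  will compute them directly if such a cohort table is supplied in the
  documented CSV schema.
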