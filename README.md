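# urorisk

Urinary biomarker risk modelling for prostate biopsy triage.

Men with an elevated serum PSA (≥ 4 ng/mL) or an adverse digital rectal
examination are referred for a TRUS biopsy, yet a large share of those
biopsies find no cancer, and many cancers found are indolent. Urine is an
attractive non-invasive window on the prostate: this package builds and
evaluates multivariable risk models that integrate clinical variables
(age, PSA, DRE prostate-size estimate, urine volume), a whole-urine EN2
protein ELISA measurement, and cell-free-RNA expression from urinary
extracellular vesicles quantified as NanoString probe counts. It is aimed
at biostatisticians and biomarker researchers who want a tested, seeded,
end-to-end reference implementation of this class of analysis.

## What it computes

**Feature selection.** Candidate predictors are filtered with the Boruta
algorithm: each feature's random-forest permutation importance is compared
against "shadow features" (permuted copies that carry no label
association); features significantly below the maximal shadow importance
are dropped, features significantly above are confirmed. Boruta is rerun
on B = 1000 bootstrap resamples of the cohort, and a feature enters a model
only if it is confirmed in ≥ 90% of resamples (selection proportion
π_f ≥ 0.9).

**Risk models.** Four comparator variants — SoC (clinical only), Engrailed
(EN2 only), ExoRNA (probe panel only), and the integrated ExoGrail — are
regression random forests (401 trees, per-tree subsampling without
replacement) trained on a continuous label L derived from biopsy outcome:

    L = 0    no evidence of cancer (unbiopsied NEC or biopsy-negative)
    L = 0.5  Gleason 6 or 3+4
    L = 1    Gleason ≥ 4+3

Risk scores r ∈ [0, 1] are the out-of-bag predictions: each sample is
scored only by the trees that never trained on it.

**Evaluation.** AUCs for any cancer, Gleason ≥ 3+4 and Gleason ≥ 4+3 with
stratified-bootstrap 95% CIs; paired bootstrap AUC-difference tests;
a proportional-odds odds ratio per 0.1 risk increase; BCa bootstrap
intervals for group mean score differences; and decision-curve analysis on
cohorts reweighted to a screening-population outcome mix (60.6% no cancer,
23.6% Gleason 6, 8.7% Gleason 7, 7.1% Gleason ≥ 8; resamples of 197), with
standardised net benefit sNB = NB / prevalence, where

    NB = TP/n − (FP/n) · p_t/(1 − p_t)

at decision threshold p_t, and the net reduction in biopsies per 100
patients, (NB_model − NB_reference) · (1 − p_t)/p_t · 100.

A synthetic-cohort generator with planted, configurable ground truth makes
the whole pipeline testable without any data download; see
`docs/methods.md` for the generative model and all defaults.

## Worked example

Generate a development-cohort-sized synthetic cohort (207 patients, 167
probes, 11 informative) and run the full pipeline. Stability selection at
the full B = 1000 with 401-tree internal forests is CPU-hungry; the example
uses B = 50 resamples and takes about a quarter of an hour on one core:

```sh
urorisk simulate --seed 42 --out cohort.csv
urorisk run --cohort cohort.csv --outdir results --seed 42 --b 50
```

which prints (output from this exact invocation):

```
wrote 207 records to cohort.csv
SoC: any_cancer=0.820, gs_ge_3p4=0.766, gs_ge_4p3=0.743
Engrailed: any_cancer=0.847, gs_ge_3p4=0.824, gs_ge_4p3=0.747
ExoRNA: any_cancer=0.862, gs_ge_3p4=0.854, gs_ge_4p3=0.849
ExoGrail: any_cancer=0.945, gs_ge_3p4=0.926, gs_ge_4p3=0.876
artefacts written to results
```

Each line is one model variant's out-of-bag AUC for the three biopsy
endpoints: on this synthetic cohort the clinical model is weakest, the two
single-biomarker models are intermediate, and the integrated model is
strongest on every endpoint — the qualitative pattern the workflow is
designed to expose. Selection behaves as intended: the SoC variant retains
exactly {age, psa}, Engrailed retains {en2}, ExoRNA recovers all 11
planted probes (plus two chance-correlated ones), and ExoGrail combines
the clinical, EN2 and probe signal (16 features). `results/metrics.json`
also reports, for this run, an ExoGrail proportional-odds OR of 2.82 per
0.1 risk increase (95% CI 2.33–3.41) and BCa mean score differences vs the
unbiopsied no-cancer group of 0.28 (Gleason 6), 0.42 (3+4) and 0.52
(≥ 4+3). `results/` further contains per-variant stability reports with
selection proportions, OOB risk scores, paired AUC tests, decision curves
(`dca_<endpoint>.csv`), biopsy-reduction curves against both the treat-all
and SoC baselines, an exclusion log, and a run manifest (seed, config
hash, package version). Re-running with the same seed reproduces every
artefact byte-for-byte.

The same steps work on a real cohort table in the documented CSV schema
(one row per sample; `probe_*` count columns, `posctl_*` positive-control
columns, clinical columns and `outcome`).

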