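"""End-to-end pipeline wiring: preprocess -> select -> train -> evaluate -> DCA.

One root seed governs every stage; per-stage streams are derived
deterministically (stage-name keyed), so a re-run with the same configuration
and seed reproduces every artefact bit-for-bit.  Each run writes a manifest
recording the configuration hash, seed and package version, and a JSON-lines
log with row/feature counts at stage boundaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dca import PrevalenceScheme, dca_curves, reduction_curves
from .errors import ConfigurationError
from .evaluation import ENDPOINTS, auc_ci, auc_difference_test, mean_diff_bca, proportional_odds_or
from .models import run_all_variants
from .preprocess import VARIANTS, apply_exclusions
from .synthetic import CohortRecord, read_cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of a full pipeline run."""

    seed: int = 0
    variants: tuple[str, ...] = VARIANTS
    # stability selection
    B: int = 1000
    threshold: float = 0.9
    alpha: float = 0.01
    max_iter: int = 100
    selection_n_trees: int = 401
    # risk-model forests
    n_trees: int = 401
    subsample_fraction: float = 0.632
    # evaluation
    n_eval_resamples: int = 1000
    # decision-curve analysis
    dca_scheme: PrevalenceScheme = field(default_factory=PrevalenceScheme)
    endpoints: tuple[str, ...] = ENDPOINTS

    def scaled_down(self, factor: int = 10) -> "PipelineConfig":
        """A cheaper configuration for smoke runs: resample counts / factor."""
        return dataclasses.replace(
            self,
            B=max(1, self.B // factor),
            n_eval_resamples=max(2, self.n_eval_resamples // factor),
            dca_scheme=dataclasses.replace(
                self.dca_scheme, n_resamples=max(1, self.dca_scheme.n_resamples // factor)
            ),
        )

    def validate(self) -> None:
        for v in self.variants:
            if v not in VARIANTS:
                raise ConfigurationError(f"unknown variant {v!r}")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                **{
                    k: v
                    for k, v in dataclasses.asdict(self).items()
                    if k != "dca_scheme"
                },
                "dca_scheme": {
                    "proportions": dict(self.dca_scheme.proportions),
                    "n": self.dca_scheme.n,
                    "n_resamples": self.dca_scheme.n_resamples,
                    "seed": self.dca_scheme.seed,
                },
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    cohort: Sequence[CohortRecord] | str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Execute the full analysis and write its artefacts under ``outdir``.

    Returns the metrics dictionary that is also written to ``metrics.json``.
    Artefacts: exclusion log (JSON lines), per-variant stability report
    (JSON), OOB risk scores (CSV), metrics (JSON), decision curves and
    reduction curves per endpoint (CSV), and a run manifest.
    """
    config = config or PipelineConfig()
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = read_cohort(cohort) if isinstance(cohort, (str, Path)) else list(cohort)
    log_path = outdir / "stages.jsonl"
    log_lines: list[dict] = []

    def stage(name: str, **info) -> None:
        log_lines.append({"stage": name, **info})

    stage("load", n_records=len(records))
    retained, exclusion_log = apply_exclusions(records)
    (outdir / "exclusions.jsonl").write_text(
        "".join(json.dumps(e) + "\n" for e in exclusion_log)
    )
    stage("exclusions", n_retained=len(retained), n_excluded=len(exclusion_log))

    results = run_all_variants(
        retained,
        variants=config.variants,
        B=config.B,
        threshold=config.threshold,
        alpha=config.alpha,
        max_iter=config.max_iter,
        selection_rf_params={"n_trees": config.selection_n_trees},
        n_trees=config.n_trees,
        subsample_fraction=config.subsample_fraction,
        seed=config.seed,
    )
    score_frames = []
    for variant, res in results.items():
        res.stability.to_json(outdir / f"stability_{variant}.json")
        score_frames.append(res.scores.frame())
        stage(
            "variant",
            variant=variant,
            n_selected=len(res.spec.selected_features),
            selected=list(res.spec.selected_features),
        )
    pd.concat(score_frames).to_csv(outdir / "risk_scores.csv", index=False, float_format="%.17g")

    outcomes = [r.outcome for r in retained]
    metrics: dict = {"variants": {}, "config_hash": config.config_hash(), "seed": config.seed}
    for variant, res in results.items():
        scores = res.scores.scores.to_numpy()
        vm: dict = {"selected_features": list(res.spec.selected_features), "auc": {}}
        from .evaluation import binary_endpoint  # local import avoids cycle at module load

        for endpoint in config.endpoints:
            y = binary_endpoint(np.asarray(outcomes, dtype=object), endpoint)
            roc = auc_ci(
                scores, y, n_resamples=config.n_eval_resamples, seed=config.seed, endpoint=endpoint
            )
            vm["auc"][endpoint] = {
                "auc": roc.auc,
                "ci_lower": roc.ci_lower,
                "ci_upper": roc.ci_upper,
            }
        ordinal = proportional_odds_or(scores, outcomes)
        vm["proportional_odds"] = {
            "or_per_01": ordinal.or_per_01,
            "ci_lower": ordinal.ci_lower,
            "ci_upper": ordinal.ci_upper,
            "converged": ordinal.converged,
        }
        # Mean score differences vs the unbiopsied no-evidence-of-cancer group.
        ref = res.scores.scores[[o == "NEC" for o in outcomes]].to_numpy()
        vm["mean_differences_vs_nec"] = {}
        for grp in ("BiopsyNegative", "Gs6", "Gs3+4", "Gs4+3plus"):
            if grp == "Gs4+3plus":
                mask = [o in ("Gs4+3", "Gs8plus") for o in outcomes]
            else:
                mask = [o == grp for o in outcomes]
            vals = res.scores.scores[mask].to_numpy()
            if len(vals) == 0 or len(ref) == 0:
                continue
            est = mean_diff_bca(
                vals, ref, n_resamples=config.n_eval_resamples, seed=config.seed, group=grp
            )
            vm["mean_differences_vs_nec"][grp] = {
                "delta": est.delta,
                "ci_lower": est.ci_lower,
                "ci_upper": est.ci_upper,
            }
        metrics["variants"][variant] = vm

    # Pairwise AUC-difference tests per endpoint.
    metrics["auc_difference_tests"] = {}
    variant_names = list(results)
    for endpoint in config.endpoints:
        y = binary_endpoint(np.asarray(outcomes, dtype=object), endpoint)
        tests = {}
        for i, va in enumerate(variant_names):
            for vb in variant_names[i + 1 :]:
                delta, p = auc_difference_test(
                    results[va].scores.scores.to_numpy(),
                    results[vb].scores.scores.to_numpy(),
                    y,
                    n_resamples=config.n_eval_resamples,
                    seed=config.seed,
                )
                tests[f"{va}_vs_{vb}"] = {"delta_auc": delta, "p_value": p}
        metrics["auc_difference_tests"][endpoint] = tests

    # Decision-curve analysis on the prevalence-matched population.
    scores_by_variant = {v: results[v].scores.scores.to_numpy() for v in results}
    metrics["dca"] = {}
    for endpoint in config.endpoints:
        curve = dca_curves(
            scores_by_variant, outcomes, scheme=config.dca_scheme, endpoint=endpoint
        )
        curve.to_csv(outdir / f"dca_{endpoint}.csv")
        reduction_curves(curve, reference="treat_all").to_csv(
            outdir / f"reduction_treat_all_{endpoint}.csv", index=False, float_format="%.10g"
        )
        if "SoC" in results:
            reduction_curves(curve, reference="SoC").to_csv(
                outdir / f"reduction_soc_{endpoint}.csv", index=False, float_format="%.10g"
            )
        metrics["dca"][endpoint] = {"prevalence": curve.prevalence}
        stage("dca", endpoint=endpoint, prevalence=curve.prevalence)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_records": len(records),
        "n_retained": len(retained),
        "variants": variant_names,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True))
    (log_path).write_text("".join(json.dumps(l) + "\n" for l in log_lines))
    return metrics
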