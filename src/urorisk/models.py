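"""Comparator random-forest risk models and out-of-bag risk scores.

Four model variants are trained on the continuous training label with a
regression random forest (401 trees, per-tree subsampling without
replacement): SoC (clinical variables), Engrailed (EN2 ELISA only), ExoRNA
(cf-RNA probes only) and the fully integrated ExoGrail.  Each variant's
features are chosen by bootstrapped Boruta stability selection on its own
variable set, all variants sharing the same resample schedule and root seed.

Risk scores are the out-of-bag predictions: a sample's score aggregates only
the trees that did not train on it, giving internally validated risks in
[0, 1] without a held-out set.  A single-feature forest (the Engrailed
variant) is effectively a bagged-stump ensemble: every split uses the one
feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .boruta import StabilityReport, stability_select
from .errors import DegenerateInputError, SchemaError, UroriskError, ValidationError
from .forest import RandomForest
from .preprocess import VARIANTS, FeatureMatrix, build_feature_matrix
from .synthetic import CohortRecord

__all__ = [
    "RiskModelSpec",
    "RiskScoreSet",
    "VariantResult",
    "train_model",
    "oob_scores",
    "run_all_variants",
]


@dataclass(frozen=True)
class RiskModelSpec:
    """Hyper-parameters and feature set for one model variant."""

    variant: str
    selected_features: tuple[str, ...]
    n_trees: int = 401
    subsample_fraction: float = 0.632
    min_samples_leaf: int = 5
    max_features: int | float | str = "third"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise SchemaError(f"unknown variant {self.variant!r}")
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if not self.selected_features:
            raise ValidationError(f"{self.variant}: selected feature set is empty")


@dataclass
class RiskScoreSet:
    """Per-sample out-of-bag risk in [0, 1] for a named model variant."""

    variant: str
    scores: pd.Series  # indexed by sample_id; NaN if never out-of-bag
    oob_tree_counts: pd.Series
    flagged: list[str] = field(default_factory=list)  # samples in-bag in all trees

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.scores.index,
                "variant": self.variant,
                "risk": self.scores.to_numpy(),
                "oob_trees": self.oob_tree_counts.to_numpy(),
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame().to_csv(path, index=False, float_format="%.17g")
        return path


def train_model(matrix: FeatureMatrix, spec: RiskModelSpec) -> RandomForest:
    """Fit the variant's regression forest on the continuous label."""
    sub = matrix.select_features(list(spec.selected_features))
    if sub.label.isna().any():
        raise ValidationError("label contains missing values")
    forest = RandomForest(
        n_trees=spec.n_trees,
        subsample_fraction=spec.subsample_fraction,
        replace=False,
        max_features=spec.max_features,
        min_samples_leaf=spec.min_samples_leaf,
        random_state=int(child_rng(spec.seed, "model", spec.variant).integers(2**31 - 1)),
    )
    forest.fit(sub.values, sub.label.to_numpy(dtype=float))
    return forest


def oob_scores(model: RandomForest, matrix: FeatureMatrix, variant: str) -> RiskScoreSet:
    """Out-of-bag risk per training sample.

    Samples that were in-bag for every tree (possible only for tiny forests)
    are flagged and carry NaN scores; downstream metrics exclude them.
    """
    preds, counts = model.oob_predict()
    ids = matrix.sample_ids
    scores = pd.Series(preds, index=ids, name="risk")
    ntrees = pd.Series(counts, index=ids, name="oob_trees")
    flagged = [ids[i] for i in np.flatnonzero(counts == 0)]
    if flagged:
        import warnings

        warnings.warn(
            f"{variant}: {len(flagged)} sample(s) were in-bag in every tree; "
            "their OOB risk is undefined",
            stacklevel=2,
        )
    return RiskScoreSet(variant=variant, scores=scores, oob_tree_counts=ntrees, flagged=flagged)


@dataclass
class VariantResult:
    """Everything produced for one model variant."""

    variant: str
    stability: StabilityReport
    spec: RiskModelSpec
    model: RandomForest
    scores: RiskScoreSet


def run_all_variants(
    records: Sequence[CohortRecord],
    variants: Sequence[str] = VARIANTS,
    B: int = 1000,
    threshold: float = 0.9,
    alpha: float = 0.01,
    max_iter: int = 100,
    selection_rf_params: Mapping | None = None,
    n_trees: int = 401,
    subsample_fraction: float = 0.632,
    seed: int = 0,
) -> dict[str, VariantResult]:
    """Feature-select, train and score every requested model variant.

    For each variant: build its predictor matrix, run bootstrapped Boruta
    stability selection on it, train the forest on the retained features and
    emit out-of-bag risk scores.  All variants share the same root seed, and
    the bootstrap schedule depends only on (n, B, seed), so resamples are
    identical across variants.
    """
    results: dict[str, VariantResult] = {}
    for variant in variants:
        if variant not in VARIANTS:
            raise SchemaError(f"unknown variant {variant!r}")
        try:
            matrix = build_feature_matrix(records, variant)
            report = stability_select(
                matrix,
                B=B,
                threshold=threshold,
                rf_params=selection_rf_params,
                alpha=alpha,
                max_iter=max_iter,
                seed=seed,
            )
            retained = report.retained
            if not retained:
                raise DegenerateInputError(
                    f"no features reached selection proportion {threshold:g}; "
                    f"max was {report.proportions.max():.3f} "
                    f"({report.proportions.idxmax()})"
                )
            spec = RiskModelSpec(
                variant=variant,
                selected_features=tuple(retained),
                n_trees=n_trees,
                subsample_fraction=subsample_fraction,
                seed=seed,
            )
            model = train_model(matrix, spec)
            scores = oob_scores(model, matrix.select_features(retained), variant)
        except UroriskError as exc:
            exc.args = (f"[variant {variant}] {exc}",)
            raise
        results[variant] = VariantResult(
            variant=variant, stability=report, spec=spec, model=model, scores=scores
        )
    return results
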