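"""Boruta shadow-feature selection and its bootstrapped stability wrapper.

A single Boruta run iteratively compares each undecided feature's random-
forest permutation importance against "shadow features" — independently
permuted copies of the undecided columns, which carry the same marginal
distribution but no association with the label.  At each iteration the
importances are normalised to Z-scores against the shadow-importance
distribution and compared with the *maximal* shadow importance: features
significantly above it (one-sided Z-test at level ``alpha``) are Confirmed,
features significantly below are Rejected and dropped, and the loop repeats
with fresh shadows until every feature is decided or ``max_iter`` is reached
(survivors are Tentative, counted as not selected).

Stability selection repeats the run on ``B`` bootstrap resamples of the
cohort (with replacement, size n) and retains the features confirmed in at
least a fraction ``threshold`` of resamples (>= comparison, so a feature
confirmed in exactly 90% of resamples is retained at threshold 0.9).  The
resample index schedule depends only on (n, B, seed), so every model variant
sees identical resamples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .errors import DegenerateInputError, ValidationError
from .forest import RandomForest
from .preprocess import FeatureMatrix

__all__ = [
    "BorutaRunResult",
    "StabilityReport",
    "boruta_once",
    "stability_select",
    "bootstrap_indices",
    "importance_trajectory",
]

#: Minimum number of shadow columns per iteration.  The shadow pool is padded
#: with extra independent permutations (cycling over the in-play features)
#: whenever fewer features remain, so the maximal-shadow reference stays a
#: high bar: with a small pool the max of the shadow importances collapses
#: towards their mean and chance-correlated noise features would be waved
#: through.
SHADOW_POOL = 64

#: Internal forest defaults.  Tree count matches the risk-model forests;
#: features-per-split uses the square-root heuristic customary for Boruta
#: implementations, which also keeps the many-shadow fits affordable.
DEFAULT_RF_PARAMS: dict = {
    "n_trees": 401,
    "subsample_fraction": 0.632,
    "replace": False,
    "max_features": "sqrt",
    "min_samples_leaf": 5,
}


@dataclass
class BorutaRunResult:
    """Outcome of one Boruta run."""

    decision: pd.Series  # {"Confirmed", "Rejected", "Tentative"} per feature
    importance_z: pd.Series  # last computed Z vs the maximal shadow importance
    iterations: int

    @property
    def confirmed(self) -> list[str]:
        return list(self.decision.index[self.decision == "Confirmed"])


@dataclass
class StabilityReport:
    """Per-feature selection proportions over ``B`` bootstrap Boruta runs."""

    proportions: pd.Series  # pi_f = confirmed count / B
    importance: pd.DataFrame  # B x features, last Z-score per resample
    B: int
    threshold: float
    seed: int

    @property
    def retained(self) -> list[str]:
        return list(self.proportions.index[self.proportions >= self.threshold])

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "B": self.B,
            "threshold": self.threshold,
            "seed": self.seed,
            "proportions": {k: float(v) for k, v in self.proportions.items()},
            "retained": self.retained,
            "importance": {
                c: [None if not np.isfinite(v) else float(v) for v in self.importance[c]]
                for c in self.importance.columns
            },
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "StabilityReport":
        d = json.loads(Path(path).read_text())
        imp = pd.DataFrame(
            {c: [np.nan if v is None else v for v in vals] for c, vals in d["importance"].items()}
        )
        return cls(
            proportions=pd.Series(d["proportions"]),
            importance=imp,
            B=d["B"],
            threshold=d["threshold"],
            seed=d["seed"],
        )


def _validate_matrix(matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    X = matrix.values
    y = matrix.label.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise DegenerateInputError("need at least 2 samples and 1 feature")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in feature matrix or label")
    if np.unique(y).size < 2:
        raise DegenerateInputError("label takes a single value; selection undefined")
    return X, y


def boruta_once(
    matrix: FeatureMatrix,
    rf_params: Mapping | None = None,
    alpha: float = 0.01,
    max_iter: int = 15,
    seed: int = 0,
) -> BorutaRunResult:
    """One Boruta run over the matrix's features.

    At each iteration the forest sees every not-yet-rejected feature
    (undecided *and* already-confirmed, the latter kept so strong signal
    continues to absorb importance) plus a shadow pool: one fresh permuted
    copy of each in-play feature, padded to at least :data:`SHADOW_POOL`
    columns.  Undecided features significantly below the maximal shadow
    importance (one-sided Z at level ``alpha``, with the Z-score taken
    against the shadow-importance distribution) are Rejected and dropped;
    features significantly above it are Confirmed, at the Bonferroni-guarded
    level ``alpha / max_iter`` because every iteration is a fresh
    confirmation opportunity.  Survivors at ``max_iter`` stay Tentative.

    Shadow permutations are keyed by feature *name*, so reordering columns
    does not change the permutation a given feature's shadow receives.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    X, y = _validate_matrix(matrix)
    names = list(matrix.feature_names)
    n, p = X.shape
    params = dict(DEFAULT_RF_PARAMS)
    if rf_params:
        params.update(rf_params)

    decision = pd.Series("Tentative", index=names, dtype=object)
    z_last = pd.Series(np.nan, index=names, dtype=float)
    undecided = list(range(p))
    confirmed: list[int] = []
    z_reject = float(stats.norm.ppf(1 - alpha))
    z_confirm = float(stats.norm.ppf(1 - alpha / max_iter))
    iterations = 0

    for it in range(max_iter):
        iterations = it + 1
        in_play = undecided + confirmed
        k = len(in_play)
        # Shadow sources: every in-play feature once, padded by cycling.
        shadow_src = list(in_play)
        pad = 0
        while len(shadow_src) < SHADOW_POOL:
            shadow_src.append(in_play[pad % k])
            pad += 1
        shadows = np.empty((n, len(shadow_src)))
        for s_i, f in enumerate(shadow_src):
            rng_f = child_rng(seed, "shadow", it, names[f], s_i // k)
            shadows[:, s_i] = X[rng_f.permutation(n), f]
        X_it = np.hstack([X[:, in_play], shadows])

        forest = RandomForest(
            random_state=int(child_rng(seed, "boruta_forest", it).integers(2**31 - 1)),
            **params,
        )
        forest.fit(X_it, y)
        imp = forest.permutation_importance(child_rng(seed, "boruta_imp", it))
        real_imp, shadow_imp = imp[:k], imp[k:]
        max_shadow = float(shadow_imp.max())
        sd = float(np.std(shadow_imp, ddof=1)) if shadow_imp.size > 1 else 0.0
        if not np.isfinite(sd) or sd <= 0:
            sd = max(abs(max_shadow) * 1e-6, 1e-12)
        z = (real_imp - max_shadow) / sd

        still = []
        for j, f in enumerate(undecided):
            z_last.iloc[f] = z[j]
            if z[j] >= z_confirm:
                decision.iloc[f] = "Confirmed"
                confirmed.append(f)
            elif z[j] <= -z_reject:
                decision.iloc[f] = "Rejected"
            else:
                still.append(f)
        undecided = still
        if not undecided:
            break

    return BorutaRunResult(decision=decision, importance_z=z_last, iterations=iterations)


def bootstrap_indices(n: int, B: int, seed: int) -> list[np.ndarray]:
    """Shared bootstrap resample schedule: B index arrays of size n.

    Depends only on (n, B, seed), never on feature content, so feature
    selection and model training across all variants see identical resamples.
    """
    rng = child_rng(seed, "bootstrap_schedule")
    return [rng.integers(0, n, size=n) for _ in range(B)]


def stability_select(
    matrix: FeatureMatrix,
    B: int = 1000,
    threshold: float = 0.9,
    rf_params: Mapping | None = None,
    alpha: float = 0.01,
    max_iter: int = 100,
    seed: int = 0,
) -> StabilityReport:
    """Bootstrapped Boruta stability selection.

    Runs :func:`boruta_once` on ``B`` bootstrap resamples (with replacement,
    size n) and computes each feature's selection proportion pi_f; the
    retained set is ``{f : pi_f >= threshold}``.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    _validate_matrix(matrix)
    names = list(matrix.feature_names)
    n = len(matrix)
    schedule = bootstrap_indices(n, B, seed)
    confirmed = np.zeros(len(names))
    z_rows = np.full((B, len(names)), np.nan)
    for b, idx in enumerate(schedule):
        sub = matrix.subset_rows(idx)
        run = boruta_once(
            sub,
            rf_params=rf_params,
            alpha=alpha,
            max_iter=max_iter,
            seed=int(child_rng(seed, "resample", b).integers(2**31 - 1)),
        )
        confirmed += (run.decision.to_numpy() == "Confirmed").astype(float)
        z_rows[b] = run.importance_z.to_numpy()
    proportions = pd.Series(confirmed / B, index=names, name="selection_proportion")
    return StabilityReport(
        proportions=proportions,
        importance=pd.DataFrame(z_rows, columns=names),
        B=B,
        threshold=threshold,
        seed=seed,
    )


def importance_trajectory(report: StabilityReport) -> pd.DataFrame:
    """Per-feature stability summary table (selection proportion, importance).

    Features never confirmed in any resample are omitted; rows are sorted by
    selection proportion then median importance, descending.
    """
    rows = []
    for f in report.proportions.index:
        pi = float(report.proportions[f])
        if pi == 0.0:
            continue
        z = report.importance[f].dropna()
        rows.append(
            {
                "feature": f,
                "selection_proportion": pi,
                "median_importance": float(z.median()) if len(z) else np.nan,
                "q25_importance": float(z.quantile(0.25)) if len(z) else np.nan,
                "q75_importance": float(z.quantile(0.75)) if len(z) else np.nan,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "feature",
            "selection_proportion",
            "median_importance",
            "q25_importance",
            "q75_importance",
        ],
    )
    if len(table):
        table = table.sort_values(
            ["selection_proportion", "median_importance"], ascending=False
        ).reset_index(drop=True)
    return table
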