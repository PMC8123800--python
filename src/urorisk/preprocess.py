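"""Cohort validation, exclusion criteria, count normalisation and labelling.

Exclusion criteria mirror the development-cohort rules: a prostate biopsy or
trans-urethral resection within the previous 6 weeks, or metastatic disease
(positive bone scan or serum PSA > 100 ng/mL).

cf-RNA probe counts are normalised with the internal positive-control probes:
each sample's counts are multiplied by ``reference / sample geometric mean``
(geometric mean over that sample's positive controls; cohort reference = the
geometric mean of the per-sample geometric means), then log2-transformed with
a pseudocount.

The training label is continuous: 0 for no evidence of cancer (unbiopsied NEC
and biopsy-negative alike), 0.5 for Gleason 6 and 3+4, and 1 for Gleason
>= 4+3, reflecting that patients with the same biopsy Gleason score do not
share identical tumour burdens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import NormalisationError, SchemaError, ValidationError
from .synthetic import OUTCOMES, CohortRecord

__all__ = [
    "VARIANTS",
    "VariableSet",
    "LABEL_BY_OUTCOME",
    "FeatureMatrix",
    "NormalisationFactors",
    "apply_exclusions",
    "normalise_counts",
    "assign_training_label",
    "build_feature_matrix",
    "write_feature_matrix",
    "read_feature_matrix",
]

VARIANTS: tuple[str, ...] = ("SoC", "Engrailed", "ExoRNA", "ExoGrail")
VariableSet = Literal["SoC", "Engrailed", "ExoRNA", "ExoGrail"]

CLINICAL_FEATURES: tuple[str, ...] = ("age", "psa", "dre_size", "urine_volume")

#: Continuous training label by biopsy outcome.
LABEL_BY_OUTCOME: dict[str, float] = {
    "NEC": 0.0,
    "BiopsyNegative": 0.0,
    "Gs6": 0.5,
    "Gs3+4": 0.5,
    "Gs4+3": 1.0,
    "Gs8plus": 1.0,
}

#: DRE prostate-size estimate as explicit ordered codes; "Unknown" is its own
#: level rather than a missing value.
DRE_CODES: dict[str, int] = {"Unknown": 0, "Small": 1, "Medium": 2, "Large": 3}

RECENT_BIOPSY_WEEKS = 6.0
METASTATIC_PSA = 100.0


@dataclass
class NormalisationFactors:
    """Per-sample positive-control scaling used for cf-RNA normalisation."""

    sample_geomeans: pd.Series
    reference: float
    scale_factors: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.scale_factors = self.reference / self.sample_geomeans


@dataclass
class FeatureMatrix:
    """Samples x features predictor table plus the continuous training label.

    ``X`` holds the predictors for one variable set (cf-RNA columns on the
    normalised log2 scale); ``label`` is the continuous training label in
    {0, 0.5, 1}; ``outcome`` retains the categorical biopsy outcome for
    evaluation, which never uses the training label.
    """

    X: pd.DataFrame
    label: pd.Series
    outcome: pd.Series
    variable_set: str | None = None

    def __post_init__(self) -> None:
        if not (self.X.index.equals(self.label.index) and self.X.index.equals(self.outcome.index)):
            raise SchemaError("X, label and outcome must share the same sample index")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.X)

    def subset_rows(self, idx: Sequence[int]) -> "FeatureMatrix":
        """Positional row subset (rows may repeat, e.g. bootstrap resamples)."""
        idx = np.asarray(idx)
        return FeatureMatrix(
            X=self.X.iloc[idx],
            label=self.label.iloc[idx],
            outcome=self.outcome.iloc[idx],
            variable_set=self.variable_set,
        )

    def select_features(self, features: Sequence[str]) -> "FeatureMatrix":
        missing = [f for f in features if f not in self.X.columns]
        if missing:
            raise SchemaError(f"features absent from matrix: {missing}")
        return FeatureMatrix(
            X=self.X.loc[:, list(features)],
            label=self.label,
            outcome=self.outcome,
            variable_set=self.variable_set,
        )


def apply_exclusions(
    records: Sequence[CohortRecord],
) -> tuple[list[CohortRecord], list[dict]]:
    """Drop ineligible records; return retained records and an exclusion log.

    A record is excluded iff it had a prostate biopsy/TURP fewer than
    ``RECENT_BIOPSY_WEEKS`` weeks before sampling, a positive bone scan, or
    PSA > ``METASTATIC_PSA`` ng/mL.  The log holds one entry per excluded
    sample listing every applicable reason.
    """
    retained: list[CohortRecord] = []
    log: list[dict] = []
    for r in records:
        if r.psa is None or (isinstance(r.psa, float) and not np.isfinite(r.psa)):
            raise ValidationError(f"{r.sample_id}: missing PSA")
        reasons = []
        if r.recent_biopsy_weeks is not None and r.recent_biopsy_weeks < RECENT_BIOPSY_WEEKS:
            reasons.append("recent_biopsy")
        if r.metastatic:
            reasons.append("positive_bone_scan")
        if r.psa > METASTATIC_PSA:
            reasons.append("psa_gt_100")
        if reasons:
            log.append({"sample_id": r.sample_id, "reasons": reasons})
        else:
            retained.append(r)
    return retained, log


def _geomean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def normalise_counts(
    records: Sequence[CohortRecord],
    posctl_names: Sequence[str] | None = None,
    pseudocount: float = 1.0,
    reference: float | None = None,
) -> tuple[pd.DataFrame, NormalisationFactors]:
    """Positive-control normalised, log2-transformed cf-RNA probe matrix.

    Each probe count is multiplied by the sample's scale factor
    ``reference / geomean(positive controls)`` and then log2(x + pseudocount)
    transformed.  By default the reference is the geometric mean of the
    per-sample geometric means; pass ``reference`` explicitly to normalise
    against a fixed external baseline (under which a sample-wide rescaling of
    one sample's counts is exactly invariant).
    """
    if not records:
        return pd.DataFrame(), NormalisationFactors(pd.Series(dtype=float), 1.0)
    if posctl_names is None:
        posctl_names = sorted(records[0].pos_control_counts)
    geomeans = {}
    for r in records:
        ctl = np.array([r.pos_control_counts[c] for c in posctl_names], dtype=float)
        if np.any(ctl <= 0):
            raise NormalisationError(
                f"sample {r.sample_id}: non-positive positive-control count"
            )
        geomeans[r.sample_id] = _geomean(ctl)
    geo = pd.Series(geomeans, name="posctl_geomean")
    ref = _geomean(geo.to_numpy()) if reference is None else float(reference)
    factors = NormalisationFactors(sample_geomeans=geo, reference=ref)

    probe_names = sorted(records[0].probe_counts)
    counts = np.array(
        [[r.probe_counts[p] for p in probe_names] for r in records], dtype=float
    )
    scaled = counts * factors.scale_factors.to_numpy()[:, None]
    log2 = np.log2(scaled + pseudocount)
    matrix = pd.DataFrame(log2, index=[r.sample_id for r in records], columns=probe_names)
    return matrix, factors


def assign_training_label(outcome: str) -> float:
    """Continuous training label: 0 (no cancer), 0.5 (Gs6/3+4), 1 (>= 4+3)."""
    try:
        return LABEL_BY_OUTCOME[outcome]
    except KeyError:
        raise ValidationError(f"unknown outcome category {outcome!r}") from None


def build_feature_matrix(
    records: Sequence[CohortRecord],
    variable_set: VariableSet,
    pseudocount: float = 1.0,
) -> FeatureMatrix:
    """Assemble the predictor table for one model variant.

    SoC: clinical variables only; Engrailed: the EN2 ELISA value only;
    ExoRNA: the normalised cf-RNA probe panel only; ExoGrail: all of the
    above.  EN2 and PSA enter untransformed (tree models are invariant to
    monotone transforms); DRE size is encoded as ordered codes with
    "Unknown" an explicit level.
    """
    if variable_set not in VARIANTS:
        raise SchemaError(f"unknown variable set {variable_set!r}; expected one of {VARIANTS}")
    if not records:
        empty = pd.Index([], dtype=object)
        return FeatureMatrix(
            X=pd.DataFrame(index=empty),
            label=pd.Series(dtype=float, index=empty),
            outcome=pd.Series(dtype=object, index=empty),
            variable_set=variable_set,
        )
    for r in records:
        r.validate()
    ids = [r.sample_id for r in records]
    blocks: list[pd.DataFrame] = []
    if variable_set in ("SoC", "ExoGrail"):
        clin = pd.DataFrame(
            {
                "age": [r.age for r in records],
                "psa": [r.psa for r in records],
                "dre_size": [DRE_CODES[r.dre_size] for r in records],
                "urine_volume": [r.urine_volume for r in records],
            },
            index=ids,
        )
        blocks.append(clin)
    if variable_set in ("Engrailed", "ExoGrail"):
        blocks.append(pd.DataFrame({"en2": [r.en2 for r in records]}, index=ids))
    if variable_set in ("ExoRNA", "ExoGrail"):
        probes, _ = normalise_counts(records, pseudocount=pseudocount)
        blocks.append(probes)
    X = pd.concat(blocks, axis=1)
    if X.isna().to_numpy().any():
        raise ValidationError("missing values in assembled feature matrix")
    label = pd.Series([assign_training_label(r.outcome) for r in records], index=ids, name="label")
    outcome = pd.Series([r.outcome for r in records], index=ids, name="outcome")
    return FeatureMatrix(X=X, label=label, outcome=outcome, variable_set=variable_set)


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> Path:
    """Write X + label + outcome as CSV, full float precision."""
    path = Path(path)
    out = matrix.X.copy()
    out.insert(0, "label", matrix.label)
    out.insert(1, "outcome", matrix.outcome)
    out.index.name = "sample_id"
    out.to_csv(path, float_format="%.17g")
    return path


def read_feature_matrix(path: str | Path, variable_set: str | None = None) -> FeatureMatrix:
    frame = pd.read_csv(Path(path), index_col="sample_id")
    frame.index.name = None
    label = frame.pop("label").astype(float)
    outcome = frame.pop("outcome").astype(str)
    return FeatureMatrix(X=frame, label=label, outcome=outcome, variable_set=variable_set)
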