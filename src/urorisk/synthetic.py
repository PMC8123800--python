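"""Synthetic urine-biomarker cohort generator.

Emulates the statistical structure of the single-site development cohort used
for urinary prostate-cancer risk modelling: per-patient clinical variables
(age, serum PSA, DRE prostate-size category, urine volume), one EN2 ELISA
concentration, raw negative-binomial counts for a cf-RNA NanoString probe
panel plus positive-control probes, and a six-level biopsy outcome
(unbiopsied no-evidence-of-cancer through Gleason >= 8), with optional
metastatic records for exercising exclusion filters.

Markers are generated log-normally (strictly positive, right-skewed), with
per-class location parameters moment-matched to the published cohort-table
medians and IQRs.  Informative cf-RNA probes carry configurable per-class
log2 mean shifts so selection-recovery and discrimination tests have a known
ground truth.  A single integer seed fully determines the cohort.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .errors import ConfigurationError, ValidationError

__all__ = [
    "OUTCOMES",
    "CANCER_OUTCOMES",
    "CLASSES",
    "GeneratorConfig",
    "CohortRecord",
    "generate_cohort",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort",
    "read_cohort",
]

#: Biopsy-outcome categories in increasing Gleason order.  ``NEC`` are men with
#: PSA < 4 ng/mL who were never biopsied; ``BiopsyNegative`` were biopsied with
#: no cancer found.
OUTCOMES: tuple[str, ...] = ("NEC", "BiopsyNegative", "Gs6", "Gs3+4", "Gs4+3", "Gs8plus")
CANCER_OUTCOMES: tuple[str, ...] = ("Gs6", "Gs3+4", "Gs4+3", "Gs8plus")

#: Generator classes: the six retained outcome classes plus metastatic cases
#: (bone-scan positive and/or PSA > 100), which downstream exclusion filters
#: remove before modelling.
CLASSES: tuple[str, ...] = OUTCOMES + ("Metastatic",)

DRE_LEVELS: tuple[str, ...] = ("Small", "Medium", "Large", "Unknown")

# Development-cohort class counts (n = 207).
_DEFAULT_N_PER_CLASS = {
    "NEC": 25,
    "BiopsyNegative": 52,
    "Gs6": 30,
    "Gs3+4": 48,
    "Gs4+3": 24,
    "Gs8plus": 28,
    "Metastatic": 0,
}

# Age ~ Normal(mean, sd): non-cancer 65.2 +/- 8.1, cancer 69.7 +/- 7.7 years.
_DEFAULT_AGE = {
    "NEC": (65.2, 8.1),
    "BiopsyNegative": (65.2, 8.1),
    "Gs6": (68.5, 7.7),
    "Gs3+4": (69.5, 7.7),
    "Gs4+3": (70.5, 7.7),
    "Gs8plus": (71.0, 7.7),
    "Metastatic": (71.0, 8.0),
}

# PSA ng/mL, log-normal (natural-log location/scale).  NEC are unbiopsied men
# with PSA < 4; biopsied classes are truncated to [4, 100) (metastatic disease,
# PSA > 100, is its own class).  Locations chosen so the pooled non-cancer
# median is ~6 and the pooled cancer median ~10 with IQR ratio ~2.4.
_DEFAULT_PSA = {
    "NEC": (math.log(2.5), 0.35),
    "BiopsyNegative": (math.log(6.8), 0.45),
    "Gs6": (math.log(8.0), 0.55),
    "Gs3+4": (math.log(9.5), 0.60),
    "Gs4+3": (math.log(12.0), 0.60),
    "Gs8plus": (math.log(16.0), 0.65),
    "Metastatic": (math.log(150.0), 0.50),
}

# EN2 ELISA concentration (arbitrary ng/mL scale), log-normal with per-class
# log-locations expressed as a baseline plus monotone log2 shifts; the shift
# sizes target single-marker any-cancer discrimination around AUC ~ 0.8.
_EN2_BASE_LOC = math.log(15.0)
_EN2_SCALE = 0.70
_DEFAULT_EN2 = {
    "NEC": (_EN2_BASE_LOC, _EN2_SCALE),
    "BiopsyNegative": (_EN2_BASE_LOC + 0.40 * math.log(2), _EN2_SCALE),
    "Gs6": (_EN2_BASE_LOC + 1.20 * math.log(2), _EN2_SCALE),
    "Gs3+4": (_EN2_BASE_LOC + 1.80 * math.log(2), _EN2_SCALE),
    "Gs4+3": (_EN2_BASE_LOC + 2.20 * math.log(2), _EN2_SCALE),
    "Gs8plus": (_EN2_BASE_LOC + 2.50 * math.log(2), _EN2_SCALE),
    "Metastatic": (_EN2_BASE_LOC + 2.80 * math.log(2), _EN2_SCALE),
}


def _default_informative(n_informative: int = 11) -> dict[str, dict[str, float]]:
    """Ground-truth informative probes: monotone log2 shifts in cancer classes.

    The default panel size (11) mirrors the size of the cf-RNA signature
    retained by stability selection in the motivating analysis; shift sizes
    are moderate so that, combined with the negative-binomial and biological
    noise, per-probe discrimination is realistic rather than saturated.
    """
    shifts = {
        "NEC": 0.0,
        "BiopsyNegative": 0.10,
        "Gs6": 0.35,
        "Gs3+4": 0.60,
        "Gs4+3": 0.80,
        "Gs8plus": 0.95,
        "Metastatic": 1.20,
    }
    return {f"probe_{i + 1:03d}": dict(shifts) for i in range(n_informative)}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of a synthetic cohort.

    Parameters
    ----------
    n_per_class
        Record count per generator class (see :data:`CLASSES`).
    age_params, psa_params, en2_params
        Per-class ``(location, scale)``: age is Normal(mean, sd) in years; PSA
        and EN2 are log-normal with natural-log location/scale.
    n_probes
        Number of cf-RNA probes, named ``probe_001`` ...
    informative_probes
        Map probe name -> per-class log2 mean shift applied to that probe's
        expected count.  Probes not listed carry no class signal.  ``None``
        (the default) plants the standard monotone signal in the first
        ``min(11, n_probes)`` probes.
    count_dispersion
        Negative-binomial size parameter for probe counts (larger = tighter).
    bio_log2_sd
        Extra per-sample, per-probe biological variability (log2 sd) on the
        expected count, beyond negative-binomial sampling noise.
    tech_log_sd
        Per-sample technical scale factor (natural-log sd) multiplying *all*
        counts including positive controls; removed by normalisation.
    n_pos_controls, pos_control_levels
        Positive-control probes at fixed expected count levels.
    seed
        Root seed; fully determines the cohort.
    """

    n_per_class: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_N_PER_CLASS))
    age_params: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(_DEFAULT_AGE))
    psa_params: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(_DEFAULT_PSA))
    en2_params: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(_DEFAULT_EN2))
    n_probes: int = 167
    informative_probes: Mapping[str, Mapping[str, float]] | None = None
    count_dispersion: float = 10.0
    bio_log2_sd: float = 0.8
    tech_log_sd: float = 0.3
    n_pos_controls: int = 6
    pos_control_levels: Sequence[float] = (8000.0, 4000.0, 2000.0, 1000.0, 400.0, 150.0)
    dre_proportions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "no_cancer": {"Small": 0.17, "Medium": 0.44, "Large": 0.27, "Unknown": 0.12},
            "cancer": {"Small": 0.10, "Medium": 0.49, "Large": 0.29, "Unknown": 0.12},
        }
    )
    urine_volume_params: tuple[float, float] = (math.log(40.0), 0.45)
    seed: int = 0

    def probe_names(self) -> list[str]:
        return [f"probe_{i + 1:03d}" for i in range(self.n_probes)]

    def pos_control_names(self) -> list[str]:
        return [f"posctl_{i + 1}" for i in range(self.n_pos_controls)]

    def resolved_informative(self) -> dict[str, dict[str, float]]:
        """The ground-truth informative set, defaulting to the standard panel."""
        if self.informative_probes is None:
            return _default_informative(min(11, self.n_probes))
        return {k: dict(v) for k, v in self.informative_probes.items()}

    def validate(self) -> None:
        for cls, n in self.n_per_class.items():
            if cls not in CLASSES:
                raise ConfigurationError(f"unknown class {cls!r}")
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise ConfigurationError(f"negative or non-integer count for class {cls!r}: {n!r}")
        for name, params in (
            ("age_params", self.age_params),
            ("psa_params", self.psa_params),
            ("en2_params", self.en2_params),
        ):
            for cls, (loc, scale) in params.items():
                if not (np.isfinite(loc) and np.isfinite(scale)) or scale < 0:
                    raise ConfigurationError(f"non-finite {name} for class {cls!r}")
        if self.n_probes < 0 or self.n_pos_controls < 1:
            raise ConfigurationError("n_probes must be >= 0 and n_pos_controls >= 1")
        if len(self.pos_control_levels) < self.n_pos_controls:
            raise ConfigurationError("pos_control_levels shorter than n_pos_controls")
        known = set(self.probe_names())
        for probe in self.resolved_informative():
            if probe not in known:
                raise ConfigurationError(f"informative probe {probe!r} not in panel")
        if self.count_dispersion <= 0 or not np.isfinite(self.count_dispersion):
            raise ConfigurationError("count_dispersion must be positive and finite")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pos_control_levels"] = list(self.pos_control_levels)
        d["informative_probes"] = self.resolved_informative()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        for key in ("age_params", "psa_params", "en2_params"):
            if key in d:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        if "urine_volume_params" in d:
            d["urine_volume_params"] = tuple(d["urine_volume_params"])
        return cls(**d)


@dataclass
class CohortRecord:
    """One patient's clinical, EN2, cf-RNA and outcome data."""

    sample_id: str
    age: float
    psa: float
    dre_size: str
    urine_volume: float
    en2: float
    probe_counts: dict[str, int]
    pos_control_counts: dict[str, int]
    outcome: str
    metastatic: bool = False
    recent_biopsy_weeks: float | None = None

    def validate(self, probe_names: Sequence[str] | None = None) -> None:
        if self.psa is None or not np.isfinite(self.psa):
            raise ValidationError(f"{self.sample_id}: missing or non-finite PSA")
        if self.psa <= 0:
            raise ValidationError(f"{self.sample_id}: PSA must be positive")
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"{self.sample_id}: unknown outcome {self.outcome!r}")
        if self.dre_size not in DRE_LEVELS:
            raise ValidationError(f"{self.sample_id}: unknown DRE level {self.dre_size!r}")
        if probe_names is not None:
            missing = set(probe_names) - set(self.probe_counts)
            if missing:
                raise ValidationError(
                    f"{self.sample_id}: missing probe counts {sorted(missing)[:5]}"
                )


def _truncated_lognormal(
    rng: np.random.Generator,
    loc: float,
    scale: float,
    size: int,
    low: float | None = None,
    high: float | None = None,
) -> np.ndarray:
    """Log-normal draws rejected outside ``(low, high)``; deterministic per rng."""
    out = np.exp(rng.normal(loc, scale, size=size))
    for _ in range(1000):
        bad = np.zeros(size, dtype=bool)
        if low is not None:
            bad |= out < low
        if high is not None:
            bad |= out >= high
        if not bad.any():
            return out
        out[bad] = np.exp(rng.normal(loc, scale, size=int(bad.sum())))
    # Pathological parameterisation: clip the stragglers.
    if low is not None:
        out = np.maximum(out, low)
    if high is not None:
        out = np.minimum(out, np.nextafter(high, 0.0))
    return out


def generate_cohort(config: GeneratorConfig) -> list[CohortRecord]:
    """Generate a cohort; class counts match ``config.n_per_class`` exactly.

    The same seed regenerates a bit-identical cohort.  Metastatic records are
    given a positive bone-scan flag and PSA > 100 ng/mL and carry the
    ``Gs8plus`` outcome; they exist to exercise exclusion filters and
    positive-control model-calibration checks.
    """
    config.validate()
    probe_names = config.probe_names()
    posctl_names = config.pos_control_names()
    seed = config.seed

    # Per-probe baseline expression, fixed by the seed (log-uniform 50..2000).
    rng_base = child_rng(seed, "probe_baseline")
    baselines = np.exp(rng_base.uniform(math.log(50.0), math.log(2000.0), size=config.n_probes))

    # log2 shift matrix: classes x probes.
    shift = np.zeros((len(CLASSES), config.n_probes))
    probe_index = {p: j for j, p in enumerate(probe_names)}
    for probe, by_class in config.resolved_informative().items():
        j = probe_index[probe]
        for cls, s in by_class.items():
            shift[CLASSES.index(cls), j] = float(s)

    records: list[CohortRecord] = []
    counter = 0
    size = float(config.count_dispersion)
    levels = np.asarray(config.pos_control_levels[: config.n_pos_controls], dtype=float)
    for ci, cls in enumerate(CLASSES):
        n = int(config.n_per_class.get(cls, 0))
        if n == 0:
            continue
        rng = child_rng(seed, "class", cls)
        age = np.clip(rng.normal(*config.age_params[cls], size=n), 40.0, 95.0)
        if cls == "NEC":
            psa = _truncated_lognormal(rng, *config.psa_params[cls], n, high=4.0)
        elif cls == "Metastatic":
            psa = _truncated_lognormal(rng, *config.psa_params[cls], n, low=4.0)
        else:
            psa = _truncated_lognormal(rng, *config.psa_params[cls], n, low=4.0, high=100.0)
        en2 = np.exp(rng.normal(*config.en2_params[cls], size=n))
        volume = np.exp(rng.normal(*config.urine_volume_params, size=n))
        status = "no_cancer" if cls in ("NEC", "BiopsyNegative") else "cancer"
        props = config.dre_proportions[status]
        pvec = np.array([props.get(l, 0.0) for l in DRE_LEVELS], dtype=float)
        pvec = pvec / pvec.sum()
        dre = rng.choice(len(DRE_LEVELS), size=n, p=pvec)
        tech = np.exp(rng.normal(0.0, config.tech_log_sd, size=n))  # per-sample scale

        if config.n_probes:
            mean = (
                baselines[None, :]
                * np.exp2(shift[ci][None, :])
                * np.exp2(rng.normal(0.0, config.bio_log2_sd, size=(n, config.n_probes)))
                * tech[:, None]
            )
            counts = rng.negative_binomial(size, size / (size + mean))
        else:
            counts = np.zeros((n, 0), dtype=int)
        ctl_mean = levels[None, :] * tech[:, None]
        ctl_size = 200.0  # technical-replicate-level tightness for controls
        ctl = rng.negative_binomial(ctl_size, ctl_size / (ctl_size + ctl_mean))

        outcome = "Gs8plus" if cls == "Metastatic" else cls
        for i in range(n):
            counter += 1
            records.append(
                CohortRecord(
                    sample_id=f"S{counter:04d}",
                    age=float(age[i]),
                    psa=float(psa[i]),
                    dre_size=DRE_LEVELS[int(dre[i])],
                    urine_volume=float(volume[i]),
                    en2=float(en2[i]),
                    probe_counts={p: int(counts[i, j]) for j, p in enumerate(probe_names)},
                    pos_control_counts={p: int(ctl[i, j]) for j, p in enumerate(posctl_names)},
                    outcome=outcome,
                    metastatic=(cls == "Metastatic"),
                    recent_biopsy_weeks=None,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Serialisation


def cohort_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Cohort as a flat table, one row per sample, probe columns ``probe_*``."""
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "age": r.age,
            "psa": r.psa,
            "dre_size": r.dre_size,
            "urine_volume": r.urine_volume,
            "en2": r.en2,
            "outcome": r.outcome,
            "metastatic": r.metastatic,
            "recent_biopsy_weeks": (
                "" if r.recent_biopsy_weeks is None else r.recent_biopsy_weeks
            ),
        }
        row.update(r.probe_counts)
        row.update(r.pos_control_counts)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(frame: pd.DataFrame) -> list[CohortRecord]:
    probe_cols = [c for c in frame.columns if c.startswith("probe_")]
    ctl_cols = [c for c in frame.columns if c.startswith("posctl_")]
    records = []
    for _, row in frame.iterrows():
        rb = row.get("recent_biopsy_weeks", "")
        rb_val = None if rb == "" or pd.isna(rb) else float(rb)
        met = row["metastatic"]
        if isinstance(met, str):  # CSV readers may leave booleans as text
            met = met.strip().lower() == "true"
        records.append(
            CohortRecord(
                sample_id=str(row["sample_id"]),
                age=float(row["age"]),
                psa=float(row["psa"]),
                dre_size=str(row["dre_size"]),
                urine_volume=float(row["urine_volume"]),
                en2=float(row["en2"]),
                probe_counts={c: int(row[c]) for c in probe_cols},
                pos_control_counts={c: int(row[c]) for c in ctl_cols},
                outcome=str(row["outcome"]),
                metastatic=bool(met),
                recent_biopsy_weeks=rb_val,
            )
        )
    return records


def write_cohort(
    records: Sequence[CohortRecord],
    path: str | Path,
    config: GeneratorConfig | None = None,
) -> Path:
    """Write the cohort CSV plus a JSON sidecar with config and ground truth.

    The sidecar (``<path>.meta.json``) records the generator configuration and
    the ground-truth informative probe set, enabling recovery checks.
    """
    path = Path(path)
    cohort_to_frame(records).to_csv(path, index=False, float_format="%.10g")
    if config is not None:
        meta = {
            "config": config.to_dict(),
            "informative_probes": sorted(config.resolved_informative()),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1, sort_keys=True)
        )
    return path


def read_cohort(path: str | Path) -> list[CohortRecord]:
    frame = pd.read_csv(Path(path), keep_default_na=False, na_values=[])
    return frame_to_cohort(frame)
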