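import numpy as np
import pandas as pd
import pytest

from urorisk.preprocess import FeatureMatrix, build_feature_matrix
from urorisk.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Development-cohort-sized synthetic cohort (207 records, 167 probes)."""
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap cohort for wiring tests: 60 records, 12-probe panel."""
    cfg = GeneratorConfig(
        seed=5,
        n_per_class={
            "NEC": 8,
            "BiopsyNegative": 14,
            "Gs6": 10,
            "Gs3+4": 12,
            "Gs4+3": 8,
            "Gs8plus": 8,
            "Metastatic": 0,
        },
        n_probes=12,
        informative_probes={
            f"probe_{i + 1:03d}": {
                "BiopsyNegative": 0.2,
                "Gs6": 1.0,
                "Gs3+4": 1.5,
                "Gs4+3": 1.8,
                "Gs8plus": 2.0,
            }
            for i in range(4)
        },
    )
    return generate_cohort(cfg)


def toy_matrix(X: np.ndarray, y: np.ndarray, outcomes=None, names=None) -> FeatureMatrix:
    """Wrap plain arrays into a FeatureMatrix for selection/forest tests."""
    n, p = X.shape
    names = names or [f"f{j}" for j in range(p)]
    idx = pd.Index([f"S{i:04d}" for i in range(n)])
    outcomes = outcomes if outcomes is not None else ["Gs6"] * n
    return FeatureMatrix(
        X=pd.DataFrame(X, index=idx, columns=names),
        label=pd.Series(np.asarray(y, dtype=float), index=idx),
        outcome=pd.Series(list(outcomes), index=idx),
    )
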