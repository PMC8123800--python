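"""Exclusion rules, positive-control normalisation, labels, matrix assembly."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from urorisk.errors import NormalisationError, SchemaError, ValidationError
from urorisk.preprocess import (
    LABEL_BY_OUTCOME,
    apply_exclusions,
    assign_training_label,
    build_feature_matrix,
    normalise_counts,
    read_feature_matrix,
    write_feature_matrix,
)
from urorisk.synthetic import OUTCOMES, CohortRecord


def make_record(sample_id="S0001", psa=5.0, outcome="Gs6", metastatic=False,
                recent_biopsy_weeks=None, probe_counts=None, pos_control_counts=None,
                en2=10.0, dre="Medium"):
    return CohortRecord(
        sample_id=sample_id,
        age=65.0,
        psa=psa,
        dre_size=dre,
        urine_volume=40.0,
        en2=en2,
        probe_counts=probe_counts or {"probe_001": 100, "probe_002": 50},
        pos_control_counts=pos_control_counts or {"posctl_1": 100, "posctl_2": 400},
        outcome=outcome,
        metastatic=metastatic,
        recent_biopsy_weeks=recent_biopsy_weeks,
    )


class TestExclusions:
    def test_manual_rule_application(self):
        """2 with PSA>100, 1 bone-scan positive, 1 recent biopsy -> 6 of 10 kept."""
        records = [make_record(sample_id=f"S{i:04d}") for i in range(10)]
        records[0] = dataclasses.replace(records[0], psa=150.0)
        records[1] = dataclasses.replace(records[1], psa=101.0)
        records[2] = dataclasses.replace(records[2], metastatic=True)
        records[3] = dataclasses.replace(records[3], recent_biopsy_weeks=4.0)
        retained, log = apply_exclusions(records)
        assert len(retained) == 6
        assert {e["sample_id"] for e in log} == {"S0000", "S0001", "S0002", "S0003"}
        reasons = {e["sample_id"]: e["reasons"] for e in log}
        assert reasons["S0000"] == ["psa_gt_100"]
        assert reasons["S0002"] == ["positive_bone_scan"]
        assert reasons["S0003"] == ["recent_biopsy"]

    def test_boundary_values_retained(self):
        """Biopsy exactly 6 weeks ago and PSA exactly 100 are eligible."""
        records = [
            make_record(sample_id="A", recent_biopsy_weeks=6.0),
            make_record(sample_id="B", psa=100.0),
        ]
        retained, log = apply_exclusions(records)
        assert len(retained) == 2 and log == []

    def test_no_flags_identity(self):
        records = [make_record(sample_id=f"S{i}") for i in range(5)]
        retained, log = apply_exclusions(records)
        assert retained == records and log == []

    def test_missing_psa_raises(self):
        with pytest.raises(ValidationError):
            apply_exclusions([make_record(psa=float("nan"))])


class TestNormalisation:
    def test_geometric_mean_reference_hand_arithmetic(self):
        """Control geomeans 4 and 16 -> reference 8, scale factors 2 and 0.5."""
        r1 = make_record(sample_id="A", pos_control_counts={"posctl_1": 2, "posctl_2": 8})
        r2 = make_record(sample_id="B", pos_control_counts={"posctl_1": 8, "posctl_2": 32})
        _, factors = normalise_counts([r1, r2])
        assert factors.sample_geomeans["A"] == pytest.approx(4.0)
        assert factors.sample_geomeans["B"] == pytest.approx(16.0)
        assert factors.reference == pytest.approx(8.0)
        assert factors.scale_factors["A"] == pytest.approx(2.0)
        assert factors.scale_factors["B"] == pytest.approx(0.5)

    def test_sample_at_reference_unchanged(self):
        """A sample whose control geomean equals the reference keeps its counts."""
        r1 = make_record(sample_id="A", probe_counts={"probe_001": 37},
                         pos_control_counts={"posctl_1": 8})
        m, factors = normalise_counts([r1], reference=8.0)
        assert factors.scale_factors["A"] == pytest.approx(1.0)
        assert m.loc["A", "probe_001"] == pytest.approx(np.log2(38))

    def test_scale_invariance_against_fixed_reference(self):
        """Doubling every count of one sample leaves its normalised values."""
        base = make_record(sample_id="A", probe_counts={"probe_001": 100, "probe_002": 7},
                           pos_control_counts={"posctl_1": 50, "posctl_2": 200})
        doubled = dataclasses.replace(
            base,
            probe_counts={k: 2 * v for k, v in base.probe_counts.items()},
            pos_control_counts={k: 2 * v for k, v in base.pos_control_counts.items()},
        )
        m1, _ = normalise_counts([base], reference=100.0)
        m2, _ = normalise_counts([doubled], reference=100.0)
        np.testing.assert_allclose(m1.to_numpy(), m2.to_numpy())

    def test_idempotent_when_factors_unity(self):
        """Equal control geomeans across samples give factors 1: plain log2."""
        recs = [
            make_record(sample_id=s, probe_counts={"probe_001": c},
                        pos_control_counts={"posctl_1": 64})
            for s, c in [("A", 10), ("B", 1000)]
        ]
        m, factors = normalise_counts(recs)
        assert np.allclose(factors.scale_factors.to_numpy(), 1.0)
        np.testing.assert_allclose(m["probe_001"].to_numpy(), np.log2(np.array([11, 1001])))

    def test_zero_control_names_sample(self):
        bad = make_record(sample_id="BAD", pos_control_counts={"posctl_1": 0})
        with pytest.raises(NormalisationError, match="BAD"):
            normalise_counts([bad])


class TestLabel:
    @pytest.mark.parametrize(
        "outcome,expected",
        [
            ("NEC", 0.0),
            ("BiopsyNegative", 0.0),
            ("Gs6", 0.5),
            ("Gs3+4", 0.5),
            ("Gs4+3", 1.0),
            ("Gs8plus", 1.0),
        ],
    )
    def test_mapping(self, outcome, expected):
        assert assign_training_label(outcome) == expected

    def test_unknown_category_raises(self):
        with pytest.raises(ValidationError):
            assign_training_label("Gs9")

    def test_label_monotone_in_gleason_order(self):
        labels = [LABEL_BY_OUTCOME[o] for o in OUTCOMES]
        assert labels == sorted(labels)


class TestFeatureMatrix:
    def test_full_matrix_dimensions(self, default_cohort):
        m = build_feature_matrix(default_cohort, "ExoGrail")
        assert m.X.shape == (207, 172)
        assert set(m.label.unique()) == {0.0, 0.5, 1.0}

    def test_variable_subsets(self, small_cohort):
        assert build_feature_matrix(small_cohort, "Engrailed").feature_names == ["en2"]
        soc = build_feature_matrix(small_cohort, "SoC")
        assert soc.feature_names == ["age", "psa", "dre_size", "urine_volume"]
        exorna = build_feature_matrix(small_cohort, "ExoRNA")
        assert all(f.startswith("probe_") for f in exorna.feature_names)

    def test_empty_cohort_gives_empty_matrix(self):
        m = build_feature_matrix([], "ExoGrail")
        assert len(m) == 0

    def test_unknown_variable_set_raises(self, small_cohort):
        with pytest.raises(SchemaError):
            build_feature_matrix(small_cohort, "PSAOnly")

    def test_dre_encoded_with_unknown_level(self, small_cohort):
        m = build_feature_matrix(small_cohort, "SoC")
        assert set(m.X["dre_size"].unique()) <= {0, 1, 2, 3}

    def test_round_trip_full_precision(self, tmp_path, small_cohort):
        m = build_feature_matrix(small_cohort, "ExoGrail")
        path = write_feature_matrix(m, tmp_path / "m.csv")
        back = read_feature_matrix(path)
        pd.testing.assert_frame_equal(back.X, m.X)
        pd.testing.assert_series_equal(back.label, m.label, check_names=False)
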