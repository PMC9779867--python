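"""Synthetic cohort generator: determinism, design structure, calibration."""

import numpy as np
import pandas as pd
import pytest

from glycodiet import (
    SimulationConfig,
    assign_plates,
    normalize_total_area,
    simulate_cohort,
)
from glycodiet.exceptions import ConfigurationError, ValidationError


def _tiny(**kw):
    base = dict(
        n_centers=2,
        subjects_per_center=12,
        n_plates=2,
        samples_per_plate=40,
        seed=5,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        a_raw, a_ann, _ = simulate_cohort(_tiny())
        b_raw, b_ann, _ = simulate_cohort(_tiny())
        pd.testing.assert_frame_equal(a_raw.data, b_raw.data)
        pd.testing.assert_frame_equal(a_ann, b_ann)

    def test_different_seed_differs(self):
        a_raw, _, _ = simulate_cohort(_tiny())
        b_raw, _, _ = simulate_cohort(_tiny(seed=6))
        assert not np.allclose(a_raw.values, b_raw.values)


class TestDegenerateNoNoise:
    def test_subject_rows_identical_across_time(self):
        cfg = _tiny(
            subject_intercept_sd=0.0,
            residual_sd=0.0,
            batch_effect_sd_location=0.0,
            batch_effect_sd_scale=0.0,
            age_loading_sd=0.0,
            sex_loading_sd=0.0,
            bmi_loading_sd=0.0,
        )
        raw, ann, _ = simulate_cohort(cfg)
        percent = normalize_total_area(raw)
        study = ann[ann["role"] == "study"]
        for _, grp in study.groupby("subject_id"):
            rows = percent.data.loc[grp["sample_id"]].to_numpy()
            assert np.allclose(rows, rows[0], atol=1e-9)


class TestStudyDesign:
    def test_time_points_and_dropout(self):
        cfg = _tiny(subjects_per_center=20, samples_per_plate=70,
                    dropout_fraction_after_T2=0.25)
        _, ann, truth = simulate_cohort(cfg)
        study = ann[ann["role"] == "study"]
        per_tp = study["time_point"].value_counts()
        assert per_tp["T1"] == per_tp["T2"] == 40
        assert per_tp["T3"] == 40 - 2 * round(0.25 * 20)
        dropped = truth.subjects[truth.subjects["dropout_after_T2"]]
        assert set(dropped["subject_id"]) & set(
            study.loc[study["time_point"] == "T3", "subject_id"]
        ) == set()

    def test_arms_only_after_randomization(self):
        _, ann, truth = simulate_cohort(_tiny())
        study = ann[ann["role"] == "study"]
        assert (study.loc[study["time_point"] == "T1", "diet_arm"] == "none").all()
        completers = truth.subjects[~truth.subjects["dropout_after_T2"]]
        assert set(completers["diet_arm"]) <= {
            "LP/LGI", "LP/HGI", "HP/LGI", "HP/HGI", "control"
        }

    def test_replicates_share_source_latent_distribution(self):
        raw, ann, truth = simulate_cohort(_tiny())
        assert truth.replicate_sources  # non-empty mapping
        for rep, src in truth.replicate_sources.items():
            assert src in set(ann["sample_id"])


class TestAssignPlates:
    def _annotation(self, n):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "subject_id": [f"p{i // 2}" for i in range(n)],
                "center": ["Maastricht"] * n,
                "time_point": ["T1", "T2"] * (n // 2),
                "plate": [np.nan] * n,
                "age": 40.0,
                "sex": 0,
                "bmi": 33.0,
                "diet_arm": "none",
                "role": "study",
            }
        )

    def test_capacity_and_balance(self):
        cfg = SimulationConfig(n_plates=2, samples_per_plate=70)
        out = assign_plates(self._annotation(138), cfg, seed=3)
        study = out[out["role"] == "study"]
        sizes = study.groupby("plate").size()
        assert (sizes <= 70).all() and sizes.sum() == 138

    def test_qc_counts_per_plate(self):
        cfg = SimulationConfig(n_plates=2, samples_per_plate=70)
        out = assign_plates(self._annotation(138), cfg, seed=3)
        reps = out[out["role"] == "replicate"].groupby("plate").size()
        stds = out[out["role"] == "standard"].groupby("plate").size()
        assert (reps == 10).all()  # 5 within + 5 cross
        assert (stds == 4).all()

    def test_reproducible_by_seed(self):
        cfg = SimulationConfig(n_plates=3, samples_per_plate=50)
        a = assign_plates(self._annotation(120), cfg, seed=9)
        b = assign_plates(self._annotation(120), cfg, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_overflow_rejected(self):
        cfg = SimulationConfig(n_plates=1, samples_per_plate=50)
        with pytest.raises(ValidationError, match="capacity"):
            assign_plates(self._annotation(60), cfg, seed=0)


class TestEffectCalibration:
    def test_single_effect_realized_matches_nominal(self, small_cohort):
        _, _, truth = small_cohort
        # AF and LB actively injected at T1T2; calibration solves them jointly
        assert truth.realized_effects.loc["AF", "T1T2"] == pytest.approx(0.35, abs=0.01)
        assert truth.realized_effects.loc["LB", "T1T2"] == pytest.approx(0.30, abs=0.01)
        assert truth.realized_effects.loc["G3", "T2T3"] == pytest.approx(-0.25, abs=0.01)

    def test_compositional_coupling_recorded_for_passive_traits(self, small_cohort):
        _, _, truth = small_cohort
        # pushing LB up must pull the complementary high-branching family down
        assert truth.realized_effects.loc["HB", "T1T2"] < -0.1

    def test_effect_into_noise_free_cohort_rejected(self):
        cfg = _tiny(
            subject_intercept_sd=0.0,
            residual_sd=0.0,
            age_loading_sd=0.0,
            sex_loading_sd=0.0,
            bmi_loading_sd=0.0,
            trait_time_effects={("AF", "T1T2"): 0.3},
            calibration_draws=2000,
        )
        with pytest.raises(ConfigurationError, match="zero-variance"):
            simulate_cohort(cfg)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw, match",
        [
            (dict(n_centers=9), "n_centers"),
            (dict(residual_sd=-0.1), "residual_sd"),
            (dict(trait_time_effects={("XX", "T1T2"): 0.1}), "unknown trait"),
            (dict(trait_time_effects={("AF", "T9"): 0.1}), "unknown period"),
            (dict(dropout_fraction_after_T2=1.0), "dropout"),
        ],
    )
    def test_invalid_config_rejected(self, kw, match):
        with pytest.raises(ConfigurationError, match=match):
            SimulationConfig(**kw).validate()
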