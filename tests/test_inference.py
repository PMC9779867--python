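"""Mixed-model time effects, ML meta-analysis, BH adjustment, diet contrast."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycodiet import (
    CenterPeriodEffect,
    bh_adjust,
    count_significant,
    fit_center_lmm,
    load_published_results,
    meta_analyze,
)
from glycodiet.exceptions import ValidationError
from glycodiet.inference import ml_tau2, _profile_loglik


def _paired_design(n, rng, sigma_u=1.0, sigma_e=0.5, beta=0.3, covariates=False):
    """Complete-pairs one-center design; returns (values, annotation)."""
    subs = [f"p{i}" for i in range(n)]
    rows = []
    y = {}
    u = rng.normal(0, sigma_u, n)
    for i, s in enumerate(subs):
        age = rng.uniform(25, 60) if covariates else 40.0
        sex = int(rng.random() < 0.5) if covariates else 1
        bmi = rng.uniform(28, 42) if covariates else 33.0
        for t, tp in enumerate(("T1", "T2")):
            sid = f"{s}_{tp}"
            rows.append(
                {
                    "sample_id": sid, "subject_id": s, "center": "Prague",
                    "time_point": tp, "plate": 1, "age": age, "sex": sex,
                    "bmi": bmi, "diet_arm": "none", "role": "study",
                }
            )
            y[sid] = (
                u[i] + beta * t + rng.normal(0, sigma_e)
                + (0.01 * age + 0.2 * sex + 0.02 * bmi if covariates else 0.0)
            )
    annot = pd.DataFrame(rows)
    return pd.Series(y), annot


class TestCenterLmm:
    def test_equals_paired_difference_estimator(self, rng):
        values, annot = _paired_design(40, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eff = fit_center_lmm(values, annot, "T1T2", "AF", "Prague")
        diffs = [
            values[f"p{i}_T2"] - values[f"p{i}_T1"] for i in range(40)
        ]
        assert eff.converged
        assert eff.effect == pytest.approx(np.mean(diffs), abs=1e-8)
        assert eff.n_subjects == 40

    def test_matches_ols_when_no_subject_variance(self, rng):
        values, annot = _paired_design(60, rng, sigma_u=0.0, sigma_e=1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eff = fit_center_lmm(values, annot, "T1T2", "AF", "Prague")
        # balanced design: the GLS time coefficient coincides with OLS
        t = np.array([sid.endswith("T2") for sid in values.index], float)
        X = np.column_stack([np.ones(len(t)), t])
        ols = np.linalg.lstsq(X, values.to_numpy(), rcond=None)[0][1]
        assert eff.effect == pytest.approx(ols, abs=1e-6)

    def test_recovers_known_effect_with_covariates(self, rng):
        values, annot = _paired_design(200, rng, beta=0.3, covariates=True)
        eff = fit_center_lmm(values, annot, "T1T2", "AF", "Prague")
        assert abs(eff.effect - 0.3) < 3 * eff.se

    def test_missing_covariates_drop_samples(self, rng):
        values, annot = _paired_design(20, rng, covariates=True)
        annot.loc[annot["subject_id"] == "p0", "bmi"] = np.nan
        eff = fit_center_lmm(values, annot, "T1T2", "AF", "Prague")
        assert eff.converged and eff.n_subjects == 19

    def test_too_few_subjects_not_converged(self, rng):
        values, annot = _paired_design(1, rng)
        eff = fit_center_lmm(values, annot, "T1T2", "AF", "Prague")
        assert not eff.converged


def _effects(pairs, trait="AF", period="T1T2"):
    return [
        CenterPeriodEffect(trait, f"c{i}", period, th, se, 100)
        for i, (th, se) in enumerate(pairs)
    ]


class TestMetaAnalyze:
    def test_homogeneous_limit(self):
        row = meta_analyze(_effects([(0.2, 0.05)] * 4))
        assert row.effect == pytest.approx(0.2, abs=1e-10)
        assert row.tau2 == pytest.approx(0.0, abs=1e-10)
        assert row.se == pytest.approx(0.05 / 2.0, rel=1e-9)

    def test_single_center_passthrough_warns(self):
        with pytest.warns(UserWarning, match="single center"):
            row = meta_analyze(_effects([(0.2, 0.1)]))
        assert (row.effect, row.se, row.tau2) == (0.2, 0.1, 0.0)

    def test_matches_grid_search_oracle(self):
        theta = np.array([0.10, 0.30, 0.50])
        se = np.array([0.05, 0.05, 0.05])
        row = meta_analyze(_effects(list(zip(theta, se))))
        grid = np.arange(0.0, 1.0, 1e-6)
        ll = np.array([_profile_loglik(t, theta, se**2) for t in
                       np.round(grid[:: 1000], 9)])  # coarse pass
        coarse = grid[:: 1000][int(np.argmax(ll))]
        fine = np.arange(max(coarse - 2e-3, 0.0), coarse + 2e-3, 1e-6)
        llf = np.array([_profile_loglik(t, theta, se**2) for t in fine])
        tau2_grid = float(fine[int(np.argmax(llf))])
        w = 1.0 / (se**2 + tau2_grid)
        mu_grid = float((w * theta).sum() / w.sum())
        assert row.tau2 == pytest.approx(tau2_grid, abs=1e-5)
        assert row.effect == pytest.approx(mu_grid, abs=1e-5)

    def test_pooled_within_input_range(self, rng):
        for _ in range(25):
            k = rng.integers(2, 8)
            theta = rng.normal(0, 0.5, k)
            se = rng.uniform(0.02, 0.3, k)
            row = meta_analyze(_effects(list(zip(theta, se))))
            assert theta.min() - 1e-12 <= row.effect <= theta.max() + 1e-12

    def test_tau2_zero_when_homogeneity_plausible(self, rng):
        # observed spread below average within-center variance → ML at 0
        theta = np.array([0.10, 0.11, 0.09, 0.10])
        se = np.array([0.2, 0.2, 0.2, 0.2])
        assert ml_tau2(theta, se) == 0.0


def _bh_oracle(p):
    """Plain step-up: sort, candidate p*(m/i), suffix cumulative minimum."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    cand = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(cand[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBhAdjust:
    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(0.0, 1.0, allow_nan=False, allow_subnormal=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_matches_step_up_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), rtol=1e-12)

    def test_invariant_to_input_order(self, rng):
        p = rng.uniform(size=32)
        perm = rng.permutation(32)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03] * 7), [0.03] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 1.2])

    def test_published_joint_pool_counts(self):
        table = load_published_results()
        adj = bh_adjust(table["p_value"].to_numpy())
        frame = table.assign(p_adjusted=adj)
        assert count_significant(frame, "T1T2", 0.05) == 11
        assert count_significant(frame, "T2T3", 0.05) == 7
        assert count_significant(frame, "T1T2", 0.0) == 0


class TestDietContrast:
    def test_contrast_table_structure(self, pipeline_result):
        diet = pipeline_result.diet_contrasts
        assert diet is not None
        assert {"trait_code", "arm", "effect", "se", "p_value", "p_adjusted"} <= set(
            diet.columns
        )
        assert diet["p_value"].between(0, 1).all()
        assert (diet["p_adjusted"] >= diet["p_value"] - 1e-12).all()
        assert set(diet["arm"]) <= {"LP/LGI", "LP/HGI", "HP/LGI", "HP/HGI"}

    def test_null_arms_rarely_significant(self, pipeline_result):
        # generator injected no arm effects; adjusted significance should be rare
        diet = pipeline_result.diet_contrasts
        assert (diet["p_adjusted"] < 0.05).mean() <= 0.05
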