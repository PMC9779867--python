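"""Normalization, log transform and empirical-Bayes batch correction."""

import numpy as np
import pandas as pd
import pytest

from glycodiet import (
    GP_COLUMNS,
    GlycanPeakMatrix,
    backtransform_and_renormalize,
    combat_correct,
    log_transform,
    normalize_total_area,
)
from glycodiet.exceptions import FitError, ValidationError
from tests.conftest import random_percent_matrix


def _raw(values, ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = ids or [f"s{i}" for i in range(len(values))]
    frame = pd.DataFrame(values, index=ids, columns=list(GP_COLUMNS))
    return GlycanPeakMatrix(frame, "raw")


class TestNormalize:
    def test_equal_areas_give_uniform_percent(self):
        out = normalize_total_area(_raw(np.full((1, 39), 7.3)))
        np.testing.assert_allclose(out.values, 100.0 / 39.0)

    def test_matches_direct_arithmetic(self, rng):
        vals = rng.uniform(0.5, 80.0, size=(5, 39))
        out = normalize_total_area(_raw(vals))
        expected = 100.0 * vals / vals.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_idempotent(self, rng):
        vals = rng.uniform(0.5, 80.0, size=(3, 39))
        once = normalize_total_area(_raw(vals))
        twice = normalize_total_area(once)
        np.testing.assert_allclose(once.values, twice.values, rtol=1e-12)

    def test_zero_row_identified(self):
        vals = np.vstack([np.full(39, 2.0), np.zeros(39)])
        with pytest.raises(ValidationError, match="s1"):
            normalize_total_area(_raw(vals))


class TestLogTransform:
    def test_closed_form_value(self):
        out = log_transform(normalize_total_area(_raw(np.full((1, 39), 1.0))))
        np.testing.assert_allclose(out.values, np.log(100.0 / 39.0))
        assert out.values[0, 0] == pytest.approx(0.94160854, abs=1e-7)

    def test_exp_inverts(self, rng):
        percent = random_percent_matrix(rng, 4)
        logged = log_transform(percent)
        np.testing.assert_allclose(np.exp(logged.values), percent.values, rtol=1e-12)

    def test_halfmin_imputation(self):
        vals = np.vstack([np.full(39, 1.0), np.full(39, 1.0)])
        vals[0, 4] = 0.0
        percent = normalize_total_area(_raw(vals))
        logged = log_transform(percent, zero_policy="halfmin")
        positive_min = percent.values[1, 4]
        assert logged.values[0, 4] == pytest.approx(np.log(0.5 * positive_min))

    def test_zero_policy_error(self):
        vals = np.full((2, 39), 1.0)
        vals[0, 4] = 0.0
        percent = normalize_total_area(_raw(vals))
        with pytest.raises(ValidationError, match="GP5"):
            log_transform(percent, zero_policy="error")


class TestBacktransform:
    def test_zero_correction_roundtrip(self, rng):
        percent = random_percent_matrix(rng, 6)
        back = backtransform_and_renormalize(log_transform(percent))
        np.testing.assert_allclose(back.values, percent.values, rtol=1e-9)

    def test_rows_close_to_100(self, rng):
        logged = log_transform(random_percent_matrix(rng, 6))
        shifted = logged.copy_with(logged.values + rng.normal(0, 0.3, (6, 39)),
                                   "log_percent")
        out = backtransform_and_renormalize(shifted)
        np.testing.assert_allclose(out.values.sum(axis=1), 100.0, rtol=1e-9)

    def test_within_sample_order_preserved(self, rng):
        logged = log_transform(random_percent_matrix(rng, 3))
        out = backtransform_and_renormalize(logged)
        for row_log, row_out in zip(logged.values, out.values):
            assert np.array_equal(np.argsort(row_log), np.argsort(row_out))


def _plated_logdata(rng, n_per_plate, gamma=0.0, n_plates=2, scale=1.0):
    """Log-scale matrix with plate labels; plate 2 shifted by gamma."""
    rows = []
    plates = []
    base = np.log(np.full(39, 100.0 / 39.0))
    for p in range(n_plates):
        block = base + rng.normal(0.0, 0.2 * scale, size=(n_per_plate, 39))
        if p == 1:
            block = block + gamma
        rows.append(block)
        plates += [f"P{p + 1}"] * n_per_plate
    vals = np.vstack(rows)
    ids = [f"s{i}" for i in range(len(vals))]
    frame = pd.DataFrame(vals, index=ids, columns=list(GP_COLUMNS))
    return GlycanPeakMatrix(frame, "log_percent"), np.array(plates)


class TestCombat:
    def test_single_plate_identity(self, rng):
        data, _ = _plated_logdata(rng, 10, n_plates=1)
        out, model = combat_correct(data, ["P1"] * 10)
        np.testing.assert_array_equal(out.values, data.values)
        assert (model.gamma_star.to_numpy() == 0).all()
        assert (model.delta2_star.to_numpy() == 1).all()

    def test_singleton_plate_rejected(self, rng):
        data, plates = _plated_logdata(rng, 5)
        plates = plates.copy()
        plates[-1] = "P3"
        with pytest.raises(FitError, match="P3"):
            combat_correct(data, plates)

    def test_injected_location_effect_removed(self, rng):
        # n and the within-plate sd chosen so the sampling-noise floor of
        # the observed between-plate mean (~sd·sqrt(2/n) per peak) sits
        # well below the 5% bound
        gamma = 0.4
        data, plates = _plated_logdata(rng, 1500, gamma=gamma, scale=0.5)
        corrected, _ = combat_correct(data, plates)
        diff = (
            corrected.values[plates == "P2"].mean(axis=0)
            - corrected.values[plates == "P1"].mean(axis=0)
        )
        assert np.abs(diff).max() < 0.05 * gamma

    def test_matches_direct_standardization_large_n(self, rng):
        # oracle: per-plate mean/variance standardization, the limit the EB
        # estimates approach as per-plate n grows
        data, plates = _plated_logdata(rng, 3000, gamma=0.3)
        corrected, _ = combat_correct(data, plates)
        X = data.values
        oracle = X.copy()
        grand_mean = X.mean(axis=0)
        pooled_sd = np.sqrt(
            np.mean(
                [
                    ((X[plates == p] - X[plates == p].mean(0)) ** 2).mean(0)
                    for p in ("P1", "P2")
                ],
                axis=0,
            )
        )
        for p in ("P1", "P2"):
            blk = X[plates == p]
            oracle[plates == p] = (
                (blk - blk.mean(0)) / blk.std(0, ddof=1) * pooled_sd + grand_mean
            )
        assert np.abs(corrected.values - oracle).max() < 0.02

    def test_no_batch_data_nearly_unchanged(self, rng):
        data, plates = _plated_logdata(rng, 400, gamma=0.0)
        corrected, _ = combat_correct(data, plates)
        assert np.abs(corrected.values - data.values).max() < 0.05

    def test_grand_moments_preserved(self, rng):
        data, plates = _plated_logdata(rng, 200, gamma=0.2)
        corrected, model = combat_correct(data, plates)
        np.testing.assert_allclose(
            corrected.values.mean(axis=0), model.alpha.to_numpy(), atol=5e-3
        )

    def test_shrunk_location_between_naive_and_prior(self, rng):
        data, plates = _plated_logdata(rng, 30, gamma=0.15)
        _, model = combat_correct(data, plates)
        for plate in model.batches:
            naive = model.gamma_hat.loc[plate].to_numpy()
            shrunk = model.gamma_star.loc[plate].to_numpy()
            prior = model.prior_gamma_bar[plate]
            lo = np.minimum(naive, prior) - 1e-9
            hi = np.maximum(naive, prior) + 1e-9
            # location-scale iteration couples the bounds through delta2;
            # shrunk estimates stay in the naive↔prior interval
            assert ((shrunk >= lo) & (shrunk <= hi)).mean() > 0.95

    def test_mean_only_leaves_scale(self, rng):
        data, plates = _plated_logdata(rng, 50, gamma=0.2)
        _, model = combat_correct(data, plates, mean_only=True)
        assert (model.delta2_star.to_numpy() == 1.0).all()
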