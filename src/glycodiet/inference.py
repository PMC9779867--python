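"""Longitudinal mixed models, cross-center meta-analysis and FDR control.

For every (trait, center, period) a random-intercept model

    y = b0 + b_time · time + b_age · age + b_sex · sex + b_bmi · bmi
        + u_subject + eps,   u ~ N(0, s_u²), eps ~ N(0, s²)

is fitted by REML on the rank-normalized trait, with time coded 0/1 within
the period (later time point = 1), so b_time is the standardized change
over that period. Center effects are pooled with a random-effects
meta-analysis whose between-center variance tau² is estimated by maximum
likelihood, and the 32 pooled p-values (16 traits × 2 periods) are adjusted
jointly with the Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from sklearn.base import BaseEstimator
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .datatypes import PERIODS, MetaResultRow, rows_to_frame
from .exceptions import FitError, ValidationError

logger = logging.getLogger(__name__)

_PERIOD_TIMES = {"T1T2": ("T1", "T2"), "T2T3": ("T2", "T3")}
_COVARIATES = ("age", "sex", "bmi")
ARM_LEVELS = ("LP/LGI", "LP/HGI", "HP/LGI", "HP/HGI")  # control = reference


@dataclass
class CenterPeriodEffect:
    """Time coefficient of one center's mixed model for one trait/period."""

    trait_code: str
    center: str
    period: str
    effect: float
    se: float
    n_subjects: int
    converged: bool = True

    def validate(self) -> None:
        if self.period not in PERIODS:
            raise ValidationError(f"unknown period {self.period!r}")
        if self.converged and not (np.isfinite(self.effect) and self.se > 0):
            raise ValidationError(
                f"{self.trait_code}/{self.center}/{self.period}: "
                "converged fit must have finite effect and positive SE"
            )


def _design_matrix(
    design: pd.DataFrame, period: str, extra_cols: Sequence[str] = ()
) -> pd.DataFrame | None:
    """Subset study samples of the period, drop rows with missing
    covariates, and attach the 0/1 time code. None if nothing remains."""
    early, late = _PERIOD_TIMES[period]
    sub = design[
        (design["role"] == "study") & design["time_point"].isin((early, late))
    ].copy()
    complete = sub[list(_COVARIATES)].notna().all(axis=1)
    if (~complete).any():
        logger.info(
            "dropping %d samples with missing covariates", int((~complete).sum())
        )
        sub = sub[complete]
    if len(sub) == 0:
        return None
    sub["time"] = (sub["time_point"] == late).astype(float)
    return sub


def _fit_mixedlm(y: np.ndarray, X: np.ndarray, groups: np.ndarray, reml: bool):
    """MixedLM fit with an optimizer fallback; None when the fit fails.

    lbfgs is fast but can hit a singular matrix when the group variance
    lands on the zero boundary; the default optimizer chain handles that.
    """
    for method in ("lbfgs", None):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                model = MixedLM(y, X, groups=groups)
                fit = (
                    model.fit(reml=reml, method=method)
                    if method
                    else model.fit(reml=reml)
                )
            if np.isfinite(fit.params).all() and np.isfinite(fit.bse[1]):
                return fit
        except (np.linalg.LinAlgError, ValueError):
            continue
    return None


def fit_center_lmm(
    trait_values: pd.Series,
    design: pd.DataFrame,
    period: str,
    trait_code: str = "",
    center: str = "",
    reml: bool = True,
) -> CenterPeriodEffect:
    """Random-intercept time-effect fit for one center and period.

    Parameters
    ----------
    trait_values
        Rank-normalized trait, indexed by sample id.
    design
        Annotation rows for this center (any time points; the period's two
        are selected here). Samples missing age/sex/BMI are dropped.
    period
        ``"T1T2"`` or ``"T2T3"``.
    reml
        Restricted (default) vs full maximum likelihood.

    Constant covariates are dropped with a warning; a fit that fails to
    converge is returned with ``converged=False`` and excluded from
    meta-analysis by the caller.
    """
    if period not in _PERIOD_TIMES:
        raise ValidationError(f"unknown period {period!r}")
    sub = _design_matrix(design, period)
    failed = CenterPeriodEffect(
        trait_code, center, period, np.nan, np.nan, 0, converged=False
    )
    if sub is None:
        return failed
    y = trait_values.reindex(sub["sample_id"]).to_numpy(dtype=float)
    keep = np.isfinite(y)
    sub, y = sub[keep], y[keep]
    n_subjects = sub["subject_id"].nunique()
    if n_subjects < 2 or len(sub) <= 2:
        return failed

    cols = ["time"]
    for cov in _COVARIATES:
        if sub[cov].nunique() > 1:
            cols.append(cov)
        else:
            warnings.warn(
                f"{trait_code}/{center}/{period}: covariate {cov!r} is "
                "constant; dropped from the model",
                stacklevel=2,
            )
    X = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy(float) for c in cols])
    if sub["time"].nunique() < 2:
        return failed
    fit = _fit_mixedlm(y, X, sub["subject_id"].to_numpy(), reml)
    if fit is None:
        return failed
    effect = float(fit.params[1])
    se = float(fit.bse[1])
    converged = bool(np.isfinite(effect) and np.isfinite(se) and se > 0)
    if not converged:
        logger.warning("non-converged fit: %s/%s/%s", trait_code, center, period)
        return failed
    out = CenterPeriodEffect(trait_code, center, period, effect, se, n_subjects, True)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# random-effects meta-analysis, ML heterogeneity
# ---------------------------------------------------------------------------

def _profile_loglik(tau2: float, theta: np.ndarray, var: np.ndarray) -> float:
    w = 1.0 / (var + tau2)
    mu = (w * theta).sum() / w.sum()
    return -0.5 * float(np.sum(np.log(var + tau2) + w * (theta - mu) ** 2))


def ml_tau2(theta: np.ndarray, se: np.ndarray) -> float:
    """Maximum-likelihood between-study variance (profile over tau²)."""
    var = se**2
    hi = max(1e-8, 10.0 * float(np.var(theta)) + float(var.max()))
    res = minimize_scalar(
        lambda t: -_profile_loglik(t, theta, var),
        bounds=(0.0, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    tau2 = float(res.x)
    # the boundary tau2=0 can beat the interior optimum
    if _profile_loglik(0.0, theta, var) >= _profile_loglik(tau2, theta, var):
        tau2 = 0.0
    return tau2


def meta_analyze(
    effects: Iterable[CenterPeriodEffect],
    trait_code: str | None = None,
    period: str | None = None,
) -> MetaResultRow:
    """Pool one trait/period across centers (random effects, ML tau²).

    The pooled estimate is the inverse-variance weighted mean with weights
    1/(se² + tau²); its SE is (sum of weights)^(-1/2); the two-sided p-value
    and the 95% CI use the normal approximation. A single converged center
    passes through with a warning and tau² = 0.
    """
    effects = [e for e in effects if e.converged]
    if not effects:
        raise FitError("no converged center effects to pool")
    trait_code = trait_code or effects[0].trait_code
    period = period or effects[0].period
    theta = np.array([e.effect for e in effects])
    se = np.array([e.se for e in effects])
    if (se <= 0).any():
        raise ValidationError("all standard errors must be positive")
    if len(effects) == 1:
        warnings.warn(
            f"{trait_code}/{period}: single center, pooled result is a "
            "passthrough",
            stacklevel=2,
        )
        return MetaResultRow(
            trait_code=trait_code,
            period=period,
            effect=float(theta[0]),
            se=float(se[0]),
            tau2=0.0,
            p_value=float(2.0 * norm.sf(abs(theta[0]) / se[0])),
            k_centers=1,
        )
    tau2 = ml_tau2(theta, se)
    w = 1.0 / (se**2 + tau2)
    mu = float((w * theta).sum() / w.sum())
    se_pooled = float(w.sum() ** -0.5)
    p = float(2.0 * norm.sf(abs(mu) / se_pooled))
    return MetaResultRow(
        trait_code=trait_code,
        period=period,
        effect=mu,
        se=se_pooled,
        tau2=tau2,
        p_value=p,
        k_centers=len(effects),
    )


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (original order kept).

    The joint pool for the longitudinal analysis is all 32 tests
    (16 traits × 2 periods); callers supply that collection.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value collection")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def count_significant(
    rows: pd.DataFrame | Iterable[MetaResultRow],
    period: str | None = None,
    alpha: float = 0.05,
) -> int:
    """Number of results with adjusted p below ``alpha`` (one period or all)."""
    frame = rows if isinstance(rows, pd.DataFrame) else rows_to_frame(list(rows))
    if period is not None:
        frame = frame[frame["period"] == period]
    return int((frame["p_adjusted"] < alpha).sum())


# ---------------------------------------------------------------------------
# orchestrating estimator
# ---------------------------------------------------------------------------

class LongitudinalTraitAnalysis(BaseEstimator):
    """Per-center mixed models → ML meta-analysis → joint BH, as one fit.

    Parameters
    ----------
    reml
        Variance estimation for the mixed models (REML default).
    alpha
        Significance threshold applied to adjusted p-values.
    periods
        Periods to analyze (both by default).

    Attributes
    ----------
    center_effects_ : pd.DataFrame
        One row per (trait, center, period) with effect, SE, n, convergence.
    results_ : pd.DataFrame
        One row per (trait, period): pooled effect, SE, CI, tau², raw and
        jointly BH-adjusted p-values.
    n_significant_ : dict
        period → count of adjusted p < alpha.
    """

    def __init__(self, reml: bool = True, alpha: float = 0.05, periods=PERIODS):
        self.reml = reml
        self.alpha = alpha
        self.periods = periods

    def fit(self, X: pd.DataFrame, annotation: pd.DataFrame):
        """X: rank-normalized trait matrix (samples × traits), indexed by
        sample id; annotation: validated sample annotation."""
        study = annotation[annotation["role"] == "study"]
        centers = sorted(study["center"].dropna().unique())
        effects: list[CenterPeriodEffect] = []
        rows: list[MetaResultRow] = []
        for trait in X.columns:
            for period in self.periods:
                per_center = []
                for center in centers:
                    eff = fit_center_lmm(
                        X[trait],
                        study[study["center"] == center],
                        period,
                        trait_code=trait,
                        center=center,
                        reml=self.reml,
                    )
                    per_center.append(eff)
                    effects.append(eff)
                rows.append(meta_analyze(per_center, trait, period))
        frame = rows_to_frame(rows)
        frame["p_adjusted"] = bh_adjust(frame["p_value"].to_numpy())
        self.center_effects_ = pd.DataFrame(
            [
                {
                    "trait_code": e.trait_code,
                    "center": e.center,
                    "period": e.period,
                    "effect": e.effect,
                    "se": e.se,
                    "n_subjects": e.n_subjects,
                    "converged": e.converged,
                }
                for e in effects
            ]
        )
        self.results_ = frame
        self.n_significant_ = {
            p: count_significant(frame, p, self.alpha) for p in self.periods
        }
        return self


# ---------------------------------------------------------------------------
# diet-arm contrast
# ---------------------------------------------------------------------------

def _fit_arm_interactions(
    y: np.ndarray, sub: pd.DataFrame, arms_present: list[str], reml: bool
) -> dict[str, tuple[float, float]] | None:
    """One center's T2/T3 model with arm main effects and arm × time
    interactions (control reference). Returns arm → (coef, se)."""
    cols: list[np.ndarray] = [np.ones(len(sub)), sub["time"].to_numpy(float)]
    for cov in _COVARIATES:
        if sub[cov].nunique() > 1:
            cols.append(sub[cov].to_numpy(float))
    inter_idx: dict[str, int] = {}
    for arm in arms_present:
        dummy = (sub["diet_arm"] == arm).to_numpy(float)
        cols.append(dummy)
        cols.append(dummy * sub["time"].to_numpy(float))
        inter_idx[arm] = len(cols) - 1
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return None
    fit = _fit_mixedlm(y, X, sub["subject_id"].to_numpy(), reml)
    if fit is None:
        return None
    out = {}
    for arm, j in inter_idx.items():
        coef, se = float(fit.params[j]), float(fit.bse[j])
        if np.isfinite(coef) and np.isfinite(se) and se > 0:
            out[arm] = (coef, se)
    return out or None


def compare_diet_arms(
    trait_values: pd.DataFrame,
    annotation: pd.DataFrame,
    reml: bool = True,
) -> pd.DataFrame:
    """Weight-maintenance arm contrasts on the T2→T3 change, pooled.

    For each center the period-T2T3 model is extended with diet-arm main
    effects and arm × time interactions (control arm as reference); each
    interaction coefficient is meta-analyzed across centers and the full
    set of (trait, arm) contrasts is BH-adjusted jointly. Centers missing
    an arm contribute nothing to that arm's pooled contrast.
    """
    study = annotation[
        (annotation["role"] == "study") & (annotation["diet_arm"] != "none")
    ]
    if study.empty:
        raise ValidationError("no randomized samples with diet arms")
    centers = sorted(study["center"].dropna().unique())
    records = []
    for trait in trait_values.columns:
        pooled_inputs: dict[str, list[CenterPeriodEffect]] = {
            a: [] for a in ARM_LEVELS
        }
        for center in centers:
            sub = _design_matrix(study[study["center"] == center], "T2T3")
            if sub is None or sub["subject_id"].nunique() < len(ARM_LEVELS) + 1:
                continue
            arms_present = [
                a for a in ARM_LEVELS if (sub["diet_arm"] == a).any()
            ]
            if "control" not in sub["diet_arm"].values or not arms_present:
                logger.info("center %s lacks arms for contrast; skipped", center)
                continue
            y = trait_values[trait].reindex(sub["sample_id"]).to_numpy(float)
            keep = np.isfinite(y)
            res = _fit_arm_interactions(y[keep], sub[keep], arms_present, reml)
            if res is None:
                continue
            for arm, (coef, se) in res.items():
                pooled_inputs[arm].append(
                    CenterPeriodEffect(
                        trait, center, "T2T3", coef, se,
                        sub["subject_id"].nunique(), True,
                    )
                )
        for arm, inputs in pooled_inputs.items():
            if not inputs:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pooled = meta_analyze(inputs, trait, "T2T3")
            records.append(
                {
                    "trait_code": trait,
                    "arm": arm,
                    "effect": pooled.effect,
                    "se": pooled.se,
                    "tau2": pooled.tau2,
                    "p_value": pooled.p_value,
                    "k_centers": pooled.k_centers,
                }
            )
    frame = pd.DataFrame.from_records(records)
    if frame.empty:
        raise FitError("no estimable diet-arm contrasts")
    frame["p_adjusted"] = bh_adjust(frame["p_value"].to_numpy())
    return frame
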