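"""Total-area normalization, log transform and plate batch correction.

Chromatogram peak areas are made comparable across samples by closing each
row to 100% (total-area normalization). Because plate-level technical
effects act multiplicatively on areas and %Area distributions are
right-skewed, batch correction operates on natural-log %Area values using a
parametric empirical-Bayes location-scale model (the ComBat model): per
peak g and plate b an additive location shift gamma_bg and a variance ratio
delta2_bg are estimated on standardized data, shrunk across peaks toward a
normal / inverse-gamma prior per plate, and removed. Corrected values are
exponentiated and re-closed to 100% before trait computation so traits stay
interpretable as percentages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import GP_COLUMNS, GlycanPeakMatrix
from .exceptions import FitError, ValidationError

logger = logging.getLogger(__name__)

ZERO_POLICIES = ("error", "halfmin")


def normalize_total_area(raw: GlycanPeakMatrix) -> GlycanPeakMatrix:
    """Close each row to 100%: value → 100 · area / (row total)."""
    if raw.scale_tag not in ("raw", "percent"):
        raise ValidationError(
            f"total-area normalization expects raw areas, got {raw.scale_tag!r}"
        )
    vals = raw.values
    totals = vals.sum(axis=1)
    if (totals <= 0).any():
        bad = raw.sample_ids[int(np.argmax(totals <= 0))]
        raise ValidationError(f"sample {bad!r} has non-positive total area")
    return raw.copy_with(100.0 * vals / totals[:, None], "percent")


def log_transform(
    percent: GlycanPeakMatrix, zero_policy: str = "halfmin"
) -> GlycanPeakMatrix:
    """Natural log of %Area values.

    ``zero_policy`` governs zero areas (never expected in clean UHPLC data
    but possible in sparse synthetic or truncated inputs): ``error`` raises;
    ``halfmin`` replaces zeros in a peak by half that peak's smallest
    positive value, logging how many cells were imputed.
    """
    if percent.scale_tag != "percent":
        raise ValidationError(
            f"log transform expects %Area data, got {percent.scale_tag!r}"
        )
    if zero_policy not in ZERO_POLICIES:
        raise ValidationError(f"zero_policy must be one of {ZERO_POLICIES}")
    vals = percent.values.copy()
    zeros = vals == 0.0
    if zeros.any():
        if zero_policy == "error":
            i, j = np.argwhere(zeros)[0]
            raise ValidationError(
                f"zero %Area at sample {percent.sample_ids[i]!r}, column "
                f"{GP_COLUMNS[j]}; set zero_policy='halfmin' to impute"
            )
        for j in np.flatnonzero(zeros.any(axis=0)):
            col = vals[:, j]
            positive = col[col > 0]
            if positive.size == 0:
                raise ValidationError(
                    f"peak {GP_COLUMNS[j]} is zero in every sample; cannot impute"
                )
            vals[zeros[:, j], j] = 0.5 * positive.min()
        logger.info("halfmin-imputed %d zero cells before log transform", zeros.sum())
    return percent.copy_with(np.log(vals), "log_percent")


def backtransform_and_renormalize(corrected: GlycanPeakMatrix) -> GlycanPeakMatrix:
    """Exponentiate log-scale values and re-close rows to 100%."""
    if corrected.scale_tag != "log_percent":
        raise ValidationError(
            f"backtransform expects log-scale data, got {corrected.scale_tag!r}"
        )
    vals = np.exp(corrected.values)
    return corrected.copy_with(100.0 * vals / vals.sum(axis=1)[:, None], "percent")


@dataclass
class BatchAdjustmentModel:
    """Fitted empirical-Bayes batch model: one location/scale pair per
    (peak, plate), plus the pooled per-peak parameters and plate priors.

    ``gamma_star``/``delta2_star`` are the shrunk estimates actually removed
    from the data (on the standardized scale); ``gamma_hat``/``delta2_hat``
    are the naive per-plate estimates they were shrunk from.
    """

    batches: tuple = ()
    alpha: pd.Series = field(default_factory=pd.Series)        # pooled mean per peak
    var_pooled: pd.Series = field(default_factory=pd.Series)   # pooled variance per peak
    gamma_hat: pd.DataFrame = field(default_factory=pd.DataFrame)
    delta2_hat: pd.DataFrame = field(default_factory=pd.DataFrame)
    gamma_star: pd.DataFrame = field(default_factory=pd.DataFrame)
    delta2_star: pd.DataFrame = field(default_factory=pd.DataFrame)
    prior_gamma_bar: pd.Series = field(default_factory=pd.Series)  # per plate
    prior_tau2: pd.Series = field(default_factory=pd.Series)
    prior_a: pd.Series = field(default_factory=pd.Series)
    prior_b: pd.Series = field(default_factory=pd.Series)
    excluded_peaks: tuple = ()
    n_iter: dict = field(default_factory=dict)
    mean_only: bool = False

    def validate(self) -> None:
        if len(self.delta2_star) and (self.delta2_star.to_numpy() <= 0).any():
            raise ValidationError("delta2 estimates must be positive")


def _identity_model(matrix: GlycanPeakMatrix, batches) -> BatchAdjustmentModel:
    plates = tuple(pd.unique(np.asarray(batches)))
    cols = list(GP_COLUMNS)
    zeros = pd.DataFrame(0.0, index=list(plates), columns=cols)
    return BatchAdjustmentModel(
        batches=plates,
        alpha=pd.Series(matrix.values.mean(axis=0), index=cols),
        var_pooled=pd.Series(matrix.values.var(axis=0), index=cols),
        gamma_hat=zeros.copy(),
        delta2_hat=zeros + 1.0,
        gamma_star=zeros.copy(),
        delta2_star=zeros + 1.0,
    )


def combat_correct(
    logdata: GlycanPeakMatrix,
    plates,
    mean_only: bool = False,
    eb_tol: float = 1e-4,
    eb_max_iter: int = 100,
) -> tuple[GlycanPeakMatrix, BatchAdjustmentModel]:
    """Parametric empirical-Bayes batch correction with plate as batch.

    Steps: (1) standardize each peak by its pooled mean and pooled
    within-plate variance; (2) compute naive per-plate location/scale
    estimates; (3) shrink locations toward a per-plate normal prior and
    scales toward an inverse-gamma prior, hyperparameters by method of
    moments across the 39 peaks; (4) iterate the coupled shrinkage
    equations to a fixed point; (5) remove the shrunk effects and restore
    the pooled scale. With a single plate no correction is possible and the
    data are returned unchanged (identity model).

    Parameters
    ----------
    logdata
        Log-scale peak matrix.
    plates
        Plate label per sample, aligned with ``logdata`` rows.
    mean_only
        If True, adjust locations only (all variance ratios fixed at 1).
    eb_tol, eb_max_iter
        Convergence control for the shrinkage fixed point (max relative
        parameter change below ``eb_tol`` stops the iteration).
    """
    if logdata.scale_tag != "log_percent":
        raise ValidationError(
            f"batch correction expects log-scale data, got {logdata.scale_tag!r}"
        )
    plates = np.asarray(pd.Series(plates).to_numpy())
    if len(plates) != logdata.n_samples:
        raise ValidationError("plate labels must align with samples")
    levels = pd.unique(plates)
    if len(levels) == 1:
        return logdata, _identity_model(logdata, plates)
    counts = pd.Series(plates).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise FitError(
            f"plate(s) {list(small.index)} have a single sample; "
            "scale not estimable"
        )

    X = logdata.values  # n × G
    n, G = X.shape
    cols = list(GP_COLUMNS)
    masks = {b: plates == b for b in levels}
    n_b = {b: int(masks[b].sum()) for b in levels}

    batch_means = np.vstack([X[masks[b]].mean(axis=0) for b in levels])  # k × G
    alpha = np.array([n_b[b] for b in levels]) @ batch_means / n  # pooled mean
    # pooled variance around per-plate means, denominator n
    sq = np.zeros(G)
    for i, b in enumerate(levels):
        sq += ((X[masks[b]] - batch_means[i]) ** 2).sum(axis=0)
    var_pooled = sq / n

    keep = var_pooled > 0
    excluded = tuple(np.array(cols)[~keep])
    if excluded:
        warnings.warn(
            f"peaks with zero pooled variance left uncorrected: {list(excluded)}",
            stacklevel=2,
        )
    sd = np.where(keep, np.sqrt(var_pooled), 1.0)
    Z = (X - alpha) / sd

    gamma_hat = np.vstack([Z[masks[b]].mean(axis=0) for b in levels])
    delta2_hat = np.vstack([Z[masks[b]].var(axis=0, ddof=1) for b in levels])

    # method-of-moments hyperpriors per plate, across peaks
    gamma_bar = gamma_hat[:, keep].mean(axis=1)
    tau2 = gamma_hat[:, keep].var(axis=1, ddof=1)
    d_mean = delta2_hat[:, keep].mean(axis=1)
    d_var = delta2_hat[:, keep].var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = (2.0 * d_var + d_mean**2) / d_var
        b_prior = (d_mean * d_var + d_mean**3) / d_var

    gamma_star = gamma_hat.copy()
    delta2_star = np.ones_like(delta2_hat) if mean_only else delta2_hat.copy()
    n_iter: dict = {}
    for i, b in enumerate(levels):
        if mean_only:
            # posterior mean with known unit variance, one-shot
            nb = n_b[b]
            gamma_star[i] = (nb * tau2[i] * gamma_hat[i] + gamma_bar[i]) / (
                nb * tau2[i] + 1.0
            )
            delta2_star[i] = 1.0
            n_iter[b] = 1
            continue
        nb = n_b[b]
        Zb = Z[masks[b]]
        g_old = gamma_hat[i].copy()
        d_old = delta2_hat[i].copy()
        it = 0
        while it < eb_max_iter:
            it += 1
            g_new = (nb * tau2[i] * gamma_hat[i] + d_old * gamma_bar[i]) / (
                nb * tau2[i] + d_old
            )
            sum2 = ((Zb - g_new) ** 2).sum(axis=0)
            d_new = (0.5 * sum2 + b_prior[i]) / (nb / 2.0 + a_prior[i] - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
            )
            g_old, d_old = g_new, d_new
            if change < eb_tol:
                break
        gamma_star[i], delta2_star[i] = g_old, d_old
        n_iter[b] = it

    # never touch zero-variance peaks
    gamma_star[:, ~keep] = 0.0
    delta2_star[:, ~keep] = 1.0
    gamma_hat[:, ~keep] = 0.0
    delta2_hat[:, ~keep] = 1.0

    Z_adj = Z.copy()
    for i, b in enumerate(levels):
        Z_adj[masks[b]] = (Z[masks[b]] - gamma_star[i]) / np.sqrt(delta2_star[i])
    X_adj = Z_adj * sd + alpha

    model = BatchAdjustmentModel(
        batches=tuple(levels),
        alpha=pd.Series(alpha, index=cols),
        var_pooled=pd.Series(var_pooled, index=cols),
        gamma_hat=pd.DataFrame(gamma_hat, index=list(levels), columns=cols),
        delta2_hat=pd.DataFrame(delta2_hat, index=list(levels), columns=cols),
        gamma_star=pd.DataFrame(gamma_star, index=list(levels), columns=cols),
        delta2_star=pd.DataFrame(delta2_star, index=list(levels), columns=cols),
        prior_gamma_bar=pd.Series(gamma_bar, index=list(levels)),
        prior_tau2=pd.Series(tau2, index=list(levels)),
        prior_a=pd.Series(a_prior, index=list(levels)),
        prior_b=pd.Series(b_prior, index=list(levels)),
        excluded_peaks=excluded,
        n_iter=n_iter,
        mean_only=mean_only,
    )
    model.validate()
    return logdata.copy_with(X_adj, "log_percent"), model


class TotalAreaNormalizer(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style wrapper around :func:`normalize_total_area`."""

    def fit(self, X: GlycanPeakMatrix, y=None):
        self.n_features_in_ = X.values.shape[1]
        return self

    def transform(self, X: GlycanPeakMatrix) -> GlycanPeakMatrix:
        return normalize_total_area(X)


class NaturalLogTransformer(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style wrapper around :func:`log_transform`."""

    def __init__(self, zero_policy: str = "halfmin"):
        self.zero_policy = zero_policy

    def fit(self, X: GlycanPeakMatrix, y=None):
        self.n_features_in_ = X.values.shape[1]
        return self

    def transform(self, X: GlycanPeakMatrix) -> GlycanPeakMatrix:
        return log_transform(X, zero_policy=self.zero_policy)


class CombatBatchCorrector(BaseEstimator, TransformerMixin):
    """Empirical-Bayes plate correction as a fit/transform estimator.

    ``fit`` estimates the batch model on log-scale data (replicates and
    standards included — that is what they are on the plate for);
    ``transform`` applies the stored adjustment to the same samples.

    Attributes
    ----------
    model_ : BatchAdjustmentModel
        Fitted location/scale batch effects and priors.
    """

    def __init__(
        self,
        batch: pd.Series | None = None,
        mean_only: bool = False,
        eb_tol: float = 1e-4,
        eb_max_iter: int = 100,
    ):
        self.batch = batch
        self.mean_only = mean_only
        self.eb_tol = eb_tol
        self.eb_max_iter = eb_max_iter

    def _labels(self, X: GlycanPeakMatrix, batch):
        if batch is None:
            batch = self.batch
        if batch is None:
            raise ValidationError("plate labels required (batch=...)")
        if isinstance(batch, pd.Series):
            batch = batch.reindex(X.sample_ids)
            if batch.isna().any():
                raise ValidationError("plate label missing for some samples")
            return batch.to_numpy()
        return np.asarray(batch)

    def fit(self, X: GlycanPeakMatrix, y=None, batch=None):
        corrected, model = combat_correct(
            X,
            self._labels(X, batch),
            mean_only=self.mean_only,
            eb_tol=self.eb_tol,
            eb_max_iter=self.eb_max_iter,
        )
        self.model_ = model
        self._corrected = corrected
        self._fit_ids = tuple(X.sample_ids)
        return self

    def transform(self, X: GlycanPeakMatrix) -> GlycanPeakMatrix:
        check_is_fitted(self, "model_")
        if tuple(X.sample_ids) != self._fit_ids:
            raise ValidationError(
                "batch correction transforms the samples it was fitted on"
            )
        return self._corrected
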