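"""Core domain types for UHPLC plasma N-glycome analysis.

The pipeline's central carrier is the :class:`GlycanPeakMatrix` — a sample ×
39 glycan-peak table in one of three scales: ``raw`` chromatogram areas
(arbitrary fluorescence units), ``percent`` (%Area, each row closed to 100),
or ``log_percent`` (natural log of %Area). Sample metadata (subject, center,
time point, plate, covariates, sample role) travels as a validated pandas
DataFrame — one row per sample — produced by :func:`validate_annotation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

N_PEAKS = 39
GP_COLUMNS: tuple[str, ...] = tuple(f"GP{i}" for i in range(1, N_PEAKS + 1))

#: The eight recruitment centers of the dietary-intervention cohort.
CENTERS: tuple[str, ...] = (
    "Maastricht",
    "Copenhagen",
    "Cambridge",
    "Heraklion",
    "Potsdam",
    "Pamplona",
    "Sofia",
    "Prague",
)

TIME_POINTS: tuple[str, ...] = ("T1", "T2", "T3")
PERIODS: tuple[str, ...] = ("T1T2", "T2T3")
#: Five weight-maintenance arms; "none" marks pre-randomization samples.
DIET_ARMS: tuple[str, ...] = ("LP/LGI", "LP/HGI", "HP/LGI", "HP/HGI", "control", "none")
ROLES: tuple[str, ...] = ("study", "replicate", "standard")
TRAIT_CODES: tuple[str, ...] = (
    "LB", "HB", "G0", "G1", "G2", "G3", "G4",
    "S0", "S1", "S2", "S3", "S4", "B", "AF", "CF", "HM",
)

SCALE_TAGS = ("raw", "percent", "log_percent")

ANNOTATION_COLUMNS = (
    "sample_id", "subject_id", "center", "time_point", "plate",
    "age", "sex", "bmi", "diet_arm", "role",
)

#: Two-sided 97.5% standard-normal quantile used for 95% confidence intervals.
Z_975 = 1.959963984540054


@dataclass
class GlycanPeakMatrix:
    """Sample × 39 glycan-peak quantities.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with exactly the columns GP1..GP39
        (canonical order enforced on construction).
    scale_tag
        One of ``raw`` (chromatogram areas), ``percent`` (%Area rows summing
        to 100) or ``log_percent`` (natural log of %Area).
    """

    data: pd.DataFrame
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValidationError(
                f"scale_tag must be one of {SCALE_TAGS}, got {self.scale_tag!r}"
            )
        self.data = canonicalize_peak_frame(self.data)
        self.validate()

    # -- container protocol -------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def copy_with(self, values: np.ndarray, scale_tag: str) -> "GlycanPeakMatrix":
        """New matrix with the same samples/columns but different values."""
        frame = pd.DataFrame(values, index=self.data.index, columns=list(GP_COLUMNS))
        return GlycanPeakMatrix(frame, scale_tag)

    def subset(self, sample_ids: Iterable[str]) -> "GlycanPeakMatrix":
        ids = list(sample_ids)
        missing = set(ids) - set(self.data.index)
        if missing:
            raise ValidationError(f"unknown sample ids: {sorted(missing)[:5]}")
        return GlycanPeakMatrix(self.data.loc[ids], self.scale_tag)

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite value at sample {self.data.index[bad[0]]!r}, "
                f"column {GP_COLUMNS[bad[1]]}"
            )
        if self.scale_tag in ("raw", "percent") and (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative value at sample {self.data.index[bad[0]]!r}, "
                f"column {GP_COLUMNS[bad[1]]}"
            )
        if self.scale_tag == "percent" and len(vals):
            sums = vals.sum(axis=1)
            if not np.allclose(sums, 100.0, rtol=1e-9, atol=1e-9):
                worst = int(np.argmax(np.abs(sums - 100.0)))
                raise ValidationError(
                    f"percent rows must sum to 100; sample "
                    f"{self.data.index[worst]!r} sums to {sums[worst]!r}"
                )


def canonicalize_peak_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Reorder columns to GP1..GP39, erroring on missing/extra peak columns."""
    cols = set(frame.columns)
    missing = [c for c in GP_COLUMNS if c not in cols]
    extra = sorted(cols - set(GP_COLUMNS))
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing peak columns: {missing}")
        if extra:
            parts.append(f"unexpected columns: {extra}")
        raise SchemaError("; ".join(parts))
    out = frame.loc[:, list(GP_COLUMNS)].astype(float)
    if out.index.has_duplicates:
        dupes = out.index[out.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
    return out


def validate_annotation(
    frame: pd.DataFrame, centers: Sequence[str] | None = None
) -> pd.DataFrame:
    """Validate and normalize a sample-annotation table.

    One row per sample. Study samples must carry subject, center, time point
    and plate; ``diet_arm`` is forced to ``"none"`` at T1 (empty values are
    normalized to ``"none"`` everywhere). Replicate and standard rows need
    only a plate. Returns a copy with canonical column order and dtypes.
    """
    allowed_centers = tuple(centers) if centers is not None else CENTERS
    frame = frame.copy()
    if "sample_id" not in frame.columns:
        raise SchemaError("annotation requires a 'sample_id' column")
    for col in ANNOTATION_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    extras = [c for c in frame.columns if c not in ANNOTATION_COLUMNS]
    frame = frame.loc[:, list(ANNOTATION_COLUMNS) + extras]
    if frame["sample_id"].duplicated().any():
        dupes = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in annotation: {dupes[:5]}")

    frame["role"] = frame["role"].fillna("study").replace("", "study")
    bad_role = ~frame["role"].isin(ROLES)
    if bad_role.any():
        raise ValidationError(
            f"unknown role {frame.loc[bad_role, 'role'].iloc[0]!r}; "
            f"allowed roles: {list(ROLES)}"
        )

    frame["diet_arm"] = frame["diet_arm"].replace("", np.nan).fillna("none")
    bad_arm = ~frame["diet_arm"].isin(DIET_ARMS)
    if bad_arm.any():
        raise ValidationError(
            f"unknown diet_arm {frame.loc[bad_arm, 'diet_arm'].iloc[0]!r}; "
            f"allowed arms: {list(DIET_ARMS)}"
        )

    study = frame["role"] == "study"
    for col in ("subject_id", "center", "time_point", "plate"):
        incomplete = study & frame[col].isna()
        if incomplete.any():
            sid = frame.loc[incomplete, "sample_id"].iloc[0]
            raise ValidationError(f"study sample {sid!r} lacks {col}")

    bad_tp = study & ~frame["time_point"].isin(TIME_POINTS)
    if bad_tp.any():
        raise ValidationError(
            f"unknown time_point {frame.loc[bad_tp, 'time_point'].iloc[0]!r}; "
            f"allowed levels: {list(TIME_POINTS)}"
        )
    bad_center = study & ~frame["center"].isin(allowed_centers)
    if bad_center.any():
        raise ValidationError(
            f"unknown center {frame.loc[bad_center, 'center'].iloc[0]!r}; "
            f"allowed centers: {list(allowed_centers)}"
        )

    at_t1 = study & (frame["time_point"] == "T1")
    bad_t1_arm = at_t1 & (frame["diet_arm"] != "none")
    if bad_t1_arm.any():
        sid = frame.loc[bad_t1_arm, "sample_id"].iloc[0]
        raise ValidationError(
            f"sample {sid!r}: diet_arm must be 'none' at T1 "
            f"(randomization happens after the low-calorie-diet period)"
        )

    for col in ("age", "bmi"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    return frame.reset_index(drop=True)


@dataclass
class MetaResultRow:
    """Pooled cross-center result for one (trait, period) — one table row.

    ``effect`` is the change over the period in units of one SD of the
    rank-normalized trait; ``tau2`` is the between-center variance from the
    maximum-likelihood random-effects model.
    """

    trait_code: str
    period: str
    effect: float
    se: float
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)
    tau2: float = 0.0
    p_value: float = np.nan
    p_adjusted: float = np.nan
    k_centers: int = 0

    def __post_init__(self) -> None:
        if np.isnan(self.ci_low):
            self.ci_low = self.effect - Z_975 * self.se
        if np.isnan(self.ci_high):
            self.ci_high = self.effect + Z_975 * self.se
        self.validate()

    def validate(self) -> None:
        if self.trait_code not in TRAIT_CODES:
            raise ValidationError(f"unknown trait code {self.trait_code!r}")
        if self.period not in PERIODS:
            raise ValidationError(f"unknown period {self.period!r}")
        if not np.isfinite(self.effect):
            raise ValidationError(f"{self.trait_code}/{self.period}: non-finite effect")
        if abs(self.ci_low - (self.effect - Z_975 * self.se)) > 1e-9 or abs(
            self.ci_high - (self.effect + Z_975 * self.se)
        ) > 1e-9:
            raise ValidationError(
                f"{self.trait_code}/{self.period}: CI inconsistent with effect ± 1.96·SE"
            )
        if not np.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")
        if not np.isnan(self.p_adjusted):
            if not 0.0 <= self.p_adjusted <= 1.0:
                raise ValidationError(f"p_adjusted {self.p_adjusted} outside [0, 1]")
            if not np.isnan(self.p_value) and self.p_adjusted < self.p_value - 1e-12:
                raise ValidationError(
                    f"{self.trait_code}/{self.period}: adjusted p below raw p"
                )


RESULT_COLUMNS = (
    "trait_code", "period", "effect", "se", "ci_low", "ci_high",
    "tau2", "p_value", "p_adjusted", "k_centers",
)


def rows_to_frame(rows: Iterable[MetaResultRow]) -> pd.DataFrame:
    """Meta-result rows → DataFrame in canonical column order."""
    recs = [
        {c: getattr(r, c) for c in RESULT_COLUMNS} for r in rows
    ]
    return pd.DataFrame(recs, columns=list(RESULT_COLUMNS))


def frame_to_rows(frame: pd.DataFrame) -> list[MetaResultRow]:
    """DataFrame → validated meta-result rows."""
    return [
        MetaResultRow(**{c: rec[c] for c in RESULT_COLUMNS if c in rec})
        for rec in frame.to_dict("records")
    ]
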