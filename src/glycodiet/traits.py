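"""Derived glycan traits and the rank-based inverse-normal transform.

Sixteen derived traits summarize the 39 glycan peaks by shared structural
features: branching (LB/HB), number of terminal galactoses (G0–G4), number
of sialic acids (S0–S4), bisecting GlcNAc (B), antennary and core fucose
(AF/CF), and high-mannose structures (HM). Each trait is a weighted sum of
%Area peak shares with weights in {0.5, 1}; peak GP12 holds co-eluting
structures and is split 50/50 between two families. Because the peak matrix
is closed to 100%, three trait families form exact partitions:

    LB + HB + HM = 100
    G0 + G1 + G2 + G3 + G4 + HM = 100
    S0 + S1 + S2 + S3 + S4 + HM = 100

Trait values are analyzed after a rank-based inverse-normal transform,
which maps each trait to a standard-normal scale so that effects are
comparable across centers.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtri
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import GP_COLUMNS, N_PEAKS, TRAIT_CODES, GlycanPeakMatrix
from .exceptions import ConfigurationError, ValidationError

_PARTITION_FAMILIES: dict[str, tuple[str, ...]] = {
    "branching": ("LB", "HB", "HM"),
    "galactosylation": ("G0", "G1", "G2", "G3", "G4", "HM"),
    "sialylation": ("S0", "S1", "S2", "S3", "S4", "HM"),
}


@dataclass
class TraitDefinitionTable:
    """Declarative weighted mapping of glycan peaks to derived traits.

    ``memberships`` maps trait code → {peak index (1-based) → weight}.
    The weight matrix form (39 × 16) is exposed via :meth:`weight_matrix`.
    """

    memberships: dict[str, dict[int, float]]
    trait_codes: tuple[str, ...] = field(default=TRAIT_CODES)

    def __post_init__(self) -> None:
        missing = [t for t in self.trait_codes if t not in self.memberships]
        if missing:
            raise ConfigurationError(f"trait definitions missing traits: {missing}")
        for trait, members in self.memberships.items():
            for gp, w in members.items():
                if not 1 <= gp <= N_PEAKS:
                    raise ConfigurationError(
                        f"trait {trait}: peak index {gp} outside 1..{N_PEAKS}"
                    )
                if w not in (0.5, 1.0):
                    raise ConfigurationError(
                        f"trait {trait}: weight {w} for GP{gp} not in {{0.5, 1}}"
                    )

    @classmethod
    def default(cls) -> "TraitDefinitionTable":
        """The trait table shipped with the package."""
        ref = importlib.resources.files("glycodiet.data") / "trait_definitions.yaml"
        return cls.from_yaml_text(ref.read_text())

    @classmethod
    def from_yaml_text(cls, text: str) -> "TraitDefinitionTable":
        raw = yaml.safe_load(text)
        memberships: dict[str, dict[int, float]] = {}
        for trait, groups in raw.items():
            members: dict[int, float] = {}
            for weight_key, peaks in groups.items():
                w = float(weight_key)
                for gp in peaks:
                    if gp in members:
                        raise ConfigurationError(
                            f"trait {trait}: GP{gp} listed twice"
                        )
                    members[int(gp)] = w
            memberships[trait] = members
        return cls(memberships)

    @classmethod
    def from_yaml(cls, path) -> "TraitDefinitionTable":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls.from_yaml_text(fh.read())

    def weight_matrix(self) -> pd.DataFrame:
        """39 × n_traits weight matrix (rows GP1..GP39)."""
        mat = pd.DataFrame(
            0.0, index=list(GP_COLUMNS), columns=list(self.trait_codes)
        )
        for trait, members in self.memberships.items():
            for gp, w in members.items():
                mat.loc[f"GP{gp}", trait] = w
        return mat

    def total_weight(self, trait: str) -> float:
        return float(sum(self.memberships[trait].values()))


def validate_trait_partitions(defs: TraitDefinitionTable) -> pd.DataFrame:
    """Check the three family closures; return a per-peak coverage report.

    For each family the weights assigned to every peak must sum to exactly 1
    (so family traits + HM close to 100%). The report has one row per
    (family, peak) with the summed weight and a pass flag.
    """
    wm = defs.weight_matrix()
    records = []
    for family, traits in _PARTITION_FAMILIES.items():
        cover = wm.loc[:, list(traits)].sum(axis=1)
        for gp_col, total in cover.items():
            records.append(
                {
                    "family": family,
                    "peak": gp_col,
                    "weight_sum": float(total),
                    "ok": bool(abs(total - 1.0) < 1e-12),
                }
            )
    return pd.DataFrame.from_records(records)


def compute_derived_traits(
    percent: GlycanPeakMatrix, defs: TraitDefinitionTable | None = None
) -> pd.DataFrame:
    """Derived-trait matrix (sample × 16, percent units) from %Area peaks.

    Since rows of ``percent`` are closed to 100, each trait is simply the
    weighted sum of its member peak percentages.
    """
    if defs is None:
        defs = TraitDefinitionTable.default()
    report = validate_trait_partitions(defs)
    if not report["ok"].all():
        bad = report.loc[~report["ok"], ["family", "peak", "weight_sum"]]
        raise ConfigurationError(
            "trait definition table fails partition closure:\n"
            + bad.to_string(index=False)
        )
    if percent.scale_tag != "percent":
        raise ValidationError(
            f"derived traits are defined on %Area data, got scale "
            f"{percent.scale_tag!r}"
        )
    wm = defs.weight_matrix()
    values = percent.values @ wm.to_numpy()
    return pd.DataFrame(values, index=percent.sample_ids, columns=list(wm.columns))


def inverse_normal_transform(
    values: Sequence[float] | np.ndarray | pd.Series,
    offset: float = 0.5,
    denominator_shift: float = 0.0,
) -> np.ndarray:
    """Rank-based inverse-normal transform.

    A value with (average, for ties) rank r among n non-missing values maps
    to Phi^-1((r - offset)/(n + denominator_shift)). The default
    (offset 0.5, shift 0) is the (r - 0.5)/n convention; Blom's variant is
    offset 3/8, shift 1/4. Missing values stay missing; ties share a value.
    """
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = np.isfinite(arr)
    n = int(mask.sum())
    if n < 2:
        raise ValidationError("inverse-normal transform needs >= 2 non-missing values")
    obs = arr[mask]
    if np.all(obs == obs[0]):
        raise ValidationError(
            "inverse-normal transform undefined: all values identical (single tie group)"
        )
    ranks = rankdata(obs, method="average")
    out[mask] = ndtri((ranks - offset) / (n + denominator_shift))
    return out


class DerivedTraitTransformer(BaseEstimator, TransformerMixin):
    """Stateless transformer: %Area peak matrix → 16 derived traits.

    Parameters
    ----------
    definitions
        Trait definition table; the shipped default when None.
    """

    def __init__(self, definitions: TraitDefinitionTable | None = None):
        self.definitions = definitions

    def fit(self, X: GlycanPeakMatrix, y=None):
        defs = self.definitions or TraitDefinitionTable.default()
        report = validate_trait_partitions(defs)
        if not report["ok"].all():
            raise ConfigurationError("trait definition table fails partition closure")
        self.definitions_ = defs
        return self

    def transform(self, X: GlycanPeakMatrix) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "definitions_")
        return compute_derived_traits(X, self.definitions_)


class RankInverseNormalTransformer(BaseEstimator, TransformerMixin):
    """Column-wise rank-INT, optionally within groups (e.g., per center).

    Fitting is a no-op (the transform is defined by the ranks of the data it
    is applied to, the convention of the longitudinal analysis); the class
    exists so the step composes with sklearn pipelines.

    Parameters
    ----------
    groups
        Optional alignable Series of group labels; the transform is applied
        within each group separately so every center sees a coherent
        standard-normal scale across its time points.
    offset, denominator_shift
        Rank-to-probability convention (see :func:`inverse_normal_transform`).
    """

    def __init__(
        self,
        groups: pd.Series | None = None,
        offset: float = 0.5,
        denominator_shift: float = 0.0,
    ):
        self.groups = groups
        self.offset = offset
        self.denominator_shift = denominator_shift

    def fit(self, X: pd.DataFrame, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(index=X.index, columns=X.columns, dtype=float)
        if self.groups is None:
            group_iter = [(None, X.index)]
        else:
            groups = self.groups.reindex(X.index)
            if groups.isna().any():
                raise ValidationError("group labels missing for some samples")
            group_iter = list(X.index.groupby(groups).items())
        for _, idx in group_iter:
            block = X.loc[idx]
            for col in X.columns:
                out.loc[idx, col] = inverse_normal_transform(
                    block[col].to_numpy(),
                    offset=self.offset,
                    denominator_shift=self.denominator_shift,
                )
        return out
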