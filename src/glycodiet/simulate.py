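"""Seeded generator of multi-center longitudinal plasma-glycome cohorts.

The generator emulates the statistical structure the downstream analysis
assumes: eight recruitment centers, three blood-collection time points
(baseline T1, post low-calorie diet T2, post weight-maintenance T3) with
random non-informative dropout after T2, block-randomized plate layout with
technical replicates and plasma standards on every plate, multiplicative
plate batch effects, right-skewed compositional peak distributions from a
log-normal latent model, per-subject random intercepts, and covariates
(age, sex, BMI) with small per-peak loadings.

Trait-level time effects are specified in standardized units (one SD of the
rank-normalized trait) and pushed down to member peaks proportionally to
trait weights. An internal Monte-Carlo fixed point — deterministic under
the seed — calibrates the latent multiplicative shift so the nominal
standardized effect equals the realized group difference on the
inverse-normal scale, including interactions between simultaneously
injected, compositionally coupled traits. The truth record keeps every
latent parameter for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .datatypes import (
    CENTERS,
    GP_COLUMNS,
    N_PEAKS,
    TRAIT_CODES,
    GlycanPeakMatrix,
    validate_annotation,
)
from .exceptions import ConfigurationError, ValidationError
from .traits import TraitDefinitionTable, inverse_normal_transform

#: Baseline %Area composition (normalized to 100 on use): a right-skewed
#: plasma-like profile dominated by biantennary sialylated peaks.
DEFAULT_BASELINE = (
    0.8, 0.4, 0.6, 2.5, 0.9, 0.5, 0.3, 8.0, 0.7, 3.5, 0.9,
    1.5, 1.2, 6.0, 1.0, 3.0, 1.0, 14.0, 0.6, 2.0, 1.8, 1.5, 1.2,
    3.0, 2.5, 6.0, 1.5, 2.0, 1.2, 2.5, 1.5, 3.5, 1.8, 1.0, 1.5,
    2.0, 4.0, 1.2, 1.0,
)


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the synthetic cohort.

    Defaults mirror the dietary-intervention design: 8 centers, dropout of
    165/938 ≈ 17.6% after T2, 26 plates holding ~70 study samples each plus
    5 within-plate and 5 cross-plate technical replicates and 4 plasma
    standards, mean age 41 y, mean BMI 34 kg/m². Variance parameters are on
    the natural-log peak scale.
    """

    n_centers: int = 8
    subjects_per_center: int = 80
    dropout_fraction_after_T2: float = 165.0 / 938.0
    n_plates: int | None = 26
    samples_per_plate: int = 70          # study-sample capacity per plate
    replicates_within_per_plate: int = 5
    replicates_cross_per_plate: int = 5
    standards_per_plate: int = 4
    baseline_composition: tuple = DEFAULT_BASELINE
    batch_effect_sd_location: float = 0.10
    batch_effect_sd_scale: float = 0.20  # sd of log residual-sd multiplier
    subject_intercept_sd: float = 0.25
    residual_sd: float = 0.10
    sample_intensity_sd: float = 0.30    # per-sample overall fluorescence factor
    age_mean: float = 41.0
    age_sd: float = 6.5
    bmi_mean: float = 34.0
    bmi_sd: float = 4.0
    sex_prob: float = 0.5
    age_loading_sd: float = 0.002        # per-peak log effect per year
    sex_loading_sd: float = 0.02
    bmi_loading_sd: float = 0.003
    trait_time_effects: dict = field(default_factory=dict)
    diet_arm_effects: dict = field(default_factory=dict)
    calibration_draws: int = 20000
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.n_centers <= len(CENTERS):
            raise ConfigurationError(
                f"n_centers must be in 1..{len(CENTERS)}"
            )
        if len(self.baseline_composition) != N_PEAKS:
            raise ConfigurationError(
                f"baseline_composition needs {N_PEAKS} entries"
            )
        if min(self.baseline_composition) <= 0:
            raise ConfigurationError("baseline composition must be positive")
        for name in (
            "batch_effect_sd_location", "batch_effect_sd_scale",
            "subject_intercept_sd", "residual_sd", "sample_intensity_sd",
            "age_loading_sd", "sex_loading_sd", "bmi_loading_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.dropout_fraction_after_T2 < 1.0:
            raise ConfigurationError("dropout fraction must be in [0, 1)")
        for (trait, period), eff in self.trait_time_effects.items():
            if trait not in TRAIT_CODES:
                raise ConfigurationError(f"unknown trait {trait!r} in time effects")
            if period not in ("T1T2", "T2T3"):
                raise ConfigurationError(f"unknown period {period!r} in time effects")
        for (trait, arm), eff in self.diet_arm_effects.items():
            if trait not in TRAIT_CODES:
                raise ConfigurationError(f"unknown trait {trait!r} in arm effects")

    @property
    def centers(self) -> tuple[str, ...]:
        return CENTERS[: self.n_centers]


@dataclass
class CohortTruth:
    """Latent parameters of one simulated cohort (for recovery tests)."""

    config: SimulationConfig
    subjects: pd.DataFrame                 # subject_id, center, covariates, dropout, arm
    subject_intercepts: pd.DataFrame       # subject × 39
    plate_location_effects: pd.DataFrame   # plate × 39
    plate_scale_factors: pd.Series         # plate → residual-sd multiplier
    covariate_loadings: pd.DataFrame       # 39 × {age, sex, bmi}
    peak_time_shifts: pd.DataFrame         # 39 × {T1T2, T2T3} latent log shifts
    nominal_effects: dict                  # (trait, period) → injected effect
    realized_effects: pd.DataFrame         # trait × period, INT-scale truth
    replicate_sources: dict                # replicate sample id → source sample id
    standard_profile: np.ndarray           # latent log profile of plasma standard

    def to_json(self, path) -> None:
        payload = {
            "config": {
                k: (dict((f"{t}|{p}", v) for (t, p), v in val.items())
                    if k in ("trait_time_effects", "diet_arm_effects") else
                    (list(val) if isinstance(val, tuple) else val))
                for k, val in asdict(self.config).items()
            },
            "subjects": self.subjects.to_dict("records"),
            "subject_intercepts": self.subject_intercepts.round(8).to_dict("index"),
            "plate_location_effects": self.plate_location_effects.round(8).to_dict("index"),
            "plate_scale_factors": self.plate_scale_factors.round(8).to_dict(),
            "covariate_loadings": self.covariate_loadings.round(8).to_dict("index"),
            "peak_time_shifts": self.peak_time_shifts.round(8).to_dict("index"),
            "nominal_effects": {f"{t}|{p}": v for (t, p), v in self.nominal_effects.items()},
            "realized_effects": self.realized_effects.round(6).to_dict("index"),
            "replicate_sources": self.replicate_sources,
            "standard_profile": np.round(self.standard_profile, 8).tolist(),
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# effect-size calibration
# ---------------------------------------------------------------------------

def _traits_from_log(latent_log: np.ndarray, weights: np.ndarray) -> np.ndarray:
    areas = np.exp(latent_log)
    percent = 100.0 * areas / areas.sum(axis=1, keepdims=True)
    return percent @ weights


def _realized_effects(
    base_log: np.ndarray,
    shift_a: np.ndarray,
    shift_b: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """INT-scale mean difference per trait between two shifted states.

    The same latent draws are evaluated under both shifts (common random
    numbers), pooled, rank-inverse-normal transformed per trait, and the
    group mean difference (state b − state a) returned.
    """
    ta = _traits_from_log(base_log + shift_a, weights)
    tb = _traits_from_log(base_log + shift_b, weights)
    m = ta.shape[0]
    out = np.zeros(weights.shape[1])
    for j in range(weights.shape[1]):
        pooled = np.concatenate([ta[:, j], tb[:, j]])
        if np.ptp(pooled) == 0:
            out[j] = 0.0
            continue
        z = inverse_normal_transform(pooled)
        out[j] = z[m:].mean() - z[:m].mean()
    return out


class _ClusteredMeasure:
    """Emulates the pipeline's measurement estimand on pseudo-centers.

    The analysis rank-normalizes each center's samples pooled across time
    points, so the group difference it estimates is defined on a pooled
    INT scale of *clustered* longitudinal data (each subject contributes
    2–3 correlated samples). For skewed traits this estimand at a finite
    center size exceeds the independent-draws population value — a
    subject's own nearby samples widen the rank distance between their
    time points — so effects are calibrated against this clustered
    measurement at the configured subjects-per-center, averaged over many
    pseudo-centers with common random numbers.
    """

    def __init__(self, config, log_base, loadings, weights, rng):
        S = config.subjects_per_center
        self.P = max(30, min(250, config.calibration_draws // max(3 * S, 1)))
        self.S = S
        self.n3 = max(2, S - int(round(config.dropout_fraction_after_T2 * S)))
        self.weights = weights
        shape = (self.P, S, N_PEAKS)
        age = np.clip(rng.normal(config.age_mean, config.age_sd, (self.P, S)), 20, 65)
        sex = (rng.random((self.P, S)) < config.sex_prob).astype(float)
        bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, (self.P, S)), 27, 55)
        cov = (
            (age - config.age_mean)[..., None] * loadings["age"].to_numpy()
            + (sex - config.sex_prob)[..., None] * loadings["sex"].to_numpy()
            + (bmi - config.bmi_mean)[..., None] * loadings["bmi"].to_numpy()
        )
        self.base = (
            log_base
            + rng.normal(0.0, config.subject_intercept_sd, shape)
            + cov
        )
        self.resid = rng.normal(0.0, config.residual_sd, (3,) + shape)

    def null_trait_std(self) -> np.ndarray:
        traits = _traits_from_log(
            (self.base + self.resid[0]).reshape(-1, N_PEAKS), self.weights
        )
        return traits.std(axis=0)

    def measure(self, shift2: np.ndarray, shift3: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mean INT differences (T2−T1, T3−T2) per trait, averaged over
        pseudo-centers; T3 holds only the non-dropout subjects."""
        t1 = _traits_from_log(
            (self.base + self.resid[0]).reshape(-1, N_PEAKS), self.weights
        ).reshape(self.P, self.S, -1)
        t2 = _traits_from_log(
            (self.base + self.resid[1] + shift2).reshape(-1, N_PEAKS), self.weights
        ).reshape(self.P, self.S, -1)
        t3 = _traits_from_log(
            (self.base[:, : self.n3] + self.resid[2][:, : self.n3] + shift3).reshape(
                -1, N_PEAKS
            ),
            self.weights,
        ).reshape(self.P, self.n3, -1)
        n_traits = self.weights.shape[1]
        d12 = np.zeros(n_traits)
        d23 = np.zeros(n_traits)
        S, n3 = self.S, self.n3
        for p in range(self.P):
            pooled = np.concatenate([t1[p], t2[p], t3[p]], axis=0)
            spread = np.ptp(pooled, axis=0)
            ranks = rankdata(pooled, method="average", axis=0)
            z = ndtri((ranks - 0.5) / pooled.shape[0])
            keep = spread > 0
            d12[keep] += z[S : 2 * S, keep].mean(axis=0) - z[:S, keep].mean(axis=0)
            d23[keep] += (
                z[2 * S :, keep].mean(axis=0) - z[S : S + n3, keep].mean(axis=0)
            )
        return d12 / self.P, d23 / self.P


def _solve_shift(
    targets: np.ndarray,
    realized_at,
    null_std: np.ndarray,
    n_traits: int,
    max_iter: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trait latent shift whose measured trait effects match ``targets``
    (0 entries stay exactly 0). ``realized_at(kappa)`` returns the measured
    effect per trait. Returns (kappa per trait, realized at the solution)."""
    active = np.flatnonzero(targets != 0.0)
    kappa = np.zeros(n_traits)
    if active.size == 0:
        return kappa, realized_at(kappa)
    if np.any(null_std[active] < 1e-9):
        raise ConfigurationError(
            "cannot inject trait effects into a zero-variance (noise-free) cohort"
        )

    # Initialize by linearizing the coupled trait response around zero:
    # probe each active trait with a small lone shift, solve the resulting
    # linear system jointly. A per-trait init would ignore family overlap
    # (e.g. G3 within HB) and start deep in the saturated rank regime.
    h0 = 0.05
    jac0 = np.zeros((active.size, active.size))
    for c, j in enumerate(active):
        probe = np.zeros(n_traits)
        probe[j] = h0
        jac0[:, c] = realized_at(probe)[active] / h0

    def damped_solve(jac: np.ndarray, gap: np.ndarray) -> np.ndarray:
        # Tikhonov-damped normal equations: closure makes some target
        # combinations (e.g. HB vs G3+G4) exactly dependent, so an
        # undamped least-squares step explodes along near-null directions
        jtj = jac.T @ jac
        lam = 1e-2 * np.trace(jtj) / max(len(jtj), 1)
        return np.linalg.solve(jtj + lam * np.eye(len(jtj)), jac.T @ gap)

    kappa[active] = damped_solve(jac0, targets[active])

    # Traits are compositionally coupled (raising one family's peaks
    # depresses every other share) and complementary targets (e.g. LB up,
    # HB down) make the Jacobian nearly singular, so a plain Newton or
    # diagonal update oscillates/diverges. Use a least-squares Newton step
    # with backtracking and a hard cap on the latent shift magnitude.
    cap = 1.5  # |log-scale shift| beyond this is outside any plausible regime
    realized = realized_at(kappa)
    gap = targets[active] - realized[active]
    tol = 5e-3 * max(np.max(np.abs(targets[active])), 1e-9)
    jac = jac0  # linearization at the origin is accurate for modest effects
    for it in range(max_iter):
        if np.max(np.abs(gap)) < tol:
            break
        if it == 3:  # one refresh near the solution
            jac = np.zeros((active.size, active.size))
            h = np.maximum(0.25 * np.abs(kappa[active]), 1e-3)
            for c, j in enumerate(active):
                kp = kappa.copy()
                kp[j] += h[c]
                jac[:, c] = (realized_at(kp)[active] - realized[active]) / h[c]
        step = damped_solve(jac, gap)
        # backtracking: accept the largest scale that reduces the residual
        best = None
        for scale in (1.0, 0.5, 0.25, 0.1):
            trial = kappa.copy()
            trial[active] = np.clip(kappa[active] + scale * step, -cap, cap)
            r_trial = realized_at(trial)
            g_trial = targets[active] - r_trial[active]
            if best is None or np.max(np.abs(g_trial)) < best[0]:
                best = (np.max(np.abs(g_trial)), trial, r_trial, g_trial)
            if np.max(np.abs(g_trial)) < np.max(np.abs(gap)):
                break
        if best[0] >= np.max(np.abs(gap)) - 1e-12:
            kappa, realized, gap = best[1], best[2], best[3]
            break  # no progress possible; accept best point found
        kappa, realized, gap = best[1], best[2], best[3]
    return kappa, realized


# ---------------------------------------------------------------------------
# plate assignment
# ---------------------------------------------------------------------------

def assign_plates(
    annotation: pd.DataFrame, config: SimulationConfig, seed: int
) -> pd.DataFrame:
    """Block-randomize study samples across plates and add QC rows.

    Study samples are shuffled and dealt round-robin into plates (balanced
    fill, at most ``samples_per_plate`` per plate). Each plate then receives
    the configured within-plate and cross-plate technical replicates and
    plasma standards; replicate rows record their source sample in a
    ``source_sample_id`` column.
    """
    rng = np.random.default_rng(seed)
    study = annotation[annotation["role"].fillna("study") == "study"].copy()
    n_study = len(study)
    n_plates = config.n_plates or int(np.ceil(n_study / config.samples_per_plate))
    capacity = n_plates * config.samples_per_plate
    if n_study > capacity:
        raise ValidationError(
            f"plate capacity overflow: {n_study} study samples > "
            f"{n_plates} plates × {config.samples_per_plate}"
        )
    order = rng.permutation(n_study)
    plate_ids = np.arange(1, n_plates + 1)
    study = study.iloc[order].reset_index(drop=True)
    study["plate"] = np.resize(plate_ids, n_study)
    study["source_sample_id"] = ""

    qc_rows = []
    by_plate = {p: study.loc[study["plate"] == p, "sample_id"].tolist() for p in plate_ids}
    for p in plate_ids:
        own = by_plate[p]
        others = [s for q in plate_ids if q != p for s in by_plate[q]]
        n_within = min(config.replicates_within_per_plate, len(own))
        n_cross = min(config.replicates_cross_per_plate, len(others))
        within = rng.choice(own, size=n_within, replace=False) if n_within else []
        cross = rng.choice(others, size=n_cross, replace=False) if n_cross else []
        for k, src in enumerate(list(within) + list(cross)):
            qc_rows.append(
                {"sample_id": f"rep_P{p:02d}_{k + 1:02d}", "plate": p,
                 "role": "replicate", "source_sample_id": src}
            )
        for k in range(config.standards_per_plate):
            qc_rows.append(
                {"sample_id": f"std_P{p:02d}_{k + 1:02d}", "plate": p,
                 "role": "standard", "source_sample_id": ""}
            )
    out = pd.concat([study, pd.DataFrame(qc_rows)], ignore_index=True)
    return validate_annotation(out, centers=config.centers)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[GlycanPeakMatrix, pd.DataFrame, CohortTruth]:
    """Generate one cohort: raw peak areas, annotation, and the truth record.

    Per subject i, peak g, time t the latent natural-log abundance is

        z_igt = log(baseline_g) + u_ig + covariate loadings · covariates_i
                + kappa_g(t) [+ arm interaction at T3]

    with u_ig ~ N(0, subject_intercept_sd²). Measured log areas add a
    per-sample intensity factor, the plate's per-peak location effect
    gamma_bg ~ N(0, batch_effect_sd_location²), and residual noise with sd
    residual_sd · d_b where log d_b ~ N(0, batch_effect_sd_scale²).
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    defs = TraitDefinitionTable.default()
    weights = defs.weight_matrix().to_numpy()  # 39 × 16
    trait_list = list(defs.trait_codes)
    baseline = np.asarray(config.baseline_composition, dtype=float)
    baseline = 100.0 * baseline / baseline.sum()
    log_base = np.log(baseline)

    # ---- subjects -------------------------------------------------------
    records = []
    for center in config.centers:
        for i in range(config.subjects_per_center):
            records.append(
                {
                    "subject_id": f"{center[:3].upper()}{i + 1:04d}",
                    "center": center,
                    "age": float(np.clip(rng.normal(config.age_mean, config.age_sd), 20, 65)),
                    "sex": int(rng.random() < config.sex_prob),
                    "bmi": float(np.clip(rng.normal(config.bmi_mean, config.bmi_sd), 27, 55)),
                }
            )
    subjects = pd.DataFrame(records)
    n_subj = len(subjects)
    n_drop = int(round(config.dropout_fraction_after_T2 * config.subjects_per_center))
    dropout = np.zeros(n_subj, dtype=bool)
    arms = np.array(["none"] * n_subj, dtype=object)
    arm_levels = ["LP/LGI", "LP/HGI", "HP/LGI", "HP/HGI", "control"]
    for center in config.centers:
        idx = np.flatnonzero((subjects["center"] == center).to_numpy())
        dropped = rng.choice(idx, size=n_drop, replace=False) if n_drop else []
        dropout[dropped] = True
        completers = [j for j in idx if not dropout[j]]
        # block randomization within center: repeat the arm block, shuffle
        blocks = np.resize(arm_levels, len(completers))
        arms[np.array(completers, dtype=int)] = rng.permutation(blocks)
    subjects["dropout_after_T2"] = dropout
    subjects["diet_arm"] = arms

    u = rng.normal(0.0, config.subject_intercept_sd, size=(n_subj, N_PEAKS))
    loadings = pd.DataFrame(
        {
            "age": rng.normal(0.0, config.age_loading_sd, N_PEAKS),
            "sex": rng.normal(0.0, config.sex_loading_sd, N_PEAKS),
            "bmi": rng.normal(0.0, config.bmi_loading_sd, N_PEAKS),
        },
        index=list(GP_COLUMNS),
    )

    # ---- effect-size calibration (common random numbers, seed-derived) --
    targets1 = np.array(
        [config.trait_time_effects.get((t, "T1T2"), 0.0) for t in trait_list]
    )
    targets2 = np.array(
        [config.trait_time_effects.get((t, "T2T3"), 0.0) for t in trait_list]
    )
    n_traits = len(trait_list)
    if targets1.any() or targets2.any():
        cal_rng = np.random.default_rng(config.seed + 101)
        bank = _ClusteredMeasure(config, log_base, loadings, weights, cal_rng)
        null_std = bank.null_trait_std()
        kappa1, _ = _solve_shift(
            targets1,
            lambda k: bank.measure(weights @ k, weights @ k)[0],
            null_std,
            n_traits,
        )
        shift_t2 = weights @ kappa1
        kappa2, _ = _solve_shift(
            targets2,
            lambda k: bank.measure(shift_t2, shift_t2 + weights @ k)[1],
            null_std,
            n_traits,
        )
        shift_t3 = shift_t2 + weights @ kappa2
        realized1, realized2 = bank.measure(shift_t2, shift_t3)
    else:
        kappa1 = kappa2 = np.zeros(n_traits)
        realized1 = realized2 = np.zeros(n_traits)
        shift_t2 = np.zeros(N_PEAKS)
        shift_t3 = np.zeros(N_PEAKS)

    peak_shifts = pd.DataFrame(
        {"T1T2": weights @ kappa1, "T2T3": weights @ kappa2}, index=list(GP_COLUMNS)
    )
    realized = pd.DataFrame(
        {"T1T2": realized1, "T2T3": realized2}, index=trait_list
    )

    # ---- annotation skeleton (study samples) ----------------------------
    rows = []
    for j, rec in enumerate(subjects.itertuples(index=False)):
        tps = ["T1", "T2"] + ([] if rec.dropout_after_T2 else ["T3"])
        for tp in tps:
            rows.append(
                {
                    "sample_id": f"{rec.subject_id}_{tp}",
                    "subject_id": rec.subject_id,
                    "center": rec.center,
                    "time_point": tp,
                    "age": rec.age,
                    "sex": rec.sex,
                    "bmi": rec.bmi,
                    "diet_arm": rec.diet_arm if (tp != "T1" and rec.diet_arm != "none") else "none",
                    "role": "study",
                }
            )
    annotation = pd.DataFrame(rows)
    annotation = assign_plates(annotation, config, seed=int(rng.integers(2**31)))

    # ---- plate effects --------------------------------------------------
    plate_ids = sorted(annotation["plate"].dropna().astype(int).unique())
    gamma = rng.normal(
        0.0, config.batch_effect_sd_location, size=(len(plate_ids), N_PEAKS)
    )
    d_scale = np.exp(rng.normal(0.0, config.batch_effect_sd_scale, len(plate_ids)))
    gamma_df = pd.DataFrame(gamma, index=plate_ids, columns=list(GP_COLUMNS))
    d_series = pd.Series(d_scale, index=plate_ids)

    # ---- arm interaction shifts at T3 (optional) ------------------------
    arm_shift: dict[str, np.ndarray] = {}
    if config.diet_arm_effects:
        arm_targets: dict[str, np.ndarray] = {}
        for (trait, arm), eff in config.diet_arm_effects.items():
            arm_targets.setdefault(arm, np.zeros(n_traits))
            arm_targets[arm][trait_list.index(trait)] = eff
        arm_rng = np.random.default_rng(config.seed + 211)
        m = config.calibration_draws
        cal_base = (
            log_base
            + arm_rng.normal(0.0, config.subject_intercept_sd, (m, N_PEAKS))
            + arm_rng.normal(0.0, config.residual_sd, (m, N_PEAKS))
        )
        arm_null_std = _traits_from_log(cal_base + shift_t3, weights).std(axis=0)
        for arm, tvec in arm_targets.items():
            kap_arm, _ = _solve_shift(
                tvec,
                lambda k: _realized_effects(
                    cal_base, shift_t3, shift_t3 + weights @ k, weights
                ),
                arm_null_std,
                n_traits,
            )
            arm_shift[arm] = weights @ kap_arm

    # ---- measured values ------------------------------------------------
    subj_index = {s: j for j, s in enumerate(subjects["subject_id"])}
    cov_contrib = (
        np.outer(subjects["age"] - config.age_mean, loadings["age"])
        + np.outer(subjects["sex"] - config.sex_prob, loadings["sex"])
        + np.outer(subjects["bmi"] - config.bmi_mean, loadings["bmi"])
    )
    time_shift = {"T1": np.zeros(N_PEAKS), "T2": shift_t2, "T3": shift_t3}
    standard_profile = log_base.copy()

    replicate_sources = {}
    latent = np.zeros((len(annotation), N_PEAKS))
    study_latent: dict[str, np.ndarray] = {}
    for pos, rec in enumerate(annotation.itertuples(index=False)):
        if rec.role == "study":
            j = subj_index[rec.subject_id]
            z = log_base + u[j] + cov_contrib[j] + time_shift[rec.time_point]
            if (
                rec.time_point == "T3"
                and arm_shift
                and rec.diet_arm in arm_shift
            ):
                z = z + arm_shift[rec.diet_arm]
            study_latent[rec.sample_id] = z
            latent[pos] = z
    for pos, rec in enumerate(annotation.itertuples(index=False)):
        if rec.role == "replicate":
            src = getattr(rec, "source_sample_id")
            replicate_sources[rec.sample_id] = src
            latent[pos] = study_latent[src]
        elif rec.role == "standard":
            latent[pos] = standard_profile

    plates = annotation["plate"].astype(int).to_numpy()
    plate_pos = {p: i for i, p in enumerate(plate_ids)}
    gamma_rows = gamma[[plate_pos[p] for p in plates]]
    resid_sd = config.residual_sd * d_scale[[plate_pos[p] for p in plates]]
    noise = rng.normal(0.0, 1.0, size=latent.shape) * resid_sd[:, None]
    intensity = rng.normal(0.0, config.sample_intensity_sd, len(annotation))
    log_areas = latent + gamma_rows + noise + intensity[:, None]

    raw = GlycanPeakMatrix(
        pd.DataFrame(
            np.exp(log_areas),
            index=pd.Index(annotation["sample_id"], name="sample_id"),
            columns=list(GP_COLUMNS),
        ),
        "raw",
    )
    truth = CohortTruth(
        config=config,
        subjects=subjects,
        subject_intercepts=pd.DataFrame(
            u, index=subjects["subject_id"], columns=list(GP_COLUMNS)
        ),
        plate_location_effects=gamma_df,
        plate_scale_factors=d_series,
        covariate_loadings=loadings,
        peak_time_shifts=peak_shifts,
        nominal_effects=dict(config.trait_time_effects),
        realized_effects=realized,
        replicate_sources=replicate_sources,
        standard_profile=standard_profile,
    )
    return raw, annotation, truth
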