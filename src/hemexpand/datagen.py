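"""Seeded synthetic ICU cohort generator.

Emulates the structure of a credentialed critical-care extract for an
intracerebral-hemorrhage cohort so that the whole prediction stack can be
exercised without any data download: long-format chart/lab event tables, a
demographics table, per-patient ground-truth volume processes, and expansion
labels. Defaults reflect the study conditions the package is designed
around: 947 patients, 28 clinical features, 72 h records at hourly sampling,
and an expansion prevalence of 0.32.

The true mean trajectory is driven by the standardized INR and systolic
blood pressure series (coagulopathy and hypertension being the canonical
clinical drivers of hematoma growth); an intercept is calibrated by root
finding so the analytic expansion probability averages to the requested
prevalence. Realized volumes are independent Gaussian draws around the true
mean at each grid point, and the label marks whether any realized volume in
the prediction window reaches the patient's expansion threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import erfc

from .crossing import TimeGrid, expansion_threshold
from .schema import DEFAULT_SCHEMA, SCHEMA_BY_NAME, SIGNAL_FEATURES, FeatureDef

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "CohortTruth",
    "simulate_cohort",
    "inject_noise",
    "split_cohort",
    "recovery_spec",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    pass


# (mean, sd, AR(1) rho, circadian amplitude) of each dynamic continuous series
DYNAMIC_PARAMS: Dict[str, tuple] = {
    "heart_rate": (82.0, 14.0, 0.90, 5.0),
    "sbp": (148.0, 18.0, 0.85, 8.0),
    "dbp": (82.0, 12.0, 0.85, 4.0),
    "map": (104.0, 13.0, 0.85, 5.0),
    "resp_rate": (18.0, 4.0, 0.80, 1.5),
    "spo2": (96.5, 1.8, 0.80, 0.5),
    "temperature": (37.0, 0.5, 0.90, 0.3),
    "gcs": (11.0, 2.5, 0.95, 0.0),
    "pt": (14.5, 3.0, 0.97, 0.0),
    "inr": (1.25, 0.35, 0.97, 0.0),
    "aptt": (32.0, 8.0, 0.97, 0.0),
    "platelets": (230.0, 60.0, 0.98, 0.0),
    "fibrinogen": (350.0, 90.0, 0.98, 0.0),
    "wbc": (9.5, 3.0, 0.97, 0.0),
    "hemoglobin": (12.5, 1.8, 0.98, 0.0),
    "glucose": (135.0, 35.0, 0.90, 6.0),
    "creatinine": (1.0, 0.4, 0.98, 0.0),
    "sodium": (139.0, 4.0, 0.97, 0.0),
}

# hourly probability a value goes unrecorded; spans all three imputation tiers
DEFAULT_MISSINGNESS: Dict[str, float] = {
    "heart_rate": 0.02,
    "sbp": 0.02,
    "dbp": 0.02,
    "map": 0.03,
    "resp_rate": 0.02,
    "spo2": 0.02,
    "temperature": 0.03,
    "gcs": 0.05,
    "pt": 0.08,
    "inr": 0.08,
    "aptt": 0.15,
    "platelets": 0.08,
    "fibrinogen": 0.30,
    "wbc": 0.06,
    "hemoglobin": 0.06,
    "glucose": 0.04,
    "creatinine": 0.04,
    "sodium": 0.04,
}

CATEGORICAL_PROBS = {
    "gender": (0.45, 0.55),
    "admission_type": (0.70, 0.20, 0.10),
    "insurance": (0.60, 0.40),
    "marital_status": (0.50, 0.30, 0.20),
    "language": (0.90, 0.10),
}

AGE_MEAN, AGE_SD = 62.0, 13.0
LOG_V0_MEAN, LOG_V0_SD = 2.9, 0.5  # baseline volume ~ lognormal, median ~18 ml

# growth-model effect sizes (ml per SD of the driving series)
LINEAR_EFFECTS = (6.0, 5.0)  # inr, sbp
SMOOTH_EFFECTS = (2.0, 2.0)
SMOOTH_GAIN = (0.9, 0.6)  # patient-level gain on mean INR / mean SBP
VARIANCE_LOGLINEAR = (np.log(6.0), 0.5, 0.25)  # gamma0, mean-INR, mean-SBP slopes
VARIANCE_CLIP = (0.5, 100.0)

MED_PARAMS = {  # (probability of use, mean duration hours)
    "antihypertensive": (0.6, 30.0),
    "mannitol": (0.35, 18.0),
    "anticoagulant_reversal": (0.2, 10.0),
    "sedative": (0.45, 24.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a simulated cohort."""

    n_patients: int = 947
    n_features: int = 28
    duration: float = 72.0  # hours of record
    sampling: float = 1.0  # hours between grid points
    horizon: float = 24.0  # prediction / labeling window (hours)
    expansion_rate: float = 0.32
    mean_model: str = "smooth"  # 'smooth' | 'linear'
    variance_model: str = "loglinear"  # 'loglinear' | 'constant'
    constant_variance: float = 4.0  # ml^2, used by variance_model='constant'
    missingness_plan: Optional[Dict[str, float]] = None
    include_events: bool = True
    seed: int = 0
    # overrides for controlled experiments: fixed effect sizes (ml per SD of
    # the two driving series) and a fixed growth intercept that bypasses the
    # prevalence calibration
    mean_effects: Optional[tuple] = None
    growth_intercept: Optional[float] = None

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not 0.0 < self.expansion_rate < 1.0:
            raise ConfigurationError("expansion_rate must be in (0, 1)")
        if self.sampling <= 0 or self.duration <= 0 or self.horizon <= 0:
            raise ConfigurationError("duration, sampling and horizon must be > 0")
        if self.horizon > self.duration:
            raise ConfigurationError("horizon cannot exceed duration")
        if self.mean_model not in ("smooth", "linear"):
            raise ConfigurationError("mean_model must be 'smooth' or 'linear'")
        if self.variance_model not in ("loglinear", "constant"):
            raise ConfigurationError("variance_model must be 'loglinear' or 'constant'")
        if self.constant_variance <= 0:
            raise ConfigurationError("constant_variance must be > 0")
        plan = self.missingness_plan or {}
        if any(not 0.0 <= r < 1.0 for r in plan.values()):
            raise ConfigurationError("missingness rates must be in [0, 1)")
        names = [f.name for f in self.features()]
        for sig in SIGNAL_FEATURES:
            if sig not in names:
                raise ConfigurationError(
                    f"feature roster must retain the signal series {sig!r}; "
                    "increase n_features"
                )

    @property
    def n_times(self) -> int:
        return int(round(self.duration / self.sampling))

    @property
    def n_horizon(self) -> int:
        return int(round(self.horizon / self.sampling))

    def features(self) -> list[FeatureDef]:
        """Feature roster: first n_features of the default schema, padded with
        auxiliary noise series when more than 28 are requested."""
        roster = list(DEFAULT_SCHEMA[: self.n_features])
        for k in range(len(DEFAULT_SCHEMA), self.n_features):
            roster.append(FeatureDef(f"aux_{k - len(DEFAULT_SCHEMA)}", "continuous"))
        return roster

    def missing_rate(self, name: str) -> float:
        plan = DEFAULT_MISSINGNESS if self.missingness_plan is None else self.missingness_plan
        return float(plan.get(name, 0.0))


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth per patient: the volume process, threshold and label."""

    grid: TimeGrid
    v0: np.ndarray  # (n,) baseline volume, ml
    threshold: np.ndarray  # (n,) expansion threshold c, ml
    mean: np.ndarray  # (n, T) true M(t), ml
    variance: np.ndarray  # (n, T) true Sigma(t), ml^2
    volumes: np.ndarray  # (n, T) realized V(t_i)
    label: np.ndarray  # (n,) bool, expansion within the horizon
    n_horizon: int
    expected_prevalence: float


@dataclass(frozen=True)
class SyntheticCohort:
    spec: CohortSpec
    subject_ids: np.ndarray
    demographics: pd.DataFrame
    events: Optional[pd.DataFrame]
    values: Dict[str, np.ndarray]  # clean feature values, (n,) static / (n,T) dynamic
    masks: Dict[str, np.ndarray]  # True where the hourly value went unrecorded
    truth: CohortTruth
    admit_times: pd.Series = field(repr=False, default=None)

    def recompute_labels(self) -> np.ndarray:
        """Labels re-derived from stored truth via the crossing threshold rule."""
        H = self.truth.n_horizon
        out = np.empty(self.truth.v0.size, dtype=bool)
        for j, v0 in enumerate(self.truth.v0):
            c = expansion_threshold(float(v0)).c
            out[j] = bool(np.any(self.truth.volumes[j, :H] >= c))
        return out

    def save(self, out_dir: str | Path, parquet: bool = False) -> None:
        """Write events/demographics tables, truth arrays and a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ext = "parquet" if parquet else "csv"
        writer = (lambda df, p: df.to_parquet(p)) if parquet else (
            lambda df, p: df.to_csv(p, index=False)
        )
        writer(self.demographics, out / f"demographics.{ext}")
        if self.events is not None:
            writer(self.events, out / f"events.{ext}")
        t = self.truth
        tidy = pd.DataFrame(
            {
                "subject_id": np.repeat(self.subject_ids, t.mean.shape[1]),
                "time_h": np.tile(t.grid.points, t.mean.shape[0]),
                "mean_ml": t.mean.ravel(),
                "variance_ml2": t.variance.ravel(),
                "volume_ml": t.volumes.ravel(),
            }
        )
        writer(tidy, out / f"truth.{ext}")
        per_patient = pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "v0_ml": t.v0,
                "threshold_ml": t.threshold,
                "label": t.label.astype(int),
            }
        )
        writer(per_patient, out / f"labels.{ext}")
        manifest = {
            "seed": self.spec.seed,
            "n_patients": self.spec.n_patients,
            "n_features": self.spec.n_features,
            "duration_h": self.spec.duration,
            "sampling_h": self.spec.sampling,
            "horizon_h": self.spec.horizon,
            "expansion_rate": self.spec.expansion_rate,
            "mean_model": self.spec.mean_model,
            "variance_model": self.spec.variance_model,
            "expected_prevalence": t.expected_prevalence,
            "empirical_prevalence": float(t.label.mean()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def recovery_spec(n_patients: int = 500, seed: int = 0) -> CohortSpec:
    """Cohort whose true mean is linear in the two driving series and whose
    variance is a known constant — the identifiable setting used for
    parameter-recovery checks."""
    return CohortSpec(
        n_patients=n_patients,
        mean_model="linear",
        variance_model="constant",
        constant_variance=4.0,
        seed=seed,
    )


# -- generation ------------------------------------------------------------

def _ar1(rng, n, T, rho):
    z = np.empty((n, T))
    z[:, 0] = rng.standard_normal(n)
    innov = rng.standard_normal((n, T - 1)) * np.sqrt(1.0 - rho**2)
    for t in range(1, T):
        z[:, t] = rho * z[:, t - 1] + innov[:, t - 1]
    return z


def _label_probability(mean, variance, c, H):
    """P(any of the first H independent draws >= c), per patient."""
    z = (c[:, None] - mean[:, :H]) / np.sqrt(2.0 * variance[:, :H])
    beta = 0.5 * erfc(z)
    with np.errstate(divide="ignore"):
        log_surv = np.sum(np.log1p(-np.clip(beta, 0.0, 1.0 - 1e-16)), axis=1)
    return 1.0 - np.exp(log_surv)


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort; bitwise reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n, T, H = spec.n_patients, spec.n_times, spec.n_horizon
    roster = spec.features()
    subject_ids = np.arange(10_000, 10_000 + n)

    values: Dict[str, np.ndarray] = {}
    # demographics (in roster order for rng determinism)
    for f in roster:
        if not f.static:
            continue
        if f.kind == "categorical":
            values[f.name] = rng.choice(f.categories, size=n, p=CATEGORICAL_PROBS[f.name])
        else:  # anchor_age
            values[f.name] = rng.normal(AGE_MEAN, AGE_SD, size=n)

    # dynamic continuous series
    hours = np.arange(T) * spec.sampling
    phase = rng.uniform(0, 24, size=n)
    standardized: Dict[str, np.ndarray] = {}
    for f in roster:
        if f.static or f.kind != "continuous":
            continue
        mean, sd, rho, camp = DYNAMIC_PARAMS.get(f.name, (0.0, 1.0, 0.9, 0.0))
        z = _ar1(rng, n, T, rho)
        circ = camp * np.sin(2 * np.pi * (hours[None, :] + phase[:, None]) / 24.0)
        val = mean + sd * z + circ
        values[f.name] = val
        standardized[f.name] = (val - mean) / sd

    # medication flags: one contiguous administration window when used
    for f in roster:
        if f.kind != "binary":
            continue
        p_use, mean_dur = MED_PARAMS.get(f.name, (0.3, 12.0))
        used = rng.random(n) < p_use
        start = rng.uniform(0, spec.duration, size=n)
        dur = rng.exponential(mean_dur, size=n) + 2.0
        flags = (
            used[:, None]
            & (hours[None, :] >= start[:, None])
            & (hours[None, :] < (start + dur)[:, None])
        )
        values[f.name] = flags.astype(float)

    # ground-truth volume process
    v0 = np.exp(rng.normal(LOG_V0_MEAN, LOG_V0_SD, size=n))
    c = np.array([expansion_threshold(float(v)).c for v in v0])
    z1, z2 = standardized[SIGNAL_FEATURES[0]], standardized[SIGNAL_FEATURES[1]]

    if spec.variance_model == "constant":
        variance = np.full((n, T), spec.constant_variance)
    else:
        g0, a1, a2 = VARIANCE_LOGLINEAR
        sig2 = np.exp(g0 + a1 * z1.mean(axis=1) + a2 * z2.mean(axis=1))
        variance = np.clip(sig2, *VARIANCE_CLIP)[:, None] * np.ones((1, T))

    if spec.mean_model == "linear":
        b1, b2 = spec.mean_effects if spec.mean_effects is not None else LINEAR_EFFECTS

        def mean_at(theta):
            return v0[:, None] + theta + b1 * z1 + b2 * z2

    else:
        b1, b2 = spec.mean_effects if spec.mean_effects is not None else SMOOTH_EFFECTS
        g1, g2 = SMOOTH_GAIN
        trend = 1.0 - np.exp(-hours / 12.0)
        drive = g1 * z1.mean(axis=1) + g2 * z2.mean(axis=1)

        def mean_at(theta):
            gain = np.logaddexp(0.0, theta + drive)  # softplus, >= 0 growth
            return v0[:, None] + gain[:, None] * trend[None, :] + b1 * z1 + b2 * z2

    def prevalence_gap(theta):
        return _label_probability(mean_at(theta), variance, c, H).mean() - spec.expansion_rate

    if spec.growth_intercept is not None:
        theta = float(spec.growth_intercept)
    else:
        lo, hi = (-200.0, 200.0) if spec.mean_model == "linear" else (-40.0, 60.0)
        if prevalence_gap(lo) > 0 or prevalence_gap(hi) < 0:
            raise ConfigurationError(
                "expansion_rate outside the achievable range for the chosen effect sizes"
            )
        theta = brentq(prevalence_gap, lo, hi, xtol=1e-10)
    mean = mean_at(theta)
    expected_prev = float(_label_probability(mean, variance, c, H).mean())

    volumes = rng.normal(mean, np.sqrt(variance))
    label = np.any(volumes[:, :H] >= c[:, None], axis=1)

    # unrecorded-hour masks for dynamic features
    masks: Dict[str, np.ndarray] = {}
    for f in roster:
        if f.static:
            continue
        rate = spec.missing_rate(f.name) if f.kind == "continuous" else 0.0
        masks[f.name] = rng.random((n, T)) < rate

    admit = pd.Series(
        pd.Timestamp("2120-01-01") + pd.to_timedelta(subject_ids - 10_000, unit="D"),
        index=subject_ids,
    )
    demographics = _demographics_table(subject_ids, roster, values, admit)
    events = (
        _events_table(spec, subject_ids, roster, values, masks, admit)
        if spec.include_events
        else None
    )

    grid = TimeGrid(0.0, spec.duration, T)
    truth = CohortTruth(
        grid=grid,
        v0=v0,
        threshold=c,
        mean=mean,
        variance=variance,
        volumes=volumes,
        label=label,
        n_horizon=H,
        expected_prevalence=expected_prev,
    )
    return SyntheticCohort(
        spec=spec,
        subject_ids=subject_ids,
        demographics=demographics,
        events=events,
        values=values,
        masks=masks,
        truth=truth,
        admit_times=admit,
    )


def _demographics_table(subject_ids, roster, values, admit) -> pd.DataFrame:
    data = {
        "subject_id": subject_ids,
        "hadm_id": subject_ids + 2_000_000,
        "admittime": admit.loc[subject_ids].to_numpy(),
    }
    for f in roster:
        if f.static:
            data[f.name] = values[f.name]
    return pd.DataFrame(data)


def _events_table(spec, subject_ids, roster, values, masks, admit) -> pd.DataFrame:
    """Long-format chart/lab/medication rows: one row per recorded hour."""
    n, T = spec.n_patients, spec.n_times
    frames = []
    hour_offsets = pd.to_timedelta(
        np.arange(T) * spec.sampling * 3600 + 1800, unit="s"
    )  # recorded ~half past the hour
    base = admit.loc[subject_ids].to_numpy()
    chart = (base[:, None] + hour_offsets.to_numpy()[None, :]).ravel()
    subj = np.repeat(subject_ids, T)
    for f in roster:
        if f.static:
            continue
        val = values[f.name].ravel()
        if f.kind == "binary":
            keep = val > 0  # presence rows only
        else:
            keep = ~masks[f.name].ravel()
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subj[keep],
                    "hadm_id": subj[keep] + 2_000_000,
                    "charttime": chart[keep],
                    "item": f.name,
                    "value": val[keep],
                }
            )
        )
    events = pd.concat(frames, ignore_index=True)
    return events.sort_values(["subject_id", "charttime", "item"], kind="stable").reset_index(
        drop=True
    )


def inject_noise(
    cohort: SyntheticCohort, noise_sd, seed: int
) -> SyntheticCohort:
    """Add independent Gaussian perturbations to continuous feature values.

    ``noise_sd`` is a scalar applied to every continuous feature or a
    per-feature mapping. Ground truth, labels and missingness masks are left
    untouched; events are rebuilt from the perturbed values under the same
    masks. Reproducible under ``seed``.
    """
    if np.isscalar(noise_sd):
        plan = {f.name: float(noise_sd) for f in cohort.spec.features() if f.kind == "continuous"}
    else:
        plan = {k: float(v) for k, v in dict(noise_sd).items()}
    if any(v < 0 for v in plan.values()):
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    new_values = dict(cohort.values)
    for f in cohort.spec.features():  # roster order keeps draws deterministic
        sd = plan.get(f.name, 0.0)
        if f.kind != "continuous" or sd == 0.0:
            continue
        arr = cohort.values[f.name]
        new_values[f.name] = arr + rng.normal(0.0, sd, size=arr.shape)
    events = (
        _events_table(
            cohort.spec,
            cohort.subject_ids,
            cohort.spec.features(),
            new_values,
            cohort.masks,
            cohort.admit_times,
        )
        if cohort.events is not None
        else None
    )
    return replace(cohort, values=new_values, events=events)


@dataclass(frozen=True)
class CohortSplit:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def split_cohort(
    cohort_or_ids,
    fractions: Sequence[float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> CohortSplit:
    """Subject-level random partition into train/validation/test.

    Validation and test sizes are ``round(n * f)``; the remainder goes to
    training, so 947 subjects at (0.70, 0.15, 0.15) split 663/142/142.
    """
    ids = (
        cohort_or_ids.subject_ids
        if isinstance(cohort_or_ids, SyntheticCohort)
        else np.asarray(cohort_or_ids)
    )
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("fractions must be three values summing to 1")
    n = ids.size
    n_val = round(n * fractions[1])
    n_test = round(n * fractions[2])
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ConfigurationError(f"{n} subjects cannot fill three nonempty sets")
    perm = np.random.default_rng(seed).permutation(n)
    shuffled = ids[perm]
    return CohortSplit(
        train=np.sort(shuffled[:n_train]),
        val=np.sort(shuffled[n_train : n_train + n_val]),
        test=np.sort(shuffled[n_train + n_val :]),
    )
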