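"""Synthetic survival cohorts with a log-linear proportional-hazards truth.

Disease-free survival times are drawn from an exponential model whose
individual hazard is ``exp(x . beta) / baseline_hazard_scale``; censoring
is independent exponential, with the censoring rate solved numerically so
that the expected censored fraction equals ``censoring_rate``. This gives a
cohort on which every downstream survival operation (univariate Cox
screening, LASSO-Cox selection, risk-score construction, cutpoint search,
time-dependent AUC) can be exercised with a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

CLINICAL_COVARIATES = (
    "sex",
    "age",
    "t_stage",
    "n_stage",
    "vascular_embolus",
    "lymph_nodes_dissected",
)


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of one simulated patient cohort.

    ``true_log_hr`` maps feature names to their true log hazard ratios
    (per unit of the feature); unlisted features have no effect.
    ``baseline_hazard_scale`` is the mean survival time (days) of a patient
    with all listed features at zero.
    """

    n_patients: int = 553
    slides_per_patient: int = 1
    true_log_hr: dict = field(default_factory=dict)
    baseline_hazard_scale: float = 1800.0
    censoring_rate: float = 0.566
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 20:
            raise ValueError("n_patients must be >= 20")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard_scale <= 0:
            raise ValueError("baseline_hazard_scale must be > 0")


def gaussian_features(names: list[str]) -> Callable:
    """Feature generator: independent standard-normal descriptors."""

    def gen(n: int, rng: np.random.Generator) -> pd.DataFrame:
        return pd.DataFrame(
            rng.standard_normal((n, len(names))), columns=list(names)
        )

    return gen


def clinical_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic clinical covariates shaped like a resected-NSCLC cohort."""
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, n),  # 1 = male
            "age": np.clip(rng.normal(60, 11, n), 30, 90),
            "t_stage": rng.choice([1, 2, 3, 4], n, p=[0.43, 0.34, 0.15, 0.08]),
            "n_stage": rng.choice([0, 1, 2], n, p=[0.63, 0.14, 0.23]),
            "vascular_embolus": rng.integers(0, 2, n),
            "lymph_nodes_dissected": np.clip(
                rng.normal(20, 11, n), 0, None
            ).round(),
        }
    )


def _censoring_hazard(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_i c/(c+h_i) = target."""
    if target <= 0:
        return 0.0

    def frac(log_c):
        c = np.exp(log_c)
        return float(np.mean(c / (c + hazards))) - target

    lo, hi = np.log(hazards.min()) - 20, np.log(hazards.max()) + 20
    return float(np.exp(brentq(frac, lo, hi)))


def simulate_cohort(
    spec: CohortSpec, feature_generator: Callable | None = None
) -> pd.DataFrame:
    """Simulate a patient table with DFS times, events, covariates, features.

    Returns a DataFrame with ``patient_id``, ``time_days``, ``event``, the
    clinical covariates, and one column per generated feature. Fully
    reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    covars = clinical_covariates(n, rng)
    if feature_generator is not None:
        feats = feature_generator(n, rng)
        if feats.shape[0] != n:
            raise ValueError("feature_generator returned wrong row count")
    else:
        feats = pd.DataFrame(index=range(n))
    table = pd.concat([covars, feats], axis=1)

    missing = [k for k in spec.true_log_hr if k not in table.columns]
    if missing:
        raise ValueError(f"true_log_hr names not in generated features: {missing}")

    lp = np.zeros(n)
    for name, beta in spec.true_log_hr.items():
        lp += beta * table[name].to_numpy(dtype=float)
    hazards = np.exp(lp) / spec.baseline_hazard_scale
    event_times = rng.exponential(1.0 / hazards)

    if spec.censoring_rate > 0:
        c = _censoring_hazard(hazards, spec.censoring_rate)
        censor_times = rng.exponential(1.0 / c, size=n)
        time = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    else:
        time, event = event_times, np.ones(n, dtype=int)

    out = pd.DataFrame({"patient_id": np.arange(n), "time_days": time, "event": event})
    return pd.concat([out, table], axis=1)


def make_irrs_study_cohort(
    n_patients: int = 553,
    n_candidates: int = 35,
    n_true: int = 10,
    effect_range: tuple[float, float] = (0.4, 1.0),
    censoring_rate: float = 0.566,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """A study-scale cohort for risk-score construction and validation.

    ``n_candidates`` standardized quantitative/spatial descriptors, of which
    ``n_true`` carry true log hazard ratios with magnitudes drawn uniformly
    from ``effect_range`` and alternating sign; the censoring rate targets
    the ~43% event fraction of a resected early-stage NSCLC cohort.

    Returns ``(patients, true_log_hr)``.
    """
    rng = np.random.default_rng(seed)
    names = [f"feat_{i:02d}" for i in range(n_candidates)]
    mags = rng.uniform(*effect_range, size=n_true)
    signs = np.where(np.arange(n_true) % 2 == 0, 1.0, -1.0)
    true_idx = rng.choice(n_candidates, size=n_true, replace=False)
    true_log_hr = {
        names[i]: float(m * s) for i, m, s in zip(sorted(true_idx), mags, signs)
    }
    spec = CohortSpec(
        n_patients=n_patients,
        true_log_hr=true_log_hr,
        censoring_rate=censoring_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    patients = simulate_cohort(spec, gaussian_features(names))
    return patients, true_log_hr
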