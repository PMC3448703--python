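"""Synthetic aging cohort with a piecewise-linear age trend in foci/cell.

Emulates the statistical structure of a 40-participant leukapheresis cohort
(ages 35-83, 26 men / 14 women): each patient's expected foci/cell follows a
hinge (change-point) model in age,

    mu(age) = b0 + beta1*age + delta*max(0, age - tau) + sum_d gamma_d*flag_d,

with a patient-level Gaussian residual and per-cell Poisson counts averaged
over the cells scored for that patient.  Disease subgroups of fixed size
(e.g. 15/40 hypertensive) receive additive mean shifts.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# Change-point model anchors: first-segment slope 0.176 foci/cell/year,
# slope change -0.217 at tau = 57 y; intercept set so the model predicts
# 4.89 foci/cell at the midpoint of the 50-59 decade.
DEFAULT_SLOPE1 = 0.176
DEFAULT_SLOPE_CHANGE = -0.217
DEFAULT_CHANGE_POINT = 57.0
DEFAULT_INTERCEPT = 4.89 - DEFAULT_SLOPE1 * 54.5

# Residual SD anchored to the cohort's overall dispersion: all-patient SEM
# 0.28 at n=40 gives a total SD of ~1.77; subtracting the systematic variance
# of the hinge model under uniform ages 35-83 (~1.11) leaves sd ~1.42.
DEFAULT_RESIDUAL_SD = 1.42


@dataclass(frozen=True)
class DiseaseSpec:
    """One binary condition: fixed count or prevalence, additive mean effect."""

    name: str
    n_affected: int | None = None
    prevalence: float | None = None
    effect: float = 0.0

    def validate(self, n_patients: int) -> None:
        if (self.n_affected is None) == (self.prevalence is None):
            raise ValueError(
                f"{self.name}: give exactly one of n_affected or prevalence")
        if self.n_affected is not None and not 0 <= self.n_affected <= n_patients:
            raise ValueError(f"{self.name}: n_affected out of range")
        if self.prevalence is not None and not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"{self.name}: prevalence out of range")


def default_disease_specs() -> tuple[DiseaseSpec, ...]:
    """Subgroup sizes of the emulated cohort with effects set from the
    printed with/without group-mean differences (0 for the null conditions)."""
    return (
        DiseaseSpec("hypertension", n_affected=15, effect=1.16),
        DiseaseSpec("vitamin_d_deficiency", n_affected=5, effect=1.99),
        DiseaseSpec("cataracts", n_affected=4, effect=1.40),
        DiseaseSpec("sleep_apnea", n_affected=3, effect=1.77),
        DiseaseSpec("irradiation_treatment", n_affected=2, effect=1.89),
        DiseaseSpec("benign_prostatic_hyperplasia", n_affected=7, effect=0.0),
        DiseaseSpec("any_cancer", n_affected=8, effect=0.0),
    )


@dataclass(frozen=True)
class CohortSimParams:
    n_patients: int = 40
    age_range: tuple[float, float] = (35.0, 83.0)
    male_fraction: float = 26 / 40
    intercept: float = DEFAULT_INTERCEPT
    slope1: float = DEFAULT_SLOPE1
    slope_change: float = DEFAULT_SLOPE_CHANGE
    change_point: float = DEFAULT_CHANGE_POINT
    disease_specs: tuple[DiseaseSpec, ...] = ()
    residual_sd: float = DEFAULT_RESIDUAL_SD
    cells_per_patient_range: tuple[int, int] = (120, 400)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range low must be < high")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        lo, hi = self.cells_per_patient_range
        if lo <= 0 or hi < lo:
            raise ValueError("cells_per_patient_range must be positive, lo<=hi")
        for spec in self.disease_specs:
            spec.validate(self.n_patients)

    def systematic_mean(self, ages: np.ndarray) -> np.ndarray:
        """Hinge-model mean foci/cell at the given ages (no disease terms)."""
        ages = np.asarray(ages, dtype=float)
        return (self.intercept + self.slope1 * ages
                + self.slope_change * np.maximum(0.0, ages - self.change_point))


def simulate_cohort(params: CohortSimParams,
                    ages: np.ndarray | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort table.

    Ages are uniform on ``age_range`` unless an explicit age vector is given.
    Sex is assigned as a fixed count of men (round(male_fraction*n)).  Each
    patient's observed value is the average of per-cell Poisson counts around
    the patient's latent mean (systematic + disease effects + Gaussian
    residual), clipped at zero because counts cannot be negative.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    if ages is None:
        ages = rng.uniform(*params.age_range, n)
    else:
        ages = np.asarray(ages, dtype=float)
        if ages.shape != (n,):
            raise ValueError("explicit age vector must have length n_patients")

    n_male = int(round(params.male_fraction * n))
    sex = np.array(["M"] * n_male + ["F"] * (n - n_male))
    rng.shuffle(sex)

    flags: dict[str, np.ndarray] = {}
    for spec in params.disease_specs:
        col = np.zeros(n, dtype=int)
        if spec.n_affected is not None:
            col[rng.choice(n, size=spec.n_affected, replace=False)] = 1
        else:
            col = (rng.random(n) < spec.prevalence).astype(int)
        flags[spec.name] = col

    true_mean = params.systematic_mean(ages)
    for spec in params.disease_specs:
        true_mean = true_mean + spec.effect * flags[spec.name]
    latent = true_mean + rng.normal(0.0, params.residual_sd, n)
    if np.any(latent < 0):
        warnings.warn("negative latent patient means clipped at 0",
                      stacklevel=2)
    latent = np.maximum(latent, 0.0)

    lo, hi = params.cells_per_patient_range
    n_cells = rng.integers(lo, hi + 1, n)
    obs_mean = np.empty(n)
    obs_sem = np.empty(n)
    for i in range(n):
        counts = rng.poisson(latent[i], n_cells[i])
        obs_mean[i] = counts.mean()
        obs_sem[i] = counts.std(ddof=1) / math.sqrt(n_cells[i])

    df = pd.DataFrame({
        "patient_id": [f"P{i+1:03d}" for i in range(n)],
        "age": ages, "sex": sex,
        **flags,
        "true_mean": true_mean,
        "mean_foci_per_cell": obs_mean,
        "sem": obs_sem,
        "n_cells": n_cells,
    })
    return df


def calibrate_sigma(params: CohortSimParams, target_r2: float,
                    n_draws: int = 10 ** 6) -> float:
    """Residual SD giving the requested population R^2 of the systematic part.

    Solves Var(systematic) / (Var(systematic) + sigma^2) = target_r2, with
    Var(systematic) estimated by Monte Carlo over the age distribution (and
    disease-flag distribution, if any) at ``n_draws`` draws.
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must be in (0, 1)")
    rng = np.random.default_rng(12345)  # fixed: calibration is deterministic
    ages = rng.uniform(*params.age_range, n_draws)
    sys = params.systematic_mean(ages)
    for spec in params.disease_specs:
        p = (spec.n_affected / params.n_patients
             if spec.n_affected is not None else spec.prevalence)
        sys = sys + spec.effect * (rng.random(n_draws) < p)
    var_sys = float(np.var(sys))
    if var_sys <= 0:
        raise ValueError("systematic variance is zero; nothing to calibrate")
    return math.sqrt(var_sys * (1.0 - target_r2) / target_r2)


def write_cohort(df: pd.DataFrame, params: CohortSimParams,
                 csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    df.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".params.json")
    payload = dataclasses.asdict(params)
    payload["disease_specs"] = [dataclasses.asdict(s)
                                for s in params.disease_specs]
    sidecar.write_text(json.dumps(payload, indent=1))


def read_cohort(csv_path: str | Path) -> pd.DataFrame:
    return pd.read_csv(csv_path)
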