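"""Disease-subgroup comparisons of mean foci/cell across a cohort table.

For each binary condition: subgroup means +/- SEM, integer percent change of
the affected group relative to the unaffected group, and two-sided p-values
from OLS — unadjusted (equivalent to a two-sample t test) and adjusted for
age and sex.  Subset filters (e.g. restricting to patients at or above the
change-point age) reproduce the age-restricted analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .changepoint import fit_ols


class EmptyGroupError(ValueError):
    pass


def percent_change(mean_with: float, mean_without: float) -> int:
    """Signed integer percent change, rounded half away from zero.

    Decreases come out negative (tables conventionally print them in
    parentheses).
    """
    if mean_without <= 0:
        raise ValueError("mean_without must be positive")
    x = 100.0 * (mean_with - mean_without) / mean_without
    return int(math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5))


@dataclass(frozen=True)
class GroupComparison:
    disease: str
    subset: str
    adjust: str
    n_with: int
    n_without: int
    mean_with: float
    mean_without: float
    sem_with: float
    sem_without: float
    percent_change: int
    p_unadjusted: float
    p_adjusted: float


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else float("nan")


def compare_groups(table: pd.DataFrame, disease: str,
                   subset: str | None = None,
                   adjust: str = "age_sex",
                   value_col: str = "mean_foci_per_cell") -> GroupComparison:
    """Compare patients with vs without a condition.

    ``subset`` is a pandas query string (e.g. ``"age >= 57"``) applied before
    the comparison.  Both the unadjusted and the age-and-sex-adjusted
    p-values are always computed; ``adjust`` records which one the caller
    treats as primary.
    """
    if adjust not in ("none", "age_sex"):
        raise ValueError("adjust must be 'none' or 'age_sex'")
    df = table.query(subset) if subset else table
    flag = df[disease].to_numpy(dtype=float)
    y = df[value_col].to_numpy(dtype=float)
    with_v = y[flag == 1]
    without_v = y[flag == 0]
    if with_v.size == 0 or without_v.size == 0:
        raise EmptyGroupError(
            f"empty group for disease={disease!r}, subset={subset!r}")

    n = y.size
    ones = np.ones(n)
    res_u = fit_ols(np.column_stack([ones, flag]), y, ["intercept", disease])
    p_unadj = float(res_u.pvalues[1])
    if n >= 5:
        age = df["age"].to_numpy(dtype=float)
        male = (df["sex"].astype(str).str.upper() == "M").to_numpy(dtype=float)
        res_a = fit_ols(np.column_stack([ones, flag, age, male]), y,
                        ["intercept", disease, "age", "sex"])
        p_adj = float(res_a.pvalues[1])
    else:
        p_adj = float("nan")

    return GroupComparison(
        disease=disease, subset=subset or "all", adjust=adjust,
        n_with=int(with_v.size), n_without=int(without_v.size),
        mean_with=float(with_v.mean()), mean_without=float(without_v.mean()),
        sem_with=_sem(with_v), sem_without=_sem(without_v),
        percent_change=percent_change(float(with_v.mean()),
                                      float(without_v.mean())),
        p_unadjusted=p_unadj, p_adjusted=p_adj)


def comparison_table(table: pd.DataFrame, diseases: list[str],
                     subsets: list[str | None] = (None,),
                     adjust: str = "age_sex") -> pd.DataFrame:
    """One row per disease x subset, mirroring a subgroup summary table."""
    rows = []
    for subset in subsets:
        for disease in diseases:
            c = compare_groups(table, disease, subset=subset, adjust=adjust)
            rows.append(vars(c) if not hasattr(c, "__dataclass_fields__")
                        else {k: getattr(c, k)
                              for k in c.__dataclass_fields__})
    return pd.DataFrame(rows)


def top_k_flag_enrichment(table: pd.DataFrame, k: int, disease: str,
                          value_col: str = "mean_foci_per_cell"
                          ) -> tuple[int, int]:
    """How many of the k highest-foci patients carry the flag.

    Sort is by foci/cell descending, ties broken by patient id ascending.
    """
    if k > len(table):
        raise ValueError(f"k={k} exceeds cohort size {len(table)}")
    ordered = table.sort_values([value_col, "patient_id"],
                                ascending=[False, True])
    top = ordered.head(k)
    return int(top[disease].sum()), int(k)
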