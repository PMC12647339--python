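"""Scale scoring, income equivalisation and binary flag derivation.

Turns raw per-child cohort fields (household income and composition, DASS
item scores, CPRS-SF subscale sums, SDQ total, sociodemographic bands) into
the binary exposure / mediator / outcome / confounder codings used by the
mediation analysis.

Conventions
-----------
* Binary flags are float columns with ``1.0`` / ``0.0`` / ``NaN`` (missing).
* Quintile flags use a weighted empirical-CDF quantile with ties included in
  the flagged group (deterministic and conservative toward flagging).
* Quintile cut-points are estimated on the sample at hand unless explicit
  ``cutoffs`` are supplied, in which case fixed thresholds are applied (the
  mode used when cut-points were defined on a larger reference sample, e.g.
  a full survey cohort, or by a simulator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HouseholdComposition",
    "CONFOUNDERS",
    "ANALYSIS_COLUMNS",
    "oecd_equivalise",
    "equivalence_factor",
    "quintile_flag",
    "relative_poverty_flag",
    "sdq_band",
    "sdq_flag",
    "dass_flag",
    "cprs_flag",
    "derive_analysis_set",
]

#: Binary confounder columns of the analysis set, in model order.
CONFOUNDERS = [
    "low_mat_education",
    "low_mat_age",
    "mat_unemployed",
    "gt4_children",
    "one_parent",
    "ethnic_minority",
]

#: Full column set of the derived analysis table.
ANALYSIS_COLUMNS = ["child_id", "X", "M1", "M2", "Y", *CONFOUNDERS, "weight"]

# OECD-modified equivalence scale weights.
_FIRST_ADULT = 1.0
_OTHER_14_PLUS = 0.5
_CHILD_UNDER_14 = 0.3

#: SDQ total-difficulties band boundaries: normal < 14, borderline 14-16,
#: abnormal >= 17.
SDQ_BORDERLINE_CUT = 14
SDQ_ABNORMAL_CUT = 17


@dataclass(frozen=True)
class HouseholdComposition:
    """Household make-up entering the OECD-modified equivalence factor."""

    n_adults: int
    n_other_14_plus: int = 0
    n_children_under_14: int = 0

    def __post_init__(self) -> None:
        if self.n_adults < 1:
            raise ValueError("household must contain at least one adult")
        if self.n_other_14_plus < 0 or self.n_children_under_14 < 0:
            raise ValueError("household member counts must be non-negative")

    @property
    def factor(self) -> float:
        return equivalence_factor(
            self.n_adults, self.n_other_14_plus, self.n_children_under_14
        )


def equivalence_factor(n_adults, n_other_14_plus=0, n_children_under_14=0):
    """OECD-modified equivalence factor (vectorised).

    First adult counts 1.0, every additional person aged 14+ counts 0.5 and
    every child under 14 counts 0.3.
    """
    n_adults = np.asarray(n_adults, dtype=float)
    if np.any(n_adults < 1):
        raise ValueError("household must contain at least one adult")
    return (
        _FIRST_ADULT
        + _OTHER_14_PLUS * (n_adults - 1 + np.asarray(n_other_14_plus, dtype=float))
        + _CHILD_UNDER_14 * np.asarray(n_children_under_14, dtype=float)
    )


def oecd_equivalise(income: float, comp: HouseholdComposition) -> float:
    """Equivalise a household income by the OECD-modified scale.

    Parameters
    ----------
    income
        Raw household income (>= 0).
    comp
        Household composition.

    Returns
    -------
    float
        ``income / comp.factor``.
    """
    if income < 0:
        raise ValueError("income must be non-negative")
    return income / comp.factor


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Type-1 (inverse empirical CDF) weighted quantile."""
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    cdf = np.cumsum(weights[order]) / weights.sum()
    idx = int(np.searchsorted(cdf, q, side="left"))
    idx = min(idx, len(v) - 1)
    return float(v[idx])


_QUINTILE_RULES = {"bottom_two": 0.4, "bottom_one": 0.2, "top_one": 0.2}


def quintile_flag(values, weights=None, rule: str = "bottom_two"):
    """Flag observations in the extreme quintile group(s) of a distribution.

    ``bottom_two`` flags values at or below the weighted 0.4-quantile,
    ``bottom_one`` at or below the 0.2-quantile and ``top_one`` at or above
    the 0.8-quantile.  Ties at the cut-point are always flagged.  Missing
    values propagate to missing flags.

    Returns a float array/Series of 0/1/NaN aligned with the input.
    """
    if rule not in _QUINTILE_RULES:
        raise ValueError(f"unknown quintile rule: {rule!r}")
    ser = pd.Series(values, dtype=float)
    vals = ser.to_numpy()
    obs = ~np.isnan(vals)
    if obs.sum() < 5:
        raise ValueError("need at least 5 non-missing values to form quintiles")
    if weights is None:
        w = np.ones(obs.sum())
    else:
        w = np.asarray(weights, dtype=float)[obs]
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be positive and finite")
    v = vals[obs]
    out = np.full(len(vals), np.nan)
    if np.all(v == v[0]):
        warnings.warn(
            "all values identical; no quintile group exists, returning all-unflagged",
            stacklevel=2,
        )
        out[obs] = 0.0
    elif rule == "top_one":
        # symmetric to a bottom flag on negated values; keeps ties flagged
        cut = _weighted_quantile(-v, w, _QUINTILE_RULES[rule])
        out[obs] = (-v <= cut).astype(float)
    else:
        cut = _weighted_quantile(v, w, _QUINTILE_RULES[rule])
        out[obs] = (v <= cut).astype(float)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    return out


def relative_poverty_flag(eq_income, weights=None):
    """Alternative exposure coding: equivalised income < 60% of the median.

    Provided as a sensitivity definition alongside the bottom-two-quintile
    rule (the two do not coincide in general).
    """
    ser = pd.Series(eq_income, dtype=float)
    vals = ser.to_numpy()
    obs = ~np.isnan(vals)
    w = np.ones(obs.sum()) if weights is None else np.asarray(weights, float)[obs]
    med = _weighted_quantile(vals[obs], w, 0.5)
    out = np.full(len(vals), np.nan)
    out[obs] = (vals[obs] < 0.6 * med).astype(float)
    if isinstance(eq_income, pd.Series):
        return pd.Series(out, index=eq_income.index)
    return out


def sdq_band(total):
    """Band an SDQ total-difficulties score.

    ``normal`` (< 14), ``borderline`` (14-16) or ``abnormal`` (>= 17).
    Accepts a scalar or array; scores outside 0-40 raise.
    """
    arr = np.asarray(total, dtype=float)
    valid = np.isnan(arr) | ((arr >= 0) & (arr <= 40))
    if not np.all(valid):
        raise ValueError("SDQ total must be in [0, 40]")
    bands = np.where(
        np.isnan(arr),
        None,
        np.where(
            arr >= SDQ_ABNORMAL_CUT,
            "abnormal",
            np.where(arr >= SDQ_BORDERLINE_CUT, "borderline", "normal"),
        ),
    )
    if np.ndim(total) == 0:
        return bands.item()
    return bands


def sdq_flag(total):
    """Binary difficulties flag: 1 if the SDQ band is abnormal (>= 17)."""
    arr = np.asarray(total, dtype=float)
    if np.any(~np.isnan(arr) & ((arr < 0) | (arr > 40))):
        raise ValueError("SDQ total must be in [0, 40]")
    out = np.where(np.isnan(arr), np.nan, (arr >= SDQ_ABNORMAL_CUT).astype(float))
    if isinstance(total, pd.Series):
        return pd.Series(out, index=total.index)
    if np.ndim(total) == 0:
        return float(out)
    return out


def dass_flag(dass_items, cutoff: float | None = None, weights=None):
    """Reduced-wellbeing flag from the six DASS items.

    Items (each scored 0-3) are summed; rows with any item missing get a
    missing sum (partial sums are left to the imputation stage).  The flag
    marks the top quintile of the summed score within the sample, or
    ``sum >= cutoff`` when a fixed ``cutoff`` is given.
    """
    items = pd.DataFrame(dass_items).astype(float)
    if items.shape[1] != 6:
        raise ValueError("expected exactly six DASS items")
    arr = items.to_numpy()
    with np.errstate(invalid="ignore"):
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 3:
            raise ValueError("DASS items must be scored 0-3")
    total = items.sum(axis=1, skipna=False)
    if cutoff is not None:
        return pd.Series(
            np.where(total.isna(), np.nan, (total >= cutoff).astype(float)),
            index=items.index,
        )
    return quintile_flag(total, weights=weights, rule="top_one")


def cprs_flag(
    closeness,
    conflict,
    cutoffs: tuple[float, float] | None = None,
    weights=None,
):
    """Poor relationship-quality flag from the CPRS-SF subscales.

    Flag = (closeness in lowest quintile) OR (conflict in highest quintile).
    With fixed ``cutoffs = (closeness_cut, conflict_cut)`` the rules become
    ``closeness <= closeness_cut`` / ``conflict >= conflict_cut``.

    Three-valued OR: if one subscale is missing the flag is 1 when the other
    triggers, otherwise missing; missing both gives missing.
    """
    close = pd.Series(closeness, dtype=float)
    confl = pd.Series(conflict, dtype=float).set_axis(close.index)
    if cutoffs is not None:
        c_cut, f_cut = cutoffs
        low_close = np.where(close.isna(), np.nan, (close <= c_cut).astype(float))
        high_confl = np.where(confl.isna(), np.nan, (confl >= f_cut).astype(float))
    else:
        low_close = quintile_flag(close, weights=weights, rule="bottom_one").to_numpy()
        high_confl = quintile_flag(confl, weights=weights, rule="top_one").to_numpy()
    either = np.fmax(low_close, high_confl)  # NaN OR 1 -> 1
    both_unknown_or_zero = np.isnan(low_close) | np.isnan(high_confl)
    out = np.where(both_unknown_or_zero & (either != 1.0), np.nan, either)
    return pd.Series(out, index=close.index)


_LOW_EDUCATION = {"no_qualifications", "standard_grade"}
_LOW_AGE_BAND = "<20"


def derive_analysis_set(
    cohort,
    cutoffs: Mapping[str, float] | None = None,
    weighted_quintiles: bool = False,
) -> pd.DataFrame:
    """Derive the binary analysis table (X, M1, M2, Y, confounders, weight).

    Parameters
    ----------
    cohort
        Raw cohort table (``pandas.DataFrame`` or an object with a ``data``
        attribute holding one) with the documented raw columns.
    cutoffs
        Optional fixed thresholds with keys ``income`` (equivalised income
        at or below which X = 1), ``dass`` (sum at or above which M1 part
        triggers), ``closeness`` and ``conflict``.  When omitted, quintile
        cut-points are estimated within the sample.
    weighted_quintiles
        Use survey weights when estimating quintile cut-points.

    Returns
    -------
    pandas.DataFrame
        Columns :data:`ANALYSIS_COLUMNS`; flags coded 1.0/0.0/NaN.
    """
    df = getattr(cohort, "data", cohort)
    weight = (
        df["weight"].astype(float)
        if "weight" in df.columns
        else pd.Series(1.0, index=df.index)
    )
    if np.any(weight.dropna() <= 0):
        raise ValueError("survey weights must be positive")
    qw = weight.to_numpy() if weighted_quintiles else None

    factor = equivalence_factor(
        df["n_adults"], df["n_other_14_plus"], df["n_children_under_14"]
    )
    eq_income = df["income"].astype(float) / factor
    if cutoffs is not None:
        x = pd.Series(
            np.where(
                eq_income.isna(), np.nan, (eq_income <= cutoffs["income"]).astype(float)
            ),
            index=df.index,
        )
    else:
        x = quintile_flag(eq_income, weights=qw, rule="bottom_two")

    dass_cols = [f"dass_{i}" for i in range(1, 7)]
    m1 = dass_flag(
        df[dass_cols],
        cutoff=None if cutoffs is None else cutoffs["dass"],
        weights=qw,
    )
    m2 = cprs_flag(
        df["closeness"],
        df["conflict"],
        cutoffs=None if cutoffs is None else (cutoffs["closeness"], cutoffs["conflict"]),
        weights=qw,
    )
    y = sdq_flag(df["sdq_total"].astype(float))

    edu = df["maternal_education"]
    low_edu = pd.Series(
        np.where(edu.isna(), np.nan, edu.isin(_LOW_EDUCATION).astype(float)),
        index=df.index,
    )
    age = df["maternal_age_band"]
    low_age = pd.Series(
        np.where(age.isna(), np.nan, (age == _LOW_AGE_BAND).astype(float)),
        index=df.index,
    )
    emp = df["maternal_employed"].astype(float)
    unemployed = 1.0 - emp
    nkids = df["n_children_under_14"].astype(float)
    gt4 = pd.Series(np.where(nkids.isna(), np.nan, (nkids > 4).astype(float)), index=df.index)

    out = pd.DataFrame(
        {
            "child_id": df["child_id"],
            "X": x,
            "M1": m1.to_numpy(),
            "M2": m2.to_numpy(),
            "Y": y.to_numpy() if isinstance(y, pd.Series) else y,
            "low_mat_education": low_edu,
            "low_mat_age": low_age,
            "mat_unemployed": unemployed,
            "gt4_children": gt4,
            "one_parent": df["one_parent"].astype(float),
            "ethnic_minority": df["ethnic_minority"].astype(float),
            "weight": weight,
        }
    )
    return out
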