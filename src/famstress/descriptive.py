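"""Descriptive tables: exposure-stratified prevalences and 2x2 odds ratios.

Odds ratios use the cross-product estimate with Woolf (log-normal)
confidence intervals; display rounding is half-up to 2 decimal places for
ratios and 1 dp for percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import CONFOUNDERS

__all__ = [
    "ORResult",
    "two_by_two_or",
    "exposure_stratified_table",
    "sample_characteristics",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention for printed tables)."""
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ORResult:
    """2x2 odds ratio with a Woolf confidence interval.

    Cells: ``a`` exposed-flagged, ``b`` exposed-unflagged, ``c``
    unexposed-flagged, ``d`` unexposed-unflagged.
    """

    a: float
    b: float
    c: float
    d: float
    or_: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    corrected: bool = field(default=False, compare=False)

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (
            round_half_up(self.or_, ndigits),
            round_half_up(self.ci_low, ndigits),
            round_half_up(self.ci_high, ndigits),
        )

    def __str__(self) -> str:  # Table-2 display style
        o, lo, hi = self.rounded()
        return f"{o:.2f} ({lo:.2f} to {hi:.2f})"


def two_by_two_or(a, b, c, d, alpha: float = 0.05) -> ORResult:
    """Cross-product odds ratio ``ad/bc`` with Woolf CI.

    ``CI = exp(ln OR +- z * sqrt(1/a + 1/b + 1/c + 1/d))``.  Zero cells get
    a +0.5 continuity correction (with a warning); negative counts raise.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    corrected = False
    if np.any(cells == 0):
        warnings.warn("zero cell; applying +0.5 continuity correction", stacklevel=2)
        cells = cells + 0.5
        corrected = True
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = stats.norm.ppf(1 - alpha / 2)
    log_or = np.log(or_)
    return ORResult(
        a=float(a),
        b=float(b),
        c=float(c),
        d=float(d),
        or_=float(or_),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        alpha=alpha,
        corrected=corrected,
    )


def exposure_stratified_table(
    analysis_set: pd.DataFrame,
    variables: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tabulate binary flags by exposure with odds ratios (Table-2 layout).

    One row per variable with exposed / unexposed counts and percentages and
    the exposed-vs-unexposed odds ratio with Woolf CI.  Rows with missing
    exposure or a missing flag are dropped per variable.
    """
    if variables is None:
        variables = ["Y", "M1", "M2", *CONFOUNDERS]
    x = analysis_set["X"]
    if (x == 1).sum() == 0 or (x == 0).sum() == 0:
        raise ValueError("empty exposure stratum")
    rows = []
    for var in variables:
        sub = analysis_set[[var]].assign(X=x).dropna()
        n_exp = int((sub["X"] == 1).sum())
        n_unexp = int((sub["X"] == 0).sum())
        if n_exp == 0 or n_unexp == 0:
            raise ValueError(f"empty stratum for variable {var!r}")
        a = int(((sub["X"] == 1) & (sub[var] == 1)).sum())
        c = int(((sub["X"] == 0) & (sub[var] == 1)).sum())
        res = two_by_two_or(a, n_exp - a, c, n_unexp - c, alpha=alpha)
        o, lo, hi = res.rounded()
        rows.append(
            {
                "variable": var,
                "n_exposed_flagged": a,
                "pct_exposed": round_half_up(100 * a / n_exp, 1),
                "n_unexposed_flagged": c,
                "pct_unexposed": round_half_up(100 * c / n_unexp, 1),
                "odds_ratio": o,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def _category_counts(ser: pd.Series) -> pd.Series:
    return ser.value_counts(dropna=True).sort_index()


def sample_characteristics(original: pd.DataFrame, imputation_set=None) -> pd.DataFrame:
    """Before/after-imputation characteristics table (Table-1 layout).

    For every column of ``original`` (besides identifiers and weights):
    category counts and percentages in the observed sample, the number of
    missing cases, and — when an imputation set is supplied — averaged
    counts/percentages over the completed datasets.
    """
    skip = {"child_id", "weight"}
    cols = [c for c in original.columns if c not in skip]
    rows = []
    datasets = None if imputation_set is None else imputation_set.datasets
    for col in cols:
        ser = original[col]
        counts = _category_counts(ser)
        n_obs = int(ser.notna().sum())
        n_miss = int(ser.isna().sum())
        for cat, cnt in counts.items():
            row = {
                "characteristic": col,
                "category": cat,
                "survey_n": int(cnt),
                "survey_pct": round_half_up(100 * cnt / n_obs, 1) if n_obs else np.nan,
            }
            if datasets is not None:
                imp_counts = [float((d[col] == cat).sum()) for d in datasets]
                mean_cnt = float(np.mean(imp_counts))
                row["imputed_n"] = round_half_up(mean_cnt, 1)
                row["imputed_pct"] = round_half_up(100 * mean_cnt / len(original), 1)
            rows.append(row)
        miss_row = {
            "characteristic": col,
            "category": "missing",
            "survey_n": n_miss,
            "survey_pct": np.nan,
        }
        if datasets is not None:
            miss_row["imputed_n"] = 0.0
            miss_row["imputed_pct"] = np.nan
        rows.append(miss_row)
    return pd.DataFrame(rows)
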