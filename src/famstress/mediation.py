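"""Natural-effects decomposition for one binary exposure and two sequential
binary mediators.

The estimator is imputation-based: a weighted logistic outcome model
``Y ~ X + M1 + M2 + C`` and a mediator model ``M1 ~ X + C`` are fitted, each
record is expanded over the counterfactual exposure copies ``(x0, x1)`` in
{0,1}^2 with the third copy ``x2`` pinned to the record's observed exposure,
the counterfactual outcome expectation is imputed by mixing over M1, and a
weighted fractional-response logistic "natural model"

    E[Y(x0, M1(x1), M2(x2, M1(x2)))] = expit(t0 + t1*x0 + t2*x1 + t3*x2 + C'b)

is fitted on the expanded table.  The effect odds ratios follow directly:

    OR_NDE = exp(t1), OR_NIE_M1 = exp(t2), OR_NIE_M2 = exp(t3),
    OR_NIE_joint = exp(t2 + t3), OR_TE = exp(t1 + t2 + t3),

so OR_TE = OR_NDE * OR_NIE_joint holds exactly by construction.

Confidence intervals come from a nonparametric percentile bootstrap
(child-level resampling); multiple-imputation point estimates are pooled as
means of the coefficients on the log-odds scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .preprocessing import CONFOUNDERS

__all__ = [
    "NaturalModelSpec",
    "NaturalEffectsFit",
    "fit_outcome_imputation_model",
    "fit_mediator_model",
    "expand_and_impute",
    "fit_natural_model",
    "natural_effects",
    "proportion_mediated",
    "bootstrap_cis",
    "pool_over_imputations",
]

_EFFECTS = ("or_te", "or_nde", "or_nie_m1", "or_nie_m2", "or_nie_joint")


@dataclass(frozen=True)
class NaturalModelSpec:
    """Settings of the natural-effects analysis.

    ``saturated=True`` replaces the logistic working models with exact
    weighted cell means over the discrete (x, m1, m2, confounder) strata —
    only sensible with few binary confounders, used for nonparametric
    g-formula checks.
    """

    confounders: tuple[str, ...] = tuple(CONFOUNDERS)
    exposure_mediator_interactions: bool = False
    mediator_interaction: bool = False  # M1*M2 term in the outcome model
    saturated: bool = False
    n_boot: int = 1000
    seed: int | None = None
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


# ---------------------------------------------------------------------------
# Working models
# ---------------------------------------------------------------------------


def _fit_weighted_logit(design: np.ndarray, y: np.ndarray, w: np.ndarray):
    """GLM-binomial fit; ridge-penalised fallback on separation.

    Returns (params, bse); bse is NaN for the fallback path.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, design, family=sm.families.Binomial(), var_weights=w).fit()
            params = np.asarray(res.params)
            if np.all(np.isfinite(params)) and np.max(np.abs(params)) < 30:
                return params, np.asarray(res.bse)
        except Exception:
            pass
        warnings.warn("logistic fit unstable; using ridge-penalised fallback")
        res = sm.GLM(
            y, design, family=sm.families.Binomial(), var_weights=w
        ).fit_regularized(alpha=1e-4, L1_wt=0.0)
        params = np.asarray(res.params)
        return params, np.full(len(params), np.nan)


def _as_matrix(analysis_set: pd.DataFrame, spec: NaturalModelSpec) -> np.ndarray:
    return analysis_set[list(spec.confounders)].to_numpy(float)


class _LogitOutcome:
    """P(Y=1 | x, m1, m2, c) from a weighted logistic fit."""

    def __init__(self, params, bse, spec: NaturalModelSpec):
        self.params = np.asarray(params)
        self.bse = np.asarray(bse)
        self.spec = spec
        self.columns = _outcome_columns(spec)

    def predict(self, x, m1, m2, c: np.ndarray) -> np.ndarray:
        return expit(_outcome_design(x, m1, m2, c, self.spec) @ self.params)


class _LogitMediator:
    """P(M1=1 | x, c) from a weighted logistic fit."""

    def __init__(self, params, bse, spec: NaturalModelSpec):
        self.params = np.asarray(params)
        self.bse = np.asarray(bse)
        self.spec = spec
        self.columns = ["const", "X", *spec.confounders]

    def predict(self, x, c: np.ndarray) -> np.ndarray:
        x = np.broadcast_to(np.asarray(x, float), (len(c),))
        design = np.column_stack([np.ones(len(c)), x, c])
        return expit(design @ self.params)


def _cell_codes(*cols: np.ndarray) -> np.ndarray:
    code = np.zeros(len(cols[0]), dtype=np.int64)
    for col in cols:
        code = code * 2 + np.asarray(col, float).astype(np.int64)
    return code


class _CellMeanModel:
    """Exact weighted cell means over binary strata (saturated mode)."""

    def __init__(self, codes: np.ndarray, y: np.ndarray, w: np.ndarray, n_bits: int):
        self.n_cells = 2**n_bits
        num = np.bincount(codes, weights=w * y, minlength=self.n_cells)
        den = np.bincount(codes, weights=w, minlength=self.n_cells)
        overall = float(np.average(y, weights=w))
        with np.errstate(invalid="ignore"):
            means = num / den
        self._empty = den == 0
        if self._empty.any():
            warnings.warn("empty cells in saturated model; using the overall mean")
        means[self._empty] = overall
        self.means = means

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        return self.means[codes]


class _SaturatedOutcome:
    def __init__(self, analysis_set: pd.DataFrame, spec: NaturalModelSpec):
        self.spec = spec
        c = _as_matrix(analysis_set, spec)
        self._n_bits = 3 + c.shape[1]
        codes = _cell_codes(
            analysis_set["X"].to_numpy(),
            analysis_set["M1"].to_numpy(),
            analysis_set["M2"].to_numpy(),
            *c.T,
        )
        self._cells = _CellMeanModel(
            codes,
            analysis_set["Y"].to_numpy(float),
            analysis_set["weight"].to_numpy(float),
            self._n_bits,
        )

    def predict(self, x, m1, m2, c: np.ndarray) -> np.ndarray:
        n = len(c)
        x = np.broadcast_to(np.asarray(x, float), (n,))
        m1 = np.broadcast_to(np.asarray(m1, float), (n,))
        m2 = np.broadcast_to(np.asarray(m2, float), (n,))
        return self._cells.lookup(_cell_codes(x, m1, m2, *c.T))


class _SaturatedMediator:
    def __init__(self, analysis_set: pd.DataFrame, spec: NaturalModelSpec):
        self.spec = spec
        c = _as_matrix(analysis_set, spec)
        self._n_bits = 1 + c.shape[1]
        codes = _cell_codes(analysis_set["X"].to_numpy(), *c.T)
        self._cells = _CellMeanModel(
            codes,
            analysis_set["M1"].to_numpy(float),
            analysis_set["weight"].to_numpy(float),
            self._n_bits,
        )

    def predict(self, x, c: np.ndarray) -> np.ndarray:
        x = np.broadcast_to(np.asarray(x, float), (len(c),))
        return self._cells.lookup(_cell_codes(x, *c.T))


def _require_complete(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if df[c].isna().any()]
    if missing:
        raise ValueError(
            f"analysis set has missing values in {missing}; impute upstream first"
        )


def _outcome_design(x, m1, m2, c: np.ndarray, spec: NaturalModelSpec) -> np.ndarray:
    n = len(c)
    x = np.broadcast_to(np.asarray(x, float), (n,))
    m1 = np.broadcast_to(np.asarray(m1, float), (n,))
    m2 = np.broadcast_to(np.asarray(m2, float), (n,))
    cols = [np.ones(n), x, m1, m2]
    if spec.exposure_mediator_interactions:
        cols += [x * m1, x * m2]
    if spec.mediator_interaction:
        cols += [m1 * m2]
    return np.column_stack(cols + [c])


def _outcome_columns(spec: NaturalModelSpec) -> list[str]:
    cols = ["const", "X", "M1", "M2"]
    if spec.exposure_mediator_interactions:
        cols += ["X:M1", "X:M2"]
    if spec.mediator_interaction:
        cols += ["M1:M2"]
    return cols + list(spec.confounders)


def fit_outcome_imputation_model(
    analysis_set: pd.DataFrame, spec: NaturalModelSpec | None = None
):
    """Fit the outcome imputation model P(Y=1 | x, m1, m2, c).

    Weighted logistic in Y on X, M1, M2 and the confounders, with optional
    exposure-mediator (X:M1, X:M2) and mediator-mediator (M1:M2)
    interactions; exact cell means in saturated mode.
    """
    spec = spec or NaturalModelSpec()
    _require_complete(analysis_set, ["Y", "X", "M1", "M2", *spec.confounders])
    if spec.saturated:
        return _SaturatedOutcome(analysis_set, spec)
    c = _as_matrix(analysis_set, spec)
    design = _outcome_design(
        analysis_set["X"].to_numpy(), analysis_set["M1"].to_numpy(),
        analysis_set["M2"].to_numpy(), c, spec,
    )
    params, bse = _fit_weighted_logit(
        design,
        analysis_set["Y"].to_numpy(float),
        analysis_set["weight"].to_numpy(float),
    )
    return _LogitOutcome(params, bse, spec)


def fit_mediator_model(analysis_set: pd.DataFrame, spec: NaturalModelSpec | None = None):
    """Fit the first-mediator model P(M1=1 | x, c) (weighted logistic)."""
    spec = spec or NaturalModelSpec()
    _require_complete(analysis_set, ["M1", "X", *spec.confounders])
    if spec.saturated:
        return _SaturatedMediator(analysis_set, spec)
    c = _as_matrix(analysis_set, spec)
    design = np.column_stack(
        [np.ones(len(analysis_set)), analysis_set["X"].to_numpy(float), c]
    )
    params, bse = _fit_weighted_logit(
        design,
        analysis_set["M1"].to_numpy(float),
        analysis_set["weight"].to_numpy(float),
    )
    return _LogitMediator(params, bse, spec)


def expand_and_impute(
    analysis_set: pd.DataFrame,
    outcome_model,
    mediator_model,
    spec: NaturalModelSpec | None = None,
) -> pd.DataFrame:
    """Expand each record over (x0, x1) and impute counterfactual outcomes.

    Every source row contributes four records — (x0, x1) in {0,1}^2, with
    ``x2`` fixed at the row's observed exposure — whose outcome expectation
    is ``sum_m1 P(M1=m1 | x1, c) * P(Y=1 | x0, m1, m2_obs, c)``.  Weights
    carry through unchanged.
    """
    spec = spec or NaturalModelSpec()
    _require_complete(analysis_set, ["X", "M2", *spec.confounders])
    n = len(analysis_set)
    c = _as_matrix(analysis_set, spec)
    x_obs = analysis_set["X"].to_numpy(float)
    m2_obs = analysis_set["M2"].to_numpy(float)
    w = analysis_set["weight"].to_numpy(float)
    row_id = analysis_set.index.to_numpy()

    frames = []
    for x0 in (0.0, 1.0):
        for x1 in (0.0, 1.0):
            p_m1 = mediator_model.predict(x1, c)
            yhat = (1 - p_m1) * outcome_model.predict(x0, 0.0, m2_obs, c)
            yhat += p_m1 * outcome_model.predict(x0, 1.0, m2_obs, c)
            frames.append(
                pd.DataFrame(
                    {
                        "row_id": row_id,
                        "x0": x0,
                        "x1": x1,
                        "x2": x_obs,
                        "yhat": yhat,
                        "weight": w,
                        **{k: c[:, j] for j, k in enumerate(spec.confounders)},
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


@dataclass
class NaturalEffectsFit:
    """Fitted natural model with effect odds ratios and proportions mediated."""

    theta: dict[str, float]
    or_te: float
    or_nde: float
    or_nie_m1: float
    or_nie_m2: float
    or_nie_joint: float
    pm_m1: float | None
    pm_m2: float | None
    pm_joint: float | None
    cis: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0
    seed: int | None = None
    m_imputations: int = 1

    def effects(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _EFFECTS}

    def log_effects(self) -> dict[str, float]:
        return {k: float(np.log(v)) for k, v in self.effects().items()}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "theta": self.theta,
            "effects": self.effects(),
            "proportion_mediated": {
                "pm_m1": self.pm_m1,
                "pm_m2": self.pm_m2,
                "pm_joint": self.pm_joint,
            },
            "cis": {k: list(v) for k, v in self.cis.items()},
            "n_boot": self.n_boot,
            "seed": self.seed,
            "m_imputations": self.m_imputations,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_table(self) -> pd.DataFrame:
        """Effects table in the published layout (Effect, OR, CI, PM)."""
        from .descriptive import round_half_up

        rows = []
        labels = {
            "or_te": ("Total Effect", None),
            "or_nde": ("Natural Direct Effect", None),
            "or_nie_m1": ("Natural Indirect Effect via M1", self.pm_m1),
            "or_nie_m2": ("Natural Indirect Effect via M2", self.pm_m2),
            "or_nie_joint": ("Natural Joint Indirect Effect via M1 and M2", self.pm_joint),
        }
        for key in _EFFECTS:
            label, pm = labels[key]
            ci = self.cis.get(key)
            rows.append(
                {
                    "effect": label,
                    "odds_ratio": round_half_up(getattr(self, key), 2),
                    "ci_low": round_half_up(ci[0], 2) if ci else np.nan,
                    "ci_high": round_half_up(ci[1], 2) if ci else np.nan,
                    "pm_percent": round_half_up(100 * pm, 2) if pm is not None else np.nan,
                }
            )
        return pd.DataFrame(rows)


def proportion_mediated(or_nde: float, or_nie: float) -> float | None:
    """Proportion mediated on the odds-ratio scale.

    ``PM = OR_NDE * (OR_NIE - 1) / (OR_NDE * OR_NIE - 1)``; returns ``None``
    when the denominator is numerically zero (PM undefined).
    """
    denom = or_nde * or_nie - 1.0
    if abs(denom) < 1e-12:
        return None
    return float(or_nde * (or_nie - 1.0) / denom)


def _fit_from_theta(theta: dict[str, float], **kw) -> NaturalEffectsFit:
    t1, t2, t3 = theta["x0"], theta["x1"], theta["x2"]
    or_nde = float(np.exp(t1))
    or_nie_m1 = float(np.exp(t2))
    or_nie_m2 = float(np.exp(t3))
    or_joint = float(np.exp(t2 + t3))
    return NaturalEffectsFit(
        theta=theta,
        or_te=float(np.exp(t1 + t2 + t3)),
        or_nde=or_nde,
        or_nie_m1=or_nie_m1,
        or_nie_m2=or_nie_m2,
        or_nie_joint=or_joint,
        pm_m1=proportion_mediated(or_nde, or_nie_m1),
        pm_m2=proportion_mediated(or_nde, or_nie_m2),
        pm_joint=proportion_mediated(or_nde, or_joint),
        **kw,
    )


def fit_natural_model(
    expanded: pd.DataFrame, spec: NaturalModelSpec | None = None
) -> NaturalEffectsFit:
    """Fit the natural model on an expanded table and read off the effects.

    A weighted logistic-type fit of the imputed expectation (fractional
    response) on x0, x1, x2 and the confounders.
    """
    spec = spec or NaturalModelSpec()
    c = expanded[list(spec.confounders)].to_numpy(float)
    design = np.column_stack(
        [
            np.ones(len(expanded)),
            expanded["x0"].to_numpy(float),
            expanded["x1"].to_numpy(float),
            expanded["x2"].to_numpy(float),
            c,
        ]
    )
    cols = ["const", "x0", "x1", "x2", *spec.confounders]
    params, _ = _fit_weighted_logit(
        design,
        expanded["yhat"].to_numpy(float),
        expanded["weight"].to_numpy(float),
    )
    theta = dict(zip(cols, (float(p) for p in params)))
    return _fit_from_theta(theta, seed=spec.seed)


def natural_effects(
    analysis_set: pd.DataFrame, spec: NaturalModelSpec | None = None
) -> NaturalEffectsFit:
    """Point estimates of the full decomposition on one complete dataset."""
    spec = spec or NaturalModelSpec()
    outcome = fit_outcome_imputation_model(analysis_set, spec)
    mediator = fit_mediator_model(analysis_set, spec)
    expanded = expand_and_impute(analysis_set, outcome, mediator, spec)
    return fit_natural_model(expanded, spec)


def bootstrap_cis(
    analysis_set: pd.DataFrame,
    spec: NaturalModelSpec | None = None,
    estimator: Callable[[pd.DataFrame, np.random.Generator], dict[str, float]] | None = None,
    max_failure_rate: float = 0.05,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap CIs for the five effect odds ratios.

    Children are resampled with replacement (weights travel with their row)
    and the full estimator re-runs on each replicate.  ``estimator`` may be
    overridden, e.g. to insert a stochastic imputation step before
    estimation; it receives the resampled table and a replicate-specific
    random generator and returns the effect ORs.  Replicates that fail are
    skipped; more than ``max_failure_rate`` failures is an error.
    """
    spec = spec or NaturalModelSpec()
    if estimator is None:
        def estimator(df, rng):  # noqa: ARG001 - default path is deterministic
            return natural_effects(df, spec).effects()

    master = np.random.default_rng(spec.seed)
    n = len(analysis_set)
    draws: dict[str, list[float]] = {k: [] for k in _EFFECTS}
    failures = 0
    for _ in range(spec.n_boot):
        rng = np.random.default_rng(master.integers(2**63))
        idx = rng.integers(0, n, n)
        sample = analysis_set.iloc[idx].reset_index(drop=True)
        try:
            eff = estimator(sample, rng)
        except Exception:
            failures += 1
            continue
        for k in _EFFECTS:
            draws[k].append(eff[k])
    if failures > max_failure_rate * spec.n_boot:
        raise RuntimeError(f"{failures}/{spec.n_boot} bootstrap replicates failed")
    lo = 100 * (1 - spec.ci_level) / 2
    hi = 100 - lo
    return {
        k: (float(np.percentile(v, lo)), float(np.percentile(v, hi)))
        for k, v in draws.items()
    }


def pool_over_imputations(fits: Sequence[NaturalEffectsFit]) -> NaturalEffectsFit:
    """Pool fits from multiply-imputed datasets (mean coefficients).

    Point estimates follow Rubin's rule for coefficients (arithmetic mean on
    the log-odds scale); CIs are left to the bootstrap-over-imputation
    procedure at the pipeline level.
    """
    if not fits:
        raise ValueError("need at least one fit to pool")
    keys = fits[0].theta.keys()
    if any(f.theta.keys() != keys for f in fits):
        raise ValueError("fits have mismatched model specifications")
    theta = {k: float(np.mean([f.theta[k] for f in fits])) for k in keys}
    return _fit_from_theta(theta, m_imputations=len(fits))
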