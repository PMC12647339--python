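"""Synthetic family-stress cohort generator and counterfactual oracle.

Simulates child-level cohorts with the causal ordering

    confounders C  ->  low income X  ->  reduced maternal wellbeing M1
                   ->  poor parent-child relationship M2  ->  SDQ difficulties Y

where each of X, M1, M2, Y follows a logistic structural equation, raw scale
scores (income, DASS items, CPRS-SF subscales, SDQ total) are back-generated
to be consistent with the binary latents across fixed thresholds, and
missingness is injected last under an MCAR / MAR / MNAR mechanism.

Ground-truth natural effects are computed by :func:`oracle_effects` via
nested-counterfactual Monte Carlo on the structural equations — a brute-force
reference entirely independent of the estimation code.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .preprocessing import CONFOUNDERS

__all__ = [
    "LogisticEq",
    "RawScaleParams",
    "StructuralParams",
    "Cohort",
    "TrueEffects",
    "default_params",
    "generate_cohort",
    "inject_missingness",
    "oracle_effects",
]

_MISSABLE = [
    "income",
    "dass",
    "closeness",
    "conflict",
    "sdq_total",
    "maternal_education",
    "maternal_age_band",
    "maternal_employed",
    "ethnic_minority",
    "one_parent",
]

_MECHANISMS = ("mcar", "mar", "mnar")


@dataclass(frozen=True)
class LogisticEq:
    """Coefficients (log-odds scale) of one structural equation.

    ``conf`` maps confounder name -> coefficient; ``x``, ``m1``, ``m2`` are
    coefficients on upstream binary variables; ``x_m1`` / ``x_m2`` optional
    exposure-mediator interaction terms (outcome equation only).
    """

    intercept: float
    x: float = 0.0
    m1: float = 0.0
    m2: float = 0.0
    x_m1: float = 0.0
    x_m2: float = 0.0
    conf: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [self.intercept, self.x, self.m1, self.m2, self.x_m1, self.x_m2,
                *self.conf.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("structural coefficients must be finite")

    def linpred(self, c: np.ndarray, x=0.0, m1=0.0, m2=0.0) -> np.ndarray:
        """Linear predictor given confounder matrix ``c`` (n x len(conf))."""
        beta = np.array([self.conf.get(k, 0.0) for k in CONFOUNDERS])
        lp = self.intercept + c @ beta
        lp = lp + self.x * np.asarray(x, float)
        lp = lp + self.m1 * np.asarray(m1, float) + self.m2 * np.asarray(m2, float)
        lp = lp + self.x_m1 * np.asarray(x, float) * np.asarray(m1, float)
        lp = lp + self.x_m2 * np.asarray(x, float) * np.asarray(m2, float)
        return lp

    def prob(self, c: np.ndarray, x=0.0, m1=0.0, m2=0.0) -> np.ndarray:
        return expit(self.linpred(c, x, m1, m2))


@dataclass(frozen=True)
class RawScaleParams:
    """Distributions used to back-generate raw scores from binary latents.

    Each latent flag determines which side of the fixed threshold the raw
    score is drawn from, so the preprocessing cut-offs recover the latents
    exactly.
    """

    income_cut: float = 15000.0  # equivalised income; X=1 iff <= cut
    income_log_sigma: float = 0.45
    dass_cut: int = 12  # DASS 6-item sum in 0..18; M1=1 iff >= cut
    closeness_cut: int = 20  # closeness sum in 7..35; low iff <= cut
    conflict_cut: int = 26  # conflict sum in 8..40; high iff >= cut
    sdq_cut: int = 17  # SDQ total 0..40; Y=1 iff >= cut

    def __post_init__(self) -> None:
        if not (0 < self.dass_cut <= 18):
            raise ValueError("dass_cut must lie in the 6-item sum support (1..18)")
        if not (7 < self.closeness_cut < 35):
            raise ValueError("closeness_cut must lie strictly inside 7..35")
        if not (8 < self.conflict_cut <= 40):
            raise ValueError("conflict_cut must lie in 9..40")
        if not (0 < self.sdq_cut <= 40):
            raise ValueError("sdq_cut must lie in 1..40")


@dataclass(frozen=True)
class StructuralParams:
    """Full simulator configuration."""

    n_children: int
    seed: int
    conf_prevalences: dict[str, float]
    alpha_x: LogisticEq
    alpha_m1: LogisticEq
    alpha_m2: LogisticEq
    alpha_y: LogisticEq
    raw_scale: RawScaleParams = field(default_factory=RawScaleParams)
    missing_rates: dict[str, float] = field(default_factory=dict)
    missing_mechanism: str = "mcar"
    mar_coef: float = 1.0
    weight_model: str = "unit"  # "unit" | "lognormal"
    weight_sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        for k, p in self.conf_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {k!r} outside [0, 1]")
        for k, r in self.missing_rates.items():
            if k not in _MISSABLE:
                raise ValueError(f"unknown missable field {k!r}")
            if not 0.0 <= r < 1.0:
                raise ValueError(f"missing rate for {k!r} outside [0, 1)")
        if self.missing_mechanism not in _MECHANISMS:
            raise ValueError(f"unknown missing mechanism {self.missing_mechanism!r}")
        if self.weight_model not in ("unit", "lognormal"):
            raise ValueError(f"unknown weight model {self.weight_model!r}")

    def replace(self, **kw) -> "StructuralParams":
        return dataclasses.replace(self, **kw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "StructuralParams":
        d = dict(d)
        for key in ("alpha_x", "alpha_m1", "alpha_m2", "alpha_y"):
            if isinstance(d.get(key), dict):
                d[key] = LogisticEq(**d[key])
        if isinstance(d.get("raw_scale"), dict):
            d["raw_scale"] = RawScaleParams(**d["raw_scale"])
        return cls(**d)


@dataclass
class Cohort:
    """A simulated (or ingested) raw cohort table.

    ``latent`` carries the pre-missingness binary flags (simulation only) and
    ``cutoffs`` the fixed thresholds the raw scores were generated around.
    """

    data: pd.DataFrame
    latent: pd.DataFrame | None = None
    cutoffs: dict[str, float] | None = None

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        return cls(data=pd.read_csv(path))


@dataclass(frozen=True)
class TrueEffects:
    """Monte-Carlo ground-truth natural effects on the odds-ratio scale."""

    or_te: float
    or_nde: float
    or_nie_m1: float
    or_nie_m2: float
    or_nie_joint: float
    mc_se: dict[str, float]
    n_mc: int
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "or_te": self.or_te,
            "or_nde": self.or_nde,
            "or_nie_m1": self.or_nie_m1,
            "or_nie_m2": self.or_nie_m2,
            "or_nie_joint": self.or_nie_joint,
        }


# ---------------------------------------------------------------------------
# Default calibration.
#
# Targets (marginal prevalences): exposure 0.389 overall; M1 0.306 / 0.184,
# M2 0.406 / 0.315 and Y 0.083 / 0.027 within the exposed / unexposed strata.
# Confounder coefficients on X reproduce the observed exposure-confounder
# odds ratios; mediator/outcome confounder coefficients are fixed at modest
# values and the intercept and X-coefficient of each equation were found by
# stratum-wise root finding on a 2,000,000-child simulation (see the
# calibration note in the repo scripts).  Values are frozen here.
# ---------------------------------------------------------------------------

_DEFAULT_CONF_PREV = {
    "low_mat_education": 0.215,
    "low_mat_age": 0.044,
    "mat_unemployed": 0.344,
    "gt4_children": 0.039,
    "one_parent": 0.141,
    "ethnic_minority": 0.027,
}

_DEFAULT_ALPHA_X = LogisticEq(
    intercept=-1.8063,
    conf={
        "low_mat_education": 1.4816,
        "low_mat_age": 2.0956,
        "mat_unemployed": 1.3507,
        "gt4_children": 1.3297,
        "one_parent": 2.3542,
        "ethnic_minority": 1.0852,
    },
)

_DEFAULT_ALPHA_M1 = LogisticEq(
    intercept=-1.6216,
    x=0.4707,
    conf={k: 0.25 for k in CONFOUNDERS},
)

_DEFAULT_ALPHA_M2 = LogisticEq(
    intercept=-0.9779,
    x=0.1780,
    m1=0.5,
    conf={k: 0.20 for k in CONFOUNDERS},
)

_DEFAULT_ALPHA_Y = LogisticEq(
    intercept=-4.2434,
    x=0.7636,
    m1=0.8,
    m2=0.7,
    conf={k: 0.30 for k in CONFOUNDERS},
)


def default_params(n_children: int = 50_000, seed: int = 0, **overrides) -> StructuralParams:
    """Calibrated default simulator parameters (see module notes)."""
    base = StructuralParams(
        n_children=n_children,
        seed=seed,
        conf_prevalences=dict(_DEFAULT_CONF_PREV),
        alpha_x=_DEFAULT_ALPHA_X,
        alpha_m1=_DEFAULT_ALPHA_M1,
        alpha_m2=_DEFAULT_ALPHA_M2,
        alpha_y=_DEFAULT_ALPHA_Y,
    )
    return base.replace(**overrides) if overrides else base


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _draw_confounders(params: StructuralParams, rng: np.random.Generator) -> np.ndarray:
    n = params.n_children
    c = np.empty((n, len(CONFOUNDERS)))
    for j, name in enumerate(CONFOUNDERS):
        c[:, j] = rng.random(n) < params.conf_prevalences.get(name, 0.0)
    return c


def _split_sum_into_items(
    totals: np.ndarray, n_items: int, item_max: int, rng: np.random.Generator
) -> np.ndarray:
    """Distribute integer totals over items bounded by [0, item_max]."""
    n = len(totals)
    items = np.zeros((n, n_items), dtype=int)
    remaining = totals.astype(int).copy()
    for i in range(n_items):
        slots_left = n_items - i - 1
        lo = np.maximum(0, remaining - item_max * slots_left)
        hi = np.minimum(item_max, remaining)
        draw = lo + (rng.random(n) * (hi - lo + 1)).astype(int)
        draw = np.minimum(draw, hi)
        items[:, i] = draw
        remaining -= draw
    return items


def generate_cohort(params: StructuralParams) -> Cohort:
    """Simulate a raw cohort with the family-stress causal structure.

    Binary latents are drawn in causal order from the four logistic
    equations; raw scale scores are back-generated on the latent-consistent
    side of the fixed thresholds in ``params.raw_scale``; missingness (if
    any) is injected last.  Fixed seed => bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_children
    rs = params.raw_scale

    c = _draw_confounders(params, rng)
    x = (rng.random(n) < params.alpha_x.prob(c)).astype(float)
    m1 = (rng.random(n) < params.alpha_m1.prob(c, x=x)).astype(float)
    m2 = (rng.random(n) < params.alpha_m2.prob(c, x=x, m1=m1)).astype(float)
    y = (rng.random(n) < params.alpha_y.prob(c, x=x, m1=m1, m2=m2)).astype(float)

    conf = pd.DataFrame(c, columns=CONFOUNDERS)

    # household composition, consistent with the one-parent and >4-children flags
    one_parent = conf["one_parent"].to_numpy()
    n_adults = np.where(one_parent == 1, 1, 2)
    n_other = rng.binomial(1, 0.05, n)
    gt4 = conf["gt4_children"].to_numpy()
    n_children_u14 = np.where(
        gt4 == 1, rng.integers(5, 8, n), rng.integers(1, 5, n)
    )
    factor = (
        1.0 + 0.5 * (n_adults - 1 + n_other) + 0.3 * n_children_u14
    )

    # equivalised income on the latent-consistent side of the cut (small gap
    # keeps the threshold rule exact under float division round-trips)
    spread = 0.03 + np.abs(rng.normal(0.0, rs.income_log_sigma, n))
    eq_income = np.where(
        x == 1, rs.income_cut * np.exp(-spread), rs.income_cut * np.exp(spread)
    )
    income = eq_income * factor

    # DASS 6-item sum (0..18): M1=1 side is [cut, 18], else [0, cut-1]
    dass_sum = np.where(
        m1 == 1,
        rng.integers(rs.dass_cut, 19, n),
        rng.integers(0, rs.dass_cut, n),
    )
    dass_items = _split_sum_into_items(dass_sum, 6, 3, rng)

    # CPRS-SF subscales: closeness 7..35 (low iff <= cut), conflict 8..40
    # (high iff >= cut); when M2=1 pick which condition(s) fire
    close_low = rng.integers(7, rs.closeness_cut + 1, n)
    close_ok = rng.integers(rs.closeness_cut + 1, 36, n)
    confl_high = rng.integers(rs.conflict_cut, 41, n)
    confl_ok = rng.integers(8, rs.conflict_cut, n)
    mode = rng.random(n)  # <0.45 closeness-only, <0.9 conflict-only, else both
    use_close = (m2 == 1) & ((mode < 0.45) | (mode >= 0.9))
    use_confl = (m2 == 1) & (mode >= 0.45)
    closeness = np.where(use_close, close_low, close_ok)
    conflict = np.where(use_confl, confl_high, confl_ok)

    # SDQ total 0..40: abnormal side [cut, 40], else [0, cut-1]
    sdq_total = np.where(
        y == 1, rng.integers(rs.sdq_cut, 41, n), rng.integers(0, rs.sdq_cut, n)
    )

    # raw confounder bands consistent with the binary codings
    low_edu = conf["low_mat_education"].to_numpy()
    edu = np.where(
        low_edu == 1,
        np.where(rng.random(n) < 0.30, "no_qualifications", "standard_grade"),
        np.where(rng.random(n) < 0.11, "higher", "degree_or_vocational"),
    )
    low_age = conf["low_mat_age"].to_numpy()
    age_pick = rng.random(n)
    age = np.where(
        low_age == 1,
        "<20",
        np.where(age_pick < 0.38, "20-29", np.where(age_pick < 0.96, "30-39", "40+")),
    )
    employed = 1.0 - conf["mat_unemployed"].to_numpy()

    if params.weight_model == "lognormal":
        weight = rng.lognormal(-params.weight_sigma**2 / 2, params.weight_sigma, n)
    else:
        weight = np.ones(n)

    data = pd.DataFrame(
        {
            "child_id": np.arange(1, n + 1),
            "income": income,
            "n_adults": n_adults,
            "n_other_14_plus": n_other,
            "n_children_under_14": n_children_u14,
            **{f"dass_{i+1}": dass_items[:, i] for i in range(6)},
            "closeness": closeness,
            "conflict": conflict,
            "sdq_total": sdq_total,
            "maternal_education": edu,
            "maternal_age_band": age,
            "maternal_employed": employed,
            "one_parent": one_parent,
            "ethnic_minority": conf["ethnic_minority"].to_numpy(),
            "weight": weight,
        }
    )
    latent = pd.DataFrame({"X": x, "M1": m1, "M2": m2, "Y": y}).join(conf)
    cutoffs = {
        "income": rs.income_cut,
        "dass": float(rs.dass_cut),
        "closeness": float(rs.closeness_cut),
        "conflict": float(rs.conflict_cut),
    }
    cohort = Cohort(data=data, latent=latent, cutoffs=cutoffs)
    if any(r > 0 for r in params.missing_rates.values()):
        cohort = inject_missingness(cohort, params)
    return cohort


_FIELD_COLUMNS = {
    "income": ["income"],
    "dass": [f"dass_{i}" for i in range(1, 7)],
    "closeness": ["closeness"],
    "conflict": ["conflict"],
    "sdq_total": ["sdq_total"],
    "maternal_education": ["maternal_education"],
    "maternal_age_band": ["maternal_age_band"],
    "maternal_employed": ["maternal_employed"],
    "ethnic_minority": ["ethnic_minority"],
    "one_parent": ["one_parent"],
}


def _mar_probabilities(rate: float, z: np.ndarray, coef: float) -> np.ndarray:
    """Logistic missingness probabilities with marginal mean = rate."""
    zs = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)

    def mean_gap(a):
        return expit(a + coef * zs).mean() - rate

    a = brentq(mean_gap, -30, 30)
    return expit(a + coef * zs)


def inject_missingness(cohort: Cohort, params: StructuralParams) -> Cohort:
    """Set cells missing per the configured mechanism.

    MCAR draws i.i.d. Bernoulli(rate); MAR ties missingness of each field to
    a logistic function of the confounder score; MNAR ties it to the
    (standardised) value of the field itself.  The marginal rate is held at
    the configured value in all three mechanisms.
    """
    if not params.missing_rates:
        return cohort
    rng = np.random.default_rng(params.seed + 1_000_003)
    data = cohort.data.copy()
    n = len(data)
    conf_score = data[["one_parent", "ethnic_minority"]].sum(axis=1).to_numpy() + (
        1.0 - data["maternal_employed"].to_numpy()
    )
    for fieldname, rate in params.missing_rates.items():
        if rate <= 0:
            continue
        cols = _FIELD_COLUMNS[fieldname]
        if params.missing_mechanism == "mcar":
            p = np.full(n, rate)
        elif params.missing_mechanism == "mar":
            p = _mar_probabilities(rate, conf_score, params.mar_coef)
        else:  # mnar: depends on the field's own value
            first = data[cols[0]]
            z = (
                first.astype("category").cat.codes.to_numpy().astype(float)
                if first.dtype == object
                else first.to_numpy().astype(float)
            )
            p = _mar_probabilities(rate, z, params.mar_coef)
        mask = rng.random(n) < p
        for col in cols:
            if data[col].dtype == object:
                data.loc[mask, col] = None
            else:
                data[col] = data[col].astype(float)
                data.loc[mask, col] = np.nan
    return Cohort(data=data, latent=cohort.latent, cutoffs=cohort.cutoffs)


# ---------------------------------------------------------------------------
# Counterfactual oracle
# ---------------------------------------------------------------------------

_SETTINGS = {
    "p000": (0, 0, 0),
    "p100": (1, 0, 0),
    "p110": (1, 1, 0),
    "p111": (1, 1, 1),
}


def _setting_probability(
    params: StructuralParams, c: np.ndarray, x0: int, x1: int, x2: int
) -> np.ndarray:
    """P(Y(x0, M1(x1), M2(x2, M1(x2))) = 1 | C) for each confounder draw.

    The mediator value entering the outcome (set by ``x1``) and the mediator
    value inside M2's equation (set by ``x2``) are mixed independently —
    the cross-world convention targeted by the natural-effects estimator.
    """
    p1_x1 = params.alpha_m1.prob(c, x=x1)
    p1_x2 = params.alpha_m1.prob(c, x=x2)
    # marginal law of M2 under exposure copy x2
    p_m2 = (1 - p1_x2) * params.alpha_m2.prob(c, x=x2, m1=0) + p1_x2 * (
        params.alpha_m2.prob(c, x=x2, m1=1)
    )
    prob = np.zeros(len(c))
    for m1 in (0, 1):
        w1 = p1_x1 if m1 == 1 else 1 - p1_x1
        for m2 in (0, 1):
            w2 = p_m2 if m2 == 1 else 1 - p_m2
            prob += w1 * w2 * params.alpha_y.prob(c, x=x0, m1=m1, m2=m2)
    return prob


def oracle_effects(params: StructuralParams, n_mc: int, seed: int | None = None) -> TrueEffects:
    """Brute-force marginal natural effects via Monte Carlo over confounders.

    Draws ``n_mc`` confounder vectors, computes the four counterfactual
    outcome probabilities (index settings (0,0,0), (1,0,0), (1,1,0),
    (1,1,1)) in closed form given each draw, averages them over the
    confounder distribution, and forms odds ratios between successive
    settings:

    ``NDE = odds(1,0,0)/odds(0,0,0)``, ``NIE_M1 = odds(1,1,0)/odds(1,0,0)``,
    ``NIE_M2 = odds(1,1,1)/odds(1,1,0)``, ``joint = NIE_M1 * NIE_M2`` and
    ``TE = odds(1,1,1)/odds(0,0,0)`` (so TE = NDE * joint identically).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    sim = params.replace(n_children=max(int(n_mc), 1))
    c = _draw_confounders(sim, rng)

    probs = {k: _setting_probability(params, c, *s) for k, s in _SETTINGS.items()}
    pbar = {k: float(v.mean()) for k, v in probs.items()}
    degenerate = any(p <= 0.0 or p >= 1.0 for p in pbar.values())

    def odds(p):
        if p <= 0.0:
            return 0.0
        if p >= 1.0:
            return np.inf
        return p / (1 - p)

    o = {k: np.float64(odds(p)) for k, p in pbar.items()}  # 0/0 -> nan, not a crash
    with np.errstate(divide="ignore", invalid="ignore"):
        or_nde = o["p100"] / o["p000"]
        or_nie_m1 = o["p110"] / o["p100"]
        or_nie_m2 = o["p111"] / o["p110"]
        or_joint = or_nie_m1 * or_nie_m2
        or_te = o["p111"] / o["p000"]

    # delta-method MC standard errors for the log-ORs (settings share draws)
    mc_se = {}
    pairs = {
        "or_nde": ("p100", "p000"),
        "or_nie_m1": ("p110", "p100"),
        "or_nie_m2": ("p111", "p110"),
        "or_te": ("p111", "p000"),
    }
    for name, (ka, kb) in pairs.items():
        pa, pb = pbar[ka], pbar[kb]
        if degenerate:
            mc_se[name] = np.nan
            continue
        ga = 1.0 / (pa * (1 - pa))
        gb = -1.0 / (pb * (1 - pb))
        cov = np.cov(probs[ka], probs[kb]) / n_mc
        var = ga * ga * cov[0, 0] + 2 * ga * gb * cov[0, 1] + gb * gb * cov[1, 1]
        mc_se[name] = float(np.sqrt(max(var, 0.0)))
    if not degenerate:
        mc_se["or_nie_joint"] = float(
            np.sqrt(mc_se["or_nie_m1"] ** 2 + mc_se["or_nie_m2"] ** 2)
        )
    else:
        mc_se["or_nie_joint"] = np.nan

    return TrueEffects(
        or_te=float(or_te),
        or_nde=float(or_nde),
        or_nie_m1=float(or_nie_m1),
        or_nie_m2=float(or_nie_m2),
        or_nie_joint=float(or_joint),
        mc_se=mc_se,
        n_mc=int(n_mc),
        degenerate=degenerate,
    )
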