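"""Missingness testing and multiple imputation by chained equations.

:func:`littles_mcar_test` implements the classical chi-square test of
missing-completely-at-random: an EM fit of a multivariate normal to the
incomplete (numerically coerced) data, then a sum over missingness patterns
of Mahalanobis distances between pattern-wise observed means and the EM
means.  Binary/ordinal variables are treated as numeric under the normal
approximation, mirroring the common implementation in mainstream software.

:func:`chained_impute` is a self-contained chained-equations imputer with
logistic draws for binary variables, multinomial draws for categoricals and
predictive-mean matching for continuous variables; every conditional model
uses all other variables as predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "McarTestResult",
    "ImputationSet",
    "littles_mcar_test",
    "chained_impute",
    "compare_imputed",
]


@dataclass(frozen=True)
class McarTestResult:
    chi2: float
    df: int
    p: float
    n_patterns: int
    applicable: bool = True

    def reject(self, alpha: float = 0.05) -> bool:
        if not self.applicable:
            return False
        return self.p < alpha


def _coerce_numeric(df: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        ser = df[col]
        if ser.dtype == object or isinstance(ser.dtype, pd.CategoricalDtype):
            codes = ser.astype("category").cat.codes.astype(float)
            codes[ser.isna()] = np.nan
            out[col] = codes
        else:
            out[col] = ser.astype(float)
    return pd.DataFrame(out, index=df.index)


def _em_mvnorm(y: np.ndarray, max_iter: int = 200, tol: float = 1e-6):
    """EM estimates of mean and covariance of an MVN with missing entries."""
    n, p = y.shape
    miss = np.isnan(y)
    mu = np.nanmean(y, axis=0)
    filled = np.where(miss, mu, y)
    sigma = np.cov(filled, rowvar=False, bias=True)
    sigma += 1e-8 * np.eye(p)

    # group rows by missingness pattern once
    pattern_ids, pattern_index = np.unique(miss, axis=0, return_inverse=True)
    groups = [np.flatnonzero(pattern_index == g) for g in range(len(pattern_ids))]

    for _ in range(max_iter):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for g, rows in enumerate(groups):
            mis = pattern_ids[g]
            obs = ~mis
            yg = y[rows]
            if not mis.any():
                s1 += yg.sum(axis=0)
                s2 += yg.T @ yg
                continue
            if not obs.any():
                k = len(rows)
                s1 += k * mu
                s2 += k * (sigma + np.outer(mu, mu))
                continue
            soo = sigma[np.ix_(obs, obs)]
            smo = sigma[np.ix_(mis, obs)]
            smm = sigma[np.ix_(mis, mis)]
            coef = np.linalg.solve(soo, smo.T).T
            resid_cov = smm - coef @ smo.T
            yo = yg[:, obs]
            ym = mu[mis] + (yo - mu[obs]) @ coef.T
            full = np.empty_like(yg)
            full[:, obs] = yo
            full[:, mis] = ym
            s1 += full.sum(axis=0)
            cross = full.T @ full
            # add conditional covariance for the missing block
            idx = np.flatnonzero(mis)
            cross[np.ix_(idx, idx)] += len(rows) * resid_cov
            s2 += cross
        mu_new = s1 / n
        sigma_new = s2 / n - np.outer(mu_new, mu_new)
        sigma_new += 1e-10 * np.eye(p)
        shift = np.max(np.abs(mu_new - mu)) + np.max(np.abs(sigma_new - sigma))
        mu, sigma = mu_new, sigma_new
        if shift < tol:
            break
    return mu, sigma, pattern_ids, groups


def littles_mcar_test(table: pd.DataFrame) -> McarTestResult:
    """Little's chi-square test of missing completely at random.

    Statistic: ``sum_j n_j (ybar_obs,j - mu_obs,j)' S_obs,j^{-1}
    (ybar_obs,j - mu_obs,j)`` over missingness patterns ``j``, with ``mu``
    and ``S`` the EM estimates; df = (total observed variables over
    patterns) - (number of variables).  A complete table yields df = 0 and
    an inapplicable result.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two variables")
    num = _coerce_numeric(table)
    # drop constant columns (no information for the test) and all-missing rows
    keep = [c for c in num.columns if num[c].nunique(dropna=True) > 1]
    num = num[keep]
    num = num.loc[num.notna().any(axis=1)]
    y = num.to_numpy()
    n, p = y.shape
    if not np.isnan(y).any():
        return McarTestResult(chi2=0.0, df=0, p=np.nan, n_patterns=1, applicable=False)

    mu, sigma, pattern_ids, groups = _em_mvnorm(y)
    chi2 = 0.0
    df = 0
    n_patterns = 0
    for g, rows in enumerate(groups):
        obs = ~pattern_ids[g]
        if not obs.any():
            continue
        n_patterns += 1
        nj = len(rows)
        ybar = y[np.ix_(rows, np.flatnonzero(obs))].mean(axis=0)
        diff = ybar - mu[obs]
        soo = sigma[np.ix_(obs, obs)]
        try:
            sol = np.linalg.solve(soo, diff)
        except np.linalg.LinAlgError:
            warnings.warn("singular observed-block covariance; ridge-regularising")
            sol = np.linalg.solve(soo + 1e-6 * np.eye(obs.sum()), diff)
        chi2 += nj * float(diff @ sol)
        df += int(obs.sum())
    df -= p
    if df <= 0:
        return McarTestResult(chi2=float(chi2), df=max(df, 0), p=np.nan,
                              n_patterns=n_patterns, applicable=False)
    pval = float(stats.chi2.sf(chi2, df))
    return McarTestResult(chi2=float(chi2), df=df, p=pval, n_patterns=n_patterns)


# ---------------------------------------------------------------------------
# Chained-equations imputation
# ---------------------------------------------------------------------------


@dataclass
class ImputationSet:
    """``m`` completed datasets plus provenance."""

    datasets: list[pd.DataFrame]
    m: int
    n_iterations: int
    seed: int | None
    methods: dict[str, str]
    trace: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.m < 1 or len(self.datasets) != self.m:
            raise ValueError("m must match the number of completed datasets")
        for d in self.datasets:
            if d.isna().any().any():
                raise ValueError("completed datasets must have no missing cells")

    def to_csvs(self, directory: str | Path, prefix: str = "imputed") -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, d in enumerate(self.datasets, start=1):
            path = directory / f"{prefix}_{i}.csv"
            d.to_csv(path, index=False)
            paths.append(path)
        manifest = directory / f"{prefix}_manifest.json"
        import json

        manifest.write_text(
            json.dumps(
                {
                    "m": self.m,
                    "n_iterations": self.n_iterations,
                    "seed": self.seed,
                    "methods": self.methods,
                    "files": [p.name for p in paths],
                },
                indent=2,
            )
        )
        return paths


def _variable_method(ser: pd.Series) -> str:
    obs = ser.dropna()
    if ser.dtype == object or isinstance(ser.dtype, pd.CategoricalDtype):
        return "multinomial" if obs.nunique() > 2 else "logreg"
    uniq = obs.unique()
    if len(uniq) <= 2 and set(np.asarray(uniq, float)) <= {0.0, 1.0}:
        return "logreg"
    if obs.nunique() <= 10 and np.allclose(obs, obs.round()):
        return "multinomial"
    return "pmm"


def _design_matrix(df: pd.DataFrame, exclude: str) -> np.ndarray:
    parts = [np.ones((len(df), 1))]
    for col in df.columns:
        if col == exclude:
            continue
        ser = df[col]
        if ser.dtype == object or isinstance(ser.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(ser, drop_first=True, dtype=float)
            parts.append(dummies.to_numpy())
        else:
            parts.append(ser.to_numpy(float).reshape(-1, 1))
    return np.hstack(parts)


def _draw_coefficients(beta: np.ndarray, cov: np.ndarray, rng) -> np.ndarray:
    try:
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(beta)))
    except np.linalg.LinAlgError:
        chol = np.sqrt(np.maximum(np.diag(cov), 0) + 1e-10)[:, None] * np.eye(len(beta))
    return beta + chol @ rng.standard_normal(len(beta))


def _penalised_logit(x: np.ndarray, y: np.ndarray, alpha: float = 1e-2):
    """Ridge-penalised logistic fit by Newton iterations; returns beta, cov."""
    from scipy.special import expit

    p = x.shape[1]
    beta = np.zeros(p)
    for _ in range(50):
        eta = x @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-8)
        h = x.T @ (x * w[:, None]) + 2 * alpha * np.eye(p)
        g = x.T @ (y - mu) - 2 * alpha * beta
        step = np.linalg.solve(h, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    cov = np.linalg.inv(h)
    return beta, cov


def _impute_logreg(df, col, miss_rows, rng):
    import statsmodels.api as sm
    from scipy.special import expit

    x = _design_matrix(df, col)
    obs = df[col].notna() & ~miss_rows  # original observed rows only
    y = df.loc[obs, col].to_numpy(float)
    xo = x[obs.to_numpy()]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, xo, family=sm.families.Binomial()).fit()
        beta, cov = np.asarray(res.params), np.asarray(res.cov_params())
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 25:
            raise ValueError("separation")
    except Exception:
        warnings.warn(f"logistic model for {col!r} unstable; penalised fallback")
        beta, cov = _penalised_logit(xo, y)
    bstar = _draw_coefficients(beta, cov, rng)
    pmiss = expit(x[miss_rows.to_numpy()] @ bstar)
    return (rng.random(len(pmiss)) < pmiss).astype(float)


def _impute_multinomial(df, col, miss_rows, rng):
    """Multinomial draw via per-category one-vs-rest logistic scores."""
    from scipy.special import softmax

    x = _design_matrix(df, col)
    obs = df[col].notna() & ~miss_rows
    cats = pd.unique(df.loc[obs, col].dropna())
    scores = np.zeros((int(miss_rows.sum()), len(cats)))
    for j, cat in enumerate(cats[1:], start=1):
        y = (df.loc[obs, col] == cat).to_numpy(float)
        xo = x[obs.to_numpy()]
        beta, cov = _penalised_logit(xo, y, alpha=1e-2)
        bstar = _draw_coefficients(beta, cov, rng)
        scores[:, j] = x[miss_rows.to_numpy()] @ bstar
    probs = softmax(scores, axis=1)
    cum = probs.cumsum(axis=1)
    u = rng.random(len(probs))[:, None]
    picks = (u > cum).sum(axis=1)
    return np.asarray(cats, dtype=object)[picks]


def _impute_pmm(df, col, miss_rows, rng, k_donors: int = 5):
    x = _design_matrix(df, col)
    obs = df[col].notna() & ~miss_rows
    y = df.loc[obs, col].to_numpy(float)
    xo = x[obs.to_numpy()]
    xtx = xo.T @ xo + 1e-8 * np.eye(x.shape[1])
    beta = np.linalg.solve(xtx, xo.T @ y)
    resid = y - xo @ beta
    dof = max(len(y) - x.shape[1], 1)
    sigma2 = float(resid @ resid) / stats.chi2.rvs(dof, random_state=rng)
    cov = sigma2 * np.linalg.inv(xtx)
    bstar = _draw_coefficients(beta, cov, rng)
    pred_obs = xo @ beta
    pred_mis = x[miss_rows.to_numpy()] @ bstar
    order = np.argsort(pred_obs)
    sorted_pred = pred_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    out = np.empty(len(pred_mis))
    for i, ps in enumerate(pos):
        lo = max(ps - k_donors, 0)
        hi = min(ps + k_donors, len(y))
        window = order[lo:hi]
        dist = np.abs(pred_obs[window] - pred_mis[i])
        donors = window[np.argsort(dist)[:k_donors]]
        out[i] = y[donors[rng.integers(len(donors))]]
    return out


_IMPUTERS = {"logreg": _impute_logreg, "multinomial": _impute_multinomial, "pmm": _impute_pmm}


def chained_impute(
    table: pd.DataFrame,
    m: int = 20,
    n_iterations: int = 50,
    seed: int | None = None,
    methods: dict[str, str] | None = None,
) -> ImputationSet:
    """Multiple imputation by chained equations.

    One independent chain per imputation: missing cells are initialised by
    draws from the observed marginals, then the per-variable conditional
    models (all other variables as predictors) are cycled ``n_iterations``
    times and the final iterate kept.  Fixed seed => reproducible output.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    incomplete = [c for c in table.columns if table[c].isna().any()]
    for col in incomplete:
        if table[col].notna().sum() == 0:
            raise ValueError(f"variable {col!r} has no observed values")
    methods = methods or {}
    method_map = {
        col: methods.get(col, _variable_method(table[col])) for col in incomplete
    }
    for col, meth in method_map.items():
        if meth not in _IMPUTERS:
            raise ValueError(f"unknown method {meth!r} for {col!r}")

    if not incomplete:
        return ImputationSet(
            datasets=[table.copy() for _ in range(m)],
            m=m,
            n_iterations=n_iterations,
            seed=seed,
            methods={},
        )

    master = np.random.default_rng(seed)
    datasets = []
    trace_rows = []
    miss_masks = {col: table[col].isna() for col in incomplete}
    for chain in range(m):
        rng = np.random.default_rng(master.integers(2**63))
        work = table.copy()
        for col in incomplete:
            obs_vals = table[col].dropna().to_numpy()
            fill = obs_vals[rng.integers(0, len(obs_vals), int(miss_masks[col].sum()))]
            work.loc[miss_masks[col], col] = fill
        for it in range(n_iterations):
            for col in incomplete:
                work.loc[miss_masks[col], col] = np.nan
                imputed = _IMPUTERS[method_map[col]](work, col, miss_masks[col], rng)
                work.loc[miss_masks[col], col] = imputed
            for col in incomplete:
                cells = work.loc[miss_masks[col], col]
                mean = (
                    cells.astype("category").cat.codes.mean()
                    if cells.dtype == object
                    else float(np.mean(cells.to_numpy(float)))
                )
                trace_rows.append(
                    {"chain": chain, "iteration": it, "variable": col, "mean": mean}
                )
        datasets.append(work)
    trace = pd.DataFrame(trace_rows)
    return ImputationSet(
        datasets=datasets,
        m=m,
        n_iterations=n_iterations,
        seed=seed,
        methods=method_map,
        trace=trace,
    )


def compare_imputed(original: pd.DataFrame, imputation_set: ImputationSet) -> pd.DataFrame:
    """Observed-vs-imputed diagnostics per variable.

    For each originally incomplete variable: mean of observed cells, mean of
    imputed cells (pooled over imputations), standardised difference
    (difference over the observed standard deviation) and a two-sample
    t-test p-value.  Categorical variables are compared on category codes.
    """
    if list(original.columns) != list(imputation_set.datasets[0].columns):
        raise ValueError("schemas do not match")
    rows = []
    for col in original.columns:
        mask = original[col].isna()
        ser = original[col]
        if ser.dtype == object or isinstance(ser.dtype, pd.CategoricalDtype):
            cats = pd.unique(ser.dropna())
            codes = {c: i for i, c in enumerate(cats)}
            obs_vals = ser.dropna().map(codes).to_numpy(float)
            imp_vals = np.concatenate(
                [d.loc[mask, col].map(codes).to_numpy(float) for d in imputation_set.datasets]
            ) if mask.any() else np.array([])
        else:
            obs_vals = ser.dropna().to_numpy(float)
            imp_vals = (
                np.concatenate(
                    [d.loc[mask, col].to_numpy(float) for d in imputation_set.datasets]
                )
                if mask.any()
                else np.array([])
            )
        obs_mean = float(np.mean(obs_vals)) if len(obs_vals) else np.nan
        sd = float(np.std(obs_vals, ddof=1)) if len(obs_vals) > 1 else np.nan
        if len(imp_vals) == 0:
            rows.append(
                {
                    "variable": col,
                    "n_missing": 0,
                    "observed_mean": obs_mean,
                    "imputed_mean": np.nan,
                    "std_difference": 0.0,
                    "p_value": np.nan,
                }
            )
            continue
        imp_mean = float(np.mean(imp_vals))
        std_diff = (imp_mean - obs_mean) / sd if sd and sd > 0 else np.nan
        pval = float(stats.ttest_ind(obs_vals, imp_vals, equal_var=False).pvalue)
        rows.append(
            {
                "variable": col,
                "n_missing": int(mask.sum()),
                "observed_mean": obs_mean,
                "imputed_mean": imp_mean,
                "std_difference": float(std_diff),
                "p_value": pval,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
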