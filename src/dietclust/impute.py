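"""Multiple imputation by chained equations, with Rubin pooling.

Covariates are imputed at the subject level (they are recorded once per
subject, so the two visit rows must stay consistent).  The always-observed
predictors entering every conditional model are the per-visit mean systolic
and diastolic pressures (which encode both subject and visit) and sex.
Predictive mean matching keeps imputed categorical codes inside the observed
code set; the linear method draws from the Bayesian posterior predictive of
a normal regression.

Pooling follows Rubin's rules with the Barnard-Rubin small-sample degrees of
freedom; joint (multi-parameter) Wald tests are pooled with the D1
statistic of Li, Raghunathan and Rubin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import columns as C

__all__ = ["ImputationSpec", "ImputedStack", "impute", "pool_rubin", "pool_wald_d1",
           "PooledScalar"]


def default_methods() -> dict[str, str]:
    m = {v: "linear" for v in C.SUBJECT_COVARIATES if v != "sex"}
    for v in C.CATEGORICAL_COVARIATES:
        m[v] = "pmm"
    return m


@dataclass
class ImputationSpec:
    m: int = 20
    methods: dict[str, str] = field(default_factory=default_methods)
    pmm_donors: int = 5
    n_cycles: int = 10
    seed: int = 0
    # Complete variables entering every conditional model.  Defaults are the
    # per-visit mean blood pressures plus sex; they are built from the cohort
    # by `impute` and must be complete.
    predictors: tuple[str, ...] = ("sbp_age20", "sbp_age22", "dbp_age20", "dbp_age22", "is_male")

    def validate(self) -> None:
        if self.m < 2:
            raise ValueError("need at least m = 2 imputations")
        if self.pmm_donors < 1:
            raise ValueError("pmm_donors must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        for v, meth in self.methods.items():
            if meth not in ("pmm", "linear"):
                raise ValueError(f"unknown imputation method {meth!r} for {v!r}")


@dataclass
class ImputedStack:
    """m completed copies of the cohort plus per-variable diagnostics."""

    datasets: list[pd.DataFrame]
    diagnostics: pd.DataFrame
    spec: ImputationSpec

    @property
    def m(self) -> int:
        return len(self.datasets)


def _subject_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: covariates + always-observed BP/sex predictors."""
    from .derive import average_bp  # local import to avoid cycle at module load

    work = cohort.copy()
    work["_sbp"] = average_bp(work[C.SBP_READINGS].to_numpy())
    work["_dbp"] = average_bp(work[C.DBP_READINGS].to_numpy())
    first = work.groupby("subject_id").first()
    sub = first[[v for v in C.SUBJECT_COVARIATES if v != "sex"]].copy()
    sbp = work.pivot(index="subject_id", columns="visit", values="_sbp")
    dbp = work.pivot(index="subject_id", columns="visit", values="_dbp")
    for visit in sbp.columns:
        sub[f"sbp_{visit}"] = sbp[visit]
        sub[f"dbp_{visit}"] = dbp[visit]
    sub["is_male"] = (first["sex"] == "male").astype(float)
    return sub


def _bayes_regression_draw(x_obs, y_obs, rng):
    """OLS fit plus a posterior draw of (beta, sigma^2)."""
    beta, _, rank, _ = np.linalg.lstsq(x_obs, y_obs, rcond=None)
    resid = y_obs - x_obs @ beta
    df = max(x_obs.shape[0] - rank, 1)
    s2 = float(resid @ resid) / df
    sigma2_star = float(resid @ resid) / rng.chisquare(df) if s2 > 0 else 0.0
    xtx_inv = np.linalg.pinv(x_obs.T @ x_obs)
    cov = sigma2_star * xtx_inv
    # symmetrize for numerical safety before the Cholesky-free draw
    cov = (cov + cov.T) / 2.0
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
        beta_star = beta + chol @ rng.normal(size=beta.shape)
    except np.linalg.LinAlgError:
        beta_star = beta
    return beta, beta_star, sigma2_star


def _impute_once(sub: pd.DataFrame, incomplete: list[str], spec: ImputationSpec,
                 rng: np.random.Generator) -> pd.DataFrame:
    data = sub.copy()
    obs_mask = {v: sub[v].notna().to_numpy() for v in incomplete}
    # initialize missing cells by draws from the observed margin
    for v in incomplete:
        obs_vals = sub.loc[obs_mask[v], v].to_numpy()
        n_mis = int((~obs_mask[v]).sum())
        data.loc[~obs_mask[v], v] = rng.choice(obs_vals, size=n_mis, replace=True)

    order = sorted(incomplete, key=lambda v: ((~obs_mask[v]).sum(), v))
    pred_cols = list(spec.predictors)
    for _ in range(spec.n_cycles):
        for v in order:
            others = [c for c in incomplete if c != v]
            xcols = others + pred_cols
            x = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(float) for c in xcols])
            y = data[v].to_numpy(float)
            obs = obs_mask[v]
            beta, beta_star, sigma2_star = _bayes_regression_draw(x[obs], y[obs], rng)
            if spec.methods.get(v, "linear") == "pmm":
                yhat_obs = x[obs] @ beta
                yhat_mis = x[~obs] @ beta_star
                donors = min(spec.pmm_donors, obs.sum())
                dist = np.abs(yhat_obs[None, :] - yhat_mis[:, None])
                part = np.argpartition(dist, donors - 1, axis=1)[:, :donors]
                pick = part[np.arange(part.shape[0]), rng.integers(0, donors, part.shape[0])]
                data.loc[~obs, v] = y[obs][pick]
            else:
                draw = x[~obs] @ beta_star + np.sqrt(sigma2_star) * rng.normal(size=int((~obs).sum()))
                data.loc[~obs, v] = draw
    return data


def impute(cohort: pd.DataFrame, spec: ImputationSpec | None = None) -> ImputedStack:
    """Create ``spec.m`` completed copies of the cohort.

    Each copy runs an independent chained-equations chain (random margin
    initialization, ``n_cycles`` sweeps over the incomplete covariates in
    ascending-missingness order).  Observed cells are never altered.
    """
    spec = spec or ImputationSpec()
    spec.validate()
    sub = _subject_frame(cohort)
    for p in spec.predictors:
        if p not in sub.columns:
            raise ValueError(f"predictor {p!r} not available")
        if sub[p].isna().any():
            raise ValueError(f"imputation predictor {p!r} has missing values")
    candidates = [v for v in C.SUBJECT_COVARIATES if v != "sex"]
    incomplete = [v for v in candidates if sub[v].isna().any()]
    for v in incomplete:
        if sub[v].notna().sum() == 0:
            raise ValueError(f"covariate {v!r} is 100% missing; nothing to learn from")

    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(spec.m)]
    datasets = []
    for rng in rngs:
        if incomplete:
            completed_sub = _impute_once(sub, incomplete, spec, rng)
        else:
            completed_sub = sub.copy()
        full = cohort.copy()
        for v in candidates:
            full[v] = completed_sub[v].reindex(full["subject_id"]).to_numpy()
        datasets.append(full)

    rows = []
    for v in incomplete:
        obs = sub[v].notna()
        imputed_means = [d.groupby("subject_id")[v].first()[~obs].mean() for d in datasets]
        rows.append({
            "variable": v,
            "n_missing": int((~obs).sum()),
            "observed_mean": float(sub.loc[obs, v].mean()),
            "imputed_mean": float(np.mean(imputed_means)),
            "method": spec.methods.get(v, "linear"),
        })
    diagnostics = pd.DataFrame(rows, columns=["variable", "n_missing", "observed_mean",
                                              "imputed_mean", "method"])
    return ImputedStack(datasets=datasets, diagnostics=diagnostics, spec=spec)


@dataclass
class PooledScalar:
    estimate: float
    se: float
    t_total: float      # total variance T = W + (1 + 1/m) B
    w_within: float
    b_between: float
    df: float
    p: float            # two-sided p for H0: estimate = 0
    ci_lo: float
    ci_hi: float


def pool_rubin(estimates: Sequence[float], variances: Sequence[float],
               dfcom: Optional[float] = None, alpha: float = 0.05) -> PooledScalar:
    """Rubin's rules for a scalar estimand across m imputations.

    T = W + (1 + 1/m) B; degrees of freedom are Barnard-Rubin when the
    complete-data df ``dfcom`` is supplied, otherwise the classical
    (m - 1) / lambda^2.
    """
    est = np.asarray(estimates, float)
    var = np.asarray(variances, float)
    m = est.size
    if m < 2:
        raise ValueError("pooling requires at least 2 imputations")
    if var.size != m:
        raise ValueError("estimates and variances differ in length")
    if np.any(var <= 0):
        raise ValueError("variances must be positive")
    qbar = float(est.mean())
    w = float(var.mean())
    b = float(est.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    lam = (1.0 + 1.0 / m) * b / t if t > 0 else 0.0
    if lam <= 0:
        df = np.inf if dfcom is None else float(dfcom)
    else:
        df_old = (m - 1) / lam**2
        if dfcom is None:
            df = df_old
        else:
            df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    se = float(np.sqrt(t))
    tstat = qbar / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(tstat), df)) if np.isfinite(df) else float(2 * stats.norm.sf(abs(tstat)))
    crit = stats.t.ppf(1 - alpha / 2, df) if np.isfinite(df) else stats.norm.ppf(1 - alpha / 2)
    return PooledScalar(qbar, se, t, w, b, float(df), p, qbar - crit * se, qbar + crit * se)


def pool_wald_d1(estimates: Sequence[np.ndarray], covariances: Sequence[np.ndarray]):
    """D1 pooled multivariate Wald test that a k-vector estimand is zero.

    Returns (statistic, df1, df2, p); the statistic is F-distributed under
    the null.
    """
    qs = [np.asarray(q, float) for q in estimates]
    us = [np.asarray(u, float) for u in covariances]
    m = len(qs)
    if m < 2:
        raise ValueError("pooling requires at least 2 imputations")
    k = qs[0].size
    qbar = np.mean(qs, axis=0)
    ubar = np.mean(us, axis=0)
    b = np.zeros((k, k))
    for q in qs:
        d = (q - qbar)[:, None]
        b += d @ d.T
    b /= m - 1
    ubar_inv = np.linalg.pinv(ubar)
    r = (1.0 + 1.0 / m) * np.trace(b @ ubar_inv) / k
    d1 = float(qbar @ ubar_inv @ qbar) / (k * (1.0 + r))
    t = k * (m - 1.0)
    if t > 4:
        df2 = 4.0 + (t - 4.0) * (1.0 + (1.0 - 2.0 / t) / r) ** 2 if r > 0 else np.inf
    else:
        df2 = t * (1.0 + 1.0 / k) * (1.0 + 1.0 / r) ** 2 / 2.0 if r > 0 else np.inf
    p = float(stats.f.sf(d1, k, df2)) if np.isfinite(df2) else float(stats.chi2.sf(k * d1, k))
    return d1, k, float(df2), p
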