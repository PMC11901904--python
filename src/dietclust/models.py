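"""Cluster-outcome association models.

Gaussian GLMs on the stacked two-visit data (two rows per subject), with
both exposure factors — the spread cluster and the fatty-acid cluster —
entered together as categorical variables.  Standard errors are
cluster-robust by subject (sandwich covariance with the small-sample factor
G/(G-1) * (N-1)/(N-p)).  Log-scale outcomes (lipids, HOMA-IR) are modelled
as natural-log transforms, so coefficients exponentiate to geometric-mean
ratios reported as percent changes.

A familywise gate controls multiplicity within each exposure factor: the
joint Wald test that all of the factor's coefficients are zero is assessed
at alpha, and individual reference contrasts are inferential only when the
gate passes.  Across imputations, scalar coefficients pool by Rubin's rules
and the gate pools by the D1 statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .impute import ImputedStack, pool_rubin, pool_wald_d1

__all__ = ["ModelSpec", "GlmFit", "fit_glm", "ratio_report", "familywise_gate",
           "run_analysis", "MODEL2_ADJUSTMENT"]

# Confounder set for the adjusted model: age, adiposity, family history,
# diet-pattern factor scores, fruit/vegetable frequency, alcohol, sodium,
# activity (METs and category).
MODEL2_ADJUSTMENT = [
    "age",
    "waist_hip_ratio",
    "family_history_hbp",
    "healthy_diet_score",
    "western_diet_score",
    "fruit_category",
    "vegetable_category",
    "alcohol_g_day",
    "sodium_mg_day",
    "mets_per_week",
    "pa_category",
]


@dataclass
class ModelSpec:
    outcome: str
    scale: str = "identity"          # "identity" | "log"
    name: str = "model1"
    adjust: list[str] = field(default_factory=list)
    fa_column: str = "fa_cluster"
    spread_column: str = "spread_cluster"
    fa_ref: int = 0
    spread_ref: int = 0
    alpha: float = 0.05

    def validate(self) -> None:
        if self.scale not in ("identity", "log"):
            raise ValueError(f"unknown scale {self.scale!r}")


@dataclass
class GlmFit:
    params: pd.Series
    cov: pd.DataFrame
    terms: dict[str, list[str]]      # factor -> its dummy column names
    factor_levels: dict[str, list]   # factor -> non-reference levels, same order
    nobs: int
    n_groups: int
    df_resid: float
    spec: ModelSpec
    design: pd.DataFrame = None
    groups: np.ndarray = None
    resid: np.ndarray = None

    def small_sample(self, cols: Sequence[str]) -> "SmallSampleInference":
        """Bias-reduced (CR2) cluster covariance and effective degrees of
        freedom for the given coefficient subset (cached per subset)."""
        key = tuple(cols)
        cache = getattr(self, "_ss_cache", None)
        if cache is None:
            cache = self._ss_cache = {}
        if key not in cache:
            cache[key] = _small_sample_inference(self, list(cols))
        return cache[key]


@dataclass
class SmallSampleInference:
    """CR2 covariance with Wishart-matched effective df.

    The usual one-step sandwich estimates each coefficient's variance from
    the clusters that actually carry that contrast, so a joint Wald
    statistic referred to chi-square is anti-conservative when factor
    levels hold only a few dozen subjects each.  This applies the
    bias-reduced CR2 cluster adjustment and matches the first two moments
    of the covariance estimator to a Wishart distribution, yielding an
    approximate Hotelling T^2 reference: F = Q (nu - k + 1) / (nu k) with
    Q the Wald quadratic form on the CR2 covariance.  For a single
    coefficient the df reduces to the Bell-McCaffrey / Satterthwaite value.
    """

    cols: list[str]
    cov: np.ndarray          # CR2 covariance of the selected coefficients
    nu: float                # joint effective df (Wishart moment matching)
    nu_per_coef: np.ndarray  # Satterthwaite df per selected coefficient


def _cr2_adjustments(x: np.ndarray, groups: np.ndarray, m_inv: np.ndarray):
    """Per-cluster CR2 blocks: yields (rows, A_i X_i, X_i) with
    A_i = (I - H_ii)^{-1/2} symmetric."""
    order = np.argsort(groups, kind="stable")
    boundaries = np.flatnonzero(np.diff(groups[order])) + 1
    for rows in np.split(order, boundaries):
        xi = x[rows]
        hii = xi @ m_inv @ xi.T
        w, q = np.linalg.eigh(np.eye(len(rows)) - hii)
        w = np.where(w > 1e-12, 1.0 / np.sqrt(np.clip(w, 1e-12, None)), 0.0)
        ai = (q * w) @ q.T
        yield rows, ai @ xi, xi


def _small_sample_inference(fit: GlmFit, cols: list[str]) -> SmallSampleInference:
    x = fit.design.to_numpy(float)
    u = fit.resid
    groups = fit.groups
    m_inv = np.linalg.inv(x.T @ x)
    idx = [fit.design.columns.get_loc(c) for c in cols]
    cm = m_inv[idx, :]                      # k x p contrast rows
    chol = np.linalg.cholesky(m_inv)        # M = L L'
    k, p = cm.shape[0], x.shape[1]

    v_cr2 = np.zeros((k, k))
    omega = np.zeros((k, k))
    tr_s = []
    w_blocks = []
    for rows, axi, xi in _cr2_adjustments(x, groups, m_inv):
        ti = cm @ axi.T                     # k x n_i
        gi = ti @ u[rows]
        v_cr2 += np.outer(gi, gi)
        si = ti @ ti.T
        wi = ti @ xi @ chol                 # k x p
        omega += si - wi @ wi.T
        tr_s.append(si)
        w_blocks.append(wi)

    # normalize by Omega^{-1/2} and Wishart-match E[tr(Vbar^2)]
    ew, eq = np.linalg.eigh(omega)
    ew = np.clip(ew, 1e-12, None)
    om_isqrt = (eq / np.sqrt(ew)) @ eq.T
    s_hat = np.array([om_isqrt @ s @ om_isqrt for s in tr_s])          # G x k x k
    w_hat = np.array([om_isqrt @ w for w in w_blocks])                 # G x k x p
    tr_shat = np.einsum("gaa->g", s_hat)
    w_vec = w_hat.reshape(len(w_hat), -1)
    gram = w_vec @ w_vec.T                                             # P_ij
    diag_tr = tr_shat - np.einsum("ij,ij->i", w_vec, w_vec)
    denom1 = float(np.sum(gram**2) - np.sum(np.diag(gram) ** 2) + np.sum(diag_tr**2))
    c4 = np.einsum("gai,gbj->aibj", w_hat, w_hat)                      # k,p,k,p
    cross_sq = float(np.einsum("aibj,ajbi->", c4, c4))
    diag_d = s_hat - np.einsum("gai,gbi->gab", w_hat, w_hat)
    diag_sq = float(np.einsum("gab,gba->", diag_d, diag_d))
    own_sq = float(sum(np.trace((w.T @ w) @ (w.T @ w)) for w in w_hat))
    denom2 = cross_sq - own_sq + diag_sq
    nu = k * (k + 1) / max(denom1 + denom2, 1e-12)

    # per-coefficient Satterthwaite (Bell-McCaffrey) df: the k = 1 case of
    # the same moment matching, on the unnormalized scale
    s_arr = np.array(tr_s)                                             # G x k x k
    w_arr = np.array(w_blocks)                                         # G x k x p
    nus = np.empty(k)
    for j in range(k):
        wj = w_arr[:, j, :]                                            # G x p
        d_diag = s_arr[:, j, j] - np.einsum("gi,gi->g", wj, wj)
        gram_j = wj @ wj.T
        total = float(np.sum(gram_j**2) - np.sum(np.diag(gram_j) ** 2)
                      + np.sum(d_diag**2))
        nus[j] = float(np.sum(d_diag)) ** 2 / max(total, 1e-300)
    return SmallSampleInference(cols=list(cols), cov=v_cr2, nu=float(nu),
                                nu_per_coef=nus)


def _build_design(data: pd.DataFrame, spec: ModelSpec):
    y = data[spec.outcome].to_numpy(float)
    if spec.scale == "log":
        if np.any(y <= 0):
            raise ValueError(f"log-scale outcome {spec.outcome!r} has non-positive values")
        y = np.log(y)
    x = pd.DataFrame(index=data.index)
    x["const"] = 1.0
    terms: dict[str, list[str]] = {}
    levels: dict[str, list] = {}
    for factor, ref in ((spec.fa_column, spec.fa_ref), (spec.spread_column, spec.spread_ref)):
        if factor not in data.columns:
            continue
        lv = sorted(data[factor].unique())
        if ref not in lv:
            raise ValueError(f"reference level {ref!r} absent from {factor!r}")
        cols, nonref = [], []
        for level in lv:
            if level == ref:
                continue
            col = f"{factor}[{level}]"
            x[col] = (data[factor] == level).astype(float)
            cols.append(col)
            nonref.append(level)
        terms[factor] = cols
        levels[factor] = nonref
    for cov in spec.adjust:
        x[cov] = data[cov].to_numpy(float)
    return y, x, terms, levels


def _collinear_columns(x: pd.DataFrame) -> list[str]:
    q, r = np.linalg.qr(x.to_numpy(float))
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    return [x.columns[i] for i in np.flatnonzero(diag < tol)]


def fit_glm(data: pd.DataFrame, spec: ModelSpec) -> GlmFit:
    """Fit one Gaussian GLM with subject-clustered robust covariance.

    ``data`` must be complete (one imputed dataset) with two stacked rows
    per subject; groups for the sandwich are ``subject_id``.
    """
    spec.validate()
    if data[spec.outcome].isna().any():
        raise ValueError("model data contain missing outcome values")
    y, x, terms, levels = _build_design(data, spec)
    if np.linalg.matrix_rank(x.to_numpy(float)) < x.shape[1]:
        raise ValueError(f"singular design; collinear columns: {_collinear_columns(x)}")
    groups = data["subject_id"].to_numpy()
    n_groups = len(np.unique(groups))
    if n_groups < x.shape[1]:
        warnings.warn(
            f"fewer clusters ({n_groups}) than parameters ({x.shape[1]}); "
            "cluster-robust inference is unreliable", stacklevel=2)
    res = sm.OLS(y, x).fit(
        cov_type="cluster",
        cov_kwds={"groups": groups, "use_correction": True},
    )
    return GlmFit(
        params=pd.Series(res.params, index=x.columns),
        cov=pd.DataFrame(res.cov_params(), index=x.columns, columns=x.columns),
        terms=terms,
        factor_levels=levels,
        nobs=int(res.nobs),
        n_groups=n_groups,
        df_resid=float(res.nobs - x.shape[1]),
        spec=spec,
        design=x,
        groups=groups,
        resid=np.asarray(res.resid),
    )


def ratio_report(beta_log: float, se: float, z: float = 1.959963984540054) -> dict:
    """Geometric-mean-ratio reporting transform for a log-scale coefficient:
    ratio = exp(beta), percent change = 100 (exp(beta) - 1), CI from the
    exponentiated normal bounds."""
    ratio = float(np.exp(beta_log))
    return {
        "ratio": ratio,
        "pct_change": 100.0 * (ratio - 1.0),
        "ci_lo": float(np.exp(beta_log - z * se)),
        "ci_hi": float(np.exp(beta_log + z * se)),
    }


def familywise_gate(fit: GlmFit, factor: str, alpha: float = 0.05) -> dict:
    """Familywise joint test that every coefficient of ``factor`` is zero.

    The Wald quadratic form is built on the bias-reduced (CR2) cluster
    covariance and referred to an approximate Hotelling T^2 distribution
    with Wishart-matched effective df (see :class:`SmallSampleInference`);
    each factor level holds only a few dozen subjects, so the plain
    chi-square reference would be anti-conservative.  Pairwise reference
    contrasts are inferential only when the gate passes; on failure they
    are still returned, flagged non-inferential.
    """
    cols = fit.terms.get(factor)
    if not cols:
        raise ValueError(f"factor {factor!r} has no non-reference levels to test")
    b = fit.params[cols].to_numpy()
    df = len(cols)
    ss = fit.small_sample(cols)
    stat = float(b @ np.linalg.solve(ss.cov, b))
    df2 = max(ss.nu - df + 1.0, 1.0)
    fstat = stat * df2 / (ss.nu * df)
    p = float(stats.f.sf(fstat, df, df2))
    passed = p < alpha
    v = fit.cov.loc[cols, cols].to_numpy()
    contrasts = pd.DataFrame({
        "level": fit.factor_levels[factor],
        "estimate": b,
        "se": np.sqrt(np.diag(v)),
    })
    contrasts["p"] = 2 * stats.norm.sf(np.abs(contrasts["estimate"] / contrasts["se"]))
    contrasts["inferential"] = passed
    return {"statistic": stat, "df": df, "df2": df2, "nu": ss.nu, "p": p,
            "passed": passed, "contrasts": contrasts}


def _pool_factor(fits: list[GlmFit], factor: str, spec: ModelSpec, sex: str) -> list[dict]:
    """Rubin-pool every coefficient of one factor plus its D1 gate.

    Scalar pooling and the D1 gate both use the small-sample (CR2)
    covariances, with the complete-data df taken from the Satterthwaite
    values of the first imputation's design.
    """
    cols = fits[0].terms[factor]
    levels = fits[0].factor_levels[factor]
    ref = spec.fa_ref if factor == spec.fa_column else spec.spread_ref
    sss = [f.small_sample(cols) for f in fits]
    bs = [f.params[cols].to_numpy() for f in fits]
    vs = [ss.cov for ss in sss]
    if len(fits) >= 2:
        stat, k, df2, gate_p = pool_wald_d1(bs, vs)
        # cap the denominator df at the complete-data Hotelling value
        df2_cap = max(sss[0].nu - k + 1.0, 1.0)
        if df2 > df2_cap:
            gate_p = float(stats.f.sf(stat, k, df2_cap))
    else:
        f = familywise_gate(fits[0], factor, spec.alpha)
        gate_p = f["p"]
    passed = gate_p < spec.alpha
    rows = []
    for j, (col, level) in enumerate(zip(cols, levels)):
        est = [b[j] for b in bs]
        var = [v[j, j] for v in vs]
        dfcom = sss[0].nu_per_coef[j]
        if len(fits) >= 2:
            pooled = pool_rubin(est, var, dfcom=dfcom, alpha=spec.alpha)
            estimate, se, p = pooled.estimate, pooled.se, pooled.p
            ci_lo, ci_hi = pooled.ci_lo, pooled.ci_hi
        else:
            estimate, se = est[0], float(np.sqrt(var[0]))
            tstat = estimate / se
            p = float(2 * stats.t.sf(abs(tstat), dfcom))
            crit = stats.t.ppf(1 - spec.alpha / 2, dfcom)
            ci_lo, ci_hi = estimate - crit * se, estimate + crit * se
        row = {
            "outcome": spec.outcome, "scale": spec.scale, "sex": sex,
            "model": spec.name, "factor": factor, "cluster": level, "reference": ref,
            "estimate": estimate, "se": se, "ci_lo": ci_lo, "ci_hi": ci_hi, "p": p,
            "gate_p": gate_p, "gate_passed": passed, "m": len(fits),
            "ratio": np.nan, "pct_change": np.nan,
        }
        if spec.scale == "log":
            row["ratio"] = float(np.exp(estimate))
            row["pct_change"] = 100.0 * (row["ratio"] - 1.0)
            row["ci_lo"], row["ci_hi"] = float(np.exp(ci_lo)), float(np.exp(ci_hi))
        rows.append(row)
    return rows


def run_analysis(stack: ImputedStack | Sequence[pd.DataFrame],
                 specs: Sequence[ModelSpec],
                 sexes: tuple[str, ...] = ("male", "female")) -> pd.DataFrame:
    """Fit every model spec on every imputed dataset, separately by sex, and
    pool.  Returns a tidy table with one row per outcome x sex x model x
    factor x non-reference cluster: the pooled coefficient (mean difference,
    or geometric-mean ratio with percent change for log outcomes), robust
    SE, 95% CI, p, and the factor's familywise gate."""
    datasets = stack.datasets if isinstance(stack, ImputedStack) else list(stack)
    if not datasets:
        raise ValueError("no datasets to analyse")
    rows = []
    for spec in specs:
        for sex in sexes:
            fits = []
            for d in datasets:
                part = d[d["sex"] == sex]
                if part.empty:
                    raise ValueError(f"no rows for sex {sex!r}")
                fits.append(fit_glm(part, spec))
            for factor in fits[0].terms:
                rows.extend(_pool_factor(fits, factor, spec, sex))
    return pd.DataFrame(rows)


def default_model_specs(adjust: Optional[list[str]] = None,
                        fa_ref: int = 0, spread_ref: int = 0) -> list[ModelSpec]:
    """The standard outcome panel: BP outcomes on the identity scale, lipid
    and insulin-resistance outcomes on the log (geometric-mean-ratio) scale;
    one unadjusted and one confounder-adjusted model each."""
    adjust = MODEL2_ADJUSTMENT if adjust is None else adjust
    outcomes = [
        ("derived_sbp", "identity"),
        ("derived_dbp", "identity"),
        ("derived_pp", "identity"),
        ("triglycerides", "log"),
        ("total_cholesterol", "log"),
        ("hdl_cholesterol", "log"),
        ("derived_non_hdl", "log"),
        ("derived_homa_ir", "log"),
    ]
    specs = []
    for outcome, scale in outcomes:
        specs.append(ModelSpec(outcome, scale, "model1", [], fa_ref=fa_ref, spread_ref=spread_ref))
        specs.append(ModelSpec(outcome, scale, "model2", list(adjust),
                               fa_ref=fa_ref, spread_ref=spread_ref))
    return specs
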