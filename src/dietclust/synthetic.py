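"""Synthetic cohort generator.

Emulates a repeat cross-sectional cohort of young adults measured at two
visits (ages 20 and 22): correlated log-normal fatty-acid intakes with
planted cluster structure, zero-inflated fat-spread usage with distinct
per-cluster usage patterns, complete outcome panels generated from additive
cluster effects, and covariates with missing-at-random gaps driven by sex
and blood pressure.  Planted labels are retained so downstream clustering
and modelling can be scored against a known truth.

The generator is deterministic given its seed: named sub-streams are spawned
from one :class:`numpy.random.SeedSequence` so each block of randomness is
independently replayable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import columns as C

__all__ = ["EffectSpec", "GeneratorConfig", "generate_cohort", "planted_truth"]

# Spread usage archetypes: (pattern name, {spread type: median g/day}).
# Cluster 0 is always the no-spread pattern; the remaining patterns differ in
# which spread types are used (structural zeros elsewhere) and how heavily.
_MODERATE, _HIGH = 7.0, 22.0
SPREAD_PATTERNS = [
    ("none", {}),
    ("mod_marg_blend", {"Marg": _MODERATE, "Marg_butter_blends": _MODERATE}),
    ("butter", {"Butter": _MODERATE}),
    ("mod_marg", {"Marg": _MODERATE}),
    ("high_blends", {"Marg_butter_blends": _HIGH}),
    ("high_marg", {"Marg": _HIGH}),
    ("marg_poly", {"Marg": _MODERATE, "Polyunsaturated_marg": _MODERATE}),
    ("poly_mono", {"Polyunsaturated_marg": _MODERATE, "Monounsaturated_marg": _MODERATE}),
    ("marg_butter", {"Marg": _MODERATE, "Butter": _MODERATE}),
    ("butter_blend", {"Butter": _MODERATE, "Marg_butter_blends": _MODERATE}),
]

# Outcomes a planted cluster effect may target.  Identity-scale effects are in
# the outcome's units (mmHg); log-scale effects are log geometric-mean ratios.
IDENTITY_OUTCOMES = ("sbp", "dbp")
LOG_OUTCOMES = ("triglycerides", "hdl_cholesterol", "non_hdl", "glucose", "insulin")


@dataclass(frozen=True)
class EffectSpec:
    """One planted cluster effect on one outcome, optionally sex-specific."""

    factor: str          # "fa" or "spread"
    cluster: int         # planted cluster id
    outcome: str         # one of IDENTITY_OUTCOMES or LOG_OUTCOMES
    value: float         # mmHg for identity outcomes, log-ratio otherwise
    sex: Optional[str] = None  # "male", "female", or None for both


def default_effect_table() -> tuple[EffectSpec, ...]:
    """Planted effects mirroring the magnitudes this kind of cohort shows:
    butter / high-margarine spread patterns raise male blood pressure and
    triglycerides; several fatty-acid patterns lower female HDL."""
    ln = np.log
    return (
        EffectSpec("spread", 2, "sbp", 4.26, "male"),
        EffectSpec("spread", 5, "sbp", 6.61, "male"),
        EffectSpec("spread", 5, "dbp", 3.4, "male"),
        EffectSpec("spread", 5, "triglycerides", ln(1.264), "male"),
        EffectSpec("spread", 6, "triglycerides", ln(1.305), "male"),
        EffectSpec("spread", 7, "triglycerides", ln(1.221), "male"),
        EffectSpec("spread", 8, "triglycerides", ln(1.291), "male"),
        EffectSpec("fa", 1, "hdl_cholesterol", ln(1 - 0.124), "female"),
        EffectSpec("fa", 2, "hdl_cholesterol", ln(1 - 0.101), "female"),
        EffectSpec("fa", 3, "hdl_cholesterol", ln(1 - 0.140), "female"),
        EffectSpec("fa", 4, "hdl_cholesterol", ln(1 - 0.150), "female"),
        EffectSpec("fa", 5, "hdl_cholesterol", ln(1 - 0.160), "female"),
    )


def default_missing_rates() -> dict[str, float]:
    """Covariate missingness proportions typical of questionnaire follow-up
    (fruit/vegetable and diet scores from an earlier survey wave are the
    gappiest; clinic measures are complete)."""
    return {
        "family_history_hbp": 0.08,
        "healthy_diet_score": 0.18,
        "western_diet_score": 0.18,
        "fruit_category": 0.19,
        "vegetable_category": 0.19,
        "alcohol_g_day": 0.135,
        "sodium_mg_day": 0.18,
        "smoking": 0.08,
        "mets_per_week": 0.10,
        "pa_category": 0.10,
    }


@dataclass
class GeneratorConfig:
    """Everything the generator needs; defaults describe a cohort of n = 785
    young adults with 8 fatty-acid patterns and 10 spread-usage patterns.

    ``cluster_separation`` is the maximal per-variable gap between cluster
    mean log-intakes, in within-cluster SD units: each planted cluster shifts
    a signature subset of roughly one third of the fatty acids by
    +-separation/2 SD, so two clusters differ by at most ``separation`` SD on
    any one fatty acid.
    """

    n_subjects: int = 785
    n_fatty_acids: int = 31
    n_spread_types: int = 5
    n_fa_clusters: int = 8
    n_spread_clusters: int = 10
    cluster_separation: float = 3.0
    within_subject_corr: float = 0.6
    effect_table: tuple[EffectSpec, ...] = field(default_factory=default_effect_table)
    missing_rates: dict[str, float] = field(default_factory=default_missing_rates)
    seed: int = 0

    # Log-intake noise structure: marginal SD of log intake, shared-factor
    # variance fraction (multicollinearity), and number of shared factors.
    fa_log_sd: float = 0.5
    fa_shared_variance: float = 0.3
    fa_n_factors: int = 3
    fa_log_covariance: Optional[np.ndarray] = None  # optional override, p x p

    # Blood pressure calibration (mmHg).
    male_sbp_mean: float = 122.2
    female_sbp_mean: float = 111.7
    sbp_sd: float = 11.0
    male_dbp_mean: float = 65.1
    female_dbp_mean: float = 65.9
    dbp_sd: float = 7.3
    visit2_sbp_shift: float = 1.7
    visit2_dbp_shift: float = 1.6
    reading_noise_sd: float = 3.0
    first_reading_shift: float = 4.0  # first seated reading runs high

    prob_male: float = 0.521

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be at least 4")
        if self.n_fa_clusters < 2 or self.n_spread_clusters < 2:
            raise ValueError("need at least 2 planted clusters per factor")
        if not 0.0 <= self.within_subject_corr <= 1.0:
            raise ValueError("within_subject_corr must be in [0, 1]")
        if not 0.0 <= self.fa_shared_variance < 1.0:
            raise ValueError("fa_shared_variance must be in [0, 1)")
        if self.cluster_separation < 0:
            raise ValueError("cluster_separation must be non-negative")
        for k, v in self.missing_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"missing rate for {k!r} outside [0, 1]")
        if self.fa_log_covariance is not None:
            cov = np.asarray(self.fa_log_covariance, float)
            if cov.shape != (self.n_fatty_acids, self.n_fatty_acids):
                raise ValueError("fa_log_covariance has the wrong shape")
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                raise ValueError("fa_log_covariance is not positive definite") from None
        for e in self.effect_table:
            if e.factor == "fa":
                if not 0 <= e.cluster < self.n_fa_clusters:
                    raise ValueError(f"effect names unknown fatty-acid cluster {e.cluster}")
            elif e.factor == "spread":
                if not 0 <= e.cluster < self.n_spread_clusters:
                    raise ValueError(f"effect names unknown spread cluster {e.cluster}")
            else:
                raise ValueError(f"unknown effect factor {e.factor!r}")
            if e.outcome not in IDENTITY_OUTCOMES + LOG_OUTCOMES:
                raise ValueError(f"unknown effect outcome {e.outcome!r}")
            if e.sex not in (None, "male", "female"):
                raise ValueError(f"unknown sex {e.sex!r}")


def _fa_covariance_root(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Matrix square root of the shared log-intake covariance (unit marginal
    variances; low-rank factor structure induces the multicollinearity that
    makes per-nutrient regression adjustment hopeless)."""
    p = config.n_fatty_acids
    if config.fa_log_covariance is not None:
        return np.linalg.cholesky(np.asarray(config.fa_log_covariance, float))
    c, q = config.fa_shared_variance, config.fa_n_factors
    load = rng.normal(size=(p, q))
    load = load / np.linalg.norm(load, axis=1, keepdims=True) * np.sqrt(c)
    root = np.zeros((p, p + q))
    root[:, :q] = load
    root[:, q:] = np.sqrt(1.0 - c) * np.eye(p)
    return root


def _fa_cluster_means(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Cluster mean log-intake profiles: each cluster's signature subset of
    fatty acids is shifted by +-separation/2 within-cluster SDs."""
    k, p = config.n_fa_clusters, config.n_fatty_acids
    n_sig = max(3, int(round(p / 3)))
    mus = np.zeros((k, p))
    for ci in range(k):
        idx = rng.choice(p, n_sig, replace=False)
        mus[ci, idx] = rng.choice([-1.0, 1.0], n_sig) * config.cluster_separation / 2.0
    return mus


def _spread_patterns(config: GeneratorConfig, rng: np.random.Generator):
    """Usage patterns for the requested number of spread clusters; extends the
    canonical archetypes with random subset/intensity combinations if more
    clusters are requested than archetypes exist."""
    types = C.SPREAD_TYPES[: config.n_spread_types]
    pats = [(n, {t: g for t, g in d.items() if t in types}) for n, d in SPREAD_PATTERNS]
    pats = [pats[0]] + [p for p in pats[1:] if p[1]]
    want = config.n_spread_clusters
    while len(pats) < want:
        size = int(rng.integers(1, min(3, len(types)) + 1))
        sub = rng.choice(len(types), size, replace=False)
        level = float(rng.choice([_MODERATE, _HIGH]))
        pats.append((f"extra_{len(pats)}", {types[i]: level for i in sub}))
    return pats[:want]


def _two_visit_normals(rng: np.random.Generator, rho: float, shape) -> tuple[np.ndarray, np.ndarray]:
    """Pairs of standard normals with correlation rho between the visits."""
    shared = rng.normal(size=shape)
    a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
    return (a * shared + b * rng.normal(size=shape),
            a * shared + b * rng.normal(size=shape))


def _calibrated_mar_mask(rate: float, score: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli missingness with P(miss) = expit(a + score), intercept a
    solved so the expected marginal rate equals ``rate``."""
    if rate <= 0:
        return np.zeros(score.size, bool)
    if rate >= 1:
        return np.ones(score.size, bool)
    f = lambda a: expit(a + score).mean() - rate
    a = brentq(f, -30.0, 30.0)
    return rng.random(score.size) < expit(a + score)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a long-format cohort table (two rows per subject).

    Returns a DataFrame with the column groups of :mod:`dietclust.columns`,
    including the planted ``true_fa_cluster`` / ``true_spread_cluster``
    labels.  Byte-identical for a fixed config.
    """
    config.validate()
    n = config.n_subjects
    rho = config.within_subject_corr
    streams = np.random.SeedSequence(config.seed).spawn(6)
    r_struct, r_intake, r_spread, r_outcome, r_covar, r_miss = (
        np.random.default_rng(s) for s in streams
    )

    # --- planted structure (drawn once per seed) -------------------------
    cov_root = _fa_covariance_root(config, r_struct)
    fa_means = _fa_cluster_means(config, r_struct)
    spread_pats = _spread_patterns(config, r_struct)

    fa_lab = r_intake.integers(0, config.n_fa_clusters, size=n)
    spread_lab = r_spread.integers(0, config.n_spread_clusters, size=n)
    sex = np.where(r_covar.random(n) < config.prob_male, "male", "female")
    male = sex == "male"

    # --- fatty-acid intakes ---------------------------------------------
    p = config.n_fatty_acids
    nfac = cov_root.shape[1]
    z1, z2 = _two_visit_normals(r_intake, rho, (n, nfac))
    base = np.log(np.asarray(C.FATTY_ACID_BASELINES_G_DAY[:p]))
    if p > len(C.FATTY_ACID_BASELINES_G_DAY):
        raise ValueError("more fatty acids requested than named columns exist")
    mu = fa_means[fa_lab]
    fa_v1 = np.exp(base + config.fa_log_sd * (mu + z1 @ cov_root.T))
    fa_v2 = np.exp(base + config.fa_log_sd * (mu + z2 @ cov_root.T))

    # --- spread intakes (structural zeros outside the cluster pattern) ---
    types = C.SPREAD_TYPES[: config.n_spread_types]
    sp_v1 = np.zeros((n, len(types)))
    sp_v2 = np.zeros((n, len(types)))
    e1, e2 = _two_visit_normals(r_spread, rho, (n, len(types)))
    for ci, (_, pat) in enumerate(spread_pats):
        members = spread_lab == ci
        for tj, t in enumerate(types):
            if t in pat:
                sp_v1[members, tj] = pat[t] * np.exp(0.35 * e1[members, tj])
                sp_v2[members, tj] = pat[t] * np.exp(0.35 * e2[members, tj])
    uses_none = np.array([len(spread_pats[c][1]) == 0 for c in spread_lab], float)

    # --- planted outcome effects ----------------------------------------
    def effect_for(outcome: str) -> np.ndarray:
        eff = np.zeros(n)
        for e in config.effect_table:
            if e.outcome != outcome:
                continue
            members = (fa_lab if e.factor == "fa" else spread_lab) == e.cluster
            if e.sex is not None:
                members = members & (male if e.sex == "male" else ~male)
            eff[members] += e.value
        return eff

    # --- blood pressure --------------------------------------------------
    def bp_readings(mean_m, mean_f, sd, visit2_shift, outcome):
        base_mean = np.where(male, mean_m, mean_f) + effect_for(outcome)
        u1, u2 = _two_visit_normals(r_outcome, rho, (n,))
        out = []
        for visit, u in ((0, u1), (1, u2)):
            true_level = base_mean + visit * visit2_shift + sd * u
            readings = true_level[:, None] + config.reading_noise_sd * r_outcome.normal(size=(n, 6))
            readings[:, 0] += config.first_reading_shift
            out.append(readings)
        return out

    sbp1, sbp2 = bp_readings(config.male_sbp_mean, config.female_sbp_mean,
                             config.sbp_sd, config.visit2_sbp_shift, "sbp")
    dbp1, dbp2 = bp_readings(config.male_dbp_mean, config.female_dbp_mean,
                             config.dbp_sd, config.visit2_dbp_shift, "dbp")

    # --- serum biochemistry (log-normal; HDL and non-HDL generated
    # separately so total = HDL + non-HDL holds with total > HDL) ---------
    def lognormal_outcome(median_m, median_f, sigma, outcome, visit2_ratio=1.0):
        mu0 = np.log(np.where(male, median_m, median_f)) + effect_for(outcome)
        u1, u2 = _two_visit_normals(r_outcome, rho, (n,))
        return (np.exp(mu0 + sigma * u1),
                np.exp(np.log(visit2_ratio) + mu0 + sigma * u2))

    trig1, trig2 = lognormal_outcome(0.97, 1.00, 0.42, "triglycerides", 1.0)
    hdl1, hdl2 = lognormal_outcome(1.21, 1.41, 0.19, "hdl_cholesterol", 1.02)
    nh1, nh2 = lognormal_outcome(2.83, 2.97, 0.24, "non_hdl", 1.08)
    glu1, glu2 = lognormal_outcome(4.7, 4.5, 0.075, "glucose", 1.0)
    ins1, ins2 = lognormal_outcome(8.0, 8.5, 0.45, "insulin", 1.0)

    # --- covariates -------------------------------------------------------
    age1 = r_covar.normal(19.95, 0.42, n)
    age2 = age1 + r_covar.normal(2.16, 0.20, n)
    w1, w2 = _two_visit_normals(r_covar, 0.8, (n,))
    whr_mean = np.where(male, 0.87, 0.77)
    whr1, whr2 = whr_mean + 0.06 * w1, whr_mean + 0.06 * w2
    fam = (r_covar.random(n) < 0.311).astype(float)
    healthy = r_covar.normal(0.07, 0.90, n)
    western = np.where(male, 0.26, -0.36) + r_covar.normal(0.0, 0.78, n)
    fruit = r_covar.binomial(4, np.where(male, 0.72, 0.78)).astype(float)
    veg = r_covar.binomial(4, np.where(male, 0.82, 0.86)).astype(float)
    drinks = r_covar.random(n) >= 0.30
    alcohol = np.where(drinks, np.exp(np.log(12.0) + 0.9 * r_covar.normal(size=n)), 0.0)
    sodium = np.clip(r_covar.normal(np.where(male, 3441, 2530), 1100), 300, None)
    smoking = (r_covar.random(n) < np.where(male, 0.162, 0.123)).astype(float)
    mets = np.exp(np.log(1200.0) + 0.8 * r_covar.normal(size=n))
    pa = r_covar.choice(3, size=n, p=[0.30, 0.45, 0.25]).astype(float)

    subj_cov = pd.DataFrame({
        "sex": sex,
        "family_history_hbp": fam,
        "healthy_diet_score": healthy,
        "western_diet_score": western,
        "fruit_category": fruit,
        "vegetable_category": veg,
        "alcohol_g_day": alcohol,
        "sodium_mg_day": sodium,
        "smoking": smoking,
        "mets_per_week": mets,
        "pa_category": pa,
    })

    # --- MAR missingness: depends only on sex and mean SBP (always
    # observed), so chained-equation imputation is correctly specified -----
    mean_sbp = (sbp1[:, 1:].mean(axis=1) + sbp2[:, 1:].mean(axis=1)) / 2.0
    zscore = (mean_sbp - mean_sbp.mean()) / mean_sbp.std()
    mar_score = 0.5 * zscore + 0.4 * male.astype(float)
    for var, rate in config.missing_rates.items():
        if var not in subj_cov.columns:
            raise ValueError(f"missing rate given for unknown covariate {var!r}")
        mask = _calibrated_mar_mask(rate, mar_score, r_miss)
        subj_cov.loc[mask, var] = np.nan

    # --- assemble long table ---------------------------------------------
    ids = np.arange(n)
    rows = []
    for visit, fa, sp, sbp, dbp, trg, hd, nh, gl, ins, age, whr in (
        ("age20", fa_v1, sp_v1, sbp1, dbp1, trig1, hdl1, nh1, glu1, ins1, age1, whr1),
        ("age22", fa_v2, sp_v2, sbp2, dbp2, trig2, hdl2, nh2, glu2, ins2, age2, whr2),
    ):
        df = pd.DataFrame({"subject_id": ids, "visit": visit})
        df[C.FATTY_ACIDS[:p]] = fa
        df[C.SPREAD_NONE] = uses_none
        df[types] = sp
        df[C.SBP_READINGS] = sbp
        df[C.DBP_READINGS] = dbp
        df["triglycerides"] = trg
        df["hdl_cholesterol"] = hd
        df["total_cholesterol"] = hd + nh
        df["glucose"] = gl
        df["insulin"] = ins
        df["age"] = age
        df["waist_hip_ratio"] = whr
        for c in subj_cov.columns:
            df[c] = subj_cov[c].to_numpy()
        df["true_fa_cluster"] = fa_lab
        df["true_spread_cluster"] = spread_lab
        rows.append(df)
    cohort = pd.concat(rows, ignore_index=True)
    cohort = cohort.sort_values(["subject_id", "visit"], kind="stable").reset_index(drop=True)
    return cohort


def planted_truth(cohort: pd.DataFrame, factor: str = "fa") -> pd.Series:
    """Planted cluster label per subject, for recovery scoring.

    Parameters
    ----------
    factor:
        ``"fa"`` for the fatty-acid clusters, ``"spread"`` for the
        spread-usage clusters.
    """
    col = {"fa": "true_fa_cluster", "spread": "true_spread_cluster"}.get(factor)
    if col is None:
        raise ValueError(f"unknown factor {factor!r}")
    if col not in cohort.columns:
        raise ValueError(f"cohort has no planted-truth column {col!r}")
    truth = cohort.groupby("subject_id")[col].first()
    truth.name = col
    return truth
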