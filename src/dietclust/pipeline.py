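"""End-to-end orchestration: generate/load -> derive -> cluster (fatty acids
and spreads) -> describe -> impute -> model -> report.

All randomness flows from one global seed through named sub-streams, so a
fixed configuration reproduces the result bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from . import columns as C
from .derive import IntakeMatrix, build_intake_matrix, derive_outcomes
from .graph import KnnParams, build_graph, knn_search
from .impute import ImputationSpec, ImputedStack, impute
from .louvain import LouvainParams, Partition, louvain, relabel_by_size
from .models import ModelSpec, default_model_specs, run_analysis
from .synthetic import GeneratorConfig, generate_cohort

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig", "PipelineResult", "run_pipeline", "cluster_subjects",
    "describe_cohort", "profile_clusters", "crosstab_association",
    "choose_reference_clusters", "write_cohort", "load_config",
]


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    input_csv: Optional[str] = None          # load instead of generate
    knn: KnnParams = field(default_factory=KnnParams)
    louvain: LouvainParams = field(default_factory=LouvainParams)
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    adjust: list[str] = None                 # model-2 confounders (None = default)
    spread_layout: str = "by_visit"
    outdir: Optional[str] = None
    seed: int = 0

    def resolve_seeds(self) -> None:
        """Derive per-stage seeds from the global seed (stages stay
        independently replayable)."""
        state = np.random.SeedSequence(self.seed).generate_state(3)
        self.generator.seed = int(state[0] % 2**31)
        self.louvain.seed = int(state[1] % 2**31)
        self.imputation.seed = int(state[2] % 2**31)


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    fa_matrix: IntakeMatrix
    spread_matrix: IntakeMatrix
    fa_partition: Partition
    spread_partition: Partition
    crosstab: dict
    fa_profile: pd.DataFrame
    spread_profile: pd.DataFrame
    description: pd.DataFrame
    stack: ImputedStack
    results: pd.DataFrame
    config: RunConfig


def cluster_subjects(matrix: IntakeMatrix, knn: KnnParams, louvain_params: LouvainParams) -> Partition:
    """One clustering run: K-NN search, network construction, Louvain, and
    size-ordered relabelling."""
    neighbors = knn_search(matrix, knn)
    graph = build_graph(neighbors, matrix, knn)
    part = louvain(graph, louvain_params)
    part = relabel_by_size(part)
    log.info("clustering: %d communities, Q = %.4f (trace %s)",
             part.n_communities, part.q, np.round(part.q_trace, 4))
    return part


# Declared variable types for the two-sample sex comparison: "normal" -> t
# test, "skewed" -> Mann-Whitney U, "categorical" -> chi-square.
DEFAULT_VARIABLE_TYPES = {
    "age": "normal",
    "waist_hip_ratio": "normal",
    "derived_sbp": "normal",
    "derived_dbp": "normal",
    "derived_pp": "normal",
    "triglycerides": "skewed",
    "total_cholesterol": "normal",
    "hdl_cholesterol": "normal",
    "derived_non_hdl": "normal",
    "derived_homa_ir": "skewed",
    "healthy_diet_score": "normal",
    "western_diet_score": "normal",
    "sodium_mg_day": "normal",
    "alcohol_g_day": "skewed",
    "mets_per_week": "skewed",
    "fruit_category": "categorical",
    "vegetable_category": "categorical",
    "family_history_hbp": "categorical",
    "smoking": "categorical",
    "pa_category": "categorical",
    "derived_htn_stage": "categorical",
}


def describe_cohort(cohort: pd.DataFrame, variable_types: Optional[dict] = None) -> pd.DataFrame:
    """Summary-table description by sex with a two-sample test per variable.

    Continuous variables report mean (SD) and median (IQR); categorical ones
    report the modal frequency.  The test is chosen by the declared type.
    Missing values are dropped pairwise.
    """
    vt = DEFAULT_VARIABLE_TYPES if variable_types is None else variable_types
    male = cohort[cohort["sex"] == "male"]
    female = cohort[cohort["sex"] == "female"]
    rows = []
    for var, kind in vt.items():
        if var not in cohort.columns:
            continue
        a = male[var].dropna()
        b = female[var].dropna()
        if kind == "categorical":
            tab = pd.crosstab(cohort["sex"], cohort[var])
            if tab.shape[1] < 2:
                p = 1.0
            else:
                p = float(stats.chi2_contingency(tab.to_numpy(), correction=False)[1])
            rows.append({"variable": var, "type": kind,
                         "male_summary": str(a.mode().iloc[0]) if len(a) else "",
                         "female_summary": str(b.mode().iloc[0]) if len(b) else "",
                         "p": p})
            continue
        an, bn = a.to_numpy(float), b.to_numpy(float)
        if kind == "normal":
            if an.mean() == bn.mean() and an.var() == bn.var():
                p = 1.0
            else:
                p = float(stats.ttest_ind(an, bn).pvalue)
            summ = lambda v: f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"
        else:
            p = float(stats.mannwhitneyu(an, bn).pvalue)
            q = lambda v: np.percentile(v, [50, 25, 75])
            summ = lambda v: "{:.2f} ({:.2f}-{:.2f})".format(*q(v))
        rows.append({"variable": var, "type": kind,
                     "male_summary": summ(an), "female_summary": summ(bn), "p": p})
    return pd.DataFrame(rows)


def profile_clusters(matrix: IntakeMatrix, partition: Partition) -> pd.DataFrame:
    """Per-cluster intake profiles: standardized and raw means per variable,
    cluster sizes, and a one-way across-cluster difference test (ANOVA on the
    standardized values) per variable."""
    if partition.labels.size != matrix.n:
        raise ValueError("partition does not cover the matrix rows")
    z = matrix.values
    raw = matrix.destandardize()
    labels = partition.labels
    k = partition.n_communities
    sizes = partition.sizes
    rows = []
    for vi, var in enumerate(matrix.variables):
        groups = [z[labels == c, vi] for c in range(k)]
        if k > 1 and labels.size > k:
            p = float(stats.f_oneway(*groups).pvalue)
        else:
            p = np.nan
        for c in range(k):
            rows.append({
                "cluster": c, "size": int(sizes[c]), "variable": var,
                "mean_standardized": float(z[labels == c, vi].mean()),
                "mean_raw": float(raw[labels == c, vi].mean()),
                "across_cluster_p": p,
            })
    return pd.DataFrame(rows)


def crosstab_association(labels_a: np.ndarray, labels_b: np.ndarray) -> dict:
    """Chi-square association between two partitions of the same subjects;
    df = (k_a - 1)(k_b - 1)."""
    tab = pd.crosstab(pd.Series(labels_a), pd.Series(labels_b))
    chi2, p, df, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    return {"chi2": float(chi2), "df": int(df), "p": float(p), "table": tab}


def choose_reference_clusters(fa_profile: pd.DataFrame, spread_profile: pd.DataFrame) -> tuple[int, int]:
    """Data-driven reference levels: the fatty-acid reference is the cluster
    with the lowest saturated-fat and highest omega-3 standardized intake
    (the low-saturated/high n-3 pattern); the spread reference is the
    cluster with the highest no-spread indicator."""
    fa = fa_profile.copy()
    fa["is_sat"] = fa["variable"].isin(C.SATURATED_FAS)
    fa["is_n3"] = fa["variable"].isin(C.N3_FAS)
    score = (fa[fa["is_sat"]].groupby("cluster")["mean_standardized"].mean()
             - fa[fa["is_n3"]].groupby("cluster")["mean_standardized"].mean())
    fa_ref = int(score.idxmin())
    none_rows = spread_profile[spread_profile["variable"].str.startswith(C.SPREAD_NONE)]
    spread_ref = int(none_rows.groupby("cluster")["mean_raw"].mean().idxmax())
    return fa_ref, spread_ref


def write_cohort(cohort: pd.DataFrame, path, config: Optional[GeneratorConfig] = None) -> None:
    """Write the cohort CSV with a data-dictionary sidecar and, when the
    cohort was generated, a provenance header file echoing the config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)
    with open(path.with_suffix(".dictionary.yaml"), "w") as fh:
        yaml.safe_dump(C.column_dictionary(), fh, sort_keys=True)
    if config is not None:
        with open(path.with_suffix(".provenance.yaml"), "w") as fh:
            yaml.safe_dump({"generator": _config_dict(config),
                            "dietclust_version": __version__}, fh, sort_keys=True)


def _config_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _config_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _config_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_config_dict(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and (optionally) write the result bundle.

    Stages: generate or load the cohort; derive outcomes; cluster subjects
    twice (fatty-acid profiles, then spread-usage profiles); cross-tabulate
    the two partitions; profile the clusters; describe the cohort by sex;
    multiply impute the covariates; fit and pool the association models.
    Any stage error aborts with a stage-tagged message.
    """
    config.resolve_seeds()

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if config.input_csv is not None:
        cohort = _stage("load", lambda: pd.read_csv(config.input_csv))
    else:
        cohort = _stage("generate", lambda: generate_cohort(config.generator))
    cohort = _stage("derive", lambda: derive_outcomes(cohort))

    fa_matrix = _stage("fa_matrix", lambda: build_intake_matrix(cohort, "fatty_acids"))
    fa_part = _stage("fa_cluster", lambda: cluster_subjects(fa_matrix, config.knn, config.louvain))
    sp_matrix = _stage("spread_matrix", lambda: build_intake_matrix(
        cohort, "spreads", spread_layout=config.spread_layout))
    sp_part = _stage("spread_cluster", lambda: cluster_subjects(sp_matrix, config.knn, config.louvain))

    xtab = _stage("crosstab", lambda: crosstab_association(fa_part.labels, sp_part.labels))
    fa_profile = _stage("fa_profile", lambda: profile_clusters(fa_matrix, fa_part))
    sp_profile = _stage("spread_profile", lambda: profile_clusters(sp_matrix, sp_part))
    description = _stage("describe", lambda: describe_cohort(cohort))

    fa_map = pd.Series(fa_part.labels, index=fa_part.subjects)
    sp_map = pd.Series(sp_part.labels, index=sp_part.subjects)
    cohort["fa_cluster"] = cohort["subject_id"].map(fa_map)
    cohort["spread_cluster"] = cohort["subject_id"].map(sp_map)

    stack = _stage("impute", lambda: impute(cohort, config.imputation))
    fa_ref, sp_ref = choose_reference_clusters(fa_profile, sp_profile)
    specs = default_model_specs(adjust=config.adjust, fa_ref=fa_ref, spread_ref=sp_ref)
    results = _stage("model", lambda: run_analysis(stack, specs))

    result = PipelineResult(cohort, fa_matrix, sp_matrix, fa_part, sp_part, xtab,
                            fa_profile, sp_profile, description, stack, results, config)
    if config.outdir is not None:
        _stage("write", lambda: _write_bundle(result, Path(config.outdir)))
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_cohort(result.cohort, outdir / "cohort.csv",
                 None if result.config.input_csv else result.config.generator)
    result.fa_partition.to_dataframe().to_csv(outdir / "fa_partition.csv", index=False)
    result.spread_partition.to_dataframe().to_csv(outdir / "spread_partition.csv", index=False)
    result.fa_profile.to_csv(outdir / "fa_profile.csv", index=False)
    result.spread_profile.to_csv(outdir / "spread_profile.csv", index=False)
    result.description.to_csv(outdir / "describe.csv", index=False)
    result.results.to_csv(outdir / "results.csv", index=False)
    result.stack.diagnostics.to_csv(outdir / "imputation_diagnostics.csv", index=False)
    result.crosstab["table"].to_csv(outdir / "cluster_crosstab.csv")
    prov = {
        "seed": result.config.seed,
        "config": _config_dict(dataclasses.replace(result.config, outdir=None)),
        "fa_modularity": float(result.fa_partition.q),
        "spread_modularity": float(result.spread_partition.q),
        "fa_n_clusters": int(result.fa_partition.n_communities),
        "spread_n_clusters": int(result.spread_partition.n_communities),
        "crosstab_chi2": result.crosstab["chi2"],
        "crosstab_df": result.crosstab["df"],
        "dietclust_version": __version__,
    }
    with open(outdir / "provenance.yaml", "w") as fh:
        yaml.safe_dump(prov, fh, sort_keys=True)


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    sections = {
        "generator": (cfg.generator, GeneratorConfig),
        "knn": (cfg.knn, KnnParams),
        "louvain": (cfg.louvain, LouvainParams),
        "imputation": (cfg.imputation, ImputationSpec),
    }
    for key, value in raw.items():
        if key in sections:
            target, cls = sections[key]
            fields = {f.name for f in dataclasses.fields(cls)}
            for k, v in (value or {}).items():
                if k not in fields:
                    raise ValueError(f"unknown {key} option {k!r}")
                setattr(target, k, v)
        elif key in ("input_csv", "adjust", "spread_layout", "outdir", "seed"):
            setattr(cfg, key, value)
        else:
            raise ValueError(f"unknown config section {key!r}")
    return cfg
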