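"""Derived outcomes and exposure matrices.

Implements the outcome derivations applied before any modelling: the
clinic blood-pressure average that discards the first of six seated
readings, HOMA-IR, non-HDL cholesterol, hypertension staging, and the
visit-averaged standardized intake matrix used for neighbor search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import columns as C

__all__ = [
    "average_bp",
    "homa_ir",
    "non_hdl",
    "stage_hypertension",
    "derive_outcomes",
    "IntakeMatrix",
    "build_intake_matrix",
]

HOMA_IR_DENOMINATOR = 22.5


def average_bp(readings) -> np.ndarray | float:
    """Mean clinic pressure from a panel of six seated readings.

    The first reading (minute 0) is discarded — it runs systematically high —
    and the five readings at minutes 2 to 10 are averaged.  Accepts a single
    panel of 6 or an (n, 6) array; anything else is an error, never padded.
    """
    arr = np.asarray(readings, dtype=float)
    if arr.ndim == 1:
        if arr.shape[0] != 6:
            raise ValueError(f"expected 6 readings, got {arr.shape[0]}")
        return float(arr[1:].mean())
    if arr.ndim == 2 and arr.shape[1] == 6:
        return arr[:, 1:].mean(axis=1)
    raise ValueError(f"expected 6 readings per panel, got shape {arr.shape}")


def homa_ir(insulin, glucose):
    """Homeostasis-model insulin-resistance index:
    fasting insulin (mU/L) x fasting glucose (mmol/L) / 22.5."""
    ins = np.asarray(insulin, dtype=float)
    glu = np.asarray(glucose, dtype=float)
    if np.any(ins <= 0) or np.any(glu <= 0):
        raise ValueError("insulin and glucose must be positive")
    out = ins * glu / HOMA_IR_DENOMINATOR
    return float(out) if out.ndim == 0 else out


def non_hdl(total_chol, hdl):
    """Non-HDL cholesterol (mmol/L): total minus HDL cholesterol."""
    tot = np.asarray(total_chol, dtype=float)
    h = np.asarray(hdl, dtype=float)
    if np.any(h < 0):
        raise ValueError("HDL cholesterol must be non-negative")
    if np.any(h > tot):
        raise ValueError("HDL cholesterol exceeds total cholesterol")
    out = tot - h
    return float(out) if out.ndim == 0 else out


def stage_hypertension(sbp, dbp):
    """Hypertension stage from mean clinic pressures.

    stage2 if SBP >= 140 or DBP >= 90; stage1 if SBP in [130, 140) or
    DBP in [80, 90); otherwise none.
    """
    s = np.asarray(sbp, dtype=float)
    d = np.asarray(dbp, dtype=float)
    if np.any(s <= 0) or np.any(d <= 0):
        raise ValueError("pressures must be positive")
    out = np.where(
        (s >= 140) | (d >= 90), "stage2",
        np.where((s >= 130) | (d >= 80), "stage1", "none"),
    )
    return str(out[()]) if out.ndim == 0 else out


def derive_outcomes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append every derived outcome column (prefix ``derived_``) to a copy of
    the cohort table: mean SBP/DBP, pulse pressure, HOMA-IR, non-HDL
    cholesterol and hypertension stage."""
    out = cohort.copy()
    out["derived_sbp"] = average_bp(cohort[C.SBP_READINGS].to_numpy())
    out["derived_dbp"] = average_bp(cohort[C.DBP_READINGS].to_numpy())
    out["derived_pp"] = out["derived_sbp"] - out["derived_dbp"]
    out["derived_homa_ir"] = homa_ir(cohort["insulin"], cohort["glucose"])
    out["derived_non_hdl"] = non_hdl(cohort["total_cholesterol"], cohort["hdl_cholesterol"])
    out["derived_htn_stage"] = stage_hypertension(out["derived_sbp"], out["derived_dbp"])
    return out


@dataclass
class IntakeMatrix:
    """Per-subject intake feature matrix for neighbor search.

    ``values`` is n_subjects x p; when ``standardized`` the per-column means
    and SDs of the raw matrix are kept so profiles can be reported on the
    g/day scale as well.
    """

    values: np.ndarray
    subjects: np.ndarray
    variables: list[str]
    standardized: bool
    raw_means: np.ndarray
    raw_sds: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def destandardize(self) -> np.ndarray:
        if not self.standardized:
            return self.values.copy()
        return self.values * self.raw_sds + self.raw_means


def _visit_average(cohort: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    counts = cohort.groupby("subject_id")["visit"].count()
    bad = counts[counts != 2]
    if len(bad):
        raise ValueError(
            "every subject must appear at exactly 2 visits; offending subject_ids: "
            + ", ".join(str(i) for i in bad.index[:20])
        )
    return cohort.groupby("subject_id")[cols].mean()


def build_intake_matrix(
    cohort: pd.DataFrame,
    variable_set: str,
    standardize: bool = True,
    spread_layout: str = "by_visit",
) -> IntakeMatrix:
    """Build the exposure matrix for one clustering run.

    Parameters
    ----------
    variable_set:
        ``"fatty_acids"`` — visit-averaged intake of each fatty acid;
        ``"spreads"`` — spread intakes plus the no-spread indicator.
    spread_layout:
        ``"by_visit"`` (default) keeps the two visits as separate columns
        (6 variables x 2 ages = 12); ``"averaged"`` averages them (6).
    standardize:
        z-score each column (zero mean, unit SD); off means raw g/day.
    """
    if variable_set == "fatty_acids":
        fa_cols = [c for c in C.FATTY_ACIDS if c in cohort.columns]
        wide = _visit_average(cohort, fa_cols)
    elif variable_set == "spreads":
        sp_cols = [c for c in C.SPREADS if c in cohort.columns]
        if spread_layout == "averaged":
            wide = _visit_average(cohort, sp_cols)
        elif spread_layout == "by_visit":
            _visit_average(cohort, sp_cols[:1])  # enforce the 2-visit invariant
            wide = cohort.pivot(index="subject_id", columns="visit", values=sp_cols)
            wide.columns = [f"{v}_{visit}" for v, visit in wide.columns]
        else:
            raise ValueError(f"unknown spread_layout {spread_layout!r}")
    else:
        raise ValueError(f"unknown variable_set {variable_set!r}")

    values = wide.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("intake matrix contains missing values")
    means = values.mean(axis=0)
    sds = values.std(axis=0)
    if standardize:
        zero = np.flatnonzero(sds == 0)
        if zero.size:
            names = [wide.columns[i] for i in zero]
            raise ValueError(f"cannot standardize zero-variance column(s): {names}")
        values = (values - means) / sds
    return IntakeMatrix(
        values=values,
        subjects=wide.index.to_numpy(),
        variables=list(wide.columns),
        standardized=standardize,
        raw_means=means,
        raw_sds=sds,
    )
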