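"""Risk-count prognostic index (PIM) and the comparison stratifiers.

A PIM index is a binary normal/risk status (by default the dichotomized
texture signature and the AST flag); the PIM score is the count of indices
at risk and strata are low (0), intermediate (1) and high (>= 2).  The
same counting rule drives the clinical-factor comparison model (AST +
CEA).  Also here: the Glasgow Prognostic Score (CRP > 10 mg/L,
albumin < 35 g/L) and the RECIST tumor-response grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.base import BaseEstimator

__all__ = [
    "DEFAULT_CUTOFFS",
    "dichotomize_clinical",
    "select_pim_indices",
    "compute_pim",
    "pim_scores",
    "compute_gps",
    "stratify_clinical_model",
    "stratify_response",
    "PIMModel",
    "GPSResult",
    "PrognosticIndex",
    "STRATUM_LABELS",
]

NORMAL, RISK = "normal", "risk"
STRATUM_LABELS = ["low", "intermediate", "high"]
RECIST_LABELS = ("CR", "PR", "SD", "PD")

#: variable -> (threshold, direction, source).  ``direction`` is the side
#: that counts as risk; risk requires STRICT exceedance (boundary = normal).
#: Only the smoking cut-off (cohort median, 9600 cigarettes) is anchored in
#: the emulated study; the rest are conventional reference limits and are
#: meant to be overridden from config where local practice differs.
DEFAULT_CUTOFFS: dict[str, tuple] = {
    "gender":              ("male", "equals", "convention: male sex as risk level"),
    "age":                 (65, "above", "geriatric-oncology convention"),
    "ecog":                (1, "above", "performance status >= 2"),
    "number_smoke":        (9600, "above", "cohort median pack-history"),
    "smoke_status":        ("yes", "equals", "ever-smoker"),
    "history_lung_cancer": ("yes", "equals", "prior disease"),
    "family_history":      ("yes", "equals", "family history present"),
    "wbc":                 (9.5, "above", "upper reference, 1e9/L"),
    "ne":                  (6.3, "above", "upper reference, 1e9/L"),
    "ly":                  (1.1, "below", "lower reference, 1e9/L"),
    "mono":                (0.6, "above", "upper reference, 1e9/L"),
    "eo":                  (0.52, "above", "upper reference, 1e9/L"),
    "hb":                  (110, "below", "anemia threshold, g/L"),
    "plt":                 (350, "above", "upper reference, 1e9/L"),
    "alt":                 (40, "above", "upper reference, U/L"),
    "tbil":                (17.1, "above", "upper reference, umol/L"),
    "alb":                 (35, "below", "hypoalbuminemia, g/L"),
    "ast":                 (40, "above", "upper reference, U/L"),
    "fg":                  (4.0, "above", "upper reference, g/L"),
    "tp":                  (60, "below", "lower reference, g/L"),
    "cea":                 (5.0, "above", "upper reference, ng/mL"),
    "t_stage":             (2, "above", "T3-T4 as risk"),
    "n_stage":             (0, "above", "nodal involvement"),
    "m_stage":             (0, "above", "distant metastasis"),
}

GPS_CRP_CUTOFF = 10.0   # mg/L
GPS_ALB_CUTOFF = 35.0   # g/L


def dichotomize_clinical(clinical: pd.DataFrame,
                         registry: dict | None = None) -> pd.DataFrame:
    """Map every clinical variable to {normal, risk} via the registry.

    Risk requires strict exceedance of the threshold in the registered
    direction; values exactly at the boundary are normal.  A variable
    without a registry entry raises, naming the variable.
    """
    registry = registry if registry is not None else DEFAULT_CUTOFFS
    out = {}
    for col in clinical.columns:
        if col not in registry:
            raise KeyError(f"no cut-off registered for variable '{col}'")
        threshold, direction, _src = registry[col]
        x = clinical[col]
        if direction == "above":
            risk = x.astype(float) > threshold
        elif direction == "below":
            risk = x.astype(float) < threshold
        elif direction == "equals":
            risk = x.astype(str) == str(threshold)
        else:
            raise ValueError(f"unknown direction '{direction}' for '{col}'")
        out[col] = np.where(risk, RISK, NORMAL)
    return pd.DataFrame(out, index=clinical.index)


# ---------------------------------------------------------------------------
# index selection (multivariable Cox)

def _vif_filter(X: pd.DataFrame, threshold: float = 10.0) -> list[str]:
    """Drop collinear columns (variance-inflation factor) with a warning."""
    cols = list(X.columns)
    keep = cols.copy()
    changed = True
    while changed and len(keep) > 1:
        changed = False
        Z = X[keep].to_numpy(float)
        Z = (Z - Z.mean(0)) / np.where(Z.std(0) == 0, 1, Z.std(0))
        for k, col in enumerate(keep):
            others = np.delete(Z, k, axis=1)
            beta, *_ = np.linalg.lstsq(others, Z[:, k], rcond=None)
            resid = Z[:, k] - others @ beta
            r2 = 1 - resid.var() / (Z[:, k].var() or 1.0)
            vif = np.inf if r2 >= 1 - 1e-12 else 1 / (1 - r2)
            if vif > threshold:
                warnings.warn(f"dropping collinear candidate '{col}' "
                              f"(VIF={vif:.1f})", stacklevel=2)
                keep.remove(col)
                changed = True
                break
    return keep


def select_pim_indices(candidates: pd.DataFrame, time, event,
                       alpha: float = 0.05) -> tuple[list[str], pd.DataFrame]:
    """Multivariable Cox over candidate risk statuses; keep p < alpha.

    ``candidates`` holds one column per candidate index with values in
    {normal, risk} (or 0/1).  Candidates should already be univariately
    significant.  Returns (index list, full Cox summary).  Raises when no
    candidate stays significant (the PIM is then undefined).
    """
    X = candidates.copy()
    for col in X.columns:
        if X[col].dtype == object:
            X[col] = (X[col] == RISK).astype(int)
    X = X.astype(float)
    keep = _vif_filter(X)
    X = X[keep]
    df = X.copy()
    df["time"] = np.asarray(time, float)
    df["event"] = np.asarray(event, int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summ = cph.summary
    sig = [c for c in X.columns if summ.loc[c, "p"] < alpha]
    if not sig:
        raise ValueError("no candidate is significant in the multivariable "
                         "fit; the prognostic index is undefined")
    return sig, summ


# ---------------------------------------------------------------------------
# the counting rule

@dataclass
class PIMModel:
    indices: list[str]
    score: int
    stratum: str

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("score must be non-negative")
        expect = STRATUM_LABELS[min(self.score, 2)]
        if self.stratum != expect:
            raise ValueError(f"stratum '{self.stratum}' inconsistent with "
                             f"score {self.score}")


def compute_pim(statuses: dict | pd.Series, indices: list[str]) -> PIMModel:
    """Count risk statuses over the index set: 0 -> low, 1 -> intermediate,
    >= 2 -> high.  A missing status raises."""
    s = 0
    for idx in indices:
        if idx not in statuses or pd.isna(statuses[idx]):
            raise KeyError(f"missing status for index '{idx}'")
        v = statuses[idx]
        if v not in (NORMAL, RISK, 0, 1):
            raise ValueError(f"invalid status {v!r} for index '{idx}'")
        s += int(v == RISK or v == 1)
    return PIMModel(indices=list(indices), score=s,
                    stratum=STRATUM_LABELS[min(s, 2)])


def pim_scores(statuses: pd.DataFrame, indices: list[str]) -> pd.DataFrame:
    """Vectorized counting rule: one (score, stratum) row per patient."""
    rows = [compute_pim(statuses.loc[i], indices) for i in statuses.index]
    return pd.DataFrame({"pim_score": [r.score for r in rows],
                         "pim_stratum": [r.stratum for r in rows]},
                        index=statuses.index)


# ---------------------------------------------------------------------------
# comparison models

@dataclass
class GPSResult:
    crp: float
    albumin: float
    gps: int


def compute_gps(crp, albumin):
    """Glasgow Prognostic Score: 2 if CRP > 10 mg/L and albumin < 35 g/L,
    0 if neither, else 1.  Scalar in, GPSResult out; arrays in, int array
    out with NaN where either record is missing (patient excluded)."""
    crp_a = np.asarray(crp, float)
    alb_a = np.asarray(albumin, float)
    scalar = crp_a.ndim == 0
    crp_a, alb_a = np.atleast_1d(crp_a), np.atleast_1d(alb_a)
    high_crp = crp_a > GPS_CRP_CUTOFF
    low_alb = alb_a < GPS_ALB_CUTOFF
    gps = high_crp.astype(float) + low_alb.astype(float)
    gps = np.where(high_crp & low_alb, 2.0, np.where(high_crp | low_alb, 1.0, 0.0))
    gps[~(np.isfinite(crp_a) & np.isfinite(alb_a))] = np.nan
    if scalar:
        if np.isnan(gps[0]):
            raise ValueError("CRP and albumin must both be present")
        return GPSResult(float(crp_a[0]), float(alb_a[0]), int(gps[0]))
    return gps


def stratify_clinical_model(statuses: pd.DataFrame,
                            indices: list[str] = ("ast", "cea")) -> pd.DataFrame:
    """Clinical-factor comparison model: same counting rule, clinical
    indices only (default AST + CEA)."""
    out = pim_scores(statuses, list(indices))
    return out.rename(columns={"pim_score": "clinical_score",
                               "pim_stratum": "clinical_stratum"})


def stratify_response(labels) -> pd.Series:
    """Validate RECIST labels (CR/PR/SD/PD) and return them as an ordered
    categorical; the CR group may be empty.  Unknown labels raise."""
    s = pd.Series(labels).astype(str)
    bad = sorted(set(s) - set(RECIST_LABELS))
    if bad:
        raise ValueError(f"unknown RECIST label(s): {bad}")
    return pd.Series(pd.Categorical(s, categories=list(RECIST_LABELS),
                                    ordered=True), index=s.index)


# ---------------------------------------------------------------------------
# estimator facade

class PrognosticIndex(BaseEstimator):
    """Risk-count prognostic index as an sklearn-style estimator.

    fit(X, y): X is a DataFrame of candidate binary statuses ({normal,
    risk} or 0/1), y a (time, event) tuple.  The multivariable Cox fit
    selects the indices (p < ``alpha``); ``predict`` returns integer
    scores and ``predict_strata`` the low/intermediate/high labels.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y):
        time, event = y
        self.indices_, self.cox_summary_ = select_pim_indices(
            X, time, event, alpha=self.alpha)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return pim_scores(X, self.indices_)["pim_score"].to_numpy()

    def predict_strata(self, X: pd.DataFrame) -> np.ndarray:
        return pim_scores(X, self.indices_)["pim_stratum"].to_numpy()
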