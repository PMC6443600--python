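"""Image-based prognostic signature: screening, LASSO-Cox, cut-point.

The signature is a sparse linear combination of texture features selected
in two steps: a univariate Cox screen at p < 0.05 against time to
progression, then an L1-penalized Cox fit whose penalty is chosen by
cross-validated partial likelihood (1-SE rule).  The continuous score is
dichotomized at the cut-point that maximizes the two-group log-rank
statistic over all admissible splits ("X-tile" practice), with a minimum
group fraction of 10%.

Scores follow the convention higher score = higher hazard = faster
progression; scores at or below the cut-off are labelled ``good-TTP``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold

__all__ = [
    "ScreeningResult",
    "SignatureModel",
    "CutpointResult",
    "univariate_screen",
    "fit_lasso_cox",
    "score_signature",
    "find_optimal_cutpoint",
    "stratify_by_signature",
    "logrank_statistic",
    "load_reference_signature",
    "LassoCoxSignature",
]

GOOD_LABEL, POOR_LABEL = "good-TTP", "poor-TTP"


@dataclass
class SignatureModel:
    feature_ids: list[str]
    weights: np.ndarray
    cutoff: float
    reference_flag: bool = False
    alpha: float | None = None          # chosen L1 penalty
    cv_trace: pd.DataFrame | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        if len(self.feature_ids) != self.weights.size:
            raise ValueError("feature_ids and weights length mismatch")

    def to_json(self) -> str:
        d = {"feature_ids": list(self.feature_ids),
             "weights": self.weights.tolist(),
             "cutoff": self.cutoff,
             "reference_flag": self.reference_flag,
             "alpha": self.alpha}
        if self.cv_trace is not None:
            d["cv_trace"] = self.cv_trace.to_dict(orient="list")
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        d = json.loads(text)
        trace = d.pop("cv_trace", None)
        m = cls(**d)
        if trace is not None:
            m.cv_trace = pd.DataFrame(trace)
        return m


def load_reference_signature() -> SignatureModel:
    """The published 8-feature signature (weights and cut-off -1.117),
    frozen for scoring; it is NOT a model re-fit on synthetic data."""
    text = (resources.files("lsccpim") / "reference"
            / "reference_model.json").read_text()
    return SignatureModel.from_json(text)


# ---------------------------------------------------------------------------
# screening

@dataclass
class ScreeningResult:
    table: pd.DataFrame          # index: feature id; beta, wald, p, kept, reason

    @property
    def kept_ids(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


def _cox_newton_1d(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                   max_iter: int = 25, tol: float = 1e-10,
                   beta_cap: float = 15.0):
    """Univariate Cox fits for every column of X at once (Newton-Raphson,
    Breslow tie handling; equals Efron when event times are distinct).

    Returns (beta, se, converged) arrays of length p.
    """
    order = np.argsort(-time, kind="stable")
    Xo, to, eo = X[order], time[order], event[order]
    n, p = Xo.shape
    # rows with equal time are contiguous after the descending sort; the
    # risk set of an event is the prefix up to the END of its tie group
    grp_last = np.searchsorted(-to, -to, side="right") - 1
    ev = eo == 1
    beta = np.zeros(p)
    converged = np.zeros(p, bool)
    for _ in range(max_iter):
        eta = np.clip(Xo * beta, -500, 500)
        w = np.exp(eta)
        S0 = np.cumsum(w, axis=0)[grp_last]
        S1 = np.cumsum(Xo * w, axis=0)[grp_last]
        S2 = np.cumsum(Xo**2 * w, axis=0)[grp_last]
        m1 = S1 / S0
        U = (Xo[ev] - m1[ev]).sum(axis=0)
        Info = (S2[ev] / S0[ev] - m1[ev] ** 2).sum(axis=0)
        Info = np.where(Info <= 0, np.nan, Info)
        step = U / Info
        beta = np.clip(beta + step, -beta_cap, beta_cap)
        converged = np.abs(step) < tol
        if converged.all():
            break
    eta = np.clip(Xo * beta, -500, 500)
    w = np.exp(eta)
    S0 = np.cumsum(w, axis=0)[grp_last]
    S1 = np.cumsum(Xo * w, axis=0)[grp_last]
    S2 = np.cumsum(Xo**2 * w, axis=0)[grp_last]
    Info = (S2[ev] / S0[ev] - (S1[ev] / S0[ev]) ** 2).sum(axis=0)
    se = np.sqrt(1.0 / np.where(Info > 0, Info, np.nan))
    converged = converged & (np.abs(beta) < beta_cap) & np.isfinite(se)
    return beta, se, converged


def univariate_screen(features: pd.DataFrame, time, event,
                      alpha: float = 0.05,
                      fdr: bool = False) -> ScreeningResult:
    """One Cox fit per feature against (time, event); keep Wald p < alpha.

    Features are z-scored internally (the Wald p of a univariate Cox fit
    is invariant to affine rescaling); constant or non-converging features
    are excluded with a recorded reason.  All fits run as one vectorized
    Newton-Raphson (Breslow ties, equal to Efron for distinct event
    times).  ``fdr=True`` switches the retention rule to
    Benjamini-Hochberg at the same alpha (sensitivity analysis; the
    emulated analysis uses raw p < 0.05).
    """
    from scipy.stats import norm

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if len(features) < 10:
        raise ValueError("need >= 10 patients for screening")
    if event.sum() < 1:
        raise ValueError("no events observed")
    rows = []
    X = features.to_numpy(float)
    finite = np.all(np.isfinite(X), axis=0)
    sd = X.std(axis=0)
    usable = finite & (sd > 0)
    Z = np.zeros_like(X)
    Z[:, usable] = ((X - X.mean(axis=0)) / np.where(sd == 0, 1, sd))[:, usable]
    beta = np.full(X.shape[1], np.nan)
    se = np.full(X.shape[1], np.nan)
    conv = np.zeros(X.shape[1], bool)
    if usable.any():
        b, s, c = _cox_newton_1d(Z[:, usable], time, event)
        beta[usable], se[usable], conv[usable] = b, s, c
    zstat = beta / se
    pvals = 2 * (1 - norm.cdf(np.abs(zstat)))
    for k, col in enumerate(features.columns):
        if not finite[k]:
            rows.append((col, np.nan, np.nan, np.nan, False, "non-finite"))
        elif sd[k] == 0:
            rows.append((col, np.nan, np.nan, np.nan, False, "constant"))
        elif not conv[k]:
            rows.append((col, np.nan, np.nan, np.nan, False, "non-convergence"))
        else:
            rows.append((col, float(beta[k]), float(zstat[k]),
                         float(pvals[k]), None, ""))
    tab = pd.DataFrame(rows, columns=["feature", "beta", "wald", "p",
                                      "kept", "reason"]).set_index("feature")
    ok = tab["reason"] == ""
    if fdr:
        from statsmodels.stats.multitest import multipletests
        rej = np.zeros(len(tab), bool)
        if ok.any():
            rej[ok.to_numpy()] = multipletests(
                tab.loc[ok, "p"], alpha=alpha, method="fdr_bh")[0]
        tab["kept"] = rej
    else:
        tab["kept"] = ok & (tab["p"] < alpha)
    tab["kept"] = tab["kept"].astype(bool)
    return ScreeningResult(table=tab)


# ---------------------------------------------------------------------------
# penalized Cox

def _breslow_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                    beta: np.ndarray) -> float:
    """Breslow partial log-likelihood (used for CV deviance only)."""
    eta = X @ beta
    order = np.argsort(-time, kind="stable")
    eta_o, t_o, e_o = eta[order], time[order], event[order]
    log_cum = np.logaddexp.accumulate(eta_o)
    ll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j < n and t_o[j] == t_o[i]:
            j += 1
        # risk set = everyone with time >= t_o[i] = entries [0, j)
        denom = log_cum[j - 1]
        ev = e_o[i:j] == 1
        ll += float(eta_o[i:j][ev].sum() - ev.sum() * denom)
        i = j
    return ll


def fit_lasso_cox(features: pd.DataFrame, time, event,
                  lambda_grid: np.ndarray | None = None,
                  cv_folds: int = 10, seed: int = 0,
                  rule: str = "1se",
                  min_group_frac: float = 0.1) -> SignatureModel:
    """L1-penalized Cox fit with cross-validated penalty selection.

    Features are z-scored before the shared penalty; reported weights are
    rescaled back so the model scores raw feature values.  CV deviance is
    the Verweij-Van Houwelingen partial likelihood
    ``loglik(all at beta_fold) - loglik(train at beta_fold)``; ``rule`` is
    ``"1se"`` (largest penalty within one SE of the optimum, the default)
    or ``"min"``.  The cut-off is the optimal log-rank cut-point of the
    training scores.  Deterministic given ``seed``.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if features.shape[1] < 2:
        raise ValueError("need >= 2 candidate features")
    if event.sum() < 2:
        raise ValueError("need >= 2 events")
    ids = list(features.columns)
    X = features.to_numpy(float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01,
                                  n_alphas=50)
    path.fit(Z, y)
    alphas = (np.asarray(lambda_grid, float) if lambda_grid is not None
              else path.alphas_)

    cv_folds = max(2, min(cv_folds, len(time) // 3))  # small-n guard
    folds = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_ll = np.zeros((cv_folds, len(alphas)))
    for k, (tr, _te) in enumerate(folds.split(Z)):
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, fit_baseline_model=False)
        m.set_params(alphas=list(alphas))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(Z[tr], y[tr])
        for a_idx, a in enumerate(alphas):
            beta = m.coef_[:, np.argmin(np.abs(m.alphas_ - a))]
            cv_ll[k, a_idx] = (_breslow_loglik(Z, time, event, beta)
                               - _breslow_loglik(Z[tr], time[tr], event[tr], beta))
    mean_ll = cv_ll.mean(axis=0)
    se_ll = cv_ll.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    best = int(np.argmax(mean_ll))
    if rule == "1se":
        ok = mean_ll >= mean_ll[best] - se_ll[best]
        chosen = int(np.min(np.nonzero(ok)[0])) if alphas[0] > alphas[-1] \
            else int(np.max(np.nonzero(ok)[0]))
        # alphas from coxnet are decreasing; take the largest admissible
        chosen = int(np.argmax(np.where(ok, alphas, -np.inf)))
    else:
        chosen = best
    alpha = float(alphas[chosen])

    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, fit_baseline_model=False)
    final.set_params(alphas=list(alphas))
    final.fit(Z, y)

    def coef_at(a):
        return final.coef_[:, np.argmin(np.abs(final.alphas_ - a))]

    beta_std = coef_at(alpha)
    if not beta_std.any() and rule == "1se":
        # the 1-SE model can be empty at small n; fall back to the optimum
        warnings.warn("1-SE penalty gives an empty model; "
                      "falling back to the CV-optimal penalty", stacklevel=2)
        alpha = float(alphas[best])
        beta_std = coef_at(alpha)
    if not beta_std.any():
        nonzero_alphas = [a for a in alphas if coef_at(a).any()]
        if nonzero_alphas:
            alpha = float(min(nonzero_alphas))
            warnings.warn("CV-optimal penalty gives an empty model; using "
                          "the smallest penalty with support", stacklevel=2)
            beta_std = coef_at(alpha)
    nz = np.nonzero(beta_std)[0]
    if nz.size == 0:
        raise ValueError(
            "all coefficients are zero at the chosen penalty; "
            "try a smaller lambda (rule='min' or a custom lambda_grid)")
    weights_raw = beta_std[nz] / sd[nz]
    sel_ids = [ids[i] for i in nz]
    scores = features[sel_ids].to_numpy(float) @ weights_raw
    cut = find_optimal_cutpoint(scores, time, event,
                                min_group_frac=min_group_frac).cutoff
    trace = pd.DataFrame({"alpha": alphas, "cv_loglik": mean_ll,
                          "cv_se": se_ll})
    return SignatureModel(feature_ids=sel_ids, weights=weights_raw,
                          cutoff=float(cut), alpha=alpha, cv_trace=trace)


def score_signature(model: SignatureModel, features) -> np.ndarray | float:
    """Linear score sum_j w_j f_j (no intercept).

    ``features`` may be a Series (one patient) or DataFrame (cohort); a
    missing feature id raises with the offending name.
    """
    if isinstance(features, pd.Series):
        missing = [f for f in model.feature_ids if f not in features.index]
        if missing:
            raise KeyError(f"missing feature id(s): {missing}")
        return float(features[model.feature_ids].to_numpy(float)
                     @ model.weights)
    missing = [f for f in model.feature_ids if f not in features.columns]
    if missing:
        raise KeyError(f"missing feature id(s): {missing}")
    return features[model.feature_ids].to_numpy(float) @ model.weights


# ---------------------------------------------------------------------------
# cut-point search

def logrank_statistic(groups: np.ndarray, time: np.ndarray,
                      event: np.ndarray) -> float:
    """Two-group log-rank chi-square statistic (no p-value), vectorized
    over event times (hypergeometric observed-minus-expected form)."""
    groups = np.asarray(groups, bool)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], groups[order]
    n_total = len(t)
    uniq, first = np.unique(t, return_index=True)
    # at-risk counts just before each unique time
    at_risk = n_total - first
    g_suffix = np.concatenate([np.cumsum(g[::-1])[::-1], [0]])
    at_risk_1 = g_suffix[first]
    d = np.add.reduceat(e, first)
    d1 = np.add.reduceat(e * g, first)
    ok = (at_risk >= 2) & (d > 0)
    n, n1 = at_risk[ok].astype(float), at_risk_1[ok].astype(float)
    dd, dd1 = d[ok].astype(float), d1[ok].astype(float)
    O = dd1.sum()
    E = (dd * n1 / n).sum()
    V = (dd * (n1 / n) * (1 - n1 / n) * (n - dd) / (n - 1)).sum()
    if V <= 0:
        return 0.0
    return float((O - E) ** 2 / V)


@dataclass
class CutpointResult:
    cutoff: float
    statistic: float
    group_sizes: tuple[int, int]   # (<= cutoff, > cutoff)
    trace: pd.DataFrame = field(repr=False, default=None)


def find_optimal_cutpoint(scores, time, event,
                          min_group_frac: float = 0.1) -> CutpointResult:
    """Maximally selected log-rank cut-point ("X-tile" practice).

    Candidates are midpoints between consecutive distinct order statistics
    whose induced split respects the minimum group fraction; the returned
    cut-off maximizes the two-group log-rank statistic, ties broken toward
    the more balanced split.  The naive p-value at the selected cut-off is
    anti-conservative (selection is not corrected for); see the methods
    note.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if not 0 < min_group_frac < 0.5:
        raise ValueError("min_group_frac must lie in (0, 0.5)")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("all scores are equal; no admissible cut-point")
    n = scores.size
    min_n = int(np.ceil(min_group_frac * n))
    cands, stats, sizes = [], [], []
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        c = (lo + hi) / 2.0
        left = scores <= c
        n1 = int(left.sum())
        if n1 < min_n or n - n1 < min_n:
            continue
        cands.append(c)
        sizes.append((n1, n - n1))
        stats.append(logrank_statistic(left, time, event))
    if not cands:
        raise ValueError("no admissible cut-point under the group-size floor")
    stats_arr = np.asarray(stats)
    best_stat = stats_arr.max()
    tied = np.nonzero(stats_arr >= best_stat - 1e-12)[0]
    balance = [abs(sizes[i][0] - sizes[i][1]) for i in tied]
    pick = int(tied[int(np.argmin(balance))])
    trace = pd.DataFrame({"candidate": cands, "statistic": stats})
    return CutpointResult(cutoff=float(cands[pick]),
                          statistic=float(stats_arr[pick]),
                          group_sizes=sizes[pick], trace=trace)


def stratify_by_signature(scores, cutoff: float) -> np.ndarray:
    """score <= cutoff -> good-TTP; score > cutoff -> poor-TTP."""
    scores = np.asarray(scores, float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return np.where(scores <= cutoff, GOOD_LABEL, POOR_LABEL)


# ---------------------------------------------------------------------------
# estimator facade

class LassoCoxSignature(BaseEstimator):
    """Screen + LASSO-Cox + cut-point as one sklearn-style estimator.

    fit(X, y): X is a feature DataFrame, y a (time, event) tuple or a
    structured survival array (sksurv convention).  Fitted attributes:
    ``screen_``, ``model_`` (SignatureModel), ``feature_ids_``,
    ``weights_``, ``cutoff_``.  ``predict`` returns the continuous risk
    score; ``predict_strata`` the good/poor labels.
    """

    def __init__(self, alpha_screen: float = 0.05, cv_folds: int = 10,
                 rule: str = "1se", min_group_frac: float = 0.1,
                 fdr: bool = False, seed: int = 0):
        self.alpha_screen = alpha_screen
        self.cv_folds = cv_folds
        self.rule = rule
        self.min_group_frac = min_group_frac
        self.fdr = fdr
        self.seed = seed

    @staticmethod
    def _unpack_y(y):
        if isinstance(y, tuple):
            return np.asarray(y[0], float), np.asarray(y[1], int)
        arr = np.asarray(y)
        if arr.dtype.names:  # sksurv structured array
            ev, t = arr.dtype.names
            return arr[t].astype(float), arr[ev].astype(int)
        raise TypeError("y must be (time, event) or a structured array")

    def fit(self, X: pd.DataFrame, y):
        time, event = self._unpack_y(y)
        self.screen_ = univariate_screen(X, time, event,
                                         alpha=self.alpha_screen, fdr=self.fdr)
        kept = self.screen_.kept_ids
        if len(kept) < 2:
            raise ValueError(f"screening kept {len(kept)} feature(s); "
                             "need >= 2 for the penalized fit")
        self.model_ = fit_lasso_cox(X[kept], time, event,
                                    cv_folds=self.cv_folds, seed=self.seed,
                                    rule=self.rule,
                                    min_group_frac=self.min_group_frac)
        self.feature_ids_ = list(self.model_.feature_ids)
        self.weights_ = self.model_.weights
        self.cutoff_ = self.model_.cutoff
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(score_signature(self.model_, X), float)

    def predict_strata(self, X: pd.DataFrame) -> np.ndarray:
        return stratify_by_signature(self.predict(X), self.cutoff_)
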