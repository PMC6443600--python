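"""Prognostic performance evaluation and model comparison.

Kaplan-Meier / log-rank / hazard ratios for stratified groups, Harrell's
concordance index with a patient-level bootstrap CI, continuous (category
free) net reclassification improvement (NRI) and integrated discrimination
improvement (IDI) at a fixed horizon with inverse-probability-of-censoring
weights, decision-curve net benefit NB(Pt) = TP/n - (FP/n) * Pt/(1-Pt),
the clinical-impact curve, Cox-model calibration at a horizon, and
Kruskal-Wallis demographic-balance testing across risk strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "SurvivalComparison",
    "km_logrank",
    "c_index",
    "nri_idi",
    "net_benefit",
    "clinical_impact",
    "calibration",
    "kruskal_wallis_balance",
]


# ---------------------------------------------------------------------------
# KM / log-rank / HR

@dataclass
class SurvivalComparison:
    medians: dict              # group -> median months (NaN if not reached)
    logrank_stat: float
    logrank_p: float
    pairwise: pd.DataFrame     # columns: ref, other, hr, ci_low, ci_high, p
    group_sizes: dict = field(default_factory=dict)


def km_logrank(groups, time, event) -> SurvivalComparison:
    """Product-limit estimates, k-group log-rank and pairwise Cox HRs.

    Median survival is NaN when the curve never crosses 0.5 (reported as
    "not reached", never imputed).
    """
    groups = np.asarray(groups)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    sizes = {}
    medians = {}
    for lab in labels:
        sel = groups == lab
        if sel.sum() == 0:
            raise ValueError(f"group '{lab}' is empty")
        sizes[lab] = int(sel.sum())
        km = KaplanMeierFitter().fit(time[sel], event[sel])
        med = km.median_survival_time_
        medians[lab] = float(med) if np.isfinite(med) else float("nan")
    lr = multivariate_logrank_test(time, groups, event)
    rows = []
    for a_idx, a in enumerate(labels):
        for b in labels[a_idx + 1:]:
            sel = (groups == a) | (groups == b)
            df = pd.DataFrame({"time": time[sel], "event": event[sel],
                               "g": (groups[sel] == b).astype(int)})
            try:
                with warnings.catch_warnings(), np.errstate(over="ignore"):
                    warnings.simplefilter("ignore")
                    cph = CoxPHFitter().fit(df, "time", "event")
                    hr = float(np.exp(cph.params_["g"]))
                    lo = float(np.exp(cph.confidence_intervals_.iloc[0, 0]))
                    hi = float(np.exp(cph.confidence_intervals_.iloc[0, 1]))
                    p = float(cph.summary.loc["g", "p"])
            except Exception:
                hr = lo = hi = p = float("nan")
            rows.append((a, b, hr, lo, hi, p))
    pw = pd.DataFrame(rows, columns=["ref", "other", "hr",
                                     "ci_low", "ci_high", "p"])
    return SurvivalComparison(medians=medians,
                              logrank_stat=float(lr.test_statistic),
                              logrank_p=float(lr.p_value),
                              pairwise=pw, group_sizes=sizes)


# ---------------------------------------------------------------------------
# Harrell's C

def _cindex_value(scores, time, event) -> float:
    t_i, t_j = time[:, None], time[None, :]
    e_i = event[:, None].astype(bool)
    e_j = event[None, :].astype(bool)
    comparable = ((t_i < t_j) & e_i) | ((t_i == t_j) & e_i & ~e_j)
    s_i, s_j = scores[:, None], scores[None, :]
    conc = np.where(s_i > s_j, 1.0, np.where(s_i == s_j, 0.5, 0.0))
    den = comparable.sum()
    if den == 0:
        raise ValueError("no comparable pair")
    return float((conc * comparable).sum() / den)


def c_index(scores, time, event, n_boot: int = 2000, seed: int = 0,
            ci: bool = True):
    """Harrell's concordance index (higher score = higher risk = earlier
    event), ties in score credited 0.5; a pair is comparable when the
    earlier time is an event (or times tie and exactly one is an event).
    95% CI by patient-level bootstrap (percentile, seeded).

    Returns ``(c, (lo, hi))`` or just ``c`` when ``ci=False``.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    c = _cindex_value(scores, time, event)
    if not ci:
        return c
    rng = np.random.default_rng(seed)
    n = len(scores)
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            draws.append(_cindex_value(scores[idx], time[idx], event[idx]))
        except ValueError:
            continue
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return c, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# NRI / IDI

def _ipcw_event_status(time, event, horizon):
    """(D, w): horizon event status and IPCW weights.

    D=1 for events by the horizon, D=0 for patients followed beyond it;
    patients censored event-free before the horizon carry weight 0.
    Weights are 1/G(T-) for events and 1/G(horizon) for survivors, with G
    the Kaplan-Meier estimate of the censoring distribution.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if not (time >= horizon).any():
        raise ValueError("horizon lies beyond all follow-up")
    # Kaplan-Meier of the censoring distribution, as a step function
    order = np.argsort(time, kind="stable")
    t_o, c_o = time[order], (1 - event)[order]
    uniq, idx = np.unique(t_o, return_index=True)
    at_risk = len(t_o) - idx
    d_cens = np.add.reduceat(c_o, idx)
    surv = np.cumprod(1.0 - d_cens / at_risk)

    def G(ts):
        pos = np.searchsorted(uniq, ts, side="right") - 1
        out = np.where(pos >= 0, surv[np.clip(pos, 0, None)], 1.0)
        return out

    is_event = (time <= horizon) & (event == 1)
    beyond = time > horizon
    D = is_event.astype(float)
    w = np.zeros(len(time))
    g_event = G(time[is_event] - 1e-9)
    w[is_event] = np.where(g_event > 0, 1.0 / g_event, 0.0)
    g_h = G(np.array([horizon]))[0]
    w[beyond] = 1.0 / g_h if g_h > 0 else 0.0
    if w[D == 1].sum() == 0 or w[D == 0].sum() == 0:
        raise ValueError("no weighted events or non-events at the horizon")
    return D, w


def nri_idi(new_risk, old_risk, time, event, horizon: float,
            n_boot: int = 500, seed: int = 0) -> dict:
    """Continuous (category-free) NRI and IDI at a fixed horizon.

    ``new_risk`` / ``old_risk`` are predicted event risks (probabilities or
    monotone scores; the NRI uses only their pairwise ordering, the IDI
    their means).  Horizon event status is IPCW-weighted to handle
    censoring.  p-values from a seeded patient-level bootstrap (normal
    approximation on the bootstrap SE); identical models give NRI = IDI =
    0 with p = 1.
    """
    new_risk = np.asarray(new_risk, float)
    old_risk = np.asarray(old_risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)

    def compute(nr, orisk, t, e):
        D, w = _ipcw_event_status(t, e, horizon)
        up = (nr > orisk).astype(float)
        down = (nr < orisk).astype(float)
        ev, ne = D == 1, D == 0
        p_up_ev = (w[ev] * up[ev]).sum() / w[ev].sum()
        p_dn_ev = (w[ev] * down[ev]).sum() / w[ev].sum()
        p_up_ne = (w[ne] * up[ne]).sum() / w[ne].sum()
        p_dn_ne = (w[ne] * down[ne]).sum() / w[ne].sum()
        nri = (p_up_ev - p_dn_ev) - (p_up_ne - p_dn_ne)
        mean_ev = lambda r: (w[ev] * r[ev]).sum() / w[ev].sum()
        mean_ne = lambda r: (w[ne] * r[ne]).sum() / w[ne].sum()
        idi = (mean_ev(nr) - mean_ne(nr)) - (mean_ev(orisk) - mean_ne(orisk))
        return nri, idi

    nri, idi = compute(new_risk, old_risk, time, event)
    rng = np.random.default_rng(seed)
    n = len(time)
    boot = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            boot.append(compute(new_risk[idx], old_risk[idx],
                                time[idx], event[idx]))
        except ValueError:
            continue
    boot = np.asarray(boot) if boot else np.zeros((1, 2))
    se = boot.std(axis=0, ddof=1) if len(boot) > 1 else np.zeros(2)

    def pval(est, s):
        if s == 0:
            return 1.0
        return float(2 * (1 - stats.norm.cdf(abs(est) / s)))

    return {"nri": float(nri), "idi": float(idi),
            "nri_p": pval(nri, se[0]), "idi_p": pval(idi, se[1]),
            "horizon": float(horizon)}


# ---------------------------------------------------------------------------
# decision curves

def net_benefit(predictions, outcomes, pt_grid) -> pd.DataFrame:
    """Decision-curve net benefit over a threshold-probability grid.

    ``predictions`` are either binary high-risk flags (used at every
    threshold) or risk probabilities (thresholded at each Pt).  Returns a
    DataFrame with columns threshold, nb_model, nb_all, nb_none; Pt >= 1
    is excluded from the grid.
    """
    pred = np.asarray(predictions, float)
    y = np.asarray(outcomes, int)
    n = len(y)
    prev = y.mean()
    binary = set(np.unique(pred)) <= {0.0, 1.0}
    rows = []
    for pt in np.asarray(pt_grid, float):
        if not 0 < pt < 1:
            continue
        flag = pred.astype(bool) if binary else pred > pt
        tp = int((flag & (y == 1)).sum())
        fp = int((flag & (y == 0)).sum())
        odds = pt / (1 - pt)
        nb = tp / n - (fp / n) * odds
        nb_all = prev - (1 - prev) * odds
        rows.append((pt, nb, nb_all, 0.0))
    return pd.DataFrame(rows, columns=["threshold", "nb_model",
                                       "nb_all", "nb_none"])


def clinical_impact(risk_probs, outcomes, pt_grid, n_boot: int = 200,
                    seed: int = 0) -> pd.DataFrame:
    """Predicted-high-risk and true-event counts per 100 patients at each
    threshold, with bootstrap percentile CIs."""
    p = np.asarray(risk_probs, float)
    y = np.asarray(outcomes, int)
    n = len(y)
    rng = np.random.default_rng(seed)
    boots = rng.integers(0, n, size=(n_boot, n))
    rows = []
    for pt in np.asarray(pt_grid, float):
        if not 0 < pt < 1:
            continue
        flag = p > pt
        n_high = 100.0 * flag.mean()
        n_high_ev = 100.0 * (flag & (y == 1)).mean()
        bh = 100.0 * (p[boots] > pt).mean(axis=1)
        bhe = 100.0 * ((p[boots] > pt) & (y[boots] == 1)).mean(axis=1)
        rows.append((pt, n_high, *np.percentile(bh, [2.5, 97.5]),
                     n_high_ev, *np.percentile(bhe, [2.5, 97.5])))
    return pd.DataFrame(rows, columns=[
        "threshold", "n_high", "n_high_lo", "n_high_hi",
        "n_high_event", "n_high_event_lo", "n_high_event_hi"])


# ---------------------------------------------------------------------------
# calibration

def calibration(linpred, time, event, horizon: float = 6.0,
                bins: int = 5) -> pd.DataFrame:
    """Predicted vs observed event-free probability at the horizon.

    A univariate Cox model on the linear predictor provides per-patient
    predicted survival at the horizon (Breslow baseline); patients are
    binned by predicted risk (quantile bins; empty/duplicate bins are
    merged with a warning) and compared with the Kaplan-Meier estimate in
    each bin.  Perfect calibration puts every point on the identity line.
    """
    lp = np.asarray(linpred, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if bins < 1:
        raise ValueError("need >= 1 bin")
    if horizon > time.max():
        raise ValueError("horizon lies beyond all follow-up")
    df = pd.DataFrame({"lp": lp, "time": time, "event": event})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph = CoxPHFitter().fit(df[["lp", "time", "event"]], "time", "event")
        surv = cph.predict_survival_function(df[["lp"]], times=[horizon])
    pred = surv.iloc[0].to_numpy()  # predicted S(horizon) per patient

    if bins == 1:
        binned = pd.Series(np.zeros(len(pred), dtype=int))
    else:
        try:
            binned = pd.qcut(pred, bins, labels=False, duplicates="drop")
        except ValueError:
            binned = pd.Series(np.zeros(len(pred), dtype=int))
        if pd.Series(binned).nunique() < bins:
            warnings.warn("empty calibration bins merged with neighbors",
                          stacklevel=2)
    rows = []
    for b in sorted(pd.unique(binned)):
        sel = np.asarray(binned) == b
        km = KaplanMeierFitter().fit(time[sel], event[sel])
        obs = float(km.survival_function_at_times(horizon).iloc[0])
        rows.append((int(b), int(sel.sum()), float(pred[sel].mean()), obs))
    return pd.DataFrame(rows, columns=["bin", "n", "predicted_survival",
                                       "observed_survival"])


# ---------------------------------------------------------------------------
# demographic balance

def kruskal_wallis_balance(demographics: pd.DataFrame, strata) -> pd.DataFrame:
    """Rank-based k-sample test of each demographic variable across the
    risk strata; constant variables get p = 1 with a note."""
    strata = np.asarray(strata)
    labels = pd.unique(strata)
    if len(labels) < 2:
        raise ValueError("need >= 2 strata")
    rows = []
    for col in demographics.columns:
        x = demographics[col]
        if x.dtype == object or isinstance(x.dtype, pd.CategoricalDtype):
            x = pd.factorize(x)[0].astype(float)
        else:
            x = x.to_numpy(float)
        if np.nanstd(x) == 0:
            rows.append((col, np.nan, 1.0, "constant variable"))
            continue
        samples = [x[strata == lab] for lab in labels]
        stat, p = stats.kruskal(*samples)
        rows.append((col, float(stat), float(p), ""))
    return pd.DataFrame(rows, columns=["variable", "statistic", "p",
                                       "note"]).set_index("variable")
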