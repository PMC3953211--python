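"""Survival endpoints and marker-outcome association.

Three endpoints are derived from clinical records, with cause-specific
censoring:

* PFS — event at lymphoma progression/relapse; death from another cause
  censors at the death date; otherwise censoring at last follow-up.
* OS — event at death from any cause; survivors censored at last follow-up.
* Lymphoma-specific OS — event only for lymphoma deaths; other deaths censor
  at the death date.

Times are in months (exact day counts / 30.44). Kaplan-Meier estimation and
the log-rank test are delegated to lifelines; Cox proportional-hazards
regression uses an in-package Newton solver on the Breslow partial likelihood
(Efron tie handling is available through lifelines). ROC analysis picks
marker cutoffs by Youden's J with the AUC computed as the tie-corrected rank
statistic and a Hanley-McNeil normal CI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from scipy.stats import rankdata

log = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.44
ENDPOINTS = ("pfs", "os", "lyos")

MIN_TIME = 1.0 / DAYS_PER_MONTH  # same-day events clipped to one day


@dataclass
class CutoffResult:
    """ROC-derived dichotomization cutoff for a continuous marker."""

    marker: str
    cutoff: float
    auc: float
    ci_low: float
    ci_high: float
    p: float
    direction: str  # 'high': larger marker values indicate risk

    def __post_init__(self) -> None:
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC must be in [0, 1]")


# ---------------------------------------------------------------------------
# Endpoint derivation
# ---------------------------------------------------------------------------

def _months(later: pd.Series, earlier: pd.Series) -> pd.Series:
    return (later - earlier).dt.days / DAYS_PER_MONTH


def derive_endpoints(records: pd.DataFrame) -> pd.DataFrame:
    """Derive (time, event) for PFS, OS and lymphoma-specific OS.

    Expects columns ``sample_id, registration_date, progression_date,
    death_date, cause, last_followup_date`` (dates ISO or datetime; blank =
    missing; ``cause`` in {lymphoma, other, alive}). Records without a
    registration date are rejected and logged. Times are clipped to at least
    one day so zero-duration follow-up never occurs.
    """
    df = records.copy()
    for col in ("registration_date", "progression_date", "death_date", "last_followup_date"):
        df[col] = pd.to_datetime(df[col], errors="coerce")
    bad = df["registration_date"].isna()
    if bad.any():
        log.warning("rejected %d records with missing registration date", int(bad.sum()))
        df = df[~bad]
    reg = df["registration_date"]
    prog = df["progression_date"]
    death = df["death_date"]
    fu = df["last_followup_date"]
    cause = df["cause"].astype(str)

    died = death.notna()
    other_death = died & (cause == "other")
    lymphoma_death = died & (cause == "lymphoma")

    # PFS: event at progression; other-cause death censors at death;
    # otherwise censored at last follow-up.
    pfs_event = prog.notna()
    pfs_end = fu.copy()
    pfs_end[other_death & ~pfs_event] = death[other_death & ~pfs_event]
    pfs_end[pfs_event] = prog[pfs_event]

    os_event = died
    os_end = fu.copy()
    os_end[died] = death[died]

    lyos_event = lymphoma_death
    lyos_end = fu.copy()
    lyos_end[died] = death[died]

    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"].to_numpy(),
            "pfs_time": _months(pfs_end, reg).to_numpy(),
            "pfs_event": pfs_event.astype(int).to_numpy(),
            "os_time": _months(os_end, reg).to_numpy(),
            "os_event": os_event.astype(int).to_numpy(),
            "lyos_time": _months(lyos_end, reg).to_numpy(),
            "lyos_event": lyos_event.astype(int).to_numpy(),
        }
    )
    for ep in ENDPOINTS:
        out[f"{ep}_time"] = out[f"{ep}_time"].clip(lower=MIN_TIME)
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve with risk/event bookkeeping."""

    times: np.ndarray       # distinct observed times (events and censorings)
    survival: np.ndarray    # S(t) just after each time
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function (S(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no observations")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    # drop lifelines' bookkeeping row at t=0 unless observations really sit there
    tab = kmf.event_table[kmf.event_table["removed"] > 0]
    surv = kmf.survival_function_
    s_at = np.array([float(surv.loc[:t].iloc[-1, 0]) for t in tab.index])
    return KMCurve(
        times=tab.index.to_numpy(dtype=float),
        survival=s_at,
        at_risk=tab["at_risk"].to_numpy(dtype=int),
        n_events=tab["observed"].to_numpy(dtype=int),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def _breslow_derivs(beta, X, first_risk_idx, event_rows):
    """Breslow partial log-likelihood with gradient and Hessian.

    Rows are sorted by ascending time; ``first_risk_idx[i]`` is the first
    sorted position of the tie group of row i, so the risk set of an event at
    row i is rows first_risk_idx[i]..n-1 (everyone still under observation,
    ties included).
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = np.einsum("i,ij,ik->ijk", w, X, X)
    # suffix sums over the sorted order
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]
    r = first_risk_idx[event_rows]
    S0 = s0[r]
    S1 = s1[r]
    S2 = s2[r]
    loglik = float(np.sum(eta[event_rows]) - np.sum(np.log(S0)))
    mu = S1 / S0[:, None]
    grad = X[event_rows].sum(axis=0) - mu.sum(axis=0)
    hess = -(S2 / S0[:, None, None] - np.einsum("ij,ik->ijk", mu, mu)).sum(axis=0)
    return loglik, grad, hess


def cox_fit(
    covariates,
    times,
    events,
    ties: str = "breslow",
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Cox proportional-hazards fit; returns per-covariate coef/se/z/p/HR.

    ``ties='breslow'`` uses the in-package Newton solver on the Breslow
    partial likelihood; ``ties='efron'`` delegates to lifelines. Constant
    covariates raise; near-separation produces a warning and a bounded
    estimate (|coef| capped at 15).
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, p = X.shape
    if events.sum() < 1:
        raise ValueError("need at least one event")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        raise ValueError("constant covariate(s): Cox model is not identifiable")
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if p > 1:
        corr = np.corrcoef(X, rowvar=False)
        if np.any(np.abs(corr[np.triu_indices(p, 1)]) > 0.9999):
            warnings.warn("collinear covariates in Cox design", stacklevel=2)

    if ties == "efron":
        return _cox_efron(X, times, events, names)
    if ties != "breslow":
        raise ValueError(f"unknown tie method {ties!r}")

    order = np.argsort(times, kind="stable")
    Xs = X[order]
    ts = times[order]
    ds = events[order]
    # first index of each tie group
    first = np.searchsorted(ts, ts, side="left")
    event_rows = np.flatnonzero(ds == 1)

    center = Xs.mean(axis=0)
    Xc = Xs - center
    beta = np.zeros(p)
    separated = False
    for _ in range(max_iter):
        ll, grad, hess = _breslow_derivs(beta, Xc, first, event_rows)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            warnings.warn("singular Hessian in Cox fit; using pseudo-inverse", stacklevel=2)
            step = np.linalg.pinv(hess) @ grad
        new = beta - step
        if np.any(np.abs(new * sds) > 15):
            separated = True
            new = np.clip(new, -15 / sds, 15 / sds)
        # step-halving on log-likelihood decrease
        for _ in range(30):
            ll_new = _breslow_derivs(new, Xc, first, event_rows)[0]
            if ll_new >= ll - 1e-12:
                break
            new = (new + beta) / 2
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    if separated:
        warnings.warn(
            "possible complete separation in Cox fit; coefficients bounded", stacklevel=2
        )
    _, _, hess = _breslow_derivs(beta, Xc, first, event_rows)
    cov = np.linalg.pinv(-hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "z": z,
            "p": pvals,
            "hr": np.exp(beta),
            "hr_lower": np.exp(beta - 1.96 * se),
            "hr_upper": np.exp(beta + 1.96 * se),
        },
        index=pd.Index(names, name="covariate"),
    )


def _cox_efron(X, times, events, names) -> pd.DataFrame:
    from lifelines import CoxPHFitter

    df = pd.DataFrame(X, columns=names)
    df["T"] = times
    df["E"] = events
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    s = cph.summary
    return pd.DataFrame(
        {
            "coef": s["coef"].to_numpy(),
            "se": s["se(coef)"].to_numpy(),
            "z": s["z"].to_numpy(),
            "p": s["p"].to_numpy(),
            "hr": np.exp(s["coef"].to_numpy()),
            "hr_lower": np.exp((s["coef"] - 1.96 * s["se(coef)"]).to_numpy()),
            "hr_upper": np.exp((s["coef"] + 1.96 * s["se(coef)"]).to_numpy()),
        },
        index=pd.Index(names, name="covariate"),
    )


# ---------------------------------------------------------------------------
# ROC cutoff selection
# ---------------------------------------------------------------------------

def roc_cutoff(
    marker, outcome, criterion: str = "youden", name: str = "marker"
) -> CutoffResult:
    """ROC analysis of a continuous marker against a binary outcome.

    AUC is the tie-corrected rank statistic (ties get half credit); the
    cutoff is the observed marker value maximizing Youden's J, classifying
    ``marker > cutoff`` as high. The 95% CI uses the Hanley-McNeil SE and the
    p-value tests AUC = 0.5. ``direction='low'`` is reported when small
    marker values indicate risk (AUC computed on the flipped marker).
    """
    if criterion != "youden":
        raise ValueError("only the youden criterion is implemented")
    x = np.asarray(marker, dtype=float)
    y = np.asarray(outcome, dtype=int)
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = rankdata(x)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    direction = "high" if auc >= 0.5 else "low"
    auc_eff = auc if direction == "high" else 1 - auc

    q1 = auc_eff / (2 - auc_eff)
    q2 = 2 * auc_eff**2 / (1 + auc_eff)
    var = (
        auc_eff * (1 - auc_eff) + (n1 - 1) * (q1 - auc_eff**2) + (n0 - 1) * (q2 - auc_eff**2)
    ) / (n1 * n0)
    se = float(np.sqrt(max(var, 0.0)))
    if se > 0:
        pval = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        pval = 0.0 if auc != 0.5 else 1.0

    best_cut, best_j = None, -np.inf
    for c in np.unique(x):
        pred = x > c if direction == "high" else x < c
        tpr = (pred & (y == 1)).sum() / n1
        fpr = (pred & (y == 0)).sum() / n0
        j = tpr - fpr
        if j > best_j + 1e-12:
            best_j, best_cut = j, float(c)
    return CutoffResult(
        marker=name,
        cutoff=best_cut,
        auc=float(auc),
        ci_low=float(np.clip(auc - 1.96 * se, 0, 1)),
        ci_high=float(np.clip(auc + 1.96 * se, 0, 1)),
        p=pval,
        direction=direction,
    )
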