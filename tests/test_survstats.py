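"""Endpoint derivation, Kaplan-Meier, log-rank, Cox and ROC cutoffs."""

import numpy as np
import pandas as pd
import pytest

from cnascreen import (
    cox_fit,
    derive_endpoints,
    km_estimate,
    logrank_test,
    roc_cutoff,
)
from cnascreen._oracles import brute_auc, brute_km
from cnascreen.survstats import DAYS_PER_MONTH


def _record(sid="p1", reg="2004-01-01", prog="", death="", cause="alive",
            fu="2008-01-01"):
    return {"sample_id": sid, "registration_date": reg, "progression_date": prog,
            "death_date": death, "cause": cause, "last_followup_date": fu}


def _months(days):
    return days / DAYS_PER_MONTH


# ---------------------------------------------------------------------------
# Endpoints
# ---------------------------------------------------------------------------

def test_relapse_is_pfs_event():
    df = pd.DataFrame([_record(prog="2005-01-01", fu="2006-01-01")])
    ep = derive_endpoints(df).iloc[0]
    assert ep["pfs_event"] == 1
    assert ep["pfs_time"] == pytest.approx(_months(366))  # 2004 is a leap year


def test_other_cause_death_censors_pfs_and_lymphoma_os_but_not_os():
    df = pd.DataFrame(
        [_record(death="2005-09-01", cause="other", fu="2005-09-01")]
    )
    ep = derive_endpoints(df).iloc[0]
    days = (pd.Timestamp("2005-09-01") - pd.Timestamp("2004-01-01")).days
    assert ep["pfs_event"] == 0 and ep["pfs_time"] == pytest.approx(_months(days))
    assert ep["os_event"] == 1 and ep["os_time"] == pytest.approx(_months(days))
    assert ep["lyos_event"] == 0 and ep["lyos_time"] == pytest.approx(_months(days))


def test_alive_in_remission_censored_at_last_followup_everywhere():
    df = pd.DataFrame([_record(fu="2008-08-01")])
    ep = derive_endpoints(df).iloc[0]
    days = (pd.Timestamp("2008-08-01") - pd.Timestamp("2004-01-01")).days
    for e in ("pfs", "os", "lyos"):
        assert ep[f"{e}_event"] == 0
        assert ep[f"{e}_time"] == pytest.approx(_months(days))


def test_lymphoma_death_after_relapse():
    df = pd.DataFrame(
        [_record(prog="2005-01-01", death="2005-06-01", cause="lymphoma",
                 fu="2005-06-01")]
    )
    ep = derive_endpoints(df).iloc[0]
    assert ep["pfs_event"] == 1 and ep["os_event"] == 1 and ep["lyos_event"] == 1


def test_missing_registration_rejected():
    df = pd.DataFrame([_record(), _record(sid="p2", reg="")])
    ep = derive_endpoints(df)
    assert list(ep["sample_id"]) == ["p1"]


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_all_events_closed_form():
    km = km_estimate([1, 2, 3], [1, 1, 1])
    assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
    assert list(km.at_risk) == [3, 2, 1]


def test_km_all_censored_stays_at_one():
    km = km_estimate([5, 8, 13], [0, 0, 0])
    assert (km.survival == 1.0).all()
    assert km.survival_at(100) == 1.0


def test_km_mixed_hand_computed():
    # times 1,2,3,4,5; events 1,0,1,1,0:
    # S(1)=4/5, S(3)=4/5*2/3=8/15, S(4)=8/15*1/2=4/15
    km = km_estimate([1, 2, 3, 4, 5], [1, 0, 1, 1, 0])
    assert km.survival_at(1) == pytest.approx(0.8)
    assert km.survival_at(3) == pytest.approx(8 / 15)
    assert km.survival_at(4.5) == pytest.approx(4 / 15)
    assert km.survival_at(0.5) == 1.0


def test_km_matches_brute_force_and_is_monotone():
    rng = np.random.default_rng(0)
    t = rng.exponential(10, 30).round(1)
    e = rng.integers(0, 2, 30)
    if e.sum() == 0:
        e[0] = 1
    km = km_estimate(t, e)
    assert (np.diff(km.survival) <= 1e-12).all()
    for tt, s in brute_km(t, e):
        assert km.survival_at(tt) == pytest.approx(s)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def test_logrank_identical_groups():
    t = [2, 4, 6, 8]
    e = [1, 0, 1, 1]
    chi2, p = logrank_test(t, e, t, e)
    assert chi2 == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)


def test_logrank_symmetric_in_group_order():
    rng = np.random.default_rng(1)
    ta, tb = rng.exponential(10, 25), rng.exponential(20, 25)
    ea = np.ones(25, int)
    s1, p1 = logrank_test(ta, ea, tb, ea)
    s2, p2 = logrank_test(tb, ea, ta, ea)
    assert s1 == pytest.approx(s2)
    assert p1 == pytest.approx(p2)


def test_logrank_power_under_strong_hazard_ratio():
    hits = 0
    reps = 20
    for i in range(reps):
        rng = np.random.default_rng(100 + i)
        ta = rng.exponential(1.0, 200)
        tb = rng.exponential(3.0, 200)
        _, p = logrank_test(ta, np.ones(200, int), tb, np.ones(200, int))
        hits += int(p < 0.001)
    assert hits >= int(0.95 * reps)


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def _sim_cox(rng, n, beta, censor=0.004, hazard=0.02):
    x = rng.normal(size=n)
    t = rng.exponential(1 / (hazard * np.exp(beta * x)))
    c = rng.exponential(1 / censor, size=n)
    return x, np.minimum(t, c), (t <= c).astype(int)


def test_cox_null_within_3se():
    rng = np.random.default_rng(2)
    x, t, e = _sim_cox(rng, 400, 0.0)
    fit = cox_fit(x, t, e)
    assert abs(fit["coef"].iloc[0]) < 3 * fit["se"].iloc[0]


def test_cox_recovers_ln2_within_15pct():
    rng = np.random.default_rng(3)
    x, t, e = _sim_cox(rng, 500, np.log(2))
    fit = cox_fit(x, t, e)
    assert abs(fit["coef"].iloc[0] - np.log(2)) / np.log(2) < 0.15


def test_cox_breslow_agrees_with_lifelines_efron_without_ties():
    rng = np.random.default_rng(4)
    x, t, e = _sim_cox(rng, 150, 0.5)
    assert len(np.unique(t)) == len(t)  # tie-free: both conventions coincide
    b = cox_fit(x, t, e, ties="breslow")
    f = cox_fit(x, t, e, ties="efron")
    assert b["coef"].iloc[0] == pytest.approx(f["coef"].iloc[0], abs=1e-4)
    assert b["se"].iloc[0] == pytest.approx(f["se"].iloc[0], rel=1e-3)


def test_cox_constant_covariate_errors_and_collinearity_warns():
    rng = np.random.default_rng(5)
    x, t, e = _sim_cox(rng, 60, 0.3)
    with pytest.raises(ValueError):
        cox_fit(np.ones(60), t, e)
    with pytest.warns(UserWarning, match="collinear"):
        cox_fit(np.column_stack([x, x]), t, e)


def test_cox_binary_covariate_sign_matches_logrank_direction():
    rng = np.random.default_rng(6)
    g = np.repeat([0, 1], 60)
    t = np.where(g == 1, rng.exponential(5, 120), rng.exponential(15, 120))
    e = np.ones(120, int)
    fit = cox_fit(g.astype(float), t, e)
    assert fit["coef"].iloc[0] > 0  # group 1 dies faster -> higher hazard


# ---------------------------------------------------------------------------
# ROC cutoff
# ---------------------------------------------------------------------------

def test_roc_perfect_separation():
    marker = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
    outcome = np.array([0, 0, 0, 1, 1, 1])
    cut = roc_cutoff(marker, outcome)
    assert cut.auc == 1.0
    assert 0.3 <= cut.cutoff < 0.7
    assert cut.direction == "high"


def test_roc_null_auc_near_half():
    rng = np.random.default_rng(7)
    cut = roc_cutoff(rng.normal(size=2000), rng.integers(0, 2, 2000))
    assert abs(cut.auc - 0.5) < 0.05


def test_roc_auc_matches_all_pairs_oracle_with_ties():
    rng = np.random.default_rng(8)
    for _ in range(25):
        m = rng.normal(size=10).round(1)
        y = rng.integers(0, 2, 10)
        if 0 < y.sum() < 10:
            cut = roc_cutoff(m, y)
            assert cut.auc == pytest.approx(brute_auc(m, y), abs=1e-12)
            assert m.min() <= cut.cutoff <= m.max()


def test_roc_single_class_errors():
    with pytest.raises(ValueError):
        roc_cutoff([1.0, 2.0], [1, 1])
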