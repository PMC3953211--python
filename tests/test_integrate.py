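"""SNR statistic, permutation p-values, BH FDR and gene selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnascreen import (
    GAIN,
    LOSS,
    GeneCNATable,
    associate,
    bh_fdr,
    expression_concordance,
    permutation_pvalue,
    snr_statistic,
)


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------

def test_snr_hand_value():
    # ({1,3} vs {0,2}): (2-1)/(sqrt(2)+sqrt(2))
    assert snr_statistic([1, 3], [0, 2]) == pytest.approx(1 / (2 * math.sqrt(2)))


def test_snr_equal_groups_zero_and_antisymmetry():
    a, b = [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]
    assert snr_statistic(a, a) == 0.0
    assert snr_statistic(a, b) == pytest.approx(-snr_statistic(b, a))


def test_snr_zero_variance_sentinels():
    assert snr_statistic([1, 1], [1, 1]) == 0.0
    assert snr_statistic([2, 2], [1, 1]) == math.inf
    assert snr_statistic([0, 0], [1, 1]) == -math.inf


def test_snr_requires_two_per_group():
    with pytest.raises(ValueError):
        snr_statistic([1.0], [0.0, 2.0])


@given(
    values=st.lists(st.floats(-50, 50), min_size=6, max_size=14),
    shift=st.floats(-100, 100),
    scale=st.floats(0.01, 100),
)
@settings(max_examples=60, derandomize=True, deadline=None)
def test_snr_location_and_scale_invariance(values, shift, scale):
    x = np.asarray(values)
    a, b = x[:3], x[3:]
    if a.std(ddof=1) + b.std(ddof=1) == 0:
        return
    base = snr_statistic(a, b)
    assert snr_statistic(a + shift, b + shift) == pytest.approx(base, rel=1e-6, abs=1e-9)
    assert snr_statistic(a * scale, b * scale) == pytest.approx(base, rel=1e-6, abs=1e-9)


# ---------------------------------------------------------------------------
# Permutation p-value
# ---------------------------------------------------------------------------

def test_permutation_add_one_convention():
    # huge separation: no random relabeling reaches the observed statistic
    values = np.concatenate([np.array([100.0, 101, 102, 103, 104, 105, 106, 107]),
                             np.random.default_rng(0).normal(size=32)])
    flags = np.arange(40) < 8
    p = permutation_pvalue(values, flags, n_perm=99, sided="greater", seed=1)
    assert p == pytest.approx(1 / 100)


def test_constant_expression_gives_p_one():
    p = permutation_pvalue(np.ones(12), np.arange(12) < 4, n_perm=200,
                           sided="two", seed=0)
    assert p == 1.0


def test_exhaustive_matches_monte_carlo_within_binomial_error():
    rng = np.random.default_rng(2)
    values = rng.normal(size=9)
    flags = np.arange(9) < 3
    p_exact = permutation_pvalue(values, flags, sided="two", exact=True)
    n_perm = 4000
    p_mc = permutation_pvalue(values, flags, n_perm=n_perm, sided="two", seed=3)
    se = math.sqrt(p_exact * (1 - p_exact) / n_perm)
    assert abs(p_mc - p_exact) < 4 * se + 1 / n_perm


def test_null_rejection_rate_near_nominal():
    rng = np.random.default_rng(4)
    flags = np.arange(40) < 8
    rej = sum(
        permutation_pvalue(rng.normal(size=40), flags, n_perm=500,
                           sided="greater", seed=100 + g) < 0.05
        for g in range(500)
    )
    assert 0.02 <= rej / 500 <= 0.08


def test_permutation_requires_both_classes():
    with pytest.raises(ValueError):
        permutation_pvalue(np.ones(6), np.zeros(6, dtype=bool), n_perm=10)


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def _bh_direct(p):
    """Literal step-up rule, written independently of the production path."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def test_bh_matches_direct_step_up_on_random_vectors():
    rng = np.random.default_rng(5)
    for _ in range(20):
        p = rng.uniform(size=int(rng.integers(1, 40)))
        assert np.allclose(bh_fdr(p), _bh_direct(p))
    assert ((bh_fdr(rng.uniform(size=50)) > 0) & (bh_fdr(rng.uniform(size=50)) <= 1)).all()


# ---------------------------------------------------------------------------
# associate
# ---------------------------------------------------------------------------

def _table(carrier_idx, delta, n=40, sd=0.5, seed=0, direction=GAIN,
           genes=("driver", "passenger")):
    rng = np.random.default_rng(seed)
    cols = [f"S{i}" for i in range(n)]
    status = pd.DataFrame("neutral", index=list(genes), columns=cols)
    status.iloc[:, list(carrier_idx)] = direction
    expr = pd.DataFrame(rng.normal(0, sd, (len(genes), n)), index=list(genes),
                        columns=cols)
    expr.iloc[0, list(carrier_idx)] += delta
    return GeneCNATable(status=status, seg_mean=expr * 0.0, expression=expr)


def test_associate_selects_planted_gain_driver():
    table = _table(range(8), delta=1.5, seed=1)
    res = associate(table, n_perm=500, seed=0).set_index("gene_id")
    assert bool(res.at["driver", "selected"])
    assert res.at["driver", "snr"] > 0
    assert res.at["driver", "n_cna"] == 8


def test_associate_selects_planted_loss_driver_with_negative_snr():
    table = _table(range(8), delta=-1.5, seed=2, direction=LOSS)
    res = associate(table, n_perm=500, seed=0).set_index("gene_id")
    assert bool(res.at["driver", "selected"])
    assert res.at["driver", "snr"] < 0
    assert res.at["driver", "direction"] == LOSS


def test_gene_aberrant_in_two_samples_never_selected():
    table = _table(range(2), delta=50.0, seed=3)
    res = associate(table, n_perm=500, seed=0, min_samples=3).set_index("gene_id")
    assert res.at["driver", "p"] < 0.05          # overwhelming signal...
    assert not bool(res.at["driver", "selected"])  # ...but below min recurrence


def test_associate_is_gene_order_invariant():
    table = _table(range(6), delta=1.0, seed=4, genes=("a", "b", "c"))
    res1 = associate(table, n_perm=300, seed=9)
    flipped = GeneCNATable(
        status=table.status.iloc[::-1], seg_mean=table.seg_mean.iloc[::-1],
        expression=table.expression.iloc[::-1],
    )
    res2 = associate(flipped, n_perm=300, seed=9)
    m1 = res1.set_index(["gene_id", "direction"]).sort_index()
    m2 = res2.set_index(["gene_id", "direction"]).sort_index()
    pd.testing.assert_frame_equal(m1, m2)


def test_associate_skips_all_missing_gene():
    table = _table(range(6), delta=1.0, seed=5)
    table.status.loc["passenger"] = "missing"
    res = associate(table, n_perm=100, seed=0)
    assert "passenger" not in set(res["gene_id"])


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def test_concordance_trivial_lines():
    x = np.array([1.0, 2, 3, 4, 5])
    r, _ = expression_concordance(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    r2, _ = expression_concordance(x, -x)
    assert r2 == pytest.approx(-1.0)


def test_concordance_recovers_true_correlation():
    rng = np.random.default_rng(6)
    rho, n, reps = 0.6, 24, 40
    cov = np.array([[1, rho], [rho, 1]])
    est = []
    for _ in range(reps):
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        est.append(expression_concordance(xy[:, 0], xy[:, 1])[0])
    se = (1 - rho**2) / math.sqrt(n - 1)
    assert abs(np.mean(est) - rho) < 3 * se / math.sqrt(reps) + 0.02
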