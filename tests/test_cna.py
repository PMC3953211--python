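"""Normalization, segmentation and calling against planted truth and oracles."""

import numpy as np
import pandas as pd
import pytest

from cnascreen import (
    GAIN,
    LOSS,
    NEUTRAL,
    NoiseModel,
    call_aberrations,
    cbs_segment,
    estimate_noise,
    lowess_normalize,
    map_genes_to_calls,
)
from cnascreen._oracles import brute_gene_call, brute_single_changepoint
from cnascreen.cna import ProbeProfile
from conftest import make_profile


# ---------------------------------------------------------------------------
# LOWESS
# ---------------------------------------------------------------------------

def test_lowess_flat_profile_nearly_unchanged():
    rng = np.random.default_rng(0)
    y = rng.normal(0, 0.05, 200)
    out = lowess_normalize(make_profile(y, normalized=False))
    assert out.normalized
    # nothing to remove beyond the (near-zero) local level
    assert np.sqrt(np.mean((out.values() - (y - np.median(y))) ** 2)) < 0.03


def test_lowess_removes_planted_sinusoidal_bias():
    rng = np.random.default_rng(1)
    n = 600
    bias = 0.3 * np.sin(2 * np.pi * np.arange(n) / n)
    noise = rng.normal(0, 0.05, n)
    out = lowess_normalize(make_profile(bias + noise, normalized=False))
    residual_bias = out.values() - noise
    assert np.sqrt(np.mean(residual_bias**2)) < 0.03


def test_lowess_defaults_are_four_iterations_30pct_window():
    import inspect

    sig = inspect.signature(lowess_normalize)
    assert sig.parameters["window_fraction"].default == 0.30
    assert sig.parameters["iterations"].default == 4


def test_lowess_constant_covariate_is_identity_with_warning():
    y = np.arange(20, dtype=float)
    with pytest.warns(UserWarning, match="constant covariate"):
        out = lowess_normalize(make_profile(y, normalized=False),
                               covariate=np.ones(20))
    assert np.allclose(out.values(), y)


def test_lowess_requires_enough_probes():
    with pytest.raises(ValueError):
        lowess_normalize(make_profile(np.zeros(5), normalized=False))


def test_nan_probes_dropped_and_counted():
    y = np.zeros(30)
    y[3] = np.nan
    prof = make_profile(y, normalized=False)
    assert prof.n_dropped == 1
    assert prof.n_probes == 29


# ---------------------------------------------------------------------------
# CBS
# ---------------------------------------------------------------------------

def test_cbs_flat_profile_single_segment():
    rng = np.random.default_rng(2)
    prof = make_profile(rng.normal(0, 0.01, 120))
    segs = cbs_segment(prof, n_perm=200, seed=0)
    assert len(segs) == 1
    assert segs["n_probes"].iloc[0] == 120


def test_cbs_recovers_single_step(step_profile):
    segs = cbs_segment(step_profile, n_perm=200, seed=0)
    assert len(segs) == 2
    boundary = segs["start"].iloc[1] // 1000
    assert abs(boundary - 50) <= 2
    # cross-check the located change point against the exhaustive maximizer
    k, _ = brute_single_changepoint(step_profile.values())
    assert abs(boundary - k) <= 2


def test_cbs_recovers_three_planted_segments():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 0.1, 300)
    x[100:200] += 0.8
    x[200:] -= 0.8
    segs = cbs_segment(make_profile(x), n_perm=200, seed=1)
    assert len(segs) == 3
    assert np.allclose(segs["seg_mean"].to_numpy(), [0.0, 0.8, -0.8], atol=0.1)


def test_cbs_partitions_probes():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 0.2, 150)
    x[40:90] += 1.0
    prof = make_profile(x)
    segs = cbs_segment(prof, n_perm=100, seed=2)
    assert segs["n_probes"].sum() == prof.n_probes
    assert (segs["start"].iloc[1:].to_numpy()
            > segs["start"].iloc[:-1].to_numpy()).all()


def test_cbs_few_probes_single_segment():
    prof = make_profile([0.0, 5.0, 0.1])
    segs = cbs_segment(prof, n_perm=50, min_width=2, seed=0)
    assert len(segs) == 1


# ---------------------------------------------------------------------------
# Noise model and calling
# ---------------------------------------------------------------------------

def test_estimate_noise_constant_and_hand_values():
    prof = make_profile(np.full(12, 0.7))
    nm = estimate_noise([prof])
    assert nm.cohort_median == pytest.approx(0.7)
    assert nm.cohort_sd == pytest.approx(0.0)

    prof2 = make_profile([-1.0, 0.0, 1.0])
    nm2 = estimate_noise([prof2])
    assert nm2.cohort_median == pytest.approx(0.0)
    assert nm2.cohort_sd == pytest.approx(1.0)  # sample SD convention
    assert nm2.k == 2  # two SDs from the median by default


def test_estimate_noise_residuals_isolate_noise_from_aberrations():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 0.1, 200)
    x[100:] += 2.0  # huge aberration would inflate a raw-pool SD
    prof = make_profile(x)
    segs = cbs_segment(prof, n_perm=100, seed=0)
    nm = estimate_noise([prof], segs)
    assert nm.cohort_sd == pytest.approx(0.1, rel=0.2)


@pytest.mark.parametrize(
    "seg_mean,expected",
    [(0.25, GAIN), (-0.25, LOSS), (0.15, NEUTRAL), (-0.15, NEUTRAL)],
)
def test_call_thresholds(seg_mean, expected):
    segs = pd.DataFrame(
        [{"sample_id": "s", "chrom": "chr1", "start": 0, "end": 10,
          "n_probes": 1, "seg_mean": seg_mean, "call": NEUTRAL}]
    )
    out = call_aberrations(segs, NoiseModel(0.0, 0.1, k=2))
    assert out["call"].iloc[0] == expected


def test_calls_monotone_in_segment_mean():
    means = np.linspace(-1, 1, 201)
    segs = pd.DataFrame(
        {"sample_id": "s", "chrom": "chr1", "start": np.arange(201) * 10,
         "end": np.arange(201) * 10 + 10, "n_probes": 1, "seg_mean": means,
         "call": NEUTRAL}
    )
    out = call_aberrations(segs, NoiseModel(0.0, 0.1, k=2))
    rank = out["call"].map({LOSS: 0, NEUTRAL: 1, GAIN: 2}).to_numpy()
    assert (np.diff(rank) >= 0).all()


def test_zero_sd_calls_everything_with_warning():
    segs = pd.DataFrame(
        [{"sample_id": "s", "chrom": "chr1", "start": 0, "end": 10,
          "n_probes": 1, "seg_mean": 1e-6, "call": NEUTRAL}]
    )
    with pytest.warns(UserWarning, match="cohort SD is 0"):
        out = call_aberrations(segs, NoiseModel(0.0, 0.0))
    assert out["call"].iloc[0] == GAIN


# ---------------------------------------------------------------------------
# Gene mapping
# ---------------------------------------------------------------------------

def _two_segment_frame():
    return pd.DataFrame(
        [
            {"sample_id": "s1", "chrom": "chr1", "start": 0, "end": 100,
             "n_probes": 10, "seg_mean": 0.9, "call": GAIN},
            {"sample_id": "s1", "chrom": "chr1", "start": 100, "end": 200,
             "n_probes": 10, "seg_mean": 0.0, "call": NEUTRAL},
        ]
    )


def test_gene_inside_gain_segment_is_gain():
    ann = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "start": [10], "end": [50]})
    table = map_genes_to_calls(_two_segment_frame(), ann)
    assert table.status.at["g", "s1"] == GAIN


def test_gene_spanning_breakpoint_takes_majority_segment():
    # 70% of the gene body in the gain segment, 30% in the neutral one
    ann = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "start": [30], "end": [130]})
    table = map_genes_to_calls(_two_segment_frame(), ann)
    assert table.status.at["g", "s1"] == GAIN
    assert table.seg_mean.at["g", "s1"] == pytest.approx(0.9)


def test_gene_on_absent_chromosome_is_missing():
    ann = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr9"], "start": [0], "end": [10]})
    table = map_genes_to_calls(_two_segment_frame(), ann)
    assert table.status.at["g", "s1"] == "missing"


def test_gene_mapping_matches_per_base_oracle():
    rng = np.random.default_rng(6)
    for _ in range(25):
        edges = [0, *sorted(rng.choice(np.arange(10, 190, 10), 2, replace=False)), 200]
        segs = pd.DataFrame(
            [{"sample_id": "s1", "chrom": "chr1", "start": int(a), "end": int(b),
              "n_probes": 1, "seg_mean": float(rng.normal()), "call": NEUTRAL}
             for a, b in zip(edges[:-1], edges[1:])]
        )
        g0 = int(rng.integers(0, 180))
        g1 = g0 + int(rng.integers(5, 50))
        ann = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                            "start": [g0], "end": [g1]})
        table = map_genes_to_calls(segs, ann)
        want_call, want_mean = brute_gene_call(segs, "chr1", g0, g1, "s1")
        assert table.status.at["g", "s1"] == want_call
        if want_call != "missing":
            assert table.seg_mean.at["g", "s1"] == pytest.approx(want_mean)
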