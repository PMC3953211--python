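"""Calibration, recovery and power studies on synthetic data.

Each study regenerates its inputs from a seed, runs the production code path
and measures a recovery or error rate against the planted truth (or against a
brute-force reference from :mod:`cnascreen._oracles`). The acceptance tests
assert on these rates; ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _oracles as oracles
from ._util import rng_for
from .cna import GAIN, LOSS, ProbeProfile, cbs_segment, GeneCNATable
from .ihc import ColourClassSpec, classify_pixels, staining_coverage, dichotomize
from .integrate import associate, permutation_pvalue
from .pipeline import PipelineConfig, run_screen
from .regions import cnv_filter, minimal_common_regions, subgroup_frequency_test
from .survstats import cox_fit, logrank_test, roc_cutoff
from .synthcohort import (
    Aberration,
    DriverGene,
    SimConfig,
    default_palettes,
    generate_cohort,
    generate_ihc_image,
)


def _step_profile(rng, n_side: int, noise_sd: float, step: float) -> ProbeProfile:
    n = 2 * n_side
    x = rng.normal(0.0, noise_sd, size=n)
    x[n_side:] += step
    df = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(n) * 1000,
         "end": np.arange(n) * 1000 + 60, "log2": x}
    )
    return ProbeProfile("sim", df, normalized=True)


def breakpoint_recovery_study(
    n_chroms: int = 200,
    n_side: int = 100,
    noise_sd: float = 0.1,
    step_mult: float = 3.0,
    alpha: float = 0.05,
    n_perm: int = 200,
    tolerance_probes: int = 2,
    seed: int = 0,
) -> dict:
    """Recovery of a single planted step and the flat false-split rate.

    Simulates ``n_chroms`` chromosomes with a step of ``step_mult * noise_sd``
    at the midpoint plus the same number of flat chromosomes; runs CBS on
    each and scores (a) the fraction of stepped chromosomes with a segment
    boundary within ``tolerance_probes`` of the true change point and (b) the
    fraction of flat chromosomes returned as a single segment.
    """
    hits = 0
    for i in range(n_chroms):
        rng = rng_for(seed, "bk", i)
        prof = _step_profile(rng, n_side, noise_sd, step_mult * noise_sd)
        segs = cbs_segment(prof, alpha=alpha, n_perm=n_perm, rng=rng)
        bounds = {int(row.start) // 1000 for row in segs.itertuples()} - {0}
        if any(abs(b - n_side) <= tolerance_probes for b in bounds):
            hits += 1
    flat_single = 0
    for i in range(n_chroms):
        rng = rng_for(seed, "flat", i)
        prof = _step_profile(rng, n_side, noise_sd, 0.0)
        segs = cbs_segment(prof, alpha=alpha, n_perm=n_perm, rng=rng)
        flat_single += int(len(segs) == 1)
    return {
        "breakpoint_recovery_rate": hits / n_chroms,
        "flat_single_segment_rate": flat_single / n_chroms,
        "n": n_chroms,
    }


def permutation_calibration_study(
    n_genes: int = 2000,
    n_samples: int = 40,
    n_cna: int = 8,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I rate of the SNR permutation test under label-independent expression."""
    rng = np.random.default_rng(rng_for(seed, "calib").integers(2**31))
    flags = np.zeros(n_samples, dtype=bool)
    flags[:n_cna] = True
    rejections = 0
    for g in range(n_genes):
        values = rng.normal(size=n_samples)
        p = permutation_pvalue(values, flags, n_perm=n_perm, sided="greater",
                               rng=rng_for(seed, "calib", g))
        rejections += int(p < alpha)
    return {"rejection_rate": rejections / n_genes, "n": n_genes}


def _toy_table(rng, n_samples, n_cna, delta, sd, n_passengers):
    genes = ["driver"] + [f"pass{i}" for i in range(n_passengers)]
    carriers = rng.choice(n_samples, size=n_cna, replace=False)
    status = pd.DataFrame("neutral", index=genes,
                          columns=[f"S{i}" for i in range(n_samples)])
    status.iloc[:, carriers] = GAIN  # all genes sit in the gained region
    expr = pd.DataFrame(rng.normal(0.0, sd, size=(len(genes), n_samples)),
                        index=genes, columns=status.columns)
    expr.iloc[0, carriers] += delta
    return GeneCNATable(status=status, seg_mean=status.notna().astype(float) * 0,
                        expression=expr)


def driver_selection_study(
    n_reps: int = 200,
    n_samples: int = 40,
    n_cna: int = 8,
    delta: float = 1.0,
    sd: float = 0.5,
    n_passengers: int = 4,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Power to select a planted CNA-coupled driver, and passenger type-I rate."""
    driver_hits = 0
    passenger_hits = 0
    passenger_tests = 0
    for rep in range(n_reps):
        rng = rng_for(seed, "drv", rep)
        table = _toy_table(rng, n_samples, n_cna, delta, sd, n_passengers)
        res = associate(table, alpha=alpha, min_samples=3, n_perm=n_perm,
                        seed=int(rng_for(seed, "drvseed", rep).integers(2**31)))
        res = res.set_index(["gene_id", "direction"])
        driver_hits += int(res.at[("driver", GAIN), "selected"])
        for i in range(n_passengers):
            passenger_hits += int(res.at[(f"pass{i}", GAIN), "selected"])
            passenger_tests += 1
    return {
        "driver_selection_rate": driver_hits / n_reps,
        "passenger_selection_rate": passenger_hits / passenger_tests,
        "n": n_reps,
    }


def logrank_type1_study(
    n_sims: int = 1000, n_per_arm: int = 50, hazard: float = 0.02,
    censor_rate: float = 0.005, alpha: float = 0.05, seed: int = 0,
) -> dict:
    """Log-rank rejection rate for two arms drawn from the same exponential."""
    rej = 0
    for i in range(n_sims):
        rng = rng_for(seed, "lr", i)
        t = rng.exponential(1 / hazard, size=2 * n_per_arm)
        c = rng.exponential(1 / censor_rate, size=2 * n_per_arm)
        obs = np.minimum(t, c)
        ev = (t <= c).astype(int)
        _, p = logrank_test(obs[:n_per_arm], ev[:n_per_arm],
                            obs[n_per_arm:], ev[n_per_arm:])
        rej += int(p < alpha)
    return {"rejection_rate": rej / n_sims, "n": n_sims}


def cox_recovery_study(
    n: int = 500, true_log_hr: float = float(np.log(2)), hazard: float = 0.02,
    censor_rate: float = 0.004, seed: int = 0,
) -> dict:
    """Breslow Cox estimate of a known log HR (standard-normal covariate)."""
    rng = rng_for(seed, "cox")
    x = rng.normal(size=n)
    t = rng.exponential(1 / (hazard * np.exp(true_log_hr * x)))
    c = rng.exponential(1 / censor_rate, size=n)
    obs = np.minimum(t, c)
    ev = (t <= c).astype(int)
    fit = cox_fit(x, obs, ev, ties="breslow")
    est = float(fit["coef"].iloc[0])
    return {
        "log_hr_estimate": est,
        "true_log_hr": true_log_hr,
        "relative_error": abs(est - true_log_hr) / true_log_hr,
        "n": n,
    }


def oracle_agreement_study(n_instances: int = 100, seed: int = 0) -> dict:
    """Fraction of random small instances where fast paths match brute force."""
    from .cna import NEUTRAL, call_aberrations, map_genes_to_calls
    from .regions import regions_to_frame

    agree = dict.fromkeys(["regions", "cnv_filter", "fisher", "auc", "gene_map"], 0)
    for i in range(n_instances):
        rng = rng_for(seed, "oracle", i)

        # minimal common regions vs per-base counting
        n_seg = int(rng.integers(3, 10))
        rows = []
        for k in range(n_seg):
            s = int(rng.integers(0, 80))
            e = s + int(rng.integers(5, 60))
            rows.append({"sample_id": f"S{rng.integers(1, 6)}", "chrom": "chr1",
                         "start": s, "end": e, "n_probes": 1,
                         "seg_mean": 1.0, "call": GAIN})
        calls = pd.DataFrame(rows).drop_duplicates(["sample_id", "start", "end"])
        n_samp = 5
        thresh = int(rng.integers(1, 4))
        got = minimal_common_regions(calls, min_freq=thresh / n_samp,
                                     direction=GAIN, n_samples=n_samp)
        want = oracles.brute_minimal_common_regions(calls, GAIN, thresh)
        agree["regions"] += int([(r.chrom, r.start, r.end) for r in got] == want)

        # CNV filter vs quadratic overlap count
        ann = pd.DataFrame(
            {"gene_id": [f"g{j}" for j in range(6)], "chrom": "chr1",
             "start": rng.integers(0, 150, 6)}
        )
        ann["end"] = ann["start"] + rng.integers(5, 40, 6)
        cat = pd.DataFrame({"chrom": "chr1", "start": rng.integers(0, 150, 25)})
        cat["end"] = cat["start"] + rng.integers(1, 30, 25)
        max_cnv = int(rng.integers(0, 6))
        retained, counts = cnv_filter(ann, cat, max_cnv=max_cnv)
        brute = oracles.brute_cnv_counts(ann, cat)
        agree["cnv_filter"] += int(
            counts.sort_index().equals(brute.sort_index())
            and set(retained) == set(brute.index[brute <= max_cnv])
        )

        # Fisher vs hypergeometric enumeration
        tab = rng.integers(0, 12, size=(2, 2))
        if tab.sum(axis=1).min() > 0:
            carriers = np.repeat([True, False, True, False],
                                 [tab[0, 0], tab[0, 1], tab[1, 0], tab[1, 1]])
            labels = np.repeat(["a", "b"], [tab[0].sum(), tab[1].sum()])
            _, p = subgroup_frequency_test(carriers, labels)
            p_brute = oracles.brute_fisher_two_sided(tab)
            agree["fisher"] += int(abs(p - p_brute) < 1e-9)
        else:
            agree["fisher"] += 1

        # AUC vs all-pairs concordance
        m = rng.normal(size=10).round(1)  # rounding forces some ties
        y = rng.integers(0, 2, size=10)
        if 0 < y.sum() < 10:
            cut = roc_cutoff(m, y)
            agree["auc"] += int(abs(cut.auc - oracles.brute_auc(m, y)) < 1e-12)
        else:
            agree["auc"] += 1

        # gene-to-segment mapping vs per-base tally
        bounds = np.sort(rng.choice(np.arange(10, 200, 10),
                                    size=int(rng.integers(1, 4)), replace=False))
        edges = [0, *bounds.tolist(), 200]
        segs = pd.DataFrame(
            [{"sample_id": "S1", "chrom": "chr1", "start": a, "end": b,
              "n_probes": 1, "seg_mean": float(rng.normal()), "call": NEUTRAL}
             for a, b in zip(edges[:-1], edges[1:])]
        )
        g0 = int(rng.integers(0, 180))
        g1 = g0 + int(rng.integers(5, 40))
        gene = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                             "start": [g0], "end": [g1]})
        table = map_genes_to_calls(segs, gene)
        want_call, want_mean = oracles.brute_gene_call(segs, "chr1", g0, g1, "S1")
        got_call = table.status.at["g", "S1"]
        got_mean = table.seg_mean.at["g", "S1"]
        same_mean = (np.isnan(want_mean) and np.isnan(got_mean)) or want_mean == got_mean
        agree["gene_map"] += int(got_call == want_call and same_mean)

    return {f"{k}_agreement": v / n_instances for k, v in agree.items()} | {
        "n": n_instances
    }


def ihc_study(seed: int = 0, jitter_sd: float = 10.0, n_patients: int = 40) -> dict:
    """Exactness on exemplar-only images, jitter error rate, cutoff recovery."""
    spec = ColourClassSpec(default_palettes())

    exact = generate_ihc_image(50, 50, (0.25, 0.45, 0.2, 0.1), jitter_sd=0.0,
                               seed=seed)
    cm = classify_pixels(exact.image, spec)
    exact_errors = int((cm != exact.true_map).sum())
    cov = staining_coverage(cm)

    jit = generate_ihc_image(100, 100, (0.3, 0.3, 0.2, 0.2), jitter_sd=jitter_sd,
                             seed=seed + 1)
    cmj = classify_pixels(jit.image, spec)
    jitter_error = float((cmj != jit.true_map).mean())

    # cutoff recovery: events occur only above a planted coverage threshold
    rng = np.random.default_rng(seed + 2)
    coverages = pd.Series(rng.uniform(0, 0.24, size=n_patients),
                          index=[f"P{i}" for i in range(n_patients)])
    c_true = 0.089
    events = pd.Series((coverages > c_true).astype(int), index=coverages.index)
    _, cut = dichotomize(coverages, events)
    below = coverages[coverages <= c_true]
    above = coverages[coverages > c_true]
    neighbours = sorted([below.max(), above.min()])
    cutoff_ok = neighbours[0] - 1e-12 <= cut.cutoff <= neighbours[1] + 1e-12
    return {
        "exact_pixel_errors": exact_errors,
        "exact_coverage_error": abs(cov.coverage_all - exact.true_coverage),
        "jitter_pixel_error_rate": jitter_error,
        "recovered_cutoff": float(cut.cutoff),
        "cutoff_within_one_value": bool(cutoff_ok),
    }


def end_to_end_config(seed: int = 0) -> SimConfig:
    """The standard one-driver screening cohort used for end-to-end studies."""
    return SimConfig(seed=seed)


def end_to_end_study(n_reps: int = 50, seed: int = 0,
                     n_perm: int = 1000, cbs_n_perm: int = 200) -> dict:
    """Fraction of replicate cohorts whose planted driver is a reported biomarker."""
    hits = 0
    for rep in range(n_reps):
        rep_seed = int(rng_for(seed, "e2e", rep).integers(2**31))
        cohort = generate_cohort(end_to_end_config(seed=rep_seed))
        cfg = PipelineConfig(seed=rep_seed, n_perm=n_perm, cbs_n_perm=cbs_n_perm)
        report = run_screen(cohort, cfg)
        driver = cohort.truth.driver_ids[0]
        hits += int(driver in set(report.biomarkers["gene_id"]))
    return {"driver_biomarker_rate": hits / n_reps, "n": n_reps}
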