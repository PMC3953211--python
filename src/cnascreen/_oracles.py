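"""Brute-force reference implementations used to validate the fast paths.

Each function here recomputes a quantity by direct enumeration (per-base
counting, all-pairs scans, exhaustive hypergeometric sums) and shares no code
with the production implementations it checks. They are quadratic or worse
and meant for small instances only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


def per_base_region_count(calls: pd.DataFrame, direction: str) -> dict[int, set[str]]:
    """Carrier set at every base position, by literal per-base tallying."""
    sub = calls[calls["call"] == direction]
    cover: dict[int, set[str]] = {}
    for _, row in sub.iterrows():
        for pos in range(int(row["start"]), int(row["end"])):
            cover.setdefault(pos, set()).add(row["sample_id"])
    return cover


def brute_minimal_common_regions(
    calls: pd.DataFrame, direction: str, threshold: int
) -> list[tuple[str, int, int]]:
    """Maximal per-base runs with carrier count >= threshold, one chrom at a time."""
    out = []
    for chrom in pd.unique(calls["chrom"]):
        cover = per_base_region_count(calls[calls["chrom"] == chrom], direction)
        qualifying = sorted(p for p, s in cover.items() if len(s) >= threshold)
        if not qualifying:
            continue
        run_start = prev = qualifying[0]
        for p in qualifying[1:]:
            if p != prev + 1:
                out.append((str(chrom), run_start, prev + 1))
                run_start = p
            prev = p
        out.append((str(chrom), run_start, prev + 1))
    return out


def brute_cnv_counts(annotation: pd.DataFrame, catalogue: pd.DataFrame) -> pd.Series:
    """All-pairs >=1 bp overlap counts between genes and catalogue records."""
    genes = annotation.set_index("gene_id") if "gene_id" in annotation.columns else annotation
    counts = {}
    for gid, g in genes.iterrows():
        c = 0
        for _, r in catalogue.iterrows():
            if r["chrom"] == g["chrom"] and r["start"] < g["end"] and g["start"] < r["end"]:
                c += 1
        counts[gid] = c
    return pd.Series(counts)


def brute_fisher_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities <= observed."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    dist = hypergeom(n, r1, c1)
    p_obs = dist.pmf(a)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = dist.pmf(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


def brute_auc(marker: np.ndarray, outcome: np.ndarray) -> float:
    """Fraction of concordant (case, control) pairs, ties getting half credit."""
    pos = np.asarray(marker)[np.asarray(outcome) == 1]
    neg = np.asarray(marker)[np.asarray(outcome) == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_gene_call(
    segments: pd.DataFrame, chrom: str, g_start: int, g_end: int, sample: str
) -> tuple[str, float]:
    """Majority per-base overlap gene call (ties to larger |seg_mean|)."""
    segs = segments[(segments["sample_id"] == sample) & (segments["chrom"] == chrom)]
    best = ("missing", float("nan"), -1, -1.0)
    for _, row in segs.iterrows():
        bp = sum(
            1
            for pos in range(g_start, g_end)
            if int(row["start"]) <= pos < int(row["end"])
        )
        key = (bp, abs(float(row["seg_mean"])))
        if bp > 0 and key > (best[2], best[3]):
            best = (row["call"], float(row["seg_mean"]), bp, abs(float(row["seg_mean"])))
    return best[0], best[1]


def brute_single_changepoint(x: np.ndarray) -> tuple[int, float]:
    """Exhaustive single change-point maximizer of the two-sample t-like statistic."""
    n = len(x)
    best_k, best_stat = 0, -np.inf
    for k in range(1, n):
        m1, m2 = x[:k].mean(), x[k:].mean()
        stat = abs(m1 - m2) / np.sqrt(1.0 / k + 1.0 / (n - k))
        if stat > best_stat:
            best_k, best_stat = k, stat
    return best_k, best_stat


def brute_km(times: np.ndarray, events: np.ndarray) -> list[tuple[float, float]]:
    """Product-limit estimate by direct risk-set counting; (time, S) at event times."""
    order = np.argsort(times)
    t = np.asarray(times, float)[order]
    e = np.asarray(events, int)[order]
    s = 1.0
    out = []
    for ut in np.unique(t[e == 1]):
        at_risk = int((t >= ut).sum())
        d = int(((t == ut) & (e == 1)).sum())
        s *= 1 - d / at_risk
        out.append((float(ut), s))
    return out
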