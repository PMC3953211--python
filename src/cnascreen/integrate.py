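"""CNA-expression association via the signal-to-noise statistic.

For each gene the cohort is split into CNA carriers (gain or loss, tested
separately) and the remaining samples, and the signal-to-noise ratio

    SNR = (mean_CNA - mean_rest) / (sd_CNA + sd_rest)

is computed on log2 expression (sample SDs). Significance comes from a label
permutation test with the add-one convention; by default the test is
one-sided in the direction implied by the aberration (gain -> upregulation,
loss -> downregulation). A gene is selected when p < alpha, it carries the
aberration in at least ``min_samples`` patients, and the SNR sign matches the
direction. Benjamini-Hochberg FDR is reported across all tested gene/direction
pairs. The requirement of stable expression in non-carriers is enforced by the
SNR denominator itself: a noisy non-carrier group shrinks the statistic.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import rng_for
from .cna import GAIN, LOSS, MISSING, GeneCNATable

log = logging.getLogger(__name__)

ASSOCIATION_COLUMNS = ["gene_id", "direction", "n_cna", "snr", "p", "fdr", "selected"]


def snr_statistic(values_cna, values_non) -> float:
    """Signal-to-noise ratio (mean1 - mean2) / (sd1 + sd2), sample SDs.

    Returns a signed infinity when both groups are constant but differ in
    mean, and 0.0 when both are constant and equal.
    """
    a = np.asarray(values_cna, dtype=float)
    b = np.asarray(values_non, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values (sample SD undefined)")
    num = a.mean() - b.mean()
    denom = a.std(ddof=1) + b.std(ddof=1)
    if denom == 0:
        return 0.0 if num == 0 else math.copysign(math.inf, num)
    return float(num / denom)


def _snr_vectorized(g1: np.ndarray, n: int, total: float, total_sq: float) -> np.ndarray:
    """SNR for many permuted group-1 draws; group 2 stats from complements."""
    n1 = g1.shape[1]
    n2 = n - n1
    s1 = g1.sum(axis=1)
    ss1 = np.square(g1).sum(axis=1)
    m1 = s1 / n1
    m2 = (total - s1) / n2
    var1 = np.clip((ss1 - n1 * m1**2) / (n1 - 1), 0.0, None)
    var2 = np.clip((total_sq - ss1 - n2 * m2**2) / (n2 - 1), 0.0, None)
    denom = np.sqrt(var1) + np.sqrt(var2)
    num = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = num / denom
    zero = denom == 0
    if zero.any():
        snr[zero] = np.where(num[zero] == 0, 0.0, np.copysign(np.inf, num[zero]))
    return snr


def permutation_pvalue(
    expression,
    cna_flags,
    n_perm: int = 10_000,
    sided: str = "two",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    exact: bool = False,
) -> float:
    """Label-permutation p-value for the SNR statistic (add-one convention).

    ``sided``: ``"two"`` counts |permuted| >= |observed|, ``"greater"`` /
    ``"less"`` count one tail. ``exact=True`` enumerates all label subsets
    instead of sampling (small n only); the add-one convention is dropped
    there since the null is exhausted.
    """
    values = np.asarray(expression, dtype=float)
    flags = np.asarray(cna_flags, dtype=bool)
    if values.shape != flags.shape:
        raise ValueError("expression and cna_flags must align")
    n = values.size
    n1 = int(flags.sum())
    if n1 < 2 or n - n1 < 2:
        raise ValueError("both label classes need at least 2 members")
    observed = snr_statistic(values[flags], values[~flags])
    total = float(values.sum())
    total_sq = float(np.square(values).sum())

    if exact:
        perms = np.array(list(itertools.combinations(range(n), n1)))
        g1 = values[perms]
        snr = _snr_vectorized(g1, n, total, total_sq)
        return float(_tail_count(snr, observed, sided) / len(perms))

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    count = 0
    block = 20_000
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        order = np.argsort(rng.random((b, n)), axis=1)[:, :n1]
        snr = _snr_vectorized(values[order], n, total, total_sq)
        count += _tail_count(snr, observed, sided)
        done += b
    return (1 + count) / (1 + n_perm)


def _tail_count(snr: np.ndarray, observed: float, sided: str) -> int:
    tol = 1e-12 * max(1.0, abs(observed) if math.isfinite(observed) else 1.0)
    if sided == "two":
        return int(np.sum(np.abs(snr) >= abs(observed) - tol))
    if sided == "greater":
        return int(np.sum(snr >= observed - tol))
    if sided == "less":
        return int(np.sum(snr <= observed + tol))
    raise ValueError(f"unknown sidedness {sided!r}")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def associate(
    table: GeneCNATable,
    genes: pd.Index | None = None,
    alpha: float = 0.05,
    min_samples: int = 3,
    n_perm: int = 10_000,
    seed: int = 0,
    sided: str = "one",
) -> pd.DataFrame:
    """Test every (gene, direction) pair for CNA-coupled expression.

    ``genes`` restricts testing (callers pass the minimal-common-region,
    CNV-filtered candidate set). Each gene draws its own seed-derived RNG
    stream, so results do not depend on gene order. ``sided='one'`` tests
    gain -> upregulation / loss -> downregulation; ``'two'`` is symmetric.
    """
    if table.expression is None:
        raise ValueError("GeneCNATable has no expression joined")
    gene_ids = table.genes if genes is None else pd.Index(genes)
    rows = []
    for gid in gene_ids:
        if gid not in table.status.index or gid not in table.expression.index:
            log.info("gene %s absent from CNA or expression table: skipped", gid)
            continue
        status = table.status.loc[gid]
        expr = table.expression.loc[gid]
        usable = (status != MISSING) & expr.notna()
        if not usable.any():
            log.info("gene %s: CNA status missing for all samples, skipped", gid)
            continue
        status = status[usable]
        expr_v = expr[usable].to_numpy(dtype=float)
        for direction in (GAIN, LOSS):
            flags = (status == direction).to_numpy()
            n_cna = int(flags.sum())
            if n_cna < 2 or flags.size - n_cna < 2:
                continue
            snr = snr_statistic(expr_v[flags], expr_v[~flags])
            one_tail = "greater" if direction == GAIN else "less"
            p = permutation_pvalue(
                expr_v,
                flags,
                n_perm=n_perm,
                sided=one_tail if sided == "one" else "two",
                rng=rng_for(seed, "assoc", str(gid), direction),
            )
            sign_ok = snr > 0 if direction == GAIN else snr < 0
            rows.append(
                {
                    "gene_id": gid,
                    "direction": direction,
                    "n_cna": n_cna,
                    "snr": snr,
                    "p": p,
                    "fdr": np.nan,
                    "selected": bool(p < alpha and n_cna >= min_samples and sign_ok),
                }
            )
    result = pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)
    if len(result):
        result["fdr"] = bh_fdr(result["p"].to_numpy())
    return result


def expression_concordance(x, y) -> tuple[float, float]:
    """Pearson correlation between paired expression measurements.

    Used for platform concordance (e.g. microarray vs qRT-PCR); returns
    (r, two-sided t-distribution p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
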