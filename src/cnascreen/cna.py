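"""Copy-number calling from probe-level aCGH log2 ratios.

The stage mirrors standard array-CGH practice: probe profiles are normalized
against a smooth intensity/positional trend with robust LOWESS, denoised with
circular binary segmentation (CBS), and segments are called gained or lost
when their mean departs from the cohort median by more than ``k`` cohort noise
standard deviations (``k`` = 2 by default). Gene-level status is obtained by
assigning each gene the call of the segment with the largest base-pair
overlap.

Coordinates are 0-based half-open throughout this package; the SEG writer in
:mod:`cnascreen.io` converts to the 1-based inclusive IGV dialect.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from ._util import chrom_categorical, rng_for

log = logging.getLogger(__name__)

GAIN = "gain"
LOSS = "loss"
NEUTRAL = "neutral"
MISSING = "missing"

SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "n_probes", "seg_mean", "call"]


@dataclass
class ProbeProfile:
    """One sample's ordered probe log2 ratios with genomic coordinates.

    ``probes`` must have columns ``chrom, start, end, log2``. Probes with NaN
    log2 ratios are dropped at construction and counted in ``n_dropped``.
    """

    sample_id: str
    probes: pd.DataFrame
    normalized: bool = False
    n_dropped: int = 0

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "log2"}
        missing = required - set(self.probes.columns)
        if missing:
            raise ValueError(f"probe table missing columns: {sorted(missing)}")
        df = self.probes.copy()
        nan_mask = df["log2"].isna()
        if nan_mask.any():
            self.n_dropped += int(nan_mask.sum())
            log.info("sample %s: dropped %d NaN probes", self.sample_id, nan_mask.sum())
            df = df[~nan_mask]
        df = df.assign(chrom=chrom_categorical(df["chrom"]))
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self.probes = df

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def values(self) -> np.ndarray:
        return self.probes["log2"].to_numpy(dtype=float)


@dataclass
class NoiseModel:
    """Cohort-level background noise: median signal and noise SD.

    An aberration is significant when a segment mean lies more than
    ``k`` standard deviations from the cohort median.
    """

    cohort_median: float
    cohort_sd: float
    k: float = 2.0

    def __post_init__(self) -> None:
        if self.cohort_sd < 0:
            raise ValueError("cohort_sd must be >= 0")

    @property
    def gain_threshold(self) -> float:
        return self.cohort_median + self.k * self.cohort_sd

    @property
    def loss_threshold(self) -> float:
        return self.cohort_median - self.k * self.cohort_sd


@dataclass
class GeneCNATable:
    """Genes x samples CNA status/segment means, optionally joined to expression."""

    status: pd.DataFrame
    seg_mean: pd.DataFrame
    expression: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.status.index.equals(self.seg_mean.index) or not self.status.columns.equals(
            self.seg_mean.columns
        ):
            raise ValueError("status and seg_mean must share index/columns")
        if self.status.index.has_duplicates:
            raise ValueError("duplicated gene ids")
        if self.expression is not None:
            common = self.status.columns.intersection(self.expression.columns)
            if len(common) == 0:
                raise ValueError("no samples shared between CNA and expression")
            self.expression = self.expression.loc[:, common]
            self.status = self.status.loc[:, common]
            self.seg_mean = self.seg_mean.loc[:, common]

    @property
    def samples(self) -> pd.Index:
        return self.status.columns

    @property
    def genes(self) -> pd.Index:
        return self.status.index


# ---------------------------------------------------------------------------
# LOWESS normalization
# ---------------------------------------------------------------------------

def lowess_normalize(
    profile: ProbeProfile,
    covariate: np.ndarray | None = None,
    window_fraction: float = 0.30,
    iterations: int = 4,
) -> ProbeProfile:
    """Subtract a robust LOWESS trend fitted against ``covariate``.

    Defaults follow the four-iteration, 30%-window convention. ``covariate``
    defaults to probe index (positional trend); a constant covariate leaves
    the profile unchanged (with a warning) since there is nothing to fit.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    if profile.n_probes < 10:
        raise ValueError("need at least 10 probes to normalize")
    y = profile.values()
    cov = np.arange(y.size, dtype=float) if covariate is None else np.asarray(covariate, float)
    if cov.size != y.size:
        raise ValueError("covariate length must match probe count")
    if np.ptp(cov) == 0:
        warnings.warn("constant covariate: LOWESS normalization is the identity", stacklevel=2)
        fit = np.zeros_like(y)
    else:
        fit = _sm_lowess(y, cov, frac=window_fraction, it=iterations, return_sorted=False)
    out = profile.probes.copy()
    out["log2"] = y - fit
    return ProbeProfile(profile.sample_id, out, normalized=True, n_dropped=profile.n_dropped)


# ---------------------------------------------------------------------------
# Circular binary segmentation
# ---------------------------------------------------------------------------

class _ArcMax:
    """Max over circular arcs of the normalized mean-difference statistic.

    For a window of n probes, arcs are index pairs (i, j), 0 <= i < j <= n,
    contrasting the mean of x[i:j] against the mean of the complement:

        Z(i,j) = (mean_arc - mean_rest) / sqrt(1/w + 1/(n-w)),  w = j - i.

    Geometry (the valid-arc mask and weights) depends only on n and
    min_width, so it is precomputed once and reused across permutations.
    """

    def __init__(self, n: int, min_width: int):
        self.n = n
        idx = np.arange(n + 1)
        w = idx[None, :] - idx[:, None]
        valid = (w >= min_width) & (n - w >= min_width)
        with np.errstate(divide="ignore"):
            inv_w = np.where(valid, 1.0 / np.where(w == 0, 1, w), 0.0)
            inv_c = np.where(valid, 1.0 / np.where(n - w == 0, 1, n - w), 0.0)
        denom = np.sqrt(inv_w + inv_c)
        self.valid = valid
        self.inv_w = inv_w
        self.inv_c = inv_c
        self.inv_denom = np.where(valid, 1.0 / np.where(denom == 0, 1, denom), 0.0)

    def _z(self, x: np.ndarray) -> np.ndarray:
        s = np.empty(x.size + 1)
        s[0] = 0.0
        np.cumsum(x, out=s[1:])
        diff = s[None, :] - s[:, None]
        z = (diff * self.inv_w - (s[-1] - diff) * self.inv_c) * self.inv_denom
        return z

    def max_abs(self, x: np.ndarray) -> float:
        z = self._z(x)
        return float(np.max(np.abs(z)))

    def argmax(self, x: np.ndarray) -> tuple[float, int, int]:
        z = self._z(x)
        flat = int(np.argmax(np.abs(z)))
        i, j = divmod(flat, self.n + 1)
        return float(abs(z[i, j])), i, j


def _split_pvalue(
    x: np.ndarray,
    observed: float,
    arcmax: _ArcMax,
    n_perm: int,
    alpha: float,
    rng: np.random.Generator,
) -> float:
    """Permutation p for the max arc statistic, with early stopping.

    Stops as soon as the exceedance count guarantees the final add-one
    p-value would be >= alpha (the returned early-stopped value is then
    itself >= alpha, so the accept/reject decision is unaffected).
    """
    stop_at = max(1, math.ceil(alpha * (n_perm + 1) - 1 - 1e-12))
    exceed = 0
    xp = x.copy()
    tol = 1e-12 * max(1.0, observed)
    for b in range(1, n_perm + 1):
        rng.shuffle(xp)
        if arcmax.max_abs(xp) >= observed - tol:
            exceed += 1
            if exceed >= stop_at:
                return (1 + exceed) / (1 + b)
    return (1 + exceed) / (1 + n_perm)


def _segment_indices(
    x: np.ndarray, alpha: float, n_perm: int, min_width: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome; returns sorted (lo, hi) probe ranges."""
    segments: list[tuple[int, int]] = []
    stack = [(0, x.size)]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo
        if n < 2 * min_width:
            segments.append((lo, hi))
            continue
        arcmax = _ArcMax(n, min_width)
        stat, i, j = arcmax.argmax(x[lo:hi])
        if stat <= 0:
            segments.append((lo, hi))
            continue
        p = _split_pvalue(x[lo:hi], stat, arcmax, n_perm, alpha, rng)
        if p < alpha:
            cuts = sorted({i, j} - {0, n})
            bounds = [0, *cuts, n]
            for a, b in zip(bounds[:-1], bounds[1:]):
                stack.append((lo + a, lo + b))
        else:
            segments.append((lo, hi))
    return sorted(segments)


def cbs_segment(
    profile: ProbeProfile,
    alpha: float = 0.05,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Segment a normalized probe profile by circular binary segmentation.

    Splits are accepted when the permutation p of the max arc statistic is
    below ``alpha``; no undo/pruning step is applied. Returns one row per
    segment with ``call`` set to ``neutral`` (calling happens later against
    the cohort noise model). A chromosome with fewer than ``2 * min_width``
    probes is returned as a single segment.
    """
    if not profile.normalized:
        warnings.warn(
            f"sample {profile.sample_id}: segmenting a profile not marked normalized",
            stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for chrom, grp in profile.probes.groupby("chrom", observed=True, sort=False):
        x = grp["log2"].to_numpy(dtype=float)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for lo, hi in _segment_indices(x, alpha, n_perm, min_width, rng):
            rows.append(
                {
                    "sample_id": profile.sample_id,
                    "chrom": chrom,
                    "start": int(starts[lo]),
                    "end": int(ends[hi - 1]),
                    "n_probes": hi - lo,
                    "seg_mean": float(x[lo:hi].mean()),
                    "call": NEUTRAL,
                }
            )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def segment_cohort(
    profiles: list[ProbeProfile],
    alpha: float = 0.05,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Segment every profile; each sample gets its own seed-derived stream."""
    parts = [
        cbs_segment(p, alpha=alpha, n_perm=n_perm, min_width=min_width,
                    rng=rng_for(seed, "cbs", p.sample_id))
        for p in profiles
    ]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=SEGMENT_COLUMNS)


# ---------------------------------------------------------------------------
# Noise estimation and calling
# ---------------------------------------------------------------------------

def probe_residuals(profiles: list[ProbeProfile], segments: pd.DataFrame) -> np.ndarray:
    """Per-probe residuals (probe log2 minus containing segment mean), pooled."""
    pooled = []
    seg_by = {k: g for k, g in segments.groupby(["sample_id", "chrom"], observed=True)}
    for prof in profiles:
        for chrom, grp in prof.probes.groupby("chrom", observed=True, sort=False):
            segs = seg_by.get((prof.sample_id, chrom))
            if segs is None:
                continue
            segs = segs.sort_values("start")
            if int(segs["n_probes"].sum()) != len(grp):
                raise ValueError(
                    f"segments do not partition probes for {prof.sample_id}/{chrom}"
                )
            fitted = np.repeat(segs["seg_mean"].to_numpy(), segs["n_probes"].to_numpy())
            pooled.append(grp["log2"].to_numpy(dtype=float) - fitted)
    if not pooled:
        raise ValueError("no residuals: segments match no profile")
    return np.concatenate(pooled)


def estimate_noise(
    profiles: list[ProbeProfile],
    segments: pd.DataFrame | None = None,
    k: float = 2.0,
) -> NoiseModel:
    """Cohort noise model from pooled probe signal of all arrays.

    The median is taken over the pooled raw probe log2 ratios. When a
    segmentation is supplied the SD is computed from pooled per-probe
    residuals (probe minus its segment mean), which isolates measurement
    noise from true aberrations; otherwise the SD of the raw pool is used.
    Sample SD (ddof=1) throughout.
    """
    if not profiles:
        raise ValueError("no profiles: cannot estimate noise")
    pool = np.concatenate([p.values() for p in profiles])
    if pool.size == 0:
        raise ValueError("empty probe pool")
    median = float(np.median(pool))
    if segments is not None:
        resid = probe_residuals(profiles, segments)
        sd = float(resid.std(ddof=1)) if resid.size > 1 else 0.0
    else:
        sd = float(pool.std(ddof=1)) if pool.size > 1 else 0.0
    return NoiseModel(cohort_median=median, cohort_sd=sd, k=k)


def call_aberrations(segments: pd.DataFrame, noise: NoiseModel) -> pd.DataFrame:
    """Label each segment gain/loss/neutral against the cohort noise model."""
    if noise.cohort_sd == 0:
        warnings.warn(
            "cohort SD is 0: any deviation from the median is called aberrant",
            stacklevel=2,
        )
    out = segments.copy()
    mean = out["seg_mean"].to_numpy(dtype=float)
    call = np.full(len(out), NEUTRAL, dtype=object)
    call[mean > noise.gain_threshold] = GAIN
    call[mean < noise.loss_threshold] = LOSS
    out["call"] = call
    return out


# ---------------------------------------------------------------------------
# Gene-level mapping
# ---------------------------------------------------------------------------

def map_genes_to_calls(
    segments: pd.DataFrame,
    annotation: pd.DataFrame,
    expression: pd.DataFrame | None = None,
) -> GeneCNATable:
    """Assign each gene, per sample, the call of its majority-overlap segment.

    The segment sharing the largest base-pair overlap with the gene body wins;
    ties are broken toward the segment with larger ``|seg_mean|`` (conservative
    toward detecting aberration). Genes overlapping no segment are ``missing``.
    """
    genes = annotation.set_index("gene_id") if "gene_id" in annotation.columns else annotation
    samples = pd.Index(pd.unique(segments["sample_id"]))
    status = pd.DataFrame(MISSING, index=genes.index, columns=samples, dtype=object)
    segmean = pd.DataFrame(np.nan, index=genes.index, columns=samples, dtype=float)
    n_unmapped = 0
    for (sid, chrom), segs in segments.groupby(["sample_id", "chrom"], observed=True):
        sub = genes[genes["chrom"] == chrom]
        if sub.empty:
            continue
        s0 = segs["start"].to_numpy()
        s1 = segs["end"].to_numpy()
        means = segs["seg_mean"].to_numpy(dtype=float)
        calls = segs["call"].to_numpy()
        for gid, g0, g1 in zip(sub.index, sub["start"].to_numpy(), sub["end"].to_numpy()):
            ov = np.minimum(s1, g1) - np.maximum(s0, g0)
            np.clip(ov, 0, None, out=ov)
            best_ov = ov.max() if ov.size else 0
            if best_ov <= 0:
                n_unmapped += 1
                continue
            cand = np.flatnonzero(ov == best_ov)
            best = cand[np.argmax(np.abs(means[cand]))]
            status.at[gid, sid] = calls[best]
            segmean.at[gid, sid] = means[best]
    absent = genes[~genes["chrom"].isin(segments["chrom"].unique())]
    if len(absent):
        log.info("%d genes on chromosomes absent from profiles -> missing", len(absent))
    if n_unmapped:
        log.info("%d gene/sample pairs overlapped no segment -> missing", n_unmapped)
    return GeneCNATable(status=status, seg_mean=segmean, expression=expression)
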