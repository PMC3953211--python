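"""Recurrent minimal common CNA regions, germline-CNV filtering, subgroup tests.

A minimal common region is a maximal genomic run where at least
``ceil(min_freq * n_samples)`` samples carry an aberration of the same
direction; gains and losses are swept independently. Candidate genes are
filtered against a germline CNV catalogue (genes overlapped by more than
``max_cnv`` records are excluded) and by recurrence (aberrant in at least
``min_samples`` patients). Region frequencies between molecular subgroups are
compared with the two-sided Fisher exact test (chi-square optional).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .cna import GAIN, GeneCNATable

REGION_COLUMNS = ["chrom", "start", "end", "direction", "n_carriers", "frequency", "carriers"]


@dataclass(frozen=True)
class CNARegion:
    chrom: str
    start: int
    end: int
    direction: str
    carriers: tuple[str, ...]
    frequency: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("region start must be < end")

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


def regions_to_frame(regions: list[CNARegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "direction": r.direction,
                "n_carriers": r.n_carriers,
                "frequency": r.frequency,
                "carriers": ",".join(r.carriers),
            }
            for r in regions
        ],
        columns=REGION_COLUMNS,
    )


def minimal_common_regions(
    segments: pd.DataFrame,
    min_freq: float = 0.10,
    direction: str = GAIN,
    n_samples: int | None = None,
) -> list[CNARegion]:
    """Sweep-line detection of maximal runs with carrier count >= threshold.

    ``n_samples`` is the cohort size the frequency refers to (e.g. the
    dual-platform subset); defaults to the number of distinct samples in
    ``segments``. The carrier threshold is ``ceil(min_freq * n_samples)``.
    Carriers of a region are all samples aberrant anywhere within it.
    """
    if not 0 < min_freq <= 1:
        raise ValueError("min_freq must be in (0, 1]")
    if n_samples is None:
        n_samples = int(segments["sample_id"].nunique())
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    thresh = math.ceil(min_freq * n_samples - 1e-9)
    calls = segments[segments["call"] == direction]
    regions: list[CNARegion] = []
    for chrom, grp in calls.groupby("chrom", observed=True, sort=False):
        # merge per-sample intervals first so each sample counts once per position
        merged = _merge_per_sample(grp)
        starts = merged["start"].to_numpy()
        ends = merged["end"].to_numpy()
        pos = np.unique(np.concatenate([starts, ends]))
        delta = np.zeros(pos.size, dtype=int)
        np.add.at(delta, np.searchsorted(pos, starts), 1)
        np.add.at(delta, np.searchsorted(pos, ends), -1)
        count = np.cumsum(delta)  # coverage on [pos[i], pos[i+1])
        run_start = None
        for i in range(pos.size - 1):
            if count[i] >= thresh and run_start is None:
                run_start = int(pos[i])
            if count[i] < thresh and run_start is not None:
                regions.append(_make_region(merged, chrom, run_start, int(pos[i]), direction, n_samples))
                run_start = None
        if run_start is not None:
            regions.append(_make_region(merged, chrom, run_start, int(pos[-1]), direction, n_samples))
    return regions


def _merge_per_sample(grp: pd.DataFrame) -> pd.DataFrame:
    """Union of each sample's intervals on one chromosome."""
    rows = []
    for sid, g in grp.groupby("sample_id", observed=True):
        ivs = sorted(zip(g["start"].astype(int), g["end"].astype(int)))
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append({"sample_id": sid, "start": cur_s, "end": cur_e})
                cur_s, cur_e = s, e
        rows.append({"sample_id": sid, "start": cur_s, "end": cur_e})
    return pd.DataFrame(rows, columns=["sample_id", "start", "end"])


def _make_region(
    grp: pd.DataFrame, chrom, start: int, end: int, direction: str, n_samples: int
) -> CNARegion:
    ov = (grp["start"].to_numpy() < end) & (grp["end"].to_numpy() > start)
    carriers = tuple(sorted(pd.unique(grp.loc[ov, "sample_id"])))
    return CNARegion(
        chrom=str(chrom),
        start=start,
        end=end,
        direction=direction,
        carriers=carriers,
        frequency=len(carriers) / n_samples,
    )


def cnv_filter(
    annotation: pd.DataFrame, catalogue: pd.DataFrame, max_cnv: int = 10
) -> tuple[pd.Index, pd.Series]:
    """Retain genes overlapped by at most ``max_cnv`` catalogue records.

    Any >= 1 bp overlap counts; raw records are counted without merging.
    Returns (retained gene index, per-gene overlap counts) so the exclusion
    can be audited. An empty catalogue retains everything.
    """
    genes = annotation.set_index("gene_id") if "gene_id" in annotation.columns else annotation
    counts = pd.Series(0, index=genes.index, dtype=int)
    if len(catalogue):
        trees: dict[str, IntervalTree] = {}
        for chrom, grp in catalogue.groupby("chrom", observed=True):
            # tag records with their row index: duplicates are distinct CNVs
            ivs = [(int(s), int(e), i)
                   for i, (s, e) in enumerate(zip(grp["start"], grp["end"])) if s < e]
            trees[str(chrom)] = IntervalTree.from_tuples(ivs)
        for gid, row in genes.iterrows():
            tree = trees.get(str(row["chrom"]))
            if tree is not None:
                counts.at[gid] = len(tree.overlap(int(row["start"]), int(row["end"])))
    retained = counts.index[counts <= max_cnv]
    return retained, counts


def recurrence_filter(
    table: GeneCNATable | pd.DataFrame, min_samples: int, direction: str = GAIN
) -> pd.Index:
    """Genes aberrant in `direction` in at least ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    status = table.status if isinstance(table, GeneCNATable) else table
    n = (status == direction).sum(axis=1)
    return status.index[n >= min_samples]


def subgroup_frequency_test(
    carriers, labels, test: str = "fisher"
) -> tuple[np.ndarray, float]:
    """Compare carrier frequency between two subgroups (e.g. GCB vs non-GCB).

    Returns the 2x2 table (rows = groups, columns = carrier yes/no) and the
    two-sided Fisher exact p (or chi-square p with ``test='chi2'``).
    """
    carriers = np.asarray(carriers, dtype=bool)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    table = np.array(
        [
            [int((carriers & (labels == g)).sum()), int((~carriers & (labels == g)).sum())]
            for g in groups
        ]
    )
    if (table.sum(axis=1) == 0).any():
        raise ValueError("a subgroup is empty")
    if test == "fisher":
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    elif test == "chi2":
        p = float(stats.chi2_contingency(table, correction=False)[1])
    else:
        raise ValueError(f"unknown test {test!r}")
    return table, p
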