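"""End-to-end screen: segment -> regions -> associate -> survival -> report.

``run_screen`` reproduces the structure of the integrative biomarker screen:
probe profiles are LOWESS-normalized and CBS-segmented, aberrations are
called against the cohort noise model, minimal common regions (>= ``min_freq``
of the cohort) are detected separately for gains and losses, genes inside
them are CNV-filtered and recurrence-filtered, expression is associated with
CNA status by the SNR permutation test, and survival is examined on two
tracks: per region (carriers vs rest, Kaplan-Meier + log-rank, for regions
with at least ``min_surv`` carriers) and per selected gene (expression as a
continuous Cox covariate, then ROC/Youden-dichotomized Kaplan-Meier). A gene
becomes a reported biomarker when it carries region, association and survival
evidence.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from . import io as _io
from ._util import rng_for
from .cna import (
    GAIN,
    LOSS,
    GeneCNATable,
    call_aberrations,
    estimate_noise,
    lowess_normalize,
    map_genes_to_calls,
    segment_cohort,
)
from .integrate import associate
from .regions import cnv_filter, minimal_common_regions, regions_to_frame
from .survstats import cox_fit, derive_endpoints, km_estimate, logrank_test, roc_cutoff

log = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Thresholds and sizes of the screen (defaults follow the study design)."""

    alpha: float = 0.05          # significance for CBS splits, association, survival
    min_freq: float = 0.10       # minimal-common-region recurrence threshold
    max_cnv: int = 10            # exclude genes with more catalogue CNVs than this
    min_cna: int = 3             # min aberrant patients for association
    min_surv: int = 5            # min aberrant samples for survival testing
    k: float = 2.0               # SD multiplier for aberration calling
    n_perm: int = 1000           # association permutations
    cbs_n_perm: int = 200        # CBS split permutations
    lowess_window: float = 0.30
    lowess_iterations: int = 4
    endpoint: str = "pfs"        # pfs | os | lyos
    cox_ties: str = "breslow"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "min_freq", "max_cnv", "min_cna", "min_surv", "k",
                     "n_perm", "cbs_n_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.endpoint not in ("pfs", "os", "lyos"):
            raise ValueError("endpoint must be pfs, os or lyos")


@dataclass
class ScreenReport:
    """Every stage's output plus the traceable biomarker shortlist."""

    segments: pd.DataFrame
    noise: dict
    regions: pd.DataFrame
    association: pd.DataFrame
    region_survival: pd.DataFrame
    gene_survival: pd.DataFrame
    biomarkers: pd.DataFrame
    filter_audit: dict
    provenance: dict


def classify_subtype_gep(
    expression: pd.DataFrame,
    panel_genes: list[str],
    signature: dict[str, int] | None = None,
) -> pd.Series:
    """GCB / non-GCB labels by complete-linkage clustering of a gene panel.

    The expression matrix (genes x samples) is restricted to ``panel_genes``
    (missing panel genes dropped with a warning, as happens when a panel gene
    is absent from the array), samples are clustered on Euclidean distance
    with complete linkage and the tree is cut into two branches. When a
    ``signature`` of per-gene directions (+1 = up in GCB) is supplied, the
    branch with the higher mean signed panel expression is labelled GCB;
    otherwise neutral labels cluster1/cluster2 are returned.
    """
    present = [g for g in panel_genes if g in expression.index]
    missing = set(panel_genes) - set(present)
    if missing:
        warnings.warn(f"{len(missing)} panel genes absent from matrix, dropped",
                      stacklevel=2)
    if not present:
        raise ValueError("no panel genes present in the expression matrix")
    mat = expression.loc[present].T  # samples x genes
    if len(mat) < 4:
        raise ValueError("need at least 4 samples to classify")
    if len(np.unique(mat.to_numpy().round(12), axis=0)) < 2:
        raise ValueError("fewer than 2 distinct expression profiles")
    z = linkage(mat.to_numpy(), method="complete", metric="euclidean")
    cl = fcluster(z, t=2, criterion="maxclust")
    labels = pd.Series(cl, index=mat.index)
    if signature is None:
        return labels.map({1: "cluster1", 2: "cluster2"})
    signs = pd.Series({g: signature.get(g, 0) for g in present})
    score = mat.mul(signs, axis=1).mean(axis=1)
    gcb_cluster = 1 if score[labels == 1].mean() >= score[labels == 2].mean() else 2
    return labels.map(lambda c: "GCB" if c == gcb_cluster else "nonGCB")


def run_screen(cohort, config: PipelineConfig | None = None) -> ScreenReport:
    """Execute the full screen on an in-memory cohort.

    ``cohort`` needs ``probe_profiles()``, ``expression``, ``annotation``,
    ``cnv_catalogue`` and ``clinical`` (a :class:`~cnascreen.synthcohort.Cohort`
    or an equivalent loaded from files).
    """
    cfg = config or PipelineConfig()

    # --- copy number --------------------------------------------------------
    profiles = [
        lowess_normalize(p, window_fraction=cfg.lowess_window,
                         iterations=cfg.lowess_iterations)
        for p in cohort.probe_profiles()
    ]
    segments = segment_cohort(profiles, alpha=cfg.alpha, n_perm=cfg.cbs_n_perm,
                              seed=cfg.seed)
    noise = estimate_noise(profiles, segments, k=cfg.k)
    segments = call_aberrations(segments, noise)
    table = map_genes_to_calls(segments, cohort.annotation, cohort.expression)

    # --- recurrent regions and candidate genes ------------------------------
    n_samples = len(cohort.expression.columns)
    all_regions = []
    for direction in (GAIN, LOSS):
        all_regions.extend(
            minimal_common_regions(segments, min_freq=cfg.min_freq,
                                   direction=direction, n_samples=n_samples)
        )
    regions_df = regions_to_frame(all_regions)

    ann = cohort.annotation.set_index("gene_id")
    in_region = set()
    for r in all_regions:
        hit = ann[(ann["chrom"] == r.chrom) & (ann["start"] < r.end) & (ann["end"] > r.start)]
        in_region.update(hit.index)
    retained, cnv_counts = cnv_filter(cohort.annotation, cohort.cnv_catalogue,
                                      max_cnv=cfg.max_cnv)
    candidates = pd.Index(sorted(in_region)).intersection(retained)
    audit = {
        "n_genes": int(len(ann)),
        "n_in_region": int(len(in_region)),
        "n_cnv_excluded": int(len(in_region) - len(candidates)),
        "n_candidates": int(len(candidates)),
    }

    # --- association --------------------------------------------------------
    assoc = associate(table, genes=candidates, alpha=cfg.alpha,
                      min_samples=cfg.min_cna, n_perm=cfg.n_perm, seed=cfg.seed)

    # --- survival -----------------------------------------------------------
    endpoints = derive_endpoints(cohort.clinical).set_index("sample_id")
    ep_time = endpoints[f"{cfg.endpoint}_time"]
    ep_event = endpoints[f"{cfg.endpoint}_event"]
    samples = [s for s in cohort.expression.columns if s in endpoints.index]

    region_rows = []
    for r in all_regions:
        carriers = [s for s in r.carriers if s in endpoints.index]
        if len(carriers) < cfg.min_surv:
            continue
        rest = [s for s in samples if s not in set(carriers)]
        if not rest or ep_event.loc[samples].sum() == 0:
            continue
        chi2, p = logrank_test(
            ep_time.loc[carriers], ep_event.loc[carriers],
            ep_time.loc[rest], ep_event.loc[rest],
        )
        km_c = km_estimate(ep_time.loc[carriers], ep_event.loc[carriers])
        km_r = km_estimate(ep_time.loc[rest], ep_event.loc[rest])
        region_rows.append(
            {
                "chrom": r.chrom, "start": r.start, "end": r.end,
                "direction": r.direction, "n_carriers": len(carriers),
                "logrank_chi2": chi2, "logrank_p": p,
                "surv5y_carriers": km_c.survival_at(60.0),
                "surv5y_rest": km_r.survival_at(60.0),
            }
        )
    region_surv = pd.DataFrame(region_rows)

    gene_rows = []
    selected = assoc[assoc["selected"]]
    for _, arow in selected.iterrows():
        gid = arow["gene_id"]
        expr = cohort.expression.loc[gid, samples].astype(float)
        ev = ep_event.loc[samples].to_numpy()
        tm = ep_time.loc[samples].to_numpy()
        if expr.nunique() < 2 or ev.sum() == 0:
            continue
        cox = cox_fit(expr.to_numpy(), tm, ev, ties=cfg.cox_ties, names=[gid])
        row = {
            "gene_id": gid, "direction": arow["direction"],
            "cox_log_hr": float(cox["coef"].iloc[0]),
            "cox_se": float(cox["se"].iloc[0]),
            "cox_p": float(cox["p"].iloc[0]),
        }
        try:
            cut = roc_cutoff(expr.to_numpy(), ev, name=gid)
            hi = expr > cut.cutoff
            if 0 < hi.sum() < len(expr):
                chi2, p = logrank_test(tm[hi.to_numpy()], ev[hi.to_numpy()],
                                       tm[~hi.to_numpy()], ev[~hi.to_numpy()])
                km_hi = km_estimate(tm[hi.to_numpy()], ev[hi.to_numpy()])
                km_lo = km_estimate(tm[~hi.to_numpy()], ev[~hi.to_numpy()])
                row.update(
                    cutoff=cut.cutoff, auc=cut.auc, logrank_p=p,
                    surv5y_high=km_hi.survival_at(60.0),
                    surv5y_low=km_lo.survival_at(60.0),
                )
        except ValueError:
            pass
        gene_rows.append(row)
    gene_surv = pd.DataFrame(gene_rows)

    # --- biomarker shortlist -------------------------------------------------
    bio_rows = []
    if len(gene_surv):
        for _, row in gene_surv.iterrows():
            if row["cox_p"] >= cfg.alpha:
                continue
            gid = row["gene_id"]
            host = next(
                (r for r in all_regions
                 if r.direction == row["direction"]
                 and r.chrom == ann.at[gid, "chrom"]
                 and r.start < ann.at[gid, "end"] and ann.at[gid, "start"] < r.end),
                None,
            )
            arow = selected[(selected["gene_id"] == gid)
                            & (selected["direction"] == row["direction"])].iloc[0]
            bio_rows.append(
                {
                    "gene_id": gid, "direction": row["direction"],
                    "region": f"{host.chrom}:{host.start}-{host.end}" if host else "",
                    "region_frequency": host.frequency if host else np.nan,
                    "n_cna": int(arow["n_cna"]), "snr": float(arow["snr"]),
                    "assoc_p": float(arow["p"]), "assoc_fdr": float(arow["fdr"]),
                    "cox_log_hr": float(row["cox_log_hr"]),
                    "cox_p": float(row["cox_p"]),
                    "logrank_p": float(row.get("logrank_p", np.nan)),
                }
            )
    biomarkers = pd.DataFrame(bio_rows).sort_values("gene_id").reset_index(drop=True) \
        if bio_rows else pd.DataFrame(
            columns=["gene_id", "direction", "region", "region_frequency", "n_cna",
                     "snr", "assoc_p", "assoc_fdr", "cox_log_hr", "cox_p", "logrank_p"])

    cfg_dict = asdict(cfg)
    provenance = {
        "config": cfg_dict,
        "seed": cfg.seed,
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_samples": n_samples,
    }
    return ScreenReport(
        segments=segments,
        noise={"cohort_median": noise.cohort_median, "cohort_sd": noise.cohort_sd,
               "k": noise.k},
        regions=regions_df,
        association=assoc,
        region_survival=region_surv,
        gene_survival=gene_surv,
        biomarkers=biomarkers,
        filter_audit=audit,
        provenance=provenance,
    )


def write_report(report: ScreenReport, outdir) -> None:
    """Persist every stage table plus a JSON summary (recomputable, no hidden state)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_seg(report.segments, outdir / "calls.seg")
    _io.write_regions_tsv(report.regions, outdir / "regions.tsv")
    report.association.to_csv(outdir / "association.tsv", sep="\t", index=False,
                              float_format="%.6g")
    report.region_survival.to_csv(outdir / "region_survival.tsv", sep="\t",
                                  index=False, float_format="%.6g")
    report.gene_survival.to_csv(outdir / "gene_survival.tsv", sep="\t",
                                index=False, float_format="%.6g")
    report.biomarkers.to_csv(outdir / "biomarkers.tsv", sep="\t", index=False,
                             float_format="%.6g")
    summary = {
        "noise": report.noise,
        "filter_audit": report.filter_audit,
        "n_regions": int(len(report.regions)),
        "n_selected_genes": int(report.association["selected"].sum())
        if len(report.association) else 0,
        "biomarkers": report.biomarkers["gene_id"].tolist(),
        "provenance": report.provenance,
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
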