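"""Readers/writers for the plain-text formats the screen consumes and emits.

Tab-delimited matrices for probes/expression/clinical, BED (0-based
half-open) for gene annotation and the CNV catalogue, SEG (1-based inclusive,
IGV dialect) for segment calls, JSON for palettes and truth, PNG for IHC
fields. Internal coordinates are 0-based half-open everywhere; only the SEG
round-trip converts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .cna import SEGMENT_COLUMNS

SEG_HEADER = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Seg.Mean", "Call"]


def write_probe_tsv(probes: pd.DataFrame, path) -> None:
    probes.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_probe_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_tsv(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_bed(intervals: pd.DataFrame, path, name_col: str | None = None) -> None:
    cols = ["chrom", "start", "end"]
    df = intervals[cols].copy()
    if name_col and name_col in intervals:
        df["name"] = intervals[name_col]
    df.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path, named: bool = False) -> pd.DataFrame:
    names = ["chrom", "start", "end"] + (["gene_id"] if named else [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = names
    return df


def write_clinical_tsv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_clinical_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=True)


def write_seg(segments: pd.DataFrame, path) -> None:
    """SEG output, 1-based inclusive coordinates (IGV dialect)."""
    out = pd.DataFrame(
        {
            "Sample": segments["sample_id"],
            "Chromosome": segments["chrom"],
            "Start": segments["start"].astype(int) + 1,
            "End": segments["end"].astype(int),
            "Num_Probes": segments["n_probes"].astype(int),
            "Seg.Mean": segments["seg_mean"],
            "Call": segments["call"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    out = pd.DataFrame(
        {
            "sample_id": df["Sample"],
            "chrom": df["Chromosome"],
            "start": df["Start"].astype(int) - 1,
            "end": df["End"].astype(int),
            "n_probes": df["Num_Probes"].astype(int),
            "seg_mean": df["Seg.Mean"].astype(float),
            "call": df.get("Call", "neutral"),
        }
    )
    return out[SEGMENT_COLUMNS]


def write_regions_tsv(regions_frame: pd.DataFrame, path) -> None:
    regions_frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_regions_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_palette_json(palettes: dict[str, np.ndarray], path) -> None:
    obj = {k: np.asarray(v).astype(int).tolist() for k, v in palettes.items()}
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_palette_json(path) -> dict[str, np.ndarray]:
    obj = json.loads(Path(path).read_text())
    return {k: np.asarray(v, dtype=np.int64) for k, v in obj.items()}


def write_png(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def read_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_truth_json(truth, path) -> None:
    obj = {
        "breakpoints": truth.breakpoints,
        "carrier_map": {s: [bool(v) for v in row]
                        for s, row in truth.carrier_map.iterrows()},
        "driver_ids": truth.driver_ids,
        "true_log_hr": truth.true_log_hr,
        "subtype": truth.subtype.to_dict(),
        "cnv_hot_genes": truth.cnv_hot_genes,
        "true_coverages": truth.true_coverages,
    }
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def write_cohort(cohort, outdir) -> dict[str, str]:
    """Write every cohort table to ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "probes": outdir / "probes.tsv",
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "annotation": outdir / "genes.bed",
        "cnv_catalogue": outdir / "cnv_catalogue.bed",
        "truth": outdir / "truth.json",
    }
    write_probe_tsv(cohort.probes, paths["probes"])
    write_expression_tsv(cohort.expression, paths["expression"])
    write_clinical_tsv(cohort.clinical, paths["clinical"])
    ann = cohort.annotation[["chrom", "start", "end", "gene_id"]]
    ann.to_csv(paths["annotation"], sep="\t", index=False, header=False)
    write_bed(cohort.cnv_catalogue, paths["cnv_catalogue"])
    write_truth_json(cohort.truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
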