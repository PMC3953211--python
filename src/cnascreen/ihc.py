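"""Quantitative IHC staining coverage by nearest-exemplar colour classification.

Brightfield DAB/hematoxylin fields are scored by assigning every pixel to one
of four colour classes — brown (specific staining), blue (counterstained
nuclei), white (unstained tissue) and background (faint, unspecific colour) —
by nearest exemplar colour in RGB space, each class being described by up to
15 example colours. Staining coverage is the brown-pixel fraction, reported
under both denominator conventions (all pixels, or tissue = brown+blue+white).
Per-patient scores average 1-3 high-power fields; patients are dichotomized
at a ROC/Youden cutoff or at a fixed externally supplied one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survstats import CutoffResult, roc_cutoff

CLASS_ORDER = ("brown", "blue", "white", "background")


@dataclass
class ColourClassSpec:
    """Exemplar colours per class; classification ties break in CLASS_ORDER."""

    palettes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        cleaned = {}
        for name in CLASS_ORDER:
            if name not in self.palettes:
                raise ValueError(f"missing colour class {name!r}")
            arr = np.asarray(self.palettes[name])
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
                raise ValueError(f"class {name!r}: exemplars must be a (k, 3) array")
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError(f"class {name!r}: exemplars must be 8-bit RGB")
            cleaned[name] = arr.astype(np.int64)
        self.palettes = cleaned

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """(exemplars stacked in class order, class index per exemplar)."""
        ex = np.concatenate([self.palettes[c] for c in CLASS_ORDER])
        labels = np.concatenate(
            [np.full(len(self.palettes[c]), i) for i, c in enumerate(CLASS_ORDER)]
        )
        return ex, labels


@dataclass
class CoverageResult:
    image_id: str
    counts: dict[str, int]
    coverage: float
    coverage_all: float
    coverage_tissue: float
    denominator: str
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.coverage <= 1:
            raise ValueError("coverage must be in [0, 1]")


def classify_pixels(image: np.ndarray, spec: ColourClassSpec) -> np.ndarray:
    """Label each pixel with the class of its nearest exemplar (RGB Euclid).

    Distances are computed in exact integer arithmetic so ties are broken
    deterministically by class order brown -> blue -> white -> background.
    Returns an (H, W) array of class indices into CLASS_ORDER.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("image must be an (H, W, 3) RGB raster")
    if img.size == 0:
        raise ValueError("empty image")
    ex, labels = spec.stacked()
    flat = img[..., :3].reshape(-1, 3).astype(np.int64)
    out = np.empty(flat.shape[0], dtype=np.int64)
    chunk = 200_000
    for lo in range(0, flat.shape[0], chunk):
        block = flat[lo : lo + chunk]
        d2 = ((block[:, None, :] - ex[None, :, :]) ** 2).sum(axis=2)
        out[lo : lo + chunk] = labels[np.argmin(d2, axis=1)]
    return out.reshape(img.shape[:2])


def staining_coverage(
    class_map: np.ndarray,
    denominator: str = "all",
    image_id: str = "",
    patient_id: str | None = None,
) -> CoverageResult:
    """Brown-pixel fraction of an image under the chosen denominator.

    ``denominator='all'`` divides by every pixel; ``'tissue'`` divides by
    brown+blue+white (excluding the unspecific background class). Both
    conventions are carried in the result.
    """
    if denominator not in ("all", "tissue"):
        raise ValueError("denominator must be 'all' or 'tissue'")
    cm = np.asarray(class_map)
    counts = {c: int((cm == i).sum()) for i, c in enumerate(CLASS_ORDER)}
    total = cm.size
    tissue = counts["brown"] + counts["blue"] + counts["white"]
    cov_all = counts["brown"] / total if total else 0.0
    cov_tissue = counts["brown"] / tissue if tissue else 0.0
    return CoverageResult(
        image_id=image_id,
        counts=counts,
        coverage=cov_all if denominator == "all" else cov_tissue,
        coverage_all=cov_all,
        coverage_tissue=cov_tissue,
        denominator=denominator,
        patient_id=patient_id,
    )


def aggregate_patient(fields: list[CoverageResult | float]) -> float:
    """Patient score = arithmetic mean of field coverages (1-3 fields typical)."""
    if not fields:
        raise ValueError("no fields for patient")
    if len(fields) > 3:
        warnings.warn(f"{len(fields)} fields for one patient (1-3 expected)", stacklevel=2)
    vals = [f.coverage if isinstance(f, CoverageResult) else float(f) for f in fields]
    return float(np.mean(vals))


def dichotomize(
    coverages: pd.Series,
    events: pd.Series | None = None,
    cutoff: float | None = None,
    name: str = "staining_coverage",
) -> tuple[pd.Series, CutoffResult | None]:
    """High/low labels from patient coverages.

    With ``cutoff=None`` the cutoff is chosen by ROC/Youden against
    ``events`` (both classes required); a fixed external cutoff (e.g. 0.089,
    carried over from a training cohort) can be supplied instead. ``high``
    means coverage strictly above the cutoff.
    """
    cov = pd.Series(coverages, dtype=float)
    result = None
    if cutoff is None:
        if events is None:
            raise ValueError("events required when no fixed cutoff is given")
        if cov.nunique() < 2:
            raise ValueError("all coverages equal: no discriminative cutoff exists")
        ev = pd.Series(events).loc[cov.index]
        result = roc_cutoff(cov.to_numpy(), ev.to_numpy(), name=name)
        cutoff = result.cutoff
    labels = pd.Series(np.where(cov > cutoff, "high", "low"), index=cov.index, name=name)
    return labels, result
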