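"""Synthetic lymphoma cohorts with known ground truth.

Emulates the data structures of an integrative DLBCL copy-number screen so
every downstream stage is testable without patient data:

* probe-level aCGH log2 ratios = planted segment shifts (carriers only)
  + a smooth intensity-dependent bias (sinusoid over probe index, which the
  LOWESS stage must remove) + Gaussian probe noise;
* gene-level log2 expression coupled to CNA status for designated driver
  genes (carriers shifted by ``delta``) and fully decoupled for passengers;
* proportional-hazards survival: progression time is exponential with
  log hazard = log(baseline_hazard) + sum of driver log-HRs x driver
  expression, followed by post-progression lymphoma death, an independent
  other-cause death process, independent exponential censoring and
  administrative censoring from staggered accrual;
* a germline CNV catalogue with designated CNV-rich genes (so the >10-CNV
  exclusion rule has something to exclude);
* brightfield IHC field images composed of brown/blue/white/background
  colour populations at known coverage.

Defaults mirror the screening-cohort conditions: ~50 samples, recurrent
aberrations carried by ~20-24% of patients at amplification-level shifts
(+/-0.8 log2), probe noise SD 0.15, driver expression effect 1.0 log2 unit
over SD 0.5, driver log hazard ratio 1.0 per log2-expression unit, accrual
over 36 months with a 96-month horizon. Fixing ``seed`` fixes every output
byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cna import ProbeProfile
from .ihc import CLASS_ORDER

DATE0 = np.datetime64("2004-01-01")
DAYS_PER_MONTH = 30.44


@dataclass(frozen=True)
class Aberration:
    """A planted copy-number aberration carried by a fraction of the cohort."""

    chrom: str
    start: int
    end: int
    shift: float              # mean log2-ratio shift in carriers
    carrier_fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.carrier_fraction <= 1:
            raise ValueError("carrier_fraction must be in (0, 1]")
        if not self.start < self.end:
            raise ValueError("aberration start must be < end")


@dataclass(frozen=True)
class DriverGene:
    """A gene whose expression is CNA-coupled and (optionally) hazard-linked."""

    gene_id: str
    delta: float               # expression shift in carriers (log2 units)
    log_hr: float              # log hazard ratio per log2-expression unit
    aberration_index: int = 0  # which planted aberration hosts the gene


DEFAULT_ABERRATIONS = (
    Aberration("chr1", 20_000_000, 45_000_000, +0.8, 0.24),
    Aberration("chr2", 50_000_000, 70_000_000, -0.8, 0.20),
)


@dataclass
class SimConfig:
    """Full parameterization of a synthetic cohort. See module docstring."""

    n_samples: int = 50
    n_probes_per_chrom: int = 120
    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 100_000_000),
        ("chr2", 100_000_000),
        ("chr3", 100_000_000),
    )
    probe_noise_sd: float = 0.15
    bias_amplitude: float = 0.10
    planted_aberrations: tuple[Aberration, ...] = DEFAULT_ABERRATIONS
    driver_genes: tuple[DriverGene, ...] = (DriverGene("GDRV1", 1.0, 1.0, 0),)
    passenger_effect: float = 0.0
    expression_sd: float = 0.5
    baseline_hazard: float = 0.010      # progression events / month
    post_progression_hazard: float = 0.05
    other_death_rate: float = 0.002
    censoring_rate: float = 0.004
    accrual_window: float = 36.0        # months
    max_followup: float = 96.0          # months from first registration
    n_genes_per_chrom: int = 20
    n_subtype_panel_genes: int = 44
    subtype_shift: float = 2.0          # GCB-vs-nonGCB mean shift on panel genes
    n_cnv_records: int = 300
    n_cnv_hot_genes: int = 2            # passengers made CNV-rich (>10 records)
    contamination: float = 1.0          # tumour-cell fraction multiplier on shifts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_noise_sd <= 0:
            raise ValueError("probe_noise_sd must be > 0")
        if self.n_samples < 1 or self.n_probes_per_chrom < 2:
            raise ValueError("n_samples >= 1 and n_probes_per_chrom >= 2 required")
        lengths = dict(self.chromosomes)
        for ab in self.planted_aberrations:
            if ab.chrom not in lengths:
                raise ValueError(f"aberration on unknown chromosome {ab.chrom!r}")
            if ab.start < 0 or ab.end > lengths[ab.chrom]:
                raise ValueError(
                    f"aberration {ab.chrom}:{ab.start}-{ab.end} outside chromosome bounds"
                )
            if round(ab.carrier_fraction * self.n_samples) < 1:
                raise ValueError(
                    "carrier_fraction x n_samples < 1: aberration would have no carriers"
                )
        for drv in self.driver_genes:
            if not 0 <= drv.aberration_index < max(len(self.planted_aberrations), 1):
                raise ValueError(f"driver {drv.gene_id}: invalid aberration_index")


@dataclass
class SyntheticTruth:
    """Planted ground truth retained for recovery tests."""

    breakpoints: dict[str, dict[str, list[int]]]   # sample -> chrom -> sorted bp
    carrier_map: pd.DataFrame                      # samples x aberrations (bool)
    driver_ids: list[str]
    driver_carrier: pd.DataFrame                   # samples x driver genes (bool)
    true_log_hr: dict[str, float]
    bias: np.ndarray                               # per-probe planted bias vector
    subtype: pd.Series
    cnv_hot_genes: list[str]
    true_coverages: dict[str, float] = field(default_factory=dict)


@dataclass
class Cohort:
    """All generated tables, cross-indexed by sample id."""

    probes: pd.DataFrame          # probe_id, chrom, start, end + one col/sample
    expression: pd.DataFrame      # genes x samples
    clinical: pd.DataFrame
    cnv_catalogue: pd.DataFrame   # chrom, start, end
    annotation: pd.DataFrame      # gene_id, chrom, start, end
    truth: SyntheticTruth
    config: SimConfig

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    def probe_profiles(self) -> list[ProbeProfile]:
        base = self.probes[["chrom", "start", "end"]]
        return [
            ProbeProfile(s, base.assign(log2=self.probes[s].to_numpy()))
            for s in self.samples
        ]


def _gene_annotation(config: SimConfig) -> tuple[pd.DataFrame, dict[str, int]]:
    """Tile passenger genes per chromosome, place drivers inside their host
    aberrations, and append the subtype signature panel on the last chromosome."""
    rows = []
    for ci, (chrom, length) in enumerate(config.chromosomes):
        for gi in range(config.n_genes_per_chrom):
            start = int((gi + 0.5) * length / config.n_genes_per_chrom)
            rows.append({"gene_id": f"G{ci + 1}_{gi:02d}", "chrom": chrom,
                         "start": start, "end": start + 50_000})
    driver_host = {}
    for k, drv in enumerate(config.driver_genes):
        ab = config.planted_aberrations[drv.aberration_index]
        mid = (ab.start + ab.end) // 2 + k * 120_000
        rows.append({"gene_id": drv.gene_id, "chrom": ab.chrom,
                     "start": mid, "end": mid + 50_000})
        driver_host[drv.gene_id] = drv.aberration_index
    panel_chrom, panel_len = config.chromosomes[-1]
    for gi in range(config.n_subtype_panel_genes):
        start = int((gi + 0.25) * panel_len / max(config.n_subtype_panel_genes, 1))
        rows.append({"gene_id": f"PNL{gi + 1:02d}", "chrom": panel_chrom,
                     "start": start + 10_000, "end": start + 35_000})
    ann = pd.DataFrame(rows).drop_duplicates("gene_id").reset_index(drop=True)
    return ann, driver_host


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate a complete cohort (copy number, expression, clinical, CNV
    catalogue, annotation) plus its ground truth. Deterministic in ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    ab_names = [f"ab{i}" for i in range(len(config.planted_aberrations))]

    # --- carriers -----------------------------------------------------------
    carrier = pd.DataFrame(False, index=samples, columns=ab_names)
    for name, ab in zip(ab_names, config.planted_aberrations):
        n_c = int(round(ab.carrier_fraction * config.n_samples))
        idx = rng.choice(config.n_samples, size=n_c, replace=False)
        carrier.iloc[idx, carrier.columns.get_loc(name)] = True

    # --- probes -------------------------------------------------------------
    probe_rows = []
    for chrom, length in config.chromosomes:
        pos = np.linspace(0, length - 60, config.n_probes_per_chrom).astype(int)
        for p in pos:
            probe_rows.append((chrom, int(p), int(p) + 60))
    probes = pd.DataFrame(probe_rows, columns=["chrom", "start", "end"])
    probes.insert(0, "probe_id", [f"P{i + 1:06d}" for i in range(len(probes))])
    n_probes = len(probes)
    t = np.arange(n_probes) / n_probes
    bias = config.bias_amplitude * np.sin(2 * np.pi * t)

    mid = (probes["start"].to_numpy() + probes["end"].to_numpy()) / 2
    base = np.zeros((n_probes, config.n_samples))
    for name, ab in zip(ab_names, config.planted_aberrations):
        in_ab = (probes["chrom"] == ab.chrom).to_numpy() & (mid >= ab.start) & (mid < ab.end)
        base[np.ix_(in_ab, carrier[name].to_numpy())] += ab.shift * config.contamination
    noise = rng.normal(0.0, config.probe_noise_sd, size=base.shape)
    signal = base + bias[:, None] + noise
    probes = pd.concat(
        [probes, pd.DataFrame(signal, columns=samples, index=probes.index)], axis=1
    )

    breakpoints: dict[str, dict[str, list[int]]] = {}
    for j, s in enumerate(samples):
        per_chrom: dict[str, set[int]] = {}
        for name, ab in zip(ab_names, config.planted_aberrations):
            if carrier.at[s, name]:
                per_chrom.setdefault(ab.chrom, set()).update((ab.start, ab.end))
        breakpoints[s] = {c: sorted(v) for c, v in per_chrom.items()}

    # --- annotation and expression -----------------------------------------
    annotation, driver_host = _gene_annotation(config)
    genes = annotation["gene_id"].tolist()
    subtype = pd.Series(
        np.where(rng.random(config.n_samples) < 0.5, "GCB", "nonGCB"),
        index=samples, name="subtype",
    )
    expr = rng.normal(0.0, config.expression_sd, size=(len(genes), config.n_samples))
    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=samples)
    driver_carrier = pd.DataFrame(False, index=samples, columns=[d.gene_id for d in config.driver_genes])
    for drv in config.driver_genes:
        flags = carrier[ab_names[drv.aberration_index]]
        driver_carrier[drv.gene_id] = flags.to_numpy()
        expression.loc[drv.gene_id] += drv.delta * flags.to_numpy()
    panel = [g for g in genes if g.startswith("PNL")]
    if panel and config.subtype_shift:
        shift = np.where(subtype.to_numpy() == "GCB", 0.5, -0.5) * config.subtype_shift
        expression.loc[panel] += shift[None, :]

    # --- survival -----------------------------------------------------------
    eta = np.zeros(config.n_samples)
    for drv in config.driver_genes:
        eta += drv.log_hr * expression.loc[drv.gene_id].to_numpy()
    hazard = config.baseline_hazard * np.exp(np.clip(eta, -30, 30))
    t_prog = rng.exponential(1.0 / hazard)
    t_death_ly = t_prog + rng.exponential(1.0 / config.post_progression_hazard,
                                          size=config.n_samples)
    t_death_other = (
        rng.exponential(1.0 / config.other_death_rate, size=config.n_samples)
        if config.other_death_rate > 0 else np.full(config.n_samples, np.inf)
    )
    t_censor = (
        rng.exponential(1.0 / config.censoring_rate, size=config.n_samples)
        if config.censoring_rate > 0 else np.full(config.n_samples, np.inf)
    )
    entry = rng.uniform(0, config.accrual_window, size=config.n_samples)
    t_admin = np.maximum(config.max_followup - entry, 1.0)
    censor = np.minimum(t_censor, t_admin)

    clin_rows = []
    for j, s in enumerate(samples):
        reg = DATE0 + np.timedelta64(int(round(entry[j] * DAYS_PER_MONTH)), "D")

        def to_date(months: float):
            return reg + np.timedelta64(int(round(months * DAYS_PER_MONTH)), "D")

        death_t = min(t_death_ly[j], t_death_other[j])
        death_cause = "lymphoma" if t_death_ly[j] <= t_death_other[j] else "other"
        if death_t <= censor[j]:
            died, cause, last = True, death_cause, death_t
        else:
            died, cause, last = False, "alive", censor[j]
        prog_seen = t_prog[j] <= min(death_t, censor[j])
        clin_rows.append(
            {
                "sample_id": s,
                "registration_date": str(reg),
                "progression_date": str(to_date(t_prog[j])) if prog_seen else "",
                "death_date": str(to_date(death_t)) if died else "",
                "cause": cause,
                "last_followup_date": str(to_date(last)),
                "subtype": subtype[s],
                "ipi": int(rng.integers(0, 4)),
            }
        )
    clinical = pd.DataFrame(clin_rows)

    # --- CNV catalogue ------------------------------------------------------
    chrom_names = [c for c, _ in config.chromosomes]
    lengths = dict(config.chromosomes)
    cnv_rows = []
    for _ in range(config.n_cnv_records):
        c = chrom_names[rng.integers(len(chrom_names))]
        ln = int(np.exp(rng.uniform(np.log(10_000), np.log(500_000))))
        s0 = int(rng.integers(0, max(lengths[c] - ln, 1)))
        cnv_rows.append({"chrom": c, "start": s0, "end": s0 + ln})
    hot = [g for g in genes if g.startswith("G") and g not in driver_host][: config.n_cnv_hot_genes]
    ann_idx = annotation.set_index("gene_id")
    for g in hot:
        row = ann_idx.loc[g]
        for k in range(12):
            cnv_rows.append(
                {"chrom": row["chrom"],
                 "start": int(row["start"]) - 5_000 - 200 * k,
                 "end": int(row["end"]) + 5_000 + 200 * k}
            )
    cnv_catalogue = pd.DataFrame(cnv_rows, columns=["chrom", "start", "end"])

    truth = SyntheticTruth(
        breakpoints=breakpoints,
        carrier_map=carrier,
        driver_ids=[d.gene_id for d in config.driver_genes],
        driver_carrier=driver_carrier,
        true_log_hr={d.gene_id: d.log_hr for d in config.driver_genes},
        bias=bias,
        subtype=subtype,
        cnv_hot_genes=hot,
    )
    return Cohort(
        probes=probes,
        expression=expression,
        clinical=clinical,
        cnv_catalogue=cnv_catalogue,
        annotation=annotation,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# IHC image synthesis
# ---------------------------------------------------------------------------

def default_palettes() -> dict[str, np.ndarray]:
    """15 exemplar RGB colours per class, spread around well-separated bases.

    Brown = DAB staining, blue = hematoxylin nuclei, white = unstained
    tissue, background = faint unspecific colour. Offsets are deterministic.
    """
    bases = {
        "brown": (130, 75, 40),
        "blue": (60, 80, 160),
        "white": (245, 245, 248),
        "background": (190, 175, 160),
    }
    rng = np.random.default_rng(20140401)
    palettes = {}
    for name in CLASS_ORDER:
        offs = rng.integers(-12, 13, size=(15, 3))
        offs[0] = 0  # keep the base colour itself as an exemplar
        palettes[name] = np.clip(np.array(bases[name]) + offs, 0, 255).astype(np.int64)
    return palettes


@dataclass
class IHCImage:
    """A synthetic brightfield field with its true class map and coverage."""

    image: np.ndarray          # (H, W, 3) uint8
    true_map: np.ndarray       # (H, W) class indices into CLASS_ORDER
    true_coverage: float       # brown fraction over all pixels
    class_fractions: tuple[float, float, float, float]


def generate_ihc_image(
    width: int,
    height: int,
    class_fractions,
    palettes: dict[str, np.ndarray] | None = None,
    jitter_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> IHCImage:
    """Compose a field image from the four colour populations.

    Pixel counts per class follow ``class_fractions`` exactly (largest-
    remainder apportionment), positions are shuffled, each pixel takes a
    uniformly chosen class exemplar plus optional Gaussian RGB jitter.
    Warns when palettes of different classes come within 4 jitter SDs.
    """
    fr = np.asarray(class_fractions, dtype=float)
    if fr.size != 4 or abs(fr.sum() - 1.0) > 1e-9 or (fr < 0).any():
        raise ValueError("class_fractions must be 4 non-negative values summing to 1")
    pal = palettes if palettes is not None else default_palettes()
    pal = {k: np.asarray(v, dtype=np.int64) for k, v in pal.items()}
    for name in CLASS_ORDER:
        if name not in pal or len(pal[name]) == 0:
            raise ValueError(f"palette for class {name!r} missing or empty")
    if jitter_sd > 0:
        dmin = np.inf
        for i, a in enumerate(CLASS_ORDER):
            for b in CLASS_ORDER[i + 1:]:
                d = np.sqrt(((pal[a][:, None, :] - pal[b][None, :, :]) ** 2).sum(-1)).min()
                dmin = min(dmin, d)
        if dmin < 4 * jitter_sd:
            warnings.warn(
                f"palette classes only {dmin:.1f} RGB units apart with jitter sd "
                f"{jitter_sd}: classes may overlap", stacklevel=2,
            )
    if rng is None:
        rng = np.random.default_rng(seed)
    n = width * height
    counts = np.floor(fr * n).astype(int)
    short = n - counts.sum()
    if short:
        order = np.argsort(-(fr * n - counts), kind="stable")
        counts[order[:short]] += 1
    labels = np.repeat(np.arange(4), counts)
    rng.shuffle(labels)
    img = np.empty((n, 3), dtype=float)
    for ci, name in enumerate(CLASS_ORDER):
        mask = labels == ci
        k = int(mask.sum())
        if k == 0:
            continue
        pick = rng.integers(len(pal[name]), size=k)
        img[mask] = pal[name][pick]
    if jitter_sd > 0:
        img += rng.normal(0.0, jitter_sd, size=img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8).reshape(height, width, 3)
    return IHCImage(
        image=image,
        true_map=labels.reshape(height, width),
        true_coverage=counts[0] / n,
        class_fractions=tuple(fr),
    )


def generate_ihc_cohort(
    n_patients: int,
    fields_per_patient: int = 2,
    width: int = 64,
    height: int = 64,
    coverage_range: tuple[float, float] = (0.0, 0.24),
    jitter_sd: float = 0.0,
    seed: int = 0,
    palettes: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, IHCImage], pd.DataFrame]:
    """Fields for a TMA-like cohort with per-patient target coverages.

    Patient coverages are uniform over ``coverage_range`` (the observed
    staining range); non-brown area splits 45/35/20 between blue, white and
    background. Returns (images by id, field-to-patient map with the true
    per-field brown fraction).
    """
    rng = np.random.default_rng(seed)
    images: dict[str, IHCImage] = {}
    rows = []
    for i in range(n_patients):
        pid = f"PT{i + 1:03d}"
        target = rng.uniform(*coverage_range)
        for f in range(fields_per_patient):
            brown = float(np.clip(target + rng.normal(0, 0.01), 0, 0.9))
            rest = 1.0 - brown
            fr = (brown, 0.45 * rest, 0.35 * rest, 0.20 * rest)
            img_id = f"{pid}_f{f + 1}"
            img = generate_ihc_image(width, height, fr, palettes=palettes,
                                     jitter_sd=jitter_sd, rng=rng)
            images[img_id] = img
            rows.append({"image_id": img_id, "patient_id": pid,
                         "true_coverage": img.true_coverage})
    return images, pd.DataFrame(rows)
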