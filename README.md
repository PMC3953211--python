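# cnascreen

An integrative screen for **copy-number-driven, survival-associated genes in
lymphoma cohorts**, built as a tested, reusable Python library with a thin
CLI. It is aimed at computational biologists who have probe-level aCGH log2
ratios, a gene-level expression matrix, clinical follow-up and (optionally)
brightfield IHC images, and want to go from raw probe signal to a shortlist
of biomarker candidates with region, association and survival evidence.

## What it computes

1. **Copy number** — probe profiles are normalized with robust LOWESS (four
   iterations, 30% window), denoised with circular binary segmentation
   (permutation p < 0.05 per split, no undo), and segments are called
   *gain*/*loss* when the segment mean departs from the cohort median by more
   than 2 cohort noise SDs (SD estimated from probe-minus-segment residuals).
2. **Recurrent regions** — minimal common CNA regions where ≥ 10% of samples
   carry an aberration of the same direction (sweep-line over segment
   boundaries); genes overlapped by more than 10 germline CNV catalogue
   records are excluded.
3. **CNA–expression association** — per gene, the cohort is split by CNA
   status and the signal-to-noise ratio
   `SNR = (μ_CNA − μ_rest) / (σ_CNA + σ_rest)` is tested with a label
   permutation test (one-sided in the direction the aberration implies);
   selection requires p < 0.05, ≥ 3 aberrant patients and a direction-
   consistent sign. Benjamini–Hochberg FDR is reported alongside.
4. **Survival** — PFS, OS and lymphoma-specific OS with cause-specific
   censoring; Kaplan–Meier + log-rank, Cox proportional hazards (Breslow
   ties, Efron via lifelines), and ROC/Youden marker cutoffs with
   Hanley–McNeil AUC confidence intervals.
5. **IHC quantification** — each pixel of a brightfield field is assigned to
   brown / blue / white / background by nearest exemplar colour (15 examples
   per class); staining coverage = brown fraction; 1–3 fields are averaged
   per patient and patients are dichotomized at a ROC cutoff (or a fixed
   external one such as 8.9%).

Because real screening cohorts of this kind are not publicly available with
outcomes, the package ships a first-class **synthetic cohort generator**
(`cnascreen.synthcohort`) that emulates all of the above inputs with planted
ground truth — segment shifts with intensity-dependent bias, CNA-coupled
driver expression, proportional-hazards survival tied to driver expression,
a CNV catalogue, and colour-population IHC images.

## Worked example

```python
from cnascreen import SimConfig, generate_cohort, PipelineConfig, run_screen

cohort = generate_cohort(SimConfig(seed=3))   # 50 samples, 1 planted driver
report = run_screen(cohort, PipelineConfig(seed=3))
print(report.noise)
print(report.regions[["chrom", "start", "end", "direction", "frequency"]])
print(report.biomarkers[["gene_id", "direction", "snr", "assoc_p", "cox_log_hr", "cox_p"]])
```

prints (seed 3):

```
{'cohort_median': 0.0005229909883559536, 'cohort_sd': 0.14791319813809706, 'k': 2.0}
  chrom     start       end direction  frequency
0  chr1  20168055  44537848      gain       0.28
1  chr2  50420137  69747917      loss       0.20
  gene_id direction       snr   assoc_p  cox_log_hr     cox_p
0   GDRV1      gain  1.270104  0.000999     1.26923  0.000134
```

Reading: the cohort noise SD is ≈ 0.148 (0.15 was planted), both planted
aberrations surface as recurrent regions at their planted frequencies, and
the planted driver `GDRV1` is the single reported biomarker — gained in 28%
of samples, strongly upregulated in carriers (SNR 1.3, permutation
p ≈ 0.001) and prognostic (Cox log HR 1.27 per log2-expression unit,
p ≈ 1e-4; truth: 1.0).

The same flow is available from the shell:

```bash
cnascreen simulate --out cohort --seed 7
cnascreen segment   --probes cohort/probes.tsv --nperm 200 --seed 7 --out calls.seg
cnascreen regions   --seg calls.seg --min-freq 0.10 --cnv-catalog cohort/cnv_catalogue.bed \
                    --genes cohort/genes.bed --out regions.tsv
cnascreen integrate --expr cohort/expression.tsv --seg calls.seg --genes cohort/genes.bed \
                    --nperm 1000 --seed 7 --out assoc.tsv
cnascreen survival  --clinical cohort/clinical.tsv --marker cohort/expression.tsv:GDRV1 \
                    --endpoint pfs --out endpoints.tsv
cnascreen run-all   --cohort cohort --out report --seed 7
```

## Layout

```
src/cnascreen/
  synthcohort.py   synthetic cohorts + IHC images with planted truth
  cna.py           LOWESS normalization, CBS, noise model, gain/loss calls
  regions.py       minimal common regions, CNV filter, subgroup tests
  integrate.py     SNR statistic, permutation p, BH FDR, gene selection
  survstats.py     endpoints, KM, log-rank, Cox (Breslow/Efron), ROC cutoffs
  ihc.py           pixel classification, coverage, patient dichotomization
  pipeline.py      GEP subtype clustering + the orchestrated screen
  evaluation.py    calibration/recovery studies used by tests and scripts
```

See `docs/methods.md` for the statistical model, parameter choices and
limitations.
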