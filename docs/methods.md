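# Methods

## Scope and overall model

`cnascreen` implements an integrative biomarker screen for DLBCL-like
cohorts: per-sample aCGH copy-number profiles are segmented and called,
recurrent aberrant regions are intersected with gene loci, gene expression is
tested for coupling to CNA status, and surviving candidates are tested for
prognostic effect. Every stage is exercised against synthetic cohorts whose
generative model mirrors the assumptions the screen itself makes; the
generator is part of the tested API, not a fixture.

## Copy-number stage

**Normalization.** Probe log2 ratios are detrended by robust LOWESS against
a covariate (probe index by default, emulating an intensity/positional
trend), with a 30% window and four robustifying iterations. A constant
covariate degenerates to the identity with a warning. NaN probes are dropped
before normalization and counted on the profile.

**Segmentation.** Circular binary segmentation: within a chromosome window
of `n` probes, every circular arc `(i, j)` is scored with the normalized
mean-difference statistic
`Z(i,j) = (mean(x[i:j]) − mean(rest)) / sqrt(1/w + 1/(n−w))`, and the
maximal |Z| is referred to a permutation distribution obtained by shuffling
the window's probes. A split is accepted when the add-one permutation p is
below `alpha` (0.05); the accepted arc contributes up to two change points
and recursion continues on the pieces. No undo/pruning pass is applied.
Permutations stop early as soon as the exceedance count guarantees
p ≥ alpha, which leaves accept/reject decisions unchanged while making flat
chromosomes cheap. Arc geometry is precomputed per window length; the
statistic matrix is O(n²) memory, appropriate for the array resolutions used
here (≤ a few thousand probes per chromosome).

**Noise model and calling.** The cohort background is the median of pooled
raw probe values across all arrays. The noise SD is taken from pooled
per-probe residuals (probe minus its segment mean) when a segmentation is
available — residuals isolate measurement noise from true aberrations, which
would otherwise inflate the SD in aberration-rich genomes — and from the raw
pool otherwise. A segment is called *gain* (*loss*) when its mean exceeds
(falls below) the median by more than `k` = 2 SDs; the threshold is applied
to segment means, since denoising precedes calling. With SD = 0 any
deviation is called, with a warning.

**Gene mapping.** Each gene takes the call of the segment with the largest
base-pair overlap with its body; ties break toward the segment with larger
|segment mean| (conservative toward detecting aberration). Genes overlapping
no segment are `missing`.

## Regions and filters

Minimal common regions are maximal genomic runs where at least
`ceil(min_freq × n_samples)` samples (default 10% of the cohort carrying
both data types) have an aberration of the same direction; per-sample
intervals are unioned first so a sample never counts twice at one position,
and gains and losses are swept independently. Region carriers are all
samples aberrant anywhere inside the region, so a reported frequency can
exceed the planted carrier fraction slightly when noise calls overlap.

The germline CNV filter counts raw catalogue records (duplicates included)
overlapping each gene by ≥ 1 bp via an interval tree and excludes genes with
more than `max_cnv` = 10; an empty catalogue retains everything. Recurrence
filters require ≥ 3 aberrant patients for association and ≥ 5 for survival
testing. Subgroup frequencies are compared with the two-sided Fisher exact
test (chi-square optional).

## Association

For each candidate gene and direction, samples split into CNA carriers vs
rest and the signal-to-noise ratio `(μ₁ − μ₂)/(σ₁ + σ₂)` (sample SDs) is
computed; both-constant groups yield a signed-infinity sentinel (0 when
means also agree). Significance comes from label permutations preserving
class sizes, with the add-one convention `p = (1 + #extreme)/(1 + B)`;
the default sidedness is one-sided in the direction the aberration implies
(gain → up, loss → down), because the selection rule is directional. The
requirement that non-carriers be "stable" is carried by the SNR denominator
rather than a separate test. Selection requires p < alpha, ≥ `min_samples`
carriers and a direction-consistent SNR sign; BH FDR is computed across all
tested gene/direction pairs for transparency. Each gene draws its RNG stream
from (seed, gene id, direction), making results invariant to gene order.

## Survival

Endpoints are derived from dates (exact day counts / 30.44 → months):
PFS events at progression/relapse with other-cause deaths censored at death;
OS events at any death; lymphoma-specific OS events only at lymphoma deaths.
Zero-duration follow-up is clipped to one day. Kaplan–Meier and the log-rank
test delegate to lifelines; 5-year survival is read off the curve at 60
months. Cox regression uses an in-package Newton solver on the Breslow
partial likelihood (chosen as the tie default; Efron available through
lifelines), with step-halving, a collinearity warning at |r| > 0.9999, a
constant-covariate error, and bounded coefficients plus a warning under
near-separation. ROC cutoffs maximize Youden's J over observed marker
values (classifying `marker > cutoff` as high); the AUC is the tie-corrected
rank statistic with a Hanley–McNeil normal CI, and the binary label is the
endpoint's event-ever indicator (the simplest label consistent with pairing
ROC with survival outcomes; event-by-60-months is a caller-side variation).

## IHC quantification

Classification is a pixelwise nearest-exemplar rule over four classes
(brown, blue, white, background; ≤ 15 exemplars each) using raw-RGB
Euclidean distance in exact integer arithmetic, so ties break
deterministically in the order brown → blue → white → background. Raw RGB is
the default colour space because the rule is defined directly on example
colours; a perceptual space would change behaviour only near class
boundaries. Coverage is the brown fraction; both denominators (all pixels
vs tissue = brown+blue+white) are always reported, with `all` the default
since the staining ranges observed are consistent with either convention.
Patient scores average 1–3 fields (more allowed with a warning). Field
selection is manual in practice and therefore an input here.

## Pipeline

`run_screen` chains the stages with one root seed; per-sample and per-gene
streams are derived from (seed, entity id) so reports are invariant to input
order. Survival is tested on two tracks, mirroring the two-step analysis the
screen is built around: per region (carriers vs rest, log-rank, ≥ 5
carriers) and per selected gene (continuous Cox, then ROC-dichotomized KM).
A biomarker needs all three evidence layers: a recurrent region, a selected
association and Cox p < alpha; the ROC/log-rank columns are reported
alongside. Survival p-values are reported unadjusted (as is conventional for
screens of this size) next to the BH column of the association table.

GEP subtyping clusters samples on a signature panel (complete linkage,
Euclidean) and cuts the tree in two; branches are labelled GCB/non-GCB only
when per-gene signature directions are supplied (the branch with higher mean
signed expression becomes GCB), otherwise neutral cluster labels are
emitted — silently inventing signature directions seemed worse than making
the caller map them.

## Synthetic cohort: what it emulates, and defaults

Per sample, probe signal = planted segment shift (carriers only, scaled by a
tumour-cell-fraction multiplier, default 1.0) + a one-cycle sinusoidal trend
of amplitude `bias_amplitude` over the probe index (a smooth target for
LOWESS) + N(0, `probe_noise_sd`). Driver genes sit mid-aberration and gain
`delta` log2 expression in carriers; passengers are fully decoupled
(effect 0). Progression is exponential with log hazard
`log(baseline_hazard) + Σ log_hr_g × expression_g`; lymphoma death follows
progression after an exponential delay; an independent exponential
other-cause death process and exponential censoring compete; staggered
accrual over `accrual_window` with a fixed analysis horizon provides
administrative censoring. The clinical table carries dates and cause labels
so all three endpoints are derivable. A 44-gene subtype panel separates
GCB/non-GCB means by `subtype_shift`. The CNV catalogue is uniform random
records plus two designated CNV-rich passenger genes (12 records each) so
the >10-CNV exclusion always has work to do.

Defaults (chosen once to mirror a realistic screening cohort of this kind):
50 samples; 3 chromosomes × 120 probes; noise SD 0.15 and bias 0.10 (log2);
a +0.8 gain in 24% and a −0.8 loss in 20% of samples; driver Δ = 1.0 log2 at
expression SD 0.5; driver log HR = 1.0 per log2-expression unit; baseline
hazard 0.01/month, post-progression hazard 0.05/month, other-cause death
0.002/month, censoring 0.004/month, accrual 36 months, horizon 96 months
(median follow-up ≈ 5 years). The generator does **not** model exon-level
signal, batch effects, clonal heterogeneity, spatially structured IHC
staining or non-proportional hazards — passing tests demonstrate correctness
of the machinery under its own assumptions, not robustness to those
violations.

## Numerical and sizing choices

* Permutation defaults: 10,000 for standalone association calls, 1,000
  inside the pipeline, 200 for CBS splits within `run_screen` (the smallest
  attainable p, 1/201 ≈ 0.005, is far below the 0.05 decision threshold, so
  split decisions are unchanged while cohort-scale studies stay fast);
  standalone `cbs_segment` defaults to 1,000.
* Study sizes in `evaluation.py`: 200 chromosomes for breakpoint recovery,
  2,000 genes for null calibration, 200 replicates for driver selection,
  1,000 log-rank null simulations, 100 random instances per brute-force
  oracle, 50 (tests) / 30 (acceptance script) replicate cohorts end-to-end —
  sizes at which the binomial noise of each estimated rate is well inside
  the asserted bands.
* Coordinates are 0-based half-open internally; SEG files are written
  1-based inclusive.
* All randomness derives from a root seed via per-entity CRC32-keyed
  streams, which makes outputs byte-reproducible *and* order-invariant.

## Known limitations

Allele-specific copy number, ploidy/purity estimation, GISTIC-style
recurrence significance, competing-risks models, time-dependent covariates
and stain deconvolution are out of scope. The Cox solver targets small
covariate counts (p ≤ ~10); the CBS statistic matrix is quadratic in probes
per chromosome; the permutation test returns an upper-bounded p (≥ alpha)
when it stops early, which is exact for decisions but not for reporting
extreme non-significant p-values.
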