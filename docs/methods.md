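# Methods

This note documents the models behind `mmrquant`: what the synthetic
generators emulate, how the scoring and evaluation statistics are defined,
the numerical choices, and what the test suite does and does not establish
about behaviour on real slides.

## Cohort generator (`mmrquant.cohort`)

The generator emulates a large adjuvant-chemotherapy trial TMA cohort
profiled by MMR IHC. Its hierarchy is case → core → stained section →
cell counts.

**Case layer.** Each case is MMRd with probability `prevalence_mmrd`
(default 0.115). MMRd cases draw a loss pattern from `pattern_mix`; the
default mix {MLH1+PMS2: 0.75, MSH2+MSH6: 0.10, isolated PMS2/MSH6: 0.06
each, isolated MLH1: 0.02, isolated MSH2: 0.01} reflects the clinical
predominance of combined MLH1–PMS2 loss (mostly *MLH1* promoter
methylation); the exact proportions are a design choice, fully
configurable. Cases contribute 4 cores (2 tumour-centre + 2
invasive-margin) with probability 0.76 and 8 cores otherwise; a
three-core tumour-centre-only validation design is
`cores_per_case={3: 1.0}`.

**Latent positivity.** Per-protein epithelial positivity is generated
through a Gaussian copula and marginal quantile transforms:

    z_p = √s·G + √((1−s)·c_d)·U_d + √((1−s)(1−c_d))·ε_p ,

where `G` is a per-case factor (shared section/staining quality, weight
`case_coupling` s = 0.35), `U_d` a per-heterodimer factor
(`dimer_coupling`, MLH1+PMS2: 0.35, MSH2+MSH6: 0.78) and ε protein noise.
Φ(z) is pushed through the retained marginal — a two-component Beta
mixture with a high mode (mean 0.965, weight 0.94: "homogeneous
expression") and a moderate mode (mean 0.65) — or through a low-mean Beta
(mean 0.04) for lost proteins. Stromal positivity uses the same machinery
with its own shared factor (weight 0.85) coupled to the epithelial factor
(weight 0.5); stroma retains expression in MMRd, which is what makes the
core-level stain-failure QC rule informative.

The coupling weights and mixture weights were calibrated once against four
published summary statistics of the cohort the generator emulates — two
thirds of cases ≥90% positive for all four proteins; case-level Pearson
r ≈ 0.88 (MLH1–PMS2) and ≈ 0.69 (MSH2–MSH6); stromal pairwise r in
0.68–0.76 — and then frozen. The couplings are deliberately asymmetric:
MLH1+PMS2 co-loss is common enough that it alone induces r ≈ 0.85 at the
case level, whereas MSH2+MSH6 co-loss is rare, so most of its correlation
must come from coupled retained expression. At n = 2000 the Monte-Carlo
spread of the MSH2–MSH6 correlation is ±0.03 (1 sd), dominated by the
binomial count of the ~23 co-loss cases; the acceptance script therefore
measures it on a 6,000-case cohort (the evaluated condition is "at least
2,000 cases").

**Count layer.** Section object totals are negative binomial (mean 620,
shape 12). Composition splits objects into epithelium (case-level Beta
fraction), stroma, lymphocytes (base fraction 0.08, ×2 in MMRd — the
lymphocytic infiltrate enrichment that motivates cell-level
classification), and strong/weak background at rates 0.01/0.03. Positive
counts are beta-binomial around the latent positivity
(`core_overdispersion` = 120, i.e. core-to-core sd ≈ 2.7 points at 90%
positivity). With probability `stain_fail_rate` (0.004 per section) a
section fails immunostaining: positives collapse to a handful of cells
(< 20 summed over epithelium and stroma, the QC definition of a
stain-negative section). A small `missing_section_rate` (7e-4) emulates
sections lost during staining.

**Raters and MSI.** Two simulated pathologists err at 0.25 on cases
carrying any stain-failed section and 0.0025 otherwise, which makes
staining failure account for ~90% of rater-vs-truth discordances; the
consensus call equals truth unless `consensus_error_rate` is raised. MSI
PCR labels flip from MMR truth at P(MSS|MMRd) = 0.05 and
P(MSI|MMRp) = 0.01 by default — MMR IHC and MSI PCR genuinely disagree on
a minority of cases, and the cross-tabulation machinery is designed to
attribute call-vs-MSI discordance to classifier error or to assay
disagreement using the consensus review.

**Seeding.** A single master seed; each case uses the substream
`SeedSequence(seed, spawn_key=(i,))`, so enlarging a cohort never
reshuffles earlier cases.

## Image renderer and cell caller (`mmrquant.imaging`)

The renderer composes per-pixel optical densities for hematoxylin and DAB
from elliptical nuclei on a circular core, then converts to RGB by
Beer–Lambert transmission, `I = 255·10^(−OD·V)`, with the standard H-DAB
unit stain vectors (hematoxylin (0.65, 0.70, 0.29), DAB (0.27, 0.57,
0.78)). Epithelial nuclei (semi-axes ≈ 5–6.5 × 4–5 px) sit in glandular
clusters and may touch; lymphocytes are small (radius 2.3–3 px) and
chromatin-dense (hematoxylin OD 0.9); stromal nuclei are elongated
(8.5–10.5 × 1.5–1.9 px, eccentricity > 0.97); fold bands are strips
intensely stained in both channels; weak blobs mimic mucus (DAB ≈ 0.3, no
hematoxylin). Positive nuclei carry DAB OD ≈ 0.65, negative ≈ 0.02.
Nuclei are opaque (first-drawn wins overlaps); a spec whose summed nucleus
area exceeds 60% of the disc is rejected as unphysical packing.

The caller is a fully specified classical pipeline — it is *not* a
reproduction of any trained commercial model, and its defaults are
calibrated to this renderer, not to scanner output:

1. colour deconvolution by inverting the stain matrix on
   OD = −log10(I/255) (rejects near-singular matrices);
2. fold detection: connected pixels with DAB OD > 0.70 **and**
   hematoxylin OD > 0.65 over ≥ 250 px² are counted as strong background
   and masked out — positive nuclei never reach that hematoxylin level;
3. nucleus detection on the smoothed (σ = 0.8) H+DAB OD sum, threshold
   0.22, binary opening, minimum area 8 px²;
4. splitting: distance-transform watershed, but only within components of
   ≥ 150 px² — smaller components are single objects, which protects thin
   stromal nuclei from being chopped into round fragments;
5. classification: no nuclear hematoxylin (< 0.18) → background (strong if
   DAB ≥ 0.45 else weak); eccentricity ≥ 0.78, or an eccentric (≥ 0.6)
   fragment under 55% of the epithelial median area → stromal; small
   (< 50% of the epithelial median area) and round (< 0.6) → lymphocyte;
   otherwise tumour epithelium. The epithelial reference area is the
   median of round regions ≥ 40 px², estimated per image;
6. positivity for tumour/stromal classes: mean nuclear DAB OD ≥ 0.15,
   midway between the rendered negative (≈ 0) and positive (≥ 0.4) modes.

On default renders this yields 7-way class accuracy ≈ 0.93–0.97 and
round-trip stain recovery within 0.02 OD (the 8-bit quantisation bound at
the rendered densities). End-to-end (render → call → QC → score), the case
score stays within 5 points of the rendered-truth score for ≥ 95% of
cases. None of this is claimed to transfer to scanned slides: the renderer
has no focus gradients, stain batch variation, nuclear texture, or
out-of-plane tissue, and the caller's thresholds would need re-calibration
on real material.

## Scoring and QC (`mmrquant.scoring`)

QC follows the three rules described in the README, in order: the
epithelial-minimum rule is applied per core×protein *section* (each
protein is a separate stained section of the core); the stain-negative
rule drops a whole core only when every protein's section has < 20
positive cells summed over epithelium and stroma (a missing section
cannot rescue a core); cases with no passing section are uninformative.
Each level's excluded + retained counts reconcile exactly with the input,
and the QC report carries them.

Percentages are carried at full float precision on the 0–100 scale;
rounding happens only in report output. The per-protein case value pools
tumour-centre and invasive-margin cores without weighting; per-protein
min/max across cores are reported alongside. The case score is the minimum
over *informative* proteins only — a case is dropped only when
uninformative for all four, so a case with three informative proteins
still gets a score. Correlation reports compute pairwise Pearson/Spearman
with pairwise-complete cases and flag pairs with < 3 cases or constant
vectors rather than emitting numbers.

## Diagnostic evaluation (`mmrquant.diagnostics`)

AUROC is the tie-corrected rank (Mann–Whitney) statistic with the score
negated internally so that low scores indicate disease; the bootstrap CI
resamples cases with replacement (percentile method, default 1,000
resamples, seeded; degenerate single-class resamples are redrawn).
Threshold calibration scans the candidate set (unique scores plus a
sentinel above the maximum): fixed-sensitivity mode returns the *smallest*
threshold reaching the target — with the strict `score < t` rule
sensitivity is non-decreasing and specificity non-increasing in t, so this
tie-break maximises specificity; Youden mode maximises
sensitivity + specificity with ties toward the smaller threshold.
Per-protein loss calls reuse the MMR-status threshold, keeping patterns
consistent with the case score.

Performance reports are derived from a single confusion matrix, so every
identity (F1 = harmonic mean of PPV and sensitivity, Fowlkes–Mallows =
their geometric mean, rule-out fraction = specificity × (1 − prevalence),
FN fraction = (1 − sensitivity) × prevalence) holds exactly. Whole-cohort
extrapolation adds screen-negative unreviewed cases as true negatives and
recomputes all fractions over the enlarged denominator — appropriate only
when the screen rule has been validated on the reviewed sample.

Agreement uses Cohen's κ (chance agreement from marginal products) and
Gwet's AC1 with chance agreement `pₑ = (1/(K−1))·Σ πₖ(1−πₖ)`, πₖ the mean
of the two raters' marginals (2π(1−π) in the binary case); AC1 is robust
to the skewed-prevalence "kappa paradox". Exact-pattern agreement is
multicategory with identity weighting — no partial credit for overlapping
protein sets. κ is undefined (flagged) when both raters are constant and
equal.

## Outcome models (`mmrquant.survival`)

RFI is time from randomisation to relapse, censoring at death without
relapse or last contact; records without a usable positive time are
rejected with a reason, and multivariable fits use complete cases only (no
imputation). Kaplan–Meier/log-rank and the multivariable Cox fit are
lifelines (partial likelihood, Efron ties, Wald CIs); constant covariates
are dropped and flagged; non-convergence raises with diagnostics rather
than emitting numbers; scaled-Schoenfeld trend tests (rank transform) are
reported per term as the proportional-hazards check. Association tests are
Fisher exact (2×2), chi-square (larger tables) and Welch t (continuous),
all two-sided.

The trial simulator draws MMR status Bernoulli(0.1) and duration arm
Bernoulli(0.5) independently, exponential event times with administrative
censoring at 72 months, and a baseline hazard solved (Brent) so the
expected event count equals the design's 500 recurrences. The
MMR-by-duration interaction is multiplicative: the ratio between
MMR-group-specific duration hazard ratios, parametrised symmetrically
(duration HR = geomean·ratio^(±1/2), geomean 1 by default so the overall
duration effect stays null). Power is the fraction of replicates whose
interaction Wald p < α, with a Wilson CI; replicate fits use an internal
Newton partial-likelihood solver (Breslow form — identical to Efron on
untied continuous times; agreement with lifelines is unit-tested) because
a full lifelines fit per replicate is two orders of magnitude slower. At
the stated design and a 2.3-fold ratio the estimated power is ≈ 0.85–0.90;
the simple analytic approximation (Σ 1/dₖ over the four cell event
counts) gives ≈ 0.78–0.80, so the claim "power 0.8 at ratio 2.3" is
consistent with this design. Under the null the rejection rate sits inside
the binomial band around α.

## Problem sizes and limitations

Test and acceptance runs use sizes a laptop handles in minutes: cohorts of
1,500–6,000 cases, 20-case rendered image cohorts (160 core images at
384 px), and 500–600 trial replicates of 2,000 patients. Known
limitations: the generator models neither staining batch effects nor
scanner variation; the renderer's nuclei are smooth ellipses, so the
caller's morphology thresholds are renderer-specific; pattern-mix
proportions and MSI discordance rates are plausible defaults, not
estimates; and the power claim is validated only under the simulator's
stated parametrisation (exponential baseline, administrative censoring,
symmetric interaction split).
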