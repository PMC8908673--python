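# Methods

This note documents the statistical procedures implemented in `pdoniche`,
the defaults chosen where the underlying assay conventions leave the design
open, and what the synthetic-study generator does and does not emulate.

## Expression normalization and subtyping

Raw intensities (genes x samples, strictly positive) are log2-transformed
and quantile-normalized across samples: the reference distribution is the
mean of the per-sample sorted value vectors, and each sample's values are
mapped onto it rank by rank. Tied values receive the mean of the reference
values at the ranks the tie group occupies (the preprocessCore/limma
convention; an independent cross-check against `limma::normalizeQuantiles`
is part of the test suite). The operation is idempotent on its own output
and leaves identical columns unchanged.

Subtype calling uses two gene signatures ("Basal-like", "Classical") given
as GMT input. Each signature gene is z-scored per gene across the cohort
(SD with n-1 denominator; zero-variance genes contribute 0 and are
reported), and the total score is the **sum** (not mean) of basal z-scores
minus the sum of classical z-scores; a score >= 0 maps to Basal-like. Design
choices made where the convention is ambiguous:

* z-scores are computed per gene across samples (cohort-comparative axis),
  on the quantile-normalized log2 scale, with no further per-gene scaling;
* summing rather than averaging means missing signature genes shrink a
  signature's weight — the number of matched/missing genes is reported so
  imbalance is visible;
* the `MoffittSubtypeClassifier` estimator freezes the cohort's per-gene
  means/SDs at `fit`, so `predict` can score new samples on the same axis
  (the classical transductive use is `fit_predict` on the cohort itself).

Correlation ranking computes each gene's Pearson r against a per-sample
score; genes with zero variance or missing values are excluded and counted.
Ordering is r descending with gene-id ascending as the deterministic
tie-break; the extraction step returns the k highest-r and k lowest-r genes
(the bottom list in ascending-r order), which are disjoint by construction
for k <= n/2.

## Niche-dependency scoring

Each well's signal is raw luminescence minus the mean blank of its batch
(global if no batch column); negative differences are clipped to 0 with a
warning rather than propagated. The proliferation fold change is
mean(day-10 signals) / mean(day-0 control signals); one day-0 control per
sample (the seeded-cell reading) is shared across its conditions, and
replicates — including repeat runs — are aggregated by arithmetic mean. The
niche-dependency score is fold(niche)/fold(serum), and factor-dropout
response is fold(niche minus factor)/fold(niche). Both are invariant to
rescaling all luminescence by a common positive constant.

High/Low assignment has no published cut, so the default policy is a median
split over the analyzed samples (strictly above the cut -> High), with a
fixed-threshold override; the policy and cut are recorded in the output.
Because published drug-group memberships can omit samples without an explicit
rule, the split accepts an explicit include-list instead of guessing an
exclusion criterion.

## Robust 4PL dose-response

Responses are first normalized so the mean response at a stated reference
dose is 100% (for potency-factor assays, the reference is another curve's
top dose — e.g. RSPO1 at 1000 ng/ml — applied to both curves of a sample).
Dose 0 is disallowed; the lowest tested dose serves as the reference/left
edge. The model on the log10-dose axis is

    r(d) = bottom + (top - bottom) / (1 + 10^((log10 EC50 - log10 d) * h))

with Hill slope `h` free in sign. Fitting minimizes a soft-L1 loss
(`scipy.optimize.least_squares`, `f_scale` = 5 response-% units — quadratic
below ~5%, linear beyond), chosen as a smooth robust loss; results are
canonicalized to top >= bottom by flipping the Hill sign if needed.
Initialization is a multi-start grid: bottom/top from the data extremes,
log10 EC50 at the quartiles of the tested log-doses, Hill in {+1, -1}; box
constraints bottom >= 0 and top <= 150 stabilize small-n fits on normalized
percentages and are overridable. Convergence is reported; flat data sets a
Hill-unidentifiable flag. Noise-free curves are recovered to optimizer
tolerance (~1e-6 relative on EC50), and fits are invariant to point order
and duplication.

AUC integrates the **fitted** curve (not the raw points) over log10 dose
across the observed dose range, by trapezoid on a 513-point grid; units are
% x log10-dose, and a larger AUC means a more resistant sample. Subtype
comparisons use the unpaired two-tailed Student's t-test on AUC (degenerate
zero-variance groups return t=0, p=1 when equal and p=0 when separated);
score-vs-AUC association uses Spearman rank correlation.

## Organoid and stain imaging

Images are single-channel arrays with a um-per-pixel calibration carried in
a YAML sidecar. Segmentation is global Otsu thresholding, binary hole
filling, and 8-connected components; per-object area is pixel count x
um_per_pixel^2. This recipe is the package's fully parameterized
segmentation stand-in for vendor well-scan software: the threshold can be
fixed, and border-touching objects are retained but flagged. The organoid
rule is inclusive — objects with area >= 2000 um^2 count — and the reported
quantities are the qualifying count and total area. Stain quantification is
the percentage of pixels above a fixed or Otsu threshold. A constant image
yields zero objects rather than an error.

## ddCt qPCR

Replicate Ct values are averaged on the Ct scale; per condition,
dCt = mean Ct(target) - mean Ct(reference gene), ddCt subtracts the baseline
condition's dCt, and fold = 2^(-ddCt). Amplification efficiency is fixed at
2 (no Pfaffl correction). The baseline condition's fold is exactly 1, and
folds are invariant to any constant added to all Ct values.

## Synthetic study generator

The generator emulates an 8-line organoid study — 3 Grade 1, 3 Grade 2 and
2 Grade 3 lines with designed niche-dependency scores (Grade 1: 3.5–5.0;
Grade 3: 0.45–0.55), Grade 1 and one plastic Grade 2 line flagged
Classical-like — and emits every input table plus a `truth.json` with the
designed ground truth, so tests never re-derive it. Noise models are the
simplest consistent with positivity, since assay conventions fix none:
log2-additive Gaussian for expression (SD 0.5), lognormal with
CV-parameterization for luminescence (CV 0.10) and dose-response responses
(CV 0.05), Gaussian on the Ct scale for qPCR (SD 0.15). Three replicates
per condition are the default throughout.

* **Expression** (6065 genes): 25-gene basal and classical signatures
  shifted by +2 log2 units in the matching samples; 15 mevalonate-pathway
  genes whose log2 mean is baseline + 0.8 x designed niche score; the rest
  i.i.d. background noise. A separate `mevalonate_noise_sd` lets that block
  be generated noise-free while background noise stays on.
* **Growth**: fold(serum) is 1.0 / 3.0 / 8.0 for Grades 1/2/3;
  fold(niche) = designed score x fold(serum), so the designed score is
  recoverable by construction. Day-0 wells read the 5,000 seeded cells;
  luminescence = blank + cells x per-cell signal. Dropout media multiply the
  niche fold by per-factor (Classical-like, Basal-like) coefficients —
  Wnt3a omission is neutral for every line, RSPO1 omission suppresses
  Classical-like lines to 35%.
* **Dose-response**: per-(drug, sample) 4PL truth curves. Gemcitabine
  (0.001–10^4 nM, 8 log-spaced doses) has EC50 and residual-survival bottom
  rising monotonically with the designed niche score; simvastatin
  (0.001–100 uM) is reversed. The RSPO scenario places two rising curves on
  a Grade 1 line (1–1000 ng/ml, 8 doses) with truth EC50s of 63.89 (RSPO3)
  and 252.5 ng/ml (RSPO1) in raw proliferation-fold units (bottom 1, top
  8–8.5). Drug truths are generated only for the six lines in the default
  include-list (the drug-comparison groups); the exact dose grids are the
  package's own choice of plausible log-spaced ranges.
* **Images**: non-overlapping bright ellipses on a dark background, placed
  on a deterministic grid with seeded aspect ratio/rotation; truth records
  both the designed areas and the realized (drawn) pixel areas, which
  differ only by discretization — relevant for objects designed exactly at
  the 2000 um^2 boundary. Stain images are two-level with an exact positive
  fraction decreasing from Grade 1 (30%) to Grade 3 (5%).
* **qPCR**: true Ct means per gene x condition (conditions 2D serum,
  3D serum, 3D organoid-conditioned medium) with only RSPO3 responding to
  conditioned medium (designed fold 8).

Determinism: each generator draws from its own seeded substream, so the same
seed and config give byte-identical files regardless of generation order.

What the generator does **not** emulate: probe-level microarray artifacts,
sequencing reads, plate-edge effects, growth kinetics between day 0 and 10,
image texture beyond plain ellipses, and qPCR efficiency variation. Passing
tests therefore demonstrate that the analysis recovers designed effects
under idealized noise — not that it is robust to those real-data artifacts.

## Problem sizes and runtime choices

The default test suite runs the full Monte-Carlo recovery check at 100
seeds of the 8-sample scenario (6065 genes, 6 gemcitabine curves per seed),
the noise-robustness check of the 4PL fitter at 200 simulated curves, and
the EC50-recovery property at 50 random parameter draws — sizes chosen so
the whole suite completes in about a minute on one CPU while keeping the
Monte-Carlo acceptance bands (>= 95/100, >= 90/100) meaningful.

## Known limitations

* The High/Low median split is undefined when all scores are equal (raised
  as an error) and sensitive near the cut for even sample counts.
* EC50 estimates are unstable when the tested dose range does not bracket
  the EC50 well (e.g. a rising curve whose top plateau is barely reached);
  the fit is still reported, with convergence and identifiability flags.
* The subtype classifier's z-axis is cohort-relative: adding samples
  changes all scores; `predict` on new samples is only as good as the
  fitted cohort's gene means/SDs.
* Quantile normalization assumes comparable global distributions across
  samples; it is inappropriate when most genes truly differ.
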