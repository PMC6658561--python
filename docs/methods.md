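# Methods

## Extreme-behavior classification

**Cutoffs.** The "lowest 20%" of a finite cohort is only well defined if
the quantile is a data point, so cutoffs use the nearest-rank definition:
for tail fraction *q* and reference size *n*, the low-direction cutoff is
the ⌈qn⌉-th order statistic (mirrored for high). No interpolation is
performed. Ties at the cutoff are all flagged — the criterion is
*inclusion in the boundary*, and flagging a strict subset of tied animals
would make the label depend on row order.

**Reference population.** Cutoffs default to the full table passed in
(for the canonical design: all trauma-exposed animals pooled across
prenatal groups). An external reference cohort can be supplied when
cutoffs are to be carried over from a previous experiment.

**Missing data.** An animal missing a test has an undefined flag there;
by default animals with incomplete batteries are excluded from labeling
(`require_complete=True`). The alternative proportional rule
(S/n_observed ≥ k/m) is implemented but off, because it silently changes
the classifier's operating point. A `min_score_filter` (e.g. "score over
4" as a tissue-sampling inclusion criterion) is exposed but off by
default; we read "over 4" as score ≥ threshold on the 0–5 scale, and
since the original meaning is ambiguous the filter is opt-in.

## Contingency statistics

The Yates-corrected statistic clamps |O−E|−0.5 at zero, so tables with
identical proportions give exactly 0 rather than a spurious positive
value. φ is computed from the **uncorrected** statistic, √(χ²/N):
recomputation shows this convention reproduces published effect sizes
(0.223, 0.587) printed next to corrected test statistics, while
√(χ²_corrected/N) does not. The reported p is the two-sided upper-tail
chi-square probability; note that analysis environments sometimes print
one-sided p-values for directional 2×2 hypotheses, which are half of
ours.

## Rank tests

Kruskal–Wallis uses pooled midranks with the tie correction
C = 1 − Σ(t³−t)/(N³−N); all-identical input returns H = 0 with a warning
instead of dividing by zero. Per-group mean ranks are reported because
they are the quantities a reader compares across groups; their weighted
mean is (N+1)/2 identically, which the tests assert. Dunn's pairwise z
uses the same tie term, with Bonferroni adjustment over all pairs
("Dunn's corrected" is not further specified in common usage; Bonferroni
is the conservative reading). With two groups, z² equals the
tie-corrected H — used as a consistency test.

## ANOVA

**Two-way.** Type III sums of squares with effect (sum-to-zero) coding,
computed as drop-term increases in residual SS. Rationale: the target
designs are unbalanced 2×2 cells (n = 6–8) with the interaction reported
alongside main effects; Type I/II would confound main effects with cell
imbalance. Variance explained defaults to classical η² (SS/SS_total),
with partial η² behind a flag — published tables rarely state which was
used; classical η² is the choice here because the printed percentages
are discussed as shares of total variance. Post-hoc pairwise t-tests are
flagged at a Bonferroni-corrected α (default 0.05/4, the planned 4
comparisons of a 2×2 design).

**Split-plot three-way.** A 2×2 between-subject design with one repeated
within-subject factor (the gene panel). Between terms are computed from
per-subject means (exact, because each subject contributes the same
number of within-levels) and tested against the subject-within-cell
error; within terms are Type III drop-term SS on subject-centered data
against the subject × gene residual. No sphericity adjustment by default:
with 4 within-levels and 6–8 subjects per cell a Greenhouse–Geisser
estimate is itself very noisy; the decomposition is exact, and the
F-reference is the standard split-plot convention. Subjects missing a
within level are excluded with a warning (imputation would distort the
stratum errors).

## Normality-gated dispatch

Each sample gets Shapiro–Wilk at α = 0.05, plus Levene across samples.
Both normal and homoscedastic → Student's t; normal but heteroscedastic
→ Welch's t; any normality failure → Mann–Whitney U. The report records
the route, the gate p-values and sample sizes, so a reader can audit why
a given test was used. The gates themselves err at their nominal 5%
rate, which the tests account for by checking the dominant route across
seeds.

## Permutation of regressor residuals

For outcome y, covariates X and regressor of interest g: g is regressed
on X, its residuals are permuted and added back to the X-explained part,
and the partial F for g in y ~ X + g is recomputed per permutation.
Because the refit only involves the component of the permuted regressor
orthogonal to X, the statistic reduces to
F = (e_yᵀe_g)² / (‖e_g‖²) / (SSE_full/df), computed with one QR
factorization of X — 10⁴ permutations run in well under a second at
n ≈ 400. The p-value uses the add-one estimator
(1 + #{F* ≥ F}) / (1 + B), so the smallest attainable p is 1/(B+1) and
the estimator is never exactly zero. F is invariant to affine transforms
of y, which is asserted as a property.

## Molecular quantification

2^−ΔΔCt with technical replicates averaged on the Ct scale (the scale on
which replicate error is approximately additive). No
amplification-efficiency correction: no efficiencies are measured in the
target assays, and assuming 100% efficiency is the standard convention
in that case. Knockdown efficiency is reported under two normalizations
— housekeeping (HPRT: downregulation across the whole dissected tissue)
and viral reporter (GFP: downregulation per infected unit) — each as
fold vs the control-virus group mean. The infection rubric maps per-side
areas to scores 1–5 with half-open-up bins [0,5), [5,10), [10,25),
[25,50), [50,∞); the rubric's "<50 / >50" wording leaves exactly 50 mm²
undefined, assigned here to the higher score and documented.

## GRE scanning

A transparent IUPAC consensus matcher (default the GRE palindrome
RGNACANNNTGTNCY) with a mismatch budget, replacing proprietary
position-weight matrices — published "n sites found" counts from matrix
scanners are therefore *not* reproduction targets; the pipeline shape
(scan → CpG filter → TSS coordinates) is. An N in the sequence never
matches, whatever the pattern allows. Minus-strand matching tests the
reverse-complemented pattern against the plus strand; a palindromic
consensus consequently reports each locus on both strands, which is the
behavior of standard motif scanners. Coordinates are 1-based inclusive;
TSS-relative numbering is promoter-style (−1 immediately upstream, +1 at
the TSS, no zero).

## Synthetic cohorts: the stated world

**Behavioral cohort.** One latent susceptibility z ~ N(0,1) per animal,
shifted by `latent_effect` for prenatally stressed animals; metric j is
`sign_j · loading_j · z + ε_j`, ε_j ~ N(0, noise_sd²), mapped onto
plausible raw scales (affine, so percentile classification is
unaffected). The shared factor is a modeling choice forced by the data
structure: without cross-test correlation the classifier cannot exceed
its 5.79% independence null, and observed prevalences do. Defaults
(35/46 trauma cells; latent_effect = 0.75, noise_sd = 0.65, unit
loadings) were calibrated **once** by a Monte-Carlo sweep so the mean
classifier prevalences sit near the target 8.6% / 26.1%, then frozen;
the acceptance suite verifies recovery against exact binomial intervals.
No distributional information exists for the individual metrics, so
Gaussian noise is a convention, not a fit.

**Expression panel.** Gene × design-cell means (fold scale, calibrator
cell = 1) chosen to mirror the qualitative published pattern: GILZ
reduced additively by both exposures; FKBP51 up / GR and CRF down with
adult trauma mainly on the stressed background. Methylation is a
Gaussian copula against standardized GILZ expression (latent
= r·z + √(1−r²)·w) squashed through a logistic onto (0,100)% — betas
stay in range by construction and the mild squash attenuates the target
Pearson r only marginally (recovered within the Fisher-z interval at
n = 200).

**Knockdown experiment.** Per-side infection areas ~ lognormal (median
≈ 22 mm², spanning rubric scores 1–5); the PTSD-like score is
`intercept + slope · rubric_total + noise`, clipped to the 0–5 battery
range, with the control-virus group at a baseline. Intercept/baseline
defaults calibrated once to land near the 6/9 and 1/10 target
prevalences at the score ≥ 3 threshold.

**Human table.** ~25% male (105/316 shape), Poisson trauma-event counts,
log2-microarray-scale expression with a sex-specific trauma-load slope
(−0.15 per event in males, 0 in females), and CpG betas coupled to
standardized expression in males only through a clamped-logistic
construction. Covariates (age, ancestry, substance use, treatment) are
generated but carry only a token age effect.

**What a green test does not establish.** The generators emulate the
*statistical* structure (effect directions, prevalences, coupling
strengths, sample sizes), not mechanism: no fear-conditioning dynamics,
no corticosterone time-courses, no batch structure, no array
preprocessing. Calibration tests therefore validate the pipeline's
inference machinery, not any biological claim.

## Seeds and determinism

Every generator takes a seed; one global seed is split into fixed
per-stream sub-seeds (cohort / panel / knockdown / human), so adding a
new stream never changes existing draws. Identical seeds give
bitwise-identical tables; the pipeline writes the seed and a config hash
into every report bundle.

## Known limitations

- The split-plot ANOVA is specific to the 2×2-between × 1-within design;
  it is not a general mixed-model engine.
- Published quantities that depend on undeposited raw data (human
  correlation coefficients, CORT mean ranks with unprinted group sizes,
  exact variance-explained percentages) cannot be reproduced and are
  covered by property-based recovery tests on synthetic data instead.
- The GRE scanner's hit counts depend on the consensus and mismatch
  budget chosen; matrix-scanner site counts are not comparable.
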