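# Methods

`seroquant` implements the computational chain of a serum biomarker study
in non-small cell lung cancer (NSCLC): shotgun-proteomics discovery by
spectral counting, followed by orthogonal verification with tissue
microarrays (TMA), calibrated western blotting (WB) and stable-isotope-
dilution multiple-reaction-monitoring (SID-MRM) absolute quantification.
This note records the models, the defaults and why, the numerical
choices, and what the synthetic-data generators do and do not emulate.

## PSM filtering and protein inference (`seroquant.psm`)

**Model.** Every peptide-spectrum match (PSM) carries SEQUEST-style
scores: the cross-correlation Xcorr and the normalized score gap ΔCn.
Confidence filtering is a ΔCn floor of 0.1 (all charge states) plus a
per-charge Xcorr threshold. False-match rates are estimated by the
target-decoy strategy: spectra are searched against forward plus reversed
sequences, and the number of decoy hits passing a filter approximates the
number of false target hits, so FDR = decoys/targets among passers (not
the 2d/(t+d) variant — the estimate approximates false positives by the
decoy count directly).

**Threshold search.** Per charge state, candidate thresholds are the
observed Xcorr values; the smallest one whose within-charge FDR (after
the ΔCn floor) falls below the target, with at least one target passing,
is selected. The pooled FDR is a count-weighted mediant of the per-charge
ratios, so each charge meeting the target implies the joint filter does.
The search is finite, exact and reproducible. A candidate cut under which
no target passes is not considered "achieving" the target; if no valid cut
exists the dedicated `ThresholdNotAttainableError` is raised (distinct
from the empty-input error).

**Protein grouping.** Greedy parsimony: peptides are iteratively assigned
to the accession covering the most still-unassigned peptides (ties break
to the lexicographically first accession — deterministic). Accessions
with identical observed peptide sets merge into one group; accessions
whose peptides are a strict subset of a claimed set are absorbed and emit
no group. Each passing PSM is counted in the single group that claimed
its peptide, so PSM counts are conserved. A group is decoy iff every
accession carries the decoy marker (`REV_` by default). Protein-level FDR
is again decoys/targets over groups; it is generally several-fold larger
than the PSM-level FDR because correct PSMs concentrate in few groups
while false ones scatter into singletons.

**Not re-checked here:** enzyme specificity, mass tolerances and
modifications are properties of the upstream database search; the package
starts from the tabulated PSMs.

## Spectral-counting quantification (`seroquant.lfq`)

**Enrichment factor.** For protein *f* in sample *s*,
Re = (n_f/n) / (N_f/N), where n_f is the protein's PSM count in the
sample, n the sample total, N_f the protein's total over all samples and
N the grand total. Re is a depth-normalized share-of-shares: 1 means the
protein occupies the same fraction of the sample as it does globally.
The exact identity Σ_f (N_f/N)·Re[f,s] = 1 per sample is used as a
correctness invariant in the tests. Never-observed proteins are dropped;
zero cells give Re = 0.

**Permutation tests.** Differential screening uses permutation p-values:
sample labels are permuted jointly across all proteins (preserving the
between-protein correlation structure), the ANOVA F or pooled two-sample
t statistic is recomputed per permutation, and
p = (1 + #{|stat_perm| ≥ |stat_obs|}) / (n_perm + 1). The +1 correction
means p is never exactly zero; constant rows are defined as p = 1.
Significance filtering flags proteins with raw p < α (default 0.01) under
an OR rule over the supplied tests (configurable to AND), recording which
test fired. No multiple-testing correction is applied — deliberate for a
screening stage whose candidates proceed to orthogonal verification, and
a known caveat when interpreting flag counts.

**Normalization.** log2(count+1) per cell, then quantile normalization:
each column is forced onto the reference distribution of per-rank row
means. Ties receive the mean of the reference values spanned by their
average rank, so tied entries stay tied; the identical-sorted-columns
property consequently holds exactly only for tie-free columns.

**Clustering and PCA.** Hierarchical clustering of samples uses Euclidean
distance with average linkage by default (configurable); cutting at k = 2
gives the cancer/normal dichotomy check. PCA is a centered SVD returning
per-sample scores and per-protein loadings (the biplot arrows); component
signs are fixed by making the largest-magnitude loading of each component
positive, so results are deterministic.

**ROC and the panel.** AUC is the rank (Mann–Whitney) statistic with ties
counted one half — invariant under strictly increasing score transforms.
The confidence interval is the DeLong-type asymptotic normal interval
from placement-value variances. The biomarker panel is an unpenalized
(maximum-likelihood) logistic regression with all features entered as one
block; its in-sample predicted probabilities are scored by the same ROC
machinery. Perfect separation is detected geometrically (every case's
linear predictor above every control's) and flagged rather than raised:
the diverging MLE still orders samples, so the AUC remains meaningful.
scikit-learn's unpenalized solver is used because it returns a finite
iterate under separation.

## TMA and WB scoring (`seroquant.ihc`)

**Quick score.** The positive-cell percentage collapses to a P score of
0–9 over ten bins — [0,5), [5,15), …, [75,85), [85,100] — and Q = P × I
with intensity I ∈ {0,1,2,3}, so Q ∈ [0,27]. Bin edges are half-open on
the left with the top bin closed at 100; the interior decade pattern
between 35% and 85% follows the evident progression of the stated ranges.
Rater combination averages raw percentages and raw intensities *before*
binning and multiplying (least information lost; per-rater Q averaging is
available via `method="average_q"`). Averaged intensity may be
fractional, so Q may be non-integer; the 0–27 bound still holds.

**Paired comparison.** Tumor minus adjacent-normal Q differences are
tested with the Wilcoxon signed-rank test (one-sided, "tumor higher", by
default; paired t test via config). Cases missing either section are
dropped; all-zero differences return p = 1 by contract.

**WB calibration.** Each membrane must carry exactly one lane of the
pooled calibration sample; dividing every lane's IOD by that lane cancels
per-membrane multiplicative batch factors exactly (an algebraic identity,
tested as such), after which groups are compared by a two-sample t test.

## SID-MRM absolute quantification (`seroquant.mrm`)

**Calibration.** Light/heavy area ratios from a base-3 dilution series
are averaged per point and fitted by ordinary least squares in
log3–log3 space — the space in which the assay is designed and plotted;
a linear-space fit is a config alternative. Pearson R of that fit is the
linearity measure. The anchor point (observed ratio closest to 1) marks
where the endogenous amount equals the heavy spike; downstream conversion
uses the full fitted line, not the single anchor point.

**LOQ / LOD.** Scanning dilution points from the lowest concentration
upward, the LOQ is the first point with replicate CV < 20% whose
restricted fit (that point and above, minimum three points) keeps
R > 0.99; if no point qualifies the assay is reported not quantifiable
(`None`). The LOD is the concentration at which the interpolated
signal-to-noise equals 3, interpolating log-log (S/N proportional to
concentration between measured points; pure proportional extrapolation
below the measured range). Inter-assay CV is 100·sd/mean with sd at
ddof = 1. The best transition per peptide is the one with highest
Pearson R, ties broken by lower LOQ then higher mean heavy area.

**Concentration conversion.** The fitted line is inverted to a nominal
ratio, multiplied by the heavy spike for fmol on column, then scaled:
µg/mL = fmol × M(g/mol) × 10⁻⁶ / V(µL), with V = 0.1 µL serum-equivalent
on column by default and molar masses 54,254 g/mol (A1BG) and
38,178 g/mol (LRG1) as config inputs. Ratios outside the calibrated
observed range are converted but flagged as extrapolated. Non-specific
isotope incorporation is treated as negligible; co-elution QC is an input
flag (`qc_pass`), not a computation — peak integration is upstream of
this package.

**Cohort statistics.** Per protein: two-sample t test cancer vs control
and ROC with DeLong CI; jointly: the logistic panel. Binary demographics
are tested by two-sample t tests on concentration, numeric ones (age) by
Pearson correlation. One best transition per protein is fixed for the
whole cohort rather than chosen per sample.

## Synthetic cohorts (`seroquant.simulate`)

The generators define the study conditions every test runs under.

* **Counts.** 647 proteins, cohorts N = 5 / AD = 8 / SCC = 5, base
  abundances log-uniform over six decades, ~35,000 PSMs per sample
  (≈629,804/18), 101/647 of proteins truly shifted. Counts are
  negative-binomial (gamma–Poisson) because spectral counts are
  overdispersed; dispersion 0.1 and a default two-fold shift
  (`log2_fold = 1`, half up, half down) are the generator's own choices —
  no generative model is implied by spectral counting itself. Sample
  depths get 10% lognormal jitter so depth normalization is actually
  exercised.
* **PSMs.** Gaussian Xcorr mixtures per population per charge (correct
  2+: 3.4 ± 0.5, 3+: 4.2 ± 0.7; incorrect/decoy 2+: 1.6 ± 0.45,
  3+: 2.0 ± 0.55) and Gaussian ΔCn (0.28 ± 0.09 vs 0.06 ± 0.04, clipped
  to [0,1]) place the accepted-score landscape in high-confidence
  SEQUEST territory. Decoys mirror the incorrect-target population in
  *distribution and count*: `n_decoys` defaults to
  round((1−frac_correct)·n_targets), since an unmatchable spectrum hits
  the forward and reverse database halves with equal chance — the regime
  in which the decoy estimator is unbiased. Incorrect and decoy matches
  draw accessions from a 50,000-protein database space, so false hits
  rarely land on the 300 truly present proteins and instead form their
  own (mostly singleton) groups, as in a real composite search.
* **MRM.** The dilution series anchors the light amount at the heavy
  spike mid-series and spans base^(n_points−1) (3⁷ over 8 points). Noise
  is multiplicative lognormal, mean-one, independent between light and
  heavy channels, parameterized by the exact coefficient of variation;
  replicate CV 5% and 5 replicates per point by default. A designed LOQ
  knee inflates the lowest points' CV (40% default). For planted-knee
  recovery simulations, 10 replicates per point are used: a design-stage
  power analysis of the sample-CV rule showed that with fewer replicates
  the CV estimate of a 40%-CV point dips below 20% too often for the
  knee to be reliably identifiable (≈70% recovery at 3 replicates vs
  ≈96% at 10). Cohort ratios apply the group fold on top of 35%
  lognormal biological spread — a typical inter-individual CV for
  moderate-abundance serum glycoproteins.
* **TMA.** 89 valid pairs scored by 2 raters; tumor percentages
  70 ± 20%, normal 25 ± 15% (truncated to [0,100]); tumor intensity mass
  concentrated on 2–3, normal on 0–1 — most tumor sections end up with
  I ≥ 2 and P above 60%, matching the verification cohort's described
  staining pattern.

**What the generators do not emulate:** raw spectra, chromatograms and
retention behavior; the chemistry of depletion/digestion/staining;
correlated protein co-regulation (proteins are independent given their
cohort means); inter-rater systematic bias (raters are independent
draws); and real serum's heavy-tailed contaminant structure. Passing
tests therefore demonstrate correctness of the statistical machinery and
recoverability of planted effects under realistic noise — not
performance on any particular clinical cohort.

## Problem sizes and determinism

Simulation-based tests use study-scale cohorts (600+ proteins, 18
samples, 10,000 permutations; 10,000-target PSM tables; 200-run LOQ and
ROC sweeps; 25-run cohort-fold averages) — sizes at which Monte-Carlo
error is comfortably inside the asserted tolerances while the full suite
runs in well under a minute of compute per module. Every stochastic
component takes an explicit seed; there is no global random state, and a
fixed seed reproduces outputs bit for bit.

## Known limitations

* The raw p < 0.01 screen is intentionally uncorrected; flag counts on
  null data are calibrated (tested) but individual flags are screening
  candidates only.
* The naive protein-level decoy count is a conservative, not exact,
  estimator of false protein groups, and its accuracy degrades if the
  decoy count is far from the incorrect-target count.
* The LOQ rule depends on the replicate-CV estimate, which is noisy at
  small replicate numbers; LOQ estimates from triplicate series should be
  treated as indicative.
* Panel AUCs are in-sample; no cross-validation is performed, matching
  the verification-phase usage, so they are optimistic for new cohorts.
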