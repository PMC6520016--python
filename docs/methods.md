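# Methods

## Model

The package implements an event-based model (EBM) of disease
progression. Each biomarker in a panel of N markers has a binary
abnormality event; a subject's latent stage k ∈ {0..N} means the first k
events of a common ordering S have occurred. Measurements are
conditionally independent given the event indicators, with Gaussian
event and non-event densities per biomarker. The subject likelihood
marginalizes the unknown stage under a uniform prior over 0..N; missing
measurements contribute a factor of 1 to every stage term, which is the
exact marginalization under conditional independence. The uniform stage
prior is the standard EBM choice; it also makes the stage posterior
proportional to the stage likelihood, so the maximum-likelihood stage
(the CARE index) and the posterior-mean stage coincide with their
prior-free definitions.

Two per-subject scores are reported. The **ML stage** (CARE index) is
the argmax of the stage posterior, with ties broken toward the lower
stage (conservative: fewer events claimed). The **expected stage** is
the posterior mean — a continuous score in [0, N]. ROC analysis uses the
expected stage, because a useful classification cutoff generally falls
between integer stages; the ML stage is what stage-histogram figures
tabulate.

## Event-model fitting

Each biomarker's mixture is fitted by EM on the pooled non-missing
values of all subjects (no healthy-control or AD anchors are assumed;
the cohorts this design targets contain only MCI subjects). Unconstrained
two-Gaussian ML on such data is badly behaved: likelihood spikes
(a component collapsing onto a few points) and bulk-splitting solutions
(two nearly identical components sharing the majority mode) often beat
the intended fit. Three constraints make the fit identifiable:

* **Shared component scale** (default): both components use one σ.
  Heteroscedastic fitting is available (`equal_scales=False`) but is not
  the default, since the scale difference is rarely identifiable at
  cohort sizes of 50–200 and the shared-scale model eliminates the
  spike solutions entirely.
* **Mean box**: component means are clipped to the 1st–99th percentile
  range of the data (the constrained M-step maximizer of the quadratic
  Q-function is exactly the clipped weighted mean), so an idle component
  cannot latch onto a single outlier.
* **Variance floor**: σ ≥ 0.1 × sample sd (`variance_floor_frac=1e-2`
  on the variance scale).

The direction constraint — the event mean lies on the biomarker's
declared abnormal side — is enforced by component relabeling at each
M-step. EM runs from a deterministic grid of 15 initializations
(component means at the 5/50, 10/60, 25/75, 40/90 and 50/95 percentile
pairs × starting weights 0.2/0.5/0.8); the run with the best final
log-likelihood wins. Convergence: log-likelihood gain < 1e-6, at most
500 iterations. Fitting is a deterministic function of the data.
Biomarkers with fewer than 10 observed values raise an error naming the
biomarker; identical values raise a degenerate-scale error.

## Sequence estimation

`sequence_loglik` evaluates the data log-likelihood of an ordering with
log-sum-exp stabilization and prefix-sum vectorization.
`find_optimal_sequence` performs multi-start steepest-ascent over a
neighborhood of all pairwise swaps plus all single-element insertions
(ties broken toward the first-encountered move in a fixed enumeration
order); the first start is the panel order, the rest are random
permutations under the given seed. An optional Metropolis sampler over
permutations (random transpositions, accepted at the data-likelihood
ratio) summarizes positional uncertainty as an event-by-position
frequency matrix; it is diagnostic only and never defines the reported
optimum.

`fit_progression_model` is the canonical fitting path and addresses a
failure mode that per-biomarker marginal fits cannot: when an event has
occurred in almost all subjects (or almost none), the marginal mixture
cannot locate its minority component, and the ordering inherits the
error. The procedure alternates a stage-informed EM with ordering
search: the stage posteriors under the current model give each subject a
soft event indicator per biomarker (P(stage ≥ position)), the densities
are re-estimated from those responsibilities — borrowing strength across
biomarkers — and a greedy ascent updates the ordering. Because this
joint EM has basins of its own, it is restarted from a diversified set
of orderings (the best marginal-fit ordering, plus that ordering with
each single event relocated to the opposite end — the targeted escape
from a single-misplaced-event basin), and the candidate with the highest
joint likelihood wins. Four refinement iterations per start are enough
in practice; the procedure is deterministic given seed and data.

## Classification and transfer

A positive call is score ≥ threshold throughout (converters score
high). ROC candidate thresholds are the midpoints between consecutive
distinct scores plus sentinels outside the score range; the AUC is the
trapezoidal area, which equals the Mann–Whitney concordance probability
with ties counted half. The optimal threshold maximizes Youden's
J = sensitivity + specificity − 1, with ties broken toward higher
specificity and then lower threshold; the criterion is configurable in
the sense that any fixed threshold can be supplied instead
(`transfer_threshold`), which is also how a discovery-cohort cutoff is
applied unchanged to a validation cohort. 2×2 intervals: Woolf log
method for the odds ratio, Katz log method for the relative risk, both
at 1.96 standard errors; a zero cell triggers the Haldane 0.5 correction
for the ratio estimates (flagged on the result). Correlated AUCs are
compared with DeLong's structural-components test; degenerate zero
variance (identical or rank-equivalent scores) reports z = 0, p = 1
rather than a division error.

When two cohorts carry different biomarker subsets, both are restricted
to the shared panel before any fitting, sequence search, or staging, so
stages are commensurable across cohorts. The stage scale then runs 0..7
rather than 0..10 when three biomarkers are absent from one cohort;
thresholds are learned and transferred on that shared scale.

## Group statistics

Two-sample t-tests use an automatic equal-variance gate: Levene's test
(mean-centered) at α = 0.05 selects the pooled-variance t when
non-significant and Welch otherwise — the convention of mainstream
point-and-click statistics software, and the only rule under which a
published mixed table of pooled and Welch statistics reproduces. From
summary statistics (mean, sd, n) the gate cannot run and the caller
must name the rule. The 2×2 chi-square is Pearson without continuity
correction. Mann–Whitney U uses exact enumeration for untied samples of
≤ 8 per group and the tie-corrected normal approximation (no continuity
correction) otherwise; fully tied data reports p = 1. Change-score
regressions fit one OLS model per outcome (Δoutcome ~ ΔCARE +
covariates) with Benjamini–Hochberg correction across outcomes; the
covariate set defaults to whatever the caller supplies (age, sex,
education being the conventional choice), and a rank-deficient design
raises an error naming the collinear columns.

## Synthetic cohorts

The generator draws each subject's latent stage from a categorical
distribution, then draws biomarkers at sequence positions ≤ stage from
their event densities and the rest from non-event densities. Converter
labels follow a stage-threshold rule (stage ≥ τ), optionally with label
noise — encoding the model's premise that the stage tracks proximity to
conversion, which makes prediction-performance recovery well-posed.

Defaults emulate the shape of the two-cohort MCI study this pipeline
targets: a discovery cohort of 46 and a validation cohort of 56
subjects; a ten-biomarker panel with the field-established ordering as
generative truth; non-event locations 0, event locations ±2 (units of
the common within-component sd — a strong, well-studied-biomarker
separation); stage distribution uniform within {0..6} and within
{7..10} with P(stage ≥ 7) = 0.27, matching the ~26–29% three-year
conversion rates of the two cohorts at τ = 7; no label noise; the CSF
assays and ADAS-Cog deleted entirely from the validation cohort; and a
−0.3 location shift on the validation cohort's MMSE and AVLT as a
between-cohort nuisance. An optional follow-up wave advances each stage
by a Poisson(1) increment (capped at N) and re-draws the biomarkers, for
change-score analyses.

What the synthetic experiments show: that the implementation recovers a
known generating ordering (Kendall τ ≥ 0.9 in ≥ 95% of replicates at
n = 200), that staging matches brute-force enumeration, and that the
end-to-end threshold transfer loses only a few points of sensitivity and
specificity relative to an oracle given the true densities and ordering
at the study's own sample sizes. What they do not show: robustness to
model misspecification — real biomarkers are not Gaussian, not
conditionally independent given stage, and real conversion is not a
deterministic function of an event count. Results on real cohorts
depend on those violations, not just on estimation noise.

## Numerical choices and edge cases

* Stage likelihoods and orderings are computed with log-sum-exp; a
  subject with every biomarker missing has likelihood exactly 1
  (flagged `uninformative`, uniform posterior, ML stage 0 by the tie
  rule).
* Greedy ascent accepts a move only on strict improvement (> 1e-12), so
  its log-likelihood trajectory is non-decreasing and termination is
  guaranteed.
* EM per-iteration log-likelihoods are non-decreasing (constrained
  M-steps are exact coordinate maximizers).
* Sequence-search candidate evaluation is batched (all neighbors per
  ascent step in one vectorized pass).
* Cohort CSVs round-trip bit-exactly: missing cells are written as
  ``NA`` and floats at full precision.

## Known limitations

* Event densities are Gaussian only; no kernel or covariate-adjusted
  densities.
* One ordering for the whole cohort: no progression subtypes.
* MCMC positional frequencies quantify uncertainty of event positions
  but are not propagated into staging or thresholds.
* The conversion threshold is a point estimate; no bootstrap or MCMC
  interval on it.
* With ~12–16 converters per cohort, all diagnostic metrics have wide
  sampling variability; the synthetic experiments average 20 replicates
  for that reason.
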