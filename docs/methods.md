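# Methods

## The clinical problem and the rule under study

Blood cultures, the diagnostic gold standard for neonatal late-onset
sepsis (LOS), often need 48–72 h to flag growth, so infants worked up for
suspected sepsis usually receive empiric antibiotics for two to three
days.  The analysis implemented here evaluates a rule-out strategy at the
24-hour mark: an infant may stop antibiotics at 24 h if, and only if, the
blood culture has not turned positive within 24 h, the infant does not
appear sick on a blinded 3-level clinical grading, CRP never exceeded
0.75 mg/dl, and the neutrophil-to-lymphocyte ratio (NLR) never exceeded
1.5 within the work-up window.  The rule is a fixed three-node classifier
(see `neolos.rule`); its three nodes double as an ordinal risk score for
ROC analysis (culture-or-sick > elevated labs > all-clear).

## Marker derivation

All thresholds are strict inequalities in the stated direction; a value
exactly at a cutoff is normal.  Markers are three-valued
(true/false/missing): a lab that was not drawn yields a missing marker,
and the discontinuation rule treats a missing CRP or NLR as elevated —
an infant cannot be shown low-risk by an absent test.  "Sick appearance"
is the worst grade across the two assessments (work-up and 24 h)
dichotomised sick vs (healthy, equivocal).  Whether the original rule
used the 24-h grade alone or the worst grade is not documented; the
worst-in-window choice is the conservative reading and is noted here as
a design decision, not an established fact.  An NLR with a zero
lymphocyte count is undefined as a ratio and is represented by an
infinite sentinel, i.e. always "elevated".

## Statistics

* **Odds ratios** are 2×2 cross-products with Woolf (logit) 95%
  intervals, `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`.  With any zero cell
  the Haldane–Anscombe correction adds 0.5 to all four cells before both
  the estimate and the interval; this choice exactly reproduces the
  published corrected ORs (212.5, 197.4), which is why it is the
  default.  Exact and mid-p intervals are out of scope.
* **Univariate logistic screening** fits each marker alone by
  maximum-likelihood (statsmodels Newton/IRLS).  For a binary exposure
  with four positive cells, the MLE equals the cross-product OR and the
  Wald interval equals the Woolf interval — asserted as a property test
  rather than assumed.  Separation (any zero cell) is detected up front
  and reported as the Haldane-corrected 2×2 OR, flagged, matching how the
  published table handled its two perfectly sensitive markers.  Markers
  with p < 0.2 (strict) become tree candidates.  The 3-level appearance
  score is screened as a factor with "healthy" as reference.
* **Diagnostic metrics** are reported as percentages rounded to one
  decimal, half away from zero.  PPV/NPV are flagged undefined on an
  empty denominator rather than forced to a number.
* **AUC** for binary and ordinal predictors is the Mann–Whitney
  probability that a random case outranks a random control, ties counted
  one half; for a binary test this is (se+sp)/2.  The Hanley–McNeil
  standard error is provided, but the published AUC confidence intervals
  were produced by an unstated method and are deliberately not
  reproduced.
* **Chi-square vs Fisher**: Pearson chi-square without continuity
  correction when every expected cell is at least 5, otherwise Fisher's
  exact test (a common convention; the source analysis said only "as
  appropriate").

## CHAID induction

The tree grower is written from scratch (`neolos.chaid`).  Per node and
per candidate predictor, observed categories are iteratively re-merged:
the pair of groups with the largest pairwise chi-square/Fisher p above
`alpha_merge` merges, ties breaking lexicographically so growth is
invariant to row order.  The merged split's raw p (chi-square/Fisher for
two groups, Pearson chi-square for more) is multiplied by the Kass
partition count — the number of ways to collapse *c* observed categories
into the *r* merged groups, a Stirling number of the second kind — and,
when `bonferroni` is on, additionally by the number of candidate
predictors examined at the node.  The extra factor departs from classic
CHAID, which corrects only within predictor: with ~10 candidates at
alpha 0.05 the classic procedure splits a null node about a third of the
time, whereas the family-wise correction keeps the null split rate below
`alpha_split` (verified by a 200-replicate permutation test).  With
well-separated data the factor is irrelevant — adjusted p-values in the
planted-structure experiments are smaller than 10⁻²⁰.

Defaults: `alpha_merge = alpha_split = 0.05`, `min_parent = 20`,
`min_child = 7`, `max_depth = 3`.  None of these are documented for the
original SPSS analysis; they are sized to be reachable on a cohort of a
hundred infants and are all exposed as estimator parameters.  Missing
values form their own floating category, free to merge with any group.
All predictors are treated as nominal (every candidate here is binary or
3-level).  The claim tested against the original analysis is
structure-level recovery on well-separated data, not bit-for-bit SPSS
equivalence.

Because grouping blood-culture status with sick appearance at the top of
the tree was a clinical safety decision rather than a data-driven split,
the estimator accepts `forced_root="culture_positive_24h OR
sick_appearing"`: a composite predictor applied unconditionally at depth
0 (missing components route to the cannot-rule-out side).

## Synthetic cohorts

No patient-level data were ever deposited, so the generator
(`neolos.simulate`) emulates the published case-control structure with
fixed margins: by default n = 105 with 33 cases / 72 controls
(development) and n = 60 with 20 / 40 (validation, same calibration,
independent seed stream, no drift model).  Calibration targets are the
published per-group frequencies and medians:

* every binary marker's per-group exceedance equals the printed count
  ratio (e.g. P(CRP > 0.75 | sepsis) = 30/33);
* CRP and NLR are log-normal with the printed group medians (7.0 and
  0.01 mg/dl; 6.0 and 0.7), with scale solved from the exceedance target
  rather than the printed IQRs — a two-parameter log-normal cannot match
  median, IQR and exceedance simultaneously, and the sepsis NLR IQR is
  visibly garbled in print.  The control CRP is a mixture of a 25% point
  mass at the assay floor (its printed lower quartile is 0.0) and a
  log-normal tail.  The sepsis NLR, printed as exceeding 1.5 in 33 of 33
  infants, is a log-normal conditioned above 1.5 (scale 0.5, so the
  unconditioned exceedance is already above 0.995);
* time to positivity is log-normal with median 25.9 h and scale fitted
  to the printed quartiles 18.7–37.3 h, giving P(TTP ≤ 24 h) ≈ 0.44;
  sepsis cases are always culture-positive, controls never;
* the worst-in-window appearance grade follows the printed per-group
  3-level multinomials; the work-up-time grade is drawn no sicker than
  the worst;
* demographics (corrected GA, birthweight) are truncated normals at the
  printed group means/SDs; line and nutrition status follow the printed
  frequencies.

Dependence between markers is a Gaussian copula with one shared
standard-normal severity factor; `latent_correlation` (default 0.3, a
moderate within-group dependence chosen once as clinically plausible) is
the pairwise channel correlation.  The CRP and NLR channels additionally
share a pair-specific factor whose loading is solved (bivariate-normal
orthant inversion) so that the *union* frequency P(CRP-high or NLR-high |
control) equals the printed 18/72 — the printed union row implies much
stronger CRP–NLR dependence (P(both) = 0.125) than the shared factor
alone provides (0.033 under independence).

Continuous labs are produced by pushing each channel's uniform through an
inverse CDF whose exceedance quantile sits exactly at the clinical
cutoff, so re-deriving markers from the stored raw values reproduces the
intended draw; empirical per-group frequencies converge to the configured
probabilities (verified within 0.01 at n = 50,000).  Raw CBC and vitals
are drawn uniformly inside or outside their normal ranges according to
the intended flag.  An impossible target (e.g. a median below the cutoff
with majority exceedance, or a union frequency violating the Fréchet
bounds) raises an explicit `CalibrationError`.

**What the generator does not emulate** — and therefore what passing
tests do not establish about real data: longitudinal trajectories within
the window (only summaries are drawn), organism identity, real lab
distribution shapes beyond median-plus-exceedance, informative
missingness (synthetic records are complete), and any temporal drift
between development and validation periods.  Recovery of the planted
tree structure shows the inducer works, not that the clinical rule is
correct.

## Known print/count inconsistencies

Four published cells disagree with the published counts and are asserted
*as discrepant* by the reproduction ledger (`neolos.evaluation`), never
reconciled: the thrombocytopenia OR (printed 17.8; counts give 18.06),
the tachycardia row (61/72 is 84.7%, not 87.1%, and the counts give OR
0.81, not 0.7, with a garbled interval), the development
abnormal-neutrophil specificity (43/72 = 59.7, printed 59.2), and the
validation decision-tree PPV (20/39 = 51.3, printed 52.3).  Two further
cells are flagged: the development "CRP or NLR" AUC (printed 0.86, but
the binary identity (se+sp)/2 with the printed 100/75.0 gives 0.875 →
0.88) and the validation sick-appearance specificity/NPV (85.4% is not
attainable with 40 controls under any integer count).  The validation
decision-tree AUC (0.92) has no recoverable node-level counts and is
marked not-recomputable.

## Problem sizes

The simulation-backed checks use the sizes the package treats as its
standard experiment grid: marginal calibration at n = 50,000; structure
recovery on 20 cohorts of n = 5,000; the null-split rate on 200
permutations of an n = 200 cohort; time-to-positivity quantiles on 10⁵
draws.  The default end-to-end pipeline runs at the study's own sizes
(105 + 60).
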