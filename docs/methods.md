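# Methods

This package re-implements, as a tested pipeline, a longitudinal trajectory
analysis of early antipsychotic response in schizophrenia: patients rated
with the Positive and Negative Syndrome Scale (PANSS) at baseline and weeks
2, 4, 6 are clustered on their percent-reduction trajectories, and the
resulting grouping is compared with the conventional dichotomous responder
rule (≥50% reduction at week 6). Because the motivating trial's raw data are
not publicly available, a synthetic cohort generator stands in for them; all
cohort-level numbers the pipeline produces are therefore recovery results on
simulated data, while the published group counts are handled as exact inputs
to the comparison statistics.

## Corrected percent reduction

The PANSS total score is bounded below by 30 (every one of the 30 items
scores at least 1), so the percent change is computed against the attainable
range rather than the raw score:

    r_w = 100 · (baseline − score_w) / (baseline − 30).

With this correction r = 100% means complete remission (score 30), not an
impossible score of 0. Subscale reductions omit the floor correction and use
the plain baseline denominator, because subscale baselines can sit at their
floor: `percent_change_subscale = 100 · (baseline − value)/baseline`. A
baseline total of exactly 30 makes the denominator zero; such records are
rejected with a logged warning (trial inclusion implies active symptoms, so
this is a data error, not a valid patient). The two formulas coincide under
a change of origin — shifting both scores down by 30 and applying the
subscale formula reproduces the corrected total formula — which the suite
exploits as a property test.

## Synthetic cohort generator

The generator emulates the study conditions of a seven-arm randomised trial:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 3010 | patients entering analysis |
| `arm_weights` | 1:1:1:1:1:½:½ | risperidone, olanzapine, quetiapine, aripiprazole, ziprasidone, perphenazine, haloperidol |
| `class_proportions` | 0.489 / 0.511 | latent high / low response classes |
| `class_mean_curves` | 35.84, 60.51, 73.58 and 15.16, 28.10, 31.99 | mean % reduction at weeks 2/4/6 |
| `within_class_sd` | 8.0 points | per-visit Gaussian noise on the reduction rate |
| `baseline_total_mean/sd` | 90 / 15 | baseline PANSS total, rounded, clipped to [60, 150] |
| `dropout_rate` | 0.1262 | probability of monotone attrition |
| `missing_rate` | 0.02 | per-cell MCAR missingness at follow-up |
| `first_episode_prop` | 0.55 | probability the episode is the patient's first |

Follow-up totals are generated by *inverting* the corrected percent-change
formula (`score_w = baseline − r_w/100 · (baseline − 30)`, rounded to an
integer and clipped to [30, 210]), so the configured class curves are exact
in reduction-rate space — the space the clustering operates in — up to
integer rounding. The class curves, class split, arm ratio and dropout rate
are fixed study conditions; the remaining defaults are one-time choices of
realistic values for an acutely ill trial population: a mean baseline total
of 90 (moderate-to-marked illness) with SD 15 clipped away from the scale
floor, 8-point reduction-rate noise (which makes the two classes overlap
near the 50% boundary at week 6, as real cohorts do), 2% incidental visit
missingness on top of attrition, and a slight majority of first-episode
patients.

Subscale scores (positive 7–49, negative 7–49, general 16–112) are
apportioned from the total by a per-patient proportional profile (around
0.26/0.25/0.49, jittered) with largest-remainder rounding and bound-aware
redistribution, so `total = positive + negative + general` holds row by row.
Dropout is monotone — a cut visit is chosen uniformly among weeks 2/4/6 and
everything from it onward is missing — while cell-level missingness is
independent MCAR. The generator does **not** model the outcome-dependent
(MNAR) attrition real trials show (dropouts tending to be younger, drug
naive, with milder symptoms), nor titration dynamics, site effects or side
effects; passing recovery tests therefore demonstrate correctness of the
machinery under MCAR conditions, not robustness to informative dropout.
Latent class labels are written to a separate file that the analysis stages
never read; only recovery checks consult it.

## Preprocessing order

The pipeline winsorizes, then imputes, then computes percent change.

* **Winsorization** uses the Tukey rule per visit column across patients:
  values beyond quartile ± 1.5·IQR are replaced by the 0.01/0.99 quantiles
  of that column's original values. Quantiles follow the linear-interpolation
  convention (numpy/R type 7) and the convention is a configuration option,
  because the replacement values depend on it. Winsorization targets raw
  scores rather than reduction rates: an out-of-range *score* is the
  plausible measurement artifact. Re-applying the operation with the fences
  and replacement values stored from the first pass is the identity;
  re-deriving fences from winsorized data is not, which is why the audit log
  records the original fences.
* **Imputation** is chained-equation with predictive mean matching, written
  in-package: each incomplete visit column is regressed (OLS with intercept)
  on the other columns, and each missing cell takes the observed value of a
  donor drawn uniformly from the 5 rows with the nearest predicted values;
  20 cycles over the columns, 5 completed datasets by default. Imputed
  values are always observed values of the same column, observed cells are
  never altered, and baselines are never imputed. Downstream stages consume
  the first completed dataset (single-dataset mode); all datasets are
  returned so the pipeline can be repeated per imputation, but no pooled
  (Rubin's rules) inference is attempted.

## Clustering

The clustering engine is a from-scratch Lloyd's algorithm on the 3-vector of
percent reductions at weeks 2/4/6 (week 0 is identically zero and carries no
information). Distance is plain Euclidean — all dimensions share units of
percent, so no standardisation is applied. Each restart begins from a
uniform random assignment of patients to clusters (with one anchor patient
per cluster so every cluster starts non-empty), alternates centroid update
and nearest-centroid reassignment until the assignment vector is a fixed
point (hard cap 200 iterations; the objective is non-increasing, so
termination is guaranteed), and an emptied cluster is re-seeded with the
point farthest from its own centroid. Twenty restarts per k; the smallest
within-cluster sum of squares wins, ties going to the earlier restart.

Model selection scans k = 2..6 and maximises the Calinski–Harabasz index

    CH = [tr(B)/(k−1)] / [tr(W)/(n−k)],

the ratio of between- to within-cluster scatter, each normalised by its
degrees of freedom. CH is invariant to rescaling all trajectories, and a
partition with zero within-scatter is reported as +∞ with a warning (it is
trivially optimal). Ties in CH break toward smaller k. For k = 2 the cluster
with the larger final-week centroid is labelled `high`, the other `low`;
larger k ranks clusters by final-week centroid (`cluster_1` lowest), with
exact ties broken by the earlier weeks in reverse order.

## Comparison of the two responder definitions

A patient is a threshold responder when the week-6 corrected reduction
reaches 50%. The boundary is counted as response by default; both the cutoff
and the strictness are configurable and recorded in the output, since
published usage alternates between "at least 50%" and ">50%".

Two cross-tabulations are produced: the paired 2×2 (trajectory × responder
status, grand total n) whose off-diagonal is the discordance count, and the
composition table (method × good/poor response, grand total 2n) comparing
the two classifications' margins as if independent samples. The composition
chi-squared uses the 2n construction because that is the construction under
which the published counts (1471/1539 vs 1726/1284) reproduce the published
statistic of 43.37; the statistically conventional paired test — McNemar on
the discordant cells — is computed alongside under its own name.

Per-arm breakdowns build 7×2 tables by trajectory and by threshold, test
each with a Pearson chi-squared omnibus (no continuity correction), and run
all 21 pairwise 2×2 Fisher exact tests (on the threshold table by default)
with Benjamini–Hochberg FDR adjustment. When any expected count falls below
5 the omnibus falls back to Fisher's exact test (2×2) or to a seeded
Monte-Carlo permutation test conditioning on the margins (r×c, 10 000
permutations, chi-squared discrepancy) — with the default cohort sizes all
expected counts are large and the chi-squared path is taken. The
episode-status analysis tests first-episode vs relapse against trajectory
membership separately within the typical (perphenazine, haloperidol) and
atypical strata.

Standard statistical steps go through the standard libraries
(`scipy.stats.chi2_contingency`, `scipy.stats.fisher_exact`, statsmodels'
`multipletests`); the test suite checks each against an independent oracle
(explicit scatter formula, full hypergeometric enumeration over the margin
class, direct step-up arithmetic). The BH adjustment is *not* idempotent in
general — re-adjusting an adjusted vector can change it — though tied
adjusted blocks such as (0.03, 0.03, 0.03) are fixed points; the suite tests
the properties that do hold (dominance over raw values, order invariance,
agreement with the step-up arithmetic).

## Determinism and problem sizes

Every random procedure derives its stream from the run's master seed via
`numpy.random.SeedSequence` (stage tags hashed with CRC-32 so derivation is
process-independent), and no artifact embeds a timestamp, so two `run-all`
executions from one config are byte-identical. The default analysis runs the
full 3010-patient cohort end-to-end in a few seconds. The test suite uses
smaller cohorts (150–600 patients) for unit tests and the full recovery
study at n = 500 × 100 seeds for model-selection validation; these sizes
give the binomial/multinomial checks 4-SD headroom while keeping the suite
quick to iterate on.

## Known limitations

* MCAR missingness only; informative dropout is documented but not modelled.
* Single-dataset imputation mode by default; between-imputation variance is
  available but not pooled into test statistics.
* The exact r×c Fisher test is approximated by a seeded conditional
  Monte-Carlo permutation test; only the 2×2 case is fully exact.
* Subscale trajectories are generated proportionally to the total, so
  subscale-specific response shapes (e.g. negative symptoms responding more
  slowly) are not emulated, and the clustering analysis here uses the total
  score only.
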