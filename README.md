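# panss-traj

Longitudinal trajectory analysis of early antipsychotic response in
schizophrenia. Patients rated with the Positive and Negative Syndrome Scale
(PANSS) at baseline and weeks 2, 4 and 6 are clustered on their corrected
percent-reduction trajectories

    r_w = 100 · (baseline − score_w) / (baseline − 30)

(the subtraction of 30 removes the scale floor, so 100% means complete
remission) using from-scratch k-means for longitudinal data: k = 2..6
clusters, 20 random-assignment restarts each, best model chosen by the
Calinski–Harabasz index CH = [tr(B)/(k−1)]/[tr(W)/(n−k)]. The resulting
high/low trajectory grouping is then compared with the conventional
dichotomous responder rule (≥50% reduction at week 6): paired discordance,
composition-ratio chi-squared, per-drug breakdowns with FDR-adjusted
pairwise Fisher tests, and first-episode/relapse splits.

The package is aimed at clinical-trial statisticians and psychiatry
researchers who want a reproducible, fully tested reference implementation
of this analysis. Because the motivating trial's patient-level data are not
public, a synthetic cohort generator (seven arms randomised 1:1:1:1:1:½:½,
two latent response classes with configurable mean reduction curves,
monotone dropout, MCAR cell missingness) drives every stage; the published
group counts are used directly where they suffice (composition statistics,
discordance bookkeeping).

## Worked example

```
panss-traj run-all --outdir results/main --seed 1
panss-traj report --outdir results/main
```

or equivalently the numbered drivers `python analysis/01_simulate_cohort.py`
… `05_published_count_checks.py`. On the default configuration (3010
patients, class curves 35.84/60.51/73.58 and 15.16/28.10/31.99, noise SD 8)
the report reads:

```
Selected number of trajectories: k = 2
Calinski-Harabasz by k: 2: 10835.97, 3: 6511.62, 4: 5166.20, 5: 4344.89, 6: 3923.03

Cluster sizes:
  high: 1507 (50.07%)
  low: 1503 (49.93%)

Mean percent reduction per cluster per week:
  high: w2: 35.75%, w4: 60.37%, w6: 73.05%
  low: w2: 15.17%, w4: 27.70%, w6: 32.46%

Discordant patients (trajectory vs threshold): 50
```

Reading: the Calinski–Harabasz index peaks at two trajectories, splitting
the cohort into a better-responding half whose recovered mean curve matches
the configured high-class curve to well under a point, and a worse-responding
half matching the low-class curve; 50 patients near the 50% boundary are
classified differently by the two responder definitions. The printed-count
driver (`05`) reproduces the exact published-count statistics: composition
chi-squared 43.37 (df 1, p < 0.001), responder percentage 57.34% vs
high-trajectory percentage 48.87%, and 349 discordant patients.

## Library layout

| module | contents |
|---|---|
| `panss_traj.cohort` | `CohortConfig`, `assign_arms`, `generate_cohort`, `apply_dropout`, CSV I/O |
| `panss_traj.metrics` | percent-change formulas, `winsorize_iqr`, `impute_chained` (PMM), `TrajectoryMatrix` |
| `panss_traj.cluster` | `kmeans_single`, `kml_fit`, `calinski_harabasz`, `select_k`, trajectory labelling |
| `panss_traj.compare` | threshold rule, cross-tabs, chi-squared/Fisher/McNemar, BH-FDR, arm & episode breakdowns |
| `panss_traj.pipeline` / `panss_traj.cli` | `RunConfig`, stage commands, `panss-traj` subcommands |

See `docs/methods.md` for the model, the generator's assumptions and the
numerical choices.

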