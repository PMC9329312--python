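# Methods

## Problem and model

`kinotox` screens for associations between kinase engagement and
treatment-emergent adverse events (AEs) in patients treated with small-molecule
kinase inhibitors (SMKIs). The unit of analysis is the *kinase-inhibition
feature*

    KI(i, k) = C_ave,ss(i) / Kd(drug(i), k)

for patient i and kinase k, where C_ave,ss is the patient's steady-state
average plasma concentration and Kd the dissociation constant of the patient's
drug against kinase k (both in nM, so the ratio is dimensionless). Because the
feature depends on the drug only through its Kd vector, patients on different
compounds share one feature space and the drug label itself is discarded:
associations are attributed to kinases, not to drugs. Missing Kd entries —
pairs the panel did not measure or did not detect binding for — are imputed
with a single large constant, 1e4 nM, so an unengaged kinase contributes a
small but finite feature rather than a missing value.

The outcome for each *customized AE term* (a consolidation of related raw
preferred terms into one analysis term, supplied as a data mapping) is the
time in days from treatment start to first onset; patients without an
occurrence are right-censored at their end of follow-up. Severity grades are
carried through and can restrict events (e.g. grade >= 4 analyses) but never
enter the feature matrix.

## Random survival forest

The association model is a random survival forest built from scratch in this
package:

- **Trees** are grown on n-out-of-n bootstrap samples drawn with replacement;
  rows never drawn form the tree's out-of-bag (OOB) set.
- **Splitting**: at each node, `mtry` candidate predictors (default
  ceil(sqrt(p))) are drawn without replacement; every midpoint between
  consecutive distinct values of each candidate is scored with the
  standardized log-rank statistic |O - E| / sqrt(V) using the hypergeometric
  variance with the Breslow convention for tied event times. The best
  (predictor, threshold) pair wins; ties are broken by first encounter in the
  seeded candidate order, so growth is deterministic given the seed. Nodes
  stop splitting below 15 members or 3 events (configurable), or when no
  candidate attains a positive statistic.
- **Leaves** store the Nelson-Aalen cumulative hazard H(t) = sum d_k/n_k of
  their in-bag members, evaluated on a single grid shared by the whole
  forest: the sorted distinct event times of the training sample.
- **Prediction** averages leaf cumulative hazards over trees; survival is
  S(t) = exp(-H(t)). The scalar risk score used everywhere ("ensemble
  mortality") is the ensemble cumulative hazard summed over the grid.
- **Defaults**: 500 trees; all hyperparameters are configurable, and the
  scaled-down benchmark below uses fewer trees (stated under *Problem sizes*).

Variable importance is Breiman-style permutation VIMP: the OOB prediction
error (1 minus Harrell's C of the OOB ensemble mortality) is recomputed after
permuting one predictor's values within each tree's OOB set — only trees that
actually split on the predictor are re-evaluated, so a never-used predictor
scores exactly 0 — and the increase over the baseline error is reported,
optionally averaged over permutation repeats (default 1). Minimal depth is the
average over trees of the depth of the predictor's first split (root = 0);
trees never using it contribute their maximal depth + 1.

## Screening, stratification, evaluation

- `screen_ae` fits one forest per AE term on time-to-that-term and ranks all
  predictors by VIMP (descending, ties by name, so re-runs are stable);
  minimal depth is reported alongside. Terms with zero events are flagged
  "not fitted" and skipped with a warning. `screen_all` additionally reports
  the pair accounting n_kinases x n_ae_terms. No multiple-testing correction
  is applied: the output is a ranking, not a set of p-values.
- `stratify_km` splits patients at the median of one kinase's feature
  (strictly above the median = "higher inhibition"; ties fall to the lower
  stratum) and averages the forest's per-patient ensemble survival curves
  pointwise within each stratum, with a 95% pointwise band mean +/- 1.96 SE
  across patients (normal approximation, no bootstrap band).
- **Harrell's C**: concordant over censoring-permissible pairs; a pair is
  permissible when the earlier time is an event (time ties only when exactly
  one is an event); risk ties count 1/2. This matches the convention of
  lifelines' `concordance_index`, which the tests use as an independent
  cross-check.
- **Bootstrap cross-validation**: B iterations (default 500), each drawing
  80% of patients *without replacement* as training (this is deliberately
  distinct from the forest-internal bootstrap, which is with replacement),
  fitting a forest, and scoring the disjoint 20% by ensemble mortality.
  Splits leaving either side event-free are redrawn and logged. The summary
  is the mean and the empirical 5th-95th percentile interval of the C
  distribution.
- **Leave-one-out**: n forests, each without one patient; the held-out risk
  scores are pooled into a single C (pooling, rather than averaging
  per-patient, is the default because a single left-out patient has no
  within-fold pairs).
- **External validation**: trained per-AE forests predict, for an independent
  cohort sharing the kinase feature space, the probability 1 - S(horizon)
  averaged over patients; the horizon defaults to the external cohort's
  maximum follow-up and is clipped to the model grid with a warning.
  Predicted and observed incidences are classified at a threshold (default
  10%, 15%/20% supported) to give sensitivity and specificity, and Pearson's
  r (two-sided) is computed over the frequently reported terms (observed >=
  threshold).
- **Reporting odds ratio**: ROR = ad/bc from the 2x2 drug-by-AE report
  table, with the Haldane-Anscombe +0.5 correction on any zero cell
  (flagged) and a log-normal 95% CI.

## Synthetic data generator

The generator stands in for confidential patient-level trial data; every
pipeline stage is exercised end-to-end against known ground truth.

It emulates, per master seed: a sparse drug x kinase Kd panel; log-normal
per-patient exposures with configurable inter-individual CV; demographics;
and per-AE-term proportional-hazards outcomes

    h_i = h0 * exp( sum_k beta_k * log1p(KI(i, k)) )

over the term's causal kinases, with an exponential (default) or Weibull
baseline, administrative censoring at end of follow-up, and onset days equal
to the ceiling of the continuous event time. The log1p link keeps the
zero-inhibition case well defined and makes effects multiplicative on the
hazard; the model downstream is non-parametric, so any monotone link would
serve. Events are emitted as raw AE records whose terms are drawn from
per-term synonym lists, so the consolidation mapping is exercised on the way
back in.

Two calibrations stabilize the study conditions across seeds:

- `target_incidence`: the baseline hazard h0 is solved by bisection so the
  marginal event fraction matches a target (the benchmark uses 45%, a
  realistic rate for a common AE over one year of follow-up). Without this,
  the exponential link makes incidence swing wildly with the kinome draw.
- `min_hr_per_sd`: each causal coefficient is floored at the value that makes
  the hazard ratio per standard deviation of the realized log1p(feature)
  reach the stated effect size (the benchmark uses 2), so the designed
  signal strength holds on every generated dataset rather than on average.

**Identifiability by design.** With a single scalar exposure per patient,
every kinase bound by the same drug has a feature that is a monotone
transform of the same C_ave,ss within that drug's patients — within-compound
data cannot distinguish a causal kinase from a co-bound bystander. Kinase
attribution therefore rests entirely on cross-compound Kd structure. The
benchmark panel makes this structure informative: causal kinases are engaged
by *every* compound, with log10 Kd = center - potency + jitter, where the
compound potencies form an evenly spaced, randomly assigned ladder spanning
+/- 0.35 decades and the kinase-specific jitter is Gaussian (0.35 decades).
Non-causal entries are independent log-uniform draws over 1-1000 nM for a
random 3% of the kinome per compound (selective compounds). The potency
ladder is what a mixed panel of promiscuous-potent and selective-weak
compounds looks like on a toxicity-driving kinase that most of them engage
(the VEGFR2/EGFR situation); at the same time it is a *designed* benchmark
regime: with only 8 compounds, fully independent per-(drug, kinase) Kd draws
leave drug-subset indicator features as good as the causal gradients, and no
method can attribute the signal to kinases. Passing the recovery tests
therefore shows the pipeline extracts kinase-level signal when the panel
carries it; it does not show that 8 compounds suffice for an arbitrary real
panel.

**What the generator does not emulate:** time-varying exposure (only the
steady-state summary), competing risks and informative censoring, correlated
AE terms, MedDRA coding noise beyond the synonym lists, covariate effects of
age and sex (generated as pure noise by default), and between-study
heterogeneity. Results on synthetic data bound what the pipeline can do when
its assumptions hold, not clinical performance.

## Versioned benchmark and problem sizes

The default `SimulationConfig` *is* the benchmark: 8 drugs x 75 patients =
600 patients, 200 kinases (202 predictors with age and sex), one AE term
("hypertension") with 5 causal kinases at per-SD hazard ratio >= 2 and 45%
incidence, one pure-noise term ("vomiting/nausea"), 365-day follow-up.
Benchmark validation uses 100-tree forests for screening and recovery and
50-tree forests inside cross-validation iterations (B = 50); these sizes give
stable rankings at interactive runtimes and are the package's versioned
choices for the shipped tests. Under them, across 20 replicate seeds, the
median top-25 VIMP recall of the 5 causal kinases is >= 0.8 and the median
held-out C-index exceeds 0.7 (the suite recomputes both).

## Numerical choices and edge cases

- Log-rank variance terms with fewer than two subjects at risk contribute 0;
  a zero-variance split scores 0 and cannot be selected.
- The all-thresholds split scan is vectorized over split positions via prefix
  sums of at-risk/event indicator matrices; it is exactly equivalent to
  statistic-by-statistic evaluation (tested).
- Event times that fall between grid points when a leaf curve is evaluated on
  the shared grid fold onto the next grid point; events after the last grid
  point do not affect values on the grid.
- All randomness descends from one master seed via `numpy.random.SeedSequence`
  spawning (master -> stage -> tree/iteration), so results are bit-reproducible
  and independent of execution order; derived seeds stay below 2^31.
- Forests serialize to a single versioned JSON file, round-tripping
  predictions, importance and depth exactly.
- Sex is encoded 0/1 (0 = female by convention, recorded in dataset
  metadata); Kd and C_ave,ss units are fixed as nM.
- Unmapped raw AE terms pass through as their own customized term; the
  consolidation map is data, not code.

## Known limitations

- Permutation VIMP shares credit among correlated predictors; co-engaged
  kinases can mask one another, and the top-k list should be read as a
  candidate set, not a causal certificate.
- The 2x2 ROR helper takes report counts as given; it does not build
  comparator groups from raw report databases.
- No competing-risks machinery, no population-PK estimation (C_ave,ss is an
  input), and no MedDRA normalization logic.
- `screen_all` over thousands of AE terms fits one forest per term;
  large-scale runs should set tree counts accordingly (trees are independent
  given their seeds, so the work parallelizes trivially across terms).
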