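# Methods

## The problem this package addresses

Community prediction challenges collect dozens of models for the same
clinical question and need an assessment apparatus that is fair, stable
and interpretable: scoring rules that respect censoring, leaderboards that
resist over-fitting, a way to say whether rank 1 is *really* better than
rank 2, and diagnostics that reveal which inputs a model actually used.
amlbench implements that apparatus for an AML prognosis setting — three
linked outcomes per patient (response to induction therapy, remission
duration, overall survival) predicted from protein-array and clinical
data — and supplies a synthetic-cohort generator so every stage can be
exercised, calibrated and tested without protected data.

## Generative model of the cohort

**Features.** Protein levels are drawn from a low-rank multivariate
normal: a k-dimensional latent factor (default k = 5) with Gaussian
loadings plus independent noise, then column-standardised.  This mimics
normalised RPPA data — correlated, continuous, centred so that a value
below 0 reads as "low" — without modelling array chemistry.  Clinical
covariates comprise three named variables (Age ~ N(57, 14²) clipped to
[18, 90]; Chemotherapy, a 4-level categorical; AHD, a yes/no flag for an
antecedent haematological disorder) plus filler covariates, alternating
continuous and small categorical, up to the configured count (default 40).

**Outcomes.** A single latent risk score ties the three outcomes
together:

    z_i = Σ_f w_f · standardise(x_if) + ε_i,   ε_i ~ N(0, 0.5)

The default weights make low levels of one designated protein
(`PIK3CA`: w = −1.5), older age (+0.6), AHD (+0.5) and low NPM1/GSK3AB/
PTEN increase risk.  Response to therapy follows a latent-utility
logistic link: patient i is Resistant iff z_i + η_i > c with η_i standard
logistic.  The intercept c is solved by bisection on the realised cohort
so that the mean of P(Resistant | z_i) equals 1 − cr_prevalence
(default prevalence 0.71 CR).  This makes the expected CR fraction exact
by construction — the acceptance check is a binomial test, not a
tolerance fudge — and, because the label is a deterministic threshold of
the *full* utility z + η, a simulated predictor with skill 1 can separate
the classes perfectly (AUROC 1), which anchors the skill scale.

Remission-duration and survival times are Weibull (shape 1.3) with scale
baseline_hazard_scale · exp(−0.5 · (z − z̄)) — higher risk, shorter
times; survival's default scale is 60 weeks, remission duration's 80% of
that.  Censoring times are independent exponentials whose mean is solved
numerically so the expected censored fraction equals the configured rate
(default 0.25 for both outcomes).  Remission duration is generated
internally for everyone but *defined* — exposed, written to files,
scored — only for CR patients; there is no remission to lose otherwise,
and Resistant patients are excluded from the RD truth.

The designated-protein weight (−1.5) was calibrated once so that the
chi-squared association between (protein < 0) and the Resistant label at
n = 291 is significant at p < 0.01 in essentially every seed (median
p ≈ 3·10⁻¹⁰), i.e. the strong-association regime the importance analysis
is meant to rediscover.

**What the generator does not emulate.** Real covariate distributions
(the actual clinical variables are only named, not distributed, in public
sources), slide/batch effects in RPPA, informative censoring, competing
risks, and any dependence between patients.  Passing tests therefore
demonstrate that the *assessment machinery* behaves correctly under a
plausible data-generating process, not that any conclusion transfers to a
specific real cohort.

## Simulated predictors

Two kinds, both deterministic given their seed:

* **Truth-mixing predictors** (`simulate_predictor`) blend the true
  standardised signal s with independent Gaussian noise ε:
  u = skill·s + √(1 − skill²)·ε.  For the response outcome s is the
  (negated) latent utility and the confidence is logistic(u); for the
  survival outcomes the predicted weeks are a rank-preserving map of u
  onto the empirical distribution of the true uncensored times, so
  skill = 1 reproduces the true times exactly.  skill interpolates
  continuously between an oracle and a coin flip.
* **Feature-reading predictors** (`LinearPredictor`) compute a weighted
  sum of named table columns (categoricals via sorted-level codes) and
  apply the same skill mixing.  Their noise stream is keyed to a hash of
  the input table: identical tables give identical predictions (the
  importance machinery requires an evaluable, deterministic handle), but
  any changed cell re-draws the noise — so scrambling a column the model
  ignores produces scores that fall above and below baseline with equal
  frequency (fraction_reducing ≈ 0.5), the behaviour expected of a null
  feature, rather than an uninformative wall of exact ties.

## Scoring conventions

* AUROC is computed by the rank (Mann–Whitney) identity; tied
  confidences earn half credit.  Undefined when the truth is
  single-class.
* BAC needs hard labels; confidences are binarised at a configurable
  threshold, default 0.5 on the CR-probability scale (the simplest
  defensible default; nothing in public sources fixes it).
* The concordance index follows Harrell: a pair is comparable iff the
  smaller actual time carries an event; pairs with tied actual times are
  not comparable; prediction ties earn 0.5.  Larger predicted *time*
  should accompany larger actual time (predictions are times, not
  risks).
* Pearson correlation is computed only over the included subset
  (relapsed responders / deceased) and requires ≥ 3 points with nonzero
  variance on both sides.
* Undefined metrics raise typed errors; the leaderboard and stability
  stages catch them, log, and record the entry as missing rather than
  inventing a sentinel score.
* The random-prediction null draws uniform confidences (response
  outcome) or permutes the observed times among the scored patients
  (survival outcomes); its median AUROC/BAC/CI sits at 0.5.

## Rank stability

Each model is re-scored on the *same* seeded subsamples (default 1000
subsets of 60 of the 74 final-week patients, drawn without replacement —
subsets, not bootstrap resamples).  For a pair of ranks, wins/losses/ties
count the sign of the per-subsample score difference; ties enter neither
side of the Bayes factor (the odds ratio conditions on strict orderings),
and the published "overlap" is the strict-loss fraction.  With zero
losses the factor is reported as the conservative lower bound
(wins − 1)/1 and flagged, rendered e.g. ">999"; lower bounds are
classified by the bound, which can only understate the evidence.

## Genetic-algorithm partitioning

Public sources state only that a genetic algorithm produced train/test
sets with equivalent distributions; the fitness function and operators
here are this package's own design.  Fitness = mean over features of a
distribution distance (two-sample KS for continuous, total variation for
categorical — both in [0, 1]) **plus** the absolute difference in CR
prevalence, treated as an additive penalty so outcome balance is not
diluted by averaging over 270 features.  The GA evolves fixed-cardinality
membership vectors: tournament selection (size 3), uniform crossover
followed by count repair (random flips restoring the train size), swap
mutation, elitism of one.  Defaults: population 100, 200 generations.
The KS statistic is evaluated exactly (including tied values) by a
pre-sorted vectorised engine; a brute-force per-feature recomputation is
the test oracle.  On a cohort of mirrored duplicates the optimum (fitness
0) exists and the GA finds it; on realistic cohorts it reliably beats the
best of 1000 random splits.

## Feature importance

Scrambling permutes a column across patients, preserving its marginal
exactly.  Baseline is scored once on the unscrambled table; each
repetition scrambles (independent RNG substream per feature, keyed by a
CRC of the feature name so results are invariant to screening order),
re-predicts and re-scores with the combined AUROC/BAC mean.
`fraction_reducing` counts strictly lower scores (exact ties do not count
as reductions); `percent_diffs` are 100·(scrambled − baseline)/baseline,
negative meaning loss — the sign convention is declared in the output
header.  Screening uses 100 repetitions per feature; features whose
reducing fraction exceeds 0.65 are re-assessed at 10,000 repetitions and
flagged `deepened`.  The performance-loss point estimate is baseline
minus the median scrambled score.

## Statistical tests

The Wilcoxon rank-sum statistic uses mid-ranks.  For pooled n ≤ 12 the
p-value is exact, enumerating all C(n, n_x) assignments of the pooled
ranks (two-sided = doubled smaller tail, clipped at 1); otherwise a
normal approximation with tie correction and a 0.5 continuity
correction, matching the standard asymptotic Mann–Whitney formulation to
numerical precision.  The chi-squared association test is the 2×2
Pearson statistic n(ad − bc)²/((a+b)(c+d)(a+c)(b+d)), one degree of
freedom, no continuity correction, and requires all margins positive.
Per-class "accuracy" is the positive predictive value, undefined (NaN,
flagged) when a model never predicts the class.

## Numerical and design choices

* All bisection solvers (logistic intercept, censoring scale) run 200
  iterations to well below measurement precision; the censoring solver
  bisects in log-space over [10⁻⁶, 10⁹] weeks.
* Randomness flows from one root seed through named CRC-keyed
  substreams; adding a stage never perturbs another stage's draws, and
  every artifact embeds the seed and a configuration hash.
* Final-ranking ties break by the first metric, then team id — ties are
  vanishingly rare with continuous scores, but the order must be total
  for determinism.
* Aggregation averages raw submitted values (not ranks or z-scores) per
  patient, including the confidences of the survival sub-challenges that
  scoring ignores, so the aggregate is itself a complete submission.
* The end-to-end pipeline's default configuration is a deliberately
  reduced demonstration problem (120 patients, 40 proteins, 8 teams,
  30 GA generations, 200 stability subsamples) chosen so a full run
  completes in seconds; every component accepts the full-scale settings
  (291 patients, 231 proteins, 191/100 split, 1000 subsamples, 200
  generations), which are the library defaults of the respective module
  configurations and are what the test suite exercises where the
  property under test demands them.

## Known limitations

* The simulated predictor family is linear-plus-noise; it cannot emulate
  models whose feature reliance is interaction-driven, so importance
  results on simulated predictors probe the machinery, not model
  diversity.
* The BAC threshold and the per-week exclusion list are configuration,
  not inference; real challenges may have used optimised thresholds.
* The exact Wilcoxon path is combinatorial (C(12, 6) = 924 assignments at
  the default limit); raising the limit much beyond 12 becomes slow.
* The GA is single-objective; it will trade a slightly worse marginal on
  one feature for a better average, with no Pareto control.
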