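# Methods

`toxfinger` implements a hazard-driven prioritization pipeline for
nontarget high-resolution mass spectrometry (NTS HRMS/MS): in-vitro
screening data are curated into binary per-endpoint toxicity calls,
imbalance-aware classifiers are trained per endpoint on molecular
fingerprints, and unidentified MS features are classified toxic/nontoxic
per mechanistic target by majority voting over replicate, MS2-derived
probabilistic fingerprints. This note documents the model choices, the
tunable parameters, the synthetic-data design, and the numerical details.

## Dose–response curation

Each chemical × endpoint series carries test responses over a log10 µM
concentration grid plus baseline (control) responses. The noise scale is
the baseline median absolute deviation, BMAD = 3 × median(|x − median(x)|),
and the efficacy cutoff defaults to 6 × BMAD (`cutoff_multiplier`,
`bmad_multiplier` in `RunConfig`). Three models are fit to
*per-concentration median* responses by bounded least squares:

- constant: f(x) ≡ 0, one parameter (noise only);
- hill: f(x) = tp / (1 + 10^((ga − x)·gw)), three parameters plus noise;
- gain–loss: the hill gain term times a mirrored loss term
  tp · [1 + 10^((ga−x)·gw)]⁻¹ · [1 + 10^((x−la)·lw)]⁻¹.

The winner minimizes a Gaussian-likelihood AIC, n·ln(rss/n) + 2k, with an
rss floor of 1e−12 to keep perfect fits finite; ties break toward fewer
parameters. The AIC variant is a package choice — it is the standard form
for least-squares fits. Slopes are bounded to [0.3, 8] and location
parameters to the tested range ± 2 log units; fits use five starts with
the midpoint guess swept across the tested range (hill least squares is
multi-modal) and analytic Jacobians with an iteration cap of 50 (hill) /
60 (gain–loss) function evaluations per start, which recovers noiseless
parameters to optimizer precision while keeping large screens fast.

A series is called active (hitc = 1) iff the winner is hill or gain–loss
AND both the modeled top and at least one concentration median exceed the
cutoff. Active calls carry AC50 = ga and ACC = the lowest concentration at
which the winning curve equals the cutoff — analytically for hill
(acc = ga − log10(tp/cutoff − 1)/gw), by bracketing + Brent root finding
for gain–loss. Throughout, the efficacy cutoff is the 6·BMAD response
threshold and the ACC is the concentration at that threshold.

Downstream filters: active calls with more than `max_flags` (default 3)
caution flags are demoted — flag taxonomies are platform-internal, so the
filter is reduced to a count threshold. The cytotoxicity-burst filter
computes, per chemical, the median AC50 over its active cytotoxicity
endpoints and the global MAD of those points; strict mode demotes
target-endpoint actives with AC50 ≥ point − 3·MAD, mild mode only those
with AC50 ≥ point. The exact constituency of strict burst filtering varies across
screening pipelines; the 3·MAD margin is this package's documented rule;
it preserves the required containment (strict demotions ⊇ mild demotions).
Endpoints enter modeling only with strictly more than 500 chemicals and
strictly more than 0.1% actives, and endpoints sharing a mechanistic
target are concatenated with an OR rule over hit calls.

## Fingerprint preprocessing

Probabilistic (Platt posterior) fingerprints are binarized at 0.5, with
values of exactly 0.50 mapped to 0. Bits are filtered for modeling in two
deterministic stages: (1) drop bits whose minority-value frequency is
below 5% — for binary bits, minority-class frequency is the natural
variability statistic and this is the standard near-zero-variance screen; (2) greedily scan the
survivors in column order and drop any bit whose |Pearson r| with an
already-kept bit exceeds 0.95 (first kept bit wins; Pearson on binary
bits is this package's choice of association measure, documented here). The filter is fit on training data only and its
kept-bit list replayed on test and prediction data. Tanimoto similarity
is |a∧b|/|a∨b|, defined as 1 for two all-zero vectors.

## Endpoint models

One binary classifier per endpoint, default family extreme gradient
boosted trees (model registry also offers random forest, logistic
regression, Bernoulli naive Bayes). Training protocol:

1. stratified 80/20 train/test split; the test set is withdrawn before
   any oversampling, bit filtering, or tuning;
2. random grid search (defaults: 50 draws, early stop after 20
   consecutive non-improving draws; "retrain mode" presets 5-fold CV with
   a 20-draw search) over max_depth ∈ {2…9}, learning rate
   log-uniform(0.01, 0.3), and boosting rounds ∈ {50…200}, selected by
   cross-validated F1 pooled over folds;
3. SMOTE oversampling to class parity applied *inside each CV fold's
   training part only*; synthetic minority samples are convex
   combinations x + u·(x_nn − x), u ~ U(0,1), over the k = 5 nearest
   minority neighbours (Euclidean), and fingerprint coordinates stay
   fractional — they are never re-binarized;
4. the winner is refit on the full oversampled training set and evaluated
   once on the untouched test set.

Early stopping counts *consecutive* non-improving draws (the alternative,
cumulative counting, is not used); the repeat count for repeated CV
defaults to 1 and is configurable. Metrics with zero denominators are
propagated as undefined, never as 0, and an undefined metric fails every
threshold — a model that never predicts a positive must not vote. The
classification threshold on predictor scores is fixed at 0.5. Each
endpoint derives its own seed stream from the global seed plus a CRC32 of
the endpoint id, so results are reproducible regardless of training
order. A model is eligible to vote iff test sensitivity AND precision are
strictly greater than 0.65.

`tune_and_train(presmote=True)` deliberately applies SMOTE before
cross-validation so the test suite can demonstrate the optimistic bias of
leaked oversampling; real training never uses it.

## Replicate voting

Each feature's replicate fingerprints (multiple spectra × up to 10
candidate fingerprints per spectrum) are binarized, projected onto each
eligible model's kept bits (a missing bit is a hard error), and
classified. The per-target hit call is a strict majority over all
replicate × endpoint votes; an exact tie is nontoxic (the prioritization
context favours precision of the toxic list), and votes are unweighted
across spectra, candidate ranks, and endpoints — candidate-rank weighting
is deliberately not invented without evidence it helps. Targets with no eligible endpoint are reported as `untested`,
never as nontoxic. In validation, voting is per compound × endpoint,
balanced accuracy is computed per endpoint over compounds, and target
scores are unweighted means over the target's endpoints; any overlap
between validation and training compounds is a hard error.

## NTS feature prioritization

Features are componentized by neutral mass (m/z minus the adduct offset;
unannotated features are assumed to be the mode's molecular ion, [M+H]+ or
[M−H]−) within 5 ppm and 0.5 min, each component represented by its
molecular-ion member with annotated adducts removed; features with
unknown adduct annotations pass through ungrouped with a warning.
Identification levels: 1 for target-list matches (precedence over any
spectral score), 2a for spectral-library matches at ≥ 85% (the cutoff is
read as inclusive), 3 for any non-missing sub-cutoff score (partial-match
evidence as exported by upstream tools). Identified features bypass the
shape/S-N screen; unidentified features need Gaussian peak shape > 0.8
and S/N > 10 (both strict). All features must satisfy a ≥ 5-fold
max-sample-area/blank ratio (the aggregation rule for the blank
comparison is unstated upstream; maximum over samples is used) and a
neutral precursor mass strictly below 600 Da (boundary direction decided
here). Every exclusion carries a reason code, and retention is invariant
to row order.

## Surrogate feature importance

A random forest (200 trees, `max_features=0.5`, seeded) is trained on the
same kept bits against the black-box model's *predictions* — that is what
makes it a surrogate for the black box rather than a second model of the
labels. Importances are impurity-based and normalized to sum to 1 per
endpoint, so importance mass is comparable across endpoints.
Surrogate fidelity (agreement rate with the black box on the evaluation
set) below 0.8 flags the table; a constant black box yields a degenerate
table with uniform importances. Half-feature subsampling per split
concentrates importance on truly predictive bits while still spreading it
across co-informative correlated bits. Per mechanistic target, a bit's
recurrence is the number of endpoint tables where it ranks in the top 25
importances, its score is recurrence × mean importance over those tables
(the product is this package's formalization of combining recurrence
with importance), and the top 10 by
score are reported with SMARTS strings.

## Synthetic data design

The generators emulate the statistical structure of the study inputs, not
their chemistry: "chemicals" are fingerprint vectors with synthetic SMARTS
labels, since the pipeline consumes bits.

- **Chemicals**: 256 bits with Beta(1.2, 5) prevalences (some below the 5%
  screen by construction) plus three blocks of five duplicated columns to
  exercise the correlation filter. The 10 toxicophore bits co-occur
  through a latent toxic-scaffold indicator (prevalence defaulting to the
  active fraction): conditional bit prevalence 0.9 given the scaffold,
  0.05 otherwise. This mirrors how a structural alert lights up several
  related substructure bits on the same molecule, and it is what makes
  well-modeled endpoints highly learnable from structure (an
  exchangeable independent-bit rule with a sharp count threshold is both
  less realistic and pathologically hard for tree learners at the class
  boundary).
- **Labels**: activity probability logistic(α + β·toxicophore count) with
  β = 12 (steep, near-deterministic); α is calibrated by bisection so the
  expected active fraction hits the target (default 10%, within the
  0.1%–50% imbalance range typical of HTS endpoint collections), and the realized fraction must land
  within ±20% relative plus a 3-standard-error binomial allowance for
  small universes. Actives draw a latent AC50 uniformly from the interior
  of the tested range.
- **Dose–response**: eight concentrations spanning log10 of 0.1–100 µM,
  two replicates each, Gaussian noise σ = 1; actives follow a hill curve
  with top 3–12× the noise-implied cutoff (6 × 3 × 0.6745σ) and slope in
  [0.5, 3]; inactives and the 30 baseline points are pure noise.
- **Replicate fingerprints**: replicate counts are rounded lognormal
  (median 6, σ_log 0.8; mean ≈ 8) clipped to [1, 67] and packed into
  spectra of at most 10 candidates; per bit the posterior is Beta(8, 2)
  when the true bit is 1 and Beta(2, 8) when 0, giving a post-binarization
  flip probability of I₀.₅(8,2) ≈ 0.020 per bit.
- **NTS table**: constructed exemplars on both sides of every
  prioritization filter (clean molecular ion + its sodium adduct, bad
  shape, bad S/N, bad blank ratio, > 600 Da, identified features that
  bypass the quality screen) with the ground-truth retained set recorded.

All generators are deterministic under the spec seed (endpoint-specific
streams are derived via CRC32, never Python's salted `hash`). What the
synthetic world does *not* contain: real substructure semantics,
mass-spectral noise structure correlated across bits, retention behaviour,
endpoint families with heterogeneous difficulty, or assay artefacts beyond
i.i.d. Gaussian response noise. Passing tests therefore demonstrate the
correctness and statistical behaviour of the pipeline machinery — not
predictive performance on real screening libraries.

## Problem sizes used in the test suite and reproduction script

The study-scale harness trains four endpoints (two mechanistic targets) on
2000 training chemicals with 300 held-out validation compounds, using the
retrain-mode preset with a compact random search (8 draws, early stop 5);
hit-call error rates use 200 seeded screens per arm; the ACC oracle
comparison uses 100 random parameter draws; the leakage comparison uses a
noisier 600-chemical endpoint (β = 1) so cross-validated F1 sits below 1
and the bias is visible. The search size is a tuning knob, not a study
condition; the study conditions (sample size, imbalance, bit noise,
replicate counts) stay at the defaults above.

## Known limitations

- The gain–loss ACC root search scans 2000 grid points before Brent
  refinement; pathological curves crossing the cutoff in a narrower window
  would need a finer scan.
- The burst filter's strict margin and the blank-ratio aggregation are
  documented package choices where the upstream procedure is unspecified.
- Voting treats all replicates as exchangeable; candidate-rank weighting
  is not modeled.
- The CLI trains models sequentially; very large endpoint sets would want
  process-level parallelism, which is out of scope here.
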