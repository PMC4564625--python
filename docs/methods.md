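# Methods

This note records the model, the numerical conventions and the design
choices behind `relapsemri`, and what the synthetic-data tests do and do
not demonstrate about clinical data.

## Decision-aligned labelling

A patient's timeline is aligned on the session at which the
radiological response assessment first assigned a class. Offsets are
**ordinal positions** in the session sequence, not calendar days: the
follow-up interval in the motivating study changed from monthly to
three-monthly, and all of its per-time-point reporting is by session
index (L+5 … L−11). Sessions at and after the decision carry the
decision class; earlier sessions are unlabeled. Evaluation scores
*every* session — labeled or not — against the patient's eventual
decision class, which is what turns pre-decision offsets into an
early-prediction experiment.

## Balanced error rate and the weighted summary

At offset *i*, `BER_i` is the mean of the two per-class error rates.
When only one class is observed at an offset (common at deep negative
offsets, where one or two patients remain), the error rate of the
present class alone is used; the absent class's term is 0/0 and is
dropped. This convention is forced by the reference tables: single
patient offsets print 0 or 1, never 0.5.

The weighted summary is

    wBER = Σ W_p^i W_t^i BER_i / Σ W_p^i W_t^i

with `W_t = 1` for offsets ≥ 0 and `1 − (0.5/11)·k` for k sessions
before the decision — a linear ramp that reaches 0.5 at the deepest
pre-decision offset observed in the motivating cohort (11). The ramp is
applied as-is for k > 11, so weights below 0.5 are possible on longer
timelines. `W_p` is proportional to the per-offset patient count; its
normaliser cancels in the ratio, which the test suite asserts
(count-rescaling invariance). Offsets with no data contribute nothing.
Summary values are conventionally printed to 3 decimals; full precision
is kept internally.

Recomputing the shipped imputed-variant reference table yields 0.228
for the pseudoinverse-LDA column, whereas the original summary row
prints 0.216; the published cell does not follow from its own per-offset
column under any weighting consistent with the other five columns, and
0.228 is what this implementation reports.

## Volume-conditioned imputation

The rule set, in order:

1. Missing feature over region CE or ED whose **volume is exactly 0**
   (no tolerance — volumes are recorded as 0 when a region is absent):
   the tissue is healthy. Perfusion fills with the constant 1 (the
   NAWM-normalised ratio of normal tissue); diffusion and spectroscopy
   fill with the feature's mean over responsive-labeled sessions.
   Spectroscopy ratios are measured over the CE region, so their
   zero-volume rule keys on the CE volume.
2. Missing feature over a positive-volume region: the feature's mean
   over all labeled sessions. This includes perfusion — the
   fill-with-1 rule applies only to the zero-volume branch.

Means are computed over present values only and are order-invariant.
Within LOPO the imputer is refitted per fold on the *training*
patients' labeled sessions, so the held-out patient never contributes
to the means it is imputed with. (Preparing a single imputed dataset up
front would be cheaper and is how a one-shot analysis would likely do
it, but it leaks the test patient's labeled sessions into the means;
the per-fold refit is the conservative choice.)

A consequence worth knowing: fill values are constants shared by every
imputed session, and which constant a session receives (responsive mean
vs labeled mean) depends on its volumes, which correlate with class
after the decision. Imputed features therefore carry a faint class
signature of their own. This is visible in the results as a
complete-vs-imputed performance gap (the reference tables show 0.148 vs
0.294 for random forests) and, on synthetic data, as occasional
single-patient errors near the decision on the imputed variant that do
not occur on complete features.

## Classifier bank

Adapters are thin wrappers over scikit-learn with the study's stated
settings: 3-nearest-neighbours with correlation distance (brute-force
search), SVMs with linear / polynomial / RBF / sigmoid kernels, CART
classification trees, a 10-hidden-unit MLP, 100-tree random forests and
100-round boosting ensembles (AdaBoost; LogitBoost as log-loss gradient
boosting; GentleBoost as exponential-loss gradient boosting). Robust
boosting has no exact open implementation; the adapter maps it to a
histogram gradient-boosting classifier and flags the substitution in
the report metadata.

The "diagonal LDA" of the motivating study is, by its own description,
a linear discriminant using the **pseudoinverse of the pooled
covariance** — not the usual diagonal-covariance estimator. It is
implemented here as described (`PooledPinvLDA`): class means, pooled
within-class covariance, Moore–Penrose pseudoinverse, argmax of linear
discriminant scores with log-prior offsets. The pseudoinverse keeps the
rule defined when labeled sessions are fewer than features, which is
the normal regime here; in that rank-deficient regime the estimator
does not guarantee perfect separation even of its own training data.

Feature standardisation (z-scoring fit on the training fold) is applied
for the distance- and margin-based families (kNN, LDA, SVM, MLP) and
not for tree ensembles, which are scale-invariant. Class priors are
library defaults with no rebalancing; BER corrects for imbalance at
scoring time. A single run seed derives per-fold sub-seeds through
`numpy.random.SeedSequence`, so every report is reproducible bit for
bit.

## Synthetic cohort generator

The generator reproduces the *structure* of the motivating cohort, not
its values — no per-feature distributional summaries by class were ever
published, so only structural fidelity is claimed:

- **Cohort shape.** 29 patients by default; per-patient pre-decision
  session counts (1–11) and post-decision counts (0–5) are drawn from
  the empirical distributions implied by the published per-offset
  sample counts, giving 178 expected sessions. Protocol-group codes use
  the published 16/7/6 prevalence. The progressive fraction is not
  derivable from the published tables and defaults to 0.5.
- **Features.** Modality features are class-conditional Gaussians;
  responsive perfusion is centred at 1 (NAWM normalisation) and the
  progressive mean is shifted by δ within-class standard deviations.
  Diffusion and spectroscopy locations are arbitrary configured
  constants; only the direction of separation is meaningful.
- **Volumes.** Lognormal baselines; after the decision, responsive
  volumes shrink and collapse to exactly 0 region-by-region (default
  probability 0.5 per session), progressive volumes grow (default
  factor 1.3 per session). The class contrast of the volume dynamics is
  scaled by min(δ, 1) so that δ = 0 produces exactly exchangeable
  classes — the chance-level tests depend on this.
- **Missingness.** Whole modality blocks are masked per session
  (Bernoulli with the configured rate; defaults 0.66 / 0.30 / 0.44 for
  spectroscopy / perfusion / diffusion), matching per-acquisition
  quality rejection. The mechanism is completely at random given the
  modality, plus an optional coupling that masks a block whose CE
  volume is exactly 0 with probability 0.2 — the true clinical
  mechanism (motion, quality control) is not recoverable from the
  published material. A modality with rate 0 is never masked, coupling
  included.

What passing tests on these cohorts shows: the pipeline's mechanics
(label propagation, leakage-free folds, imputation rules, weighting)
behave correctly, classification quality responds monotonically to δ,
and with δ = 0 every classifier sits at chance (seed-averaged wBER in
[0.35, 0.65]; single-seed values at n = 29 are highly variable, so the
band is checked on the average over 20 seeds). What it does not show:
anything about the attainable accuracy on real multiparametric MRI,
where features are correlated within and across modalities, drift over
time within patients, and missingness is informative.

## Problem sizes and tolerances

The synthetic acceptance checks use the cohort scale the generator
defaults to (29 patients, ~180 sessions) over 20 seeds per check.
Weighted-BER oracle equivalence is asserted to 1e−12 on 1,000 random
series; the published summary rows are asserted to their printed 3
decimals. Degenerate inputs are errors, not silent defaults: empty
truth vectors, negative temporal indices, single-class training folds,
sub-2-patient cohorts and unfittable imputation features all raise
named exceptions.
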