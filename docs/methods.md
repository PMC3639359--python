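# Methods

## Model

Every data point is a Gaussian. A measurement is N(μ_obs, σ_obs) with
μ_obs the replicate mean and σ_obs = σ_exp/√N; a prediction is
N(μ_pred, σ_pred) emitted by a *PD method*: a point-prediction model
(supplying μ_pred) paired with an error-estimation method (supplying
σ_pred). The quality of a set of predictive distributions is the mean
Kullback–Leibler divergence of the predictions from the measurements,

    D_KL(P‖Q) = ln(σ_q/σ_p) + (σ_p² + (μ_p − μ_q)²) / (2 σ_q²) − ½,

which is zero iff the prediction matches the measurement distribution
exactly and grows with inaccuracy, overconfidence, or unnecessary
imprecision. The KL direction is fixed: the measurement is the true
distribution P, the prediction the model distribution Q. Because a
model cannot predict an experimental result more precisely than the
measurement itself, every σ_pred is floored at the assay's single-shot
error σ_exp *before* scoring; the floor is never applied to measurement
distributions.

The Gaussian error assumption is a modelling convenience, not a
requirement of the divergence framework; heavy-tailed prediction errors
(e.g. from unrepresentable stereochemistry) inflate the mean KL of the
affected bins rather than being modelled explicitly.

## Experimental error

σ_exp is pooled from quality-control compound replicates as the
root-mean-square within-compound deviation, normalised by the **total**
number of measurements (maximum-likelihood pooling, no
degrees-of-freedom correction). This estimator has a small negative
bias of order 1/(2·N_per_compound); at the replicate depths QC
compounds accumulate (hundreds of measurements) the bias is negligible.
QC sets with a single measurement carry no variance information and are
excluded rather than allowed to inflate the denominator. All non-QC
compounds inherit the QC-derived σ_exp.

## Error-estimation methods

Uniform methods assign one σ_pred to every query:

- **TS** — RMSE on the temporal parameterization test set;
- **CV** — RMSE of double-loop (nested) cross-validated training-set
  predictions. The outer loop produces out-of-fold predictions; the
  inner loop confines hyperparameter tuning to the outer-training
  partition, so the estimate is not optimistically biased by tuning.

Variable methods map a per-query reliability score to σ_pred:

| tag | score | transform |
|---|---|---|
| D2M-EUC / D2M-MD | mean distance to k nearest training compounds | calibrated |
| LE-EUC / LE-MD | RMSE of k nearest neighbours' CV residuals | direct |
| LEC-EUC / LEC-MD | same score as LE | calibrated |
| BV | SD of bagged-ensemble member predictions | direct |
| BVC | same score as BV | calibrated |
| EM | predicted absolute CV error from a second regressor | direct |

The calibration regresses squared residuals on the score with the
intercept pinned at σ_exp², giving σ_pred(s) = √(m·s + σ_exp²); the
slope has the closed form m = Σ s(r² − σ_exp²)/Σ s², clamped at zero so
calibrated errors are nondecreasing in the score. The fit uses
per-compound squared residuals; a moving-average RMSE overlay is a
diagnostic only. For BVC the abscissa is the ensemble SD (variance
would give a different slope but the same ranking). EM uses the
predicted absolute error directly as σ_pred — no √(π/2) half-normal
correction — with negative predictions handled by the σ_exp floor.

The neighbour count k is chosen on the parameterization set as the
candidate (default grid 1, 2, 3, 5, 8, 12, 20, 50, 100, 200) minimising
the mean KL of the resulting predictive distributions, ties going to
the smallest k. Distances are computed on descriptors standardised to
zero mean and unit variance using training-set statistics, with
zero-variance descriptors dropped. The Mahalanobis covariance inverse
uses an SVD pseudo-inverse (relative singular-value cutoff 1e-9), since
descriptor covariance matrices are routinely rank-deficient; distances
are evaluated in whitened coordinates so neighbour searches stay
vectorised. Nearest-neighbour ties break by ascending training-row
index.

## Learners

Point-prediction models are consumed through an adapter registry over
scikit-learn (random forest with 250 trees and node size 1, RBF-kernel
SVM with cost 2 and γ tuned over {2⁻⁸, 2⁻⁷, 2⁻⁶}, distance-weighted
k-NN with cross-validated k, PLS, ridge, and a mean-predictor
baseline). Bagged ensembles train each member on a with-replacement
resample the size of the training set (default 100 members; a random
forest is already such an ensemble); member spread uses the sample SD
(denominator B−1). The test suite exercises the framework with cheap
deterministic learners (ridge, 1-NN, mean) so no heavy training is
needed.

## Temporal protocol

The harness splits a compound series at two dates: everything earlier
is the initial training set, the next window (typically a quarter) is
the parameterization test set, and the remainder is cut into calendar
months. Error-method parameters (m, c, k, uniform RMSEs) are fitted
once on the parameterization set with the initial model and frozen.
For each month the model — and every training-set-dependent estimator
component: scaled descriptors, CV residual tables, bagged ensembles,
the EM error model — is rebuilt on all data preceding that month, with
hyperparameters re-tuned; the frozen calibration parameters are reused
unchanged, including the TS RMSE (not refreshed monthly). Training
sets larger than 35,000 compounds are reduced to the 20,000 most
recent plus a seeded random 15,000 of the rest. Qualified measurements
(">5", "<−1.4") are used numerically with the qualifier retained as
metadata; rows flagged as problematic via the `excluded` column are
dropped before modelling.

## Evaluation diagnostics

- **Binned RMSE**: predictions ranked by σ_pred, cut into bins of a
  configured size (a final partial bin merges into the preceding one);
  per bin, the estimated RMSE aggregates the σ_pred values as a
  root-mean-square (an RMSE is an L2 object, so RMS rather than the
  arithmetic mean) and is compared to the observed residual RMSE with
  a 95% Faber interval, half-width 1.96 · RMSE · √(1/2n).
- **KL-difference profiles**: per-bin mean KL of a variable method
  minus the matched uniform TS method, binned by the variable method's
  σ_pred; negative values are information gains.
- **Normalized errors**: (μ_obs − μ_pred)/σ_pred tested against N(0,1)
  with a one-sample Kolmogorov–Smirnov test, plus histogram data with
  the unit-Gaussian overlay.
- **Probability calibration**: compounds ranked and binned by estimated
  hit probability; per bin the mean estimated probability is compared
  to the observed hit fraction with a 95% central-limit interval,
  flagged reliable only when the bin holds more than 5 hits.

The KL quadrature oracle integrates p·ln(p/q) by the trapezoid rule
over ±12 combined standard deviations with 100,001 points, placing
truncation and discretisation error far below the 1e-6 agreement
tolerance used in tests.

## Synthetic data

The generator emulates a sequential exploration of chemical space:
month-m descriptors are drawn from N(m·drift·u, I) along a fixed random
unit direction u (default drift 0.25 SD/month over 20 descriptors), so
later compounds sit progressively farther from where the initial model
was trained. Each compound's true value is a latent linear response
(unit-variance coefficients; an optional smooth tanh component, off by
default so the planted error structure stays exactly linear) plus a
difficulty deviation with variance `noise_slope · d`, where d is the
Euclidean distance to the initial-month centroid; the defaults
noise_slope = 0.037 and σ_exp = 0.2 match a published
distance-to-error calibration of the form σ_pred = √(0.037·D + 0.04)
for a cell-permeability assay. Measurements add i.i.d. N(0, σ_exp)
single-shot noise; 20% of compounds are measured 2–3 times; 2% of
values carry inequality qualifiers; five QC compounds are measured 200
times each. A ground-truth sidecar records latent values, difficulty
draws, distances and replicate counts so tests can check parameter
recovery (the QC pooling recovers σ_exp within sampling error; the
error regression recovers noise_slope within ±20% end-to-end at
n = 5,000).

The generator does **not** emulate real molecular descriptors,
activity cliffs, assay drift, or non-Gaussian error tails. A passing
suite therefore demonstrates that the machinery is correct under its
own assumptions — heteroscedastic difficulty that genuinely grows with
distance-to-model — not that any particular real assay satisfies them.
The ground truth is D2M-favourable by construction, which is exactly
what the directional tests (variable beats uniform, gains concentrated
in the least-reliable bin) require.

## Problem sizes and numerical choices in the test suite

The drifting fixture used for the end-to-end checks has ~5,000
training, ~1,000 parameterization and ~1,000 test compounds (500 per
month over 14 months), scored with bin size 200 — the bin size used in
published binned-RMSE diagnostics at comparable test-set sizes; with
many smaller bins the location of the largest per-bin gain fluctuates
between the last few bins through sampling noise. Coverage checks use
100,000 simulated predictions; probability-calibration checks use
10,000 compounds in bins of 500. Hypothesis-based property tests run
derandomised. All stochastic stages are seeded, and the acceptance
script derives independent per-stage substreams from a single seed.

## Known limitations

- Endpoint independence is assumed when multiplying profile
  probabilities; correlated endpoints are out of scope.
- The pooled σ_exp is homoscedastic per assay; per-compound
  experimental error models are not supported.
- Only Gaussian predictive distributions are emitted; non-parametric
  distributions would require replacing the closed-form KL with the
  quadrature path.
- Statistical comparison of PD methods across endpoints/months is
  reported descriptively (mean KL), without a mixed-effects
  significance layer.
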