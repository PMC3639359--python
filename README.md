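# qsarpd

**QSAR predictions as Gaussian predictive distributions.**

Property models in drug discovery (LogD, permeability, plasma protein
binding, …) are only useful to a project team if every prediction comes
with an honest error estimate. `qsarpd` treats both experimental
measurements and model predictions as Gaussian probability
distributions — a measurement as N(μ_obs, σ_obs), a prediction as
N(μ_pred, σ_pred) — and provides the machinery to build, score, and use
such *predictive distribution (PD) methods*:

- **Scoring with Kullback–Leibler divergence.** A predictive
  distribution Q is scored against the measurement distribution P with

  D_KL(P‖Q) = ln(σ_q/σ_p) + (σ_p² + (μ_p−μ_q)²)/(2σ_q²) − ½,

  and a PD method is judged by the *mean* KL over a test set: a single
  criterion that rewards accurate predictions *and* accurate error
  estimates. A prediction claiming more precision than the measurement
  itself is penalised, so every σ_pred is floored at the assay's
  experimental error.
- **Experimental error from QC compounds.** The single-shot assay error
  σ_exp is pooled from quality-control replicates,
  σ_exp = √(Σᵢⱼ (QCᵢⱼ − mean(QCᵢ))² / Σᵢ Nᵢ), and a compound measured N
  times gets σ_obs = σ_exp/√N.
- **Error-estimation methods.** Uniform methods (test-set RMSE `TS`,
  double-loop cross-validation RMSE `CV`) give every query the same
  error. Variable methods assign compound-specific errors from a
  reliability index: distance-to-model (`D2M-EUC`, `D2M-MD`), local
  error of the k nearest neighbours (`LE`, corrected `LEC`), bagged
  ensemble variance (`BV`, corrected `BVC`), or a second error-model
  regressor (`EM`). Calibrated methods map the score s to
  σ_pred(s) = √(m·s + σ_exp²) with the intercept pinned so that zero
  distance means experimental precision.
- **Temporal validation.** A growing-window harness splits compound
  series chronologically, parameterises the error methods once on a
  held-out quarter, freezes m, c, k, and retrains the models monthly —
  the way such models are actually deployed.
- **Target-profile probabilities.** Predictive distributions convert
  directly into the probability that a compound hits a property profile
  (e.g. LogD in 2.5–3.5 **and** permeability > −5), via Gaussian CDFs
  multiplied across endpoints, with binned calibration plots to verify
  the probabilities.

Proprietary assay data are not required anywhere: a synthetic-data
module generates temporally drifting compound series with
distance-dependent difficulty, replicates, and QC compounds, so the
whole pipeline is testable end to end.

## Worked example

Three candidate models predict a compound whose measurement
distribution is P = N(0, 1):

```python
from qsarpd import GaussianDist, kl_gaussian

p = GaussianDist(0.0, 1.0)
for name, q in [("Q1", GaussianDist(2.5, 1.5)),
                ("Q2", GaussianDist(2.0, 1.5)),
                ("Q3", GaussianDist(2.5, 3.0))]:
    print(name, f"residual={abs(p.mu - q.mu):.1f}", f"KL={kl_gaussian(p, q):.4f}")
```

```
Q1 residual=2.5 KL=1.5166
Q2 residual=2.0 KL=1.0166
Q3 residual=2.5 KL=1.0014
```

Q2 is the most *accurate* model (residual 2.0 vs 2.5), but its claimed
error is too small to cover the truth; Q3, less accurate but honest
about its uncertainty, carries the lowest divergence. This is the
entire point of scoring predictive distributions instead of point
predictions: over- and under-confidence are penalised on the same scale
as inaccuracy.

Converting a prediction to a target-profile hit probability:

```python
from qsarpd.target_profile import hit_probability
hit_probability(GaussianDist(0.0, 1.0), -1.0, 1.0)  # -> 0.6827
```

## Command line

```bash
qsarpd simulate --outdir data --seed 1            # synthetic dataset
qsarpd run --data-dir data --config config.yaml --outdir out
qsarpd evaluate --predictions out/predictions.csv --bin-size 200
qsarpd profile --predictions out/predictions.csv --lower 2.5 --upper 3.5
qsarpd calibrate-errors --table scores.csv --sigma-exp 0.2
```

`run` executes the full temporal protocol and reports the mean KL per
PD method along with every frozen calibration parameter.

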