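# subcox

Bayesian Cox regression with graph-structured variable selection across
predefined patient subgroups.

## The problem

Molecular risk models (gene or protein expression vs. a survival endpoint)
are usually built per cohort. When cohorts are small, a per-cohort
("Subgroup") model loses power; naively pooling heterogeneous cohorts
("Pooled") biases effects that differ between them. `subcox` implements a
hierarchical Bayesian Cox model that fits **one risk model per subgroup**
while **borrowing strength between subgroups through a jointly inferred
graph**: it identifies prognostic covariates, estimates their effects per
subgroup, and learns a network linking genes within subgroups and the same
gene across subgroups.

## The model

For subgroup *s* with covariates X_s (n_s × p) and right-censored survival
data, the hazard is h(t|x) = h_0s(t) exp(β_s′x). The likelihood has three
parts, combined over subgroups:

- **Grouped-data Cox likelihood** over a partition of the time axis at the
  unique event times, with interval baseline increments h_{s,g} carrying
  independent gamma priors G(a_0 ΔH*, a_0) centred on a Weibull guess
  H*(t) = η_s t^κ_s fitted to the training survival data (a_0 = 2).
- **Spike-and-slab selection prior** on each coefficient:
  β_{s,i} | γ_{s,i} ~ (1−γ) N(0, τ²) + γ N(0, c²τ²) with τ = 0.0375,
  c = 20 (slab sd 0.75, central 95% interval ±1.47).
- **Markov random field prior** on the pS selection indicators,
  p(γ|G) ∝ exp(a 1′γ + b γ′Gγ), over a joint graph G with gene–gene edges
  within each subgroup and same-gene edges between subgroups (defaults
  a = −4, b = 1; with an empty graph the marginal inclusion probability is
  expit(−4) ≈ 0.018). The graph itself is inferred: each within-subgroup
  block pairs a Gaussian graphical model for X_s with a continuous
  spike-and-slab prior on the precision matrix (sds ν0 = 0.1 / ν1 = 10,
  exponential diagonals, edge prior π_G = 2/(p−1)), sampled with a
  PD-preserving block Gibbs sweep.

Posterior computation is MCMC (block Gibbs for Ω, Gibbs for G and γ,
adaptive random-walk Metropolis–Hastings for β plus a joint add/delete move,
gamma full conditionals for h). Four variants are available:
`coxbvs_sl` (full model), `sub_struct` (no cross-subgroup edges),
`subgroup` and `pooled` (independent Bernoulli(π_γ = 0.02) selection
priors — the standard baselines). Chains feed posterior selection
probabilities, median-probability-model (MPM) and model-averaged (BMA)
coefficient estimates, posterior edge probabilities, and IPCW
(integrated) Brier-score prediction evaluation on held-out data.

A synthetic-data engine generates the study designs used to validate all of
this: block-correlated multivariate-normal expression, Weibull survival
calibrated to printed Kaplan–Meier anchors (two-point inversion of
S(t) = exp(−η t^κ)), subgroup-specific effect patterns, and plasmode
resampling of a real expression matrix.

## Worked example

Simulate the two-subgroup gene-panel design (p = 20, n = 100 per subgroup;
genes 1–3 prognostic only in subgroup 1, genes 7–9 only in subgroup 2,
genes 4–6 shared), fit the full model, and evaluate:

```python
import numpy as np
from subcox import *

train, test, truth = make_scenario_I(ScenarioConfig(p=20, n_per_subgroup=100, seed=1))
train_std, params = standardize(train, "per_subgroup")
test_std = apply_standardization(test, params)

chain = run_chain(train_std, ChainConfig(variant="coxbvs_sl",
                                         n_iter=2000, burn_in=1000, seed=1))
summary = summarize(chain)
for s, label in enumerate(summary.labels):
    top = np.argsort(summary.selection_prob[s])[::-1][:6]
    print(f"subgroup {label}: mean model size {summary.mean_model_size[s]:.1f}")
    for i in top:
        print(f"  {summary.gene_names[i]:>7}  P(select)={summary.selection_prob[s, i]:.3f}"
              f"  beta|select={summary.conditional_mean_beta[s, i]:+.2f}")

selected, coeffs = median_probability_model(summary)
res = evaluate_model(coeffs[0], chain.boundaries[0], summary.mean_h[0],
                     test_std[0].covariates, test_std[0].time, test_std[0].event,
                     train_std[0].time, train_std[0].event)
print(f"subgroup S1 MPM integrated Brier score: {res.ibs:.3f} (t* = {res.t_star:.2f})")
```

Output:

```
subgroup S1: mean model size 6.0
    gene4  P(select)=1.000  beta|select=-1.19
    gene5  P(select)=1.000  beta|select=-0.95
    gene6  P(select)=1.000  beta|select=-1.11
    gene2  P(select)=0.941  beta|select=+0.92
    gene1  P(select)=0.931  beta|select=+0.76
    gene3  P(select)=0.924  beta|select=+0.74
subgroup S2: mean model size 6.0
    gene5  P(select)=1.000  beta|select=-1.08
    gene6  P(select)=1.000  beta|select=-0.82
    gene4  P(select)=0.999  beta|select=-0.73
    gene8  P(select)=0.964  beta|select=+1.16
    gene7  P(select)=0.944  beta|select=+0.84
    gene9  P(select)=0.918  beta|select=+0.65
subgroup S1 MPM integrated Brier score: 0.139 (t* = 5.99)
```

Each subgroup recovers exactly its six true prognostic genes (true effects
±1) with high selection probability and conditional posterior means near the
truth, while the twelve noise genes stay near the prior inclusion level. The
integrated Brier score summarises out-of-sample prediction error over
[0, t*] (0.25 is an uninformative coin-flip; lower is better).

A command-line interface mirrors this workflow:

```bash
subcox simulate --p 20 --n 100 --seed 1 --out-dir data/
subcox fit      --survival data/train_survival.csv --covariates data/train_covariates.csv \
                --model coxbvs_sl --iters 20000 --burnin 10000 --out chain.npz
subcox summarize --survival ... --covariates ... --out summary.csv
subcox evaluate  --train-survival ... --test-survival ... --out ibs.csv
```

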