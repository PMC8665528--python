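# Methods

## Model

Data consist of S predefined patient subgroups. For patient m of subgroup s
we observe a covariate vector x ∈ R^p (continuous molecular measurements,
standardized), an observed time t̃ = min(T, C) > 0 and an event indicator
δ = 1(T ≤ C). The joint likelihood factorizes over subgroups into a survival
part and an expression part.

**Survival part.** The time axis of each subgroup is partitioned at its
unique observed event times, 0 = c_0 < c_1 < … < c_J, with a final boundary
max(observed time)·(1 + 1e−6) appended whenever the largest observed time
reaches the last event boundary, so c_J strictly exceeds every observed
time. A time t̃ belongs to I_g = (c_{g−1}, c_g]; the risk set R_g contains
subjects with t̃ > c_{g−1} and the failure set D_g the events inside I_g.
With baseline-hazard increments h_g = H_0(c_g) − H_0(c_{g−1}) the
grouped-data likelihood is

    ∏_g exp(−h_g Σ_{k∈R_g−D_g} e^{β′x_k}) ∏_{l∈D_g} (1 − e^{−h_g e^{β′x_l}}),

which handles tied event times without approximation (subjects failing in
the same interval simply share a failure set). The gamma-process prior on
H_0 makes the increments independent: h_{s,g} ~ G(a_0 ΔH*_{s,g}, a_0) with
H*(t) = η_s t^{κ_s}. (η_s, κ_s) are estimated once per subgroup by a
covariate-free censored Weibull fit (via lifelines, reparameterized to the
cumulative-hazard form); a_0 = 2 by default and weighs the parametric guess
against the data.

**Selection part.** Coefficients carry the spike-and-slab mixture
β_{s,i}|γ_{s,i} ~ (1−γ)N(0, τ²) + γN(0, c²τ²), τ = 0.0375, c = 20 — so
"excluded" covariates are shrunk hard rather than removed, and the slab
admits hazard ratios up to about e^{1.47} per sd at 95% prior probability.
The pS indicators carry the MRF prior p(γ|G) ∝ exp(a 1′γ + b γ′Gγ) over a
joint adjacency G: arbitrary gene–gene edges within a subgroup, only
same-gene edges between subgroups. Each edge whose endpoints are both
selected adds 2b to the log-prior (symmetric adjacency), so selection
propagates along the graph — within pathways, and across cohorts for genes
prognostic in several of them. a controls sparsity (empty-graph marginal
inclusion expit(a); a = −4 ⇒ 0.018); b1 (within) and b2 (between) split the
single b of the base model; the Sub-struct variant is b2 = 0 with the
cross-subgroup block empty. The normalizing constant of the MRF prior is
never computed: a and b are fixed, so it cancels from every Gibbs ratio.

**Graph part.** X_s is modelled as mean-zero multivariate normal with
precision Ω_ss; off-diagonal precision entries get continuous spike/slab
normals (sd ν0 = 0.1 absent, ν1 = 10 present), diagonals Exp(λ/2), λ = 1,
restricted to the PD cone; edges are Bernoulli(π_G) a priori with
π_G = 2/(p−1) (clipped to ≤ 0.5 for tiny panels; a named case-study preset
ships ν0 = 0.6, ν1 = 360, a = −1.75, b = 0.5, π_γ = 0.2 for protein-panel
plasmode analyses). No cross-subgroup precision entries exist — the
expression likelihood factorizes over subgroups and subgroup similarity
enters only through the MRF prior.

## Posterior computation

A single seeded RNG stream drives one Gibbs sweep per iteration, in fixed
order (reproducible bit-for-bit):

1. **Ω_ss** per subgroup: column-wise block Gibbs. For column j, the
   off-diagonal block is N(−C s_12, C), C = [(s_jj + λ)Ω_11^{−1} +
   diag(ν_g^{−2})]^{−1}, and the transformed diagonal v = ω_jj −
   u′Ω_11^{−1}u is G(n/2 + 1, (s_jj + λ)/2); the update is a diffeomorphism
   of the PD cone, so positive definiteness is preserved exactly.
2. **G**: within-subgroup edges from odds
   π_G N(ω|0, ν1²) e^{2b1 γ_i γ_j} : (1−π_G) N(ω|0, ν0²); cross-subgroup
   edges from expit(logit(π_G) + 2b2 γ_{r,i} γ_{s,i}). These conditionals
   are validated against brute-force enumeration of the unnormalized joint
   in the tests (the G-dependence of the MRF normalizing constant is
   ignored in these ratios, as is standard for this prior).
3. **γ**: sequential Gibbs from w1/(w0 + w1), w1 = N(β|0, c²τ²)·exp(a +
   2b1 Σ_j γ_{s,j} g_{ss,ij} + 2b2 Σ_r γ_{r,i} g_{rs,ii}), w0 = N(β|0, τ²)
   (Bernoulli variants replace the exponent by logit(π_γ)). This is
   followed by one **add/delete Metropolis sweep** proposing
   (γ_{s,i}, β_{s,i}) jointly, with the coefficient drawn fresh from the
   proposed mixture component; the prior and proposal densities cancel and
   the acceptance ratio reduces to the likelihood ratio times the
   conditional prior odds. The move leaves the posterior invariant; it
   exists because a random walk crosses the spike/slab modes only rarely,
   which at desk-scale chain lengths would leave weak-marginal-signal
   blocks (see below) unexplored.
4. **β**: per-coefficient random-walk MH (3 substeps per sweep by default),
   acceptance = grouped-likelihood ratio × spike/slab prior ratio at the
   current indicator. Proposal scales start at 0.1 and adapt per coefficient
   in 100-iteration windows (×1.1 if acceptance > 0.44, ×0.9 if < 0.23),
   frozen after burn-in to preserve ergodicity.
5. **h**: each increment from its (approximate) gamma full conditional
   G(a_0 ΔH* + d_g, a_0 + Σ_{R_g−D_g} e^{β′x}).

Starting values are an empty model: G = 0, Ω = I, γ = 0,
β ~ U[−0.02, 0.02], h ~ G(1, 1). Default run length is 20 000 iterations
with 10 000 burn-in; the test profile uses 2 000 / 1 000. The per-iteration
Cox log-likelihood is stored for model ranking and diagnostics
(autocorrelation, running means, batch-means MC standard errors).

**Correctness strategy.** Every conditional with a tractable counterpart is
tested against an independent route: MRF γ-conditionals and graph
g-conditionals against enumeration of the joint (≤ 2^6 configurations,
1e−10); the grouped likelihood against per-subject hand computation
(1e−12); the p = 1 block Gibbs against its conjugate closed form
(Kolmogorov–Smirnov at 5 000 draws); and the combined (γ, β) kernel against
brute-force posterior enumeration with β integrated by Gauss–Hermite
quadrature on a 2-gene instance with h fixed (3 MC standard errors). With a
flat likelihood (all-zero covariates) the chain provably samples the prior,
and the tests confirm sd(β) ≈ τ and mean(γ) ≈ π_γ.

## Posterior summaries, selection and prediction

After burn-in removal the package reports per-gene posterior selection
probabilities, marginal and conditional (on γ = 1) coefficient means and
sds, and the mean model size m*. Selection rules: (i) mean-model-size —
round m* half-to-even and take that many genes by selection probability
(ties by gene index); (ii) median probability model — probability strictly
above 0.5, coefficients = marginal posterior means; (iii) BMA — average β
over the iterations belonging to the 100 distinct γ-patterns with the
highest attained joint log-likelihood (a per-iteration ranking is available
behind a flag; "model" is read as a distinct γ-pattern because ranking raw
iterations conflates model quality with within-model parameter noise).

Prediction uses the proportional-hazards plug-in Ŝ(t|x) =
exp(−Ĥ_0(t) e^{β′x}) with posterior-mean baseline increments accumulated
over the training partition (linear interpolation within intervals, no
extrapolation past the last boundary). Accuracy is the IPCW Brier score
BS(t) = n^{−1} Σ ŵ_m(t)(1(t̃_m > t) − Ŝ(t|x_m))², ŵ_m(t) =
1(t̃_m ≤ t)δ_m/Ĉ(t̃_m) + 1(t̃_m > t)/Ĉ(t), with Ĉ the Kaplan–Meier
estimator of the censoring distribution fitted on training data (test-based
Ĉ configurable); subjects censored before t get weight zero, and with no
censoring the score reduces exactly to the mean squared error of the
survival indicator. The integrated Brier score is the trapezoidal time
average over [0, t*]; the evaluation grid is the unique test event times and
t* defaults to the 90th percentile of observed test times (clipped to the
training follow-up).

## Synthetic-data engine

The generator reproduces the two validation designs end to end.

**Gene-panel design** (two subgroups): expression is multivariate normal
with unit variances; the standardized precision has off-diagonals +0.5
inside three 3-gene blocks (genes 1–3, 4–6, 7–9) and zeros elsewhere, then
Σ = Ω^{−1} is rescaled to unit diagonal. The resulting partial correlations
are −0.5: a 3-block with partial correlations exactly +0.5 (precision
off-diagonal −0.5) is singular — eigenvalue 0 of 1.5I − 0.5J — so the
magnitude is matched with the sign that keeps the matrix PD, and the signed
request raises an informative error. Effects are β_1 = (1,1,1,−1,−1,−1,0,…)
and β_2 = (0,0,0,−1,−1,−1,1,1,1,0,…): genes 1–3 and 7–9 subgroup-specific,
4–6 shared, the rest noise. Event times follow Bender-style inverse
sampling T = (−log U/(η_s e^{xβ}))^{1/κ_s}; (η_s, κ_s) are obtained by
exact two-point inversion of exp(−η t^κ) through Kaplan–Meier anchors of
two cancer cohorts — (57%, 42%) at 3/5 years for subgroup 1 giving
η ≈ 0.221, κ ≈ 0.850, and (75%, 62%) for subgroup 2 giving η ≈ 0.0965,
κ ≈ 0.994 (the cohort-to-subgroup assignment is a package choice; the
anchors do not dictate one). Censoring times are drawn from the same
Weibull *without* the covariate term (non-informative censoring), which
yields ≈ 50% censoring when effects are near zero on standardized data; a
covariate-matched alternative (exactly 50% in expectation always) is
available behind a flag. Train and test replicates are i.i.d. from the same
law; defaults are p = 20 and n = 100 per subgroup.

**Plasmode design**: a supplied real expression matrix keeps its empirical
correlation structure; its rows are split into two equal subgroups and only
the outcome is simulated, with a bundled 20-protein effect pattern
(β_1 = (2,2,2,0,0,0,−1.5,1.5,−2,−2,−2,0×9), β_2 =
(0,0,0,2,2,2,1.5,−1.5,−2,−2,−2,0×9)) in which groups of phospho-sites or
isoforms of one protein share an effect. Because no real protein data ships
with the package, `fabricate_protein_matrix` provides a clearly-labelled
synthetic stand-in: 212 × 20 Gaussian columns in which same-protein groups
load on a shared latent factor (within-group correlation ≈ 0.6). It
emulates the correlation *structure* of a phospho-protein panel, not any
real measurements.

What the generator does not emulate: non-Gaussian expression marginals,
batch effects, informative censoring, covariate-dependent censoring, or
model misspecification of the proportional-hazards form. Tests passing on
these designs therefore demonstrate internal correctness and the claimed
qualitative behaviours, not robustness to those real-data features.

## Numerical choices and degenerate inputs

Likelihood evaluation is in the log domain with log1p(−exp(−x)) for the
failure terms; risk-set sums exploit the nestedness of risk sets (reverse
cumulative sums), making one evaluation O(n + J). Sample sds use
denominator n − 1; test data are always standardized with training
parameters. Subgroups with no events are rejected (the model is undefined);
zero-variance covariates are rejected by name; non-PD precision inputs
raise; conditional coefficient summaries of never-selected genes are NaN
and flagged. Stratified splitting requires at least two members per
(subgroup × event) stratum and rounds stratum counts to the nearest
integer. m* rounds half-to-even.

## Desk-scale validation and limitations

The behavioural test suite runs at a deliberately small problem size —
p = 20, n = 100 per subgroup, 2 000 iterations with 1 000 burn-in, chosen
so the full suite completes on a single CPU in minutes. At this scale the
full model reproduces the method's signature behaviour: every truly
prognostic gene outranks the best noise gene in both subgroups, while the
pooled baseline misses subgroup-specific effects. Two caveats are known and
deliberate:

- Within-block correlations make a block's *marginal* signal about a third
  of its conditional effect, so block entry is a nucleation event; the
  add/delete move exists to make nucleation reliable at desk scale. At the
  default 20 000-iteration production profile this is not a concern.
- On zero-effect data the mean posterior selection probability settles near
  0.03 — above the empty-graph prior level expit(−4) ≈ 0.018 — because the
  inferred (nonempty) expression graph combined with b = 1 raises the
  marginal prior inclusion, and at ~50 events the slab/spike evidence
  balance is near-critical. Sampling the joint prior directly (flat
  likelihood) gives ≈ 0.022. Exact agreement with the empty-graph constant
  should not be expected from the full model, and the corresponding strict
  calibration test documents this as a known failure.

Computation is the main scalability limit: the block Gibbs sweep is
O(p⁴) per subgroup per iteration, so panels beyond a few hundred covariates
are out of practical reach, and the model assumes subgroup membership is
known, fixed and unique (no latent clustering, no time-varying covariates,
left truncation or competing risks).
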