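# Methods

## The problem

Diagnostic accuracy studies routinely verify disease status with a gold
standard (biopsy, angiography) only for a subset of subjects, usually those
who tested positive. Restricting estimation to the verified subjects then
biases sensitivity upward and specificity downward — verification bias. This
package estimates the accuracy of two paired tests, singly and combined,
from the full cross-tabulated study (verified diseased `s`, verified
non-diseased `r`, unverified `u` per joint test-outcome cell) under the
missing-at-random (MAR) assumption: the probability of being verified
depends only on the observed test outcomes, `P[V=1 | Y1, Y2, D] =
P[V=1 | Y1, Y2]`.

## Model and posterior

Parameters are the joint outcome probabilities `θ_ij = P[Y1=i, Y2=j]` and
the cell-wise disease probabilities `φ_ij = P[D=1 | Y1=i, Y2=j]`. Under MAR
the likelihood factorises so that, with the improper prior
`∝ Π θ_ij⁻¹ φ_ij⁻¹`, the posterior is

- `φ_ij ~ beta(s_ij, r_ij)`, independently per cell, and
- `θ ~ Dirichlet(m_00, m_01, m_10, m_11)` with `m_ij = s_ij + r_ij + u_ij`.

A uniform prior adds one to every hyperparameter. Draws are exact iid
conjugate samples (Dirichlet via normalised gamma deviates; the gamma rate
constant cancels, we use rate 1), so there is no burn-in and no convergence
question — an intentional simplification relative to general-purpose MCMC
treatments of the same model.

Accuracy per test follows by Bayes' theorem, e.g.
`tpf1 = φ_1.θ_1. / (φ_1.θ_1. + φ_0.θ_0.)`. Combined accuracy uses the
believe-the-positive rule (BP: combined test positive if either test is)
and believe-the-negative rule (BN: positive only if both are):

```
tpf_bp = (φ11θ11 + φ01θ01 + φ10θ10) / P[D=1]      tpf_bn = φ11θ11 / P[D=1]
fpf_bp = Σ (1-φ)θ over the same cells / P[D=0]     fpf_bn = (1-φ11)θ11 / P[D=0]
```

with `P[D=1] = Σ φ_ijθ_ij`. Every fpf denominator is `P[D=0] = 1 − P[D=1]`.

**Marginal construction.** The marginal disease probabilities `φ_1.`, `φ_.1`
are by default sampled as *independent* betas from the row/column-aggregated
counts (`φ_1. ~ beta(s_11+s_10, r_11+r_10)`), although they are functions of
the joint parameters. This replicates the construction under which the
reference results for the lung-cancer worked example were produced.
`marginals="derived"` computes them from the joint draw instead, which is
the coherent choice for simulation studies (the recovery experiment uses
it); the two agree in posterior mean to O(1/n) on real tables.

## Extreme verification bias

If no double-negative subject is ever verified, prevalence is not estimable
and neither are TPF/FPF. Still estimable, as deterministic functions of the
same (φ, θ) draws:

- detection probability `DP = P[Y=1, D=1] = ρ·TPF` per test,
- false referral probability `FRP = P[Y=1, D=0] = (1−ρ)·FPF`,
- the BP:BN ratios `tpf_bp/tpf_bn` and `fpf_bp/fpf_bn`, in which ρ cancels.

The empty double-negative cell makes the improper beta posterior undefined
there; the `add_one` zero-cell policy substitutes `s=r=1` in the offending
cell only. The default policy is to refuse (`zero_fix="error"`), because the
substitution changes the posterior; callers opt in explicitly, and the
substitution is recorded in the hyperparameter provenance notes. The FPF
ratio posterior is strongly right-skewed; the median is the better point
estimate and both are always reported.

## Ordinal tests and ROC areas

For ordinal ratings 1..K (ascending suspicion of disease — this input
convention is required), the same conjugate structure applies over the K²
joint cells. The class-conditional category distributions follow by Bayes:
`α_i ∝ φ_i.θ_i.` (diseased), `β_i ∝ (1−φ_i.)θ_i.` (non-diseased), and the
ROC area is the Mann–Whitney probability with half-credit for ties,

```
A = Σ_{i>j} α_i β_j + ½ Σ_i α_i β_i ,
```

implemented for arbitrary K via cumulative sums (the K=3 closed form is the
special case; a K=2 reduction test cross-checks against the binary TPF/FPF
expression). `auc_from_dirichlet_counts` applies the same kernel to two
independent Dirichlet vectors given directly by their (possibly fractional)
count hyperparameters. Because the kernel is bilinear and the two vectors
independent, the posterior mean equals the plug-in AUC at the Dirichlet
means exactly in expectation — which a test exploits as an analytic oracle.

## IPW imputation and the risk score

Inverse probability weighting rescales each cell's verified counts by the
reciprocal of that cell's verification rate: `s'_c = s_c m_c/(s_c+r_c)`,
`r'_c = r_c m_c/(s_c+r_c)`. Pre-rounding, `s'_c + r'_c = m_c` exactly; for
binary tables the plug-in TPF/FPF from the biased table equal the naive
estimators on the imputed table as an algebraic identity (tested). Rounding
(half away from zero) is applied only when expanding to per-subject records;
unrounded values are the default for computation.

The combined accuracy of two ordinal tests is the ROC area of the risk score
`RS(Y) = P[D=1 | Y]`, a monotone function of the likelihood ratio and hence
ROC-optimal. It is estimated by Bayesian logistic regression on the expanded
records, `logit P[D=1|T1,T2] = b1 + b2·T1 + b3·T2`, with independent
normal(0, sd=100) priors. The sampler is an adaptive random-walk Metropolis
chain on the grouped-binomial likelihood (one term per distinct covariate
pattern — identical likelihood, per-iteration cost independent of study
size). The proposal is multivariate normal with covariance
`(2.38²/3)·Σ̂` from the inverse observed information at the ML fit, and a
global log-scale tuned every 200 burn-in iterations toward 30% acceptance,
frozen afterwards (so the retained chain is a valid fixed-kernel chain).
Defaults: 45,000 retained draws after 5,000 burn-in. Complete separation is
flagged when a posterior coefficient mean exceeds a divergence bound
(default 50 on the logit scale).

Patterns are grouped by exact covariate value, not by rounded risk; patterns
are then ordered by ascending posterior-median risk (ties broken
lexicographically, with a warning) and their diseased/non-diseased counts
fed to the Dirichlet AUC posterior, alongside the deterministic plug-in.

Two AUC variants exist for the two-reader mammography example. The
hyperparameter list distributed with the original analysis (shipped verbatim
as `bugscode4_list.json`, including a 0.125 entry that is evidently a
misprint for 125 and one transposed pair of cells) yields posterior mean
0.8428; the counts computed here from the imputed table in strict risk order
yield a plug-in of 0.8247. Both paths are implemented; the package makes no
claim about which the original authorship intended, and reproduces each from
its own inputs.

## Synthetic data

`generate_table` simulates the assumed data-generating process exactly: per
subject a joint cell from multinomial(θ), disease from Bernoulli(φ_cell),
verification from Bernoulli(v_cell) — MAR by construction since v depends
only on the cell. Implementation draws the per-cell (s, r, u) split as a
multinomial with probabilities (φv, (1−φ)v, 1−v), which is distributionally
identical to the subject-level loop. An optional `v_diseased` override
breaks MAR deliberately, for demonstrating the bias the method corrects.

What the generator does *not* emulate: covariate-driven verification,
continuous test scores, reader drift, or clustering of subjects — so passing
recovery tests demonstrate correctness of the posterior under the model's
own assumptions, not robustness to their violation (except for the explicit
MNAR demonstrations).

`recovery_experiment` covers the binary design: it generates a study, runs
the posterior (derived marginals, so truth and estimand coincide), and
reports 95%-interval coverage of φ, θ and the derived accuracies against the
generating truth. Default experiment conditions: n = 5,000 subjects,
θ = (0.40, 0.25, 0.20, 0.15), φ = (0.10, 0.30, 0.45, 0.80) increasing in
test positivity, verification v = (0.3, 0.5, 0.7, 1.0) increasing in test
positivity — a realistic referral pattern where positives are verified far
more often — and 4,000 posterior draws per replicate. The coverage test runs
100 enumerated seeds and requires ≥ 90/100 per φ cell at nominal 95%.

## Numerical choices

- **Summaries**: sample mean and sd (ddof=1); quantiles by linear
  interpolation between order statistics (type 7) — deterministic and the
  numpy default; MC error by batch means with 50 equal batches, remainder
  draws dropped (the draws are iid, so this is a convention, not a
  necessity).
- **Seeds** are mandatory for every stochastic operation; the CLI and the
  reproduction script derive per-command substreams from the single run seed
  via `SeedSequence`, so adding a command never perturbs another's draws.
- **Zero cells**: refuse by default; `add_one` substitutes 1 for offending
  zero s/r entries only and records it.
- **Degenerate draws**: prevalence 0 or 1 raises; undefined BP:BN ratios
  warn and propagate NaN/inf so the remaining quantities survive.
- **Rounding** for record expansion: half away from zero.

## Limitations

- Two tests only; no conditional-dependence modelling beyond the saturated
  φ_ij parameterisation; no covariates in the binary model.
- No model-based (regression) estimate of verification probability — IPW
  uses the empirical per-cell rate.
- The logistic risk score is linear in the test values; no interactions or
  splines, and no retrospective-design intercept correction.
- Under extreme verification bias, prevalence and absolute TPF/FPF are not
  estimable in principle; the package deliberately refuses to report them.
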