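# Methods

## Model

The observation model for one trait is

    y = mu + u_E + u_g [+ u_gE] + [X beta] + eps,
    u_k ~ N(0, sigma_k^2 K_k),  beta ~ N(0, sigma_beta^2 I),
    eps ~ N(0, sigma^2 I).

Kernels are built once per cross-validation fold:

- `G = M M' / p` on marker dosages centred per column and divided by the
  sample standard deviation (denominator J−1).  Monomorphic markers cannot
  be standardized and are dropped with a warning, adjusting p.  With this
  convention diag(G) averages (J−1)/J, i.e. ~1 for realistic panel sizes.
- `K_g = Z_g G Z_g'`, `K_E = X_E X_E'/I` (NoEC) or
  `X_E (W W'/q) X_E'/I` (EC/FE), `K_gE = K_g ∘ K_E`.
  The I×I covariate kernel is divided by the number of selected covariates
  q, by analogy with the /p in G; the expansion is divided by I.  The
  Hadamard interaction kernel is PSD by the Schur product theorem.
- Kernel constructors enforce symmetry and positive semidefiniteness;
  eigenvalues in (−1e−8·λmax, 0) are treated as numerical noise, anything
  more negative is an error.

## Feature engineering

From q measured covariates the FE set adds, deterministically ordered:
pairwise a+b, a−b, a·b, a/b per unordered pair (one direction per pair;
ratio only when min|denominator| > 1e−12), and per column: 1/x (same
guard), x², and for strictly positive columns √x, ln x, and Box–Cox
(x^λ−1)/λ with λ ∈ {0.25, 0.75, 1.5}.  λ ∈ {−1, 0.5, 2} are excluded by
default because Box–Cox at those exponents differs from the explicit
inverse/sqrt/square columns only affinely, which correlation screening
cannot distinguish; λ = 0 is covered by the log.  Ineligible transforms are
skipped (never shifted) and logged, so outputs are always finite and runs
are reproducible.  Engineering refuses already-engineered input: it is a
single pass.

## Covariate selection

Per fold and trait, each candidate column is scored by the Pearson
correlation between training-set responses and the covariate value of each
observation's environment (observation level — environment-level
correlation on 3–4 training environments is near-degenerate for the
smallest realistic designs).  The cascade walks thresholds 0.5 → 0.4 → 0.3;
the first threshold with at least one |r| ≥ t fixes the set; if none
qualifies the fold trains without covariates (the NoEC kernel is reused and
the fallback is logged).  Absolute correlation is used: a strongly negative
covariate is equally informative for a linear kernel.  Selected columns are
standardized with mean/sd over all I environments — covariates, unlike
responses, are known for the held-out environment and its kernel row must
be built; no response information leaks.  Held-out responses can therefore
influence nothing but the final MSE, which a dedicated test verifies by
mutating them.

## Gibbs sampler

Each kernel is eigendecomposed once (eigenvalues ≤ 1e−10·λmax truncated)
and its effect re-parametrized as independent Gaussian coefficients on the
scaled eigenvectors, making every block draw exact and O(n·r) per sweep.
The coefficient (BRR) block is drawn jointly via Cholesky.  The intercept
has a flat prior.  Missing responses are imputed each sweep (data
augmentation), so prediction-target rows participate in kernels but carry
no likelihood information.

Variance components get scaled-inverse-chi-square full conditionals with
prior df 5.  The explained-variance budget R² = 0.5 · var(y_obs) is split
equally across model terms; each term's prior scale is set on the scale its
design implies — divided by mean(diag K) for kernel terms and by the summed
column variance for the BRR block — following the default prior convention
of the standard Bayesian ridge/RKHS software for this model class.  Without
the diagonal scaling the environment term (diag 1/I) would be shrunk
severely.  The residual prior mode is (1−R²)·var(y_obs).

Chain defaults are 10000 iterations, 1000 burn-in, thinning 5; results are
deterministic given the seed, and per-fold chains use seed + fold index.
Convergence of the residual variance is monitored by a split-chain
potential-scale-reduction factor (warning above 1.1).  For validation the
variances can be pinned (`fixed_variances`), in which case the posterior
mean of each effect equals the closed-form BLUP with the intercept profiled
out by GLS — the test oracle.

Predictions `y_hat` are posterior means of the linear predictor (no
residual draw).  Under the NoEC strategy the BRR predictors have no
covariate block (there are no covariates), so `E+G+BRR`/NoEC coincides with
`E+G`/NoEC; identical model structures within a fold share one fit.

## Evaluation

Leave-one-environment-out: every environment with data for the trait is
held out exactly once (environments with zero observations are excluded
with a warning).  Test MSE per (predictor, trait, fold, strategy); relative
efficiencies RE_NoEC_vs_EC = MSE(NoEC)/MSE(EC) etc., so the chain identity
RE_NoEC_vs_FE = RE_NoEC_vs_EC · RE_EC_vs_FE holds per fold.  "Across" rows
are arithmetic means of per-environment REs — the aggregation that
reproduces the published summary tables; the package-level summary averages
Across REs over traits per predictor (unweighted) and appends an Average
row over predictors.  Reports round REs to 3 decimals; a companion
`*.full.csv` keeps full precision; a JSON sidecar per fold records the
selection (columns, threshold, correlations) for audit.

## Synthetic trials

The generator emulates multi-environment trial structure: markers
Binomial(2, f), f ~ U(0.1, 0.5); genetic values g = M̃α,
α ~ N(0, var_geno/p); i.i.d. standard-normal covariates per environment;
interaction and residual i.i.d. normal; an optional fraction of
(environment, genotype) cells dropped for unbalance.  The environment
effect mixes a covariate-driven signal (90% of variance) with independent
noise and is standardized so its realized variance equals `var_env`
exactly.  Signal scenarios: `linear` (random linear combination of the
informative covariates), `product` (product of the first two — a signal
pairwise feature engineering can linearize but raw-covariate selection
cannot), `none` (covariate-independent).  Defaults: 100 genotypes, 5
environments, 1000 markers, 20 covariates, variances (env, geno, gE,
resid) = (1, 1, 0.5, 1), mean 10.

What the generator does *not* emulate: linkage disequilibrium, weather-like
autocorrelation or units in covariates, non-additive genetic architecture,
heterogeneous error variances.  Passing tests show the pipeline's
statistical machinery is correct under the assumed model, not that FE will
help on any particular real dataset.

## Test problem sizes and known behaviour

Validation suites use desk-scale designs chosen to keep each property
measurable: sampler-vs-BLUP at n = 50; variance recovery at J = 100, I = 5
with components stated on the observation scale (σ_k²·mean diag K_k), where
20-replicate recovery rates are 85–100% within ±40% — the residual misses
on the environment term reflect χ²₅-level realized-draw noise from having
only five environments, which no estimator can remove.  The FE-benefit and
null simulations use J = 50, I = 8, q = 20 with var_env = 2 (environment
variance dominant, matching published variance-component tables; the
product scenario also needs it for the engineered column to clear the 0.5
screen at the observation level).

One known behaviour surfaced by the null simulation (environment effects
independent of all covariates): mean RE_NoEC_vs_EC and RE_NoEC_vs_FE stay
near 1, but mean RE_EC_vs_FE is systematically above 1 (~1.6 under these
conditions).  The threshold cascade stops at the first threshold with at
least one qualifying column, so under a null EC selects very few spurious
covariates — a high-variance, nearly rank-one environment kernel that can
badly mislead single folds — while FE selects many of its ~900 candidates,
averaging to a near-neutral kernel.  The fold-MSE ratio is then heavy-tailed
in EC's disfavour.  This is a genuine property of the selection cascade
under model misspecification, worth knowing before interpreting small
EC-vs-FE gains on real data.

## Limitations

Single-trait models only; no marker QC/imputation (inputs must be complete
dosages); no pedigree, Gaussian or factor-analytic kernels; no
multiple-testing control on the correlation screen; Pearson correlation is
deliberately not offered as an accuracy metric (MSE and RE only).
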