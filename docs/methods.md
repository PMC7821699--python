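# Methods

## Model

`conga` fits a pairwise Markov random field to an n x P matrix of
non-negative integer counts (rows = independent replicates, columns =
nodes).  The joint pmf of one replicate X = (X_1, ..., X_P) is

    Pr(X) ∝ ∏_j (λ_j^{X_j} / X_j!) · exp( − Σ_{j<l} β_jl F(X_j) F(X_l) ),

with the bounded, strictly increasing transform F(x) = (arctan x)^θ.
Because F is bounded by U = (π/2)^θ, the joint pmf is normalizable for
any sign pattern of the edge coefficients β_jl — unlike the Poisson
auto-model, which admits only non-positive dependence.  β_jl = 0 is
equivalent to conditional independence of nodes j and l; the estimated
graph is the support of β.  The normalizing constant A satisfies

    exp(Σ_j λ_j − U² Σ_{j<l}|β_jl|) ≤ A ≤ exp(Σ_j λ_j + U² Σ_{j<l}|β_jl|),

exposed in log space by `normalizing_constant_bounds`.

The rates are replicate-specific random effects λ_tj ~ D_j with a
Dirichlet-process prior D_j ~ DP(M_j · Gamma(a, b)) and
M_j ~ Gamma(c, d).  The DP clusters replicates within each column,
letting marginal count distributions be overdispersed or multimodal
relative to the Poisson.

### Transform exponent θ

θ is chosen before sampling by covariance matching: minimize
‖cov((arctan X)^θ) − cov(X)‖_F over θ ∈ [0.1, 10] (coarse geometric
grid, then bounded scalar refinement, so a non-unimodal objective is
still handled).  This puts F(X) on the covariance scale of X so that β
behaves like a precision-matrix entry.  Constant columns carry no
signal and are dropped from the objective with a warning.

## Inference

The joint normalizing constant is intractable, so inference targets a
pseudo-posterior: the product over replicates and nodes of truncated
node-conditional likelihoods

    P_B(x_tj | x_t,−j) ∝ exp( x_tj log λ_tj − log x_tj! − F(x_tj) η_tj ),
    η_tj = Σ_{l≠j} β_jl F(x_tl),

renormalized over {0, ..., B} (default B = 100), times N(0, ν₃) priors
on each β_jl and the DP prior on the rates.  The truncated conditional
is treated as a proper pmf, which keeps every Metropolis–Hastings
ratio exact for the surrogate model; `truncation_error_bound` gives
the analytic distance to the untruncated conditional,
exp(λ)·P(Pois(λ) > B)·exp(−Σ_{β_jl<0} β_jl (π/2)^θ (arctan x_tl)^θ),
which is numerically zero at B = 70 already for λ ≤ 5.  Counts above B
raise an error rather than being clipped.

### MCMC sweep

One outer iteration updates, in fixed order:

1. **Rate reassignment** (collapsed Gibbs, Neal 2000 Algorithm 8).
   For each (t, j), existing rates in column j are weighted by the
   full truncated conditional likelihood of x_tj (normalizers memoized
   over the column's distinct values) and the fresh-draw branch is
   represented by 3 auxiliary rates drawn from the Gamma(a, b) base
   measure; a singleton's current value occupies the first auxiliary
   slot.  The move is exact — no Metropolis correction.  Two cheaper
   historical variants (plain-Poisson weights with a shrunk
   conjugate-proposal MH fresh draw; weight semantics `'predictive'`
   or `'density'`) are kept behind `ChainConfig.reassign_mode`.
2. **Cluster remix.**  Each distinct rate in a column is resampled
   given all its members by a log-scale random-walk MH step with
   standard deviation 2.4/√(a + Σ member counts).  Without this move
   shared rates can only ever originate from single-observation
   proposals and settle at marginal rather than conditional-posterior
   levels, which biases the edge coefficients.
3. **Concentrations.**  δ ~ Beta(M_j, n), then
   M_j ~ Gamma(c + U_j, d − log δ) with U_j the number of distinct
   rates in column j (the usual augmentation update).
4. **Edge rows.**  The proposal geometry comes from a Gaussian
   surrogate in which the column-standardized F(X) has precision Ω
   with off-diagonals β and a diagonal frozen at the reciprocal sample
   variance (≡ 1 after standardization).  For row l,
   C = ((s_ll + γ) Ω_{−l,−l}^{-1} + I/ν₃)^{-1} and m = −C s_{l,−l},
   where s is the gram matrix of the standardized transform.  With
   probability 0.2 the move is an independence draw from MVN(m, C)
   with its exact Gaussian density correction; otherwise it is a
   symmetric preconditioned random walk cur + K2·chol(C)·z (no
   correction).  Both kernels leave the pseudo-posterior invariant;
   because m and C involve only Ω_{−l,−l}, forward and reverse share
   them.  The surrogate precision is eigenvalue-floored at 1/ν₃
   because the chain may visit β values for which Ω_{−l,−l} is
   indefinite.  On frozen-rate models this kernel's stationary law
   matches an independent random-walk MH and direct quadrature of the
   pseudo-posterior to Monte-Carlo accuracy; with the DP forced to a
   single cluster, the full joint (β, λ) chain matches a parametric
   shared-rate oracle.

K2 is adapted multiplicatively toward a 20–40% acceptance rate in
batches of 50 sweeps during burn-in, then frozen, so the post-burn-in
chain is time-homogeneous.  K1 (legacy fresh-draw shrinkage) adapts
upward only, since acceptance is monotone increasing in K1 for that
independence-style proposal.  All randomness is pre-drawn from a
single `numpy.random.Generator`; identical seeds give bit-identical
draws.

### Initialization

β starts at the ridge-regularized precision of the standardized
transform, soft-thresholded at 2/√n (≈ two standard errors of a null
partial correlation), so noise-level entries start at zero; a cold
start at zero needs far longer burn-in at larger P
(`ChainConfig.warm_start=False` restores it).  Rates start collapsed,
one shared value per column at the base-measure posterior mean.

### Defaults

| parameter | default | meaning |
|---|---|---|
| ν₃ | 100 | prior variance of each β_jl (weakly informative) |
| γ | 5 | ridge term of the surrogate proposal covariance |
| a, b | 1, 1 | Gamma base measure of the DP |
| c, d | 10, 10 | Gamma prior on each concentration M_j |
| B | 100 | truncation of the conditional normalizer |
| iterations / burn-in | 10000 / 5000 | outer sweeps |
| level | 0.95 | credible level for edge selection |

## Edge selection and comparison

An edge (j, l) is included iff the equal-tailed 95% credible interval
of β_jl (from the stored draws) excludes zero; equal-tailed intervals
are used because they are the simplest reproducible convention.  The
significance measure S_jl = |0.5 − P(β_jl > 0)|/0.5 ∈ [0, 1] equals 1
under posterior sign certainty.  Cross-condition comparison pairs
draws by index across two independent chains (valid since the chains
are independent), forms Δ_jl = β^s_jl − β^{s'}_jl, flags pairs whose
interval for Δ excludes zero, and reports the percentage of unflagged
pairs as graph similarity.  Recovery against a known truth is scored
by p1 (falsely connected / truly absent pairs) and p2 (falsely
unconnected / truly present pairs), both over unordered pairs.

## Synthetic data

Two generators:

* **Gaussian-copula Poisson** (the benchmark): Z ~ MVN(0, Ω⁻¹),
  U = Φ(Z), Y = Q_Pois(λ)(U) columnwise with the left-continuous
  quantile function.  A zero off-diagonal of the latent precision Ω
  implies conditional independence of the count columns while the
  marginals stay exactly Poisson(λ); marginals can be multimodal when
  Ω is dense.  The benchmark precision has ⌈0.1·P(P−1)/2⌉ edges with
  weights of random sign, magnitude uniform in [0.3, 0.6], and
  diagonals set to the absolute row sum plus a margin of 0.5 (strict
  diagonal dominance guarantees positive definiteness; the margin was
  fixed once so that latent partial correlations fall in the
  0.25–0.5 range standard in graphical-model simulation studies).
  Default Poisson mean 5, n = 100.
* **Enumeration oracle**: the model's own joint pmf enumerated exactly
  on a truncated lattice (P ≤ 3), used for exact sampling and for
  conditional-independence and normalization checks.

What the copula data do *not* emulate: the counts are marginally
Poisson (no overdispersion), the latent dependence is elliptical, and
the data are not generated from the fitted model class — so benchmark
results measure robustness of the graph estimate under
misspecification, not calibration of the posterior itself.

## Scaled-down study sizes

The packaged acceptance runs use 10 replications at P = 10 and 5 at
P = 30 (n = 100), each with 2000 burn-in plus 2000 kept sweeps, and 20
replications for the P = 3 recovery study; these sizes were chosen to
keep a complete reproduction on a single workstation core while
leaving Monte-Carlo error well below the effect sizes of interest.

## Known limitations

* The pseudo-posterior is not a calibrated posterior: every pair
  enters two node conditionals, so credible intervals for β are
  systematically narrower than the sampling variability of the
  pseudo-likelihood estimator (on pure-null data roughly 20% of pairs
  are falsely selected at the 95% level rather than 5%).  False-positive
  proportions on the copula benchmarks are correspondingly higher than
  a calibrated procedure would give; false-negative proportions are
  near zero.
* Because F is uncentered, a nonzero β_jl also shifts node means (an
  intercept-like channel).  When the Gamma(a, b) base measure
  conflicts with the data's rate scale, negative edge coefficients can
  absorb part of the mismatch, tilting null edges; choosing a, b
  compatible with the observed rates mitigates this.
* The equal-tailed interval rule applies no multiplicity adjustment
  across the P(P−1)/2 pairs.
* Fits require max(count) ≤ B; extremely heavy-tailed columns need a
  larger B, with quadratic cost in the scan width of the normalizer.
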