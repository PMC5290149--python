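# Methods notes

This note documents the models, the simulator, the numerical choices and
the limitations of `spatialsort`, in the spirit of a statistical methods
appendix. Nothing here reports an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The dispersal model

Net displacement magnitudes are modelled as Poisson-inverse-Gaussian (PIG)
counts: a Poisson whose rate is drawn from an inverse-Gaussian density.
We parameterize by the mean ξ (patches) and a dimensionless shape ω, with
variance ξ(1 + ξ/ω). This is the Sichel distribution with index fixed at
−1/2; small ω gives heavy tails (excess kurtosis beyond what a negative
binomial can reach), which matters because rare long-distance movers
dominate invasion fronts. The mixing density consistent with this
parameterization is inverse-Gaussian with mean ξ and IG shape ξω — the
identity used both for exact sampling (`rng.wald` + `rng.poisson`) and for
the quadrature oracle in the tests.

The pmf is evaluated in log space by a two-term forward recursion derived
from the Bessel-K recurrence (with L = ξω, z² = ω² + 2L):

    p₀    = exp(ω − z)
    p₁    = (L/z)·p₀
    pₖ₊₁  = [L(2k−1)·pₖ + L²·pₖ₋₁/k] / (z²(k+1))

All recursion coefficients are positive, so `logaddexp` carries it without
cancellation; the implementation agrees with direct Bessel-function
evaluation to <1e−8 relative error where the latter is finite and stays
finite at (ξ=50, ω=0.01, k=500) where it is not.

**The signed kernel K.** On the landscape, displacement is symmetric:
K(0) = PIG(0) and K(x) = PIG(|x|)/2 for x ≠ 0. Halving only the nonzero
classes is required for K to sum to one — a blanket 1/2 would lose half the
zero-class mass. The finite stored support is chosen adaptively so the
truncated tail is below 1e−9 (hard cap 10,000 with an explicit
`TruncationError`) and renormalized, so stored kernels are exact
probability distributions.

**The wave mixture M.** A cohort dispersing simultaneously from N
contiguous, equally occupied patches produces position distribution
M(x) = (1/N)·Σ_{s=0}^{N−1} K(x−s). Fitting observed post-dispersal counts
to M by multinomial ML recovers (ξ, ω) from wave shape alone — the only way
to estimate a kernel for generation 1, where no common-point release
exists. The experiment's design fixes N = 5.

## 2. The simulator

One replicate is a landscape of 144 patches with 50 founders (5 females +
5 males in each of patches 0–4), run for 10 non-overlapping generations of

1. **dispersal** — every individual draws a signed displacement from its
   realized kernel; individuals landing left of patch −2 are discarded
   (only the right-moving wave is tracked), the right edge clamps (never
   binding in practice);
2. **census** — per-patch, per-sex counts; invasion extent = farthest patch
   with ≥ 4 beetles (a wave-position marker robust to single-beetle
   detection error; `None` if no patch qualifies); bottleneck = females in
   the farthest occupied patch;
3. **shuffle** (shuffled treatment only) — genotypes are permuted uniformly
   at random within each sex across the whole landscape. Per-patch density
   and sex ratio are preserved *exactly* and the global genotype multiset
   is conserved; only the genotype–position association is destroyed. The
   final generation is never shuffled, so common-garden founders reached
   the front by their own dispersal in both treatments;
4. **trailing-edge truncation** (from generation 6) — only offspring from
   the leading 60 patches continue;
5. **demography** — in each patch with both sexes, each female draws one
   mate uniformly (polygyny allowed) and a Poisson number of offspring with
   Beverton–Holt mean R₀ / (1 + (R₀−2)·N/(2K)). This calibration makes the
   two-sex fixed point (two offspring per female) sit exactly at K adults;
   a long single-patch run fluctuates around K = 40. Offspring get
   Bernoulli(1/2) sex, midparent breeding values plus N(0, G/2) segregation
   noise (infinitesimal model), fresh environmental deviates, and their
   mother's patch.

**Genetic architecture.** Each individual carries a breeding value for
(log ξ, log ω) with additive covariance G, plus an environmental deviate
with covariance E; sex enters as a fixed baseline offset (males disperse
slightly farther). Heritability of ω is supported but may be set to zero.

**Default parameters** (one choice, used everywhere):

| parameter | value | why |
|---|---|---|
| ξ baseline (F, M) | 0.55, 0.7 patches | most beetles stay or move one patch in a 2-h bout; gives speeds ~1.5 patches/gen and extents ~16 at generation 10, the scale of the mesocosm experiments |
| ω baseline | 0.6 | heavy-tailed kernels (variance ≈ 2.7× mean for ξ=0.7): rare long jumps create the sparse leading edges (≈0.5 females in the farthest patch) that drive sorting and surfing |
| R₀ | 10 offspring/female | strong low-density growth, consistent with high beetle fecundity on abundant beans |
| K | 40 adults/patch | resource limit of seven beans |
| G | diag(0.15, 0.05) | additive variance of log ξ chosen so the emergent sorted-vs-shuffled speed advantage is of the observed order (~9%); smaller values produce fronts that barely sort |
| E | diag(0.05, 0.05) | modest micro-environmental kernel variation |

With these defaults the simulator reproduces the study's qualitative
signature: sorted invasions spread farther on average, among-replicate
variance in speed is amplified severalfold (the experiment's much larger
41× amplification reflects its larger realized genetic variance and only
the *direction* is asserted in tests), breeding values for log ξ are
elevated at sorted fronts but not shuffled ones, and with G = E = 0 the two
treatments are bitwise identical under shared seeds (per-phase random
streams make the coupling exact).

**What the generator does not emulate:** overlapping generations, 2-D
landscapes, mutation, dominance/maternal variance, bean-level resource
dynamics, the experiment's partial sexing bookkeeping in late generations
(the in-silico shuffle preserves exact sex counts everywhere, making it
unnecessary), and observation error in counts. Passing tests therefore
demonstrate that the *methods* recover known truths under the model's
assumptions — not that real beetles satisfy those assumptions.

## 3. Spread models

Extent of replicate i (treatment j, generation k) follows a lagged-response
AR(1) linear mixed model; the lag for generation 1 is the founder extent
(patch 4). Generation is coded 1–10, uncentered; treatment is 0 = sorted,
1 = shuffled.

*Mean structure* is selected by ML + AIC over all marginality-respecting
subsets of {TRT, GEN, TRT×GEN, GEN²} (intercept and AR term always
present). The replicate velocity effect γᵢ is integrated analytically — the
marginal covariance per replicate is σ²_w·I + σ²_a·g·gᵀ, handled by
Woodbury identities — and β is profiled by GLS, leaving a 2-parameter
Nelder–Mead problem per candidate. AIC counts fixed effects + 2 variance
parameters. Wald intervals from the profiled information matrix achieve
≥85% empirical coverage at the experimental dimensions (50-simulation
check in the acceptance suite).

*Variance structure* (within- and/or among-replicate variance
treatment-specific: four models) is compared by WAIC on Bayesian fits.
Priors: N(0, 10²) on fixed effects, Uniform(−1, 1) on β_AR, Half-Normal(0, 5)
on both standard deviations. The sampler works on the marginalized
likelihood directly (no funnel). The WAIC "observations" are the 18
independent replicate trajectories (marginal block likelihoods): treating
single extents as observations conditional on γᵢ leaves the criterion
nearly blind to the variance structure, because the fitted deviations
absorb whatever the variance parameters imply. The among-replicate
variance ratio σ²_a(sorted)/σ²_a(shuffled) is summarized by its posterior
median and 95% interval; with 9 replicates per arm it is intrinsically
noisy (an order-of-magnitude interval is normal).

## 4. Common-garden kernel hierarchy

For one sex, displacement magnitude of individual i in replicate j,
treatment k, common-garden generation l is PIG(ξ_jkl, ω_jkl) with

    log ξ_jkl = α₀ + α_TRT·TRT + α_CGG·CGG + α_TRT×CGG·TRT·CGG + ε_jk
    log ω_jkl = β₀ + β_TRT·TRT + β_CGG·CGG + β_TRT×CGG·TRT·CGG + γ_jk

ε_jk ~ N(0, σ²_ε[k]), γ_jk ~ N(0, σ²_γ[k]), variances optionally
treatment-specific. The candidate lattice applies each fixed-effect subset
to both parameters jointly (effects on "neither or both"), crossed with
homogeneous/heterogeneous variances; 10 specifications after
deduplication. Magnitudes |d| are the response (the PIG has nonnegative
support); the signed form is used only for landscape waves.

Numerics: log links; priors N(0, 2.5²) on the two intercepts,
**N(0, 1) on all other effects** (a unit log-effect is already e ≈ 2.7-fold —
anything larger is biologically implausible, and the weakly-informative
prior is what keeps WAIC from favoring spurious effects at n = 18
replicates), Half-Normal(0, 1) on random-effect SDs; non-centered random
effects; likelihood evaluated from per-cell distance histograms through a
vectorized pmf-table recursion. WAIC blocks are replicates, with (ε, γ)
integrated out by 9-point tensor Gauss–Hermite quadrature (block error
< 0.01 nats, checked against 2-D adaptive quadrature in the tests).

The discrete KS test reports D⁺ = max_x(F_a − F_b) on the pooled integer
support with p-values from multinomial resampling of the pooled empirical
distribution — the classical continuous-support formula is conservative
under heavy ties. The pipeline calls it with a = shuffled, b = sorted, so
D⁺ > 0 means sorted beetles disperse farther. Achieved type-I error at
α = 0.05 is 0.05 ± 0.02 (1000-simulation check).

## 5. Half-sib models

Net distances of full siblings (per sex) are PIG with log ξ_jk = α₀ + ε_jk
and a single shape ω (family-level shape effects are not estimable from
families with as few as 4 dispersers — attempting them is what breaks
convergence). The *sire* model decomposes ε_jk = S_k + D_jk (dam nested in
sire); the *dam-only* model keeps a single family variance. Both share the
fixed structure exactly, so the WAIC difference isolates the sire variance —
which is V_A/4 under half-sib theory; the package reports
V_A = 4σ²_sire *on the latent log-mean scale only* (no observed-scale
heritability is defined or computed). WAIC blocks are sire groups with
nested Gauss–Hermite integration over (S, D). Trials padded with
source-population companions are represented simply by their absence:
only full-sib records enter the likelihood.

## 6. Demography GLMMs

Fertility: offspring counts ~ NB(mean μ, overdispersion φ constant), log μ
with fixed effects ⊆ {TRT, CGG, TRT×CGG} and a replicate random intercept.
Bottlenecks: leading-patch female counts ~ Poisson, same fixed-effect menu
over generations, replicate random intercept. Both are ML fits with the
random intercept integrated by 15–20-node Gauss–Hermite quadrature
(matching `lme4::glmer` with nAGQ=20 to ~4 decimals on a fixture panel)
and compared by AIC with k = fixed effects + σ (+ φ). The marginal surface
can plateau in σ when the quadrature saturates, so the optimizer restarts
from four random-intercept scales and keeps the best; φ starts at its
method-of-moments value. Bottleneck extraction from simulator output uses
the farthest *occupied* patch (≥1 beetle), not the 4-beetle extent patch;
the reader accepts either convention as data.

## 7. Inference engine

Posterior sampling: `emcee` ensemble sampler, 90% differential-evolution +
10% snooker moves, walkers = max(2·dim + 2, 32), default 2000 steps with
the first half discarded. Convergence: R-hat over four pooled time
segments (classic walkers-as-chains split-R-hat is inflated by walker
dependence in affine-invariant ensembles; segment pooling still exposes
warm-up drift, the dominant failure mode) with threshold 1.01, plus
autocorrelation-time ESS ≥ 400 per parameter. Non-convergence is flagged
on the result, never silently dropped; model-comparison tables carry the
flag per row. Given a seed, fits are bitwise reproducible.

WAIC: waic = −2·Σᵢ(lppd_i − p_i) with lppd_i = log-mean-exp over draws and
p_i the pointwise draw variance; relative support weights are
w_m ∝ exp(−Δ_m/2) for both WAIC and AIC tables. For hierarchical models
the pointwise unit is a *marginal block* (replicate or sire group), a
deliberate departure from conditional pointwise likelihoods: conditioning
on random effects makes models that differ only through those effects (the
variance-structure and sire-model comparisons, and any between-replicate
fixed effect) nearly indistinguishable to WAIC. Marginalized blocks restore
the comparisons' power at the cost of treating the block, not the
observation, as the exchangeable unit — with 17–18 blocks, WAIC remains a
noisy instrument, which is visible in the weight tables.

## 8. Problem sizes in the test suite

The acceptance suite runs every check at the experimental dimensions
(9 + 9 replicates × 10 generations; 45 dispersal observations per sex per
replicate per generation; 17 sires × 3 dams) but with replication counts
chosen to keep the full suite near five minutes on one core: 50 simulations
for ML coverage, 4–5 runs for each Bayesian model-selection direction
(thresholds keep the original proportions: majority, ≥80%), 40 fits for
posterior calibration, 1000 null simulations (300 bootstrap resamples
each) for the KS size check, and 10 batches for the simulator direction
checks. Sampler lengths in tests (800–1500 steps) are shorter than the
2000-step default.

## 9. Known limitations

* WAIC at 17–18 marginal blocks has limited resolution; weights should be
  read as order-of-magnitude support, and single-run selections can flip.
* The ensemble sampler handles the ~50-dimensional kernel hierarchies but
  occasionally misses the 1.01 R-hat bar at default lengths; fits carry
  the flag and rerunning with more steps resolves it.
* The variance-ratio posterior is heavy-tailed at 9 replicates per arm.
* Wave-mixture fits pool replicates within treatment by default (the
  generation-1 data carry no population-level replication); per-replicate
  fits are possible but report only sampling uncertainty.
* The pre/post dispersal comparison contrasts estimates from different
  designs (wave inference vs common-garden trials); its shifts are
  interpretable directionally, not as calibrated effect sizes.
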