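# spatialsort

Simulation and statistics for **spatial sorting** in replicated experimental
invasions.

When a population spreads through fragmented habitat, the most dispersive
genotypes accumulate at the expanding front generation after generation —
spatial sorting — and the small founder groups at the leading edge let
allele frequencies drift between replicate invasions (gene surfing). Both
processes act even without any fitness advantage to dispersal, and together
they are predicted to make invasions *faster* and *less predictable*.

`spatialsort` packages the computational machinery needed to study this in
replicated mesocosm experiments (the motivating system is the bean beetle
*Callosobruchus maculatus* spreading through a 1-D chain of bean patches):

* **An individual-based eco-evolutionary simulator.** Beetles carry
  breeding values for the parameters of a Poisson-inverse-Gaussian (PIG)
  dispersal kernel (mean ξ, shape ω, variance ξ(1+ξ/ω)), inherited under
  the infinitesimal model. Each generation: kernel-driven dispersal on a
  144-patch landscape, an optional *shuffle* treatment that redistributes
  genotypes while preserving every patch's density and sex ratio exactly
  (switching off spatial sorting), then Beverton–Holt density-dependent
  reproduction with a patch carrying capacity of ~40. The simulator also
  generates every downstream dataset: extent series, common-garden
  dispersal and fertility trials, nested half-sib pedigrees, and
  leading-patch bottleneck records.
* **The analysis stack.**
  - AR(1) linear mixed models of invasion extent
    (μ = β₀ + β_TRT·TRT + (β_GEN + γᵢ + β_TRT×GEN·TRT)·GEN + β_AR·extentₖ₋₁),
    with ML+AIC selection of the mean structure and Bayesian WAIC comparison
    of four variance structures (within- and among-replicate variances
    shared or treatment-specific);
  - hierarchical PIG kernel regression for common-garden dispersal, with
    log-linear treatment × generation effects on both ξ and ω and
    treatment-specific replicate variances;
  - discrete Kolmogorov–Smirnov tests with resampling p-values (exact under
    ties);
  - wave-mixture kernel inference: the post-dispersal density profile of
    generation 1 is a mixture M(x) = (1/N)·Σₛ K(x−s) of symmetric kernels
    over the N=5 founder patches, fitted by multinomial ML;
  - nested paternal half-sib models (dam-only vs sire+dam) for additive
    genetic variance in dispersal, V_A = 4·σ²_sire on the latent scale;
  - negative-binomial fertility and Poisson bottleneck GLMMs with replicate
    random intercepts (ML via Gauss–Hermite quadrature, cross-checked
    against lme4).

Posterior sampling uses an affine-invariant ensemble sampler with
differential-evolution moves; WAIC uses marginal block likelihoods
(replicate or sire-group blocks) so that comparisons of random-effect
structures have power. See `docs/methods.md` for the full model notes.

## Worked example

```python
from spatialsort import SimConfig, run_experiment

exp = run_experiment(SimConfig(), n_replicates=9, seed=42)
final = exp["extents"].query("generation == 10")
print(final.groupby("treatment")["extent"].agg(["mean", "var"]))
```

prints

```
           mean       var
treatment
shuffled  15.44  3.78
sorted    18.11  7.11
```

Sorted invasions spread 17.3% farther on average than shuffled ones and
their final extents vary ~1.9× more across replicates: preventing spatial
sorting (the shuffle) slows invasions down and makes them more
repeatable. Each `examples/*.py` script walks one capability end to end —
kernels, the invasion experiment, spread models, common-garden kernels +
KS, half-sib genetics, demography GLMMs, and the full pipeline — and prints
what the numbers mean.

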