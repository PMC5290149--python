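"""Fertility and bottleneck GLMMs.

Two auxiliary checks that the treatments differ only in dispersal: a
negative-binomial GLMM on common-garden lifetime reproductive success and a
Poisson GLMM on the number of females in the farthest occupied patch, each
with AIC selection over fixed-effect subsets.
"""

from spatialsort import (
    PipelineConfig,
    fit_bottleneck_models,
    fit_fertility_models,
    simulate_datasets,
)

data = simulate_datasets(PipelineConfig(seed=42))

fert = fit_fertility_models(data["fertility"])
print("Fertility (NB GLMM) AIC table:")
print(fert.table().to_string(index=False))
null_w = dict(zip(fert.names, fert.weights))["1"]
print(f"\nNull-model weight {100 * null_w:.0f}%: fertility did not evolve — as expected, "
      "since the generator gives fecundity no genetic variation.")

bn = fit_bottleneck_models(data["bottlenecks"])
print("\nBottleneck (Poisson GLMM) AIC table:")
print(bn.table().to_string(index=False))
print("\nTreatment terms receive little support: leading-edge densities are similar, "
      "so speed differences are not a demographic artifact.")
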