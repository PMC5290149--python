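import numpy as np
import pandas as pd
import pytest

from spatialsort.pig import PIGParams, pig_sample
from spatialsort.simulate import SimConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_sim_config():
    """Reduced landscape for fast end-to-end runs."""
    return SimConfig(n_patches=80, generations=6)


def simulate_kernel_obs(
    alpha_trt=0.0,
    seed=0,
    n_rep=9,
    n_per=45,
    sd_eps=0.15,
    sd_gam=0.1,
    xi0=1.8,
    omega0=1.0,
    a_cgg=0.0,
    b_cgg=0.0,
    generations=(1,),
    sexes=("female",),
):
    """Common-garden style dispersal observations drawn directly from the
    hierarchical PIG kernel model (treatment coded on log xi and log omega;
    'shuffled' carries the alpha_trt offset)."""
    rng = np.random.default_rng(seed)
    rows = []
    for trt_i, trt in enumerate(("sorted", "shuffled")):
        for r in range(n_rep):
            eps = rng.normal(0, sd_eps)
            gam = rng.normal(0, sd_gam)
            for sex in sexes:
                for g in generations:
                    xi = np.exp(np.log(xi0) + alpha_trt * trt_i + a_cgg * (g - 1) + eps)
                    om = np.exp(np.log(omega0) + b_cgg * (g - 1) + gam)
                    for x in pig_sample(n_per, PIGParams(xi, om), rng):
                        rows.append(
                            {
                                "distance": int(x),
                                "sex": sex,
                                "replicate": f"{trt}{r}",
                                "treatment": trt,
                                "cg_generation": g,
                                "trial": 1,
                            }
                        )
    return pd.DataFrame(rows)
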