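"""Fertility and invasion-bottleneck generalized linear mixed models.

Two auxiliary analyses check whether the invasion treatments diverged in
anything other than dispersal:

* **Fertility** — lifetime reproductive success of common-garden females,
  negative-binomial response (overdispersion ``phi`` constant) with
  log-linear fixed effects of treatment, common-garden generation and
  their interaction, and a replicate random intercept.
* **Bottleneck size** — females in the farthest occupied patch each
  generation, Poisson response with the same fixed-effect menu and a
  replicate random intercept.

Both are fitted by maximum likelihood with the replicate intercept
integrated out by adaptive-order Gauss-Hermite quadrature, and all
hierarchy-respecting fixed-effect subsets are compared by AIC.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, special
from scipy.special import logsumexp

from .inference import FitResult, ModelComparison

__all__ = [
    "nb_logpmf",
    "fit_glmm_ml",
    "candidate_fixed_subsets",
    "fit_fertility_models",
    "fit_bottleneck_models",
]


def nb_logpmf(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial log-pmf, mean ``mu``, variance ``mu + mu^2/phi``."""
    y = np.asarray(y, dtype=float)
    return (
        special.gammaln(y + phi)
        - special.gammaln(phi)
        - special.gammaln(y + 1.0)
        + phi * (np.log(phi) - np.log(phi + mu))
        + y * (np.log(mu) - np.log(phi + mu))
    )


def _poisson_logpmf(y, mu):
    return y * np.log(mu) - mu - special.gammaln(y + 1.0)


def candidate_fixed_subsets() -> list[tuple[str, ...]]:
    """Hierarchy-respecting subsets of {TRT, GEN, TRTxGEN} (interaction
    requires both main effects); intercept always included."""
    out = []
    for trt, gen, inter in product((False, True), repeat=3):
        if inter and not (trt and gen):
            continue
        out.append(
            tuple(t for t, on in (("TRT", trt), ("GEN", gen), ("TRTxGEN", inter)) if on)
        )
    return out


def _design(records: pd.DataFrame, response: str, gen_col: str, terms) -> dict:
    trt = (records["treatment"].to_numpy() == "shuffled").astype(float)
    gen = records[gen_col].to_numpy(dtype=float)
    y = records[response].to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("counts must be nonnegative")
    cols = {"1": np.ones_like(y)}
    for t in terms:
        cols[t] = {"TRT": trt, "GEN": gen, "TRTxGEN": trt * gen}[t]
    X = np.column_stack(list(cols.values()))
    groups, gidx = np.unique(records["replicate"], return_inverse=True)
    return {"X": X, "names": list(cols.keys()), "y": y, "gidx": gidx, "n_groups": groups.size}


def _glmm_negloglik(params, d, family, n_quad):
    p = d["X"].shape[1]
    beta = params[:p]
    log_sd = params[p]
    sd = np.exp(log_sd)
    phi = np.exp(params[p + 1]) if family == "nb" else None
    eta = d["X"] @ beta
    x, w = hermegauss(n_quad)
    logw = np.log(w) - 0.5 * np.log(2 * np.pi)
    # (obs, nodes) conditional log-likelihoods at u = sd * x
    mu = np.exp(np.clip(eta[:, None] + sd * x[None, :], -30, 30))
    if family == "nb":
        ll = nb_logpmf(d["y"][:, None], mu, phi)
    else:
        ll = _poisson_logpmf(d["y"][:, None], mu)
    # sum within group, integrate per group
    gll = np.zeros((d["n_groups"], n_quad))
    np.add.at(gll, d["gidx"], ll)
    return -float(logsumexp(gll + logw[None, :], axis=1).sum())


def fit_glmm_ml(
    records: pd.DataFrame,
    response: str,
    family: str,
    terms: tuple[str, ...],
    gen_col: str = "generation",
    n_quad: int = 20,
) -> FitResult:
    """ML fit of one fixed-effect subset with a replicate random intercept.

    AIC counts all estimated fixed effects plus the random-intercept
    standard deviation (plus ``phi`` for the negative binomial).
    """
    if family not in ("poisson", "nb"):
        raise ValueError(f"unknown family {family!r}")
    d = _design(records, response, gen_col, terms)
    p = d["X"].shape[1]
    mean_y = max(d["y"].mean(), 0.1)
    start = np.zeros(p + 1 + (family == "nb"))
    start[0] = np.log(mean_y)
    start[p] = np.log(0.3)
    if family == "nb":
        # moment-matched overdispersion: var = mu + mu^2/phi
        var_y = d["y"].var(ddof=1)
        phi0 = mean_y**2 / max(var_y - mean_y, mean_y / 10.0)
        start[p + 1] = np.log(np.clip(phi0, 0.05, 1e4))
    # the marginal surface can plateau in the variance component; restart
    # the simplex from several random-intercept scales
    best = None
    for log_sd0 in (-4.0, -2.0, np.log(0.3), 0.0):
        s = start.copy()
        s[p] = log_sd0
        res = optimize.minimize(
            _glmm_negloglik,
            s,
            args=(d, family, n_quad),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    k = best.x.size
    loglik = -best.fun
    row = dict(zip(d["names"], best.x[:p]))
    row["sd_replicate"] = np.exp(best.x[p])
    if family == "nb":
        row["phi"] = np.exp(best.x[p + 1])
    # Wald SEs for fixed effects from a numerical Hessian
    se = _wald_se(best.x, d, family, n_quad)
    return FitResult(
        draws=pd.DataFrame([row]),
        pointwise_loglik=None,
        diagnostics={
            "converged": bool(best.success),
            "loglik": loglik,
            "n_params": k,
            "se": dict(zip(d["names"], se[:p])),
        },
        criterion=-2.0 * loglik + 2.0 * k,
        criterion_name="aic",
        p_eff=float(k),
        name="+".join(d["names"]),
    )


def _wald_se(x0, d, family, n_quad, h: float = 1e-4):
    n = x0.size
    H = np.zeros((n, n))
    f = lambda v: _glmm_negloglik(v, d, family, n_quad)
    for i in range(n):
        for j in range(i, n):
            ei = np.eye(n)[i] * h
            ej = np.eye(n)[j] * h
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)


def fit_fertility_models(
    records: pd.DataFrame, n_quad: int = 20
) -> ModelComparison:
    """AIC table over fixed-effect subsets for the NB fertility GLMM.

    ``records`` needs columns replicate, treatment, cg_generation,
    offspring.
    """
    if records.groupby("treatment")["replicate"].nunique().min() < 2:
        raise ValueError("need >= 2 replicates per treatment")
    names, fits = [], []
    for terms in candidate_fixed_subsets():
        fit = fit_glmm_ml(
            records, "offspring", "nb", terms, gen_col="cg_generation", n_quad=n_quad
        )
        if not fit.converged:
            import warnings

            warnings.warn(f"fertility candidate {fit.name} flagged non-converged")
        names.append(fit.name)
        fits.append(fit)
    return ModelComparison.from_results(names, fits)


def fit_bottleneck_models(
    records: pd.DataFrame, n_quad: int = 20
) -> ModelComparison:
    """AIC table over fixed-effect subsets for the Poisson bottleneck GLMM.

    ``records`` needs columns replicate, treatment, generation,
    females_in_leading_patch.
    """
    names, fits = [], []
    for terms in candidate_fixed_subsets():
        fit = fit_glmm_ml(
            records,
            "females_in_leading_patch",
            "poisson",
            terms,
            gen_col="generation",
            n_quad=n_quad,
        )
        names.append(fit.name)
        fits.append(fit)
    return ModelComparison.from_results(names, fits)
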