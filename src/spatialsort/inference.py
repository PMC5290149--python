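"""Shared fitting and model-selection machinery.

Every model module in the package funnels through the same three pieces:

* :func:`sample_posterior` — a posterior-sampling contract built on the
  affine-invariant ensemble sampler (emcee), with differential-evolution
  moves for the higher-dimensional hierarchical models, split-chain R-hat
  and autocorrelation-based effective sample size diagnostics;
* :func:`compute_waic` — the widely applicable information criterion from a
  draws-by-observations pointwise log-likelihood matrix;
* :func:`criterion_weights` — Akaike-style relative support weights,
  ``w_m \\propto exp(-Delta_m / 2)``, used for both AIC and WAIC tables.

Pointwise likelihoods for hierarchical models are conditional on the
replicate/family random effects, matching common WAIC practice for
multilevel models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import emcee
import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "FitResult",
    "ModelComparison",
    "SamplerConfig",
    "PosteriorModel",
    "compute_waic",
    "criterion_weights",
    "sample_posterior",
    "split_rhat",
    "effective_sample_size",
]


class PosteriorModel(Protocol):
    """Contract a model must satisfy to be fitted by :func:`sample_posterior`."""

    param_names: Sequence[str]

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        """Vectorized log joint density for a (walkers, ndim) matrix."""

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        """(draws, n_obs) conditional log-likelihood matrix."""

    def initial(self, rng: np.random.Generator, n_walkers: int) -> np.ndarray:
        """Overdispersed starting positions, shape (n_walkers, ndim)."""


@dataclass
class SamplerConfig:
    """Ensemble-sampler settings.

    ``n_steps`` counts total steps per walker; the first ``burn_frac`` are
    discarded as warm-up. ``n_walkers`` defaults to ``max(2*ndim + 2, 32)``.
    ``thin`` keeps every ``thin``-th retained draw.
    """

    n_steps: int = 2000
    burn_frac: float = 0.5
    n_walkers: int | None = None
    thin: int = 1
    seed: int = 0
    rhat_max: float = 1.01
    ess_min: float = 400.0
    max_pointwise_draws: int = 2000


@dataclass
class FitResult:
    """Posterior draws (or ML point estimate), pointwise log-likelihood and
    information-criterion bookkeeping for one fitted model."""

    draws: pd.DataFrame
    pointwise_loglik: np.ndarray | None
    diagnostics: dict = field(default_factory=dict)
    criterion: float = np.nan
    criterion_name: str = "waic"
    p_eff: float = np.nan
    name: str = ""

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", True))

    def summary(self, probs=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        q = self.draws.quantile(list(probs)).T
        q.columns = [f"q{int(1000 * p) / 10:g}" for p in probs]
        q.insert(0, "mean", self.draws.mean())
        return q

    def to_dir(self, path) -> None:
        """Serialize draws, diagnostics and the criterion to a directory of
        delimited-text files."""
        import json
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.draws.to_csv(path / "draws.csv", index=False)
        diag = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in self.diagnostics.items()}
        diag.update(criterion=self.criterion, criterion_name=self.criterion_name, p_eff=self.p_eff, name=self.name)
        (path / "diagnostics.json").write_text(json.dumps(diag, indent=1, default=float))


@dataclass
class ModelComparison:
    """A set of named fits compared on a common information criterion."""

    names: list[str]
    results: list[FitResult]
    weights: np.ndarray

    @property
    def criteria(self) -> np.ndarray:
        return np.array([r.criterion for r in self.results])

    @property
    def best(self) -> FitResult:
        return self.results[int(np.argmin(self.criteria))]

    @property
    def best_name(self) -> str:
        return self.names[int(np.argmin(self.criteria))]

    def table(self) -> pd.DataFrame:
        crit = self.criteria
        return pd.DataFrame(
            {
                "model": self.names,
                "criterion": crit,
                "delta": crit - crit.min(),
                "weight": self.weights,
                "p_eff": [r.p_eff for r in self.results],
                "converged": [r.converged for r in self.results],
            }
        ).sort_values("criterion", ignore_index=True)

    @classmethod
    def from_results(cls, names, results) -> "ModelComparison":
        crit = [r.criterion for r in results]
        return cls(list(names), list(results), criterion_weights(crit))


def compute_waic(pointwise_loglik: np.ndarray) -> tuple[float, float]:
    """WAIC on the deviance scale from a (draws, n_obs) matrix.

    ``lppd_i = log mean_s exp(ll_si)``; ``p_i = var_s(ll_si)`` (sample
    variance over draws); ``waic = -2 * sum_i (lppd_i - p_i)``. Returns
    ``(waic, p_waic)``.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise_loglik must be 2-D (draws x observations)")
    if ll.shape[0] < 2:
        raise ValueError("WAIC needs at least 2 draws (pointwise variance undefined)")
    if ll.shape[1] < 1:
        raise ValueError("WAIC needs at least 1 observation")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise_loglik contains non-finite entries")
    s = ll.shape[0]
    lppd = logsumexp(ll, axis=0) - np.log(s)
    p_i = ll.var(axis=0, ddof=1)
    waic = -2.0 * float(np.sum(lppd - p_i))
    return waic, float(np.sum(p_i))


def criterion_weights(criteria) -> np.ndarray:
    """Relative support weights from information-criterion values."""
    c = np.asarray(criteria, dtype=float)
    if c.size == 0:
        raise ValueError("criteria must be non-empty")
    if not np.all(np.isfinite(c)):
        raise ValueError("criteria must be finite")
    delta = c - c.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def split_rhat(chains: np.ndarray, n_segments: int = 4) -> np.ndarray:
    """Potential scale reduction factor per parameter for ensemble chains.

    ``chains`` has shape (steps, walkers, ndim). Individual walkers of an
    affine-invariant ensemble are mutually dependent, so treating each as
    an independent chain grossly inflates the classic statistic. Instead
    the retained run is split into ``n_segments`` consecutive time
    segments, each pooling every walker, and the Gelman-Rubin B/W
    computation is applied across segments: residual warm-up drift or slow
    trends appear as between-segment variance, the ensemble's main failure
    mode.
    """
    n, m, d = chains.shape
    seg = n // n_segments
    if seg < 2:
        return np.full(d, np.nan)
    segs = chains[: seg * n_segments].reshape(n_segments, seg * m, d)
    mean_c = segs.mean(axis=1)            # (S, d)
    var_c = segs.var(axis=1, ddof=1)      # (S, d)
    w = var_c.mean(axis=0)
    size = seg * m
    b = size * mean_c.var(axis=0, ddof=1)
    var_plus = (size - 1) / size * w + b / size
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_plus / w)


def effective_sample_size(chains: np.ndarray) -> np.ndarray:
    """ESS per parameter via emcee's integrated autocorrelation time,
    averaged across walkers."""
    n, m, d = chains.shape
    ess = np.empty(d)
    for j in range(d):
        try:
            with np.errstate(invalid="ignore", divide="ignore"):
                tau = emcee.autocorr.integrated_time(chains[:, :, j], tol=0)
        except Exception:  # pragma: no cover - degenerate chains
            tau = np.array([np.inf])
        t = float(np.atleast_1d(tau)[0])
        ess[j] = 0.0 if not np.isfinite(t) else n * m / max(t, 1.0)
    return ess


def sample_posterior(model: PosteriorModel, config: SamplerConfig | None = None) -> FitResult:
    """Fit ``model`` by ensemble MCMC and attach WAIC.

    Non-convergence (any split R-hat above ``rhat_max`` or ESS below
    ``ess_min``) is flagged in ``diagnostics['converged']`` — the fit is
    still returned so the caller can inspect or re-run it, never silently
    discarded.
    """
    config = config or SamplerConfig()
    names = list(model.param_names)
    ndim = len(names)
    n_walkers = config.n_walkers or max(2 * ndim + 2, 32)
    rng = np.random.default_rng(config.seed)
    p0 = np.asarray(model.initial(rng, n_walkers), dtype=float)
    if p0.shape != (n_walkers, ndim):
        raise ValueError("initial positions have wrong shape")
    lp0 = model.log_posterior(p0)
    if not np.all(np.isfinite(lp0)):
        raise ValueError("some initial positions have non-finite log posterior")

    moves = [(emcee.moves.DEMove(), 0.9), (emcee.moves.DESnookerMove(), 0.1)]
    sampler = emcee.EnsembleSampler(
        n_walkers, ndim, model.log_posterior, vectorize=True, moves=moves
    )
    sampler.random_state = np.random.RandomState(config.seed % (2**32)).get_state()
    sampler.run_mcmc(p0, config.n_steps, progress=False)

    burn = int(config.burn_frac * config.n_steps)
    chain = sampler.get_chain(discard=burn, thin=config.thin)  # (steps, walkers, ndim)
    rhat = split_rhat(chain)
    ess = effective_sample_size(chain)
    max_rhat = float(np.nanmax(rhat)) if np.any(np.isfinite(rhat)) else np.inf
    min_ess = float(np.nanmin(ess)) if np.any(np.isfinite(ess)) else 0.0
    converged = bool(max_rhat <= config.rhat_max and min_ess >= config.ess_min)

    flat = chain.reshape(-1, ndim)
    draws = pd.DataFrame(flat, columns=names)
    # subsample for the pointwise matrix to bound WAIC cost on long runs
    if flat.shape[0] > config.max_pointwise_draws:
        idx = rng.choice(flat.shape[0], config.max_pointwise_draws, replace=False)
        ll = model.pointwise_loglik(flat[np.sort(idx)])
    else:
        ll = model.pointwise_loglik(flat)
    waic, p_waic = compute_waic(ll)

    return FitResult(
        draws=draws,
        pointwise_loglik=ll,
        diagnostics={
            "rhat": rhat,
            "ess": ess,
            "max_rhat": max_rhat,
            "min_ess": min_ess,
            "converged": converged,
            "acceptance_fraction": float(sampler.acceptance_fraction.mean()),
            "n_walkers": n_walkers,
            "n_steps": config.n_steps,
            "seed": config.seed,
        },
        criterion=waic,
        criterion_name="waic",
        p_eff=p_waic,
    )
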