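"""AR(1) linear mixed models of invasion extent.

The response is the invasion-extent series: extent of replicate *i* in
treatment *j* at generation *k*, modelled with a lagged-response AR(1)
linear predictor

    mu_ijk = b0 + b_TRT*TRT + (b_GEN + gamma_i + b_TRTxGEN*TRT)*GEN
             + b_AR*extent_{i,k-1}

where ``gamma_i ~ N(0, sigma2_among)`` is a replicate-specific velocity
deviation and residuals are independent Normal(0, sigma2_within) given the
lagged extent. Generation 1 uses the known founder extent as its lag.

Model selection runs in two steps, mirroring the study design:

1. :func:`select_mean_model` — maximum likelihood over all
   hierarchy-respecting fixed-effect subsets (optionally with a quadratic
   generation term), compared by AIC; the replicate velocity effect is
   integrated out analytically (marginal Gaussian likelihood).
2. :func:`compare_variance_models` — Bayesian fits of the four variance
   structures (within- and/or among-replicate variance treatment-specific
   or shared), compared by WAIC.

Treatment is coded 0 = sorted (reference), 1 = shuffled.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .inference import (
    FitResult,
    ModelComparison,
    SamplerConfig,
    sample_posterior,
)

__all__ = [
    "MeanSpec",
    "VarianceStructure",
    "VARIANCE_STRUCTURES",
    "candidate_mean_specs",
    "ar1_loglik",
    "fit_mean_model",
    "select_mean_model",
    "SpreadVarianceModel",
    "compare_variance_models",
    "variance_ratio",
    "cv_by_generation",
    "simulate_extent_series",
]

FOUNDER_EXTENT = 4  # founders occupy patches 0..4


@dataclass(frozen=True)
class MeanSpec:
    """Fixed-effect structure. ``terms`` is a subset of
    {"TRT", "GEN", "TRTxGEN", "GEN2"}; intercept and the AR lag term are
    always present, the replicate velocity effect rides on GEN."""

    terms: tuple[str, ...] = ("TRT", "GEN", "TRTxGEN")

    def label(self) -> str:
        return "1+AR" + ("+" + "+".join(self.terms) if self.terms else "")


@dataclass(frozen=True)
class VarianceStructure:
    within_by_treatment: bool = False
    among_by_treatment: bool = False

    def label(self) -> str:
        w = "trt" if self.within_by_treatment else "hom"
        a = "trt" if self.among_by_treatment else "hom"
        return f"within={w},among={a}"


VARIANCE_STRUCTURES = tuple(
    VarianceStructure(w, a) for w, a in product((False, True), repeat=2)
)


def candidate_mean_specs(include_quadratic: bool = True) -> list[MeanSpec]:
    """All fixed-effect subsets respecting marginality (TRTxGEN needs both
    main effects; GEN2 needs GEN)."""
    specs = []
    for trt, gen, inter, quad in product((False, True), repeat=4):
        if inter and not (trt and gen):
            continue
        if quad and not gen:
            continue
        if quad and not include_quadratic:
            continue
        terms = tuple(
            t
            for t, on in (("TRT", trt), ("GEN", gen), ("TRTxGEN", inter), ("GEN2", quad))
            if on
        )
        specs.append(MeanSpec(terms))
    return specs


def _validate_series(series: pd.DataFrame) -> pd.DataFrame:
    need = {"replicate", "treatment", "generation", "extent"}
    missing = need - set(series.columns)
    if missing:
        raise ValueError(f"extent series missing columns {sorted(missing)}")
    s = series.dropna(subset=["extent"])
    if len(s) < len(series):
        import warnings

        warnings.warn("dropping generations with no measurable extent", stacklevel=3)
    for _, g in s.groupby("replicate"):
        if not g["generation"].is_monotonic_increasing:
            raise ValueError("generations must be ordered within replicate")
    return s


def _design(series: pd.DataFrame, spec: MeanSpec, founder_extent: int = FOUNDER_EXTENT):
    """Design pieces: fixed matrix X (intercept, AR lag, then spec terms),
    generation vector, replicate index, treatment indicator."""
    s = _validate_series(series).sort_values(["replicate", "generation"])
    trt = (s["treatment"].to_numpy() == "shuffled").astype(float)
    if not np.isin(s["treatment"].unique(), ["sorted", "shuffled"]).all():
        raise ValueError("treatment labels must be 'sorted'/'shuffled'")
    gen = s["generation"].to_numpy(dtype=float)
    y = s["extent"].to_numpy(dtype=float)
    lag = s.groupby("replicate")["extent"].shift(1).fillna(founder_extent).to_numpy(dtype=float)
    cols = {"1": np.ones_like(y), "AR": lag}
    for t in spec.terms:
        cols[t] = {
            "TRT": trt,
            "GEN": gen,
            "TRTxGEN": trt * gen,
            "GEN2": gen**2,
        }[t]
    X = np.column_stack(list(cols.values()))
    rep_codes, rep_idx = np.unique(s["replicate"].to_numpy(), return_inverse=True)
    rep_trt = np.zeros(rep_codes.size)
    for i in range(rep_codes.size):
        rep_trt[i] = trt[rep_idx == i][0]
    return {
        "X": X,
        "names": list(cols.keys()),
        "y": y,
        "gen": gen,
        "trt": trt,
        "rep_idx": rep_idx,
        "rep_trt": rep_trt,
        "n_reps": rep_codes.size,
        "replicates": rep_codes,
    }


def ar1_loglik(
    series: pd.DataFrame,
    params: dict,
    structure: VarianceStructure = VarianceStructure(),
    spec: MeanSpec = MeanSpec(),
    founder_extent: int = FOUNDER_EXTENT,
) -> float:
    """Conditional log-likelihood given replicate effects.

    ``params`` holds the fixed effects keyed like the design columns
    ("1", "AR", "TRT", "GEN", "TRTxGEN", "GEN2"), a ``gamma`` array of
    per-replicate velocity deviations (replicates in sorted label order),
    and ``sigma2_within`` (scalar, or (sorted, shuffled) pair when the
    structure is treatment-specific).
    """
    d = _design(series, spec, founder_extent)
    beta = np.array([params.get(n, 0.0) for n in d["names"]])
    gamma = np.asarray(params.get("gamma", np.zeros(d["n_reps"])), dtype=float)
    if gamma.size != d["n_reps"]:
        raise ValueError("gamma length must equal the number of replicates")
    mu = d["X"] @ beta + gamma[d["rep_idx"]] * d["gen"]
    s2w = np.atleast_1d(np.asarray(params["sigma2_within"], dtype=float))
    if structure.within_by_treatment:
        sig2 = s2w[d["trt"].astype(int)]
    else:
        sig2 = np.full_like(mu, s2w[0])
    return float(stats.norm.logpdf(d["y"], mu, np.sqrt(sig2)).sum())


def _marginal_negloglik(log_sd: np.ndarray, d: dict) -> float:
    """Negative marginal log-likelihood with beta profiled out by GLS; the
    replicate velocity effect is integrated analytically."""
    sa2, sw2 = np.exp(2.0 * log_sd)
    X, y, gen, rep_idx = d["X"], d["y"], d["gen"], d["rep_idx"]
    n_reps = d["n_reps"]
    # Build per-replicate inverse covariance via Woodbury: V = sw2 I + sa2 g g'
    XtViX = np.zeros((X.shape[1], X.shape[1]))
    XtViy = np.zeros(X.shape[1])
    logdet = 0.0
    quad_const = 0.0
    Vi_y_all = np.empty_like(y)
    Vi_X_all = np.empty_like(X)
    for i in range(n_reps):
        m = rep_idx == i
        g = gen[m]
        denom = sw2 + sa2 * (g @ g)
        # V^{-1} = I/sw2 - (sa2/sw2) g g' / denom
        def vinv(v):
            return v / sw2 - (sa2 / sw2) * g * (g @ v) / denom

        Xi, yi = X[m], y[m]
        ViX = np.column_stack([vinv(Xi[:, j]) for j in range(Xi.shape[1])])
        Viy = vinv(yi)
        XtViX += Xi.T @ ViX
        XtViy += Xi.T @ Viy
        logdet += m.sum() * np.log(sw2) + np.log(denom / sw2)
        Vi_X_all[m] = ViX
        Vi_y_all[m] = Viy
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return 1e10
    resid_quad = y @ Vi_y_all - 2 * beta @ XtViy + beta @ XtViX @ beta
    n = y.size
    nll = 0.5 * (n * np.log(2 * np.pi) + logdet + resid_quad)
    d["_beta"] = beta
    d["_XtViX"] = XtViX
    return float(nll)


def fit_mean_model(series: pd.DataFrame, spec: MeanSpec, founder_extent: int = FOUNDER_EXTENT) -> FitResult:
    """Maximum-likelihood fit of one mean specification.

    Returns a :class:`FitResult` whose ``draws`` frame holds the point
    estimates, with Wald standard errors in ``diagnostics`` and
    ``criterion`` = AIC (parameters counted as fixed effects + the two
    variance components).
    """
    d = _design(series, spec, founder_extent)
    best = None
    for start in ([0.0, 1.0], [-1.0, 0.0], [1.0, 0.5]):
        res = optimize.minimize(
            _marginal_negloglik, start, args=(d,), method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 600},
        )
        if best is None or res.fun < best.fun:
            best = res
    _marginal_negloglik(best.x, d)  # refresh profiled beta at the optimum
    beta, XtViX = d["_beta"], d["_XtViX"]
    se = np.sqrt(np.diag(np.linalg.inv(XtViX)))
    k = beta.size + 2
    loglik = -best.fun
    names = d["names"]
    draws = pd.DataFrame([dict(zip(names, beta))])
    draws["sigma_among"] = np.exp(best.x[0])
    draws["sigma_within"] = np.exp(best.x[1])
    return FitResult(
        draws=draws,
        pointwise_loglik=None,
        diagnostics={
            "se": dict(zip(names, se)),
            "converged": bool(best.success),
            "loglik": loglik,
            "n_params": k,
        },
        criterion=-2.0 * loglik + 2.0 * k,
        criterion_name="aic",
        p_eff=float(k),
        name=spec.label(),
    )


def select_mean_model(
    series: pd.DataFrame, include_quadratic: bool = True, founder_extent: int = FOUNDER_EXTENT
) -> ModelComparison:
    """AIC comparison over all candidate fixed-effect subsets."""
    specs = candidate_mean_specs(include_quadratic)
    names, fits = [], []
    for spec in specs:
        fit = fit_mean_model(series, spec, founder_extent)
        if not np.isfinite(fit.criterion):
            import warnings

            warnings.warn(f"candidate {spec.label()} did not converge; excluded")
            continue
        names.append(spec.label())
        fits.append(fit)
    return ModelComparison.from_results(names, fits)


class SpreadVarianceModel:
    """Bayesian AR(1) extent model with one of four variance structures.

    The replicate velocity deviations are integrated out analytically
    (Gaussian random slope on generation), so the sampler works on the
    fixed effects and the log standard deviations only — no funnel, and the
    WAIC "observations" are the independent replicate trajectories. Priors:
    Normal(0, 10^2) on fixed effects, Uniform(-1, 1) on the AR coefficient,
    Half-Normal(0, 5) on both standard deviations.
    """

    def __init__(
        self,
        series: pd.DataFrame,
        structure: VarianceStructure,
        spec: MeanSpec = MeanSpec(),
        founder_extent: int = FOUNDER_EXTENT,
    ):
        self.structure = structure
        self.spec = spec
        self.d = _design(series, spec, founder_extent)
        d = self.d
        self.n_fixed = d["X"].shape[1]
        self.n_reps = d["n_reps"]
        self.nw = 2 if structure.within_by_treatment else 1
        self.na = 2 if structure.among_by_treatment else 1
        self.param_names = (
            [f"beta_{n}" for n in d["names"]]
            + [f"log_sd_within_{i}" for i in range(self.nw)]
            + [f"log_sd_among_{i}" for i in range(self.na)]
        )
        self._ar_col = d["names"].index("AR")

    # --- parameter unpacking ------------------------------------------------
    def _unpack(self, th):
        p = self.n_fixed
        beta = th[:, :p]
        lw = th[:, p : p + self.nw]
        la = th[:, p + self.nw :]
        return beta, lw, la

    def log_posterior(self, th):
        th = np.atleast_2d(th)
        beta, lw, la = self._unpack(th)
        ll = self.pointwise_loglik(th).sum(axis=1)
        lp = (-0.5 * (beta / 10.0) ** 2).sum(axis=1)
        ar = th[:, self._ar_col]
        lp = np.where(np.abs(ar) < 1.0, lp, -np.inf)
        # Half-Normal(0,5) on sds with the log-sd change-of-variable jacobian
        for lsd in (lw, la):
            sd = np.exp(lsd)
            lp += (-0.5 * (sd / 5.0) ** 2 + lsd).sum(axis=1)
        return lp + ll

    def pointwise_loglik(self, th):
        """Replicate-block marginal log-likelihoods, (draws, n_replicates).

        The replicate velocity deviation is integrated out analytically, so
        the WAIC "observations" are the independent replicate trajectories.
        A blockwise-marginal criterion is far more sensitive to the
        among-replicate variance structure than a conditional pointwise one
        (conditioning on the deviations leaves their variance visible only
        through shrinkage).
        """
        th = np.atleast_2d(th)
        d = self.d
        beta, lw, la = self._unpack(th)
        sd_w = np.exp(lw)
        sd_a = np.exp(la)
        resid = d["y"][None, :] - beta @ d["X"].T          # (m, n_obs)
        rep_trt_i = d["rep_trt"].astype(int)
        m = th.shape[0]
        out = np.empty((m, self.n_reps))
        for i in range(self.n_reps):
            sel = d["rep_idx"] == i
            g = d["gen"][sel]
            r = resid[:, sel]                              # (m, n_i)
            ti = rep_trt_i[i]
            sw2 = sd_w[:, ti if self.nw == 2 else 0] ** 2  # (m,)
            sa2 = sd_a[:, ti if self.na == 2 else 0] ** 2
            gg = g @ g
            denom = sw2 + sa2 * gg
            n_i = g.size
            # N(r; 0, sw2 I + sa2 g g') via Woodbury/matrix determinant lemma
            rg = r @ g                                     # (m,)
            quad = (r**2).sum(axis=1) / sw2 - sa2 * rg**2 / (sw2 * denom)
            logdet = n_i * np.log(sw2) + np.log(denom / sw2)
            out[:, i] = -0.5 * (n_i * np.log(2 * np.pi) + logdet + quad)
        return out

    def initial(self, rng, n_walkers):
        d = self.d
        beta0, *_ = np.linalg.lstsq(d["X"], d["y"], rcond=None)
        p = self.n_fixed
        th = np.empty((n_walkers, len(self.param_names)))
        th[:, :p] = beta0 + rng.normal(0, 0.05, size=(n_walkers, p))
        th[:, self._ar_col] = np.clip(th[:, self._ar_col], -0.9, 0.9)
        resid_sd = np.std(d["y"] - d["X"] @ beta0) + 0.5
        th[:, p:] = np.log(resid_sd) + rng.normal(
            0, 0.4, size=(n_walkers, self.nw + self.na)
        )
        return th


def compare_variance_models(
    series: pd.DataFrame,
    spec: MeanSpec = MeanSpec(),
    config: SamplerConfig | None = None,
    founder_extent: int = FOUNDER_EXTENT,
) -> ModelComparison:
    """WAIC comparison of the four variance structures at a fixed mean
    specification."""
    names, fits = [], []
    for k, structure in enumerate(VARIANCE_STRUCTURES):
        cfg = config or SamplerConfig()
        cfg = SamplerConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 * k})
        model = SpreadVarianceModel(series, structure, spec, founder_extent)
        fit = sample_posterior(model, cfg)
        fit.name = structure.label()
        names.append(structure.label())
        fits.append(fit)
    return ModelComparison.from_results(names, fits)


def variance_ratio(fit: FitResult) -> dict:
    """Posterior summary of sigma2_among(sorted) / sigma2_among(shuffled).

    Requires a fit whose among-replicate variance is treatment-specific.
    """
    cols = [c for c in fit.draws.columns if c.startswith("log_sd_among_")]
    if len(cols) != 2:
        raise ValueError("fit does not have treatment-specific among-replicate variance")
    ratio = np.exp(2.0 * (fit.draws[cols[0]] - fit.draws[cols[1]])).to_numpy()
    q = np.quantile(ratio, [0.025, 0.5, 0.975])
    return {"median": q[1], "q2.5": q[0], "q97.5": q[2], "draws": ratio}


def cv_by_generation(series: pd.DataFrame) -> pd.DataFrame:
    """Coefficient of variation of extent across replicates, per treatment
    and generation. Cells with zero mean are flagged NaN."""
    s = _validate_series(series)
    def _cv(g):
        m = g.mean()
        if g.size < 2:
            raise ValueError("CV needs >= 2 replicates per cell")
        return np.nan if m == 0 else g.std(ddof=1) / m
    out = (
        s.groupby(["treatment", "generation"])["extent"].apply(_cv).rename("cv").reset_index()
    )
    return out


def simulate_extent_series(
    params: dict,
    n_reps_per_treatment: int = 9,
    n_generations: int = 10,
    seed: int = 0,
    founder_extent: int = FOUNDER_EXTENT,
) -> pd.DataFrame:
    """Generate an extent panel directly from the AR(1) model (for
    parameter-recovery and calibration studies).

    ``params`` keys: "1", "AR", "TRT", "GEN", "TRTxGEN", "GEN2" (missing
    terms are 0), "sigma_among" (scalar or (sorted, shuffled)),
    "sigma_within" (same).
    """
    rng = np.random.default_rng(seed)
    sa = np.broadcast_to(np.atleast_1d(params.get("sigma_among", 0.0)), (2,))
    sw = np.broadcast_to(np.atleast_1d(params.get("sigma_within", 1.0)), (2,))
    rows = []
    for t_i, trt in enumerate(("sorted", "shuffled")):
        tt = float(t_i)
        for r in range(n_reps_per_treatment):
            gamma = rng.normal(0, sa[t_i])
            prev = float(founder_extent)
            for gen in range(1, n_generations + 1):
                mu = (
                    params.get("1", 0.0)
                    + params.get("TRT", 0.0) * tt
                    + (params.get("GEN", 0.0) + gamma + params.get("TRTxGEN", 0.0) * tt) * gen
                    + params.get("GEN2", 0.0) * gen**2
                    + params.get("AR", 0.0) * prev
                )
                y = rng.normal(mu, sw[t_i])
                rows.append(
                    {"replicate": f"{trt[:4]}_{r+1}", "treatment": trt,
                     "generation": gen, "extent": y}
                )
                prev = y
    return pd.DataFrame(rows)
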