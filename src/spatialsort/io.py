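"""Table I/O, configuration and end-to-end pipeline orchestration.

All datasets move as tidy delimited-text tables with documented headers —
the same layout whether they come from the simulator or from a real
experiment's deposited data. ``read_table`` validates column presence,
dtypes, label sets and sign constraints and reports offending rows by
number.

``run_pipeline`` chains the full analysis: simulate (or load) -> spread
model selection -> variance-structure comparison -> kernel fits -> KS test
-> wave-kernel pre/post comparison -> half-sib comparison -> demography
GLMMs, and stamps every artifact with the configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demography, kernels, spread
from .halfsib import additive_variance_summary, compare_halfsib_models
from .inference import SamplerConfig
from .kernels import KernelSpec, discrete_ks_test, fit_pig_ml, fit_wave_kernels
from .simulate import SimConfig, generate_common_garden, generate_halfsib_design, run_experiment

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "read_table",
    "write_table",
    "PipelineConfig",
    "run_pipeline",
    "simulate_datasets",
]

log = logging.getLogger("spatialsort")

TREATMENTS = ("sorted", "shuffled")
SEXES = ("female", "male")

#: kind -> {column: (dtype kind, validator description, validator)}
SCHEMAS: dict[str, dict] = {
    "extents": {
        "replicate": ("str", None),
        "treatment": ("str", TREATMENTS),
        "generation": ("int", "nonneg"),
        "extent": ("int", "nonneg"),
    },
    "patch_counts": {
        "replicate": ("str", None),
        "treatment": ("str", TREATMENTS),
        "generation": ("int", "nonneg"),
        "patch": ("int", None),
        "females": ("int", "nonneg"),
        "males": ("int", "nonneg"),
    },
    "bottlenecks": {
        "replicate": ("str", None),
        "treatment": ("str", TREATMENTS),
        "generation": ("int", "nonneg"),
        "females_in_leading_patch": ("int", "nonneg"),
    },
    "dispersal": {
        "replicate": ("str", None),
        "treatment": ("str", TREATMENTS),
        "sex": ("str", SEXES),
        "cg_generation": ("int", "nonneg"),
        "trial": ("int", "nonneg"),
        "distance": ("int", None),
    },
    "fertility": {
        "replicate": ("str", None),
        "treatment": ("str", TREATMENTS),
        "cg_generation": ("int", "nonneg"),
        "female": ("int", "nonneg"),
        "offspring": ("int", "nonneg"),
    },
    "pedigree": {
        "sire": ("str", None),
        "dam": ("str", None),
        "family": ("int", "nonneg"),
        "trial": ("int", "nonneg"),
        "sex": ("str", SEXES),
        "distance": ("int", "nonneg"),
    },
}


class SchemaError(ValueError):
    """A table violated its declared schema."""


def _validate(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; know {sorted(SCHEMAS)}")
    schema = SCHEMAS[kind]
    missing = set(schema) - set(df.columns)
    if missing:
        raise SchemaError(f"{kind}: missing columns {sorted(missing)}")
    for col, (dtype, check) in schema.items():
        s = df[col]
        if dtype == "int":
            bad = s.isna() | (s.astype(float) != s.astype(float).round())
            if bad.any():
                raise SchemaError(
                    f"{kind}.{col}: non-integer values at rows {df.index[bad].tolist()[:5]}"
                )
            df[col] = s.astype(int)
            if check == "nonneg" and (df[col] < 0).any():
                rows = df.index[df[col] < 0].tolist()[:5]
                raise SchemaError(f"{kind}.{col}: negative values at rows {rows}")
        elif isinstance(check, tuple):
            bad = ~s.isin(check)
            if bad.any():
                rows = df.index[bad].tolist()[:5]
                raise SchemaError(
                    f"{kind}.{col}: labels outside {check} at rows {rows}"
                )
    return df


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and validate one tidy table (comma- or tab-delimited)."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    df = _validate(df, kind)
    log.info("read %s: %d rows from %s", kind, len(df), path)
    return df


def write_table(df: pd.DataFrame, path, kind: str | None = None) -> None:
    """Write a tidy table (validating first when ``kind`` is given)."""
    if kind is not None:
        _validate(df.copy(), kind)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=False)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    Either ``simulate=True`` (the simulator generates every dataset from
    ``sim``) or ``input_dir`` points at a directory of tables named
    ``extents.csv``, ``patch_counts.csv``, ``bottlenecks.csv``,
    ``dispersal.csv``, ``fertility.csv``, ``pedigree.csv``.
    """

    simulate: bool = True
    input_dir: str | None = None
    output_dir: str | None = None
    seed: int = 0
    n_replicates: int = 9
    sim: SimConfig = field(default_factory=SimConfig)
    sampler_steps: int = 2000
    kernel_specs: tuple = (
        ("", False),
        ("", True),
        ("TRT", False),
        ("TRT", True),
        ("TRT+CGG", False),
    )
    ks_n_boot: int = 10_000
    glmm_quad: int = 15

    def __post_init__(self) -> None:
        if not self.simulate and self.input_dir is None:
            raise ValueError("need input_dir when simulate is False")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir", None)  # where results land is not what they are
        payload["sim"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self.sim).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["sim"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self.sim).items()
        }
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        sim = payload.pop("sim", {})
        for k in ("g_cov", "e_cov"):
            if k in sim:
                sim[k] = np.asarray(sim[k])
        ks = payload.pop("kernel_specs", None)
        cfg = cls(sim=SimConfig(**sim), **payload)
        if ks is not None:
            cfg.kernel_specs = tuple(tuple(s) for s in ks)
        return cfg


def simulate_datasets(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the full two-treatment experiment and derive every downstream
    dataset (spread series, common-garden dispersal + fertility, half-sib
    pedigree, bottleneck records)."""
    exp = run_experiment(config.sim, config.n_replicates, seed=config.seed)
    finals = {
        rid: ("shuffled" if rid.startswith("shuf") else "sorted", res.final_state)
        for rid, res in exp["results"].items()
    }
    disp, fert = generate_common_garden(finals, config.sim, config.seed)
    ped = generate_halfsib_design(config.sim, config.seed)
    return {
        "extents": exp["extents"],
        "patch_counts": exp["patch_counts"],
        "bottlenecks": exp["bottlenecks"],
        "dispersal": disp,
        "fertility": fert,
        "pedigree": ped,
    }


def load_datasets(input_dir) -> dict[str, pd.DataFrame]:
    input_dir = Path(input_dir)
    return {
        kind: read_table(input_dir / f"{kind}.csv", kind) for kind in SCHEMAS
    }


def _kernel_spec(terms_str: str, het: bool) -> KernelSpec:
    terms = tuple(t for t in terms_str.split("+") if t)
    return KernelSpec(terms, het)


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Execute the analysis pipeline and return a structured report.

    ``stages`` selects a subset of
    ``("spread", "kernels", "ks", "wave", "halfsib", "demography")``;
    default runs everything. If ``config.output_dir`` is set, tables and a
    JSON report are written there, stamped with the config hash and seed.
    """
    stages = stages or ("spread", "kernels", "ks", "wave", "halfsib", "demography")
    data = (
        simulate_datasets(config) if config.simulate else load_datasets(config.input_dir)
    )
    for kind, df in data.items():
        log.info("stage data: %s has %d rows", kind, len(df))
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_rows": {k: len(v) for k, v in data.items()},
    }
    sc = SamplerConfig(n_steps=config.sampler_steps, seed=config.seed)

    if "spread" in stages:
        mean_cmp = spread.select_mean_model(data["extents"])
        best_spec = spread.MeanSpec(
            tuple(t for t in mean_cmp.best_name.split("+") if t not in ("1", "AR"))
        )
        var_cmp = spread.compare_variance_models(data["extents"], best_spec, sc)
        w = dict(zip(var_cmp.names, var_cmp.weights))
        among_fit = var_cmp.results[var_cmp.names.index("within=hom,among=trt")]
        ratio = spread.variance_ratio(among_fit)
        ratio.pop("draws", None)
        fin = data["extents"].query("generation == generation.max()")
        mean_ext = fin.groupby("treatment")["extent"].mean()
        report["spread"] = {
            "mean_model_table": mean_cmp.table(),
            "best_mean_model": mean_cmp.best_name,
            "variance_model_table": var_cmp.table(),
            "among_variance_weight": w["within=hom,among=trt"] + w["within=trt,among=trt"],
            "variance_ratio_sorted_over_shuffled": ratio,
            "final_extent_sorted": float(mean_ext.get("sorted", np.nan)),
            "final_extent_shuffled": float(mean_ext.get("shuffled", np.nan)),
            "sorted_advantage_pct": float(
                100.0 * (mean_ext["sorted"] / mean_ext["shuffled"] - 1.0)
            ),
            "cv": spread.cv_by_generation(data["extents"]),
        }
        log.info("stage spread: best mean model %s", mean_cmp.best_name)

    if "kernels" in stages:
        specs = [_kernel_spec(t, h) for t, h in config.kernel_specs]
        kernel_report = {}
        for sex in SEXES:
            cmp = kernels.compare_kernel_models(data["dispersal"], sex, specs, sc)
            wt = dict(zip(cmp.names, cmp.weights))
            trt_weight = sum(v for k, v in wt.items() if "TRT" in k)
            kernel_report[sex] = {
                "table": cmp.table(),
                "best": cmp.best_name,
                "treatment_effect_weight": trt_weight,
            }
            log.info("stage kernels (%s): best %s", sex, cmp.best_name)
        report["kernels"] = kernel_report

    if "ks" in stages:
        # sample a = shuffled, b = sorted: D+ measures the excess of the
        # shuffled ecdf over the sorted one, i.e. D+ > 0 when beetles from
        # sorted invasions disperse farther
        d = data["dispersal"]
        a = d.loc[d.treatment == "shuffled", "distance"].abs()
        b = d.loc[d.treatment == "sorted", "distance"].abs()
        ks = discrete_ks_test(a, b, n_boot=config.ks_n_boot, rng=config.seed)
        report["ks"] = ks
        log.info("stage ks: D+=%.4f p=%.3g", ks.d_plus, ks.p_value_plus)

    if "wave" in stages:
        gen1 = data["patch_counts"].query("generation == 1")
        pre_fits, post_fits = {}, {}
        for trt in TREATMENTS:
            for sex in SEXES:
                pre_fits[(trt, sex)] = fit_wave_kernels(gen1, sex, trt)
        d1 = data["dispersal"].query("cg_generation == 1")
        for (rep, trt, sex), grp in d1.groupby(["replicate", "treatment", "sex"]):
            post_fits[(rep, trt, sex)] = fit_pig_ml(grp["distance"].abs())
        shifts = kernels.compare_pre_post(pre_fits, post_fits)
        report["wave"] = {
            "pre_estimates": {
                k: dict(xi=float(f.draws["xi"].iloc[0]), omega=float(f.draws["omega"].iloc[0]))
                for k, f in pre_fits.items()
            },
            "shift_table": shifts,
            "mean_shift_by_treatment": shifts.groupby("treatment")["shift"].mean().to_dict(),
        }
        log.info("stage wave: %d shifts", len(shifts))

    if "halfsib" in stages:
        hs_report = {}
        for sex in SEXES:
            cmp = compare_halfsib_models(data["pedigree"], sex, sc)
            wt = dict(zip(cmp.names, cmp.weights))
            summary = additive_variance_summary(cmp.results[cmp.names.index("sire+dam")])
            hs_report[sex] = {
                "table": cmp.table(),
                "best": cmp.best_name,
                "sire_model_weight": wt["sire+dam"],
                "additive_variance": summary,
            }
            log.info("stage halfsib (%s): best %s", sex, cmp.best_name)
        report["halfsib"] = hs_report

    if "demography" in stages:
        fert_cmp = demography.fit_fertility_models(data["fertility"], config.glmm_quad)
        bn_cmp = demography.fit_bottleneck_models(data["bottlenecks"], config.glmm_quad)
        report["demography"] = {
            "fertility_table": fert_cmp.table(),
            "fertility_best": fert_cmp.best_name,
            "fertility_null_weight": dict(zip(fert_cmp.names, fert_cmp.weights))["1"],
            "bottleneck_table": bn_cmp.table(),
            "bottleneck_best": bn_cmp.best_name,
        }
        log.info(
            "stage demography: fertility best %s, bottleneck best %s",
            fert_cmp.best_name,
            bn_cmp.best_name,
        )

    if config.output_dir is not None:
        _write_report(report, data, config)
    return report


def _jsonable(obj):
    import dataclasses

    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_report(report: dict, data: dict, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": report["config_hash"], "seed": config.seed}
    for kind, df in data.items():
        write_table(df, out / f"{kind}.csv", kind)
    for key in ("spread", "kernels", "halfsib", "demography"):
        if key not in report:
            continue
        section = report[key]
        for name, val in list(section.items()) if isinstance(section, dict) else []:
            if isinstance(val, pd.DataFrame):
                t = val.copy()
                for k, v in stamp.items():
                    t[k] = v
                write_table(t, out / f"{key}_{name}.csv")
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=1, default=str))
    config.to_yaml(out / "config.yaml")
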