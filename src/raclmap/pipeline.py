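"""Reproducible simulate → quantify → screen → fit → report workflow.

:class:`PipelineConfig` is a validated (pydantic) mirror of a YAML config
file; :func:`run_pipeline` executes the requested stages in order, writing
every artifact to the output directory stamped with the root seed and a
hash of the canonical config.  All randomness flows from the one root
seed, and no artifact embeds a timestamp, so a rerun with the same config
is byte-identical.

Artifacts
---------
``bp.csv``               long BP_ND table (Logan-quantified, or the simulated
                         truth when the logan stage is off)
``tacs/<subject>.csv``   simulated TACs (only when the logan stage runs)
``screening.json``       outlier / distribution screening report
``fit_<model>.json``     one FitResult export per requested model
``fit_comparison.csv``   fit-index table across models
``striatal_linkage.json``  optional striatal-linkage correlations
``summary.md``           human-readable report
``manifest.json``        versions, config hash, seed, artifact list
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from pydantic import BaseModel, Field, field_validator

from .kinetics import TimeActivityCurve, batch_bpnd, read_tacs, write_tacs
from .models import (build_anatomical_spec, build_functional_spec,
                     build_one_factor_spec, striatal_linkage)
from .population import (KineticConfig, attach_tacs, default_population,
                         simulate_bp_table)
from .regions import HEMISPHERES, NeighborPolicy, wide_table
from .screening import screen_outliers
from .sem import FactorModelResults, HierarchicalFactorModel

logger = logging.getLogger(__name__)

#: Conventional good-fit bounds used for flagging in reports.
CFI_GOOD = 0.90
RMSEA_GOOD = 0.08

STAGES = ("simulate", "logan", "screen", "fit", "report")
MODEL_CHOICES = ("anatomical", "anatomical-one-factor",
                 "functional", "functional-one-factor")
REFERENCE_LABEL = "cerebellum"


class NumericalError(RuntimeError):
    """A stage failed for numerical reasons (singular moments,
    non-convergence); distinct from configuration/user errors."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

class PopulationConfig(BaseModel):
    model_config = {"extra": "forbid"}

    model_id: str = "anatomical"
    n_subjects: int = Field(176, ge=4)
    loading: float = Field(0.9, gt=0.0, lt=1.0)
    residual_cov_scale: float = Field(0.1, ge=0.0)
    overrides: dict = Field(default_factory=dict)

    @field_validator("model_id")
    @classmethod
    def _known_model(cls, v):
        if v not in ("anatomical", "functional"):
            raise ValueError("model_id must be 'anatomical' or 'functional'")
        return v


class KineticsConfig(BaseModel):
    model_config = {"extra": "forbid"}

    t_star: float = Field(18.0, gt=0.0)
    method: str = "perpendicular"
    noise_sigma: float = Field(0.0, ge=0.0)
    r1: float = Field(1.0, gt=0.0)
    k2: float = Field(0.4, gt=0.0)
    negative_bp: str = "truncate"
    schedule_durations: list[float] | None = None
    write_tacs: bool = False

    @field_validator("method")
    @classmethod
    def _known_method(cls, v):
        if v not in ("ols", "perpendicular"):
            raise ValueError("method must be 'ols' or 'perpendicular'")
        return v

    @field_validator("negative_bp")
    @classmethod
    def _known_policy(cls, v):
        if v not in ("reject", "truncate"):
            raise ValueError("negative_bp must be 'reject' or 'truncate'")
        return v


class ScreeningConfig(BaseModel):
    model_config = {"extra": "forbid"}

    z_cut: float = Field(3.29, gt=0.0)
    maha_p: float = Field(0.001, gt=0.0, lt=1.0)
    max_missing_fraction: float = Field(0.01, ge=0.0, le=1.0)


class FitConfig(BaseModel):
    model_config = {"extra": "forbid"}

    models: list[str] = Field(default_factory=lambda: ["anatomical",
                                                       "anatomical-one-factor"])
    mean_structure: bool = True
    n_restarts: int = Field(2, ge=0)
    compute_se: bool = True
    neighbor_pairs: list[list[str]] | None = None
    striatal_linkage: bool = False

    @field_validator("models")
    @classmethod
    def _known_models(cls, v):
        bad = [m for m in v if m not in MODEL_CHOICES]
        if bad:
            raise ValueError(f"unknown model(s) {bad}; choose from {MODEL_CHOICES}")
        if not v:
            raise ValueError("at least one model must be requested")
        return v


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML-loadable)."""

    model_config = {"extra": "forbid"}

    seed: int = Field(42, ge=0, lt=2 ** 31)
    stages: list[str] = Field(default_factory=lambda: list(STAGES))
    output_dir: str = "raclmap_out"
    tac_dir: str | None = None          # external TACs for the logan stage
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    screening: ScreeningConfig = Field(default_factory=ScreeningConfig)
    fit: FitConfig = Field(default_factory=FitConfig)

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v):
        bad = [s for s in v if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage(s) {bad}; choose from {STAGES}")
        if not v:
            raise ValueError("at least one stage must be requested")
        return [s for s in STAGES if s in v]     # canonical order

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a YAML mapping")
        return cls(**raw)

    def canonical_json(self) -> str:
        # output_dir is where artifacts land, not what they contain; leaving
        # it out keeps reruns into different directories byte-identical
        dumped = self.model_dump()
        dumped.pop("output_dir")
        return json.dumps(dumped, sort_keys=True, separators=(",", ":"))

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# stage helpers
# --------------------------------------------------------------------------

def _build_population(cfg: PipelineConfig):
    pop = default_population(cfg.population.model_id,
                             n_subjects=cfg.population.n_subjects,
                             seed=cfg.seed,
                             loading=cfg.population.loading,
                             residual_cov_scale=cfg.population.residual_cov_scale)
    if cfg.population.overrides:
        fields = {"latent_means", "latent_sd", "first_order_loadings",
                  "second_order_loadings", "residual_sd", "residual_cov_pairs",
                  "n_subjects"}
        bad = set(cfg.population.overrides) - fields
        if bad:
            raise ValueError(f"unknown population override(s): {sorted(bad)}")
        updates = {}
        for k, v in cfg.population.overrides.items():
            if isinstance(v, dict) and isinstance(getattr(pop, k), dict):
                updates[k] = {**getattr(pop, k), **v}
            elif k == "residual_cov_pairs":
                updates[k] = tuple(tuple(p) for p in v)
            else:
                updates[k] = v
        pop = replace(pop, **updates)
    return pop


def _kinetic_config(cfg: PipelineConfig) -> KineticConfig:
    k = cfg.kinetics
    return KineticConfig(
        r1=k.r1, k2=k.k2, noise_sigma=k.noise_sigma, negative_bp=k.negative_bp,
        schedule_durations=tuple(k.schedule_durations) if k.schedule_durations
        else None)


def _neighbor_policy(cfg: PipelineConfig) -> NeighborPolicy | None:
    if cfg.fit.neighbor_pairs is None:
        return None
    pairs = []
    for pair in cfg.fit.neighbor_pairs:
        if len(pair) != 2:
            raise ValueError(f"neighbor pair must have 2 regions, got {pair}")
        pairs.append(tuple(pair))
    return NeighborPolicy(tuple(pairs))


def _build_spec(name: str, cfg: PipelineConfig):
    policy = _neighbor_policy(cfg)
    mean = cfg.fit.mean_structure
    if name.startswith("anatomical"):
        kw = {} if policy is None else {"policy": policy}
        base = build_anatomical_spec(mean_structure=mean, **kw)
    else:
        kw = {} if policy is None else {"policy": policy}
        base = build_functional_spec(mean_structure=mean, **kw)
    if name.endswith("one-factor"):
        return build_one_factor_spec(base)
    return base


def read_tac_directory(tac_dir) -> tuple[dict, dict]:
    """Read per-subject TAC CSVs (``<subject_id>.csv`` in the
    :func:`raclmap.kinetics.write_tacs` format).  The curve labelled
    ``cerebellum`` is the reference; all others are target regions."""
    tac_dir = Path(tac_dir)
    if not tac_dir.is_dir():
        raise FileNotFoundError(f"TAC directory not found: {tac_dir}")
    files = sorted(tac_dir.glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no .csv TAC files in {tac_dir}")
    tac_set: dict[str, dict[str, TimeActivityCurve]] = {}
    references: dict[str, TimeActivityCurve] = {}
    for f in files:
        sid = f.stem
        curves = {t.region: t for t in read_tacs(f)}
        if REFERENCE_LABEL not in curves:
            raise ValueError(f"{f} has no '{REFERENCE_LABEL}' reference curve")
        references[sid] = curves.pop(REFERENCE_LABEL)
        tac_set[sid] = curves
    return tac_set, references


def _write_tac_directory(tac_set, references, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for sid, curves in tac_set.items():
        ref = references[sid]
        ref = TimeActivityCurve(ref.schedule, ref.activity, region=REFERENCE_LABEL)
        write_tacs([ref] + list(curves.values()), out_dir / f"{sid}.csv")


def _json_bytes(obj) -> str:
    return json.dumps(obj, sort_keys=True, indent=2) + "\n"


def _fit_flags(res_dict: dict) -> dict:
    return {"cfi_ok": res_dict["cfi"] >= CFI_GOOD,
            "rmsea_ok": res_dict["rmsea"] <= RMSEA_GOOD}


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

def report(fit_results) -> tuple[str, dict]:
    """Markdown + JSON summary of one or more fitted models.

    Accepts :class:`FactorModelResults` objects or previously exported
    JSON dicts.  Flags each model against the conventional good-fit
    bounds (CFI >= 0.90, RMSEA <= 0.08).
    """
    if not fit_results:
        raise ValueError("report requires at least one fit result")
    dicts = []
    for r in fit_results:
        d = r.to_json_dict() if isinstance(r, FactorModelResults) else dict(r)
        d["flags"] = _fit_flags(d)
        dicts.append(d)

    lines = ["# Model fit report", "",
             "| model | chi2 | df | p | CFI | RMSEA | RMSEA 90% CI | fit |",
             "|---|---|---|---|---|---|---|---|"]
    for d in dicts:
        lo, hi = d["rmsea_ci90"]
        ok = d["flags"]["cfi_ok"] and d["flags"]["rmsea_ok"]
        verdict = "good" if ok else "poor"
        lines.append(
            f"| {d['model']} | {d['chi_square']:.2f} | {d['df']} | "
            f"{d['p_value']:.4f} | {d['cfi']:.3f} | {d['rmsea']:.3f} | "
            f"[{lo:.3f}, {hi:.3f}] | {verdict} |")
    lines.append("")
    lines.append(f"Good fit is flagged as CFI >= {CFI_GOOD:.2f} and "
                 f"RMSEA <= {RMSEA_GOOD:.2f}.")

    for d in dicts:
        if d.get("factor_correlations"):
            lines += ["", f"## {d['model']}: second-order factor correlations", ""]
            for pair, val in sorted(d["factor_correlations"].items()):
                lines.append(f"- {pair.replace(',', ' – ')}: {val:.3f}")
        if d.get("latent_means"):
            lines += ["", f"## {d['model']}: latent region means (BP_ND)", "",
                      "| factor | mean | SE |", "|---|---|---|"]
            for f, row in d["latent_means"].items():
                lines.append(f"| {f} | {row['mean']:.3f} | {row['se']:.3f} |")

    summary = {"models": dicts,
               "bounds": {"cfi": CFI_GOOD, "rmsea": RMSEA_GOOD}}
    return "\n".join(lines) + "\n", summary


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """In-memory handles to everything the pipeline produced."""

    config: PipelineConfig
    output_dir: Path
    bp_table: pd.DataFrame | None = None
    screening_report: object = None
    fits: dict = None
    comparison: pd.DataFrame | None = None
    summary_markdown: str | None = None
    artifacts: list = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the configured stages in order, writing artifacts as we go.

    A stage failure raises after the already-produced artifacts are on
    disk, with the failing stage named in the exception.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}
    artifacts: list[str] = []
    result = PipelineResult(config=config, output_dir=out, fits={}, artifacts=artifacts)

    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("raclmap")
    root.addHandler(log_handler)
    try:
        _run_stages(config, out, stamp, artifacts, result)
    except Exception:
        logger.exception("pipeline aborted; partial outputs kept in %s", out)
        raise
    finally:
        root.removeHandler(log_handler)
        log_handler.close()

    manifest = {
        **stamp,
        "config": config.model_dump(),
        "versions": _versions(),
        "artifacts": sorted(artifacts),
    }
    (out / "manifest.json").write_text(_json_bytes(manifest))
    return result


def _versions() -> dict:
    import scipy

    from . import __version__
    return {"raclmap": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__}


def _run_stages(config, out, stamp, artifacts, result):
    stages = config.stages
    dataset = None
    bp = None

    if "simulate" in stages:
        logger.info("stage simulate: model=%s n=%d seed=%d",
                    config.population.model_id, config.population.n_subjects,
                    config.seed)
        try:
            dataset = simulate_bp_table(_build_population(config))
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"stage simulate: {exc}") from exc
        bp = dataset.bp_table

    if "logan" in stages:
        logger.info("stage logan: t_star=%.1f method=%s",
                    config.kinetics.t_star, config.kinetics.method)
        if config.tac_dir is not None:
            tac_set, references = read_tac_directory(config.tac_dir)
        elif dataset is not None:
            tac_set, references = attach_tacs(dataset, _kinetic_config(config))
            if config.kinetics.write_tacs:
                _write_tac_directory(tac_set, references, out / "tacs")
                artifacts.append("tacs/")
        else:
            raise ValueError("stage logan needs either the simulate stage "
                             "or a tac_dir in the config")
        bp_logan = batch_bpnd(tac_set, references,
                              t_star=config.kinetics.t_star,
                              method=config.kinetics.method)
        n_failed = int(bp_logan["bp_nd"].isna().sum())
        if n_failed == len(bp_logan):
            raise NumericalError("stage logan: every Logan fit failed")
        if n_failed:
            logger.warning("stage logan: %d fit(s) failed and are missing",
                           n_failed)
        if dataset is not None:
            # striatal subdivisions are quantified from bilateral-mean data,
            # not per-hemisphere TACs; carry the simulated values through
            non_hemi = bp[~bp["hemisphere"].isin(HEMISPHERES)]
            bp = pd.concat([bp_logan, non_hemi], ignore_index=True)
        else:
            bp = bp_logan

    if bp is not None:
        bp_out = bp.copy()
        bp_out.insert(0, "seed", stamp["seed"])
        bp_out.insert(1, "config_hash", stamp["config_hash"])
        bp_out.to_csv(out / "bp.csv", index=False, float_format="%.8g")
        artifacts.append("bp.csv")
    result.bp_table = bp

    wide = None
    if bp is not None:
        wide = wide_table(bp[bp["hemisphere"].isin(HEMISPHERES)])

    if "screen" in stages:
        if wide is None:
            raise ValueError("stage screen needs BP_ND data from a prior stage")
        logger.info("stage screen: z_cut=%.2f maha_p=%g",
                    config.screening.z_cut, config.screening.maha_p)
        try:
            wide, sreport = screen_outliers(
                wide, z_cut=config.screening.z_cut,
                maha_p=config.screening.maha_p,
                max_missing_fraction=config.screening.max_missing_fraction)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"stage screen: {exc}") from exc
        for w in sreport.warnings:
            logger.warning("stage screen: %s", w)
        payload = json.loads(sreport.to_json())
        payload.update(stamp)
        (out / "screening.json").write_text(_json_bytes(payload))
        artifacts.append("screening.json")
        result.screening_report = sreport

    if "fit" in stages:
        if wide is None:
            raise ValueError("stage fit needs BP_ND data from a prior stage")
        _fit_stage(config, out, stamp, artifacts, result, wide, dataset)

    if "report" in stages:
        if not result.fits:
            raise ValueError("stage report needs at least one fitted model")
        md, summary = report(list(result.fits.values()))
        summary.update(stamp)
        (out / "summary.md").write_text(md)
        (out / "summary.json").write_text(_json_bytes(summary))
        artifacts += ["summary.md", "summary.json"]
        result.summary_markdown = md


def _fit_stage(config, out, stamp, artifacts, result, wide, dataset):
    cohort_kind = config.population.model_id if "simulate" in config.stages else None
    rows = []
    for name in config.fit.models:
        if cohort_kind is not None and not name.startswith(cohort_kind):
            raise ValueError(
                f"model {name!r} cannot be fitted to a {cohort_kind!r} cohort: "
                "the indicator sets differ")
        logger.info("stage fit: model=%s", name)
        spec = _build_spec(name, config)
        missing = [i for i in spec.indicators if i not in wide.columns]
        if missing:
            raise ValueError(f"model {name!r} needs indicators absent from the "
                             f"data: {missing}")
        model = HierarchicalFactorModel(spec, data=wide)
        try:
            res = model.fit(n_restarts=config.fit.n_restarts,
                            compute_se=config.fit.compute_se,
                            rng=config.seed)
        except (np.linalg.LinAlgError, RuntimeError) as exc:
            raise NumericalError(f"stage fit ({name}): {exc}") from exc
        if not res.info.get("converged", True):
            raise NumericalError(f"stage fit ({name}): optimizer did not converge")
        result.fits[name] = res
        payload = res.to_json_dict()
        payload["flags"] = _fit_flags(payload)
        payload.update(stamp)
        (out / f"fit_{name}.json").write_text(_json_bytes(payload))
        artifacts.append(f"fit_{name}.json")
        lo, hi = res.rmsea_ci90
        rows.append((name, res.chi_square, res.df, res.p_value, res.cfi,
                     res.rmsea, lo, hi,
                     res.cfi >= CFI_GOOD and res.rmsea <= RMSEA_GOOD))

    comparison = pd.DataFrame(rows, columns=["model", "chi_square", "df", "p_value",
                                             "cfi", "rmsea", "rmsea_ci_lo",
                                             "rmsea_ci_hi", "good_fit"])
    comparison.insert(0, "seed", stamp["seed"])
    comparison.to_csv(out / "fit_comparison.csv", index=False, float_format="%.6f")
    artifacts.append("fit_comparison.csv")
    result.comparison = comparison

    # hierarchical vs one-factor comparison, when both were fitted (the
    # one-factor model is nested in distribution; its parameter names
    # differ, so the difference test is computed directly)
    for base in ("anatomical", "functional"):
        free, cons = result.fits.get(base), result.fits.get(f"{base}-one-factor")
        if free is not None and cons is not None:
            d = cons.chi_square - free.chi_square
            ddf = cons.df - free.df
            p = float(stats.chi2.sf(d, ddf)) if d > 0 and ddf > 0 else 1.0
            logger.info("delta chi-square %s vs one-factor: %.2f (df=%d, p=%.4g)",
                        base, d, ddf, p)

    if config.fit.striatal_linkage:
        if dataset is None or dataset.params.striatal is None:
            raise ValueError("striatal_linkage requires a simulated functional "
                             "cohort (striatal subdivisions present)")
        logger.info("stage fit: striatal linkage")
        try:
            link = striatal_linkage(wide, dataset.striatal_wide(),
                                    n_restarts=config.fit.n_restarts,
                                    rng=config.seed)
        except (np.linalg.LinAlgError, RuntimeError) as exc:
            raise NumericalError(f"stage fit (striatal linkage): {exc}") from exc
        payload = {
            "raw": {s: {f: round(float(v), 6) for f, v in r.items()}
                    for s, r in link.raw.iterrows()},
            "adjusted": {s: {f: round(float(v), 6) for f, v in r.items()}
                         for s, r in link.adjusted.iterrows()},
            **stamp,
        }
        (out / "striatal_linkage.json").write_text(_json_bytes(payload))
        artifacts.append("striatal_linkage.json")
        result.fits["striatal-linkage"] = link.fit
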