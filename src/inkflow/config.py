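"""Pipeline configuration, orchestration and reporting.

A single YAML (or programmatic) :class:`PipelineConfig` drives the whole
composition -> rheology -> nozzle-flow -> surrogate -> toolpath pipeline.
The schema is strict (unknown keys rejected) and every run writes the
resolved configuration, all artifact tables and a manifest of output
hashes into its run directory, so a rerun with the same configuration is
byte-identical.

One master seed deterministically derives the per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import nozzleflow, pathplan, rheology, rsm, surrogate, synth

log = logging.getLogger("inkflow")

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "report"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySegmentConfig(_Strict):
    length_mm: float = Field(gt=0)
    r_in_mm: float = Field(gt=0)
    r_out_mm: float = Field(gt=0)


class GeometryConfig(_Strict):
    segments: list[GeometrySegmentConfig] = Field(
        default_factory=lambda: [
            GeometrySegmentConfig(length_mm=10.0, r_in_mm=4.8, r_out_mm=4.8),
            GeometrySegmentConfig(length_mm=20.0, r_in_mm=4.8, r_out_mm=0.125),
            GeometrySegmentConfig(length_mm=12.7, r_in_mm=0.125, r_out_mm=0.125),
        ])

    def build(self) -> nozzleflow.NozzleGeometry:
        return nozzleflow.NozzleGeometry(tuple(
            nozzleflow.NozzleSegment(s.length_mm, s.r_in_mm, s.r_out_mm)
            for s in self.segments))


class BoundsConfig(_Strict):
    n: tuple[float, float] = (0.45, 0.7)
    K_pa_s: tuple[float, float] = (10.0, 100.0)
    P_kpa: tuple[float, float] = (50.0, 350.0)

    @model_validator(mode="after")
    def _ordered(self) -> "BoundsConfig":
        for name in ("n", "K_pa_s", "P_kpa"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"bounds for '{name}' must satisfy low < high, "
                                 f"got ({lo}, {hi})")
        return self

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {"n": self.n, "K_pa_s": self.K_pa_s, "P_kpa": self.P_kpa}


class SurrogateConfig(_Strict):
    n_train: int = Field(default=300, ge=30)
    n_test: int = Field(default=50, ge=1)
    hidden_units: int = Field(default=8, ge=1)
    ridge: float = Field(default=1e-5, ge=0)
    backend: str = "mlp"
    surface_pressure_kpa: float = Field(default=250.0, gt=0)
    surface_grid_steps: int = Field(default=20, ge=2)


class PathConfigSchema(_Strict):
    speed_mm_s: float = Field(default=12.0, gt=0)
    slow_speed_mm_s: float = Field(default=1.0, gt=0)
    slow_time_s: float = Field(default=0.1, ge=0)
    travel_speed_mm_s: float = Field(default=30.0, gt=0)
    layer_thickness_mm: float = Field(default=0.2, gt=0)
    fill_spacing_mm: float = Field(default=0.8, gt=0)
    frame_margin_mm: float = Field(default=0.5, gt=0)
    overlap_d2_mm: float = Field(default=0.3, ge=0)
    nozzle_diameter_mm: float = Field(default=0.25, gt=0)

    def build(self) -> pathplan.PathConfig:
        return pathplan.PathConfig(**self.model_dump())


class PartConfig(_Strict):
    width_mm: float = Field(default=10.0, gt=0)
    depth_mm: float = Field(default=10.0, gt=0)
    layers: int = Field(default=3, ge=1)
    pattern: str = "grid"


class SynthSection(_Strict):
    sigma_log_viscosity: float = Field(default=0.03, ge=0)
    sigma_n: float = Field(default=0.005, ge=0)
    sigma_K_pa_s: float = Field(default=2.0, ge=0)


class PipelineConfig(_Strict):
    """Validated hierarchical configuration for ``run_pipeline``."""

    seed: int = 0
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    bounds: BoundsConfig = Field(default_factory=BoundsConfig)
    surrogate: SurrogateConfig = Field(default_factory=SurrogateConfig)
    path: PathConfigSchema = Field(default_factory=PathConfigSchema)
    part: PartConfig = Field(default_factory=PartConfig)
    synth: SynthSection = Field(default_factory=SynthSection)
    compositions: list[tuple[float, float, float]] = Field(
        default_factory=lambda: [(10, 4, 3), (6, 5, 4), (7, 4, 4),
                                 (7.5, 3, 2), (9, 5, 3)])


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def _stage_seeds(master: int) -> dict[str, int]:
    rng = np.random.default_rng(master)
    return {name: int(rng.integers(2 ** 31))
            for name in ("rheometry", "design", "flows", "surrogate", "regimes")}


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the full pipeline into ``out_dir``; returns the directory.

    Stages: synthetic rheometry fits for the validation compositions ->
    Box-Behnken response fit on synthetic responses -> LHS + solver flow
    dataset -> surrogate training/evaluation -> regime classification ->
    toolpath planning.  Deterministic under the master seed; a manifest of
    SHA-256 output hashes is written last.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    geometry = config.geometry.build()

    (out / "config.yaml").write_text(
        yaml.safe_dump(json.loads(config.model_dump_json()), sort_keys=True),
        encoding="utf-8")

    # -- stage 1: rheometry + power-law fits for validation compositions --
    log.info("stage rheometry: %d compositions", len(config.compositions))
    rows = []
    for i, (g, s, m) in enumerate(config.compositions):
        ratio = rsm.CompositionRatio(g, s, m)
        cfg = synth.SynthConfig(seed=seeds["rheometry"] + i,
                                sigma_log_viscosity=config.synth.sigma_log_viscosity)
        curve = synth.synth_rheometry(ratio, cfg)
        fit = rheology.fit_power_law(curve)
        rows.append({
            "gel_wtpct": g, "sa_wtpct": s, "mc_wtpct": m,
            "n_model": rsm.predict_n(ratio), "K_model_pa_s": rsm.predict_K(ratio),
            "n_fit": fit.params.n, "K_fit_pa_s": fit.params.K,
            "r_squared_loglog": fit.r_squared,
            "n_accuracy": rsm.prediction_accuracy(rsm.predict_n(ratio), fit.params.n),
            "K_accuracy": rsm.prediction_accuracy(rsm.predict_K(ratio), fit.params.K),
        })
    _write_csv(pd.DataFrame(rows), out / "rheology_validation.csv")

    # -- stage 2: Box-Behnken design + response-surface recovery ----------
    log.info("stage design: 17-run Box-Behnken fit")
    design = rsm.make_bb_design()
    responses = synth.synth_bb_responses(design, config.synth.sigma_n,
                                         config.synth.sigma_K_pa_s,
                                         seed=seeds["design"])
    _write_csv(responses, out / "bb_responses.csv")
    n_model, n_report = rsm.backward_eliminate(design, responses["n"].to_numpy(),
                                               response_name="n")
    k_model, k_report = rsm.fit_quadratic(design, responses["K_pa_s"].to_numpy(),
                                          response_name="K")
    (out / "model_n.json").write_text(n_model.to_json(), encoding="utf-8")
    (out / "model_K.json").write_text(k_model.to_json(), encoding="utf-8")
    diag = pd.DataFrame([
        {"response": "n", "r_squared": n_report.r_squared,
         "adj_r_squared": n_report.adj_r_squared,
         "pred_r_squared": n_report.pred_r_squared,
         "lack_of_fit_p": n_report.lack_of_fit_p},
        {"response": "K", "r_squared": k_report.r_squared,
         "adj_r_squared": k_report.adj_r_squared,
         "pred_r_squared": k_report.pred_r_squared,
         "lack_of_fit_p": k_report.lack_of_fit_p},
    ])
    _write_csv(diag, out / "rsm_diagnostics.csv")

    # -- stage 3: flow dataset --------------------------------------------
    log.info("stage flows: %d train + %d test solves",
             config.surrogate.n_train, config.surrogate.n_test)
    train, test = synth.synth_flow_dataset(
        n_train=config.surrogate.n_train, n_test=config.surrogate.n_test,
        bounds=config.bounds.as_dict(), geometry=geometry, seed=seeds["flows"])
    if train.failures or test.failures:
        raise RuntimeError(
            f"flow solver failed at train rows {train.failures} / "
            f"test rows {test.failures}")
    _write_csv(train.points, out / "flow_train.csv")
    _write_csv(test.points, out / "flow_test.csv")

    # -- stage 4: surrogate ------------------------------------------------
    log.info("stage surrogate: backend=%s", config.surrogate.backend)
    model = surrogate.train_surrogate(
        train, hidden_units=config.surrogate.hidden_units,
        ridge=config.surrogate.ridge, seed=seeds["surrogate"],
        backend=config.surrogate.backend)
    err = surrogate.evaluate_surrogate(
        model, test.points[["n", "K_pa_s", "P_kpa"]].to_numpy(),
        test.points["Q_ul_s"].to_numpy())
    if model.backend == "mlp":
        (out / "surrogate.json").write_text(model.to_json(), encoding="utf-8")
    (out / "surrogate_errors.json").write_text(json.dumps({
        "mae_ul_s": err.mae, "rmse_ul_s": err.rmse,
        "mae_pct_of_range": err.mae_pct_of_range,
        "rmse_pct_of_range": err.rmse_pct_of_range,
        "q_range_ul_s": err.q_range, "n_test": err.n_test,
    }, indent=2, sort_keys=True), encoding="utf-8")

    # -- stage 5: regimes ---------------------------------------------------
    surface = surrogate.flow_surface(
        config.surrogate.surface_pressure_kpa,
        grid_steps=config.surrogate.surface_grid_steps, model=model,
        bounds=config.bounds.as_dict())
    labelled = surrogate.classify_regimes(surface, seed=seeds["regimes"])
    _write_csv(labelled, out / "flow_surface_regimes.csv")

    # -- stage 6: toolpath --------------------------------------------------
    log.info("stage toolpath: %s part", config.part.pattern)
    pcfg = config.path.build()
    path = pathplan.plan_grid_prism(config.part.width_mm, config.part.depth_mm,
                                    config.part.layers, pcfg,
                                    pattern=config.part.pattern)
    ref_q = surrogate_reference_flow(model, config)
    book = pathplan.extrusion_bookkeeping(path, ref_q)
    _write_csv(book, out / "toolpath_bookkeeping.csv")
    pathplan.export_gcode(path, out / "part.gcode")

    manifest = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return out


def surrogate_reference_flow(model, config: PipelineConfig) -> float:
    """Surrogate flow rate at the centre of the sampling box."""
    b = config.bounds.as_dict()
    centre = [(lo + hi) / 2 for lo, hi in (b["n"], b["K_pa_s"], b["P_kpa"])]
    return float(model.predict([centre])[0])


def report(run_dir) -> str:
    """Human-readable summary of a completed run (pure read)."""
    run = Path(run_dir)
    manifest_path = run / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {run}; not a completed run")
    lines = [f"inkflow run report: {run}", ""]
    rheo = pd.read_csv(run / "rheology_validation.csv")
    lines.append("Composition model validation (synthetic rheometry):")
    for _, r in rheo.iterrows():
        lines.append(
            f"  {r.gel_wtpct:g}:{r.sa_wtpct:g}:{r.mc_wtpct:g}  "
            f"n {r.n_model:.2f} (fit {r.n_fit:.2f}, acc {100 * r.n_accuracy:.2f}%)  "
            f"K {r.K_model_pa_s:.2f} (fit {r.K_fit_pa_s:.2f}, "
            f"acc {100 * r.K_accuracy:.2f}%) Pa*s")
    err = json.loads((run / "surrogate_errors.json").read_text(encoding="utf-8"))
    lines.append("")
    lines.append(
        f"Surrogate on {err['n_test']} test points: "
        f"MAE {err['mae_ul_s']:.4f} uL/s ({err['mae_pct_of_range']:.2f}% of range), "
        f"RMSE {err['rmse_ul_s']:.4f} uL/s ({err['rmse_pct_of_range']:.2f}% of range)")
    regimes = pd.read_csv(run / "flow_surface_regimes.csv")
    counts = regimes["regime"].value_counts().to_dict()
    lines.append(f"Viscosity regimes on the surface grid: {counts}")
    book = pd.read_csv(run / "toolpath_bookkeeping.csv")
    printing = book[book.extruding]
    lines.append(
        f"Toolpath: {len(book)} segments, {printing.length_mm.sum():.1f} mm printed, "
        f"{printing.volume_ul.sum():.2f} uL deposited, "
        f"{int(printing.slow_start.sum())} slow-starts")
    return "\n".join(lines)
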