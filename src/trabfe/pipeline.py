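"""End-to-end pipeline: phantoms/stacks → coarsening → FE → analysis.

One YAML config drives the whole study: the input (a stack on disk or a
list of phantom specs), the coarsening methods with their d/s grids, the
material, the load, solver options and the output directory. Outputs are
plain CSVs (indices, curves, fits, slope-index table) plus a JSON run
report with per-stage counts. A fixed config seed makes the run
byte-reproducible.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, morphometry
from .errors import ConfigurationError
from .fesolve import LoadCase, MaterialProps, compute_apparent_modulus
from .io_stack import ImageStack, apply_cylinder_mask, read_stack
from .model_build import BASE_UM, D_RANGE_UM, H_RANGE_UM, build_basic_model
from .phantoms import PhantomSpec, make_phantom

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "load_config"]

log = logging.getLogger("trabfe")

DEFAULT_METHOD_GRIDS = {
    "H": [72, 144, 216, 288],
    "FL": [72, 144, 216, 288],
    "FS": [72, 144, 216, 288],
    "FT": [72, 144, 216, 288],
}


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "trabfe_out"
    stack_path: str | None = None
    mask_diameter_mm: float | None = None
    phantoms: list[PhantomSpec] = field(default_factory=list)
    methods: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_METHOD_GRIDS.items()})
    material: MaterialProps = field(default_factory=MaterialProps)
    load: LoadCase = field(default_factory=LoadCase)
    solver: str = "auto"
    tol: float = 1e-8
    enforce_range: bool = True
    compute_indices: bool = True
    log_level: str = "INFO"


def load_config(path) -> PipelineConfig:
    """Parse a YAML pipeline config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw or {})


def config_from_dict(raw: dict) -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.seed = int(raw.get("seed", 0))
    cfg.output_dir = raw.get("output_dir", cfg.output_dir)
    cfg.stack_path = raw.get("stack")
    cfg.mask_diameter_mm = raw.get("mask_diameter_mm")
    for i, ph in enumerate(raw.get("phantoms", [])):
        ph = dict(ph)
        kind = ph.pop("kind")
        shape = tuple(ph.pop("shape", (64, 64, 120)))
        spec = PhantomSpec(
            kind=kind, shape=shape,
            pixel_size=float(ph.pop("pixel_size", 36.0)),
            slice_increment=float(ph.pop("slice_increment", 36.0)),
            target_bvtv=float(ph.pop("target_bvtv", 0.22)),
            correlation_length=float(ph.pop("correlation_length", 80.0)),
            axial_elongation=float(ph.pop("axial_elongation", 3.0)),
            seed=int(ph.pop("seed", (cfg.seed * 1009 + i) % (2**31))),
            params=ph,
        )
        cfg.phantoms.append(spec)
    if "methods" in raw:
        cfg.methods = {m: [float(d) for d in ds] for m, ds in raw["methods"].items()}
    matd = raw.get("material", {})
    cfg.material = MaterialProps(float(matd.get("e_tissue_gpa", 10.0)),
                                 float(matd.get("nu", 0.3)))
    cfg.load = LoadCase(float(raw.get("load", {}).get("strain", 0.008)))
    sv = raw.get("solver", {})
    cfg.solver = sv.get("name", "auto")
    cfg.tol = float(sv.get("tol", 1e-8))
    cfg.enforce_range = bool(raw.get("enforce_range", True))
    cfg.compute_indices = bool(raw.get("compute_indices", True))
    cfg.log_level = raw.get("log_level", "INFO")
    return cfg


def validate_config(cfg: PipelineConfig) -> list[str]:
    """List of issues; empty iff run_pipeline's preconditions hold."""
    issues = []
    if cfg.stack_path is None and not cfg.phantoms:
        issues.append("input: neither a stack path nor phantoms given")
    if cfg.stack_path is not None and not Path(cfg.stack_path).exists():
        issues.append(f"stack: path {cfg.stack_path!r} does not exist")
    known = {"solid_block", "prism_column", "plate_lattice", "rod_lattice", "grf"}
    for i, ph in enumerate(cfg.phantoms):
        if ph.kind not in known:
            issues.append(f"phantoms[{i}].kind: unknown kind {ph.kind!r}")
    for method, ds in cfg.methods.items():
        if method not in {"H", "FL", "FS", "FT"}:
            issues.append(f"methods: unknown method {method!r}")
            continue
        step = 2 * BASE_UM if method == "FT" else BASE_UM
        lo, hi = H_RANGE_UM if method == "H" else D_RANGE_UM
        for d in ds:
            if abs(d / step - round(d / step)) > 1e-9:
                issues.append(
                    f"methods.{method}: d={d} µm is not a multiple of the "
                    f"method step {step:.0f} µm")
            elif cfg.enforce_range and not lo <= d <= hi:
                issues.append(
                    f"methods.{method}: d={d} µm outside range [{lo:.0f}, {hi:.0f}] µm")
    if not 0 < cfg.load.strain < 0.05:
        issues.append("load.strain outside (0, 0.05)")
    if cfg.solver not in {"auto", "direct", "iterative"}:
        issues.append(f"solver.name: unknown solver {cfg.solver!r}")
    return issues


def _samples(cfg: PipelineConfig):
    if cfg.stack_path is not None:
        stack = read_stack(cfg.stack_path)
        if cfg.mask_diameter_mm is not None:
            stack = apply_cylinder_mask(stack, cfg.mask_diameter_mm)
        yield Path(cfg.stack_path).stem, stack
    for i, spec in enumerate(cfg.phantoms):
        yield f"{spec.kind}_{i:02d}", make_phantom(spec)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages for every sample; write CSVs and a run report.

    Returns the report dict (also written as ``report.json``). Deterministic
    for a fixed config: the per-phantom seeds derive from the config seed.
    """
    issues = validate_config(cfg)
    if issues:
        raise ConfigurationError("invalid config: " + "; ".join(issues))
    logging.basicConfig(level=cfg.log_level)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    idx_rows, curve_frames, fit_rows = [], [], []
    report = {"seed": cfg.seed, "samples": []}
    for sample_id, stack in _samples(cfg):
        log.info("sample %s: %d slices of %s", sample_id, stack.n_slices,
                 stack.shape[1:])
        basic = build_basic_model(stack)
        entry = {
            "sample_id": sample_id,
            "slices": stack.n_slices,
            "bone_voxels_basic": basic.bone_voxel_count(),
        }
        if cfg.compute_indices:
            ind = morphometry.compute_indices(basic)
            idx_rows.append({"sample_id": sample_id, "method": "basic",
                             "voxel_length_um": basic.dz, **vars(ind)})
        basic_e = compute_apparent_modulus(basic, cfg.material, cfg.load,
                                           solver=cfg.solver, tol=cfg.tol)
        entry["basic_e_app_gpa"] = basic_e
        for method, ds in sorted(cfg.methods.items()):
            curve = analysis.relative_modulus_curve(
                stack, method, ds, sample_id=sample_id, mat=cfg.material,
                load=cfg.load, solver=cfg.solver, tol=cfg.tol,
                basic_modulus=basic_e, enforce_range=cfg.enforce_range)
            curve_frames.append(curve.as_frame())
            for form, fit in (("linear", analysis.linear_fit(curve.d_um,
                                                             curve.relative_e)),
                              ("log", analysis.log_fit(curve.d_um,
                                                       curve.relative_e))):
                fit_rows.append({"sample_id": sample_id, "method": method,
                                 "form": form, "a": fit.slope, "b": fit.intercept,
                                 "r2": fit.r2, "n": fit.n_points})
        report["samples"].append(entry)

    curves = pd.concat(curve_frames, ignore_index=True)
    fits = pd.DataFrame(fit_rows)
    fmt = "%.10g"
    curves.to_csv(outdir / "curves.csv", index=False, float_format=fmt)
    fits.to_csv(outdir / "fits.csv", index=False, float_format=fmt)
    if idx_rows:
        pd.DataFrame(idx_rows).to_csv(outdir / "indices.csv", index=False,
                                      float_format=fmt)

    if cfg.compute_indices and len(report["samples"]) >= 3:
        logfits = fits[fits["form"] == "log"][["sample_id", "method", "a"]]
        ind_df = pd.DataFrame(idx_rows)[["sample_id", *analysis.INDEX_COLUMNS]]
        table = analysis.slope_index_table(logfits.merge(ind_df, on="sample_id"))
        table.to_csv(outdir / "table2.csv", index=False, float_format=fmt)
        report["table2_rows"] = len(table)

    report["n_curve_points"] = int(len(curves))
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
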