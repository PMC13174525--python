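"""End-to-end pipeline orchestration from a single config document.

The config is one YAML (or JSON) document with exactly one input source
(image files or a phantom block), per-stage parameter blocks, and a
single top-level seed feeding every source of randomness.  Validation
rejects unknown keys and reports every violation at once; every
defaulted parameter appears in the config echo written next to the
outputs, so a run is reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .drymass import DryMassParams, analyze_fragments, fragment_table, ri_probability_density
from .errors import ValidationError
from .extraction import (
    ExtractionParams,
    binarize_foreground,
    build_width_weighted_mask,
    enhance_section,
    trace_fibers,
)
from .kinetics import fit_saturating_kinetics, time_color_composite, trajectory
from .metrics import describe_fiber, descriptor_table, summarize_descriptors
from .phantom import (
    PhantomConfig,
    PolymerizationConfig,
    generate_phantom,
    generate_polymerization_series,
    phantom_preset,
)
from .tomo import extract_axial_section, read_series, read_tomogram, write_tomogram

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "section", "extract", "metrics", "mass", "density", "kinetics")

_KNOWN_TOP = {
    "input",
    "phantom",
    "polymerization",
    "section",
    "extraction",
    "dry_mass",
    "kinetics",
    "stages",
    "output_dir",
    "seed",
    "log_level",
}


@dataclass
class PipelineConfig:
    """Validated, fully defaulted pipeline configuration."""

    raw: dict
    stages: tuple[str, ...]
    output_dir: Path
    seed: int
    input_paths: Optional[dict]
    phantom: Optional[PhantomConfig]
    polymerization: Optional[PolymerizationConfig]
    section_rule: Any
    extraction: ExtractionParams
    dry_mass: DryMassParams
    thickness_mode: str
    guard_px: int
    fit_kinetics: bool
    log_level: str

    def echo(self) -> dict:
        out = {
            "version": __version__,
            "stages": list(self.stages),
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "section_rule": self.section_rule,
            "extraction": dataclasses.asdict(self.extraction),
            "dry_mass": dataclasses.asdict(self.dry_mass),
            "thickness_mode": self.thickness_mode,
            "guard_px": self.guard_px,
            "fit_kinetics": self.fit_kinetics,
            "log_level": self.log_level,
        }
        if self.input_paths is not None:
            out["input"] = self.input_paths
        if self.phantom is not None:
            out["phantom"] = dataclasses.asdict(self.phantom)
        if self.polymerization is not None:
            p = dataclasses.asdict(self.polymerization)
            out["polymerization"] = p
        return out


def _build(cls, block: dict, errors: list[str], label: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        errors.append(f"{label}: unknown keys {sorted(unknown)}")
    try:
        return cls(**{k: v for k, v in block.items() if k in known})
    except (ValidationError, TypeError, ValueError) as exc:
        errors.append(f"{label}: {exc}")
        return None


def validate_config(raw: dict) -> PipelineConfig:
    """Validate and default a raw config document.

    Raises :class:`ValidationError` listing *every* violation.
    """
    if not isinstance(raw, dict):
        raise ValidationError("config must be a mapping")
    errors: list[str] = []
    unknown = set(raw) - _KNOWN_TOP
    if unknown:
        errors.append(f"unknown top-level keys {sorted(unknown)}")

    has_input = "input" in raw and raw["input"]
    has_phantom = "phantom" in raw and raw["phantom"] is not None
    if has_input and has_phantom:
        errors.append("config must name exactly one input source, not both 'input' and 'phantom'")
    if not has_input and not has_phantom:
        errors.append("config must name an input source: 'input' (files) or 'phantom'")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed must be an integer, got {seed!r}")
        seed = 0

    input_paths = None
    if has_input:
        blk = raw["input"]
        if not isinstance(blk, dict) or not ({"tomogram", "series"} & set(blk)):
            errors.append("input block needs 'tomogram: <path>' or 'series: [<paths>]'")
        else:
            paths = [blk.get("tomogram")] if "tomogram" in blk else list(blk.get("series", []))
            for p in paths:
                if p and not Path(p).exists():
                    errors.append(f"input path does not exist: {p}")
            input_paths = blk

    phantom_cfg = None
    if has_phantom:
        blk = dict(raw["phantom"])
        preset = blk.pop("preset", None)
        if preset is not None:
            conc = blk.pop("concentration_mg_ml", 0.8)
            try:
                phantom_cfg = phantom_preset(preset, conc, seed=seed, **blk)
            except (ValidationError, TypeError) as exc:
                errors.append(f"phantom: {exc}")
        else:
            blk.setdefault("seed", seed)
            phantom_cfg = _build(PhantomConfig, blk, errors, "phantom")

    poly_cfg = None
    if raw.get("polymerization") is not None:
        if phantom_cfg is None:
            errors.append("polymerization requires a phantom input")
        else:
            blk = dict(raw["polymerization"])
            blk.setdefault("base", phantom_cfg)
            blk.setdefault("seed", seed)
            if isinstance(blk.get("time_points_min"), list):
                blk["time_points_min"] = tuple(blk["time_points_min"])
            poly_cfg = _build(PolymerizationConfig, blk, errors, "polymerization")

    section_rule = raw.get("section", {}).get("rule", "max_contrast") if isinstance(
        raw.get("section", {}), dict
    ) else raw.get("section")
    if not (section_rule == "max_contrast" or isinstance(section_rule, int)):
        errors.append(f"section rule must be 'max_contrast' or an integer z, got {section_rule!r}")

    extraction = _build(ExtractionParams, raw.get("extraction", {}) or {}, errors, "extraction")

    dm_blk = dict(raw.get("dry_mass", {}) or {})
    thickness_mode = dm_blk.pop("thickness_mode", "voxel")
    guard_px = dm_blk.pop("guard_px", 2)
    if thickness_mode not in ("voxel", "cylinder"):
        errors.append(f"dry_mass.thickness_mode must be 'voxel' or 'cylinder', got {thickness_mode!r}")
    if not isinstance(guard_px, int) or guard_px < 0:
        errors.append(f"dry_mass.guard_px must be a non-negative integer, got {guard_px!r}")
        guard_px = 2
    dry_mass = _build(DryMassParams, dm_blk, errors, "dry_mass")

    kin_blk = raw.get("kinetics", {}) or {}
    fit_kinetics = bool(kin_blk.get("fit", True)) if isinstance(kin_blk, dict) else True

    stages = tuple(raw.get("stages", ALL_STAGES))
    bad = [s for s in stages if s not in ALL_STAGES]
    if bad:
        errors.append(f"unknown stages {bad}; valid: {list(ALL_STAGES)}")
    if "kinetics" in stages and poly_cfg is None and not (
        input_paths and "series" in (input_paths or {})
    ):
        errors.append("kinetics stage needs a time-lapse input (series or polymerization block)")

    if errors:
        raise ValidationError("invalid config:\n  - " + "\n  - ".join(errors))

    return PipelineConfig(
        raw=raw,
        stages=stages,
        output_dir=Path(raw.get("output_dir", "rifiber_out")),
        seed=seed,
        input_paths=input_paths,
        phantom=phantom_cfg,
        polymerization=poly_cfg,
        section_rule=section_rule,
        extraction=extraction,
        dry_mass=dry_mass,
        thickness_mode=thickness_mode,
        guard_px=guard_px,
        fit_kinetics=fit_kinetics,
        log_level=str(raw.get("log_level", "INFO")),
    )


def load_config(path) -> PipelineConfig:
    return validate_config(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Per-stage manifest of one pipeline run."""

    manifest: dict[str, list[str]] = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)
    version: str = ""
    timings_s: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    failed_stage: Optional[str] = None
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.failed_stage is None

    def to_json(self) -> str:
        return json.dumps(
            {
                "manifest": self.manifest,
                "config_echo": self.config_echo,
                "version": self.version,
                "timings_s": self.timings_s,
                "warnings": self.warnings,
                "failed_stage": self.failed_stage,
                "error": self.error,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in order, writing artifacts and a manifest.

    Identical config and seed give identical numeric outputs.  A stage
    failure marks the report failed and skips dependent stages.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_echo=config.echo(), version=__version__)
    state: dict[str, Any] = {}

    def emit(stage: str, *paths: Path) -> None:
        report.manifest.setdefault(stage, []).extend(str(p) for p in paths)

    stage_fns = {
        "simulate": _stage_simulate,
        "section": _stage_section,
        "extract": _stage_extract,
        "metrics": _stage_metrics,
        "mass": _stage_mass,
        "density": _stage_density,
        "kinetics": _stage_kinetics,
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                stage_fns[stage](config, state, out, emit)
            report.warnings.extend(f"{stage}: {w.message}" for w in caught)
        except Exception as exc:  # noqa: BLE001 - report and stop downstream stages
            logger.error("stage %s failed: %s", stage, exc)
            report.failed_stage = stage
            report.error = str(exc)
            break
        finally:
            report.timings_s[stage] = time.perf_counter() - t0

    manifest_path = out / "run_report.json"
    manifest_path.write_text(report.to_json())
    return report


def _stage_simulate(config: PipelineConfig, state: dict, out: Path, emit) -> None:
    if config.phantom is not None:
        if config.polymerization is not None:
            series, targets = generate_polymerization_series(config.polymerization)
            state["series"] = series
            state["tomo"] = series.frames[-1]
            state["poly_targets"] = targets
        else:
            tomo, truth = generate_phantom(config.phantom)
            state["tomo"] = tomo
            state["truth"] = truth
            gt_path = out / "ground_truth.csv"
            truth.table().to_csv(gt_path, index=False)
            emit("simulate", gt_path)
        tomo_path = out / "tomogram.tiff"
        write_tomogram(state["tomo"], tomo_path)
        emit("simulate", tomo_path, out / "tomogram.tiff.json")
    else:
        blk = config.input_paths or {}
        if "series" in blk:
            state["series"] = read_series(blk["series"])
            state["tomo"] = state["series"].frames[-1]
        else:
            state["tomo"] = read_tomogram(blk["tomogram"])


def _stage_section(config: PipelineConfig, state: dict, out: Path, emit) -> None:
    section = extract_axial_section(state["tomo"], config.section_rule)
    state["section"] = section
    meta_path = out / "section.json"
    meta_path.write_text(
        json.dumps(
            {
                "z_index": section.z_index,
                "rule": config.section_rule,
                "pixel_size_um": list(section.pixel_size),
                "slice_thickness_um": section.slice_thickness,
            },
            indent=2,
        )
    )
    emit("section", meta_path)


def _stage_extract(config: PipelineConfig, state: dict, out: Path, emit) -> None:
    import tifffile

    section = state["section"]
    enhanced = enhance_section(section, config.extraction)
    mask_bin = binarize_foreground(enhanced, config.extraction)
    traces = trace_fibers(section, mask_bin, config.extraction)
    fmask = build_width_weighted_mask(traces, section.shape)
    state.update(traces=traces, fmask=fmask)

    rows = [
        {"fiber_id": t.fiber_id, "point_index": i, "y": p[0], "x": p[1], "width_px": w}
        for t in traces
        for i, (p, w) in enumerate(zip(t.centerline, t.widths_px))
    ]
    traces_path = out / "traces.csv"
    pd.DataFrame(rows, columns=["fiber_id", "point_index", "y", "x", "width_px"]).to_csv(
        traces_path, index=False
    )
    label_path = out / "fiber_labels.tiff"
    tifffile.imwrite(label_path, fmask.label_image.astype(np.uint16))
    emit("extract", traces_path, label_path)


def _stage_metrics(config: PipelineConfig, state: dict, out: Path, emit) -> None:
    section = state["section"]
    descriptors = [describe_fiber(t, section.pixel_size) for t in state["traces"]]
    state["descriptors"] = descriptors
    desc_path = out / "descriptors.csv"
    descriptor_table(descriptors).to_csv(desc_path, index=False)
    emit("metrics", desc_path)
    if descriptors:
        summary, _ = summarize_descriptors(descriptors)
        sum_path = out / "descriptor_summary.csv"
        summary.to_csv(sum_path, index=False)
        emit("metrics", sum_path)


def _stage_mass(config: PipelineConfig, state: dict, out: Path, emit) -> None:
    fragments = analyze_fragments(
        state["section"],
        state["fmask"],
        config.dry_mass,
        traces=state["traces"],
        thickness_mode=config.thickness_mode,
    )
    state["fragments"] = fragments
    path = out / "fragment_mass.csv"
    fragment_table(fragments).to_csv(path, index=False)
    emit("mass", path)


def _stage_density(config: PipelineConfig, state: dict, out: Path, emit) -> None:
    density = ri_probability_density(state["section"], state["fmask"], guard_px=config.guard_px)
    centers = 0.5 * (density.bin_edges[:-1] + density.bin_edges[1:])
    path = out / "ri_density.csv"
    pd.DataFrame(
        {
            "bin_center_ri": centers,
            "fiber_density": density.fiber_density,
            "background_density": density.background_density,
        }
    ).to_csv(path, index=False)
    emit("density", path)


def _stage_kinetics(config: PipelineConfig, state: dict, out: Path, emit) -> None:
    series = state["series"]
    traj = trajectory(series)
    path = out / "trajectory.csv"
    pd.DataFrame({"time_min": traj.times_min, "mean_delta_n": traj.mean_delta_n}).to_csv(
        path, index=False
    )
    emit("kinetics", path)
    if config.fit_kinetics and len(traj.times_min) >= 4:
        fit = fit_saturating_kinetics(traj)
        fit_path = out / "kinetics_fit.json"
        fit_path.write_text(
            json.dumps(
                {
                    "dn_max_hat": fit.dn_max_hat,
                    "tau_hat_min": fit.tau_hat_min,
                    "residual_rms": fit.residual_rms,
                    "tau_identifiable": fit.tau_identifiable,
                    "monotonicity_score": traj.monotonicity_score(),
                },
                indent=2,
            )
        )
        emit("kinetics", fit_path)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        rgb = time_color_composite(series)
        comp_path = out / "time_color_composite.png"
        plt.imsave(comp_path, rgb)
        emit("kinetics", comp_path)
    except Exception as exc:  # noqa: BLE001 - composite is a convenience artifact
        logger.warning("composite rendering skipped: %s", exc)
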