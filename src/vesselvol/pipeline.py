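"""End-to-end pipeline: config, staged execution, run manifests.

A :class:`RunConfig` is a single YAML/JSON-serializable document (unknown
keys rejected) describing one run: input volume or phantom preset,
threshold choice, cleanup, skeletonization parameters, landmarks, segment
arms. :func:`run_pipeline` executes segment -> skeletonize -> radii ->
measure and emits a JSON report plus a manifest (config hash, package
versions, seed) sufficient to reproduce the run byte-for-byte where
deterministic; the only stochastic step is phantom noise, governed by the
single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .errors import ConfigError, DataError, VesselVolError
from .graph import build_graph, estimate_radii, prune_spurs, skeletonize
from .io import read_volume
from .morphometry import (
    Landmark,
    extract_segment,
    measure_diameter_at,
    segment_volume,
    volume_per_length,
)
from .segmentation import clean_mask, suggest_threshold, threshold_segment

logger = logging.getLogger(__name__)


class LandmarkConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    position: tuple[float, float, float]
    snap_radius: float = Field(default=float("inf"), gt=0)


class ArmConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    direction: str  # landmark name
    length: float = Field(ge=0)


class ThresholdConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    value: Optional[float] = None
    auto: Optional[Literal["otsu", "percentile"]] = None
    percentile: float = 99.0


class PhantomConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    preset: Literal["tube", "stenosis", "bifurcation", "ring"]
    params: dict = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Complete description of one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    input: Optional[str] = None
    input_spacing: Optional[tuple[float, float, float]] = None
    input_unit: Optional[Literal["um", "mm"]] = None
    phantom: Optional[PhantomConfig] = None

    threshold: ThresholdConfig = Field(default_factory=ThresholdConfig)
    bone_threshold: Optional[float] = None
    min_component: int = Field(default=0, ge=0)
    keep_largest: bool = True

    prune_length: float = Field(default=0.0, ge=0)
    smooth_window: int = 5
    step: Optional[float] = Field(default=None, gt=0)

    landmarks: list[LandmarkConfig] = Field(default_factory=list)
    anchor: Optional[str] = None
    arms: list[ArmConfig] = Field(default_factory=list)

    seed: int = 0
    output_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                doc = yaml.safe_load(fh)
            return cls.model_validate(doc or {})
        except (yaml.YAMLError, ValidationError) as exc:
            raise ConfigError(f"invalid run config {path}: {exc}") from exc

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)


_PRESETS = {}


def _presets():
    if not _PRESETS:
        from . import phantom as ph

        _PRESETS.update(
            tube=ph.preset_tube,
            stenosis=ph.preset_stenosis,
            bifurcation=ph.preset_bifurcation,
            ring=ph.preset_ring,
        )
    return _PRESETS


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline; returns (and optionally writes) the
    report. Any stage failure aborts with the stage name and a hint."""
    if (config.input is None) == (config.phantom is None):
        raise ConfigError("specify exactly one of 'input' or 'phantom'")
    known = {lm.name for lm in config.landmarks}
    if config.anchor is not None and config.anchor not in known:
        raise ConfigError(f"[landmarks] anchor {config.anchor!r} is not a defined landmark")
    for arm in config.arms:
        if arm.direction not in known:
            raise ConfigError(
                f"[landmarks] arm direction {arm.direction!r} is not a defined landmark; "
                "add it to the landmarks list"
            )
    if config.arms and config.anchor is None:
        raise ConfigError("[landmarks] arms require an anchor landmark")

    report: dict = {"config_hash": _sha256(config.canonical_json()), "seed": config.seed}

    # -- load ---------------------------------------------------------------
    with _stage("load", "check the input path / phantom parameters"):
        if config.input is not None:
            grid = read_volume(
                config.input, spacing=config.input_spacing, unit=config.input_unit
            )
        else:
            params = dict(config.phantom.params)
            params.setdefault("seed", config.seed)
            grid, _truth = _presets()[config.phantom.preset](**params)
    report["input"] = {
        "shape": list(grid.shape),
        "spacing": list(grid.spacing),
        "unit": grid.unit,
    }

    # -- segmentation -------------------------------------------------------
    with _stage("segmentation", "check threshold settings"):
        if config.bone_threshold is not None:
            from .segmentation import subtract_bone

            grid = subtract_bone(grid, bone_threshold=config.bone_threshold)
        if config.threshold.value is not None:
            thr = float(config.threshold.value)
        elif config.threshold.auto is not None:
            thr = suggest_threshold(
                grid, strategy=config.threshold.auto, percentile=config.threshold.percentile
            )
        else:
            raise ConfigError("threshold requires either 'value' or 'auto'")
        mask = threshold_segment(grid, thr)
        logger.info("threshold %g -> %d foreground voxels", thr, mask.foreground_count)
        if config.min_component or config.keep_largest:
            mask = clean_mask(mask, config.min_component, config.keep_largest)
    report["segmentation"] = {"threshold": thr, "foreground_voxels": mask.foreground_count}

    # -- centerline ---------------------------------------------------------
    with _stage("centerline", "the mask may be empty; lower the threshold"):
        graph = build_graph(skeletonize(mask), smooth_window=config.smooth_window)
        graph = estimate_radii(graph, mask)
        if config.prune_length > 0:
            graph = prune_spurs(graph, config.prune_length)
    report["graph"] = {
        "n_nodes": len(graph.nodes),
        "n_edges": len(graph.edges),
        "n_endpoints": len(graph.endpoints()),
        "n_branch_nodes": len(graph.branch_nodes()),
        "n_cycles": graph.cycle_count(),
        "total_length": graph.total_length,
        "unit": graph.unit,
    }

    # -- measurements -------------------------------------------------------
    landmarks = {
        lm.name: Landmark(lm.name, lm.position, lm.snap_radius) for lm in config.landmarks
    }
    diameters = {}
    for name, lm in landmarks.items():
        with _stage(f"landmark:{name}", "move the landmark or enlarge its snap radius"):
            diameters[name] = measure_diameter_at(graph, lm)
    report["diameters"] = diameters

    if config.anchor is not None and config.arms:
        with _stage("segment", "check anchor/arm landmarks"):
            seg = extract_segment(
                graph,
                landmarks[config.anchor],
                [(landmarks[a.direction], a.length) for a in config.arms],
                step=config.step,
            )
            report["segment"] = {
                "anchor": config.anchor,
                "total_length": seg.total_length,
                "truncated": seg.truncated,
                "arm_lengths": {a.direction: a.achieved_length for a in seg.arms},
                "volume_ul": segment_volume(seg),
                "arm_volumes_ul": seg.arm_volumes,
                "volume_per_length_ul_per_mm": volume_per_length(seg),
            }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        (out / "manifest.json").write_text(json.dumps(_manifest(config), indent=2))
    return report


def _manifest(config: RunConfig) -> dict:
    import scipy
    import skimage

    return {
        "config": config.model_dump(mode="json"),
        "config_hash": _sha256(config.canonical_json()),
        "seed": config.seed,
        "versions": {
            "vesselvol": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
        },
    }


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


class _stage:
    def __init__(self, name: str, hint: str):
        self.name, self.hint = name, hint

    def __enter__(self):
        logger.info("stage %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, VesselVolError):
            raise type(exc)(f"[{self.name}] {exc} (hint: {self.hint})") from exc
        return False


# -- phantom vasospasm analysis --------------------------------------------


def analyze_vasospasm_pair(
    severity: float = 0.2,
    seed: int = 0,
    threshold: float = 127.5,
    prune_length_voxels: float = 4.0,
    step: float | None = None,
) -> dict:
    """Run the full imaging pipeline on a matched sham/spastic phantom pair
    and recover the spasm severity from the images alone.

    Returns the diameters at the stenosis center, the cylindrical volumes
    of the fully-stenosed interval, and their sham-normalized ratios, next
    to the analytic expectations (1 - f) and (1 - f)^2.
    """
    from .phantom import preset_vasospasm_pair

    pair = preset_vasospasm_pair(severity=severity, seed=seed)
    plateau = pair.stenosis_plateau
    s_mid = 0.5 * (plateau[0] + plateau[1])
    axis = pair.sah_truth.tubes[0].curve
    lm_mid = Landmark("stenosis_center", axis.point(s_mid)[0], snap_radius=10 * 15.0)
    lm_start = Landmark("interval_start", axis.point(plateau[0])[0], snap_radius=10 * 15.0)
    lm_end = Landmark("interval_end", axis.point(plateau[1])[0], snap_radius=10 * 15.0)
    interval_len = plateau[1] - plateau[0]

    results = {}
    for label, grid in (("sham", pair.sham_grid), ("sah", pair.sah_grid)):
        mask = clean_mask(threshold_segment(grid, threshold), keep_largest=True)
        graph = estimate_radii(build_graph(skeletonize(mask)), mask)
        graph = prune_spurs(graph, prune_length_voxels * min(grid.spacing))
        seg = extract_segment(graph, lm_start, [(lm_end, interval_len)], step=step)
        results[label] = {
            "diameter_um": measure_diameter_at(graph, lm_mid),
            "interval_volume_ul": segment_volume(seg),
            "graph": graph,
        }

    d_ratio = results["sah"]["diameter_um"] / results["sham"]["diameter_um"]
    v_ratio = results["sah"]["interval_volume_ul"] / results["sham"]["interval_volume_ul"]
    return {
        "severity": severity,
        "sham_diameter_um": results["sham"]["diameter_um"],
        "sah_diameter_um": results["sah"]["diameter_um"],
        "diameter_ratio": d_ratio,
        "expected_diameter_ratio": pair.expected_diameter_ratio,
        "sham_interval_volume_ul": results["sham"]["interval_volume_ul"],
        "sah_interval_volume_ul": results["sah"]["interval_volume_ul"],
        "interval_volume_ratio": v_ratio,
        "expected_volume_ratio": pair.expected_volume_ratio,
    }
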