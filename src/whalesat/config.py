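"""Run configuration, validation and the end-to-end pipeline.

``run_pipeline`` ties simulate -> detect -> evaluate -> report together
and writes every artifact (scene GeoTIFFs, truth/detection GeoJSON,
metrics CSV/JSON, the comparison table and a manifest) into one output
directory, reproducible from the manifest's seed and parameters alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .detect import (
    DETECTION_METHODS,
    DetectionConfig,
    detect_whales,
    write_detections,
)
from .evaluate import (
    confusion_counts,
    compute_metrics,
    format_report,
    match_detections,
    table1_report,
)
from .scene import read_annotations, read_scene, write_annotations, write_scene
from .simulate import SimulationConfig, simulate_scene

__all__ = ["RunConfig", "ConfigError", "PipelineError", "validate_config", "run_pipeline"]

log = logging.getLogger("whalesat")


class ConfigError(ValueError):
    """Aggregated, human-readable configuration errors."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    scene_path: str | None = None       # use an existing scene instead of simulating
    reference_path: str | None = None   # reference annotations for evaluation
    methods: list[str] = field(
        default_factory=lambda: ["threshold_band5", "threshold_pan", "kmeans", "isodata"]
    )
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    match_radius_m: float = 10.0
    outdir: str = "runs/demo"
    seed: int = 0
    verbosity: str = "info"


def _coerce_dataclass(cls, doc: dict, prefix: str, errors: list[str]):
    kwargs: dict[str, Any] = {}
    names = {f.name for f in fields(cls)}
    for key, val in doc.items():
        if key not in names:
            errors.append(f"{prefix}{key}: unknown key")
            continue
        kwargs[key] = val
    try:
        obj = cls(**{
            k: (tuple(v) if isinstance(v, list) and k.endswith(("_shape", "_range_m", "_range", "_xy_m")) else v)
            for k, v in kwargs.items()
        })
    except (TypeError, ValueError) as exc:
        errors.append(f"{prefix}{exc}")
        return None
    return obj


def validate_config(document: dict | None) -> RunConfig:
    """Typed RunConfig from a parsed JSON/YAML mapping.

    Defaults fill every omitted key; unknown keys and invalid values are
    rejected with one aggregated error listing each offending key.
    """
    doc = dict(document or {})
    errors: list[str] = []
    sim_doc = doc.pop("simulation", {})
    det_doc = doc.pop("detection", {})
    if not isinstance(sim_doc, dict):
        errors.append("simulation: expected a mapping")
        sim_doc = {}
    if not isinstance(det_doc, dict):
        errors.append("detection: expected a mapping")
        det_doc = {}
    if "n_whales" in sim_doc and isinstance(sim_doc["n_whales"], int) and sim_doc["n_whales"] < 0:
        errors.append("simulation.n_whales: must be >= 0")
    for key in ("n_seabird_clusters", "n_bubble_slicks", "n_boats", "n_rocks"):
        if isinstance(sim_doc.get(key), int) and sim_doc[key] < 0:
            errors.append(f"simulation.{key}: must be >= 0")
    sim = _coerce_dataclass(SimulationConfig, sim_doc, "simulation.", errors)
    det = _coerce_dataclass(DetectionConfig, det_doc, "detection.", errors)
    run = _coerce_dataclass(RunConfig, doc, "", errors)
    if run is not None:
        for m in run.methods:
            if m not in DETECTION_METHODS:
                errors.append(f"methods: unknown method {m!r}")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(sorted(errors)))
    assert run is not None and sim is not None and det is not None
    run.simulation = sim
    run.detection = det
    return run


def config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["detection"]["signatures"] = None  # not serialized
    return d


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage tagging contract
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the full pipeline; returns a name -> path map of artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    @_stage("scene")
    def load_scene():
        if config.scene_path is not None:
            p = Path(config.scene_path)
            if not p.exists():
                raise FileNotFoundError(f"missing scene path: {p}")
            return read_scene(p), None
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        scene, truth = simulate_scene(sim)
        sp = outdir / "scene.tif"
        write_scene(scene, sp)
        tp = outdir / "truth.geojson"
        write_annotations(truth.annotations, tp)
        artifacts["scene"] = str(sp)
        artifacts["truth"] = str(tp)
        return scene, truth

    scene, truth = load_scene()

    @_stage("reference")
    def load_reference():
        if config.reference_path is not None:
            p = Path(config.reference_path)
            if not p.exists():
                raise FileNotFoundError(f"missing reference path: {p}")
            return read_annotations(p)
        return truth.annotations if truth is not None else None

    reference = load_reference()

    counts_by_method = {}
    for method in config.methods:
        @_stage(f"detect:{method}")
        def run_method(method=method):
            dets = detect_whales(scene, method, config.detection)
            gpath = outdir / f"detections_{method}.geojson"
            write_detections(
                dets, gpath,
                gsd_by_grid={"ms": scene.ms_gsd_m, "pan": scene.pan_gsd_m},
                origin_xy_m=scene.origin_xy_m,
            )
            write_detections(dets, outdir / f"detections_{method}.csv")
            artifacts[f"detections_{method}"] = str(gpath)
            return dets

        dets = run_method()
        log.info("%s: %d detections", method, len(dets))
        if reference is not None:
            @_stage(f"evaluate:{method}")
            def run_eval(dets=dets):
                m = match_detections(dets, reference, config.match_radius_m)
                return confusion_counts(m, reference)

            counts_by_method[method] = run_eval()

    if counts_by_method:
        @_stage("report")
        def run_report():
            df = table1_report(counts_by_method)
            csv_path = outdir / "metrics_table.csv"
            df.to_csv(csv_path)
            (outdir / "metrics_table.txt").write_text(format_report(df) + "\n")
            metrics = {
                method: dataclasses.asdict(compute_metrics(c))
                for method, c in counts_by_method.items()
            }
            jpath = outdir / "metrics.json"
            jpath.write_text(json.dumps(metrics, indent=1))
            artifacts["metrics_table"] = str(csv_path)
            artifacts["metrics"] = str(jpath)

        run_report()

    @_stage("manifest")
    def write_manifest():
        import scipy
        import skimage

        manifest = {
            "whalesat": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "config": config_to_dict(config),
            "artifacts": artifacts,
        }
        mp = outdir / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=1, default=str))
        artifacts["manifest"] = str(mp)

    write_manifest()
    return artifacts
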