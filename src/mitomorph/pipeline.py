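"""End-to-end batch runs: synthesize or ingest → morphometrics → stats.

A single :class:`RunConfig` (usually loaded from YAML) drives every
stage.  Stages communicate only through their CSV/JSON outputs, every
output directory carries a manifest with the config hash and the seed,
and a rerun with the same config and seed is byte-identical.

Config schema (all blocks optional unless a stage needs them)::

    seed: 1
    output_dir: results
    pixels_per_micron: 23.4
    preprocess:
      rolling_ball_radius_px: 50
      median_radius_px: 1
      clahe_tile_px: 64
      clahe_clip: 0.01
    images:                # ingest mode: list of TIFF paths with metadata
      - {path: cell01.tif, cell_id: c01, line: Control, condition: normal}
    synth_cells:           # or synthesis mode
      - {line: Control, condition: normal, n_cells: 12, scene: {...SceneSpec}}
    traces_csv: traces.csv # long format: trace_id, probe, group, frame, time_s, intensity
    synth_traces:
      - {group: Control, probe: DCF, n_traces: 10, trace: {...TraceSpec}}
    kinetics:
      control_group: Control
      fccp_frame: null     # set for TMRM/FCCP traces
    stats:
      metrics: [footprint_um2, individual_to_network_ratio]
      design: one_way
      control_group: Control
      n_comparisons: null  # defaults to C(k,2)
    metadata_csv: meta.csv # line, condition, donor_age, donor_sex per cell line
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import metadata as importlib_metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .images import Micrograph, DEFAULT_PIXELS_PER_MICRON
from .kinetics import (
    fit_rate,
    measure_potential,
    normalize_potentials,
    normalize_to_control,
    potential_results_frame,
    rate_results_frame,
    traces_from_frame,
)
from .morphology import MitoNetworkAnalyzer, objects_frame
from .preprocess import MicrographBinarizer
from .images import BinaryMask
from . import stats as mstats
from .synth import SceneSpec, TraceSpec, generate_scene, generate_trace, traces_to_frame

log = logging.getLogger("mitomorph")

MORPHOMETRIC_COLUMNS = [
    "footprint_um2",
    "median_network_branch_len_um",
    "individual_to_network_ratio",
    "median_individual_len_um",
    "mean_junctions_per_network",
    "median_individual_aspect_ratio",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated run configuration; see the module docstring for schema."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixels_per_micron <= 0:
            raise ValueError("pixels_per_micron must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def output_dir(self) -> Path:
        return Path(self.raw.get("output_dir", "results"))

    @property
    def pixels_per_micron(self) -> float:
        return float(self.raw.get("pixels_per_micron", DEFAULT_PIXELS_PER_MICRON))

    def section(self, name: str) -> dict:
        return dict(self.raw.get(name) or {})

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _derive_seed(base: int, i: int) -> int:
    return int((base * 100_003 + 7919 * i + 1) % (2**31))


def _write_manifest(config: RunConfig, out_dir: Path, stage: str,
                    outputs: dict[str, str]) -> None:
    try:
        version = importlib_metadata.version("mitomorph")
    except importlib_metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mitomorph_version": version,
        "outputs": outputs,
    }
    path = out_dir / f"manifest_{stage}.json"
    existing = {}
    if path.exists():
        existing = json.loads(path.read_text())
    existing.update(manifest)
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _iter_cells(config: RunConfig):
    """Yield (cell_id, line, condition, mask-producer) for every input cell."""
    binarizer_cfg = config.section("preprocess")
    binarizer = MicrographBinarizer(
        rolling_ball_radius_px=int(binarizer_cfg.get("rolling_ball_radius_px", 50)),
        median_radius_px=int(binarizer_cfg.get("median_radius_px", 1)),
        clahe_tile_px=int(binarizer_cfg.get("clahe_tile_px", 64)),
        clahe_clip=float(binarizer_cfg.get("clahe_clip", 0.01)),
    )

    images = config.raw.get("images")
    synth_cells = config.raw.get("synth_cells")
    if not images and not synth_cells:
        raise PipelineError("morphology stage: no 'images' or 'synth_cells' configured")

    if images:
        for rec in images:
            yield rec, binarizer, None
    else:
        i = 0
        for block in synth_cells:
            scene_overrides = dict(block.get("scene") or {})
            for j in range(int(block.get("n_cells", 1))):
                rec = {
                    "cell_id": f"{block.get('line', 'cell')}_{block.get('condition', 'normal')}_{j:03d}",
                    "line": block.get("line", "Control"),
                    "condition": block.get("condition", "normal"),
                }
                overrides = dict(scene_overrides)
                overrides.setdefault("pixels_per_micron", config.pixels_per_micron)
                if "image_size" in overrides:
                    overrides["image_size"] = tuple(overrides["image_size"])
                if "branch_length_range" in overrides:
                    overrides["branch_length_range"] = tuple(overrides["branch_length_range"])
                overrides["seed"] = _derive_seed(config.seed, i)
                yield rec, binarizer, SceneSpec(**overrides)
                i += 1


def run_morphology(config: RunConfig, out_dir: Path | None = None) -> dict[str, Path]:
    """Process every input image through the fixed protocol.

    Writes per-cell and per-object CSVs plus a manifest; unreadable
    images are skipped with a logged reason, and the stage fails only
    if no image could be processed.
    """
    out = Path(out_dir) if out_dir else config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    analyzer = MitoNetworkAnalyzer()
    cell_rows, object_frames = [], []
    n_skipped = 0
    for rec, binarizer, scene_spec in _iter_cells(config):
        cell_id = str(rec.get("cell_id", rec.get("path", "cell")))
        try:
            if scene_spec is None:
                img = Micrograph.from_tiff(rec["path"], config.pixels_per_micron)
                binarizer.intensity_max = float(img.intensity_max)
                mask = BinaryMask(
                    binarizer.transform(img.pixels), img.pixels_per_micron
                )
            else:
                img, _truth_mask, _truth = generate_scene(scene_spec)
                binarizer.intensity_max = float(img.intensity_max)
                mask = BinaryMask(
                    binarizer.transform(img.pixels), img.pixels_per_micron
                )
            result = analyzer.analyze(mask, cell_id=cell_id)
        except Exception as exc:  # noqa: BLE001 - skip-and-log contract
            log.warning("skipping cell %s: %s", cell_id, exc)
            n_skipped += 1
            continue
        row = result.morphometrics.as_dict()
        row["line"] = rec.get("line", "")
        row["condition"] = rec.get("condition", "normal")
        cell_rows.append(row)
        object_frames.append(objects_frame(result.objects, cell_id=cell_id))
    if not cell_rows:
        raise PipelineError(
            f"morphology stage: all {n_skipped} input image(s) failed"
        )
    cells = pd.DataFrame(cell_rows)
    front = ["cell_id", "line", "condition"]
    cells = cells[front + [c for c in cells.columns if c not in front]]
    objects = pd.concat(object_frames, ignore_index=True)
    paths = {
        "cells_csv": out / "cells.csv",
        "objects_csv": out / "objects.csv",
    }
    cells.to_csv(paths["cells_csv"], index=False)
    objects.to_csv(paths["objects_csv"], index=False)
    _write_manifest(config, out, "morphology", {k: str(v) for k, v in paths.items()})
    log.info("morphology: %d cells, %d skipped", len(cells), n_skipped)
    return paths


def run_traces(config: RunConfig, out_dir: Path | None = None) -> dict[str, Path]:
    """Fit rates (and ΔΨm proxies when configured) on all traces."""
    out = Path(out_dir) if out_dir else config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    kin = config.section("kinetics")

    if config.raw.get("traces_csv"):
        df = pd.read_csv(config.raw["traces_csv"])
        traces = traces_from_frame(df)
    elif config.raw.get("synth_traces"):
        traces = []
        i = 0
        for block in config.raw["synth_traces"]:
            spec_kw = dict(block.get("trace") or {})
            for j in range(int(block.get("n_traces", 1))):
                spec_kw["seed"] = _derive_seed(config.seed + 17, i)
                tr = generate_trace(
                    TraceSpec(**spec_kw),
                    trace_id=f"{block.get('group', 'g')}_{j:03d}",
                )
                tr.group = str(block.get("group", ""))
                tr.probe = str(block.get("probe", ""))
                traces.append(tr)
                i += 1
        traces_to_frame(traces).to_csv(out / "traces.csv", index=False)
    else:
        raise PipelineError("kinetics stage: no 'traces_csv' or 'synth_traces' configured")

    control = kin.get("control_group", "Control")
    paths: dict[str, Path] = {}
    fccp_frame = kin.get("fccp_frame")
    if fccp_frame is not None:
        results = [measure_potential(t, int(fccp_frame)) for t in traces]
        results = normalize_potentials(results, control)
        paths["potential_csv"] = out / "potential.csv"
        potential_results_frame(results).to_csv(paths["potential_csv"], index=False)
    else:
        window = kin.get("fit_window")
        results = [fit_rate(t, tuple(window) if window else None) for t in traces]
        results = normalize_to_control(results, control)
        paths["rates_csv"] = out / "rates.csv"
        rate_results_frame(results).to_csv(paths["rates_csv"], index=False)
    _write_manifest(config, out, "kinetics", {k: str(v) for k, v in paths.items()})
    return paths


def run_stats(
    config: RunConfig,
    cells_csv: str | Path | None = None,
    out_dir: Path | None = None,
) -> dict[str, Path]:
    """Statistics layer over the per-cell table from the morphology stage."""
    out = Path(out_dir) if out_dir else config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    scfg = config.section("stats")
    cells_path = Path(cells_csv or out / "cells.csv")
    if not cells_path.exists():
        raise PipelineError(f"stats stage: per-cell table {cells_path} not found")
    cells = pd.read_csv(cells_path)

    meta_path = config.raw.get("metadata_csv")
    if meta_path:
        meta = pd.read_csv(meta_path)
        join_cols = [c for c in ("line", "condition") if c in meta.columns]
        cells = cells.merge(meta, on=join_cols, how="left")

    control = scfg.get("control_group", "Control")
    if control not in set(cells.get("line", [])):
        raise PipelineError(
            f"stats stage: control group {control!r} absent from the per-cell table"
        )

    metrics = scfg.get("metrics") or [
        c for c in MORPHOMETRIC_COLUMNS if c in cells.columns
    ]
    design = scfg.get("design", "one_way")
    n_comparisons = scfg.get("n_comparisons")
    reports = []
    summary: dict[str, dict] = {}
    for metric in metrics:
        if cells[metric].dropna().empty:
            log.warning("stats: metric %s has no data, skipping", metric)
            continue
        per_metric: dict = {}
        try:
            gate = mstats.normality_gate(cells, metric, ["line"])
            reports.append(gate.assign(groups=gate["line"]))
            per_metric["all_normal"] = bool(gate["normal"].all())
        except ValueError as exc:
            log.warning("stats: normality gate for %s failed: %s", metric, exc)
        comp = mstats.compare_groups(
            cells, metric, design=design, n_comparisons=n_comparisons
        )
        reports.append(comp)
        means = comp.attrs.get("group_means", {})
        if control in means and means[control] > 0:
            fc = mstats.fold_change(means, control)
            per_metric["fold_change_vs_control"] = dict(
                zip(fc["group"], fc["fold_change"])
            )
        per_metric["group_means"] = means
        summary[metric] = per_metric
    if not reports:
        raise PipelineError("stats stage: no metric produced a report")
    report = pd.concat(reports, ignore_index=True)
    paths = {
        "stats_csv": out / "stats.csv",
        "stats_json": out / "stats_summary.json",
    }
    report.to_csv(paths["stats_csv"], index=False)
    Path(paths["stats_json"]).write_text(json.dumps(summary, indent=1, sort_keys=True))
    _write_manifest(config, out, "stats", {k: str(v) for k, v in paths.items()})
    return paths


def run_full(config: RunConfig) -> dict[str, Path]:
    """Morphology → (optional kinetics) → stats, one manifest per stage."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    try:
        paths.update(run_morphology(config, out))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"morphology stage failed: {exc}") from exc
    if config.raw.get("traces_csv") or config.raw.get("synth_traces"):
        try:
            paths.update(run_traces(config, out))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"kinetics stage failed: {exc}") from exc
    try:
        paths.update(run_stats(config, paths["cells_csv"], out))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stats stage failed: {exc}") from exc
    return paths


def demo_config(output_dir: str | Path = "results", seed: int = 1) -> RunConfig:
    """A small self-contained synthetic run (two groups, 6 cells each)."""
    scene = {
        "image_size": [256, 256],
        "n_networks": 1,
        "n_individuals": 4,
        "branch_length_range": [0.8, 2.0],
    }
    scene_frag = dict(scene, n_individuals=7, n_networks=1)
    return RunConfig(
        {
            "seed": int(seed),
            "output_dir": str(output_dir),
            "synth_cells": [
                {"line": "Control", "condition": "normal", "n_cells": 6,
                 "scene": scene},
                {"line": "PinkParkin", "condition": "normal", "n_cells": 6,
                 "scene": scene_frag},
            ],
            "synth_traces": [
                {"group": "Control", "probe": "DCF", "n_traces": 6,
                 "trace": {"n_frames": 60, "slope": 2.0, "noise_sd": 4.0}},
                {"group": "PinkParkin", "probe": "DCF", "n_traces": 6,
                 "trace": {"n_frames": 60, "slope": 3.6, "noise_sd": 4.0}},
            ],
            "kinetics": {"control_group": "Control"},
            "stats": {
                "control_group": "Control",
                "metrics": ["footprint_um2", "individual_to_network_ratio"],
            },
        }
    )
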