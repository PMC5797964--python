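"""Batch orchestration: configuration, the full per-stack analysis chain,
scene simulation, and FRAP batch fitting.

``analyze_stack`` runs the complete chain on one multichannel z-stack —
oocyte mask, spindle segmentation, aMTOC detection, Feret poles, shape
metrics, per-aMTOC positions, per-oocyte summary — and writes the result
tables; ``analyze_batch`` drives it across files, recording per-file
failures in a manifest instead of aborting. Every output carries the hash
of the configuration actually used so mismatched re-analyses are
detectable. All operations are deterministic, so re-running a batch
produces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import morphometry, photometry, segment, synth
from .errors import ConfigurationError, OospindleError
from .volume import MicroscopyVolume, read_volume

logger = logging.getLogger("oospindle")

ROLES = ("bright_field", "microtubule", "mtoc")


@dataclass
class PipelineConfig:
    """Every knob of the analysis chain, with the package defaults.

    ``channels`` maps each role to the channel index of a multichannel TIFF
    (axis order (C, Z, Y, X)); per-channel scene files produced by
    :func:`simulate` are matched by role-suffixed filename instead.
    """

    channels: dict = field(
        default_factory=lambda: {"bright_field": 0, "microtubule": 1, "mtoc": 2}
    )
    voxel_size_um: tuple[float, float, float] = (1.0, 0.25, 0.25)
    variance_radius_vox: int = 3
    gaussian_radius_vox: float = 2.0
    dog_sigma_small_vox: float = 1.5
    dog_sigma_large_vox: float = 3.0
    min_mtoc_volume_um3: float = 0.1
    pole_slab_fraction: float = 0.1
    central_slab_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.channels]
        if missing:
            raise ConfigurationError(f"channel role map missing roles: {missing}")
        unknown = [r for r in self.channels if r not in ROLES]
        if unknown:
            raise ConfigurationError(f"unknown channel roles: {unknown}")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ConfigurationError("voxel_size_um components must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["voxel_size_um"] = list(self.voxel_size_um)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        if "voxel_size_um" in raw:
            raw["voxel_size_um"] = tuple(raw["voxel_size_um"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------

def load_channels(stack_path, config: PipelineConfig) -> dict[str, MicroscopyVolume]:
    """Load the three role channels for one stack.

    ``stack_path`` is either a multichannel TIFF (axes (C, Z, Y, X), roles
    via ``config.channels``) or a scene stem/path written by
    :func:`simulate` with per-role files ``<stem>.<role>.tif``.
    """
    path = Path(stack_path)
    stem = str(path)
    for suffix in (".truth.json", ".bright_field.tif", ".microtubule.tif", ".mtoc.tif"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    per_channel = {role: Path(f"{stem}.{role}.tif") for role in ROLES}
    if all(p.exists() for p in per_channel.values()):
        return {
            role: read_volume(p, config.voxel_size_um, role)
            for role, p in per_channel.items()
        }
    if not path.exists():
        raise ConfigurationError(f"stack not found: {path}")
    data = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    if data.ndim != 4:
        raise ConfigurationError(
            f"expected a (C, Z, Y, X) multichannel stack, got shape {data.shape}"
        )
    out = {}
    for role, idx in config.channels.items():
        if not (0 <= idx < data.shape[0]):
            raise ConfigurationError(f"channel index {idx} for {role} out of range")
        out[role] = MicroscopyVolume(data[idx], config.voxel_size_um, role)
    return out


# ---------------------------------------------------------------------------
# Single-stack analysis
# ---------------------------------------------------------------------------

@dataclass
class StackResult:
    """Everything computed for one stack."""

    stack_id: str
    oocyte_mask: np.ndarray
    spindle_objects: segment.LabeledObjects
    spindle_model: morphometry.SpindleModel
    mtoc_objects: segment.LabeledObjects
    records: list[morphometry.MTOCRecord]
    summary: morphometry.OocyteSummary


def analyze_channels(
    channels: dict[str, MicroscopyVolume], config: PipelineConfig, stack_id: str = ""
) -> StackResult:
    """Run the full chain on in-memory channels."""
    oocyte = segment.extract_oocyte_mask(
        channels["bright_field"], radius_vox=config.variance_radius_vox
    )
    spindle_objs = segment.segment_spindle(
        channels["microtubule"], oocyte, gaussian_radius_vox=config.gaussian_radius_vox
    )
    spindle_mask = spindle_objs.mask(1)
    model = morphometry.spindle_model_from_mask(
        spindle_mask,
        channels["microtubule"].voxel_size,
        pole_slab_fraction=config.pole_slab_fraction,
        central_slab_fraction=config.central_slab_fraction,
    )
    mtocs = segment.detect_mtocs(
        channels["mtoc"],
        oocyte,
        min_volume_um3=config.min_mtoc_volume_um3,
        sigma_small_vox=config.dog_sigma_small_vox,
        sigma_large_vox=config.dog_sigma_large_vox,
    )
    records = morphometry.mtoc_records(mtocs, model, spindle_mask)
    summary = morphometry.summarize_oocyte(model, records)
    return StackResult(
        stack_id=stack_id,
        oocyte_mask=oocyte,
        spindle_objects=spindle_objs,
        spindle_model=model,
        mtoc_objects=mtocs,
        records=records,
        summary=summary,
    )


def analyze_stack(stack_path, config: PipelineConfig, out_dir=None) -> StackResult:
    """Analyze one stack from disk, optionally writing the result bundle."""
    stack_id = Path(stack_path).name
    for suffix in (".truth.json", ".tif"):
        if stack_id.endswith(suffix):
            stack_id = stack_id[: -len(suffix)]
    channels = load_channels(stack_path, config)
    result = analyze_channels(channels, config, stack_id=stack_id)
    if out_dir is not None:
        write_result(result, config, out_dir)
    return result


def records_frame(result: StackResult, config: PipelineConfig) -> pd.DataFrame:
    rows = [
        {
            "stack_id": result.stack_id,
            "mtoc_index": i,
            "centroid_z_um": r.centroid_um[0],
            "centroid_y_um": r.centroid_um[1],
            "centroid_x_um": r.centroid_um[2],
            "volume_um3": r.volume_um3,
            "dist_pole_min_um": r.dist_pole_min_um,
            "normalized_position": r.normalized_position,
            "border_distance_um": r.border_distance_um,
            "config_hash": config.config_hash,
        }
        for i, r in enumerate(result.records)
    ]
    columns = [
        "stack_id", "mtoc_index", "centroid_z_um", "centroid_y_um", "centroid_x_um",
        "volume_um3", "dist_pole_min_um", "normalized_position", "border_distance_um",
        "config_hash",
    ]
    return pd.DataFrame(rows, columns=columns)


def summary_frame(result: StackResult, config: PipelineConfig) -> pd.DataFrame:
    s = result.summary
    row = {
        "stack_id": result.stack_id,
        "n_mtocs": s.n_mtocs,
        "total_mtoc_volume_um3": s.total_mtoc_volume_um3,
        "sorting_sd": s.sorting_sd,
        "spindle_length_um": s.spindle_length_um,
        "central_width_um": s.central_width_um,
        "pole_width_um": s.pole_width_um,
        "pole_width_a_um": s.pole_width_a_um,
        "pole_width_b_um": s.pole_width_b_um,
        "config_hash": config.config_hash,
    }
    return pd.DataFrame([row])


def write_result(result: StackResult, config: PipelineConfig, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = out_dir / result.stack_id
    tifffile.imwrite(f"{prefix}.spindle_labels.tif",
                     result.spindle_objects.label_grid.astype(np.uint16))
    tifffile.imwrite(f"{prefix}.mtoc_labels.tif",
                     result.mtoc_objects.label_grid.astype(np.uint16))


def write_qc_overlay(
    result: StackResult, channels: dict[str, MicroscopyVolume], path
) -> None:
    """Mid-plane QC figure: microtubule channel with poles and aMTOC centroids."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mt = channels["microtubule"]
    vz, vy, vx = mt.voxel_size
    mid = mt.shape[0] // 2
    fig, ax = plt.subplots(figsize=(6, 6))
    extent = (0, mt.shape[2] * vx, mt.shape[1] * vy, 0)
    ax.imshow(mt.data[mid], cmap="gray", extent=extent)
    model = result.spindle_model
    ax.plot(
        [model.pole_a[2], model.pole_b[2]],
        [model.pole_a[1], model.pole_b[1]],
        "c+-", markersize=12, label="spindle poles",
    )
    if result.records:
        ys = [r.centroid_um[1] for r in result.records]
        xs = [r.centroid_um[2] for r in result.records]
        ax.plot(xs, ys, "ro", fillstyle="none", label="aMTOCs")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_title(f"{result.stack_id}: mid-plane z={mid}")
    ax.legend(loc="lower right", fontsize=8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def analyze_batch(stack_paths, config: PipelineConfig, out_dir) -> pd.DataFrame:
    """Analyze many stacks; failures are recorded, not fatal.

    Writes ``mtocs.csv`` (one row per aMTOC), ``oocytes.csv`` (one row per
    stack), ``run_metadata.json`` (full configuration + hash) and
    ``manifest.csv`` (per-file status) under ``out_dir``. Returns the
    per-oocyte table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mtoc_frames, oocyte_frames, manifest = [], [], []
    for path in stack_paths:
        try:
            result = analyze_stack(path, config, out_dir=out_dir / "labels")
        except OospindleError as exc:
            logger.error("analysis failed for %s: %s", path, exc)
            manifest.append(
                {"stack": str(path), "status": "failed",
                 "stage": type(exc).__name__, "message": str(exc)}
            )
            continue
        mtoc_frames.append(records_frame(result, config))
        oocyte_frames.append(summary_frame(result, config))
        manifest.append({"stack": str(path), "status": "ok", "stage": "", "message": ""})

    mtocs = (pd.concat(mtoc_frames, ignore_index=True)
             if mtoc_frames else records_frame_empty(config))
    oocytes = (pd.concat(oocyte_frames, ignore_index=True)
               if oocyte_frames else pd.DataFrame())
    float_fmt = "%.6f"
    mtocs.to_csv(out_dir / "mtocs.csv", index=False, float_format=float_fmt)
    oocytes.to_csv(out_dir / "oocytes.csv", index=False, float_format=float_fmt)
    pd.DataFrame(manifest).to_csv(out_dir / "manifest.csv", index=False)
    metadata = {"config": config.to_dict(), "config_hash": config.config_hash,
                "n_stacks": len(list(stack_paths))}
    (out_dir / "run_metadata.json").write_text(json.dumps(metadata, indent=2, sort_keys=True))
    return oocytes


def records_frame_empty(config: PipelineConfig) -> pd.DataFrame:
    class _Empty:
        stack_id = ""
        records: list = []
    return records_frame(_Empty(), config)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

def simulate(params: synth.SceneParams, n_scenes: int, seed: int, out_dir) -> list[dict]:
    """Generate and write ``n_scenes`` synthetic scenes (deterministic per seed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i in range(n_scenes):
        scene_seed = int(seed) + i
        truth = synth.generate_scene(params, seed=scene_seed)
        paths = synth.write_scene(truth, out_dir, prefix=f"scene_{i:03d}")
        written.append({k: str(v) for k, v in paths.items()})
    return written


# ---------------------------------------------------------------------------
# FRAP driver
# ---------------------------------------------------------------------------

def fit_frap_csv(csv_path, pre_bleach_index: int = 0, first_post_index: int = 1) -> dict:
    """Normalize and fit one FRAP trace CSV with time_s and intensity columns."""
    try:
        table = pd.read_csv(csv_path)
    except Exception as exc:
        raise ConfigurationError(f"cannot parse {csv_path}: {exc}") from exc
    cols = {c.lower(): c for c in table.columns}
    tcol = cols.get("time_s") or cols.get("time")
    icol = cols.get("intensity") or cols.get("raw")
    if tcol is None or icol is None:
        raise ConfigurationError(
            f"{csv_path}: need time_s and intensity columns, found {list(table.columns)}"
        )
    trace = photometry.normalize_frap(
        table[tcol].to_numpy(), table[icol].to_numpy(),
        pre_bleach_index=pre_bleach_index, first_post_index=first_post_index,
    )
    fit = photometry.fit_frap(trace)
    return {
        "file": str(csv_path),
        "t_half_s": fit.t_half,
        "k_per_s": fit.k,
        "plateau": fit.plateau,
        "rss": fit.rss,
        "n_post_samples": int(trace.post_bleach_times.size),
    }
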