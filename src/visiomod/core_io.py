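"""Shared file I/O, run configuration, and the end-to-end pipeline.

Stacks travel as multi-page TIFF with a JSON sidecar carrying acquisition
metadata (frame rate, bit depth, modality); maps as 32-bit float TIFF plus
JSON; area masks as label TIFF/PNG plus a JSON name map; tables as CSV.
:func:`run_pipeline` chains simulation (or loading), Fourier analysis,
segmentation, and quantification, and writes a machine-readable manifest
echoing every parameter so the run can be regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__
from .isoi_fourier import FourierMaps, ImagingStack, bin_stack, fourier_maps
from .quantify import area_responses, responsive_mask
from .segmentation import AreaROISet, RetinotopyPair, field_sign, load_manual_rois, segment_areas
from .stimulus import StimulusProtocol, load_protocol, stimulus_frequency

logger = logging.getLogger("visiomod")

__all__ = [
    "RunConfig",
    "read_stack",
    "write_stack",
    "write_maps",
    "read_maps",
    "write_rois",
    "read_rois",
    "run_pipeline",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImagingStack, path) -> None:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    frames = stack.frames
    if stack.bit_depth == "float":
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames)
    meta = {
        "frame_rate_hz": stack.frame_rate_hz,
        "bit_depth": stack.bit_depth,
        "modality": stack.modality,
        **{k: v for k, v in stack.meta.items() if isinstance(v, (str, int, float, list, tuple))},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_stack(path, frame_rate_hz: float | None = None) -> ImagingStack:
    """Read a single-channel multi-page TIFF stack.

    Frame rate comes from the JSON sidecar unless given explicitly; bit
    depth is inferred from dtype and maximum value (integer data fitting
    in 12 bits is tagged 12-bit).
    """
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface a parse error with context
        raise ValueError(f"cannot parse TIFF stack {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel T×H×W stack, got shape {frames.shape}"
        )
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    rate = frame_rate_hz if frame_rate_hz is not None else meta.get("frame_rate_hz")
    if rate is None:
        raise ValueError(f"{path}: frame rate missing (no sidecar and none given)")
    if np.issubdtype(frames.dtype, np.floating):
        depth: int | str = "float"
    elif meta.get("bit_depth") in (12, 16):
        depth = meta["bit_depth"]
    else:
        depth = 12 if frames.max(initial=0) < 4096 else 16
    return ImagingStack(frames=frames, frame_rate_hz=float(rate), bit_depth=depth,
                        modality=meta.get("modality", "isoi"), meta=meta)


def write_maps(maps: FourierMaps, out_dir) -> None:
    """Write magnitude/phase maps as float32 TIFF plus JSON metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out_dir / "magnitude.tif", maps.magnitude.astype(np.float32))
    tifffile.imwrite(out_dir / "phase.tif", maps.phase.astype(np.float32))
    if maps.mean_image is not None:
        tifffile.imwrite(out_dir / "mean.tif", maps.mean_image.astype(np.float32))
    (out_dir / "maps.json").write_text(json.dumps({
        "analysis_frequency_hz": maps.analysis_frequency_hz,
        "frame_rate_hz": maps.frame_rate_hz,
        "binning": list(maps.binning),
    }, indent=2))


def read_maps(out_dir) -> FourierMaps:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "maps.json").read_text())
    mean_path = out_dir / "mean.tif"
    return FourierMaps(
        magnitude=tifffile.imread(out_dir / "magnitude.tif").astype(float),
        phase=tifffile.imread(out_dir / "phase.tif").astype(float),
        analysis_frequency_hz=meta["analysis_frequency_hz"],
        frame_rate_hz=meta["frame_rate_hz"],
        binning=tuple(meta["binning"]),
        mean_image=tifffile.imread(mean_path).astype(float) if mean_path.exists() else None,
    )


def write_rois(rois: AreaROISet, path) -> None:
    """Write an area set as a 16-bit label TIFF plus a JSON name map."""
    path = Path(path)
    shape = next(iter(rois.masks.values())).shape
    label_img = np.zeros(shape, dtype=np.uint16)
    names = {}
    for i, (name, mask) in enumerate(rois.masks.items(), start=1):
        label_img[mask] = i
        names[i] = name
    tifffile.imwrite(path, label_img)
    _sidecar(path).write_text(json.dumps(
        {"names": names, "provenance": rois.provenance}, indent=2))


def read_rois(path) -> AreaROISet:
    path = Path(path)
    label_img = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    rois = load_manual_rois(label_img, {int(k): v for k, v in meta["names"].items()})
    rois.provenance = meta.get("provenance", "manual")
    return rois


@dataclass
class RunConfig:
    """Everything one pipeline run needs, validated up front."""

    out_dir: str
    protocol_path: str | None = None
    stack_path: str | None = None
    elevation_stack_path: str | None = None
    azimuth_stack_path: str | None = None
    manual_rois_path: str | None = None
    simulate: bool = False
    seed: int = 0
    temporal_bin: int = 4
    spatial_bin: int = 2
    smoothing_sigma: float = 2.0
    support_fraction: float = 0.30
    min_area_px: int = 30
    threshold_fraction: float = 0.25
    animal: str = "synthetic"
    genotype: str = "WT"
    age: str = "P85"
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.simulate:
            if self.protocol_path is None:
                raise ValueError("config needs protocol_path (or simulate=true)")
            for p in (self.protocol_path, self.stack_path,
                      self.elevation_stack_path, self.azimuth_stack_path,
                      self.manual_rois_path):
                if p is not None and not Path(p).exists():
                    raise ValueError(f"configured path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


def _hash_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run the full ISOI pipeline and write maps, ROIs, table, manifest.

    With ``simulate=True`` the bundled synthetic scene provides the input
    stacks (slow-fast grating drive plus both bar sweeps); otherwise the
    configured stacks are loaded. Output is deterministic given the
    config, including its seed.
    """
    from . import synthetic
    from .quantify import group_table
    from .stimulus import build_grating_protocol

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": asdict(config), "inputs": {}}

    if config.simulate:
        logger.info("simulating synthetic scene (seed=%d)", config.seed)
        scene = synthetic.make_cortex_scene()
        protocol = build_grating_protocol(10, 50, 6.0, 2.0, n_cycles=4, frame_rate_hz=30.0)
        stack = synthetic.simulate_isoi(scene, protocol, seed=config.seed)
        elev = synthetic.simulate_bar_retinotopy(scene, "horizontal", seed=config.seed + 1)
        azim = synthetic.simulate_bar_retinotopy(scene, "vertical", seed=config.seed + 2)
        bar_frames = elev.meta["sweep_frames"]
    else:
        protocol = load_protocol(config.protocol_path)
        manifest["inputs"]["protocol"] = _hash_file(config.protocol_path)
        stack = read_stack(config.stack_path)
        manifest["inputs"]["stack"] = _hash_file(config.stack_path)
        elev = azim = None
        if config.elevation_stack_path and config.azimuth_stack_path:
            elev = read_stack(config.elevation_stack_path)
            azim = read_stack(config.azimuth_stack_path)
            manifest["inputs"]["elevation_stack"] = _hash_file(config.elevation_stack_path)
            manifest["inputs"]["azimuth_stack"] = _hash_file(config.azimuth_stack_path)
            bar_frames = elev.meta.get("sweep_frames")
            if bar_frames is None:
                raise ValueError("bar stacks need 'sweep_frames' in their sidecar metadata")

    def stage(name):
        logger.info("stage: %s", name)

    stage("isoi-fourier")
    f_stim = stimulus_frequency(protocol)
    binned = bin_stack(stack, config.temporal_bin, config.spatial_bin)
    maps = fourier_maps(binned, f_stim)
    write_maps(maps, out / "maps_stimulus")

    rois = None
    if config.manual_rois_path:
        stage("manual-rois")
        rois = read_rois(config.manual_rois_path)
    elif elev is not None and azim is not None:
        stage("segment")
        f_bar = elev.frame_rate_hz / bar_frames
        elev_maps = fourier_maps(bin_stack(elev, config.temporal_bin, config.spatial_bin), f_bar)
        azim_maps = fourier_maps(bin_stack(azim, config.temporal_bin, config.spatial_bin), f_bar)
        fsm = field_sign(RetinotopyPair(elevation=elev_maps, azimuth=azim_maps),
                         smoothing_sigma=config.smoothing_sigma,
                         support_fraction=config.support_fraction)
        rois = segment_areas(fsm, min_area=config.min_area_px)
        write_rois(rois, out / "rois.tif")
    if rois is None:
        raise ValueError("no ROIs: give manual_rois_path or both bar stacks (or simulate)")

    stage("quantify")
    mask = responsive_mask(maps.magnitude, threshold_fraction=config.threshold_fraction)
    responses = area_responses(maps.magnitude, mask, rois, stimulus=protocol.name or "stimulus")
    table = group_table(
        [(config.animal, r) for r in responses],
        {config.animal: {"genotype": config.genotype, "age": config.age}},
    )
    table.to_csv(out / "responses.csv", index=False)

    manifest["parameters"] = {
        "analysis_frequency_hz": f_stim,
        "threshold_value": mask.threshold_value,
        "threshold_rule": mask.threshold_rule,
        "seed": config.seed,
    }
    manifest["areas"] = {r.area: {"normalized": r.normalized, "n_pixels": r.n_pixels}
                         for r in responses}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete: %s", out)
    return out
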