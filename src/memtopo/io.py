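"""Image-stack, scene and configuration I/O.

Movies are multi-page TIFFs with a JSON sidecar (same path + ".json")
recording axes, pixel size, frame interval and provenance; pixel size and
frame interval are never guessed from the TIFF alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .optics_sim import OpticsConfig, Scene, SimImage

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "read_scene",
    "write_scene",
    "read_optics_config",
    "sidecar_path",
]


class MetadataError(ValueError):
    """Required image metadata (pixel size, frame interval) is missing."""


@dataclass
class ImageStack:
    """channels x frames x Y x X image data with physical calibration.

    ``frame_interval_s`` may be None for single-timepoint stacks; any
    time-resolved operation must raise MetadataError in that case.
    """

    data: np.ndarray  # (C, T, Y, X)
    pixel_size_um: float
    frame_interval_s: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None, None]
        elif self.data.ndim == 3:  # interpreted as (T, Y, X)
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError("ImageStack data must be 2-D, 3-D or 4-D")
        if self.pixel_size_um <= 0:
            raise MetadataError("pixel_size_um must be positive")
        if self.frame_interval_s is not None and self.frame_interval_s <= 0:
            raise MetadataError("frame_interval_s must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def frame(self, channel: int, t: int) -> np.ndarray:
        return self.data[channel, t]

    def require_dt(self) -> float:
        if self.frame_interval_s is None:
            raise MetadataError(
                "frame_interval_s is required for time-resolved analysis "
                "but was not supplied")
        return self.frame_interval_s


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as float32 TIFF pages (C*T pages, C fastest) + sidecar."""
    path = Path(path)
    c, t, y, x = stack.data.shape
    pages = stack.data.reshape(c * t, y, x).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "axes": "CTYX",
        "shape": [c, t, y, x],
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "provenance": stack.provenance,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_stack(path: str | Path, pixel_size_um: float | None = None,
               frame_interval_s: float | None = None) -> ImageStack:
    """Read a TIFF stack; calibration comes from the sidecar or the keyword
    overrides. Counts are preserved bit-exactly (float32 round-trip)."""
    path = Path(path)
    pages = np.asarray(tifffile.imread(path))
    sp = sidecar_path(path)
    meta: dict = {}
    if sp.exists():
        meta = json.loads(sp.read_text())
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise MetadataError(
            f"pixel size for {path} not found: supply pixel_size_um or a "
            f"sidecar {sp.name}")
    dt = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
    if "shape" in meta:
        data = pages.reshape(meta["shape"])
    else:
        data = pages
    return ImageStack(data=data, pixel_size_um=float(px),
                      frame_interval_s=None if dt is None else float(dt),
                      provenance=meta.get("provenance", {}))


def stack_from_sim(sim: SimImage) -> ImageStack:
    """Wrap a simulated single-timepoint image as an ImageStack."""
    plane = sim.plane if sim.plane.ndim == 3 else sim.plane[None]
    return ImageStack(data=plane[:, None], pixel_size_um=sim.pixel_size_um,
                      provenance=sim.provenance)


def write_scene(scene: Scene, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(scene.to_dict(), indent=1))
    return path


def read_scene(path: str | Path) -> Scene:
    return Scene.from_dict(json.loads(Path(path).read_text()))


def read_optics_config(path: str | Path) -> OpticsConfig:
    """Read an OpticsConfig from YAML/JSON; unknown keys are rejected."""
    d = yaml.safe_load(Path(path).read_text()) or {}
    allowed = {"psf_sigma_nm", "out_px_nm", "gain", "read_noise_sd", "seed"}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown optics config keys: {sorted(unknown)}")
    return OpticsConfig(**d)
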