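"""The in-memory substrate of the pipeline: a single-channel 3D intensity grid.

Conventions used everywhere in this package:

* axis order is ``(z, y, x)``;
* all physical coordinates are in micrometres (µm), with the origin at the
  volume corner and voxel *centres* at ``(index + 0.5) * voxel_size``;
* filters operate in voxel units (matching the convention of ImageJ-style tools),
  while every distance, position and volume reported downstream is physical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class MicroscopyVolume:
    """One channel of a 3D z-stack plus its per-axis voxel size in µm."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        vz, vy, vx = self.voxel_size
        if not (vz > 0 and vy > 0 and vx > 0):
            raise ValueError(f"voxel_size components must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("intensities must be >= 0")
        self.voxel_size = (float(vz), float(vy), float(vx))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        vz, vy, vx = self.voxel_size
        return vz * vy * vx

    def with_data(self, data: np.ndarray, channel_name: str | None = None) -> "MicroscopyVolume":
        """New volume sharing this volume's voxel size."""
        return MicroscopyVolume(
            data=data,
            voxel_size=self.voxel_size,
            channel_name=self.channel_name if channel_name is None else channel_name,
        )


def voxel_centers_um(
    shape: tuple[int, int, int], voxel_size: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-axis voxel-centre coordinate vectors (µm), broadcastable to ``shape``."""
    vz, vy, vx = voxel_size
    z = (np.arange(shape[0]) + 0.5) * vz
    y = (np.arange(shape[1]) + 0.5) * vy
    x = (np.arange(shape[2]) + 0.5) * vx
    return z[:, None, None], y[None, :, None], x[None, None, :]


def indices_to_um(indices: np.ndarray, voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Convert (n, 3) voxel indices to physical voxel-centre coordinates."""
    return (np.asarray(indices, dtype=np.float64) + 0.5) * np.asarray(voxel_size)


def read_volume(
    path, voxel_size: tuple[float, float, float], channel_name: str = ""
) -> MicroscopyVolume:
    """Read a single-channel z-stack from a (multi-page) TIFF file."""
    data = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    if data.ndim == 2:
        data = data[None]
    return MicroscopyVolume(data=data, voxel_size=voxel_size, channel_name=channel_name)


def write_volume(path, volume: MicroscopyVolume) -> None:
    """Write a volume as a float32 multi-page TIFF with resolution metadata."""
    vz, vy, vx = volume.voxel_size
    tifffile.imwrite(
        str(path),
        volume.data.astype(np.float32),
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZYX"},
    )
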