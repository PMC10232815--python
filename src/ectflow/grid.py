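"""Voxel grid primitives shared by every stage of the pipeline.

Axis convention (fixed throughout the package):

* ``x`` — subject left → right,
* ``y`` — posterior → anterior,
* ``z`` — inferior → superior.

Arrays are indexed ``labels[ix, iy, iz]`` and voxel *centres* sit at
``origin + (index + 0.5) * spacing`` so that a grid of shape ``n`` spans
``n * spacing`` millimetres per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class Tissue(IntEnum):
    """Integer label vocabulary for the segmented volume."""

    AIR = 0
    SKIN = 1
    SKULL = 2
    CSF = 3
    GREY = 4
    WHITE = 5
    MUSCLE = 6
    TORSO_SOFT = 7
    LOWER_BODY = 8
    GEL = 9
    ELECTRODE = 10


#: Labels that form the brain compartment for every metric.
BRAIN_LABELS = (Tissue.GREY, Tissue.WHITE)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular isotropic voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z); each entry must be >= 8.
    spacing
        Edge length of a voxel in millimetres (isotropic).
    origin
        Millimetre offset of the corner of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: float = 2.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 8 for n in self.shape):
            raise ValueError(f"grid shape must be 3 entries >= 8, got {self.shape}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.spacing) ** 3

    def centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (mm) along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable voxel-centre coordinate arrays (mm)."""
        cx = self.centers(0)[:, None, None]
        cy = self.centers(1)[None, :, None]
        cz = self.centers(2)[None, None, :]
        return cx, cy, cz

    def affine(self) -> np.ndarray:
        """NIfTI-style affine mapping voxel indices to mm coordinates."""
        aff = np.eye(4)
        aff[:3, :3] = np.eye(3) * self.spacing
        aff[:3, 3] = np.asarray(self.origin) + 0.5 * self.spacing
        return aff


@dataclass
class LabelVolume:
    """A 3-D integer tissue-label array on a :class:`GridSpec`.

    ``planes`` carries named horizontal cut planes (z in mm) recorded by the
    phantom builder; the field-of-view truncation stage reads them back, so
    they survive round-trips through copies and (as a JSON sidecar) disk.
    """

    labels: np.ndarray
    grid: GridSpec
    planes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError(
                f"labels shape {self.labels.shape} != grid shape {self.grid.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.labels.copy(), self.grid, dict(self.planes))

    def mask(self, *tissues: Tissue) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given labels."""
        out = np.zeros(self.labels.shape, dtype=bool)
        for t in tissues:
            out |= self.labels == int(t)
        return out

    def brain_mask(self) -> np.ndarray:
        return self.mask(*BRAIN_LABELS)

    def body_mask(self) -> np.ndarray:
        return self.labels != int(Tissue.AIR)

    def count(self, tissue: Tissue) -> int:
        return int(np.count_nonzero(self.labels == int(tissue)))
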