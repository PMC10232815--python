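"""Parametric voxel phantom: nested head shells fused with neck and body blocks.

The phantom emulates the geometry used in MRI-derived full-body current-flow
models: five nested ellipsoidal head shells (skin, skull, a continuous CSF
layer, grey matter, white matter) sitting on a cylindrical neck, a soft-tissue
torso block and an abstract lower-body block.  It is deliberately mirror
symmetric about the midsagittal plane so that symmetric montages admit exact
laterality checks.

The same module owns the field-of-view (FOV) truncation: a phantom can be cut
at four anatomical planes (upper head, full head, neck, torso), the full-body
volume acting as the reference extent.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .grid import GridSpec, LabelVolume, Tissue

__all__ = ["PhantomParams", "FOVLevel", "build_phantom", "truncate_fov"]

#: Order in which nested head shells are stamped (outermost first).
_SHELLS = (Tissue.SKIN, Tissue.SKULL, Tissue.CSF, Tissue.GREY, Tissue.WHITE)


class FOVLevel(str, Enum):
    """Axial extent of the model, from most truncated to the full reference.

    ``UPPER_HEAD`` cuts one voxel below the inferior-most brain voxel (the
    whole-brain extent), ``FULL_HEAD`` at the inferior end of the head shells,
    ``NECK`` at the base of the neck, ``TORSO`` at the base of the torso;
    ``FULL_BODY`` keeps everything.
    """

    UPPER_HEAD = "upper_head"
    FULL_HEAD = "full_head"
    NECK = "neck"
    TORSO = "torso"
    FULL_BODY = "full_body"

    @classmethod
    def ordered(cls) -> tuple["FOVLevel", ...]:
        """Levels from smallest to largest extent."""
        return (cls.UPPER_HEAD, cls.FULL_HEAD, cls.NECK, cls.TORSO, cls.FULL_BODY)


@dataclass(frozen=True)
class PhantomParams:
    """Dimensions (mm) of the synthetic head–neck–torso phantom.

    Shell semi-axes are (x, y, z) half-extents of the nested head ellipsoids
    and must be strictly nested skin > skull > csf > grey > white along every
    axis; the white shell may be zero (degenerate, producing no white matter).
    Defaults approximate an adult head (skin half-width 75 mm, half-length
    92 mm) with abstract neck/torso/lower-body blocks whose exact dimensions
    only weakly influence brain metrics.
    """

    skin: tuple[float, float, float] = (75.0, 92.0, 88.0)
    skull: tuple[float, float, float] = (68.0, 85.0, 81.0)
    csf: tuple[float, float, float] = (62.0, 79.0, 75.0)
    grey: tuple[float, float, float] = (57.0, 74.0, 70.0)
    white: tuple[float, float, float] = (44.0, 60.0, 55.0)
    neck_radius: float = 50.0
    neck_length: float = 70.0
    neck_overlap: float = 10.0  # how far the neck collar rises past the head bottom
    torso_halfwidth: tuple[float, float] = (80.0, 60.0)  # (x, y) half-extents
    torso_length: float = 300.0
    lower_halfwidth: tuple[float, float] = (60.0, 50.0)
    lower_length: float = 280.0
    spacing: float = 2.0
    margin: float = 6.0
    grid: GridSpec | None = None  # derived from the geometry when omitted
    jitter_mm: float = 0.0  # σ of radial surface noise; 0 keeps exact symmetry
    seed: int = 0

    def __post_init__(self) -> None:
        shells = [self.skin, self.skull, self.csf, self.grey, self.white]
        names = ["skin", "skull", "csf", "grey", "white"]
        for s, name in zip(shells, names):
            if len(s) != 3:
                raise ValueError(f"{name} semi-axes must have 3 entries")
            if name != "white" and any(v <= 0 for v in s):
                raise ValueError(f"{name} semi-axes must be positive, got {s}")
            if name == "white" and any(v < 0 for v in s):
                raise ValueError(f"white semi-axes must be >= 0, got {s}")
        for outer, inner, no, ni in zip(shells[:-1], shells[1:], names[:-1], names[1:]):
            if not all(o > i for o, i in zip(outer, inner)):
                raise ValueError(
                    f"shell semi-axes must be strictly nested: {no} {outer} "
                    f"must exceed {ni} {inner} on every axis"
                )
        for name in ("neck_radius", "neck_length", "torso_length", "lower_length",
                     "spacing", "margin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.neck_overlap < self.neck_length:
            raise ValueError("neck_overlap must lie in [0, neck_length)")

    # ---- derived geometry -------------------------------------------------

    @property
    def head_center(self) -> tuple[float, float, float]:
        g = self.derive_grid()
        xc = g.shape[0] * g.spacing / 2.0 + g.origin[0]
        yc = g.shape[1] * g.spacing / 2.0 + g.origin[1]
        zc = (g.origin[2] + self.margin + self.lower_length + self.torso_length
              + self.neck_length - self.neck_overlap + self.skin[2])
        return (xc, yc, zc)

    def derive_grid(self) -> GridSpec:
        if self.grid is not None:
            return self.grid
        h = self.spacing
        half_x = max(self.skin[0], self.torso_halfwidth[0],
                     self.lower_halfwidth[0], self.neck_radius)
        half_y = max(self.skin[1], self.torso_halfwidth[1],
                     self.lower_halfwidth[1], self.neck_radius)
        # even voxel counts keep the midsagittal plane between voxel centres
        nx = int(np.ceil((half_x + self.margin) / h)) * 2
        ny = int(np.ceil((half_y + self.margin) / h)) * 2
        height = (self.margin + self.lower_length + self.torso_length
                  + self.neck_length - self.neck_overlap
                  + 2 * self.skin[2] + self.margin)
        nz = int(np.ceil(height / h))
        return GridSpec(shape=(nx, ny, nz), spacing=h)


def _ellipsoid_mask(grid: GridSpec, center: tuple[float, float, float],
                    semi: tuple[float, float, float],
                    noise: np.ndarray | None = None) -> np.ndarray:
    if min(semi) <= 0:
        return np.zeros(grid.shape, dtype=bool)
    cx, cy, cz = grid.meshgrid()
    r2 = (((cx - center[0]) / semi[0]) ** 2
          + ((cy - center[1]) / semi[1]) ** 2
          + ((cz - center[2]) / semi[2]) ** 2)
    if noise is not None:
        r2 = r2 + noise
    return r2 <= 1.0


def build_phantom(params: PhantomParams) -> LabelVolume:
    """Rasterise the phantom described by ``params`` onto its voxel grid.

    Later compartments overwrite earlier ones, so head shells take priority
    over the neck collar where they overlap.  With ``jitter_mm == 0`` the
    output is exactly mirror symmetric about the midsagittal plane.  The
    returned volume carries the four FOV cut planes in ``planes``.
    """
    grid = params.derive_grid()
    h = grid.spacing
    xc, yc, zc = params.head_center
    if (zc + params.skin[2] > grid.origin[2] + grid.shape[2] * h
            or params.skin[0] + xc > grid.origin[0] + grid.shape[0] * h
            or params.skin[1] + yc > grid.origin[1] + grid.shape[1] * h):
        raise ValueError("grid too small to contain the phantom geometry")

    labels = np.zeros(grid.shape, dtype=np.int16)
    gx, gy, gz = grid.meshgrid()

    z0 = grid.origin[2] + params.margin
    lower_top = z0 + params.lower_length
    torso_top = lower_top + params.torso_length
    neck_top = torso_top + params.neck_length
    head_bottom = zc - params.skin[2]  # == neck_top - neck_overlap

    def _block(halfwidth: tuple[float, float], z_lo: float, z_hi: float) -> np.ndarray:
        return ((np.abs(gx - xc) <= halfwidth[0])
                & (np.abs(gy - yc) <= halfwidth[1])
                & (gz >= z_lo) & (gz < z_hi))

    labels[_block(params.lower_halfwidth, z0, lower_top)] = Tissue.LOWER_BODY
    labels[_block(params.torso_halfwidth, lower_top, torso_top)] = Tissue.TORSO_SOFT
    neck = (((gx - xc) ** 2 + (gy - yc) ** 2 <= params.neck_radius ** 2)
            & (gz >= torso_top) & (gz < neck_top))
    labels[neck] = Tissue.MUSCLE

    rng = np.random.default_rng(params.seed)
    semis = (params.skin, params.skull, params.csf, params.grey, params.white)
    for tissue, semi in zip(_SHELLS, semis):
        noise = None
        if params.jitter_mm > 0:
            # perturb the implicit surface; scale keeps σ roughly in mm
            noise = rng.normal(0.0, params.jitter_mm / max(semi), size=grid.shape)
        labels[_ellipsoid_mask(grid, (xc, yc, zc), semi, noise)] = tissue

    vol = LabelVolume(labels, grid)
    brain = vol.brain_mask()
    if not brain.any():
        raise ValueError("phantom contains no brain voxels")
    brain_zmin = int(np.flatnonzero(brain.any(axis=(0, 1))).min())

    def _layer_edge(k: int) -> float:
        return grid.origin[2] + k * h

    vol.planes = {
        FOVLevel.UPPER_HEAD.value: _layer_edge(max(brain_zmin - 1, 0)),
        FOVLevel.FULL_HEAD.value: head_bottom,
        FOVLevel.NECK.value: torso_top,
        FOVLevel.TORSO.value: lower_top,
    }
    order = [vol.planes[lv.value] for lv in FOVLevel.ordered()[:-1]]
    if not all(a > b for a, b in zip(order, order[1:])):
        raise ValueError(f"FOV cut planes not strictly ordered: {vol.planes}")
    return vol


def truncate_fov(vol: LabelVolume, level: FOVLevel) -> LabelVolume:
    """Return a copy of ``vol`` with all voxels below the FOV cut plane cleared.

    ``FULL_BODY`` returns an identical copy.  Raises if the cut would remove
    brain voxels (the upper-head extent is the whole-brain extent by
    definition).
    """
    level = FOVLevel(level)
    out = vol.copy()
    if level is FOVLevel.FULL_BODY:
        return out
    try:
        plane_z = vol.planes[level.value]
    except KeyError as exc:
        raise ValueError(
            f"volume has no recorded cut plane for {level.value!r}"
        ) from exc
    grid = vol.grid
    k = int(np.round((plane_z - grid.origin[2]) / grid.spacing))
    k = max(k, 0)
    removed_brain = vol.brain_mask()[:, :, :k]
    if removed_brain.any():
        raise ValueError(
            f"truncating at {level.value} (z={plane_z} mm) would remove "
            f"{int(removed_brain.sum())} brain voxels"
        )
    out.labels[:, :, :k] = Tissue.AIR
    return out
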