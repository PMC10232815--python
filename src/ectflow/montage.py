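"""ECT electrode montages (RUL, BL) stamped onto the phantom scalp.

Clinical landmark rules (frontotemporal position 2.5 cm above the
canthus–tragus midpoint; right unilateral vertex electrode 2.5 cm right of
the vertex) have no literal counterpart on an ellipsoidal head, so positions
are defined by their topological equivalents: the frontotemporal centre sits
on the antero-lateral skin surface 2.5 cm above the widest lateral plane
(the head equator), and the vertex electrode 2.5 cm right of the apex.

Electrodes are 25 mm radius discs of gel plus a metal layer, stamped as voxel
shells that follow the local scalp surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .grid import LabelVolume, Tissue
from .phantom import PhantomParams

__all__ = ["Electrode", "ElectrodeMontage", "place_electrodes"]

MONTAGES = ("RUL", "BL")


@dataclass
class Electrode:
    """One disc electrode: placement geometry plus its stamped voxels."""

    center: tuple[float, float, float]  # mm, on the skin surface
    normal: tuple[float, float, float]  # outward unit normal
    radius: float
    role: str  # "anode" | "cathode"
    name: str
    voxels: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.intp))
    gel_voxels: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=np.intp))


@dataclass
class ElectrodeMontage:
    """A named pair of disc electrodes with the injected current."""

    name: str  # "RUL" | "BL"
    electrodes: list[Electrode]
    current_mA: float
    gel_thickness: float = 2.0
    electrode_thickness: float = 2.0

    def __post_init__(self) -> None:
        roles = sorted(e.role for e in self.electrodes)
        if roles != ["anode", "cathode"]:
            raise ValueError(f"montage needs exactly one anode and one cathode, got {roles}")
        if self.current_mA <= 0:
            raise ValueError("injected current must be positive")

    @property
    def anode(self) -> Electrode:
        return next(e for e in self.electrodes if e.role == "anode")

    @property
    def cathode(self) -> Electrode:
        return next(e for e in self.electrodes if e.role == "cathode")

    def scaled(self, current_mA: float) -> "ElectrodeMontage":
        return ElectrodeMontage(self.name, self.electrodes, current_mA,
                                self.gel_thickness, self.electrode_thickness)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "current_mA": self.current_mA,
            "gel_thickness_mm": self.gel_thickness,
            "electrode_thickness_mm": self.electrode_thickness,
            "electrodes": [
                {"name": e.name, "role": e.role, "radius_mm": e.radius,
                 "center_mm": list(map(float, e.center)),
                 "normal": list(map(float, e.normal)),
                 "n_electrode_voxels": int(len(e.voxels)),
                 "n_gel_voxels": int(len(e.gel_voxels))}
                for e in self.electrodes
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)


# ---------------------------------------------------------------------------
# surface geometry on the skin ellipsoid


def _surface_point(center, semi, direction):
    """Intersection of a ray from the ellipsoid centre with its surface."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    t = 1.0 / np.sqrt(np.sum((d / np.asarray(semi)) ** 2))
    return np.asarray(center) + t * d


def _surface_normal(center, semi, point):
    v = (np.asarray(point) - np.asarray(center)) / np.asarray(semi) ** 2
    return tuple(v / np.linalg.norm(v))


def _frontotemporal(params: PhantomParams, side: int, azimuth_deg: float,
                    height_mm: float):
    """Centre + normal of the frontotemporal electrode on the given side.

    ``side`` is +1 (right) or -1 (left).  The centre lies ``height_mm`` above
    the equator of the skin ellipsoid, at ``azimuth_deg`` anterior of the pure
    lateral direction.
    """
    semi = params.skin
    center = params.head_center
    az = np.deg2rad(azimuth_deg)
    base = np.array([side * np.cos(az), np.sin(az), 0.0])

    def height_error(s: float) -> float:
        p = _surface_point(center, semi, base + np.array([0.0, 0.0, s]))
        return p[2] - center[2] - height_mm

    try:
        s = optimize.brentq(height_error, -100.0, 100.0)
    except ValueError as exc:
        raise ValueError(
            f"no frontotemporal position {height_mm} mm above the equator on "
            f"a head with vertical semi-axis {semi[2]} mm") from exc
    p = _surface_point(center, semi, base + np.array([0.0, 0.0, s]))
    return tuple(p), _surface_normal(center, semi, p)


def _vertex_offset(params: PhantomParams, offset_mm: float):
    """Centre + normal of the vertex electrode, offset to the right in
    horizontal projection."""
    semi = params.skin
    cx, cy, cz = params.head_center
    x = offset_mm
    z = semi[2] * np.sqrt(1.0 - (x / semi[0]) ** 2)
    p = (cx + x, cy, cz + z)
    return p, _surface_normal((cx, cy, cz), semi, p)


# ---------------------------------------------------------------------------
# voxel stamping


def _disc_shells(vol: LabelVolume, center, normal, radius: float,
                 gel_t: float, elec_t: float):
    """Boolean (gel, electrode) masks for one disc, following the scalp."""
    grid = vol.grid
    h = grid.spacing
    c = np.asarray(center)
    n = np.asarray(normal)

    # bounding box around the disc keeps the distance transform cheap
    reach = radius + gel_t + elec_t + 6 * h
    lo = np.maximum(((c - reach - np.asarray(grid.origin)) / h).astype(int), 0)
    hi = np.minimum(((c + reach - np.asarray(grid.origin)) / h).astype(int) + 1,
                    grid.shape)
    sub = tuple(slice(a, b) for a, b in zip(lo, hi))
    air = vol.labels[sub] == Tissue.AIR
    dist = ndimage.distance_transform_edt(air, sampling=h)

    cx = grid.centers(0)[sub[0]][:, None, None]
    cy = grid.centers(1)[sub[1]][None, :, None]
    cz = grid.centers(2)[sub[2]][None, None, :]
    vx, vy, vz = cx - c[0], cy - c[1], cz - c[2]
    axial = vx * n[0] + vy * n[1] + vz * n[2]
    tang2 = vx**2 + vy**2 + vz**2 - axial**2
    in_disc = (tang2 <= radius**2) & (axial >= -h) & (axial <= gel_t + elec_t + 3 * h)

    gel_sub = air & in_disc & (dist > 0) & (dist <= gel_t)
    elec_sub = air & in_disc & (dist > gel_t) & (dist <= gel_t + elec_t)

    gel = np.zeros(grid.shape, dtype=bool)
    elec = np.zeros(grid.shape, dtype=bool)
    gel[sub] = gel_sub
    elec[sub] = elec_sub
    return gel, elec


def _stamp(vol: LabelVolume, gel: np.ndarray, elec: np.ndarray, name: str) -> None:
    if not gel.any() or not elec.any():
        raise ValueError(f"electrode {name!r}: no scalp surface at the target location")
    occupied = (vol.labels == Tissue.GEL) | (vol.labels == Tissue.ELECTRODE)
    if (occupied & (gel | elec)).any():
        raise ValueError(f"electrode {name!r} overlaps a previously placed disc")
    # a disc reaching past a truncation plane would wrap onto the cut face
    body_z = np.flatnonzero(vol.body_mask().any(axis=(0, 1)))
    stamp_z = np.flatnonzero((gel | elec).any(axis=(0, 1)))
    if stamp_z.min() < body_z.min():
        raise ValueError(
            f"electrode {name!r} extends below the truncated domain")
    vol.labels[gel] = Tissue.GEL
    vol.labels[elec] = Tissue.ELECTRODE


def _mirror_x(mask: np.ndarray) -> np.ndarray:
    return mask[::-1, :, :]


def place_electrodes(
    vol: LabelVolume,
    montage_name: str,
    current_mA: float,
    params: PhantomParams,
    *,
    radius: float = 25.0,
    gel_thickness: float = 2.0,
    electrode_thickness: float = 2.0,
    ft_azimuth_deg: float = 35.0,
    ft_height_mm: float = 25.0,
    vertex_offset_mm: float = 25.0,
) -> tuple[LabelVolume, ElectrodeMontage]:
    """Stamp an RUL or BL electrode pair onto a phantom.

    Returns a new volume with GEL/ELECTRODE voxels added, plus the montage
    record (roles, geometry, stamped voxel indices).  For BL the left disc is
    the exact voxel mirror of the right one, preserving phantom symmetry.
    Role assignment (immaterial to field magnitudes, by linearity): RUL vertex
    and BL right electrodes are anodes; the remaining frontotemporal electrode
    is the grounded cathode.
    """
    if montage_name not in MONTAGES:
        raise ValueError(f"unknown montage {montage_name!r}; expected one of {MONTAGES}")
    out = vol.copy()

    ft_r_center, ft_r_normal = _frontotemporal(params, +1, ft_azimuth_deg, ft_height_mm)
    gel_r, elec_r = _disc_shells(out, ft_r_center, ft_r_normal, radius,
                                 gel_thickness, electrode_thickness)

    electrodes: list[Electrode] = []
    if montage_name == "RUL":
        v_center, v_normal = _vertex_offset(params, vertex_offset_mm)
        gel_v, elec_v = _disc_shells(out, v_center, v_normal, radius,
                                     gel_thickness, electrode_thickness)
        _stamp(out, gel_v, elec_v, "vertex")
        _stamp(out, gel_r, elec_r, "right_frontotemporal")
        electrodes.append(Electrode(v_center, v_normal, radius, "anode", "vertex",
                                    np.argwhere(elec_v), np.argwhere(gel_v)))
        electrodes.append(Electrode(ft_r_center, ft_r_normal, radius, "cathode",
                                    "right_frontotemporal",
                                    np.argwhere(elec_r), np.argwhere(gel_r)))
    else:  # BL
        gel_l, elec_l = _mirror_x(gel_r), _mirror_x(elec_r)
        _stamp(out, gel_r, elec_r, "right_frontotemporal")
        _stamp(out, gel_l, elec_l, "left_frontotemporal")
        xc = params.head_center[0]
        ft_l_center = (2 * xc - ft_r_center[0], ft_r_center[1], ft_r_center[2])
        ft_l_normal = (-ft_r_normal[0], ft_r_normal[1], ft_r_normal[2])
        electrodes.append(Electrode(ft_r_center, ft_r_normal, radius, "anode",
                                    "right_frontotemporal",
                                    np.argwhere(elec_r), np.argwhere(gel_r)))
        electrodes.append(Electrode(ft_l_center, ft_l_normal, radius, "cathode",
                                    "left_frontotemporal",
                                    np.argwhere(elec_l), np.argwhere(gel_l)))

    montage = ElectrodeMontage(montage_name, electrodes, current_mA,
                               gel_thickness, electrode_thickness)
    return out, montage
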