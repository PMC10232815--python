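"""Experiment orchestration: phantom → montages → extents → solves → metrics.

One experiment is the full factorial design: every requested montage is
simulated on every requested field-of-view extent (10 solves for the default
2 montages × 5 extents), each geometry is solved once at a reference current
and the 100–900 mA amplitude range is obtained by linear scaling, and every
stimulation/laterality/focality metric is collected into one tidy table with
relative errors against the full-body reference extent.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .grid import GridSpec, LabelVolume, Tissue
from .metrics import ThresholdSet, amplitude_sweep
from .montage import place_electrodes
from .phantom import FOVLevel, PhantomParams, build_phantom, truncate_fov
from .solver import ConductivityTable, assemble_system, check_current_conservation, \
    compute_efield, solve_potential

__all__ = ["ExperimentConfig", "RunManifest", "run_experiment", "report_tables",
           "make_fixtures"]

DEFAULT_AMPLITUDES = tuple(float(a) for a in range(100, 1000, 100))


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    phantom: PhantomParams = field(default_factory=PhantomParams)
    montages: tuple[str, ...] = ("RUL", "BL")
    fov_levels: tuple[FOVLevel, ...] = FOVLevel.ordered()
    amplitudes_mA: tuple[float, ...] = DEFAULT_AMPLITUDES
    reference_current_mA: float = 100.0
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    conductivity_overrides: dict = field(default_factory=dict)
    electrode: dict = field(default_factory=dict)  # place_electrodes keywords
    solver_tol: float = 1e-8
    solver_max_iter: int = 20000
    compute_re: bool = True
    save_fields: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.fov_levels = tuple(FOVLevel(lv) for lv in self.fov_levels)
        self.amplitudes_mA = tuple(float(a) for a in self.amplitudes_mA)
        if any(a <= 0 for a in self.amplitudes_mA):
            raise ValueError("amplitudes must be positive")
        if self.reference_current_mA <= 0:
            raise ValueError("reference current must be positive")
        if self.compute_re and FOVLevel.FULL_BODY not in self.fov_levels:
            raise ValueError(
                "relative errors need the FULL_BODY reference extent; include "
                "it in fov_levels or set compute_re=False")

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom"]["grid"] = (None if self.phantom.grid is None
                                else asdict(self.phantom.grid))
        d["fov_levels"] = [lv.value for lv in self.fov_levels]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "phantom" in d:
            ph = dict(d["phantom"])
            if ph.get("grid") is not None:
                ph["grid"] = GridSpec(**{k: tuple(v) if isinstance(v, list) else v
                                         for k, v in ph["grid"].items()})
            for key in ("skin", "skull", "csf", "grey", "white",
                        "torso_halfwidth", "lower_halfwidth"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            d["phantom"] = PhantomParams(**ph)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = ThresholdSet(**d["thresholds"])
        for key in ("montages", "fov_levels", "amplitudes_mA"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance for one experiment run."""

    config_hash: str
    software_version: str
    seed: int
    solves: list = field(default_factory=list)
    failures: list = field(default_factory=list)
    files: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        eio.write_json(self.to_dict(), path)


def run_experiment(
    config: ExperimentConfig,
    output_dir=None,
) -> tuple[pd.DataFrame, RunManifest]:
    """Run the full montage × extent experiment.

    Builds the phantom once; for every montage × extent the volume is
    truncated, electrodes are stamped, the potential is solved once at the
    reference current, and all amplitudes follow by linearity.  A failing
    condition is logged in the manifest and skipped; the rest continue.

    Returns the tidy metrics table (one row per condition × amplitude ×
    threshold, with ``re_pct`` against the full-body extent) and the run
    manifest.  Deterministic for a fixed config.
    """
    from . import __version__

    manifest = RunManifest(config_hash=config.config_hash(),
                           software_version=__version__, seed=config.seed)
    sigma = ConductivityTable.default(**config.conductivity_overrides)
    params = config.phantom
    base = build_phantom(params)
    midline = params.head_center[0]
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    frames = []
    for montage_name in config.montages:
        for level in config.fov_levels:
            t0 = time.perf_counter()
            try:
                vol = truncate_fov(base, level)
                vol, montage = place_electrodes(
                    vol, montage_name, config.reference_current_mA, params,
                    **config.electrode)
                system = assemble_system(vol, sigma)
                sol = solve_potential(system, montage, tol=config.solver_tol,
                                      max_iter=config.solver_max_iter)
                compute_efield(sol)
                imbalance = check_current_conservation(sol, montage, system)
                brain = vol.brain_mask()
                df = amplitude_sweep(sol, brain, config.amplitudes_mA,
                                     config.thresholds, midline_x_mm=midline)
                df.insert(0, "montage", montage_name)
                df.insert(1, "fov", level.value)
                frames.append(df)
                manifest.solves.append({
                    "montage": montage_name, "fov": level.value,
                    "n_unknowns": int(system.n_unknowns),
                    "iterations": int(sol.iterations),
                    "residual": float(sol.residual),
                    "imbalance": float(imbalance),
                    "seconds": round(time.perf_counter() - t0, 2),
                })
                if out is not None and config.save_fields:
                    stem = f"{montage_name}_{level.value}".lower()
                    for name, data in (("V", sol.V), ("Emag", sol.Emag)):
                        p = out / f"{stem}_{name}.nii"
                        eio.write_field_volume(data, vol.grid, p)
                        manifest.files.append(str(p))
            except Exception as exc:  # noqa: BLE001 — isolate per condition
                manifest.failures.append({
                    "montage": montage_name, "fov": level.value,
                    "error": f"{type(exc).__name__}: {exc}",
                })

    if not frames:
        raise RuntimeError(f"every condition failed: {manifest.failures}")
    report = pd.concat(frames, ignore_index=True)

    if config.compute_re:
        fb = report[report["fov"] == FOVLevel.FULL_BODY.value]
        fb = fb[["montage", "amplitude_mA", "threshold_name", "p99_strength"]]
        fb = fb.rename(columns={"p99_strength": "_p99_fb"})
        report = report.merge(fb, on=["montage", "amplitude_mA", "threshold_name"],
                              how="left")
        report["re_pct"] = ((report["p99_strength"] - report["_p99_fb"])
                            / report["_p99_fb"] * 100.0)
        report = report.drop(columns="_p99_fb")
    else:
        report["re_pct"] = np.nan

    if out is not None:
        metrics_path = out / "metrics_long.csv"
        report.to_csv(metrics_path, index=False, float_format="%.10g")
        manifest.files.append(str(metrics_path))
        json_path = out / "metrics_long.json"
        report.to_json(json_path, orient="records", indent=2)
        manifest.files.append(str(json_path))
        manifest.files.extend(report_tables(report, out))
        manifest_path = out / "manifest.json"
        manifest.to_json(manifest_path)
    return report, manifest


def report_tables(report: pd.DataFrame, out_dir) -> list[str]:
    """Write the summary tables: per-montage p99 grids (rows = amplitude,
    columns = extent), the RE and laterality tables, and long-format
    focality curves with distinct trace labels (e.g. ``BL_21`` for the
    brief-pulse BL trace)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fov_order = [lv.value for lv in FOVLevel.ordered()]
    ub = report[report["threshold_name"] == "ultrabrief"]
    written: list[str] = []

    for montage_name, sub in ub.groupby("montage"):
        grid = sub.pivot_table(index="amplitude_mA", columns="fov",
                               values="p99_strength")
        grid = grid.reindex(columns=[c for c in fov_order if c in grid.columns])
        p = out / f"p99_{montage_name}.csv"
        grid.round(4).to_csv(p)
        written.append(str(p))

    re_tab = ub.pivot_table(index=["montage", "amplitude_mA"], columns="fov",
                            values="re_pct")
    re_tab = re_tab.reindex(columns=[c for c in fov_order if c in re_tab.columns])
    p = out / "re_table.csv"
    re_tab.round(2).to_csv(p)
    written.append(str(p))

    lat = ub.pivot_table(index="montage", columns="fov", values="laterality")
    lat = lat.reindex(columns=[c for c in fov_order if c in lat.columns])
    p = out / "laterality_table.csv"
    lat.round(4).to_csv(p)
    written.append(str(p))

    foc = report.copy()
    foc["trace"] = (foc["montage"] + "_"
                    + foc["threshold_V_per_m"].round().astype(int).astype(str))
    foc = foc[["montage", "fov", "trace", "threshold_name", "threshold_V_per_m",
               "amplitude_mA", "focality_pct"]]
    p = out / "focality_curves.csv"
    foc.to_csv(p, index=False, float_format="%.6g")
    written.append(str(p))
    return written


# ---------------------------------------------------------------------------
# fixtures


def _slab_fixture(shape=(10, 10, 10), spacing=10.0, sigma1=0.5, sigma2=None,
                  current_mA=1.0):
    """Homogeneous or two-layer conductive slab with full opposite-face
    electrodes along x, plus its closed-form solution.

    Returns a dict with the volume, montage, conductivity table, and the
    analytic potential drop / layer fields (current continuity: E = J/σ).
    """
    from .montage import Electrode, ElectrodeMontage

    labels = np.full(shape, int(Tissue.MUSCLE), dtype=np.int16)
    half = shape[0] // 2
    if sigma2 is not None:
        labels[half:] = int(Tissue.TORSO_SOFT)
    vol = LabelVolume(labels, GridSpec(shape=shape, spacing=spacing))

    face_lo = np.argwhere(vol.labels[:1] > 0)
    face_hi = np.argwhere(vol.labels[-1:] > 0)
    face_hi[:, 0] = shape[0] - 1
    anode = Electrode(center=(0.0, 0.0, 0.0), normal=(-1.0, 0.0, 0.0),
                      radius=0.0, role="anode", name="face_lo",
                      voxels=face_lo, gel_voxels=face_lo)
    cathode = Electrode(center=(0.0, 0.0, 0.0), normal=(1.0, 0.0, 0.0),
                        radius=0.0, role="cathode", name="face_hi",
                        voxels=face_hi, gel_voxels=face_hi)
    montage = ElectrodeMontage("SLAB", [anode, cathode], current_mA)

    sigma = ConductivityTable.default(muscle=sigma1,
                                      torso_soft=sigma2 if sigma2 else 0.35)
    h_m = spacing * 1e-3
    area = shape[1] * shape[2] * h_m ** 2
    j = current_mA * 1e-3 / area  # A/m²
    out = {
        "volume": vol, "montage": montage, "sigma": sigma,
        "current_density_A_per_m2": j,
        "E1_V_per_m": j / sigma1,
    }
    if sigma2 is not None:
        out["E2_V_per_m"] = j / sigma2
    length = shape[0] * h_m
    if sigma2 is None:
        out["potential_drop_V"] = current_mA * 1e-3 * length / (sigma1 * area)
    return out


_TINY_PARAMS = PhantomParams(
    skin=(34.0, 42.0, 40.0), skull=(29.0, 37.0, 35.0), csf=(24.0, 32.0, 30.0),
    grey=(20.0, 27.0, 25.0), white=(12.0, 17.0, 15.0),
    neck_radius=18.0, neck_length=28.0, neck_overlap=8.0,
    torso_halfwidth=(30.0, 24.0), torso_length=48.0,
    lower_halfwidth=(22.0, 18.0), lower_length=40.0,
    spacing=4.0, margin=8.0)

_TINY_ELECTRODE = dict(radius=12.0, gel_thickness=4.0, electrode_thickness=4.0,
                       ft_height_mm=12.0, vertex_offset_mm=12.0)

_SMALL_PARAMS = PhantomParams(
    skin=(52.0, 64.0, 62.0), skull=(47.0, 59.0, 57.0), csf=(42.0, 54.0, 52.0),
    grey=(38.0, 50.0, 48.0), white=(28.0, 38.0, 36.0),
    neck_radius=35.0, neck_length=50.0, neck_overlap=8.0,
    torso_halfwidth=(56.0, 42.0), torso_length=150.0,
    lower_halfwidth=(42.0, 35.0), lower_length=120.0,
    spacing=3.0, margin=6.0)

_SMALL_ELECTRODE = dict(radius=18.0, gel_thickness=3.0, electrode_thickness=3.0,
                        ft_height_mm=18.0, vertex_offset_mm=18.0)


def make_fixtures(seed: int = 0, size: str = "tiny", out_dir=None) -> dict:
    """Deterministic miniature inputs for tests and quick demos.

    Returns phantom parameters scaled to solve in seconds, matching electrode
    keywords, slab volumes with closed-form solutions, and a small random
    label volume for dense-solver cross-checks.  With ``out_dir`` the phantom
    and slab volumes are also written as (uncompressed) NIfTI plus JSON
    sidecars, byte-identical across runs with the same seed.
    """
    if size not in ("tiny", "small"):
        raise ValueError(f"size must be 'tiny' or 'small', got {size!r}")
    params = _TINY_PARAMS if size == "tiny" else _SMALL_PARAMS
    params = replace(params, seed=seed)
    electrode = dict(_TINY_ELECTRODE if size == "tiny" else _SMALL_ELECTRODE)

    rng = np.random.default_rng(seed)
    rand_labels = rng.integers(1, 7, size=(8, 8, 8)).astype(np.int16)
    rand_vol = LabelVolume(rand_labels, GridSpec(shape=(8, 8, 8), spacing=2.0))

    fixtures = {
        "phantom_params": params,
        "electrode": electrode,
        "phantom": build_phantom(params),
        "slab_homogeneous": _slab_fixture(),
        # 10 mA over the 100×100 mm face gives a unit current density (1 A/m²)
        "slab_two_layer": _slab_fixture(sigma1=1.0, sigma2=0.2, current_mA=10.0),
        "random_label_volume": rand_vol,
        "seed": seed,
        "size": size,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        eio.write_label_volume(fixtures["phantom"], out / f"phantom_{size}.nii")
        eio.write_label_volume(rand_vol, out / "random_labels.nii")
        for name in ("slab_homogeneous", "slab_two_layer"):
            eio.write_label_volume(fixtures[name]["volume"], out / f"{name}.nii")
        meta = {"seed": seed, "size": size,
                "phantom_params": ExperimentConfig(phantom=params).to_dict()["phantom"],
                "electrode": electrode,
                "slab_homogeneous_drop_V":
                    fixtures["slab_homogeneous"]["potential_drop_V"],
                "slab_two_layer_E_V_per_m":
                    [fixtures["slab_two_layer"]["E1_V_per_m"],
                     fixtures["slab_two_layer"]["E2_V_per_m"]]}
        eio.write_json(meta, out / "fixtures.json")
    return fixtures
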