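"""Finite-volume assembly, boundary conditions, and field recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ectflow.grid import GridSpec, LabelVolume, Tissue
from ectflow.montage import Electrode, ElectrodeMontage
from ectflow.pipeline import _slab_fixture
from ectflow.solver import (
    ConductivityTable,
    FieldSolution,
    assemble_system,
    check_current_conservation,
    compute_efield,
    solve_montage,
    solve_potential,
)


def _two_voxel_volume(sigma_a: float, sigma_b: float, spacing: float = 1.0):
    """An 8³ air grid holding a single conductive 2×1×1 pair."""
    labels = np.zeros((8, 8, 8), dtype=np.int16)
    labels[3, 4, 4] = int(Tissue.MUSCLE)
    labels[4, 4, 4] = int(Tissue.TORSO_SOFT)
    vol = LabelVolume(labels, GridSpec((8, 8, 8), spacing))
    table = ConductivityTable({int(Tissue.MUSCLE): sigma_a,
                               int(Tissue.TORSO_SOFT): sigma_b})
    return vol, table


class TestAssembly:
    def test_unit_conductance(self):
        # σ = 1 S/m across a 1 mm² face over 1 mm → 1e-3 S
        vol, table = _two_voxel_volume(1.0, 1.0)
        A = assemble_system(vol, table).matrix.toarray()
        assert A[0, 1] == pytest.approx(-1e-3)
        assert A[0, 0] == pytest.approx(1e-3)

    def test_harmonic_mean_conductance(self):
        vol, table = _two_voxel_volume(1.0, 3.0)
        A = assemble_system(vol, table).matrix.toarray()
        assert A[0, 1] == pytest.approx(-1.5e-3)  # 2·1·3/(1+3) = 1.5 S/m scale

    def test_interior_row_sums_vanish(self, tiny_phantom):
        system = assemble_system(tiny_phantom, ConductivityTable())
        ones = np.ones(system.n_unknowns)
        resid = system.matrix @ ones
        assert np.max(np.abs(resid)) < 1e-12 * system.matrix.diagonal().max()

    def test_missing_label_rejected(self):
        vol, _ = _two_voxel_volume(1.0, 1.0)
        with pytest.raises(KeyError):
            assemble_system(vol, ConductivityTable({int(Tissue.MUSCLE): 1.0}))


class TestSlabSolves:
    def test_homogeneous_slab_linear_potential_and_ohms_law(self):
        fx = _slab_fixture()  # 100 mm cube, σ = 0.5, 1 mA
        sol, imbalance = solve_montage(fx["volume"], fx["montage"], fx["sigma"],
                                       tol=1e-10)
        V = sol.V
        # V varies only along x and linearly: per-voxel drop I·h/(σA)
        assert np.allclose(V.std(axis=(1, 2))[sol.mask.any(axis=(1, 2))], 0,
                           atol=1e-12)
        profile = V[:, 5, 5]
        drops = -np.diff(profile)
        assert np.allclose(drops, drops[0], rtol=1e-9)
        # field E = J/σ and total drop I·L/(σ·A) = 0.02 V over L = 0.1 m
        assert np.allclose(sol.Emag[sol.mask], fx["E1_V_per_m"], rtol=1e-6)
        length = fx["volume"].grid.shape[0] * fx["volume"].grid.spacing * 1e-3
        drop = float(np.mean(sol.Emag[sol.mask])) * length
        assert drop == pytest.approx(fx["potential_drop_V"], rel=1e-6)
        assert imbalance <= 1e-6

    def test_two_layer_slab_current_continuity(self):
        fx = _slab_fixture(sigma1=1.0, sigma2=0.2, current_mA=10.0)  # J = 1 A/m²
        sol, _ = solve_montage(fx["volume"], fx["montage"], fx["sigma"],
                               tol=1e-10)
        emag = sol.Emag
        # skip the two planes whose central difference straddles the interface
        assert np.allclose(emag[:4], fx["E1_V_per_m"], rtol=1e-6)
        assert np.allclose(emag[6:], fx["E2_V_per_m"], rtol=1e-6)

    def test_unconverged_solve_reports_diagnostics(self):
        fx = _slab_fixture()
        from ectflow.solver import assemble_system as asm
        system = asm(fx["volume"], fx["sigma"])
        sol = solve_potential(system, fx["montage"], tol=1e-12, max_iter=1,
                              strict=False)
        assert not sol.converged
        compute_efield(sol)
        imbalance = check_current_conservation(sol, fx["montage"], system)
        assert imbalance >= 0.0

    def test_strict_unconverged_raises(self):
        from ectflow.solver import SolverError
        fx = _slab_fixture()
        system = assemble_system(fx["volume"], fx["sigma"])
        with pytest.raises(SolverError):
            solve_potential(system, fx["montage"], tol=1e-12, max_iter=1)


# ---------------------------------------------------------------------------
# dense-oracle cross-check: independent brute-force assembly + dense solve


def _dense_oracle(labels, sigma_of, spacing_mm, anode_vox, cathode_vox, I_mA):
    """Brute-force potential: loop-assembled dense Laplacian, anode voxels
    merged into one terminal carrying I, cathode voxels grounded."""
    shape = labels.shape
    h = spacing_mm * 1e-3
    idx = {tuple(v): k for k, v in enumerate(np.argwhere(labels > 0))}
    n = len(idx)
    A = np.zeros((n, n))
    for (x, y, z), i in idx.items():
        si = sigma_of[labels[x, y, z]]
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                  (0, 0, 1), (0, 0, -1)):
            nb = (x + d[0], y + d[1], z + d[2])
            if nb in idx:
                sj = sigma_of[labels[nb]]
                g = 2 * si * sj / (si + sj) * h
                A[i, idx[nb]] -= g
                A[i, i] += g
    a_ids = sorted({idx[tuple(v)] for v in anode_vox})
    c_ids = sorted({idx[tuple(v)] for v in cathode_vox})
    # merge anode rows/columns into a single terminal unknown
    keep = [i for i in range(n) if i not in set(a_ids[1:]) | set(c_ids)]
    merge = np.zeros((n, len(keep)))
    col = {i: k for k, i in enumerate(keep)}
    for i in range(n):
        j = a_ids[0] if i in set(a_ids) else i
        if j in col:
            merge[i, col[j]] = 1.0
    A_red = merge.T @ A @ merge
    b = np.zeros(len(keep))
    b[col[a_ids[0]]] = I_mA * 1e-3
    v = merge @ np.linalg.solve(A_red, b)
    V = np.zeros(shape)
    for pos, i in idx.items():
        V[pos] = v[i]
    return V


def _face_montage(labels, current_mA):
    lo = np.argwhere(labels[:1] > 0)
    hi = np.argwhere(labels[-1:] > 0)
    hi[:, 0] = labels.shape[0] - 1
    anode = Electrode((0, 0, 0), (-1, 0, 0), 0.0, "anode", "lo", lo, lo)
    cathode = Electrode((0, 0, 0), (1, 0, 0), 0.0, "cathode", "hi", hi, hi)
    return ElectrodeMontage("ORACLE", [anode, cathode], current_mA)


@settings(max_examples=5, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_iterative_matches_dense_oracle(seed):
    """CG potential equals a brute-force dense solve on small random volumes."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(1, 7, size=(8, 8, 8)).astype(np.int16)
    sigma_of = {lab: float(s) for lab, s in
                zip(range(1, 7), rng.uniform(0.05, 2.0, size=6))}
    vol = LabelVolume(labels, GridSpec((8, 8, 8), spacing=2.0))
    table = ConductivityTable(dict(sigma_of))
    montage = _face_montage(labels, current_mA=5.0)

    system = assemble_system(vol, table)
    sol = solve_potential(system, montage, tol=1e-12, max_iter=5000,
                          preconditioner="jacobi")
    V_dense = _dense_oracle(labels, sigma_of, 2.0, montage.anode.voxels,
                            montage.cathode.voxels, 5.0)
    vrange = V_dense.max() - V_dense.min()
    assert np.max(np.abs(sol.V - V_dense)) <= 1e-8 * vrange


class TestEField:
    def test_linear_potential_gives_uniform_field(self):
        grid = GridSpec((8, 8, 8), spacing=1.0)
        z_m = grid.centers(2)[None, None, :] * 1e-3
        V = np.broadcast_to(-0.02 * z_m, grid.shape).copy()
        sol = FieldSolution(V=V, mask=np.ones(grid.shape, bool), grid=grid,
                            injected_current_mA=1.0, iterations=0,
                            residual=0.0, converged=True)
        compute_efield(sol)
        assert np.allclose(sol.E[..., 2], 0.02)
        assert np.allclose(sol.E[..., 0], 0.0)
        assert np.allclose(sol.Emag, 0.02)

    def test_constant_potential_gives_zero_field(self):
        grid = GridSpec((8, 8, 8), spacing=1.0)
        sol = FieldSolution(V=np.full(grid.shape, 3.7),
                            mask=np.ones(grid.shape, bool), grid=grid,
                            injected_current_mA=1.0, iterations=0,
                            residual=0.0, converged=True)
        compute_efield(sol)
        assert np.all(sol.Emag == 0.0)

    def test_isolated_voxel_component_zeroed(self):
        grid = GridSpec((8, 8, 8), spacing=1.0)
        mask = np.zeros(grid.shape, bool)
        mask[4, 4, 4] = True  # no neighbours along any axis
        sol = FieldSolution(V=np.ones(grid.shape), mask=mask, grid=grid,
                            injected_current_mA=1.0, iterations=0,
                            residual=0.0, converged=True)
        compute_efield(sol)
        assert sol.Emag[4, 4, 4] == 0.0
        assert sol.n_isolated == 1


class TestPhysicalInvariants:
    def test_linearity_in_current(self, tiny_rul):
        base = tiny_rul["solution"]
        system, montage = tiny_rul["system"], tiny_rul["montage"]
        double = solve_potential(system, montage.scaled(200.0), tol=1e-9)
        assert np.max(np.abs(double.V - 2.0 * base.V)) \
            <= 1e-10 * np.max(np.abs(double.V))

    def test_reciprocity_of_role_swap(self, tiny_rul):
        system, montage = tiny_rul["system"], tiny_rul["montage"]
        base = tiny_rul["solution"]
        swapped_electrodes = [
            Electrode(e.center, e.normal, e.radius,
                      "cathode" if e.role == "anode" else "anode",
                      e.name, e.voxels, e.gel_voxels)
            for e in montage.electrodes]
        swapped = ElectrodeMontage(montage.name, swapped_electrodes,
                                   montage.current_mA)
        sol2 = compute_efield(solve_potential(system, swapped, tol=1e-9))
        # V + V_swapped is constant over the domain; |E| is unchanged
        s = (base.V + sol2.V)[base.mask]
        vrange = base.V.max() - base.V.min()
        assert np.ptp(s) <= 1e-6 * vrange
        assert np.max(np.abs(sol2.Emag - base.Emag)) \
            <= 1e-5 * base.Emag.max()

    def test_bl_field_is_mirror_symmetric(self, tiny_bl):
        emag = tiny_bl["solution"].Emag
        assert np.max(np.abs(emag - emag[::-1, :, :])) <= 1e-6 * emag.max()

    def test_current_conservation_on_tiny_phantom(self, tiny_rul, tiny_bl):
        assert tiny_rul["imbalance"] <= 1e-6
        assert tiny_bl["imbalance"] <= 1e-6

    def test_mesh_refinement_converges(self):
        """Halving the spacing changes the brain-median |E| by a shrinking
        amount (Cauchy-style consistency of the discretisation)."""
        from dataclasses import replace
        from ectflow.phantom import PhantomParams, build_phantom
        from ectflow.montage import place_electrodes

        base = PhantomParams(
            skin=(68., 84., 80.), skull=(58., 74., 70.), csf=(48., 64., 60.),
            grey=(40., 54., 50.), white=(24., 34., 30.),
            neck_radius=36., neck_length=56., neck_overlap=16.,
            torso_halfwidth=(60., 48.), torso_length=96.,
            lower_halfwidth=(44., 36.), lower_length=80., margin=16.)
        ek = dict(radius=24., ft_height_mm=24., vertex_offset_mm=24.,
                  gel_thickness=8.0, electrode_thickness=8.0)
        medians = {}
        for h in (8.0, 4.0, 2.0):
            params = replace(base, spacing=h)
            vol = build_phantom(params)
            vol, montage = place_electrodes(vol, "RUL", 100.0, params, **ek)
            sol, _ = solve_montage(vol, montage, ConductivityTable(), tol=1e-9)
            medians[h] = float(np.median(sol.Emag[vol.brain_mask()]))
        coarse_step = abs(medians[4.0] - medians[8.0])
        fine_step = abs(medians[2.0] - medians[4.0])
        assert fine_step < coarse_step
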