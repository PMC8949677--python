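"""Kabsch superposition, RMSD/RMSF and the partial-fit fluctuation."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import flexmap as fm
from flexmap import ContractError, FitError, Selection, SelectionError


def random_rigid(seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=seed).as_matrix()
    t = rng.normal(0, 5, 3)
    return R, t


def grid_oracle_rmsd(mobile: np.ndarray, reference: np.ndarray, seed: int = 0) -> float:
    """Brute-force minimum RMSD: coarse rotation sweep + local refinement.

    Independent of the SVD path: evaluates the objective directly over a
    large random rotation sample and polishes the best candidate with
    Nelder-Mead on the rotation vector (translation handled by centering).
    """
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = P @ R.T - Q
        return np.sqrt(np.mean(np.sum(d * d, axis=1)))

    sample = Rotation.random(20000, random_state=seed)
    rotated = np.einsum("nij,kj->nki", sample.as_matrix(), P)
    costs = np.sqrt(np.mean(np.sum((rotated - Q) ** 2, axis=2), axis=1))
    best = sample[int(np.argmin(costs))].as_rotvec()
    res = minimize(rmsd_of, best, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12})
    return float(res.fun)


class TestKabsch:
    def test_identity_case(self):
        pts = np.random.default_rng(0).normal(0, 2, (7, 3))
        tr, rmsd = fm.kabsch_superpose(pts, pts)
        assert rmsd <= 1e-10
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(tr.translation, 0, atol=1e-9)

    def test_exact_rigid_motion_recovered(self):
        pts = np.random.default_rng(1).normal(0, 2, (8, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ Rz.T + np.array([1.0, 2.0, 3.0])
        tr, rmsd = fm.kabsch_superpose(moved, pts)
        assert rmsd <= 1e-8
        assert np.allclose(tr.apply(moved), pts, atol=1e-8)

    def test_proper_rotation_enforced(self):
        # mirrored points would invite a reflection; the fit must stay proper
        pts = np.random.default_rng(2).normal(0, 2, (6, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        tr, _ = fm.kabsch_superpose(mirrored, pts)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(tr.rotation @ tr.rotation.T, np.eye(3), atol=1e-9)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_rotation_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mobile = rng.normal(0, 2, (5, 3))
        reference = rng.normal(0, 2, (5, 3))
        _, rmsd = fm.kabsch_superpose(mobile, reference)
        assert rmsd == pytest.approx(grid_oracle_rmsd(mobile, reference, seed), abs=1e-3)

    @pytest.mark.parametrize("seed", [6, 7])
    def test_matches_scipy_align_vectors(self, seed):
        rng = np.random.default_rng(seed)
        mobile = rng.normal(0, 2, (9, 3))
        reference = rng.normal(0, 2, (9, 3))
        _, rmsd = fm.kabsch_superpose(mobile, reference)
        rot, rssd = Rotation.align_vectors(
            reference - reference.mean(0), mobile - mobile.mean(0)
        )
        assert rmsd == pytest.approx(rssd / np.sqrt(len(mobile)), abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        ok = np.random.default_rng(0).normal(0, 1, (5, 3))
        with pytest.raises(FitError):
            fm.kabsch_superpose(line, ok)
        with pytest.raises(FitError):
            fm.kabsch_superpose(ok[:2], ok[:2])


class TestRmsdSeries:
    def test_rigidly_moved_frames_give_zero(self, toy_structure):
        base = toy_structure.coords[0]
        frames = []
        for seed in range(5):
            R, t = random_rigid(seed)
            frames.append(base @ R.T + t)
        traj = fm.Trajectory(atoms=toy_structure.atoms, coords=np.array(frames))
        series = fm.rmsd_series(traj, base, Selection(atom_class="backbone"))
        assert np.all(series <= 1e-8)

    def test_empty_selection_and_bad_window_rejected(self, toy_structure):
        base = toy_structure.coords[0]
        with pytest.raises(SelectionError):
            fm.rmsd_series(toy_structure, base, Selection(residue_range=(900, 901)))
        with pytest.raises(ContractError):
            fm.rmsd_series(toy_structure, base, Selection(atom_class="backbone"), window=(0, 99))


class TestRmsf:
    def test_static_trajectory_is_zero(self, toy_structure):
        traj = fm.Trajectory(
            atoms=toy_structure.atoms, coords=np.repeat(toy_structure.coords, 4, axis=0)
        )
        prof = fm.rmsf(traj, Selection(atom_class="backbone"))
        assert np.all(prof.rmsf == 0)

    def test_isotropic_gaussian_closed_form(self, tiny_spec):
        # jittered residues around a rigid fit core: per-atom RMSF -> sqrt(3) sigma
        sigma = 0.5
        lo = tiny_spec.first_residue
        spec = replace(
            tiny_spec,
            n_frames=250,
            n_runs=2,
            harmonic_sigma={r: sigma for r in range(lo + 10, lo + 20)},
        )
        traj = fm.gen_harmonic_trajectory(spec)
        prof = fm.rmsf(
            traj,
            report_sel=Selection(residue_range=(lo + 10, lo + 19), atom_class="backbone"),
            fit_sel=Selection(residue_range=(lo, lo + 9), atom_class="backbone"),
        )
        assert prof.rmsf == pytest.approx(np.sqrt(3) * sigma, rel=0.10)

    def test_fraction_window_matches_manual_recomputation(self, tiny_spec):
        spec = replace(tiny_spec, harmonic_sigma=0.4, n_frames=20, n_runs=2)
        traj = fm.gen_harmonic_trajectory(spec)
        sel = Selection(atom_class="backbone")
        windowed = fm.rmsf(traj, sel, sel, window=0.5)
        # manual oracle: pool exactly the trailing half of each run
        pooled = np.concatenate([np.arange(10, 20), np.arange(30, 40)])
        manual_traj = fm.Trajectory(atoms=traj.atoms, coords=traj.coords[pooled])
        manual = fm.rmsf(manual_traj, sel, sel)
        assert np.allclose(windowed.rmsf, manual.rmsf, atol=1e-12)
        assert windowed.n_frames == 20

    def test_single_frame_window_rejected(self, toy_structure):
        with pytest.raises(ContractError):
            fm.rmsf(toy_structure, Selection(atom_class="backbone"))


class TestPartialFit:
    def test_rigid_trajectory_gives_zero_series(self, toy_structure):
        traj = fm.Trajectory(
            atoms=toy_structure.atoms, coords=np.repeat(toy_structure.coords, 3, axis=0)
        )
        lo = toy_structure.atoms[0].residue_number
        tr = fm.partial_fit_fluctuation(
            traj,
            toy_structure.coords[0],
            fit_sel=Selection(residue_range=(lo + 6, lo + 19), atom_class="backbone"),
            report_sel=Selection(residue_range=(lo, lo + 5), atom_class="backbone"),
        )
        assert np.all(tr.core_rmsd <= 1e-8)
        assert np.all(tr.nterm_displacement <= 1e-8)

    def test_planted_alternating_displacement_recovered(self):
        spec = fm.SyntheticSpec(n_residues=30, n_frames=10, n_runs=2, seed=5)
        traj, series = fm.gen_alternating_nterm(spec, displacement=3.0)
        ref = fm.gen_toy_structure(spec).coords[0]
        tr = fm.partial_fit_fluctuation(
            traj,
            ref,
            fit_sel=Selection(residue_range=(207, 230), atom_class="backbone"),
            report_sel=Selection(residue_range=(201, 206), atom_class="backbone"),
        )
        assert np.allclose(tr.nterm_displacement, series, atol=1e-9)
        assert np.all(tr.core_rmsd <= 1e-6)

    def test_overlapping_selections_rejected(self, toy_structure):
        with pytest.raises(ContractError, match="disjoint"):
            fm.partial_fit_fluctuation(
                toy_structure,
                toy_structure.coords[0],
                fit_sel=Selection(residue_range=(201, 210), atom_class="backbone"),
                report_sel=Selection(residue_range=(205, 208), atom_class="backbone"),
            )


class TestRigidInvariance:
    @pytest.mark.parametrize("seed", [11, 12])
    def test_outputs_unchanged_under_rigid_motion(self, tiny_spec, seed):
        spec = replace(tiny_spec, harmonic_sigma=0.3, n_frames=15, n_runs=1)
        traj = fm.gen_harmonic_trajectory(spec)
        R, t = random_rigid(seed)
        moved = fm.Trajectory(atoms=traj.atoms, coords=traj.coords @ R.T + t)
        sel = Selection(atom_class="backbone")
        lo = tiny_spec.first_residue
        fit = Selection(residue_range=(lo + 6, lo + 19), atom_class="backbone")
        rep = Selection(residue_range=(lo, lo + 5), atom_class="backbone")
        ref = traj.coords[0]
        moved_ref = ref @ R.T + t

        assert np.allclose(
            fm.rmsd_series(traj, ref, sel), fm.rmsd_series(moved, moved_ref, sel), atol=1e-6
        )
        assert np.allclose(
            fm.rmsf(traj, sel, sel).rmsf, fm.rmsf(moved, sel, sel).rmsf, atol=1e-6
        )
        a = fm.partial_fit_fluctuation(traj, ref, fit, rep)
        b = fm.partial_fit_fluctuation(moved, moved_ref, fit, rep)
        assert np.allclose(a.core_rmsd, b.core_rmsd, atol=1e-6)
        assert np.allclose(a.nterm_displacement, b.nterm_displacement, atol=1e-6)
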