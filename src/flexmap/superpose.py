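"""Rigid-body superposition, RMSD/RMSF and partial-fit fluctuation.

The central trick reproduced here is the *partial fit*: frames are
least-squares superposed (Kabsch) on a rigid core selection only, and the
deviation of a *different*, flexible selection is measured under that same
transform.  For the HNF1A POU-homeodomain this isolates the motion of the
N-terminal arm (residues 201-206) after fitting the 207-278 core, which is
how the destabilization of the mutant's N-terminus becomes visible as a
per-frame displacement trace.

RMSF here follows the standard convention: deviations are measured from the
window-mean structure after fitting (not from the crystal reference); a
``reference`` argument switches the fit target for workflows that need it.
Per-residue values aggregate atomic RMSFs as the root of their mean square;
no mass weighting (deterministic, and the analyses are backbone/heavy based).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ContractError, FitError, SelectionError
from .structure_io import Selection, Trajectory, resolve_window

__all__ = [
    "RigidTransform",
    "RMSFProfile",
    "FluctuationTrace",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "partial_fit_fluctuation",
    "write_rmsf_tsv",
    "write_fluctuation_tsv",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, applied as ``x -> R x + t``."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def _as_points(x, label: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise FitError(f"{label} must be an (n, 3) coordinate set, got {a.shape}")
    return a


def kabsch_superpose(mobile, reference) -> tuple[RigidTransform, float]:
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Returns the minimizing :class:`RigidTransform` and the residual RMSD in
    Angstrom.  Reflections are excluded by sign-correcting the smallest
    singular vector.  Degenerate inputs (< 3 points, or a point set of rank
    < 2 after centering, i.e. collinear) raise :class:`FitError`.
    """
    P = _as_points(mobile, "mobile")
    Q = _as_points(reference, "reference")
    if P.shape != Q.shape:
        raise FitError(f"point counts differ: {P.shape[0]} vs {Q.shape[0]}")
    if P.shape[0] < 3:
        raise FitError("superposition needs at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    for X, label in ((P0, "mobile"), (Q0, "reference")):
        s = np.linalg.svd(X, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise FitError(f"{label} points are collinear (rank < 2); fit is degenerate")
    U, _, Vt = np.linalg.svd(P0.T @ Q0)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    transform = RigidTransform(rotation=R, translation=t)
    delta = transform.apply(P) - Q
    rmsd = float(np.sqrt(np.mean(np.sum(delta * delta, axis=1))))
    return transform, rmsd


def _rms_displacement(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def _resolve_nonempty(traj: Trajectory, sel: Selection, label: str) -> np.ndarray:
    idx = sel.resolve(traj)
    if idx.size == 0:
        raise SelectionError(f"{label} selection ({sel.describe()}) matches no atoms")
    return idx


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    fit_sel: Selection,
    window=None,
) -> np.ndarray:
    """Per-frame RMSD over ``fit_sel`` after superposing each frame on it.

    ``reference`` is a full-topology coordinate frame ``(n_atoms, 3)``, e.g.
    a crystal structure mapped onto the trajectory topology.
    """
    fit_idx = _resolve_nonempty(traj, fit_sel, "fit")
    frames = resolve_window(traj, window)
    ref = np.asarray(reference, float)[fit_idx]
    out = np.empty(frames.size)
    for k, t in enumerate(frames):
        _, out[k] = kabsch_superpose(traj.coords[t, fit_idx], ref)
    return out


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation in Angstrom."""

    residue_numbers: np.ndarray
    rmsf: np.ndarray
    frame_indices: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        if len(self.residue_numbers) != len(self.rmsf):
            raise ContractError("residue_numbers and rmsf lengths differ")
        if np.any(np.asarray(self.rmsf) < 0):  # pragma: no cover - defensive
            raise ContractError("negative RMSF")

    def as_dict(self) -> dict[int, float]:
        return {int(r): float(v) for r, v in zip(self.residue_numbers, self.rmsf)}


def _fit_frames_to_target(
    coords: np.ndarray, fit_idx: np.ndarray, target: np.ndarray
) -> list[RigidTransform]:
    return [kabsch_superpose(coords[t, fit_idx], target)[0] for t in range(coords.shape[0])]


def rmsf(
    traj: Trajectory,
    report_sel: Selection,
    fit_sel: Selection | None = None,
    window=None,
    reference: np.ndarray | None = None,
    n_iter: int = 2,
) -> RMSFProfile:
    """Windowed per-residue RMSF after superposition on ``fit_sel``.

    Frames selected by ``window`` (a trailing per-run fraction pools the last
    frames of each run) are superposed on the window-mean structure of the
    fit selection, obtained by a short fixed-point iteration; if ``reference``
    is given the fit target is that structure instead.  Per-atom RMSF is the
    RMS deviation from the mean fitted position; per-residue values are the
    RMS over the residue's reported atoms.
    """
    fit_sel = fit_sel if fit_sel is not None else Selection(atom_class="backbone")
    fit_idx = _resolve_nonempty(traj, fit_sel, "fit")
    report_idx = _resolve_nonempty(traj, report_sel, "report")
    frames = resolve_window(traj, window)
    if frames.size < 2:
        raise ContractError("RMSF needs a window of at least 2 frames")
    X = traj.coords[frames]

    if reference is not None:
        target = np.asarray(reference, float)[fit_idx]
        transforms = _fit_frames_to_target(X, fit_idx, target)
    else:
        target = X[0, fit_idx]
        transforms = _fit_frames_to_target(X, fit_idx, target)
        for _ in range(max(1, n_iter)):
            fitted_fit = np.stack([tr.apply(X[t, fit_idx]) for t, tr in enumerate(transforms)])
            target = fitted_fit.mean(axis=0)
            transforms = _fit_frames_to_target(X, fit_idx, target)

    fitted = np.stack([tr.apply(X[t, report_idx]) for t, tr in enumerate(transforms)])
    mean_pos = fitted.mean(axis=0)
    dev2 = np.sum((fitted - mean_pos) ** 2, axis=2)  # (T, n_report)
    atom_rmsf2 = dev2.mean(axis=0)

    res_of_atom = np.array([traj.atoms[i].residue_number for i in report_idx])
    residues = []
    values = []
    for r in dict.fromkeys(res_of_atom.tolist()):
        mask = res_of_atom == r
        residues.append(int(r))
        values.append(float(np.sqrt(atom_rmsf2[mask].mean())))
    return RMSFProfile(
        residue_numbers=np.array(residues),
        rmsf=np.array(values),
        frame_indices=frames,
        n_frames=int(frames.size),
    )


@dataclass
class FluctuationTrace:
    """Core-fit RMSD and flexible-segment displacement, per frame (A)."""

    frame_indices: np.ndarray
    core_rmsd: np.ndarray
    nterm_displacement: np.ndarray
    run_boundaries: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.frame_indices) == len(self.core_rmsd) == len(self.nterm_displacement)):
            raise ContractError("trace series lengths differ")

    def displacement_rms(self) -> float:
        """Windowed scalar summary: RMS of the per-frame displacement."""
        return float(np.sqrt(np.mean(self.nterm_displacement**2)))


def partial_fit_fluctuation(
    traj: Trajectory,
    reference: np.ndarray,
    fit_sel: Selection,
    report_sel: Selection,
    window=None,
) -> FluctuationTrace:
    """Fit on the core, report the flexible segment under the same transform.

    Per frame: superpose the ``fit_sel`` atoms onto the reference and record
    the residual RMSD (``core_rmsd``); then, *without re-fitting*, record the
    RMSD of the ``report_sel`` atoms from their reference positions under the
    same rigid transform (``nterm_displacement``).  The two selections must
    not share any residue.
    """
    fit_idx = _resolve_nonempty(traj, fit_sel, "fit")
    report_idx = _resolve_nonempty(traj, report_sel, "report")
    fit_res = {traj.atoms[i].residue_number for i in fit_idx}
    rep_res = {traj.atoms[i].residue_number for i in report_idx}
    overlap = fit_res & rep_res
    if overlap:
        raise ContractError(
            f"fit and report selections share residues {sorted(overlap)}; "
            "the partial fit requires residue-level disjoint selections"
        )
    ref = np.asarray(reference, float)
    frames = resolve_window(traj, window)
    core = np.empty(frames.size)
    disp = np.empty(frames.size)
    for k, t in enumerate(frames):
        tr, core[k] = kabsch_superpose(traj.coords[t, fit_idx], ref[fit_idx])
        disp[k] = _rms_displacement(tr.apply(traj.coords[t, report_idx]), ref[report_idx])
    return FluctuationTrace(
        frame_indices=frames,
        core_rmsd=core,
        nterm_displacement=disp,
        run_boundaries=traj.run_boundaries.copy(),
    )


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------

def _header_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k} = {v}\n" for k, v in meta.items())


def write_rmsf_tsv(profile: RMSFProfile, path: str | Path, meta: dict | None = None) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header_lines(meta))
        fh.write(f"# n_frames = {profile.n_frames}\n")
        fh.write("residue_number\trmsf_A\n")
        for r, v in zip(profile.residue_numbers, profile.rmsf):
            fh.write(f"{int(r)}\t{v:.6g}\n")
    return path


def write_fluctuation_tsv(
    trace: FluctuationTrace, path: str | Path, meta: dict | None = None
) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header_lines(meta))
        fh.write(f"# run_boundaries = {','.join(str(int(b)) for b in trace.run_boundaries)}\n")
        fh.write("frame_index\tcore_rmsd_A\tnterm_displacement_A\n")
        for t, c, d in zip(trace.frame_indices, trace.core_rmsd, trace.nterm_displacement):
            fh.write(f"{int(t)}\t{c:.6g}\t{d:.6g}\n")
    return path
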