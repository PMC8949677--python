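"""Synthetic conformational ensembles with planted, analytically known truth.

Every pipeline stage (contact ratios, difference maps, partial-fit
fluctuation, SASA-fluctuation coupling) is made falsifiable by generating
ensembles in which the quantity the analysis is supposed to recover is
*planted*: two-state residue contacts toggle with known Bernoulli occupancy,
the N-terminal segment displaces rigidly by a known per-frame amount, and a
single reporter sphere is occluded by one approaching atom so that its SASA
follows a known spherical-cap closed form, correlated with the N-terminal
displacement at a chosen coefficient.

The geometry is a deliberately non-physical extended chain (3.8 A residue
spacing, planar pseudo-sidechains): the package analyzes geometry, and
physical realism is the job of an MD engine, which is out of scope.  Chain
geometry and mover placement are chosen so that *no* residue pair other than
the planted ones ever crosses the contact cutoff; a built-in geometric guard
re-verifies this at generation time and refuses unsafe specifications.

Design notes
------------
* Noise is i.i.d. per frame (no autocorrelation): closed-form expectations.
* The planted SASA-fluctuation correlation is constructed *in sample*: the
  independent noise component is orthogonalized against the realized latent
  series before mixing, so the sample correlation of the planted series
  equals rho exactly and the recovered coefficient is limited only by the
  quadrature error of the SASA measurement.
* Every generator returns machine-readable ground truth next to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import SpecValidationError
from .sasa import RadiiTable
from .structure_io import AtomRecord, Trajectory

__all__ = [
    "PlantedContact",
    "SyntheticSpec",
    "EnsembleTruth",
    "TwoStateTruth",
    "ExposureTruth",
    "gen_toy_structure",
    "gen_harmonic_trajectory",
    "gen_two_state_trajectory",
    "gen_exposure_coupled_trajectory",
    "gen_ensemble",
    "gen_alternating_nterm",
    "demo_specs",
    "write_truth_tsv",
]

RESIDUE_SPACING = 3.8  # A between successive residue origins along x

_BACKBONE_OFFSETS = {
    "N": np.array([0.0, 0.0, 0.0]),
    "CA": np.array([1.2, 0.8, 0.0]),
    "C": np.array([2.4, 0.0, 0.0]),
    "O": np.array([2.9, -1.0, 0.0]),
}
_SIDECHAIN_NAMES = ("CB", "CG", "CD", "CE", "CZ")
_SIDECHAIN_OFFSETS = {
    "CB": np.array([1.2, 2.3, 0.0]),
    "CG": np.array([1.5, 3.4, 0.6]),
    "CD": np.array([0.9, 4.5, 0.0]),
    "CE": np.array([1.4, 5.6, 0.5]),
    "CZ": np.array([1.0, 6.7, 0.0]),
}

# Reporter-sphere geometry: the probe residue's CB is detached below the
# chain plane so nothing but the dedicated occluder can shade it.
_EXPOSURE_DROP = -12.0
# Safe mover directions in the y-z plane, u = (0, sin a, cos a) degrees.
_SIDECHAIN_ANCHOR_ANGLES = (0.0, 90.0, 180.0, 45.0, 135.0)
_CA_ANCHOR_ANGLES = (150.0, 40.0)
_GUARD_MARGIN = 0.2  # A of clearance demanded beyond the contact cutoff
_EXPOSURE_CLEARANCE = 6.3  # A; nothing mobile may come this close to the reporter
_NTERM_MEAN_SIGMAS = 4.0  # displacement mean, in units of its std


@dataclass(frozen=True)
class PlantedContact:
    """A residue pair toggling across the cutoff with known occupancy."""

    residue_i: int
    residue_j: int
    occupancy: float
    in_distance: float = 3.5
    out_distance: float = 8.0


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic ensemble; the seed fully determines output."""

    n_residues: int = 78
    first_residue: int = 201  # author numbering offset
    atoms_per_residue: int = 5  # N, CA, C, O + CB...
    n_frames: int = 200  # frames per run
    n_runs: int = 10
    seed: int = 0
    cutoff: float = 4.5  # analysis cutoff the planted distances must straddle
    harmonic_sigma: float | Mapping[int, float] = 0.0  # per-residue, per-axis (A)
    two_state_pairs: Sequence[PlantedContact] = ()
    nterm_range: tuple[int, int] = (201, 206)
    nterm_amplitude: float = 0.0  # per-frame std of the rigid z displacement (A)
    exposure_residue: int | None = None
    exposure_rho: float = 0.0
    exposure_mean_occlusion: float = 0.25  # mean occluded cap fraction
    exposure_occlusion_scale: float = 0.06  # cap-fraction change per latent sd
    occluder_residue: int = 230
    residue_names: Mapping[int, str] = field(default_factory=dict)
    frame_dt: float | None = 0.5  # ns per frame (metadata only)

    # -- derived helpers ---------------------------------------------------
    @property
    def last_residue(self) -> int:
        return self.first_residue + self.n_residues - 1

    @property
    def n_total_frames(self) -> int:
        return self.n_frames * self.n_runs

    @property
    def run_boundaries(self) -> np.ndarray:
        return np.arange(self.n_runs) * self.n_frames

    def sigma_for(self, residue: int) -> float:
        if isinstance(self.harmonic_sigma, Mapping):
            return float(self.harmonic_sigma.get(residue, 0.0))
        return float(self.harmonic_sigma)

    def validate(self) -> None:
        """Raise :class:`SpecValidationError` listing every violation."""
        v: list[str] = []
        if self.n_residues < 1:
            v.append("n_residues must be >= 1")
        if self.atoms_per_residue < 4:
            v.append("atoms_per_residue must be >= 4 (N, CA, C, O)")
        if self.atoms_per_residue > 4 + len(_SIDECHAIN_NAMES):
            v.append(f"atoms_per_residue must be <= {4 + len(_SIDECHAIN_NAMES)}")
        if self.n_frames < 1 or self.n_runs < 1:
            v.append("n_frames and n_runs must be >= 1")
        lo, hi = self.first_residue, self.last_residue
        sigmas = (
            self.harmonic_sigma.values()
            if isinstance(self.harmonic_sigma, Mapping)
            else [self.harmonic_sigma]
        )
        if any(s < 0 for s in sigmas):
            v.append("harmonic_sigma must be nonnegative")
        for p in self.two_state_pairs:
            if not (0.0 <= p.occupancy <= 1.0):
                v.append(f"occupancy of pair ({p.residue_i},{p.residue_j}) outside [0, 1]")
            if not (p.in_distance < self.cutoff < p.out_distance):
                v.append(
                    f"pair ({p.residue_i},{p.residue_j}): need "
                    f"in {p.in_distance} < cutoff {self.cutoff} < out {p.out_distance}"
                )
            if abs(p.residue_i - p.residue_j) < 2:
                v.append(f"pair ({p.residue_i},{p.residue_j}): sequence separation < 2")
            for r in (p.residue_i, p.residue_j):
                if not (lo <= r <= hi):
                    v.append(f"pair residue {r} outside [{lo}, {hi}]")
        if self.nterm_amplitude < 0:
            v.append("nterm_amplitude must be nonnegative")
        if self.nterm_amplitude > 0 and not (
            lo <= self.nterm_range[0] <= self.nterm_range[1] <= hi
        ):
            v.append(f"nterm_range {self.nterm_range} outside the chain [{lo}, {hi}]")
        if self.exposure_residue is not None:
            if not (lo <= self.exposure_residue <= hi):
                v.append(f"exposure_residue {self.exposure_residue} outside [{lo}, {hi}]")
            if self.nterm_range[0] <= self.exposure_residue <= self.nterm_range[1]:
                v.append("exposure_residue must lie outside the flexible N-terminal segment")
            if self.atoms_per_residue < 5:
                v.append("exposure coupling needs atoms_per_residue >= 5 (a CB reporter)")
            if not (-1.0 < self.exposure_rho < 1.0):
                v.append(f"|exposure_rho| must be < 1, got {self.exposure_rho}")
            if not (lo <= self.occluder_residue <= hi) or self.occluder_residue == self.exposure_residue:
                v.append("occluder_residue must be a chain residue distinct from exposure_residue")
            f_lo = self.exposure_mean_occlusion - 4.0 * self.exposure_occlusion_scale
            f_hi = self.exposure_mean_occlusion + 4.0 * self.exposure_occlusion_scale
            if f_lo < 0.0 or f_hi > 0.5:
                v.append(
                    "exposure occlusion fraction must stay within (0, 0.5): "
                    f"mean {self.exposure_mean_occlusion} +- 4 x scale "
                    f"{self.exposure_occlusion_scale} leaves that band"
                )
        if v:
            raise SpecValidationError("; ".join(v))


# ---------------------------------------------------------------------------
# Topology and base geometry
# ---------------------------------------------------------------------------

def _topology(spec: SyntheticSpec) -> tuple[list[AtomRecord], np.ndarray, dict]:
    """Atom records, base coordinates, and named special-atom indices."""
    atoms: list[AtomRecord] = []
    xyz: list[np.ndarray] = []
    special: dict = {"exposure_atom": None, "occluder_atom": None}
    sidechain_count = spec.atoms_per_residue - 4
    serial = 0
    for i in range(spec.n_residues):
        resnum = spec.first_residue + i
        origin = np.array([i * RESIDUE_SPACING, 0.0, 0.0])
        names = list(_BACKBONE_OFFSETS)
        if spec.exposure_residue is not None and resnum == spec.exposure_residue:
            names += ["CB"]  # single reporter sphere regardless of atoms_per_residue
        else:
            names += list(_SIDECHAIN_NAMES[:sidechain_count])
        if spec.exposure_residue is not None and resnum == spec.occluder_residue:
            names += [_SIDECHAIN_NAMES[sidechain_count]]  # dedicated occluder atom
        for name in names:
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=name[0],
                    residue_number=resnum,
                    residue_name=spec.residue_names.get(resnum, "ALA"),
                    chain_id="A",
                )
            )
            pos = origin + (_BACKBONE_OFFSETS.get(name) if name in _BACKBONE_OFFSETS else _SIDECHAIN_OFFSETS[name])
            if spec.exposure_residue is not None and resnum == spec.exposure_residue and name == "CB":
                pos = origin + np.array([1.2, 2.3, _EXPOSURE_DROP])
                special["exposure_atom"] = len(atoms) - 1
            if (
                spec.exposure_residue is not None
                and resnum == spec.occluder_residue
                and name == _SIDECHAIN_NAMES[sidechain_count]
            ):
                special["occluder_atom"] = len(atoms) - 1
                pos = None  # set below, under the reporter sphere
            xyz.append(pos)
    coords = np.zeros((len(atoms), 3))
    for k, p in enumerate(xyz):
        if p is not None:
            coords[k] = p
    if special["occluder_atom"] is not None:
        exp = coords[special["exposure_atom"]]
        coords[special["occluder_atom"]] = exp + np.array([0.0, 0.0, -8.0])
    return atoms, coords, special


def gen_toy_structure(spec: SyntheticSpec) -> Trajectory:
    """Single-frame extended-chain reference structure (deterministic)."""
    spec.validate()
    atoms, coords, _ = _topology(spec)
    return Trajectory(
        atoms=atoms,
        coords=coords[None, :, :],
        run_boundaries=np.array([0]),
        frame_dt=spec.frame_dt,
    )


# ---------------------------------------------------------------------------
# Planted-contact mover placement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _MoverPlan:
    pair_index: int
    mover_atom: int  # topology index of the atom that toggles
    anchor_atom: int
    in_pos: np.ndarray
    out_pos: np.ndarray


def _segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Distance from point ``p`` to segment ``ab``."""
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def _plan_movers(
    spec: SyntheticSpec,
    atoms: list[AtomRecord],
    base: np.ndarray,
    special: dict,
) -> list[_MoverPlan]:
    """Assign a toggling atom, an anchor and a safe direction per pair.

    Pass 1 allocates one sidechain atom per pair as the mover (preferring the
    pair's first residue, skipping the reporter atom).  Pass 2 picks an
    anchor (a static sidechain atom of the partner residue, falling back to
    its CA) and a direction from a pre-vetted set, verifying numerically that
    neither the in- nor the out-position creates any off-target contact or
    approaches the reporter sphere.
    """
    by_res: dict[int, list[int]] = {}
    for k, a in enumerate(atoms):
        by_res.setdefault(a.residue_number, []).append(k)
    reserved = {special["exposure_atom"], special["occluder_atom"]} - {None}

    def sidechain_atoms(res: int) -> list[int]:
        return [k for k in by_res[res] if atoms[k].role == "sidechain" and k not in reserved]

    movers: dict[int, int] = {}  # pair index -> atom index
    used: set[int] = set()
    for pi, pair in enumerate(spec.two_state_pairs):
        chosen = None
        for res in (pair.residue_i, pair.residue_j):
            avail = [k for k in sidechain_atoms(res) if k not in used]
            if avail:
                chosen = avail[0]
                break
        if chosen is None:
            raise SpecValidationError(
                f"pair ({pair.residue_i},{pair.residue_j}): no free sidechain atom "
                "left to act as the toggling atom; raise atoms_per_residue"
            )
        movers[pi] = chosen
        used.add(chosen)

    all_mover_atoms = set(movers.values())
    nterm_lo, nterm_hi = spec.nterm_range
    d_max = spec.nterm_amplitude * (_NTERM_MEAN_SIGMAS + 5.0)

    def static_envelope(k: int) -> tuple[np.ndarray, np.ndarray]:
        """Segment swept by a non-mover atom over the whole ensemble."""
        p = base[k]
        if nterm_lo <= atoms[k].residue_number <= nterm_hi:
            return p, p + np.array([0.0, 0.0, d_max])
        return p, p

    def clearance(pos: np.ndarray, skip_residues: set[int]) -> float:
        dmin = np.inf
        for k in range(len(atoms)):
            if k in all_mover_atoms or k == special["occluder_atom"]:
                continue
            if atoms[k].residue_number in skip_residues:
                continue
            a, b = static_envelope(k)
            dmin = min(dmin, _segment_distance(pos, a, b))
        return dmin

    def exposure_clear(pos: np.ndarray) -> bool:
        if special["exposure_atom"] is None:
            return True
        exp = base[special["exposure_atom"]]
        if np.linalg.norm(pos - exp) < _EXPOSURE_CLEARANCE:
            return False
        occ_far = exp + np.array([0.0, 0.0, -7.0])
        return _segment_distance(pos, exp, occ_far) >= _EXPOSURE_CLEARANCE

    plans: list[_MoverPlan] = []
    need = spec.cutoff + _GUARD_MARGIN
    for pi, pair in enumerate(spec.two_state_pairs):
        mover_atom = movers[pi]
        mover_res = atoms[mover_atom].residue_number
        partner = pair.residue_j if mover_res == pair.residue_i else pair.residue_i
        anchor_candidates = [
            k for k in sidechain_atoms(partner) if k not in all_mover_atoms
        ]
        if anchor_candidates:
            anchor = anchor_candidates[0]
            angles = _SIDECHAIN_ANCHOR_ANGLES
        else:
            anchor = next(k for k in by_res[partner] if atoms[k].name == "CA")
            angles = _CA_ANCHOR_ANGLES
        anchor_pos = base[anchor]

        placed = None
        for ang in angles:
            rad = np.deg2rad(ang)
            u = np.array([0.0, np.sin(rad), np.cos(rad)])
            in_pos = anchor_pos + pair.in_distance * u
            out_pos = anchor_pos + pair.out_distance * u
            ok = True
            for pos in (in_pos, out_pos):
                if clearance(pos, {mover_res, partner}) < need or not exposure_clear(pos):
                    ok = False
                    break
            if ok:
                # the anchor must realize the planted minimum distance ...
                partner_static = [
                    k for k in by_res[partner] if k not in all_mover_atoms and k != special["occluder_atom"]
                ]
                din = min(np.linalg.norm(in_pos - base[k]) for k in partner_static)
                dout = min(np.linalg.norm(out_pos - base[k]) for k in partner_static)
                if din < pair.in_distance - 1e-9 or dout < need:
                    ok = False
                # ... and no contact with the mover's own home residue may appear
                own_static = [
                    k
                    for k in by_res[mover_res]
                    if k not in all_mover_atoms and k != special["occluder_atom"]
                ]
                if ok and own_static:
                    for pos in (in_pos, out_pos):
                        for k in own_static:
                            a, b = static_envelope(k)
                            if _segment_distance(pos, a, b) < need:
                                ok = False
            if ok:
                # keep clear of every previously placed mover of another residue
                for prev in plans:
                    if atoms[prev.mover_atom].residue_number == mover_res:
                        continue
                    for p1 in (in_pos, out_pos):
                        for p2 in (prev.in_pos, prev.out_pos):
                            if np.linalg.norm(p1 - p2) < need:
                                ok = False
            if ok:
                placed = _MoverPlan(pi, mover_atom, anchor, in_pos, out_pos)
                break
        if placed is None:
            raise SpecValidationError(
                f"pair ({pair.residue_i},{pair.residue_j}): no collision-free "
                "placement found for the toggling atom"
            )
        plans.append(placed)
    return plans


# ---------------------------------------------------------------------------
# Ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class TwoStateTruth:
    """Realized Bernoulli bookkeeping of the planted contacts."""

    pairs: list[PlantedContact]
    states: np.ndarray  # (T, P) bool, True = in contact
    realized_occupancy: np.ndarray  # (P,)


@dataclass
class ExposureTruth:
    """Planted SASA-fluctuation coupling, with closed-form expectations."""

    planted_rho: float
    latent: np.ndarray  # standardized driver of the N-terminal displacement
    mixed: np.ndarray  # driver of the occlusion, sample-correlated at rho
    nterm_displacement: np.ndarray  # planted per-frame displacement (A)
    occlusion_fraction: np.ndarray  # planted occluded cap fraction
    occluder_distance: np.ndarray  # occluder center distance (A)
    expected_sasa: np.ndarray  # 4 pi R^2 (1 - f), A^2


@dataclass
class EnsembleTruth:
    two_state: TwoStateTruth | None = None
    exposure: ExposureTruth | None = None
    nterm_displacement: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _sample_correlated(rng: np.random.Generator, T: int, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Two standardized series whose *sample* correlation is exactly rho."""
    z = _standardize(rng.standard_normal(T))
    eta = rng.standard_normal(T)
    eta = eta - (eta @ z) / (z @ z) * z  # orthogonalize in sample
    eta = _standardize(eta)
    y = rho * z + np.sqrt(1.0 - rho * rho) * eta
    return z, y


def gen_ensemble(spec: SyntheticSpec) -> tuple[Trajectory, EnsembleTruth]:
    """Generate a full synthetic ensemble with every planted feature enabled.

    Construction order per frame: harmonic jitter on designated residues,
    rigid z-displacement of the N-terminal segment, planted-contact atoms set
    to their in/out rendezvous points, occluder placed below the reporter.
    """
    spec.validate()
    atoms, base, special = _topology(spec)
    plans = _plan_movers(spec, atoms, base, special) if spec.two_state_pairs else []
    T = spec.n_total_frames
    rng = np.random.default_rng(spec.seed)
    truth = EnsembleTruth()

    # latent drivers (drawn first: fixed stream order for reproducibility)
    z, y = _sample_correlated(rng, T, spec.exposure_rho if spec.exposure_residue else 0.0)

    coords = np.repeat(base[None, :, :], T, axis=0)

    mover_atoms = {p.mover_atom for p in plans}
    animated = set(mover_atoms)
    if special["occluder_atom"] is not None:
        animated.add(special["occluder_atom"])
    if special["exposure_atom"] is not None:
        animated.add(special["exposure_atom"])  # static, but never jittered

    # harmonic jitter
    for res, idx in _group_by_residue(atoms).items():
        sigma = spec.sigma_for(res)
        if sigma <= 0:
            continue
        idx = [k for k in idx if k not in animated]
        if idx:
            coords[:, idx, :] += rng.normal(0.0, sigma, size=(T, len(idx), 3))

    # rigid N-terminal displacement along +z
    if spec.nterm_amplitude > 0:
        disp = np.clip(spec.nterm_amplitude * (_NTERM_MEAN_SIGMAS + z), 0.0, None)
        lo, hi = spec.nterm_range
        nterm_idx = [
            k
            for k, a in enumerate(atoms)
            if lo <= a.residue_number <= hi and k not in animated
        ]
        coords[:, nterm_idx, 2] += disp[:, None]
        truth.nterm_displacement = disp
    else:
        disp = np.zeros(T)

    # planted two-state contacts
    if plans:
        states = np.column_stack(
            [rng.random(T) < p.occupancy for p in spec.two_state_pairs]
        )
        for plan in plans:
            s = states[:, plan.pair_index]
            coords[:, plan.mover_atom, :] = np.where(
                s[:, None], plan.in_pos[None, :], plan.out_pos[None, :]
            )
        truth.two_state = TwoStateTruth(
            pairs=list(spec.two_state_pairs),
            states=states,
            realized_occupancy=states.mean(axis=0),
        )

    # exposure coupling: one occluder carves a spherical cap of known fraction
    if spec.exposure_residue is not None:
        radii = RadiiTable()
        R = radii.radius("C") + radii.probe_radius
        f = np.clip(
            spec.exposure_mean_occlusion - spec.exposure_occlusion_scale * y,
            0.005,
            0.495,
        )
        d_occ = 2.0 * R * (1.0 - 2.0 * f)
        exp_pos = base[special["exposure_atom"]]
        occ = special["occluder_atom"]
        coords[:, occ, 0] = exp_pos[0]
        coords[:, occ, 1] = exp_pos[1]
        coords[:, occ, 2] = exp_pos[2] - d_occ
        truth.exposure = ExposureTruth(
            planted_rho=spec.exposure_rho,
            latent=z,
            mixed=y,
            nterm_displacement=disp,
            occlusion_fraction=f,
            occluder_distance=d_occ,
            expected_sasa=4.0 * np.pi * R * R * (1.0 - f),
        )

    traj = Trajectory(
        atoms=atoms,
        coords=coords,
        run_boundaries=spec.run_boundaries,
        frame_dt=spec.frame_dt,
    )
    return traj, truth


def _group_by_residue(atoms: list[AtomRecord]) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for k, a in enumerate(atoms):
        groups.setdefault(a.residue_number, []).append(k)
    return groups


def gen_harmonic_trajectory(spec: SyntheticSpec) -> Trajectory:
    """Reference + i.i.d. isotropic Gaussian displacement on designated residues.

    Residues with sigma 0 form a rigid core; the expected per-atom RMSF of a
    jittered atom is sqrt(3) * sigma.
    """
    clean = replace(spec, two_state_pairs=(), exposure_residue=None, nterm_amplitude=0.0)
    traj, _ = gen_ensemble(clean)
    return traj


def gen_two_state_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, TwoStateTruth]:
    """Planted Bernoulli contact toggling; everything else static."""
    clean = replace(spec, harmonic_sigma=0.0, exposure_residue=None, nterm_amplitude=0.0)
    traj, truth = gen_ensemble(clean)
    if truth.two_state is None:
        raise SpecValidationError("spec plants no two-state pairs")
    return traj, truth.two_state


def gen_exposure_coupled_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, ExposureTruth]:
    """Latent-coupled N-terminal displacement and reporter-sphere occlusion."""
    if spec.exposure_residue is None:
        raise SpecValidationError("spec.exposure_residue is not set")
    clean = replace(spec, harmonic_sigma=0.0, two_state_pairs=())
    traj, truth = gen_ensemble(clean)
    return traj, truth.exposure


def gen_alternating_nterm(
    spec: SyntheticSpec, displacement: float = 3.0
) -> tuple[Trajectory, np.ndarray]:
    """Rigid chain whose N-terminal segment shifts by a fixed amount in
    alternating frames; the planted per-frame displacement series is returned."""
    spec.validate()
    atoms, base, _ = _topology(spec)
    T = spec.n_total_frames
    lo, hi = spec.nterm_range
    nterm_idx = [k for k, a in enumerate(atoms) if lo <= a.residue_number <= hi]
    coords = np.repeat(base[None, :, :], T, axis=0)
    series = np.where(np.arange(T) % 2 == 1, float(displacement), 0.0)
    coords[:, nterm_idx, 2] += series[:, None]
    traj = Trajectory(
        atoms=atoms, coords=coords, run_boundaries=spec.run_boundaries, frame_dt=spec.frame_dt
    )
    return traj, series


# ---------------------------------------------------------------------------
# The bundled wild-type / mutant demonstration pair
# ---------------------------------------------------------------------------

#: Planted lost contacts, echoing the interactions the V259F mutant loses.
DEMO_LOST_PAIRS = ((203, 256), (205, 256), (237, 257), (237, 258), (259, 264))


def demo_specs(seed: int = 0) -> tuple[SyntheticSpec, SyntheticSpec]:
    """WT-like and mutant-like ensemble specs emulating the published contrast.

    The wild type holds the five planted contacts 90% of the time, keeps its
    reporter sidechain buried and its N-terminal arm quiet; the mutant loses
    the contacts (5% occupancy), exposes the reporter and couples that
    exposure to a large N-terminal displacement at rho = 0.8.
    """
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=2)
    common = dict(
        n_residues=78,
        first_residue=201,
        atoms_per_residue=5,
        n_frames=200,
        n_runs=10,
        cutoff=4.5,
        harmonic_sigma=0.05,
        nterm_range=(201, 206),
        exposure_residue=259,
        occluder_residue=230,
    )
    wt = SyntheticSpec(
        seed=int(seeds[0]),
        two_state_pairs=tuple(
            PlantedContact(i, j, occupancy=0.90) for i, j in DEMO_LOST_PAIRS
        ),
        nterm_amplitude=0.10,
        exposure_rho=0.0,
        exposure_mean_occlusion=0.45,
        exposure_occlusion_scale=0.01,
        residue_names={259: "VAL"},
        **common,
    )
    mut = SyntheticSpec(
        seed=int(seeds[1]),
        two_state_pairs=tuple(
            PlantedContact(i, j, occupancy=0.05) for i, j in DEMO_LOST_PAIRS
        ),
        nterm_amplitude=0.75,
        exposure_rho=0.8,
        exposure_mean_occlusion=0.25,
        exposure_occlusion_scale=0.06,
        residue_names={259: "PHE"},
        **common,
    )
    return wt, mut


# ---------------------------------------------------------------------------
# Ground-truth TSV output
# ---------------------------------------------------------------------------

def write_truth_tsv(truth: EnsembleTruth, path: str | Path) -> Path:
    """Machine-readable ground truth: per-pair occupancies and per-frame series."""
    path = Path(path)
    with path.open("w") as fh:
        if truth.two_state is not None:
            for p, q in zip(truth.two_state.pairs, truth.two_state.realized_occupancy):
                fh.write(
                    f"# planted_pair = {p.residue_i},{p.residue_j}"
                    f"\tp={p.occupancy}\trealized={q:.6g}\n"
                )
        if truth.exposure is not None:
            fh.write(f"# planted_rho = {truth.exposure.planted_rho}\n")
        cols: dict[str, np.ndarray] = {}
        if truth.nterm_displacement is not None:
            cols["nterm_displacement_A"] = truth.nterm_displacement
        if truth.exposure is not None:
            cols["occlusion_fraction"] = truth.exposure.occlusion_fraction
            cols["expected_sasa_A2"] = truth.exposure.expected_sasa
        if truth.two_state is not None:
            for k, p in enumerate(truth.two_state.pairs):
                cols[f"contact_{p.residue_i}_{p.residue_j}"] = truth.two_state.states[:, k].astype(int)
        if cols:
            names = list(cols)
            fh.write("frame_index\t" + "\t".join(names) + "\n")
            T = len(next(iter(cols.values())))
            for t in range(T):
                fh.write(
                    f"{t}\t" + "\t".join(f"{cols[n][t]:.6g}" for n in names) + "\n"
                )
    return path
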