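"""Multi-model PDB I/O and reproducible atom selections.

A conformational ensemble is carried as a :class:`Trajectory`: a fixed atom
topology plus ``T`` coordinate frames (one per ``MODEL`` block) and the frame
indices at which independent simulation runs start.  Multi-model PDB is the
canonical on-disk format here: it is plain text, diffable and desk-scale.
Binary MD formats (XTC/DCD) are deliberately out of scope; an adapter only
needs to produce a :class:`Trajectory` to plug into every analysis.

Residues are always addressed by their author numbers (e.g. 201-278 for the
POU-homeodomain of HNF1A), never by a zero-based re-index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    ContractError,
    PDBFormatError,
    PDBParseError,
    SelectionError,
    TopologyMismatchError,
)

__all__ = [
    "AtomRecord",
    "Trajectory",
    "Selection",
    "read_pdb_models",
    "write_pdb_models",
    "resolve_selection",
    "read_run_manifest",
    "write_run_manifest",
    "resolve_window",
]

#: Backbone atom names; every other atom of a residue counts as sidechain.
BACKBONE_NAMES = ("N", "CA", "C", "O")

#: Residue names treated as water and dropped on read by default.
WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP4", "SPC", "H2O"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the (frame-independent) topology."""

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def role(self) -> str:
        """``"backbone"`` for N/CA/C/O, ``"sidechain"`` for everything else."""
        return "backbone" if self.name in BACKBONE_NAMES else "sidechain"

    def identity(self) -> tuple:
        """Key used to compare atoms across models of a multi-model file."""
        return (self.name, self.residue_number, self.residue_name, self.chain_id)


@dataclass
class Trajectory:
    """Fixed topology + ``(T, n_atoms, 3)`` coordinates in Angstrom."""

    atoms: list[AtomRecord]
    coords: np.ndarray
    run_boundaries: np.ndarray = field(default_factory=lambda: np.array([0]))
    frame_dt: float | None = None  # ns per frame, optional metadata

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ContractError(
                f"coords must have shape (T, n_atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ContractError("a trajectory needs at least one frame")
        if self.coords.shape[1] != len(self.atoms):
            raise ContractError(
                f"{len(self.atoms)} atoms but frames carry "
                f"{self.coords.shape[1]} coordinates"
            )
        rb = np.asarray(self.run_boundaries, dtype=int)
        if rb.size == 0 or rb[0] != 0 or np.any(np.diff(rb) <= 0) or rb[-1] >= self.n_frames:
            raise ContractError(
                "run_boundaries must start at 0, be strictly increasing and "
                f"stay below T={self.n_frames}; got {rb.tolist()}"
            )
        self.run_boundaries = rb

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_numbers(self) -> np.ndarray:
        """Author residue numbers in order of first appearance."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_number, None)
        return np.array(list(seen), dtype=int)

    def runs(self) -> list[tuple[int, int]]:
        """Half-open ``[start, stop)`` frame ranges of the independent runs."""
        edges = list(self.run_boundaries) + [self.n_frames]
        return [(int(edges[i]), int(edges[i + 1])) for i in range(len(edges) - 1)]

    def atom_residue_numbers(self) -> np.ndarray:
        return np.array([a.residue_number for a in self.atoms], dtype=int)

    def residue_atom_indices(self) -> dict[int, np.ndarray]:
        """Atom indices grouped by residue number, order preserved."""
        groups: dict[int, list[int]] = {}
        for i, a in enumerate(self.atoms):
            groups.setdefault(a.residue_number, []).append(i)
        return {r: np.array(ix, dtype=int) for r, ix in groups.items()}


@dataclass(frozen=True)
class Selection:
    """A reproducible atom subset: residue range x atom class (x chain).

    ``residue_range=None`` means all residues.  ``atom_class`` is one of
    ``all``, ``heavy`` (element != H), ``backbone`` (N/CA/C/O) or
    ``sidechain`` (everything that is not backbone).
    """

    residue_range: tuple[int, int] | None = None
    atom_class: str = "all"
    chain_id: str | None = None

    _CLASSES = ("all", "heavy", "backbone", "sidechain")

    def __post_init__(self) -> None:
        if self.atom_class not in self._CLASSES:
            raise SelectionError(
                f"unknown atom_class {self.atom_class!r}; expected one of {self._CLASSES}"
            )
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if lo > hi:
                raise SelectionError(f"empty residue range [{lo}, {hi}]")

    def describe(self) -> str:
        rng = "all" if self.residue_range is None else f"{self.residue_range[0]}-{self.residue_range[1]}"
        chain = "" if self.chain_id is None else f"/chain {self.chain_id}"
        return f"residues {rng}, {self.atom_class}{chain}"

    def resolve(self, traj: Trajectory) -> np.ndarray:
        return resolve_selection(traj, self)


def resolve_selection(traj: Trajectory, sel: Selection) -> np.ndarray:
    """Deterministic, order-preserving atom indices of ``sel`` in ``traj``.

    An empty result is legal; downstream operations that cannot work with an
    empty selection are responsible for rejecting it.
    """
    out: list[int] = []
    lo, hi = sel.residue_range if sel.residue_range is not None else (None, None)
    for i, a in enumerate(traj.atoms):
        if sel.chain_id is not None and a.chain_id != sel.chain_id:
            continue
        if lo is not None and not (lo <= a.residue_number <= hi):
            continue
        if sel.atom_class == "heavy" and not a.is_heavy:
            continue
        if sel.atom_class in ("backbone", "sidechain") and a.role != sel.atom_class:
            continue
        out.append(i)
    return np.array(out, dtype=int)


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _infer_element(raw_element: str, atom_name: str) -> str:
    """Element from columns 77-78, falling back to the atom-name letters."""
    el = raw_element.strip().upper()
    if el:
        return el
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray]:
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0  # serial is metadata only; tolerate overflow markers
    name = line[12:16].strip()
    residue_name = line[17:20].strip()
    chain_id = line[21:22]
    try:
        residue_number = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: unparseable residue number") from exc
    try:
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])], dtype=float
        )
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: unparseable coordinate field") from exc
    element = _infer_element(line[76:78] if len(line) >= 78 else "", name)
    rec = AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_number=residue_number,
        residue_name=residue_name,
        chain_id=chain_id,
    )
    return rec, xyz


def read_pdb_models(
    path: str | Path,
    *,
    include_waters: bool = False,
    include_hetero: bool = False,
    run_boundaries: Sequence[int] | None = None,
    frame_dt: float | None = None,
) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    One frame per ``MODEL`` block; a file without ``MODEL`` records yields a
    single-frame trajectory.  Waters and HETATM records are dropped unless
    explicitly retained -- every in-scope analysis is protein-only.

    Raises :class:`TopologyMismatchError` naming the offending model when the
    models do not list the same atoms in the same order, and
    :class:`PDBParseError` with a line number for malformed records.
    """
    path = Path(path)
    frames: list[list[np.ndarray]] = []
    topologies: list[list[AtomRecord]] = []
    current_atoms: list[AtomRecord] | None = None
    current_xyz: list[np.ndarray] | None = None
    saw_model = False

    def _flush() -> None:
        nonlocal current_atoms, current_xyz
        if current_xyz is not None and len(current_xyz) > 0:
            topologies.append(current_atoms)
            frames.append(current_xyz)
        current_atoms, current_xyz = None, None

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6]
            if record.startswith("MODEL"):
                saw_model = True
                _flush()
                current_atoms, current_xyz = [], []
            elif record == "ENDMDL":
                _flush()
            elif record in ("ATOM  ", "HETATM"):
                rec, xyz = _parse_atom_line(line, lineno)
                if rec.residue_name in WATER_RESNAMES and not include_waters:
                    continue
                if record == "HETATM" and not include_hetero:
                    continue
                if current_xyz is None:
                    current_atoms, current_xyz = [], []
                current_atoms.append(rec)
                current_xyz.append(xyz)
    _flush()

    if not frames:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    if not saw_model and len(frames) > 1:  # pragma: no cover - defensive
        raise PDBParseError(f"{path}: multiple frames without MODEL records")

    ref_atoms = topologies[0]
    ref_identity = [a.identity() for a in ref_atoms]
    for m, atoms in enumerate(topologies[1:], start=2):
        if len(atoms) != len(ref_atoms):
            raise TopologyMismatchError(
                f"{path}: model {m} has {len(atoms)} atoms, model 1 has {len(ref_atoms)}"
            )
        ident = [a.identity() for a in atoms]
        if ident != ref_identity:
            k = next(i for i, (a, b) in enumerate(zip(ident, ref_identity)) if a != b)
            raise TopologyMismatchError(
                f"{path}: model {m} atom {k + 1} is {ident[k]}, model 1 has {ref_identity[k]}"
            )

    coords = np.array([np.vstack(f) for f in frames], dtype=float)
    rb = np.array([0]) if run_boundaries is None else np.asarray(run_boundaries, int)
    return Trajectory(atoms=list(ref_atoms), coords=coords, run_boundaries=rb, frame_dt=frame_dt)


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom_name(name: str) -> str:
    # Names shorter than 4 characters start in column 14 by convention.
    return f"{name:<4s}" if len(name) >= 4 else f" {name:<3s}"


def _format_atom_line(rec: AtomRecord, xyz: np.ndarray) -> str:
    x, y, z = (float(v) for v in xyz)
    for v in (x, y, z):
        if not (-999.999 <= v <= 9999.999):
            raise PDBFormatError(
                f"coordinate {v:.3f} does not fit the fixed-width PDB columns"
            )
    if not (-999 <= rec.residue_number <= 9999):
        raise PDBFormatError(f"residue number {rec.residue_number} does not fit PDB columns")
    return (
        f"ATOM  {rec.serial % 100000:5d} {_format_atom_name(rec.name)} "
        f"{rec.residue_name:>3s} {rec.chain_id:1s}{rec.residue_number:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{rec.element:>2s}\n"
    )


def write_pdb_models(traj: Trajectory, path: str | Path) -> Path:
    """Write ``traj`` as MODEL/ENDMDL-delimited PDB (3-decimal coordinates).

    Round-tripping through :func:`read_pdb_models` preserves atom identities
    exactly and coordinates to 0.001 A (the format precision).
    """
    path = Path(path)
    with path.open("w") as fh:
        for t in range(traj.n_frames):
            fh.write(f"MODEL     {t + 1:4d}\n")
            for rec, xyz in zip(traj.atoms, traj.coords[t]):
                fh.write(_format_atom_line(rec, xyz))
            fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


# ---------------------------------------------------------------------------
# Run manifests and frame windows
# ---------------------------------------------------------------------------

def read_run_manifest(path: str | Path) -> np.ndarray:
    """Plain-text run manifest: one frame index per line, first line 0."""
    values: list[int] = []
    for lineno, line in enumerate(Path(path).open(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            values.append(int(line))
        except ValueError as exc:
            raise PDBParseError(f"{path} line {lineno}: not an integer frame index") from exc
    if not values or values[0] != 0:
        raise PDBParseError(f"{path}: run manifest must start with frame index 0")
    return np.array(values, dtype=int)


def write_run_manifest(run_boundaries: Iterable[int], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{int(b)}\n" for b in run_boundaries))
    return path


def resolve_window(traj: Trajectory, window) -> np.ndarray:
    """Turn a window specifier into sorted frame indices.

    ``None``
        all frames.
    fraction ``f`` in ``(0, 1]`` (float)
        the trailing ``ceil(f * len(run))`` frames of each run, pooled -- the
        "last 100 ns of each 200 ns run" convention generalized.
    ``(start, stop)``
        a half-open frame interval.
    sequence of ints
        explicit frame indices.
    """
    T = traj.n_frames
    if window is None:
        return np.arange(T)
    if isinstance(window, float):
        if not (0.0 < window <= 1.0):
            raise ContractError(f"window fraction must be in (0, 1], got {window}")
        chunks = []
        for start, stop in traj.runs():
            k = int(np.ceil(window * (stop - start)))
            chunks.append(np.arange(stop - k, stop))
        return np.concatenate(chunks)
    if isinstance(window, tuple) and len(window) == 2:
        start, stop = int(window[0]), int(window[1])
        if not (0 <= start < stop <= T):
            raise ContractError(f"window [{start}, {stop}) outside [0, {T})")
        return np.arange(start, stop)
    idx = np.asarray(window, dtype=int)
    if idx.size == 0 or idx.min() < 0 or idx.max() >= T:
        raise ContractError(f"explicit window indices outside [0, {T}) or empty")
    return np.sort(idx)
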