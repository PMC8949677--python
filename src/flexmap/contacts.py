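"""Residue-residue contact ratios, WT-mutant difference maps, pair ranking.

A residue pair is "in contact" in a frame when *any* pair of their heavy
atoms is closer than the cutoff (strictly less than; default 4.5 A).  The
contact *ratio* of a pair is the fraction of analyzed frames in contact, and
the difference map subtracts the mutant's ratios from the wild type's, so a
positive entry marks a contact lost upon mutation.

Near-diagonal pairs (|i - j| < ``min_seq_sep``, default 2) are trivially in
contact through the chain and are *excluded* from the maps, flagged rather
than reported as 0-by-measurement.

Two interchangeable minimum-distance backends are provided: a cell-list
(k-d tree) path and an all-pairs brute-force path.  They must agree
bit-for-bit on the boolean contact matrix; the brute-force path doubles as
the in-package oracle.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import ContractError
from .structure_io import Trajectory, resolve_window

__all__ = [
    "ContactRatioMap",
    "ContactDiffMap",
    "ContactPair",
    "frame_contacts",
    "contact_residues",
    "contact_ratio_map",
    "diff_map",
    "top_pairs",
    "write_map_tsv",
    "read_map_tsv",
    "write_pairs_tsv",
]

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 4.5  # A; heavy-atom minimum-distance criterion
DEFAULT_MIN_SEQ_SEP = 2


def _heavy_index(traj: Trajectory) -> tuple[np.ndarray, list[np.ndarray]]:
    """Residue numbers (ordered) and per-residue heavy-atom index arrays.

    Residues with no heavy atoms are excluded with a logged warning.
    Duplicate residue numbers across chains are rejected: contact maps are
    labelled by author residue number alone.
    """
    groups: dict[int, list[int]] = {}
    seen_chain: dict[int, str] = {}
    for i, a in enumerate(traj.atoms):
        if seen_chain.setdefault(a.residue_number, a.chain_id) != a.chain_id:
            raise ContractError(
                f"residue number {a.residue_number} appears in more than one chain; "
                "restrict the trajectory to a single chain first"
            )
        if a.is_heavy:
            groups.setdefault(a.residue_number, []).append(i)
        else:
            groups.setdefault(a.residue_number, groups.get(a.residue_number, []))
    residues, blocks = [], []
    for r, ix in groups.items():
        if not ix:
            warnings.warn(
                f"residue {r} has no heavy atoms and is excluded from contact maps",
                stacklevel=2,
            )
            continue
        residues.append(r)
        blocks.append(np.array(ix, dtype=int))
    return np.array(residues, dtype=int), blocks


def contact_residues(traj: Trajectory) -> np.ndarray:
    """Residue numbers that participate in contact maps for ``traj``."""
    residues, _ = _heavy_index(traj)
    return residues


def _excluded_mask(residues: np.ndarray, min_seq_sep: int) -> np.ndarray:
    sep = np.abs(residues[:, None] - residues[None, :])
    return sep < min_seq_sep


def _contacts_kdtree(
    frame: np.ndarray,
    residues: np.ndarray,
    blocks: list[np.ndarray],
    cutoff: float,
    min_seq_sep: int,
) -> np.ndarray:
    heavy = np.concatenate(blocks)
    res_pos = np.concatenate([np.full(b.size, k) for k, b in enumerate(blocks)])
    pts = frame[heavy]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    R = residues.size
    out = np.zeros((R, R), dtype=bool)
    if pairs.size:
        d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        strict = pairs[d < cutoff]  # "less than": the boundary itself is no contact
        ri, rj = res_pos[strict[:, 0]], res_pos[strict[:, 1]]
        keep = np.abs(residues[ri] - residues[rj]) >= min_seq_sep
        out[ri[keep], rj[keep]] = True
        out[rj[keep], ri[keep]] = True
    return out


def _contacts_brute(
    frame: np.ndarray,
    residues: np.ndarray,
    blocks: list[np.ndarray],
    cutoff: float,
    min_seq_sep: int,
) -> np.ndarray:
    R = residues.size
    out = np.zeros((R, R), dtype=bool)
    for i in range(R):
        for j in range(i + 1, R):
            if abs(int(residues[i]) - int(residues[j])) < min_seq_sep:
                continue
            dmin = cdist(frame[blocks[i]], frame[blocks[j]]).min()
            if dmin < cutoff:
                out[i, j] = out[j, i] = True
    return out


def frame_contacts(
    traj: Trajectory,
    frame_index: int = 0,
    cutoff: float = DEFAULT_CUTOFF,
    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP,
    method: str = "kdtree",
) -> np.ndarray:
    """Symmetric boolean residue-pair contact matrix for one frame.

    Rows/columns follow :func:`contact_residues`.  ``method`` selects the
    k-d tree path or the all-pairs brute-force oracle; the results are
    identical by contract.
    """
    if cutoff <= 0:
        raise ContractError(f"cutoff must be positive, got {cutoff}")
    residues, blocks = _heavy_index(traj)
    if residues.size < 2:
        raise ContractError("contact analysis needs at least 2 residues with heavy atoms")
    frame = traj.coords[frame_index]
    fn = {"kdtree": _contacts_kdtree, "brute": _contacts_brute}[method]
    return fn(frame, residues, blocks, cutoff, min_seq_sep)


@dataclass
class ContactRatioMap:
    """R x R matrix of per-residue-pair contact frequencies in [0, 1]."""

    residue_numbers: np.ndarray
    ratio: np.ndarray
    cutoff: float
    min_seq_sep: int
    n_frames: int
    excluded: np.ndarray = field(default=None)  # True where |i-j| < min_seq_sep
    label: str = ""

    def __post_init__(self) -> None:
        if self.excluded is None:
            self.excluded = _excluded_mask(np.asarray(self.residue_numbers), self.min_seq_sep)
        measured = self.ratio[~self.excluded]
        if measured.size and (measured.min() < 0 or measured.max() > 1):
            raise ContractError("contact ratios outside [0, 1]")
        if not np.allclose(self.ratio, self.ratio.T):
            raise ContractError("contact ratio matrix is not symmetric")

    def pair_ratio(self, res_i: int, res_j: int) -> float:
        i = int(np.flatnonzero(self.residue_numbers == res_i)[0])
        j = int(np.flatnonzero(self.residue_numbers == res_j)[0])
        return float(self.ratio[i, j])


def contact_ratio_map(
    traj: Trajectory,
    cutoff: float = DEFAULT_CUTOFF,
    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP,
    window=None,
    method: str = "kdtree",
    label: str = "",
) -> ContactRatioMap:
    """Fraction of window frames in contact, per residue pair.

    A trailing per-run fraction window pools the last frames of each run
    before counting (the "last 100 ns of all runs" convention).
    """
    if cutoff <= 0:
        raise ContractError(f"cutoff must be positive, got {cutoff}")
    residues, blocks = _heavy_index(traj)
    frames = resolve_window(traj, window)
    if frames.size < 1:
        raise ContractError("empty frame window")
    fn = {"kdtree": _contacts_kdtree, "brute": _contacts_brute}[method]
    counts = np.zeros((residues.size, residues.size), dtype=np.int64)
    for t in frames:
        counts += fn(traj.coords[t], residues, blocks, cutoff, min_seq_sep)
    ratio = counts / float(frames.size)
    return ContactRatioMap(
        residue_numbers=residues,
        ratio=ratio,
        cutoff=cutoff,
        min_seq_sep=min_seq_sep,
        n_frames=int(frames.size),
        label=label,
    )


@dataclass
class ContactDiffMap:
    """WT minus mutant contact-ratio difference; positive = lost in mutant."""

    residue_numbers: np.ndarray
    delta: np.ndarray
    excluded: np.ndarray
    provenance: tuple[str, str]
    cutoff: float
    min_seq_sep: int
    wt_ratio: np.ndarray = None
    mut_ratio: np.ndarray = None


def diff_map(wt: ContactRatioMap, mut: ContactRatioMap) -> ContactDiffMap:
    """Elementwise ``wt.ratio - mut.ratio`` with compatibility checks."""
    if not np.array_equal(wt.residue_numbers, mut.residue_numbers):
        raise ContractError("contact maps cover different residue sets")
    if wt.cutoff != mut.cutoff or wt.min_seq_sep != mut.min_seq_sep:
        raise ContractError(
            f"contact maps computed with different parameters: "
            f"cutoff {wt.cutoff} vs {mut.cutoff}, "
            f"min_seq_sep {wt.min_seq_sep} vs {mut.min_seq_sep}"
        )
    return ContactDiffMap(
        residue_numbers=wt.residue_numbers.copy(),
        delta=wt.ratio - mut.ratio,
        excluded=wt.excluded | mut.excluded,
        provenance=(wt.label or "wt", mut.label or "mut"),
        cutoff=wt.cutoff,
        min_seq_sep=wt.min_seq_sep,
        wt_ratio=wt.ratio.copy(),
        mut_ratio=mut.ratio.copy(),
    )


@dataclass(frozen=True)
class ContactPair:
    """One ranked residue pair of a difference map (i < j)."""

    residue_i: int
    residue_j: int
    delta: float
    wt_ratio: float
    mut_ratio: float


def top_pairs(d: ContactDiffMap, k: int, direction: str = "lost") -> list[ContactPair]:
    """Rank unordered residue pairs of a difference map.

    ``lost`` ranks by descending delta (contacts present in WT, gone in the
    mutant), ``gained`` by ascending delta, ``abs`` by descending |delta|.
    Ties break lexicographically on ``(residue_i, residue_j)``.
    """
    if k < 1:
        raise ContractError(f"k must be >= 1, got {k}")
    if direction not in ("lost", "gained", "abs"):
        raise ContractError(f"unknown direction {direction!r}")
    keyfun = {
        "lost": lambda dv: -dv,
        "gained": lambda dv: dv,
        "abs": lambda dv: -abs(dv),
    }[direction]
    entries = []
    R = d.residue_numbers.size
    for i in range(R):
        for j in range(i + 1, R):
            if d.excluded[i, j]:
                continue
            dv = float(d.delta[i, j])
            ri, rj = int(d.residue_numbers[i]), int(d.residue_numbers[j])
            entries.append(
                (
                    (keyfun(dv), ri, rj),
                    ContactPair(
                        residue_i=ri,
                        residue_j=rj,
                        delta=dv,
                        wt_ratio=float(d.wt_ratio[i, j]) if d.wt_ratio is not None else float("nan"),
                        mut_ratio=float(d.mut_ratio[i, j]) if d.mut_ratio is not None else float("nan"),
                    ),
                )
            )
    if k > len(entries):
        logger.info("requested top %d pairs but only %d available; returning all", k, len(entries))
        k = len(entries)
    return [pair for _, pair in heapq.nsmallest(k, entries, key=lambda e: e[0])]


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def _write_matrix(
    fh, residues: np.ndarray, matrix: np.ndarray, excluded: np.ndarray
) -> None:
    fh.write("residue\t" + "\t".join(str(int(r)) for r in residues) + "\n")
    for i, r in enumerate(residues):
        cells = [
            "NA" if excluded[i, j] else f"{matrix[i, j]:.6g}"
            for j in range(residues.size)
        ]
        fh.write(f"{int(r)}\t" + "\t".join(cells) + "\n")


def write_map_tsv(m: ContactRatioMap | ContactDiffMap, path: str | Path, meta: dict | None = None) -> Path:
    """Write a ratio or difference map as a TSV matrix; excluded cells as NA."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key} = {val}\n")
        fh.write(f"# cutoff = {m.cutoff}\n")
        fh.write(f"# min_seq_sep = {m.min_seq_sep}\n")
        if isinstance(m, ContactRatioMap):
            fh.write(f"# n_frames = {m.n_frames}\n")
            if m.label:
                fh.write(f"# label = {m.label}\n")
            _write_matrix(fh, m.residue_numbers, m.ratio, m.excluded)
        else:
            fh.write(f"# provenance = {m.provenance[0]} - {m.provenance[1]}\n")
            _write_matrix(fh, m.residue_numbers, m.delta, m.excluded)
    return path


def read_map_tsv(path: str | Path) -> ContactRatioMap:
    """Read a contact-ratio map written by :func:`write_map_tsv`."""
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    header: list[str] | None = None
    for line in Path(path).open():
        line = line.rstrip("\n")
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
            continue
        cells = line.split("\t")
        if header is None:
            header = cells
        else:
            rows.append(cells)
    if header is None or not rows:
        raise ContractError(f"{path}: not a contact-map TSV")
    residues = np.array([int(c) for c in header[1:]], dtype=int)
    ratio = np.zeros((residues.size, residues.size))
    excluded = np.zeros_like(ratio, dtype=bool)
    for i, cells in enumerate(rows):
        for j, c in enumerate(cells[1:]):
            if c == "NA":
                excluded[i, j] = True
            else:
                ratio[i, j] = float(c)
    return ContactRatioMap(
        residue_numbers=residues,
        ratio=ratio,
        cutoff=float(meta.get("cutoff", DEFAULT_CUTOFF)),
        min_seq_sep=int(meta.get("min_seq_sep", DEFAULT_MIN_SEQ_SEP)),
        n_frames=int(meta.get("n_frames", 0)),
        excluded=excluded,
        label=meta.get("label", ""),
    )


def write_pairs_tsv(pairs: list[ContactPair], path: str | Path, meta: dict | None = None) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key} = {val}\n")
        fh.write("residue_i\tresidue_j\twt_ratio\tmut_ratio\tdelta\n")
        for p in pairs:
            fh.write(
                f"{p.residue_i}\t{p.residue_j}\t{p.wt_ratio:.6g}\t{p.mut_ratio:.6g}\t{p.delta:.6g}\n"
            )
    return path
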