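"""Shrake-Rupley solvent-accessible surface area and trace correlation.

SASA is computed by point quadrature: each reported atom carries a
deterministic generalized-spiral (Fibonacci) lattice of ``n_points`` on the
sphere of radius ``r_vdw + probe``; a lattice point is accessible iff it lies
strictly outside every other context atom's probe-expanded sphere, and the
atom contributes ``4 pi (r_vdw + probe)^2`` times its accessible fraction.
The deterministic lattice (instead of random sampling) makes traces
bit-reproducible.

By default only protein heavy atoms occlude -- consistent with the
heavy-atom contact convention; a flag includes hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .errors import ConstantSeriesError, ContractError, SelectionError
from .structure_io import Selection, Trajectory, resolve_window

__all__ = [
    "RadiiTable",
    "SASATrace",
    "CorrelationReport",
    "fibonacci_sphere",
    "shrake_rupley_frame",
    "sasa_trace",
    "correlate_traces",
    "write_sasa_tsv",
    "write_correlation_tsv",
]

#: Bondi-style van der Waals radii (A); anything absent falls back to 1.70.
DEFAULT_RADII: Mapping[str, float] = MappingProxyType(
    {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
)


@dataclass(frozen=True)
class RadiiTable:
    """Element -> vdW radius mapping, total via a fallback radius."""

    radii: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    probe_radius: float = 1.4
    default_radius: float = 1.70

    def __post_init__(self) -> None:
        if self.probe_radius < 0 or self.default_radius <= 0:
            raise ContractError("probe and fallback radii must be positive")
        if any(r <= 0 for r in self.radii.values()):
            raise ContractError("all van der Waals radii must be positive")

    def radius(self, element: str) -> float:
        return float(self.radii.get(element, self.default_radius))

    def expanded(self, elements) -> np.ndarray:
        """Probe-expanded radii ``r_vdw + probe`` for a list of elements."""
        return np.array([self.radius(e) + self.probe_radius for e in elements])


def _canonical_axes(report_pos: np.ndarray) -> np.ndarray:
    """Rotation-equivariant orthonormal frame of the reported atoms.

    Principal axes of the centered report positions, signs fixed by the
    third moment of the projections (a rotation-invariant quantity),
    handedness enforced.  Evaluating the quadrature lattice in this frame
    makes the SASA of a generic (>= 3 atom, non-degenerate) report set
    *exactly* invariant under rigid motion of the whole structure, instead
    of invariant only up to quadrature error.  Deriving the frame from the
    report atoms alone (never the occluding context) keeps another exact
    property: growing the context can only remove accessible lattice
    points, so adding an occluder never increases any atom's SASA.  For
    degenerate report sets (single atoms, symmetric clouds) the axes are
    arbitrary but deterministic, and any orthonormal lattice orientation is
    an equally valid quadrature.
    """
    X = report_pos - report_pos.mean(axis=0)
    _, V = np.linalg.eigh(X.T @ X)
    V = V[:, ::-1]  # descending variance
    skew = np.einsum("ij->j", (X @ V) ** 3)
    for k in range(3):
        if skew[k] < 0:
            V[:, k] *= -1
    if np.linalg.det(V) < 0:
        V[:, int(np.argmin(np.abs(skew)))] *= -1
    return V


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (generalized spiral)."""
    if n_points < 1:
        raise ContractError("n_points must be positive")
    i = np.arange(n_points)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley_frame(
    coords: np.ndarray,
    elements,
    report_indices,
    context_indices=None,
    radii: RadiiTable | None = None,
    n_points: int = 960,
    return_per_atom: bool = False,
):
    """SASA (A^2) of the reported atoms within the occluding context.

    ``coords`` is an ``(n_atoms, 3)`` frame, ``elements`` the matching element
    symbols.  ``context_indices`` defaults to all atoms; reported atoms are
    always part of the context.  Coincident atoms occlude each other fully
    (no division by zero).
    """
    radii = radii if radii is not None else RadiiTable()
    if n_points < 32:
        raise ContractError(f"n_points must be >= 32, got {n_points}")
    coords = np.asarray(coords, dtype=float)
    report = np.asarray(report_indices, dtype=int)
    if report.size == 0:
        raise SelectionError("SASA requested for an empty report selection")
    if context_indices is None:
        context = np.arange(coords.shape[0])
    else:
        context = np.union1d(np.asarray(context_indices, dtype=int), report)
    elements = list(elements)
    ctx_pos = coords[context]
    ctx_r = radii.expanded(elements[i] for i in context)
    r_max = float(ctx_r.max())
    tree = cKDTree(ctx_pos)
    pos_in_context = {int(a): k for k, a in enumerate(context)}
    unit = fibonacci_sphere(n_points) @ _canonical_axes(coords[report]).T

    per_atom = np.zeros(report.size)
    for out_i, a in enumerate(report):
        center = coords[a]
        ra = radii.radius(elements[a]) + radii.probe_radius
        pts = center + ra * unit
        neigh = tree.query_ball_point(center, ra + r_max)
        neigh = [k for k in neigh if k != pos_in_context[int(a)]]
        if neigh:
            occ_pos = ctx_pos[neigh]
            occ_r2 = ctx_r[neigh] ** 2
            d2 = ((pts[:, None, :] - occ_pos[None, :, :]) ** 2).sum(axis=2)
            # small slack so exactly coincident/tangent spheres occlude fully
            accessible = np.all(d2 > occ_r2[None, :] + 1e-9, axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        per_atom[out_i] = 4.0 * np.pi * ra * ra * frac
    if return_per_atom:
        return per_atom
    return float(per_atom.sum())


@dataclass
class SASATrace:
    """Per-frame SASA (A^2) of a selection, with run boundaries."""

    frame_indices: np.ndarray
    sasa: np.ndarray
    selection: Selection
    run_boundaries: np.ndarray

    def __post_init__(self) -> None:
        if len(self.frame_indices) != len(self.sasa):
            raise ContractError("trace lengths differ")
        if np.any(np.asarray(self.sasa) < 0):  # pragma: no cover - defensive
            raise ContractError("negative SASA")


def sasa_trace(
    traj: Trajectory,
    report_sel: Selection,
    radii: RadiiTable | None = None,
    n_points: int = 960,
    window=None,
    context_sel: Selection | None = None,
    include_hydrogens: bool = False,
) -> SASATrace:
    """Per-frame Shrake-Rupley SASA of ``report_sel``.

    The occluding context defaults to all protein heavy atoms.  Hydrogens are
    excluded from both report and context unless ``include_hydrogens``.
    """
    radii = radii if radii is not None else RadiiTable()
    report = report_sel.resolve(traj)
    if not include_hydrogens:
        report = np.array([i for i in report if traj.atoms[i].is_heavy], dtype=int)
    if report.size == 0:
        raise SelectionError(f"report selection ({report_sel.describe()}) has no atoms")
    if context_sel is None:
        context_sel = Selection(atom_class="all" if include_hydrogens else "heavy")
    context = context_sel.resolve(traj)
    elements = [a.element for a in traj.atoms]
    frames = resolve_window(traj, window)
    values = np.empty(frames.size)
    for k, t in enumerate(frames):
        values[k] = shrake_rupley_frame(
            traj.coords[t], elements, report, context, radii=radii, n_points=n_points
        )
    return SASATrace(
        frame_indices=frames,
        sasa=values,
        selection=report_sel,
        run_boundaries=traj.run_boundaries.copy(),
    )


# ---------------------------------------------------------------------------
# Trace correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunCorrelation:
    run: int
    r: float | None  # None when the segment is degenerate (constant)
    n: int


@dataclass
class CorrelationReport:
    method: str
    r: float
    n: int
    per_run: list[RunCorrelation] | None = None


def _check_series(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError("series must be 1-D and of equal length")
    if a.size < 3:
        raise ContractError("correlation needs at least 3 points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConstantSeriesError(
            "correlation is undefined for a constant series; "
            "the input shows no variation"
        )


def _coefficient(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ContractError(f"unknown correlation method {method!r}")


def correlate_traces(
    a,
    b,
    method: str = "pearson",
    per_run: bool = False,
    run_boundaries=None,
) -> CorrelationReport:
    """Pooled (and optionally per-run) correlation of two per-frame series.

    A constant input series raises :class:`ConstantSeriesError` rather than
    silently reporting 0; degenerate *segments* in the per-run breakdown are
    reported with ``r = None``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_series(a, b)
    report = CorrelationReport(method=method, r=_coefficient(a, b, method), n=int(a.size))
    if per_run:
        if run_boundaries is None:
            raise ContractError("per_run correlation needs run_boundaries")
        edges = list(np.asarray(run_boundaries, int)) + [a.size]
        runs = []
        for k in range(len(edges) - 1):
            seg = slice(edges[k], edges[k + 1])
            n = edges[k + 1] - edges[k]
            if n < 3 or np.ptp(a[seg]) == 0 or np.ptp(b[seg]) == 0:
                runs.append(RunCorrelation(run=k, r=None, n=n))
            else:
                runs.append(RunCorrelation(run=k, r=_coefficient(a[seg], b[seg], method), n=n))
        report.per_run = runs
    return report


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------

def write_sasa_tsv(trace: SASATrace, path: str | Path, meta: dict | None = None) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key} = {val}\n")
        fh.write(f"# selection = {trace.selection.describe()}\n")
        fh.write(f"# run_boundaries = {','.join(str(int(b)) for b in trace.run_boundaries)}\n")
        fh.write("frame_index\tsasa_A2\n")
        for t, s in zip(trace.frame_indices, trace.sasa):
            fh.write(f"{int(t)}\t{s:.6g}\n")
    return path


def write_correlation_tsv(
    reports: Mapping[str, CorrelationReport | None], path: str | Path, meta: dict | None = None
) -> Path:
    """One row per (labelled) report: pooled first, then per-run segments."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key} = {val}\n")
        fh.write("label\tsegment\tmethod\tr\tn\n")
        for label, rep in reports.items():
            if rep is None:
                fh.write(f"{label}\tpooled\tNA\tNA\t0\n")
                continue
            fh.write(f"{label}\tpooled\t{rep.method}\t{rep.r:.6g}\t{rep.n}\n")
            for rc in rep.per_run or []:
                rtxt = "NA" if rc.r is None else f"{rc.r:.6g}"
                fh.write(f"{label}\trun{rc.run}\t{rep.method}\t{rtxt}\t{rc.n}\n")
    return path
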