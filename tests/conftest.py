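"""Shared fixtures: hand-built micro-trajectories and the seeded demo pair."""

from __future__ import annotations

import numpy as np
import pytest

from flexmap import SyntheticSpec, Trajectory, gen_ensemble
from flexmap.structure_io import AtomRecord
from flexmap.synthetic import gen_toy_structure, demo_specs


def build_trajectory(atom_spec, frames, run_boundaries=(0,)) -> Trajectory:
    """Build a Trajectory from ``(name, element, resnum, resname)`` tuples and
    a list/array of per-frame coordinate sets."""
    atoms = [
        AtomRecord(
            serial=i + 1,
            name=name,
            element=element,
            residue_number=resnum,
            residue_name=resname,
            chain_id="A",
        )
        for i, (name, element, resnum, resname) in enumerate(atom_spec)
    ]
    return Trajectory(
        atoms=atoms, coords=np.asarray(frames, float), run_boundaries=np.array(run_boundaries)
    )


@pytest.fixture
def two_residue_factory():
    """Two single-heavy-atom residues at a controllable separation."""

    def make(distance: float, resnums=(201, 210)) -> Trajectory:
        spec = [("CA", "C", resnums[0], "ALA"), ("CA", "C", resnums[1], "ALA")]
        frames = [[[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]]
        return build_trajectory(spec, frames)

    return make


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticSpec:
    return SyntheticSpec(n_residues=20, first_residue=201, n_frames=10, n_runs=2, seed=42)


@pytest.fixture(scope="session")
def toy_structure(tiny_spec):
    return gen_toy_structure(tiny_spec)


@pytest.fixture(scope="session")
def demo_pair():
    """Full-size seeded WT/mutant demonstration ensembles with ground truth."""
    wt_spec, mut_spec = demo_specs(seed=0)
    wt, wt_truth = gen_ensemble(wt_spec)
    mut, mut_truth = gen_ensemble(mut_spec)
    reference = gen_toy_structure(wt_spec).coords[0]
    return {
        "wt_spec": wt_spec,
        "mut_spec": mut_spec,
        "wt": wt,
        "mut": mut,
        "wt_truth": wt_truth,
        "mut_truth": mut_truth,
        "reference": reference,
    }
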