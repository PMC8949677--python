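#!/usr/bin/env python
"""Generate the seeded wild-type / mutant-like conformational ensembles.

Writes the two multi-model PDB ensembles (10 runs x 200 frames each), their
run-boundary manifests, the extended-chain reference structure, and the
machine-readable ground truth (planted contact occupancies, per-frame
N-terminal displacement, planted exposure coupling) that scripts 02-04
check their recoveries against.

Large trajectory files go to scratch/sim/; ground-truth tables to results/.
"""

import argparse
from pathlib import Path

import flexmap as fm
from flexmap.synthetic import gen_toy_structure, demo_specs, write_truth_tsv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    sim = ROOT / "scratch" / "sim"
    res = ROOT / "results"
    sim.mkdir(parents=True, exist_ok=True)
    res.mkdir(parents=True, exist_ok=True)

    wt_spec, mut_spec = demo_specs(args.seed)
    fm.write_pdb_models(gen_toy_structure(wt_spec), sim / "reference.pdb")
    for label, spec in (("wt", wt_spec), ("mut", mut_spec)):
        traj, truth = fm.gen_ensemble(spec)
        fm.write_pdb_models(traj, sim / f"{label}.pdb")
        fm.write_run_manifest(traj.run_boundaries, sim / f"{label}_runs.txt")
        write_truth_tsv(truth, res / f"ground_truth_{label}.tsv")
        print(
            f"{label}: {traj.n_frames} frames, {traj.n_atoms} atoms, "
            f"{len(traj.runs())} runs -> {sim / (label + '.pdb')}"
        )
        if truth.two_state is not None:
            for p, q in zip(truth.two_state.pairs, truth.two_state.realized_occupancy):
                print(f"  planted contact {p.residue_i}-{p.residue_j}: p = {p.occupancy}, realized {q:.3f}")
    print(f"ground truth written to {res}/")


if __name__ == "__main__":
    main()
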