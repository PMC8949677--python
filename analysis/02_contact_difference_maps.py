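#!/usr/bin/env python
"""Contact-ratio maps, the WT-minus-mutant difference, and lost contacts.

Reads the ensembles written by 01_simulate_ensembles.py, computes windowed
(last 50% of each run) heavy-atom contact-ratio maps at the 4.5 A cutoff,
subtracts mutant from wild type, and ranks the lost residue pairs.  The top
five ranked pairs should be exactly the five planted ones.
"""

import argparse
from pathlib import Path

import flexmap as fm
from flexmap.contacts import write_map_tsv, write_pairs_tsv
from flexmap.pipeline import load_trajectory

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cutoff", type=float, default=4.5)
    args = ap.parse_args()

    sim = ROOT / "scratch" / "sim"
    res = ROOT / "results"
    if not (sim / "wt.pdb").exists():
        raise SystemExit("run analysis/01_simulate_ensembles.py first")

    maps = {}
    for label in ("wt", "mut"):
        traj = load_trajectory(sim / f"{label}.pdb", sim / f"{label}_runs.txt")
        maps[label] = fm.contact_ratio_map(traj, cutoff=args.cutoff, window=0.5, label=label)
        write_map_tsv(maps[label], res / f"contact_ratio_{label}.tsv")

    d = fm.diff_map(maps["wt"], maps["mut"])
    write_map_tsv(d, res / "contact_diff.tsv")
    pairs = fm.top_pairs(d, k=5, direction="lost")
    write_pairs_tsv(pairs, res / "top_pairs.tsv")

    print(f"cutoff {args.cutoff} A, window = trailing 50% of each run")
    print("top lost contacts (WT ratio -> mutant ratio):")
    for p in pairs:
        print(
            f"  {p.residue_i}-{p.residue_j}: {p.wt_ratio:.3f} -> {p.mut_ratio:.3f} "
            f"(delta {p.delta:+.3f})"
        )
    print(f"tables written to {res}/")


if __name__ == "__main__":
    main()
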