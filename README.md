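# flexmap

Post-analysis of protein conformational ensembles for wild-type / mutant
contrasts: residue-contact ratio maps and their WT − mutant difference,
windowed backbone RMSF, partial-fit fluctuation of a flexible segment, and
Shrake–Rupley solvent-accessible surface area (SASA) traces correlated with
that fluctuation.

The package grew out of a concrete structural question: how a single
point mutation in the POU-homeodomain (POUh) of the transcription factor
HNF1A — V259F, found in liver-cancer genomes — destabilizes the domain's
N-terminal arm (residues 201–206) and thereby its DNA binding.  The analyses
needed to make that argument from molecular-dynamics ensembles are general,
so they are packaged here as a reusable library + CLI, together with a
synthetic-ensemble generator that plants every signal with known ground
truth so the whole pipeline is falsifiable without an MD engine.

## What it computes

For two ensembles (e.g. WT and mutant) of the same topology, read from
multi-model PDB files with a run-boundary manifest:

* **Contact-ratio maps.**  Residues *i*, *j* are in contact in a frame when
  any pair of their heavy atoms is closer than a cutoff (default 4.5 Å,
  strict `<`).  The ratio map entry is the fraction of analyzed frames in
  contact, pooled over the trailing fraction of each independent run
  (default: last 50%).  The difference map Δ = r_WT − r_mut is positive
  where a contact is *lost* in the mutant; `top_pairs` ranks the losses.
* **RMSF.**  Frames are Kabsch-superposed on a fit selection onto the
  window-mean structure; per-atom RMSF is the RMS deviation from the mean
  position, aggregated per residue.
* **Partial-fit fluctuation.**  Each frame is superposed on a rigid *core*
  selection (backbone 207–278) against a reference structure; the RMSD of a
  disjoint *report* selection (backbone 201–206) is measured under that same
  transform, isolating the flexible segment's motion as a per-frame trace.
* **SASA.**  Shrake–Rupley point quadrature with a deterministic Fibonacci
  lattice (default 960 points, probe 1.4 Å, Bondi-style radii); per-frame
  traces of any selection, e.g. the sidechain of residue 259.
* **Trace correlation.**  Pearson/Spearman between the SASA trace and the
  N-terminal displacement trace, pooled and per run.

## Worked example

The four scripts under `analysis/` run the whole study on synthetic
ensembles (78 residues numbered 201–278, 10 independent runs × 200 frames
per ensemble) in which the generator plants: five contacts held 90% of the
time in the WT but 5% in the mutant, a quiet vs. strongly displaced
N-terminal arm, and a mutant-only coupling (ρ = 0.8) between the probe
sidechain's exposure and the N-terminal displacement.

```sh
python analysis/01_simulate_ensembles.py --seed 1
python analysis/02_contact_difference_maps.py
python analysis/03_backbone_fluctuation.py
python analysis/04_sasa_fluctuation_coupling.py
```

prints, among other things:

```
top lost contacts (WT ratio -> mutant ratio):
  237-257: 0.910 -> 0.054 (delta +0.856)
  203-256: 0.904 -> 0.050 (delta +0.854)
  259-264: 0.902 -> 0.048 (delta +0.854)
  237-258: 0.899 -> 0.050 (delta +0.849)
  205-256: 0.898 -> 0.050 (delta +0.848)
RMSF excess (mutant - WT): N-terminal 201-206 min 0.432 A; elsewhere max |excess| 0.121 A
wt:  mean sidechain SASA 66.5 A^2, SASA-fluctuation r = -0.008
mut: mean sidechain SASA 90.6 A^2, SASA-fluctuation r = +0.798
```

i.e. the ranking recovers exactly the five planted lost contacts at their
planted occupancy contrast, the mutant's extra flexibility is confined to
the N-terminal segment, and the planted exposure–fluctuation coupling
(0.8) is recovered in the mutant ensemble only.  Tables land in
`results/`, trajectories in `scratch/sim/`.

The same workflow is available as a CLI on any trajectory pair:

```sh
flexmap simulate --preset pouh-demo --seed 1 --out-dir demo_data
flexmap run --wt demo_data/wt.pdb --mut demo_data/mut.pdb \
            --reference demo_data/reference.pdb \
            --wt-runs demo_data/wt_runs.txt --mut-runs demo_data/mut_runs.txt \
            --out-dir results
```

with per-stage subcommands (`contacts`, `diffmap`, `rmsf`, `nterm-fluct`,
`sasa`, `correlate`) for scripting.  Every output TSV embeds the effective
configuration; identical inputs and configuration reproduce byte-identical
bundles.

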