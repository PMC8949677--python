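# Methods

This note records the conventions, defaults and numerical choices behind
each analysis, what the synthetic generator does and does not emulate, and
the design decisions taken where more than one reasonable convention exists.

## Trajectory model and selections

A trajectory is a fixed atom topology plus `T` coordinate frames in Å and a
list of frame indices marking the start of each independent run.  The
canonical on-disk form is multi-model PDB (one `MODEL` block per frame) plus
a plain-text run manifest (one frame index per line, starting at 0).  Binary
MD formats are deliberately not parsed; an adapter only needs to produce the
in-memory trajectory to use every analysis.  Multi-model PDB keeps fixtures
diffable, text-only and desk-scale, which matters more here than
compactness.

Residues are addressed by author numbers throughout (the POUh domain of
HNF1A spans 201–278; the probe residue is 259; the recognition helix is
260–274), never re-indexed from zero.  Selections are residue-range ×
atom-class: `backbone` is exactly {N, CA, C, O}, `sidechain` is every other
atom of the residue (so glycine has an empty sidechain and an amide
hydrogen, when present, classes as sidechain — the two classes partition a
residue exactly), `heavy` is element ≠ H.  Elements come from PDB columns
77–78, falling back to the first alphabetic character of the atom name.
Waters and HETATM records are dropped on read by default (flags retain
them): every analysis here is protein-only.  One known divergence from the
original workflow this reproduces: simulation systems may retain crystal
waters near the domain, and a water-aware SASA could differ slightly from
the protein-only SASA computed here.

Frame windows come in three forms: all frames, an explicit `[start, stop)`
interval, or a trailing per-run fraction `f` that pools the last
`ceil(f·len(run))` frames of each run — the generalization of "analyze the
last 100 ns of each 200 ns run", giving `f = 0.5` as the default analysis
window.

## Superposition, RMSF, partial-fit fluctuation

Rigid-body fits use the Kabsch algorithm via SVD of the cross-covariance of
the centered point sets, with the smallest singular vector sign-corrected so
the rotation is always proper (no reflections).  Fewer than 3 points, or
point sets of rank < 2 after centering (collinear), raise an error rather
than returning an ill-defined fit.

RMSF follows the standard convention: frames in the window are superposed
on the fit selection onto the *window-mean* structure (obtained by a short
fixed-point iteration: fit to the first frame, re-fit to the running mean
twice — further iterations change nothing at these noise levels), and
per-atom RMSF is the RMS deviation from the mean fitted position.  An
optional reference structure replaces the mean as the fit target for
workflows that need a crystal-frame fit.  Per-residue values are the root
of the mean squared atomic RMSF over the residue's reported atoms; no mass
weighting (deterministic, and all reported selections are single-element
backbone sets in practice).

The partial fit is the load-bearing trick for flexible-segment analysis:
each frame is superposed on the *core* selection only (backbone 207–278
against the reference), the residual over the core is reported as
`core_rmsd`, and the RMSD of the disjoint *report* selection (backbone
201–206) from its reference positions is evaluated **under that same
transform** — no re-fit on the report atoms.  The fit and report selections
must be disjoint at residue level; overlap is rejected.  The per-frame
displacement trace is the primary output; a windowed RMS summary is exposed
alongside it since a published "fluctuation" curve could be either reading.

## Contacts

A residue pair is in contact in a frame when the minimum heavy-atom
distance is strictly below the cutoff.  The default cutoff is 4.5 Å, the
value used by the workflow this reproduces; a 4 Å convention also circulates
for the same kind of analysis, so the cutoff is an explicit `--cutoff`
option rather than a silently resolved constant.  Strict inequality at the boundary is a
measure-zero choice fixed for determinism.  Contact is binary per frame
(an existence criterion over atom pairs), not an atom-pair count.

Pairs with |i − j| < `min_seq_sep` (default 2, i.e. self and sequence
neighbours) are *excluded* — flagged and written as `NA`, never reported as
a measured 0 — because chain-adjacent residues are trivially always in
contact and would dominate any map.  All reported lost pairs in the
motivating study have separation ≥ 5, so the default cannot affect that
ranking.

Two minimum-distance backends exist: a k-d tree path (`scipy.spatial.cKDTree`)
and an all-pairs brute-force path kept as the in-package oracle; they are
required (and tested) to agree bit-for-bit on the boolean matrix.  The
difference map is WT − mutant, so positive entries mark contacts lost upon
mutation; ranking ties break lexicographically on (residue_i, residue_j)
for determinism.

## SASA

Shrake–Rupley quadrature: each reported atom carries `n_points` (default
960) quasi-uniform points on its probe-expanded sphere (r_vdw + 1.4 Å); a
point is accessible iff strictly outside every other context atom's
expanded sphere, and the atom contributes 4π(r_vdw + probe)² × accessible
fraction.  Radii are Bondi-style (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20)
with a 1.70 Å fallback.  The context defaults to all protein heavy atoms;
hydrogens neither occlude nor report unless requested — consistent with the
heavy-atom contact convention, and a documented source of difference from
visualization-package defaults.

The lattice is a deterministic generalized-spiral (Fibonacci) point set —
bit-reproducible traces — and its orientation is canonicalized from the
principal axes of the *reported* atoms (signs fixed by third moments, a
rotation-equivariant construction).  Two exact properties follow: for
generic report sets the SASA is exactly invariant under rigid motion of the
whole structure (not merely up to quadrature error), and growing the
occluding context can only remove accessible points, so adding an occluder
never increases any atom's SASA.  For degenerate report sets (a single
atom) the orientation falls back to the lab frame: still deterministic, and
rotation invariance then holds to quadrature accuracy (~0.3% at 960
points).  Exactly coincident atoms occlude each other fully (a small slack
term in the occlusion test; no division by zero).

Trace correlation uses `scipy.stats` Pearson (default) or Spearman, pooled
and optionally per run.  A constant input series raises an explicit
undefined-correlation error; a constant *segment* in the per-run breakdown
is reported as `NA` rather than aborting the pooled result.

## Synthetic ensembles

The generator emulates exactly the contrast the analyses are meant to
detect, with non-physical but geometrically controlled structures: an
extended chain, one residue per 3.8 Å along x, four backbone atoms plus up
to five pseudo-sidechain atoms per residue, 78 residues numbered from 201,
10 runs × 200 frames by default.  Baseline geometry admits *no* contact at
sequence separation ≥ 2; this is verified by tests and by a built-in guard.

* **Harmonic jitter** adds i.i.d. isotropic per-frame Gaussian displacement
  (per-residue σ) to designated residues; the expected per-atom RMSF is
  √3·σ.  Noise is i.i.d. by design — no autocorrelation — so closed-form
  expectations hold exactly; it emulates thermal fluctuation amplitude, not
  dynamics.
* **Planted contacts** toggle a dedicated sidechain "mover" atom of one
  pair residue between an in-position (default 3.5 Å from an anchor atom of
  the partner residue) and an out-position (default 8.0 Å) with Bernoulli
  occupancy per frame.  Mover directions are drawn from a vetted set in the
  plane normal to the chain, and a numerical guard re-verifies at
  generation time that neither position creates any off-target contact,
  disturbs the reporter sphere, or collides with another mover — an unsafe
  specification is refused, never silently mis-planted.  Realized Bernoulli
  draws are returned as ground truth, so occupancy recovery can be asserted
  bit-exactly against the realization and statistically against p.
* **N-terminal displacement** shifts residues 201–206 rigidly along +z by
  `amplitude × (4 + ẑ_t)` where ẑ is the standardized latent series; the
  mean sits 4 standard deviations above zero so the displacement never
  clips at these trajectory lengths, and the measured partial-fit
  displacement equals the planted series exactly (every report atom moves
  by the same vector).
* **Exposure coupling** detaches the probe residue's CB reporter sphere
  12 Å below the chain plane (nothing else can come within occlusion range;
  the guard enforces a 6.3 Å clearance) and drives a single dedicated
  occluder atom toward it from below.  The occluded spherical-cap fraction
  f_t is set directly and converted to an occluder distance through the
  equal-radii cap closed form d = 2R(1 − 2f), so the expected SASA is the
  affine 4πR²(1 − f_t).  The occlusion driver is mixed from the latent as
  y = ρ·ẑ + √(1−ρ²)·η̂ with η̂ orthogonalized against ẑ *in sample*, so the
  sample correlation between the planted displacement and the planted SASA
  is exactly ρ; the recovered Pearson r is then limited only by the
  quadrature error of the SASA measurement (≲0.002 at 960 points), not by
  sampling noise.  An incidental side effect of the exposure machinery: the
  occluder atom belongs to a chain residue, so a genuine occluder–reporter
  residue contact appears in the maps near full occupancy — it cancels in
  the WT/mutant difference and sits far below the planted contrast.

The bundled WT/mutant demonstration pair holds five planted contacts —
labelled (203,256), (205,256), (237,257), (237,258), (259,264), echoing the
interactions the motivating mutant loses — at occupancy 0.90 (WT) vs 0.05
(mutant), gives both ensembles σ = 0.05 Å background jitter, a quiet
(amplitude 0.10 Å) vs. mobile (0.75 Å, mean ≈ 3 Å) N-terminal arm, and a
buried/uncoupled (mean cap fraction 0.45, ρ = 0) vs. exposed/coupled (0.25,
ρ = 0.8) reporter.  These are the study conditions; the per-ensemble seeds
derive from one user seed.

What the generator does *not* emulate: physical sterics, secondary
structure, solvent, autocorrelated dynamics, force-field energetics.
Passing tests therefore demonstrate that the analysis pipeline recovers
planted geometric/statistical signals correctly — not that any particular
biological system behaves this way.

## Workflow and reproducibility

The end-to-end workflow checks residue-level compatibility of the two
ensembles before any computation (residue *numbers* must match; names may
differ at the mutation site and are logged).  The reference structure
defaults to the wild type's first frame when none is configured.  Every
output TSV embeds the full effective configuration as `# key = value`
headers; the run log contains no timestamps; and identical inputs +
configuration reproduce byte-identical bundles.  CLI exit codes: 0 success,
2 usage, 3 input format, 4 contract violation.

Problem sizes in tests and the acceptance script (T = 2000 frames for
closed-form RMSF and correlation recovery, T = 1000 for occupancy recovery,
50-residue random structures for backend equality, 20-atom clusters for
quadrature convergence) are the sizes at which the corresponding
statistical bounds (3 binomial standard errors, the Fisher-z 95% interval)
are meaningfully tight while the whole suite stays interactive.

## Known limitations

* Single chain per analysis: contact maps are labelled by residue number
  alone and reject duplicate numbers across chains.
* PDB fixed columns bound coordinates to (−999.999, 9999.999] and residue
  numbers to ≤ 9999; out-of-range values are a formatting error.
* Element inference from atom names takes the first alphabetic character,
  which mis-types two-letter elements without explicit element columns
  (irrelevant for protein heavy atoms and hydrogens).
* SASA of hydrogen-containing selections excludes the hydrogens by default;
  enable `include_hydrogens` to match an all-atom convention.
* The correlation between SASA and fluctuation is reported as a
  coefficient; the motivating study states the relationship qualitatively,
  so there is no published value to compare against — the acceptance
  checks instead recover the generator's planted coefficient.
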