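# Methods

## Model and assumptions

The pipeline treats biocatalyst triage as a structure-conditioned
rescoring problem. Its central assumptions are:

- **Catalytic geometry is a hard filter.** IRED catalysis proceeds by
  hydride transfer from the NADPH nicotinamide C4 to the iminium
  carbon–nitrogen system; crystal structures place this contact near
  4 Å. Docked poses with a C4···N distance below 3.5 Å (steric clash
  with the nicotinamide) or above 6.0 Å (out of hydride-transfer
  range) are discarded outright rather than down-weighted. Among
  surviving poses the closest one is taken as the candidate's
  representative geometry; ties on distance fall back to the better
  (lower) docking score, then the lower pose index.
- **The active-site composition modifies affinity linearly.** With
  `N_acidic` and `N_basic` the counts of Asp/Glu and Lys/Arg residues
  within the shell and `N_His ∈ {0, 1}` a histidine presence flag, the
  refined score is
  `4.0·Vina + 1.0·N_acidic − 9.0·N_His + 9.0·N_basic` (lower =
  better). Acidic residues and the conserved histidine stabilize the
  iminium intermediate and provide the catalytic proton; basic
  residues compete with the iminium, hence the large symmetric
  penalty/bonus pair of 9.
- **The shell is geometric, not energetic.** A residue belongs to the
  active-site shell iff its minimum heavy-atom distance to any
  substrate heavy atom is ≤ 8 Å (inclusive). Hydrogens are ignored
  (models do not carry them), hetero groups (cofactor, ligands) are
  excluded from the census, and both chains of the dimer are
  considered. Protonation-variant residue names (HID/HIE/HIP, ASH,
  GLH, LYN) are normalized to their parents before classification so
  counts do not depend on the file dialect.

## Parameters

| parameter | default | unit | notes |
|---|---|---|---|
| pose filter window | 3.5 – 6.0 | Å | strict removal outside, inclusive at the bounds |
| shell radius | 8.0 | Å | inclusive |
| scoring weights | 4.0 / 1.0 / 9.0 / 9.0 | — | `w_his` enters negatively |
| panel size | 20 | sequences | screening budget |
| Ramachandran cutoff | 0.90 | fraction | inclusive, see below |
| homology filters | >0.30 / >0.80 / <10 | identity / coverage / E-value | strict inequalities |
| clustering threshold | 0.7 | identity over shorter sequence | greedy longest-first |
| docking box | max(2.9·Rg, 10) | Å | cubic, centered on the reference ligand centroid |
| docking exhaustiveness | 10 | — | recorded in backend provenance |
| tuning grid | −10 … 10, step 1 | — | all four weights by default |
| conversion cutoffs | 2 / 50 | % | inclusive ≥ at both |
| random baseline | 10 000 draws, CI ×1.96 | — | explicit seed required |

## Design choices in genuinely open territory

- **Sequence identity.** Global alignment with BLOSUM62, gap open 10 /
  extend 0.5. The identity denominator is all alignment columns for
  template assignment and the shorter sequence for clustering — the
  latter matching the convention of cd-hit-style tools. Both are
  configurable.
- **Strictness conventions.** "Over 30%/80%" and "under 10" are strict
  inequalities. The Ramachandran "over 90%" cutoff is implemented as
  an inclusive `core_fraction ≥ 0.90` to avoid a floating-point
  knife-edge at the stated value; the 2% and 50% conversion cutoffs
  are likewise inclusive `≥`.
- **Ramachandran regions.** Rectangular favorable/core boxes
  (φ ∈ [−180, −30] with ψ ∈ [−90, 45] ∪ [90, 180]) applied to all
  residues and all chains; only the core-fraction-versus-cutoff
  behavior matters downstream, and the region map is overridable.
  Residues lacking a complete backbone or a neighbor are skipped, not
  counted against the model.
- **Torsion convention.** Signed torsions in (−180, 180], invariant
  under reversal of the atom order and negated by mirror reflection
  (the standard convention; asserted explicitly by tests).
- **Box center.** Unweighted centroid of the reference ligand.
  Element masses would displace the center by far less than the box
  edge at these sizes.
- **Candidate statuses.** Candidates that fail a stage are kept in the
  output with statuses `not_homolog`, `model_unqualified`,
  `no_valid_pose` or `failed` (per-candidate backend errors); only
  `scored` rows are ranked. The vina score entering the refined score
  is the selected pose's own score — the selected pose is the physical
  model, not the best score across poses.
- **Tuning tie-breaks.** Grid points tie first on the 50%-cutoff hit
  rate, then the 2%-cutoff hit rate, then the smallest L1 norm of the
  weight vector, then lexicographic weight order — fully
  deterministic.
- **Random baselines.** Best-hit retrieval under random selection has
  the exact hypergeometric form `1 − C(N−m, k)/C(N, k)`; the
  Monte-Carlo baseline exists to attach SEM-based confidence bands to
  hit rates and cross-checks the closed form in tests.

## Modeling and docking backends

Comparative modeling and pose generation are *contracts*
(`ModelingBackend.build_model`, `DockingBackend.dock`), not
re-implementations: the package's contribution is everything around
them — the doubled dimer alignment they consume, the qualification
gate on their models, the cofactor transfer, the box geometry, and the
rescoring of their poses. The shipped fixture backends serve pre-built
models and pose sets keyed by query/receptor id, which makes the full
pipeline deterministic and testable offline.

## What the synthetic generators emulate — and what they do not

`fixtures` builds receptors whose residues sit at *exact, re-verified*
minimum distances from the substrate (axis-aligned exact placement for
up to six residues, a bracketing solve beyond that; a placement
requested exactly at a shell boundary is guaranteed not to overshoot
it), backbones with prescribed φ/ψ via internal-coordinate chain
extension, pose sets at exact C4···N separations, and screening panels
whose conversions either are uniform or follow a strictly monotone
logistic map of a known linear score plus Gaussian noise (default: 93
sequences, 5-percentage-point noise, emulating the largest published
IRED panel used for calibration). Every generator re-measures its own
geometric claims and stores the achieved values in metadata; tests
assert against those.

These fixtures exercise the pipeline's *semantics* — distances,
counts, filters, orderings, tie-breaks — not protein physics. Passing
tests show the method is implemented as specified; they say nothing
about docking accuracy, model quality on real sequences, or wet-lab
hit rates, all of which depend on the external engines and on
experimental screening.

## Numerical notes

- Shell membership and pose filtering are inclusive at their
  boundaries; generators construct boundary cases so these comparisons
  are exact in floating point rather than tolerance-based.
- Kabsch superposition rejects fewer than three pairs and collinear
  configurations; the returned rotation is always proper
  (determinant +1).
- Coordinate files round-trip to 3 decimals (the PDB fixed-column
  precision); pose files carry per-pose score and imine-nitrogen-index
  remarks and refuse to load without them.
- All stochastic operations take an explicit seed and are bit-reproducible;
  ranking output is byte-identical across reruns.

## Problem sizes

The test and acceptance workloads run on one CPU in seconds: distance
grids of 51 and 17 points, a 21-point qualification scan on
100-residue chains, 100 randomized receptors for the shell-census
oracle check, 1000 random rigid motions for superposition invariance,
a 5×5 tuning grid over 200 synthetic candidates, and Monte-Carlo
baselines of 4000–10 000 draws.

## Known limitations

- Greedy longest-first clustering compares only against cluster
  representatives (no word filters); adequate at package scale, slow
  for tens of thousands of sequences.
- The Ramachandran region map is rectangular and ignores
  glycine/pre-proline special cases; models near the 90% boundary may
  classify differently than under density-based region definitions.
- The evaluation report's Monte-Carlo fields are computed at the low
  (2%) cutoff; the JSON written by `run_evaluate` additionally carries
  the high-cutoff baseline.
- Enantioselectivity and absolute conversion are out of scope; the
  ranking orders candidates, it does not predict activity values.
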