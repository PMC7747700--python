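# Methods

## Scope and data model

All structural inputs are treated as an *ensemble*: an ordered list of
coordinate models sharing one atom topology. Crystallographic
ensemble-refinement output and trajectory frames are the same object; only
the downstream statistic differs (per-model persistence vs per-frame
occupancy vs correlation). Files are read with gemmi (PDB v3.3, MODEL/ENDMDL
blocks, altlocs, occupancies and B-factors preserved) and written back in
fixed-column PDB; a TSV "XYZ-table" dialect (`frame chain resid name x y z`)
covers plain-text trajectories. Residue numbering is taken verbatim from the
file — all residue identifiers in criteria (e.g. 345, 352, 390, 410, 534)
are author numbering. Coordinates are Å and B-factors Å² throughout.

Entity classification is by residue name: the 20 standard amino acids are
protein, HOH/WAT are water (configurable), everything else — including
modified residues deposited as HETATM such as MSE — is ligand, with a log
message. Alternate locations are kept; `highest_occupancy_altloc` reduces
to the major conformer when a single-copy view is needed.

## Interaction criteria

* **Hydrogen bond** — heavy-atom donor–acceptor distance strictly below
  `dmax` (default 3.5 Å). No angle term: the criterion mirrors
  distance-based bonding-range analysis of ensembles where hydrogens are
  not modelled. The cutoff is configurable per criterion.
* **Edge-to-face π–π stacking** — the angle between least-squares ring
  planes (SVD plane fit, 5- or 6-membered rings) must fall in [60°, 120°]
  and ring centroids within 5.5 Å. The raw angle in [0°, 180°) is reported
  without folding; the symmetric window makes folding immaterial for the
  pass/fail decision.
* **Water network** — waters and anchor atoms form a graph with edges below
  the linking distance (default 3.5 Å); the network size is the number of
  waters in components containing at least one anchor, and the network is
  intact when the size reaches `expected_count` (default 4). "Intact" has
  no universal definition; a simpler radius rule (waters directly within
  the linking distance of an anchor) is available via `rule="radius"`.

Persistence applies an evaluator to every model and reports the exact
fraction plus a half-up-rounded integer percent, the convention used when
occupancies are quoted in text (5/35 → 14%, 36/38 → 95%).

## Dynamics statistics

Superposition is least-squares rigid (proper rotations only) via
scipy's `Rotation.align_vectors`; degenerate (collinear or < 3 point) sets
are rejected. RMSF and the correlation matrix use frames superposed onto
the mean structure (seeded from frame 1, one refinement iteration).

The correlation matrix is the normalized covariance of 3-D displacement
vectors, C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) — the dynamical-network
convention. One estimator property matters in validation: the rigid fit
removes six degrees of freedom per frame, so coherent motion of a block of
residues is partially absorbed into the fitted global motion and the
estimated correlation of a planted block is attenuated (≈ 0.80 observed
for 0.9 planted on a 6-of-24-residue corridor). `correlation_matrix` and
`rmsf` therefore take `superpose` (default True, correct for real
trajectories); for synthetic displacement fields already expressed in a
common frame, `superpose=False` gives the unbiased estimator and is what
the recovery tests use. Estimator invariance to per-frame rigid motion is
tested separately.

B-factor means are occupancy-weighted and exclude waters. The per-atom
ligand ratio sample (each ligand atom's B over the mean protein B) feeds
the two-sample Student t-test comparing refinement strategies; Welch's
variant is available by flag.

## Dynamical network

Contacts: fraction of frames in which two residues are within the cutoff
(default 4.5 Å). The default pair rule is closest-heavy-atom distance (the
NetworkView convention); a Cα–Cα mode exists by flag. A literal Cα–Cα
4.5 Å rule would leave a real chain nearly edgeless, which is why
closest-atom is the default even though nodes are Cα.

Edges require contact fraction ≥ 0.75 and |C_ij| > 0; the length is
−log |C_ij| ≥ 0. Sequence neighbours (i, i±1) are excluded from the graph
by default so communication paths cannot trivially run along the backbone
(flag to include). Zero-correlation contacts produce no edge, with a
warning.

Optimal paths: Floyd–Warshall all-pairs distances and predecessors
(networkx); unreachable pairs have infinite distance. Suboptimal paths:
Yen's k-shortest-simple-paths enumeration, continued through length ties
at the k-th position and sorted (length, node sequence) so equal-length
paths have a deterministic lexicographic order. The top-k default is 1000.
Correctness is established against exhaustive simple-path enumeration on
all random graphs up to 8 nodes and against per-source Dijkstra.

## Assay models

**Competition FP.** The displacement curve has a fixed Hill slope of 1 (a
variable-slope variant exists behind a flag but is not the default). The
fit is least-squares over all replicate points jointly, multi-started over
candidate midpoints spanning the dose range; per-replicate fits provide
the log K_i sample for paired tests. The probe K_d is a required input,
never re-fit. K_i follows from the exact inversion
logK_i = logEC50 − log10(1 + [probe]/K_d) (probe and K_d in nM), so
K_i < EC50 always.

**DSF.** Boltzmann sigmoid with T_m at the inflection. Because
SYPRO-orange curves decay after the transition, the fit window is
truncated at the global fluorescence maximum by default; an optional
no-protein blank column is subtracted pointwise. Flat or non-rising
windows are a fit error, not a silent bad number. The estimator is
unbiased on symmetric noise (checked: |mean error| < 0.05 °C over 200
simulated melts at 2%-of-range noise).

Paired comparisons (log K_i, T_m) use the classical two-tailed paired t;
all-zero differences give p = 1, and a constant non-zero shift with zero
variance is flagged degenerate rather than assigned a fabricated p.

## Synthetic data

Generators place geometry; they never sample acceptance, so planted counts
are exact rather than stochastic, and the same seed reproduces outputs
bit-for-bit.

* **Chain.** A Cα-only chain on a compact coil (2/7 turn per residue,
  rise 0.35 Å, 3.8 Å bond length). The coil brings sequence separations
  {1, 3, 4, 6, 7, 10, 11} within the 4.5 Å contact cutoff, giving a
  protein-like contact density so the network stage has many distinct
  paths to rank. The geometry is deliberately abstract: interaction
  detection needs geometry, not chemistry, and some non-bonded Cα–Cα
  distances are shorter than physical.
* **Interaction ensembles.** Residues 340–359 with MET345 (SD acceptor),
  THR352 (OG1 water anchor) and an appended HIS390 five-membered ring;
  the ligand contributes a hydroxyl oxygen and a six-membered phenyl.
  H-bond-true models place the donor 2.5–3.3 Å from the acceptor, false
  models ≥ 1 Å beyond the cutoff; stacking-true models use perpendicular
  rings (65°–115°) within 5.3 Å, false models near-parallel rings (≤ 25°,
  face-to-face) at the same distance; model i carries `water_counts[i]`
  waters chained to the anchor at 2.8 Å, with unused water slots parked
  > 25 Å away so the topology is identical across models. Per-atom
  B-factors vary randomly around exactly-planted means (defaults: protein
  37.7 Å², ligand 61.5 Å², water 43.3 Å² — refinement-table values).
* **Trajectories.** Frames are the chain plus multivariate-normal
  displacements, the three Cartesian axes sampled independently with the
  same residue–residue correlation matrix, so the population correlation
  of displacement vectors equals the target entry for entry. Blocks and
  the communication corridor are equicorrelated groups (positive
  definiteness checked before sampling; non-PD targets are rejected).
  The default corridor steps by 4 in sequence (residues 1, 5, 9, 13, 17,
  21) — consecutive corridor residues are in spatial contact while the
  corridor is invisible to the excluded backbone edges. Desk-scale default
  length is 2000 frames with a 0.3 Å per-axis displacement; neighbour
  contacts then hold in ≥ 75% of frames by construction.
* **Assay curves.** Noiseless skeletons follow the fitting equations
  exactly (so self-consistency recovery is exact); noise is homoscedastic
  Gaussian in measurement units, default 2% of the dynamic range. FP
  defaults: 10 nM probe, probe K_d 10 nM, doses log-spaced 10⁻¹¹–10⁻⁴ M
  (a full-log dilution series wide enough to bracket micromolar
  midpoints), four replicates. DSF defaults: reads every 0.5 °C over
  25–80 °C, transition slope 1.5 °C, optional linear pre/post baselines
  (zero by default).

What the generators do *not* emulate: real chemistry (no force field, no
solvent, no protonation), correlated or heteroscedastic assay noise,
crystallographic restraints coupling models of an ensemble, and B-factor
gradients along the chain. Passing tests therefore demonstrate that the
estimators and detection rules recover known ground truth under the stated
noise model — not that any particular biological system behaves this way.

## Numerical choices

* Strict inequality at the H-bond cutoff; inclusive bounds for the
  stacking window and centroid distance.
* Percent reporting rounds half-up; full precision is retained internally.
* Path-length ties are resolved lexicographically after rounding lengths
  to 10 decimals (guards float jitter in summed edge weights).
* Logistic and Boltzmann fits multi-start and report convergence honestly;
  flat data raise errors instead of returning boundary parameters.
* Zero-variance residues get zero off-diagonal correlation with a warning;
  the matrix is symmetrized and clipped to [−1, 1] before use.

## Problem sizes used in validation

Trajectory recovery checks run at 500–8000 frames (correlation
convergence is checked at three sizes), K_i recovery at 100 simulated
plates per condition, T_m bias at 200 melts, and path-enumeration
equivalence at 200 random graphs of ≤ 8 nodes. These sizes are the
package's validation choices: large enough for the stated tolerances
(±0.05 on correlations, ±25% on median K_i, 0.05 °C on T_m bias), small
enough that the full suite runs in well under a minute per module.

## Known limitations

* The H-bond rule is distance-only; donors/acceptors are not typed and
  hydrogens are never placed.
* The water-network "intact" rule is one reasonable formalization among
  several; both implemented rules are configurable but neither is
  canonical.
* The suboptimal-path stage ranks by total length only; no path
  clustering or node-betweenness summary is provided.
* The competition model is the probe-corrected logistic approximation,
  not the exact cubic competitive-binding solution, and it assumes the
  competitor does not deplete.
* Binary trajectory formats (DCD/XTC), mmCIF, anisotropic B-factors and
  TLS reconstruction are out of scope.
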