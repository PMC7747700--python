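# allopath

Analysis pipeline for comparing how two ligands (for example the two
enantiomers of a nuclear-receptor agonist) differ in their structural and
energetic engagement of a receptor: per-model interaction persistence in
crystallographic ensembles, dynamical-network allostery in trajectories,
B-factor and RMSF statistics, and the binding (competition fluorescence
polarization) and stability (differential scanning fluorimetry) assay
models. A synthetic-data module generates ground-truth-known stand-ins for
every input — multi-model ensembles with exactly planted interaction
occupancies, Cα trajectories with a prescribed correlation structure, and
noisy assay plates — so every stage of the pipeline is testable against
known answers.

## What it computes

**Interaction persistence.** Ensemble refinement of crystallographic data
produces a set of coordinate models jointly fitting the diffraction data;
a geometric criterion evaluated per model yields an occupancy ("persists
in 5 of 35 models = 14%"). Criteria implemented:

* hydrogen bond: heavy-atom donor–acceptor distance < d_max (default 3.5 Å);
* edge-to-face π–π stacking: ring-plane angle in [60°, 120°] and ring
  centroids within 5.5 Å;
* water-network intactness: the number of water molecules connected
  (directly or through other waters, links < 3.5 Å) to a polar anchor
  atom, intact when it reaches the expected count (default 4).

**Dynamical network / suboptimal paths.** Residue Cα atoms are nodes; an
edge joins residues within 4.5 Å in ≥ 75% of frames, with length

    w_ij = −log |C_ij|,   C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)

so strongly correlated persistent contacts are short. Optimal paths come
from Floyd–Warshall; the top-k (default 1000) suboptimal source→sink paths
are enumerated with Yen's algorithm and summarized as a length histogram —
a shorter path population means stronger allosteric communication.

**Structure statistics.** Kabsch superposition, per-frame RMSD, per-residue
RMSF, and occupancy-weighted ligand/protein B-factor ratios with a
two-sample Student t comparison.

**Assay fits.** Competition FP: Y = Bottom + (Top−Bottom)/(1+10^(X−logEC50)),
with the probe-occupancy correction logEC50 = logK_i + log10(1+[probe]/K_d);
DSF: Boltzmann sigmoid F(T) = F_min + (F_max−F_min)/(1+exp((T_m−T)/slope)),
with ΔT_m between conditions and paired t-tests on log K_i or T_m.

## Worked example

Generate a 35-model ensemble in which the ligand hydroxyl H-bond is
planted in exactly 5 models, then measure interaction persistence:

```sh
$ allopath synth ensemble --seed 1 --out ens.pdb
$ allopath ensemble ens.pdb --out results
{
 "n_models": 35,
 "hbond":         {"n_true": 5,  "n_models": 35, "fraction": 0.1428…, "percent": 14},
 "stacking":      {"n_true": 31, "n_models": 35, "fraction": 0.8857…, "percent": 89},
 "water_network": {"n_true": 12, "n_models": 35, "fraction": 0.3428…, "percent": 34}
}
```

The H-bond holds in 5/35 models (14%) — a ligand that only transiently
reaches its polar partner — while stacking is much more persistent (89%),
and the 4-water network is intact in about a third of the models.

Fit a binding affinity from a simulated competition-FP plate (true
K_i = 0.4 µM, 10 nM probe, probe K_d = 10 nM):

```sh
$ allopath synth fp --seed 2 --out fp.csv
$ allopath ki fp.csv --probe-nm 10 --probe-kd-nm 10
{
 "logKi": -6.3766…,
 "Ki_M": 4.201e-07,
 "ci95_logKi": [-6.4160…, -6.3372…],
 "per_replicate_logKi": [-6.3477…, -6.3734…, -6.4110…, -6.3763…]
}
```

The fitted K_i of 0.42 µM recovers the planted 0.4 µM; the per-replicate
log K_i values are what paired t-tests between ligands operate on.

Library use mirrors the CLI — see `allopath.pipeline.run` and the module
functions (`interactions.persistence`, `allosteric_network.suboptimal_paths`,
`assay_fits.fit_ki`, `assay_fits.fit_boltzmann`).

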