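"""Ground-truth-known synthetic inputs for every pipeline stage.

The generators place geometry; they never sample acceptance.  An
interaction ensemble therefore satisfies each geometric criterion in
*exactly* the requested number of models, a trajectory realizes a
prescribed residue-residue correlation matrix in population, and assay
curves follow the fitting equations exactly before noise is added.

The synthetic "protein" is a Calpha-only chain laid on a helix with 3.8 A
between sequence neighbours; the helix parameters additionally bring i and
i+4 within contact distance, giving the chain a non-trivial contact graph
for network analysis.  Ligand, aromatic rings and waters are minimal atom
sets sufficient for each geometric criterion.  Residue numbering mimics a
nuclear-receptor ligand binding domain: the chain covers residues 340-359
with a methionine at 345 (H-bond acceptor), a threonine at 352 (water
network anchor) and an appended histidine 390 carrying the stacking ring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assay_fits import CompetitionDataset, MeltCurve, logki_to_logec50
from .assay_fits import logistic_competition as _logistic
from .ensemble_io import Atom, Ensemble, StructureModel
from .errors import SpecificationError

__all__ = [
    "EnsembleSpec",
    "TrajectorySpec",
    "CompetitionSpec",
    "MeltSpec",
    "helix_chain",
    "MET_ACCEPTOR_RESID",
    "THR_ANCHOR_RESID",
    "HIS_RING_RESID",
    "LIGAND_RING_NAMES",
    "HIS_RING_NAMES",
    "make_interaction_ensemble",
    "make_correlated_trajectory",
    "make_competition_dataset",
    "make_melt_curve",
]

# compact coil: 3.8 A between sequence neighbours, and a protein-like
# contact shell — residues i and i+k are within the 4.5 A contact cutoff
# for k in {1, 3, 4, 6, 7, 10, 11}, so the contact graph supports many
# distinct communication paths (2/7-turn per residue, rise 0.35 A)
_HELIX_OMEGA = 4.0 * np.pi / 7.0
_HELIX_RISE = 0.35
_HELIX_RADIUS = float(
    np.sqrt((3.8**2 - _HELIX_RISE**2) / (4.0 * np.sin(_HELIX_OMEGA / 2.0) ** 2))
)


def helix_chain(n_residues: int) -> np.ndarray:
    """Calpha positions of the synthetic helical chain, (n, 3) in A."""
    i = np.arange(n_residues)
    return np.column_stack(
        [
            _HELIX_RADIUS * np.cos(_HELIX_OMEGA * i),
            _HELIX_RADIUS * np.sin(_HELIX_OMEGA * i),
            _HELIX_RISE * i,
        ]
    )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _ring_coords(
    centroid: np.ndarray, normal: np.ndarray, n_atoms: int, radius: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Regular planar n-gon with the given centroid and plane normal."""
    normal = _unit(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, normal)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(normal, helper))
    e2 = np.cross(normal, e1)
    phase = rng.uniform(0, 2 * np.pi)
    ang = phase + 2 * np.pi * np.arange(n_atoms) / n_atoms
    return centroid + radius * (
        np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2)
    )


# ---------------------------------------------------------------------------
# Interaction ensembles


@dataclass
class EnsembleSpec:
    """Planted per-model truth for the three interaction criteria.

    Defaults reproduce the frustrated-enantiomer study conditions for a
    35-model crystallographic ensemble: the ligand hydroxyl H-bond holds in
    5 models, edge-to-face stacking in 31, and the 4-water network is
    intact in 12.  Mean B-factors default to the refinement-table values
    (protein 37.7 A^2, ligand 61.5 A^2, water 43.3 A^2) and are planted
    exactly: per-atom B values vary but average to the requested means.
    """

    n_models: int = 35
    hbond_true_count: int = 5
    stack_true_count: int = 31
    water_counts: Sequence[int] | None = None  # default: 12 intact (4), rest 2
    n_water_slots: int = 4
    geometry_noise_sd: float = 0.1
    hbond_dmax: float = 3.5
    protein_mean_b: float = 37.7
    ligand_mean_b: float = 61.5
    water_mean_b: float = 43.3
    seed: int = 0

    def __post_init__(self):
        if self.water_counts is None:
            n_intact = min(12, self.n_models)
            self.water_counts = [self.n_water_slots] * n_intact + [2] * (
                self.n_models - n_intact
            )
        self.water_counts = list(self.water_counts)
        if len(self.water_counts) != self.n_models:
            raise SpecificationError("water_counts must have one entry per model")
        for name in ("hbond_true_count", "stack_true_count"):
            v = getattr(self, name)
            if not 0 <= v <= self.n_models:
                raise SpecificationError(
                    f"{name}={v} outside [0, n_models={self.n_models}]"
                )
        if any(not 0 <= w <= self.n_water_slots for w in self.water_counts):
            raise SpecificationError("water counts must lie in [0, n_water_slots]")


# resids of the special residues on the synthetic chain
MET_ACCEPTOR_RESID = 345
THR_ANCHOR_RESID = 352
HIS_RING_RESID = 390
CHAIN_FIRST_RESID = 340
CHAIN_N_RESIDUES = 20

LIGAND_RING_NAMES = ("C11", "C12", "C13", "C14", "C15", "C16")
HIS_RING_NAMES = ("CG", "ND1", "CD2", "CE1", "NE2")


def _planted_b(rng, n, mean, sd):
    """Per-atom B-factors varying around an exactly-planted sample mean."""
    if n == 1:
        return np.array([mean])
    b = rng.normal(mean, sd, size=n)
    b = b - b.mean() + mean
    if b.min() <= 1.0:  # keep B positive while preserving the mean
        b = mean + (b - mean) * 0.25
    return b


def make_interaction_ensemble(spec: EnsembleSpec) -> Ensemble:
    """Build an ensemble satisfying each criterion in exactly the planted
    number of models.

    H-bond-true models place the ligand hydroxyl 2.5-3.3 A from the M345
    sulfur; false models place it at least 1 A beyond the cutoff.
    Stacking-true models orient the ligand phenyl perpendicular (65-115
    deg) to the H390 ring within 5.3 A; false models use a face-to-face
    (near-parallel) geometry that fails the angle window.  Model i carries
    ``water_counts[i]`` waters chained to the T352 hydroxyl at 2.8 A
    spacing; unused water slots are parked >25 A away so every model keeps
    an identical atom topology.
    """
    rng = np.random.default_rng(spec.seed)
    base = helix_chain(CHAIN_N_RESIDUES)
    resids = CHAIN_FIRST_RESID + np.arange(CHAIN_N_RESIDUES)
    ca_met = base[list(resids).index(MET_ACCEPTOR_RESID)]
    ca_thr = base[list(resids).index(THR_ANCHOR_RESID)]
    # fixed interaction sites, well separated from each other
    p_acceptor = ca_met + np.array([4.0, 0.0, 0.0])
    w_anchor = ca_thr + np.array([3.0, 0.0, 0.0])
    ca_his = ca_thr + np.array([12.0, 0.0, 0.0])
    q_his_ring = ca_his + np.array([2.5, 0.0, 0.0])

    hbond_true = set(rng.permutation(spec.n_models)[: spec.hbond_true_count])
    stack_true = set(rng.permutation(spec.n_models)[: spec.stack_true_count])

    n_prot_atoms = CHAIN_N_RESIDUES + 2 + 1 + len(HIS_RING_NAMES)
    n_lig_atoms = 1 + len(LIGAND_RING_NAMES)
    b_prot = _planted_b(rng, n_prot_atoms, spec.protein_mean_b, 8.0)
    b_lig = _planted_b(rng, n_lig_atoms, spec.ligand_mean_b, 5.0)
    b_wat = _planted_b(rng, spec.n_water_slots, spec.water_mean_b, 4.0)

    models = []
    for m in range(spec.n_models):
        atoms: list[Atom] = []
        serial = 0

        def add(name, element, resname, resid, chain, xyz, b):
            nonlocal serial
            serial += 1
            atoms.append(
                Atom(serial=serial, name=name, element=element, resname=resname,
                     resid=int(resid), chain=chain, altloc="", occupancy=1.0,
                     bfactor=round(float(b), 2), coords=np.asarray(xyz, float)))

        jitter = lambda: rng.normal(0.0, spec.geometry_noise_sd, size=3)
        bi = iter(b_prot)
        for i, resid in enumerate(resids):
            resname = {MET_ACCEPTOR_RESID: "MET", THR_ANCHOR_RESID: "THR"}.get(
                int(resid), "ALA")
            add("CA", "C", resname, resid, "A", base[i] + jitter(), next(bi))
            if resid == MET_ACCEPTOR_RESID:
                add("SD", "S", "MET", resid, "A", p_acceptor, next(bi))
            if resid == THR_ANCHOR_RESID:
                add("OG1", "O", "THR", resid, "A", w_anchor, next(bi))
        add("CA", "C", "HIS", HIS_RING_RESID, "A", ca_his + jitter(), next(bi))
        his_ring = _ring_coords(q_his_ring, np.array([0.0, 0.0, 1.0]), 5, 1.15, rng)
        for name, xyz in zip(HIS_RING_NAMES, his_ring):
            add(name, name[0], "HIS", HIS_RING_RESID, "A", xyz, next(bi))

        # ligand hydroxyl oxygen: planted H-bond distance from the M345 sulfur
        if m in hbond_true:
            d = float(np.clip(rng.normal(2.9, spec.geometry_noise_sd),
                              2.5, spec.hbond_dmax - 0.2))
        else:
            d = float(np.clip(rng.normal(spec.hbond_dmax + 1.4,
                                         spec.geometry_noise_sd),
                              spec.hbond_dmax + 1.0, spec.hbond_dmax + 1.9))
        bj = iter(b_lig)
        add("O1", "O", "LIG", 1, "L", p_acceptor + d * _random_unit(rng), next(bj))

        # ligand phenyl ring: perpendicular (true) or parallel (false) to H390
        if m in stack_true:
            alpha = np.radians(np.clip(rng.normal(90.0, 8.0), 65.0, 115.0))
            dist = float(np.clip(rng.normal(4.7, 0.2), 3.8, 5.3))
        else:
            alpha = np.radians(np.clip(abs(rng.normal(0.0, 8.0)), 0.0, 25.0))
            dist = float(np.clip(rng.normal(4.7, 0.2), 3.8, 5.3))
        phi = rng.uniform(0, 2 * np.pi)
        n1 = np.array([np.sin(alpha) * np.cos(phi),
                       np.sin(alpha) * np.sin(phi),
                       np.cos(alpha)])
        lig_centroid = q_his_ring + dist * _random_unit(rng)
        for name, xyz in zip(
            LIGAND_RING_NAMES, _ring_coords(lig_centroid, n1, 6, 1.39, rng)
        ):
            add(name, "C", "LIG", 1, "L", xyz, next(bj))

        # water slots: first water_counts[m] chained to the anchor, rest parked
        direction = _random_unit(rng)
        n_present = spec.water_counts[m]
        for w in range(spec.n_water_slots):
            if w < n_present:
                xyz = w_anchor + (w + 1) * 2.8 * direction
            else:
                xyz = w_anchor + np.array([30.0 + 8.0 * w, 25.0, -20.0])
            add("O", "O", "HOH", 901 + w, "W", xyz, b_wat[w])

        models.append(StructureModel(model_id=m + 1, atoms=atoms))
    return Ensemble(models=models)


# ---------------------------------------------------------------------------
# Correlated trajectories


@dataclass
class TrajectorySpec:
    """Prescribed correlation structure for a synthetic Calpha trajectory.

    ``block_structure`` lists (residue tuple/range, rho) groups that move
    together with pairwise correlation rho; ``corridor`` plants a
    communication corridor: the listed residues (source first, sink last)
    share correlation ``corridor_rho``.  On the helical chain residues i
    and i+4 are in persistent contact, so a corridor stepping by 4 in
    sequence is realizable as a network path while being invisible to the
    (excluded) backbone i, i+1 edges.  The trajectory length defaults to a
    desk-scale 2000 frames.
    """

    n_residues: int = 24
    n_frames: int = 2000
    block_structure: Sequence[tuple[Sequence[int], float]] = ()
    corridor: Sequence[int] = (1, 5, 9, 13, 17, 21)
    corridor_rho: float = 0.9
    displacement_sd: float = 0.3
    first_resid: int = 1
    seed: int = 0

    def __post_init__(self):
        for _, rho in self.block_structure:
            if not -1 < rho < 1:
                raise SpecificationError(f"block rho {rho} outside (-1, 1)")
        if self.corridor and not -1 < self.corridor_rho < 1:
            raise SpecificationError("corridor rho outside (-1, 1)")

    @property
    def source(self) -> int:
        return int(self.corridor[0]) if self.corridor else self.first_resid

    @property
    def sink(self) -> int:
        return int(self.corridor[-1]) if self.corridor else self.first_resid

    def target_correlation(self) -> np.ndarray:
        """The planted population correlation matrix (checked PD)."""
        n = self.n_residues
        R = np.eye(n)
        groups = [(list(g), rho) for g, rho in self.block_structure]
        if self.corridor:
            groups.append((list(self.corridor), self.corridor_rho))
        for members, rho in groups:
            idx = [int(r) - self.first_resid for r in members]
            if any(not 0 <= i < n for i in idx):
                raise SpecificationError("block/corridor residue outside chain")
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    R[idx[a], idx[b]] = R[idx[b], idx[a]] = rho
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            raise SpecificationError(
                "target correlation matrix is not positive definite"
            ) from None
        return R


def make_correlated_trajectory(spec: TrajectorySpec) -> Ensemble:
    """Sample frames = helix + multivariate-normal displacements.

    The three Cartesian axes are sampled independently with the same
    residue-residue correlation matrix, so the population correlation of
    displacement *vectors* equals the planted matrix entry for entry.
    """
    R = spec.target_correlation()
    L = np.linalg.cholesky(R)
    rng = np.random.default_rng(spec.seed)
    base = helix_chain(spec.n_residues)
    disp = np.empty((spec.n_frames, spec.n_residues, 3))
    for axis in range(3):
        Z = rng.standard_normal((spec.n_frames, spec.n_residues))
        disp[:, :, axis] = Z @ L.T * spec.displacement_sd
    models = []
    for t in range(spec.n_frames):
        atoms = [
            Atom(serial=i + 1, name="CA", element="C", resname="ALA",
                 resid=spec.first_resid + i, chain="A", altloc="", occupancy=1.0,
                 bfactor=0.0, coords=base[i] + disp[t, i])
            for i in range(spec.n_residues)
        ]
        models.append(StructureModel(model_id=t + 1, atoms=atoms))
    return Ensemble(models=models)


# ---------------------------------------------------------------------------
# Assay curves


@dataclass
class CompetitionSpec:
    """Competition FP generating conditions.

    Defaults mirror the stronger-binding receptor condition: true Ki
    0.4 uM probed with 10 nM fluorescent probe against a 10 nM probe Kd,
    doses log-spaced over 1e-11 to 1e-4 M (a full-log dilution series wide
    enough to bracket micromolar midpoints), four replicates, homoscedastic
    Gaussian noise of 2% of the dynamic range in mP.
    """

    true_Ki: float = 0.4e-6  # molar
    probe_conc: float = 10.0  # nM
    probe_Kd: float = 10.0  # nM
    top: float = 200.0  # mP
    bottom: float = 50.0  # mP
    conc_grid: Sequence[float] = tuple(10.0**-k for k in range(11, 3, -1))
    n_replicates: int = 4
    noise_sd: float = 3.0  # mP
    seed: int = 0

    def __post_init__(self):
        if self.true_Ki <= 0 or self.probe_conc <= 0 or self.probe_Kd <= 0:
            raise SpecificationError("Ki and probe values must be positive")
        if self.top <= self.bottom:
            raise SpecificationError("top must exceed bottom")


def make_competition_dataset(spec: CompetitionSpec) -> CompetitionDataset:
    """Noiseless displacement logistic from the planted Ki, plus noise."""
    rng = np.random.default_rng(spec.seed)
    X = np.log10(np.asarray(spec.conc_grid, float))
    logec50 = logki_to_logec50(np.log10(spec.true_Ki), spec.probe_conc, spec.probe_Kd)
    y0 = _logistic(X, spec.top, spec.bottom, logec50)
    Y = y0[:, None] + rng.normal(0.0, spec.noise_sd, size=(len(X), spec.n_replicates))
    return CompetitionDataset(
        X=X, Y=Y, probe_conc=spec.probe_conc, probe_Kd=spec.probe_Kd
    )


@dataclass
class MeltSpec:
    """DSF generating conditions: Boltzmann transition with linear
    baselines, sampled every 0.5 degC (the ramp-rate-limited read spacing),
    noise 2% of the fluorescence range."""

    true_Tm: float = 55.0  # degC
    slope: float = 1.5  # degC
    f_min: float = 200.0
    f_max: float = 1800.0
    baseline_slopes: tuple[float, float] = (0.0, 0.0)  # pre/post, units per degC
    temp_grid: Sequence[float] | None = None  # default 25..80 by 0.5
    noise_sd: float = 32.0
    seed: int = 0

    def __post_init__(self):
        if self.temp_grid is None:
            self.temp_grid = np.arange(25.0, 80.0 + 1e-9, 0.5)
        self.temp_grid = np.asarray(self.temp_grid, float)
        if self.slope <= 0:
            raise SpecificationError("transition slope must be positive")
        if not self.temp_grid.min() < self.true_Tm < self.temp_grid.max():
            raise SpecificationError("true_Tm must lie inside the temperature grid")


def make_melt_curve(spec: MeltSpec) -> MeltCurve:
    """Sigmoid melt with linear pre/post baselines blended by the
    transition fraction, plus Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    T = spec.temp_grid
    frac = 1.0 / (1.0 + np.exp((spec.true_Tm - T) / spec.slope))
    m_pre, m_post = spec.baseline_slopes
    lower = spec.f_min + m_pre * (T - T[0])
    upper = spec.f_max + m_post * (T - spec.true_Tm)
    F = lower + (upper - lower) * frac + rng.normal(0.0, spec.noise_sd, size=T.shape)
    return MeltCurve(T=T, F=F)
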