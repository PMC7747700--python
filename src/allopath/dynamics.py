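"""Superposition, RMSD/RMSF, Calpha correlation matrices and B-factor stats.

The correlation matrix follows the dynamical-network convention: the
normalized covariance of 3-D displacement vectors,

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>),  dr = r - <r>,

computed after superposing every frame onto the mean structure.  This is
the quantity from which network edge lengths are later derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial.transform import Rotation

from .ensemble_io import Ensemble, Selection, StructureModel, select_atoms
from .errors import FitError, GeometryError, SelectionError

__all__ = [
    "SuperpositionResult",
    "RMSFProfile",
    "CorrelationMatrix",
    "BFactorStats",
    "kabsch_superpose",
    "rmsd_series",
    "superposed_coords",
    "rmsf",
    "correlation_matrix",
    "bfactor_ratio",
    "compare_bfactor_ratios",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # applied after rotation
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RMSFProfile:
    resids: list[tuple[str, int]]  # (chain, resid)
    rmsf: np.ndarray
    reference: np.ndarray  # mean structure over the selection


@dataclass
class CorrelationMatrix:
    labels: list[tuple[str, int]]
    C: np.ndarray


@dataclass
class BFactorStats:
    mean_ligand_B: float
    mean_protein_B: float
    per_atom_ligand_ratios: np.ndarray

    @property
    def ratio(self) -> float:
        return self.mean_ligand_B / self.mean_protein_B

    @property
    def ratio_sd(self) -> float:
        """SD over per-atom ligand/mean-protein ratios (ddof=1)."""
        return float(np.std(self.per_atom_ligand_ratios, ddof=1))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Proper rotations only (reflections excluded).  Requires >= 3 points
    that are not collinear.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("point sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    mc = np.average(mobile, axis=0, weights=w)
    rc = np.average(reference, axis=0, weights=w)
    mob_c, ref_c = mobile - mc, reference - rc
    if np.linalg.matrix_rank(ref_c, tol=1e-9) < 2 or np.linalg.matrix_rank(
        mob_c, tol=1e-9
    ) < 2:
        raise GeometryError("degenerate (collinear) point set")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # exact superpositions trigger scipy notes
        rot, rssd = Rotation.align_vectors(ref_c, mob_c, weights=w)
    rmsd = float(rssd / np.sqrt(w.sum()))
    rotation = rot.as_matrix()
    translation = rc - rotation @ mc
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def rmsd_series(
    traj: Ensemble, reference: StructureModel, sel: Selection | Sequence[int]
) -> np.ndarray:
    """Per-frame RMSD (A) over a selection after superposing each frame."""
    idx = _resolve(traj, sel)
    ref = reference.coords[idx]
    out = np.empty(traj.n_models)
    for t, model in enumerate(traj.models):
        out[t] = kabsch_superpose(model.coords[idx], ref).rmsd
    return out


def _resolve(traj: Ensemble, sel: Selection | Sequence[int]) -> np.ndarray:
    idx = select_atoms(traj, sel) if isinstance(sel, Selection) else np.asarray(sel, int)
    if len(idx) == 0:
        raise SelectionError("selection is empty")
    return idx


def superposed_coords(
    traj: Ensemble, sel: Selection | Sequence[int]
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Superpose all frames onto the mean structure over a selection.

    The mean is seeded from the first frame and refined with one
    iteration: superpose on frame 0, average, then superpose on the
    average.  Returns (coords (T, n, 3), mean (n, 3), residue labels).
    """
    idx = _resolve(traj, sel)
    X = traj.coords()[:, idx, :]
    ref = X[0]
    for _ in range(2):
        aligned = np.stack([kabsch_superpose(x, ref).apply(x) for x in X])
        ref = aligned.mean(axis=0)
    labels = [
        (traj.models[0].atoms[int(i)].chain, traj.models[0].atoms[int(i)].resid)
        for i in idx
    ]
    return aligned, ref, labels


def rmsf(
    traj: Ensemble, sel: Selection | Sequence[int], superpose: bool = True
) -> RMSFProfile:
    """Per-atom RMSF about the mean structure: sqrt(mean_t |r_i(t)-<r_i>|^2).

    Frames are superposed onto the mean structure first (as needed when
    frames carry global motion); pass ``superpose=False`` for frames
    already in a common reference frame, where the rigid fit would only
    redistribute a small amount of variance between atoms.
    """
    if traj.n_models < 2:
        raise GeometryError("RMSF is undefined for a single frame")
    if superpose:
        aligned, mean, labels = superposed_coords(traj, sel)
    else:
        idx = _resolve(traj, sel)
        aligned = traj.coords()[:, idx, :]
        mean = aligned.mean(axis=0)
        labels = [
            (traj.models[0].atoms[int(i)].chain, traj.models[0].atoms[int(i)].resid)
            for i in idx
        ]
    disp = aligned - mean
    values = np.sqrt((disp**2).sum(axis=2).mean(axis=0))
    return RMSFProfile(resids=labels, rmsf=values, reference=mean)


def correlation_matrix(
    traj: Ensemble, sel: Selection | Sequence[int], superpose: bool = True
) -> CorrelationMatrix:
    """Normalized covariance of 3-D displacement vectors over a trajectory.

    By default each frame is first superposed onto the mean structure, as
    required when frames carry global rigid motion.  The rigid fit removes
    six degrees of freedom and therefore slightly attenuates coherent
    block motion; for trajectories already expressed in a common frame
    (e.g. synthetic displacement fields) pass ``superpose=False`` to get
    the unbiased estimator.  Zero-variance atoms get zero off-diagonal
    correlation (with a warning) and unit diagonal.
    """
    if traj.n_models < 2:
        raise GeometryError("correlations are undefined for a single frame")
    if superpose:
        aligned, mean, labels = superposed_coords(traj, sel)
    else:
        idx = _resolve(traj, sel)
        aligned = traj.coords()[:, idx, :]
        mean = aligned.mean(axis=0)
        labels = [
            (traj.models[0].atoms[int(i)].chain, traj.models[0].atoms[int(i)].resid)
            for i in idx
        ]
    disp = aligned - mean  # (T, n, 3)
    S = np.einsum("tik,tjk->ij", disp, disp) / disp.shape[0]
    var = np.diag(S).copy()
    dead = var <= 1e-30
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance atoms; correlations set to 0",
            stacklevel=2,
        )
        var[dead] = 1.0
    C = S / np.sqrt(np.outer(var, var))
    C[dead, :] = 0.0
    C[:, dead] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(labels=labels, C=C)


def bfactor_ratio(
    model: StructureModel,
    ligand_sel: Sequence[int],
    protein_sel: Sequence[int],
) -> BFactorStats:
    """Occupancy-weighted mean ligand and protein B-factors and their ratio.

    ``per_atom_ligand_ratios`` divides each ligand atom's B by the mean
    protein B, the sample used when comparing two refinement strategies.
    """
    lig = [model.atoms[int(i)] for i in ligand_sel]
    prot = [model.atoms[int(i)] for i in protein_sel]
    if not lig or not prot:
        raise SelectionError("ligand and protein selections must be non-empty")

    def wmean(atoms):
        b = np.array([a.bfactor for a in atoms])
        w = np.array([a.occupancy for a in atoms])
        if w.sum() <= 0:
            raise SelectionError("total occupancy is zero")
        return float(np.average(b, weights=w))

    mean_p = wmean(prot)
    mean_l = wmean(lig)
    per_atom = np.array([a.bfactor for a in lig]) / mean_p
    return BFactorStats(
        mean_ligand_B=mean_l, mean_protein_B=mean_p, per_atom_ligand_ratios=per_atom
    )


def compare_bfactor_ratios(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    welch: bool = False,
) -> tuple[float, float]:
    """Two-tailed unpaired t-test on two ratio samples.

    Student (equal-variance) by default; Welch behind a flag.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise FitError("each sample needs n >= 2")
    if np.var(a, ddof=1) + np.var(b, ddof=1) <= 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise FitError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
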