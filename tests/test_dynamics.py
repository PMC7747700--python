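"""Superposition, RMSD/RMSF, correlation matrices and B-factor statistics."""

import numpy as np
import pytest
from scipy import stats

from allopath.dynamics import (
    bfactor_ratio,
    compare_bfactor_ratios,
    correlation_matrix,
    kabsch_superpose,
    rmsd_series,
    rmsf,
)
from allopath.ensemble_io import Selection
from allopath.errors import FitError, GeometryError
from allopath.synthetic_data import TrajectorySpec, make_correlated_trajectory

from conftest import build_model, coords_ensemble, random_rigid_motion


# ---------------------------------------------------------------------------
# Kabsch


def test_identical_sets_superpose_exactly(rng):
    pts = rng.normal(size=(10, 3))
    res = kabsch_superpose(pts, pts)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(res.rotation, np.eye(3), atol=1e-8)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0)


def test_rotated_set_recovers_inverse_rotation(rng):
    pts = rng.normal(size=(12, 3))
    theta = np.radians(90)
    Rz = np.array([[np.cos(theta), -np.sin(theta), 0],
                   [np.sin(theta), np.cos(theta), 0],
                   [0, 0, 1]])
    res = kabsch_superpose(pts @ Rz.T, pts)
    assert res.rmsd == pytest.approx(0.0, abs=1e-8)
    assert np.allclose(res.rotation, Rz.T, atol=1e-8)


def test_kabsch_beats_unsuperposed_rmsd(rng):
    for _ in range(5):
        a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        raw = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        assert kabsch_superpose(a, b).rmsd <= raw + 1e-12


def test_kabsch_matches_grid_search_on_planar_toy(rng):
    """Brute-force 1-degree rotation scan on z=0 point sets.

    For planar sets every optimal proper rotation is either a rotation
    about z or a rotation about z composed with a 180-degree flip about an
    in-plane axis (which mirrors the plane), so the scan covers both.
    """
    a = np.column_stack([rng.normal(size=(8, 2)), np.zeros(8)])
    b = np.column_stack([rng.normal(size=(8, 2)), np.zeros(8)])
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    flip = np.diag([1.0, -1.0, -1.0])  # 180 degrees about x
    best = np.inf
    for deg in np.arange(0.0, 360.0, 1.0):
        th = np.radians(deg)
        Rz = np.array([[np.cos(th), -np.sin(th), 0],
                       [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        for R in (Rz, Rz @ flip):
            best = min(best,
                       np.sqrt(np.mean(np.sum((bc @ R.T - ac) ** 2, axis=1))))
    kab = kabsch_superpose(b, a).rmsd
    assert kab <= best + 1e-9
    assert kab == pytest.approx(best, abs=5e-3)  # 1-degree grid resolution


def test_degenerate_point_sets_rejected():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(GeometryError):
        kabsch_superpose(line, line)
    with pytest.raises(GeometryError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# RMSD series / RMSF


def test_static_trajectory_rmsd_and_rmsf_zero(rng):
    frame = rng.normal(size=(6, 3)) * 4
    traj = coords_ensemble(np.repeat(frame[None], 5, axis=0))
    series = rmsd_series(traj, traj.models[0], Selection(name="CA"))
    assert np.allclose(series, 0.0, atol=1e-6)
    prof = rmsf(traj, Selection(name="CA"))
    assert np.allclose(prof.rmsf, 0.0, atol=1e-6)


def test_rigidly_shifted_frame_has_zero_rmsd(rng):
    frame = rng.normal(size=(8, 3)) * 4
    R, t = random_rigid_motion(rng)
    traj = coords_ensemble(np.stack([frame, frame @ R.T + t + 5.0]))
    series = rmsd_series(traj, traj.models[0], Selection(name="CA"))
    assert series[1] == pytest.approx(0.0, abs=1e-6)


def test_isotropic_noise_rmsd_closed_form():
    """Per-axis sd sigma gives frame RMSD ~ sigma*sqrt(3) to the reference."""
    sd = 0.5
    spec = TrajectorySpec(n_residues=40, n_frames=400, corridor=(),
                          displacement_sd=sd, seed=7)
    traj = make_correlated_trajectory(spec)
    from allopath.synthetic_data import helix_chain

    ref = coords_ensemble(helix_chain(40)[None]).models[0]
    series = rmsd_series(traj, ref, Selection(name="CA"))
    assert np.mean(series) == pytest.approx(sd * np.sqrt(3), rel=0.10)


def test_isotropic_noise_rmsf_closed_form():
    sd = 0.2
    spec = TrajectorySpec(n_residues=60, n_frames=5000, corridor=(),
                          displacement_sd=sd, seed=8)
    prof = rmsf(make_correlated_trajectory(spec), Selection(name="CA"))
    assert np.allclose(prof.rmsf, sd * np.sqrt(3), rtol=0.05)
    assert np.mean(prof.rmsf) == pytest.approx(sd * np.sqrt(3), rel=0.05)


def test_two_block_rmsf_ratio(rng):
    """Atoms with 4x the displacement sd show ~4x the RMSF."""
    base = rng.normal(size=(40, 3)) * 10
    noise = rng.normal(size=(2000, 40, 3))
    noise[:, :20] *= 0.2
    noise[:, 20:] *= 0.8
    traj = coords_ensemble(base[None] + noise)
    prof = rmsf(traj, Selection(name="CA"), superpose=False)
    ratio = prof.rmsf[20:].mean() / prof.rmsf[:20].mean()
    assert ratio == pytest.approx(4.0, rel=0.05)
    # the superposed estimator still clearly separates the blocks, though
    # the rigid fit redistributes some variance toward the quiet block
    prof_sup = rmsf(traj, Selection(name="CA"))
    assert prof_sup.rmsf[20:].mean() / prof_sup.rmsf[:20].mean() > 2.5


def test_single_frame_rmsf_rejected(rng):
    traj = coords_ensemble(rng.normal(size=(1, 5, 3)))
    with pytest.raises(GeometryError):
        rmsf(traj, Selection(name="CA"))


# ---------------------------------------------------------------------------
# correlation matrix


def test_duplicated_node_fully_correlated(rng):
    disp = rng.normal(size=(200, 1, 3))
    frames = np.concatenate([disp, disp + 5.0], axis=1)  # same motion, offset
    cm = correlation_matrix(coords_ensemble(frames), Selection(name="CA"),
                            superpose=False)
    assert cm.C[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_mirrored_displacements_anticorrelated(rng):
    disp = rng.normal(size=(300, 1, 3))
    frames = np.concatenate([disp, -disp + 10.0], axis=1)
    cm = correlation_matrix(coords_ensemble(frames), Selection(name="CA"),
                            superpose=False)
    assert cm.C[0, 1] == pytest.approx(-1.0, abs=1e-12)


def test_block_correlation_recovery():
    spec = TrajectorySpec(n_residues=20, n_frames=5000, corridor=(),
                          block_structure=[(range(2, 9), 0.9)], seed=9)
    cm = correlation_matrix(make_correlated_trajectory(spec),
                            Selection(name="CA"), superpose=False)
    assert np.abs(cm.C - spec.target_correlation()).max() < 0.05


def test_correlation_matrix_invariants(rng):
    traj = make_correlated_trajectory(TrajectorySpec(n_frames=300, seed=10))
    C = correlation_matrix(traj, Selection(name="CA")).C
    assert np.allclose(C, C.T)
    assert np.allclose(np.diag(C), 1.0)
    assert C.max() <= 1.0 and C.min() >= -1.0


def test_correlation_invariant_under_per_frame_rigid_motion(rng):
    traj = make_correlated_trajectory(TrajectorySpec(n_residues=12, n_frames=400,
                                                     corridor=(1, 5, 9), seed=11))
    X = traj.coords()
    moved = np.empty_like(X)
    for t in range(X.shape[0]):
        R, tr = random_rigid_motion(rng)
        moved[t] = X[t] @ R.T + tr
    a = correlation_matrix(traj, Selection(name="CA"), superpose=True).C
    b = correlation_matrix(coords_ensemble(moved), Selection(name="CA"),
                           superpose=True).C
    assert np.abs(a - b).max() < 1e-6


def test_zero_variance_atom_warns_and_zeroes(rng):
    frames = rng.normal(size=(100, 3, 3))
    frames[:, 2] = 7.0  # frozen atom
    with pytest.warns(UserWarning, match="zero-variance"):
        cm = correlation_matrix(coords_ensemble(frames), Selection(name="CA"),
                                superpose=False)
    assert np.all(cm.C[2, :2] == 0.0) and cm.C[2, 2] == 1.0


# ---------------------------------------------------------------------------
# B-factor statistics


def uniform_b_model(protein_b, ligand_b):
    rows = [("CA", "C", "ALA", i, "A", (3.8 * i, 0, 0), 1.0, protein_b)
            for i in range(5)]
    rows += [(f"C{i}", "C", "LIG", 50, "L", (i, 5, 0), 1.0, ligand_b)
             for i in range(3)]
    return build_model(rows), list(range(5, 8)), list(range(5))


def test_uniform_b_gives_unit_ratio():
    m, lig, prot = uniform_b_model(50.0, 50.0)
    assert bfactor_ratio(m, lig, prot).ratio == pytest.approx(1.0)


def test_doubled_ligand_b_gives_ratio_two():
    m, lig, prot = uniform_b_model(25.0, 50.0)
    assert bfactor_ratio(m, lig, prot).ratio == pytest.approx(2.0)


def test_refinement_table_means_give_1_63():
    """Mean ligand B 61.5 over mean protein B 37.7 is 1.63 at 2 d.p."""
    m, lig, prot = uniform_b_model(37.7, 61.5)
    assert round(bfactor_ratio(m, lig, prot).ratio, 2) == 1.63


def test_occupancy_weighting():
    rows = [("CA", "C", "ALA", 1, "A", (0, 0, 0), 1.0, 40.0),
            ("C1", "C", "LIG", 9, "L", (5, 0, 0), 0.75, 80.0),
            ("C1", "C", "LIG", 9, "L", (6, 0, 0), 0.25, 40.0, "B")]
    m = build_model(rows)
    st = bfactor_ratio(m, [1, 2], [0])
    assert st.mean_ligand_B == pytest.approx(0.75 * 80 + 0.25 * 40)


def test_ttest_trivial_and_shifted_cases():
    t, p = compare_bfactor_ratios([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (t, p) == (0.0, 1.0)
    t, p = compare_bfactor_ratios([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
    # closed form: |t| = 10 / sqrt(1 * 2/3), df = 4
    assert p == pytest.approx(2 * stats.t.sf(10 / np.sqrt(2 / 3), 4), abs=1e-12)
    assert p < 1e-3


def test_ttest_matches_textbook_formula(rng):
    a = rng.normal(2.1, 0.4, size=9)
    b = rng.normal(1.6, 0.1, size=12)
    t, p = compare_bfactor_ratios(a, b)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
        na + nb - 2)
    t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p_hand = 2 * stats.t.sf(abs(t_hand), na + nb - 2)
    assert t == pytest.approx(t_hand, abs=1e-12)
    assert p == pytest.approx(p_hand, abs=1e-12)


def test_degenerate_zero_variance_samples_raise():
    with pytest.raises(FitError):
        compare_bfactor_ratios([1.0, 1.0], [2.0, 2.0])
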