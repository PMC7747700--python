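"""Shared fixtures: tiny hand-built structures and generator shortcuts."""

from __future__ import annotations

import numpy as np
import pytest

from allopath.ensemble_io import Atom, Ensemble, StructureModel


def build_model(atom_rows, model_id=1):
    """Construct a StructureModel from rows of
    (name, element, resname, resid, chain, (x, y, z)) with optional
    trailing occupancy / bfactor / altloc entries."""
    atoms = []
    for i, row in enumerate(atom_rows):
        name, element, resname, resid, chain, xyz = row[:6]
        occ = row[6] if len(row) > 6 else 1.0
        b = row[7] if len(row) > 7 else 20.0
        alt = row[8] if len(row) > 8 else ""
        atoms.append(
            Atom(serial=i + 1, name=name, element=element, resname=resname,
                 resid=resid, chain=chain, altloc=alt, occupancy=occ,
                 bfactor=b, coords=np.asarray(xyz, float))
        )
    return StructureModel(model_id=model_id, atoms=atoms)


def build_ensemble(models):
    return Ensemble(models=models)


def coords_ensemble(frames, name="CA", resname="ALA", chain="A"):
    """Ensemble of single-atom-per-residue models from an (n_frames,
    n_atoms, 3) array; atom i gets resid i+1."""
    frames = np.asarray(frames, float)
    models = []
    for t, frame in enumerate(frames):
        rows = [
            (name, "C", resname, i + 1, chain, xyz) for i, xyz in enumerate(frame)
        ]
        models.append(build_model(rows, model_id=t + 1))
    return Ensemble(models=models)


def random_rigid_motion(rng):
    """A uniformly random proper rotation matrix and a random translation."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix(), rng.uniform(-20, 20, size=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
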