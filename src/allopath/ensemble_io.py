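"""Multi-model structure I/O, atom selection and entity classification.

Crystallographic ensemble-refinement output and coordinate trajectories are
both represented as an :class:`Ensemble`: an ordered list of models sharing
one atom topology.  Files are parsed with :mod:`gemmi` and written back out
in fixed-column PDB v3.3 format; a plain-text per-frame XYZ table dialect is
supported as a second trajectory format.

Residue numbering is taken verbatim from the file (author numbering) and
coordinates are in Angstrom throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import ParseError, SelectionError, TopologyError

logger = logging.getLogger(__name__)

#: Residue names treated as protein.  Deliberately the 20 standard amino
#: acids: modified residues deposited as HETATM (e.g. MSE) fall into the
#: ligand class, which is logged when it happens.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Residue names recognized as water (configurable per call).
WATER_RESNAMES = frozenset({"HOH", "WAT"})


@dataclass
class Atom:
    """One atom of one model.

    Coordinates are Angstrom; ``bfactor`` is the isotropic B-factor in
    Angstrom^2; ``altloc`` is '' when the atom has a single location.
    """

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    altloc: str
    occupancy: float
    bfactor: float
    coords: np.ndarray

    def key(self) -> tuple:
        """Topology identity of the atom: (chain, resid, name, altloc)."""
        return (self.chain, self.resid, self.name, self.altloc)


@dataclass
class StructureModel:
    """One coordinate model (ensemble member or trajectory frame)."""

    model_id: int
    atoms: list[Atom]

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, file order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class Ensemble:
    """Ordered models sharing one atom topology.

    Every model must have the same atom count and the same sequence of
    (chain, resid, name, altloc) keys; this is validated on construction.
    """

    models: list[StructureModel]
    topology_key: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.models:
            raise TopologyError("an Ensemble needs at least one model")
        ref = [a.key() for a in self.models[0].atoms]
        for m in self.models[1:]:
            keys = [a.key() for a in m.atoms]
            if keys != ref:
                raise TopologyError(
                    f"model {m.model_id} has inconsistent topology "
                    f"({len(keys)} atoms vs {len(ref)} in model "
                    f"{self.models[0].model_id})"
                )
        if not self.topology_key:
            self.topology_key = ref

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_atoms(self) -> int:
        return len(self.models[0].atoms)

    def coords(self) -> np.ndarray:
        """(n_models, n_atoms, 3) coordinate array."""
        return np.stack([m.coords for m in self.models])

    def select(self, sel: "Selection") -> np.ndarray:
        return select_atoms(self, sel)


@dataclass(frozen=True)
class Selection:
    """Predicate over atom fields; fields left as None do not constrain.

    ``resid`` accepts a single residue number or an iterable of numbers;
    ``entity`` is one of 'protein', 'ligand', 'water' under the default
    classification rule of :func:`classify_entities`.
    """

    chain: str | None = None
    resid: int | Iterable[int] | None = None
    resname: str | Iterable[str] | None = None
    name: str | Iterable[str] | None = None
    element: str | Iterable[str] | None = None
    altloc: str | Iterable[str] | None = None
    entity: str | None = None

    def _as_set(self, value) -> frozenset | None:
        if value is None:
            return None
        if isinstance(value, (str, int)):
            return frozenset({value})
        return frozenset(value)

    def matches(self, atom: Atom) -> bool:
        for attr in ("chain", "resid", "resname", "name", "element", "altloc"):
            allowed = self._as_set(getattr(self, attr))
            if allowed is not None and getattr(atom, attr) not in allowed:
                return False
        if self.entity is not None:
            if self.entity not in ("protein", "ligand", "water"):
                raise SelectionError(f"unknown entity class {self.entity!r}")
            if _entity_of(atom) != self.entity:
                return False
        return True


def _entity_of(atom: Atom, water_resnames: frozenset = WATER_RESNAMES) -> str:
    if atom.resname in water_resnames:
        return "water"
    if atom.resname in STANDARD_AA:
        return "protein"
    return "ligand"


# ---------------------------------------------------------------------------
# PDB reading / writing


def _validate_pdb_lines(path: Path) -> None:
    """Pre-scan coordinate records so parse errors carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                    fieldtxt = line[lo:hi].strip()
                    try:
                        value = float(fieldtxt)
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: unparseable {what} coordinate "
                            f"field {fieldtxt!r}"
                        ) from None
                    if not np.isfinite(value):
                        raise ParseError(
                            f"{path}:{lineno}: non-finite {what} coordinate"
                        )


def read_multimodel_pdb(path: str | Path) -> Ensemble:
    """Read a (possibly multi-model) PDB file into an :class:`Ensemble`.

    MODEL/ENDMDL blocks become successive models; a file without MODEL
    records yields a single-model ensemble.  HETATM records, altlocs,
    occupancies and B-factors are preserved.

    Raises
    ------
    ParseError
        On an unparseable coordinate field (the message names the line).
    TopologyError
        When models disagree on atom count or identity (the message names
        the first offending model).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_lines(path)
    try:
        st = gemmi.read_pdb(str(path))
    except Exception as exc:  # pragma: no cover - gemmi is lenient
        raise ParseError(f"{path}: {exc}") from exc
    models: list[StructureModel] = []
    for gm in st:
        atoms: list[Atom] = []
        for chain in gm:
            for res in chain:
                for at in res:
                    altloc = "" if at.altloc in ("\0", " ", "") else at.altloc
                    atoms.append(
                        Atom(
                            serial=at.serial,
                            name=at.name,
                            element=at.element.name,
                            resname=res.name,
                            resid=res.seqid.num,
                            chain=chain.name,
                            altloc=altloc,
                            occupancy=round(float(at.occ), 2),
                            bfactor=round(float(at.b_iso), 2),
                            coords=np.array(
                                [at.pos.x, at.pos.y, at.pos.z], dtype=float
                            ),
                        )
                    )
        models.append(StructureModel(model_id=int(gm.num), atoms=atoms))
    if not models:
        raise ParseError(f"{path}: no coordinate records found")
    n0 = len(models[0].atoms)
    for m in models[1:]:
        if len(m.atoms) != n0:
            raise TopologyError(
                f"{path}: model {m.model_id} has {len(m.atoms)} atoms, "
                f"expected {n0}"
            )
    return Ensemble(models=models)


def _format_atom_name(name: str, element: str) -> str:
    """PDB columns 13-16: short names of 1-letter elements start in col 14."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def _atom_record(atom: Atom) -> str:
    record = "ATOM" if atom.resname in STANDARD_AA else "HETATM"
    x, y, z = atom.coords
    return (
        f"{record:<6}{atom.serial:>5} {_format_atom_name(atom.name, atom.element)}"
        f"{atom.altloc or ' '}{atom.resname:>3} {atom.chain[:1] or 'A'}"
        f"{atom.resid:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}          {atom.element:>2}"
    )


def write_multimodel_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble in fixed-column PDB v3.3 format.

    Round trip through :func:`read_multimodel_pdb` preserves identifiers
    exactly, coordinates to 3 decimals and occupancy/B-factor to 2 decimals.
    """
    path = Path(path)
    lines: list[str] = []
    multi = ensemble.n_models > 1
    for model in ensemble.models:
        if multi:
            lines.append(f"MODEL     {model.model_id:>4}")
        lines.extend(_atom_record(a) for a in model.atoms)
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# XYZ-table trajectory dialect

XYZ_COLUMNS = ["frame", "chain", "resid", "name", "x", "y", "z"]


def read_xyz_table(path: str | Path) -> Ensemble:
    """Read the TSV trajectory dialect (frame, chain, resid, name, x, y, z).

    Atoms are assigned element 'C', unit occupancy and zero B-factor; each
    distinct frame value becomes one model, in order of first appearance.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in XYZ_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    models = []
    for frame, grp in df.groupby("frame", sort=True):
        atoms = [
            Atom(
                serial=i + 1,
                name=str(name),
                element="C",
                resname="GLY",
                resid=int(resid),
                chain=str(chain),
                altloc="",
                occupancy=1.0,
                bfactor=0.0,
                coords=np.array([x, y, z], dtype=float),
            )
            for i, (chain, resid, name, x, y, z) in enumerate(
                zip(grp["chain"], grp["resid"], grp["name"],
                    grp["x"], grp["y"], grp["z"])
            )
        ]
        models.append(StructureModel(model_id=int(frame), atoms=atoms))
    if not models:
        raise ParseError(f"{path}: empty trajectory table")
    return Ensemble(models=models)


def write_xyz_table(ensemble: Ensemble, path: str | Path) -> None:
    rows = [
        (m.model_id, a.chain, a.resid, a.name, *a.coords)
        for m in ensemble.models
        for a in m.atoms
    ]
    pd.DataFrame(rows, columns=XYZ_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )


# ---------------------------------------------------------------------------
# Selection and classification


def select_atoms(ensemble: Ensemble, sel: Selection) -> np.ndarray:
    """Indices (file order) of atoms matching ``sel``.

    Because all models share one topology the same indices are valid in
    every model.  An empty result is not an error.
    """
    if not isinstance(sel, Selection):
        raise SelectionError(f"expected a Selection, got {type(sel).__name__}")
    atoms = ensemble.models[0].atoms
    return np.array([i for i, a in enumerate(atoms) if sel.matches(a)], dtype=int)


def select_single_atom(ensemble_or_model, sel: Selection) -> int:
    """Resolve a selection expected to match exactly one atom."""
    if isinstance(ensemble_or_model, StructureModel):
        atoms = ensemble_or_model.atoms
        idx = [i for i, a in enumerate(atoms) if sel.matches(a)]
    else:
        idx = list(select_atoms(ensemble_or_model, sel))
    if len(idx) != 1:
        raise SelectionError(f"selection {sel} resolved to {len(idx)} atoms, expected 1")
    return int(idx[0])


def classify_entities(
    ensemble: Ensemble, water_resnames: Iterable[str] = WATER_RESNAMES
) -> dict[str, np.ndarray]:
    """Partition atoms into protein / ligand / water index arrays.

    Protein = the 20 standard amino-acid residue names; water = resname in
    ``water_resnames``; everything else (including modified residues such
    as MSE) = ligand, with a log message for non-water HETATM resnames that
    look polymeric.
    """
    water = frozenset(water_resnames)
    out: dict[str, list[int]] = {"protein": [], "ligand": [], "water": []}
    seen_unknown: set[str] = set()
    for i, atom in enumerate(ensemble.models[0].atoms):
        cls = _entity_of(atom, water)
        out[cls].append(i)
        if cls == "ligand" and atom.resname not in seen_unknown:
            seen_unknown.add(atom.resname)
            logger.info("residue %s classified as ligand", atom.resname)
    return {k: np.array(v, dtype=int) for k, v in out.items()}


def highest_occupancy_altloc(ensemble: Ensemble) -> np.ndarray:
    """Indices keeping, for each (chain, resid, name), only the altloc of
    highest occupancy (ties broken by altloc letter).  Atoms without
    alternates are always kept."""
    atoms = ensemble.models[0].atoms
    best: dict[tuple, int] = {}
    for i, a in enumerate(atoms):
        k = (a.chain, a.resid, a.name)
        if k not in best:
            best[k] = i
            continue
        b = atoms[best[k]]
        if a.occupancy > b.occupancy or (
            a.occupancy == b.occupancy and a.altloc < b.altloc
        ):
            best[k] = i
    return np.array(sorted(best.values()), dtype=int)


def residue_groups(
    ensemble: Ensemble, indices: Sequence[int] | None = None
) -> dict[tuple[str, int], np.ndarray]:
    """Map (chain, resid) -> atom indices, preserving file order."""
    atoms = ensemble.models[0].atoms
    if indices is None:
        indices = range(len(atoms))
    groups: dict[tuple[str, int], list[int]] = {}
    for i in indices:
        a = atoms[int(i)]
        groups.setdefault((a.chain, a.resid), []).append(int(i))
    return {k: np.array(v, dtype=int) for k, v in groups.items()}
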