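"""Geometric interaction criteria and their persistence over an ensemble.

Three criteria are implemented, matching the conventions used to analyse
ligand stability in nuclear-receptor ligand-binding-domain ensembles:

* hydrogen bond: heavy-atom donor--acceptor distance below a cutoff
  (default 3.5 A, no angle term);
* edge-to-face pi-pi stacking: angle between the two aromatic ring planes
  within [60, 120] degrees and ring-centroid distance within 5.5 A;
* water-network intactness: the number of water oxygens connected (directly
  or through other network waters) to at least one polar anchor atom within
  a linking distance, counted as a graph connected component.

``persistence`` applies any per-model evaluator over an ensemble (which may
equally be a trajectory) and reports the fraction of models in which the
criterion holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .ensemble_io import Ensemble, Selection, StructureModel, select_single_atom
from .errors import GeometryError, SelectionError, SpecificationError

__all__ = [
    "HBondCriterion",
    "AromaticRing",
    "StackingCriterion",
    "WaterNetworkSpec",
    "PersistenceResult",
    "hbond_satisfied",
    "ring_geometry",
    "edge_to_face_satisfied",
    "water_network_state",
    "persistence",
]


@dataclass(frozen=True)
class HBondCriterion:
    """Distance-only hydrogen-bond rule between two single-atom selections."""

    donor: Selection
    acceptor: Selection
    dmax: float = 3.5

    def __post_init__(self):
        if self.dmax <= 0:
            raise SpecificationError("H-bond dmax must be positive")


@dataclass(frozen=True)
class AromaticRing:
    """An aromatic ring given by the indices of its ring atoms (5 or 6)."""

    atom_indices: tuple[int, ...]

    def __post_init__(self):
        if not 5 <= len(self.atom_indices) <= 6:
            raise SpecificationError(
                f"aromatic ring needs 5-6 atoms, got {len(self.atom_indices)}"
            )


@dataclass(frozen=True)
class StackingCriterion:
    """Edge-to-face stacking window: plane angle and centroid distance."""

    angle_min: float = 60.0
    angle_max: float = 120.0
    centroid_dmax: float = 5.5

    def __post_init__(self):
        if not (0 <= self.angle_min <= self.angle_max <= 180):
            raise SpecificationError("stacking angle window must lie in [0, 180]")


@dataclass(frozen=True)
class WaterNetworkSpec:
    """Water-network rule: anchors, expected size and linking distance."""

    anchors: Selection | tuple[int, ...]
    expected_count: int = 4
    link_dmax: float = 3.5
    # 'component': waters connected to an anchor through the water graph;
    # 'radius': waters within link_dmax of any anchor directly.
    rule: str = "component"

    def __post_init__(self):
        if self.expected_count < 1:
            raise SpecificationError("expected_count must be >= 1")
        if self.rule not in ("component", "radius"):
            raise SpecificationError(f"unknown water-network rule {self.rule!r}")


@dataclass
class PersistenceResult:
    """Per-model satisfaction of a criterion plus summary fractions."""

    per_model: list[bool]
    values: list[float] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.per_model)

    @property
    def n_true(self) -> int:
        return sum(self.per_model)

    @property
    def fraction(self) -> float:
        return self.n_true / self.n_models

    @property
    def percent_rounded(self) -> int:
        # half-up, to match how occupancies are conventionally reported
        return int(np.floor(100.0 * self.fraction + 0.5))


# ---------------------------------------------------------------------------


def hbond_satisfied(
    model: StructureModel, crit: HBondCriterion
) -> tuple[bool, float]:
    """Evaluate the distance H-bond rule on one model.

    Returns (satisfied, donor-acceptor distance in A); satisfied is True
    iff distance < ``crit.dmax`` (strict).  Symmetric in donor/acceptor.
    """
    i = select_single_atom(model, crit.donor)
    j = select_single_atom(model, crit.acceptor)
    d = float(np.linalg.norm(model.atoms[i].coords - model.atoms[j].coords))
    return d < crit.dmax, d


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through >= 3 points."""
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear points: the two largest singular values collapse to one
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise GeometryError("ring atoms are collinear; plane undefined")
    return vt[2]


def ring_geometry(
    model: StructureModel, ring1: AromaticRing, ring2: AromaticRing
) -> tuple[float, float]:
    """Angle between ring planes (degrees, in [0, 180)) and centroid distance.

    Plane normals come from a least-squares (SVD) plane fit; the raw angle
    between normals is reported without folding, which is immaterial for
    the symmetric [60, 120] stacking window.
    """
    c1 = np.array([model.atoms[i].coords for i in ring1.atom_indices])
    c2 = np.array([model.atoms[i].coords for i in ring2.atom_indices])
    n1, n2 = _plane_normal(c1), _plane_normal(c2)
    cosang = float(np.clip(np.dot(n1, n2), -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang))) % 180.0
    dist = float(np.linalg.norm(c1.mean(axis=0) - c2.mean(axis=0)))
    return angle, dist


def edge_to_face_satisfied(
    model: StructureModel,
    ring1: AromaticRing,
    ring2: AromaticRing,
    crit: StackingCriterion = StackingCriterion(),
) -> bool:
    """True iff the plane angle is inside the window and centroids within
    the distance cutoff.  Symmetric in the two rings."""
    angle, dist = ring_geometry(model, ring1, ring2)
    return crit.angle_min <= angle <= crit.angle_max and dist <= crit.centroid_dmax


def _resolve_anchor_indices(
    model: StructureModel, anchors: Selection | Sequence[int]
) -> list[int]:
    if isinstance(anchors, Selection):
        idx = [i for i, a in enumerate(model.atoms) if anchors.matches(a)]
    else:
        idx = [int(i) for i in anchors]
    if not idx:
        raise SpecificationError("water-network spec resolves no anchor atoms")
    return idx


def water_network_state(
    model: StructureModel,
    spec: WaterNetworkSpec,
    water_resnames: frozenset = frozenset({"HOH", "WAT"}),
) -> tuple[int, bool]:
    """Count network waters in one model and test intactness.

    Under the default 'component' rule the network size is the number of
    water oxygens in graph components (edges: pairwise distance <
    ``link_dmax`` over anchors and waters) that contain at least one
    anchor; 'radius' counts waters directly within ``link_dmax`` of any
    anchor.  Intact iff the count reaches ``expected_count``.
    """
    anchors = _resolve_anchor_indices(model, spec.anchors)
    waters = [
        i
        for i, a in enumerate(model.atoms)
        if a.resname in water_resnames and a.element == "O"
    ]
    if not waters:
        return 0, False
    acoords = np.array([model.atoms[i].coords for i in anchors])
    wcoords = np.array([model.atoms[i].coords for i in waters])
    if spec.rule == "radius":
        n = int(np.sum(cdist(wcoords, acoords).min(axis=1) < spec.link_dmax))
        return n, n >= spec.expected_count
    nodes = anchors + waters
    coords = np.vstack([acoords, wcoords])
    dmat = cdist(coords, coords)
    graph = nx.Graph()
    graph.add_nodes_from(range(len(nodes)))
    ii, jj = np.nonzero(np.triu(dmat < spec.link_dmax, k=1))
    graph.add_edges_from(zip(ii.tolist(), jj.tolist()))
    anchor_set = set(range(len(anchors)))
    n = 0
    for comp in nx.connected_components(graph):
        if comp & anchor_set:
            n += sum(1 for node in comp if node not in anchor_set)
    return n, n >= spec.expected_count


def persistence(
    ensemble: Ensemble,
    evaluator: Callable[[StructureModel], bool | tuple],
) -> PersistenceResult:
    """Apply a per-model boolean evaluator over every model of an ensemble.

    The evaluator may return a bare bool or a (bool, value) tuple, in which
    case the auxiliary values (distances, angles, counts) are collected in
    ``PersistenceResult.values``.  A failure on any model is re-raised with
    the offending model id named.
    """
    per_model: list[bool] = []
    values: list[float] = []
    for model in ensemble.models:
        try:
            out = evaluator(model)
        except (SelectionError, GeometryError, SpecificationError) as exc:
            raise type(exc)(f"model {model.model_id}: {exc}") from exc
        if isinstance(out, tuple):
            per_model.append(bool(out[0]))
            values.append(float(out[1]))
        else:
            per_model.append(bool(out))
    return PersistenceResult(per_model=per_model, values=values)
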