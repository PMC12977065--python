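"""Constrained distance-geometry sampling of transition-state conformers.

The reaction-center positions and all pairwise distances among the frozen
atoms are taken from the input structure and written into the distance
bounds matrix with a symmetric slack (``tolerance``, default 0.01 A).  The
distance-geometry backend (RDKit ETKDG) is used as a primitive; this module
owns constraint construction and conformer acceptance:

* every fixed distance must be reproduced within ``tolerance + 0.1`` A;
* after rigid superposition of the frozen core onto the input, every
  reaction-center atom must lie within 0.2 A of its fixed position;
* mirror images of the frozen core (distance geometry is chirality-blind)
  are rejected via a signed-volume check on a non-planar frozen quadruple.

Bonds incident to reaction-center atoms are encoded with zero bond order so
exotic valences (pentacoordinate carbons, metal centers) never trip the
backend's valence model; their geometry is fully pinned by the bounds matrix.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import networkx as nx
import numpy as np
import yaml
from rdkit import Chem, DistanceGeometry
from rdkit.Chem import rdDistGeom
from rdkit.Geometry import Point3D

from .errors import EmbeddingError, GeometryError, ValidationError
from .pruning import superpose
from .structure_io import Ensemble, Member, Structure
from .topology import FrozenAtomSet, ReactionCenter, Topology

log = logging.getLogger(__name__)

__all__ = [
    "ConstraintSpec",
    "GenerationConfig",
    "build_constraints",
    "count_free_rotatable_bonds",
    "n_initial_conformers",
    "embed_conformers",
    "mol_from_topology",
]

_BOND_TYPES = {
    0.0: Chem.BondType.ZERO,
    1.0: Chem.BondType.SINGLE,
    1.5: Chem.BondType.AROMATIC,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
}


@dataclass
class ConstraintSpec:
    """Fixed reaction-center positions and frozen-atom pairwise distances."""

    fixed_positions: Dict[int, np.ndarray] = field(default_factory=dict)
    fixed_distances: Dict[Tuple[int, int], float] = field(default_factory=dict)
    tolerance: float = 0.01

    def __post_init__(self) -> None:
        self.fixed_positions = {
            int(i): np.asarray(p, dtype=float) for i, p in self.fixed_positions.items()
        }
        canon = {}
        for (i, j), d in self.fixed_distances.items():
            if d <= 0:
                raise ValidationError(f"non-positive target distance for pair ({i},{j})")
            canon[(min(i, j), max(i, j))] = float(d)
        self.fixed_distances = canon

    @property
    def frozen_indices(self) -> Tuple[int, ...]:
        atoms = set(self.fixed_positions)
        for i, j in self.fixed_distances:
            atoms.update((i, j))
        return tuple(sorted(atoms))

    def to_yaml(self) -> str:
        data = {
            "tolerance": self.tolerance,
            "fixed_positions": {
                int(i): [float(x) for x in p] for i, p in sorted(self.fixed_positions.items())
            },
            "fixed_distances": {
                f"{i}-{j}": float(d) for (i, j), d in sorted(self.fixed_distances.items())
            },
        }
        return yaml.safe_dump(data, sort_keys=True)


@dataclass
class GenerationConfig:
    """Knobs of the conformer generator."""

    conf_factor: int = 30
    seed: int = 0
    max_embed_attempts: Optional[int] = None

    def __post_init__(self) -> None:
        if self.conf_factor < 1:
            raise ValidationError("conf_factor must be >= 1")


def build_constraints(
    structure: Structure,
    frozen: FrozenAtomSet,
    reaction_center: ReactionCenter,
    tolerance: float = 0.01,
) -> ConstraintSpec:
    """Measure constraint targets off the input structure.

    Positions are fixed for every reaction-center atom; distances are fixed
    for every unordered pair of frozen atoms.
    """
    if not set(reaction_center.indices) <= set(frozen.indices) and reaction_center.indices:
        raise ValidationError("frozen set must contain the reaction center")
    fixed_positions = {i: structure.coords[i] for i in sorted(reaction_center.indices)}
    fixed_distances = {}
    frozen_sorted = sorted(frozen.indices)
    for a, i in enumerate(frozen_sorted):
        for j in frozen_sorted[a + 1:]:
            d = structure.distance(i, j)
            if d < 0.4:
                raise GeometryError(
                    f"frozen atoms {i} and {j} are {d:.3f} A apart (< 0.4 A)"
                )
            fixed_distances[(i, j)] = d
    return ConstraintSpec(fixed_positions, fixed_distances, tolerance=tolerance)


def count_free_rotatable_bonds(topology: Topology, frozen: FrozenAtomSet) -> int:
    """Rotatable bonds outside the frozen set.

    A bond counts as rotatable when it is acyclic, both endpoints have at
    least two neighbors, and at least one endpoint is not frozen.
    """
    g = topology.graph()
    cyclic = set()
    for cycle in nx.cycle_basis(g):
        for k in range(len(cycle)):
            i, j = cycle[k], cycle[(k + 1) % len(cycle)]
            cyclic.add((min(i, j), max(i, j)))
    n = 0
    for (i, j) in topology.bonds:
        if (i, j) in cyclic:
            continue
        if g.degree(i) < 2 or g.degree(j) < 2:
            continue
        if i in frozen and j in frozen:
            continue
        n += 1
    return n


def n_initial_conformers(
    config: GenerationConfig, topology: Topology, frozen: Optional[FrozenAtomSet] = None
) -> int:
    """``conf_factor x max(1, free rotatable bonds)``, deterministically."""
    if frozen is None:
        frozen = FrozenAtomSet(frozenset())
    return config.conf_factor * max(1, count_free_rotatable_bonds(topology, frozen))


def mol_from_topology(
    topology: Topology,
    zero_order_atoms: Tuple[int, ...] = (),
    drop_bond_atoms: Tuple[int, ...] = (),
    coords: Optional[np.ndarray] = None,
) -> Chem.Mol:
    """Build an RDKit mol mirroring a :class:`Topology`.

    ``zero_order_atoms``: bonds incident to these atoms get zero bond order
    (valence-model safe, distance handled elsewhere).  ``drop_bond_atoms``:
    bonds with *both* endpoints in this set are omitted entirely.
    """
    zero = set(zero_order_atoms)
    drop = set(drop_bond_atoms)
    rw = Chem.RWMol()
    for k, s in enumerate(topology.structure.symbols):
        atom = Chem.Atom(s)
        atom.SetNoImplicit(True)
        if topology.formal_charges is not None:
            atom.SetFormalCharge(topology.formal_charges[k])
        rw.AddAtom(atom)
    for (i, j), order in topology.bonds.items():
        if i in drop and j in drop:
            continue
        if i in zero or j in zero:
            bt = Chem.BondType.ZERO
        else:
            bt = _BOND_TYPES.get(order, Chem.BondType.SINGLE)
        rw.AddBond(i, j, bt)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
        )
    except Exception:
        Chem.FastFindRings(mol)
    if coords is not None:
        conf = Chem.Conformer(mol.GetNumAtoms())
        for k, c in enumerate(np.asarray(coords, dtype=float)):
            conf.SetAtomPosition(k, [float(x) for x in c])
        mol.AddConformer(conf, assignId=True)
    return mol


def _valence_ok(mol: Chem.Mol) -> bool:
    try:
        Chem.SanitizeMol(Chem.Mol(mol), Chem.SanitizeFlags.SANITIZE_PROPERTIES)
        return True
    except Exception:
        return False


def _embedding_mol(
    topology: Topology, constraints: ConstraintSpec, rc_sorted, frozen_sorted
) -> Chem.Mol:
    """RDKit mol for the DG backend.

    Close unbonded frozen pairs (forming/breaking bonds, detached fragments)
    get just enough zero-order helper bonds to keep the DG graph connected;
    adding the whole frozen clique degrades the backend's refinement stage.
    Real bonds keep their orders when the valence model tolerates them and
    are demoted to zero order around the reaction center otherwise.
    """
    structure = topology.structure
    bonds = dict(topology.bonds)
    g = nx.Graph()
    g.add_nodes_from(range(structure.n_atoms))
    g.add_edges_from(bonds)
    for (i, j), d in sorted(constraints.fixed_distances.items(), key=lambda kv: kv[1]):
        if d < 3.2 and not nx.has_path(g, i, j):
            bonds[(i, j)] = 0.0
            g.add_edge(i, j)

    rc = set(rc_sorted)
    frozen = set(frozen_sorted)
    variants = [
        bonds,
        {p: (0.0 if (o is None and (p[0] in rc or p[1] in rc)) else o)
         for p, o in bonds.items()},
        {p: (0.0 if (p[0] in rc or p[1] in rc) else o) for p, o in bonds.items()},
        {p: (0.0 if (p[0] in frozen and p[1] in frozen) else o)
         for p, o in bonds.items()},
    ]
    topo_kwargs = dict(formal_charges=None, connectivity_only=True)
    mol = None
    for var in variants:
        mol = mol_from_topology(Topology(structure, var, **topo_kwargs))
        if _valence_ok(mol):
            return mol
    return mol  # let the backend report the remaining problem


def _signed_volume(coords: np.ndarray, quad) -> float:
    a, b, c, d = (coords[k] for k in quad)
    return float(np.dot(b - a, np.cross(c - a, d - a))) / 6.0


def _chirality_reference(coords: np.ndarray, frozen_sorted, min_volume: float = 0.1):
    """First frozen quadruple with a clearly non-planar signed volume."""
    for quad in itertools.combinations(frozen_sorted, 4):
        v = _signed_volume(coords, quad)
        if abs(v) > min_volume:
            return quad, v
    return None, 0.0


def embed_conformers(
    topology: Topology, constraints: ConstraintSpec, config: GenerationConfig
) -> Ensemble:
    """Sample conformers by repeated constrained distance-geometry embedding.

    Returns an unranked :class:`Ensemble` (energies ``None``) whose members
    all satisfy the constraint spec; failed attempts are skipped and counted.
    Deterministic for a fixed :attr:`GenerationConfig.seed`.
    """
    structure = topology.structure
    frozen_sorted = list(constraints.frozen_indices)
    rc_sorted = sorted(constraints.fixed_positions)
    frozen_set = FrozenAtomSet(frozenset(frozen_sorted))

    target = n_initial_conformers(config, topology, frozen_set)
    max_attempts = config.max_embed_attempts or 10 * target

    mol = _embedding_mol(topology, constraints, rc_sorted, frozen_sorted)
    bm = rdDistGeom.GetMoleculeBoundsMatrix(mol)
    for (i, j), d in constraints.fixed_distances.items():
        bm[min(i, j), max(i, j)] = d + constraints.tolerance
        bm[max(i, j), min(i, j)] = max(d - constraints.tolerance, 0.0)
    if not DistanceGeometry.DoTriangleSmoothing(bm):
        raise EmbeddingError("constraint bounds failed triangle smoothing")

    ref_quad, ref_vol = (None, 0.0)
    if len(frozen_sorted) >= 4:
        ref_quad, ref_vol = _chirality_reference(structure.coords, frozen_sorted)

    frozen_ref = structure.coords[frozen_sorted]
    dist_tol = constraints.tolerance + 0.1

    accepted = []
    attempts = 0
    rejects = {"distance": 0, "chirality": 0, "position": 0}
    round_no = 0
    while len(accepted) < target and attempts < max_attempts:
        want = min(target - len(accepted), max_attempts - attempts)
        params = rdDistGeom.ETKDGv3()
        params.randomSeed = int(config.seed) % (2**31 - 1) + 7919 * round_no + 1
        params.useRandomCoords = True
        params.SetBoundsMat(bm)
        if frozen_sorted:
            # seed the frozen core at its input coordinates: positions of the
            # reaction center (and, by fixed pairwise distances, the whole
            # core) are constrained, so embed straight into that frame
            params.SetCoordMap({
                int(i): Point3D(*map(float, structure.coords[i]))
                for i in frozen_sorted
            })
        work = Chem.Mol(mol)
        cids = rdDistGeom.EmbedMultipleConfs(work, want, params)
        attempts += want
        round_no += 1
        for cid in cids:
            pos = work.GetConformer(cid).GetPositions()
            ok = True
            for (i, j), d in constraints.fixed_distances.items():
                if abs(np.linalg.norm(pos[i] - pos[j]) - d) > dist_tol:
                    rejects["distance"] += 1
                    ok = False
                    break
            if not ok:
                continue
            if frozen_sorted:
                rot, trans = superpose(pos[frozen_sorted], frozen_ref)
                pos = pos @ rot.T + trans
            if ref_quad is not None:
                if np.sign(_signed_volume(pos, ref_quad)) != np.sign(ref_vol):
                    rejects["chirality"] += 1
                    continue
            bad_rc = [
                i for i in rc_sorted
                if np.linalg.norm(pos[i] - constraints.fixed_positions[i]) > 0.2
            ]
            if bad_rc:
                rejects["position"] += 1
                continue
            accepted.append(pos)
        if not cids and attempts >= max_attempts:
            break

    if not accepted:
        raise EmbeddingError(
            f"no acceptable conformer after {attempts} attempts "
            f"(rejected: {rejects})"
        )
    log.info(
        "embedded %d/%d conformers in %d attempts (rejected: %s)",
        len(accepted), target, attempts, rejects,
    )
    members = [
        Member(structure.with_coords(pos, comment=""), None, f"dg{k:04d}")
        for k, pos in enumerate(accepted)
    ]
    return Ensemble(members, reference_input=structure)
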