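"""Bond-graph perception, SMILES bonding templates and frozen-atom sets.

Connectivity is perceived from distances against Pyykko single-bond covalent
radii (factor 1.3, 0.4 A overlap floor).  Full bond-order/valence assignment
is attempted through RDKit's determine-bonds machinery and degrades to a
connectivity-only graph whenever typing fails (typical for transition-metal
centers and exotic reaction cores) -- degradation is logged, never fatal.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Optional, Tuple

import networkx as nx
import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdDetermineBonds
from scipy.spatial.distance import pdist, squareform

from .errors import GeometryError, MappingError, TemplateError, ValidationError
from .structure_io import Structure

RDLogger.DisableLog("rdApp.*")
log = logging.getLogger(__name__)

__all__ = [
    "Topology",
    "ReactionCenter",
    "FrozenAtomSet",
    "infer_connectivity",
    "perceive_bond_orders",
    "apply_smiles_template",
    "frozen_atoms",
    "covalent_radius",
]

#: Pyykko & Atsumi single-bond covalent radii (Angstrom).
PYYKKO_RADII = {
    "H": 0.32, "He": 0.46, "Li": 1.33, "Be": 1.02, "B": 0.85, "C": 0.75,
    "N": 0.71, "O": 0.63, "F": 0.64, "Ne": 0.67, "Na": 1.55, "Mg": 1.39,
    "Al": 1.26, "Si": 1.16, "P": 1.11, "S": 1.03, "Cl": 0.99, "Ar": 0.96,
    "K": 1.96, "Ca": 1.71, "Sc": 1.48, "Ti": 1.36, "V": 1.34, "Cr": 1.22,
    "Mn": 1.19, "Fe": 1.16, "Co": 1.11, "Ni": 1.10, "Cu": 1.12, "Zn": 1.18,
    "Ga": 1.24, "Ge": 1.21, "As": 1.21, "Se": 1.16, "Br": 1.14, "Kr": 1.17,
    "Rb": 2.10, "Sr": 1.85, "Y": 1.63, "Zr": 1.54, "Nb": 1.47, "Mo": 1.38,
    "Tc": 1.28, "Ru": 1.25, "Rh": 1.25, "Pd": 1.20, "Ag": 1.28, "Cd": 1.36,
    "In": 1.42, "Sn": 1.40, "Sb": 1.40, "Te": 1.36, "I": 1.33, "Xe": 1.31,
    "Cs": 2.32, "Ba": 1.96, "La": 1.80, "Hf": 1.52, "Ta": 1.46, "W": 1.37,
    "Re": 1.31, "Os": 1.29, "Ir": 1.22, "Pt": 1.23, "Au": 1.24, "Hg": 1.33,
    "Tl": 1.44, "Pb": 1.44, "Bi": 1.51,
}

BOND_FACTOR = 1.3
MIN_DISTANCE = 0.4

_PT = Chem.GetPeriodicTable()


def covalent_radius(symbol: str) -> float:
    try:
        return PYYKKO_RADII[symbol]
    except KeyError:
        r = _PT.GetRcovalent(symbol)
        if r <= 0:
            raise ValidationError(f"no covalent radius for {symbol!r}")
        return float(r)


def _canon(i: int, j: int) -> Tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass
class Topology:
    """A bond graph over a :class:`Structure`.

    ``bonds`` maps unordered index pairs ``(i, j)`` (``i < j``) to a bond
    order, or ``None`` for connectivity-only bonds (order unknown -- e.g.
    forming/breaking bonds of a reaction center).
    """

    structure: Structure
    bonds: Dict[Tuple[int, int], Optional[float]] = field(default_factory=dict)
    formal_charges: Optional[list] = None
    connectivity_only: bool = False

    def __post_init__(self) -> None:
        n = self.structure.n_atoms
        canon: Dict[Tuple[int, int], Optional[float]] = {}
        for (i, j), order in self.bonds.items():
            if i == j:
                raise ValidationError(f"self-loop bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(f"bond ({i},{j}) out of range for {n} atoms")
            canon[_canon(i, j)] = order
        self.bonds = canon
        if self.formal_charges is not None:
            self.formal_charges = [int(c) for c in self.formal_charges]
            if len(self.formal_charges) != n:
                raise ValidationError("formal_charges length mismatch")
            if not self.connectivity_only and sum(self.formal_charges) != self.structure.charge:
                raise ValidationError(
                    "formal charges do not sum to the total molecular charge"
                )

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.structure.n_atoms))
        for (i, j), order in self.bonds.items():
            g.add_edge(i, j, order=order)
        return g

    def neighbors(self, i: int) -> FrozenSet[int]:
        out = set()
        for a, b in self.bonds:
            if a == i:
                out.add(b)
            elif b == i:
                out.add(a)
        return frozenset(out)

    def has_bond(self, i: int, j: int) -> bool:
        return _canon(i, j) in self.bonds

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


@dataclass(frozen=True)
class ReactionCenter:
    """User-supplied 0-based atom indices of the reacting atoms."""

    indices: FrozenSet[int]

    def __init__(self, indices: Iterable[int]):
        object.__setattr__(self, "indices", frozenset(int(i) for i in indices))
        if any(i < 0 for i in self.indices):
            raise ValidationError("reaction-center indices must be >= 0")

    def validate(self, n_atoms: int, require_nonempty: bool = True) -> None:
        if require_nonempty and not self.indices:
            raise ValidationError("reaction center must not be empty")
        bad = [i for i in self.indices if i >= n_atoms]
        if bad:
            raise ValidationError(f"reaction-center indices out of range: {bad}")


@dataclass(frozen=True)
class FrozenAtomSet:
    """Reaction center plus every bonded neighbor of a reaction-center atom."""

    indices: FrozenSet[int]

    def __contains__(self, i: int) -> bool:
        return i in self.indices

    def __iter__(self):
        return iter(sorted(self.indices))

    def __len__(self) -> int:
        return len(self.indices)


def _distance_bonds(structure: Structure) -> Dict[Tuple[int, int], None]:
    coords = structure.coords
    n = structure.n_atoms
    if n == 1:
        return {}
    dists = squareform(pdist(coords))
    iu = np.triu_indices(n, k=1)
    too_close = np.flatnonzero(dists[iu] < MIN_DISTANCE)
    if too_close.size:
        k = too_close[0]
        i, j = iu[0][k], iu[1][k]
        raise GeometryError(
            f"atoms {i} and {j} overlap ({dists[i, j]:.3f} A < {MIN_DISTANCE} A)"
        )
    radii = np.array([covalent_radius(s) for s in structure.symbols])
    cutoff = BOND_FACTOR * (radii[:, None] + radii[None, :])
    bonds: Dict[Tuple[int, int], None] = {}
    for i, j in zip(*np.nonzero(np.triu(dists <= cutoff, k=1))):
        bonds[(int(i), int(j))] = None
    return bonds


def infer_connectivity(structure: Structure) -> Topology:
    """Perceive bonds from interatomic distances only.

    A bond is present iff ``d <= 1.3 * (r_cov_i + r_cov_j)``.  Atom pairs
    closer than 0.4 A raise :class:`GeometryError`.  Disconnected graphs are
    allowed but produce a warning.
    """
    bonds = _distance_bonds(structure)
    topo = Topology(structure, bonds, formal_charges=None, connectivity_only=True)
    if structure.n_atoms > 1 and not nx.is_connected(topo.graph()):
        warnings.warn(
            "connectivity graph is disconnected", stacklevel=2
        )
        log.warning("connectivity graph of %d atoms is disconnected", structure.n_atoms)
    return topo


def _xyz_block(structure: Structure) -> str:
    lines = [str(structure.n_atoms), ""]
    for s, (x, y, z) in zip(structure.symbols, structure.coords):
        lines.append(f"{s} {x:.8f} {y:.8f} {z:.8f}")
    return "\n".join(lines) + "\n"


def perceive_bond_orders(
    structure: Structure, reaction_center: Optional[ReactionCenter] = None
) -> Topology:
    """Attempt full bond-order and formal-charge assignment.

    Any internally valid assignment is accepted for reaction-center atoms and
    bonds; those are geometrically constrained downstream, so chemically
    "correct" labels are not required.  On failure the result degrades to
    :func:`infer_connectivity` plus sanitization-light (``connectivity_only``
    set).  This operation never raises on perception failure; geometry errors
    (overlapping atoms) still propagate.
    """
    dist_bonds = _distance_bonds(structure)

    try:
        mol = Chem.MolFromXYZBlock(_xyz_block(structure))
        if mol is None:
            raise ValueError("xyz block rejected")
        rdDetermineBonds.DetermineBonds(mol, charge=structure.charge)
        bonds: Dict[Tuple[int, int], Optional[float]] = {}
        for b in mol.GetBonds():
            bonds[_canon(b.GetBeginAtomIdx(), b.GetEndAtomIdx())] = b.GetBondTypeAsDouble()
        # keep close-contact bonds the valence model dropped (e.g. long
        # forming/breaking bonds) as connectivity-only entries
        for pair in dist_bonds:
            bonds.setdefault(pair, None)
        charges = [a.GetFormalCharge() for a in mol.GetAtoms()]
        return Topology(structure, bonds, formal_charges=charges, connectivity_only=False)
    except GeometryError:
        raise
    except Exception as exc:  # perception failure -> connectivity fallback
        log.info("bond-order perception failed (%s); falling back to connectivity", exc)
        topo = Topology(structure, dist_bonds, formal_charges=None, connectivity_only=True)
        if structure.n_atoms > 1 and not nx.is_connected(topo.graph()):
            log.warning("connectivity graph is disconnected")
        return topo


def _heavy_graph(symbols, bonds) -> nx.Graph:
    g = nx.Graph()
    for i, s in enumerate(symbols):
        if s != "H":
            g.add_node(i, element=s)
    for i, j in bonds:
        if symbols[i] != "H" and symbols[j] != "H":
            g.add_edge(i, j)
    return g


def apply_smiles_template(topology: Topology, smiles: str) -> Topology:
    """Transfer bond orders and formal charges from a SMILES template.

    The template's heavy-atom graph is mapped onto the 3D structure's heavy
    atoms by subgraph monomorphism with element-label matching (the 3D graph
    may hold extra forming/breaking bonds, which are retained as
    connectivity-only).  Atom order of the 3D structure is never changed.
    """
    structure = topology.structure
    tmpl = Chem.MolFromSmiles(smiles)
    if tmpl is None:
        raise TemplateError(f"could not parse SMILES template: {smiles!r}")

    struct_heavy = Counter(s for s in structure.symbols if s != "H")
    tmpl_heavy = Counter(a.GetSymbol() for a in tmpl.GetAtoms())
    if struct_heavy != tmpl_heavy:
        raise TemplateError(
            f"heavy-atom composition mismatch: structure {dict(struct_heavy)} "
            f"vs template {dict(tmpl_heavy)}"
        )

    g_struct = _heavy_graph(structure.symbols, topology.bonds)
    g_tmpl = nx.Graph()
    for a in tmpl.GetAtoms():
        g_tmpl.add_node(a.GetIdx(), element=a.GetSymbol())
    for b in tmpl.GetBonds():
        g_tmpl.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())

    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g_struct, g_tmpl,
        node_match=lambda a, b: a["element"] == b["element"],
    )
    mapping = None  # structure heavy index -> template atom index
    for cand in matcher.subgraph_monomorphisms_iter():
        if len(cand) == g_tmpl.number_of_nodes():
            mapping = cand
            break
    if mapping is None:
        raise MappingError(
            "no consistent atom mapping between SMILES template and 3D structure"
        )
    inverse = {t: s for s, t in mapping.items()}

    bonds: Dict[Tuple[int, int], Optional[float]] = {}
    for (i, j), order in topology.bonds.items():
        if structure.symbols[i] == "H" or structure.symbols[j] == "H":
            bonds[(i, j)] = 1.0
        else:
            bonds[(i, j)] = None  # overwritten below when templated
    for b in tmpl.GetBonds():
        i = inverse[b.GetBeginAtomIdx()]
        j = inverse[b.GetEndAtomIdx()]
        bonds[_canon(i, j)] = b.GetBondTypeAsDouble()

    charges = [0] * structure.n_atoms
    for s_idx, t_idx in mapping.items():
        charges[s_idx] = tmpl.GetAtomWithIdx(t_idx).GetFormalCharge()

    connectivity_only = False
    if sum(charges) != structure.charge:
        warnings.warn(
            "template formal charges do not sum to the total charge; "
            "keeping connectivity-only flag", stacklevel=2
        )
        connectivity_only = True
    return Topology(
        structure, bonds, formal_charges=charges, connectivity_only=connectivity_only
    )


def frozen_atoms(topology: Topology, reaction_center: ReactionCenter) -> FrozenAtomSet:
    """Reaction center united with all of its immediate bond-graph neighbors."""
    reaction_center.validate(topology.structure.n_atoms)
    frozen = set(reaction_center.indices)
    for i in reaction_center.indices:
        frozen |= topology.neighbors(i)
    return FrozenAtomSet(frozenset(frozen))
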