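"""Programmatic toy transition-state systems for testing and demos.

Every generator here is a deterministic function of its parameters (no
hidden RNG) and uses textbook geometry: C-C 1.54 A, C-H 1.09 A, tetrahedral
109.47 deg, forming/breaking bonds at 2.0 A.  The SN2-like toy has a
pentacoordinate carbon with collinear nucleophile/leaving group and an
n-alkyl tail whose rotamer inventory is enumerable by a brute-force torsion
scan, which makes it an independent oracle for the sampling modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import networkx as nx
import numpy as np

from .errors import ValidationError
from .refinement import EnergyEngine, MockEngine
from .structure_io import Structure
from .topology import ReactionCenter, frozen_atoms, infer_connectivity

__all__ = [
    "ToyTS",
    "make_sn2_toy",
    "make_metal_toy",
    "make_overlap_toy",
    "torsion_scan_oracle",
    "dihedral_angle",
]

CC = 1.54
CH = 1.09
NC = 1.47
TET = 109.47122063449069  # arccos(-1/3)
AXIAL = 2.0               # forming/breaking bond length
PD_L = 2.3


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """NeRF atom placement: bond r to c, angle theta at c w.r.t. b, dihedral
    phi about the b->c axis measured from a."""
    theta = math.radians(theta_deg)
    phi = math.radians(phi_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = (
        -bc * math.cos(theta)
        + m * math.sin(theta) * math.cos(phi)
        + n * math.sin(theta) * math.sin(phi)
    )
    return c + r * d


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees for the chain p0-p1-p2-p3."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


@dataclass
class ToyTS:
    """A synthetic TS with known frozen core and enumerable rotamers."""

    structure: Structure
    reaction_center: ReactionCenter
    expected_rotamer_count: int
    template_smiles: Optional[str] = None


def make_sn2_toy(tail_length: int = 0) -> ToyTS:
    """Pentacoordinate SN2-like toy TS.

    Central carbon (index 0) with fluorine nucleophile (1) and chlorine
    leaving group (2) collinear at 2.0 A, equatorial hydrogens, and an
    n-alkyl tail of ``tail_length`` carbons replacing one equatorial site.
    The tail contributes ``tail_length - 1`` free rotatable bonds.
    Reaction center: {0, 1, 2}.
    """
    if tail_length < 0:
        raise ValidationError("tail_length must be >= 0")
    symbols: List[str] = ["C", "F", "Cl"]
    coords: List[np.ndarray] = [
        np.zeros(3),
        np.array([0.0, 0.0, AXIAL]),
        np.array([0.0, 0.0, -AXIAL]),
    ]
    eq = [
        np.array([math.cos(2 * math.pi * k / 3), math.sin(2 * math.pi * k / 3), 0.0])
        for k in range(3)
    ]
    n_eq_h = 3 if tail_length == 0 else 2
    for k in range(3 - n_eq_h, 3):
        symbols.append("H")
        coords.append(CH * eq[k])

    if tail_length:
        chain = [np.zeros(3), CC * eq[0]]  # center + first tail carbon
        for k in range(1, tail_length):
            prev2 = coords[1] if k == 1 else chain[k - 1]
            # first extension bends toward the fluorine side to keep the
            # chain clear of the leaving group; the backbone is anti after
            phi = 0.0 if k == 1 else 180.0
            a = coords[1] if k == 1 else chain[k - 2]
            chain.append(_place(a, chain[k - 1], chain[k], CC, TET, phi))
        tail = chain[1:]
        for c in tail:
            symbols.append("C")
            coords.append(c)
        # tail hydrogens: two per inner carbon, three on the terminus
        full = [np.zeros(3)] + tail
        for k in range(1, len(full)):
            here = full[k]
            prev = full[k - 1]
            if k < len(full) - 1:
                nxt = full[k + 1]
                for phi in (120.0, -120.0):
                    symbols.append("H")
                    coords.append(_place(nxt, prev, here, CH, TET, phi))
            else:
                a = full[k - 2] if k >= 2 else coords[1]
                for phi in (60.0, 180.0, 300.0):
                    symbols.append("H")
                    coords.append(_place(a, prev, here, CH, TET, phi))

    structure = Structure(symbols, np.array(coords), charge=-1, comment="sn2 toy")
    template = "[F-].Cl" + "C" * (1 + tail_length)
    return ToyTS(
        structure=structure,
        reaction_center=ReactionCenter({0, 1, 2}),
        expected_rotamer_count=3 ** max(0, tail_length - 1),
        template_smiles=template,
    )


def make_metal_toy() -> ToyTS:
    """Square-planar Pd surrogate with three chlorides, an ethylamine arm
    and reaction center {Pd}; bond-order perception is expected to fail so
    the connectivity-only pipeline gets exercised."""
    pd = np.zeros(3)
    cl1 = np.array([PD_L, 0.0, 0.0])
    cl2 = np.array([-PD_L, 0.0, 0.0])
    cl3 = np.array([0.0, PD_L, 0.0])
    n = np.array([0.0, -PD_L, 0.0])
    c5 = _place(cl1, pd, n, NC, TET, 90.0)
    c6 = _place(pd, n, c5, CC, TET, 180.0)
    h_n = [_place(cl1, pd, n, 1.01, TET, 90.0 + s) for s in (120.0, 240.0)]
    h_c5 = [_place(c6, n, c5, CH, TET, s) for s in (120.0, -120.0)]
    h_c6 = [_place(n, c5, c6, CH, TET, s) for s in (60.0, 180.0, 300.0)]
    symbols = ["Pd", "Cl", "Cl", "Cl", "N", "C", "C"] + ["H"] * 7
    coords = [pd, cl1, cl2, cl3, n, c5, c6] + h_n + h_c5 + h_c6
    structure = Structure(symbols, np.array(coords), charge=-1, comment="metal toy")
    return ToyTS(
        structure=structure,
        reaction_center=ReactionCenter({0}),
        expected_rotamer_count=9,
        template_smiles=None,
    )


def make_overlap_toy() -> Structure:
    """Deliberately pathological input: two hydrogens 0.1 A apart."""
    return Structure(
        ["H", "H"], np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0]]), charge=0,
        comment="pathological overlap",
    )


def _rotate_about_axis(points: np.ndarray, origin: np.ndarray,
                       axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    ang = math.radians(angle_deg)
    k = axis
    p = points - origin
    rot = (
        p * math.cos(ang)
        + np.cross(k, p) * math.sin(ang)
        + np.outer(p @ k, k) * (1 - math.cos(ang))
    )
    return rot + origin


def torsion_scan_oracle(
    toy: ToyTS,
    torsion: Tuple[int, int, int, int],
    step: float = 10.0,
    engine: Optional[EnergyEngine] = None,
) -> List[float]:
    """Exhaustive rigid torsion scan; returns the dihedral angles (deg) of
    the strict local minima of the energy profile.

    The atoms beyond the rotated bond move as a rigid body.  Scanning a
    torsion whose central bond lies inside the frozen set is meaningless and
    raises :class:`ValidationError`.
    """
    if 360.0 % step:
        raise ValidationError("step must divide 360")
    a, b, c, d = torsion
    structure = toy.structure
    topo = infer_connectivity(structure)
    for i, j in ((a, b), (b, c), (c, d)):
        if not topo.has_bond(i, j):
            raise ValidationError(f"torsion atoms {i} and {j} are not bonded")
    frozen = frozen_atoms(topo, toy.reaction_center)
    if b in frozen and c in frozen:
        raise ValidationError(
            f"central bond ({b},{c}) lies inside the frozen set; scanning it "
            "is meaningless"
        )
    engine = engine or MockEngine()

    g = topo.graph()
    g.remove_edge(b, c)
    moving = sorted(nx.node_connected_component(g, c))
    if b in moving:
        raise ValidationError(f"bond ({b},{c}) is in a ring; cannot scan rigidly")

    base = structure.coords.copy()
    phi0 = dihedral_angle(base[a], base[b], base[c], base[d])
    angles = np.arange(0.0, 360.0, step)
    energies = []
    for phi in angles:
        coords = base.copy()
        coords[moving] = _rotate_about_axis(
            base[moving], base[b], base[c] - base[b], phi - phi0
        )
        energies.append(engine.single_point(structure.with_coords(coords), topo))
    energies = np.asarray(energies)

    minima = []
    n = len(angles)
    for i in range(n):
        if energies[i] < energies[(i - 1) % n] and energies[i] < energies[(i + 1) % n]:
            minima.append(float(angles[i]))
    return minima
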