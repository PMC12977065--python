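"""Frozen-atom force-field refinement and the pluggable energy-engine contract.

The default chain is MMFF94 -> UFF -> mock.  The first engine whose typing
accepts every atom is used; anything downstream of the primary sets
``fallback_used``.  Frozen atoms are fixed exactly (fixed points in the
RDKit force fields, excluded variables in the mock engine), and their input
coordinates are restored verbatim after minimization so drift is strictly 0.

Because reaction-center atoms can carry arbitrary valences (pentacoordinate
carbons, metal centers), bonds whose two endpoints are both frozen are
omitted from the force-field topology: every such bond connects fixed
points, so it contributes no force on any free atom.

An adapter for an external tight-binding backend (``xtb``) is provided; when
the binary is absent the pipeline simply runs in its force-field-only mode.

Engine adapter contract (for plugging in external backends)::

    minimize(symbols, coords_A, charge, fixed_indices)
        -> (coords_A, energy_kcal_mol, converged)
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.optimize import minimize as scipy_minimize

from .embedding import mol_from_topology
from .errors import EngineUnavailableError, RefinementError, ValidationError
from .structure_io import Ensemble, Member, Structure
from .topology import FrozenAtomSet, Topology

log = logging.getLogger(__name__)

HARTREE_TO_KCAL = 627.509474

MAX_STEPS = 5000
FORCE_TOL = 1e-6

__all__ = [
    "EnergyEngine",
    "MMFFEngine",
    "UFFEngine",
    "MockEngine",
    "XTBEngine",
    "RefinedConformer",
    "default_engine_chain",
    "minimize",
    "rank",
    "refine_ensemble",
]


@dataclass
class RefinedConformer:
    structure: Structure
    energy: float
    engine: str
    fallback_used: bool
    converged: bool


class EnergyEngine:
    """Base energy engine: pure single-point evaluation plus minimization."""

    name: str = "base"
    minimizes: bool = True
    fixes_atoms_exactly: bool = True

    def accepts(self, topology: Topology, frozen: FrozenAtomSet) -> bool:
        raise NotImplementedError

    def single_point(self, structure: Structure, topology: Topology,
                     frozen: FrozenAtomSet = FrozenAtomSet(frozenset())) -> float:
        raise NotImplementedError

    def minimize(
        self,
        structure: Structure,
        topology: Topology,
        frozen: FrozenAtomSet,
        max_steps: int = MAX_STEPS,
        force_tol: float = FORCE_TOL,
    ) -> Tuple[np.ndarray, float, bool]:
        raise NotImplementedError


class _RDKitFFEngine(EnergyEngine):
    """Shared machinery for the RDKit classical force fields.

    ``_get_ff`` returns ``(force_field, mol)``; the mol must stay referenced
    for the force field's lifetime (the field does not own it).
    """

    def _get_ff(self, mol: Chem.Mol, conf_id: int = 0):
        raise NotImplementedError

    def _working_mol(self, topology: Topology, frozen: FrozenAtomSet,
                     coords: np.ndarray) -> Chem.Mol:
        return mol_from_topology(
            topology, drop_bond_atoms=tuple(frozen.indices), coords=coords
        )

    def accepts(self, topology: Topology, frozen: FrozenAtomSet) -> bool:
        try:
            mol = self._working_mol(topology, frozen, topology.structure.coords)
            ff, _ref = self._get_ff(mol)
            return ff is not None
        except Exception:
            return False

    def single_point(self, structure, topology, frozen=FrozenAtomSet(frozenset())):
        mol = self._working_mol(topology, frozen, structure.coords)
        ff, _ref = self._get_ff(mol)
        if ff is None:
            raise RefinementError(f"{self.name} cannot type this system")
        return float(ff.CalcEnergy())

    def minimize(self, structure, topology, frozen,
                 max_steps=MAX_STEPS, force_tol=FORCE_TOL):
        mol = self._working_mol(topology, frozen, structure.coords)
        ff, mol = self._get_ff(mol)
        if ff is None:
            raise RefinementError(f"{self.name} cannot type this system")
        for i in frozen:
            ff.AddFixedPoint(int(i))
        ff.Initialize()
        start = float(ff.CalcEnergy())
        ret = ff.Minimize(maxIts=max_steps, forceTol=force_tol)
        energy = float(ff.CalcEnergy())
        coords = mol.GetConformer().GetPositions()
        if energy > start:  # never hand back an uphill "minimization"
            coords = structure.coords.copy()
            energy = start
        coords = np.array(coords, dtype=float)
        coords[list(frozen.indices)] = structure.coords[list(frozen.indices)]
        return coords, energy, ret == 0


class MMFFEngine(_RDKitFFEngine):
    """MMFF94 via RDKit; requires a fully typeable (sanitizable) system."""

    name = "mmff94"

    def _get_ff(self, mol: Chem.Mol, conf_id: int = 0):
        work = Chem.Mol(mol)
        Chem.SanitizeMol(work)  # MMFF typing needs full sanitization
        props = AllChem.MMFFGetMoleculeProperties(work)
        if props is None or not AllChem.MMFFHasAllMoleculeParams(work):
            return None, None
        return AllChem.MMFFGetMoleculeForceField(work, props, confId=conf_id), work


class UFFEngine(_RDKitFFEngine):
    """Universal force field; unrecognized atom types get default parameters."""

    name = "uff"

    def _get_ff(self, mol: Chem.Mol, conf_id: int = 0):
        return AllChem.UFFGetMoleculeForceField(mol, confId=conf_id), mol


class MockEngine(EnergyEngine):
    """Dependency-free smooth pair potential (harmonic bonds + 12-6 terms).

    Exists so the full pipeline and every test run without external binaries.
    Pure function of (symbols, coordinates, bond graph).
    """

    name = "mock"
    K_BOND = 300.0  # kcal/mol/A^2
    EPS = 0.05      # kcal/mol

    def __init__(self) -> None:
        self._pt = Chem.GetPeriodicTable()

    def _terms(self, topology: Topology):
        from .topology import covalent_radius

        n = topology.structure.n_atoms
        g = topology.graph()
        bonds = []
        for (i, j) in topology.bonds:
            r0 = covalent_radius(topology.structure.symbols[i]) + covalent_radius(
                topology.structure.symbols[j]
            )
            bonds.append((i, j, r0))
        spl = dict(nx.all_pairs_shortest_path_length(g)) if n > 1 else {}
        nonbonded = []
        rvdw = [max(self._pt.GetRvdw(s), 1.0) for s in topology.structure.symbols]
        for i in range(n):
            for j in range(i + 1, n):
                d = spl.get(i, {}).get(j)
                if d is None or d >= 3:
                    nonbonded.append((i, j, rvdw[i] + rvdw[j]))
        return bonds, nonbonded

    def _energy_grad(self, coords: np.ndarray, bonds, nonbonded):
        e = 0.0
        grad = np.zeros_like(coords)
        for i, j, r0 in bonds:
            v = coords[i] - coords[j]
            r = np.linalg.norm(v)
            e += 0.5 * self.K_BOND * (r - r0) ** 2
            g = self.K_BOND * (r - r0) * v / max(r, 1e-12)
            grad[i] += g
            grad[j] -= g
        for i, j, sigma in nonbonded:
            v = coords[i] - coords[j]
            r = max(np.linalg.norm(v), 1e-6)
            sr6 = (sigma / r) ** 6
            e += self.EPS * (sr6 * sr6 - 2.0 * sr6)
            de_dr = self.EPS * (-12.0 * sr6 * sr6 + 12.0 * sr6) / r
            g = de_dr * v / r
            grad[i] += g
            grad[j] -= g
        return e, grad

    def accepts(self, topology: Topology, frozen: FrozenAtomSet) -> bool:
        return True

    def single_point(self, structure, topology, frozen=FrozenAtomSet(frozenset())):
        bonds, nonbonded = self._terms(topology)
        e, _ = self._energy_grad(structure.coords, bonds, nonbonded)
        return float(e)

    def minimize(self, structure, topology, frozen,
                 max_steps=MAX_STEPS, force_tol=FORCE_TOL):
        bonds, nonbonded = self._terms(topology)
        free = np.array(
            [i for i in range(structure.n_atoms) if i not in frozen], dtype=int
        )
        coords0 = structure.coords.copy()
        e_start, _ = self._energy_grad(coords0, bonds, nonbonded)
        if free.size == 0:
            return coords0, float(e_start), True

        def fun(x):
            c = coords0.copy()
            c[free] = x.reshape(-1, 3)
            e, g = self._energy_grad(c, bonds, nonbonded)
            return e, g[free].ravel()

        res = scipy_minimize(
            fun, coords0[free].ravel(), jac=True, method="L-BFGS-B",
            options={"maxiter": max_steps, "gtol": force_tol},
        )
        coords = coords0.copy()
        coords[free] = res.x.reshape(-1, 3)
        energy = float(res.fun)
        if energy > e_start:
            return coords0, float(e_start), True
        return coords, energy, bool(res.success)


class XTBEngine(EnergyEngine):
    """Adapter shelling out to an installed ``xtb`` binary (GFN-FF / GFN2-xTB).

    Optional: when the binary is missing, :meth:`available` is False and the
    pipeline runs in its no-xTB mode.  Energies are converted from hartree to
    kcal/mol at this boundary.
    """

    name = "xtb"

    def __init__(self, method: str = "--gfnff") -> None:
        self.method = method

    @staticmethod
    def available() -> bool:
        return shutil.which("xtb") is not None

    def _require(self) -> None:
        if not self.available():
            raise EngineUnavailableError("the 'xtb' executable is not on PATH")

    def accepts(self, topology: Topology, frozen: FrozenAtomSet) -> bool:
        return self.available()

    def _run(self, structure: Structure, frozen: FrozenAtomSet, opt: bool):
        self._require()
        from .structure_io import write_xyz, read_xyz

        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            write_xyz(structure, tmp / "in.xyz")
            args = ["xtb", "in.xyz", self.method, "--chrg", str(structure.charge)]
            if opt:
                args.append("--opt")
            if len(frozen):
                atoms = ",".join(str(i + 1) for i in sorted(frozen.indices))
                (tmp / "constrain.inp").write_text(
                    f"$fix\n  atoms: {atoms}\n$end\n"
                )
                args += ["--input", "constrain.inp"]
            out = subprocess.run(
                args, cwd=tmp, capture_output=True, text=True, check=False
            )
            energy = None
            for line in out.stdout.splitlines():
                if "TOTAL ENERGY" in line:
                    energy = float(line.split()[-3]) * HARTREE_TO_KCAL
            if energy is None:
                raise RefinementError("xtb produced no total energy")
            coords = structure.coords
            if opt and (tmp / "xtbopt.xyz").exists():
                coords = read_xyz(tmp / "xtbopt.xyz").coords
            return np.array(coords), energy, out.returncode == 0

    def single_point(self, structure, topology, frozen=FrozenAtomSet(frozenset())):
        _, energy, _ = self._run(structure, frozen, opt=False)
        return energy

    def minimize(self, structure, topology, frozen,
                 max_steps=MAX_STEPS, force_tol=FORCE_TOL):
        coords, energy, ok = self._run(structure, frozen, opt=True)
        coords = np.array(coords, dtype=float)
        coords[list(frozen.indices)] = structure.coords[list(frozen.indices)]
        return coords, energy, ok


def default_engine_chain() -> List[EnergyEngine]:
    return [MMFFEngine(), UFFEngine(), MockEngine()]


def _select_engine(engine_chain, topology, frozen):
    for pos, engine in enumerate(engine_chain):
        if engine.accepts(topology, frozen):
            return engine, pos > 0
    raise RefinementError(
        "no engine in the chain accepts this system "
        f"(symbols: {sorted(set(topology.structure.symbols))})"
    )


def minimize(
    conformer: Structure,
    topology: Topology,
    frozen: FrozenAtomSet,
    engine_chain: Optional[Sequence[EnergyEngine]] = None,
) -> RefinedConformer:
    """Minimize one conformer with the first engine that types every atom.

    Frozen atoms are exactly fixed; the returned energy never exceeds the
    starting energy under the chosen engine.
    """
    chain = list(engine_chain) if engine_chain is not None else default_engine_chain()
    if not chain:
        raise ValidationError("engine chain must not be empty")
    engine, fallback_used = _select_engine(chain, topology, frozen)
    coords, energy, converged = engine.minimize(conformer, topology, frozen)
    return RefinedConformer(
        structure=conformer.with_coords(coords),
        energy=float(energy),
        engine=engine.name,
        fallback_used=fallback_used,
        converged=converged,
    )


def rank(ensemble: Ensemble, engine: EnergyEngine,
         topology: Optional[Topology] = None) -> Ensemble:
    """Attach single-point energies from ``engine`` and stably re-sort.

    Members the engine fails on are dropped with a warning -- never silently
    reordered.
    """
    members = []
    for m in ensemble:
        try:
            e = engine.single_point(m.structure, topology)
        except Exception as exc:
            log.warning("dropping member %r: %s single-point failed (%s)",
                        m.label, engine.name, exc)
            continue
        members.append(Member(m.structure, float(e), m.label))
    members.sort(key=lambda m: m.energy)  # stable: ties keep prior order
    return Ensemble(members, reference_input=ensemble.reference_input)


def refine_ensemble(
    ensemble: Ensemble,
    topology: Topology,
    frozen: FrozenAtomSet,
    engine_chain: Optional[Sequence[EnergyEngine]] = None,
) -> Tuple[Ensemble, List[RefinedConformer]]:
    """Minimize every member and return the energy-sorted refined ensemble."""
    refined = [
        minimize(m.structure, topology, frozen, engine_chain) for m in ensemble
    ]
    members = [
        Member(r.structure, r.energy, m.label) for r, m in zip(refined, ensemble)
    ]
    members.sort(key=lambda m: m.energy)
    return Ensemble(members, reference_input=ensemble.reference_input), refined
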