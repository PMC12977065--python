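"""Duplicate/high-energy conformer removal and the rigid-superposition RMSD.

RMSD is the minimum over all proper rigid motions (Kabsch, determinant
corrected -- never a reflection), computed over heavy atoms by default.
No atom-permutation or symmetry canonicalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .errors import ValidationError
from .structure_io import Ensemble, Structure

__all__ = [
    "PruneConfig",
    "superpose",
    "rmsd_coords",
    "rmsd",
    "prune_energy",
    "prune_rmsd",
    "conformers_identical",
]


@dataclass
class PruneConfig:
    rmsd_threshold: float = 0.125
    energy_window: float = 20.0
    heavy_only: bool = True

    def __post_init__(self) -> None:
        if self.rmsd_threshold <= 0 or self.energy_window <= 0:
            raise ValidationError("pruning thresholds must be positive")


def superpose(P: np.ndarray, Q: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation + translation mapping points P onto Q.

    Returns ``(R, t)`` with ``P @ R.T + t`` least-squares closest to ``Q``.
    The rotation determinant is forced to +1 (no reflections).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - pc @ R.T
    return R, t


def rmsd_coords(A: np.ndarray, B: np.ndarray) -> float:
    """Minimal RMSD between two coordinate sets after optimal superposition."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValidationError(f"coordinate shape mismatch: {A.shape} vs {B.shape}")
    R, t = superpose(A, B)
    diff = A @ R.T + t - B
    return float(np.sqrt((diff * diff).sum() / len(A)))


def rmsd(a: Structure, b: Structure, heavy_only: bool = True) -> float:
    """Heavy-atom (by default) RMSD between two conformers of one molecule."""
    if a.symbols != b.symbols:
        raise ValidationError("structures have different atom lists")
    if heavy_only:
        sel = a.heavy_indices
        if sel.size == 0:  # all-hydrogen edge case
            sel = np.arange(a.n_atoms)
    else:
        sel = np.arange(a.n_atoms)
    return rmsd_coords(a.coords[sel], b.coords[sel])


def prune_energy(ensemble: Ensemble, window: float) -> Ensemble:
    """Keep members with ``E - E_min <= window`` (kcal/mol); order preserved."""
    if not ensemble.is_ranked:
        raise ValidationError("energy pruning requires defined energies")
    e_min = float(ensemble.energies.min())
    members = [m for m in ensemble if m.energy - e_min <= window]
    return Ensemble(members, reference_input=ensemble.reference_input)


def prune_rmsd(ensemble: Ensemble, config: PruneConfig = None) -> Ensemble:
    """Greedy ascending-energy sweep removing near-duplicate conformers.

    A member is retained iff its RMSD to every already-retained member is at
    least ``rmsd_threshold``.  The input must already be energy-sorted (sort
    responsibility stays with the caller, keeping this operation pure); the
    lowest-energy member is always retained.
    """
    config = config or PruneConfig()
    if not ensemble.is_ranked:
        raise ValidationError("RMSD pruning requires defined energies")
    if not ensemble.is_energy_sorted():
        raise ValidationError("RMSD pruning requires an energy-sorted ensemble")
    retained = []
    for m in ensemble:
        if all(
            rmsd(m.structure, kept.structure, heavy_only=config.heavy_only)
            >= config.rmsd_threshold
            for kept in retained
        ):
            retained.append(m)
    return Ensemble(retained, reference_input=ensemble.reference_input)


def conformers_identical(
    a,
    b,
    rmsd_threshold: float = 0.125,
    energy_threshold: float = 0.05,
    heavy_only: bool = True,
) -> bool:
    """Identity test: heavy-atom RMSD < 0.125 A and |dE| < 0.05 kcal/mol.

    ``a`` and ``b`` are ``(Structure, energy)`` pairs (ensemble members work).
    """
    sa, ea = a[0], a[1]
    sb, eb = b[0], b[1]
    if ea is None or eb is None:
        raise ValidationError("identity test requires defined energies")
    if abs(ea - eb) >= energy_threshold:
        return False
    return rmsd(sa, sb, heavy_only=heavy_only) < rmsd_threshold
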