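"""End-to-end conformer-ensemble generation (the `racerts run` pipeline).

Input structure -> topology (direct perception or SMILES template) ->
frozen atoms -> constrained embedding -> frozen-atom force-field refinement
-> energy-window + RMSD pruning -> energy-sorted ensemble.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .embedding import GenerationConfig, build_constraints, embed_conformers
from .pruning import PruneConfig, prune_energy, prune_rmsd
from .refinement import EnergyEngine, default_engine_chain, refine_ensemble
from .structure_io import Ensemble, Structure
from .topology import (
    ReactionCenter,
    apply_smiles_template,
    frozen_atoms,
    perceive_bond_orders,
)

log = logging.getLogger(__name__)

__all__ = ["generate_ensemble"]


def generate_ensemble(
    structure: Structure,
    reaction_center: ReactionCenter,
    smiles: Optional[str] = None,
    conf_factor: int = 30,
    energy_window: float = 20.0,
    rmsd_threshold: float = 0.125,
    tolerance: float = 0.01,
    seed: int = 0,
    engine_chain: Optional[Sequence[EnergyEngine]] = None,
) -> Ensemble:
    """Generate a pruned, energy-sorted TS conformer ensemble."""
    reaction_center.validate(structure.n_atoms)
    topology = perceive_bond_orders(structure, reaction_center)
    if smiles:
        topology = apply_smiles_template(topology, smiles)
    frozen = frozen_atoms(topology, reaction_center)
    constraints = build_constraints(structure, frozen, reaction_center, tolerance)
    config = GenerationConfig(conf_factor=conf_factor, seed=seed)
    raw = embed_conformers(topology, constraints, config)
    log.info("embedded %d raw conformers", len(raw))
    refined, records = refine_ensemble(
        raw, topology, frozen, engine_chain or default_engine_chain()
    )
    pruned = prune_energy(refined, energy_window)
    pruned = prune_rmsd(
        pruned, PruneConfig(rmsd_threshold=rmsd_threshold, energy_window=energy_window)
    )
    log.info(
        "kept %d conformers after pruning (engine=%s, fallback=%s)",
        len(pruned), records[0].engine if records else "-",
        records[0].fallback_used if records else "-",
    )
    return pruned
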