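# racerts

Rapid transition-state (TS) conformer ensembles by **constrained distance
geometry**, plus a quantitative benchmark framework for comparing conformer
generators.

Given a single 3D TS guess (xyz), the total charge, and the 0-based indices
of the reaction-center atoms, `racerts`:

1. perceives a bond graph (full bond orders where possible; connectivity-only
   fallback for exotic valences and metal centers), optionally transferring
   bonding from a reactant/product SMILES template;
2. freezes the reaction center plus its immediate bonded neighbors and
   samples conformers with a distance-geometry backend whose bounds matrix
   pins every frozen-atom pairwise distance (frozen-core chirality is
   checked; mirror images are rejected);
3. minimizes each conformer with MMFF94, falling back to UFF for
   unrecognized atom types (and to a dependency-free mock pair potential as
   a last resort), holding frozen atoms exactly fixed;
4. prunes duplicates (heavy-atom Kabsch RMSD < 0.125 Å to a lower-energy
   conformer) and high-energy members (default window 20 kcal/mol) and
   writes a multi-structure xyz, one block per conformer, energies on the
   comment line as `E=<kcal/mol>`.

The `metrics` module implements the ensemble benchmark: wall-time cost
normalization, combined-reference-ensemble construction, Butina
sphere-exclusion clustering, space exploration (precision/recall/F1), space
distribution (Jensen–Shannon divergence of RMSD-to-input distributions),
success rate, top-N accuracy, and Boltzmann-averaged activation-energy
errors.

**Conventions**: Å and kcal/mol everywhere at module boundaries; atom
indices are 0-based and follow xyz body order.

## CLI

```bash
# generate a toy TS fixture (writes toy.xyz + toy.yaml metadata)
racerts fixtures --system sn2 --tail 2 -o toy.xyz

# generate a TS conformer ensemble
racerts run toy.xyz --charge -1 --reaction-center 0,1,2 \
    --conf-factor 30 --energy-window 20 --rmsd-threshold 0.125 \
    --seed 1 -o ensemble.xyz

# benchmark ensembles against each other
racerts bench --manifest bench.yaml --timings timings.csv -o report.json
```

`bench.yaml` maps methods to per-reaction multi-xyz files:

```yaml
inputs:            # reaction -> input TS guess
  rxn1: input1.xyz
methods:
  method_a: {rxn1: a1.xyz}
  method_b: {rxn1: b1.xyz}
reference: method_a   # wall-time normalization reference
```

`timings.csv` has columns `method,reaction,wall_seconds`.

An external tight-binding post-optimizer (`xtb`) is supported as a
pluggable energy engine (`--engine external`); when the binary is absent
the pipeline simply runs in force-field-only mode.

## Python API

```python
from racerts import (ReactionCenter, generate_ensemble, read_xyz,
                     write_multi_xyz)

structure = read_xyz("ts_guess.xyz", charge=-1)
ensemble = generate_ensemble(structure, ReactionCenter({0, 1, 2}), seed=1)
write_multi_xyz(ensemble, "ensemble.xyz")
```

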