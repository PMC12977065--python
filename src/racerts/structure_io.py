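"""Single- and multi-structure xyz I/O and the core coordinate types.

Conventions at every module boundary:

* coordinates are Cartesian and in Angstrom;
* energies are in kcal/mol;
* atom indices are 0-based and follow xyz body line order;
* per-conformer energies are carried on the xyz comment line as a
  machine-parseable ``E=<value>`` token (8 significant digits).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Optional, Union

import numpy as np
from rdkit import Chem

from .errors import ValidationError, XYZFormatError

__all__ = [
    "Structure",
    "Member",
    "Ensemble",
    "read_xyz",
    "write_xyz",
    "read_multi_xyz",
    "write_multi_xyz",
]

_PT = Chem.GetPeriodicTable()
_ENERGY_RE = re.compile(r"(?:^|\s)E=([-+0-9.eE]+)(?:\s|$)")


def _atomic_number(symbol: str) -> int:
    try:
        z = _PT.GetAtomicNumber(symbol)
    except Exception:
        z = 0
    if z <= 0:
        raise ValidationError(f"unknown element symbol: {symbol!r}")
    return z


@dataclass(frozen=True)
class Structure:
    """An ordered set of atoms with Cartesian coordinates in Angstrom."""

    symbols: tuple
    coords: np.ndarray
    charge: int = 0
    comment: str = ""

    def __post_init__(self) -> None:
        symbols = tuple(self.symbols)
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(symbols) != coords.shape[0]:
            raise ValidationError(
                f"{len(symbols)} symbols but {coords.shape[0]} coordinate rows"
            )
        if len(symbols) == 0:
            raise ValidationError("a structure needs at least one atom")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coordinates must be finite")
        for s in symbols:
            _atomic_number(s)
        coords = coords.copy()
        coords.setflags(write=False)
        object.__setattr__(self, "symbols", symbols)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "charge", int(self.charge))

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([_atomic_number(s) for s in self.symbols], dtype=int)

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.flatnonzero(self.atomic_numbers > 1)

    def with_coords(self, coords: np.ndarray, comment: Optional[str] = None) -> "Structure":
        return Structure(
            self.symbols,
            coords,
            charge=self.charge,
            comment=self.comment if comment is None else comment,
        )

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))


class Member(NamedTuple):
    """One ensemble entry: a conformer, its energy (kcal/mol) and a label."""

    structure: Structure
    energy: Optional[float]
    label: str = ""


@dataclass
class Ensemble:
    """An ordered conformer ensemble sharing one atom list.

    Energies may be ``None`` (e.g. straight after embedding); such an
    ensemble is *unranked*.  Generators and refiners always hand back
    energy-ascending ensembles; readers preserve file order.
    """

    members: list = field(default_factory=list)
    reference_input: Optional[Structure] = None

    def __post_init__(self) -> None:
        members = [m if isinstance(m, Member) else Member(*m) for m in self.members]
        if members:
            ref = members[0].structure.symbols
            for m in members:
                if m.structure.symbols != ref:
                    raise ValidationError("ensemble members must share one atom list")
                if m.energy is not None and not np.isfinite(m.energy):
                    raise ValidationError("member energies must be finite")
        self.members = members

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Member]:
        return iter(self.members)

    def __getitem__(self, i):
        return self.members[i]

    @property
    def is_ranked(self) -> bool:
        return bool(self.members) and all(m.energy is not None for m in self.members)

    @property
    def energies(self) -> np.ndarray:
        return np.array(
            [np.nan if m.energy is None else m.energy for m in self.members], dtype=float
        )

    def sorted_by_energy(self) -> "Ensemble":
        """Stable ascending energy sort; requires all energies defined."""
        if not self.is_ranked:
            raise ValidationError("cannot sort an unranked ensemble")
        order = sorted(range(len(self.members)), key=lambda k: self.members[k].energy)
        return Ensemble([self.members[k] for k in order], reference_input=self.reference_input)

    def is_energy_sorted(self) -> bool:
        e = self.energies
        return bool(np.all(np.diff(e) >= 0)) if self.is_ranked else False


# ---------------------------------------------------------------------------
# xyz parsing / formatting
# ---------------------------------------------------------------------------

def _format_block(structure: Structure, energy: Optional[float], label: str = "") -> str:
    if energy is not None:
        comment = f"E={energy:.8g}"
        if label:
            comment += f" {label}"
    else:
        comment = label or structure.comment
    lines = [str(structure.n_atoms), comment]
    for s, (x, y, z) in zip(structure.symbols, structure.coords):
        lines.append(f"{s:<3s}{x:15.8f}{y:15.8f}{z:15.8f}")
    return "\n".join(lines) + "\n"


def _parse_blocks(text: str, path: str) -> list:
    lines = text.splitlines()
    blocks = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():  # tolerate blank separator lines
            pos += 1
            continue
        count_line = lines[pos].strip()
        try:
            n = int(count_line)
        except ValueError:
            raise XYZFormatError(
                f"{path}: line {pos + 1}: expected an integer atom count, got {count_line!r}"
            )
        if n <= 0:
            raise XYZFormatError(f"{path}: line {pos + 1}: non-positive atom count {n}")
        if pos + 1 + n >= len(lines) + 1 and pos + 1 + n > len(lines):
            raise XYZFormatError(
                f"{path}: header declares {n} atoms but the file ends early"
            )
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        symbols, coords = [], []
        for k in range(n):
            ln = pos + 2 + k
            if ln >= len(lines) or not lines[ln].split():
                raise XYZFormatError(
                    f"{path}: header declares {n} atoms but only {k} atom lines follow"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZFormatError(f"{path}: line {ln + 1}: malformed atom line")
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError:
                raise XYZFormatError(f"{path}: line {ln + 1}: non-numeric coordinate")
            symbols.append(parts[0])
            coords.append(xyz)
        # a trailing body line that parses as a bare count starts a new block;
        # anything else right after the block is a structural error
        nxt = pos + 2 + n
        if nxt < len(lines) and lines[nxt].strip():
            try:
                int(lines[nxt].strip())
            except ValueError:
                raise XYZFormatError(
                    f"{path}: line {nxt + 1}: unexpected content after a "
                    f"{n}-atom block (atom-count mismatch?)"
                )
        blocks.append((symbols, np.array(coords, dtype=float), comment))
        pos = nxt
    if not blocks:
        raise XYZFormatError(f"{path}: no xyz blocks found")
    return blocks


def _energy_from_comment(comment: str):
    m = _ENERGY_RE.search(comment)
    if not m:
        return None, comment.strip()
    label = (comment[: m.start()] + " " + comment[m.end():]).strip()
    try:
        return float(m.group(1)), label
    except ValueError:
        return None, comment.strip()


def read_xyz(path: Union[str, Path], charge: int = 0) -> Structure:
    """Read a single-structure xyz file."""
    text = Path(path).read_text()
    blocks = _parse_blocks(text, str(path))
    symbols, coords, comment = blocks[0]
    return Structure(symbols, coords, charge=charge, comment=comment.strip())


def write_xyz(structure: Structure, path: Union[str, Path],
              energy: Optional[float] = None) -> Path:
    """Write a single xyz block in canonical formatting."""
    path = Path(path)
    path.write_text(_format_block(structure, energy, label=structure.comment))
    return path


def read_multi_xyz(path: Union[str, Path], charge: int = 0) -> Ensemble:
    """Read a concatenated multi-structure xyz file into an :class:`Ensemble`.

    Energies are taken from ``E=`` comment tokens; members stay in file
    order.  Blocks with differing atom lists are a structural error.
    """
    text = Path(path).read_text()
    blocks = _parse_blocks(text, str(path))
    ref = tuple(blocks[0][0])
    members = []
    for k, (symbols, coords, comment) in enumerate(blocks):
        if tuple(symbols) != ref:
            raise XYZFormatError(
                f"{path}: block {k} atom list differs from block 0"
            )
        energy, label = _energy_from_comment(comment)
        members.append(Member(Structure(symbols, coords, charge=charge), energy, label))
    return Ensemble(members)


def write_multi_xyz(ensemble: Ensemble, path: Union[str, Path]) -> Path:
    """Write an ensemble as concatenated xyz blocks, one per member.

    Each comment line carries the member energy as ``E=<kcal/mol>``.
    Refuses to write an empty ensemble.
    """
    if len(ensemble) == 0:
        raise ValidationError("refusing to write an empty ensemble")
    path = Path(path)
    with open(path, "w") as fh:
        for m in ensemble:
            fh.write(_format_block(m.structure, m.energy, m.label))
    return path
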