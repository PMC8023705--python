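"""Molecular geometry container and XYZ input.

Coordinates are stored in bohr.  The XYZ reader accepts the standard
two-header-line dialect (atom count, comment, then ``symbol x y z`` lines)
and converts from angstrom on request.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import ANGSTROM, ELEMENTS, SYMBOL_TO_Z


class XYZParseError(ValueError):
    """Raised when an XYZ file violates the two-header-line layout."""


@dataclass
class Atom:
    symbol: str
    charge: float
    position: np.ndarray  # (3,) bohr

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")


@dataclass
class Molecule:
    """A set of nuclei with Cartesian coordinates in bohr."""

    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a molecule needs at least one atom")
        for a in self.atoms:
            if not np.all(np.isfinite(a.position)):
                raise ValueError(f"non-finite coordinates for atom {a.symbol}")
            z = SYMBOL_TO_Z.get(a.symbol)
            if z is None:
                raise ValueError(f"unknown element symbol {a.symbol!r}")
            if abs(a.charge - z) > 1e-12:
                raise ValueError(
                    f"nuclear charge {a.charge} inconsistent with element "
                    f"{a.symbol} (Z={z})"
                )

    @classmethod
    def from_arrays(cls, symbols, coords) -> "Molecule":
        coords = np.asarray(coords, dtype=float).reshape(len(symbols), 3)
        atoms = [
            Atom(s, float(SYMBOL_TO_Z[s]), c) for s, c in zip(symbols, coords)
        ]
        return cls(atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def symbols(self) -> list[str]:
        return [a.symbol for a in self.atoms]

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of positions in bohr."""
        return np.array([a.position for a in self.atoms])

    def translated(self, shift) -> "Molecule":
        shift = np.asarray(shift, dtype=float)
        return Molecule.from_arrays(self.symbols, self.coords + shift)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Molecule):
            return NotImplemented
        return self.symbols == other.symbols and np.array_equal(
            self.coords, other.coords
        )


def read_xyz(path, unit: str = "angstrom") -> Molecule:
    """Read a standard XYZ file.

    Parameters
    ----------
    path:
        File in the two-header-line XYZ dialect.
    unit:
        ``"angstrom"`` (default; converted to bohr) or ``"bohr"``.
    """
    if unit not in ("angstrom", "bohr"):
        raise ValueError(f"unit must be 'angstrom' or 'bohr', got {unit!r}")
    factor = ANGSTROM if unit == "angstrom" else 1.0
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise XYZParseError(f"{path}: line 1: expected an atom count")
    body = lines[2 : 2 + count]
    if len(body) < count:
        raise XYZParseError(
            f"{path}: count line says {count} atoms but only "
            f"{len(body)} atom lines present"
        )
    symbols, coords = [], []
    for i, line in enumerate(body, start=3):
        parts = line.split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}: line {i}: expected 'symbol x y z'")
        sym = parts[0].capitalize()
        if sym not in SYMBOL_TO_Z:
            raise XYZParseError(f"{path}: line {i}: unknown element {parts[0]!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"{path}: line {i}: malformed coordinate")
        symbols.append(sym)
        coords.append(xyz)
    return Molecule.from_arrays(symbols, np.asarray(coords) * factor)


def write_xyz(molecule: Molecule, path, unit: str = "angstrom",
              comment: str = "") -> None:
    factor = 1.0 / ANGSTROM if unit == "angstrom" else 1.0
    lines = [str(molecule.n_atoms), comment]
    for a in molecule.atoms:
        x, y, z = a.position * factor
        lines.append(f"{a.symbol:<3s} {x:20.12f} {y:20.12f} {z:20.12f}")
    Path(path).write_text("\n".join(lines) + "\n")
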