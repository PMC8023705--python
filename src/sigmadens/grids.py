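"""Assembly of per-atom molecular integration grids.

Each atom owns an :class:`AtomicGrid` whose weights combine the radial
weight (with the r^2 volume factor), the 4*pi-scaled angular weight and
the Becke fuzzy-cell weight of the owner atom.  Summing an integrand over
the union of all atomic grids approximates its whole-space integral; the
per-atom partial sums are the Becke atomic domains used in the shielding
decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .angular import LEBEDEV_ORDERS, lebedev_grid, product_grid
from .becke import BeckeSpec, becke_weights
from .constants import SYMBOL_TO_Z
from .radial import radial_grid, radial_grid_from_exponents


@dataclass
class AtomicGrid:
    """Quadrature points owned by one atom; weights in bohr^3."""

    atom_index: int
    points: np.ndarray   # (n, 3)
    weights: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if self.points.shape[0] != self.weights.shape[0]:
            raise ValueError("points/weights length mismatch")

    @property
    def n_points(self) -> int:
        return self.weights.size


def _exponent_ranges(molecule, shells):
    """Per-atom (zeta_min, zeta_max) from an explicit basis, if given."""
    ranges = {}
    if shells is None:
        return ranges
    for sh in shells:
        e = sh.exponents
        lo, hi = float(e.min()), float(e.max())
        cur = ranges.get(sh.center)
        if cur is None:
            ranges[sh.center] = [lo, hi]
        else:
            cur[0] = min(cur[0], lo)
            cur[1] = max(cur[1], hi)
    return ranges


def build_grids(
    molecule,
    radial_accuracy: float = 1e-10,
    angular_order: int = 29,
    becke: BeckeSpec | None = None,
    shells=None,
    angular_scheme: str = "product",
    prune: bool = False,
) -> list[AtomicGrid]:
    """Build one Becke-weighted atomic grid per atom.

    Parameters
    ----------
    radial_accuracy:
        Relative accuracy parameter of the exponential radial grid.
    angular_order:
        For ``angular_scheme="product"`` the algebraic degree of the
        Gauss-Legendre x trapezoid sphere rule; for ``"lebedev"`` the
        Lebedev point count (one of the implemented orders).
    becke:
        Fuzzy-cell parameters (iteration order k, radii, size adjustment).
    shells:
        Optional basis (sequence of GaussianShell); when given, each
        atom's radial range is derived from the exponents actually
        centered on it instead of the per-element defaults.
    prune:
        If true, drop points whose combined weight is below 1e-16 of the
        grid's maximum weight (pure storage saving; off by default).
    """
    becke = becke or BeckeSpec()
    if angular_scheme == "lebedev":
        if angular_order not in LEBEDEV_ORDERS:
            raise ValueError(
                f"Lebedev order {angular_order} unavailable; "
                f"choose from {list(LEBEDEV_ORDERS)}"
            )
        ang_pts, ang_w = lebedev_grid(angular_order)
    elif angular_scheme == "product":
        ang_pts, ang_w = product_grid(angular_order)
    else:
        raise ValueError("angular_scheme must be 'product' or 'lebedev'")
    ang_w = ang_w * 4.0 * np.pi

    ranges = _exponent_ranges(molecule, shells)
    grids = []
    coords = molecule.coords
    for ia, atom in enumerate(molecule.atoms):
        if ia in ranges:
            zmin, zmax = ranges[ia]
            # Pad: products of Gaussians on different centers can be more
            # diffuse/steep than either factor alone only within this range.
            r, rw = radial_grid_from_exponents(
                0.5 * zmin, 2.0 * zmax, radial_accuracy
            )
        else:
            r, rw = radial_grid(atom.symbol, radial_accuracy)
        pts = (
            coords[ia][None, None, :]
            + r[:, None, None] * ang_pts[None, :, :]
        ).reshape(-1, 3)
        w = (rw[:, None] * ang_w[None, :]).reshape(-1)
        if molecule.n_atoms > 1:
            bw = becke_weights(pts, molecule, becke)[:, ia]
            w = w * bw
        if prune:
            keep = w > 1e-16 * w.max()
            pts, w = pts[keep], w[keep]
        grids.append(AtomicGrid(ia, pts, w))
    return grids


def total_points(grids) -> int:
    return sum(g.n_points for g in grids)


def integrate(grids, func) -> float:
    """Integrate ``func(points) -> values`` over the union of atomic grids."""
    return float(
        sum(np.dot(g.weights, np.asarray(func(g.points))) for g in grids)
    )


def dump_grid_text(grids, path) -> None:
    """Write all grid points as plain columns ``x y z w atom`` (bohr)."""
    with open(path, "w") as fh:
        fh.write("# x y z w atom_index  (bohr, bohr^3)\n")
        for g in grids:
            for (x, y, z), w in zip(g.points, g.weights):
                fh.write(
                    f"{x:22.14e} {y:22.14e} {z:22.14e} {w:22.14e} {g.atom_index:4d}\n"
                )


def load_grid_text(path) -> list[AtomicGrid]:
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return []
    grids = []
    for ia in np.unique(data[:, 4].astype(int)):
        rows = data[data[:, 4].astype(int) == ia]
        grids.append(AtomicGrid(int(ia), rows[:, :3], rows[:, 3]))
    return grids
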