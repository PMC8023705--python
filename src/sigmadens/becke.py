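"""Becke fuzzy-cell multicenter partitioning.

Space is divided into overlapping atomic cells via the iterated smoothed
step function of the confocal coordinate mu_ij = (r_i - r_j)/R_ij.  The
default iteration order is k = 3 and the cell-function argument uses
Bragg-Slater radii with Becke's heteronuclear size adjustment (clamped to
|a| <= 1/2), both configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import bragg_slater_radius


@dataclass
class BeckeSpec:
    """Parameters of the fuzzy-cell construction.

    iteration_order:
        Number of applications of p(x) = (3x - x^3)/2 (Becke's k; k=3 is
        the recommended and default value).
    size_adjust:
        Apply the heteronuclear cell-boundary shift derived from the
        per-element radii.  Disabling it makes all cells meet at bond
        midpoints.
    radii:
        Optional {element symbol: radius in bohr} override of the
        Bragg-Slater radii.
    """

    iteration_order: int = 3
    size_adjust: bool = True
    radii: dict | None = None

    def __post_init__(self) -> None:
        if self.iteration_order < 1:
            raise ValueError("Becke iteration order k must be >= 1")

    def radius(self, symbol: str) -> float:
        if self.radii and symbol in self.radii:
            return self.radii[symbol]
        return bragg_slater_radius(symbol)


def becke_cell(mu, k: int = 3):
    """Smoothed step s(mu) on [-1, 1]: s(-1) = 1, s(0) = 1/2, s(1) = 0.

    Iterates p(x) = (3x - x^3)/2 k times and maps to (1 - p_k)/2.
    Accepts scalars or arrays; values outside [-1, 1] by more than 1e-12
    raise a domain error.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < -1.0 - 1e-12) or np.any(mu > 1.0 + 1e-12):
        raise ValueError("becke_cell argument must lie in [-1, 1]")
    f = np.clip(mu, -1.0, 1.0)
    for _ in range(k):
        f = 0.5 * f * (3.0 - f * f)
    s = 0.5 * (1.0 - f)
    return float(s) if s.ndim == 0 else s


def _size_adjustment(molecule, spec: BeckeSpec) -> np.ndarray:
    """Pairwise boundary-shift parameters a_ij (Becke's appendix)."""
    n = molecule.n_atoms
    a = np.zeros((n, n))
    if not spec.size_adjust:
        return a
    radii = np.array([spec.radius(s) for s in molecule.symbols])
    chi = radii[:, None] / radii[None, :]
    u = (chi - 1.0) / (chi + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(np.abs(u) > 0, u / (u * u - 1.0), 0.0)
    np.fill_diagonal(a, 0.0)
    return np.clip(a, -0.5, 0.5)


def becke_weights(points, molecule, spec: BeckeSpec | None = None) -> np.ndarray:
    """Per-atom fuzzy-cell weights at each point.

    Returns a (n_points, n_atoms) array; each row is non-negative and sums
    to 1 (partition of unity).
    """
    spec = spec or BeckeSpec()
    points = np.atleast_2d(np.asarray(points, dtype=float))
    coords = molecule.coords
    n_at = molecule.n_atoms
    if n_at == 1:
        return np.ones((points.shape[0], 1))
    rij = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    aij = _size_adjustment(molecule, spec)
    dist = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=2)
    cell = np.ones((points.shape[0], n_at))
    for i in range(n_at):
        for j in range(n_at):
            if i == j:
                continue
            mu = (dist[:, i] - dist[:, j]) / rij[i, j]
            mu = np.clip(mu, -1.0, 1.0)
            nu = mu + aij[i, j] * (1.0 - mu * mu)
            cell[:, i] *= becke_cell(nu, spec.iteration_order)
    total = cell.sum(axis=1, keepdims=True)
    return cell / total
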