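"""Plane scans and volumetric export of shielding-density fields.

Plane scans sample a scalar field on a regular 2-D lattice defined by an
origin, two orthonormal in-plane axes and an offset along their normal
(e.g. the molecular plane, or 1 a0 above it).  Volumetric fields are
written in the Gaussian cube dialect: lengths in bohr, an atom block, and
z-fastest value ordering.  Cube files always store raw values; display
clamp ranges and isovalues are only recorded as header metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class PlaneSpec:
    """A regular rectangular lattice in an arbitrary plane (bohr)."""

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_u: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    axis_v: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    extent_u: tuple = (-5.0, 5.0)
    extent_v: tuple = (-5.0, 5.0)
    spacing: float = 0.2
    offset: float = 0.0
    clamp: tuple | None = None   # display clamp (lo, hi); raw values kept

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axis_u = np.asarray(self.axis_u, dtype=float).reshape(3)
        self.axis_v = np.asarray(self.axis_v, dtype=float).reshape(3)
        for name, ax in (("axis_u", self.axis_u), ("axis_v", self.axis_v)):
            n = np.linalg.norm(ax)
            if abs(n - 1.0) > 1e-12:
                raise ValueError(f"{name} must be a unit vector")
        if abs(self.axis_u @ self.axis_v) > 1e-12:
            raise ValueError("plane axes must be orthonormal")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.axis_u, self.axis_v)

    def lattice(self):
        """(u values, v values, (nu, nv, 3) world coordinates)."""
        u = np.arange(self.extent_u[0], self.extent_u[1] + 0.5 * self.spacing,
                      self.spacing)
        v = np.arange(self.extent_v[0], self.extent_v[1] + 0.5 * self.spacing,
                      self.spacing)
        base = self.origin + self.offset * self.normal
        pts = (
            base[None, None, :]
            + u[:, None, None] * self.axis_u[None, None, :]
            + v[None, :, None] * self.axis_v[None, None, :]
        )
        return u, v, pts


@dataclass
class PlaneScan:
    spec: PlaneSpec
    u: np.ndarray
    v: np.ndarray
    points: np.ndarray   # (nu, nv, 3)
    values: np.ndarray   # (nu, nv) raw values

    @property
    def clamped(self) -> np.ndarray:
        """Export channel: values clipped to the spec's clamp range."""
        if self.spec.clamp is None:
            return self.values
        lo, hi = self.spec.clamp
        return np.clip(self.values, lo, hi)

    def to_csv(self, path) -> None:
        """Columns x, y, z, value (bohr; raw, unclamped values)."""
        with open(path, "w") as fh:
            fh.write("x,y,z,value\n")
            flat_p = self.points.reshape(-1, 3)
            flat_v = self.values.reshape(-1)
            for (x, y, z), val in zip(flat_p, flat_v):
                fh.write(f"{x:.12g},{y:.12g},{z:.12g},{val:.12g}\n")


def plane_scan(field_source, spec: PlaneSpec) -> PlaneScan:
    """Sample ``field_source(points (n,3)) -> (n,)`` on the plane lattice."""
    u, v, pts = spec.lattice()
    vals = np.asarray(field_source(pts.reshape(-1, 3))).reshape(len(u), len(v))
    return PlaneScan(spec, u, v, pts, vals)


def write_cube(values, origin, axes_spacing, molecule, path,
               comment: str = "", metadata: str = "") -> None:
    """Write a scalar lattice as a Gaussian cube file.

    Parameters
    ----------
    values : (nx, ny, nz) array
    origin : corner of the lattice (bohr)
    axes_spacing : scalar or 3-vector of uniform spacings along x, y, z
    molecule : Molecule for the atom block
    metadata : free-form text for the second comment line (e.g. clamp
        range or suggested isovalue)
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("cube values must be a 3-D lattice")
    spacing = np.broadcast_to(np.asarray(axes_spacing, dtype=float), (3,))
    if np.any(spacing <= 0):
        raise ValueError("cube spacing must be positive and uniform per axis")
    origin = np.asarray(origin, dtype=float).reshape(3)
    nx, ny, nz = values.shape
    lines = [comment.replace("\n", " "), metadata.replace("\n", " ")]
    lines.append(
        f"{molecule.n_atoms:5d} {origin[0]:12.6f} {origin[1]:12.6f} "
        f"{origin[2]:12.6f}"
    )
    for n, ax in zip((nx, ny, nz), np.diag(spacing)):
        lines.append(
            f"{n:5d} {ax[0]:12.6f} {ax[1]:12.6f} {ax[2]:12.6f}"
        )
    for atom in molecule.atoms:
        x, y, z = atom.position
        lines.append(
            f"{int(atom.charge):5d} {atom.charge:12.6f} "
            f"{x:12.6f} {y:12.6f} {z:12.6f}"
        )
    flat = values.reshape(nx * ny, nz)
    for row in flat:
        for k in range(0, nz, 6):
            lines.append(" ".join(f"{val:13.5e}" for val in row[k : k + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path):
    """Read a cube file written by :func:`write_cube`.

    Returns (values (nx,ny,nz), origin, spacing (3,), atom block rows).
    """
    lines = Path(path).read_text().splitlines()
    n_atoms = int(lines[2].split()[0])
    origin = np.array([float(x) for x in lines[2].split()[1:4]])
    dims, spacing = [], []
    for i in range(3):
        parts = lines[3 + i].split()
        dims.append(int(parts[0]))
        spacing.append(float(parts[1 + i]))
    atoms = []
    for i in range(n_atoms):
        parts = lines[6 + i].split()
        atoms.append(
            (int(parts[0]), np.array([float(x) for x in parts[2:5]]))
        )
    data = []
    for line in lines[6 + n_atoms :]:
        data.extend(float(x) for x in line.split())
    values = np.array(data).reshape(tuple(dims))
    return values, origin, np.array(spacing), atoms


def volume_scan(field_source, origin, spacing, shape, chunk: int = 100000):
    """Sample a field on a regular axis-aligned lattice (z fastest)."""
    origin = np.asarray(origin, dtype=float).reshape(3)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    nx, ny, nz = shape
    xs = origin[0] + spacing[0] * np.arange(nx)
    ys = origin[1] + spacing[1] * np.arange(ny)
    zs = origin[2] + spacing[2] * np.arange(nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    out = np.empty(pts.shape[0])
    for s in range(0, pts.shape[0], chunk):
        out[s : s + chunk] = np.asarray(field_source(pts[s : s + chunk]))
    return out.reshape(nx, ny, nz)
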