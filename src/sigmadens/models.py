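"""Analytic current-density models and minimal synthetic response bundles.

These are first-class, engine-free current-density providers with
closed-form Biot-Savart answers:

* :class:`LoopModel` -- a toroidal ring current with Gaussian cross
  section; the thin-loop limit reproduces the textbook field of a current
  loop, and the finite-width on-axis shielding reduces to a 2-D profile
  integral (superposition of thin loops).
* :class:`VortexModel` -- the diamagnetic Larmor vortex of a spherical
  Gaussian density; its isotropic shielding at the center is the Lamb
  closed form alpha^2/3 <1/r>.
* :func:`make_min_bundle` -- hand-checkable 1-2 center s-type response
  bundles whose CDT is reproduced independently by a symbolic oracle.
* :func:`benzene_like_composite` -- a qualitative superposition
  (perimeter diatropic loop + inner paratropic loop + atomic vortices)
  with the sign topology of an aromatic ring; used for map smoke tests
  only, never compared to ab initio numbers.

All providers return the c-scaled current-density derivative (the package
convention; see the cdt module), are linear in their strength parameters
and divergence-free by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .basis import GaussianShell, primitive_normalization
from .bundle import ResponseBundle
from .constants import ALPHA, PPM
from .molecule import Molecule


@dataclass
class LoopModel:
    """Toroidal ring current with Gaussian cross-section profile.

    The current density for a unit external field along the loop normal is
    ``J(r) = sign * strength * g(s) phi_hat``, where s is the distance
    from the circular centerline, ``g(s) = exp(-s^2/2w^2) / (2 pi w^2)``
    (so the total circulating current is ``strength``), and the sign is
    chosen so a *diatropic* loop opposes the external field at its center
    (current in the -phi_hat sense for a field along +normal).  The
    response projects onto the field component along the normal.
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    radius: float = 1.0
    strength: float = 1.0
    width: float = 0.1
    tropicity: str = "diatropic"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        self.normal = n / np.linalg.norm(n)
        if self.radius <= 0 or self.width <= 0:
            raise ValueError("loop radius and width must be positive")
        if self.tropicity not in ("diatropic", "paratropic"):
            raise ValueError("tropicity must be 'diatropic' or 'paratropic'")

    @property
    def sign(self) -> float:
        return -1.0 if self.tropicity == "diatropic" else +1.0


class LoopProvider:
    def __init__(self, model: LoopModel):
        self.model = model

    def _current(self, points) -> np.ndarray:
        m = self.model
        d = np.atleast_2d(points) - m.center
        zp = d @ m.normal
        rho_vec = d - np.outer(zp, m.normal)
        rho = np.linalg.norm(rho_vec, axis=1)
        s2 = (rho - m.radius) ** 2 + zp**2
        g = np.exp(-0.5 * s2 / m.width**2) / (2.0 * np.pi * m.width**2)
        phi_hat = np.zeros_like(rho_vec)
        ok = rho > 1e-14
        phi_hat[ok] = np.cross(m.normal, rho_vec[ok] / rho[ok, None])
        return m.sign * m.strength * g[:, None] * phi_hat

    def tensor(self, points) -> np.ndarray:
        J = self._current(points)
        return J[:, :, None] * self.model.normal[None, None, :]

    def __call__(self, points, beta: int) -> np.ndarray:
        return self._current(points) * self.model.normal[beta]


def make_loop_provider(model: LoopModel) -> LoopProvider:
    return LoopProvider(model)


def loop_center_shielding(model: LoopModel) -> float:
    """Thin-loop limit sigma_nn at the loop center, in ppm.

    Textbook Biot-Savart: B = mu0 I / 2R, i.e. 2 pi alpha^2 I / R in this
    package's units, with the diatropic sign giving a positive
    (shielding) value.
    """
    sgn = 1.0 if model.tropicity == "diatropic" else -1.0
    return sgn * 2.0 * np.pi * ALPHA**2 * model.strength / model.radius * PPM


def loop_on_axis_field(strength, radius, z):
    """On-axis thin-loop field magnitude 2 pi I R^2/(R^2+z^2)^(3/2) x alpha^2."""
    return (
        2.0 * np.pi * ALPHA**2 * strength * radius**2
        / (radius**2 + z**2) ** 1.5
    )


def loop_center_shielding_profile(model: LoopModel, n_quad: int = 150) -> float:
    """Finite-width sigma_nn at the loop center by thin-loop superposition.

    Each cross-section element at radial offset u and height v is a thin
    loop of radius R+u at height v; its on-axis contribution at the center
    is 2 pi alpha^2 (R+u)^2 / ((R+u)^2 + v^2)^(3/2) per unit current.
    Evaluated with Gauss-Hermite quadrature over the Gaussian profile;
    serves as the independent closed-form oracle for the 3-D quadrature.
    """
    from scipy.special import roots_hermitenorm

    t, wt = roots_hermitenorm(n_quad)
    u = model.width * t
    keep = u > -model.radius  # loops with negative radius don't exist
    u, wu = u[keep], wt[keep]
    v, wv = model.width * t, wt
    a = model.radius + u
    contrib = (
        a[:, None] ** 2 / (a[:, None] ** 2 + v[None, :] ** 2) ** 1.5
    )
    w2d = np.outer(wu, wv) / (2.0 * np.pi)
    sgn = 1.0 if model.tropicity == "diatropic" else -1.0
    return (
        sgn * 2.0 * np.pi * ALPHA**2 * model.strength
        * float(np.sum(w2d * contrib)) * PPM
    )


@dataclass
class VortexModel:
    """Larmor (diamagnetic) vortex of a spherical Gaussian 1s density.

    rho(r) = n_electrons * phi_1s(zeta)^2 and
    J(r) = -1/2 rho(r) (B_hat x (r - center)) -- the atomic-current
    idealization of core contributions.
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    zeta: float = 1.0
    n_electrons: float = 1.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")

    def density(self, points) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        r2 = np.einsum("ij,ij->i", d, d)
        return (
            self.n_electrons
            * (2.0 * self.zeta / np.pi) ** 1.5
            * np.exp(-2.0 * self.zeta * r2)
        )

    def lamb_shielding(self) -> float:
        """Closed-form Lamb isotropic shielding at the center, ppm.

        sigma = alpha^2/3 <1/r> with <1/r> = 2 sqrt(2 zeta / pi) per
        electron for the Gaussian 1s density.
        """
        inv_r = 2.0 * math.sqrt(2.0 * self.zeta / np.pi) * self.n_electrons
        return ALPHA**2 / 3.0 * inv_r * PPM


class VortexProvider:
    def __init__(self, model: VortexModel):
        self.model = model

    def tensor(self, points) -> np.ndarray:
        pts = np.atleast_2d(points)
        rho = self.model.density(pts)
        d = pts - self.model.center
        # T[a, b] = -1/2 rho eps_abg d_g
        T = np.zeros((pts.shape[0], 3, 3))
        for a in range(3):
            for b in range(3):
                g = 3 - a - b
                if a == b or g not in (0, 1, 2):
                    continue
                sign = 1.0 if (a, b) in ((0, 1), (1, 2), (2, 0)) else -1.0
                T[:, a, b] = -0.5 * rho * sign * d[:, g]
        return T

    def __call__(self, points, beta: int) -> np.ndarray:
        pts = np.atleast_2d(points)
        rho = self.model.density(pts)
        e = np.zeros(3)
        e[beta] = 1.0
        return -0.5 * rho[:, None] * np.cross(e, pts - self.model.center)


def make_vortex_provider(model: VortexModel) -> VortexProvider:
    return VortexProvider(model)


class SuperpositionProvider:
    """Linear superposition of current-density providers."""

    def __init__(self, *providers, molecule=None):
        self.providers = providers
        if molecule is not None:
            self.molecule = molecule

    def tensor(self, points) -> np.ndarray:
        from .cdt import provider_tensor

        return sum(provider_tensor(p, points) for p in self.providers)

    def __call__(self, points, beta: int) -> np.ndarray:
        return sum(np.asarray(p(points, beta)) for p in self.providers)


def scaled_provider(provider, factor: float):
    """Provider scaled by a constant (used for linearity checks)."""

    class _Scaled:
        def tensor(self, points):
            from .cdt import provider_tensor

            return factor * provider_tensor(provider, points)

        def __call__(self, points, beta):
            return factor * np.asarray(provider(points, beta))

    return _Scaled()


def _s_overlap(zeta_a, A, zeta_b, B) -> float:
    """Overlap of two normalized s-type Gaussian primitives."""
    p = zeta_a + zeta_b
    ab2 = float(np.sum((np.asarray(A) - np.asarray(B)) ** 2))
    return (4.0 * zeta_a * zeta_b / p**2) ** 0.75 * math.exp(
        -zeta_a * zeta_b / p * ab2
    )


def s_shell_overlap(shell_a, shell_b, coords) -> float:
    """Overlap of two contracted s shells (normalized-primitive coefficients)."""
    A, B = coords[shell_a.center], coords[shell_b.center]
    tot = 0.0
    for za, ca in shell_a.primitives:
        for zb, cb in shell_b.primitives:
            tot += ca * cb * _s_overlap(za, A, zb, B)
    return tot


def make_min_bundle(symbols, coords, exponents, density, perturbed_density,
                    metadata=None) -> ResponseBundle:
    """Minimal s-type response bundle with analytic overlap.

    Parameters
    ----------
    symbols, coords:
        One or two centers (coords in bohr).
    exponents:
        One s-shell exponent per center (single primitive each).
    density, perturbed_density:
        Chosen matrices satisfying the bundle invariants; the electron
        count is taken as tr(D S).
    """
    mol = Molecule.from_arrays(symbols, coords)
    shells = [
        GaussianShell(i, 0, [(float(z), 1.0)]) for i, z in enumerate(exponents)
    ]
    n = len(shells)
    S = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            S[i, j] = s_shell_overlap(shells[i], shells[j], mol.coords)
    D = np.asarray(density, dtype=float)
    Db = np.asarray(perturbed_density, dtype=float).reshape(3, n, n)
    return ResponseBundle(
        molecule=mol,
        shells=shells,
        overlap=S,
        density=D,
        perturbed_density=Db,
        n_electrons=float(np.trace(D @ S)),
        metadata=metadata or {"method": "synthetic"},
    )


def benzene_ring_molecule(cc: float = 2.6361, ch: float = 2.0408) -> Molecule:
    """Idealized D6h benzene-like ring geometry (bond lengths in bohr)."""
    r_c = cc  # ring radius equals the C-C bond length for a hexagon
    r_h = r_c + ch
    symbols, coords = [], []
    for k in range(6):
        a = np.pi / 3.0 * k
        symbols.append("C")
        coords.append([r_c * np.cos(a), r_c * np.sin(a), 0.0])
    for k in range(6):
        a = np.pi / 3.0 * k
        symbols.append("H")
        coords.append([r_h * np.cos(a), r_h * np.sin(a), 0.0])
    return Molecule.from_arrays(symbols, coords)


def benzene_like_composite(
    perimeter_strength: float = 1.0,
    inner_strength: float = 0.35,
    with_inner_loop: bool = True,
    with_vortices: bool = True,
) -> SuperpositionProvider:
    """Qualitative aromatic-ring current model.

    A diatropic perimeter loop (radius just inside the H positions, where
    the pi ring current of an aromatic ring flows), a weaker paratropic
    loop inside the ring, and Larmor vortices on each atom.  The sign
    topology of its shielding-density maps mimics an aromatic ring; the
    numbers are arbitrary model units, never compared to ab initio data.
    """
    mol = benzene_ring_molecule()
    parts = [
        make_loop_provider(
            LoopModel(radius=3.9, strength=perimeter_strength, width=0.9,
                      tropicity="diatropic")
        )
    ]
    if with_inner_loop:
        parts.append(
            make_loop_provider(
                LoopModel(radius=1.4, strength=inner_strength, width=0.6,
                          tropicity="paratropic")
            )
        )
    if with_vortices:
        for i, atom in enumerate(mol.atoms):
            if atom.symbol == "C":
                # tight core-like vortex: large on-site shielding, weak
                # net contribution to distant nuclei (near/far sides of
                # the vortex nearly cancel, as for real atomic currents)
                parts.append(
                    make_vortex_provider(
                        VortexModel(center=atom.position, zeta=8.0,
                                    n_electrons=2.0)
                    )
                )
            else:
                parts.append(
                    make_vortex_provider(
                        VortexModel(center=atom.position, zeta=1.2,
                                    n_electrons=1.0)
                    )
                )
    return SuperpositionProvider(*parts, molecule=mol)
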