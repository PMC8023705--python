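"""Current-density susceptibility tensor (CDT) from GIAO response matrices.

The magnetically induced current density of a molecule in an external
field B, expanded in London orbitals (GIAOs)

    chi_mu(r) = exp[-i/(2c) (B x (R_mu - R_O)) . r] phi_mu(r),

is linear in B; its derivative is the CDT, T_ab(r) = dJ_a(r)/dB_b.  In
this package T is kept in the c-scaled convention (T = c dJ/dB in pure
atomic units), so that a rigid closed-shell density with no paramagnetic
response carries the Larmor tensor

    T_ab(r) = -1/2 rho(r) eps_abg (r - R)_g ,

and the Biot-Savart kernel of the shielding module supplies the overall
alpha^2.  Expanding J = -Re sum_munu Dt_munu chi_nu^* (p + A/c) chi_mu to
first order in B (Dt = D + i sum_b B_b Db_b) gives three terms in which
the gauge origin R_O cancels identically:

    T_ab(r) = - c sum_munu Db_b,munu  phi_nu d_a phi_mu
              + 1/2 sum_munu D_munu [(e_b x (R_mu - R_nu)) . r]
                                     phi_nu d_a phi_mu
              - 1/2 sum_munu D_munu phi_mu phi_nu [e_b x (r - R_mu)]_a

No gauge-origin parameter exists anywhere in this module; the derivation
is spelled out in docs/methods.md and cross-checked against a symbolic
evaluation that keeps R_O explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import eval_ao, n_ao
from .constants import SPEED_OF_LIGHT

#: Levi-Civita tensor, eps[a, b, g].
EPS = np.zeros((3, 3, 3))
EPS[0, 1, 2] = EPS[1, 2, 0] = EPS[2, 0, 1] = 1.0
EPS[0, 2, 1] = EPS[2, 1, 0] = EPS[1, 0, 2] = -1.0


@dataclass
class CdtSample:
    """CDT values at a point set: tensor[i, a, b] = dJ_a/dB_b at points[i]."""

    points: np.ndarray   # (n, 3)
    tensor: np.ndarray   # (n, 3, 3)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.shape != (self.points.shape[0], 3, 3):
            raise ValueError("tensor must have shape (n_points, 3, 3)")
        if not np.all(np.isfinite(self.tensor)):
            raise ValueError("CDT values must be finite")


def eval_cdt(bundle, points, chunk_size: int = 5000) -> CdtSample:
    """Evaluate the full 3x3 CDT of a response bundle at arbitrary points.

    Points are processed in chunks of ``chunk_size`` to bound the working
    set (typical production grids have ~2e5 points and hundreds of AOs).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    nao = n_ao(bundle.shells)
    for name, mat, shape in (
        ("density", bundle.density, (nao, nao)),
        ("perturbed_density", bundle.perturbed_density, (3, nao, nao)),
    ):
        if mat.shape != shape:
            raise ValueError(
                f"{name} dimension {mat.shape} does not match the "
                f"{nao} AOs implied by the shell list"
            )
    centers = np.array(
        [c for sh in bundle.shells for c in [sh.center] * sh.n_functions]
    )
    r_ao = bundle.molecule.coords[centers]          # (nao, 3)
    D = bundle.density
    Db = bundle.perturbed_density
    c = SPEED_OF_LIGHT
    ex = np.eye(3)
    cross_e_rao = np.stack([np.cross(ex[b], r_ao) for b in range(3)])  # (3, nao, 3)

    out = np.empty((points.shape[0], 3, 3))
    for start in range(0, points.shape[0], chunk_size):
        pts = points[start : start + chunk_size]
        phi, grad = eval_ao(bundle.shells, bundle.molecule, pts)
        V = phi @ D                       # (np, nao)
        rho = np.einsum("pm,pm->p", phi, V)
        for beta in range(3):
            W = pts @ cross_e_rao[beta].T             # (np, nao)
            M = phi @ Db[beta].T
            X = (W * phi) @ D
            para = np.einsum("pam,pm->pa", grad, -c * M + 0.5 * (W * V - X))
            # term3: -1/2 eps_abg [rho r_g - sum_mu phi_mu V_mu R_mu,g]
            Q = rho[:, None] * pts - (phi * V) @ r_ao  # (np, 3)
            dia = -0.5 * Q @ EPS[:, beta, :].T
            out[start : start + len(pts), :, beta] = para + dia
    return CdtSample(points, out)


def bundle_provider(bundle, chunk_size: int = 5000):
    """Wrap a bundle as a current-density provider.

    The provider contract: ``provider(points, beta) -> (n, 3)`` returns
    the c-scaled current-density derivative field for a unit external
    field along axis ``beta``.  Providers may additionally expose
    ``provider.tensor(points) -> (n, 3, 3)``; this one does.
    """

    def tensor(points):
        return eval_cdt(bundle, points, chunk_size=chunk_size).tensor

    def provider(points, beta):
        return tensor(points)[:, :, beta]

    provider.tensor = tensor
    provider.molecule = bundle.molecule
    return provider


def provider_tensor(provider, points) -> np.ndarray:
    """Full (n, 3, 3) CDT from any provider (uses .tensor when available)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    t = getattr(provider, "tensor", None)
    if t is not None:
        return np.asarray(t(points))
    return np.stack([np.asarray(provider(points, b)) for b in range(3)], axis=2)


def divergence_residual(provider, point, spacing: float = 1e-3) -> np.ndarray:
    """Central-difference estimate of div(dJ/dB_beta) for beta = x, y, z.

    The induced current of an exact calculation is solenoidal; the
    residual is a numerical sanity probe (second-order in ``spacing``).
    """
    point = np.asarray(point, dtype=float).reshape(3)
    res = np.zeros(3)
    for beta in range(3):
        div = 0.0
        for axis in range(3):
            e = np.zeros(3)
            e[axis] = spacing
            jp = np.asarray(provider((point + e)[None, :], beta))[0, axis]
            jm = np.asarray(provider((point - e)[None, :], beta))[0, axis]
            div += (jp - jm) / (2.0 * spacing)
        res[beta] = div
    return res
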