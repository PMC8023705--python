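"""Contracted solid-harmonic Gaussian basis functions and their gradients.

The canonical AO ordering is: shells in input order, and within a shell the
real solid harmonics m = -l, ..., +l.  Real solid harmonics are defined
without the Condon-Shortley phase, so S(1,1) is proportional to +x,
S(2,2) to x^2 - y^2, etc.; the monomial expansions are generated
symbolically once per angular momentum and cached.

Only spherical (pure) shells are supported beyond l = 1; this is the
canonical dialect of the toolkit and adapters are expected to transform
Cartesian engine output into it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

MAX_L = 4  # up to g functions


class UnsupportedAngularMomentumError(ValueError):
    pass


@dataclass
class GaussianShell:
    """One contracted shell: ``sum_i c_i N_i C_lm(r-A) exp(-zeta_i |r-A|^2)``.

    ``coefficients`` refer to unit-normalized solid-harmonic primitives
    (N_i is the primitive normalization, applied internally).
    """

    center: int                       # index into Molecule.atoms
    l: int
    primitives: list = field(default_factory=list)  # [(exponent, coefficient)]
    pure: bool = True

    def __post_init__(self) -> None:
        if self.l < 0:
            raise ValueError("angular momentum must be >= 0")
        if self.l > MAX_L:
            raise UnsupportedAngularMomentumError(
                f"l={self.l} not supported (max l={MAX_L}, i.e. g functions)"
            )
        if not self.pure and self.l > 1:
            raise UnsupportedAngularMomentumError(
                "Cartesian shells beyond p are not part of the canonical "
                "dialect; transform to solid harmonics in the adapter"
            )
        if not self.primitives:
            raise ValueError("a shell needs at least one primitive")
        exps = [e for e, _ in self.primitives]
        if any(e <= 0 for e in exps):
            raise ValueError("primitive exponents must be strictly positive")
        if any(exps[i] < exps[i + 1] for i in range(len(exps) - 1)):
            raise ValueError("primitive exponents must be sorted descending")

    @property
    def n_functions(self) -> int:
        return 2 * self.l + 1

    @property
    def exponents(self) -> np.ndarray:
        return np.array([e for e, _ in self.primitives])

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for _, c in self.primitives])


def primitive_normalization(zeta: float, l: int) -> float:
    """Normalization of a solid-harmonic Gaussian primitive.

    ``int |N C_lm(r) exp(-zeta r^2)|^2 d^3r = 1`` with C_lm carrying the
    orthonormal-on-the-sphere angular normalization.
    """
    return math.sqrt(2.0 * (2.0 * zeta) ** (l + 1.5) / math.gamma(l + 1.5))


@lru_cache(maxsize=None)
def solid_harmonic_monomials(l: int):
    """Monomial expansion of the real solid harmonics of angular momentum l.

    Returns a list over m = -l..l; each entry is a list of
    ``(coefficient, (px, py, pz))`` monomial terms of
    C_lm(x, y, z) = r^l S_lm(theta, phi), with S_lm orthonormal real
    spherical harmonics (no Condon-Shortley phase).
    """
    if l > MAX_L:
        raise UnsupportedAngularMomentumError(f"l={l} beyond supported maximum")
    import sympy as sp

    x, y, z, u = sp.symbols("x y z u", real=True)
    r2 = x * x + y * y + z * z
    out_by_m: dict[int, list] = {}
    for m in range(0, l + 1):
        # Q = d^m/du^m P_l(u): polynomial part of the associated Legendre fn.
        Q = sp.diff(sp.legendre(l, u), u, m)
        Qp = sp.Poly(Q, u)
        # r^(l-m) * Q(z/r) as a polynomial in z and r^2.
        radial = sp.Integer(0)
        for (j,), q in Qp.terms():
            k = l - m - j
            assert k % 2 == 0
            radial += q * z**j * r2 ** (k // 2)
        norm = sp.sqrt(
            sp.Rational(2 * l + 1, 4)
            / sp.pi
            * sp.factorial(l - m)
            / sp.factorial(l + m)
        )
        if m == 0:
            polys = {0: norm * radial}
        else:
            xy = sp.expand((x + sp.I * y) ** m)
            a_m = sp.re(xy)
            b_m = sp.im(xy)
            polys = {
                m: sp.sqrt(2) * norm * a_m * radial,
                -m: sp.sqrt(2) * norm * b_m * radial,
            }
        for mm, expr in polys.items():
            p = sp.Poly(sp.expand(expr), x, y, z)
            out_by_m[mm] = [
                (float(c), tuple(int(e) for e in mono))
                for mono, c in p.terms()
            ]
    return [out_by_m[m] for m in range(-l, l + 1)]


@lru_cache(maxsize=None)
def _monomial_tables(l: int):
    """Per-m arrays (coefs, powers) and gradient tables for fast evaluation."""
    tables = []
    for terms in solid_harmonic_monomials(l):
        coefs = np.array([c for c, _ in terms])
        powers = np.array([p for _, p in terms], dtype=int)  # (nt, 3)
        grads = []
        for axis in range(3):
            gc, gp = [], []
            for c, p in terms:
                if p[axis] > 0:
                    q = list(p)
                    q[axis] -= 1
                    gc.append(c * p[axis])
                    gp.append(tuple(q))
            grads.append((np.array(gc), np.array(gp, dtype=int).reshape(-1, 3)))
        tables.append((coefs, powers, grads))
    return tables


def _poly_eval(d: np.ndarray, coefs: np.ndarray, powers: np.ndarray) -> np.ndarray:
    if coefs.size == 0:
        return np.zeros(d.shape[0])
    # d: (n, 3); powers: (nt, 3)
    mono = np.prod(d[:, None, :] ** powers[None, :, :], axis=2)
    return mono @ coefs


def n_ao(shells) -> int:
    return sum(sh.n_functions for sh in shells)


def eval_ao(shells, molecule, points, chunk_size: int = 20000):
    """Values and Cartesian gradients of every contracted AO at every point.

    Parameters
    ----------
    shells : sequence of GaussianShell
    molecule : Molecule (supplies shell centers)
    points : (n, 3) array, bohr

    Returns
    -------
    values : (n, nao) array
    gradients : (n, 3, nao) array, gradients[i, a, mu] = d(phi_mu)/dr_a at
        point i.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(points)):
        raise ValueError("evaluation points must be finite")
    n = points.shape[0]
    nao = n_ao(shells)
    values = np.empty((n, nao))
    grads = np.empty((n, 3, nao))
    coords = molecule.coords
    for start in range(0, n, chunk_size):
        pts = points[start : start + chunk_size]
        ofs = 0
        for sh in shells:
            d = pts - coords[sh.center]
            s2 = np.einsum("ij,ij->i", d, d)
            exps = sh.exponents
            cN = sh.coefficients * np.array(
                [primitive_normalization(e, sh.l) for e in exps]
            )
            eterm = np.exp(-np.outer(s2, exps))  # (np, nprim)
            g = eterm @ cN
            h = eterm @ (cN * exps)
            for k, (coefs, powers, gtabs) in enumerate(_monomial_tables(sh.l)):
                P = _poly_eval(d, coefs, powers)
                col = ofs + k
                values[start : start + len(pts), col] = P * g
                for axis in range(3):
                    gc, gp = gtabs[axis]
                    dP = _poly_eval(d, gc, gp)
                    grads[start : start + len(pts), axis, col] = (
                        dP * g - 2.0 * d[:, axis] * P * h
                    )
            ofs += sh.n_functions
    return values, grads
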