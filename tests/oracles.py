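"""Slow, independent oracles used by the test suite.

The symbolic CDT oracle re-derives the current-density susceptibility
from first principles with sympy: it builds the London orbitals with an
*explicit* symbolic/numeric gauge origin, forms the first-order complex
density, applies the velocity operator p + A/c, takes the real part and
differentiates with respect to the field components.  It shares no code
path with ``sigmadens.cdt.eval_cdt`` (which implements the analytically
gauge-origin-free expression), so agreement between the two also proves
the gauge-origin cancellation.
"""

from __future__ import annotations

import numpy as np
import sympy as sp

from sigmadens.constants import SPEED_OF_LIGHT


def symbolic_cdt(bundle, gauge_origin):
    """Return f(x, y, z) -> 3x3 c-scaled CDT for an s-type bundle."""
    c = SPEED_OF_LIGHT
    x, y, z = sp.symbols("x y z", real=True)
    Bx, By, Bz = sp.symbols("Bx By Bz", real=True)
    r = sp.Matrix([x, y, z])
    B = sp.Matrix([Bx, By, Bz])
    RO = sp.Matrix([sp.Float(v) for v in gauge_origin])
    coords = bundle.molecule.coords
    phis, lams = [], []
    for sh in bundle.shells:
        assert sh.l == 0, "symbolic oracle covers s shells"
        A = sp.Matrix([sp.Float(v) for v in coords[sh.center]])
        d = r - A
        phi = sp.Integer(0)
        for zeta, coef in sh.primitives:
            N = (2 * zeta / sp.pi) ** sp.Rational(3, 4)
            phi += coef * N * sp.exp(-zeta * d.dot(d))
        phis.append(phi)
        lams.append(-(B.cross(A - RO)).dot(r) / (2 * c))
    n = len(phis)
    D = bundle.density
    Db = bundle.perturbed_density
    A_B = B.cross(r - RO) / 2
    Jc = [sp.Integer(0)] * 3
    for mu in range(n):
        chi_mu = sp.exp(sp.I * lams[mu]) * phis[mu]
        v_chi = [
            -sp.I * sp.diff(chi_mu, s) + A_B[k] / c * chi_mu
            for k, s in enumerate((x, y, z))
        ]
        for nu in range(n):
            Dt = D[mu, nu] + sp.I * (
                Bx * Db[0, mu, nu] + By * Db[1, mu, nu] + Bz * Db[2, mu, nu]
            )
            chi_nu_c = sp.conjugate(sp.exp(sp.I * lams[nu]) * phis[nu])
            for k in range(3):
                term = Dt * chi_nu_c * v_chi[k]
                Jc[k] += -(term + sp.conjugate(term)) / 2
    T = sp.zeros(3, 3)
    zero = {Bx: 0, By: 0, Bz: 0}
    for a in range(3):
        Ja = sp.expand(Jc[a])
        for b, Bb in enumerate((Bx, By, Bz)):
            T[a, b] = c * sp.diff(Ja, Bb).subs(zero)
    return sp.lambdify((x, y, z), T, "numpy")


def random_two_center_bundle(rng, separation=None):
    """A random valid 2-center s-type bundle for oracle comparisons."""
    from sigmadens.models import make_min_bundle

    if separation is None:
        separation = rng.uniform(0.8, 2.0, size=3)
    Db = rng.normal(size=(3, 2, 2))
    Db = Db - np.transpose(Db, (0, 2, 1))
    D = rng.normal(size=(2, 2))
    D = D + D.T
    coords = np.vstack([rng.normal(scale=0.3, size=3),
                        rng.normal(scale=0.3, size=3) + separation])
    zetas = rng.uniform(0.5, 2.0, size=2)
    return make_min_bundle(["He", "H"], coords, zetas, D, Db)
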