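"""Unit-sphere quadrature.

Two families are provided:

* :func:`lebedev_grid` -- octahedrally symmetric Lebedev rules for the
  orders whose closed forms are implemented here (6, 14, 26, 38 and 50
  points; algebraic degrees 3, 5, 7, 9 and 11).  The parameters are exact
  algebraic expressions, not copied floating-point tables, and every rule
  is covered by an exactness test over all sphere moments of its degree.
* :func:`product_grid` -- Gauss-Legendre (in cos theta) x trapezoid (in
  phi) product rules, available for any algebraic degree.  These serve as
  the high-accuracy angular grids in production integration.

All rules use the unit-measure convention: weights sum to 1, and are
multiplied by 4 pi at atomic-grid assembly.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product as _iproduct

import numpy as np

__all__ = ["lebedev_grid", "product_grid", "LEBEDEV_ORDERS", "LEBEDEV_DEGREE"]

LEBEDEV_DEGREE = {6: 3, 14: 5, 26: 7, 38: 9, 50: 11}
LEBEDEV_ORDERS = tuple(sorted(LEBEDEV_DEGREE))


def _orbit_vertices():
    pts = []
    for i in range(3):
        for s in (1.0, -1.0):
            v = [0.0, 0.0, 0.0]
            v[i] = s
            pts.append(v)
    return np.array(pts)


def _orbit_edges():
    s = 1.0 / np.sqrt(2.0)
    pts = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        for si, sj in _iproduct((1.0, -1.0), repeat=2):
            v = [0.0, 0.0, 0.0]
            v[i], v[j] = si * s, sj * s
            pts.append(v)
    return np.array(pts)


def _orbit_corners():
    s = 1.0 / np.sqrt(3.0)
    return np.array(list(_iproduct((s, -s), repeat=3)))


def _orbit_pq0(p):
    """24 points of type (+-p, +-q, 0) and permutations, q = sqrt(1-p^2)."""
    q = np.sqrt(1.0 - p * p)
    pts = []
    for i, j in ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)):
        for si, sj in _iproduct((1.0, -1.0), repeat=2):
            v = [0.0, 0.0, 0.0]
            v[i], v[j] = si * p, sj * q
            pts.append(v)
    return np.array(pts)


def _orbit_llm(l):
    """24 points of type (+-l, +-l, +-m) and permutations, m = sqrt(1-2l^2)."""
    m = np.sqrt(1.0 - 2.0 * l * l)
    pts = []
    for pos in range(3):
        rest = [k for k in range(3) if k != pos]
        for sm, s1, s2 in _iproduct((1.0, -1.0), repeat=3):
            v = [0.0, 0.0, 0.0]
            v[pos] = sm * m
            v[rest[0]], v[rest[1]] = s1 * l, s2 * l
            pts.append(v)
    return np.array(pts)


def _rule_6():
    return _orbit_vertices(), np.full(6, 1.0 / 6.0)


def _rule_14():
    pts = np.vstack([_orbit_vertices(), _orbit_corners()])
    w = np.concatenate([np.full(6, 1.0 / 15.0), np.full(8, 3.0 / 40.0)])
    return pts, w


def _rule_26():
    pts = np.vstack([_orbit_vertices(), _orbit_edges(), _orbit_corners()])
    w = np.concatenate(
        [
            np.full(6, float(Fraction(1, 21))),
            np.full(12, float(Fraction(4, 105))),
            np.full(8, float(Fraction(27, 840))),
        ]
    )
    return pts, w


def _rule_38():
    p = np.sqrt((1.0 + 1.0 / np.sqrt(3.0)) / 2.0)
    pts = np.vstack([_orbit_vertices(), _orbit_corners(), _orbit_pq0(p)])
    w = np.concatenate(
        [
            np.full(6, float(Fraction(1, 105))),
            np.full(8, float(Fraction(9, 280))),
            np.full(24, float(Fraction(1, 35))),
        ]
    )
    return pts, w


def _rule_50():
    l = 1.0 / np.sqrt(11.0)
    pts = np.vstack(
        [_orbit_vertices(), _orbit_edges(), _orbit_corners(), _orbit_llm(l)]
    )
    w = np.concatenate(
        [
            np.full(6, float(Fraction(4, 315))),
            np.full(12, float(Fraction(64, 2835))),
            np.full(8, float(Fraction(27, 1280))),
            np.full(24, float(Fraction(11**4, 725760))),
        ]
    )
    return pts, w


_RULES = {6: _rule_6, 14: _rule_14, 26: _rule_26, 38: _rule_38, 50: _rule_50}


def lebedev_grid(order: int):
    """Nodes and weights of an implemented Lebedev rule.

    Parameters
    ----------
    order:
        Number of points; one of ``LEBEDEV_ORDERS``.

    Returns
    -------
    points : (order, 3) unit vectors
    weights : (order,) weights summing to 1
    """
    try:
        pts, w = _RULES[order]()
    except KeyError:
        raise ValueError(
            f"unsupported Lebedev order {order}; supported orders: "
            f"{list(LEBEDEV_ORDERS)} (use product_grid for higher degrees)"
        )
    return pts, w


def product_grid(degree: int):
    """Gauss-Legendre x trapezoid sphere rule exact to the given degree.

    ``n_theta = ceil((degree+1)/2)`` Gauss-Legendre nodes in cos(theta) and
    ``degree+1`` equispaced azimuthal nodes; exactly integrates every
    spherical polynomial of total degree <= ``degree``.
    """
    if degree < 0:
        raise ValueError("degree must be non-negative")
    n_theta = (degree + 2) // 2
    n_phi = max(degree + 1, 1)
    ct, wt = np.polynomial.legendre.leggauss(n_theta)
    phi = 2.0 * np.pi * (np.arange(n_phi) + 0.5) / n_phi
    st = np.sqrt(1.0 - ct * ct)
    pts = np.empty((n_theta * n_phi, 3))
    w = np.empty(n_theta * n_phi)
    k = 0
    for c, s, wgt in zip(ct, st, wt):
        pts[k : k + n_phi, 0] = s * np.cos(phi)
        pts[k : k + n_phi, 1] = s * np.sin(phi)
        pts[k : k + n_phi, 2] = c
        w[k : k + n_phi] = wgt / (2.0 * n_phi)
        k += n_phi
    return pts, w
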