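"""Exponential-type radial quadrature keyed by a single accuracy parameter.

The grid follows the Lindh-Malmqvist-Gagliardi idea: the half-line is
mapped by r = e^x and the trapezoidal rule is applied on a uniform x grid,
which converges geometrically for integrands that decay exponentially (or
Gaussian-like) at both ends of the map.  Nodes and weights satisfy

    sum_k w_k f(r_k)  ~=  int_0^inf f(r) r^2 dr,      w_k = h r_k^3,

i.e. the volume factor r^2 and the Jacobian are folded into the weights.

The step size h and the inner/outer cutoffs are derived from the requested
relative accuracy and from the range of Gaussian exponents the grid must
resolve.  The step law h(eps) = 2.2 / (-ln eps)^0.85 was calibrated once
against the analytic integrals of r^2 exp(-z r^2) over z in [1e-2, 1e4]
and holds a safety margin of roughly an order of magnitude.
"""

from __future__ import annotations

import math

import numpy as np

from .constants import SYMBOL_TO_Z

#: Default ranges of Gaussian exponents the per-element grids resolve when
#: no basis set is supplied.  Generous on the steep side: the cost of the
#: exponential grid is logarithmic in the exponent range.
DEFAULT_ZETA_MIN = 0.05


def _default_zeta_max(z: int) -> float:
    return max(100.0, 100.0 * z**2.5)


def _step(accuracy: float) -> float:
    return 2.2 / (-math.log(accuracy)) ** 0.85


def radial_grid_from_exponents(
    zeta_min: float, zeta_max: float, accuracy: float = 1e-10
):
    """Radial nodes/weights resolving Gaussians with exponents in a range.

    Parameters
    ----------
    zeta_min, zeta_max:
        Smallest/largest Gaussian exponent that must be integrated to the
        requested relative accuracy.
    accuracy:
        Target relative quadrature error; must lie in (1e-14, 1e-2].
    """
    if not (1e-14 < accuracy <= 1e-2):
        raise ValueError("accuracy must lie in (1e-14, 1e-2]")
    if not (0 < zeta_min <= zeta_max):
        raise ValueError("need 0 < zeta_min <= zeta_max")
    h = _step(accuracy)
    # Inner truncation: int_0^rmin r^2 dr relative to (2 zeta)^-3/2 scale.
    r_min = 0.5 * accuracy ** (1.0 / 3.0) / math.sqrt(zeta_max)
    # Outer truncation: Gaussian tail of the most diffuse exponent.
    r_max = 1.1 * math.sqrt(-math.log(accuracy * 1e-2) / zeta_min)
    n = int(math.ceil(math.log(r_max / r_min) / h)) + 1
    x = math.log(r_min) + h * np.arange(n)
    r = np.exp(x)
    w = h * r**3
    return r, w


def radial_grid(element: str, accuracy: float = 1e-10):
    """Per-element radial grid using default exponent ranges.

    Nodes are strictly increasing and weights positive; the node count
    grows as the accuracy parameter tightens.
    """
    z = SYMBOL_TO_Z.get(element)
    if z is None:
        raise ValueError(f"unsupported element {element!r}")
    return radial_grid_from_exponents(
        DEFAULT_ZETA_MIN, _default_zeta_max(z), accuracy
    )
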