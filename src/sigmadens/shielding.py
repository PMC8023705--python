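"""Biot-Savart shielding densities, their integrals, and atomic decomposition.

The nuclear magnetic shielding tensor of nucleus I is the volume integral
of the shielding density

    sigma_ab(r) = alpha^2 [ (c dJ/dB_b)(r) x (r - R_I) ]_a / |r - R_I|^3 ,

where the bracketed field is the c-scaled current-density susceptibility
delivered by any provider (Eq-8 evaluation of a response bundle, or an
analytic model).  Positive values shield the nucleus (a diatropic ring
current enclosing the nucleus gives a positive zz density everywhere on
the ring), negative values deshield it.  Shieldings are reported in ppm
(dimensionless value x 1e6).

Integration runs over Becke-weighted atomic grids; because the fuzzy-cell
weights form a partition of unity, the per-atom partial sums add up to the
global integral exactly (same points, same weights), which is the basis of
the atomic decomposition tables.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .cdt import provider_tensor
from .constants import ALPHA, PPM

#: Points closer to the nucleus than this are excluded from the integrand.
EXCLUSION_RADIUS = 1e-10

_COMPONENTS = {
    a + b: (i, j)
    for i, a in enumerate("xyz")
    for j, b in enumerate("xyz")
}


def parse_component(component):
    """Normalize a tensor-component selector.

    Accepts ``"xx" ... "zz"``, an (a, b) index pair, or ``"isotropic"``.
    Returns an (a, b) tuple or the string ``"isotropic"``.
    """
    if component == "isotropic":
        return "isotropic"
    if isinstance(component, str):
        try:
            return _COMPONENTS[component.lower()]
        except KeyError:
            raise ValueError(
                f"unknown component {component!r}; use xx..zz or isotropic"
            )
    a, b = component
    if not (0 <= a < 3 and 0 <= b < 3):
        raise ValueError(f"component indices out of range: {component}")
    return (int(a), int(b))


def resolve_nucleus(nucleus, molecule=None, provider=None):
    """A nucleus may be an atom index (needs a molecule) or a 3-vector."""
    if np.isscalar(nucleus) and not isinstance(nucleus, (list, tuple)):
        idx = int(nucleus)
        mol = molecule or getattr(provider, "molecule", None)
        if mol is None:
            raise ValueError(
                "nucleus given as atom index but no molecule is available"
            )
        if not (0 <= idx < mol.n_atoms):
            raise IndexError(
                f"nucleus index {idx} out of range for {mol.n_atoms} atoms"
            )
        return mol.coords[idx]
    return np.asarray(nucleus, dtype=float).reshape(3)


def biot_savart_kernel(points, nucleus_position, exclusion=EXCLUSION_RADIUS):
    """Linear map from J(r) to the shielding-density tensor rows.

    Returns K with shape (n, 3, 3) such that
    ``sigma_ab(r_i) = sum_g K[i, a, g] J_g(r_i)`` for the current field of
    unit external field along b.  K[i] = alpha^2 eps_{a g d} d_d / |d|^3
    with d = r_i - R_I; points inside the exclusion radius get K = 0.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = points - np.asarray(nucleus_position, dtype=float)[None, :]
    r = np.linalg.norm(d, axis=1)
    mask = r > exclusion
    inv3 = np.zeros_like(r)
    inv3[mask] = 1.0 / r[mask] ** 3
    # [J x d]_a = eps_agd J_g d_d  ->  K[a, g] = alpha^2 eps_agd d_d / r^3
    K = np.zeros((points.shape[0], 3, 3))
    f = ALPHA**2 * inv3
    K[:, 0, 1] = d[:, 2] * f
    K[:, 0, 2] = -d[:, 1] * f
    K[:, 1, 0] = -d[:, 2] * f
    K[:, 1, 2] = d[:, 0] * f
    K[:, 2, 0] = d[:, 1] * f
    K[:, 2, 1] = -d[:, 0] * f
    return K


@dataclass
class ShieldingDensityField:
    """Per-point shielding-density values for one nucleus and component."""

    nucleus_position: np.ndarray
    component: object            # (a, b) or "isotropic"
    points: np.ndarray           # (n, 3)
    values: np.ndarray           # (n,), atomic units

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("shielding-density values must be finite")

    @property
    def ppm_per_bohr3(self) -> np.ndarray:
        return self.values * PPM


def shielding_density(provider, nucleus, component, points,
                      molecule=None) -> ShieldingDensityField:
    """Evaluate the shielding-density integrand at arbitrary points."""
    comp = parse_component(component)
    pos = resolve_nucleus(nucleus, molecule, provider)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    K = biot_savart_kernel(points, pos)
    if comp == "isotropic":
        T = provider_tensor(provider, points)        # (n, 3, 3): T[g, b]
        # 1/3 sum_a sigma_aa, sigma_aa = sum_g K[a, g] T[g, a]
        vals = np.einsum("nag,nga->n", K, T) / 3.0
    else:
        a, b = comp
        J = np.asarray(provider(points, b))
        vals = np.einsum("ng,ng->n", K[:, a, :], J)
    return ShieldingDensityField(pos, comp, points, vals)


def integrate_component(provider, nucleus, component, grids, molecule=None):
    """Integrate the shielding density over the union of atomic grids.

    Returns ``(total, positive, negative)`` in ppm with
    total = positive + negative; the split is taken pointwise on the
    quadrature contributions w_i * value_i.
    """
    comp = parse_component(component)
    pos_nuc = resolve_nucleus(nucleus, molecule, provider)
    tot = pos = neg = 0.0
    for g in grids:
        f = shielding_density(provider, pos_nuc, comp, g.points)
        contrib = g.weights * f.values
        pos += contrib[contrib > 0].sum()
        neg += contrib[contrib < 0].sum()
        tot += contrib.sum()
    return tot * PPM, pos * PPM, neg * PPM


def isotropic(sigma_xx, sigma_yy, sigma_zz):
    """Isotropic shielding constant: the mean of the diagonal components."""
    return (sigma_xx + sigma_yy + sigma_zz) / 3.0


@dataclass
class DecompositionRow:
    label: str
    total: float
    positive: float
    negative: float
    percentage: float


@dataclass
class DecompositionTable:
    """Per-domain shielding contributions (ppm) and their percentages."""

    nucleus_label: str
    component: object
    rows: list = field(default_factory=list)
    grand_total: float = 0.0
    grand_positive: float = 0.0
    grand_negative: float = 0.0
    percentages_defined: bool = True

    def to_text(self) -> str:
        buf = io.StringIO()
        comp = (
            self.component
            if isinstance(self.component, str)
            else "".join("xyz"[i] for i in self.component)
        )
        buf.write(
            f"Shielding decomposition for {self.nucleus_label} "
            f"({comp} component, ppm)\n"
        )
        buf.write(
            f"{'domain':<12s} {'total':>10s} {'positive':>10s} "
            f"{'negative':>10s} {'percentage':>11s}\n"
        )
        for r in self.rows:
            buf.write(
                f"{r.label:<12s} {r.total:>10.2f} {r.positive:>10.2f} "
                f"{r.negative:>10.2f} {r.percentage:>10.2f}%\n"
            )
        buf.write(
            f"{'total':<12s} {self.grand_total:>10.2f} "
            f"{self.grand_positive:>10.2f} {self.grand_negative:>10.2f} "
            f"{100.0 if self.percentages_defined else 0.0:>10.2f}%\n"
        )
        if not self.percentages_defined:
            buf.write("(percentages undefined: zero grand total)\n")
        return buf.getvalue()

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("domain,total_ppm,positive_ppm,negative_ppm,percentage\n")
            for r in self.rows:
                fh.write(
                    f"{r.label},{r.total:.10g},{r.positive:.10g},"
                    f"{r.negative:.10g},{r.percentage:.10g}\n"
                )
            fh.write(
                f"total,{self.grand_total:.10g},{self.grand_positive:.10g},"
                f"{self.grand_negative:.10g},"
                f"{100.0 if self.percentages_defined else 0.0:.10g}\n"
            )


def decompose_atomic(provider, nucleus, grids, labeling=None,
                     component="isotropic", molecule=None) -> DecompositionTable:
    """Integrate the shielding density per Becke atomic domain.

    Parameters
    ----------
    labeling:
        Optional {atom_index: label} map; atoms sharing a label (e.g. the
        symmetry-equivalent *ortho* positions) are merged into one row.
        Defaults to one row per atom labelled ``<symbol><index+1>``.
    """
    comp = parse_component(component)
    mol = molecule or getattr(provider, "molecule", None)
    pos_nuc = resolve_nucleus(nucleus, mol, provider)
    if labeling is not None:
        n_atoms = mol.n_atoms if mol is not None else (
            max(g.atom_index for g in grids) + 1
        )
        bad = [i for i in labeling if not (0 <= int(i) < n_atoms)]
        if bad:
            raise IndexError(f"labeling refers to absent atoms {bad}")

    per_label: dict[str, list[float]] = {}
    order: list[str] = []
    g_tot = g_pos = g_neg = 0.0
    for g in grids:
        f = shielding_density(provider, pos_nuc, comp, g.points)
        contrib = g.weights * f.values
        t = contrib.sum() * PPM
        p = contrib[contrib > 0].sum() * PPM
        n = contrib[contrib < 0].sum() * PPM
        if labeling is not None and g.atom_index in labeling:
            label = str(labeling[g.atom_index])
        elif mol is not None:
            label = f"{mol.symbols[g.atom_index]}{g.atom_index + 1}"
        else:
            label = f"atom{g.atom_index + 1}"
        if label not in per_label:
            per_label[label] = [0.0, 0.0, 0.0]
            order.append(label)
        per_label[label][0] += t
        per_label[label][1] += p
        per_label[label][2] += n
        g_tot += t
        g_pos += p
        g_neg += n

    defined = abs(g_tot) > 0.0
    rows = []
    for label in order:
        t, p, n = per_label[label]
        pct = (t / g_tot * 100.0) if defined else 0.0
        rows.append(DecompositionRow(label, t, p, n, pct))
    if isinstance(nucleus, (int, np.integer)) and mol is not None:
        nuc_label = f"{mol.symbols[int(nucleus)]}{int(nucleus) + 1}"
    else:
        nuc_label = "nucleus"
    return DecompositionTable(
        nucleus_label=nuc_label,
        component=comp,
        rows=rows,
        grand_total=g_tot,
        grand_positive=g_pos,
        grand_negative=g_neg,
        percentages_defined=defined,
    )
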