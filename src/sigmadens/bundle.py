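"""Response bundles: the interchange format between a quantum-chemistry
engine and the shielding-density toolkit.

A bundle holds everything the current-density susceptibility evaluation
needs: the geometry, the Gaussian basis, the AO overlap matrix, the
unperturbed one-electron density matrix D, and the three magnetically
perturbed density matrices dD/dB_beta.

Adapter contract
----------------
Any engine adapter must deliver matrices in the canonical convention:

* AO ordering: shells in input order; within a shell the real solid
  harmonics m = -l..l without Condon-Shortley phase (see ``basis``).
* D is the real symmetric AO density with tr(D S) = n_electrons.
* dD/dB_beta is the *real antisymmetric* matrix R such that the complex
  first-order density is ``D + i sum_beta B_beta R_beta`` for an external
  field B (in atomic units) along +x, +y, +z.  Engines that differentiate
  with respect to -B, use the Condon-Shortley phase, or order harmonics
  differently must flip signs / permute before building the bundle.
* Perturbed densities are those of a GIAO (London-orbital) calculation;
  gauge-origin information must not be needed to interpret them.

The container file is HDF5 with the dataset names written by
:func:`write_bundle`; a plain-JSON twin format with identical field names
is supported for small text fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .basis import GaussianShell, n_ao
from .constants import SPEED_OF_LIGHT
from .molecule import Molecule

SCHEMA_VERSION = "sigmadens-bundle-1"

SYMMETRY_TOL = 1e-10
ANTISYMMETRY_TOL = 1e-8
TRACE_TOL = 1e-8


class BundleValidationError(ValueError):
    """A bundle invariant failed; the message lists the failed check."""


@dataclass
class ResponseBundle:
    """Inputs of the CDT evaluation for one molecule/basis/method."""

    molecule: Molecule
    shells: list[GaussianShell]
    overlap: np.ndarray            # (nao, nao)
    density: np.ndarray            # (nao, nao), symmetric
    perturbed_density: np.ndarray  # (3, nao, nao), antisymmetric slices
    n_electrons: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.overlap = np.asarray(self.overlap, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        self.perturbed_density = np.asarray(self.perturbed_density, dtype=float)
        self.validate()

    @property
    def nao(self) -> int:
        return n_ao(self.shells)

    def validate(self) -> None:
        nao = self.nao
        for name, mat, shape in (
            ("overlap", self.overlap, (nao, nao)),
            ("density", self.density, (nao, nao)),
            ("perturbed_density", self.perturbed_density, (3, nao, nao)),
        ):
            if mat.shape != shape:
                raise BundleValidationError(
                    f"{name} has shape {mat.shape}, expected {shape} "
                    f"from the shell list"
                )
        sym_defect = np.abs(self.density - self.density.T).max()
        if sym_defect > SYMMETRY_TOL:
            raise BundleValidationError(
                f"density not symmetric (defect {sym_defect:.3e} > "
                f"{SYMMETRY_TOL:.0e})"
            )
        for beta, name in enumerate("xyz"):
            m = self.perturbed_density[beta]
            defect = np.abs(m + m.T).max()
            if defect > ANTISYMMETRY_TOL:
                raise BundleValidationError(
                    f"perturbed density d/dB_{name} not antisymmetric "
                    f"(defect {defect:.3e} > {ANTISYMMETRY_TOL:.0e})"
                )
        tr = float(np.trace(self.density @ self.overlap))
        if abs(tr - self.n_electrons) > TRACE_TOL:
            raise BundleValidationError(
                f"tr(D S) = {tr:.10f} does not match n_electrons = "
                f"{self.n_electrons} (tolerance {TRACE_TOL:.0e})"
            )
        for sh in self.shells:
            if not (0 <= sh.center < self.molecule.n_atoms):
                raise BundleValidationError(
                    f"shell centered on missing atom index {sh.center}"
                )

    def translated(self, shift) -> "ResponseBundle":
        """Rigidly translate the whole system by ``shift`` (bohr).

        London-orbital response matrices are not invariant under
        translation: the magnetic-translation phase of the GIAOs adds
        ``(e_beta x (R_mu - R_nu)) . t / (2c) * D_munu`` to dD/dB_beta.
        With this law the current-density susceptibility field is exactly
        the translate of the original.
        """
        shift = np.asarray(shift, dtype=float)
        mol = self.molecule.translated(shift)
        centers = np.array(
            [c for sh in self.shells for c in [sh.center] * sh.n_functions]
        )
        r_ao = self.molecule.coords[centers]          # (nao, 3)
        dperts = self.perturbed_density.copy()
        ex = np.eye(3)
        for beta in range(3):
            # (e_beta x (R_mu - R_nu)) . t  =  (e_beta x R_mu).t - (e_beta x R_nu).t
            f = (np.cross(ex[beta], r_ao) @ shift)    # (nao,)
            dperts[beta] += (
                (f[:, None] - f[None, :]) * self.density / (2.0 * SPEED_OF_LIGHT)
            )
        return ResponseBundle(
            molecule=mol,
            shells=[replace(sh) for sh in self.shells],
            overlap=self.overlap.copy(),
            density=self.density.copy(),
            perturbed_density=dperts,
            n_electrons=self.n_electrons,
            metadata=dict(self.metadata),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ResponseBundle):
            return NotImplemented
        return (
            self.molecule == other.molecule
            and len(self.shells) == len(other.shells)
            and all(
                a.center == b.center
                and a.l == b.l
                and a.pure == b.pure
                and a.primitives == b.primitives
                for a, b in zip(self.shells, other.shells)
            )
            and np.array_equal(self.overlap, other.overlap)
            and np.array_equal(self.density, other.density)
            and np.array_equal(self.perturbed_density, other.perturbed_density)
            and self.n_electrons == other.n_electrons
        )


def _shell_arrays(shells):
    centers = np.array([sh.center for sh in shells], dtype=int)
    ls = np.array([sh.l for sh in shells], dtype=int)
    pure = np.array([sh.pure for sh in shells], dtype=bool)
    nprim = np.array([len(sh.primitives) for sh in shells], dtype=int)
    exps = np.concatenate([sh.exponents for sh in shells])
    coefs = np.concatenate([sh.coefficients for sh in shells])
    return centers, ls, pure, nprim, exps, coefs


def _shells_from_arrays(centers, ls, pure, nprim, exps, coefs):
    shells, ofs = [], 0
    for c, l, p, n in zip(centers, ls, pure, nprim):
        prims = [
            (float(exps[ofs + i]), float(coefs[ofs + i])) for i in range(n)
        ]
        shells.append(GaussianShell(int(c), int(l), prims, bool(p)))
        ofs += n
    return shells


def write_bundle(bundle: ResponseBundle, path) -> None:
    """Write a bundle container (HDF5 for .h5/.hdf5, JSON otherwise)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_hdf5(bundle, path)
    else:
        _write_json(bundle, path)


def read_bundle(path) -> ResponseBundle:
    """Read and validate a bundle container written by :func:`write_bundle`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_hdf5(path)
    return _read_json(path)


_DATASETS = (
    "molecule/symbols", "molecule/coords",
    "shells/center", "shells/l", "shells/pure", "shells/nprim",
    "shells/exponents", "shells/coefficients",
    "matrices/overlap", "matrices/density", "matrices/perturbed_density",
)


def _write_hdf5(bundle, path):
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["n_electrons"] = bundle.n_electrons
        for k, v in bundle.metadata.items():
            f.attrs[f"meta:{k}"] = v
        f.create_dataset(
            "molecule/symbols",
            data=np.array(bundle.molecule.symbols, dtype="S4"),
        )
        f["molecule/coords"] = bundle.molecule.coords
        centers, ls, pure, nprim, exps, coefs = _shell_arrays(bundle.shells)
        f["shells/center"] = centers
        f["shells/l"] = ls
        f["shells/pure"] = pure
        f["shells/nprim"] = nprim
        f["shells/exponents"] = exps
        f["shells/coefficients"] = coefs
        f["matrices/overlap"] = bundle.overlap
        f["matrices/density"] = bundle.density
        f["matrices/perturbed_density"] = bundle.perturbed_density


def _read_hdf5(path):
    import h5py

    with h5py.File(path, "r") as f:
        for name in _DATASETS:
            if name not in f:
                raise BundleValidationError(
                    f"{path}: missing dataset {name!r}"
                )
        symbols = [s.decode() for s in f["molecule/symbols"][...]]
        mol = Molecule.from_arrays(symbols, f["molecule/coords"][...])
        shells = _shells_from_arrays(
            f["shells/center"][...], f["shells/l"][...],
            f["shells/pure"][...], f["shells/nprim"][...],
            f["shells/exponents"][...], f["shells/coefficients"][...],
        )
        metadata = {
            k[5:]: v for k, v in f.attrs.items() if k.startswith("meta:")
        }
        return ResponseBundle(
            molecule=mol,
            shells=shells,
            overlap=f["matrices/overlap"][...],
            density=f["matrices/density"][...],
            perturbed_density=f["matrices/perturbed_density"][...],
            n_electrons=float(f.attrs["n_electrons"]),
            metadata=metadata,
        )


def _write_json(bundle, path):
    centers, ls, pure, nprim, exps, coefs = _shell_arrays(bundle.shells)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "n_electrons": bundle.n_electrons,
        "metadata": bundle.metadata,
        "molecule": {
            "symbols": bundle.molecule.symbols,
            "coords": bundle.molecule.coords.tolist(),
        },
        "shells": {
            "center": centers.tolist(),
            "l": ls.tolist(),
            "pure": pure.tolist(),
            "nprim": nprim.tolist(),
            "exponents": exps.tolist(),
            "coefficients": coefs.tolist(),
        },
        "matrices": {
            "overlap": bundle.overlap.tolist(),
            "density": bundle.density.tolist(),
            "perturbed_density": bundle.perturbed_density.tolist(),
        },
    }
    Path(path).write_text(json.dumps(doc))


def _read_json(path):
    doc = json.loads(Path(path).read_text())
    for top, sub in (
        ("molecule", ("symbols", "coords")),
        ("shells", ("center", "l", "pure", "nprim", "exponents", "coefficients")),
        ("matrices", ("overlap", "density", "perturbed_density")),
    ):
        if top not in doc:
            raise BundleValidationError(f"{path}: missing dataset {top!r}")
        for name in sub:
            if name not in doc[top]:
                raise BundleValidationError(
                    f"{path}: missing dataset {top}/{name!r}"
                )
    mol = Molecule.from_arrays(
        doc["molecule"]["symbols"], np.array(doc["molecule"]["coords"])
    )
    sh = doc["shells"]
    shells = _shells_from_arrays(
        sh["center"], sh["l"], sh["pure"], sh["nprim"],
        sh["exponents"], sh["coefficients"],
    )
    return ResponseBundle(
        molecule=mol,
        shells=shells,
        overlap=np.array(doc["matrices"]["overlap"]),
        density=np.array(doc["matrices"]["density"]),
        perturbed_density=np.array(doc["matrices"]["perturbed_density"]),
        n_electrons=float(doc["n_electrons"]),
        metadata=doc.get("metadata", {}),
    )


class EngineAdapterError(RuntimeError):
    pass


def adapt_engine(payload: dict) -> ResponseBundle:
    """Build a canonical bundle from a generic engine output payload.

    ``payload`` is a dictionary an engine-specific extractor assembles:

    ====================  ==================================================
    key                   meaning
    ====================  ==================================================
    symbols, coords       geometry (coords in bohr)
    shells                list of (center, l, [(exp, coef), ...], pure)
    overlap               AO overlap in the engine's AO ordering
    density               AO density in the engine's AO ordering
    perturbed_density     (3, nao, nao) real antisymmetric dD/dB
    n_electrons           electron count
    ao_permutation        optional engine-AO -> canonical-AO permutation
    field_sign            +1 if the engine differentiates wrt +B (default),
                          -1 to flip the perturbed densities
    isotropic_shielding_ppm   optional {atom_index: ppm} analytic GIAO
                          values, stored in metadata for later comparison
    ====================  ==================================================
    """
    missing = [
        k
        for k in ("symbols", "coords", "shells", "overlap", "density",
                  "n_electrons")
        if k not in payload
    ]
    if missing:
        raise EngineAdapterError(f"engine payload missing {missing}")
    if "perturbed_density" not in payload:
        raise EngineAdapterError("perturbed densities unavailable")
    mol = Molecule.from_arrays(payload["symbols"], payload["coords"])
    shells = [GaussianShell(*args) for args in payload["shells"]]
    S = np.asarray(payload["overlap"], dtype=float)
    D = np.asarray(payload["density"], dtype=float)
    Db = np.asarray(payload["perturbed_density"], dtype=float)
    perm = payload.get("ao_permutation")
    if perm is not None:
        perm = np.asarray(perm, dtype=int)
        if sorted(perm.tolist()) != list(range(S.shape[0])):
            raise EngineAdapterError("ao_permutation is not a permutation")
        S = S[np.ix_(perm, perm)]
        D = D[np.ix_(perm, perm)]
        Db = Db[:, perm][:, :, perm]
    sign = payload.get("field_sign", +1)
    if sign not in (+1, -1):
        raise EngineAdapterError(f"unsupported field_sign convention {sign!r}")
    metadata = {"method": payload.get("method", "unknown")}
    iso = payload.get("isotropic_shielding_ppm")
    if iso is not None:
        metadata["isotropic_shielding_ppm"] = json.dumps(
            {str(k): float(v) for k, v in iso.items()}
        )
    return ResponseBundle(
        molecule=mol,
        shells=shells,
        overlap=S,
        density=D,
        perturbed_density=sign * Db,
        n_electrons=float(payload["n_electrons"]),
        metadata=metadata,
    )
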