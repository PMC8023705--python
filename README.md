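# sigmadens

Nuclear magnetic shielding **densities** from magnetically induced current
densities.

An NMR shielding constant is usually delivered as a single number per
nucleus.  `sigmadens` unpacks that number into space: it evaluates the
current-density susceptibility tensor (CDT) of a molecule, forms the
Biot–Savart integrand whose volume integral is the shielding tensor, and
then shows *where* the shielding comes from — as plane maps and volumetric
fields of shielding/deshielding regions, and as per-atom contributions
obtained by integrating over Becke fuzzy atomic cells.  It is aimed at
quantum chemists studying ring currents, aromaticity and the spatial
origin of NMR chemical shifts.

## The model

For an external field **B**, gauge-including atomic orbitals (GIAOs,
London orbitals)

$$\chi_\mu(\mathbf r) = e^{-\tfrac{i}{2c}\,[\mathbf B\times(\mathbf R_\mu-\mathbf R_O)]\cdot\mathbf r}\,\phi_\mu(\mathbf r)$$

make the induced current density gauge-origin independent.  Expanding
$\mathbf J = -\mathrm{Re}\sum_{\mu\nu}\tilde D_{\mu\nu}\,
\chi_\nu^*(\mathbf p + \mathbf A/c)\chi_\mu$ to first order in **B** gives
the CDT from the AO density matrix **D** and the magnetically perturbed
density matrices $\partial\mathbf D/\partial B_\beta$ (all $\mathbf R_O$
terms cancel analytically):

$$\mathcal T_{\alpha\beta}(\mathbf r) =
-\,c\sum_{\mu\nu}\frac{\partial D_{\mu\nu}}{\partial B_\beta}\,\phi_\nu\partial_\alpha\phi_\mu
+\tfrac12\sum_{\mu\nu}D_{\mu\nu}\,[(\mathbf e_\beta\times\mathbf R_{\mu\nu})\cdot\mathbf r]\,\phi_\nu\partial_\alpha\phi_\mu
-\tfrac12\sum_{\mu\nu}D_{\mu\nu}\,\phi_\mu\phi_\nu\,[\mathbf e_\beta\times(\mathbf r-\mathbf R_\mu)]_\alpha .$$

The shielding tensor of nucleus *I* is the Biot–Savart volume integral

$$\sigma^I_{\alpha\beta} = \alpha^2 \int
\frac{[\,\mathcal T_{\cdot\beta}(\mathbf r)\times(\mathbf r-\mathbf R_I)\,]_\alpha}
{|\mathbf r-\mathbf R_I|^3}\, d^3r ,$$

whose integrand — the *shielding density* — is positive where the local
current flux shields the nucleus and negative where it deshields it.
Integration uses Becke multicenter partitioning (iteration order k = 3)
with exponential (Lindh-style) radial grids and Lebedev / Gauss–Legendre
product angular grids; summing the per-cell integrals decomposes
$\sigma_{\rm iso}$ into atomic contributions exactly.

Analytic current models (Gaussian-profile ring currents, atomic Larmor
vortices) are first-class providers with closed-form Biot–Savart answers,
so the entire pipeline is verifiable without a quantum-chemistry engine;
ab initio response matrices enter through a documented adapter contract
(`sigmadens.bundle`).

## Worked example

Integrating the shielding density of a single-Gaussian atomic vortex must
reproduce the Lamb formula $\sigma = \tfrac{\alpha^2}{3}\langle 1/r\rangle$
— an exact end-to-end check of kernel, grids and units:

```sh
$ python examples/lamb_oracle.py
quadrature isotropic shielding : 28.325622 ppm
Lamb closed form               : 28.325622 ppm
absolute error                 : 2.61e-08 ppm
positive / negative split      : 28.325622 / 0.000000 ppm
```

The 28.33 ppm is the diamagnetic shielding of one electron in a unit-
exponent Gaussian 1s density; the quadrature reproduces the closed form
to 3·10⁻⁸ ppm, and the purely diamagnetic vortex has no deshielding part.

A Becke decomposition of a model aromatic ring
(`examples/atomic_decomposition.py`) prints the familiar table layout:

```
domain            total   positive   negative  percentage
ipso C            -4.51       1.84      -6.35     -15.47%
...
ipso H            28.83      29.83      -1.00      98.87%
...
total             29.16      37.87      -8.71     100.00%
```

The studied proton's own domain dominates, the ring-current flux passing
inside the proton shows up as deshielding assigned to the adjacent
carbon, and each row satisfies total = positive + negative exactly.

Other examples: `ring_current_loop.py` (closed-form Biot–Savart checks),
`plane_map.py` (σ_zz maps in and 1 a₀ above the molecular plane),
`cube_export.py` (|density| volumes for isosurface viewing),
`bundle_workflow.py` (response-bundle container round trip).  The same
capabilities are scriptable via the `sigmadens` CLI
(`validate`, `bundle`, `atoms`, `plane`, `cube`).

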