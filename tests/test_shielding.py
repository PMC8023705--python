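import numpy as np
import pytest

from sigmadens import (
    Molecule,
    biot_savart_kernel,
    build_grids,
    decompose_atomic,
    integrate_component,
    isotropic,
    shielding_density,
)
from sigmadens.models import (
    LoopModel,
    VortexModel,
    loop_center_shielding,
    loop_center_shielding_profile,
    make_loop_provider,
    make_vortex_provider,
    scaled_provider,
)
from sigmadens.constants import ALPHA, PPM


def ring_molecule(radius, n=6, symbol="He"):
    ang = 2 * np.pi * np.arange(n) / n
    return Molecule.from_arrays(
        [symbol] * n,
        np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)], 1),
    )


class TestKernel:
    def test_cross_product_structure(self):
        # separation along +z, J along +x: only the y-row couples
        K = biot_savart_kernel([[0.0, 0.0, 2.0]], [0.0, 0.0, 0.0])[0]
        J = np.array([1.0, 0.0, 0.0])
        sigma_rows = K @ J
        assert sigma_rows[1] != 0.0
        assert sigma_rows[0] == 0.0 and sigma_rows[2] == 0.0

    def test_inverse_square_scaling(self):
        K1 = biot_savart_kernel([[0, 0, 1.0]], [0, 0, 0])
        K2 = biot_savart_kernel([[0, 0, 2.0]], [0, 0, 0])
        assert np.abs(K1).max() == pytest.approx(4 * np.abs(K2).max())

    def test_exclusion_radius_returns_zero(self):
        K = biot_savart_kernel([[0.0, 0.0, 1e-12]], [0.0, 0.0, 0.0])
        np.testing.assert_array_equal(K, 0.0)

    def test_discretized_loop_center_field(self):
        # assemble B at the center of a unit thin loop from the kernel:
        # magnitude alpha^2 * 2 pi I / R (the mu0 I / 2R analog)
        R, I, n = 1.5, 2.0, 10_000
        ang = 2 * np.pi * np.arange(n) / n
        pts = np.stack([R * np.cos(ang), R * np.sin(ang), np.zeros(n)], 1)
        # diatropic sense for B || +z: current along -phi_hat
        J = I * np.stack([np.sin(ang), -np.cos(ang), np.zeros(n)], 1)
        K = biot_savart_kernel(pts, [0.0, 0.0, 0.0])
        dl = 2 * np.pi * R / n
        # sigma_zz rows integrate J to minus the induced field along z
        field = float(np.einsum("ng,ng->", K[:, 2, :], J) * dl)
        assert field == pytest.approx(
            ALPHA**2 * 2 * np.pi * I / R, rel=1e-8
        )


class TestShieldingDensity:
    def test_diatropic_ring_shields_center_everywhere_on_ring(self):
        prov = make_loop_provider(LoopModel(radius=3.0, strength=1.0, width=0.3))
        ang = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        pts = np.stack([3 * np.cos(ang), 3 * np.sin(ang), np.zeros(24)], 1)
        f = shielding_density(prov, [0.0, 0.0, 0.0], "zz", pts)
        assert np.all(f.values > 0)

    def test_nucleus_outside_ring_sees_both_signs(self):
        # near arc deshields, far arc shields (direction rule)
        prov = make_loop_provider(LoopModel(radius=3.0, strength=1.0, width=0.3))
        nucleus = [4.5, 0.0, 0.0]
        near = shielding_density(prov, nucleus, "zz", [[3.0, 0.0, 0.0]])
        far = shielding_density(prov, nucleus, "zz", [[-3.0, 0.0, 0.0]])
        assert near.values[0] < 0
        assert far.values[0] > 0

    def test_zero_provider_zero_field(self):
        class Zero:
            def __call__(self, pts, beta):
                return np.zeros((len(np.atleast_2d(pts)), 3))

        f = shielding_density(Zero(), [0, 0, 0], "zz", [[1.0, 0, 0]])
        np.testing.assert_array_equal(f.values, 0.0)

    def test_unknown_component_rejected(self):
        prov = make_vortex_provider(VortexModel())
        with pytest.raises(ValueError, match="component"):
            shielding_density(prov, [0, 0, 0], "zx_", [[1.0, 0, 0]])


class TestIntegration:
    def test_lamb_formula_end_to_end(self):
        # single-Gaussian Larmor vortex: sigma_iso = alpha^2/3 <1/r>
        vm = VortexModel(zeta=1.0, n_electrons=1.0)
        prov = make_vortex_provider(vm)
        mol = Molecule.from_arrays(["H"], [[0.0, 0.0, 0.0]])
        grids = build_grids(mol, radial_accuracy=1e-10, angular_order=17)
        tot, pos, neg = integrate_component(prov, [0, 0, 0], "isotropic", grids)
        assert tot == pytest.approx(vm.lamb_shielding(), abs=0.01)
        assert tot == pytest.approx(pos + neg, abs=1e-10)
        assert neg == pytest.approx(0.0, abs=1e-6)

    def test_loop_profile_matches_analytic_superposition(self):
        lm = LoopModel(radius=3.0, strength=2.0, width=0.3)
        prov = make_loop_provider(lm)
        grids = build_grids(
            ring_molecule(3.0), radial_accuracy=1e-10, angular_order=29
        )
        tot, _, _ = integrate_component(prov, [0, 0, 0], "zz", grids)
        oracle = loop_center_shielding_profile(lm)
        assert tot == pytest.approx(oracle, rel=1e-6)
        # and the thin-loop closed form is the width->0 limit, close here
        assert tot == pytest.approx(loop_center_shielding(lm), rel=2e-2)

    def test_reversing_circulation_flips_everything(self):
        dia = make_loop_provider(LoopModel(radius=2.0, strength=1.0, width=0.4))
        para = make_loop_provider(
            LoopModel(radius=2.0, strength=1.0, width=0.4,
                      tropicity="paratropic")
        )
        grids = build_grids(ring_molecule(2.0, n=4), radial_accuracy=1e-6,
                            angular_order=17)
        td, pd_, nd = integrate_component(dia, [0, 0, 0], "zz", grids)
        tp, pp, np_ = integrate_component(para, [0, 0, 0], "zz", grids)
        assert tp == pytest.approx(-td, rel=1e-12)
        assert pp == pytest.approx(-nd, rel=1e-12)
        assert np_ == pytest.approx(-pd_, rel=1e-12)

    def test_linearity_in_circulation(self):
        base = make_loop_provider(LoopModel(radius=2.0, strength=1.0, width=0.4))
        grids = build_grids(ring_molecule(2.0, n=4), radial_accuracy=1e-6,
                            angular_order=17)
        t1, _, _ = integrate_component(base, [0, 0, 0], "zz", grids)
        t3, _, _ = integrate_component(
            scaled_provider(base, 3.0), [0, 0, 0], "zz", grids
        )
        assert t3 == pytest.approx(3.0 * t1, rel=1e-12)

    def test_isotropic_is_mean_of_diagonal(self):
        assert isotropic(3.0, 3.0, 3.0) == 3.0
        assert isotropic(1.0, 2.0, 3.0) == 2.0

    def test_quadrature_isotropic_equals_component_mean(self):
        prov = make_vortex_provider(VortexModel(zeta=0.8, center=[0.5, 0, 0]))
        mol = Molecule.from_arrays(["He"], [[0.5, 0.0, 0.0]])
        grids = build_grids(mol, radial_accuracy=1e-8, angular_order=17)
        nucleus = [0.0, 0.0, 0.0]
        comps = [
            integrate_component(prov, nucleus, c, grids)[0]
            for c in ("xx", "yy", "zz")
        ]
        iso, _, _ = integrate_component(prov, nucleus, "isotropic", grids)
        assert iso == pytest.approx(isotropic(*comps), abs=1e-10)

    def test_translation_invariance_of_integral(self, larmor_bundle):
        from sigmadens.cdt import bundle_provider

        t = np.array([1.5, -0.7, 2.0])
        bt = larmor_bundle.translated(t)
        g0 = build_grids(larmor_bundle.molecule, radial_accuracy=1e-8,
                         angular_order=17, shells=larmor_bundle.shells)
        g1 = build_grids(bt.molecule, radial_accuracy=1e-8,
                         angular_order=17, shells=bt.shells)
        nuc0 = larmor_bundle.molecule.coords[0] + [0.3, 0.0, 0.0]
        s0 = integrate_component(bundle_provider(larmor_bundle), nuc0,
                                 "isotropic", g0)[0]
        s1 = integrate_component(bundle_provider(bt), nuc0 + t,
                                 "isotropic", g1)[0]
        assert s1 == pytest.approx(s0, abs=1e-8)


class TestDecomposition:
    def test_rows_sum_to_global_integral_exactly(self):
        prov = make_loop_provider(LoopModel(radius=2.5, strength=1.5, width=0.5))
        mol = ring_molecule(2.5, n=4)
        grids = build_grids(mol, radial_accuracy=1e-8, angular_order=17)
        table = decompose_atomic(prov, [0.0, 0.0, 0.0], grids, molecule=mol,
                                 component="zz")
        tot, pos, neg = integrate_component(prov, [0.0, 0.0, 0.0], "zz", grids)
        assert sum(r.total for r in table.rows) == pytest.approx(
            table.grand_total, abs=1e-12
        )
        assert table.grand_total == pytest.approx(tot, abs=1e-12)
        for r in table.rows:
            assert r.total == pytest.approx(r.positive + r.negative, abs=1e-8)
        assert sum(r.percentage for r in table.rows) == pytest.approx(
            100.0, abs=1e-9
        )

    def test_labeling_merges_symmetry_equivalent_rows(self):
        prov = make_vortex_provider(VortexModel(center=[0, 0, 0], zeta=1.0))
        mol = ring_molecule(2.0, n=4)
        grids = build_grids(mol, radial_accuracy=1e-6, angular_order=11)
        labeling = {0: "near", 1: "flank", 3: "flank", 2: "far"}
        table = decompose_atomic(prov, [2.0, 0.0, 0.0], grids,
                                 labeling=labeling, molecule=mol)
        assert [r.label for r in table.rows] == ["near", "flank", "far"]

    def test_labeling_with_absent_atom_rejected(self):
        prov = make_vortex_provider(VortexModel())
        mol = ring_molecule(2.0, n=4)
        grids = build_grids(mol, radial_accuracy=1e-4, angular_order=5)
        with pytest.raises(IndexError, match="absent"):
            decompose_atomic(prov, [0, 0, 0], grids, labeling={7: "x"},
                             molecule=mol)

    def test_zero_provider_percentages_flagged(self):
        class Zero:
            def __call__(self, pts, beta):
                return np.zeros((len(np.atleast_2d(pts)), 3))

        mol = ring_molecule(2.0, n=3)
        grids = build_grids(mol, radial_accuracy=1e-4, angular_order=5)
        table = decompose_atomic(Zero(), [0, 0, 0], grids, molecule=mol)
        assert not table.percentages_defined
        assert all(r.percentage == 0.0 for r in table.rows)
        assert "undefined" in table.to_text()

    def test_csv_export(self, tmp_path):
        prov = make_vortex_provider(VortexModel())
        mol = ring_molecule(1.5, n=3)
        grids = build_grids(mol, radial_accuracy=1e-4, angular_order=5)
        table = decompose_atomic(prov, [0, 0, 0], grids, molecule=mol)
        p = tmp_path / "t.csv"
        table.to_csv(p)
        lines = p.read_text().splitlines()
        assert lines[0] == "domain,total_ppm,positive_ppm,negative_ppm,percentage"
        assert len(lines) == 1 + len(table.rows) + 1
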