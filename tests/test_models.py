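import numpy as np
import pytest

from sigmadens import BundleValidationError
from sigmadens.cdt import provider_tensor
from sigmadens.constants import ALPHA, PPM
from sigmadens.models import (
    LoopModel,
    VortexModel,
    benzene_like_composite,
    loop_on_axis_field,
    make_loop_provider,
    make_min_bundle,
    make_vortex_provider,
)
from sigmadens.shielding import biot_savart_kernel, shielding_density


def kernel_field_at(provider, nucleus, points, weights):
    """sigma_zz assembled from kernel x provider over explicit points."""
    K = biot_savart_kernel(points, nucleus)
    J = provider(points, 2)
    return float(np.einsum("n,ng,ng->", weights, K[:, 2, :], J))


class TestLoopModel:
    def test_thin_loop_center_and_on_axis_fields(self):
        # discretize the thin-loop limit (width -> 0) along the centerline
        R, I, n = 2.0, 1.5, 10_000
        ang = 2 * np.pi * np.arange(n) / n
        pts = np.stack([R * np.cos(ang), R * np.sin(ang), np.zeros(n)], 1)
        # diatropic: -phi_hat circulation
        J = I * np.stack([np.sin(ang), -np.cos(ang), np.zeros(n)], 1)
        dl = np.full(n, 2 * np.pi * R / n)
        K0 = kernel_field_at(lambda p, b: J, [0.0, 0.0, 0.0], pts, dl)
        assert K0 == pytest.approx(ALPHA**2 * 2 * np.pi * I / R, rel=1e-8)
        for z in (0.5, 1.7):
            Kz = kernel_field_at(lambda p, b: J, [0.0, 0.0, z], pts, dl)
            assert Kz == pytest.approx(loop_on_axis_field(I, R, z), rel=1e-8)

    def test_tropicity_flag_negates_output(self, rng):
        kwargs = dict(radius=2.0, strength=1.3, width=0.4)
        dia = make_loop_provider(LoopModel(tropicity="diatropic", **kwargs))
        para = make_loop_provider(LoopModel(tropicity="paratropic", **kwargs))
        pts = rng.normal(scale=2.0, size=(40, 3))
        for beta in range(3):
            np.testing.assert_allclose(
                para(pts, beta), -dia(pts, beta), atol=1e-15
            )

    def test_response_projects_on_normal(self, rng):
        prov = make_loop_provider(
            LoopModel(normal=[0, 0, 1], radius=2.0, width=0.3)
        )
        pts = rng.normal(size=(10, 3))
        # field in the loop plane induces nothing in this idealization
        np.testing.assert_array_equal(prov(pts, 0), 0.0)
        np.testing.assert_array_equal(prov(pts, 1), 0.0)

    def test_tensor_consistent_with_call(self, rng):
        prov = make_loop_provider(
            LoopModel(normal=[0, 1, 1], radius=1.5, width=0.2)
        )
        pts = rng.normal(size=(15, 3))
        T = prov.tensor(pts)
        for beta in range(3):
            np.testing.assert_allclose(T[:, :, beta], prov(pts, beta))

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            LoopModel(radius=-1.0)
        with pytest.raises(ValueError):
            LoopModel(tropicity="sideways")


class TestVortexModel:
    def test_lamb_closed_form_value(self):
        vm = VortexModel(zeta=2.5, n_electrons=2.0)
        expected = ALPHA**2 / 3.0 * 2.0 * 2.0 * np.sqrt(2 * 2.5 / np.pi) * PPM
        assert vm.lamb_shielding() == pytest.approx(expected, rel=1e-14)

    def test_shielding_vanishes_far_from_vortex(self):
        prov = make_vortex_provider(VortexModel(zeta=1.0))
        near = shielding_density(prov, [0.0, 0.0, 0.0], "zz",
                                 [[0.5, 0.0, 0.0]]).values[0]
        # nucleus far away: kernel decays as distance^-2 at the vortex
        far = shielding_density(prov, [500.0, 0.0, 0.0], "zz",
                                [[0.5, 0.0, 0.0]]).values[0]
        assert abs(far) < 1e-4 * abs(near)

    def test_rotation_covariance_zz_vs_xx(self, rng):
        # sigma_zz of an xy-plane vortex equals sigma_xx of the same
        # vortex rotated into the yz-plane (cyclic axis permutation)
        center = np.array([0.8, -0.3, 0.5])
        prov_z = make_vortex_provider(VortexModel(center=center, zeta=1.2))
        rot = np.roll(np.eye(3), 1, axis=0)  # new x-axis along old z
        prov_x = make_vortex_provider(
            VortexModel(center=rot @ center, zeta=1.2)
        )
        nucleus = np.array([0.2, 0.1, -0.4])
        pts = rng.normal(size=(20, 3))
        vz = shielding_density(prov_z, nucleus, "zz", pts).values
        vx = shielding_density(
            prov_x, rot @ nucleus, "xx", (pts @ rot.T)
        ).values
        np.testing.assert_allclose(vx, vz, atol=1e-14)

    def test_vortex_matches_larmor_bundle(self, larmor_bundle, rng):
        # the analytic vortex and the Eq-8 route on the equivalent
        # one-center bundle are the same physical field
        from sigmadens.cdt import bundle_provider

        zeta = larmor_bundle.shells[0].primitives[0][0]
        vm = VortexModel(
            center=larmor_bundle.molecule.coords[0], zeta=zeta,
            n_electrons=larmor_bundle.n_electrons,
        )
        pts = rng.normal(size=(20, 3))
        np.testing.assert_allclose(
            provider_tensor(make_vortex_provider(vm), pts),
            provider_tensor(bundle_provider(larmor_bundle), pts),
            atol=1e-12,
        )


class TestMinBundle:
    def test_invariants_enforced(self):
        with pytest.raises(BundleValidationError):
            make_min_bundle(
                ["He"], [[0, 0, 0]], [1.0],
                [[1.0]], np.ones((3, 1, 1)),  # diagonal dD/dB not antisym
            )

    def test_zero_matrices_accepted(self):
        b = make_min_bundle(
            ["He"], [[0, 0, 0]], [1.0], [[0.0]], np.zeros((3, 1, 1))
        )
        assert b.n_electrons == 0.0


class TestComposite:
    def test_positive_band_outside_perimeter_one_bohr_above(self):
        prov = benzene_like_composite()
        mol = prov.molecule
        h_pos = mol.coords[6]  # H on the +x axis
        ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.stack(
            [6.0 * np.cos(ang), 6.0 * np.sin(ang), np.ones_like(ang)], 1
        )
        vals = shielding_density(prov, h_pos, "zz", pts).values
        assert np.all(vals > 0)

    def test_removing_paratropic_loop_removes_far_inner_deshielding(self):
        mol = benzene_like_composite().molecule
        h_pos = mol.coords[6]
        probe = [[-1.5, 0.0, 0.0]]  # remote half of the ring interior
        with_loop = shielding_density(
            benzene_like_composite(), h_pos, "zz", probe
        ).values[0]
        without = shielding_density(
            benzene_like_composite(with_inner_loop=False), h_pos, "zz", probe
        ).values[0]
        assert with_loop < 0
        assert without > 0

    def test_sixfold_symmetry(self):
        prov = benzene_like_composite()
        rot = np.array(
            [[0.5, -np.sqrt(3) / 2, 0],
             [np.sqrt(3) / 2, 0.5, 0],
             [0, 0, 1.0]]
        )
        pts = np.array([[3.3, 0.7, 0.5], [1.1, -0.4, 1.0]])
        nucleus = np.zeros(3)
        v0 = shielding_density(prov, nucleus, "zz", pts).values
        v1 = shielding_density(prov, nucleus, "zz", pts @ rot.T).values
        np.testing.assert_allclose(v1, v0, atol=1e-12)
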