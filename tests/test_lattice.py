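import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfmicelle.lattice import make_lattice, local_average, poisson_solve
from sfmicelle.segments import UnitConversions

COUPLING = UnitConversions().coupling


class TestGeometry:
    def test_planar(self):
        lat = make_lattice("planar", 10)
        np.testing.assert_allclose(lat.L, 1.0)
        np.testing.assert_allclose(lat.lam_minus, 1 / 6)
        np.testing.assert_allclose(lat.lam_plus, 1 / 6)
        np.testing.assert_allclose(lat.lam_zero, 4 / 6)

    def test_spherical_shell_volumes(self):
        lat = make_lattice("spherical", 50)
        r = np.arange(1, 51, dtype=float)
        expected = (4 * np.pi / 3) * (r**3 - (r - 1) ** 3)
        np.testing.assert_allclose(lat.L, expected)

    def test_cylindrical_shell_volumes(self):
        lat = make_lattice("cylindrical", 20)
        r = np.arange(1, 21, dtype=float)
        np.testing.assert_allclose(lat.L, np.pi * (r**2 - (r - 1) ** 2))

    def test_too_small(self):
        with pytest.raises(ValueError):
            make_lattice("spherical", 2)

    def test_unknown_geometry(self):
        with pytest.raises(ValueError):
            make_lattice("hyperbolic", 10)


@given(geometry=st.sampled_from(["planar", "cylindrical", "spherical"]),
       M=st.integers(min_value=3, max_value=200))
@settings(max_examples=30, deadline=None)
def test_lattice_invariants(geometry, M):
    lat = make_lattice(geometry, M)
    np.testing.assert_allclose(lat.lam_minus + lat.lam_zero + lat.lam_plus,
                               1.0, atol=1e-12)
    # flux balance L(r) lam+(r) = L(r+1) lam-(r+1)
    np.testing.assert_allclose(lat.L[:-1] * lat.lam_plus[:-1],
                               lat.L[1:] * lat.lam_minus[1:], rtol=1e-12)
    assert np.all(lat.L > 0)
    assert np.all(lat.lam_zero >= 0)


class TestLocalAverage:
    @pytest.mark.parametrize("geometry", ["planar", "cylindrical", "spherical"])
    def test_constant_preserved(self, geometry):
        lat = make_lattice(geometry, 30)
        np.testing.assert_allclose(local_average(np.full(30, 0.7), lat), 0.7)

    def test_planar_impulse(self):
        lat = make_lattice("planar", 9)
        f = np.zeros(9)
        f[4] = 1.0
        out = local_average(f, lat)
        np.testing.assert_allclose(out[3:6], [1 / 6, 4 / 6, 1 / 6])
        assert out.sum() == pytest.approx(1.0)

    def test_spherical_impulse_hand_computed(self):
        lat = make_lattice("spherical", 10)
        r0 = 4  # layer 5
        f = np.zeros(10)
        f[r0] = 1.0
        out = local_average(f, lat)
        # hand values from the lambda definitions
        assert out[r0 - 1] == pytest.approx(lat.lam_plus[r0 - 1])
        assert out[r0] == pytest.approx(lat.lam_zero[r0])
        assert out[r0 + 1] == pytest.approx(lat.lam_minus[r0 + 1])
        assert out[r0 + 1] == pytest.approx(lat.S[r0 + 1] / (6 * lat.L[r0 + 1]))

    def test_outer_boundary_value(self):
        lat = make_lattice("planar", 5)
        f = np.ones(5)
        out = local_average(f, lat, outer=0.0)
        assert out[-1] == pytest.approx(1.0 - 1 / 6)

    def test_length_mismatch(self):
        lat = make_lattice("planar", 5)
        with pytest.raises(ValueError):
            local_average(np.ones(4), lat)


class TestPoisson:
    def test_zero_charge(self):
        lat = make_lattice("spherical", 30)
        psi = poisson_solve(np.zeros(30), 80.0, lat)
        np.testing.assert_allclose(psi, 0.0, atol=1e-15)

    def test_charged_shell_gauss_law(self):
        # single charged shell in uniform eps: constant potential inside,
        # discrete-Coulomb decay outside (closed form by telescoping the
        # Gauss law from the outer Dirichlet boundary)
        M = 50
        lat = make_lattice("spherical", M)
        q = np.zeros(M)
        q[9] = 2.5 / lat.L[9]
        psi = poisson_solve(q, 80.0, lat, coupling=COUPLING)
        Qenc = np.cumsum(lat.L * q)
        dpsi = COUPLING * Qenc[: M - 1] / (lat.S[1:M] * 80.0)
        psi_ref = np.concatenate([np.cumsum(dpsi[::-1])[::-1], [0.0]])
        np.testing.assert_allclose(psi, psi_ref, rtol=1e-10)
        np.testing.assert_allclose(psi[:9], psi[0], rtol=1e-12)

    def test_neutral_concentric_shells(self):
        M = 40
        lat = make_lattice("spherical", M)
        q = np.zeros(M)
        q[5] = 1.0 / lat.L[5]
        q[14] = -1.0 / lat.L[14]
        psi = poisson_solve(q, 80.0, lat, coupling=COUPLING)
        np.testing.assert_allclose(psi[15:], 0.0, atol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(7)
        M = 25
        lat = make_lattice("cylindrical", M)
        s1, s2 = rng.normal(size=M), rng.normal(size=M)
        a, b = 0.3, -1.7
        p1 = poisson_solve(s1, 40.0, lat)
        p2 = poisson_solve(s2, 40.0, lat)
        p12 = poisson_solve(a * s1 + b * s2, 40.0, lat)
        np.testing.assert_allclose(p12, a * p1 + b * p2, atol=1e-12)

    def test_planar_capacitor(self):
        # charged plane in a large planar box: linear potential between
        # the plane and the boundary, zero field behind the plane
        M = 200
        lat = make_lattice("planar", M)
        q = np.zeros(M)
        q[49] = 0.01
        psi = poisson_solve(q, 80.0, lat, coupling=COUPLING)
        grad = np.diff(psi)
        np.testing.assert_allclose(grad[:48], 0.0, atol=1e-12)
        np.testing.assert_allclose(grad[51:], grad[-1], rtol=1e-10)
        expected_slope = -COUPLING * 0.01 / 80.0
        assert grad[-1] == pytest.approx(expected_slope, rel=1e-10)

    def test_nonpositive_permittivity(self):
        lat = make_lattice("planar", 5)
        with pytest.raises(ValueError):
            poisson_solve(np.zeros(5), 0.0, lat)


class TestSecondMomentWeights:
    def test_spherical_step_profile(self):
        lat = make_lattice("spherical", 30)
        w2 = lat.r2_weight()
        R = 12
        inside = np.arange(30) < R
        mean_r2 = (lat.L[inside] @ w2[inside]) / lat.L[inside].sum()
        assert np.sqrt(mean_r2) == pytest.approx(np.sqrt(3 / 5) * R, rel=1e-12)
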