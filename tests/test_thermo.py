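import numpy as np
import pandas as pd
import pytest

from sfmicelle import (
    SystemSpec,
    build_molecule,
    chemical_potential,
    default_segment_table,
    find_micelle,
    grand_potential,
    make_lattice,
    solve_scf,
)
from sfmicelle.molecule import linear_chain
from sfmicelle.segments import InteractionTable, SegmentKind
from sfmicelle.thermo import (
    grand_potential_bookkeeping,
    helmholtz_excess,
    omega_two_route,
    suggest_layers,
)


def _binary_state(N=10, phi_b=0.01, chi=0.0, tol=1e-10):
    """Uniform binary polymer/solvent cell for closed-form checks.

    Initialized from zero fields so the solver lands on the homogeneous
    root regardless of chi.
    """
    kinds = [SegmentKind("W"), SegmentKind("C")]
    tbl = InteractionTable(kinds, {("W", "C"): chi})
    lat = make_lattice("spherical", 25)
    mol = linear_chain(["C"] * N)
    theta = phi_b * lat.volume
    spec = SystemSpec(molecule=mol, lattice=lat, table=tbl,
                      theta_surf=theta, phi_salt_b=0.0)
    return solve_scf(spec, init=np.zeros((2, 25)), tol=tol)


class TestChemicalPotential:
    def test_ideal_binary_closed_form(self):
        # mu_p = ln(phi) + (1 - N) phi_s for chi = 0
        N = 10
        st = _binary_state(N, 0.01, chi=0.0)
        phi = st.phi_b["surf"]          # converged bulk fraction
        expected = np.log(phi) + (1 - N) * (1 - phi)
        assert chemical_potential(st) == pytest.approx(expected, rel=1e-12)

    def test_binary_with_chi_hand_evaluated(self):
        # full expression: ln phi + 1 - N(phi/N + phi_s) + N chi phi_s^2
        N, chi = 10, 1.2
        st = _binary_state(N, 0.01, chi=chi)
        phi = st.phi_b["surf"]
        phi_s = 1 - phi
        expected = (np.log(phi) + 1.0 - N * (phi / N + phi_s)
                    + N * chi * phi_s**2)
        assert chemical_potential(st) == pytest.approx(expected, rel=1e-9)

    def test_melt_limit(self):
        # the standard normalization vanishes for a one-component melt
        kinds = [SegmentKind("W"), SegmentKind("C")]
        tbl = InteractionTable(kinds, np.zeros((2, 2)))
        lat = make_lattice("planar", 10)
        mol = linear_chain(["C"] * 5)
        # direct evaluation of the formula at phi_b = 1
        from sfmicelle.thermo import _mu_fh
        spec = SystemSpec(molecule=mol, lattice=lat, table=tbl,
                          theta_surf=0.0, phi_salt_b=0.0)
        st = solve_scf(spec)
        st.phi_b = {"surf": 1.0, "W": 0.0, "Na": 0.0, "Cl": 0.0}
        st.phi_kind_b = np.array([0.0, 1.0])
        assert _mu_fh(st, "surf", "standard") == pytest.approx(0.0, abs=1e-12)

    def test_zero_bulk_fraction_error(self, table):
        lat = make_lattice("planar", 10)
        mol = linear_chain(["C"] * 3)
        spec = SystemSpec(molecule=mol, lattice=lat, table=table,
                          theta_surf=0.0, phi_salt_b=0.01)
        st = solve_scf(spec)
        with pytest.raises(ValueError):
            chemical_potential(st)


class TestGrandPotential:
    def test_homogeneous_is_zero(self):
        st = _binary_state(8, 0.02, chi=0.4)
        assert grand_potential(st) == pytest.approx(0.0, abs=1e-8)
        assert grand_potential_bookkeeping(st) == pytest.approx(0.0, abs=1e-6)

    def test_unconverged_rejected(self):
        st = _binary_state(8, 0.02)
        st.converged = False
        with pytest.raises(ValueError):
            grand_potential(st)

    def test_two_routes_agree_on_micelle(self, micelle_g1_nt30):
        o1, o2 = omega_two_route(micelle_g1_nt30)
        assert abs(o1 - o2) <= 1e-3

    def test_eq2_consistency(self, micelle_g1_nt30):
        # Omega = F - sum_i mu_i n_i^exc; with the bookkeeping route this
        # is exactly how F is related to mu and n
        st = micelle_g1_nt30
        F = helmholtz_excess(st)
        o2 = grand_potential_bookkeeping(st)
        assert np.isfinite(F)
        # F differs from mu_surf*n_agg by the other species' contributions,
        # all bundled in the bookkeeping route; consistency with the field
        # route closes the loop
        assert abs(o2 - grand_potential(st)) <= 1e-3


class TestFindMicelle:
    def test_synthetic_parabola_crossing(self):
        n = np.arange(0, 30)
        omega = 10 - (n - 5) ** 2 / 10.0
        tab = pd.DataFrame({"n_agg": n, "Omega": omega,
                            "mu": -20 + 0.01 * n,
                            "phi_surf_b": 1e-4 + 1e-6 * n,
                            "converged": True})
        mic = find_micelle(tab)
        assert mic.found
        assert mic.n_agg == pytest.approx(15.0, abs=0.5)
        assert mic.phi_cmc_b == pytest.approx(1e-4 + 1e-6 * 5, rel=1e-6)

    def test_no_crossing(self):
        n = np.arange(0, 10)
        tab = pd.DataFrame({"n_agg": n, "Omega": 1.0 + 0.1 * n,
                            "mu": np.zeros(10), "phi_surf_b": np.full(10, 1e-4),
                            "converged": True})
        mic = find_micelle(tab)
        assert not mic.found

    def test_flat_noise_curve_rejected(self):
        # a fully dissolved scan (Omega ~ 0 everywhere) must not report a
        # spurious micelle
        n = np.linspace(0, 1e-8, 12)
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({"n_agg": n, "Omega": rng.normal(0, 1e-7, 12),
                            "mu": np.zeros(12), "phi_surf_b": np.full(12, 1e-4),
                            "converged": True})
        mic = find_micelle(tab)
        assert not mic.found


class TestSuggestLayers:
    def test_monotone_in_theta(self):
        mol = build_molecule(1, 2, 15)
        m1 = suggest_layers(mol, 1000, "spherical")
        m2 = suggest_layers(mol, 30000, "spherical")
        assert m2 > m1 >= 20


class TestTransitionPoints:
    def test_synthetic_crossing_recovered(self):
        from sfmicelle.thermo import transition_points
        nt = np.array([10.0, 20.0, 30.0, 40.0])
        # mu_sphere - mu_cylinder crosses zero at Nt = 25
        tab = pd.DataFrame({
            "Nt": nt,
            "mu_sphere": -30 + 0.2 * nt,
            "mu_cylinder": -28 + 0.12 * nt,
        })
        out = transition_points(tab, ("sphere", "cylinder"))
        assert len(out) == 1
        assert out[0]["pair"] == "sphere-cylinder"
        assert out[0]["Nt"] == pytest.approx(25.0)

    def test_no_crossing_open_boundary(self):
        from sfmicelle.thermo import transition_points
        tab = pd.DataFrame({"Nt": [10.0, 20.0],
                            "mu_sphere": [-30.0, -29.0],
                            "mu_cylinder": [-25.0, -24.0]})
        assert transition_points(tab, ("sphere", "cylinder")) == []
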