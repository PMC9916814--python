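import numpy as np
import pytest

from sfmicelle import (
    build_molecule,
    charge_analysis,
    core_metrics,
    make_lattice,
    stratification_report,
)
from sfmicelle.fixtures import make_fixture
from sfmicelle.observables import local_maxima, _second_moment_radius


class TestLocalMaxima:
    def test_single_peak(self):
        y = np.exp(-0.5 * (np.arange(50) - 20.0) ** 2 / 9)
        assert local_maxima(y) == [20]

    def test_two_peaks(self):
        x = np.arange(60, dtype=float)
        y = np.exp(-0.5 * ((x - 15) / 3) ** 2) + 0.8 * np.exp(-0.5 * ((x - 40) / 4) ** 2)
        assert local_maxima(y) == [15, 40]

    def test_plateau_counts_once_at_midpoint(self):
        y = np.array([0, 1, 2, 2, 2, 1, 0], dtype=float)
        assert local_maxima(y) == [3]

    def test_small_peaks_ignored(self):
        x = np.arange(80, dtype=float)
        y = np.exp(-0.5 * ((x - 20) / 3) ** 2)
        y += 0.001 * np.exp(-0.5 * ((x - 60) / 2) ** 2)
        assert local_maxima(y, min_frac=0.01) == [20]

    def test_mask_frac_excludes_tail_noise(self):
        y = np.zeros(40)
        y[10] = 1.0
        y[30] = 1e-12   # far below 1e-8 of the peak
        assert local_maxima(y, min_frac=0.0, mask_frac=1e-8) == [10]

    def test_monotone_has_no_interior_maximum(self):
        y = np.linspace(0, 1, 20)
        assert local_maxima(y) == [19] or local_maxima(y) == []


class TestSecondMomentRadius:
    def test_step_profile_spherical(self):
        lat = make_lattice("spherical", 40)
        R = 15
        prof = np.where(np.arange(40) < R, 1.0, 0.0)
        assert _second_moment_radius(prof, lat) == pytest.approx(
            np.sqrt(3 / 5) * R, rel=1e-12)

    def test_delta_shell(self):
        lat = make_lattice("spherical", 40)
        prof = np.zeros(40)
        prof[24] = 1.0   # shell at layer 25
        r = _second_moment_radius(prof, lat)
        assert 24.0 < r < 25.0

    def test_empty_profile_rejected(self):
        lat = make_lattice("spherical", 10)
        with pytest.raises(ValueError):
            _second_moment_radius(np.zeros(10), lat)


class TestHandProfiles:
    def test_double_layer_single_maximum(self):
        fx = make_fixture("hand-profiles-doublelayer")
        Q = fx.payload["Q"]
        assert abs(Q[-1]) < 1e-6          # net neutral
        peaks = local_maxima(Q)
        assert len(peaks) == 1
        assert fx.payload["lattice"].r_centers[peaks[0]] == pytest.approx(9.5)

    def test_stratified_two_maxima(self):
        fx = make_fixture("hand-profiles-stratified")
        peaks = local_maxima(fx.payload["nt"], min_frac=0.0, mask_frac=1e-8)
        assert len(peaks) == 2


class TestMicelleObservables:
    def test_core_metrics_consistency(self, micelle_g1_nt30):
        st = micelle_g1_nt30
        m = core_metrics(st)
        assert m.Hshell == pytest.approx(m.Rm - m.Rcore)
        assert m.s * st.n_agg == pytest.approx(4 * np.pi * m.Rcore**2, rel=1e-10)
        # terminal bookkeeping: integral of nt = n_agg * 2^(G+1)
        expected = st.n_agg * 4
        assert m.Nterm == pytest.approx(expected, rel=0.01)
        assert m.Rcore_nm == pytest.approx(m.Rcore * 0.3, rel=1e-12)
        assert m.Rm > m.Rcore > 0

    def test_charge_analysis_neutral_and_signed(self, micelle_g1_nt30):
        st = micelle_g1_nt30
        ca = charge_analysis(st)
        assert abs(ca.Q[-1]) < 1e-6
        assert ca.Qeff <= ca.Qbare + 1e-9
        assert ca.Qeff > 0
        assert np.sign(ca.zeta) == np.sign(ca.Qeff)
        assert ca.Reff > 0
        assert ca.n_maxima >= 1

    def test_classical_double_layer_single_maximum(self, micelle_g1_nt30):
        # a small-generation dendron corona forms one double layer
        ca = charge_analysis(micelle_g1_nt30)
        assert ca.n_maxima == 1

    def test_stratification_report_classes(self, micelle_g1_nt30):
        st = micelle_g1_nt30
        rep = stratification_report(st)
        # per-class distributions sum to the total
        total = sum(rep.nt_by_contour.values())
        np.testing.assert_allclose(total, rep.nt_total, atol=1e-10)
        assert set(rep.branch_points_by_subgen) == {0, 1}
        assert set(rep.segments_by_subgen) == {0, 1}

    def test_no_micelle_rejected(self, table):
        from sfmicelle import SystemSpec, solve_scf
        from sfmicelle.molecule import linear_chain
        lat = make_lattice("spherical", 20)
        spec = SystemSpec(molecule=linear_chain(["C"]), lattice=lat,
                          table=table, theta_surf=0.0, phi_salt_b=0.01)
        st = solve_scf(spec)
        with pytest.raises(ValueError):
            core_metrics(st)
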