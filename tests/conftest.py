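import warnings

import numpy as np
import pytest

from sfmicelle import (
    SystemSpec,
    build_molecule,
    default_segment_table,
    make_lattice,
    solve_scf,
)

warnings.filterwarnings("ignore", message="outer layers deviate")


@pytest.fixture(scope="session")
def table():
    tbl, _ = default_segment_table()
    return tbl


@pytest.fixture(scope="session")
def lysine_g1(table):
    return build_molecule(1, 2, 12)


# ---------------------------------------------------------------------------
# expensive converged systems, shared across the whole session
# ---------------------------------------------------------------------------

def _solve_micelle(G, t, Nt, n_agg, M, salt=0.01, init=None, tol=1e-9):
    tbl, _ = default_segment_table()
    mol = build_molecule(G, t, Nt)
    lat = make_lattice("spherical", M)
    spec = SystemSpec(molecule=mol, lattice=lat, table=tbl,
                      theta_surf=n_agg * mol.n_segments, phi_salt_b=salt)
    return solve_scf(spec, init=init, tol=tol, raise_on_fail=False)


@pytest.fixture(scope="session")
def micelle_g1_nt30():
    """Converged spherical micelle near its equilibrium size (Omega ~ 0),
    G=1 t=2 Nt=30; tight tolerance so global neutrality holds to 1e-8."""
    state = _solve_micelle(1, 2, 30, 16, 100)
    assert state.converged and state.n_agg > 10
    return state


@pytest.fixture(scope="session")
def g4_cascade():
    """Generation-continuation chain to large G=4 micelles (Nt=90) and a
    tail-length walk toward the Nt=60 system of the stratification study.

    Returns dict with keys "nt90" (large stratifying G=4 micelle or
    None) and "nt60" (the G=4,t=2,Nt=60 system if reachable, else None).
    """
    tbl, _ = default_segment_table()
    lat = make_lattice("spherical", 105)
    prev = None
    state = None
    for G, n in [(1, 40), (2, 30), (3, 20), (4, 25), (4, 50), (4, 70)]:
        mol = build_molecule(G, 2, 90)
        spec = SystemSpec(molecule=mol, lattice=lat, table=tbl,
                          theta_surf=n * mol.n_segments, phi_salt_b=0.01)
        st = solve_scf(spec, init=prev, tol=1e-9, raise_on_fail=False,
                       fallbacks=False)
        if st.converged and st.n_agg > 3:
            prev = st.u.copy()
            state = st
    nt90 = state if state is not None and state.n_agg > 30 else None

    nt60 = None
    if nt90 is not None:
        u = prev
        for Nt in (80, 70, 60):
            mol = build_molecule(4, 2, Nt)
            spec = SystemSpec(molecule=mol, lattice=lat, table=tbl,
                              theta_surf=50 * mol.n_segments, phi_salt_b=0.01)
            st = solve_scf(spec, init=u, tol=1e-9, raise_on_fail=False,
                           fallbacks=False)
            if not (st.converged and st.n_agg > 10):
                break
            u = st.u.copy()
            if Nt == 60:
                nt60 = st
    return {"nt90": nt90, "nt60": nt60}
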