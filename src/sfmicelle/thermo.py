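"""Micelle thermodynamics.

The work of formation of the most probable aggregate is the excess
grand potential Omega of the cell relative to the homogeneous bulk; it
rises with the aggregation number in the pre-micellar regime, passes
through a maximum (the c.m.c.) and decays through zero.  Omega = 0
defines the equilibrium micelle; morphologies are compared through the
surfactant chemical potential evaluated there, and the transition
between two morphologies is where their chemical potentials are equal.

Omega is computed by two independent routes:

* the *field route*: a local grand-potential density assembled from the
  converged profiles, the incompressibility field ``alpha`` and the
  electrostatic potential;
* the *bookkeeping route*: ``F - sum_i mu_i n_i`` (excess versus bulk)
  with the Helmholtz free energy from the single-molecule partition
  functions and multicomponent Flory-Huggins chemical potentials.

Their agreement (<= 1e-3 kT on converged micelles) is the central
internal consistency contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import (
    SCFConvergenceError,
    SCFState,
    SystemSpec,
    solve_scf,
    SOLVENT,
    CATION,
    ANION,
)
from .lattice import local_average, make_lattice
from .molecule import ChainGraph, build_molecule
from .segments import InteractionTable, UnitConversions, default_segment_table

__all__ = [
    "MicelleThermo",
    "StateDiagram",
    "ScanResult",
    "chemical_potential",
    "grand_potential",
    "grand_potential_bookkeeping",
    "helmholtz_excess",
    "omega_two_route",
    "scan_micelles",
    "find_micelle",
    "morphology_transitions",
    "build_state_diagram",
    "suggest_layers",
]

#: morphology label per lattice geometry
MORPHOLOGY = {"spherical": "sphere", "cylindrical": "cylinder", "planar": "lamella"}
GEOMETRY_OF = {v: k for k, v in MORPHOLOGY.items()}


# ---------------------------------------------------------------------------
# species bookkeeping helpers
# ---------------------------------------------------------------------------

def _species_info(state: SCFState):
    """Name, chain length and kind-composition vector of every species."""
    spec = state.spec
    K = len(spec.table.names)
    kindex = spec.table.index
    species = []
    counts = np.zeros(K)
    for k in spec.molecule.kinds:
        counts[kindex[k]] += 1.0
    species.append(("surf", spec.n_segments, counts))
    for name in (SOLVENT, CATION, ANION):
        if name in kindex:
            c = np.zeros(K)
            c[kindex[name]] = 1.0
            species.append((name, 1, c))
    return species


def _mu_fh(state: SCFState, name: str, normalization: str = "standard") -> float:
    """Multicomponent Flory-Huggins chemical potential at bulk composition.

    ``normalization='standard'`` gives the conventional form

        mu_i = ln phi_i^b + 1 - N_i sum_j phi_j^b / N_j
               - (N_i/2) sum_XY (phi_X^b - f_iX) chi_XY (phi_Y^b - f_iY)

    with ``f_iX`` the kind fractions of species ``i`` (zero for a pure
    surfactant melt).  ``normalization='derivative'`` gives the direct
    derivative of the bulk free energy used by the bookkeeping route of
    the grand potential; the two differ by a per-species constant only.
    """
    species = _species_info(state)
    names = [s[0] for s in species]
    if name not in names:
        raise ValueError(f"unknown species {name!r}")
    phi_b = np.array([state.phi_b[n] for n in names])
    Ns = np.array([float(s[1]) for s in species])
    i = names.index(name)
    if phi_b[i] <= 0:
        raise ValueError(f"species {name!r} has zero bulk fraction")
    chi = state.spec.table.chi_matrix
    phi_kind_b = state.phi_kind_b
    f_i = species[i][2] / Ns[i]
    N_i = Ns[i]
    if normalization == "standard":
        dev = phi_kind_b - f_i
        return float(np.log(phi_b[i]) + 1.0 - N_i * np.sum(phi_b / Ns)
                     - 0.5 * N_i * dev @ chi @ dev)
    if normalization == "derivative":
        return float(np.log(phi_b[i] / N_i) - N_i * np.sum(phi_b / Ns)
                     + N_i * f_i @ chi @ phi_kind_b
                     - 0.5 * N_i * phi_kind_b @ chi @ phi_kind_b)
    raise ValueError("normalization must be 'standard' or 'derivative'")


def chemical_potential(state: SCFState, molecule: Optional[ChainGraph] = None) -> float:
    """Surfactant chemical potential (kT) at the bulk composition.

    Standard multicomponent Flory-Huggins expression: translational term
    ``ln phi_surf^b``, the size-asymmetry term
    ``1 - N sum_j phi_j^b/N_j`` and the chi-weighted composition terms.
    Vanishes for a pure surfactant melt.
    """
    if molecule is not None and molecule is not state.spec.molecule:
        raise ValueError("state was converged for a different molecule")
    return _mu_fh(state, "surf", "standard")


# ---------------------------------------------------------------------------
# grand potential, two routes
# ---------------------------------------------------------------------------

def _require_converged(state: SCFState) -> None:
    if not state.converged:
        raise ValueError("grand potential requires a converged state")


def _interaction_pieces(state: SCFState):
    spec = state.spec
    lat = spec.lattice
    chi = spec.table.chi_matrix
    phi = state.phi
    phi_b = state.phi_kind_b
    avg = np.empty_like(phi)
    for k in range(phi.shape[0]):
        avg[k] = local_average(phi[k], lat, outer=phi_b[k])
    e_int_local = 0.5 * np.einsum("xr,xy,yr->r", phi, chi, avg)
    e_int_bulk = 0.5 * phi_b @ chi @ phi_b
    q_species = spec.table.valencies @ phi
    q_ext = spec.external_charge if spec.external_charge is not None else 0.0
    return e_int_local, e_int_bulk, q_species, q_ext


def grand_potential(state: SCFState) -> float:
    """Excess grand potential (kT) via the local field route.

    ``Omega = sum_r L(r) omega(r)`` with

        omega(r) = - sum_i (phi_i - phi_i^b)/N_i - alpha(r)
                   - (1/2) sum_XY chi_XY [phi_X <phi_Y> - phi_X^b phi_Y^b]
                   - (1/2) (q_species(r) - q_ext(r)) psi(r)

    and vanishes identically for the homogeneous bulk.
    """
    _require_converged(state)
    spec = state.spec
    lat = spec.lattice
    omega_r = -state.alpha.copy()
    for name, N_i, _ in _species_info(state):
        omega_r -= (state.phi_species[name] - state.phi_b[name]) / N_i
    e_int_local, e_int_bulk, q_species, q_ext = _interaction_pieces(state)
    omega_r -= e_int_local - e_int_bulk
    omega_r -= 0.5 * (q_species - q_ext) * state.psi
    return float(lat.L @ omega_r)


def helmholtz_excess(state: SCFState) -> float:
    """Excess Helmholtz free energy (kT) of the cell relative to bulk.

    Assembled from single-molecule partition functions, the mean-field
    interaction energy and the electrostatic energy; independent of the
    incompressibility field.
    """
    _require_converged(state)
    spec = state.spec
    lat = spec.lattice
    V = lat.volume
    species = _species_info(state)

    f_ideal = 0.0
    for name, N_i, _ in species:
        theta_i = state.theta(name)
        n_i = theta_i / N_i
        phi_b = state.phi_b[name]
        n_b = V * phi_b / N_i
        if name == "surf":
            if spec.theta_surf <= 0:
                continue
            logq = state.logq_surf
        else:
            i = spec.table.index[name]
            g = np.exp(-np.clip(state.u[i], -200.0, 200.0))
            logq = float(np.log(lat.L @ g))
        if n_i > 0:
            f_ideal += n_i * (np.log(n_i) - logq - 1.0)
        if n_b > 0:
            f_ideal += -n_b * (np.log(n_b / V) - 1.0)

    field_term = -float(np.einsum("xr,xr,r->", state.u, state.phi, lat.L))
    e_int_local, e_int_bulk, q_species, q_ext = _interaction_pieces(state)
    e_int = float(lat.L @ e_int_local) - V * e_int_bulk
    if np.isscalar(q_ext):
        q_tot = q_species + q_ext
    else:
        q_tot = q_species + q_ext
    e_el = 0.5 * float(lat.L @ (q_tot * state.psi))
    return f_ideal + field_term + e_int + e_el


def grand_potential_bookkeeping(state: SCFState) -> float:
    """Excess grand potential (kT) via ``F_exc - sum_i mu_i n_i^exc``.

    Independent of the field route: uses partition functions and the
    Flory-Huggins bulk chemical potentials rather than the local
    ``alpha`` field.
    """
    _require_converged(state)
    spec = state.spec
    V = spec.lattice.volume
    omega = helmholtz_excess(state)
    for name, N_i, _ in _species_info(state):
        if state.phi_b[name] <= 0:
            continue
        n_exc = state.theta(name) / N_i - V * state.phi_b[name] / N_i
        omega -= _mu_fh(state, name, "derivative") * n_exc
    return omega


def omega_two_route(state: SCFState) -> Tuple[float, float]:
    """Both grand-potential routes (field, bookkeeping)."""
    return grand_potential(state), grand_potential_bookkeeping(state)


# ---------------------------------------------------------------------------
# theta scans and micelle location
# ---------------------------------------------------------------------------

@dataclass
class MicelleThermo:
    """Thermodynamic summary of one equilibrium micelle (Omega = 0)."""

    found: bool
    morphology: str
    n_agg: float = float("nan")
    Omega: float = float("nan")
    mu_surf: float = float("nan")
    F: float = float("nan")
    phi_surf_b: float = float("nan")
    phi_cmc_b: float = float("nan")
    theta: float = float("nan")
    state: Optional[SCFState] = None

    def to_dict(self) -> dict:
        return {
            "found": self.found,
            "morphology": self.morphology,
            "n_agg": self.n_agg,
            "Omega": self.Omega,
            "mu_surf": self.mu_surf,
            "F": self.F,
            "phi_surf_b": self.phi_surf_b,
            "phi_cmc_b": self.phi_cmc_b,
            "theta": self.theta,
        }


@dataclass
class ScanResult:
    """Per-theta thermodynamic curves of one molecule/geometry."""

    table: pd.DataFrame
    states: Dict[float, SCFState] = field(default_factory=dict)
    solver: Optional[Callable[[float, Optional[SCFState]], SCFState]] = None
    morphology: str = "sphere"

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.12g")


def suggest_layers(molecule: ChainGraph, theta_max: float, geometry: str,
                   margin: int = 60) -> int:
    """Lattice size heuristic: core radius + maximal corona extent + margin.

    The margin buries the Debye tail so that global electroneutrality
    holds to ~1e-8 at the outer (bulk) boundary.
    """
    n_tail = sum(molecule.is_tail) or molecule.kind_count("C")
    N = molecule.n_segments
    theta_tail = theta_max * n_tail / max(N, 1)
    if geometry == "spherical":
        r0 = (3.0 * theta_tail / (4.0 * np.pi)) ** (1.0 / 3.0)
    elif geometry == "cylindrical":
        r0 = np.sqrt(theta_tail / np.pi)
    else:
        r0 = theta_tail
    dendron_contour = [c for c, t in zip(molecule.contour, molecule.is_tail)
                       if not t]
    corona = max(dendron_contour) if dendron_contour else 0
    return max(int(np.ceil(r0 + corona + margin)), 20)


def _thermo_row(state: SCFState) -> dict:
    return {
        "theta": state.spec.theta_surf,
        "n_agg": state.n_agg,
        "Omega": grand_potential(state),
        "mu": chemical_potential(state),
        "phi_surf_b": state.phi_b["surf"],
        "converged": state.converged,
        "residual": state.residual,
        "iterations": state.iterations,
    }


def scan_micelles(molecule: ChainGraph, geometry: str,
                  thetas: Sequence[float], *,
                  table: Optional[InteractionTable] = None,
                  phi_salt_b: float = 0.01,
                  conversions: Optional[UnitConversions] = None,
                  M: Optional[int] = None,
                  refine: int = 2,
                  tol: float = 1e-7,
                  solver_kwargs: Optional[dict] = None) -> ScanResult:
    """Converge a cell at each theta and collect (n_agg, Omega, mu, phi_b).

    The scan runs from the largest theta downward with warm starts, so
    the aggregate persists metastably into the pre-micellar branch and
    the rise-maximum-decay shape of Omega(n_agg) is resolved.
    Convergence failures are recorded per point and the scan continues.
    ``refine`` adds up to two levels of midpoints around the Omega = 0
    crossing.
    """
    thetas = np.sort(np.asarray(thetas, dtype=float))
    if np.any(np.diff(thetas) <= 0):
        raise ValueError("theta grid must be strictly increasing")
    if table is None:
        table, _ = default_segment_table()
    conversions = conversions or UnitConversions()
    if M is None:
        M = suggest_layers(molecule, thetas[-1], GEOMETRY_OF.get(geometry, geometry))
    geom = GEOMETRY_OF.get(geometry, geometry)
    lattice = make_lattice(geom, M)
    kwargs = dict(solver_kwargs or {})

    states: Dict[float, SCFState] = {}

    def solve_at(theta: float, warm: Optional[SCFState]) -> SCFState:
        # each point is solved from a fresh amount-consistent seed; the
        # previous point's Jacobian is recycled as a starting guess
        spec = SystemSpec(molecule=molecule, lattice=lattice, table=table,
                          theta_surf=float(theta), phi_salt_b=phi_salt_b,
                          conversions=conversions)
        jac = warm.jacobian if warm is not None else None
        kw = dict(fallbacks=False)
        kw.update(kwargs)
        return solve_scf(spec, init=None, tol=tol, raise_on_fail=False,
                         jacobian=jac, **kw)

    rows: List[dict] = []
    warm: Optional[SCFState] = None
    for theta in thetas[::-1]:
        st = solve_at(theta, warm)
        states[float(theta)] = st
        if st.converged:
            rows.append(_thermo_row(st))
            warm = st
        else:
            rows.append({"theta": float(theta), "n_agg": np.nan, "Omega": np.nan,
                         "mu": np.nan, "phi_surf_b": np.nan, "converged": False,
                         "residual": st.residual, "iterations": st.iterations})

    tab = pd.DataFrame(rows).sort_values("theta").reset_index(drop=True)

    for _ in range(refine):
        bracket = _zero_bracket(tab)
        if bracket is None:
            break
        ta, tb = bracket
        tmid = 0.5 * (ta + tb)
        st = solve_at(tmid, states.get(tb) or states.get(ta))
        states[float(tmid)] = st
        if not st.converged:
            break
        tab = pd.concat([tab, pd.DataFrame([_thermo_row(st)])], ignore_index=True)
        tab = tab.sort_values("theta").reset_index(drop=True)

    return ScanResult(table=tab, states=states, solver=solve_at,
                      morphology=MORPHOLOGY[geom])


def _zero_bracket(tab: pd.DataFrame) -> Optional[Tuple[float, float]]:
    """Theta bracket of the Omega sign change on the post-maximum branch."""
    ok = tab[tab["converged"]].reset_index(drop=True)
    if len(ok) < 2:
        return None
    om = ok["Omega"].to_numpy()
    imax = int(np.argmax(om))
    if om[imax] <= 0.01:
        return None
    for i in range(imax, len(ok) - 1):
        if om[i] > 0 >= om[i + 1]:
            return float(ok["theta"][i]), float(ok["theta"][i + 1])
    return None


def find_micelle(curves: ScanResult | pd.DataFrame, *,
                 polish: bool = True, omega_tol: float = 1e-3,
                 max_polish: int = 20) -> MicelleThermo:
    """Locate the equilibrium micelle (Omega = 0 after the maximum).

    Accepts a :class:`ScanResult` or any table with columns ``n_agg``
    and ``Omega`` (and optionally ``mu``, ``phi_surf_b``, ``theta``).
    With a live :class:`ScanResult`, the crossing is polished by secant
    iteration on theta until ``|Omega| <= omega_tol`` kT and the
    converged state is attached; otherwise local linear interpolation
    on the grid is used.
    """
    if isinstance(curves, ScanResult):
        tab = curves.table
        morphology = curves.morphology
        solver = curves.solver if polish else None
        states = curves.states
    else:
        tab = curves
        morphology = "sphere"
        solver = None
        states = {}

    ok = tab[tab.get("converged", pd.Series(True, index=tab.index))].reset_index(drop=True)
    ok = ok.sort_values("n_agg").reset_index(drop=True)
    if len(ok) < 2:
        return MicelleThermo(found=False, morphology=morphology)
    om = ok["Omega"].to_numpy()
    n = ok["n_agg"].to_numpy()
    imax = int(np.argmax(om))
    phi_cmc = float(ok["phi_surf_b"][imax]) if "phi_surf_b" in ok else float("nan")
    cross = None
    for i in range(imax, len(ok) - 1):
        if om[i] > 0 >= om[i + 1]:
            cross = i
            break
    # a real aggregate requires a genuine Omega maximum and a crossing at
    # a finite excess amount (cylinders/lamellae count per unit cell, so
    # the thresholds are small); flat dissolved curves are noise
    if cross is None or om[imax] <= 0.01 or n[cross + 1] < 0.05:
        return MicelleThermo(found=False, morphology=morphology, phi_cmc_b=phi_cmc)

    # linear interpolation in n_agg
    w = om[cross] / (om[cross] - om[cross + 1])
    out = MicelleThermo(found=True, morphology=morphology, phi_cmc_b=phi_cmc)
    out.n_agg = float(n[cross] + w * (n[cross + 1] - n[cross]))
    out.Omega = 0.0
    for col, attr in (("mu", "mu_surf"), ("phi_surf_b", "phi_surf_b"), ("theta", "theta")):
        if col in ok:
            v = ok[col].to_numpy()
            setattr(out, attr, float(v[cross] + w * (v[cross + 1] - v[cross])))

    if solver is not None and "theta" in ok:
        ta, oa = float(ok["theta"][cross]), float(om[cross])
        tb, ob = float(ok["theta"][cross + 1]), float(om[cross + 1])
        warm = states.get(tb) or states.get(ta)
        best_state = None
        for _ in range(max_polish):
            tm = ta + oa * (tb - ta) / (oa - ob)
            st = solver(tm, warm)
            if not st.converged:
                break
            warm = st
            omm = grand_potential(st)
            best_state = st
            if abs(omm) <= omega_tol:
                break
            if omm > 0:
                ta, oa = tm, omm
            else:
                tb, ob = tm, omm
        if best_state is not None:
            out.state = best_state
            out.n_agg = best_state.n_agg
            out.Omega = grand_potential(best_state)
            out.mu_surf = chemical_potential(best_state)
            out.phi_surf_b = best_state.phi_b["surf"]
            out.theta = best_state.spec.theta_surf
            out.F = helmholtz_excess(best_state)
    return out


# ---------------------------------------------------------------------------
# morphology comparison and state diagram
# ---------------------------------------------------------------------------

def default_theta_grid(molecule: ChainGraph, geometry: str,
                       n_agg_range: Tuple[float, float] = (2.0, 300.0),
                       points_per_decade: int = 12) -> np.ndarray:
    """Geometric theta grid targeting an aggregation-number range.

    For cylinders and lamellae the 'aggregation number' is the excess
    amount per unit-length / unit-area cell, so the ranges are scaled
    by the cell size.
    """
    N = molecule.n_segments
    lo, hi = n_agg_range
    scale = {"sphere": 1.0, "cylinder": 1.0 / 8.0, "lamella": 1.0 / 80.0}[geometry]
    lo, hi = lo * scale * N, hi * scale * N
    n_points = max(int(np.ceil(points_per_decade * np.log10(hi / lo))), 4)
    return np.geomspace(lo, hi, n_points)


@dataclass
class StateDiagram:
    """Morphology boundaries per tail count in the (Nt*t, G) plane."""

    boundaries: Dict[int, Dict[str, List[Tuple[float, float]]]]

    def boundary(self, t: int, which: str = "sphere-cylinder") -> List[Tuple[float, float]]:
        return self.boundaries[t][which]


def morphology_transitions(G: int, t: int, Nt_values: Sequence[int], *,
                           morphologies: Sequence[str] = ("sphere", "cylinder", "lamella"),
                           theta_grids: Optional[Dict[str, Sequence[float]]] = None,
                           scan_kwargs: Optional[dict] = None) -> dict:
    """Equilibrium chemical potential per morphology over a tail-length range.

    For each ``Nt`` and each morphology, scans theta, locates the
    Omega = 0 micelle and records ``mu_surf`` there (NaN when the
    morphology does not form).  Transition points between consecutive
    morphologies are located by bracketing the sign change of the
    chemical-potential difference and linear interpolation in ``Nt``.
    """
    scan_kwargs = dict(scan_kwargs or {})
    rows = []
    for Nt in Nt_values:
        mol = build_molecule(G, t, Nt)
        row: Dict[str, float] = {"Nt": Nt}
        for morph in morphologies:
            grid = (theta_grids or {}).get(morph)
            if grid is None:
                grid = default_theta_grid(mol, morph)
            scan = scan_micelles(mol, morph, grid, **scan_kwargs)
            mic = find_micelle(scan)
            row[f"mu_{morph}"] = mic.mu_surf if mic.found else np.nan
        rows.append(row)
    tab = pd.DataFrame(rows)
    return {"table": tab, "transitions": transition_points(tab, morphologies)}


def transition_points(tab: pd.DataFrame, morphologies: Sequence[str]) -> list:
    """Locate morphology transitions from per-Nt chemical potentials.

    For each consecutive morphology pair, brackets the sign change of
    ``mu_a - mu_b`` along ``Nt`` and interpolates linearly.
    """
    transitions = []
    for a, b in zip(morphologies[:-1], morphologies[1:]):
        d = (tab[f"mu_{a}"] - tab[f"mu_{b}"]).to_numpy(dtype=float)
        nt = tab["Nt"].to_numpy(dtype=float)
        for i in range(len(nt) - 1):
            if np.isfinite(d[i]) and np.isfinite(d[i + 1]) and d[i] < 0 <= d[i + 1]:
                w = -d[i] / (d[i + 1] - d[i])
                transitions.append({"pair": f"{a}-{b}",
                                    "Nt": float(nt[i] + w * (nt[i + 1] - nt[i]))})
                break
    return transitions


def build_state_diagram(G_values: Sequence[int], t_values: Sequence[int],
                        Ntt_values: Sequence[int], *,
                        scan_kwargs: Optional[dict] = None) -> StateDiagram:
    """Assemble morphology boundaries in (Nt*t, G) per tail count.

    For each ``t`` and ``G``, the sphere-cylinder (and cylinder-lamella)
    transition is located along the ``Nt*t`` axis; boundary curves
    collect the transition loci.
    """
    boundaries: Dict[int, Dict[str, List[Tuple[float, float]]]] = {}
    for t in t_values:
        nts = sorted({max(int(round(ntt / t)), 1) for ntt in Ntt_values})
        per_t = {"sphere-cylinder": [], "cylinder-lamella": []}
        for G in G_values:
            res = morphology_transitions(G, t, nts, scan_kwargs=scan_kwargs)
            for tr in res["transitions"]:
                if tr["pair"] == "sphere-cylinder":
                    per_t["sphere-cylinder"].append((tr["Nt"] * t, float(G)))
                elif tr["pair"] == "cylinder-lamella":
                    per_t["cylinder-lamella"].append((tr["Nt"] * t, float(G)))
        boundaries[t] = per_t
    return StateDiagram(boundaries)
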