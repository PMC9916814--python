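"""Self-consistent-field engine.

Chain statistics are computed by dynamic programming over the molecule
tree (message passing of end-point distributions between neighbouring
segments) in a layer potential

    u_X(r) = alpha(r) + sum_Y chi_XY (<phi_Y>(r) - phi_Y^b) + nu_X psi(r)

where ``alpha`` is the pressure-like incompressibility field and ``psi``
the dimensionless electrostatic potential of the lattice Poisson
equation.

Amounts: the surfactant is canonical (``theta_surf`` segments in the
cell); water and the two ions are grand-canonical, pinned to an
electroneutral bulk with salt volume fraction ``phi_salt_b``.  The bulk
surfactant fraction follows from the single-molecule partition function,
``phi_surf^b = theta_surf / q``, and the aggregation number is the
excess amount ``n_agg = (theta_surf - V phi_surf^b) / N``.

Solver strategy.  The micellar fixed point is stiff and saddle-like:
plain damped mixing either dissolves the aggregate (the micelle<->bulk
amount-exchange mode) or enters ion/psi limit cycles.  The engine
therefore solves the canonical cell by damped trust-region Newton on
the full potential residual plus ``ln(phi_b)`` as an explicit unknown
(finite-difference Jacobian, Broyden rank-one updates, line search),
seeded with an amount-consistent segregated droplet whose charged rows
are pre-screened by one nonlinear Poisson-Boltzmann solve.  Fallbacks:
alternative seed strengths, a grand-canonical split (fixed-phi_b Newton
alternated with a secant on the amount constraint), and a theta ladder
(nucleate a larger aggregate, walk back down).  A stable slaved-ion
relaxation map is kept as ``method="picard"``.  Warm starts reuse the
previous fields and Jacobian; large theta jumps are walked in small
logarithmic steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve, solve_banded

from . import _kernel
from .lattice import LatticeGeometry, local_average, poisson_solve
from .molecule import ChainGraph
from .segments import InteractionTable, UnitConversions

__all__ = [
    "SystemSpec",
    "SCFState",
    "SCFConvergenceError",
    "update_potentials",
    "propagate",
    "solve_scf",
    "segment_densities",
]

SOLVENT = "W"
CATION = "Na"
ANION = "Cl"

_CLIP = 200.0  # exponent clip for e^{-u}
_LN_EMPTY = -700.0  # log bulk fraction of an absent species


class SCFConvergenceError(RuntimeError):
    """Raised when the SCF iteration does not reach tolerance."""

    def __init__(self, message: str, residual_trace: Optional[np.ndarray] = None,
                 state: Optional["SCFState"] = None):
        super().__init__(message)
        self.residual_trace = residual_trace
        self.state = state


# ---------------------------------------------------------------------------
# system specification
# ---------------------------------------------------------------------------

@dataclass
class SystemSpec:
    """Complete specification of one SCF cell.

    ``theta_surf`` is the total number of surfactant segments in the
    cell; ``external_charge`` is an optional fixed charge profile
    (elementary charges per site) that enters the Poisson equation but
    occupies no volume.
    """

    molecule: ChainGraph
    lattice: LatticeGeometry
    table: InteractionTable
    theta_surf: float = 0.0
    phi_salt_b: float = 0.01
    conversions: UnitConversions = field(default_factory=UnitConversions)
    external_charge: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi_salt_b < 1.0:
            raise ValueError("phi_salt_b must be in [0, 1)")
        if self.theta_surf < 0:
            raise ValueError("theta_surf must be >= 0")
        if self.theta_surf > 0.9 * self.lattice.volume:
            raise ValueError("theta_surf overfills the lattice")
        names = self.table.names
        if SOLVENT not in names:
            raise ValueError(f"interaction table must contain solvent kind {SOLVENT!r}")
        for k in set(self.molecule.kinds):
            if k not in names:
                raise ValueError(f"molecule kind {k!r} missing from interaction table")
        need_ions = self.phi_salt_b > 0 or any(
            self.table.valency(k) != 0 for k in set(self.molecule.kinds))
        if need_ions and (CATION not in names or ANION not in names):
            raise ValueError("charged system requires Na and Cl kinds in the table")
        if self.external_charge is not None:
            ext = np.asarray(self.external_charge, dtype=float)
            if ext.shape != (self.lattice.M,):
                raise ValueError("external_charge must have one value per layer")
            self.external_charge = ext

    @property
    def n_segments(self) -> int:
        return self.molecule.n_segments

    @property
    def molecule_valency(self) -> float:
        return self.molecule.net_valency(self.table)


# ---------------------------------------------------------------------------
# converged state
# ---------------------------------------------------------------------------

@dataclass
class SCFState:
    """Converged (or best-effort) fields and profiles of one SCF cell."""

    spec: SystemSpec
    u: np.ndarray            # (K, M) segment potentials per kind
    phi: np.ndarray          # (K, M) volume fractions per kind
    phi_species: Dict[str, np.ndarray]   # per molecular species
    phi_b: Dict[str, float]  # bulk volume fraction per species
    phi_kind_b: np.ndarray   # (K,) bulk volume fraction per kind
    alpha: np.ndarray        # (M,)
    psi: np.ndarray          # (M,)
    logq_surf: float         # log single-molecule partition function
    logq_spread: float       # composition-law consistency of logq
    residual: float
    iterations: int
    converged: bool
    residual_trace: Optional[np.ndarray] = None
    jacobian: Optional[object] = None    # reusable Newton cache (not serialized)

    # -- derived quantities --------------------------------------------
    @property
    def kinds(self) -> Tuple[str, ...]:
        return self.spec.table.names

    @property
    def M(self) -> int:
        return self.spec.lattice.M

    def phi_sum(self) -> np.ndarray:
        return self.phi.sum(axis=0)

    def charge_profile(self) -> np.ndarray:
        """Net charge per site per layer (including external charge)."""
        q = self.spec.table.valencies @ self.phi
        if self.spec.external_charge is not None:
            q = q + self.spec.external_charge
        return q

    def total_charge(self) -> float:
        """Global excess charge of the cell (elementary charges)."""
        return float(self.spec.lattice.L @ self.charge_profile())

    def theta(self, species: str) -> float:
        return float(self.spec.lattice.L @ self.phi_species[species])

    @property
    def n_agg(self) -> float:
        """Excess surfactant molecules relative to the homogeneous bulk."""
        V = self.spec.lattice.volume
        N = self.spec.n_segments
        return (self.spec.theta_surf - V * self.phi_b["surf"]) / N

    def bulk_deviation(self, n_last: int = 5) -> float:
        """Largest deviation of the outermost layers from bulk composition."""
        dev = 0.0
        for name, prof in self.phi_species.items():
            dev = max(dev, float(np.abs(prof[-n_last:] - self.phi_b[name]).max()))
        dev = max(dev, float(np.abs(self.psi[-n_last:]).max()))
        return dev

    def to_dataframe(self) -> pd.DataFrame:
        """Per-layer table: layer, phi per kind, psi, alpha."""
        data = {"layer": np.arange(1, self.M + 1)}
        for i, name in enumerate(self.kinds):
            data[f"phi_{name}"] = self.phi[i]
        data["psi"] = self.psi
        data["alpha"] = self.alpha
        return pd.DataFrame(data)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# potentials
# ---------------------------------------------------------------------------

def update_potentials(profiles: np.ndarray, table: InteractionTable,
                      psi: np.ndarray, alpha: np.ndarray,
                      lattice: LatticeGeometry,
                      phi_kind_b: Optional[np.ndarray] = None) -> np.ndarray:
    """Segment potentials from profiles, fields and the chi matrix.

    ``u_X(r) = alpha(r) + sum_Y chi_XY (<phi_Y>(r) - phi_Y^b) + nu_X psi(r)``

    ``profiles`` has shape (K, M) in table kind order; ``phi_kind_b``
    defaults to zero bulk fractions.
    """
    phi = np.asarray(profiles, dtype=float)
    K = len(table.names)
    if phi.shape != (K, lattice.M):
        raise ValueError(f"profiles must have shape ({K}, {lattice.M})")
    if phi_kind_b is None:
        phi_kind_b = np.zeros(K)
    avg = np.empty_like(phi)
    for k in range(K):
        avg[k] = local_average(phi[k], lattice, outer=phi_kind_b[k])
    dev = avg - phi_kind_b[:, None]
    u = table.chi_matrix @ dev
    u += table.valencies[:, None] * psi[None, :]
    u += alpha[None, :]
    return u


# ---------------------------------------------------------------------------
# tree propagators
# ---------------------------------------------------------------------------

def _avg(arr: np.ndarray, lat: LatticeGeometry, outer_val: Optional[float]) -> np.ndarray:
    """Local average of one message; mirror inner, fixed-value or mirror outer."""
    out = lat.lam_zero * arr
    out[1:] += lat.lam_minus[1:] * arr[:-1]
    out[0] += lat.lam_minus[0] * arr[0]
    out[:-1] += lat.lam_plus[:-1] * arr[1:]
    out[-1] += lat.lam_plus[-1] * (arr[-1] if outer_val is None else outer_val)
    return out


class _Tree:
    """Flattened propagation order for a molecule tree."""

    def __init__(self, graph: ChainGraph, kind_index: Mapping[str, int]):
        self.n = graph.n_segments
        self.kind_idx = np.array([kind_index[k] for k in graph.kinds], dtype=np.intp)
        self.children: List[List[int]] = [list(c) for c in graph.children]
        self.parents = list(graph.parents)
        # CSR layout for the compiled kernel
        counts = [len(c) for c in self.children]
        self.child_ptr = np.zeros(self.n + 1, dtype=np.int64)
        np.cumsum(counts, out=self.child_ptr[1:])
        self.child_idx = np.array(
            [c for ch in self.children for c in ch], dtype=np.int64)
        # node indices grouped by kind (for density accumulation)
        self.by_kind: Dict[int, np.ndarray] = {}
        for k in sorted(set(self.kind_idx.tolist())):
            self.by_kind[k] = np.where(self.kind_idx == k)[0]


def _propagate_scaled(tree: _Tree, G: np.ndarray, lat: LatticeGeometry,
                      outer: str, node_ext: Optional[np.ndarray] = None
                      ) -> Tuple[np.ndarray, float, float]:
    """Message passing over the tree with per-message log scaling.

    ``node_ext`` is an optional per-node external potential (n, M); its
    Boltzmann factor multiplies the node weights (used to pin the seed
    core during nucleation).

    Returns per-node single-molecule densities (rows normalized so that
    ``sum_r L(r) phi_v(r) = 1``), ``log q`` and the spread of ``log q``
    across nodes (composition-law consistency).
    """
    n, M = tree.n, lat.M
    bulk = outer == "bulk"
    Grows = G[tree.kind_idx]
    if node_ext is not None:
        Grows = Grows * np.exp(-np.clip(node_ext, -_CLIP, _CLIP))
    if not np.all(np.isfinite(Grows)) or np.any(Grows <= 0):
        raise ValueError("propagation weights must be positive and finite")

    if _kernel.HAVE_NUMBA:
        node_phi, logq_v = _kernel.propagate_tree(
            np.ascontiguousarray(Grows), tree.child_ptr, tree.child_idx,
            lat.lam_minus, lat.lam_zero, lat.lam_plus, lat.L, bulk)
        if node_phi.size == 0:
            raise FloatingPointError("propagator underflow/overflow")
        logq = float(logq_v[0])
        spread = float(np.abs(logq_v - logq).max())
        return node_phi, logq, spread

    up_arr = np.empty((n, M))
    up_ln = np.zeros(n)
    pre_arr = np.empty((n, M))   # G_v * prod of children messages (not averaged)
    pre_ln = np.zeros(n)

    for v in range(n - 1, -1, -1):
        prod = Grows[v].copy()
        ln = 0.0
        for c in tree.children[v]:
            prod *= up_arr[c]
            ln += up_ln[c]
        pre_arr[v] = prod
        pre_ln[v] = ln
        outer_val = np.exp(-min(ln, _CLIP)) if bulk else None
        avg = _avg(prod, lat, outer_val)
        s = float(avg.max())
        if not np.isfinite(s) or s <= 0:
            raise FloatingPointError("propagator underflow/overflow")
        up_arr[v] = avg / s
        up_ln[v] = ln + np.log(s)

    down_arr = np.empty((n, M))
    down_ln = np.zeros(n)
    down_arr[0] = 1.0
    for v in range(n):
        ch = tree.children[v]
        if not ch:
            continue
        base = Grows[v] * down_arr[v]
        ln_base = down_ln[v]
        k = len(ch)
        if k == 1:
            raws = [base]
            lns = [ln_base]
        else:
            # prefix/suffix products over sibling messages
            pref = [np.ones(M)]
            pref_ln = [0.0]
            for c in ch[:-1]:
                pref.append(pref[-1] * up_arr[c])
                pref_ln.append(pref_ln[-1] + up_ln[c])
            suff = [np.ones(M)]
            suff_ln = [0.0]
            for c in ch[:0:-1]:
                suff.append(suff[-1] * up_arr[c])
                suff_ln.append(suff_ln[-1] + up_ln[c])
            suff = suff[::-1]
            suff_ln = suff_ln[::-1]
            raws = [base * pref[i] * suff[i] for i in range(k)]
            lns = [ln_base + pref_ln[i] + suff_ln[i] for i in range(k)]
        for i, c in enumerate(ch):
            outer_val = np.exp(-min(lns[i], _CLIP)) if bulk else None
            avg = _avg(raws[i], lat, outer_val)
            s = float(avg.max())
            if not np.isfinite(s) or s <= 0:
                raise FloatingPointError("propagator underflow/overflow")
            down_arr[c] = avg / s
            down_ln[c] = lns[i] + np.log(s)

    raw = pre_arr * down_arr
    ln_v = pre_ln + down_ln
    w = raw @ lat.L
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise FloatingPointError("vanishing partition function")
    logq_v = np.log(w) + ln_v
    logq = float(logq_v[0])
    spread = float(np.abs(logq_v - logq).max())
    node_phi = raw / w[:, None]
    return node_phi, logq, spread


def propagate(graph: ChainGraph, weights: Mapping[str, np.ndarray],
              lattice: LatticeGeometry, outer: str = "bulk"
              ) -> Tuple[np.ndarray, float]:
    """Segment-resolved single-molecule densities and partition function.

    Parameters
    ----------
    graph : ChainGraph
    weights : mapping kind -> array of free-segment weights ``G_X(r) = exp(-u_X(r))``
    lattice : LatticeGeometry
    outer : {"bulk", "mirror"}
        Outer-boundary handling: continuation into a homogeneous bulk
        with unit weights, or a reflecting wall.

    Returns
    -------
    node_phi : ndarray (n_segments, M)
        Per-node densities normalized per molecule
        (``sum_r L(r) node_phi[v, r] = 1``).
    q : float
        Single-molecule partition function (``sum_r L(r)`` for unit
        weights); independent of the segment used to evaluate it.
    """
    if outer not in ("bulk", "mirror"):
        raise ValueError("outer must be 'bulk' or 'mirror'")
    names = sorted(set(graph.kinds))
    kind_index = {k: i for i, k in enumerate(names)}
    G = np.vstack([np.asarray(weights[k], dtype=float) for k in names])
    if G.shape[1] != lattice.M:
        raise ValueError("weight arrays must have length M")
    tree = _Tree(graph, kind_index)
    node_phi, logq, spread = _propagate_scaled(tree, G, lattice, outer)
    return node_phi, float(np.exp(logq))


# ---------------------------------------------------------------------------
# nonlinear Poisson-Boltzmann sub-solve (ions slaved to psi)
# ---------------------------------------------------------------------------

def _pb_solve(q_fix: np.ndarray, a: np.ndarray, b: np.ndarray,
              eps: np.ndarray, lat: LatticeGeometry, coupling: float,
              psi0: np.ndarray) -> np.ndarray:
    """Newton solve of div(eps grad psi) = -C (q_fix + a e^{-psi} - b e^{psi}).

    ``a``/``b`` are the cation/anion prefactors (bulk fraction times the
    Boltzmann factor of the chemical potential part); Dirichlet
    ``psi(M) = 0`` and a zero-field inner boundary.
    """
    M = lat.M
    c = lat.S[1:M] * 0.5 * (eps[:-1] + eps[1:])
    psi = psi0.copy()
    i = np.arange(M - 1)
    for _ in range(200):
        ex = np.clip(psi, -80.0, 80.0)
        expm = np.exp(-ex)
        expp = np.exp(ex)
        rho = q_fix + a * expm - b * expp
        F = np.zeros(M)
        flux = c * (psi[1:] - psi[:-1])
        F[:M - 1] += flux
        F[1:M - 1] -= flux[:M - 2]
        F += coupling * lat.L * rho
        diag = np.zeros(M)
        lower = np.zeros(M)
        upper = np.zeros(M)
        diag[i] -= c[i]
        diag[1:M - 1] -= c[:M - 2]
        upper[i + 1] = c[i]
        lower[i] = c[i]
        diag -= coupling * lat.L * (a * expm + b * expp)
        diag[M - 1] = 1.0
        lower[M - 2] = 0.0
        upper[M - 1] = 0.0
        F[M - 1] = psi[M - 1]
        dpsi = solve_banded((1, 1), np.vstack([upper, diag, lower]), -F)
        psi = psi + np.clip(dpsi, -1.5, 1.5)
        if float(np.abs(dpsi).max()) < 1e-13:
            break
    return psi


# ---------------------------------------------------------------------------
# the SCF model: shared profile assembly and the two iteration maps
# ---------------------------------------------------------------------------

class _Model:
    """Precomputed quantities and the SCF iteration maps.

    The model is *grand-canonical in the surfactant*: the bulk fraction
    ``phi_b_surf`` is a fixed parameter of the maps and the converged
    amount follows as ``theta = phi_b_surf * q``.  Canonical cells
    (requested ``theta_surf``) are handled by an outer secant on
    ``ln phi_b_surf`` in :func:`solve_scf`; this decouples the stiff
    micelle<->bulk amount-exchange mode from the field iteration.
    """

    def __init__(self, spec: SystemSpec):
        self.spec = spec
        self.table = spec.table
        self.lat = spec.lattice
        self.K = len(spec.table.names)
        self.kindex = {k: i for i, k in enumerate(spec.table.names)}
        self.tree = _Tree(spec.molecule, self.kindex)
        self.N = spec.n_segments
        self.z_mol = spec.molecule_valency
        self.chi = spec.table.chi_matrix
        self.nu = spec.table.valencies
        self.eps = spec.table.permittivities
        self.coupling = spec.conversions.coupling
        self.counts = np.zeros(self.K)
        for k in spec.molecule.kinds:
            self.counts[self.kindex[k]] += 1.0
        self.i_w = self.kindex[SOLVENT]
        self.i_na = self.kindex.get(CATION)
        self.i_cl = self.kindex.get(ANION)
        self.has_ions = self.i_na is not None and self.i_cl is not None
        self.charged = self.has_ions and (
            spec.phi_salt_b > 0 or self.z_mol != 0
            or spec.external_charge is not None)
        self.phi_b_surf = 0.0    # fixed surfactant bulk fraction
        self.node_ext: Optional[np.ndarray] = None  # optional seed potential

    # -- bulk composition ----------------------------------------------
    def bulk(self, phi_surf_b: float) -> Dict[str, float]:
        spec = self.spec
        comp = {"surf": phi_surf_b, CATION: 0.0, ANION: 0.0}
        if self.has_ions:
            comp[CATION] = spec.phi_salt_b
            comp[ANION] = spec.phi_salt_b
            # the counterion neutralizes the bulk surfactant charge
            if self.z_mol > 0:
                comp[ANION] += self.z_mol * phi_surf_b / self.N
            elif self.z_mol < 0:
                comp[CATION] += -self.z_mol * phi_surf_b / self.N
        comp[SOLVENT] = 1.0 - comp["surf"] - comp[CATION] - comp[ANION]
        if comp[SOLVENT] <= 0:
            raise ValueError("bulk composition overfilled (no room for solvent)")
        return comp

    def kind_bulk(self, comp: Dict[str, float]) -> np.ndarray:
        out = np.zeros(self.K)
        out += comp["surf"] * self.counts / self.N
        out[self.i_w] += comp[SOLVENT]
        if self.has_ions:
            out[self.i_na] += comp[CATION]
            out[self.i_cl] += comp[ANION]
        return out

    # -- shared assembly -----------------------------------------------
    def _polymer_profiles(self, G: np.ndarray):
        """Surfactant and solvent profiles from the current weights."""
        spec = self.spec
        M = self.lat.M
        phi = np.zeros((self.K, M))
        aux: dict = {}
        phi_b = self.phi_b_surf
        if phi_b > 0:
            node_phi, logq, spread = _propagate_scaled(
                self.tree, G, self.lat, "bulk", self.node_ext)
            expo = np.log(phi_b) + logq
            if expo > 600.0:   # guard against float overflow only
                raise FloatingPointError("surfactant amplitude overflow")
            per_node = np.exp(expo) / self.N
            surf = per_node * node_phi
            np.add.at(phi, self.tree.kind_idx, surf)
            aux["node_phi"] = node_phi
            aux["logq"] = logq
            aux["logq_spread"] = spread
            aux["surf_profile"] = surf.sum(axis=0)
            aux["theta_actual"] = float(phi_b * np.exp(logq))
        else:
            aux["logq"] = float(np.log(self.lat.volume))
            aux["logq_spread"] = 0.0
            aux["surf_profile"] = np.zeros(M)
            aux["theta_actual"] = 0.0
        comp = self.bulk(phi_b)
        phi[self.i_w] += comp[SOLVENT] * G[self.i_w]
        return phi, comp, aux

    def _finish(self, u, phi, comp, psi, aux):
        """Normalized profiles, potentials and the map target."""
        phi_tot = phi.sum(axis=0)
        if np.any(phi_tot <= 0) or not np.all(np.isfinite(phi_tot)):
            raise FloatingPointError("invalid total density")
        phin = phi / phi_tot
        phi_kind_b = self.kind_bulk(comp)
        avg = np.empty_like(phin)
        for k in range(self.K):
            avg[k] = local_average(phin[k], self.lat, outer=phi_kind_b[k])
        E = self.chi @ (avg - phi_kind_b[:, None])
        E += self.nu[:, None] * psi[None, :]
        alpha = (u - E).mean(axis=0) + np.log(phi_tot)
        u_target = E + alpha[None, :]
        aux.update(phi=phi, phi_b=comp, phi_kind_b=phi_kind_b, psi=psi,
                   alpha=alpha, avg=avg,
                   incomp=float(np.abs(phi_tot - 1.0).max()))
        return u_target, aux

    # -- Newton residual map -------------------------------------------
    def step(self, x: np.ndarray) -> Tuple[np.ndarray, dict]:
        """Full SCF map u -> u_target; ions taken from the u iterate.

        The electrostatic potential is the linear Poisson solution of
        the (locally normalized) charge profile, evaluated inside the
        map, so the fixed point satisfies all equations simultaneously.
        """
        u = x.reshape(self.K, self.lat.M)
        G = np.exp(-np.clip(u, -_CLIP, _CLIP))
        phi, comp, aux = self._polymer_profiles(G)
        if self.has_ions:
            phi[self.i_na] += comp[CATION] * G[self.i_na]
            phi[self.i_cl] += comp[ANION] * G[self.i_cl]
        phi_tot = phi.sum(axis=0)
        phin = phi / phi_tot
        if self.charged:
            eps_r = self.eps @ phin
            q_e = self.nu @ phin
            if self.spec.external_charge is not None:
                q_e = q_e + self.spec.external_charge
            psi = poisson_solve(q_e, eps_r, self.lat, coupling=self.coupling)
        else:
            psi = np.zeros(self.lat.M)
        u_target, aux = self._finish(u, phi, comp, psi, aux)
        return u_target.ravel(), aux

    # -- stable relaxation map (nucleation phase) ----------------------
    def step_relax(self, x: np.ndarray, carry: dict) -> Tuple[np.ndarray, dict]:
        """Relaxation map with ions slaved to a Poisson-Boltzmann solve.

        The ion densities are Boltzmann factors of the electrostatic
        potential (solved to self-consistency per iteration) on top of
        a chemical potential part built from lagged slow fields in
        ``carry``; this removes the ion/psi limit cycle of plain
        mixing.  Shares its fixed point with :meth:`step`.
        """
        u = x.reshape(self.K, self.lat.M)
        G = np.exp(-np.clip(u, -_CLIP, _CLIP))
        phi, comp, aux = self._polymer_profiles(G)
        phi_kind_b = self.kind_bulk(comp)
        if self.charged:
            q_poly = self.nu @ phi
            if self.spec.external_charge is not None:
                q_poly = q_poly + self.spec.external_charge
            E_prev = self.chi @ (carry["avg"] - phi_kind_b[:, None])
            w_na = carry["alpha"] + E_prev[self.i_na]
            w_cl = carry["alpha"] + E_prev[self.i_cl]
            a = comp[CATION] * np.exp(-np.clip(w_na, -60.0, 60.0))
            b = comp[ANION] * np.exp(-np.clip(w_cl, -60.0, 60.0))
            eps_prev = self.eps @ carry["avg"] / np.maximum(carry["avg"].sum(0), 1e-12)
            psi = _pb_solve(q_poly, a, b, eps_prev, self.lat, self.coupling,
                            carry["psi"])
            ex = np.clip(psi, -60.0, 60.0)
            phi[self.i_na] += a * np.exp(-ex)
            phi[self.i_cl] += b * np.exp(ex)
        else:
            psi = np.zeros(self.lat.M)
            if self.has_ions:
                phi[self.i_na] += comp[CATION] * G[self.i_na]
                phi[self.i_cl] += comp[ANION] * G[self.i_cl]
        u_target, aux = self._finish(u, phi, comp, psi, aux)
        carry["alpha"] = aux["alpha"]
        carry["avg"] = aux["avg"]
        carry["psi"] = psi
        return u_target.ravel(), aux

    def fresh_carry(self) -> dict:
        M = self.lat.M
        phi_kind_b = self.kind_bulk(self.bulk(0.0))
        return {"alpha": np.zeros(M), "psi": np.zeros(M),
                "avg": np.tile(phi_kind_b[:, None], (1, M))}


def _initial_guess(model: _Model) -> Tuple[np.ndarray, float]:
    """Strongly segregated seed fields and the seed core radius."""
    spec, lat = model.spec, model.lat
    M = lat.M
    tail_segments = sum(spec.molecule.is_tail)
    if tail_segments == 0:
        tail_segments = spec.molecule.kind_count("C")
    theta_tail = spec.theta_surf * tail_segments / max(model.N, 1)
    if lat.geometry == "spherical":
        R0 = (3.0 * theta_tail / (4.0 * np.pi)) ** (1.0 / 3.0)
    elif lat.geometry == "cylindrical":
        R0 = np.sqrt(theta_tail / np.pi)
    else:
        R0 = theta_tail
    u = np.zeros((model.K, M))
    core = lat.r_centers < R0
    if core.any() and "C" in model.kindex:
        u[:, core] = 2.0
        u[model.kindex["C"], core] = -2.0
    return u, R0


class _NewtonCache:
    """Finite-difference Jacobian with rank-one (Broyden) updates."""

    def __init__(self):
        self.J: Optional[np.ndarray] = None
        self.lu = None
        self.age = 0

    def build(self, fun, x: np.ndarray, g0: np.ndarray, h: float = 1e-6) -> None:
        """Forward-difference Jacobian of the map ``g``; ``g0 = g(x)``."""
        n = x.size
        J = np.empty((n, n))
        for j in range(n):
            xp = x.copy()
            xp[j] += h
            J[:, j] = (fun(xp) - g0) / h
        self.J = J
        self._factor()
        self.age = 0

    def _factor(self) -> None:
        A = self.J - np.eye(self.J.shape[0])  # d(residual)/dx, residual = g(x)-x
        try:
            self.lu = lu_factor(A)
        except Exception:
            self.lu = None

    def update(self, dx: np.ndarray, dg: np.ndarray) -> None:
        denom = float(dx @ dx)
        if denom <= 0 or self.J is None:
            return
        self.J += np.outer(dg - self.J @ dx, dx) / denom
        self._factor()
        self.age += 1

    def solve(self, f: np.ndarray) -> Optional[np.ndarray]:
        if self.lu is None:
            return None
        try:
            dx = lu_solve(self.lu, -f)
        except Exception:
            return None
        if not np.all(np.isfinite(dx)):
            return None
        return dx

    def solve_lm(self, f: np.ndarray, lam: float) -> Optional[np.ndarray]:
        """Levenberg-Marquardt step on the residual (a descent direction
        of ||f||^2 for accurate J and large enough lam)."""
        if self.J is None:
            return None
        A = self.J - np.eye(self.J.shape[0])
        H = A.T @ A + lam * np.eye(A.shape[0])
        try:
            dx = np.linalg.solve(H, -A.T @ f)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(dx)):
            return None
        return dx


class _Canonical:
    """Canonical residual map: state ``x = [u.ravel(), ln(phi_b)]``.

    Wraps the grand-canonical field map of :class:`_Model` and appends
    the amount constraint ``ln phi_b = ln theta_req - ln q`` as one more
    fixed-point coordinate, so the Newton iteration resolves the stiff
    micelle<->bulk exchange mode explicitly.
    """

    def __init__(self, model: _Model, theta_req: float):
        self.model = model
        self.theta_req = theta_req
        self.size = model.K * model.lat.M + (1 if theta_req > 0 else 0)

    def step(self, x: np.ndarray) -> Tuple[np.ndarray, dict]:
        if self.theta_req <= 0:
            self.model.phi_b_surf = 0.0
            return self.model.step(x)
        self.model.phi_b_surf = float(np.exp(min(x[-1], np.log(0.5))))
        u_t, aux = self.model.step(x[:-1])
        s_t = float(np.log(self.theta_req) - aux["logq"])
        return np.concatenate([u_t, [s_t]]), aux


class _GCWrap:
    """Fixed-bulk-fraction (grand-canonical) residual map over u only."""

    def __init__(self, model: _Model):
        self.model = model
        self.theta_req = 0.0   # amount handled outside

    def step(self, x: np.ndarray) -> Tuple[np.ndarray, dict]:
        return self.model.step(x)


class _Solver:
    """Damped trust-region Newton driver for the canonical residual."""

    def __init__(self, can: _Canonical, tol: float, keep_trace: bool):
        self.can = can
        self.tol = tol
        self.trace: List[float] = []
        self.keep_trace = keep_trace
        self.evals = 0
        self.cache = _NewtonCache()

    def g_of(self, x: np.ndarray) -> np.ndarray:
        self.evals += 1
        x_t, _ = self.can.step(x)
        return x_t

    def f_of(self, x: np.ndarray) -> Tuple[np.ndarray, dict, float]:
        self.evals += 1
        x_t, aux = self.can.step(x)
        f = x_t - x
        res = max(float(np.abs(f).max()), aux["incomp"])
        if self.keep_trace:
            self.trace.append(res)
        return f, aux, res

    def newton(self, x: np.ndarray, target: Optional[float] = None, *,
               max_steps: int = 600, stale: int = 20, cap: float = 3.0
               ) -> Tuple[np.ndarray, float, bool, Optional[dict]]:
        """Newton with FD Jacobian, Broyden updates, line search and a
        per-component trust-region cap on the step."""
        target = self.tol if target is None else target
        cache = self.cache
        try:
            f, aux, res = self.f_of(x)
        except (FloatingPointError, ValueError):
            return x, np.inf, False, None
        fn = float(np.linalg.norm(f))
        noprog = 0
        for _ in range(max_steps):
            if res < target:
                return x, res, True, aux
            if cache.J is None or cache.J.shape[0] != x.size or cache.age > stale:
                cache.build(self.g_of, x, f + x)
            dx = cache.solve(f)
            if dx is None:
                cache.build(self.g_of, x, f + x)
                dx = cache.solve(f)
                if dx is None:
                    return x, res, False, aux
            dmax = float(np.abs(dx).max())
            if dmax > cap:
                dx = dx * (cap / dmax)
            if self.can.theta_req > 0 and abs(dx[-1]) > 0.8:
                # the bulk-amount coordinate moves slowly: it controls the
                # micelle<->bulk exchange and large jumps change branch
                dx = dx * (0.8 / abs(dx[-1]))
            moved = False
            for t in (1.0, 0.5, 0.2, 0.05, 0.01, 0.002):
                xn = x + t * dx
                try:
                    f2, aux2, res2 = self.f_of(xn)
                except (FloatingPointError, ValueError):
                    continue
                fn2 = float(np.linalg.norm(f2))
                if fn2 < fn * (1.0 - 1e-4 * t) or fn2 < 1e-13:
                    cache.update(xn - x, (f2 + xn) - (f + x))
                    x, f, fn, aux, res = xn, f2, fn2, aux2, res2
                    moved = True
                    break
            if not moved:
                if cache.age > 0:
                    cache.build(self.g_of, x, f + x)
                    continue
                noprog += 1
                if noprog > 2:
                    return x, res, False, aux
                cap *= 0.3
            else:
                noprog = 0
        return x, res, res < target, aux

    def relax(self, x: np.ndarray, target: float, budget: int,
              mixing: float = 0.05) -> np.ndarray:
        """Stable slaved-ion relaxation with instant canonical amount.

        Kept as a fallback and for ``method='picard'``; note that this
        dynamics can dissolve metastable aggregates.
        """
        model = self.can.model
        theta_req = self.can.theta_req
        carry = model.fresh_carry()
        has_amount = theta_req > 0
        for _ in range(budget):
            if has_amount:
                model.phi_b_surf = float(np.exp(min(x[-1], np.log(0.5))))
                u = x[:-1]
            else:
                model.phi_b_surf = 0.0
                u = x
            try:
                u_t, aux = model.step_relax(u, carry)
            except (FloatingPointError, ValueError):
                break
            self.evals += 1
            if has_amount:
                s_t = float(np.log(theta_req) - aux["logq"])
                x_t = np.concatenate([u_t, [s_t]])
            else:
                x_t = u_t
            f = x_t - x
            res = max(float(np.abs(f).max()), aux["incomp"])
            if self.keep_trace:
                self.trace.append(res)
            if res < target:
                break
            x = x + mixing * np.clip(f, -1.0, 1.0)
            if has_amount:
                x[-1] = x_t[-1]    # amount responds instantly
        return x


def _seed_vector(model: _Model, theta_req: float, scale: float = 1.0) -> np.ndarray:
    """Amount-consistent, pre-screened cold-start vector.

    The segregated hydrophobe seed is complemented by one nonlinear
    Poisson-Boltzmann solve of the seeded polymer charge; the resulting
    potential is imprinted on the charged rows so that the first Newton
    evaluation does not see an unscreened macroion.
    """
    u, R0 = _initial_guess(model)
    if scale != 1.0:
        u = u * scale
    G = np.exp(-np.clip(u, -_CLIP, _CLIP))
    _, logq, _ = _propagate_scaled(model.tree, G, model.lat, "bulk")
    s0 = float(np.log(max(theta_req, 1e-300)) - logq)
    if model.charged:
        model.phi_b_surf = float(np.exp(min(s0, np.log(0.5))))
        try:
            node_phi, _, _ = _propagate_scaled(model.tree, G, model.lat, "bulk")
            phi = np.zeros((model.K, model.lat.M))
            per_node = np.exp(min(s0 + logq, 600.0)) / model.N
            np.add.at(phi, model.tree.kind_idx, per_node * node_phi)
            q_poly = model.nu @ phi
            if model.spec.external_charge is not None:
                q_poly = q_poly + model.spec.external_charge
            comp = model.bulk(model.phi_b_surf)
            a = np.full(model.lat.M, comp[CATION])
            b = np.full(model.lat.M, comp[ANION])
            psi0 = _pb_solve(q_poly, a, b, np.full(model.lat.M, 80.0),
                             model.lat, model.coupling, np.zeros(model.lat.M))
            u += model.nu[:, None] * psi0[None, :]
        except (FloatingPointError, ValueError):
            pass
    return np.concatenate([u.ravel(), [s0]])


def _amount_secant(model: _Model, theta_req: float, x_can: np.ndarray,
                   tol: float, max_outer: int = 60
                   ) -> Tuple[np.ndarray, float, bool, Optional[dict]]:
    """Split solve: Newton on the fields at fixed bulk fraction, secant
    on ``ln phi_b`` to match the amount.

    Robust when the canonical Newton stalls in the stiff amount
    direction (the single-molecule partition function responds
    exponentially to the fields).
    """
    gc = _GCWrap(model)
    sol = _Solver(gc, tol, False)
    u = x_can[:-1].copy()
    s_val = float(x_can[-1])
    history: List[Tuple[float, float]] = []
    aux = None
    res = np.inf
    for _ in range(max_outer):
        model.phi_b_surf = float(np.exp(min(s_val, np.log(0.5))))
        u, res, ok_u, aux = sol.newton(u, max_steps=120)
        if not ok_u or aux is None:
            return x_can, np.inf, False, None
        h = float(s_val + aux["logq"] - np.log(theta_req))  # ln(theta_act/theta_req)
        if abs(h) < 1e-11:
            x = np.concatenate([u, [s_val]])
            return x, res, True, aux
        history.append((s_val, h))
        if len(history) >= 2 and history[-1][1] != history[-2][1]:
            (s0, h0), (s1, h1) = history[-2], history[-1]
            step = -h1 * (s1 - s0) / (h1 - h0)
        else:
            step = -h
        s_val = s_val + float(np.clip(step, -0.75, 0.75))
    return x_can, np.inf, False, None


def solve_scf(spec: SystemSpec, init: Optional[np.ndarray | SCFState] = None, *,
              tol: float = 1e-7, max_iter: int = 100000,
              method: str = "newton", mixing: float = 0.05,
              raise_on_fail: bool = True, keep_trace: bool = False,
              jacobian: Optional[_NewtonCache] = None,
              fallbacks: bool = True, newton_steps: int = 600,
              _ladder_depth: int = 0) -> SCFState:
    """Solve the SCF equations for one canonical cell.

    The state vector is the full set of segment potentials plus the log
    bulk surfactant fraction; the amount constraint ``phi_b q = theta``
    is one of the residual equations.  A damped finite-difference
    Newton iteration (Broyden updates, line search, trust-region step
    cap) converges it; cold starts are seeded with a segregated
    hydrophobe droplet, and if the target cell resists nucleation the
    solver climbs a theta ladder (larger aggregates first) and walks
    back down with warm starts.

    Parameters
    ----------
    spec : SystemSpec
    init : optional
        A previous :class:`SCFState` (warm start) or a (K, M) potential
        array.
    tol : float
        Convergence tolerance on the maximum absolute residual (also
        bounds ``|sum_X phi_X - 1|``).
    method : {"newton", "picard"}
        Newton (default) or the plain relaxation map (stable but can
        dissolve metastable aggregates; mainly for homogeneous cells).
    jacobian :
        Optional Newton cache from a previous solve at nearby
        parameters (reused and updated in place).

    Raises
    ------
    SCFConvergenceError
        If the residual does not reach ``tol`` (unless
        ``raise_on_fail=False``; then the best state is returned with
        ``converged=False``).
    """
    model = _Model(spec)
    K, M = model.K, spec.lattice.M
    theta_req = spec.theta_surf
    can = _Canonical(model, theta_req)
    solver = _Solver(can, tol, keep_trace)
    warm = isinstance(init, SCFState)
    if jacobian is not None:
        solver.cache = jacobian
    elif warm and isinstance(init.jacobian, _NewtonCache):
        solver.cache = init.jacobian
    if warm:
        u0 = init.u.ravel().copy()
        if theta_req > 0:
            pb = max(init.phi_b.get("surf", 0.0), 1e-300)
            x = np.concatenate([u0, [np.log(pb)]])
        else:
            x = u0
    elif init is not None:
        u0 = np.asarray(init, dtype=float).ravel()
        if u0.size != K * M:
            raise ValueError(f"init must have shape ({K}, {M})")
        if theta_req > 0:
            G = np.exp(-np.clip(u0.reshape(K, M), -_CLIP, _CLIP))
            _, logq, _ = _propagate_scaled(model.tree, G, spec.lattice, "bulk")
            x = np.concatenate([u0, [np.log(theta_req) - logq]])
        else:
            x = u0
    else:
        x = (_seed_vector(model, theta_req) if theta_req > 0
             else np.zeros(K * M))

    if method == "picard":
        x = solver.relax(x, tol, max_iter, mixing)
        f, aux, res = solver.f_of(x)
        ok = res < tol
        return _finish_state(spec, model, solver, x, aux, res, ok,
                             raise_on_fail)

    if (warm and theta_req > 0 and init.spec.theta_surf > 0
            and abs(np.log(theta_req / init.spec.theta_surf)) > 0.12):
        # walk theta in small log steps: the micellar branch is strongly
        # curved in the amount direction and long jumps defeat Newton
        s_from = np.log(init.spec.theta_surf)
        s_to = np.log(theta_req)
        n_steps = int(np.ceil(abs(s_to - s_from) / 0.1))
        ok = True
        aux = None
        for s_i in np.linspace(s_from, s_to, n_steps + 1)[1:]:
            can.theta_req = float(np.exp(s_i))
            x, res, ok, aux = solver.newton(x, max_steps=newton_steps)
            if not ok:
                break
        can.theta_req = theta_req
        if ok:
            x, res, ok, aux = solver.newton(x, max_steps=newton_steps)
    else:
        x, res, ok, aux = solver.newton(x, max_steps=newton_steps)
    if not ok and theta_req > 0:
        x2, res2, ok2, aux2 = _amount_secant(model, theta_req, x, tol)
        if ok2:
            x, res, ok, aux = x2, res2, ok2, aux2
    if not ok and fallbacks and not warm and init is None and theta_req > 0:
        # alternative seed strengths
        for scale in (0.6, 1.5):
            solver.cache = _NewtonCache()
            x2 = _seed_vector(model, theta_req, scale)
            x2, res2, ok, aux2 = solver.newton(x2, max_steps=newton_steps)
            if ok:
                x, res, aux = x2, res2, aux2
                break
        if not ok:
            for scale in (0.5, 1.5):
                x2 = _seed_vector(model, theta_req, scale)
                x2, res2, ok, aux2 = _amount_secant(model, theta_req, x2, tol)
                if ok:
                    x, res, aux = x2, res2, aux2
                    break
        if not ok and _ladder_depth < 2:
            # theta ladder: nucleate a larger aggregate, walk back down
            try:
                spec_hi = SystemSpec(
                    molecule=spec.molecule, lattice=spec.lattice,
                    table=spec.table, theta_surf=min(1.6 * theta_req,
                                                     0.9 * spec.lattice.volume),
                    phi_salt_b=spec.phi_salt_b, conversions=spec.conversions,
                    external_charge=spec.external_charge)
                hi = solve_scf(spec_hi, tol=tol, method=method,
                               raise_on_fail=False, _ladder_depth=_ladder_depth + 1)
                if hi.converged:
                    solver.cache = (hi.jacobian if isinstance(hi.jacobian,
                                                              _NewtonCache)
                                    else _NewtonCache())
                    pb = max(hi.phi_b.get("surf", 0.0), 1e-300)
                    x2 = np.concatenate([hi.u.ravel(), [np.log(pb)]])
                    x2, res2, ok, aux2 = solver.newton(x2, max_steps=newton_steps)
                    if ok:
                        x, res, aux = x2, res2, aux2
            except (SCFConvergenceError, ValueError):
                pass
    if aux is None:
        try:
            f, aux, res = solver.f_of(x)
        except (FloatingPointError, ValueError):
            raise SCFConvergenceError("SCF evaluation failed at the final state")
    return _finish_state(spec, model, solver, x, aux, res, ok, raise_on_fail)


def _finish_state(spec: SystemSpec, model: _Model, solver: _Solver,
                  x: np.ndarray, aux: dict, res: float, ok: bool,
                  raise_on_fail: bool) -> SCFState:
    K, M = model.K, spec.lattice.M
    converged = bool(ok and res < solver.tol)
    u_final = (x[:-1] if spec.theta_surf > 0 else x).reshape(K, M)
    G = np.exp(-np.clip(u_final, -_CLIP, _CLIP))
    phi_species = {"surf": aux["surf_profile"]}
    phi_species[SOLVENT] = aux["phi_b"][SOLVENT] * G[model.i_w]
    if model.has_ions:
        phi_species[CATION] = aux["phi"][model.i_na].copy()
        phi_species[ANION] = aux["phi"][model.i_cl].copy()
    else:
        phi_species[CATION] = np.zeros(M)
        phi_species[ANION] = np.zeros(M)

    state = SCFState(
        spec=spec,
        u=u_final,
        phi=aux["phi"],
        phi_species=phi_species,
        phi_b=aux["phi_b"],
        phi_kind_b=aux["phi_kind_b"],
        alpha=aux["alpha"],
        psi=aux["psi"],
        logq_surf=aux["logq"],
        logq_spread=aux["logq_spread"],
        residual=res,
        iterations=solver.evals,
        converged=converged,
        residual_trace=np.array(solver.trace) if solver.keep_trace else None,
        jacobian=solver.cache,
    )
    if not converged:
        if raise_on_fail:
            raise SCFConvergenceError(
                f"SCF did not converge ({solver.evals} evaluations, "
                f"residual {res:.3e})",
                residual_trace=(np.array(solver.trace) if solver.keep_trace
                                else None),
                state=state)
        return state
    if state.bulk_deviation() > 1e-8:
        warnings.warn(
            f"outer layers deviate from bulk by {state.bulk_deviation():.2e}; "
            "the lattice may be too small", stacklevel=2)
    return state


def segment_densities(state: SCFState) -> Tuple[np.ndarray, float]:
    """Node-resolved absolute density profiles of the converged surfactant.

    Returns an (n_segments, M) array of per-node volume fractions (the
    kind profiles are their sums by kind) and the per-node bulk value
    ``phi_surf^b / N``.
    """
    model = _Model(state.spec)
    G = np.exp(-np.clip(state.u, -_CLIP, _CLIP))
    node_phi, _, _ = _propagate_scaled(model.tree, G, state.spec.lattice, "bulk")
    per_node = state.spec.theta_surf / state.spec.n_segments
    return per_node * node_phi, state.phi_b["surf"] / state.spec.n_segments
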