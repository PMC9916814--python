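"""Structural and electrostatic micelle characteristics.

All radii are second-moment radii: the square root of the
volume-weighted mean of ``r^2`` over the relevant *excess* profile
(excess over the homogeneous bulk), evaluated with exact per-layer
moments of the volume element so that a sharp step profile of radius R
gives exactly ``sqrt(3/5) R`` in spherical geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .engine import SCFState, segment_densities
from .molecule import ChainGraph, contour_classes
from .segments import UnitConversions
from .units import convert_units

__all__ = [
    "MicelleMetrics",
    "ChargeAnalysis",
    "StratificationReport",
    "core_metrics",
    "charge_analysis",
    "stratification_report",
    "local_maxima",
]


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def local_maxima(y: np.ndarray, min_frac: float = 0.01,
                 mask_frac: Optional[float] = None) -> List[int]:
    """Indices of strict local maxima with plateau handling.

    A plateau flanked by lower values counts as a single maximum at its
    midpoint.  Peaks below ``min_frac`` of the global maximum are
    ignored.  With ``mask_frac``, layers below ``mask_frac`` of the peak
    are excluded before detection (used by the stratification analysis).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n == 0:
        return []
    gmax = float(y.max())
    active = np.ones(n, dtype=bool)
    if mask_frac is not None and gmax > 0:
        active = y >= mask_frac * gmax
    out: List[int] = []
    i = 0
    while i < n:
        if not active[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and active[j + 1] and y[j + 1] == y[i]:
            j += 1
        left_lower = (i == 0) or (not active[i - 1]) or (y[i - 1] < y[i])
        right_lower = (j == n - 1) or (not active[j + 1]) or (y[j + 1] < y[i])
        if left_lower and right_lower:
            if not (gmax > 0 and y[i] < min_frac * gmax):
                out.append((i + j) // 2)
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# structural metrics
# ---------------------------------------------------------------------------

@dataclass
class MicelleMetrics:
    """Core/corona structure of one equilibrium micelle."""

    Rcore: float          # lattice units
    Rm: float             # second moment of the terminal distribution
    Hshell: float         # Rm - Rcore
    s: float              # core surface area per dendron
    Nterm: float          # terminal charged groups in the micelle
    n_agg: float
    Rcore_nm: float
    Hshell_nm: float
    nt: np.ndarray        # terminal number distribution per layer
    tail_profile: np.ndarray
    terminal_profile: np.ndarray

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("Rcore", "Rm", "Hshell", "s", "Nterm", "n_agg",
                 "Rcore_nm", "Hshell_nm")}


def _second_moment_radius(excess: np.ndarray, lat) -> float:
    w = lat.L * excess
    tot = float(w.sum())
    if tot <= 0:
        raise ValueError("no excess density to take a moment of")
    return float(np.sqrt((w @ lat.r2_weight()) / tot))


def core_metrics(state: SCFState, molecule: Optional[ChainGraph] = None,
                 thermo=None) -> MicelleMetrics:
    """Structural micelle metrics from a converged equilibrium state.

    ``Rcore`` is the second-moment radius of the excess hydrophobic-tail
    profile, ``Rm`` the same for terminal groups, ``Hshell = Rm -
    Rcore`` and ``s`` the core surface area per aggregated molecule.
    """
    mol = molecule if molecule is not None else state.spec.molecule
    lat = state.spec.lattice
    node_phi, node_bulk = segment_densities(state)

    tail_idx = mol.tail_indices()
    if not tail_idx:
        tail_idx = [i for i, k in enumerate(mol.kinds) if k == "C"]
    term_idx = mol.terminal_indices()
    tail = node_phi[tail_idx].sum(axis=0)
    term = node_phi[term_idx].sum(axis=0)
    tail_exc = tail - len(tail_idx) * node_bulk
    term_exc = term - len(term_idx) * node_bulk
    if float((lat.L * tail_exc).sum()) <= 1e-6:
        raise ValueError("no hydrophobe excess: the cell holds no micelle")

    Rcore = _second_moment_radius(tail_exc, lat)
    Rm = _second_moment_radius(term_exc, lat)
    n_agg = state.n_agg
    if lat.geometry == "spherical":
        area = 4.0 * np.pi * Rcore**2
    elif lat.geometry == "cylindrical":
        area = 2.0 * np.pi * Rcore
    else:
        area = 1.0
    nt = lat.L * term_exc
    conv = state.spec.conversions
    return MicelleMetrics(
        Rcore=Rcore,
        Rm=Rm,
        Hshell=Rm - Rcore,
        s=area / n_agg,
        Nterm=float(nt.sum()),
        n_agg=n_agg,
        Rcore_nm=convert_units(Rcore, "length", conv),
        Hshell_nm=convert_units(Rm - Rcore, "length", conv),
        nt=nt,
        tail_profile=tail,
        terminal_profile=term,
    )


# ---------------------------------------------------------------------------
# charge analysis
# ---------------------------------------------------------------------------

@dataclass
class ChargeAnalysis:
    """Shell-resolved and cumulative charge of the micelle."""

    q: np.ndarray         # excess charge per layer (shell-integrated)
    Q: np.ndarray         # cumulative charge
    Reff: float           # location of the right maximum of Q
    Qeff: float           # Q(Reff)
    Qbare: float          # total terminal charge
    zeta: float           # psi(Reff) in volts
    n_maxima: int
    psi_at_reff: float    # dimensionless

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("Reff", "Qeff", "Qbare", "zeta", "n_maxima")}


def charge_analysis(state: SCFState,
                    conversions: Optional[UnitConversions] = None) -> ChargeAnalysis:
    """Charge distribution q(r), cumulative charge Q(r), Reff, Qeff, zeta.

    ``q(r)`` is the shell-integrated excess net charge (terminal groups
    plus co-ions minus counterions, bulk offset subtracted), ``Q(r)``
    its running sum.  The rightmost local maximum of ``Q`` defines the
    effective radius; the zeta potential is the electrostatic potential
    there, converted to volts.
    """
    lat = state.spec.lattice
    conv = conversions or state.spec.conversions
    rho = state.charge_profile()
    rho_b = float(state.spec.table.valencies @ state.phi_kind_b)
    q = lat.L * (rho - rho_b)
    Q = np.cumsum(q)
    if abs(Q[-1]) > 1e-6:
        raise ValueError(
            f"state is not globally neutral (residual charge {Q[-1]:.2e})")
    peaks = local_maxima(Q, min_frac=0.01)
    if not peaks:
        raise ValueError("cumulative charge has no maximum")
    i_eff = peaks[-1]
    reff = float(lat.r_centers[i_eff])
    mol = state.spec.molecule
    n_term = len(mol.terminal_indices())
    qbare = state.n_agg * n_term
    psi_eff = float(state.psi[i_eff])
    return ChargeAnalysis(
        q=q,
        Q=Q,
        Reff=reff,
        Qeff=float(Q[i_eff]),
        Qbare=qbare,
        zeta=convert_units(psi_eff, "potential", conv),
        n_maxima=len(peaks),
        psi_at_reff=psi_eff,
    )


# ---------------------------------------------------------------------------
# corona stratification
# ---------------------------------------------------------------------------

@dataclass
class StratificationReport:
    """Radial stratification diagnostics of the dendron corona."""

    nt_total: np.ndarray
    nt_by_contour: Dict[int, np.ndarray]
    branch_points_by_subgen: Dict[int, np.ndarray]
    segments_by_subgen: Dict[int, np.ndarray]
    n_maxima_total: int
    maxima_by_contour: Dict[int, int]
    bimodal: bool
    bimodal_by_contour: Dict[int, bool]
    split_radius: Optional[float]

    def summary(self) -> dict:
        return {
            "bimodal": self.bimodal,
            "n_maxima_total": self.n_maxima_total,
            "split_radius": self.split_radius,
            "maxima_by_contour": dict(self.maxima_by_contour),
        }


def stratification_report(state: SCFState,
                          molecule: Optional[ChainGraph] = None) -> StratificationReport:
    """Group corona distributions by contour length and subgeneration.

    Terminal-group number distributions are resolved per root-to-leaf
    contour class; branch points and all dendron segments are resolved
    per subgeneration.  A distribution is bimodal when it has at least
    two strict local maxima after excluding layers below 1e-8 of its
    peak.
    """
    mol = molecule if molecule is not None else state.spec.molecule
    lat = state.spec.lattice
    node_phi, node_bulk = segment_densities(state)

    def number_profile(indices) -> np.ndarray:
        if len(indices) == 0:
            return np.zeros(lat.M)
        prof = node_phi[list(indices)].sum(axis=0) - len(indices) * node_bulk
        return lat.L * prof

    classes = contour_classes(mol)
    by_contour: Dict[int, List[int]] = {}
    for idx, length in classes.items():
        by_contour.setdefault(length, []).append(idx)
    nt_by_contour = {L: number_profile(idx) for L, idx in sorted(by_contour.items())}
    nt_total = number_profile(list(classes.keys()))

    bp_by_subgen: Dict[int, np.ndarray] = {}
    seg_by_subgen: Dict[int, np.ndarray] = {}
    for g in sorted(set(s for s in mol.subgeneration if s >= 0)):
        bp = [i for i in mol.branch_point_indices() if mol.subgeneration[i] == g]
        seg = [i for i in range(mol.n_segments)
               if mol.subgeneration[i] == g and not mol.is_tail[i]]
        bp_by_subgen[g] = number_profile(bp)
        seg_by_subgen[g] = number_profile(seg)

    def count_max(y: np.ndarray) -> int:
        return len(local_maxima(y, min_frac=0.0, mask_frac=1e-8))

    n_max_total = count_max(nt_total)
    max_by_contour = {L: count_max(p) for L, p in nt_by_contour.items()}
    bimodal = n_max_total >= 2
    split = None
    if bimodal:
        peaks = local_maxima(nt_total, min_frac=0.0, mask_frac=1e-8)
        i1, i2 = sorted(np.argsort([nt_total[p] for p in peaks])[-2:])
        a, b = sorted((peaks[i1], peaks[i2]))
        split = float(lat.r_centers[a + int(np.argmin(nt_total[a:b + 1]))])
    return StratificationReport(
        nt_total=nt_total,
        nt_by_contour=nt_by_contour,
        branch_points_by_subgen=bp_by_subgen,
        segments_by_subgen=seg_by_subgen,
        n_maxima_total=n_max_total,
        maxima_by_contour=max_by_contour,
        bimodal=bimodal,
        bimodal_by_contour={L: c >= 2 for L, c in max_by_contour.items()},
        split_radius=split,
    )
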