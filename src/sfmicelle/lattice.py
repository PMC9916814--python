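"""One-dimensional lattices in planar, cylindrical and spherical geometry.

Layers are numbered ``r = 1..M``.  ``L(r)`` is the number of lattice
sites in layer ``r`` (the dimensionless layer volume), ``S(r)`` the
contact area between layers ``r`` and ``r+1``.  Step probabilities
follow the simple-cubic convention (``lambda = 1/6`` towards each
neighbouring layer in the planar limit) with curvature corrections
derived from the contact areas,

    lambda_plus(r)  = (1/6) S(r) / L(r)
    lambda_minus(r) = (1/6) S(r-1) / L(r)

which satisfy the flux balance ``L(r) lambda_plus(r) =
L(r+1) lambda_minus(r+1)`` by construction.  The inner boundary is
reflecting (``S(0) = 0`` for curved geometries, mirror for planar), the
outer boundary is attached to the homogeneous bulk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import solve_banded

from .segments import UnitConversions

__all__ = ["LatticeGeometry", "make_lattice", "local_average", "poisson_solve"]

GEOMETRIES = ("planar", "cylindrical", "spherical")


@dataclass(frozen=True)
class LatticeGeometry:
    """A 1D lattice: geometry label, layer volumes and step probabilities.

    Arrays are 0-indexed: index ``i`` holds layer ``r = i + 1``.
    ``S`` has length ``M + 1`` and ``S[i]`` is the contact area between
    layers ``i`` and ``i + 1`` (``S[0]`` is the inner boundary area).
    """

    geometry: str
    M: int
    L: np.ndarray
    S: np.ndarray
    lam_minus: np.ndarray
    lam_zero: np.ndarray
    lam_plus: np.ndarray

    @property
    def volume(self) -> float:
        """Total number of lattice sites."""
        return float(self.L.sum())

    @property
    def r_centers(self) -> np.ndarray:
        """Nominal layer centers ``r - 1/2``."""
        return np.arange(1, self.M + 1, dtype=float) - 0.5

    def r2_weight(self) -> np.ndarray:
        """Exact mean of ``r^2`` over each layer's volume element.

        Used by second-moment radii so that moments of stepwise
        profiles match their continuum values exactly.
        """
        r = np.arange(1, self.M + 1, dtype=float)
        rm = r - 1.0
        if self.geometry == "spherical":
            return 0.6 * (r**5 - rm**5) / (r**3 - rm**3)
        if self.geometry == "cylindrical":
            return 0.5 * (r**4 - rm**4) / (r**2 - rm**2)
        return (r**3 - rm**3) / 3.0

    def validate(self) -> None:
        lam_sum = self.lam_minus + self.lam_zero + self.lam_plus
        if not np.allclose(lam_sum, 1.0, atol=1e-12):
            raise ValueError("step probabilities do not sum to 1")
        flux = self.L[:-1] * self.lam_plus[:-1] - self.L[1:] * self.lam_minus[1:]
        if not np.allclose(flux, 0.0, atol=1e-10):
            raise ValueError("flux balance violated")
        if np.any(self.L <= 0):
            raise ValueError("layer volumes must be positive")


def make_lattice(geometry: str, M: int) -> LatticeGeometry:
    """Create a lattice of ``M`` layers in the requested geometry."""
    if geometry not in GEOMETRIES:
        raise ValueError(f"geometry must be one of {GEOMETRIES}, got {geometry!r}")
    if M < 3:
        raise ValueError(f"need at least 3 layers, got {M}")
    r = np.arange(0, M + 1, dtype=float)  # layer boundaries 0..M
    if geometry == "planar":
        L = np.ones(M)
        S = np.ones(M + 1)
        S[0] = 0.0  # reflecting inner boundary
    elif geometry == "cylindrical":
        L = np.pi * (r[1:] ** 2 - r[:-1] ** 2)
        S = 2.0 * np.pi * r
    else:
        L = (4.0 * np.pi / 3.0) * (r[1:] ** 3 - r[:-1] ** 3)
        S = 4.0 * np.pi * r**2
    lam_plus = (S[1:] / L) / 6.0
    lam_minus = (S[:-1] / L) / 6.0
    if geometry == "planar":
        # planar convention: r-independent lambdas, mirror handled by
        # boundary folding in local_average
        lam_minus = np.full(M, 1.0 / 6.0)
        lam_plus = np.full(M, 1.0 / 6.0)
    lam_zero = 1.0 - lam_plus - lam_minus
    lat = LatticeGeometry(geometry, M, L, S, lam_minus, lam_zero, lam_plus)
    lat.validate()
    return lat


def local_average(profile: np.ndarray, lattice: LatticeGeometry,
                  outer: Optional[float] = None) -> np.ndarray:
    """Three-layer local average ``<f>(r)``.

    ``<f>(r) = lam_minus(r) f(r-1) + lam_zero(r) f(r) + lam_plus(r) f(r+1)``
    with a mirrored inner boundary (``f(0) = f(1)``) and either a
    mirrored outer boundary (``outer=None``) or a fixed bulk value
    ``f(M+1) = outer``.
    """
    f = np.asarray(profile, dtype=float)
    if f.shape[-1] != lattice.M:
        raise ValueError(f"profile length {f.shape[-1]} != M = {lattice.M}")
    out = lattice.lam_zero * f
    out[..., 1:] += lattice.lam_minus[1:] * f[..., :-1]
    out[..., 0] += lattice.lam_minus[0] * f[..., 0]  # mirror (no-op when lam_minus[0]=0)
    out[..., :-1] += lattice.lam_plus[:-1] * f[..., 1:]
    edge = f[..., -1] if outer is None else outer
    out[..., -1] += lattice.lam_plus[-1] * edge
    return out


def poisson_solve(charge_density: np.ndarray, permittivity, lattice: LatticeGeometry,
                  coupling: Optional[float] = None) -> np.ndarray:
    """Solve the discrete Poisson equation on the lattice.

    Flux (conservative) discretization with arithmetic-mean interface
    permittivity:

        S(r) eps(r+1/2) [psi(r+1) - psi(r)]
          - S(r-1) eps(r-1/2) [psi(r) - psi(r-1)] = -coupling L(r) q(r)

    for ``r = 1..M-1`` plus the Dirichlet condition ``psi(M) = 0``; the
    inner boundary carries zero field.  ``charge_density`` is in
    elementary charges per lattice site, ``psi`` is returned in units
    of kT/e.

    The default ``coupling`` is ``e^2/(eps0 kT b)`` evaluated with
    ``b = 3e-10 m`` and ``T = 298 K``.
    """
    q = np.asarray(charge_density, dtype=float)
    M = lattice.M
    if q.shape != (M,):
        raise ValueError(f"charge profile must have length {M}")
    eps = np.broadcast_to(np.asarray(permittivity, dtype=float), (M,)).copy()
    if np.any(eps <= 0):
        raise ValueError("permittivity must be positive everywhere")
    if coupling is None:
        coupling = UnitConversions().coupling

    # conductance c[i] couples layers i and i+1 (0-based, i = 0..M-2);
    # the inner boundary area S[0] is zero, so the inner field vanishes.
    c = lattice.S[1:M] * 0.5 * (eps[:-1] + eps[1:])  # length M-1

    diag = np.zeros(M)
    lower = np.zeros(M)  # lower[i] = A[i+1, i]
    upper = np.zeros(M)  # upper[i] = A[i-1, i]
    rhs = -coupling * lattice.L * q
    i = np.arange(M - 1)
    diag[i] -= c[i]
    diag[1:M - 1] -= c[:M - 2]
    upper[i + 1] = c[i]
    lower[i] = c[i]
    # Dirichlet psi(M) = 0 replaces the last Gauss row
    diag[M - 1] = 1.0
    lower[M - 2] = 0.0
    rhs[M - 1] = 0.0

    ab = np.vstack([upper, diag, lower])
    psi = solve_banded((1, 1), ab, rhs)
    return psi
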