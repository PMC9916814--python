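"""Segment kinds, interaction table and unit conversions.

The united-atom model distinguishes seven segment kinds: water ``W``,
aliphatic carbon ``C`` (CH/CH2/CH3), the charged amino group ``NH3+``,
the neutral amide/amine ``NH``, carbonyl oxygen ``O``, and the generic
co-ion ``Na`` and counterion ``Cl``.  Each kind carries an integer
valency (elementary charges) and a relative dielectric permittivity;
pairs of kinds interact through a symmetric dimensionless Flory-Huggins
``chi`` matrix (in units of kT).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np

__all__ = [
    "SEGMENT_NAMES",
    "SegmentKind",
    "InteractionTable",
    "UnitConversions",
    "default_segment_table",
]

#: canonical ordering of the seven united-atom segment kinds
SEGMENT_NAMES: Tuple[str, ...] = ("W", "C", "NH3+", "NH", "O", "Na", "Cl")


@dataclass(frozen=True)
class SegmentKind:
    """A united-atom segment type.

    Parameters
    ----------
    name : str
        Kind label, one of :data:`SEGMENT_NAMES` for the default model
        (custom kinds are allowed in toy systems).
    valency : int
        Charge in elementary units; must be -1, 0 or +1.
    permittivity : float
        Relative dielectric permittivity of a pure phase of this kind.
    """

    name: str
    valency: int = 0
    permittivity: float = 80.0

    def __post_init__(self) -> None:
        if self.valency not in (-1, 0, 1):
            raise ValueError(f"valency must be in {{-1, 0, +1}}, got {self.valency}")
        if not self.permittivity > 0:
            raise ValueError(f"permittivity must be > 0, got {self.permittivity}")


class InteractionTable:
    """Symmetric Flory-Huggins ``chi`` matrix over a set of segment kinds.

    The table also owns the :class:`SegmentKind` objects so that valency
    and permittivity lookups share one index space with ``chi``.
    Symmetry and the zero diagonal are validated on construction and
    after every edit.
    """

    def __init__(self, kinds: Iterable[SegmentKind], chi: Mapping[Tuple[str, str], float] | np.ndarray):
        self.kinds: Tuple[SegmentKind, ...] = tuple(kinds)
        self.names: Tuple[str, ...] = tuple(k.name for k in self.kinds)
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate segment kind names")
        self.index: Dict[str, int] = {n: i for i, n in enumerate(self.names)}
        n = len(self.names)
        if isinstance(chi, np.ndarray):
            mat = np.array(chi, dtype=float)
            if mat.shape != (n, n):
                raise ValueError(f"chi matrix must be {n}x{n}")
        else:
            mat = np.zeros((n, n))
            for (a, b), v in chi.items():
                ia, ib = self.index[a], self.index[b]
                mat[ia, ib] = v
                mat[ib, ia] = v
        self._chi = mat
        self.validate()

    # -- basic accessors ------------------------------------------------
    @property
    def chi_matrix(self) -> np.ndarray:
        """Return a copy of the full chi matrix (canonical kind order)."""
        return self._chi.copy()

    def chi(self, a: str, b: str) -> float:
        return float(self._chi[self.index[a], self.index[b]])

    def valency(self, name: str) -> int:
        return self.kinds[self.index[name]].valency

    def permittivity(self, name: str) -> float:
        return self.kinds[self.index[name]].permittivity

    @property
    def valencies(self) -> np.ndarray:
        return np.array([k.valency for k in self.kinds], dtype=float)

    @property
    def permittivities(self) -> np.ndarray:
        return np.array([k.permittivity for k in self.kinds], dtype=float)

    # -- editing --------------------------------------------------------
    def set_chi(self, a: str, b: str, value: float) -> None:
        """Set ``chi(a, b) = chi(b, a) = value``; diagonal stays zero."""
        if a == b and value != 0.0:
            raise ValueError("diagonal chi must remain zero")
        ia, ib = self.index[a], self.index[b]
        self._chi[ia, ib] = value
        self._chi[ib, ia] = value
        self.validate()

    def validate(self) -> None:
        if not np.array_equal(self._chi, self._chi.T):
            raise ValueError("chi matrix is not symmetric")
        if np.any(np.diag(self._chi) != 0.0):
            raise ValueError("chi matrix has a nonzero diagonal")

    def copy(self) -> "InteractionTable":
        return InteractionTable(self.kinds, self._chi.copy())

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kinds": [
                {"name": k.name, "valency": k.valency, "permittivity": k.permittivity}
                for k in self.kinds
            ],
            "chi": self._chi.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InteractionTable":
        kinds = [SegmentKind(k["name"], k["valency"], k["permittivity"]) for k in d["kinds"]]
        return cls(kinds, np.array(d["chi"], dtype=float))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "InteractionTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __repr__(self) -> str:  # pragma: no cover
        return f"InteractionTable(kinds={self.names})"


# boltzmann constant (J/K), elementary charge (C), Avogadro (1/mol)
KB = 1.380649e-23
E_CHARGE = 1.602176634e-19
EPS0 = 8.8541878128e-12
N_AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class UnitConversions:
    """Factors translating dimensionless lattice quantities to physical units.

    ``b`` is the lattice cell size in meters, ``k`` the factor between a
    dimensionless volume fraction and a molar concentration, ``T`` the
    temperature in kelvin.
    """

    b: float = 3.0e-10
    k: float = 10.0
    T: float = 298.0

    def __post_init__(self) -> None:
        for name in ("b", "k", "T"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def kT_over_e(self) -> float:
        """Thermal voltage kT/e in volts (~25.7 mV at 298 K)."""
        return KB * self.T / E_CHARGE

    @property
    def site_volume(self) -> float:
        """Volume of one lattice site in m^3, ``1 / (1000 k N_A)``.

        The density-to-molar factor ``k`` fixes the molar volume of a
        segment (a dimensionless fraction phi corresponds to ``k phi``
        mol/L), so one site occupies ``1/(1000 k N_A)`` cubic meters.
        """
        return 1.0 / (1000.0 * self.k * N_AVOGADRO)

    @property
    def coupling(self) -> float:
        """Dimensionless electrostatic prefactor of the lattice Poisson
        equation ``div(eps_r grad psi) = -coupling * q`` (lengths in
        units of ``b``, ``psi`` in kT/e, ``q`` in elementary charges per
        site): ``e^2 b^2 / (eps0 kT v_site)``.

        The site volume follows from the concentration factor ``k``
        rather than from ``b^3``; with the defaults (b = 3 Angstrom,
        k = 10) this gives ~382 and reproduces the physical Debye
        length of a 0.1 M salt solution (phi_salt = 0.01 -> 0.96 nm).
        """
        return (E_CHARGE**2 * self.b**2
                / (EPS0 * KB * self.T * self.site_volume))


def default_segment_table() -> Tuple[InteractionTable, Tuple[SegmentKind, ...]]:
    """Return the default interaction table of the united-atom model.

    The chi matrix encodes the hydrophobic repulsion between water and
    aliphatic carbon (1.2), a strong repulsion between carbon and all
    hydrophilic head/ion species, and a hydrophilic attraction of NH and
    O for water (-0.6).  NH3+ and Na carry +1, Cl carries -1.
    """
    vals = {"W": 0, "C": 0, "NH3+": 1, "NH": 0, "O": 0, "Na": 1, "Cl": -1}
    eps = {"W": 80.0, "C": 2.0, "NH3+": 5.0, "NH": 5.0, "O": 5.0, "Na": 10.0, "Cl": 10.0}
    kinds = tuple(SegmentKind(n, vals[n], eps[n]) for n in SEGMENT_NAMES)
    chi = {
        ("W", "C"): 1.2,
        ("W", "NH"): -0.6,
        ("W", "O"): -0.6,
        ("C", "NH3+"): 3.0,
        ("C", "NH"): 2.0,
        ("C", "O"): 2.0,
        ("C", "Na"): 2.0,
        ("C", "Cl"): 2.0,
    }
    return InteractionTable(kinds, chi), kinds
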