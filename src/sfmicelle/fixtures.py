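"""Deterministic synthetic fixtures.

Every stage of the pipeline can be exercised without any external data:
toy molecules, the default parameter table, hand-built radial profiles
and exhaustively enumerable conformation sets.  Each fixture carries
annotations about the properties it is expected to exhibit and can
self-validate them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Callable, Dict, List

import numpy as np

from .lattice import make_lattice
from .molecule import ChainGraph, LysineTemplate, build_molecule, linear_chain, tree_from_parents
from .segments import InteractionTable, default_segment_table

__all__ = ["Fixture", "make_fixture", "perturb_table", "FIXTURE_NAMES"]


@dataclass
class Fixture:
    """A named deterministic test system with expected-property notes."""

    name: str
    payload: Any
    annotations: Dict[str, Any] = field(default_factory=dict)
    _validator: Callable[["Fixture"], None] | None = None

    def validate(self) -> None:
        """Re-check the annotated properties of the payload."""
        if self._validator is not None:
            self._validator(self)


def _fx_table() -> Fixture:
    table, kinds = default_segment_table()

    def check(fx: Fixture) -> None:
        t: InteractionTable = fx.payload
        assert t.chi("C", "W") == 1.2
        assert t.valency("Cl") == -1
        t.validate()

    return Fixture("paper-default-table", table,
                   {"chi_CW": 1.2, "nu_Cl": -1}, check)


def _fx_diblock() -> Fixture:
    mol = linear_chain(["C"] * 3 + ["NH"] * 3)

    def check(fx: Fixture) -> None:
        m: ChainGraph = fx.payload
        assert m.n_segments == 6
        assert m.kind_count("C") == 3 and m.kind_count("NH") == 3

    return Fixture("toy-linear-diblock", mol,
                   {"N": 6, "hydrophobic": 3, "philic": 3}, check)


def _fx_symmetric_dendron() -> Fixture:
    tmpl = LysineTemplate(stem=("C",), stem_side=(),
                          short_arm=("C", "NH"), long_arm=("C", "NH"))
    mol = build_molecule(2, 1, 4, repeat_unit=tmpl)

    def check(fx: Fixture) -> None:
        m: ChainGraph = fx.payload
        from .molecule import contour_classes
        lengths = set(contour_classes(m).values())
        assert len(lengths) == 1, "symmetric dendron must have one contour class"

    return Fixture("symmetric-dendron-G2", mol, {"contour_classes": 1}, check)


def _fx_lysine_g1() -> Fixture:
    mol = build_molecule(1, 2, 12)

    def check(fx: Fixture) -> None:
        m: ChainGraph = fx.payload
        assert len(m.terminal_indices()) == 4
        assert sum(m.is_tail) == 24

    return Fixture("lysine-G1-t2-Nt12", mol,
                   {"terminals": 4, "tail_segments": 24}, check)


def _enumerate_parent_arrays(n: int):
    """All rooted trees on n labelled nodes with parent[i] < i."""
    if n == 1:
        yield [-1]
        return
    for tail in itertools.product(*[range(i) for i in range(1, n)]):
        yield [-1] + list(tail)


def _brute_force_q(parents: List[int], M: int = 4) -> float:
    """Exhaustive conformation sum on a planar lattice with unit weights.

    The weight of a conformation is ``L(r_root)`` times the product of
    step probabilities along every bond (mirror boundaries).
    """
    lat = make_lattice("planar", M)
    lamm, lam0, lamp = lat.lam_minus, lat.lam_zero, lat.lam_plus

    def stepw(a: int, b: int) -> float:
        if b == a - 1:
            return lamm[a]
        if b == a + 1:
            return lamp[a]
        if b == a:
            w = lam0[a]
            if a == 0:
                w += lamm[a]
            if a == M - 1:
                w += lamp[a]
            return w
        return 0.0

    n = len(parents)
    total = 0.0
    for conf in itertools.product(range(M), repeat=n):
        w = lat.L[conf[0]]
        for i in range(1, n):
            w *= stepw(conf[parents[i]], conf[i])
        total += w
    return total


def _fx_enumeration_trees() -> Fixture:
    entries = []
    for n in range(1, 7):
        for parents in _enumerate_parent_arrays(n):
            entries.append({
                "parents": list(parents),
                "graph": tree_from_parents(["C"] * n, parents),
                "q_unit_weights": _brute_force_q(list(parents)),
            })

    def check(fx: Fixture) -> None:
        # with unit weights every conformation sum equals sum(L) = M
        for e in fx.payload:
            assert abs(e["q_unit_weights"] - 4.0) < 1e-10

    return Fixture("enumeration-trees", entries,
                   {"max_nodes": 6, "lattice_layers": 4}, check)


def _fx_double_layer() -> Fixture:
    """Hand-built single positive shell plus diffuse negative cloud."""
    M = 50
    lat = make_lattice("spherical", M)
    rho = np.zeros(M)
    rho[9] = 1.0 / lat.L[9]             # +1 charge at r ~ 10
    r = lat.r_centers
    cloud = np.where(r > 10, np.exp(-(r - 10) / 3.0), 0.0)
    cloud *= 1.0 / (lat.L * cloud).sum()
    rho -= cloud                        # -1 charge diffuse outside
    Q = np.cumsum(lat.L * rho)

    def check(fx: Fixture) -> None:
        q = fx.payload["Q"]
        assert abs(q[-1]) < 1e-12
        from .observables import local_maxima
        assert len(local_maxima(q)) == 1

    return Fixture("hand-profiles-doublelayer",
                   {"lattice": lat, "rho": rho, "Q": Q},
                   {"n_maxima": 1}, check)


def _fx_stratified() -> Fixture:
    """Hand-built bimodal terminal-group number distribution."""
    M = 60
    lat = make_lattice("spherical", M)
    r = lat.r_centers
    nt = 10.0 * np.exp(-0.5 * ((r - 15) / 2.5) ** 2)
    nt += 6.0 * np.exp(-0.5 * ((r - 35) / 4.0) ** 2)

    def check(fx: Fixture) -> None:
        from .observables import local_maxima
        assert len(local_maxima(fx.payload["nt"], mask_frac=1e-8)) == 2

    return Fixture("hand-profiles-stratified",
                   {"lattice": lat, "nt": nt},
                   {"n_maxima": 2}, check)


_REGISTRY: Dict[str, Callable[[], Fixture]] = {
    "paper-default-table": _fx_table,
    "toy-linear-diblock": _fx_diblock,
    "symmetric-dendron-G2": _fx_symmetric_dendron,
    "lysine-G1-t2-Nt12": _fx_lysine_g1,
    "enumeration-trees": _fx_enumeration_trees,
    "hand-profiles-doublelayer": _fx_double_layer,
    "hand-profiles-stratified": _fx_stratified,
}

FIXTURE_NAMES = tuple(_REGISTRY)


def make_fixture(name: str) -> Fixture:
    """Build a registered fixture by name (deterministic)."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    return builder()


def perturb_table(table: InteractionTable, pair, delta: float) -> InteractionTable:
    """Return a copy of ``table`` with ``chi(pair)`` changed by ``delta``.

    The perturbation is applied symmetrically; asymmetric requests are
    impossible by construction and diagonal perturbations are rejected.
    """
    a, b = pair
    if a == b and delta != 0.0:
        raise ValueError("cannot perturb the diagonal (chi_XX = 0)")
    out = table.copy()
    out.set_chi(a, b, out.chi(a, b) + delta)
    return out
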