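"""Tree-structured united-atom molecule builder.

A hybrid amphiphile is one lysine-type dendron of generation ``G`` with
``t`` hydrophobic tails of ``Nt`` carbon segments each, all attached to
the dendron root segment.  The dendron is a binary tree of repeat
units; each unit has a short arm (alpha-amino side) and a long arm
(epsilon-amino side) so that root-to-terminal contour lengths are
asymmetric.  Arms of the last generation terminate in charged ``NH3+``
groups, giving ``2**(G+1)`` terminals in total.

The exact per-unit segment sequence is a configurable
:class:`LysineTemplate`; the default encodes, per unit,

* a two-carbon backbone stem (carbonyl C with an O side group, then the
  branching alpha-C),
* a short arm of one ``NH`` segment,
* a long arm of four ``C`` segments followed by one ``NH``,

and replaces the last arm segment by ``NH3+`` when the arm is terminal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

__all__ = ["LysineTemplate", "ChainGraph", "build_molecule", "contour_classes",
           "linear_chain", "tree_from_parents"]


@dataclass(frozen=True)
class LysineTemplate:
    """Per-generation repeat unit of the dendron.

    ``stem`` runs from the unit attachment point to the branch point
    (inclusive); ``stem_side`` hangs single-segment side groups off stem
    positions.  ``short_arm`` and ``long_arm`` connect the branch point
    to the next generation (or to a terminal group, in which case the
    last arm segment is replaced by ``terminal``).
    """

    stem: Tuple[str, ...] = ("C", "C")
    stem_side: Tuple[Tuple[int, str], ...] = ((0, "O"),)
    short_arm: Tuple[str, ...] = ("NH",)
    long_arm: Tuple[str, ...] = ("C", "C", "C", "C", "NH")
    terminal: str = "NH3+"

    def __post_init__(self) -> None:
        if not self.stem:
            raise ValueError("template stem must contain at least one segment")
        if not self.short_arm or not self.long_arm:
            raise ValueError("both branch arms must contain at least one segment")
        for pos, _ in self.stem_side:
            if not 0 <= pos < len(self.stem):
                raise ValueError(f"stem side-group position {pos} out of range")

    @property
    def segments_per_unit(self) -> int:
        return len(self.stem) + len(self.stem_side) + len(self.short_arm) + len(self.long_arm)


class ChainGraph:
    """Connected acyclic molecule as flat parallel node arrays.

    Attributes
    ----------
    kinds : list of str
        Segment kind name per node.
    parents : list of int
        Parent node index (-1 for the root).
    subgeneration : list of int
        Dendron unit level 0..G, or -1 for tail segments.
    is_tail, is_terminal, is_branch_point : list of bool
        Node annotations used by the stratification analysis.
    contour : list of int
        Contour distance from the root in bonds (root = 0).
    """

    def __init__(self, G: Optional[int] = None, t: Optional[int] = None,
                 Nt: Optional[int] = None,
                 template: Optional[LysineTemplate] = None):
        self.G = G
        self.t = t
        self.Nt = Nt
        self.template = template
        self.kinds: List[str] = []
        self.parents: List[int] = []
        self.subgeneration: List[int] = []
        self.is_tail: List[bool] = []
        self.is_terminal: List[bool] = []
        self.is_branch_point: List[bool] = []
        self.contour: List[int] = []
        self.children: List[List[int]] = []

    # -- construction helpers ------------------------------------------
    def _add(self, kind: str, parent: int, subgen: int, *, tail: bool = False,
             terminal: bool = False, branch_point: bool = False) -> int:
        idx = len(self.kinds)
        self.kinds.append(kind)
        self.parents.append(parent)
        self.subgeneration.append(subgen)
        self.is_tail.append(tail)
        self.is_terminal.append(terminal)
        self.is_branch_point.append(branch_point)
        self.contour.append(0 if parent < 0 else self.contour[parent] + 1)
        self.children.append([])
        if parent >= 0:
            self.children[parent].append(idx)
        return idx

    # -- accessors ------------------------------------------------------
    @property
    def n_segments(self) -> int:
        return len(self.kinds)

    @property
    def root(self) -> int:
        return 0

    def kind_count(self, kind: str) -> int:
        return sum(1 for k in self.kinds if k == kind)

    def terminal_indices(self) -> List[int]:
        return [i for i, f in enumerate(self.is_terminal) if f]

    def tail_indices(self) -> List[int]:
        return [i for i, f in enumerate(self.is_tail) if f]

    def branch_point_indices(self) -> List[int]:
        return [i for i, f in enumerate(self.is_branch_point) if f]

    def kind_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for k in self.kinds:
            out[k] = out.get(k, 0) + 1
        return out

    def net_valency(self, table) -> float:
        """Total charge of one molecule given an interaction table."""
        return float(sum(table.valency(k) for k in self.kinds))

    def validate(self) -> None:
        if sum(1 for p in self.parents if p < 0) != 1:
            raise ValueError("molecule must have exactly one root")
        # parent pointers on a contiguous index range guarantee acyclicity
        for i, p in enumerate(self.parents):
            if p >= i:
                raise ValueError("parent indices must precede children")
        if self.G is None:
            return
        n_term = sum(self.is_terminal)
        if n_term != 2 ** (self.G + 1):
            raise ValueError(
                f"expected {2 ** (self.G + 1)} terminal groups, found {n_term}")
        n_tail = sum(self.is_tail)
        if n_tail != self.t * self.Nt:
            raise ValueError(f"expected {self.t * self.Nt} tail segments, found {n_tail}")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        tmpl = None
        if self.template is not None:
            tmpl = {
                "stem": list(self.template.stem),
                "stem_side": [list(p) for p in self.template.stem_side],
                "short_arm": list(self.template.short_arm),
                "long_arm": list(self.template.long_arm),
                "terminal": self.template.terminal,
            }
        return {
            "G": self.G,
            "t": self.t,
            "Nt": self.Nt,
            "template": tmpl,
            "kinds": list(self.kinds),
            "parents": list(self.parents),
            "subgeneration": list(self.subgeneration),
            "is_tail": list(self.is_tail),
            "is_terminal": list(self.is_terminal),
            "is_branch_point": list(self.is_branch_point),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChainGraph":
        tmpl = None
        if d.get("template") is not None:
            tmpl = LysineTemplate(
                stem=tuple(d["template"]["stem"]),
                stem_side=tuple((int(p), k) for p, k in d["template"]["stem_side"]),
                short_arm=tuple(d["template"]["short_arm"]),
                long_arm=tuple(d["template"]["long_arm"]),
                terminal=d["template"]["terminal"],
            )
        g = cls(d["G"], d["t"], d["Nt"], tmpl)
        for i in range(len(d["kinds"])):
            g._add(
                d["kinds"][i],
                d["parents"][i],
                d["subgeneration"][i],
                tail=d["is_tail"][i],
                terminal=d["is_terminal"][i],
                branch_point=d["is_branch_point"][i],
            )
        g.validate()
        return g

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "ChainGraph":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ChainGraph(G={self.G}, t={self.t}, Nt={self.Nt}, "
                f"n_segments={self.n_segments})")


def build_molecule(G: int, t: int, Nt: int,
                   repeat_unit: Optional[LysineTemplate] = None) -> ChainGraph:
    """Build the dendron-plus-tails molecule tree.

    Parameters
    ----------
    G : int
        Dendron generation number (>= 0).
    t : int
        Number of hydrophobic tails (>= 1), all attached to the root.
    Nt : int
        Number of ``C`` segments per tail (>= 1).
    repeat_unit : LysineTemplate, optional
        Per-generation segment template; defaults to the documented
        lysine-like template.

    Returns
    -------
    ChainGraph
        Validated molecule with ``2**(G+1)`` terminal ``NH3+`` groups
        and ``t * Nt`` tail segments.
    """
    if G < 0:
        raise ValueError(f"generation number must be >= 0, got {G}")
    if t < 1:
        raise ValueError(f"tail count must be >= 1, got {t}")
    if Nt < 1:
        raise ValueError(f"tail length must be >= 1, got {Nt}")
    tmpl = repeat_unit if repeat_unit is not None else LysineTemplate()
    graph = ChainGraph(G, t, Nt, tmpl)

    def add_unit(parent: int, gen: int) -> None:
        side = dict((pos, kind) for pos, kind in tmpl.stem_side)
        node = parent
        stem_nodes = []
        for i, kind in enumerate(tmpl.stem):
            node = graph._add(kind, node, gen)
            stem_nodes.append(node)
            if i in side:
                graph._add(side[i], node, gen)
        branch = stem_nodes[-1]
        graph.is_branch_point[branch] = True
        for arm in (tmpl.short_arm, tmpl.long_arm):
            arm_node = branch
            if gen < G:
                for kind in arm:
                    arm_node = graph._add(kind, arm_node, gen)
                add_unit(arm_node, gen + 1)
            else:
                for kind in arm[:-1]:
                    arm_node = graph._add(kind, arm_node, gen)
                graph._add(tmpl.terminal, arm_node, gen, terminal=True)

    add_unit(-1, 0)
    root = graph.root
    for _ in range(t):
        node = root
        for _ in range(Nt):
            node = graph._add("C", node, -1, tail=True)
    graph.validate()
    return graph


def linear_chain(kinds: Sequence[str]) -> ChainGraph:
    """Build a linear molecule from a kind sequence (a toy helper)."""
    return tree_from_parents(kinds, [-1] + list(range(len(kinds) - 1)))


def tree_from_parents(kinds: Sequence[str], parents: Sequence[int]) -> ChainGraph:
    """Build an arbitrary tree molecule from parallel kind/parent arrays.

    ``parents[i]`` must be ``< i`` (``-1`` for the root); leaves are
    flagged as terminal.
    """
    if len(kinds) != len(parents):
        raise ValueError("kinds and parents must have equal length")
    for i, p in enumerate(parents):
        if p >= i:
            raise ValueError("parent indices must precede children")
    g = ChainGraph()
    for kind, parent in zip(kinds, parents):
        g._add(kind, parent, -1)
    for i in range(g.n_segments):
        if not g.children[i]:
            g.is_terminal[i] = True
    g.validate()
    return g


def contour_classes(graph: ChainGraph) -> Dict[int, int]:
    """Map each terminal segment to its root-to-terminal contour length.

    Distinct contour lengths define the contour classes used by the
    corona stratification analysis; for the asymmetric default template
    the class count grows with the number of long-arm choices along a
    root-to-leaf path.
    """
    return {i: graph.contour[i] for i in graph.terminal_indices()}
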