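"""Catalog of the plane (wallpaper) symmetry groups and projected Laue classes.

The catalog carries the 21 setting-qualified plane-group entries (the 17
wallpaper groups, with both settings listed for p1m1/p11m, p1g1/p11g,
c1m1/c11m and p2mg/p2gm, because a rectangular pattern breaks the two
settings by different amounts), the six centrosymmetric 2D point groups
that occur as projected Laue classes of Fourier-amplitude maps, and the
*translationengleiche* maximal-subgroup/minimal-supergroup hierarchy that
the climbing-up model selection walks.

Conventions
-----------
* Operations act on fractional coordinates, ``x' = W x + t`` with ``W`` a
  2x2 integer matrix and ``t`` a translation with components in {0, 1/2}.
* The ``1m1`` position of a symbol means the mirror/glide line runs
  perpendicular to the first cell axis; ``11m`` perpendicular to the second.
* Centered groups are indexed on the conventional cell; the centering
  translation (1/2, 1/2) is handled through the h+k-even reflection
  condition and is not counted in ``k``, the number of non-translational
  operations per lattice point.
* On reciprocal indices (row vectors) an operation acts as ``h' = h W``
  and contributes a phase increment of ``h . t`` cycles:
  ``F(h W) = F(h) exp(2 pi i h.t)`` for an exactly symmetric pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
import json

import networkx as nx
import numpy as np

__all__ = [
    "SymmetryOperation",
    "PlaneGroup",
    "LaueClassNode",
    "HierarchyEdge",
    "PLANE_GROUP_SYMBOLS",
    "LAUE_SYMBOLS",
    "get_group",
    "get_laue_class",
    "maximal_subgroups",
    "minimal_supergroups",
    "laue_tree",
    "laue_maximal_subgroups",
    "laue_minimal_supergroups",
    "reciprocal_orbit",
    "plane_group_laue_class",
    "serialize_catalog",
    "CatalogError",
]


class CatalogError(KeyError):
    """Raised for unknown group or Laue-class symbols."""


# --------------------------------------------------------------------------
# operations


@dataclass(frozen=True)
class SymmetryOperation:
    """A plane-group operation (W, t) on fractional coordinates."""

    linear: tuple[tuple[int, int], tuple[int, int]]
    translation: tuple[Fraction, Fraction] = (Fraction(0), Fraction(0))
    label: str = ""

    def __post_init__(self):
        det = (
            self.linear[0][0] * self.linear[1][1]
            - self.linear[0][1] * self.linear[1][0]
        )
        if det not in (1, -1):
            raise ValueError(f"operation determinant must be +/-1, got {det}")

    @property
    def matrix(self) -> np.ndarray:
        return np.array(self.linear, dtype=int)

    @property
    def t(self) -> np.ndarray:
        return np.array([float(self.translation[0]), float(self.translation[1])])

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Map fractional coordinates (..., 2); not reduced modulo 1."""
        xy = np.asarray(xy, dtype=float)
        return xy @ self.matrix.T + self.t

    def compose(self, other: "SymmetryOperation") -> "SymmetryOperation":
        """self after other: x -> W_self (W_other x + t_other) + t_self."""
        w = tuple(
            tuple(int(v) for v in row) for row in (self.matrix @ other.matrix)
        )
        tr = tuple(
            (Fraction(int(self.linear[i][0])) * other.translation[0]
             + Fraction(int(self.linear[i][1])) * other.translation[1]
             + self.translation[i]) % 1
            for i in range(2)
        )
        return SymmetryOperation(w, tr)

    def key(self) -> tuple:
        return (self.linear, self.translation)


_I = ((1, 0), (0, 1))
_ROT2 = ((-1, 0), (0, -1))
_ROT4 = ((0, -1), (1, 0))          # (x, y) -> (-y, x)
_MX = ((-1, 0), (0, 1))            # mirror line perpendicular to a
_MY = ((1, 0), (0, -1))            # mirror line perpendicular to b
_ROT3 = ((0, -1), (1, -1))         # hexagonal basis, (x, y) -> (-y, x - y)
_ROT6 = ((1, -1), (1, 0))          # (x, y) -> (x - y, x)
_MD1 = ((0, 1), (1, 0))            # (x, y) -> (y, x)
_MD2 = ((0, -1), (-1, 0))          # (x, y) -> (-y, -x)

_H = Fraction(1, 2)
_T0 = (Fraction(0), Fraction(0))


def _close(generators: list[SymmetryOperation]) -> list[SymmetryOperation]:
    """Group closure under composition modulo lattice translations."""
    ops = {SymmetryOperation(_I, _T0).key(): SymmetryOperation(_I, _T0, "1")}
    frontier = list(generators)
    while frontier:
        new = []
        for g in frontier:
            if g.key() not in ops:
                ops[g.key()] = g
                new.append(g)
        frontier = []
        for g in new:
            for h in list(ops.values()):
                for comp in (g.compose(h), h.compose(g)):
                    if comp.key() not in ops:
                        frontier.append(comp)
    return list(ops.values())


# --------------------------------------------------------------------------
# groups


@dataclass(frozen=True)
class PlaneGroup:
    symbol: str
    centering: str                      # "p" or "c"
    operations: tuple[SymmetryOperation, ...]
    lattice_constraint: str             # oblique|rectangular|square|hexagonal

    @property
    def k(self) -> int:
        """Number of non-translational operations per lattice point."""
        return len(self.operations)

    @property
    def is_centered(self) -> bool:
        return self.centering == "c"


@dataclass(frozen=True)
class LaueClassNode:
    symbol: str
    operations: tuple[SymmetryOperation, ...]

    @property
    def k(self) -> int:
        return len(self.operations)


def _group(symbol, centering, gens, lattice) -> PlaneGroup:
    ops = tuple(sorted(_close(gens), key=lambda o: o.key()))
    return PlaneGroup(symbol, centering, ops, lattice)


def _op(w, t=_T0) -> SymmetryOperation:
    return SymmetryOperation(w, t)


_GROUPS: dict[str, PlaneGroup] = {
    g.symbol: g
    for g in [
        _group("p1", "p", [], "oblique"),
        _group("p2", "p", [_op(_ROT2)], "oblique"),
        _group("p1m1", "p", [_op(_MX)], "rectangular"),
        _group("p11m", "p", [_op(_MY)], "rectangular"),
        _group("p1g1", "p", [_op(_MX, (Fraction(0), _H))], "rectangular"),
        _group("p11g", "p", [_op(_MY, (_H, Fraction(0)))], "rectangular"),
        _group("c1m1", "c", [_op(_MX)], "rectangular"),
        _group("c11m", "c", [_op(_MY)], "rectangular"),
        _group("p2mm", "p", [_op(_ROT2), _op(_MX)], "rectangular"),
        _group("p2mg", "p", [_op(_ROT2), _op(_MX, (_H, Fraction(0)))], "rectangular"),
        _group("p2gm", "p", [_op(_ROT2), _op(_MY, (Fraction(0), _H))], "rectangular"),
        _group("p2gg", "p", [_op(_ROT2), _op(_MX, (_H, _H))], "rectangular"),
        _group("c2mm", "c", [_op(_ROT2), _op(_MX)], "rectangular"),
        _group("p4", "p", [_op(_ROT4)], "square"),
        _group("p4mm", "p", [_op(_ROT4), _op(_MX)], "square"),
        _group("p4gm", "p", [_op(_ROT4), _op(_MX, (_H, _H))], "square"),
        _group("p3", "p", [_op(_ROT3)], "hexagonal"),
        _group("p3m1", "p", [_op(_ROT3), _op(_MD2)], "hexagonal"),
        _group("p31m", "p", [_op(_ROT3), _op(_MD1)], "hexagonal"),
        _group("p6", "p", [_op(_ROT6)], "hexagonal"),
        _group("p6mm", "p", [_op(_ROT6), _op(_MD1)], "hexagonal"),
    ]
}

PLANE_GROUP_SYMBOLS = tuple(_GROUPS)

_LAUE: dict[str, LaueClassNode] = {
    n.symbol: n
    for n in [
        LaueClassNode("2", tuple(_close([_op(_ROT2)]))),
        LaueClassNode("2mm", tuple(_close([_op(_ROT2), _op(_MX)]))),
        LaueClassNode("4", tuple(_close([_op(_ROT4)]))),
        LaueClassNode("4mm", tuple(_close([_op(_ROT4), _op(_MX)]))),
        LaueClassNode("6", tuple(_close([_op(_ROT6)]))),
        LaueClassNode("6mm", tuple(_close([_op(_ROT6), _op(_MD1)]))),
    ]
}

LAUE_SYMBOLS = tuple(_LAUE)


# --------------------------------------------------------------------------
# hierarchy


@dataclass(frozen=True)
class HierarchyEdge:
    sub: str
    super_: str
    kind: str = "translationengleiche"


# Maximal-subgroup -> minimal-supergroup arrows of the plane-group hierarchy
# tree.  Edges exercised by the classifier's tables follow the model hierarchy
# of the CRISP workflow (axis-aligned centered groups with the h+k-even
# condition on the pattern's own cell); the remaining edges follow ITA
# conventions.
_PLANE_EDGES: tuple[tuple[str, str], ...] = (
    ("p1", "p2"), ("p1", "p1m1"), ("p1", "p11m"), ("p1", "p1g1"),
    ("p1", "p11g"), ("p1", "c1m1"), ("p1", "c11m"), ("p1", "p3"),
    ("p2", "p2mm"), ("p2", "p2mg"), ("p2", "p2gm"), ("p2", "p2gg"),
    ("p2", "c2mm"), ("p2", "p4"), ("p2", "p6"),
    ("p1m1", "p2mm"), ("p1m1", "p2mg"),
    ("p11m", "p2mm"), ("p11m", "p2gm"),
    ("p1g1", "p2gg"), ("p1g1", "p2gm"),
    ("p11g", "p2gg"), ("p11g", "p2mg"),
    ("c1m1", "c2mm"), ("c1m1", "p3m1"),
    ("c11m", "c2mm"), ("c11m", "p31m"),
    ("p3", "p6"), ("p3", "p3m1"), ("p3", "p31m"),
    ("p2mm", "p4mm"), ("p2gg", "p4gm"),
    ("c2mm", "p4mm"), ("c2mm", "p4gm"), ("c2mm", "p6mm"),
    ("p4", "p4mm"), ("p4", "p4gm"),
    ("p3m1", "p6mm"), ("p31m", "p6mm"), ("p6", "p6mm"),
)

_LAUE_EDGES: tuple[tuple[str, str], ...] = (
    ("2", "2mm"), ("2", "4"), ("2", "6"),
    ("2mm", "4mm"), ("4", "4mm"),
    ("2mm", "6mm"), ("6", "6mm"),
)


def _digraph(edges) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return g


_PLANE_TREE = _digraph(_PLANE_EDGES)
_LAUE_TREE = _digraph(_LAUE_EDGES)


# --------------------------------------------------------------------------
# public API


def get_group(symbol: str) -> PlaneGroup:
    """Return a plane group by its setting-qualified Hermann-Mauguin symbol."""
    try:
        return _GROUPS[symbol]
    except KeyError:
        raise CatalogError(f"unknown plane group symbol: {symbol!r}") from None


def get_laue_class(symbol: str) -> LaueClassNode:
    try:
        return _LAUE[symbol]
    except KeyError:
        raise CatalogError(f"unknown Laue class symbol: {symbol!r}") from None


def maximal_subgroups(symbol: str) -> list[str]:
    get_group(symbol)
    return sorted(_PLANE_TREE.predecessors(symbol)) if symbol in _PLANE_TREE else []


def minimal_supergroups(symbol: str) -> list[str]:
    get_group(symbol)
    return sorted(_PLANE_TREE.successors(symbol)) if symbol in _PLANE_TREE else []


def laue_tree() -> list[HierarchyEdge]:
    return [HierarchyEdge(a, b) for a, b in _LAUE_EDGES]


def laue_maximal_subgroups(symbol: str) -> list[str]:
    get_laue_class(symbol)
    return sorted(_LAUE_TREE.predecessors(symbol)) if symbol in _LAUE_TREE else []


def laue_minimal_supergroups(symbol: str) -> list[str]:
    get_laue_class(symbol)
    return sorted(_LAUE_TREE.successors(symbol)) if symbol in _LAUE_TREE else []


def plane_group_laue_class(symbol: str) -> str:
    """Point symmetry of the Fourier-amplitude map of a group-symmetrized model.

    The amplitude map always contains the inversion (Friedel symmetry), so
    the result is one of the six projected Laue classes.
    """
    group = get_group(symbol)
    mats = {tuple(map(tuple, op.matrix)) for op in group.operations}
    mats |= {tuple(map(tuple, -op.matrix)) for op in group.operations}
    order = len(mats)
    has_reflection = any(
        m[0][0] * m[1][1] - m[0][1] * m[1][0] == -1 for m in mats
    )
    rot = order // 2 if has_reflection else order
    if rot == 3:  # 3 and 3m gain the inversion and become 6 / 6mm
        rot = 6
    return f"{rot}mm" if has_reflection else str(rot)


def reciprocal_orbit(
    group: PlaneGroup, index: tuple[int, int]
) -> tuple[list[tuple[tuple[int, int], float]], bool]:
    """Orbit of a reciprocal index under a group, with phase increments.

    Returns ``(members, absent)`` where ``members`` is a list of
    ``((h', k'), phase_increment_cycles)`` pairs, one entry per distinct
    index, such that an exactly symmetric pattern obeys
    ``F(h') = F(h) * exp(2 pi i * phase_increment)``.  ``absent`` is True
    when the orbit constraints (a self-mapping operation with fractional
    phase, or the centering condition) force zero amplitude.
    """
    h = np.asarray(index, dtype=int)
    if not h.any():
        raise ValueError("the (0,0) coefficient has no symmetry orbit")
    members: dict[tuple[int, int], float] = {}
    absent = False
    if group.is_centered and (h[0] + h[1]) % 2 != 0:
        absent = True
    for op in group.operations:
        hp = tuple(int(v) for v in (h @ op.matrix))
        phase = float(h @ op.t) % 1.0
        if hp in members:
            if not np.isclose((members[hp] - phase) % 1.0, 0.0) and not np.isclose(
                (members[hp] - phase) % 1.0, 1.0
            ):
                absent = True
        else:
            members[hp] = phase
    return [((hk[0], hk[1]), ph) for hk, ph in members.items()], absent


def serialize_catalog() -> str:
    """The whole catalog (groups, operations, hierarchy) as JSON text."""
    payload = {
        "plane_groups": {
            s: {
                "k": g.k,
                "centering": g.centering,
                "lattice_constraint": g.lattice_constraint,
                "laue_class": plane_group_laue_class(s),
                "operations": [
                    {"linear": op.linear,
                     "translation": [str(t) for t in op.translation]}
                    for op in g.operations
                ],
                "maximal_subgroups": maximal_subgroups(s),
            }
            for s, g in _GROUPS.items()
        },
        "laue_classes": {
            s: {
                "k": n.k,
                "operations": [{"linear": op.linear} for op in n.operations],
                "maximal_subgroups": laue_maximal_subgroups(s),
            }
            for s, n in _LAUE.items()
        },
        "hierarchy_edges": [list(e) for e in _PLANE_EDGES],
        "laue_edges": [list(e) for e in _LAUE_EDGES],
        "notes": (
            "Edges exercised by the climbing tables follow the CRISP model "
            "hierarchy; remaining edges (e.g. p6mm maximal subgroups) follow "
            "ITA conventions."
        ),
    }
    return json.dumps(payload, indent=1)
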