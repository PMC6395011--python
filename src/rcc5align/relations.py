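"""RCC-5 base relations, the R32 disjunction lattice, converse and composition.

The five base relations compare two *nonempty* regions (sets):
congruence ``==``, proper inclusion ``>``, inverse proper inclusion ``<``,
overlap ``><`` and exclusion ``!``.  A :class:`RelationSet` is any of the 32
subsets of the base five; non-singleton sets express uncertainty
(disjunction), the empty set is the lattice bottom (contradiction).
"""

from __future__ import annotations

import enum
import itertools
from typing import FrozenSet, Iterable


class Relation(enum.Enum):
    """One of the five RCC-5 base relations."""

    EQ = "=="
    GT = ">"
    LT = "<"
    OV = "><"
    EX = "!"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Relation.{self.name}"


#: Word aliases accepted on input alongside the symbolic tokens.
_WORD_ALIASES = {
    "equals": Relation.EQ,
    "includes": Relation.GT,
    "is_included_in": Relation.LT,
    "overlaps": Relation.OV,
    "disjoint": Relation.EX,
}

_TOKEN_TO_RELATION = {r.value: r for r in Relation}
_TOKEN_TO_RELATION.update(_WORD_ALIASES)

#: Canonical order used for serialization.
_ORDER = (Relation.EQ, Relation.GT, Relation.LT, Relation.OV, Relation.EX)


class RelationSet(frozenset):
    """A subset of the five base relations (an element of the R32 lattice).

    Immutable; supports the usual set algebra.  ``RelationSet()`` is the
    contradiction (bottom), :meth:`full` the uninformative top.
    """

    def __new__(cls, members: Iterable[Relation] = ()) -> "RelationSet":
        members = frozenset(members)
        for m in members:
            if not isinstance(m, Relation):
                raise TypeError(f"not a base relation: {m!r}")
        return super().__new__(cls, members)

    @classmethod
    def full(cls) -> "RelationSet":
        return cls(Relation)

    @classmethod
    def of(cls, *members: Relation) -> "RelationSet":
        return cls(members)

    def serialize(self) -> str:
        """Render with the field's symbols: ``==``, or ``{== or <}`` etc."""
        toks = [r.value for r in _ORDER if r in self]
        if not toks:
            return "{}"
        if len(toks) == 1:
            return toks[0]
        return "{" + " or ".join(toks) + "}"

    @classmethod
    def parse(cls, text: str) -> "RelationSet":
        """Inverse of :meth:`serialize`; also accepts word aliases."""
        text = text.strip()
        if text == "{}":
            return cls()
        if text.startswith("{") and text.endswith("}"):
            parts = [p.strip() for p in text[1:-1].split(" or ")]
        else:
            parts = [text]
        members = []
        for p in parts:
            if p not in _TOKEN_TO_RELATION:
                raise ValueError(f"unknown relation token: {p!r}")
            members.append(_TOKEN_TO_RELATION[p])
        return cls(members)

    def converse(self) -> "RelationSet":
        return RelationSet(converse_base(r) for r in self)

    def __repr__(self) -> str:
        return f"RelationSet({self.serialize()!r})"


def base_relation_of_sets(a: frozenset, b: frozenset) -> Relation:
    """The unique base relation holding between two nonempty finite sets."""
    a, b = frozenset(a), frozenset(b)
    if not a or not b:
        raise ValueError("undefined for empty region")
    if a == b:
        return Relation.EQ
    if a > b:
        return Relation.GT
    if a < b:
        return Relation.LT
    if not (a & b):
        return Relation.EX
    return Relation.OV


def converse_base(r: Relation) -> Relation:
    if r is Relation.GT:
        return Relation.LT
    if r is Relation.LT:
        return Relation.GT
    return r


def converse(rs: RelationSet) -> RelationSet:
    """Element-wise converse (swap > and <); the source-swap symmetry."""
    return rs.converse()


def _brute_force_composition(universe_size: int) -> dict:
    """Enumerate all triples of nonempty subsets of a small universe and
    record which base relations co-occur along a->b->c paths."""
    universe = range(universe_size)
    subsets = [
        frozenset(c)
        for n in range(1, universe_size + 1)
        for c in itertools.combinations(universe, n)
    ]
    rel = {
        (a, b): base_relation_of_sets(a, b)
        for a in subsets
        for b in subsets
    }
    table: dict = {
        (r1, r2): set() for r1 in Relation for r2 in Relation
    }
    for a in subsets:
        for b in subsets:
            r1 = rel[(a, b)]
            for c in subsets:
                table[(r1, rel[(b, c)])].add(rel[(a, c)])
    return {k: RelationSet(v) for k, v in table.items()}


# A 4-point universe realizes every composable combination of the five base
# relations; the test suite re-derives the table over universes up to 6
# points and checks equality.
_COMPOSITION = _brute_force_composition(4)


def compose(r1: Relation, r2: Relation) -> RelationSet:
    """All base relations s admitting nonempty a, b, c with a r1 b, b r2 c,
    a s c (the RCC-5 weak composition, here exact for set models)."""
    return _COMPOSITION[(r1, r2)]
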