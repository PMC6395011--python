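"""Domain types: concept labels, source trees, articulations, problems.

A *taxonomic concept label* pins a name usage to its source hierarchy
(``2015.Neoaves`` vs ``2014.Neoaves`` are distinct concepts even though the
name matches).  A :class:`SourceTree` is one source's rooted is_a hierarchy
with a per-parent coverage flag: a covered parent's region is exactly the
union of its children, an uncovered ("nocoverage") parent may exceed them,
the residue being the auxiliary ``nc_<parent>`` region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .relations import RelationSet

NC_PREFIX = "nc_"


@dataclass(frozen=True, order=True)
class ConceptLabel:
    source_tag: str
    name: str
    is_nc_region: bool = False

    def __post_init__(self) -> None:
        if self.is_nc_region and not self.name.startswith(NC_PREFIX):
            raise ValueError(f"nc region name must start with {NC_PREFIX!r}: {self.name}")

    @property
    def qualified(self) -> str:
        return f"{self.source_tag}.{self.name}"

    def __str__(self) -> str:
        return self.qualified


class TreeError(ValueError):
    """Raised for structurally invalid source hierarchies."""


class SourceTree:
    """A single source's rooted concept hierarchy.

    Parameters
    ----------
    tag:
        Short source identifier (``"2015"``, ``"Class2015"``, ...).
    children:
        Mapping parent name -> ordered child names.  Names not appearing as
        keys are terminals.
    uncovered:
        Parent names whose coverage constraint is relaxed (default: coverage
        on for every parent).
    nc_names:
        Names flagged as materialized no-coverage residue concepts.
    """

    def __init__(
        self,
        tag: str,
        children: Mapping[str, Sequence[str]],
        uncovered: Iterable[str] = (),
        nc_names: Iterable[str] = (),
        root: Optional[str] = None,
    ) -> None:
        self.tag = tag
        self._children: Dict[str, Tuple[str, ...]] = {
            p: tuple(cs) for p, cs in children.items()
        }
        self._parent: Dict[str, str] = {}
        for p, cs in self._children.items():
            if not cs:
                raise TreeError(f"{tag}: parent {p!r} listed with no children")
            for c in cs:
                if c in self._parent:
                    raise TreeError(f"{tag}: concept {c!r} has two parents")
                if c == p:
                    raise TreeError(f"{tag}: concept {c!r} is its own parent")
                self._parent[c] = p
        names = set(self._children) | set(self._parent)
        if not names:
            if root is None:
                raise TreeError(f"{tag}: empty tree needs an explicit root concept")
            names = {root}
        roots = [n for n in names if n not in self._parent]
        if len(roots) != 1:
            raise TreeError(f"{tag}: expected exactly one root, found {sorted(roots)}")
        self._root = roots[0]
        # cycle check doubles as reachability check
        seen: Set[str] = set()
        stack = [self._root]
        while stack:
            n = stack.pop()
            if n in seen:
                raise TreeError(f"{tag}: cycle at {n!r}")
            seen.add(n)
            stack.extend(self._children.get(n, ()))
        if seen != names:
            raise TreeError(f"{tag}: unreachable concepts {sorted(names - seen)}")
        self._names: Tuple[str, ...] = tuple(sorted(names))
        unk = set(uncovered) - set(self._children)
        if unk:
            raise TreeError(f"{tag}: nocoverage on non-parent concepts {sorted(unk)}")
        self.covered: Dict[str, bool] = {
            p: (p not in set(uncovered)) for p in self._children
        }
        self.nc_names: Set[str] = set(nc_names)
        bad = self.nc_names - names
        if bad:
            raise TreeError(f"{tag}: unknown nc concepts {sorted(bad)}")

    # -- structure -----------------------------------------------------
    @property
    def root(self) -> str:
        return self._root

    @property
    def concepts(self) -> Tuple[str, ...]:
        return self._names

    def __contains__(self, name: str) -> bool:
        return name in set(self._names)

    def __len__(self) -> int:
        return len(self._names)

    def children(self, name: str) -> Tuple[str, ...]:
        return self._children.get(name, ())

    def parent(self, name: str) -> Optional[str]:
        return self._parent.get(name)

    def is_terminal(self, name: str) -> bool:
        return name not in self._children

    @property
    def terminals(self) -> Tuple[str, ...]:
        return tuple(n for n in self._names if self.is_terminal(n))

    def ancestors(self, name: str) -> List[str]:
        """Proper ancestors, nearest first."""
        out = []
        p = self._parent.get(name)
        while p is not None:
            out.append(p)
            p = self._parent.get(p)
        return out

    def subtree(self, name: str) -> List[str]:
        """Descendants-or-self in preorder."""
        out, stack = [], [name]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self._children.get(n, ())))
        return out

    def label(self, name: str) -> ConceptLabel:
        if name not in self:
            raise KeyError(f"{self.tag}: unknown concept {name!r}")
        return ConceptLabel(self.tag, name, is_nc_region=name in self.nc_names)

    @property
    def labels(self) -> List[ConceptLabel]:
        return [self.label(n) for n in self._names]

    # -- coverage ------------------------------------------------------
    def is_covered(self, name: str) -> bool:
        return self.covered.get(name, True)

    @property
    def uncovered_parents(self) -> List[str]:
        return [p for p, cov in self.covered.items() if not cov]

    def materialize_nc(self) -> "SourceTree":
        """Give every uncovered parent an explicit ``nc_<parent>`` child.

        Idempotent; existing residue children are kept.
        """
        children = {p: list(cs) for p, cs in self._children.items()}
        nc_names = set(self.nc_names)
        for p in self.uncovered_parents:
            nc = NC_PREFIX + p
            if nc in children.get(p, []):
                continue
            if nc in self._names:
                raise TreeError(f"{self.tag}: name clash materializing {nc!r}")
            children[p].append(nc)
            nc_names.add(nc)
        return SourceTree(self.tag, children, self.uncovered_parents, nc_names,
                          root=self._root)

    def restrict(self, keep: Iterable[str]) -> "SourceTree":
        """Restrict to an up-closed concept set; parents that lose children
        get coverage switched off (children below the cut may exist)."""
        keep = set(keep)
        missing = keep - set(self._names)
        if missing:
            raise TreeError(f"{self.tag}: cannot keep unknown {sorted(missing)}")
        for n in keep:
            p = self._parent.get(n)
            if p is not None and p not in keep:
                raise TreeError(f"{self.tag}: keep set not up-closed at {n!r}")
        children = {}
        uncovered = []
        for p, cs in self._children.items():
            if p not in keep:
                continue
            kept = [c for c in cs if c in keep]
            if kept:
                children[p] = kept
                if not self.is_covered(p) or len(kept) < len(cs):
                    uncovered.append(p)
        nc_names = self.nc_names & keep
        return SourceTree(self.tag, children, uncovered, nc_names, root=self._root)

    # -- equality ------------------------------------------------------
    def _key(self):
        return (
            self.tag,
            tuple(sorted((p, tuple(sorted(cs))) for p, cs in self._children.items())),
            tuple(sorted(self.covered.items())),
            tuple(sorted(self.nc_names)),
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, SourceTree) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<SourceTree {self.tag}: {len(self)} concepts, root {self._root}>"


@dataclass(frozen=True)
class Articulation:
    """An RCC-5 assertion between two source-qualified concepts."""

    left: ConceptLabel
    right: ConceptLabel
    relation: RelationSet

    def __post_init__(self) -> None:
        if not self.relation:
            raise ValueError("articulation with empty (contradictory) relation set")

    def swapped(self) -> "Articulation":
        return Articulation(self.right, self.left, self.relation.converse())

    def __str__(self) -> str:
        return f"[{self.left} {self.relation.serialize()} {self.right}]"


@dataclass(frozen=True)
class Options:
    enforce_sibling_disjointness: bool = True
    materialize_nc_regions: bool = True


class ProblemError(ValueError):
    """Raised for ill-formed alignment problems."""


@dataclass
class AlignmentProblem:
    """Two or more source trees plus cross-source articulations."""

    trees: List[SourceTree]
    articulations: List[Articulation] = field(default_factory=list)
    options: Options = field(default_factory=Options)

    def __post_init__(self) -> None:
        if len(self.trees) < 2:
            raise ProblemError("an alignment needs at least two source trees")
        tags = [t.tag for t in self.trees]
        if len(set(tags)) != len(tags):
            raise ProblemError(f"duplicate source tags: {tags}")
        if self.options.materialize_nc_regions:
            self.trees = [t.materialize_nc() for t in self.trees]
        by_tag = {t.tag: t for t in self.trees}
        for a in self.articulations:
            if a.left.source_tag == a.right.source_tag:
                raise ProblemError(f"same-source articulation {a}")
            for side in (a.left, a.right):
                tree = by_tag.get(side.source_tag)
                if tree is None:
                    raise ProblemError(f"unknown source tag {side.source_tag!r} in {a}")
                if side.name not in tree:
                    raise ProblemError(f"unknown concept {side.qualified} in {a}")

    def tree(self, tag: str) -> SourceTree:
        for t in self.trees:
            if t.tag == tag:
                return t
        raise KeyError(tag)

    def source_pairs(self) -> List[Tuple[SourceTree, SourceTree]]:
        """Consecutive source pairs, the scope of MIR inference."""
        return list(zip(self.trees, self.trees[1:]))

    def articulations_between(self, tag_a: str, tag_b: str) -> List[Articulation]:
        """Articulations between two sources, oriented tag_a -> tag_b."""
        out = []
        for a in self.articulations:
            if (a.left.source_tag, a.right.source_tag) == (tag_a, tag_b):
                out.append(a)
            elif (a.left.source_tag, a.right.source_tag) == (tag_b, tag_a):
                out.append(a.swapped())
        return out

    def swapped(self) -> "AlignmentProblem":
        """Source-swap of a two-tree problem (for the converse symmetry)."""
        return AlignmentProblem(
            list(reversed(self.trees)),
            [a.swapped() for a in self.articulations],
            self.options,
        )

    def without_articulation(self, index: int) -> "AlignmentProblem":
        arts = self.articulations[:index] + self.articulations[index + 1:]
        return AlignmentProblem(list(self.trees), arts, self.options)

    def _key(self):
        return (
            tuple(t._key() for t in self.trees),
            frozenset((a.left, a.right, a.relation) for a in self.articulations),
            self.options,
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, AlignmentProblem) and self._key() == other._key()
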