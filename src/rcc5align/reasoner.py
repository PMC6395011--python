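"""Consistency checking, possible-world enumeration and MIR inference.

Semantics.  A *witness* (possible world) interprets every concept as a
nonempty subset of a finite universe such that (i) each child is contained
in its parent, (ii) siblings are pairwise disjoint (when enforced), (iii) a
covered parent equals the union of its children while an uncovered parent
may exceed it, the residue being its ``nc_`` region, and (iv) every input
articulation's realized base relation is a member of its relation set.

The scalable backend exploits the fact that, for sibling-disjoint trees,
every concept's extension is the union of the *pseudo-terminals* below it
(terminal concepts plus coverage residues).  A world is therefore fully
described by an occupancy grid over atom classes ``(row, column)`` where a
row is a pseudo-terminal of the first tree or "outside its root" and a
column likewise for the second tree.  Constraints compile to CNF over the
grid bits and are solved by a small DPLL engine.  The exhaustive backend
enumerates occupancy patterns directly and checks them by straightforward
set evaluation; it is the reference oracle.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .model import (
    NC_PREFIX,
    AlignmentProblem,
    Articulation,
    ConceptLabel,
    Options,
    SourceTree,
)
from .relations import Relation, RelationSet, base_relation_of_sets


class ReasonerError(Exception):
    pass


class InconsistentProblemError(ReasonerError):
    """Raised when an operation requires a consistent problem."""

    def __init__(self, diagnosis: Optional[List[Articulation]] = None):
        self.diagnosis = diagnosis
        detail = ""
        if diagnosis:
            detail = "; minimal conflicting articulations: " + ", ".join(
                str(a) for a in diagnosis
            )
        super().__init__("problem is inconsistent" + detail)


class ResourceLimitError(ReasonerError):
    """The backend could not decide within its resource limits."""


# ---------------------------------------------------------------------------
# Semantic constraint system (direct set evaluation)
# ---------------------------------------------------------------------------

Extension = Mapping[ConceptLabel, FrozenSet]


@dataclass
class ConstraintSystem:
    """The set-theoretic constraints of a problem, checkable by direct
    evaluation of a candidate extension assignment."""

    problem: AlignmentProblem

    def violations(self, extension: Extension) -> List[str]:
        out: List[str] = []
        opts = self.problem.options
        ext = {lbl: frozenset(pts) for lbl, pts in extension.items()}
        for tree in self.problem.trees:
            for name in tree.concepts:
                lbl = tree.label(name)
                if lbl not in ext:
                    out.append(f"missing extension for {lbl}")
                    continue
                if not ext[lbl]:
                    out.append(f"empty region {lbl}")
            for parent in tree.concepts:
                kids = tree.children(parent)
                if not kids:
                    continue
                plbl = tree.label(parent)
                if plbl not in ext or any(tree.label(k) not in ext for k in kids):
                    continue
                union = frozenset().union(*(ext[tree.label(k)] for k in kids))
                for k in kids:
                    if not ext[tree.label(k)] <= ext[plbl]:
                        out.append(f"{tree.tag}.{k} not within parent {parent}")
                if opts.enforce_sibling_disjointness:
                    for k1, k2 in itertools.combinations(kids, 2):
                        if ext[tree.label(k1)] & ext[tree.label(k2)]:
                            out.append(f"siblings {tree.tag}.{k1} / {k2} overlap")
                nc_kids = [k for k in kids if k in tree.nc_names]
                if tree.is_covered(parent):
                    if ext[plbl] != union:
                        out.append(f"coverage violated at {plbl}")
                else:
                    if not union <= ext[plbl]:
                        out.append(f"children exceed uncovered parent {plbl}")
                    for nc in nc_kids:
                        others = frozenset().union(
                            frozenset(),
                            *(ext[tree.label(k)] for k in kids if k != nc),
                        )
                        if ext[tree.label(nc)] != ext[plbl] - others:
                            out.append(f"nc region {tree.tag}.{nc} is not the residue")
        for art in self.problem.articulations:
            a, b = ext.get(art.left), ext.get(art.right)
            if a is None or b is None or not a or not b:
                continue
            if base_relation_of_sets(a, b) not in art.relation:
                out.append(f"articulation violated: {art}")
        return out

    def evaluate(self, extension: Extension) -> bool:
        return not self.violations(extension)


def encode(problem: AlignmentProblem) -> ConstraintSystem:
    """The total encoding of a problem into set constraints."""
    return ConstraintSystem(problem)


# ---------------------------------------------------------------------------
# Witnesses and world signatures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WitnessModel:
    """A satisfying interpretation: nonempty extensions over a finite
    universe of anonymous points."""

    universe: FrozenSet
    extension: Mapping[ConceptLabel, FrozenSet]

    def satisfies(self, problem: AlignmentProblem) -> bool:
        return encode(problem).evaluate(self.extension)


@dataclass(frozen=True)
class WorldSignature:
    """The pairwise base-relation matrix over all concepts; two witnesses
    describe the same possible world iff their signatures are equal."""

    pairs: Tuple[Tuple[Tuple[ConceptLabel, ConceptLabel], Relation], ...]

    @classmethod
    def from_witness(cls, witness: WitnessModel) -> "WorldSignature":
        labels = sorted(witness.extension)
        out = []
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                out.append(
                    ((a, b), base_relation_of_sets(witness.extension[a], witness.extension[b]))
                )
        return cls(tuple(out))

    def relation(self, a: ConceptLabel, b: ConceptLabel) -> Relation:
        key = (a, b) if a <= b else (b, a)
        for pair, rel in self.pairs:
            if pair == key:
                return rel if pair == (a, b) else _conv(rel)
        raise KeyError((a, b))


def _conv(rel: Relation) -> Relation:
    if rel is Relation.GT:
        return Relation.LT
    if rel is Relation.LT:
        return Relation.GT
    return rel


@dataclass
class MIR:
    """Maximally Informative Relations: the strongest entailed relation set
    for every cross-source concept pair (first-listed source first)."""

    entries: Dict[Tuple[ConceptLabel, ConceptLabel], RelationSet]

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, a: ConceptLabel, b: ConceptLabel) -> RelationSet:
        if (a, b) in self.entries:
            return self.entries[(a, b)]
        if (b, a) in self.entries:
            return self.entries[(b, a)].converse()
        raise KeyError((a, b))

    def overlap_pairs(self) -> List[Tuple[ConceptLabel, ConceptLabel]]:
        return sorted(
            k for k, v in self.entries.items() if v == RelationSet.of(Relation.OV)
        )


# ---------------------------------------------------------------------------
# A small DPLL SAT core (two watched literals, chronological backtracking)
# ---------------------------------------------------------------------------


def sat_solve(nvars: int, clauses: Sequence[Sequence[int]]) -> Optional[List[bool]]:
    """Solve CNF over variables 1..nvars; literals are +-var.  Returns a
    satisfying assignment (index 1..nvars) or None."""
    assign: List[Optional[bool]] = [None] * (nvars + 1)
    watch: Dict[int, List[int]] = defaultdict(list)
    cl: List[List[int]] = []
    units: List[int] = []
    for c in clauses:
        c = list(dict.fromkeys(c))
        if any(-l in c for l in c):
            continue
        if not c:
            return None
        if len(c) == 1:
            units.append(c[0])
            continue
        idx = len(cl)
        cl.append(c)
        watch[c[0]].append(idx)
        watch[c[1]].append(idx)

    trail: List[int] = []
    decisions: List[Tuple[int, int]] = []  # (literal decided, trail length before)

    def lit_value(lit: int) -> Optional[bool]:
        v = assign[abs(lit)]
        if v is None:
            return None
        return v if lit > 0 else not v

    def enqueue(lit: int) -> bool:
        v = lit_value(lit)
        if v is False:
            return False
        if v is None:
            assign[abs(lit)] = lit > 0
            trail.append(lit)
        return True

    def propagate(start: int) -> bool:
        qi = start
        while qi < len(trail):
            lit = trail[qi]
            qi += 1
            falsified = -lit
            wl = watch[falsified]
            i = 0
            while i < len(wl):
                ci = wl[i]
                c = cl[ci]
                # ensure falsified literal is at position 1
                if c[0] == falsified:
                    c[0], c[1] = c[1], c[0]
                if lit_value(c[0]) is True:
                    i += 1
                    continue
                moved = False
                for j in range(2, len(c)):
                    if lit_value(c[j]) is not False:
                        c[1], c[j] = c[j], c[1]
                        watch[c[1]].append(ci)
                        wl[i] = wl[-1]
                        wl.pop()
                        moved = True
                        break
                if moved:
                    continue
                # clause is unit or conflicting on c[0]
                if not enqueue(c[0]):
                    return False
                i += 1
        return True

    for u in units:
        if not enqueue(u):
            return None
    if not propagate(0):
        return None

    next_var = 1
    while True:
        while next_var <= nvars and assign[next_var] is not None:
            next_var += 1
        if next_var > nvars:
            return [bool(assign[v]) for v in range(nvars + 1)]
        lit = -next_var  # try False first
        while True:
            mark = len(trail)
            decisions.append((lit, mark))
            enqueue(lit)
            if propagate(mark):
                break
            # conflict: backtrack to last decision not yet flipped
            while decisions:
                dlit, dmark = decisions.pop()
                for l in trail[dmark:]:
                    assign[abs(l)] = None
                del trail[dmark:]
                if dlit < 0:  # tried False, flip to True
                    lit = -dlit
                    break
            else:
                return None
            next_var = 1


# ---------------------------------------------------------------------------
# Grid encoding backend
# ---------------------------------------------------------------------------

_TRIPLES = {
    Relation.EQ: (1, 0, 0),
    Relation.GT: (1, 1, 0),
    Relation.LT: (1, 0, 1),
    Relation.OV: (1, 1, 1),
    Relation.EX: (0, 1, 1),
}


def _pseudo_terminals(tree: SourceTree) -> Tuple[List[Tuple[str, str]], Dict[str, List[int]]]:
    """Atoms of one tree: terminal concepts plus hidden coverage residues
    (for uncovered parents lacking a materialized nc child).  Returns the
    atom list and the concept -> atom-index map."""
    atoms: List[Tuple[str, str]] = []
    for name in tree.concepts:
        if tree.is_terminal(name):
            atoms.append(("t", name))
        elif not tree.is_covered(name) and (NC_PREFIX + name) not in tree.children(name):
            atoms.append(("r", name))
    index = {a: i for i, a in enumerate(atoms)}
    of: Dict[str, List[int]] = {}
    for name in tree.concepts:
        sub = set(tree.subtree(name))
        of[name] = sorted(
            i for (kind, n), i in index.items() if n in sub
        )
    return atoms, of


class GridBackend:
    """Propositional grid encoding for a two-tree, sibling-disjoint problem."""

    def __init__(self, problem: AlignmentProblem):
        if len(problem.trees) != 2:
            raise ValueError("grid backend aligns exactly two trees")
        if not problem.options.enforce_sibling_disjointness:
            raise ValueError("grid backend requires sibling disjointness")
        self.problem = problem
        self.tree_a, self.tree_b = problem.trees
        self.rows, self.rows_of = _pseudo_terminals(self.tree_a)
        self.cols, self.cols_of = _pseudo_terminals(self.tree_b)
        nr, nc = len(self.rows), len(self.cols)
        self.OUT_R, self.OUT_C = nr, nc
        self.cell_var: Dict[Tuple[int, int], int] = {}
        v = 0
        for r in range(nr + 1):
            for c in range(nc + 1):
                if r == nr and c == nc:
                    continue
                v += 1
                self.cell_var[(r, c)] = v
        self.ncells = v
        self.naux = 0
        self.base_clauses: List[List[int]] = []
        self._build()

    # -- clause construction ------------------------------------------
    def _row_cells(self, r: int) -> List[int]:
        return [self.cell_var[(r, c)] for c in range(len(self.cols) + 1)]

    def _col_cells(self, c: int) -> List[int]:
        return [self.cell_var[(r, c)] for r in range(len(self.rows) + 1)]

    def _groups(self, left_name: str, right_name: str):
        rx = set(self.rows_of[left_name])
        cy = set(self.cols_of[right_name])
        all_c = set(range(len(self.cols) + 1))
        all_r = set(range(len(self.rows) + 1))
        sh = [self.cell_var[(r, c)] for r in rx for c in cy]
        ao = [self.cell_var[(r, c)] for r in rx for c in all_c - cy]
        bo = [self.cell_var[(r, c)] for r in all_r - rx for c in cy]
        return sh, ao, bo

    def _fresh_aux(self) -> int:
        self.naux += 1
        return self.ncells + self.naux

    def _relation_clauses(self, rel: RelationSet, groups) -> List[List[int]]:
        if rel == RelationSet.full():
            return []
        triples = {_TRIPLES[r] for r in rel}
        values = [sorted({t[i] for t in triples}) for i in range(3)]
        clauses: List[List[int]] = []
        if len(triples) == len(values[0]) * len(values[1]) * len(values[2]):
            # decomposes per aggregate bit
            for vals, group in zip(values, groups):
                if vals == [0]:
                    clauses.extend([-g] for g in group)
                elif vals == [1]:
                    clauses.append(list(group))
            return clauses
        # Tseitin: one aux bit per aggregate, forbid disallowed combinations
        bits = []
        for group in groups:
            b = self._fresh_aux()
            bits.append(b)
            for g in group:
                clauses.append([-g, b])
            clauses.append([-b] + list(group))
        for combo in itertools.product((0, 1), repeat=3):
            if combo in triples:
                continue
            clauses.append([(-b if v else b) for b, v in zip(bits, combo)])
        return clauses

    def _build(self) -> None:
        for r, (kind, _name) in enumerate(self.rows):
            if kind == "t":
                self.base_clauses.append(self._row_cells(r))
        for c, (kind, _name) in enumerate(self.cols):
            if kind == "t":
                self.base_clauses.append(self._col_cells(c))
        arts = self.problem.articulations_between(self.tree_a.tag, self.tree_b.tag)
        for art in arts:
            groups = self._groups(art.left.name, art.right.name)
            self.base_clauses.extend(self._relation_clauses(art.relation, groups))

    # -- solving -------------------------------------------------------
    @property
    def nvars(self) -> int:
        return self.ncells + self.naux

    def solve(self, extra: Sequence[Sequence[int]] = ()) -> Optional[Dict[Tuple[int, int], bool]]:
        model = sat_solve(self.nvars, list(self.base_clauses) + list(extra))
        if model is None:
            return None
        return {cell: model[v] for cell, v in self.cell_var.items()}

    def query_relation(
        self,
        left_name: str,
        right_name: str,
        rel: Relation,
        extra: Sequence[Sequence[int]] = (),
    ) -> Optional[Dict[Tuple[int, int], bool]]:
        """Is ``left rel right`` realizable? (consistency of problem + assertion)"""
        groups = self._groups(left_name, right_name)
        clauses = self._relation_clauses(RelationSet.of(rel), groups)
        return self.solve(list(extra) + clauses)

    # -- model interpretation -----------------------------------------
    def witness(self, matrix: Mapping[Tuple[int, int], bool]) -> WitnessModel:
        occupied = sorted(cell for cell, v in matrix.items() if v)
        points = {cell: i for i, cell in enumerate(occupied)}
        ext: Dict[ConceptLabel, FrozenSet] = {}
        for tree, of, axis in (
            (self.tree_a, self.rows_of, 0),
            (self.tree_b, self.cols_of, 1),
        ):
            for name in tree.concepts:
                atoms = set(of[name])
                ext[tree.label(name)] = frozenset(
                    points[cell] for cell in occupied if cell[axis] in atoms
                )
        return WitnessModel(frozenset(points.values()), ext)

    def blocking_clause(self, matrix: Mapping[Tuple[int, int], bool]) -> List[int]:
        return [(-v if matrix[cell] else v) for cell, v in self.cell_var.items()]


# ---------------------------------------------------------------------------
# Exhaustive backend (reference oracle)
# ---------------------------------------------------------------------------


class ExhaustiveBackend:
    """Brute-force enumeration of occupancy patterns over atom classes,
    each candidate checked by direct set evaluation of encode(problem).

    With sibling disjointness, a point's membership in one tree is a single
    root-to-atom chain; without it, any nonempty set of chains.  Capped to
    keep the enumeration tractable; exceeding the cap is an explicit
    resource-limit outcome.
    """

    def __init__(self, problem: AlignmentProblem, max_atoms: int = 18):
        if len(problem.trees) != 2:
            raise ValueError("exhaustive backend aligns exactly two trees")
        self.problem = problem
        self.system = encode(problem)
        ta, tb = problem.trees
        disjoint = problem.options.enforce_sibling_disjointness
        ma = self._memberships(ta, disjoint)
        mb = self._memberships(tb, disjoint)
        self.types: List[Tuple[FrozenSet[ConceptLabel], ...]] = []
        for sa in ma + [frozenset()]:
            for sb in mb + [frozenset()]:
                if not sa and not sb:
                    continue
                self.types.append((sa, sb))
        if len(self.types) > max_atoms:
            raise ResourceLimitError(
                f"undecided (limit): {len(self.types)} atom classes exceed cap {max_atoms}"
            )

    @staticmethod
    def _memberships(tree: SourceTree, disjoint: bool) -> List[FrozenSet[ConceptLabel]]:
        stops = [
            n
            for n in tree.concepts
            if tree.is_terminal(n)
            or (not tree.is_covered(n) and (NC_PREFIX + n) not in tree.children(n))
        ]
        chains = [
            frozenset(tree.label(x) for x in [s] + tree.ancestors(s)) for s in stops
        ]
        if disjoint:
            return chains
        out = []
        for k in range(1, len(chains) + 1):
            for combo in itertools.combinations(chains, k):
                out.append(frozenset().union(*combo))
        return sorted(set(out), key=sorted)

    def _extensions(self, occupied: Sequence[int]) -> Dict[ConceptLabel, FrozenSet]:
        ext: Dict[ConceptLabel, Set] = defaultdict(set)
        for tree in self.problem.trees:
            for name in tree.concepts:
                ext[tree.label(name)]  # ensure key
        for pt in occupied:
            sa, sb = self.types[pt]
            for lbl in sa | sb:
                ext[lbl].add(pt)
        return {k: frozenset(v) for k, v in ext.items()}

    def worlds(self) -> List[WitnessModel]:
        n = len(self.types)
        found: Dict[WorldSignature, WitnessModel] = {}
        for mask in range(1, 1 << n):
            occupied = [i for i in range(n) if mask >> i & 1]
            ext = self._extensions(occupied)
            if any(not v for v in ext.values()):
                continue
            if self.system.evaluate(ext):
                w = WitnessModel(frozenset(occupied), ext)
                found.setdefault(WorldSignature.from_witness(w), w)
        return list(found.values())


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


@dataclass
class ConsistencyResult:
    status: str  # "consistent" | "inconsistent" | "undecided"
    witness: Optional[WitnessModel] = None
    conflict: Optional[List[Articulation]] = None

    def __bool__(self) -> bool:
        return self.status == "consistent"


@dataclass
class WorldEnumeration:
    worlds: List[WorldSignature]
    witnesses: List[WitnessModel]
    truncated: bool


def _pair_subproblems(problem: AlignmentProblem) -> List[AlignmentProblem]:
    """Split a multi-tree problem into its consecutive two-tree alignments."""
    if len(problem.trees) == 2:
        return [problem]
    out = []
    opts = replace(problem.options, materialize_nc_regions=False)  # already done
    for ta, tb in problem.source_pairs():
        arts = problem.articulations_between(ta.tag, tb.tag)
        out.append(AlignmentProblem([ta, tb], arts, opts))
    return out


def _backend_for(problem: AlignmentProblem, backend: str):
    if backend == "grid":
        return GridBackend(problem)
    if backend == "exhaustive":
        return ExhaustiveBackend(problem)
    if backend == "auto":
        if problem.options.enforce_sibling_disjointness:
            return GridBackend(problem)
        return ExhaustiveBackend(problem)
    raise ValueError(f"unknown backend {backend!r}")


def check_consistency(
    problem: AlignmentProblem,
    backend: str = "auto",
    diagnose_limit: int = 24,
) -> ConsistencyResult:
    """Sound and complete consistency check; on success the witness is
    verified against the direct set semantics before being returned."""
    results = []
    for sub in _pair_subproblems(problem):
        res = _check_pair(sub, backend, diagnose_limit)
        if res.status != "consistent":
            return res
        results.append(res)
    return results[0] if len(results) == 1 else ConsistencyResult(
        "consistent", results[0].witness
    )


def _check_pair(problem, backend, diagnose_limit) -> ConsistencyResult:
    try:
        be = _backend_for(problem, backend)
        if isinstance(be, GridBackend):
            matrix = be.solve()
            witness = be.witness(matrix) if matrix is not None else None
        else:
            ws = be.worlds()
            witness = ws[0] if ws else None
    except ResourceLimitError:
        return ConsistencyResult("undecided")
    if witness is not None:
        bad = encode(problem).violations(witness.extension)
        if bad:  # pragma: no cover - internal invariant
            raise ReasonerError(f"backend produced invalid witness: {bad}")
        return ConsistencyResult("consistent", witness)
    conflict = None
    if len(problem.articulations) <= diagnose_limit:
        conflict = _minimize_conflict(problem, backend)
    return ConsistencyResult("inconsistent", conflict=conflict)


def _minimize_conflict(problem: AlignmentProblem, backend: str) -> List[Articulation]:
    """Deletion-based minimization of a conflicting articulation subset."""
    keep = list(problem.articulations)
    i = 0
    while i < len(keep):
        trial = keep[:i] + keep[i + 1:]
        sub = AlignmentProblem(list(problem.trees), trial,
                               replace(problem.options, materialize_nc_regions=False))
        try:
            if not _satisfiable(sub, backend):
                keep = trial
                continue
        except ResourceLimitError:
            pass
        i += 1
    return keep


def _satisfiable(problem: AlignmentProblem, backend: str) -> bool:
    be = _backend_for(problem, backend)
    if isinstance(be, GridBackend):
        return be.solve() is not None
    return bool(be.worlds())


def enumerate_worlds(
    problem: AlignmentProblem,
    limit: int = 64,
    backend: str = "auto",
    matrix_cap: Optional[int] = None,
) -> WorldEnumeration:
    """Distinct possible worlds (pairwise-relation signatures), complete if
    fewer than ``limit`` exist; otherwise truncated and flagged."""
    if limit <= 0:
        raise ValueError("world limit must be positive")
    if len(problem.trees) != 2:
        raise ValueError("world enumeration is defined per two-tree alignment")
    be = _backend_for(problem, backend)
    if isinstance(be, ExhaustiveBackend):
        ws = be.worlds()
        trunc = len(ws) > limit
        ws = ws[:limit] if trunc else ws
        return WorldEnumeration([WorldSignature.from_witness(w) for w in ws], ws, trunc)
    cap = matrix_cap if matrix_cap is not None else max(1024, 16 * limit)
    clauses: List[List[int]] = []
    found: Dict[WorldSignature, WitnessModel] = {}
    truncated = False
    for _ in range(cap):
        matrix = be.solve(clauses)
        if matrix is None:
            break
        w = be.witness(matrix)
        sig = WorldSignature.from_witness(w)
        if sig not in found:
            if len(found) >= limit:
                truncated = True
                break
            found[sig] = w
        clauses.append(be.blocking_clause(matrix))
    else:
        truncated = True
    return WorldEnumeration(list(found.keys()), list(found.values()), truncated)


def _cross_pairs(ta: SourceTree, tb: SourceTree) -> List[Tuple[ConceptLabel, ConceptLabel]]:
    return [
        (ta.label(x), tb.label(y)) for x in ta.concepts for y in tb.concepts
    ]


def infer_mir(
    problem: AlignmentProblem,
    backend: str = "auto",
    worlds_probe: int = 64,
) -> MIR:
    """The strongest entailed relation set for every cross-source pair:
    relation r is in entry(a, b) iff the problem plus "a r b" is consistent.

    Implementation first tries to enumerate all possible worlds (cheap when
    the alignment is well specified); if there are too many, it falls back
    to per-pair entailment queries, seeding entries from every witness found
    so that the result is identical to the naive five-query method.
    """
    entries: Dict[Tuple[ConceptLabel, ConceptLabel], RelationSet] = {}
    for sub in _pair_subproblems(problem):
        entries.update(_infer_pair(sub, backend, worlds_probe).entries)
    return MIR(entries)


def _infer_pair(problem, backend, worlds_probe) -> MIR:
    ta, tb = problem.trees
    pairs = _cross_pairs(ta, tb)
    res = check_consistency(problem, backend=backend)
    if res.status == "inconsistent":
        raise InconsistentProblemError(res.conflict)
    if res.status == "undecided":
        raise ResourceLimitError("undecided (limit) during consistency check")
    try:
        enum = enumerate_worlds(problem, limit=worlds_probe, backend=backend)
    except ResourceLimitError:
        enum = WorldEnumeration([], [], True)
    if not enum.truncated:
        acc: Dict[Tuple[ConceptLabel, ConceptLabel], Set[Relation]] = {
            p: set() for p in pairs
        }
        for w in enum.witnesses:
            for a, b in pairs:
                acc[(a, b)].add(
                    base_relation_of_sets(w.extension[a], w.extension[b])
                )
        return MIR({p: RelationSet(v) for p, v in acc.items()})
    # fall back to per-pair entailment queries (grid backend only reaches
    # here; the exhaustive backend always enumerates completely)
    be = _backend_for(problem, backend)
    if not isinstance(be, GridBackend):  # pragma: no cover - defensive
        raise ResourceLimitError("exhaustive backend truncated unexpectedly")
    acc = {p: set() for p in pairs}

    def seed(witness: WitnessModel) -> None:
        for a, b in pairs:
            acc[(a, b)].add(base_relation_of_sets(witness.extension[a], witness.extension[b]))

    seed(res.witness)
    for a, b in pairs:
        for rel in Relation:
            if rel in acc[(a, b)]:
                continue
            matrix = be.query_relation(a.name, b.name, rel)
            if matrix is not None:
                seed(be.witness(matrix))
    return MIR({p: RelationSet(v) for p, v in acc.items()})


def prune_and_propagate(
    problem: AlignmentProblem,
    mir: MIR,
    keep: Iterable[ConceptLabel],
) -> AlignmentProblem:
    """The bottom-up partition step: restrict the trees to an up-closed
    concept region, relax coverage for parents that lost children, and
    install the inferred MIR among kept pairs as input articulations."""
    keep_names = {(lbl.source_tag, lbl.name) for lbl in keep}
    by_tag: Dict[str, Set[str]] = defaultdict(set)
    for tag, name in keep_names:
        by_tag[tag].add(name)
    trees = [t.restrict(by_tag.get(t.tag, set())) for t in problem.trees]
    arts = []
    for (a, b), rel in sorted(mir.entries.items()):
        kept = (a.source_tag, a.name) in keep_names and (b.source_tag, b.name) in keep_names
        if kept and rel and rel != RelationSet.full():
            arts.append(Articulation(a, b, rel))
    return AlignmentProblem(
        trees, arts, replace(problem.options, materialize_nc_regions=False)
    )
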