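"""Derived conflict analyses.

Includes the overlap matrix and overlap-chain participation counts, the
congruent-refinement census, the clade-name reliability cross-tabulation,
and an Open-Tree-of-Life-style rooted-bipartition concordance/conflict
comparator for contrasting edge-based and RCC-5 views of the same
disagreement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import pandas as pd

from .model import ConceptLabel
from .reasoner import MIR
from .relations import Relation, RelationSet

_OV_ONLY = RelationSet.of(Relation.OV)
_EQ_ONLY = RelationSet.of(Relation.EQ)


# ---------------------------------------------------------------------------
# Overlap matrix and chains
# ---------------------------------------------------------------------------


@dataclass
class OverlapMatrix:
    rows: List[ConceptLabel]
    cols: List[ConceptLabel]
    cells: Dict[Tuple[ConceptLabel, ConceptLabel], bool]
    row_totals: Dict[ConceptLabel, int]
    col_totals: Dict[ConceptLabel, int]
    grand_total: int

    def to_frame(self) -> pd.DataFrame:
        data = {
            str(c): [int(self.cells.get((r, c), False)) for r in self.rows]
            for c in self.cols
        }
        df = pd.DataFrame(data, index=[str(r) for r in self.rows])
        df["Totals"] = [self.row_totals[r] for r in self.rows]
        totals = [self.col_totals[c] for c in self.cols] + [self.grand_total]
        df.loc["Totals"] = totals
        return df


def overlap_matrix(
    mir: MIR,
    restrict: Optional[Tuple[Iterable[ConceptLabel], Iterable[ConceptLabel]]] = None,
) -> OverlapMatrix:
    """Cross-tabulate the MIR entries whose relation set is exactly the
    overlap relation; rows and columns are sorted by descending totals."""
    ov = mir.overlap_pairs()
    if restrict is not None:
        keep_a, keep_b = set(restrict[0]), set(restrict[1])
        ov = [(a, b) for a, b in ov if a in keep_a and b in keep_b]
    cells = {(a, b): True for a, b in ov}
    row_totals: Dict[ConceptLabel, int] = {}
    col_totals: Dict[ConceptLabel, int] = {}
    for a, b in ov:
        row_totals[a] = row_totals.get(a, 0) + 1
        col_totals[b] = col_totals.get(b, 0) + 1
    rows = sorted(row_totals, key=lambda r: (-row_totals[r], r))
    cols = sorted(col_totals, key=lambda c: (-col_totals[c], c))
    return OverlapMatrix(rows, cols, cells, row_totals, col_totals, len(ov))


def chain_overlap_count(mir: MIR, concepts: Iterable[ConceptLabel]) -> int:
    """Number of overlap entries whose same-source member lies in the given
    (single-source) concept set."""
    concepts = set(concepts)
    tags = {c.source_tag for c in concepts}
    if len(tags) > 1:
        raise ValueError(f"chain must be drawn from one source, got {sorted(tags)}")
    count = 0
    for a, b in mir.overlap_pairs():
        if a in concepts or b in concepts:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Refinements and name reliability
# ---------------------------------------------------------------------------


@dataclass
class RefinementCensus:
    """Concepts that add resolution: non-terminal concepts of one source
    that sit strictly inside the other source's hierarchy (some entry is
    exactly <, resp. >) without being congruent to any of its concepts."""

    left: int
    right: int
    left_concepts: List[ConceptLabel] = field(default_factory=list)
    right_concepts: List[ConceptLabel] = field(default_factory=list)


def refinement_census(mir: MIR, problem) -> RefinementCensus:
    ta, tb = problem.trees[0], problem.trees[1]
    lt_by_left: Dict[ConceptLabel, Set[RelationSet]] = {}
    out_left, out_right = [], []
    for name in ta.concepts:
        lbl = ta.label(name)
        if ta.is_terminal(name) or lbl.is_nc_region:
            continue
        rels = [mir.entries[(lbl, tb.label(y))] for y in tb.concepts]
        if any(r == _EQ_ONLY for r in rels):
            continue
        if any(r == RelationSet.of(Relation.LT) for r in rels):
            out_left.append(lbl)
    for name in tb.concepts:
        lbl = tb.label(name)
        if tb.is_terminal(name) or lbl.is_nc_region:
            continue
        rels = [mir.entries[(ta.label(x), lbl)] for x in ta.concepts]
        if any(r == _EQ_ONLY for r in rels):
            continue
        if any(r == RelationSet.of(Relation.GT) for r in rels):
            out_right.append(lbl)
    return RefinementCensus(len(out_left), len(out_right), out_left, out_right)


@dataclass
class NameReliabilityTable:
    """2 x 5 cross-tab of clade-name sameness against the MIR relation;
    nc-involving entries are excluded, disjunctive entries fall into a
    separate ambiguous bucket (empty for single-world alignments)."""

    counts: Dict[Tuple[str, Relation], int]
    ambiguous: int
    analyzed: int
    cells: Dict[Tuple[str, Relation], List[Tuple[ConceptLabel, ConceptLabel]]]

    def to_frame(self) -> pd.DataFrame:
        order = [Relation.EQ, Relation.GT, Relation.LT, Relation.OV, Relation.EX]
        data = {
            r.value: [
                self.counts.get(("same", r), 0),
                self.counts.get(("different", r), 0),
            ]
            for r in order
        }
        df = pd.DataFrame(data, index=["Same clade name", "Different clade names"])
        df["Totals"] = df.sum(axis=1)
        df.loc["Totals"] = df.sum(axis=0)
        return df

    def unreliable_pairs(self) -> List[Tuple[ConceptLabel, ConceptLabel]]:
        """Pairings where the name signal contradicts the relation: same
        name without congruence, or different names with congruence."""
        out = []
        for (kind, rel), pairs in self.cells.items():
            if (kind == "same") != (rel is Relation.EQ):
                out.extend(pairs)
        return sorted(out)


def name_reliability(mir: MIR) -> NameReliabilityTable:
    counts: Dict[Tuple[str, Relation], int] = {}
    cells: Dict[Tuple[str, Relation], List] = {}
    ambiguous = analyzed = 0
    for (a, b), rel in mir.entries.items():
        if a.is_nc_region or b.is_nc_region:
            continue
        analyzed += 1
        if len(rel) != 1:
            ambiguous += 1
            continue
        (r,) = rel
        kind = "same" if a.name == b.name else "different"
        counts[(kind, r)] = counts.get((kind, r), 0) + 1
        cells.setdefault((kind, r), []).append((a, b))
    return NameReliabilityTable(counts, ambiguous, analyzed, cells)


# ---------------------------------------------------------------------------
# Rooted-bipartition (OToL-style) comparator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BipartitionEdge:
    """A source edge j read as the rooted bipartition S(j) = S_in | S_out
    over the shared tip universe."""

    edge_id: str
    s_in: FrozenSet[str]
    s_out: FrozenSet[str]
    informative: bool


def _strip_prefix(name: str) -> str:
    return name.split(".", 1)[1] if "." in name else name


def _leaf_names(node) -> List[str]:
    return [
        (l.taxon.label if l.taxon else l.label).replace(" ", "_")
        for l in node.leaf_iter()
    ]


def bipartitions(tree: "dendropy.Tree", shared_tips: Iterable[str]) -> List[BipartitionEdge]:
    """One rooted bipartition per internal edge, tip sets restricted to the
    shared universe; restricted ingroups smaller than two tips (or covering
    everything) are uninformative."""
    shared = frozenset(shared_tips)
    out = []
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        counter += 1
        label = (node.label or "").replace(" ", "_") or f"edge{counter}"
        s_in = frozenset(_strip_prefix(n) for n in _leaf_names(node)) & shared
        s_out = shared - s_in
        informative = len(s_in) >= 2 and len(s_out) >= 1
        out.append(BipartitionEdge(label, s_in, s_out, informative))
    return out


@dataclass
class EdgeAnnotation:
    edge_id: str
    concordant: bool
    conflicting: bool
    concordant_with: Optional[str] = None
    conflicting_with: Optional[str] = None

    @property
    def status(self) -> str:
        # conflict takes reporting precedence when both flags arise
        if self.conflicting:
            return "conflicting"
        if self.concordant:
            return "concordant"
        return "neither"


def _graft_unmatched(
    alternative: "dendropy.Tree",
    unmatched: Sequence[str],
    taxonomy: "dendropy.Tree",
) -> "dendropy.Tree":
    """Attach tips missing from the alternative tree as children of their
    nearest taxonomy ancestor whose name labels an alternative node -
    emulating placement through a reference taxonomy."""
    alt = alternative.clone(depth=1)
    by_label = {}
    for node in alt.preorder_node_iter():
        if node.label:
            by_label[node.label.replace(" ", "_")] = node
    tax_leaves = {
        (l.taxon.label if l.taxon else l.label).replace(" ", "_"): l
        for l in taxonomy.leaf_node_iter()
    }
    for tip in unmatched:
        leaf = tax_leaves.get(tip)
        if leaf is None:
            continue
        node = leaf.parent_node
        target = None
        while node is not None:
            label = (node.label or "").replace(" ", "_")
            if label and label in by_label:
                target = by_label[label]
                break
            node = node.parent_node
        if target is None:
            continue
        new = target.new_child()
        new.taxon = dendropy.Taxon(label=tip)
    return alt


def annotate_conflict(
    primary: "dendropy.Tree",
    alternative: "dendropy.Tree",
    taxonomy: Optional["dendropy.Tree"] = None,
) -> Dict[str, EdgeAnnotation]:
    """Per-edge concordance/conflict of the primary tree against the
    alternative.

    An edge A is concordant when some alternative edge B has B_in within
    A_in and B_out within A_out (subset, allowing equality); it conflicts
    with B when A_in meets B_in, A_in meets B_out, and B_in meets A_out are
    all nonempty.  Tip names are matched by exact string equality after
    stripping source prefixes; with a taxonomy given, primary tips missing
    from the alternative are grafted into it first.
    """
    prim_tips = {_strip_prefix(n) for n in _leaf_names(primary.seed_node)}
    alt_tips = {_strip_prefix(n) for n in _leaf_names(alternative.seed_node)}
    if taxonomy is not None:
        unmatched = sorted(prim_tips - alt_tips)
        alternative = _graft_unmatched(alternative, unmatched, taxonomy)
        alt_tips = {_strip_prefix(n) for n in _leaf_names(alternative.seed_node)}
    shared = prim_tips & alt_tips
    if not shared:
        raise ValueError("no shared tips between the trees")
    prim_edges = bipartitions(primary, shared)
    alt_edges = [e for e in bipartitions(alternative, shared) if e.informative]
    out: Dict[str, EdgeAnnotation] = {}
    for e in prim_edges:
        ann = EdgeAnnotation(e.edge_id, False, False)
        if e.informative:
            for f in alt_edges:
                if f.s_in <= e.s_in and f.s_out <= e.s_out:
                    if not ann.concordant:
                        ann.concordant, ann.concordant_with = True, f.edge_id
                if (e.s_in & f.s_in) and (e.s_in & f.s_out) and (f.s_in & e.s_out):
                    if not ann.conflicting:
                        ann.conflicting, ann.conflicting_with = True, f.edge_id
        out[e.edge_id] = ann
    return out


# ---------------------------------------------------------------------------
# Cross-method discrepancy report
# ---------------------------------------------------------------------------


@dataclass
class DiscrepancyReport:
    """Agreement between the edge comparator and the RCC-5 overlaps.

    false_positives: concepts whose RCC-5 entries include an overlap that
    the edge method does not flag as conflict (conflict not recovered).
    false_negatives: edges flagged conflicting although RCC-5 sees no
    overlap for the mapped concept (e.g. mere refinement).
    """

    agreements: List[str]
    false_positives: List[str]
    false_negatives: List[str]
    warnings: List[str]


def compare_with_rcc5(
    annotations: Mapping[str, EdgeAnnotation],
    mir: MIR,
    concept_edge_map: Mapping[ConceptLabel, str],
) -> DiscrepancyReport:
    overlapping: Set[ConceptLabel] = set()
    for a, b in mir.overlap_pairs():
        overlapping.add(a)
        overlapping.add(b)
    agree, fpos, fneg, warn = [], [], [], []
    for concept, edge_id in sorted(concept_edge_map.items()):
        ann = annotations.get(edge_id)
        if ann is None:
            warn.append(f"edge {edge_id!r} for {concept} not found; skipped")
            continue
        rcc5_overlap = concept in overlapping
        if rcc5_overlap and not ann.conflicting:
            fpos.append(f"{concept}: RCC-5 overlap not recovered by edge method")
        elif ann.conflicting and not rcc5_overlap:
            fneg.append(f"{concept}: edge conflict without RCC-5 overlap")
        else:
            agree.append(str(concept))
    return DiscrepancyReport(agree, fpos, fneg, warn)
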