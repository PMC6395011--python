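"""Alignment region graphs and whole- vs split-concept resolution.

A consistent alignment is displayed as a graph of *regions*: maximal sets
of concepts whose extensions coincide in a chosen witness.  Overlapping
input pairs can either be joined by an overlap edge (whole-concept
resolution) or resolved into the three product regions ``A*B``, ``A\\B``
and ``B\\A`` (split-concept resolution), which supplies labels for regions
that no source phylogeny names.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .model import AlignmentProblem, ConceptLabel
from .reasoner import MIR, WitnessModel
from .relations import Relation, RelationSet, base_relation_of_sets

_OV_ONLY = RelationSet.of(Relation.OV)
_EQ_ONLY = RelationSet.of(Relation.EQ)


@dataclass(frozen=True)
class SplitLabel:
    """A split-concept resolution label for one overlapping pair: the
    shared product (``A*B``) or one of the two one-parent remainders."""

    left: ConceptLabel
    right: ConceptLabel
    operator: str  # "AND" | "LEFT_NOT" | "RIGHT_NOT"

    def serialize(self) -> str:
        if self.operator == "AND":
            return f"{self.left} * {self.right}"
        if self.operator == "LEFT_NOT":
            return f"{self.left} \\ {self.right}"
        if self.operator == "RIGHT_NOT":
            return f"{self.right} \\ {self.left}"
        raise ValueError(self.operator)

    def __str__(self) -> str:
        return self.serialize()


@dataclass
class AlignmentRegion:
    region_id: str
    extent: FrozenSet
    member_labels: Set[ConceptLabel]
    kind: str  # "congruent" | "source_only" | "split_product"
    split_labels: List[SplitLabel] = field(default_factory=list)

    def display_labels(self) -> List[str]:
        out = [str(l) for l in sorted(self.member_labels)]
        out.extend(sorted(s.serialize() for s in self.split_labels))
        return out

    @property
    def sort_key(self):
        return (min(self.display_labels()), self.region_id)


@dataclass
class RegionGraph:
    regions: List[AlignmentRegion]
    inclusion_edges: List[Tuple[str, str]]  # (smaller, larger), transitive reduction
    overlap_edges: List[Tuple[str, str]]
    source_order: List[str]
    resolution: str

    def region_by_id(self, rid: str) -> AlignmentRegion:
        for r in self.regions:
            if r.region_id == rid:
                return r
        raise KeyError(rid)


def build_regions(
    problem: AlignmentProblem,
    mir: MIR,
    witness: WitnessModel,
    resolution: str = "whole",
) -> RegionGraph:
    """Derive the region graph from a concrete witness.

    Pairwise MIR alone does not determine triple-wise intersections, so the
    displayed graph is computed from one witness; for well-specified
    (single-world) alignments this is canonical.
    """
    if resolution not in ("whole", "split"):
        raise ValueError(f"unknown resolution {resolution!r}")
    if not witness.satisfies(problem):
        raise ValueError("witness does not satisfy the problem")
    source_order = [t.tag for t in problem.trees]
    concepts: List[ConceptLabel] = [
        t.label(n) for t in problem.trees for n in t.concepts
    ]
    by_extent: Dict[FrozenSet, AlignmentRegion] = {}
    for lbl in concepts:
        ext = witness.extension[lbl]
        region = by_extent.get(ext)
        if region is None:
            region = AlignmentRegion(f"r{len(by_extent)}", ext, set(), "source_only")
            by_extent[ext] = region
        region.member_labels.add(lbl)
    for region in by_extent.values():
        tags = {l.source_tag for l in region.member_labels}
        region.kind = "congruent" if len(tags) >= 2 else "source_only"

    overlap_pairs = mir.overlap_pairs()
    overlap_edges: List[Tuple[str, str]] = []
    if resolution == "whole":
        seen = set()
        for a, b in overlap_pairs:
            ra, rb = by_extent[witness.extension[a]], by_extent[witness.extension[b]]
            key = tuple(sorted((ra.region_id, rb.region_id)))
            if key not in seen:
                seen.add(key)
                overlap_edges.append(key)
    else:
        for a, b in overlap_pairs:
            ea, eb = witness.extension[a], witness.extension[b]
            for op, ext in (
                ("AND", ea & eb),
                ("LEFT_NOT", ea - eb),
                ("RIGHT_NOT", eb - ea),
            ):
                region = by_extent.get(ext)
                if region is None:
                    region = AlignmentRegion(
                        f"r{len(by_extent)}", ext, set(), "split_product"
                    )
                    by_extent[ext] = region
                region.split_labels.append(SplitLabel(a, b, op))

    regions = list(by_extent.values())
    g = nx.DiGraph()
    for r in regions:
        g.add_node(r.region_id)
    for r1, r2 in itertools.permutations(regions, 2):
        if r1.extent < r2.extent:
            g.add_edge(r1.region_id, r2.region_id)
    reduced = nx.transitive_reduction(g)
    return RegionGraph(
        regions,
        sorted(reduced.edges()),
        overlap_edges,
        source_order,
        resolution,
    )


@dataclass
class SplitCensus:
    """Bookkeeping for split-concept resolution labels (three per
    overlapping input pair)."""

    total_labels: int
    synonym_labels: int          # labels on regions that carry an input label
    novel_labels: int            # labels on regions with no input label
    novel_regions: int           # distinct such regions
    novel_uniquely_labeled: int  # novel regions with exactly one label
    novel_redundantly_labeled: int  # novel regions with >= 2 labels


def split_label_census(mir: MIR, regions: RegionGraph) -> SplitCensus:
    if regions.resolution != "split":
        raise ValueError("census requires split-resolution regions")
    total = 3 * len(mir.overlap_pairs())
    synonym = novel = 0
    novel_regions = []
    for r in regions.regions:
        if not r.split_labels:
            continue
        if r.member_labels:
            synonym += len(r.split_labels)
        else:
            novel += len(r.split_labels)
            novel_regions.append(r)
    uniquely = sum(1 for r in novel_regions if len(r.split_labels) == 1)
    return SplitCensus(
        total_labels=total,
        synonym_labels=synonym,
        novel_labels=novel,
        novel_regions=len(novel_regions),
        novel_uniquely_labeled=uniquely,
        novel_redundantly_labeled=len(novel_regions) - uniquely,
    )


def count_congruent_regions(mir: MIR) -> int:
    """Maximal cross-source clusters of pairwise-congruent concepts."""
    g = nx.Graph()
    for (a, b), rel in mir.entries.items():
        if rel == _EQ_ONLY:
            g.add_edge(a, b)
    count = 0
    for comp in nx.connected_components(g):
        if len({l.source_tag for l in comp}) >= 2:
            count += 1
    return count
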