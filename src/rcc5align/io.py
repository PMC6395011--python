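"""Parsing and serialization of alignment problems, Newick ingestion,
clade-concept label generation, and MIR/graph writers.

Problem dialect::

    # comment
    taxonomy 2015 Prum et al.
    (Psittaciformes Psittacidae)
    (Psittacidae Nestor Probosciger)
    nocoverage Psittacidae
    articulation 2015-2014
    [2015.Psittaciformes == 2014.Psittaciformes]

Relation tokens: ``==``, ``>``, ``<``, ``><``, ``!``; disjunctions
``{== or <}``; word aliases ``equals``, ``includes``, ``is_included_in``,
``overlaps``, ``disjoint``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy

from .model import (
    NC_PREFIX,
    AlignmentProblem,
    Articulation,
    ConceptLabel,
    Options,
    SourceTree,
    TreeError,
)
from .relations import RelationSet

_NAME_RE = re.compile(r"^[A-Za-z0-9_]+$")
_UNNAMED_PREFIX = "_unnamed_"


class ParseError(ValueError):
    def __init__(self, message: str, line: int):
        self.line = line
        super().__init__(f"line {line}: {message}")


@dataclass
class ProblemDocument:
    """A parsed problem plus raw text and source locations (line numbers
    for concepts and articulations, for error reporting)."""

    text: str
    problem: AlignmentProblem
    locations: Dict[object, int] = field(default_factory=dict)


def parse_problem(text: str, options: Optional[Options] = None) -> ProblemDocument:
    options = options or Options()
    trees_raw: List[dict] = []
    arts: List[Articulation] = []
    locations: Dict[object, int] = {}
    mode = None  # None | ("tax", dict) | ("art", (tagL, tagR))
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("taxonomy"):
            parts = line.split()
            if len(parts) < 2:
                raise ParseError("taxonomy line needs a source tag", lineno)
            tag = parts[1]
            if any(t["tag"] == tag for t in trees_raw):
                raise ParseError(f"duplicate taxonomy tag {tag!r}", lineno)
            cur = {"tag": tag, "children": {}, "nocoverage": [], "line": lineno}
            trees_raw.append(cur)
            mode = ("tax", cur)
            continue
        if line.startswith("articulation"):
            parts = line.split()
            if len(parts) != 2 or "-" not in parts[1]:
                raise ParseError("expected: articulation <tagL>-<tagR>", lineno)
            tag_l, _, tag_r = parts[1].partition("-")
            mode = ("art", (tag_l, tag_r))
            continue
        if line.startswith("("):
            if mode is None or mode[0] != "tax":
                raise ParseError("parent/child list outside a taxonomy block", lineno)
            if not line.endswith(")"):
                raise ParseError(f"malformed parent/child list {line!r}", lineno)
            names = line[1:-1].split()
            if not names:
                raise ParseError("empty parent/child list", lineno)
            for n in names:
                if not _NAME_RE.match(n):
                    raise ParseError(f"bad concept name {n!r}", lineno)
            cur = mode[1]
            if len(names) == 1:  # single-concept tree: bare root declaration
                if cur["children"] or cur.get("root"):
                    raise ParseError("bare root in a non-empty taxonomy block", lineno)
                cur["root"] = names[0]
                locations[(cur["tag"], names[0])] = lineno
                continue
            parent, kids = names[0], names[1:]
            if parent in cur["children"]:
                raise ParseError(f"duplicate parent line for {parent!r}", lineno)
            if len(set(kids)) != len(kids):
                raise ParseError(f"duplicate child under {parent!r}", lineno)
            cur["children"][parent] = kids
            locations[(cur["tag"], parent)] = lineno
            continue
        if line.startswith("nocoverage"):
            if mode is None or mode[0] != "tax":
                raise ParseError("nocoverage outside a taxonomy block", lineno)
            parts = line.split()
            if len(parts) != 2:
                raise ParseError("expected: nocoverage <parent>", lineno)
            mode[1]["nocoverage"].append((parts[1], lineno))
            continue
        if line.startswith("["):
            if mode is None or mode[0] != "art":
                raise ParseError("articulation outside an articulation block", lineno)
            if not line.endswith("]"):
                raise ParseError(f"malformed articulation {line!r}", lineno)
            art = _parse_articulation(line[1:-1], mode[1], lineno)
            arts.append(art)
            locations[art] = lineno
            continue
        raise ParseError(f"unrecognized line {line!r}", lineno)

    trees = []
    for t in trees_raw:
        if not t["children"] and not t.get("root"):
            raise ParseError(f"taxonomy {t['tag']!r} has no parent/child lines", t["line"])
        for parent, ln in t["nocoverage"]:
            if parent not in t["children"]:
                raise ParseError(
                    f"nocoverage on {parent!r} which has no children", ln
                )
        try:
            trees.append(
                SourceTree(
                    t["tag"],
                    t["children"],
                    [p for p, _ in t["nocoverage"]],
                    root=t.get("root"),
                )
            )
        except TreeError as exc:
            raise ParseError(str(exc), t["line"]) from exc

    lookup = {
        t.tag: (t.materialize_nc() if options.materialize_nc_regions else t)
        for t in trees
    }
    requalified = []
    for art in arts:
        sides = []
        for side in (art.left, art.right):
            if side.source_tag not in lookup:
                raise ParseError(
                    f"articulation references unknown source tag {side.source_tag!r}",
                    locations[art],
                )
            if side.name not in lookup[side.source_tag]:
                raise ParseError(
                    f"articulation references unknown concept {side.qualified}",
                    locations[art],
                )
            sides.append(lookup[side.source_tag].label(side.name))
        if art.left.source_tag == art.right.source_tag:
            raise ParseError("same-source articulation", locations[art])
        requalified.append(Articulation(sides[0], sides[1], art.relation))

    problem = AlignmentProblem(trees, requalified, options)
    return ProblemDocument(text, problem, locations)


def _parse_articulation(body: str, tags: Tuple[str, str], lineno: int) -> Articulation:
    parts = body.split()
    if len(parts) < 3:
        raise ParseError(f"malformed articulation body {body!r}", lineno)
    left_tok, right_tok = parts[0], parts[-1]
    rel_text = " ".join(parts[1:-1])
    try:
        rel = RelationSet.parse(rel_text)
    except ValueError as exc:
        raise ParseError(str(exc), lineno) from exc
    if not rel:
        raise ParseError("empty (contradictory) relation set in input", lineno)

    def split_label(tok: str) -> ConceptLabel:
        if "." not in tok:
            raise ParseError(f"expected <tag>.<name>, got {tok!r}", lineno)
        tag, _, name = tok.partition(".")
        if tag not in tags:
            raise ParseError(
                f"tag {tag!r} not declared in articulation block {tags[0]}-{tags[1]}",
                lineno,
            )
        if not _NAME_RE.match(name):
            raise ParseError(f"bad concept name {name!r}", lineno)
        return ConceptLabel(tag, name, is_nc_region=name.startswith(NC_PREFIX))

    return Articulation(split_label(left_tok), split_label(right_tok), rel)


def serialize_problem(problem: AlignmentProblem) -> str:
    """Deterministic, order-normalized rendering; materialized nc children
    are emitted as ``nocoverage`` directives, not as structural children."""
    lines: List[str] = []
    for tree in problem.trees:
        lines.append(f"taxonomy {tree.tag}")
        if len(tree) == 1:
            lines.append(f"({tree.root})")
        for parent in sorted(p for p in tree.concepts if tree.children(p)):
            kids = sorted(
                k for k in tree.children(parent) if k not in tree.nc_names
            )
            if kids:
                lines.append("(" + " ".join([parent] + kids) + ")")
        for parent in sorted(tree.uncovered_parents):
            lines.append(f"nocoverage {parent}")
    groups: Dict[Tuple[str, str], List[Articulation]] = {}
    order = [t.tag for t in problem.trees]
    for a in problem.articulations:
        lt, rt = a.left.source_tag, a.right.source_tag
        if order.index(lt) > order.index(rt):
            a = a.swapped()
            lt, rt = rt, lt
        groups.setdefault((lt, rt), []).append(a)
    for (lt, rt) in sorted(groups, key=lambda p: (order.index(p[0]), order.index(p[1]))):
        lines.append(f"articulation {lt}-{rt}")
        for a in sorted(
            groups[(lt, rt)], key=lambda a: (a.left, a.right, a.relation.serialize())
        ):
            lines.append(f"[{a.left} {a.relation.serialize()} {a.right}]")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Newick ingestion and clade label generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelPolicy:
    """Naming convention for unlabeled internal nodes: append
    ``_Clade1``, ``_Clade2``, ... to the nearest labeled ancestor,
    numbering depth-first, siblings ordered by the alphabetically first
    labeled name in their subtree."""

    suffix_base: str = "_Clade"


def generate_clade_labels(tree: SourceTree, policy: LabelPolicy = LabelPolicy()) -> SourceTree:
    """Replace ``_unnamed_*`` placeholder names with generated clade labels."""

    def unlabeled(n: str) -> bool:
        return n.startswith(_UNNAMED_PREFIX)

    if unlabeled(tree.root):
        raise TreeError("root must be labeled")

    rename: Dict[str, str] = {}

    def subtree_min_label(n: str) -> str:
        labels = [
            x for x in tree.subtree(n) if not unlabeled(x)
        ]
        return min(labels) if labels else "~"

    def assign_from(labeled: str) -> None:
        counter = 0

        def walk(children: Sequence[str]) -> None:
            nonlocal counter
            unl = sorted(
                (c for c in children if unlabeled(c)), key=subtree_min_label
            )
            for c in unl:
                counter += 1
                rename[c] = f"{labeled}{policy.suffix_base}{counter}"
                walk(tree.children(c))

        walk(tree.children(labeled))

    for n in tree.concepts:
        if not unlabeled(n) and tree.children(n):
            assign_from(n)

    missing = [n for n in tree.concepts if n.startswith(_UNNAMED_PREFIX) and n not in rename]
    if missing:  # pragma: no cover - defensive; every unlabeled node has a labeled ancestor
        raise TreeError(f"could not label {missing}")

    def nm(n: str) -> str:
        return rename.get(n, n)

    children = {
        nm(p): [nm(c) for c in tree.children(p)]
        for p in tree.concepts
        if tree.children(p)
    }
    return SourceTree(
        tree.tag, children, [nm(p) for p in tree.uncovered_parents],
        {nm(n) for n in tree.nc_names},
    )


def ingest_newick(
    newick_text: str, tag: str, policy: LabelPolicy = LabelPolicy()
) -> SourceTree:
    """Build a SourceTree from a rooted Newick string; branch lengths and
    support values are discarded, unlabeled internals receive generated
    clade labels."""
    try:
        dtree = dendropy.Tree.get(data=newick_text, schema="newick")
    except Exception as exc:
        raise TreeError(f"{tag}: invalid newick ({exc})") from exc
    return source_tree_from_dendropy(dtree, tag, policy)


def source_tree_from_dendropy(
    dtree: "dendropy.Tree", tag: str, policy: LabelPolicy = LabelPolicy()
) -> SourceTree:
    counter = 0
    names: Dict[int, str] = {}
    seen_leaves = set()
    for node in dtree.preorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label if node.taxon else node.label
            if not name:
                raise TreeError(f"{tag}: unlabeled leaf")
            name = name.replace(" ", "_")
            if name in seen_leaves:
                raise TreeError(f"{tag}: duplicate leaf name {name!r}")
            seen_leaves.add(name)
        else:
            name = node.label
            if name:
                name = name.replace(" ", "_")
            else:
                counter += 1
                name = f"{_UNNAMED_PREFIX}{counter}"
        names[id(node)] = name
    children = {}
    for node in dtree.preorder_node_iter():
        kids = node.child_nodes()
        if kids:
            children[names[id(node)]] = [names[id(k)] for k in kids]
    if not children:
        raise TreeError(f"{tag}: tree has no internal structure")
    tree = SourceTree(tag, children)
    if names[id(dtree.seed_node)].startswith(_UNNAMED_PREFIX):
        raise TreeError("root must be labeled")
    return generate_clade_labels(tree, policy)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_mir_csv(mir) -> str:
    """``left,right,relation`` rows, sorted; UTF-8/LF by convention."""
    lines = ["left,right,relation"]
    for (a, b) in sorted(mir.entries):
        lines.append(f"{a},{b},{mir.entries[(a, b)].serialize()}")
    return "\n".join(lines) + "\n"


def read_mir_csv(text: str):
    from .reasoner import MIR  # local import to avoid a cycle

    entries = {}
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines or lines[0] != "left,right,relation":
        raise ValueError("expected header 'left,right,relation'")
    for line in lines[1:]:
        left, right, rel = line.split(",", 2)

        def lbl(tok: str) -> ConceptLabel:
            tag, _, name = tok.partition(".")
            return ConceptLabel(tag, name, is_nc_region=name.startswith(NC_PREFIX))

        entries[(lbl(left), lbl(right))] = RelationSet.parse(rel)
    return MIR(entries)


_DOT_STYLE = {
    # figure-legend conventions: first source green boxes, second source
    # yellow octagons, congruent clusters gray rounded boxes, split-product
    # regions without input labels salmon
    "first": 'shape=box, style=filled, fillcolor="#ccffcc"',
    "second": 'shape=octagon, style=filled, fillcolor="#ffffcc"',
    "congruent": 'shape=box, style="rounded,filled", fillcolor="#dddddd"',
    "split": 'shape=box, style=filled, fillcolor="#ffc0a0"',
}


def write_dot(graph, title: str = "alignment") -> str:
    """Render a region graph (see resolution.build_regions) as DOT text:
    solid arrows for inclusion, dashed blue lines for overlap."""
    lines = [f'digraph "{title}" {{', "  rankdir=BT;", '  node [fontsize=10];']
    first_tag = graph.source_order[0]
    for region in sorted(graph.regions, key=lambda r: r.sort_key):
        if region.kind == "congruent":
            style = _DOT_STYLE["congruent"]
        elif region.kind == "split_product":
            style = _DOT_STYLE["split"]
        else:
            tag = next(iter(region.member_labels)).source_tag
            style = _DOT_STYLE["first" if tag == first_tag else "second"]
        label = "\\n".join(region.display_labels())
        lines.append(f'  "{region.region_id}" [label="{label}", {style}];')
    for lo, hi in sorted(graph.inclusion_edges):
        lines.append(f'  "{lo}" -> "{hi}";')
    for a, b in sorted(graph.overlap_edges):
        lines.append(
            f'  "{a}" -> "{b}" [dir=none, style=dashed, color=blue, constraint=false];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_newick_annotated(dtree: "dendropy.Tree", statuses: Dict[str, str]) -> str:
    """Newick with per-internal-node ``[&status=...]`` comments."""

    def render(node) -> str:
        if node.is_leaf():
            return (node.taxon.label if node.taxon else node.label or "").replace(" ", "_")
        inner = ",".join(render(c) for c in node.child_nodes())
        name = (node.label or "").replace(" ", "_")
        status = statuses.get(name or id(node))
        comment = f"[&status={status}]" if status else ""
        return f"({inner}){name}{comment}"

    return render(dtree.seed_node) + ";"
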