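"""Reconstructed and generated alignment inputs.

The neoavian-explosion use case aligns two phylogenomic reconstructions of
higher-level bird relationships, tagged ``2015`` (Prum et al.) and ``2014``
(Jarvis et al.).  The supra-ordinal topologies are reconstructed from the
published clade-concept label tables; the parrot (Psittaciformes) example
illustrates strict vs locally relaxed coverage; the Neoaves "zoom" is the
main conflict region.  A deterministic synthetic-partition builder and a
random generator with known ground truth round out the catalog.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .model import (
    AlignmentProblem,
    Articulation,
    ConceptLabel,
    Options,
    SourceTree,
)
from .reasoner import WitnessModel, encode
from .relations import Relation, RelationSet, base_relation_of_sets

_EQ = RelationSet.of(Relation.EQ)
_EX = RelationSet.of(Relation.EX)
_LT = RelationSet.of(Relation.LT)


# ---------------------------------------------------------------------------
# Supra-ordinal topologies of the two bird phylogenies
# ---------------------------------------------------------------------------

#: 41 supra-ordinal clade concepts of the 2015 reconstruction with their
#: immediate children (order-level and a few family-level children appear
#: only as terminals here).
TABLE_2015: Dict[str, Tuple[str, ...]] = {
    "Neornithes": ("Palaeognathae", "Neognathae"),
    "Palaeognathae": ("Notopalaeognathae", "Struthioniformes"),
    "Notopalaeognathae": ("Novaeratitae", "Rheiformes"),
    "Novaeratitae": ("Apterygiformes", "Novaeratitae_Clade1"),
    "Novaeratitae_Clade1": ("Casuariiformes", "Tinamiformes"),
    "Neognathae": ("Galloanserae", "Neoaves"),
    "Galloanserae": ("Anseriformes", "Galliformes"),
    "Neoaves": ("Strisores", "Neoaves_Clade1"),
    "Strisores": ("Caprimulgidae", "Strisores_Clade1"),
    "Strisores_Clade1": ("Nyctibiidae", "Steatornithidae", "Strisores_Clade2"),
    "Strisores_Clade2": ("Apodiformes", "Aegothelidae", "Podargidae"),
    "Neoaves_Clade1": ("Columbaves", "Neoaves_Clade2"),
    "Columbaves": ("Columbimorphae", "Otidimorphae"),
    "Columbimorphae": ("Columbiformes", "Columbimorphae_Clade1"),
    "Columbimorphae_Clade1": ("Mesitornithiformes", "Pterocliformes"),
    "Otidimorphae": ("Musophagiformes", "Otidimorphae_Clade1"),
    "Otidimorphae_Clade1": ("Cuculiformes", "Otidiformes"),  # corrected; see below
    "Neoaves_Clade2": ("Gruiformes", "Neoaves_Clade3"),
    "Neoaves_Clade3": ("Aequorlitornithes", "Inopinaves"),
    "Aequorlitornithes": ("Aequorlitornithes_Clade1", "Ardeae"),
    "Aequorlitornithes_Clade1": ("Charadriiformes", "Phoenicopterimorphae"),
    "Phoenicopterimorphae": ("Phoenicopteriformes", "Podicipediformes"),
    "Ardeae": ("Aequornithia", "Phaethontimorphae"),
    "Aequornithia": ("Aequornithia_Clade1", "Gaviiformes"),
    "Aequornithia_Clade1": ("Pelecanimorphae", "Procellariimorphae"),
    "Pelecanimorphae": ("Ciconiiformes", "Pelecanimorphae_Clade1"),
    "Pelecanimorphae_Clade1": ("Pelecaniformes", "Suliformes"),
    "Procellariimorphae": ("Procellariiformes", "Sphenisciformes"),
    "Phaethontimorphae": ("Eurypygiformes", "Phaethontiformes"),
    "Inopinaves": ("Opisthocomiformes", "Telluraves"),
    "Telluraves": ("Accipitriformes", "Eutelluraves"),
    "Eutelluraves": ("Australaves", "Coracornithia"),
    "Australaves": ("Cariamiformes", "Eufalconimorphae"),
    "Eufalconimorphae": ("Falconiformes", "Passerimorphae"),
    "Passerimorphae": ("Passeriformes", "Psittaciformes"),
    "Coracornithia": ("Coraciimorphae", "Strigiformes"),
    "Coraciimorphae": ("Coliiformes", "Eucavitaves"),
    "Eucavitaves": ("Cavitaves", "Leptosomiformes"),
    "Cavitaves": ("Picocoraciae", "Trogoniformes"),
    "Picocoraciae": ("Bucerotiformes", "Picodynastornithes"),
    "Picodynastornithes": ("Coraciiformes", "Piciformes"),
}

#: The 2015 table's row for Otidimorphae_Clade1 as printed duplicates the
#: children of Columbimorphae_Clade1 (an apparent erratum: a tree cannot
#: give Mesitornithiformes two parents).  The corrected reading above
#: follows the 2014 analogue and the conflict-region narrative, which
#: require the two Otidimorphae_Clade1 concepts to share Otidiformes.
TABLE_2015_P17_PRINTED: Tuple[str, ...] = ("Mesitornithiformes", "Ptercoclidiformes")

#: 37 supra-ordinal clade concepts of the 2014 reconstruction.
TABLE_2014: Dict[str, Tuple[str, ...]] = {
    "Neornithes": ("Palaeognathae", "Neognathae"),
    "Palaeognathae": ("Struthioniformes", "Tinamiformes"),
    "Neognathae": ("Galloanseres", "Neoaves"),
    "Galloanseres": ("Anseriformes", "Galliformes"),
    "Neoaves": ("Columbea", "Passerea"),
    "Columbea": ("Columbimorphae", "Phoenicopterimorphae"),
    "Columbimorphae": ("Columbiformes", "Columbimorphae_Clade1"),
    "Columbimorphae_Clade1": ("Mesitornithiformes", "Pterocliformes"),
    "Phoenicopterimorphae": ("Phoenicopteriformes", "Podicipediformes"),
    "Passerea": ("Passerea_Clade1", "Passerea_Clade4"),
    "Passerea_Clade1": ("Passerea_Clade2", "Passerea_Clade3"),
    "Passerea_Clade2": ("Ardeae", "Telluraves"),
    "Ardeae": ("Aequornithia", "Phaethontimorphae"),
    "Aequornithia": ("Aequornithia_Clade1", "Gaviimorphae"),
    "Aequornithia_Clade1": ("Pelecanimorphae", "Procellariimorphae"),
    "Pelecanimorphae": ("Pelecaniformes",),
    "Procellariimorphae": ("Procellariiformes", "Sphenisciformes"),
    "Gaviimorphae": ("Gaviiformes",),
    "Phaethontimorphae": ("Eurypygiformes", "Phaethontiformes"),
    "Telluraves": ("Afroaves", "Australaves"),
    "Afroaves": ("Accipitrimorphae", "Coracornithia"),
    "Accipitrimorphae": ("Accipitriformes",),
    "Coracornithia": ("Coraciimorphae", "Strigiformes"),
    "Coraciimorphae": ("Coliiformes", "Eucavitaves"),
    "Eucavitaves": ("Cavitates", "Leptosomiformes"),
    "Cavitates": ("Picocoraciae", "Trogoniformes"),
    "Picocoraciae": ("Bucerotiformes", "Picodynastornithes"),
    "Picodynastornithes": ("Coraciiformes", "Piciformes"),
    "Australaves": ("Cariamiformes", "Eufalconimorphae"),
    "Eufalconimorphae": ("Falconiformes", "Passerimorphae"),
    "Passerimorphae": ("Passeriformes", "Psittaciformes"),
    "Passerea_Clade3": ("Cursorimorphae", "Opisthocomiformes"),
    "Cursorimorphae": ("Charadriiformes", "Gruiformes"),
    "Passerea_Clade4": ("Caprimulgimorphae", "Otidimorphae"),
    "Caprimulgimorphae": ("Caprimulgiformes",),
    "Otidimorphae": ("Cuculiformes", "Otidimorphae_Clade1"),
    "Otidimorphae_Clade1": ("Musophagiformes", "Otidiformes"),
}


def fixture_tables_1_2(p17: str = "corrected") -> Tuple[SourceTree, SourceTree]:
    """The two supra-ordinal bird hierarchies (41 and 37 labeled concepts
    plus their order-level terminal children).

    ``p17="printed"`` reproduces the published Otidimorphae_Clade1 row
    verbatim, which assigns two parents to Mesitornithiformes and therefore
    raises a tree error; ``"corrected"`` (default) uses the reading
    required by the conflict-region analyses.
    """
    if p17 not in ("corrected", "printed"):
        raise ValueError(p17)
    t1 = dict(TABLE_2015)
    if p17 == "printed":
        t1["Otidimorphae_Clade1"] = TABLE_2015_P17_PRINTED
    return SourceTree("2015", t1), SourceTree("2014", TABLE_2014)


# ---------------------------------------------------------------------------
# Psittaciformes (parrot) fixtures
# ---------------------------------------------------------------------------

# Exemplar species named in the study; the three remaining 2015 genera and
# their species are deterministic placeholders (the source text does not
# enumerate them) - they only carry concept counts, not taxon identity.
_P2015_GENERA = [
    ("Nestor", "Nestor_meridionalis"),
    ("Probosciger", "Probosciger_aterrimus"),
    ("Psittacus", "Psittacus_erithacus"),
    ("Psittacidae_gen1", "Psittacidae_gen1_sp1"),
    ("Psittacidae_gen2", "Psittacidae_gen2_sp1"),
    ("Psittacidae_gen3", "Psittacidae_gen3_sp1"),
]


def fixture_psittaciformes(variant: str = "strict") -> AlignmentProblem:
    """The parrot alignment of the coverage illustration.

    Both sources place the deep-branching Nestor lineage outside their
    Psittacidae, so the order, family and Nestor regions stay distinct
    (the relaxed alignment shows three separate congruent clusters).  The
    2015 tree has 18 concepts (order, Nestor + species, family, four
    unnamed internal clades, five family genera, five species); the 2014
    tree has 6 (order, family, genus Melopsittacus + species, Nestor +
    species).  ``strict``: coverage everywhere, eight species-level
    exclusion articulations against the other source's order.
    ``relaxed``: coverage off for both families and both Nestor concepts
    (four nc regions), eight species-membership inclusions and three
    higher-level congruences.
    """
    if variant not in ("strict", "relaxed"):
        raise ValueError(variant)
    children_2015: Dict[str, List[str]] = {
        "Psittaciformes": ["Nestor", "Psittacidae"],
        "Psittacidae": ["Probosciger", "Psittacidae_Clade1"],
        "Psittacidae_Clade1": ["Psittacus", "Psittacidae_Clade2"],
        "Psittacidae_Clade2": ["Psittacidae_gen1", "Psittacidae_Clade3"],
        "Psittacidae_Clade3": ["Psittacidae_gen2", "Psittacidae_Clade4"],
        "Psittacidae_Clade4": ["Psittacidae_gen3"],
    }
    for genus, species in _P2015_GENERA:
        children_2015[genus] = [species]
    children_2014 = {
        "Psittaciformes": ["Psittacidae", "Nestor"],
        "Psittacidae": ["Melopsittacus"],
        "Melopsittacus": ["Melopsittacus_undulatus"],
        "Nestor": ["Nestor_notabilis"],
    }
    species_2015 = [s for _, s in _P2015_GENERA]
    species_2014 = ["Melopsittacus_undulatus", "Nestor_notabilis"]

    if variant == "strict":
        t15 = SourceTree("2015", children_2015)
        t14 = SourceTree("2014", children_2014)
        arts = [
            Articulation(t15.label(s), t14.label("Psittaciformes"), _EX)
            for s in species_2015
        ] + [
            Articulation(t15.label("Psittaciformes"), t14.label(s), _EX.converse())
            for s in species_2014
        ]
        return AlignmentProblem([t15, t14], arts)

    t15 = SourceTree("2015", children_2015, uncovered=["Psittacidae", "Nestor"])
    t14 = SourceTree("2014", children_2014, uncovered=["Psittacidae", "Nestor"])
    arts = [
        Articulation(t15.label(s), t14.label("Psittacidae"), _LT)
        for s in species_2015
        if s != "Nestor_meridionalis"
    ]
    arts.append(Articulation(t15.label("Nestor_meridionalis"), t14.label("Nestor"), _LT))
    arts.append(
        Articulation(t15.label("Psittacidae"), t14.label("Melopsittacus_undulatus"), _LT.converse())
    )
    arts.append(
        Articulation(t15.label("Nestor"), t14.label("Nestor_notabilis"), _LT.converse())
    )
    for name in ("Psittaciformes", "Psittacidae", "Nestor"):
        arts.append(Articulation(t15.label(name), t14.label(name), _EQ))
    return AlignmentProblem([t15, t14], arts)


# ---------------------------------------------------------------------------
# The Neoaves conflict-region ("zoom") fixture
# ---------------------------------------------------------------------------

_ZOOM_2015_TERMINALS = (
    "Strisores",
    "Columbimorphae",
    "Musophagiformes",
    "Cuculiformes",
    "Otidiformes",
    "Gruiformes",
    "Charadriiformes",
    "Phoenicopterimorphae",
    "Ardeae",
    "Opisthocomiformes",
    "Telluraves",
)

#: Congruent terminal pairs of the zoom alignment (2015 name, 2014 name).
ZOOM_CONGRUENCES: Tuple[Tuple[str, str], ...] = (
    ("Strisores", "Caprimulgimorphae"),
    ("Columbimorphae", "Columbimorphae"),
    ("Musophagiformes", "Musophagiformes"),
    ("Cuculiformes", "Cuculiformes"),
    ("Otidiformes", "Otidiformes"),
    ("Gruiformes", "Gruiformes"),
    ("Charadriiformes", "Charadriiformes"),
    ("Phoenicopterimorphae", "Phoenicopterimorphae"),
    ("Ardeae", "Ardeae"),
    ("Opisthocomiformes", "Opisthocomiformes"),
    ("Telluraves", "Telluraves"),
)


def _zoom_tree(table: Dict[str, Tuple[str, ...]], root: str, terminals: Sequence[str], tag: str) -> SourceTree:
    keep: Dict[str, List[str]] = {}
    stack = [root]
    while stack:
        n = stack.pop()
        if n in terminals:
            continue
        kids = list(table[n])
        keep[n] = kids
        stack.extend(kids)
    return SourceTree(tag, keep)


def fixture_neoaves_zoom() -> AlignmentProblem:
    """The main neoavian conflict region: both supra-ordinal trees
    restricted below (and including) Neoaves down to the ordinal level,
    21 concepts per side, with the congruent terminal pairs articulated
    and all other terminal pairs exclusive."""
    t2015_full, t2014_full = fixture_tables_1_2("corrected")
    t15 = _zoom_tree(TABLE_2015, "Neoaves", _ZOOM_2015_TERMINALS, "2015")
    terminals_2014 = tuple(b for _, b in ZOOM_CONGRUENCES)
    t14 = _zoom_tree(TABLE_2014, "Neoaves", terminals_2014, "2014")
    arts = [
        Articulation(t15.label(a), t14.label(b), _EQ) for a, b in ZOOM_CONGRUENCES
    ]
    matched = dict(ZOOM_CONGRUENCES)
    for a in t15.terminals:
        for b in t14.terminals:
            if matched[a] != b:
                arts.append(Articulation(t15.label(a), t14.label(b), _EX))
    return AlignmentProblem([t15, t14], arts)


# ---------------------------------------------------------------------------
# Deterministic synthetic partition problems
# ---------------------------------------------------------------------------


def synthetic_partition(
    n_left: int,
    n_right: int,
    nc_right: int,
    matched: int,
    extra_left: int,
    seed: int = 0,
    tags: Tuple[str, str] = ("T1", "T2"),
) -> AlignmentProblem:
    """A consistent two-tree problem with exact concept counts, emulating
    the bottom-up partition recipe: sampled terminals matched one-to-one by
    congruence, surplus first-tree terminals placed into relaxed-coverage
    parents of the second tree (inclusion plus exclusions from its sampled
    terminals), and congruent roots.  The resulting alignment has a single
    possible world, so the MIR size is the concept-count product.

    ``n_right`` includes the ``nc_right`` materialized nc regions.
    """
    if min(n_left, n_right, matched) < 1 or nc_right < 0 or extra_left < 0:
        raise ValueError("invalid sizes")
    if nc_right and extra_left < nc_right:
        raise ValueError("need at least one surplus left terminal per nc region")
    internals_left = n_left - matched - extra_left
    base_right = n_right - nc_right
    chain_right = base_right - matched - 1 - nc_right
    if internals_left < 1 or chain_right < 0:
        raise ValueError("sizes do not admit a tree")
    rng = random.Random(seed)

    b_terms = [f"b{i}" for i in range(1, matched + 1)]
    a_terms = [f"a{i}" for i in range(1, matched + 1)]
    extras = [f"x{i}" for i in range(1, extra_left + 1)]
    rng.shuffle(a_terms)  # decouple name order from match order

    # right tree: root -> nc parents (one sampled terminal each) + chain
    right: Dict[str, List[str]] = {}
    nc_parents = [f"P{i}" for i in range(1, nc_right + 1)]
    root_kids = list(nc_parents)
    for i, p in enumerate(nc_parents):
        right[p] = [b_terms[i]]
    rest = b_terms[nc_right:]
    if chain_right:
        chain = [f"C{i}" for i in range(1, chain_right + 1)]
        root_kids.append(chain[0])
        slots: Dict[str, List[str]] = {c: [] for c in chain}
        if rest:
            slots[chain[-1]].append(rest[0])
            for i, t in enumerate(rest[1:]):
                slots[chain[i % chain_right]].append(t)
        for i, c in enumerate(chain):
            kids = slots[c][:]
            if i + 1 < len(chain):
                kids.insert(0, chain[i + 1])
            if not kids:
                raise ValueError("right chain too long for its terminals")
            right[c] = kids
    else:
        root_kids.extend(rest)
    if not root_kids:
        raise ValueError("right root would be childless")
    right["Broot"] = root_kids

    # left tree: caterpillar over matched + extra terminals
    left: Dict[str, List[str]] = {}
    l_terms = a_terms + extras
    chain = ["Aroot"] + [f"D{i}" for i in range(1, internals_left)]
    slots = {c: [] for c in chain}
    slots[chain[-1]].append(l_terms[0])
    for i, t in enumerate(l_terms[1:]):
        slots[chain[i % len(chain)]].append(t)
    for i, c in enumerate(chain):
        kids = slots[c][:]
        if i + 1 < len(chain):
            kids.insert(0, chain[i + 1])
        if not kids:
            raise ValueError("left chain too long for its terminals")
        left[c] = kids

    t_left = SourceTree(tags[0], left)
    t_right = SourceTree(tags[1], right, uncovered=nc_parents)
    arts = [Articulation(t_left.label("Aroot"), t_right.label("Broot"), _EQ)]
    for a, b in zip(a_terms, b_terms):
        arts.append(Articulation(t_left.label(a), t_right.label(b), _EQ))
    for j, x in enumerate(extras):
        p = nc_parents[j % nc_right] if nc_right else "Broot"
        arts.append(Articulation(t_left.label(x), t_right.label(p), _LT))
        for b in b_terms:
            arts.append(Articulation(t_left.label(x), t_right.label(b), _EX))
    problem = AlignmentProblem([t_left, t_right], arts)
    assert len(problem.trees[0]) == n_left and len(problem.trees[1]) == n_right
    return problem


def fixture_passeriformes_scale(seed: int = 0) -> AlignmentProblem:
    """Synthetic stand-in for the largest order-level partition: 148 x 22
    input concepts with seven relaxed-coverage parents on the smaller tree."""
    return synthetic_partition(
        n_left=148, n_right=22, nc_right=7, matched=7, extra_left=93, seed=seed
    )


def fixture_root_to_order_scale(seed: int = 0) -> AlignmentProblem:
    """Synthetic stand-in for the root-to-order alignment: 97 x 83 input
    concepts with four nc regions on the second tree."""
    return synthetic_partition(
        n_left=97, n_right=83, nc_right=4, matched=34, extra_left=4, seed=seed
    )


# ---------------------------------------------------------------------------
# Random problems with known ground truth
# ---------------------------------------------------------------------------


@dataclass
class GeneratedProblem:
    problem: AlignmentProblem
    ground_truth: WitnessModel
    seed: int


def _random_partition(
    rng: random.Random,
    tag: str,
    prefix: str,
    n_concepts: int,
    universe: Sequence[int],
    other_blocks: Optional[List[FrozenSet[int]]],
    overlap_rate: float,
) -> Tuple[Dict[str, List[str]], Dict[str, Set[int]]]:
    root = f"{prefix}0"
    ext: Dict[str, Set[int]] = {root: set(universe)}
    children: Dict[str, List[str]] = {}
    counter = 1
    while len(ext) < n_concepts:
        splittable = sorted(n for n in ext if n not in children and len(ext[n]) >= 2)
        if not splittable:
            break
        node = rng.choice(splittable)
        pts = sorted(ext[node])
        part = None
        if other_blocks is not None and rng.random() > overlap_rate:
            cands = [b for b in other_blocks if b < frozenset(pts) and b]
            if cands:
                part = set(rng.choice(sorted(cands, key=sorted)))
        if part is None:
            rng.shuffle(pts)
            cut = rng.randint(1, len(pts) - 1)
            part = set(pts[:cut])
        c1, c2 = f"{prefix}{counter}", f"{prefix}{counter + 1}"
        counter += 2
        ext[c1], ext[c2] = part, set(ext[node]) - part
        children[node] = [c1, c2]
    return children, ext


def generate_problem(
    seed: int,
    n_left: int = 7,
    n_right: int = 7,
    overlap_rate: float = 0.5,
    nc_rate: float = 0.0,
    n_points: Optional[int] = None,
    articulation_rate: float = 0.5,
    widen_rate: float = 0.2,
    tags: Tuple[str, str] = ("L", "R"),
) -> GeneratedProblem:
    """Draw a hidden universe and two random hierarchical partitions over
    it, derive the trees, sample a subset of true cross-source relations as
    articulations (occasionally widened to disjunctions), and optionally
    hide child subtrees behind relaxed coverage.  The hidden interpretation
    is returned as ground truth; everything is reproducible from the seed.
    """
    for name, rate in (
        ("overlap_rate", overlap_rate),
        ("nc_rate", nc_rate),
        ("articulation_rate", articulation_rate),
        ("widen_rate", widen_rate),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be within [0, 1]")
    if min(n_left, n_right) < 1:
        raise ValueError("concept counts must be >= 1")
    rng = random.Random(seed)
    n_points = n_points or 2 * max(n_left, n_right)
    universe = list(range(n_points))
    kids_l, ext_l = _random_partition(rng, tags[0], "L", n_left, universe, None, overlap_rate)
    blocks = [frozenset(v) for v in ext_l.values()]
    kids_r, ext_r = _random_partition(
        rng, tags[1], "R", n_right, universe, blocks, overlap_rate
    )

    def hide(children: Dict[str, List[str]], ext: Dict[str, Set[int]]):
        uncovered = []
        for parent in sorted(children):
            if len(children.get(parent, [])) >= 2 and rng.random() < nc_rate:
                victim = rng.choice(sorted(children[parent]))
                for d in _descendants(children, victim):
                    children.pop(d, None)
                    ext.pop(d, None)
                children[parent] = [c for c in children[parent] if c != victim]
                uncovered.append(parent)
        return uncovered

    unc_l = hide(kids_l, ext_l) if nc_rate else []
    unc_r = hide(kids_r, ext_r) if nc_rate else []
    t_left = SourceTree(tags[0], kids_l, unc_l) if kids_l else None
    if t_left is None:
        raise ValueError("left tree degenerated to a single concept; enlarge n_points")
    t_right = SourceTree(tags[1], kids_r, unc_r) if kids_r else None
    if t_right is None:
        raise ValueError("right tree degenerated to a single concept; enlarge n_points")

    extension: Dict[ConceptLabel, FrozenSet[int]] = {}
    for tree, ext in ((t_left.materialize_nc(), ext_l), (t_right.materialize_nc(), ext_r)):
        for name in tree.concepts:
            if name in tree.nc_names:
                parent = tree.parent(name)
                others = set().union(
                    set(),
                    *(ext[k] for k in tree.children(parent) if k != name),
                )
                extension[tree.label(name)] = frozenset(ext[parent] - others)
            else:
                extension[tree.label(name)] = frozenset(ext[name])

    arts: List[Articulation] = []
    mat_l, mat_r = t_left.materialize_nc(), t_right.materialize_nc()
    for x in mat_l.concepts:
        for y in mat_r.concepts:
            if rng.random() >= articulation_rate:
                continue
            a, b = mat_l.label(x), mat_r.label(y)
            true = base_relation_of_sets(extension[a], extension[b])
            members = {true}
            if rng.random() < widen_rate:
                members.add(rng.choice(list(Relation)))
            arts.append(Articulation(a, b, RelationSet(members)))

    problem = AlignmentProblem([t_left, t_right], arts)
    witness = WitnessModel(frozenset(universe), extension)
    bad = encode(problem).violations(extension)
    if bad:  # pragma: no cover - generator invariant
        raise AssertionError(f"generated witness invalid: {bad}")
    return GeneratedProblem(problem, witness, seed)


def _descendants(children: Dict[str, List[str]], node: str) -> List[str]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(children.get(n, []))
    return out


# ---------------------------------------------------------------------------
# Catalog (CLI entry point)
# ---------------------------------------------------------------------------

FIXTURES = {
    "psittaciformes-strict": lambda seed=0: fixture_psittaciformes("strict"),
    "psittaciformes-relaxed": lambda seed=0: fixture_psittaciformes("relaxed"),
    "tables-1-2": lambda seed=0: AlignmentProblem(list(fixture_tables_1_2())),
    "neoaves-zoom": lambda seed=0: fixture_neoaves_zoom(),
    "passeriformes-scale": fixture_passeriformes_scale,
    "root-to-order-scale": fixture_root_to_order_scale,
    "random": lambda seed=0: generate_problem(seed).problem,
}
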