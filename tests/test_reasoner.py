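"""Consistency, possible worlds, MIR inference and the partition helper."""

import pytest

from rcc5align.fixtures import fixture_psittaciformes, generate_problem
from rcc5align.model import (
    AlignmentProblem,
    Articulation,
    ConceptLabel,
    Options,
    SourceTree,
)
from rcc5align.reasoner import (
    InconsistentProblemError,
    check_consistency,
    encode,
    enumerate_worlds,
    infer_mir,
    prune_and_propagate,
)
from rcc5align.relations import Relation, RelationSet, base_relation_of_sets

EQ = RelationSet.of(Relation.EQ)
EX = RelationSet.of(Relation.EX)


def _single_concept_problem(relation: RelationSet) -> AlignmentProblem:
    ta = SourceTree("A", {}, root="x")
    tb = SourceTree("B", {}, root="y")
    return AlignmentProblem(
        [ta, tb], [Articulation(ta.label("x"), tb.label("y"), relation)]
    )


class TestEncode:
    def test_covered_parent_equals_union_and_siblings_disjoint(self):
        p = AlignmentProblem(
            [SourceTree("A", {"P": ["a", "b"]}), SourceTree("B", {}, root="q")]
        )
        res = check_consistency(p)
        ext = res.witness.extension
        A = lambda n: ConceptLabel("A", n)
        assert ext[A("P")] == ext[A("a")] | ext[A("b")]
        assert not ext[A("a")] & ext[A("b")]

    def test_uncovered_parent_nc_region_is_nonempty_residue(self):
        p = AlignmentProblem(
            [
                SourceTree("A", {"P": ["a", "b"]}, uncovered=["P"]),
                SourceTree("B", {}, root="q"),
            ]
        )
        res = check_consistency(p)
        ext = res.witness.extension
        nc = ConceptLabel("A", "nc_P", is_nc_region=True)
        assert nc in ext and ext[nc]
        assert ext[nc] == ext[ConceptLabel("A", "P")] - (
            ext[ConceptLabel("A", "a")] | ext[ConceptLabel("A", "b")]
        )

    def test_single_covered_child_forces_congruence(self):
        ta = SourceTree("A", {"P": ["c"]})
        tb = SourceTree("B", {}, root="q")
        p = AlignmentProblem(
            [ta, tb], [Articulation(ta.label("c"), tb.label("q"), EQ)]
        )
        mir = infer_mir(p)
        assert mir.entry(ta.label("P"), tb.label("q")) == EQ

    def test_direct_evaluation_rejects_bad_witness(self):
        p = AlignmentProblem(
            [SourceTree("A", {"P": ["a", "b"]}), SourceTree("B", {}, root="q")]
        )
        ext = {
            ConceptLabel("A", "P"): frozenset({1}),
            ConceptLabel("A", "a"): frozenset({1}),
            ConceptLabel("A", "b"): frozenset({1}),  # siblings overlap
            ConceptLabel("B", "q"): frozenset({2}),
        }
        assert not encode(p).evaluate(ext)
        assert any("siblings" in v for v in encode(p).violations(ext))


class TestConsistency:
    def test_contradictory_articulations(self):
        ta = SourceTree("A", {}, root="x")
        tb = SourceTree("B", {}, root="y")
        p = AlignmentProblem(
            [ta, tb],
            [
                Articulation(ta.label("x"), tb.label("y"), EQ),
                Articulation(ta.label("x"), tb.label("y"), EX),
            ],
        )
        res = check_consistency(p)
        assert res.status == "inconsistent"
        assert res.conflict is not None and len(res.conflict) == 2

    def test_strict_parrot_fixture_is_consistent(self, psitta_strict):
        res = check_consistency(psitta_strict)
        assert res.status == "consistent"
        assert res.witness.satisfies(psitta_strict)

    @pytest.mark.parametrize("seed", range(5))
    def test_generated_problems_consistent_by_construction(self, seed):
        gp = generate_problem(seed, n_left=6, n_right=6, nc_rate=0.2)
        res = check_consistency(gp.problem)
        assert res.status == "consistent"
        assert gp.ground_truth.satisfies(gp.problem)

    def test_sibling_disjointness_switch(self):
        """With disjointness off, one concept may be congruent to two
        same-source siblings; with it on, that is contradictory."""
        ta = SourceTree("A", {}, root="x")
        tb = SourceTree("B", {"q": ["y", "z"]})
        arts = lambda ta, tb: [
            Articulation(ta.label("x"), tb.label("y"), EQ),
            Articulation(ta.label("x"), tb.label("z"), EQ),
        ]
        strict = AlignmentProblem([ta, tb], arts(ta, tb))
        assert check_consistency(strict).status == "inconsistent"
        loose = AlignmentProblem(
            [ta, tb], arts(ta, tb), Options(enforce_sibling_disjointness=False)
        )
        assert check_consistency(loose).status == "consistent"


class TestWorlds:
    def test_single_world(self):
        enum = enumerate_worlds(_single_concept_problem(EQ), limit=10)
        assert len(enum.worlds) == 1 and not enum.truncated

    def test_one_world_per_disjunct(self):
        enum = enumerate_worlds(
            _single_concept_problem(RelationSet.of(Relation.EQ, Relation.EX)), limit=10
        )
        assert len(enum.worlds) == 2 and not enum.truncated

    def test_limit_zero_rejected(self):
        with pytest.raises(ValueError):
            enumerate_worlds(_single_concept_problem(EQ), limit=0)

    def test_truncation_flagged(self):
        p = AlignmentProblem(
            [SourceTree("A", {"P": ["a", "b"]}), SourceTree("B", {"Q": ["c", "d"]})]
        )
        enum = enumerate_worlds(p, limit=3)
        assert enum.truncated and len(enum.worlds) == 3

    @pytest.mark.parametrize("seed", range(6))
    def test_world_count_matches_exhaustive_oracle(self, seed):
        gp = generate_problem(
            seed, n_left=4, n_right=4, n_points=5, articulation_rate=0.6
        )
        grid = enumerate_worlds(gp.problem, limit=4096, backend="grid")
        brute = enumerate_worlds(gp.problem, limit=4096, backend="exhaustive")
        assert not grid.truncated and not brute.truncated
        assert set(grid.worlds) == set(brute.worlds)


class TestMIR:
    def test_unconstrained_roots_full_disjunction(self):
        ta = SourceTree("A", {}, root="x")
        tb = SourceTree("B", {}, root="y")
        mir = infer_mir(AlignmentProblem([ta, tb], []))
        assert mir.entry(ta.label("x"), tb.label("y")) == RelationSet.full()

    def test_mir_size_is_concept_product(self, psitta_relaxed, psitta_relaxed_mir):
        na, nb = (len(t) for t in psitta_relaxed.trees)
        assert len(psitta_relaxed_mir) == na * nb == 160

    def test_inconsistent_problem_raises_with_diagnosis(self):
        ta = SourceTree("A", {}, root="x")
        tb = SourceTree("B", {}, root="y")
        p = AlignmentProblem(
            [ta, tb],
            [
                Articulation(ta.label("x"), tb.label("y"), EQ),
                Articulation(ta.label("x"), tb.label("y"), EX),
            ],
        )
        with pytest.raises(InconsistentProblemError) as exc:
            infer_mir(p)
        assert exc.value.diagnosis

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_small_problems(self, seed):
        """Grid-backend MIR equals exhaustive witness enumeration on
        problems with <= 8 concepts per side pair."""
        gp = generate_problem(
            seed, n_left=4, n_right=4, n_points=5, nc_rate=0.2, widen_rate=0.4
        )
        grid = infer_mir(gp.problem, backend="grid")
        brute = infer_mir(gp.problem, backend="exhaustive")
        assert grid.entries == brute.entries

    @pytest.mark.parametrize("seed", range(4))
    def test_source_swap_converse_symmetry(self, seed):
        gp = generate_problem(seed, n_left=4, n_right=5, n_points=6)
        mir = infer_mir(gp.problem)
        swapped = infer_mir(gp.problem.swapped())
        for (a, b), rel in mir.entries.items():
            assert swapped.entries[(b, a)] == rel.converse()

    @pytest.mark.parametrize("seed", range(3))
    def test_monotonicity_under_articulation_deletion(self, seed):
        gp = generate_problem(seed, n_left=4, n_right=4, n_points=5,
                              articulation_rate=0.7)
        p = gp.problem
        mir = infer_mir(p)
        for i in range(len(p.articulations)):
            weaker = infer_mir(p.without_articulation(i))
            for key, rel in mir.entries.items():
                assert rel <= weaker.entries[key]

    def test_input_articulations_are_entailed(self, psitta_relaxed, psitta_relaxed_mir):
        for art in psitta_relaxed.articulations:
            assert psitta_relaxed_mir.entry(art.left, art.right) <= art.relation

    @pytest.mark.parametrize("seed", range(3))
    def test_ground_truth_relation_always_realizable(self, seed):
        gp = generate_problem(seed, n_left=5, n_right=5, n_points=7, nc_rate=0.2)
        mir = infer_mir(gp.problem)
        for (a, b), rel in mir.entries.items():
            truth = base_relation_of_sets(
                gp.ground_truth.extension[a], gp.ground_truth.extension[b]
            )
            assert truth in rel

    @pytest.mark.parametrize("seed", range(3))
    def test_coverage_relaxation_preserves_consistency(self, seed):
        """Relaxing coverage weakens the parent=union constraint, so a
        consistent problem stays consistent (residues left anonymous)."""
        gp = generate_problem(seed, n_left=5, n_right=5, n_points=7)
        p = gp.problem
        relaxed_trees = [
            SourceTree(
                t.tag,
                {x: list(t.children(x)) for x in t.concepts if t.children(x)},
                uncovered=[x for x in t.concepts if t.children(x)],
            )
            for t in p.trees
        ]
        relaxed = AlignmentProblem(
            relaxed_trees,
            list(p.articulations),
            Options(materialize_nc_regions=False),
        )
        assert check_consistency(relaxed).status == "consistent"


class TestPrune:
    def test_prune_to_roots_installs_parent_articulation(self, psitta_relaxed,
                                                         psitta_relaxed_mir):
        keep = [
            ConceptLabel("2015", "Psittaciformes"),
            ConceptLabel("2014", "Psittaciformes"),
        ]
        pruned = prune_and_propagate(psitta_relaxed, psitta_relaxed_mir, keep)
        assert [len(t) for t in pruned.trees] == [1, 1]
        assert len(pruned.articulations) == 1
        assert pruned.articulations[0].relation == EQ

    def test_keep_all_strengthens_articulations_only(self, psitta_strict,
                                                     psitta_strict_mir):
        keep = [t.label(n) for t in psitta_strict.trees for n in t.concepts]
        pruned = prune_and_propagate(psitta_strict, psitta_strict_mir, keep)
        assert [len(t) for t in pruned.trees] == [len(t) for t in psitta_strict.trees]
        mir2 = infer_mir(pruned)
        assert mir2.entries == psitta_strict_mir.entries

    def test_not_up_closed_keep_rejected(self, psitta_strict, psitta_strict_mir):
        with pytest.raises(Exception, match="up-closed"):
            prune_and_propagate(
                psitta_strict, psitta_strict_mir, [ConceptLabel("2015", "Psittacidae")]
            )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_pruned_partition_reproduces_parent_level_mir(self, seed):
        gp = generate_problem(seed, n_left=7, n_right=7, n_points=10)
        p = gp.problem
        mir = infer_mir(p)
        keep = [
            t.label(n)
            for t in p.trees
            for n in t.concepts
            if len(t.ancestors(n)) <= 1
        ]
        pruned = prune_and_propagate(p, mir, keep)
        mir2 = infer_mir(pruned)
        for key, rel in mir2.entries.items():
            assert mir.entry(*key) == rel
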