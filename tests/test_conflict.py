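"""Overlap matrix, chains, refinements, name reliability, bipartitions."""

import dendropy
import pytest

from rcc5align.conflict import (
    annotate_conflict,
    bipartitions,
    chain_overlap_count,
    compare_with_rcc5,
    name_reliability,
    overlap_matrix,
    refinement_census,
)
from rcc5align.fixtures import generate_problem
from rcc5align.model import AlignmentProblem, Articulation, ConceptLabel, SourceTree
from rcc5align.reasoner import infer_mir
from rcc5align.relations import Relation, RelationSet

EQ = RelationSet.of(Relation.EQ)


def _tree(data: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=data, schema="newick")


class TestOverlapMatrix:
    def test_zoom_matrix_matches_published_totals(self, zoom_mir):
        m = overlap_matrix(zoom_mir)
        assert m.grand_total == 26
        assert m.row_totals[ConceptLabel("2015", "Aequorlitornithes")] == 6
        assert m.col_totals[ConceptLabel("2014", "Passerea")] == 6

    def test_overlap_free_alignment_empty(self, psitta_relaxed_mir):
        m = overlap_matrix(psitta_relaxed_mir)
        assert m.grand_total == 0 and not m.rows and not m.cols

    @pytest.mark.parametrize("seed", range(4))
    def test_grand_total_recounts_ov_entries(self, seed):
        mir = infer_mir(
            generate_problem(seed, n_left=6, n_right=6, n_points=9,
                             overlap_rate=0.9).problem
        )
        m = overlap_matrix(mir)
        direct = sum(
            1 for rel in mir.entries.values() if rel == RelationSet.of(Relation.OV)
        )
        assert m.grand_total == direct
        assert sum(m.row_totals.values()) == sum(m.col_totals.values()) == direct

    def test_frame_has_totals_margin(self, zoom_mir):
        df = overlap_matrix(zoom_mir).to_frame()
        assert df.loc["Totals", "Totals"] == 26


class TestChains:
    def test_mixed_source_chain_rejected(self, zoom_mir):
        with pytest.raises(ValueError, match="one source"):
            chain_overlap_count(
                zoom_mir,
                [ConceptLabel("2015", "Inopinaves"), ConceptLabel("2014", "Passerea")],
            )

    def test_concept_without_overlaps_counts_zero(self, zoom_mir):
        assert chain_overlap_count(zoom_mir, [ConceptLabel("2015", "Neoaves")]) == 0


class TestRefinements:
    def test_identical_trees_have_no_refinements(self):
        kids = {"P": ["a", "b", "c"]}
        ta, tb = SourceTree("X", kids), SourceTree("Y", kids)
        arts = [Articulation(ta.label(t), tb.label(t), EQ) for t in "abc"]
        p = AlignmentProblem([ta, tb], arts)
        census = refinement_census(infer_mir(p), p)
        assert census.left == census.right == 0

    def test_extra_internal_node_is_one_refinement(self):
        ta = SourceTree("X", {"r": ["x", "c"], "x": ["a", "b"]})
        tb = SourceTree("Y", {"r": ["a", "b", "c"]})
        arts = [Articulation(ta.label(t), tb.label(t), EQ) for t in "abc"]
        p = AlignmentProblem([ta, tb], arts)
        census = refinement_census(infer_mir(p), p)
        assert census.left == 1 and census.right == 0
        assert census.left_concepts == [ConceptLabel("X", "x")]


class TestNameReliability:
    def test_zoom_table_signals(self, zoom_mir):
        """The conflict region shows the published same-name overlap
        (Otidimorphae_Clade1) and different-name congruence
        (Strisores/Caprimulgimorphae)."""
        table = name_reliability(zoom_mir)
        assert table.ambiguous == 0
        assert table.analyzed == sum(table.counts.values()) == len(zoom_mir)
        assert table.counts[("same", Relation.OV)] == 1
        assert (
            ConceptLabel("2015", "Otidimorphae_Clade1"),
            ConceptLabel("2014", "Otidimorphae_Clade1"),
        ) in table.cells[("same", Relation.OV)]
        assert table.counts[("different", Relation.EQ)] == 1
        assert (
            ConceptLabel("2015", "Strisores"),
            ConceptLabel("2014", "Caprimulgimorphae"),
        ) in table.cells[("different", Relation.EQ)]
        unreliable = table.unreliable_pairs()
        assert len(unreliable) == 2

    def test_nc_entries_excluded(self, psitta_relaxed_mir):
        table = name_reliability(psitta_relaxed_mir)
        assert table.analyzed == 18 * 6  # 160 minus nc-involving entries

    def test_self_alignment_mass_forced(self):
        kids = {"P": ["a", "b"]}
        ta, tb = SourceTree("X", kids), SourceTree("Y", kids)
        arts = [Articulation(ta.label(t), tb.label(t), EQ) for t in "ab"]
        table = name_reliability(infer_mir(AlignmentProblem([ta, tb], arts)))
        assert table.counts[("same", Relation.EQ)] == 3
        assert table.counts[("different", Relation.EX)] == 2
        assert table.counts.get(("same", Relation.OV)) is None
        assert not table.unreliable_pairs()


class TestBipartitions:
    def test_cherry_edge(self):
        edges = bipartitions(_tree("((a,b)ab,c)r;"), {"a", "b", "c"})
        (e,) = edges
        assert e.s_in == {"a", "b"} and e.s_out == {"c"} and e.informative

    def test_star_tree_has_no_informative_edges(self):
        edges = bipartitions(_tree("(a,b,c,d)r;"), {"a", "b", "c", "d"})
        assert not [e for e in edges if e.informative]

    def test_restriction_commutes(self):
        full = bipartitions(_tree("(((a,b)x,(c,d)y)w,e)r;"), {"a", "b", "c", "d", "e"})
        sub = bipartitions(_tree("(((a,b)x,(c,d)y)w,e)r;"), {"a", "c", "e"})
        by_id_full = {e.edge_id: e for e in full}
        for e in sub:
            assert e.s_in == by_id_full[e.edge_id].s_in & {"a", "c", "e"}


class TestAnnotateConflict:
    def test_identical_bipartition_is_concordant(self):
        ann = annotate_conflict(_tree("((a,b)ab,(c,d)cd)r;"),
                                _tree("((a,b)ab,(c,d)cd)r;"))
        assert ann["ab"].status == "concordant"
        assert not ann["ab"].conflicting

    def test_reciprocal_overlap_is_conflicting(self):
        ann = annotate_conflict(_tree("((a,b)ab,(c,d)cd)r;"),
                                _tree("((b,c)bc,(a,d)ad)r;"))
        assert ann["ab"].status == "conflicting"
        assert ann["cd"].status == "conflicting"

    def test_source_prefixes_stripped_for_matching(self):
        ann = annotate_conflict(
            _tree("((2015.a,2015.b)ab,2015.c)r;"),
            _tree("((2014.a,2014.b)ab2,2014.c)r2;"),
        )
        assert ann["ab"].status == "concordant"

    def test_tip_relabeling_invariance(self):
        base = annotate_conflict(_tree("((a,b)n1,(c,d)n2)r;"),
                                 _tree("((b,c)n3,(a,d)n4)r;"))
        sub = {"a": "w", "b": "x", "c": "y", "d": "z"}
        relabel = lambda s: "".join(sub.get(ch, ch) for ch in s)
        mapped = annotate_conflict(
            _tree(relabel("((a,b)n1,(c,d)n2)r;")), _tree(relabel("((b,c)n3,(a,d)n4)r;"))
        )
        assert {k: v.status for k, v in base.items()} == {
            k: v.status for k, v in mapped.items()
        }

    def test_no_shared_tips_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            annotate_conflict(_tree("((a,b)x,c)r;"), _tree("((p,q)y,s)t;"))

    def test_grafting_asymmetry(self):
        """With unmatched tips grafted high through a taxonomy, an edge
        concordant in one direction becomes conflicting in the other -
        the sampling-direction artifact of taxonomy-based placement."""
        dense = "(((a,b)ab,(c,e)ce)abce,d)Root;"
        sparse = "(((a,b)ab2,c)abc,d)Root;"
        # the taxonomy places the tip e (unsampled by the sparse tree)
        # directly under the root, far from its true sister c
        taxonomy = "((a,b)ab,c,d,e)Root;"
        fwd = annotate_conflict(_tree(sparse), _tree(dense))
        assert fwd["abc"].status == "concordant"
        grafted = annotate_conflict(_tree(dense), _tree(sparse), taxonomy=_tree(taxonomy))
        assert grafted["ce"].status == "conflicting"

    def test_never_both_with_same_alternative_edge(self):
        ann = annotate_conflict(
            _tree("(((a,b)ab,c)abc,(d,e)de)r;"), _tree("(((a,c)ac,b)acb,(d,e)de2)r;")
        )
        for v in ann.values():
            if v.concordant and v.conflicting:
                assert v.concordant_with != v.conflicting_with


class TestCompareWithRcc5:
    def _toy(self, overlap: bool):
        ta = SourceTree("X", {"r": ["p", "q"], "p": ["a", "b"], "q": ["c", "d"]})
        if overlap:
            tb = SourceTree("Y", {"r": ["p", "q"], "p": ["b", "c"], "q": ["a", "d"]})
        else:
            tb = SourceTree("Y", {"r": ["p", "q"], "p": ["a", "b"], "q": ["c", "d"]})
        arts = [Articulation(ta.label(t), tb.label(t), EQ) for t in "abcd"]
        return AlignmentProblem([ta, tb], arts)

    def test_congruent_pair_empty_report(self):
        p = self._toy(overlap=False)
        mir = infer_mir(p)
        ann = annotate_conflict(_tree("((a,b)p,(c,d)q)r;"), _tree("((a,b)p,(c,d)q)r;"))
        report = compare_with_rcc5(
            ann, mir, {ConceptLabel("X", "p"): "p", ConceptLabel("X", "q"): "q"}
        )
        assert not report.false_positives and not report.false_negatives
        assert len(report.agreements) == 2

    def test_true_overlap_agrees(self):
        p = self._toy(overlap=True)
        mir = infer_mir(p)
        ann = annotate_conflict(_tree("((a,b)p,(c,d)q)r;"), _tree("((b,c)p,(a,d)q)r;"))
        report = compare_with_rcc5(
            ann, mir, {ConceptLabel("X", "p"): "p", ConceptLabel("X", "q"): "q"}
        )
        assert not report.false_positives and not report.false_negatives

    def test_refinement_flagged_as_conflict_is_false_negative(self):
        """Differential sampling: the analyst places the unsampled tip a
        inside the alternative's bc clade via relaxed coverage, so the MIR
        reads X.ab as a congruent refinement (<) of Y.bc; the edge method,
        grafting a at the root through the taxonomy, reports conflict."""
        ta = SourceTree("X", {"r": ["ab", "cd"], "ab": ["a", "b"], "cd": ["c", "d"]})
        tb = SourceTree("Y", {"r": ["bc", "d"], "bc": ["b", "c"]}, uncovered=["bc"])
        arts = [
            Articulation(ta.label(t), tb.label(t), EQ) for t in "bcd"
        ] + [
            Articulation(ta.label("a"), tb.label("bc"), RelationSet.of(Relation.LT))
        ]
        p = AlignmentProblem([ta, tb], arts)
        mir = infer_mir(p)
        assert mir.entry(ConceptLabel("X", "ab"), ConceptLabel("Y", "bc")) == \
            RelationSet.of(Relation.LT)
        ann = annotate_conflict(
            _tree("((a,b)ab,(c,d)cd)r;"),
            _tree("((b,c)bc,d)r;"),
            taxonomy=_tree("(a,b,c,d)r;"),
        )
        assert ann["ab"].conflicting
        report = compare_with_rcc5(ann, mir, {ConceptLabel("X", "ab"): "ab"})
        assert report.false_negatives

    def test_unmapped_edges_warn(self):
        p = self._toy(overlap=False)
        mir = infer_mir(p)
        ann = annotate_conflict(_tree("((a,b)p,(c,d)q)r;"), _tree("((a,b)p,(c,d)q)r;"))
        report = compare_with_rcc5(ann, mir, {ConceptLabel("X", "p"): "nope"})
        assert report.warnings
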