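# Methods

## The model

`rcc5align` aligns two (or more) rooted *concept hierarchies* — taxonomies
or phylogenies whose every node is a source-qualified concept label such as
`2015.Neoaves` — using the five base relations of the Region Connection
Calculus: congruence `==`, proper inclusion `>`, inverse proper inclusion
`<`, overlap `><` and exclusion `!`. A concept is interpreted as a nonempty
region (a set of anonymous points); uncertainty is expressed by
disjunctions over the five relations, giving the 32-element lattice of
relation sets (we include both endpoints: the empty set as contradiction
and the full disjunction as "unknown").

A *witness* (possible world) assigns every concept a nonempty extension
such that:

1. each child is contained in its parent;
2. siblings are pairwise disjoint (switchable; on by default — trees
   partition their parents);
3. a *covered* parent equals the union of its children, an uncovered
   (`nocoverage`) parent may exceed it, the residue being the `nc_<parent>`
   region (this is how intensional, property-based node definitions are
   approximated: a parent may subsume children the source did not sample);
4. every input articulation's realized base relation belongs to its
   relation set.

The problem is *consistent* if a witness exists. The **MIR** (Maximally
Informative Relations) assign to every cross-source concept pair the set of
base relations realizable in some witness; equivalently, relation `r` is in
the entry for `(a, b)` iff the problem plus the assertion `a r b` is
consistent. The MIR always has exactly |C_A|·|C_B| entries, materialized
`nc_` regions included.

## Reasoning backends

No external solver is used; both backends are part of the package and must
agree (the test suite enforces this on randomized problems).

**Grid backend (default).** For sibling-disjoint trees every concept's
extension is the union of the *pseudo-terminals* beneath it: terminal
concepts (including materialized `nc_` regions, which make an uncovered
parent exactly covered again) plus one anonymous residue per uncovered
parent lacking an `nc_` child. Because only the emptiness/nonemptiness of
intersections matters in RCC-5, a world is fully described by a Boolean
occupancy grid over atom classes `(row, column)` where rows are the first
tree's pseudo-terminals plus "outside its root" and columns likewise for
the second tree (the both-outside cell is irrelevant and omitted). Concept
nonemptiness becomes an at-least-one clause per terminal row/column; an
articulation becomes a constraint over three aggregate bits — "shared
region occupied", "left-only occupied", "right-only occupied" — whose
allowed combinations are determined by the relation set (compiled per-bit
when the set is a product, via three Tseitin variables otherwise). The CNF
is solved by a small DPLL engine (two watched literals, chronological
backtracking). Worlds are enumerated with blocking clauses; distinct grids
correspond to distinct pairwise-relation signatures except on anonymous
residues, so signatures are deduplicated. MIR inference first tries full
world enumeration (cheap for well-specified alignments, which have one
world); past a probe limit (64 worlds) it falls back to the five
entailment queries per pair, seeding entries from every witness found —
results are identical to the naive method, only faster.

**Exhaustive backend (reference oracle).** Enumerates all occupancy
patterns over the atom classes directly and checks each candidate by plain
set evaluation of the constraint system (`encode(problem)`), with no
propagation or compilation involved; capped at 18 atom classes, beyond
which it reports an explicit resource-limit outcome rather than a silent
answer. It also covers the non-sibling-disjoint case (atom classes become
unions of root-to-atom chains), which the grid backend refuses; that
switch is therefore practical only at toy scale.

**Possible-world identity** is signature equality: two witnesses are the
same world iff they realize the same base relation for every concept pair
(within and across sources). Witness-set equality would distinguish worlds
that no RCC-5 statement can tell apart.

**Diagnosis.** For inconsistent problems with at most 24 articulations a
minimal conflicting articulation subset is found by deletion-based
minimization; above that the inconsistency is reported undiagnosed.

## Regions and split-concept resolution

Alignment graphs group concepts by identical extension in a chosen
witness (pairwise MIR alone does not fix triple-wise intersections; for
multi-world problems the CLI warns and names the witness used). Regions are
congruent clusters (labels from ≥ 2 sources), single-source regions, or —
under split-concept resolution — products of each overlapping pair
`{A*B, A\B, B\A}`, which always partition the union of the two extensions.
Product regions that coincide with no input concept's region are the
"novel" regions only the split syntax can name (salmon in DOT output).
Split labels are serialized with full concept labels (`2015.X * 2014.Y`,
`2015.X \ 2014.Y`), following the published tables rather than the
lower-case schematic `A\b`.

## Derived analyses

* **Overlap matrix / chains**: cross-tab of entries whose relation set is
  exactly `{><}` (established overlap; disjunctions containing `><` are
  not counted), with row/column totals sorted descending.
* **Refinement census**: non-terminal, non-`nc` concepts of one source
  congruent to nothing in the other but properly included in something —
  added resolution rather than conflict.
* **Name reliability**: 2×5 cross-tab of name-string equality (exact,
  case-sensitive — `Galloanserae` ≠ `Galloanseres`) against singleton MIR
  relations; `nc_` entries excluded, disjunctive entries counted in a
  separate ambiguous bucket (empty for single-world alignments).
* **Rooted-bipartition comparator**: each internal edge of a rooted tree
  defines `S_in | S_out` over the shared tips. An edge is *concordant*
  with an alternative edge when `B_in ⊆ A_in` and `B_out ⊆ A_out` — the
  subset is taken as improper, otherwise identical bipartitions would be
  neither concordant nor conflicting, contradicting the intended black
  "congruent backbone" reading; it *conflicts* when `A_in∩B_in`,
  `A_in∩B_out`, `B_in∩A_out` are all nonempty. Both flags are kept per
  edge; conflict takes reporting precedence. Restricted ingroups of size
  < 2 are uninformative. Optionally, tips absent from the alternative tree
  are grafted in as children of their nearest taxonomy ancestor whose name
  labels an alternative node — off by default, since such placement
  manufactures conflict (the sampling-direction asymmetry the comparator
  is meant to expose).

## Fixtures: what they emulate, and what they do not

* **Supra-ordinal bird tables** (41 + 37 labeled concepts): transcribed
  topologies of the two source phylogenies. The printed Otidimorphae row
  of the 2015 table duplicates another row's children — unrepresentable
  in a tree — so the package ships it verbatim (constructing it raises
  the two-parents error) alongside the corrected reading (children
  Cuculiformes, Otidiformes) required by the conflict-region results.
* **Psittaciformes**: both coverage variants at the published concept
  counts (18 × 6; 20 × 8 with four `nc_` regions). Exemplars beyond the
  species the text names are deterministic placeholders
  (`Psittacidae_gen1_sp1`, ...) that carry counts, not identity. Both
  sources place the deep-branching Nestor lineage outside Psittacidae so
  that order, family and Nestor remain three distinct congruent regions.
* **Neoaves zoom**: both trees below Neoaves at ordinal resolution (21
  each), eleven congruent terminal pairs, all other terminal pairs
  exclusive. The congruences alone already force a unique world; the
  exclusions are emitted anyway as part of the fixture contract.
* **Synthetic partitions** (148 × 22 with 7 relaxed parents; 97 × 83 with
  4): caterpillar topologies at the published concept counts, sampled
  terminals matched one-to-one, surplus terminals placed into
  relaxed-coverage parents, roots congruent — the bottom-up partition
  recipe under the assumption that terminal labels reliably signal
  congruence or exclusion. They reproduce the published MIR *sizes* (pure
  concept-count products); their topology is synthetic, so no other
  statistic of those alignments is meaningful.
* **Random generator**: hides a ground-truth witness (two random
  hierarchical partitions of one point universe), samples true relations
  as articulations (optionally widened to disjunctions), optionally
  deletes child subtrees behind `nocoverage`. Consistency is guaranteed by
  construction and the truth must appear in every MIR entry — the
  recovery property the tests exercise. Real alignments differ in having
  *expert-asserted*, possibly wrong or deliberately coarse articulations;
  passing on generated data shows soundness/completeness of the
  reasoning, not robustness to mis-assertion.

## Numerical and design choices

* Concepts, including materialized `nc_` regions, are nonempty; RCC-5 is
  undefined on empty regions, and the published MIR counts include `nc_`
  regions as ordinary concepts. Relaxation *without* materialization
  (`materialize_nc_regions=False`, also used for pruned problems) leaves
  the residue anonymous and possibly empty — a pure weakening.
* Child ⊆ parent is non-strict: a covered single-child parent is
  congruent with its child.
* Problems with three or more trees are reasoned per consecutive source
  pair; transitivity across pairs is exposed only through the composition
  table.
* The composition table is generated by brute force over a 4-point
  universe at import and re-derived over 5- and 6-point universes in the
  tests.
* Problem sizes in tests are chosen so the exhaustive oracle (2^atoms
  candidates) stays at ≤ 15 atom classes; oracle-equivalence suites use
  ≤ 8 concepts per side pair.

## Known limitations

* Pruning a parent that keeps an `nc_` child while losing other children
  folds the lost region into the `nc_` residue on reserialization; the
  distinction between "unsampled" and "pruned" residue is not preserved.
* The non-sibling-disjoint switch is supported only by the exhaustive
  backend and hence only at toy scale.
* The comparator's concordance/conflict definitions follow the published
  edge rules; how the original method resolves an edge that is concordant
  with one alternative edge and conflicting with another is not specified
  there, so both flags are reported.
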