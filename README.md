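# rcc5align

Logic-based alignment of conflicting phylogenomic and taxonomic concept
hierarchies with the five-relation Region Connection Calculus (RCC-5).

## The problem

Independent phylogenomic studies publish strongly conflicting hierarchies
for the same group — the textbook case being the "neoavian explosion",
where two landmark bird phylogenies disagree on the earliest divergences
within Neoaves. Because a name like *Pelecaniformes* means different
things in different studies, synthesis needs *concepts* (`2015.X` vs
`2014.X`), not names. `rcc5align` takes two (or more) rooted concept
hierarchies plus expert articulations in RCC-5 — congruence `==`,
proper inclusion `>` / `<`, overlap `><`, exclusion `!`, and disjunctions
like `{== or <}` for uncertainty — and answers, by exact logical
reasoning over set interpretations:

* are the inputs jointly consistent (is there a "possible world")?
* for **every** cross-source concept pair, which relations remain
  possible — the *Maximally Informative Relations* (MIR)?
* how do the hierarchies decompose into congruent, source-only and
  overlapping regions, and how can overlap products be named
  (*split-concept resolution*: `A*B`, `A\B`, `B\A`)?

A per-parent *coverage* constraint (parent = union of its children) can be
relaxed locally (`nocoverage`), creating an `nc_` residue region; this
models intensionally defined parents whose children were only partially
sampled, and lets higher-level concepts attain congruence despite disjoint
terminal sampling. Companion analyses include overlap matrices and
overlap-chain counts, a congruent-refinement census, a clade-name
reliability cross-tab, and a rooted-bipartition (ingroup|outgroup)
concordance/conflict comparator for contrasting edge-based conflict calls
with the RCC-5 view.

It is aimed at systematists and builders of synthesis platforms who need
conflict *verbalized* — machine-readable statements of exactly where and
how reconstructions disagree.

## Worked example

The parrot alignment: 18 concepts in the densely sampled source, 6 in the
sparse one, species-level sampling completely disjoint. Under strict
coverage the exclusion propagates to the roots; relaxing coverage at four
lower-level parents recovers the intuitive higher-level congruences:

```python
from rcc5align import infer_mir
from rcc5align.fixtures import fixture_psittaciformes

strict = fixture_psittaciformes("strict")
mir = infer_mir(strict)
t15, t14 = strict.trees
print(len(mir))                                                  # 108
print(mir.entry(t15.label("Psittaciformes"),
                t14.label("Psittaciformes")).serialize())        # !

relaxed = fixture_psittaciformes("relaxed")
mir = infer_mir(relaxed)
t15, t14 = relaxed.trees
print(len(mir))                                                  # 160
for name in ("Psittaciformes", "Psittacidae", "Nestor"):
    print(name, mir.entry(t15.label(name), t14.label(name)).serialize())
# Psittaciformes ==
# Psittacidae ==
# Nestor ==
```

108 and 160 are the full MIR sizes (every cross-source pair, including the
four materialized `nc_` regions in the relaxed variant: 20 × 8). The same
pipeline from the shell, on the neoavian conflict region:

```
$ rcc5align fixtures neoaves-zoom --out zoom.txt
$ rcc5align align zoom.txt --mir zoom_mir.csv --dot zoom.dot --resolution split
consistency: consistent
possible worlds: 1
MIR entries: 441
split labels: 78 total, 15 novel regions
congruent region clusters: 13
```

441 = 21 × 21 pairs; the alignment is well specified (one possible
world); 26 of the entries are overlaps, whose 78 split-concept labels
name 15 regions that neither source phylogeny labels; 13 region clusters
are congruent across the sources. `rcc5align overlaps zoom_mir.csv --out
m.csv` writes the overlap matrix with row/column totals, and `rcc5align
names zoom_mir.csv --out t.csv` the name-reliability cross-tab.

Input problems use a small line dialect (`taxonomy` blocks of
`(parent child ...)` lists with `nocoverage` directives, `articulation`
blocks of `[2015.X == 2014.Y]` lines); rooted Newick trees can be
ingested directly, with unlabeled internal nodes named by the
`_Clade1`, `_Clade2`, ... convention.

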