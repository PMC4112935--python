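# Methods

## Molecule model and the extended query dialect

Compounds and queries share one in-memory model: 1-based indexed atoms, an
undirected bond list with integer orders 1–3, and per-atom element
constraints. Compound atoms are always exact element symbols; query atoms
may use the extended grammar `[!]SYMBOL(|SYMBOL)*[*]`:

* `X|Y|Z` — any of the listed elements;
* `!X` — any element except X (`!` may not combine with `|`; the
  single-element form is the only one the dialect defines);
* `A` — any element at all (the conventional query-atom symbol);
* trailing `*` — *contextual*: the atom must be matched for the group to be
  recognized but does not belong to the group's core. Contextual atoms are
  what separate a ketone carbonyl (flanked by two carbons) from an
  aldehyde's (one carbon, one hydrogen).

Aromatic bond type 4 is rejected with a diagnostic asking for Kekulé
structures: the adjacency matrices carry integer orders only, and implicit
valence arithmetic is ill-defined on "order 4" rings. Coordinates are
parsed and ignored — every algorithm here is connectivity-only.

## Implicit hydrogens and formulae

Database records usually omit hydrogens; queries may reference them, so
every compound is completed before searching. Target valences: C 4, N 3,
O 2, S 2, P 3, H 1, halogens 1, B 3. A formal charge (atom-block code or
`M  CHG` property line, the latter winning) shifts the target by its sign
for N and O (ammonium N binds 4, alkoxide O binds 1). No pH/pKa model:
molecules complete to neutral species unless the record says otherwise.
Elements outside the table get no hydrogens rather than a guess. The
procedure is idempotent and is validated continuously: every registered
reference compound must reach its literature formula and atom/bond counts,
and a bond over the target valence is a hard error naming the atom.

Formulae render in Hill order. Two renderings coexist deliberately: the
plain one (`CH4`, `C3H6O`) for human-facing output and the explicit-1 one
(`C1H4`, `C3H6O1`) inside extended formulae and database keys, where
unambiguous concatenation with group names matters. Queries normalize both.

## Mapping matrix, node coloring and m

For query B (b atoms) against compound A (a atoms), `M[i,j] = 1` when query
atom i may map to compound atom j under the selected constraint:

* `element_only` — the element constraint alone;
* `element_plus_degree` — additionally `degree_A(j) >= degree_B(i)`, the
  classic Ullmann node condition;
* `n_bond(N)` — equal neighborhood-refinement colors to depth N. Depth 0 is
  the element symbol; each round refines a color with the sorted multiset
  of (bond order, neighbor color) pairs, so equal depth-N+1 colors imply
  equal depth-N colors and candidate sets shrink monotonically with depth.

The *possible node mapping count* m sums M over non-contextual query rows
only. That convention is the one under which the reference table of m
values is internally consistent: contextual atoms (the alkene query's four
wildcard substituents, the ketone's flanking carbons) are matching
requirements, not search work attributable to the group core. An all-zero
row anywhere (contextual included) proves no isomorphism exists and skips
enumeration entirely, while m is still reported.

The degree constraint is OFF for m reporting (the reference m values count
elements only) and ON by default for enumeration, where it is a pure
pruning step: any valid induced mapping needs the compound atom to carry at
least the query atom's bonds, so pruning by degree cannot change the result
set. Coloring beyond depth 0 is reserved for whole-molecule comparison;
applying it to fragment queries would mis-color atoms whose neighborhoods
extend past the fragment boundary.

## Enumeration

Depth-first assignment over query atoms in descending-degree order (ties by
index), candidates in ascending compound-index order — any order is
correct; this one is the deterministic default and assigns the most
constrained atoms first. State lives in two vectors rather than copied
matrices: `v` maps query atoms to compound atoms (−1 while unmapped), `u`
flags compound atoms consumed by previously stored matches. Each tentative
assignment is checked against all already-mapped atoms for induced
equality — bond orders must match *and* non-bonds must map to non-bonds —
so invalid partial mappings prune immediately. Optional behaviors:

* `short_circuit` — return after the first valid mapping (existence
  questions, e.g. stereoisomer confirmation);
* `disjoint_counting` — after storing a mapping, its non-contextual image
  is marked in `u`. Exclusion applies only when assigning *non-contextual*
  query atoms, and is re-checked when a branch completes (branches that
  assigned their structural atoms before `u` changed would otherwise slip
  through, since mirror branches share their structural prefix in the
  DFS). Contextual atoms may match consumed atoms freely, which is why both
  carbonyls of 2,3-butanedione are found even though each is the other's
  flanking context;
* `initial_exclusions` — caller-supplied `u` entries, for layering searches
  on top of previously detected substructure.

Mirror-image duplicates (a symmetric anhydride matches twice) are *not*
suppressed during enumeration; classification handles them, keyed on the
core-atom set.

A deliberately naive matrix-copying enumerator (`ullmann_reference`) ships
as an independent oracle: per candidate it copies M, fixes one 1 in the
current row, recurses, and validates only at the leaves. It is exponential
on permissive queries — which is precisely why the vector engine exists —
so it guards against misuse above 25 compound atoms, and tests compare it
(and a pure product-space brute force) only on instances whose candidate
product fits a work budget; networkx's VF2 induced-subgraph matcher covers
the full test corpus as a third, library-independent oracle.

## Match classification and extended formulae

Two instances E, F relate through `O = core(E) ∩ core(F)`: disjoint
(O empty), mirror (O equals both cores), subgraph (O equals exactly one
core), else overlapping. Every mirror-deduplicated instance lands in
exactly one category, most specific first: mirror collapse, then subgraph,
then overlapping, then distinct. Cross-group and within-group instances
enter the same pairwise pass, so one compound can carry both a free
`Alcohol` and a `subgraph`-categorized alcohol inside its carboxylic acid.
Groups flagged *super* (umbrella patterns like alkyl halide that would
otherwise overlap every specific halide) are excluded from the relation
pass entirely: they always count distinct and never demote others.

One consequence worth knowing: the carboxylic-acid query's fourth carbon
substituent is a structural `!H` (the published group size, 5 atoms /
4 bonds with all rows counted, forces this), so on acetic acid the acid
core contains the methyl carbon and the acid instance is categorized
*overlapping* with the methyl instance. Counting scopes that include
overlapping and subgraph instances see the acid; the strictest
distinct-only scope does not. The six counting scopes (distinct through
distinct+subgraph+overlapping+super, plus super-only) exist exactly to
express these detection-permissiveness choices.

Extended formulae append `<Name><count>` segments (CamelCased group names,
alphabetical) to the explicit-1 formula: acetone against a ketone-only
library is `C3H6O1Ketone1`. The database stores the fully category-resolved
rendering (`Subgraph<Name>`/`Overlapping<Name>` segments) so any scope's
counts are regenerable.

## Database layer

SQLite, one file: a `compounds` table (formula, stored extended formula,
molfile text, serialized atom/bond lists, sizes), a long-format
`group_counts` table keyed (compound, group, category) — stable under
library changes, no per-group schema columns — and a `library` table with
the query molfiles, super flags and a fingerprint (SHA-256 of the ordered
name list). Incremental `add_entry` annotates against the stored library
and refuses a caller-supplied library whose fingerprint differs, because
subgraph/overlapping designations are relative to the whole library and a
changed list invalidates every stored count. Records without native ids get
a content hash of their canonical molfile.

## Stereoisomer detection

Candidate pairs share a basis key — (formula, bond count) or (extended
formula, bond count), both taken from the hydrogen-complete records — and
are confirmed by finding one bijective mapping with induced equality, i.e.
graph isomorphism, via the same engine with `short_circuit` and `n_bond`
coloring. Defaults: depth 2, escalating one shell when the candidate matrix
exceeds a configurable budget (2000), hydrogens omitted (heavy-atom
connectivity decides once formulae match; a property test pins result
invariance to both depth and omission). Connection tables carry no R/S or
E/Z information here, so confirmed pairs are "identical connectivity":
true stereoisomers and duplicate records are indistinguishable by
construction. The census reports the percentage of *compounds* in at least
one confirmed pair, not the pair count.

## Isomer statistics

A formula is isomeric when ≥ 2 entries carry it. (One published figure
legend describes the single-entry count as the isomeric one; the complement
implemented here is the only reading consistent with the plotted
percentages.) Percentages use two denominators — distinct formulae, and
entries — and the entry percentage runs ahead whenever a formula carries
more than two isomers, which a fixture with a three-entry formula pins.
The historical trend replays the census over growing id-sorted prefixes
(lexicographic ids, one step per percent; combined mode appends the next
slice of each source per step); the final point equals the full census by
construction.

## Strategy search

A strategy's signature per compound is (formula, transformed effective
count per group, groups in sorted order). Effective counts come from the
chosen scope; the transform models adduct chemistry: exact
(stoichiometric), 0/1/2/"3+" (pseudostoichiometric — one or two instances
resolve precisely, three or more saturate), or presence
(non-stoichiometric). Performance is the percentage of compounds with a
unique signature. Two provable orderings anchor the tests: adding a group
never merges signatures (monotonicity in the group set), and the three
transforms are successively coarser (stoichiometric ≥ pseudostoichiometric
≥ non-stoichiometric for any fixed strategy).

The beam search scores all singletons, keeps the top `keep_first` (50);
each later iteration expands every survivor with every group, drops
children whose improvement over their parent does not *exceed* `cutoff`
(0.1 percentage points — strict, so a `cutoff` of 100 can never be
cleared), deduplicates set-equal children globally across parents, keeps
the top `keep` (15), and stops after `iterations` (15) rounds or when no
child survives. Ranking everywhere: performance descending, then set size,
then lexicographic group list — reproducible tables. Greedy expansion can
in principle miss synergistic pairs whose singletons both fall below the
cutoff; `keep_first`/`keep` are exposed as parameters for exactly that
reason.

## Fixtures and what they do (not) show

The reference corpus encodes ~30 compounds from standard connectivities,
including the ten reference database compounds (two flagged: one printed
atom/bond pair is inconsistent with its own formula, and one printed m cell
disagrees with element arithmetic; both are excluded from hard assertions
and kept with self-consistent structures). The shipped 14-group library is
a representative, fully specified subset — the published 210-group library
is not public. Random molecules are seed-deterministic valence-legal
trees with occasional rings over C/N/O/S; they exercise the engine's
correctness envelope, not realistic chemistry (no aromatic systems, no
charged species, modest ring density). Planted databases carry their
ground truth alongside: which formulae are isomeric, which pairs are
connectivity-identical, and which group set separates which isomer pair.
Consequently, passing tests certify the algorithms and conventions on
exactly specified inputs; they say nothing about coverage of real HMDB/KEGG
chemistry (metals, organometallics, aromatic perception), which requires
user-supplied dumps through the documented `cass build-db` path.

Test and acceptance problem sizes — a 100-molecule random corpus capped at
25 atoms, reference compounds up to 55 atoms, 12-compound planted
databases — are chosen so the full suite runs in seconds while every
algorithmic branch (wildcards, contextual exclusion, mirror collapse,
coloring escalation) is exercised.
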