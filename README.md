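# cass — chemically aware substructure search

Ultra-high-resolution FT-MS gives a metabolite's molecular formula, but a
formula alone rarely names the compound: metabolite databases are full of
isomers sharing one formula. Chemoselective (CS) tagging adds a second,
orthogonal observable — which functional groups a metabolite carries, and
how many. This package implements the computational side of that workflow
for metabolomics and cheminformatics researchers:

* an **extended molfile dialect** for functional-group queries: atoms may be
  any-of several elements (`F|Cl|Br|I`), any-except (`!H`), or fully wild
  (`A`), and a trailing `*` marks *contextual* atoms that must be matched
  but are not counted as part of the group (so a ketone carbonyl is not
  confused with an aldehyde's);
* a **subgraph-isomorphism engine** over molecular graphs. A query B with
  `b` atoms against a compound A with `a` atoms is screened through a
  binary mapping matrix **M** (`b x a`), where `M[i,j] = 1` when query atom
  `i` may map onto compound atom `j`. The *possible node mapping count*
  `m = Σ M[i,j]` (non-contextual rows) predicts enumeration effort. The
  enumerator tracks state in two vectors — `v` (current atom assignments)
  and `u` (atoms consumed by previously stored matches) — validates induced
  bond-order equality `A_B[i,j] = A_A[v[i],v[j]]` incrementally, and can
  short-circuit at the first hit. A matrix-copying Ullmann-style enumerator
  ships alongside as an independent correctness oracle;
* **match classification**: overlapping instances are related through their
  core-atom sets (disjoint / mirror / subgraph / overlapping), mirror pairs
  (e.g. a symmetric anhydride) collapse to one count, and per-group counts
  append to the formula as an *extended formula* such as `C3H6O1Ketone1`;
* a **functional-group-resolved SQLite database** supporting formula and
  formula-plus-group queries and incremental entry addition pinned to a
  library fingerprint;
* **isomer and stereoisomer censuses** (identical-connectivity detection
  with n-bond node coloring and short-circuiting) and
* a **beam search over CS-tagging strategies** that scores a set of
  functional groups by the percentage of database compounds whose
  (formula, transformed group counts) signature is unique, under
  stoichiometric, pseudostoichiometric (0/1/2/"3+") or presence-only
  quantification.

## Worked example

```python
from cass import fixtures as fx
from cass.graph_core import mapping_matrix, ELEMENT_ONLY
from cass.match_classify import annotate

groups = {g.name: g for g in fx.build_group_library()}

mol = fx.build_compound("deoxycytidine")      # hydrogen-complete
print(mol.n_atoms, mol.n_bonds)               # 29 30

M = mapping_matrix(groups["carboxylic acid"].query, mol, ELEMENT_ONLY)
print(M.m)                                    # 46

ext, table = annotate(fx.build_compound("acetone"), [groups["ketone"]])
print(ext)                                    # C3H6O1Ketone1
```

2′-Deoxycytidine's heavy-atom connection table gains 13 implicit hydrogens
to reach 29 atoms and 30 bonds (C9H13N3O4). The 5-atom carboxylic-acid
query (C, O, O, H, `!H`) has 46 possible node mappings into it under
element-only screening — the work estimate before enumeration. Acetone
annotated against a ketone-only library carries exactly one ketone, giving
the extended formula `C3H6O1Ketone1`; the two mirror-image mappings of the
symmetric query collapse to one counted instance.

The same flows are scriptable from the shell:

```sh
cass fixtures --out corpus/                   # emit SDF + query library
cass build-db --sdf corpus/compounds.sdf --out metabolites.db
cass query --db metabolites.db --formula C3H6O1 --group ketone=1
cass stereo --db metabolites.db --report stereo.tsv
cass stats --db metabolites.db --trend
cass strategy --db metabolites.db --mode pseudostoichiometric --report s.tsv
```

Users with full database dumps (e.g. an HMDB SDF export) can run the same
pipeline on their own files via `cass build-db --sdf <dump.sdf>`; the
shipped corpus is a small, fully specified reference set.

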