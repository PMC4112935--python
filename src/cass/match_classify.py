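"""Classify functional-group matches and build extended formulae.

Two match instances E and F on the same compound are related through the
overlap of their *core* atom sets (images of non-contextual query atoms),
``O = core(E) ∩ core(F)``:

* ``O`` empty — disjoint;
* ``O`` equals both cores — mirror images of one substructure (a symmetric
  query such as an anhydride matches twice; mirrors collapse to one counted
  instance);
* ``O`` equals exactly one core — that instance is a *subgraph* of the
  other (the hydroxyl inside a carboxylic acid);
* otherwise — the two instances *overlap* without containment.

Every instance lands in exactly one category (mirror collapse first, then
subgraph, then overlapping, else distinct).  Groups flagged *super* (broad
umbrella patterns such as alkyl halide) neither receive nor confer
subgraph/overlapping designations.  Category counts append to the
molecular formula as the *extended formula*, e.g. ``C3H6O1Ketone1`` for
acetone against a ketone library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cass_search import MappingVector, SearchOptions, enumerate_isomorphisms
from .molfile_io import Molecule, molecular_formula

__all__ = [
    "FunctionalGroupDef",
    "MatchInstance",
    "GroupCountTable",
    "CountingScope",
    "find_instances",
    "relate",
    "tabulate",
    "extended_formula",
    "annotate",
]

CATEGORIES = ("distinct", "subgraph", "overlapping")


@dataclass(frozen=True)
class FunctionalGroupDef:
    name: str
    query: Molecule
    is_super: bool = False

    def __post_init__(self) -> None:
        if all(a.spec.contextual for a in self.query.atoms):
            raise ValueError(
                f"group {self.name!r} has no non-contextual atom"
            )

    @property
    def formula_token(self) -> str:
        """Name as it appears in extended formulae (no spaces)."""
        return "".join(part[:1].upper() + part[1:]
                       for part in self.name.split())


@dataclass(frozen=True)
class MatchInstance:
    group: str
    compound_id: str
    mapping: MappingVector
    core_atoms: frozenset[int]
    is_super: bool = False


@dataclass
class GroupCountTable:
    """Per-group counts by category after mirror deduplication."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def get(self, group: str, category: str) -> int:
        return self.counts.get(group, {}).get(category, 0)

    def add(self, group: str, category: str) -> None:
        row = self.counts.setdefault(
            group, {c: 0 for c in CATEGORIES}
        )
        row[category] += 1

    def total(self, group: str) -> int:
        return sum(self.counts.get(group, {}).values())


@dataclass(frozen=True)
class CountingScope:
    """Which categories (and which groups) contribute to effective counts."""

    categories: frozenset[str]
    include_super: bool = False
    super_only: bool = False

    def effective_count(
        self, table: GroupCountTable, group: str, is_super: bool
    ) -> int:
        if self.super_only:
            return table.total(group) if is_super else 0
        if is_super:
            return table.total(group) if self.include_super else 0
        return sum(table.get(group, c) for c in self.categories)


SCOPES: dict[str, CountingScope] = {
    "distinct": CountingScope(frozenset({"distinct"})),
    "distinct+overlapping": CountingScope(
        frozenset({"distinct", "overlapping"})
    ),
    "distinct+subgraph": CountingScope(frozenset({"distinct", "subgraph"})),
    "distinct+subgraph+overlapping": CountingScope(
        frozenset(CATEGORIES)
    ),
    "distinct+subgraph+overlapping+super": CountingScope(
        frozenset(CATEGORIES), include_super=True
    ),
    "super_only": CountingScope(frozenset(), super_only=True),
}


def find_instances(
    compound: Molecule, library: list[FunctionalGroupDef]
) -> list[MatchInstance]:
    """Full enumeration of every library group on one compound."""
    seen_names = set()
    for g in library:
        if g.name in seen_names:
            raise ValueError(f"duplicate group name {g.name!r}")
        seen_names.add(g.name)
    instances = []
    cid = compound.id or compound.name
    for group in library:
        for v in enumerate_isomorphisms(compound=compound, query=group.query,
                                        options=SearchOptions()):
            instances.append(
                MatchInstance(
                    group=group.name,
                    compound_id=cid,
                    mapping=v,
                    core_atoms=v.core_atoms(group.query),
                    is_super=group.is_super,
                )
            )
    return instances


def relate(E: MatchInstance, F: MatchInstance) -> str:
    """Relation between two instances: disjoint | mirror | E_subgraph_of_F |
    F_subgraph_of_E | overlapping."""
    if E.compound_id != F.compound_id:
        raise ValueError("instances come from different compounds")
    O = E.core_atoms & F.core_atoms
    if not O:
        return "disjoint"
    if len(O) == len(E.core_atoms) == len(F.core_atoms):
        return "mirror"
    if len(O) == len(E.core_atoms):
        return "E_subgraph_of_F"
    if len(O) == len(F.core_atoms):
        return "F_subgraph_of_E"
    return "overlapping"


def tabulate(
    instances: list[MatchInstance], library: list[FunctionalGroupDef]
) -> GroupCountTable:
    """Mirror-deduplicate, run the pairwise relation pass, count categories.

    Mirror dedup keys on (group, core atom set).  Super-group instances are
    excluded from the relation pass entirely: they always count as distinct
    and never push another instance into subgraph/overlapping.
    """
    names = {g.name for g in library}
    for inst in instances:
        if inst.group not in names:
            raise ValueError(f"instance of unknown group {inst.group!r}")

    deduped: list[MatchInstance] = []
    seen: set[tuple[str, frozenset[int]]] = set()
    for inst in instances:
        key = (inst.group, inst.core_atoms)
        if key in seen:
            continue
        seen.add(key)
        deduped.append(inst)

    table = GroupCountTable()
    participants = [i for i in deduped if not i.is_super]
    for inst in deduped:
        if inst.is_super:
            table.add(inst.group, "distinct")
            continue
        category = "distinct"
        overlapping = False
        for other in participants:
            if other is inst:
                continue
            rel = relate(inst, other)
            if rel == "E_subgraph_of_F":
                category = "subgraph"
                break
            if rel == "overlapping":
                overlapping = True
        if category == "distinct" and overlapping:
            category = "overlapping"
        table.add(inst.group, category)
    return table


def extended_formula(
    formula: str,
    table: GroupCountTable,
    library: list[FunctionalGroupDef],
    scope: CountingScope | str = "distinct",
) -> str:
    """Formula plus ``<Name><count>`` segments, names in alphabetical order.

    ``formula`` should use the explicit-1 rendering (``C3H6O1``); segments
    appear only for groups with a nonzero effective count under ``scope``.
    """
    if isinstance(scope, str):
        scope = SCOPES[scope]
    by_name = {g.name: g for g in library}
    segments = []
    for name in sorted(by_name):
        g = by_name[name]
        count = scope.effective_count(table, name, g.is_super)
        if count:
            segments.append(f"{g.formula_token}{count}")
    return formula + "".join(segments)


def annotate(
    compound: Molecule,
    library: list[FunctionalGroupDef],
    scope: CountingScope | str = "distinct",
) -> tuple[str, GroupCountTable]:
    """Extended formula and count table for one hydrogen-complete compound."""
    instances = find_instances(compound, library)
    table = tabulate(instances, library)
    formula = molecular_formula(compound, explicit_ones=True)
    return extended_formula(formula, table, library, scope), table
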