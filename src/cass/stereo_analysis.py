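"""Stereoisomer detection by whole-molecule connectivity comparison.

Two database entries are *potentially* stereoisomeric when they share a
molecular formula (or extended formula) and a bond count; such candidate
pairs are then confirmed by searching for one complete bijective atom
mapping preserving every bond order.  Connection tables carry no spatial
configuration here, so a confirmed pair is "identical connectivity" —
genuine stereoisomers and duplicate records are indistinguishable, as are
entries differing only in atom order.

The confirmation search uses neighborhood-refinement node coloring to
shrink the candidate mapping matrix and short-circuits at the first valid
mapping, since existence alone answers the question.  Hydrogens may be
dropped before the search (the default): when the hydrogen-complete
formulae already match, heavy-atom connectivity equality decides.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .cass_search import SearchOptions, enumerate_isomorphisms
from .fg_database import FGDatabase
from .graph_core import n_bond
from .molfile_io import Atom, Bond, Molecule, parse_molfile

__all__ = [
    "StereoPair",
    "candidate_pairs",
    "are_stereoisomeric",
    "stereo_census",
    "strip_hydrogens",
]


@dataclass(frozen=True)
class StereoPair:
    id_A: str
    id_B: str
    basis: str  # "formula+bonds" | "extended_formula+bonds"
    hydrogens_omitted: bool = True


def strip_hydrogens(mol: Molecule) -> Molecule:
    """Heavy-atom copy of a molecule (reindexed, bond orders kept)."""
    keep = [a for a in mol.atoms if a.symbol != "H"]
    remap = {a.index: i for i, a in enumerate(keep, start=1)}
    atoms = [Atom(index=remap[a.index], spec=a.spec,
                  formal_charge=a.formal_charge) for a in keep]
    bonds = [
        Bond(a=remap[b.a], b=remap[b.b], order=b.order)
        for b in mol.bonds
        if b.a in remap and b.b in remap
    ]
    return Molecule(atoms=atoms, bonds=bonds, id=mol.id, name=mol.name)


def _pair_key(db: FGDatabase, cid: str, basis: str) -> tuple[str, int]:
    rec = db.get_entry(cid)
    if basis == "formula+bonds":
        return (rec.formula, rec.n_bonds)
    if basis == "extended_formula+bonds":
        return (rec.extended_formula, rec.n_bonds)
    raise ValueError(f"unknown basis {basis!r}")


def candidate_pairs(
    db: FGDatabase,
    db2: FGDatabase | None = None,
    basis: str = "formula+bonds",
) -> list[StereoPair]:
    """All unordered entry pairs sharing the basis key.

    Bond counts compare on the hydrogen-complete records even when the
    confirmation search later omits hydrogens.  In cross-database mode
    pairs span the two sources and same-name pairs are dropped to avoid
    comparing identical entries.
    """
    pairs: list[StereoPair] = []
    if db2 is None:
        by_key: dict[tuple[str, int], list[str]] = {}
        for cid in db.ids():
            by_key.setdefault(_pair_key(db, cid, basis), []).append(cid)
        for ids in by_key.values():
            for a, b in itertools.combinations(sorted(ids), 2):
                pairs.append(StereoPair(id_A=a, id_B=b, basis=basis))
    else:
        keys_b: dict[tuple[str, int], list[str]] = {}
        for cid in db2.ids():
            keys_b.setdefault(_pair_key(db2, cid, basis), []).append(cid)
        for cid in db.ids():
            key = _pair_key(db, cid, basis)
            name_a = db.get_entry(cid).name
            for other in keys_b.get(key, []):
                if name_a and db2.get_entry(other).name == name_a:
                    continue
                pairs.append(StereoPair(id_A=cid, id_B=other, basis=basis))
    return pairs


def are_stereoisomeric(
    A: Molecule,
    B: Molecule,
    depth: int = 2,
    omit_hydrogens: bool = True,
    mapping_budget: int | None = 2000,
) -> bool:
    """Whether A and B share identical atom connectivity and bond orders.

    ``depth`` selects the node-coloring shells used to prune candidate
    mappings; the boolean result does not depend on it.  When a
    ``mapping_budget`` is given and the candidate matrix at ``depth`` still
    exceeds it, coloring escalates one shell deeper before enumeration.
    """
    a, b = (strip_hydrogens(A), strip_hydrogens(B)) if omit_hydrogens \
        else (A, B)
    if a.n_atoms != b.n_atoms or a.n_bonds != b.n_bonds:
        return False
    if a.n_atoms == 0:
        return True
    from .graph_core import mapping_matrix

    use_depth = depth
    if mapping_budget is not None:
        M = mapping_matrix(b, a, n_bond(use_depth))
        if M.m > mapping_budget:
            use_depth = depth + 1
    found = enumerate_isomorphisms(
        query=b,
        compound=a,
        options=SearchOptions(short_circuit=True, coloring=n_bond(use_depth)),
    )
    return bool(found)


def _molecule_of(db: FGDatabase, cid: str) -> Molecule:
    rec = db.get_entry(cid)
    mol = parse_molfile(rec.molfile_text, dialect="standard")
    mol.id = cid
    # Stored molfiles are hydrogen-complete already (build_database inserts
    # the completed molecule); do not re-add.
    return mol


def stereo_census(
    db: FGDatabase,
    depth: int = 2,
    omit_hydrogens: bool = True,
    basis: str = "formula+bonds",
) -> dict:
    """Fraction of entries participating in >=1 confirmed stereo pair."""
    ids = db.ids()
    confirmed: list[StereoPair] = []
    in_pair: set[str] = set()
    cache: dict[str, Molecule] = {}
    for pair in candidate_pairs(db, basis=basis):
        for cid in (pair.id_A, pair.id_B):
            if cid not in cache:
                cache[cid] = _molecule_of(db, cid)
        if are_stereoisomeric(cache[pair.id_A], cache[pair.id_B],
                              depth=depth, omit_hydrogens=omit_hydrogens):
            confirmed.append(pair)
            in_pair.update((pair.id_A, pair.id_B))
    n = len(ids)
    return {
        "n_compounds": n,
        "n_in_stereo_pairs": len(in_pair),
        "percent": 100.0 * len(in_pair) / n if n else 0.0,
        "pairs": confirmed,
    }
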