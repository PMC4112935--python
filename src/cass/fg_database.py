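"""Functional-group-resolved compound database on SQLite.

One file holds two logical stores: a ``compounds`` table (formula, extended
formula, original molfile text, serialized atom/bond lists) with a
long-format ``group_counts`` table keyed (compound id, group name,
category), and a ``library`` table carrying the group query molfiles, super
flags and a fingerprint of the ordered group-name list.  The fingerprint
pins the library a database was annotated against: entries may be appended
incrementally, but changing the group list requires a rebuild because
subgraph/overlapping designations are relative to the whole library.
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
from dataclasses import dataclass

from .match_classify import (
    CATEGORIES,
    FunctionalGroupDef,
    GroupCountTable,
    annotate,
)
from .molfile_io import (
    Molecule,
    add_implicit_hydrogens,
    molecular_formula,
    normalize_formula,
    parse_molfile,
    serialize_molfile,
)

__all__ = [
    "CompoundRecord",
    "FGDatabase",
    "build_database",
    "library_fingerprint",
]


class DatabaseError(RuntimeError):
    pass


@dataclass(frozen=True)
class CompoundRecord:
    id: str
    name: str
    formula: str  # explicit-1 rendering
    extended_formula: str
    molfile_text: str
    n_atoms: int
    n_bonds: int
    counts: dict[str, dict[str, int]]  # group -> category -> count

    def count(self, group: str, category: str) -> int:
        return self.counts.get(group, {}).get(category, 0)


def library_fingerprint(library: list[FunctionalGroupDef]) -> str:
    names = [g.name for g in library]
    return hashlib.sha256("\n".join(names).encode()).hexdigest()


_SCHEMA = """
CREATE TABLE IF NOT EXISTS compounds (
    id TEXT PRIMARY KEY,
    name TEXT,
    formula TEXT,
    extended_formula TEXT,
    molfile TEXT,
    atoms_text TEXT,
    bonds_text TEXT,
    n_atoms INTEGER,
    n_bonds INTEGER
);
CREATE TABLE IF NOT EXISTS group_counts (
    compound_id TEXT,
    group_name TEXT,
    category TEXT,
    count INTEGER,
    PRIMARY KEY (compound_id, group_name, category)
);
CREATE TABLE IF NOT EXISTS library (
    position INTEGER PRIMARY KEY,
    name TEXT UNIQUE,
    molfile TEXT,
    is_super INTEGER,
    fingerprint TEXT
);
CREATE INDEX IF NOT EXISTS idx_formula ON compounds (formula);
"""


class FGDatabase:
    """Handle on one functional-group-resolved SQLite file.

    ``path`` may be ``":memory:"`` for ephemeral use.
    """

    def __init__(self, path: str):
        self.path = path
        self.conn = sqlite3.connect(path)
        self.conn.executescript(_SCHEMA)

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "FGDatabase":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- library ---------------------------------------------------------

    def store_library(self, library: list[FunctionalGroupDef]) -> None:
        if not library:
            raise DatabaseError("library must be non-empty")
        fp = library_fingerprint(library)
        with self.conn:
            self.conn.execute("DELETE FROM library")
            for pos, g in enumerate(library):
                self.conn.execute(
                    "INSERT INTO library VALUES (?,?,?,?,?)",
                    (pos, g.name,
                     serialize_molfile(g.query, dialect="extended"),
                     int(g.is_super), fp),
                )

    def load_library(self) -> list[FunctionalGroupDef]:
        rows = self.conn.execute(
            "SELECT name, molfile, is_super FROM library ORDER BY position"
        ).fetchall()
        return [
            FunctionalGroupDef(
                name=name,
                query=parse_molfile(text, dialect="extended"),
                is_super=bool(sup),
            )
            for name, text, sup in rows
        ]

    @property
    def fingerprint(self) -> str:
        row = self.conn.execute(
            "SELECT fingerprint FROM library LIMIT 1"
        ).fetchone()
        if row is None:
            raise DatabaseError("database has no library table contents")
        return row[0]

    # -- compounds -------------------------------------------------------

    def _insert(self, mol: Molecule, library: list[FunctionalGroupDef],
                molfile_text: str | None = None) -> None:
        cid = mol.id or mol.content_hash()
        if self.has_entry(cid):
            raise DatabaseError(f"duplicate compound id {cid!r}")
        ext, table = annotate(mol, library, scope="distinct")
        formula = molecular_formula(mol, explicit_ones=True)
        ext_full = _stored_extended_formula(formula, table, library)
        atoms_text = json.dumps(
            [[a.index, a.symbol, a.formal_charge] for a in mol.atoms]
        )
        bonds_text = json.dumps([[b.a, b.b, b.order] for b in mol.bonds])
        with self.conn:
            self.conn.execute(
                "INSERT INTO compounds VALUES (?,?,?,?,?,?,?,?,?)",
                (cid, mol.name, formula, ext_full,
                 molfile_text or serialize_molfile(mol),
                 atoms_text, bonds_text, mol.n_atoms, mol.n_bonds),
            )
            for g in library:
                for cat in CATEGORIES:
                    n = table.get(g.name, cat)
                    if n:
                        self.conn.execute(
                            "INSERT INTO group_counts VALUES (?,?,?,?)",
                            (cid, g.name, cat, n),
                        )

    def add_entry(self, molfile_text: str,
                  library: list[FunctionalGroupDef] | None = None,
                  hydrogenate: bool = True,
                  mol_id: str | None = None) -> str:
        """Annotate one new molfile record against the stored library.

        A caller-supplied ``library`` must match the stored fingerprint;
        otherwise the database would need reconstruction.  ``mol_id``
        overrides the record id (molfile connection tables carry no id of
        their own); without one, a content hash is used.
        """
        stored = self.load_library()
        if not stored:
            raise DatabaseError("database has no stored library")
        if library is not None:
            if library_fingerprint(library) != self.fingerprint:
                raise DatabaseError(
                    "library fingerprint mismatch: the functional-group list "
                    "changed, rebuild the database"
                )
        mol = parse_molfile(molfile_text, dialect="standard")
        if hydrogenate:
            mol = add_implicit_hydrogens(mol)
        if mol_id:
            mol.id = mol_id
        self._insert(mol, stored, molfile_text=molfile_text)
        return mol.id or mol.content_hash()

    def has_entry(self, cid: str) -> bool:
        row = self.conn.execute(
            "SELECT 1 FROM compounds WHERE id = ?", (cid,)
        ).fetchone()
        return row is not None

    def get_entry(self, cid: str) -> CompoundRecord:
        row = self.conn.execute(
            "SELECT id, name, formula, extended_formula, molfile, "
            "n_atoms, n_bonds FROM compounds WHERE id = ?",
            (cid,),
        ).fetchone()
        if row is None:
            raise KeyError(f"no compound with id {cid!r}")
        counts: dict[str, dict[str, int]] = {}
        for g, cat, n in self.conn.execute(
            "SELECT group_name, category, count FROM group_counts "
            "WHERE compound_id = ?",
            (cid,),
        ):
            counts.setdefault(g, {})[cat] = n
        return CompoundRecord(
            id=row[0], name=row[1], formula=row[2], extended_formula=row[3],
            molfile_text=row[4], n_atoms=row[5], n_bonds=row[6],
            counts=counts,
        )

    def ids(self) -> list[str]:
        return [r[0] for r in self.conn.execute(
            "SELECT id FROM compounds ORDER BY id"
        )]

    def records(self) -> list[CompoundRecord]:
        return [self.get_entry(i) for i in self.ids()]

    def count_table(self, cid: str) -> GroupCountTable:
        rec = self.get_entry(cid)
        table = GroupCountTable()
        for g, cats in rec.counts.items():
            for cat, n in cats.items():
                for _ in range(n):
                    table.add(g, cat)
        return table

    def query(
        self,
        formula: str | None = None,
        group_constraints: dict[str, int | bool] | None = None,
        scope: str = "distinct",
        mode: str = "stoichiometric",
    ) -> list[CompoundRecord]:
        """Records matching a formula and/or per-group count constraints.

        Count comparison happens after the quantification-mode transform on
        both sides, so e.g. under ``non_stoichiometric`` a constraint of 1
        means "present".  Boolean constraint values mean presence/absence
        regardless of mode.
        """
        from .match_classify import SCOPES
        from .strategy_search import transform_count

        if formula is None and not group_constraints:
            raise ValueError("query needs at least one criterion")
        if group_constraints:
            known = {g.name for g in self.load_library()}
            for name in group_constraints:
                if name not in known:
                    raise KeyError(f"unknown functional group {name!r}")
        scope_obj = SCOPES[scope]
        supers = {g.name for g in self.load_library() if g.is_super}
        out = []
        for rec in self.records():
            if formula is not None and rec.formula != normalize_formula(
                formula
            ):
                continue
            ok = True
            for name, want in (group_constraints or {}).items():
                table = self.count_table(rec.id)
                have = scope_obj.effective_count(table, name, name in supers)
                if isinstance(want, bool):
                    if bool(have) != want:
                        ok = False
                        break
                elif transform_count(have, mode) != transform_count(
                    want, mode
                ):
                    ok = False
                    break
            if ok:
                out.append(rec)
        return out


def _stored_extended_formula(
    formula: str, table: GroupCountTable, library: list[FunctionalGroupDef]
) -> str:
    """Category-resolved rendering stored in the database.

    Distinct counts use the plain group token; subgraph/overlapping
    instances append as ``Subgraph<Name>``/``Overlapping<Name>`` segments,
    all in alphabetical segment order.
    """
    segments: list[str] = []
    for g in sorted(library, key=lambda g: g.name):
        tok = g.formula_token
        n = table.get(g.name, "distinct")
        if n:
            segments.append(f"{tok}{n}")
        n = table.get(g.name, "subgraph")
        if n:
            segments.append(f"Subgraph{tok}{n}")
        n = table.get(g.name, "overlapping")
        if n:
            segments.append(f"Overlapping{tok}{n}")
    return formula + "".join(sorted(segments))


def build_database(
    compounds: list[Molecule],
    library: list[FunctionalGroupDef],
    path: str = ":memory:",
) -> FGDatabase:
    """Annotate every compound against ``library`` and persist the result.

    Compounds must already be hydrogen-complete.  Deterministic given the
    inputs; duplicate ids are an error naming the offenders.
    """
    if not library:
        raise DatabaseError("library must be non-empty")
    ids = [m.id or m.content_hash() for m in compounds]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise DatabaseError(f"duplicate compound ids: {dupes}")
    db = FGDatabase(path)
    db.store_library(library)
    for mol in compounds:
        db._insert(mol, library)
    return db
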