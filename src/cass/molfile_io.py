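"""Molfile/SDF parsing, serialization, implicit hydrogens and formulae.

The in-memory molecule model is shared by compound records and substructure
queries.  Compounds carry plain element symbols; queries may use an extended
atom-symbol grammar:

* ``X|Y|Z`` — the atom may be any of the listed elements,
* ``!X``   — the atom may be any element except ``X``,
* ``A``    — the atom may be any element at all,
* a trailing ``*`` marks the atom *contextual*: it must be matched for the
  substructure to be recognized but is not counted as part of it.

Connectivity is V2000-style: a counts line, an atom block (coordinates are
read but ignored by every algorithm) and a bond block with integer bond
orders 1-3.  Aromatic (type 4) bonds are rejected; supply Kekulé structures.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

__all__ = [
    "ElementSpec",
    "Atom",
    "Bond",
    "Molecule",
    "MolfileError",
    "ValenceError",
    "parse_element_token",
    "parse_molfile",
    "parse_sdf",
    "add_implicit_hydrogens",
    "molecular_formula",
    "serialize_molfile",
    "serialize_sdf",
    "DEFAULT_VALENCES",
]


class MolfileError(ValueError):
    """Malformed molfile/SDF content or extended-grammar token."""


class ValenceError(MolfileError):
    """An atom's bonds already exceed its allowed valence."""


#: Target valences used when adding implicit hydrogens.  Formal charge
#: shifts the target by its sign for N and O (ammonium N -> 4, alkoxide
#: O -> 1); other elements keep their neutral valence.
DEFAULT_VALENCES: dict[str, int] = {
    "H": 1,
    "B": 3,
    "C": 4,
    "N": 3,
    "O": 2,
    "P": 3,
    "S": 2,
    "F": 1,
    "Cl": 1,
    "Br": 1,
    "I": 1,
}

_CHARGE_SHIFT_ELEMENTS = {"N", "O"}

# Atom-block charge column code -> formal charge (V2000 convention).
_BLOCK_CHARGE = {0: 0, 1: +3, 2: +2, 3: +1, 4: 0, 5: -1, 6: -2, 7: -3}


@dataclass(frozen=True)
class ElementSpec:
    """Element constraint for one query (or compound) atom."""

    mode: str  # exact | any_of | not_of | wildcard
    elements: frozenset[str] = frozenset()
    contextual: bool = False

    def __post_init__(self) -> None:
        if self.mode == "exact" and len(self.elements) != 1:
            raise MolfileError("exact spec needs exactly one element")
        if self.mode == "any_of" and len(self.elements) < 2:
            raise MolfileError("any_of spec needs at least two elements")
        if self.mode == "not_of" and len(self.elements) < 1:
            raise MolfileError("not_of spec needs at least one element")
        if self.mode == "wildcard" and self.elements:
            raise MolfileError("wildcard spec carries no elements")

    @property
    def symbol(self) -> str:
        """The single element symbol of an exact spec."""
        if self.mode != "exact":
            raise MolfileError(f"spec has no single symbol (mode={self.mode})")
        return next(iter(self.elements))

    @property
    def is_exact(self) -> bool:
        return self.mode == "exact"

    def matches(self, symbol: str) -> bool:
        """Whether a plain element symbol satisfies this constraint."""
        if self.mode == "exact" or self.mode == "any_of":
            return symbol in self.elements
        if self.mode == "not_of":
            return symbol not in self.elements
        return True  # wildcard

    def token(self) -> str:
        """Render back to the extended atom-symbol grammar."""
        star = "*" if self.contextual else ""
        if self.mode == "wildcard":
            return "A" + star
        body = "|".join(sorted(self.elements))
        if self.mode == "not_of":
            return "!" + body + star
        return body + star


def exact(symbol: str, contextual: bool = False) -> ElementSpec:
    return ElementSpec("exact", frozenset({symbol}), contextual)


@dataclass(frozen=True)
class Atom:
    """One atom: 1-based index, element constraint and formal charge."""

    index: int
    spec: ElementSpec
    formal_charge: int = 0

    @property
    def symbol(self) -> str:
        return self.spec.symbol


@dataclass(frozen=True)
class Bond:
    """Undirected bond between atom indices ``a`` and ``b`` (1-based)."""

    a: int
    b: int
    order: int

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise MolfileError(f"bond joins atom {self.a} to itself")
        if self.order not in (1, 2, 3):
            raise MolfileError(f"bond order {self.order} not in 1..3")

    def key(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass
class Molecule:
    """Atoms plus bonds; used for both compounds and substructure queries."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    id: str = ""
    name: str = ""
    source_text: str | None = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for pos, atom in enumerate(self.atoms, start=1):
            if atom.index != pos:
                raise MolfileError(
                    f"atom at position {pos} carries index {atom.index}"
                )
        seen: set[tuple[int, int]] = set()
        for bond in self.bonds:
            for idx in (bond.a, bond.b):
                if not 1 <= idx <= n:
                    raise MolfileError(f"bond references missing atom {idx}")
            if bond.key() in seen:
                raise MolfileError(f"duplicate bond {bond.key()}")
            seen.add(bond.key())

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def degree(self, index: int) -> int:
        return sum(1 for b in self.bonds if index in (b.a, b.b))

    def bond_order_sum(self, index: int) -> int:
        return sum(b.order for b in self.bonds if index in (b.a, b.b))

    def neighbors(self, index: int) -> list[tuple[int, int]]:
        """(neighbor index, bond order) pairs for one atom."""
        out = []
        for b in self.bonds:
            if b.a == index:
                out.append((b.b, b.order))
            elif b.b == index:
                out.append((b.a, b.order))
        return out

    @property
    def is_query(self) -> bool:
        """True when any atom uses a non-exact or contextual spec."""
        return any(not a.spec.is_exact or a.spec.contextual for a in self.atoms)

    def content_hash(self) -> str:
        """Stable id for molecules lacking a database identifier."""
        text = serialize_molfile(self, dialect="extended")
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def parse_element_token(token: str) -> ElementSpec:
    """Parse one extended atom symbol (``H|O|N``, ``!H``, ``C*``, ``A``)."""
    if not token:
        raise MolfileError("empty element token")
    work = token
    contextual = False
    if work.endswith("*"):
        contextual = True
        work = work[:-1]
    if not work:
        raise MolfileError(f"malformed element token {token!r}")
    negated = work.startswith("!")
    if negated:
        work = work[1:]
    parts = work.split("|")
    if any(not p for p in parts):
        raise MolfileError(f"malformed element token {token!r}")
    if negated and len(parts) > 1:
        raise MolfileError(
            f"element token {token!r} mixes '!' with '|'; negation takes a "
            "single element"
        )
    if not negated and parts == ["A"]:
        return ElementSpec("wildcard", frozenset(), contextual)
    if negated:
        return ElementSpec("not_of", frozenset(parts), contextual)
    if len(parts) == 1:
        return ElementSpec("exact", frozenset(parts), contextual)
    return ElementSpec("any_of", frozenset(parts), contextual)


def _parse_counts_line(line: str) -> tuple[int, int]:
    try:
        n_atoms = int(line[0:3])
        n_bonds = int(line[3:6])
    except (ValueError, IndexError) as exc:
        raise MolfileError(f"bad counts line: {line!r}") from exc
    return n_atoms, n_bonds


def parse_molfile(text: str, dialect: str = "standard") -> Molecule:
    """Parse one V2000-style connection table.

    ``dialect`` is ``"standard"`` (plain element symbols only) or
    ``"extended"`` (symbols pass through :func:`parse_element_token`).
    """
    if dialect not in ("standard", "extended"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileError("truncated molfile: missing header/counts line")
    name = lines[0].strip()
    counts_idx = 3
    n_atoms, n_bonds = _parse_counts_line(lines[counts_idx])
    atom_lines = lines[counts_idx + 1 : counts_idx + 1 + n_atoms]
    bond_lines = lines[
        counts_idx + 1 + n_atoms : counts_idx + 1 + n_atoms + n_bonds
    ]
    if len(atom_lines) < n_atoms or len(bond_lines) < n_bonds:
        raise MolfileError("truncated molfile: atom or bond block short")

    atoms: list[Atom] = []
    block_charges: dict[int, int] = {}
    for i, line in enumerate(atom_lines, start=1):
        fields = line.split()
        if len(fields) < 4:
            raise MolfileError(f"bad atom line {i}: {line!r}")
        token = fields[3]
        if dialect == "standard":
            if token not in DEFAULT_VALENCES and not token.isalpha():
                raise MolfileError(
                    f"atom {i}: symbol {token!r} is not a plain element "
                    "(use the extended dialect for query symbols)"
                )
            if any(c in token for c in "!|*"):
                raise MolfileError(
                    f"atom {i}: extended symbol {token!r} in standard dialect"
                )
            spec = ElementSpec("exact", frozenset({token}))
        else:
            spec = parse_element_token(token)
        charge_code = 0
        if len(fields) >= 6:
            try:
                charge_code = int(fields[5])
            except ValueError:
                charge_code = 0
        if charge_code in _BLOCK_CHARGE and _BLOCK_CHARGE[charge_code]:
            block_charges[i] = _BLOCK_CHARGE[charge_code]
        atoms.append(Atom(index=i, spec=spec))

    bonds: list[Bond] = []
    for line in bond_lines:
        try:
            a = int(line[0:3])
            b = int(line[3:6])
            order = int(line[6:9])
        except (ValueError, IndexError):
            fields = line.split()
            if len(fields) < 3:
                raise MolfileError(f"bad bond line: {line!r}") from None
            a, b, order = int(fields[0]), int(fields[1]), int(fields[2])
        if order == 4:
            raise MolfileError(
                "aromatic bond type 4 not supported; supply a Kekulé "
                "structure with integer bond orders"
            )
        if not (1 <= a <= n_atoms) or not (1 <= b <= n_atoms):
            raise MolfileError(f"bond references missing atom ({a},{b})")
        bonds.append(Bond(a=a, b=b, order=order))

    # Property block: M  CHG lines override atom-block charge codes.
    chg_lines = [ln for ln in lines[counts_idx + 1 + n_atoms + n_bonds :]
                 if ln.startswith("M  CHG")]
    prop_charges: dict[int, int] = {}
    for ln in chg_lines:
        fields = ln.split()
        n_pairs = int(fields[2])
        vals = fields[3 : 3 + 2 * n_pairs]
        for k in range(n_pairs):
            prop_charges[int(vals[2 * k])] = int(vals[2 * k + 1])
    charges = dict(block_charges)
    charges.update(prop_charges)

    atoms = [
        replace(a, formal_charge=charges.get(a.index, 0)) for a in atoms
    ]
    return Molecule(atoms=atoms, bonds=bonds, name=name, source_text=text)


def parse_sdf(
    text: str, dialect: str = "standard", strict: bool = True,
    id_field: str | None = None,
) -> list[Molecule]:
    """Parse an SDF (``$$$$``-delimited concatenation of molfile records).

    In non-strict mode malformed records are skipped (their ordinal is noted
    in the error list attached to the exception-free return); in strict mode
    the first malformed record raises with its ordinal.  ``id_field`` names
    an SDF data field (``> <FIELD>``) to use as the record id; the header
    name line is always captured as the name, and a data field named ID /
    DATABASE_ID is used when ``id_field`` is not given.
    """
    molecules: list[Molecule] = []
    if not text.strip():
        return molecules
    records = text.split("$$$$")
    ordinal = 0
    for raw in records:
        if not raw.strip():
            continue
        ordinal += 1
        raw = raw.lstrip("\n")
        try:
            mol = parse_molfile(raw, dialect=dialect)
        except MolfileError as exc:
            if strict:
                raise MolfileError(f"record {ordinal}: {exc}") from exc
            continue
        fields = _sdf_data_fields(raw)
        wanted = (id_field,) if id_field else ("ID", "DATABASE_ID", "HMDB_ID",
                                               "KEGG_ID")
        for key in wanted:
            if key and key in fields:
                mol.id = fields[key]
                break
        if "NAME" in fields and not mol.name:
            mol.name = fields["NAME"]
        molecules.append(mol)
    return molecules


def _sdf_data_fields(record: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    lines = record.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("> ") or line.startswith(">  "):
            key = line[line.find("<") + 1 : line.rfind(">")]
            vals = []
            i += 1
            while i < len(lines) and lines[i].strip():
                vals.append(lines[i].strip())
                i += 1
            fields[key.upper()] = " ".join(vals)
        i += 1
    return fields


def _target_valence(symbol: str, charge: int) -> int | None:
    base = DEFAULT_VALENCES.get(symbol)
    if base is None:
        return None
    if symbol in _CHARGE_SHIFT_ELEMENTS and charge:
        return base + (1 if charge > 0 else -1)
    return base


def add_implicit_hydrogens(mol: Molecule) -> Molecule:
    """Complete every atom to its default valence with new hydrogens.

    Hydrogens are appended after the existing atoms, each with a single bond
    to its heavy atom.  Molecules are completed to neutral valences unless
    the record carries explicit formal charges (no pH/pKa modeling).
    Elements outside the valence table receive no hydrogens.  Idempotent.
    """
    if any(not a.spec.is_exact for a in mol.atoms):
        raise MolfileError("implicit hydrogens need exact element symbols")
    atoms = list(mol.atoms)
    bonds = list(mol.bonds)
    next_index = len(atoms)
    for atom in mol.atoms:
        target = _target_valence(atom.symbol, atom.formal_charge)
        if target is None:
            continue
        have = mol.bond_order_sum(atom.index)
        if have > target:
            raise ValenceError(
                f"atom {atom.index} ({atom.symbol}) has bond order sum "
                f"{have} above its valence {target}"
            )
        for _ in range(target - have):
            next_index += 1
            atoms.append(Atom(index=next_index, spec=exact("H")))
            bonds.append(Bond(a=atom.index, b=next_index, order=1))
    return Molecule(atoms=atoms, bonds=bonds, id=mol.id, name=mol.name,
                    source_text=mol.source_text)


def molecular_formula(mol: Molecule, explicit_ones: bool = False) -> str:
    """Hill-order formula (C, H, then others alphabetically).

    ``explicit_ones`` renders count 1 explicitly (the rendering used inside
    extended formulae, e.g. ``C3H6O1``); the default omits it (``CH4``).
    """
    counts: dict[str, int] = {}
    for atom in mol.atoms:
        if not atom.spec.is_exact:
            raise MolfileError("query molecules have no molecular formula")
        counts[atom.symbol] = counts.get(atom.symbol, 0) + 1
    ordered: list[str] = []
    if "C" in counts:
        ordered.append("C")
        if "H" in counts:
            ordered.append("H")
        ordered.extend(s for s in sorted(counts) if s not in ("C", "H"))
    else:
        ordered = sorted(counts)
    parts = []
    for sym in ordered:
        n = counts[sym]
        if n == 1 and not explicit_ones:
            parts.append(sym)
        else:
            parts.append(f"{sym}{n}")
    return "".join(parts)


def normalize_formula(formula: str) -> str:
    """Canonicalize a formula string to the explicit-1 rendering."""
    import re

    counts: dict[str, int] = {}
    for sym, num in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if sym:
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    ordered: list[str] = []
    if "C" in counts:
        ordered.append("C")
        if "H" in counts:
            ordered.append("H")
        ordered.extend(s for s in sorted(counts) if s not in ("C", "H"))
    else:
        ordered = sorted(counts)
    return "".join(f"{s}{counts[s]}" for s in ordered)


def serialize_molfile(mol: Molecule, dialect: str = "extended") -> str:
    """Render a molecule back to a V2000-style connection table.

    Coordinates are written as zeros (no algorithm reads them).  In the
    standard dialect extended specs are an error; the extended dialect
    writes the ``!``/``|``/``*`` grammar.
    """
    lines = [mol.name, "  cass", ""]
    lines.append(
        f"{mol.n_atoms:3d}{mol.n_bonds:3d}  0  0  0  0  0  0  0  0999 V2000"
    )
    charged: list[tuple[int, int]] = []
    for atom in mol.atoms:
        if atom.spec.is_exact and not atom.spec.contextual:
            token = atom.symbol
        else:
            if dialect == "standard":
                raise MolfileError(
                    "extended atom spec cannot be written in standard dialect"
                )
            token = atom.spec.token()
        lines.append(
            f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {token:<3s} 0  0  0  0  0"
        )
        if atom.formal_charge:
            charged.append((atom.index, atom.formal_charge))
    for bond in mol.bonds:
        lines.append(f"{bond.a:3d}{bond.b:3d}{bond.order:3d}  0")
    for idx, chg in charged:
        lines.append(f"M  CHG  1 {idx:3d} {chg:3d}")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def serialize_sdf(mols: list[Molecule], dialect: str = "standard") -> str:
    """Concatenate molfile records with ``$$$$`` delimiters, with id fields."""
    chunks = []
    for mol in mols:
        rec = serialize_molfile(mol, dialect=dialect)
        if mol.id:
            rec += f"> <ID>\n{mol.id}\n\n"
        chunks.append(rec + "$$$$\n")
    return "".join(chunks)
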