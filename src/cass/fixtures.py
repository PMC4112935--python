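"""Programmatic test corpus: reference compounds, the functional-group
library, random valence-legal molecules, and planted ground-truth databases.

Compounds are registered as heavy-atom connection tables (standard
connectivities from their IUPAC structures); :func:`build_compound` returns
the hydrogen-complete molecule and every registry entry records the
literature formula and the expected hydrogen-complete atom/bond counts so
the valence model is continuously validated against known chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .match_classify import FunctionalGroupDef
from .molfile_io import (
    Atom,
    Bond,
    ElementSpec,
    Molecule,
    add_implicit_hydrogens,
    parse_element_token,
)

__all__ = [
    "FixtureSpec",
    "COMPOUND_REGISTRY",
    "build_compound",
    "build_group_library",
    "random_molecule",
    "planted_database",
    "heavy_molecule",
]


def heavy_molecule(
    symbols: list[str],
    bonds: list[tuple[int, int, int] | tuple[int, int]],
    name: str = "",
    mol_id: str = "",
) -> Molecule:
    """Build a heavy-atom molecule from element symbols and 1-based bonds."""
    atoms = [
        Atom(index=i, spec=ElementSpec("exact", frozenset({s})))
        for i, s in enumerate(symbols, start=1)
    ]
    blist = [
        Bond(a=b[0], b=b[1], order=b[2] if len(b) == 3 else 1) for b in bonds
    ]
    return Molecule(atoms=atoms, bonds=blist, name=name, id=mol_id)


def query_molecule(
    tokens: list[str],
    bonds: list[tuple[int, int, int] | tuple[int, int]],
    name: str = "",
) -> Molecule:
    """Build an extended-dialect query from atom-symbol tokens."""
    atoms = [
        Atom(index=i, spec=parse_element_token(t))
        for i, t in enumerate(tokens, start=1)
    ]
    blist = [
        Bond(a=b[0], b=b[1], order=b[2] if len(b) == 3 else 1) for b in bonds
    ]
    return Molecule(atoms=atoms, bonds=blist, name=name)


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    symbols: tuple[str, ...]
    bonds: tuple[tuple[int, int, int], ...]
    expected_formula: str
    expected_atoms: int  # hydrogen-complete
    expected_bonds: int  # hydrogen-complete
    note: str = ""
    misprint: bool = False  # printed reference counts known to be wrong


def _spec(name, symbols, bonds, formula, atoms, nbonds, note="",
          misprint=False):
    norm = tuple((x[0], x[1], x[2] if len(x) == 3 else 1) for x in bonds)
    return FixtureSpec(
        name=name,
        symbols=tuple(symbols),
        bonds=norm,
        expected_formula=formula,
        expected_atoms=atoms,
        expected_bonds=nbonds,
        note=note,
        misprint=misprint,
    )


_SUGAR_ATOMS = ["C", "C", "C", "O", "C", "C", "O", "O"]  # C1' C2' C3' O3' C4' C5' O5' O4'


def _registry() -> dict[str, FixtureSpec]:
    r: dict[str, FixtureSpec] = {}

    def add(name, symbols, bonds, formula, atoms, nbonds, note="",
            misprint=False):
        r[name] = _spec(name, symbols, bonds, formula, atoms, nbonds, note,
                        misprint)

    # -- small molecules -------------------------------------------------
    add("methane", ["C"], [], "CH4", 5, 4)
    add("ethane", ["C", "C"], [(1, 2)], "C2H6", 8, 7)
    add("ethanol", ["C", "C", "O"], [(1, 2), (2, 3)], "C2H6O", 9, 8)
    add("dimethyl ether", ["C", "O", "C"], [(1, 2), (2, 3)], "C2H6O", 9, 8)
    add("ethylene glycol", ["O", "C", "C", "O"],
        [(1, 2), (2, 3), (3, 4)], "C2H6O2", 10, 9)
    add("methoxymethanol", ["C", "O", "C", "O"],
        [(1, 2), (2, 3), (3, 4)], "C2H6O2", 10, 9,
        note="hemiformal methyl ether; one hydroxyl vs glycol's two")
    add("ethylene oxide", ["C", "C", "O"],
        [(1, 2), (2, 3), (1, 3)], "C2H4O", 7, 7)
    add("ethene", ["C", "C"], [(1, 2, 2)], "C2H4", 6, 5)
    add("acetone", ["C", "C", "C", "O"],
        [(1, 2), (2, 3), (2, 4, 2)], "C3H6O", 10, 9)
    add("propanal", ["C", "C", "C", "O"],
        [(1, 2), (2, 3), (3, 4, 2)], "C3H6O", 10, 9)
    add("propan-1-ol", ["C", "C", "C", "O"],
        [(1, 2), (2, 3), (3, 4)], "C3H8O", 12, 11)
    add("propan-2-ol", ["C", "C", "C", "O"],
        [(1, 2), (2, 3), (2, 4)], "C3H8O", 12, 11)
    add("methoxyethane", ["C", "C", "O", "C"],
        [(1, 2), (2, 3), (3, 4)], "C3H8O", 12, 11)
    add("glycerol", ["C", "C", "C", "O", "O", "O"],
        [(1, 2), (2, 3), (1, 4), (2, 5), (3, 6)], "C3H8O3", 14, 13)
    add("acetic acid", ["C", "C", "O", "O"],
        [(1, 2), (2, 3, 2), (2, 4)], "C2H4O2", 8, 7)
    add("methyl formate", ["C", "O", "O", "C"],
        [(1, 2, 2), (1, 3), (3, 4)], "C2H4O2", 8, 7)
    add("propionic acid", ["C", "C", "C", "O", "O"],
        [(1, 2), (2, 3), (3, 4, 2), (3, 5)], "C3H6O2", 11, 10)
    add("methyl acetate", ["C", "C", "O", "O", "C"],
        [(1, 2), (2, 3, 2), (2, 4), (4, 5)], "C3H6O2", 11, 10)
    add("butan-2-one", ["C", "C", "C", "C", "O"],
        [(1, 2), (2, 3), (3, 4), (2, 5, 2)], "C4H8O", 13, 12)
    add("butanal", ["C", "C", "C", "C", "O"],
        [(1, 2), (2, 3), (3, 4), (4, 5, 2)], "C4H8O", 13, 12)
    add("2,3-butanedione", ["C", "C", "C", "C", "O", "O"],
        [(1, 2), (2, 3), (3, 4), (2, 5, 2), (3, 6, 2)], "C4H6O2", 12, 11,
        note="adjacent carbonyls share flanking carbons as ketone context")
    add("acetic anhydride", ["C", "C", "O", "O", "C", "O", "C"],
        [(1, 2), (2, 3, 2), (2, 4), (4, 5), (5, 6, 2), (5, 7)],
        "C4H6O3", 13, 12,
        note="symmetric anhydride; the anhydride query matches as a mirror "
             "pair")
    add("pyruvic acid", ["C", "C", "O", "C", "O", "O"],
        [(1, 2), (2, 3, 2), (2, 4), (4, 5, 2), (4, 6)], "C3H4O3", 10, 9)
    add("l-alanine", ["N", "C", "C", "O", "O", "C"],
        [(1, 2), (2, 3), (3, 4, 2), (3, 5), (2, 6)], "C3H7NO2", 13, 12)
    # D-alanine: same connectivity as L-alanine under an atom permutation;
    # connection tables cannot distinguish enantiomers.
    add("d-alanine", ["C", "C", "O", "O", "N", "C"],
        [(5, 1), (1, 2), (2, 3, 2), (2, 4), (1, 6)], "C3H7NO2", 13, 12,
        note="atom-permuted enantiomer record of l-alanine")
    add("pentane-1,2,3,4-tetraol",
        ["C", "C", "C", "C", "C", "O", "O", "O", "O"],
        [(1, 2), (2, 3), (3, 4), (4, 5), (1, 6), (2, 7), (3, 8), (4, 9)],
        "C5H12O4", 21, 20, note="four hydroxyls")
    add("2-methoxybutane-1,3,4-triol",
        ["C", "C", "C", "C", "O", "O", "C", "O", "O"],
        [(1, 2), (2, 3), (3, 4), (1, 5), (2, 6), (6, 7), (3, 8), (4, 9)],
        "C5H12O4", 21, 20, note="three hydroxyls plus a methyl ether")

    # -- reference database compounds ------------------------------------
    sugar = _SUGAR_ATOMS  # indices base+1..base+8
    add("deoxycytidine",
        ["N", "C", "O", "N", "C", "N", "C", "C"] + sugar,
        [(1, 2), (2, 3, 2), (2, 4), (4, 5, 2), (5, 6), (5, 7), (7, 8, 2),
         (8, 1), (1, 9), (9, 10), (10, 11), (11, 12), (11, 13), (13, 14),
         (14, 15), (13, 16), (16, 9)],
        "C9H13N3O4", 29, 30,
        note="cytosine N1-glycosidically bonded to 2-deoxyribofuranose")
    add("deoxyuridine",
        ["N", "C", "O", "N", "C", "O", "C", "C"] + sugar,
        [(1, 2), (2, 3, 2), (2, 4), (4, 5), (5, 6, 2), (5, 7), (7, 8, 2),
         (8, 1), (1, 9), (9, 10), (10, 11), (11, 12), (11, 13), (13, 14),
         (14, 15), (13, 16), (16, 9)],
        "C9H12N2O5", 28, 29)
    add("r-3-hydroxybutyric acid",
        ["C", "C", "O", "C", "C", "O", "O"],
        [(1, 2), (2, 3), (2, 4), (4, 5), (5, 6, 2), (5, 7)],
        "C4H8O3", 15, 14)
    add("2-hydroxybutyric acid",
        ["C", "C", "C", "O", "C", "O", "O"],
        [(1, 2), (2, 3), (3, 4), (3, 5), (5, 6, 2), (5, 7)],
        "C4H8O3", 15, 14,
        note="positional isomer of 3-hydroxybutyric acid, not a stereoisomer")
    add("1-methylhistidine",
        ["N", "C", "N", "C", "C", "C", "C", "C", "N", "C", "O", "O"],
        [(1, 2), (2, 3, 2), (3, 4), (4, 5, 2), (5, 1), (1, 6), (4, 7),
         (7, 8), (8, 9), (8, 10), (10, 11, 2), (10, 12)],
        "C7H11N3O2", 23, 23)
    add("1,3-diaminopropane", ["N", "C", "C", "C", "N"],
        [(1, 2), (2, 3), (3, 4), (4, 5)], "C3H10N2", 15, 14)
    add("2-ketobutyric acid",
        ["C", "C", "C", "O", "C", "O", "O"],
        [(1, 2), (2, 3), (3, 4, 2), (3, 5), (5, 6, 2), (5, 7)],
        "C4H6O3", 13, 12)
    # Steroids: C1..C21 in standard steroid numbering, then oxygens.
    _steroid_core = [
        (1, 2), (2, 3), (3, 4), (4, 5, 2), (5, 10), (10, 1),  # ring A
        (5, 6), (6, 7), (7, 8), (8, 9), (9, 10),              # ring B
        (9, 11), (11, 12), (12, 13), (13, 14), (14, 8),       # ring C
        (14, 15), (15, 16), (16, 17), (17, 13),               # ring D
        (10, 19), (13, 18),                                   # angular methyls
    ]
    add("cortexolone",
        ["C"] * 21 + ["O", "O", "O", "O"],
        _steroid_core + [(3, 22, 2), (17, 23), (17, 20), (20, 24, 2),
                         (20, 21), (21, 25)],
        "C21H30O4", 55, 58,
        note="11-deoxycortisol: pregn-4-ene-3,20-dione, 17a,21-diol")
    add("deoxycorticosterone",
        ["C"] * 21 + ["O", "O", "O"],
        _steroid_core + [(3, 22, 2), (17, 20), (20, 23, 2), (20, 21),
                         (21, 24)],
        "C21H30O3", 54, 57, misprint=True,
        note="reference table prints 43 atoms / 69 bonds, inconsistent with "
             "C21H30O3; excluded from hard count assertions")
    add("2-methoxyestrone",
        ["C"] * 18 + ["O", "O", "C", "O"],
        [(1, 2, 2), (2, 3), (3, 4, 2), (4, 5), (5, 10, 2), (10, 1),
         (5, 6), (6, 7), (7, 8), (8, 9), (9, 10),
         (9, 11), (11, 12), (12, 13), (13, 14), (14, 8),
         (14, 15), (15, 16), (16, 17), (17, 13), (13, 18),
         (17, 22, 2), (3, 19), (2, 20), (20, 21)],
        "C19H24O3", 46, 49,
        note="aromatic A ring written as a Kekulé structure")
    return r


COMPOUND_REGISTRY: dict[str, FixtureSpec] = _registry()


def build_compound(name: str, mol_id: str | None = None) -> Molecule:
    """Hydrogen-complete fixture compound by registry name."""
    key = name.lower()
    if key not in COMPOUND_REGISTRY:
        raise KeyError(f"unknown fixture compound {name!r}")
    spec = COMPOUND_REGISTRY[key]
    mol = heavy_molecule(
        list(spec.symbols), list(spec.bonds), name=spec.name,
        mol_id=mol_id or spec.name,
    )
    return add_implicit_hydrogens(mol)


def build_group_library() -> list[FunctionalGroupDef]:
    """The shipped functional-group library (extended-dialect queries).

    The four reference groups carry their published sizes: carboxylic acid
    5 atoms / 4 bonds (all structural, the acid carbon's fourth neighbor a
    structural ``!H``), epoxide 3/3, alkene 6/5 with four contextual
    substituents, alcohol 3/2.  The remainder give test breadth.  Alkyl
    halide is the shipped example of a *super* group.
    """
    defs = [
        FunctionalGroupDef(
            "carboxylic acid",
            query_molecule(["C", "O", "H", "O", "!H"],
                           [(1, 2), (2, 3), (1, 4, 2), (1, 5)],
                           name="carboxylic acid"),
        ),
        FunctionalGroupDef(
            "epoxide",
            query_molecule(["C", "C", "O"], [(1, 2), (2, 3), (3, 1)],
                           name="epoxide"),
        ),
        FunctionalGroupDef(
            "alkene",
            query_molecule(["C", "C", "A*", "A*", "A*", "A*"],
                           [(1, 2, 2), (1, 3), (1, 4), (2, 5), (2, 6)],
                           name="alkene"),
        ),
        FunctionalGroupDef(
            "alcohol",
            query_molecule(["C", "O", "H"], [(1, 2), (2, 3)], name="alcohol"),
        ),
        FunctionalGroupDef(
            "ketone",
            query_molecule(["C", "O", "C*", "C*"],
                           [(1, 2, 2), (1, 3), (1, 4)], name="ketone"),
        ),
        FunctionalGroupDef(
            "aldehyde",
            query_molecule(["C", "O", "H", "C*"],
                           [(1, 2, 2), (1, 3), (1, 4)], name="aldehyde"),
        ),
        FunctionalGroupDef(
            "primary amine",
            query_molecule(["N", "H", "H", "C*"],
                           [(1, 2), (1, 3), (1, 4)], name="primary amine"),
        ),
        FunctionalGroupDef(
            "dialkyl ether",
            query_molecule(["O", "C*", "C*"], [(1, 2), (1, 3)],
                           name="dialkyl ether"),
        ),
        FunctionalGroupDef(
            "enol",
            query_molecule(["C", "C", "O", "H"],
                           [(1, 2, 2), (2, 3), (3, 4)], name="enol"),
        ),
        FunctionalGroupDef(
            "methyl",
            query_molecule(["C", "H", "H", "H", "!H*"],
                           [(1, 2), (1, 3), (1, 4), (1, 5)], name="methyl"),
        ),
        FunctionalGroupDef(
            "thiol",
            query_molecule(["S", "H", "C*"], [(1, 2), (1, 3)], name="thiol"),
        ),
        FunctionalGroupDef(
            "anhydride",
            query_molecule(["C", "O", "O", "C", "O"],
                           [(1, 2, 2), (1, 3), (3, 4), (4, 5, 2)],
                           name="anhydride"),
        ),
        FunctionalGroupDef(
            "alkyl halide",
            query_molecule(["C", "F|Cl|Br|I"], [(1, 2)], name="alkyl halide"),
            is_super=True,
        ),
        FunctionalGroupDef(
            "alkyl chloride",
            query_molecule(["C", "Cl"], [(1, 2)], name="alkyl chloride"),
        ),
    ]
    return defs


def table1_groups() -> list[FunctionalGroupDef]:
    """The four reference functional groups only."""
    wanted = {"carboxylic acid", "epoxide", "alkene", "alcohol"}
    return [g for g in build_group_library() if g.name in wanted]


_DEFAULT_WEIGHTS = {"C": 0.65, "N": 0.12, "O": 0.18, "S": 0.05}
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}


def random_molecule(
    seed: int,
    n_heavy: int,
    element_weights: dict[str, float] | None = None,
) -> Molecule:
    """Connected, valence-legal random tree-plus-rings heavy-atom molecule.

    Deterministic per seed; always survives implicit hydrogen addition.
    """
    if n_heavy < 1:
        raise ValueError("n_heavy must be >= 1")
    weights = element_weights or _DEFAULT_WEIGHTS
    for sym in weights:
        if sym not in _VALENCE:
            raise ValueError(f"no valence entry for element {sym!r}")
    rng = np.random.default_rng(seed)
    syms = list(weights)
    probs = np.array([weights[s] for s in syms], dtype=float)
    probs = probs / probs.sum()

    symbols: list[str] = []
    bonds: list[tuple[int, int, int]] = []
    free: list[int] = []  # remaining valence per atom (0-based)

    def draw() -> str:
        return syms[int(rng.choice(len(syms), p=probs))]

    symbols.append(draw())
    free.append(_VALENCE[symbols[0]])
    for k in range(1, n_heavy):
        hosts = [i for i, f in enumerate(free) if f >= 1]
        if not hosts:
            raise ValueError("infeasible valence request: no open attachment")
        host = int(rng.choice(hosts))
        sym = draw()
        remaining = n_heavy - k - 1
        order = 1
        if free[host] >= 2 and _VALENCE[sym] >= 2 and rng.random() < 0.15:
            # Keep an open valence somewhere while atoms remain to place.
            left = sum(free) - free[host] + (free[host] - 2) + _VALENCE[sym] - 2
            if remaining == 0 or left >= 1:
                order = 2
        symbols.append(sym)
        free.append(_VALENCE[sym] - order)
        free[host] -= order
        bonds.append((host + 1, len(symbols), order))

    # Occasional ring closure between non-adjacent open atoms.
    if n_heavy >= 3 and rng.random() < 0.35:
        adjacent = {(min(a, b), max(a, b)) for a, b, _ in bonds}
        open_atoms = [i for i, f in enumerate(free) if f >= 1]
        rng.shuffle(open_atoms)
        for ai in range(len(open_atoms)):
            for bi in range(ai + 1, len(open_atoms)):
                a, b = open_atoms[ai] + 1, open_atoms[bi] + 1
                if (min(a, b), max(a, b)) in adjacent:
                    continue
                bonds.append((min(a, b), max(a, b), 1))
                free[a - 1] -= 1
                free[b - 1] -= 1
                open_atoms = []
                break
            if not open_atoms:
                break

    return heavy_molecule(symbols, bonds, name=f"random-{seed}",
                          mol_id=f"RND{seed:06d}")


def planted_database(kind: str, seed: int = 0):
    """Ground-truth fixture databases.

    Returns ``(molecules, truth)`` where ``truth`` records the planted
    structure: for ``isomer_pairs`` the isomeric formulae; for
    ``stereo_pairs`` the stereoisomeric id pairs; for ``strategy_testbed``
    the group set that fully disambiguates the planted isomer pairs.
    """
    if kind == "isomer_pairs":
        names = [
            "ethanol", "dimethyl ether",      # C2H6O x2
            "acetone", "propanal",            # C3H6O x2
            "propan-1-ol", "propan-2-ol", "methoxyethane",  # C3H8O x3
            "methane", "glycerol",            # unique formulae
        ]
        mols = [build_compound(n, mol_id=f"P{i:03d}")
                for i, n in enumerate(names)]
        truth = {
            "isomeric_formulae": {"C2H6O1", "C3H6O1", "C3H8O1"},
            "n_distinct_formulae": 5,
            "n_isomeric_entries": 7,
        }
        return mols, truth
    if kind == "stereo_pairs":
        names = ["l-alanine", "d-alanine", "r-3-hydroxybutyric acid",
                 "2-hydroxybutyric acid", "acetone", "glycerol",
                 "deoxycytidine", "deoxyuridine", "methane", "ethanol"]
        mols = [build_compound(n, mol_id=f"S{i:03d}")
                for i, n in enumerate(names)]
        truth = {
            "stereo_pairs": {("S000", "S001")},
            "candidate_pairs": {("S000", "S001"), ("S002", "S003")},
        }
        return mols, truth
    if kind == "strategy_testbed":
        pairs = [
            ("acetone", "propanal"),            # ketone separates
            ("butan-2-one", "butanal"),         # ketone separates
            ("ethanol", "dimethyl ether"),      # alcohol separates
            ("propan-1-ol", "methoxyethane"),   # alcohol separates
            ("acetic acid", "methyl formate"),  # carboxylic acid separates
            ("propionic acid", "methyl acetate"),
        ]
        names = [n for pair in pairs for n in pair]
        mols = [build_compound(n, mol_id=f"T{i:03d}")
                for i, n in enumerate(names)]
        truth = {
            "separating_groups": {"ketone", "alcohol", "carboxylic acid"},
            # The acid's structural !H atom claims the alpha carbon, so on
            # acids the carboxylic-acid instance overlaps an adjacent methyl
            # instance; the planted set separates every pair once
            # overlapping and subgraph instances count toward the signature.
            "scope": "distinct+subgraph+overlapping",
            "n_pairs": len(pairs),
        }
        return mols, truth
    raise ValueError(f"unknown planted database kind {kind!r}")
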