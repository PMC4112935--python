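"""Adjacency matrices, node coloring and the candidate mapping matrix.

A molecule with ``n`` atoms becomes a symmetric ``n x n`` integer matrix
whose entry (i, j) is the bond order between atoms i+1 and j+1 (0 when not
bonded).  A substructure query B against a compound A is screened through a
binary *mapping matrix* ``M`` of shape (b, a): ``M[i, j] = 1`` when query
atom i+1 may map onto compound atom j+1 under the selected node-coloring
constraint.  The *possible node mapping count* ``m`` is the sum of ``M``
over rows of non-contextual query atoms; it predicts enumeration effort.

Colorings, from coarsest to finest:

* ``element_only`` — the query atom's element constraint alone,
* ``element_plus_degree`` — additionally the compound atom must have at
  least the query atom's degree (the classic Ullmann node condition),
* ``n_bond(N)`` — equal iterative neighborhood-refinement colors to depth
  N; exact-symbol molecules only, used for whole-molecule (stereoisomer)
  comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molfile_io import Molecule, MolfileError

__all__ = [
    "AdjacencyMatrix",
    "MappingMatrix",
    "Coloring",
    "adjacency_matrix",
    "node_colors",
    "mapping_matrix",
    "has_empty_row",
]


@dataclass(frozen=True)
class AdjacencyMatrix:
    n: int
    entries: np.ndarray  # (n, n) int array of bond orders

    def order(self, i: int, j: int) -> int:
        """Bond order between 1-based atom indices i and j."""
        return int(self.entries[i - 1, j - 1])


@dataclass(frozen=True)
class Coloring:
    """Mapping-matrix node constraint selector."""

    kind: str  # element_only | element_plus_degree | n_bond
    depth: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("element_only", "element_plus_degree", "n_bond"):
            raise ValueError(f"unknown coloring {self.kind!r}")
        if self.kind == "n_bond" and self.depth < 0:
            raise ValueError("n_bond depth must be >= 0")


ELEMENT_ONLY = Coloring("element_only")
ELEMENT_PLUS_DEGREE = Coloring("element_plus_degree")


def n_bond(depth: int) -> Coloring:
    return Coloring("n_bond", depth)


@dataclass(frozen=True)
class MappingMatrix:
    rows: int  # b, query atoms
    cols: int  # a, compound atoms
    entries: np.ndarray  # (b, a) binary
    m: int  # possible node mapping count over non-contextual rows


def adjacency_matrix(mol: Molecule) -> AdjacencyMatrix:
    """Symmetric bond-order matrix of a molecule."""
    n = mol.n_atoms
    entries = np.zeros((n, n), dtype=np.int64)
    for bond in mol.bonds:
        entries[bond.a - 1, bond.b - 1] = bond.order
        entries[bond.b - 1, bond.a - 1] = bond.order
    return AdjacencyMatrix(n=n, entries=entries)


def node_colors(mol: Molecule, depth: int) -> list[str]:
    """Canonical neighborhood-refinement color per atom, to ``depth`` bonds.

    Depth 0 is the element symbol alone; each further round refines an
    atom's color with the sorted multiset of (bond order, neighbor color)
    pairs.  Equal colors at depth N+1 imply equal colors at depth N.
    Signatures are deterministic strings, so ties break identically across
    runs.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if any(not a.spec.is_exact for a in mol.atoms):
        raise MolfileError(
            "node coloring applies to exact-element molecules only"
        )
    colors = {a.index: a.symbol for a in mol.atoms}
    neigh = {a.index: mol.neighbors(a.index) for a in mol.atoms}
    for _ in range(depth):
        new = {}
        for idx, base in colors.items():
            shell = sorted(f"{order}:{colors[j]}" for j, order in neigh[idx])
            new[idx] = base.split("(")[0] + "(" + ",".join(shell) + ")"
        colors = new
    return [colors[a.index] for a in mol.atoms]


def mapping_matrix(
    query: Molecule, compound: Molecule, coloring: Coloring = ELEMENT_ONLY
) -> MappingMatrix:
    """Build the candidate matrix M and its possible node mapping count m.

    ``m`` sums M over non-contextual query rows only, so contextual atoms
    never inflate the reported search-effort estimate.
    """
    b, a = query.n_atoms, compound.n_atoms
    entries = np.zeros((b, a), dtype=np.int64)

    if coloring.kind == "n_bond":
        qcolors = node_colors(query, coloring.depth)
        ccolors = node_colors(compound, coloring.depth)
        for i in range(b):
            for j in range(a):
                entries[i, j] = 1 if qcolors[i] == ccolors[j] else 0
    else:
        csyms = [atom.symbol for atom in compound.atoms]
        cdeg = [compound.degree(atom.index) for atom in compound.atoms]
        for i, qatom in enumerate(query.atoms):
            qd = query.degree(qatom.index)
            for j in range(a):
                if not qatom.spec.matches(csyms[j]):
                    continue
                if coloring.kind == "element_plus_degree" and cdeg[j] < qd:
                    continue
                entries[i, j] = 1

    structural = [not atom.spec.contextual for atom in query.atoms]
    m = int(entries[np.array(structural, dtype=bool)].sum()) if b else 0
    return MappingMatrix(rows=b, cols=a, entries=entries, m=m)


def has_empty_row(M: MappingMatrix) -> bool:
    """True when some query atom (contextual included) has no candidate."""
    if M.rows == 0:
        return False
    return bool((M.entries.sum(axis=1) == 0).any())
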