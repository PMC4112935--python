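"""Subgraph-isomorphism enumeration over molecular graphs.

The enumerator tracks the search state with two integer vectors instead of
copying mapping matrices:

* ``v`` (length b) — the compound atom currently mapped to each query atom,
  or -1 while unmapped;
* ``u`` (length a) — compound atoms excluded from further *structural*
  mapping because they already belong to a stored isomorphism (or were
  supplied as input exclusions).

Validity is induced equality: a complete ``v`` is an isomorphism when the
compound bond order between images equals the query bond order for *every*
query atom pair, bonds and non-bonds alike.  Partial assignments violating
this are pruned immediately, and an optional short-circuit stops at the
first valid mapping (useful when existence alone answers the question, as
in stereoisomer detection).

A straightforward matrix-copying enumerator in the style of Ullmann's 1976
procedure (modern control flow, no gotos) ships alongside as an independent
correctness oracle for small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_core import (
    ELEMENT_PLUS_DEGREE,
    AdjacencyMatrix,
    Coloring,
    MappingMatrix,
    adjacency_matrix,
    has_empty_row,
    mapping_matrix,
)
from .molfile_io import Molecule

__all__ = [
    "MappingVector",
    "SearchOptions",
    "is_valid_isomorphism",
    "enumerate_isomorphisms",
    "ullmann_reference",
    "UNMAPPED",
]

UNMAPPED = -1


@dataclass(frozen=True)
class MappingVector:
    """Compound atom index (1-based) per query atom; -1 while unmapped."""

    entries: tuple[int, ...]

    def __getitem__(self, i: int) -> int:
        return self.entries[i]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def complete(self) -> bool:
        return UNMAPPED not in self.entries

    def core_atoms(self, query: Molecule) -> frozenset[int]:
        """Images of the non-contextual query atoms."""
        return frozenset(
            self.entries[i]
            for i, atom in enumerate(query.atoms)
            if not atom.spec.contextual
        )


@dataclass
class SearchOptions:
    short_circuit: bool = False
    disjoint_counting: bool = False
    initial_exclusions: frozenset[int] = frozenset()  # 1-based compound atoms
    coloring: Coloring = ELEMENT_PLUS_DEGREE


class ContractError(RuntimeError):
    """A caller violated an enumeration precondition."""


def is_valid_isomorphism(
    v: MappingVector, A_query: AdjacencyMatrix, A_compound: AdjacencyMatrix
) -> bool:
    """Induced bond-order equality over every query atom pair."""
    if not v.complete:
        raise ContractError("mapping vector has unassigned entries")
    if len(set(v.entries)) != len(v.entries):
        raise ContractError("mapping vector is not injective")
    b = len(v)
    for i in range(b):
        for j in range(i + 1, b):
            if A_query.order(i + 1, j + 1) != A_compound.order(v[i], v[j]):
                return False
    return True


def _assignment_order(query: Molecule) -> list[int]:
    # Descending degree, ties by index: high-constraint atoms first.
    return sorted(
        range(query.n_atoms),
        key=lambda i: (-query.degree(i + 1), i),
    )


def enumerate_isomorphisms(
    query: Molecule,
    compound: Molecule,
    options: SearchOptions | None = None,
) -> list[MappingVector]:
    """All (or, short-circuited, the first) isomorphisms of query in compound.

    Candidates come from the mapping matrix; assignment is depth-first in
    descending query-degree order with ascending compound-index candidates,
    so output order is deterministic.  With ``disjoint_counting`` the
    non-contextual image of each stored mapping is marked used and becomes
    unavailable to later *non-contextual* query atoms; contextual atoms may
    still match used atoms, so adjacent groups sharing context are all
    found.  Mirror-image duplicates are not suppressed here.
    """
    opts = options or SearchOptions()
    b, a = query.n_atoms, compound.n_atoms
    if b == 0 or a < b:
        return []
    M: MappingMatrix = mapping_matrix(query, compound, opts.coloring)
    if has_empty_row(M):
        return []

    Aq = adjacency_matrix(query).entries
    Ac = adjacency_matrix(compound).entries
    order = _assignment_order(query)
    contextual = [atom.spec.contextual for atom in query.atoms]
    candidates = [np.flatnonzero(M.entries[i]) + 1 for i in range(b)]

    u = np.zeros(a + 1, dtype=bool)  # 1-based; u[j] == atom j excluded
    for j in opts.initial_exclusions:
        u[j] = True

    v = [UNMAPPED] * b
    used = [False] * (a + 1)  # injectivity within the current partial map
    results: list[MappingVector] = []

    def consistent(i: int, j: int) -> bool:
        # Δ short-circuit: check the new assignment against all mapped atoms.
        for k in range(b):
            if v[k] == UNMAPPED or k == i:
                continue
            if Aq[i, k] != Ac[j - 1, v[k] - 1]:
                return False
        return True

    def dfs(pos: int) -> bool:
        if pos == b:
            # Atoms may have been marked used after this branch assigned
            # them; re-check the structural image before storing.
            if opts.disjoint_counting and any(
                u[v[k]] for k in range(b) if not contextual[k]
            ):
                return False
            results.append(MappingVector(tuple(v)))
            if opts.disjoint_counting:
                for k in range(b):
                    if not contextual[k]:
                        u[v[k]] = True
            return opts.short_circuit
        i = order[pos]
        for j in candidates[i]:
            j = int(j)
            if used[j]:
                continue
            if u[j] and not contextual[i]:
                continue
            if not consistent(i, j):
                continue
            v[i] = j
            used[j] = True
            stop = dfs(pos + 1)
            v[i] = UNMAPPED
            used[j] = False
            if stop:
                return True
        return False

    dfs(0)
    return results


def ullmann_reference(
    query: Molecule, compound: Molecule, max_compound_atoms: int = 25
) -> list[MappingVector]:
    """Matrix-copying exhaustive enumerator (test oracle for small inputs).

    Follows the depth-first scheme of the classic mapping-matrix procedure:
    at depth d a candidate matrix M' fixes row d to a single 1, recursing
    until every row is fixed, then validates induced bond-order equality.
    No exclusion vector, no short-circuiting, no degree pruning beyond the
    mapping matrix itself.
    """
    if compound.n_atoms > max_compound_atoms:
        raise ValueError(
            f"oracle guard: compound has {compound.n_atoms} atoms "
            f"(> {max_compound_atoms}); use enumerate_isomorphisms"
        )
    b, a = query.n_atoms, compound.n_atoms
    if b == 0 or a < b:
        return []
    M = mapping_matrix(query, compound).entries.copy()
    if (M.sum(axis=1) == 0).any():
        return []
    Aq = adjacency_matrix(query)
    Ac = adjacency_matrix(compound)
    results: list[MappingVector] = []

    def recurse(depth: int, Mp: np.ndarray, used_cols: set[int]) -> None:
        if depth == b:
            v = MappingVector(
                tuple(int(np.flatnonzero(Mp[i])[0]) + 1 for i in range(b))
            )
            if is_valid_isomorphism(v, Aq, Ac):
                results.append(v)
            return
        for j in range(a):
            if Mp[depth, j] == 0 or j in used_cols:
                continue
            child = Mp.copy()  # the deliberate matrix copy of the original
            child[depth, :] = 0
            child[depth, j] = 1
            recurse(depth + 1, child, used_cols | {j})

    recurse(0, M, set())
    return results
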