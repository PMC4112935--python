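import math

import networkx as nx
import pytest

from cass import fixtures as fx
from cass.molfile_io import add_implicit_hydrogens


@pytest.fixture(scope="session")
def library():
    return fx.build_group_library()


@pytest.fixture(scope="session")
def groups(library):
    return {g.name: g for g in library}


@pytest.fixture(scope="session")
def compound():
    """Factory for hydrogen-complete registry compounds."""
    return fx.build_compound


def to_networkx(mol):
    g = nx.Graph()
    for a in mol.atoms:
        g.add_node(a.index, spec=a.spec,
                   symbol=a.symbol if a.spec.is_exact else None)
    for b in mol.bonds:
        g.add_edge(b.a, b.b, order=b.order)
    return g


def networkx_mappings(query, mol):
    """Independent induced-subgraph-isomorphism oracle (VF2)."""
    gm = nx.algorithms.isomorphism.GraphMatcher(
        to_networkx(mol), to_networkx(query),
        node_match=lambda cn, qn: qn["spec"].matches(cn["symbol"]),
        edge_match=lambda ce, qe: ce["order"] == qe["order"],
    )
    out = set()
    for mapping in gm.subgraph_isomorphisms_iter():
        inv = {q: c for c, q in mapping.items()}
        out.add(tuple(inv[i] for i in range(1, query.n_atoms + 1)))
    return sorted(out)


def candidate_work(query, mol):
    """Product of per-row element-candidate counts (brute-force size)."""
    return math.prod(
        sum(1 for ca in mol.atoms if qa.spec.matches(ca.symbol))
        for qa in query.atoms
    )


@pytest.fixture(scope="session")
def random_corpus():
    """Seed-deterministic hydrogen-complete random molecules (<= 25 atoms)."""
    mols = []
    for seed in range(100):
        mol = add_implicit_hydrogens(fx.random_molecule(seed, 3 + seed % 4))
        assert mol.n_atoms <= 25
        mols.append(mol)
    return mols
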