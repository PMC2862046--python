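import networkx as nx
import pytest
from rdkit import Chem

import chemflow as cf


@pytest.fixture(scope="session")
def organic_set():
    """Twenty clean organic molecules (no metals)."""
    return cf.gen_molecules(20, seed=11, contaminate_metals=0.0)


@pytest.fixture(scope="session")
def contaminated_set():
    """Twenty molecules, exactly three carrying a catalogue-absent metal."""
    return cf.gen_molecules(20, seed=11, contaminate_metals=0.15)


@pytest.fixture()
def smiles_set():
    def build(smiles):
        return cf.MoleculeSet([cf.parse_smiles(s) for s in smiles])

    return build


def mol_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), z=atom.GetAtomicNum(), arom=atom.GetIsAromatic())
    for bond in mol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(),
            bond.GetEndAtomIdx(),
            order=str(bond.GetBondType()),
        )
    return g


def brute_force_match(target: Chem.Mol, query: Chem.Mol) -> bool:
    """Independent subgraph-monomorphism substructure oracle (VF2, networkx).

    Matching semantics mirror topological substructure search: atoms match on
    atomic number + aromatic flag, bonds on order (aromatic only matches
    aromatic).
    """
    gm = nx.algorithms.isomorphism.GraphMatcher(
        mol_graph(target),
        mol_graph(query),
        node_match=lambda a, b: a["z"] == b["z"] and a["arom"] == b["arom"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    return gm.subgraph_is_monomorphic()


# queries for which SMARTS-compiled and plain-graph matching semantics agree:
# uncharged, explicit aromatic/aliphatic atoms, explicit bond orders
ORACLE_QUERIES = [
    "CC",
    "CO",
    "CN",
    "C=O",
    "CCC",
    "CCO",
    "C#N",
    "CCN",
    "c1ccccc1",
    "c1ccncc1",
]
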