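"""Seeded synthetic fixtures: molecule sets, labeled vector clouds, reactions.

Everything a workflow needs for testing is generated here, reproducibly from
a seed, so no external chemistry database is required.  Molecules are built
by fragment assembly from a fixed vocabulary of valence-safe organic
fragments — outputs always parse and sanitize.  Vector clouds emulate the
geometry ART 2-A consumes (non-negative descriptor-like vectors forming
tight, well-separated cosine clusters) with ground-truth labels for recovery
tests; they do not emulate real descriptor distributions.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import MoleculeRecord, MoleculeSet
from .enumeration import GenericReaction, ReactantSet, reaction_from_block
from .qsar import QSARVectorTable

__all__ = [
    "CloudSpec",
    "gen_molecules",
    "gen_vector_clouds",
    "gen_reaction_fixture",
    "reaction_fixture_rxn_block",
]

# valence-safe organic scaffolds (complete molecules; substituents attach at
# atoms that still carry implicit hydrogens)
_SCAFFOLDS = [
    "c1ccccc1", "c1ccncc1", "c1ccsc1", "c1ccoc1", "C1CCCCC1", "C1CCNCC1",
    "C1CCOCC1", "c1ccc2ccccc2c1", "C1CCC1", "c1cnc[nH]1",
]
_SUBSTITUENTS = [
    "C", "CC", "CCC", "CC(C)C", "CO", "OC", "CN", "NC(C)=O", "C(=O)O",
    "C(=O)N", "C#N", "F", "Cl", "Br", "S", "OCC", "N(C)C", "C(F)(F)F",
    "CCO", "CC=C",
]
_METALS = ["Na", "Ti", "Fe", "Tc", "Pt"]


def _attachable_atoms(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]


def _attach(core: Chem.Mol, sub: Chem.Mol, core_idx: int, sub_idx: int) -> Chem.Mol:
    """Join two fragments by a single bond, consuming one implicit H per side.

    Returns the core unchanged when the junction cannot be sanitized (e.g. a
    pyrrole NH that would become pentavalent).
    """
    offset = core.GetNumAtoms()
    rw = Chem.RWMol(Chem.CombineMols(core, sub))
    rw.AddBond(core_idx, offset + sub_idx, Chem.BondType.SINGLE)
    for idx in (core_idx, offset + sub_idx):
        atom = rw.GetAtomWithIdx(idx)
        if atom.GetNumExplicitHs() > 0:
            atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return core
    return mol


def gen_molecules(n: int, seed: int = 0, contaminate_metals: float = 0.0) -> MoleculeSet:
    """Generate ``n`` small organic molecules by seeded fragment assembly.

    ``contaminate_metals`` is the fraction (rounded to a count) of molecules
    that receive one catalogue-absent metal atom, for atom-type validation
    tests.  Same seed → identical SMILES list.
    """
    if not 0.0 <= contaminate_metals <= 1.0:
        raise ValueError("contaminate_metals must lie in [0, 1]")
    rng = random.Random(seed)
    n_metal = int(round(n * contaminate_metals))
    metal_slots = set(rng.sample(range(n), n_metal)) if n else set()
    out = MoleculeSet(provenance=f"gen_molecules(seed={seed})")
    for i in range(n):
        mol = Chem.MolFromSmiles(rng.choice(_SCAFFOLDS))
        for _ in range(rng.randint(0, 3)):
            sub = Chem.MolFromSmiles(rng.choice(_SUBSTITUENTS))
            sites = _attachable_atoms(mol)
            sub_sites = _attachable_atoms(sub)
            if not sites or not sub_sites:
                continue
            mol = _attach(mol, sub, rng.choice(sites), rng.choice(sub_sites))
        if i in metal_slots:
            metal = Chem.MolFromSmiles(f"[{rng.choice(_METALS)}]")
            sites = _attachable_atoms(mol)
            rng.shuffle(sites)
            for site in sites:
                grown = _attach(mol, metal, site, 0)
                if grown.GetNumAtoms() > mol.GetNumAtoms():
                    mol = grown
                    break
            else:  # no bondable site: carry the metal as a separate component
                mol = Chem.CombineMols(mol, metal)
        out.records.append(MoleculeRecord(mol, {"synthetic": "true"}))
    return out


@dataclass
class CloudSpec:
    """Geometry of a labeled synthetic descriptor-vector cloud set."""

    n_clusters: int = 2
    points_per_cluster: int = 10
    dim: int = 8
    within_cluster_cosine_min: float = 0.95
    between_cluster_cosine_max: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for b in (self.within_cluster_cosine_min, self.between_cluster_cosine_max):
            if not 0.0 <= b <= 1.0:
                raise ValueError("cosine bounds must lie in [0, 1]")
        if self.within_cluster_cosine_min <= self.between_cluster_cosine_max:
            raise ValueError("within-cluster bound must exceed between-cluster bound")
        if self.dim < self.n_clusters:
            raise ValueError("dim must be >= n_clusters for separable centroids")


def _cloud_attempt(spec: CloudSpec, rng: np.random.Generator) -> np.ndarray:
    # centroids on disjoint coordinate blocks -> exactly orthogonal
    block = spec.dim // spec.n_clusters
    points = np.empty((spec.n_clusters * spec.points_per_cluster, spec.dim))
    eps = 0.12  # noise amplitude keeping within-cluster cosine high
    for k in range(spec.n_clusters):
        centroid = np.zeros(spec.dim)
        lo = k * block
        hi = spec.dim if k == spec.n_clusters - 1 else lo + block
        centroid[lo:hi] = rng.uniform(0.5, 1.0, hi - lo)
        centroid /= np.linalg.norm(centroid)
        for j in range(spec.points_per_cluster):
            p = centroid + eps * rng.uniform(0.0, 1.0, spec.dim)
            points[k * spec.points_per_cluster + j] = p / np.linalg.norm(p)
    return points


def _cosine_ok(points: np.ndarray, spec: CloudSpec) -> bool:
    m = spec.points_per_cluster
    G = points @ points.T
    for a in range(spec.n_clusters):
        sa = slice(a * m, (a + 1) * m)
        if G[sa, sa].min() <= spec.within_cluster_cosine_min:
            return False
        for b in range(a + 1, spec.n_clusters):
            sb = slice(b * m, (b + 1) * m)
            if G[sa, sb].max() >= spec.between_cluster_cosine_max:
                return False
    return True


def gen_vector_clouds(spec: CloudSpec) -> tuple[QSARVectorTable, dict[str, int]]:
    """Labeled descriptor-like vector clouds satisfying the cosine bounds.

    Candidate clouds are resampled until the pairwise-cosine bounds hold
    (verified post hoc, not assumed).  Returns the table (rows
    ``v-000001``.., non-negative cells) and the ground-truth label of every
    row.
    """
    rng = np.random.default_rng(spec.seed)
    for _ in range(200):
        points = _cloud_attempt(spec, rng)
        if _cosine_ok(points, spec):
            break
    else:
        raise RuntimeError("could not satisfy cosine bounds; loosen the spec")
    uids = [f"v-{i + 1:06d}" for i in range(points.shape[0])]
    labels = {
        uid: i // spec.points_per_cluster for i, uid in enumerate(uids)
    }
    table = pd.DataFrame(
        points, index=uids, columns=[f"x{j}" for j in range(spec.dim)]
    )
    table.index.name = "uid"
    return table, labels


# ---------------------------------------------------------------------------
# Reaction fixtures

_FRAGMENTS = [
    "*C", "*CC", "*CCC", "*C(C)C", "*CO", "*CCO", "*CN", "*N(C)C", "*OC",
    "*c1ccccc1", "*C(F)(F)F", "*CC=C", "*C#N", "*CCCC", "*OCC", "*SC",
]


def reaction_fixture_rxn_block(k_positions: int) -> str:
    """MDL RXN block of a k-position generic reaction.

    The product skeleton is a k-carbon chain bearing one R-group per carbon;
    each reactant template is the corresponding ``R#``-carbon fragment.
    """
    if k_positions < 1:
        raise ValueError("need at least one position")
    from rdkit.Chem import rdChemReactions

    def _labeled_dummy(label: int) -> Chem.Atom:
        a = Chem.Atom(0)
        a.SetIntProp("_MolFileRLabel", label)
        return a

    rxn = rdChemReactions.ChemicalReaction()
    for label in range(1, k_positions + 1):
        rw = Chem.RWMol()
        c = rw.AddAtom(Chem.Atom(6))
        d = rw.AddAtom(_labeled_dummy(label))
        rw.AddBond(c, d, Chem.BondType.SINGLE)
        rxn.AddReactantTemplate(rw.GetMol())
    rw = Chem.RWMol()
    chain = [rw.AddAtom(Chem.Atom(6)) for _ in range(k_positions)]
    for i in range(k_positions - 1):
        rw.AddBond(chain[i], chain[i + 1], Chem.BondType.SINGLE)
    for label, c in enumerate(chain, start=1):
        d = rw.AddAtom(_labeled_dummy(label))
        rw.AddBond(c, d, Chem.BondType.SINGLE)
    rxn.AddProductTemplate(rw.GetMol())
    return rdChemReactions.ReactionToRxnBlock(rxn)


def gen_reaction_fixture(
    k_positions: int, sizes: tuple[int, ...], seed: int = 0
) -> tuple[GenericReaction, list[ReactantSet]]:
    """A k-position generic reaction plus per-position reactant lists.

    Fragments are drawn without replacement from a fixed vocabulary and the
    positions receive disjoint fragments, so distinct combinations yield
    distinct products and the enumeration count law |products| = ∏ sizes
    holds exactly.
    """
    if len(sizes) != k_positions:
        raise ValueError("one size per position required")
    total = sum(sizes)
    if total > len(_FRAGMENTS):
        raise ValueError(f"at most {len(_FRAGMENTS)} fragments available, {total} requested")
    rng = random.Random(seed)
    picks = rng.sample(_FRAGMENTS, total)
    reaction = reaction_from_block(reaction_fixture_rxn_block(k_positions))
    sets: list[ReactantSet] = []
    start = 0
    for pos, size in enumerate(sizes, start=1):
        molset = MoleculeSet(provenance=f"reaction fixture position R{pos}")
        for j, smi in enumerate(picks[start : start + size]):
            rec = MoleculeRecord(Chem.MolFromSmiles(smi), {}, uid=f"R{pos}-{j + 1}")
            molset.records.append(rec)
        sets.append(ReactantSet(position=f"R{pos}", molecules=molset))
        start += size
    return reaction, sets
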