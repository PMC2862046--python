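"""Generic (Markush) reaction enumeration.

A generic reaction drawn with R-group placeholders (R1..Rk) describes a whole
compound class: each placeholder position is a building block for which a
scientist supplies a list of concrete reactant fragments.  Enumeration takes
the cartesian product over positions and grafts each fragment combination
onto the product-side skeleton, yielding the full library of products — the
classic route to targeted screening libraries and patent claim expansion.

Attachment semantics: each reactant fragment designates exactly one
attachment atom (either via an ``attachment_atom`` property or a single
dummy ``*`` atom whose neighbor is the attachment); it replaces the R#
pseudo-atom in the skeleton, forming a single bond of the order drawn in the
template.  Product identity is canonical SMILES; duplicate products collapse
with a logged multiplicity.
"""

from __future__ import annotations

import csv
import itertools
import logging
import os
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import rdChemReactions

from .chem_io import MoleculeRecord, MoleculeSet

logger = logging.getLogger(__name__)

__all__ = [
    "GenericReaction",
    "ReactantSet",
    "read_rxn",
    "reaction_from_block",
    "enumerate_products",
    "enumeration_report",
]

_RLABEL = "_MolFileRLabel"


def _r_labels(mol: Chem.Mol) -> dict[int, int]:
    """Map R-group label number -> atom index of the R# pseudo-atom."""
    out: dict[int, int] = {}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.HasProp(_RLABEL):
            out[atom.GetIntProp(_RLABEL)] = atom.GetIdx()
    return out


@dataclass
class GenericReaction:
    """Reaction template with R-group placeholder positions.

    ``labels`` are the sorted placeholder numbers (R1..Rk appearing on the
    product side); ``skeleton`` is the product-side molecule still carrying
    its R# pseudo-atoms.  Every product-side label must also appear on the
    reactant side.
    """

    skeleton: Chem.Mol
    labels: list[int]
    reactant_labels: set[int] = field(default_factory=set)

    @property
    def k(self) -> int:
        return len(self.labels)

    def position_names(self) -> list[str]:
        return [f"R{n}" for n in self.labels]


@dataclass
class ReactantSet:
    """Reactant fragments for one placeholder position.

    Each molecule must carry exactly one attachment point: an
    ``attachment_atom`` property holding an atom index, or a single dummy
    atom whose sole neighbor is the attachment.
    """

    position: str
    molecules: MoleculeSet

    def __post_init__(self) -> None:
        if len(self.molecules) == 0:
            raise ValueError(f"reactant list for {self.position} is empty")
        for i, rec in enumerate(self.molecules):
            _fragment_with_attachment(rec)  # validates

    def fragments(self) -> list[tuple[Chem.Mol, int, str]]:
        """(clean fragment, attachment atom index, reactant id) per molecule."""
        out = []
        for i, rec in enumerate(self.molecules):
            mol, att = _fragment_with_attachment(rec)
            rid = rec.uid or f"{self.position}-{i + 1}"
            out.append((mol, att, rid))
        return out


def _fragment_with_attachment(record: MoleculeRecord) -> tuple[Chem.Mol, int]:
    """Resolve a reactant fragment to (dummy-free mol, attachment atom index)."""
    mol = record.mol
    if "attachment_atom" in record.properties:
        idx = int(record.properties["attachment_atom"])
        if not 0 <= idx < mol.GetNumAtoms():
            raise ValueError(f"attachment_atom {idx} out of range")
        return Chem.Mol(mol), idx
    dummies = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise ValueError(
            "reactant fragment must carry exactly one attachment point "
            f"(found {len(dummies)} dummy atoms and no attachment_atom property)"
        )
    d = dummies[0]
    neighbors = [n.GetIdx() for n in mol.GetAtomWithIdx(d).GetNeighbors()]
    if len(neighbors) != 1:
        raise ValueError("attachment dummy atom must have exactly one neighbor")
    att = neighbors[0]
    rw = Chem.RWMol(mol)
    rw.RemoveAtom(d)
    if att > d:
        att -= 1
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out, att


# ---------------------------------------------------------------------------
# RXN reading


def reaction_from_block(block: str) -> GenericReaction:
    rxn = rdChemReactions.ReactionFromRxnBlock(block)
    if rxn is None:
        raise ValueError("unparseable RXN block")
    return _generic_from_reaction(rxn)


def read_rxn(path: str | os.PathLike) -> GenericReaction:
    """Load a generic reaction from an MDL RXNfile (V2000, R# pseudo-atoms)."""
    rxn = rdChemReactions.ReactionFromRxnFile(os.fspath(path))
    if rxn is None:
        raise ValueError(f"unparseable RXN file: {path}")
    return _generic_from_reaction(rxn)


def _generic_from_reaction(rxn: rdChemReactions.ChemicalReaction) -> GenericReaction:
    if rxn.GetNumProductTemplates() != 1:
        raise ValueError(
            f"expected exactly one product template, found {rxn.GetNumProductTemplates()}"
        )
    reactant_labels: set[int] = set()
    for t in rxn.GetReactants():
        reactant_labels |= set(_r_labels(t))
    skeleton = Chem.Mol(rxn.GetProducts()[0])
    product_labels = _r_labels(skeleton)
    if not product_labels and not reactant_labels:
        raise ValueError("reaction template contains no R# placeholder atoms")
    orphans = sorted(set(product_labels) - reactant_labels)
    if orphans:
        raise ValueError(
            f"product-side labels with no reactant-side counterpart: "
            f"{['R%d' % n for n in orphans]}"
        )
    if not product_labels:
        raise ValueError("product skeleton carries no R# placeholder atoms")
    return GenericReaction(
        skeleton=skeleton,
        labels=sorted(product_labels),
        reactant_labels=reactant_labels,
    )


# ---------------------------------------------------------------------------
# Enumeration


def _graft(skeleton: Chem.Mol, pieces: dict[int, tuple[Chem.Mol, int]]) -> Chem.Mol:
    """Replace each R# pseudo-atom with its fragment; returns sanitized product."""
    mol = Chem.Mol(skeleton)
    for label, (frag, att) in pieces.items():
        positions = _r_labels(mol)
        d = positions[label]
        dummy = mol.GetAtomWithIdx(d)
        nbrs = dummy.GetNeighbors()
        if len(nbrs) != 1:
            raise ValueError(f"R{label} pseudo-atom must have exactly one neighbor")
        anchor = nbrs[0].GetIdx()
        order = mol.GetBondBetweenAtoms(d, anchor).GetBondType()
        offset = mol.GetNumAtoms()
        rw = Chem.RWMol(Chem.CombineMols(mol, frag))
        rw.AddBond(anchor, offset + att, order)
        rw.RemoveAtom(d)
        mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def enumerate_products(
    reaction: GenericReaction, reactant_sets: list[ReactantSet]
) -> MoleculeSet:
    """Enumerate all fragment combinations through a generic reaction.

    One :class:`ReactantSet` per template position, in ``R1..Rk`` order.
    Products carry a ``combination`` property (reactant ids per position) and
    a ``multiplicity`` property counting how many combinations collapsed onto
    the same canonical SMILES.  Combinations whose graft violates valence are
    skipped and logged.
    """
    if len(reactant_sets) != reaction.k:
        raise ValueError(
            f"reaction has {reaction.k} positions but {len(reactant_sets)} "
            "reactant sets were supplied"
        )
    per_position = [rs.fragments() for rs in reactant_sets]
    out = MoleculeSet(provenance="enumeration")
    by_smiles: dict[str, MoleculeRecord] = {}
    n_products = 0
    for combo in itertools.product(*per_position):
        combo_ids = [rid for (_, _, rid) in combo]
        pieces = {
            label: (frag, att)
            for label, (frag, att, _) in zip(reaction.labels, combo)
        }
        try:
            product = _graft(reaction.skeleton, pieces)
        except Exception as exc:
            logger.warning("combination %s skipped: %s", "+".join(combo_ids), exc)
            continue
        smiles = Chem.MolToSmiles(product)
        if smiles in by_smiles:
            rec = by_smiles[smiles]
            rec.properties["multiplicity"] = str(int(rec.properties["multiplicity"]) + 1)
            logger.info("duplicate product %s from %s", smiles, "+".join(combo_ids))
            continue
        n_products += 1
        rec = MoleculeRecord(
            product,
            {
                "combination": "+".join(combo_ids),
                "multiplicity": "1",
            },
            uid=f"p-{n_products:06d}",
        )
        by_smiles[smiles] = rec
        out.records.append(rec)
    return out


def enumeration_report(products: MoleculeSet, directory: str | os.PathLike) -> dict[str, object]:
    """Write one Molfile per product plus a CSV manifest; returns the paths."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    molfile_paths = []
    manifest_path = os.path.join(directory, "products.csv")
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["product_id", "canonical_smiles", "combination", "multiplicity"])
        for rec in products:
            p = os.path.join(directory, f"{rec.uid}.mol")
            Chem.MolToMolFile(rec.mol, p)
            molfile_paths.append(p)
            writer.writerow(
                [
                    rec.uid,
                    rec.canonical_smiles(),
                    rec.properties.get("combination", ""),
                    rec.properties.get("multiplicity", "1"),
                ]
            )
    return {"molfiles": molfile_paths, "manifest": manifest_path}
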