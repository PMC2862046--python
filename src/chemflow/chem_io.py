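"""Molecule payload types and readers/writers for the exchanged formats.

Molecules flow between workers as :class:`MoleculeRecord` objects — an RDKit
molecular graph plus a free-form string property map and a universal identifier
tag (``uid``).  Collections travel as :class:`MoleculeSet`, which preserves
input order across read → process → write.

Supported formats: MDL SDfile/Molfile (V2000), SMILES, InChI, and a small CML
(Chemical Markup Language) subset covering ``molecule``/``atomArray``/
``bondArray``/``property`` elements.  Readers never abort a whole file on one
bad record: rejections are collected per record and reported.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from lxml import etree
from rdkit import Chem, RDLogger
from rdkit.Chem import inchi as _inchi

RDLogger.DisableLog("rdApp.*")

UID_PROP = "uid"

__all__ = [
    "MoleculeRecord",
    "MoleculeSet",
    "RejectedRecord",
    "read_sdf",
    "write_sdf",
    "write_molfiles",
    "parse_smiles",
    "to_smiles",
    "parse_inchi",
    "to_inchi",
    "read_cml",
    "write_cml",
]


@dataclass
class MoleculeRecord:
    """One molecule: graph + string property map + identifier tag.

    ``uid`` may be empty before tagging (see :func:`chemflow.qsar.tag_molecules`);
    once assigned it must be unique within a pipeline run.
    """

    mol: Chem.Mol
    properties: dict[str, str] = field(default_factory=dict)
    uid: str = ""

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def num_bonds(self) -> int:
        return self.mol.GetNumBonds()

    def canonical_smiles(self) -> str:
        """Canonical SMILES — the molecule identity used for deduplication."""
        return Chem.MolToSmiles(self.mol)

    def copy(self) -> "MoleculeRecord":
        return MoleculeRecord(Chem.Mol(self.mol), dict(self.properties), self.uid)


@dataclass
class RejectedRecord:
    """A record a reader could not parse; the run continues without it."""

    index: int
    reason: str


@dataclass
class MoleculeSet:
    """Ordered list of molecule records with provenance and rejection log."""

    records: list[MoleculeRecord] = field(default_factory=list)
    provenance: str = ""
    rejections: list[RejectedRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def smiles(self) -> list[str]:
        return [r.canonical_smiles() for r in self.records]


# ---------------------------------------------------------------------------
# SMILES / InChI


def parse_smiles(s: str) -> MoleculeRecord:
    """Parse a SMILES string into a molecule record.

    Raises ``ValueError`` on empty input or a syntax/valence error.
    """
    if not isinstance(s, str) or not s.strip():
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {s!r}")
    return MoleculeRecord(mol)


def to_smiles(record: MoleculeRecord) -> str:
    """Canonical SMILES of a record (idempotent under re-parsing)."""
    return record.canonical_smiles()


def to_inchi(record: MoleculeRecord) -> str:
    s = _inchi.MolToInchi(record.mol)
    if not s:
        raise ValueError("InChI generation failed")
    return s


def parse_inchi(s: str) -> MoleculeRecord:
    if not isinstance(s, str) or not s.startswith("InChI="):
        raise ValueError(f"not an InChI string: {s!r}")
    mol = _inchi.MolFromInchi(s)
    if mol is None:
        raise ValueError(f"unparseable InChI: {s!r}")
    return MoleculeRecord(mol)


# ---------------------------------------------------------------------------
# SDF / Molfile


def _record_from_mol(mol: Chem.Mol) -> MoleculeRecord:
    props = {k: str(mol.GetProp(k)) for k in mol.GetPropNames()}
    uid = props.pop(UID_PROP, "")
    return MoleculeRecord(mol, props, uid)


def _apply_props(record: MoleculeRecord) -> Chem.Mol:
    mol = Chem.Mol(record.mol)
    for k, v in record.properties.items():
        mol.SetProp(k, str(v))
    if record.uid:
        mol.SetProp(UID_PROP, record.uid)
    return mol


def read_sdf(path: str | os.PathLike) -> MoleculeSet:
    """Read a V2000 SDfile; one record per ``$$$$`` block, SD tags → properties.

    Unparseable blocks are logged in ``rejections`` and skipped; the read
    continues — pipelines here may process very large files and must not die
    on one corrupt entry.
    """
    path = os.fspath(path)
    supplier = Chem.SDMolSupplier(path, sanitize=True, removeHs=True)
    out = MoleculeSet(provenance=path)
    for i, mol in enumerate(supplier):
        if mol is None:
            out.rejections.append(RejectedRecord(i, "unparseable SDF block"))
            continue
        out.records.append(_record_from_mol(mol))
    return out


def write_sdf(molset: MoleculeSet, path: str | os.PathLike) -> str:
    path = os.fspath(path)
    writer = Chem.SDWriter(path)
    try:
        for rec in molset:
            writer.write(_apply_props(rec))
    finally:
        writer.close()
    return path


def write_molfiles(molset: MoleculeSet, directory: str | os.PathLike) -> list[str]:
    """Write each record as an individual MDL Molfile; returns the paths."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = []
    for i, rec in enumerate(molset):
        name = rec.uid or f"mol-{i:06d}"
        p = os.path.join(directory, f"{name}.mol")
        Chem.MolToMolFile(rec.mol, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# CML subset
#
# molecule/atomArray/bondArray/property only.  Atoms carry elementType,
# formalCharge and hydrogenCount; bonds carry order (1/2/3/A).  Unsupported
# elements are skipped with a warning collected on the returned set.

_CML_NS = "http://www.xml-cml.org/schema"
_BOND_ORDER_OUT = {
    Chem.BondType.SINGLE: "1",
    Chem.BondType.DOUBLE: "2",
    Chem.BondType.TRIPLE: "3",
    Chem.BondType.AROMATIC: "A",
}
_BOND_ORDER_IN = {
    "1": Chem.BondType.SINGLE,
    "S": Chem.BondType.SINGLE,
    "2": Chem.BondType.DOUBLE,
    "D": Chem.BondType.DOUBLE,
    "3": Chem.BondType.TRIPLE,
    "T": Chem.BondType.TRIPLE,
    "A": Chem.BondType.AROMATIC,
}


def write_cml(molset: MoleculeSet, path: str | os.PathLike) -> str:
    """Serialize a molecule set to a CML subset document."""
    root = etree.Element("cml", nsmap={None: _CML_NS})
    for i, rec in enumerate(molset):
        mol_el = etree.SubElement(root, "molecule")
        mol_el.set("id", rec.uid or f"m{i}")
        atoms = etree.SubElement(mol_el, "atomArray")
        for atom in rec.mol.GetAtoms():
            a = etree.SubElement(atoms, "atom")
            a.set("id", f"a{atom.GetIdx()}")
            a.set("elementType", atom.GetSymbol())
            if atom.GetFormalCharge():
                a.set("formalCharge", str(atom.GetFormalCharge()))
            a.set("hydrogenCount", str(atom.GetTotalNumHs()))
            if atom.GetIsAromatic():
                a.set("aromatic", "true")
        bonds = etree.SubElement(mol_el, "bondArray")
        for bond in rec.mol.GetBonds():
            b = etree.SubElement(bonds, "bond")
            b.set("atomRefs2", f"a{bond.GetBeginAtomIdx()} a{bond.GetEndAtomIdx()}")
            b.set("order", _BOND_ORDER_OUT.get(bond.GetBondType(), "1"))
        for k, v in rec.properties.items():
            p = etree.SubElement(mol_el, "property")
            p.set("title", k)
            etree.SubElement(p, "scalar").text = str(v)
    tree = etree.ElementTree(root)
    tree.write(os.fspath(path), pretty_print=True, xml_declaration=True, encoding="utf-8")
    return os.fspath(path)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_cml(path: str | os.PathLike) -> MoleculeSet:
    """Read a CML subset document written by :func:`write_cml`.

    Unsupported CML elements are skipped; a warning per skipped element kind
    is recorded in the set's rejection log.
    """
    tree = etree.parse(os.fspath(path))
    out = MoleculeSet(provenance=os.fspath(path))
    skipped: set[str] = set()
    for idx, mol_el in enumerate(tree.iter()):
        if _local(mol_el.tag) != "molecule":
            continue
        rw = Chem.RWMol()
        id_map: dict[str, int] = {}
        props: dict[str, str] = {}
        aromatic_atoms: set[int] = set()
        for child in mol_el:
            tag = _local(child.tag)
            if tag == "atomArray":
                for a in child:
                    if _local(a.tag) != "atom":
                        skipped.add(_local(a.tag))
                        continue
                    atom = Chem.Atom(a.get("elementType", "C"))
                    atom.SetFormalCharge(int(a.get("formalCharge", "0")))
                    if a.get("hydrogenCount") is not None:
                        atom.SetNumExplicitHs(int(a.get("hydrogenCount")))
                        atom.SetNoImplicit(True)
                    i = rw.AddAtom(atom)
                    if a.get("aromatic") == "true":
                        aromatic_atoms.add(i)
                    id_map[a.get("id", f"a{i}")] = i
            elif tag == "bondArray":
                for b in child:
                    if _local(b.tag) != "bond":
                        skipped.add(_local(b.tag))
                        continue
                    ref1, ref2 = b.get("atomRefs2").split()
                    order = _BOND_ORDER_IN.get(b.get("order", "1"), Chem.BondType.SINGLE)
                    bidx = rw.AddBond(id_map[ref1], id_map[ref2], order) - 1
                    if order is Chem.BondType.AROMATIC:
                        rw.GetBondWithIdx(bidx).SetIsAromatic(True)
            elif tag == "property":
                vals = [s.text for s in child if _local(s.tag) == "scalar"]
                props[child.get("title", f"p{len(props)}")] = vals[0] if vals else ""
            else:
                skipped.add(tag)
        for i in aromatic_atoms:
            rw.GetAtomWithIdx(i).SetIsAromatic(True)
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # keep reading the rest of the file
            out.rejections.append(RejectedRecord(idx, f"sanitization failed: {exc}"))
            continue
        uid = mol_el.get("id", "")
        # ids of the form m<digits> are writer-generated placeholders, not uids
        if uid and uid[0] == "m" and uid[1:].isdigit():
            uid = ""
        out.records.append(MoleculeRecord(mol, props, uid))
    for tag in sorted(skipped):
        out.rejections.append(RejectedRecord(-1, f"unsupported CML element skipped: {tag}"))
    return out
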