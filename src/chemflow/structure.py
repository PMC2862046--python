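"""Atom-type perception and validation, molecule preparation, substructure filtering.

Preparation mirrors the classic descriptor-pipeline front end: resolve each
atom against a valence catalogue, fill implicit hydrogen counts, and perceive
aromaticity with a Hückel-style (4n+2 π-electron) ring model.  Atoms whose
element/valence/charge combination is absent from the catalogue are flagged
*unknown* — that is data to report, not a failure: missing atom types (metals,
exotic valences) are a real property of large public structure collections
and an important up-front filter for descriptor calculations.

Substructure filtering is graph-topological: element + bond order +
aromaticity, charge-sensitive, stereo-insensitive.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

from rdkit import Chem

from .chem_io import MoleculeRecord, MoleculeSet

__all__ = [
    "AtomTypeReport",
    "SubstructureQuery",
    "perceive_and_prepare",
    "validate_atom_types",
    "substructure_filter",
    "unknown_atoms",
]

UNKNOWN_ATOMS_PROP = "chemflow_unknown_atoms"
AROMATICITY_MODEL = "rdkit-default (Hückel 4n+2 electron-count ring model)"

# Curated common-organic atom-type catalogue: element -> allowed
# (total valence, formal charge) pairs.  Everything outside this table —
# metals, heavy elements, exotic valence states — is an *unknown* atom type.
ATOM_TYPE_TABLE: dict[str, frozenset[tuple[int, int]]] = {
    "H": frozenset({(1, 0)}),
    "B": frozenset({(3, 0), (4, -1)}),
    "C": frozenset({(4, 0), (3, -1), (3, 1)}),
    "N": frozenset({(3, 0), (4, 1), (2, -1)}),
    "O": frozenset({(2, 0), (1, -1), (3, 1)}),
    "F": frozenset({(1, 0), (0, -1)}),
    "Si": frozenset({(4, 0)}),
    "P": frozenset({(3, 0), (5, 0), (4, 1)}),
    "S": frozenset({(2, 0), (4, 0), (6, 0), (1, -1), (3, 1)}),
    "Cl": frozenset({(1, 0), (0, -1)}),
    "Se": frozenset({(2, 0), (4, 0), (6, 0)}),
    "Br": frozenset({(1, 0), (0, -1)}),
    "I": frozenset({(1, 0), (0, -1), (3, 0)}),
}


def _atom_type_known(atom: Chem.Atom) -> bool:
    allowed = ATOM_TYPE_TABLE.get(atom.GetSymbol())
    if allowed is None:
        return False
    return (atom.GetTotalValence(), atom.GetFormalCharge()) in allowed


def perceive_and_prepare(record: MoleculeRecord) -> MoleculeRecord:
    """Resolve atom types, fill implicit hydrogens, perceive aromaticity.

    Returns a new record; atoms with no catalogue entry are flagged and their
    ``index:element`` pairs stored in the record's property map under
    ``chemflow_unknown_atoms`` (empty string when all atoms are recognized).
    """
    mol = Chem.Mol(record.mol)
    Chem.SanitizeMol(mol)  # valence + implicit H
    Chem.SetAromaticity(mol)  # electron-count ring aromaticity
    unknown: list[tuple[int, str]] = []
    for atom in mol.GetAtoms():
        if not _atom_type_known(atom):
            unknown.append((atom.GetIdx(), atom.GetSymbol()))
    props = dict(record.properties)
    props[UNKNOWN_ATOMS_PROP] = ";".join(f"{i}:{sym}" for i, sym in unknown)
    return MoleculeRecord(mol, props, record.uid)


def unknown_atoms(record: MoleculeRecord) -> list[tuple[int, str]]:
    """Unknown-atom (index, element) pairs of a prepared record."""
    raw = record.properties.get(UNKNOWN_ATOMS_PROP)
    if raw is None:
        record = perceive_and_prepare(record)
        raw = record.properties[UNKNOWN_ATOMS_PROP]
    if not raw:
        return []
    out = []
    for item in raw.split(";"):
        i, sym = item.split(":")
        out.append((int(i), sym))
    return out


@dataclass
class AtomTypeReport:
    """Audit of unrecognized atom types over a molecule set.

    ``per_molecule`` lists, for each molecule with at least one unknown atom,
    its uid and the (atom index, element) pairs.  Totals satisfy
    ``percent_molecules_unknown = 100 * molecules_with_unknown /
    molecules_checked`` and ``atoms_unknown >= molecules_with_unknown``.
    """

    per_molecule: list[tuple[str, list[tuple[int, str]]]] = field(default_factory=list)
    molecules_checked: int = 0
    molecules_with_unknown: int = 0
    atoms_unknown: int = 0
    aromaticity_model: str = AROMATICITY_MODEL

    @property
    def percent_molecules_unknown(self) -> float:
        if self.molecules_checked == 0:
            return 0.0
        return 100.0 * self.molecules_with_unknown / self.molecules_checked

    def percent_printed(self, decimals: int = 2) -> float:
        """Percent truncated to the printed precision.

        Audit reports conventionally truncate rather than round the
        percentage, so 8.369... prints as 8.36 at two decimals.
        """
        factor = 10**decimals
        return math.floor(self.percent_molecules_unknown * factor) / factor

    def element_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, atoms in self.per_molecule:
            for _, sym in atoms:
                counts[sym] = counts.get(sym, 0) + 1
        return counts

    def write(self, directory: str | os.PathLike) -> dict[str, str]:
        """Write the two text outputs (ids file; per-atom details) + CSV totals."""
        directory = os.fspath(directory)
        os.makedirs(directory, exist_ok=True)
        ids_path = os.path.join(directory, "unknown_molecule_ids.txt")
        with open(ids_path, "w") as fh:
            for uid, _ in self.per_molecule:
                fh.write(uid + "\n")
        detail_path = os.path.join(directory, "unknown_atom_details.txt")
        with open(detail_path, "w") as fh:
            for uid, atoms in self.per_molecule:
                for idx, sym in atoms:
                    fh.write(f"{uid}\tatom {idx}\t{sym}\n")
        totals_path = os.path.join(directory, "atom_type_totals.csv")
        with open(totals_path, "w") as fh:
            fh.write("molecules_checked,molecules_with_unknown,atoms_unknown,percent_molecules_unknown\n")
            fh.write(
                f"{self.molecules_checked},{self.molecules_with_unknown},"
                f"{self.atoms_unknown},{self.percent_molecules_unknown:.2f}\n"
            )
        return {"ids": ids_path, "details": detail_path, "totals": totals_path}


def validate_atom_types(molset: MoleculeSet) -> AtomTypeReport:
    """Audit a tagged molecule set for atoms with unrecognized atom types.

    Raises ``ValueError`` if any molecule is untagged — the per-molecule
    listing is keyed by uid, so tag first.
    """
    untagged = [i for i, rec in enumerate(molset) if not rec.uid]
    if untagged:
        raise ValueError(
            f"{len(untagged)} molecules have no uid (first at index {untagged[0]}); "
            "run tag_molecules before validate_atom_types"
        )
    report = AtomTypeReport()
    for rec in molset:
        bad = unknown_atoms(rec)
        report.molecules_checked += 1
        if bad:
            report.molecules_with_unknown += 1
            report.atoms_unknown += len(bad)
            report.per_molecule.append((rec.uid, bad))
    return report


class SubstructureQuery:
    """Compiled topological substructure query from a SMILES or SMARTS pattern."""

    def __init__(self, pattern: str):
        if not isinstance(pattern, str) or not pattern.strip():
            raise ValueError("empty substructure pattern")
        query = Chem.MolFromSmarts(pattern)
        if query is None:
            query = Chem.MolFromSmiles(pattern)
        if query is None:
            raise ValueError(f"uncompilable substructure pattern: {pattern!r}")
        if query.GetNumAtoms() == 0:
            raise ValueError("substructure pattern has no atoms")
        self.pattern = pattern
        self.query = query

    def matches(self, record: MoleculeRecord) -> bool:
        return record.mol.HasSubstructMatch(self.query, useChirality=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SubstructureQuery({self.pattern!r})"


def substructure_filter(
    molset: MoleculeSet, query: SubstructureQuery | str
) -> tuple[MoleculeSet, MoleculeSet]:
    """Partition a molecule set into (matching, non-matching) by a query.

    The two outputs are disjoint, order-preserving, and their union is the
    input set.
    """
    if isinstance(query, str):
        query = SubstructureQuery(query)
    matching = MoleculeSet(provenance=molset.provenance)
    non_matching = MoleculeSet(provenance=molset.provenance)
    for rec in molset:
        (matching if query.matches(rec) else non_matching).records.append(rec)
    return matching, non_matching
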