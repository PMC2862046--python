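"""Molecule tagging, QSAR descriptor vectors, vector cleaning, and CSV I/O.

The descriptor table (``QSARVectorTable``) is a pandas ``DataFrame`` whose
index is the molecule uid and whose columns are named descriptor components,
in selection order.  Cells are floats; a descriptor failure on one molecule
is recorded as a missing cell (NaN) and logged, never an abort — property
pipelines must survive individual bad molecules.

Cleaning implements the pre-clustering rules: remove components (columns)
whose minimum equals their maximum or with too many missing values, then
remove rows carrying NaN/Infinity, iterated to a fixpoint so the operation
is idempotent.
"""

from __future__ import annotations

import csv
import logging
import math
import os
from collections.abc import Callable, Iterable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors, rdPartialCharges

from .chem_io import MoleculeRecord, MoleculeSet

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorSelection",
    "CleaningPolicy",
    "RemovalReport",
    "DESCRIPTOR_REGISTRY",
    "descriptor_names",
    "tag_molecules",
    "compute_descriptors",
    "clean_vectors",
    "write_csv",
    "read_csv",
]

# A QSARVectorTable is a DataFrame: index = uid, columns = component names.
QSARVectorTable = pd.DataFrame


# ---------------------------------------------------------------------------
# Tagging


def tag_molecules(molset: MoleculeSet, prefix: str = "m-", width: int = 6) -> MoleculeSet:
    """Assign a universal identifier to every untagged molecule.

    Existing uids are preserved; duplicates among them raise ``ValueError``.
    New uids are ``<prefix><zero-padded counter>`` and never collide with
    existing ones.
    """
    seen: dict[str, int] = {}
    for rec in molset:
        if rec.uid:
            seen[rec.uid] = seen.get(rec.uid, 0) + 1
    dupes = sorted(uid for uid, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"duplicate pre-existing uids: {dupes}")
    out = MoleculeSet(provenance=molset.provenance, rejections=list(molset.rejections))
    counter = 0
    for rec in molset:
        rec = rec.copy()
        if not rec.uid:
            counter += 1
            uid = f"{prefix}{counter:0{width}d}"
            while uid in seen:
                counter += 1
                uid = f"{prefix}{counter:0{width}d}"
            rec.uid = uid
            seen[uid] = 1
        out.records.append(rec)
    return out


# ---------------------------------------------------------------------------
# Descriptor registry
#
# Each descriptor maps a MoleculeRecord to one or more named numeric
# components.  Single-component descriptors reuse the descriptor name as the
# component name; multi-component ones suffix it.

DescriptorFn = Callable[[Chem.Mol], dict[str, float]]


def _single(name: str, fn: Callable[[Chem.Mol], float]) -> tuple[str, DescriptorFn]:
    return name, lambda mol: {name: float(fn(mol))}


def _gasteiger(mol: Chem.Mol) -> dict[str, float]:
    mol = Chem.Mol(mol)
    rdPartialCharges.ComputeGasteigerCharges(mol)
    charges = [float(a.GetDoubleProp("_GasteigerCharge")) for a in mol.GetAtoms()]
    if not charges or any(math.isnan(c) for c in charges):
        raise ValueError("Gasteiger charge computation failed")
    return {
        "gasteiger_charge_min": min(charges),
        "gasteiger_charge_max": max(charges),
        "gasteiger_charge_mean": sum(charges) / len(charges),
    }


def _largest_chain(mol: Chem.Mol) -> float:
    # longest simple path through acyclic, non-aromatic carbon atoms
    carbons = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and not a.GetIsAromatic() and not a.IsInRing()
    ]
    allowed = set(carbons)
    adj = {
        i: [
            n.GetIdx()
            for n in mol.GetAtomWithIdx(i).GetNeighbors()
            if n.GetIdx() in allowed
        ]
        for i in allowed
    }
    best = 1 if allowed else 0

    def dfs(node: int, visited: set[int]) -> int:
        length = 1
        for nxt in adj[node]:
            if nxt not in visited:
                length = max(length, 1 + dfs(nxt, visited | {nxt}))
        return length

    for start in allowed:
        best = max(best, dfs(start, {start}))
    return float(best)


_halogens = {9, 17, 35, 53}

DESCRIPTOR_REGISTRY: dict[str, DescriptorFn] = dict(
    [
        # constitutional counts
        _single("atom_count", lambda m: m.GetNumAtoms()),
        _single("bond_count", lambda m: m.GetNumBonds()),
        _single("molecular_weight", Descriptors.MolWt),
        _single("hbd_count", rdMolDescriptors.CalcNumHBD),
        _single("hba_count", rdMolDescriptors.CalcNumHBA),
        _single("rotatable_bond_count", rdMolDescriptors.CalcNumRotatableBonds),
        _single(
            "halogen_count",
            lambda m: sum(1 for a in m.GetAtoms() if a.GetAtomicNum() in _halogens),
        ),
        _single("heteroatom_count", rdMolDescriptors.CalcNumHeteroatoms),
        # ring / chain
        _single("ring_count", rdMolDescriptors.CalcNumRings),
        _single("aromatic_ring_count", rdMolDescriptors.CalcNumAromaticRings),
        _single("fraction_csp3", rdMolDescriptors.CalcFractionCSP3),
        _single("largest_chain", _largest_chain),
        # topological indices
        _single("chi0v", rdMolDescriptors.CalcChi0v),
        _single("chi1v", rdMolDescriptors.CalcChi1v),
        _single("kappa1", rdMolDescriptors.CalcKappa1),
        _single("kappa2", rdMolDescriptors.CalcKappa2),
        _single("balaban_j", Descriptors.BalabanJ),
        _single("bertz_ct", Descriptors.BertzCT),
        _single("tpsa", rdMolDescriptors.CalcTPSA),
        # lipophilicity / partial charge
        _single("clogp", Crippen.MolLogP),
        _single("molar_refractivity", Crippen.MolMR),
        ("gasteiger_charges", _gasteiger),
    ]
)

_COMPONENT_NAMES: dict[str, list[str]] = {
    name: (
        ["gasteiger_charge_min", "gasteiger_charge_max", "gasteiger_charge_mean"]
        if name == "gasteiger_charges"
        else [name]
    )
    for name in DESCRIPTOR_REGISTRY
}


def descriptor_names() -> list[str]:
    """Registered descriptor names, selectable by :class:`DescriptorSelection`."""
    return sorted(DESCRIPTOR_REGISTRY)


@dataclass
class DescriptorSelection:
    """Ordered selection of registry descriptor names.

    Unknown names are rejected at construction time, not at compute time.
    """

    names: list[str]

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("empty descriptor selection")
        unknown = [n for n in self.names if n not in DESCRIPTOR_REGISTRY]
        if unknown:
            raise ValueError(f"unknown descriptor names: {unknown}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate descriptor names in selection")

    def component_names(self) -> list[str]:
        out: list[str] = []
        for n in self.names:
            out.extend(_COMPONENT_NAMES[n])
        return out


def compute_descriptors(
    molset: MoleculeSet, selection: DescriptorSelection | Iterable[str]
) -> QSARVectorTable:
    """Compute the selected descriptor vector for every tagged molecule.

    Returns a DataFrame with one row per molecule (index = uid) and columns
    in selection order.  A descriptor that raises on a molecule yields NaN
    cells for its components plus a log entry.
    """
    if not isinstance(selection, DescriptorSelection):
        selection = DescriptorSelection(list(selection))
    untagged = [i for i, r in enumerate(molset) if not r.uid]
    if untagged:
        raise ValueError("molecules must be tagged before descriptor calculation")
    columns = selection.component_names()
    rows: dict[str, list[float]] = {}
    for rec in molset:
        values: dict[str, float] = {}
        for name in selection.names:
            fn = DESCRIPTOR_REGISTRY[name]
            try:
                values.update(fn(rec.mol))
            except Exception as exc:
                logger.warning("descriptor %s failed on %s: %s", name, rec.uid, exc)
                values.update({c: math.nan for c in _COMPONENT_NAMES[name]})
        rows[rec.uid] = [values[c] for c in columns]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns, dtype=float)
    table.index.name = "uid"
    return table


# ---------------------------------------------------------------------------
# Cleaning


@dataclass
class CleaningPolicy:
    """Rules applied to a descriptor table before clustering.

    Columns are examined before rows, so one broken component does not
    condemn every molecule; the passes repeat until nothing changes, making
    cleaning idempotent.
    """

    drop_nan_rows: bool = True
    drop_inf_rows: bool = True
    drop_constant_components: bool = True
    component_missing_fraction_max: float = 0.1
    row_missing_fraction_max: float = 0.0

    def __post_init__(self) -> None:
        for f in (self.component_missing_fraction_max, self.row_missing_fraction_max):
            if not 0.0 <= f <= 1.0:
                raise ValueError("missing-fraction thresholds must lie in [0, 1]")


@dataclass
class RemovalReport:
    """Every dropped row/column with the rule that removed it."""

    removed_columns: list[tuple[str, str]] = field(default_factory=list)
    removed_rows: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_columns_removed(self) -> int:
        return len(self.removed_columns)

    @property
    def n_rows_removed(self) -> int:
        return len(self.removed_rows)


def clean_vectors(
    table: QSARVectorTable, policy: CleaningPolicy | None = None
) -> tuple[QSARVectorTable, RemovalReport]:
    """Apply a cleaning policy; returns (clean table, removal report).

    Raises ``ValueError`` on an empty input table or when cleaning removes
    every row or every column (degenerate output).
    """
    if policy is None:
        policy = CleaningPolicy()
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("cannot clean an empty table")
    t = table.copy()
    report = RemovalReport()
    changed = True
    while changed and t.shape[0] and t.shape[1]:
        changed = False
        finite = np.isfinite(t.to_numpy(dtype=float))
        # column pass
        drop_cols: list[tuple[str, str]] = []
        for j, col in enumerate(t.columns):
            col_finite = finite[:, j]
            missing_frac = 1.0 - col_finite.mean()
            if missing_frac > policy.component_missing_fraction_max:
                drop_cols.append((col, f"missing fraction {missing_frac:.3f}"))
                continue
            vals = t.iloc[:, j].to_numpy(dtype=float)[col_finite]
            if policy.drop_constant_components and vals.size and vals.min() == vals.max():
                drop_cols.append((col, "constant component (min == max)"))
        if drop_cols:
            t = t.drop(columns=[c for c, _ in drop_cols])
            report.removed_columns.extend(drop_cols)
            changed = True
            continue  # re-derive finiteness before the row pass
        # row pass
        arr = t.to_numpy(dtype=float)
        drop_rows: list[tuple[str, str]] = []
        for i, uid in enumerate(t.index):
            row = arr[i]
            if policy.drop_nan_rows and np.isnan(row).any():
                drop_rows.append((uid, "contains NaN"))
            elif policy.drop_inf_rows and np.isinf(row).any():
                drop_rows.append((uid, "contains Infinity"))
            elif (~np.isfinite(row)).mean() > policy.row_missing_fraction_max:
                drop_rows.append((uid, "missing fraction above threshold"))
        if drop_rows:
            t = t.drop(index=[u for u, _ in drop_rows])
            report.removed_rows.extend(drop_rows)
            changed = True
    if t.shape[0] == 0 or t.shape[1] == 0:
        raise ValueError(
            "cleaning produced a degenerate table "
            f"({t.shape[0]} rows × {t.shape[1]} columns remain)"
        )
    return t, report


# ---------------------------------------------------------------------------
# CSV I/O — header contract: "uid,<component names...>"


def _format_cell(x: float) -> str:
    if math.isnan(x):
        return "NaN"
    if math.isinf(x):
        return "Infinity" if x > 0 else "-Infinity"
    return f"{x:.17g}"


def _parse_cell(s: str) -> float:
    return float(s)  # float() accepts "NaN", "Infinity", "-Infinity"


def write_csv(table: QSARVectorTable, path: str | os.PathLike) -> str:
    """Write a descriptor table as CSV: molecule uid + property values."""
    path = os.fspath(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["uid", *table.columns])
        for uid, row in zip(table.index, table.to_numpy(dtype=float)):
            writer.writerow([uid, *(_format_cell(x) for x in row)])
    return path


def read_csv(path: str | os.PathLike) -> QSARVectorTable:
    """Read a descriptor CSV written by :func:`write_csv`."""
    with open(os.fspath(path), newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if not header or header[0] != "uid":
            raise ValueError("descriptor CSV must start with a 'uid' column")
        columns = header[1:]
        index, data = [], []
        for row in reader:
            index.append(row[0])
            data.append([_parse_cell(x) for x in row[1:]])
    table = pd.DataFrame(data, index=index, columns=columns, dtype=float)
    table.index.name = "uid"
    return table
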