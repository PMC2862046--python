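"""Embedded paged molecule store with LIMIT/OFFSET iteration semantics.

A single-file SQLite database replaces the client/server chemistry cartridge
a production deployment would use, at desk scale: insert molecule sets, page
through query results deterministically (ORDER BY id, LIMIT/OFFSET), and ask
whether rows remain beyond the current page — the *has-next* signal the
workflow loop construct consumes.  Substructure queries are answered by a
scan, optionally preceded by a pattern-fingerprint prefilter that is
superset-safe: it only ever removes guaranteed non-matches, so results are
identical to filtering the full store contents.
"""

from __future__ import annotations

import json
import os
import sqlite3
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import DataStructs

from .chem_io import MoleculeRecord, MoleculeSet
from .structure import SubstructureQuery

__all__ = ["MoleculeStore", "PageCursor", "insert_molecules", "get_page", "substructure_query"]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS molecules (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    uid TEXT,
    smiles TEXT NOT NULL,
    molblock TEXT NOT NULL,
    properties TEXT NOT NULL DEFAULT '{}',
    fingerprint TEXT
);
CREATE TABLE IF NOT EXISTS runs (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    started TEXT DEFAULT CURRENT_TIMESTAMP,
    description TEXT
);
"""


class MoleculeStore:
    """Single-file SQL molecule store; ids are unique and monotone."""

    def __init__(self, path: str | os.PathLike = ":memory:"):
        self.path = os.fspath(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.executescript(_SCHEMA)
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "MoleculeStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def count(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM molecules").fetchone()[0]

    # -- write -------------------------------------------------------------

    def insert(self, molset: MoleculeSet) -> list[int]:
        """Insert a molecule set; returns new ids in input order."""
        ids = []
        cur = self.conn.cursor()
        for rec in molset:
            fp = Chem.PatternFingerprint(rec.mol)
            cur.execute(
                "INSERT INTO molecules (uid, smiles, molblock, properties, fingerprint)"
                " VALUES (?, ?, ?, ?, ?)",
                (
                    rec.uid,
                    rec.canonical_smiles(),
                    Chem.MolToMolBlock(rec.mol),
                    json.dumps(rec.properties),
                    fp.ToBase64(),
                ),
            )
            ids.append(cur.lastrowid)
        self.conn.commit()
        return ids

    # -- read --------------------------------------------------------------

    @staticmethod
    def _record(row) -> MoleculeRecord:
        _id, uid, smiles, molblock, props = row[:5]
        mol = Chem.MolFromMolBlock(molblock, sanitize=True, removeHs=True)
        if mol is None:  # fall back to the canonical SMILES
            mol = Chem.MolFromSmiles(smiles)
        rec = MoleculeRecord(mol, json.loads(props), uid or "")
        rec.properties.setdefault("store_id", str(_id))
        return rec

    def fetch(self, limit: int | None = None, offset: int = 0) -> MoleculeSet:
        sql = "SELECT id, uid, smiles, molblock, properties FROM molecules ORDER BY id"
        args: tuple = ()
        if limit is not None:
            sql += " LIMIT ? OFFSET ?"
            args = (limit, offset)
        out = MoleculeSet(provenance=f"store:{self.path}")
        for row in self.conn.execute(sql, args):
            out.records.append(self._record(row))
        return out

    def fetch_by_id(self, mol_id: int) -> MoleculeRecord:
        row = self.conn.execute(
            "SELECT id, uid, smiles, molblock, properties FROM molecules WHERE id = ?",
            (mol_id,),
        ).fetchone()
        if row is None:
            raise KeyError(f"no molecule with id {mol_id}")
        return self._record(row)

    def substructure_search(
        self,
        query: SubstructureQuery | str,
        limit: int | None = None,
        offset: int = 0,
        use_prefilter: bool = True,
    ) -> MoleculeSet:
        """All molecules matching a substructure query, in id order.

        LIMIT/OFFSET page over the *matching* rows.  The fingerprint
        prefilter only discards guaranteed non-matches; every survivor is
        verified with the full topological matcher, so the result equals a
        scan of the entire store.
        """
        if isinstance(query, str):
            query = SubstructureQuery(query)
        qfp = Chem.PatternFingerprint(query.query) if use_prefilter else None
        out = MoleculeSet(provenance=f"store:{self.path}")
        seen = 0
        for row in self.conn.execute(
            "SELECT id, uid, smiles, molblock, properties, fingerprint "
            "FROM molecules ORDER BY id"
        ):
            if qfp is not None and row[5]:
                mfp = DataStructs.ExplicitBitVect(qfp.GetNumBits())
                mfp.FromBase64(row[5])
                if not DataStructs.AllProbeBitsMatch(qfp, mfp):
                    continue  # guaranteed non-match
            rec = self._record(row)
            if not query.matches(rec):
                continue
            if seen >= offset:
                out.records.append(rec)
                if limit is not None and len(out) >= limit:
                    break
            seen += 1
        return out


@dataclass
class PageCursor:
    """LIMIT/OFFSET paging state over a store (optionally filtered).

    ``advance()`` moves the offset forward by ``limit`` after each page, so a
    loop draws successive disjoint pages until ``has_next`` turns "false".
    """

    store: MoleculeStore
    limit: int
    offset: int = 0
    query: SubstructureQuery | None = None

    def __post_init__(self) -> None:
        if self.limit <= 0:
            raise ValueError("page limit must be positive")
        if self.offset < 0:
            raise ValueError("page offset must be non-negative")

    def _total(self) -> int:
        if self.query is None:
            return self.store.count()
        return len(self.store.substructure_search(self.query, use_prefilter=True))

    def page(self) -> tuple[MoleculeSet, str]:
        """Current page and the has-next flag ("true"/"false") beyond it."""
        if self.query is None:
            molset = self.store.fetch(limit=self.limit, offset=self.offset)
        else:
            molset = self.store.substructure_search(
                self.query, limit=self.limit, offset=self.offset
            )
        has_next = "true" if self.offset + self.limit < self._total() else "false"
        return molset, has_next

    def advance(self) -> None:
        self.offset += self.limit

    # -- paged-source protocol used by the engine loop constructs ----------

    @property
    def page_size(self) -> int:
        return self.limit

    def has_remaining(self) -> bool:
        return self.offset < self._total()

    def next_page(self) -> MoleculeSet:
        molset, _ = self.page()
        self.advance()
        return molset

    def has_next(self) -> str:
        return "true" if self.has_remaining() else "false"


# ---------------------------------------------------------------------------
# Functional worker-facing surface


def insert_molecules(store: MoleculeStore, molset: MoleculeSet) -> list[int]:
    return store.insert(molset)


def get_page(cursor: PageCursor) -> tuple[MoleculeSet, str]:
    return cursor.page()


def substructure_query(
    store: MoleculeStore,
    query: SubstructureQuery | str,
    limit: int | None = None,
    offset: int = 0,
) -> MoleculeSet:
    return store.substructure_search(query, limit=limit, offset=offset)
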