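"""Generic analysis-result store: typed attributes, per-subregion
observations, and incrementally cached attribute distributions.

Any analysis result is modelled as an *observation*: a subregion of a
sequence (0-based half-open, strand carried separately) annotated with an
*attribute* — a value belonging to an *attribute type* that declares its
structure (flat or hierarchical) and value domain (discrete or continuous).
A taxonomic call, a protein-family hit and a GC-content measurement all fit
this one schema, so several annotation strategies can coexist on the same
sequence and be queried together.

The store is a single-file (or in-memory) SQLite database. Discrete
distributions are maintained incrementally on insert, so summary queries
cost the same regardless of how many observations exist; continuous types
are summarized on demand into fixed-width bins.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

FLAT, HIERARCHICAL = "flat", "hierarchical"
DISCRETE, CONTINUOUS = "discrete", "continuous"


class StoreError(ValueError):
    pass


@dataclass(frozen=True)
class AttributeType:
    type_id: int
    name: str
    structure: str
    value_domain: str


@dataclass(frozen=True)
class Attribute:
    attr_id: int
    type_id: int
    value: str | float
    parent_id: int | None


_SCHEMA = """
CREATE TABLE IF NOT EXISTS attribute_type (
    type_id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    structure TEXT NOT NULL,
    value_domain TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS attribute (
    attr_id INTEGER PRIMARY KEY,
    type_id INTEGER NOT NULL REFERENCES attribute_type(type_id),
    value TEXT,
    num_value REAL,
    parent_id INTEGER REFERENCES attribute(attr_id),
    UNIQUE (type_id, value)
);
CREATE TABLE IF NOT EXISTS observation (
    obs_id INTEGER PRIMARY KEY,
    seq_id TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL,
    strand TEXT NOT NULL DEFAULT '+',
    attr_id INTEGER NOT NULL REFERENCES attribute(attr_id)
);
CREATE INDEX IF NOT EXISTS obs_attr ON observation(attr_id);
CREATE INDEX IF NOT EXISTS obs_seq ON observation(seq_id);
CREATE TABLE IF NOT EXISTS dist_cache (
    attr_id INTEGER PRIMARY KEY REFERENCES attribute(attr_id),
    count INTEGER NOT NULL
);
"""


class ObservationStore:
    """SQLite-backed store of typed observations with cached distributions."""

    def __init__(self, path: str | Path | None = None, label: str = ""):
        self._db = sqlite3.connect(str(path) if path else ":memory:")
        self._db.executescript(_SCHEMA)
        self.label = label

    def close(self) -> None:
        self._db.close()

    # -- attribute types --------------------------------------------------

    def register_type(self, name: str, structure: str, value_domain: str) -> AttributeType:
        if structure not in (FLAT, HIERARCHICAL):
            raise StoreError(f"unknown structure {structure!r}")
        if value_domain not in (DISCRETE, CONTINUOUS):
            raise StoreError(f"unknown value domain {value_domain!r}")
        if structure == HIERARCHICAL and value_domain == CONTINUOUS:
            raise StoreError("hierarchical types require a discrete value domain")
        cur = self._db.execute(
            "SELECT type_id FROM attribute_type WHERE name = ?", (name,)
        )
        if cur.fetchone() is not None:
            raise StoreError(f"attribute type {name!r} already registered")
        cur = self._db.execute(
            "INSERT INTO attribute_type (name, structure, value_domain) VALUES (?,?,?)",
            (name, structure, value_domain),
        )
        return AttributeType(cur.lastrowid, name, structure, value_domain)

    def get_type(self, name: str) -> AttributeType:
        row = self._db.execute(
            "SELECT type_id, name, structure, value_domain FROM attribute_type "
            "WHERE name = ?", (name,)
        ).fetchone()
        if row is None:
            raise StoreError(f"unknown attribute type {name!r}")
        return AttributeType(*row)

    # -- attributes -------------------------------------------------------

    def add_attribute(
        self,
        type_name: str,
        value: str | float,
        parent: Attribute | None = None,
    ) -> Attribute:
        """Create (or return) the attribute `value` of the given type.

        `parent` links hierarchical values (e.g. species under genus); it
        must belong to the same type and is rejected on flat types.
        """
        at = self.get_type(type_name)
        if parent is not None:
            if at.structure != HIERARCHICAL:
                raise StoreError(f"type {type_name!r} is flat; no parent allowed")
            if parent.type_id != at.type_id:
                raise StoreError("parent attribute belongs to a different type")
        if at.value_domain == CONTINUOUS:
            num = float(value)
            cur = self._db.execute(
                "INSERT INTO attribute (type_id, value, num_value, parent_id) "
                "VALUES (?,NULL,?,NULL)", (at.type_id, num),
            )
            return Attribute(cur.lastrowid, at.type_id, num, None)
        sval = str(value)
        row = self._db.execute(
            "SELECT attr_id, parent_id FROM attribute WHERE type_id=? AND value=?",
            (at.type_id, sval),
        ).fetchone()
        if row is not None:
            return Attribute(row[0], at.type_id, sval, row[1])
        # Parent chains stay acyclic by construction: a new attribute can only
        # point at an already-existing (hence acyclic) chain.
        parent_id = parent.attr_id if parent is not None else None
        cur = self._db.execute(
            "INSERT INTO attribute (type_id, value, parent_id) VALUES (?,?,?)",
            (at.type_id, sval, parent_id),
        )
        return Attribute(cur.lastrowid, at.type_id, sval, parent_id)

    # -- observations -----------------------------------------------------

    def add_observation(
        self,
        seq_id: str,
        start: int,
        end: int,
        attribute: Attribute,
        strand: str = "+",
    ) -> int:
        """Persist one observation and update the cached distribution."""
        if not (0 <= start < end):
            raise StoreError(f"bad coordinates [{start}, {end})")
        if strand not in ("+", "-"):
            raise StoreError(f"bad strand {strand!r}")
        cur = self._db.execute(
            "INSERT INTO observation (seq_id, start, end, strand, attr_id) "
            "VALUES (?,?,?,?,?)",
            (seq_id, start, end, strand, attribute.attr_id),
        )
        self._db.execute(
            "INSERT INTO dist_cache (attr_id, count) VALUES (?, 1) "
            "ON CONFLICT(attr_id) DO UPDATE SET count = count + 1",
            (attribute.attr_id,),
        )
        return cur.lastrowid

    def n_observations(self) -> int:
        return self._db.execute("SELECT COUNT(*) FROM observation").fetchone()[0]

    # -- distributions ----------------------------------------------------

    def _direct_counts(self, at: AttributeType, cached: bool = True) -> dict[str, int]:
        if cached:
            rows = self._db.execute(
                "SELECT a.value, c.count FROM dist_cache c "
                "JOIN attribute a ON a.attr_id = c.attr_id "
                "WHERE a.type_id = ? AND c.count > 0", (at.type_id,),
            ).fetchall()
        else:
            rows = self._db.execute(
                "SELECT a.value, COUNT(*) FROM observation o "
                "JOIN attribute a ON a.attr_id = o.attr_id "
                "WHERE a.type_id = ? GROUP BY a.attr_id", (at.type_id,),
            ).fetchall()
        return {v: int(c) for v, c in rows}

    def _children(self, at: AttributeType) -> dict[str, list[str]]:
        rows = self._db.execute(
            "SELECT a.value, p.value FROM attribute a "
            "LEFT JOIN attribute p ON p.attr_id = a.parent_id "
            "WHERE a.type_id = ?", (at.type_id,),
        ).fetchall()
        kids: dict[str, list[str]] = {}
        for value, parent in rows:
            if parent is not None:
                kids.setdefault(parent, []).append(value)
        return kids

    def distribution(
        self,
        type_name: str,
        hierarchical_rollup: bool = False,
        from_cache: bool = True,
        bins: int = 100,
    ):
        """Attribute distribution for a type.

        Discrete types return a value→count mapping (from the incremental
        cache by default; ``from_cache=False`` recounts the observation
        table from scratch). With ``hierarchical_rollup=True`` each value's
        count includes all its descendants. Continuous types return a list
        of (bin_low, bin_high, count) over `bins` fixed-width bins spanning
        the observed range.
        """
        at = self.get_type(type_name)
        if at.value_domain == CONTINUOUS:
            if hierarchical_rollup:
                raise StoreError("rollup is undefined for continuous types")
            values = [
                r[0] for r in self._db.execute(
                    "SELECT a.num_value FROM observation o "
                    "JOIN attribute a ON a.attr_id = o.attr_id "
                    "WHERE a.type_id = ?", (at.type_id,),
                )
            ]
            if not values:
                return []
            lo, hi = min(values), max(values)
            width = (hi - lo) / bins or 1.0
            counts = [0] * bins
            for v in values:
                counts[min(int((v - lo) / width), bins - 1)] += 1
            return [(lo + i * width, lo + (i + 1) * width, c)
                    for i, c in enumerate(counts) if c > 0]

        direct = self._direct_counts(at, cached=from_cache)
        if not hierarchical_rollup:
            return dict(direct)
        if at.structure != HIERARCHICAL:
            raise StoreError(f"rollup requested on flat type {type_name!r}")
        kids = self._children(at)
        rolled: dict[str, int] = {}

        def subtree(value: str) -> int:
            if value in rolled:
                return rolled[value]
            total = direct.get(value, 0) + sum(subtree(k) for k in kids.get(value, []))
            rolled[value] = total
            return total

        all_values = set(direct) | set(kids)
        for k in kids.values():
            all_values.update(k)
        for v in all_values:
            subtree(v)
        return {v: c for v, c in rolled.items() if c > 0}

    # -- export -----------------------------------------------------------

    def _descendant_attr_ids(self, at: AttributeType, value: str) -> list[int]:
        rows = self._db.execute(
            "SELECT attr_id, value, parent_id FROM attribute WHERE type_id = ?",
            (at.type_id,),
        ).fetchall()
        by_parent: dict[int, list[int]] = {}
        ids_by_value: dict[str, list[int]] = {}
        for attr_id, v, parent_id in rows:
            ids_by_value.setdefault(v, []).append(attr_id)
            if parent_id is not None:
                by_parent.setdefault(parent_id, []).append(attr_id)
        start = ids_by_value.get(value, [])
        if at.structure != HIERARCHICAL:
            return start
        out: list[int] = []
        stack = list(start)
        while stack:
            a = stack.pop()
            out.append(a)
            stack.extend(by_parent.get(a, []))
        return out

    def export_subset(self, criteria: Mapping[str, str | float]) -> list[str]:
        """Sequence ids having >=1 matching observation for EVERY criterion.

        `criteria` maps attribute-type name to a value; for hierarchical
        types a value matches itself and all its descendants. An unknown
        value yields an empty result (never an error).
        """
        if not criteria:
            raise StoreError("export_subset needs at least one criterion")
        result: set[str] | None = None
        for type_name, value in criteria.items():
            at = self.get_type(type_name)
            attr_ids = self._descendant_attr_ids(at, str(value))
            if not attr_ids:
                return []
            q = ",".join("?" * len(attr_ids))
            rows = self._db.execute(
                f"SELECT DISTINCT seq_id FROM observation WHERE attr_id IN ({q})",
                attr_ids,
            ).fetchall()
            ids = {r[0] for r in rows}
            result = ids if result is None else (result & ids)
            if not result:
                return []
        return sorted(result or [])
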