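"""Rooted taxonomy trees with LCA and rank-projection primitives.

Loads NCBI-taxdump-style ``nodes.dmp`` / ``names.dmp`` files (pipe-and-tab
delimited; plain TSV is tolerated) into a validated :class:`TaxonomyTree`.
The tree is the substrate for lowest-common-ancestor assignment of reads and
for projecting taxa to a fixed rank (e.g. genus) during evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable


class TaxonomyError(Exception):
    """Structural problem in a taxonomy (unresolvable parent, cycle)."""


class UnknownTaxidError(KeyError):
    """A queried taxid is not present in the tree (strict mode)."""


@dataclass(frozen=True)
class TaxNode:
    """One taxon: identifier, parent link, rank label and scientific name."""

    taxid: int
    parent: int
    rank: str
    name: str


def _split_dmp_line(line: str) -> list[str]:
    # NCBI taxdump rows look like "1\t|\t1\t|\tno rank\t|"; fixture files may
    # use plain tabs. Accept both by splitting on '|' when present.
    line = line.rstrip("\n")
    if "|" in line:
        fields = [f.strip("\t ") for f in line.split("|")]
        if fields and fields[-1] == "":
            fields.pop()
        return fields
    return [f.strip() for f in line.split("\t")]


class TaxonomyTree:
    """A rooted taxonomy keyed by taxid.

    Invariants enforced at construction: every parent taxid resolves, exactly
    one node is its own parent (the root), and every node reaches the root by
    parent-walking (no cycles).
    """

    def __init__(self, nodes: Iterable[TaxNode]):
        self.nodes: dict[int, TaxNode] = {}
        for node in nodes:
            if node.taxid in self.nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid}")
            self.nodes[node.taxid] = node
        if not self.nodes:
            raise TaxonomyError("empty taxonomy")
        roots = [n.taxid for n in self.nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one self-parent root, found {roots}")
        self.root_taxid: int = roots[0]
        for node in self.nodes.values():
            if node.parent not in self.nodes:
                raise TaxonomyError(
                    f"taxid {node.taxid} references missing parent {node.parent}"
                )
        self._depth: dict[int, int] = {}
        self._compute_depths()

    def _compute_depths(self) -> None:
        # Iterative parent-walk with path compression; detects cycles.
        for start in self.nodes:
            if start in self._depth:
                continue
            path: list[int] = []
            cur = start
            while cur not in self._depth and cur != self.root_taxid:
                if cur in path:
                    cycle = path[path.index(cur):] + [cur]
                    raise TaxonomyError(f"cycle detected: {cycle}")
                path.append(cur)
                cur = self.nodes[cur].parent
            base = 0 if cur == self.root_taxid else self._depth[cur]
            self._depth.setdefault(self.root_taxid, 0)
            for i, taxid in enumerate(reversed(path)):
                self._depth[taxid] = base + i + 1

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def node(self, taxid: int) -> TaxNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise UnknownTaxidError(taxid) from None

    def depth(self, taxid: int) -> int:
        self.node(taxid)
        return self._depth[taxid]

    def lineage(self, taxid: int) -> list[int]:
        """Path from the node up to and including the root."""
        self.node(taxid)
        path = [taxid]
        while taxid != self.root_taxid:
            taxid = self.nodes[taxid].parent
            path.append(taxid)
        return path

    def is_ancestor(self, ancestor: int, descendant: int) -> bool:
        """True if `ancestor` is an ancestor-or-self of `descendant`."""
        return ancestor in set(self.lineage(descendant))

    def lca(self, taxids: Iterable[int], mode: str = "strict") -> int:
        """Lowest common ancestor of a non-empty set of taxids.

        Parameters
        ----------
        taxids
            Taxids to combine; order and multiplicity are irrelevant.
        mode
            ``"strict"`` raises :class:`UnknownTaxidError` on a taxid absent
            from the tree; ``"lenient"`` skips such taxids (and raises only if
            none remain). Lenient mode exists for alignment hits referencing
            merged or retired taxa.
        """
        if mode not in ("strict", "lenient"):
            raise ValueError(f"unknown taxid mode {mode!r}")
        ids = set(taxids)
        if not ids:
            raise ValueError("lca of an empty taxid set")
        if mode == "lenient":
            ids = {t for t in ids if t in self.nodes}
            if not ids:
                raise ValueError("no input taxid present in the tree")
        it = iter(ids)
        acc = next(it)
        self.node(acc)
        for t in it:
            acc = self._lca_pair(acc, t)
        return acc

    def _lca_pair(self, a: int, b: int) -> int:
        self.node(a), self.node(b)
        da, db = self._depth[a], self._depth[b]
        while da > db:
            a = self.nodes[a].parent
            da -= 1
        while db > da:
            b = self.nodes[b].parent
            db -= 1
        while a != b:
            a = self.nodes[a].parent
            b = self.nodes[b].parent
        return a

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """First ancestor-or-self whose rank equals `rank`, or None."""
        for t in self.lineage(taxid):
            if self.nodes[t].rank == rank:
                return t
        return None

    # -- serialization ----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Flat dump: taxid, parent, rank, name (one row per node)."""
        with open(path, "w") as fh:
            fh.write("#taxid\tparent\trank\tname\n")
            for taxid in sorted(self.nodes):
                n = self.nodes[taxid]
                fh.write(f"{n.taxid}\t{n.parent}\t{n.rank}\t{n.name}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTree":
        nodes = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                taxid, parent, rank, name = line.rstrip("\n").split("\t")
                nodes.append(TaxNode(int(taxid), int(parent), rank, name))
        return cls(nodes)


def load_taxonomy(nodes_path: str | Path, names_path: str | Path | None = None) -> TaxonomyTree:
    """Load a taxonomy from taxdump-dialect nodes/names files.

    Only the first three columns of the nodes file (taxid, parent, rank) and
    the "scientific name" class of the names file are consulted. Nodes
    lacking a scientific name get their stringified taxid as name.
    """
    raw: list[tuple[int, int, str]] = []
    with open(nodes_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _split_dmp_line(line)
            if len(fields) < 3:
                raise TaxonomyError(
                    f"{nodes_path}:{lineno}: expected at least 3 columns, got {len(fields)}"
                )
            try:
                taxid, parent = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise TaxonomyError(f"{nodes_path}:{lineno}: non-integer taxid") from exc
            rank = fields[2]
            if not rank:
                raise TaxonomyError(f"{nodes_path}:{lineno}: empty rank for taxid {taxid}")
            raw.append((taxid, parent, rank))

    names: dict[int, str] = {}
    if names_path is not None and Path(names_path).exists():
        with open(names_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = _split_dmp_line(line)
                if len(fields) >= 4 and fields[3] == "scientific name":
                    names.setdefault(int(fields[0]), fields[1])
                elif len(fields) in (2, 3):  # tolerant TSV: taxid, name[, class]
                    names.setdefault(int(fields[0]), fields[1])

    nodes = [
        TaxNode(taxid, parent, rank, names.get(taxid, str(taxid)))
        for taxid, parent, rank in raw
    ]
    return TaxonomyTree(nodes)
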