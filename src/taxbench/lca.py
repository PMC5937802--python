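"""Combined taxonomic classification: alignment-LCA plus k-mer fallback.

The default classification route pairs a fast k-mer classifier's per-read
calls (the *primary* stream) with a lowest-common-ancestor assignment over
filtered protein-alignment hits (the *secondary* stream). Reads classified by
the primary keep that call; reads it leaves unclassified take the LCA call
when one exists. This fallback policy leaves the primary's precision intact
while recovering sensitivity from the more permissive protein search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io import UNCLASSIFIED, AlignmentHit, ReadAssignment
from .taxonomy import TaxonomyTree, UnknownTaxidError


@dataclass(frozen=True)
class LcaParameters:
    """Hit-filtering thresholds applied per read before taking the LCA.

    top_score_fraction
        Retain hits with bitscore >= (1 - fraction) * best bitscore of the
        read. 0 keeps only the best-scoring hit(s); 1 keeps all.
    min_bitscore, max_evalue
        Absolute quality floors on individual hits.
    """

    top_score_fraction: float = 0.10
    min_bitscore: float = 50.0
    max_evalue: float = 1e-5

    def __post_init__(self) -> None:
        if not 0.0 <= self.top_score_fraction <= 1.0:
            raise ValueError("top_score_fraction must be in [0, 1]")
        if self.min_bitscore < 0 or self.max_evalue < 0:
            raise ValueError("thresholds must be non-negative")


def filter_hits(hits: list[AlignmentHit], params: LcaParameters) -> list[AlignmentHit]:
    """Apply the per-read hit filter; all hits must share one read id.

    Hits below the absolute floors are dropped first, then the top-score
    window is applied relative to the best surviving bitscore. An empty input
    yields an empty output.
    """
    if not hits:
        return []
    if len({h.read_id for h in hits}) > 1:
        raise ValueError("filter_hits expects hits of a single read")
    ok = [h for h in hits if h.bitscore >= params.min_bitscore and h.evalue <= params.max_evalue]
    if not ok:
        return []
    best = max(h.bitscore for h in ok)
    cutoff = (1.0 - params.top_score_fraction) * best
    return [h for h in ok if h.bitscore >= cutoff]


def assign_lca(
    tree: TaxonomyTree,
    hits: Iterable[AlignmentHit],
    params: LcaParameters | None = None,
    taxid_mode: str = "strict",
) -> list[ReadAssignment]:
    """Per-read LCA assignment over filtered alignment hits.

    For each read: filter hits, then assign the LCA of the surviving hits'
    taxids (source ``"lca"``). Reads with no surviving hit (or, under lenient
    mode, no hit with a known taxid) are UNCLASSIFIED. Under strict mode a
    hit with an absent or unknown taxid raises.
    """
    params = params or LcaParameters()
    by_read: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_read.setdefault(h.read_id, []).append(h)

    out: list[ReadAssignment] = []
    for read_id, read_hits in by_read.items():
        kept = filter_hits(read_hits, params)
        taxids = []
        for h in kept:
            if h.taxid is None:
                if taxid_mode == "strict":
                    raise UnknownTaxidError(
                        f"hit {h.read_id}->{h.subject_id} has no taxid (strict mode)"
                    )
                continue
            if h.taxid not in tree:
                if taxid_mode == "strict":
                    raise UnknownTaxidError(h.taxid)
                continue
            taxids.append(h.taxid)
        if taxids:
            out.append(ReadAssignment(read_id, tree.lca(taxids), "lca"))
        else:
            out.append(ReadAssignment(read_id, UNCLASSIFIED, "lca"))
    return out


def combine_assignments(
    primary: Iterable[ReadAssignment],
    secondary: Iterable[ReadAssignment],
    policy: str = "fallback",
) -> list[ReadAssignment]:
    """Merge two per-read assignment streams into one (source ``"combined"``).

    Under the fallback policy each read classified by the primary keeps its
    primary call; reads the primary leaves unclassified (or never saw) take
    the secondary call when classified, else remain UNCLASSIFIED. The output
    covers the union of both read-id universes, each read exactly once.
    """
    if policy != "fallback":
        raise ValueError(f"unsupported combination policy {policy!r}")

    prim: dict[str, ReadAssignment] = {}
    for a in primary:
        if a.read_id in prim:
            raise ValueError(f"duplicate read id in primary stream: {a.read_id}")
        prim[a.read_id] = a
    sec: dict[str, ReadAssignment] = {}
    for a in secondary:
        if a.read_id in sec:
            raise ValueError(f"duplicate read id in secondary stream: {a.read_id}")
        sec[a.read_id] = a

    out: list[ReadAssignment] = []
    for read_id, a in prim.items():
        if a.is_classified:
            out.append(ReadAssignment(read_id, a.taxid, "combined"))
        else:
            b = sec.get(read_id)
            taxid = b.taxid if b is not None and b.is_classified else UNCLASSIFIED
            out.append(ReadAssignment(read_id, taxid, "combined"))
    for read_id, b in sec.items():
        if read_id not in prim:
            out.append(ReadAssignment(read_id, b.taxid if b.is_classified else UNCLASSIFIED,
                                      "combined"))
    return out
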