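"""Shared fixtures: hand-built and random taxonomies plus brute-force
oracles used across the suite."""

from __future__ import annotations

import random

import pytest

from taxbench.taxonomy import TaxNode, TaxonomyTree

RANKS = ["no rank", "superkingdom", "phylum", "class", "order",
         "family", "genus", "species"]


@pytest.fixture
def small_tree() -> TaxonomyTree:
    """root(1) -> Bacteria(2, superkingdom) -> Escherichia(561, genus)
    -> {E. coli(562), E. fergusonii(564)}; Staphylococcus(1279, genus)
    -> S. aureus(1280)."""
    return TaxonomyTree([
        TaxNode(1, 1, "no rank", "root"),
        TaxNode(2, 1, "superkingdom", "Bacteria"),
        TaxNode(543, 2, "family", "Enterobacteriaceae"),
        TaxNode(561, 543, "genus", "Escherichia"),
        TaxNode(562, 561, "species", "Escherichia coli"),
        TaxNode(564, 561, "species", "Escherichia fergusonii"),
        TaxNode(1279, 2, "genus", "Staphylococcus"),
        TaxNode(1280, 1279, "species", "Staphylococcus aureus"),
    ])


def random_tree(rng: random.Random, n: int) -> TaxonomyTree:
    """Random rooted tree with shuffled taxids and random ranks."""
    taxids = rng.sample(range(1, 100 * n), n)
    nodes = [TaxNode(taxids[0], taxids[0], "no rank", "root")]
    for i in range(1, n):
        parent = taxids[rng.randrange(i)]
        nodes.append(TaxNode(taxids[i], parent, rng.choice(RANKS), f"node{i}"))
    return TaxonomyTree(nodes)


def brute_force_lca(tree: TaxonomyTree, taxids) -> int:
    """Oracle: intersect root-paths, take the deepest common element."""
    paths = [tree.lineage(t) for t in taxids]
    common = set(paths[0]).intersection(*map(set, paths[1:]))
    return max(common, key=tree.depth)


def brute_force_ancestor_at_rank(tree: TaxonomyTree, taxid: int, rank: str):
    """Oracle: full root-path scan for the first node at the rank."""
    for t in tree.lineage(taxid):
        if tree.nodes[t].rank == rank:
            return t
    return None
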