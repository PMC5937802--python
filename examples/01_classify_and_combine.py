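"""LCA classification over alignment hits, combined with a k-mer primary.

Builds a toy taxonomy, hands three reads' protein-alignment hits to the LCA
assigner, and merges the result with a k-mer classifier's calls under the
fallback policy (primary call kept; LCA fills unclassified reads).
"""

from taxbench import (
    UNCLASSIFIED,
    AlignmentHit,
    LcaParameters,
    ReadAssignment,
    assign_lca,
    combine_assignments,
)
from taxbench.fixtures import FixtureSpec, make_taxonomy_tree

tree = make_taxonomy_tree(FixtureSpec(n_genera=3, species_per_genus=2))
species = sorted(t for t, n in tree.nodes.items() if n.rank == "species")
s1, s2 = species[0], species[1]          # two species of the same genus
s_other = species[2]                     # species of a different genus

hits = [
    # read1: equally good hits to two species of one genus -> genus-level call
    AlignmentHit("read1", "protA", 95.0, 120.0, 1e-30, taxid=s1),
    AlignmentHit("read1", "protB", 94.0, 118.0, 1e-28, taxid=s2),
    # read2: one dominant hit -> species-level call
    AlignmentHit("read2", "protC", 99.0, 200.0, 1e-50, taxid=s_other),
    # read3: hits too weak to survive the bitscore floor -> unclassified
    AlignmentHit("read3", "protD", 40.0, 30.0, 1e-3, taxid=s1),
]

lca_calls = assign_lca(tree, hits, LcaParameters(top_score_fraction=0.10,
                                                 min_bitscore=50, max_evalue=1e-5))
print("LCA assignments (alignment route):")
for a in sorted(lca_calls, key=lambda a: a.read_id):
    name = tree.node(a.taxid).name if a.is_classified else "unclassified"
    print(f"  {a.read_id}: taxid {a.taxid} ({name})")

kmer_calls = [
    ReadAssignment("read1", s1, "kmer"),          # k-mer already classified read1
    ReadAssignment("read2", UNCLASSIFIED, "kmer"),
    ReadAssignment("read3", UNCLASSIFIED, "kmer"),
]
combined = combine_assignments(kmer_calls, lca_calls)
print("\nCombined (k-mer primary, LCA fallback):")
for a in sorted(combined, key=lambda a: a.read_id):
    name = tree.node(a.taxid).name if a.is_classified else "unclassified"
    print(f"  {a.read_id}: taxid {a.taxid} ({name})")

print("\nread1 keeps its k-mer species call, read2 gains the LCA call, and")
print("read3 stays unclassified because its only hit failed the filters.")
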