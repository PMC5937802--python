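"""Deterministic toy fixtures: taxonomies, genomes and mock classifier
output, so every pipeline stage is testable offline.

The generated taxonomy is a four-level tree (root → superkingdom → genera →
species) with predictable taxids; genomes are i.i.d. uniform-base sequences,
one per species; the mock classifier turns a truth manifest into per-read
assignments with configurable wrong-genus and unclassified rates, which
makes evaluation metrics analytic functions of those rates.

All randomness flows from one seed through named substreams, so adding a new
fixture kind never perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import UNCLASSIFIED, ReadAssignment, TruthRecord
from .simulate import GenomeRecord
from .taxonomy import TaxNode, TaxonomyTree

ROOT_TAXID = 1
SUPERKINGDOM_TAXID = 2
GENUS_BASE = 100
SPECIES_BASE = 10_000


@dataclass(frozen=True)
class FixtureSpec:
    n_genera: int = 5
    species_per_genus: int = 3
    genome_length: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genera, self.species_per_genus, self.genome_length) < 1:
            raise ValueError("fixture dimensions must be positive")


def _stream(spec: FixtureSpec, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def genus_taxid(i: int) -> int:
    return GENUS_BASE + i


def species_taxid(spec: FixtureSpec, genus_i: int, species_j: int) -> int:
    return SPECIES_BASE + genus_i * spec.species_per_genus + species_j


def make_taxonomy_tree(spec: FixtureSpec) -> TaxonomyTree:
    """Build the fixture taxonomy in memory: 2 + n_genera (1 + species) nodes."""
    nodes = [
        TaxNode(ROOT_TAXID, ROOT_TAXID, "no rank", "root"),
        TaxNode(SUPERKINGDOM_TAXID, ROOT_TAXID, "superkingdom", "Bacteria"),
    ]
    for i in range(spec.n_genera):
        g = genus_taxid(i)
        nodes.append(TaxNode(g, SUPERKINGDOM_TAXID, "genus", f"Genus{i}"))
        for j in range(spec.species_per_genus):
            s = species_taxid(spec, i, j)
            nodes.append(TaxNode(s, g, "species", f"Genus{i} species{j}"))
    return TaxonomyTree(nodes)


def make_taxonomy(spec: FixtureSpec, outdir: str | Path) -> tuple[Path, Path]:
    """Write taxdump-dialect nodes.dmp / names.dmp; returns the two paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = make_taxonomy_tree(spec)
    nodes_path, names_path = outdir / "nodes.dmp", outdir / "names.dmp"
    with open(nodes_path, "w") as nf, open(names_path, "w") as mf:
        for taxid in sorted(tree.nodes):
            n = tree.nodes[taxid]
            nf.write(f"{n.taxid}\t|\t{n.parent}\t|\t{n.rank}\t|\n")
            mf.write(f"{n.taxid}\t|\t{n.name}\t|\t\t|\tscientific name\t|\n")
    return nodes_path, names_path


def make_genomes(spec: FixtureSpec, tree: TaxonomyTree) -> list[GenomeRecord]:
    """One uniform-random genome per species leaf, ranks pre-resolved."""
    rng = _stream(spec, "genomes")
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    records = []
    for i in range(spec.n_genera):
        for j in range(spec.species_per_genus):
            s = species_taxid(spec, i, j)
            seq = bases[rng.integers(0, 4, size=spec.genome_length)].tobytes().decode()
            records.append(
                GenomeRecord(
                    accession=f"FIX{s:06d}.1",
                    taxid=s,
                    sequence=seq,
                    species_taxid=s,
                    genus_taxid=tree.ancestor_at_rank(s, "genus"),
                )
            )
    return records


def write_genomes(
    records: Sequence[GenomeRecord], outdir: str | Path
) -> tuple[Path, Path]:
    """Write genomes.fasta plus a manifest TSV (accession, taxid, path)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genomes.fasta"
    manifest = outdir / "genomes.tsv"
    with open(fasta, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n{rec.sequence}\n")
    with open(manifest, "w") as fh:
        fh.write("#accession\ttaxid\tfasta\n")
        for rec in records:
            fh.write(f"{rec.accession}\t{rec.taxid}\t{fasta.name}\n")
    return fasta, manifest


def make_mock_classifier(
    truth: Iterable[TruthRecord],
    tree: TaxonomyTree,
    error_rate: float = 0.0,
    unclassified_rate: float = 0.0,
    seed: int = 0,
    source: str = "mock",
) -> list[ReadAssignment]:
    """Per-read mock calls from truth: with `unclassified_rate` the read is
    left unclassified, with `error_rate` it gets a species from a uniformly
    chosen *wrong* genus, otherwise its true taxid.

    With error rate e and unclassified rate u the expected genus-level
    accuracy is 1 - e - u, sensitivity (1 - e - u)/(1 - e) and precision
    (1 - e - u)/(1 - u), which makes parameter recovery checkable
    analytically.
    """
    if error_rate < 0 or unclassified_rate < 0 or error_rate + unclassified_rate > 1:
        raise ValueError("rates must be >= 0 with error + unclassified <= 1")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(source.encode())])
    )
    species_by_genus: dict[int, list[int]] = {}
    for taxid, node in tree.nodes.items():
        if node.rank == "species":
            g = tree.ancestor_at_rank(taxid, "genus")
            if g is not None:
                species_by_genus.setdefault(g, []).append(taxid)
    genera = sorted(species_by_genus)

    out = []
    for t in truth:
        u = rng.random()
        if u < unclassified_rate:
            out.append(ReadAssignment(t.read_id, UNCLASSIFIED, source))
            continue
        if u < unclassified_rate + error_rate:
            true_genus = tree.ancestor_at_rank(t.taxid, "genus")
            wrong = [g for g in genera if g != true_genus]
            if wrong:
                g = wrong[rng.integers(0, len(wrong))]
                sp = species_by_genus[g]
                out.append(ReadAssignment(t.read_id, sp[rng.integers(0, len(sp))], source))
                continue
        out.append(ReadAssignment(t.read_id, t.taxid, source))
    return out
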