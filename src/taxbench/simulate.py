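"""Benchmark construction: genome-set selection and Illumina-like read
simulation with truth tracking.

Two selection steps mirror the standard benchmark designs for taxonomic
classifiers: *one genome per species* (organism present in the reference),
and *clade exclusion* (species absent from the reference while its genus is
present, probing generalization to novel species). Reads are single-end,
fixed length, sampled uniformly over positions and strands, with an
independent per-base substitution error at a configurable mismatch
probability (3% by default). Every read's origin (genome, taxid, strand,
0-based half-open coordinates) is recorded in a truth manifest.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .io import SequenceRecord, TruthRecord
from .taxonomy import TaxonomyTree

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# uint8 code -> base index; 255 marks non-ACGT (N etc.)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_COMPLEMENT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_a] = _b


class SimulationError(RuntimeError):
    pass


@dataclass
class GenomeRecord:
    """A genome sequence tied to its taxonomy (species / genus resolved)."""

    accession: str
    taxid: int
    sequence: str
    species_taxid: int | None = None
    genus_taxid: int | None = None


def resolve_ranks(records: Iterable[GenomeRecord], tree: TaxonomyTree) -> list[GenomeRecord]:
    """Fill species_taxid / genus_taxid from the taxonomy in place."""
    out = []
    for rec in records:
        rec.species_taxid = tree.ancestor_at_rank(rec.taxid, "species")
        rec.genus_taxid = tree.ancestor_at_rank(rec.taxid, "genus")
        out.append(rec)
    return out


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; identical configs give byte-identical output."""

    read_length: int = 100
    mismatch_prob: float = 0.03
    reads_per_genome: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0.0 <= self.mismatch_prob <= 1.0:
            raise ValueError("mismatch_prob must be in [0, 1]")
        if self.reads_per_genome < 1:
            raise ValueError("reads_per_genome must be >= 1")


def dedupe_one_per_species(
    catalog: Iterable[GenomeRecord],
) -> tuple[list[GenomeRecord], list[GenomeRecord]]:
    """Keep exactly one genome per species (lexicographically smallest
    accession); returns (selected, excluded-for-unresolvable-species)."""
    excluded = []
    by_species: dict[int, GenomeRecord] = {}
    for rec in catalog:
        if rec.species_taxid is None:
            excluded.append(rec)
            continue
        cur = by_species.get(rec.species_taxid)
        if cur is None or rec.accession < cur.accession:
            by_species[rec.species_taxid] = rec
    selected = sorted(by_species.values(), key=lambda r: r.accession)
    return selected, excluded


def clade_exclusion_select(
    catalog: Iterable[GenomeRecord],
    reference_species: set[int],
    tree: TaxonomyTree,
) -> list[GenomeRecord]:
    """Keep genomes whose species is NOT in the reference set but whose genus
    is the genus of some reference species (novel species, known genus)."""
    ref_genera = {
        g for s in reference_species
        if (g := tree.ancestor_at_rank(s, "genus")) is not None
    }
    kept = []
    for rec in catalog:
        if rec.species_taxid is None or rec.genus_taxid is None:
            continue
        if rec.species_taxid not in reference_species and rec.genus_taxid in ref_genera:
            kept.append(rec)
    return kept


def _genome_rng(seed: int, accession: str) -> np.random.Generator:
    # Per-genome substream keyed by accession: adding or removing a genome
    # never perturbs the reads of any other genome.
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(accession.encode())])
    )


def _sample_genome(
    genome: GenomeRecord, config: SimConfig, rng: np.random.Generator
) -> Iterator[tuple[SequenceRecord, TruthRecord]]:
    rl = config.read_length
    arr = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
    L = arr.size
    if L < rl:
        raise SimulationError(
            f"genome {genome.accession} (length {L}) shorter than read length {rl}"
        )
    n = config.reads_per_genome
    starts = rng.integers(0, L - rl + 1, size=n)
    strands = rng.integers(0, 2, size=n)  # 0 = '+', 1 = '-'

    windows = arr[starts[:, None] + np.arange(rl)]
    codes = _CODE[windows]
    # Windows containing ambiguity codes are rejected and resampled.
    bad = (codes == 255).any(axis=1)
    tries = 0
    while bad.any():
        tries += 1
        if tries > 100:
            raise SimulationError(
                f"genome {genome.accession}: no N-free window found in 100 tries"
            )
        nbad = int(bad.sum())
        starts[bad] = rng.integers(0, L - rl + 1, size=nbad)
        windows[bad] = arr[starts[bad][:, None] + np.arange(rl)]
        codes[bad] = _CODE[windows[bad]]
        bad = (codes == 255).any(axis=1)

    # Minus-strand reads are reverse-complemented before error injection.
    minus = strands == 1
    codes[minus] = 3 - codes[minus, ::-1]  # A<->T, C<->G under ACGT indexing

    if config.mismatch_prob > 0:
        err = rng.random((n, rl)) < config.mismatch_prob
        shifts = rng.integers(1, 4, size=(n, rl))
        codes = np.where(err, (codes + shifts) % 4, codes)

    seqs = _BASES[codes]
    qual = "I" * rl
    for k in range(n):
        read_id = f"{genome.accession}_{k}"
        seq = seqs[k].tobytes().decode("ascii")
        strand = "-" if strands[k] else "+"
        s = int(starts[k])
        yield (
            SequenceRecord(read_id, seq, qual),
            TruthRecord(read_id, genome.accession, genome.taxid, strand, s, s + rl),
        )


def simulate_reads(
    genomes: Sequence[GenomeRecord], config: SimConfig
) -> Iterator[tuple[SequenceRecord, TruthRecord]]:
    """Yield (read, truth) pairs: reads_per_genome reads from each genome.

    Fully deterministic given the config (including seed); genomes are
    processed in catalog order but each draws from its own seeded substream.
    """
    for genome in genomes:
        rng = _genome_rng(config.seed, genome.accession)
        yield from _sample_genome(genome, config, rng)


def simulate_to_files(
    genomes: Sequence[GenomeRecord],
    config: SimConfig,
    fastq_path,
    truth_path,
) -> int:
    """Run the simulation writing FASTQ + truth manifest; returns read count."""
    n = 0
    with open(fastq_path, "w") as fq, open(truth_path, "w") as tr:
        tr.write("#read_id\taccession\ttaxid\tstrand\tstart\tend\n")
        for read, truth in simulate_reads(genomes, config):
            fq.write(f"@{read.id}\n{read.sequence}\n+\n{read.quality}\n")
            tr.write(
                f"{truth.read_id}\t{truth.accession}\t{truth.taxid}\t"
                f"{truth.strand}\t{truth.start}\t{truth.end}\n"
            )
            n += 1
    return n


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _COMPLEMENT[arr[::-1]].tobytes().decode("ascii")
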