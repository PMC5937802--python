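"""Published genus-level benchmark counts for five taxonomic classifiers.

Two synthetic metagenomes underlie these numbers: a *RefSeq* scenario
(2672 complete genomes, one per species, organisms present in every tool's
reference database; 2672 x 5000 = 13,360,000 reads) and a *GenBank*
clade-exclusion scenario (2376 genomes whose genus but not species is in
RefSeq; 11,880,000 reads). Counts are per-read true/false positives and
false negatives at genus level, as published.

The Kaiju false-negative count for the GenBank scenario was published with a
garbled thousands grouping; it is stored as None here and reconstructed from
the dataset-size closure tp + fp + fn = dataset size, which every other
column satisfies exactly.
"""

from __future__ import annotations

from .evaluate import ConfusionCounts

#: reads per scenario: genomes x 5000 reads/genome
DATASET_SIZES = {"refseq": 2672 * 5000, "genbank": 2376 * 5000}

TOOLS = ("Kraken", "Kaiju", "Centrifuge", "MetaPhlAn 2", "Combined")

# (tp, fp, fn); fn None -> derived from closure against the dataset size.
_RAW: dict[str, dict[str, tuple[int, int, int | None]]] = {
    "refseq": {
        "Kraken": (12_059_412, 18_748, 1_281_840),
        "Kaiju": (9_329_288, 185_899, 3_844_813),
        "Centrifuge": (12_611_380, 53_092, 695_528),
        "MetaPhlAn 2": (414_943, 7_171, 12_937_886),
        "Combined": (12_566_362, 20_698, 772_940),
    },
    "genbank": {
        "Kraken": (1_851_436, 398_899, 9_629_665),
        "Kaiju": (2_592_655, 1_230_445, None),
        "Centrifuge": (2_175_122, 864_989, 8_839_889),
        "MetaPhlAn 2": (92_383, 10_378, 11_777_239),
        "Combined": (3_976_270, 734_389, 7_169_341),
    },
}

#: published metric values (4 d.p.) for cross-checking, keyed like _RAW.
PUBLISHED_METRICS: dict[str, dict[str, dict[str, float]]] = {
    "refseq": {
        "Kraken": {"sensitivity": 0.9039, "precision": 0.9984, "accuracy": 0.9027, "f1": 0.9488},
        "Kaiju": {"sensitivity": 0.7082, "precision": 0.9805, "accuracy": 0.6983, "f1": 0.8224},
        "Centrifuge": {"sensitivity": 0.9477, "precision": 0.9958, "accuracy": 0.9440, "f1": 0.9712},
        "MetaPhlAn 2": {"sensitivity": 0.0311, "precision": 0.9830, "accuracy": 0.0311, "f1": 0.0602},
        "Combined": {"sensitivity": 0.9421, "precision": 0.9984, "accuracy": 0.9406, "f1": 0.9694},
    },
    "genbank": {
        "Kraken": {"sensitivity": 0.1613, "precision": 0.8227, "accuracy": 0.1558, "f1": 0.2697},
        "Kaiju": {"sensitivity": 0.2435, "precision": 0.6782, "accuracy": 0.2182, "f1": 0.3583},
        "Centrifuge": {"sensitivity": 0.1975, "precision": 0.7155, "accuracy": 0.1831, "f1": 0.3095},
        "MetaPhlAn 2": {"sensitivity": 0.0078, "precision": 0.8990, "accuracy": 0.0078, "f1": 0.0154},
        "Combined": {"sensitivity": 0.3568, "precision": 0.8441, "accuracy": 0.3347, "f1": 0.5015},
    },
}


def published_counts() -> dict[str, dict[str, ConfusionCounts]]:
    """Return the published confusion counts, with any garbled false-negative
    entry reconstructed from dataset-size closure."""
    out: dict[str, dict[str, ConfusionCounts]] = {}
    for dataset, cols in _RAW.items():
        size = DATASET_SIZES[dataset]
        out[dataset] = {}
        for tool, (tp, fp, fn) in cols.items():
            if fn is None:
                fn = size - tp - fp
            out[dataset][tool] = ConfusionCounts(tp, fp, fn)
    return out
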