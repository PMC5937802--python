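"""Genus-level scoring of per-read assignments against a truth manifest.

Each evaluated read lands in exactly one bucket after projecting both the
prediction and the truth to the target rank:

* **tp** — projected prediction equals the truth's rank-level taxon;
* **fp** — projected prediction exists but differs (wrong genus);
* **fn** — read unclassified, absent from the assignments, or assigned
  strictly above the target rank (no ancestor at that rank).

Truth reads whose own lineage lacks the target rank are excluded from the
evaluation (undefined ground truth), with a count reported. The derived
metrics are sensitivity tp/(tp+fn), precision tp/(tp+fp), accuracy tp/total
and the F1 harmonic mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import ReadAssignment, TruthRecord
from .taxonomy import TaxonomyTree


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-read confusion counts at a fixed rank; tp + fp + fn = total."""

    tp: int
    fp: int
    fn: int
    excluded: int = 0  # truth reads unresolvable at the rank (not in total)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    precision: float
    accuracy: float
    f1: float
    #: set when a denominator was zero and the metric was reported as 0
    undefined: frozenset = frozenset()


def score_at_rank(
    assignments: Iterable[ReadAssignment],
    truth: Iterable[TruthRecord],
    tree: TaxonomyTree,
    rank: str = "genus",
) -> ConfusionCounts:
    """Score assignments against truth after projection to `rank`."""
    calls: dict[str, ReadAssignment] = {}
    for a in assignments:
        if a.read_id in calls:
            raise ValueError(f"duplicate assignment for read {a.read_id}")
        calls[a.read_id] = a

    tp = fp = fn = excluded = 0
    seen_truth = 0
    for t in truth:
        seen_truth += 1
        true_at_rank = tree.ancestor_at_rank(t.taxid, rank)
        if true_at_rank is None:
            excluded += 1
            continue
        a = calls.get(t.read_id)
        if a is None or not a.is_classified or a.taxid not in tree:
            fn += 1
            continue
        pred_at_rank = tree.ancestor_at_rank(a.taxid, rank)
        if pred_at_rank is None:
            fn += 1  # call strictly above the target rank
        elif pred_at_rank == true_at_rank:
            tp += 1
        else:
            fp += 1
    if seen_truth == 0:
        raise ValueError("empty truth manifest")
    return ConfusionCounts(tp, fp, fn, excluded)


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Sensitivity / precision / accuracy / F1 from confusion counts.

    Zero denominators yield 0.0 with the metric name recorded in
    ``MetricSet.undefined`` rather than an error; F1 is 0 when precision and
    sensitivity are both 0.
    """
    if counts.total <= 0:
        raise ValueError("cannot compute metrics on zero evaluated reads")
    undefined = set()
    if counts.tp + counts.fn > 0:
        sens = counts.tp / (counts.tp + counts.fn)
    else:
        sens = 0.0
        undefined.add("sensitivity")
    if counts.tp + counts.fp > 0:
        prec = counts.tp / (counts.tp + counts.fp)
    else:
        prec = 0.0
        undefined.add("precision")
    acc = counts.tp / counts.total
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) > 0 else 0.0
    return MetricSet(sens, prec, acc, f1, frozenset(undefined))


_METRIC_ROWS = ("sensitivity", "precision", "accuracy", "f1")
_COUNT_ROWS = ("tp", "fp", "fn", "total")


def benchmark_report(
    results: Sequence[tuple[str, ConfusionCounts]], fmt: str = "tsv"
) -> str:
    """Render a tool-comparison table: counts plus metrics at 4 d.p.

    The best value per metric row is flagged with ``*`` (ties: all flagged).
    `fmt` is ``"tsv"`` or ``"markdown"``.
    """
    if not results:
        raise ValueError("benchmark_report needs at least one result")
    labels = [label for label, _ in results]
    metrics = [compute_metrics(c) for _, c in results]

    rows: list[tuple[str, list[str]]] = []
    for row in _COUNT_ROWS:
        rows.append((row, [f"{getattr(c, row):,}" for _, c in results]))
    for row in _METRIC_ROWS:
        vals = [getattr(m, row) for m in metrics]
        best = max(round(v, 4) for v in vals)
        cells = [
            f"{v:.4f}*" if round(v, 4) == best else f"{v:.4f}" for v in vals
        ]
        rows.append((row, cells))

    if fmt == "markdown":
        lines = ["| metric | " + " | ".join(labels) + " |",
                 "|---" * (len(labels) + 1) + "|"]
        for name, cells in rows:
            lines.append("| " + name + " | " + " | ".join(cells) + " |")
    elif fmt == "tsv":
        lines = ["metric\t" + "\t".join(labels)]
        for name, cells in rows:
            lines.append(name + "\t" + "\t".join(cells))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return "\n".join(lines) + "\n"
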