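"""Read-level confusion counting, F1-macro, organism detection, quartiles.

Evaluation is performed at a chosen taxonomic rank.  The per-read
categories follow the usual classifier-benchmarking convention:

* TP — read classified to its correct taxon (after rank projection);
* FP — read classified to an incorrect taxon;
* TN — read left unclassified whose organism is absent from the database
  (including negative/randomized reads with no source organism);
* FN — read left unclassified whose organism is present in the database.

An assignment above the evaluation rank counts as unclassified.  Host
reads (by true origin or by assignment) are dropped from the evaluation
entirely, so that metrics reflect only the microbial community.

Accuracy weighs every read equally and is therefore dominated by abundant
organisms; the macro-averaged F1 gives each organism (class) equal weight
instead, omitting classes absent from the database, whose F1 is zero by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .classification_io import UNCLASSIFIED, ReadClassification
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

__all__ = [
    "NEGATIVE",
    "GroundTruth",
    "ConfusionCounts",
    "DetectionReport",
    "confusion_at_rank",
    "accuracy",
    "precision",
    "recall",
    "f1_macro",
    "detect_organisms",
    "read_length_quartiles",
]

#: Truth sentinel for randomized reads with no source organism.
NEGATIVE = 0


@dataclass
class GroundTruth:
    """Read id -> true taxid; :data:`NEGATIVE` (0) marks randomized reads."""

    entries: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#read_id\ttaxid\n")
            for read_id in sorted(self.entries):
                fh.write(f"{read_id}\t{self.entries[read_id]}\n")

    @classmethod
    def from_tsv(cls, source: str | Path | IO[str]) -> "GroundTruth":
        entries: dict[str, int] = {}
        lines = open(source) if isinstance(source, (str, Path)) else source
        try:
            for lineno, line in enumerate(lines, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    raise ValueError(f"ground truth line {lineno}: expected 2 columns")
                if parts[0] in entries:
                    raise ValueError(f"ground truth line {lineno}: duplicate read id {parts[0]!r}")
                entries[parts[0]] = int(parts[1])
        finally:
            if isinstance(source, (str, Path)):
                lines.close()
        return cls(entries=entries)


@dataclass
class ConfusionCounts:
    """Global TP/FP/TN/FN plus per-class (tp_c, fp_c, fn_c) triples.

    Classes are the rank-projected organisms present in the sample.
    ``tp + fp + tn + fn`` equals the number of evaluated reads (reads
    surviving host exclusion).  Per-class false positives count reads
    *predicted* as the class; assignments to taxa outside the sample
    contribute to the global FP only.
    """

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    per_class: dict[int, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class DetectionReport:
    """Detected taxa per read-count threshold, optionally scored vs truth.

    ``detected[t]`` is the set of rank-level taxids with at least ``t``
    assigned reads; sets are nested decreasing as thresholds increase.
    ``tp_fp[t]`` holds (true-positive, false-positive) detection counts
    when a truth taxon set was supplied.
    """

    thresholds: list[int]
    counts: dict[int, int]
    detected: dict[int, set[int]]
    tp_fp: dict[int, tuple[int, int]] | None = None


def _rank_set(tree: TaxonomyTree, taxa: Iterable[int], rank: str) -> set[int]:
    """Project a taxid set to ``rank``, dropping taxa above it."""
    out: set[int] = set()
    for taxid in taxa:
        projected = tree.ancestor_at_rank(taxid, rank)
        if projected is not None:
            out.add(projected)
    return out


def _project(tree: TaxonomyTree, taxid: int, rank: str) -> int | None:
    if taxid == UNCLASSIFIED:
        return None
    resolved = tree.resolve(taxid)
    if resolved not in tree.nodes:
        logger.warning("unknown taxid %d in assignment; treated as unclassified", taxid)
        return None
    return tree.ancestor_at_rank(resolved, rank)


def _on_excluded_lineage(tree: TaxonomyTree, taxid: int, exclude: frozenset[int]) -> bool:
    if not exclude or taxid == UNCLASSIFIED:
        return False
    resolved = tree.resolve(taxid)
    if resolved not in tree.nodes:
        return False
    return tree.descends_from_any(resolved, exclude)


def confusion_at_rank(
    classification: ReadClassification,
    truth: GroundTruth,
    tree: TaxonomyTree,
    rank: str = "species",
    db_taxa: Iterable[int] = (),
    exclude: Iterable[int] = (),
) -> ConfusionCounts:
    """Count TP/FP/TN/FN at ``rank`` against a total ground truth.

    The evaluation universe is the set of truth reads.  Reads are dropped
    when either their true organism or their assignment lies on an
    excluded lineage (host filtering on both sides).  An assignment above
    ``rank`` is treated as unclassified.  A classified read is TP when its
    projection equals the truth projection, else FP.  An unclassified read
    is FN when its true organism projects into the database taxon set,
    else TN; negative-truth reads are TN unclassified and FP classified.

    Reads present in the classification but absent from the truth are an
    input error: ground truth must be total for synthetic data.
    """
    excl = frozenset(exclude)
    db_rank = _rank_set(tree, db_taxa, rank)

    extra = set(classification.assignments) - set(truth.entries)
    if extra:
        raise ValueError(
            f"{len(extra)} classified read(s) absent from ground truth, e.g. {sorted(extra)[:3]}"
        )

    # pass 1: the sample's classes at rank (non-negative, non-excluded truth)
    sample_classes: set[int] = set()
    for true_taxid in truth.entries.values():
        if true_taxid == NEGATIVE or _on_excluded_lineage(tree, true_taxid, excl):
            continue
        projected = _project(tree, true_taxid, rank)
        if projected is not None:
            sample_classes.add(projected)

    counts = ConfusionCounts()
    tp_c: dict[int, int] = {c: 0 for c in sample_classes}
    fp_c: dict[int, int] = {c: 0 for c in sample_classes}
    fn_c: dict[int, int] = {c: 0 for c in sample_classes}

    for read_id, true_taxid in truth.entries.items():
        assigned = classification.taxid_of(read_id)
        if _on_excluded_lineage(tree, true_taxid, excl) or _on_excluded_lineage(
            tree, assigned, excl
        ):
            continue

        pred = _project(tree, assigned, rank)

        if true_taxid == NEGATIVE:
            if pred is None:
                counts.tn += 1
            else:
                counts.fp += 1
                if pred in fp_c:
                    fp_c[pred] += 1
            continue

        true_proj = _project(tree, true_taxid, rank)
        if pred is None:
            # unclassified read: FN when the organism is in the database
            if true_proj is not None and true_proj in db_rank:
                counts.fn += 1
                if true_proj in fn_c:
                    fn_c[true_proj] += 1
            else:
                counts.tn += 1
            continue
        if true_proj is not None and pred == true_proj:
            counts.tp += 1
            tp_c[true_proj] += 1
        else:
            counts.fp += 1
            if pred in fp_c:
                fp_c[pred] += 1
            if true_proj in fn_c:
                # misclassified read also misses its own class
                fn_c[true_proj] += 1

    counts.per_class = {c: (tp_c[c], fp_c[c], fn_c[c]) for c in sample_classes}
    return counts


def accuracy(counts: ConfusionCounts) -> float:
    """ACC = (TP + TN) / (TP + FP + TN + FN)."""
    if counts.total == 0:
        raise ValueError("cannot compute accuracy over zero evaluated reads")
    return (counts.tp + counts.tn) / counts.total


def precision(counts: ConfusionCounts) -> float:
    """PR = TP / (TP + FP); 0 when nothing was classified."""
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else 0.0


def recall(counts: ConfusionCounts) -> float:
    """RC = TP / (TP + FN); 0 when there are no positives."""
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else 0.0


def _f1(tp: int, fp: int, fn: int) -> float:
    pr = tp / (tp + fp) if (tp + fp) else 0.0
    rc = tp / (tp + fn) if (tp + fn) else 0.0
    return 2 * pr * rc / (pr + rc) if (pr + rc) else 0.0


def f1_macro(
    counts: ConfusionCounts,
    db_taxa: Iterable[int],
    tree: TaxonomyTree | None = None,
    rank: str = "species",
) -> float:
    """Unweighted mean of per-class F1 over sample organisms in the database.

    Per class c: PR_c = tp_c/(tp_c+fp_c), RC_c = tp_c/(tp_c+fn_c) and
    F1_c = 2·PR_c·RC_c/(PR_c+RC_c), with F1_c = 0 when both are zero.
    Classes absent from the database are omitted (their F1 is zero by
    construction and would only dilute the average).  ``db_taxa`` is
    projected to ``rank`` when a tree is given, otherwise matched as-is.
    """
    db = _rank_set(tree, db_taxa, rank) if tree is not None else set(db_taxa)
    eligible = [c for c in counts.per_class if c in db]
    if not eligible:
        raise ValueError("no database class present in the sample; F1-macro undefined")
    return float(np.mean([_f1(*counts.per_class[c]) for c in eligible]))


def detect_organisms(
    classification: ReadClassification,
    tree: TaxonomyTree,
    rank: str = "species",
    thresholds: Sequence[int] = (1, 10, 50),
    truth_taxa: Iterable[int] | None = None,
    exclude: Iterable[int] = (),
) -> DetectionReport:
    """Report taxa whose assigned-read count reaches each threshold.

    Counts are taken after rank projection and host exclusion.  With a
    truth taxon set, each threshold also yields (TP, FP) detection counts:
    detected taxa inside vs outside the truth set (both at ``rank``).
    Raising the threshold prunes false positives at the risk of losing
    low-abundance organisms.
    """
    thresholds = list(thresholds)
    if any(t < 1 for t in thresholds):
        raise ValueError("thresholds must be >= 1")
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")

    excl = frozenset(exclude)
    tally: dict[int, int] = {}
    for taxid in classification.assignments.values():
        if _on_excluded_lineage(tree, taxid, excl):
            continue
        projected = _project(tree, taxid, rank)
        if projected is None or projected in excl:
            continue
        tally[projected] = tally.get(projected, 0) + 1

    detected = {t: {taxon for taxon, n in tally.items() if n >= t} for t in thresholds}
    tp_fp = None
    if truth_taxa is not None:
        truth_rank = _rank_set(tree, truth_taxa, rank)
        tp_fp = {
            t: (len(detected[t] & truth_rank), len(detected[t] - truth_rank)) for t in thresholds
        }
    return DetectionReport(thresholds=thresholds, counts=tally, detected=detected, tp_fp=tp_fp)


@dataclass(frozen=True)
class LengthQuartiles:
    """(Q1, median, Q3) of read lengths for TP and FP reads; None when empty."""

    tp: tuple[float, float, float] | None
    fp: tuple[float, float, float] | None


def read_length_quartiles(
    classification: ReadClassification,
    truth: GroundTruth,
    read_lengths: Mapping[str, int],
    tree: TaxonomyTree,
    rank: str = "species",
    db_taxa: Iterable[int] = (),
    exclude: Iterable[int] = (),
) -> LengthQuartiles:
    """Quartiles of read length for TP and FP classifications.

    FP lengths are restricted to reads whose true organism is in the
    database, so that the comparison is not confounded by out-of-database
    reads that no classifier could have placed.  Quartiles use linear
    interpolation between order statistics.
    """
    excl = frozenset(exclude)
    db_rank = _rank_set(tree, db_taxa, rank)
    tp_lengths: list[int] = []
    fp_lengths: list[int] = []
    for read_id, true_taxid in truth.entries.items():
        assigned = classification.taxid_of(read_id)
        if _on_excluded_lineage(tree, true_taxid, excl) or _on_excluded_lineage(
            tree, assigned, excl
        ):
            continue
        pred = _project(tree, assigned, rank)
        if pred is None:
            continue
        if read_id not in read_lengths:
            raise KeyError(f"no length for classified read {read_id!r}")
        true_proj = None if true_taxid == NEGATIVE else _project(tree, true_taxid, rank)
        if true_proj is not None and pred == true_proj:
            tp_lengths.append(read_lengths[read_id])
        elif true_proj is not None and true_proj in db_rank:
            fp_lengths.append(read_lengths[read_id])

    def quartiles(lengths: list[int]) -> tuple[float, float, float] | None:
        if not lengths:
            return None
        q1, q2, q3 = np.percentile(lengths, [25, 50, 75])
        return float(q1), float(q2), float(q3)

    return LengthQuartiles(tp=quartiles(tp_lengths), fp=quartiles(fp_lengths))
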