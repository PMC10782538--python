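"""Taxon abundance profiles and the L1 abundance error.

Three definitions of relative abundance are supported, all normalized to
sum to 1 over the reported taxa:

* ``read_count``   — C_i = number of reads assigned to taxon i;
* ``base_count``   — C_i = sum of assigned read lengths (genomic DNA);
* ``genome_count`` — C_i = sum of assigned read lengths divided by the
  taxon's average genome length G_i, i.e. its sequenced coverage.

The genome-count measure corrects for the fact that a large genome emits
proportionally more reads at equal organism (cell/genome) abundance, which
matters for long-read data where read-length distributions differ between
technologies and species.  Abundance accuracy is measured with the L1 norm
``L1 = sum_i |est_i - true_i|``, decomposed into the error over taxa truly
present (in-sample) and taxa reported but absent (out-of-sample).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

from .classification_io import UNCLASSIFIED, ReadClassification
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

__all__ = [
    "MEASURES",
    "GenomeLengthTable",
    "AbundanceProfile",
    "AbundanceError",
    "compute_profile",
    "profile_from_counts",
    "l1_error",
]

MEASURES = ("read_count", "base_count", "genome_count")


@dataclass
class GenomeLengthTable:
    """Taxid -> average genome length in bases (G_i); all lengths > 0."""

    entries: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxid, length in self.entries.items():
            if length <= 0:
                raise ValueError(f"genome length for taxid {taxid} must be > 0, got {length}")

    @classmethod
    def from_tsv(cls, source: str | Path | IO[str], units: str = "bp") -> "GenomeLengthTable":
        """Load a two-column (taxid, length) TSV.

        ``units="mb"`` converts megabase entries (the statistic NCBI
        reports as "median total length (Mb)") to bases.
        """
        if units not in ("bp", "mb"):
            raise ValueError(f"units must be 'bp' or 'mb', got {units!r}")
        factor = 1e6 if units == "mb" else 1.0
        entries: dict[int, float] = {}
        lines = open(source) if isinstance(source, (str, Path)) else source
        try:
            for lineno, line in enumerate(lines, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    raise ValueError(f"genome-length table line {lineno}: expected 2 columns")
                entries[int(parts[0])] = float(parts[1]) * factor
        finally:
            if isinstance(source, (str, Path)):
                lines.close()
        return cls(entries=entries)

    def get(self, taxid: int) -> float | None:
        return self.entries.get(taxid)


@dataclass
class AbundanceProfile:
    """Relative abundances A_i at one rank under one measure.

    ``values`` maps rank-level taxids to fractions that are >= 0 and sum
    to 1 (within 1e-9) whenever the profile is non-empty.
    """

    measure: str
    values: dict[int, float] = field(default_factory=dict)
    rank: str = "species"
    label: str = ""

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; expected one of {MEASURES}")
        if self.values:
            total = sum(self.values.values())
            if any(v < 0 for v in self.values.values()):
                raise ValueError("abundances must be non-negative")
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"non-empty profile must sum to 1, got {total!r}")

    def to_tsv(self, path: str | Path, tree: TaxonomyTree | None = None) -> None:
        """Write ``taxid <tab> name <tab> abundance``, descending by abundance."""
        with open(path, "w") as fh:
            fh.write(f"#measure={self.measure}\trank={self.rank}\n")
            for taxid, value in sorted(self.values.items(), key=lambda kv: (-kv[1], kv[0])):
                name = ""
                if tree is not None and taxid in tree:
                    name = tree.node(taxid).name
                fh.write(f"{taxid}\t{name}\t{value:.10g}\n")

    @classmethod
    def from_tsv(
        cls,
        source: str | Path | IO[str],
        measure: str = "genome_count",
        rank: str = "species",
        label: str = "",
    ) -> "AbundanceProfile":
        values: dict[int, float] = {}
        lines = open(source) if isinstance(source, (str, Path)) else source
        try:
            for line in lines:
                if not line.strip():
                    continue
                if line.startswith("#"):
                    for token in line[1:].split("\t"):
                        key, _, val = token.strip().partition("=")
                        if key == "measure" and val:
                            measure = val
                        elif key == "rank" and val:
                            rank = val
                    continue
                parts = line.rstrip("\n").split("\t")
                values[int(parts[0])] = float(parts[-1])
        finally:
            if isinstance(source, (str, Path)):
                lines.close()
        total = sum(values.values())
        if values and not math.isclose(total, 1.0, abs_tol=1e-9):
            # tolerate rounded inputs by renormalizing, loudly
            logger.warning("profile %s sums to %.6f; renormalizing", label or source, total)
            values = {t: v / total for t, v in values.items()}
        return cls(measure=measure, values=values, rank=rank, label=label)


@dataclass(frozen=True)
class AbundanceError:
    """L1 abundance error with its in-/out-of-sample decomposition.

    ``total_l1 = in_sample_l1 + out_of_sample_l1``; the total lies in
    [0, 2] since both profiles sum to 1.
    """

    total_l1: float
    in_sample_l1: float
    out_of_sample_l1: float


def _project_and_filter(
    taxid: int,
    tree: TaxonomyTree,
    rank: str,
    exclude: frozenset[int] | set[int],
) -> int | None:
    """Project an assignment to ``rank``; None if unusable.

    Drops unclassified ids, ids above the rank (treated as unclassified),
    unknown ids, and ids on an excluded lineage (e.g. host).
    """
    if taxid == UNCLASSIFIED:
        return None
    resolved = tree.resolve(taxid)
    if resolved not in tree.nodes:
        logger.warning("taxid %d not in taxonomy; read treated as unclassified", taxid)
        return None
    if exclude and tree.descends_from_any(resolved, exclude):
        return None
    projected = tree.ancestor_at_rank(resolved, rank)
    if projected is None:
        return None
    if exclude and projected in exclude:
        return None
    return projected


def compute_profile(
    classification: ReadClassification,
    read_lengths: Mapping[str, int] | None,
    glt: GenomeLengthTable | None,
    tree: TaxonomyTree,
    rank: str = "species",
    measure: str = "genome_count",
    exclude: Iterable[int] = (),
) -> AbundanceProfile:
    """Aggregate per-read assignments into a relative abundance profile.

    Reads assigned above ``rank`` are treated as unclassified and ignored;
    the rest are projected to ``rank``.  Per projected taxon i the raw
    quantity C_i is the read count, the summed read length, or the summed
    read length divided by the average genome length G_i, depending on
    ``measure``; values are then normalized to sum to 1 over the reported
    taxa.  Taxa on an excluded lineage (e.g. the host) are removed before
    normalization.  Under ``genome_count`` a taxon missing from the
    genome-length table is dropped with a warning before normalization.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    if measure in ("base_count", "genome_count") and read_lengths is None:
        raise ValueError(f"measure {measure!r} requires read lengths")
    if measure == "genome_count" and glt is None:
        raise ValueError("measure 'genome_count' requires a genome-length table")

    excl = frozenset(exclude)
    raw: dict[int, float] = {}
    for read_id, taxid in classification.assignments.items():
        projected = _project_and_filter(taxid, tree, rank, excl)
        if projected is None:
            continue
        if measure == "read_count":
            raw[projected] = raw.get(projected, 0.0) + 1.0
        else:
            if read_id not in read_lengths:
                raise KeyError(f"no read length for classified read {read_id!r}")
            raw[projected] = raw.get(projected, 0.0) + float(read_lengths[read_id])

    if measure == "genome_count":
        scaled: dict[int, float] = {}
        for taxid, bases in raw.items():
            g = glt.get(taxid)
            if g is None:
                logger.warning(
                    "taxid %d has no genome length; dropped from genome_count profile", taxid
                )
                continue
            scaled[taxid] = bases / g
        raw = scaled

    total = sum(raw.values())
    values = {t: c / total for t, c in raw.items() if c > 0} if total > 0 else {}
    return AbundanceProfile(
        measure=measure, values=values, rank=rank, label=classification.source_label
    )


def profile_from_counts(
    counts: Mapping[int, float],
    glt: GenomeLengthTable,
    rank: str = "species",
    label: str = "",
) -> AbundanceProfile:
    """Genome-count profile from per-taxon read counts alone.

    For tools that report only read counts per taxon (Bracken-style), the
    count stands in for sequenced DNA: C_i = count_i / G_i, normalized to
    sum to 1.  Taxa without a genome length are dropped with a warning.
    """
    raw: dict[int, float] = {}
    for taxid, count in counts.items():
        if count < 0:
            raise ValueError(f"negative count for taxid {taxid}")
        if count == 0:
            continue
        g = glt.get(taxid)
        if g is None:
            logger.warning("taxid %d has no genome length; dropped from profile", taxid)
            continue
        raw[taxid] = count / g
    total = sum(raw.values())
    values = {t: c / total for t, c in raw.items()} if total > 0 else {}
    return AbundanceProfile(measure="genome_count", values=values, rank=rank, label=label)


def l1_error(estimated: AbundanceProfile, truth: AbundanceProfile) -> AbundanceError:
    """L1 distance between two profiles, split in-sample / out-of-sample.

    The total sums ``|est_i - true_i|`` over the union of taxa (absent
    taxa contribute 0); the in-sample term restricts to taxa with true
    abundance > 0 and the out-of-sample term to taxa reported with true
    abundance 0.  The two terms partition the total exactly.
    """
    if estimated.rank != truth.rank:
        raise ValueError(f"rank mismatch: {estimated.rank!r} vs {truth.rank!r}")
    if estimated.measure != truth.measure:
        raise ValueError(f"measure mismatch: {estimated.measure!r} vs {truth.measure!r}")
    taxa = set(estimated.values) | set(truth.values)
    in_sample = 0.0
    out_of_sample = 0.0
    for taxid in taxa:
        est = estimated.values.get(taxid, 0.0)
        tru = truth.values.get(taxid, 0.0)
        diff = abs(est - tru)
        if tru > 0:
            in_sample += diff
        elif est > 0:
            out_of_sample += diff
    return AbundanceError(
        total_l1=in_sample + out_of_sample,
        in_sample_l1=in_sample,
        out_of_sample_l1=out_of_sample,
    )
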