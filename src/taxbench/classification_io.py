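"""Adapt mapper and classifier outputs into uniform per-read assignments.

General-purpose long-read mappers (minimap2, ram, ...) are not classifiers:
they print several candidate mappings per read.  This module turns their
PAF/SAM output into a per-read taxonomic call:

* PAF candidates are scored with the harmonic mean of the alignment block
  length (ML) and the number of matching bases (NM),
  ``2 * ML * NM / (ML + NM)``, and the best-scoring record wins;
* SAM candidates are ranked by the ``AS`` alignment-score tag;
* ties are broken by taking the record that appears first in the file.

Native classifier outputs (Kraken2-style C/U lines, generic two-column
read/taxid TSV) are parsed into the same :class:`ReadClassification`
container; taxid 0 denotes an unclassified read throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "UNCLASSIFIED",
    "MappingRecord",
    "ReadClassification",
    "SeqTaxMap",
    "harmonic_score",
    "parse_paf",
    "parse_sam",
    "best_assignment_per_read",
    "parse_kraken_style",
    "parse_assignment_tsv",
]

#: Sentinel taxid for reads with no taxonomic call (Kraken's convention).
UNCLASSIFIED = 0


class ClassificationParseError(ValueError):
    """Input does not follow the declared dialect."""


@dataclass(frozen=True)
class MappingRecord:
    """One candidate mapping of a read with its score ingredients.

    ``ml`` is the alignment/mapping block length and ``nm`` the number of
    matching bases (PAF columns 11 and 10 respectively); ``aln_score`` is
    the integer SAM ``AS`` tag when present.  ``file_order`` is the 0-based
    ordinal of the record in its source file and backs the first-in-file
    tie rule.
    """

    read_id: str
    read_length: int
    target_name: str
    ml: int
    nm: int
    aln_score: int | None = None
    file_order: int = 0

    def __post_init__(self) -> None:
        if self.ml < 1:
            raise ValueError(f"mapped record must have ML >= 1, got {self.ml}")
        if self.nm > self.ml:
            raise ValueError(f"NM ({self.nm}) cannot exceed ML ({self.ml})")


@dataclass
class ReadClassification:
    """Final read -> taxid assignment set for one tool run.

    ``assignments`` maps each read id to a taxid, with
    :data:`UNCLASSIFIED` (0) marking explicit non-calls.  Reads absent from
    the mapping are treated as unclassified downstream.
    """

    assignments: dict[str, int] = field(default_factory=dict)
    source_label: str = ""

    def taxid_of(self, read_id: str) -> int:
        return self.assignments.get(read_id, UNCLASSIFIED)

    def __len__(self) -> int:
        return len(self.assignments)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#read_id\ttaxid\n")
            for read_id in sorted(self.assignments):
                fh.write(f"{read_id}\t{self.assignments[read_id]}\n")

    @classmethod
    def from_tsv(cls, source: str | Path | IO[str], source_label: str = "") -> "ReadClassification":
        return parse_assignment_tsv(source, source_label=source_label)


@dataclass
class SeqTaxMap:
    """Target sequence name -> taxid lookup (the accession-to-taxid link).

    Names are keyed after truncation at the first whitespace; a lookup that
    misses is retried with a trailing ``.N`` accession-version suffix
    stripped, since accession tables and FASTA headers commonly differ only
    in the version.
    """

    entries: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, source: str | Path | IO[str]) -> "SeqTaxMap":
        entries: dict[str, int] = {}
        for lineno, line in enumerate(_iter_lines(source), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ClassificationParseError(f"seqmap line {lineno}: expected 2 columns")
            name = parts[0].split()[0]
            try:
                entries[name] = int(parts[1])
            except ValueError as exc:
                raise ClassificationParseError(f"seqmap line {lineno}: non-integer taxid") from exc
        return cls(entries=entries)

    def lookup(self, target_name: str) -> int | None:
        name = target_name.split()[0] if target_name.strip() else target_name
        if name in self.entries:
            return self.entries[name]
        base, dot, suffix = name.rpartition(".")
        if dot and suffix.isdigit() and base in self.entries:
            return self.entries[base]
        return None


def harmonic_score(ml: float, nm: float) -> float:
    """Harmonic-mean score ``2 * ml * nm / (ml + nm)`` of a mapping.

    ``ml`` is the mapping/alignment block length, ``nm`` the number of
    matching bases; the score lies between the two (equals both when they
    coincide) and is 0 when there are no matches.
    """
    if ml <= 0:
        raise ValueError(f"ml must be positive, got {ml}")
    if not 0 <= nm <= ml:
        raise ValueError(f"nm must satisfy 0 <= nm <= ml, got nm={nm}, ml={ml}")
    if nm == 0:
        return 0.0
    return 2.0 * ml * nm / (ml + nm)


def _iter_lines(source: str | Path | IO[str]) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def parse_paf(source: str | Path | IO[str]) -> list[MappingRecord]:
    """Parse PAF text into mapping records, preserving file order.

    Standard PAF: >=12 tab-separated columns; column 10 (1-based) holds the
    number of residue matches (NM) and column 11 the alignment block length
    (ML); column 2 the query length.
    """
    records: list[MappingRecord] = []
    order = 0
    for lineno, line in enumerate(_iter_lines(source), start=1):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 12:
            raise ClassificationParseError(
                f"PAF line {lineno}: expected >=12 columns, got {len(cols)}"
            )
        try:
            read_length = int(cols[1])
            nm = int(cols[9])
            ml = int(cols[10])
        except ValueError as exc:
            raise ClassificationParseError(f"PAF line {lineno}: non-integer numeric column") from exc
        records.append(
            MappingRecord(
                read_id=cols[0],
                read_length=read_length,
                target_name=cols[5],
                ml=ml,
                nm=min(nm, ml),
                file_order=order,
            )
        )
        order += 1
    return records


def parse_sam(source: str | Path | IO[str]) -> list[MappingRecord]:
    """Parse SAM text into mapping records, one per mapped alignment line.

    Unmapped records (flag 0x4) and supplementary alignments (0x800) are
    skipped; secondary alignments are retained as candidates.  The ``AS``
    integer tag supplies the alignment score; a record lacking it is kept
    with ``aln_score=None`` (ranking below any present score) and a logged
    warning.  ML/NM are derived from the CIGAR for diagnostics only: ML is
    the sum of M/=/X/I/D operation lengths, NM the aligned-base count minus
    the ``NM`` edit-distance tag when available.
    """
    if not isinstance(source, (str, Path)):
        # pysam wants a real file; spool text streams to a temp file
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as tmp:
            tmp.write("".join(source))
            path = tmp.name
        try:
            return parse_sam(path)
        finally:
            import os

            os.unlink(path)

    records: list[MappingRecord] = []
    order = 0
    with pysam.AlignmentFile(str(source), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_supplementary:
                continue
            if aln.has_tag("AS"):
                score: int | None = int(aln.get_tag("AS"))
            else:
                score = None
                logger.warning("SAM record for read %s lacks AS tag; ranked last", aln.query_name)
            stats = aln.get_cigar_stats()[0]
            # cigar op codes: 0=M 1=I 2=D 7== 8=X
            ml = stats[0] + stats[1] + stats[2] + stats[7] + stats[8]
            aligned = stats[0] + stats[7] + stats[8]
            if aln.has_tag("NM"):
                nm = max(aligned - int(aln.get_tag("NM")), 0)
            else:
                nm = aligned
            records.append(
                MappingRecord(
                    read_id=aln.query_name,
                    read_length=aln.query_length or aln.infer_read_length() or 0,
                    target_name=sam.get_reference_name(aln.reference_id) or "*",
                    ml=max(ml, 1),
                    nm=min(nm, max(ml, 1)),
                    aln_score=score,
                    file_order=order,
                )
            )
            order += 1
    return records


def best_assignment_per_read(
    records: Sequence[MappingRecord],
    seqmap: SeqTaxMap,
    mode: str = "paf-harmonic",
    source_label: str = "",
) -> ReadClassification:
    """Select one taxonomic call per read from its candidate mappings.

    ``mode="paf-harmonic"`` maximizes :func:`harmonic_score` over (ML, NM);
    ``mode="sam-alignment-score"`` maximizes the ``AS`` tag, with missing
    scores ranking below any present score.  Ties keep the record with the
    smallest ``file_order`` (the first alignment in the file).  Records
    whose target is not covered by ``seqmap`` are discarded with a warning;
    a read whose records are all discarded is absent from the result and
    therefore unclassified downstream.
    """
    if mode not in ("paf-harmonic", "sam-alignment-score"):
        raise ValueError(f"unknown mode {mode!r}")

    best: dict[str, tuple[float, int, int]] = {}  # read -> (score, file_order, taxid)
    for rec in sorted(records, key=lambda r: r.file_order):
        taxid = seqmap.lookup(rec.target_name)
        if taxid is None:
            logger.warning(
                "target %s of read %s absent from sequence-taxid map; record discarded",
                rec.target_name,
                rec.read_id,
            )
            continue
        if mode == "paf-harmonic":
            score = harmonic_score(rec.ml, rec.nm)
        else:
            score = float("-inf") if rec.aln_score is None else float(rec.aln_score)
        cur = best.get(rec.read_id)
        if cur is None or score > cur[0]:
            best[rec.read_id] = (score, rec.file_order, taxid)
    return ReadClassification(
        assignments={read: taxid for read, (_, _, taxid) in best.items()},
        source_label=source_label,
    )


def parse_kraken_style(source: str | Path | IO[str], source_label: str = "") -> ReadClassification:
    """Parse Kraken2-style classification lines: ``C|U <tab> read <tab> taxid``."""
    assignments: dict[str, int] = {}
    for lineno, line in enumerate(_iter_lines(source), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or parts[0] not in ("C", "U"):
            raise ClassificationParseError(
                f"kraken-style line {lineno}: expected 'C' or 'U' leading token"
            )
        read_id = parts[1]
        if read_id in assignments:
            raise ClassificationParseError(
                f"kraken-style line {lineno}: duplicate read id {read_id!r}"
            )
        if parts[0] == "U":
            assignments[read_id] = UNCLASSIFIED
        else:
            try:
                assignments[read_id] = int(parts[2])
            except ValueError as exc:
                raise ClassificationParseError(
                    f"kraken-style line {lineno}: non-integer taxid"
                ) from exc
    return ReadClassification(assignments=assignments, source_label=source_label)


def parse_assignment_tsv(source: str | Path | IO[str], source_label: str = "") -> ReadClassification:
    """Parse the generic two-column ``read_id <tab> taxid`` interchange dialect.

    Taxid 0 means unclassified; blank lines and ``#`` comments are ignored.
    """
    assignments: dict[str, int] = {}
    for lineno, line in enumerate(_iter_lines(source), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ClassificationParseError(f"assignment line {lineno}: expected 2 columns")
        read_id = parts[0]
        if read_id in assignments:
            raise ClassificationParseError(
                f"assignment line {lineno}: duplicate read id {read_id!r}"
            )
        try:
            assignments[read_id] = int(parts[1])
        except ValueError as exc:
            raise ClassificationParseError(f"assignment line {lineno}: non-integer taxid") from exc
    return ReadClassification(assignments=assignments, source_label=source_label)
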