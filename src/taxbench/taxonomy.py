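"""NCBI-style taxonomy handling: dump parsing, rank projection, LCA.

The taxonomy is the backbone of every downstream stage: read-level
evaluation and abundance profiling both project assignments onto a named
rank (species, genus, ...) by walking parent pointers, and assignments that
sit *above* the evaluation rank are treated as unclassified rather than
redistributed.

Rank labels are matched by exact string equality against the dump; no
synonym normalization is attempted, because ``nodes.dmp`` is the single
source of truth for ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "TaxNode",
    "TaxonomyTree",
    "TaxonomyParseError",
    "TaxonomyStructureError",
    "load_taxonomy",
    "load_merged",
]


class TaxonomyParseError(ValueError):
    """A dump line does not follow the NCBI pipe-and-tab dialect."""


class TaxonomyStructureError(ValueError):
    """The parsed node set is not a single rooted tree."""


@dataclass(frozen=True)
class TaxNode:
    """One taxonomy node: identifier, parent link, rank label and name.

    The rank label is exactly the string from the dump (``"species"``,
    ``"genus"``, ``"no rank"``, ...), untransformed.
    """

    taxid: int
    parent: int
    rank: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.taxid < 1:
            raise ValueError(f"taxid must be >= 1, got {self.taxid}")


@dataclass
class TaxonomyTree:
    """Parent-pointer tree over :class:`TaxNode`, keyed by taxid.

    Exactly one node (the root) is its own parent; every parent pointer
    resolves inside the node set and every upward walk terminates at the
    root.  An optional merged-id table (old taxid -> current taxid) is
    applied transparently before every lookup so that classifier outputs
    carrying obsolete ids from a different taxonomy snapshot still resolve.
    """

    nodes: dict[int, TaxNode]
    root: int
    merged: dict[int, int] = field(default_factory=dict)

    # -- construction ----------------------------------------------------

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        roots = [n.taxid for n in self.nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise TaxonomyStructureError(
                f"expected exactly one self-parented root, found {roots}"
            )
        if roots[0] != self.root:
            raise TaxonomyStructureError(
                f"declared root {self.root} but self-parented node is {roots[0]}"
            )
        for node in self.nodes.values():
            if node.parent not in self.nodes:
                raise TaxonomyStructureError(
                    f"node {node.taxid} references missing parent {node.parent}"
                )
        # Upward walks must reach the root (acyclicity).
        ok: set[int] = {self.root}
        for taxid in self.nodes:
            path = []
            cur = taxid
            while cur not in ok:
                path.append(cur)
                nxt = self.nodes[cur].parent
                if nxt in path or (nxt == cur and cur != self.root):
                    raise TaxonomyStructureError(f"cycle detected at taxid {cur}")
                cur = nxt
            ok.update(path)

    # -- queries ---------------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return self.resolve(taxid) in self.nodes

    def resolve(self, taxid: int) -> int:
        """Apply the merged-id remap (identity for current ids)."""
        return self.merged.get(taxid, taxid)

    def node(self, taxid: int) -> TaxNode:
        return self.nodes[self.resolve(taxid)]

    def lineage(self, taxid: int) -> list[int]:
        """Taxids from the node itself up to and including the root."""
        cur = self.resolve(taxid)
        if cur not in self.nodes:
            raise KeyError(f"taxid {taxid} not in taxonomy")
        out = [cur]
        while cur != self.root:
            cur = self.nodes[cur].parent
            out.append(cur)
        return out

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """First node at ``rank`` on the walk from ``taxid`` to the root.

        Returns ``None`` when the walk reaches the root without a match,
        i.e. the node lies above the requested rank or its lineage lacks
        the rank.  Unknown taxids warn and return ``None`` instead of
        raising, so that one stray id cannot abort a batch evaluation.
        """
        cur = self.resolve(taxid)
        if cur not in self.nodes:
            logger.warning("unknown taxid %d in ancestor_at_rank; treating as unranked", taxid)
            return None
        while True:
            node = self.nodes[cur]
            if node.rank == rank:
                return cur
            if cur == self.root:
                return None
            cur = node.parent

    def is_at_or_below(self, taxid: int, rank: str) -> bool:
        """True iff the node projects onto ``rank`` (is at it or below it)."""
        return self.ancestor_at_rank(taxid, rank) is not None

    def lca(self, a: int, b: int) -> int:
        """Deepest node present on both root paths."""
        ancestors_a = set(self.lineage(a))
        for taxid in self.lineage(b):
            if taxid in ancestors_a:
                return taxid
        raise TaxonomyStructureError(f"no common ancestor for {a} and {b}")  # pragma: no cover

    def descends_from_any(self, taxid: int, ancestors: Iterable[int]) -> bool:
        """True iff any member of ``ancestors`` lies on the node's lineage."""
        anc = set(ancestors)
        if not anc:
            return False
        cur = self.resolve(taxid)
        if cur not in self.nodes:
            return False
        return any(t in anc for t in self.lineage(cur))

    # -- serialization ---------------------------------------------------

    def write_dumps(self, nodes_path: str | Path, names_path: str | Path) -> None:
        """Write NCBI-dialect nodes.dmp / names.dmp (round-trips with load)."""
        with open(nodes_path, "w") as fh:
            for node in sorted(self.nodes.values(), key=lambda n: n.taxid):
                fh.write(f"{node.taxid}\t|\t{node.parent}\t|\t{node.rank}\t|\n")
        with open(names_path, "w") as fh:
            for node in sorted(self.nodes.values(), key=lambda n: n.taxid):
                if node.name:
                    fh.write(f"{node.taxid}\t|\t{node.name}\t|\t\t|\tscientific name\t|\n")


def _dump_fields(line: str) -> list[str]:
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def _iter_lines(source: str | Path | IO[str]) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def load_taxonomy(
    nodes_source: str | Path | IO[str],
    names_source: str | Path | IO[str] | None = None,
    merged_source: str | Path | IO[str] | None = None,
) -> TaxonomyTree:
    """Load a taxonomy from NCBI-style ``nodes.dmp`` / ``names.dmp`` dumps.

    Fields are separated by ``"\\t|\\t"`` and lines terminated by ``"\\t|"``.
    Nodes without a scientific-name entry receive an empty name.  An
    optional merged table (two columns: old taxid, new taxid) is attached
    for transparent remapping of obsolete ids.

    Raises :class:`TaxonomyParseError` (with the line number) on a
    malformed line and :class:`TaxonomyStructureError` on a missing parent,
    multiple roots, or a cycle.
    """
    nodes: dict[int, TaxNode] = {}
    raw: dict[int, tuple[int, str]] = {}
    for lineno, line in enumerate(_iter_lines(nodes_source), start=1):
        if not line.strip():
            continue
        fields = _dump_fields(line)
        if len(fields) < 3:
            raise TaxonomyParseError(
                f"nodes dump line {lineno}: expected >=3 pipe-delimited fields, got {len(fields)}"
            )
        try:
            taxid = int(fields[0])
            parent = int(fields[1])
        except ValueError as exc:
            raise TaxonomyParseError(f"nodes dump line {lineno}: non-integer taxid field") from exc
        raw[taxid] = (parent, fields[2].strip())

    names: dict[int, str] = {}
    if names_source is not None:
        for lineno, line in enumerate(_iter_lines(names_source), start=1):
            if not line.strip():
                continue
            fields = _dump_fields(line)
            if len(fields) < 4:
                raise TaxonomyParseError(
                    f"names dump line {lineno}: expected >=4 fields, got {len(fields)}"
                )
            if fields[3].strip() == "scientific name":
                try:
                    names[int(fields[0])] = fields[1].strip()
                except ValueError as exc:
                    raise TaxonomyParseError(
                        f"names dump line {lineno}: non-integer taxid field"
                    ) from exc

    for taxid, (parent, rank) in raw.items():
        nodes[taxid] = TaxNode(taxid=taxid, parent=parent, rank=rank, name=names.get(taxid, ""))

    roots = [t for t, n in nodes.items() if n.parent == t]
    if len(roots) != 1:
        raise TaxonomyStructureError(f"expected exactly one root, found {roots}")

    merged = load_merged(merged_source) if merged_source is not None else {}
    return TaxonomyTree(nodes=nodes, root=roots[0], merged=merged)


def load_merged(source: str | Path | IO[str]) -> dict[int, int]:
    """Load an old->new taxid remap table (two tab-separated columns).

    The NCBI ``merged.dmp`` pipe dialect is accepted too.
    """
    merged: dict[int, int] = {}
    for lineno, line in enumerate(_iter_lines(source), start=1):
        if not line.strip():
            continue
        fields = _dump_fields(line) if "\t|\t" in line else line.split()
        if len(fields) < 2:
            raise TaxonomyParseError(f"merged table line {lineno}: expected 2 columns")
        try:
            merged[int(fields[0])] = int(fields[1])
        except ValueError as exc:
            raise TaxonomyParseError(f"merged table line {lineno}: non-integer taxid") from exc
    return merged
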