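"""Ground-truthed mock communities and a controlled classifier simulator.

Real benchmark communities are built by mixing reads from isolated,
sequenced species at declared proportions — even mixes, staggered designs
spanning several orders of magnitude (18% down to 0.01%, 10% down to
0.005%), host-dominated samples (99% human), and negative controls made of
composition-preserving shuffled reads that match no organism.  This module
reproduces that structure synthetically:

* :func:`toy_world` builds a self-consistent universe — taxonomy, genomes,
  genome-length table and per-species read pools — from a seed;
* :func:`build_community` mixes pool reads at declared proportions with
  largest-remainder rounding and emits the ground truth and the declared
  profile;
* :func:`shuffle_negative_reads` produces shuffled (mononucleotide
  composition preserving, order destroying) negative reads;
* :func:`simulate_classifier_output` perturbs the truth under an explicit
  five-outcome error model so every evaluation metric has an analytic
  expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .abundance import AbundanceProfile, GenomeLengthTable
from .classification_io import UNCLASSIFIED, ReadClassification
from .evaluation import NEGATIVE, GroundTruth
from .taxonomy import TaxNode, TaxonomyTree

__all__ = [
    "CommunityDesign",
    "ClassifierErrorModel",
    "ToyWorld",
    "LengthSampler",
    "build_community",
    "shuffle_negative_reads",
    "simulate_classifier_output",
    "toy_world",
    "largest_remainder_counts",
    "write_reads",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CommunityDesign:
    """Declared composition of a mock community.

    ``members`` lists (pool id, taxid, proportion); proportions are > 0 and
    sum to 1.  ``negative`` optionally requests shuffled reads *on top of*
    ``total_reads`` (mirroring a community plus a negative spike-in), as
    (source sequence id, count).
    """

    members: tuple[tuple[str, int, float], ...]
    total_reads: int
    negative: tuple[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("community design needs at least one member")
        if any(p <= 0 for _, _, p in self.members):
            raise ValueError("member proportions must be > 0")
        total = sum(p for _, _, p in self.members)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"member proportions must sum to 1, got {total!r}")

    @classmethod
    def from_file(cls, source: str | Path | IO[str], total_reads: int, seed: int = 0) -> "CommunityDesign":
        """Parse member lines ``pool_id <tab> taxid <tab> proportion``.

        A line ``negative <tab> source_id <tab> count`` requests shuffled
        negative reads.
        """
        members: list[tuple[str, int, float]] = []
        negative: tuple[str, int] | None = None
        lines = open(source) if isinstance(source, (str, Path)) else source
        try:
            for line in lines:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "negative":
                    negative = (parts[1], int(parts[2]))
                else:
                    members.append((parts[0], int(parts[1]), float(parts[2])))
        finally:
            if isinstance(source, (str, Path)):
                lines.close()
        return cls(members=tuple(members), total_reads=total_reads, negative=negative, seed=seed)


@dataclass(frozen=True)
class ClassifierErrorModel:
    """Five-outcome categorical error model for a simulated classifier.

    Per read: correct taxid; a congeneric database species (sibling); the
    genus ancestor; an unrelated database species; or no call.  The five
    probabilities sum to 1.
    """

    p_correct: float
    p_sibling: float = 0.0
    p_ancestor: float = 0.0
    p_random_other: float = 0.0
    p_unclassified: float = 0.0

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (
            self.p_correct,
            self.p_sibling,
            self.p_ancestor,
            self.p_random_other,
            self.p_unclassified,
        )

    def __post_init__(self) -> None:
        probs = self.as_tuple()
        if any(p < 0 for p in probs):
            raise ValueError("probabilities must be non-negative")
        if not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
            raise ValueError(f"probabilities must sum to 1, got {sum(probs)!r}")


@dataclass
class LengthSampler:
    """Read-length distribution: constant, lognormal, or empirical.

    Long-read technologies differ sharply here — HiFi libraries are narrow
    while nanopore length distributions are wide and skewed — so all three
    dialects are supported:

    * ``LengthSampler("constant", length=n)``
    * ``LengthSampler("lognormal", mu=…, sigma=…, minimum=…, maximum=…)``
      (mu/sigma on the log scale, clamped to [minimum, maximum])
    * ``LengthSampler("empirical", lengths=[…])`` (resampled uniformly)
    """

    kind: str
    length: int = 1000
    mu: float = 8.0
    sigma: float = 0.5
    minimum: int = 100
    maximum: int = 100_000
    lengths: Sequence[int] = field(default_factory=list)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "constant":
            return np.full(n, self.length, dtype=np.int64)
        if self.kind == "lognormal":
            draw = rng.lognormal(self.mu, self.sigma, size=n)
            return np.clip(draw, self.minimum, self.maximum).astype(np.int64)
        if self.kind == "empirical":
            if not self.lengths:
                raise ValueError("empirical length sampler needs a non-empty length list")
            return rng.choice(np.asarray(self.lengths, dtype=np.int64), size=n, replace=True)
        raise ValueError(f"unknown length sampler kind {self.kind!r}")


def largest_remainder_counts(proportions: Sequence[float], total: int) -> list[int]:
    """Integer counts ~ proportion*total, summing exactly to ``total``.

    Each count starts at floor(p*total); the leftover units go to the
    largest fractional remainders (ties to earlier members), so every
    count deviates from p*total by less than 1.
    """
    exact = [p * total for p in proportions]
    counts = [int(math.floor(x)) for x in exact]
    leftover = total - sum(counts)
    order = sorted(range(len(exact)), key=lambda i: (-(exact[i] - counts[i]), i))
    for i in order[:leftover]:
        counts[i] += 1
    return counts


def build_community(
    design: CommunityDesign,
    pools: Mapping[str, str | Path | Sequence[SeqRecord]],
) -> tuple[list[SeqRecord], GroundTruth, AbundanceProfile]:
    """Mix pool reads at the declared proportions into one community.

    Reads are sampled without replacement from each pool with the seeded
    generator; per-member counts are proportion×total rounded by largest
    remainder so they sum exactly to ``total_reads``.  Read ids are
    rewritten to ``<taxid>_<ordinal>`` and recorded in the ground truth.
    The declared profile carries the design proportions as a
    read-count-measure profile.

    Negative reads requested by the design are *not* generated here (the
    shuffle source is a genome, not a pool); use
    :func:`shuffle_negative_reads` and concatenate.
    """
    rng = np.random.default_rng(design.seed)
    counts = largest_remainder_counts([p for _, _, p in design.members], design.total_reads)

    out_reads: list[SeqRecord] = []
    truth: dict[str, int] = {}
    for (pool_id, taxid, _), count in zip(design.members, counts):
        source = pools[pool_id]
        if isinstance(source, (str, Path)):
            fmt = "fastq" if str(source).endswith(("q", "fastq")) else "fasta"
            pool_reads = list(SeqIO.parse(str(source), fmt))
        else:
            pool_reads = list(source)
        if len(pool_reads) < count:
            raise ValueError(
                f"pool {pool_id!r} holds {len(pool_reads)} reads but {count} are needed "
                f"(deficit {count - len(pool_reads)})"
            )
        chosen = rng.choice(len(pool_reads), size=count, replace=False)
        for ordinal, idx in enumerate(chosen):
            rec = pool_reads[int(idx)]
            read_id = f"{taxid}_{ordinal}"
            new = SeqRecord(rec.seq, id=read_id, description="")
            if "phred_quality" in rec.letter_annotations:
                new.letter_annotations["phred_quality"] = rec.letter_annotations["phred_quality"]
            out_reads.append(new)
            truth[read_id] = taxid

    declared: dict[int, float] = {}
    for _, taxid, proportion in design.members:
        declared[taxid] = declared.get(taxid, 0.0) + proportion
    profile = AbundanceProfile(measure="read_count", values=declared, label="declared")
    return out_reads, GroundTruth(entries=truth), profile


def shuffle_negative_reads(
    source: str,
    n_reads: int,
    length_sampler: LengthSampler,
    seed: int = 0,
    id_prefix: str = "neg_",
) -> tuple[list[SeqRecord], GroundTruth]:
    """Shuffled negative reads that should match no database organism.

    For each read a window of the sampled length is drawn uniformly from
    the source sequence and its residues are uniformly permuted: the
    mononucleotide composition of the window is preserved exactly while
    all sequence order is destroyed.  Truth entries are NEGATIVE.
    """
    if n_reads == 0:
        return [], GroundTruth(entries={})
    rng = np.random.default_rng(seed)
    lengths = length_sampler.sample(n_reads, rng)
    if int(lengths.max()) > len(source):
        raise ValueError(
            f"source length {len(source)} shorter than max sampled read length {int(lengths.max())}"
        )
    reads: list[SeqRecord] = []
    truth: dict[str, int] = {}
    arr = np.frombuffer(source.encode(), dtype="S1")
    for i, length in enumerate(lengths):
        start = int(rng.integers(0, len(source) - int(length) + 1))
        window = arr[start : start + int(length)]
        shuffled = window[rng.permutation(int(length))]
        read_id = f"{id_prefix}{i}"
        reads.append(SeqRecord(Seq(shuffled.tobytes().decode()), id=read_id, description=""))
        truth[read_id] = NEGATIVE
    return reads, GroundTruth(entries=truth)


def simulate_classifier_output(
    truth: GroundTruth,
    tree: TaxonomyTree,
    model: ClassifierErrorModel,
    db_taxa: Sequence[int],
    seed: int = 0,
    source_label: str = "simulated",
) -> ReadClassification:
    """Draw a classification for every truth read under the error model.

    Per in-database read one of five outcomes is drawn: the correct taxid;
    a uniformly chosen same-genus database species (falling back to
    ``random_other`` when no congeneric exists); the genus ancestor; a
    uniformly chosen unrelated database species; or no call.  Negative
    reads use only {random_other, unclassified} with renormalized
    probabilities (a read with no source organism has no correct call,
    sibling, or ancestor); reads from organisms outside the database use
    {sibling, random_other, unclassified} renormalized, which reproduces
    the congeneric-confusion behaviour seen for species missing from
    databases.
    """
    rng = np.random.default_rng(seed)
    db = [tree.resolve(t) for t in db_taxa]
    db_set = set(db)

    genus_of: dict[int, int | None] = {}
    congeners: dict[int, list[int]] = {}
    for taxid in db:
        genus_of[taxid] = tree.ancestor_at_rank(taxid, "genus")
    by_genus: dict[int, list[int]] = {}
    for taxid, genus in genus_of.items():
        if genus is not None:
            by_genus.setdefault(genus, []).append(taxid)
    for taxid, genus in genus_of.items():
        congeners[taxid] = (
            [t for t in by_genus.get(genus, []) if t != taxid] if genus is not None else []
        )

    def others(taxid: int) -> list[int]:
        related = set(congeners.get(taxid, ())) | {taxid}
        return [t for t in db if t not in related]

    assignments: dict[str, int] = {}
    outcomes = ("correct", "sibling", "ancestor", "random_other", "unclassified")
    base = np.asarray(model.as_tuple())

    for read_id, true_taxid in truth.entries.items():
        if true_taxid == NEGATIVE:
            mask = np.array([0.0, 0.0, 0.0, base[3], base[4]])
        elif tree.resolve(true_taxid) not in db_set:
            mask = np.array([0.0, base[1], 0.0, base[3], base[4]])
        else:
            mask = base
        if mask.sum() == 0:
            assignments[read_id] = UNCLASSIFIED
            continue
        probs = mask / mask.sum()
        outcome = outcomes[int(rng.choice(5, p=probs))]

        resolved = tree.resolve(true_taxid) if true_taxid != NEGATIVE else NEGATIVE
        if outcome == "correct":
            assignments[read_id] = resolved
        elif outcome == "sibling":
            sibs = congeners.get(resolved)
            if sibs is None and resolved != NEGATIVE:
                genus = tree.ancestor_at_rank(resolved, "genus") if resolved in tree.nodes else None
                sibs = [t for t in by_genus.get(genus, []) if t != resolved] if genus else []
            if sibs:
                assignments[read_id] = int(sibs[int(rng.integers(len(sibs)))])
            else:
                pool = others(resolved)
                assignments[read_id] = (
                    int(pool[int(rng.integers(len(pool)))]) if pool else UNCLASSIFIED
                )
        elif outcome == "ancestor":
            genus = genus_of.get(resolved) or (
                tree.ancestor_at_rank(resolved, "genus") if resolved in tree.nodes else None
            )
            assignments[read_id] = genus if genus is not None else UNCLASSIFIED
        elif outcome == "random_other":
            pool = others(resolved) if resolved != NEGATIVE else db
            assignments[read_id] = int(pool[int(rng.integers(len(pool)))]) if pool else UNCLASSIFIED
        else:
            assignments[read_id] = UNCLASSIFIED
    return ReadClassification(assignments=assignments, source_label=source_label)


@dataclass
class ToyWorld:
    """A self-consistent synthetic universe for end-to-end testing.

    Holds the taxonomy, per-species genomes, the genome-length table and
    per-species read pools keyed by species taxid (as strings, usable as
    pool ids).
    """

    tree: TaxonomyTree
    genomes: dict[int, str]
    genome_lengths: GenomeLengthTable
    pools: dict[str, list[SeqRecord]]

    @property
    def species(self) -> list[int]:
        return sorted(self.genomes)


def _mutate(seq: np.ndarray, sub_rate: float, indel_rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions and single-base indels to a base array."""
    if sub_rate > 0:
        hits = rng.random(len(seq)) < sub_rate
        if hits.any():
            seq = seq.copy()
            seq[hits] = _BASES[rng.integers(0, 4, size=int(hits.sum()))]
    if indel_rate > 0:
        out: list[str] = []
        dice = rng.random(len(seq))
        ins = dice < indel_rate / 2
        dele = (dice >= indel_rate / 2) & (dice < indel_rate)
        for i, base in enumerate(seq):
            if dele[i]:
                continue
            out.append(base)
            if ins[i]:
                out.append(str(_BASES[int(rng.integers(0, 4))]))
        return "".join(out)
    return "".join(seq)


def toy_world(
    n_genera: int = 2,
    n_species_per_genus: int = 3,
    genome_length_range: tuple[int, int] = (20_000, 40_000),
    reads_per_species: int = 200,
    length_sampler: LengthSampler | None = None,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> ToyWorld:
    """Generate taxonomy, genomes, genome lengths and read pools from a seed.

    The taxonomy is root -> genera -> species (1 + G + G·S nodes); genomes
    are i.i.d. uniform base strings with lengths drawn from
    ``genome_length_range``; reads are genome substrings with optional
    substitution/indel noise.  All four outputs are mutually consistent:
    every pool read originates from its species' genome, and the length
    table records the exact genome lengths.
    """
    if n_genera < 1 or n_species_per_genus < 1:
        raise ValueError("need at least one genus and one species per genus")
    rng = np.random.default_rng(seed)
    sampler = length_sampler or LengthSampler("constant", length=1000)

    nodes: dict[int, TaxNode] = {1: TaxNode(1, 1, "no rank", "root")}
    genomes: dict[int, str] = {}
    pools: dict[str, list[SeqRecord]] = {}
    lengths: dict[int, float] = {}

    species_id = 100
    for g in range(n_genera):
        genus_id = 10 + g
        nodes[genus_id] = TaxNode(genus_id, 1, "genus", f"Genus_{g}")
        for s in range(n_species_per_genus):
            nodes[species_id] = TaxNode(species_id, genus_id, "species", f"Genus_{g} species_{s}")
            glen = int(rng.integers(genome_length_range[0], genome_length_range[1] + 1))
            genome = "".join(_BASES[rng.integers(0, 4, size=glen)])
            genomes[species_id] = genome
            lengths[species_id] = float(glen)

            read_lengths = sampler.sample(reads_per_species, rng)
            reads: list[SeqRecord] = []
            for j, rl in enumerate(read_lengths):
                rl = int(min(rl, glen))
                if rl > glen:
                    raise ValueError("read length exceeds genome length")
                start = int(rng.integers(0, glen - rl + 1))
                raw = np.array(list(genome[start : start + rl]))
                seq = _mutate(raw, sub_rate, indel_rate, rng)
                reads.append(SeqRecord(Seq(seq), id=f"pool{species_id}_{j}", description=""))
            pools[str(species_id)] = reads
            species_id += 1

    tree = TaxonomyTree(nodes=nodes, root=1)
    return ToyWorld(
        tree=tree,
        genomes=genomes,
        genome_lengths=GenomeLengthTable(entries=lengths),
        pools=pools,
    )


def write_reads(reads: Sequence[SeqRecord], path: str | Path, fmt: str = "fastq") -> None:
    """Write reads as FASTA or FASTQ (constant quality 'I' when absent)."""
    out = []
    for rec in reads:
        if fmt == "fastq" and "phred_quality" not in rec.letter_annotations:
            rec = SeqRecord(rec.seq, id=rec.id, description=rec.description)
            rec.letter_annotations["phred_quality"] = [40] * len(rec.seq)
        out.append(rec)
    SeqIO.write(out, str(path), fmt)
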