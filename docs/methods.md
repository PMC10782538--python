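# Methods

`taxbench` evaluates long-read metagenomic classifiers. It adapts
general-purpose mapper output into per-read taxonomic calls, aggregates
calls into abundance profiles under three definitions, scores classifiers
at the read, abundance and organism-detection levels against ground truth,
and synthesizes the ground-truthed mock communities it is evaluated on.
This note records the models, the defaults and why, the numerical
conventions, and what the synthetic data does and does not show.

## Taxonomy and rank projection

All evaluation happens at a named taxonomic rank (default `species`). A
taxid is *projected* to a rank by walking parent pointers in an NCBI-style
`nodes.dmp` tree until a node with exactly that rank label is met; a taxid
whose walk reaches the root without a match lies **above** the rank and is
treated as unclassified, never redistributed downward. Rank labels are
compared by exact string equality against the dump — the dump is the single
source of truth, and synonym normalization would silently change results.

Obsolete taxids are handled by an optional merged-id remap table applied
before every lookup. Classifier outputs routinely carry ids from a
different taxonomy snapshot than the evaluation tree; ids that remain
unknown after remapping are warned about and treated as unclassified
rather than aborting a batch run.

## Mapper-to-classifier adaptation

Mappers report several candidate mappings per read. For PAF input each
candidate is scored with the harmonic mean of the alignment block length
ML and the number of matching bases NM:

    score = 2 · ML · NM / (ML + NM)

which lies between NM and ML, rewarding mappings that are simultaneously
long and accurate; a long sloppy mapping and a short perfect one both
score below a long accurate one. ML is PAF column 11 (alignment block
length) and NM column 10 (residue matches) — the standard PAF fields
matching "mapping length" and "number of matches"; the query-span reading
of "mapping length" is the one deliberate interpretation here, and block
length was chosen because it is what the format defines as the alignment's
extent. For SAM input candidates are ranked by the `AS` alignment-score
tag; records lacking `AS` rank below any scored record (with a warning)
instead of aborting, so mixed-producer files stay usable.

Ties — for both PAF and SAM — keep the record that appears first in the
file. Secondary alignments are retained as candidates; supplementary
records are skipped because they are partial alignments of a read already
represented. Target names are mapped to taxids by exact match after
whitespace truncation, with a fallback that strips a trailing accession
version (`.N`); unmappable targets are discarded with a warning, and a
read whose candidates are all discarded is unclassified.

## Abundance measures

With L_ij the length of read j assigned to taxon i and G_i the taxon's
average genome length, the raw quantity per taxon is

* read count:    C_i = #reads
* base count:    C_i = Σ_j L_ij
* genome count:  C_i = Σ_j L_ij / G_i   (sequenced coverage)

and the reported abundance is A_i = C_i / Σ_k C_k over the reported taxa
only. Genome counting corrects for genome size: at equal organism
abundance a 10× larger genome emits ~10× more sequenced bases. The
distinction matters most for nanopore data, whose read-length distribution
is wide and skewed, so read counts and sequenced bases diverge. For tools
that report only per-taxon read counts, `profile_from_counts` uses the
count itself as the DNA proxy (C_i = count_i / G_i) — the natural
degradation when read lengths are unavailable.

Host exclusion (default lineage: taxid 9606) removes reads on an excluded
lineage **before** normalization, so profiles describe the microbial
fraction. Genome lengths are a user-supplied TSV (taxid, length); a `mb`
units flag converts megabase tables to bases at load time, since public
genome-size tables are commonly printed in Mb. A genome-count taxon with
no length entry is dropped with a warning before normalization rather than
poisoning the profile.

Profile accuracy is the L1 distance Σ_i |A_i − A*_i| over the union of
reported and true taxa, in [0, 2]. It is decomposed exactly into an
in-sample term (taxa truly present — how well abundances of real community
members are estimated) and an out-of-sample term (taxa reported but
absent — the mass hallucinated onto organisms not in the sample). The two
terms always sum to the total; only the total is symmetric.

## Read-level evaluation

Per read, after projecting both the truth and the assignment to the
evaluation rank and dropping host reads (by true origin *or* by
assignment — the conservative reading, configurable):

* classified, projection equals truth projection → TP;
* classified otherwise → FP (this includes reads whose organism is not in
  the database: classifying them cannot be right);
* unclassified, organism's projection in the database → FN;
* unclassified otherwise (including negative/shuffled reads) → TN.

Accuracy is (TP+TN)/(TP+FP+TN+FN). Because it weighs reads, not
organisms, a staggered community lets the dominant species mask failures
on rare ones; the macro-averaged F1 therefore computes per-class
precision/recall/F1 for each organism in the sample and averages them
unweighted. Classes absent from the database are omitted (their F1 is
zero by construction and would only encode database content, not
classifier quality). Per-class false negatives count both unclassified
and *misclassified* reads of the class — the standard macro-F1 recall —
since a recall that ignored misclassification would be blind to exactly
the confusions the measure exists to expose; per-class false positives
count reads predicted as the class, and assignments to taxa outside the
sample contribute to the global FP only. Division-by-zero conventions:
PR, RC and F1 are 0 when their denominators vanish.

Ground truth must be total: a classified read missing from the truth
aborts with an error, because for synthetic data that can only be an
input mix-up, and silently ignoring it would inflate every metric.

Organism detection reports, per read-count threshold t (default 1, 10,
50), the rank-level taxa with ≥ t assigned reads, and TP/FP detection
counts against a truth taxon set. Raising t prunes spuriously reported
organisms but eventually deletes genuinely rare ones — in a staggered
community a species at 0.005% of 100,000 reads has only 5 reads and
disappears beyond t = 5.

Read-length quartiles (Q1/median/Q3, linear interpolation between order
statistics — the common "type 7" rule; no other convention is documented
for this analysis) are reported separately for TP reads and for FP reads
whose organism is in the database, excluding out-of-database reads that no
classifier could have placed.

## Synthetic communities

`toy_world` builds a self-consistent universe from one seed: a
root→genera→species taxonomy, i.i.d. uniform-base genomes (default
20–40 kb — large enough that 1 kb reads are effectively unique, small
enough to generate thousands of reads per second), per-species read pools
cut from the genomes with optional substitution/indel noise, and the
matching genome-length table.

`build_community` mixes pool reads at declared proportions: counts are
proportion×total rounded by largest remainder (each count within 1 read of
exact), sampling is without replacement (real mixed communities never
duplicate a read), and read ids are rewritten `<taxid>_<ordinal>` with the
truth recorded per read. Reference designs shipped in `designs.py` mirror
the study conditions this toolkit targets: an even 10×10% community, a
host-dominated 99%/0.9%/0.1% design, a 20,000-read negative spike-in, and
~100,000 reads per dataset as the default scale.

Negative reads are made by drawing a window from a source genome and
uniformly permuting its residues: mononucleotide composition is preserved
exactly, all order is destroyed. Window-then-permute is
distribution-equivalent to shuffling the whole genome first and cutting
windows (for a mononucleotide shuffle) and far cheaper;
dinucleotide-preserving shuffling is out of scope. Read lengths come from
a constant, lognormal or empirical sampler — the three shapes needed to
imitate HiFi (narrow) versus nanopore (wide, skewed) libraries.

`simulate_classifier_output` perturbs the truth under an explicit
five-outcome model (correct / congeneric sibling / genus ancestor /
unrelated database species / unclassified), so every metric has an
analytic expectation — e.g. with p_correct = 0.8 on in-database reads,
E[ACC] = 0.8 exactly, because sibling and random errors are FP, the
ancestor outcome lands above species rank and becomes FN, and TN is
impossible. Negative reads draw only from {random other, unclassified}
(renormalized): a read with no source organism has no correct call,
sibling, or ancestor. Reads from organisms absent from the database draw
from {sibling, random other, unclassified} (renormalized), with the
sibling outcome reproducing the congeneric-confusion behaviour real
classifiers show for species whose relatives are in the database; when no
congeneric exists the sibling mass falls through to a random other
species.

What the generator does **not** emulate: platform-specific error profiles
(pore/polymerase signal, homopolymer artifacts), shared k-mer content
between related genomes (toy genomes are independent, so inter-species
confusability is injected by the error model rather than emergent),
database incompleteness beyond an explicit db-taxa set, and GC or
coverage bias. Passing tests therefore certify the *bookkeeping* —
scoring, projection, counting, normalization, decomposition — under
controlled conditions, not any claim about classifier accuracy on real
samples.

## Profile comparison

For samples without ground truth, each tool's profile is a vector over
the union of reported taxa (absent taxa 0, columns ordered by taxid).
Pairwise distances default to L1 for consistency with the abundance
error — on the union matrix the L1 distance between two tools equals
`l1_error` of their profiles exactly, a cross-module identity under test.
Hierarchical clustering uses average linkage by default (an explicit
choice; complete and single are available), via SciPy. PCA centers
columns and projects rows onto the top-2 right singular directions; the
sign of each component is pinned by making its largest-magnitude loading
positive, so coordinates are deterministic and row-order invariant.

## Numerical conventions and degenerate inputs

* Non-empty profiles must sum to 1 within 1e-9 (constructor-enforced);
  rounded external profile TSVs are renormalized with a warning.
* `harmonic_score` requires ML ≥ 1 and 0 ≤ NM ≤ ML; NM = 0 scores 0.
* Accuracy over zero evaluated reads, F1-macro with no eligible class,
  a PCA with fewer than two rows, and a distance matrix from one profile
  are errors, not NaNs.
* Empty TP or FP sets yield `None` quartile triples.
* All randomness flows through `numpy.random.default_rng(seed)`; each
  stage derives its own sub-seed deterministically, and identical
  configurations are byte-identical on disk.

## Problem sizes

Default test and acceptance runs use a 2-genera × 5-species universe,
10,000-read communities, 100 randomized oracle fixtures of up to 1,000
reads, and 1,000 random profile pairs — sizes at which every expectation
used in an assertion is either exact (identities, closed forms) or has
binomial/multinomial noise small enough for 99% intervals to be tight.
The community builder itself scales to the ~100,000-read default of the
reference designs.
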