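"""Reference community designs and mock-standard composition facts.

These constants encode the benchmark study conditions this toolkit is
built around: synthetic communities mixed from real isolate reads at
declared proportions (even, staggered, host-dominated, and a negative
spike-in), and the vendor-declared composition facts needed to interpret
the PacBio HiFi Zymo D6331 gut-standard results.
"""

from __future__ import annotations

__all__ = [
    "PB1_PROPORTIONS",
    "PB3_PROPORTIONS",
    "PB1_NEG_READ_COUNT",
    "DEFAULT_TOTAL_READS",
    "DEFAULT_DETECTION_THRESHOLDS",
    "HUMAN_TAXID",
    "PB_ZYMO_DB_ABSENT",
]

#: Human (host) taxid; the default exclusion lineage for microbial metrics.
HUMAN_TAXID = 9606

#: Typical community size: around 100,000 reads per dataset.
DEFAULT_TOTAL_READS = 100_000

#: Detection read-count thresholds used in organism-detection reports.
DEFAULT_DETECTION_THRESHOLDS = (1, 10, 50)

#: Even 10-species bacterial community: 10 bacteria at 10% each
#: (two of the ten members are distinct E. coli strains).
PB1_PROPORTIONS = tuple(0.10 for _ in range(10))

#: Infection-like host-dominated design: 99% human reads plus two
#: low-abundance bacteria, 0.9% E. coli and 0.1% Staphylococcus aureus.
PB3_PROPORTIONS = {
    "human": 0.99,
    "e_coli": 0.009,
    "s_aureus": 0.001,
}

#: Negative spike-in size: 20,000 shuffled human-genome reads appended to
#: the even community, forming its "+NEG" variant.
PB1_NEG_READ_COUNT = 20_000

#: Zymo D6331 gut-standard members missing from the reference database,
#: with their vendor-declared abundance fractions: Veillonella rogosae
#: (19.94%) and Prevotella corporis (6.26%).  Together they exceed a
#: quarter of the declared composition, which caps any classifier's
#: attainable in-sample accuracy on that dataset.
PB_ZYMO_DB_ABSENT = {
    423477: 0.1994,  # Veillonella rogosae
    28128: 0.0626,  # Prevotella corporis
}
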