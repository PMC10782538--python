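import random

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from taxbench.classification_io import ReadClassification
from taxbench.evaluation import (
    NEGATIVE,
    ConfusionCounts,
    GroundTruth,
    accuracy,
    confusion_at_rank,
    detect_organisms,
    f1_macro,
    read_length_quartiles,
)


def brute_force_confusion(classification, truth, tree, rank, db_taxa, exclude=frozenset()):
    """Independent per-read recount of the four categories.

    Written directly from the category definitions, without reusing any
    evaluation-module helpers beyond raw taxonomy walks.
    """

    def proj(taxid):
        if taxid == 0:
            return None
        t = tree.resolve(taxid)
        if t not in tree.nodes:
            return None
        while True:
            node = tree.nodes[t]
            if node.rank == rank:
                return t
            if t == tree.root:
                return None
            t = node.parent

    def on_excluded(taxid):
        if taxid == 0 or not exclude:
            return False
        t = tree.resolve(taxid)
        if t not in tree.nodes:
            return False
        while True:
            if t in exclude:
                return True
            if t == tree.root:
                return False
            t = tree.nodes[t].parent

    db_rank = {proj(t) for t in db_taxa} - {None}
    tp = fp = tn = fn = 0
    for read, true_taxid in truth.entries.items():
        assigned = classification.assignments.get(read, 0)
        if on_excluded(true_taxid) or on_excluded(assigned):
            continue
        pred = proj(assigned)
        true_proj = None if true_taxid == NEGATIVE else proj(true_taxid)
        if pred is None:
            if true_taxid != NEGATIVE and true_proj in db_rank:
                fn += 1
            else:
                tn += 1
        elif true_taxid != NEGATIVE and pred == true_proj:
            tp += 1
        else:
            fp += 1
    return tp, fp, tn, fn


class TestConfusionAtRank:
    def test_perfect_classifier(self, mini_tree):
        truth = GroundTruth(entries={f"r{i}": 100 for i in range(1000)})
        cls = ReadClassification(assignments={f"r{i}": 100 for i in range(1000)})
        counts = confusion_at_rank(cls, truth, mini_tree, db_taxa={100})
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (1000, 0, 0, 0)

    def test_negative_read_unclassified_is_tn(self, mini_tree):
        truth = GroundTruth(entries={"neg_0": NEGATIVE})
        counts = confusion_at_rank(
            ReadClassification(assignments={}), truth, mini_tree, db_taxa={100}
        )
        assert counts.tn == 1 and counts.total == 1

    def test_negative_read_classified_is_fp(self, mini_tree):
        truth = GroundTruth(entries={"neg_0": NEGATIVE})
        cls = ReadClassification(assignments={"neg_0": 100})
        counts = confusion_at_rank(cls, truth, mini_tree, db_taxa={100})
        assert counts.fp == 1

    def test_genus_assignment_at_species_rank_is_fn(self, mini_tree):
        """A read assigned to a higher taxon counts as unclassified -> FN in db."""
        truth = GroundTruth(entries={"r0": 100})
        cls = ReadClassification(assignments={"r0": 10})  # genus of 100
        counts = confusion_at_rank(cls, truth, mini_tree, rank="species", db_taxa={100})
        assert counts.fn == 1

    def test_same_read_at_genus_rank_is_tp(self, mini_tree):
        truth = GroundTruth(entries={"r0": 100})
        cls = ReadClassification(assignments={"r0": 10})
        counts = confusion_at_rank(cls, truth, mini_tree, rank="genus", db_taxa={100})
        assert counts.tp == 1

    def test_out_of_db_read_unclassified_is_tn(self, mini_tree):
        truth = GroundTruth(entries={"r0": 200})  # organism not in db
        counts = confusion_at_rank(
            ReadClassification(assignments={}), truth, mini_tree, db_taxa={100}
        )
        assert counts.tn == 1

    def test_out_of_db_read_classified_is_fp(self, mini_tree):
        truth = GroundTruth(entries={"r0": 200})
        cls = ReadClassification(assignments={"r0": 100})
        counts = confusion_at_rank(cls, truth, mini_tree, db_taxa={100})
        assert counts.fp == 1

    def test_strain_truth_matches_species_assignment(self, mini_tree):
        truth = GroundTruth(entries={"r0": 150})  # strain under species 100
        cls = ReadClassification(assignments={"r0": 100})
        counts = confusion_at_rank(cls, truth, mini_tree, db_taxa={100})
        assert counts.tp == 1

    def test_host_reads_dropped_on_either_side(self, host_tree):
        truth = GroundTruth(entries={"h0": 9606, "m0": 100, "m1": 100})
        cls = ReadClassification(assignments={"h0": 9606, "m0": 100, "m1": 9606})
        counts = confusion_at_rank(cls, truth, host_tree, db_taxa={100}, exclude={9606})
        # h0 dropped (host truth); m1 dropped (host assignment); m0 is TP
        assert (counts.tp, counts.total) == (1, 1)

    def test_classified_read_missing_from_truth_aborts(self, mini_tree):
        truth = GroundTruth(entries={"r0": 100})
        cls = ReadClassification(assignments={"r0": 100, "ghost": 100})
        with pytest.raises(ValueError, match="ghost"):
            confusion_at_rank(cls, truth, mini_tree, db_taxa={100})

    def test_unknown_assigned_taxid_treated_unclassified(self, mini_tree, caplog):
        truth = GroundTruth(entries={"r0": 100})
        cls = ReadClassification(assignments={"r0": 31337})
        with caplog.at_level("WARNING"):
            counts = confusion_at_rank(cls, truth, mini_tree, db_taxa={100})
        assert counts.fn == 1

    def test_per_class_totals_match_global(self, mini_tree):
        rng = random.Random(3)
        species = [100, 101, 200]
        truth = GroundTruth(entries={f"r{i}": rng.choice(species) for i in range(500)})
        cls = ReadClassification(
            assignments={
                r: rng.choice(species + [0, 10]) for r in truth.entries if rng.random() < 0.9
            }
        )
        counts = confusion_at_rank(cls, truth, mini_tree, db_taxa=set(species))
        assert sum(tp for tp, _, _ in counts.per_class.values()) == counts.tp
        assert sum(fp for _, fp, _ in counts.per_class.values()) <= counts.fp

    def test_matches_brute_force_on_random_fixtures(self, mini_tree):
        """Oracle equivalence over 100 random <=1,000-read fixtures."""
        rng = random.Random(42)
        taxa_pool = [100, 101, 150, 200, 10, 20, 0]
        for trial in range(100):
            n = rng.randint(1, 1000)
            db = set(rng.sample([100, 101, 200], rng.randint(1, 3)))
            truth = GroundTruth(
                entries={
                    f"t{trial}_r{i}": rng.choice([100, 101, 150, 200, NEGATIVE])
                    for i in range(n)
                }
            )
            cls = ReadClassification(
                assignments={
                    r: rng.choice(taxa_pool)
                    for r in truth.entries
                    if rng.random() < 0.8
                }
            )
            counts = confusion_at_rank(cls, truth, mini_tree, db_taxa=db)
            expected = brute_force_confusion(cls, truth, mini_tree, "species", db)
            assert (counts.tp, counts.fp, counts.tn, counts.fn) == expected
            assert counts.total == n


class TestAccuracy:
    def test_worked_example(self):
        assert accuracy(ConfusionCounts(tp=80, fp=10, tn=5, fn=5)) == pytest.approx(0.85)

    def test_all_tp(self):
        assert accuracy(ConfusionCounts(tp=10)) == 1.0

    def test_all_fp(self):
        assert accuracy(ConfusionCounts(fp=10)) == 0.0

    def test_zero_reads_error(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts())


class TestF1Macro:
    def test_averaging(self):
        counts = ConfusionCounts(per_class={100: (10, 0, 0), 101: (5, 5, 5)})
        # class 100: F1 = 1.0 ; class 101: PR = RC = 0.5 -> F1 = 0.5
        assert f1_macro(counts, db_taxa={100, 101}) == pytest.approx(0.75)

    def test_out_of_db_class_omitted(self):
        counts = ConfusionCounts(per_class={100: (9, 1, 1), 200: (0, 0, 10)})
        # class 200 not in db: omitted; class 100 F1 = 0.9
        assert f1_macro(counts, db_taxa={100}) == pytest.approx(0.9)

    def test_zero_division_convention(self):
        counts = ConfusionCounts(per_class={100: (0, 0, 10), 101: (10, 0, 0)})
        assert f1_macro(counts, db_taxa={100, 101}) == pytest.approx(0.5)

    def test_no_eligible_class_errors(self):
        counts = ConfusionCounts(per_class={200: (0, 0, 5)})
        with pytest.raises(ValueError):
            f1_macro(counts, db_taxa={100})

    def test_permutation_invariance(self, mini_tree):
        rng = random.Random(11)
        reads = [(f"r{i}", rng.choice([100, 101, 200])) for i in range(400)]
        assignments = {r: rng.choice([100, 101, 200, 0]) for r, _ in reads}
        db = {100, 101, 200}
        results = []
        for _ in range(3):
            rng.shuffle(reads)
            truth = GroundTruth(entries=dict(reads))
            cls = ReadClassification(assignments=dict(assignments))
            counts = confusion_at_rank(cls, truth, mini_tree, db_taxa=db)
            results.append((accuracy(counts), f1_macro(counts, db)))
        assert results[0] == results[1] == results[2]


class TestDetectOrganisms:
    def _classification(self, counts):
        assignments = {}
        i = 0
        for taxid, n in counts.items():
            for _ in range(n):
                assignments[f"r{i}"] = taxid
                i += 1
        return ReadClassification(assignments=assignments)

    def test_threshold_filtering(self, mini_tree):
        cls = self._classification({100: 60, 101: 12, 200: 3})
        report = detect_organisms(cls, mini_tree, thresholds=[1, 10, 50])
        assert [len(report.detected[t]) for t in (1, 10, 50)] == [3, 2, 1]

    def test_tp_fp_against_truth(self, mini_tree):
        cls = self._classification({100: 60, 101: 12, 200: 3})
        report = detect_organisms(
            cls, mini_tree, thresholds=[1, 10, 50], truth_taxa={100, 101}
        )
        assert report.tp_fp[10] == (2, 0)
        assert report.tp_fp[50] == (1, 0)
        assert report.tp_fp[1] == (2, 1)

    def test_empty_classification(self, mini_tree):
        report = detect_organisms(ReadClassification(assignments={}), mini_tree)
        assert all(len(s) == 0 for s in report.detected.values())

    def test_detected_sets_nested(self, mini_tree):
        cls = self._classification({100: 7, 101: 60, 200: 1})
        report = detect_organisms(cls, mini_tree, thresholds=[1, 10, 50])
        assert report.detected[50] <= report.detected[10] <= report.detected[1]

    # the taxonomy fixture is read-only, so reuse across examples is safe
    @settings(
        derandomize=True,
        max_examples=100,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(
        counts=st.dictionaries(
            st.sampled_from([100, 101, 150, 200]), st.integers(0, 120), max_size=4
        )
    )
    def test_monotonicity_over_random_count_tables(self, mini_tree, counts):
        """Raising the threshold never increases detections, TP, or FP."""
        cls = self._classification({t: n for t, n in counts.items() if n > 0})
        report = detect_organisms(
            cls, mini_tree, thresholds=[1, 5, 20, 80], truth_taxa={100, 200}
        )
        sizes = [len(report.detected[t]) for t in report.thresholds]
        tps = [report.tp_fp[t][0] for t in report.thresholds]
        fps = [report.tp_fp[t][1] for t in report.thresholds]
        for seq in (sizes, tps, fps):
            assert all(a >= b for a, b in zip(seq, seq[1:]))


class TestReadLengthQuartiles:
    def test_worked_quartiles(self, mini_tree):
        truth = GroundTruth(entries={f"r{i}": 100 for i in range(5)})
        cls = ReadClassification(assignments={f"r{i}": 100 for i in range(5)})
        lengths = {f"r{i}": (i + 1) * 1000 for i in range(5)}  # 1..5 kb
        q = read_length_quartiles(cls, truth, lengths, mini_tree, db_taxa={100})
        assert q.tp == (2000.0, 3000.0, 4000.0)
        assert q.fp is None

    def test_single_tp_read(self, mini_tree):
        truth = GroundTruth(entries={"r0": 100})
        cls = ReadClassification(assignments={"r0": 100})
        q = read_length_quartiles(cls, truth, {"r0": 1234}, mini_tree, db_taxa={100})
        assert q.tp == (1234.0, 1234.0, 1234.0)

    def test_fp_restricted_to_in_db_truth(self, mini_tree):
        truth = GroundTruth(entries={"r0": 100, "r1": 200})
        # both misclassified; only r0's organism is in the db
        cls = ReadClassification(assignments={"r0": 101, "r1": 101})
        lengths = {"r0": 1000, "r1": 9000}
        q = read_length_quartiles(cls, truth, lengths, mini_tree, db_taxa={100, 101})
        assert q.fp == (1000.0, 1000.0, 1000.0)

    def test_quartiles_match_numpy_oracle(self, mini_tree):
        rng = random.Random(2)
        n = 40
        truth = GroundTruth(entries={f"r{i}": 100 for i in range(n)})
        cls = ReadClassification(assignments={f"r{i}": 100 for i in range(n)})
        lengths = {f"r{i}": rng.randint(100, 50_000) for i in range(n)}
        q = read_length_quartiles(cls, truth, lengths, mini_tree, db_taxa={100})
        expected = np.percentile(list(lengths.values()), [25, 50, 75])
        assert q.tp == pytest.approx(tuple(expected))
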