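import numpy as np
import pytest

from appm.benchmark import (
    BenchmarkRecord,
    ConfusionCounts,
    ProteinLookupError,
    call_binders_by_rank,
    combine_predictions,
    compute_metrics,
    confusion_from_calls,
    false_positive_overlap,
    generate_decoys,
    length_allocation,
)


class TestLengthAllocation:
    def test_99_split(self):
        assert length_allocation(99) == {8: 25, 9: 25, 10: 25, 11: 24}

    def test_minimal_four(self):
        assert length_allocation(4) == {8: 1, 9: 1, 10: 1, 11: 1}

    def test_divisible(self):
        assert length_allocation(100) == {8: 25, 9: 25, 10: 25, 11: 25}

    def test_too_few(self):
        with pytest.raises(ValueError):
            length_allocation(3)


class TestGenerateDecoys:
    @pytest.fixture
    def single_hit_setup(self, rng):
        from appm.codec import ALPHABET

        protein = "".join(rng.choice(list(ALPHABET), size=500))
        hit = protein[100:109]
        return {"P1": protein}, [(hit, "P1")]

    def test_99_decoys_with_balanced_lengths(self, single_hit_setup):
        proteome, hits = single_hit_setup
        bset = generate_decoys(hits, proteome, set(), decoys_per_hit=99, seed=0)
        assert bset.prefilter_decoy_counts[hits[0][0]] == 99
        lengths = [r.length for r in bset.decoys]
        counts = {length: lengths.count(length) for length in (8, 9, 10, 11)}
        # duplicates within one random 500-aa protein are overwhelmingly unlikely
        assert counts == {8: 25, 9: 25, 10: 25, 11: 24}

    def test_minimal_one_per_length(self, single_hit_setup):
        proteome, hits = single_hit_setup
        bset = generate_decoys(hits, proteome, set(), decoys_per_hit=4, seed=0)
        assert sorted(r.length for r in bset.decoys) == [8, 9, 10, 11]

    def test_training_peptides_filtered(self, single_hit_setup):
        proteome, hits = single_hit_setup
        ref = generate_decoys(hits, proteome, set(), decoys_per_hit=99, seed=3)
        leak = {ref.decoys[0].peptide, ref.decoys[5].peptide}
        bset = generate_decoys(hits, proteome, leak, decoys_per_hit=99, seed=3)
        assert not leak & {r.peptide for r in bset.decoys}
        # pre-filter count is unchanged; post-filter is smaller
        assert bset.prefilter_decoy_counts[hits[0][0]] == 99
        assert len(bset.decoys) == len(ref.decoys) - 2

    def test_decoy_never_equals_a_hit(self, toy_proteome):
        proteome, hits = toy_proteome
        pairs = [(seq, pid) for seq, pid, _ in hits]
        bset = generate_decoys(pairs, proteome, set(), decoys_per_hit=20, seed=1)
        hit_seqs = {seq for seq, _, _ in hits}
        assert not hit_seqs & {r.peptide for r in bset.decoys}

    def test_no_duplicate_sequences_in_set(self, toy_proteome):
        proteome, hits = toy_proteome
        pairs = [(seq, pid) for seq, pid, _ in hits]
        bset = generate_decoys(pairs, proteome, set(), decoys_per_hit=40, seed=2)
        seqs = [r.peptide for r in bset.records]
        assert len(seqs) == len(set(seqs))

    def test_provenance_offsets_correct(self, toy_proteome):
        proteome, hits = toy_proteome
        pairs = [(seq, pid) for seq, pid, _ in hits]
        bset = generate_decoys(pairs, proteome, set(), decoys_per_hit=8, seed=4)
        for r in bset.records:
            protein = proteome[r.source_protein]
            assert protein[r.offset:r.offset + r.length] == r.peptide

    def test_missing_protein(self):
        with pytest.raises(ProteinLookupError):
            generate_decoys([("SIINFEKLV", "NOPE")], {"P1": "A" * 50}, set())

    def test_deterministic(self, single_hit_setup):
        proteome, hits = single_hit_setup
        a = generate_decoys(hits, proteome, set(), seed=11)
        b = generate_decoys(hits, proteome, set(), seed=11)
        assert [r.peptide for r in a.records] == [r.peptide for r in b.records]

    def test_short_protein_warns_and_restricts(self, caplog):
        proteome = {"P1": "ACDEFGHIKL"}  # 10 aa: no 11-mers exist
        with caplog.at_level("WARNING"):
            bset = generate_decoys([("ACDEFGHIK", "P1")], proteome, set(), decoys_per_hit=8)
        assert all(r.length <= 10 for r in bset.decoys)
        assert any("shorter" in r.message or "only" in r.message for r in caplog.records)


class TestComputeMetrics:
    def test_printed_formulas(self):
        m = compute_metrics(ConfusionCounts(tp=40, fp=60, tn=9840, fn=60))
        assert m.sensitivity == pytest.approx(0.40)
        assert m.specificity == pytest.approx(9840 / 9900)
        assert m.ppv == pytest.approx(0.40)

    def test_undefined_ppv(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=100, fn=0))
        assert m.ppv is None
        assert m.sensitivity is None
        assert m.specificity == pytest.approx(1.0)

    def test_metric_identities(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 100, size=4))
            m = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert m.sensitivity + fn / (tp + fn) == pytest.approx(1.0)
            assert m.specificity + fp / (tn + fp) == pytest.approx(1.0)

    def test_brute_force_recount_oracle(self, rng):
        # 200-record toy benchmark scored by an arbitrary seeded predictor
        from appm.codec import ALPHABET

        records = []
        for i in range(200):
            seq = "".join(rng.choice(list(ALPHABET), size=9))
            records.append(BenchmarkRecord(seq + str(i), int(rng.random() < 0.3), "P", -1, 9))
        calls = {r.peptide for r in records if rng.random() < 0.4}
        counts = confusion_from_calls(records, calls)
        # independent brute-force recount of per-record correctness
        tp = sum(1 for r in records if r.label == 1 and r.peptide in calls)
        fn = sum(1 for r in records if r.label == 1 and r.peptide not in calls)
        fp = sum(1 for r in records if r.label == 0 and r.peptide in calls)
        tn = sum(1 for r in records if r.label == 0 and r.peptide not in calls)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (tp, fp, tn, fn)
        m = compute_metrics(counts)
        assert m.sensitivity == pytest.approx(tp / (tp + fn))
        assert m.specificity == pytest.approx(tn / (tn + fp))
        assert m.ppv == pytest.approx(tp / (tp + fp))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestCallBindersByRank:
    def test_arithmetic_grid(self):
        table = {f"p{i}": i / 10 for i in range(1, 1001)}  # ranks 0.1 .. 100.0
        binders = call_binders_by_rank(table, threshold_percent=2.0)
        assert len(binders) == 20

    def test_threshold_100_takes_all(self):
        table = {"a": 50.0, "b": 99.9, "c": 100.0}
        assert call_binders_by_rank(table, 100.0) == {"a", "b", "c"}

    def test_empty_table(self):
        assert call_binders_by_rank({}) == set()

    def test_rank_out_of_range(self):
        with pytest.raises(ValueError):
            call_binders_by_rank({"a": 0.0})
        with pytest.raises(ValueError):
            call_binders_by_rank({"a": 101.0})


class TestCombine:
    def test_intersection(self):
        assert combine_predictions({"p1", "p2", "p3"}, {"p2", "p3", "p4"}) == {"p2", "p3"}

    def test_empty_b(self):
        assert combine_predictions({"p1"}, set()) == set()

    def test_subset_and_monotone(self, rng):
        universe = [f"x{i}" for i in range(50)]
        a = {u for u in universe if rng.random() < 0.5}
        b = {u for u in universe if rng.random() < 0.5}
        c = combine_predictions(a, b)
        assert c <= a and c <= b
        assert len(c) <= min(len(a), len(b))
        assert combine_predictions(a | {"extra"}, b) >= c

    def test_combined_ppv_improves_on_constructed_benchmark(self):
        # both predictors share TPs but have mostly disjoint FPs
        records = [BenchmarkRecord(f"t{i}", 1, "P", -1, 9) for i in range(10)]
        records += [BenchmarkRecord(f"d{i}", 0, "P", -1, 9) for i in range(100)]
        tps = {f"t{i}" for i in range(8)}
        calls_a = tps | {f"d{i}" for i in range(0, 12)}
        calls_b = tps | {f"d{i}" for i in range(10, 22)}
        ppv = lambda calls: compute_metrics(confusion_from_calls(records, calls)).ppv
        combined = combine_predictions(calls_a, calls_b)
        assert ppv(combined) >= max(ppv(calls_a), ppv(calls_b))


class TestFalsePositiveOverlap:
    def test_jaccard(self):
        assert false_positive_overlap({1, 2, 3, 4}, {3, 4, 5, 6}) == pytest.approx(2 / 6)

    def test_identical(self):
        assert false_positive_overlap({1, 2}, {1, 2}) == 1.0

    def test_disjoint(self):
        assert false_positive_overlap({1}, {2}) == 0.0

    def test_both_empty_undefined(self):
        assert false_positive_overlap(set(), set()) is None

    def test_min_method(self):
        assert false_positive_overlap({1, 2, 3, 4}, {3, 4}, method="min") == 1.0


def test_oracle_predictor_perfect_metrics(toy_proteome):
    proteome, hits = toy_proteome
    pairs = [(seq, pid) for seq, pid, _ in hits]
    bset = generate_decoys(pairs, proteome, set(), decoys_per_hit=20, seed=0)
    oracle_calls = {r.peptide for r in bset.records if r.label == 1}
    m = compute_metrics(confusion_from_calls(bset.records, oracle_calls))
    assert m.sensitivity == 1.0 and m.specificity == 1.0 and m.ppv == 1.0
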