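import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ytriage import seqstats
from ytriage._seq import mutate, random_seq
from ytriage.io_formats import Contig


class TestAssemblyMetrics:
    def test_hand_enumerated_n50(self):
        # descending 6,5,4,3,2: cumulative 6,11 >= 10 at the 5-length contig
        stats = seqstats.assembly_metrics([2, 3, 4, 5, 6])
        assert (stats.total_bases, stats.n50, stats.l50) == (20, 5, 2)

    def test_single_contig(self):
        stats = seqstats.assembly_metrics([7])
        assert (stats.n50, stats.l50, stats.mean_length) == (7, 1, 7)

    def test_mean_from_printed_totals(self):
        assert seqstats.mean_contig_length(20_060_146, 652) == 30_767

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            seqstats.assembly_metrics([])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=1, max_value=10**6), min_size=1, max_size=60), st.randoms())
    def test_permutation_invariance(self, lengths, rnd):
        shuffled = list(lengths)
        rnd.shuffle(shuffled)
        assert seqstats.assembly_metrics(lengths) == seqstats.assembly_metrics(shuffled)

    def test_invariants(self):
        stats = seqstats.assembly_metrics([10, 20, 30, 40])
        assert stats.smallest <= stats.mean_length <= stats.largest
        assert stats.smallest <= stats.n50 <= stats.largest
        assert stats.l50 <= stats.contig_count


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("GGCC", 1.0), ("ACGT", 0.5), ("ACGN", 2 / 3)])
    def test_values(self, seq, expected):
        assert seqstats.gc_content(seq) == pytest.approx(expected)

    def test_all_n_missing(self):
        assert seqstats.gc_content("NNNN") is None


class TestSimpleRepeats:
    def test_dinucleotide_array_detected(self, rng):
        seq = random_seq(rng, 2000) + "AC" * 20 + random_seq(rng, 2000)
        arrays = [a for a in seqstats.find_simple_repeats(seq) if a.end - a.start >= 30]
        assert len(arrays) == 1
        a = arrays[0]
        # maximal run: may extend a base or two into chance-matching flanks
        assert 40 <= a.end - a.start <= 44
        assert a.unit in ("AC", "CA")
        assert abs(a.start - 2000) <= 2 and abs(a.end - 2040) <= 2

    def test_below_copy_threshold_not_reported(self, rng):
        seq = random_seq(rng, 500) + "ACG" * 4 + random_seq(rng, 500)
        arrays = seqstats.find_simple_repeats(seq)
        assert not any(490 < a.start < 530 for a in arrays)

    def test_interrupted_array_fully_masked(self, rng):
        # a TT insert interrupts the array; whether reported as one merged
        # call or two pure calls, the array is (almost) fully masked
        array = "AC" * 12 + "TT" + "AC" * 12
        seq = random_seq(rng, 1000) + array + random_seq(rng, 1000)
        arrays = seqstats.find_simple_repeats(seq)
        covered = sum(
            max(0, min(a.end, 1000 + len(array)) - max(a.start, 1000)) for a in arrays
        )
        assert covered >= len(array) - 4


class TestAnnotateRepeats:
    def test_planted_line_fraction(self, rng):
        consensus = random_seq(rng, 3000)
        contig = Contig("c", random_seq(rng, 3500) + mutate(consensus, 0.1, rng) + random_seq(rng, 3500))
        ann = seqstats.annotate_repeats(contig, [("L1", "LINE", consensus)])
        assert ann.class_fractions["LINE"] == pytest.approx(0.30, abs=0.02)
        assert ann.total_repetitive >= ann.class_fractions["LINE"]

    def test_empty_library_zero_interspersed(self, rng):
        contig = Contig("c", random_seq(rng, 20_000))
        ann = seqstats.annotate_repeats(contig, [])
        assert ann.class_fractions["LINE"] == 0.0
        assert ann.class_fractions["LTR"] == 0.0

    def test_unknown_class_rejected(self, rng):
        contig = Contig("c", random_seq(rng, 5000))
        with pytest.raises(ValueError, match="unknown class"):
            seqstats.annotate_repeats(contig, [("x", "DNA", random_seq(rng, 300))])

    def test_union_never_exceeds_contig(self, small_fixture):
        for contig in small_fixture.y_contigs[:4]:
            ann = seqstats.annotate_repeats(contig, small_fixture.repeat_library)
            assert 0.0 <= ann.total_repetitive <= 1.0
            assert ann.total_repetitive <= sum(ann.class_fractions.values()) + 1e-9

    def test_line_dominates_msy_contigs(self, paper_fixture):
        # the fixture emulates a LINE-dominated repeat landscape: LINE is the
        # largest interspersed class fraction on every MSY contig
        msy_names = [n for n, _ in paper_fixture.spec.msy_contigs]
        for name in msy_names:
            ann = seqstats.annotate_repeats(paper_fixture.contig(name), paper_fixture.repeat_library)
            line = ann.class_fractions["LINE"]
            assert line > ann.class_fractions["SINE"]
            assert line > ann.class_fractions["LTR"]
            assert line > ann.class_fractions["SIMPLE"]

    def test_planted_microsatellite_fraction(self, paper_fixture):
        msy_names = [n for n, _ in paper_fixture.spec.msy_contigs]
        detected = total = 0
        for name in msy_names:
            contig = paper_fixture.contig(name)
            detected += sum(a.end - a.start for a in seqstats.find_simple_repeats(contig))
            total += contig.length
        assert 100 * detected / total == pytest.approx(1.0, abs=0.2)


class TestFeatureReport:
    def test_weighted_mean_hand_example(self):
        df = pd.DataFrame(
            {
                "contig": ["a", "b"],
                "size_bp": [1000, 3000],
                "gc_pct": [40.0, 30.0],
                "line_pct": [0, 0],
                "sine_pct": [0, 0],
                "simple_pct": [0, 0],
                "ltr_pct": [0, 0],
                "total_repetitive_pct": [0, 0],
            }
        )
        summary = seqstats.summarize_features(df)
        assert summary["gc_pct"] == pytest.approx(32.5)
        assert summary["size_bp"] == 4000

    def test_single_contig_summary_equals_row(self, rng):
        contig = Contig("only", random_seq(rng, 5000))
        table = seqstats.feature_report([contig], {"only": seqstats.annotate_repeats(contig, [])})
        row, summary = table.iloc[0], table.iloc[1]
        for col in seqstats.PERCENT_COLUMNS:
            assert summary[col] == pytest.approx(row[col])

    def test_summary_between_min_and_max(self, small_fixture):
        contigs = small_fixture.y_contigs[:4]
        annotations = {c.id: seqstats.annotate_repeats(c, small_fixture.repeat_library) for c in contigs}
        table = seqstats.feature_report(contigs, annotations)
        body = table[table["contig"] != seqstats.SUMMARY_ROW]
        summary = table[table["contig"] == seqstats.SUMMARY_ROW].iloc[0]
        for col in seqstats.PERCENT_COLUMNS:
            assert body[col].min() - 1e-9 <= summary[col] <= body[col].max() + 1e-9

    def test_rows_sorted_by_size(self, small_fixture):
        contigs = small_fixture.y_contigs[:4]
        annotations = {c.id: seqstats.annotate_repeats(c, []) for c in contigs}
        table = seqstats.feature_report(contigs, annotations)
        sizes = table[table["contig"] != seqstats.SUMMARY_ROW]["size_bp"].tolist()
        assert sizes == sorted(sizes, reverse=True)
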