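import numpy as np
import pytest

from ytriage import synthetic_data as sd, triage
from ytriage._seq import mutate, random_seq, revcomp
from ytriage.homology import build_index, local_hits, AlignParams
from ytriage.io_formats import Contig, PrimerPair, ReferenceScaffold


@pytest.fixture(scope="module")
def reference(request):
    rng = np.random.default_rng(7)
    return [
        ReferenceScaffold("X1", random_seq(rng, 60_000), "X"),
        ReferenceScaffold("A1", random_seq(rng, 40_000), "AUTOSOME"),
    ], rng


@pytest.fixture(scope="module")
def ref_index(reference):
    scaffolds, _ = reference
    return build_index(scaffolds, k=15)


def _classify(contig, ref_index, params=None):
    params = params or triage.TriageParams()
    hits = local_hits(contig, ref_index, AlignParams(min_hit_length=100))
    return triage.classify_contig(contig, hits, params, ref_index.classes)


class TestClassification:
    def test_short_contig_skips_homology(self, ref_index, reference):
        scaffolds, _ = reference
        contig = Contig("short", scaffolds[0].sequence[:5000])  # would be PAR by homology
        label = _classify(contig, ref_index)
        assert label.label == "TOO_SHORT"

    def test_x_homologous_contig_is_par_candidate(self, ref_index, reference):
        scaffolds, rng = reference
        contig = Contig("p", mutate(scaffolds[0].sequence[10_000:25_000], 0.01, rng))
        label = _classify(contig, ref_index)
        assert label.label == "PAR_CANDIDATE"
        assert label.identity == pytest.approx(0.99, abs=0.005)

    def test_autosomal_contig_is_contaminant(self, ref_index, reference):
        scaffolds, rng = reference
        contig = Contig("a", mutate(scaffolds[1].sequence[5_000:20_000], 0.03, rng))
        assert _classify(contig, ref_index).label == "AUTOSOMAL_CONTAMINANT"

    def test_coverage_gate_failure_is_msy(self, ref_index, reference):
        # 20% X-derived at high identity: identity passes, coverage does not
        scaffolds, rng = reference
        piece = mutate(scaffolds[0].sequence[30_000:32_000], 0.01, rng)
        contig = Contig("m", piece + random_seq(rng, 8_000))
        label = _classify(contig, ref_index)
        assert label.label == "PUTATIVE_MSY"
        assert not label.near_threshold

    def test_sub_gate_identity_flagged_near_threshold(self, ref_index, reference):
        scaffolds, rng = reference
        contig = Contig("n", mutate(scaffolds[1].sequence[20_000:32_000], 0.06, rng))
        label = _classify(contig, ref_index)
        assert label.label == "PUTATIVE_MSY"
        assert label.near_threshold

    def test_random_contig_is_msy(self, ref_index):
        rng = np.random.default_rng(99)
        label = _classify(Contig("r", random_seq(rng, 12_000)), ref_index)
        assert label.label == "PUTATIVE_MSY" and label.coverage == 0.0

    def test_missing_class_annotation_rejected(self, ref_index, reference):
        scaffolds, rng = reference
        contig = Contig("p", scaffolds[0].sequence[:12_000])
        hits = local_hits(contig, ref_index, AlignParams(min_hit_length=100))
        with pytest.raises(ValueError, match="scaffold-class"):
            triage.classify_contig(contig, hits, triage.TriageParams(), {})


class TestAssemblyTriage:
    def test_empty_assembly(self, ref_index):
        report = triage.triage_assembly([], ref_index)
        assert report.total_bases == 0 and report.counts == {}

    def test_bases_partition_exactly(self, small_fixture):
        index = build_index(small_fixture.female_reference)
        report = triage.triage_assembly(small_fixture.y_contigs, index)
        assert sum(report.bases.values()) == report.total_bases
        assert report.total_bases == sum(c.length for c in small_fixture.y_contigs)

    def test_planted_labels_recovered(self, small_fixture):
        index = build_index(small_fixture.female_reference)
        report = triage.triage_assembly(small_fixture.y_contigs, index)
        expected = {
            "PAR": "PAR_CANDIDATE",
            "MSY": "PUTATIVE_MSY",
            "CONTAMINANT": "AUTOSOMAL_CONTAMINANT",
            "JUNK": "TOO_SHORT",
        }
        truth = {
            row.contig: expected[row.name]
            for row in small_fixture.manifest_rows("contig").itertuples()
            if row.name in expected
        }
        truth[small_fixture.spec.boundary_contig[0]] = "PAR_CANDIDATE"
        got = {lab.contig_id: lab.label for lab in report.labels}
        assert got == truth

    def test_determinism(self, small_fixture):
        index = build_index(small_fixture.female_reference)
        a = triage.triage_assembly(small_fixture.y_contigs, index)
        b = triage.triage_assembly(small_fixture.y_contigs, index)
        assert a == b


class TestInSilicoPcr:
    def _genome(self, rng, inserts):
        parts, coords, pos = [], [], 0
        for name, seq in inserts:
            spacer = random_seq(rng, 2000)
            parts.append(spacer + seq)
            coords.append(pos + 2000)
            pos += 2000 + len(seq)
        return Contig("g", "".join(parts) + random_seq(rng, 1000)), coords

    def test_exact_product(self, rng):
        target = random_seq(rng, 400)
        genome, (start,) = self._genome(rng, [("t", target)])
        pair = PrimerPair("p", target[:20], revcomp(target[-20:]))
        call = triage.in_silico_pcr(pair, [genome])
        assert call.products == ((genome.id, start, start + 400, 400),)

    def test_mismatch_budget(self, rng):
        target = random_seq(rng, 400)
        genome, _ = self._genome(rng, [("t", target)])
        fwd = list(target[:20])
        for i in (2, 5, 8):  # 3 mismatches, away from the 3' end
            fwd[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[fwd[i]]
        pair = PrimerPair("p", "".join(fwd), revcomp(target[-20:]))
        assert triage.in_silico_pcr(pair, [genome]).products == ()
        params = triage.PcrParams(max_mismatch=3)
        assert len(triage.in_silico_pcr(pair, [genome], params).products) == 1

    def test_three_prime_mismatch_rejected(self, rng):
        target = random_seq(rng, 400)
        genome, _ = self._genome(rng, [("t", target)])
        fwd = list(target[:20])
        fwd[-1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[fwd[-1]]
        pair = PrimerPair("p", "".join(fwd), revcomp(target[-20:]))
        assert triage.in_silico_pcr(pair, [genome]).products == ()

    def test_size_window(self, rng):
        target = random_seq(rng, 3000)
        genome, _ = self._genome(rng, [("t", target)])
        pair = PrimerPair("p", target[:20], revcomp(target[-20:]))
        assert triage.in_silico_pcr(pair, [genome]).products == ()  # 3000 > max_size
        params = triage.PcrParams(max_size=5000)
        assert len(triage.in_silico_pcr(pair, [genome], params).products) == 1


class TestMaleSpecificity:
    def test_patterns(self, rng):
        site = random_seq(rng, 300)
        pair = PrimerPair("p", site[:20], revcomp(site[-20:]))
        male = [Contig("m", random_seq(rng, 1000) + site + random_seq(rng, 1000))]
        female = [Contig("f", random_seq(rng, 1000) + site + random_seq(rng, 500))]
        empty = [Contig("e", random_seq(rng, 2000))]
        assert triage.male_specificity(pair, male, empty) == "MALE_SPECIFIC"
        assert triage.male_specificity(pair, male, female) == "BOTH"
        assert triage.male_specificity(pair, empty, empty) == "NONE"
        ladder = [Contig("l", "".join(random_seq(rng, 500) + site for _ in range(5)))]
        assert triage.male_specificity(pair, ladder, empty) == "AMBIGUOUS"

    def test_fixture_primers(self, small_fixture):
        statuses = {
            p.name: triage.male_specificity(p, small_fixture.y_contigs, small_fixture.female_reference)
            for p in small_fixture.primers
        }
        assert statuses["PAR_control"] == "BOTH"
        msy = [s for name, s in statuses.items() if name.endswith("_msy")]
        assert "MALE_SPECIFIC" in msy
        assert all(s in ("MALE_SPECIFIC", "AMBIGUOUS") for s in msy)
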