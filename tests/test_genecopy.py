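import numpy as np
import pytest

from _oracles import brute_orfs
from ytriage import genecopy, synthetic_data as sd
from ytriage._seq import mutate, random_seq, revcomp
from ytriage.homology import SeedIndex
from ytriage.io_formats import Contig, write_gene_models_gff3


def _truncated(gene, contig, q_interval, coverage):
    return genecopy.GeneModel(
        gene=gene,
        contig_id=contig,
        exons=((0, q_interval[1] - q_interval[0]),),
        orientation="direct",
        status="TRUNCATED",
        covered_transcript_fraction=coverage,
        matched_bases=int((q_interval[1] - q_interval[0]) * 0.99),
        transcript_interval=q_interval,
        mean_identity=0.99,
    )


class TestOrfs:
    def test_coding_sequence_single_maximal_orf(self, rng):
        # ATG + 239 sense codons + stop: 723 bases encode a 240-residue ORF
        seq = sd._coding_sequence(rng, 723)
        orfs = genecopy.find_orfs(("t", seq), min_aa=100)
        complete = [o for o in orfs if not o.partial and o.strand == "+"]
        assert complete[0].aa_length == 240
        assert complete[0].end - complete[0].start == 3 * (240 + 1) == 723

    def test_minimal_orf_and_threshold(self):
        orfs = genecopy.find_orfs(("t", "ATGTAA"), min_aa=1)
        assert orfs[0].aa_length == 1
        assert genecopy.find_orfs(("t", "ATGTAA"), min_aa=100) == []

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 10_000)
        ours = {
            (o.strand, o.frame, o.start, o.end, o.aa_length, o.partial)
            for o in genecopy.find_orfs(("t", seq), min_aa=25)
        }
        assert ours == brute_orfs(seq, min_aa=25)

    def test_sorted_longest_first(self, rng):
        seq = random_seq(rng, 8000)
        lengths = [o.aa_length for o in genecopy.find_orfs(("t", seq), min_aa=10)]
        assert lengths == sorted(lengths, reverse=True)


class TestStatusRules:
    def _plant(self, rng, transcript_piece, contig_length=12_000):
        background = random_seq(rng, contig_length)
        mid = contig_length // 2
        seq = background[:mid] + transcript_piece + background[mid:]
        return Contig("host", seq)

    def test_fragment_rule_boundary(self, rng):
        transcript = Contig("g", random_seq(rng, 1500))
        for size, expected in ((199, "FRAGMENT"), (260, "TRUNCATED")):
            host = self._plant(rng, transcript.sequence[:size])
            models = genecopy.detect_copies("g", transcript, [host])
            assert [m.status for m in models] == [expected], size

    def test_full_copy(self, rng):
        transcript = Contig("g", random_seq(rng, 1200))
        host = self._plant(rng, mutate(transcript.sequence, 0.01, rng))
        (model,) = genecopy.detect_copies("g", transcript, [host])
        assert model.status == "FULL"
        assert model.covered_transcript_fraction >= 0.95

    def test_transcript_too_short_rejected(self, rng):
        with pytest.raises(ValueError, match="100"):
            genecopy.detect_copies("g", Contig("g", "ACGT" * 20), [Contig("c", random_seq(rng, 1000))])

    def test_no_hits_empty_result(self, rng):
        transcript = Contig("g", random_seq(rng, 1000))
        assert genecopy.detect_copies("g", transcript, [Contig("c", random_seq(rng, 5000))]) == []


class TestSplitGenes:
    def test_complementary_truncated_models_merge(self):
        a = _truncated("UTY", "tigA", (0, 2500), 0.56)
        b = _truncated("UTY", "tigB", (2500, 4480), 0.44)
        (call,) = genecopy.detect_split_genes([a, b])
        assert call.contigs == ("tigA", "tigB")
        summary = genecopy.copy_summary([a, b], [call])
        assert summary.total_copies == 1 and summary.split_calls == 1

    def test_overlapping_exon_sets_not_merged(self):
        # both copies start at exon 1: overlap, so they stay two copies
        a = _truncated("G", "tigA", (0, 2000), 0.45)
        b = _truncated("G", "tigB", (0, 1800), 0.40)
        assert genecopy.detect_split_genes([a, b]) == []
        assert genecopy.copy_summary([a, b]).total_copies == 2

    def test_single_full_model_no_flag(self, rng):
        transcript = Contig("g", random_seq(rng, 1200))
        host = Contig("c", random_seq(rng, 3000) + transcript.sequence + random_seq(rng, 3000))
        models = genecopy.detect_copies("g", transcript, [host])
        assert genecopy.detect_split_genes(models) == []

    def test_same_contig_not_merged(self):
        a = _truncated("G", "tigA", (0, 2000), 0.45)
        b = _truncated("G", "tigA", (2100, 4400), 0.50)
        assert genecopy.detect_split_genes([a, b]) == []


class TestOrientation:
    def test_revcomp_flips_orientation_and_preserves_counts(self, rng):
        exons = [random_seq(rng, 250) for _ in range(3)]
        introns = [random_seq(rng, 350) for _ in range(2)]
        gene = exons[0] + introns[0] + exons[1] + introns[1] + exons[2]
        contig = Contig("c", random_seq(rng, 2000) + gene + random_seq(rng, 2000))
        flipped = Contig("c", revcomp(contig.sequence))
        transcript = Contig("g", "".join(exons))
        (fwd,) = genecopy.detect_copies("g", transcript, [contig])
        (rev,) = genecopy.detect_copies("g", transcript, [flipped])
        assert fwd.orientation == "direct" and rev.orientation == "inverted"
        assert fwd.exon_count == rev.exon_count == 3
        # exon order along the contig reverses; transcript order is preserved
        assert [s for s, _ in rev.exons] == sorted((s for s, _ in rev.exons), reverse=True)


class TestPaperArchitecture:
    def test_ampliconic_gene_copy_layout(self, paper_fixture, paper_gene_models):
        models, _, summary = paper_gene_models["HSFY"]
        assert summary.total_copies == 26
        tig1 = summary.orientation_counts("ytig1")
        assert tig1[("direct", "FULL")] == 15 and tig1[("inverted", "FULL")] == 1
        assert summary.orientation_counts("ytig223")[("direct", "FULL")] == 9
        assert sum(summary.orientation_counts("ytigPAB").values()) == 1

    def test_seven_exon_gene_with_truncated_inverted_copy(self, paper_gene_models, tmp_path, paper_fixture):
        models, _, summary = paper_gene_models["EIF1AY"]
        assert summary.total_copies == 2
        full = next(m for m in models if m.status == "FULL")
        truncated = next(m for m in models if m.status == "TRUNCATED")
        assert full.exon_count == 7 and full.orientation == "direct"
        assert truncated.exon_count == 4 and truncated.orientation == "inverted"
        # the full copy serializes as seven exon rows
        path = tmp_path / "eif1ay.gff3"
        write_gene_models_gff3([full], path, {c.id: c.length for c in paper_fixture.y_contigs})
        assert sum("\texon\t" in line for line in path.read_text().splitlines()) == 7

    def test_split_single_copy_gene(self, paper_gene_models):
        models, splits, summary = paper_gene_models["UTY"]
        assert len(splits) == 1
        assert set(splits[0].contigs) == {"ytig467", "ytig723"}
        assert summary.total_copies == 1

    def test_fragments_counted_separately(self, paper_gene_models):
        _, _, rbmy = paper_gene_models["RBMY"]
        assert rbmy.total_copies == 3 and rbmy.fragments == 2
        _, _, tspy = paper_gene_models["TSPY"]
        assert tspy.total_copies == 3

    def test_cross_species_transcript_locates_gene_only(self, paper_gene_models):
        models, _, summary = paper_gene_models["AMELY"]
        assert summary.total_copies == 0
        assert summary.located == 1
        assert models[0].contig_id == "ytig3291"

    def test_orientation_calls_match_planted_strand(self, paper_fixture, paper_gene_models):
        for gene in ("HSFY", "EIF1AY", "RBMY", "TSPY"):
            planted = paper_fixture.manifest_rows("gene_copy", name=gene)
            planted = planted[planted["status"].isin(["full", "truncated"])]
            models, _, _ = paper_gene_models[gene]
            detected = sorted((m.contig_id, m.contig_span[0] // 100, m.orientation) for m in models if m.status != "FRAGMENT")
            truth = sorted((r.contig, r.start // 100, r.orientation) for r in planted.itertuples())
            assert [(c, o) for c, _, o in detected] == [(c, o) for c, _, o in truth]
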