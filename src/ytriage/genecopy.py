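"""Gene copy detection, gene models, split-gene calls and ORF finding.

A gene model is one genomic copy of a gene, built from a spliced
transcript-to-contig alignment chain.  Copies are individuated by contig
footprint: chains overlapping an already-accepted copy by >=20% of the
shorter footprint are collapsed onto the higher-coverage chain, so
tandem arrays count copy by copy while redundant chains do not.

Completeness statuses:

FULL
    the chain covers (>=95% of) the reference transcript, i.e. every exon
    is represented near its reference length.
TRUNCATED
    a partial copy (a subset of exons) with >=200 matched bases.
FRAGMENT
    total matched homology below 200 bases — incompletely assembled
    copies or pseudogene relics; excluded from copy totals.
LOCATED
    cross-species mode only: homology places the gene on a contig but no
    chain is solid enough to resolve its exon-intron structure.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._seq import revcomp
from .homology import SeedIndex, SplicedAlignment, SplicedParams, spliced_align_index
from .io_formats import Contig

FRAGMENT_MAX_BASES = 200   # matched homology below this is a fragment
FULL_COVERAGE = 0.95       # transcript fraction required for FULL


@dataclass(frozen=True)
class GeneParams:
    k: int = 15
    min_exon_identity: float = 0.8
    min_exon_length: int = 30
    max_intron: int = 10_000
    max_footprint_overlap: float = 0.2
    cross_species: bool = False   # relaxed identity, LOCATED fallback
    cross_species_identity: float = 0.75

    def spliced(self) -> SplicedParams:
        if self.cross_species:
            # deep divergence thins exact seeds; shorten them
            return SplicedParams(
                k=min(self.k, 11),
                min_exon_identity=self.cross_species_identity,
                min_exon_length=self.min_exon_length,
                max_intron=self.max_intron,
            )
        return SplicedParams(
            k=self.k,
            min_exon_identity=self.min_exon_identity,
            min_exon_length=self.min_exon_length,
            max_intron=self.max_intron,
        )


@dataclass(frozen=True)
class GeneModel:
    gene: str
    contig_id: str
    exons: tuple[tuple[int, int], ...]   # contig intervals, transcript order
    orientation: str                     # 'direct' | 'inverted'
    status: str                          # FULL | TRUNCATED | FRAGMENT | LOCATED
    covered_transcript_fraction: float
    matched_bases: int
    transcript_interval: tuple[int, int]
    mean_identity: float

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def contig_span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))


@dataclass(frozen=True)
class SplitCall:
    """One gene reconstructed from complementary truncated copies on two contigs."""

    gene: str
    contigs: tuple[str, ...]
    members: tuple[GeneModel, ...]


@dataclass(frozen=True)
class CopySummary:
    gene: str
    total_copies: int            # FULL + TRUNCATED; split pairs count once
    fragments: int
    located: int
    split_calls: int
    per_contig: dict

    def orientation_counts(self, contig_id: str) -> Counter:
        return self.per_contig.get(contig_id, Counter())


def _model_from_alignment(gene: str, aln: SplicedAlignment, params: GeneParams) -> GeneModel:
    exons = tuple((b.contig_start, b.contig_end) for b in aln.exon_blocks)
    weak = (
        aln.matched_bases < FRAGMENT_MAX_BASES
        or aln.mean_identity < params.min_exon_identity
    )
    if params.cross_species and weak:
        # homology strong enough to place the gene but too weak to resolve
        # its exon-intron structure (cross-species transcript mapping)
        status = "LOCATED"
    elif aln.matched_bases < FRAGMENT_MAX_BASES:
        status = "FRAGMENT"
    elif aln.covered_transcript_fraction >= FULL_COVERAGE:
        status = "FULL"
    else:
        status = "TRUNCATED"
    return GeneModel(
        gene=gene,
        contig_id=aln.contig_id,
        exons=exons,
        orientation=aln.orientation,
        status=status,
        covered_transcript_fraction=aln.covered_transcript_fraction,
        matched_bases=aln.matched_bases,
        transcript_interval=(
            min(b.transcript_start for b in aln.exon_blocks),
            max(b.transcript_end for b in aln.exon_blocks),
        ),
        mean_identity=aln.mean_identity,
    )


def _overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return inter / min(a[1] - a[0], b[1] - b[0])


def detect_copies(
    gene: str,
    transcript: Contig,
    contigs: Sequence[Contig] | SeedIndex,
    params: GeneParams | None = None,
) -> list[GeneModel]:
    """Detect all genomic copies of a gene from its representative transcript.

    Each spliced-alignment chain becomes one model; overlapping chains on a
    locus are resolved to the higher-coverage chain.
    """
    params = params or GeneParams()
    if transcript.length < 100:
        raise ValueError(f"transcript {transcript.id} shorter than 100 bases")
    index = contigs if isinstance(contigs, SeedIndex) else SeedIndex(contigs, k=params.k)
    alignments = spliced_align_index(transcript, index, params.spliced())
    models: list[GeneModel] = []
    # alignments arrive sorted by matched bases descending
    for aln in alignments:
        model = _model_from_alignment(gene, aln, params)
        redundant = any(
            kept.contig_id == model.contig_id
            and _overlap_fraction(kept.contig_span, model.contig_span)
            >= params.max_footprint_overlap
            for kept in models
        )
        if not redundant:
            models.append(model)
    models.sort(key=lambda m: (m.contig_id, m.contig_span))
    return models


def detect_split_genes(
    models: Sequence[GeneModel],
    min_combined_coverage: float = 0.9,
    max_transcript_overlap: int = 30,
) -> list[SplitCall]:
    """Find genes split across contigs.

    Two TRUNCATED models on different contigs whose transcript intervals do
    not overlap (beyond a small tolerance) and together cover the transcript
    are merged into one SPLIT single-copy call.  Overlapping exon sets (e.g.
    two copies that both start at exon 1) are left as independent copies.
    """
    truncated = [m for m in models if m.status == "TRUNCATED"]
    calls = []
    used: set[int] = set()
    for i in range(len(truncated)):
        for j in range(i + 1, len(truncated)):
            if i in used or j in used:
                continue
            a, b = truncated[i], truncated[j]
            if a.contig_id == b.contig_id:
                continue
            overlap = min(a.transcript_interval[1], b.transcript_interval[1]) - max(
                a.transcript_interval[0], b.transcript_interval[0]
            )
            if overlap > max_transcript_overlap:
                continue
            combined = a.covered_transcript_fraction + b.covered_transcript_fraction
            if combined < min_combined_coverage:
                continue
            first, second = sorted((a, b), key=lambda m: m.transcript_interval)
            calls.append(
                SplitCall(
                    gene=a.gene,
                    contigs=(first.contig_id, second.contig_id),
                    members=(first, second),
                )
            )
            used.update({i, j})
    return calls


def copy_summary(models: Sequence[GeneModel], splits: Sequence[SplitCall] = ()) -> CopySummary:
    """Copy accounting for one gene: totals exclude fragments, split pairs count once."""
    genes = {m.gene for m in models}
    if len(genes) > 1:
        raise ValueError(f"models from multiple genes: {sorted(genes)}")
    gene = genes.pop() if genes else ""
    per_contig: dict[str, Counter] = {}
    for m in models:
        per_contig.setdefault(m.contig_id, Counter())[(m.orientation, m.status)] += 1
    countable = sum(1 for m in models if m.status in ("FULL", "TRUNCATED"))
    merged_away = sum(len(s.members) - 1 for s in splits)
    return CopySummary(
        gene=gene,
        total_copies=countable - merged_away,
        fragments=sum(1 for m in models if m.status == "FRAGMENT"),
        located=sum(1 for m in models if m.status == "LOCATED"),
        split_calls=len(splits),
        per_contig=per_contig,
    )


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class Orf:
    transcript_id: str
    strand: str
    frame: int
    start: int       # forward-transcript coordinates, 0-based half-open
    end: int
    aa_length: int   # residues, stop excluded; ATG counts as one residue
    partial: bool    # no in-frame stop before the sequence end


def find_orfs(transcript: Contig | tuple[str, str], min_aa: int = 100, include_partial: bool = True) -> list[Orf]:
    """Six-frame ORF scan, longest first.

    An ORF runs from the first ATG after the previous in-frame stop to the
    next stop (one maximal ORF per stop, so nested ATGs do not spawn
    sub-ORFs).  ORFs reaching the sequence end without a stop are reported
    as partial.  With a stop, end - start == 3 * (aa_length + 1).
    """
    if isinstance(transcript, tuple):
        tid, seq = transcript
    else:
        tid, seq = transcript.id, transcript.sequence
    n = len(seq)
    orfs = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            start = None
            for pos in range(frame, n - 2, 3):
                codon = s[pos : pos + 3]
                if codon in STOP_CODONS:
                    if start is not None:
                        aa = (pos - start) // 3
                        orfs.append((strand, frame, start, pos + 3, aa, False))
                        start = None
                elif codon == "ATG" and start is None:
                    start = pos
            if start is not None and include_partial:
                end = start + 3 * ((n - start) // 3)
                orfs.append((strand, frame, start, end, (end - start) // 3, True))
    out = []
    for strand, frame, start, end, aa, partial in orfs:
        if aa < min_aa:
            continue
        if strand == "-":
            start, end = n - end, n - start
        out.append(Orf(tid, strand, frame, start, end, aa, partial))
    out.sort(key=lambda o: (-o.aa_length, o.strand, o.frame, o.start))
    return out
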