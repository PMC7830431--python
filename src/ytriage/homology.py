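"""Seeded local-alignment engine: identity/coverage hits and spliced alignments.

The engine is deliberately simple: exact k-mer seeds on both strands,
diagonal-band chaining, ungapped x-drop extension, and identity scoring
with mismatches in the denominator (N never matches).  It targets
substitution-dominated homology — diverged copies of a common source —
which is the regime of flow-sorted chromosome triage, repeat masking and
transcript-to-contig mapping in this package.  It does not model
alignment statistics (no E-values): acceptance is gated on percent
identity over a minimum aligned length instead.

Seeds are chained per (target, strand) diagonal band with a tolerated
drift of ``band_width`` bases; equal-score hits are ordered by
(target id, target start) for determinism.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import N_CODE, encode, kmer_codes, match_mask, revcomp
from .io_formats import Contig


@dataclass(frozen=True)
class AlignParams:
    """Tunables for :func:`local_hits`.

    min_seed_chain is the minimum number of seeds per chain; xdrop is the
    ungapped extension drop-off (match +1, mismatch -2); max_seed_gap splits
    chains whose consecutive seeds are further apart than this on the query.
    """

    min_identity: float = 0.0
    min_hit_length: int = 50
    min_seed_chain: int = 1
    xdrop: int = 20
    band_width: int = 30
    max_seed_gap: int = 1000


@dataclass(frozen=True)
class HomologyHit:
    """A local alignment between a query and one reference scaffold."""

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str  # '-' means the query aligns to the reverse complement of the target
    identity: float
    aligned_length: int
    score: float

    @property
    def query_interval(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)

    @property
    def target_interval(self) -> tuple[int, int]:
        return (self.target_start, self.target_end)


class SeedIndex:
    """Sorted k-mer position index over a set of reference sequences.

    Seeds containing N are excluded.  Scaffolds are concatenated with k-1 N
    spacers so no seed spans a boundary.
    """

    def __init__(self, reference: Iterable, k: int = 15):
        if not 2 <= k <= 31:
            raise ValueError(f"k must be in [2, 31], got {k}")
        self.k = k
        self.ids: list[str] = []
        self.lengths: list[int] = []
        self.classes: dict[str, str] = {}
        chunks = []
        offsets = []
        offset = 0
        spacer = np.full(k - 1, N_CODE, dtype=np.uint8)
        for item in reference:
            if isinstance(item, tuple):
                sid, seq = item
            else:
                sid, seq = item.id, item.sequence
                cls = getattr(item, "scaffold_class", None)
                if cls is not None:
                    self.classes[sid] = cls
            enc = encode(seq)
            self.ids.append(sid)
            self.lengths.append(len(enc))
            offsets.append(offset)
            chunks.append(enc)
            chunks.append(spacer)
            offset += len(enc) + len(spacer)
        if not self.ids:
            raise ValueError("empty reference")
        if k > max(self.lengths):
            raise ValueError(f"k={k} exceeds every scaffold length")
        self.enc = np.concatenate(chunks)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        codes, valid = kmer_codes(self.enc, k)
        pos = np.nonzero(valid)[0].astype(np.int64)
        codes = codes[valid]
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order]

    # -- retrieval ---------------------------------------------------------

    def scaffold_of(self, gpos: np.ndarray) -> np.ndarray:
        """Scaffold index for each global position."""
        return np.searchsorted(self.offsets, gpos, side="right") - 1

    def occurrences(self, kmer: str) -> list[tuple[str, int, str]]:
        """All (scaffold id, local position, strand) occurrences of a seed.

        The minus-strand occurrences are those of the reverse complement on
        the forward strand; a palindromic seed therefore reports both
        strands at the same locus.
        """
        if len(kmer) != self.k:
            raise ValueError(f"seed length {len(kmer)} != k={self.k}")
        out = []
        for strand, probe in (("+", kmer), ("-", revcomp(kmer))):
            code, valid = kmer_codes(encode(probe), self.k)
            if not valid[0]:
                continue
            lo = np.searchsorted(self._codes, code[0], side="left")
            hi = np.searchsorted(self._codes, code[0], side="right")
            for gpos in self._pos[lo:hi]:
                scaff = int(self.scaffold_of(np.asarray([gpos]))[0])
                out.append((self.ids[scaff], int(gpos - self.offsets[scaff]), strand))
        return sorted(out)

    def match_positions(self, qenc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(query positions, global target positions) of all exact seed matches."""
        codes, valid = kmer_codes(qenc, self.k)
        qpos = np.nonzero(valid)[0]
        codes = codes[valid]
        lo = np.searchsorted(self._codes, codes, side="left")
        hi = np.searchsorted(self._codes, codes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qrep = np.repeat(qpos, counts)
        starts = np.repeat(np.cumsum(counts) - counts, counts)
        take = np.repeat(lo, counts) + (np.arange(total) - starts)
        return qrep.astype(np.int64), self._pos[take]


def build_index(reference: Iterable, k: int = 15) -> SeedIndex:
    """Build a two-strand-retrievable seed index (see :class:`SeedIndex`)."""
    return SeedIndex(reference, k=k)


def _extend(qenc, tenc, qlo, qhi, diag, tmin, tmax, xdrop):
    """Ungapped x-drop extension of [qlo, qhi) along a fixed diagonal."""
    # rightwards
    score, best, best_q = 0, 0, qhi
    q = qhi
    while q < len(qenc) and q + diag < tmax:
        score += 1 if (qenc[q] == tenc[q + diag] and qenc[q] != N_CODE) else -2
        q += 1
        if score > best:
            best, best_q = score, q
        elif best - score > xdrop:
            break
    qhi = best_q
    # leftwards
    score, best, best_q = 0, 0, qlo
    q = qlo - 1
    while q >= 0 and q + diag >= tmin:
        score += 1 if (qenc[q] == tenc[q + diag] and qenc[q] != N_CODE) else -2
        if score > best:
            best, best_q = score, q
        elif best - score > xdrop:
            break
        q -= 1
    return best_q, qhi


def _hits_one_strand(query_id, qenc, index: SeedIndex, params: AlignParams, strand, qlen):
    qpos, tpos = index.match_positions(qenc)
    if len(qpos) == 0:
        return []
    diag = tpos - qpos
    order = np.lexsort((qpos, diag))
    d, q, t = diag[order], qpos[order], tpos[order]
    scaff = index.scaffold_of(t)
    breaks = np.nonzero(
        (np.diff(d) > params.band_width)
        | (np.abs(np.diff(q)) > params.max_seed_gap)
        | (np.diff(scaff) != 0)
    )[0] + 1
    bounds = np.concatenate(([0], breaks, [len(d)]))
    hits = []
    k = index.k
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo < params.min_seed_chain:
            continue
        sidx = int(scaff[lo])
        toff = int(index.offsets[sidx])
        tmin, tmax = toff, toff + index.lengths[sidx]
        cdiag = int(np.median(d[lo:hi]))
        qlo = int(q[lo:hi].min())
        qhi = int(q[lo:hi].max()) + k
        # clip to scaffold bounds on the chain diagonal
        qlo = max(qlo, tmin - cdiag, 0)
        qhi = min(qhi, tmax - cdiag, len(qenc))
        if qhi <= qlo:
            continue
        qlo, qhi = _extend(qenc, index.enc, qlo, qhi, cdiag, tmin, tmax, params.xdrop)
        aligned = qhi - qlo
        if aligned < params.min_hit_length:
            continue
        matches = int(match_mask(qenc[qlo:qhi], index.enc[qlo + cdiag : qhi + cdiag]).sum())
        identity = matches / aligned
        if identity < params.min_identity:
            continue
        score = float(matches - 2 * (aligned - matches))
        ts = qlo + cdiag - toff
        te = qhi + cdiag - toff
        if strand == "+":
            qs, qe = qlo, qhi
        else:  # hit coordinates were computed on the reverse-complemented query
            qs, qe = qlen - qhi, qlen - qlo
        hits.append(
            HomologyHit(
                query_id=query_id,
                target_id=index.ids[sidx],
                query_start=qs,
                query_end=qe,
                target_start=ts,
                target_end=te,
                strand=strand,
                identity=identity,
                aligned_length=aligned,
                score=score,
            )
        )
    return hits


def local_hits(query: Contig | tuple[str, str] | str, index: SeedIndex, params: AlignParams | None = None) -> list[HomologyHit]:
    """All chained local hits of a query against the index, best score first."""
    params = params or AlignParams()
    if isinstance(query, str):
        query_id, seq = "query", query
    elif isinstance(query, tuple):
        query_id, seq = query
    else:
        query_id, seq = query.id, query.sequence
    if len(seq) < index.k:
        return []
    hits = _hits_one_strand(query_id, encode(seq), index, params, "+", len(seq))
    hits += _hits_one_strand(query_id, encode(revcomp(seq)), index, params, "-", len(seq))
    hits.sort(key=lambda h: (-h.score, h.target_id, h.target_start))
    return hits


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def query_coverage(
    hits: Sequence[HomologyHit],
    query_length: int,
    target_class: str | None = None,
    scaffold_classes: Mapping[str, str] | None = None,
) -> tuple[float, float | None]:
    """Union coverage of the query by hits (optionally restricted to one
    scaffold class) and the alignment-length-weighted mean identity."""
    if query_length <= 0:
        raise ValueError("query_length must be positive")
    if target_class is not None:
        if scaffold_classes is None:
            raise ValueError("target_class given without scaffold_classes")
        selected = []
        for h in hits:
            if h.target_id not in scaffold_classes:
                raise ValueError(f"scaffold {h.target_id} has no class annotation")
            if scaffold_classes[h.target_id] == target_class:
                selected.append(h)
        hits = selected
    if not hits:
        return 0.0, None
    covered = sum(e - s for s, e in merge_intervals(h.query_interval for h in hits))
    weight = sum(h.aligned_length for h in hits)
    mean_identity = sum(h.identity * h.aligned_length for h in hits) / weight
    return covered / query_length, mean_identity


# ---------------------------------------------------------------------------
# Spliced transcript-to-contig alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplicedParams:
    k: int = 15
    min_exon_identity: float = 0.8
    min_exon_length: int = 30
    max_intron: int = 10_000
    min_intron: int = 40          # contig gaps below this merge into one exon block
    max_block_overlap: int = 40   # tolerated overlap between chained blocks
                                  # (x-drop extension can overrun an exon end
                                  # by chance matches, bounded well below this)
    # linear intron cost: keeps tandem copies pairing exons with their own
    # copy (the cost over an inter-copy distance exceeds per-copy identity
    # noise) while staying far below any exon's match score
    intron_penalty_per_base: float = 5e-3


@dataclass(frozen=True)
class ExonBlock:
    transcript_start: int
    transcript_end: int
    contig_start: int
    contig_end: int
    identity: float


@dataclass(frozen=True)
class SplicedAlignment:
    """One chained (possibly partial) genomic copy of a transcript."""

    transcript_id: str
    contig_id: str
    exon_blocks: tuple[ExonBlock, ...]  # transcript order
    orientation: str                    # 'direct' | 'inverted'
    covered_transcript_fraction: float
    matched_bases: int
    mean_identity: float

    @property
    def contig_span(self) -> tuple[int, int]:
        return (
            min(b.contig_start for b in self.exon_blocks),
            max(b.contig_end for b in self.exon_blocks),
        )


def _chain_group(hits: list[HomologyHit], strand: str, params: SplicedParams) -> list[list[HomologyHit]]:
    """Extract colinear chains from one (target, strand) hit group.

    Repeated best-chain extraction: a dynamic programme over hits sorted by
    transcript start maximizes matched bases with a small penalty on contig
    gaps (so tandem copies pair exons with their own copy), then the winning
    chain's hits are removed and the programme repeats.
    """
    hits = sorted(hits, key=lambda h: (h.query_start, h.query_end))
    chains = []
    remaining = list(hits)
    while remaining:
        n = len(remaining)
        score = [h.identity * h.aligned_length for h in remaining]
        parent = [-1] * n
        for j in range(n):
            hj = remaining[j]
            base = hj.identity * hj.aligned_length
            for i in range(j):
                hi = remaining[i]
                if hj.query_start < hi.query_end - params.max_block_overlap:
                    continue
                if strand == "+":
                    gap = hj.target_start - hi.target_end
                else:
                    gap = hi.target_start - hj.target_end
                if gap < -params.max_block_overlap or gap > params.max_intron:
                    continue
                cand = score[i] + base - params.intron_penalty_per_base * max(gap, 0)
                if cand > score[j]:
                    score[j] = cand
                    parent[j] = i
        best = int(np.argmax(score))
        chain_idx = []
        node = best
        while node != -1:
            chain_idx.append(node)
            node = parent[node]
        chain_idx.reverse()
        chains.append([remaining[i] for i in chain_idx])
        used = set(chain_idx)
        remaining = [h for i, h in enumerate(remaining) if i not in used]
    return chains


def _blocks_from_chain(chain: list[HomologyHit], params: SplicedParams) -> list[ExonBlock]:
    blocks: list[list] = []
    for h in chain:
        if blocks:
            prev = blocks[-1]
            qgap = h.query_start - prev[1]
            tgap = h.target_start - prev[3] if h.strand == "+" else prev[2] - h.target_end
            if 0 <= qgap <= params.max_block_overlap and abs(tgap) < params.min_intron:
                # same exon, chain split by a mismatch cluster: merge
                prev[1] = max(prev[1], h.query_end)
                prev[2] = min(prev[2], h.target_start)
                prev[3] = max(prev[3], h.target_end)
                prev[4] += h.identity * h.aligned_length
                prev[5] += h.aligned_length
                continue
        blocks.append(
            [h.query_start, h.query_end, h.target_start, h.target_end,
             h.identity * h.aligned_length, h.aligned_length]
        )
    return [
        ExonBlock(qs, qe, ts, te, weighted / length)
        for qs, qe, ts, te, weighted, length in blocks
    ]


def spliced_align_index(transcript: Contig, index: SeedIndex, params: SplicedParams | None = None) -> list[SplicedAlignment]:
    """Spliced alignments of one transcript against all indexed contigs."""
    params = params or SplicedParams()
    if transcript.length < params.min_exon_length:
        raise ValueError(
            f"transcript {transcript.id} shorter than min_exon_length={params.min_exon_length}"
        )
    hit_params = AlignParams(
        min_identity=params.min_exon_identity,
        min_hit_length=params.min_exon_length,
        max_seed_gap=max(params.min_intron, 200),
    )
    hits = local_hits(transcript, index, hit_params)
    groups: dict[tuple[str, str], list[HomologyHit]] = {}
    for h in hits:
        groups.setdefault((h.target_id, h.strand), []).append(h)
    alignments = []
    for (target_id, strand), group in sorted(groups.items()):
        for chain in _chain_group(group, strand, params):
            blocks = _blocks_from_chain(chain, params)
            covered = sum(b.transcript_end - b.transcript_start for b in blocks)
            total = sum(
                b.identity * (b.transcript_end - b.transcript_start) for b in blocks
            )
            alignments.append(
                SplicedAlignment(
                    transcript_id=transcript.id,
                    contig_id=target_id,
                    exon_blocks=tuple(blocks),
                    orientation="direct" if strand == "+" else "inverted",
                    covered_transcript_fraction=min(covered / transcript.length, 1.0),
                    matched_bases=int(round(total)),
                    mean_identity=total / covered if covered else 0.0,
                )
            )
    alignments.sort(key=lambda a: (-a.matched_bases, a.contig_id, a.contig_span))
    return alignments


def spliced_align(transcript: Contig, contig: Contig, params: SplicedParams | None = None) -> list[SplicedAlignment]:
    """Spliced alignments of a transcript against a single contig."""
    params = params or SplicedParams()
    return spliced_align_index(transcript, SeedIndex([contig], k=params.k), params)


def hits_to_table(hits: Sequence[HomologyHit]):
    """Hit list as a blast-tabular-like DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "query": [h.query_id for h in hits],
            "target": [h.target_id for h in hits],
            "identity": [h.identity for h in hits],
            "length": [h.aligned_length for h in hits],
            "q_start": [h.query_start for h in hits],
            "q_end": [h.query_end for h in hits],
            "t_start": [h.target_start for h in hits],
            "t_end": [h.target_end for h in hits],
            "strand": [h.strand for h in hits],
            "score": [h.score for h in hits],
        }
    )
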