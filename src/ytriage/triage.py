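"""Contig triage: length filter, homology-gated classification, in-silico PCR.

Classification of a flow-sorted chromosome assembly against a female
reference:

* contigs shorter than the length threshold (default: the mean long-read
  length, 8,034 bases) are set aside before any homology evaluation;
* significant similarity means >=95% identity over >=25% of the contig
  length (union coverage of homology hits);
* autosomal/unplaced similarity wins over X similarity (contamination is
  removed before X-homology assignment); X similarity marks a PAR
  candidate; contigs with no significant similarity to the female
  reference are putatively MSY.

Male specificity of a primer pair is assessed by in-silico PCR against
the male contig set and the female reference: amplification only in the
male is evidence of Y origin; more than three products in the male is a
ladder-like pattern and is flagged ambiguous.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import encode, revcomp
from .homology import AlignParams, HomologyHit, SeedIndex, build_index, local_hits, query_coverage
from .io_formats import Contig, PrimerPair, ReferenceScaffold

logger = logging.getLogger(__name__)

LABELS = ("TOO_SHORT", "AUTOSOMAL_CONTAMINANT", "PAR_CANDIDATE", "PUTATIVE_MSY")
NEAR_THRESHOLD_MARGIN = 0.02


@dataclass(frozen=True)
class TriageParams:
    min_identity: float = 0.95
    min_coverage: float = 0.25
    length_threshold: int = 8034
    k: int = 15

    def __post_init__(self):
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")


@dataclass(frozen=True)
class TriageLabel:
    contig_id: str
    label: str
    best_class: str | None = None
    coverage: float = 0.0
    identity: float | None = None
    near_threshold: bool = False


@dataclass(frozen=True)
class TriageReport:
    labels: tuple[TriageLabel, ...]
    counts: dict
    bases: dict
    total_bases: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": label, "contigs": self.counts.get(label, 0), "bases": self.bases.get(label, 0)}
            for label in LABELS
        ]
        rows.append({"class": "TOTAL", "contigs": sum(self.counts.values()), "bases": self.total_bases})
        return pd.DataFrame(rows)


def classify_contig(
    contig: Contig,
    hits: Sequence[HomologyHit],
    params: TriageParams,
    scaffold_classes: Mapping[str, str],
) -> TriageLabel:
    """Assign one triage label from precomputed hits against the female reference."""
    if contig.length < params.length_threshold:
        return TriageLabel(contig.id, "TOO_SHORT")
    for h in hits:
        if h.target_id not in scaffold_classes:
            raise ValueError(f"hit target {h.target_id} has no scaffold-class annotation")

    def class_stats(*classes: str) -> tuple[float, float | None]:
        selected = [h for h in hits if scaffold_classes[h.target_id] in classes]
        return query_coverage(selected, contig.length)

    # identity gate applies per hit: only hits at or above the gate count
    gated = [h for h in hits if h.identity >= params.min_identity]
    auto_cov, auto_ident = query_coverage(
        [h for h in gated if scaffold_classes[h.target_id] in ("AUTOSOME", "UNPLACED")],
        contig.length,
    )
    x_cov, x_ident = query_coverage(
        [h for h in gated if scaffold_classes[h.target_id] == "X"], contig.length
    )
    if auto_cov >= params.min_coverage:
        return TriageLabel(contig.id, "AUTOSOMAL_CONTAMINANT", "AUTOSOME", auto_cov, auto_ident)
    if x_cov >= params.min_coverage:
        return TriageLabel(contig.id, "PAR_CANDIDATE", "X", x_cov, x_ident)
    # no class passes: record the best near-miss evidence
    near = False
    best_class, best_cov, best_ident = None, 0.0, None
    for cls_name, classes in (("AUTOSOME", ("AUTOSOME", "UNPLACED")), ("X", ("X",))):
        cov, ident = class_stats(*classes)
        if cov > best_cov:
            best_class, best_cov, best_ident = cls_name, cov, ident
        if (
            ident is not None
            and cov >= params.min_coverage
            and abs(ident - params.min_identity) <= NEAR_THRESHOLD_MARGIN
        ):
            near = True
    return TriageLabel(contig.id, "PUTATIVE_MSY", best_class, best_cov, best_ident, near)


def triage_assembly(
    contigs: Sequence[Contig],
    reference: Sequence[ReferenceScaffold] | SeedIndex,
    params: TriageParams | None = None,
) -> TriageReport:
    """Label every contig; report per-class counts and cumulative bases.

    The per-class base totals partition the input exactly.
    """
    params = params or TriageParams()
    if not contigs:
        return TriageReport((), {}, {}, 0)
    index = reference if isinstance(reference, SeedIndex) else build_index(reference, k=params.k)
    scaffold_classes = index.classes
    align_params = AlignParams(min_identity=0.0, min_hit_length=100)
    labels = []
    for contig in contigs:
        if contig.length < params.length_threshold:
            labels.append(TriageLabel(contig.id, "TOO_SHORT"))
            continue
        hits = local_hits(contig, index, align_params)
        labels.append(classify_contig(contig, hits, params, scaffold_classes))
    counts: dict[str, int] = {}
    bases: dict[str, int] = {}
    lengths = {c.id: c.length for c in contigs}
    for lab in labels:
        counts[lab.label] = counts.get(lab.label, 0) + 1
        bases[lab.label] = bases.get(lab.label, 0) + lengths[lab.contig_id]
    return TriageReport(tuple(labels), counts, bases, sum(lengths.values()))


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PcrParams:
    max_mismatch: int = 2
    three_prime_exact: int = 3
    min_size: int = 50
    max_size: int = 2000


@dataclass(frozen=True)
class AmpliconCall:
    primer_name: str
    genome_id: str
    products: tuple[tuple[str, int, int, int], ...]  # (contig, start, end, size)


def _site_positions(enc: np.ndarray, primer: str, params: PcrParams, three_prime: str) -> np.ndarray:
    """Start positions where the primer anneals on the forward strand.

    ``three_prime`` is 'right' when the primer's 3' end is at the site's
    high coordinate (plus-strand primer) and 'left' for a reverse-complement
    site.  The 3'-terminal bases must match exactly.
    """
    p = encode(primer)
    m = len(p)
    n = len(enc) - m + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    mismatches = np.zeros(n, dtype=np.int32)
    exact_zone = (
        range(m - params.three_prime_exact, m)
        if three_prime == "right"
        else range(params.three_prime_exact)
    )
    exact_ok = np.ones(n, dtype=bool)
    for j in range(m):
        mis = ~((enc[j : j + n] == p[j]) & (p[j] != 4))
        mismatches += mis
        if j in exact_zone:
            exact_ok &= ~mis
    return np.nonzero((mismatches <= params.max_mismatch) & exact_ok)[0]


def in_silico_pcr(
    primer_pair: PrimerPair,
    genome: Sequence[Contig],
    params: PcrParams | None = None,
    genome_id: str = "genome",
) -> AmpliconCall:
    """Predict amplicons: convergent primer sites within the size window.

    Both primer orientations are searched (forward primer priming either
    strand), sites match with at most ``max_mismatch`` substitutions and no
    mismatch in the 3'-terminal ``three_prime_exact`` bases.
    """
    params = params or PcrParams()
    products = []
    for contig in genome:
        enc = encode(contig.sequence)
        for left, right in (
            (primer_pair.forward, primer_pair.reverse),
            (primer_pair.reverse, primer_pair.forward),
        ):
            fwd_sites = _site_positions(enc, left, params, "right")
            rev_sites = _site_positions(enc, revcomp(right), params, "left")
            if len(fwd_sites) == 0 or len(rev_sites) == 0:
                continue
            rev_ends = rev_sites + len(right)
            for f in fwd_sites:
                lo = np.searchsorted(rev_ends, f + params.min_size, side="left")
                hi = np.searchsorted(rev_ends, f + params.max_size, side="right")
                for e in rev_ends[lo:hi]:
                    products.append((contig.id, int(f), int(e), int(e - f)))
    # de-duplicate products found in both primer orderings (palindromic cases)
    products = sorted(set(products))
    return AmpliconCall(primer_pair.name, genome_id, tuple(products))


LADDER_THRESHOLD = 3  # more male products than this looks ladder-like


def male_specificity(
    primer_pair: PrimerPair,
    male_genome: Sequence[Contig],
    female_genome: Sequence[Contig],
    params: PcrParams | None = None,
) -> str:
    """MALE_SPECIFIC, BOTH, NONE, or AMBIGUOUS (ladder-like male pattern)."""
    male = in_silico_pcr(primer_pair, male_genome, params, "male").products
    female = in_silico_pcr(primer_pair, female_genome, params, "female").products
    if len(male) > LADDER_THRESHOLD:
        return "AMBIGUOUS"
    if male and not female:
        return "MALE_SPECIFIC"
    if male and female:
        return "BOTH"
    if female:
        return "BOTH" if male else "NONE"
    return "NONE"
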