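"""Pseudoautosomal boundary (PAB) detection and PAR contig ordering.

A boundary-spanning contig shows X homology along a prefix (the PAR,
which still recombines with the X) and none along the remainder (the
male-specific side).  The boundary is found in two stages: a windowed
X-coverage profile is split at the changepoint maximizing the
two-segment mean separation, then refined to base precision by
re-aligning the transition region and taking the rightmost X-homologous
base.  A call is only made when the left segment is well covered
(mean >= 0.5) and the right is nearly empty (mean <= 0.1).

PAR contigs are linearly ordered against a template X sequence (e.g. a
better-assembled related species' X) by their best-hit placement.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import AlignParams, SeedIndex, local_hits, query_coverage
from .io_formats import Contig

PROFILE_COLUMNS = ("start", "end", "covered_fraction", "identity")


@dataclass(frozen=True)
class PabParams:
    window: int = 10_000
    step: int = 2_000
    min_flank_windows: int = 5
    min_left_coverage: float = 0.5
    max_right_coverage: float = 0.1
    min_refine_identity: float = 0.9


@dataclass(frozen=True)
class PabCall:
    contig_id: str
    boundary: int                 # 1-based coordinate of the last PAR base
    par_side_identity: float
    msy_side_identity: float | None
    window: int


@dataclass(frozen=True)
class ParMapPlacement:
    contig_id: str
    template_id: str | None
    start: int | None
    end: int | None
    orientation: str | None
    identity: float | None
    placed: bool


def homology_profile(
    contig: Contig,
    x_index: SeedIndex,
    window: int = 10_000,
    step: int = 2_000,
    align_params: AlignParams | None = None,
) -> pd.DataFrame:
    """Per-window (covered_fraction, identity) of a contig against the X.

    A contig shorter than the window yields a single whole-contig window.
    """
    if window < 1000:
        raise ValueError("window must be >= 1000")
    if step > window:
        raise ValueError("step must be <= window")
    align_params = align_params or AlignParams(min_hit_length=100)
    length = contig.length
    if length <= window:
        starts = [0]
        window = length
    else:
        n = int(np.ceil((length - window) / step)) + 1
        starts = [min(i * step, length - window) for i in range(n)]
    rows = []
    for start in starts:
        piece = contig.sequence[start : start + window]
        hits = local_hits((contig.id, piece), x_index, align_params)
        covered, identity = query_coverage(hits, len(piece))
        rows.append(
            {
                "start": start,
                "end": start + window,
                "covered_fraction": covered,
                "identity": np.nan if identity is None else identity,
            }
        )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def detect_boundary(
    profile: pd.DataFrame,
    params: PabParams | None = None,
    contig: Contig | None = None,
    x_index: SeedIndex | None = None,
) -> PabCall | None:
    """Changepoint split of an X-coverage profile into PAR and MSY segments.

    Returns None when no split reaches the left/right coverage gates (a
    uniformly covered contig has no male-specific side).  When the contig
    and X index are provided, the window-precision changepoint is refined
    to base precision by re-aligning the transition region.
    """
    params = params or PabParams()
    cov = profile["covered_fraction"].to_numpy(dtype=float)
    n = len(cov)
    # short profiles get a proportionally smaller guard flank
    flank = max(1, min(params.min_flank_windows, n // 4))
    if n < 2 * flank + 1:
        return None
    best_b, best_sep = None, -np.inf
    for b in range(flank, n - flank + 1):
        left, right = cov[:b].mean(), cov[b:].mean()
        sep = left - right
        if sep > best_sep:
            best_sep, best_b = sep, b
    left_mean = cov[:best_b].mean()
    right_mean = cov[best_b:].mean()
    if left_mean < params.min_left_coverage or right_mean > params.max_right_coverage:
        return None
    window = int(profile["end"].iloc[0] - profile["start"].iloc[0])
    # coarse boundary: end of the last left-segment window
    coarse = int(profile["end"].iloc[best_b - 1])
    identities = profile["identity"].to_numpy(dtype=float)[:best_b]
    weights = cov[:best_b]
    ok = ~np.isnan(identities)
    par_identity = float(np.average(identities[ok], weights=weights[ok])) if ok.any() else float("nan")
    boundary = coarse
    if contig is not None and x_index is not None:
        boundary = _refine_boundary(contig, x_index, profile, best_b, params) or coarse
    boundary = min(boundary, contig.length - 1 if contig is not None else boundary)
    return PabCall(
        contig_id=str(profile.attrs.get("contig_id", contig.id if contig else "contig")),
        boundary=int(boundary),
        par_side_identity=par_identity,
        msy_side_identity=None,
        window=window,
    )


def _refine_boundary(contig, x_index, profile, best_b, params: PabParams) -> int | None:
    """Rightmost X-homologous base within the transition region (1-based)."""
    lo = int(profile["start"].iloc[max(best_b - 2, 0)])
    hi = int(profile["end"].iloc[min(best_b + 1, len(profile) - 1)])
    piece = contig.sequence[lo:hi]
    hits = local_hits((contig.id, piece), x_index, AlignParams(min_hit_length=100))
    ends = [h.query_end for h in hits if h.identity >= params.min_refine_identity]
    if not ends:
        return None
    return lo + max(ends)  # 0-based exclusive end == 1-based last aligned base


def find_boundary(contig: Contig, x_index: SeedIndex, params: PabParams | None = None) -> PabCall | None:
    """Profile + changepoint + base refinement in one call."""
    params = params or PabParams()
    profile = homology_profile(contig, x_index, params.window, params.step)
    profile.attrs["contig_id"] = contig.id
    return detect_boundary(profile, params, contig=contig, x_index=x_index)


def gametolog_divergence(
    x_copy: Contig | str,
    y_copy: Contig | str,
    min_hit_length: int = 100,
    k: int = 15,
) -> float | None:
    """Identity of the best chained alignment between X and Y gene copies.

    None when no alignment above the engine floor exists (non-homologous).
    Both sequences must be at least 200 bases.
    """
    x_seq = x_copy if isinstance(x_copy, str) else x_copy.sequence
    y_seq = y_copy if isinstance(y_copy, str) else y_copy.sequence
    if len(x_seq) < 200 or len(y_seq) < 200:
        raise ValueError("gametolog divergence needs sequences of >= 200 bases")
    index = SeedIndex([("x_copy", x_seq)], k=k)
    hits = local_hits(("y_copy", y_seq), index, AlignParams(min_hit_length=min_hit_length))
    if not hits:
        return None
    _, identity = query_coverage(hits, len(y_seq))
    return identity


def order_par_contigs(
    par_contigs: Sequence[Contig],
    template_index: SeedIndex,
    align_params: AlignParams | None = None,
) -> list[ParMapPlacement]:
    """Place PAR contigs on a template X map, sorted by template position.

    Each contig lands at its best-hit interval; overlapping placements are
    resolved to the higher identity and the loser is flagged unplaced.
    """
    align_params = align_params or AlignParams(min_hit_length=200)
    provisional = []
    for contig in par_contigs:
        hits = local_hits(contig, template_index, align_params)
        if not hits:
            provisional.append(ParMapPlacement(contig.id, None, None, None, None, None, False))
            continue
        best = hits[0]
        # extend the placement to the union of same-strand hits on the best target
        same = [h for h in hits if h.target_id == best.target_id and h.strand == best.strand]
        start = min(h.target_start for h in same)
        end = max(h.target_end for h in same)
        _, identity = query_coverage(same, contig.length)
        provisional.append(
            ParMapPlacement(
                contig.id,
                best.target_id,
                start,
                end,
                "direct" if best.strand == "+" else "inverted",
                identity,
                True,
            )
        )
    placed = sorted(
        (p for p in provisional if p.placed),
        key=lambda p: -(p.identity or 0.0),
    )
    accepted: list[ParMapPlacement] = []
    for cand in placed:
        clash = any(
            a.template_id == cand.template_id and cand.start < a.end and a.start < cand.end
            for a in accepted
        )
        if clash:
            accepted.append(
                ParMapPlacement(cand.contig_id, None, None, None, None, cand.identity, False)
            )
        else:
            accepted.append(cand)
    unplaced = [p for p in provisional if not p.placed]
    result = accepted + unplaced
    result.sort(key=lambda p: (not p.placed, p.start if p.start is not None else 0, p.contig_id))
    return result


def par_coverage(placed_bases: float, template_par_bases: float) -> dict:
    """Assembled-PAR coverage of the estimated PAR span.

    Reports the raw fraction, the one-decimal percentage and the
    round-half-up integer percentage side by side, because printed figures
    in the literature often round the span estimate before dividing.
    """
    if template_par_bases <= 0:
        raise ValueError("template PAR span must be positive")
    fraction = placed_bases / template_par_bases
    percent = 100 * fraction
    return {
        "fraction": fraction,
        "percent_one_decimal": round(percent, 1),
        "percent_integer": int(np.floor(percent + 0.5)),
    }
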