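"""Deterministic generator of a complete fixture study.

Emulates the inputs of a flow-sorted Y-chromosome project: a female
reference (X scaffolds + autosomes), the Y contig set (PAR contigs
diverged from the X, MSY contigs with planted multi-exon gene copies in
both orientations, autosomal contaminants, sub-threshold junk and a
boundary-spanning contig), spliced transcripts, a repeat-consensus
library, PCR primers, and a qPCR Ct table.  Every planted feature is
recorded with exact coordinates in a ground-truth manifest.

Divergence is simulated with substitutions only (uniform positions,
uniform alternative base, exact count = round(rate x length)) so planted
coordinates and identities stay exact; background sequence is i.i.d.
uniform A/C/G/T, which keeps spurious cross-identity far below the
triage gates.  The ``paper`` preset plants the full emulated study
architecture: a 26-copy two-exon ampliconic gene laid out 15 direct + 1
inverted / 9 direct / 1 on the boundary contig, a 7-exon gene with an
additional inverted copy truncated to exons 1-4, a 28-exon single-copy
gene split between two contigs (exons 1-16 / 17-28), and a
307,557-base boundary contig whose first 177,307 bases are X-derived at
99.1% identity.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import mutate, random_seq, revcomp
from .io_formats import (
    Contig,
    PrimerPair,
    ReferenceScaffold,
    write_ct_table,
    write_fasta,
    write_primers,
    write_reference,
    write_repeat_library,
)

LENGTH_THRESHOLD_DEFAULT = 8034  # mean long-read length of the emulated study

STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# Plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneCopyPlan:
    contig: str
    orientation: str = "direct"        # direct | inverted
    status: str = "full"               # full | truncated | fragment | located
    exons: tuple[int, ...] | None = None   # 1-based exon indices for truncated copies
    fragment_length: int = 150
    # 'located' copies: only a short conserved core of each exon is planted
    # (what deep cross-species homology looks like), at its own divergence
    segment_length: int = 60
    segment_divergence: float = 0.08


@dataclass(frozen=True)
class GenePlan:
    name: str
    exon_lengths: tuple[int, ...]
    intron_range: tuple[int, int] = (200, 2000)
    copy_divergence: float = 0.01
    copies: tuple[GeneCopyPlan, ...] = ()
    coding: bool = False               # transcript = ATG + sense codons + stop
    transcript_divergence: float = 0.0  # extra divergence of the *transcript* vs
                                        # the planted copies (cross-species mode)

    @property
    def transcript_length(self) -> int:
        return sum(self.exon_lengths)


@dataclass(frozen=True)
class RepeatPlan:
    line_fraction: float = 0.10
    sine_fraction: float = 0.01
    ltr_fraction: float = 0.03
    microsat_fraction: float = 0.01
    line_length: int = 3000
    sine_length: int = 300
    ltr_length: int = 500
    copy_divergence: float = 0.10


@dataclass(frozen=True)
class CtPlan:
    reference_gene: str = "UTY"
    ratios: tuple[tuple[str, float], ...] = ()
    base_ct: float = 22.0
    sd: float = 0.15
    efficiency: float = 1.0
    n_assays: int = 2
    n_replicates: int = 3


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 42
    x_scaffolds: tuple[tuple[str, int], ...] = (("X1", 320_000), ("X2", 30_000))
    autosomes: tuple[tuple[str, int], ...] = (("A1", 60_000), ("A2", 40_000))
    # (name, length, identity to the X source interval)
    par_contigs: tuple[tuple[str, int, float], ...] = ()
    # (name, length)
    msy_contigs: tuple[tuple[str, int], ...] = ()
    # (name, length, identity to an autosome source interval)
    contaminants: tuple[tuple[str, int, float], ...] = ()
    junk_contigs: tuple[tuple[str, int], ...] = ()
    # (name, total length, X-homologous prefix length, prefix identity)
    boundary_contig: tuple[str, int, int, float] | None = None
    genes: tuple[GenePlan, ...] = ()
    repeat_plan: RepeatPlan = RepeatPlan()
    ct_plan: CtPlan = CtPlan()
    length_threshold: int = LENGTH_THRESHOLD_DEFAULT
    gametolog_divergences: tuple[tuple[str, int, float], ...] = (("SHROOM2", 1500, 0.016),)

    def validate(self) -> None:
        for name, _, identity in self.par_contigs + self.contaminants:
            if not 0.9 <= identity <= 1.0:
                raise ValueError(f"{name}: planted identity {identity} outside [0.9, 1.0]")
        if self.boundary_contig is not None:
            _, total, prefix, identity = self.boundary_contig
            if not 0.9 <= identity <= 1.0:
                raise ValueError(f"boundary identity {identity} outside [0.9, 1.0]")
            if not 0 < prefix < total:
                raise ValueError("boundary prefix must be inside the contig")
        for name, length in self.junk_contigs:
            if length >= self.length_threshold:
                raise ValueError(f"junk contig {name} not below the length threshold")
        ratios = dict(self.ct_plan.ratios)
        if ratios.get(self.ct_plan.reference_gene, 1.0) != 1.0:
            raise ValueError("the single-copy reference gene must have true ratio 1")


def paper_preset(seed: int = 42) -> FixtureSpec:
    """The full-architecture fixture study (copy layout, boundary coordinates)."""
    hsfy = GenePlan(
        "HSFY",
        exon_lengths=(500, 582),
        intron_range=(300, 900),
        copies=tuple(
            [GeneCopyPlan("ytig1") for _ in range(15)]
            + [GeneCopyPlan("ytig1", orientation="inverted")]
            + [GeneCopyPlan("ytig223") for _ in range(9)]
            + [GeneCopyPlan("ytigPAB")]
        ),
    )
    eif1ay = GenePlan(
        "EIF1AY",
        exon_lengths=(260, 200, 180, 160, 200, 200, 195),
        intron_range=(200, 700),
        copies=(
            GeneCopyPlan("ytigPAB"),
            GeneCopyPlan("ytigPAB", orientation="inverted", status="truncated", exons=(1, 2, 3, 4)),
        ),
    )
    uty = GenePlan(
        "UTY",
        exon_lengths=tuple([160] * 28),
        intron_range=(200, 500),
        copies=(
            GeneCopyPlan("ytig467", status="truncated", exons=tuple(range(1, 17))),
            GeneCopyPlan("ytig723", status="truncated", exons=tuple(range(17, 29))),
        ),
    )
    rbmy = GenePlan(
        "RBMY",
        exon_lengths=(250, 300, 280, 170),
        intron_range=(200, 800),
        copies=(
            GeneCopyPlan("ytig713"),
            GeneCopyPlan("ytig3300"),
            GeneCopyPlan("ytig3301"),
            GeneCopyPlan("ytig3300", status="fragment"),
            GeneCopyPlan("ytig3301", status="fragment"),
        ),
    )
    tspy = GenePlan(
        "TSPY",
        exon_lengths=(200, 150, 150, 150, 150, 150, 150),
        intron_range=(200, 700),
        copies=(
            GeneCopyPlan("ytig251"),
            GeneCopyPlan("ytig3300"),
            GeneCopyPlan("ytig3301"),
        ),
    )
    cul4by = GenePlan(
        "CUL4BY",
        exon_lengths=tuple([150] * 8),
        intron_range=(200, 600),
        copies=(
            GeneCopyPlan("ytig538"),
            GeneCopyPlan("ytig469", status="fragment"),
        ),
    )
    sry = GenePlan(
        "SRY",
        exon_lengths=(723,),
        coding=True,
        copies=(GeneCopyPlan("ytig3262"),),
    )
    amely = GenePlan(
        "AMELY",
        exon_lengths=(150, 120, 130),
        intron_range=(200, 500),
        copies=(GeneCopyPlan("ytig3291", status="located"),),
    )
    return FixtureSpec(
        seed=seed,
        par_contigs=(("par1", 50_000, 0.99), ("par2", 40_000, 0.985), ("par3", 30_000, 0.995)),
        msy_contigs=(
            ("ytig1", 70_000),
            ("ytig223", 40_000),
            ("ytig467", 35_000),
            ("ytig723", 25_000),
            ("ytig713", 15_000),
            ("ytig3300", 20_000),
            ("ytig3301", 20_000),
            ("ytig251", 18_000),
            ("ytig538", 15_000),
            ("ytig469", 12_000),
            ("ytig3262", 12_000),
            ("ytig3291", 15_000),
        ),
        contaminants=(("cont1", 15_000, 0.97), ("cont2", 12_000, 0.96)),
        junk_contigs=(("junk1", 3_000), ("junk2", 5_000), ("junk3", 7_000)),
        boundary_contig=("ytigPAB", 307_557, 177_307, 0.991),
        genes=(hsfy, eif1ay, uty, rbmy, tspy, cul4by, sry, amely),
        ct_plan=CtPlan(
            ratios=(
                ("UTY", 1.0),
                ("RBMY", 13.0),
                ("HSFY", 9.0),
                ("TSPY", 2.0),
                ("EIF1AY", 1.0),
                ("CUL4BY", 1.0),
            )
        ),
    )


def small_preset(seed: int = 0) -> FixtureSpec:
    """A down-scaled fixture for fast property tests (same statistical structure)."""
    genes = (
        GenePlan(
            "HSFY",
            exon_lengths=(300, 300),
            intron_range=(200, 500),
            copies=(
                GeneCopyPlan("m1"),
                GeneCopyPlan("m1", orientation="inverted"),
                GeneCopyPlan("m2"),
            ),
        ),
        GenePlan(
            "UTY",
            exon_lengths=tuple([150] * 6),
            intron_range=(200, 400),
            copies=(GeneCopyPlan("m3", status="truncated", exons=(1, 2, 3)),
                    GeneCopyPlan("m4", status="truncated", exons=(4, 5, 6))),
        ),
    )
    return FixtureSpec(
        seed=seed,
        x_scaffolds=(("X1", 80_000),),
        autosomes=(("A1", 30_000),),
        par_contigs=(("par1", 12_000, 0.98), ("par2", 10_000, 0.99), ("par3", 9_000, 0.995)),
        msy_contigs=(("m1", 14_000), ("m2", 10_000), ("m3", 10_000), ("m4", 9_000)),
        contaminants=(("cont1", 9_000, 0.97), ("cont2", 9_000, 0.96)),
        junk_contigs=(("junk1", 3_000), ("junk2", 5_000)),
        boundary_contig=("bnd1", 30_000, 18_000, 0.99),
        genes=genes,
        ct_plan=CtPlan(ratios=(("UTY", 1.0), ("HSFY", 3.0))),
        gametolog_divergences=(("SHROOM2", 800, 0.016),),
    )


# ---------------------------------------------------------------------------
# Fixture container
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    spec: FixtureSpec
    female_reference: list[ReferenceScaffold]
    y_contigs: list[Contig]
    transcripts: list[Contig]
    repeat_library: list[tuple[str, str, str]]
    primers: list[PrimerPair]
    ct_table: pd.DataFrame
    truth_manifest: pd.DataFrame
    gametologs: dict
    homolog_alignment: list[Contig]
    template_map: pd.DataFrame

    def contig(self, name: str) -> Contig:
        return next(c for c in self.y_contigs if c.id == name)

    def transcript(self, name: str) -> Contig:
        return next(t for t in self.transcripts if t.id == name)

    def manifest_rows(self, feature: str, **match) -> pd.DataFrame:
        df = self.truth_manifest[self.truth_manifest["feature"] == feature]
        for key, value in match.items():
            df = df[df[key] == value]
        return df


# ---------------------------------------------------------------------------
# Generation helpers
# ---------------------------------------------------------------------------

def _coding_sequence(rng: np.random.Generator, length: int) -> str:
    """ATG + random sense codons + TAA, total length a multiple of 3."""
    if length % 3 != 0 or length < 9:
        raise ValueError("coding transcript length must be a multiple of 3, >= 9")
    n_sense = length // 3 - 2
    codons = []
    while len(codons) < n_sense:
        codon = random_seq(rng, 3)
        if codon not in STOPS and codon != "ATG":
            codons.append(codon)
    return "ATG" + "".join(codons) + "TAA"


def _build_transcripts(rng: np.random.Generator, genes: Sequence[GenePlan]) -> dict[str, dict]:
    """Per gene: the planted exon sequences and the published transcript."""
    out = {}
    for plan in genes:
        if plan.coding:
            coding = _coding_sequence(rng, plan.transcript_length)
            exons, offset = [], 0
            for length in plan.exon_lengths:
                exons.append(coding[offset : offset + length])
                offset += length
        else:
            exons = [random_seq(rng, length) for length in plan.exon_lengths]
        planted = "".join(exons)
        transcript = (
            mutate(planted, plan.transcript_divergence, rng)
            if plan.transcript_divergence
            else planted
        )
        out[plan.name] = {"exons": exons, "transcript": transcript}
    return out


@dataclass
class _Feature:
    sequence: str
    rows: list  # manifest rows relative to the feature start


def _gene_copy_feature(rng, plan: GenePlan, copy: GeneCopyPlan, exon_seqs: list[str]) -> _Feature:
    if copy.status == "fragment":
        transcript = "".join(exon_seqs)
        start = int(rng.integers(0, len(transcript) - copy.fragment_length))
        seq = mutate(transcript[start : start + copy.fragment_length], plan.copy_divergence, rng)
        if copy.orientation == "inverted":
            seq = revcomp(seq)
        row = {
            "feature": "gene_copy",
            "name": plan.name,
            "orientation": copy.orientation,
            "status": "fragment",
            "exons": "",
            "rel_start": 0,
            "rel_end": len(seq),
            "exon_coords": "",
        }
        return _Feature(seq, [row])
    if copy.status == "located":
        pieces, offset = [], 0
        for exon in exon_seqs:
            core_start = (len(exon) - copy.segment_length) // 2
            core = exon[core_start : core_start + copy.segment_length]
            pieces.append(mutate(core, copy.segment_divergence, rng))
            pieces.append(random_seq(rng, int(rng.integers(plan.intron_range[0], plan.intron_range[1] + 1))))
        region = "".join(pieces[:-1])
        row = {
            "feature": "gene_copy",
            "name": plan.name,
            "orientation": copy.orientation,
            "status": "located",
            "exons": "",
            "rel_start": 0,
            "rel_end": len(region),
            "exon_coords": "",
        }
        return _Feature(region, [row])
    which = copy.exons or tuple(range(1, len(exon_seqs) + 1))
    pieces, exon_rel = [], []
    offset = 0
    for rank, idx in enumerate(which):
        exon = exon_seqs[idx - 1]
        pieces.append(exon)
        exon_rel.append((idx, offset, offset + len(exon)))
        offset += len(exon)
        if rank < len(which) - 1:
            intron = random_seq(rng, int(rng.integers(plan.intron_range[0], plan.intron_range[1] + 1)))
            pieces.append(intron)
            offset += len(intron)
    region = mutate("".join(pieces), plan.copy_divergence, rng)
    total = len(region)
    if copy.orientation == "inverted":
        region = revcomp(region)
        exon_rel = [(idx, total - e, total - s) for idx, s, e in exon_rel]
    status = copy.status if copy.status != "full" else ("full" if len(which) == len(exon_seqs) else "truncated")
    row = {
        "feature": "gene_copy",
        "name": plan.name,
        "orientation": copy.orientation,
        "status": status,
        "exons": ",".join(str(i) for i in which),
        "rel_start": 0,
        "rel_end": total,
        "exon_coords": ";".join(f"{idx}:{s}-{e}" for idx, s, e in exon_rel),
    }
    return _Feature(region, [row])


_MICROSAT_UNITS = ("A", "AC", "AG", "AAT", "AGAT", "AAGG", "ACGTC", "ACGCTG")


def _repeat_features(rng, plan: RepeatPlan, contig_length: int, consensi: dict[str, str]) -> list[_Feature]:
    """Truncated LINE copies plus SINE/LTR copies and microsatellite arrays
    sized to hit the per-contig target fractions."""
    features = []

    def add_copies(cls: str, target: float, full_length: int, truncatable: bool):
        budget = int(round(target * contig_length))
        while budget >= 100:
            length = min(full_length, budget)
            if truncatable and length == full_length and rng.random() < 0.5:
                length = int(rng.integers(full_length // 3, full_length))
            consensus = consensi[cls]
            piece = consensus[len(consensus) - length :]  # 3'-anchored truncation
            seq = mutate(piece, plan.copy_divergence, rng)
            src_start = len(consensus) - length
            features.append(
                _Feature(
                    seq,
                    [{
                        "feature": "repeat",
                        "name": cls,
                        "orientation": "direct",
                        "status": "copy",
                        "exons": "",
                        "rel_start": 0,
                        "rel_end": length,
                        "exon_coords": f"{src_start}-{len(consensus)}",
                    }],
                )
            )
            budget -= length

    add_copies("LINE", plan.line_fraction, plan.line_length, truncatable=True)
    add_copies("SINE", plan.sine_fraction, plan.sine_length, truncatable=False)
    add_copies("LTR", plan.ltr_fraction, plan.ltr_length, truncatable=False)

    budget = int(round(plan.microsat_fraction * contig_length))
    while budget >= 30:
        unit = _MICROSAT_UNITS[int(rng.integers(0, len(_MICROSAT_UNITS)))]
        min_copies = max(6, -(-30 // len(unit)))  # at least 30 bases and 6 copies
        copies = min_copies + int(rng.integers(0, 20))
        seq = (unit * copies)[: min(len(unit) * copies, budget)]
        if len(seq) < max(30, 6 * len(unit)):
            break
        features.append(
            _Feature(
                seq,
                [{
                    "feature": "microsatellite",
                    "name": unit,
                    "orientation": "direct",
                    "status": "array",
                    "exons": "",
                    "rel_start": 0,
                    "rel_end": len(seq),
                    "exon_coords": "",
                }],
            )
        )
        budget -= len(seq)
    return features


def _assemble(rng, name: str, length: int, features: list[_Feature], manifest: list, min_gap: int = 60) -> str:
    """Concatenate features with random spacers to an exact total length."""
    feature_total = sum(len(f.sequence) for f in features)
    n_gaps = len(features) + 1
    remaining = length - feature_total
    if remaining < n_gaps * min_gap:
        raise ValueError(
            f"contig {name}: planted features ({feature_total} bases) do not fit in {length}"
        )
    weights = rng.random(n_gaps)
    gaps = min_gap + np.floor((remaining - n_gaps * min_gap) * weights / weights.sum()).astype(int)
    gaps[-1] += remaining - int(gaps.sum())
    parts = []
    pos = 0
    for gap, feat in zip(gaps[:-1], features):
        parts.append(random_seq(rng, int(gap)))
        pos += int(gap)
        parts.append(feat.sequence)
        for row in feat.rows:
            entry = dict(row)
            entry["contig"] = name
            entry["start"] = pos + entry.pop("rel_start")
            entry["end"] = pos + entry.pop("rel_end")
            manifest.append(entry)
        pos += len(feat.sequence)
    parts.append(random_seq(rng, int(gaps[-1])))
    seq = "".join(parts)
    assert len(seq) == length
    return seq


def _unmutated_window(source: str, derived: str, width: int, rng, attempts: int = 200) -> int | None:
    """Start of a window where the derived sequence equals its source."""
    n = len(source) - width
    for _ in range(attempts):
        start = int(rng.integers(0, n))
        if source[start : start + width] == derived[start : start + width]:
            return start
    return None


# ---------------------------------------------------------------------------
# Ct simulation
# ---------------------------------------------------------------------------

def simulate_ct(ct_plan: CtPlan, seed: int | np.random.Generator) -> pd.DataFrame:
    """Simulated qPCR Ct table: duplicate assays x triplicate replicates.

    For a gene with true copy ratio r and efficiency E, each replicate Ct is
    Normal(base_ct - log(r)/log(1+E), sd).  The single-copy reference gene
    must have true ratio 1.
    """
    if ct_plan.sd < 0:
        raise ValueError("ct noise sd must be non-negative")
    ratios = dict(ct_plan.ratios)
    if ct_plan.reference_gene not in ratios:
        ratios = {ct_plan.reference_gene: 1.0, **ratios}
    if ratios[ct_plan.reference_gene] != 1.0:
        raise ValueError("reference gene must have true copy ratio 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    log_base = np.log(1.0 + ct_plan.efficiency)
    rows = []
    for gene, ratio in ratios.items():
        if ratio <= 0:
            raise ValueError(f"gene {gene}: true copy ratio must be positive")
        mean_ct = ct_plan.base_ct - np.log(ratio) / log_base
        for assay in range(1, ct_plan.n_assays + 1):
            for rep in range(1, ct_plan.n_replicates + 1):
                noise = rng.normal(0.0, ct_plan.sd) if ct_plan.sd > 0 else 0.0
                rows.append(
                    {"gene": gene, "assay": assay, "replicate": rep, "ct": mean_ct + noise}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Homolog alignment for comparative trees
# ---------------------------------------------------------------------------

_HOMOLOG_TREE = (
    # (taxon, cumulative divergence from the root sequence)
    ("alpaca_Y", 0.03),
    ("vicuna_Y", 0.035),
    ("dromedary_Y", 0.05),
    ("bactrian_camel_Y", 0.055),
    ("human_Y", 0.14),
    ("mouse_Y", 0.20),
)


def _homolog_alignment(rng: np.random.Generator, length: int = 1200) -> list[Contig]:
    """A gap-free alignment of gene homologs with a camelid clade.

    Camelid taxa share a common diverged ancestor (so they form a clade and
    can serve as a rooting outgroup for the non-camelid pair and vice
    versa); per-taxon divergence accumulates on top.
    """
    root = random_seq(rng, length)
    camelid_ancestor = mutate(root, 0.02, rng)
    other_ancestor = mutate(root, 0.08, rng)
    records = []
    for taxon, total in _HOMOLOG_TREE:
        base = camelid_ancestor if taxon.split("_")[0] in ("alpaca", "vicuna", "dromedary", "bactrian") else other_ancestor
        extra = max(total - (0.02 if base is camelid_ancestor else 0.08), 0.0)
        records.append(Contig(taxon, mutate(base, extra, rng)))
    return records


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the full fixture study; identical spec+seed give identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    manifest: list[dict] = []

    # 1. repeat consensus library
    rp = spec.repeat_plan
    consensi = {
        "LINE": random_seq(rng, rp.line_length),
        "SINE": random_seq(rng, rp.sine_length),
        "LTR": random_seq(rng, rp.ltr_length),
    }
    repeat_library = [(f"{cls}_consensus", cls, seq) for cls, seq in consensi.items()]

    # 2. female reference
    scaffolds = []
    for sid, length in spec.x_scaffolds:
        scaffolds.append(ReferenceScaffold(sid, random_seq(rng, length), "X"))
    for sid, length in spec.autosomes:
        scaffolds.append(ReferenceScaffold(sid, random_seq(rng, length), "AUTOSOME"))
    x_main = scaffolds[0]

    # 3. transcripts and exon sequences
    genes = _build_transcripts(rng, spec.genes)
    transcripts = [Contig(plan.name, genes[plan.name]["transcript"]) for plan in spec.genes]

    # 4. allocate X source intervals: boundary prefix first, then PAR contigs
    cursor = 0
    boundary_source = None
    if spec.boundary_contig is not None:
        _, _, prefix_len, _ = spec.boundary_contig
        if prefix_len > x_main.length:
            raise ValueError("boundary prefix longer than the X scaffold")
        boundary_source = (0, prefix_len)
        cursor = prefix_len + 2000
    par_sources = {}
    for name, length, _ in spec.par_contigs:
        if cursor + length > x_main.length:
            raise ValueError(f"X scaffold too short for PAR contig {name}")
        par_sources[name] = (cursor, cursor + length)
        cursor += length + 2000

    y_contigs: list[Contig] = []

    # 5. PAR contigs: mutated substrings of the X
    for name, length, identity in spec.par_contigs:
        s, e = par_sources[name]
        seq = mutate(x_main.sequence[s:e], 1.0 - identity, rng)
        y_contigs.append(Contig(name, seq))
        manifest.append(
            {
                "feature": "contig",
                "name": "PAR",
                "contig": name,
                "start": 0,
                "end": length,
                "orientation": "direct",
                "status": f"identity={identity}",
                "exons": "",
                "exon_coords": f"{x_main.id}:{s}-{e}",
            }
        )

    # 6. MSY contigs with planted genes, repeats and microsatellites
    copies_by_contig: dict[str, list] = {}
    for plan in spec.genes:
        for copy in plan.copies:
            copies_by_contig.setdefault(copy.contig, []).append((plan, copy))

    def build_msy_portion(name: str, length: int, label: str, offset: int = 0) -> str:
        features = [
            _gene_copy_feature(rng, plan, copy, genes[plan.name]["exons"])
            for plan, copy in copies_by_contig.get(name, [])
        ]
        features += _repeat_features(rng, rp, length, consensi)
        local: list[dict] = []
        seq = _assemble(rng, name, length, features, local)
        for row in local:
            row["start"] += offset
            row["end"] += offset
            manifest.append(row)
        manifest.append(
            {
                "feature": "contig",
                "name": label,
                "contig": name,
                "start": offset,
                "end": offset + length,
                "orientation": "direct",
                "status": "",
                "exons": "",
                "exon_coords": "",
            }
        )
        return seq

    for name, length in spec.msy_contigs:
        y_contigs.append(Contig(name, build_msy_portion(name, length, "MSY")))

    # 7. boundary-spanning contig: X-derived prefix + MSY-style suffix
    if spec.boundary_contig is not None:
        name, total, prefix_len, identity = spec.boundary_contig
        s, e = boundary_source
        prefix = mutate(x_main.sequence[s:e], 1.0 - identity, rng)
        suffix = build_msy_portion(name, total - prefix_len, "BOUNDARY_MSY_SEGMENT", offset=prefix_len)
        y_contigs.append(Contig(name, prefix + suffix))
        manifest.append(
            {
                "feature": "boundary",
                "name": "PAB",
                "contig": name,
                "start": 0,
                "end": prefix_len,
                "orientation": "direct",
                "status": f"identity={identity}",
                "exons": "",
                "exon_coords": f"{x_main.id}:{s}-{e}",
            }
        )

    # 8. contaminants and junk
    autosome_cursor = {sid: 0 for sid, _ in spec.autosomes}
    autosomes = {sc.id: sc for sc in scaffolds if sc.scaffold_class == "AUTOSOME"}
    auto_ids = list(autosomes)
    for i, (name, length, identity) in enumerate(spec.contaminants):
        sid = auto_ids[i % len(auto_ids)]
        start = autosome_cursor[sid]
        if start + length > autosomes[sid].length:
            raise ValueError(f"autosome {sid} too short for contaminant {name}")
        autosome_cursor[sid] = start + length + 500
        seq = mutate(autosomes[sid].sequence[start : start + length], 1.0 - identity, rng)
        y_contigs.append(Contig(name, seq))
        manifest.append(
            {
                "feature": "contig",
                "name": "CONTAMINANT",
                "contig": name,
                "start": 0,
                "end": length,
                "orientation": "direct",
                "status": f"identity={identity}",
                "exons": "",
                "exon_coords": f"{sid}:{start}-{start + length}",
            }
        )
    for name, length in spec.junk_contigs:
        y_contigs.append(Contig(name, random_seq(rng, length)))
        manifest.append(
            {
                "feature": "contig",
                "name": "JUNK",
                "contig": name,
                "start": 0,
                "end": length,
                "orientation": "direct",
                "status": "",
                "exons": "",
                "exon_coords": "",
            }
        )

    # 9. primers
    primers = _design_primers(rng, spec, y_contigs, x_main, boundary_source, manifest)

    # 10. Ct table
    ct_table = simulate_ct(spec.ct_plan, rng)

    # 11. gametolog pairs (X copy and its diverged Y counterpart)
    gametologs = {}
    for gname, length, divergence in spec.gametolog_divergences:
        x_seq = random_seq(rng, length)
        gametologs[gname] = (x_seq, mutate(x_seq, divergence, rng))

    # 12. homolog alignment for comparative trees
    homolog_alignment = _homolog_alignment(rng)

    # 13. template X gene map (positions on the main X scaffold)
    template_rows = []
    if boundary_source is not None:
        pab = boundary_source[1]
        template_rows.append({"gene": "SHROOM2", "scaffold": x_main.id, "start": max(pab - 12_000, 0), "end": max(pab - 9_000, 1)})
    for i, (name, _, _) in enumerate(spec.par_contigs):
        s, e = par_sources[name]
        template_rows.append({"gene": f"PARG{i + 1}", "scaffold": x_main.id, "start": s + 1000, "end": s + 3000})
    template_map = pd.DataFrame(template_rows, columns=["gene", "scaffold", "start", "end"])

    manifest_df = pd.DataFrame(
        manifest,
        columns=["feature", "name", "contig", "start", "end", "orientation", "status", "exons", "exon_coords"],
    ).sort_values(["feature", "contig", "start"], ignore_index=True)

    return Fixture(
        spec=spec,
        female_reference=scaffolds,
        y_contigs=y_contigs,
        transcripts=transcripts,
        repeat_library=repeat_library,
        primers=primers,
        ct_table=ct_table,
        truth_manifest=manifest_df,
        gametologs=gametologs,
        homolog_alignment=homolog_alignment,
        template_map=template_map,
    )


def _design_primers(rng, spec, y_contigs, x_main, boundary_source, manifest) -> list[PrimerPair]:
    """Primer pairs with planted specificity patterns.

    * one male-specific pair per multi-/single-copy gene region (drawn from
      the realized MSY contig sequence, so it matches the male exactly and
      the female not at all);
    * one control pair drawn from a mutation-free window of the boundary
      contig's X-derived prefix (amplifies in male and female);
    * the pair inside an ampliconic-gene exon doubles as the ladder case.
    """
    primers = []
    by_id = {c.id: c for c in y_contigs}
    copy_rows = [r for r in manifest if r["feature"] == "gene_copy" and r["status"] in ("full", "truncated")]
    seen_genes = set()
    for row in copy_rows:
        gene = row["name"]
        if gene in seen_genes:
            continue
        seen_genes.add(gene)
        contig = by_id[row["contig"]]
        start, end = row["start"], row["end"]
        if end - start < 500:
            continue
        product_len = min(420, end - start - 40)
        p_start = start + (end - start - product_len) // 2
        window = contig.sequence[p_start : p_start + product_len]
        primers.append(
            PrimerPair(
                f"{gene}_msy",
                window[:21],
                revcomp(window[-21:]),
                expected_size=product_len,
            )
        )
    if boundary_source is not None:
        name = next(r["contig"] for r in manifest if r["feature"] == "boundary")
        contig = by_id[name]
        s, e = boundary_source
        source = x_main.sequence[s:e]
        derived = contig.sequence[: e - s]
        for _ in range(100):
            start = _unmutated_window(source, derived, 21, rng)
            if start is None or start + 400 + 21 > len(source):
                continue
            if source[start + 400 : start + 421] == derived[start + 400 : start + 421]:
                primers.append(
                    PrimerPair("PAR_control", derived[start : start + 21],
                               revcomp(derived[start + 400 : start + 421]), expected_size=421)
                )
                break
    return primers


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture component; identical fixtures give identical bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "female_fasta": outdir / "female_reference.fasta",
        "female_classes": outdir / "scaffold_classes.tsv",
        "y_contigs": outdir / "y_contigs.fasta",
        "transcripts": outdir / "transcripts.fasta",
        "repeat_fasta": outdir / "repeat_library.fasta",
        "repeat_classes": outdir / "repeat_classes.tsv",
        "primers": outdir / "primers.tsv",
        "ct_table": outdir / "ct_table.tsv",
        "manifest": outdir / "truth_manifest.tsv",
        "gametologs": outdir / "gametologs.fasta",
        "homologs": outdir / "homolog_alignment.fasta",
        "template_map": outdir / "template_map.tsv",
    }
    write_reference(fixture.female_reference, paths["female_fasta"], paths["female_classes"])
    write_fasta(fixture.y_contigs, paths["y_contigs"])
    write_fasta(fixture.transcripts, paths["transcripts"])
    write_repeat_library(fixture.repeat_library, paths["repeat_fasta"], paths["repeat_classes"])
    write_primers(fixture.primers, paths["primers"])
    write_ct_table(fixture.ct_table, paths["ct_table"])
    fixture.truth_manifest.to_csv(paths["manifest"], sep="\t", index=False)
    gametolog_records = []
    for gene, (x_seq, y_seq) in fixture.gametologs.items():
        gametolog_records.append(Contig(f"{gene}_X", x_seq))
        gametolog_records.append(Contig(f"{gene}_Y", y_seq))
    write_fasta(gametolog_records, paths["gametologs"])
    write_fasta(fixture.homolog_alignment, paths["homologs"])
    fixture.template_map.to_csv(paths["template_map"], sep="\t", index=False)
    return paths
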