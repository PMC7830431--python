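"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* Coordinates are 0-based half-open internally; GFF3 and human-readable
  reports use 1-based inclusive coordinates.
* Sequences are uppercase strings over {A,C,G,T,N}; U is rejected.
* Report tables are tab-separated with a fixed header row; percentage
  columns are printed with one decimal.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import VALID_BASES

logger = logging.getLogger(__name__)

SCAFFOLD_CLASSES = ("X", "AUTOSOME", "UNPLACED")


@dataclass(frozen=True)
class Contig:
    """A named DNA sequence; the unit of triage and annotation."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceScaffold:
    """A female-reference scaffold with its chromosome-class assignment."""

    id: str
    sequence: str
    scaffold_class: str

    def __post_init__(self):
        if self.scaffold_class not in SCAFFOLD_CLASSES:
            raise ValueError(
                f"scaffold {self.id}: class must be one of {SCAFFOLD_CLASSES}, "
                f"got {self.scaffold_class!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str
    expected_size: int | None = None

    def __post_init__(self):
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not 15 <= len(seq) <= 35:
                raise ValueError(
                    f"primer {self.name}/{label}: length {len(seq)} outside [15, 35]"
                )
            if set(seq) - set("ACGT"):
                raise ValueError(f"primer {self.name}/{label}: degenerate bases not allowed")


def _validate_sequence(name: str, seq: str) -> str:
    seq = seq.upper()
    if "U" in seq:
        raise ValueError(f"record {name}: RNA base U rejected (DNA expected)")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"record {name}: non-IUPAC characters {sorted(bad)}")
    return seq


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a FASTA file into Contigs (order preserved, lowercase uppercased).

    Raises on an empty file, duplicate ids, U, or characters outside {A,C,G,T,N}.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or malformed FASTA (no records)")
    seen: set[str] = set()
    contigs = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        contigs.append(Contig(rec.id, _validate_sequence(rec.id, str(rec.seq))))
    return contigs


def write_fasta(records: Iterable[Contig | ReferenceScaffold], path: str | Path, width: int = 70) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def read_reference(fasta_path: str | Path, classes_path: str | Path) -> list[ReferenceScaffold]:
    """Read a female reference: FASTA plus a (scaffold, class) TSV."""
    table = pd.read_csv(classes_path, sep="\t", dtype=str)
    if not {"scaffold", "class"} <= set(table.columns):
        raise ValueError(f"{classes_path}: expected columns 'scaffold' and 'class'")
    classes = dict(zip(table["scaffold"], table["class"]))
    scaffolds = []
    for contig in read_fasta(fasta_path):
        if contig.id not in classes:
            raise ValueError(f"scaffold {contig.id} missing from class table {classes_path}")
        scaffolds.append(ReferenceScaffold(contig.id, contig.sequence, classes[contig.id]))
    return scaffolds


def write_reference(scaffolds: Sequence[ReferenceScaffold], fasta_path: str | Path, classes_path: str | Path) -> None:
    write_fasta(scaffolds, fasta_path)
    pd.DataFrame(
        {"scaffold": [s.id for s in scaffolds], "class": [s.scaffold_class for s in scaffolds]}
    ).to_csv(classes_path, sep="\t", index=False)


def read_primers(path: str | Path) -> list[PrimerPair]:
    table = pd.read_csv(path, sep="\t", dtype={"name": str, "forward": str, "reverse": str})
    pairs = []
    for row in table.itertuples(index=False):
        size = getattr(row, "expected_size", None)
        size = None if size is None or pd.isna(size) else int(size)
        pairs.append(PrimerPair(row.name, row.forward.upper(), row.reverse.upper(), size))
    return pairs


def write_primers(pairs: Sequence[PrimerPair], path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": [p.name for p in pairs],
            "forward": [p.forward for p in pairs],
            "reverse": [p.reverse for p in pairs],
            "expected_size": [p.expected_size if p.expected_size is not None else "" for p in pairs],
        }
    ).to_csv(path, sep="\t", index=False)


CT_COLUMNS = ("gene", "assay", "replicate", "ct")


def validate_ct_table(table: pd.DataFrame, reference_gene: str | None = None) -> pd.DataFrame:
    if list(table.columns) != list(CT_COLUMNS):
        raise ValueError(f"Ct table must have columns {CT_COLUMNS}, got {tuple(table.columns)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    if reference_gene is not None:
        assays = set(table["assay"].unique())
        ref_assays = set(table.loc[table["gene"] == reference_gene, "assay"].unique())
        if assays - ref_assays:
            raise ValueError(
                f"reference gene {reference_gene!r} missing from assays {sorted(assays - ref_assays)}"
            )
    return table


def read_ct_table(path: str | Path, reference_gene: str | None = None) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    table["assay"] = table["assay"].astype(int)
    table["replicate"] = table["replicate"].astype(int)
    table["ct"] = table["ct"].astype(float)
    return validate_ct_table(table, reference_gene)


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_ct_table(table).to_csv(path, sep="\t", index=False, float_format="%.6g")


REPEAT_LIBRARY_CLASSES = ("LINE", "SINE", "LTR")


def read_repeat_library(fasta_path: str | Path, classes_path: str | Path) -> list[tuple[str, str, str]]:
    """Read a repeat-consensus library: FASTA plus a (consensus, class) TSV."""
    table = pd.read_csv(classes_path, sep="\t", dtype=str)
    classes = dict(zip(table["consensus"], table["class"]))
    library = []
    for contig in read_fasta(fasta_path):
        cls = classes.get(contig.id)
        if cls not in REPEAT_LIBRARY_CLASSES:
            raise ValueError(f"consensus {contig.id}: class must be one of {REPEAT_LIBRARY_CLASSES}")
        library.append((contig.id, cls, contig.sequence))
    return library


def write_repeat_library(library: Sequence[tuple[str, str, str]], fasta_path: str | Path, classes_path: str | Path) -> None:
    write_fasta([Contig(cid, seq) for cid, _, seq in library], fasta_path)
    pd.DataFrame(
        {"consensus": [cid for cid, _, _ in library], "class": [cls for _, cls, _ in library]}
    ).to_csv(classes_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def write_gene_models_gff3(models, path: str | Path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Serialize gene models (see :mod:`ytriage.genecopy`) as GFF3.

    One gene/mRNA pair per model plus exon rows; 1-based inclusive
    coordinates; strand from orientation.  Exons of inverted copies are
    numbered descending along the contig (i.e. in transcript order).
    Deterministic ordering by (contig, start, gene).
    """
    rows = []
    for model in models:
        exons = list(model.exons)
        if not exons:
            raise ValueError(f"model {model.gene} on {model.contig_id}: no exons")
        for (s1, e1) in exons:
            if s1 >= e1:
                raise ValueError(f"model {model.gene}: degenerate exon [{s1}, {e1})")
        span = sorted(exons)
        for (a_s, a_e), (b_s, b_e) in zip(span, span[1:]):
            if b_s < a_e:
                raise ValueError(
                    f"model {model.gene} on {model.contig_id}: overlapping exons "
                    f"[{a_s}, {a_e}) and [{b_s}, {b_e})"
                )
        start = min(s for s, _ in exons)
        end = max(e for _, e in exons)
        if contig_lengths is not None:
            clen = contig_lengths.get(model.contig_id)
            if clen is None:
                raise ValueError(f"unknown contig {model.contig_id}")
            if start < 0 or end > clen:
                raise ValueError(
                    f"model {model.gene} on {model.contig_id}: exons exceed contig bounds"
                )
        rows.append((model.contig_id, start, model, exons))

    rows.sort(key=lambda r: (r[0], r[1], r[2].gene))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for idx, (contig_id, start, model, exons) in enumerate(rows, 1):
            strand = "+" if model.orientation == "direct" else "-"
            end = max(e for _, e in exons)
            gid = f"gene{idx:04d}.{model.gene}"
            attrs = f"ID={gid};Name={model.gene};status={model.status}"
            fh.write(
                f"{contig_id}\tytriage\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{contig_id}\tytriage\tmRNA\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            # exon rows in transcript order: ascending contig position for
            # direct copies, descending for inverted ones
            ordered = exons if strand == "+" else sorted(exons, reverse=True)
            for n, (s, e) in enumerate(ordered, 1):
                fh.write(
                    f"{contig_id}\tytriage\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={gid}.t1.exon{n};Parent={gid}.t1\n"
                )


def read_gene_models_gff3(path: str | Path) -> list[dict]:
    """Re-read GFF3 written by :func:`write_gene_models_gff3`.

    Returns one dict per gene with 0-based half-open exon intervals in the
    file's exon order (transcript order).
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            contig, _, kind, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";"))
            if kind == "gene":
                genes[fields["ID"]] = {
                    "gene": fields["Name"],
                    "contig_id": contig,
                    "orientation": "direct" if strand == "+" else "inverted",
                    "status": fields.get("status"),
                    "exons": [],
                }
            elif kind == "exon":
                gid = fields["Parent"].rsplit(".t1", 1)[0]
                genes[gid]["exons"].append((int(start) - 1, int(end)))
    return list(genes.values())


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_triage_bed(
    labels,
    contig_lengths: Mapping[str, int],
    path: str | Path,
    boundaries: Mapping[str, int] | None = None,
) -> None:
    """Write triage labels as BED (0-based half-open), one row per contig.

    ``boundaries`` maps a boundary-spanning contig id to its 1-based PAB
    coordinate; such contigs are written as two rows (PAR then MSY segment)
    partitioning the contig.
    """
    labels = list(labels)
    if not labels:
        logger.warning("write_triage_bed: empty label set, writing empty BED %s", path)
        Path(path).write_text("")
        return
    boundaries = boundaries or {}
    with open(path, "w") as fh:
        for lab in labels:
            length = contig_lengths.get(lab.contig_id)
            if length is None:
                raise ValueError(f"unlabeled or unknown contig {lab.contig_id!r}")
            if lab.contig_id in boundaries:
                pab = boundaries[lab.contig_id]
                if not 0 < pab < length:
                    raise ValueError(f"boundary {pab} outside contig {lab.contig_id}")
                fh.write(f"{lab.contig_id}\t0\t{pab}\tPAR_SEGMENT\n")
                fh.write(f"{lab.contig_id}\t{pab}\t{length}\tMSY_SEGMENT\n")
            else:
                fh.write(f"{lab.contig_id}\t0\t{length}\t{lab.label}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    rows = []
    text = Path(path).read_text()
    for line in text.splitlines():
        if not line.strip():
            continue
        contig, start, end, name = line.split("\t")[:4]
        rows.append((contig, int(start), int(end), name))
    return rows


def write_masked_bed(intervals_by_contig: Mapping[str, Sequence[tuple[int, int, str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig in sorted(intervals_by_contig):
            for start, end, name in sorted(intervals_by_contig[contig]):
                fh.write(f"{contig}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# Key-value configuration
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict[str, str]:
    """Parse a plain-text ``key = value`` configuration file.

    Blank lines and ``#`` comments are ignored; later keys override earlier
    ones.  All values are returned as strings; callers coerce.
    """
    config: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, value = stripped.split("=", 1)
        config[key.strip()] = value.strip()
    return config


def write_config(config: Mapping[str, object], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, value in config.items():
            fh.write(f"{key} = {value}\n")


def write_table(df: pd.DataFrame, path: str | Path, percent_columns: Sequence[str] = ()) -> None:
    """Write a report table as TSV; percentage columns printed with one decimal."""
    out = df.copy()
    for col in percent_columns:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.1f}")
    out.to_csv(path, sep="\t", index=False)
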