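"""End-to-end run: fixture -> triage -> stats -> genes -> pab -> qpcr -> tree.

All randomness flows from the single configured seed; rerunning with the
same configuration is byte-identical.  Each stage logs one line with its
input/output counts and appends to a machine-readable JSON log; a stage
failure aborts the run naming the stage.  The summary table partitions
the assembly exactly: MSY + PAR + contaminant + short totals equal the
input base count, and the combined confirmed-Y total equals the
validated-MSY plus PAR cumulative sizes.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import genecopy, io_formats, njtree, pab, qpcr, seqstats, synthetic_data, triage
from .homology import SeedIndex, build_index
from .io_formats import read_config

logger = logging.getLogger("ytriage")


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 42
    preset: str = "paper"             # fixture preset when inputs are generated
    fixture_dir: Path | None = None   # pre-existing fixture to load instead
    min_identity: float = 0.95
    min_coverage: float = 0.25
    length_threshold: int = synthetic_data.LENGTH_THRESHOLD_DEFAULT
    k: int = 15
    pab_window: int = 10_000
    pab_step: int = 2_000
    reference_gene: str = "UTY"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = read_config(path)
        kwargs = {}
        for key, caster in (
            ("outdir", Path),
            ("seed", int),
            ("preset", str),
            ("fixture_dir", Path),
            ("min_identity", float),
            ("min_coverage", float),
            ("length_threshold", int),
            ("k", int),
            ("pab_window", int),
            ("pab_step", int),
            ("reference_gene", str),
        ):
            if key in raw:
                kwargs[key] = caster(raw[key])
        if "outdir" not in kwargs:
            raise ValueError(f"{path}: 'outdir' is required")
        return cls(**kwargs)


@dataclass
class RunResult:
    outdir: Path
    summary: pd.DataFrame
    triage_report: triage.TriageReport
    copy_summaries: dict
    pab_calls: list
    qpcr_estimates: pd.DataFrame | None
    log: list


def _stage(log: list, name: str, message: str, **counts) -> None:
    logger.info("[%s] %s %s", name, message, counts if counts else "")
    log.append({"stage": name, "message": message, **counts})


def run_all(config: RunConfig) -> RunResult:
    """Run every stage; returns the summary and writes all reports to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    stage = "fixture"
    try:
        fixture = _load_fixture(config, outdir, log)
        stage = "triage"
        tri_report, reference_index = _run_triage(config, fixture, outdir, log)
        stage = "validate"
        validated, specificity = _run_validation(config, fixture, outdir, log, tri_report)
        stage = "stats"
        _run_stats(config, fixture, outdir, log, tri_report)
        stage = "genes"
        summaries, models = _run_genes(config, fixture, outdir, log)
        stage = "pab"
        pab_calls = _run_pab(config, fixture, outdir, log, tri_report)
        stage = "qpcr"
        estimates = _run_qpcr(config, fixture, outdir, log)
        stage = "tree"
        _run_tree(config, fixture, outdir, log)
        stage = "summary"
        summary = _write_summary(
            config, fixture, outdir, tri_report, validated, pab_calls, summaries, estimates
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1, default=str) + "\n")
    return RunResult(outdir, summary, tri_report, summaries, pab_calls, estimates, log)


def _load_fixture(config: RunConfig, outdir: Path, log):
    if config.fixture_dir is not None:
        fdir = Path(config.fixture_dir)
        _stage(log, "fixture", f"loading fixture from {fdir}")
        spec = None
        fixture = _read_fixture_dir(fdir)
    else:
        spec = (
            synthetic_data.paper_preset(config.seed)
            if config.preset == "paper"
            else synthetic_data.small_preset(config.seed)
        )
        fixture = synthetic_data.generate_fixture(spec)
        synthetic_data.write_fixture(fixture, outdir / "fixture")
        _stage(
            log,
            "fixture",
            f"generated preset {config.preset!r} seed {config.seed}",
            y_contigs=len(fixture.y_contigs),
            transcripts=len(fixture.transcripts),
        )
    return fixture


@dataclass
class _LoadedFixture:
    female_reference: list
    y_contigs: list
    transcripts: list
    repeat_library: list
    primers: list
    ct_table: pd.DataFrame | None
    template_map: pd.DataFrame | None
    homolog_alignment: list | None
    truth_manifest: pd.DataFrame | None = None
    gametologs: dict = field(default_factory=dict)


def _read_fixture_dir(fdir: Path) -> _LoadedFixture:
    ct_path = fdir / "ct_table.tsv"
    homologs = fdir / "homolog_alignment.fasta"
    template = fdir / "template_map.tsv"
    return _LoadedFixture(
        female_reference=io_formats.read_reference(
            fdir / "female_reference.fasta", fdir / "scaffold_classes.tsv"
        ),
        y_contigs=io_formats.read_fasta(fdir / "y_contigs.fasta"),
        transcripts=io_formats.read_fasta(fdir / "transcripts.fasta"),
        repeat_library=io_formats.read_repeat_library(
            fdir / "repeat_library.fasta", fdir / "repeat_classes.tsv"
        ),
        primers=io_formats.read_primers(fdir / "primers.tsv") if (fdir / "primers.tsv").exists() else [],
        ct_table=io_formats.read_ct_table(ct_path) if ct_path.exists() else None,
        template_map=pd.read_csv(template, sep="\t") if template.exists() else None,
        homolog_alignment=io_formats.read_fasta(homologs) if homologs.exists() else None,
    )


def _run_triage(config: RunConfig, fixture, outdir: Path, log):
    params = triage.TriageParams(
        min_identity=config.min_identity,
        min_coverage=config.min_coverage,
        length_threshold=config.length_threshold,
        k=config.k,
    )
    index = build_index(fixture.female_reference, k=config.k)
    report = triage.triage_assembly(fixture.y_contigs, index, params)
    report.to_frame().to_csv(outdir / "triage_summary.tsv", sep="\t", index=False)
    rows = pd.DataFrame(
        [
            {
                "contig": lab.contig_id,
                "label": lab.label,
                "best_class": lab.best_class or "",
                "coverage": round(lab.coverage, 4),
                "identity": "" if lab.identity is None else round(lab.identity, 4),
                "near_threshold": lab.near_threshold,
            }
            for lab in report.labels
        ]
    )
    rows.to_csv(outdir / "triage_labels.tsv", sep="\t", index=False)
    _stage(log, "triage", "classified contigs", **{k: v for k, v in report.counts.items()})
    return report, index


def _run_validation(config: RunConfig, fixture, outdir: Path, log, report):
    """In-silico PCR male-specificity of every primer pair; a putative MSY
    contig with at least one male-specific marker is validated MSY."""
    rows = []
    validated = set()
    for pair in fixture.primers:
        call = triage.in_silico_pcr(pair, fixture.y_contigs, genome_id="male")
        status = triage.male_specificity(pair, fixture.y_contigs, fixture.female_reference)
        rows.append(
            {
                "primer": pair.name,
                "male_products": len(call.products),
                "status": status,
                "contigs": ",".join(sorted({p[0] for p in call.products})),
            }
        )
        if status == "MALE_SPECIFIC":
            validated.update(p[0] for p in call.products)
    table = pd.DataFrame(rows, columns=["primer", "male_products", "status", "contigs"])
    table.to_csv(outdir / "male_specificity.tsv", sep="\t", index=False)
    labels = {lab.contig_id: lab.label for lab in report.labels}
    validated = {c for c in validated if labels.get(c) == "PUTATIVE_MSY"}
    _stage(log, "validate", "in-silico PCR", primers=len(fixture.primers), validated_contigs=len(validated))
    return validated, table


def _run_stats(config: RunConfig, fixture, outdir: Path, log, report):
    labels = {lab.contig_id: lab.label for lab in report.labels}
    kept = [c for c in fixture.y_contigs if labels[c.id] in ("PUTATIVE_MSY", "PAR_CANDIDATE")]
    annotations = {
        c.id: seqstats.annotate_repeats(c, fixture.repeat_library) for c in kept
    }
    table = seqstats.feature_report(kept, annotations)
    io_formats.write_table(table, outdir / "contig_features.tsv", seqstats.PERCENT_COLUMNS)
    metrics = seqstats.assembly_metrics([c.length for c in fixture.y_contigs])
    pd.DataFrame([metrics.__dict__]).to_csv(outdir / "assembly_metrics.tsv", sep="\t", index=False)
    _stage(log, "stats", "feature report", contigs=len(kept))


def _run_genes(config: RunConfig, fixture, outdir: Path, log):
    labels_index = SeedIndex(fixture.y_contigs, k=config.k)
    summaries: dict[str, genecopy.CopySummary] = {}
    all_models = []
    rows = []
    for transcript in fixture.transcripts:
        gene = transcript.id
        cross = gene.upper().startswith("AMELY")
        params = genecopy.GeneParams(k=config.k, cross_species=cross)
        models = genecopy.detect_copies(gene, transcript, labels_index, params)
        splits = genecopy.detect_split_genes(models)
        summary = genecopy.copy_summary(models, splits)
        summaries[gene] = summary
        all_models.extend(m for m in models if m.status in ("FULL", "TRUNCATED"))
        rows.append(
            {
                "gene": gene,
                "contigs": ",".join(sorted({m.contig_id for m in models})),
                "copy_number": summary.total_copies,
                "fragments": summary.fragments,
                "located": summary.located,
                "split_gene": "yes" if splits else "no",
                "transcript_size": transcript.length,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "gene_copies.tsv", sep="\t", index=False)
    contig_lengths = {c.id: c.length for c in fixture.y_contigs}
    io_formats.write_gene_models_gff3(all_models, outdir / "gene_models.gff3", contig_lengths)
    _stage(log, "genes", "copy detection", genes=len(rows), models=len(all_models))
    return summaries, all_models


def _run_pab(config: RunConfig, fixture, outdir: Path, log, report):
    x_scaffolds = [s for s in fixture.female_reference if s.scaffold_class == "X"]
    x_index = build_index(x_scaffolds, k=config.k)
    params = pab.PabParams(window=config.pab_window, step=config.pab_step)
    calls = []
    candidates = [
        c
        for c in fixture.y_contigs
        if {lab.contig_id: lab for lab in report.labels}[c.id].label
        in ("PAR_CANDIDATE", "PUTATIVE_MSY")
        and c.length >= 2 * config.pab_window
    ]
    for contig in candidates:
        call = pab.find_boundary(contig, x_index, params)
        if call is not None:
            calls.append(call)
    pd.DataFrame(
        [
            {
                "contig": c.contig_id,
                "boundary": c.boundary,
                "par_side_identity": round(c.par_side_identity, 4),
                "window": c.window,
            }
            for c in calls
        ],
        columns=["contig", "boundary", "par_side_identity", "window"],
    ).to_csv(outdir / "pab_calls.tsv", sep="\t", index=False)
    labels = {lab.contig_id: lab for lab in report.labels}
    io_formats.write_triage_bed(
        report.labels,
        {c.id: c.length for c in fixture.y_contigs},
        outdir / "triage.bed",
        boundaries={c.contig_id: c.boundary for c in calls},
    )
    # order PAR contigs on the template X map
    par_contigs = [c for c in fixture.y_contigs if labels[c.id].label == "PAR_CANDIDATE"]
    placements = pab.order_par_contigs(par_contigs, x_index)
    pd.DataFrame(
        [
            {
                "contig": p.contig_id,
                "template": p.template_id or "UNPLACED",
                "start": "" if p.start is None else p.start,
                "end": "" if p.end is None else p.end,
                "orientation": p.orientation or "",
            }
            for p in placements
        ]
    ).to_csv(outdir / "par_order.tsv", sep="\t", index=False)
    _stage(log, "pab", "boundary detection", candidates=len(candidates), calls=len(calls))
    return calls


def _run_qpcr(config: RunConfig, fixture, outdir: Path, log):
    if fixture.ct_table is None:
        logger.warning("[qpcr] no Ct table provided; stage skipped")
        log.append({"stage": "qpcr", "message": "skipped: no Ct table"})
        return None
    estimates = qpcr.estimate_all(fixture.ct_table, config.reference_gene)
    estimates.to_csv(outdir / "qpcr_estimates.tsv", sep="\t", index=False, float_format="%.4g")
    _stage(log, "qpcr", "fold changes", genes=len(estimates))
    return estimates


def _run_tree(config: RunConfig, fixture, outdir: Path, log):
    if not fixture.homolog_alignment:
        log.append({"stage": "tree", "message": "skipped: no homolog alignment"})
        return
    dm = njtree.p_distance(fixture.homolog_alignment)
    tree = njtree.neighbor_joining(dm)
    rooted = njtree.root_tree(tree, midpoint=True)
    njtree.write_newick(rooted, outdir / "homolog_tree.nwk")
    _stage(log, "tree", "neighbor joining", taxa=len(dm.taxa))


def _write_summary(config, fixture, outdir: Path, report, validated, pab_calls, summaries, estimates):
    labels = {lab.contig_id: lab.label for lab in report.labels}
    lengths = {c.id: c.length for c in fixture.y_contigs}
    pab_by_contig = {c.contig_id: c.boundary for c in pab_calls}
    msy_bases = sum(lengths[c] for c, l in labels.items() if l == "PUTATIVE_MSY")
    par_bases = 0
    for contig_id, label in labels.items():
        if label != "PAR_CANDIDATE":
            continue
        if contig_id in pab_by_contig:
            par_bases += pab_by_contig[contig_id]
            msy_bases += lengths[contig_id] - pab_by_contig[contig_id]
        else:
            par_bases += lengths[contig_id]
    validated_bases = sum(lengths[c] for c in validated)
    rows = [
        ("seed", config.seed),
        ("total_contigs", len(fixture.y_contigs)),
        ("total_bases", report.total_bases),
        ("too_short_bases", report.bases.get("TOO_SHORT", 0)),
        ("contaminant_bases", report.bases.get("AUTOSOMAL_CONTAMINANT", 0)),
        ("msy_bases", msy_bases),
        ("par_bases", par_bases),
        ("combined_y_bases", msy_bases + par_bases),
        ("validated_msy_bases", validated_bases),
        ("pab_contig", ",".join(sorted(pab_by_contig)) or "none"),
        ("pab_boundary", ",".join(str(pab_by_contig[c]) for c in sorted(pab_by_contig)) or ""),
    ]
    for gene in sorted(summaries):
        rows.append((f"copies_{gene}", summaries[gene].total_copies))
    if estimates is not None:
        for row in estimates.itertuples(index=False):
            rows.append((f"qpcr_fold_{row.gene}", f"{row.fold_change:.3f}"))
    summary = pd.DataFrame(rows, columns=["key", "value"])
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    return summary
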