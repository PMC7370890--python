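"""End-to-end orchestration of the two analysis pipelines.

``run_excov`` chains annotation flattening, read loading, novel-exon
discovery, PSI quantification and the candidate filter cascade;
``run_phase`` chains read loading, cassette-exon phasing and transcript
matching.  The CLI is a thin wrapper over these functions, which are also
the programmatic entry points used in tests.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from . import annotation as anno
from . import excovator as excov
from . import exphaser as phaser
from . import reads as rio

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Shared thresholds and flags for a pipeline run.

    Defaults are the published operating points: genes need 10 consensus
    reads, parts 30x consensus coverage in two samples and a 20-point PSI
    difference; junction display support 5; 10 bp of splice-site slop.
    """

    min_gene_consensus: int = excov.DEFAULT_MIN_GENE_CONSENSUS
    min_part_consensus: int = excov.DEFAULT_MIN_PART_CONSENSUS
    min_psi_delta: float = excov.DEFAULT_MIN_PSI_DELTA
    min_junction_support: int = 5
    boundary_slop: int = excov.DEFAULT_BOUNDARY_SLOP
    min_overlap: int = excov.DEFAULT_MIN_OVERLAP
    novel_min_support: int = excov.DEFAULT_NOVEL_MIN_SUPPORT
    novel_min_length: int = excov.DEFAULT_NOVEL_MIN_LENGTH
    min_mapq: int = 0
    strict_strand: bool = False
    emit_plots: bool = False

    def __post_init__(self) -> None:
        for name in (
            "min_gene_consensus",
            "min_part_consensus",
            "min_psi_delta",
            "min_junction_support",
            "boundary_slop",
            "min_overlap",
            "novel_min_support",
            "novel_min_length",
            "min_mapq",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ExcovResult:
    flats: dict[str, anno.FlattenedGene]  # gene_id -> parts incl. novel
    records: list[excov.PsiRecord]
    candidates: list[excov.CandidateExon]
    gene_consensus: dict[str, int]
    outputs: dict[str, str] = field(default_factory=dict)


def load_samples(
    sams: dict[str, str],
    sidecars: dict[str, str] | None = None,
    min_mapq: int = 0,
    reference_names: set[str] | None = None,
) -> dict[str, list[rio.ConsensusRead]]:
    sidecars = sidecars or {}
    return {
        label: rio.load_reads(
            path,
            sample_label=label,
            fl_sidecar=sidecars.get(label),
            min_mapq=min_mapq,
            reference_names=reference_names,
        )
        for label, path in sams.items()
    }


def _gene_reads(
    reads: list[rio.ConsensusRead],
    flat: anno.FlattenedGene,
    strict_strand: bool = False,
) -> list[rio.ConsensusRead]:
    span = flat.gene.span
    out = []
    for r in reads:
        if r.chrom != span.chrom:
            continue
        if strict_strand and span.strand in "+-" and r.strand != span.strand:
            continue
        if min(r.span.end, span.end) - max(r.span.start, span.start) > 0:
            out.append(r)
    return out


def run_excov(
    gtf: str,
    sams: dict[str, str],
    outdir: str,
    sidecars: dict[str, str] | None = None,
    config: RunConfig | None = None,
    genes: set[str] | None = None,
) -> ExcovResult:
    """The exon-centric pipeline: flatten -> load -> discover -> PSI -> filter.

    Writes psi.tsv, candidates.tsv, novel_parts.bed, flattened.gff and
    junctions.tsv into *outdir* and logs a filtration funnel (genes seen,
    genes covered, novel parts, parts evaluated/passing).
    """
    config = config or RunConfig()
    os.makedirs(outdir, exist_ok=True)
    gene_models = anno.load_gtf(gtf, feature_filter=genes)
    logger.info("annotation: %d genes", len(gene_models))
    reference_names = {g.chrom for g in gene_models}
    reads_by_sample = load_samples(
        sams, sidecars, min_mapq=config.min_mapq, reference_names=reference_names
    )

    flats: dict[str, anno.FlattenedGene] = {}
    all_records: list[excov.PsiRecord] = []
    gene_consensus: dict[str, int] = {}
    covered_genes = 0
    novel_total = 0
    for gene in gene_models:
        flat = anno.flatten_gene(gene)
        per_sample = {
            label: _gene_reads(reads, flat, config.strict_strand)
            for label, reads in reads_by_sample.items()
        }
        n_gene_reads = sum(len(v) for v in per_sample.values())
        gene_consensus[gene.gene_id] = n_gene_reads
        if n_gene_reads >= config.min_gene_consensus:
            covered_genes += 1
        pooled = [r for label in sorted(per_sample) for r in per_sample[label]]
        flat = excov.discover_novel_exons(
            pooled,
            flat,
            min_support_reads=config.novel_min_support,
            min_length=config.novel_min_length,
        )
        novel_total += sum(1 for p in flat.parts if p.source == "novel")
        flats[gene.gene_id] = flat
        all_records.extend(
            excov.psi_table(
                per_sample,
                flat,
                boundary_slop=config.boundary_slop,
                min_overlap=config.min_overlap,
            )
        )

    candidates = excov.filter_candidates(
        all_records,
        min_gene_consensus=config.min_gene_consensus,
        min_part_consensus=config.min_part_consensus,
        min_psi_delta=config.min_psi_delta,
        gene_consensus=gene_consensus,
    )
    n_pass = sum(1 for c in candidates if c.passes_filters)
    logger.info(
        "funnel: %d genes, %d with >=%d consensus reads, %d novel parts, "
        "%d parts evaluated, %d pass filters",
        len(gene_models),
        covered_genes,
        config.min_gene_consensus,
        novel_total,
        len(candidates),
        n_pass,
    )

    outputs = {
        "psi": os.path.join(outdir, "psi.tsv"),
        "candidates": os.path.join(outdir, "candidates.tsv"),
        "novel_bed": os.path.join(outdir, "novel_parts.bed"),
        "flattened_gff": os.path.join(outdir, "flattened.gff"),
        "junctions": os.path.join(outdir, "junctions.tsv"),
    }
    excov.coverage_report(all_records, outputs["psi"])
    excov.candidate_report(candidates, outputs["candidates"])
    with open(outputs["novel_bed"], "w") as _:
        pass
    for flat in flats.values():
        _append_novel_bed(flat, outputs["novel_bed"])
    anno.write_flattened_gff(list(flats.values()), outputs["flattened_gff"])
    all_reads = [r for label in sorted(reads_by_sample) for r in reads_by_sample[label]]
    rio.write_junction_tsv(
        rio.junction_table(all_reads, min_support=config.min_junction_support),
        outputs["junctions"],
    )
    if config.emit_plots:
        for gene_id, flat in flats.items():
            recs = [r for r in all_records if r.gene_id == gene_id]
            if any(r.total_fl for r in recs):
                plot_path = os.path.join(outdir, f"coverage_{gene_id}.png")
                excov.coverage_plot(recs, plot_path)
                outputs[f"plot_{gene_id}"] = plot_path
    return ExcovResult(
        flats=flats,
        records=all_records,
        candidates=candidates,
        gene_consensus=gene_consensus,
        outputs=outputs,
    )


def _append_novel_bed(flat: anno.FlattenedGene, path: str) -> None:
    with open(path, "a") as fh:
        for p in flat.parts:
            if p.source != "novel":
                continue
            strand = p.interval.strand if p.interval.strand != "." else "+"
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{p.label}\t0\t{strand}\n"
            )


@dataclass
class PhaseResult:
    report: phaser.PhaseReport
    outputs: dict[str, str] = field(default_factory=dict)


def run_phase(
    gtf: str,
    bed: str,
    sams: dict[str, str],
    outdir: str,
    sidecars: dict[str, str] | None = None,
    config: RunConfig | None = None,
    gene_id: str = "",
) -> PhaseResult:
    """The phasing pipeline: load -> phase -> match -> report."""
    config = config or RunConfig()
    os.makedirs(outdir, exist_ok=True)
    targets = phaser.TargetExonSet.from_bed(bed, gene_id=gene_id)
    gene_models = anno.load_gtf(gtf)
    region = targets.region
    if not any(
        g.chrom == region.chrom and g.span.overlap(region) > 0 for g in gene_models
    ):
        logger.warning(
            "target region %s:%d-%d overlaps no annotated gene; phasing by "
            "coordinates only",
            region.chrom,
            region.start,
            region.end,
        )
    transcripts = [t for g in gene_models for t in g.transcripts]
    reads_by_sample = load_samples(
        sams, sidecars, min_mapq=config.min_mapq,
        reference_names={g.chrom for g in gene_models},
    )
    report = phaser.phase(
        reads_by_sample,
        targets,
        annotation=transcripts,
        boundary_slop=config.boundary_slop,
        min_overlap=config.min_overlap,
    )
    out_path = os.path.join(outdir, "phase.tsv")
    phaser.phase_report_tsv(report, out_path)
    return PhaseResult(report=report, outputs={"phase": out_path})
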