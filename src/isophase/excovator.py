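"""Exon-centric analysis of consensus reads (the exCOVator stage).

For every exonic part of a flattened gene, each spanning read either
contains the part (MATCHING) or splices it out (SKIPPING); reads that are
3'-truncated inside or short of the part are NON_INFORMATIVE and enter
neither count.  Percent spliced-in (PSI) is the FL-weighted fraction

    PSI = 100 * matching_FL / (matching_FL + skipping_FL)

per (sample, exonic part).  Unannotated exons are discovered from read
blocks falling in annotation gaps and injected into the part list before
quantification.  A threshold cascade (gene coverage, part coverage,
cross-sample PSI difference) nominates differentially used exons.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .annotation import ExonicPart, FlattenedGene, renumber_parts
from .intervals import GenomicInterval, merge_intervals, subtract_intervals
from .reads import ConsensusRead

logger = logging.getLogger(__name__)

DEFAULT_BOUNDARY_SLOP = 10
DEFAULT_MIN_OVERLAP = 10
DEFAULT_MIN_GENE_CONSENSUS = 10
DEFAULT_MIN_PART_CONSENSUS = 30
DEFAULT_MIN_PSI_DELTA = 20.0
DEFAULT_NOVEL_MIN_SUPPORT = 5
DEFAULT_NOVEL_MIN_LENGTH = 10


class PartReadClass(enum.Enum):
    MATCHING = "matching"
    SKIPPING = "skipping"
    NON_INFORMATIVE = "non_informative"


@dataclass(frozen=True)
class PsiRecord:
    """Per (sample, exonic part) inclusion counts and PSI."""

    gene_id: str
    part: ExonicPart
    sample: str
    matching_consensus: int
    total_consensus: int
    matching_fl: int
    total_fl: int

    def __post_init__(self) -> None:
        if self.matching_consensus > self.total_consensus:
            raise ValueError("matching consensus count exceeds total")
        if self.matching_fl > self.total_fl:
            raise ValueError("matching FL count exceeds total")

    @property
    def psi_percent(self) -> float | None:
        """100 * matching_FL / total_FL, or None when no read spans the part."""
        if self.total_fl == 0:
            return None
        return 100.0 * self.matching_fl / self.total_fl


@dataclass(frozen=True)
class CandidateExon:
    """One exonic part's PSI records across samples plus filter outcome."""

    gene_id: str
    part: ExonicPart
    records: tuple[PsiRecord, ...]
    max_pairwise_psi_delta: float | None
    passes_filters: bool


def classify_read_for_part(
    read: ConsensusRead,
    part: ExonicPart,
    boundary_slop: int = DEFAULT_BOUNDARY_SLOP,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> PartReadClass:
    """Classify one read against one exonic part.

    MATCHING: a single aligned block covers the part, missing each part
    boundary by at most ``boundary_slop`` bases (absorbs splice-site wobble).
    SKIPPING: the read spans the whole part but no block overlaps it by more
    than ``min_overlap`` bases - the part sits in one of the read's introns.
    Anything else (read ends inside/before/after the part, or an ambiguous
    partial overlap) is NON_INFORMATIVE.
    """
    iv = part.interval
    if read.chrom != iv.chrom:
        logger.debug("read %s on %s vs part on %s", read.read_id, read.chrom, iv.chrom)
        return PartReadClass.NON_INFORMATIVE

    for block in read.blocks:
        if (
            block.overlap(iv) > 0
            and max(0, block.start - iv.start) <= boundary_slop
            and max(0, iv.end - block.end) <= boundary_slop
        ):
            return PartReadClass.MATCHING

    span = read.span
    if span.start <= iv.start and iv.end <= span.end:
        if all(block.overlap(iv) <= min_overlap for block in read.blocks):
            return PartReadClass.SKIPPING
    return PartReadClass.NON_INFORMATIVE


def discover_novel_exons(
    reads: list[ConsensusRead],
    flat: FlattenedGene,
    min_support_reads: int = DEFAULT_NOVEL_MIN_SUPPORT,
    min_length: int = DEFAULT_NOVEL_MIN_LENGTH,
) -> FlattenedGene:
    """Inject unannotated exonic parts observed in the reads.

    Candidate intervals are maximal pieces of read blocks not covered by any
    annotated part; candidates are clustered by overlap and a cluster with at
    least ``min_support_reads`` supporting reads emits one novel part whose
    boundaries are the modal observed start and end.  All parts are then
    renumbered by genomic coordinate.
    """
    chrom = flat.gene.chrom
    annotated = merge_intervals(
        [(p.interval.start, p.interval.end) for p in flat.parts]
    )
    candidates: list[tuple[int, int, str]] = []  # (start, end, read_id)
    for read in reads:
        if read.chrom != chrom:
            continue
        for block in read.blocks:
            for s, e in subtract_intervals((block.start, block.end), annotated):
                if e - s >= min_length:
                    candidates.append((s, e, read.read_id))

    if not candidates:
        return flat

    # Cluster by any-overlap via a sort-sweep over candidate intervals.
    candidates.sort()
    clusters: list[list[tuple[int, int, str]]] = []
    cur_end = None
    for cand in candidates:
        if cur_end is not None and cand[0] < cur_end:
            clusters[-1].append(cand)
            cur_end = max(cur_end, cand[1])
        else:
            clusters.append([cand])
            cur_end = cand[1]

    novel: list[ExonicPart] = []
    for cluster in clusters:
        supporting = {read_id for _, _, read_id in cluster}
        if len(supporting) < min_support_reads:
            continue
        start = _mode(c[0] for c in cluster)
        end = _mode(c[1] for c in cluster)
        novel.append(
            ExonicPart(
                gene_id=flat.gene.gene_id,
                part_index=1,  # placeholder, renumbered below
                interval=GenomicInterval(chrom, start, end, flat.gene.strand),
                source="novel",
            )
        )

    if not novel:
        return flat
    parts = renumber_parts(flat.gene.gene_id, list(flat.parts) + novel)
    return FlattenedGene(gene=flat.gene, parts=parts)


def _mode(values) -> int:
    """Most frequent value; ties broken toward the smallest."""
    counts: dict[int, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return min(counts, key=lambda v: (-counts[v], v))


def psi_table(
    reads_by_sample: dict[str, list[ConsensusRead]],
    flat: FlattenedGene,
    boundary_slop: int = DEFAULT_BOUNDARY_SLOP,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[PsiRecord]:
    """FL-weighted PSI per (sample, exonic part).

    MATCHING reads enter the numerator; MATCHING plus SKIPPING reads the
    denominator; NON_INFORMATIVE reads (truncated inside or short of the
    part) enter neither.  Consensus-read and FL tallies are kept side by
    side; PSI uses the FL counts.
    """
    records: list[PsiRecord] = []
    for sample in sorted(reads_by_sample):
        reads = reads_by_sample[sample]
        for part in flat.parts:
            m_cons = m_fl = t_cons = t_fl = 0
            for read in reads:
                cls = classify_read_for_part(read, part, boundary_slop, min_overlap)
                if cls is PartReadClass.NON_INFORMATIVE:
                    continue
                t_cons += 1
                t_fl += read.fl_count
                if cls is PartReadClass.MATCHING:
                    m_cons += 1
                    m_fl += read.fl_count
            records.append(
                PsiRecord(
                    gene_id=flat.gene.gene_id,
                    part=part,
                    sample=sample,
                    matching_consensus=m_cons,
                    total_consensus=t_cons,
                    matching_fl=m_fl,
                    total_fl=t_fl,
                )
            )
    return records


def filter_candidates(
    records: list[PsiRecord],
    min_gene_consensus: int = DEFAULT_MIN_GENE_CONSENSUS,
    min_part_consensus: int = DEFAULT_MIN_PART_CONSENSUS,
    min_psi_delta: float = DEFAULT_MIN_PSI_DELTA,
    gene_consensus: dict[str, int] | None = None,
) -> list[CandidateExon]:
    """Apply the differential-usage filter cascade.

    A gene is eligible when the consensus reads overlapping it, summed over
    samples, reach ``min_gene_consensus`` (supply ``gene_consensus`` with the
    true per-gene read tallies; otherwise the best per-part total is used as
    a lower bound).  A part is evaluated when at least two samples reach
    ``min_part_consensus`` consensus reads over it, and passes when the
    largest pairwise PSI difference among those coverage-eligible samples is
    at least ``min_psi_delta`` percentage points.  Unrounded PSI values are
    compared.
    """
    by_part: dict[tuple[str, int], list[PsiRecord]] = {}
    for rec in records:
        by_part.setdefault((rec.gene_id, rec.part.part_index), []).append(rec)

    if gene_consensus is None:
        gene_consensus = {}
        for (gene_id, _), recs in by_part.items():
            total = sum(r.total_consensus for r in recs)
            gene_consensus[gene_id] = max(gene_consensus.get(gene_id, 0), total)

    out: list[CandidateExon] = []
    for (gene_id, part_index) in sorted(by_part):
        recs = sorted(by_part[(gene_id, part_index)], key=lambda r: r.sample)
        if gene_consensus.get(gene_id, 0) < min_gene_consensus:
            continue
        eligible = [
            r
            for r in recs
            if r.total_consensus >= min_part_consensus and r.psi_percent is not None
        ]
        delta: float | None = None
        if len(eligible) >= 2:
            psis = [r.psi_percent for r in eligible]
            delta = max(psis) - min(psis)
        out.append(
            CandidateExon(
                gene_id=gene_id,
                part=recs[0].part,
                records=tuple(recs),
                max_pairwise_psi_delta=delta,
                passes_filters=delta is not None and delta >= min_psi_delta,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "gene_id",
    "part_id",
    "source",
    "chrom",
    "start",
    "end",
    "sample",
    "matching_consensus",
    "total_consensus",
    "matching_fl",
    "total_fl",
    "psi_percent",
]


def coverage_frame(records: list[PsiRecord]) -> pd.DataFrame:
    """PSI records as a DataFrame, sorted (gene, part, sample)."""
    rows = [
        {
            "gene_id": r.gene_id,
            "part_id": r.part.part_id,
            "source": r.part.source,
            "chrom": r.part.interval.chrom,
            "start": r.part.interval.start,
            "end": r.part.interval.end,
            "sample": r.sample,
            "matching_consensus": r.matching_consensus,
            "total_consensus": r.total_consensus,
            "matching_fl": r.matching_fl,
            "total_fl": r.total_fl,
            "psi_percent": (
                None if r.psi_percent is None else round(r.psi_percent, 1)
            ),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    if not df.empty:
        df = df.sort_values(["gene_id", "part_id", "sample"], kind="mergesort")
        df = df.reset_index(drop=True)
    return df


def coverage_report(records: list[PsiRecord], path: str) -> pd.DataFrame:
    """Write the per-(gene, part, sample) PSI table as TSV; PSI rendered to
    one decimal, undefined PSI rendered "NA"."""
    df = coverage_frame(records)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return df


def candidate_report(candidates: list[CandidateExon], path: str) -> pd.DataFrame:
    rows = []
    for c in candidates:
        psis = {
            r.sample: (None if r.psi_percent is None else round(r.psi_percent, 1))
            for r in c.records
        }
        rows.append(
            {
                "gene_id": c.gene_id,
                "part_id": c.part.part_id,
                "source": c.part.source,
                "chrom": c.part.interval.chrom,
                "start": c.part.interval.start,
                "end": c.part.interval.end,
                "max_psi_delta": (
                    None
                    if c.max_pairwise_psi_delta is None
                    else round(c.max_pairwise_psi_delta, 1)
                ),
                "passes_filters": c.passes_filters,
                "psi_by_sample": ";".join(
                    f"{s}={'NA' if v is None else v}" for s, v in sorted(psis.items())
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "part_id",
            "source",
            "chrom",
            "start",
            "end",
            "max_psi_delta",
            "passes_filters",
            "psi_by_sample",
        ],
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return df


def novel_parts_bed(flat: FlattenedGene, path: str) -> int:
    """Write read-discovered parts as BED (0-based half-open); returns count."""
    n = 0
    with open(path, "w") as fh:
        for p in flat.parts:
            if p.source != "novel":
                continue
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{p.label}\t0\t{p.interval.strand if p.interval.strand != '.' else '+'}\n"
            )
            n += 1
    return n


def coverage_plot(records: list[PsiRecord], path: str) -> None:
    """Stacked FL-coverage bars per exonic part with a PSI line per sample."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = coverage_frame(records)
    if df.empty:
        raise ValueError("no PSI records to plot")
    fig, (ax_psi, ax_cov) = plt.subplots(
        2, 1, sharex=True, figsize=(max(6, df["part_id"].nunique() * 0.5), 6)
    )
    parts = sorted(df["part_id"].unique())
    x = range(len(parts))
    for sample, sub in df.groupby("sample"):
        sub = sub.set_index("part_id").reindex(parts)
        ax_psi.plot(x, sub["psi_percent"], marker="o", label=sample)
        ax_cov.bar(
            x,
            sub["total_fl"].fillna(0),
            alpha=0.5,
            label=sample,
        )
    ax_psi.set_ylabel("PSI (%)")
    ax_psi.set_ylim(-5, 105)
    ax_psi.legend(fontsize="small")
    ax_cov.set_ylabel("total FL reads")
    ax_cov.set_xticks(list(x))
    ax_cov.set_xticklabels(parts, rotation=90, fontsize="small")
    ax_cov.set_xlabel("exonic part")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
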