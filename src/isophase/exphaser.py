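"""Cassette-exon phasing and pattern-to-transcript matching (exPhaser).

Given a set of target cassette exons inside one gene, each consensus read
that spans the whole target region yields a binary inclusion vector (one bit
per exon).  Vectors are tallied with FL-read weights per sample, matched
against the inclusion vectors of annotated transcripts, and reported as
relative isoform percentages:

    percent(pattern) = 100 * FL(pattern) / FL(all phased patterns in sample)

Reads that do not span the full region cannot phase unseen exons and are
rejected, so internally-primed 3'-truncated reads never distort the tallies.
Exons farther apart than a read length must be phased in separate runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .annotation import TranscriptModel
from .excovator import (
    DEFAULT_BOUNDARY_SLOP,
    DEFAULT_MIN_OVERLAP,
    PartReadClass,
    classify_read_for_part,
)
from .annotation import ExonicPart
from .intervals import GenomicInterval
from .reads import ConsensusRead

logger = logging.getLogger(__name__)

UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class TargetExonSet:
    """Ordered, labelled cassette-exon intervals to phase jointly."""

    gene_id: str
    exons: tuple[tuple[str, GenomicInterval], ...]

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.exons]
        if len(set(labels)) != len(labels):
            raise ValueError("target exon labels must be unique")
        ivs = [iv for _, iv in self.exons]
        if ivs != sorted(ivs, key=lambda iv: (iv.start, iv.end)):
            raise ValueError("target exons must be sorted by coordinate")
        chroms = {iv.chrom for iv in ivs}
        if len(chroms) != 1:
            raise ValueError("target exons must share one chromosome")

    @property
    def chrom(self) -> str:
        return self.exons[0][1].chrom

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.exons)

    @property
    def region(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(iv.start for _, iv in self.exons),
            max(iv.end for _, iv in self.exons),
        )

    @classmethod
    def from_bed(cls, path: str, gene_id: str = "") -> "TargetExonSet":
        """Read target exons from a BED file (0-based half-open).

        Column 4 supplies the exon label; unnamed rows are labelled by
        1-based rank.  Warns when the region exceeds 10 kb, the nominal
        maximum read length, since no read could phase such a set.
        """
        exons = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path} line {lineno}: fewer than 3 BED columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                label = fields[3] if len(fields) > 3 else str(lineno)
                exons.append((label, GenomicInterval(chrom, start, end)))
        exons.sort(key=lambda t: (t[1].start, t[1].end))
        targets = cls(gene_id=gene_id, exons=tuple(exons))
        if len(targets.region) > 10_000:
            logger.warning(
                "target region spans %d bases; reads are unlikely to phase it",
                len(targets.region),
            )
        return targets


@dataclass(frozen=True)
class PhasePattern:
    """One observed inclusion vector with its tallies and matching isoforms."""

    inclusion: tuple[int, ...]
    consensus_count: int
    fl_count: int
    matched_transcripts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.consensus_count < 0 or self.fl_count < 0:
            raise ValueError("pattern counts must be >= 0")
        if any(b not in (0, 1) for b in self.inclusion):
            raise ValueError("inclusion vector must be binary")

    @property
    def pattern_string(self) -> str:
        return "-".join(str(b) for b in self.inclusion)


@dataclass(frozen=True)
class PhaseReport:
    """Per-sample phased pattern tallies for one target exon set."""

    targets: TargetExonSet
    patterns: dict[str, tuple[PhasePattern, ...]]  # sample -> patterns

    def percents(self, sample: str) -> dict[tuple[int, ...], float]:
        pats = self.patterns.get(sample, ())
        total = sum(p.fl_count for p in pats)
        if total == 0:
            return {}
        return {p.inclusion: 100.0 * p.fl_count / total for p in pats}


def _exon_as_part(gene_id: str, index: int, iv: GenomicInterval) -> ExonicPart:
    return ExonicPart(gene_id=gene_id or "target", part_index=index, interval=iv)


def read_pattern(
    read: ConsensusRead,
    targets: TargetExonSet,
    boundary_slop: int = DEFAULT_BOUNDARY_SLOP,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[int, ...] | None:
    """Inclusion vector of the target exons within one read, or None (reject).

    The read must span the whole target region: truncated reads cannot
    witness exons they never covered.  Each exon must classify cleanly as
    contained (1) or spliced out (0); any ambiguous exon rejects the read.
    """
    if read.chrom != targets.chrom:
        return None
    region = targets.region
    span = read.span
    if span.start > region.start or span.end < region.end:
        return None
    bits = []
    for i, (label, iv) in enumerate(targets.exons, start=1):
        cls = classify_read_for_part(
            read, _exon_as_part(targets.gene_id, i, iv), boundary_slop, min_overlap
        )
        if cls is PartReadClass.MATCHING:
            bits.append(1)
        elif cls is PartReadClass.SKIPPING:
            bits.append(0)
        else:
            return None
    return tuple(bits)


def transcript_pattern(
    tx: TranscriptModel,
    targets: TargetExonSet,
    boundary_slop: int = DEFAULT_BOUNDARY_SLOP,
) -> tuple[int, ...] | None:
    """Inclusion vector of an annotated transcript, or None (not applicable).

    Transcripts that do not span the target region are not comparable and
    return None so that short transcripts are never spuriously matched.
    Bit i is 1 iff some transcript exon covers target exon i within
    ``boundary_slop`` at each edge.
    """
    if tx.chrom != targets.chrom:
        return None
    region = targets.region
    span = tx.span
    if span.start > region.start or span.end < region.end:
        return None
    bits = []
    for _, iv in targets.exons:
        covered = any(
            exon.overlap(iv) > 0
            and max(0, exon.start - iv.start) <= boundary_slop
            and max(0, iv.end - exon.end) <= boundary_slop
            for exon in tx.exons
        )
        bits.append(1 if covered else 0)
    return tuple(bits)


def phase(
    reads_by_sample: dict[str, list[ConsensusRead]],
    targets: TargetExonSet,
    annotation: list[TranscriptModel] = (),
    boundary_slop: int = DEFAULT_BOUNDARY_SLOP,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> PhaseReport:
    """Phase target exons in every sample and match patterns to transcripts.

    Patterns are sorted by descending FL count, ties by lexicographic
    inclusion vector.  A pattern matched by no transcript is unannotated;
    one matched by several is ambiguous given these exons, and all matches
    are listed.  A sample with no phaseable read yields an empty tuple.
    """
    tx_patterns: dict[tuple[int, ...], list[str]] = {}
    for tx in annotation:
        vec = transcript_pattern(tx, targets, boundary_slop)
        if vec is not None:
            tx_patterns.setdefault(vec, []).append(tx.transcript_id)

    report: dict[str, tuple[PhasePattern, ...]] = {}
    for sample in sorted(reads_by_sample):
        tallies: dict[tuple[int, ...], list[int]] = {}
        for read in reads_by_sample[sample]:
            vec = read_pattern(read, targets, boundary_slop, min_overlap)
            if vec is None:
                continue
            entry = tallies.setdefault(vec, [0, 0])
            entry[0] += 1
            entry[1] += read.fl_count
        if not tallies:
            logger.warning("sample %s: no read phases the target region", sample)
        patterns = [
            PhasePattern(
                inclusion=vec,
                consensus_count=n_cons,
                fl_count=n_fl,
                matched_transcripts=tuple(sorted(tx_patterns.get(vec, ()))),
            )
            for vec, (n_cons, n_fl) in tallies.items()
        ]
        patterns.sort(key=lambda p: (-p.fl_count, p.inclusion))
        report[sample] = tuple(patterns)
    return PhaseReport(targets=targets, patterns=report)


def phase_report_tsv(report: PhaseReport, path: str) -> None:
    """Write per-sample pattern tallies, percentages and matched isoforms."""
    header = (
        "sample\tpattern\tconsensus_count\tfl_count\tpercent\tmatched_transcripts\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for sample in sorted(report.patterns):
            pats = report.patterns[sample]
            total_fl = sum(p.fl_count for p in pats)
            for p in pats:
                percent = 100.0 * p.fl_count / total_fl if total_fl else 0.0
                matched = (
                    ",".join(p.matched_transcripts)
                    if p.matched_transcripts
                    else UNANNOTATED
                )
                fh.write(
                    f"{sample}\t{p.pattern_string}\t{p.consensus_count}\t"
                    f"{p.fl_count}\t{percent:.1f}\t{matched}\n"
                )
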