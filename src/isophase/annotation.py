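"""Gene models from GTF and per-gene exonic-part flattening.

A gene's transcripts are collapsed into a single *metatranscript*: the union
of all exons, split at every annotated exon boundary into disjoint *exonic
parts* numbered 1..k in increasing genomic coordinate (rendered zero-padded,
e.g. part 38 -> "038").  This mirrors the DEXSeq flattened-annotation
convention, applied per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gffutils.feature

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


class GtfParseError(ValueError):
    """Raised when a GTF/GFF line cannot be interpreted."""


@dataclass(frozen=True)
class TranscriptModel:
    """One annotated transcript: an ordered chain of exon intervals."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(
                f"transcript {self.transcript_id} spans chromosomes {chroms}"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id} exons overlap or are unsorted"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with >=1 transcript models on one chromosome."""

    gene_id: str
    gene_name: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)


@dataclass(frozen=True)
class ExonicPart:
    """A disjoint sub-exon interval of a gene's metatranscript.

    ``part_index`` is the 1-based ordinal in genomic coordinate order; it is
    rendered 3-digit zero-padded ("EP 038").  ``source`` is "annotated" for
    parts derived from the GTF and "novel" for read-discovered parts.
    """

    gene_id: str
    part_index: int
    interval: GenomicInterval
    source: str = "annotated"
    source_exon_labels: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.part_index < 1:
            raise ValueError("part_index must be >= 1")
        if self.source not in ("annotated", "novel"):
            raise ValueError(f"unknown part source {self.source!r}")

    @property
    def part_id(self) -> str:
        return f"{self.part_index:03d}"

    @property
    def label(self) -> str:
        return f"{self.gene_id}:EP{self.part_id}"


@dataclass(frozen=True)
class FlattenedGene:
    """A gene plus its ordered, disjoint exonic parts."""

    gene: GeneModel
    parts: tuple[ExonicPart, ...]

    def part_by_id(self, part_id: str) -> ExonicPart:
        for p in self.parts:
            if p.part_id == part_id or str(p.part_index) == part_id:
                return p
        raise KeyError(f"no exonic part {part_id!r} in {self.gene.gene_id}")


# ---------------------------------------------------------------------------
# GTF parsing
# ---------------------------------------------------------------------------


def _parse_gtf_line(line: str, lineno: int) -> gffutils.feature.Feature:
    if line.count("\t") != 8:
        raise GtfParseError(
            f"line {lineno}: expected 9 tab-separated GTF columns, "
            f"found {line.count(chr(9)) + 1}"
        )
    try:
        return gffutils.feature.feature_from_line(line)
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise GtfParseError(f"line {lineno}: cannot parse GTF record: {exc}") from exc


def load_gtf(
    path: str, feature_filter: set[str] | None = None
) -> list[GeneModel]:
    """Parse a GENCODE-dialect GTF into per-gene transcript models.

    Only ``exon`` features are consumed; each must carry ``gene_id`` and
    ``transcript_id`` attributes.  GTF 1-based inclusive coordinates are
    converted to internal 0-based half-open.  ``feature_filter`` optionally
    restricts the result to the given gene_ids.

    Zero-length and duplicate exon records are dropped with a warning;
    overlapping exons within one transcript are merged with a warning.
    """
    exons: dict[str, dict[str, list[GenomicInterval]]] = {}
    gene_names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = _parse_gtf_line(line, lineno)
            if feat.featuretype != "exon":
                continue
            attrs = feat.attributes
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon without gene_id")
            if "transcript_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon without transcript_id")
            gene_id = attrs["gene_id"][0]
            if feature_filter is not None and gene_id not in feature_filter:
                continue
            tx_id = attrs["transcript_id"][0]
            if "gene_name" in attrs:
                gene_names[gene_id] = attrs["gene_name"][0]
            start0 = feat.start - 1  # GTF is 1-based inclusive
            end0 = feat.end
            if end0 <= start0:
                logger.warning("line %d: zero-length exon dropped", lineno)
                continue
            strand = feat.strand if feat.strand in ("+", "-") else "."
            iv = GenomicInterval(feat.seqid, start0, end0, strand)
            tx_exons = exons.setdefault(gene_id, {}).setdefault(tx_id, [])
            if iv in tx_exons:
                logger.warning("line %d: duplicate exon record dropped", lineno)
                continue
            tx_exons.append(iv)

    genes: list[GeneModel] = []
    for gene_id in sorted(exons):
        transcripts = []
        for tx_id in sorted(exons[gene_id]):
            ivs = sorted(exons[gene_id][tx_id], key=lambda e: (e.start, e.end))
            clean: list[GenomicInterval] = []
            for iv in ivs:
                if clean and iv.start < clean[-1].end:
                    logger.warning(
                        "transcript %s: overlapping exons merged", tx_id
                    )
                    prev = clean.pop()
                    iv = GenomicInterval(
                        iv.chrom, prev.start, max(prev.end, iv.end), iv.strand
                    )
                clean.append(iv)
            transcripts.append(
                TranscriptModel(tx_id, gene_id, tuple(clean))
            )
        genes.append(
            GeneModel(gene_id, gene_names.get(gene_id, gene_id), tuple(transcripts))
        )
    return genes


# ---------------------------------------------------------------------------
# Flattening
# ---------------------------------------------------------------------------


def flatten_gene(gene: GeneModel) -> FlattenedGene:
    """Collapse a gene into disjoint exonic parts (its metatranscript).

    Parts are the maximal intervals between consecutive distinct exon
    boundary coordinates, restricted to exon-covered bases, so every
    annotated exon boundary coincides with a part boundary.
    """
    labelled: list[tuple[GenomicInterval, str, int]] = []
    for tx in gene.transcripts:
        for ordinal, exon in enumerate(tx.exons, start=1):
            labelled.append((exon, tx.transcript_id, ordinal))

    boundaries = sorted({c for exon, _, _ in labelled for c in (exon.start, exon.end)})
    parts: list[ExonicPart] = []
    idx = 0
    for s, e in zip(boundaries, boundaries[1:]):
        covering = tuple(
            sorted(
                (tx_id, ordinal)
                for exon, tx_id, ordinal in labelled
                if exon.start <= s and e <= exon.end
            )
        )
        if not covering:
            continue
        idx += 1
        parts.append(
            ExonicPart(
                gene_id=gene.gene_id,
                part_index=idx,
                interval=GenomicInterval(gene.chrom, s, e, gene.strand),
                source="annotated",
                source_exon_labels=covering,
            )
        )
    return FlattenedGene(gene=gene, parts=tuple(parts))


def renumber_parts(
    gene_id: str, parts: list[ExonicPart]
) -> tuple[ExonicPart, ...]:
    """Re-assign part_index 1..k in increasing genomic coordinate."""
    ordered = sorted(parts, key=lambda p: (p.interval.start, p.interval.end))
    return tuple(
        replace(p, part_index=i) for i, p in enumerate(ordered, start=1)
    )


# ---------------------------------------------------------------------------
# Flattened-GFF I/O
# ---------------------------------------------------------------------------


def write_flattened_gff(flat: list[FlattenedGene], path: str) -> None:
    """Write flattened genes as a DEXSeq-style GFF.

    One ``aggregate_gene`` feature per gene plus one ``exonic_part`` per
    part.  Coordinates are written 1-based inclusive; part ids are 3-digit
    zero-padded so a reload reproduces identical parts.
    """
    with open(path, "w") as fh:
        for fg in flat:
            g = fg.gene
            span = g.span
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "isophase",
                        "aggregate_gene",
                        str(span.start + 1),
                        str(span.end),
                        ".",
                        g.strand if g.strand != "." else ".",
                        ".",
                        f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"',
                    ]
                )
                + "\n"
            )
            for p in fg.parts:
                labels = ",".join(f"{t}:{o}" for t, o in p.source_exon_labels)
                attrs = (
                    f'gene_id "{p.gene_id}"; exonic_part_number "{p.part_id}"; '
                    f'source_class "{p.source}"'
                )
                if labels:
                    attrs += f'; source_exons "{labels}"'
                fh.write(
                    "\t".join(
                        [
                            p.interval.chrom,
                            "isophase",
                            "exonic_part",
                            str(p.interval.start + 1),
                            str(p.interval.end),
                            ".",
                            p.interval.strand if p.interval.strand != "." else ".",
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def load_flattened_gff(path: str) -> dict[str, tuple[ExonicPart, ...]]:
    """Read a flattened GFF back into per-gene exonic-part lists."""
    parts: dict[str, list[ExonicPart]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = _parse_gtf_line(line, lineno)
            if feat.featuretype != "exonic_part":
                continue
            attrs = feat.attributes
            gene_id = attrs["gene_id"][0]
            labels = ()
            if "source_exons" in attrs:
                # gffutils splits the comma-separated value into list items
                tokens = [
                    tok for item in attrs["source_exons"] for tok in item.split(",")
                ]
                labels = tuple(
                    (t, int(o)) for t, o in (tok.rsplit(":", 1) for tok in tokens)
                )
            strand = feat.strand if feat.strand in ("+", "-") else "."
            parts.setdefault(gene_id, []).append(
                ExonicPart(
                    gene_id=gene_id,
                    part_index=int(attrs["exonic_part_number"][0]),
                    interval=GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand),
                    source=attrs.get("source_class", ["annotated"])[0],
                    source_exon_labels=labels,
                )
            )
    return {g: tuple(sorted(ps, key=lambda p: p.part_index)) for g, ps in parts.items()}


def strand_aware_part_id(part: ExonicPart, total_parts: int) -> str:
    """Display-only renderer numbering parts 5'->3' on the gene's strand."""
    if part.interval.strand == "-":
        return f"{total_parts - part.part_index + 1:03d}"
    return part.part_id
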