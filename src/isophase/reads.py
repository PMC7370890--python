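"""Aligned Iso-Seq consensus reads: block reconstruction and FL multiplicities.

Each SAM/BAM record is one polished consensus (cluster) read.  Its exonic
structure is recovered from the CIGAR (N gaps are introns) and its weight is
the number of full-length (FL) reads that supported the cluster, taken from a
sidecar TSV or from Iso-Seq read-name conventions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pysam

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
# Iso-Seq cluster naming: ".../f8p2/..." carries FL support 8; newer
# pipelines embed "full_length_coverage=8".
_FL_TOKEN_RE = re.compile(r"(?:^|/)f(\d+)p(\d+)(?:/|$)")
_FL_KV_RE = re.compile(r"full_length_coverage=(\d+)")


@dataclass(frozen=True)
class ConsensusRead:
    """One aligned consensus read with its exonic blocks and FL weight."""

    read_id: str
    sample: str
    chrom: str
    strand: str
    blocks: tuple[GenomicInterval, ...]
    fl_count: int

    def __post_init__(self) -> None:
        if self.fl_count < 0:
            raise ValueError("fl_count must be >= 0")
        if not self.blocks:
            raise ValueError("read must have >= 1 aligned block")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start < a.end:
                raise ValueError(f"read {self.read_id}: blocks overlap/unsorted")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.blocks[0].start, self.blocks[-1].end, self.strand
        )

    def junctions(self) -> list[tuple[int, int]]:
        """(donor_end, acceptor_start) pairs between consecutive blocks."""
        return [
            (a.end, b.start) for a, b in zip(self.blocks, self.blocks[1:])
        ]


@dataclass(frozen=True)
class SpliceJunction:
    chrom: str
    donor_end: int
    acceptor_start: int
    consensus_support: int
    fl_support: int

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ValueError("junction donor_end must precede acceptor_start")
        if self.consensus_support < 1 or self.fl_support < 1:
            raise ValueError("junction supports must be >= 1")


class FlCountTable(dict):
    """read_id -> FL count mapping (a sidecar for SAM files)."""

    @classmethod
    def from_tsv(cls, path: str) -> "FlCountTable":
        table = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(
                        f"{path} line {lineno}: expected 2 tab-separated columns"
                    )
                if fields[0] == "read_id":  # optional header
                    continue
                count = int(fields[1])
                if count < 0:
                    raise ValueError(
                        f"{path} line {lineno}: negative FL count {count}"
                    )
                table[fields[0]] = count
        return table


def cigar_to_blocks(reference_start: int, cigar: str) -> list[GenomicInterval]:
    """Reconstruct aligned exonic blocks from a CIGAR string.

    M/=/X and D advance the reference within the current block; N closes the
    block (intron); I/S/H/P consume no reference.  ``reference_start`` is
    0-based.  Chromosome/strand are unknown at this level; callers re-wrap
    the coordinates.
    """
    consumed = sum(len(m.group(0)) for m in _CIGAR_RE.finditer(cigar))
    if consumed != len(cigar):
        raise ValueError(f"unparseable CIGAR {cigar!r}")
    blocks: list[tuple[int, int]] = []
    pos = reference_start
    block_start: int | None = None
    for m in _CIGAR_RE.finditer(cigar):
        length, op = int(m.group(1)), m.group(2)
        if op in "M=XD":
            if block_start is None:
                block_start = pos
            pos += length
        elif op == "N":
            if block_start is not None:
                blocks.append((block_start, pos))
                block_start = None
            pos += length
        elif op in "ISHP":
            pass
        else:  # pragma: no cover - regex restricts ops
            raise ValueError(f"unknown CIGAR op {op!r}")
    if block_start is not None:
        blocks.append((block_start, pos))
    return [GenomicInterval("_", s, e) for s, e in blocks]


def parse_fl_count(
    read_name: str, sidecar: FlCountTable | None = None
) -> int:
    """FL multiplicity of a consensus read.

    Precedence: sidecar table > Iso-Seq "f<k>p<j>" token >
    "full_length_coverage=<k>" token > 1 (with a warning).
    """
    if not read_name:
        raise ValueError("empty read name")
    if sidecar is not None and read_name in sidecar:
        count = sidecar[read_name]
        if count < 0:
            raise ValueError(f"negative FL count for {read_name}")
        return count
    m = _FL_TOKEN_RE.search(read_name)
    if m:
        return int(m.group(1))
    m = _FL_KV_RE.search(read_name)
    if m:
        return int(m.group(1))
    logger.warning(
        "read %s: no FL count available, defaulting to 1", read_name
    )
    return 1


def load_reads(
    path: str,
    sample_label: str,
    fl_sidecar: str | FlCountTable | None = None,
    min_mapq: int = 0,
    reference_names: set[str] | None = None,
) -> list[ConsensusRead]:
    """Load primary alignments from a SAM/BAM file as ConsensusReads.

    Secondary, supplementary and unmapped records are excluded, as are
    records below ``min_mapq``.  ``reference_names``, when given, is the set
    of chromosomes known to the annotation; reads on other references are
    kept with a warning (they simply fail all overlap queries).
    """
    sidecar: FlCountTable | None
    if isinstance(fl_sidecar, str):
        sidecar = FlCountTable.from_tsv(fl_sidecar)
    else:
        sidecar = fl_sidecar
    reads: list[ConsensusRead] = []
    warned_refs: set[str] = set()
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            chrom = rec.reference_name
            if (
                reference_names is not None
                and chrom not in reference_names
                and chrom not in warned_refs
            ):
                logger.warning(
                    "read %s maps to %s, absent from the annotation",
                    rec.query_name,
                    chrom,
                )
                warned_refs.add(chrom)
            strand = "-" if rec.is_reverse else "+"
            blocks = tuple(
                GenomicInterval(chrom, b.start, b.end, strand)
                for b in cigar_to_blocks(rec.reference_start, rec.cigarstring)
            )
            reads.append(
                ConsensusRead(
                    read_id=rec.query_name,
                    sample=sample_label,
                    chrom=chrom,
                    strand=strand,
                    blocks=blocks,
                    fl_count=parse_fl_count(rec.query_name, sidecar),
                )
            )
    return reads


def junction_table(
    reads: list[ConsensusRead], min_support: int = 5
) -> list[SpliceJunction]:
    """Tally distinct splice junctions across reads.

    A junction is a (chrom, donor_end, acceptor_start) triple; its consensus
    support is the number of reads containing it and its FL support the sum
    of their FL counts.  Junctions below ``min_support`` consensus reads are
    dropped (the sashimi-display convention).
    """
    tally: dict[tuple[str, int, int], list[int]] = {}
    for read in reads:
        for donor_end, acceptor_start in read.junctions():
            key = (read.chrom, donor_end, acceptor_start)
            entry = tally.setdefault(key, [0, 0])
            entry[0] += 1
            entry[1] += read.fl_count
    return [
        SpliceJunction(chrom, d, a, n_cons, n_fl)
        for (chrom, d, a), (n_cons, n_fl) in sorted(tally.items())
        if n_cons >= min_support
    ]


def write_junction_tsv(junctions: list[SpliceJunction], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tdonor_end\tacceptor_start\tconsensus_support\tfl_support\n")
        for j in junctions:
            fh.write(
                f"{j.chrom}\t{j.donor_end}\t{j.acceptor_start}\t"
                f"{j.consensus_support}\t{j.fl_support}\n"
            )
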