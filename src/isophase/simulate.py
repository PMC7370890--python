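"""Self-contained synthetic Iso-Seq fixtures from declarative scenarios.

A :class:`SyntheticScenario` declares toy genes on a toy genome, per-sample
exon-inclusion patterns with consensus-read and FL-read counts, oligo(dT)
internal-priming sites (planted genomic A-runs), and a size-selection
window.  From it the generator emits a FASTA genome, a GTF annotation, one
aligned SAM per sample, an FL-count sidecar TSV, and an exact truth table of
expected PSI records and phase patterns - everything needed to exercise the
pipeline with no sequencing data.

Reads whose mature transcript exceeds the size window are 3'-anchored either
at the poly(A) end or (with a configurable probability) at an internal
priming site - ending 0-20 bases upstream of the planted A-run, as
internally-primed cDNAs do - and then 5'-trimmed into the window.  With the
noise rate at 0, CIGARs are exact (pure M/N) and the truth table follows
from integer arithmetic over the realized read layouts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GeneModel, TranscriptModel, flatten_gene
from .intervals import GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

PRIMING_RUN_LENGTH = 10  # planted A-run length (>= the 8-base motif)
PRIMING_MAX_UPSTREAM = 20  # reads end within 20 bases upstream of the run
_ACCIDENTAL_RUN_LIMIT = 6  # background sequence never reaches this run length


@dataclass(frozen=True)
class GeneSpec:
    """A toy gene: an exon catalog plus transcripts as exon-index subsets."""

    gene_id: str
    chrom: str
    exons: tuple[tuple[int, int], ...]
    transcripts: dict[str, tuple[int, ...]]
    gene_name: str = ""
    strand: str = "+"

    def exon_chain(self, indices: tuple[int, ...]) -> list[tuple[int, int]]:
        ivs = sorted(self.exons[i] for i in indices)
        return merge_intervals(list(ivs))


@dataclass(frozen=True)
class PatternSpec:
    """Requested reads realizing one exon-inclusion pattern in one sample.

    ``isoform`` names a transcript of the gene, or ``exons`` gives an
    explicit exon-index set (allowing unannotated patterns).  Each of the
    ``consensus_reads`` reads carries ``fl_per_read`` FL multiplicity (an
    int, or a per-read list of length ``consensus_reads``).
    """

    gene_id: str
    consensus_reads: int
    fl_per_read: int | tuple[int, ...] = 1
    isoform: str | None = None
    exons: tuple[int, ...] | None = None

    def fl_counts(self) -> list[int]:
        if isinstance(self.fl_per_read, int):
            return [self.fl_per_read] * self.consensus_reads
        if len(self.fl_per_read) != self.consensus_reads:
            raise ValueError(
                f"pattern on {self.gene_id}: fl_per_read list length "
                f"{len(self.fl_per_read)} != consensus_reads {self.consensus_reads}"
            )
        return list(self.fl_per_read)


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    patterns: tuple[PatternSpec, ...]


@dataclass(frozen=True)
class SyntheticScenario:
    """Declarative description of a complete synthetic study."""

    genes: tuple[GeneSpec, ...]
    samples: tuple[SampleSpec, ...]
    chrom_lengths: dict[str, int]
    priming_sites: tuple[tuple[str, int], ...] = ()
    size_window: tuple[int, int] | None = None
    internal_prime_prob: float = 0.5
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def gene(self, gene_id: str) -> GeneSpec:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def validate(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chrom_lengths:
                raise ValueError(f"gene {g.gene_id}: unknown chrom {g.chrom}")
            for s, e in g.exons:
                if not (0 <= s < e <= self.chrom_lengths[g.chrom]):
                    raise ValueError(
                        f"gene {g.gene_id}: exon ({s},{e}) outside chromosome"
                    )
            for tx_id, idxs in g.transcripts.items():
                for i in idxs:
                    if not 0 <= i < len(g.exons):
                        raise ValueError(
                            f"transcript {tx_id}: undefined exon index {i}"
                        )
        gene_ids = {g.gene_id for g in self.genes}
        for sample in self.samples:
            for pat in sample.patterns:
                if pat.gene_id not in gene_ids:
                    raise ValueError(f"pattern references unknown gene {pat.gene_id}")
                if pat.consensus_reads < 0:
                    raise ValueError("consensus_reads must be >= 0")
                if any(f < 0 for f in pat.fl_counts()):
                    raise ValueError("FL counts must be >= 0")
                gene = self.gene(pat.gene_id)
                if (pat.isoform is None) == (pat.exons is None):
                    raise ValueError(
                        f"pattern on {pat.gene_id}: give exactly one of isoform/exons"
                    )
                if pat.isoform is not None and pat.isoform not in gene.transcripts:
                    raise ValueError(
                        f"pattern references unknown transcript {pat.isoform}"
                    )
                if pat.exons is not None:
                    for i in pat.exons:
                        if not 0 <= i < len(gene.exons):
                            raise ValueError(
                                f"pattern on {pat.gene_id}: undefined exon index {i}"
                            )
        sites = sorted(
            (chrom, pos) for chrom, pos in self.priming_sites
        )
        for (c1, p1), (c2, p2) in zip(sites, sites[1:]):
            if c1 == c2 and p1 + PRIMING_RUN_LENGTH > p2:
                raise ValueError(f"planted A-runs at {c1}:{p1} and {p2} overlap")
        for chrom, pos in sites:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"priming site on unknown chrom {chrom}")
            if pos + PRIMING_RUN_LENGTH > self.chrom_lengths[chrom]:
                raise ValueError(f"priming site {chrom}:{pos} beyond chromosome end")
        if self.size_window is not None:
            lo, hi = self.size_window
            if not 0 < lo < hi:
                raise ValueError("size_window must be (min, max) with 0 < min < max")
        if not 0.0 <= self.internal_prime_prob <= 1.0:
            raise ValueError("internal_prime_prob must be in [0, 1]")
        if not 0.0 <= self.noise < 1.0:
            raise ValueError("noise must be in [0, 1)")

    def pattern_exons(self, pat: PatternSpec) -> tuple[int, ...]:
        gene = self.gene(pat.gene_id)
        if pat.isoform is not None:
            return tuple(gene.transcripts[pat.isoform])
        return tuple(pat.exons)

    # -- YAML round-trip ----------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        genes = tuple(
            GeneSpec(
                gene_id=g["gene_id"],
                gene_name=g.get("gene_name", g["gene_id"]),
                chrom=g["chrom"],
                strand=g.get("strand", "+"),
                exons=tuple((int(s), int(e)) for s, e in g["exons"]),
                transcripts={
                    tx: tuple(int(i) for i in idxs)
                    for tx, idxs in g["transcripts"].items()
                },
            )
            for g in d["genes"]
        )
        samples = tuple(
            SampleSpec(
                sample_id=s["sample_id"],
                patterns=tuple(
                    PatternSpec(
                        gene_id=p["gene_id"],
                        consensus_reads=int(p["consensus_reads"]),
                        fl_per_read=(
                            tuple(int(x) for x in p["fl_per_read"])
                            if isinstance(p.get("fl_per_read", 1), (list, tuple))
                            else int(p.get("fl_per_read", 1))
                        ),
                        isoform=p.get("isoform"),
                        exons=(
                            tuple(int(i) for i in p["exons"])
                            if p.get("exons") is not None
                            else None
                        ),
                    )
                    for p in s["patterns"]
                ),
            )
            for s in d["samples"]
        )
        window = d.get("size_window")
        return cls(
            genes=genes,
            samples=samples,
            chrom_lengths={k: int(v) for k, v in d["chrom_lengths"].items()},
            priming_sites=tuple(
                (c, int(p)) for c, p in d.get("priming_sites", [])
            ),
            size_window=tuple(window) if window else None,
            internal_prime_prob=float(d.get("internal_prime_prob", 0.5)),
            noise=float(d.get("noise", 0.0)),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticScenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "noise": self.noise,
            "internal_prime_prob": self.internal_prime_prob,
            "size_window": list(self.size_window) if self.size_window else None,
            "chrom_lengths": dict(self.chrom_lengths),
            "priming_sites": [[c, p] for c, p in self.priming_sites],
            "genes": [
                {
                    "gene_id": g.gene_id,
                    "gene_name": g.gene_name,
                    "chrom": g.chrom,
                    "strand": g.strand,
                    "exons": [list(e) for e in g.exons],
                    "transcripts": {t: list(i) for t, i in g.transcripts.items()},
                }
                for g in self.genes
            ],
            "samples": [
                {
                    "sample_id": s.sample_id,
                    "patterns": [
                        {
                            "gene_id": p.gene_id,
                            "consensus_reads": p.consensus_reads,
                            "fl_per_read": (
                                list(p.fl_per_read)
                                if isinstance(p.fl_per_read, tuple)
                                else p.fl_per_read
                            ),
                            **({"isoform": p.isoform} if p.isoform else {}),
                            **(
                                {"exons": list(p.exons)}
                                if p.exons is not None
                                else {}
                            ),
                        }
                        for p in s.patterns
                    ],
                }
                for s in self.samples
            ],
        }

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------


def build_genome(scenario: SyntheticScenario) -> dict[str, str]:
    """Seeded random genome with A-runs planted at the priming sites.

    Background sequence is cleaned so no accidental A-run reaches
    ``_ACCIDENTAL_RUN_LIMIT`` bases; the only >=8-base A-runs are the
    planted ones.
    """
    rng = np.random.default_rng([scenario.seed, 0])
    genome: dict[str, str] = {}
    bases = np.array(list("ACGT"))
    for chrom in sorted(scenario.chrom_lengths):
        length = scenario.chrom_lengths[chrom]
        seq = rng.choice(bases, size=length)
        run = 0
        for i in range(length):
            if seq[i] == "A":
                run += 1
                if run >= _ACCIDENTAL_RUN_LIMIT:
                    seq[i] = "G"
                    run = 0
            else:
                run = 0
        genome[chrom] = "".join(seq)
    for chrom, pos in scenario.priming_sites:
        s = genome[chrom]
        genome[chrom] = (
            s[:pos] + "A" * PRIMING_RUN_LENGTH + s[pos + PRIMING_RUN_LENGTH :]
        )
    return genome


def write_fasta(genome: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(genome[chrom]), id=chrom, description="")
        for chrom in sorted(genome)
    ]
    SeqIO.write(records, path, "fasta")


def gene_models(scenario: SyntheticScenario) -> list[GeneModel]:
    """The scenario's annotation as in-memory gene models."""
    out = []
    for g in scenario.genes:
        transcripts = []
        for tx_id in sorted(g.transcripts):
            chain = g.exon_chain(g.transcripts[tx_id])
            transcripts.append(
                TranscriptModel(
                    transcript_id=tx_id,
                    gene_id=g.gene_id,
                    exons=tuple(
                        GenomicInterval(g.chrom, s, e, g.strand) for s, e in chain
                    ),
                )
            )
        out.append(
            GeneModel(
                gene_id=g.gene_id,
                gene_name=g.gene_name or g.gene_id,
                transcripts=tuple(transcripts),
            )
        )
    return out


def write_gtf(scenario: SyntheticScenario, path: str) -> None:
    """GENCODE-dialect GTF (1-based inclusive) of the scenario annotation."""
    with open(path, "w") as fh:
        for gene in gene_models(scenario):
            for tx in gene.transcripts:
                for exon in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{tx.transcript_id}"; '
                        f'gene_name "{gene.gene_name}"'
                    )
                    fh.write(
                        "\t".join(
                            [
                                exon.chrom,
                                "isophase_sim",
                                "exon",
                                str(exon.start + 1),
                                str(exon.end),
                                ".",
                                exon.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# Read layout realization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadLayout:
    """The realized genomic geometry of one simulated consensus read."""

    read_id: str
    sample: str
    gene_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    fl_count: int
    pattern_exons: tuple[int, ...]
    truncated: bool


def _chain_length(chain: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in chain)


def _genomic_to_tx(chain: list[tuple[int, int]], g: int, strand: str) -> int | None:
    """Transcript coordinate of genomic base *g*, or None if intronic."""
    if strand == "-":
        pos = 0
        for s, e in reversed(chain):
            if s <= g < e:
                return pos + (e - 1 - g)
            pos += e - s
        return None
    pos = 0
    for s, e in chain:
        if s <= g < e:
            return pos + (g - s)
        pos += e - s
    return None


def _tx_slice_to_blocks(
    chain: list[tuple[int, int]], t5: int, t3: int, strand: str
) -> tuple[tuple[int, int], ...]:
    """Genomic blocks covering transcript interval [t5, t3)."""
    blocks = []
    pos = 0
    order = list(reversed(chain)) if strand == "-" else chain
    for s, e in order:
        blen = e - s
        lo = max(t5, pos)
        hi = min(t3, pos + blen)
        if lo < hi:
            if strand == "-":
                blocks.append((e - (hi - pos), e - (lo - pos)))
            else:
                blocks.append((s + (lo - pos), s + (hi - pos)))
        pos += blen
    return tuple(sorted(blocks))


def realize_reads(scenario: SyntheticScenario) -> dict[str, list[ReadLayout]]:
    """Deterministically realize every requested read's genomic layout.

    This is the single source of read geometry: the SAM writer renders these
    layouts, and the truth table classifies them analytically, so simulator
    and oracle can never drift apart.
    """
    rng = np.random.default_rng([scenario.seed, 1])
    layouts: dict[str, list[ReadLayout]] = {}
    warned_short: set[str] = set()
    for sample in scenario.samples:
        sample_layouts: list[ReadLayout] = []
        serial = 0
        for pat in sample.patterns:
            gene = scenario.gene(pat.gene_id)
            exon_idxs = scenario.pattern_exons(pat)
            chain = gene.exon_chain(exon_idxs)
            length = _chain_length(chain)
            site_coords = [
                (pos, _genomic_to_tx(chain, pos, gene.strand))
                for chrom, pos in scenario.priming_sites
                if chrom == gene.chrom
            ]
            internal_sites = [
                t for _, t in site_coords if t is not None and t > PRIMING_MAX_UPSTREAM
            ]
            for fl in pat.fl_counts():
                truncated = False
                if scenario.size_window is None or length <= scenario.size_window[1]:
                    t5, t3 = 0, length
                    if (
                        scenario.size_window is not None
                        and length < scenario.size_window[0]
                        and pat.gene_id not in warned_short
                    ):
                        logger.warning(
                            "gene %s: transcript (%d nt) below size window minimum",
                            pat.gene_id,
                            length,
                        )
                        warned_short.add(pat.gene_id)
                else:
                    truncated = True
                    use_internal = (
                        internal_sites
                        and rng.random() < scenario.internal_prime_prob
                    )
                    if use_internal:
                        t_site = internal_sites[
                            int(rng.integers(0, len(internal_sites)))
                        ]
                        t3 = t_site - int(rng.integers(0, PRIMING_MAX_UPSTREAM + 1))
                    else:
                        t3 = length
                    lo, hi = scenario.size_window
                    target = int(rng.integers(lo, hi + 1))
                    t5 = max(0, t3 - target)
                blocks = _tx_slice_to_blocks(chain, t5, t3, gene.strand)
                readlen = t3 - t5
                serial += 1
                read_id = f"{sample.sample_id}/c{serial}/f{fl}p0/{readlen}"
                sample_layouts.append(
                    ReadLayout(
                        read_id=read_id,
                        sample=sample.sample_id,
                        gene_id=gene.gene_id,
                        chrom=gene.chrom,
                        strand=gene.strand,
                        blocks=blocks,
                        fl_count=fl,
                        pattern_exons=exon_idxs,
                        truncated=truncated,
                    )
                )
        layouts[sample.sample_id] = sample_layouts
    return layouts


# ---------------------------------------------------------------------------
# SAM + sidecar emission
# ---------------------------------------------------------------------------


def _layout_cigar(blocks: tuple[tuple[int, int], ...]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            parts.append(f"{gap}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def write_sample_sam(
    layouts: list[ReadLayout],
    genome: dict[str, str],
    path: str,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> None:
    """Write one sample's layouts as a SAM file (pure M/N CIGARs)."""
    if noise > 0 and rng is None:
        raise ValueError("a Generator is required when noise > 0")
    chroms = sorted(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms],
    }
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for layout in layouts:
            seq = "".join(genome[layout.chrom][s:e] for s, e in layout.blocks)
            if noise > 0:
                arr = np.array(list(seq))
                hit = rng.random(len(arr)) < noise
                if hit.any():
                    subs = rng.choice(np.array(list("ACGT")), size=int(hit.sum()))
                    arr[hit] = subs
                    seq = "".join(arr)
            rec = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
            rec.query_name = layout.read_id
            rec.query_sequence = seq
            rec.flag = 16 if layout.strand == "-" else 0
            rec.reference_id = chroms.index(layout.chrom)
            rec.reference_start = layout.blocks[0][0]
            rec.mapping_quality = 60
            rec.cigarstring = _layout_cigar(layout.blocks)
            out.write(rec)


def write_sidecar(layouts: list[ReadLayout], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tfl_count\n")
        for layout in layouts:
            fh.write(f"{layout.read_id}\t{layout.fl_count}\n")


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------


def _truth_classify(
    blocks: tuple[tuple[int, int], ...], part: tuple[int, int]
) -> str:
    """Exact (slop-free) classification of a noise-free layout vs a part."""
    ps, pe = part
    if any(s <= ps and pe <= e for s, e in blocks):
        return "matching"
    span = (blocks[0][0], blocks[-1][1])
    if span[0] <= ps and pe <= span[1]:
        if all(min(e, pe) - max(s, ps) <= 0 for s, e in blocks):
            return "skipping"
    return "non_informative"


def truth_parts(scenario: SyntheticScenario) -> dict[str, list[tuple[int, int, str]]]:
    """Expected final exonic parts per gene: annotated flattening plus one
    novel part per exon that only read patterns use, ordered by coordinate.
    Returns gene_id -> [(start, end, source)]."""
    used_by_patterns: dict[str, set[int]] = {}
    for sample in scenario.samples:
        for pat in sample.patterns:
            used_by_patterns.setdefault(pat.gene_id, set()).update(
                scenario.pattern_exons(pat)
            )
    out: dict[str, list[tuple[int, int, str]]] = {}
    for gene_spec, gene in zip(scenario.genes, gene_models(scenario)):
        annotated_idx = {
            i for idxs in gene_spec.transcripts.values() for i in idxs
        }
        flat = flatten_gene(gene)
        parts = [
            (p.interval.start, p.interval.end, "annotated") for p in flat.parts
        ]
        for i in sorted(used_by_patterns.get(gene_spec.gene_id, ()) - annotated_idx):
            s, e = gene_spec.exons[i]
            parts.append((s, e, "novel"))
        out[gene_spec.gene_id] = sorted(parts)
    return out


def truth_psi_records(scenario: SyntheticScenario) -> list[dict]:
    """Expected PSI table rows by exact arithmetic over realized layouts.

    Keys: gene_id, start, end, source, sample, matching_consensus,
    total_consensus, matching_fl, total_fl, psi_percent (None if undefined).
    """
    layouts = realize_reads(scenario)
    parts = truth_parts(scenario)
    rows: list[dict] = []
    for gene_spec in scenario.genes:
        gid = gene_spec.gene_id
        for sample in scenario.samples:
            sample_reads = [
                l for l in layouts[sample.sample_id] if l.gene_id == gid
            ]
            for (s, e, source) in parts[gid]:
                m_cons = m_fl = t_cons = t_fl = 0
                for l in sample_reads:
                    cls = _truth_classify(l.blocks, (s, e))
                    if cls == "non_informative":
                        continue
                    t_cons += 1
                    t_fl += l.fl_count
                    if cls == "matching":
                        m_cons += 1
                        m_fl += l.fl_count
                rows.append(
                    {
                        "gene_id": gid,
                        "start": s,
                        "end": e,
                        "source": source,
                        "sample": sample.sample_id,
                        "matching_consensus": m_cons,
                        "total_consensus": t_cons,
                        "matching_fl": m_fl,
                        "total_fl": t_fl,
                        "psi_percent": (
                            100.0 * m_fl / t_fl if t_fl > 0 else None
                        ),
                    }
                )
    return rows


def truth_phase_patterns(
    scenario: SyntheticScenario,
    gene_id: str,
    target_exon_indices: tuple[int, ...],
) -> dict[str, dict[tuple[int, ...], tuple[int, int]]]:
    """Expected phase tallies: sample -> inclusion vector -> (consensus, fl).

    Target exons are scenario exon indices of *gene_id*; a layout must span
    the whole target region, and must contain or cleanly skip each target
    exon, to be counted.
    """
    gene = next(g for g in scenario.genes if g.gene_id == gene_id)
    targets = [gene.exons[i] for i in sorted(target_exon_indices)]
    region = (min(s for s, _ in targets), max(e for _, e in targets))
    layouts = realize_reads(scenario)
    out: dict[str, dict[tuple[int, ...], tuple[int, int]]] = {}
    for sample in scenario.samples:
        tallies: dict[tuple[int, ...], list[int]] = {}
        for l in layouts[sample.sample_id]:
            if l.gene_id != gene_id:
                continue
            span = (l.blocks[0][0], l.blocks[-1][1])
            if span[0] > region[0] or span[1] < region[1]:
                continue
            bits = []
            ok = True
            for part in targets:
                cls = _truth_classify(l.blocks, part)
                if cls == "matching":
                    bits.append(1)
                elif cls == "skipping":
                    bits.append(0)
                else:
                    ok = False
                    break
            if not ok:
                continue
            entry = tallies.setdefault(tuple(bits), [0, 0])
            entry[0] += 1
            entry[1] += l.fl_count
        out[sample.sample_id] = {k: (v[0], v[1]) for k, v in tallies.items()}
    return out


def write_truth_psi_tsv(scenario: SyntheticScenario, path: str) -> None:
    rows = truth_psi_records(scenario)
    cols = [
        "gene_id",
        "start",
        "end",
        "source",
        "sample",
        "matching_consensus",
        "total_consensus",
        "matching_fl",
        "total_fl",
        "psi_percent",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            vals = [r[c] for c in cols]
            vals[-1] = "NA" if vals[-1] is None else f"{vals[-1]:.4f}"
            fh.write("\t".join(str(v) for v in vals) + "\n")


# ---------------------------------------------------------------------------
# Fixture assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fixture:
    """Paths of one fully materialized synthetic dataset."""

    fasta: str
    gtf: str
    sams: dict[str, str]  # sample -> SAM path
    sidecars: dict[str, str]  # sample -> FL TSV path
    truth_psi: str


def simulate(scenario: SyntheticScenario, outdir: str) -> Fixture:
    """Materialize a scenario: FASTA, GTF, per-sample SAM + sidecar, truth."""
    import os

    os.makedirs(outdir, exist_ok=True)
    genome = build_genome(scenario)
    fasta = os.path.join(outdir, "genome.fa")
    write_fasta(genome, fasta)
    gtf = os.path.join(outdir, "annotation.gtf")
    write_gtf(scenario, gtf)
    layouts = realize_reads(scenario)
    noise_rng = np.random.default_rng([scenario.seed, 2])
    sams: dict[str, str] = {}
    sidecars: dict[str, str] = {}
    for sample in scenario.samples:
        sam_path = os.path.join(outdir, f"{sample.sample_id}.sam")
        tsv_path = os.path.join(outdir, f"{sample.sample_id}.fl.tsv")
        write_sample_sam(
            layouts[sample.sample_id],
            genome,
            sam_path,
            noise=scenario.noise,
            rng=noise_rng,
        )
        write_sidecar(layouts[sample.sample_id], tsv_path)
        sams[sample.sample_id] = sam_path
        sidecars[sample.sample_id] = tsv_path
    truth_psi = os.path.join(outdir, "truth_psi.tsv")
    write_truth_psi_tsv(scenario, truth_psi)
    return Fixture(
        fasta=fasta, gtf=gtf, sams=sams, sidecars=sidecars, truth_psi=truth_psi
    )
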