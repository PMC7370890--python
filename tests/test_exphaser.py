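"""Cassette-exon phasing, pattern-transcript matching and reporting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isophase.annotation import TranscriptModel
from isophase.exphaser import (
    PhasePattern,
    TargetExonSet,
    phase,
    phase_report_tsv,
    read_pattern,
    transcript_pattern,
)
from isophase.intervals import GenomicInterval
from isophase.reads import ConsensusRead

# A toy gene: six exons e0..e5 at 100*i..100*i+50 for i in 0,2,4,6,8,10.
EXONS = [(100 * i, 100 * i + 50) for i in (0, 2, 4, 6, 8, 10)]


def make_targets(exon_ids=range(6), labels=None):
    labels = labels or [str(i) for i in exon_ids]
    return TargetExonSet(
        gene_id="g",
        exons=tuple(
            (lab, GenomicInterval("chr1", *EXONS[i]))
            for lab, i in zip(labels, exon_ids)
        ),
    )


def make_read(exon_ids, fl=1, read_id="r", chrom="chr1"):
    return ConsensusRead(
        read_id=read_id,
        sample="s",
        chrom=chrom,
        strand="+",
        blocks=tuple(
            GenomicInterval(chrom, s, e, "+") for s, e in (EXONS[i] for i in exon_ids)
        ),
        fl_count=fl,
    )


def make_tx(exon_ids, tx_id="tx"):
    return TranscriptModel(
        tx_id,
        "g",
        tuple(GenomicInterval("chr1", s, e, "+") for s, e in (EXONS[i] for i in exon_ids)),
    )


class TestReadPattern:
    def test_all_exons_present(self):
        targets = make_targets()
        assert read_pattern(make_read(range(6)), targets) == (1, 1, 1, 1, 1, 1)

    def test_single_exon_spliced_out(self):
        targets = make_targets(labels=["2", "12", "17", "37", "38", "39"])
        vec = read_pattern(make_read([0, 2, 3, 4, 5]), targets)
        assert vec == (1, 0, 1, 1, 1, 1)

    def test_read_ending_inside_region_rejected(self):
        targets = make_targets()
        assert read_pattern(make_read([0, 1, 2]), targets) is None

    def test_spanning_read_with_ambiguous_exon_rejected(self):
        targets = make_targets([0, 2, 4])
        read = ConsensusRead(
            read_id="r",
            sample="s",
            chrom="chr1",
            strand="+",
            blocks=(
                GenomicInterval("chr1", 0, 50, "+"),
                GenomicInterval("chr1", 380, 430, "+"),  # covers only part of e2
                GenomicInterval("chr1", 800, 850, "+"),
            ),
            fl_count=1,
        )
        assert read_pattern(read, targets, boundary_slop=5) is None


class TestTranscriptPattern:
    def test_missing_exon_gives_zero(self):
        targets = make_targets(labels=["2", "12", "17", "37", "38", "39"])
        tx = make_tx([0, 2, 3, 4, 5], "no-12")
        assert transcript_pattern(tx, targets) == (1, 0, 1, 1, 1, 1)

    def test_non_spanning_transcript_not_applicable(self):
        targets = make_targets()
        assert transcript_pattern(make_tx([0, 1, 2]), targets) is None

    def test_half_covering_exon_is_zero(self):
        targets = make_targets([0, 2])
        s, e = EXONS[2]
        tx = TranscriptModel(
            "half",
            "g",
            (
                GenomicInterval("chr1", *EXONS[0], "+"),
                GenomicInterval("chr1", s, s + 20, "+"),  # half of target exon
                GenomicInterval("chr1", *EXONS[4], "+"),
            ),
        )
        assert transcript_pattern(tx, targets) == (1, 0)

    def test_oracle_equivalence_brute_force(self):
        """Pattern matching equals comparing every transcript against every
        pattern by direct exon-set containment on a small fixture."""
        targets = make_targets()
        txs = [make_tx(sorted({0, 5} | set(extra)), f"t{j}")
               for j, extra in enumerate([(1, 2, 3, 4), (2, 3, 4), (1, 3), (1, 2, 3)])]
        reads = [make_read(sorted({0, 5} | set(extra)), read_id=f"r{j}")
                 for j, extra in enumerate([(1, 2, 3, 4), (2, 3, 4), (4,)])]
        report = phase({"s": reads}, targets, annotation=txs)
        for pat in report.patterns["s"]:
            expected = {
                tx.transcript_id
                for tx in txs
                if transcript_pattern(tx, targets) == pat.inclusion
            }
            # brute force: a transcript matches iff its exon index set equals
            # the pattern's included target exons
            brute = {
                tx.transcript_id
                for tx in txs
                if tuple(
                    1 if any(ex.start == s and ex.end == e for ex in tx.exons) else 0
                    for s, e in EXONS
                )
                == pat.inclusion
            }
            assert set(pat.matched_transcripts) == expected == brute


class TestPhase:
    def test_cardiac_fixture_percentages(self):
        """541 vs 14 FL reads on two patterns give 97.5% / 2.5%."""
        targets = make_targets(labels=["2", "12", "17", "37", "38", "39"])
        reads = [make_read([0, 2, 3, 4, 5], fl=1, read_id=f"a{i}") for i in range(541)]
        reads += [
            ConsensusRead(
                read_id=f"b{i}",
                sample="s",
                chrom="chr1",
                strand="+",
                blocks=(
                    GenomicInterval("chr1", 0, 50, "+"),
                    GenomicInterval("chr1", 600, 650, "+"),
                    GenomicInterval("chr1", 800, 850, "+"),
                    GenomicInterval("chr1", 1000, 1050, "+"),
                ),
                fl_count=1,
            )
            for i in range(14)
        ]
        report = phase({"cardiac": reads}, targets)
        percents = report.percents("cardiac")
        assert percents[(1, 0, 1, 1, 1, 1)] == pytest.approx(97.5, abs=0.05)
        assert percents[(1, 0, 0, 1, 1, 1)] == pytest.approx(2.5, abs=0.05)

    def test_majority_pattern_66_5(self):
        targets = make_targets()
        reads = [make_read(range(6), read_id=f"a{i}") for i in range(557)]
        reads += [make_read([0, 1, 2, 3, 5], read_id=f"b{i}") for i in range(280)]
        report = phase({"edl": reads}, targets)
        assert report.percents("edl")[(1, 1, 1, 1, 1, 1)] == pytest.approx(66.5, abs=0.05)

    def test_ambiguous_transcripts_both_listed(self):
        targets = make_targets([1, 2])
        txs = [make_tx(range(6), "tx-a"), make_tx([0, 1, 2, 3, 4], "tx-b")]
        reads = [make_read(range(6), read_id=f"r{i}") for i in range(3)]
        report = phase({"s": reads}, targets, annotation=txs)
        (pat,) = report.patterns["s"]
        assert pat.matched_transcripts == ("tx-a", "tx-b")

    def test_empty_sample_reported_not_fatal(self, caplog):
        targets = make_targets()
        with caplog.at_level("WARNING"):
            report = phase({"empty": []}, targets)
        assert report.patterns["empty"] == ()

    def test_sorted_by_descending_fl_then_vector(self):
        targets = make_targets([0, 2, 4])
        reads = [make_read([0, 2, 4], fl=5, read_id="a")]
        reads += [make_read([0, 4], fl=5, read_id="b")]
        reads += [make_read([0, 2, 5], fl=9, read_id="c")]  # spans past e4, skips it
        report = phase({"s": reads}, targets)
        pats = report.patterns["s"]
        assert [p.fl_count for p in pats] == [9, 5, 5]
        assert [p.inclusion for p in pats[1:]] == [(1, 0, 1), (1, 1, 1)]

    def test_partial_exon_target_behaves_like_full(self):
        """A shortened 3'-terminal target interval phases identically to the
        full exon when reads cover that sub-interval."""
        full = make_targets([0, 2])
        s, e = EXONS[2]
        short = TargetExonSet(
            gene_id="g",
            exons=(
                ("up", GenomicInterval("chr1", *EXONS[0])),
                ("term", GenomicInterval("chr1", s, s + 20)),  # 5' 20 bp only
            ),
        )
        reads = [make_read([0, 2, 4], read_id="a"), make_read([0, 4], read_id="b")]
        rep_full = phase({"s": reads}, full)
        rep_short = phase({"s": reads}, short)
        assert {p.inclusion: p.fl_count for p in rep_full.patterns["s"]} == {
            p.inclusion: p.fl_count for p in rep_short.patterns["s"]
        }


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    counts=st.lists(st.integers(min_value=0, max_value=40), min_size=4, max_size=4),
    fl=st.integers(min_value=1, max_value=7),
    n_trunc=st.integers(min_value=0, max_value=10),
)
def test_count_conservation_and_percent_normalization(counts, fl, n_trunc):
    """Pattern FL counts per sample sum to the FL of phaseable reads;
    percents sum to 100; truncated reads never change the tallies."""
    targets = make_targets()
    variants = [tuple(range(6)), (0, 2, 3, 4, 5), (0, 1, 3, 4, 5), (0, 1, 2, 3, 5)]
    reads = []
    for j, (variant, n) in enumerate(zip(variants, counts)):
        reads += [make_read(variant, fl=fl, read_id=f"v{j}_{i}") for i in range(n)]
    phaseable_fl = sum(r.fl_count for r in reads)
    # internally-primed truncated reads: do not span the region
    reads += [make_read([3, 4, 5], fl=fl, read_id=f"t{i}") for i in range(n_trunc)]
    report = phase({"s": reads}, targets)
    total = sum(p.fl_count for p in report.patterns["s"])
    assert total == phaseable_fl
    percents = report.percents("s")
    if percents:
        assert sum(percents.values()) == pytest.approx(100.0, abs=1e-9)


class TestPhaseReportTsv:
    def test_unannotated_pattern_and_percent_sum(self, tmp_path):
        targets = make_targets([0, 2, 4])
        txs = [make_tx([0, 2, 4], "known")]
        reads = [make_read([0, 2, 4], read_id=f"a{i}") for i in range(3)]
        reads += [make_read([0, 4], read_id=f"b{i}") for i in range(1)]
        report = phase({"s": reads}, targets, annotation=txs)
        path = str(tmp_path / "phase.tsv")
        phase_report_tsv(report, path)
        lines = open(path).read().splitlines()
        assert lines[0].split("\t") == [
            "sample", "pattern", "consensus_count", "fl_count", "percent",
            "matched_transcripts",
        ]
        body = [l.split("\t") for l in lines[1:]]
        assert {row[1]: row[5] for row in body} == {
            "1-1-1": "known",
            "1-0-1": "unannotated",
        }
        assert sum(float(row[4]) for row in body) == pytest.approx(100.0, abs=0.1)

    def test_empty_sample_has_no_rows(self, tmp_path):
        report = phase({"empty": []}, make_targets())
        path = str(tmp_path / "phase.tsv")
        phase_report_tsv(report, path)
        assert len(open(path).read().splitlines()) == 1

    def test_bed_round_trip(self, tmp_path):
        bed = tmp_path / "targets.bed"
        bed.write_text("chr1\t200\t250\t12\nchr1\t0\t50\t2\n")
        targets = TargetExonSet.from_bed(str(bed), gene_id="g")
        assert targets.labels == ("2", "12")  # sorted by coordinate
        assert targets.region.start == 0 and targets.region.end == 250
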