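"""Read classification, novel-exon discovery, PSI and the filter cascade."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isophase.annotation import ExonicPart, FlattenedGene, GeneModel, TranscriptModel
from isophase.excovator import (
    PartReadClass,
    PsiRecord,
    classify_read_for_part,
    coverage_frame,
    coverage_report,
    discover_novel_exons,
    filter_candidates,
    psi_table,
)
from isophase.intervals import GenomicInterval
from isophase.reads import ConsensusRead


def make_read(blocks, fl=1, read_id="r", sample="s", chrom="chr1"):
    return ConsensusRead(
        read_id=read_id,
        sample=sample,
        chrom=chrom,
        strand="+",
        blocks=tuple(GenomicInterval(chrom, s, e, "+") for s, e in blocks),
        fl_count=fl,
    )


def make_part(start, end, index=1, gene="g", chrom="chr1"):
    return ExonicPart(
        gene_id=gene,
        part_index=index,
        interval=GenomicInterval(chrom, start, end, "+"),
    )


def make_flat(gene_id, tx_exons, chrom="chr1"):
    from isophase.annotation import flatten_gene

    transcripts = tuple(
        TranscriptModel(
            tx, gene_id, tuple(GenomicInterval(chrom, s, e, "+") for s, e in sorted(ex))
        )
        for tx, ex in sorted(tx_exons.items())
    )
    return flatten_gene(GeneModel(gene_id, gene_id, transcripts))


class TestClassify:
    def test_block_covering_part_matches(self):
        read = make_read([(0, 100), (200, 300)])
        assert (
            classify_read_for_part(read, make_part(200, 300), boundary_slop=10)
            is PartReadClass.MATCHING
        )

    def test_part_inside_read_intron_is_skipping(self):
        read = make_read([(0, 100), (400, 500)])
        assert (
            classify_read_for_part(read, make_part(200, 300))
            is PartReadClass.SKIPPING
        )

    def test_truncation_inside_part_is_non_informative(self):
        read = make_read([(0, 250)])
        assert (
            classify_read_for_part(read, make_part(200, 300))
            is PartReadClass.NON_INFORMATIVE
        )

    def test_boundary_slop_absorbs_wobble(self):
        read = make_read([(205, 298)])  # misses both part edges by <= 10
        assert (
            classify_read_for_part(read, make_part(200, 300), boundary_slop=10)
            is PartReadClass.MATCHING
        )
        assert (
            classify_read_for_part(read, make_part(200, 300), boundary_slop=2)
            is PartReadClass.NON_INFORMATIVE
        )

    def test_read_not_spanning_part_is_non_informative(self):
        read = make_read([(400, 500)])
        assert (
            classify_read_for_part(read, make_part(200, 300))
            is PartReadClass.NON_INFORMATIVE
        )

    def test_other_chromosome_is_non_informative(self):
        read = make_read([(0, 500)], chrom="chr2")
        assert (
            classify_read_for_part(read, make_part(200, 300))
            is PartReadClass.NON_INFORMATIVE
        )


class TestDiscoverNovelExons:
    def setup_method(self):
        self.flat = make_flat("g", {"t": [(0, 100), (300, 400)]})

    def reads_with_extra(self, n, block=(150, 180)):
        return [
            make_read([(0, 100), block, (300, 400)], read_id=f"r{i}")
            for i in range(n)
        ]

    def test_six_supporting_reads_emit_part(self):
        flat = discover_novel_exons(self.reads_with_extra(6), self.flat, 5, 10)
        novel = [p for p in flat.parts if p.source == "novel"]
        assert [(p.interval.start, p.interval.end) for p in novel] == [(150, 180)]
        # inserted in coordinate order and renumbered
        assert [p.part_index for p in flat.parts] == [1, 2, 3]
        assert flat.parts[1].source == "novel"

    def test_below_support_emits_nothing(self):
        flat = discover_novel_exons(self.reads_with_extra(3), self.flat, 5, 10)
        assert flat == self.flat

    def test_modal_boundary(self):
        reads = self.reads_with_extra(4, (150, 180)) + [
            make_read([(0, 100), (152, 180), (300, 400)], read_id=f"q{i}")
            for i in range(2)
        ]
        flat = discover_novel_exons(reads, self.flat, 5, 10)
        novel = [p for p in flat.parts if p.source == "novel"]
        assert [(p.interval.start, p.interval.end) for p in novel] == [(150, 180)]

    def test_short_candidates_ignored(self):
        flat = discover_novel_exons(self.reads_with_extra(6, (150, 156)), self.flat, 5, 10)
        assert flat == self.flat


class TestPsiTable:
    def test_printed_worked_example_counts(self):
        """576 matching vs 286 skipping FL reads give 66.8% PSI; a sample
        with 0 matching of 567 gives 0."""
        flat = make_flat("g", {"inc": [(0, 100), (200, 300), (400, 500)],
                               "exc": [(0, 100), (400, 500)]})
        part = next(p for p in flat.parts if p.interval.start == 200)
        inc = [make_read([(0, 100), (200, 300), (400, 500)], fl=2, read_id=f"i{k}") for k in range(288)]
        exc = [make_read([(0, 100), (400, 500)], fl=2, read_id=f"e{k}") for k in range(143)]
        heart = [make_read([(0, 100), (400, 500)], fl=1, read_id=f"h{k}") for k in range(567)]
        records = psi_table({"edl": inc + exc, "heart": heart}, flat)
        by = {(r.sample, r.part.part_index): r for r in records}
        r = by[("edl", part.part_index)]
        assert (r.matching_fl, r.total_fl) == (576, 862)
        assert round(r.psi_percent, 1) == 66.8
        r = by[("heart", part.part_index)]
        assert (r.matching_fl, r.total_fl) == (0, 567)
        assert r.psi_percent == 0.0

    def test_no_informative_reads_gives_undefined_psi(self):
        flat = make_flat("g", {"t": [(0, 100), (200, 300)]})
        records = psi_table({"s": []}, flat)
        assert all(r.psi_percent is None for r in records)

    def test_truncated_reads_enter_neither_count(self):
        flat = make_flat("g", {"t": [(0, 100), (200, 300)]})
        part = flat.parts[1]
        trunc = make_read([(0, 250)])  # ends inside the part
        records = psi_table({"s": [trunc]}, flat)
        r = next(x for x in records if x.part == part)
        assert (r.total_consensus, r.total_fl) == (0, 0)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    n_match=st.integers(min_value=0, max_value=30),
    n_skip=st.integers(min_value=0, max_value=30),
    fls=st.lists(st.integers(min_value=1, max_value=20), min_size=60, max_size=60),
)
def test_psi_bounds_and_monotonicity(n_match, n_skip, fls):
    """PSI stays in [0,100]; adding a matching read never lowers it and
    adding a skipping read never raises it."""
    flat = make_flat("g", {"inc": [(0, 100), (200, 300), (400, 500)],
                           "exc": [(0, 100), (400, 500)]})
    part = next(p for p in flat.parts if p.interval.start == 200)

    def psi_of(nm, ns):
        reads = [
            make_read([(0, 100), (200, 300), (400, 500)], fl=fls[i], read_id=f"m{i}")
            for i in range(nm)
        ] + [
            make_read([(0, 100), (400, 500)], fl=fls[30 + i], read_id=f"s{i}")
            for i in range(ns)
        ]
        records = psi_table({"s": reads}, flat)
        r = next(x for x in records if x.part == part)
        assert r.matching_fl <= r.total_fl
        assert r.matching_consensus <= r.total_consensus
        return r.psi_percent

    psi = psi_of(n_match, n_skip)
    if psi is not None:
        assert 0.0 <= psi <= 100.0
    plus_match = psi_of(n_match + 1, n_skip)
    plus_skip = psi_of(n_match, n_skip + 1)
    if psi is not None:
        assert plus_match >= psi
        assert plus_skip <= psi


def psi_record(gene, part_index, sample, m_fl, t_fl, m_cons=None, t_cons=None):
    t_cons = t_cons if t_cons is not None else t_fl
    m_cons = m_cons if m_cons is not None else m_fl
    return PsiRecord(
        gene_id=gene,
        part=make_part(100 * part_index, 100 * part_index + 50, part_index, gene),
        sample=sample,
        matching_consensus=m_cons,
        total_consensus=t_cons,
        matching_fl=m_fl,
        total_fl=t_fl,
    )


class TestFilterCascade:
    def test_gene_below_ten_consensus_reads_excluded(self):
        records = [
            psi_record("g", 1, "a", 3, 5),
            psi_record("g", 1, "b", 1, 4),
        ]
        assert filter_candidates(records, gene_consensus={"g": 9}) == []

    def test_psi_67_vs_14_passes_at_30x(self):
        records = [
            psi_record("g", 1, "edl", 576, 862, m_cons=46, t_cons=46),
            psi_record("g", 1, "soleus", 377, 2621, m_cons=30, t_cons=73),
        ]
        (cand,) = filter_candidates(records, gene_consensus={"g": 119})
        assert cand.passes_filters
        assert cand.max_pairwise_psi_delta == pytest.approx(52.4, abs=0.05)

    def test_delta_ten_fails(self):
        records = [
            psi_record("g", 1, "a", 50, 100),
            psi_record("g", 1, "b", 40, 100),
        ]
        (cand,) = filter_candidates(records, gene_consensus={"g": 200})
        assert not cand.passes_filters
        assert cand.max_pairwise_psi_delta == pytest.approx(10.0)

    def test_part_coverage_below_30_in_second_sample_not_evaluated(self):
        records = [
            psi_record("g", 1, "a", 90, 100),
            psi_record("g", 1, "b", 2, 20),  # under 30x
        ]
        (cand,) = filter_candidates(records, gene_consensus={"g": 120})
        assert cand.max_pairwise_psi_delta is None
        assert not cand.passes_filters

    def test_output_sorted_by_gene_then_part(self):
        records = [
            psi_record("gB", 2, "a", 40, 40),
            psi_record("gB", 1, "a", 40, 40),
            psi_record("gA", 1, "a", 40, 40),
        ]
        cands = filter_candidates(records, gene_consensus={"gA": 50, "gB": 50})
        assert [(c.gene_id, c.part.part_index) for c in cands] == [
            ("gA", 1),
            ("gB", 1),
            ("gB", 2),
        ]


class TestCoverageReport:
    def test_rows_sorted_and_rendered(self, tmp_path):
        records = [
            psi_record("g", 2, "b", 1, 3),
            psi_record("g", 1, "a", 576, 862),
            psi_record("g", 1, "b", 0, 0),
        ]
        path = str(tmp_path / "psi.tsv")
        df = coverage_report(records, path)
        assert list(df["part_id"]) == ["001", "001", "002"]
        lines = open(path).read().splitlines()
        assert lines[0].startswith("gene_id\tpart_id")
        assert "66.8" in lines[1]
        assert lines[2].endswith("NA")

    def test_empty_records_give_header_only(self, tmp_path):
        path = str(tmp_path / "psi.tsv")
        coverage_report([], path)
        lines = open(path).read().splitlines()
        assert len(lines) == 1

    def test_frame_deterministic_columns(self):
        df = coverage_frame([psi_record("g", 1, "a", 1, 2)])
        assert list(df.columns)[:4] == ["gene_id", "part_id", "source", "chrom"]
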