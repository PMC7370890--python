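"""Packaged demonstration scenarios.

These encode, at toy genomic scale (exons ~1/10 real size), the headline
muscle splicing comparisons: the Nrap exon-12 cassette (fast EDL vs slow
soleus vs heart), the titin cardiac cassette exon, the nebulin Z-disk
region with its mutually exclusive exon pair, a novel-exon discovery case,
and a long gene covered via oligo(dT) internal priming.  All reads carry FL
multiplicity 1, so consensus and FL tallies coincide and every quoted
FL-read ratio is realized read-for-read.
"""

from __future__ import annotations

from .simulate import GeneSpec, PatternSpec, SampleSpec, SyntheticScenario

# Toy Nrap-like gene: nine disjoint exons; index 2 plays the role of the
# skeletal-muscle cassette exon 12.  Transcript ids follow the annotated
# isoforms: all-exon (skeletal), exon-12-skipping (cardiac), and the rare
# exon-2-and-12-skipping isoform.
NRAP_ALL = "ENSMUST00000073536"
NRAP_NO12 = "ENSMUST00000040711"
NRAP_NO2_12 = "ENSMUST00000095947"
NRAP_EXON12_INDEX = 2


def _nrap_gene() -> GeneSpec:
    exons = tuple((100 + 320 * i, 220 + 320 * i) for i in range(9))
    return GeneSpec(
        gene_id="Nrap",
        gene_name="Nrap",
        chrom="chrT",
        strand="+",
        exons=exons,
        transcripts={
            NRAP_ALL: tuple(range(9)),
            NRAP_NO12: tuple(i for i in range(9) if i != 2),
            NRAP_NO2_12: tuple(i for i in range(9) if i not in (1, 2)),
        },
    )


def nrap_psi_scenario(seed: int = 0) -> SyntheticScenario:
    """Exon-12 PSI: EDL 576/862 (67%), soleus 377/2621 (14%), heart 0/567."""
    gene = _nrap_gene()

    def pats(include: int, exclude: int) -> tuple[PatternSpec, ...]:
        out = []
        if include:
            out.append(
                PatternSpec(gene_id="Nrap", isoform=NRAP_ALL, consensus_reads=include)
            )
        if exclude:
            out.append(
                PatternSpec(gene_id="Nrap", isoform=NRAP_NO12, consensus_reads=exclude)
            )
        return tuple(out)

    return SyntheticScenario(
        genes=(gene,),
        samples=(
            SampleSpec("edl", pats(576, 286)),
            SampleSpec("heart", pats(0, 567)),
            SampleSpec("soleus", pats(377, 2244)),
        ),
        chrom_lengths={"chrT": 5000},
        seed=seed,
    )


def nrap_phase_scenario(seed: int = 0) -> SyntheticScenario:
    """Whole-transcript phasing of the Nrap cassette exons.

    Heart: 541 FL exon-12-skipping + 14 FL exon-2-and-12-skipping
    (97.5% / 2.5% of 555); EDL: 557/837 all-exon (66.5%); soleus:
    2177/2544 exon-12-skipping (85.6%) and 26 FL rare isoform (1.0%).
    """
    gene = _nrap_gene()
    return SyntheticScenario(
        genes=(gene,),
        samples=(
            SampleSpec(
                "heart",
                (
                    PatternSpec("Nrap", isoform=NRAP_NO12, consensus_reads=541),
                    PatternSpec("Nrap", isoform=NRAP_NO2_12, consensus_reads=14),
                ),
            ),
            SampleSpec(
                "edl",
                (
                    PatternSpec("Nrap", isoform=NRAP_ALL, consensus_reads=557),
                    PatternSpec("Nrap", isoform=NRAP_NO12, consensus_reads=280),
                ),
            ),
            SampleSpec(
                "soleus",
                (
                    PatternSpec("Nrap", isoform=NRAP_NO12, consensus_reads=2177),
                    PatternSpec("Nrap", isoform=NRAP_ALL, consensus_reads=341),
                    PatternSpec("Nrap", isoform=NRAP_NO2_12, consensus_reads=26),
                ),
            ),
        ),
        chrom_lengths={"chrT": 5000},
        seed=seed,
    )


# Cassette-exon labels for phasing the Nrap gene (exon numbering of the
# skeletal reference transcript): exons 2, 12, 17, 37-40 -> indices 1..7.
NRAP_TARGET_LABELS = ("2", "12", "17", "37", "38", "39", "40")
NRAP_TARGET_INDICES = (1, 2, 3, 4, 5, 6, 7)


def titin_ep_scenario(seed: int = 0) -> SyntheticScenario:
    """Titin cardiac cassette exon (EP129-like): soleus 34/35 (97%),
    EDL 357/361 (99%), heart 84/232 (36%)."""
    exons = tuple((200 + 400 * i, 330 + 400 * i) for i in range(5))
    gene = GeneSpec(
        gene_id="Ttn",
        gene_name="Ttn",
        chrom="chrT",
        strand="+",
        exons=exons,
        transcripts={
            "Ttn-N2A": tuple(range(5)),
            "Ttn-noCassette": (0, 1, 3, 4),
        },
    )

    def pats(include: int, exclude: int) -> tuple[PatternSpec, ...]:
        out = []
        if include:
            out.append(PatternSpec("Ttn", isoform="Ttn-N2A", consensus_reads=include))
        if exclude:
            out.append(
                PatternSpec("Ttn", isoform="Ttn-noCassette", consensus_reads=exclude)
            )
        return tuple(out)

    return SyntheticScenario(
        genes=(gene,),
        samples=(
            SampleSpec("edl", pats(357, 4)),
            SampleSpec("heart", pats(84, 148)),
            SampleSpec("soleus", pats(34, 1)),
        ),
        chrom_lengths={"chrT": 3000},
        seed=seed,
    )


TTN_CASSETTE_INDEX = 2


def neb_phase_scenario(seed: int = 0) -> SyntheticScenario:
    """Nebulin Z-disk region: a mutually exclusive exon pair plus six
    cassette exons, phased jointly.

    EDL: 14/155 FL retain all cassettes (9.0%); the mutually exclusive
    exon "7s" appears in 155/155 (100%).  Soleus: 733/817 retain all
    cassettes (89.7%); "7s" in 514/817 (63%), "123" in 303/817 (37%).
    """
    # index 0: 5' flank; 1: MX exon "123"; 2: MX exon "7s" (downstream
    # alternative); 3-8: cassette exons; 9: 3' flank.
    exons = tuple((150 + 300 * i, 250 + 300 * i) for i in range(10))
    all_cassettes = (3, 4, 5, 6, 7, 8)
    with_b = (0, 2) + all_cassettes + (9,)
    with_a = (0, 1) + all_cassettes + (9,)
    b_skip_all = (0, 2, 9)
    b_skip_one = (0, 2, 4, 5, 6, 7, 8, 9)  # cassette 3 spliced out
    gene = GeneSpec(
        gene_id="Neb",
        gene_name="Neb",
        chrom="chrT",
        strand="+",
        exons=exons,
        transcripts={"Neb-ref": with_a},  # reference carries the "123" exon
    )
    return SyntheticScenario(
        genes=(gene,),
        samples=(
            SampleSpec(
                "edl",
                (
                    PatternSpec("Neb", exons=with_b, consensus_reads=14),
                    PatternSpec("Neb", exons=b_skip_all, consensus_reads=141),
                ),
            ),
            SampleSpec(
                "soleus",
                (
                    PatternSpec("Neb", exons=with_b, consensus_reads=430),
                    PatternSpec("Neb", exons=with_a, consensus_reads=303),
                    PatternSpec("Neb", exons=b_skip_one, consensus_reads=84),
                ),
            ),
        ),
        chrom_lengths={"chrT": 4000},
        seed=seed,
    )


NEB_TARGET_LABELS = ("123", "7s", "c1", "c2", "c3", "c4", "c5", "c6")
NEB_TARGET_INDICES = (1, 2, 3, 4, 5, 6, 7, 8)
NEB_ALL_CASSETTE_INDICES = (3, 4, 5, 6, 7, 8)


def novel_exon_scenario(seed: int = 0) -> SyntheticScenario:
    """A read-supported exon absent from the annotation (cf. exon u-002)."""
    gene = GeneSpec(
        gene_id="NovelDemo",
        gene_name="NovelDemo",
        chrom="chrT",
        strand="+",
        exons=((100, 220), (400, 520), (700, 820), (560, 590)),
        transcripts={"tx-known": (0, 1, 2)},
    )
    return SyntheticScenario(
        genes=(gene,),
        samples=(
            SampleSpec(
                "muscle",
                (
                    PatternSpec(
                        "NovelDemo", exons=(0, 1, 3, 2), consensus_reads=6
                    ),
                    PatternSpec("NovelDemo", isoform="tx-known", consensus_reads=4),
                ),
            ),
        ),
        chrom_lengths={"chrT": 2000},
        seed=seed,
    )


NOVEL_EXON_INTERVAL = (560, 590)


def internal_priming_scenario(seed: int = 0) -> SyntheticScenario:
    """A gene whose transcript (3 kb) far exceeds the size window (0.8-1.2
    kb), with an A-run planted mid-gene: poly(A)-anchored reads cover the
    3' end and internally-primed reads extend coverage 5'-ward, ending
    within 20 bases upstream of the A-run."""
    exons = tuple((500 + 500 * i, 800 + 500 * i) for i in range(10))
    gene = GeneSpec(
        gene_id="BigGene",
        gene_name="BigGene",
        chrom="chrB",
        strand="+",
        exons=exons,
        transcripts={"big-tx": tuple(range(10))},
    )
    return SyntheticScenario(
        genes=(gene,),
        samples=(
            SampleSpec(
                "muscle",
                (PatternSpec("BigGene", isoform="big-tx", consensus_reads=60),),
            ),
        ),
        chrom_lengths={"chrB": 8000},
        priming_sites=(("chrB", 3650),),  # inside exon index 6
        size_window=(800, 1200),
        internal_prime_prob=0.5,
        seed=seed,
    )


PRIMING_SITE_POSITION = 3650

BUILTIN_SCENARIOS = {
    "nrap_psi": nrap_psi_scenario,
    "nrap_phase": nrap_phase_scenario,
    "titin_ep": titin_ep_scenario,
    "neb_phase": neb_phase_scenario,
    "novel_exon": novel_exon_scenario,
    "internal_priming": internal_priming_scenario,
}
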