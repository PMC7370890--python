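# Methods

## Coordinate model

All internal coordinates are 0-based half-open. GTF I/O is 1-based
inclusive, BED I/O 0-based half-open; conversion happens only at the file
boundary, so round-trips are bit-exact. Exonic parts are numbered by
increasing genomic coordinate regardless of strand (the DEXSeq
convention); `strand_aware_part_id` is a display-only renderer for 5′→3′
numbering. Genes are flattened independently — overlapping genes are not
merged into multi-gene aggregates, since the analyses this package serves
examine named genes one at a time.

## Annotation flattening

A gene's exonic parts are the maximal intervals between consecutive
distinct exon-boundary coordinates, restricted to exon-covered bases.
Every transcript exon boundary therefore coincides with a part boundary,
parts are pairwise disjoint, and their total length equals the length of
the exon union. The property suite checks this construction against a
brute-force base-by-base labeling (group consecutive bases with identical
covering-exon sets) on random small genes. Zero-length and duplicate exon
records are dropped with a warning; overlapping exons within one
transcript (occasionally present in real annotations) are merged with a
warning.

## Read model

Each SAM/BAM record is one consensus read. Blocks are reconstructed from
the CIGAR: M/=/X and D advance the reference within a block, N closes a
block, I/S/H/P consume no reference. Secondary, supplementary and
unmapped records are excluded; only primary alignments are kept (how
multi-mapped consensus reads should be weighted is an open question for
noisy data; primary-only is the conservative choice). No MAPQ filter is
applied by default (`min_mapq=0`), as Iso-Seq consensus alignments are
high-confidence. FL multiplicity is resolved in order: sidecar TSV →
`f<k>p<j>` read-name token → `full_length_coverage=<k>` token → 1 with a
warning. The sidecar takes precedence because cluster-naming conventions
vary across SMRT Analysis versions. Strand is taken from the SAM flag but
overlap logic is coordinate-based unless `--strict-strand` is set:
oligo(dT) cDNA orientation is reliable, but annotation comparisons here
are positional.

## Read classification and PSI

For a read and an exonic part:

- **matching** — one aligned block covers the part, missing each part
  boundary by at most `boundary_slop` bases (default 10 bp, absorbing
  splice-site wobble in noisy long-read alignments);
- **skipping** — the read's span encloses the whole part but no block
  overlaps it by more than `min_overlap` bases (default 10 bp): the part
  lies in one of the read's introns;
- **non-informative** — everything else, in particular reads that are
  3′-truncated inside or short of the part.

PSI per (sample, part) is 100 × matching FL / (matching + skipping) FL.
The denominator deliberately excludes non-informative reads: counting
internally-primed truncated reads as "skipping" would bias PSI downward
for 3′-distal parts. Consensus-read tallies are kept alongside FL tallies;
coverage thresholds use consensus counts, PSI uses FL counts. PSI is
rendered to one decimal in reports; filters compare unrounded values.
When no spanning read exists, PSI is undefined and rendered `NA`.

## Novel-exon discovery

Candidate intervals are maximal pieces of read blocks not covered by the
annotated parts, at least `novel_min_length` (10 bp) long. Candidates are
clustered by overlap; a cluster supported by at least `novel_min_support`
(5) distinct reads — pooled across samples — emits one novel part whose
boundaries are the modal observed start and end (ties broken toward the
smaller coordinate for determinism). Parts are then renumbered by
coordinate. The support default matches the junction-display threshold of
5 and suppresses single-read artifacts; manual-inspection-style artifact
curation has no algorithmic counterpart here and is out of scope.

## Candidate filter cascade

A gene enters the analysis with ≥ 10 consensus reads overlapping its span
(summed over samples). A part is evaluated when ≥ 2 samples reach ≥ 30
consensus reads spanning it, and passes when the largest pairwise PSI
difference among those coverage-eligible samples is ≥ 20 percentage
points. "Between two of three samples" is generalized to the maximum
pairwise difference over any number of eligible samples. The run log
records the filtration funnel (genes seen / covered, novel parts, parts
evaluated / passing).

## Phasing

A read phases a target exon set only if its span encloses the whole
target region: truncated reads cannot witness exons they never covered,
so they are rejected rather than guessed at. Each target exon must
classify cleanly as contained (1) or spliced out (0); an ambiguous exon
rejects the read. Exon sets wider than a read length must be split into
proximity groups and phased in separate runs (the loader warns when a
region exceeds 10 kb). Pattern identity is exact vector equality.
Annotated transcripts are compared the same way, and only transcripts
spanning the region are eligible, so short transcripts are never
spuriously matched; a pattern matched by several transcripts lists all of
them (the targets cannot distinguish them), and one matched by none is
reported `unannotated`. Percentages are FL(pattern) / FL(all phased
patterns in the sample), rendered to one decimal. Mutually exclusive exon
pairs need no special handling: both exons are targets and the patterns
fall out.

## Synthetic data

Scenarios declare toy genes (exon catalog + transcripts as exon-index
subsets), per-sample inclusion patterns with consensus/FL counts, priming
sites, a size-selection window, a substitution-noise rate and a seed.
Genes are built at roughly one-tenth real exon/intron scale so even
large-gene stress cases simulate in well under a second; scale is entirely
scenario-controlled.

The genome is seeded random sequence in which accidental A-runs are
broken before they reach 6 bases, then 10-base A-runs are planted at the
declared priming sites (overlapping plants are an error) — so the only
≥8-base A-runs are intentional. Reads whose mature transcript fits the
size window span their whole exon chain. Longer transcripts are
3′-anchored at the poly(A) end or, with probability
`internal_prime_prob` (default 0.5; no empirical estimate exists, so it
is exposed rather than asserted), at an internal priming site — ending
0–20 bases upstream of the A-run, the geometry internally-primed cDNAs
show — and then 5′-trimmed to a length drawn uniformly from the window.
CIGARs are pure M/N at noise 0; the optional substitution noise (default
0, 0.001 mimics HiFi-consensus error rates) perturbs only the SEQ field.
SAM output is unpaired, primary-only, MAPQ 60, with @SQ lines from the
generated genome. Fixed seed gives byte-identical outputs.

A single routine (`realize_reads`) fixes every read's genomic geometry;
the SAM writer renders those layouts and the truth table classifies the
same layouts analytically with exact slop-free interval logic, so the
expected counts follow from integer arithmetic and cannot drift from the
emitted files. Closure tests therefore run the pipeline with
`boundary_slop=0, min_overlap=0` on noise-free fixtures: slop exists to
absorb alignment wobble, of which error-free fixtures have none. What
passing these tests shows is that counting, classification and phasing
are exact on clean data; it does not exercise alignment error, spurious
splice wobble, degraded RNA or expression-level stochasticity, which real
data contain.

## Packaged scenarios and problem sizes

The built-in scenarios realize the headline cross-muscle comparisons
read-for-read with FL multiplicity 1 (so consensus and FL tallies
coincide): the Nrap-like cassette exon (576/862, 377/2621, 0/567 FL for
PSI; 541+14, 557+280, 2177+341+26 FL for phasing), the titin-like cardiac
cassette (34/35, 357/361, 84/232), the nebulin-like Z-disk region with a
mutually exclusive pair (155 and 817 FL reads per sample), a novel-exon
case (6 of 10 reads carry the unannotated exon), and an
internal-priming case (60 reads over a 3 kb transcript with a 0.8–1.2 kb
window). These sizes keep the full test suite under ~15 s and the
acceptance script under ~5 s on one CPU while preserving every printed
ratio exactly.

## Known limitations

- Quantification is relative within a gene and sample; PSI and isoform
  percentages are not comparable across genes and are not absolute
  abundances.
- No statistical test accompanies the candidate filter; it is a
  threshold cascade by design.
- Phasing cannot chain patterns across regions longer than a read;
  distant exon groups must be analyzed separately.
- The simulator does not model polymerase subreads, barcode chemistry,
  clustering, or alignment itself.
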