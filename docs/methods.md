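# Methods

This note documents the models, parameter choices and numerical
conventions behind each module, what the synthetic study emulates and
what it deliberately does not, and the known limitations.

## Coordinates and conventions

All internal coordinates are 0-based half-open intervals on the forward
genome strand; GFF3 and the MISA-style SSR table convert to 1-based
inclusive on output. Donor and acceptor are strand-aware: on the plus
strand the donor is the intron start and the acceptor the intron end,
swapped on the minus strand. Library/line tags are encoded as a
`LIB|read` prefix on read ids (G = the reference line, H = the line
carrying variants).

## Gene regions and spliced alignment

A gene region is the annotated gene extended by up to 1,000 nt on each
side — anchored at the translation start/stop when a CDS is annotated,
else at the transcript bounds — clipped at chromosome ends and truncated
at the midpoint of the intergenic gap whenever two neighbors' flanks
would otherwise overlap (overlapping gene *bodies* truncate at the
bodies and are logged). The midpoint rule is a declared resolution: the
no-overlap constraint itself does not dictate one.

The aligner is a deliberately small seed-and-chain spliced aligner, not
a production tool. Exact k-mer anchors (k = 15) merge into maximal
exact diagonal segments, which are chained collinearly (overlaps
trimmed) maximizing exactly matched length. Genomic gaps of
≥ `min_intron` = 40 nt between chained segments become introns
(≤ `max_intron` = 10,000 nt); smaller gaps are absorbed as
mismatch/indel columns. Clean junctions slide within ±10 nt to land on
GT..AG (CT..AC for minus-strand genes), preferring zero shift, then the
smallest |shift|. Two rescue passes handle read ends too short to carry
an anchor: (a) a splice-consistent placement of a junction-straddling
end, accepted only when the motif check plus an exact match of the
leftover bases has a *unique* solution in the region; (b) a 1–2 nt
indel-shifted diagonal with an exact match of ≥ 6 leftover bases.
Remaining ends extend by X-drop (match +1, mismatch −2, drop 6).
Identity counts matching columns over aligned columns (indel columns
count as errors); coverage is the aligned fraction of the read; both
must meet the 95% / 80% acceptance rule. Reads are tried in both
orientations; the best accepted alignment per read wins by
identity×coverage, then aligned length, then lexicographic gene id — a
deterministic tie-break.

k, the intron bounds and the shift window suit compact plant genes and
the bundled simulator; all are exposed in `AlignParams`. The 80%
coverage is applied to the query (the EST being aligned).

## Junctions and AS classification

Junctions are distinct (gene, intron interval) pairs read off accepted
alignments, requiring ≥ 8 aligned nt on both flanking blocks
(`min_overhang`, configurable); support counts distinct ESTs.
Concordance is the fraction of observed junctions exactly matching an
annotated intron.

Events are classified against the union of annotated and EST-derived
introns with a fixed precedence that makes classification a function:
ExonS (the most specific two-boundary pattern) consumes its intron
pairs first; remaining overlapping pairs are AltA (shared donor), AltD
(shared acceptor) or AltP (no shared boundary); IntronR is orthogonal
and requires an EST block contiguously covering the intron plus 8 nt on
both sides — distinguishing genuine retention from alignment
truncation. Every reported event carries EST evidence: a pair with two
annotation-only introns is impossible (annotated introns of one gene
are disjoint), and pairs with zero total EST support are skipped.
These operational definitions are declared, not canonical; published
event taxonomies rarely state the boundary rules exactly.

## Digital expression

For counts x over libraries with sizes N, the statistic is
R = Σⱼ xⱼ ln(xⱼ/(Nⱼ f)) with f = Σx/ΣN and 0·ln 0 = 0 — the
log-likelihood ratio of library-specific Poisson rates against a pooled
rate (verified in tests against numeric maximization to 1e−9). Genes
with zero total count are excluded. Raw p-values default to the upper
χ²₁ tail of 2R; a Monte-Carlo alternative resamples the pooled total
multinomially over library sizes with the (r+1)/(n+1) correction. The
χ² tail and the exact conditional null differ by a continuity-type
term at moderate counts, which the self-consistency test acknowledges
with a proportional tolerance band. q-values are Benjamini–Hochberg by
default; the Storey variant multiplies by π̂₀ estimated at a fixed
λ = 0.5 (no smoother — deterministic and adequate at these list sizes).
Fold change puts +1 pseudocounts on the raw counts before library-size
normalization, avoiding infinite folds at (x, 0); `direction` names the
library with the higher pseudocounted rate, so it is invariant under
column order (ties resolve to the first library). DE requires
fold > 2 **and** q < 0.05.

## SSR mining

An SSR is a maximal perfect tandem tract of a primitive 2–6 nt motif:
for each period u the scanner finds maximal runs of s[i] = s[i+u]
(N never matches), truncates to whole units (k = ⌊run/u⌋), and reports
when k ≥ 6 (u = 2) or k ≥ 5 (u = 3..6) and the motif is not a power of
a shorter motif — so (AT)₁₀ is a dinucleotide, never ATAT, and
homopolymers are excluded entirely. Single-base maximality implies
full-unit maximality. SSRs on one sequence chain transitively into a
compound when gaps are ≤ 100 nt. The canonical motif class is the
lexicographic minimum over all rotations of the motif and of its
reverse complement. Flank sufficiency defaults to ≥ 50 non-N nt on
both sides — a declared, configurable stand-in for "enough sequence to
design a primer"; primer design itself is out of scope.

## SNP filters

The caller is a transparent column pileup, not a Bayesian genotyper:
the filters are the substance. Reads are placed on the gene's
transcript consensus by edlib infix alignment (both orientations,
accepting ≤ 15% edits), stacked into per-position columns plus gap
columns for insertions; reads spanning an insertion point without the
insertion contribute the gap allele there. The first and last two
aligned bases of each read contribute no evidence: an indel touching a
read end admits equal-cost alignment paths whose arbitrary resolution
would otherwise fabricate within-line variation. Candidates are
columns with ≥ 2 observed alleles. The three filters: (1) per-line
coverage ≥ 2; (2) an indel is rejected when a consensus homopolymer
run ≥ 3 overlaps [pos−1, pos+1] (the "surrounded by" neighborhood is
operationalized as this window); (3) the two lines' allele sets must be
disjoint, with an optional stricter single-allele-per-line mode (off by
default; the lines are near-isogenic but disjointness is what the rule
states). Passing sites classify as indel if a gap is present, else
transition/transversion for biallelic sites; multi-allelic non-indel
candidates are rejected because the ts/tv dichotomy is biallelic.

## GO slim and enrichment

The ontology is an is_a/part_of DAG (obonet/networkx; obsolete terms
dropped and counted). A term's slim image is its set of *nearest* slim
ancestors-or-self: slim terms reachable upward through no other slim
term — computed by memoized upward recursion that stops at slim terms.
Slim classification counts a gene once per slim term. Enrichment
propagates annotations to all ancestors, then tests each term with the
exact hypergeometric upper tail P(X ≥ k), X ~ Hypergeom(N, K, n),
adjusted by BH (default) or Bonferroni, enriched iff adjusted p < 0.05.
The recommended population is the expressed set (genes with ≥ 1
assigned read); it is an explicit argument, never implicit.

## The synthetic study

The generator emulates a two-library 454-style EST experiment at desk
scale. Conditions that the emulated design states are defaults: two
libraries; read lengths normal(175, 50) truncated at 40 nt and at the
transcript. The rest are declared choices: 40 genes on 2 chromosomes,
2–5 exons of 90–240 nt with 60–120 nt GT..AG introns, per-gene
expression weights gamma(shape 2) around a mean of 25 expected reads —
the gamma-Poisson is a stand-in, not an inference about real libraries
— reads sampled uniformly along transcripts (no 3′ bias; the protocol's
bias is unknown), library sizes drawn multinomially so totals are
exact, DE injected at fold 4 alternating in direction, one AS event per
host gene, SSRs embedded in the UTR of the first exon, and inter-line
variants only in genes without AS events. Homopolymer errors
insert/delete one base (equal probability) per run ≥ 3 at a configured
per-run rate, mirroring the error mode the SNP filter targets; the
default rate is 0 so the fixture doubles as an exact oracle. One seed
drives a single RNG stream with sub-stages in fixed order, so a fixed
seed reproduces the fixture byte for byte.

Three constructions make truth recovery deterministic rather than
merely probable. (i) At every junction — annotated or alternative —
the exon base preceding the donor differs from the base preceding the
acceptor, and the base following the acceptor differs from the donor's
first base; this removes every alternative motif-consistent junction
placement within the aligner's shift window. (ii) Injected variants
sit ≥ 17 nt from splice junctions (so anchors around junctions stay
intact), ≥ 25 nt apart, substitution alleles differ from both
neighboring bases and deleted bases differ from their neighbors (so no
equal-cost gapped alignment exists), and indels avoid ≥ 3-homopolymer
windows (so they survive filter 2). (iii) One guided read per AS event
(library G) spans the event with generous overhang, guaranteeing
junction/retention evidence at any expression level; it counts toward
the library total.

What passing tests on this fixture do **not** show: performance on real
454 data with flowgram noise, chimeras, vector contamination, assembly
artifacts, paralog cross-mapping, or expression bias along transcripts.
The generator omits quality scores and flowgram-level simulation by
design.

## Problem sizes

The bundled studies are scaled for routine re-runs: the end-to-end
fixture uses 40 genes and 2 × 1,500 reads; the type-I-error study uses
2,000 genes × 5 seeds and the power study 300 genes × 10 seeds at the
count level (the same expression/count machinery the read simulator
uses, without read synthesis); the SSR cross-check uses 200 random 2 kb
sequences; the enrichment cross-check enumerates every hypergeometric
configuration with N ≤ 30. The whole test suite runs in well under a
minute.

## Known limitations

- The aligner assumes compact genes and near-exact reads; it is not a
  general-purpose spliced aligner (no affine-gap DP across regions, no
  polyA handling) and its identity bookkeeping treats absorbed indels
  as single errors.
- The Monte-Carlo p-value conditions on the observed total per gene;
  the χ² default is asymptotic and slightly anticonservative at very
  small counts (the fold filter dominates there).
- SNP calling on transcripts ignores genes hosting AS events; in real
  data, isoform-aware pileups would be needed.
- Imperfect (interrupted) single SSRs are not detected; only perfect
  tracts, optionally grouped into compounds.
- Junction concordance on the fixture is below 1.0 by construction
  (injected alternative junctions are absent from the annotation);
  on real data the gap also reflects alignment noise.
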