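# Methods

## The locus model

The package models a ~13 Mbp chromosomal locus delimited by five
segmental-duplication clusters (BP blocks, BP1–BP5; lettered BPA–BPE
when describing nonhuman primates).  Five candidate regions are
analysed: the four inter-block intervals BP1-BP2, BP2-BP3, BP3-BP4 and
BP4-BP5, plus the BP3-BP5 span, which *nests* the last two.  All
internal coordinates are 0-based half-open; UCSC-style printed tables
(1-based inclusive) are converted only at the I/O boundary.  The
packaged fixture stores the printed region coordinates on the
telomere-to-telomere human reference; two printed adjacent regions
share their boundary base, so the locus-map disjointness check
tolerates exactly 1 bp of overlap.  BP block extents are not printed
anywhere, so the fixture infers them from the gaps between regions and
the published locus bounds; BP2 collapses to a 1 bp placeholder between
its two flanking regions.  (The running text describes BP1-BP2 as
~300 kbp while the printed coordinates span ~720 kbp; the fixture
keeps the printed coordinates.)

Species are fixed to the six-leaf rooted tree
`(CJA,(MMU,(PPY,(GGO,(HSA,PTR)))))` with the ancestors of
{HSA,PTR,GGO}, {…,PPY} and {…,MMU} labelled "African great ape
ancestor", "great apes ancestor" and "Catarrhini ancestor".  Marmoset
(CJA) is an ordinary leaf; its outgroup role is a property of the
rooting, not of the data.

## Strand-state genotyping

A Strand-seq-like library is summarized as binned Watson/Crick read
counts per cell.  Cells whose two homologs inherited the same template
strand (WW or CC) are informative for inversions; WC cells are
discarded rather than phased.  Informativeness is judged by the
majority-strand fraction over background bins; when several candidate
regions lie on one locus the *other* candidate intervals must be
excluded from the background (`exclude=`), because a species carrying
other homozygous inversions otherwise has no clean background at all.
The genome-wide switch scanner, which has no designated target region,
instead reads each cell's template state from the per-bin **median**
Watson fraction, which is robust as long as switched segments cover a
minority of bins.

Genotypes are called by a per-cell binomial likelihood on the
minority-strand count inside the region, p ∈ {ε, ½, 1−ε} for
{dir/dir, dir/inv, inv/inv}, summed over cells.  Defaults: τ = 0.8
(background majority), min_cells = 5, min_margin = 3 nats, ε = 0.05.
These are deliberately conservative for desk-scale simulations (40
cells at ~50 reads/bin give margins of hundreds of nats) and are all
overridable.  Switch scanning uses binary segmentation on the
aggregated minority fraction (split accepted when it reduces the
squared error by ≥ 0.3), then classifies maximal segments of ≥ 5 bins
with mean in [0.35, 0.65] as *partial* (heterozygous signature) and
≥ 0.85 as *complete* (homozygous).  Deletion detection normalizes
per-bin depth by the locus median — robust to inversions, which
preserve depth — and calls runs of ≥ 5 bins at ≤ 0.6 (heterozygous) or
≤ 0.15 (homozygous).

## Homology and SD blocks

The internal aligner is intentionally minimal: exact k-mer anchors
(k = 15) on both strands, chained per diagonal with a per-step gap
bound (2 kbp), identity measured by gapless comparison over the chain
span.  It is exact for the substitution-only sequences the generator
emits; for indel-bearing or real data the supported path is PAF import
from an external aligner.  Identity is matches/alignment-columns (PAF
column arithmetic), not gap-compressed.  Self-alignments exclude the
trivial main diagonal and keep the mirror copy with query start ≤
target start; self mode applies when the same sequence object is
aligned against itself, so two *equal copies* still align normally.

Blocks merge records of equal orientation whose query and target gaps
are both within ±2 kbp; the sign matters — a large negative "gap"
means the same query segment re-aligned to a *different* copy of the
target, which must not be merged (unchecked, this chains all copies of
a repeat into one giant block).  Block identity is the length-weighted
mean; defaults min_len = 1 kbp and min_identity = 0.90 at 1/10 scale
(representing a ~10 kbp working resolution at real scale).  Region
orientation against a reference requires ≥ 80% strand majority of
aligned bases and ≥ 50% coverage, else *unresolved*.

## Parsimony reconstruction

Each region is an independent two-state character even though BP3-BP5
nests BP3-BP4/BP4-BP5 (the nesting is flagged in reports, exactly as
the source genotype table treats it).  Heterozygous species enter as
the ambiguity set {d,i} — cheapest-resolution semantics — and are
reported as polymorphic annotations, not extra events; missing species
contribute the full set.  `fitch_min_changes` is the standard
set-intersection pass; the test suite proves it equal to brute-force
enumeration over all internal assignments for every one of the 3⁶
possible leaf-state characters.  `place_events` enumerates all
most-parsimonious reconstructions and selects the one whose earliest
change lies on the most basal branch, with ties broken by fewer
terminal-branch changes and then lexicographic branch order.  This
encodes the interpretation "one ancestral event plus later reversions"
for discordant characters; the selected placements for the published
table are the published ancestral branches, with the human branch
recurrent for BP3-BP4 and the gorilla branch for BP4-BP5.  Event
direction is reported as a state flip without asserting which
orientation "is" the inversion (for BP4-BP5 the ancestral state is the
non-reference orientation).

Haplotype enumeration uses an explicit phasing rule: each heterozygous
species contributes two haplotypes, the first carrying the direct
allele and the second all inverted (minor) alleles, with the outgroup
excluded; under this rule the published table yields 7 distinct
haplotypes (8 when the outgroup is included — the alternative noted,
not adopted).  The inverted-allele frequency is
(#inv alleles)/(2 × #non-missing individuals); the published *pooled*
human frequency is not computable because the pooled cohort counts are
not printed, so only the cohort arithmetic is implemented.

## NAHR susceptibility

For every BP pair, directly oriented blocks with one side in each
block (assigned by side midpoint) are collected; the flanked interval
runs between the copies' inner edges; susceptibility requires one such
block with identity ≥ 0.95 and length ≥ 10 kbp at real scale (scaled
by the blueprint scale).  Inverted-orientation pairs are reported
descriptively only — they relate to inversion formation, which the
parsimony module handles.  The cross-species expansion fold compares
high-identity direct flanking totals; its threshold defaults to 0.975
rather than a literal 0.98 because printed block identities are
rounded to whole percent, and a copy planted at exactly "98%" has
realized identity symmetric around 0.980.

## The synthetic-data generator

A blueprint lists ordered segments — unique sequence or `sd_copy`
(source, target identity ∈ (0.8, 1], orientation) — with real-scale
lengths divided by a scale factor (default 10, so the published
"~160 kbp at 99%" block becomes 16 kbp at 99%).  Unique segments are
i.i.d. uniform nucleotides; copies receive i.i.d. substitutions at
rate 1 − identity (substitution-only, keeping planted identity
interpretable) and are reverse-complemented when inverted.  Identical
blueprint and seed give bit-identical outputs.

Three shipped blueprints define the study conditions: the *human-like*
architecture (160 kbp @ 99% in both orientations plus 320 kbp @ 98%
direct between BP1 and BP3; 100 kbp @ 98% both orientations between
BP2 and BP3; 35 kbp @ 99% both orientations between BP4 and BP5;
inter-region lengths from the printed coordinates), the *macaque-like*
architecture (sparse, mostly inverted tandem copies; one third of the
human duplication content in total and one sixteenth of its
high-identity direct BP1↔BP3 flanking homology, so the two published
fold changes are planted as truth ratios), and a compact *history*
locus whose five regions are flanked by copies of one shared core
duplication.

Inversion events toggle the net orientation state of a named region on
a tree branch; homozygous events apply to both haplotypes, heterozygous
events to the second haplotype of their designated species; toggling
twice along a lineage restores the ancestral state.  The four disjoint
content regions are realized physically (reverse-complemented in place;
reads from inverted intervals flip strand, with an independent ε
background flip per read; heterozygous deletions silence the carrier
homolog's bins).  The BP3-BP5 span is tracked as its own character and
observed **only** through the probe-order channel: the published
region states are not jointly realizable as strand parities of any
single physical event composition once span events rearrange their
sub-regions, and the original analysis likewise resolved the span with
hybridization assays rather than strand data.  Per-bin homolog counts
are Poisson with mean depth/2, so a diploid bin averages `depth` reads
and W+C totals equal the simulated read count exactly.

What the generator does **not** emulate: read-length/error profiles or
alignment (counts are binned directly, matching how the strand evidence
is consumed), indels (optional in principle, off by default),
sister-chromatid exchanges (one template state per homolog per cell),
positional shuffling of nested inversions, interspersed repeats, and
GC or mappability bias.  Passing recovery tests therefore demonstrate
correctness of the inference logic under the planted model, not
robustness to alignment artifacts or repeat-driven noise in real
libraries.

## Problem sizes

The test suite and the acceptance script use: 1/10-scale loci (~200
kbp for the history locus, ~950 kbp for the human-like architecture);
30–40 cells per individual at 30–50 reads per 1 kbp bin with ε = 0.05;
200 replicate individuals for genotype-recovery rates; single
self-alignments for SD calling.  Everything runs in a few seconds on
one CPU; the scale factor is the single knob for larger experiments.

## Known limitations

* WC cells are discarded, not phased; no composite-file construction
  across libraries and no genome-wide discovery (locus-scoped only).
* The aligner is substitution-aware only; indel-bearing data must come
  through PAF import.
* Discordance is flagged, not probabilistically attributed: there is no
  coalescent model to distinguish incomplete lineage sorting from
  recurrence, and no divergence-time estimation.
* Default thresholds are not calibrated to any real Strand-seq cohort
  (per-individual library counts behind the published calls are not
  reported); they are stated defaults, all overridable.
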