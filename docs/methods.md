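# Methods

This note documents the models, conventions and design choices behind
`longiso`, and what the synthetic-data generator does and does not
emulate.

## Coordinate convention

All internal coordinates are 0-based, half-open `[start, end)` on the
forward genome axis, as in BED.  GTF input (1-based, fully closed) is
converted at the reader boundary (`start−1`, `end`) and converted back on
write; no other module handles a 1-based coordinate.  Transcripts must
carry a `+` or `−` strand: the TSS and the strand-resolved splicing
classes are undefined without one, so strandless GTF transcripts are
dropped (with a logged count) rather than guessed.

## TSS distances and transcript filtering

The TSS is the first transcribed base: the first exon's `start` on `+`,
the last exon's `end − 1` on `−`.  The distance from a TSS to a feature
interval is 0 when the TSS lies inside it, otherwise the gap to the
nearest interval edge (`start` or `end − 1`).  The sign encodes
transcription direction: negative when the nearest feature lies upstream
of the TSS, positive downstream; on `−` transcripts "upstream" is
genomically rightward.  When an upstream and a downstream feature are
equally distant, the downstream one is reported — an arbitrary but fixed
tie-break that never affects the magnitude.

Edge distance (rather than, say, midpoint distance) is the genome-browser
reading of "how far is the nearest peak", and makes "distance 0" coincide
exactly with overlap.

The filter keeps a transcript when at least one track (`any` mode,
default) — or every track (`all` mode) — has a feature with
|distance| ≤ cutoff.  The default cutoff is 1000 bp, the conventional
"within 1 kb of the first nucleotide" window for promoter-proximal
evidence, and the boundary is inclusive.  Distance histograms default to
bins 0, 100, 500, 1000, 5000, 10000, ∞ in |distance|, bracketing that
cutoff from both sides.

Nearest-feature queries binary-search start-sorted per-chromosome interval
lists, walking outward until no remaining interval can beat the best gap
(the leftward walk is bounded using the longest interval length on the
chromosome).  An exhaustive linear scan serves as the test oracle.

## Splicing event classification

Events are local splicing variations between isoform pairs of one gene,
in the seven-type scheme standard for transcript-model analysis.  With
exons written `(s, e)` on the forward axis:

* **SE** — an exon `(s2, e2)` spliced between flanks ending at `e1` and
  starting at `s3` in one path, with the direct junction `e1→s3` in the
  other.  Coordinates `(e1, s2, e2, s3)`.
* **RI** — a single exon `(s1, e2)` in one isoform spanning exactly what
  another splits into `(s1, e1)` and `(s2, e2)`.  Coordinates
  `(s1, e1, s2, e2)`; the retaining isoform is the inclusion form.
* **A5 / A3** — two junctions sharing one boundary while the other edge
  shifts, with the two alternative exons overlapping.  Whether the varying
  site is a donor (A5) or an acceptor (A3) depends on strand: a shared
  genomic-right boundary with varying left edges is A5 on `+` and A3 on
  `−`, and vice versa.  The isoform with the longer exonic form (shorter
  intron) is the inclusion form.
* **MX** — two non-overlapping middle exons, each spliced to the same
  upstream flank end `e1` and downstream flank start `s4`, with no
  isoform carrying both between those flanks.  Coordinates
  `(e1, s2, e2, s3, e3, s4)`; inclusion is the path through the middle
  exon that comes first in transcription direction.
* **AF / AL** — two isoforms whose first (respectively last) exons in
  transcription direction differ, do not overlap, and splice to the same
  inner boundary.  Overlapping alternative terminal exons are A5/A3
  territory instead; requiring non-overlap keeps the two classes
  disjoint.

Non-overlapping *internal* alternative exons at a shared boundary fit
none of the seven classes and are deliberately not reported.

Events are deduplicated at the gene level by a canonical id
`gene;TYPE:chrom:coords:strand`; the same coordinates arising from
different isoform pairs count once, with inclusion/exclusion sets unioned
over supporting pairs.  Detection is index-based (junction, exon and
flank-triple maps per gene); the test suite checks it against an
independent brute-force pairwise enumerator, both on randomized fixture
genes and on an exhaustive grid of genes built from a 6-exon template
with variant edges.

Two geometric symmetries are property-tested: mirroring all coordinates
with the strand *kept* reverses the transcription axis and must swap
A5↔A3 and AF↔AL while fixing SE/RI/MX; mirroring *and* flipping strand is
the reverse complement and must fix every type.

## Sample comparison

Per-sample counts of distinct events by type form a samples × 7 table.
Profiles are compared with Pearson's χ² homogeneity test (no Yates
correction — the table is r×c, not 2×2).  Event types absent from every
sample are dropped before testing so no expected count is zero; tables
with fewer than two non-empty rows or columns are rejected as degenerate
rather than silently returning a statistic.

## Isoform diversity

Per gene and sample, with pᵢ the read-support proportion of isoform i
(zero-support isoforms excluded), the diversity score is the Shannon
entropy H = −Σ pᵢ log₂ pᵢ, in bits: 0 for a single expressed isoform,
log₂ n for n uniformly supported isoforms.  Entropy is used because it is
the canonical scalar measure of how evenly usage spreads across isoforms
and needs no tuning; the scorer sits behind a small interface so an
alternative (e.g. a perplexity or Gini-style score) can be swapped
without touching the ranking code.

The between-sample statistic is D = |H_a − H_b| per gene, sorted
descending with gene-id tie-breaks.  A gene present in only one sample
scores 0 in the other and is flagged `one_sample_only`, so users can
exclude genes whose D reflects detection rather than splicing.  Top genes
are selected by rank prefix or by a D threshold (inclusive).

## GO enrichment

For a query of n annotated genes against a background of N, a term with K
members containing k query genes gets the hypergeometric upper-tail
p-value P(X ≥ k), computed with scipy's stable survival function and
cross-checked in tests against exhaustive enumeration at small N.
Benjamini–Hochberg step-up adjustment controls the FDR across tested
terms (the `p_adj ≥ p` contract is guarded against float rounding).
Terms with fewer than 3 genes are not tested by default — their p-values
are uninformative and they inflate the correction burden.

The annotation file is taken as given: no ontology-graph propagation of
memberships to ancestor terms (users wanting it should pre-propagate),
and the background defaults to all annotated genes, with a user-supplied
background (e.g. all expressed genes) recommended for real data.  The
test suite includes a null calibration: uniformly random queries must
yield at most 5% BH-significant terms on average.

## lncRNA combination, catalog matching, tissue specificity

Coding-potential classification itself is external: PLEK- and CNCI-style
output tables (plus a generic two-column dialect) are parsed and
normalized to {coding, noncoding}.  The four derived sets — each tool,
intersection, union — let users trade precision against recall;
downstream examples default to the intersection.

A candidate is **known** when a catalog entry on the same chromosome and
strand has the identical ordered intron chain.  Intron-chain identity
deliberately ignores terminal-exon extents because long-read models have
ragged 5′/3′ ends; demanding end agreement would flood the "novel" set
with re-detections.  Single-exon candidates have no introns, so they fall
back to reciprocal exonic overlap (default threshold 0.5), which is also
available as an explicit mode.

A known candidate is **tissue-specific** when the union of tissue labels
over all its matched entries has exactly size 1; candidates matching only
unlabelled entries are reported under `unassigned`, and multi-tissue or
novel candidates are omitted.  This is a catalog-annotation notion of
specificity — no expression-based measure (τ etc.) is computed.

## Synthetic-data generator

The generator emulates the *structural* content of a long-read
transcriptome and its companion inputs; it is the basis of almost every
test.

* **Gene models.**  Genes are laid out along two chromosomes with 100 kb
  spacing, each with 5–8 exons of 80–300 bp separated by introns of
  400–2000 bp — compact but realistically proportioned mammalian gene
  shapes.  Strand is random per gene.  An implanted event edits the base
  exon chain (drop an internal exon, merge two exons, shift one junction
  edge, swap the middle exon, swap a terminal exon), so each event gene
  carries exactly the planned event and the truth table lists it in the
  classifier's canonical coordinates.  One event per gene keeps truth
  unambiguous.  Event-free genes emit one isoform, or two sharing the
  intron chain with a shifted outer end (ragged ends create no events).
* **Read supports** are drawn as 1 + NegativeBinomial(r=2, p=0.15),
  giving the skewed, always-positive per-isoform counts typical of
  long-read libraries (median ≈ 10, long right tail); positivity keeps
  entropy defined.
* **Feature tracks.**  One 20 bp feature per transcript and track is
  placed at a planned signed distance drawn from
  {0, ±50, ±200, ±800, ±1500, ±5000} — spanning the histogram bins and
  both sides of the 1 kb cutoff — plus far decoy features per chromosome.
  The 100 kb gene spacing guarantees one transcript's feature can never
  be another's nearest; the generator verifies this and fails loudly on
  collision (e.g. multi-isoform genes sharing a TSS neighbourhood), so
  distance fixtures use single-isoform genes.
* **lncRNA inputs.**  Half the candidates are catalog clones with shifted
  terminal extents (known), half carry a shifted internal junction
  (novel).  Catalog tissue labels cycle single / two / none, and
  classifier calls cycle both-noncoding / A-only / B-only / both-coding,
  so every downstream branch is exercised with known truth.

Not emulated: nucleotide sequence, sequencing error, mono-exonic noise
transcripts, expression-level biology (supports are i.i.d.), overlapping
genes, and multi-event genes (available via an explicit plan but not
default).  Passing tests therefore demonstrate correctness of the
*structural* logic — classification, distances, matching, counting — not
robustness to base-level noise, which lives upstream of this toolkit.

All randomness flows from `numpy.random.default_rng(seed)` with fixed
draw order; identical seed and spec give byte-identical files.

## Figures

Every plot writes a JSON layout manifest beside the image (exon boxes
with genomic coordinates, bar percentages, histogram counts, Venn region
counts).  Tests assert on manifests and only smoke-test the rendered
file: pixel comparisons are brittle across fonts and matplotlib
backends.  Colors are style roles (novel red, known long-read black,
annotation blue, per-mark arrow colors), overridable per call.

## Numerical choices and degenerate inputs

* χ² drops all-zero event-type columns; degenerate tables raise.
* Missing nearest features (empty chromosome) are reported as missing
  values, never as sentinel integers.
* Entropy excludes zero-support isoforms; an all-zero gene raises.
* BH adjustment clamps to `p_adj ≥ p` against rounding; agreement with
  statsmodels is tested to 1e-12.
* Readers fail with line-numbered errors on malformed records instead of
  skipping silently (except GAF, where unparseable lines are skipped with
  a logged count, matching common practice for that format).

## Problem sizes

Defaults used by the test suite and the acceptance script: 21 event genes
(three per type), 200 single-isoform genes × 4 tracks for distance
recovery, 30 lncRNA candidates against a 15-entry catalog, a 60-gene ×
12-term annotation with 500–1000 null queries, and an exhaustive
~1900-case template grid for oracle equivalence.  These sizes make every
structural code path and all seven event types well represented while the
whole suite runs in seconds.
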