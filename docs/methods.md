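# Methods

## Promoter model

A gene's promoter is the fixed-length window immediately upstream of its
transcription start site (TSS), taken on the gene's own strand. Internally
all coordinates are 0-based half-open; GFF3 input (1-based inclusive) is
converted on read and human-readable headers print 1-based inclusive.

Conventions, all deliberate and fixed:

- **Anchor.** The annotated TSS (the 5'-most base of the `gene` feature) by
  default; `anchor=cds_start` switches to the 5'-most CDS base for
  annotations where the transcription start is unreliable. Either choice
  shifts windows by the 5'-UTR length; TSS is the conventional reading of
  "upstream promoter region".
- **Window.** `promoter_length` bases (default **3000**) ending at, and
  excluding, the TSS base: for a + gene the forward-strand interval
  `[tss−L, tss)`; for a − gene `[tss+1, tss+1+L)` reverse-complemented so
  the returned string always reads 5'→3' toward the gene. "Upstream" is
  conventionally exclusive of the start base; either convention shifts
  results by 1 bp, so one is fixed and documented.
- **Truncation.** Windows are clipped at chromosome bounds and flagged, not
  dropped; `len(sequence) + clipped = L` always. Truncated promoters stay in
  the denominator of the representation statistic unless `--drop-truncated`
  is given, because a clipped promoter is still evidence about motif
  presence. No trimming at upstream neighboring genes (fixed-window
  semantics); isoform-aware promoters and repeat masking are out of scope.

## Motif model and scanning

CRE motifs are degenerate consensus strings over the 15 IUPAC codes, grouped
into CRE families: a family such as the MYB-binding site may list several
variants, and a promoter carries the family if **any** variant matches.
Grouping with OR-over-variants is the only reading compatible with
reporting one percent per CRE family.

Scanning tests every window of each variant's length on the + strand
(pattern vs window) and the − strand (reverse-complemented pattern vs
window, equivalent to pattern vs reverse-complemented window). Both strands
are scanned by default because CRE function is generally
orientation-independent; `--strands forward` disables the reverse strand.
Implementation is a compiled regex with a lookahead so overlapping hits are
all reported; the test suite checks it against an independent per-window,
per-position set-membership oracle on random sequence/pattern pairs.

Two edge rules:

- A sequence `N` satisfies a pattern position only when that position allows
  the full `{A,C,G,T}` set: the scanner never claims a match the sequence
  cannot guarantee.
- A self-reverse-complementary pattern (e.g. `CANNTG`) produces mirrored
  +/− hits over the same span; both are reported in the occurrence list but
  they count as **one** presence span, so `--min-occurrences` thresholds are
  not inflated by palindromes.

Presence/absence — not occurrence counts — drives the statistic, since the
question is how many *genes* carry a CRE; counts are still emitted for
reporting, and `--min-occurrences k` (default 1) requires k distinct spans.

## Representation tiers

For CRE *c* and gene set *S*, `f = n_present / n_total` is carried as an
exact rational (`fractions.Fraction`). Tiers partition [0, 1]:
over-represented on [0.75, 1], moderately over-represented on [0.50, 0.75),
under-represented on [0, 0.50). The half-open boundaries are the only
partition consistent with describing the moderate band as "50–74%" and the
under band as "≤49%" in integer percents while leaving no fraction
unassigned: 74.9% is moderate, 49.5% is under. Display percents are rounded
to integers in reports but never before classification (747/1000 prints as
75 yet classifies moderate). Thresholds are configurable
(`--over`, `--moderate-low`) with the invariant 0 < moderate_low < over ≤ 1.

No significance test is attached. The scheme is a descriptive threshold
classification; adding a hypergeometric/binomial enrichment test against a
genomic background would change the method, and is deliberately out of
scope.

The classification-only mode consumes a `cre_id / percent_up / percent_down`
table; a blank cell means the CRE is absent from that set's listing and is
excluded from that set's tier counts. Percent values are converted to exact
fractions via their decimal string, so printed integers classify exactly.

## Category rollup

Each CRE's catalog entry carries its interacting TFs and category tags from
a fixed growth/stress/light vocabulary plus free-form hormone tags (ABA, JA,
SA, CK, GA, BR, auxin, ...). Category summaries use multi-membership
counting — a CRE tagged both stress and light contributes to both counts —
because CRE families genuinely serve several response classes at once.

The bundled `example_catalog.tsv` is a convenience fixture of widely cited
consensus forms (W box `TTGACC/TTGACT`, E box `CANNTG`, GATA box `WGATAR`,
I box `GATAAG`, ...); it is illustrative, not authoritative database
content, and no quantitative check in this package depends on its
sequences. `synthetic_gene_labels.tsv` is likewise a synthetic stand-in
gene list (random AGI-style identifiers) at a realistic two-set size of
61 up / 54 down genes.

## Synthetic data generator

The generator emulates a typical two-set differential-expression design:
two labeled gene sets
(defaults **61 up / 54 down**) with **3-kb** promoters, i.i.d. background
base composition (default uniform), and each CRE planted independently per
gene with a set-specific Bernoulli probability at a uniform random offset.
One synthetic chromosome per gene (promoter + 100 bp upstream pad + 200 bp
gene body) avoids promoter-overlap bookkeeping; strands alternate + / − so
both extraction branches are exercised. Output files (FASTA, GFF3, label
TSV, truth TSV) are byte-identical across reruns with the same seed
(default 20230131).

Planting may overwrite background or earlier plants, so the **truth table
records post-hoc re-scan ground truth** — what is actually present in the
final promoter — rather than planting intent. Recovery checks are therefore
exact: with a pure-A background and a C-containing motif, background hits
are impossible and the observed presence fraction equals the planted
fraction identically.

What the generator does **not** emulate: promoter grammar (nucleosome
positioning, GC/CpG structure, motif clustering near the TSS), linked genes
on shared chromosomes, and phylogenetic conservation. Passing recovery
tests therefore demonstrates correctness of the bookkeeping and the
scanner, not realism of background hit rates on real genomes, where short
degenerate motifs (the catalog warns below 4 bp) are near-saturated.

## Verification design and problem sizes

- Scanner correctness: 200 random (sequence ≤50 bp, IUPAC pattern ≤8 bp)
  pairs against the naive oracle, both strands, plus strand-symmetry of the
  presence matrix on 50 random 8-promoter sets.
- Tier boundaries: fixed boundary cases plus a 10,000-fraction partition
  sweep and hypothesis property tests (derandomized profile).
- Deterministic percent recovery: 40 pure-A promoters (1 kb) with a W-box
  instance planted in 30 give exactly 75% / over-represented; this is also
  what `scripts/acceptance.py` recomputes.
- Stochastic recovery, with seed lists fixed in advance (0–19 and 0–49):
  planting probabilities 0.9 / 0.6 / 0.2 at 100 genes must recover the
  over / moderate / under tier in ≥48 of 50 seeds (binomial tail bounds
  make misclassification vanishingly rare at these distances from the
  thresholds); observed presence counts at 200 genes must fall inside the
  exact central binomial 99% interval (`scipy.stats.binom.interval`) in at
  least 18 of 20 seeds. The 18/20 acceptance region is the ~0.1%-level
  exact test of the 99%-coverage property: each seed independently misses a
  99% interval with probability ≤1%, so demanding 20/20 would falsely
  reject a correct generator ≈18% of the time, while three or more misses
  has probability ≈0.1% under correct coverage.
- Promoter lengths in stochastic tests are 300 bp rather than 3 kb: with a
  pure-A background the presence statistic is independent of promoter
  length, so the shorter windows change nothing but the constant factor in
  runtime.

## Known limitations

- Consensus matching has no mismatch tolerance and no match-quality score;
  a PWM-based scanner would rank sites but answers a different question.
- The fixed-window promoter ignores neighboring-gene boundaries and
  alternative TSSs.
- Tier calls on small gene sets are sensitive to single genes (1/61 ≈ 1.6%
  steps); the exact-fraction boundaries make the behavior reproducible but
  cannot add statistical power the design does not have.
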