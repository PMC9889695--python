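# crescan

Promoter cis-regulatory-element (CRE) scanning and representation-tier
analysis for labeled gene sets.

## The problem

When a treatment changes the expression of a set of genes, the transcription
factors (TFs) driving that response leave a footprint in the genes'
promoters: short degenerate DNA motifs — cis-regulatory elements such as the
W box (bound by WRKY TFs), the GATA box, the E box, or MYB-binding sites.
Asking *which CRE families are unusually common among the up- and
down-regulated genes* is a standard first step toward the signaling pathways
involved. `crescan` implements that analysis end to end for anyone with a
genome FASTA, a gene annotation, a two-way gene-set labeling (up/down), and
a catalog of CRE consensus motifs.

## The statistic

For each CRE group *c* (one or more IUPAC consensus variants) and each gene
set *S*, the pipeline computes the presence fraction

&nbsp;&nbsp;&nbsp;&nbsp;f(c, S) = |{g ∈ S : promoter(g) carries ≥ 1 occurrence of any variant of c, on either strand}| / |S|

over a fixed upstream promoter window (3 kb upstream of the TSS by default,
TSS base excluded). Each CRE is then assigned a representation tier from the
exact fraction:

| tier | fraction |
|---|---|
| over-represented | f ≥ 0.75 |
| moderately over-represented | 0.50 ≤ f < 0.75 |
| under-represented | f < 0.50 |

and the up- and down-regulated sets are compared at each tier (common /
up-only / down-only CREs). Matching is exact set-membership per IUPAC
position — no position weight matrices, no mismatches — and a sequence `N`
only satisfies a pattern position that allows all four bases. Classification
always uses the exact rational fraction, never the rounded display percent.

A classification-only mode reanalyzes a precomputed percent table
(`cre_id<TAB>percent_up<TAB>percent_down`) without any sequences, which is
how published percent columns can be re-classified and compared.

## Worked example

Classify the packaged percent table for the over-represented tier listing
(`src/crescan/data/table1_overrepresented.tsv`, 25 CRE groups with percent
columns for an up-set and a down-set):

```bash
crescan classify \
    --percent-table src/crescan/data/table1_overrepresented.tsv \
    --out demo_out
```

prints

```json
{
  "up": {
    "overrepresented": 22,
    "moderately_overrepresented": 3,
    "underrepresented": 0
  },
  "down": {
    "overrepresented": 10,
    "moderately_overrepresented": 1,
    "underrepresented": 0
  }
}
```

i.e. 22 CREs are over-represented (≥75% of promoters) among the up-regulated
genes and 10 among the down-regulated genes. `crescan report --run-dir
demo_out` adds the set comparison:

```
CREs over-represented in both sets (7): DRE_LIKE_MOTIF, GATA_BOX, I_BOX,
MYB_BINDING_SITE, RAV1_BINDING_SITE, SORLIP, W_BOX
```

— seven CRE families (DRE-like motif, GATA box, I box, MYB-binding site,
RAV1-binding site, SORLIP, W box) are over-represented in both gene sets.

For the sequence mode, generate a fully synthetic dataset with known
planting probabilities and run the whole pipeline on it:

```bash
crescan simulate --n-up 10 --n-down 10 --promoter-length 500 \
    --catalog src/crescan/data/example_catalog.tsv \
    --plant-prob W_BOX:1.0:0.2 --seed 1 --out sim_data
crescan scan --genome sim_data/genome.fasta --annotation sim_data/genes.gff3 \
    --labels sim_data/labels.tsv --catalog src/crescan/data/example_catalog.tsv \
    --promoter-length 500 --out sim_out
```

The output directory contains the extracted promoters (FASTA), all motif
occurrences (BED + TSV), the gene × CRE presence matrix, the classified
representation table, the tier comparison, and a category summary joining
each CRE to its TFs and growth/stress/light/hormone tags.

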