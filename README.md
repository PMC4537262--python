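# pankit

Comparative bacterial pan-genome analysis as a reusable, tested Python
package:

* **`matrix_io`** — parse ortholog cluster files (OrthoMCL "groups" dialect)
  or strain×group TSVs into an occurrence matrix; partition groups into
  core / moderately common / rare; pairwise shared-ortholog counts with
  complete-linkage clustering (Newick out); well-spaced housekeeping-marker
  selection on a reference genome.
* **`curves`** — pan/core/new-gene accumulation curves over random strain
  inclusion orders (exact enumeration for ≤ 8 strains), power-law fitting
  (`y = k·xᵅ`), power-plus-linear core fitting (`y = K·xᵃ + b·x + c`),
  openness classification (open iff −1 < α < 0), threshold extrapolation
  (smallest N with `k·Nᵅ ≤ t`), and a delete-half jackknife of the exponent.
* **`core_additions`** — gene sets conserved in every member of a strain
  subset and absent from all others, with exhaustive or sampled nulls over
  random subsets of the same size.
* **`compatibility`** — four-gamete compatibility scoring of presence/absence
  characters with a within-character permutation null.
* **`ani`** — fragment-based average nucleotide identity (1020-bp fragments;
  retain matches with > 30 % overall identity over ≥ 70 % alignable length;
  ANI = mean local identity of retained matches). Ships a dependency-free
  seed-and-extend aligner and an optional `blastn` adapter.
* **`profiles`** — GC content, genome-length summaries with an exact
  Mann–Whitney group comparison, glycoside-hydrolase family PCA (with the
  peptidoglycan families GH23/25/73/103 excluded by default), per-family
  Kruskal–Wallis under Holm–Bonferroni, and functional-class enrichment
  across pan-genome partitions under Benjamini–Hochberg.
* **`synthetic`** — simulators for pan-genome matrices (Beta frequency
  spectrum or an "open stream" process with a tunable Heaps-like exponent)
  and genome pairs with controlled substitution divergence, GC content and
  indels; every downstream stage is testable without external downloads.

## CLI

All functionality is exposed through one `pankit` entry point:

```sh
pankit simulate pangenome --n-strains 20 --n-core 100 --model open-stream \
    --seed 1 --out groups.txt --truth-out truth.json
pankit matrix summarize groups.txt
pankit curves fit groups.txt --n-perm 10000 --seed 1
pankit curves jackknife groups.txt --n-subsamples 2000 --n-perm 1000 --seed 1
pankit curves threshold --k 469.7 --alpha -0.76 --threshold 1
pankit core-add run groups.txt --subset S1,S2
pankit core-add null groups.txt --m 2 --exclude S1,S2
pankit compat --matrix groups.txt --n-perm 1000 --seed 7
pankit simulate seqpair --length 200000 --sub-rate 0.02 --seed 1 --out pair.fna
pankit ani pair query.fna reference.fna --aligner internal
pankit stats gc genome.fna
pankit stats lengths *.fna --labels labels.tsv --compare infantis,longum
pankit profile pca gh_counts.tsv --labels labels.tsv --out coords.csv
pankit enrich partitions groups.txt --classes classes.tsv --out enrichment.csv
```

## Notes on conventions

* Presence is binary (occurrence ≥ 1) everywhere except where counts are
  explicitly used; paralog multiplicity is preserved in the matrix but
  collapsed for sharing, core additions and compatibility.
* Shared-ortholog counts use binary presence (whether paralog counts should
  enter is not standardised; this choice is documented here).
* Coordinates are 1-based inclusive (GFF convention).
* `α = −1` classifies as *closed* (the open band is strictly −1 < α < 0).
* Pairwise ANI reports the mean of the two directional values; both
  directions are available on the result objects.
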