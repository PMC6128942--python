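# barcode-eval

Distance-based evaluation of DNA-barcode reference libraries.

DNA barcoding identifies specimens by comparing a short standard marker —
for animals the ~658 bp 5' fragment of mitochondrial COI — against a
reference library of sequences from morphologically identified specimens.
Whether that works for a given taxon depends on the *barcode gap*: whether
intraspecific divergence stays below the divergence between species. This
package implements the standard distance-based toolkit used to audit a
reference library (curators of COI libraries, barcoding practitioners,
and anyone benchmarking threshold-based identification):

* **K2P distances.** Pairwise Kimura two-parameter distances with
  pairwise deletion of gaps/ambiguities. For transition and transversion
  difference proportions *P* and *Q* over the compared sites,

  d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)

  Saturated pairs (log argument ≤ 0) are flagged undefined, never capped.
* **Intra/interspecific decomposition** of the distance matrix, with
  mean [min–max] summaries in the conventional percent notation.
* **Optimal threshold (OT) by cumulative-error minimization.** At a
  threshold *t*, a sequence is a false positive (FP) if its nearest
  conspecific lies beyond *t*, and a false negative (FN) if any
  heterospecific lies within *t*. The cumulative error CE(*t*) = FP + FN
  is scanned over a grid (default 0.1%–10% in 0.1% steps) and OT is the
  argmin, smallest *t* on ties. Scans run per family and per subfamily
  partition, and the two schemes are compared with a Student *t* test on
  per-sequence error indicators.
* **Best Close Match (BCM) identification.** Each sequence is classified
  by the species of its minimal-distance matches within *t*: correct /
  incorrect / ambiguous / no id, with the convention that a singleton
  species with no match inside *t* counts as correct.
* **Haplotype networks.** Specimens collapse into haplotypes
  (missing-data tolerant) and a minimum-spanning network — the union of
  all minimum spanning trees of the Hamming-distance graph — visualizes
  problem groups, in particular haplotypes shared between species.
* **Synthetic library generator.** Star-phylogeny K2P simulation with
  controlled intra/interspecific targets, transition bias, singleton
  frequency, subfamily structure, and injectable failure modes (shared
  haplotypes, near-zero interspecific pairs, deep intraspecific splits),
  so the whole pipeline is testable without downloading any data.

## Worked example

```python
from barcode_eval import (SimulationConfig, simulate_library, distance_matrix,
                          decompose, threshold_scan, default_grid,
                          best_close_match)

cfg = SimulationConfig(seed=42, n_subfamilies=2, species_per_subfamily=8,
                       seqs_per_species=3, alignment_length=658)
library, truth = simulate_library(cfg)
matrix = distance_matrix(library, model="K2P")
summary = decompose(matrix, library).summary()
scan = threshold_scan(matrix, library.species_labels, default_grid())
report = best_close_match(matrix, library.species_labels, scan.optimal)
```

prints (via the obvious format strings):

```
intra mean 2.1% [0.6-4.1]
inter mean 22.2% [5.5-44.7]
optimal threshold 3.5%  CE 0 (FP 0, FN 0)
BCM efficiency 100.0%  counts {'correct': 48, 'incorrect': 0, 'ambiguous': 0, 'no_id': 0}
```

Intraspecific divergence (mean 2.1%) stays well below interspecific
divergence for every sequence, so a threshold at 3.5% separates them with
zero cumulative error and every one of the 48 sequences identifies to the
right species. On real libraries the two distributions overlap; the same
calls then report which sequences fail, and the haplotype-network module
shows why (e.g. two species sharing one COI haplotype).

The same analyses are available from the shell:

```bash
barcode-eval simulate --seed 42 --out-prefix lib
barcode-eval run --fasta lib.fasta --metadata lib.tsv --outdir out
barcode-eval bcm --fasta lib.fasta --metadata lib.tsv --threshold auto
```

`run` writes a versioned `report.json` plus TSV tables (distance matrix,
per-threshold scans, per-sequence BCM states) and GraphML networks for
flagged species groups.

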