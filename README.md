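# sscoi

Toolkit for building and verifying species-specific COI (SS-COI) PCR
assays from taxon-labeled DNA barcode panels:

- **seqio** — FASTA / sample-sheet / Newick / distance-TSV I/O and
  validated labeled alignments (records carry a species label and a
  target / non-target role).
- **phylo** — uncorrected p-distance matrices (pairwise or complete
  deletion), neighbor-joining trees, and nonparametric bootstrap support.
- **diagnostic_scan** — per-column conservation/divergence profiles and
  discovery of windows conserved within the target taxon but divergent
  against every non-target species.
- **primer_design** — primer candidate enumeration inside diagnostic
  windows under length/GC/Tm/homopolymer/3'-self-complementarity
  constraints, Wallace and nearest-neighbor melting temperatures, pairing
  by product size and Tm spread, annealing-temperature recommendation.
- **insilico_pcr** — degenerate-aware (IUPAC) primer binding with a 3'
  clamp rule, amplicon prediction, specificity and mixture panels, and a
  text virtual gel against the DL2000 ladder.
- **synthetic_panel** — simulated barcode panels with controlled
  within-target and between-species divergence and optional planted
  primer binding sites, so the whole pipeline is testable offline.

## CLI

```sh
# simulate a labeled panel (29 records, 658 bp) with planted diagnostic
# primer sites
sscoi simulate --seed 1 --out panel.fa --sheet panel.tsv \
      --truth truth.json --plant-asm-primers

# p-distance matrix + NJ tree with bootstrap support
sscoi tree --fasta panel.fa --sheet panel.tsv --replicates 1000 \
      --seed 1 --out-prefix run

# diagnostic windows + ranked primer pairs
sscoi design --fasta panel.fa --sheet panel.tsv --out-prefix design

# in-silico specificity panel + virtual gel for a primer pair
sscoi verify --fasta panel.fa \
      --fwd CCTTCTACTTTTATCTTTACCTGTT --rev ATTGTAGCAGAGGTAAAG \
      --out-prefix verify
```

Exit codes: 0 success, 2 validation error, 3 empty result (no windows /
no pairs). Every command writes a `.log` echoing the effective
configuration and input digests.

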