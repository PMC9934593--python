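# mycobarcode

DNA-barcoding hundreds of individual fungarium specimens in a single
sequencing run — the analysis toolkit for a nested-barcode, two-step-PCR
metabarcoding workflow applied to *specimens* rather than environmental
communities.

Natural-history fungal collections hold far more taxonomic information than
Sanger sequencing can affordably unlock: many specimens are old, degraded, or
carry doubtful identifications. The workflow this package supports multiplexes
hundreds of specimens into one Illumina MiSeq run by combining a 5-bp inline
barcode and a variable heterogeneity spacer in the first PCR (targeting the
nrITS2 region with fITS7/ITS4 primers, flanked by Fluidigm CS tags) with
Illumina indices added per pool of eight barcoded specimens in a second PCR.
Each specimen then yields its own read pool, and a single DNA barcode must be
distilled from it.

## What the package does

- **scheme** — validates the primer/barcode/spacer construct
  (`cs1 + spacer + fITS7` forward, `cs2 + spacer + barcode + ITS4` reverse),
  enforces pairwise barcode Hamming distance ≥ 3, assigns specimens to pools
  of eight with cycling barcodes, and maps gel assessments (strong/weak/none)
  to pooling volumes (3/5/10 µL).
- **simulate** — generates seeded synthetic runs with full ground truth:
  per-specimen templates, log-normal read depths (reduced for "no visible PCR
  band" specimens), quality-dependent substitution errors, two-parent
  chimeras, and cross-specimen contamination; outputs per-pool and
  per-specimen paired FASTQ.
- **trimdemux** — spacer-tolerant inline-barcode demultiplexing (≤1 barcode
  mismatch, ≤2 IUPAC-aware primer mismatches) and 3′ read-through trimming
  with a 200-bp minimum-length filter.
- **denoise** — expected-error filtering (EE = Σ 10^(−Q/10) ≤ 3), collapse of
  reads into denoised sequence variants with supporting counts, exact-overlap
  merging of forward/reverse variants into full fragments, and per-specimen
  bimera removal.
- **select** — picks the most read-supported variant as each specimen's
  representative barcode (a real barcode is expected to have > 2× the reads
  of any other variant; closer calls are flagged ambiguous, ties broken by
  table order), and computes run-level depth/success statistics.
- **compare** — local affine-gap alignment (match +2, mismatch −3, gap open
  −5, extend −2) of representatives against Sanger/reference FASTA, percent
  identity and subject coverage, similarity bins (97.5–100 / 95–97.5 /
  90–95 / 85–90 / <85), and genus-level concordance verdicts
  (concordant / discordant-nomenclature / putative-contaminant / unresolved).
- **motu** — extracts MOTUs from a bootstrap-annotated Newick tree: clades of
  ≥ 4 tips with support > 75, or the highest-supported polytomy of ≥ 6 tips,
  resolved rootmost-disjoint, with a modal species-label agreement
  requirement.

## Worked example

Simulate a 12-specimen run with the bundled demonstration scheme and push it
through the whole pipeline:

```bash
mycobarcode simulate --scheme src/mycobarcode/data/demo_scheme.yaml \
    --out sim --n-specimens 12 --depth-mean 120 --seed 42
mycobarcode run-all --scheme src/mycobarcode/data/demo_scheme.yaml \
    --sheet sim/specimen_sheet.tsv --pools sim/pools --out run
```

The first command reports
`simulated 12 specimens, 1187 read pairs, 2 pools`. The second writes
per-specimen FASTQ, variant tables, `representatives.fasta` and a run summary,
and prints the aggregates, beginning:

```json
"raw_pairs":      {"mean": 98.9, "median": 91.0, "n": 12},
"raw_pairs_by_amplification": {
    "amplified": {"mean": 122.6, "median": 125.5, "n": 8},
    "none":      {"mean": 51.5,  "median": 54.0,  "n": 4}}
```

Specimens whose PCR showed no band get fewer reads (here 51.5 vs 122.6 on
average) but still yield usable barcodes — the central premise of the
approach. `run/run_summary.tsv` holds the per-specimen rows:

```
catalog_id  taxon_label         year  gel_category  raw_pairs  representative_support  ambiguous
FS0001      Lactarius montanus  1960  weak          46         46                      False
FS0002      Russula montanus    2010  weak          214        214                     False
```

and `run/representatives.fasta` one barcode per specimen
(`>FS0001 support=46`). MOTU extraction from a bootstrap tree:

```bash
mycobarcode motu --tree src/mycobarcode/data/demo_tree.nwk --out motus.tsv
# extracted 4 MOTUs -> motus.tsv
```

## Data notes

The bundled `demo_scheme.yaml` uses the public fITS7/ITS4 primers and
Fluidigm CS1/CS2 tags, but its eight 5-bp barcodes are a synthetic
demonstration set, and `demo_tree.nwk` is a synthetic demonstration
phylogeny — neither reproduces any published study's oligos or data.
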