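# Methods

This note documents the models and procedures implemented in `mycobarcode`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical/design decisions made
where the underlying workflow left them open.

## The library construct and pool layout

PCR1 oligos follow the grammar

```
forward: CS1-tag + spacer(0–6 bp) + fITS7
reverse: CS2-tag + spacer(0–4 bp) + barcode(5 bp) + ITS4
```

with the CS tag 5′-most so that PCR2 index primers can anneal to it. The
heterogeneity spacers phase-shift the low-diversity primer bases across the
flow cell; the simulator samples a spacer uniformly per read, which treats
frame diversity as the spacers' purpose rather than assuming any batch
structure (an assumption — a lab might instead fix one spacer per primer
aliquot).

Barcode sets are validated to pairwise Hamming distance ≥ 3 at load time.
This is what makes the default demultiplexing tolerance (≤ 1 barcode
mismatch) provably unambiguous: two barcodes at distance ≥ 3 cannot both be
within one mismatch of the same read. Eight barcodes is the standard layout
(pools of eight specimens, one reaction per pool: 766 specimens fill 94
pools of eight plus two of seven); other set sizes are accepted with a
warning. Pool remainders are spread so pool sizes differ by at most one
("balanced" policy, configurable to "greedy"), and barcode ids cycle 1..n
within each pool. Gel assessments map to pooling volumes 3 µL (strong),
5 µL (weak), 10 µL (no visible band) — weaker products are sampled more
heavily to roughly normalise pool composition.

## The synthetic-data generator

`simulate.SimConfig` defaults describe a MiSeq-Nano-scale fungarium run:

| parameter | default | rationale |
|---|---|---|
| depth | log-normal, mean 800 pairs/specimen, σ = 0.5 | raw depth scale of a ~766-specimen Nano run |
| no-band fraction / depth multiplier | 0.18 / 0.85 | ~18% of specimens show no PCR band yet still average ~0.85× the overall depth |
| mean Phred / 3′ decay / jitter | 36.5 / 0.02 per base / σ = 3, clamped [2, 40] | run-level mean quality ≈ 36.5; the profile shape (linear decay + Gaussian jitter) is this package's own model |
| substitution errors | per base, probability 10^(−Q/10) × `error_scale` | errors consistent with the emitted qualities; `error_scale=0` gives noise-free runs |
| chimera rate | 0.02 per read | two-parent (bimera) PCR artefacts |
| contamination | 8% of specimens; contaminant read fraction U(0.5, 0.95) | ~8% of specimens in this kind of run yield a barcode that is not their own taxon. Observed contamination is *defined* by the wrong sequence winning the read pool, so the simulated contaminant fraction is drawn to dominate; a sub-majority contaminant would be invisible to the representative-selection criterion and appear only as a minor variant |
| template length | uniform 220–400 bp | ITS2 fragments between fITS7 and ITS4 essentially never fall below the pipeline's 200-bp post-trim floor; templates under the floor would be deterministically discarded by design, so the default range keeps every specimen recoverable and the floor is exercised separately in tests with short templates |
| read length | 250 | 2 × 250 bp paired-end chemistry |

Each noise process (sheet, templates, depths, contamination, chimera
decisions, chimera details, construct, quality/errors) consumes an
independent substream spawned from the run seed: identical configs reproduce
runs byte-for-byte, and raising one rate does not perturb another process's
draws (so, e.g., labelled chimeric read counts are monotone in the chimera
rate).

Chimeric reads join a prefix of one parent to the suffix of another at a
uniform interior breakpoint. Parents are drawn from the sequences actually
present in the specimen's reaction (its template, plus the contaminant
template when contaminated); a "chimera" of a template with itself is the
template, so single-source specimens emit ordinary reads in that case.

What the generator does **not** emulate: PCR-cycle-level amplification bias,
index hopping, indels (off by default; the denoiser treats indel variants as
distinct sequences), intragenomic ITS variation, quality-dependent
base-call biases, or adapter artefacts beyond clean 3′ read-through.
Passing tests on this generator therefore demonstrate the pipeline's logic
and bookkeeping — demultiplexing, filtering arithmetic, variant collapse,
chimera structure, selection — not its robustness to every failure mode of
real herbarium DNA.

## Demultiplexing and trimming

R2 reads are scanned at every candidate spacer length s ∈ 0–4: the 5-mer at
offset s is matched against the pool's barcodes (≤ 1 mismatch) and the
following window against ITS4 (≤ 2 mismatches, IUPAC-aware). The candidate
with the fewest total mismatches wins; equal-scoring distinct barcodes yield
`ambiguous_barcode`, and reads failing the barcode or primer check are
recorded as `no_barcode` / `no_primer`. Tolerances are configurable; the
defaults keep the barcode tolerance below half the enforced minimum barcode
distance. A strict zero-mismatch call is tallied alongside for
comparability. The assigned + unassigned partition is asserted on every
pool.

3′ read-through (fragments shorter than the read) is trimmed by locating the
reverse complement of the opposite primer: a full-pattern approximate infix
search (edlib, error rate 0.1, rightmost best-scoring hit) followed by a
3′-terminal partial-prefix scan (≥ 5 bp) for read-through shorter than the
primer. Pairs are discarded when either trimmed mate is shorter than the
scheme's minimum (200 bp); the filter is resolved at pair level to keep
mate files synchronized, with per-mate counts retained in the trim report.

## Filtering, denoising, merging, bimera removal

Reads are truncated at the first base with Q < 2 and pairs kept when both
mates have expected errors EE = Σ 10^(−Q/10) ≤ 3. The denoiser is a
deliberate simplification of learned-error-model denoising: after
dereplication, sequences are processed in descending abundance and absorbed
into the most abundant earlier equal-length sequence within Hamming distance
`d_max` (default 2) whose accumulated count is at least `r_min` (default 4)
times their own. The output contract — unique sequence variants with
supporting read counts, counts conserved — matches the original tool; the
likelihood machinery does not, which is why run statistics downstream of
denoising are expected to track, not reproduce, those of the original
workflow.

Forward and reverse variants are paired through the read-to-variant
assignment, reverse-complemented, and merged at the longest end-gap-free
overlap ≥ 12 bases with 0 mismatches (both configurable; these are the
conventional merge defaults, as the workflow itself states none).
Unmergeable classes are dropped with their counts logged.

A merged variant C is removed as a bimera when two distinct variants A and B
in the *same specimen's* table each carry ≥ 2× C's reads and C equals A's
prefix joined to B's suffix at some interior breakpoint (exact comparison,
prefixes anchored 5′, suffixes 3′). Parent abundance is judged on the input
table in one pass, without cascading.

## Representative selection and run statistics

The representative barcode is the top-count bimera-free merged variant. A
true barcode is expected to carry more than twice the reads of any other
variant; a representative at or below that margin is *flagged* ambiguous,
never dropped — intragenomic variants and low-level contamination are facts
of the data, and downstream users decide. Exact ties take the first variant
in table order, recorded via `tie_broken`. Empty tables are recorded
failures. The run summary reports mean/median raw, filtered and merged
depths, grouped by amplification success (strong+weak vs none) and
collection decade, plus failure counts and representative support — the
same statistics used to judge the multiplexing approach.

## Concordance scoring

Alignment is local (Smith–Waterman) with affine gaps, match +2, mismatch −3,
gap open −5 (covering the first gapped base), extend −2 — a
megablast-like scheme, configurable. Among co-optimal alignments the
reported one maximises, lexicographically, (score, matches, −gap columns,
−mismatches), then ends earliest in row-major order, with a fixed
within-cell move preference. The first four criteria are symmetric in query
and subject, which makes percent identity (matching columns / aligned
columns) exactly symmetric; percent coverage (aligned subject span /
subject length) is intentionally not — with the Illumina representative as
subject, it measures how much of the barcode a trimmed Sanger read covers.
The implementation is a numba-compiled Gotoh DP; the test suite checks it
cell-for-cell against an independently written pure-Python DP with the same
documented policy.

Best-hit search is exhaustive by default; an optional shared-k-mer prefilter
aligns only the top candidates and is tested to leave top hits unchanged.
Identity bins are half-open at their lower edges ([97.5, 100] closed at the
top): 97.5–100, 95–97.5, 90–95, 85–90, <85.

Concordance is automated at genus level: same genus → concordant; genera
linked only by a user synonym map → discordant_nomenclature; an unrelated
genus at ≥ 90% identity → putative_contaminant; everything else (including
unparseable labels) → unresolved. Species-level adjudication of
misidentifications versus nomenclature changes is curatorial judgment and
deliberately out of automated scope.

## MOTU extraction

From a bootstrap-annotated tree (supports as internal node labels or
bracketed comments), MOTU candidates are internal nodes with support > 75
and ≥ 4 tips ("more than three sequences"), plus multifurcating nodes with
≥ 6 tips ("more than five") — on any nested path of polytomy candidates
only the highest-supported survives, with missing support counted as 0 and
ties resolved rootward. Nested candidates overall resolve to the rootmost,
making MOTUs tip-disjoint. A kept clade must show modal species-label
agreement ≥ 0.5 among labelled tips (threshold configurable; collections
include unidentified material), and clades with no labelled tips are
dropped. Trees are consumed as given by default; midpoint or outgroup
rerooting is available but changes no MOTU whose clade the root does not
cross. Where a node qualifies through both arms, it is reported as a
supported clade.

## Problem sizes and determinism

The bundled checks run at desk scale: a 16-specimen noise-free run and a
100-specimen run at depth mean 200 (the default noise rates), sizes at which
every stage's behaviour is already fully exercised while a complete
simulation-plus-pipeline pass stays within a couple of minutes on one CPU.
Under the default quality model (mean Phred 36.5, floor 2) the EE ≤ 3 filter
removes almost nothing — per-read expected errors are ~0.05 — so filtered
depth tracks raw depth closely in simulation; real runs lose far more
because real 3′ quality collapses below anything this clamped model
produces. All randomness flows from explicit seeds; two runs with the same
config and seed produce byte-identical FASTQ, TSV and FASTA outputs.

## Known limitations

- The denoiser's abundance-ratio collapse can merge true variants closer
  than `d_max` when their abundances differ by more than `r_min`-fold, and
  keeps sequencing-error variants that exceed the ratio test; it has no
  quality awareness.
- Bimera detection requires both parents present and ≥ 2× in the same
  specimen — cross-specimen (pool-level) chimeras with an absent parent are
  not detectable per specimen, matching the per-sample detection mode it
  mirrors.
- Genus-level concordance cannot distinguish congeneric contamination from
  a correct identification.
- Coverage uses the subject length as denominator; callers comparing
  "coverage of the Sanger read" must swap the argument order.
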