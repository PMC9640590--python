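# Methods

This note records the model implemented by `regsig`, the parameters that
matter, the choices made where the design was genuinely open, and what
the synthetic benchmark does and does not demonstrate.

## Signatures and regulated gene sets

A transcriptome signature is a per-gene vector of unitless differential
scores for one entity (drug treatment or disease-vs-control). The
package consumes scores as given — moderated Z-scores, Characteristic
Direction scores, or log2 fold changes — and never re-processes raw
expression beyond two operations:

* **Sparsification** keeps the top- and bottom-`fraction` genes
  (default 0.05) and zeroes the rest, the usual noise-suppression step
  for dense differential profiles. The retained count is
  `floor(fraction·n)` per side. Ranking uses a single total order on
  `(score, gene_id)`: the bottom tail is the head of that order and the
  top tail its end. This makes tie-breaking deterministic and guarantees
  the two tails are disjoint for any `fraction ≤ 0.5`, including the
  all-tied degenerate case.
* **Regulated-set extraction** produces the up/down gene sets the
  enrichment consumes. `top_bottom_fraction` (drug convention, and the
  convention for dense disease profiles such as tumor/normal fold
  changes) takes the top tail restricted to positive scores as "up" and
  the bottom tail restricted to negative scores as "down";
  `sign` (the convention for already-sparse disease profiles) takes all
  strictly positive / strictly negative genes. Zero-scored genes are
  never regulated. Note one corner: on a signature whose retained tails
  are single-signed (e.g. all scores positive), the bottom tail contains
  positive scores and is *not* the "down" set — extraction returns an
  empty down set there, by design.

Replicate averaging is per-gene over the signatures that contain the
gene; a missing gene is missing, not zero, because zero is a meaningful
score (no regulation). The default aggregation is the mean for disease
replicates and the median for drug profiles — drug profile collections
(cell lines × timepoints) are heavy-tailed and the median is robust to a
single extreme condition; per-profile scoring remains possible by simply
not aggregating. Log2 fold change uses a pseudocount of 1.0 on
normalized abundances, the customary stabilizer at FPKM-like scale.

## Binding

TF *i* binds gene *j* iff some peak of *i* with MACS2-style score
−10·log₁₀(Q) ≥ `score_threshold` (default 100, i.e. Q ≤ 10⁻¹⁰)
intersects the closed window `[tss − window, tss + window]`
(default ±5000 bp) on the same chromosome. Peaks are BED 0-based
half-open; the TSS is a 0-based point; the window is clipped at
coordinate 0. The window is symmetric, so strand is stored for
provenance but does not enter the computation. Experiments pool: any
qualifying peak from any experiment of a TF creates the edge, giving a
binary per-TF relation. A `cell_type` column in the peak manifest allows
restricting to context-appropriate experiments. Peaks on chromosomes
absent from the TSS table are skipped and counted in the log.

These conventions make binding monotone by construction: enlarging the
window or lowering the threshold can only add edges. The implementation
(interval trees per TF × chromosome) is tested against an all-pairs
brute-force oracle.

## Enrichment

Per TF, the 2×2 table counts up/down genes × bound/unbound, restricted
to genes inside the binding table's universe (binding status is
undefined elsewhere). The test is the **two-sided Fisher exact test**:
the hypergeometric point probability of the observed table plus all
tables with the same margins whose point probability does not exceed it
(relative tolerance 1e−7 on the comparison). A one-sided alternative is
available behind a flag. Degenerate margins (no up genes, no down genes,
or an empty table) give p = 1. Multiple testing is corrected by
Benjamini–Hochberg **within one signature's TF family**; correcting
across signatures would couple unrelated entities' scores through the
shared ranking.

Direction is carried by the fold enrichment
`FE = [(a+pc)/(a+b+2pc)] / [(c+pc)/(c+d+2pc)]` with `pc = 0.5` per cell
(a Haldane–Anscombe-style correction): the ratio of bound fractions
among up vs down genes, finite and positive on empty cells. The signed
score is `+|log10 q|` when FE ≥ 1 and `−|log10 q|` when FE < 1; FE
exactly 1 takes the positive branch. `q` underflowing past 1e−320 is
capped so |score| ≤ 320 and vectors stay finite. Swapping the up and
down sets swaps table rows, leaving p and q invariant and inverting FE,
so every score flips sign — an antisymmetry the tests check on random
instances.

The regulome signature of an entity is the vector of signed scores over
all TFs of the binding table, in the table's TF order. An entity with no
regulated genes in the universe gets the all-zero vector with a warning.

## Prediction scores and polarity

Cosine correlations are computed on the strict intersection of the two
vectors' ID universes; missing IDs are dropped, never zero-imputed,
because an absent TF carries no evidence while a zero score asserts "not
enriched". An empty intersection is an error; an all-zero vector on
either side yields score 0 (flagged in logs).

* Transcriptome level: `S_trans = −cos` — reversal is good.
* Regulome level: `S_reg = ±cos`, the sign set per disease by the
  median cosine between the disease and its approved drugs' regulome
  signatures — positive polarity iff that median ≥ 0.0 (the boundary
  counts as positive). All approved drugs contribute, including the
  drug currently being scored; a leave-one-out option recomputes the
  polarity without it for stricter evaluation (off by default).
  Diseases without approved drugs take their polarity from a
  user-supplied disease-class prior (shipping defaults: negative for
  neoplasm-class, positive for immune-class); with no prior the scoring
  refuses rather than guessing.

Ranking is by descending score with ties sharing the minimum rank and
listed by ascending drug ID. Evaluation computes, per disease, the
difference of the median score of approved drugs and the median score of
all other drugs (mean available behind a flag; the median was chosen as
the robust default for small approved sets), and tests the paired
per-disease (approved, other) summaries with a two-sided Wilcoxon
signed-rank test. All-zero differences make the test degenerate; it is
flagged and reported as p = 1.

## Synthetic benchmark

The generator emulates the structure the method presumes: coordinated
TF-driven expression. Each TF owns a random *program* of
`program_fraction` (default 0.1) of the genes which it binds with
probability `p_driver = 0.8` against a background edge probability
`p_bg = 0.1`. An entity is a set of `drivers_per_program = 2` driver TFs
with directions ±1; a gene bound by a driver gets expression mean
±μ (μ = 3.0, effects adding over drivers) and every gene receives
Gaussian noise (sd 1.0). Two drivers give entities composite programs so
that signatures overlap partially, not all-or-nothing, while keeping the
planted signal recoverable at the default sizes (1,000 genes, 50 TFs,
200 drugs, 50 diseases).

A quarter of the drugs (`therapeutic_fraction = 0.25`, i.e. one per
disease at the defaults) are planted therapeutics: they reuse their
disease's drivers with directions flipped for negative-polarity diseases
and kept for positive-polarity ones. Planted polarities are split half
negative (cancer-like inverse correlation) and half positive
(immune-like), which is what makes the transcriptome-level baseline
fail overall: signature reversal is the wrong model for half the
diseases, so its approved-vs-other separation washes out while the
polarity-aware regulome score separates essentially perfectly. The
approved-drug map lists exactly the planted therapeutics.

A `gene`-level mode plants expression programs on random gene sets not
mediated by any TF, with therapeutic drugs exactly reversing the disease
program. This is the control regime: transcriptome reversal separates
strongly, and the regulome method holds no advantage — passing both
regimes shows the benchmark measures the mechanism, not an artifact of
the generator. All randomness flows from one seed through a single
generator in fixed order, so collections are bit-reproducible.

What the benchmark does **not** emulate: real signature distributions
(moderated Z / Characteristic Direction are not Gaussian), LINCS
plate/batch structure, cell-type-specific binding, correlated TF
programs (co-binding, redundancy), or gene universes that differ between
drugs and diseases. Passing it demonstrates the pipeline's statistical
machinery and the sign-conditional scoring logic, not performance on
real compendia.

## Numerical notes

* Fisher p-values are validated against exhaustive fixed-margin
  enumeration in exact rational arithmetic for all m ≤ 30; BH against a
  direct step-up oracle.
* Score magnitudes are capped at 320 (|log10| of the smallest positive
  double, rounded down).
* Cosines are clipped to [−1, 1] to absorb floating-point excursions.
* Score TSVs are written with `%.10g`, which is what makes repeated
  pipeline runs byte-identical.
* Benchmark problem sizes (1,000 genes / 50 TFs / 200 drugs /
  50 diseases; 100 driver-recovery replicates) were chosen as the
  smallest scales at which the planted effects are comfortably resolved
  by the statistics involved.

## Known limitations

* The binary binding relation discards peak strength beyond the
  threshold; a weighted relation might rank TFs differently.
* Per-signature FDR means scores are not comparable across signatures
  with very different regulated-set sizes, only within one signature and
  through the cosine (which is scale-invariant).
* Polarity estimation from a single approved drug is noisy; the
  class-prior fallback exists precisely because the median of one or two
  cosines is a weak estimator.
* The pipeline assumes one shared gene namespace between signatures and
  the binding table; identifier mapping is out of scope.
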