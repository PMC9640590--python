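# regsig

Regulome-signature scoring of drug–disease pairs.

Connectivity-map drug repositioning asks whether a drug's induced
expression changes reverse a disease's expression changes. In practice
that inverse correlation is often weak: individual gene scores are
noisy, and diseases of the same class can correlate with their approved
drugs *positively* rather than negatively. `regsig` lifts the comparison
from genes to their regulators. Each transcriptome signature is
converted into a **regulome signature** — one signed enrichment score
per transcription factor (TF) — using ChIP-seq-derived TF–gene binding,
and drug–disease pairs are scored by a sign-conditional cosine
correlation that learns, per disease, whether approved drugs correlate
positively (typical of immune diseases) or negatively (typical of
cancers) with the disease regulome.

It is intended for computational drug-repositioning work with
LINCS-style drug signatures, CREEDS/TCGA-style disease signatures, and a
TF–gene binding table built from ChIP-seq peaks (e.g. a ChIP-Atlas
export); a synthetic-data generator makes the whole pipeline testable
without any of those downloads.

## The method

For a signature with up-regulated gene set *U* and down-regulated set
*D* (top/bottom 5 % by score for drugs; positive/negative scores for
diseases), each TF *i* gets the 2×2 table

|            | bound | not bound |
|------------|-------|-----------|
| up genes   | *a*   | *b*       |
| down genes | *c*   | *d*       |

where "bound" means the TF has a ChIP-seq peak with MACS2 score
−10·log₁₀(Q) ≥ 100 within ±5000 bp of the gene's TSS. The table is
scored by the two-sided Fisher exact test and corrected across the TFs
of the signature by Benjamini–Hochberg, giving *q*ᵢ. Direction comes
from the fold enrichment FE = [(a+½)/(a+b+1)] / [(c+½)/(c+d+1)], and the
signed enrichment score is

    xᵢ = +|log₁₀ qᵢ|  if FE ≥ 1,    xᵢ = −|log₁₀ qᵢ|  if FE < 1.

The vector **x** = (x₁, …, xₙ) over all TFs is the regulome signature.
Prediction scores for a drug **x** against a disease **y** (cosines are
taken over the intersection of the ID universes):

* transcriptome level: S‖trans = −cos(**x**trans, **y**trans)
* regulome level: S‖reg = ±cos(**x**reg, **y**reg), with "+" when the
  median cosine between the disease and its approved drugs' regulome
  signatures is ≥ 0 and "−" otherwise.

Evaluation compares prediction scores of approved vs other drugs per
disease (median difference) with a two-sided Wilcoxon signed-rank test
across diseases.

## Worked example

Generate a small synthetic collection with planted TF-driven programs
and score it end to end:

```python
from regsig import SimulationConfig, simulate_collection
from regsig.pipeline import benchmark_collection

cfg = SimulationConfig(n_genes=300, n_tfs=10, n_drugs=20, n_diseases=5, seed=1)
coll = simulate_collection(cfg)
result = benchmark_collection(coll)
print(result.summary())
```

prints

```
planted therapeutic pairs: 5 over 20 drugs
median regulome rank of planted drugs: 1.0
median transcriptome rank of planted drugs: 20.0
polarity recovery: 100.0%
-- regulome separation --
diseases evaluated: 5 (excluded: 0)
positive deltas (approved > other): 5/5
median delta: +0.9961
Wilcoxon signed-rank: statistic=0.0, p=0.0625
-- transcriptome separation --
diseases evaluated: 5 (excluded: 0)
positive deltas (approved > other): 2/5
median delta: -0.3386
Wilcoxon signed-rank: statistic=5.0, p=0.625
```

Every planted therapeutic drug is ranked first for its disease by the
regulome score, and in all 5 diseases the approved drug outscores the
others (delta ≈ +1). The transcriptome score only rewards drugs for the
planted *negative*-polarity diseases — signature reversal is the wrong
model for the positive-polarity ones — so its separation is mixed (2/5)
and the signed-rank test stays null. The per-disease polarity inferred
from approved drugs matches the planted polarity everywhere.

The same pipeline runs from the shell on files:

```sh
regsig simulate --out-dir fixtures --seed 1
regsig run --config run.yaml          # signatures -> enrichment -> scores -> evaluation
regsig evaluate --scores run/scores_regulome.tsv --approved fixtures/approved.tsv
```

with subcommands for the individual stages (`regsig signature …`,
`regsig binding build`, `regsig enrich`, `regsig score`).

## Layout

* `regsig.signatures` — transcriptome signatures: sparsification,
  up/down gene-set extraction, replicate averaging, log2 fold change, TSV I/O
* `regsig.binding` — TF–gene binding tables from BED peaks + TSS tables
* `regsig.enrichment` — Fisher/FDR enrichment, signed scores, regulome
  signatures
* `regsig.scoring` — cosine prediction scores, polarity, ranking,
  approved-vs-other evaluation
* `regsig.simulate` — synthetic collections with planted ground truth
* `regsig.pipeline` / `regsig.cli` — end-to-end workbench and the
  `regsig` command

See `docs/methods.md` for the modeling details and design decisions.
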