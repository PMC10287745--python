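# binsig

Discretization-based gene-expression signatures for predicting
prostate-cancer **biochemical recurrence (BCR)** — the post-treatment rise
in PSA that signals relapse in roughly a quarter of patients. The package
is for computational biologists who want an interpretable alternative to
black-box classifiers: instead of weighting continuous expression, it bins
each gene's expression into intervals and learns which *interval* of which
gene carries risk.

## Method

Given a genes × samples expression matrix and a clinical table (BCR
status, disease-free months, PSA):

1. **Preprocess** — log2(x+1); drop genes with coefficient of variation
   sd/μ ≤ 1.5 (log2 scale); rescale each gene to [0, 1] by min-max fitted
   on training only.
2. **Discretize** — equal-width or equal-frequency bins, with the bin
   count k from classical histogram rules (√n, Čencov n^⅓, Rice 2n^⅓,
   Terrell–Scott (2n)^⅓, Sturges log₂n+1, Brooks–Carruthers 5·log₁₀n,
   Freedman–Diaconis R/(2·IQR·n^(−⅓)), Scott R/(3.49·σ·n^(−⅓))). At
   n = 143 samples the static rules give k = 12, 5, 10, 6, 8, 11.
3. **Select** — correlation-based feature selection: best-first search for
   the gene subset S (|S| = l) maximising

       merit(S) = l·t̄_c / √(l + l(l−1)·t̄_f)

   where t̄_c is the mean symmetrical-uncertainty correlation with the
   outcome and t̄_f the mean gene–gene correlation; subsets are retained
   only above merit 0.60.
4. **Train / score** — L2-logistic regression on one-hot (gene, bin)
   indicators; adjacent bins with near-equal weights merge into interval
   unions. A sample's risk is σ(b₀ + Σ wᵢ·1[xᵢ ∈ intervalᵢ]), optionally
   plus a PSA < 0.38 ng/mL indicator term.
5. **Evaluate** — accuracy, precision, Mann–Whitney AUC, and Kaplan–Meier
   disease-free-survival curves for predicted high/low-risk groups.

The published ten-gene signature (ZFHX3, EMP2, ITPR1, NFIB, PCCA, RGS2,
WDR5, SRGAP2, AIDA, SLC25A30; intercept 1.5; five-bin equal-width
intervals) ships with the package:

```python
>>> import binsig as bs
>>> model = bs.load_printed_signature()
>>> profile = {g: 0.5 for g in model.gene_ids} | {"RGS2": 0.1, "AIDA": 0.1}
>>> bs.score_sample(model, profile).probability   # no interval matched: sigma(1.5)
0.8175744761936437
```

## Worked example

Real cohorts are not bundled; the `simulate` subcommand writes a seeded
synthetic cohort with the structure the method assumes — 143 training
samples (71 BCR / 72 not), 500 genes with 10 planted informative genes
whose five-bin occupancy differs by class, plus an imbalanced 36/104 test
cohort:

```
$ binsig simulate --n-genes 500 --effect 0.4 --seed 7 \
      --test-n-bcr 36 --test-n-nonbcr 104 --out-dir .
wrote cohort (500 genes x 143 samples) to .

$ printf 'cv_threshold=0.2\nrule=cencov\nseed=7\n' > config.txt
$ binsig run expression.tsv clinical.tsv --config config.txt \
      --test-expression expression_test.tsv --test-clinical clinical_test.tsv \
      --out-dir out
[input] genes=500 samples=143
[preprocess] genes_out=500
[discretize] strategy=equal_width rule=cencov k_min=5 k_max=5
[select] n_genes=9 merit=0.762
[train] terms=43
[evaluate] n=140 accuracy=1.0 auc=1.0
accuracy=1.000 auc=1.000 genes=9 -> out
```

Reading the log: the Čencov rule puts every gene on 5 equal-width bins;
CFS keeps a 9-gene subset whose merit 0.762 clears the 0.60 cut (all nine
are planted genes — at this effect size the tenth fell below the search's
improvement margin); the logistic fit produces 43 interval terms; and on
the held-out cohort every one of the 140 patients is ranked and classified
correctly — planted Beta-shifted signal at effect 0.4 is deliberately easy.
`out/` contains `model.json` (the signature), `report.json` (confusion
counts, accuracy, precision, AUC), `scheme.json`, `selection.tsv`,
`predictions.tsv`, `km.tsv` and a provenance `manifest.json`.
`binsig compare-rules` repeats the run over all eight bin rules × both
strategies plus an undiscretized baseline.

(cv_threshold is 0.2 here rather than the 1.5 default because the
synthetic genes are not zero-inflated counts; see `docs/methods.md`.)

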