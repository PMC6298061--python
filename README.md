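# dcoex — differential coexpression with expression-confound control

Differential coexpression analysis (DCA) looks for gene pairs whose
correlation changes between biological conditions — here, human tissues —
in the hope of revealing regulatory "rewiring". A central pitfall is that
differential coexpression is confounded with differential *expression*:
two genes cannot be correlated where one of them is not expressed at all,
and expression variance itself depends on expression level. `dcoex`
implements a pipeline that builds robust per-tissue coexpression networks
from many independent datasets, scores tissue-specific links, and then
explicitly asks how much of each link's tissue specificity is explained by
the genes' mean expression levels — isolating the minority of **pure**
differential-coexpression links whose rewiring is *not* attributable to
expression changes.

It is written for computational biologists who work with multi-cohort
expression compendia (microarray or RNA-seq, genes × samples on a log
scale) and want link-level differential coexpression with an honest null.

## Method

For each dataset *k*, Pearson correlations are computed between all pairs
of genes expressed in that dataset's tissue; pairs above the dataset's
90th correlation percentile form a binary network. A **tissue-aggregated
network (TAN)** keeps links present in at least *n* of the tissue's binary
networks, with *n* chosen against a Binomial(K, 0.1) null at FDR 1e-4.

Correlations are made comparable across datasets by a **binned rank
transform**: each correlation is replaced by its quantile bin *SB* among
all expressed-pair correlations of its dataset (per-milles by default),
with negative correlations floored at SB = 0.5 ("no coexpression"). The
**tissue-specificity score** of a link for target tissue *t* is the mean
positive difference between its SB values in the target datasets and all
others:

    TSS(i, j, t) = Σ_{p∈CT_t} Σ_{q∈CT_t̄} max(SB_p − SB_q, 0) / (|CT_t|·|CT_t̄|)

TSS ∈ [0, 0.5]. Its null is estimated from **pseudo-tissues** — random,
tissue-balanced dataset subsets of the same size — giving an empirical FDR
curve; links passing FDR 0.01 in their tissue and scoring TSS < 0.4 in
every other tissue form the **tissue-specific network (TSN)**. A one-sided
Wilcoxon rank-sum score is provided as a cross-check.

Each TSN link is then fit with a per-link linear model across all K
datasets,

    SB_ijk = β0 + β1 (e_ik + e_jk) + β2 |e_ik − e_jk|,

where e_ik is gene *i*'s mean log expression in dataset *k*. R² measures
how predictable the link's coexpression profile is from expression level
alone; significance comes from refitting under shuffled expression vectors
with Benjamini–Hochberg control across links. **Pure** links have an
insignificant R² *and* both genes expressed in every tissue; links with a
gene silent in some tissue are **expression-induced**; the rest are
**expression-associated**.

Validation and functional modules compare link groups against an
independent external collection through density-matched binary networks
(overlap likelihood ratios, reproduced fractions, correlation-distribution
shifts), compute neighborhood topological overlap, and run link-based term
enrichment with a drop-out analysis (which enriched functions disappear
when pure links are removed, versus random or expression-induced links of
equal number).

A synthetic-data generator plants all three link classes with exact
control of the correlation/mean-expression decoupling, so every stage can
be tested against ground truth.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate.py            --seed 11 --out-dir results/synthetic
python analysis/02_build_tans.py          --seed 11 --data-dir results/synthetic --out-dir results/tans
python analysis/03_score_tss.py           --seed 11 --data-dir results/synthetic --out-dir results/tss
python analysis/04_fit_expression_model.py --seed 11 --data-dir results/synthetic --out-dir results/links
python analysis/05_validate.py            --seed 11 --data-dir results/synthetic --out-dir results/validation
python analysis/06_enrichment.py          --seed 11 --data-dir results/synthetic --out-dir results/enrichment
```

Output of steps 02 and 04 on the default design (5 tissues, 56 datasets,
600 genes, 20 planted links per class):

```
tissue1: 16 TAN links from 9 datasets (support >= 6, 349 expressed genes)
tissue2: 14 TAN links from 14 datasets (support >= 8, 347 expressed genes)
...
70 tissue-specific link rows; classes: {'induced_offgene': 41, 'pure': 29}
planted-link recovery: 60/60 (100%) in the correct tissue's TSN
  planted pure: 20 called pure, 0 called expression-driven, 0 not selected
  planted induced1: 0 called pure, 20 called expression-driven, 0 not selected
  planted induced2: 0 called pure, 20 called expression-driven, 0 not selected
```

Reading: each tissue's TAN is dominated by the links planted for it
(`support >= n` is the binomial-FDR aggregation threshold); all 60 planted
links are recovered as tissue-specific in the right tissue; the expression
model separates the planted pure links (flat mean expression across
tissues, insignificant R²) from the induced links (driven by a gene that
is silent outside the target tissue). The `induced_offgene` surplus (41 vs
40 planted) and the `pure` surplus are occasional background pairs that
entered a TAN by chance; being top-decile in many datasets of one tissue,
such links genuinely look tissue-specific.

Step 05 prints per-tissue reproducibility in an independent collection
(own-TSN overlap likelihood ratios in the thousands at TAN-matched
density), and step 06 the drop-out analysis (e.g. `removing 4 pure links
drops 1 of 3 enriched terms ... sensitive only to pure removal:
['term_tissue1_pure']`).

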