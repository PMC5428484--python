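# gofunsim

Protein functional similarity from Gene Ontology annotations.

Two proteins that perform related biological roles tend to be annotated
with semantically close GO terms. `gofunsim` quantifies this: it parses
an ontology (OBO) and annotation corpora (GAF 2.x), derives per-term
information content, scores term pairs with six semantic-similarity
measures, aggregates them into protein-level functional-similarity (FS)
scores with five mixing strategies, normalizes raw scores into
background z-scores that correct for annotation bias, and evaluates any
measure/mixing combination with an orthology-based benchmark. It is
aimed at computational biologists comparing gene products within or
across organisms — candidate-gene prioritization, orthologue function
transfer, or method comparison studies.

## The model

For a namespace DAG (BP, MF or CC) and an annotation corpus, each term
gets a probability P(t) = N(t)/N(root), where N(t) counts the distinct
proteins annotated to t or any descendant, and an information content
I(t) = −ln P(t). With S(s, t) the set of common ancestors of two terms
(reflexive: a term is its own ancestor):

| measure  | definition |
|----------|------------|
| simRes   | max over c ∈ S(s,t) of I(c) — the MICA's information content |
| simLin   | 2·I(MICA) / (I(s) + I(t)) |
| simRel   | max over c of [2·I(c)/(I(s)+I(t))]·(1 − P(c)) |
| simIC    | simLin · (1 − 1/(1 + I(MICA))) |
| simJC    | 1 / (1 + I(s) + I(t) − 2·I(MICA)) |
| simGIC   | Σ I(c) over ancestors(s) ∩ ancestors(t) ÷ Σ over the union |

For proteins P (m terms) and R (n terms), the m×n matrix of pairwise
term scores s<sub>ij</sub> is reduced by a mixing strategy: fsMax
(matrix maximum), fsAvg (matrix mean), and three best-match variants
built from the row maxima and column maxima — fsBMM (max of the two
means), fsBMA (their average), fsABM ((Σ rowmax + Σ colmax)/(m+n)).
Per-namespace scores combine as a root mean square, e.g.
F<sub>BP+MF</sub> = √(½(F²<sub>BP</sub> + F²<sub>MF</sub>)).

Raw FS scores are biased toward heavily annotated proteins. The z-score

  z(P, R) = (2·F(P,R) − (μ_P + μ_R)) / √(σ²_P + σ²_R)

uses each protein's background mean/SD over partners sampled without
replacement (default 1000) from the other organism's annotated
proteins, so a high score over a high background is no longer
impressive by itself.

The benchmark treats one-to-one orthologue pairs (below 80% sequence
identity) as positives and derangements of the second-organism column —
permutations without fixed points — as matched negatives, finds the
threshold h\* minimizing (FP+FN)/total, and repeats over 225 control
sets to report a mean error rate with a 99% confidence interval.
Paired per-repeat error rates from two corpus configurations are
compared with a one-sided Wilcoxon signed-rank test, Bonferroni-
corrected across the 6 × 5 measure grid.

## Worked example

The package ships a synthetic-world generator, so everything runs
without downloads:

```sh
gofunsim fixtures --out demo --seed 7
gofunsim pair --obo demo/fixture.obo --gaf demo/org_1001.gaf --gaf demo/org_2002.gaf \
    --ns BP --measure simGIC --mix fsBMA A0000 B0000
```

```
idA     idB     measure mix     namespaces      raw_score       m       n
A0000   B0000   simGIC  fsBMA   BP      0.718189022     2       2
```

A0000 (organism 1001) and B0000 (organism 2002) are a planted
orthologue pair; their simGIC/fsBMA score of 0.72 over a 2×2 term
matrix reflects the high annotation overlap the generator planted.
Benchmarking all ten planted orthologue pairs against random controls:

```sh
gofunsim benchmark --obo demo/fixture.obo --gaf demo/org_1001.gaf --gaf demo/org_2002.gaf \
    --ns BP --measure simGIC --mix fsBMA --orthologs demo/orthologs.tsv --repeats 50 --seed 1
```

```
measure mix   namespaces iea      n_pairs repeats mean_error ci99_lo      ci99_hi      mean_h_star
simGIC  fsBMA BP         included 10      50      0.022      0.0102708675 0.0337291325 0.580921578
```

A mean error rate of 2.2% means that, at the per-repeat optimal score
threshold (on average 0.58), about one pair in 45 is misclassified —
the planted functional signal is clearly separable from random
pairings. Library use mirrors the CLI: `parse_obo`, `parse_gaf`,
`build_ic`, `ss_matrix`/`mix`/`combine`, `estimate_background`/`zscore`,
and `repeat_benchmark` compose the same pipeline in Python.

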