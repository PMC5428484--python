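# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `gofunsim`, in the order the pipeline
runs.

## Ontology model

Each GO namespace is a self-contained DAG with exactly one root (the
unique term without ancestors); cross-namespace edges are discarded
because every score is computed per namespace and namespaces are only
recombined at the protein level (root-mean-square combination).
Ancestry is defined over a configurable relation set, default
`{is_a, part_of}` — the GO Consortium convention for annotation
propagation. Other relation closures (e.g. `regulates`) can be added
via the `relations` argument / `--relations` flag; different releases
and storage backends of GO encode relation closures slightly
differently, so ancestor sets from other toolchains may differ at the
margin.

Ancestor sets are **reflexive** (t ∈ ancestors(t)). This single
convention makes all self-comparisons consistent: the MICA of (t, t)
is t itself, simLin(t, t) = simJC(t, t) = 1, and simGIC(t, t) = 1,
because the intersection and union of identical ancestor sets
coincide. Obsolete terms are excluded; `alt_id` aliases resolve to
their primary accession.

## Information content

N(t) counts **distinct proteins** annotated to t or any descendant — a
protein annotated to two descendants of t contributes once. (The
alternative, counting annotation rows, inflates N for multiply
annotated proteins; distinct-protein counting is the standard Resnik
convention.) P(t) = N(t)/N(root) is always computed relative to the
corpus after filtering: an IEA(−) or taxon-restricted corpus gets its
own N(root). Information content uses the natural logarithm; the base
only rescales simRes (all normalized measures are base-invariant) and
is exposed as `build_ic(..., log_base=...)` for cross-tool comparison.

Terms with zero annotations have no defined information content. They
are stored as *unscorable* rather than given I = +∞: any term-pair
comparison that rests only on unscorable terms scores 0, which keeps
every measure total without inventing infinite values. The same
present-vs-missing distinction recurs at the protein level: a protein
with no annotation in a namespace makes the pair *unscorable* there
(reported as missing), while a present score of 0 is a real value that
enters averages and combinations.

## Similarity measures — edge cases and variants

* **Degenerate ratio**: when I(s) + I(t) = 0 (both terms carried by
  every protein), simLin, simRel and simIC return 0. simJC is defined
  (its denominator is 1) and returns 1 for s = t, which is the correct
  limit of a distance-derived similarity.
* **simRel** maximizes the weighted product 2·I(c)/(I(s)+I(t))·(1−P(c))
  over *all* common ancestors; the maximizer need not be the MICA
  (a slightly shallower ancestor with a much smaller P can win). A
  `rel_mica_only=True` flag evaluates at the MICA only, for comparison
  with implementations that do so.
* **simIC** uses the weight (1 − 1/(1 + I(MICA))). The superficially
  similar form with a minus sign in the denominator, which appears in
  some write-ups, is negative for 0 < I < 1 and singular at I = 1 and
  so cannot serve as a similarity weight; it is available as
  `ic_weight="printed"` strictly for side-by-side comparison.
* **simGIC** is used in its pairwise term-level form (ancestor-closure
  intersection over union of the two *terms*), and then flows through
  the mixing strategies like every other measure; the group-wise
  protein-level variant is deliberately out of scope.
* **MICA ties** (equal information content) break toward the
  lexicographically smallest accession, so runs are reproducible. One
  visible consequence: for a term t whose information content equals
  an ancestor's, mica(t, t) may name the ancestor — the information
  content is identical either way.

## Mixing and combining

The SS matrix is built over the proteins' *direct* annotation sets
(deduplicated, sorted for deterministic row/column order); the
ancestor closure enters only through information content and simGIC's
closure sums. The five mixing strategies satisfy, on every matrix,
fsAvg ≤ fsABM ≤ fsBMM ≤ fsMax and fsAvg ≤ fsBMA ≤ fsBMM, with
fsBMA = fsBMM iff the row-maxima and column-maxima means agree; these
orderings are enforced by property tests. Combined-ontology scores are
the RMS of the per-namespace scores over any requested subset; a pair
missing one requested namespace is missing, not zero.

## Backgrounds and z-scores

Backgrounds sample partners **without replacement** from the annotated
proteins of the partner organism (default k = 1000, clamped to the
pool with a warning — synthetic worlds are far smaller). σ is the
sample standard deviation (n−1); unscorable partners are skipped and
n_sampled shrinks rather than polluting the background with zeros.
The query's own orthologue is not excluded from the pool: at realistic
pool sizes one partner shifts μ by O(1/k), and excluding it would
require knowing the orthology in advance. Combined-ontology z-scores
use backgrounds of the combined score itself (sample, combine, then
μ/σ) rather than combining per-namespace z-scores. A pair whose two
backgrounds both have σ = 0 has no defined z; it is reported as
missing with the raw score still emitted.

## Benchmark engine

Controls are derangements sampled by rejection (shuffle until
fixed-point-free; acceptance probability → 1/e, so ≈2.7 draws per
control set) — exact uniformity over derangements is not needed for
an error-rate average. Classification is "score ≥ h ⇒ orthologue";
candidate thresholds are the midpoints of adjacent distinct observed
scores plus ∓∞ sentinels, which is exact because the error curve is
constant between observed scores. Ties in error resolve toward the
smallest threshold. Per run we report the mean of the per-repeat
error rates (default R = 225), the mean of the per-repeat optimal
thresholds, and a normal-theory 99% CI of the mean
(mean ± z₀.₀₀₅·SD/√R). Case pairs the scorer cannot handle are
dropped once, before control construction, with a logged count;
control partners are drawn from the already-scorable case pool, so
unscorable controls cannot arise in single-namespace runs. Per-repeat
control sets depend only on (seed, repeat index), so two scorers run
with the same seed — raw scores and z-scores, or ALL and AOO corpora —
see identical control sets and their per-repeat errors pair exactly,
which is what the one-sided Wilcoxon signed-rank comparison
(Bonferroni-corrected, default 30 tests) assumes.

Note on calibration: the optimal threshold is chosen and evaluated on
the same case/control sample, so the measured error is an in-sample
minimum and sits slightly *below* the analytic Bayes error of the
generating distributions (≈0.14–0.15 vs Φ(−1) ≈ 0.1587 for 200 + 200
Gaussian scores one σ from the midpoint). The calibration test
therefore compares against the Bayes error on the per-repeat
standard-deviation scale, which absorbs both the resampling spread and
this small optimism.

## Synthetic worlds

The fixture generator emulates the statistical features the methods
respond to, not real GO topology: per-namespace DAGs built by giving
each new term 1–2 random earlier parents (acyclic with a single root
by construction; ~20% `part_of` edges); a heavy-tailed annotation-count
mixture (90% of proteins draw 1–4 terms, 10% draw 10–16 — the
"disease-gene" tail that motivates z-scores); a 20% fraction of
IEA-only proteins that vanish under IEA(−) filtering; and 10 planted
orthologue pairs per 30-protein organism whose annotation sets overlap
70% (orthologues are kept manually curated so the planted signal
survives IEA(−) filtering). Identity values in the orthologue table
are drawn in [20, 75), below the 80% exclusion line. Defaults are
deliberately small: they make exhaustive oracles (transitive-closure
enumeration, all-pairs background means) affordable, which is what the
test suite trades realism for. Consequently, passing tests demonstrate
algorithmic correctness and qualitative behavior (planted signal
detected, z-scores help under bias), not quantitative error rates on
real corpora — those depend on the GO release and orthologue catalogue
used and are corpus facts, not package facts.

## Determinism

Every stochastic component (fixture generation, background sampling,
derangement draws, calibration scores) flows from an explicit integer
seed through `numpy.random.default_rng`; repeat-level generators are
keyed by (seed, repeat index). CLI output is byte-identical across
runs with the same configuration and seed; scores print with nine
significant digits.
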