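"""Orthology-based benchmarking of functional-similarity measures.

One-to-one orthologue pairs between two organisms serve as the
positive class (orthologues should be functionally similar); an
equally sized control set is built by deranging the second-organism
column — a permutation without fixed points, so no orthologous pair
survives and every control gene is used exactly once. Trivial cases
are removed beforehand by excluding pairs at or above 80% sequence
identity (identity values are supplied, not computed here).

For a scored case/control set the optimal threshold h* minimizes the
error rate (FP + FN)/(TP + FP + TN + FN) under the rule "score >= h
predicts orthologue". Because controls are random, the whole procedure
is repeated (default 225 control sets) and the mean error rate with a
99% normal-theory confidence interval is reported, along with the mean
of the per-repeat optimal thresholds.

Corpus comparisons (e.g. ALL vs AOO information content) pair the
per-repeat error rates of the two conditions and apply a one-sided
Wilcoxon signed-rank test with Bonferroni correction across the
measure grid (six similarities x five mixing strategies = 30 tests).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class OrthologSet:
    """One-to-one orthologue pairs, optionally with percent identity."""

    pairs: list
    pct_identity: list | None = None
    organisms: tuple | None = None

    def __post_init__(self):
        for col in (0, 1):
            ids = [p[col] for p in self.pairs]
            if len(ids) != len(set(ids)):
                raise ValueError(
                    "orthology must be one-to-one: duplicate id in column "
                    f"{col + 1}"
                )
        if self.pct_identity is not None and len(self.pct_identity) != len(self.pairs):
            raise ValueError("pct_identity length must match pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    def filter_identity(self, max_pct: float = 80.0) -> "OrthologSet":
        """Drop trivially similar pairs (identity >= ``max_pct``)."""
        if self.pct_identity is None:
            return self
        keep = [i for i, pid in enumerate(self.pct_identity) if pid < max_pct]
        dropped = len(self.pairs) - len(keep)
        if dropped:
            logger.info("excluded %d pair(s) with identity >= %g%%", dropped, max_pct)
        return OrthologSet(
            pairs=[self.pairs[i] for i in keep],
            pct_identity=[self.pct_identity[i] for i in keep],
            organisms=self.organisms,
        )

    @classmethod
    def from_tsv(cls, path, organisms=None) -> "OrthologSet":
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        if df.shape[1] < 2:
            raise ValueError("orthologue TSV needs at least two columns (idA, idB)")
        pairs = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
        pct = df.iloc[:, 2].astype(float).tolist() if df.shape[1] >= 3 else None
        return cls(pairs=pairs, pct_identity=pct, organisms=organisms)

    def to_tsv(self, path) -> None:
        data = {"idA": [a for a, _ in self.pairs], "idB": [b for _, b in self.pairs]}
        if self.pct_identity is not None:
            data["pct_identity"] = self.pct_identity
        pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    # rejection sampling: P(no fixed point) -> 1/e, so ~2.7 shuffles expected
    if n < 2:
        raise ValueError("a derangement needs at least 2 elements")
    idx = np.arange(n)
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == idx):
            return perm


def make_controls(cases, seed) -> list:
    """Random matched controls: derange the second-organism column.

    ``cases`` is an :class:`OrthologSet` or a plain list of (idA, idB)
    pairs; ``seed`` is an int or a ``numpy`` Generator. Each control
    gene is used once and no case pair survives intact.
    """
    pairs = cases.pairs if isinstance(cases, OrthologSet) else list(cases)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = _derangement(len(pairs), rng)
    return [(pairs[i][0], pairs[perm[i]][1]) for i in range(len(pairs))]


class ThresholdResult(NamedTuple):
    h_star: float
    error_rate: float
    tp: int
    fp: int
    tn: int
    fn: int


def optimal_threshold(cases, controls) -> ThresholdResult:
    """Threshold minimizing (FP + FN)/total under "score >= h -> positive".

    Candidate thresholds are the midpoints of adjacent distinct
    observed scores plus -inf/+inf sentinels; this grid is exact
    because the error curve is constant between observed scores. Ties
    on the error rate resolve toward the smallest threshold.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("cases and controls must be non-empty")
    if not (np.isfinite(cases).all() and np.isfinite(controls).all()):
        raise ValueError("scores must be finite")
    values = np.unique(np.concatenate([cases, controls]))
    # candidate k=0 is below every score; candidate k>=1 sits just above values[k-1]
    cand = np.empty(values.size + 1)
    cand[0] = -np.inf
    cand[1:-1] = 0.5 * (values[:-1] + values[1:])
    cand[-1] = np.inf
    # counts of scores <= values[k-1] (i.e. classified negative at candidate k)
    sorted_cases = np.sort(cases)
    sorted_controls = np.sort(controls)
    fn = np.concatenate([[0], np.searchsorted(sorted_cases, values, side="right")])
    neg_controls = np.concatenate([[0], np.searchsorted(sorted_controls, values, side="right")])
    fp = controls.size - neg_controls
    total = cases.size + controls.size
    errors = (fn + fp) / total
    best = int(np.argmin(errors))  # argmin takes the first = smallest h on ties
    h = float(cand[best])
    return ThresholdResult(
        h_star=h,
        error_rate=float(errors[best]),
        tp=int(cases.size - fn[best]),
        fp=int(fp[best]),
        tn=int(neg_controls[best]),
        fn=int(fn[best]),
    )


@dataclass
class BenchmarkRun:
    """Per-repeat thresholds/errors and their resampling summary."""

    case_pairs: list
    case_scores: np.ndarray
    per_repeat: pd.DataFrame
    mean_error: float
    ci99: tuple
    mean_h_star: float
    n_dropped_cases: int = 0
    n_dropped_controls: int = 0
    context: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flat summary row (the machine-readable report format)."""
        row = dict(self.context)
        row.update(
            n_pairs=len(self.case_pairs),
            repeats=len(self.per_repeat),
            mean_error=self.mean_error,
            ci99_lo=self.ci99[0],
            ci99_hi=self.ci99[1],
            mean_h_star=self.mean_h_star,
        )
        return row


#: two-sided 99% normal quantile, for the CI of the mean error rate
_Z_995 = float(sps.norm.ppf(0.995))


def repeat_benchmark(
    cases: OrthologSet,
    scorer,
    R: int = 225,
    seed: int = 0,
    context: dict | None = None,
) -> BenchmarkRun:
    """Repeat control construction and threshold optimization R times.

    Case pairs are scored once; pairs the scorer cannot handle are
    dropped up front with a logged count. Each repeat builds a fresh
    derangement control set from the retained cases (seeded per
    repeat, so two runs with the same seed — e.g. raw scores vs
    z-scores — see identical control sets), scores it, and records the
    optimal threshold and its error rate. The summary is the mean
    error, its 99% normal-theory CI (mean +/- z_.995 * sd/sqrt(R)),
    and the mean optimal threshold.
    """
    pairs = cases.pairs if isinstance(cases, OrthologSet) else list(cases)
    scored = [(p, scorer(*p)) for p in pairs]
    kept = [(p, s) for p, s in scored if s is not None]
    n_dropped = len(scored) - len(kept)
    if n_dropped:
        logger.info("dropped %d unscorable case pair(s)", n_dropped)
    if len(kept) < 2:
        raise ValueError("need at least 2 scorable case pairs")
    kept_pairs = [p for p, _ in kept]
    case_scores = np.array([s for _, s in kept])

    rows = []
    dropped_controls = 0
    for r in range(R):
        rng = np.random.default_rng((seed, r))
        controls = make_controls(kept_pairs, rng)
        control_scores = [scorer(a, b) for a, b in controls]
        ok = [s for s in control_scores if s is not None]
        dropped_controls += len(control_scores) - len(ok)
        res = optimal_threshold(case_scores, np.array(ok))
        rows.append({"h_star": res.h_star, "error_rate": res.error_rate})
    if dropped_controls:
        logger.info("dropped %d unscorable control pair(s) across repeats", dropped_controls)
    per_repeat = pd.DataFrame(rows)
    errors = per_repeat["error_rate"].to_numpy()
    mean_error = float(errors.mean())
    sd = float(errors.std(ddof=1)) if R > 1 else 0.0
    half = _Z_995 * sd / math.sqrt(R)
    finite_h = per_repeat["h_star"].replace([np.inf, -np.inf], np.nan).dropna()
    return BenchmarkRun(
        case_pairs=kept_pairs,
        case_scores=case_scores,
        per_repeat=per_repeat,
        mean_error=mean_error,
        ci99=(mean_error - half, mean_error + half),
        mean_h_star=float(finite_h.mean()) if len(finite_h) else float("nan"),
        n_dropped_cases=n_dropped,
        n_dropped_controls=dropped_controls,
        context=dict(context or {}),
    )


class CorpusComparison(NamedTuple):
    statistic: float
    pvalue: float
    significant: bool
    degenerate: bool


def compare_corpora(
    errors_a,
    errors_b,
    n_tests: int = 30,
    alpha: float = 0.01,
    alternative: str = "less",
) -> CorpusComparison:
    """Paired one-sided Wilcoxon signed-rank test on per-repeat errors.

    With the default ``alternative="less"`` the test asks whether the
    first condition's error rates are systematically smaller.
    Significance applies a Bonferroni correction: p < alpha/n_tests.
    A test with all paired differences zero is undefined and reported
    as non-significant with the ``degenerate`` flag set.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired error vectors must have equal length")
    if np.all(a == b):
        return CorpusComparison(float("nan"), 1.0, False, True)
    res = sps.wilcoxon(a, b, alternative=alternative)
    return CorpusComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        significant=bool(res.pvalue < alpha / n_tests),
        degenerate=False,
    )
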