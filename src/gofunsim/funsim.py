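"""Protein-level functional similarity: SS matrices, mixing, combining.

For proteins P (m direct terms) and R (n direct terms) the semantic
similarity matrix M holds all m*n pairwise term scores. A mixing
strategy reduces M to one functional-similarity (FS) score:

* ``fsMax``  — max over all cells; sensitive to a single good match.
* ``fsAvg``  — mean over all cells; rewards globally similar sets.
* ``fsBMM``  — max of (mean of row maxima, mean of column maxima).
* ``fsBMA``  — mean of those two means (best match average).
* ``fsABM``  — (sum of row maxima + sum of column maxima)/(m+n).

Per-ontology FS scores combine into a single value as a root mean
square, e.g. F_BP+MF = sqrt((F_BP^2 + F_MF^2)/2). A protein with no
annotation in a requested namespace is *unscorable* there — the pair's
score is missing, which is different from a present score of 0 (a
present 0 enters the RMS and drags the combination down).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from io import StringIO

import numpy as np

from .corpus import AnnotationCorpus, ICTable
from .ontology_io import OntologyDAG
from .semsim import mica, sim

MIXES = ("fsAvg", "fsMax", "fsBMM", "fsBMA", "fsABM")


class UnscorableError(ValueError):
    """A protein lacks annotation in a required namespace.

    Distinct from a score of zero: the comparison is undefined, not
    maximally dissimilar.
    """


@dataclass
class SSMatrix:
    """All pairwise term similarities for one protein pair.

    Rows follow protein P's sorted direct terms, columns protein R's.
    """

    rows: tuple
    cols: tuple
    values: np.ndarray
    measure: str

    @property
    def shape(self):
        return self.values.shape

    def transpose(self) -> "SSMatrix":
        return SSMatrix(self.cols, self.rows, self.values.T, self.measure)

    def to_tsv(self, path=None):
        """Dump the matrix with term ids and row/col maximum flags.

        Cell flags: ``R`` row maximum, ``C`` column maximum, ``RC``
        both — the cells a best-match mixing strategy is built from.
        """
        v = self.values
        rowmax = v.max(axis=1, keepdims=True)
        colmax = v.max(axis=0, keepdims=True)
        out = StringIO()
        out.write("term\t" + "\t".join(self.cols) + "\n")
        for i, rid in enumerate(self.rows):
            cells = []
            for j in range(v.shape[1]):
                flag = ("R" if v[i, j] == rowmax[i, 0] else "") + (
                    "C" if v[i, j] == colmax[0, j] else ""
                )
                cells.append(f"{v[i, j]:.9g}" + (f" [{flag}]" if flag else ""))
            out.write(rid + "\t" + "\t".join(cells) + "\n")
        text = out.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass(frozen=True)
class FSScore:
    """One functional-similarity value with its full provenance."""

    value: float
    measure: str
    mix: str
    namespaces: tuple
    m: int
    n: int


def ss_matrix(
    P: str,
    R: str,
    measure: str,
    namespace: str,
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    ic: ICTable,
    **sim_kwargs,
) -> SSMatrix:
    """Build the m*n semantic-similarity matrix for a protein pair.

    Raises
    ------
    UnscorableError
        If either protein has no direct annotation in ``namespace``
        under the corpus's active filter.
    """
    direct = corpus.direct(namespace)
    for pid in (P, R):
        if pid not in direct:
            raise UnscorableError(
                f"protein {pid!r} has no {namespace} annotation in this corpus"
            )
    rows = tuple(sorted(direct[P]))
    cols = tuple(sorted(direct[R]))
    values = np.empty((len(rows), len(cols)))
    cache = {}
    for i, s in enumerate(rows):
        for j, t in enumerate(cols):
            key = (s, t) if s <= t else (t, s)
            if key not in cache:
                cache[key] = sim(measure, mica(dag, ic, s, t), dag, ic, **sim_kwargs)
            values[i, j] = cache[key]
    return SSMatrix(rows=rows, cols=cols, values=values, measure=measure)


def mix_values(values: np.ndarray, mix_name: str) -> float:
    """Apply a mixing strategy to a raw m*n score array."""
    if mix_name not in MIXES:
        raise ValueError(f"unknown mixing strategy {mix_name!r}; choose from {MIXES}")
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.size == 0:
        raise ValueError("SS matrix must be a non-empty 2-D array")
    if mix_name == "fsMax":
        return float(v.max())
    if mix_name == "fsAvg":
        return float(v.mean())
    rowmax = v.max(axis=1)
    colmax = v.max(axis=0)
    if mix_name == "fsBMM":
        return float(max(rowmax.mean(), colmax.mean()))
    if mix_name == "fsBMA":
        return float(0.5 * (rowmax.mean() + colmax.mean()))
    # fsABM
    m, n = v.shape
    return float((rowmax.sum() + colmax.sum()) / (m + n))


def mix(M: SSMatrix, mix_name: str, namespace: str | None = None) -> FSScore:
    """Reduce an :class:`SSMatrix` to a single :class:`FSScore`."""
    value = mix_values(M.values, mix_name)
    m, n = M.values.shape
    return FSScore(
        value=value,
        measure=M.measure,
        mix=mix_name,
        namespaces=(namespace,) if namespace else (),
        m=m,
        n=n,
    )


def combine(scores: dict, which) -> FSScore:
    """Root-mean-square combination of per-namespace FS scores.

    ``scores`` maps namespace to :class:`FSScore` (or bare float);
    ``which`` selects the namespaces entering the combination. Any
    requested namespace missing from ``scores`` makes the combined
    score unscorable.
    """
    which = tuple(which)
    missing = [ns for ns in which if ns not in scores]
    if missing:
        raise UnscorableError(f"no FS score for namespace(s) {missing}")
    vals = []
    measure = mix_name = None
    m = n = 0
    for ns in which:
        s = scores[ns]
        if isinstance(s, FSScore):
            vals.append(s.value)
            measure, mix_name = s.measure, s.mix
            m, n = s.m, s.n
        else:
            vals.append(float(s))
    value = math.sqrt(sum(x * x for x in vals) / len(vals))
    return FSScore(
        value=value,
        measure=measure or "",
        mix=mix_name or "",
        namespaces=which,
        m=m,
        n=n,
    )


def score_pair(
    P: str,
    R: str,
    measure: str,
    mix_name: str,
    namespaces,
    corpus: AnnotationCorpus,
    dags: dict,
    ics: dict,
    **sim_kwargs,
):
    """Full pipeline for one pair: per-namespace FS, combined if asked.

    Returns the combined :class:`FSScore` over ``namespaces`` (a single
    namespace gives that namespace's score), or ``None`` if the pair is
    unscorable in any requested namespace.
    """
    namespaces = tuple(namespaces)
    per_ns = {}
    try:
        for ns in namespaces:
            M = ss_matrix(P, R, measure, ns, corpus, dags[ns], ics[ns], **sim_kwargs)
            per_ns[ns] = mix(M, mix_name, namespace=ns)
    except UnscorableError:
        return None
    if len(namespaces) == 1:
        return per_ns[namespaces[0]]
    return combine(per_ns, namespaces)


def make_scorer(measure, mix_name, namespaces, corpus, dags, ics, **sim_kwargs):
    """Bind the scoring context into a ``scorer(P, R) -> float | None``.

    The returned callable is the interface the background and benchmark
    engines consume: a raw combined FS value, or ``None`` for an
    unscorable pair.
    """

    def scorer(P: str, R: str):
        fs = score_pair(P, R, measure, mix_name, namespaces, corpus, dags, ics, **sim_kwargs)
        return None if fs is None else fs.value

    return scorer
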