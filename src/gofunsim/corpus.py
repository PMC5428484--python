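"""GAF annotation corpora and information-content tables.

An annotation corpus links gene products to GO terms with an evidence
code and taxon of origin. From a corpus and a namespace DAG we derive
term probabilities P(t) = N(t)/N(root), where N(t) is the number of
*distinct* proteins annotated to t or any of its descendants, and the
information content I(t) = -ln P(t). P is always computed relative to
the corpus it came from: filtering (IEA exclusion, taxon restriction)
changes N(root) along with every N(t).

Filters mirror the two corpus axes commonly studied: IEA(+) vs IEA(-)
(include or omit electronically inferred annotations) and ALL vs AOO
(annotations from all organisms vs only the organisms under
comparison).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .ontology_io import OntologyDAG

logger = logging.getLogger(__name__)

GAF_COLUMNS = [
    "db",
    "protein",
    "symbol",
    "qualifier",
    "term",
    "reference",
    "evidence",
    "with_from",
    "aspect",
    "name",
    "synonym",
    "type",
    "taxon",
    "date",
    "assigned_by",
    "extension",
    "form_id",
]

RECORD_COLUMNS = ["protein", "term", "evidence", "taxon", "namespace"]


class CorpusError(ValueError):
    """Corpus-level inconsistency (e.g. no annotated proteins)."""


class GafFormatError(ValueError):
    """Structurally invalid GAF line."""


@dataclass
class AnnotationCorpus:
    """Annotation records plus per-namespace direct-annotation maps."""

    records: pd.DataFrame
    filter_state: dict = field(
        default_factory=lambda: {"iea": "included", "taxa": "ALL"}
    )
    _direct_cache: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.records)

    def direct(self, namespace: str) -> dict:
        """Deduplicated direct annotation sets, protein -> frozenset of terms."""
        cached = self._direct_cache.get(namespace)
        if cached is None:
            sub = self.records[self.records["namespace"] == namespace]
            cached = {
                protein: frozenset(group)
                for protein, group in sub.groupby("protein")["term"]
            }
            self._direct_cache[namespace] = cached
        return cached

    def annotated_proteins(self, namespace: str) -> frozenset:
        return frozenset(self.direct(namespace))

    def taxa(self) -> frozenset:
        return frozenset(self.records["taxon"].unique())


def _parse_taxon(raw: str) -> int:
    # GAF column 13 is "taxon:NNNN" optionally "|taxon:MMMM" for interactions;
    # the first entry is the annotated object's organism.
    first = raw.split("|")[0]
    return int(first.split(":")[1])


def parse_gaf(path, dag_set: dict) -> AnnotationCorpus:
    """Parse a GAF 2.x file into an :class:`AnnotationCorpus`.

    NOT-qualified lines are dropped (they state what a product does
    *not* do). Term accessions are resolved through ``alt_id`` aliases;
    annotations to terms absent from every DAG are dropped with a
    logged count.

    Raises
    ------
    GafFormatError
        If a data line does not have the 17 tab-separated GAF columns.
    """
    rows = []
    n_not = n_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) != len(GAF_COLUMNS):
                raise GafFormatError(
                    f"line {lineno}: expected {len(GAF_COLUMNS)} tab-separated "
                    f"GAF columns, found {len(fields)}"
                )
            rec = dict(zip(GAF_COLUMNS, fields))
            if "NOT" in rec["qualifier"].split("|"):
                n_not += 1
                continue
            resolved = None
            for dag in dag_set.values():
                if rec["term"] in dag:
                    resolved = (dag.resolve(rec["term"]), dag.namespace)
                    break
            if resolved is None:
                n_unknown += 1
                continue
            term, namespace = resolved
            rows.append(
                (rec["protein"], term, rec["evidence"], _parse_taxon(rec["taxon"]), namespace)
            )
    if n_not:
        logger.info("dropped %d NOT-qualified annotation(s)", n_not)
    if n_unknown:
        logger.warning("dropped %d annotation(s) to unknown GO terms", n_unknown)
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return AnnotationCorpus(records=records)


def filter_corpus(corpus: AnnotationCorpus, iea: str = "included", taxa="ALL") -> AnnotationCorpus:
    """Return a new corpus with evidence and/or taxon filters applied.

    Parameters
    ----------
    iea : {"included", "excluded"}
        ``"excluded"`` removes every record with evidence code IEA.
    taxa : "ALL" or iterable of int
        Restricting to the organisms under comparison yields the
        AOO ("annotations of own organisms") corpus.
    """
    if iea not in ("included", "excluded"):
        raise ValueError(f"iea must be 'included' or 'excluded', got {iea!r}")
    records = corpus.records
    if iea == "excluded":
        records = records[records["evidence"] != "IEA"]
    if taxa != "ALL":
        taxa = frozenset(int(t) for t in taxa)
        records = records[records["taxon"].isin(taxa)]
    if records.empty:
        logger.warning("corpus filter (iea=%s, taxa=%s) left no records", iea, taxa)
    state = {"iea": iea, "taxa": taxa if taxa == "ALL" else frozenset(taxa)}
    return AnnotationCorpus(records=records.reset_index(drop=True), filter_state=state)


@dataclass
class ICTable:
    """Annotation counts, probabilities, and information content.

    ``N[t]`` counts distinct proteins annotated to ``t`` or any
    descendant; ``P[t] = N[t]/n_root``; ``I[t] = -ln P[t]`` in natural-log
    units (nats). Terms with zero annotations are *unscorable*: they do
    not appear in the tables and similarity involving only unscorable
    ancestors evaluates to 0 downstream.
    """

    namespace: str
    N: dict
    P: dict
    I: dict
    n_root: int
    log_base: float = math.e

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.I

    def ic(self, term_id: str):
        """Information content, or ``None`` for unscorable terms."""
        return self.I.get(term_id)

    def max_ic(self) -> float:
        return max(self.I.values())

    def to_frame(self) -> pd.DataFrame:
        terms = sorted(self.N)
        return pd.DataFrame(
            {
                "term": terms,
                "N": [self.N[t] for t in terms],
                "P": [self.P[t] for t in terms],
                "I": [self.I[t] for t in terms],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.9g")


def build_ic(corpus: AnnotationCorpus, dag: OntologyDAG, log_base: float = math.e) -> ICTable:
    """Propagate annotation counts up the DAG and derive P and I.

    A protein annotated to several descendants of ``t`` contributes to
    ``N[t]`` exactly once (distinct-protein counting): each protein's
    contribution is the union of the reflexive ancestor closures of its
    direct terms.

    Raises
    ------
    CorpusError
        If no protein in the corpus is annotated in the DAG's namespace.
    """
    direct = corpus.direct(dag.namespace)
    if not direct:
        raise CorpusError(f"no annotated proteins in namespace {dag.namespace}")
    counts: dict = {}
    for terms in direct.values():
        closure = frozenset().union(*(dag.ancestors(t) for t in terms))
        for t in closure:
            counts[t] = counts.get(t, 0) + 1
    n_root = counts[dag.root]
    assert n_root == len(direct)
    log = math.log if log_base == math.e else (lambda x: math.log(x, log_base))
    P = {t: n / n_root for t, n in counts.items()}
    I = {t: -log(p) for t, p in P.items()}
    I[dag.root] = 0.0  # exact, avoids -0.0
    return ICTable(
        namespace=dag.namespace, N=counts, P=P, I=I, n_root=n_root, log_base=log_base
    )
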