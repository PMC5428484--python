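"""Synthetic ontology / annotation / orthology worlds.

Generates self-contained two-organism test worlds in the exact formats
the readers consume — an OBO ontology, one GAF 2.2 file per organism,
and an orthologue TSV — together with a truth record of every direct
annotation and the planted orthology, so oracle tests can check the
parsers and scorers against ground truth without any download.

The generator emulates the statistical structure that motivates
background z-scores rather than real GO topology:

* a heavy-tailed annotation-count mixture — most proteins carry a few
  terms, a small "disease-gene" tail carries tens of terms — which
  inflates raw similarity scores for the tail;
* a fraction of proteins annotated only electronically (evidence code
  IEA), which vanish under IEA(-) filtering;
* orthologue pairs whose annotation sets overlap far more than random
  pairs' (the planted signal the benchmark must detect).

Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NAMESPACE_ASPECT = {"BP": "P", "MF": "F", "CC": "C"}
_OBO_NS = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}


@dataclass
class FixtureSpec:
    """Parameters of a synthetic world.

    Defaults give a small but non-degenerate world: three namespaces,
    30 proteins per organism, 10 orthologue pairs with 70% annotation
    overlap, 20% IEA-only proteins, and a 10% heavily annotated tail.
    """

    n_terms: dict = field(default_factory=lambda: {"BP": 20, "MF": 12, "CC": 10})
    max_parents: int = 2
    part_of_fraction: float = 0.2
    n_proteins: int = 30
    taxa: tuple = (1001, 2002)
    low_count_range: tuple = (1, 4)
    tail_count_range: tuple = (10, 16)
    tail_fraction: float = 0.1
    iea_fraction: float = 0.2
    n_orthologs: int = 10
    ortholog_overlap: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        for ns, n in self.n_terms.items():
            if n < 2:
                raise ValueError(f"namespace {ns} needs >= 2 terms")
            if self.max_parents >= n:
                raise ValueError(
                    f"max_parents={self.max_parents} must be < n_terms[{ns}]={n}"
                )
            # per-protein counts are clamped to n-1 at draw time (the root is
            # never a direct annotation); only the smallest count must fit
            if self.low_count_range[0] >= n:
                raise ValueError(
                    f"minimum annotation count must be < n_terms[{ns}]={n}"
                )
        if self.n_orthologs > self.n_proteins:
            raise ValueError("cannot plant more orthologues than proteins")
        if not 0.0 <= self.ortholog_overlap <= 1.0:
            raise ValueError("ortholog_overlap must be in [0, 1]")


@dataclass
class FixtureWorld:
    """Paths of the written files plus the ground-truth record."""

    obo_path: Path
    gaf_paths: dict
    ortholog_path: Path
    truth: dict

    def truth_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=1, default=list)


def _make_terms(spec: FixtureSpec, rng: np.random.Generator):
    """One acyclic single-root term layer per namespace.

    Term i > 0 receives 1..max_parents parents among earlier terms, so
    acyclicity and reachability of the root are guaranteed by
    construction. GO ids are globally sequential across namespaces.
    """
    terms = {}
    counter = 1
    for ns in spec.n_terms:
        ids = [f"GO:{counter + i:07d}" for i in range(spec.n_terms[ns])]
        counter += spec.n_terms[ns]
        parents = {ids[0]: []}
        for i in range(1, len(ids)):
            k = int(rng.integers(1, min(spec.max_parents, i) + 1))
            choices = rng.choice(i, size=k, replace=False)
            rels = []
            for c in choices:
                rel = "part_of" if rng.random() < spec.part_of_fraction else "is_a"
                rels.append((ids[int(c)], rel))
            parents[ids[i]] = rels
        terms[ns] = {"ids": ids, "parents": parents}
    return terms


def _write_obo(terms: dict, path: Path) -> None:
    lines = ["format-version: 1.2", "ontology: go-synthetic", ""]
    for ns, layer in terms.items():
        for tid in layer["ids"]:
            lines.append("[Term]")
            lines.append(f"id: {tid}")
            lines.append(f"name: synthetic {ns} term {tid[3:]}")
            lines.append(f"namespace: {_OBO_NS[ns]}")
            for pid, rel in layer["parents"][tid]:
                if rel == "is_a":
                    lines.append(f"is_a: {pid}")
                else:
                    lines.append(f"relationship: {rel} {pid}")
            lines.append("")
    path.write_text("\n".join(lines))


def _draw_count(spec: FixtureSpec, rng: np.random.Generator, n_terms: int) -> int:
    if rng.random() < spec.tail_fraction:
        lo, hi = spec.tail_count_range
    else:
        lo, hi = spec.low_count_range
    # the annotatable pool excludes the root, hence the n-1 clamp
    hi = min(hi, n_terms - 1)
    lo = min(lo, hi)
    return int(rng.integers(lo, hi + 1))


def _annotate_organism(spec, rng, terms, prefix, partner_truth=None, ortho_ids=None):
    """Direct annotation sets for one organism.

    When ``partner_truth`` is given, proteins paired in ``ortho_ids``
    copy ``ortholog_overlap`` of the partner's terms per namespace and
    fill the remainder randomly — the planted orthology signal.
    """
    truth = {}
    iea_only = set()
    ids = [f"{prefix}{i:04d}" for i in range(spec.n_proteins)]
    for i, pid in enumerate(ids):
        # orthologue proteins stay manually curated so the planted
        # signal survives IEA(-) filtering
        is_ortho = ortho_ids is not None and i < spec.n_orthologs
        if not is_ortho and rng.random() < spec.iea_fraction:
            iea_only.add(pid)
        annot = {}
        for ns, layer in terms.items():
            pool = layer["ids"]
            n_terms = len(pool)
            count = _draw_count(spec, rng, n_terms)
            if is_ortho and partner_truth is not None:
                partner_terms = sorted(partner_truth[ortho_ids[i]][ns])
                n_shared = int(round(spec.ortholog_overlap * len(partner_terms)))
                shared = list(
                    rng.choice(partner_terms, size=n_shared, replace=False)
                ) if n_shared else []
                rest_pool = [t for t in pool if t not in shared]
                n_extra = max(count - len(shared), 0)
                extra = list(rng.choice(rest_pool, size=min(n_extra, len(rest_pool)), replace=False))
                chosen = shared + extra
                if not chosen:
                    chosen = [pool[int(rng.integers(1, n_terms))]]
            else:
                chosen = list(rng.choice(pool[1:], size=count, replace=False))
            annot[ns] = sorted(chosen)
        truth[pid] = annot
    return ids, truth, iea_only


def _write_gaf(path, truth, iea_only, taxon):
    lines = ["!gaf-version: 2.2"]
    ns_of = {}
    for annot in truth.values():
        for ns in annot:
            ns_of[ns] = NAMESPACE_ASPECT[ns]
    for pid in sorted(truth):
        evidence = "IEA" if pid in iea_only else "EXP"
        for ns in sorted(truth[pid]):
            for term in truth[pid][ns]:
                fields = [
                    "SYN",            # db
                    pid,              # object id
                    pid,              # symbol
                    "involved_in",    # qualifier
                    term,             # GO id
                    "SYN_REF:0000001",
                    evidence,
                    "",
                    ns_of[ns],        # aspect
                    f"synthetic protein {pid}",
                    "",
                    "protein",
                    f"taxon:{taxon}",
                    "20150901",
                    "SYN",
                    "",
                    "",
                ]
                lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def planted_maxima_matrix(
    m: int,
    n: int,
    row_max_sum: float,
    col_max_sum: float,
    zero_col: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """An m x n score matrix with prescribed row/column maxima sums.

    Construction: one column (``zero_col``) is all zeros — a term with
    no similarity to any partner term, the situation where best-match
    averaging visibly penalizes an unmatched annotation. The remaining
    ``n - 1`` columns each carry one column maximum of
    ``col_max_sum/(n-1)``; the surplus ``row_max_sum - col_max_sum`` is
    spread as the row maxima of the leftover rows in the first active
    column. All other cells are filled with values strictly below every
    placed maximum (zeros, or small random values when ``rng`` is
    given), so the maxima structure is realized by the fill-in, not
    assumed.
    """
    if zero_col is None:
        zero_col = min(2, n - 1)
    active = [j for j in range(n) if j != zero_col]
    if m < len(active):
        raise ValueError("need at least n-1 rows to place the column maxima")
    if row_max_sum < col_max_sum:
        raise ValueError("row-maxima sum cannot be below column-maxima sum here")
    col_peak = col_max_sum / len(active)
    k = m - (len(active) - 1)  # rows whose maximum lives in the first active column
    surplus = row_max_sum - col_max_sum
    y = surplus / (k - 1) if k > 1 else 0.0
    if y > col_peak:
        raise ValueError("surplus per row exceeds the column peak; infeasible layout")
    M = np.zeros((m, n))
    M[0, active[0]] = col_peak
    for i in range(1, k):
        M[i, active[0]] = y
    for offset, j in enumerate(active[1:]):
        M[k + offset, j] = col_peak
    if rng is not None:
        floor = min(v for v in (col_peak, y) if v > 0)
        for i in range(m):
            for j in active:
                if M[i, j] == 0.0:
                    M[i, j] = rng.uniform(0.0, 0.5 * floor)
    assert np.isclose(M.max(axis=1).sum(), row_max_sum)
    assert np.isclose(M.max(axis=0).sum(), col_max_sum)
    return M


def make_world(spec: FixtureSpec, outdir) -> FixtureWorld:
    """Write a complete synthetic world and return paths plus truth.

    Files: ``fixture.obo``, ``org_<taxon>.gaf`` per organism,
    ``orthologs.tsv`` (with a pct_identity column drawn uniformly in
    [20, 75), i.e. below the 80% exclusion line).
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    terms = _make_terms(spec, rng)
    obo_path = outdir / "fixture.obo"
    _write_obo(terms, obo_path)

    taxon_a, taxon_b = spec.taxa
    ids_a, truth_a, iea_a = _annotate_organism(spec, rng, terms, "A")
    ortho_ids = {i: ids_a[i] for i in range(spec.n_orthologs)}
    ids_b, truth_b, iea_b = _annotate_organism(
        spec, rng, terms, "B", partner_truth=truth_a, ortho_ids=ortho_ids
    )

    gaf_paths = {}
    for taxon, truth_x, iea_x in ((taxon_a, truth_a, iea_a), (taxon_b, truth_b, iea_b)):
        p = outdir / f"org_{taxon}.gaf"
        _write_gaf(p, truth_x, iea_x, taxon)
        gaf_paths[taxon] = p

    pairs = [(ids_a[i], ids_b[i]) for i in range(spec.n_orthologs)]
    pct = [float(x) for x in rng.uniform(20.0, 75.0, size=len(pairs))]
    ortho_path = outdir / "orthologs.tsv"
    with open(ortho_path, "w") as fh:
        fh.write("idA\tidB\tpct_identity\n")
        for (a, b), x in zip(pairs, pct):
            fh.write(f"{a}\t{b}\t{x:.2f}\n")

    truth = {
        "seed": spec.seed,
        "taxa": list(spec.taxa),
        "terms": {ns: layer["ids"] for ns, layer in terms.items()},
        "parents": {
            ns: {t: [list(p) for p in layer["parents"][t]] for t in layer["ids"]}
            for ns, layer in terms.items()
        },
        "annotations": {taxon_a: truth_a, taxon_b: truth_b},
        "iea_only": {taxon_a: sorted(iea_a), taxon_b: sorted(iea_b)},
        "orthologs": [list(p) for p in pairs],
        "pct_identity": pct,
    }
    return FixtureWorld(
        obo_path=obo_path, gaf_paths=gaf_paths, ortholog_path=ortho_path, truth=truth
    )
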