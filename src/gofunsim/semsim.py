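"""Pairwise term-level semantic similarity measures.

Six measures over a pair of GO terms (s, t) with common-ancestor set
S(s, t) and information content I from an annotation corpus:

* ``simRes`` — I of the most informative common ancestor (MICA);
  unbounded above.
* ``simLin`` — 2 I(MICA) / (I(s) + I(t)); in [0, 1].
* ``simRel`` — Lin's ratio weighted by the counter-probability
  (1 - P(c)) of the ancestor, jointly maximized over all common
  ancestors (the maximizer need not be the MICA); down-weights
  shallow annotations.
* ``simIC`` — Lin's ratio weighted by (1 - 1/(1 + I(MICA))); an
  alternative weighting that keeps weight for near-leaf ancestors.
* ``simJC`` — 1 / (1 + I(s) + I(t) - 2 I(MICA)); the Jiang-Conrath
  distance turned into a similarity.
* ``simGIC`` — ratio of summed I over the intersection vs the union of
  the two reflexive ancestor closures; the only measure that uses the
  whole closure rather than a single ancestor.

Terms never annotated in the corpus are unscorable; every measure
returns 0 for a pair whose comparison rests only on unscorable terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .corpus import ICTable
from .ontology_io import OntologyDAG

logger = logging.getLogger(__name__)

MEASURES = ("simRes", "simLin", "simRel", "simIC", "simJC", "simGIC")


@dataclass(frozen=True)
class TermPairContext:
    """Everything a single-ancestor measure needs about a term pair.

    ``mica`` is ``None`` when either term, or every common ancestor,
    is unscorable (zero annotations) — all measures then score 0.
    """

    s: str
    t: str
    common_ancestors: frozenset
    mica: str | None
    i_s: float | None
    i_t: float | None
    i_mica: float | None
    p_mica: float | None


def mica(dag: OntologyDAG, ic: ICTable, s: str, t: str) -> TermPairContext:
    """Locate the most informative common ancestor of ``s`` and ``t``.

    Ancestor closures are reflexive, so ``mica(t, t) == t``. Ties on
    information content are broken toward the lexicographically
    smallest accession, making runs reproducible.

    Raises
    ------
    UnknownTermError
        If either term is not in ``dag``'s namespace (this is also how
        a cross-namespace pair surfaces).
    """
    s = dag.resolve(s)
    t = dag.resolve(t)
    common = dag.ancestors(s) & dag.ancestors(t)
    i_s = ic.ic(s)
    i_t = ic.ic(t)
    scorable = [c for c in common if c in ic]
    if i_s is None or i_t is None or not scorable:
        logger.debug("unscorable term pair (%s, %s)", s, t)
        return TermPairContext(s, t, common, None, i_s, i_t, None, None)
    best = min(scorable, key=lambda c: (-ic.I[c], c))
    return TermPairContext(
        s=s,
        t=t,
        common_ancestors=common,
        mica=best,
        i_s=i_s,
        i_t=i_t,
        i_mica=ic.I[best],
        p_mica=ic.P[best],
    )


def _sim_gic(ctx: TermPairContext, dag: OntologyDAG, ic: ICTable) -> float:
    anc_s = dag.ancestors(ctx.s)
    anc_t = dag.ancestors(ctx.t)
    num = sum(ic.I[c] for c in anc_s & anc_t if c in ic)
    den = sum(ic.I[c] for c in anc_s | anc_t if c in ic)
    return num / den if den > 0 else 0.0


def _sim_rel(ctx: TermPairContext, ic: ICTable, denom: float, mica_only: bool) -> float:
    if mica_only:
        return (2.0 * ic.I[ctx.mica] / denom) * (1.0 - ic.P[ctx.mica])
    return max(
        (2.0 * ic.I[c] / denom) * (1.0 - ic.P[c])
        for c in ctx.common_ancestors
        if c in ic
    )


def sim(
    measure: str,
    ctx: TermPairContext,
    dag: OntologyDAG,
    ic: ICTable,
    *,
    rel_mica_only: bool = False,
    ic_weight: str = "plus",
) -> float:
    """Evaluate one similarity measure on a prepared term-pair context.

    Parameters
    ----------
    measure : str
        One of :data:`MEASURES`.
    rel_mica_only : bool
        Evaluate simRel's weighted ratio at the MICA only instead of
        maximizing the product over all common ancestors.
    ic_weight : {"plus", "printed"}
        simIC weight form. ``"plus"`` is (1 - 1/(1 + I(MICA))), the
        original information-coefficient weight that keeps scores in
        [0, 1]. ``"printed"`` is the (1 - 1/(1 - I(MICA))) variant seen
        in some write-ups; it is negative or singular for I > 0 and is
        provided only for comparison.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    if ctx.mica is None:
        return 0.0
    if measure == "simGIC":
        return _sim_gic(ctx, dag, ic)
    i_mica = ctx.i_mica
    if measure == "simRes":
        return i_mica
    if measure == "simJC":
        return 1.0 / (1.0 + ctx.i_s + ctx.i_t - 2.0 * i_mica)
    denom = ctx.i_s + ctx.i_t
    if denom == 0.0:
        # both terms carry probability 1; the ratio measures are defined as 0
        return 0.0
    if measure == "simLin":
        return 2.0 * i_mica / denom
    if measure == "simRel":
        return _sim_rel(ctx, ic, denom, rel_mica_only)
    # simIC
    lin = 2.0 * i_mica / denom
    if ic_weight == "plus":
        return lin * (1.0 - 1.0 / (1.0 + i_mica))
    if ic_weight == "printed":
        if i_mica == 1.0:
            raise ZeroDivisionError("printed simIC weight is singular at I(MICA)=1")
        return lin * (1.0 - 1.0 / (1.0 - i_mica))
    raise ValueError(f"ic_weight must be 'plus' or 'printed', got {ic_weight!r}")


def pair_sim(
    dag: OntologyDAG,
    ic: ICTable,
    s: str,
    t: str,
    measure: str,
    **kwargs,
) -> float:
    """Convenience: MICA search plus measure evaluation in one call."""
    return sim(measure, mica(dag, ic, s, t), dag, ic, **kwargs)
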