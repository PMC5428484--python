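"""Per-protein score backgrounds and similarity z-scores.

Raw functional-similarity scores are not comparable across proteins:
heavily annotated proteins (disease genes and other well-studied
products) receive systematically higher scores against *any* partner.
The background of a protein P is the empirical distribution of F(P, Q)
over partners Q sampled without replacement from the annotated
proteins of the partner organism; its mean mu_P and standard deviation
sigma_P normalize a raw pair score into

    z(P, R) = (2 F(P, R) - (mu_P + mu_R)) / sqrt(sigma_P^2 + sigma_R^2),

treating F(P, R) as one draw from each of the two backgrounds (hence
the factor 2 and the summed variances). A large raw score over a high
background yields a modest z, while the same raw score over a low
background is genuinely surprising.

Backgrounds are expensive (k scores per protein, default k = 1000) and
deterministic under a fixed seed, so they can be computed once and
persisted as TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class UndefinedZScoreError(ZeroDivisionError):
    """Both background standard deviations are zero; z is undefined."""


@dataclass
class BackgroundStats:
    """Per-protein (mu, sigma, n_sampled) plus the scoring context."""

    stats: dict
    context: dict = field(default_factory=dict)

    def __contains__(self, protein: str) -> bool:
        return protein in self.stats

    def __getitem__(self, protein: str):
        return self.stats[protein]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"protein": p, "mu": mu, "sigma": sigma, "n_sampled": n}
            for p, (mu, sigma, n) in sorted(self.stats.items())
        ]
        return pd.DataFrame(rows, columns=["protein", "mu", "sigma", "n_sampled"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.9g")

    @classmethod
    def from_tsv(cls, path, context=None) -> "BackgroundStats":
        df = pd.read_csv(path, sep="\t")
        stats = {
            r.protein: (float(r.mu), float(r.sigma), int(r.n_sampled))
            for r in df.itertuples()
        }
        return cls(stats=stats, context=context or {})


def estimate_background(
    proteins,
    partner_pool,
    k: int,
    seed: int,
    scorer,
    context: dict | None = None,
) -> BackgroundStats:
    """Estimate mu/sigma of an FS measure for each protein.

    Parameters
    ----------
    proteins : sequence of str
        Query proteins needing a background.
    partner_pool : sequence of str
        Annotated proteins of the partner organism; sampling is
        without replacement within each protein's background.
    k : int
        Partners per protein (clamped to the pool size with a warning).
    seed : int
        Drives a single PRNG stream; with the protein order fixed the
        result is bit-reproducible.
    scorer : callable (P, Q) -> float or None
        ``None`` marks an unscorable pair; such pairs are skipped and
        ``n_sampled`` shrinks accordingly.

    Notes
    -----
    sigma is the sample standard deviation (n-1 denominator); a
    background with fewer than two scorable partners gets sigma 0.
    """
    pool = np.asarray(list(partner_pool))
    if pool.size == 0:
        raise ValueError("partner pool is empty")
    if k > pool.size:
        logger.warning(
            "background sample size k=%d exceeds pool size %d; clamping", k, pool.size
        )
        k = pool.size
    rng = np.random.default_rng(seed)
    stats = {}
    for P in proteins:
        partners = rng.choice(pool, size=k, replace=False)
        scores = [s for Q in partners if (s := scorer(P, str(Q))) is not None]
        n = len(scores)
        if n == 0:
            logger.warning("protein %s: no scorable background partners", P)
            stats[P] = (float("nan"), float("nan"), 0)
            continue
        arr = np.asarray(scores)
        sigma = float(arr.std(ddof=1)) if n > 1 else 0.0
        stats[P] = (float(arr.mean()), sigma, n)
    ctx = dict(context or {})
    ctx.update({"k": k, "seed": seed})
    return BackgroundStats(stats=stats, context=ctx)


def zscore(F: float, stats_P, stats_R) -> float:
    """Similarity z-score of a raw pair score against two backgrounds.

    ``stats_P`` and ``stats_R`` are ``(mu, sigma)`` pairs (a trailing
    ``n_sampled`` entry is tolerated and ignored).

    Raises
    ------
    UndefinedZScoreError
        If both sigmas are zero.
    """
    mu_p, sigma_p = stats_P[0], stats_P[1]
    mu_r, sigma_r = stats_R[0], stats_R[1]
    denom_sq = sigma_p**2 + sigma_r**2
    if denom_sq <= 0.0:
        raise UndefinedZScoreError(
            "both background standard deviations are zero; z-score undefined"
        )
    return (2.0 * F - (mu_p + mu_r)) / denom_sq**0.5
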