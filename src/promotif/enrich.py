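"""Hypergeometric over-representation of bona fide elements in gene sets.

With N scored promoters genome-wide, K of them called as carrying a bona
fide element, and a gene set of size n containing k called members, the
over-representation p-value is the upper tail P(X >= k) of the
hypergeometric distribution Hypergeom(N, K, n).

The universe for the test is the set of promoters with a non-missing best
score for the motif — the same population the mixture was fit to — so the
reported (N, K, n, k) are always mutually consistent and auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

from scipy.stats import hypergeom

from .mixture import BonaFideCalls
from .promoters import PromoterUniverse
from .scan import ScoreTable

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    """Hypergeometric test result for one (motif, gene set) pair."""

    motif_id: str
    set_name: str
    N: int
    K: int
    n: int
    k: int
    proportion: float
    p: float


@dataclass
class CoOccurrenceRecord:
    """Genes in a set called for both members of a family pair."""

    set_name: str
    family_pair: tuple[str, str]
    genes: set[str]

    @property
    def count(self) -> int:
        return len(self.genes)


def hypergeometric_tail(N: int, K: int, n: int, k: int, lower: bool = False) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``lower=True`` gives the depletion tail P(X <= k) instead.  Arguments
    outside the distribution's support are rejected.
    """
    if not (0 <= K <= N):
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    k_min, k_max = max(0, n + K - N), min(n, K)
    if not (k_min <= k <= k_max):
        raise ValueError(
            f"k={k} outside support [{k_min}, {k_max}] for N={N}, K={K}, n={n}"
        )
    if lower:
        return float(min(1.0, hypergeom.cdf(k, N, K, n)))
    if k == k_min:
        return 1.0
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def enrich_set(
    calls: BonaFideCalls,
    gene_set: set[str],
    universe: PromoterUniverse | set[str],
    set_name: str,
    table: ScoreTable | None = None,
) -> EnrichmentRecord:
    """Test over-representation of called elements within a gene set.

    The test universe is the scored-promoter population behind ``calls``
    (``table`` restricted to the motif when given, otherwise the supplied
    universe).  Set members outside the universe are dropped with a logged
    count.
    """
    if table is not None:
        univ_ids = set(table.motif_hits(calls.motif_id)["gene_id"])
    elif isinstance(universe, PromoterUniverse):
        univ_ids = set(universe.gene_ids)
    else:
        univ_ids = set(universe)
    gene_set = set(gene_set)
    dropped = len(gene_set - univ_ids)
    if dropped:
        logger.info(
            "set %s: dropping %d gene(s) outside the scored universe",
            set_name, dropped,
        )
    in_universe = gene_set & univ_ids
    n = len(in_universe)
    if n == 0:
        raise ValueError(
            f"gene set {set_name!r} has no members in the scored universe"
        )
    N = len(univ_ids)
    K = len(calls.called & univ_ids)
    k = len(in_universe & calls.called)
    p = hypergeometric_tail(N, K, n, k)
    return EnrichmentRecord(
        motif_id=calls.motif_id, set_name=set_name,
        N=N, K=K, n=n, k=k, proportion=k / n, p=p,
    )


def co_occurrence(
    calls_by_family: dict[str, BonaFideCalls],
    gene_set: set[str],
    set_name: str,
) -> list[CoOccurrenceRecord]:
    """Per unordered family pair, the set-restricted intersection of calls."""
    if len(calls_by_family) < 2:
        raise ValueError("co-occurrence needs at least two families")
    gene_set = set(gene_set)
    out = []
    for fam_a, fam_b in combinations(sorted(calls_by_family), 2):
        genes = (
            calls_by_family[fam_a].called
            & calls_by_family[fam_b].called
            & gene_set
        )
        out.append(
            CoOccurrenceRecord(
                set_name=set_name, family_pair=(fam_a, fam_b), genes=genes
            )
        )
    return out
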