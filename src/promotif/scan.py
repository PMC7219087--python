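"""Genome-wide PWM scanning and set-vs-genome enrichment.

Every promoter is scored against each weight matrix on both strands and the
single best-scoring window per (gene, motif) is kept — the per-gene summary
whose genome-wide distribution the mixture model is later fit to.  Scores
are also normalised to [0, 1] between the matrix's theoretical minimum and
maximum so distributions are comparable across matrices.

Set enrichment follows the set-mean z-test of promoter-scanning tools such
as Pscan: with the genome-wide mean and standard deviation of best scores
known, the mean score of an n-gene set has standard error sd_pop/sqrt(n)
under the null, giving a one-sided upper-tail normal p-value per motif.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .motifs import ALPHABET, WeightMatrix
from .promoters import PromoterRecord, PromoterUniverse

logger = logging.getLogger(__name__)

_ENCODE = np.full(128, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
_ENCODE[ord("N")] = 4


def encode_sequence(seq: str) -> np.ndarray:
    """Map A,C,G,T,N -> 0..4 as an int8 array."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class MatchHit:
    """Best-scoring window of one motif in one promoter."""

    gene_id: str
    motif_id: str
    raw_score: float
    norm_score: float
    offset: int  # 0-based start within the promoter (forward coordinates)
    strand: str  # '+' or '-'


@dataclass
class ScoreTable:
    """Best-match hits per (motif, gene) over a promoter universe.

    ``hits`` holds one row per (motif, gene) pair that had at least one
    N-free window; promoters too short for the motif (or fully masked by N)
    are simply absent.
    """

    hits: pd.DataFrame  # gene_id, motif_id, raw_score, norm_score, offset, strand
    universe_ids: list[str]
    widths: dict[str, int] = field(default_factory=dict)

    @property
    def n_universe(self) -> int:
        return len(self.universe_ids)

    def motif_ids(self) -> list[str]:
        return list(dict.fromkeys(self.hits["motif_id"]))

    def motif_hits(self, motif_id: str) -> pd.DataFrame:
        return self.hits[self.hits["motif_id"] == motif_id]

    def norm_scores(self, motif_id: str) -> pd.Series:
        sub = self.motif_hits(motif_id)
        return pd.Series(
            sub["norm_score"].to_numpy(), index=sub["gene_id"].to_numpy()
        )

    def hit_for(self, motif_id: str, gene_id: str) -> MatchHit | None:
        sub = self.hits[
            (self.hits["motif_id"] == motif_id)
            & (self.hits["gene_id"] == gene_id)
        ]
        if sub.empty:
            return None
        r = sub.iloc[0]
        return MatchHit(
            gene_id=r["gene_id"], motif_id=r["motif_id"],
            raw_score=float(r["raw_score"]), norm_score=float(r["norm_score"]),
            offset=int(r["offset"]), strand=r["strand"],
        )


@dataclass
class MotifEnrichment:
    """Set-vs-genome z-test result for one motif."""

    motif_id: str
    set_name: str
    n_set: int
    mean_set: float
    mean_pop: float
    sd_pop: float
    z: float
    p: float
    p_adjusted: float = math.nan


def window_score(wm: WeightMatrix, window: str) -> float:
    """Additive log-odds score of a single N-free window of motif width."""
    if len(window) != wm.width:
        raise ValueError(
            f"window length {len(window)} != motif width {wm.width}"
        )
    idx = encode_sequence(window)
    if np.any(idx == 4):
        raise ValueError("window contains N; caller must filter N windows")
    return float(wm.weights[idx, np.arange(wm.width)].sum())


def _lookup_tables(wm: WeightMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-column base->weight lookups (5th row = -inf for N) for both strands.

    Scanning the reverse strand is equivalent to scanning the forward
    sequence with the reverse-complemented matrix.
    """
    fwd = np.full((5, wm.width), -np.inf)
    fwd[:4] = wm.weights
    rev = np.full((5, wm.width), -np.inf)
    rev[:4] = wm.weights[::-1, ::-1]
    return fwd, rev


def _window_scores_matrix(
    codes: np.ndarray, table: np.ndarray, descending: bool = False
) -> np.ndarray:
    """Scores of all windows for encoded sequences (n, P) -> (n, P-L+1).

    Windows containing N score -inf (excluded from the maximum).  With
    ``descending`` the per-window sum accumulates columns right-to-left;
    used for the reverse-complement table so that a palindromic window sums
    its terms in exactly the forward order and ties are bit-exact.
    """
    L = table.shape[1]
    npos = codes.shape[1] - L + 1
    scores = np.zeros((codes.shape[0], npos))
    order = range(L - 1, -1, -1) if descending else range(L)
    for j in order:
        scores += table[:, j][codes[:, j : j + npos]]
    return scores


def best_match(wm: WeightMatrix, promoter: PromoterRecord) -> MatchHit | None:
    """Best-scoring window over both strands of one promoter.

    Ties are broken by smaller offset, then by the + strand.  Returns None
    when no N-free window of motif width exists.
    """
    hits = scan_universe(
        [wm], PromoterUniverse.from_records([promoter])
    )
    return hits.hit_for(wm.motif_id, promoter.gene_id)


def scan_universe(
    wms: list[WeightMatrix], universe: PromoterUniverse
) -> ScoreTable:
    """Score every promoter against every matrix; keep best hits only."""
    if not wms:
        raise ValueError("at least one weight matrix required")
    if len(universe) == 0:
        raise ValueError("empty promoter universe")
    gene_ids = universe.gene_ids
    lengths = np.array([len(universe[g]) for g in gene_ids])
    P = int(lengths.max()) if len(lengths) else 0
    # pad shorter promoters with N so their phantom windows score -inf
    codes = np.full((len(gene_ids), P), 4, dtype=np.int8)
    for i, g in enumerate(gene_ids):
        s = universe[g].sequence
        codes[i, : len(s)] = encode_sequence(s) if s else []

    frames = []
    widths: dict[str, int] = {}
    for wm in wms:
        widths[wm.motif_id] = wm.width
        L = wm.width
        if P < L:
            continue
        fwd_t, rev_t = _lookup_tables(wm)
        fwd = _window_scores_matrix(codes, fwd_t)
        rev = _window_scores_matrix(codes, rev_t, descending=True)
        # interleave (offset, strand) so argmax tie-breaks: smaller offset,
        # then '+' before '-'
        npos = fwd.shape[1]
        both = np.empty((fwd.shape[0], npos * 2))
        both[:, 0::2] = fwd
        both[:, 1::2] = rev
        flat_idx = np.argmax(both, axis=1)
        raw = both[np.arange(both.shape[0]), flat_idx]
        valid = np.isfinite(raw)
        offsets = flat_idx // 2
        strands = np.where(flat_idx % 2 == 0, "+", "-")
        denom = wm.max_score - wm.min_score
        norm = (
            (raw - wm.min_score) / denom if denom > 0
            else np.where(np.isfinite(raw), 0.5, raw)
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": np.asarray(gene_ids)[valid],
                    "motif_id": wm.motif_id,
                    "raw_score": raw[valid],
                    "norm_score": np.asarray(norm)[valid],
                    "offset": offsets[valid],
                    "strand": strands[valid],
                }
            )
        )
    if frames:
        hits = pd.concat(frames, ignore_index=True)
    else:
        hits = pd.DataFrame(
            columns=[
                "gene_id", "motif_id", "raw_score",
                "norm_score", "offset", "strand",
            ]
        )
    return ScoreTable(hits=hits, universe_ids=gene_ids, widths=widths)


def zscore_enrichment(
    table: ScoreTable,
    gene_set: set[str],
    set_name: str,
    use_raw: bool = False,
) -> list[MotifEnrichment]:
    """Set-mean z-test per motif against the genome-wide score population.

    z = (mean_set - mean_pop) / (sd_pop / sqrt(n_set)) over normalised best
    scores; the population is every scored gene in the universe.  One-sided
    upper-tail normal p-values; Benjamini-Hochberg adjustment across the
    motifs tested in this call.
    """
    col = "raw_score" if use_raw else "norm_score"
    out: list[MotifEnrichment] = []
    for motif_id in table.motif_ids():
        sub = table.motif_hits(motif_id)
        pop = sub[col].to_numpy()
        sd_pop = float(pop.std(ddof=0))
        if sd_pop == 0 or np.ptp(pop) == 0:
            raise ValueError(
                f"motif {motif_id!r}: degenerate population (sd = 0)"
            )
        in_set = sub["gene_id"].isin(gene_set).to_numpy()
        n_set = int(in_set.sum())
        if n_set < 2:
            raise ValueError(
                f"motif {motif_id!r}: gene set {set_name!r} has fewer than "
                f"2 scored genes ({n_set})"
            )
        mean_set = float(pop[in_set].mean())
        mean_pop = float(pop.mean())
        z = (mean_set - mean_pop) / (sd_pop / math.sqrt(n_set))
        p = float(stats.norm.sf(z))
        out.append(
            MotifEnrichment(
                motif_id=motif_id, set_name=set_name, n_set=n_set,
                mean_set=mean_set, mean_pop=mean_pop, sd_pop=sd_pop,
                z=z, p=max(p, 1e-300),
            )
        )
    if out:
        adj = multipletests([e.p for e in out], method="fdr_bh")[1]
        for e, pa in zip(out, adj):
            e.p_adjusted = float(pa)
    return out


def select_archetype(
    enrichments: list[MotifEnrichment],
    family_map: dict[str, str],
) -> dict[str, str]:
    """Pick, per element family, the matrix with the strongest enrichment.

    Smallest p wins (equivalently largest z); exact ties go to the
    lexicographically smaller motif id, with a logged warning.
    """
    by_family: dict[str, list[MotifEnrichment]] = {}
    for e in enrichments:
        fam = family_map.get(e.motif_id)
        if fam is not None:
            by_family.setdefault(fam, []).append(e)
    missing = set(family_map.values()) - set(by_family)
    if missing:
        raise ValueError(
            f"no enrichment computed for family/families: {sorted(missing)}"
        )
    chosen: dict[str, str] = {}
    for fam, es in by_family.items():
        es_sorted = sorted(es, key=lambda e: (e.p, e.motif_id))
        if len(es_sorted) > 1 and es_sorted[0].p == es_sorted[1].p:
            logger.warning(
                "family %s: enrichment tie between %s and %s; choosing %s",
                fam, es_sorted[0].motif_id, es_sorted[1].motif_id,
                es_sorted[0].motif_id,
            )
        chosen[fam] = es_sorted[0].motif_id
    return chosen
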