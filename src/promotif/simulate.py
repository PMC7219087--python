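"""Synthetic promoter universes with planted motifs and known ground truth.

The generator emulates the shape of a genome-scale promoter study at desk
scale: a universe of fixed-length promoters with i.i.d. base composition, a
small set of "regulated" genes (default 31 up / 171 down, the shape of the
motivating DEG lists) into which motif instances are planted at an elevated
rate against a low background rate, and a DEG table for those sets.  Every
planting decision is recorded so signal-recovery and calibration tests have
exact truth.

All randomness flows from a single seed through ``numpy``'s SeedSequence:
the global seed spawns one child stream per stage (background universe, set
sampling, one stream per planted motif, gene table), so each stage is
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import ALPHABET, MotifCountMatrix
from .promoters import PromoterRecord, PromoterUniverse, reverse_complement
from .tables import GeneTable

#: Default base composition: Arabidopsis genome-wide GC fraction.
DEFAULT_GC = 0.36


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters.

    ``planting`` maps motif_id -> {set_name_or_'background': rate}; a motif
    absent from the mapping is never planted.
    """

    n_promoters: int = 5000
    promoter_length: int = 500
    gc_content: float = DEFAULT_GC
    motifs: list[MotifCountMatrix] = field(default_factory=list)
    set_sizes: dict[str, int] = field(
        default_factory=lambda: {"up": 31, "down": 171}
    )
    planting: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must lie in (0, 1)")
        if sum(self.set_sizes.values()) > self.n_promoters:
            raise ValueError("requested set sizes exceed the universe size")
        for motif_id, rates in self.planting.items():
            for name, r in rates.items():
                if not (0 <= r <= 1):
                    raise ValueError(
                        f"planting rate for ({motif_id}, {name}) outside [0,1]"
                    )


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated study.

    ``planted`` has one row per (motif, gene) planting decision with the
    insert offset, strand and sampled site; ``sets`` records set membership.
    """

    planted: pd.DataFrame  # motif_id, gene_id, planted, offset, strand, site
    sets: dict[str, set[str]] = field(default_factory=dict)

    def planted_genes(self, motif_id: str) -> set[str]:
        sub = self.planted[
            (self.planted["motif_id"] == motif_id) & self.planted["planted"]
        ]
        return set(sub["gene_id"])


def _empty_truth_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["motif_id", "gene_id", "planted", "offset", "strand", "site"]
    )


def simulate_background_promoters(
    n: int, length: int, gc: float, seed
) -> PromoterUniverse:
    """I.i.d. promoters: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if not (0 < gc < 1):
        raise ValueError("gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer("ACGT".encode(), dtype="S1")
    records = []
    for i in range(n):
        draw = rng.choice(4, size=length, p=probs)
        seq = alphabet[draw].tobytes().decode()
        records.append(PromoterRecord(gene_id=f"G{i:05d}", sequence=seq))
    return PromoterUniverse.from_records(records)


def sample_site(pfm: MotifCountMatrix, rng: np.random.Generator) -> str:
    """Draw one site column-wise from the pseudocounted probability matrix."""
    probs = pfm.probabilities()
    return "".join(
        ALPHABET[rng.choice(4, p=probs[:, j])] for j in range(pfm.width)
    )


def plant_motif_instances(
    universe: PromoterUniverse,
    pfm: MotifCountMatrix,
    target_genes: set[str],
    rate: float,
    seed,
    truth: pd.DataFrame | None = None,
) -> tuple[PromoterUniverse, SyntheticTruth]:
    """Plant at most one motif instance per target gene at the given rate.

    Each target independently receives one insert with probability ``rate``;
    the site is sampled from the motif's probability matrix, placed at a
    uniform offset on a uniform strand, and overwrites (does not lengthen)
    the promoter sequence.
    """
    if not (0 <= rate <= 1):
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    L = pfm.width
    new_records = []
    rows = []
    # iterate in universe order so the outcome is a pure function of the seed
    for rec in universe:
        if rec.gene_id not in target_genes:
            new_records.append(rec)
            continue
        if len(rec.sequence) < L:
            raise ValueError(
                f"promoter {rec.gene_id!r} shorter than motif width {L}"
            )
        if rng.random() >= rate:
            rows.append(
                {
                    "motif_id": pfm.motif_id, "gene_id": rec.gene_id,
                    "planted": False, "offset": -1, "strand": "",
                    "site": "",
                }
            )
            new_records.append(rec)
            continue
        site = sample_site(pfm, rng)
        offset = int(rng.integers(0, len(rec.sequence) - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        insert = site if strand == "+" else reverse_complement(site)
        seq = rec.sequence[:offset] + insert + rec.sequence[offset + L :]
        new_records.append(
            PromoterRecord(
                gene_id=rec.gene_id, sequence=seq, chrom=rec.chrom,
                strand=rec.strand, start=rec.start, end=rec.end,
            )
        )
        rows.append(
            {
                "motif_id": pfm.motif_id, "gene_id": rec.gene_id,
                "planted": True, "offset": offset, "strand": strand,
                "site": site,
            }
        )
    frame = pd.DataFrame(rows) if rows else _empty_truth_frame()
    if truth is not None and len(truth):
        frame = pd.concat([truth, frame], ignore_index=True)
    return (
        PromoterUniverse.from_records(new_records),
        SyntheticTruth(planted=frame),
    )


def simulate_study(
    config: SimulationConfig,
) -> tuple[PromoterUniverse, GeneTable, SyntheticTruth]:
    """Generate a full study: universe, disjoint DEG sets, planted signal.

    DEG sets are sampled without replacement and are disjoint; planting
    applies each motif's in-set rate to its sets and the background rate to
    all remaining genes.  The gene table carries placeholder log
    fold-changes (+1 for 'up' sets, -1 otherwise) and FDR 0.01.
    """
    ss = np.random.SeedSequence(config.seed)
    n_stage = 3 + len(config.motifs)
    children = ss.spawn(n_stage)
    universe = simulate_background_promoters(
        config.n_promoters, config.promoter_length, config.gc_content,
        children[0],
    )
    gene_ids = universe.gene_ids

    rng_sets = np.random.default_rng(children[1])
    total = sum(config.set_sizes.values())
    chosen = rng_sets.choice(len(gene_ids), size=total, replace=False)
    sets: dict[str, set[str]] = {}
    pos = 0
    for name, size in config.set_sizes.items():
        sets[name] = {gene_ids[i] for i in chosen[pos : pos + size]}
        pos += size

    truth_frame = _empty_truth_frame()
    for mi, pfm in enumerate(config.motifs):
        rates = config.planting.get(pfm.motif_id, {})
        set_members: set[str] = set()
        child = children[2 + mi]
        sub_children = child.spawn(len(config.set_sizes) + 1)
        for si, (name, members) in enumerate(sorted(sets.items())):
            set_members |= members
            r = rates.get(name, 0.0)
            universe, t = plant_motif_instances(
                universe, pfm, members, r, sub_children[si]
            )
            truth_frame = pd.concat(
                [truth_frame, t.planted], ignore_index=True
            )
        bg_rate = rates.get("background", 0.0)
        background = set(gene_ids) - set_members
        universe, t = plant_motif_instances(
            universe, pfm, background, bg_rate, sub_children[-1]
        )
        truth_frame = pd.concat([truth_frame, t.planted], ignore_index=True)

    rows = []
    for name in config.set_sizes:
        lfc = 1.0 if "up" in name.lower() else -1.0
        for g in sorted(sets[name]):
            rows.append(
                {
                    "gene_id": g,
                    "direction": "up" if lfc > 0 else "down",
                    "log_fc": lfc,
                    "fdr": 0.01,
                }
            )
    gene_table = GeneTable(
        rows=pd.DataFrame(rows, columns=["gene_id", "direction", "log_fc", "fdr"])
    )
    return universe, gene_table, SyntheticTruth(planted=truth_frame, sets=sets)


def simulate_mixture_scores(pi, mu, sigma, n: int, seed) -> np.ndarray:
    """Draw n values from a two-component Gaussian mixture (component, then value)."""
    pi = np.asarray(pi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if pi.shape != (2,) or mu.shape != (2,) or sigma.shape != (2,):
        raise ValueError("pi, mu, sigma must each be pairs")
    if abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
        raise ValueError("pi must be a probability pair")
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    sigma = np.maximum(sigma, 1e-12)
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < pi[1]
    return rng.normal(np.where(comp, mu[1], mu[0]),
                      np.where(comp, sigma[1], sigma[0]))


def high_information_pfm(
    consensus: str,
    motif_id: str,
    motif_name: str = "",
    family: str | None = None,
    dominance: float = 0.94,
    total: int = 100,
) -> MotifCountMatrix:
    """A sharply peaked count matrix around a consensus (for planted signal).

    ``dominance`` is the per-column frequency of the consensus base; 0.94
    over 10 columns gives roughly 16 bits of information.
    """
    if not (0.25 < dominance <= 1):
        raise ValueError("dominance must exceed 0.25")
    counts = np.full((4, len(consensus)), total * (1 - dominance) / 3)
    for j, base in enumerate(consensus.upper()):
        counts[ALPHABET.index(base), j] = total * dominance
    return MotifCountMatrix(
        motif_id=motif_id, motif_name=motif_name or motif_id,
        counts=counts, family=family,
    )


def example_motifs() -> list[MotifCountMatrix]:
    """Three planted-signal archetypes: G-box, W-box and CArG-box consensus."""
    return [
        high_information_pfm(
            "GCCACGTGGC", "SYN_GBOX", "synthetic G-box", family="G-box"
        ),
        high_information_pfm(
            "TTTGACCTTT", "SYN_WBOX", "synthetic W-box", family="W-box"
        ),
        high_information_pfm(
            "CCAAATAAGG", "SYN_CARG", "synthetic CArG-box", family="MADS-box"
        ),
    ]
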