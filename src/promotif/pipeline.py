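"""End-to-end orchestration: scan -> enrich -> fit -> call -> test -> report.

`run_pipeline` wires the stages together and writes every artifact into a
run directory: z-score enrichment tables per gene set, the per-family
archetype choice, the mixture-fit report, BED6 files of called elements,
hypergeometric enrichment and co-occurrence tables, a JSON manifest and a
log.  Given identical inputs, configuration and seed the run directory is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrich import (
    CoOccurrenceRecord,
    EnrichmentRecord,
    co_occurrence,
    enrich_set,
)
from .mixture import call_bona_fide, fit_two_component_em, mixture_report
from .motifs import build_weight_matrix, parse_jaspar_pfm
from .promoters import PromoterUniverse, extract_promoters, read_promoter_fasta
from .scan import ScoreTable, scan_universe, select_archetype, zscore_enrichment
from .tables import read_gene_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and the input."""


@dataclass
class RunConfig:
    """Paths and knobs for a full pipeline run."""

    motifs_path: str
    gene_table_path: str
    promoters_path: str | None = None
    annotation_path: str | None = None
    genome_path: str | None = None
    family_map: dict[str, str] = field(default_factory=dict)
    window: int = 500
    confidence: float = 0.95
    background_mode: str = "uniform"  # or "empirical"
    pseudocount: float | None = None  # None -> 1% of column sum
    seed: int = 0
    out_dir: str = "promotif_run"

    def validate(self) -> None:
        if not (0 < self.confidence < 1):
            raise ValueError("confidence must lie in (0, 1)")
        if self.background_mode not in ("uniform", "empirical"):
            raise ValueError(
                f"unknown background mode {self.background_mode!r}"
            )
        if self.promoters_path is None and (
            self.annotation_path is None or self.genome_path is None
        ):
            raise ValueError(
                "either promoters_path or annotation_path + genome_path "
                "must be given"
            )
        for name in ("motifs_path", "gene_table_path", "promoters_path",
                     "annotation_path", "genome_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} does not exist: {p}")


def empirical_background(universe: PromoterUniverse) -> np.ndarray:
    """Base frequencies over the whole promoter universe (N excluded)."""
    counts = np.zeros(4)
    for rec in universe:
        for i, b in enumerate("ACGT"):
            counts[i] += rec.sequence.count(b)
    if counts.sum() == 0:
        raise ValueError("universe contains no unambiguous bases")
    bg = counts / counts.sum()
    return np.maximum(bg, 1e-6) / np.maximum(bg, 1e-6).sum()


def standardize_expression_rows(
    matrix: pd.DataFrame, scale: bool = False
) -> pd.DataFrame:
    """Mean-center each gene row; optionally divide by the row sd.

    This is the heatmap-display transform: expression standardized with
    respect to each gene's average so replicate groups are comparable.
    Rows with zero spread are left centered (all zeros) and logged.
    """
    if matrix.size == 0:
        raise ValueError("empty expression matrix")
    if matrix.shape[1] < 2:
        raise ValueError("each gene row needs at least 2 samples")
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    centered = matrix.sub(matrix.mean(axis=1), axis=0)
    if not scale:
        return centered
    sd = matrix.std(axis=1, ddof=0)
    flat = sd.index[sd == 0].tolist()
    if flat:
        logger.warning(
            "%d row(s) with zero variance left centered: %s",
            len(flat), flat[:10],
        )
    sd = sd.replace(0, 1.0)
    return centered.div(sd, axis=0)


def write_hits_bed(table: ScoreTable, calls, path) -> None:
    """Write called elements as BED6 (0-based half-open).

    Coordinates are promoter-relative, or genomic when the score table's
    universe carried provenance (handled by the caller passing genomic
    offsets).  Score column is round(1000 * norm_score).
    """
    sub = table.motif_hits(calls.motif_id)
    width = table.widths.get(calls.motif_id)
    if width is None:
        raise ValueError(f"unknown motif width for {calls.motif_id!r}")
    sub = sub[sub["gene_id"].isin(calls.called)].sort_values("gene_id")
    with open(path, "w") as fh:
        for r in sub.itertuples(index=False):
            start = int(r.offset)
            fh.write(
                "\t".join(
                    [
                        r.gene_id,
                        str(start),
                        str(start + width),
                        f"{r.gene_id}|{r.motif_id}",
                        str(int(round(1000 * r.norm_score))),
                        r.strand,
                    ]
                )
                + "\n"
            )


_ZSCORE_COLS = [
    "motif_id", "set_name", "n_set", "mean_set", "mean_pop", "sd_pop",
    "z", "p", "p_adjusted",
]
_HYPERGEOM_COLS = ["motif_id", "set_name", "N", "K", "n", "k", "proportion", "p"]


def write_enrichment_tsv(records, path) -> None:
    """Serialise a homogeneous list of enrichment records, sorted by p."""
    if not records:
        kinds = _HYPERGEOM_COLS
        pd.DataFrame(columns=kinds + ["p_display"]).to_csv(
            path, sep="\t", index=False
        )
        return
    kinds = {type(r).__name__ for r in records}
    if len(kinds) != 1:
        raise ValueError(f"mixed record types: {sorted(kinds)}")
    rows = [asdict(r) for r in records]
    cols = (
        _HYPERGEOM_COLS if isinstance(records[0], EnrichmentRecord)
        else _ZSCORE_COLS
    )
    df = pd.DataFrame(rows)[cols]
    df = df.sort_values(["p", "motif_id"], kind="stable").reset_index(drop=True)
    df["p_display"] = [f"{p:.3g}" for p in df["p"]]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_enrichment_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cooccurrence_tsv(records: list[CoOccurrenceRecord], path) -> None:
    rows = [
        {
            "set_name": r.set_name,
            "family_a": r.family_pair[0],
            "family_b": r.family_pair[1],
            "count": r.count,
            "genes": ",".join(sorted(r.genes)),
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["set_name", "family_a", "family_b", "count", "genes"]
    ).to_csv(path, sep="\t", index=False)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the whole analysis and write artifacts into the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("promotif")
    root.addHandler(handler)
    try:
        return _run_pipeline_inner(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def _run_pipeline_inner(config: RunConfig, out: Path) -> Path:
    pfms = _stage("load_motifs", parse_jaspar_pfm, config.motifs_path)
    family_map = dict(config.family_map) or {
        p.motif_id: (p.family or p.motif_id) for p in pfms
    }
    if config.promoters_path is not None:
        universe = _stage(
            "load_promoters", read_promoter_fasta, config.promoters_path
        )
    else:
        universe = _stage(
            "extract_promoters", extract_promoters,
            config.annotation_path, config.genome_path, window=config.window,
        )
    gene_table = _stage("load_gene_table", read_gene_table,
                        config.gene_table_path)
    sets = {
        d: gene_table.gene_set(d)
        for d in sorted(set(gene_table.rows["direction"]))
    }

    background = (
        empirical_background(universe)
        if config.background_mode == "empirical" else None
    )
    wms = [
        _stage("build_weight_matrix", build_weight_matrix, p,
               background, config.pseudocount)
        for p in pfms
    ]
    table = _stage("scan_universe", scan_universe, wms, universe)

    all_enrichments = []
    for set_name, genes in sets.items():
        enr = _stage(
            f"zscore_enrichment[{set_name}]", zscore_enrichment,
            table, genes, set_name,
        )
        all_enrichments.extend(enr)
        write_enrichment_tsv(enr, out / f"enrichment_zscore_{set_name}.tsv")

    # archetype per family: strongest enrichment across all tested sets
    best_per_motif = {}
    for e in all_enrichments:
        cur = best_per_motif.get(e.motif_id)
        if cur is None or (e.p, e.motif_id) < (cur.p, cur.motif_id):
            best_per_motif[e.motif_id] = e
    archetypes = _stage(
        "select_archetype", select_archetype,
        list(best_per_motif.values()), family_map,
    )
    with open(out / "archetypes.json", "w") as fh:
        json.dump(archetypes, fh, indent=2, sort_keys=True)

    models, calls_list = [], []
    calls_by_family = {}
    for family in sorted(archetypes):
        motif_id = archetypes[family]
        scores = table.norm_scores(motif_id).to_numpy()
        model = _stage(
            f"fit_mixture[{motif_id}]", fit_two_component_em,
            scores, seed=config.seed, motif_id=motif_id,
        )
        calls = _stage(
            f"call_bona_fide[{motif_id}]", call_bona_fide,
            model, table, confidence=config.confidence,
        )
        models.append(model)
        calls_list.append(calls)
        calls_by_family[family] = calls
        write_hits_bed(table, calls, out / f"hits_{family}.bed")
    mixture_report(models, calls_list).to_csv(
        out / "mixture_report.tsv", sep="\t", index=False,
        float_format="%.17g",
    )

    hyper_records = []
    cooc_records = []
    for set_name, genes in sets.items():
        for family in sorted(calls_by_family):
            hyper_records.append(
                _stage(
                    f"enrich_set[{family},{set_name}]", enrich_set,
                    calls_by_family[family], genes, universe, set_name,
                    table,
                )
            )
        if len(calls_by_family) >= 2:
            cooc_records.extend(
                _stage(
                    f"co_occurrence[{set_name}]", co_occurrence,
                    calls_by_family, genes, set_name,
                )
            )
    write_enrichment_tsv(hyper_records, out / "enrichment_hypergeom.tsv")
    write_cooccurrence_tsv(cooc_records, out / "cooccurrence.tsv")

    n_sig = {
        set_name: sum(
            1 for e in all_enrichments
            if e.set_name == set_name and e.p_adjusted < 0.05
        )
        for set_name in sets
    }
    manifest = {
        "promotif_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_promoters": universe.size,
        "n_motifs": len(pfms),
        "archetypes": archetypes,
        "set_sizes": {k: len(v) for k, v in sets.items()},
        "n_families_adjusted_significant": n_sig,
        "bona_fide_counts": {c.motif_id: c.K for c in calls_list},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out)
    return out
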