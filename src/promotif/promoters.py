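"""Promoter records and promoter extraction from genome + annotation.

Promoters are the windows immediately upstream of the transcription start
site (TSS), 500 bp by default, read 5'->3' toward the TSS on the gene's own
strand.  Coordinates are 0-based half-open internally; GFF3 input (1-based
inclusive) is converted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from pyfaidx import Fasta

VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterRecord:
    """One gene's promoter sequence with optional genomic provenance."""

    gene_id: str
    sequence: str
    chrom: str | None = None
    strand: str | None = None
    start: int | None = None  # 0-based half-open genomic interval
    end: int | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence) if c in bad
            )
            raise ValueError(
                f"promoter {self.gene_id!r}: illegal character "
                f"{self.sequence[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PromoterUniverse:
    """The full promoter set scanned genome-wide, keyed by unique gene id."""

    records: dict[str, PromoterRecord] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records) -> "PromoterUniverse":
        out: dict[str, PromoterRecord] = {}
        for rec in records:
            if rec.gene_id in out:
                raise ValueError(f"duplicate gene id {rec.gene_id!r}")
            out[rec.gene_id] = rec
        return cls(records=out)

    @property
    def size(self) -> int:
        return len(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __getitem__(self, gene_id: str) -> PromoterRecord:
        return self.records[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __len__(self) -> int:
        return len(self.records)


_GFF_COLUMNS = [
    "chrom", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


def _read_gff3_genes(path, feature_types=("gene",)) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLUMNS,
        dtype={"chrom": str},
    )
    df = df[df["type"].isin(feature_types)].copy()
    ids = []
    for attrs in df["attributes"]:
        m = re.search(r"(?:^|;)ID=([^;]+)", attrs)
        if m is None:
            m = re.search(r"(?:^|;)Name=([^;]+)", attrs)
        if m is None:
            raise ValueError(f"GFF3 record without ID/Name attribute: {attrs!r}")
        ids.append(m.group(1))
    df["gene_id"] = ids
    # GFF3 is 1-based inclusive -> 0-based half-open
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df[["gene_id", "chrom", "start", "end", "strand"]]


def _read_bed6_genes(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        usecols=range(6), dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df[["gene_id", "chrom", "start", "end", "strand"]]


def extract_promoters(
    annotation_path,
    genome_path,
    window: int = 500,
    annotation_format: str | None = None,
    feature_types=("gene",),
    include_tss_base: bool = False,
) -> PromoterUniverse:
    """Extract the upstream promoter window for every annotated gene.

    For a + strand gene with TSS ``t`` (0-based) the promoter is the genomic
    interval ``[t-window, t)`` clipped at the chromosome start; for a -
    strand gene with TSS ``t`` it is ``[t+1, t+1+window)`` clipped at the
    chromosome end and reverse-complemented, so the returned sequence always
    reads 5'->3' toward the TSS.  ``include_tss_base`` shifts the window by
    one to also cover the TSS base itself.
    """
    fmt = annotation_format
    if fmt is None:
        s = str(annotation_path).lower()
        fmt = "bed" if s.endswith((".bed", ".bed6")) else "gff3"
    if fmt == "gff3":
        genes = _read_gff3_genes(annotation_path, feature_types=feature_types)
    elif fmt == "bed":
        genes = _read_bed6_genes(annotation_path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")

    dup = genes["gene_id"][genes["gene_id"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate gene ids in annotation: {sorted(dup)}")
    bad_strand = set(genes["strand"]) - {"+", "-"}
    if bad_strand:
        raise ValueError(f"invalid strand value(s): {sorted(bad_strand)}")

    genome = Fasta(str(genome_path), as_raw=True, sequence_always_upper=True)
    missing = sorted(set(genes["chrom"]) - set(genome.keys()))
    if missing:
        raise ValueError(
            "gene(s) on chromosome(s) absent from the genome FASTA: "
            + ", ".join(
                genes.loc[genes["chrom"].isin(missing), "gene_id"].tolist()
            )
        )

    records = []
    for row in genes.itertuples(index=False):
        chrom_len = len(genome[row.chrom])
        if row.strand == "+":
            tss = row.start
            hi = tss + (1 if include_tss_base else 0)
            lo = max(0, hi - window)
            hi = min(hi, chrom_len)
            seq = str(genome[row.chrom][lo:hi]) if hi > lo else ""
        else:
            tss = row.end - 1
            lo = tss + (0 if include_tss_base else 1)
            hi = min(chrom_len, lo + window)
            lo = max(0, lo)
            seq = str(genome[row.chrom][lo:hi]) if hi > lo else ""
            seq = reverse_complement(seq)
        records.append(
            PromoterRecord(
                gene_id=row.gene_id, sequence=seq, chrom=row.chrom,
                strand=row.strand, start=lo, end=hi,
            )
        )
    return PromoterUniverse.from_records(records)


def read_promoter_fasta(path) -> PromoterUniverse:
    """Load a promoter FASTA; sequences are upper-cased and validated."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise ValueError(
                f"record {rec.id!r}: illegal character {seq[pos]!r} "
                f"at position {pos}"
            )
        records.append(PromoterRecord(gene_id=rec.id, sequence=seq))
    return PromoterUniverse.from_records(records)


def write_promoter_fasta(universe: PromoterUniverse, path) -> None:
    with open(path, "w") as fh:
        for rec in universe:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")
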