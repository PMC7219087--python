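"""Motif count matrices and their log-odds scoring form.

A motif is stored as a position count matrix (PFM) in the fixed alphabet
order A, C, G, T — one row per base, one column per motif position — as
printed in JASPAR flat files.  Scoring uses the standard log2-odds
transformation with a pseudocount spread according to the background base
composition:

    w[b, j] = log2( (c[b, j] + s_j * q_b) / (colsum_j + s_j) / q_b )

where ``q`` is the background distribution and ``s_j`` the pseudocount mass
added to column ``j``.  With the default pseudocount (1% of the column sum)
sparse JASPAR counts never produce infinite weights.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as _bio_motifs

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class MotifParseError(ValueError):
    """Raised when a motif file block violates the PFM contract."""


@dataclass
class MotifCountMatrix:
    """A position count matrix in A, C, G, T row order."""

    motif_id: str
    motif_name: str
    counts: np.ndarray  # shape (4, L)
    family: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise MotifParseError(
                f"motif {self.motif_id!r}: counts must be a 4xL matrix, "
                f"got shape {self.counts.shape}"
            )
        if self.counts.shape[1] < 1:
            raise MotifParseError(f"motif {self.motif_id!r}: zero-width matrix")
        if not np.all(np.isfinite(self.counts)):
            raise MotifParseError(f"motif {self.motif_id!r}: non-finite count")
        if np.any(self.counts < 0):
            raise MotifParseError(f"motif {self.motif_id!r}: negative count")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise MotifParseError(
                f"motif {self.motif_id!r}: a column has zero total count"
            )

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        """Most-frequent base per column (ties to the earlier base in ACGT)."""
        return "".join(ALPHABET[i] for i in np.argmax(self.counts, axis=0))

    def probabilities(self, background=None, pseudocount=None) -> np.ndarray:
        """Pseudocounted per-column base probabilities (columns sum to 1)."""
        bg = _validate_background(background)
        colsum = self.counts.sum(axis=0)
        s = _resolve_pseudocount(pseudocount, colsum)
        return (self.counts + s * bg[:, None]) / (colsum + s)


@dataclass
class WeightMatrix:
    """Log2-odds scoring matrix derived from a :class:`MotifCountMatrix`."""

    motif_id: str
    weights: np.ndarray  # shape (4, L)
    background: np.ndarray  # shape (4,)
    pseudocount: np.ndarray  # per-column pseudocount mass, shape (L,)
    motif_name: str = ""
    family: str | None = None
    min_score: float = field(init=False)
    max_score: float = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError(f"motif {self.motif_id!r}: non-finite weights")
        _validate_background(self.background)
        self.min_score = float(self.weights.min(axis=0).sum())
        self.max_score = float(self.weights.max(axis=0).sum())

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.weights, axis=0))


def _validate_background(background) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,):
        raise ValueError("background must be a 4-vector over A,C,G,T")
    if np.any(bg <= 0):
        raise ValueError("background frequencies must all be positive")
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError(f"background must sum to 1 (got {bg.sum()!r})")
    return bg


def _resolve_pseudocount(pseudocount, colsum: np.ndarray) -> np.ndarray:
    """Default pseudocount: 1% of each column's total count."""
    if pseudocount is None:
        return 0.01 * np.asarray(colsum, dtype=float)
    s = np.broadcast_to(np.asarray(pseudocount, dtype=float), colsum.shape).copy()
    if np.any(s < 0):
        raise ValueError("pseudocount must be non-negative")
    return s


def build_weight_matrix(
    pfm: MotifCountMatrix,
    background=None,
    pseudocount=None,
) -> WeightMatrix:
    """Convert a count matrix into its log2-odds scoring form.

    A zero pseudocount is rejected whenever any count is zero, because it
    would produce ``-inf`` weights.
    """
    bg = _validate_background(background)
    colsum = pfm.counts.sum(axis=0)
    s = _resolve_pseudocount(pseudocount, colsum)
    zero_cols = (s == 0) & (pfm.counts == 0).any(axis=0)
    if np.any(zero_cols):
        raise ValueError(
            f"motif {pfm.motif_id!r}: zero pseudocount with zero counts in "
            f"column(s) {np.nonzero(zero_cols)[0].tolist()} would give "
            "-inf weights; use a positive pseudocount"
        )
    probs = (pfm.counts + s * bg[:, None]) / (colsum + s)
    weights = np.log2(probs / bg[:, None])
    return WeightMatrix(
        motif_id=pfm.motif_id,
        weights=weights,
        background=bg,
        pseudocount=s,
        motif_name=pfm.motif_name,
        family=pfm.family,
    )


def _split_jaspar_blocks(text: str) -> list[tuple[str, str]]:
    """Split a JASPAR flat file into (header_id, block_text) pairs."""
    blocks: list[tuple[str, str]] = []
    current: list[str] | None = None
    header = ""
    for line in text.splitlines():
        if line.startswith(">"):
            if current is not None:
                blocks.append((header, "\n".join(current) + "\n"))
            header = line[1:].split()[0] if line[1:].split() else "<unnamed>"
            current = [line]
        elif line.strip():
            if current is None:
                raise MotifParseError(
                    "matrix rows found before any '>' header line"
                )
            current.append(line)
    if current is not None:
        blocks.append((header, "\n".join(current) + "\n"))
    return blocks


def parse_jaspar_pfm(path) -> list[MotifCountMatrix]:
    """Read JASPAR-format count matrices from a flat file.

    Each block has a ``>ID name`` header followed by four labelled rows
    (``A [ ... ]`` etc., brackets optional).  Rows are reordered to
    A, C, G, T regardless of file order.  Malformed blocks raise
    :class:`MotifParseError` naming the offending motif id.
    """
    with open(path) as fh:
        text = fh.read()
    result: list[MotifCountMatrix] = []
    for motif_id, block in _split_jaspar_blocks(text):
        row_lines = [ln for ln in block.splitlines()[1:] if ln.strip()]
        if len(row_lines) != 4:
            raise MotifParseError(
                f"motif {motif_id!r}: expected 4 base rows, got {len(row_lines)}"
            )
        try:
            parsed = _bio_motifs.parse(io.StringIO(block), "jaspar")
        except Exception as exc:
            raise MotifParseError(f"motif {motif_id!r}: {exc}") from exc
        if len(parsed) != 1:
            raise MotifParseError(f"motif {motif_id!r}: unparseable block")
        m = parsed[0]
        counts = np.array([m.counts[b] for b in ALPHABET], dtype=float)
        name = m.name or ""
        try:
            result.append(
                MotifCountMatrix(
                    motif_id=m.matrix_id or motif_id,
                    motif_name=name,
                    counts=counts,
                )
            )
        except MotifParseError:
            raise
    return result


def write_jaspar_pfm(pfms: list[MotifCountMatrix], path) -> None:
    """Write count matrices back out in JASPAR flat format."""
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.motif_id} {pfm.motif_name}\n")
            for i, base in enumerate(ALPHABET):
                row = " ".join(_fmt_count(v) for v in pfm.counts[i])
                fh.write(f"{base} [ {row} ]\n")


def _fmt_count(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def information_content(pfm: MotifCountMatrix, pseudocount=None) -> float:
    """Total information content in bits against a uniform background."""
    p = pfm.probabilities(pseudocount=pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(p > 0, -p * np.log2(p), 0.0).sum(axis=0)
    return float((2.0 - h).sum())


def reverse_complement_matrix(counts: np.ndarray) -> np.ndarray:
    """Reverse-complement a 4xL matrix (rows A,C,G,T): flip rows and columns."""
    return counts[::-1, ::-1].copy()
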