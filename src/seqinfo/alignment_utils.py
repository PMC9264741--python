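"""Pairwise distance/identity matrices and column stripping for alignments.

Operates on already-aligned multi-FASTA input (no alignment is
constructed here and no evolutionary distance correction is applied).
Comparisons are case-insensitive and literal: a gap character versus a
base counts as one difference, exactly like a base-versus-base mismatch.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

import numpy as np

from .formats import SequenceRecord, read_fasta, write_fasta

__all__ = [
    "Alignment",
    "DistanceMatrices",
    "RaggedAlignmentError",
    "EmptyAlignmentError",
    "DegenerateAlignmentError",
    "load_alignment",
    "count_differences",
    "remove_char_columns",
    "write_matrices",
]


class RaggedAlignmentError(ValueError):
    """Records in the input do not all have the same length."""


class EmptyAlignmentError(ValueError):
    """The input contains no records."""


class DegenerateAlignmentError(ValueError):
    """Matrix operations need >= 2 records and >= 1 column."""


@dataclass(frozen=True)
class Alignment:
    """An equal-length set of sequence records."""

    records: tuple[SequenceRecord, ...]
    n_columns: int

    @staticmethod
    def from_records(records: Sequence[SequenceRecord]) -> "Alignment":
        if not records:
            raise EmptyAlignmentError("alignment contains no records")
        n = len(records[0].sequence)
        for rec in records:
            if len(rec.sequence) != n:
                raise RaggedAlignmentError(
                    f"record {rec.identifier!r} has length {len(rec.sequence)},"
                    f" expected {n}"
                )
        return Alignment(records=tuple(records), n_columns=n)


@dataclass(frozen=True)
class DistanceMatrices:
    """Pairwise difference counts (bp) and percent identity.

    Both matrices are symmetric with zero (differences) and 100
    (identity) diagonals; labels follow input record order.
    """

    labels: tuple[str, ...]
    differences: np.ndarray  # (n, n) int
    identity_pct: np.ndarray  # (n, n) float


def load_alignment(source: str | Path | IO) -> Alignment:
    """Read an aligned multi-FASTA file, validating equal lengths."""
    return Alignment.from_records(read_fasta(source))


def _char_matrix(aln: Alignment) -> np.ndarray:
    # uppercase byte matrix, one row per record
    rows = [
        np.frombuffer(rec.sequence.upper().encode("ascii"), dtype="S1")
        for rec in aln.records
    ]
    return np.vstack(rows) if rows else np.empty((0, 0), dtype="S1")


def count_differences(aln: Alignment, ignore_gap_columns: bool = False) -> DistanceMatrices:
    """Pairwise difference and percent-identity matrices for an alignment.

    ``differences[i, j]`` is the number of columns where the uppercased
    characters of records i and j differ; gaps and ambiguity codes are
    compared literally as characters.  Identity is
    ``(n_columns - differences) / n_columns * 100``.

    With ``ignore_gap_columns=True``, columns where either member of a
    pair carries '-' are excluded from that pair's comparison and the
    identity denominator becomes the number of compared columns (100.0
    when a pair shares no gap-free column).
    """
    if len(aln.records) < 2:
        raise DegenerateAlignmentError("need at least two records")
    if aln.n_columns == 0:
        raise DegenerateAlignmentError("alignment has zero columns")
    chars = _char_matrix(aln)
    n = len(aln.records)
    diffs = np.zeros((n, n), dtype=int)
    ident = np.full((n, n), 100.0)
    gap = chars == b"-"
    for i in range(n):
        for j in range(i + 1, n):
            mismatch = chars[i] != chars[j]
            if ignore_gap_columns:
                keep = ~(gap[i] | gap[j])
                d = int(np.count_nonzero(mismatch & keep))
                denom = int(np.count_nonzero(keep))
            else:
                d = int(np.count_nonzero(mismatch))
                denom = aln.n_columns
            diffs[i, j] = diffs[j, i] = d
            pct = 100.0 if denom == 0 else (denom - d) / denom * 100.0
            ident[i, j] = ident[j, i] = pct
    labels = tuple(rec.identifier for rec in aln.records)
    return DistanceMatrices(labels=labels, differences=diffs, identity_pct=ident)


def remove_char_columns(aln: Alignment, char: str) -> Alignment:
    """Drop every column where ``char`` occurs in ANY record.

    Case-insensitive; surviving columns keep their order and content, so
    the operation is a pure column projection and is idempotent.  The
    result may have zero columns.
    """
    if len(char) != 1:
        raise ValueError("char must be a single character")
    if not aln.records:
        raise EmptyAlignmentError("alignment contains no records")
    if aln.n_columns == 0:
        return aln
    chars = _char_matrix(aln)
    target = char.upper().encode("ascii")
    keep = ~np.any(chars == target, axis=0)
    new_records = []
    for rec in aln.records:
        arr = np.frombuffer(rec.sequence.encode("ascii"), dtype="S1")
        seq = arr[keep].tobytes().decode("ascii")
        new_records.append(
            SequenceRecord(rec.identifier, rec.description, seq)
        )
    return Alignment(records=tuple(new_records), n_columns=int(keep.sum()))


def write_matrices(dm: DistanceMatrices, out_dir: str | Path) -> tuple[Path, Path]:
    """Write differences.tsv and percentage_identity.tsv under ``out_dir``.

    Both files carry the record identifiers as header row and first
    column; identity is reported to 2 decimals.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    diff_path = out / "differences.tsv"
    ident_path = out / "percentage_identity.tsv"

    def render(matrix: np.ndarray, fmt) -> str:
        buf = io.StringIO()
        buf.write("\t".join(("",) + dm.labels) + "\n")
        for label, row in zip(dm.labels, matrix):
            buf.write(label + "\t" + "\t".join(fmt(v) for v in row) + "\n")
        return buf.getvalue()

    diff_path.write_text(render(dm.differences, lambda v: str(int(v))))
    ident_path.write_text(render(dm.identity_pct, lambda v: f"{v:.2f}"))
    return diff_path, ident_path
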