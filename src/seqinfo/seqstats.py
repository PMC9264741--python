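"""Nucleotide composition statistics and the NucleScore.

The NucleScore is an empirical, composition-only summary of a genome
assembly intended to band assemblies by species without a reference
genome::

    NucleScore = log2( Var * GC% * (AT/GC)^3 / sqrt(length) )

where ``Var`` is the variance of the four per-nucleotide percentages
(A%, T%, G%, C%), ``GC%`` the GC content in percent, ``AT/GC`` the ratio
(A+T)/(G+C), and ``length`` the total assembly size in bases (including
ambiguous characters such as N).

All composition metrics (GC%, AT/GC, nuc%) use only the unambiguous
A/C/G/T tallies in numerator and denominator; ambiguous characters are
counted separately and contribute only to ``length``.  Metrics that are
mathematically undefined on a given input (G+C = 0, or a non-positive
log argument) are carried as ``None`` rather than raised, so batch
reports over many assemblies never abort; reports render them as "NA".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "NucleotideCounts",
    "CompositionStats",
    "NoUnambiguousNucleotidesError",
    "count_nucleotides",
    "merge_counts",
    "gc_content",
    "at_gc_ratio",
    "nuc_percentages",
    "nuc_variance",
    "nucle_score",
    "stats_from_counts",
    "composition_stats",
    "composition_table",
]

#: Delta degrees of freedom for the variance of the four nuc% values.
#: 0 = population variance (divide by 4): the four percentages are the
#: entire population of interest, not a sample from one.  Flip to 1 for
#: the sample (divide by 3) convention.
VARIANCE_DDOF: int = 0

#: Decimal places used when formatting metric values in TSV reports.
REPORT_PRECISION: int = 3


class NoUnambiguousNucleotidesError(ValueError):
    """Raised when a metric is requested for counts with A+T+G+C == 0."""


@dataclass(frozen=True)
class NucleotideCounts:
    """Raw A/T/G/C/ambiguity tallies for one sequence or an aggregate.

    ``ambiguous`` counts every non-whitespace character outside
    {A, C, G, T} after uppercasing (N, IUPAC codes, U, gaps, ...).
    """

    a: int = 0
    t: int = 0
    g: int = 0
    c: int = 0
    ambiguous: int = 0

    def __post_init__(self) -> None:
        for name in ("a", "t", "g", "c", "ambiguous"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count for {name!r}")

    @property
    def acgt_total(self) -> int:
        """Number of unambiguous nucleotides (A+T+G+C)."""
        return self.a + self.t + self.g + self.c

    @property
    def total_length(self) -> int:
        """Total size in characters, ambiguous included."""
        return self.acgt_total + self.ambiguous


@dataclass(frozen=True)
class CompositionStats:
    """The five derived composition metrics for one sequence set.

    ``at_gc_ratio`` and ``nucle_score`` are ``None`` when undefined
    (G+C = 0, or log argument <= 0).
    """

    gc_content: float
    at_gc_ratio: float | None
    nuc_pct: tuple[float, float, float, float]  # (A%, T%, G%, C%)
    variance: float
    nucle_score: float | None
    acgt_total: int
    total_length: int


def count_nucleotides(sequence: str) -> NucleotideCounts:
    """Tally nucleotides in ``sequence``, case-insensitively.

    Whitespace (spaces, newlines) is ignored; every other character not
    in {A, C, G, T} increments the ambiguous count.  The empty sequence
    yields all-zero counts.
    """
    s = "".join(sequence.split()).upper()
    a = s.count("A")
    c = s.count("C")
    g = s.count("G")
    t = s.count("T")
    return NucleotideCounts(a=a, t=t, g=g, c=c, ambiguous=len(s) - (a + c + g + t))


def merge_counts(parts: Iterable[NucleotideCounts]) -> NucleotideCounts:
    """Field-wise sum of counts; the empty iterable yields zero counts."""
    a = t = g = c = amb = 0
    for p in parts:
        a += p.a
        t += p.t
        g += p.g
        c += p.c
        amb += p.ambiguous
    return NucleotideCounts(a=a, t=t, g=g, c=c, ambiguous=amb)


def _require_acgt(counts: NucleotideCounts) -> int:
    total = counts.acgt_total
    if total == 0:
        raise NoUnambiguousNucleotidesError(
            "no unambiguous nucleotides (A+T+G+C == 0)"
        )
    return total


def gc_content(counts: NucleotideCounts) -> float:
    """GC content in percent: (G+C)/(A+T+C+G) * 100."""
    return (counts.g + counts.c) / _require_acgt(counts) * 100.0


def at_gc_ratio(counts: NucleotideCounts) -> float | None:
    """(A+T)/(G+C), or ``None`` when G+C == 0."""
    _require_acgt(counts)
    gc = counts.g + counts.c
    if gc == 0:
        return None
    return (counts.a + counts.t) / gc


def nuc_percentages(counts: NucleotideCounts) -> tuple[float, float, float, float]:
    """Per-nucleotide percentages (A%, T%, G%, C%) over A+T+C+G."""
    total = _require_acgt(counts)
    return (
        counts.a / total * 100.0,
        counts.t / total * 100.0,
        counts.g / total * 100.0,
        counts.c / total * 100.0,
    )


def nuc_variance(nuc_pct: Sequence[float]) -> float:
    """Variance of the four nuc% values (population variance by default)."""
    if len(nuc_pct) != 4:
        raise ValueError("expected exactly four nucleotide percentages")
    mean = sum(nuc_pct) / 4.0
    ss = sum((p - mean) ** 2 for p in nuc_pct)
    return ss / (4 - VARIANCE_DDOF)


def nucle_score(counts: NucleotideCounts) -> float | None:
    """log2(Var * GC% * (AT/GC)^3 / sqrt(total_length)), or ``None``.

    ``total_length`` includes ambiguous characters (the assembly's total
    size).  Undefined when the AT/GC ratio is undefined or the log
    argument is non-positive (e.g. Var == 0 for perfectly uniform
    composition).
    """
    ratio = at_gc_ratio(counts)
    if ratio is None:
        return None
    gc = gc_content(counts)
    var = nuc_variance(nuc_percentages(counts))
    arg = var * gc * ratio**3 / math.sqrt(counts.total_length)
    if arg <= 0.0:
        return None
    return math.log2(arg)


def stats_from_counts(counts: NucleotideCounts) -> CompositionStats:
    """Bundle all five metrics for one set of counts."""
    pct = nuc_percentages(counts)
    return CompositionStats(
        gc_content=gc_content(counts),
        at_gc_ratio=at_gc_ratio(counts),
        nuc_pct=pct,
        variance=nuc_variance(pct),
        nucle_score=nucle_score(counts),
        acgt_total=counts.acgt_total,
        total_length=counts.total_length,
    )


def _sequence_of(record: object) -> str:
    # accept plain strings or anything with a .sequence attribute
    if isinstance(record, str):
        return record
    seq = getattr(record, "sequence", None)
    if seq is None:
        # Biopython SeqRecord compatibility
        seq = getattr(record, "seq", None)
    if seq is None:
        raise TypeError(f"cannot extract a sequence from {type(record).__name__}")
    return str(seq)


def composition_stats(
    records: Iterable[object], per_record: bool = False
) -> CompositionStats | tuple[CompositionStats, list[CompositionStats | None]]:
    """Aggregate composition statistics over a set of sequence records.

    The aggregate is computed on the merged counts of all records, so it
    is invariant under re-partitioning of an assembly into records.
    With ``per_record=True`` returns ``(aggregate, per_record_list)``
    where records with zero unambiguous nucleotides contribute ``None``
    entries instead of aborting the batch.
    """
    seqs = [_sequence_of(r) for r in records]
    if not seqs:
        raise ValueError("no sequence records given")
    counts = [count_nucleotides(s) for s in seqs]
    aggregate = stats_from_counts(merge_counts(counts))
    if not per_record:
        return aggregate
    per: list[CompositionStats | None] = []
    for cn in counts:
        try:
            per.append(stats_from_counts(cn))
        except NoUnambiguousNucleotidesError:
            per.append(None)
    return aggregate, per


# --- TSV report over FASTA files ------------------------------------------

_TABLE_COLUMNS = [
    "file", "n_records", "length", "A", "T", "G", "C", "ambiguous",
    "A%", "T%", "G%", "C%", "GC%", "AT/GC", "variance", "NucleScore",
]


def _fmt(value: float | None, precision: int = REPORT_PRECISION) -> str:
    if value is None:
        return "NA"
    return f"{value:.{precision}f}"


def composition_table(paths: Iterable[str], per_record: bool = False) -> str:
    """One TSV row of composition metrics per FASTA file.

    With ``per_record=True`` an extra row per sequence record is emitted,
    labelled ``<file>:<record id>``.  Undefined metrics render as "NA";
    the dialect is tab-separated with UNIX line endings.
    """
    from . import formats  # local import: formats depends on nothing here

    lines = ["\t".join(_TABLE_COLUMNS)]

    def row(label: str, n_records: int, counts: NucleotideCounts) -> str:
        try:
            st: CompositionStats | None = stats_from_counts(counts)
        except NoUnambiguousNucleotidesError:
            st = None
        cells = [
            label, str(n_records), str(counts.total_length),
            str(counts.a), str(counts.t), str(counts.g), str(counts.c),
            str(counts.ambiguous),
        ]
        if st is None:
            cells += ["NA"] * 8
        else:
            cells += [_fmt(p) for p in st.nuc_pct]
            cells += [_fmt(st.gc_content), _fmt(st.at_gc_ratio),
                      _fmt(st.variance), _fmt(st.nucle_score)]
        return "\t".join(cells)

    for path in paths:
        records = formats.read_fasta(path)
        counts = [count_nucleotides(r.sequence) for r in records]
        lines.append(row(str(path), len(records), merge_counts(counts)))
        if per_record:
            for rec, cn in zip(records, counts):
                lines.append(row(f"{path}:{rec.identifier}", 1, cn))
    return "\n".join(lines) + "\n"
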