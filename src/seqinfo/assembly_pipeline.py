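"""Assembly query filtering, component separation and report building.

The pipeline ties the other modules together: filter an NCBI assembly
index by species/taxid/date/level, download each matching assembly's
FASTA and GenBank files, split the records into chromosome/plasmid/other
folders, and emit a per-assembly report joining composition statistics
with mined metadata.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import repo_client
from .formats import (
    AssemblyMetadata,
    AssemblySummaryRow,
    SequenceRecord,
    parse_assembly_summary,
    parse_genbank_metadata,
    read_fasta,
    summarize_metadata,
    write_fasta,
)
from .seqstats import (
    CompositionStats,
    NoUnambiguousNucleotidesError,
    count_nucleotides,
    merge_counts,
    stats_from_counts,
)

__all__ = [
    "ComponentClass",
    "AssemblyQuery",
    "AssemblyReportRow",
    "filter_assemblies",
    "classify_component",
    "separate_components",
    "build_report",
    "render_report",
    "run_fetch",
]

log = logging.getLogger("seqinfo")

ASSEMBLY_LEVELS = ("Complete Genome", "Chromosome", "Scaffold", "Contig")


class ComponentClass(str, Enum):
    """Exhaustive, mutually exclusive classification of assembly records."""

    CHROMOSOME = "chromosome"
    PLASMID = "plasmid"
    OTHER = "other"


@dataclass(frozen=True)
class AssemblyQuery:
    """Filter criteria over an assembly index; filters compose as AND."""

    section: str = "refseq"
    kingdom: str = "bacteria"
    species_pattern: str | None = None
    taxid: int | None = None
    min_release_date: date | None = None
    level: str | None = None
    limit: int | None = None
    components: frozenset[ComponentClass] | None = None
    exact_species: bool = False

    def __post_init__(self) -> None:
        if self.limit is not None and self.limit < 1:
            raise ValueError("limit must be >= 1 when present")


def filter_assemblies(
    rows: Iterable[AssemblySummaryRow], query: AssemblyQuery
) -> list[AssemblySummaryRow]:
    """Apply the query's filters conjunctively, then sort and truncate.

    Species matching is a case-insensitive substring match on the
    organism name (exact match with ``exact_species``); a taxid matches
    either the row taxid or species taxid; the date filter is inclusive
    (rows released ON the given date are kept) and drops rows whose date
    failed to parse; level must match exactly.  Survivors are stable
    sorted by accession, then truncated to ``limit``.
    """
    kept = []
    for row in rows:
        if query.species_pattern is not None:
            pat = query.species_pattern.lower()
            name = row.organism_name.lower()
            if query.exact_species:
                if name != pat:
                    continue
            elif pat not in name:
                continue
        if query.taxid is not None:
            if query.taxid not in (row.taxid, row.species_taxid):
                continue
        if query.min_release_date is not None:
            if row.seq_rel_date is None or row.seq_rel_date < query.min_release_date:
                continue
        if query.level is not None and row.assembly_level != query.level:
            continue
        kept.append(row)
    kept.sort(key=lambda r: r.assembly_accession)
    if query.limit is not None:
        kept = kept[: query.limit]
    return kept


def classify_component(description: str) -> ComponentClass:
    """Classify a FASTA header as chromosome, plasmid or other.

    Case-insensitive keyword rules, plasmid first (plasmid headers
    routinely also say "complete sequence"/"complete genome"):
    "plasmid" -> plasmid; else "chromosome" or "complete genome" ->
    chromosome; else other.
    """
    d = description.lower()
    if "plasmid" in d:
        return ComponentClass.PLASMID
    if "chromosome" in d or "complete genome" in d:
        return ComponentClass.CHROMOSOME
    return ComponentClass.OTHER


def separate_components(
    records: Sequence[SequenceRecord],
    out_dir: str | Path | None = None,
    classes_wanted: Iterable[ComponentClass] | None = None,
) -> dict[ComponentClass, list[SequenceRecord]]:
    """Partition records by component class; optionally write per-class FASTA.

    Every record lands in exactly one class, in input order.  When
    ``out_dir`` is given, one ``<class>/<class>.fasta`` file is written
    for each non-empty class intersected with ``classes_wanted`` (all
    classes when absent).
    """
    wanted = set(classes_wanted) if classes_wanted is not None else set(ComponentClass)
    groups: dict[ComponentClass, list[SequenceRecord]] = {
        cls: [] for cls in ComponentClass
    }
    for rec in records:
        groups[classify_component(rec.description)].append(rec)
    if out_dir is not None:
        base = Path(out_dir)
        for cls, recs in groups.items():
            if recs and cls in wanted:
                folder = base / cls.value
                folder.mkdir(parents=True, exist_ok=True)
                (folder / f"{cls.value}.fasta").write_bytes(write_fasta(recs))
    return groups


# --- report ------------------------------------------------------------------

REPORT_COLUMNS = [
    "assembly_accession", "organism_name", "assembly_level", "release_date",
    "n_records", "n_chromosome", "n_plasmid", "n_other",
    "length", "A", "T", "G", "C", "ambiguous",
    "A%", "T%", "G%", "C%", "GC%", "AT/GC", "variance", "NucleScore",
    "strain", "country", "host", "isolation_source", "collection_date",
    "pubmed_ids", "definition",
]


@dataclass(frozen=True)
class AssemblyReportRow:
    """One report row: composition statistics joined with metadata."""

    cells: tuple[str, ...]  # formatted values, aligned with REPORT_COLUMNS

    @property
    def accession(self) -> str:
        return self.cells[0]


def _fmt_float(value: float | None, precision: int = 3) -> str:
    return "NA" if value is None else f"{value:.{precision}f}"


def build_report(
    stats: CompositionStats | None,
    metadata: AssemblyMetadata | None,
    summary_row: AssemblySummaryRow,
    component_counts: Mapping[ComponentClass, int] | None = None,
    raw_counts=None,
) -> AssemblyReportRow:
    """Join statistics, metadata and index fields into one report row.

    Missing metadata or undefined metrics render as "NA".  A mismatch
    between the metadata accession and the index accession is warned
    about, never fatal (RefSeq assemblies legitimately wrap GenBank
    records).
    """
    if (
        metadata is not None
        and metadata.accession
        and not summary_row.assembly_accession.startswith(metadata.accession)
        and metadata.accession.split(".")[0]
        not in summary_row.assembly_accession
    ):
        warnings.warn(
            f"metadata accession {metadata.accession!r} does not match assembly"
            f" {summary_row.assembly_accession!r}",
            stacklevel=2,
        )
    counts = component_counts or {}
    n_chrom = counts.get(ComponentClass.CHROMOSOME, 0)
    n_plasmid = counts.get(ComponentClass.PLASMID, 0)
    n_other = counts.get(ComponentClass.OTHER, 0)

    cells: list[str] = [
        summary_row.assembly_accession,
        summary_row.organism_name,
        summary_row.assembly_level,
        summary_row.seq_rel_date.isoformat() if summary_row.seq_rel_date else "NA",
        str(n_chrom + n_plasmid + n_other),
        str(n_chrom), str(n_plasmid), str(n_other),
    ]
    if stats is None:
        cells += ["NA"] * 14
    else:
        if raw_counts is not None:
            cells += [
                str(raw_counts.total_length), str(raw_counts.a), str(raw_counts.t),
                str(raw_counts.g), str(raw_counts.c), str(raw_counts.ambiguous),
            ]
        else:
            cells += [str(stats.total_length)] + ["NA"] * 5
        cells += [_fmt_float(p) for p in stats.nuc_pct]
        cells += [
            _fmt_float(stats.gc_content),
            _fmt_float(stats.at_gc_ratio),
            _fmt_float(stats.variance),
            _fmt_float(stats.nucle_score),
        ]
    if metadata is None:
        cells += ["NA"] * 7
    else:
        cells += [
            metadata.strain or "NA",
            metadata.country or "NA",
            metadata.host or "NA",
            metadata.isolation_source or "NA",
            metadata.collection_date or "NA",
            ";".join(str(p) for p in metadata.pubmed_ids) or "NA",
            metadata.definition or "NA",
        ]
    assert len(cells) == len(REPORT_COLUMNS)
    return AssemblyReportRow(cells=tuple(cells))


def render_report(rows: Sequence[AssemblyReportRow], format: str = "tsv") -> bytes:
    """Render report rows as TSV or a self-contained HTML table.

    Cell values are identical across formats; TSV is tab-separated with
    a header row, "NA" for missing values and UNIX line endings.
    """
    if format == "tsv":
        lines = ["\t".join(REPORT_COLUMNS)]
        lines += ["\t".join(row.cells) for row in rows]
        return ("\n".join(lines) + "\n").encode("utf-8")
    if format == "html":
        df = pd.DataFrame([row.cells for row in rows], columns=REPORT_COLUMNS)
        table = df.to_html(index=False, border=1)
        doc = (
            "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
            "<title>Assembly report</title></head>\n<body>\n"
            f"{table}\n</body></html>\n"
        )
        return doc.encode("utf-8")
    raise ValueError(f"unknown report format {format!r}")


# --- orchestration -----------------------------------------------------------

_FINAL_NAMES = {
    "genomic_fasta": ("assembly.fna", True),
    "genomic_genbank": ("assembly.gbff", True),
    "assembly_report": ("assembly_report.txt", False),
}


def run_fetch(
    query: AssemblyQuery,
    out_root: str | Path,
    transport: repo_client.Transport,
    endpoints: repo_client.EndpointConfig = repo_client.DEFAULT_ENDPOINTS,
    summary_source: str | Path | None = None,
) -> list[AssemblyReportRow]:
    """Fetch, filter, download, separate and report matching assemblies.

    ``summary_source`` short-circuits the index download with a local
    assembly_summary file.  The output tree is
    ``<out>/<accession>/{assembly.fna, assembly.gbff, assembly_report.txt,
    components/<class>/<class>.fasta, report.tsv}`` plus combined
    ``report.tsv`` and ``report.html`` at the top level.
    """
    out = Path(out_root)
    out.mkdir(parents=True, exist_ok=True)
    if summary_source is not None:
        rows = parse_assembly_summary(summary_source)
    else:
        url = repo_client.build_assembly_summary_url(
            query.section, query.kingdom, endpoints
        )
        rows = parse_assembly_summary(io.BytesIO(transport.fetch(url)))
    log.info("index: %d assemblies", len(rows))
    selected = filter_assemblies(rows, query)
    log.info("matching query: %d assemblies", len(selected))

    report_rows: list[AssemblyReportRow] = []
    for row in selected:
        acc_dir = out / row.assembly_accession
        if not row.downloadable:
            log.warning("skipping %s: no FTP path", row.assembly_accession)
            report_rows.append(build_report(None, None, row))
            continue
        plans = repo_client.build_assembly_file_urls(row)
        local: dict[str, Path] = {}
        for plan in plans:
            name, decompress = _FINAL_NAMES[plan.kind]
            final = repo_client.plan_with_destination(
                plan, f"{row.assembly_accession}/{name}", decompress=decompress
            )
            local[plan.kind] = repo_client.execute_plan(final, transport, out)
        records = read_fasta(local["genomic_fasta"])
        groups = separate_components(
            records, acc_dir / "components", query.components
        )
        comp_counts = {cls: len(recs) for cls, recs in groups.items()}
        try:
            raw = merge_counts(count_nucleotides(r.sequence) for r in records)
            stats = stats_from_counts(raw)
        except (NoUnambiguousNucleotidesError, ValueError):
            raw = None
            stats = None
        try:
            meta = summarize_metadata(parse_genbank_metadata(local["genomic_genbank"]))
        except Exception as exc:  # metadata is best-effort, never fatal
            log.warning("no metadata for %s: %s", row.assembly_accession, exc)
            meta = None
        report_row = build_report(stats, meta, row, comp_counts, raw_counts=raw)
        report_rows.append(report_row)
        (acc_dir / "report.tsv").write_bytes(render_report([report_row]))

    report_rows.sort(key=lambda r: r.accession)
    (out / "report.tsv").write_bytes(render_report(report_rows, "tsv"))
    (out / "report.html").write_bytes(render_report(report_rows, "html"))
    log.info("wrote %d report rows", len(report_rows))
    return report_rows
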