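"""Readers and writers for the formats the suite touches.

FASTA (plain or gzip), GenBank flat files (.gb/.gbk/.gbff, plain or
gzip) and NCBI ``assembly_summary.txt`` index files.  GenBank and FASTA
parsing is delegated to Biopython; the assembly-summary dialect (tab
separated, '#' comment lines, column names on the last comment line) is
parsed here by column NAME so it survives NCBI layout changes.
"""

from __future__ import annotations

import csv
import gzip
import io
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import IO, Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "AssemblySummaryRow",
    "AssemblyMetadata",
    "MalformedFastaError",
    "MalformedIndexError",
    "MalformedGenBankError",
    "read_fasta",
    "write_fasta",
    "parse_assembly_summary",
    "parse_genbank_metadata",
    "summarize_metadata",
]


class MalformedFastaError(ValueError):
    """Input is not FASTA (first non-blank line does not start with '>')."""


class MalformedIndexError(ValueError):
    """Assembly index is missing required columns."""


class MalformedGenBankError(ValueError):
    """No LOCUS..// entry could be parsed from the input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: id (first header token), full header, sequence."""

    identifier: str
    description: str
    sequence: str


@dataclass(frozen=True)
class AssemblySummaryRow:
    """One record of NCBI's assembly_summary index."""

    assembly_accession: str
    organism_name: str
    taxid: int
    species_taxid: int
    assembly_level: str
    seq_rel_date: date | None
    ftp_path: str
    refseq_category: str = ""
    asm_name: str = ""

    @property
    def downloadable(self) -> bool:
        """False when NCBI lists no FTP path for the assembly."""
        return self.ftp_path.lower() not in ("", "na")


@dataclass(frozen=True)
class AssemblyMetadata:
    """Provenance fields mined from a GenBank flat-file entry."""

    accession: str
    organism: str
    definition: str
    strain: str | None = None
    country: str | None = None
    host: str | None = None
    isolation_source: str | None = None
    collection_date: str | None = None
    pubmed_ids: tuple[int, ...] = field(default_factory=tuple)


# --- stream plumbing --------------------------------------------------------

def _open_text(source: str | Path | IO, gz_allowed: bool = True) -> IO[str]:
    """Return a text handle over ``source`` (path, binary or text stream).

    Gzip payloads are detected by magic bytes when ``gz_allowed``.
    """
    if isinstance(source, (str, Path)):
        raw: IO[bytes] = open(source, "rb")
    elif isinstance(source, io.TextIOBase):
        return source
    elif hasattr(source, "read"):
        data = source.read()
        if isinstance(data, str):
            return io.StringIO(data)
        raw = io.BytesIO(data)
    else:
        raise TypeError(f"cannot read from {type(source).__name__}")
    head = raw.read(2)
    raw.seek(0)
    if gz_allowed and head == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="ascii")
    return io.TextIOWrapper(raw, encoding="ascii")


# --- FASTA ------------------------------------------------------------------

def read_fasta(source: str | Path | IO, gz_allowed: bool = True) -> list[SequenceRecord]:
    """Parse FASTA (optionally gzip-compressed) into records, file order.

    Wrapped sequence lines are joined, blank lines tolerated and
    empty-sequence records preserved.  Raises :class:`MalformedFastaError`
    when the first non-blank line does not start with '>'.
    """
    handle = _open_text(source, gz_allowed)
    lines = [l for l in handle.read().splitlines() if l.strip()]
    if lines and not lines[0].startswith(">"):
        raise MalformedFastaError("first non-blank line does not start with '>'")
    records = []
    for rec in SeqIO.parse(io.StringIO("\n".join(lines) + "\n" if lines else ""), "fasta"):
        records.append(
            SequenceRecord(
                identifier=rec.id,
                description=rec.description,
                sequence=str(rec.seq),
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], width: int = 70) -> bytes:
    """Serialize records to FASTA bytes, wrapping sequence lines at ``width``.

    The header is '>' + description verbatim, which makes
    ``read_fasta(write_fasta(R)) == R`` hold exactly.
    """
    if width < 1:
        raise ValueError("width must be positive")
    out = []
    for rec in records:
        header = rec.description if rec.description else rec.identifier
        out.append(f">{header}\n")
        seq = rec.sequence
        for i in range(0, len(seq), width):
            out.append(seq[i : i + width] + "\n")
    return "".join(out).encode("ascii")


# --- NCBI assembly_summary ---------------------------------------------------

_REQUIRED_COLUMNS = (
    "assembly_accession",
    "organism_name",
    "taxid",
    "species_taxid",
    "assembly_level",
    "seq_rel_date",
    "ftp_path",
)


def _parse_date(text: str) -> date | None:
    text = text.strip()
    for fmt in ("%Y/%m/%d", "%Y-%m-%d"):
        try:
            return datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    return None


def parse_assembly_summary(source: str | Path | IO) -> list[AssemblySummaryRow]:
    """Parse an NCBI assembly_summary.txt index into rows, file order.

    Columns are located by NAME from the last '#' comment line (the
    header), so column reordering and trailing unknown columns are
    harmless.  Rows with unparsable release dates are retained with a
    null date; rows with ftp_path "na" are retained but flagged
    non-downloadable.
    """
    handle = _open_text(source)
    header: list[str] | None = None
    data_lines: list[str] = []
    for line in handle.read().splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").lstrip()
            if "\t" in stripped:
                header = stripped.split("\t")
            continue
        if line.strip():
            data_lines.append(line)
    if header is None:
        raise MalformedIndexError("no '#'-prefixed header line found")
    index = {name.strip(): i for i, name in enumerate(header)}
    missing = [c for c in _REQUIRED_COLUMNS if c not in index]
    if missing:
        raise MalformedIndexError(f"missing required columns: {', '.join(missing)}")

    rows = []
    for fields_ in csv.reader(data_lines, delimiter="\t", quoting=csv.QUOTE_NONE):
        def cell(name: str, default: str = "") -> str:
            i = index.get(name)
            return fields_[i] if i is not None and i < len(fields_) else default

        rows.append(
            AssemblySummaryRow(
                assembly_accession=cell("assembly_accession"),
                organism_name=cell("organism_name"),
                taxid=int(cell("taxid") or 0),
                species_taxid=int(cell("species_taxid") or 0),
                assembly_level=cell("assembly_level"),
                seq_rel_date=_parse_date(cell("seq_rel_date")),
                ftp_path=cell("ftp_path"),
                refseq_category=cell("refseq_category"),
                asm_name=cell("asm_name"),
            )
        )
    return rows


# --- GenBank metadata --------------------------------------------------------

def _first(qualifiers: dict, key: str) -> str | None:
    values = qualifiers.get(key)
    if not values:
        return None
    value = str(values[0]).strip()
    return value or None


def parse_genbank_metadata(source: str | Path | IO) -> list[AssemblyMetadata]:
    """Extract provenance metadata from a GenBank flat file, one per entry.

    Country comes from the source feature's /country qualifier, falling
    back to /geo_loc_name (the newer INSDC spelling); host, isolation
    source, collection date and strain from the like-named qualifiers;
    the organism from the ORGANISM line (fallback /organism); PubMed IDs
    from all reference blocks, de-duplicated in first-seen order.
    """
    handle = _open_text(source)
    entries = []
    for rec in SeqIO.parse(handle, "genbank"):
        ann = rec.annotations
        accession = (ann.get("accessions") or [rec.id])[0]
        src_quals: dict = {}
        for feat in rec.features:
            if feat.type == "source":
                src_quals = feat.qualifiers
                break
        organism = ann.get("organism") or _first(src_quals, "organism") or ""
        pubmed: list[int] = []
        for ref in ann.get("references", []):
            pm = getattr(ref, "pubmed_id", "")
            if pm and pm.isdigit() and int(pm) not in pubmed:
                pubmed.append(int(pm))
        country = _first(src_quals, "country") or _first(src_quals, "geo_loc_name")
        entries.append(
            AssemblyMetadata(
                accession=accession,
                organism=organism,
                definition=rec.description,
                strain=_first(src_quals, "strain"),
                country=country,
                host=_first(src_quals, "host"),
                isolation_source=_first(src_quals, "isolation_source"),
                collection_date=_first(src_quals, "collection_date"),
                pubmed_ids=tuple(pubmed),
            )
        )
    if not entries:
        raise MalformedGenBankError("no LOCUS entry found in GenBank input")
    return entries


def summarize_metadata(entries: Sequence[AssemblyMetadata]) -> AssemblyMetadata:
    """Assembly-level summary of per-entry metadata.

    Single-valued fields come from the first entry that defines them;
    PubMed IDs are the de-duplicated union across entries.
    """
    if not entries:
        raise ValueError("no metadata entries")

    def first_defined(attr: str) -> str | None:
        for e in entries:
            v = getattr(e, attr)
            if v:
                return v
        return None

    pubmed: list[int] = []
    for e in entries:
        for pm in e.pubmed_ids:
            if pm not in pubmed:
                pubmed.append(pm)
    head = entries[0]
    return AssemblyMetadata(
        accession=head.accession,
        organism=head.organism,
        definition=head.definition,
        strain=first_defined("strain"),
        country=first_defined("country"),
        host=first_defined("host"),
        isolation_source=first_defined("isolation_source"),
        collection_date=first_defined("collection_date"),
        pubmed_ids=tuple(pubmed),
    )
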