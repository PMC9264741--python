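"""Remote-retrieval plans for NCBI GenBank/RefSeq, ENA and SRA run info.

Every URL builder is pure; the only operations that touch the network
are :func:`execute_plan` and :func:`resolve_fastq_urls`, and both go
through an injectable :class:`Transport`, so the whole module is
testable offline with a stub.  Endpoint roots live in one
:class:`EndpointConfig` record so mirrors can be substituted.
"""

from __future__ import annotations

import csv
import gzip
import io
import os
import re
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field, replace
from pathlib import Path, PurePosixPath
from typing import Protocol
from urllib.parse import urlparse

__all__ = [
    "DownloadPlan",
    "Transport",
    "UrllibTransport",
    "EndpointConfig",
    "DEFAULT_ENDPOINTS",
    "NCBI_DIVISIONS",
    "InvalidSectionError",
    "InvalidAccessionError",
    "NonDownloadableError",
    "NoFilesError",
    "RetrievalError",
    "UnsafeDestinationError",
    "build_assembly_summary_url",
    "build_assembly_file_urls",
    "build_ena_fasta_url",
    "resolve_fastq_urls",
    "build_sra_runinfo_url",
    "execute_plan",
]


class InvalidSectionError(ValueError):
    """Section is not one of genbank/refseq (or unknown NCBI division)."""


class InvalidAccessionError(ValueError):
    """Accession is empty, malformed or of the wrong type."""


class NonDownloadableError(ValueError):
    """The assembly row carries no FTP path (ftp_path == 'na')."""


class NoFilesError(ValueError):
    """ENA lists no FASTQ files for the run accession."""


class UnsafeDestinationError(ValueError):
    """A plan destination is absolute or escapes the output root."""


class RetrievalError(IOError):
    """A fetch failed after all retries; carries the URL."""

    def __init__(self, url: str, cause: Exception | None = None):
        super().__init__(f"failed to retrieve {url}" + (f": {cause}" if cause else ""))
        self.url = url


#: NCBI genomes FTP divisions ("kingdoms" in the query vocabulary).
NCBI_DIVISIONS = frozenset(
    {
        "archaea",
        "bacteria",
        "fungi",
        "invertebrate",
        "metagenomes",
        "plant",
        "protozoa",
        "vertebrate_mammalian",
        "vertebrate_other",
        "viral",
    }
)

_RUN_ACCESSION_RE = re.compile(r"^[ESD]RR\d+$")


@dataclass(frozen=True)
class EndpointConfig:
    """Root URLs of the remote services; swap for mirrors if needed."""

    ncbi_genomes_root: str = "https://ftp.ncbi.nlm.nih.gov/genomes"
    ena_browser_root: str = "https://www.ebi.ac.uk/ena/browser/api"
    ena_portal_root: str = "https://www.ebi.ac.uk/ena/portal/api"
    sra_runinfo_root: str = "https://trace.ncbi.nlm.nih.gov/Traces/sra/sra.cgi"


DEFAULT_ENDPOINTS = EndpointConfig()

_PLAN_KINDS = frozenset(
    {
        "assembly_summary",
        "genomic_fasta",
        "genomic_genbank",
        "assembly_report",
        "ena_fasta",
        "ena_fastq",
        "sra_runinfo",
    }
)


@dataclass(frozen=True)
class DownloadPlan:
    """One planned retrieval: source URL, relative destination, kind."""

    url: str
    destination: str
    kind: str
    decompress: bool = False

    def __post_init__(self) -> None:
        scheme = urlparse(self.url).scheme
        if scheme not in ("http", "https", "ftp"):
            raise ValueError(f"unsupported URL scheme in {self.url!r}")
        if self.kind not in _PLAN_KINDS:
            raise ValueError(f"unknown plan kind {self.kind!r}")
        dest = PurePosixPath(self.destination)
        if dest.is_absolute() or ".." in dest.parts or not dest.parts:
            raise UnsafeDestinationError(
                f"destination {self.destination!r} must be a safe relative path"
            )


class Transport(Protocol):
    """Fetch capability: url -> response bytes."""

    def fetch(self, url: str) -> bytes: ...


@dataclass
class UrllibTransport:
    """Default transport: urllib with timeout, retries, exponential backoff."""

    timeout: float = 60.0
    retries: int = 3
    backoff: float = 1.0

    def fetch(self, url: str) -> bytes:
        last: Exception | None = None
        for attempt in range(self.retries + 1):
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    return resp.read()
            except (urllib.error.URLError, OSError) as exc:
                last = exc
                if attempt < self.retries:
                    time.sleep(self.backoff * 2**attempt)
        raise RetrievalError(url, last)


# --- URL builders ------------------------------------------------------------

def build_assembly_summary_url(
    section: str, kingdom: str, config: EndpointConfig = DEFAULT_ENDPOINTS
) -> str:
    """URL of the assembly_summary.txt index for a section and division.

    ``section`` is "genbank" or "refseq"; ``kingdom`` an NCBI genomes
    division such as "bacteria" or "viral".
    """
    section = section.lower()
    if section not in ("genbank", "refseq"):
        raise InvalidSectionError(f"section must be genbank or refseq, got {section!r}")
    kingdom = kingdom.lower()
    if kingdom not in NCBI_DIVISIONS:
        raise InvalidSectionError(
            f"unknown NCBI genomes division {kingdom!r};"
            f" expected one of {sorted(NCBI_DIVISIONS)}"
        )
    return f"{config.ncbi_genomes_root}/{section}/{kingdom}/assembly_summary.txt"


def build_assembly_file_urls(row) -> list[DownloadPlan]:
    """Plans for the genomic FASTA, GenBank flat file and assembly report.

    NCBI stores assembly files under ``<ftp_path>/<asm>_<suffix>`` where
    ``<asm>`` is the final component of the FTP path.  Destinations are
    placed under the assembly's accession folder.
    """
    if not row.downloadable:
        raise NonDownloadableError(
            f"assembly {row.assembly_accession} has no FTP path"
        )
    base = row.ftp_path.rstrip("/")
    asm = base.rsplit("/", 1)[-1]
    acc = row.assembly_accession
    return [
        DownloadPlan(
            url=f"{base}/{asm}_genomic.fna.gz",
            destination=f"{acc}/{asm}_genomic.fna.gz",
            kind="genomic_fasta",
        ),
        DownloadPlan(
            url=f"{base}/{asm}_genomic.gbff.gz",
            destination=f"{acc}/{asm}_genomic.gbff.gz",
            kind="genomic_genbank",
        ),
        DownloadPlan(
            url=f"{base}/{asm}_assembly_report.txt",
            destination=f"{acc}/{asm}_assembly_report.txt",
            kind="assembly_report",
        ),
    ]


def build_ena_fasta_url(
    accession: str, config: EndpointConfig = DEFAULT_ENDPOINTS
) -> str:
    """ENA browser API URL returning FASTA for a sequence accession."""
    if not accession or accession != accession.strip() or " " in accession:
        raise InvalidAccessionError(f"invalid ENA accession {accession!r}")
    return f"{config.ena_browser_root}/fasta/{accession}"


def build_sra_runinfo_url(
    run_accession: str, config: EndpointConfig = DEFAULT_ENDPOINTS
) -> str:
    """NCBI run-info (CSV) endpoint URL for an ERR/SRR/DRR run accession."""
    if not _RUN_ACCESSION_RE.match(run_accession or ""):
        raise InvalidAccessionError(
            f"run accession must match ERR/SRR/DRR + digits, got {run_accession!r}"
        )
    return (
        f"{config.sra_runinfo_root}"
        f"?save=efetch&db=sra&rettype=runinfo&term={run_accession}"
    )


def resolve_fastq_urls(
    run_accession: str,
    transport: Transport,
    config: EndpointConfig = DEFAULT_ENDPOINTS,
) -> list[DownloadPlan]:
    """Query the ENA filereport for a run and plan its FASTQ downloads.

    Returns one plan per FASTQ file listed in the ``fastq_ftp`` column
    (1 for single-end, 2+ for paired runs); files stay compressed.
    """
    if not _RUN_ACCESSION_RE.match(run_accession or ""):
        raise InvalidAccessionError(
            f"run accession must match ERR/SRR/DRR + digits, got {run_accession!r}"
        )
    url = (
        f"{config.ena_portal_root}/filereport?accession={run_accession}"
        f"&result=read_run&fields=fastq_ftp&format=tsv"
    )
    payload = transport.fetch(url).decode("utf-8", errors="replace")
    reader = csv.DictReader(io.StringIO(payload), delimiter="\t")
    ftp_fields: list[str] = []
    for record in reader:
        value = (record.get("fastq_ftp") or "").strip()
        if value:
            ftp_fields.extend(p for p in value.split(";") if p)
    if not ftp_fields:
        raise NoFilesError(f"ENA lists no FASTQ files for {run_accession}")
    plans = []
    for entry in ftp_fields:
        file_url = entry if "://" in entry else f"https://{entry}"
        filename = PurePosixPath(urlparse(file_url).path).name
        plans.append(
            DownloadPlan(
                url=file_url,
                destination=f"{run_accession}/{filename}",
                kind="ena_fastq",
            )
        )
    return plans


# --- execution ---------------------------------------------------------------

def execute_plan(plan: DownloadPlan, transport: Transport, out_root: str | Path) -> Path:
    """Fetch a plan's URL and store the bytes under ``out_root``.

    Writes atomically (temp file then rename), creating parent folders;
    decompresses gzip payloads when the plan says so.  The destination
    is re-checked against ``out_root`` to exclude path traversal.
    """
    root = Path(out_root).resolve()
    target = (root / plan.destination).resolve()
    if root != target and root not in target.parents:
        raise UnsafeDestinationError(
            f"destination {plan.destination!r} escapes the output root"
        )
    data = transport.fetch(plan.url)
    if plan.decompress:
        try:
            data = gzip.decompress(data)
        except (OSError, EOFError) as exc:
            raise RetrievalError(plan.url, exc)
    target.parent.mkdir(parents=True, exist_ok=True)
    tmp = target.with_name(target.name + ".part")
    tmp.write_bytes(data)
    os.replace(tmp, target)
    return target


def plan_with_destination(
    plan: DownloadPlan, destination: str, decompress: bool | None = None
) -> DownloadPlan:
    """A copy of ``plan`` with a new destination (and optionally decompress)."""
    kwargs = {"destination": destination}
    if decompress is not None:
        kwargs["decompress"] = decompress
    return replace(plan, **kwargs)
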