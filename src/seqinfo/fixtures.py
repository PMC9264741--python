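"""Seed-deterministic synthetic fixtures: sequences, assemblies, indexes.

Everything the pipeline consumes can be generated here without any
network access: random nucleotide sequences with a target composition,
whole fixture assemblies (FASTA + GenBank flat file + index row), an
NCBI-style assembly_summary index, mutated alignments, and a
:class:`StubTransport` that serves the generated bytes by URL.

All generators are deterministic for a fixed seed and emit only formats
the :mod:`seqinfo.formats` parsers re-read (closure property).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .alignment_utils import Alignment
from .assembly_pipeline import ComponentClass
from .formats import AssemblySummaryRow, SequenceRecord, write_fasta

__all__ = [
    "gen_sequence",
    "gen_alignment",
    "gen_assembly_fixture",
    "gen_default_index",
    "render_assembly_summary",
    "gen_repository",
    "FixtureAssembly",
    "StubTransport",
]

ALPHABET = "ACGTN"

#: Root under which fixture assemblies pretend to live; the stub
#: transport maps these URLs to generated bytes.
FIXTURE_FTP_ROOT = "https://fixtures.invalid/genomes/all"


def gen_sequence(
    length: int,
    composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25, 0.0),
    seed: int = 0,
) -> str:
    """Random nucleotide text with target (A, C, G, T, ambiguous) frequencies.

    ``composition`` must be five non-negative probabilities summing to 1;
    the fifth is the chance of an 'N'.  Deterministic per seed; the
    empirical composition converges to the target as ``length`` grows.
    """
    if length < 0:
        raise ValueError("length must be non-negative")
    probs = np.asarray(composition, dtype=float)
    if probs.shape != (5,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(
            "composition must be 5 non-negative probabilities summing to 1"
        )
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(ALPHABET), size=length, p=probs)
    return "".join(letters)


def gen_alignment(
    n_records: int,
    n_columns: int,
    per_column_mutation_rate: float = 0.0,
    gap_rate: float = 0.0,
    seed: int = 0,
) -> Alignment:
    """A reference sequence plus independently mutated copies.

    Record 1 is the reference; in every other record each column is,
    independently, turned into a gap with probability ``gap_rate``, else
    substituted with a DIFFERENT base with probability
    ``per_column_mutation_rate``.  Expected reference-vs-mutant
    differences are about ``n_columns * (gap + (1-gap) * mutation)``.
    """
    if n_records < 2:
        raise ValueError("need at least two records")
    for name, rate in (("mutation", per_column_mutation_rate), ("gap", gap_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=n_columns)
    records = [SequenceRecord("ref", "ref reference", "".join(ref))]
    for k in range(1, n_records):
        seq = ref.copy()
        gaps = rng.random(n_columns) < gap_rate
        mutate = (~gaps) & (rng.random(n_columns) < per_column_mutation_rate)
        if mutate.any():
            # shift each mutated base by 1-3 positions in ACGT: always different
            idx = np.searchsorted(bases, seq[mutate])
            shift = rng.integers(1, 4, size=int(mutate.sum()))
            seq[mutate] = bases[(idx + shift) % 4]
        seq[gaps] = "-"
        name = f"mut{k}"
        records.append(SequenceRecord(name, f"{name} mutated copy", "".join(seq)))
    return Alignment.from_records(records)


# --- whole-assembly fixtures ---------------------------------------------------

_CLASS_HEADERS = {
    ComponentClass.CHROMOSOME: "{organism} chromosome, complete genome",
    ComponentClass.PLASMID: "{organism} plasmid p{idx}, complete sequence",
    ComponentClass.OTHER: "contig{idx:05d}",
}

_DEFAULT_METADATA = {
    "country": "France: Guadeloupe",
    "host": "Homo sapiens",
    "isolation_source": "blood culture",
    "collection_date": "2019-07-20",
    "strain": "FX-1",
    "pubmed_ids": (35794520,),
}


@dataclass(frozen=True)
class FixtureAssembly:
    """One generated assembly: records, serialized files and its index row."""

    summary_row: AssemblySummaryRow
    records: tuple[SequenceRecord, ...]
    classes: tuple[ComponentClass, ...]
    fasta_bytes: bytes
    genbank_bytes: bytes
    report_bytes: bytes
    metadata: Mapping[str, object]


def _genbank_bytes(
    accession: str,
    organism: str,
    records: Sequence[SequenceRecord],
    metadata: Mapping[str, object],
    geo_qualifier: str = "country",
) -> bytes:
    """Serialize fixture records as a GenBank flat file via Biopython."""
    out: list[SeqRecord] = []
    for i, rec in enumerate(records):
        entry_id = accession if i == 0 else f"SYN{i:07d}.1"
        sr = SeqRecord(
            Seq(rec.sequence),
            id=entry_id,
            name=f"LOCUS{i:04d}",
            description=rec.description,
        )
        sr.annotations["molecule_type"] = "DNA"
        sr.annotations["organism"] = organism
        sr.annotations["source"] = organism
        sr.annotations["date"] = "01-JAN-2020"
        sr.annotations["accessions"] = [entry_id.split(".")[0]]
        refs = []
        for pm in metadata.get("pubmed_ids", ()):
            from Bio.SeqFeature import Reference  # lazy: moved across Bio versions

            ref = Reference()
            ref.title = "Direct Submission"
            ref.pubmed_id = str(pm)
            refs.append(ref)
        if refs:
            sr.annotations["references"] = refs
        quals: dict[str, list[str]] = {"organism": [organism], "mol_type": ["genomic DNA"]}
        for key in ("strain", "host", "isolation_source", "collection_date"):
            value = metadata.get(key)
            if value:
                quals[key] = [str(value)]
        country = metadata.get("country")
        if country:
            quals[geo_qualifier] = [str(country)]
        sr.features.append(
            SeqFeature(FeatureLocation(0, len(rec.sequence)), type="source",
                       qualifiers=quals)
        )
        out.append(sr)
    buf = io.StringIO()
    SeqIO.write(out, buf, "genbank")
    return buf.getvalue().encode("ascii")


def gen_assembly_fixture(
    n_records: int = 2,
    classes: Sequence[ComponentClass] | None = None,
    stats_profile: Sequence[float] = (0.3, 0.2, 0.2, 0.3, 0.0),
    seed: int = 0,
    accession: str = "GCF_000000001.1",
    organism: str = "Escherichia coli",
    taxid: int = 562,
    species_taxid: int = 562,
    level: str = "Complete Genome",
    release_date: date | None = date(2020, 1, 15),
    record_length: int = 5000,
    metadata: Mapping[str, object] | None = None,
    geo_qualifier: str = "country",
) -> FixtureAssembly:
    """Generate one coherent fixture assembly.

    FASTA headers carry the keywords that ``classify_component`` maps to
    the requested classes, the GenBank flat file embeds the requested
    provenance metadata (under ``geo_qualifier``, /country by default),
    and the index row's ftp_path points under :data:`FIXTURE_FTP_ROOT`
    so a :class:`StubTransport` can serve the files.
    """
    if classes is None:
        classes = [ComponentClass.CHROMOSOME] + [ComponentClass.PLASMID] * (
            n_records - 1
        )
    if len(classes) != n_records:
        raise ValueError("classes length must equal n_records")
    meta = dict(_DEFAULT_METADATA)
    if metadata:
        meta.update(metadata)

    records = []
    for i, cls in enumerate(classes):
        header_body = _CLASS_HEADERS[cls].format(organism=organism, idx=i + 1)
        ident = f"{accession}_seq{i + 1}"
        # plasmids an order of magnitude shorter than chromosomes
        length = record_length if cls is ComponentClass.CHROMOSOME else max(
            record_length // 10, 50
        )
        seq = gen_sequence(length, stats_profile, seed=seed * 1000 + i)
        records.append(SequenceRecord(ident, f"{ident} {header_body}", seq))

    asm_name = f"ASM{accession.split('_')[1].split('.')[0][-6:]}v1"
    row = AssemblySummaryRow(
        assembly_accession=accession,
        organism_name=organism,
        taxid=taxid,
        species_taxid=species_taxid,
        assembly_level=level,
        seq_rel_date=release_date,
        ftp_path=f"{FIXTURE_FTP_ROOT}/{accession}_{asm_name}",
        refseq_category="na",
        asm_name=asm_name,
    )
    report = (
        f"# Assembly name:  {asm_name}\n# Organism name:  {organism}\n"
        f"# Assembly level: {level}\n"
    ).encode("ascii")
    return FixtureAssembly(
        summary_row=row,
        records=tuple(records),
        classes=tuple(classes),
        fasta_bytes=write_fasta(records),
        genbank_bytes=_genbank_bytes(accession, organism, records, meta, geo_qualifier),
        report_bytes=report,
        metadata=meta,
    )


# --- index fixtures ------------------------------------------------------------

_SUMMARY_HEADER = (
    "#   See ftp://ftp.ncbi.nlm.nih.gov/genomes/README_assembly_summary.txt\n"
    "# assembly_accession\tbioproject\tbiosample\twgs_master\trefseq_category\t"
    "taxid\tspecies_taxid\torganism_name\tinfraspecific_name\tisolate\t"
    "version_status\tassembly_level\trelease_type\tgenome_rep\tseq_rel_date\t"
    "asm_name\tsubmitter\tgbrs_paired_asm\tpaired_asm_comp\tftp_path\t"
    "excluded_from_refseq\trelation_to_type_material\n"
)


def render_assembly_summary(rows: Iterable[AssemblySummaryRow]) -> bytes:
    """Serialize rows in the NCBI assembly_summary.txt dialect."""
    lines = [_SUMMARY_HEADER.rstrip("\n")]
    for r in rows:
        rel = r.seq_rel_date.strftime("%Y/%m/%d") if r.seq_rel_date else "na"
        cells = [
            r.assembly_accession, "PRJNA000000", "SAMN00000000", "",
            r.refseq_category or "na", str(r.taxid), str(r.species_taxid),
            r.organism_name, "", "", "latest", r.assembly_level, "Major",
            "Full", rel, r.asm_name, "Fixture Institute", "", "", r.ftp_path,
            "", "",
        ]
        lines.append("\t".join(cells))
    return ("\n".join(lines) + "\n").encode("ascii")


#: The fixed 10-assembly study index: (accession, organism, taxid,
#: species taxid, level, release date, composition profile in
#: (A, C, G, T, N) order; classes are derived from the level).  Profiles
#: roughly mirror each species' real GC content; dates and levels are
#: chosen so a species+level+date query has a small hand-enumerable answer.
_DEFAULT_INDEX_SPEC = [
    ("GCF_000000101.1", "Escherichia coli str. K-12 substr. MG1655", 511145, 562,
     "Complete Genome", date(2020, 1, 15), (0.246, 0.254, 0.254, 0.246, 0.0)),
    ("GCF_000000102.1", "Escherichia coli O157:H7 str. Sakai", 386585, 562,
     "Complete Genome", date(2019, 6, 1), (0.247, 0.253, 0.253, 0.247, 0.0)),
    ("GCF_000000103.1", "Escherichia coli", 562, 562,
     "Contig", date(2021, 3, 10), (0.25, 0.25, 0.25, 0.25, 0.0)),
    ("GCF_000000104.1", "Salmonella enterica subsp. enterica", 59201, 28901,
     "Complete Genome", date(2020, 5, 20), (0.24, 0.26, 0.26, 0.24, 0.0)),
    ("GCF_000000105.1", "Salmonella enterica", 28901, 28901,
     "Scaffold", date(2018, 11, 2), (0.2375, 0.2575, 0.2575, 0.2375, 0.01)),
    ("GCF_000000106.1", "Klebsiella pneumoniae", 573, 573,
     "Complete Genome", date(2017, 2, 14), (0.215, 0.285, 0.285, 0.215, 0.0)),
    ("GCF_000000107.1", "Klebsiella pneumoniae", 573, 573,
     "Chromosome", date(2022, 8, 30), (0.215, 0.285, 0.285, 0.215, 0.0)),
    ("GCF_000000108.1", "Staphylococcus aureus", 1280, 1280,
     "Complete Genome", date(2021, 12, 1), (0.335, 0.165, 0.165, 0.335, 0.0)),
    ("GCF_000000109.1", "Bacillus subtilis", 224308, 1423,
     "Complete Genome", date(2016, 7, 4), (0.2825, 0.2175, 0.2175, 0.2825, 0.0)),
    ("GCF_000000110.1", "Escherichia coli", 562, 562,
     "Complete Genome", date(2018, 9, 9), (0.25, 0.25, 0.25, 0.25, 0.0)),
]


def gen_default_index(seed: int = 0, record_length: int = 5000) -> list[FixtureAssembly]:
    """Ten fixture assemblies with fixed organisms, levels and dates.

    The index content (who matches which filter) is independent of the
    seed; only the nucleotide content derives from it.  Complete
    Genome/Chromosome assemblies get a chromosome plus plasmid(s);
    Scaffold/Contig assemblies get "other" contig records.  The Contig
    assembly (GCF_000000103.1) carries ftp_path "na" and the last one
    plants its country under /geo_loc_name to exercise both dialects.
    """
    fixtures = []
    for i, (acc, organism, taxid, sp_taxid, level, rel, profile) in enumerate(
        _DEFAULT_INDEX_SPEC
    ):
        if level in ("Complete Genome", "Chromosome"):
            classes = [ComponentClass.CHROMOSOME, ComponentClass.PLASMID]
            if i % 2 == 0:
                classes.append(ComponentClass.PLASMID)
        else:
            classes = [ComponentClass.OTHER] * 3
        geo = "geo_loc_name" if acc.endswith("110.1") else "country"
        fx = gen_assembly_fixture(
            n_records=len(classes),
            classes=classes,
            stats_profile=profile,
            seed=seed * 100 + i,
            accession=acc,
            organism=organism,
            taxid=taxid,
            species_taxid=sp_taxid,
            level=level,
            release_date=rel,
            record_length=record_length,
            metadata={"pubmed_ids": (35794520, 30000000 + i)},
            geo_qualifier=geo,
        )
        if acc.endswith("103.1"):  # the flagged non-downloadable row
            from dataclasses import replace

            fx = FixtureAssembly(
                summary_row=replace(fx.summary_row, ftp_path="na"),
                records=fx.records,
                classes=fx.classes,
                fasta_bytes=fx.fasta_bytes,
                genbank_bytes=fx.genbank_bytes,
                report_bytes=fx.report_bytes,
                metadata=fx.metadata,
            )
        fixtures.append(fx)
    return fixtures


# --- stub transport -------------------------------------------------------------

@dataclass
class StubTransport:
    """In-memory transport: serves preset bytes by URL and records requests."""

    responses: dict[str, bytes] = field(default_factory=dict)
    requested: list[str] = field(default_factory=list)
    fail_with: Exception | None = None

    def fetch(self, url: str) -> bytes:
        self.requested.append(url)
        if self.fail_with is not None:
            raise self.fail_with
        if url not in self.responses:
            raise KeyError(f"stub transport has no response for {url}")
        return self.responses[url]


def gen_repository(
    seed: int = 0,
    section: str = "refseq",
    kingdom: str = "bacteria",
    record_length: int = 5000,
) -> tuple[StubTransport, list[FixtureAssembly]]:
    """A stub transport preloaded with the default index and its files.

    Serves the assembly_summary URL plus, for every downloadable fixture
    assembly, its gzipped genomic FASTA, gzipped GenBank flat file and
    assembly report under the fixture FTP root.
    """
    from .repo_client import build_assembly_file_urls, build_assembly_summary_url

    fixtures = gen_default_index(seed=seed, record_length=record_length)
    responses: dict[str, bytes] = {
        build_assembly_summary_url(section, kingdom): render_assembly_summary(
            fx.summary_row for fx in fixtures
        )
    }
    for fx in fixtures:
        if not fx.summary_row.downloadable:
            continue
        for plan in build_assembly_file_urls(fx.summary_row):
            if plan.kind == "genomic_fasta":
                responses[plan.url] = gzip.compress(fx.fasta_bytes)
            elif plan.kind == "genomic_genbank":
                responses[plan.url] = gzip.compress(fx.genbank_bytes)
            else:
                responses[plan.url] = fx.report_bytes
    return StubTransport(responses=responses), fixtures
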