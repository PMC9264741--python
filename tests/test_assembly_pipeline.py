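"""Index filtering, component separation and report generation."""

import datetime
import io

import pytest

from seqinfo.assembly_pipeline import (
    AssemblyQuery,
    ComponentClass,
    build_report,
    classify_component,
    filter_assemblies,
    render_report,
    run_fetch,
    separate_components,
)
from seqinfo.fixtures import (
    StubTransport,
    gen_default_index,
    gen_repository,
    render_assembly_summary,
)
from seqinfo.formats import SequenceRecord, parse_assembly_summary, read_fasta
from seqinfo.repo_client import RetrievalError


@pytest.fixture(scope="module")
def index_rows():
    return [fx.summary_row for fx in gen_default_index(seed=3, record_length=400)]


# --- filtering -------------------------------------------------------------------


def test_species_substring_filter(index_rows):
    q = AssemblyQuery(species_pattern="Escherichia coli")
    got = [r.assembly_accession for r in filter_assemblies(index_rows, q)]
    assert got == [
        "GCF_000000101.1", "GCF_000000102.1", "GCF_000000103.1", "GCF_000000110.1",
    ]


def test_species_match_is_case_insensitive(index_rows):
    q = AssemblyQuery(species_pattern="escherichia COLI")
    assert len(filter_assemblies(index_rows, q)) == 4


def test_taxid_matches_taxid_or_species_taxid(index_rows):
    by_species_taxid = filter_assemblies(index_rows, AssemblyQuery(taxid=562))
    assert len(by_species_taxid) == 4  # strain taxids differ, species taxid matches
    by_strain_taxid = filter_assemblies(index_rows, AssemblyQuery(taxid=511145))
    assert [r.assembly_accession for r in by_strain_taxid] == ["GCF_000000101.1"]


def test_date_filter_is_inclusive(index_rows):
    q = AssemblyQuery(min_release_date=datetime.date(2020, 1, 15))
    got = filter_assemblies(index_rows, q)
    assert "GCF_000000101.1" in [r.assembly_accession for r in got]


def test_date_filter_later_than_all_rows_empty(index_rows):
    q = AssemblyQuery(min_release_date=datetime.date(2030, 1, 1))
    assert filter_assemblies(index_rows, q) == []


def test_level_filter(index_rows):
    q = AssemblyQuery(level="Scaffold")
    got = filter_assemblies(index_rows, q)
    assert [r.assembly_accession for r in got] == ["GCF_000000105.1"]


def test_limit_truncates_sorted_matches(index_rows):
    q = AssemblyQuery(species_pattern="Escherichia coli", limit=1)
    got = filter_assemblies(index_rows, q)
    assert [r.assembly_accession for r in got] == ["GCF_000000101.1"]


def test_limit_zero_rejected():
    with pytest.raises(ValueError):
        AssemblyQuery(limit=0)


def test_filters_compose_as_conjunction(index_rows):
    q1 = AssemblyQuery(species_pattern="Escherichia coli")
    q2 = AssemblyQuery(level="Complete Genome")
    both = AssemblyQuery(species_pattern="Escherichia coli", level="Complete Genome")
    sequential = filter_assemblies(filter_assemblies(index_rows, q1), q2)
    assert filter_assemblies(index_rows, both) == sequential


def test_rows_with_null_date_excluded_only_by_date_filter():
    text = (
        "# assembly_accession\ttaxid\tspecies_taxid\torganism_name\t"
        "assembly_level\tseq_rel_date\tftp_path\n"
        "GCF_1\t1\t1\tX y\tContig\tgarbage\tna\n"
    )
    rows = parse_assembly_summary(io.StringIO(text))
    assert filter_assemblies(rows, AssemblyQuery()) == rows
    assert (
        filter_assemblies(
            rows, AssemblyQuery(min_release_date=datetime.date(2000, 1, 1))
        )
        == []
    )


# --- component classification ------------------------------------------------------


@pytest.mark.parametrize(
    "header, expected",
    [
        ("NZ_X plasmid pO157, complete sequence", ComponentClass.PLASMID),
        ("NC_Y Escherichia coli chromosome, complete genome", ComponentClass.CHROMOSOME),
        ("NC_Z Escherichia coli, complete genome", ComponentClass.CHROMOSOME),
        ("contig00042", ComponentClass.OTHER),
        ("NZ_W PLASMID unnamed", ComponentClass.PLASMID),
        ("something chromosome plasmid", ComponentClass.PLASMID),  # plasmid rule first
    ],
)
def test_classify_component(header, expected):
    assert classify_component(header) == expected


def records_for(classes):
    headers = {
        ComponentClass.CHROMOSOME: "chromosome, complete genome",
        ComponentClass.PLASMID: "plasmid pX, complete sequence",
        ComponentClass.OTHER: "contig",
    }
    return [
        SequenceRecord(f"r{i}", f"r{i} {headers[c]}", "ACGT" * (i + 1))
        for i, c in enumerate(classes)
    ]


def test_separate_components_writes_only_wanted_classes(tmp_path):
    recs = records_for(
        [ComponentClass.CHROMOSOME, ComponentClass.PLASMID, ComponentClass.PLASMID]
    )
    groups = separate_components(recs, tmp_path, {ComponentClass.PLASMID})
    assert [r.identifier for r in groups[ComponentClass.PLASMID]] == ["r1", "r2"]
    assert (tmp_path / "plasmid" / "plasmid.fasta").exists()
    assert not (tmp_path / "chromosome").exists()
    written = read_fasta(tmp_path / "plasmid" / "plasmid.fasta")
    assert written == groups[ComponentClass.PLASMID]


def test_separate_components_all_other(tmp_path):
    recs = records_for([ComponentClass.OTHER] * 3)
    separate_components(recs, tmp_path)
    assert {p.name for p in tmp_path.iterdir()} == {"other"}


def test_separation_conserves_records(rng):
    classes = [rng.choice(list(ComponentClass)) for _ in range(20)]
    recs = records_for(classes)
    groups = separate_components(recs)
    regrouped = [r for cls in ComponentClass for r in groups[cls]]
    assert sorted(r.identifier for r in regrouped) == sorted(
        r.identifier for r in recs
    )
    assert sum(len(v) for v in groups.values()) == len(recs)


# --- report -----------------------------------------------------------------------


def test_render_report_tsv_and_html_share_cells(index_rows):
    from seqinfo.formats import AssemblyMetadata
    from seqinfo.seqstats import count_nucleotides, stats_from_counts

    counts = count_nucleotides("AATGCAATGC")
    meta = AssemblyMetadata(
        accession="GCF_000000101",
        organism="Escherichia coli",
        definition="fixture",
        country="France",
        pubmed_ids=(111,),
    )
    row = build_report(
        stats_from_counts(counts), meta, index_rows[0],
        {ComponentClass.CHROMOSOME: 1}, raw_counts=counts,
    )
    tsv = render_report([row], "tsv").decode()
    html = render_report([row], "html").decode()
    cells = tsv.splitlines()[1].split("\t")
    for cell in cells:
        assert cell in html
    assert html.lstrip().startswith("<!DOCTYPE html>")


def test_render_report_empty_is_header_only():
    tsv = render_report([], "tsv").decode()
    assert len(tsv.splitlines()) == 1


def test_report_missing_metadata_renders_na(index_rows):
    row = build_report(None, None, index_rows[0])
    cells = row.cells
    assert "NA" in cells
    tsv = render_report([row]).decode()
    assert "\tNA\t" in tsv


def test_report_warns_on_accession_mismatch(index_rows):
    from seqinfo.formats import AssemblyMetadata

    meta = AssemblyMetadata(accession="OTHER1", organism="x", definition="d")
    with pytest.warns(UserWarning):
        build_report(None, meta, index_rows[0])


# --- end-to-end fetch over the stub transport ----------------------------------------


QUERY = AssemblyQuery(
    species_pattern="Escherichia coli",
    level="Complete Genome",
    min_release_date=datetime.date(2019, 1, 1),
)


def test_run_fetch_end_to_end(tmp_path):
    transport, fixtures = gen_repository(seed=5, record_length=600)
    rows = run_fetch(QUERY, tmp_path / "out", transport)
    assert [r.accession for r in rows] == ["GCF_000000101.1", "GCF_000000102.1"]
    # per-class folders partition the downloaded records
    for fx in fixtures[:2]:
        acc = fx.summary_row.assembly_accession
        comp_dir = tmp_path / "out" / acc / "components"
        regrouped = []
        for sub in comp_dir.iterdir():
            regrouped += read_fasta(sub / f"{sub.name}.fasta")
        assert sorted(r.identifier for r in regrouped) == sorted(
            r.identifier for r in fx.records
        )
    report = (tmp_path / "out" / "report.tsv").read_bytes()
    assert report.decode().count("\n") == 3  # header + 2 rows


def test_run_fetch_deterministic_report(tmp_path):
    t1, _ = gen_repository(seed=5, record_length=600)
    t2, _ = gen_repository(seed=5, record_length=600)
    run_fetch(QUERY, tmp_path / "a", t1)
    run_fetch(QUERY, tmp_path / "b", t2)
    assert (tmp_path / "a" / "report.tsv").read_bytes() == (
        tmp_path / "b" / "report.tsv"
    ).read_bytes()


def test_run_fetch_requests_only_planned_urls(tmp_path):
    transport, _ = gen_repository(seed=5, record_length=600)
    run_fetch(QUERY, tmp_path / "out", transport)
    assert len(transport.requested) == 1 + 2 * 3  # index + 3 files per assembly
    assert len(set(transport.requested)) == len(transport.requested)


def test_run_fetch_empty_match_is_not_an_error(tmp_path):
    transport, _ = gen_repository(seed=5, record_length=600)
    q = AssemblyQuery(species_pattern="Vibrio cholerae")
    assert run_fetch(q, tmp_path / "out", transport) == []
    assert (tmp_path / "out" / "report.tsv").exists()


def test_run_fetch_skips_non_downloadable_rows(tmp_path):
    transport, fixtures = gen_repository(seed=5, record_length=600)
    q = AssemblyQuery(species_pattern="Escherichia coli", level="Contig")
    rows = run_fetch(q, tmp_path / "out", transport)
    assert [r.accession for r in rows] == ["GCF_000000103.1"]
    assert not (tmp_path / "out" / "GCF_000000103.1" / "assembly.fna").exists()


def test_run_fetch_propagates_transport_failure(tmp_path):
    transport, fixtures = gen_repository(seed=5, record_length=600)
    summary = render_assembly_summary(fx.summary_row for fx in fixtures)
    broken = StubTransport(fail_with=RetrievalError("https://x"))
    path = tmp_path / "summary.txt"
    path.write_bytes(summary)
    with pytest.raises(RetrievalError):
        run_fetch(QUERY, tmp_path / "out", broken, summary_source=path)
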