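import pytest

from yeastprimers import (
    CHECK_COLUMNS,
    DesignParams,
    PRIMER_COLUMNS,
    ReportError,
    RunManifest,
    build_catalog,
    design_primer_set,
    export_xlsx,
    read_header_file,
    read_primer_table,
    write_check_file,
    write_header_file,
    write_primer_table,
    write_run_outputs,
)


@pytest.fixture
def cds_primersets(small_syn):
    params = DesignParams(homology_length=50, ftype="CDS")
    return [
        design_primer_set(f, small_syn.index, params)
        for f in build_catalog(small_syn.records, "CDS")
    ]


def test_header_file_round_trips(tmp_path, small_syn, cds_primersets):
    manifest = RunManifest(
        genome_label="synthetic",
        feature_code="CDS",
        homology_length=50,
        chromosomes=tuple((c.id, c.length) for c in small_syn.chromosomes),
        feature_count=len(cds_primersets),
    )
    path = tmp_path / "header.txt"
    write_header_file(manifest, path)
    parsed = read_header_file(path)
    assert parsed["genome_label"] == "synthetic"
    assert parsed["homology_length"] == 50
    assert parsed["feature_count"] == len(cds_primersets)
    assert parsed["chromosomes"] == [(c.id, c.length) for c in small_syn.chromosomes]


def test_primer_table_round_trips_bit_exactly(tmp_path, cds_primersets):
    path = tmp_path / "primers.tsv"
    write_primer_table(cds_primersets, path)
    frame = read_primer_table(path)
    assert list(frame.columns) == PRIMER_COLUMNS
    assert len(frame) == len(cds_primersets)
    for row, ps in zip(frame.itertuples(index=False), cds_primersets):
        f = ps.feature
        assert (row.systematic_name, row.common_name) == (f.systematic_name, f.common_name)
        assert (int(row.start), int(row.end), row.strand) == (f.start, f.end, f.strand)
        assert row.deletion_fwd == ps.fwd_del
        assert row.deletion_fwd_tailed == ps.fwd_del_tailed
        assert row.ctag_fwd == ps.fwd_tag and row.ctag_fwd_tailed == ps.fwd_tag_tailed
        assert (row.rev, row.rev_tailed) == (ps.rev, ps.rev_tailed)
        assert row.overlapping_features == ";".join(ps.overlap_names)
        assert int(row.overlap_count) == ps.overlap_count


def test_primer_table_row_accounting(tmp_path, cds_primersets):
    path = tmp_path / "primers.tsv"
    write_primer_table(cds_primersets[:5], path)
    assert len(path.read_text().splitlines()) == 6  # header + 5 rows


def test_duplicate_systematic_names_are_fatal(tmp_path, cds_primersets):
    with pytest.raises(ReportError, match="duplicate"):
        write_primer_table([cds_primersets[0], cds_primersets[0]], tmp_path / "p.tsv")


def test_ncrna_table_keeps_blank_tagging_columns(tmp_path, small_syn):
    params = DesignParams(homology_length=50, ftype="ncRNA")
    sets = [
        design_primer_set(f, small_syn.index, params)
        for f in build_catalog(small_syn.records, "ncRNA")
    ]
    path = tmp_path / "nc.tsv"
    write_primer_table(sets, path)
    frame = read_primer_table(path)
    assert list(frame.columns) == PRIMER_COLUMNS  # schema is stable across types
    assert (frame["ctag_fwd"] == "").all() and (frame["ctag_fwd_tailed"] == "").all()


def test_check_file_end_regions(tmp_path, toy_genome, toy_cds_plus):
    ps = design_primer_set(toy_cds_plus, toy_genome, DesignParams(6))
    path = tmp_path / "check.tsv"
    write_check_file([ps], toy_genome, path, end_region_len=3)
    frame = read_primer_table(path)
    assert list(frame.columns) == CHECK_COLUMNS
    row = frame.iloc[0]
    assert (row.five_prime_region, row.three_prime_region) == ("ATG", "TAG")
    assert row.full_sequence == "ATGAAATAG"


def test_check_file_clamps_short_features(tmp_path, toy_genome, toy_cds_plus):
    ps = design_primer_set(toy_cds_plus, toy_genome, DesignParams(6))
    path = tmp_path / "check.tsv"
    write_check_file([ps], toy_genome, path, end_region_len=100)
    row = read_primer_table(path).iloc[0]
    assert row.five_prime_region == row.three_prime_region == row.full_sequence == "ATGAAATAG"


def test_run_outputs_triple_even_for_empty_catalog(tmp_path, small_syn):
    manifest = RunManifest(
        genome_label="synthetic", feature_code="CDS", homology_length=50,
        chromosomes=tuple((c.id, c.length) for c in small_syn.chromosomes),
        feature_count=0,
    )
    paths = write_run_outputs(manifest, [], small_syn.index, tmp_path / "empty")
    assert sorted(paths) == ["check", "header", "primers"]
    assert all(p.exists() for p in paths.values())
    assert read_header_file(paths["header"])["feature_count"] == 0


def test_run_outputs_enforce_manifest_consistency(tmp_path, small_syn, cds_primersets):
    manifest = RunManifest(
        genome_label="synthetic", feature_code="CDS", homology_length=50,
        chromosomes=(), feature_count=len(cds_primersets) + 1,
    )
    with pytest.raises(ReportError, match="feature count"):
        write_run_outputs(manifest, cds_primersets, small_syn.index, tmp_path / "bad")
    assert not list(tmp_path.glob("bad*"))  # nothing partial left behind


def test_xlsx_export_mirrors_table(tmp_path, cds_primersets):
    openpyxl = pytest.importorskip("openpyxl")
    path = tmp_path / "primers.xlsx"
    export_xlsx(cds_primersets[:4], "CDS", path)
    wb = openpyxl.load_workbook(path)
    ws = wb["CDS"]
    assert [c.value for c in ws[1]] == PRIMER_COLUMNS
    assert ws.max_row == 5
    assert ws.cell(row=2, column=1).value == cds_primersets[0].feature.systematic_name
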