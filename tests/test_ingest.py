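"""Spreadsheet import workflow: mapping, gates, atomic replacement."""

import pytest

from phenofield import fieldbook, ingest
from phenofield.core import InvariantError
from phenofield.fieldbook import TemplateSpec
from phenofield.ingest import (
    ConsistencyError,
    DuplicateUploadError,
    ValidationFailedError,
    check_plot_genotype_consistency,
    propose_mapping,
    register_mapping,
)

from conftest import EXP_KEY, fill_template


@pytest.fixture()
def filled_file(tmp_path, aug_plan, catalog):
    spec = TemplateSpec(plan=aug_plan, methodologies=tuple(catalog.methodologies[:3]))
    template, _ = fieldbook.observation_template(spec)
    filled = fill_template(template, seed=3)
    path = tmp_path / "filled.csv"
    filled.to_csv(path, index=False)
    return path, filled


@pytest.fixture()
def protocol(filled_file, catalog):
    _, filled = filled_file
    draft = propose_mapping(list(filled.columns), catalog.methodologies)
    return register_mapping(draft, protocol_id="tmpl")


class TestProposeMapping:
    def test_attribute_normalization(self, catalog):
        draft = propose_mapping(["Accession number", "LANE", " Plot "], catalog.methodologies)
        assert [e.attribute for e in draft.entries] == ["accession_number", "lane", "plot"]

    def test_template_grammar_resolves_methodology(self, catalog):
        draft = propose_mapping(["crown_rust__pct_leaf_area"], catalog.methodologies)
        e = draft.entries[0]
        assert e.methodology_id == "crown_rust__pct_leaf_area"
        assert e.observation_type == "percentage"

    def test_foreign_column_left_unmapped(self, catalog):
        draft = propose_mapping(["Crown rust %"], catalog.methodologies)
        assert draft.entries[0].is_mapped is False
        assert draft.unmapped == ("Crown rust %",)

    def test_duplicate_heads_rejected(self, catalog):
        with pytest.raises(InvariantError):
            propose_mapping(["lane", "lane"], catalog.methodologies)


class TestRegisterMapping:
    def test_assignment_completes_draft(self, catalog):
        draft = propose_mapping(["lane", "plot", "Crown rust %"], catalog.methodologies)
        protocol = register_mapping(
            draft,
            {"Crown rust %": ("crown_rust__pct_leaf_area", "percentage")},
            catalog=catalog.methodologies,
        )
        assert protocol.entry_for("Crown rust %").methodology_id == "crown_rust__pct_leaf_area"

    def test_missing_assignment_lists_columns(self, catalog):
        draft = propose_mapping(["lane", "Mystery"], catalog.methodologies)
        with pytest.raises(InvariantError, match="Mystery"):
            register_mapping(draft)

    def test_attribute_methodology_conflict_rejected(self, catalog):
        draft = propose_mapping(["lane"], catalog.methodologies)
        with pytest.raises(InvariantError):
            register_mapping(draft, {"lane": ("crown_rust__pct_leaf_area", "percentage")})

    def test_stored_protocol_reusable(self, populated_store, catalog):
        draft = propose_mapping(["lane", "plot", "accession_number"], catalog.methodologies)
        register_mapping(draft, store=populated_store, protocol_id="p1")
        again = populated_store.get_protocol("p1")
        assert again is not None and len(again.entries) == 3


class TestImport:
    def test_full_template_counts(self, populated_store, filled_file, protocol):
        path, filled = filled_file
        report = ingest.import_spreadsheet(populated_store, path, protocol, EXP_KEY, "2024-07-01")
        assert report.n_rows_read == 32
        assert report.n_observations_written == 96
        assert report.n_skipped == 0
        assert populated_store.count("raw_observation") == 96

    def test_duplicate_file_rejected_with_zero_writes(self, populated_store, filled_file, protocol):
        path, _ = filled_file
        ingest.import_spreadsheet(populated_store, path, protocol, EXP_KEY, "2024-07-01")
        before = populated_store.count("raw_observation")
        with pytest.raises(DuplicateUploadError):
            ingest.import_spreadsheet(populated_store, path, protocol, EXP_KEY, "2024-07-02")
        assert populated_store.count("raw_observation") == before

    def test_swapped_accessions_rejected_with_two_mismatches(
        self, tmp_path, populated_store, filled_file, protocol
    ):
        path, filled = filled_file
        swapped = filled.copy()
        cols = ["accession_number", "holding_institute_code"]
        a, b = swapped.loc[2, cols].copy(), swapped.loc[3, cols].copy()
        assert a["accession_number"] != b["accession_number"]
        swapped.loc[2, cols], swapped.loc[3, cols] = b.values, a.values
        bad = tmp_path / "swapped.csv"
        swapped.to_csv(bad, index=False)
        with pytest.raises(ConsistencyError) as exc:
            ingest.import_spreadsheet(populated_store, bad, protocol, EXP_KEY, "2024-07-01")
        assert len(exc.value.mismatches) == 2
        assert populated_store.count("raw_observation") == 0

    def test_empty_and_na_cells_skipped_not_errors(
        self, tmp_path, populated_store, filled_file, protocol
    ):
        path, filled = filled_file
        sparse = filled.copy().astype(object)
        col = "plant_height__height_cm"
        sparse.loc[0, col] = ""
        sparse.loc[1, col] = "NA"
        sparse.loc[2, col] = None
        p = tmp_path / "sparse.csv"
        sparse.to_csv(p, index=False)
        report = ingest.import_spreadsheet(populated_store, p, protocol, EXP_KEY, "2024-07-01")
        assert report.n_skipped == 3
        assert report.n_observations_written == 93

    def test_out_of_range_percentage_rejects_whole_file(
        self, tmp_path, populated_store, filled_file, protocol
    ):
        path, filled = filled_file
        bad = filled.copy()
        bad.loc[0, "crown_rust__pct_leaf_area"] = 130.0
        p = tmp_path / "bad.csv"
        bad.to_csv(p, index=False)
        with pytest.raises(ValidationFailedError):
            ingest.import_spreadsheet(populated_store, p, protocol, EXP_KEY, "2024-07-01")
        assert populated_store.count("raw_observation") == 0

    def test_xlsx_import(self, tmp_path, populated_store, filled_file, protocol):
        _, filled = filled_file
        p = tmp_path / "filled.xlsx"
        filled.to_excel(p, index=False)
        report = ingest.import_spreadsheet(populated_store, p, protocol, EXP_KEY, "2024-07-01")
        assert report.n_observations_written == 96


class TestConsistencyCheck:
    def test_agreement_yields_empty_list(self, aug_plan):
        rows = [
            {"row": i, "lane": p.lane, "plot": p.plot,
             "found_accession": p.accession_key[1], "target": None}
            for i, p in enumerate(aug_plan.data_plots)
        ]
        assert check_plot_genotype_consistency(rows, aug_plan) == []

    def test_unknown_plot_reported(self, aug_plan):
        rows = [{"row": 0, "lane": 99, "plot": 1, "found_accession": "AVE-0001"}]
        (m,) = check_plot_genotype_consistency(rows, aug_plan)
        assert m.kind == "unknown_plot"

    def test_accession_on_orientation_plot_mismatches(self, aug_request):
        from dataclasses import replace

        from phenofield import design

        plan = design.randomize(replace(aug_request, orientation_every=10))
        orient = next(p for p in plan.plots if p.role == "orientation")
        rows = [{"row": 0, "lane": orient.lane, "plot": orient.plot,
                 "found_accession": "AVE-0001"}]
        (m,) = check_plot_genotype_consistency(rows, plan)
        assert m.kind == "genotype"


class TestReplaceUpload:
    def test_replace_with_corrected_file(self, tmp_path, populated_store, filled_file, protocol):
        path, filled = filled_file
        first = ingest.import_spreadsheet(populated_store, path, protocol, EXP_KEY, "2024-07-01")
        corrected = filled.copy()
        corrected.loc[0, "plant_height__height_cm"] += 1.0
        p2 = tmp_path / "corrected.csv"
        corrected.to_csv(p2, index=False)
        report = ingest.replace_upload(
            populated_store, first.upload.upload_id, p2, protocol, "2024-07-01"
        )
        assert report.n_observations_written == 96
        assert populated_store.count("raw_observation") == 96
        old = populated_store.get_upload(first.upload.upload_id)
        assert old.status == "replaced"
        # no observation may reference the replaced upload
        orphans = populated_store._conn.execute(
            "SELECT COUNT(*) c FROM raw_observation WHERE upload_id = ?",
            (first.upload.upload_id,),
        ).fetchone()["c"]
        assert orphans == 0

    def test_replace_with_invalid_file_leaves_store_untouched(
        self, tmp_path, populated_store, filled_file, protocol
    ):
        path, filled = filled_file
        first = ingest.import_spreadsheet(populated_store, path, protocol, EXP_KEY, "2024-07-01")
        snapshot = populated_store._conn.execute(
            "SELECT * FROM raw_observation ORDER BY lane, plot, methodology_id"
        ).fetchall()
        bad = filled.copy()
        bad.loc[5, "crown_rust__pct_leaf_area"] = 999.0
        p2 = tmp_path / "bad.csv"
        bad.to_csv(p2, index=False)
        with pytest.raises(ValidationFailedError):
            ingest.replace_upload(populated_store, first.upload.upload_id, p2, protocol, "2024-07-01")
        after = populated_store._conn.execute(
            "SELECT * FROM raw_observation ORDER BY lane, plot, methodology_id"
        ).fetchall()
        assert [tuple(r) for r in snapshot] == [tuple(r) for r in after]
        assert populated_store.get_upload(first.upload.upload_id).status == "active"

    def test_replacing_inactive_upload_rejected(self, populated_store):
        from phenofield.store import StoreIntegrityError

        with pytest.raises(StoreIntegrityError):
            ingest.replace_upload(populated_store, 12345, "nofile.csv", None, "2024-07-01")


class TestProvenance:
    def test_every_observation_traces_to_one_active_upload(
        self, populated_store, filled_file, protocol
    ):
        path, _ = filled_file
        ingest.import_spreadsheet(populated_store, path, protocol, EXP_KEY, "2024-07-01")
        rows = populated_store._conn.execute(
            """SELECT o.upload_id, u.status, u.protocol_id
               FROM raw_observation o JOIN upload u ON o.upload_id = u.upload_id"""
        ).fetchall()
        assert len(rows) == 96
        assert all(r["status"] == "active" and r["protocol_id"] == "tmpl" for r in rows)
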