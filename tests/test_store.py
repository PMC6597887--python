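"""Persistence: schema lifecycle, natural-key semantics, FK integrity,
CSV round-trips and the hierarchical observation query."""

import sqlite3

import pytest

from phenofield import FieldExperiment, Measurement, Plot, RawObservation
from phenofield.core import Accession, InvariantError, Method, TraitDescriptor
from phenofield.store import (
    CSV_KINDS,
    ObservationQuery,
    SchemaVersionError,
    StoreIntegrityError,
    init_schema,
)

EXP = ("AVEQ", "DEU146", "QLB-A1", "2024-03-15")


class TestSchema:
    def test_fresh_store_is_empty(self, tmp_path):
        with init_schema(tmp_path / "a.db") as s:
            assert s.count("accession") == 0
            assert s.count("raw_observation") == 0

    def test_reinit_is_idempotent(self, tmp_path):
        path = tmp_path / "a.db"
        with init_schema(path) as s:
            s.upsert(Accession("IPK", "AVE-1", "Avena"))
        with init_schema(path) as s:
            assert s.count("accession") == 1

    def test_alien_schema_rejected(self, tmp_path):
        path = tmp_path / "alien.db"
        conn = sqlite3.connect(path)
        conn.execute("CREATE TABLE something_else (x INTEGER)")
        conn.commit()
        conn.close()
        with pytest.raises(SchemaVersionError):
            init_schema(path)

    def test_wrong_version_rejected(self, tmp_path):
        path = tmp_path / "v.db"
        with init_schema(path) as s:
            s._conn.execute("UPDATE meta SET value = '999' WHERE key = 'schema_version'")
            s._conn.commit()
        with pytest.raises(SchemaVersionError):
            init_schema(path)


class TestUpsert:
    def test_identical_reinsert_is_noop(self, store):
        acc = Accession("IPK", "AVE-1", "Avena")
        store.upsert(acc)
        store.upsert(acc)
        assert store.count("accession") == 1

    def test_different_payload_same_key_rejected(self, store):
        store.upsert(Accession("IPK", "AVE-1", "Avena", accession_name="one"))
        with pytest.raises(StoreIntegrityError):
            store.upsert(Accession("IPK", "AVE-1", "Avena", accession_name="two"))

    def test_observation_for_missing_plot_rejected(self, populated_store):
        obs = RawObservation(
            measurement_key=EXP + ("plant_height__height_cm", "2024-07-01"),
            plot_key=EXP + (99, 99),
            value_absolute=1.0,
        )
        populated_store.upsert(
            Measurement(EXP, "plant_height__height_cm", "2024-07-01")
        )
        with pytest.raises(StoreIntegrityError):
            populated_store.upsert(obs)

    def test_plot_for_missing_experiment_rejected(self, store):
        with pytest.raises(StoreIntegrityError):
            store.upsert(
                Plot(("NO", "SUCH", "EXP", "2020-01-01"), 1, 1, 1, accession_key=None,
                     plot_role="orientation")
            )

    def test_cyclic_method_parent_rejected(self, store):
        store.upsert(Method("m1", "M1", "count"))
        store.upsert(Method("m2", "M2", "count", parent_method_id="m1"))
        with pytest.raises(StoreIntegrityError):
            store.upsert(Method("m3", "M3", "count", parent_method_id="m3"))

    def test_delete_plot_cascades_only_to_picture_links(self, populated_store):
        from phenofield import images

        s = populated_store
        plan = s.load_plan(EXP)
        p = plan.plots[0]
        pic, _ = images.register_picture(s, "http://example.org/a.jpg", picture_id="pic1")
        images.link_picture(s, "pic1", plot_key=EXP + (p.lane, p.plot))
        assert s.count("plot_picture") == 1
        s.delete("plot", EXP + (p.lane, p.plot))
        assert s.count("plot_picture") == 0
        assert s.count("picture") == 1  # the picture itself survives


class TestCsvRoundTrip:
    def test_accession_round_trip_identical(self, tmp_path, store, collection):
        entries, checks = collection
        store.upsert_many(entries + checks)
        out = tmp_path / "acc.csv"
        n = store.export_csv("accession", out)
        assert n == len(entries) + len(checks)
        with init_schema(tmp_path / "fresh.db") as fresh:
            assert fresh.import_csv("accession", out) == n
            out2 = tmp_path / "acc2.csv"
            fresh.export_csv("accession", out2)
        assert out.read_bytes() == out2.read_bytes()

    def test_catalog_round_trip_byte_stable(self, tmp_path, store, catalog):
        for m in catalog.methodologies:
            store.upsert_methodology(m)
        paths = {}
        for kind in ("trait", "scoring_key", "method", "methodology"):
            paths[kind] = tmp_path / f"{kind}.csv"
            store.export_csv(kind, paths[kind])
        with init_schema(tmp_path / "fresh.db") as fresh:
            for kind in ("trait", "scoring_key", "method", "methodology"):
                fresh.import_csv(kind, paths[kind])
            for kind in ("trait", "scoring_key", "method", "methodology"):
                again = tmp_path / f"{kind}_again.csv"
                fresh.export_csv(kind, again)
                assert paths[kind].read_bytes() == again.read_bytes()

    def test_bad_latitude_reported_with_line(self, tmp_path, store):
        bad = tmp_path / "sites.csv"
        bad.write_text(
            "site_id,country,latitude,longitude\n"
            "s1,DEU,51.8,11.3\n"
            "s2,DEU,200,11.3\n"
        )
        with pytest.raises(InvariantError, match="line 3"):
            store.import_csv("site", bad)
        assert store.count("site") == 0  # all-or-nothing

    def test_header_only_csv_imports_zero(self, tmp_path, store):
        empty = tmp_path / "acc.csv"
        empty.write_text("holding_institute_code,accession_number,genus\n")
        assert store.import_csv("accession", empty) == 0

    def test_unknown_kind_rejected(self, store, tmp_path):
        with pytest.raises(StoreIntegrityError):
            store.export_csv("nonsense", tmp_path / "x.csv")


class TestQueryHierarchy:
    @pytest.fixture()
    def store_with_obs(self, populated_store, catalog, aug_plan):
        s = populated_store
        date = "2024-07-01"
        for m in catalog.methodologies:
            if m.method.method_type == "text_score":
                continue
            s.upsert(Measurement(EXP, m.methodology_id, date))
            field = {
                "measurement": "value_absolute",
                "count": "value_count",
                "percentage": "value_percent",
                "numeric_score": "value_score_numeric",
            }[m.method.method_type]
            for i, p in enumerate(aug_plan.data_plots[:10]):
                s.upsert(
                    RawObservation(
                        measurement_key=EXP + (m.methodology_id, date),
                        plot_key=EXP + (p.lane, p.plot),
                        **{field: 1 + i},
                    )
                )
        return s

    def test_group_query_equals_union_of_member_traits(self, store_with_obs, catalog):
        s = store_with_obs
        group_rows = s.query_observations(ObservationQuery(trait_group="agronomy"))
        union = set()
        for t in catalog.traits:
            if t.trait_group != "agronomy":
                continue
            rows = s.query_observations(ObservationQuery(trait_id=t.trait_id))
            union |= {tuple(r) for r in rows[["methodology_id", "lane", "plot"]].itertuples(index=False)}
        got = {tuple(r) for r in group_rows[["methodology_id", "lane", "plot"]].itertuples(index=False)}
        assert got == union

    def test_methodology_query_subset_of_trait_query(self, store_with_obs):
        s = store_with_obs
        trait_rows = s.query_observations(ObservationQuery(trait_id="plant_height"))
        meth_rows = s.query_observations(
            ObservationQuery(methodology_id="plant_height__height_cm")
        )
        assert len(meth_rows) <= len(trait_rows)
        t = {tuple(r) for r in trait_rows[["methodology_id", "lane", "plot"]].itertuples(index=False)}
        m = {tuple(r) for r in meth_rows[["methodology_id", "lane", "plot"]].itertuples(index=False)}
        assert m <= t

    def test_empty_store_empty_result(self, store):
        assert len(store.query_observations(ObservationQuery(trait_group="quality"))) == 0

    def test_unknown_group_rejected(self):
        with pytest.raises(InvariantError):
            ObservationQuery(trait_group="flavor")

    def test_no_filter_requires_select_all(self):
        with pytest.raises(InvariantError):
            ObservationQuery()
        ObservationQuery(select_all=True)  # fine

    def test_value_range_filter(self, store_with_obs):
        rows = store_with_obs.query_observations(
            ObservationQuery(
                methodology_id="plant_height__height_cm",
                value_range={"value_absolute": (3, 5)},
            )
        )
        assert len(rows) == 3
        assert rows["value_absolute"].between(3, 5).all()
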