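"""Observation template round trip: generate, fill, map, import, query.

Creates a store, persists collection + trait catalog + plan, writes an
observation template for three methodologies (columns ordered by the
recommended phenological stage), fills it with simulated values, and imports
it. The template headers follow the ``trait__method`` grammar, so the column
mapping is proposed fully automatically; the import is gated by the
duplicate-upload and plot-genotype consistency checks.
"""

import tempfile
from pathlib import Path

from phenofield import (
    FieldExperiment,
    ObservationQuery,
    design,
    fieldbook,
    fixtures,
    ingest,
    init_schema,
)

workdir = Path(tempfile.mkdtemp())
EXP = ("AVEQ", "DEU146", "QLB-A1", "2024-03-15")

entries, checks = fixtures.make_collection(20, 3, seed=1)
catalog = fixtures.make_trait_catalog()

store = init_schema(workdir / "pheno.db")
store.upsert_many(entries + checks)
for m in catalog.methodologies:
    store.upsert_methodology(m)
store.upsert(FieldExperiment(*EXP, design_type="augmented", replications=4, plots_per_lane=10))

plan = design.randomize(
    design.DesignRequest(
        experiment_key=EXP,
        design_type="augmented",
        entry_accessions=tuple(a.key for a in entries),
        check_accessions=tuple(c.key for c in checks),
        blocks=4,
        plots_per_lane=10,
        seed=42,
    )
)
store.save_plan(plan)

selected = fieldbook.select_methodologies(
    catalog.methodologies,
    ["plant_height__height_cm", "crown_rust__pct_leaf_area", "lodging__score_lodging"],
)
print("methodologies in stage order:",
      [(m.methodology_id, m.recommended_stage) for m in selected], "\n")

spec = fieldbook.TemplateSpec(plan=plan, methodologies=tuple(selected))
template, legend = fieldbook.observation_template(spec)
print(f"template: {template.shape[0]} rows x {template.shape[1]} columns")
print(legend.to_string(index=False), "\n")

# fill as a field book would and import
import numpy as np

rng = np.random.default_rng(0)
template["crown_rust__pct_leaf_area"] = rng.uniform(0, 60, len(template)).round(1)
template["plant_height__height_cm"] = rng.normal(105, 8, len(template)).round(1)
template["lodging__score_lodging"] = rng.integers(1, 10, len(template))
filled_path = workdir / "fieldbook_2024-07-01.csv"
template.to_csv(filled_path, index=False)

draft = ingest.propose_mapping(list(template.columns), catalog.methodologies)
protocol = ingest.register_mapping(draft, protocol_id="template-v1", store=store)
report = ingest.import_spreadsheet(store, filled_path, protocol, EXP, "2024-07-01")
print(f"imported: {report.n_observations_written} observations "
      f"from {report.n_rows_read} rows (skipped cells: {report.n_skipped})")

try:
    ingest.import_spreadsheet(store, filled_path, protocol, EXP, "2024-07-02")
except ingest.DuplicateUploadError as e:
    print("re-import rejected:", e, "\n")

# attribute-centric query through the trait hierarchy
rows = store.query_observations(ObservationQuery(trait_group="biotic_stress"))
print(f"biotic_stress group query: {len(rows)} raw observations "
      f"(= all crown rust plot values)")
store.close()
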