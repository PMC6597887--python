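import numpy as np
import pytest

from phenofield import FieldExperiment, design, fixtures
from phenofield.store import init_schema

EXP_KEY = ("AVEQ", "DEU146", "QLB-A1", "2024-03-15")


@pytest.fixture(scope="session")
def catalog():
    return fixtures.make_trait_catalog()


@pytest.fixture(scope="session")
def collection():
    entries, checks = fixtures.make_collection(20, 3, seed=11)
    return entries, checks


@pytest.fixture()
def aug_request(collection):
    entries, checks = collection
    return design.DesignRequest(
        experiment_key=EXP_KEY,
        design_type="augmented",
        entry_accessions=tuple(a.key for a in entries),
        check_accessions=tuple(a.key for a in checks),
        blocks=4,
        plots_per_lane=10,
        seed=42,
    )


@pytest.fixture()
def aug_plan(aug_request):
    return design.randomize(aug_request)


@pytest.fixture()
def store(tmp_path):
    s = init_schema(tmp_path / "pheno.db")
    yield s
    s.close()


@pytest.fixture()
def populated_store(store, collection, catalog, aug_plan):
    """Store holding the toy collection, catalog, experiment and its plan."""
    entries, checks = collection
    store.upsert_many(entries + checks)
    for m in catalog.methodologies:
        store.upsert_methodology(m)
    store.upsert(
        FieldExperiment(
            *EXP_KEY, design_type="augmented", replications=4, plots_per_lane=10
        )
    )
    store.save_plan(aug_plan)
    return store


def fill_template(template, seed=0):
    """Populate a template's methodology columns with plausible values."""
    rng = np.random.default_rng(seed)
    out = template.copy()
    for col in out.columns:
        if col == "plant_height__height_cm":
            out[col] = rng.normal(100, 10, len(out)).round(1)
        elif col == "crown_rust__pct_leaf_area":
            out[col] = rng.uniform(0, 100, len(out)).round(1)
        elif col == "panicle_number__panicle_count":
            out[col] = rng.integers(10, 50, len(out))
        elif col == "lodging__score_lodging":
            out[col] = rng.integers(1, 10, len(out))
        elif col == "growth_habit__habit_class":
            out[col] = rng.choice(["E", "I", "P"], len(out))
    return out
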