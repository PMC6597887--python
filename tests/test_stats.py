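"""Statistics: moments against independent oracles, block adjustment,
harmonization and multi-trait ranking."""

import math
import statistics as pystats

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy import stats as sps

from phenofield import design, fixtures, stats
from phenofield.core import InvariantError

EXP = ("P", "INST", "E1", "2024-03-15")


def _oracle(values):
    """Independent moment computation: stdlib statistics + scipy."""
    x = list(map(float, values))
    n = len(x)
    out = {
        "n": n,
        "mean": pystats.fmean(x),
        "median": pystats.median(x),
        "min": min(x),
        "max": max(x),
        "sd": pystats.stdev(x) if n >= 2 else None,
    }
    out["se"] = out["sd"] / math.sqrt(n) if out["sd"] is not None else None
    arr = np.asarray(x)
    constant = bool(np.all(arr == arr[0]))
    out["skewness"] = float(sps.skew(arr, bias=True)) if n >= 3 and not constant else None
    out["kurtosis"] = float(sps.kurtosis(arr, bias=True)) if n >= 4 and not constant else None
    return out


class TestDescribe:
    def test_symmetric_closed_case(self):
        st = stats.describe([2, 4, 6])
        assert st["mean"] == 4 and st["median"] == 4
        assert st["sd"] == 2 and st["min"] == 2 and st["max"] == 6
        assert st["n"] == 3 and st["skewness"] == 0

    def test_uniform_three_point_excess_kurtosis(self):
        assert stats.describe([1, 2, 3])["kurtosis"] is None  # n < 4
        st = stats.describe([1, 2, 3, 1, 2, 3])
        oracle = _oracle([1, 2, 3, 1, 2, 3])
        assert st["kurtosis"] == pytest.approx(oracle["kurtosis"], abs=1e-12)
        assert oracle["kurtosis"] == pytest.approx(-1.5)

    def test_single_value_degenerate(self):
        st = stats.describe([7])
        assert st["mean"] == 7 and st["sd"] is None and st["se"] is None

    def test_constant_sample_has_no_shape_statistics(self):
        st = stats.describe([5, 5, 5, 5])
        assert st["sd"] == 0 and st["skewness"] is None and st["kurtosis"] is None

    def test_agrees_with_oracle_on_random_samples(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            n = int(rng.integers(2, 51))
            x = rng.normal(rng.uniform(-50, 50), rng.uniform(0.1, 20), size=n)
            mine, ref = stats.describe(x), _oracle(x)
            for k in ("mean", "median", "sd", "se", "min", "max", "skewness", "kurtosis"):
                if ref[k] is None:
                    assert mine[k] is None, k
                else:
                    assert mine[k] == pytest.approx(ref[k], abs=1e-9), k

    def test_empty_rejected(self):
        with pytest.raises(InvariantError):
            stats.describe([])


def _tiny_aug_plan(checks=2, blocks=2, entries=4, seed=0):
    req = design.DesignRequest(
        experiment_key=EXP,
        design_type="augmented",
        entry_accessions=tuple(("IPK", f"E-{i}") for i in range(entries)),
        check_accessions=tuple(("IPK", f"C-{i}") for i in range(checks)),
        blocks=blocks,
        plots_per_lane=6,
        seed=seed,
    )
    return design.randomize(req)


class TestAugmentedAdjust:
    def test_direct_formula_case(self):
        """Block check means 11 and 15 (grand 13); entry raw 20 in block 2
        adjusts to 18."""
        plan = _tiny_aug_plan(checks=2, blocks=2, entries=2, seed=1)
        values = {}
        for p in plan.plots:
            if p.role == "check":
                base = {1: 11.0, 2: 15.0}[p.block]
                values[(p.lane, p.plot)] = base
            else:
                values[(p.lane, p.plot)] = 20.0
        out = stats.augmented_adjust(plan, values)
        entry_b2 = out[(out["role"] == "entry") & (out["block"] == 2)]
        assert entry_b2["adjusted"].tolist() == [18.0]
        entry_b1 = out[(out["role"] == "entry") & (out["block"] == 1)]
        assert entry_b1["adjusted"].tolist() == [22.0]

    def test_equal_check_means_leave_entries_unchanged(self):
        plan = _tiny_aug_plan(checks=2, blocks=3, entries=6, seed=2)
        values = {}
        rng = np.random.default_rng(0)
        for p in plan.plots:
            values[(p.lane, p.plot)] = 10.0 if p.role == "check" else float(rng.uniform(0, 50))
        out = stats.augmented_adjust(plan, values)
        entries = out[out["role"] == "entry"]
        assert np.allclose(entries["adjusted"], entries["raw"])

    def test_noiseless_simulation_recovers_genotype_values(self):
        plan = _tiny_aug_plan(checks=3, blocks=4, entries=20, seed=3)
        truth = fixtures.make_truth(plan, error_sd=0.0, seed=5)
        cat = fixtures.make_trait_catalog()
        df = fixtures.simulate_trial(plan, truth, cat.methodology("plant_height__height_cm"))
        values = {
            (r["lane"], r["plot"]): r["plant_height__height_cm"]
            for _, r in df.iterrows()
        }
        out = stats.augmented_adjust(plan, values)
        for row in out[out["role"] == "entry"].itertuples():
            expected = truth.mu + truth.genotype_effects[
                (row.holding_institute_code, row.accession_number)
            ]
            assert row.adjusted == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        shifts=st_.lists(
            st_.floats(-100, 100, allow_nan=False), min_size=3, max_size=3
        ),
        seed=st_.integers(0, 10_000),
    )
    def test_invariant_under_per_block_constant_shifts(self, shifts, seed):
        """Adding a constant c_j to all values of block j moves every
        adjusted entry value by exactly mean(c) -- block adjustment removes
        all between-block differences, so adjusted values are invariant up
        to the common level (and exactly invariant for mean-zero shifts),
        the defining property of block adjustment."""
        plan = _tiny_aug_plan(checks=2, blocks=3, entries=7, seed=11)
        rng = np.random.default_rng(seed)
        base = {(p.lane, p.plot): float(rng.uniform(0, 100)) for p in plan.plots}
        shifted = {
            (p.lane, p.plot): base[(p.lane, p.plot)] + shifts[p.block - 1]
            for p in plan.plots
        }
        a = stats.augmented_adjust(plan, base)
        b = stats.augmented_adjust(plan, shifted)
        ea = a[a["role"] == "entry"]["adjusted"].to_numpy()
        eb = b[b["role"] == "entry"]["adjusted"].to_numpy()
        assert np.allclose(eb - ea, np.mean(shifts), atol=1e-7)
        # mean-zero shifts leave adjusted values exactly unchanged
        centered = [s - np.mean(shifts) for s in shifts]
        c = stats.augmented_adjust(
            plan,
            {
                (p.lane, p.plot): base[(p.lane, p.plot)] + centered[p.block - 1]
                for p in plan.plots
            },
        )
        ec = c[c["role"] == "entry"]["adjusted"].to_numpy()
        assert np.allclose(ec, ea, atol=1e-7)

    def test_missing_check_flags_block_unadjustable(self):
        plan = _tiny_aug_plan(checks=2, blocks=2, entries=4, seed=4)
        values = {
            (p.lane, p.plot): 10.0
            for p in plan.plots
            if not (p.role == "check" and p.block == 2 and p.accession_key[1] == "C-0")
        }
        out = stats.augmented_adjust(plan, values)
        b2_entries = out[(out["block"] == 2) & (out["role"] == "entry")]
        assert (~b2_entries["adjustable"]).all()
        assert b2_entries["adjusted"].isna().all()
        b1_entries = out[(out["block"] == 1) & (out["role"] == "entry")]
        assert b1_entries["adjustable"].all()

    def test_adjustment_beats_raw_under_strong_block_effects(self):
        """With sigma_b = 2*sigma_e, the adjusted values track the true
        genotype values more closely than the raw ones nearly always.
        Replicate trials use a representative screening size (60 entries,
        6 blocks, 3 checks)."""
        cat = fixtures.make_trait_catalog()
        meth = cat.methodology("plant_height__height_cm")
        wins = 0
        n_rep = 200
        for rep in range(n_rep):
            plan = _tiny_aug_plan(checks=3, blocks=6, entries=60, seed=rep)
            truth = fixtures.make_truth(plan, block_sd=2.0, error_sd=1.0, seed=rep)
            df = fixtures.simulate_trial(plan, truth, meth)
            values = {
                (r["lane"], r["plot"]): r["plant_height__height_cm"]
                for _, r in df.iterrows()
            }
            out = stats.augmented_adjust(plan, values)
            ent = out[out["role"] == "entry"]
            true_vals = np.array(
                [
                    truth.mu
                    + truth.genotype_effects[(r.holding_institute_code, r.accession_number)]
                    for r in ent.itertuples()
                ]
            )
            rmse_adj = np.sqrt(np.mean((ent["adjusted"].to_numpy() - true_vals) ** 2))
            rmse_raw = np.sqrt(np.mean((ent["raw"].to_numpy() - true_vals) ** 2))
            wins += rmse_adj < rmse_raw
        assert wins / n_rep >= 0.95

    def test_non_augmented_plan_rejected(self):
        req = design.DesignRequest(
            experiment_key=EXP,
            design_type="block",
            entry_accessions=tuple(("IPK", f"E-{i}") for i in range(4)),
            blocks=2,
            plots_per_lane=4,
        )
        plan = design.randomize(req)
        with pytest.raises(InvariantError):
            stats.augmented_adjust(plan, {})


class TestHarmonize:
    def test_midpoint_and_endpoints(self):
        values = {"a": 2.0, "b": 6.0, "c": 10.0}
        grades = stats.harmonize_score(values, "higher_better")
        assert grades == {"a": 1, "b": 5, "c": 9}

    def test_lower_better_reverses(self):
        values = {"a": 2.0, "b": 10.0}
        grades = stats.harmonize_score(values, "lower_better")
        assert grades == {"a": 9, "b": 1}

    def test_all_identical_gives_grade_five(self):
        assert stats.harmonize_score({"a": 3.0, "b": 3.0}) == {"a": 5, "b": 5}

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        xs=st_.lists(
            st_.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=30, unique=True
        )
    )
    def test_monotone_and_endpoint_exact(self, xs):
        values = {i: x for i, x in enumerate(xs)}
        grades = stats.harmonize_score(values, "higher_better")
        order = sorted(values, key=values.get)
        gs = [grades[k] for k in order]
        assert gs == sorted(gs)  # monotone
        assert grades[order[0]] == 1 and grades[order[-1]] == 9
        assert all(1 <= g <= 9 for g in gs)


class TestRanking:
    def test_dominator_listed_first(self):
        means = {
            "m1": {"A": 10.0, "B": 5.0, "C": 1.0},
            "m2": {"A": 9.0, "B": 2.0, "C": 4.0},
        }
        spec = stats.RankingSpec(("m1", "m2"), (0.5, 0.5), ("higher_better",) * 2)
        out = stats.rank_genotypes(means, spec)
        assert out.iloc[0]["accession"] == "A"
        assert out.iloc[0]["composite"] == 1.0

    def test_single_trait_reduces_to_mean_ordering(self):
        means = {"m1": {"A": 3.0, "B": 9.0, "C": 6.0}}
        spec = stats.RankingSpec(("m1",), (1.0,), ("higher_better",))
        out = stats.rank_genotypes(means, spec)
        assert list(out["accession"]) == ["B", "C", "A"]

    def test_ties_get_average_rank(self):
        means = {"m1": {"A": 5.0, "B": 5.0, "C": 1.0}}
        spec = stats.RankingSpec(("m1",), (1.0,), ("higher_better",))
        out = stats.rank_genotypes(means, spec)
        tied = out[out["accession"].isin(["A", "B"])]["rank:m1"]
        assert set(tied) == {1.5}

    def test_lower_better_direction(self):
        means = {"m1": {"A": 5.0, "B": 1.0}}
        spec = stats.RankingSpec(("m1",), (1.0,), ("lower_better",))
        out = stats.rank_genotypes(means, spec)
        assert out.iloc[0]["accession"] == "B"

    def test_missing_trait_gets_worst_rank_and_flag(self):
        means = {"m1": {"A": 1.0, "B": 2.0, "C": 3.0}, "m2": {"A": 1.0, "B": 2.0}}
        spec = stats.RankingSpec(("m1", "m2"), (0.5, 0.5), ("higher_better",) * 2)
        out = stats.rank_genotypes(means, spec)
        c = out[out["accession"] == "C"].iloc[0]
        assert c["rank:m2"] == 3 and bool(c["missing_trait"])

    def test_bad_weights_rejected(self):
        with pytest.raises(InvariantError):
            stats.RankingSpec(("m1", "m2"), (0.5, 0.6), ("higher_better",) * 2)
        with pytest.raises(InvariantError):
            stats.RankingSpec(("m1",), (-1.0,), ("higher_better",))


class TestAggregateFromStore:
    def test_aggregate_counts_and_moments(self, populated_store, catalog, aug_plan, tmp_path):
        from conftest import EXP_KEY, fill_template
        from phenofield import fieldbook, ingest

        spec = fieldbook.TemplateSpec(plan=aug_plan, methodologies=(catalog.methodologies[0],))
        template, _ = fieldbook.observation_template(spec)
        filled = fill_template(template, seed=9)
        path = tmp_path / "f.csv"
        filled.to_csv(path, index=False)
        draft = ingest.propose_mapping(list(filled.columns), catalog.methodologies)
        protocol = ingest.register_mapping(draft, protocol_id="p")
        ingest.import_spreadsheet(populated_store, path, protocol, EXP_KEY, "2024-07-01")

        meth_id = catalog.methodologies[0].methodology_id
        rows = stats.aggregate(populated_store, EXP_KEY, meth_id, "2024-07-01")
        assert len(rows) == 23  # 20 entries + 3 checks
        by_n = {r.accession_key: r for r in rows}
        checks = [k for k in by_n if k[1].startswith("CHK")]
        assert all(by_n[c].n_replications == 4 for c in checks)
        # cross-check one check's mean against the raw file
        c = checks[0]
        col = filled[filled["accession_number"] == c[1]]["plant_height__height_cm"]
        assert by_n[c].mean == pytest.approx(col.mean())
        assert by_n[c].se == pytest.approx(col.std(ddof=1) / np.sqrt(4))

    def test_no_raw_data_yields_empty_result(self, populated_store, catalog):
        from conftest import EXP_KEY

        rows = stats.aggregate(
            populated_store, EXP_KEY, catalog.methodologies[0].methodology_id, "2030-01-01"
        )
        assert rows == []

    def test_text_scores_aggregate_to_mode(self, catalog):
        meth = catalog.methodology("growth_habit__habit_class")
        rows = stats.aggregate_values(
            {("IPK", "A1"): ["E", "E", "P"]}, meth, EXP, "2024-07-01"
        )
        assert rows[0].modal_score_text == "E"
        assert rows[0].mean is None
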