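"""Descriptive aggregation, 1-9 harmonization and multi-trait ranking.

Aggregates plot values per accession (mean, median, sd/se, range, skewness,
excess kurtosis, n), rescales means onto the universal 1-9 grade scale, and
ranks genotypes over two traits with user weights -- higher yield is better,
lower rust severity is better. Raw data remain authoritative; grades and
composite ranks are presentation aids.
"""

import numpy as np

from phenofield import fixtures, stats

rng = np.random.default_rng(3)
accessions = [("IPK", f"AVE-{i:03d}") for i in range(8)]
catalog = fixtures.make_trait_catalog()

# per-accession plot values from 4 field replications
yield_vals = {a: list(rng.normal(rng.uniform(80, 120), 5, 4)) for a in accessions}
rust_vals = {a: list(np.clip(rng.normal(rng.uniform(5, 60), 4, 4), 0, 100)) for a in accessions}

exp = ("AVEQ", "DEU146", "QLB-A1", "2024-03-15")
agg_yield = stats.aggregate_values(
    yield_vals, catalog.methodology("plant_height__height_cm"), exp, "2024-07-20"
)
print("aggregated statistics (first 3 accessions):")
for a in agg_yield[:3]:
    print(f"  {a.accession_key[1]}: n={a.n_replications} mean={a.mean:.1f} "
          f"median={a.median:.1f} sd={a.sd:.2f} se={a.se:.2f} "
          f"range=[{a.min:.1f}, {a.max:.1f}] g1={a.skewness:+.2f} g2={a.kurtosis:+.2f}")

means_yield = {a.accession_key: a.mean for a in agg_yield}
grades = stats.harmonize_score(means_yield, "higher_better")
print("\nuniversal 1-9 grades for mean height (9 = tallest):")
print("  " + ", ".join(f"{k[1]}:{g}" for k, g in sorted(grades.items())))

means_rust = {
    a.accession_key: a.mean
    for a in stats.aggregate_values(
        rust_vals, catalog.methodology("crown_rust__pct_leaf_area"), exp, "2024-06-15"
    )
}
spec = stats.RankingSpec(
    methodology_ids=("plant_height__height_cm", "crown_rust__pct_leaf_area"),
    weights=(0.6, 0.4),
    directions=("higher_better", "lower_better"),
)
ranked = stats.rank_genotypes(
    {"plant_height__height_cm": means_yield, "crown_rust__pct_leaf_area": means_rust}, spec
)
print("\nweighted two-trait ranking (composite = 0.6*height rank + 0.4*rust rank,"
      " 1 = best):")
print(ranked.to_string(index=False))
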