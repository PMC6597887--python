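"""Randomize an augmented field trial and derive its field books.

Builds a toy working collection (20 entries, 3 standard cultivars), lays an
augmented block design on a 10-plots-per-lane field, and prints the plan
matrix, the field list head and a sowing list. In an augmented design the
checks appear once per block (the replicated backbone); entries once overall.
"""

from phenofield import design, fieldbook, fixtures

entries, checks = fixtures.make_collection(20, 3, seed=1)

req = design.DesignRequest(
    experiment_key=("AVEQ", "DEU146", "QLB-A1", "2024-03-15"),
    design_type="augmented",
    entry_accessions=tuple(a.key for a in entries),
    check_accessions=tuple(c.key for c in checks),
    blocks=4,                # each block: 3 checks + 5 entries
    plots_per_lane=10,
    orientation_every=16,    # an unsown orientation plot after every 16 data plots
    seed=42,
)
plan = design.randomize(req)
print(f"{len(plan.plots)} plots "
      f"({len(plan.data_plots)} data = 4 blocks x 3 checks + 20 entries, "
      f"{len(plan.plots) - len(plan.data_plots)} orientation)\n")

print("plan as matrix (lanes x plots; X = orientation plot):")
print(design.render_plan(plan, "matrix").to_string(), "\n")

print("field list, first rows:")
print(fieldbook.field_list(plan).head(5).to_string(index=False), "\n")

# sowing amounts scale by germination test results: ceil(300 / rate)
rates = {a.key: 0.8 for a in entries} | {c.key: 0.95 for c in checks}
plots, summary = fieldbook.sowing_list(plan, seeds_per_plot=300, germination=rates)
print("sowing summary, first rows (seed_amount = ceil(300/rate) x n_plots):")
print(summary.head(5).to_string(index=False))
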