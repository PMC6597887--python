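# phenofield

A field-phenotyping information system for plant genetic resources, built as
a Python library with a thin `pheno` command-line front end.

Genebanks and evaluation networks phenotype germplasm accessions in
randomized field trials across many sites and seasons. The data only become
usable when each observed value stays connected to its full experimental
context: which accession, in which plot of which randomized plan, observed
with which trait–method combination at which phenological stage, under which
treatments, imported from which spreadsheet. `phenofield` implements that
backbone:

- **Observation model** — raw plot-level observations in an
  entity–attribute–value table with typed value fields (absolute value,
  percentage, count, numeric score, text score), validated against the
  *methodology* (trait descriptor × observation method, with unit or scoring
  key and a recommended BBCH-style stage); per-accession aggregates carry
  mean, median, sd/se, range, skewness, kurtosis and n. Natural compound
  keys (institute + accession number; project + institute + code + date)
  are the primary keys throughout.
- **Trial designs** — seeded randomization of complete block designs (every
  entry once per block) and augmented block designs (checks once per block,
  entries once overall, block sizes within one), orientation plots, and
  row-major or serpentine (lane, plot) layout with matrix/list rendering.
- **Field books** — sowing lists scaled by germination rates, field lists,
  and observation templates whose columns follow the recommended
  phenological stages and whose `trait__method` headers import back with
  zero mapping effort.
- **Validated import** — column-mapping protocols (stored, reusable),
  duplicate-upload detection (SHA-256 per experiment), plot–genotype
  consistency checks against the field plan, all-or-nothing imports and
  atomic upload replacement.
- **Statistics** — for augmented designs, the Federer-style single-factor
  check adjustment: block effect `b_j = (check mean in block j) − (grand
  check mean)`, adjusted entry value `= raw − b_j`; linear harmonization to
  the universal 1–9 grade scale; weighted multi-trait genotype ranking with
  average ranks on ties and deficiency tabulation.
- **Pictures** — images registered by locator (path or URL) with extracted
  camera metadata, linked n:m to plots and accessions, searchable by
  taxonomy and experiment.
- **Fixtures** — a deterministic synthetic working collection, trait catalog
  covering every method type, and simulated trials under the additive model
  `value = μ + g (genotype) + b (block) + ε`, so every workflow runs from an
  empty store with known ground truth.

## Worked example

`examples/03_augmented_adjustment.py` simulates an augmented trial
(60 entries, 6 blocks, 3 checks; σ_b = 2, σ_e = 1) and removes the block
noise with the check backbone:

```
estimated block effects (from checks) vs simulated truth:
  block 1: estimated +0.603   true -0.067
  block 2: estimated -2.783   true -2.540
  block 3: estimated -2.301   true -2.466
  block 4: estimated +1.580   true +1.534
  block 5: estimated +3.266   true +3.745
  block 6: estimated -0.363   true -0.206

RMSE against true genotype values (mu + g), 60 entries:
  raw      2.433
  adjusted 1.036   (block noise removed by the check backbone)
```

Each block's effect is estimated from its three check plots, so the
estimates track the simulated truth up to the checks' residual error; the
adjusted entry values are roughly 2.4× closer to the true genotype values
than the raw plot values. The other examples cover design + field books
(`01`), the template → import round trip with its duplicate and consistency
gates (`02`), and aggregation, 1–9 grading and two-trait ranking (`04`).

The same workflows are available from the shell:

```bash
pheno demo --seed 3 --out demo/         # catalog, plan, filled fieldbook, truth
pheno init trial.db
pheno design augmented --experiment AVEQ/DEU146/QLB-A1/2024-03-15 \
    --entries entries.csv --checks checks.csv --blocks 4 --seed 42
pheno import apply trial.db fieldbook.csv \
    --experiment AVEQ/DEU146/QLB-A1/2024-03-15 --date 2024-07-01
```

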