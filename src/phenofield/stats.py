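"""Descriptive statistics, check-based adjustment, harmonization and ranking.

Raw plot observations are aggregated per accession to the descriptive
statistics preferred for presentation: mean, median, sample standard
deviation and standard error, range, skewness and excess kurtosis, with the
replication count. Moments use the Fisher-Pearson definitions on central
moments m_k = (1/n) * sum((x - mean)^k):

    g1 = m3 / m2^(3/2)          (skewness, null if n < 3 or m2 = 0)
    g2 = m4 / m2^2 - 3          (excess kurtosis, null if n < 4 or m2 = 0)

For augmented block designs, only the checks are replicated; their block
means estimate block effects that adjust the unreplicated entries
(single-factor check adjustment after Federer):

    b_j      = mean(check values in block j) - grand mean of check values
    adjusted = raw - b_j                      for an entry in block j

Check adjusted values are their per-check means across blocks. Adjusted
values are invariant under adding any constant to all values of a block --
the defining property of block adjustment.

Harmonization maps values linearly onto the universal 1-9 grade scale; it is
a presentation aid (raw data are always retained). Ranking combines
per-methodology mean ranks with user weights into a composite score for
multi-trait genotype comparison and deficiency tabulation.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import (
    AggregatedObservation,
    InvariantError,
    Methodology,
    value_field_for,
)
from .design import FieldPlan

__all__ = [
    "describe",
    "aggregate",
    "aggregate_values",
    "augmented_adjust",
    "harmonize_score",
    "RankingSpec",
    "rank_genotypes",
]


def describe(values: Sequence[float]) -> dict:
    """Descriptive statistics of one accession's plot values.

    Returns mean, median, sd (sample, n-1), se = sd/sqrt(n), min, max, n,
    skewness g1 and excess kurtosis g2; sd/se are None at n = 1, g1 requires
    n >= 3, g2 requires n >= 4, and both are None when the values are
    constant (m2 = 0).
    """
    x = np.asarray(list(values), dtype=float)
    n = x.size
    if n == 0:
        raise InvariantError("describe requires at least one value")
    out = {
        "n": int(n),
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "sd": None,
        "se": None,
        "skewness": None,
        "kurtosis": None,
    }
    if n >= 2:
        sd = float(np.std(x, ddof=1))
        out["sd"] = sd
        out["se"] = sd / float(np.sqrt(n))
    d = x - np.mean(x)
    m2 = float(np.mean(d**2))
    if m2 > 0.0:
        if n >= 3:
            out["skewness"] = float(np.mean(d**3)) / m2**1.5
        if n >= 4:
            out["kurtosis"] = float(np.mean(d**4)) / m2**2 - 3.0
    return out


def aggregate_values(
    per_accession: Mapping[tuple, Sequence],
    methodology: Methodology,
    experiment_key: tuple,
    observation_date: str,
) -> list[AggregatedObservation]:
    """Aggregate per-accession value lists into AggregatedObservation rows.

    Numeric-capable method types aggregate to the full statistics; text
    scores aggregate to the modal value only (ties broken by scoring-key
    order). Accessions are emitted in sorted key order.
    """
    out: list[AggregatedObservation] = []
    text = methodology.method.method_type == "text_score"
    for acc_key in sorted(per_accession):
        vals = [v for v in per_accession[acc_key] if v is not None]
        if not vals:
            continue
        if text:
            counts = Counter(str(v) for v in vals)
            key_order = {c: i for i, c in enumerate(methodology.method.scoring_key.codes)}
            modal = min(counts, key=lambda c: (-counts[c], key_order.get(c, len(key_order)), c))
            out.append(
                AggregatedObservation(
                    experiment_key=experiment_key,
                    accession_key=acc_key,
                    methodology_id=methodology.methodology_id,
                    observation_date=observation_date,
                    n_replications=len(vals),
                    modal_score_text=modal,
                )
            )
            continue
        st = describe([float(v) for v in vals])
        out.append(
            AggregatedObservation(
                experiment_key=experiment_key,
                accession_key=acc_key,
                methodology_id=methodology.methodology_id,
                observation_date=observation_date,
                n_replications=st["n"],
                mean=st["mean"],
                median=st["median"],
                sd=st["sd"],
                se=st["se"],
                min=st["min"],
                max=st["max"],
                skewness=st["skewness"],
                kurtosis=st["kurtosis"],
            )
        )
    return out


def aggregate(store, experiment_key, methodology_id, observation_date) -> list[AggregatedObservation]:
    """Aggregate a stored measurement's raw observations per accession.

    Values are taken from the field implied by the methodology's method
    type; orientation plots never contribute (they carry no accession).
    Returns an empty list when no raw data exist.
    """
    methodology = store.get_methodology(methodology_id)
    rows = store.raw_values(experiment_key, methodology_id, str(observation_date))
    fieldname = value_field_for(methodology.method.method_type)
    per_acc: dict[tuple, list] = {}
    for row in rows:
        if row["plot_role"] == "orientation" or row["accession_key"] is None:
            continue
        per_acc.setdefault(row["accession_key"], []).append(row[fieldname])
    return aggregate_values(per_acc, methodology, tuple(experiment_key), str(observation_date))


def augmented_adjust(plan: FieldPlan, values: Mapping) -> pd.DataFrame:
    """Adjust augmented-design entry values by check-estimated block effects.

    ``values`` maps (lane, plot) or the plan's fill index to the raw value
    of that plot. Returns one row per data plot with columns raw,
    block_effect, adjusted, role, block, accession; entries in a block
    missing any check value are flagged unadjustable (adjusted NaN). Check
    rows report the per-check mean across blocks as their adjusted value.
    """
    if plan.design_type != "augmented":
        raise InvariantError("augmented_adjust requires an augmented-design plan")

    def value_of(i, p):
        if (p.lane, p.plot) in values:
            return values[(p.lane, p.plot)]
        return values.get(i)

    checks_by_block: dict[int, list[float]] = {}
    blocks = sorted({p.block for p in plan.data_plots})
    check_keys = sorted({p.accession_key for p in plan.data_plots if p.role == "check"})
    complete: dict[int, bool] = {}
    all_check_values: list[float] = []
    for b in blocks:
        vals = []
        seen = set()
        for i, p in enumerate(plan.plots):
            if p.block == b and p.role == "check":
                v = value_of(i, p)
                if v is not None:
                    vals.append(float(v))
                    seen.add(p.accession_key)
        complete[b] = set(check_keys) == seen and len(vals) == len(check_keys)
        checks_by_block[b] = vals
        all_check_values.extend(vals)

    if not all_check_values:
        raise InvariantError("no check values found; cannot estimate block effects")
    grand = float(np.mean(all_check_values))
    block_effect = {
        b: (float(np.mean(checks_by_block[b])) - grand if complete[b] else None) for b in blocks
    }

    check_values: dict[tuple, list[float]] = {k: [] for k in check_keys}
    rows = []
    for i, p in enumerate(plan.plots):
        if p.role == "orientation":
            continue
        raw = value_of(i, p)
        raw = None if raw is None else float(raw)
        if p.role == "check" and raw is not None:
            check_values[p.accession_key].append(raw)
        eff = block_effect[p.block]
        if p.role == "entry":
            adjusted = raw - eff if (raw is not None and eff is not None) else np.nan
        else:
            adjusted = np.nan  # filled with per-check means below
        rows.append(
            {
                "lane": p.lane,
                "plot": p.plot,
                "block": p.block,
                "role": p.role,
                "holding_institute_code": p.accession_key[0],
                "accession_number": p.accession_key[1],
                "raw": raw,
                "block_effect": np.nan if eff is None else eff,
                "adjusted": adjusted,
                "adjustable": p.role == "check" or (raw is not None and eff is not None),
            }
        )
    df = pd.DataFrame(rows)
    for k, vals in check_values.items():
        if vals:
            mask = (df["holding_institute_code"] == k[0]) & (df["accession_number"] == k[1])
            df.loc[mask, "adjusted"] = float(np.mean(vals))
    return df


def harmonize_score(values: Mapping, direction: str = "higher_better") -> dict:
    """Linearly rescale values onto the universal 1-9 grade scale.

    grade = round(1 + 8 * (x - min) / (max - min)); the minimum maps to 1
    and the maximum to 9 (reversed under ``lower_better``). When all values
    are identical every accession gets grade 5 by convention.
    """
    if direction not in ("higher_better", "lower_better"):
        raise InvariantError("direction must be 'higher_better' or 'lower_better'")
    keys = list(values)
    if not keys:
        return {}
    xs = np.asarray([float(values[k]) for k in keys])
    lo, hi = float(xs.min()), float(xs.max())
    if hi == lo:
        return {k: 5 for k in keys}
    grades = np.rint(1.0 + 8.0 * (xs - lo) / (hi - lo)).astype(int)
    if direction == "lower_better":
        grades = 10 - grades
    return {k: int(g) for k, g in zip(keys, grades)}


@dataclass(frozen=True)
class RankingSpec:
    """Multi-trait ranking: methodologies, positive weights summing to 1,
    and a per-methodology direction (which end of the scale is desirable)."""

    methodology_ids: tuple[str, ...]
    weights: tuple[float, ...]
    directions: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "methodology_ids", tuple(self.methodology_ids))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        object.__setattr__(self, "directions", tuple(self.directions))
        if not (len(self.methodology_ids) == len(self.weights) == len(self.directions)):
            raise InvariantError("methodologies, weights and directions must align")
        if any(w <= 0 for w in self.weights):
            raise InvariantError("weights must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise InvariantError("weights must sum to 1")
        for d in self.directions:
            if d not in ("higher_better", "lower_better"):
                raise InvariantError("directions must be 'higher_better' or 'lower_better'")


def rank_genotypes(means: Mapping[str, Mapping], spec: RankingSpec) -> pd.DataFrame:
    """Rank accessions over multiple traits by weighted mean ranks.

    ``means`` maps methodology_id -> {accession_key: mean}. Per methodology,
    accessions are ranked under its direction (rank 1 = best, average ranks
    on ties); an accession missing a trait receives the worst rank and a
    flag. The composite is the weighted rank sum; rows are sorted ascending
    by composite. Per-trait ranks are retained so callers can tabulate
    specific deficiencies (ranks above a threshold of their choosing).
    """
    for mid in spec.methodology_ids:
        if mid not in means:
            raise InvariantError(f"no aggregated means for methodology {mid!r}")
        if len(means[mid]) < 2:
            raise InvariantError(f"methodology {mid!r} needs means for >= 2 accessions")
    accessions = sorted({a for mid in spec.methodology_ids for a in means[mid]})
    n = len(accessions)
    table: dict[str, list] = {"accession": accessions}
    composite = np.zeros(n)
    missing_any = np.zeros(n, dtype=bool)
    for mid, w, direction in zip(spec.methodology_ids, spec.weights, spec.directions):
        col = np.full(n, np.nan)
        present = [i for i, a in enumerate(accessions) if a in means[mid]]
        vals = np.asarray([float(means[mid][accessions[i]]) for i in present])
        signed = -vals if direction == "higher_better" else vals
        ranks = rankdata(signed, method="average")
        for i, r in zip(present, ranks):
            col[i] = r
        for i in range(n):
            if np.isnan(col[i]):
                col[i] = n  # worst rank
                missing_any[i] = True
        table[f"rank:{mid}"] = col
        composite += w * col
    table["composite"] = composite
    table["missing_trait"] = missing_any
    df = pd.DataFrame(table).sort_values(
        ["composite", "accession"], kind="stable", ignore_index=True
    )
    return df
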