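"""Synthetic working collection, trait catalog and simulated trials.

Everything the other modules need for testing and demonstration is generated
here deterministically from a seed: an oat-style working collection with
disjoint check and entry sets, a trait catalog covering every observation
method type, and simulated trial spreadsheets following the additive
phenotype model

    value(plot) = mu + g[accession] + b[block] + Normal(0, error_sd)

with genotype, block (small-scale environment) and error as the factors.
Block effects are centered to sum to zero -- the standard identifiability
constraint, under which check-based adjustment recovers mu + g exactly in
the noiseless case. The simulated spreadsheet is template-compatible, so the
full pipeline (design -> template -> fill -> import -> aggregate -> adjust)
runs from an empty store with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import (
    Accession,
    InvariantError,
    Method,
    Methodology,
    ScoreClass,
    ScoringKey,
    TraitDescriptor,
)
from .design import FieldPlan
from .fieldbook import ID_COLUMNS, methodology_header

__all__ = [
    "SimulationTruth",
    "Catalog",
    "make_collection",
    "make_trait_catalog",
    "make_truth",
    "simulate_trial",
]

_INSTITUTES = ("DEU146", "GBR004", "POL003", "FRA040", "CZE061")
_SPECIES = ("sativa", "strigosa", "byzantina", "abyssinica")
_STATUS = ("traditional cultivar", "breeding line", "advanced cultivar", "landrace")


def make_collection(
    n_accessions: int, n_checks: int = 0, seed: int = 0
) -> tuple[list[Accession], list[Accession]]:
    """Deterministic synthetic oat accessions: (entries, checks), disjoint.

    Checks are named standard cultivars (the replicated backbone of
    augmented designs); entries carry genebank-style numbers.
    """
    if n_accessions < 1:
        raise InvariantError("n_accessions must be >= 1")
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n_accessions):
        inst = _INSTITUTES[int(rng.integers(len(_INSTITUTES)))]
        entries.append(
            Accession(
                holding_institute_code=inst,
                accession_number=f"AVE-{i + 1:04d}",
                genus="Avena",
                species=str(rng.choice(_SPECIES)),
                accession_name=f"Entry {i + 1}",
                biological_status=str(rng.choice(_STATUS)),
            )
        )
    checks = [
        Accession(
            holding_institute_code="DEU146",
            accession_number=f"CHK-{j + 1:02d}",
            genus="Avena",
            species="sativa",
            accession_name=f"Standard {j + 1}",
            biological_status="advanced cultivar",
        )
        for j in range(n_checks)
    ]
    return entries, checks


@dataclass
class Catalog:
    traits: list[TraitDescriptor]
    scoring_keys: list[ScoringKey]
    methods: list[Method]
    methodologies: list[Methodology]

    def methodology(self, methodology_id: str) -> Methodology:
        for m in self.methodologies:
            if m.methodology_id == methodology_id:
                return m
        raise LookupError(methodology_id)


def make_trait_catalog() -> Catalog:
    """Fixed toy catalog covering every method type.

    One measurement (plant height, cm), one count (panicles per plot), one
    percentage (crown rust leaf area), one numeric 1-9 score (lodging) and
    one text score (growth habit); agronomy, biotic-stress and morphology
    groups; staged and unstaged methodologies.
    """
    height = TraitDescriptor("plant_height", "Plant height", "agronomy", plant_part="whole plant")
    panicles = TraitDescriptor("panicle_number", "Panicles per plot", "agronomy")
    rust = TraitDescriptor(
        "crown_rust", "Crown rust severity", "biotic_stress", plant_part="leaf",
        source_list="IBPGR Avena descriptors",
    )
    lodging = TraitDescriptor("lodging", "Lodging tendency", "agronomy")
    habit = TraitDescriptor("growth_habit", "Juvenile growth habit", "morphology")

    nine = ScoringKey(
        key_id="score_1_9",
        classes=tuple(ScoreClass(str(i), f"grade {i}", i) for i in range(1, 10)),
        direction="lower_is_better",
    )
    habit_key = ScoringKey(
        key_id="growth_habit_key",
        classes=(
            ScoreClass("E", "erect", 1),
            ScoreClass("I", "intermediate", 2),
            ScoreClass("P", "prostrate", 3),
        ),
    )

    m_height = Method("height_cm", "Ruler measurement", "measurement", unit="cm")
    m_panicle = Method("panicle_count", "Panicle count per plot", "count")
    m_rust_pct = Method("pct_leaf_area", "Percent leaf area affected", "percentage")
    m_lodging = Method("score_lodging", "Visual 1-9 score", "numeric_score", scoring_key=nine)
    m_habit = Method("habit_class", "Visual classification", "text_score", scoring_key=habit_key)

    methodologies = [
        Methodology("plant_height__height_cm", height, m_height, recommended_stage="BBCH 75"),
        Methodology("panicle_number__panicle_count", panicles, m_panicle, recommended_stage="BBCH 85"),
        Methodology("crown_rust__pct_leaf_area", rust, m_rust_pct, recommended_stage="BBCH 65"),
        Methodology("lodging__score_lodging", lodging, m_lodging, recommended_stage="BBCH 90"),
        Methodology("growth_habit__habit_class", habit, m_habit),  # unstaged: opportunistic
    ]
    return Catalog(
        traits=[height, panicles, rust, lodging, habit],
        scoring_keys=[nine, habit_key],
        methods=[m_height, m_panicle, m_rust_pct, m_lodging, m_habit],
        methodologies=methodologies,
    )


@dataclass
class SimulationTruth:
    """Ground truth of one simulated trial (reproducible from seed)."""

    mu: float
    genotype_effects: dict
    block_effects: dict
    error_sd: float
    seed: int

    def expected(self, accession_key, block: int) -> float:
        return self.mu + self.genotype_effects[accession_key] + self.block_effects[block]

    def to_json(self) -> dict:
        return {
            "mu": self.mu,
            "genotype_effects": {f"{k[0]}:{k[1]}": v for k, v in self.genotype_effects.items()},
            "block_effects": {str(k): v for k, v in self.block_effects.items()},
            "error_sd": self.error_sd,
            "seed": self.seed,
        }


def make_truth(
    plan: FieldPlan,
    mu: float = 100.0,
    genotype_sd: float = 10.0,
    block_sd: float = 2.0,
    error_sd: float = 1.0,
    seed: int = 0,
) -> SimulationTruth:
    """Draw genotype and block effects for a plan's accessions and blocks.

    Block effects are centered to mean zero (sum-to-zero constraint).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7]))
    accessions = sorted({p.accession_key for p in plan.data_plots})
    blocks = sorted({p.block for p in plan.data_plots})
    g = rng.normal(0.0, genotype_sd, size=len(accessions))
    b = rng.normal(0.0, block_sd, size=len(blocks))
    if len(blocks) > 1 and block_sd > 0:
        b = b - b.mean()
    else:
        b = np.zeros(len(blocks))
    return SimulationTruth(
        mu=mu,
        genotype_effects={a: float(x) for a, x in zip(accessions, g)},
        block_effects={blk: float(x) for blk, x in zip(blocks, b)},
        error_sd=error_sd,
        seed=seed,
    )


def simulate_trial(
    plan: FieldPlan,
    truth: SimulationTruth,
    methodology: Methodology,
    path: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Fill a fieldbook template with simulated values for one methodology.

    value = mu + g[accession] + b[block] + Normal(0, error_sd), drawn in
    fill order from a generator seeded by truth.seed, so the same truth
    yields an identical file. When ``path`` is given the frame is written as
    CSV (byte-deterministic).
    """
    if not plan.laid_out:
        raise InvariantError("plan must be laid out")
    missing = [
        p.accession_key for p in plan.data_plots if p.accession_key not in truth.genotype_effects
    ]
    if missing:
        raise InvariantError(f"truth missing genotype effects for {sorted(set(missing))}")
    missing_b = [p.block for p in plan.data_plots if p.block not in truth.block_effects]
    if missing_b:
        raise InvariantError(f"truth missing block effects for blocks {sorted(set(missing_b))}")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x51]))
    exp_label = "/".join(map(str, plan.experiment_key))
    header = methodology_header(methodology)
    rows = []
    for p in plan.data_plots:
        noise = rng.normal(0.0, truth.error_sd) if truth.error_sd > 0 else 0.0
        value = truth.expected(p.accession_key, p.block) + noise
        rows.append(
            {
                "experiment": exp_label,
                "lane": p.lane,
                "plot": p.plot,
                "block": p.block,
                "accession_number": p.accession_key[1],
                "holding_institute_code": p.accession_key[0],
                header: float(value),
            }
        )
    df = pd.DataFrame(rows, columns=list(ID_COLUMNS) + [header])
    if path is not None:
        # default float formatting is repr-exact, so round-trips are lossless
        df.to_csv(path, index=False)
    return df
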