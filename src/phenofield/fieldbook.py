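"""Field books: sowing lists, field lists and observation templates.

From a laid-out field plan the module derives the working documents of a
trial season: a sowing list with seed amounts scaled by germination test
results, a field list of all plots for demonstration, and observation
templates -- spreadsheets with one row per plot and one empty column per
selected methodology, ordered by the phenological stage recommended for
observation so the column order follows the season. Template column headers
use the machine-parseable grammar ``<trait_id>__<method_id>`` so a filled
template imports with zero mapping effort.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .core import InvariantError, Methodology
from .design import FieldPlan

__all__ = [
    "TemplateSpec",
    "ID_COLUMNS",
    "methodology_header",
    "parse_header",
    "sowing_list",
    "field_list",
    "select_methodologies",
    "observation_template",
    "write_template",
]

#: identifier columns heading every observation template
ID_COLUMNS = (
    "experiment",
    "lane",
    "plot",
    "block",
    "accession_number",
    "holding_institute_code",
)

_HEADER_RE = re.compile(r"^(?P<trait>[^_].*?)__(?P<method>.+)$")


def methodology_header(m: Methodology) -> str:
    return f"{m.trait.trait_id}__{m.method.method_id}"


def parse_header(head: str) -> Optional[tuple[str, str]]:
    """Split a template-grammar header into (trait_id, method_id), else None."""
    match = _HEADER_RE.match(head.strip())
    return (match["trait"], match["method"]) if match else None


@dataclass(frozen=True)
class TemplateSpec:
    plan: FieldPlan
    methodologies: tuple[Methodology, ...]
    sort_by_stage: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "methodologies", tuple(self.methodologies))
        if not self.methodologies:
            raise InvariantError("template needs at least one methodology")


def sowing_list(
    plan: FieldPlan,
    seeds_per_plot: int,
    germination: Mapping[tuple, float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seed amounts per plot and per accession, scaled by germination rate.

    seed_amount = ceil(seeds_per_plot / germination_rate). Accessions with a
    missing or zero rate are flagged and get a null amount (no division).
    Orientation plots are excluded (they are not sown with trial seed).
    Returns (per-plot table, per-accession summary).
    """
    rows = []
    for p in plan.data_plots:
        rate = germination.get(p.accession_key)
        flagged = rate is None or rate == 0
        if rate is not None and not 0 <= rate <= 1:
            raise InvariantError(f"germination rate {rate} outside [0, 1]")
        amount = None if flagged else int(math.ceil(seeds_per_plot / rate))
        rows.append(
            {
                "lane": p.lane,
                "plot": p.plot,
                "block": p.block,
                "holding_institute_code": p.accession_key[0],
                "accession_number": p.accession_key[1],
                "germination_rate": rate,
                "seed_amount": amount,
                "flagged": flagged,
            }
        )
    plots = pd.DataFrame(rows)
    summary = (
        plots.groupby(["holding_institute_code", "accession_number"], dropna=False)
        .agg(
            n_plots=("seed_amount", "size"),
            seed_amount=("seed_amount", lambda s: s.sum(min_count=len(s))),
            flagged=("flagged", "any"),
        )
        .reset_index()
    )
    return plots, summary


def field_list(plan: FieldPlan) -> pd.DataFrame:
    """One row per plot in fill order: position, block, role, accession."""
    if not plan.laid_out:
        raise InvariantError("plan must be laid out")
    rows = []
    for p in plan.plots:
        rows.append(
            {
                "lane": p.lane,
                "plot": p.plot,
                "block": p.block,
                "role": p.role,
                "holding_institute_code": p.accession_key[0] if p.accession_key else "",
                "accession_number": p.accession_key[1] if p.accession_key else "",
            }
        )
    return pd.DataFrame(rows)


def _stage_sort_key(stage: Optional[str]) -> tuple:
    if stage is None:
        return (1, float("inf"), "")
    digits = re.search(r"\d+(?:\.\d+)?", stage)
    return (0, float(digits.group()) if digits else float("inf"), stage)


def select_methodologies(
    catalog: Sequence[Methodology], checked_ids: Sequence[str]
) -> list[Methodology]:
    """Resolve checked ids against a catalog, ordered by recommended stage.

    Ascending BBCH-style stage (numeric part), unstaged methodologies last,
    ties broken by trait name; the sort is stable and deterministic.
    """
    by_id = {m.methodology_id: m for m in catalog}
    missing = [i for i in checked_ids if i not in by_id]
    if missing:
        raise LookupError(f"unknown methodology ids: {missing}")
    selected = [by_id[i] for i in checked_ids]
    return sorted(
        selected,
        key=lambda m: _stage_sort_key(m.recommended_stage) + (m.trait.name, m.methodology_id),
    )


def observation_template(spec: TemplateSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the data-entry template and its methodology legend.

    The template has one row per non-orientation plot: the identifier
    columns, then one empty column per methodology headed by the
    ``trait__method`` label. The legend describes each column (trait,
    method, type, unit or scoring key, recommended stage) -- the analog of
    the methodology description page on printed field books.
    """
    plan = spec.plan
    if not plan.laid_out:
        raise InvariantError("plan must be laid out")
    methodologies = (
        select_methodologies(spec.methodologies, [m.methodology_id for m in spec.methodologies])
        if spec.sort_by_stage
        else list(spec.methodologies)
    )
    headers = [methodology_header(m) for m in methodologies]
    if len(set(headers)) != len(headers):
        raise InvariantError("duplicate methodology columns in template")
    exp_label = "/".join(map(str, plan.experiment_key))
    rows = []
    for p in plan.data_plots:
        row = {
            "experiment": exp_label,
            "lane": p.lane,
            "plot": p.plot,
            "block": p.block,
            "accession_number": p.accession_key[1],
            "holding_institute_code": p.accession_key[0],
        }
        row.update({h: None for h in headers})
        rows.append(row)
    template = pd.DataFrame(rows, columns=list(ID_COLUMNS) + headers)
    legend = pd.DataFrame(
        [
            {
                "column": methodology_header(m),
                "methodology_id": m.methodology_id,
                "trait": m.trait.name,
                "trait_group": m.trait.trait_group,
                "method": m.method.name,
                "observation_type": m.method.method_type,
                "unit_or_key": m.method.unit
                or (m.method.scoring_key.key_id if m.method.scoring_key else ""),
                "recommended_stage": m.recommended_stage or "",
            }
            for m in methodologies
        ]
    )
    return template, legend


def write_template(
    spec: TemplateSpec, path: Union[str, Path], fmt: Optional[str] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write the template to CSV (legend as sibling ``*_legend.csv``) or to
    XLSX with the legend on a second sheet. Returns (template, legend)."""
    template, legend = observation_template(spec)
    path = Path(path)
    fmt = fmt or ("xlsx" if path.suffix.lower() == ".xlsx" else "csv")
    if fmt == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as xl:
            template.to_excel(xl, sheet_name="observations", index=False)
            legend.to_excel(xl, sheet_name="methodology legend", index=False)
    elif fmt == "csv":
        template.to_csv(path, index=False)
        legend.to_csv(path.with_name(path.stem + "_legend.csv"), index=False)
    else:
        raise InvariantError("fmt must be 'csv' or 'xlsx'")
    return template, legend
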