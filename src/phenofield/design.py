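"""Randomized field-plan generation.

Two designs are supported. The randomized complete block design (RCBD)
replicates every entry once per block. The augmented block design replicates
only the checks (standard cultivars) -- once in every block, forming the
statistical backbone -- while test entries appear once overall, distributed
as evenly as possible across blocks; entry values are later adjusted by
check-estimated block effects (see :mod:`phenofield.stats`).

Randomization is a Fisher-Yates shuffle per block, with one PRNG stream per
block index derived from the single request seed, so a plan is a pure
function of (request, seed). Plans are laid out on a (lane, plot) matrix in
row-major or serpentine fill order; orientation plots (unsown aids for
checking the sowing operation) can be interleaved every k data plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import InvariantError, Plot

__all__ = [
    "DesignRequest",
    "PlanPlot",
    "FieldPlan",
    "randomize_block",
    "randomize_augmented",
    "randomize",
    "insert_orientation",
    "layout",
    "render_plan",
]

AccKey = tuple[str, str]


@dataclass(frozen=True)
class PlanPlot:
    """One plan position in fill order; coordinates assigned by layout()."""

    block: int
    role: str  # entry | check | orientation
    accession_key: Optional[AccKey] = None
    lane: Optional[int] = None
    plot: Optional[int] = None


@dataclass
class FieldPlan:
    """A randomized plan: ordered plots plus the geometry used to lay them out."""

    experiment_key: tuple[str, str, str, str]
    design_type: str
    plots: list[PlanPlot]
    design_seed: int
    plots_per_lane: Optional[int] = None
    fill_order: str = "row_major"

    @property
    def laid_out(self) -> bool:
        return bool(self.plots) and all(p.lane is not None for p in self.plots)

    @property
    def data_plots(self) -> list[PlanPlot]:
        return [p for p in self.plots if p.role != "orientation"]

    def accession_at(self, lane: int, plot: int) -> Optional[AccKey]:
        for p in self.plots:
            if p.lane == lane and p.plot == plot:
                return p.accession_key
        return None

    def to_plot_rows(self) -> list[Plot]:
        """Persistable core Plot rows (requires layout)."""
        if not self.laid_out:
            raise InvariantError("plan must be laid out before persisting")
        return [
            Plot(
                experiment_key=self.experiment_key,
                lane=p.lane,
                plot=p.plot,
                block=p.block,
                plot_role=p.role,
                accession_key=p.accession_key,
            )
            for p in self.plots
        ]


@dataclass(frozen=True)
class DesignRequest:
    experiment_key: tuple[str, str, str, str]
    design_type: str
    entry_accessions: tuple[AccKey, ...]
    check_accessions: tuple[AccKey, ...] = ()
    blocks: int = 1
    plots_per_lane: int = 1
    orientation_every: Optional[int] = None
    fill_order: str = "row_major"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "experiment_key", tuple(self.experiment_key))
        object.__setattr__(self, "entry_accessions", tuple(map(tuple, self.entry_accessions)))
        object.__setattr__(self, "check_accessions", tuple(map(tuple, self.check_accessions)))
        if self.design_type not in ("block", "augmented"):
            raise InvariantError("design_type must be 'block' or 'augmented' for randomization")
        if self.blocks < 1:
            raise InvariantError("blocks must be >= 1")
        if self.plots_per_lane < 1:
            raise InvariantError("plots_per_lane must be >= 1")
        if self.fill_order not in ("row_major", "serpentine"):
            raise InvariantError("fill_order must be 'row_major' or 'serpentine'")
        if self.orientation_every is not None and self.orientation_every < 1:
            raise InvariantError("orientation_every must be >= 1")
        overlap = set(self.entry_accessions) & set(self.check_accessions)
        if overlap:
            raise InvariantError(f"accessions listed as both check and entry: {sorted(overlap)}")
        if self.design_type == "augmented":
            if not self.check_accessions:
                raise InvariantError("augmented design requires at least one check")
        else:
            if not self.entry_accessions:
                raise InvariantError("block design requires entries")
            if self.blocks < 2:
                raise InvariantError("block design requires replications >= 2")


def _block_rng(seed: int, block: int) -> np.random.Generator:
    # independent named stream per block index, all derived from one seed
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(block + 1)[block])


def randomize_block(req: DesignRequest) -> FieldPlan:
    """RCBD: every entry exactly once per block, within-block order shuffled.

    ``req.blocks`` is the number of replications; each block occupies a
    contiguous range of the fill sequence.
    """
    if req.design_type != "block":
        raise InvariantError("randomize_block requires design_type='block'")
    plots: list[PlanPlot] = []
    for b in range(1, req.blocks + 1):
        members = list(req.entry_accessions) + list(req.check_accessions)
        roles = {a: ("check" if a in req.check_accessions else "entry") for a in members}
        order = _block_rng(req.seed, b - 1).permutation(len(members))
        for i in order:
            plots.append(PlanPlot(block=b, role=roles[members[i]], accession_key=members[i]))
    return FieldPlan(
        experiment_key=req.experiment_key,
        design_type="block",
        plots=plots,
        design_seed=req.seed,
        fill_order=req.fill_order,
    )


def randomize_augmented(req: DesignRequest) -> FieldPlan:
    """Augmented block design: checks once per block, entries once overall.

    Entries are assigned to blocks by a seeded shuffle followed by
    round-robin, so block sizes differ by at most one; each block is then
    shuffled internally with its own stream.
    """
    if req.design_type != "augmented":
        raise InvariantError("randomize_augmented requires design_type='augmented'")
    if req.blocks * len(req.check_accessions) == 0:
        raise InvariantError("augmented design needs blocks >= 1 and checks >= 1")

    entry_rng = np.random.default_rng(np.random.SeedSequence([req.seed, 0x45]))
    shuffled = [req.entry_accessions[i] for i in entry_rng.permutation(len(req.entry_accessions))]
    per_block: list[list[AccKey]] = [[] for _ in range(req.blocks)]
    for i, acc in enumerate(shuffled):
        per_block[i % req.blocks].append(acc)

    plots: list[PlanPlot] = []
    for b in range(1, req.blocks + 1):
        members = [(a, "check") for a in req.check_accessions] + [
            (a, "entry") for a in per_block[b - 1]
        ]
        order = _block_rng(req.seed, b - 1).permutation(len(members))
        for i in order:
            acc, role = members[i]
            plots.append(PlanPlot(block=b, role=role, accession_key=acc))
    return FieldPlan(
        experiment_key=req.experiment_key,
        design_type="augmented",
        plots=plots,
        design_seed=req.seed,
        fill_order=req.fill_order,
    )


def randomize(req: DesignRequest) -> FieldPlan:
    """Dispatch to the requested design, apply orientation plots and layout."""
    plan = randomize_block(req) if req.design_type == "block" else randomize_augmented(req)
    if req.orientation_every:
        plan = insert_orientation(plan, req.orientation_every)
    return layout(plan, req.plots_per_lane, req.fill_order)


def insert_orientation(plan: FieldPlan, every_k: int) -> FieldPlan:
    """Insert an orientation plot after every k-th data plot in fill order.

    Data plots keep their relative order; coordinates are cleared (re-layout
    required). Orientation plots inherit the block of the preceding data plot.
    """
    if every_k < 1:
        raise InvariantError("every_k must be >= 1")
    out: list[PlanPlot] = []
    n_data = 0
    for p in plan.data_plots:
        out.append(replace(p, lane=None, plot=None))
        n_data += 1
        if n_data % every_k == 0:
            out.append(PlanPlot(block=p.block, role="orientation"))
    return FieldPlan(
        experiment_key=plan.experiment_key,
        design_type=plan.design_type,
        plots=out,
        design_seed=plan.design_seed,
        plots_per_lane=plan.plots_per_lane,
        fill_order=plan.fill_order,
    )


def layout(plan: FieldPlan, plots_per_lane: int, fill_order: str = "row_major") -> FieldPlan:
    """Map the fill sequence onto the (lane, plot) matrix, lane by lane.

    row_major numbers plots 1..k left-to-right in every lane; serpentine
    reverses the numbering direction in even lanes (k..1), matching how a
    sowing machine traverses the field.
    """
    if plots_per_lane < 1:
        raise InvariantError("plots_per_lane must be >= 1")
    if fill_order not in ("row_major", "serpentine"):
        raise InvariantError("fill_order must be 'row_major' or 'serpentine'")
    out: list[PlanPlot] = []
    for i, p in enumerate(plan.plots):
        lane = i // plots_per_lane + 1
        pos = i % plots_per_lane
        if fill_order == "serpentine" and lane % 2 == 0:
            number = plots_per_lane - pos
        else:
            number = pos + 1
        out.append(replace(p, lane=lane, plot=number))
    return FieldPlan(
        experiment_key=plan.experiment_key,
        design_type=plan.design_type,
        plots=out,
        design_seed=plan.design_seed,
        plots_per_lane=plots_per_lane,
        fill_order=fill_order,
    )


def render_plan(plan: FieldPlan, mode: str = "list") -> pd.DataFrame:
    """Render a laid-out plan as a lanes x plots matrix or a plot list.

    Matrix cells hold accession labels, ``X`` for orientation plots, empty
    string for unused positions. Both renderings are CSV-writable.
    """
    if not plan.laid_out:
        raise InvariantError("plan must be laid out before rendering")
    if mode == "list":
        rows = [
            {
                "lane": p.lane,
                "plot": p.plot,
                "block": p.block,
                "role": p.role,
                "holding_institute_code": p.accession_key[0] if p.accession_key else "",
                "accession_number": p.accession_key[1] if p.accession_key else "",
            }
            for p in plan.plots
        ]
        return pd.DataFrame(rows)
    if mode == "matrix":
        lanes = sorted({p.lane for p in plan.plots})
        numbers = sorted({p.plot for p in plan.plots})
        grid = pd.DataFrame("", index=pd.Index(lanes, name="lane"), columns=numbers)
        for p in plan.plots:
            if p.role == "orientation":
                grid.loc[p.lane, p.plot] = "X"
            else:
                grid.loc[p.lane, p.plot] = f"{p.accession_key[0]}:{p.accession_key[1]}"
        return grid
    raise InvariantError("mode must be 'list' or 'matrix'")
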