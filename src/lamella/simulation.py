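"""The grow / divide / relax time-step loop and run orchestration.

A run starts from a single cell of unit size at the origin and iterates
a fixed number of steps.  Each step, in order:

1. every cell grows using the pressure stored at the end of the
   previous step (zero at the very first step);
2. cells that have doubled their birth volume divide, swept in
   ascending id order over the cells existing at sweep start (daughters
   created during the sweep are not re-examined until the next step);
3. the interaction pair list is rebuilt;
4. N synchronous steepest-descent sweeps relax the forces;
5. the virial pressure of every cell is computed and stored for the
   next step's growth stage.

All randomness flows through one seeded generator with a fixed draw
order (growth draws in ascending id order, then division-direction
draws in ascending id order), so a (params, seed) pair pins down the
whole trajectory.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_analysis, mechanics
from .growth_division import DivisionEvent, divide_cell, division_direction, grow_all
from .model_core import DIVISION_RATIO, ModelParams, SummaryStats, Tissue, validate_params

__all__ = ["RunResult", "init_tissue", "step", "run"]


@dataclass
class RunResult:
    """Everything a finished run produced."""

    tissue: Tissue
    stats: list[SummaryStats]
    events: list[DivisionEvent]
    params: ModelParams
    #: cell count after every step, stats[i].n_cells convenience view
    n_cells_trace: list[int] = field(default_factory=list)


def init_tissue(p: ModelParams) -> Tissue:
    """A single cell with R = R_birth = 1 at the origin, zero pressure."""
    t = Tissue(p)
    t.add_cell(np.zeros(3), R=1.0, R_birth=1.0, P=0.0)
    return t


def step(t: Tissue, p: ModelParams) -> list[DivisionEvent]:
    """Advance the tissue one iteration in place; returns the divisions."""
    grow_all(t, p)

    due_ids = [int(i) for i in t.ids[t.R >= DIVISION_RATIO * t.R_birth]]
    events: list[DivisionEvent] = []
    for mother in due_ids:
        c = t.cell(mother)
        s_hat = division_direction(c, t, p)
        events.append(divide_cell(t, mother, s_hat, p))

    pl = mechanics.build_pair_list(t, p.skin)
    try:
        mechanics.relax(t, pl, p.n_relax, p.delta, p.k)
    except FloatingPointError as exc:
        raise FloatingPointError(f"step {t.step + 1}: {exc}") from exc
    t.P = mechanics.all_pressures(t, pl, p.k)
    t.step += 1
    return events


def _collect_stats(t: Tissue, p: ModelParams, n_divisions: int) -> SummaryStats:
    pl = mechanics.build_pair_list(t, p.skin)
    return SummaryStats(
        step=t.step,
        n_cells=t.n_cells,
        n_bonds=t.n_bonds,
        n_divisions_this_step=n_divisions,
        P_min=float(t.P.min()),
        P_mean=float(t.P.mean()),
        P_max=float(t.P.max()),
        mean_coordination=2.0 * t.n_bonds / t.n_cells,
        total_potential=mechanics.total_potential(t, pl, p.k),
    )


def run(
    p: ModelParams,
    out_dir: str | Path | None = None,
    snapshot_every: int = 0,
    render: bool = False,
) -> RunResult:
    """Run ``p.n_steps`` steps from a single cell.

    When ``out_dir`` is given, writes per-step statistics
    (``stats.csv``), the lineage log (``lineage.csv``), the final
    snapshot, and optionally intermediate snapshots every
    ``snapshot_every`` steps (with PNG frames if ``render``).  The whole
    trajectory is reproducible from (params, seed).
    """
    p = validate_params(p)
    t = init_tissue(p)
    stats: list[SummaryStats] = []
    all_events: list[DivisionEvent] = []

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for _ in range(p.n_steps):
        events = step(t, p)
        all_events.extend(events)
        stats.append(_collect_stats(t, p, len(events)))
        if out is not None and snapshot_every and t.step % snapshot_every == 0:
            snap = out / f"snapshot_{t.step:05d}"
            io_analysis.write_snapshot(t, snap)
            if render:
                io_analysis.render_frame(t, snap / "frame.png")

    if out is not None:
        _write_stats_csv(stats, out / "stats.csv")
        _write_lineage_csv(all_events, out / "lineage.csv")
        io_analysis.write_snapshot(t, out / "final")
        if render:
            io_analysis.render_frame(t, out / "final" / "frame.png")

    return RunResult(
        tissue=t,
        stats=stats,
        events=all_events,
        params=p,
        n_cells_trace=[s.n_cells for s in stats],
    )


_STATS_HEADER = [
    "step",
    "n_cells",
    "n_bonds",
    "n_divisions",
    "P_min",
    "P_mean",
    "P_max",
    "mean_coordination",
    "total_potential",
]


def _write_stats_csv(stats: list[SummaryStats], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_STATS_HEADER)
        for s in stats:
            w.writerow(
                [
                    s.step,
                    s.n_cells,
                    s.n_bonds,
                    s.n_divisions_this_step,
                    f"{s.P_min:.17g}",
                    f"{s.P_mean:.17g}",
                    f"{s.P_max:.17g}",
                    f"{s.mean_coordination:.17g}",
                    f"{s.total_potential:.17g}",
                ]
            )


def _write_lineage_csv(events: list[DivisionEvent], path: Path) -> None:
    """Division log: geometry of every split plus the bond audit trail."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["step", "mother", "daughter1", "daughter2", "s_x", "s_y", "s_z",
             "bonds_added", "bonds_removed"]
        )
        for e in events:
            added = removed = ""
            if e.rewiring is not None:
                added = ";".join(f"{a}-{b}" for a, b in e.rewiring.added)
                removed = ";".join(f"{a}-{b}" for a, b in e.rewiring.removed)
            w.writerow(
                [
                    e.step,
                    e.mother_id,
                    e.daughter_ids[0],
                    e.daughter_ids[1],
                    f"{e.s_hat[0]:.17g}",
                    f"{e.s_hat[1]:.17g}",
                    f"{e.s_hat[2]:.17g}",
                    added,
                    removed,
                ]
            )
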