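"""Snapshot readers/writers, rendering and summary statistics.

Snapshots are plain CSV (a cell table and a bond table) so they diff
cleanly and read back from any language; positions are serialised with
17 significant digits so a write/read round trip is exact.  The bond
network can also be exported as GraphML for graph tooling.  Rendering
draws each cell as a circle of radius R (the size parameter) with a
line per bond, filled with a heat-map colour of its pressure: blue at
-1, green at 0, yellow at +1/2, red at +1, clamped outside [-1, 1].
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
from matplotlib.collections import LineCollection
from matplotlib.patches import Circle

from . import mechanics
from .model_core import SummaryStats, Tissue

__all__ = [
    "write_snapshot",
    "read_snapshot",
    "write_graphml",
    "pressure_colour",
    "render_frame",
    "summary_stats",
    "bond_graph",
    "perimeter_cells",
    "graph_depth_from_perimeter",
    "pressure_depth_contrast",
]

_CELL_COLS = ["id", "x", "y", "z", "R", "R_birth", "P"]


def write_snapshot(t: Tissue, path: str | Path) -> Path:
    """Write ``cells.csv``, ``bonds.csv`` and ``meta.json`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cells = pd.DataFrame(
        {
            "id": t.ids,
            "x": t.pos[:, 0],
            "y": t.pos[:, 1],
            "z": t.pos[:, 2],
            "R": t.R,
            "R_birth": t.R_birth,
            "P": t.P,
        }
    )
    cells.to_csv(path / "cells.csv", index=False, float_format="%.17g")
    bonds = pd.DataFrame(sorted(t.bonds), columns=["id_i", "id_j"])
    bonds.to_csv(path / "bonds.csv", index=False)
    (path / "meta.json").write_text(json.dumps({"step": t.step, "next_id": t.next_id}))
    return path


def read_snapshot(path: str | Path) -> Tissue:
    """Rebuild a tissue from a snapshot directory.

    Raises ``ValueError`` naming the offending row for duplicate ids or
    bonds whose endpoints do not resolve.
    """
    path = Path(path)
    cells = pd.read_csv(path / "cells.csv", float_precision="round_trip")
    missing = [c for c in _CELL_COLS if c not in cells.columns]
    if missing:
        raise ValueError(f"{path / 'cells.csv'}: missing columns {missing}")
    if cells["id"].duplicated().any():
        dup = cells.loc[cells["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"{path / 'cells.csv'}: duplicate cell id {dup}")
    cells = cells.sort_values("id")

    t = Tissue()
    t.ids = cells["id"].to_numpy(dtype=np.int64)
    t.pos = cells[["x", "y", "z"]].to_numpy(dtype=np.float64)
    t.R = cells["R"].to_numpy(dtype=np.float64)
    t.R_birth = cells["R_birth"].to_numpy(dtype=np.float64)
    t.P = cells["P"].to_numpy(dtype=np.float64)
    if np.any(t.R <= 0) or np.any(t.R_birth <= 0):
        bad = int(t.ids[np.argmax((t.R <= 0) | (t.R_birth <= 0))])
        raise ValueError(f"{path / 'cells.csv'}: non-positive size parameter on cell {bad}")
    t.next_id = int(t.ids.max()) + 1 if t.ids.size else 0

    bonds = pd.read_csv(path / "bonds.csv")
    known = set(t.ids.tolist())
    for _, row in bonds.iterrows():
        a, b = int(row["id_i"]), int(row["id_j"])
        if a == b:
            raise ValueError(f"{path / 'bonds.csv'}: self-bond on cell {a}")
        if a not in known or b not in known:
            raise ValueError(f"{path / 'bonds.csv'}: bond ({a}, {b}) references a missing cell")
        t.bonds.add((a, b) if a < b else (b, a))

    meta_path = path / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        t.step = int(meta.get("step", 0))
        t.next_id = int(meta.get("next_id", t.next_id))
    return t


def bond_graph(t: Tissue) -> nx.Graph:
    """The permanent bond network as a networkx graph with R/P attributes."""
    g = nx.Graph()
    for i, cid in enumerate(t.ids):
        g.add_node(int(cid), R=float(t.R[i]), P=float(t.P[i]))
    g.add_edges_from(t.bonds)
    return g


def write_graphml(t: Tissue, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(bond_graph(t), path)
    return path


#: heat-map anchors: pressure -> RGB in [0, 1]
_ANCHORS = [
    (-1.0, (0.0, 0.0, 1.0)),  # blue
    (0.0, (0.0, 1.0, 0.0)),  # green
    (0.5, (1.0, 1.0, 0.0)),  # yellow
    (1.0, (1.0, 0.0, 0.0)),  # red
]


def pressure_colour(P: float) -> tuple[float, float, float]:
    """Piecewise-linear heat map blue(-1) -> green(0) -> yellow -> red(+1).

    Pressures outside [-1, 1] are clamped to the end colours.
    """
    P = float(np.clip(P, -1.0, 1.0))
    for (p0, c0), (p1, c1) in zip(_ANCHORS[:-1], _ANCHORS[1:]):
        if P <= p1:
            w = (P - p0) / (p1 - p0)
            return tuple(a + w * (b - a) for a, b in zip(c0, c1))
    return _ANCHORS[-1][1]  # pragma: no cover


def render_frame(
    t: Tissue,
    path: str | Path,
    outlines: bool = True,
    depth_shade: bool = False,
    dpi: int = 150,
) -> Path:
    """Render the tissue to a PNG: one circle per cell, one line per bond.

    Circles have radius R in world units and are filled with the
    pressure heat map.  ``outlines=False`` drops the circle perimeters
    so the bond network stands out in large samples; ``depth_shade``
    darkens cells further back in z (a depth cue for 3D samples).  The
    world-to-pixel scale auto-fits the bounding box with a 5% margin,
    so a fixed tissue renders identically every time.
    """
    if t.n_cells == 0:
        raise ValueError("cannot render an empty tissue")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    lo = (t.pos[:, :2] - t.R[:, None]).min(axis=0)
    hi = (t.pos[:, :2] + t.R[:, None]).max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    margin = 0.05 * span

    if depth_shade and t.n_cells > 1:
        z = t.pos[:, 2]
        depth = (z - z.min()) / max(z.max() - z.min(), 1e-12)
        shade = 0.4 + 0.6 * depth  # far back -> 0.4, front -> 1.0
    else:
        shade = np.ones(t.n_cells)

    order = np.argsort(t.pos[:, 2])  # paint back-to-front
    fig, ax = plt.subplots(figsize=(6, 6), dpi=dpi)
    segs = [(t.pos[i, :2], t.pos[j, :2]) for i, j in t.bond_array()]
    if segs:
        ax.add_collection(LineCollection(segs, colors="0.3", linewidths=0.5, zorder=1))
    for i in order:
        colour = tuple(c * shade[i] for c in pressure_colour(float(t.P[i])))
        ax.add_patch(
            Circle(
                t.pos[i, :2],
                radius=float(t.R[i]),
                facecolor=colour,
                edgecolor="black" if outlines else "none",
                linewidth=0.4,
                zorder=2,
            )
        )
    ax.set_xlim(lo[0] - margin[0], hi[0] + margin[0])
    ax.set_ylim(lo[1] - margin[1], hi[1] + margin[1])
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=dpi, metadata={"Software": None})
    plt.close(fig)
    return path


def summary_stats(t: Tissue, k: float = 1.0, skin: float = 0.5, n_divisions: int = 0) -> SummaryStats:
    """Aggregate observables of the current state."""
    pl = mechanics.build_pair_list(t, skin)
    return SummaryStats(
        step=t.step,
        n_cells=t.n_cells,
        n_bonds=t.n_bonds,
        n_divisions_this_step=n_divisions,
        P_min=float(t.P.min()) if t.n_cells else 0.0,
        P_mean=float(t.P.mean()) if t.n_cells else 0.0,
        P_max=float(t.P.max()) if t.n_cells else 0.0,
        mean_coordination=2.0 * t.n_bonds / t.n_cells if t.n_cells else 0.0,
        total_potential=mechanics.total_potential(t, pl, k),
    )


#: disc inflation used to outline a planar sample.  1.5 R covers the
#: interstices of a triangular packing at rest spacing 2R (their
#: circumradius is 2R/sqrt(3) ~ 1.15 R), so only the true free surface
#: survives as the exterior ring.
_OUTLINE_INFLATION = 1.5


def perimeter_cells(t: Tissue) -> np.ndarray:
    """Ids of cells on the free boundary of a planar sample.

    The sample outline is the exterior ring of the union of inflated
    cell discs (radius 1.5 R); a cell whose inflated disc reaches that
    ring is a perimeter cell.  Interior holes in the union (the small
    interstices of a close packing) are deliberately ignored.  Only
    meaningful for planar tissues.
    """
    from shapely.geometry import MultiPolygon, Point, Polygon
    from shapely.ops import unary_union

    radii = _OUTLINE_INFLATION * t.R
    discs = [Point(x, y).buffer(r, quad_segs=32) for (x, y), r in zip(t.pos[:, :2], radii)]
    union = unary_union(discs)
    polys = list(union.geoms) if isinstance(union, MultiPolygon) else [union]
    exterior = unary_union([Polygon(p.exterior).boundary for p in polys])
    on_edge = [
        bool(exterior.distance(Point(x, y)) <= r + 1e-9)
        for (x, y), r in zip(t.pos[:, :2], radii)
    ]
    return t.ids[np.asarray(on_edge, dtype=bool)]


def graph_depth_from_perimeter(t: Tissue) -> dict[int, int]:
    """Graph distance of every cell to the nearest perimeter cell."""
    g = bond_graph(t)
    sources = [int(i) for i in perimeter_cells(t)]
    if not sources:
        return {int(i): 0 for i in t.ids}
    depth = nx.multi_source_dijkstra_path_length(g, sources, weight=None)
    # unreachable cells (isolated components with no perimeter member) sit at 0
    return {int(i): int(depth.get(int(i), 0)) for i in t.ids}


def pressure_depth_contrast(t: Tissue) -> tuple[float, float]:
    """Mean perimeter depth of the top vs bottom pressure decile.

    Returns (depth of the 10% highest-pressure cells, depth of the 10%
    lowest).  In compact high-P0 samples squeezed interior cells carry
    the pressure, so the first number exceeds the second.
    """
    depth = graph_depth_from_perimeter(t)
    order = np.argsort(t.P)
    n = max(1, t.n_cells // 10)
    low_ids = t.ids[order[:n]]
    high_ids = t.ids[order[-n:]]
    high = float(np.mean([depth[int(i)] for i in high_ids]))
    low = float(np.mean([depth[int(i)] for i in low_ids]))
    return high, low
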