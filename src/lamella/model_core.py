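"""Domain types, parameter defaults and the tissue container.

A tissue sample is a set of point cells, each carrying a position ``r``
(a 3-vector in model length units, one unit being roughly one cell
diameter's worth of radius), a size parameter ``R``, the size parameter
``R_birth`` it had when it was created, and the virial pressure ``P``
from the most recent relaxation.  Cells that share a cell wall are
joined by a *permanent* bond — the middle lamella glues plant cells
together irreversibly — so the bond network only ever changes inside a
division event.

Internally the cell table is kept in flat numpy arrays sorted by cell
id.  Ids are allocated monotonically and never reused: a dividing
mother's id is retired and two fresh ids are created, which keeps the
lineage log unambiguous and keeps the arrays sorted by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "CellState",
    "ModelParams",
    "SummaryStats",
    "Tissue",
    "default_params",
    "validate_params",
    "params_from_config",
]

#: Volume-doubling threshold on the size parameter: a cell divides once
#: R >= 2**(1/3) * R_birth.
DIVISION_RATIO = 2.0 ** (1.0 / 3.0)


@dataclass(frozen=True)
class CellState:
    """One cell: identity, position, size and last relaxed pressure."""

    id: int
    r: np.ndarray  # 3-vector, model length units
    R: float  # size parameter (radius-like)
    R_birth: float  # size parameter at creation
    P: float = 0.0  # virial pressure from the last relaxation


@dataclass
class ModelParams:
    """All model parameters plus mode flags and the seed.

    Defaults are the reference parameter set: alpha=0.4, gamma=0.01,
    epsilon=0.85, tau=0.4, k=1, n_relax=10, p0=1 and a random division
    plane.  ``delta`` defaults to 0.1 with n_relax=10 (the combination
    actually used for the production runs; the single-sweep optimum for
    an isolated spring would be 1/(2k) = 0.5, but with many overlapping
    neighbours that overshoots, so several smaller sweeps are taken).

    Parameters
    ----------
    alpha : displacement size at division; daughters are placed at
        +- alpha * R_mother along the division vector.
    gamma : relative growth rate per step (sets the time scale).
    delta : steepest-descent displacement per unit force.
    epsilon : double-connectedness ratio in (0, 1); both daughters
        inherit a mother's bond when the daughter-neighbour distance
        ratio lies in (epsilon, 1/epsilon).
    tau : tetrahedron thickness fraction; a division 4-clique thinner
        than tau times the daughter separation loses a diagonal bond.
    k : Hookean force constant.
    n_relax : number of steepest-descent sweeps per time step.
    p0 : width of the pressure moderation of growth.
    division_plane : 'random' or 'orthogonal' (normal perpendicular to
        the link to the nearest connected neighbour).
    planar : restrict division vectors to the xy-plane, so the sample
        stays two-dimensional inside the 3D engine.
    seed : RNG seed; identical (params, seed) gives identical runs.
    n_steps : number of grow/divide/relax iterations in a run.
    skin : neighbour-list margin in model length units.
    """

    alpha: float = 0.4
    gamma: float = 0.01
    delta: float = 0.1
    epsilon: float = 0.85
    tau: float = 0.4
    k: float = 1.0
    n_relax: int = 10
    p0: float = 1.0
    division_plane: str = "random"
    planar: bool = False
    seed: int = 0
    n_steps: int = 250
    skin: float = 0.5


@dataclass
class SummaryStats:
    """Per-step aggregate observables."""

    step: int
    n_cells: int
    n_bonds: int
    n_divisions_this_step: int
    P_min: float
    P_mean: float
    P_max: float
    mean_coordination: float
    total_potential: float


def default_params() -> ModelParams:
    """Return the reference parameter set (see :class:`ModelParams`)."""
    return ModelParams()


def validate_params(p: ModelParams) -> ModelParams:
    """Return ``p`` unchanged if every invariant holds, else raise.

    Raises
    ------
    ValueError
        Naming the offending field.
    """
    if not (0.0 < p.epsilon < 1.0):
        raise ValueError(f"epsilon must lie in (0, 1), got {p.epsilon}")
    if p.k <= 0:
        raise ValueError(f"k must be positive, got {p.k}")
    if p.gamma < 0:
        raise ValueError(f"gamma must be non-negative, got {p.gamma}")
    if p.p0 <= 0:
        raise ValueError(f"p0 must be positive, got {p.p0}")
    if p.n_relax < 1:
        raise ValueError(f"n_relax must be a positive integer, got {p.n_relax}")
    if p.delta <= 0:
        raise ValueError(f"delta must be positive, got {p.delta}")
    if p.tau < 0:
        raise ValueError(f"tau must be non-negative, got {p.tau}")
    if p.alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {p.alpha}")
    if p.skin < 0:
        raise ValueError(f"skin must be non-negative, got {p.skin}")
    if p.n_steps < 0:
        raise ValueError(f"n_steps must be non-negative, got {p.n_steps}")
    if p.division_plane not in ("random", "orthogonal"):
        raise ValueError(
            f"division_plane must be 'random' or 'orthogonal', got {p.division_plane!r}"
        )
    return p


_BOOL_KEYS = {"planar"}
_INT_KEYS = {"n_relax", "seed", "n_steps"}
_STR_KEYS = {"division_plane"}
_KEY_ALIASES = {"division_plane": "division_plane", "p0": "p0"}


def params_from_config(path: str | Path, **overrides) -> ModelParams:
    """Read a plain-text ``key=value`` config file into a ModelParams.

    Recognised keys: alpha, gamma, delta, epsilon, tau, k, n_relax, p0,
    division_plane, planar, seed, n_steps, skin.  Blank lines and lines
    starting with ``#`` are ignored.  Keyword ``overrides`` (e.g. from
    CLI flags) take precedence over the file.
    """
    known = {f.name for f in fields(ModelParams)}
    values: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        if key in _BOOL_KEYS:
            values[key] = val.lower() in ("1", "true", "yes", "on")
        elif key in _INT_KEYS:
            values[key] = int(val)
        elif key in _STR_KEYS:
            values[key] = val
        else:
            values[key] = float(val)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return validate_params(ModelParams(**values))


class Tissue:
    """The whole sample: cell table, permanent bond set, step counter, RNG.

    The cell table lives in parallel numpy arrays sorted by ascending
    cell id (monotonic id allocation plus append-on-division keeps this
    ordering for free).  Bonds are stored as a set of ``(i, j)`` id
    tuples with ``i < j``; the set is mutated only inside a division
    event.
    """

    def __init__(self, params: ModelParams | None = None, *, rng: np.random.Generator | None = None):
        p = params if params is not None else default_params()
        self.ids = np.empty(0, dtype=np.int64)
        self.pos = np.empty((0, 3), dtype=np.float64)
        self.R = np.empty(0, dtype=np.float64)
        self.R_birth = np.empty(0, dtype=np.float64)
        self.P = np.empty(0, dtype=np.float64)
        self.bonds: set[tuple[int, int]] = set()
        self.step = 0
        self.next_id = 0
        self.rng = rng if rng is not None else np.random.default_rng(p.seed)

    # -- basic queries -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.ids.size

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def index_of(self, cell_id: int) -> int:
        """Row index of a cell id in the sorted arrays."""
        idx = int(np.searchsorted(self.ids, cell_id))
        if idx >= self.ids.size or self.ids[idx] != cell_id:
            raise KeyError(f"no cell with id {cell_id}")
        return idx

    def __contains__(self, cell_id: int) -> bool:
        idx = int(np.searchsorted(self.ids, cell_id))
        return idx < self.ids.size and self.ids[idx] == cell_id

    def cell(self, cell_id: int) -> CellState:
        i = self.index_of(cell_id)
        return CellState(
            id=int(self.ids[i]),
            r=self.pos[i].copy(),
            R=float(self.R[i]),
            R_birth=float(self.R_birth[i]),
            P=float(self.P[i]),
        )

    def cells(self) -> Iterator[CellState]:
        for cid in self.ids:
            yield self.cell(int(cid))

    def neighbours(self, cell_id: int) -> list[int]:
        """Ids of cells bonded to ``cell_id``, ascending."""
        out = []
        for a, b in self.bonds:
            if a == cell_id:
                out.append(b)
            elif b == cell_id:
                out.append(a)
        return sorted(out)

    def bond_array(self) -> np.ndarray:
        """Bonds as an (n_bonds, 2) array of row indices, deterministic order."""
        if not self.bonds:
            return np.empty((0, 2), dtype=np.int64)
        pairs = np.array(sorted(self.bonds), dtype=np.int64)
        return np.searchsorted(self.ids, pairs)

    # -- mutation ------------------------------------------------------

    def add_cell(self, r, R: float, R_birth: float | None = None, P: float = 0.0) -> int:
        """Append a new cell with a fresh id; returns the id."""
        cid = self.next_id
        self.next_id += 1
        self.ids = np.append(self.ids, cid)
        self.pos = np.vstack([self.pos, np.asarray(r, dtype=np.float64).reshape(1, 3)])
        self.R = np.append(self.R, float(R))
        self.R_birth = np.append(self.R_birth, float(R) if R_birth is None else float(R_birth))
        self.P = np.append(self.P, float(P))
        return cid

    def remove_cell(self, cell_id: int) -> None:
        """Retire a cell; its bonds must already have been detached."""
        if any(cell_id in b for b in self.bonds):
            raise ValueError(f"cell {cell_id} still has bonds attached")
        i = self.index_of(cell_id)
        keep = np.ones(self.ids.size, dtype=bool)
        keep[i] = False
        self.ids = self.ids[keep]
        self.pos = self.pos[keep]
        self.R = self.R[keep]
        self.R_birth = self.R_birth[keep]
        self.P = self.P[keep]

    def add_bond(self, a: int, b: int) -> None:
        if a == b:
            raise ValueError(f"self-bond on cell {a}")
        if a not in self or b not in self:
            raise ValueError(f"bond ({a}, {b}) references a missing cell")
        self.bonds.add((a, b) if a < b else (b, a))

    def remove_bond(self, a: int, b: int) -> None:
        self.bonds.discard((a, b) if a < b else (b, a))

    def has_bond(self, a: int, b: int) -> bool:
        return ((a, b) if a < b else (b, a)) in self.bonds

    def copy(self) -> "Tissue":
        t = Tissue.__new__(Tissue)
        t.ids = self.ids.copy()
        t.pos = self.pos.copy()
        t.R = self.R.copy()
        t.R_birth = self.R_birth.copy()
        t.P = self.P.copy()
        t.bonds = set(self.bonds)
        t.step = self.step
        t.next_id = self.next_id
        t.rng = np.random.default_rng()
        t.rng.bit_generator.state = self.rng.bit_generator.state
        return t
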