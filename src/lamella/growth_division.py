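"""Pressure-moderated stochastic growth and cell division.

Each step every cell's size parameter grows by

    dR = R * gamma * u * 2 / (1 + exp(P / P0)),   u ~ U[0, 2),

so at zero pressure the mean relative growth rate is gamma, high
positive pressure throttles growth towards zero and strongly negative
pressure doubles it — a stand-in for turgor-driven growth being
squeezed off by the neighbourhood.  A cell divides once its volume has
doubled relative to its own creation (R >= 2^(1/3) * R_birth); the two
daughters each carry half the mother's volume (R_d = 2^(-1/3) * R_m)
and are placed at r +- alpha * R_m * s_hat along the division vector
s_hat, the unit normal to the division plane.  s_hat is drawn uniformly
(on the sphere, or on the circle in planar mode) or, under the
orthogonal policy, perpendicular to the link to the nearest connected
neighbour — the model's reading of cells dividing across their short
axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .model_core import DIVISION_RATIO, CellState, ModelParams, Tissue
from .network_update import RewiringResult, reassign_bonds

__all__ = [
    "DivisionEvent",
    "growth_increment",
    "grow_all",
    "is_division_due",
    "daughter_radius",
    "division_direction",
    "divide_cell",
]


@dataclass
class DivisionEvent:
    """One division: who split, into whom, along which normal, when."""

    mother_id: int
    daughter_ids: tuple[int, int]
    s_hat: np.ndarray  # unit normal to the division plane
    step: int
    rewiring: RewiringResult | None = None
    #: the mother's neighbour ids before the split (audit trail)
    mother_neighbours: tuple[int, ...] = ()


def growth_increment(R: float, P: float, gamma: float, P0: float, u: float) -> float:
    """Size-parameter increment R * gamma * u * 2/(1 + exp(P/P0)).

    ``u`` is the stochastic factor (uniform on [0, 2), mean 1).  The
    logistic moderation saturates smoothly: dR -> 2*R*gamma*u for
    P -> -inf and -> 0 for P -> +inf, with no overflow for extreme
    pressures.
    """
    return float(R * gamma * u * 2.0 * expit(-P / P0))


def grow_all(t: Tissue, p: ModelParams, u: np.ndarray | float | None = None) -> Tissue:
    """Grow every cell once, in place, using its last stored pressure.

    One independent u-draw per cell, taken in ascending id order (the
    array order).  ``u`` can be forced for deterministic tests.
    Positions and bonds are untouched.
    """
    if u is None:
        u_arr = t.rng.uniform(0.0, 2.0, size=t.n_cells)
    else:
        u_arr = np.broadcast_to(np.asarray(u, dtype=np.float64), (t.n_cells,))
    t.R = t.R + t.R * p.gamma * u_arr * 2.0 * expit(-t.P / p.p0)
    return t


def is_division_due(c: CellState) -> bool:
    """True once the cell has doubled the volume it was created with."""
    return c.R >= DIVISION_RATIO * c.R_birth


def daughter_radius(R_mother: float) -> float:
    """Size parameter of each daughter, R_mother * 2^(-1/3) ~ 0.794 R.

    The two daughters jointly conserve the mother's volume.
    """
    if R_mother <= 0:
        raise ValueError(f"mother size parameter must be positive, got {R_mother}")
    return R_mother * 2.0 ** (-1.0 / 3.0)


def _orthonormal_in_plane(link: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis of the plane perpendicular to link."""
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(link)))] = 1.0
    u1 = np.cross(link, axis)
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(link, u1)
    u2 /= np.linalg.norm(u2)
    return u1, u2


def division_direction(c: CellState, t: Tissue, p: ModelParams) -> np.ndarray:
    """Draw the unit normal to the division plane for cell ``c``.

    random policy: uniform on the unit sphere, or on the unit circle in
    the xy-plane in planar mode.  orthogonal policy: perpendicular to
    the link to the nearest connected neighbour (ties broken by lowest
    id; no neighbour at all falls back to random) — in planar mode the
    unique in-plane perpendicular with a random sign, in 3D a uniform
    direction on the circle orthogonal to the link.
    """
    policy = p.division_plane
    if policy == "orthogonal":
        nbrs = t.neighbours(c.id)
        if not nbrs:
            policy = "random"
        else:
            dists = np.array([np.linalg.norm(t.pos[t.index_of(n)] - c.r) for n in nbrs])
            nearest = nbrs[int(np.argmin(dists))]  # argmin keeps lowest id on ties
            link = t.pos[t.index_of(nearest)] - c.r
            link = link / np.linalg.norm(link)
            if p.planar:
                s = np.array([-link[1], link[0], 0.0])
                s /= np.linalg.norm(s)
                if t.rng.uniform() < 0.5:
                    s = -s
                return s
            u1, u2 = _orthonormal_in_plane(link)
            theta = t.rng.uniform(0.0, 2.0 * np.pi)
            return np.cos(theta) * u1 + np.sin(theta) * u2
    if p.planar:
        theta = t.rng.uniform(0.0, 2.0 * np.pi)
        return np.array([np.cos(theta), np.sin(theta), 0.0])
    v = t.rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - astronomically rare
        v = t.rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


def divide_cell(t: Tissue, mother: int, s_hat: np.ndarray, p: ModelParams) -> DivisionEvent:
    """Split a division-due mother into two daughters, in place.

    The mother's id is retired; daughters get fresh ids, positions
    r +- alpha * R_mother * s_hat, size parameter (= birth size)
    2^(-1/3) * R_mother and the mother's last pressure.  Bonds are
    redistributed locally by :func:`lamella.network_update.reassign_bonds`.
    """
    c = t.cell(mother)
    if not is_division_due(c):
        raise ValueError(f"cell {mother} has not doubled its volume (R={c.R}, R_birth={c.R_birth})")
    s_hat = np.asarray(s_hat, dtype=np.float64)
    mother_bonds = set(t.neighbours(mother))
    for j in mother_bonds:
        t.remove_bond(mother, j)
    R_d = daughter_radius(c.R)
    offset = p.alpha * c.R * s_hat
    t.remove_cell(mother)
    d1 = t.add_cell(c.r + offset, R_d, R_birth=R_d, P=c.P)
    d2 = t.add_cell(c.r - offset, R_d, R_birth=R_d, P=c.P)
    rew = reassign_bonds(t, mother_bonds, d1, d2, p)
    return DivisionEvent(
        mother_id=mother,
        daughter_ids=(d1, d2),
        s_hat=s_hat,
        step=t.step,
        rewiring=rew,
        mother_neighbours=tuple(sorted(mother_bonds)),
    )
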