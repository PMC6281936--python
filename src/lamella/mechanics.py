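"""Pair potentials, forces, neighbour list and steepest-descent relaxation.

Two bonded cells behave as point particles joined by a Hookean spring
whose rest length is the sum of their size parameters,

    U_ij = 1/2 k (R_i + R_j - d_ij)^2,

acting at any separation.  Unbonded cells feel the same potential only
while they overlap (d < R_i + R_j) — the spring then merely removes the
overlap.  Relaxation is a fixed number N of synchronous steepest-descent
sweeps r <- r + delta * F.  The model is quasi-static: there are no
velocities, masses or noise, only a force balance that never fully
relaxes because the bonded topology is frozen; the residual force field
is what generates the per-cell virial pressure

    P_i = -1/(3 V_i) sum_j F_ij . (r_j - r_i),   V_i = 4/3 pi R_i^3,

positive when the neighbourhood compresses cell i, negative under
tension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model_core import Tissue

__all__ = [
    "InteractionPairList",
    "pair_potential",
    "pair_force_on_i",
    "build_pair_list",
    "total_forces",
    "total_potential",
    "relax",
    "cell_volume",
    "cell_pressure",
    "all_pressures",
]


@dataclass
class InteractionPairList:
    """Pairs currently considered for forces.

    Contains every bonded pair regardless of separation, plus every
    unbonded pair whose separation was below R_i + R_j + skin when the
    list was built.  ``i`` / ``j`` are row indices into the tissue
    arrays (valid until the next membership change), ``bonded`` flags
    the permanent pairs.
    """

    i: np.ndarray
    j: np.ndarray
    bonded: np.ndarray
    built_at_step: int

    @property
    def n_pairs(self) -> int:
        return self.i.size


def pair_potential(R_i: float, R_j: float, d: float, k: float, bonded: bool) -> float:
    """Energy of one pair; zero for unbonded pairs that do not overlap."""
    if R_i <= 0 or R_j <= 0:
        raise ValueError(f"size parameters must be positive, got {R_i}, {R_j}")
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    if k <= 0:
        raise ValueError(f"force constant must be positive, got {k}")
    if not bonded and d >= R_i + R_j:
        return 0.0
    return 0.5 * k * (R_i + R_j - d) ** 2


def pair_force_on_i(r_i, r_j, R_i: float, R_j: float, k: float, bonded: bool) -> np.ndarray:
    """Force on cell i from cell j, -dU/dr_i.

    Repulsive (pointing from j towards i) under overlap, attractive for
    a stretched bond.  A coincident interacting pair has no defined
    direction and is rejected.
    """
    r_i = np.asarray(r_i, dtype=np.float64)
    r_j = np.asarray(r_j, dtype=np.float64)
    dvec = r_i - r_j
    d = float(np.linalg.norm(dvec))
    if not bonded and d >= R_i + R_j:
        return np.zeros(3)
    if d == 0.0:
        raise ValueError("coincident interacting cells: force direction undefined")
    return k * (R_i + R_j - d) * dvec / d


def build_pair_list(t: Tissue, skin: float) -> InteractionPairList:
    """Collect bonded pairs plus unbonded pairs within interaction reach.

    An unbonded pair enters the list when d < R_i + R_j + skin at build
    time; the skin margin keeps the list valid while cells drift during
    the relaxation sweeps of a step.
    """
    if t.n_cells == 0:
        raise ValueError("cannot build a pair list for an empty tissue")
    bond_idx = t.bond_array()
    if t.n_cells > 1:
        cutoff = float(2.0 * t.R.max() + skin)
        tree = cKDTree(t.pos)
        cand = tree.query_pairs(cutoff, output_type="ndarray")
    else:
        cand = np.empty((0, 2), dtype=np.int64)
    if cand.size:
        d = np.linalg.norm(t.pos[cand[:, 0]] - t.pos[cand[:, 1]], axis=1)
        cand = cand[d < t.R[cand[:, 0]] + t.R[cand[:, 1]] + skin]
    # drop candidates that are bonds (bonds are added unconditionally)
    bonded_keys = set(map(tuple, np.sort(bond_idx, axis=1).tolist()))
    if cand.size:
        cand = np.sort(cand, axis=1)
        keep = [tuple(p) not in bonded_keys for p in cand.tolist()]
        cand = cand[np.asarray(keep, dtype=bool)] if len(keep) else cand
    i = np.concatenate([bond_idx[:, 0], cand[:, 0]]) if cand.size else bond_idx[:, 0].copy()
    j = np.concatenate([bond_idx[:, 1], cand[:, 1]]) if cand.size else bond_idx[:, 1].copy()
    bonded = np.zeros(i.size, dtype=bool)
    bonded[: bond_idx.shape[0]] = True
    return InteractionPairList(i=i, j=j, bonded=bonded, built_at_step=t.step)


def _pair_terms(t: Tissue, pl: InteractionPairList, k: float):
    """Vectorised per-pair geometry shared by forces/energy/pressure.

    Returns (i, j, unit vectors j->i scaled, overlap, d, active mask).
    ``overlap`` is R_i + R_j - d; a pair is active when bonded or
    overlapping.
    """
    i, j = pl.i, pl.j
    dvec = t.pos[i] - t.pos[j]
    d = np.linalg.norm(dvec, axis=1)
    overlap = t.R[i] + t.R[j] - d
    active = pl.bonded | (overlap > 0.0)
    if np.any(active & (d == 0.0)):
        raise ValueError("coincident interacting cells: force direction undefined")
    return i, j, dvec, d, overlap, active


def total_forces(t: Tissue, pl: InteractionPairList, k: float) -> np.ndarray:
    """Net force on every cell, as an (n_cells, 3) array in row order.

    Pair contributions are antisymmetric, so the column sums vanish up
    to floating-point roundoff.
    """
    i, j, dvec, d, overlap, active = _pair_terms(t, pl, k)
    F = np.zeros_like(t.pos)
    if np.any(active):
        ia, ja = i[active], j[active]
        fij = (k * overlap[active] / d[active])[:, None] * dvec[active]
        np.add.at(F, ia, fij)
        np.add.at(F, ja, -fij)
    return F


def total_potential(t: Tissue, pl: InteractionPairList, k: float) -> float:
    """Sum of pair energies over the interaction list."""
    _, _, _, _, overlap, active = _pair_terms(t, pl, k)
    return float(0.5 * k * np.sum(overlap[active] ** 2))


def relax(t: Tissue, pl: InteractionPairList, N: int, delta: float, k: float) -> Tissue:
    """N synchronous steepest-descent sweeps r <- r + delta * F, in place.

    Every sweep evaluates all forces at the sweep-start positions and
    then displaces all cells simultaneously.  Radii, bonds and (because
    forces between coplanar cells stay in the plane) any common
    out-of-plane coordinate are untouched.  Returns the same tissue.
    """
    if N < 1:
        raise ValueError(f"n_relax must be >= 1, got {N}")
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    for _ in range(N):
        F = total_forces(t, pl, k)
        t.pos += delta * F
        if not np.all(np.isfinite(t.pos)):
            raise FloatingPointError(
                f"relaxation diverged (non-finite positions with delta={delta}); "
                "reduce delta or increase n_relax"
            )
    return t


def cell_volume(R: float) -> float:
    """Volume of a cell of size parameter R, (4/3) pi R^3."""
    if R <= 0:
        raise ValueError(f"size parameter must be positive, got {R}")
    return 4.0 / 3.0 * np.pi * R**3


def all_pressures(t: Tissue, pl: InteractionPairList, k: float) -> np.ndarray:
    """Virial pressure of every cell, in row order.

    Sums F_ij . (r_j - r_i) over all interacting partners of each cell
    (bonded at any distance, unbonded while overlapping).  With the
    Hookean pair force the dot product reduces to -k * overlap * d.
    """
    i, j, _, d, overlap, active = _pair_terms(t, pl, k)
    P = np.zeros(t.n_cells)
    if np.any(active):
        term = k * overlap[active] * d[active]  # = -F_ij.(r_j - r_i)
        np.add.at(P, i[active], term)
        np.add.at(P, j[active], term)
    V = 4.0 / 3.0 * np.pi * t.R**3
    return P / (3.0 * V)


def cell_pressure(t: Tissue, pl: InteractionPairList, cell_id: int, k: float) -> float:
    """Virial pressure of one cell (see :func:`all_pressures`)."""
    return float(all_pressures(t, pl, k)[t.index_of(cell_id)])
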