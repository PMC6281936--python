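"""Local reassignment of permanent bonds when a cell divides.

When a mother cell splits, the cell walls it shared with its neighbours
must be handed down.  Three strictly local rules decide the new edges:

1. the two daughters are always bonded to each other (the new wall
   between them physically exists);
2. every former neighbour j is bonded to the daughter nearest to it;
3. the *farther* daughter is additionally bonded to j when the two
   daughter-neighbour distances are comparable,
   epsilon < d1j/d2j < 1/epsilon  (the triangle criterion),

after which a tetrahedron rule prunes over-connected 4-cliques: if two
former neighbours nA, nB are bonded to each other and both daughters
are bonded to both of them, the four cells form a tetrahedron whose
opposite edges are d1-d2 and nA-nB.  When that tetrahedron is too flat
— the minimal distance between the two opposite edge segments is below
tau times the daughter separation — the two diagonal walls cannot both
exist, and the longer of the two diagonal bonds is discarded.  The
daughter-daughter bond is never removed (rule 1 is unconditional), so
in that case nA-nB goes instead.  For a regular tetrahedron the
thickness fraction is 1/sqrt(2) ~ 0.7, comfortably above the default
tau = 0.4, so well-shaped cliques are left alone.

Every decision reads only the mother's former neighbourhood, never the
rest of the tissue; the work per division is a function of the mother's
coordination number alone, which is what makes total effort linear in
the number of cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .model_core import ModelParams, Tissue

__all__ = [
    "TriangleOutcome",
    "RewiringResult",
    "triangle_rule",
    "segment_min_distance",
    "tetrahedron_prune",
    "reassign_bonds",
]


class TriangleOutcome(Enum):
    NEAREST_ONLY = "nearest_only"
    BOTH = "both"


@dataclass
class RewiringResult:
    """Audit record of one rewiring: bonds touched and work done."""

    added: list[tuple[int, int]] = field(default_factory=list)
    removed: list[tuple[int, int]] = field(default_factory=list)
    #: distance evaluations performed (point-point and segment-segment);
    #: depends only on the mother's degree, never on tissue size.
    distance_evaluations: int = 0


def triangle_rule(d1j: float, d2j: float, epsilon: float) -> TriangleOutcome:
    """Decide whether both daughters inherit a neighbour's bond.

    Both are bonded iff epsilon < d1j/d2j < 1/epsilon; the inequalities
    are strict, so an exact tie with epsilon keeps only the nearest.
    """
    if d1j <= 0 or d2j <= 0:
        raise ValueError(f"daughter-neighbour distances must be positive, got {d1j}, {d2j}")
    if not (0.0 < epsilon < 1.0):
        raise ValueError(f"epsilon must lie in (0, 1), got {epsilon}")
    ratio = d1j / d2j
    if epsilon < ratio < 1.0 / epsilon:
        return TriangleOutcome.BOTH
    return TriangleOutcome.NEAREST_ONLY


def segment_min_distance(a0, a1, b0, b1) -> float:
    """Minimal Euclidean distance between two closed 3D segments.

    Standard clamped closest-point computation; degenerate zero-length
    segments are treated as points.  Symmetric in its two segments.
    """
    a0 = np.asarray(a0, dtype=np.float64)
    a1 = np.asarray(a1, dtype=np.float64)
    b0 = np.asarray(b0, dtype=np.float64)
    b1 = np.asarray(b1, dtype=np.float64)
    u = a1 - a0
    v = b1 - b0
    w0 = a0 - b0
    a = float(u @ u)
    b = float(u @ v)
    c = float(v @ v)
    d = float(u @ w0)
    e = float(v @ w0)
    denom = a * c - b * b

    eps = 1e-14
    if a <= eps and c <= eps:  # point vs point
        return float(np.linalg.norm(w0))
    if a <= eps:  # point vs segment
        t = np.clip(e / c, 0.0, 1.0)
        return float(np.linalg.norm(a0 - (b0 + t * v)))
    if c <= eps:  # segment vs point
        s = np.clip(-d / a, 0.0, 1.0)
        return float(np.linalg.norm(a0 + s * u - b0))

    if denom > eps * a * c:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:  # near-parallel: pick an endpoint projection
        s = 0.0
    t = (b * s + e) / c
    if t < 0.0:
        t = 0.0
        s = np.clip(-d / a, 0.0, 1.0)
    elif t > 1.0:
        t = 1.0
        s = np.clip((b - d) / a, 0.0, 1.0)
    return float(np.linalg.norm(a0 + s * u - (b0 + t * v)))


def tetrahedron_prune(
    t: Tissue,
    d1: int,
    d2: int,
    tau: float,
    result: RewiringResult | None = None,
) -> list[tuple[int, int]]:
    """Remove one diagonal bond from every too-flat division 4-clique.

    Candidate cliques are pairs (nA, nB) of cells bonded to each other
    with all four daughter bonds d1-nA, d1-nB, d2-nA, d2-nB present.
    Cliques are examined in ascending (nA, nB) id order; a bond removed
    by an earlier clique dissolves later cliques that relied on it.
    Returns the removed bonds.
    """
    res = result if result is not None else RewiringResult()
    common = sorted(set(t.neighbours(d1)) & set(t.neighbours(d2)) - {d1, d2})
    p1 = t.pos[t.index_of(d1)]
    p2 = t.pos[t.index_of(d2)]
    d12 = float(np.linalg.norm(p2 - p1))
    res.distance_evaluations += 1
    removed: list[tuple[int, int]] = []
    for ai in range(len(common)):
        for bi in range(ai + 1, len(common)):
            nA, nB = common[ai], common[bi]
            if not t.has_bond(nA, nB):
                continue
            # clique may have lost a daughter bond to an earlier prune
            if not (
                t.has_bond(d1, nA)
                and t.has_bond(d1, nB)
                and t.has_bond(d2, nA)
                and t.has_bond(d2, nB)
            ):
                continue
            pA = t.pos[t.index_of(nA)]
            pB = t.pos[t.index_of(nB)]
            thickness = segment_min_distance(pA, pB, p1, p2)
            res.distance_evaluations += 1
            if thickness < tau * d12:
                # drop the longer diagonal; the daughter-daughter wall
                # is unconditional, so nA-nB goes in either case
                bond = (nA, nB) if nA < nB else (nB, nA)
                t.remove_bond(*bond)
                removed.append(bond)
                res.removed.append(bond)
    return removed


def reassign_bonds(
    t: Tissue,
    mother_bonds: set[int],
    d1: int,
    d2: int,
    p: ModelParams,
) -> RewiringResult:
    """Distribute a retired mother's bonds over her two daughters.

    ``mother_bonds`` are the mother's former neighbour ids, captured
    before her removal; the daughters must already be placed.  Mutates
    the tissue in place and returns the audit record.  Only bonds
    within the mother's former neighbourhood are read or written.
    """
    res = RewiringResult()

    def _add(a: int, b: int) -> None:
        t.add_bond(a, b)
        res.added.append((a, b) if a < b else (b, a))

    _add(d1, d2)
    p1 = t.pos[t.index_of(d1)]
    p2 = t.pos[t.index_of(d2)]
    for j in sorted(mother_bonds):
        pj = t.pos[t.index_of(j)]
        d1j = float(np.linalg.norm(pj - p1))
        d2j = float(np.linalg.norm(pj - p2))
        res.distance_evaluations += 2
        nearest = d1 if d1j <= d2j else d2
        _add(nearest, j)
        if triangle_rule(d1j, d2j, p.epsilon) is TriangleOutcome.BOTH:
            _add(d2 if nearest == d1 else d1, j)
    tetrahedron_prune(t, d1, d2, p.tau, result=res)
    return res
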