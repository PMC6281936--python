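# Methods

## Model and assumptions

The simulator treats a plant tissue sample as point particles with one
scalar size parameter each, joined by permanent bonds wherever two
cells share a wall. The physical premises are:

- **Irreversible adjacency.** The middle lamella glues plant cells
  together for good, so bonds are never created or destroyed by
  motion; the network topology changes only inside a division event.
  Cells neither migrate, slide nor roll past each other.
- **Soft spherical interactions.** A bonded pair is a Hookean spring
  with rest length R_i + R_j acting at any distance; an unbonded pair
  interacts only while overlapping. Nothing in the dynamics assumes an
  actual cell shape — the circles in renders are a visualisation aid.
- **Quasi-static mechanics.** There are no masses, velocities or
  noise. After each growth/division stage a fixed number N of
  synchronous steepest-descent sweeps (r ← r + δF) partially relaxes
  the stresses. Because the frozen topology prevents full relaxation,
  a residual force field survives; its virial,
  P_i = −1/(3V_i) Σ_j F_ij·(r_j − r_i), defines the per-cell pressure.
  The virial sum runs over *every* interacting partner, bonded or
  (overlapping) unbonded: the overlap forces are real forces in the
  relaxation, and dropping them would break the relation between
  compression and positive pressure.
- **Pressure-moderated stochastic growth.** ΔR = R γ u · 2/(1 +
  exp(P/P₀)), u ~ U[0, 2). The logistic factor is evaluated with a
  numerically saturating sigmoid, so extreme |P|/P₀ yields 0 or 2γR
  without overflow. The pressure used at step n is the one stored at
  the end of step n−1 (zero at the first step): the cycle is grow →
  divide → relax → measure.
- **Division at volume doubling.** "Twice its original volume" is read
  per cell relative to its own creation (R_birth is stored), which
  makes the division cycle self-similar: daughters get exactly half
  the mother's volume (R_d = 2^(−1/3) R_m) and start with
  R = R_birth = R_d. Daughters are placed at r ± αR_m ŝ and inherit
  the mother's last pressure for bookkeeping (it is overwritten by the
  next relaxation before anything reads it).

## Step ordering and determinism

Within one step: growth draws (one uniform per cell, ascending id
order), then a division sweep in ascending id order over the cells
present at sweep start (daughters created during the sweep are not
re-examined until the next step; with 2γ = 2% ≪ 2^(1/3) − 1 ≈ 26% a
cell can never be due twice in a step anyway), then one neighbour-list
rebuild, then N relaxation sweeps over the fixed list, then pressures.
All randomness flows through a single seeded generator with this fixed
draw order, so (params, seed) determines the trajectory bit-for-bit;
snapshots and stats files from two equal-seed runs are byte-identical.

Ids are allocated monotonically and never reused; a mother's id is
retired at division, which keeps the lineage log unambiguous and the
id-sorted cell arrays sorted by construction.

## Network rewiring at division

The daughters are always bonded to each other; each former neighbour j
is bonded to the nearest daughter; the farther daughter is also bonded
iff ε < d1j/d2j < 1/ε (strict inequalities — an exact tie keeps only
the nearest). The tetrahedron prune then examines, in ascending
(nA, nB) id order, every pair of former neighbours that are bonded to
each other and to both daughters: if the minimal distance between the
closed segments nA–nB and d1–d2 is below τ·|d1−d2|, the flat 4-clique
cannot carry both diagonal walls and the longer diagonal is removed.
Where the longer diagonal is the daughter–daughter bond itself, the
daughter wall wins (it physically exists, and the nearest-daughter
rule is unconditional), so nA–nB is removed instead; a bond removed by
an earlier clique dissolves later cliques that relied on it, and at
most one bond is removed per clique. The regular-tetrahedron thickness
fraction is 1/√2 ≈ 0.7, well above the default τ = 0.4, so only
genuinely degenerate cliques are pruned.

Every decision reads only the mother's former neighbourhood. The
distance-evaluation count per division is 1 + 2·deg + (examined
cliques), a function of the mother's degree only — this is what makes
the division cost per event O(1) and the total effort linear in cell
count, and it is asserted in the tests by counting evaluations.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| α | daughter displacement, in units of R_mother | 0.4 | small α piles the daughters up, α ~ 1 rams them into the neighbours; both strain the relaxation |
| γ | mean relative growth per step | 0.01 | sets the time scale; volume doubles in ⌈log 2 / (3 log 1.01)⌉ = 24 steps at zero pressure |
| δ | steepest-descent step per unit force | 0.1 | 1/(2k) = 0.5 would relax an isolated pair in one sweep but overshoots in crowded neighbourhoods; 10 sweeps of 0.1 are used instead. An alternative convention of 0.2 appears in some parameter listings; both are configurable, 0.1 is the production default |
| ε | double-connectedness ratio | 0.85 | sensible range ~0.75–0.95; larger ε → fewer double bonds → more tenuous, branchy samples |
| τ | tetrahedron thickness fraction | 0.4 | safely below the regular-tetrahedron value 0.71 |
| k | spring constant | 1 | with 10 µm cells and ~1 atm cell pressure this maps to ~1 N/m; the engine itself is dimensionless |
| N | relaxation sweeps per step | 10 | paired with δ: smaller δ needs larger N |
| P₀ | pressure-moderation width | 1 | 0.1 nearly freezes growth under any load; 10 lets the interior keep dividing |
| skin | neighbour-list margin | 0.5 | per-step displacements are ≪ 0.5 at the defaults, so one rebuild per step (after the division sweep, before relaxation) is safe; the list is held fixed across the N sweeps |

The division normal is drawn uniformly (sphere, or circle in planar
mode) or, under the `orthogonal` policy, perpendicular to the link to
the nearest connected neighbour — the in-plane perpendicular with a
random sign in planar mode, a uniform direction on the orthogonal
circle in 3D (the rule fixes only one direction, so the remaining
freedom is drawn uniformly; nearest-neighbour ties break to the lowest
id). A cell with no bonded neighbour falls back to the random policy.
Orthogonal division bonds both daughters to that nearest neighbour,
which densifies the network — mean coordination rises relative to the
random policy.

## Degenerate inputs and numerical choices

- A coincident *interacting* pair (d = 0) aborts with a diagnostic
  rather than inventing a direction; with α > 0 daughters never
  coincide, so this only flags corrupted input (α = 0 is accepted as a
  parameter but leaves coincident daughters that relaxation cannot
  separate).
- Non-finite positions during relaxation abort with the step number
  and δ named.
- Snapshots serialise floats with 17 significant digits and are read
  back with round-trip parsing, so write→read is the identity.
- Segment–segment minimal distance uses the standard clamped
  closest-point algorithm with an absolute parallelism guard of 1e−14;
  zero-length segments degrade to points.
- Planarity is exact, not approximate: forces between coplanar cells
  have zero out-of-plane component, so a planar sample's z-column
  stays identically 0.0 for the whole run.

## What the simulator emulates, and what it does not

All experiments start from a single cell of unit size; there is no
external data. The stochastic growth factor u is the only biological
noise; real tissues add agent/morphogen signalling, resource
limitation, anisotropic walls and regulated division timing, none of
which are modelled. Passing tests therefore demonstrate the mechanics
and the locality/consistency of the network-update algorithm — that
the generated morphologies (branched, fractal-like samples; smoother
ones under the orthogonal rule) behave as this model family describes
— not that real organs grow this way. Holes in the bond network can
appear at large sample sizes; no triangulation-based repair is
attempted, since no strictly local variant of it is known.

## Analysis conventions

The perimeter of a planar sample is defined from geometry, not the
graph: the exterior ring of the union of cell discs inflated to 1.5 R
(inflation covers the interstices of a close packing, whose
circumradius is 2R/√3 ≈ 1.15 R, so interior holes of the union do not
masquerade as boundary). A cell is a perimeter cell when its inflated
disc reaches that ring; depth is then the unweighted graph distance to
the nearest perimeter cell. The pressure-localisation check compares
the mean depth of the top and bottom pressure deciles.

## Problem sizes used in tests and the acceptance script

The reference runs are 250 steps from one cell (≈ 400–1300 cells
depending on P₀ and dimension), averaged over five seeds; the
reported single-run counts they are compared against come from one
published seed, so the across-seed mean is matched within ±25%.
Unit and property tests use configurations of 1–30 cells and short
trajectories of 50–120 steps, which already exercise hundreds of
division events.
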