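# lamella

A particle-based growth simulator for plant tissues. Each cell is a
single point particle with a size parameter; cells that share a cell
wall are joined by a **permanent** bond — plant cells are glued
together irreversibly by the middle lamella, so the tissue is a fixed
network whose topology changes only when a cell divides. The package
is aimed at modellers who want a cheap, strictly local spatial
substrate for plant morphogenesis (e.g. as the network on which
agent/morphogen models can later live), in two and three dimensions
with the same algorithm.

## The model

Cell *i* has position **r**<sub>i</sub> and size parameter
*R*<sub>i</sub>. Connected cells interact through a Hookean spring
with rest length the sum of their sizes,

U<sub>ij</sub> = ½ k (R<sub>i</sub> + R<sub>j</sub> − d<sub>ij</sub>)²,

while unconnected cells feel the same potential only while they
overlap (d<sub>ij</sub> < R<sub>i</sub> + R<sub>j</sub>). Each time
step has three stages:

1. **Growth.** ΔR<sub>i</sub> = R<sub>i</sub> γ u · 2/(1 +
   exp(P<sub>i</sub>/P₀)) with u ~ U[0, 2): the mean relative growth
   rate is γ at zero pressure, throttled by compression and up to
   doubled under tension (a stand-in for turgor-limited growth).
2. **Division.** When a cell has doubled the volume it was born with
   (R ≥ 2^⅓ R_birth) it splits into two daughters of half its volume
   (R_d = 2^−⅓ R_m ≈ 0.794 R_m), placed at **r** ± αR**ŝ** along the
   division normal **ŝ** (random, or orthogonal to the link to the
   nearest connected neighbour). Bonds are redistributed *locally*:
   the daughters are always bonded to each other; every former
   neighbour goes to the nearest daughter; the farther daughter is
   also connected when the distance ratio lies in (ε, 1/ε); and a
   tetrahedron rule prunes a diagonal bond from any division 4-clique
   whose thickness is below τ times the daughter separation.
3. **Relaxation.** N synchronous steepest-descent sweeps
   **r** ← **r** + δ**F**, after which the per-cell virial pressure
   P<sub>i</sub> = −1/(3V<sub>i</sub>) Σ<sub>j</sub> **F**<sub>ij</sub>·(**r**<sub>j</sub>−**r**<sub>i</sub>)
   (V<sub>i</sub> = 4/3 πR<sub>i</sub>³) is stored and moderates the
   next step's growth.

Defaults: α=0.4, γ=0.01, δ=0.1, ε=0.85, τ=0.4, k=1, N=10, P₀=1,
random division plane. Restricting **ŝ** to the xy-plane keeps a
sample exactly planar forever; nothing else changes between 2D and 3D.

## Worked example

Grow a planar sample from a single cell for 100 steps:

```sh
$ lamella run --steps 100 --planar --seed 1 --out out/demo --render
100 steps: 14 cells, 21 bonds, 13 divisions -> /root/pkg/out/demo
```

Thirteen divisions turn one cell into 14; 21 bonds on 14 cells is a
mean coordination of 3.0 — a small, fully connected patch that is
already organising into the distorted triangular lattice typical of
these samples. `out/demo` contains `stats.csv` (per-step cell/bond
counts, divisions and pressure statistics), `lineage.csv` (every
division with its normal vector and the bonds added/removed), and a
`final/` snapshot (cell and bond tables as CSV, plus a PNG in which
each cell is a circle of radius R coloured by its pressure: blue at
−1, green at 0, red at +1).

The same run from Python:

```python
from lamella import ModelParams, run

res = run(ModelParams(planar=True, seed=1, n_steps=250))
print(res.tissue.n_cells)          # ~900 cells after 250 steps
print(res.stats[-1].mean_coordination)
```

Pressure feedback matters: with P₀ = 0.1 the same 250 steps yield
~380 cells, with P₀ = 10 about 1100 — unconstrained 1%-per-step
growth would give 2^(250/23) ≈ 1900.

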