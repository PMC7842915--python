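# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates. It is the package's own account; every number
quoted here is computed by the tests or by `scripts/acceptance.py`.

## Blood flow and hematocrit

Each vessel segment is a straight cylinder (chord) between two nodes.
Tortuous vessels must be pre-split into chords in the input. Flow obeys
Hagen–Poiseuille, `f_s = (p_head − p_tail)/R_s` with
`R = 128 µ(d,h) L/(π d⁴)` in mmHg·s/µm³ (µm–s–mmHg units throughout;
1 nL/s = 10⁶ µm³/s). Two viscosity models:

* `constant` — plasma-equivalent viscosity (default 1.2 cP), useful for
  closed-form tests because flow then decouples from hematocrit;
* `in_vitro` — the empirical glass-tube relative-viscosity fit in diameter
  and hematocrit (Fåhræus–Lindqvist minimum near capillary calibers, steep
  rise with hematocrit), times plasma viscosity. This is the default for
  simulations.

Nodal pressures solve the weighted graph Laplacian `C1ᵀR⁻¹C1 p = rhs` with
Dirichlet rows replaced by identity; the system is tiny (≤ ~10⁴ nodes at
desk scale) and is solved by a sparse direct factorization, giving
Kirchhoff residuals at round-off (~10⁻¹¹ % of inflow on the bundled
networks).

Hematocrit is transported by upwinding: nodes are visited in a topological
order of the flow-directed graph (always acyclic when flow follows a
pressure gradient); each node takes the flux-weighted mix of its inflows;
outgoing segments take the node value (`proportional` skimming — the unique
rule fixed by conservation alone) or a flow-biased split
(`threshold_skim`, share ∝ flowᵞ, capped at h = 1 with conservative
redistribution). If a cycle defeats the ordering, the equivalent nodal
linear system is solved instead. Segments with |f| below 10⁻¹⁵ of the mean
are treated as stagnant and take the mean of their endpoint values.

Flow and hematocrit alternate in a fixed-point loop until the max relative
change of both fields falls below tolerance (default 10⁻⁶). With the
constant-viscosity model this takes exactly 2 iterations (the second pass
confirms stationarity); with `in_vitro` viscosity and proportional
skimming on the synthetic networks the median is 2 as well, because
proportional skimming keeps hematocrit uniform at the systemic value on a
tree-fed lattice. Divergence (10 consecutive growing changes) raises with
the iterate history attached.

Occluded segments keep their matrix rows; their diameter is set to
numerical zero and their resistance to 1/ε (ε = 10⁻³⁰), so the graph
structure is preserved while the segment carries essentially no flow.

## Masking (voxel labeling)

The grid stores only origin, spacing Δ (cubic cells) and counts;
linearization is x-fastest (`lin = i + nx·j + nx·ny·k`). For each
non-occluded segment, candidate cells are those whose centers lie in the
chord's bounding box expanded by r + w/2 — the expansion is a candidate-set
safety margin only and cannot change labels. Each candidate's center
distance `d` to the finite chord (clamped point-to-segment, flat caps)
yields the claim: endothelial if `|d − r| ≤ w/2`, else interior if
`d < r`. The endothelial shell is symmetric about the vessel surface; the
wording "thickness w/2 from the vessel edge" is ambiguous between
one-sided and symmetric, and the symmetric reading keeps the interior rule
("not an edge cell and d < r") consistent and the shell one cell thick at
w = 1 µm, Δ ≈ 1 µm.

Across overlapping segments the priority is INTERIOR > ENDOTHELIAL >
EXTRAVASCULAR; a shared endothelial cell belongs to the segment of minimal
|d − r| (ties: lowest segment index, for determinism). Interior cells
record the nearer endpoint of their claiming segment for the lumen
elimination. The masking is verified bit-identical against an exhaustive
per-cell oracle (no bounding boxes) on cylinder, bifurcation and
random-network fixtures.

Before masking, the network is re-segmented: any segment whose endpoints do
not lie in the same or Chebyshev-adjacent voxels is bisected recursively
(> 64 rounds raises a scale-mismatch error). Partitioning preserves total
length and vascular volume to 10⁻⁹ relative and is idempotent. Flow is
solved once on the original network and inherited exactly by the children
(series subdivision leaves segment flow unchanged); the 3D grid never
carries the flow problem.

Each segment's lateral surface π·d·L is split evenly over its endothelial
cells (A_cell = π·d·L/N). A segment that claims no endothelial cell couples
its full surface to the single cell containing its midpoint; if that cell
is another vessel's lumen, the nearest non-lumen cell hosts the coupling
instead. This fallback extends to segments whose endothelial shell was
entirely claimed by neighbors, so every non-occluded segment exchanges
oxygen somewhere — otherwise its wall flux would silently vanish.

## Coupled oxygen system

Unknowns: oxygen tensions (mmHg) at the vascular nodes (cv) and at the
non-lumen cells (ct). Row n of the vascular block balances node n:

    Σ_in φ·cv_up − (Σ_in φ)·cv_n − Σ_cells g·(cv_n − ct_c) = 0

where φ = f·β(h) is the effective (carrying-capacity-weighted) convective
flux and g = U·A_cell/w. Row sums of the convection operator vanish at
every node; at boundary outlets the difference between inflow and
downstream outflow is the exit flux, implicit in the diagonal. β(h) =
h/h_ref by default (h_ref = systemic hematocrit), so convected oxygen
follows the red-cell flux: this is what makes a 30% hematocrit reduction
reduce oxygen delivery even though it lowers viscosity and *raises* bulk
flow. Because β is linear in h and the skimming rule conserves RBC flux,
the weighted convection operator is exactly conservative. β ≡ 1 (`unit`)
convects the bare tension instead.

Tissue rows combine the 7-point finite-volume Laplacian (face conductance
D·Δ between adjacent non-lumen cells; zero flux to lumen faces and the
domain exterior), the exchange term, and the metabolic sink k_met·Vt·ct.
`k_met` is accepted in 1/ms in configuration and converted to 1/s
internally. Intravascular diffusion is not modeled (axial Peclet ≫ 1), and
radial intravascular profiles are not resolved.

Vascular Dirichlet rows sit at the oxygen inlets — the nodes where
effective flux enters the domain; each must carry an inlet tension, or
assembly raises. Endothelial couplings are never attached to an inlet
Dirichlet node (they move to the segment's other endpoint): a pinned node
supplies whatever flux its identity row implies, so wall transfer there
would be boundary influx the audit cannot see, and the global identity
"inlet feed = outlet flux + Σ transfer" would not close. Tissue Dirichlet
values (used when imposing measured edge values around a field of view)
replace rows the same way; the outer boundary is otherwise zero-flux.

Lumen cells are eliminated by identity with their nearest vascular node and
reconstructed after the solve, so the system dimension is
nPts + (non-lumen cell count). The reduced solution is verified against a
monolithic dense solve that keeps every lumen cell explicit with its
identity constraint row.

### A note on the default metabolic rate

The default k_met = 14.17 ms⁻¹ = 14 170 s⁻¹ together with D = 1800 µm²/s
gives a diffusion–consumption length √(D/k) ≈ 0.36 µm, far below the
capillary spacing, so the steady tissue field is near-zero a few cells away
from vessel walls and essentially all delivered oxygen is consumed
immediately (outlet flux ≈ 0 in the audits). All conservation, structure
and convergence properties are independent of this steepness. Analyses
that need dynamic range around the 5–15 mmHg hypoxia thresholds (e.g. the
strict-inequality aging sensitivity test and the aging example) use a
moderate rate of 10 s⁻¹, stated where they do so; k_met is a plain
configuration parameter.

## Linear solver

`solve_sparse` is restarted GMRES (restart 200, max 10·restart inner
iterations) with a choice of preconditioner: ILU of the row-equilibrated
matrix (default), two-block block-Jacobi in the natural vascular/tissue
split, or none. Row magnitudes in the coupled system span ~7 orders
(convection ~ µm³/s-level fluxes vs. reaction ~ k·Vt), so the system is
row-equilibrated internally (D = diag(1/max|row|)) and the convergence
criterion — recomputed from the matrix and right-hand side, never taken
from the iterative method's internal estimate — is the relative residual
of the equilibrated system. A few outer iterative-refinement passes polish
the iterate; a solve that cannot reach the tolerance raises with the
residual history instead of returning silently. Identical inputs produce
identical iterate sequences.

The multiscale mode solves the same coupled physics on a coarse→fine grid
hierarchy (factor 2). The network is partitioned once for the finest grid
(the span-two-voxels criterion then holds a fortiori on coarser grids), so
vascular unknowns are identical across levels: cv carries over directly,
ct is trilinearly interpolated from cell centers, with lumen cells first
replaced by their nearest coupled cell's value (distance transform). Labels
are recomputed per level, never downsampled. Multiscale initialization
changes only the path to the solution: 1-, 2- and 3-level runs agree to
10× the solver tolerance. At desk scale (≤ 64³) the direct fine solve is
already fast; the hierarchy is exercised for correctness and available for
larger grids where cold GMRES starts degrade.

## Audits

The blood audit sums boundary inflow and outflow from the Kirchhoff
residuals at boundary nodes: normalized loss |in − out|/in × 100 (%), plus
the worst interior nodal imbalance relative to total inflow. The oxygen
audit recomputes, from the raw couplings and flux bookkeeping rather than
from the solver, inlet feed Σ φ_in·c̄v, outlet flux Σ φ_out·cv, and total
transfer Σ g(cv − ct); the loss |in − out − transfer|/in × 100 closes to
the solver residual (≈10⁻¹³ % at rtol 10⁻¹²). Pointwise steady-state
residuals of every non-Dirichlet equation are reported as an ∞-norm
normalized by the total inlet feed — a per-row throughput normalization
degenerates to 0/0 round-off noise in stagnant regions, where both the
residual and the local throughput underflow.

## Synthetic networks

The generator emulates the essential architecture, not the statistics, of
cortical angioarchitecture: per arteriole/venule pair, a trunk descends
from the pial surface (z = 0, depth increasing downward) in steps of 1.5
lattice spacings to 85% depth, with a connector from each trunk node to the
nearest unused lattice node; trunk and connector diameters taper by
2^(−1/3) per level (dyadic, Murray-style) from a root drawn in 20–40 µm,
floored at 6 µm so tree segments stay non-capillary. Capillaries form a
jittered (±25%) rectangular lattice with diameters uniform in 3–5.5 µm;
the per-axis node counts are chosen by a small search so that lattice edges
plus tree segments land within 20% of the target density (11,600/mm³
default) — at 300³ µm³ this yields 312 segments (11,556/mm³). Every
segment lies on an inlet→outlet path by construction (full lattice, no
pruning), which the generator asserts by BFS from both sides. A single
seed drives all randomness and is recorded in the network metadata.

What this generator does *not* reproduce: tortuosity (segments are
chords), realistic Strahler/loop statistics, pial surface networks,
diameter–depth correlations, and boundary-crossing vessels of real
two-photon reconstructions. Tests passing on these networks therefore
demonstrate numerical correctness (conservation, convergence, orderings),
not physiological field accuracy.

Vessel classification for file-read networks uses the strict diameter
cutoff (capillary iff d < 6 µm), a user-supplied surface depth separating
pial from penetrating vessels (the empirical datasets' depth/diameter
thresholds are not published), and inlet/outlet-rooted traversal to split
arterial from venous trees — a simplification of Strahler-order labeling.

## Aging scenarios

`aging_scenario` applies, per mode: occlusion of ⌊0.30 · n_capillaries⌋
uniformly sampled capillaries (diameter → numerical zero, seeded,
reproducible), inlet hematocrit × 0.70 (0.35 → 0.245), or both. On the
seeded synthetic cortex the hypoxic tissue fraction below 10 mmHg is
ordered young ≤ occlusions-only, young ≤ hematocrit-only, combined ≥ each
single insult; at the default (steep) metabolic rate the fractions sit
near saturation so some comparisons tie, while at k = 10 s⁻¹ the ordering
is strict (see `examples/05_aging_scenarios.py`). Hypoxic "pockets" are
6-connected components (face adjacency, matching the FV stencil) of
sub-threshold tissue cells; thresholds default to 5/10/15 mmHg. The ROI
tools crop fields and statistics to an interior box to exclude
boundary-affected margins, mirroring the strategy of simulating a domain
much larger than the analysis region.

## Problem sizes

The bundled configurations are desk-scale by design: 300³ µm³ networks
(~310 segments, ~2 nL/s–4 nL/s total flow), grids up to 64³ (~2.6·10⁵
coupled unknowns, solving in tens of seconds on one core), ten-seed
ensembles for iteration statistics. The formulation has no intrinsic scale
cap: grids, hierarchy depth and network extent are configuration.

## Known limitations

* No pulsatility, vessel compliance, RBC-resolved transport, or 3D
  Navier–Stokes flow.
* No hemoglobin-dissociation kinetics, CO₂/pH coupling, or interstitial
  convection; oxygen is a single linear scalar per compartment.
* The exact plasma-skimming and viscosity laws of empirical datasets vary
  by source; numerical equality with any particular published flow field
  is not claimed — conservation and structural properties are the tested
  surface.
* Molar audits (nmol/s) require a solubility α, which is configuration;
  without it audits are reported in tension-volume units and normalized
  percentages.
* Endothelial cells diffuse with the tissue D; no distinct wall
  diffusivity.
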