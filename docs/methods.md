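# Methods

## Model

`stentdamage` evolves a per-element continuum-damage field on a hexahedral
mesh of a biodegradable zinc-alloy stent. Damage is the linear sum of four
mechanisms — uniform corrosion, stress corrosion, pitting and fatigue —
each integrated explicitly in time; an element is deleted when its total
damage reaches 1, which re-exposes its neighbours and lets corrosion
penetrate inward. Mass loss is the removed-volume fraction (density is
uniform, so volume fraction equals mass fraction), and structural fracture
is flagged the first time the surviving elements stop forming a single
face-connected component.

Assumptions worth stating plainly:

* The mechanical state is a *frozen* residual stress field (the product of
  balloon expansion and elastic recoil, supplied as a table or generated
  analytically). No finite-element re-solve is performed during
  degradation; stresses change only through multiplicative modifiers
  (pulsatile pressure scale, damage discount, optional concentration factor
  κ). Load redistribution after element loss is not modelled.
* The pulsatile pressure cycle (default 100 ± 20 mmHg) is represented
  quasi-statically: within a macro time step the stent completes many
  cardiac cycles, and all rate laws are evaluated at the per-cycle peak
  pressure (120 mmHg → stress scale 1.2 relative to the 100 mmHg reference
  field). No mean-stress correction (Goodman/Gerber) is applied.
* Fatigue is single-frequency constant-amplitude per step (Miner linear
  accumulation of `f·dt / N(σ)` with Basquin life `N = A σ^(−k)`), so no
  rainflow counting is needed.

## Driving stress versus effective stress

Damage discounts an element's load-bearing capability: the *effective*
stress `σ̄(1−D)` and modulus `Ē(1−D)` decay linearly to zero (strain
equivalence), and this is what `region_mean_effective_stress` reports — the
mean effective stress of a region falls linearly as it degrades.

The stress *driving* the stress-corrosion and fatigue rate laws is
deliberately **not** discounted by the element's own damage. In a frozen-
field model the load a damaged element sheds is in reality carried by the
immediately surrounding material of the same region, so the mechanical
driving force for corrosion and fatigue there does not vanish with the
element's integrity. Discounting the driving stress makes the model
self-quenching: every element's σ decays toward the stress-corrosion
threshold, the gate `σ ≥ σ_th` shuts mid-life, and damaged regions slow
down instead of accelerating — the opposite of the stress-concentration
behaviour observed around surface defects. It also breaks the expected
group orderings: with a discounted driving stress the fatigue channel's
contribution is diluted out of the self-accelerating `(1−D_SC)^(−R)` term
and the coupled group can transiently degrade *slower* than the pulsatile
group, at any time step (verified on a single-element ODE at dt = 1e-4 h).
With an undiscounted driving stress the per-element damage ODEs are
autonomous and monotone in the pressure scale, so "pulsatile ≥ control" and
"coupled ≥ pulsatile" hold pointwise by construction. Both stresses use the
same von Mises measure, so the corrosion and fatigue channels see identical
σ values, and κ (when enabled) multiplies the driving stress of exposed
elements bordering deleted ones.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| density | 8.5 | g/cm³ | zinc alloy |
| Ē | 74 500 | MPa | undamaged modulus |
| ν | 0.3 | – | |
| yield / ultimate | 220 / 325 | MPa | σ_th basis |
| δ_U | 0.1 | mm | uniform-corrosion feature size |
| k_U | 0.05 | 1/h | uniform kinetics; front speed δ_U·k_U = 5 µm/h |
| δ_SC | 0.07 | mm | stress-corrosion feature size |
| S | 0.005 | mm²·h/N | stress-corrosion kinetics |
| R | 2 | – | damage feedback exponent |
| σ_th | 66 | MPa | 0.30 × yield by default (low end of the 30 %-of-yield to 90 %-of-ultimate range); explicit value overrides |
| β | 0.8 | – | pit propagation factor (< 1: pits decelerate inward) |
| Weibull shape, scale | 1, 1 | – | unit exponential — the minimal-assumption "standard" Weibull; mean pit intensity 1 makes the expected pitting rate equal the uniform rate |
| A, k | 1e12 MPa^k·cyc, 3 | | **placeholders**, not calibrated to a measured zinc S-N curve |
| f | 4320 | cycles/h | 1.2 Hz ≈ 72 bpm resting heart rate |
| σ_floor | 0 | MPa | optional endurance floor, off by default (pure Basquin) |
| κ | 1 | – | optional stress-concentration multiplier on exposed elements bordering deleted ones; 1 = off |

## Synthetic inputs

`build_ring_stent_mesh` generates an idealised single-ring stent: a closed
zig-zag (triangle-wave) loop of hexahedra on a cylinder, with
`2·n_crowns·elements_per_segment` elements, ring height fixed at the radius,
and the two elements meeting at each apex labelled `"corolla"`. It
reproduces the *topology* of a laser-cut ring (crowns joined by straight
struts, every element on the free surface), not any particular product
geometry: real stents have multiple rings with connectors, filleted crowns,
and several elements across the strut cross-section, so through-thickness
corrosion gradients and intra-strut stress gradients are absent here.

`analytic_crown_field` stands in for the deployment FE stage: crown
elements carry a uniaxial peak stress (default 230 MPa, comfortably above
the 66 MPa threshold, as after expansion and recoil) decaying geometrically
with face-graph distance into the struts (default 0.5 per element). It
reproduces the qualitative stress topology of a deployed stent — bending
stress concentrated at the crowns — which is what the group-ordering and
crown-first-failure results exercise. Passing those tests therefore shows
the coupling logic is right, not that absolute lifetimes match any
particular device; for that, supply a real residual field
(`load_stress_field` / `read_stress_table`) and calibrated S-N constants.

The default study configuration (examples/ring_study.toml and the
acceptance script) uses n_crowns = 6 with 6 elements per segment
(72 elements), dt = 0.005 h and t_max = 40 h: the sub-crown struts then sit
both above and below σ_th across the groups, so the runs exercise the
stress-corrosion-dominated early phase and the uniform/pitting-dominated
late phase, and the step resolves the fastest stress-corrosion lifetimes
(~0.1 h) with ~20 steps.

## Numerics

* **Integration** — explicit Euler per component with a user time step;
  all elements crossing `D ≥ 1` within a step are deleted *simultaneously*
  at step end, after which exposure and pit inheritance are recomputed
  once. This makes the update order-independent and runs bit-reproducible
  (same config + seed ⇒ identical removal logs).
* **Overshoot** — component sums may exceed 1 inside a step; deletion
  triggers at `D ≥ 1` and reported damage is clamped to 1. Halving dt moves
  the pure-uniform-corrosion degradation time by at most one coarse dt.
* **Pit inheritance tie-break** — a newly exposed element bordering
  several removed pitted elements takes `λ_e = β · max(λ_n)`: growth is
  dominated by the deepest adjacent pit.
* **Characteristic length** — `Le = volume^(1/3)`: equals the edge length
  for cubic elements and stays well-defined for distorted hexahedra, and
  makes the uniform front speed `δ_U·k_U` mesh-independent (halving Le
  doubles the per-element rate exactly).
* **Exposure** — an alive element is exposed iff it has at least one free
  face (domain boundary or face shared with a deleted element). Boundary
  faces can be marked *sealed* (`seal_all_but_axis_ends`) to emulate coated
  or symmetry surfaces — used by the 1-D layer-peeling oracle, where a
  single-end-exposed column of n 0.1 mm layers degrades in exactly
  n × 20 h under the default kinetics.
* **Fracture criterion** — loss of face-connectivity of the alive-element
  graph (SciPy connected components; an independent BFS oracle backs the
  tests). A closed ring is a loop, so it takes two separate cuts to
  disconnect it; the run continues past fracture since the severed pieces
  keep corroding, and the fracture time is reported separately as
  end-of-service.
* **Degenerate inputs** — `D_SC ≥ 1` in the rate law is a state error
  (such an element should already be deleted); `k_U = 0` or `S = 0` switch
  a channel off; a stress field must carry one finite record per element
  (scalars are embedded as uniaxial tensors, preserving von Mises).

## Limitations

* No FE re-solve: load redistribution enters only through the optional κ
  multiplier, and the residual field is frozen.
* Basquin constants and cardiac frequency are stand-ins; absolute fatigue
  lifetimes are not quantitative until calibrated.
* Idealised geometry (single ring, one element per strut cross-section in
  the generator) and idealised vessel (none — vessel mechanics are outside
  the model; their product, the residual stress field, is the input).
* Corrosion is phenomenological: no electrochemistry, ion transport,
  corrosion-product layers or galvanic coupling.
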