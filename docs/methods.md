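# Methods

`woundchip` models and analyses a microfluidic platform for DC electrical
stimulation of in vitro scratch wounds: a channel network filled with
physiological saline, electrodes in open reservoirs driving a constant
current across a wounded keratinocyte monolayer, a colorimetric PANI layer
reporting pH, and time-lapse phase-contrast imaging of the closing wound.
This note records the models, their assumptions, the defaults that matter,
and the design choices made where the design was genuinely open.

## Chip geometry

Three parametric layouts are built from straight channel segments meeting at
the origin, terminated by circular reservoirs: `straight` (one channel),
`t_junction` (three perpendicular branches), and `peace_sign` (four
branches). In the peace sign, the central cathode branch points up (+y), the
two anode branches are angled 45° below the horizontal on either side — so
their current crosses the junction before bending toward the cathode — and a
fourth "scratch runway" (0.9 mm wide, sized for a p10 pipette tip) points
down. Exact channel dimensions are not published for the device this
emulates, so canonical defaults are used and exposed as parameters: all
branches 0.9 mm wide, 0.08 mm high, 5 mm long; reservoir radius 2 mm.
Absolute network resistances therefore need not match any particular
fabricated device; they are validated against closed forms instead.

Units are SI internally; interfaces use mm, µA, mV/mm, kΩ. Coordinates: mm,
origin at the junction, x right, y up. The wound zone is a 0.7 × 0.9 mm
rectangle centred on the junction.

Rasterization covers the bounding box (plus a configurable margin) with a
square cell-centred grid; a cell is conducting if its centre lies inside the
channel/reservoir polygon (shapely), with sheet conductance σ·h. The
rasterized area converges to the polygon area at first order in the spacing;
the spacing must be at most one sixth of the narrowest channel width.

## Electric field solver

The channel height (0.08 mm) is far smaller than any lateral dimension, so
the potential is solved in a thin-sheet (2.5-D) approximation: steady
current conservation ∇·(σh∇V) = 0 discretized with the 5-point stencil,
face conductances by harmonic mean, zero-flux walls. The injected current is
distributed uniformly over the active anode's footprint (a disc of 0.6× the
reservoir radius, standing for the submerged electrode tip) and withdrawn at
the cathode; the gauge is fixed by pinning one cathode cell to 0 V. The
sparse system is solved directly; a relative residual above 1e−8 is an
error, not a warning. Network resistance is the footprint-averaged potential
difference divided by the current.

Conventions: E = −∇V by central differences (one-sided at channel edges);
anode left / cathode right in the canonical uni-directional placement, so
the field and cathodal migration point along +x. Electrode roles are
per-experiment: the pseudo-converging scheme places anodes in the leftmost
and rightmost reservoirs and the cathode in the central branch, alternating
the active anode every 30 min (configurable).

Because the problem is linear in the injected current, calibration to a
target wound-centre field strength is one unit-current solve plus scaling,
verified by a confirming solve to 0.5%. The dead-zone metric is the
wound-centre |E| divided by the mean |E| in the middle third of the
cathode-containing branch (the branch that carries the full current in every
state): 1 for a uniform channel, < 1 when current short-cuts the junction.
On these canonical geometries the t-junction's converging dead-zone ratio is
≈ 0.55 and the peace sign's ≈ 0.80 — the angled anode branches recover much
of the lost field, which is the design rationale for the layout.

What the 2.5-D model does not capture: the three-dimensional current
constriction where reservoirs meet channels and the electrode–electrolyte
interface itself. Absolute resistances of a real device depend on both, so
solver validation uses uniform-conductor closed forms (|E| = I/(σA),
I = σEA), current conservation through arbitrary cuts, mirror symmetry, and
grid-refinement stability — not published device values.

## Joule heating and thermal bound

Energy: E = I²Rt. For the two canonical protocols (25 µA, 101.6 kΩ, 12 h)
and (20 µA, 108.3 kΩ, 12 h) this gives 2.74 J and 1.87 J.

The transient solve bounds the wound-zone temperature rise. The chip is a
layered plan-view sheet: electrolyte (only in channels, 0.08 mm), plastic
substrate (1 mm) below, plastic lid (8.5 mm) above. Each grid cell carries
the lumped areal heat capacity and in-plane sheet thermal conductance of its
layer stack; the Joule source σh|E|² (W/m²) acts on conducting cells; heat
leaves by convection (h = 5 W m⁻² K⁻¹, both faces by default) to
surroundings at 310.15 K. Backward-Euler time stepping (default 120 s) with
a single sparse factorization makes the 12-h protocol a few-second
computation. Losses are linear, so the rise grows monotonically to a steady
state and the reported maximum is conservative in protocol length; the
steady state is independent of the heat capacities (a property the tests
exploit by scaling Cp ×10).

Lateral spreading matters: heat diffuses ~√(k_sheet/h_loss) ≈ 15 mm through
the plastic before convecting away, so the rasterization margin for thermal
runs should be several mm (6 mm default in the acceptance computation; the
finite margin makes the bound conservative). With the default materials
(electrolyte k = 2 W m⁻¹ K⁻¹; acrylic k = 0.19; PEDOT:PSS entries included
for completeness) the canonical uni-directional protocol heats the wound
zone by ≈ 0.02 °C — comfortably below the 0.1 °C level at which thermal
effects on cell migration would become a concern. Two notes on the material
table: the electrolyte thermal conductivity of 2 W m⁻¹ K⁻¹ (≈3× water) is
kept as configured upstream but is conservative for this bound; and the
electrolyte heat capacity defaults to water's 4184 J kg⁻¹ K⁻¹ (a literature
value of 4 J kg⁻¹ K⁻¹ appears to drop a ×10³ and would only affect the
transient, not the steady bound).

Electrode dose bookkeeping is closed-form: disc current density I/(π(d/2)²)
(0.40 mA on a 3-mm disc ≈ 5.7 mA cm⁻², ≈256× the 25 µA/12-mm device
electrode), capacitive delivery time t = q/i with q = CSC·area (≈1810 s for
40 mC cm⁻² at 25 µA), and a relay charge budget in which each anode
discharges I·τ per active phase and recovers `recharge_fraction` (default
0.9; no published value) of one phase's delivery while idle, flagging the
phase in which net discharge first exceeds q.

## pH colorimetry

PANI's color tracks its protonation/oxidation state from yellow-green
(acid) through blue to purple (base). Hue is computed from the mean RGB
color of the region of interest — averaging RGB first and converting once,
not averaging per-pixel hues; the two differ because hue is nonlinear and
circular. Achromatic means return 0° with a warning. PANI hues span roughly
60–300°, away from the 0°/360° wrap, so no circular statistics are needed.

The calibration model is a bi-dose-response (dual-logistic) curve

    hue(pH) = A1 + (A2−A1)·[ p/(1+10^{h1(logx01−pH)}) + (1−p)/(1+10^{h2(logx02−pH)}) ]

fitted by bounded nonlinear least squares with heuristic initialization
(asymptotes from the extreme hues, transition centres from the 25%/75%
response crossings, unit slopes, p = 0.5). At least 8 distinct pH points are
required; a 15-buffer series spanning pH 2.7–11.3 is the reference design.
pH estimation inverts the fitted curve by bisection (tolerance 1e−4 pH) on
its calibration domain after a numerical monotonicity check; hues outside
the curve's range are clamped to the domain edge and flagged extrapolated.
The synthetic renderer's default curve (A1 = 80°, A2 = 280°, centres at pH
6 and 9.5, unit slopes, p = 0.5) spans the green→purple range.

## Wound closure analysis

A scratch wound in phase contrast is a smooth band between two textured
sheets. Segmentation: sliding-window standard deviation (window 15 px,
about 1.5 cell diameters at the synthetic scale — tune to the imaging
scale), Otsu threshold on the texture map, morphological closing (radius
5 px, edge-padded to avoid border artefacts), selection of the low-texture
component straddling the declared wound axis (centre column by default),
then a compensating dilation of window//3 px because the windowed statistic
smears cell texture into the gap and biases the boundary inward. Frames with
no texture contrast are flagged: fully textured → empty wound (area 0);
fully smooth → whole-frame wound, degenerate. Because the statistic is
local contrast, closure is invariant to affine intensity rescaling.

Closure is area normalized to frame 0; closure% = 100(1 − A/A0); the
closure rate is the least-squares slope of closure% vs time from t = 0
until the first frame at ≥95% closure (else all frames), so a saturated
plateau does not dilute the estimate. Kymographs average 7 evenly spaced
horizontal lines per frame (line rows at the centres of equal vertical
strips of the ROI); a 12-h, 10-min-interval stack yields 72 rows (frames at
t = 0, 10, …, 710 min — half-open convention). Directedness: per
displacement step, cosθ = Δx/√(Δx²+Δy²), zero-length steps skipped; the
per-cell mean step cosine is the headline statistic (+1 rightward/cathodal,
−1 leftward), with the net-displacement cosine reported alongside because
the two can differ for meandering tracks; all-stationary cells are excluded
and counted.

## Synthetic data generator

No microscope data ships with the package; a seeded generator stands in for
it and carries full ground truth (tracks, per-frame true wound masks, true
closure rate, true directedness), so every analysis operator is tested
against known answers. It emulates the observables of collective
keratinocyte electrotaxis — closure, directedness, relay reversal — with no
mechanistic claim.

Two cell sheets (320 cells each by default) flank a 160-px gap in a 512-px
field, imaged every 10 min for 12 h (72 frames). Per frame each cell's
heading blends its previous heading (persistence 0.6), a random turn, and a
field-bias term β along ±x; the step is speed × Δt × motility factor
(12 px/h ≈ 30 µm/h at ~2.5 µm/px). Four ingredients keep the monolayer
behaving like a tissue rather than a gas — a persistent random walk alone
disperses, fragments, or jams:

- **Exclusion + adhesion.** Overlapping neighbours (< 16 px) are pushed
  apart; separated nearest neighbours are pulled back toward a rest length,
  making the sheet an elastic, cohesive monolayer that transmits edge
  forces as tension.
- **Edge march.** Cells within 22 px of their sheet's gap-facing front
  advance deterministically into the gap at 1.8 px/h (the kenotactic term
  that closes unstimulated wounds), modulated asymmetrically by the field:
  the edge advancing with the field is boosted by (1 + gain·β), the
  opposing edge attenuated but floored at 60% of its kenotactic speed —
  leader cells respond to the field far more strongly than the bulk, and
  the against-field edge still closes.
- **Division backfill.** Cells with ≤ 4 neighbours divide (probability
  0.15·√m per frame), but never within two edge bands of the front, so
  proliferation replenishes the stretching bulk without itself pushing the
  front. The √m coupling reflects that motility inhibition also slows
  proliferation.
- **Wall anchoring.** Cells within 12 px of the outer walls are frozen:
  the monolayer continues beyond the field of view, which prevents
  wholesale sheet translation under bias.

Scenario presets were calibrated once to the study conditions they emulate
and then frozen: `control` (β = 0) closes at ≈3.5 %/h, `uni` (β = 0.55)
at ≈6–8 %/h, `converging` (relay-signed β = 0.8, 30-min period) between
the two, `inhibited` (motility factor 0.28) at ≈1.0 %/h, and
`inhibited+uni` at ≈2.8 %/h (with stimulation also restoring proliferative
backfill). The true closure rate is the slope of the true-mask closure
curve under the same fit-window convention as the estimator. The true wound
mask is the cell-free connected component straddling the centre column
after stamping cells as discs and closing at half the exclusion radius.

Rendering draws each cell as a bright-rimmed disc with a noisy interior on
a smooth shaded background plus white noise, 16-bit grayscale — giving the
texture contrast the segmenter keys on. Rendering is deterministic given
the simulation seed. The pH renderer maps a pH field through the
calibration curve to hue (fixed saturation/value, per-pixel hue noise,
8-bit RGB), so ROI pH is recoverable by the colorimetry module.

What the generator does not emulate: phase-contrast optics (halos, shading
gradients beyond a linear ramp), cell shape and intercalation, mechanistic
electrotaxis (membrane polarization, traction), debris and uneven
illumination. Passing tests therefore demonstrate that the analysis
operators are correct and unbiased on well-posed inputs with this noise
structure — not that segmentation parameters transfer unchanged to any
particular microscope.

## Numerical choices and degenerate inputs

- Field solve: direct sparse factorization; singular systems (isolated
  conducting islands) are excluded by restricting to the electrode-bearing
  component; islands report the gauge potential.
- Calibration fit: deterministic for given data; non-convergence raises
  with diagnostics rather than returning a silent best-effort.
- hue_to_pH at a domain edge returns the edge pH without the extrapolation
  flag only if the hue equals the edge value exactly; beyond it, clamped
  and flagged.
- Wound segmentation of an image with zero intensity spread is degenerate
  by definition (whole-frame wound, flagged).
- closure_rate requires ≥ 3 points and a non-degenerate time window.
- All generators take an explicit seed; identical seeds give bit-identical
  stacks and tracks.

## Problem sizes

Default working resolutions keep every computation interactive on one CPU:
field solves on 0.1 mm grids (≈10⁴–10⁵ unknowns, < 1 s), the 12-h thermal
protocol at 0.125 mm spacing and 120-s steps (≈5×10⁴ cells × 360 steps,
seconds), simulations of ≈650–1500 cells over 72 frames (≈4 s), rendering
and segmentation of 72 512² frames (≈4 s each). Grid-refinement checks in
the tests halve the field-solver spacing and confirm < 1% movement in the
wound-centre field.

## Known limitations

- The 2.5-D electrical and thermal models omit genuinely 3-D effects
  (reservoir constriction, vertical temperature stratification); both are
  used for bounds and relative comparisons, not absolute device prediction.
- The segmentation defaults are tuned to the synthetic renderer's scale;
  real data at other magnifications needs the texture window rescaled.
- The migration model's parameters are phenomenological; its scenario rates
  are calibration targets, not predictions.
- Electrode electrochemistry (double-layer structure, faradaic kinetics) is
  reduced to charge bookkeeping; pH is measured optically, not predicted
  from current.
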