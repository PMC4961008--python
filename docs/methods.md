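# Methods

## Model

A plant is `n` identical, independent stems; all traits are `n` times the
single-stem value, so `V_s(h, n) = n·V_t(h)` holds exactly and the
equal-height volume ratio between a shrub and a tree with identical
per-stem parameters is exactly `n`. Foliage and roots are outside the
model; so is self-thinning within an individual, which restricts the
model's realism to small plants.

### Segments

Each stem or branch of length `l` (cm) is a truncated cone with basal
radius `max(b·l, r_tip)` and tip radius `r_tip`; when `b·l ≤ r_tip` the
segment is a cylinder of radius `r_tip`. Volume uses the frustum closed
form `(π l/3)(R² + R r + r²)`. Surface area is the lateral (slant-height)
area `π (R + r) √(l² + (R − r)²)`, end caps excluded, because the quantity
stands for bark/epidermis (and equivalently cambium and
stem-photosynthetic) area; at the slenderness used here (`b = 0.0075`) the
slant correction relative to `π (R + r) l` is below 1e−5, so no option is
exposed. Junction overlap between parent and child segments is ignored:
segments are disjoint idealised solids, and branch positions and angles are
irrelevant to volumes, areas and counts.

### Branching recursion

A parent of length `l ≥ l_min` carries `a` children of length `p·l` (the
parent's own continuing tip is not counted as a child). Children are born
with zero length when the parent reaches `(2/3)·l_min` and grow linearly
until the parent reaches `l_min`, where they attain `p·l_min`; beyond that
they track `p·parent`. The ramp start value of zero is the natural reading
of children "beginning to grow" at the lower joint, and it makes every
plant trait continuous in stem length; the generation recursion then
terminates without an arbitrary depth cap because `p < 1` drives child
lengths to zero in finitely many steps. Whether the `r_tip` floor is
applied before or after the ramp is unobservable at the default parameters:
newborn children are cylinders of radius `r_tip` either way.

### Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| `n` | stems per plant | 1 (tree) | – |
| `a` | child branches per parent per branching step | 2 | – |
| `p` | child/parent length ratio | 0.5 | – |
| `l_min` | branching threshold length | 20 | cm |
| `r_tip` | tip radius of any stem or branch | 0.1 | cm |
| `b` | basal-radius-to-length ratio | 0.0075 | – |
| `g_s` | shrub/tree woody-volume growth-rate ratio | 1 | – |

The same `b` and `r_tip` floor apply to stems and branches alike. The
defaults above are the reference parameterisation used by the comparison
examples, the tests and the acceptance script.

### Height inversion and comparisons

`V(h)` is continuous, strictly increasing and piecewise smooth (kinks at
generation births), so `height_from_volume` brackets the root by geometric
expansion from `h = 1 cm` and refines with Brent's method
(`xtol = 1e-13`, relative tolerance near machine precision); the residual
satisfies `|V(h) − v|/v ≤ 1e-10` across volumes from 1e−3 to 1e5 cm³, and
the result is independent of the initial bracket to that tolerance.
`compare_trait` solves the tree at volume `v` and the shrub at `g_s·v`,
evaluates the trait at each height and reports
`100·(shrub − tree)/tree`, unrounded. Curve tables default to a 200-point
log-spaced volume grid on 1–1000 cm³.

### Niklas–Spatz radius mode

The alternative mode replaces the proportional radius rule by inverting
`L = k₅·D^(2/3) − k₆` to get a segment's basal diameter from its length
(same `r_tip` floor). `k₅` (cm^⅓) and `k₆` (cm) are empirical constants
that must be supplied by the user; this package fixes no defaults because
none are part of the model specification proper. Tests exercise the mode
with representative values (`k₅ = 30`, `k₆ = 5`) and check qualitative
properties only: tree taller than shrub, and percent-greater
cross-section/surface increasing in `n`.

### Biomechanics

The bending-moment magnitude about the stem base is
`M = ∫₀ᴸ ρ g π r(s)² x(s) ds` (SI units) with `x(s)` the horizontal offset
of arc position `s`: `s·sin θ` for a straight stem leaning at `θ` from the
vertical, and `min(s·sin θ, cutoff)` for an uprising stem that turns
vertical once its offset reaches the cutoff (default 1 m) — a sharp
corner, with the bend supplied to the integrator as a breakpoint.
Branches and foliage are excluded from the mass, so computed moments are
lower bounds for a stem carrying a canopy; wind and snow loading are out of
scope. The default taper is the conical profile (radius linear from
`max(b·L, r_tip)` to `r_tip`); any other taper, e.g. a Niklas–Spatz profile
with user-supplied constants, can be passed as a callable. Wood density
defaults to 600 kg·m⁻³ and `g = 9.81 m·s⁻²`; both are configurable, and
because published constants for the taper used in comparable figures are
not available, all checks on this module are closed-form, ordering and
independent-oracle based — absolute N·m values are not a validation
surface. Quadrature is `scipy.integrate.quad` at `epsrel = 1e-10`,
cross-checked against a 10⁶-panel midpoint Riemann sum to 1e−6 relative.

### Evidence table

The packaged TSV transcribes 14 published shrub-vs-tree growth comparisons
with evidence grades `++` (good support), `+` (support), `+/-`
(inconclusive), `-` (against); the typographic minus (`+/−`) is normalised
to ASCII on load. The tally is a plain vote count: 3 `++`, 9 `+`, 2 `+/-`,
0 `-` → 12 of 14 supportive. No effect sizes are modelled.

## Verification and known discrepancy

The test suite verifies the closed forms against hand-evaluated arithmetic,
the plant totals against explicit hand enumeration of all segments for
small plants, the `n`-fold volume identity to machine precision, continuity
across the ramp joints to 1e−9 relative, the solver round-trip, and the
bending moment against an analytic cylinder case and the Riemann oracle.

At 500 cm³ with the reference parameters the model computes percent-greater
basal cross-sectional areas of **38.9 / 61.2 / 76.0%** for 3/5/7 stems.
The corresponding integer predictions reported in earlier work on this
model are 39 / 61 / 75%; the implied shrub/tree height ratios agree with
this implementation to better than 0.3%, confirming the volume model.

For total surface area this implementation computes **43.0 / 67.1 /
89.1%**, whereas the earlier reported integers are 35 / 53 / 74%. These
reported values could not be reproduced from the model as specified under
any surface-area definition examined (slant vs projected lateral area,
basal-radius cylinders, stems-only, taper-continuous segment chains,
alternative branch-count conventions, or the Niklas–Spatz substitution),
nor under perturbed parameters; the implied surface ratios are mutually
inconsistent with every per-segment area formula at the heights fixed by
the (verified) cross-sectional results. The geometrically correct frustum
lateral area is therefore used throughout, and the surface-area
percentages this package reports are the ones its own model actually
implies. The qualitative claim — surface advantage positive and increasing
with `n` — holds regardless.

## Limitations

- Valid for small plants only: no within-individual thinning, no foliage
  or root mass, no junction geometry.
- Strict ordering of cross-section and surface curves by stem count holds
  for volumes above ≈15 cm³; in the clamped-cylinder regime of very small
  plants the discrete branching structure can locally invert neighbouring
  curves.
- `twig_count` is piecewise constant in height (jumps by factors of `a`),
  so twig comparisons at a single volume are sensitive to the readout
  point near a branching threshold.
- The biomechanics module treats a stem as a rigid line of distributed
  mass; no stress/strain fields, reaction wood or buckling limits.
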