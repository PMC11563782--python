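# Methods

## The measurement principle

A hypha growing from a side wall into a rectangular microchannel is a
clamped cantilever of annular cross-section exposed to a pressure-driven
laminar flow. The flow exerts a distributed drag f(y) on the filament; the
resulting tip deflection, observed by microscopy over a set of volumetric
flow rates Q, is inverted through Euler–Bernoulli beam theory to the
bending stiffness k_b = E·I. With the wall cross-section known (outer
radius r, wall thickness t), the longitudinal Young's modulus of the wall
material follows as E = k_b/I with I = (π/4)(r⁴ − (r−t)⁴).

Two device variants are modeled. In the *floor configuration* the hypha
lies on the channel floor and the drag is proportional to the unperturbed
wall shear gradient ∂u/∂z|₀; in the *center configuration* it sits midway
between two plates and the drag is proportional to the local center-plane
velocity with a logarithmic confinement factor ε = 1/(ln(h/2r) − 0.92),
valid only for h > 2r·e^0.92 ≈ 5r. Both force series share the
rectangular-duct harmonic envelope and are evaluated with the classical 2-D
Stokes drag coefficients (both reduce to 4πµ × {r·gradient, ε·velocity};
the implementation evaluates the printed series forms, and tests confirm
the proportionality).

## Units

Internally everything is µm, s, µN. Consequences: viscosity in µN·s·µm⁻²
(water ≈ 1.0·10⁻⁹ at 20 °C), pressure in MPa, k_b in µN·µm², E in MPa, with
no hidden conversion factors. Interfaces accept µL·min⁻¹ for flow rates
(1 µL·min⁻¹ = 10⁹/60 µm³·s⁻¹) and degrees for angles; forces per length are
reported in pN·µm⁻¹.

## Flow model

The duct velocity field is the standard odd-harmonic series (sine modes
across the height h, cosh envelope across the width w), normalized through
the hydraulic resistance per unit length

    R_f = 12µ/(h³w) · [1 − (192h/π⁵w) Σ_odd n⁻⁵ tanh(nπw/2h)]⁻¹

so that the cross-section integral of u equals Q. The velocity series
defaults to n_max = 51 (pointwise converged to <10⁻³); the drag series
defaults to n_max = 11, the truncation used when the method was
established. At mid-span and aspect ratio w/h = 10 the first neglected
center-configuration term contributes <0.05 % (the claim bound is 0.5 %).
A caveat the diagnostic `truncation_tail_report` makes explicit: for the
floor configuration the series decays only as n⁻², and while the *single*
n = 13 term is ≈0.5 %, the *cumulative* tail at n = 11 is several percent.
Both metrics are reported; the default truncation follows the established
convention, and the proportionality tests pin the force to the converged
reference gradient to within 1 % across the usable span.

Flow-rate recovery from µPIV profiles fits the single scale factor Q to the
analytical horizontal (mid-height) profile by linear least squares, with
the chamber geometry taken as known. Vertical-axis samples are excluded by
default: out-of-focus particles keep the apparent velocity near the
horizontal walls at roughly 30 % of the center maximum (depth-of-field
artifact), which would bias the fit. A flag re-admits them for sensitivity
studies.

## Beam model

The deflection under the distributed load solves d⁴w/dy′⁴ = cos(α₁)·f/k_b
with clamped base and free end, by four successive cumulative Simpson
integrations on a uniform 1201-point arc grid — exact for polynomial loads
through cubic order and within 10⁻⁵ of an independent fine-mesh
boundary-value solution for the series loads (tested). The hemispherical
tip end-effect enters as a point force F_tip = ∫_{L−r}^L f* dy′ (with the
diminished load f* = cos α₁·f), deflecting the tip by F_tip·L³/(3k_b);
neglecting it biases k_b low by an amount that grows as L shrinks
(≈8–9 % at L = 40 µm under the implemented load shapes; reported by
`tip_force_neglect_bias` as a diagnostic rather than asserted, since the
exact figure depends on the assumed load profile near the wall).

Angle conventions: the hypha's initial chord makes angle α₀ with the
spanwise axis; the deflected chord angle α₁ both diminishes the effective
load (cos α₁) and is how deflections appear in images. Measured x-direction
displacements are converted to axis-perpendicular deflections by 1/cos α₀.
The forward simulation solves the α₁–load coupling by fixed-point iteration
(start α₁ = α₀, tolerance 10⁻⁸ rad, ≤50 iterations — non-convergence flags
a deflection far outside small-angle validity). In fitting, α₁ is taken
from the measurement record, mirroring how it is read from images; it is
not recomputed.

The inverse fit uses the linearity of the model: w_max = (A/k_b)·Q·cos α₁,
with the per-hypha response A computed once at unit flow rate. Ordinary
least squares through the origin on the predictor Q·cos α₁ yields 1/k_b
(zero flow produces zero deflection, so no intercept; an optional intercept
diagnoses adhesion artifacts such as a first point stuck to the glass).
Standard errors come from the delta method. Validity criteria applied
first: relative tip deflection w_max/L ≤ 0.25 (boundary inclusive), and in
the center configuration the whole hypha is rejected if it sits more than
10 µm from the channel mid-plane — at the default 90 µm chamber height a
10 µm offset changes the mid-plane load estimate by <5 %, at half that
height it no longer does (tested). Fits use absolute displacements and warn
on sign flips. Zero-flow anchor rows pass through the filter but are
excluded from the through-origin fit (they carry no information for it) and
are reported as exclusions with that reason.

## Loading-circuit model

The spore-loading design reduces to a resistor network: the loading chamber
feeds a serpentine bypass to one outlet and N = 80 parallel growth channels
(hydraulic diameter 2.8 µm) to the other. Growth channels are modeled as
square ducts of side 2.8 µm and (assumed) length 100 µm using the same R_f
series — the fabricated funnel shape is out of scope, and the absolute
resistance cancels from the design ratio. The serpentine is sized to 20×
the parallel resistance of all open channels; with ideal (zero-resistance)
outlets the growth-to-serpentine flow ratio is then exactly 20 at the start
of loading. Blocked channels are removed outright (spores as perfect
plugs). The nodal solve is a dense conductance-matrix solve with an
explicit connectivity check; flows satisfy conservation to solver accuracy.
Sweeping the blocking count shows the ratio falling monotonically to zero
and the chamber pressure rising to its finite all-blocked maximum
Q_in·R_serpentine — the property that makes loading safe against
overpressure. Downstream chamber/outlet resistances default to zero and are
configurable.

## Synthetic-data generator

The generator emulates the experimental envelope, not the imaging: exposed
lengths uniform on 30–150 µm (30 µm is the minimum measurable length),
radii normal (mean 1.4 µm, sd 0.1 µm), initial tilts normal (sd 5°),
mid-plane offsets normal (sd 3 µm, truncated to the channel), true k_b
log-normal with mean 18.3 µN·µm² and coefficient of variation 8.7/18.3, and
an optional linear k_b-vs-length trend (centered so the population mean is
preserved) emulating cell-wall maturation along older, longer hyphae.
Measurement noise is Gaussian on the scalar tip displacement (default
σ = 0.2 µm), reflecting that the image analysis reduces each frame to tip
and base coordinates before any fitting. The flow schedule is adaptive per
hypha: the top rate targets a relative tip deflection of 0.2, capped at the
50 µL·min⁻¹ pump limit, plus a zero-flow anchor row — mirroring the
practice of dialing the pump per specimen, where required rates differ by
an order of magnitude or more between short stiff and long compliant
hyphae. The µPIV emulation optionally clamps the vertical profile at 30 %
of the center maximum (a hard floor — the simplest model consistent with
the documented artifact; a smooth depth-of-correlation kernel is out of
scope).

The chamber geometry defaults (w = 500 µm; h = 90 µm center, 45 µm floor —
the same molded footprint with doubled height) are package assumptions, not
published dimensions: the width is a plausible chamber scale and the height
is chosen so the ±10 µm center-plane tolerance corresponds to a <5 % force
deviation. All geometry-dependent absolute force values therefore depend on
these assumptions; the recovery tests do not, since the same geometry
enters the forward and inverse paths.

Determinism: population draws, measurement noise and profile noise use
separate children of the master seed (`numpy` `SeedSequence.spawn`), so any
stage can be regenerated independently; a fixed seed reproduces output
files byte for byte.

What passing tests show — and do not. Parameter-recovery results (noiseless
round trips to <10⁻⁴; median error <5 % at σ = 0.2 µm over 200 hyphae)
validate the *inversion* under the generator's assumptions: ideal
Euler–Bernoulli behavior, exactly known geometry, white Gaussian noise.
They do not probe wall-adhesion artifacts, out-of-plane growth, meandering
shapes, radius variation along the filament, or systematic force-model
error — the main real-data failure modes, which enter the analysis only
through the exclusion criteria.

## Numerical choices

* Beam quadrature: cumulative Simpson, 1201 points; boundary conditions
  imposed by subtracting end values of the cumulative integrals.
* Tip-force integral: adaptive quadrature, relative tolerance 10⁻⁸.
* cosh-ratio envelope: evaluated in exponential form to avoid overflow at
  high harmonic order; sin(nπ/2) over odd n generated as the exact
  alternating sequence ±1.
* Tilted hyphae: the load is sampled at the channel coordinate
  y₀ + y′·cos α₀ of each arc point (preserving the geometric span of the
  tip segment) and diminished by the single global factor cos α₁; no
  per-point angle refinement.
* Fit degeneracies: fewer than two usable points, an all-filtered dataset,
  or a non-positive fitted response each raise a dedicated error listing
  the exclusion reasons.
* The k_b-vs-length regression is a single OLS fit with a two-sided slope
  test; only one test is run per report, so no multiple-testing correction
  is applied.

## Limitations

* Linear (small-deflection) beam theory only; the w_max/L ≤ 0.25 filter is
  the guard, not a cure. No viscoelasticity, hysteresis, or turgor
  mechanics.
* The drag model assumes a rigid, straight, isolated cylinder in an
  undisturbed duct flow: no deformed-geometry drag update, no
  hypha–hypha interaction, no end effects beyond the single tip point
  force.
* The cell wall is a homogeneous isotropic annulus of constant
  cross-section; gradients of wall properties along the hypha are outside
  the model.
* The loading-circuit model is quasi-static with ideal plugs; no transient
  loading dynamics or spore-capture statistics.
* An external force-profile table (e.g. from CFD) can be compared against
  the analytical load (`drag_model.compare_with_cfd`), but no CFD is
  performed.
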