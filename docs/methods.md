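# Methods

This note records the models behind `wheezekit`, their assumptions, the
parameters that matter, and the choices made where the design was open.

## Dimensionless tube law

The static law `p_c = f_t(A_c)` is represented in the dimensionless groups
`Π_A = (A_c/πa²)(l/l0)^α` and
`Π_p = (p_c/(E/(1−ν²)))(l/l0)^β(h/a)^γ(l0/a)^δ`.  The pressure scale is the
plane-strain modulus `E/(1−ν²)` because thin-shell deformation energy
depends on `E` and `ν` only through that combination.  The stretch factor
next to the area group accounts for the area lost to axial straining at
zero transmural pressure (volume conservation of an incompressible wall).
Default exponents are α = 1.0, β = −2.0, γ = −1.0, δ = 1.0 and the contact
constants are Π_A* = 0.27, Π_p* = −0.12; all are configurable.

**Master curve.**  Only the anchors are constrained: the open tube at
(0, 1) and wall contact at (−0.12, 0.27), with a plateau below contact.
The shape between them is a modelling choice: a monotone cubic (PCHIP)
through three interior knots, stiff near the open state and compliant
through partial collapse, which is the characteristic shape of collapsible
tube laws.  Users can substitute their own knots; everything downstream
(equilibria, sweeps, generators) takes the curve as an argument.  The
dimensional evaluation inverts the interpolant by bracketed root-finding,
so nondimensionalize/dimensionalize and forward/inverse pairs are exact to
machine precision; the slope `∂f_t/∂A_c` is the analytic derivative of the
interpolant through the chain rule.

**Exponent fit.**  The optimizer recovers exponents by making the pooled
dimensionless cloud collapse onto a single monotone curve.  The objective
fits an isotonic (monotone non-decreasing) reference to the pooled
(Π_p, Π_A) samples and takes the mean squared vertical deviation divided by
the pooled Π_A variance; the normalization removes the trivial shrinkage of
raw residuals when an extreme area exponent compresses the cloud.  Search
is an exhaustive coarse grid (step 1.0 over the requested bounds) followed
by refinement at the requested resolution (default 0.25) around the coarse
optimum, with ties broken toward the smallest L1 exponent norm.  A dataset
identifies the exponents only if each of l/l0, h/a and l0/a takes at least
two distinct values; violations raise an error naming the constant ratio.
Contact constants are estimated as the mean dimensionless coordinates of
each curve's most-collapsed sample.

## Fluid law

Stations: stagnant room (gauge 0) → clean tube of area `A1` → throat `A_c`
→ clean tube `A2` (= `A1` by default) → plenum at `p_d < 0`.  Assumptions:
quasi-steady incompressible flow (density 1.2 kg/m³), lossless inlet leg
(rig tubing friction is negligible at these lengths), and a jet-dump exit —
the plenum is effectively infinite, so the jet's static pressure equals
`p_d` and its dynamic head is lost.  Losses concentrate downstream of the
throat once the flow separates: a Borda–Carnot sudden-expansion term
`σ(A_c/A2) · K · ½ρv_c² (1 − A_c/A2)²`, with the separation fraction σ a
smoothstep rising from 0 at area ratio `r_on = 0.8` to 1 at `r_full = 0.5`
and `K = 1.0` by default.  These three loss parameters are the closure of
the model; they reproduce the qualitative features the measured law must
have (Bernoulli near open, flowrate drop under constriction, a single
interior minimum of `p_c(A_c)`, and `p_c → p_d` as the throat closes) with
the simplest standard loss element.  The flowrate solves the
stagnation-to-plenum energy budget by Brent's method on `[0, Q_lossless]` —
losses can only reduce flow, so the bracket is guaranteed; the tests verify
the solver against a 10⁵-point brute-force scan of the same budget.

## Equilibrium and static stability

Equilibria are roots of `f_t(A) − f_f(A, p_d)` on the physical bracket from
just above the contact area to the open-tube area, located by a 200-point
sign-change scan and polished by Brent to machine tolerance.  If the
fluid-law minimum produces several intersections, all are returned and the
largest-area root is flagged as the quasi-steady branch (the state a slow
suction ramp tracks from the open tube).  Static instability is the strict
inequality `slope_f > slope_t`; the equal-slope boundary is classified
stable.  Suction sweeps record per-point failures without aborting and warn
when the tracked area jumps by more than 25 % between neighbouring grid
points (a branch-jump signature).

## Shell dynamics

The wall is a thin elastic cylindrical shell with harmonic displacements in
axial wavenumber `k` and azimuthal mode `m`.  The operator is
Donnell–Mushtari with the Morley–Koiter bending correction — the bending
term uses `(λ² + m² − 1)²` with `λ = ka` — chosen because it restores the
classical inextensional ring frequencies at `k = 0`, where the plain
Donnell operator overpredicts the m = 2 ring mode by about a third in
frequency.  Axial pre-tension enters as a geometric stiffness `n_x λ²` on
the radial equation, with `n_x = N_x/((E/(1−ν²))h)` equal to the axial
strain when the pre-stress is derived from the mounted stretch.  The
eigenproblem is a symmetric 3×3 matrix; ν = 0.5 poses no singularity.
Group velocity is computed analytically by first-order eigenvalue
perturbation (Hellmann–Feynman), with finite differences retained as the
test oracle; branch continuity along a k grid is tracked by eigenvector
overlap.  Standing waves use the pinned-end half-wavelength `k = π/l`.
Whether the upstream wave is the m = 2 flattening mode or an axisymmetric
one is genuinely open; `m` is therefore an explicit argument (default 2)
and the acceptance script reports the group velocity for both settings.

## Onset criteria, prediction, detection

The two onset conditions are bands: pressure proximity `p_c/p_c*` in
[0.8, 1.0] ("just before total collapse") and dynamic ratio
`½ρv_c²/|p_c*|` in [0.2, 5] ("comparable to the collapse pressure"), with
`v_c` evaluated at the contact area.  The band edges are not measured
constants; they are qualitative calibrations, exposed in
`OnsetThresholds` and reported with every assessment.  The cycle count `n`
in the Strouhal relation is a required input (default 1): no rule selects
it automatically.  Detection computes spectrograms (Hann window, 4096
samples, 75 % overlap) of `p_1`, `p_2`, `p_a`; a frame is tonal when its
peak exceeds the frame's median level by 20 dB; consecutive tonal frames
within ±10 % frequency drift form a track; the earliest track lasting at
least 100 cycles is the onset.  Peak frequencies are refined by parabolic
interpolation of log power, giving sub-bin accuracy well inside the ±2 %
tolerance used in the round-trip tests.  Dominance is a ratio, so
detection is invariant to overall amplitude scaling.

## Airway-tree maps

The packaged table (`data/airway_generations_synthetic.csv`) is a
*synthetic* symmetric dichotomy: per-generation diameters follow classical
morphometric values, branch lengths are kept within about four diameters
(typical of upper airways), and — lacking airway-by-airway measurements —
wall thickness is `h = 0.1 a` and axial stretch `l/l0 = 1.25` uniformly
(airways are in tension, most stretched at the start of exhale).  Tissue is
incompressible with `E = 1 MPa`.  The cumulative-area velocity model
assumes uncollapsed airways and conserves volumetric flux exactly.  The
driving pressure for the collapse map is an upper bound (20 cmH₂O for
normal breathing; forced expiration reaches 39–100 cmH₂O), since real
pressure drops distribute along the tree.  With these defaults the model
reproduces the expected physiology: no generation is collapsible at
20 cmH₂O, several are at the top of the forced range, and fully open
dynamic ratios sit below the onset band until a collapse-level area
reduction (one tenth) lifts them a hundredfold into it.

## Synthetic data

The tube-law generator samples the master curve per geometry from the open
state to wall contact and applies multiplicative log-normal area noise
(areas are the repeat-measured quantity; pressures are taken as exact).
Each tube is sampled at its own slightly staggered pressure stations, as on
a real rig where stations are set per tube; identical grids across tubes
would make pooled collapse misfits blind to the pressure exponents.  The
default campaign is 27 geometries (3×3×3 over stretch 1.05–1.3, wall ratio
0.07–0.2, slenderness 4–8, radius 3 mm) with 15 samples per curve.

The run generator marches the suction schedule (ramp up / hold / ramp
down; default peak −2000 Pa, the deepest level with a quasi-steady
equilibrium margin for the example tube) through precomputed equilibrium
tracks, then synthesizes channels at 51 200 Hz: `p_2` mirrors the plenum,
`p_1` follows the upstream Bernoulli pressure, and after onset `p_1` and
`Q` plateau (with a 10 % flowrate drop) until the ramp-down releases the
tube.  The tone (default 25 Pa against 1 Pa RMS Gaussian broadband) starts
when the onset criteria first fire — or at a prescribed time/frequency —
with a raised-cosine ramp over 10 cycles.  What the generator does *not*
emulate: real wheeze timbre (harmonics, amplitude modulation), flow
turbulence spectra, transducer dynamics, or intermittent onset; passing
closed-loop tests therefore demonstrates the pipeline's internal
consistency and the detector's behaviour on clean tonal onsets, not
performance on clinical recordings.

## Numerical choices and problem sizes

Root-finding tolerances are machine-level (Brent relative tolerance
~9e-16); equilibrium residuals are below 1e-8 Pa.  The exponent search
evaluates ~9000 objective points (coarse 7⁴ grid plus 9⁴ refinement),
about 8 s for 27 curves.  Test and acceptance problem sizes — 27- and
20-curve campaigns, 50-point sweeps, 10 s runs at 51 200 Hz — are chosen so
the full pipeline re-runs from scratch in about a minute while keeping
every estimate comfortably inside its tolerance.

## Known limitations

- The loss closure and master-curve interior are stand-ins calibrated to
  qualitative behaviour, not fitted to measured fluid laws; both are
  replaceable through the public interfaces.
- The flutter model is phenomenological: it predicts the frequency given
  the operating point but contains no eigenvalue analysis of the coupled
  fluid–shell system, and the onset bands are qualitative.
- The airway table is representative, not subject-specific; per-generation
  strain and wall thickness are single defaults.
- Absolute onset frequencies of particular bench runs depend on the
  measured flowrate at onset, which is an input, not a model output.
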