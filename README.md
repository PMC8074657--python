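# wheezekit

Quantitative modelling of **wheeze onset in collapsible tubes**, for
respiratory biomechanics and physiological fluid–structure interaction work.

Wheezes are tonal lung sounds produced when airways — short, thin-walled
elastic tubes held in axial tension — self-excite as air flows through them.
The bench analogue is a modified Starling resistor: a stretched rubber tube
clamped between rigid tubes, with suction applied downstream.  `wheezekit`
packages the quantitative model of that system:

- **Tube law** `p_c = f_t(A_c)`: the static relation between transmural
  pressure and minimum cross-sectional area.  For tubes of geometry
  (`l`, `l0`, `a`, `h`) and material (`E`, `ν`), measurements collapse onto
  a single master curve in the dimensionless groups

  ```
  Π_A = (A_c / πa²) (l/l0)^α
  Π_p = (p_c / (E/(1−ν²))) (l/l0)^β (h/a)^γ (l0/a)^δ
  ```

  with fitted exponents α = 1.0, β = −2.0, γ = −1.0, δ = 1.0.  The walls
  touch (total collapse) at Π_A* = 0.27 and Π_p* = −0.12, which predicts the
  collapse area `A_c*` and pressure `p_c*` of an arbitrary tube — including
  an airway — from its geometry and material alone.
- **Fluid law** `p_c = f_f(A_c, p_d)`: quasi-1D Bernoulli flow with a
  Borda–Carnot separation-loss closure, giving the choke-point pressure and
  flowrate for a fixed plenum suction `p_d`.
- **Equilibrium & static stability**: intersections of the two laws, and the
  criterion `∂f_f/∂A_c > ∂f_t/∂A_c` for static instability (none occurs on
  the packaged laws: onset must be dynamic).
- **Onset criteria and flutter frequency**: oscillation requires the tube
  near total collapse (`p_c/p_c*` close to 1) *and* throat dynamic pressure
  `½ρv_c²` comparable to `|p_c*|`.  The frequency follows from two coupled
  longitudinal waves — a convected flow structure travelling down at
  `v = Q/πa²` and an elastic shell wave travelling up at the group velocity
  `u = c_g` — via the modified Strouhal relation `1/f = n(l/v + l/u)`,
  `S = f(l/v + l/u) = 1/n` for n = 1, 2.
- **Shell dynamics**: thin cylindrical shell dispersion under axial
  pre-tension (Donnell–Mushtari operator with Morley–Koiter bending
  correction), giving `c_g` and linear modal frequencies.
- **Onset detection**: the measurement-side rule — the first dominant
  spectrogram tone sustained for at least 100 cycles — applied to
  multichannel pressure recordings (51 200 Hz).
- **Airway-tree maps**: the onset criteria applied generation by generation
  to a per-generation airway model, with `v(x) = A_i v_i / A(x)`, showing
  why normal breathing cannot wheeze and forced expiration can.
- **Synthetic data**: seeded generators for tube-law measurement campaigns
  (with known ground truth) and virtual suction-ramp runs, so every
  pipeline stage can be tested closed-loop.

## Worked example

The bench tube `l = 23 mm, l0 = 20.4 mm, a = 3 mm, h = 0.35 mm` in rubber
(`E = 1 MPa, ν = 0.5, ρ_s = 1000 kg/m³`), with air (`ρ = 1.2 kg/m³`):

```python
import wheezekit as wk

geom, mat = wk.EXAMPLE_TUBE, wk.EXAMPLE_MATERIAL
rig = wk.RigConfig.for_tube(geom)

cs = wk.collapse_state(geom, mat)
# A_c* = 6.77e-06 m^2   p_c* = -3489.4 Pa (-35.6 cmH2O)

eq = wk.find_equilibrium(geom, mat, rig, p_d=-1800.0)[0]
# A_c0 = 8.19e-06 m^2   p_c0 = -3058.2 Pa   Q = 5.84e-4 m^3/s

oc = wk.onset_criteria(geom, mat, rig, eq.p_c0, eq.Q)
# proximity = 0.876, dynamic ratio = 1.28  ->  onset = True

pred = wk.predict_frequency(geom, mat, Q=eq.Q, n=1, m=2)
# v = 20.67 m/s, u = 10.51 m/s, f = 302.8 Hz, S = 1.0
```

At −1800 Pa suction the tube sits at 88 % of its collapse pressure with an
in-band dynamic ratio, so both onset conditions hold; the coupled-wave model
then predicts a tone near 300 Hz for this operating point.  The same
machinery runs in reverse on recordings: a synthetic run carrying a 164 Hz
tone from t = 3 s is detected at `t = 2.96 s, f = 164.1 Hz` (663 sustained
cycles).

A thin CLI mirrors the library:

```bash
wheezekit collapse --l 23 --l0 20.4 --a 3 --h 0.35
wheezekit onset-predict --l 23 --l0 20.4 --a 3 --h 0.35 --q 8e-4
wheezekit lung-map --p-drive 20 --q-mouth 6.5
```

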