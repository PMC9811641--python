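# Methods

`cavibridge` models and measures what happens when a fast microfluidic jet
(diameter 50–120 µm, speed 8–69.5 m/s) strikes a millimetre-scale capillary
bridge — a droplet or gel volume held by surface tension between two
parallel walls 1 mm apart.  The impact opens an air cavity; the cavity
expands, collapses, and may trap bubbles.  The package covers the forward
models (cavity expansion, traversal threshold, front speed), the regime
logic (seal type, bubble expectations), the wall energetics (Laplace
pressure, adhesion, contact-line dissipation), and the shadowgraph
metrology that extracts all of these from high-speed image stacks, plus a
seeded synthetic-data generator that closes the loop.

## Cavity expansion models

**Crater law (inertial limit).**  At Weber and Reynolds numbers far above
unity, each axial slice of the cavity is opened impulsively as the front
passes and then coasts, giving

    R(x, t)^2 = a (t − t0(x)),   a = β D0 U0,   t0(x) = x / Uc,

a parabola with apex at the front `Hc = Uc t`.  The coefficient `a` follows
from partitioning the jet's kinetic-energy flux over the slices opened per
unit time; `β` (default 1) absorbs the O(1) uncertainty of that partition.
The opening time `x/Uc` is the only dimensionally consistent choice and is
the one implemented; a literal `x/Hc` variant is refused rather than
silently accepted.

**Per-slice radial momentum balance.**  The cylindrical-slice analogue of
the Rayleigh equation,

    ρ d/dt(R Ṙ) = p(t) − γ/R − 4 µ Ṙ / R,

is integrated with `scipy.solve_ivp` (LSODA, rtol 1e−8, atol 1e−12, a
terminal event at collapse).  Under an impulsive drive and zero γ, µ its
late-time solution is exactly the square-root coasting law above; the test
suite uses this as an oracle (fitted exponent 0.50 ± 0.02).

**Droplet-train superposition (viscous targets).**  The jet is replaced by
a train of droplets of equal volumetric flux: volume equivalence fixes
`r_d = r_cyl √(3/2f)` and `h_cyl = 2 r_d / f`; the duty-cycle momentum
argument gives the train's cavity speed `Uc = f U_d`, so matching the jet
requires `U_d = U0 / 2f` (defaults use `f = 1/2`, the continuous-jet
limit).  Each drop feeds one slice for `4 r_d / U_d` — its length consumed
at the relative speed `U_d/2` — as a direct momentum injection, then the
slice coasts against viscous (and optionally capillary) stresses through
the balance above.  The feed is treated as inviscid and non-capillary
because the drop's dynamic pressure exceeds both the capillary pressure
(above a sub-micron radius) and the boundary-layer shear stress during
contact; modelling the feed as a pressure acting against `γ/R` from a
micro-seed instead produces an unphysical exponential bottleneck at low
Reynolds number.  The drive coefficient `C_p(f) = β f √(2f/3) / (2 ρ_r)` is
derived, not fitted: it is the unique value for which the dissipation-free
train reproduces the jet crater law.  Successive drops are time-shifted by
the train period, own consecutive axial bands of width `2 r_d`, and are
combined by pointwise maximum — a rule chosen because it preserves
non-negativity and monotone growth.  For a water-like target the composite
agrees with the crater parabola within 10% away from the front; for viscous
targets it is narrower, as observed.

**Cavity front speed.**  `Uc = U0 · √ρ_r/(1+√ρ_r) · 1/(1 + C_v µ_cb/(ρ0 U0 D0))`
with `ρ_r = ρ0/ρ_cb`.  The first factor is the impedance-matching
penetration speed (1/2 for matched densities); the second discounts viscous
dissipation of scale `µ U0²/D0²` against the jet's dynamic pressure.
`C_v = 20` (order ten) is the one genuinely adjustable constant of the
model; with it the predicted `Uc/U0` is ≈0.49 for water and ≈0.13 for the
stiffest gel, i.e. all bundled materials fall below the inviscid 0.5, in
line with the wall-confined measurements the model is meant to describe.

## Traversal

Surface tension terminates the cavity: each slice carries radial momentum
`a/2` per unit density, which the capillary pressure at the jet-scale
curvature `2γ/D0` cancels after

    t_c = β ρ_cb U0 D0² / (4 γ_cb),    H_max = (U0/2) t_c.

For the water cases of interest this gives `t_c` of a few hundred
microseconds, consistent with the millisecond recording window.  Setting
`H_max = D_cb` and eliminating `U0` for the Weber number yields

    We* = 8 (ρ0/ρ_cb) D_cb / (β D0),

a single-group form in `D_cb/D0` (≈520 for a 6 mm bridge and a 93 µm jet).
An alternative closure — self-consistent capillary collapse of the entry
radius — was derived and rejected during development: it scales as
`We* ∝ √(D_cb/D0)` but predicts second-scale collapse times, three orders
too slow.  The decision boundary is `We/We* ≥ 0.7` (closed at the
boundary), the value measured for unconfined pendant droplets; wall
confinement raises the true threshold, so classification of viscoelastic
and stiff-gel targets attaches explicit caveats (≈50% misfit for PEO
solutions, ≈30% for the 536 Pa gel, an order of magnitude for the 3961 Pa
gel, attributed to the property relations extrapolating badly above
~500 Pa).

## Dimensionless groups

`We = ρ0 D0 U0²/γ_cb` uses the jet's inertia against the *target's*
surface tension.  `Oh = µ/√(ργL)` takes an explicit length scale: the jet
diameter for impact-scale arguments, the bridge diameter for the
seal-regime map — only the bridge-scale choice puts water below the
reported surface-seal bound (0.0015 < 0.004) and makes the 78 wt% glycerol
and 1.0 wt% PEO 1M solutions neighbours on the regime map, as observed.
`De = λ/τ_c` uses the inertio-capillary time `τ_c = √(ρ D³/γ)` by default;
the dimensionally inconsistent literal `ρD/γ` sometimes quoted is available
behind `convention="printed"` for comparison only.

## Seal regimes and bubbles

Observational classification is definitional and total: surface seal if a
dome closes over the mouth while the cavity still grows; else deep seal if
any pinch-off sits deeper than `L_max/3`; else shallow seal if there is any
pinch; else no seal.  The shallow/deep split at `L_max/3` operationalises
"close to the entry point" as the exact complement of the deep-seal rule so
the partition is exhaustive and exclusive.  Predictive rules mirror the
experimental map with class precedence gel → viscoelastic → Newtonian:
gels always shallow-seal; PEO solutions deep-seal inside closed
per-material Weber windows ([500,600], [400,700], [500,900] for 600k
0.1 wt%, 600k 1.0 wt%, 1M 1.0 wt%; union fallback for unnamed viscoelastic
liquids); Newtonian liquids surface-seal for `Oh ≤ 0.004` and `We ≤ 700`.
The `We ≤ 700` bound is implemented as the upper bound it was reported as,
although surface seal classically appears at high We — a flagged oddity
inherited from the source data.  Expected bubble outcomes per regime:
nothing for no seal; several bubbles at area ratio ≤ 0.6 for deep seal;
several small bubbles near ratio 0.5 for shallow seal; one large bubble
near ratio 1 for surface seal.

## Wall energetics

`ΔP = −2 γ cosθ_E / H` (axial curvature only) is the default Laplace
pressure: it is the form that reproduces both worked adhesion forces
(+3.05 mN on glass at θ_E = 23°, R_c = 2.5 mm; −1.24 mN on a hydrophobic
coating at θ_E = 160°, R_c = 1.9 mm) through
`F_a = 2π γ R_c sinθ_E − π R_c² ΔP`; the variant with the in-plane term
`+γ/R_c` gives 2.48/−1.67 mN and is exposed as an option only.  The
contact-line hysteresis term `Φ_cl = 2π R_c γ |cosθ_a − cosθ_r|` is a
force; converting it to an energy requires a contact-line travel distance
that the wetting parameters alone do not determine, so that length is an
explicit input (`dissipation_energy(Φ, travel)`), defaulting to `2 R_c` in
the wall-assessment report.  An 18° hysteresis is split symmetrically about
θ_E unless both dynamic angles are supplied.  A Worthington jet is deemed
favourable only if the dissipation energy stays below half the jet kinetic
energy `(π/8) ρ0 U0² D0² L0` *and* the walls do not attract the bridge
(`F_a ≤ 0`); mixed hydrophilic–hydrophobic wall pairs are categorically
unfavourable (asymmetric collapse), encoded as a rule rather than
simulated.

## Shadowgraph metrology

Frames are dark-liquid/bright-air backlit images.  The analysis region is
the bridge disk, constructed analytically from the calibrated geometry
(bridge diameter, pixel scale, impact-point origin) whenever available;
the image-derived fallback (opening with an 8 px disk to delete the jet
column, largest component, convex hull eroded by 2 px) exists for
uncalibrated stacks but over-covers when the bridge is clipped by the
frame.  Two cavity masks are kept per frame: the mouth-connected *open*
cavity (profile, closure detection) and the *total* bright-inside-bridge
cavity (area, front, pinch detection by axial gaps between connected
components).  Kinematics are restricted to the contiguous cavity episode —
from first detection to the first frame where the cavity has vanished — so
bright features appearing later (settled bubbles) never contaminate
`A_max` or the front fit.  The front-speed fit uses the frames before the
area maximum in which the front is still advancing, dropping the stalled
tail at the confinement cap; area maxima tie-break to the latest frame.
Bubble metrology fills holes in the post-collapse dark mask (`A_total`
includes bubble interiors), merges holes with gaps below the 100 µm
optical floor by morphological closing with a 5 px disk, assigns each
cluster its combined hole area, and counts a cluster only if its bounding
extent reaches the floor — the extent rule, rather than a combined-area
rule, is what keeps a cluster of two 60 µm bubbles 30 µm apart countable
while an isolated 60 µm bubble is not.

## Synthetic-data generator

The generator draws the study conditions: material uniformly from the
bundled nine-material table, `U0 ~ U[8, 69.5]` m/s, `D0 ~ U[50, 120]` µm,
a 6 mm bridge between walls 1 mm apart, rendered at 768 × 328 px, 10 µm/px,
50k frames/s, 250 frames (5 ms).  For gels the impact speed is redrawn
until `ρU0²/G ≥ 100`, reflecting the critical inertia a gel needs to admit
a cavity at all.  Truth kinematics come from the package's own models:
front speed from the cavity-velocity model; depth `L_max` as the predicted
`H_max` clamped between a 0.3 mm renderable floor (and at least 4.5 front
displacements per frame interval, so the fit has sub-plateau frames) and
0.45 `D_cb` (confinement); radii from the crater law for bridge-scale
`Oh < 0.01` and from the droplet-train model otherwise, run
dissipative-only because the capillary retraction is prescribed separately:
the cavity shrinks radially at a constant area rate after the growth phase,
which makes the collapse time linear in the peak area by construction, with
the rate set by the capillary velocity `√(γ/ρD_cb)` and floored at six
frame intervals so collapse is always resolved.  Seal events are rendered
literally: a 5 px dark gap at the planned pinch position (deep at
0.45–0.75 `L_max`, shallow at ≤ 0.30 `L_max` but at least 9 px off the
mouth), or a dark band sealing the mouth at 50–70% of the growth phase for
surface seal.  Post-collapse frames appear after a 3-frame settling gap and
show the injected-liquid blob (a darker gray than the bridge, separable by
a second threshold) with bright bubble disks: counts and local hole/area
ratios are drawn from the regime's expected band, disks are spaced to
avoid unintended cluster merging, and every outer disk is kept fully
inside the bridge so annuli are never broken by the boundary.

All truth labels that the pipeline is asked to recover (front positions,
areas, bubble census) are reported from the generator's *rendered* clean
geometry — pixel-quantised, exactly what a perfect segmentation would see —
so closed-loop tests measure metrology error, not model error.  Optional
Gaussian pixel noise (σ in gray levels, clipped to [0, 255]) is seeded
separately from the experiment draw.

What the generator does not emulate: surface waves on the cavity, jet
break-up and the enlarged jet head (both noted experimentally to roughen
real profiles), refraction and illumination gradients, antibubbles as
distinct objects, Worthington-jet droplets, or out-of-plane geometry.
Passing closed-loop tests therefore demonstrates that the metrology
recovers known kinematics and bubble censuses from noisy idealised
shadowgraphs; it does not validate the physical models against real
videos.

## Numerical and degenerate-input choices

ODE tolerances rtol 1e−8 / atol 1e−12 with a terminal collapse event; drop
cavities initialise at `10⁻³ r_d`; profiles sample 512 axial points by
default.  Binarization is strict-`<` for fixed thresholds (making the
complement test exact in uint8) and inclusive-`≤` for Otsu (so an exact
two-level image keeps its dark phase).  Cavity components below 8 px are
treated as noise.  Uniform frames binarize to an empty mask; pre-impact
frames yield empty profiles, not errors; a never-closing stack sets an
open-ended flag instead of a collapse time.  Zero-velocity jets give zero
We, Fr, shear rate, front speed and kinetic energy throughout.

## Known limitations

The figure-level equations of the source experiments were not available in
the text this package was built against; every model here is a standard
form chosen to satisfy the documented qualitative and quantitative
behaviour (growth exponents, monotonicities, sign laws, worked values,
magnitudes), with the O(1) prefactors `β`, `C_v` and the collapse
coefficient exposed as parameters.  Absolute `We*` values therefore carry
O(1) prefactor uncertainty even where the scaling is right.  The traversal
model knowingly misfits viscoelastic and stiff-gel targets (caveats are
attached to predictions).  The imaging module assumes an axis-aligned jet
and a circular bridge; it does not correct lens distortion or background
flicker, and does not track Worthington-jet droplets.
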