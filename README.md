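# cavibridge

Cavity dynamics of microfluidic-jet impact on confined capillary bridges.

When a fast microjet (D₀ = 50–120 µm, U₀ = 8–69.5 m/s — the regime of
needle-free drug injection) strikes a millimetre-scale droplet or gel held
between two walls by surface tension, it opens an air cavity.  Whether the
jet traverses the bridge or embeds, how the cavity collapses, and how many
air bubbles it traps all decide whether an injection delivers liquid or
air.  `cavibridge` is a tested pipeline for this problem, for experimenters
analysing high-speed shadowgraphs of such impacts and for modellers
exploring the parameter space: material property relations and
dimensionless groups, cavity-expansion forward models, a traverse/embed
classifier, seal-regime logic, wall-wettability energetics, shadowgraph
metrology, and a seeded synthetic-data generator that closes the loop.

## The models in brief

* **Crater growth:** each axial slice of the cavity opens impulsively and
  coasts, `R(x,t)² = a (t − x/U_c)` with `a = β D₀ U₀` — a parabolic
  cavity with front `H_c = U_c t`.  A per-slice 2D Rayleigh-type balance
  `ρ d(RṘ)/dt = p − γ/R − 4µṘ/R` provides the viscous generalisation,
  driven drop-by-drop by an equivalent droplet train of matched volumetric
  flux (`r_d = r_cyl √(3/2f)`, `U_c = f U_d`).
* **Traversal:** capillarity kills the cavity after
  `t_c = β ρ_cb U₀ D₀²/(4γ_cb)`; the jet traverses when
  `H_max = (U₀/2) t_c` exceeds the bridge diameter, i.e. above
  `We* = 8 (ρ₀/ρ_cb) D_cb/(β D₀)`, with the measured boundary at
  `We/We* ≥ 0.7`.
* **Front speed:** `U_c/U₀ = √ρ_r/(1+√ρ_r) · 1/(1 + C_v µ_cb/(ρ₀U₀D₀))` —
  ½ in the inviscid density-matched limit, reduced by target viscosity.
* **Seal regimes:** no seal / shallow seal (pinch ≤ L_max/3) / deep seal
  (pinch > L_max/3) / surface seal (dome closes while still expanding),
  observed from kinematics or predicted from (We, Oh, material class).
* **Wettability:** `ΔP = −2γ cosθ_E/H`,
  `F_a = 2πγR_c sinθ_E − πR_c²ΔP`,
  `Φ_cl = 2πR_cγ(cosθ_a − cosθ_r)`, and a Worthington-jet favourability
  rule comparing contact-line dissipation with the jet energy
  `(π/8)ρ₀U₀²D₀²L₀`.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

A water bridge (6 mm diameter, from the bundled property table) hit by a
93 µm jet at 19.6 m/s:

```python
from cavibridge.materials import JetSpec, BridgeGeometry, load_materials, ohnesorge
from cavibridge import traversal, cavity_models, seal_classifier

water = load_materials()["water"]
jet = JetSpec(rho_0=1000.0, D_0=93e-6, U_0=19.6)
geom = BridgeGeometry()          # D_cb = 6 mm, walls 1 mm apart

a = traversal.assess(jet, water, geom)
uc = cavity_models.cavity_velocity_model(jet, water)
oh = ohnesorge(water, geom.D_cb)
pred = seal_classifier.predict_seal(a.We, oh, water.material_class, "water")
```

prints (via the obvious f-strings):

```
We        = 495.5
Oh (D_cb) = 0.0015
t_c       = 0.587 ms
H_max     = 5.75 mm
We*       = 517.2
We/We*    = 0.96  ->  traverse
U_c       = 9.70 m/s  (U_c/U_0 = 0.495)
predicted seal regime: surface_seal
```

Reading: this jet sits just below the critical Weber number for a 6 mm
bridge (We/We* = 0.96) but above the 0.7 decision boundary, so it is
classified as traversing; the cavity front advances at just under half the
impact speed; and a low-viscosity bridge at this Weber number is a
surface-seal candidate — the collapse mode that traps the most air.

The same pipeline runs end-to-end on synthetic shadowgraphs from a shell:

```bash
cavibridge report --seed 1 --out report.csv      # simulate + measure + classify
cavibridge simulate --seed 1 --n 3 --out stacks/ # rendered TIFF stacks + truth
cavibridge analyze stacks/exp_* --out out.csv    # metrology on stacks
cavibridge regime-map --out map.csv              # (We, Oh) -> regime table
```

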