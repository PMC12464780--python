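# memcurve

Analysis tools for how the ceramide/sphingomyelin (CER/SM) ratio shapes
the mechanics of lipid membranes — the lipid system behind
matrix-vesicle budding in bone mineralization. `memcurve` covers the
three quantitative layers of such a study:

1. **Langmuir monolayer thermodynamics** from π–A trough isotherms:
   the excess molecular area
   *A*_exc(π) = *A*_mix − (*A*_CER·*X*_CER + *A*_SM·*X*_SM),
   the excess Gibbs energy
   ΔG_exc(π₀) = *N*_A ∫₀^π₀ *A*_exc dπ′,
   the compressibility modulus *C*_s⁻¹ = −*A*_π (dπ/dA)_T with
   monolayer phase-state classification, and isotherm similarity
   metrics. Negative *A*_exc and ΔG_exc signal attractive, non-ideal
   CER–SM mixing.
2. **Elastic constants from lateral pressure profiles.** From
   stress-tensor profiles P(z) along the membrane normal,
   LPP(z) = [P_xx(z)+P_yy(z)]/2 − P_zz(z); the spontaneous bending
   moment is the first moment *K*_C·*c*₀ = ∫ z·LPP(z) dz over the
   membrane slab [d₋, d₊], and the Gaussian (saddle-splay) modulus is
   the negative second moment K̄_G = −∫ z²·LPP(z) dz, with unit
   conversions to pN and k_B·T and the curvature radius R = 1/|*c*₀|.
   Leaflet-asymmetric stress makes both quantities grow — the membrane
   wants to bud.
3. **Surface-curvature descriptors of simulated bilayers.** A periodic
   Gaussian-kernel height field is fitted to one reference point per
   lipid; from its normals come the curvature order parameter
   *S*_C = ⟨P₂(cos θ)⟩ (1 for a planar bilayer, smaller with
   curvature), the area per lipid *A*_L (projected or
   surface-corrected), and the head-to-head thickness *D*_HH.

A synthetic-data module generates isotherm families, Gaussian-bump
stress profiles and analytic membrane surfaces with closed-form ground
truth, so every stage is testable without trough hardware or MD
trajectories — and writes them through the same file formats the
analysis readers consume (CSV isotherms, xvg-dialect stress tables,
coordinate tables or GRO files).

## Worked example

```python
import numpy as np
import memcurve as mc

# 1) monolayer mixing thermodynamics for an equimolar CER/SM film
cer = mc.IsothermModel("linear", (90.6, -1.6), (30.0, 52.0))
sm = mc.IsothermModel("linear", (73.6, -0.9), (30.0, 75.0))
family = mc.gen_mixture_family(
    cer, sm, mc.MixtureScenario(mole_fraction_first=0.5,
                                excess_area_coeffs=(-7.5,)))
curve = mc.excess_area(family.mixture, family.pure_first,
                       family.pure_second, family.spec,
                       grid=np.linspace(10.0, 40.0, 201))
i = 100  # grid node at 25 mN/m
print(f"A_ideal(25 mN/m) = {curve.a_ideal[i]:.1f} A^2")
print(f"A_mix(25 mN/m)   = {curve.a_mix[i]:.1f} A^2")
print(f"A_exc(25 mN/m)   = {curve.a_exc[i]:.1f} A^2")
print(f"dG_exc(25 mN/m)  = {mc.excess_gibbs_energy(curve, 25.0):.0f} J/mol")

# 2) elastic constants of a leaflet-asymmetric membrane model
from memcurve.synthetic import bilayer_bumps
model = mc.StressFieldModel(bumps=bilayer_bumps(outer_gain=2.5))
stress, truth = mc.gen_stress_profile(model)
profile = mc.center_midplane(mc.compute_lpp(stress))
ec = mc.elastic_constants(profile, mc.detect_bounds(profile, full_box=True),
                          temperature=303.15)
print(f"K_C*c_0 = {ec.bending_moment_pn:.1f} pN")
print(f"K_G     = {ec.gaussian_modulus_kbt:.1f} k_B T")
print(f"R = 1/|C0| for C0 = -0.015/nm: {mc.curvature_radius(-0.015):.2f} nm")

# 3) curvature order parameter of an undulating leaflet
surf = mc.SurfaceModel("sinusoid",
                       {"height": 2.0, "amplitude": 1.0, "wavelength": 10.0},
                       n_lipids_per_leaflet=4000, seed=1)
frame, oracle = mc.gen_surface_cloud(surf)
grid = mc.fit_surface(frame, "upper", 64, 64)
print(f"S_C fitted = {mc.curvature_order_parameter(grid):.3f} "
      f"(analytic {oracle:.3f})")
```

which prints

```
A_ideal(25 mN/m) = 47.5 A^2
A_mix(25 mN/m)   = 40.0 A^2
A_exc(25 mN/m)   = -7.5 A^2
dG_exc(25 mN/m)  = -1129 J/mol
K_C*c_0 = 15.0 pN
K_G     = -29.6 k_B T
R = 1/|C0| for C0 = -0.015/nm: 66.67 nm
S_C fitted = 0.767 (analytic 0.770)
```

Reading the numbers: the pure films occupy 54 (SM) and 41 (CER) Å² per
molecule at 25 mN/m, so ideal mixing predicts 47.5 Å² for the
equimolar film; the measured-style mixture value of 40 Å² means a
−7.5 Å² excess — a strongly condensed film whose ΔG_exc of about
−1129 J/mol confirms favourable CER–SM attraction. The asymmetric
membrane (outer-leaflet stress amplified 2.5×) carries a positive
spontaneous bending moment and a negative Gaussian modulus, the
signature of a membrane primed to form curved buds; a spontaneous
curvature of 0.015 nm⁻¹ corresponds to a 66.67 nm curvature radius.
The fitted order parameter of the undulating leaflet reproduces the
analytic value to well under a percent.

## Command line

```bash
memcurve synth isotherm --seed 1 --out run/      # synthetic fixtures
memcurve isotherm --mixture run/mixture.csv \
    --pure-cer run/pure_cer.csv --pure-sm run/pure_sm.csv --out run/
memcurve lpp --stress run/stress.xvg --temperature 303.15 --out run/
memcurve surface --frames run/frame0.csv --nx 64 --ny 64 --out run/
memcurve all --seed 1 --out run/                 # full chain
```

Every subcommand writes a JSON report echoing its full configuration
and seed, so any report can be regenerated bit-identically.

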