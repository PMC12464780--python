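# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Units and constants

Monolayer quantities stay in trough units end to end: surface pressure
π in mN/m, molecular area A in Å² per molecule. Membrane-normal
quantities stay in MD units: z in nm, stress in bar. SI enters only at
fixed conversion points:

| conversion | value | where used |
|---|---|---|
| 1 Å²·mN/m per molecule | 6.02214076 J/mol | ΔG_exc |
| 1 bar·nm² | 0.1 pN | bending moment |
| 1 bar·nm³ | 10⁻²² J | Gaussian modulus |
| k_B | 1.380649×10⁻²³ J/K | k_B·T scaling |

The default temperature for thermal-energy scaling is 303.15 K, the
usual simulation temperature for these lipid systems; it is an explicit
argument wherever k_B·T units are produced, because the choice visibly
rescales the Gaussian modulus.

## Isotherm thermodynamics

**Canonical form.** Isotherms are stored sorted by strictly decreasing
area with exact duplicate areas averaged; hysteresis branches must be
split by the caller. All cross-isotherm arithmetic happens on an
explicit common pressure grid (default 200 uniform points over the
shared range) because raw trough curves never share pressure samples.
Area lookup A(π) is monotone piecewise-linear interpolation, and
requests outside the sampled range raise rather than extrapolate.

**Excess area and excess Gibbs energy.** A_exc = A_mix − A_ideal with
A_ideal the mole-fraction-weighted pure areas at equal π. ΔG_exc is a
composite-trapezoid integral of A_exc from π = 0. Trough data rarely
reach zero pressure, so the curve is extended to π = 0 by holding the
lowest-pressure value constant (default) or by linear extrapolation of
the first segment (configurable); with either rule ΔG_exc(0) = 0 and
refinement of the grid converges to the analytic integral (exactly for
linear A_exc, at O(h²) otherwise).

**Compressibility modulus.** Cs⁻¹ = −A·(dπ/dA) needs a derivative of
noisy data, estimated by a Savitzky–Golay local-polynomial filter
(default window 11 points, order 3) on the area-ordered curve; window 0
switches to plain central differences, which is exact for piecewise
behaviour such as phase plateaus. The estimator and its parameters are
recorded in the output for reproducibility. If the area grid is not
uniform (Savitzky–Golay's assumption) the code falls back to
`np.gradient` and records that instead. Phase labels follow the
classical monolayer convention — gaseous < 12.5 < liquid-expanded < 50
< transitional < 100 < liquid-condensed < 250 < solid, in mN/m — and
are fully configurable; non-finite Cs⁻¹ values are labelled
`unclassified` rather than raising.

## Lateral pressure profile and elastic constants

LPP(z) = (Pxx+Pyy)/2 − Pzz is computed pointwise with no smoothing.
Inputs are *pressure*-tensor components as MD engines report them; no
virial-sign flip is applied. Feeding mechanical stress (the negative of
pressure) negates both moments — this is the single most common sign
error in this analysis, hence the prominent convention.

**Midplane.** Both moments assume the bilayer midplane at z = 0. The
default locator takes the midpoint of the outermost zero crossings of
LPP (each crossing located by linear interpolation), falling back to
the geometric centre of the support (|LPP| above 1% of its peak) when
the profile never changes sign. Centring is a pure translation; the
shift is recorded so original coordinates are recoverable, and
re-centring is idempotent to numerical precision.

**Integration slab.** The default bounds rule takes the outermost z
where |LPP| exceeds f = 0.01 of its peak, padded by one grid step and
widened to straddle z = 0. This keeps bulk-water noise out of the
moments on real profiles, at the price of truncating Gaussian-like
tails at roughly 3σ, which moves the moments by a few tenths of a
percent. Where closed-form agreement tighter than that is needed
(oracle tests, the synthetic round trip), use explicit wide bounds, a
smaller `support_fraction`, or `full_box=True` — all part of the
public interface. Per-leaflet integration (summing [d₋,0] and [0,d₊]
moments separately) is equivalent for the first moment by additivity of
the integral and is therefore not a separate mode.

**Quadrature.** Composite trapezoid on the native grid, no spline
resampling: stress profiles are already binned averages, and
higher-order rules add no information. On smooth profiles the moments
converge at least at O(h²); for rapidly decaying integrands the
trapezoid rule is substantially better. Moments are linear in the
profile to machine precision; even profiles have zero bending moment;
reflection z → −z negates the bending moment and preserves the
Gaussian modulus.

The bending stiffness K_C and spontaneous curvature c₀ are never
resolved individually — only their product (the first moment) is
computable from the LPP — so no field for either exists. The curvature
radius helper R = 1/|c₀| accepts a user-supplied c₀ and returns
`math.inf` for a flat membrane instead of raising.

## Surface fitting and curvature descriptors

**Height-field estimator.** One reference point per lipid (the caller
picks the head atom/bead; the module never parses chemistry) is fitted
by Nadaraya–Watson regression with a Gaussian kernel in wrapped (x, y)
distance on a node-centred nx×ny grid over the half-open periodic box.
The default bandwidth is 1.5× the mean nearest-neighbour spacing; a
bandwidth below that spacing is allowed but recorded as a warning, and
nodes whose kernel mass underflows to zero fall back to the nearest
point's height. The estimator is deterministic, periodic-safe and
convergence-testable; its one systematic effect is low-pass
attenuation of undulations by about exp(−k²·bw²/2) at wavenumber k,
which for the default bandwidth biases S_C upward by a few tenths of a
percent on the test fixtures.

**Normals and S_C.** Node normals come from periodic central
differences of the height field, oriented to non-negative z so leaflet
orientation never flips signs; θ = arccos(n_z) ∈ [0, π/2]. The
curvature order parameter is the mean of P₂(cos θ) = (3cos²θ−1)/2 over
grid nodes, i.e. weighted by the (equal) projected area of each grid
element. The projected-weighting convention was a genuine design
choice: it matches the uniform in-plane sampling of the generators'
analytic oracles (a 1-D quadrature of P₂((1+h′²)^(−1/2)) for a
sinusoid carries no arc-length weight) and keeps generator and
analyzer self-consistent. Surface-area weighting would emphasise steep
regions more; with the projected convention a localized bud can score
*above* an extended undulation of equal RMS height, so comparisons
between surface families should fix the geometry class.

**A_L and D_HH.** Projected area per lipid is Lx·Ly/N; surface mode
divides the triangulated area of the periodic height field (two
triangles per cell) by N and always meets or exceeds the projected
value. Thickness is the grid mean of (h_upper − h_lower); nodes where
the fitted leaflets cross are counted and reported, not dropped.
Trajectory summaries report per-frame S_C/A_L/D_HH plus mean, median
and interquartile range over a configurable frame window (the
statistics usually drawn as violin plots).

## Synthetic data: what it emulates, what it does not

The generators provide *ground-truth-bearing* stand-ins, not realistic
physics:

* **Isotherms** are declared analytic forms — linear, hyperbolic
  (πA = const), or piecewise-linear with a low-slope plateau segment
  emulating a phase transition — sampled on a uniform area grid with
  optional additive Gaussian π-noise, clipped at zero. The default
  pure-component models are calibrated so pure CER reaches 41 Å² and
  pure SM 54 Å² at 25 mN/m with CER the stiffer film, the scales a
  C18 CER/SM trough experiment produces. Mixture families are built so
  the mixture area is exactly the mole-fraction-weighted pure areas
  plus a declared polynomial excess A_exc(π) (default −7.5 Å²
  constant, the equimolar condensation scale), which makes the
  downstream excess-area recovery exactly invertible. At boundary
  compositions the family degenerates to the pure isotherm. Real
  isotherms have correlated noise, hysteresis and collapse features
  none of which are modelled, so passing tests demonstrate correctness
  of the arithmetic and quadrature, not robustness to trough
  artefacts; measurement noise SDs are free parameters since no error
  model is available to copy.
* **Stress profiles** are sums of Gaussian bumps in the
  lateral-minus-normal combination (components emitted as Pxx = Pyy =
  bump sum, Pzz = 0, optional i.i.d. Gaussian noise per component).
  Gaussians were chosen because their first and second moments have
  closed forms, giving exact oracles: a bump a·exp(−(z−μ)²/2σ²)
  contributes aσ√(2π)·μ and aσ√(2π)·(μ²+σ²). The canonical
  three-regime leaflet (positive headgroup bump, negative
  interfacial-tension trough, positive chain bump; 300/−500/200 bar at
  2.0/1.4/0.5 nm) mirrors the shape of coarse-grained bilayer
  profiles; `bilayer_bumps(outer_gain)` mirrors it to both leaflets and
  amplifies the outer one to emulate leaflet asymmetry (gain 1 is the
  symmetric control, whose bending moment is exactly zero). The model
  enforces a ≥5σ margin between every bump and the grid edge so
  truncated moments match the infinite-range closed forms to ~10⁻⁶.
* **Surfaces** are planes, sinusoids (wavelength constrained to divide
  the box), spherical caps on a plane, or a planar cloud with a
  declared uniformly tilted normal field (the tilt exists only in the
  oracle — it is not realisable as a periodic height field — and in a
  helper grid for testing the order parameter directly). Points are
  uniform random in (x, y), lifted to the surface, optionally jittered
  isotropically; the lower leaflet is the same surface shifted down by
  a configurable separation (default 4 nm, a typical head-to-head
  thickness). Lipid diffusion, protrusions and finite-size undulation
  spectra are not modelled.

Determinism: every generator draws all randomness from one
`numpy.random.default_rng(seed)`; identical seeds give bitwise
identical outputs, and the pipeline records seeds in every report.

## Problem sizes

Defaults were chosen as the smallest sizes at which the numerical
errors are comfortably below the assertions made about them: 200-point
isotherms, 512-point stress grids (trapezoid error on the Gaussian
fixtures ≪ 0.1%), 64×64 surface grids with 4000-lipid clouds (fitted
S_C within ~0.4% of the analytic value), and smaller clouds/grids for
invariance tests where absolute accuracy is not the point.

## Known limitations

* No monolayer-to-bilayer pressure mapping, equation-of-state fitting
  or hysteresis analysis; the composition of an enzymatically
  converted film is treated as a label, not inferred.
* The stress tensor itself is never computed from trajectories; the
  package starts from profiles.
* No principal- or Gaussian-curvature maps and no lipid-domain
  detection; S_C is a single scalar summary of the normal
  distribution.
* Reports at which pressure a single representative Cs⁻¹ should be
  read are deliberately not hard-wired: both "at a stated pressure"
  and "maximum over the isotherm" readings are one line of numpy on
  the returned curve, since conventions differ between laboratories.
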