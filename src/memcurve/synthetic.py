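"""Synthetic trough, stress-profile and surface data with known ground truth.

Every downstream stage of the package is testable without trough
measurements or MD trajectories because the generators here emit the same
objects (and, through :mod:`memcurve.io`, the same file formats) the
analysis modules consume, together with analytically known answers:

* π–A isotherms from declared functional forms (linear, hyperbolic,
  piecewise with a phase-plateau segment), monotone before noise;
* binary-mixture isotherm families built so the mixture area equals the
  mole-fraction-weighted pure areas plus a declared excess-area function,
  making the excess-area/Gibbs analysis exactly invertible;
* lateral-pressure profiles as sums of Gaussian bumps, whose first and
  second z-moments have closed forms — exact oracles for the bending
  moment and Gaussian modulus;
* leaflet point clouds on planes, sinusoids and spherical buds, with the
  curvature order parameter of the analytic surface computed by dense
  quadrature.

Noise is additive Gaussian (on π, on stress components, and positionally
on surface points); all randomness flows through a single integer seed
per model, so identical seeds reproduce identical outputs bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.integrate import quad

from .datatypes import (
    ElasticConstants,
    Isotherm,
    LipidFrame,
    MixtureSpec,
    StressProfile,
    SurfaceGrid,
)
from .errors import ConfigurationError
from .surface import p2
from .units import DEFAULT_TEMPERATURE

ISOTHERM_FORMS = ("linear", "hyperbolic", "piecewise-with-plateau")
SURFACE_FORMS = ("plane", "tilted_normal_field", "sinusoid", "spherical_bud")


@dataclass(frozen=True)
class IsothermModel:
    """Declared analytic form of a π(A) isotherm.

    coefficients by form:
      linear                  [c0, c1]: π = c0 + c1·A, c1 < 0
      hyperbolic              [c]: π = c/A (two-dimensional ideal gas-like)
      piecewise-with-plateau  [π0, π1, π2, π3, A1, A2]: piecewise linear
          through (A_min, π0), (A1, π1), (A2, π2), (A_max, π3) with the
          middle (A1..A2) segment the low-slope phase plateau
    """

    form: str
    coefficients: tuple
    area_range: tuple[float, float]
    noise_sd: float = 0.0
    seed: int = 0
    n_points: int = 200

    def __post_init__(self) -> None:
        a_min, a_max = self.area_range
        if not (0 < a_min < a_max):
            raise ConfigurationError("area_range must satisfy 0 < A_min < A_max")
        if self.n_points < 8:
            raise ConfigurationError("n_points must be >= 8")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        c = self.coefficients
        if self.form == "linear":
            if len(c) != 2 or c[1] >= 0:
                raise ConfigurationError(
                    "linear form needs [intercept, slope] with slope < 0"
                )
        elif self.form == "hyperbolic":
            if len(c) != 1 or c[0] <= 0:
                raise ConfigurationError("hyperbolic form needs one positive constant")
        elif self.form == "piecewise-with-plateau":
            if len(c) != 6:
                raise ConfigurationError(
                    "piecewise form needs [pi0, pi1, pi2, pi3, A1, A2]"
                )
            pi0, pi1, pi2, pi3, a1, a2 = c
            if not (a_min < a1 < a2 < a_max):
                raise ConfigurationError("knees must satisfy A_min < A1 < A2 < A_max")
            if not (pi0 > pi1 >= pi2 > pi3 >= 0):
                raise ConfigurationError(
                    "pressures must decrease along compression release"
                )
        else:
            raise ConfigurationError(f"unknown isotherm form {self.form!r}")
        if self.pressure(np.array([a_min, a_max])).min() < 0:
            raise ConfigurationError("form yields negative pressure in range")

    def pressure(self, area: np.ndarray) -> np.ndarray:
        """Noiseless π(A) in mN/m."""
        area = np.asarray(area, dtype=float)
        c = self.coefficients
        if self.form == "linear":
            return c[0] + c[1] * area
        if self.form == "hyperbolic":
            return c[0] / area
        pi0, pi1, pi2, pi3, a1, a2 = c
        knots_a = np.array([self.area_range[0], a1, a2, self.area_range[1]])
        knots_pi = np.array([pi0, pi1, pi2, pi3])
        return np.interp(area, knots_a, knots_pi)

    def area(self, pressure: np.ndarray) -> np.ndarray:
        """Analytic inverse A(π) in Å² (forms are strictly monotone
        except on an exactly flat plateau, which these validators forbid
        only when π1 = π2; the interp inverse then picks the plateau edge).
        """
        pressure = np.asarray(pressure, dtype=float)
        c = self.coefficients
        if self.form == "linear":
            return (pressure - c[0]) / c[1]
        if self.form == "hyperbolic":
            return c[0] / pressure
        pi0, pi1, pi2, pi3, a1, a2 = c
        knots_a = np.array([self.area_range[0], a1, a2, self.area_range[1]])
        knots_pi = np.array([pi0, pi1, pi2, pi3])
        return np.interp(pressure, knots_pi[::-1], knots_a[::-1])

    @property
    def pressure_range(self) -> tuple[float, float]:
        lo = float(self.pressure(np.array([self.area_range[1]]))[0])
        hi = float(self.pressure(np.array([self.area_range[0]]))[0])
        return lo, hi


def gen_isotherm(model: IsothermModel, label: str = "",
                 composition: MixtureSpec | None = None) -> Isotherm:
    """Sample an isotherm from its declared model, optionally with noise.

    Areas are sampled uniformly over the model's range; Gaussian noise of
    the declared SD is added to π and the result clipped at zero (surface
    pressure cannot be negative). The model is recorded as provenance.
    """
    area = np.linspace(*model.area_range, model.n_points)
    pi = model.pressure(area)
    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        pi = np.clip(pi + rng.normal(0.0, model.noise_sd, pi.shape), 0.0, None)
    return Isotherm(
        pressure=pi,
        area=area,
        label=label or model.form,
        composition=composition,
        provenance={"model": model},
    )


@dataclass(frozen=True)
class MixtureScenario:
    """Declared binary-mixture construction for an isotherm family.

    ``excess_area_coeffs`` are ascending polynomial coefficients of
    A_exc(π) in Å² (a single value declares a constant excess); they must
    evaluate finitely over the shared pressure range. At boundary
    compositions (X = 0 or 1) the family degenerates to the relevant pure
    isotherm and the excess is necessarily zero.
    """

    component_names: tuple[str, str] = ("CER", "SM")
    mole_fraction_first: float = 0.5
    excess_area_coeffs: tuple = (0.0,)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mole_fraction_first <= 1.0):
            raise ConfigurationError("mole_fraction_first must lie in [0, 1]")
        if len(self.component_names) != 2:
            raise ConfigurationError("component_names must be a pair")
        if not len(self.excess_area_coeffs):
            raise ConfigurationError("excess_area_coeffs must be non-empty")
        if not np.all(np.isfinite(self.excess_area_coeffs)):
            raise ConfigurationError("excess_area_coeffs must be finite")

    def excess_area(self, pressure: np.ndarray) -> np.ndarray:
        return npoly.polyval(np.asarray(pressure, dtype=float),
                             self.excess_area_coeffs)


@dataclass(frozen=True)
class MixtureFamily:
    """Pure-component and mixture isotherms from one scenario."""

    pure_first: Isotherm
    pure_second: Isotherm
    mixture: Isotherm
    scenario: MixtureScenario
    spec: MixtureSpec


def gen_mixture_family(
    pure_first: IsothermModel,
    pure_second: IsothermModel,
    scenario: MixtureScenario,
) -> MixtureFamily:
    """Build a pure/pure/mixture isotherm triple with declared excess.

    At every pressure in the shared range, the noiseless mixture area is
    X·A₁(π) + (1−X)·A₂(π) + A_exc(π), so downstream excess-area recovery
    has an exact target.
    """
    lo1, hi1 = pure_first.pressure_range
    lo2, hi2 = pure_second.pressure_range
    lo, hi = max(lo1, lo2), min(hi1, hi2)
    if hi <= lo:
        raise ConfigurationError(
            f"pure-component pressure ranges [{lo1},{hi1}] and [{lo2},{hi2}] "
            "do not overlap"
        )
    x = scenario.mole_fraction_first
    spec = MixtureSpec(fraction_cer=x, fraction_sm=1.0 - x)
    names = scenario.component_names
    iso1 = gen_isotherm(pure_first, label=f"pure {names[0]}",
                        composition=MixtureSpec.from_cer(1.0))
    iso2 = gen_isotherm(pure_second, label=f"pure {names[1]}",
                        composition=MixtureSpec.from_cer(0.0))
    if x == 1.0:
        mixture = gen_isotherm(pure_first, label="mixture (pure first)",
                               composition=spec)
    elif x == 0.0:
        mixture = gen_isotherm(pure_second, label="mixture (pure second)",
                               composition=spec)
    else:
        n = max(pure_first.n_points, pure_second.n_points)
        grid = np.linspace(lo, hi, n)
        a_mix = (
            x * pure_first.area(grid)
            + (1.0 - x) * pure_second.area(grid)
            + scenario.excess_area(grid)
        )
        if np.any(a_mix <= 0):
            raise ConfigurationError("declared excess drives mixture area <= 0")
        pi = grid
        if scenario.noise_sd > 0:
            rng = np.random.default_rng(scenario.seed)
            pi = np.clip(pi + rng.normal(0.0, scenario.noise_sd, pi.shape),
                         0.0, None)
        mixture = Isotherm(
            pressure=pi,
            area=a_mix,
            label=f"{names[0]}/{names[1]} X={x:g}",
            composition=spec,
            provenance={"scenario": scenario},
        )
    return MixtureFamily(iso1, iso2, mixture, scenario, spec)


@dataclass(frozen=True)
class StressFieldModel:
    """Lateral-minus-normal stress as a sum of Gaussian bumps.

    Each bump is (amplitude [bar], centre μ [nm], width σ [nm]); a
    realistic leaflet signature is a positive headgroup bump, a negative
    interfacial-tension bump and a positive chain-repulsion bump. The z
    range must span every centre by ≥ 5 widths so truncated moments match
    the infinite-range closed forms.
    """

    bumps: tuple
    z_range: tuple[float, float] = (-4.0, 4.0)
    n_points: int = 512
    noise_sd: float = 0.0
    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.n_points < 16:
            raise ConfigurationError("n_points must be >= 16")
        z_lo, z_hi = self.z_range
        if z_hi <= z_lo:
            raise ConfigurationError("z_range must be increasing")
        if not self.bumps:
            raise ConfigurationError("need at least one bump")
        for amp, mu, sigma in self.bumps:
            if sigma <= 0:
                raise ConfigurationError("bump widths must be positive")
            if mu - 5 * sigma < z_lo or mu + 5 * sigma > z_hi:
                raise ConfigurationError(
                    f"z_range must span bump at mu={mu} by >= 5 widths "
                    f"(needs [{mu - 5 * sigma}, {mu + 5 * sigma}])"
                )

    def lpp(self, z: np.ndarray) -> np.ndarray:
        """Noiseless declared bump sum, bar."""
        z = np.asarray(z, dtype=float)
        out = np.zeros_like(z)
        for amp, mu, sigma in self.bumps:
            out += amp * np.exp(-((z - mu) ** 2) / (2.0 * sigma**2))
        return out

    def true_moments(self) -> tuple[float, float]:
        """Closed-form (∫ z·LPP dz, ∫ z²·LPP dz) over the whole line.

        For a bump a·exp(−(z−μ)²/2σ²): ∫z = a·σ·√(2π)·μ and
        ∫z² = a·σ·√(2π)·(μ² + σ²).
        """
        m1 = m2 = 0.0
        for amp, mu, sigma in self.bumps:
            mass = amp * sigma * math.sqrt(2.0 * math.pi)
            m1 += mass * mu
            m2 += mass * (mu**2 + sigma**2)
        return m1, m2


#: Canonical three-regime leaflet stress signature (bar, nm, nm):
#: headgroup repulsion (+, outermost), interfacial-tension trough (−),
#: acyl-chain repulsion (+, innermost).
THREE_REGIME_LEAFLET = (
    (300.0, 2.0, 0.3),
    (-500.0, 1.4, 0.25),
    (200.0, 0.5, 0.35),
)


def bilayer_bumps(leaflet=THREE_REGIME_LEAFLET, outer_gain: float = 1.0) -> tuple:
    """Bilayer bump set: the leaflet at +z plus its mirror at −z.

    ``outer_gain`` amplifies only the outer (+z) leaflet, producing the
    leaflet-asymmetric stress signature of a mixed-composition outer
    monolayer; gain 1 gives the symmetric control membrane.
    """
    outer = tuple((a * outer_gain, mu, s) for a, mu, s in leaflet)
    inner = tuple((a, -mu, s) for a, mu, s in leaflet)
    return outer + inner


def mirror_bumps(bumps) -> tuple:
    """Symmetrize a leaflet bump set: each bump plus its z → −z image,
    amplitudes halved so the total integrated stress is preserved."""
    out = []
    for amp, mu, sigma in bumps:
        out.append((amp / 2.0, mu, sigma))
        out.append((amp / 2.0, -mu, sigma))
    return tuple(out)


def gen_stress_profile(model: StressFieldModel) -> tuple[StressProfile, ElasticConstants]:
    """Gridded stress components plus exact elastic-constant ground truth.

    The components are constructed so (Pxx+Pyy)/2 − Pzz equals the
    declared bump sum (Pzz ≡ 0, Pxx = Pyy = bump sum), then optional
    Gaussian noise is added to each component independently. The returned
    ground truth is the closed-form first moment and negative second
    moment of the noiseless sum.
    """
    z = np.linspace(*model.z_range, model.n_points)
    lpp = model.lpp(z)
    pxx = lpp.copy()
    pyy = lpp.copy()
    pzz = np.zeros_like(z)
    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        pxx = pxx + rng.normal(0.0, model.noise_sd, z.shape)
        pyy = pyy + rng.normal(0.0, model.noise_sd, z.shape)
        pzz = pzz + rng.normal(0.0, model.noise_sd, z.shape)
    m1, m2 = model.true_moments()
    truth = ElasticConstants(
        bending_moment_bar_nm2=m1,
        gaussian_modulus_bar_nm3=-m2,
        temperature=model.temperature,
    )
    return StressProfile(z=z, pxx=pxx, pyy=pyy, pzz=pzz), truth


@dataclass(frozen=True)
class SurfaceModel:
    """Analytic leaflet surface to sample lipid reference points from.

    parameters by form (all lengths nm, angles rad):
      plane               {height}
      tilted_normal_field {height, tilt}: planar point cloud whose
                          *declared* normal field is uniformly tilted —
                          the tilt lives in the oracle and in
                          :func:`uniform_tilt_grid`, not in the heights
      sinusoid            {height, amplitude, wavelength}: h(x) = height +
                          amplitude·sin(2πx/wavelength); the wavelength
                          must divide the box Lx for periodicity
      spherical_bud       {height, radius, cap_angle}: a spherical cap of
                          the given radius and polar cap angle rising from
                          a plane at the box centre

    The lower leaflet mirrors the upper, shifted down by
    ``leaflet_separation``.
    """

    form: str
    parameters: dict
    box: tuple[float, float] = (10.0, 10.0)
    n_lipids_per_leaflet: int = 1000
    jitter_sd: float = 0.0
    seed: int = 0
    leaflet_separation: float = 4.0

    def __post_init__(self) -> None:
        if self.form not in SURFACE_FORMS:
            raise ConfigurationError(f"unknown surface form {self.form!r}")
        if self.n_lipids_per_leaflet < 4:
            raise ConfigurationError("need >= 4 lipids per leaflet")
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter_sd must be non-negative")
        lx, ly = self.box
        p = self.parameters
        if self.form == "sinusoid":
            lam = p["wavelength"]
            if lam <= 0 or abs(lx / lam - round(lx / lam)) > 1e-9:
                raise ConfigurationError(
                    f"wavelength {lam} must divide the box Lx={lx}"
                )
            if p["amplitude"] < 0:
                raise ConfigurationError("amplitude must be non-negative")
        elif self.form == "spherical_bud":
            r, alpha = p["radius"], p["cap_angle"]
            if not (0 < alpha <= math.pi / 2):
                raise ConfigurationError("cap_angle must lie in (0, pi/2]")
            if r <= 0:
                raise ConfigurationError("radius must be positive")
            if r > min(lx, ly) / 2.0:
                raise ConfigurationError(
                    f"bud radius {r} exceeds box half-width {min(lx, ly) / 2}"
                )
        elif self.form == "tilted_normal_field":
            if not (0 <= p.get("tilt", 0.0) <= math.pi / 2):
                raise ConfigurationError("tilt must lie in [0, pi/2]")

    def height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Analytic upper-leaflet height h(x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        h0 = self.parameters.get("height", 0.0)
        if self.form in ("plane", "tilted_normal_field"):
            return np.full(np.broadcast(x, y).shape, float(h0))
        if self.form == "sinusoid":
            a = self.parameters["amplitude"]
            lam = self.parameters["wavelength"]
            return h0 + a * np.sin(2.0 * math.pi * x / lam)
        r0, alpha = self.parameters["radius"], self.parameters["cap_angle"]
        cx, cy = self.box[0] / 2.0, self.box[1] / 2.0
        r = np.hypot(x - cx, y - cy)
        r_cap = r0 * math.sin(alpha)
        h = np.full(np.broadcast(x, y).shape, float(h0))
        inside = r < r_cap
        h = np.where(
            inside,
            h0 + np.sqrt(np.clip(r0**2 - r**2, 0.0, None)) - r0 * math.cos(alpha),
            h,
        )
        return h

    def oracle_order_parameter(self) -> float:
        """S_C of the analytic surface by dense quadrature.

        Mean of P₂(cos θ) of the analytic normal over the projected box
        (uniform in-plane weighting, matching the uniform (x, y) sampling
        of the point cloud and the grid average downstream).
        """
        if self.form == "plane":
            return 1.0
        if self.form == "tilted_normal_field":
            return float(p2(math.cos(self.parameters.get("tilt", 0.0))))
        if self.form == "sinusoid":
            a = self.parameters["amplitude"]
            lam = self.parameters["wavelength"]
            k = 2.0 * math.pi / lam

            def integrand(x):
                hprime = a * k * math.cos(k * x)
                return p2(1.0 / math.sqrt(1.0 + hprime**2))

            val, _ = quad(integrand, 0.0, lam, limit=200)
            return float(val / lam)
        # spherical bud: cap contributes P2(cos phi) with sin phi = r/R,
        # over projected annuli 2πr dr; the flat remainder contributes 1
        r0, alpha = self.parameters["radius"], self.parameters["cap_angle"]
        r_cap = r0 * math.sin(alpha)
        box_area = self.box[0] * self.box[1]

        def integrand(r):
            cos_phi = math.sqrt(max(1.0 - (r / r0) ** 2, 0.0))
            return p2(cos_phi) * 2.0 * math.pi * r

        cap, _ = quad(integrand, 0.0, r_cap, limit=200)
        flat = box_area - math.pi * r_cap**2
        return float((cap + flat) / box_area)


def gen_surface_cloud(model: SurfaceModel) -> tuple[LipidFrame, float]:
    """Sample a two-leaflet point cloud from the model surface.

    Points are uniform random in (x, y) (mimicking in-plane lipid
    disorder), lifted to the analytic surface, and jittered isotropically
    by ``jitter_sd``. Returns the frame and the oracle curvature order
    parameter of the noiseless surface.
    """
    rng = np.random.default_rng(model.seed)
    lx, ly = model.box
    n = model.n_lipids_per_leaflet
    frames = []
    labels = []
    for leaflet, z_off in (("upper", 0.0), ("lower", -model.leaflet_separation)):
        x = rng.uniform(0.0, lx, n)
        y = rng.uniform(0.0, ly, n)
        z = model.height(x, y) + z_off
        pts = np.column_stack([x, y, z])
        if model.jitter_sd > 0:
            pts = pts + rng.normal(0.0, model.jitter_sd, pts.shape)
        frames.append(pts)
        labels.extend([leaflet] * n)
    frame = LipidFrame(
        positions=np.vstack(frames),
        leaflet=np.array(labels),
        box=model.box,
    )
    return frame, model.oracle_order_parameter()


def uniform_tilt_grid(tilt: float, box=(10.0, 10.0), nx: int = 16,
                      ny: int = 16, height: float = 0.0) -> SurfaceGrid:
    """A flat grid whose declared normal field is uniformly tilted.

    Not realisable as a periodic height field for tilt > 0; exists so the
    order-parameter calculation can be checked against P₂(cos tilt)
    directly.
    """
    heights = np.full((nx, ny), float(height))
    normals = np.zeros((nx, ny, 3))
    normals[..., 0] = math.sin(tilt)
    normals[..., 2] = math.cos(tilt)
    theta = np.full((nx, ny), float(tilt))
    return SurfaceGrid(heights=heights, normals=normals, theta=theta, box=box)
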