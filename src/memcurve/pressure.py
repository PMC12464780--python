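"""Lateral pressure profile and membrane elastic constants.

The depth-resolved lateral pressure profile of a bilayer,

    LPP(z) = [Pxx(z) + Pyy(z)]/2 − Pzz(z),

carries the membrane's curvature energetics in its low-order z-moments:
the first moment over the membrane slab [d₋, d₊] is the spontaneous
bending moment K_C·c₀ (the intrinsic drive to curve), and the negative
second moment is the Gaussian (saddle-splay) modulus K̄_G, which prices
topology-changing deformations such as budding. Both moments assume the
bilayer midplane sits at z = 0, so profiles are centred before
integration.

Sign convention: inputs are pressure-tensor components as MD engines
report them; no virial-sign flip is applied anywhere. Feeding stress
(negative pressure) instead negates both moments.
"""

from __future__ import annotations

import math

import numpy as np

from .datatypes import (
    ElasticConstants,
    LateralPressureProfile,
    MembraneBounds,
    StressProfile,
    shift_profile,
)
from .errors import CenteringError, DegenerateProfileError, RangeError
from .units import DEFAULT_TEMPERATURE

#: Support threshold for bounds detection, as a fraction of max |LPP|.
DEFAULT_SUPPORT_FRACTION = 0.01


def compute_lpp(stress: StressProfile) -> LateralPressureProfile:
    """LPP(z) = (Pxx + Pyy)/2 − Pzz, pointwise, no smoothing."""
    lpp = 0.5 * (stress.pxx + stress.pyy) - stress.pzz
    return LateralPressureProfile(z=stress.z.copy(), lpp=lpp)


def _support_mask(lpp: np.ndarray, fraction: float) -> np.ndarray:
    peak = np.max(np.abs(lpp))
    if peak == 0.0:
        raise DegenerateProfileError("profile is identically zero")
    return np.abs(lpp) > fraction * peak


def locate_midplane(
    profile: LateralPressureProfile,
    mode: str = "zero_crossings",
    support_fraction: float = DEFAULT_SUPPORT_FRACTION,
) -> float:
    """Estimate the midplane position on the profile's current z axis.

    ``"zero_crossings"`` (default): midpoint between the outermost
    sign changes of LPP, each located by linear interpolation; falls back
    to the support centre when the profile never changes sign.
    ``"support_center"``: geometric centre of the region where |LPP|
    exceeds ``support_fraction`` of its peak.
    """
    z, lpp = profile.z, profile.lpp
    try:
        mask = _support_mask(lpp, support_fraction)
    except DegenerateProfileError as exc:
        raise CenteringError("cannot centre an all-zero profile") from exc
    support_center = 0.5 * (z[mask].min() + z[mask].max())
    if mode == "support_center":
        return float(support_center)
    if mode != "zero_crossings":
        raise CenteringError(f"unknown midplane locator mode {mode!r}")
    sign = np.sign(lpp)
    nonzero = sign != 0
    changes = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if changes.size == 0 or not np.any(nonzero):
        return float(support_center)
    crossings = []
    for i in (changes[0], changes[-1]):
        z0, z1, f0, f1 = z[i], z[i + 1], lpp[i], lpp[i + 1]
        crossings.append(z0 - f0 * (z1 - z0) / (f1 - f0))
    return float(0.5 * (crossings[0] + crossings[-1]))


def center_midplane(
    profile: LateralPressureProfile,
    mode: str = "zero_crossings",
    support_fraction: float = DEFAULT_SUPPORT_FRACTION,
) -> LateralPressureProfile:
    """Shift z so the detected midplane sits at 0; the shift is recorded.

    Idempotent up to the locator's resolution: re-centring an already
    centred profile applies a (numerically) zero shift.
    """
    midplane = locate_midplane(profile, mode=mode, support_fraction=support_fraction)
    return shift_profile(profile, -midplane)


def detect_bounds(
    profile: LateralPressureProfile,
    support_fraction: float = DEFAULT_SUPPORT_FRACTION,
    explicit: tuple[float, float] | None = None,
    full_box: bool = False,
) -> MembraneBounds:
    """Locate the membrane slab [d₋, d₊] on a centred profile.

    Default rule: outermost z where |LPP| exceeds ``support_fraction`` of
    its peak, padded outward by one grid step (keeps bulk-water noise out
    of the moments while capturing the full stress support); the bounds
    are widened to straddle the midplane when the support lies on one
    side only. ``full_box=True`` integrates the whole grid instead, and
    an ``explicit`` (d₋, d₊) pair overrides detection and is returned
    verbatim.
    """
    if explicit is not None:
        return MembraneBounds(explicit[0], explicit[1], detection_rule="explicit")
    dz = profile.spacing
    if full_box:
        return MembraneBounds(
            float(profile.z[0]), float(profile.z[-1]), detection_rule="full_box"
        )
    mask = _support_mask(profile.lpp, support_fraction)
    z_sup = profile.z[mask]
    d_minus = float(max(z_sup.min() - dz, profile.z[0]))
    d_plus = float(min(z_sup.max() + dz, profile.z[-1]))
    # moments are defined about the midplane; always bracket it
    d_minus = min(d_minus, -dz)
    d_plus = max(d_plus, dz)
    return MembraneBounds(
        d_minus,
        d_plus,
        detection_rule=f"support_threshold f={support_fraction} pad=1 step",
    )


def _window(profile: LateralPressureProfile, bounds: MembraneBounds):
    z = profile.z
    if bounds.d_minus < z[0] - 1e-9 or bounds.d_plus > z[-1] + 1e-9:
        raise RangeError(
            f"bounds [{bounds.d_minus}, {bounds.d_plus}] outside grid "
            f"[{z[0]}, {z[-1]}]"
        )
    mask = (z >= bounds.d_minus - 1e-12) & (z <= bounds.d_plus + 1e-12)
    return z[mask], profile.lpp[mask]


def bending_moment(
    profile: LateralPressureProfile,
    bounds: MembraneBounds,
    temperature: float = DEFAULT_TEMPERATURE,
) -> ElasticConstants:
    """Spontaneous bending moment K_C·c₀ = ∫ z·LPP(z) dz over [d₋, d₊].

    Composite trapezoid on the native grid; reported in bar·nm² with a pN
    view (1 bar·nm² = 0.1 pN). The Gaussian-modulus slot of the returned
    record is zero; use :func:`elastic_constants` for both at once.
    """
    z, lpp = _window(profile, bounds)
    m1 = float(np.trapezoid(z * lpp, z))
    return ElasticConstants(
        bending_moment_bar_nm2=m1,
        gaussian_modulus_bar_nm3=0.0,
        temperature=temperature,
    )


def gaussian_modulus(
    profile: LateralPressureProfile,
    bounds: MembraneBounds,
    temperature: float = DEFAULT_TEMPERATURE,
) -> ElasticConstants:
    """Gaussian modulus K̄_G = −∫ z²·LPP(z) dz over [d₋, d₊].

    Reported in bar·nm³ with a k_B·T view at the stated temperature
    (1 bar·nm³ = 10⁻²² J). Negative K̄_G disfavours saddle topologies.
    """
    z, lpp = _window(profile, bounds)
    m2 = float(np.trapezoid(z**2 * lpp, z))
    return ElasticConstants(
        bending_moment_bar_nm2=0.0,
        gaussian_modulus_bar_nm3=-m2,
        temperature=temperature,
    )


def elastic_constants(
    profile: LateralPressureProfile,
    bounds: MembraneBounds | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> ElasticConstants:
    """Both moments of a centred profile in one pass.

    Detects bounds with the default support rule when none are given.
    """
    if bounds is None:
        bounds = detect_bounds(profile)
    z, lpp = _window(profile, bounds)
    m1 = float(np.trapezoid(z * lpp, z))
    m2 = float(np.trapezoid(z**2 * lpp, z))
    return ElasticConstants(
        bending_moment_bar_nm2=m1,
        gaussian_modulus_bar_nm3=-m2,
        temperature=temperature,
    )


def curvature_radius(c0: float) -> float:
    """Radius of spontaneous curvature R = 1/|c₀| in nm.

    A flat membrane (c₀ = 0) is signalled by the distinguished value
    ``math.inf`` rather than an exception.
    """
    if c0 == 0:
        return math.inf
    return 1.0 / abs(c0)
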