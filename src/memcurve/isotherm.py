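"""Langmuir isotherm thermodynamics for binary lipid monolayers.

Implements the standard excess-quantity analysis of π–A trough data for a
ceramide/sphingomyelin (CER/SM) binary mixture:

* excess molecular area  A_exc(π) = A_mix − (A_CER·X_CER + A_SM·X_SM),
* excess Gibbs energy    ΔG_exc(π₀) = N_A ∫₀^π₀ A_exc dπ′,
* compressibility modulus Cs⁻¹(π) = −A_π (dπ/dA)_T,

plus monolayer phase-state classification from Cs⁻¹ and a similarity
metric between isotherms. All multi-isotherm operations interpolate areas
onto an explicit common pressure grid, because trough curves never share
raw pressure samples exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .datatypes import (
    CompressibilityCurve,
    ExcessAreaCurve,
    GibbsExcessResult,
    Isotherm,
    MixtureSpec,
)
from .errors import (
    ExtrapolationError,
    InsufficientDataError,
    RangeError,
    ValidationError,
)
from .units import A2_MNM_TO_J_PER_MOL

#: Monolayer phase-state thresholds on Cs⁻¹ (mN/m), classical convention.
DEFAULT_PHASE_THRESHOLDS = {
    "gaseous": (0.0, 12.5),
    "liquid-expanded": (12.5, 50.0),
    "transitional": (50.0, 100.0),
    "liquid-condensed": (100.0, 250.0),
    "solid": (250.0, np.inf),
}


def area_at_pressure(iso: Isotherm, pi_target: float) -> float:
    """Molecular area [Å²] at a target surface pressure by interpolation.

    Monotone linear interpolation of A(π) on the canonically sorted
    isotherm; refuses to extrapolate outside the sampled pressure range.
    """
    lo, hi = iso.pressure_range
    if not (lo <= pi_target <= hi):
        raise ExtrapolationError(
            f"pi_target {pi_target} mN/m outside sampled range [{lo}, {hi}]"
        )
    # canonical storage is decreasing in area => increasing in pi for
    # monotone isotherms; sort by pi to be safe against local noise
    order = np.argsort(iso.pressure, kind="stable")
    return float(np.interp(pi_target, iso.pressure[order], iso.area[order]))


def common_pressure_grid(
    isotherms: list[Isotherm], n: int = 200, pi_min: float | None = None,
    pi_max: float | None = None,
) -> np.ndarray:
    """Uniform pressure grid over the shared range of several isotherms."""
    lo = max(iso.pressure_range[0] for iso in isotherms)
    hi = min(iso.pressure_range[1] for iso in isotherms)
    if pi_min is not None:
        lo = max(lo, pi_min)
    if pi_max is not None:
        hi = min(hi, pi_max)
    if hi <= lo:
        raise RangeError("isotherm pressure ranges do not overlap")
    return np.linspace(lo, hi, n)


def excess_area(
    mixture: Isotherm,
    pure_cer: Isotherm,
    pure_sm: Isotherm,
    spec: MixtureSpec,
    grid: np.ndarray | None = None,
    n_grid: int = 200,
) -> ExcessAreaCurve:
    """Excess molecular area of a binary mixture on a common pressure grid.

    A_ideal(π) = X_CER·A_CER(π) + X_SM·A_SM(π);  A_exc = A_mix − A_ideal.
    Negative A_exc signals attractive CER–SM interactions, positive
    repulsive, zero ideal mixing.
    """
    isos = [mixture, pure_cer, pure_sm]
    if grid is None:
        grid = common_pressure_grid(isos, n=n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
        lo = max(iso.pressure_range[0] for iso in isos)
        hi = min(iso.pressure_range[1] for iso in isos)
        if grid.min() < lo - 1e-12 or grid.max() > hi + 1e-12:
            raise RangeError(
                f"grid [{grid.min()}, {grid.max()}] exceeds shared pressure "
                f"range [{lo}, {hi}]"
            )
    a_mix = np.array([area_at_pressure(mixture, p) for p in grid])
    a_cer = np.array([area_at_pressure(pure_cer, p) for p in grid])
    a_sm = np.array([area_at_pressure(pure_sm, p) for p in grid])
    a_ideal = spec.fraction_cer * a_cer + spec.fraction_sm * a_sm
    return ExcessAreaCurve(
        pressure_grid=grid,
        a_exc=a_mix - a_ideal,
        a_ideal=a_ideal,
        a_mix=a_mix,
        spec=spec,
    )


def excess_gibbs_energy(
    curve: ExcessAreaCurve,
    upper_limit: float,
    zero_extension: str = "constant",
) -> float:
    """Excess Gibbs energy ΔG_exc(π₀) = N_A ∫₀^π₀ A_exc dπ′ in J/mol.

    Composite-trapezoid quadrature of A_exc over [0, upper_limit]. Trough
    data rarely reach π = 0, so the curve is extended down to zero pressure
    by the ``zero_extension`` rule: ``"constant"`` holds the
    lowest-pressure value (default), ``"linear"`` extrapolates the first
    grid segment. One Å²·mN/m per molecule is 6.02214076 J/mol.
    """
    grid = curve.pressure_grid
    if upper_limit > grid[-1] + 1e-12:
        raise RangeError(
            f"upper limit {upper_limit} beyond grid maximum {grid[-1]}"
        )
    if upper_limit < 0:
        raise RangeError("upper limit must be non-negative")
    if upper_limit == 0:
        return 0.0
    pi, a = grid, curve.a_exc
    if pi[0] > 0:
        if zero_extension == "constant":
            a0 = a[0]
        elif zero_extension == "linear":
            slope = (a[1] - a[0]) / (pi[1] - pi[0])
            a0 = a[0] - slope * pi[0]
        else:
            raise ValidationError(f"unknown zero_extension rule {zero_extension!r}")
        pi = np.concatenate([[0.0], pi])
        a = np.concatenate([[a0], a])
    # truncate at the upper limit, adding an interpolated end node
    keep = pi <= upper_limit + 1e-12
    pi_t, a_t = pi[keep], a[keep]
    if pi_t[-1] < upper_limit:
        a_end = np.interp(upper_limit, pi, a)
        pi_t = np.concatenate([pi_t, [upper_limit]])
        a_t = np.concatenate([a_t, [a_end]])
    integral = np.trapezoid(a_t, pi_t)  # Å²·mN/m per molecule
    return float(integral * A2_MNM_TO_J_PER_MOL)


def excess_gibbs_curve(
    curve: ExcessAreaCurve,
    upper_limits: np.ndarray | None = None,
    zero_extension: str = "constant",
) -> GibbsExcessResult:
    """ΔG_exc evaluated at a series of upper pressure limits."""
    if upper_limits is None:
        upper_limits = curve.pressure_grid
    upper_limits = np.asarray(upper_limits, dtype=float)
    values = np.array(
        [excess_gibbs_energy(curve, p, zero_extension) for p in upper_limits]
    )
    return GibbsExcessResult(
        upper_limits=upper_limits,
        delta_g_exc=values,
        quadrature_rule=f"trapezoid, zero_extension={zero_extension}",
    )


@dataclass(frozen=True)
class SmoothingConfig:
    """Derivative-estimation settings for the compressibility modulus.

    Savitzky–Golay local-polynomial derivative with the given window and
    order; ``window=0`` disables smoothing and uses plain second-order
    finite differences. Trough data are noisy, so the smoothed default is
    appropriate for real measurements; the unsmoothed mode is exact on
    clean analytic fixtures.
    """

    window: int = 11
    polyorder: int = 3


def compressibility_modulus(
    iso: Isotherm,
    grid: np.ndarray | None = None,
    smoothing: SmoothingConfig = SmoothingConfig(),
    n_grid: int = 200,
) -> CompressibilityCurve:
    """Compressibility modulus Cs⁻¹(π) = −A_π (dπ/dA)_T on a pressure grid.

    The derivative dπ/dA is estimated on the area-ordered isotherm; the
    resulting Cs⁻¹ values are then interpolated onto the requested
    pressure grid. High Cs⁻¹ means a stiff, densely packed monolayer.
    """
    a = iso.area[::-1]  # ascending area
    pi = iso.pressure[::-1]
    if smoothing.window:
        if a.size < smoothing.window:
            raise InsufficientDataError(
                f"{a.size} points < Savitzky-Golay window {smoothing.window}"
            )
        da = np.diff(a)
        if np.ptp(da) > 1e-6 * abs(da.mean()):
            # savgol assumes a uniform abscissa; fall back to differences
            dpi_da = np.gradient(pi, a)
            descriptor = "np.gradient (non-uniform area grid)"
        else:
            dpi_da = savgol_filter(
                pi, smoothing.window, smoothing.polyorder, deriv=1,
                delta=float(da.mean()),
            )
            descriptor = (
                f"savgol window={smoothing.window} order={smoothing.polyorder}"
            )
    else:
        if a.size < 3:
            raise InsufficientDataError("need >= 3 points for finite differences")
        dpi_da = np.gradient(pi, a)
        descriptor = "np.gradient central differences"
    cs_inv = -a * dpi_da
    if isinstance(grid, str):
        if grid != "native":
            raise ValidationError(f"unknown grid mode {grid!r}")
        # report at the measured pressures (ascending area order)
        return CompressibilityCurve(
            pressure_grid=pi,
            cs_inv=cs_inv,
            derivative_estimate=dpi_da,
            smoothing_descriptor=descriptor + ", native grid",
        )
    if grid is None:
        grid = common_pressure_grid([iso], n=n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
        lo, hi = iso.pressure_range
        if grid.min() < lo - 1e-12 or grid.max() > hi + 1e-12:
            raise RangeError("grid outside the isotherm's pressure range")
    order = np.argsort(pi, kind="stable")
    cs_on_grid = np.interp(grid, pi[order], cs_inv[order])
    d_on_grid = np.interp(grid, pi[order], dpi_da[order])
    return CompressibilityCurve(
        pressure_grid=grid,
        cs_inv=cs_on_grid,
        derivative_estimate=d_on_grid,
        smoothing_descriptor=descriptor,
    )


def classify_phase(
    curve: CompressibilityCurve,
    thresholds: dict | None = None,
) -> dict:
    """Map each Cs⁻¹ value to a monolayer phase-state label.

    Thresholds follow the classical monolayer-state convention by default
    (gaseous < 12.5 < liquid-expanded < 50 < transitional < 100 <
    liquid-condensed < 250 < solid, in mN/m) and are fully configurable.
    Non-finite Cs⁻¹ values are flagged 'unclassified' rather than raising.
    """
    if thresholds is None:
        thresholds = DEFAULT_PHASE_THRESHOLDS
    labels = []
    for v in curve.cs_inv:
        if not np.isfinite(v):
            labels.append("unclassified")
            continue
        label = "unclassified"
        for name, (lo, hi) in thresholds.items():
            if lo <= v < hi:
                label = name
                break
        if label == "unclassified" and v < 0:
            label = "gaseous"  # noise below zero: treat as the lowest class
        labels.append(label)
    return {
        "pressure_grid": curve.pressure_grid,
        "cs_inv": curve.cs_inv,
        "phase": np.array(labels),
        "thresholds": {k: tuple(v) for k, v in thresholds.items()},
    }


def compare_isotherms(
    a: Isotherm,
    b: Isotherm,
    grid: np.ndarray | None = None,
    n_grid: int = 200,
) -> dict:
    """Quantify how alike two isotherms are at equal surface pressure.

    Returns the RMS and maximum absolute molecular-area differences [Å²]
    on a common pressure grid; symmetric in its arguments.
    """
    if grid is None:
        grid = common_pressure_grid([a, b], n=n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
        lo = max(a.pressure_range[0], b.pressure_range[0])
        hi = min(a.pressure_range[1], b.pressure_range[1])
        if grid.min() < lo - 1e-12 or grid.max() > hi + 1e-12:
            raise RangeError("grid outside the shared pressure range")
    area_a = np.array([area_at_pressure(a, p) for p in grid])
    area_b = np.array([area_at_pressure(b, p) for p in grid])
    diff = area_a - area_b
    return {
        "pressure_grid": grid,
        "area_difference": diff,
        "rms_difference_A2": float(np.sqrt(np.mean(diff**2))),
        "max_difference_A2": float(np.max(np.abs(diff))),
        "labels": (a.label, b.label),
    }
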