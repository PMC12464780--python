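"""Core data containers.

Frozen-ish dataclasses around numpy arrays. Each container validates its
documented invariants at construction; analysis functions can therefore
assume well-formed inputs. Units are fixed per field and never carried
symbolically: pressures in mN/m, molecular areas in Å², membrane-normal
coordinates in nm, stresses in bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .units import BAR_NM2_TO_PN, bar_nm3_to_kbt


@dataclass(frozen=True)
class MixtureSpec:
    """Binary ceramide/sphingomyelin composition.

    Mole fractions of the two components; they must sum to one. A pure
    component is a valid edge case (``fraction_cer`` 0 or 1).
    """

    fraction_cer: float
    fraction_sm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_cer <= 1.0 and 0.0 <= self.fraction_sm <= 1.0):
            raise ValidationError("mole fractions must lie in [0, 1]")
        if abs(self.fraction_cer + self.fraction_sm - 1.0) > 1e-12:
            raise ValidationError(
                f"mole fractions must sum to 1, got "
                f"{self.fraction_cer + self.fraction_sm!r}"
            )

    @classmethod
    def from_cer(cls, x_cer: float) -> "MixtureSpec":
        return cls(fraction_cer=x_cer, fraction_sm=1.0 - x_cer)


@dataclass
class Isotherm:
    """A surface pressure–molecular area (π–A) isotherm.

    ``pressure`` in mN/m and ``area`` in Å² per molecule, stored
    canonically: sorted by strictly decreasing area, with exact duplicate
    areas averaged. Compression/expansion hysteresis branches must be split
    by the caller before construction.
    """

    pressure: np.ndarray
    area: np.ndarray
    temperature: float = 298.15
    composition: Optional[MixtureSpec] = None
    label: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pi = np.asarray(self.pressure, dtype=float)
        a = np.asarray(self.area, dtype=float)
        if pi.ndim != 1 or a.ndim != 1 or pi.size != a.size:
            raise ValidationError("pressure and area must be equal-length 1-D series")
        if pi.size < 8:
            raise ValidationError(f"isotherm needs >= 8 points, got {pi.size}")
        if not np.all(np.isfinite(pi)) or not np.all(np.isfinite(a)):
            raise ValidationError("isotherm contains non-finite values")
        if np.any(a <= 0):
            raise ValidationError("molecular areas must be strictly positive")
        # canonicalize: decreasing area, duplicates averaged
        order = np.argsort(-a, kind="stable")
        a, pi = a[order], pi[order]
        uniq, inverse = np.unique(-a, return_inverse=True)
        if uniq.size != a.size:
            pi = np.bincount(inverse, weights=pi) / np.bincount(inverse)
            a = -uniq
        if a.size < 8:
            raise ValidationError("fewer than 8 distinct areas after averaging")
        self.pressure = pi
        self.area = a

    @property
    def pressure_range(self) -> tuple[float, float]:
        return float(self.pressure.min()), float(self.pressure.max())

    def __len__(self) -> int:
        return self.pressure.size


@dataclass
class ExcessAreaCurve:
    """Excess molecular area of a binary mixture on a common pressure grid.

    A_exc = A_mix − A_ideal, with A_ideal the mole-fraction-weighted sum of
    the pure-component areas at equal surface pressure. Negative values
    indicate attractive lipid–lipid interactions, positive repulsive, zero
    ideal mixing.
    """

    pressure_grid: np.ndarray
    a_exc: np.ndarray
    a_ideal: np.ndarray
    a_mix: np.ndarray
    spec: Optional[MixtureSpec] = None

    def __post_init__(self) -> None:
        g = np.asarray(self.pressure_grid, dtype=float)
        if np.any(np.diff(g) <= 0):
            raise ValidationError("pressure grid must be strictly increasing")
        for name in ("a_exc", "a_ideal", "a_mix"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != g.shape:
                raise ValidationError(f"{name} shape mismatch with pressure grid")
            setattr(self, name, arr)
        self.pressure_grid = g
        if not np.allclose(self.a_exc, self.a_mix - self.a_ideal, atol=1e-12, rtol=0):
            raise ValidationError("a_exc must equal a_mix - a_ideal elementwise")


@dataclass
class GibbsExcessResult:
    """Excess Gibbs energy ΔG_exc(π₀) = N_A ∫₀^π₀ A_exc dπ′ in J/mol."""

    upper_limits: np.ndarray
    delta_g_exc: np.ndarray
    quadrature_rule: str = "trapezoid"


@dataclass
class CompressibilityCurve:
    """Compressibility modulus Cs⁻¹(π) = −A_π (dπ/dA)_T in mN/m."""

    pressure_grid: np.ndarray
    cs_inv: np.ndarray
    derivative_estimate: np.ndarray
    smoothing_descriptor: str = ""


@dataclass
class StressProfile:
    """Diagonal stress-tensor components on a uniform grid along the normal.

    z in nm, components in bar (pressure-tensor sign convention, as MD
    engines report).
    """

    z: np.ndarray
    pxx: np.ndarray
    pyy: np.ndarray
    pzz: np.ndarray
    frame_count: int = 1

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 1 or z.size < 4:
            raise ValidationError("z grid must be a 1-D series with >= 4 points")
        dz = np.diff(z)
        if np.any(dz <= 0):
            raise ValidationError("z grid must be strictly increasing")
        if np.ptp(dz) > 1e-9 * abs(dz.mean()):
            raise ValidationError("z grid must be uniform (resampling required)")
        for name in ("pxx", "pyy", "pzz"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != z.shape:
                raise ValidationError(f"{name} length must match z")
            setattr(self, name, arr)
        self.z = z

    @property
    def spacing(self) -> float:
        return float(self.z[1] - self.z[0])


@dataclass
class LateralPressureProfile:
    """Lateral pressure profile LPP(z) = (Pxx + Pyy)/2 − Pzz, bar vs nm.

    ``midplane_shift`` records the translation applied during centring so
    the original coordinates remain recoverable
    (z_original = z − midplane_shift).
    """

    z: np.ndarray
    lpp: np.ndarray
    midplane_shift: float = 0.0

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        lpp = np.asarray(self.lpp, dtype=float)
        if z.shape != lpp.shape or z.ndim != 1:
            raise ValidationError("z and lpp must be equal-length 1-D series")
        self.z, self.lpp = z, lpp

    @property
    def spacing(self) -> float:
        return float(self.z[1] - self.z[0])


@dataclass(frozen=True)
class MembraneBounds:
    """Integration bounds [d₋, d₊] bracketing the membrane, nm.

    d₋ < 0 < d₊ is required: the profile must be midplane-centred before
    bounds are attached.
    """

    d_minus: float
    d_plus: float
    detection_rule: str = "explicit"

    def __post_init__(self) -> None:
        if not (self.d_minus < 0.0 < self.d_plus):
            raise ValidationError(
                f"bounds must straddle zero, got [{self.d_minus}, {self.d_plus}]"
            )


@dataclass(frozen=True)
class ElasticConstants:
    """Spontaneous bending moment and Gaussian modulus of a membrane.

    The bending moment is the product K_C·c₀ — the first z-moment of the
    lateral pressure profile — kept as a product throughout since neither
    factor is resolved separately here. Stored in native bar·nm^k units;
    pN and k_B·T views are derived properties.
    """

    bending_moment_bar_nm2: float
    gaussian_modulus_bar_nm3: float
    temperature: float = 303.15

    @property
    def bending_moment_pn(self) -> float:
        return self.bending_moment_bar_nm2 * BAR_NM2_TO_PN

    @property
    def gaussian_modulus_kbt(self) -> float:
        return bar_nm3_to_kbt(self.gaussian_modulus_bar_nm3, self.temperature)

    def as_dict(self) -> dict:
        return {
            "bending_moment_bar_nm2": self.bending_moment_bar_nm2,
            "bending_moment_pN": self.bending_moment_pn,
            "gaussian_modulus_bar_nm3": self.gaussian_modulus_bar_nm3,
            "gaussian_modulus_kBT": self.gaussian_modulus_kbt,
            "temperature_K": self.temperature,
        }


LEAFLETS = ("upper", "lower")


@dataclass
class LipidFrame:
    """One frame of lipid reference points (one point per lipid).

    ``positions`` N×3 in nm; x, y are wrapped into the periodic box
    [0, Lx) × [0, Ly) at construction. ``leaflet`` labels each point
    'upper' or 'lower'.
    """

    positions: np.ndarray
    leaflet: np.ndarray
    box: tuple[float, float]
    time: Optional[float] = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValidationError("positions must be an N x 3 array")
        lab = np.asarray(self.leaflet)
        if lab.shape != (pos.shape[0],):
            raise ValidationError("leaflet labels must match positions length")
        bad = set(np.unique(lab)) - set(LEAFLETS)
        if bad:
            raise ValidationError(f"unknown leaflet labels: {sorted(bad)}")
        lx, ly = float(self.box[0]), float(self.box[1])
        if lx <= 0 or ly <= 0:
            raise ValidationError("box dimensions must be positive")
        pos = pos.copy()
        pos[:, 0] %= lx
        pos[:, 1] %= ly
        self.positions = pos
        self.leaflet = lab
        self.box = (lx, ly)

    def points(self, leaflet: str) -> np.ndarray:
        """Positions of one leaflet (N_leaflet × 3 view copy)."""
        if leaflet not in LEAFLETS:
            raise ValidationError(f"leaflet must be one of {LEAFLETS}")
        return self.positions[self.leaflet == leaflet]

    def count(self, leaflet: str) -> int:
        return int(np.sum(self.leaflet == leaflet))


@dataclass
class SurfaceGrid:
    """A fitted periodic height field with per-node normals.

    Heights h(x_i, y_j) on an nx × ny node-centred grid over the periodic
    box; normals unit-length and oriented with non-negative z-component, so
    the tilt angle theta = arccos(n_z) lies in [0, π/2].
    """

    heights: np.ndarray
    normals: np.ndarray
    theta: np.ndarray
    box: tuple[float, float]
    bandwidth: float = 0.0
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2:
            raise ValidationError("heights must be a 2-D nx x ny array")
        n = np.asarray(self.normals, dtype=float)
        if n.shape != h.shape + (3,):
            raise ValidationError("normals must be nx x ny x 3")
        norms = np.linalg.norm(n, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValidationError("normals must be unit length")
        th = np.asarray(self.theta, dtype=float)
        if th.shape != h.shape:
            raise ValidationError("theta shape mismatch")
        if np.any(th < -1e-12) or np.any(th > np.pi / 2 + 1e-9):
            raise ValidationError("theta must lie in [0, pi/2] after orientation")
        self.heights, self.normals, self.theta = h, n, th
        self.box = (float(self.box[0]), float(self.box[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape


@dataclass
class CurvatureSummary:
    """Windowed summary of curvature descriptors over a trajectory.

    Means, medians and interquartile ranges of the curvature order
    parameter S_C (dimensionless), area per lipid A_L (Å²) and head-to-head
    thickness D_HH (nm), plus the per-frame series they summarise.
    """

    s_c_mean: float
    s_c_median: float
    s_c_iqr: float
    a_l_mean: float
    a_l_median: float
    a_l_iqr: float
    d_hh_mean: float
    d_hh_median: float
    d_hh_iqr: float
    per_frame: Optional[dict] = None

    def as_dict(self) -> dict:
        out = {
            "S_C": {"mean": self.s_c_mean, "median": self.s_c_median, "iqr": self.s_c_iqr},
            "A_L_A2": {"mean": self.a_l_mean, "median": self.a_l_median, "iqr": self.a_l_iqr},
            "D_HH_nm": {"mean": self.d_hh_mean, "median": self.d_hh_median, "iqr": self.d_hh_iqr},
        }
        if self.per_frame is not None:
            out["per_frame"] = {k: list(map(float, v)) for k, v in self.per_frame.items()}
        return out


def shift_profile(profile: LateralPressureProfile, shift: float) -> LateralPressureProfile:
    """Translate a profile along z by ``shift`` (z_new = z + shift).

    The accumulated shift is recorded so z_original = z − midplane_shift.
    """
    return replace(
        profile,
        z=profile.z + shift,
        midplane_shift=profile.midplane_shift + shift,
    )
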