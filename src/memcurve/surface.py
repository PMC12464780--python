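"""Membrane surface fitting and curvature descriptors.

Fits a periodic height field h(x, y) to one reference point per lipid
(Gaussian-kernel regression with minimum-image distances), derives node
normals by central differences, and computes the three descriptors used
to characterise simulated bilayers:

* curvature order parameter S_C = ⟨P₂(cos θ)⟩, where θ is the angle
  between each node normal and the z-axis — 1 for a planar bilayer,
  decreasing as the surface wrinkles or buds;
* area per lipid A_L, either projected (box area / N) or
  surface-corrected (triangulated grid area / N);
* head-to-head thickness D_HH, the mean height gap between the two
  fitted leaflet surfaces.

Grids are node-centred over the half-open periodic box [0, Lx) × [0, Ly);
normals are flipped to non-negative z before θ so leaflet orientation
never changes signs.
"""

from __future__ import annotations

import numpy as np

from .datatypes import CurvatureSummary, LipidFrame, SurfaceGrid
from .errors import ValidationError
from .units import NM2_TO_A2


def p2(x: np.ndarray | float) -> np.ndarray | float:
    """Second Legendre polynomial P₂(x) = (3x² − 1)/2."""
    return 0.5 * (3.0 * np.asarray(x) ** 2 - 1.0)


def mean_nn_spacing(points_xy: np.ndarray, box: tuple[float, float]) -> float:
    """Mean nearest-neighbour distance of the in-plane point pattern.

    Used to sanity-check the kernel bandwidth; computed with
    minimum-image wrapping.
    """
    n = points_xy.shape[0]
    if n < 2:
        raise ValidationError("need >= 2 points for spacing estimate")
    dx = points_xy[:, None, 0] - points_xy[None, :, 0]
    dy = points_xy[:, None, 1] - points_xy[None, :, 1]
    lx, ly = box
    dx -= lx * np.round(dx / lx)
    dy -= ly * np.round(dy / ly)
    d2 = dx**2 + dy**2
    np.fill_diagonal(d2, np.inf)
    return float(np.mean(np.sqrt(d2.min(axis=1))))


def default_bandwidth(points_xy: np.ndarray, box: tuple[float, float]) -> float:
    """Default kernel width: 1.5× the mean nearest-neighbour spacing."""
    return 1.5 * mean_nn_spacing(points_xy, box)


def _grid_axes(box: tuple[float, float], nx: int, ny: int):
    lx, ly = box
    return (
        np.arange(nx) * lx / nx,
        np.arange(ny) * ly / ny,
    )


def _normals_from_heights(h: np.ndarray, box: tuple[float, float]):
    """Unit normals and tilt angles from periodic central differences."""
    nx, ny = h.shape
    dx, dy = box[0] / nx, box[1] / ny
    hx = (np.roll(h, -1, axis=0) - np.roll(h, 1, axis=0)) / (2 * dx)
    hy = (np.roll(h, -1, axis=1) - np.roll(h, 1, axis=1)) / (2 * dy)
    normals = np.stack([-hx, -hy, np.ones_like(h)], axis=-1)
    normals /= np.linalg.norm(normals, axis=-1, keepdims=True)
    # construction already gives n_z > 0; clip guards rounding only
    theta = np.arccos(np.clip(normals[..., 2], -1.0, 1.0))
    return normals, theta


def fit_surface(
    frame: LipidFrame,
    leaflet: str,
    nx: int = 64,
    ny: int = 64,
    bandwidth: float | None = None,
) -> SurfaceGrid:
    """Fit a periodic height field to one leaflet's reference points.

    Nadaraya–Watson regression with a Gaussian kernel in wrapped (x, y)
    distance: h(node) = Σᵢ wᵢ zᵢ / Σᵢ wᵢ with
    wᵢ = exp(−d²ᵢ / 2·bandwidth²). Deterministic for fixed inputs. A
    bandwidth below the mean nearest-neighbour spacing is allowed but
    recorded as a warning on the returned grid.
    """
    if nx < 4 or ny < 4:
        raise ValidationError("grid resolution must be at least 4 x 4")
    pts = frame.points(leaflet)
    if pts.shape[0] == 0:
        raise ValidationError(f"leaflet {leaflet!r} is empty")
    if pts.shape[0] < 4:
        raise ValidationError("need >= 4 points per leaflet")
    if bandwidth is None:
        bandwidth = default_bandwidth(pts[:, :2], frame.box)
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be positive")
    warnings = []
    spacing = mean_nn_spacing(pts[:, :2], frame.box)
    if bandwidth < spacing:
        warnings.append(
            f"bandwidth {bandwidth:.3g} nm below mean nearest-neighbour "
            f"spacing {spacing:.3g} nm; fit may be noisy"
        )
    lx, ly = frame.box
    gx, gy = _grid_axes(frame.box, nx, ny)
    heights = np.empty((nx, ny))
    inv2b2 = 1.0 / (2.0 * bandwidth**2)
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    for i, xg in enumerate(gx):  # row-chunked to bound memory at O(N·ny)
        dx = x[None, :] - xg
        dx -= lx * np.round(dx / lx)
        dy = y[None, :] - gy[:, None]
        dy -= ly * np.round(dy / ly)
        d2 = dx**2 + dy**2
        w = np.exp(-d2 * inv2b2)
        wsum = w.sum(axis=1)
        heights[i, :] = np.divide(
            w @ z, wsum, out=np.zeros(ny), where=wsum > 0
        )
        # kernels far narrower than the point spacing can underflow to
        # zero weight; fall back to the nearest point's height there
        dead = wsum <= 0
        if dead.any():
            heights[i, dead] = z[np.argmin(d2[dead, :], axis=1)]
    normals, theta = _normals_from_heights(heights, frame.box)
    return SurfaceGrid(
        heights=heights,
        normals=normals,
        theta=theta,
        box=frame.box,
        bandwidth=float(bandwidth),
        warnings=warnings,
    )


def curvature_order_parameter(grid: SurfaceGrid) -> float:
    """S_C = ⟨P₂(cos θ)⟩ over grid elements.

    The average weights every node by its (equal) projected grid-element
    area. S_C = 1 iff every normal is parallel to z (planar bilayer);
    deviations below 1 indicate curvature, down to −1/2 for normals lying
    in the membrane plane.
    """
    return float(np.mean(p2(np.cos(grid.theta))))


def surface_area(grid: SurfaceGrid) -> float:
    """Triangulated area of the periodic height field, nm².

    Each grid cell (with periodic closure) is split into two triangles;
    the sum is never below the projected box area.
    """
    h = grid.heights
    nx, ny = h.shape
    dx, dy = grid.box[0] / nx, grid.box[1] / ny
    h10 = np.roll(h, -1, axis=0)
    h01 = np.roll(h, -1, axis=1)
    h11 = np.roll(h10, -1, axis=1)
    # triangle (00,10,01) and (10,11,01) per cell
    a1 = np.cross(
        np.stack([np.full_like(h, dx), np.zeros_like(h), h10 - h], axis=-1),
        np.stack([np.zeros_like(h), np.full_like(h, dy), h01 - h], axis=-1),
    )
    a2 = np.cross(
        np.stack([-np.full_like(h, dx), np.zeros_like(h), h01 - h11], axis=-1),
        np.stack([np.zeros_like(h), -np.full_like(h, dy), h10 - h11], axis=-1),
    )
    area = 0.5 * (np.linalg.norm(a1, axis=-1) + np.linalg.norm(a2, axis=-1))
    return float(area.sum())


def area_per_lipid(
    grid: SurfaceGrid, n_lipids: int, mode: str = "projected"
) -> float:
    """Area per lipid A_L in Å².

    ``"projected"``: Lx·Ly / N. ``"surface"``: triangulated fitted-grid
    area / N, which corrects for undulations and always meets or exceeds
    the projected value.
    """
    if n_lipids <= 0:
        raise ValidationError("n_lipids must be positive")
    if mode == "projected":
        area_nm2 = grid.box[0] * grid.box[1]
    elif mode == "surface":
        area_nm2 = surface_area(grid)
    else:
        raise ValidationError(f"unknown area mode {mode!r}")
    return float(area_nm2 / n_lipids * NM2_TO_A2)


def membrane_thickness(upper: SurfaceGrid, lower: SurfaceGrid) -> dict:
    """Head-to-head thickness D_HH: grid mean of (h_upper − h_lower), nm.

    Nodes where the leaflet surfaces cross (negative gap) are counted and
    reported, not silently dropped.
    """
    if upper.shape != lower.shape or upper.box != lower.box:
        raise ValidationError("leaflet grids must share resolution and box")
    gap = upper.heights - lower.heights
    return {
        "d_hh_nm": float(gap.mean()),
        "negative_nodes": int(np.sum(gap < 0)),
        "gap": gap,
    }


def analyze_frame(
    frame: LipidFrame,
    nx: int = 64,
    ny: int = 64,
    bandwidth: float | None = None,
    area_mode: str = "projected",
) -> dict:
    """S_C, A_L and D_HH of a single frame.

    Both leaflets are fitted; S_C is the mean of the two per-leaflet
    values and A_L the mean of the two per-leaflet areas (leaflet lipid
    counts may differ in asymmetric membranes).
    """
    upper = fit_surface(frame, "upper", nx, ny, bandwidth)
    lower = fit_surface(frame, "lower", nx, ny, bandwidth)
    s_c = 0.5 * (
        curvature_order_parameter(upper) + curvature_order_parameter(lower)
    )
    a_l = 0.5 * (
        area_per_lipid(upper, frame.count("upper"), area_mode)
        + area_per_lipid(lower, frame.count("lower"), area_mode)
    )
    thick = membrane_thickness(upper, lower)
    return {
        "S_C": s_c,
        "A_L_A2": a_l,
        "D_HH_nm": thick["d_hh_nm"],
        "negative_nodes": thick["negative_nodes"],
        "upper": upper,
        "lower": lower,
    }


def _iqr(values: np.ndarray) -> float:
    q75, q25 = np.percentile(values, [75, 25])
    return float(q75 - q25)


def trajectory_summary(
    frames,
    nx: int = 64,
    ny: int = 64,
    bandwidth: float | None = None,
    area_mode: str = "projected",
    window: slice | None = None,
) -> CurvatureSummary:
    """Per-frame descriptors plus windowed mean/median/IQR.

    ``window`` selects the frames entering the summary statistics (e.g.
    the equilibrated tail of a trajectory); the per-frame series always
    covers every input frame.
    """
    frames = list(frames)
    if not frames:
        raise ValidationError("need at least one frame")
    s_c, a_l, d_hh = [], [], []
    for frame in frames:
        res = analyze_frame(frame, nx, ny, bandwidth, area_mode)
        s_c.append(res["S_C"])
        a_l.append(res["A_L_A2"])
        d_hh.append(res["D_HH_nm"])
    s_c, a_l, d_hh = map(np.asarray, (s_c, a_l, d_hh))
    sel = window if window is not None else slice(None)
    s_w, a_w, d_w = s_c[sel], a_l[sel], d_hh[sel]
    if s_w.size == 0:
        raise ValidationError("selected window contains no frames")
    return CurvatureSummary(
        s_c_mean=float(s_w.mean()),
        s_c_median=float(np.median(s_w)),
        s_c_iqr=_iqr(s_w),
        a_l_mean=float(a_w.mean()),
        a_l_median=float(np.median(a_w)),
        a_l_iqr=_iqr(a_w),
        d_hh_mean=float(d_w.mean()),
        d_hh_median=float(np.median(d_w)),
        d_hh_iqr=_iqr(d_w),
        per_frame={"S_C": s_c, "A_L_A2": a_l, "D_HH_nm": d_hh},
    )
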