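"""Lesion contour extraction by radial gradient analysis (stage 2).

From the candidate center found in stage 1, rays are cast every 0.5 degrees
(720 rays).  Along each ray the brightness gradient is measured with a
sliding window

    dP_i = sum_{j=1..S} P_{i+j} - sum_{j=1..S} P_{i-j},

and the sample with the largest positive gradient — the strongest
dark-to-bright transition, since lesions are hypoechoic — marks the
approximate boundary on that ray.  The resulting polar boundary
(angle, radius) is smoothed by least-squares cubic regression over sliding
angular windows (window M points, stride W, the first M0 points wrapped to
the end so the contour closes), and points deviating from the smoothed curve
by more than the Niblack threshold B = mean + k*std are replaced by
circular linear interpolation between their surviving neighbors.

Geometry conventions: (x, y) = (column, row), 0-based, y increases
downward; ray angles grow counterclockwise on screen from the +x axis, so a
ray at angle a passes through (x + r*cos a, y - r*sin a).  Rays sample at
unit radial steps with bilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw

from .errors import (
    EmptyContourError,
    InvalidInputError,
    InvalidParameterError,
    RayTooShortError,
)

DEFAULT_STEP_DEG: float = 0.5       # -> T = 720 rays
DEFAULT_GRADIENT_WINDOW: int = 5    # S, samples on either side


@dataclass
class RayProfile:
    """Unit-step intensity samples along one ray from the lesion center."""

    angle_deg: float
    intensities: np.ndarray  # P_i at radii 0, 1, ..., len-1

    @property
    def n_samples(self) -> int:
        return len(self.intensities)


@dataclass
class PolarContour:
    """A closed boundary as one radius per ray around a fixed center."""

    center: tuple[float, float]      # (x_A, y_A)
    angles_deg: np.ndarray           # strictly increasing, [0, 360)
    radii: np.ndarray                # r_j > 0
    smoothed: np.ndarray | None = None   # regression radii, same length
    interpolated: np.ndarray | None = None  # bool mask of filled/replaced points

    @property
    def n_rays(self) -> int:
        return len(self.angles_deg)

    def to_cartesian(self, radii: np.ndarray | None = None) -> np.ndarray:
        """Contour vertices as an (T, 2) array of (x, y) pixels."""
        r = self.radii if radii is None else radii
        a = np.deg2rad(self.angles_deg)
        cx, cy = self.center
        return np.column_stack([cx + r * np.cos(a), cy - r * np.sin(a)])


@dataclass
class ContourConfig:
    """Tunable parameters of the contour stage (defaults as published)."""

    step_deg: float = DEFAULT_STEP_DEG
    gradient_window: int = DEFAULT_GRADIENT_WINDOW  # S
    regression_window: int = 180                    # M
    window_stride: int = 10                         # W
    closure_pad: int = 180                          # M0
    niblack_k: float = 0.2                          # k
    max_radius: float | None = None


def _border_distance(center, shape, dx, dy) -> float:
    """Largest t with (x + t*dx, y + t*dy) inside [0, m-1] x [0, n-1]."""
    n, m = shape
    x, y = center
    t = np.inf
    for pos, d, hi in ((x, dx, m - 1), (y, dy, n - 1)):
        if d > 1e-12:
            t = min(t, (hi - pos) / d)
        elif d < -1e-12:
            t = min(t, (0 - pos) / d)
    return max(t, 0.0)


def cast_rays(frame: np.ndarray, center, *, step_deg: float = DEFAULT_STEP_DEG,
              max_radius: float | None = None) -> list[RayProfile]:
    """Cast 360/step rays from *center*, sampled at unit radial steps.

    Each ray stops at ``max_radius`` or the frame border, whichever comes
    first; off-grid samples are bilinearly interpolated.
    """
    frame = np.asarray(frame, dtype=np.float64)
    n, m = frame.shape
    x, y = float(center[0]), float(center[1])
    if not (0 <= x <= m - 1 and 0 <= y <= n - 1):
        raise InvalidInputError(f"center {center} lies outside the frame")
    n_rays = 360.0 / step_deg
    if abs(n_rays - round(n_rays)) > 1e-9:
        raise InvalidParameterError(f"step {step_deg} does not divide 360 evenly")
    n_rays = int(round(n_rays))
    angles = np.arange(n_rays) * step_deg
    rad = np.deg2rad(angles)
    dxs, dys = np.cos(rad), -np.sin(rad)

    lengths, coord_rows, coord_cols = [], [], []
    for dx, dy in zip(dxs, dys):
        r_max = _border_distance((x, y), (n, m), dx, dy)
        if max_radius is not None:
            r_max = min(r_max, float(max_radius))
        radii = np.arange(int(np.floor(r_max)) + 1, dtype=np.float64)
        lengths.append(len(radii))
        coord_rows.append(y + radii * dy)
        coord_cols.append(x + radii * dx)
    values = ndimage.map_coordinates(
        frame, [np.concatenate(coord_rows), np.concatenate(coord_cols)],
        order=1, mode="nearest")
    splits = np.cumsum(lengths)[:-1]
    return [RayProfile(angle_deg=float(a), intensities=v)
            for a, v in zip(angles, np.split(values, splits))]


def ray_gradient(intensities: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window brightness gradient along one ray.

    For samples ``P_0 .. P_{L-1}`` and window ``S``, returns
    ``(indices, values)`` with ``indices = S .. L-1-S`` and
    ``values[i] = sum(P[i+1..i+S]) - sum(P[i-S..i-1])``.
    """
    p = np.asarray(intensities, dtype=np.float64)
    s = int(window)
    if s < 1:
        raise InvalidParameterError("gradient window must be >= 1")
    if len(p) < 2 * s + 1:
        raise RayTooShortError(
            f"ray with {len(p)} samples is too short for window {s}")
    kernel = np.concatenate([-np.ones(s), [0.0], np.ones(s)])
    values = np.correlate(p, kernel, mode="valid")
    indices = np.arange(s, len(p) - s)
    return indices, values


def boundary_from_gradients(rays: list[RayProfile], *,
                            window: int = DEFAULT_GRADIENT_WINDOW,
                            center=(0.0, 0.0)) -> PolarContour:
    """Pick the strongest dark-to-bright transition on every ray.

    The boundary radius on a ray is the sample index attaining the global
    maximum of the signed gradient; ties resolve toward the center.  Rays
    that are too short or show no positive gradient are flagged and their
    radii filled by circular linear interpolation from neighboring rays.
    Raises :class:`EmptyContourError` if every ray is flagged.
    """
    n_rays = len(rays)
    angles = np.array([r.angle_deg for r in rays])
    radii = np.full(n_rays, np.nan)
    for j, ray in enumerate(rays):
        s = min(window, (ray.n_samples - 1) // 2)
        if s < 1:
            continue
        idx, grad = ray_gradient(ray.intensities, s)
        best = int(np.argmax(grad))  # first occurrence = smallest radius
        if grad[best] > 1e-6:  # tolerance absorbs interpolation round-off
            radii[j] = idx[best]
    flagged = np.isnan(radii)
    if flagged.all():
        raise EmptyContourError("no ray shows a positive brightness gradient")
    if flagged.any():
        good = ~flagged
        radii[flagged] = np.interp(angles[flagged], angles[good], radii[good],
                                   period=360.0)
    return PolarContour(center=(float(center[0]), float(center[1])),
                        angles_deg=angles, radii=radii,
                        interpolated=flagged)


def fit_cubic(phi: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Least-squares cubic fit; returns ``(a0, a1, a2, a3)``."""
    coeffs = np.polynomial.polynomial.polyfit(phi, r, 3)
    return coeffs


def sliding_cubic_regression(contour: PolarContour, *,
                             regression_window: int = 180,
                             window_stride: int = 10,
                             closure_pad: int = 180,
                             return_counts: bool = False):
    """Smooth the polar boundary with averaged sliding cubic fits.

    The radius array is extended by wrapping its first ``closure_pad``
    points (their angles shifted by 360 deg) so fits near 360 deg see the
    closure.  A cubic is fitted on every window of ``regression_window``
    points advanced by ``window_stride``; each point's smoothed radius is
    the mean of the predictions of all windows covering it, with wrapped
    copies folded back onto their source index.  Window abscissae are
    shifted to start at zero (radians) to condition the fit; predictions
    are invariant to that shift.
    """
    t = contour.n_rays
    m = int(regression_window)
    w = int(window_stride)
    m0 = int(closure_pad)
    if m > t:
        raise InvalidParameterError(f"regression window {m} exceeds {t} points")
    if w < 1 or m0 < 0:
        raise InvalidParameterError("stride must be >= 1 and closure pad >= 0")
    phi = np.deg2rad(contour.angles_deg)
    phi_ext = np.concatenate([phi, phi[:m0] + 2 * np.pi])
    r_ext = np.concatenate([contour.radii, contour.radii[:m0]])
    t_ext = t + m0

    starts = list(range(0, t_ext - m + 1, w))
    if starts[-1] != t_ext - m:  # cover the tail so no point is left out
        starts.append(t_ext - m)
    sums = np.zeros(t_ext)
    counts = np.zeros(t_ext, dtype=np.int64)
    for s0 in starts:
        sl = slice(s0, s0 + m)
        x = phi_ext[sl] - phi_ext[s0]
        coeffs = fit_cubic(x, r_ext[sl])
        sums[sl] += np.polynomial.polynomial.polyval(x, coeffs)
        counts[sl] += 1

    folded_sums = sums[:t].copy()
    folded_counts = counts[:t].copy()
    folded_sums[:m0] += sums[t:]
    folded_counts[:m0] += counts[t:]
    smoothed = folded_sums / folded_counts
    if return_counts:
        return smoothed, counts, folded_counts
    return smoothed


def niblack_correct(contour: PolarContour, smoothed: np.ndarray, *,
                    k: float = 0.2) -> PolarContour:
    """Replace boundary points far from the regression curve.

    Deviations ``dr_j = |smoothed_j - r_j|`` are thresholded at the Niblack
    value ``B = mean(dr) + k * std(dr)`` (population standard deviation,
    computed globally over all rays).  Points with ``dr_j > B`` keep their
    angle but get a radius linearly interpolated (circularly in angle)
    between the nearest surviving points.
    """
    r = np.asarray(contour.radii, dtype=np.float64)
    rbar = np.asarray(smoothed, dtype=np.float64)
    if r.shape != rbar.shape:
        raise InvalidInputError("radii and smoothed radii differ in length")
    dr = np.abs(rbar - r)
    threshold = dr.mean() + k * dr.std()
    outlier = dr > threshold
    corrected = r.copy()
    if outlier.any():
        if outlier.all():  # unreachable for k >= 0; guard division below
            raise EmptyContourError("every boundary point flagged as outlier")
        good = ~outlier
        corrected[outlier] = np.interp(
            contour.angles_deg[outlier], contour.angles_deg[good], r[good],
            period=360.0)
    return PolarContour(center=contour.center, angles_deg=contour.angles_deg,
                        radii=corrected, smoothed=rbar, interpolated=outlier)


def rasterize_contour(contour_xy: np.ndarray, shape) -> np.ndarray:
    """Fill a closed (x, y) polygon into a boolean mask of *shape*."""
    rows, cols = draw.polygon(contour_xy[:, 1], contour_xy[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rows, cols] = True
    return mask


def segment_lesion(frame: np.ndarray, center, config: ContourConfig | None = None):
    """Full stage-2 contour extraction around a candidate center.

    Pipeline: cast rays -> per-ray gradient maxima -> sliding cubic
    regression -> Niblack outlier replacement.  Returns
    ``(contour_xy, mask, polar)``: a closed (T, 2) Cartesian polygon, its
    filled boolean mask, and the corrected :class:`PolarContour`.
    """
    cfg = config or ContourConfig()
    rays = cast_rays(frame, center, step_deg=cfg.step_deg,
                     max_radius=cfg.max_radius)
    polar = boundary_from_gradients(rays, window=cfg.gradient_window,
                                    center=center)
    smoothed = sliding_cubic_regression(
        polar, regression_window=cfg.regression_window,
        window_stride=cfg.window_stride, closure_pad=cfg.closure_pad)
    corrected = niblack_correct(polar, smoothed, k=cfg.niblack_k)
    contour_xy = corrected.to_cartesian()
    mask = rasterize_contour(contour_xy, frame.shape)
    return contour_xy, mask, corrected
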