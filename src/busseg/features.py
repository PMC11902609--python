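"""Per-pixel features for normal-tissue classification.

Each pixel of an 8-bit grayscale ultrasound frame is described by the two
eigenvalues of the Gaussian-smoothed Hessian matrix computed at several
scales, plus a local binary pattern (LBP) texture code.  With the default
schedule of 8 scales this yields a 17-dimensional feature vector per pixel:
``lambda1(s1), lambda2(s1), ..., lambda1(s8), lambda2(s8), LBP``.

Conventions
-----------
* Frames are 2-D arrays, row 0 is the transducer (skin) side.
* Intensities are promoted to float64 before any filtering; LBP works on
  the raw 8-bit values.
* Smoothing and derivative filters use reflect padding; callers asserting
  analytic values should restrict themselves to interior pixels.
* Hessian eigenvalues are ordered algebraically, ``lambda1 >= lambda2``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, InvalidParameterError

#: Doubling scale schedule 1, 2, 4, ... capped at 128 (8 scales -> 16
#: eigenvalue features + 1 LBP code = 17 features).
DEFAULT_SIGMAS: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)

#: LBP neighbor offsets (drow, dcol), clockwise from the top-left neighbor.
#: Bit p carries weight 2**p.
LBP_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


def validate_frame(frame: np.ndarray) -> np.ndarray:
    """Check that *frame* is a valid 8-bit grayscale image array.

    Returns the frame unchanged (no copy).  Raises
    :class:`InvalidInputError` for wrong dimensionality, a frame smaller
    than 3x3, or intensities outside [0, 255].
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise InvalidInputError(f"frame must be 2-D, got shape {frame.shape}")
    if frame.shape[0] < 3 or frame.shape[1] < 3:
        raise InvalidInputError(f"frame must be at least 3x3, got {frame.shape}")
    if frame.size and (frame.min() < 0 or frame.max() > 255):
        raise InvalidInputError("frame intensities must lie in [0, 255]")
    return frame


def validate_schedule(sigmas) -> tuple[float, ...]:
    """Validate a scale schedule: strictly increasing positive sigmas <= 128."""
    sigmas = tuple(float(s) for s in sigmas)
    if not sigmas:
        raise InvalidParameterError("scale schedule must not be empty")
    if any(s <= 0 for s in sigmas):
        raise InvalidParameterError("all sigmas must be positive")
    if any(b <= a for a, b in zip(sigmas, sigmas[1:])):
        raise InvalidParameterError("sigmas must be strictly increasing")
    if sigmas[-1] > 128:
        raise InvalidParameterError("sigmas must not exceed 128")
    return sigmas


def gaussian_smooth(frame: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with a normalized kernel (reflect borders)."""
    if sigma <= 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    frame = validate_frame(frame)
    return ndimage.gaussian_filter(frame.astype(np.float64), sigma, mode="reflect")


def hessian_eigenvalues(frame: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues of the per-pixel Hessian of the sigma-smoothed frame.

    The Hessian entries are second-order central finite differences of the
    smoothed image.  Returns ``(lambda1, lambda2)`` with
    ``lambda1 >= lambda2`` everywhere; their sum and product equal the
    Hessian trace and determinant by construction.
    """
    smoothed = gaussian_smooth(frame, sigma)
    hxx, hyy, hxy = hessian_entries(smoothed)
    mean = 0.5 * (hxx + hyy)
    half_diff = 0.5 * (hxx - hyy)
    root = np.sqrt(half_diff * half_diff + hxy * hxy)
    return mean + root, mean - root


def hessian_entries(smoothed: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Second-order central-difference Hessian entries (hxx, hyy, hxy).

    x is the column axis, y the row axis; reflect borders.
    """
    second = np.array([1.0, -2.0, 1.0])
    first = np.array([0.5, 0.0, -0.5])
    hxx = ndimage.correlate1d(smoothed, second, axis=1, mode="reflect")
    hyy = ndimage.correlate1d(smoothed, second, axis=0, mode="reflect")
    hxy = ndimage.correlate1d(
        ndimage.correlate1d(smoothed, first, axis=0, mode="reflect"),
        first, axis=1, mode="reflect",
    )
    return hxx, hyy, hxy


def lbp_codes(frame: np.ndarray) -> np.ndarray:
    """8-neighbor local binary pattern codes in [0, 255].

    Bit ``p`` (weight ``2**p``) is set iff ``neighbor - center >= 0``; the
    neighbor order runs clockwise from the top-left (see
    :data:`LBP_OFFSETS`).  The frame is replicate-padded so border pixels
    receive a code too.  Works on raw integer intensities.
    """
    frame = validate_frame(frame)
    center = frame.astype(np.int16)
    padded = np.pad(center, 1, mode="edge")
    codes = np.zeros(frame.shape, dtype=np.uint8)
    n, m = frame.shape
    for p, (dr, dc) in enumerate(LBP_OFFSETS):
        neighbor = padded[1 + dr:1 + dr + n, 1 + dc:1 + dc + m]
        codes |= ((neighbor - center) >= 0).astype(np.uint8) << p
    return codes


def feature_stack(frame: np.ndarray, sigmas=DEFAULT_SIGMAS) -> np.ndarray:
    """Full per-pixel feature stack.

    Returns an array of shape ``(n, m, 2*K + 1)`` where ``K = len(sigmas)``.
    Component order is fixed:
    ``lambda1(s1), lambda2(s1), ..., lambda1(sK), lambda2(sK), LBP``.
    """
    frame = validate_frame(frame)
    sigmas = validate_schedule(sigmas)
    layers = []
    for sigma in sigmas:
        lam1, lam2 = hessian_eigenvalues(frame, sigma)
        layers.append(lam1)
        layers.append(lam2)
    layers.append(lbp_codes(frame).astype(np.float64))
    return np.stack(layers, axis=-1)
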