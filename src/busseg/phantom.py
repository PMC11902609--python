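"""Synthetic breast-ultrasound phantoms with known ground truth.

A phantom emulates the layered anatomy of a linear-array breast scan:
a bright skin line, hypoechoic subcutaneous fat, thin echogenic fibrous
bands, glandular parenchyma, deeper fibrous tissue, and a dark far-field
artifact zone with vertical reverberation streaks.  Layer thicknesses vary
from frame to frame (patients differ), layer interfaces undulate gently,
and elliptical islands of other tissues are scattered through the depth so
that tissue class cannot be read off the row index alone.  Each tissue
carries its own multiplicative speckle texture (a Rayleigh field smoothed
by a small Gaussian; fibrous textures are smoothed anisotropically into
streaks).

The optional lesion is a star-convex, strongly hypoechoic, nearly anechoic
region whose radius is modulated by low-order Fourier harmonics — a stylized
malignant mass: markedly darker than every normal tissue, almost free of
internal echoes, with a sharp boundary.  An optional posterior acoustic
shadow attenuates the columns below it.

This is a texture phantom, not an acoustic simulation: there is no wave
propagation or point-spread modeling, only the intensity statistics the
segmentation pipeline relies on.  The default 256x256 frame keeps the
lesion-to-frame and sigma-to-frame proportions of a clinical scan while
staying cheap to process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .classify import DEFAULT_CLASSES
from .errors import InvalidSpecError

IGNORE_LABEL: int = -1  # lesion pixels in a lesioned phantom's tissue map


@dataclass(frozen=True)
class LayerSpec:
    """One horizontal tissue band."""

    name: str
    mean_intensity: float     # 0-255 before speckle
    thickness: float          # mean fraction of frame height
    speckle_strength: float   # 0 = smooth .. ~0.8 = strongly textured
    grain: tuple[float, float] = (1.0, 1.0)  # speckle smoothing (row, col) sigmas


#: Default layer stack, top (transducer) to bottom.  Names index into
#: :data:`busseg.classify.DEFAULT_CLASSES`.
DEFAULT_LAYERS: tuple[LayerSpec, ...] = (
    LayerSpec("skin", 190.0, 0.06, 0.25, (1.0, 2.0)),
    LayerSpec("fat", 80.0, 0.22, 0.45, (1.2, 1.2)),
    LayerSpec("fibrous bands", 200.0, 0.06, 0.35, (0.8, 4.0)),
    LayerSpec("glandular tissue", 130.0, 0.34, 0.50, (1.0, 1.0)),
    LayerSpec("fibrous tissue", 170.0, 0.16, 0.40, (0.8, 5.0)),
    LayerSpec("artifacts", 45.0, 0.16, 0.50, (4.0, 0.8)),  # vertical streaks
)


@dataclass(frozen=True)
class InclusionSpec:
    """Elliptical islands of one tissue inside another (anatomic mixing)."""

    count_range: tuple[int, int] = (10, 16)
    half_axis_range: tuple[float, float] = (4.0, 12.0)
    depth_range: tuple[float, float] = (0.15, 0.95)  # fraction of height
    classes: tuple[str, ...] = ("fat", "fibrous tissue", "fibrous bands",
                                "glandular tissue", "artifacts")


@dataclass(frozen=True)
class LesionSpec:
    """A star-convex, nearly anechoic lesion."""

    present: bool = True
    center: tuple[float, float] | None = None  # (x, y); default mid-glandular
    mean_radius: float = 30.0
    irregularity: float = 0.12        # relative radius modulation amplitude
    harmonics: tuple[int, ...] = (3,)
    contrast: float = -114.0          # intensity offset vs surroundings (< 0)
    speckle_strength: float = 0.04    # faint internal echoes
    grain: tuple[float, float] = (1.8, 1.8)


@dataclass(frozen=True)
class ShadowSpec:
    """Posterior acoustic shadow: attenuated column band below the lesion."""

    present: bool = False
    attenuation: float = 0.35  # multiplicative factor in the shadow
    width_factor: float = 1.2  # shadow half-width = factor * lesion radius


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to render one phantom frame deterministically."""

    height: int = 256
    width: int = 256
    layers: tuple[LayerSpec, ...] = DEFAULT_LAYERS
    inclusions: InclusionSpec = field(default_factory=InclusionSpec)
    lesion: LesionSpec = field(default_factory=LesionSpec)
    shadow: ShadowSpec = field(default_factory=ShadowSpec)
    thickness_jitter: float = 0.3  # relative per-frame layer thickness spread
    boundary_wobble: float = 2.0   # px amplitude of layer-interface undulation
    seed: int = 0

    def without_lesion(self) -> "PhantomSpec":
        return replace(self, lesion=replace(self.lesion, present=False))


@dataclass
class PhantomSample:
    """A rendered phantom with its full ground truth."""

    frame: np.ndarray            # uint8 (height, width)
    tissue_labels: np.ndarray    # int map, class indices; IGNORE_LABEL on lesion
    lesion_mask: np.ndarray      # bool
    true_center: tuple[float, float] | None   # (x, y)
    true_contour: np.ndarray | None           # (720, 2) polygon, (x, y)
    true_radius: np.ndarray | None            # radius at 0.5-degree steps


def class_index(name: str, class_list=DEFAULT_CLASSES) -> int:
    return class_list.index(name)


def _radius_function(spec: LesionSpec, rng) -> np.ndarray:
    """Star-convex boundary radius at 720 angles (0.5 deg steps)."""
    theta = np.deg2rad(np.arange(720) * 0.5)
    if spec.irregularity <= 0 or not spec.harmonics:
        return np.full(720, spec.mean_radius)
    amps = rng.uniform(0.4, 1.0, len(spec.harmonics))
    amps *= spec.irregularity / amps.sum()
    phases = rng.uniform(0, 2 * np.pi, len(spec.harmonics))
    mod = np.zeros(720)
    for k, a, p in zip(spec.harmonics, amps, phases):
        mod += a * np.cos(k * theta + p)
    return spec.mean_radius * (1.0 + mod)


def _speckle_field(shape, strength, grain, rng) -> np.ndarray:
    """Unit-mean multiplicative speckle: smoothed Rayleigh noise."""
    if strength <= 0:
        return np.ones(shape)
    raw = rng.rayleigh(scale=1.0, size=shape)
    smooth = ndimage.gaussian_filter(raw, grain, mode="reflect")
    smooth /= smooth.mean()
    return (1.0 - strength) + strength * smooth


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom frame with labels, lesion mask and true contour.

    Deterministic given ``spec.seed``.  Raises
    :class:`InvalidSpecError` when the layer stack or lesion geometry is
    inconsistent with the frame.
    """
    n, m = spec.height, spec.width
    if abs(sum(l.thickness for l in spec.layers) - 1.0) > 1e-6:
        raise InvalidSpecError("layer thickness fractions must sum to 1")
    rng = np.random.default_rng(spec.seed)

    # per-frame layer thicknesses (anatomy varies between patients)
    fractions = np.array([l.thickness for l in spec.layers])
    if spec.thickness_jitter > 0:
        fractions = fractions * rng.uniform(1 - spec.thickness_jitter,
                                            1 + spec.thickness_jitter,
                                            len(fractions))
        fractions /= fractions.sum()

    # band interfaces with gentle sinusoidal undulation per column
    cols = np.arange(m)
    edges = np.zeros((len(spec.layers) + 1, m))
    cum = 0.0
    for i, frac in enumerate(fractions[:-1]):
        cum += frac
        phase = rng.uniform(0, 2 * np.pi)
        period = rng.uniform(0.6, 1.4) * m
        edges[i + 1] = cum * n + spec.boundary_wobble * np.sin(
            2 * np.pi * cols / period + phase)
    edges[-1] = n

    rows = np.arange(n)[:, None]
    labels = np.zeros((n, m), dtype=np.int64)
    for i, layer in enumerate(spec.layers):
        band = (rows >= edges[i][None, :]) & (rows < edges[i + 1][None, :])
        labels[band] = class_index(layer.name)

    # elliptical tissue islands at arbitrary depths
    yy, xx = np.mgrid[0:n, 0:m]
    inc = spec.inclusions
    for _ in range(int(rng.integers(inc.count_range[0], inc.count_range[1] + 1))):
        c = class_index(inc.classes[int(rng.integers(len(inc.classes)))])
        cy = rng.uniform(inc.depth_range[0] * n, inc.depth_range[1] * n)
        cx = rng.uniform(0, m)
        a = rng.uniform(*inc.half_axis_range)
        b = a * rng.uniform(0.3, 1.0)
        th = rng.uniform(0, np.pi)
        u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        labels[(u / a) ** 2 + (v / b) ** 2 <= 1] = c

    intensity_of = {class_index(l.name): l.mean_intensity for l in spec.layers}
    base = np.vectorize(intensity_of.get)(labels).astype(np.float64)

    # lesion geometry
    lesion_mask = np.zeros((n, m), dtype=bool)
    true_center = true_contour = true_radius = None
    if spec.lesion.present:
        les = spec.lesion
        cx, cy = les.center if les.center is not None else (m / 2.0, 0.51 * n)
        true_radius = _radius_function(les, rng)
        r_max = true_radius.max()
        if not (r_max <= cx <= m - 1 - r_max and r_max <= cy <= n - 1 - r_max):
            raise InvalidSpecError("lesion does not fit inside the frame")
        dx, dy = xx - cx, -(yy - cy)  # y axis up for angles
        theta = np.rad2deg(np.arctan2(dy, dx)) % 360.0
        rr = np.hypot(dx, dy)
        r_at = np.interp(theta.ravel(), np.arange(720) * 0.5, true_radius,
                         period=360.0).reshape(n, m)
        lesion_mask = rr <= r_at
        surround = base[lesion_mask].mean()
        base[lesion_mask] = np.clip(surround + les.contrast, 5.0, 255.0)
        true_center = (float(cx), float(cy))
        angles = np.deg2rad(np.arange(720) * 0.5)
        true_contour = np.column_stack([
            cx + true_radius * np.cos(angles),
            cy - true_radius * np.sin(angles),
        ])

    # per-class speckle texture, plus faint echoes inside the lesion
    frame = base.copy()
    for layer in spec.layers:
        region = (labels == class_index(layer.name)) & ~lesion_mask
        if region.any():
            fieldv = _speckle_field((n, m), layer.speckle_strength,
                                    layer.grain, rng)
            frame[region] = base[region] * fieldv[region]
    if spec.lesion.present:
        fieldv = _speckle_field((n, m), spec.lesion.speckle_strength,
                                spec.lesion.grain, rng)
        frame[lesion_mask] = base[lesion_mask] * fieldv[lesion_mask]
        labels = labels.copy()
        labels[lesion_mask] = IGNORE_LABEL

    # posterior acoustic shadow
    if spec.shadow.present and spec.lesion.present:
        cx, cy = true_center
        half_w = spec.shadow.width_factor * spec.lesion.mean_radius
        col_sel = np.abs(np.arange(m) - cx) <= half_w
        bottom = int(np.ceil(cy + true_radius.max()))
        shade = np.ones((n, m))
        shade[bottom:, col_sel] = spec.shadow.attenuation
        shade = ndimage.gaussian_filter(shade, 2.0, mode="nearest")
        frame *= shade

    frame = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
    return PhantomSample(frame=frame, tissue_labels=labels,
                         lesion_mask=lesion_mask, true_center=true_center,
                         true_contour=true_contour, true_radius=true_radius)


def _child_seed(seed: int, i: int) -> int:
    return int((seed * 100003 + 17 * i + 1) % (2**31 - 1))


def generate_video(spec: PhantomSpec, n_frames: int, *,
                   drift: tuple[float, float] = (0.0, 0.0),
                   lesion_visible=None) -> list[PhantomSample]:
    """Render a frame sequence with per-frame lesion drift and visibility.

    Frame ``i`` contains the lesion iff ``lesion_visible[i]`` (all frames
    by default) at center ``center + i * drift``.  Each frame gets fresh
    speckle and anatomy jitter; the whole sequence is deterministic given
    ``spec.seed``.  A drift that pushes the lesion off-frame raises
    :class:`InvalidSpecError`.
    """
    if n_frames < 1:
        raise InvalidSpecError("n_frames must be >= 1")
    if lesion_visible is None:
        lesion_visible = [True] * n_frames
    if len(lesion_visible) != n_frames:
        raise InvalidSpecError("lesion_visible must have one flag per frame")
    base_center = spec.lesion.center or (spec.width / 2.0, 0.51 * spec.height)
    samples = []
    for i in range(n_frames):
        center_i = (base_center[0] + i * drift[0], base_center[1] + i * drift[1])
        lesion_i = replace(spec.lesion, present=bool(lesion_visible[i]),
                           center=center_i)
        spec_i = replace(spec, lesion=lesion_i, seed=_child_seed(spec.seed, i))
        samples.append(generate_phantom(spec_i))
    return samples


def training_bundle(specs, n_images: int):
    """Lesion-free frames + dense tissue annotations for classifier training.

    Cycles through ``specs`` with distinct per-image seeds until
    ``n_images`` pairs are produced.  Lesioned specs are rejected: training
    images must contain only normal tissue.
    """
    specs = list(specs)
    if not specs:
        raise InvalidSpecError("need at least one phantom spec")
    for spec in specs:
        if spec.lesion.present:
            raise InvalidSpecError("training phantoms must not contain a lesion")
    frames, annotations = [], []
    for i in range(n_images):
        spec = specs[i % len(specs)]
        sample = generate_phantom(replace(spec, seed=_child_seed(spec.seed, i)))
        frames.append(sample.frame)
        annotations.append(sample.tissue_labels)
    return frames, annotations
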