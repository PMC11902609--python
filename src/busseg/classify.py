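"""Normal-tissue classification and lesion-candidate extraction (stage 1).

A random forest is trained to recognize *normal* breast tissues (skin, fat,
fibrous tissue, fibrous bands, glandular tissue, artifacts).  At inference,
each tree votes for a class per pixel and the vote fractions are read as
class probabilities.  Pixels whose best class receives less than
``unknown_threshold`` (default 20%) of the votes are left *unknown* — the
residue the model cannot explain is exactly where a suspicious lesion is
expected.  The unknown mask is refined morphologically, its connected
components are measured, elongated bright artifact shapes are rejected, and
each surviving component becomes a lesion candidate with a contour
center-of-mass and a padded ROI box.

Labels
------
Label maps are integer arrays: ``0 .. C-1`` index into the class list and
``UNKNOWN`` (= -1) marks unexplained pixels.  Training annotations use the
same indices but must not contain ``UNKNOWN``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from sklearn.ensemble import RandomForestClassifier

from . import features as feat
from .errors import InvalidInputError, InvalidParameterError, TrainingError

UNKNOWN: int = -1

#: Default tissue classes (the six normal-tissue types annotated for
#: training; configurable — some deployments merge the two fibrous types).
DEFAULT_CLASSES: tuple[str, ...] = (
    "skin", "fat", "fibrous tissue", "fibrous bands", "glandular tissue", "artifacts",
)

#: Vote-fraction threshold below which a pixel is left unannotated.
DEFAULT_UNKNOWN_THRESHOLD: float = 0.20

MODEL_FORMAT_VERSION = 1


@dataclass
class TissueModel:
    """A trained normal-tissue forest plus everything needed to reuse it."""

    forest: RandomForestClassifier
    class_list: tuple[str, ...]
    sigmas: tuple[float, ...]
    n_trees: int
    version: int = MODEL_FORMAT_VERSION

    def save(self, path) -> None:
        joblib.dump(
            {
                "format_version": self.version,
                "forest": self.forest,
                "class_list": self.class_list,
                "sigmas": self.sigmas,
                "n_trees": self.n_trees,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "TissueModel":
        payload = joblib.load(path)
        return cls(
            forest=payload["forest"],
            class_list=tuple(payload["class_list"]),
            sigmas=tuple(payload["sigmas"]),
            n_trees=payload["n_trees"],
            version=payload["format_version"],
        )


def _collect_training_pixels(frames, annotations, n_classes, samples_per_class,
                             sigmas, rng):
    xs, ys = [], []
    for frame, ann in zip(frames, annotations):
        frame = feat.validate_frame(frame)
        ann = np.asarray(ann)
        if ann.shape != frame.shape:
            raise InvalidInputError(
                f"annotation shape {ann.shape} != frame shape {frame.shape}")
        stack = feat.feature_stack(frame, sigmas)
        flat_x = stack.reshape(-1, stack.shape[-1])
        flat_y = ann.reshape(-1)
        for c in range(n_classes):
            idx = np.flatnonzero(flat_y == c)
            if idx.size == 0:
                continue
            if idx.size > samples_per_class:
                idx = rng.choice(idx, size=samples_per_class, replace=False)
            xs.append(flat_x[idx])
            ys.append(np.full(idx.size, c, dtype=np.int64))
    if not xs:
        raise TrainingError("no annotated pixels found in any frame")
    return np.concatenate(xs), np.concatenate(ys)


def train_model(frames, annotations, class_list=DEFAULT_CLASSES, *,
                n_trees: int = 50, samples_per_class: int = 2000,
                seed: int = 0, sigmas=feat.DEFAULT_SIGMAS) -> TissueModel:
    """Train the Gini random forest on annotated lesion-free frames.

    ``annotations`` are per-pixel integer maps indexing ``class_list``
    (negative entries are ignored pixels).  A balanced subsample of at most
    ``samples_per_class`` pixels per class per frame bounds memory.
    Training is deterministic given ``seed``.
    """
    class_list = tuple(class_list)
    if len(set(class_list)) != len(class_list) or not class_list:
        raise InvalidParameterError("class_list must be non-empty and duplicate-free")
    if n_trees < 1:
        raise InvalidParameterError("n_trees must be >= 1")
    if not frames:
        raise TrainingError("at least one annotated frame is required")
    sigmas = feat.validate_schedule(sigmas)
    rng = np.random.default_rng(seed)
    x, y = _collect_training_pixels(frames, annotations, len(class_list),
                                    samples_per_class, sigmas, rng)
    present = np.unique(y)
    missing = [class_list[c] for c in range(len(class_list)) if c not in present]
    if missing:
        raise TrainingError(
            f"no annotated pixels for class(es): {', '.join(missing)}")
    forest = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini",
        random_state=int(seed) % (2**31), n_jobs=1,
    )
    forest.fit(x, y)
    return TissueModel(forest=forest, class_list=class_list, sigmas=sigmas,
                       n_trees=n_trees)


def vote_probabilities(model: TissueModel, x: np.ndarray) -> np.ndarray:
    """Per-sample class probabilities as tree vote fractions.

    Each tree casts one hard vote; the fraction of the ``N`` trees voting
    for class ``c`` is the probability of class ``c``.  (This differs from
    scikit-learn's ``predict_proba``, which averages leaf frequencies.)
    """
    counts = np.zeros((x.shape[0], len(model.class_list)), dtype=np.float64)
    classes = model.forest.classes_.astype(int)
    rows = np.arange(x.shape[0])
    for tree in model.forest.estimators_:
        pred = classes[tree.predict(x).astype(int)] \
            if not np.array_equal(classes, np.arange(len(model.class_list))) \
            else tree.predict(x).astype(int)
        counts[rows, pred] += 1.0
    return counts / len(model.forest.estimators_)


def classify(model: TissueModel, frame: np.ndarray, *,
             unknown_threshold: float = DEFAULT_UNKNOWN_THRESHOLD):
    """Classify every pixel of *frame*.

    Returns ``(probabilities, labels)`` where ``probabilities`` has shape
    ``(n, m, C)`` (vote fractions, rows sum to 1) and ``labels`` is the
    argmax class index, or ``UNKNOWN`` where the best class falls below
    ``unknown_threshold``.  Ties in the argmax resolve to the lowest class
    index.
    """
    frame = feat.validate_frame(frame)
    stack = feat.feature_stack(frame, model.sigmas)
    flat = stack.reshape(-1, stack.shape[-1])
    probs = vote_probabilities(model, flat)
    labels = probs.argmax(axis=1).astype(np.int64)
    labels[probs.max(axis=1) < unknown_threshold] = UNKNOWN
    n, m = frame.shape
    return probs.reshape(n, m, -1), labels.reshape(n, m)


def refine_unknown_mask(labels: np.ndarray, *, dilation_radius: int = 2,
                        median_size: int = 5) -> np.ndarray:
    """Merge and despeckle the unknown-pixel mask.

    A median filter first removes sparse isolated unknown pixels (false
    outliers), then a morphological dilation (disk structuring element)
    merges the surviving dense clusters into solid candidate blobs.
    Filtering before dilating keeps sparse noise from being inflated into
    spurious blobs; dilation itself never removes a set pixel.
    ``dilation_radius = 0`` / ``median_size = 1`` skip the respective step.
    """
    if dilation_radius < 0:
        raise InvalidParameterError("dilation_radius must be >= 0")
    if median_size < 1 or median_size % 2 == 0:
        raise InvalidParameterError("median_size must be odd and >= 1")
    mask = np.asarray(labels) == UNKNOWN
    if median_size > 1:
        mask = ndimage.median_filter(
            mask.astype(np.uint8), size=median_size, mode="constant", cval=0
        ).astype(bool)
    if dilation_radius > 0:
        mask = ndimage.binary_dilation(
            mask, structure=morphology.disk(dilation_radius))
    return mask


def calibrate_unknown_threshold(model: TissueModel, frames, *,
                                quantile: float = 0.005) -> float:
    """Transfer the unknown rule to a new image distribution.

    The published 20% cut-off is an absolute vote-fraction threshold tied
    to the data the forest was built for; vote-confidence distributions
    shift with imaging conditions, so on other material the threshold must
    be recalibrated.  This helper fixes it from *specificity*: given
    representative **lesion-free** frames, it returns the ``quantile`` of
    the per-pixel maximum vote fraction, so that roughly that fraction of
    normal-tissue pixels is left unannotated (default 0.5%, mirroring the
    sparse unmarked pixels normal frames are expected to show).  Lesions
    play no part in the calibration.
    """
    if not frames:
        raise InvalidInputError("need at least one calibration frame")
    if not 0 < quantile < 1:
        raise InvalidParameterError("quantile must be in (0, 1)")
    maxima = []
    for frame in frames:
        probs, _ = classify(model, frame, unknown_threshold=0.0)
        maxima.append(probs.max(axis=2).ravel())
    return float(np.quantile(np.concatenate(maxima), quantile))


@dataclass(eq=False)
class CandidateObject:
    """One connected component of unexplained pixels with its shape stats."""

    coords: np.ndarray          # (S, 2) array of (row, col) member pixels
    contour: np.ndarray         # (K, 2) ordered closed boundary, (x, y) subpixel
    mean_intensity: float       # I_aver, 0-255
    eccentricity: float         # fitted-ellipse eccentricity, 0 round .. 1 line
    perimeter: float            # length of the traced boundary polygon (px)
    area: int                   # S, member pixel count
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), half-open
    center: tuple[float, float] = field(init=False)  # (x0, y0), contour mass center

    def __post_init__(self):
        self.center = object_center(self.contour)

    @property
    def shape_ratio(self) -> float:
        """Perimeter-to-area ratio R = P / S."""
        return self.perimeter / self.area


def object_center(contour: np.ndarray) -> tuple[float, float]:
    """Center of mass of a contour: the arithmetic mean of its points."""
    contour = np.asarray(contour, dtype=np.float64)
    if contour.size == 0:
        raise InvalidInputError("contour must contain at least one point")
    x0, y0 = contour.reshape(-1, 2).mean(axis=0)
    return float(x0), float(y0)


def _trace_contour(component_mask: np.ndarray) -> np.ndarray:
    """Ordered closed boundary of a binary component as (x, y) points.

    Marching-squares at level 0.5 on a zero-padded copy, so components
    touching the frame edge still close.  The duplicated closing vertex is
    dropped.
    """
    padded = np.pad(component_mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    longest = max(contours, key=len)
    rc = longest[:-1] - 1.0  # drop closing duplicate, undo pad
    return rc[:, ::-1].copy()  # (row, col) -> (x, y)


def extract_objects(mask: np.ndarray, frame: np.ndarray) -> list[CandidateObject]:
    """Measure every 8-connected component of the unknown mask."""
    mask = np.asarray(mask, dtype=bool)
    frame = np.asarray(frame)
    if mask.shape != frame.shape:
        raise InvalidInputError("mask and frame shapes differ")
    labeled = measure.label(mask, connectivity=2)
    objects = []
    for prop in measure.regionprops(labeled, intensity_image=frame.astype(np.float64)):
        component = labeled[prop.slice] == prop.label
        contour = _trace_contour(component)
        offset = np.array([prop.bbox[1], prop.bbox[0]], dtype=np.float64)  # (x, y)
        contour = contour + offset
        diffs = np.diff(np.vstack([contour, contour[:1]]), axis=0)
        perimeter = float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())
        objects.append(CandidateObject(
            coords=prop.coords,
            contour=contour,
            mean_intensity=float(prop.intensity_mean),
            eccentricity=float(prop.eccentricity),
            perimeter=perimeter,
            area=int(prop.area),
            bbox=tuple(int(b) for b in prop.bbox),
        ))
    return objects


def filter_artifacts(objects, *, intensity_threshold: float = 93.0,
                     eccentricity_threshold: float = 0.9,
                     ratio_threshold: float = 0.1) -> list[CandidateObject]:
    """Drop bright, elongated, thin components — typical reflection artifacts.

    An object is removed iff **all three** hold strictly:
    mean intensity > 93, eccentricity > 0.9 and perimeter/area > 0.1.
    Survivor order is preserved; the filter is idempotent.
    """
    return [
        obj for obj in objects
        if not (obj.mean_intensity > intensity_threshold
                and obj.eccentricity > eccentricity_threshold
                and obj.shape_ratio > ratio_threshold)
    ]


@dataclass(frozen=True)
class RoiBox:
    """Half-open pixel rectangle [top, bottom) x [left, right)."""

    top: int
    left: int
    bottom: int
    right: int

    def contains(self, x: float, y: float) -> bool:
        return self.left <= x < self.right and self.top <= y < self.bottom

    @property
    def shape(self) -> tuple[int, int]:
        return self.bottom - self.top, self.right - self.left


def roi_boxes(objects, frame_shape, pad_fraction: float = 0.15) -> list[RoiBox]:
    """Bounding boxes expanded by ``pad_fraction`` per side, clipped to frame."""
    n, m = frame_shape
    boxes = []
    for obj in objects:
        top, left, bottom, right = obj.bbox
        pad_r = int(round(pad_fraction * (bottom - top)))
        pad_c = int(round(pad_fraction * (right - left)))
        boxes.append(RoiBox(
            top=max(0, top - pad_r), left=max(0, left - pad_c),
            bottom=min(n, bottom + pad_r), right=min(m, right + pad_c),
        ))
    return boxes


def cross_validate(frames, annotations, class_list=DEFAULT_CLASSES, *,
                   n_folds: int = 2, seed: int = 0, **train_kwargs):
    """Frame-level cross-validated per-class pixel accuracy.

    Splits the annotated frames into ``n_folds`` groups, trains on all but
    one group and scores argmax labels on the held-out frames (the unknown
    rule is not applied — this measures pure tissue classification).
    Returns a dict ``{class_name: accuracy}`` plus ``"overall"``.
    """
    frames = list(frames)
    annotations = list(annotations)
    if len(frames) < n_folds:
        raise InvalidParameterError("need at least one frame per fold")
    folds = [list(range(i, len(frames), n_folds)) for i in range(n_folds)]
    n_classes = len(class_list)
    correct = np.zeros(n_classes)
    total = np.zeros(n_classes)
    for held_out in folds:
        train_idx = [i for i in range(len(frames)) if i not in held_out]
        model = train_model([frames[i] for i in train_idx],
                            [annotations[i] for i in train_idx],
                            class_list, seed=seed, **train_kwargs)
        for i in held_out:
            _, labels = classify(model, frames[i], unknown_threshold=0.0)
            ann = np.asarray(annotations[i])
            for c in range(n_classes):
                sel = ann == c
                total[c] += sel.sum()
                correct[c] += (labels[sel] == c).sum()
    report = {name: float(correct[c] / total[c]) if total[c] else float("nan")
              for c, name in enumerate(class_list)}
    report["overall"] = float(correct.sum() / total.sum())
    return report
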