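"""Frame-by-frame detection + segmentation pipeline and batch evaluation.

``process_frame`` chains the two stages: classify normal tissue, refine the
unknown-pixel mask, extract and shape-filter candidate objects, then run
ray-cast contour extraction around each surviving candidate's contour
center.  Frames are processed independently — no information is shared
between neighboring video frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

import busseg.classify as cls
import busseg.contour as cnt
import busseg.io as bio
import busseg.metrics as met
from .errors import BussegError

logger = logging.getLogger("busseg")


@dataclass
class PipelineConfig:
    """All tunable knobs of the pipeline with their published defaults."""

    # stage 1
    unknown_threshold: float = cls.DEFAULT_UNKNOWN_THRESHOLD  # vote fraction
    dilation_radius: int = 2
    median_size: int = 5
    min_object_area: int = 300    # smallest candidate worth segmenting (px)
    intensity_threshold: float = 93.0   # artifact filter: mean intensity
    eccentricity_threshold: float = 0.9
    ratio_threshold: float = 0.1        # perimeter/area
    pad_fraction: float = 0.15          # ROI padding per side
    # ray seeding inside the ROI
    seed_mode: str = "dark-core"        # or "object-center"
    core_quantile: float = 10.0         # darkest percentile defining the core
    core_min_area: int = 50             # smallest credible hypoechoic core (px)
    radius_factor: float = 2.0          # ray bound = factor * core radius
    min_ray_bound: float = 20.0         # px
    # stage 2
    step_deg: float = cnt.DEFAULT_STEP_DEG
    gradient_window: int = cnt.DEFAULT_GRADIENT_WINDOW
    regression_window: int = 180
    window_stride: int = 10
    closure_pad: int = 180
    niblack_k: float = 0.2

    def contour_config(self, max_radius: float | None = None) -> cnt.ContourConfig:
        return cnt.ContourConfig(
            step_deg=self.step_deg, gradient_window=self.gradient_window,
            regression_window=self.regression_window,
            window_stride=self.window_stride, closure_pad=self.closure_pad,
            niblack_k=self.niblack_k, max_radius=max_radius)


@dataclass(eq=False)
class Detection:
    """One segmented lesion candidate.

    ``center`` is the reported lesion center: the mass center of the final
    segmented contour.  ``seed`` is the point the rays were cast from.
    """

    roi: cls.RoiBox
    center: tuple[float, float]
    seed: tuple[float, float]
    contour_xy: np.ndarray
    mask: np.ndarray
    polar: cnt.PolarContour


@dataclass
class FrameResult:
    """Outcome of processing one frame."""

    index: int
    detections: list[Detection]
    errors: list[str] = field(default_factory=list)

    @property
    def status(self) -> str:
        return "detected" if self.detections else "no-candidate"


@dataclass
class VideoReport:
    """Aggregate of per-frame results for a sequence."""

    results: list[FrameResult]

    @property
    def n_frames(self) -> int:
        return len(self.results)

    @property
    def n_detected(self) -> int:
        return sum(1 for r in self.results if r.detections)

    @property
    def detection_rate(self) -> float:
        """Percentage of frames with at least one detection."""
        return 100.0 * self.n_detected / self.n_frames

    def summary(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "n_detected": self.n_detected,
            "n_no_candidate": self.n_frames - self.n_detected,
            "detection_rate_percent": self.detection_rate,
        }


def _hypoechoic_core(frame: np.ndarray, box: cls.RoiBox,
                     cfg: PipelineConfig):
    """Seed point and radius scale from the darkest blob inside the ROI.

    The candidate object's contour mass center only localizes the lesion
    roughly (the unknown mask includes halo pixels around it), but the
    lesion itself is the most hypoechoic structure in its ROI.  Threshold
    the ROI at its darkest ``core_quantile`` percent, take the connected
    component with the lowest mean intensity, and return its centroid plus
    equivalent radius.  Returns ``None`` when no credible core exists.
    """
    from skimage import measure

    sub = frame[box.top:box.bottom, box.left:box.right].astype(np.float64)
    if sub.size < 9 or sub.max() == sub.min():
        return None
    labeled = measure.label(sub <= np.percentile(sub, cfg.core_quantile),
                            connectivity=2)
    props = [r for r in measure.regionprops(labeled, intensity_image=sub)
             if r.area >= cfg.core_min_area]
    if not props:
        return None
    core = min(props, key=lambda r: r.intensity_mean)
    cy, cx = core.centroid
    return (box.left + cx, box.top + cy), float(np.sqrt(core.area / np.pi))


def process_frame(frame: np.ndarray, model: cls.TissueModel,
                  config: PipelineConfig | None = None,
                  index: int = 0) -> FrameResult:
    """Run both stages on a single frame.

    Every surviving candidate is segmented; a stage error on one candidate
    (e.g. no boundary gradient) is recorded and does not abort the others.
    Deterministic given the model and frame.
    """
    cfg = config or PipelineConfig()
    _, labels = cls.classify(model, frame,
                             unknown_threshold=cfg.unknown_threshold)
    mask = cls.refine_unknown_mask(labels, dilation_radius=cfg.dilation_radius,
                                   median_size=cfg.median_size)
    objects = cls.extract_objects(mask, frame)
    objects = [o for o in objects if o.area >= cfg.min_object_area]
    objects = cls.filter_artifacts(
        objects, intensity_threshold=cfg.intensity_threshold,
        eccentricity_threshold=cfg.eccentricity_threshold,
        ratio_threshold=cfg.ratio_threshold)
    boxes = cls.roi_boxes(objects, frame.shape, pad_fraction=cfg.pad_fraction)

    detections, errors = [], []
    for obj, box in zip(objects, boxes):
        seed = obj.center
        max_radius = 0.5 * float(np.hypot(*box.shape))
        if cfg.seed_mode == "dark-core":
            core = _hypoechoic_core(frame, box, cfg)
            if core is not None:
                seed, core_radius = core
                max_radius = max(cfg.radius_factor * core_radius,
                                 cfg.min_ray_bound)
        try:
            contour_xy, seg_mask, polar = cnt.segment_lesion(
                frame, seed, cfg.contour_config(max_radius))
        except BussegError as exc:
            errors.append(f"candidate at {obj.center}: {exc}")
            logger.warning("frame %d: %s", index, errors[-1])
            continue
        detections.append(Detection(roi=box,
                                    center=cls.object_center(contour_xy),
                                    seed=seed, contour_xy=contour_xy,
                                    mask=seg_mask, polar=polar))
    logger.info("frame %d: %s (%d candidate(s))", index,
                "detected" if detections else "no-candidate", len(detections))
    return FrameResult(index=index, detections=detections, errors=errors)


def process_video(frames, model: cls.TissueModel,
                  config: PipelineConfig | None = None) -> VideoReport:
    """Process a frame sequence independently frame by frame."""
    if not len(frames):
        raise BussegError("need at least one frame")
    results = [process_frame(f, model, config, index=i)
               for i, f in enumerate(frames)]
    return VideoReport(results=results)


def detection_accuracy(report: VideoReport, true_centers) -> dict:
    """Score detections against known per-frame lesion centers.

    ``true_centers[i]`` is the (x, y) lesion center of frame ``i`` or
    ``None`` when the frame has no lesion.  A lesioned frame counts as
    correctly detected iff some ROI contains the true center; a
    lesion-free frame counts as correct iff no candidate was reported.
    (This criterion is a convention of this package for phantom data.)
    """
    correct = 0
    for result, center in zip(report.results, true_centers):
        if center is None:
            correct += not result.detections
        else:
            correct += any(d.roi.contains(*center) for d in result.detections)
    total = report.n_frames
    return {
        "n_frames": total,
        "n_correct": int(correct),
        "n_incorrect": total - int(correct),
        "accuracy_percent": 100.0 * correct / total,
    }


def evaluate_batch(manifest, *, hemisphere: bool = False) -> pd.DataFrame:
    """Metric reports for a batch of (predicted, truth) mask pairs.

    ``manifest`` is a DataFrame (or CSV path) with columns ``pred_mask``
    and ``truth_mask`` (file paths) and optionally ``video`` and ``frame``.
    Returns one row per pair plus, labeled in the ``kind`` column,
    per-video averages (``video-mean``), the arithmetic mean over rows
    (``mean-of-rows``) and a pooled recomputation over all pixels
    (``pooled``).  A row whose files cannot be processed is recorded with
    its error and skipped in the summaries.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = bio.read_manifest(manifest)
    rows = []
    pooled_pred, pooled_truth = [], []
    for i, rec in manifest.iterrows():
        row = {"kind": "frame", "row": i}
        for col in ("video", "frame"):
            if col in manifest.columns:
                row[col] = rec[col]
        try:
            pred = bio.read_mask(rec["pred_mask"])
            truth = bio.read_mask(rec["truth_mask"])
            report = met.evaluate_masks(pred, truth, hemisphere=hemisphere)
        except Exception as exc:  # record and continue
            row["error"] = str(exc)
            rows.append(row)
            continue
        row.update(report.as_dict())
        rows.append(row)
        pooled_pred.append(pred)
        pooled_truth.append(truth)
    table = pd.DataFrame(rows)
    metric_cols = [c for c in ("d_mean", "d_std", "iou", "tp", "fp", "fn",
                               "precision", "recall", "f1") if c in table.columns]
    ok = table[table["kind"] == "frame"]
    if "error" in table.columns:
        ok = ok[ok["error"].isna()]
    summaries = []
    if len(ok):
        if "video" in table.columns:
            for video, grp in ok.groupby("video"):
                s = grp[metric_cols].mean().to_dict()
                s.update({"kind": "video-mean", "video": video})
                summaries.append(s)
        s = ok[metric_cols].mean().to_dict()
        s["kind"] = "mean-of-rows"
        summaries.append(s)
        # pooled: recompute overlap metrics over all pixels of all pairs
        pred_all = np.concatenate([p.ravel() for p in pooled_pred])
        truth_all = np.concatenate([t.ravel() for t in pooled_truth])
        tp, fp, fn = met.overlap_fractions(pred_all[None], truth_all[None])
        prec, rec, f1, _ = met.precision_recall_f1(tp, fp, fn)
        summaries.append({"kind": "pooled", "iou": met.iou(pred_all, truth_all),
                          "tp": tp, "fp": fp, "fn": fn, "precision": prec,
                          "recall": rec, "f1": f1})
    return pd.concat([table, pd.DataFrame(summaries)], ignore_index=True)
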