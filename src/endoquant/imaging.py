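"""Fluorescence internalization quantification.

Implements the per-frame robust normalization (centre by the median, scale
by the median absolute deviation), threshold estimation (99th percentile of
the first four normalized frames for time-lapse stacks, or of pooled
control-condition images for static end points), the super-threshold pixel
sum ``S_int = sum(x * [x > k])``, connected-component cluster counting and
per-ROI positivity calls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from skimage import measure

from .errors import DegenerateFrameError, SpecValidationError

log = logging.getLogger(__name__)

__all__ = [
    "FrameStack",
    "NormalizedFrame",
    "InternalizationResult",
    "ClusterCount",
    "RoiPositivity",
    "normalize_frame",
    "estimate_threshold_timelapse",
    "estimate_threshold_static",
    "sum_above_threshold",
    "quantify_timelapse",
    "quantify_static",
    "count_clusters",
    "classify_rois",
]


@dataclass
class FrameStack:
    """Ordered fluorescence frames from one imaging position.

    Parameters
    ----------
    frames:
        Array of shape ``(n_frames, height, width)``; non-negative, finite.
    frame_interval:
        Minutes between consecutive frames.
    position_id:
        Free-form identifier of the imaging position.
    """

    frames: np.ndarray
    frame_interval: float = 15.0
    position_id: str = "pos0"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise SpecValidationError(
                "frames", "expected a non-empty (n_frames, height, width) array"
            )
        if not np.all(np.isfinite(self.frames)):
            raise SpecValidationError("frames", "intensities must be finite")
        if np.any(self.frames < 0):
            raise SpecValidationError("frames", "intensities must be >= 0")
        if self.frame_interval <= 0:
            raise SpecValidationError("frame_interval", "must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class NormalizedFrame:
    """A robust z-scored frame: ``(raw - median) / MAD``."""

    values: np.ndarray
    source_median: float
    source_mad: float


@dataclass
class InternalizationResult:
    k: float
    per_frame_Sint: np.ndarray
    threshold_mode: Literal["time-lapse", "static"]
    n_baseline_frames: Optional[int] = None
    degenerate_frames: list[int] = field(default_factory=list)


@dataclass
class ClusterCount:
    n_clusters: int
    cluster_labels: np.ndarray
    min_area: int
    connectivity: Literal[4, 8]


@dataclass
class RoiPositivity:
    roi_ids: list
    per_roi_Sint: np.ndarray
    positive_flags: np.ndarray
    fraction_positive: float


def normalize_frame(
    frame: np.ndarray,
    mad_constant: float = 1.0,
    order: Literal["center_then_scale", "scale_then_center"] = "center_then_scale",
) -> NormalizedFrame:
    """Centre a frame by its median and scale by its median absolute deviation.

    The MAD is the raw ``median(|x - median(x)|)``; no 1.4826 consistency
    factor is applied unless ``mad_constant`` says otherwise.  The
    alternative operation order (scale first, then subtract the median of
    the scaled values) is provided for sensitivity checks only; with a pure
    rescale followed by recentring both orders give identical values.

    Raises
    ------
    DegenerateFrameError
        If the MAD is zero (constant or near-constant frame).  The error
        carries the frame median so the caller can pick a fallback.
    """
    raw = np.asarray(frame, dtype=float)
    if raw.size == 0:
        raise SpecValidationError("frame", "frame is empty")
    if not np.all(np.isfinite(raw)):
        raise SpecValidationError("frame", "frame contains non-finite values")
    med = float(np.median(raw))
    mad = float(np.median(np.abs(raw - med))) * mad_constant
    if mad == 0.0:
        raise DegenerateFrameError(med)
    if order == "center_then_scale":
        values = (raw - med) / mad
    elif order == "scale_then_center":
        scaled = raw / mad
        values = scaled - np.median(scaled)
    else:  # pragma: no cover - guarded by the Literal type
        raise SpecValidationError("order", f"unknown normalization order {order!r}")
    return NormalizedFrame(values=values, source_median=med, source_mad=mad)


def _normalize_stack(
    stack: FrameStack,
    mad_constant: float,
    order: str,
    degenerate_fallback: Literal["error", "center_only"],
) -> tuple[list[np.ndarray], list[int]]:
    normalized: list[np.ndarray] = []
    degenerate: list[int] = []
    for i in range(stack.n_frames):
        try:
            normalized.append(
                normalize_frame(stack.frames[i], mad_constant=mad_constant, order=order).values
            )
        except DegenerateFrameError as err:
            if degenerate_fallback == "error":
                raise
            # Centre-only fallback: treat MAD as 1 and log it.
            log.warning(
                "frame %d of %s is degenerate (MAD=0); using centre-only fallback",
                i,
                stack.position_id,
            )
            degenerate.append(i)
            normalized.append(np.asarray(stack.frames[i], dtype=float) - err.median)
    return normalized, degenerate


def estimate_threshold_timelapse(
    normalized_frames: Sequence[np.ndarray],
    n_baseline: int = 4,
    percentile: float = 99.0,
    method: str = "linear",
) -> float:
    """99th percentile over the pooled pixels of the first ``n_baseline`` frames.

    Frames must already be normalized.  The percentile uses linear
    interpolation between order statistics by default; any quantile method
    accepted by :func:`numpy.percentile` may be supplied.
    """
    if len(normalized_frames) < n_baseline:
        raise SpecValidationError(
            "n_baseline",
            f"stack has {len(normalized_frames)} frames, needs >= {n_baseline}",
        )
    if n_baseline < 1:
        raise SpecValidationError("n_baseline", "must be >= 1")
    pooled = np.concatenate([np.ravel(f) for f in normalized_frames[:n_baseline]])
    return float(np.percentile(pooled, percentile, method=method))


def estimate_threshold_static(
    control_images: Sequence[np.ndarray],
    percentile: float = 99.0,
    method: str = "linear",
) -> float:
    """99th percentile over all pooled pixels of the control-condition images."""
    if len(control_images) == 0:
        raise SpecValidationError("control_images", "need at least one control image")
    pooled = np.concatenate([np.ravel(f) for f in control_images])
    if pooled.size == 0:
        raise SpecValidationError("control_images", "control pixel pool is empty")
    return float(np.percentile(pooled, percentile, method=method))


def sum_above_threshold(values: np.ndarray, k: float, strict: bool = True) -> float:
    """``S_int``: sum of pixel values strictly exceeding ``k``.

    The Iverson bracket is strict (``x > k``) by default; ``strict=False``
    switches to ``x >= k`` for sensitivity checks.
    """
    if not np.isfinite(k):
        raise SpecValidationError("k", "threshold must be finite")
    v = np.asarray(values, dtype=float)
    mask = v > k if strict else v >= k
    # fsum: correctly rounded and order-independent, so the result agrees
    # exactly with a naive enumeration oracle regardless of summation order
    return math.fsum(v[mask])


def quantify_timelapse(
    stack: FrameStack,
    n_baseline: int = 4,
    percentile: float = 99.0,
    percentile_method: str = "linear",
    mad_constant: float = 1.0,
    normalization_order: str = "center_then_scale",
    strict: bool = True,
    degenerate_fallback: Literal["error", "center_only"] = "center_only",
) -> InternalizationResult:
    """Per-frame super-threshold sums for a time-lapse stack.

    Each frame is normalized independently; ``k`` is the 99th percentile of
    the pooled first ``n_baseline`` normalized frames; ``S_int`` is then
    computed per frame.  Degenerate frames (MAD 0) fall back to centre-only
    normalization by default and are recorded in the result.
    """
    normalized, degenerate = _normalize_stack(
        stack, mad_constant, normalization_order, degenerate_fallback
    )
    k = estimate_threshold_timelapse(
        normalized, n_baseline=n_baseline, percentile=percentile, method=percentile_method
    )
    sints = np.array([sum_above_threshold(v, k, strict=strict) for v in normalized])
    return InternalizationResult(
        k=k,
        per_frame_Sint=sints,
        threshold_mode="time-lapse",
        n_baseline_frames=n_baseline,
        degenerate_frames=degenerate,
    )


def quantify_static(
    test_images: Sequence[np.ndarray],
    control_images: Sequence[np.ndarray],
    percentile: float = 99.0,
    percentile_method: str = "linear",
    mad_constant: float = 1.0,
    normalization_order: str = "center_then_scale",
    strict: bool = True,
) -> InternalizationResult:
    """``S_int`` per test image with ``k`` taken from control-condition images.

    Both lists are normalized with the same convention before pooling the
    controls for the threshold.
    """
    if len(test_images) == 0:
        raise SpecValidationError("test_images", "need at least one test image")
    norm = lambda f: normalize_frame(  # noqa: E731
        f, mad_constant=mad_constant, order=normalization_order
    ).values
    controls = [norm(f) for f in control_images] if control_images else []
    k = estimate_threshold_static(
        controls, percentile=percentile, method=percentile_method
    )
    sints = np.array([sum_above_threshold(norm(f), k, strict=strict) for f in test_images])
    return InternalizationResult(k=k, per_frame_Sint=sints, threshold_mode="static")


def count_clusters(
    values: np.ndarray,
    k: float,
    min_area: int = 5,
    connectivity: Literal[4, 8] = 8,
) -> ClusterCount:
    """Connected components of the super-threshold mask with area >= ``min_area``.

    An algorithmic surrogate for blinded manual cluster counts: threshold,
    label (4- or 8-connectivity), drop small components, relabel in raster
    order of each component's first pixel.
    """
    if min_area < 1:
        raise SpecValidationError("min_area", "must be >= 1")
    if connectivity not in (4, 8):
        raise SpecValidationError("connectivity", "must be 4 or 8")
    mask = np.asarray(values, dtype=float) > k
    skimage_conn = 1 if connectivity == 4 else 2
    labels = measure.label(mask, connectivity=skimage_conn)
    out = np.zeros_like(labels)
    next_label = 0
    # skimage labels in raster-scan order of first encounter, so iterating
    # label ids ascending preserves the raster ordering after filtering.
    for lab in range(1, labels.max() + 1):
        component = labels == lab
        if component.sum() >= min_area:
            next_label += 1
            out[component] = next_label
    return ClusterCount(
        n_clusters=next_label, cluster_labels=out, min_area=min_area, connectivity=connectivity
    )


def classify_rois(
    values: np.ndarray,
    rois: Sequence[np.ndarray],
    k: float,
    positivity_threshold: float = 0.0,
    roi_ids: Optional[Sequence] = None,
    strict: bool = True,
) -> RoiPositivity:
    """Per-ROI ``S_int`` and positivity calls.

    Each ROI is a boolean mask with the image's shape.  A ROI is positive
    when its ``S_int`` exceeds ``positivity_threshold`` (default 0).
    """
    img = np.asarray(values, dtype=float)
    if roi_ids is None:
        roi_ids = list(range(len(rois)))
    if len(roi_ids) != len(rois):
        raise SpecValidationError("roi_ids", "length must match rois")
    sints = np.empty(len(rois))
    for i, roi in enumerate(rois):
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != img.shape:
            raise SpecValidationError(
                "rois", f"ROI {roi_ids[i]!r} shape {roi.shape} != image shape {img.shape}"
            )
        sints[i] = sum_above_threshold(img[roi], k, strict=strict)
    flags = sints > positivity_threshold
    frac = float(flags.mean()) if len(rois) else 0.0
    return RoiPositivity(
        roi_ids=list(roi_ids),
        per_roi_Sint=sints,
        positive_flags=flags,
        fraction_positive=frac,
    )
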