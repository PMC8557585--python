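"""Vascularization quantification of monochrome SMI sonograms.

In monochrome superb-microvascular-imaging (SMI) mode the strength of the
Doppler flow signal is encoded as the gray value of each pixel.  Two simple
statistics over an examiner-drawn region of interest summarise nodal
vascularization:

* the mean gray value over the ROI, and
* the *area fraction*: the proportion of ROI pixels at or above a
  flow-positivity threshold.

Each nodule statistic is divided by the same statistic in a matched region of
adjacent normal parenchyma, yielding a *vascularization quotient* (VQ) that is
comparable to the vendor vascularization index.  A full study acquires two
frames per section plane (longitudinal and cross), plus one whole-lobe frame
from which nodal and parenchymal sub-areas give the "all" quotients; the ten
resulting parameters form a :class:`VascularizationProfile`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from typing import Mapping, Sequence

import numpy as np

from .roi import GeometryError, RoiPolygon, rasterize_roi

__all__ = [
    "ThresholdRule",
    "VascularizationProfile",
    "rasterize_roi",
    "mean_gray",
    "area_fraction",
    "resolve_threshold",
    "quotient",
    "compute_profile",
]

PROFILE_FIELDS = (
    "roi_longitudinal",
    "roi_longitudinal_area_fraction",
    "roi_cross",
    "roi_cross_area_fraction",
    "quotient_longitudinal",
    "quotient_longitudinal_area_fraction",
    "quotient_cross",
    "quotient_cross_area_fraction",
    "quotient_all",
    "quotient_all_area_fraction",
)


@dataclass(frozen=True)
class ThresholdRule:
    """How the flow-positivity threshold is chosen for one analyzed region.

    ``ThresholdRule.fixed(k)`` always returns ``k``; ``ThresholdRule.isodata()``
    computes the intermeans (ISODATA) fixed point of the masked gray-value
    histogram, the default auto-threshold family of common image-analysis
    tools.  Pixels with value >= threshold count as flow-positive.
    """

    method: str = "isodata"
    value: int | None = None

    @classmethod
    def fixed(cls, value: int) -> "ThresholdRule":
        return cls(method="fixed", value=int(value))

    @classmethod
    def isodata(cls) -> "ThresholdRule":
        return cls(method="isodata")

    def __post_init__(self) -> None:
        if self.method not in ("fixed", "isodata"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.method == "fixed" and self.value is None:
            raise ValueError("fixed threshold rule needs a value")


@dataclass(frozen=True)
class VascularizationProfile:
    """The ten per-nodule SMI vascularization parameters.

    Mean-gray entries are dimensionless gray levels, area fractions are
    proportions in [0, 1], quotients are node/parenchyma ratios.  A quotient
    whose parenchyma denominator is zero is undefined and stored as NaN.
    """

    roi_longitudinal: float
    roi_longitudinal_area_fraction: float
    roi_cross: float
    roi_cross_area_fraction: float
    quotient_longitudinal: float
    quotient_longitudinal_area_fraction: float
    quotient_cross: float
    quotient_cross_area_fraction: float
    quotient_all: float
    quotient_all_area_fraction: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __post_init__(self) -> None:
        for name in ("roi_longitudinal_area_fraction", "roi_cross_area_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in PROFILE_FIELDS[4:]:
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{name}={v} negative")


def _validate_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("gray values must lie in [0, 255]")
    return img


def _mask_of(image: np.ndarray, roi: RoiPolygon | np.ndarray) -> np.ndarray:
    if isinstance(roi, RoiPolygon):
        return rasterize_roi(roi, image.shape)
    mask = np.asarray(roi, dtype=bool)
    if mask.shape != image.shape:
        raise GeometryError("mask shape does not match image shape")
    if not mask.any():
        raise GeometryError("empty ROI mask")
    return mask


def mean_gray(image: np.ndarray, roi: RoiPolygon | np.ndarray) -> float:
    """Arithmetic mean gray value of *image* over the ROI."""
    img = _validate_gray(image)
    mask = _mask_of(img, roi)
    return float(img[mask].mean(dtype=np.float64))


def resolve_threshold(image: np.ndarray, mask: np.ndarray,
                      rule: ThresholdRule) -> int:
    """Resolve *rule* to an integer gray-value threshold for the masked pixels.

    For ``isodata`` the threshold t is iterated to the intermeans
    (Ridler-Calvard) fixed point t = round(((mean of values < t) + (mean of
    values >= t)) / 2) on the masked histogram, starting from the midpoint of
    the occupied gray range.  The midpoint start selects the between-class
    fixed point even when one class is rare (the masked-mean start can
    collapse into a split of the dominant mode).  A constant histogram has no
    intermeans split; the threshold is then max + 1 (area fraction 0) and a
    warning is emitted.
    """
    if rule.method == "fixed":
        return int(rule.value)
    values = np.asarray(image)[np.asarray(mask, dtype=bool)]
    if values.size == 0:
        raise GeometryError("empty ROI mask")
    hist = np.bincount(values.astype(np.int64), minlength=256).astype(np.float64)
    levels = np.arange(256, dtype=np.float64)
    lo, hi = int(values.min()), int(values.max())
    if lo == hi:
        warnings.warn("constant region: isodata threshold undefined, "
                      "returning max+1", stacklevel=2)
        return hi + 1
    t = int(round((lo + hi) / 2.0))
    seen: set[int] = set()
    for _ in range(256):
        below = hist[:t].sum()
        above = hist[t:].sum()
        if below == 0:
            t_new = t + 1
        elif above == 0:
            t_new = t - 1
        else:
            mu_lo = (hist[:t] * levels[:t]).sum() / below
            mu_hi = (hist[t:] * levels[t:]).sum() / above
            t_new = int(round((mu_lo + mu_hi) / 2.0))
        if t_new == t or t_new in seen:  # fixed point or 2-cycle
            break
        seen.add(t)
        t = t_new
    return t


def area_fraction(image: np.ndarray, roi: RoiPolygon | np.ndarray,
                  threshold: ThresholdRule | int) -> float:
    """Fraction of ROI pixels at or above the flow-positivity threshold."""
    img = _validate_gray(image)
    mask = _mask_of(img, roi)
    rule = (ThresholdRule.fixed(threshold) if isinstance(threshold, (int, np.integer))
            else threshold)
    t = resolve_threshold(img, mask, rule)
    values = img[mask]
    return float(np.count_nonzero(values >= t)) / values.size


def quotient(node_value: float, parenchyma_value: float) -> float:
    """Node/parenchyma ratio; NaN (undefined, never infinite) when the
    parenchyma value is zero."""
    if parenchyma_value < 0:
        raise ValueError("parenchyma value must be >= 0")
    if parenchyma_value == 0 or math.isnan(parenchyma_value) or math.isnan(node_value):
        return float("nan")
    return float(node_value) / float(parenchyma_value)


def _check_matched_areas(mask_a: np.ndarray, mask_b: np.ndarray) -> None:
    # ROI-B should match ROI-A in size "when possible"; warn on gross mismatch
    a, b = int(mask_a.sum()), int(mask_b.sum())
    if a > 0 and abs(a - b) / a > 0.25:
        warnings.warn(
            f"parenchyma ROI area ({b} px) differs from node ROI area "
            f"({a} px) by more than 25%", stacklevel=3)


def _plane_values(frames: Sequence[np.ndarray], roi_a: RoiPolygon,
                  roi_b: RoiPolygon, rule: ThresholdRule
                  ) -> tuple[float, float, float, float]:
    """Per-plane (node mean, node fraction, parenchyma mean, parenchyma
    fraction), each averaged over the acquired frames."""
    means_a, fracs_a, means_b, fracs_b = [], [], [], []
    for frame in frames:
        img = _validate_gray(frame)
        mask_a = rasterize_roi(roi_a, img.shape)
        mask_b = rasterize_roi(roi_b, img.shape)
        _check_matched_areas(mask_a, mask_b)
        means_a.append(mean_gray(img, mask_a))
        fracs_a.append(area_fraction(img, mask_a, rule))
        means_b.append(mean_gray(img, mask_b))
        fracs_b.append(area_fraction(img, mask_b, rule))
    return (float(np.mean(means_a)), float(np.mean(fracs_a)),
            float(np.mean(means_b)), float(np.mean(fracs_b)))


def compute_profile(images: Mapping[str, Sequence[np.ndarray] | np.ndarray],
                    rois: Mapping[str, RoiPolygon],
                    threshold: ThresholdRule | None = None
                    ) -> VascularizationProfile:
    """Compute the ten-parameter vascularization profile of one nodule.

    Parameters
    ----------
    images
        ``{"longitudinal": [frame, frame], "cross": [frame, frame],
        "total": frame}``.  Each plane may carry one or more frames; the
        per-frame statistics are averaged (parameter averaging, robust to
        frame misalignment).
    rois
        ``{"A_long", "B_long", "A_cross", "B_cross", "total_node",
        "total_parenchyma"}`` mapped to :class:`RoiPolygon`.
    threshold
        Threshold rule, resolved independently per analyzed region.
        Defaults to ISODATA.

    Undefined quotients (zero parenchyma denominator) are NaN.
    """
    rule = threshold if threshold is not None else ThresholdRule.isodata()
    missing = [k for k in ("longitudinal", "cross", "total") if k not in images]
    if missing:
        raise ValueError(f"missing image plane(s): {', '.join(missing)}")
    missing = [k for k in ("A_long", "B_long", "A_cross", "B_cross",
                           "total_node", "total_parenchyma") if k not in rois]
    if missing:
        raise ValueError(f"missing ROI(s): {', '.join(missing)}")

    def frames_of(key: str) -> list[np.ndarray]:
        val = images[key]
        if isinstance(val, np.ndarray):
            return [val]
        frames = list(val)
        if not frames:
            raise ValueError(f"no frames supplied for plane {key!r}")
        return frames

    mean_l, frac_l, mean_lb, frac_lb = _plane_values(
        frames_of("longitudinal"), rois["A_long"], rois["B_long"], rule)
    mean_c, frac_c, mean_cb, frac_cb = _plane_values(
        frames_of("cross"), rois["A_cross"], rois["B_cross"], rule)

    total = frames_of("total")
    mean_tn, frac_tn, mean_tp, frac_tp = _plane_values(
        total, rois["total_node"], rois["total_parenchyma"], rule)

    return VascularizationProfile(
        roi_longitudinal=mean_l,
        roi_longitudinal_area_fraction=frac_l,
        roi_cross=mean_c,
        roi_cross_area_fraction=frac_c,
        quotient_longitudinal=quotient(mean_l, mean_lb),
        quotient_longitudinal_area_fraction=quotient(frac_l, frac_lb),
        quotient_cross=quotient(mean_c, mean_cb),
        quotient_cross_area_fraction=quotient(frac_c, frac_cb),
        quotient_all=quotient(mean_tn, mean_tp),
        quotient_all_area_fraction=quotient(frac_tn, frac_tp),
    )
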