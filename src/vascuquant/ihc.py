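"""CD34 immunohistochemistry quantification by stain unmixing.

Brightfield micrographs of CD34-stained thyroid sections carry two chromogens:
haematoxylin (blue nuclei) and Fast Red (pink, marking CD34-positive vascular
endothelium).  Because stain contributions add linearly in optical-density
space (Beer-Lambert), the per-pixel RGB optical densities can be unmixed into
per-stain concentration images by solving a small least-squares system.  The
CD34-positive area fraction of a calibrated sampling rectangle — the fraction
of pixels whose Fast-Red concentration exceeds a positivity threshold — is the
microscopic measure of vascularization.

The study protocol samples four rectangles at 100x magnification and one at
25x; the 100x fractions are averaged (*CD34 100 fold*), the 25x rectangle
gives *CD34 25 fold*, and their mean is *CD34 all*.  The standard rectangle is
1440 x 1443 px = 2,077,920 px, corresponding to 1 mm^2 at 100x and 16 mm^2 at
25x.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np

__all__ = [
    "StainMatrix",
    "SamplingRect",
    "Cd34Profile",
    "STANDARD_RECT_PIXELS",
    "rgb_to_od",
    "od_to_rgb",
    "unmix",
    "compose",
    "cd34_fraction",
    "cd34_summary",
    "physical_area",
]

#: pixel count of the standard sampling rectangle (1440 x 1443)
STANDARD_RECT_PIXELS = 1440 * 1443

# Published normalized OD vectors (R, G, B): haematoxylin after Ruifrok &
# Johnston; Fast Red from the Fiji colour-deconvolution vector set.
_HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
_FAST_RED_OD = (0.21393921, 0.85112669, 0.47794022)


class StainConfigurationError(ValueError):
    """Stain vectors are collinear or otherwise unusable."""


@dataclass(frozen=True)
class StainMatrix:
    """Unit-norm stain OD vectors in RGB space, one column per stain.

    Defaults to haematoxylin + Fast Red, the two chromogens of a CD34/ABC
    Fast-Red protocol.  Real-slide vectors vary with staining batch and camera;
    override them per study when calibration images are available.
    """

    hematoxylin: tuple[float, float, float] = _HEMATOXYLIN_OD
    fast_red: tuple[float, float, float] = _FAST_RED_OD

    def __post_init__(self) -> None:
        m = self.matrix
        norms = np.linalg.norm(m, axis=0)
        if np.any(norms <= 0):
            raise StainConfigurationError("zero-norm stain vector")
        if not np.allclose(norms, 1.0, atol=1e-6):
            # normalize silently only if close; otherwise require explicit norm
            object.__setattr__(self, "hematoxylin",
                               tuple(np.asarray(self.hematoxylin) / norms[0]))
            object.__setattr__(self, "fast_red",
                               tuple(np.asarray(self.fast_red) / norms[1]))
            m = self.matrix
        cosang = float(np.dot(m[:, 0], m[:, 1]))
        if abs(cosang) > 1.0 - 1e-8:
            raise StainConfigurationError("stain vectors are collinear")

    @property
    def matrix(self) -> np.ndarray:
        """3x2 array with stains as columns (haematoxylin, fast_red)."""
        return np.column_stack([np.asarray(self.hematoxylin, dtype=float),
                                np.asarray(self.fast_red, dtype=float)])

    @property
    def names(self) -> tuple[str, str]:
        return ("hematoxylin", "fast_red")


@dataclass(frozen=True)
class SamplingRect:
    """A calibrated sampling rectangle within a micrograph.

    The default size is the study standard of 1440 (wide) x 1443 (high)
    pixels; its physical area is 1 mm^2 at 100x magnification and 16 mm^2 at
    25x (area scales with the square of the magnification ratio).
    """

    top_left: tuple[int, int] = (0, 0)
    height_px: int = 1443
    width_px: int = 1440
    magnification: str = "x100"

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("sampling rectangle must have positive size")
        if not self.magnification.startswith("x"):
            raise StainConfigurationError(
                f"unknown magnification {self.magnification!r}")

    @property
    def pixel_count(self) -> int:
        return self.height_px * self.width_px

    def slices(self) -> tuple[slice, slice]:
        r, c = self.top_left
        return slice(r, r + self.height_px), slice(c, c + self.width_px)


def physical_area(rect: SamplingRect) -> float:
    """Physical area of *rect* in mm^2.

    Calibration: the standard 2,077,920-pixel rectangle covers 1 mm^2 at 100x;
    area scales as (100 / magnification)^2 and linearly with pixel count.
    """
    try:
        mag = float(rect.magnification.lstrip("x"))
    except ValueError as exc:
        raise StainConfigurationError(
            f"unknown magnification {rect.magnification!r}") from exc
    if mag <= 0:
        raise StainConfigurationError(
            f"unknown magnification {rect.magnification!r}")
    return (100.0 / mag) ** 2 * rect.pixel_count / STANDARD_RECT_PIXELS


@dataclass(frozen=True)
class Cd34Profile:
    """The three per-nodule CD34 area-fraction summaries."""

    cd34_100_fold: float
    cd34_25_fold: float
    cd34_all: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{f.name}={v} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def rgb_to_od(image: np.ndarray, white_level: int = 255) -> np.ndarray:
    """Beer-Lambert transform of an RGB image to optical densities.

    ``od = -log10(max(I, 1) / white_level)`` per channel; white maps to OD 0
    and the OD is monotone decreasing in intensity.  Zero intensities are
    clamped to 1 before the log, so the transform never diverges.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    if img.min() < 0 or img.max() > white_level:
        raise ValueError(f"pixel values must lie in [0, {white_level}]")
    return -np.log10(np.maximum(img, 1.0) / float(white_level))


def od_to_rgb(od: np.ndarray, white_level: int = 255) -> np.ndarray:
    """Inverse Beer-Lambert map: OD -> float RGB in [0, white_level]."""
    od = np.asarray(od, dtype=np.float64)
    return np.clip(float(white_level) * 10.0 ** (-od), 0.0, float(white_level))


def compose(concentrations: np.ndarray, stains: StainMatrix,
            white_level: int = 255) -> np.ndarray:
    """Forward map: per-pixel stain concentrations -> float RGB image.

    ``concentrations`` is HxWxS with one channel per stain column.  The result
    is continuous-valued; quantize to uint8 only when writing image files.
    """
    conc = np.asarray(concentrations, dtype=np.float64)
    m = stains.matrix
    if conc.ndim != 3 or conc.shape[2] != m.shape[1]:
        raise ValueError(f"expected HxWx{m.shape[1]} concentration stack")
    od = conc @ m.T
    return od_to_rgb(od, white_level)


def unmix(od_image: np.ndarray, stains: StainMatrix) -> np.ndarray:
    """Least-squares two-stain unmixing of an OD image.

    Solves ``M c = od`` per pixel for the stain-concentration vector ``c``
    (M the 3xS stain matrix), then clips negative components to zero.  Returns
    an HxWxS stack ordered (haematoxylin, fast_red).
    """
    od = np.asarray(od_image, dtype=np.float64)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError("expected an HxWx3 optical-density image")
    m = stains.matrix
    # normal-equations pseudo-inverse; M is tall (3x2) and well-conditioned
    pinv = np.linalg.pinv(m)
    conc = od @ pinv.T
    return np.clip(conc, 0.0, None)


def cd34_fraction(fastred_concentration: np.ndarray, rect: SamplingRect,
                  positive_threshold: float = 0.15) -> float:
    """Fraction of rectangle pixels whose Fast-Red concentration is at or
    above *positive_threshold*.

    The denominator is the rectangle pixel count (2,077,920 for the standard
    rectangle).
    """
    img = np.asarray(fastred_concentration, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D Fast-Red concentration image")
    r, c = rect.top_left
    if r < 0 or c < 0 or r + rect.height_px > img.shape[0] \
            or c + rect.width_px > img.shape[1]:
        raise ValueError(
            f"sampling rectangle {rect.top_left}+"
            f"{rect.height_px}x{rect.width_px} exceeds image {img.shape}")
    sub = img[rect.slices()]
    return float(np.count_nonzero(sub >= positive_threshold)) / rect.pixel_count


def cd34_summary(field_fractions_100x: Sequence[float],
                 fraction_25x: float) -> Cd34Profile:
    """Summarise the four 100x field fractions and the 25x fraction.

    ``cd34_100_fold`` is the mean of the four 100x fields; ``cd34_all`` is the
    mean of ``cd34_100_fold`` and the 25x fraction.
    """
    fields_ = [float(v) for v in field_fractions_100x]
    if len(fields_) != 4:
        raise ValueError(f"expected exactly four 100x field fractions, "
                         f"got {len(fields_)}")
    for v in fields_ + [float(fraction_25x)]:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"fraction {v} outside [0, 1]")
    f100 = float(np.mean(fields_))
    f25 = float(fraction_25x)
    return Cd34Profile(cd34_100_fold=f100, cd34_25_fold=f25,
                       cd34_all=(f100 + f25) / 2.0)
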