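"""Synthetic sonograms, histology images and cohorts with known ground truth.

No raw study images are publicly deposited, so every downstream stage is
exercised on generated data whose ground truth is known exactly:

* **SMI scenes** — speckled 8-bit grayscale frames in which flow-positive
  vessel pixels (brighter than background, as in monochrome SMI) are planted
  inside the node and parenchyma polygons as curvilinear random-walk strokes
  until an exact target pixel count is reached.  The planted masks are
  returned as per-pixel ground truth.
* **IHC scenes** — brightfield RGB micrographs composed by the Beer-Lambert
  forward map from per-pixel haematoxylin/Fast-Red concentrations: vessel-mask
  pixels carry Fast-Red optical density, nucleus disks carry haematoxylin.
  The realized vessel fraction is reported exactly.
* **Cohorts** — paired (vascularization quotient, CD34 fraction) outcomes per
  patient, coupled through a Gaussian copula whose correlation is
  sin-transformed so the *Spearman* coefficient is the targeted quantity,
  with benign/malignant group shifts on the scale of the study's summaries.

Every generator is deterministic for a fixed seed: all randomness flows from
one ``numpy`` Generator per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from skimage.morphology import disk

from .ihc import STANDARD_RECT_PIXELS, StainMatrix, compose
from .roi import GeometryError, RoiPolygon, rasterize_roi
from .records import CohortRecord

__all__ = [
    "SmiSceneSpec",
    "IhcSceneSpec",
    "CohortSpec",
    "generate_smi_scene",
    "generate_ihc_scene",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# vessel planting

def _stroke_offsets(width: int) -> np.ndarray:
    """(row, col) offsets of the stamp disk for a stroke of given width."""
    radius = max(0, width // 2)
    d = disk(radius)
    rr, cc = np.nonzero(d)
    return np.column_stack([rr - radius, cc - radius])


def _plant_strokes(rng: np.random.Generator, allowed: np.ndarray,
                   target: int, width: int = 3,
                   max_steps: int = 60) -> np.ndarray:
    """Plant curvilinear strokes inside ``allowed`` until exactly *target*
    pixels are marked.

    Strokes are random walks with direction jitter, stamped with a disk of
    the given width; pixels outside ``allowed`` are never marked.  If strokes
    stall (dense fill), the remainder is completed pixel-wise so the realized
    count is always exact.
    """
    mask = np.zeros_like(allowed, dtype=bool)
    n_allowed = int(allowed.sum())
    target = int(target)
    if target <= 0:
        return mask
    if target >= n_allowed:
        return allowed.copy()
    h, w = allowed.shape
    rows, cols = np.nonzero(allowed)
    offsets = _stroke_offsets(width)
    count = 0
    stalled = 0
    while count < target and stalled < 50:
        start = int(rng.integers(len(rows)))
        r, c = float(rows[start]), float(cols[start])
        theta = float(rng.uniform(0.0, 2.0 * math.pi))
        added_this_stroke = 0
        for _ in range(max_steps):
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < h and 0 <= ci < w) or not allowed[ri, ci]:
                break
            pts = offsets + (ri, ci)
            ok = ((pts[:, 0] >= 0) & (pts[:, 0] < h)
                  & (pts[:, 1] >= 0) & (pts[:, 1] < w))
            pts = pts[ok]
            fresh = pts[allowed[pts[:, 0], pts[:, 1]]
                        & ~mask[pts[:, 0], pts[:, 1]]]
            room = target - count
            if len(fresh) > room:
                fresh = fresh[:room]
            mask[fresh[:, 0], fresh[:, 1]] = True
            count += len(fresh)
            added_this_stroke += len(fresh)
            if count >= target:
                break
            theta += float(rng.normal(0.0, 0.35))
            r += math.sin(theta)
            c += math.cos(theta)
        stalled = stalled + 1 if added_this_stroke == 0 else 0
    if count < target:
        # dense fill: complete with randomly ordered leftover pixels
        leftover = np.flatnonzero(allowed.ravel() & ~mask.ravel())
        pick = rng.permutation(leftover)[: target - count]
        mask.ravel()[pick] = True
    return mask


# ---------------------------------------------------------------------------
# SMI scenes

@dataclass(frozen=True)
class SmiSceneSpec:
    """Parameters of one synthetic monochrome SMI frame.

    ``node_vessel_fraction`` / ``parenchyma_vessel_fraction`` are the target
    fractions of flow-positive pixels inside the respective polygon; the
    realized count is exact to one pixel (the placement quantum).  Background
    speckle is Gaussian with ``speckle_sd``, truncated to [0, 255].
    """

    image_height_px: int
    image_width_px: int
    node_polygon: RoiPolygon
    parenchyma_polygon: RoiPolygon
    node_vessel_fraction: float = 0.3
    parenchyma_vessel_fraction: float = 0.3
    vessel_intensity_mean: float = 180.0
    background_intensity_mean: float = 30.0
    speckle_sd: float = 8.0
    vessel_width_px: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        for name in ("node_vessel_fraction", "parenchyma_vessel_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0.0 < self.vessel_intensity_mean <= 255.0):
            raise ValueError("vessel_intensity_mean outside (0, 255]")
        if not (0.0 <= self.background_intensity_mean < 255.0):
            raise ValueError("background_intensity_mean outside [0, 255)")
        if self.vessel_intensity_mean <= self.background_intensity_mean:
            raise ValueError("flow signal must be brighter than background")
        if self.speckle_sd < 0:
            raise ValueError("speckle_sd must be >= 0")


def generate_smi_scene(spec: SmiSceneSpec
                       ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Render one SMI frame; returns ``(image, ground_truth)``.

    ``ground_truth`` carries the exact planted masks under
    ``node_vessel_mask`` and ``parenchyma_vessel_mask``.  Raises
    :class:`GeometryError` when a polygon leaves the image or the two
    polygons overlap.
    """
    shape = (spec.image_height_px, spec.image_width_px)
    node_mask = rasterize_roi(spec.node_polygon, shape)
    par_mask = rasterize_roi(spec.parenchyma_polygon, shape)
    if (node_mask & par_mask).any():
        raise GeometryError("node and parenchyma polygons overlap")

    rng = np.random.default_rng(spec.seed)
    node_target = int(round(spec.node_vessel_fraction * node_mask.sum()))
    par_target = int(round(spec.parenchyma_vessel_fraction * par_mask.sum()))
    node_vessels = _plant_strokes(rng, node_mask, node_target,
                                  spec.vessel_width_px)
    par_vessels = _plant_strokes(rng, par_mask, par_target,
                                 spec.vessel_width_px)

    image = rng.normal(spec.background_intensity_mean, spec.speckle_sd, shape)
    vessels = node_vessels | par_vessels
    image[vessels] = rng.normal(spec.vessel_intensity_mean, spec.speckle_sd,
                                int(vessels.sum()))
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return image, {"node_vessel_mask": node_vessels,
                   "parenchyma_vessel_mask": par_vessels}


# ---------------------------------------------------------------------------
# IHC scenes

@dataclass(frozen=True)
class IhcSceneSpec:
    """Parameters of one synthetic CD34 brightfield micrograph.

    Vessel-mask pixels receive ``fastred_od_level`` of Fast-Red concentration;
    nucleus disks (``nucleus_density`` per mm^2, with the pixel/mm calibration
    implied by the magnification) receive ``hematoxylin_od_level``.  RGB is
    the Beer-Lambert forward map of the summed optical densities plus
    Gaussian OD noise.
    """

    image_height_px: int = 256
    image_width_px: int = 256
    vessel_mask_fraction: float = 0.05
    nucleus_density: float = 2000.0
    hematoxylin_od_level: float = 0.6
    fastred_od_level: float = 0.8
    stain_matrix: StainMatrix = field(default_factory=StainMatrix)
    noise_od_sd: float = 0.0
    magnification: str = "x100"
    vessel_width_px: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.vessel_mask_fraction <= 1.0):
            raise ValueError("vessel_mask_fraction outside [0, 1]")
        if self.nucleus_density < 0 or self.noise_od_sd < 0:
            raise ValueError("densities and noise sd must be >= 0")
        if self.hematoxylin_od_level < 0 or self.fastred_od_level < 0:
            raise ValueError("OD levels must be >= 0")
        if self.magnification not in ("x25", "x100"):
            raise ValueError(f"unknown magnification {self.magnification!r}")


def _image_area_mm2(spec: IhcSceneSpec) -> float:
    mag = float(spec.magnification.lstrip("x"))
    n_px = spec.image_height_px * spec.image_width_px
    return (100.0 / mag) ** 2 * n_px / STANDARD_RECT_PIXELS


def generate_ihc_scene(spec: IhcSceneSpec
                       ) -> tuple[np.ndarray, dict[str, object]]:
    """Render one IHC micrograph; returns ``(rgb_image, ground_truth)``.

    The RGB image is continuous-valued in [0, 255] (quantize only when
    writing files, so stain round-trips stay exact).  ``ground_truth`` holds
    the exact ``vessel_mask``, the realized ``true_fraction`` and the
    per-pixel ``concentrations`` stack fed to the forward map.
    """
    shape = (spec.image_height_px, spec.image_width_px)
    rng = np.random.default_rng(spec.seed)

    allowed = np.ones(shape, dtype=bool)
    target = int(round(spec.vessel_mask_fraction * allowed.size))
    vessel_mask = _plant_strokes(rng, allowed, target, spec.vessel_width_px,
                                 max_steps=100)

    # nuclei: disks at a radius matching ~7 um at the pixel pitch in use
    mag = float(spec.magnification.lstrip("x"))
    nucleus_radius = max(1, int(round(5 * mag / 100.0)))
    n_nuclei = int(round(spec.nucleus_density * _image_area_mm2(spec)))
    nucleus_mask = np.zeros(shape, dtype=bool)
    if n_nuclei > 0:
        centers_r = rng.integers(0, shape[0], n_nuclei)
        centers_c = rng.integers(0, shape[1], n_nuclei)
        stamp = disk(nucleus_radius)
        rr, cc = np.nonzero(stamp)
        rr, cc = rr - nucleus_radius, cc - nucleus_radius
        for r0, c0 in zip(centers_r, centers_c):
            pr, pc = rr + int(r0), cc + int(c0)
            ok = (pr >= 0) & (pr < shape[0]) & (pc >= 0) & (pc < shape[1])
            nucleus_mask[pr[ok], pc[ok]] = True

    conc = np.zeros(shape + (2,), dtype=np.float64)
    conc[..., 0][nucleus_mask] = spec.hematoxylin_od_level
    conc[..., 1][vessel_mask] = spec.fastred_od_level

    od = conc @ spec.stain_matrix.matrix.T
    if spec.noise_od_sd > 0:
        od = np.clip(od + rng.normal(0.0, spec.noise_od_sd, od.shape), 0.0, None)
    rgb = np.clip(255.0 * 10.0 ** (-od), 0.0, 255.0)
    true_fraction = float(vessel_mask.sum()) / vessel_mask.size
    return rgb, {"vessel_mask": vessel_mask, "true_fraction": true_fraction,
                 "concentrations": conc}


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic benign/malignant cohort.

    Outcome marginals: the vascularization quotient follows a Gamma
    distribution (positive support) and the CD34 fraction a Beta distribution
    (support [0, 1]), each moment-matched to the group mean/SD.  The two
    outcomes are coupled by a Gaussian copula whose latent Pearson
    correlation is ``2 sin(pi * rho / 6)``, so ``latent_spearman_rho`` is the
    *population Spearman* coefficient of the pair.  Defaults mirror the
    study's group summaries (quotient 0.88 +/- 0.89 benign vs 1.13 +/- 0.19
    malignant; CD34 0.05 +/- 0.05 vs 0.08 +/- 0.06) and cohort covariates
    (age 39.75 +/- 12.74 y, BMI 26.08 +/- 5.18 kg/m^2, nodule length
    27.92 mm benign / 35 mm malignant).
    """

    n_benign: int = 13
    n_malignant: int = 3
    latent_spearman_rho: float = 0.556
    benign_quotient_mean: float = 0.88
    benign_quotient_sd: float = 0.89
    malignant_quotient_mean: float = 1.13
    malignant_quotient_sd: float = 0.19
    benign_cd34_mean: float = 0.05
    benign_cd34_sd: float = 0.05
    malignant_cd34_mean: float = 0.08
    malignant_cd34_sd: float = 0.06
    age_mean: float = 39.75
    age_sd: float = 12.74
    bmi_mean: float = 26.08
    bmi_sd: float = 5.18
    benign_length_mean: float = 27.92
    malignant_length_mean: float = 35.0
    length_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benign < 0 or self.n_malignant < 0:
            raise ValueError("group sizes must be >= 0")
        if self.n_benign + self.n_malignant < 2:
            raise ValueError("cohort needs at least 2 records")
        if abs(self.latent_spearman_rho) > 1.0:
            raise ValueError("latent_spearman_rho outside [-1, 1]")


def _gamma_ppf(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    if sd <= 0:
        return np.full_like(u, mean)
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return sps.gamma.ppf(u, a=shape, scale=scale)


def _beta_ppf(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    if sd <= 0:
        return np.full_like(u, mean)
    var = sd ** 2
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible Beta moments: mean {mean}, sd {sd}")
    nu = mean * (1.0 - mean) / var - 1.0
    return sps.beta.ppf(u, a=mean * nu, b=(1.0 - mean) * nu)


def generate_cohort(spec: CohortSpec) -> list[CohortRecord]:
    """Draw one synthetic cohort of paired SMI/CD34 outcomes.

    The Gaussian copula is rank-preserving, so monotone marginal transforms
    leave the Spearman correlation at its latent target; with
    ``latent_spearman_rho = 1`` the two outcome rank orders are identical.
    """
    rng = np.random.default_rng(spec.seed)
    rho_z = 2.0 * math.sin(math.pi * spec.latent_spearman_rho / 6.0)
    records: list[CohortRecord] = []
    pid = 0
    for label, n, qm, qs, cm, cs, lm in (
            ("benign", spec.n_benign, spec.benign_quotient_mean,
             spec.benign_quotient_sd, spec.benign_cd34_mean,
             spec.benign_cd34_sd, spec.benign_length_mean),
            ("malignant", spec.n_malignant, spec.malignant_quotient_mean,
             spec.malignant_quotient_sd, spec.malignant_cd34_mean,
             spec.malignant_cd34_sd, spec.malignant_length_mean)):
        if n == 0:
            continue
        z1 = rng.standard_normal(n)
        z2 = rho_z * z1 + math.sqrt(max(0.0, 1.0 - rho_z ** 2)) \
            * rng.standard_normal(n)
        u1 = sps.norm.cdf(z1)
        u2 = sps.norm.cdf(z2)
        quotients = _gamma_ppf(u1, qm, qs)
        cd34 = _beta_ppf(u2, cm, cs)
        ages = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18.0, None)
        bmis = np.clip(rng.normal(spec.bmi_mean, spec.bmi_sd, n), 12.0, None)
        lengths = np.clip(rng.normal(lm, spec.length_sd, n), 1.0, None)
        for i in range(n):
            pid += 1
            records.append(CohortRecord(
                patient_id=f"P{pid:03d}", label=label,
                age=float(ages[i]), bmi=float(bmis[i]),
                length_mm=float(lengths[i]),
                quotient=float(quotients[i]),
                cd34_fraction=float(cd34[i])))
    return records
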